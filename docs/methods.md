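# Methods

This note documents the models, algorithms and numerical choices behind
`pbodyquant`, what the synthetic generators do and do not emulate, and the
design decisions taken where the procedure left room.

## Synthetic micrographs

A field of view is a stack of 2-D channels (default 1,024 × 1,024 px,
single confocal plane): a membrane channel plus one or more granule
channels. Germ cells are modelled as non-overlapping discs placed by
rejection sampling, with radii drawn from a normal distribution (default
45 ± 5 px, clipped away from degeneracy) and a soft-edged annulus of width
`membrane_width` (default 4 px) rendered at each boundary. Granule counts
per cell are Poisson with channel-specific means (default 6); each granule
is an isotropic 2-D Gaussian of scale `granule_sigma` (default 1.5 px)
placed uniformly, strictly inside the cell and at least 5σ from its
neighbours so that detection, not rendering, limits resolvability (the
separation is relaxed stepwise down to 2 px in crowded cells rather than
failing). Noise is i.i.d. Gaussian, added to a constant background and
clipped at zero.

Co-localization is defined at generation time: per cell, exactly
`round(coloc_fraction · n_A)` channel-A granules are placed at the position
of a distinct channel-B granule with ±1 px uniform jitter per axis, and the
pairing is recorded mutually in the ground truth. This matches the
detection-side criterion (centroid distance) by construction.

Not modelled, deliberately: the point-spread function, 3-D stacks, spectral
bleed-through, uneven illumination, and shot (Poisson) noise. Passing
recovery tests therefore demonstrates correctness of the operators under
the stated geometric and noise model, not robustness to those optical
effects.

The expression-study generator plants `n_planted_targets` probes (default
19 of 5,000) carrying all three selection effects — fold-down in induced
XX (default 3×), fold-up in knockout XY (default 4×), IP/input enrichment
(default 8×) — on a log-normal baseline (log2 mean 8, SD 2), with
multiplicative log2-normal noise per entry (default SD 0.15) and two
replicate arrays per sample, matching the duplicate-hybridisation design.
Configured effects must clear the selection thresholds (1.5×, 2×, 4×) so
that noiseless recovery is exact by construction; with noise they degrade
gracefully.

Amplification curves are four-parameter logistics,
`baseline + (plateau − baseline)·σ(slope·(c − midpoint))`, sampled at
integer cycles (default 40) with optional Gaussian noise. Midpoints can be
derived from true relative abundances assuming perfect per-cycle doubling:
`midpoint = base_midpoint − log2(abundance)`.

All three generators are driven by a single `numpy` `Generator` seeded
from the config; identical config + seed gives bit-identical output.

## Germ-cell segmentation

The chain is Gaussian blur (σ default 2 px, reflective boundary) → local
thresholding → skeletonization → hole filling → shape filtering.

*Local threshold*: a pixel is membrane iff it exceeds the mean of its
square window (radius default 25 px) by more than `threshold_offset`
(default 20 intensity units). The window-mean statistic makes the
constant-image case well defined and renders segmentation invariant to
adding a constant to the channel.

*Region definition*: the thresholded membrane is reduced to 1-px-wide
boundaries (skeletonization), and candidate cells are the connected
components of the complement that do not touch the image border — i.e. the
holes of the boundary network, filled. The complement is labelled with
4-connectivity so that the 8-connected skeleton actually separates inside
from outside. Border-touching regions are discarded because partial cells
would bias per-cell counts.

*Filters*: area within `[min_area, max_area]` (defaults 300–50,000 px²)
and boundary-radius regularity. The radius profile is the Euclidean
distance from the region centroid to each boundary pixel; by default the
filter is scale-free — SD/mean ≤ `max_radius_sd_ratio` (default 0.15,
digital discs score < 0.05, a 40 × 4 px bar scores > 0.3) — with an
absolute-SD variant available via `max_radius_sd_px`. Labels are
re-assigned consecutively after filtering.

On the generator's default scenes with noise at 10% of membrane intensity,
these defaults recover ≥ 90% of cells (centroid error < 5 px) with ≤ 5%
spurious labels; the acceptance script measures this on five 1,024 px
scenes of 20 cells.

## Granule detection and co-localization

The detector band-passes each channel with a difference of Gaussians
(σ 1 and 3 px by default, bracketing the rendered granule scale), applies
an absolute response threshold, and keeps 8-connected components with area
in `[min_size, max_size]` (defaults 5–200 px). Centroids are
response-weighted. When no threshold is configured it is derived per image
as 3 × a robust background SD (1.4826 × MAD of the response), falling back
to 10% of the peak response on noiseless images where the MAD is zero. The
`min_size` of 5 px suppresses the 2–3-px clusters that smoothed noise
produces above 3σ. One parameter set serves all granule channels unless
overridden, since one procedure was used for all stains.

Granules are assigned to the cell label under their centroid; granules on
background are dropped and tallied. Co-localization between channels A and
B is one-to-one greedy matching by ascending centroid distance with cutoff
`coloc_max_distance` (default 2.5 px, comfortably above the √2 px
generation jitter); the per-cell fraction is (matched A granules)/(A
granules in the cell). Cells with no A granules carry an undefined (NaN)
fraction and are excluded from pooled distributions rather than counted as
zeros, which would add an atom at 0 unrelated to co-localization. A
pixel-overlap criterion was considered and rejected as threshold-dependent;
centroid matching is robust to area changes under re-thresholding.

## Expression preprocessing and target selection

Raw probe × sample intensities are floored at 1, each column rescaled so
its 75th percentile equals the geometric mean of the per-column 75th
percentiles (the geometric mean keeps the common scale symmetric in the
samples), then log2-transformed. Fold changes are differences of
replicate-mean log2 signals. Note one consequence: when planted probes
shift a column's 75th percentile, measured fold changes move by a few
hundredths of a log2 unit relative to the planted effect — the selection
thresholds leave ample margin.

IP enrichment per probe is the replicate-mean log2 IP − input difference;
its p-value is a pooled-variance two-tailed Student's t on the log2
replicate signals (2 vs 2 by default), consistent with the t-tests used
elsewhere in the analysis. Zero-variance probes resolve by convention
(equal means → p = 1; separated constants → p = 0, flagged) so sparse
noiseless data do not abort.

Selection intersects three flags: log2FC ≤ −log2 1.5 in induced XX,
log2FC ≥ log2 2 in knockout XY, and log2 enrichment ≥ log2 4 with
p < 0.05. Comparisons are closed (≥/≤) by default so exact planted effects
sit on the boundary without floating-point knife edges; a `strict` switch
gives the strict reading of "more than n-fold". Probe universes must match
exactly across the three inputs; mismatches raise with offending ids
rather than silently intersecting. All seven Venn region counts are
reported, and two-set overlaps are summarised as |A|, |B|, |A∩B| and
100·|A∩B|/|A| to one decimal (undefined when |A| = 0).

RIP-qPCR-style enrichment tables normalize (IP/input) ratios against a
reference transcript on the linear scale, so the reference's normalized
ratio is 1 and global rescaling of either matrix cancels. The
association-vs-expression correlation uses the package's own Pearson
implementation on log2-scale inputs (the log scale keeps the x-axis
symmetric around no change).

## qPCR

The second-derivative-maximum Ct interpolates the (optionally
moving-average-smoothed) curve with a quintic spline, evaluates its second
derivative on a dense grid (40 points per cycle) and refines the maximum
by bounded scalar minimisation. A quintic, rather than cubic, interpolant
is used because a cubic spline's second derivative is piecewise linear and
its argmax collapses onto the knots, losing sub-cycle resolution. On a
noiseless unit-slope logistic the result matches the closed form — the
second derivative of `σ(x)` peaks where `σ = (3−√3)/6`, i.e.
`ln(2+√3) ≈ 1.317` cycles before the midpoint — to 0.012 cycles with no
smoothing (the default; the tolerance budget is 0.05). Flat or
overall-decreasing curves raise a "no amplification" error.

ΔΔCt assumes amplification efficiency 2 (the classical assumption of the
method; efficiency correction is out of scope). Replicates are aggregated
as mean Ct before differencing, the convention of the method as cited.
Replicate SDs of gene and normalizer combine in quadrature and are
reported as a fold-dispersion `2^sd`, giving an asymmetric RQ range. The
reference sample's RQ is exactly 1 for every gene, and adding a constant
to all Ct values leaves every RQ unchanged.

## Statistics

All tests are implemented in the package; scipy contributes only
distribution functions (Student's t via the regularized incomplete beta,
the normal, and the studentized range).

* **Student's t** — pooled variance (the named form of the test), with a
  Welch switch. Degenerate zero-variance cases use the conventions above.
* **Mann–Whitney U** — midranks for ties; for pooled n ≤ 12 the p-value is
  exact by enumerating all C(n, n₁) assignments of the pooled values
  (conditioning on the observed tie pattern); larger samples use the
  normal approximation with tie-corrected variance and 0.5 continuity
  correction. The approximation agrees with the exact p to ~0.01 in the
  tails at n = 6 + 6; mid-range p's can differ by slightly more, which is
  inherent to the normal approximation at that size.
* **Pearson** — sample r with the t-transform p, df = n − 2.
* **Steel–Dwass** — for each pair, only those two groups are ranked
  jointly (midranks); the rank-sum is standardized by the exact
  permutation variance (which absorbs tie correction), and √2·|z| is
  referred to the studentized range with k groups and df = ∞. A 0.5
  continuity correction on the rank sum (default on) compensates the
  discreteness of the rank statistic: at k = 3, n = 4 per group the
  uncorrected approximation can deviate from the exact family-wise p by
  ~0.15 in the mid-range, the corrected one stays within ~0.05. A
  permutation mode (pooled relabelling, max-|z|-over-pairs adjustment,
  add-one convention) provides the exact reference; it uses the
  uncorrected statistic on both observed and resampled sides.
* **Permutation oracle** — exhaustive when C(n, n₁) ≤ 10⁵, else seeded
  Monte-Carlo with the add-one convention (p ≥ 1/(reps+1)); two-sided by
  |statistic|.

Under a simulated null (1,000 replicates) the t and Mann–Whitney
rejection rates at α = 0.05 fall within 0.05 ± 0.02, and the Steel–Dwass
family-wise error across three null groups stays below 0.07 (slightly
conservative, as expected with the continuity correction).

## Pipelines and problem sizes

`run_granule_study` and `run_target_selection` drive
simulate-or-load → analyse → test from one config; every output table
carries a `config_hash=… seed=…` provenance line and reruns are
byte-identical. Cells are pooled across images within a condition, as the
original quantification pooled cells across sections and embryos; no
per-embryo random effect is modelled, a simplification the pooled test
inherits.

The test-suite and acceptance problem sizes are chosen to exercise every
claim at desk scale: five 1,024 px scenes of 20 cells for segmentation
recovery, nine 512 px scenes of 8 cells across co-localization fractions
{0, 0.5, 1} for detection recovery, a 5,000-probe noiseless study with 19
planted targets for selection, 40-cycle curves for qPCR, and 10⁵
permutation resamples / 10³ null replicates for the statistics checks.

## Known limitations

* Segmentation assumes closed membrane outlines; heavily broken membranes
  yield no region (no gap-closing morphology is attempted).
* The DoG detector's auto-threshold presumes granule pixels are a small
  minority of the image; dense granule fields would inflate the MAD and
  the threshold with it.
* The ΔΔCt implementation does not correct for amplification efficiency
  ≠ 2, and the Ct caller expects a visible sigmoid within the cycle range.
* The synthetic generators' omissions (PSF, 3-D, illumination, shot
  noise) bound what green tests prove about real micrographs.
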