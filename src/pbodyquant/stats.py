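"""Statistical tests used by the figures, implemented from first principles.

The package implements (rather than wraps) the tests the quantifications
rely on — pooled-variance Student's t, Mann–Whitney U with midranks and
exact small-sample enumeration, Pearson correlation with the t-transform
p-value, and the Steel–Dwass all-pairs nonparametric comparison — plus
permutation oracles used to verify them.  Only distribution functions
(t, normal, studentized range) come from scipy.

Degenerate zero-variance inputs resolve by convention instead of raising:
identical groups give p = 1, perfectly separated constant groups give
p = 0 with a note, so pipelines on sparse synthetic data do not abort.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import special
from scipy import stats as sps

__all__ = [
    "TestResult",
    "student_t_two_tailed",
    "mann_whitney_u",
    "pearson_correlation",
    "steel_dwass",
    "permutation_oracle",
]

_EXACT_MW_MAX_N = 12  # pooled size up to which the U null is enumerated


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    pvalue: float
    group_sizes: tuple[int, ...]
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _clean(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError("observations must be finite")
    return arr


def _t_sf(t: float, df: float) -> float:
    # survival function of Student's t via the regularized incomplete beta
    x = df / (df + t * t)
    p = 0.5 * special.betainc(df / 2.0, 0.5, x)
    return p if t >= 0 else 1.0 - p


def student_t_two_tailed(x, y, welch: bool = False) -> TestResult:
    """Two-sample two-tailed Student's t-test (pooled variance by default).

    ``welch=True`` switches to the unequal-variance form with
    Welch–Satterthwaite degrees of freedom.
    """
    x, y = _clean(x), _clean(y)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    dx = x.mean() - y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    notes: list[str] = []
    if vx == 0.0 and vy == 0.0:
        if dx == 0.0:
            return TestResult("student_t", 0.0, 1.0, (nx, ny), ("degenerate: zero variance, equal means",))
        return TestResult(
            "student_t", math.inf if dx > 0 else -math.inf, 0.0, (nx, ny),
            ("degenerate: zero variance, unequal means",),
        )
    if welch:
        se2x, se2y = vx / nx, vy / ny
        se = math.sqrt(se2x + se2y)
        df = (se2x + se2y) ** 2 / (se2x**2 / (nx - 1) + se2y**2 / (ny - 1))
        notes.append("welch")
    else:
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    t = dx / se
    p = min(1.0, 2.0 * _t_sf(abs(t), df))
    return TestResult("student_t", t, p, (nx, ny), tuple(notes))


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _u_statistic(pooled_ranks: np.ndarray, nx: int) -> float:
    return float(pooled_ranks[:nx].sum() - nx * (nx + 1) / 2.0)


def mann_whitney_u(x, y, method: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney U with midrank ties.

    For pooled sizes ≤ 12 (``method="auto"``) the p-value is exact, by
    enumerating every assignment of the pooled observations to the two
    groups (which conditions on the observed tie pattern).  Larger
    samples use the normal approximation with tie correction and a 0.5
    continuity correction.  ``method`` may force ``"exact"`` or
    ``"asymptotic"``.
    """
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError("method must be auto, exact or asymptotic")
    x, y = _clean(x), _clean(y)
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise ValueError("each group needs at least 1 observation")
    pooled = np.concatenate([x, y])
    n = nx + ny
    ranks = _midranks(pooled)
    u = _u_statistic(ranks, nx)
    mu = nx * ny / 2.0

    if method == "exact" or (method == "auto" and n <= _EXACT_MW_MAX_N):
        dev = abs(u - mu) - 1e-12
        count = total = 0
        for combo in itertools.combinations(range(n), nx):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            u_perm = float(ranks[mask].sum() - nx * (nx + 1) / 2.0)
            total += 1
            if abs(u_perm - mu) >= dev:
                count += 1
        return TestResult("mann_whitney_u", u, count / total, (nx, ny), ("exact",))

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    notes = ["normal approximation"]
    if tie_term:
        notes.append("tie correction applied")
    if var == 0.0:
        return TestResult("mann_whitney_u", u, 1.0, (nx, ny), ("degenerate: all values tied",))
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return TestResult("mann_whitney_u", u, p, (nx, ny), tuple(notes))


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p from the t-transform (df = n−2)."""
    x, y = _clean(x), _clean(y)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    xd, yd = x - x.mean(), y - y.mean()
    sx, sy = math.sqrt((xd**2).sum()), math.sqrt((yd**2).sum())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    r = float((xd * yd).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = min(1.0, 2.0 * _t_sf(abs(t), n - 2))
    return r, p


# ---------------------------------------------------------------------------
# Steel–Dwass all-pairs comparison


def _pairwise_z(xi: np.ndarray, xj: np.ndarray, cc: float = 0.0) -> float:
    """Standardized rank-sum statistic for one pair, midranks + tie-corrected
    variance (the exact permutation variance of the rank sum).  ``cc`` is a
    continuity correction subtracted from |R1 − E| before standardizing."""
    ni, nj = len(xi), len(xj)
    pooled = np.concatenate([xi, xj])
    n = ni + nj
    ranks = _midranks(pooled)
    r1 = ranks[:ni].sum()
    e = ni * (n + 1) / 2.0
    centred = ranks - (n + 1) / 2.0
    var = ni * nj / (n * (n - 1.0)) * float((centred**2).sum())
    if var == 0.0:
        return 0.0
    z = (max(abs(r1 - e) - cc, 0.0)) / math.sqrt(var)
    return float(math.copysign(z, r1 - e))


def _pairwise_z_batch(values: np.ndarray, ni: int) -> np.ndarray:
    """Vectorized `_pairwise_z` over rows of a (reps, ni+nj) value matrix."""
    n = values.shape[1]
    ranks = sps.rankdata(values, axis=1)
    r1 = ranks[:, :ni].sum(axis=1)
    e = ni * (n + 1) / 2.0
    centred = ranks - (n + 1) / 2.0
    var = ni * (n - ni) / (n * (n - 1.0)) * (centred**2).sum(axis=1)
    z = np.zeros(len(values))
    ok = var > 0
    z[ok] = (r1[ok] - e) / np.sqrt(var[ok])
    return z


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float  # standardized rank-sum z for the pair
    pvalue: float
    n_a: int
    n_b: int


def steel_dwass(
    groups: dict[str, Sequence[float]],
    method: str = "asymptotic",
    n_resamples: int = 10_000,
    seed: Optional[int] = None,
    continuity_correction: bool = True,
) -> list[PairwiseComparison]:
    """Steel–Dwass all-pairs nonparametric comparison.

    For each pair of groups only those two groups are ranked jointly
    (midranks for ties) and the standardized rank-sum statistic z is
    computed with the tie-corrected permutation variance.  In the
    classical ``asymptotic`` mode, √2·|z| is referred to the studentized
    range distribution with k = number of groups (df = ∞) for a
    family-wise two-sided p; a 0.5 continuity correction on the rank sum
    (default on) compensates the small-sample discreteness of the rank
    statistic.  ``method="permutation"`` instead permutes the pooled
    observations across all groups and compares each observed |z| with
    the permutation distribution of the maximum |z| over pairs
    (max-over-pairs adjustment, add-one convention); the correction is
    not applied there since observed and resampled statistics are
    compared on the same scale.  The reported ``statistic`` is always
    the uncorrected z.
    """
    names = list(groups)
    k = len(names)
    if k < 3:
        raise ValueError("Steel–Dwass needs at least 3 groups")
    arrays = {name: _clean(groups[name]) for name in names}
    for name, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    pairs = list(itertools.combinations(names, 2))
    z_obs = {
        (a, b): _pairwise_z(arrays[a], arrays[b]) for a, b in pairs
    }

    if method == "asymptotic":
        cc = 0.5 if continuity_correction else 0.0
        results = []
        for a, b in pairs:
            z_cc = _pairwise_z(arrays[a], arrays[b], cc=cc)
            q = math.sqrt(2.0) * abs(z_cc)
            p = float(sps.studentized_range.sf(q, k, np.inf))
            p = min(1.0, max(0.0, p))
            results.append(
                PairwiseComparison(a, b, z_obs[(a, b)], p, len(arrays[a]), len(arrays[b]))
            )
        return results

    if method != "permutation":
        raise ValueError("method must be 'asymptotic' or 'permutation'")

    rng = np.random.default_rng(seed)
    sizes = [len(arrays[name]) for name in names]
    offsets = np.cumsum([0] + sizes)
    pooled = np.concatenate([arrays[name] for name in names])
    n_tot = len(pooled)
    perm_idx = np.argsort(rng.random((n_resamples, n_tot)), axis=1)
    perm_vals = pooled[perm_idx]
    max_abs_z = np.zeros(n_resamples)
    for ia, ib in itertools.combinations(range(k), 2):
        cols = np.concatenate(
            [
                np.arange(offsets[ia], offsets[ia + 1]),
                np.arange(offsets[ib], offsets[ib + 1]),
            ]
        )
        z = _pairwise_z_batch(perm_vals[:, cols], sizes[ia])
        np.maximum(max_abs_z, np.abs(z), out=max_abs_z)

    results = []
    for a, b in pairs:
        z = abs(z_obs[(a, b)])
        p = (1.0 + float((max_abs_z >= z - 1e-12).sum())) / (n_resamples + 1.0)
        results.append(
            PairwiseComparison(a, b, z_obs[(a, b)], min(p, 1.0),
                               len(arrays[a]), len(arrays[b]))
        )
    return results


# ---------------------------------------------------------------------------
# permutation oracle


def permutation_oracle(
    statistic: Callable[[np.ndarray, np.ndarray], float],
    x,
    y,
    n_resamples: Optional[int] = None,
    seed: Optional[int] = None,
    exhaustive_limit: int = 100_000,
) -> float:
    """Two-sided permutation p-value for an arbitrary two-sample statistic.

    Enumerates all C(nx+ny, nx) relabellings when that count is within
    ``exhaustive_limit`` (exact p); otherwise draws ``n_resamples`` seeded
    Monte-Carlo permutations and applies the add-one convention, so the
    returned p lies in [1/(reps+1), 1].  Two-sidedness is by |statistic|.
    """
    x, y = _clean(x), _clean(y)
    nx = len(x)
    pooled = np.concatenate([x, y])
    n = len(pooled)
    t_obs = abs(float(statistic(x, y)))
    n_comb = math.comb(n, nx)

    if n_comb <= exhaustive_limit:
        count = 0
        for combo in itertools.combinations(range(n), nx):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            t = abs(float(statistic(pooled[mask], pooled[~mask])))
            if t >= t_obs - 1e-12:
                count += 1
        return count / n_comb

    if n_resamples is None:
        n_resamples = 10_000
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(pooled)
        t = abs(float(statistic(perm[:nx], perm[nx:])))
        if t >= t_obs - 1e-12:
            count += 1
    return (1.0 + count) / (n_resamples + 1.0)
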