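"""Ground-truthed synthetic inputs: micrographs, expression studies, qPCR curves.

The generators emulate the statistical structure the analysis operators
assume, with every latent quantity (cell positions, granule ownership and
co-localization partners, planted probe effects, logistic curve midpoints)
recorded as ground truth so that recovery can be scored exactly.

Micrographs are single confocal planes: germ cells appear as roughly round
objects outlined by a bright membrane (CDH1-like) channel, and granule
channels carry punctate 2-D Gaussian spots strictly inside cells.  A
configurable fraction of channel-A granules is placed at the position of a
channel-B granule (±1 px jitter), defining co-localization at generation
time by shared centroid — the same criterion the detection side uses.
Noise is i.i.d. Gaussian clipped at zero; point-spread realism, 3-D stacks
and uneven illumination are deliberately not modelled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "MultiChannelImage",
    "SceneConfig",
    "GroundTruth",
    "CellTruth",
    "GranuleTruth",
    "StudyConfig",
    "ExpressionStudy",
    "QpcrConfig",
    "AmplificationCurve",
    "generate_micrograph",
    "generate_expression_study",
    "generate_amplification_curves",
]


class SynthesisError(ValueError):
    """Raised when a scene cannot be realised under its constraints."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class MultiChannelImage:
    """Stacked 2-D intensity grids, one per fluorescence channel.

    ``data`` has shape ``(n_channels, height, width)``; ``channel_names``
    gives the order.  ``pixel_size`` is carried as metadata (µm/px) and is
    not used by any operator, which all work in pixel units.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be (n_channels, H, W) matching channel_names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}")
        return self.data[i]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channel(name)


@dataclass(frozen=True)
class CellTruth:
    id: int
    centroid: tuple[float, float]  # (row, col)
    radius: float


@dataclass(frozen=True)
class GranuleTruth:
    centroid: tuple[float, float]  # (row, col)
    cell_id: int
    partner: Optional[tuple[str, int]] = None  # (channel, index in that channel)


@dataclass
class GroundTruth:
    """Latent scene description used as the oracle for recovery tests."""

    cells: list[CellTruth]
    granules: dict[str, list[GranuleTruth]]

    def granule_count(self, channel: str) -> int:
        return len(self.granules.get(channel, []))

    def per_cell_counts(self, channel: str) -> dict[int, int]:
        counts = {c.id: 0 for c in self.cells}
        for g in self.granules.get(channel, []):
            counts[g.cell_id] += 1
        return counts

    def coloc_fraction(self, channel: str) -> float:
        """Fraction of this channel's granules that have a partner."""
        gs = self.granules.get(channel, [])
        if not gs:
            return float("nan")
        return sum(g.partner is not None for g in gs) / len(gs)

    def validate(self) -> None:
        ids = [c.id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError("cell ids are not unique")
        idset = set(ids)
        for ch, gs in self.granules.items():
            for i, g in enumerate(gs):
                if g.cell_id not in idset:
                    raise ValueError(f"granule {ch}[{i}] owned by unknown cell {g.cell_id}")
                if g.partner is not None:
                    pch, pi = g.partner
                    back = self.granules[pch][pi].partner
                    if back != (ch, i):
                        raise ValueError(f"co-localization partners not mutual at {ch}[{i}]")

    def to_json(self) -> str:
        return json.dumps(
            {
                "cells": [dataclasses.asdict(c) for c in self.cells],
                "granules": {
                    ch: [dataclasses.asdict(g) for g in gs]
                    for ch, gs in self.granules.items()
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        cells = [
            CellTruth(c["id"], tuple(c["centroid"]), c["radius"]) for c in raw["cells"]
        ]
        granules = {
            ch: [
                GranuleTruth(
                    tuple(g["centroid"]),
                    g["cell_id"],
                    tuple(g["partner"]) if g["partner"] is not None else None,
                )
                for g in gs
            ]
            for ch, gs in raw["granules"].items()
        }
        return cls(cells=cells, granules=granules)


# ---------------------------------------------------------------------------
# micrograph generation


@dataclass
class SceneConfig:
    """Parameters of one synthetic field of view.

    Defaults mirror the acquisition the analysis was built for: 1,024 ×
    1,024 px single planes with ~20 germ cells in view.  Intensities are
    arbitrary units; granule counts per cell are Poisson means.
    ``coloc_fraction`` is the fraction of channel-A granules placed at a
    channel-B granule position (A and B given by ``coloc_channels``).
    """

    image_size: int = 1024
    n_cells: int = 20
    cell_radius_mean: float = 45.0
    cell_radius_sd: float = 5.0
    membrane_width: float = 4.0
    membrane_intensity: float = 200.0
    granule_peak_intensity: float = 150.0
    background_level: float = 10.0
    noise_sd: float = 5.0
    granules_per_cell_by_channel: dict[str, float] = field(
        default_factory=lambda: {"dcp1a": 6.0, "nanos2": 6.0}
    )
    granule_sigma: float = 1.5
    coloc_fraction: float = 0.0
    coloc_channels: tuple[str, str] = ("dcp1a", "nanos2")
    membrane_channel: str = "cdh1"
    seed: int = 0
    max_placement_tries: int = 5000

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        for name in (
            "membrane_intensity",
            "granule_peak_intensity",
            "background_level",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cell_radius_mean <= self.membrane_width:
            raise ValueError("cell radius must exceed membrane_width")
        if any(m < 0 for m in self.granules_per_cell_by_channel.values()):
            raise ValueError("granule means must be >= 0")
        a, b = self.coloc_channels
        if self.coloc_fraction > 0 and (
            a not in self.granules_per_cell_by_channel
            or b not in self.granules_per_cell_by_channel
        ):
            raise ValueError("coloc_channels must be keys of granules_per_cell_by_channel")


def _place_cells(cfg: SceneConfig, rng: np.random.Generator) -> list[CellTruth]:
    """Rejection-sample non-overlapping discs away from the image border."""
    cells: list[CellTruth] = []
    gap = cfg.membrane_width + 2.0  # clearance between membrane rings
    for cid in range(1, cfg.n_cells + 1):
        radius = float(
            np.clip(
                rng.normal(cfg.cell_radius_mean, cfg.cell_radius_sd),
                cfg.membrane_width + 4.0,
                None,
            )
        )
        margin = radius + cfg.membrane_width + 3.0
        if 2 * margin >= cfg.image_size:
            raise SynthesisError(
                f"cell radius {radius:.1f} px does not fit in a "
                f"{cfg.image_size} px image"
            )
        for _ in range(cfg.max_placement_tries):
            r0 = rng.uniform(margin, cfg.image_size - margin)
            c0 = rng.uniform(margin, cfg.image_size - margin)
            ok = all(
                np.hypot(r0 - c.centroid[0], c0 - c.centroid[1])
                >= radius + c.radius + gap
                for c in cells
            )
            if ok:
                cells.append(CellTruth(cid, (r0, c0), radius))
                break
        else:
            raise SynthesisError(
                f"could not place cell {cid} without overlap after "
                f"{cfg.max_placement_tries} tries (n_cells={cfg.n_cells}, "
                f"mean radius {cfg.cell_radius_mean} px, image {cfg.image_size} px)"
            )
    return cells


def _granule_positions_in_cell(
    cell: CellTruth,
    n: int,
    cfg: SceneConfig,
    rng: np.random.Generator,
    min_sep: float,
) -> list[tuple[float, float]]:
    """Uniform positions strictly inside the cell, mutually separated.

    The separation constraint is relaxed stepwise (down to 2 px) when a
    crowded cell cannot accommodate the drawn count at full separation.
    """
    inner = cell.radius - cfg.membrane_width / 2.0 - 3.0 * cfg.granule_sigma
    inner = max(inner, 1.0)
    pts: list[tuple[float, float]] = []
    sep = min_sep
    for _ in range(n):
        while True:
            for _ in range(cfg.max_placement_tries):
                rad = inner * np.sqrt(rng.uniform())
                ang = rng.uniform(0.0, 2.0 * np.pi)
                p = (cell.centroid[0] + rad * np.sin(ang),
                     cell.centroid[1] + rad * np.cos(ang))
                if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= sep for q in pts):
                    pts.append(p)
                    break
            else:
                if sep > 2.0:
                    sep = max(0.7 * sep, 2.0)
                    continue
                raise SynthesisError(
                    f"could not place {n} granules with separation {sep:.1f} px "
                    f"inside a cell of radius {cell.radius:.1f} px"
                )
            break
    return pts


def _render_ring(img: np.ndarray, cell: CellTruth, cfg: SceneConfig) -> None:
    r0, c0 = cell.centroid
    half = cfg.membrane_width / 2.0
    ext = int(np.ceil(cell.radius + half + 2))
    rlo, rhi = int(np.floor(r0)) - ext, int(np.ceil(r0)) + ext + 1
    clo, chi = int(np.floor(c0)) - ext, int(np.ceil(c0)) + ext + 1
    rlo, clo = max(rlo, 0), max(clo, 0)
    rhi, chi = min(rhi, img.shape[0]), min(chi, img.shape[1])
    rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi), indexing="ij")
    dist = np.hypot(rr - r0, cc - c0)
    # soft-edged annulus: full intensity inside the ring, ~1 px roll-off
    prof = np.clip(half + 0.5 - np.abs(dist - cell.radius), 0.0, 1.0)
    np.maximum(img[rlo:rhi, clo:chi], cfg.membrane_intensity * prof,
               out=img[rlo:rhi, clo:chi])


def _render_spot(img: np.ndarray, centroid: tuple[float, float],
                 peak: float, sigma: float) -> None:
    r0, c0 = centroid
    ext = int(np.ceil(4 * sigma)) + 1
    rlo, rhi = int(np.floor(r0)) - ext, int(np.ceil(r0)) + ext + 1
    clo, chi = int(np.floor(c0)) - ext, int(np.ceil(c0)) + ext + 1
    rlo, clo = max(rlo, 0), max(clo, 0)
    rhi, chi = min(rhi, img.shape[0]), min(chi, img.shape[1])
    rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi), indexing="ij")
    img[rlo:rhi, clo:chi] += peak * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2)
    )


def generate_micrograph(cfg: SceneConfig) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one synthetic field of view plus its ground truth.

    The membrane channel contains a bright ring of width ``membrane_width``
    on each cell boundary; granule channels contain Gaussian puncta of
    scale ``granule_sigma`` strictly inside cells.  Exactly
    ``round(coloc_fraction * n_A)`` channel-A granules per cell share a
    centroid (±1 px jitter per axis) with a channel-B granule.  The same
    config and seed give bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cells = _place_cells(cfg, rng)

    ch_a, ch_b = cfg.coloc_channels
    channel_order = list(cfg.granules_per_cell_by_channel)
    granules: dict[str, list[GranuleTruth]] = {ch: [] for ch in channel_order}
    min_sep = max(5.0 * cfg.granule_sigma, 4.0)

    for cell in cells:
        counts = {
            ch: int(rng.poisson(mean))
            for ch, mean in cfg.granules_per_cell_by_channel.items()
        }
        n_coloc = 0
        if cfg.coloc_fraction > 0 and ch_a in counts and ch_b in counts:
            n_coloc = int(round(cfg.coloc_fraction * counts[ch_a]))
            counts[ch_b] = max(counts[ch_b], n_coloc)  # enough partners to pair with

        positions = {
            ch: _granule_positions_in_cell(cell, counts[ch], cfg, rng, min_sep)
            for ch in channel_order
        }
        partner_a: dict[int, int] = {}
        if n_coloc:
            a_idx = rng.choice(counts[ch_a], size=n_coloc, replace=False)
            b_idx = rng.choice(counts[ch_b], size=n_coloc, replace=False)
            for ia, ib in zip(a_idx, b_idx):
                jr, jc = rng.uniform(-1.0, 1.0, size=2)
                br, bc = positions[ch_b][ib]
                positions[ch_a][ia] = (br + jr, bc + jc)
                partner_a[int(ia)] = int(ib)

        for ch in channel_order:
            for i, p in enumerate(positions[ch]):
                # placeholder mark; flat-list indices are linked below
                partner = (ch_b, -1) if (ch == ch_a and i in partner_a) else None
                granules[ch].append(GranuleTruth(p, cell.id, partner))

    granules = _link_partners(granules, ch_a, ch_b)

    names = [cfg.membrane_channel] + channel_order
    stack = np.zeros((len(names), cfg.image_size, cfg.image_size), dtype=float)
    for cell in cells:
        _render_ring(stack[0], cell, cfg)
    for k, ch in enumerate(channel_order, start=1):
        for g in granules[ch]:
            _render_spot(stack[k], g.centroid, cfg.granule_peak_intensity,
                         cfg.granule_sigma)
    stack += cfg.background_level
    if cfg.noise_sd > 0:
        stack += rng.normal(0.0, cfg.noise_sd, size=stack.shape)
    np.clip(stack, 0.0, None, out=stack)

    truth = GroundTruth(cells=cells, granules=granules)
    truth.validate()
    return MultiChannelImage(stack, tuple(names)), truth


def _link_partners(
    granules: dict[str, list[GranuleTruth]],
    ch_a: str,
    ch_b: str,
) -> dict[str, list[GranuleTruth]]:
    """Rebuild mutual partner links by matching shared centroids (≤ √2 px apart)."""
    if ch_a not in granules or ch_b not in granules:
        return granules
    a_list = granules[ch_a]
    b_list = granules[ch_b]
    new_a = [GranuleTruth(g.centroid, g.cell_id, None) for g in a_list]
    new_b = [GranuleTruth(g.centroid, g.cell_id, None) for g in b_list]
    used_b: set[int] = set()
    for ia, ga in enumerate(a_list):
        if ga.partner is None:
            continue
        # nearest unused B granule in the same cell; jitter keeps it within √2 px
        best, best_d = None, np.inf
        for ib, gb in enumerate(b_list):
            if ib in used_b or gb.cell_id != ga.cell_id:
                continue
            d = np.hypot(ga.centroid[0] - gb.centroid[0], ga.centroid[1] - gb.centroid[1])
            if d < best_d:
                best, best_d = ib, d
        if best is None or best_d > 1.5:
            raise SynthesisError("internal: co-localized granule lost its partner")
        used_b.add(best)
        new_a[ia] = GranuleTruth(ga.centroid, ga.cell_id, (ch_b, best))
        new_b[best] = GranuleTruth(b_list[best].centroid, b_list[best].cell_id, (ch_a, ia))
    out = dict(granules)
    out[ch_a] = new_a
    out[ch_b] = new_b
    return out


# ---------------------------------------------------------------------------
# expression study generation


@dataclass
class StudyConfig:
    """Synthetic three-dataset RIP-chip study with planted target probes.

    Planted probes carry all three effects of the Venn selection: reduced
    in gain-of-function XX gonads, increased in knockout XY gonads, and
    enriched in the NANOS2 immunoprecipitate over input.  Effects are
    linear fold changes and must clear the selection thresholds
    (1.5×, 2×, 4×); non-planted probes have no effect in expectation.
    ``noise_sd`` is the SD of multiplicative log2-normal noise per entry.
    Two replicate arrays per sample, as in the original hybridisations.
    """

    n_probes: int = 5000
    n_planted_targets: int = 19
    n_replicates: int = 2
    fold_down_xx: float = 3.0
    fold_up_ko: float = 4.0
    fold_ip_enrichment: float = 8.0
    noise_sd: float = 0.15
    base_log2_mean: float = 8.0
    base_log2_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted_targets > self.n_probes:
            raise ValueError("n_planted_targets cannot exceed n_probes")
        if self.n_probes < 0 or self.n_planted_targets < 0:
            raise ValueError("counts must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate per sample")
        if self.fold_down_xx <= 1.5 or self.fold_up_ko <= 2.0 or self.fold_ip_enrichment <= 4.0:
            raise ValueError(
                "planted effects must exceed the selection thresholds (1.5, 2, 4)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class ExpressionStudy:
    """Three raw signal-matrix pairs plus the planted-target probe ids."""

    datasets: dict[str, "SignalMatrixPair"]
    planted: set[str]


@dataclass
class SignalMatrixPair:
    """One comparison: raw matrix with two named replicate groups."""

    matrix: "pd.DataFrame"
    group_a: list[str]
    group_b: list[str]


_DATASETS = (
    # name, group_a label, group_b label, effect direction on group_a
    ("induced_xx", "induced", "control"),
    ("knockout_xy", "knockout", "het"),
    ("nanos2_rip", "ip", "input"),
)


def generate_expression_study(cfg: StudyConfig) -> ExpressionStudy:
    """Simulate the three probe-level datasets intersected by the Venn selection.

    Returns raw (un-normalised, un-logged) matrices: ``induced_xx``
    (Nanos2-expressing XX vs control XX), ``knockout_xy`` (Nanos2-null XY
    vs heterozygote XY) and ``nanos2_rip`` (NANOS2 IP vs input), each with
    ``n_replicates`` columns per group, plus the set of planted probe ids.
    With ``noise_sd=0`` measured ratios equal the configured effects exactly.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    probes = [f"P{i:05d}" for i in range(cfg.n_probes)]
    planted_idx = rng.choice(cfg.n_probes, size=cfg.n_planted_targets, replace=False) \
        if cfg.n_planted_targets else np.array([], dtype=int)
    planted = {probes[i] for i in planted_idx}

    base = 2.0 ** rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=cfg.n_probes)
    effects = {
        "induced_xx": 1.0 / cfg.fold_down_xx,
        "knockout_xy": cfg.fold_up_ko,
        "nanos2_rip": cfg.fold_ip_enrichment,
    }

    datasets: dict[str, SignalMatrixPair] = {}
    for name, lab_a, lab_b in _DATASETS:
        eff = np.ones(cfg.n_probes)
        if len(planted_idx):
            eff[planted_idx] = effects[name]
        cols: dict[str, np.ndarray] = {}
        for lab, fac in ((lab_a, eff), (lab_b, np.ones(cfg.n_probes))):
            for r in range(1, cfg.n_replicates + 1):
                noise = (
                    2.0 ** rng.normal(0.0, cfg.noise_sd, size=cfg.n_probes)
                    if cfg.noise_sd > 0
                    else 1.0
                )
                cols[f"{lab}_{r}"] = base * fac * noise
        frame = pd.DataFrame(cols, index=pd.Index(probes, name="probe"))
        datasets[name] = SignalMatrixPair(
            matrix=frame,
            group_a=[f"{lab_a}_{r}" for r in range(1, cfg.n_replicates + 1)],
            group_b=[f"{lab_b}_{r}" for r in range(1, cfg.n_replicates + 1)],
        )
    return ExpressionStudy(datasets=datasets, planted=planted)


# ---------------------------------------------------------------------------
# qPCR curve generation


@dataclass(frozen=True)
class AmplificationCurve:
    """One qPCR trace: fluorescence per integer cycle."""

    cycles: np.ndarray
    fluorescence: np.ndarray
    sample: str
    gene: str
    replicate: int = 1
    true_midpoint: Optional[float] = None


@dataclass
class QpcrConfig:
    """Logistic amplification-curve generator.

    Each curve is ``baseline + (plateau - baseline) * logistic(slope * (c -
    midpoint)) + noise``.  Midpoints per (sample, gene) can be given
    directly, or derived from ``true_abundances`` assuming perfect
    per-cycle doubling: ``midpoint = base_midpoint - log2(abundance)``, so
    a 4-fold more abundant template crosses threshold 2 cycles earlier.
    """

    n_cycles: int = 40
    baseline: float = 50.0
    plateau: float = 3000.0
    slope: float = 1.0
    noise_sd: float = 0.0
    n_replicates: int = 3
    base_midpoint: float = 24.0
    midpoints: Optional[dict[tuple[str, str], float]] = None
    true_abundances: Optional[dict[tuple[str, str], float]] = None
    seed: int = 0

    def resolved_midpoints(self) -> dict[tuple[str, str], float]:
        if self.midpoints is not None:
            return dict(self.midpoints)
        if self.true_abundances is not None:
            return {
                key: self.base_midpoint - float(np.log2(ab))
                for key, ab in self.true_abundances.items()
            }
        raise ValueError("provide midpoints or true_abundances")

    def validate(self) -> None:
        if self.n_cycles < 10:
            raise ValueError("need at least 10 cycles")
        if self.plateau < self.baseline:
            raise ValueError("plateau must be >= baseline")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        for key, m in self.resolved_midpoints().items():
            if not 1.0 <= m <= self.n_cycles:
                raise ValueError(f"midpoint {m:.2f} for {key} outside cycle range")


def generate_amplification_curves(cfg: QpcrConfig) -> list[AmplificationCurve]:
    """Generate seeded logistic curves with their true midpoints recorded."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cycles = np.arange(1, cfg.n_cycles + 1, dtype=float)
    amp = cfg.plateau - cfg.baseline
    curves: list[AmplificationCurve] = []
    for (sample, gene), mid in sorted(cfg.resolved_midpoints().items()):
        for rep in range(1, cfg.n_replicates + 1):
            f = cfg.baseline + amp / (1.0 + np.exp(-cfg.slope * (cycles - mid)))
            if cfg.noise_sd > 0:
                f = f + rng.normal(0.0, cfg.noise_sd, size=f.shape)
            curves.append(
                AmplificationCurve(
                    cycles=cycles.copy(),
                    fluorescence=f,
                    sample=sample,
                    gene=gene,
                    replicate=rep,
                    true_midpoint=mid,
                )
            )
    return curves
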