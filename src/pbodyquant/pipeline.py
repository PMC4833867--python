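"""End-to-end orchestration of the image study and the expression study.

``run_granule_study`` takes one or more conditions — each either a set of
multi-channel TIFFs or a synthetic scene configuration — segments germ
cells, detects granules in two channels, pools per-cell counts and
co-localization fractions across images, and compares conditions with the
Steel–Dwass all-pairs test.  ``run_target_selection`` preprocesses the
three expression dataset pairs, computes fold changes and IP enrichment,
and applies the three-criteria Venn selection.

Every output table carries a provenance line (config hash + seed) and
reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from pbodyquant import io as pbio
from pbodyquant import stats as pbstats
from pbodyquant.expression import (
    SelectionCriteria,
    SignalMatrix,
    association_expression_correlation,
    fold_change,
    ip_enrichment_with_pvalues,
    preprocess_signals,
    select_candidate_targets,
    venn_overlap,
)
from pbodyquant.granulequant import (
    DetConfig,
    colocalization_fraction,
    count_granules_per_cell,
    detect_granules,
)
from pbodyquant.imgseg import SegConfig, segment_germ_cells
from pbodyquant.synthdata import (
    MultiChannelImage,
    SceneConfig,
    StudyConfig,
    generate_expression_study,
    generate_micrograph,
)

__all__ = [
    "GranuleStudyConfig",
    "TargetSelectionConfig",
    "run_granule_study",
    "run_target_selection",
]

log = logging.getLogger("pbodyquant")


def _config_hash(obj) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, set):
            return sorted(o)
        return str(o)

    text = json.dumps(obj, default=default, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass
class ConditionSpec:
    """One experimental condition: image paths or a simulated scene."""

    name: str
    image_paths: list[str] = field(default_factory=list)
    scene: Optional[SceneConfig] = None
    n_images: int = 1


@dataclass
class GranuleStudyConfig:
    conditions: list[ConditionSpec]
    seg: SegConfig = field(default_factory=SegConfig)
    det: DetConfig = field(default_factory=DetConfig)
    channel_a: str = "dcp1a"
    channel_b: str = "nanos2"
    out_dir: Optional[str] = None
    seed: int = 0


@dataclass
class GranuleStudyReport:
    counts: pd.DataFrame  # condition, image, cell_id, channel, count
    fractions: pd.DataFrame  # condition, image, cell_id, n_a, n_coloc, fraction
    summary: pd.DataFrame  # per condition/channel: n_cells, median, q1, q3, mean
    comparisons: pd.DataFrame  # Steel–Dwass pairwise table (per channel + fraction)
    config_hash: str = ""
    seed: int = 0


def _condition_images(
    spec: ConditionSpec, base_seed: int, index: int
) -> list[tuple[str, MultiChannelImage, Optional[object]]]:
    out = []
    if spec.scene is not None:
        for i in range(spec.n_images):
            cfg = dataclasses.replace(
                spec.scene, seed=(base_seed + 7919 * index + i) % (2**31 - 1)
            )
            img, truth = generate_micrograph(cfg)
            out.append((f"{spec.name}_{i}", img, truth))
    for p in spec.image_paths:
        out.append((Path(p).stem, pbio.read_micrograph(p), None))
    if not out:
        raise ValueError(f"condition {spec.name!r} has neither images nor a scene")
    return out


def run_granule_study(cfg: GranuleStudyConfig) -> GranuleStudyReport:
    """Segment, detect, count and compare granules across conditions."""
    chash = _config_hash(cfg)
    count_rows: list[pd.DataFrame] = []
    frac_rows: list[pd.DataFrame] = []
    empty_conditions: list[str] = []

    for ci, spec in enumerate(cfg.conditions):
        n_cells_cond = 0
        for image_name, img, _truth in _condition_images(spec, cfg.seed, ci):
            labelmap = segment_germ_cells(img.channel("cdh1") if "cdh1" in img.channel_names
                                          else img.data[0], cfg.seg)
            ga = detect_granules(img.channel(cfg.channel_a), cfg.det, cfg.channel_a)
            gb = detect_granules(img.channel(cfg.channel_b), cfg.det, cfg.channel_b)
            counts = count_granules_per_cell(list(ga) + list(gb), labelmap)
            fracs = colocalization_fraction(ga, gb, cfg.det, labelmap)
            log.info(
                "%s/%s: %d cells, %d %s + %d %s granules (%d on background)",
                spec.name, image_name, labelmap.n_cells, len(ga), cfg.channel_a,
                len(gb), cfg.channel_b, counts.dropped,
            )
            n_cells_cond += labelmap.n_cells
            c = counts.counts.assign(condition=spec.name, image=image_name)
            f = fracs.assign(condition=spec.name, image=image_name)
            count_rows.append(c)
            frac_rows.append(f)
        if n_cells_cond == 0:
            empty_conditions.append(spec.name)
            log.warning("condition %s: no cells segmented; excluded from stats", spec.name)

    counts = pd.concat(count_rows, ignore_index=True)[
        ["condition", "image", "cell_id", "channel", "count"]
    ]
    fractions = pd.concat(frac_rows, ignore_index=True)[
        ["condition", "image", "cell_id", "n_a", "n_coloc", "fraction"]
    ]

    # box-plot style summary: n cells, quartiles, mean — per condition/channel
    summary_rows = []
    for (cond, ch), grp in counts.groupby(["condition", "channel"]):
        v = grp["count"].to_numpy(float)
        summary_rows.append(
            (cond, ch, len(v), float(np.median(v)), float(np.percentile(v, 25)),
             float(np.percentile(v, 75)), float(v.mean()))
        )
    for cond, grp in fractions.groupby("condition"):
        v = grp["fraction"].dropna().to_numpy(float)
        if len(v):
            summary_rows.append(
                (cond, "coloc_fraction", len(v), float(np.median(v)),
                 float(np.percentile(v, 25)), float(np.percentile(v, 75)), float(v.mean()))
            )
    summary = pd.DataFrame(
        summary_rows,
        columns=["condition", "measure", "n_cells", "median", "q1", "q3", "mean"],
    ).sort_values(["measure", "condition"], ignore_index=True)

    comparisons = _all_pairs_comparisons(cfg, counts, fractions, empty_conditions)
    report = GranuleStudyReport(counts, fractions, summary, comparisons, chash, cfg.seed)
    if cfg.out_dir:
        _write_granule_report(cfg.out_dir, report)
    return report


def _all_pairs_comparisons(
    cfg: GranuleStudyConfig,
    counts: pd.DataFrame,
    fractions: pd.DataFrame,
    excluded: list[str],
) -> pd.DataFrame:
    rows = []
    conditions = [c.name for c in cfg.conditions if c.name not in excluded]
    if len(conditions) < 3:
        if len(conditions) >= 2:
            log.info("fewer than 3 conditions; all-pairs comparison table empty")
        return pd.DataFrame(
            columns=["measure", "group_a", "group_b", "statistic", "pvalue", "n_a", "n_b"]
        )
    for ch in sorted(counts["channel"].unique()):
        groups = {
            cond: counts.loc[
                (counts["condition"] == cond) & (counts["channel"] == ch), "count"
            ].to_numpy(float)
            for cond in conditions
        }
        for res in pbstats.steel_dwass(groups):
            rows.append((ch, res.group_a, res.group_b, res.statistic, res.pvalue,
                         res.n_a, res.n_b))
    frac_groups = {
        cond: fractions.loc[fractions["condition"] == cond, "fraction"]
        .dropna()
        .to_numpy(float)
        for cond in conditions
    }
    if all(len(v) >= 2 for v in frac_groups.values()):
        for res in pbstats.steel_dwass(frac_groups):
            rows.append(("coloc_fraction", res.group_a, res.group_b, res.statistic,
                         res.pvalue, res.n_a, res.n_b))
    return pd.DataFrame(
        rows, columns=["measure", "group_a", "group_b", "statistic", "pvalue", "n_a", "n_b"]
    )


def _write_granule_report(out_dir: str, report: GranuleStudyReport) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash={report.config_hash} seed={report.seed}"
    pbio.write_table(out / "per_cell_counts.csv", report.counts, tag)
    pbio.write_table(out / "coloc_fractions.csv", report.fractions, tag)
    pbio.write_table(out / "summary.csv", report.summary, tag)
    pbio.write_table(out / "comparisons.csv", report.comparisons, tag)


# ---------------------------------------------------------------------------
# expression study pipeline


@dataclass
class TargetSelectionConfig:
    study: Optional[StudyConfig] = None
    csv_paths: Optional[dict[str, tuple[str, str, str]]] = None  # name -> (csv, grpA, grpB)
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    out_dir: Optional[str] = None
    seed: int = 0


@dataclass
class TargetSelectionReport:
    fold_changes: pd.DataFrame  # per probe: down_xx, up_ko, rip enrichment + p
    selection_flags: pd.DataFrame
    venn: dict[str, int]
    selected: set[str]
    planted: Optional[set[str]]
    overlap_down_vs_rip: "object"
    correlation: tuple[float, float]
    scatter: pd.DataFrame
    config_hash: str = ""
    seed: int = 0


def run_target_selection(cfg: TargetSelectionConfig) -> TargetSelectionReport:
    """Preprocess the three dataset pairs and apply the Venn selection."""
    chash = _config_hash(cfg)
    planted: Optional[set[str]] = None
    if cfg.study is not None:
        study_cfg = dataclasses.replace(cfg.study, seed=cfg.seed or cfg.study.seed)
        study = generate_expression_study(study_cfg)
        pairs = {
            name: (SignalMatrix(ds.matrix), ds.group_a, ds.group_b)
            for name, ds in study.datasets.items()
        }
        planted = study.planted
    elif cfg.csv_paths is not None:
        pairs = {}
        for name, (path, ga, gb) in cfg.csv_paths.items():
            frame = pbio.read_table(path, index_col=0)
            m = SignalMatrix(frame)
            pairs[name] = (m, ga, gb)
    else:
        raise ValueError("provide either a study config or csv_paths")
    for required in ("induced_xx", "knockout_xy", "nanos2_rip"):
        if required not in pairs:
            raise ValueError(f"missing dataset {required!r}")

    processed = {}
    for name, (m, ga, gb) in pairs.items():
        pm = preprocess_signals(m)
        processed[name] = (pm, m.group_columns(ga) if isinstance(ga, str) else ga,
                           m.group_columns(gb) if isinstance(gb, str) else gb)

    universes = [set(m.probes) for m, _, _ in processed.values()]
    if not all(u == universes[0] for u in universes):
        offending = sorted(set.union(*universes) - set.intersection(*universes))[:10]
        raise ValueError(f"probe universe mismatch across datasets: e.g. {offending}")

    m_xx, a_xx, b_xx = processed["induced_xx"]
    m_ko, a_ko, b_ko = processed["knockout_xy"]
    m_rip, a_rip, b_rip = processed["nanos2_rip"]
    down_xx = fold_change(m_xx, a_xx, b_xx)
    up_ko = fold_change(m_ko, a_ko, b_ko)
    rip = ip_enrichment_with_pvalues(m_rip.data[a_rip], m_rip.data[b_rip])

    selection = select_candidate_targets(down_xx, up_ko, rip, cfg.criteria)
    fold_frame = pd.DataFrame(
        {
            "down_xx_log2fc": down_xx,
            "up_ko_log2fc": up_ko,
            "rip_log2_enrichment": rip["log2_enrichment"],
            "rip_pvalue": rip["pvalue"],
        }
    )

    set_down = set(selection.flags.index[selection.flags["down_xx"]])
    set_rip = set(selection.flags.index[selection.flags["ip_enriched"]])
    overlap = venn_overlap(set_rip, set_down)

    r, p, scatter = association_expression_correlation(
        rip["log2_enrichment"], up_ko, subset=None
    )

    report = TargetSelectionReport(
        fold_changes=fold_frame,
        selection_flags=selection.flags,
        venn=selection.venn,
        selected=selection.selected,
        planted=planted,
        overlap_down_vs_rip=overlap,
        correlation=(r, p),
        scatter=scatter,
        config_hash=chash,
        seed=cfg.seed,
    )
    if cfg.out_dir:
        _write_selection_report(cfg.out_dir, report)
    return report


def _write_selection_report(out_dir: str, report: TargetSelectionReport) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash={report.config_hash} seed={report.seed}"
    pbio.write_table(out / "fold_changes.csv",
                     report.fold_changes.reset_index(), tag)
    pbio.write_table(out / "selection_flags.csv",
                     report.selection_flags.reset_index(), tag)
    pbio.write_table(out / "scatter.csv", report.scatter.reset_index(), tag)
    venn = pd.DataFrame(sorted(report.venn.items()), columns=["region", "count"])
    pbio.write_table(out / "venn_regions.csv", venn, tag)
    selected = pd.DataFrame({"probe": sorted(report.selected)})
    pbio.write_table(out / "selected_probes.csv", selected, tag)
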