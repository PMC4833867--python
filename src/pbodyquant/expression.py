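"""Microarray preprocessing, RIP enrichment and three-criteria target selection.

Probe-level signals are floored at 1, normalized so every array's 75th
percentile equals a common scale (the geometric mean of the per-array 75th
percentiles), and log2-transformed; fold changes are differences of
replicate-mean log2 signals.  Candidate NANOS2 targets are probes that are
(i) down more than 1.5-fold in Nanos2-expressing XX gonads, (ii) up more
than 2-fold in Nanos2-null XY gonads, and (iii) enriched at least 4-fold
(P < 0.05) in the NANOS2 immunoprecipitate over input — the intersection
of the three sets of a Venn diagram whose seven region counts are all
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from pbodyquant import stats as pbstats

__all__ = [
    "SignalMatrix",
    "SelectionCriteria",
    "ProbeSelection",
    "VennOverlap",
    "PercentileNormalizer",
    "preprocess_signals",
    "fold_change",
    "rip_enrichment",
    "ip_enrichment_with_pvalues",
    "select_candidate_targets",
    "venn_overlap",
    "association_expression_correlation",
]

_STATES = ("raw", "floored", "p75-normalized", "log2")


@dataclass
class SignalMatrix:
    """Probe × sample intensity table with an explicit processing state."""

    data: pd.DataFrame
    state: str = "raw"
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {_STATES}")
        if self.state != "log2" and (self.data.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def probes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def group_columns(self, group: str) -> list[str]:
        if group in self.groups:
            return self.groups[group]
        cols = [c for c in self.data.columns if c == group or c.startswith(group + "_")]
        if not cols:
            raise KeyError(f"no sample columns for group {group!r}")
        return cols


class PercentileNormalizer(BaseEstimator, TransformerMixin):
    """Floor, 75th-percentile-normalize and log2-transform signal columns.

    scikit-learn transformer over probe × sample tables (DataFrame or
    ndarray).  ``fit`` learns the common scale ``target_`` — the geometric
    mean of the per-column 75th percentiles of the floored data — and
    ``transform`` floors at ``floor``, rescales every column so its 75th
    percentile equals ``target_``, and (optionally) log2-transforms.
    """

    def __init__(self, percentile: float = 75.0, floor: float = 1.0, log2: bool = True):
        self.percentile = percentile
        self.floor = floor
        self.log2 = log2

    def fit(self, X, y=None) -> "PercentileNormalizer":
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D probe × sample table")
        if (arr < 0).any():
            raise ValueError("raw intensities must be non-negative")
        if (arr.max(axis=0) == 0).any():
            raise ValueError("a sample has all-zero signal")
        floored = np.maximum(arr, self.floor)
        self.percentiles_ = np.percentile(floored, self.percentile, axis=0)
        self.target_ = float(np.exp(np.mean(np.log(self.percentiles_))))
        return self

    def transform(self, X) -> "np.ndarray | pd.DataFrame":
        arr = np.asarray(X, dtype=float)
        floored = np.maximum(arr, self.floor)
        p = np.percentile(floored, self.percentile, axis=0)
        scaled = floored * (self.target_ / p)
        out = np.log2(scaled) if self.log2 else scaled
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


def preprocess_signals(m: SignalMatrix) -> SignalMatrix:
    """Floor at 1, normalize columns to a common 75th percentile, log2.

    The state flag advances raw → floored → p75-normalized → log2; the
    returned matrix is in log2 state, ready for :func:`fold_change`.
    """
    if m.state != "raw":
        raise ValueError(f"expected a raw matrix, got state {m.state!r}")
    norm = PercentileNormalizer().fit(m.data)
    out = norm.transform(m.data)
    return SignalMatrix(data=out, state="log2", groups=dict(m.groups))


def fold_change(m: SignalMatrix, group_a: str | Iterable[str],
                group_b: str | Iterable[str]) -> pd.Series:
    """Per-probe log2 fold change: mean(log2 A) − mean(log2 B)."""
    if m.state != "log2":
        raise ValueError("fold_change needs a log2-state matrix")
    cols_a = m.group_columns(group_a) if isinstance(group_a, str) else list(group_a)
    cols_b = m.group_columns(group_b) if isinstance(group_b, str) else list(group_b)
    missing = [c for c in cols_a + cols_b if c not in m.data.columns]
    if missing:
        raise KeyError(f"unknown sample columns: {missing}")
    fc = m.data[cols_a].mean(axis=1) - m.data[cols_b].mean(axis=1)
    fc.name = "log2fc"
    return fc


def rip_enrichment(
    ip: pd.DataFrame | pd.Series,
    input_: pd.DataFrame | pd.Series,
    reference: str,
) -> pd.DataFrame:
    """IP/input ratios normalized against a reference transcript.

    ``ratio_g = (IP_g / input_g) / (IP_ref / input_ref)``; replicate
    columns are averaged on the linear scale first.  The reference
    transcript's normalized ratio is 1 by construction.
    """
    ip_mean = ip.mean(axis=1) if isinstance(ip, pd.DataFrame) else ip.astype(float)
    in_mean = (
        input_.mean(axis=1) if isinstance(input_, pd.DataFrame) else input_.astype(float)
    )
    ip_mean, in_mean = ip_mean.align(in_mean, join="inner")
    if reference not in ip_mean.index:
        raise KeyError(f"reference {reference!r} not present in both tables")
    if (in_mean <= 0).any():
        bad = in_mean.index[in_mean <= 0][:5].tolist()
        raise ValueError(f"non-positive input signal for {bad}")
    raw_ratio = ip_mean / in_mean
    ref_ratio = raw_ratio.loc[reference]
    if ref_ratio <= 0:
        raise ValueError("reference has non-positive IP/input ratio")
    return pd.DataFrame(
        {
            "ip_over_input": raw_ratio,
            "normalized_ratio": raw_ratio / ref_ratio,
        }
    )


def ip_enrichment_with_pvalues(
    ip: pd.DataFrame, input_: pd.DataFrame
) -> pd.DataFrame:
    """Per-probe log2 IP/input enrichment with a two-tailed t-test p-value.

    Columns are replicate arrays (already log2).  The p-value is a
    pooled-variance Student's t on the log2 replicate signals, matching
    the two-replicate design of the original hybridisations; degenerate
    zero-variance probes follow the conventions of
    :func:`pbodyquant.stats.student_t_two_tailed`.
    """
    if not ip.index.equals(input_.index):
        raise ValueError("IP and input must share the probe index")
    log2fc = ip.mean(axis=1) - input_.mean(axis=1)
    pvals = np.empty(len(ip))
    ip_arr, in_arr = ip.to_numpy(), input_.to_numpy()
    for i in range(len(ip)):
        pvals[i] = pbstats.student_t_two_tailed(ip_arr[i], in_arr[i]).pvalue
    return pd.DataFrame({"log2_enrichment": log2fc, "pvalue": pvals}, index=ip.index)


@dataclass
class SelectionCriteria:
    """Thresholds of the three-way Venn selection.

    Folds are linear ratios applied on the log2 scale; comparisons are
    closed (≥/≤) by default, with ``strict=True`` switching to the
    strict reading of "more than n-fold".
    """

    down_fold_xx: float = 1.5
    up_fold_ko: float = 2.0
    ip_enrich_fold: float = 4.0
    ip_p_threshold: float = 0.05
    strict: bool = False

    def validate(self) -> None:
        if min(self.down_fold_xx, self.up_fold_ko, self.ip_enrich_fold) <= 1.0:
            raise ValueError("fold thresholds must exceed 1")
        if not 0 < self.ip_p_threshold <= 1:
            raise ValueError("ip_p_threshold must lie in (0, 1]")


@dataclass
class ProbeSelection:
    """Per-probe criterion flags, final membership, and Venn region counts."""

    flags: pd.DataFrame  # columns down_xx, up_ko, ip_enriched, selected
    venn: dict[str, int]  # exclusive regions: A, B, C, AB, AC, BC, ABC

    @property
    def selected(self) -> set[str]:
        return set(self.flags.index[self.flags["selected"]])


def _venn_regions(a: set, b: set, c: set) -> dict[str, int]:
    return {
        "A": len(a - b - c),
        "B": len(b - a - c),
        "C": len(c - a - b),
        "AB": len((a & b) - c),
        "AC": len((a & c) - b),
        "BC": len((b & c) - a),
        "ABC": len(a & b & c),
    }


def select_candidate_targets(
    down_xx: pd.Series,
    up_ko: pd.Series,
    rip: pd.DataFrame,
    crit: Optional[SelectionCriteria] = None,
) -> ProbeSelection:
    """Intersect the three selection criteria over a shared probe universe.

    ``down_xx`` and ``up_ko`` are per-probe log2 fold changes; ``rip``
    needs columns ``log2_enrichment`` and ``pvalue`` (see
    :func:`ip_enrichment_with_pvalues`).  Probe universes must match
    exactly — mismatches raise, listing offending ids, rather than being
    silently intersected.
    """
    crit = crit or SelectionCriteria()
    crit.validate()
    universe = set(down_xx.index)
    for name, idx in (("up_ko", up_ko.index), ("rip", rip.index)):
        if set(idx) != universe:
            diff = sorted(set(idx) ^ universe)[:10]
            raise ValueError(f"probe universe mismatch in {name}: e.g. {diff}")
    up_ko = up_ko.reindex(down_xx.index)
    rip = rip.reindex(down_xx.index)

    lt = np.less if crit.strict else np.less_equal
    gt = np.greater if crit.strict else np.greater_equal
    flag_a = lt(down_xx.to_numpy(), -math.log2(crit.down_fold_xx))
    flag_b = gt(up_ko.to_numpy(), math.log2(crit.up_fold_ko))
    flag_c = gt(rip["log2_enrichment"].to_numpy(), math.log2(crit.ip_enrich_fold)) & (
        rip["pvalue"].to_numpy() < crit.ip_p_threshold
    )
    flags = pd.DataFrame(
        {
            "down_xx": flag_a,
            "up_ko": flag_b,
            "ip_enriched": flag_c,
            "selected": flag_a & flag_b & flag_c,
        },
        index=down_xx.index,
    )
    sets = tuple(
        set(flags.index[flags[col]]) for col in ("down_xx", "up_ko", "ip_enriched")
    )
    return ProbeSelection(flags=flags, venn=_venn_regions(*sets))


@dataclass(frozen=True)
class VennOverlap:
    size_a: int
    size_b: int
    intersection: int
    percent_of_a: Optional[float]  # 100·|A∩B|/|A| to one decimal; None if |A|=0


def venn_overlap(set_a: Iterable, set_b: Iterable) -> VennOverlap:
    """Exact two-set overlap with the percentage of A in the intersection."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    pct = round(100.0 * inter / len(a), 1) if a else None
    return VennOverlap(len(a), len(b), inter, pct)


def association_expression_correlation(
    dazl_ip_diff: pd.Series,
    expr_change: pd.Series,
    subset: Optional[Iterable[str]] = None,
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation between DAZL-association difference and expression change.

    ``dazl_ip_diff`` is the per-probe difference of log2 IP/input values
    (e.g. XX − XY); ``expr_change`` the log2 expression change in
    knockout vs wild-type gonads.  Returns (r, two-sided p, scatter table
    over the subset) using the package's own Pearson implementation.
    """
    if subset is not None:
        subset = list(subset)
        missing = [p for p in subset if p not in dazl_ip_diff.index or p not in expr_change.index]
        if missing:
            raise KeyError(f"subset probes missing from inputs: {missing[:10]}")
        x = dazl_ip_diff.loc[subset]
        y = expr_change.loc[subset]
    else:
        x, y = dazl_ip_diff.align(expr_change, join="inner")
    if len(x) < 3:
        raise ValueError("need at least 3 probes for a correlation")
    r, p = pbstats.pearson_correlation(x.to_numpy(), y.to_numpy())
    scatter = pd.DataFrame({"ip_diff": x, "expr_change": y})
    return r, p, scatter
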