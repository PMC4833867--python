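"""Ct calling by the second-derivative maximum and ΔΔCt relative quantification.

The threshold cycle is defined as the cycle at which the amplification
curve's second derivative is maximal — for a logistic curve of unit slope
this sits 1.317 cycles (= ln(2+√3)) before the midpoint, where the
logistic fraction equals (3−√3)/6.  The curve is interpolated with a
quintic spline (optionally after moving-average smoothing) and the second
derivative maximised by dense evaluation plus golden-section refinement.

Relative quantities follow the classical ΔΔCt method with amplification
efficiency fixed at 2: ΔCt = Ct(gene) − Ct(normalizer) per sample on
replicate-mean Ct values, ΔΔCt relative to a reference sample, and
RQ = 2^(−ΔΔCt).  Replicate SDs are propagated into a dispersion per
(sample, gene).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, optimize
from sklearn.base import BaseEstimator

from pbodyquant.synthdata import AmplificationCurve

__all__ = [
    "NoAmplificationError",
    "SecondDerivativeCtCaller",
    "ct_second_derivative_max",
    "ct_table",
    "ddct_relative_quantity",
]


class NoAmplificationError(ValueError):
    """Raised for flat or decreasing curves with no rising phase."""


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(y)]
    return out


def ct_second_derivative_max(
    curve: AmplificationCurve | tuple[np.ndarray, np.ndarray],
    smoothing: int = 1,
    rise_floor: float = 1e-6,
) -> float:
    """Ct of one amplification curve: argmax of the spline second derivative.

    ``smoothing`` is a moving-average span in cycles (1 = none, the
    default; odd values recommended).  Curves whose total rise is below
    ``rise_floor`` × max|F|, or that decrease overall, raise
    :class:`NoAmplificationError`.
    """
    if isinstance(curve, AmplificationCurve):
        cycles, fluo = curve.cycles, curve.fluorescence
    else:
        cycles, fluo = curve
    cycles = np.asarray(cycles, dtype=float)
    fluo = np.asarray(fluo, dtype=float)
    if len(cycles) < 10:
        raise ValueError("need at least 10 cycles")
    rise = fluo.max() - fluo.min()
    scale = max(np.abs(fluo).max(), 1.0)
    if rise <= rise_floor * scale or fluo[-1] <= fluo[0]:
        raise NoAmplificationError("no amplification: flat or decreasing curve")

    smooth = _moving_average(fluo, smoothing)
    spline = interpolate.InterpolatedUnivariateSpline(cycles, smooth, k=5)
    d2 = spline.derivative(2)
    lo, hi = cycles[0], cycles[-1]
    grid = np.linspace(lo, hi, 40 * len(cycles))
    vals = d2(grid)
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    if a == b:
        ct = grid[i]
    else:
        res = optimize.minimize_scalar(
            lambda c: -float(d2(c)), bounds=(a, b), method="bounded",
            options={"xatol": 1e-6},
        )
        ct = float(res.x)
    return float(np.clip(ct, lo, hi))


class SecondDerivativeCtCaller(BaseEstimator):
    """Call Ct values for a batch of amplification curves.

    scikit-learn-style estimator: ``fit`` on a sequence of
    :class:`~pbodyquant.synthdata.AmplificationCurve` computes
    ``ct_table_``, a tidy (sample, gene, replicate, ct) DataFrame;
    ``transform`` returns the same table for new curves.
    """

    def __init__(self, smoothing: int = 1, rise_floor: float = 1e-6):
        self.smoothing = smoothing
        self.rise_floor = rise_floor

    def _call(self, curves: Sequence[AmplificationCurve]) -> pd.DataFrame:
        rows = [
            (
                c.sample,
                c.gene,
                c.replicate,
                ct_second_derivative_max(c, self.smoothing, self.rise_floor),
            )
            for c in curves
        ]
        return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])

    def fit(self, X: Sequence[AmplificationCurve], y=None) -> "SecondDerivativeCtCaller":
        self.ct_table_ = self._call(X)
        return self

    def transform(self, X: Sequence[AmplificationCurve]) -> pd.DataFrame:
        return self._call(X)


def ct_table(curves: Iterable[AmplificationCurve], smoothing: int = 1) -> pd.DataFrame:
    """Functional wrapper: Ct table for a batch of curves."""
    return SecondDerivativeCtCaller(smoothing=smoothing).transform(list(curves))


def ddct_relative_quantity(
    ct: pd.DataFrame,
    normalizer_gene: str,
    reference_sample: str,
) -> pd.DataFrame:
    """ΔΔCt relative quantification against a normalizer gene and reference sample.

    ``ct`` is a tidy table with columns (sample, gene, replicate, ct).
    Replicates are aggregated as mean Ct before differencing; the
    replicate SDs of gene and normalizer are combined in quadrature and
    expressed as a fold-dispersion (``rq_sd_fold = 2**sd_ct``), giving
    the asymmetric range ``rq / rq_sd_fold .. rq * rq_sd_fold``.
    RQ of the reference sample is 1 for every gene by construction.
    """
    required = {"sample", "gene", "replicate", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"ct table needs columns {sorted(required)}")
    agg = ct.groupby(["sample", "gene"])["ct"].agg(["mean", "std", "count"])
    samples = agg.index.get_level_values("sample").unique()
    genes = agg.index.get_level_values("gene").unique()
    if normalizer_gene not in genes:
        raise KeyError(f"normalizer gene {normalizer_gene!r} not in Ct table")
    if reference_sample not in samples:
        raise KeyError(f"reference sample {reference_sample!r} not in Ct table")

    rows = []
    for sample in samples:
        try:
            norm = agg.loc[(sample, normalizer_gene)]
        except KeyError:
            raise KeyError(f"normalizer {normalizer_gene!r} missing for sample {sample!r}")
        for gene in genes:
            if (sample, gene) not in agg.index:
                continue
            g = agg.loc[(sample, gene)]
            dct = g["mean"] - norm["mean"]
            sd_g = 0.0 if np.isnan(g["std"]) else g["std"]
            sd_n = 0.0 if np.isnan(norm["std"]) else norm["std"]
            sd = float(np.hypot(sd_g, sd_n)) if gene != normalizer_gene else float(sd_g)
            rows.append((sample, gene, dct, sd))
    dct_frame = pd.DataFrame(rows, columns=["sample", "gene", "dct", "sd_ct"])

    ref = dct_frame[dct_frame["sample"] == reference_sample].set_index("gene")["dct"]
    missing = set(dct_frame["gene"]) - set(ref.index)
    if missing:
        raise KeyError(f"genes missing in reference sample: {sorted(missing)}")
    ddct = dct_frame["dct"] - dct_frame["gene"].map(ref)
    out = dct_frame.assign(
        ddct=ddct,
        rq=2.0 ** (-ddct),
        rq_sd_fold=2.0 ** dct_frame["sd_ct"],
    )
    return out[["sample", "gene", "ddct", "rq", "rq_sd_fold"]]
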