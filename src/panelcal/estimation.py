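"""Weighted prevalence estimation with linearized variance.

Point estimates are Hajek ratio means ``p = sum(w*y)/sum(w)``; their
variance uses the single-stage Taylor-series linearization

    V = (n/(n-1)) * sum(w_i^2 (y_i - p)^2) / (sum w)^2

with 95% intervals ``p +/- 1.96 sqrt(V)`` truncated to [0, 1].  Quota
strata are deliberately ignored in the variance (self-weighting base,
single-stage assumption); with an opt-in nonprobability sample the
intervals describe precision within the sampling framework, not true
coverage probabilities.  No finite-population correction (n << N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import EndorsementMatrix, PanelValidationError

Z_95 = 1.96


@dataclass
class ProportionEstimate:
    p: float          # proportion scale
    se: float         # NaN when undefined (n < 2)
    lo: float
    hi: float

    @property
    def pct(self) -> float:
        return 100.0 * self.p


def weighted_proportion(y: np.ndarray, weights: np.ndarray,
                        z: float = Z_95) -> ProportionEstimate:
    """Weighted proportion of a binary indicator with linearized SE/CI."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.shape != w.shape:
        raise PanelValidationError("indicator and weights must align")
    if ((y != 0) & (y != 1)).any():
        raise PanelValidationError("indicator must be binary")
    if (w <= 0).any():
        raise PanelValidationError("weights must be positive")
    n = y.size
    total = w.sum()
    p = float((w * y).sum() / total)
    if n < 2:
        return ProportionEstimate(p, float("nan"), float("nan"), float("nan"))
    v = (n / (n - 1)) * float((w ** 2 * (y - p) ** 2).sum()) / total ** 2
    se = float(np.sqrt(v))
    return ProportionEstimate(
        p, se, max(0.0, p - z * se), min(1.0, p + z * se)
    )


def estimate_table(
    panel_df: pd.DataFrame,
    weights: np.ndarray,
    indicators: list[tuple[str, str, str]],
    N: float | None = None,
    suppress_below: int = 5,
) -> pd.DataFrame:
    """Unweighted and weighted estimates for a list of indicators.

    ``indicators`` is a list of ``(label, variable, level)``: the indicator
    is 1 where ``panel_df[variable] == level``.  Cells with an unweighted
    count below ``suppress_below`` get ``suppressed=True`` (stored values
    are kept; suppression is a display convention).
    """
    w = np.asarray(weights, dtype=float)
    if N is None:
        N = float(w.sum())
    rows = []
    for label, variable, level in indicators:
        if variable not in panel_df.columns:
            raise PanelValidationError(f"unknown indicator variable {variable!r}")
        y = (panel_df[variable].astype(str) == str(level)).to_numpy()
        est = weighted_proportion(y.astype(float), w)
        n_cell = int(y.sum())
        rows.append({
            "indicator": label,
            "variable": variable,
            "level": level,
            "unweighted_n": n_cell,
            "unweighted_pct": 100.0 * n_cell / len(panel_df),
            "weighted_pct": est.pct,
            "ci_lo_pct": 100.0 * est.lo,
            "ci_hi_pct": 100.0 * est.hi,
            "weighted_count": est.p * N,
            "suppressed": n_cell < suppress_below,
        })
    return pd.DataFrame(rows)


@dataclass
class OrderEffectResult:
    """Endorsement rate by presentation position plus a monotone-trend
    rank statistic (diagnostic only; no correction is applied)."""

    rates: pd.DataFrame  # position, endorsement_rate, n
    rho: float
    pvalue: float


def order_effect_diagnostic(matrix: EndorsementMatrix) -> OrderEffectResult:
    """Endorsement rate at each presentation position with a Spearman
    trend test across positions."""
    if matrix.m < 2:
        raise PanelValidationError(
            "order-effect diagnostic needs at least two presentation positions"
        )
    ordered = matrix.in_presentation_order()
    rates = ordered.mean(axis=0)
    table = pd.DataFrame({
        "position": np.arange(matrix.m),
        "endorsement_rate": rates,
        "n": matrix.n,
    })
    rho, p = stats.spearmanr(table["position"], table["endorsement_rate"])
    return OrderEffectResult(rates=table, rho=float(rho), pvalue=float(p))
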