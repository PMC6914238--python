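"""Base weights and generalized raking to marginal targets.

Raking (iterative proportional fitting with incomplete stratification)
starts every respondent at the uniform base weight ``w_b = N/n`` and
cycles through the weighting variables in their given order, multiplying
the weights in each category by target-count / current-weighted-count.
The stopping rule is on weighted marginal *proportions* (scale-free); the
final weighted-*frequency* discrepancy is reported alongside it.  Weights
are never trimmed; an extreme-weight diagnostic is reported instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MarginalTargets, PanelValidationError

# 0.1 percentage points, on the proportion scale.
DEFAULT_TOL_MARGINAL = 1e-3
# 0.1 persons of weighted frequency (reported, not the stopping rule).
DEFAULT_TOL_FREQ = 0.1


def base_weight(N: float, n: int) -> float:
    """Uniform base weight ``w_b = N/n``."""
    if n <= 0:
        raise PanelValidationError("sample size n must be positive")
    if N <= 0:
        raise PanelValidationError("population size N must be positive")
    return N / n


@dataclass
class RakingResult:
    """Analytic weights with convergence metadata."""

    weights: np.ndarray
    base_weights: np.ndarray
    iterations: int
    converged: bool
    max_marginal_gap: float  # proportion scale
    max_freq_gap: float      # weighted-count scale
    tol_marginal: float
    tol_freq: float
    variables: tuple[str, ...]


def _prepare_constraints(
    sample: pd.DataFrame, variables, targets: MarginalTargets
):
    """Per-variable category index arrays and target counts; target
    categories absent from the sample are dropped (incomplete
    stratification) with a warning and the remainder renormalized."""
    constraints = []
    for var in variables:
        if var not in sample.columns:
            raise PanelValidationError(f"sample has no column {var!r}")
        if var not in targets.variables:
            raise PanelValidationError(f"no marginal targets for variable {var!r}")
        props = dict(targets.variables[var])
        present = set(sample[var].unique())
        missing_target = present - set(props)
        if missing_target:
            raise PanelValidationError(
                f"sample categories {sorted(missing_target)!r} of {var!r} "
                "have no (positive) target proportion"
            )
        dropped = [lev for lev in props if lev not in present]
        if dropped:
            warnings.warn(
                f"target categories {dropped!r} of {var!r} absent from the "
                "sample; dropped from the constraint",
                stacklevel=3,
            )
            for lev in dropped:
                props.pop(lev)
            total = sum(props.values())
            props = {k: v / total for k, v in props.items()}
        levels = list(props)
        codes = sample[var].map({lev: k for k, lev in enumerate(levels)})
        constraints.append(
            (var, levels, codes.to_numpy(),
             np.array([props[lev] for lev in levels]) * targets.N)
        )
    return constraints


def rake(
    sample: pd.DataFrame,
    variables,
    targets: MarginalTargets,
    base_weights: np.ndarray | None = None,
    tol_marginal: float = DEFAULT_TOL_MARGINAL,
    tol_freq: float = DEFAULT_TOL_FREQ,
    max_iter: int = 100,
) -> RakingResult:
    """Rake ``sample`` (one row per respondent, one column per weighting
    variable) to the marginal ``targets``.

    Returns converged=False (with a warning) when ``max_iter`` full cycles
    do not bring every weighted marginal within ``tol_marginal`` (0.1
    percentage points by default) of its target.
    """
    variables = tuple(variables)
    n = len(sample)
    if n == 0:
        raise PanelValidationError("no respondents")
    targets.validate()
    if base_weights is None:
        base_weights = np.full(n, base_weight(targets.N, n))
    else:
        base_weights = np.asarray(base_weights, dtype=float)
        if (base_weights <= 0).any():
            raise PanelValidationError("base weights must be positive")
    w = base_weights.copy()

    constraints = _prepare_constraints(sample, variables, targets)
    if not constraints:
        return RakingResult(w, base_weights, 0, True, 0.0, 0.0,
                            tol_marginal, tol_freq, variables)

    def gaps(w):
        max_prop = 0.0
        max_freq = 0.0
        total = w.sum()
        for _, levels, codes, target_counts in constraints:
            got = np.bincount(codes, weights=w, minlength=len(levels))
            max_freq = max(max_freq, np.abs(got - target_counts).max())
            max_prop = max(
                max_prop,
                np.abs(got / total - target_counts / targets.N).max(),
            )
        return max_prop, max_freq

    iterations = 0
    converged = False
    max_prop, max_freq = gaps(w)
    if max_prop <= tol_marginal:
        converged = True
    while not converged and iterations < max_iter:
        for _, levels, codes, target_counts in constraints:
            got = np.bincount(codes, weights=w, minlength=len(levels))
            if (got <= 0).any():
                raise PanelValidationError(
                    "zero weighted count in a sample-present category during "
                    "raking"
                )
            w *= (target_counts / got)[codes]
        iterations += 1
        max_prop, max_freq = gaps(w)
        if max_prop <= tol_marginal:
            converged = True
    if not converged:
        warnings.warn(
            f"raking did not converge in {max_iter} cycles "
            f"(max marginal gap {max_prop:.3g})",
            stacklevel=2,
        )
    return RakingResult(
        weights=w,
        base_weights=base_weights,
        iterations=iterations,
        converged=converged,
        max_marginal_gap=float(max_prop),
        max_freq_gap=float(max_freq),
        tol_marginal=tol_marginal,
        tol_freq=tol_freq,
        variables=variables,
    )


def weight_diagnostics(weights: np.ndarray, round_decimals: int = 6) -> dict:
    """Distributional diagnostics of an analytic-weight vector.

    The unique-weight count groups exact values after rounding to 1e-6;
    weights above five times the median are counted as extreme (reported
    only — never trimmed).
    """
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise PanelValidationError("weights must be positive")
    med = float(np.median(w))
    q1, q3 = (float(np.quantile(w, q)) for q in (0.25, 0.75))
    cv = float(w.std(ddof=0) / w.mean())
    return {
        "n": int(w.size),
        "n_unique_weights": int(np.unique(np.round(w, round_decimals)).size),
        "median": med,
        "iqr": [q1, q3],
        "min": float(w.min()),
        "max": float(w.max()),
        "design_effect_proxy": 1.0 + cv ** 2,
        "n_extreme": int((w > 5 * med).sum()),
    }
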