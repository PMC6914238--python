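"""Benchmark scoring and weighting-scheme selection.

A candidate weighting scheme is the three core demographics plus any
subset of the optional variables.  Each raked scheme is scored against a
set of external benchmark estimates by the absolute relative difference

    D_i = 100 * |p_i - pi_i| / pi_i

averaged over the included benchmarks (Dbar); the average relative
standard error of the benchmark estimates tracks the precision cost.
Scheme selection is a parsimony rule standing in for the published visual
choice: the smallest scheme whose Dbar is within a slack (default 1
percentage point of Dbar) of the global minimum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import CORE_WEIGHTING_VARS, OPTIONAL_WEIGHTING_VARS
from .estimation import weighted_proportion
from .raking import RakingResult, base_weight, rake, weight_diagnostics
from .types import BenchmarkSet, MarginalTargets, PanelValidationError


def relative_difference(p: float, pi: float) -> float:
    """Absolute relative difference ``100*|p - pi|/pi`` (any common scale)."""
    if pi <= 0:
        raise PanelValidationError(
            "relative difference undefined for a non-positive benchmark"
        )
    return 100.0 * abs(p - pi) / pi


def average_relative_difference(values) -> float:
    """Arithmetic mean of per-benchmark relative differences."""
    values = list(values)
    if not values:
        raise PanelValidationError("no benchmark relative differences to average")
    return float(np.mean(values))


@dataclass(frozen=True)
class WeightingScheme:
    """A weighting configuration; empty ``variables`` is the unweighted
    baseline."""

    variables: tuple[str, ...]

    @property
    def name(self) -> str:
        return "unweighted" if not self.variables else "+".join(self.variables)

    @property
    def n_variables(self) -> int:
        return len(self.variables)


def enumerate_schemes(
    core=CORE_WEIGHTING_VARS, optional=OPTIONAL_WEIGHTING_VARS
) -> list[WeightingScheme]:
    """All candidate configurations: the unweighted baseline, then the core
    demographics unioned with every subset of the optional variables,
    ordered by subset size then lexicographically (2^k raked schemes + 1)."""
    core = tuple(core)
    optional = tuple(optional)
    if set(core) & set(optional):
        raise PanelValidationError(
            f"core and optional variables overlap: {set(core) & set(optional)}"
        )
    schemes = [WeightingScheme(())]
    subsets = []
    for size in range(len(optional) + 1):
        for combo in itertools.combinations(sorted(optional), size):
            subsets.append(combo)
    subsets.sort(key=lambda c: (len(c), c))
    for combo in subsets:
        schemes.append(WeightingScheme(core + combo))
    return schemes


@dataclass
class SchemeSearchResult:
    table: pd.DataFrame            # one row per scheme
    per_benchmark: pd.DataFrame    # scheme x benchmark D_i detail
    selected: WeightingScheme
    weights: dict[str, np.ndarray]  # scheme name -> analytic weights


def _benchmark_estimates(panel_df, weights, benchmarks: BenchmarkSet):
    rows = []
    for b in benchmarks:
        if b.variable not in panel_df.columns:
            raise PanelValidationError(
                f"benchmark {b.benchmark_id!r} not estimable: no column "
                f"{b.variable!r}"
            )
        y = (panel_df[b.variable].astype(str) == str(b.level)).to_numpy(float)
        est = weighted_proportion(y, weights)
        rows.append((b, est))
    return rows


def evaluate_schemes(
    panel_df: pd.DataFrame,
    targets: MarginalTargets,
    benchmarks: BenchmarkSet,
    schemes: list[WeightingScheme] | None = None,
    selection_slack_pp: float = 1.0,
    tol_marginal: float = 1e-3,
    max_iter: int = 100,
) -> SchemeSearchResult:
    """Rake and score every candidate scheme; select by the parsimony rule.

    A scheme whose raking fails is marked ``failed`` and skipped by the
    selection; the unweighted baseline is always present and its Dbar is
    the average relative difference of the unweighted estimates.
    """
    if schemes is None:
        schemes = enumerate_schemes()
    benchmarks.validate()
    n = len(panel_df)
    if n == 0:
        raise PanelValidationError("no respondents")
    w_base = np.full(n, base_weight(targets.N, n))

    table_rows = []
    detail_rows = []
    weights_of: dict[str, np.ndarray] = {}
    for scheme in schemes:
        failed = False
        converged = True
        if scheme.variables:
            try:
                result: RakingResult = rake(
                    panel_df, scheme.variables, targets,
                    tol_marginal=tol_marginal, max_iter=max_iter,
                )
                w = result.weights
                converged = result.converged
            except PanelValidationError:
                failed = True
                w = None
        else:
            w = w_base
        row = {
            "scheme": scheme.name,
            "n_variables": scheme.n_variables,
            "failed": failed,
            "converged": converged if not failed else False,
        }
        if not failed:
            weights_of[scheme.name] = w
            d_all, d_health, d_nonhealth, rel_ses = [], [], [], []
            for b, est in _benchmark_estimates(panel_df, w, benchmarks):
                d_i = relative_difference(est.pct, b.value_pct)
                detail_rows.append({
                    "scheme": scheme.name,
                    "benchmark_id": b.benchmark_id,
                    "estimate_pct": est.pct,
                    "benchmark_pct": b.value_pct,
                    "D_i": d_i,
                    "included": b.included,
                    "group": b.group,
                })
                if b.included:
                    d_all.append(d_i)
                    (d_health if b.group == "health" else d_nonhealth).append(d_i)
                    if est.p > 0 and np.isfinite(est.se):
                        rel_ses.append(est.se / est.p)
            diag = weight_diagnostics(w)
            row.update({
                "D_bar": average_relative_difference(d_all),
                "D_bar_health": average_relative_difference(d_health)
                if d_health else np.nan,
                "D_bar_nonhealth": average_relative_difference(d_nonhealth)
                if d_nonhealth else np.nan,
                "avg_relative_se": float(np.mean(rel_ses)) if rel_ses else np.nan,
                "n_unique_weights": diag["n_unique_weights"],
            })
        else:
            row.update({"D_bar": np.nan, "D_bar_health": np.nan,
                        "D_bar_nonhealth": np.nan, "avg_relative_se": np.nan,
                        "n_unique_weights": 0})
        table_rows.append(row)

    table = pd.DataFrame(table_rows)
    ok = table.loc[~table["failed"]]
    if ok.empty:
        raise PanelValidationError("every candidate scheme failed to rake")
    d_min = ok["D_bar"].min()
    candidates = ok.loc[ok["D_bar"] <= d_min + selection_slack_pp]
    pick = candidates.sort_values(["n_variables", "scheme"]).iloc[0]
    selected = next(s for s in schemes if s.name == pick["scheme"])
    table["selected"] = table["scheme"] == selected.name

    d0 = float(table.loc[table["scheme"] == "unweighted", "D_bar"].iloc[0]) \
        if (table["scheme"] == "unweighted").any() else np.nan
    if np.isfinite(d0) and d0 > 0:
        table["reduction_vs_unweighted_pct"] = 100.0 * (d0 - table["D_bar"]) / d0
    return SchemeSearchResult(
        table=table,
        per_benchmark=pd.DataFrame(detail_rows),
        selected=selected,
        weights=weights_of,
    )
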