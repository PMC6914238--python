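"""End-to-end post-fielding pipeline: screen -> weigh -> estimate.

``run_pipeline`` chains careless-response screening, calibration weighting
(either a fixed scheme or the benchmark-scored scheme search), and the
weighted national estimate table, logging n-in/n-out at every stage to a
run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .benchmarks import SchemeSearchResult, WeightingScheme, evaluate_schemes
from .careless import ScreenResult, screen
from .io import RunManifest, logger
from .raking import RakingResult, rake, weight_diagnostics
from .estimation import estimate_table
from .types import (
    BenchmarkSet,
    CutPoints,
    MarginalTargets,
    Panel,
    PanelValidationError,
    RESPONDENT_ID,
)


@dataclass
class PipelineOptions:
    cuts: CutPoints = field(default_factory=CutPoints)
    scheme: tuple[str, ...] | None = None  # None -> benchmark scheme search
    selection_slack_pp: float = 1.0
    tol_marginal: float = 1e-3
    max_iter: int = 100
    indicators: list[tuple[str, str, str]] | None = None
    outdir: str | Path | None = None


@dataclass
class PipelineResult:
    screen_result: ScreenResult
    kept: pd.DataFrame
    weights: np.ndarray
    raking: RakingResult | None
    scheme_search: SchemeSearchResult | None
    estimates: pd.DataFrame
    manifest: RunManifest


def _default_indicators(panel_df: pd.DataFrame) -> list[tuple[str, str, str]]:
    indicators = []
    for var in ("age", "sex", "region", "smoking", "health_status"):
        if var in panel_df.columns:
            for level in sorted(panel_df[var].astype(str).unique()):
                indicators.append((f"{var}={level}", var, level))
    if "any_last12m_nmu" in panel_df.columns:
        indicators.append(("any_last12m_nmu", "any_last12m_nmu", "True"))
    return indicators


def run_pipeline(
    panel: Panel,
    targets: MarginalTargets,
    benchmarks: BenchmarkSet | None,
    options: PipelineOptions | None = None,
) -> PipelineResult:
    """Run screening, weighting and estimation over a loaded panel."""
    options = options or PipelineOptions()
    if panel.n == 0:
        raise PanelValidationError("no respondents")
    manifest = RunManifest()

    screened = screen(panel, options.cuts)
    n_excl = screened.n_excluded
    manifest.log_stage("screen", panel.n, panel.n - n_excl,
                       cuts=vars(options.cuts) if hasattr(options.cuts, "__dict__")
                       else options.cuts.__dict__)
    excluded_ids = set(screened.excluded_ids)
    kept = panel.respondents.loc[
        ~panel.respondents[RESPONDENT_ID].isin(excluded_ids)
    ].reset_index(drop=True)
    if kept.empty:
        raise PanelValidationError("screening excluded every respondent")

    scheme_search = None
    raking_result = None
    if options.scheme is None and benchmarks is not None:
        scheme_search = evaluate_schemes(
            kept, targets, benchmarks,
            selection_slack_pp=options.selection_slack_pp,
            tol_marginal=options.tol_marginal, max_iter=options.max_iter,
        )
        weights = scheme_search.weights[scheme_search.selected.name]
        scheme = scheme_search.selected
        manifest.log_stage("evaluate_schemes", len(kept), len(kept),
                           n_schemes=len(scheme_search.table),
                           selected=scheme.name)
    else:
        scheme = WeightingScheme(tuple(options.scheme or ()))
        if scheme.variables:
            raking_result = rake(kept, scheme.variables, targets,
                                 tol_marginal=options.tol_marginal,
                                 max_iter=options.max_iter)
            weights = raking_result.weights
        else:
            weights = np.full(len(kept), targets.N / len(kept))
        manifest.log_stage("weigh", len(kept), len(kept), scheme=scheme.name)
    logger.info("weight diagnostics: %s", weight_diagnostics(weights))

    indicators = options.indicators or _default_indicators(kept)
    estimates = estimate_table(kept, weights, indicators, N=targets.N)
    manifest.log_stage("estimate", len(kept), len(estimates),
                       n_indicators=len(indicators))

    result = PipelineResult(
        screen_result=screened,
        kept=kept,
        weights=weights,
        raking=raking_result,
        scheme_search=scheme_search,
        estimates=estimates,
        manifest=manifest,
    )
    if options.outdir is not None:
        _write_outputs(result, options.outdir)
    return result


def _write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.screen_result.report.to_csv(outdir / "exclusion_report.csv",
                                       index=False)
    weights = pd.DataFrame({
        RESPONDENT_ID: result.kept[RESPONDENT_ID],
        "weight": result.weights,
    })
    weights.to_csv(outdir / "weights.csv", index=False)
    if result.scheme_search is not None:
        result.scheme_search.table.to_csv(outdir / "schemes.csv", index=False)
    result.estimates.to_csv(outdir / "estimates.csv", index=False)
    result.manifest.write(outdir / "run_manifest.yaml")
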