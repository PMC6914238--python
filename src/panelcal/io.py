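"""Readers and writers for panel artifacts and configuration.

All artifacts are plain CSV (comma-separated, UTF-8, header row) or
human-editable YAML.  Endorsement matrices are stored wide — one file per
horizon, one column per item — with each respondent's presentation order
kept as a single ``|``-joined column of item ids.  A long-format converter
is provided for interoperability.

Proportions are carried on the 0-1 scale everywhere inside the package;
percentages appear only at report boundaries.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .types import (
    Benchmark,
    BenchmarkSet,
    EndorsementMatrix,
    ItemCatalog,
    MarginalTargets,
    Panel,
    PanelValidationError,
    ParticipationCounts,
    RESPONDENT_ID,
    SchemaError,
)

logger = logging.getLogger("panelcal")
if not logger.handlers:  # default: stage logs to stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

ORDER_COLUMN = "presentation_order"
ORDER_SEP = "|"


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys."""


def _strict_mapping(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise SchemaError(f"duplicate key {key!r} in config")
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_mapping
)


def load_strict_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.load(fh, Loader=_StrictLoader)


# ---------------------------------------------------------------------------
# Endorsement matrices
# ---------------------------------------------------------------------------

def matrix_to_frame(matrix: EndorsementMatrix) -> pd.DataFrame:
    order_strings = [
        ORDER_SEP.join(matrix.items[k] for k in row)
        for row in matrix.presentation_order
    ]
    frame = pd.DataFrame(matrix.values, columns=matrix.items)
    frame.insert(0, RESPONDENT_ID, matrix.respondents)
    frame.insert(1, ORDER_COLUMN, order_strings)
    return frame


def frame_to_matrix(frame: pd.DataFrame, horizon: str) -> EndorsementMatrix:
    for col in (RESPONDENT_ID, ORDER_COLUMN):
        if col not in frame.columns:
            raise SchemaError(f"endorsement file missing column {col!r}")
    items = [c for c in frame.columns if c not in (RESPONDENT_ID, ORDER_COLUMN)]
    idx = {it: k for k, it in enumerate(items)}
    respondents = list(frame[RESPONDENT_ID].astype(str))
    raw = frame[items].to_numpy()
    numeric = pd.DataFrame(raw).apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = ~np.isin(numeric, (0, 1)) | np.isnan(numeric)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise PanelValidationError(
            f"non-binary endorsement cell at row {i} "
            f"(respondent {respondents[i]!r}), column {items[j]!r}: {raw[i, j]!r}"
        )
    order = np.empty((len(respondents), len(items)), dtype=np.int32)
    for i, s in enumerate(frame[ORDER_COLUMN]):
        try:
            order[i] = [idx[tok] for tok in str(s).split(ORDER_SEP)]
        except (KeyError, ValueError) as exc:
            raise PanelValidationError(
                f"invalid presentation order for respondent "
                f"{respondents[i]!r}: {exc}"
            ) from exc
    return EndorsementMatrix(
        horizon=horizon,
        respondents=respondents,
        items=items,
        values=numeric.astype(np.uint8),
        presentation_order=order,
    )


def endorsements_to_long(matrix: EndorsementMatrix) -> pd.DataFrame:
    """Wide matrix -> long (respondent_id, item_id, endorsed, position)."""
    n, m = matrix.values.shape
    position = np.empty_like(matrix.presentation_order)
    np.put_along_axis(
        position, matrix.presentation_order, np.arange(m)[None, :].repeat(n, 0), axis=1
    )
    return pd.DataFrame(
        {
            RESPONDENT_ID: np.repeat(matrix.respondents, m),
            "item_id": np.tile(matrix.items, n),
            "endorsed": matrix.values.ravel(),
            "position": position.ravel(),
        }
    )


def long_to_matrix(long: pd.DataFrame, horizon: str) -> EndorsementMatrix:
    wide = long.pivot(index=RESPONDENT_ID, columns="item_id", values="endorsed")
    pos = long.pivot(index=RESPONDENT_ID, columns="item_id", values="position")
    respondents = list(wide.index.astype(str))
    items = list(wide.columns)
    order = np.argsort(pos.to_numpy(), axis=1).astype(np.int32)
    return EndorsementMatrix(
        horizon=horizon,
        respondents=respondents,
        items=items,
        values=wide.to_numpy().astype(np.uint8),
        presentation_order=order,
    )


# ---------------------------------------------------------------------------
# Panel read/write
# ---------------------------------------------------------------------------

def write_panel(panel: Panel, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel.respondents.to_csv(outdir / "respondents.csv", index=False)
    panel.catalog.table.to_csv(outdir / "catalog.csv", index=False)
    panel.timelines.to_csv(outdir / "timelines.csv", index=False)
    for horizon, matrix in panel.matrices.items():
        matrix_to_frame(matrix).to_csv(
            outdir / f"endorsements_{horizon}.csv", index=False
        )


def read_panel(
    respondent_path: str | Path | None = None,
    endorsement_paths: Mapping[str, str | Path] | None = None,
    catalog_path: str | Path | None = None,
    timeline_path: str | Path | None = None,
    directory: str | Path | None = None,
) -> Panel:
    """Load and validate a panel from CSV files.

    Either pass explicit paths, or ``directory`` holding the conventional
    file names written by :func:`write_panel`.
    """
    if directory is not None:
        directory = Path(directory)
        respondent_path = directory / "respondents.csv"
        catalog_path = directory / "catalog.csv"
        timeline_path = directory / "timelines.csv"
        endorsement_paths = {
            p.stem.removeprefix("endorsements_"): p
            for p in sorted(directory.glob("endorsements_*.csv"))
        }
    if respondent_path is None or catalog_path is None or not endorsement_paths:
        raise SchemaError("respondent, catalog and endorsement paths are required")
    respondents = pd.read_csv(respondent_path, dtype={RESPONDENT_ID: str})
    catalog = ItemCatalog(pd.read_csv(catalog_path))
    matrices = {
        horizon: frame_to_matrix(pd.read_csv(path), horizon)
        for horizon, path in endorsement_paths.items()
    }
    if timeline_path is not None and Path(timeline_path).exists():
        timelines = pd.read_csv(timeline_path, dtype={RESPONDENT_ID: str})
        if timelines.empty:
            timelines = empty_timelines()
    else:
        timelines = empty_timelines()
    panel = Panel(
        respondents=respondents,
        matrices=matrices,
        catalog=catalog,
        timelines=timelines,
    )
    panel.validate()
    return panel


def empty_timelines() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[RESPONDENT_ID, "drug_class", "first_use_period", "last_use_period"]
    )


# ---------------------------------------------------------------------------
# Targets / benchmarks configuration
# ---------------------------------------------------------------------------

def _coerce_levels(var: str, spec) -> dict[str, float]:
    """Accept either a mapping level->proportion or a list of
    {level, proportion} records (the list form preserves duplicate-level
    detection through YAML)."""
    if isinstance(spec, dict):
        return {str(k): float(v) for k, v in spec.items()}
    levels: dict[str, float] = {}
    for rec in spec:
        level = str(rec["level"])
        if level in levels:
            raise SchemaError(f"duplicate category {level!r} for variable {var!r}")
        levels[level] = float(rec["proportion"])
    return levels


def read_targets(config_path: str | Path, renorm_tol: float = 1e-6) -> MarginalTargets:
    """Read marginal raking targets from YAML.

    Proportions are renormalized only when their sum is within
    ``renorm_tol`` of 1; anything further off is an error.
    """
    raw = load_strict_yaml(config_path)
    for key in ("N", "variables"):
        if key not in raw:
            raise SchemaError(f"targets config missing key {key!r}")
    variables: dict[str, dict[str, float]] = {}
    for var, spec in raw["variables"].items():
        levels = _coerce_levels(var, spec)
        total = sum(levels.values())
        if abs(total - 1.0) > renorm_tol:
            raise PanelValidationError(
                f"target proportions for {var!r} sum to {total:.6g}, not 1"
            )
        variables[var] = {k: v / total for k, v in levels.items()}
    targets = MarginalTargets(
        N=float(raw["N"]), variables=variables, source=str(raw.get("source", ""))
    )
    targets.validate(tol=1e-9)
    return targets


def write_targets(targets: MarginalTargets, path: str | Path) -> None:
    doc = {
        "N": targets.N,
        "source": targets.source,
        "variables": {
            var: [{"level": k, "proportion": float(v)} for k, v in props.items()]
            for var, props in targets.variables.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_benchmarks(config_path: str | Path) -> BenchmarkSet:
    """Read a benchmark set from YAML (``benchmarks:`` list of records)."""
    raw = load_strict_yaml(config_path)
    if "benchmarks" not in raw:
        raise SchemaError("benchmark config missing key 'benchmarks'")
    benchmarks = []
    for rec in raw["benchmarks"]:
        benchmarks.append(
            Benchmark(
                benchmark_id=str(rec["benchmark_id"]),
                variable=str(rec["variable"]),
                level=str(rec["level"]),
                value_pct=float(rec["value_pct"]),
                source=str(rec.get("source", "")),
                included=bool(rec.get("included", True)),
                group=str(rec.get("group", "nonhealth")),
            )
        )
    bset = BenchmarkSet(benchmarks)
    bset.validate()
    return bset


def write_benchmarks(bset: BenchmarkSet, path: str | Path) -> None:
    doc = {
        "benchmarks": [
            {
                "benchmark_id": b.benchmark_id,
                "variable": b.variable,
                "level": b.level,
                "value_pct": b.value_pct,
                "source": b.source,
                "included": b.included,
                "group": b.group,
            }
            for b in bset
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_participation_counts(path: str | Path) -> ParticipationCounts:
    raw = load_strict_yaml(path)
    return ParticipationCounts(
        invited=int(raw["invited"]),
        initiated=int(raw["initiated"]),
        eligible_complete=int(raw["eligible_complete"]),
        excluded=int(raw["excluded"]),
    )


# ---------------------------------------------------------------------------
# Run manifest / stage logging
# ---------------------------------------------------------------------------

class RunManifest:
    """Accumulates per-stage logs (n in/out, parameters) for reproducibility."""

    def __init__(self) -> None:
        self.stages: list[dict] = []

    def log_stage(self, name: str, n_in: int, n_out: int, **params) -> None:
        entry = {"stage": name, "n_in": int(n_in), "n_out": int(n_out),
                 "params": params}
        self.stages.append(entry)
        logger.info("stage %s: n_in=%d n_out=%d params=%s", name, n_in, n_out, params)

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"stages": self.stages}, fh, sort_keys=False)
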