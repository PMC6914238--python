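"""Loaders for the bundled published reference tables.

These are the published figures that ship with the package: the national
marginal targets for the core demographics, the benchmark relative-
difference table, the opioid dispensing-volume attrition table, and the
fielding flow counters.  They serve as worked-example inputs and as
regression anchors; no survey microdata are bundled (the underlying
respondent-level data are proprietary).
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .io import read_participation_counts, read_targets
from .types import Benchmark, BenchmarkSet, MarginalTargets, ParticipationCounts

_DATA = importlib.resources.files("panelcal") / "data"


def acs_marginal_targets() -> MarginalTargets:
    """2017 adult-population marginal targets (age, sex, region); N=252,063,800."""
    with importlib.resources.as_file(_DATA / "acs_targets.yaml") as path:
        return read_targets(path)


def participation_counts() -> ParticipationCounts:
    """Published fielding flow counters for the 2018 Q3 wave."""
    with importlib.resources.as_file(_DATA / "participation_counts.yaml") as path:
        return read_participation_counts(path)


def benchmark_table() -> pd.DataFrame:
    """The published benchmark comparison table.

    One row per benchmark level: unweighted sample n/%, weighted % with CI,
    the national benchmark % with CI, the published relative differences,
    and the inclusion flag (reference/complement levels carry 0 and do not
    enter the 26-benchmark average).
    """
    with importlib.resources.as_file(_DATA / "benchmark_table.csv") as path:
        return pd.read_csv(path)


def benchmark_set() -> BenchmarkSet:
    """The 26-benchmark set (plus excluded reference levels) as a
    :class:`BenchmarkSet`, values on the percentage scale."""
    table = benchmark_table()
    benchmarks = [
        Benchmark(
            benchmark_id=f"{row.variable}:{row.level}",
            variable=row.variable,
            level=row.level,
            value_pct=float(row.benchmark_pct),
            source=row.source,
            included=bool(row.included),
            group=row.group,
        )
        for row in table.itertuples()
    ]
    bset = BenchmarkSet(benchmarks)
    bset.validate()
    return bset


def opioid_attrition_table() -> pd.DataFrame:
    """Published opioid-ingredient endorsement counts before/after the
    careless-response exclusions, with national dispensing volumes
    (dosage units)."""
    with importlib.resources.as_file(_DATA / "opioid_dispensing.csv") as path:
        return pd.read_csv(path)
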