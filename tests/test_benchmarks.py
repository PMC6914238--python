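"""Relative-difference scoring and the weighting-scheme search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panelcal import synthetic
from panelcal.benchmarks import (
    WeightingScheme,
    average_relative_difference,
    enumerate_schemes,
    evaluate_schemes,
    relative_difference,
)
from panelcal.types import Benchmark, BenchmarkSet, PanelValidationError


def test_relative_difference_published_examples():
    assert relative_difference(83.60, 75.90) == pytest.approx(10.14, abs=0.005)
    assert relative_difference(82.20, 75.90) == pytest.approx(8.30, abs=0.005)
    assert relative_difference(5.0, 5.0) == 0.0
    with pytest.raises(PanelValidationError):
        relative_difference(5.0, 0.0)


@given(
    st.floats(0.0, 100.0),
    st.floats(0.01, 100.0),
)
@settings(max_examples=200, deadline=None)
def test_relative_difference_is_scale_invariant(p, pi):
    on_pct = relative_difference(p, pi)
    on_props = relative_difference(p / 100.0, pi / 100.0)
    assert on_props == pytest.approx(on_pct, rel=1e-9, abs=1e-9)


def test_average_relative_difference_basics():
    assert average_relative_difference([10.0, 20.0, 30.0]) == pytest.approx(20.0)
    assert average_relative_difference([7.7]) == pytest.approx(7.7)
    with pytest.raises(PanelValidationError):
        average_relative_difference([])


@pytest.mark.parametrize(
    "n_optional, expected",
    [(5, 33), (0, 2), (2, 5)],
)
def test_enumerate_scheme_counts(n_optional, expected):
    optional = tuple(f"opt{i}" for i in range(n_optional))
    schemes = enumerate_schemes(("age", "sex", "region"), optional)
    assert len(schemes) == expected
    assert schemes[0].variables == ()  # unweighted baseline first
    assert schemes[1].variables == ("age", "sex", "region")  # core-only next
    assert len({s.name for s in schemes}) == expected


def test_core_optional_overlap_rejected():
    with pytest.raises(PanelValidationError, match="overlap"):
        enumerate_schemes(("age", "sex"), ("sex",))


def _self_benchmarks(panel_df, variables):
    """Benchmarks equal to the unweighted sample estimates."""
    benchmarks = []
    for var in variables:
        for level, frac in panel_df[var].value_counts(normalize=True).items():
            benchmarks.append(Benchmark(
                f"{var}:{level}", var, level, 100.0 * frac
            ))
    return BenchmarkSet(benchmarks)


def test_targets_and_benchmarks_at_sample_values_give_zero_dbar(clean_panel):
    design, panel, _ = clean_panel
    df = panel.respondents
    variables = ("sex", "region")
    sample_targets = {
        var: df[var].value_counts(normalize=True).to_dict() for var in variables
    }
    from panelcal.types import MarginalTargets
    targets = MarginalTargets(N=1e6, variables=sample_targets)
    schemes = [WeightingScheme(()), WeightingScheme(variables)]
    result = evaluate_schemes(df, targets, _self_benchmarks(df, variables),
                              schemes)
    assert np.allclose(result.table["D_bar"], 0.0, atol=1e-6)


def test_baseline_row_always_present_and_consistent(clean_panel):
    design, panel, _ = clean_panel
    df = panel.respondents
    targets = design.marginal_targets()
    benchmarks = BenchmarkSet([
        Benchmark(f"smoking:{lev}", "smoking", lev, 100.0 * p)
        for lev, p in design.demo_targets["smoking"].items()
    ])
    schemes = enumerate_schemes(("age", "sex", "region"), ("smoking",))
    result = evaluate_schemes(df, targets, benchmarks, schemes)
    table = result.table
    assert "unweighted" in set(table["scheme"])
    # baseline D-bar equals the average of unweighted per-benchmark D_i
    base_detail = result.per_benchmark.query(
        "scheme == 'unweighted' and included"
    )
    expected = average_relative_difference(base_detail["D_i"])
    got = float(table.loc[table["scheme"] == "unweighted", "D_bar"].iloc[0])
    assert got == pytest.approx(expected, rel=1e-12)
    assert (table.loc[~table["failed"], "D_bar"] >= 0).all()


def test_planted_bias_scheme_dominance():
    """When selection bias is planted on one variable only, every scheme
    containing it beats every scheme without it on average relative
    difference."""
    design = synthetic.PanelDesign(
        n_target=4000, seed=31,
        stratum_fill={"male": 1.0, "female": 1.0},
        bias_profile={"smoking": {"current": 3.0, "former": 1.3, "never": 0.7}},
    )
    panel, _ = synthetic.generate_panel(design, None, seed=31)
    targets = design.marginal_targets()
    benchmarks = BenchmarkSet([
        Benchmark(f"smoking:{lev}", "smoking", lev, 100.0 * p, group="health")
        for lev, p in design.demo_targets["smoking"].items()
    ])
    schemes = enumerate_schemes(
        ("age", "sex", "region"), ("smoking", "activity_limitation")
    )
    result = evaluate_schemes(panel.respondents, targets, benchmarks, schemes)
    table = result.table
    with_bias_var = table[table["scheme"].str.contains("smoking")]
    without = table[~table["scheme"].str.contains("smoking")]
    assert with_bias_var["D_bar"].max() < without["D_bar"].min()
    assert "smoking" in result.selected.variables
    # weighting reduces the benchmark bias relative to the unweighted run
    reduction = table.loc[table["selected"], "reduction_vs_unweighted_pct"]
    assert float(reduction.iloc[0]) > 50.0


def test_unestimable_benchmark_raises(clean_panel):
    design, panel, _ = clean_panel
    targets = design.marginal_targets()
    benchmarks = BenchmarkSet([
        Benchmark("ghost", "no_such_column", "x", 10.0)
    ])
    with pytest.raises(PanelValidationError, match="no_such_column"):
        evaluate_schemes(panel.respondents, targets, benchmarks,
                         [WeightingScheme(())])
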