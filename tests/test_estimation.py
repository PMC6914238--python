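"""Weighted proportions, the estimate table, and the order-effect
diagnostic."""

import numpy as np
import pandas as pd
import pytest

from panelcal import synthetic
from panelcal.estimation import (
    estimate_table,
    order_effect_diagnostic,
    weighted_proportion,
)
from panelcal.raking import rake
from panelcal.types import EndorsementMatrix, PanelValidationError


def test_equal_weights_reduce_to_srs_closed_form():
    rng = np.random.default_rng(5)
    n, k = 40, 12
    y = np.zeros(n)
    y[:k] = 1
    rng.shuffle(y)
    est = weighted_proportion(y, np.full(n, 7.3))
    p = k / n
    assert est.p == pytest.approx(p)
    assert est.se ** 2 == pytest.approx(p * (1 - p) / (n - 1), abs=1e-12)


def test_degenerate_indicators():
    est = weighted_proportion(np.ones(10), np.full(10, 2.0))
    assert est.p == 1.0 and est.se == 0.0
    single = weighted_proportion(np.array([1.0]), np.array([1.0]))
    assert np.isnan(single.se) and np.isnan(single.lo)


def test_linearized_se_agrees_with_bootstrap():
    rng = np.random.default_rng(17)
    n = 300
    w = rng.lognormal(0.0, 0.8, n)
    y = (rng.random(n) < 0.3).astype(float)
    est = weighted_proportion(y, w)
    B = 10_000
    idx = rng.integers(0, n, size=(B, n))
    W, Y = w[idx], y[idx]
    boots = (W * Y).sum(axis=1) / W.sum(axis=1)
    assert est.se == pytest.approx(boots.std(ddof=1), rel=0.05)


def test_ci_truncated_to_unit_interval():
    y = np.r_[np.ones(2), np.zeros(48)]
    est = weighted_proportion(y, np.ones(50))
    assert 0.0 <= est.lo <= est.p <= est.hi <= 1.0


def test_estimate_table_aligns_scheme_variables_with_targets(clean_panel):
    design, panel, _ = clean_panel
    targets = design.marginal_targets()
    variables = ("age", "sex", "region")
    result = rake(panel.respondents, variables, targets)
    indicators = [
        (f"{var}={lev}", var, lev)
        for var in variables for lev in targets.variables[var]
    ]
    table = estimate_table(panel.respondents, result.weights, indicators,
                           N=targets.N)
    for row in table.itertuples():
        target_pct = 100.0 * targets.variables[row.variable][row.level]
        assert abs(row.weighted_pct - target_pct) <= 0.1 + 1e-9
    # weighted counts over an exhaustive variable partition sum to N
    ages = table[table["variable"] == "age"]
    assert ages["weighted_count"].sum() == pytest.approx(targets.N, rel=1e-6)


def test_empty_indicator_and_suppression(clean_panel):
    design, panel, _ = clean_panel
    df = panel.respondents.copy()
    df["nobody"] = "no"
    table = estimate_table(df, np.ones(len(df)), [("nobody", "nobody", "yes")])
    row = table.iloc[0]
    assert row.unweighted_n == 0
    assert row.weighted_pct == 0.0 and row.ci_lo_pct == 0.0
    assert row.suppressed
    with pytest.raises(PanelValidationError, match="unknown"):
        estimate_table(df, np.ones(len(df)), [("x", "ghost", "yes")])


def test_weighting_moves_biased_prevalence_toward_truth():
    """With selection bias planted on smoking and drug use elevated among
    smokers, raking on smoking strictly reduces the error of the
    last-12-month NMU prevalence against the generating truth."""
    design = synthetic.PanelDesign(
        n_target=6000, seed=23,
        stratum_fill={"male": 1.0, "female": 1.0},
        bias_profile={"smoking": {"current": 3.5, "former": 1.3, "never": 0.6}},
        use_multipliers={"smoking": {"current": 2.6, "former": 1.2,
                                     "never": 0.72}},
    )
    panel, _ = synthetic.generate_panel(design, None, seed=23)
    truth = design.true_prevalence_last12m_any()
    df = panel.respondents
    y = df["any_last12m_nmu"].to_numpy().astype(float)
    unweighted = y.mean()
    targets = design.marginal_targets()
    result = rake(df, ("age", "sex", "region", "smoking"), targets)
    weighted = weighted_proportion(y, result.weights).p
    assert unweighted > truth  # bias inflates the raw estimate
    assert abs(weighted - truth) < abs(unweighted - truth)


def test_nominal_coverage_under_srs():
    """Equal-weight 95% intervals cover Bernoulli(p) truth in >=93% of
    seeded replicates for p in {0.05, 0.3}."""
    rng = np.random.default_rng(2718)
    n, B = 1000, 1000
    for p in (0.05, 0.3):
        covered = 0
        draws = rng.random((B, n)) < p
        for b in range(B):
            est = weighted_proportion(draws[b].astype(float), np.ones(n))
            covered += est.lo <= p <= est.hi
        assert covered / B >= 0.93


# ---------------------------------------------------------------------------
# Order-effect diagnostic
# ---------------------------------------------------------------------------

def _null_design(seed):
    return synthetic.PanelDesign(
        n_target=220, seed=seed, lifetime_prevalences=0.10,
        stratum_fill={"male": 1.0, "female": 1.0}, bias_profile={},
    )


def test_order_effect_type_one_error_near_nominal():
    """With constant endorsement probability the positional trend test
    rejects at roughly the nominal 5% rate across seeded generator runs."""
    rejections = 0
    runs = 200
    for seed in range(runs):
        panel, _ = synthetic.generate_panel(_null_design(seed), None,
                                            seed=10_000 + seed)
        res = order_effect_diagnostic(panel.matrices["lifetime"])
        rejections += res.pvalue < 0.05
    rate = rejections / runs
    assert 0.005 <= rate <= 0.11  # ~3.5 binomial SDs around 0.05


def test_order_effect_power_against_planted_decay():
    """A planted linear decay of endorsement probability with position is
    detected as a negative trend in >=90% of runs."""
    detected = 0
    runs = 50
    for seed in range(runs):
        design = synthetic.PanelDesign(
            n_target=400, seed=seed, lifetime_prevalences=0.10,
            position_effect=0.6,
            stratum_fill={"male": 1.0, "female": 1.0}, bias_profile={},
        )
        panel, _ = synthetic.generate_panel(design, None, seed=20_000 + seed)
        res = order_effect_diagnostic(panel.matrices["lifetime"])
        detected += (res.rho < 0) and (res.pvalue < 0.05)
    assert detected / runs >= 0.9


def test_per_position_rates_within_binomial_noise():
    panel, _ = synthetic.generate_panel(_null_design(7), None, seed=7)
    res = order_effect_diagnostic(panel.matrices["lifetime"])
    rates = res.rates["endorsement_rate"].to_numpy()
    overall = rates.mean()
    sd = np.sqrt(overall * (1 - overall) / panel.n)
    assert (np.abs(rates - overall) <= 3 * sd + 1e-12).all()


def test_single_position_matrix_rejected():
    matrix = EndorsementMatrix(
        "lifetime", ["r1", "r2"], ["only"],
        np.array([[1], [0]], dtype=np.uint8),
        np.zeros((2, 1), dtype=np.int32),
    )
    with pytest.raises(PanelValidationError):
        order_effect_diagnostic(matrix)
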