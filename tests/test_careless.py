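"""Exclusion criteria, validation metrics, and the attrition analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import panelcal as pc
from panelcal import fixtures, synthetic
from panelcal.careless import (
    alternation_consistency,
    attrition_correlation,
    contradiction_count,
    endorsement_attrition_analysis,
    longest_positive_run,
    mahalanobis_distances,
    relative_decrease,
)
from panelcal.types import CutPoints, PanelValidationError

from _oracles import pearson_oracle, spearman_oracle


# ---------------------------------------------------------------------------
# LongString
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "responses, labels, expected",
    [
        (np.ones(42), np.repeat(["a", "b", "c", "d"], [18, 10, 8, 6]), (42, 4)),
        (np.tile([1, 0], 21), np.repeat(["a", "b"], 21), (1, 1)),
        (np.zeros(42), np.repeat(["a", "b"], 21), (0, 0)),
        # 22 consecutive endorsements straddling two classes
        (np.r_[np.zeros(10), np.ones(22), np.zeros(10)],
         np.repeat(["a", "b"], 21), (22, 2)),
    ],
)
def test_longest_run_examples(responses, labels, expected):
    assert longest_positive_run(responses, labels) == expected


def test_longest_run_ties_take_earliest_run():
    x = np.r_[np.ones(5), 0, np.ones(5)]
    labels = np.array(list("aaaaa") + ["a"] + list("bbbbb"))
    run, span = longest_positive_run(x, labels)
    assert (run, span) == (5, 1)  # earliest maximal run spans only "a"


def test_longest_run_length_mismatch_raises():
    with pytest.raises(PanelValidationError):
        longest_positive_run(np.ones(5), np.array(["a"] * 4))


@given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
@settings(max_examples=200, deadline=None)
def test_longest_run_matches_enumeration_oracle(bits):
    x = np.array(bits)
    labels = np.array(["c"] * len(bits))
    # oracle: longest all-ones substring by explicit enumeration
    best = 0
    for i in range(len(bits)):
        for j in range(i, len(bits)):
            if all(bits[i:j + 1]):
                best = max(best, j - i + 1)
    assert longest_positive_run(x, labels)[0] == best


# ---------------------------------------------------------------------------
# Even-odd / alternation consistency
# ---------------------------------------------------------------------------

def test_strict_alternation_is_perfectly_anticonsistent():
    r = alternation_consistency(np.tile([1, 0], 4))
    assert r == pytest.approx(-1.0)
    cuts = CutPoints()
    assert r < cuts.c2_threshold


@pytest.mark.parametrize("vec", [np.zeros(20), np.ones(20)])
def test_constant_vectors_are_undefined_never_flagged(vec):
    assert np.isnan(alternation_consistency(vec))


def test_short_vectors_are_undefined():
    assert np.isnan(alternation_consistency(np.array([1, 0, 1])))


def test_serial_consistency_matches_pearson_oracle():
    rng = np.random.default_rng(2024)
    checked = 0
    for _ in range(1000):
        x = rng.integers(0, 2, size=42)
        r = alternation_consistency(x)
        if np.isnan(r):
            continue
        assert r == pytest.approx(pearson_oracle(x[:-1], x[1:]), abs=1e-12)
        checked += 1
    assert checked > 900


def test_split_mode_pairs_odd_against_even_positions():
    x = np.array([1, 0, 0, 0, 1, 1, 0, 1, 1, 0])
    odd, even = x[0::2], x[1::2]
    expected = pearson_oracle(odd, even)
    assert alternation_consistency(x, mode="split") == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Overendorsement
# ---------------------------------------------------------------------------

def test_total_endorsed_and_cut_boundary():
    assert pc.total_endorsed(np.zeros(298)) == 0
    assert not pc.flag_overendorser(0, 35)
    assert pc.flag_overendorser(298, 35)
    assert pc.flag_overendorser(35, 35)  # the conservative cut is inclusive
    assert not pc.flag_overendorser(34, 35)
    assert not pc.flag_overendorser(3, 35)  # the included-respondent median


# ---------------------------------------------------------------------------
# Mahalanobis
# ---------------------------------------------------------------------------

def test_mahalanobis_hand_computed_two_item_example():
    X = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [1, 0]], dtype=float)
    mean = X.mean(axis=0)
    d = X - mean
    # explicit 2x2 covariance and its closed-form inverse
    s11 = (d[:, 0] ** 2).sum() / 4
    s22 = (d[:, 1] ** 2).sum() / 4
    s12 = (d[:, 0] * d[:, 1]).sum() / 4
    det = s11 * s22 - s12 ** 2
    inv = np.array([[s22, -s12], [-s12, s11]]) / det
    expected = np.sqrt(np.einsum("ij,jk,ik->i", d, inv, d))
    np.testing.assert_allclose(mahalanobis_distances(X), expected, atol=1e-12)


def test_respondent_at_the_mean_has_zero_distance():
    X = np.array([[1.0, 2.0], [3.0, 4.0], [2.0, 3.0]])
    assert mahalanobis_distances(X)[2] == pytest.approx(0.0, abs=1e-9)


def test_mahalanobis_chi_square_expectation():
    """For multivariate normal data the mean squared distance is ~p (the
    chi-square expectation; exactly p(n-1)/n with the sample covariance)."""
    rng = np.random.default_rng(8)
    n, p = 2000, 10
    X = rng.standard_normal((n, p)) @ rng.standard_normal((p, p))
    d = mahalanobis_distances(X)
    assert (d ** 2).mean() == pytest.approx(p * (n - 1) / n, rel=1e-9)
    assert abs((d ** 2).mean() - p) < 0.1


def test_mahalanobis_singular_matrix_uses_ridge():
    X = np.array([[0, 0.0], [0, 1], [0, 0], [0, 1]])  # first item constant
    d = mahalanobis_distances(X)
    assert np.isfinite(d).all() and (d >= 0).all()
    with pytest.raises(PanelValidationError):
        mahalanobis_distances(np.zeros((4, 2)))


# ---------------------------------------------------------------------------
# Contradictions
# ---------------------------------------------------------------------------

def test_contradiction_counting():
    timelines = pd.DataFrame({
        "respondent_id": ["r1", "r1", "r2"],
        "drug_class": ["pain_relievers", "sedatives", "pain_relievers"],
        "first_use_period": ["past_12m", "past_30d", "1_10y_ago"],
        "last_use_period": ["past_12m", "over_10y_ago", "past_30d"],
    })
    counts = contradiction_count(timelines)
    assert counts["r1"] == 1  # last use predates first use once
    assert counts["r2"] == 0
    with pytest.raises(PanelValidationError):
        contradiction_count(timelines.assign(first_use_period="yesterday"))


# ---------------------------------------------------------------------------
# screen()
# ---------------------------------------------------------------------------

def test_clean_panel_has_near_zero_false_positives(clean_panel):
    _, panel, _ = clean_panel
    result = pc.screen(panel)
    assert result.summary["pct_excluded"] <= 0.5
    assert result.report["excluded"].equals(
        result.report[["c1", "c2", "c3", "c4"]].any(axis=1)
    )


def test_all_straightliner_toy_panel(tiny_unbiased_design):
    profiles = [synthetic.CarelessProfile("straightliner", 1.0)]
    panel, _ = synthetic.generate_panel(tiny_unbiased_design, profiles, seed=3)
    result = pc.screen(panel)
    assert result.n_excluded == panel.n
    assert result.summary["criterion_counts"]["c1"] == panel.n


def test_planted_profiles_recovered(default_panel):
    _, panel, truth = default_panel
    result = pc.screen(panel)
    merged = result.report.merge(truth, on="respondent_id")
    for kind in ("straightliner", "alternator_rx", "alternator_illicit",
                 "overendorser"):
        sub = merged[merged["profile"] == kind]
        assert len(sub) > 0
        assert sub["excluded"].mean() >= 0.95
    honest = merged[merged["profile"] == "honest"]
    assert honest["excluded"].mean() <= 0.005


def test_excluded_group_separates_on_validation_metrics(default_panel):
    """Excluded respondents show larger Mahalanobis distances and far more
    contradictory timeline answers than included respondents."""
    _, panel, _ = default_panel
    summary = pc.screen(panel).summary
    exc, inc = summary["excluded_stats"], summary["included_stats"]
    assert exc["mahalanobis_mean"] > 2 * inc["mahalanobis_mean"]
    assert exc["contradiction_pct"] > 10 * max(inc["contradiction_pct"], 1.0)


def test_cut_point_monotonicity(default_panel):
    """Lowering the overendorsement cut, or moving a correlation threshold
    toward zero, can only grow the excluded set."""
    _, panel, _ = default_panel
    base = pc.screen(panel, CutPoints()).n_excluded
    looser_c4 = pc.screen(panel, CutPoints(c4_max_endorsed=20)).n_excluded
    looser_c2 = pc.screen(panel, CutPoints(c2_threshold=-0.3)).n_excluded
    assert looser_c4 >= base
    assert looser_c2 >= base


def test_fast_intro_metric_is_reported_but_never_flags(tiny_unbiased_design):
    profiles = [synthetic.CarelessProfile("speeder", 0.10, time_scale=0.05)]
    panel, truth = synthetic.generate_panel(tiny_unbiased_design, profiles, seed=6)
    result = pc.screen(panel)
    merged = result.report.merge(truth, on="respondent_id")
    speeders = merged[merged["profile"] == "speeder"]
    assert result.summary["n_fast_intro"] > 0
    assert speeders["fast_intro"].mean() > 0.5
    # timing alone never excludes
    assert not (speeders["fast_intro"] & ~speeders[["c1", "c2", "c3", "c4"]]
                .any(axis=1) & speeders["excluded"]).any()


# ---------------------------------------------------------------------------
# Attrition vs dispensing volume
# ---------------------------------------------------------------------------

def test_relative_decrease_published_rows():
    assert relative_decrease(905, 855) == pytest.approx(5.52, abs=0.005)
    assert relative_decrease(78, 47) == pytest.approx(39.74, abs=0.005)


def test_spearman_matches_brute_force_oracle():
    rng = np.random.default_rng(99)
    for _ in range(1000):
        x = rng.integers(0, 6, size=12)  # ties on purpose
        y = rng.integers(0, 6, size=12)
        if len(set(x)) < 2 or len(set(y)) < 2:
            continue
        table = pd.DataFrame({
            "relative_decrease_pct": x, "dispensing_volume": y
        })
        rho, _ = attrition_correlation(table)
        assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-10)


def test_monotone_decrease_gives_perfect_negative_correlation():
    table = pd.DataFrame({
        "relative_decrease_pct": [40, 30, 20, 10, 5],
        "dispensing_volume": [1e6, 2e6, 3e6, 4e6, 5e6],
    })
    rho, _ = attrition_correlation(table)
    assert rho == pytest.approx(-1.0)


def test_attrition_analysis_on_synthetic_panel(default_panel):
    _, panel, _ = default_panel
    result = pc.screen(panel)
    table, rho, p = endorsement_attrition_analysis(
        result.excluded_ids, panel.matrices["last12m"], panel.catalog
    )
    assert len(table) == 10  # the ten ingredients carrying volumes
    assert (table["n_after"] <= table["n_before"]).all()


def test_zero_before_ingredient_dropped_from_correlation():
    catalog = synthetic.build_item_catalog()
    matrix = synthetic.generate_panel(
        synthetic.PanelDesign(n_target=800, seed=5,
                              stratum_fill={"male": 1.0, "female": 1.0}),
        None, seed=5,
    )[0].matrices["last12m"]
    # zero out every product of one volumed ingredient
    cols = [k for k, it in enumerate(matrix.items) if "dihydrocodeine" in it]
    matrix.values[:, cols] = 0
    excluded = matrix.respondents[:40]  # drop a slice so decreases vary
    table, rho, _ = endorsement_attrition_analysis(excluded, matrix, catalog)
    assert np.isnan(
        table.loc[table["ingredient"] == "dihydrocodeine",
                  "relative_decrease_pct"]
    ).all()
    assert np.isfinite(rho)
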