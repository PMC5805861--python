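"""Subtraction algebra for latent-group summaries, with constructive oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genestrat.characteristics import (
    bonferroni,
    build_tables,
    chi_square_2x2,
    compare_groups,
    derive_group,
    derived_categorical,
    derived_mean,
    derived_sd,
    summarize_group,
    type2_summary,
    welch_t_from_summary,
)
from genestrat.io_config import PipelineConfig, ValidationError
from genestrat.survival import StratifiedCohort


# ---------------------------------------------------------------------------
# pure subtraction algebra


def test_derived_mean_hand_arithmetic():
    # latent members {4, 4}: high = {0, 0, 4, 4}, low = {0, 0}
    assert derived_mean(4, 2.0, 2, 0.0, 2) == 4.0


def test_derived_mean_shift_invariance():
    assert derived_mean(10, 3.5, 4, 3.5, 6) == pytest.approx(3.5)


def test_derived_mean_requires_positive_latent_n():
    with pytest.raises(ValidationError):
        derived_mean(4, 2.0, 4, 1.0, 0)
    with pytest.raises(ValidationError):
        derived_mean(4, 2.0, 2, 1.0, 3)  # n mismatch


def test_derived_sd_zero_variance_latent_group():
    high = np.array([0.0, 0.0, 4.0, 4.0])
    low = np.array([0.0, 0.0])
    sd = derived_sd(
        4, high.mean(), high.std(), 2, low.mean(), low.std(), 2, mode="moment_subtraction"
    )
    assert sd == pytest.approx(0.0, abs=1e-12)


def test_derived_sd_borrow_mode_passthrough():
    assert derived_sd(10, 27.0, 4.0, 4, 32.4, 6.0, 6, mode="borrow_t2d_sd") == 6.0


def test_derived_sd_negative_variance_errors():
    with pytest.raises(ValidationError, match="negative reconstructed variance"):
        derived_sd(4, 0.0, 10.0, 2, 0.0, 100.0, 2)


def test_constructive_oracle_recovers_latent_moments(rng):
    """For explicit latent decompositions (high = low ∪ latent), subtraction
    recovers the latent population mean and SD to numerical precision."""
    for _ in range(50):
        n_low = rng.integers(2, 40)
        n_t1d = rng.integers(2, 40)
        low = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), n_low)
        latent = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), n_t1d)
        high = np.concatenate([low, latent])
        m = derived_mean(len(high), high.mean(), n_low, low.mean(), n_t1d)
        sd = derived_sd(
            len(high), high.mean(), high.std(), n_low, low.mean(), low.std(), n_t1d
        )
        assert m == pytest.approx(latent.mean(), rel=1e-10, abs=1e-10)
        assert sd == pytest.approx(latent.std(), rel=1e-10, abs=1e-10)
        # recombination identity
        assert n_low * low.mean() + n_t1d * m == pytest.approx(len(high) * high.mean(), rel=1e-12)


def test_derived_sd_sample_convention_round_trip(rng):
    low = rng.normal(0, 1, 30)
    latent = rng.normal(2, 1.5, 20)
    high = np.concatenate([low, latent])
    sd = derived_sd(
        50, high.mean(), high.std(ddof=1), 30, low.mean(), low.std(ddof=1), 20, ddof=1
    )
    # converting in and out through population moments
    expected = np.sqrt(latent.std() ** 2 * 20 / 19)
    assert sd == pytest.approx(expected, rel=1e-10)


def test_derived_categorical(caplog):
    assert derived_categorical(537, 0) == 537
    assert derived_categorical(7, 7) == 0
    with caplog.at_level("WARNING"):
        assert derived_categorical(3, 5) == -2
    assert "negative derived category count" in caplog.text


# ---------------------------------------------------------------------------
# comparisons


def test_welch_matches_raw_data_oracle(rng):
    a = rng.normal(0, 1, 40)
    b = rng.normal(0.5, 2, 25)
    p_summary = welch_t_from_summary(40, a.mean(), a.std(), 25, b.mean(), b.std())
    p_raw = stats.ttest_ind(a, b, equal_var=False).pvalue
    assert p_summary == pytest.approx(p_raw, rel=1e-10)


def test_chi_square_dka_example():
    # ketoacidosis: 61 of 537 vs 30 of 11,696
    assert chi_square_2x2(61, 537, 30, 11_696) < 1e-4


def test_chi_square_identical_groups_p_one():
    assert chi_square_2x2(10, 100, 10, 100) == pytest.approx(1.0)


def test_chi_square_invalid_cells_reported_missing(caplog):
    with caplog.at_level("WARNING"):
        assert np.isnan(chi_square_2x2(5, 4, 1, 10))  # negative "no" cell
        assert np.isnan(chi_square_2x2(0, 10, 0, 12))  # zero marginal


def test_bonferroni_monotone_and_capped():
    assert bonferroni(0.01, 7) == pytest.approx(0.07)
    assert bonferroni(0.4, 7) == 1.0
    assert bonferroni(0.001, 7) <= bonferroni(0.002, 7)


# ---------------------------------------------------------------------------
# derived groups and report tables on a hand-built latent decomposition


def _case_row(i, group, age, bmi, insulin1, insulin_e, dka, sex="male"):
    return {
        "id": f"x{i}", "group": group, "score": 1.0 if group == "high" else -1.0,
        "sex": sex, "enrolment_age": 60.0, "has_diabetes": True,
        "age_at_diagnosis": float(age), "insulin_within_1yr": insulin1,
        "insulin_at_entry": insulin_e, "bmi": float(bmi), "dka_admission": dka,
    }


@pytest.fixture()
def toy_stratified():
    """Explicit decomposition in the 31-60 band: the high group is the low
    group's four type-2 cases plus two known latent type-1 cases."""
    rows = []
    i = 0
    low_cases = [(40, 31.0, False, False, False), (50, 33.0, False, True, False),
                 (45, 35.0, True, True, False), (55, 29.0, False, False, False)]
    latent = [(35, 24.0, True, True, True), (42, 26.0, True, True, False)]
    for age, bmi, i1, ie, dka in low_cases:
        rows.append(_case_row(i := i + 1, "low", age, bmi, i1, ie, dka))
        rows.append(_case_row(i := i + 1, "high", age, bmi, i1, ie, dka))
    for age, bmi, i1, ie, dka in latent:
        rows.append(_case_row(i := i + 1, "high", age, bmi, i1, ie, dka))
    # a young-band latent pair so table 2 exists (high-only cases, age <= 30)
    rows.append(_case_row(i := i + 1, "high", 12, 22.0, True, True, False, sex="female"))
    rows.append(_case_row(i := i + 1, "high", 20, 23.0, True, True, True, sex="female"))
    return StratifiedCohort(pd.DataFrame(rows), 0.0)


def test_derive_group_matches_hand_arithmetic(toy_stratified):
    cases = toy_stratified.data
    band = cases[cases["age_at_diagnosis"] > 30]
    dg = derive_group(
        band[band["group"] == "high"], band[band["group"] == "low"], "31-60", n_boot=50
    )
    assert dg.n_t1d == 2
    n, mean, sd = dg.summary.continuous["bmi"]
    assert mean == pytest.approx(25.0)  # latent BMIs {24, 26}
    # BMI SD is borrowed from the type 2 (low) group
    assert sd == pytest.approx(band[band["group"] == "low"]["bmi"].std(ddof=0))
    n, mean, _ = dg.summary.continuous["age_at_diagnosis"]
    assert mean == pytest.approx(38.5)  # latent ages {35, 42}
    assert dg.summary.categorical["insulin_1yr"] == (2, 2)
    assert dg.summary.categorical["dka"] == (2, 1)


def test_type2_summary_doubles_low_group(toy_stratified):
    cases = toy_stratified.data
    low = cases[(cases["group"] == "low") & (cases["age_at_diagnosis"] > 30)]
    t2 = type2_summary(low)
    assert t2.n == 8  # total - excess = 2 x low count
    n, mean, _ = t2.continuous["bmi"]
    assert n == 8 and mean == pytest.approx(32.0)
    assert t2.categorical["insulin_entry"] == (8, 4)


def test_build_tables_cells_match_hand_arithmetic(toy_stratified):
    cfg = PipelineConfig(n_bootstrap=50)
    table1, table2 = build_tables(toy_stratified, cfg)
    t1 = table1.set_index(["group", "characteristic"])
    assert t1.loc[("T1D_31-60", "bmi"), "estimate"] == pytest.approx(25.0)
    assert t1.loc[("T2D_31-60", "bmi"), "estimate"] == pytest.approx(32.0)
    assert t1.loc[("T1D_31-60", "insulin_1yr"), "estimate"] == pytest.approx(100.0)
    assert t1.loc[("T2D_31-60", "insulin_1yr"), "estimate"] == pytest.approx(25.0)
    t2 = table2.set_index(["group", "characteristic"])
    assert t2.loc[("T1D_0-30", "bmi"), "estimate"] == pytest.approx(22.5)
    assert t2.loc[("T1D_0-30", "male"), "estimate"] == pytest.approx(0.0)
    # Bonferroni column is raw x 7 capped at 1
    finite = table1["p_raw"].notna()
    np.testing.assert_allclose(
        table1.loc[finite, "p_bonferroni"],
        np.minimum(1.0, table1.loc[finite, "p_raw"] * 7),
    )


def test_compare_groups_between_summaries(toy_stratified):
    cases = toy_stratified.data
    band = cases[cases["age_at_diagnosis"] > 30]
    a = summarize_group(band[band["group"] == "high"], "high")
    b = summarize_group(band[band["group"] == "low"], "low")
    p_raw, p_adj = compare_groups(a, b, "bmi", n_tested=7)
    assert 0 <= p_raw <= 1 and p_adj == bonferroni(p_raw, 7)
    with pytest.raises(ValidationError):
        compare_groups(a, b, "not_a_characteristic")


def test_derive_group_negative_latent_n_errors(toy_stratified):
    cases = toy_stratified.data
    band = cases[cases["age_at_diagnosis"] > 30]
    with pytest.raises(ValidationError, match="not positive"):
        derive_group(band[band["group"] == "low"], band[band["group"] == "high"], "flip")


def test_simulation_recovery_of_configured_characteristics(small_stratified, small_synth):
    """Derived insulin and DKA proportions land within 3 Monte-Carlo SEs of
    the class-conditional simulation settings (young-onset band)."""
    cases = small_stratified.data
    cases = cases[cases["has_diabetes"] & (cases["age_at_diagnosis"] <= 60)]
    young = cases[cases["age_at_diagnosis"] <= 30]
    high, low = young[young["group"] == "high"], young[young["group"] == "low"]
    dg = derive_group(high, low, "0-30", n_boot=100)

    def mc_se(target, col):
        p_low = low[col].astype(float).mean() if len(low) else 0.0
        n_t2 = 2 * len(low)
        var = (
            n_t2 * ((p_low - target) ** 2 + p_low * (1 - p_low))
            + dg.n_t1d * target * (1 - target)
        ) / dg.n_t1d**2
        return np.sqrt(var)

    nt, count = dg.summary.categorical["insulin_1yr"]
    assert count / nt == pytest.approx(0.97, abs=3 * mc_se(0.97, "insulin_within_1yr") + 0.01)
    nt, count = dg.summary.categorical["dka"]
    assert count / nt == pytest.approx(0.10, abs=3 * mc_se(0.10, "dka_admission") + 0.01)
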