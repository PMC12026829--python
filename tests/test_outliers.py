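import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gsbench import (
    PValueMatrix,
    SimulationConfig,
    base_pvalues,
    combine,
    combine_invchi,
    combine_logit,
    combine_meanp,
    combine_sumz,
    compute_grm,
    flag_outliers,
    simulate_dataset,
)
from gsbench.errors import ConfigurationError, DegenerateInputError, InputError

# ------------------------------------------------------------- combiners


def test_invchi_boundary_and_chisq_oracle():
    res = combine_invchi([1.0, 1.0, 1.0])
    assert res.statistic[0] == pytest.approx(0.0)
    assert res.combined_p[0] == pytest.approx(1.0)

    res = combine_invchi([0.05, 0.05])
    # L = -2(ln .05 + ln .05); upper tail of chi^2_4 (scipy sf oracle, frozen)
    assert res.statistic[0] == pytest.approx(11.982929094215963)
    assert res.combined_p[0] == pytest.approx(0.017478661367769956, rel=1e-12)
    assert res.df_or_null == "chi2_4"


def test_logit_symmetry_and_t_oracle():
    res = combine_logit([0.5, 0.5, 0.5])
    assert res.statistic[0] == pytest.approx(0.0)
    assert res.combined_p[0] == pytest.approx(0.5)

    res = combine_logit([0.01, 0.02, 0.03])
    # T = -sum logit(p) / sqrt(K pi^2 (5K+2) / (3(5K+4))), upper tail of t_19
    assert res.statistic[0] == pytest.approx(4.025723842734265, rel=1e-12)
    assert res.combined_p[0] == pytest.approx(0.0003612345499594231, rel=1e-9)
    assert res.df_or_null == "t_19"


def test_meanp_normal_oracle():
    res = combine_meanp([0.5] * 4)
    assert res.combined_p[0] == pytest.approx(0.5)

    res = combine_meanp([0.25] * 12)
    # W = (0.5 - 0.25) * sqrt(144) = 3, upper tail of N(0,1)
    assert res.statistic[0] == pytest.approx(3.0)
    assert res.combined_p[0] == pytest.approx(0.0013498980316300933, rel=1e-9)


def test_sumz_inverse_normal_and_weight_invariance():
    res = combine_sumz([0.5] * 3)
    assert res.statistic[0] == pytest.approx(0.0)
    assert res.combined_p[0] == pytest.approx(0.5)

    res = combine_sumz([0.0228] * 4)
    assert res.statistic[0] == pytest.approx(3.99815442994354, rel=1e-10)

    p = [0.01, 0.2, 0.6]
    unit = combine_sumz(p)
    scaled = combine_sumz(p, weights=[7.0, 7.0, 7.0])
    assert scaled.statistic[0] == pytest.approx(unit.statistic[0], rel=1e-12)


@pytest.mark.parametrize("method", ["invchi", "logit", "meanp", "sumz"])
def test_combined_p_uniform_under_the_null(method, rng):
    """Independent U(0,1) base p-values give uniform combined p-values."""
    p = rng.uniform(size=(10_000, 5))
    combined = combine(method, p).combined_p
    rejection = np.mean(combined < 0.05)
    assert 0.04 <= rejection <= 0.06
    sorted_p = np.sort(combined)
    ks = np.max(np.abs(sorted_p - np.arange(1, 10_001) / 10_000))
    assert ks < 0.02


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.floats(1e-6, 1.0 - 1e-6), min_size=2, max_size=6),
    st.integers(0, 5),
    st.floats(0.05, 0.95),
)
def test_combiners_are_monotone_in_each_p(p_row, which, factor):
    """Decreasing any single base p-value never increases the combined p."""
    k = which % len(p_row)
    smaller = list(p_row)
    smaller[k] = p_row[k] * factor
    for method in ("invchi", "logit", "meanp", "sumz"):
        before = combine(method, p_row).combined_p[0]
        after = combine(method, smaller).combined_p[0]
        assert after <= before + 1e-12


def test_pvalue_validation():
    with pytest.raises(InputError):
        combine_invchi([0.0, 0.5])
    with pytest.raises(InputError):
        combine_sumz([0.5, 0.5], weights=[1.0, -1.0])
    with pytest.raises(ConfigurationError):
        combine("median", [0.5, 0.5])
    with pytest.raises(InputError):
        PValueMatrix(np.array(["a"]), np.array([[0.5, 0.5], [0.5, 0.5]]), ("x", "y"))


# ----------------------------------------------------------- flag_outliers


def test_flagging_thresholds():
    p = pd.Series([0.001, 0.2, 0.04], index=["l1", "l2", "l3"])
    none = flag_outliers(p, alpha=0.0)
    assert len(none.flagged_ids) == 0
    report = flag_outliers(p, alpha=0.05, method="invchi")
    assert set(report.flagged_ids) == {"l1", "l3"}
    assert report.proportion_flagged == pytest.approx(2 / 3)


# ----------------------------------------------------------- base_pvalues


@pytest.fixture(scope="module")
def clean_pvals():
    ds = simulate_dataset(SimulationConfig(n_lines=300, n_markers=800, seed=17))
    grm = compute_grm(ds.markers)
    return base_pvalues(ds.phenotype_series(), grm, seed=17)


def test_base_pvalues_are_calibrated_on_clean_data(clean_pvals):
    assert clean_pvals.values.shape == (300, 3)
    col_means = clean_pvals.values.mean(axis=0)
    assert np.all(col_means > 0.45) and np.all(col_means < 0.55)


def test_shifted_line_is_detected():
    """A +6 sigma phenotype shift drives that line's minimum base p below
    0.01 in (nearly) every replicate."""
    hits = 0
    for seed in range(10):
        ds = simulate_dataset(SimulationConfig(n_lines=200, n_markers=500, seed=seed))
        phen = ds.phenotype_series()
        resid_sd = np.sqrt(1 - 0.5) * 1.0
        target = phen.index[0]
        phen.loc[target] += 6.0 * resid_sd
        pvals = base_pvalues(phen, compute_grm(ds.markers), seed=seed)
        row = pvals.values[list(pvals.line_ids).index(target)]
        hits += row.min() < 0.01
    assert hits >= 9


def test_identical_observations_are_degenerate(small_grm, small_dataset):
    phen = pd.Series(1.0, index=small_dataset.line_ids)
    with pytest.raises(DegenerateInputError):
        base_pvalues(phen, small_grm)


def test_too_few_lines_rejected(small_grm, small_dataset):
    phen = small_dataset.phenotype_series().iloc[:5]
    with pytest.raises(DegenerateInputError):
        base_pvalues(phen, small_grm)


def test_contaminated_lines_get_small_combined_p():
    ds = simulate_dataset(
        SimulationConfig(
            n_lines=300, n_markers=500, outlier_fraction=0.05,
            outlier_magnitude=6.0, seed=23,
        )
    )
    pvals = base_pvalues(ds.phenotype_series(), compute_grm(ds.markers), seed=23)
    combined = combine("invchi", pvals).combined_p
    flagged_truth = ds.true_outlier_flags
    assert np.median(combined[flagged_truth]) < 0.01 < np.median(combined[~flagged_truth])
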