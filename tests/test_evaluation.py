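import logging

import numpy as np
import pandas as pd
import pytest

from gsbench import (
    VARIANTS,
    EvalSettings,
    SimulationConfig,
    compute_grm,
    fit_gblup,
    make_partitions,
    nrmse,
    pearson_cor,
    relative_efficiency_cor,
    relative_efficiency_nrmse,
    run_grid,
    run_variant,
    simulate_dataset,
    summarize_across,
    variant_from_name,
)
from gsbench.errors import ConfigurationError, InputError
from gsbench.evaluation import EvaluationTable, narrate_summary

# ------------------------------------------------------------ partitions


def test_partitions_have_exact_test_fraction_and_are_seeded():
    ids = [f"L{i}" for i in range(100)]
    folds = make_partitions(ids, n_reps=10, test_fraction=0.2, master_seed=5)
    assert folds.n_reps == 10
    for split in folds:
        assert len(split.test_ids) == 20
        assert len(split.train_ids) == 80
        assert not set(split.test_ids) & set(split.train_ids)
    again = make_partitions(ids, n_reps=10, test_fraction=0.2, master_seed=5)
    for a, b in zip(folds, again):
        np.testing.assert_array_equal(a.test_ids, b.test_ids)
    # Monte Carlo splits are sampled independently, not a partition
    all_test = np.concatenate([s.test_ids for s in folds])
    assert len(np.unique(all_test)) < len(all_test)


def test_kfold_scheme_partitions_the_data():
    ids = [f"L{i}" for i in range(50)]
    folds = make_partitions(ids, n_reps=5, master_seed=1, scheme="kfold")
    all_test = np.concatenate([s.test_ids for s in folds])
    assert sorted(all_test) == sorted(ids)


# --------------------------------------------------------------- metrics


def test_pearson_trivial_and_hand_oracle():
    obs = np.array([1.0, 2.0, 3.0])
    assert pearson_cor(obs, obs) == pytest.approx(1.0)
    assert pearson_cor(obs, -obs) == pytest.approx(-1.0)
    # hand-computed: cov = 1.5, sd_x = 1, sd_y = sqrt(7/3)
    assert pearson_cor(obs, [1.0, 2.0, 4.0]) == pytest.approx(0.9819805060619659)


def test_pearson_constant_input_is_nan_with_warning(caplog):
    with caplog.at_level(logging.WARNING):
        value = pearson_cor([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert np.isnan(value)
    assert "constant" in caplog.text


def test_nrmse_conventions():
    obs = np.array([2.0, 2.0, 2.0, 2.0])
    pred = np.array([3.0, 3.0, 3.0, 3.0])
    assert nrmse(obs, obs) == pytest.approx(0.0)
    assert nrmse(obs, pred, "mean") == pytest.approx(0.5)
    rng = np.random.default_rng(3)
    o, p = rng.normal(5, 1, 40), rng.normal(5, 1, 40)
    for norm in ("mean", "range"):
        assert nrmse(2 * o, 2 * p, norm) == pytest.approx(nrmse(o, p, norm))
    assert nrmse(o, p, "sd") == pytest.approx(
        np.sqrt(np.mean((o - p) ** 2)) / np.std(o, ddof=1)
    )
    with pytest.raises(ConfigurationError, match="normalization"):
        nrmse(np.array([-1.0, 1.0]), np.array([0.0, 0.0]), "mean")


# --------------------------------------------------- relative efficiency


def test_relative_efficiency_conventions():
    assert relative_efficiency_cor(0.3, 0.3) == pytest.approx(0.0)
    assert relative_efficiency_nrmse(0.4, 0.4) == pytest.approx(0.0)
    # COR: comparison method in the denominator
    assert relative_efficiency_cor(0.22, 0.20) == pytest.approx(10.0)
    # NRMSE: reference (best) method in the denominator
    assert relative_efficiency_nrmse(0.20, 0.22) == pytest.approx(10.0)


# ------------------------------------------------------------- the grid


def test_variant_grid_is_exactly_ten():
    assert len(VARIANTS) == 10
    names = {v.name for v in VARIANTS}
    assert names == {
        "GBLUP", "QM", "Invchi", "Logit", "Meanp", "SumZ",
        "QM_Invchi", "QM_Logit", "QM_Meanp", "QM_SumZ",
    }
    with pytest.raises(ConfigurationError):
        variant_from_name("LASSO")


@pytest.fixture(scope="module")
def grid_inputs():
    ds = simulate_dataset(
        SimulationConfig(
            n_lines=150, n_markers=500, seed=31,
            outlier_fraction=0.05, outlier_magnitude=5.0,
        )
    )
    grm = compute_grm(ds.markers)
    folds = make_partitions(ds.line_ids, n_reps=3, master_seed=9)
    return ds.phenotype_series(), grm, folds


def test_plain_gblup_variant_matches_direct_fit(grid_inputs):
    phen, grm, folds = grid_inputs
    split = folds.splits[0]
    row = run_variant(variant_from_name("GBLUP"), phen, grm, split)
    fit = fit_gblup(phen.loc[split.train_ids], grm, split)
    pred = fit.predictions.loc[split.test_ids].to_numpy()
    obs = phen.loc[split.test_ids].to_numpy()
    assert row["cor"] == pytest.approx(pearson_cor(obs, pred))
    assert row["nrmse"] == pytest.approx(nrmse(obs, pred))
    assert row["n_flagged"] == 0


def test_filtered_variants_share_flags_with_their_qm_twin(grid_inputs):
    phen, grm, folds = grid_inputs
    split = folds.splits[0]
    cache = {}
    plain = run_variant(variant_from_name("SumZ"), phen, grm, split, _cache=cache)
    qm = run_variant(variant_from_name("QM_SumZ"), phen, grm, split, _cache=cache)
    assert plain["n_flagged"] == qm["n_flagged"]
    assert plain["n_train_used"] == qm["n_train_used"]


def test_grid_shape_determinism_and_average_bookkeeping(grid_inputs):
    phen, grm, folds = grid_inputs
    settings = EvalSettings(seed=9)
    t1 = run_grid(phen, grm, folds, settings=settings, dataset="sim")
    t2 = run_grid(phen, grm, folds, settings=settings, dataset="sim")
    assert len(t1.rows) == 10 * 3
    pd.testing.assert_frame_equal(t1.rows, t2.rows)

    avg = t1.variant_averages()
    for _, row in avg.iterrows():
        fold_rows = t1.rows[
            (t1.rows.variant == row.variant) & (t1.rows.status == "ok")
        ]
        assert row.cor == pytest.approx(fold_rows.cor.mean(), abs=1e-12)
        assert row.nrmse == pytest.approx(fold_rows.nrmse.mean(), abs=1e-12)


def test_overzealous_filtering_marks_fold_failed(grid_inputs):
    phen, grm, folds = grid_inputs
    settings = EvalSettings(alpha=1.0)  # flags every line
    row = run_variant(
        variant_from_name("Invchi"), phen, grm, folds.splits[0], settings=settings
    )
    assert row["status"] == "failed"
    assert np.isnan(row["cor"])


def test_variants_agree_when_nothing_is_filtered():
    """On clean, well-specified data the filtered variants stay within 0.05
    COR of plain GBLUP (few lines removed, QM near-affine)."""
    ds = simulate_dataset(SimulationConfig(n_lines=200, n_markers=600, seed=77,
                                           heritability=0.8))
    grm = compute_grm(ds.markers)
    folds = make_partitions(ds.line_ids, n_reps=3, master_seed=2)
    table = run_grid(ds.phenotype_series(), grm, folds, settings=EvalSettings(seed=2))
    avg = table.variant_averages().set_index("variant")
    assert avg.loc["GBLUP", "cor"] > 0
    assert abs(avg.loc["GBLUP", "cor"] - avg.loc["Meanp", "cor"]) < 0.05


def test_filtering_does_not_hurt_under_heavy_contamination():
    """With 10% contamination at 6 sigma, each filtered variant's average
    test COR is no worse than unfiltered GBLUP minus 0.02 (20-seed means)."""
    filtered = ["Invchi", "Logit", "Meanp", "SumZ"]
    variants = tuple(variant_from_name(n) for n in ["GBLUP"] + filtered)
    sums = {name: [] for name in ["GBLUP"] + filtered}
    for seed in range(20):
        ds = simulate_dataset(
            SimulationConfig(n_lines=300, n_markers=1000, seed=60 + seed,
                             outlier_fraction=0.10, outlier_magnitude=6.0)
        )
        grm = compute_grm(ds.markers)
        folds = make_partitions(ds.line_ids, n_reps=2, master_seed=seed)
        table = run_grid(ds.phenotype_series(), grm, folds,
                         settings=EvalSettings(seed=seed), variants=variants)
        avg = table.variant_averages().set_index("variant")
        for name in sums:
            sums[name].append(avg.loc[name, "cor"])
    gblup = np.mean(sums["GBLUP"])
    for name in filtered:
        assert np.mean(sums[name]) >= gblup - 0.02, name


# ---------------------------------------------------------- summarization


def test_summarize_across_is_the_unweighted_mean():
    def table(dataset, cor_by_variant):
        rows = [
            {"dataset": dataset, "variant": v, "fold": 0, "cor": c, "nrmse": 1.0}
            for v, c in cor_by_variant.items()
        ]
        return EvaluationTable(pd.DataFrame(rows))

    t1 = table("d1", {"GBLUP": 0.2, "QM": 0.1})
    t2 = table("d2", {"GBLUP": 0.4, "QM": 0.3})
    single = summarize_across([t1])
    assert single.set_index("variant").loc["GBLUP", "cor"] == pytest.approx(0.2)
    both = summarize_across([t1, t2]).set_index("variant")
    assert both.loc["GBLUP", "cor"] == pytest.approx(0.3)
    assert both.loc["QM", "cor"] == pytest.approx(0.2)


def test_narration_contains_percent_differences():
    summary = pd.DataFrame(
        {"variant": ["GBLUP", "QM"], "cor": [0.1766, 0.1751], "nrmse": [0.4313, 0.5234]}
    )
    text = narrate_summary(summary, dataset="demo")
    assert "0.8567%" in text
    assert "21.3540%" in text


def test_evaluation_table_requires_core_columns():
    with pytest.raises(InputError):
        EvaluationTable(pd.DataFrame({"variant": ["GBLUP"]}))
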