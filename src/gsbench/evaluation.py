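"""Benchmark orchestration: the 10-model grid under repeated 80/20 splits.

The model grid crosses plain GBLUP with quantile-mapping calibration (QM)
and with four p-value-combination outlier filters applied to the training
set, plus the four QM-after-filtering compositions:

    GBLUP, QM, Invchi, Logit, Meanp, SumZ,
    QM_Invchi, QM_Logit, QM_Meanp, QM_SumZ.

Per fold and variant the pipeline is: (a) optionally flag and remove
training outliers, (b) fit GBLUP on the (possibly reduced) training set and
predict both test and training lines, (c) optionally build the quantile
transfer from the training (predicted, observed) pairs and apply it to the
test predictions, (d) score the test set with Pearson correlation (COR) and
normalized RMSE (NRMSE).

Cross-validation is Monte Carlo: ``n_reps`` independent seeded random 80/20
train/test splits (an exhaustive k-fold switch is available).  Relative
efficiencies between variants are percentage differences with the
conventions used in this literature: for COR the comparison method sits in
the denominator; for NRMSE the reference (best) method does.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .gblup import GBLUPSettings, GBLUPFit, TrainTestSplit, fit_gblup
from .grm import GRM
from .outliers import DEFAULT_ALPHA, base_pvalues, combine, flag_outliers
from .quantile_mapping import apply_transfer, build_transfer

logger = logging.getLogger(__name__)

__all__ = [
    "ModelVariant",
    "VARIANTS",
    "variant_from_name",
    "FoldAssignment",
    "EvalSettings",
    "EvaluationTable",
    "make_partitions",
    "pearson_cor",
    "nrmse",
    "run_variant",
    "run_grid",
    "relative_efficiency_cor",
    "relative_efficiency_nrmse",
    "summarize_across",
    "narrate_summary",
]

_OUTLIER_METHODS = ("invchi", "logit", "meanp", "sumz")


@dataclass(frozen=True)
class ModelVariant:
    """One cell of the model grid."""

    name: str
    uses_qm: bool
    outlier_method: str  # "none" or one of the four combiners

    def __post_init__(self) -> None:
        expected = _variant_name(self.uses_qm, self.outlier_method)
        if self.name != expected:
            raise ConfigurationError(
                f"variant name {self.name!r} inconsistent with flags ({expected!r})"
            )


_LABELS = {"invchi": "Invchi", "logit": "Logit", "meanp": "Meanp", "sumz": "SumZ"}


def _variant_name(uses_qm: bool, outlier_method: str) -> str:
    if outlier_method == "none":
        return "QM" if uses_qm else "GBLUP"
    label = _LABELS[outlier_method]
    return f"QM_{label}" if uses_qm else label


#: the full 10-variant grid, in reporting order
VARIANTS: tuple[ModelVariant, ...] = tuple(
    ModelVariant(_variant_name(qm, om), qm, om)
    for qm, om in itertools.product((False, True), ("none",) + _OUTLIER_METHODS)
)


def variant_from_name(name: str) -> ModelVariant:
    for v in VARIANTS:
        if v.name == name:
            return v
    raise ConfigurationError(f"unknown model variant {name!r}")


@dataclass
class FoldAssignment:
    """Repeated train/test partitions over one line set."""

    splits: list[TrainTestSplit]
    n_reps: int
    master_seed: int

    def __iter__(self):
        return iter(self.splits)


def make_partitions(
    line_ids,
    n_reps: int = 10,
    test_fraction: float = 0.2,
    master_seed: int = 0,
    scheme: str = "monte_carlo",
) -> FoldAssignment:
    """Seeded random 80/20 splits (Monte Carlo CV) or exhaustive k-fold.

    With ``scheme="monte_carlo"`` (default) the ``n_reps`` test sets are
    sampled independently and need not partition the data; with
    ``scheme="kfold"`` the data are partitioned into ``n_reps`` folds and
    ``test_fraction`` is ignored.
    """
    ids = np.asarray(line_ids, dtype=str)
    n = len(ids)
    if scheme == "monte_carlo":
        if not (0.0 < test_fraction < 1.0):
            raise ConfigurationError("test_fraction must lie in (0, 1)")
        n_test = int(round(test_fraction * n))
        if n_test == 0 or n_test == n:
            raise ConfigurationError("test_fraction leaves an empty train or test set")
        splits = []
        for rep in range(n_reps):
            rng = np.random.default_rng(np.random.SeedSequence([int(master_seed), rep]))
            perm = rng.permutation(n)
            splits.append(TrainTestSplit(ids[perm[n_test:]], ids[perm[:n_test]]))
    elif scheme == "kfold":
        rng = np.random.default_rng(np.random.SeedSequence([int(master_seed), 0]))
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_reps)
        splits = [
            TrainTestSplit(ids[np.setdiff1d(perm, fold)], ids[fold]) for fold in folds
        ]
    else:
        raise ConfigurationError(f"unknown CV scheme {scheme!r}")
    return FoldAssignment(splits=splits, n_reps=n_reps, master_seed=int(master_seed))


def pearson_cor(observed, predicted) -> float:
    """Sample Pearson correlation; NaN (with a logged warning) when either
    vector is constant, so degenerate folds drop out of averages."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 2:
        raise InputError("observed and predicted must be equal-length vectors (>= 2)")
    if np.std(obs) == 0 or np.std(pred) == 0:
        logger.warning("Pearson correlation undefined for constant input; returning NaN")
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


def nrmse(observed, predicted, normalization: str = "mean") -> float:
    """RMSE divided by a scale of the observed values (mean, sd, or range)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 1:
        raise InputError("observed and predicted must be equal-length vectors")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if normalization == "mean":
        scale = float(np.mean(obs))
    elif normalization == "sd":
        scale = float(np.std(obs, ddof=1)) if len(obs) > 1 else 0.0
    elif normalization == "range":
        scale = float(np.ptp(obs))
    else:
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    if scale <= 0:
        raise ConfigurationError(
            f"NRMSE normalizer {normalization!r} is {scale:g} (must be positive); "
            "choose another normalization (mean|sd|range)"
        )
    return rmse / scale


@dataclass(frozen=True)
class EvalSettings:
    """Everything a grid run needs beyond the data."""

    method: str = "reml"  # GBLUP estimation path for the grid
    gblup: GBLUPSettings = field(default_factory=GBLUPSettings)
    n_knots: int | None = None  # None -> min(100, n_train)
    extrapolation_policy: str = "constant_offset"
    alpha: float = DEFAULT_ALPHA
    sumz_weights: tuple[float, ...] | None = None
    p_adjust: str | None = None  # None | "bonferroni" | "bh"
    nrmse_normalization: str = "mean"
    inner_folds: int = 5
    min_train_lines: int = 10
    seed: int = 0


def _adjust_pvalues(p: np.ndarray, how: str | None) -> np.ndarray:
    if how is None:
        return p
    from statsmodels.stats.multitest import multipletests

    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(how)
    if key is None:
        raise ConfigurationError(f"unknown p_adjust {how!r}")
    return multipletests(p, method=key)[1]


def run_variant(
    variant: ModelVariant,
    phenotypes,
    grm: GRM,
    split: TrainTestSplit,
    settings: EvalSettings | None = None,
    fold: int = 0,
    dataset: str = "dataset",
    _cache: dict | None = None,
) -> dict:
    """Score one model variant on one fold; returns a fold-row dict.

    ``_cache`` (shared across variants of a fold by :func:`run_grid`) holds
    the base p-value matrix and GBLUP fits keyed by training set, so the
    four filters reuse one inner cross-validation and matching variants
    reuse fits.
    """
    settings = settings or EvalSettings()
    cache = _cache if _cache is not None else {}
    phen = pd.Series(phenotypes, dtype=float)
    phen.index = phen.index.astype(str)

    row = {
        "dataset": dataset,
        "variant": variant.name,
        "fold": fold,
        "cor": np.nan,
        "nrmse": np.nan,
        "n_train_used": len(split.train_ids),
        "n_flagged": 0,
        "status": "ok",
    }

    train_ids = split.train_ids
    if variant.outlier_method != "none":
        if "pvals" not in cache:
            cache["pvals"] = base_pvalues(
                phen.loc[train_ids],
                grm,
                inner_folds=settings.inner_folds,
                gblup_settings=settings.gblup,
                seed=settings.seed + fold,
            )
        pvals = cache["pvals"]
        combined = combine(
            variant.outlier_method,
            pvals,
            weights=settings.sumz_weights if variant.outlier_method == "sumz" else None,
        )
        adj = _adjust_pvalues(combined.combined_p, settings.p_adjust)
        report = flag_outliers(
            pd.Series(adj, index=pvals.line_ids),
            alpha=settings.alpha,
            method=variant.outlier_method,
        )
        train_ids = np.setdiff1d(train_ids, report.flagged_ids)
        row["n_flagged"] = len(report.flagged_ids)
        if len(train_ids) < settings.min_train_lines:
            logger.warning(
                "fold %d / %s: only %d training lines after outlier removal; "
                "marking fold as failed",
                fold,
                variant.name,
                len(train_ids),
            )
            row["status"] = "failed"
            row["n_train_used"] = len(train_ids)
            return row
    row["n_train_used"] = len(train_ids)

    fit_key = frozenset(train_ids)
    fits = cache.setdefault("fits", {})
    if fit_key not in fits:
        fits[fit_key] = fit_gblup(
            phen.loc[train_ids],
            grm,
            TrainTestSplit(train_ids, split.test_ids),
            method=settings.method,
            settings=settings.gblup,
            seed=settings.seed + fold,
        )
    fit: GBLUPFit = fits[fit_key]

    pred_test = fit.predictions.loc[split.test_ids].to_numpy()
    if variant.uses_qm:
        tf = build_transfer(
            phen.loc[train_ids].to_numpy(),
            fit.predictions.loc[train_ids].to_numpy(),
            n_knots=settings.n_knots,
            extrapolation_policy=settings.extrapolation_policy,
        )
        pred_test = apply_transfer(tf, pred_test)

    obs_test = phen.loc[split.test_ids].to_numpy()
    row["cor"] = pearson_cor(obs_test, pred_test)
    row["nrmse"] = nrmse(obs_test, pred_test, settings.nrmse_normalization)
    return row


@dataclass
class EvaluationTable:
    """Long-format fold rows plus summary helpers."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"dataset", "variant", "fold", "cor", "nrmse"}
        missing = required - set(self.rows.columns)
        if missing:
            raise InputError(f"EvaluationTable rows missing columns {sorted(missing)}")

    def variant_averages(self) -> pd.DataFrame:
        """Per-dataset, per-variant fold averages (NaN folds excluded)."""
        if "status" in self.rows.columns:
            ok = self.rows[self.rows["status"] == "ok"]
        else:
            ok = self.rows
        return (
            ok.groupby(["dataset", "variant"], sort=False)[["cor", "nrmse"]]
            .mean()
            .reset_index()
        )

    def wide_summary(self) -> pd.DataFrame:
        """Variant x metric table in the layout of the appendix tables."""
        avg = self.variant_averages()
        return avg.pivot(index="variant", columns="dataset", values=["cor", "nrmse"])

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EvaluationTable":
        return cls(pd.read_csv(path))


def run_grid(
    phenotypes,
    grm: GRM,
    folds: FoldAssignment,
    settings: EvalSettings | None = None,
    dataset: str = "dataset",
    variants: tuple[ModelVariant, ...] = VARIANTS,
) -> EvaluationTable:
    """All model variants on all folds, sharing splits, GRM and fits."""
    settings = settings or EvalSettings()
    rows = []
    for fold, split in enumerate(folds):
        cache: dict = {}
        for variant in variants:
            rows.append(
                run_variant(
                    variant,
                    phenotypes,
                    grm,
                    split,
                    settings=settings,
                    fold=fold,
                    dataset=dataset,
                    _cache=cache,
                )
            )
        logger.info("dataset %s: fold %d/%d done", dataset, fold + 1, folds.n_reps)
    return EvaluationTable(pd.DataFrame(rows))


def relative_efficiency_cor(cor_ref: float, cor_other: float) -> float:
    """Percent COR advantage of the reference over a comparison method:
    100 * (cor_ref - cor_other) / cor_other."""
    if cor_other == 0:
        raise ConfigurationError("comparison correlation is zero; percent undefined")
    return 100.0 * (cor_ref - cor_other) / cor_other


def relative_efficiency_nrmse(nrmse_ref: float, nrmse_other: float) -> float:
    """Percent NRMSE advantage of the reference (lower-error) method:
    100 * (nrmse_other - nrmse_ref) / nrmse_ref."""
    if nrmse_ref == 0:
        raise ConfigurationError("reference NRMSE is zero; percent undefined")
    return 100.0 * (nrmse_other - nrmse_ref) / nrmse_ref


def summarize_across(tables: list[EvaluationTable]) -> pd.DataFrame:
    """Unweighted mean of per-dataset per-variant averages (variant, cor, nrmse)."""
    per_dataset = pd.concat([t.variant_averages() for t in tables], ignore_index=True)
    return (
        per_dataset.groupby("variant", sort=False)[["cor", "nrmse"]]
        .mean()
        .reset_index()
    )


def narrate_summary(summary: pd.DataFrame, dataset: str = "across datasets") -> str:
    """Plain-text narration of a (variant, cor, nrmse) summary with the
    percent differences relative to the best variant under each metric."""
    s = summary.set_index("variant")
    lines = [f"# Results for {dataset}", ""]

    by_cor = s["cor"].sort_values(ascending=False)
    best = by_cor.index[0]
    lines.append(
        f"Best COR: {best} ({by_cor.iloc[0]:.4f}). Percent advantage over the others:"
    )
    for name, value in by_cor.iloc[1:].items():
        pct = relative_efficiency_cor(by_cor.iloc[0], value)
        lines.append(f"  - vs {name} ({value:.4f}): {pct:.4f}%")
    lines.append("")

    by_nrmse = s["nrmse"].sort_values()
    best = by_nrmse.index[0]
    lines.append(
        f"Lowest NRMSE: {best} ({by_nrmse.iloc[0]:.4f}). Percent advantage over the others:"
    )
    for name, value in by_nrmse.iloc[1:].items():
        pct = relative_efficiency_nrmse(by_nrmse.iloc[0], value)
        lines.append(f"  - vs {name} ({value:.4f}): {pct:.4f}%")
    lines.append("")
    return "\n".join(lines)
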