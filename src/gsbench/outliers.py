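"""Influential-observation detection by p-value combination.

Each training observation gets K base p-values from residual diagnostics of
a cross-validated GBLUP fit, which are then combined into one p-value per
observation with a meta-analytic statistic whose null distribution is known
in closed form (assuming independent uniform base p-values under H0):

=========  ============================================  ==============
method     statistic                                     null
=========  ============================================  ==============
invchi     L = sum_k -2 ln p_k  (Fisher)                 chi^2_{2K}
logit      T = -sum_k ln(p_k/(1-p_k)) / C                t_{5K+4}
meanp      W = (0.5 - pbar) sqrt(12 K)  (Edgington)      N(0, 1)
sumz       Z = sum_k w_k z(p_k) / sqrt(sum w_k^2)        N(0, 1)
=========  ============================================  ==============

with z(p) = Phi^{-1}(1 - p) and the Mudholkar-George scaling constant
C = sqrt(K pi^2 (5K + 2) / (3 (5K + 4))) that the logit statistic needs for
its t null.  Small base p-values (evidence of outlyingness) map to large
positive statistics in every method, so all combined p-values are upper-tail
probabilities.  Observations with combined p below ``alpha`` are flagged;
removal from the training set is the evaluation layer's job.

The base diagnostics (K = 3) are this package's own choice and are pluggable:
any (n x K) p-value matrix can be fed to the combiners directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateInputError, InputError
from .gblup import GBLUPSettings, TrainTestSplit, estimate_variance_ratio, fit_gblup
from .grm import GRM

__all__ = [
    "PValueMatrix",
    "CombinedOutlierResult",
    "OutlierReport",
    "base_pvalues",
    "combine_invchi",
    "combine_logit",
    "combine_meanp",
    "combine_sumz",
    "combine",
    "flag_outliers",
    "COMBINERS",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 0.01
P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16

BASE_TEST_NAMES = ("mad_z", "studentized", "rank_mahalanobis")


@dataclass
class PValueMatrix:
    """Per-observation base p-values (n_lines x K)."""

    line_ids: np.ndarray
    values: np.ndarray
    base_test_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=str)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.line_ids):
            raise InputError("values must be (n_lines, K)")
        if self.values.shape[1] < 2:
            raise InputError("combiners need K >= 2 base tests")
        if len(self.base_test_names) != self.values.shape[1]:
            raise InputError("one name per base test required")
        if np.any(self.values <= 0) or np.any(self.values > 1):
            raise InputError("p-values must lie in (0, 1]")

    @property
    def K(self) -> int:
        return self.values.shape[1]


@dataclass
class CombinedOutlierResult:
    """Combined statistic and p-value per observation for one method."""

    method: str
    statistic: np.ndarray
    combined_p: np.ndarray
    df_or_null: str
    weights: np.ndarray | None = None
    line_ids: np.ndarray | None = None


@dataclass
class OutlierReport:
    """Which training lines were flagged at a given threshold."""

    flagged_ids: np.ndarray
    alpha: float
    proportion_flagged: float
    method: str
    combined_p: pd.Series | None = field(default=None, repr=False)


def _clip(p) -> np.ndarray:
    if isinstance(p, PValueMatrix):
        p = p.values
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    return np.clip(p, P_FLOOR, P_CEIL)


def combine_invchi(p_values) -> CombinedOutlierResult:
    """Fisher / inverse chi-square combination."""
    p = _clip(p_values)
    K = p.shape[1]
    L = np.sum(-2.0 * np.log(p), axis=1)
    return CombinedOutlierResult(
        method="invchi",
        statistic=L,
        combined_p=stats.chi2.sf(L, 2 * K),
        df_or_null=f"chi2_{2 * K}",
    )


def mudholkar_george_constant(K: int) -> float:
    """Scaling constant giving the logit statistic its t_{5K+4} null."""
    return float(np.sqrt(K * np.pi**2 * (5 * K + 2) / (3.0 * (5 * K + 4))))


def combine_logit(p_values) -> CombinedOutlierResult:
    """Mudholkar-George logit combination with t_{5K+4} null."""
    p = _clip(p_values)
    K = p.shape[1]
    S = np.sum(np.log(p / (1.0 - p)), axis=1)
    T = -S / mudholkar_george_constant(K)
    df = 5 * K + 4
    return CombinedOutlierResult(
        method="logit",
        statistic=T,
        combined_p=stats.t.sf(T, df),
        df_or_null=f"t_{df}",
    )


def combine_meanp(p_values) -> CombinedOutlierResult:
    """Edgington mean-p combination with asymptotic N(0,1) null."""
    p = _clip(p_values)
    K = p.shape[1]
    W = (0.5 - p.mean(axis=1)) * np.sqrt(12.0 * K)
    return CombinedOutlierResult(
        method="meanp",
        statistic=W,
        combined_p=stats.norm.sf(W),
        df_or_null="N(0,1)",
    )


def combine_sumz(p_values, weights=None) -> CombinedOutlierResult:
    """Stouffer weighted sum-of-Z combination."""
    p = _clip(p_values)
    K = p.shape[1]
    if weights is None:
        w = np.ones(K)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (K,) or np.any(w <= 0):
            raise InputError("weights must be K positive reals")
    z = stats.norm.isf(p)  # Phi^{-1}(1 - p)
    Z = (z @ w) / np.sqrt(np.sum(w * w))
    return CombinedOutlierResult(
        method="sumz",
        statistic=Z,
        combined_p=stats.norm.sf(Z),
        df_or_null="N(0,1)",
        weights=w,
    )


COMBINERS = {
    "invchi": combine_invchi,
    "logit": combine_logit,
    "meanp": combine_meanp,
    "sumz": combine_sumz,
}


def combine(method: str, p_values, weights=None) -> CombinedOutlierResult:
    """Dispatch to one of the four combiners by name."""
    if method not in COMBINERS:
        raise ConfigurationError(f"unknown combiner {method!r}")
    if method == "sumz":
        result = combine_sumz(p_values, weights=weights)
    else:
        result = COMBINERS[method](p_values)
    if isinstance(p_values, PValueMatrix):
        result.line_ids = p_values.line_ids
    return result


def flag_outliers(combined_p, alpha: float = DEFAULT_ALPHA, method: str = "") -> OutlierReport:
    """Flag lines whose combined p-value falls strictly below ``alpha``."""
    if not (0.0 <= alpha <= 1.0):
        raise ConfigurationError("alpha must lie in [0, 1]")
    p = pd.Series(combined_p, dtype=float)
    p.index = p.index.astype(str)
    flagged = p.index[p.to_numpy() < alpha].to_numpy(dtype=str)
    return OutlierReport(
        flagged_ids=flagged,
        alpha=float(alpha),
        proportion_flagged=len(flagged) / len(p),
        method=method,
        combined_p=p,
    )


def _inner_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [fold for fold in np.array_split(perm, k) if len(fold) > 0]


def _rank_normal_scores(x: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf(ranks / (len(x) + 1.0))


def base_pvalues(
    phenotypes_train,
    grm: GRM,
    inner_folds: int = 5,
    gblup_settings: GBLUPSettings | None = None,
    seed: int = 0,
) -> PValueMatrix:
    """K = 3 per-observation diagnostics from a cross-validated GBLUP fit.

    The training fold is split into ``inner_folds`` inner folds; each line's
    phenotype is predicted out-of-fold by GBLUP at the variance ratio
    estimated once by REML on the whole training fold.  From the out-of-fold
    residuals e_i three two-sided p-values are computed per line:

    1. ``mad_z`` — e_i standardized by median/MAD, referred to N(0, 1);
    2. ``studentized`` — e_i divided by the leave-one-out residual standard
       deviation, referred to t_{m-2} with m the inner-fold training size;
    3. ``rank_mahalanobis`` — squared Mahalanobis distance of the
       (observed, predicted) pair after rank-to-normal-scores transformation
       of each coordinate, referred to chi^2_2.

    All p-values are floored at 1e-300.
    """
    phen = pd.Series(phenotypes_train, dtype=float)
    phen.index = phen.index.astype(str)
    n = len(phen)
    if n < 10:
        raise DegenerateInputError("need at least 10 training lines")
    ids = phen.index.to_numpy(dtype=str)
    y = phen.to_numpy()
    if np.ptp(y) == 0:
        raise DegenerateInputError("all phenotypes identical; diagnostics undefined")

    # one REML fit on the whole training fold pins the shrinkage level
    rng = np.random.default_rng(np.random.SeedSequence([11, int(seed)]))
    full_fit_ratio = estimate_variance_ratio(phen, grm, gblup_settings)
    if not np.isfinite(full_fit_ratio):
        full_fit_ratio = 1e6

    oof_pred = np.full(n, np.nan)
    inner_train_sizes = []
    for fold in _inner_folds(n, inner_folds, rng):
        test_ids = ids[fold]
        train_ids = np.setdiff1d(ids, test_ids)
        inner_train_sizes.append(len(train_ids))
        fit = fit_gblup(
            phen.loc[train_ids],
            grm,
            TrainTestSplit(train_ids, test_ids),
            method="fixed",
            variance_ratio=full_fit_ratio,
        )
        oof_pred[fold] = fit.predictions.loc[test_ids].to_numpy()

    e = y - oof_pred

    # 1) median/MAD z-score vs N(0,1)
    mad = np.median(np.abs(e - np.median(e)))
    if mad == 0:
        raise DegenerateInputError("zero MAD of out-of-fold residuals")
    z = (e - np.median(e)) / (1.4826 * mad)
    p1 = 2.0 * stats.norm.sf(np.abs(z))

    # 2) leave-one-out studentized residual vs t_{m-2}
    m = int(np.min(inner_train_sizes))
    sse = np.sum(e * e)
    loo_var = (sse - e * e) / (n - 2)
    loo_sd = np.sqrt(np.maximum(loo_var, 1e-300))
    t_stat = e / loo_sd
    p2 = 2.0 * stats.t.sf(np.abs(t_stat), max(m - 2, 1))

    # 3) rank-based Mahalanobis distance of (observed, predicted) vs chi^2_2
    u = _rank_normal_scores(y)
    v = _rank_normal_scores(oof_pred)
    r = float(np.clip(np.corrcoef(u, v)[0, 1], -0.999, 0.999))
    d2 = (u * u - 2.0 * r * u * v + v * v) / (1.0 - r * r)
    p3 = stats.chi2.sf(d2, 2)

    values = np.clip(np.column_stack([p1, p2, p3]), P_FLOOR, 1.0)
    return PValueMatrix(line_ids=ids, values=values, base_test_names=BASE_TEST_NAMES)
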