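"""GBLUP: the genomic best linear unbiased prediction mixed model.

Model:  y = mu * 1 + g + e,  g ~ N(0, sigma_g^2 G),  e ~ N(0, sigma_e^2 I),
with G the genomic relationship matrix.  Two estimation paths are provided:

``reml``
    Restricted maximum likelihood via a single eigendecomposition of the
    training block of G.  The variance ratio delta = sigma_e^2 / sigma_g^2 is
    profiled out by 1-D bounded optimization of the restricted likelihood;
    held-out lines are predicted by the conditional mean

        g_test = G_test,train (G_train,train + delta I)^{-1} (y_train - mu 1).

``gibbs``
    A Gibbs sampler with scaled-inverse-chi-square priors on both variance
    components and data augmentation of the missing (test) phenotypes, so
    test predictions are posterior means of mu + g_i.  Priors follow the
    common genomic-prediction default: df = 5 and scale set so each prior
    mode equals half the phenotypic variance of the training set.

A third path, ``fixed``, skips variance estimation and predicts at a caller
supplied ratio; it exists for shrinkage studies and for the algebraic
equivalence with ridge regression on markers (RR-BLUP) that the test suite
exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import ConfigurationError, DegenerateInputError, InputError
from .grm import GRM, MarkerMatrix, impute_missing

__all__ = [
    "TrainTestSplit",
    "GBLUPSettings",
    "GBLUPFit",
    "fit_gblup",
    "predict_rrblup_oracle",
]


@dataclass
class TrainTestSplit:
    """Disjoint train/test line-identifier sets covering a dataset."""

    train_ids: np.ndarray
    test_ids: np.ndarray

    def __post_init__(self) -> None:
        self.train_ids = np.asarray(self.train_ids, dtype=str)
        self.test_ids = np.asarray(self.test_ids, dtype=str)
        if len(self.train_ids) == 0 or len(self.test_ids) == 0:
            raise InputError("train and test sets must both be non-empty")
        if set(self.train_ids) & set(self.test_ids):
            raise InputError("train and test sets overlap")


@dataclass(frozen=True)
class GBLUPSettings:
    """Sampler/optimizer knobs.

    Gibbs defaults are on the scale commonly used for Bayesian GBLUP:
    12,000 iterations, 2,000 burn-in, thinning 5 (2,000 retained samples).
    """

    iterations: int = 12000
    burn_in: int = 2000
    thin: int = 5
    prior_df: float = 5.0
    prior_mode_fraction: float = 0.5  # prior mode = fraction * var(y_train)
    delta_bounds: tuple[float, float] = (1e-6, 1e6)

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ConfigurationError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        if self.prior_df <= 0:
            raise ConfigurationError("prior_df must be positive")


@dataclass
class GBLUPFit:
    """Fitted model state and predictions for every line in the GRM."""

    mu_hat: float
    sigma_g2: float
    sigma_e2: float
    g_hat: pd.Series
    predictions: pd.Series
    method: str
    mcmc_diagnostics: dict = field(default_factory=dict)

    @property
    def heritability(self) -> float:
        """Genomic heritability estimate sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
        total = self.sigma_g2 + self.sigma_e2
        return float(self.sigma_g2 / total) if total > 0 else 0.0

    @property
    def variance_ratio(self) -> float:
        """delta = sigma_e^2 / sigma_g^2 (inf when sigma_g^2 = 0)."""
        return float(self.sigma_e2 / self.sigma_g2) if self.sigma_g2 > 0 else np.inf


def _as_series(phenotypes) -> pd.Series:
    s = pd.Series(phenotypes, dtype=float)
    s.index = s.index.astype(str)
    if not np.isfinite(s.to_numpy()).all():
        raise InputError("phenotypes must be finite")
    return s


def _conditional_predictions(
    G: np.ndarray,
    idx_train: np.ndarray,
    y_train: np.ndarray,
    mu: float,
    delta: float,
) -> np.ndarray:
    """g_hat for all lines: G[:, train] (G_tt + delta I)^{-1} (y - mu)."""
    Gtt = G[np.ix_(idx_train, idx_train)]
    A = Gtt + delta * np.eye(len(idx_train))
    alpha = np.linalg.solve(A, y_train - mu)
    return G[:, idx_train] @ alpha


def _reml_profile(d: np.ndarray, y_rot: np.ndarray, one_rot: np.ndarray, delta: float):
    """Profiled REML pieces at a given variance ratio.

    Works in the eigenbasis of G_train,train: d are eigenvalues, y_rot/one_rot
    the rotated response and intercept column.  Returns (-2 restricted
    log-likelihood up to a constant, mu_hat, sigma_g2_hat).
    """
    n = len(d)
    w = 1.0 / (d + delta)
    swo = np.sum(w * one_rot * one_rot)
    mu = np.sum(w * one_rot * y_rot) / swo
    r = y_rot - mu * one_rot
    sg2 = np.sum(w * r * r) / (n - 1)
    sg2 = max(sg2, 1e-300)
    neg2ll = (n - 1) * np.log(sg2) + np.sum(np.log(d + delta)) + np.log(swo)
    return neg2ll, mu, sg2


def fit_gblup(
    phenotypes,
    grm: GRM,
    split: TrainTestSplit,
    method: str = "reml",
    settings: GBLUPSettings | None = None,
    variance_ratio: float | None = None,
    seed: int = 0,
) -> GBLUPFit:
    """Fit the GBLUP model on the training lines and predict every line.

    Parameters
    ----------
    phenotypes
        Mapping/Series of phenotype values; must cover ``split.train_ids``.
    grm
        Genomic relationship matrix over all lines (train and test).
    split
        Which lines are observed (train) and which are to be predicted.
    method
        ``"reml"``, ``"gibbs"`` or ``"fixed"`` (requires ``variance_ratio``).
    variance_ratio
        delta = sigma_e^2/sigma_g^2 for the fixed path.
    seed
        Seeds the Gibbs sampler; ignored by the deterministic paths.
    """
    settings = settings or GBLUPSettings()
    if method not in ("reml", "gibbs", "fixed"):
        raise ConfigurationError(f"unknown method {method!r}")
    if method == "fixed" and (variance_ratio is None or variance_ratio <= 0):
        raise ConfigurationError("fixed method requires a positive variance_ratio")

    phen = _as_series(phenotypes)
    missing = [lid for lid in split.train_ids if lid not in phen.index]
    if missing:
        raise InputError(f"no phenotype for training line {missing[0]!r}")
    idx_train = grm.indices_of(split.train_ids)
    grm.indices_of(split.test_ids)  # validate test ids are present
    y_train = phen.loc[split.train_ids].to_numpy()
    n_train = len(y_train)
    G = grm.regularized
    line_index = pd.Index(grm.line_ids)

    var_y = float(np.var(y_train, ddof=1)) if n_train > 1 else 0.0
    if var_y <= 1e-14 * (1.0 + float(np.mean(y_train)) ** 2):
        # constant response: no genetic signal can be estimated
        mu = float(y_train[0]) if n_train else 0.0
        zeros = pd.Series(np.zeros(grm.n_lines), index=line_index)
        return GBLUPFit(
            mu_hat=mu,
            sigma_g2=0.0,
            sigma_e2=1e-12,
            g_hat=zeros,
            predictions=zeros + mu,
            method=method,
        )

    if method == "gibbs":
        return _fit_gibbs(phen, grm, split, settings, seed)

    Gtt = G[np.ix_(idx_train, idx_train)]
    d, U = np.linalg.eigh(Gtt)
    d = np.maximum(d, 0.0)
    y_rot = U.T @ y_train
    one_rot = U.T @ np.ones(n_train)

    if method == "fixed":
        delta = float(variance_ratio)
        _, mu, sg2 = _reml_profile(d, y_rot, one_rot, delta)
    else:
        lo, hi = settings.delta_bounds
        res = minimize_scalar(
            lambda t: _reml_profile(d, y_rot, one_rot, float(np.exp(t)))[0],
            bounds=(np.log(lo), np.log(hi)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        delta = float(np.exp(res.x))
        _, mu, sg2 = _reml_profile(d, y_rot, one_rot, delta)

    se2 = delta * sg2
    g_all = _conditional_predictions(G, idx_train, y_train, mu, delta)
    g_hat = pd.Series(g_all, index=line_index)
    return GBLUPFit(
        mu_hat=float(mu),
        sigma_g2=float(sg2),
        sigma_e2=float(se2),
        g_hat=g_hat,
        predictions=g_hat + float(mu),
        method=method,
    )


def estimate_variance_ratio(
    phenotypes, grm: GRM, settings: GBLUPSettings | None = None
) -> float:
    """REML estimate of delta = sigma_e^2/sigma_g^2 using all supplied lines.

    Unlike :func:`fit_gblup`, no held-out set is required; this is the
    estimator the outlier diagnostics use to pin the shrinkage level before
    their inner cross-validation.
    """
    settings = settings or GBLUPSettings()
    phen = _as_series(phenotypes)
    ids = phen.index.to_numpy(dtype=str)
    idx = grm.indices_of(ids)
    y = phen.to_numpy()
    if np.var(y, ddof=1) <= 1e-14 * (1.0 + float(np.mean(y)) ** 2):
        raise DegenerateInputError("constant phenotypes; variance ratio undefined")
    Gtt = grm.regularized[np.ix_(idx, idx)]
    d, U = np.linalg.eigh(Gtt)
    d = np.maximum(d, 0.0)
    y_rot = U.T @ y
    one_rot = U.T @ np.ones(len(y))
    lo, hi = settings.delta_bounds
    res = minimize_scalar(
        lambda t: _reml_profile(d, y_rot, one_rot, float(np.exp(t)))[0],
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


def _sample_scaled_inv_chi2(
    rng: np.random.Generator, df: float, scale_sum: float
) -> float:
    """Draw from the scaled-inverse-chi-square with the given df and
    df*scale = scale_sum (the standard conjugate-update form)."""
    return scale_sum / rng.chisquare(df)


def _fit_gibbs(
    phen: pd.Series,
    grm: GRM,
    split: TrainTestSplit,
    settings: GBLUPSettings,
    seed: int,
) -> GBLUPFit:
    """Gibbs sampler in the eigenbasis of the full (regularized) GRM.

    Writing g = U a with G = U diag(d) U', the conditional of the spectral
    coefficients a given complete data is diagonal, which keeps each sweep at
    O(n^2).  Missing (test) phenotypes are re-imputed every sweep from their
    predictive distribution, so their posterior-mean predictions follow the
    usual missing-value-augmentation convention.
    """
    rng = np.random.default_rng(np.random.SeedSequence([7, int(seed)]))
    n = grm.n_lines
    idx_train = grm.indices_of(split.train_ids)
    y_train = phen.loc[split.train_ids].to_numpy()
    obs_mask = np.zeros(n, dtype=bool)
    obs_mask[idx_train] = True
    n_obs = int(obs_mask.sum())

    d, U = np.linalg.eigh(grm.regularized)
    d = np.maximum(d, 1e-12)

    var_y = float(np.var(y_train, ddof=1))
    nu = settings.prior_df
    # scale chosen so the prior mode nu*s2/(nu+2) equals prior_mode_fraction*var_y
    s2 = settings.prior_mode_fraction * var_y * (nu + 2.0) / nu

    mu = float(np.mean(y_train))
    sg2 = se2 = 0.5 * var_y
    a = np.zeros(n)
    y_complete = np.full(n, mu)
    y_complete[idx_train] = y_train

    n_saved = 0
    sum_pred = np.zeros(n)
    sums = np.zeros(3)  # mu, sg2, se2

    for it in range(settings.iterations):
        g = U @ a
        # impute missing phenotypes from their predictive distribution
        miss = ~obs_mask
        if miss.any():
            y_complete[miss] = mu + g[miss] + rng.normal(0.0, np.sqrt(se2), miss.sum())
        # intercept
        mu = rng.normal(np.mean(y_complete - g), np.sqrt(se2 / n))
        # spectral coefficients (diagonal conditional)
        y_rot = U.T @ (y_complete - mu)
        post_var = 1.0 / (1.0 / (sg2 * d) + 1.0 / se2)
        post_mean = post_var * y_rot / se2
        a = post_mean + rng.normal(size=n) * np.sqrt(post_var)
        # variance components
        ss_g = np.sum(a * a / d)
        sg2 = _sample_scaled_inv_chi2(rng, nu + n, nu * s2 + ss_g)
        g = U @ a
        resid = y_train - mu - g[idx_train]
        se2 = _sample_scaled_inv_chi2(rng, nu + n_obs, nu * s2 + np.sum(resid * resid))

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            sum_pred += mu + g
            sums += (mu, sg2, se2)
            n_saved += 1

    pred = sum_pred / n_saved
    mu_mean, sg2_mean, se2_mean = sums / n_saved
    line_index = pd.Index(grm.line_ids)
    predictions = pd.Series(pred, index=line_index)
    return GBLUPFit(
        mu_hat=float(mu_mean),
        sigma_g2=float(sg2_mean),
        sigma_e2=float(se2_mean),
        g_hat=predictions - float(mu_mean),
        predictions=predictions,
        method="gibbs",
        mcmc_diagnostics={
            "iterations": settings.iterations,
            "burn_in": settings.burn_in,
            "thin": settings.thin,
            "n_saved": n_saved,
        },
    )


def predict_rrblup_oracle(
    markers: MarkerMatrix,
    phenotypes,
    split: TrainTestSplit,
    lam: float,
    intercept: float | None = None,
) -> pd.Series:
    """Ridge regression on centered markers (RR-BLUP), for testing only.

    Solves the primal normal equations (W'W + lam I) beta = W'(y - mu) on the
    training lines, with W the dosage matrix centered at twice the full-data
    allele frequencies, and returns mu + W beta for every line.  With
    lam = delta * 2*sum p(1-p) this reproduces fixed-variance GBLUP
    predictions exactly, which is the equivalence the test suite checks.
    """
    if lam < 0:
        raise InputError("ridge penalty must be non-negative")
    phen = _as_series(phenotypes)
    dosages = impute_missing(markers.dosages)
    p = dosages.mean(axis=0) / 2.0
    W = dosages - 2.0 * p
    lookup = {lid: i for i, lid in enumerate(markers.line_ids)}
    idx_train = np.array([lookup[str(i)] for i in split.train_ids])
    y = phen.loc[split.train_ids].to_numpy()
    mu = float(np.mean(y)) if intercept is None else float(intercept)
    Wt = W[idx_train]
    m = W.shape[1]
    if lam == 0:
        # OLS limit: minimum-norm least squares (interpolates when Wt has
        # full row rank)
        beta, *_ = np.linalg.lstsq(Wt, y - mu, rcond=None)
    else:
        beta = np.linalg.solve(Wt.T @ Wt + lam * np.eye(m), Wt.T @ (y - mu))
    return pd.Series(mu + W @ beta, index=pd.Index(markers.line_ids))
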