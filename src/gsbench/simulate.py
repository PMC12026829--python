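"""Synthetic genotype/phenotype simulator.

Generates SNP dosage matrices under Hardy-Weinberg sampling and single-trait
phenotypes from a purely additive model

    y_i = mu + g_i + e_i,

where ``g`` is a linear combination of a subset of marker dosages (the QTL)
rescaled to hit a target narrow-sense heritability, and ``e`` is symmetric
Gaussian noise or, when ``skew != 0``, standardized shifted-gamma noise with
the requested skewness coefficient.  A fraction of lines may be contaminated
by an additive location shift of ``+-outlier_magnitude`` residual standard
deviations (random sign), emulating influential observations in a training
set; contaminated lines are recorded in ``true_outlier_flags``.

Profiles named after real plant-breeding datasets reproduce their line counts
with the marker count capped at ``MARKER_CAP`` — they are scaled stand-ins
for desk-scale benchmarking, not reconstructions of the real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DegenerateInputError
from .grm import MarkerMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "dataset_profile",
    "MARKER_CAP",
    "PROFILE_SHAPES",
]

#: marker-count ceiling for named profiles; GRM-based prediction accuracy
#: saturates well below the array sizes of the original datasets, and the
#: capped profiles keep single-CPU runs fast.
MARKER_CAP = 5000

#: (n_lines, n_markers) of the real datasets the profiles emulate.
PROFILE_SHAPES: dict[str, tuple[int, int]] = {
    "Indica": (327, 16383),
    "Japonica": (320, 16383),
    "Groundnut": (318, 8268),
    "Maize": (722, 54113),
    "Wheat_1": (1301, 78606),
    "Wheat_2": (1403, 78606),
    "Wheat_3": (1403, 78606),
    "Wheat_4": (1388, 78606),
    "Wheat_5": (1398, 78606),
    "Wheat_6": (1277, 78606),
    "EYT_1": (776, 2038),
    "EYT_2": (775, 2038),
    "EYT_3": (964, 2038),
    "Disease": (438, 11617),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``trait_mean``/``trait_sd`` default to a yield-like scale (5 ± 1) so that
    mean-normalized error metrics are well-defined; ``heritability`` defaults
    to 0.5, a typical value for complex agronomic traits.
    """

    n_lines: int
    n_markers: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int | None = None
    heritability: float = 0.5
    trait_mean: float = 5.0
    trait_sd: float = 1.0
    skew: float = 0.0
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.n_markers < 1:
            raise ConfigurationError("n_lines and n_markers must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}"
            )
        if self.n_qtl is not None and not (1 <= self.n_qtl <= self.n_markers):
            raise ConfigurationError("n_qtl must be in [1, n_markers]")
        if not (0.0 < self.heritability < 1.0):
            raise ConfigurationError("heritability must lie strictly in (0, 1)")
        if self.trait_sd <= 0:
            raise ConfigurationError("trait_sd must be positive")
        if not (0.0 <= self.outlier_fraction < 0.5):
            raise ConfigurationError("outlier_fraction must lie in [0, 0.5)")
        if self.outlier_magnitude <= 0:
            raise ConfigurationError("outlier_magnitude must be positive")

    @property
    def resolved_n_qtl(self) -> int:
        return self.n_qtl if self.n_qtl is not None else min(300, self.n_markers)


@dataclass
class SyntheticDataset:
    """A simulated dataset: markers plus the trait and its hidden truth."""

    markers: MarkerMatrix
    phenotypes: np.ndarray
    true_genetic_values: np.ndarray
    true_outlier_flags: np.ndarray
    config: SimulationConfig

    @property
    def line_ids(self) -> np.ndarray:
        return self.markers.line_ids

    def phenotype_series(self):
        import pandas as pd

        return pd.Series(self.phenotypes, index=self.markers.line_ids, name="phenotype")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(stream), int(seed)]))


def simulate_genotypes(config: SimulationConfig) -> MarkerMatrix:
    """Draw a lines x markers dosage matrix under Hardy-Weinberg sampling.

    Each marker's allele frequency is sampled uniformly from ``maf_range``;
    dosages are Binomial(2, p).  Deterministic for a fixed ``config.seed``.
    """
    rng = _rng(config.seed, stream=0)
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_markers)
    dosages = rng.binomial(2, mafs, size=(config.n_lines, config.n_markers)).astype(float)
    width = max(4, len(str(config.n_lines)))
    line_ids = np.array([f"L{i:0{width}d}" for i in range(config.n_lines)])
    return MarkerMatrix(line_ids=line_ids, dosages=dosages)


def _skewed_noise(rng: np.random.Generator, n: int, sd: float, skew: float) -> np.ndarray:
    """Mean-0, variance-sd^2 noise with the requested skewness coefficient.

    Gamma(k) has skewness 2/sqrt(k); a standardized, possibly reflected gamma
    therefore realizes any nonzero target skew with k = (2/skew)^2.
    """
    if skew == 0.0:
        return rng.normal(0.0, sd, size=n)
    shape = (2.0 / abs(skew)) ** 2
    raw = rng.gamma(shape, 1.0, size=n)
    standardized = (raw - shape) / np.sqrt(shape)
    return sd * np.sign(skew) * standardized


def simulate_phenotypes(markers: MarkerMatrix, config: SimulationConfig) -> SyntheticDataset:
    """Simulate the trait for an existing marker matrix.

    Genetic values come from ``resolved_n_qtl`` randomly placed additive QTL;
    they are rescaled so the realized genetic variance is exactly
    ``heritability * trait_sd**2``, which pins var(g)/var(y) near the target
    up to residual sampling error.
    """
    n = markers.n_lines
    rng = _rng(config.seed, stream=1)

    qtl_idx = rng.choice(markers.n_markers, size=config.resolved_n_qtl, replace=False)
    effects = rng.normal(size=config.resolved_n_qtl)
    qtl = markers.dosages[:, qtl_idx]
    centered = qtl - qtl.mean(axis=0)
    g_raw = centered @ effects
    g_sd = g_raw.std()
    if g_sd == 0:
        raise DegenerateInputError(
            "all selected QTL are monomorphic; cannot scale genetic values"
        )
    target_g_sd = np.sqrt(config.heritability) * config.trait_sd
    g = g_raw * (target_g_sd / g_sd)

    resid_sd = np.sqrt(1.0 - config.heritability) * config.trait_sd
    e = _skewed_noise(rng, n, resid_sd, config.skew)
    phenotypes = config.trait_mean + g + e

    flags = np.zeros(n, dtype=bool)
    n_out = int(round(config.outlier_fraction * n))
    if n_out > 0:
        idx = rng.choice(n, size=n_out, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_out)
        phenotypes[idx] += signs * config.outlier_magnitude * resid_sd
        flags[idx] = True

    return SyntheticDataset(
        markers=markers,
        phenotypes=phenotypes,
        true_genetic_values=g,
        true_outlier_flags=flags,
        config=config,
    )


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Genotypes and phenotypes in one call (common entry point)."""
    return simulate_phenotypes(simulate_genotypes(config), config)


def dataset_profile(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Config emulating a named real dataset's shape at desk scale.

    Line counts are taken verbatim; marker counts are capped at
    ``MARKER_CAP``.  Trait parameters use neutral defaults (heritability 0.5,
    symmetric noise) — the real traits' distributions are not public, so
    profiles are explicitly stand-ins for shape, not for substance.
    """
    try:
        n_lines, n_markers = PROFILE_SHAPES[name]
    except KeyError:
        known = ", ".join(sorted(PROFILE_SHAPES))
        raise KeyError(f"unknown dataset profile {name!r}; known profiles: {known}")
    cfg = SimulationConfig(
        n_lines=n_lines, n_markers=min(n_markers, MARKER_CAP), seed=seed
    )
    return replace(cfg, **overrides) if overrides else cfg
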