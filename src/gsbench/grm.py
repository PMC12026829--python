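"""Genomic relationship matrix (GRM) construction.

The GRM quantifies realized additive genetic similarity between lines from
genome-wide SNP dosages.  We use VanRaden's first method: with dosage matrix
``X`` (lines x markers, values 0/1/2) and per-marker allele frequencies
``p_j = mean(x_j)/2``,

    G = W W^T / (2 * sum_j p_j (1 - p_j)),    w_ij = x_ij - 2 p_j.

``G`` is symmetric positive semi-definite by construction; a small ridge
``epsilon * I`` is added on demand to guarantee the invertibility that mixed
model prediction requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InputError

#: default ridge added to G before any linear solve
DEFAULT_EPSILON = 1e-6


@dataclass
class MarkerMatrix:
    """Biallelic SNP dosages for a set of lines.

    Parameters
    ----------
    line_ids
        Unique string identifiers, one per row.
    dosages
        ``(n_lines, n_markers)`` array with entries in {0, 1, 2}; ``NaN``
        marks a missing genotype (mean-imputed before any GRM computation).
    marker_ids
        Optional marker names (generated if omitted).
    """

    line_ids: np.ndarray
    dosages: np.ndarray
    marker_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=str)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise InputError("dosages must be a 2-D lines x markers array")
        if len(self.line_ids) != self.dosages.shape[0]:
            raise InputError(
                f"{len(self.line_ids)} line ids for {self.dosages.shape[0]} dosage rows"
            )
        if len(np.unique(self.line_ids)) != len(self.line_ids):
            raise InputError("duplicate line identifiers")
        if self.marker_ids is None:
            width = max(5, len(str(self.dosages.shape[1])))
            self.marker_ids = np.array(
                [f"M{j:0{width}d}" for j in range(self.dosages.shape[1])]
            )
        else:
            self.marker_ids = np.asarray(self.marker_ids, dtype=str)
            if len(self.marker_ids) != self.dosages.shape[1]:
                raise InputError("marker_ids length does not match dosage columns")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]


@dataclass
class GRM:
    """Genomic relationship matrix over a set of lines."""

    line_ids: np.ndarray
    values: np.ndarray
    regularization_epsilon: float = DEFAULT_EPSILON
    n_markers_used: int = field(default=0)

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=str)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise InputError("GRM must be square over line_ids")
        if self.regularization_epsilon < 0:
            raise InputError("regularization epsilon must be non-negative")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def regularized(self) -> np.ndarray:
        """G + epsilon * I — the matrix every solver in the package uses."""
        return self.values + self.regularization_epsilon * np.eye(self.n_lines)

    def indices_of(self, ids) -> np.ndarray:
        """Positions of ``ids`` within ``line_ids`` (order preserved)."""
        lookup = {lid: i for i, lid in enumerate(self.line_ids)}
        try:
            return np.array([lookup[str(i)] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise InputError(f"line id {exc.args[0]!r} not present in GRM") from exc


def impute_missing(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per marker column.

    Columns that are entirely missing become all-zero (monomorphic) and are
    handled by the monomorphic policy downstream.
    """
    out = np.array(dosages, dtype=float)
    if not np.isnan(out).any():
        return out
    col_mean = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.where(np.isnan(out))
    out[nan_r, nan_c] = col_mean[nan_c]
    return out


def allele_frequencies(markers: MarkerMatrix) -> np.ndarray:
    """Per-marker allele frequency ``p_j = mean(dosage_j) / 2``."""
    dosages = impute_missing(markers.dosages)
    return dosages.mean(axis=0) / 2.0


def compute_grm(
    markers: MarkerMatrix,
    monomorphic_policy: str = "drop",
    epsilon: float = DEFAULT_EPSILON,
) -> GRM:
    """VanRaden method-1 genomic relationship matrix.

    Parameters
    ----------
    markers
        Dosage matrix; missing values are mean-imputed per marker first.
    monomorphic_policy
        ``"drop"`` removes zero-variance markers before centering (default);
        ``"keep"`` retains them (they contribute nothing to W but inflate the
        denominator through p(1-p) when heterozygous-fixed).
    epsilon
        Ridge recorded on the returned GRM and applied by ``.regularized``.
    """
    if monomorphic_policy not in ("drop", "keep"):
        raise InputError(f"unknown monomorphic_policy {monomorphic_policy!r}")
    dosages = impute_missing(markers.dosages)
    if dosages.shape[0] < 2:
        raise DegenerateInputError("need at least 2 lines to build a GRM")

    variances = dosages.var(axis=0)
    polymorphic = variances > 0
    if not polymorphic.any():
        raise DegenerateInputError("all markers are monomorphic")
    if monomorphic_policy == "drop":
        dosages = dosages[:, polymorphic]
    if dosages.shape[1] < 2:
        raise DegenerateInputError("fewer than 2 polymorphic markers")

    p = dosages.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise DegenerateInputError("zero heterozygosity; GRM denominator is 0")
    w = dosages - 2.0 * p
    values = (w @ w.T) / denom
    values = 0.5 * (values + values.T)  # kill asymmetric round-off
    return GRM(
        line_ids=markers.line_ids,
        values=values,
        regularization_epsilon=epsilon,
        n_markers_used=dosages.shape[1],
    )
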