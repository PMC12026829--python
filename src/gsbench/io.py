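"""Plain-text readers and writers for every artifact the pipeline produces.

All formats are headered CSV: markers (lines as rows, first column the line
ID, remaining columns marker dosages), phenotypes (line ID, value),
outlier flags (line ID, boolean), GRM (line IDs as both header and first
column), quantile-transfer knots, fold-level evaluation tables, and a JSON
fit summary.  A read-only VCF path converts GT fields to 0/1/2 dosages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .gblup import GBLUPFit
from .grm import GRM, MarkerMatrix
from .quantile_mapping import TransferFunction
from .simulate import SyntheticDataset

logger = logging.getLogger(__name__)

MISSING_TOKENS = ("", "NA", "NaN", "nan")


# ---------------------------------------------------------------- markers

def write_markers(markers: MarkerMatrix, path) -> None:
    df = pd.DataFrame(
        markers.dosages, index=markers.line_ids, columns=markers.marker_ids
    )
    df.index.name = "line_id"
    df.to_csv(path)


def read_markers(path, format: str = "csv") -> MarkerMatrix:
    """Read a marker matrix from CSV (as written here) or VCF."""
    if format == "csv":
        return _read_markers_csv(path)
    if format == "vcf":
        return _read_markers_vcf(path)
    raise InputError(f"unknown marker format {format!r}")


def _read_markers_csv(path) -> MarkerMatrix:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise InputError(f"marker file {path} is missing or empty")
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise InputError(f"could not parse marker CSV {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise InputError(f"marker CSV {path} contains no data")
    ids = df.index.astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()][0]
        raise InputError(f"duplicate line id {dup!r} in {path}")
    return MarkerMatrix(
        line_ids=ids.to_numpy(),
        dosages=df.to_numpy(dtype=float),
        marker_ids=df.columns.astype(str).to_numpy(),
    )


def _read_markers_vcf(path) -> MarkerMatrix:
    """Biallelic SNPs only; multi-allelic records are dropped (counted in the
    log) and missing genotypes mean-imputed."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise InputError("VCF support requires the cyvcf2 package") from exc

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=str)
    if len(samples) == 0:
        raise InputError(f"VCF {path} has no samples")
    rows, marker_ids, n_dropped = [], [], 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_dropped += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = variant.gt_types
        dosage = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        rows.append(dosage)
        marker_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    if n_dropped:
        logger.warning("dropped %d non-biallelic records from %s", n_dropped, path)
    if not rows:
        raise InputError(f"no biallelic records in VCF {path}")
    dosages = np.array(rows).T  # rows are per-marker; transpose to lines x markers
    mm = MarkerMatrix(
        line_ids=samples, dosages=dosages, marker_ids=np.asarray(marker_ids, dtype=str)
    )
    from .grm import impute_missing

    mm.dosages = impute_missing(mm.dosages)
    return mm


# ------------------------------------------------------------- phenotypes

def write_phenotypes(phenotypes: pd.Series, path) -> None:
    s = pd.Series(phenotypes)
    s.index.name = "line_id"
    s.rename("value").to_csv(path)


def read_phenotypes(path, known_ids=None) -> pd.Series:
    """Two-column CSV (line_id, value).  Missing-value tokens are kept as NaN
    (prediction-only lines).  If ``known_ids`` is given, an unknown line ID
    is an error naming the offender."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise InputError(f"phenotype file {path} is missing or empty")
    df = pd.read_csv(path, na_values=list(MISSING_TOKENS), keep_default_na=True)
    if df.shape[1] < 2:
        raise InputError(f"phenotype CSV {path} needs (line_id, value) columns")
    s = pd.Series(
        df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str), name="value"
    )
    if s.index.duplicated().any():
        dup = s.index[s.index.duplicated()][0]
        raise InputError(f"duplicate line id {dup!r} in {path}")
    if known_ids is not None:
        known = set(np.asarray(known_ids, dtype=str))
        unknown = [lid for lid in s.index if lid not in known]
        if unknown:
            raise InputError(f"phenotype for unknown line id {unknown[0]!r}")
    return s


def write_flags(flags: pd.Series, path) -> None:
    s = pd.Series(flags, dtype=bool)
    s.index.name = "line_id"
    s.rename("is_outlier").to_csv(path)


def read_flags(path) -> pd.Series:
    df = pd.read_csv(path, index_col=0)
    return df.iloc[:, 0].astype(bool)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Write a simulated dataset's marker/phenotype/flag files; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "markers": outdir / "markers.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "flags": outdir / "outlier_flags.csv",
        "config": outdir / "simulation_config.json",
    }
    write_markers(dataset.markers, paths["markers"])
    write_phenotypes(dataset.phenotype_series(), paths["phenotypes"])
    write_flags(
        pd.Series(dataset.true_outlier_flags, index=dataset.line_ids), paths["flags"]
    )
    paths["config"].write_text(json.dumps(asdict(dataset.config), indent=2) + "\n")
    return {k: str(v) for k, v in paths.items()}


# -------------------------------------------------------------------- GRM

def write_grm(grm: GRM, path) -> None:
    df = pd.DataFrame(grm.values, index=grm.line_ids, columns=grm.line_ids)
    df.index.name = "line_id"
    df.to_csv(path)


def read_grm(path, epsilon: float | None = None) -> GRM:
    df = pd.read_csv(path, index_col=0)
    kwargs = {} if epsilon is None else {"regularization_epsilon": epsilon}
    return GRM(
        line_ids=df.index.astype(str).to_numpy(), values=df.to_numpy(dtype=float), **kwargs
    )


# ------------------------------------------------------------- transfer fn

def write_transfer(tf: TransferFunction, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_knots={tf.n_knots} policy={tf.extrapolation_policy}\n")
        fh.write("x_quantile,y_quantile\n")
        for x, y in zip(tf.x_quantiles, tf.y_quantiles):
            fh.write(f"{float(x)!r},{float(y)!r}\n")


def read_transfer(path) -> TransferFunction:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise InputError(f"transfer file {path} lacks its metadata header")
        meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
        df = pd.read_csv(fh, float_precision="round_trip")
    return TransferFunction(
        x_quantiles=df["x_quantile"].to_numpy(),
        y_quantiles=df["y_quantile"].to_numpy(),
        n_knots=int(meta["n_knots"]),
        extrapolation_policy=meta["policy"],
    )


# ------------------------------------------------------------ fit summary

def write_fit_summary(fit: GBLUPFit, path, observed: pd.Series | None = None) -> None:
    """JSON with the variance components plus a predictions CSV alongside."""
    path = Path(path)
    summary = {
        "mu_hat": fit.mu_hat,
        "sigma_g2": fit.sigma_g2,
        "sigma_e2": fit.sigma_e2,
        "heritability": fit.heritability,
        "method": fit.method,
        "mcmc_diagnostics": fit.mcmc_diagnostics,
    }
    path.write_text(json.dumps(summary, indent=2) + "\n")
    pred = pd.DataFrame({"predicted": fit.predictions})
    pred.index.name = "line_id"
    if observed is not None:
        pred.insert(0, "observed", pd.Series(observed).reindex(pred.index))
    pred.to_csv(path.with_suffix(".predictions.csv"))
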