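#!/usr/bin/env python
"""Generate the three profile-shaped synthetic datasets used by the benchmark.

The profiles reproduce the line counts of the Disease, EYT_1 and Wheat_1
datasets (marker counts capped at the desk-scale ceiling) with heritability
0.5, symmetric noise and 5% contamination at 5 residual SD — the shapes the
downstream scripts analyze.  Full marker/phenotype CSVs go to scratch/
(regenerable; they are large); a compact per-dataset summary table is kept
under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gsbench import dataset_profile, simulate_dataset
from gsbench.io import write_dataset

ROOT = Path(__file__).resolve().parents[1]
PROFILES = ("Disease", "EYT_1", "Wheat_1")
MASTER_SEED = 2025


def main() -> None:
    rows = []
    for name in PROFILES:
        cfg = dataset_profile(
            name, seed=MASTER_SEED, outlier_fraction=0.05, outlier_magnitude=5.0
        )
        ds = simulate_dataset(cfg)
        write_dataset(ds, ROOT / "scratch" / "datasets" / name)
        rows.append(
            {
                "dataset": name,
                "n_lines": cfg.n_lines,
                "n_markers": cfg.n_markers,
                "heritability": cfg.heritability,
                "outlier_fraction": cfg.outlier_fraction,
                "phenotype_mean": round(float(np.mean(ds.phenotypes)), 4),
                "phenotype_sd": round(float(np.std(ds.phenotypes, ddof=1)), 4),
                "n_true_outliers": int(ds.true_outlier_flags.sum()),
            }
        )
        print(f"{name}: {cfg.n_lines} lines x {cfg.n_markers} markers, "
              f"{rows[-1]['n_true_outliers']} contaminated lines")
    out = ROOT / "results" / "dataset_summary.csv"
    out.parent.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
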