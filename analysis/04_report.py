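#!/usr/bin/env python
"""Narrate the benchmark: per-dataset and across-dataset summaries with
relative efficiencies (percent differences between model variants).

Reads the fold metrics written by 03_run_benchmark.py and writes a plain
markdown report ranking the 10 variants by average COR and NRMSE.
"""

from pathlib import Path

from gsbench import summarize_across
from gsbench.evaluation import EvaluationTable, narrate_summary

ROOT = Path(__file__).resolve().parents[1]
PROFILES = ("Disease", "EYT_1", "Wheat_1")


def main() -> None:
    outdir = ROOT / "results" / "benchmark"
    tables = [
        EvaluationTable.from_csv(outdir / f"{name}_fold_metrics.csv")
        for name in PROFILES
    ]
    chunks = [
        narrate_summary(t.variant_averages().drop(columns="dataset"), dataset=name)
        for name, t in zip(PROFILES, tables)
    ]
    across = summarize_across(tables)
    across.to_csv(ROOT / "results" / "across_datasets_summary.csv", index=False)
    chunks.append(narrate_summary(across, dataset="across datasets"))
    report = ROOT / "results" / "report.md"
    report.write_text("\n".join(chunks))
    print(chunks[-1])
    print(f"wrote {report}")


if __name__ == "__main__":
    main()
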