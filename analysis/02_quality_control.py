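#!/usr/bin/env python
"""Quality control and neutral-SNP-panel construction.

Runs the QC cascade (duplicates, sex-linked screen, call-rate / MAF / tag
filters) and the two outlier scans on the synthetic study, then removes
consensus outliers to form the neutral panel every later stage uses.
"""

import json
from pathlib import Path

from seascapegen.pipeline import RunConfig, run_pipeline

IN = Path("results/synthetic")
OUT = Path("results/pipeline")


def config() -> RunConfig:
    return RunConfig(
        genotypes=str(IN / "genotypes.csv"),
        metadata=str(IN / "metadata.csv"),
        bathymetry=str(IN / "bathymetry.asc"),
        out_dir=str(OUT),
        k_range=[1, 2, 3, 4, 5],
        admixture_replicates=3,
        admixture_max_iter=2000,
        n_boot=1000,
        n_perm=999,
        de_maxiter=8,
        de_popsize=6,
    )


def main() -> None:
    run_pipeline(config(), stages=["qc"])
    report = json.loads((OUT / "qc_report.json").read_text())
    f = report["filter"]
    print(f"QC: {f['n_samples_in']} samples x {f['n_loci_in']} loci in -> "
          f"{f['n_samples_out']} x {f['n_loci_out']} out")
    for step in f["steps"]:
        print(f"  {step['step']}: removed {step['removed']}")
    print(f"duplicates: {len(report['duplicates'])}, "
          f"sex-linked removed: {len(report['sex_linked_removed'])}, "
          f"consensus outliers removed: "
          f"{len(report['consensus_outliers_removed'])}")


if __name__ == "__main__":
    main()
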