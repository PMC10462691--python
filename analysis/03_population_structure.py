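#!/usr/bin/env python
"""Population structure on the neutral panel.

Pairwise Weir–Cockerham FST and Jost's D with 1000 locus bootstraps and
Benjamini–Hochberg correction, spatially regularized admixture with
cross-entropy choice of K, and relative directional migration with
bootstrap asymmetry tests.
"""

import importlib.util
import json
from pathlib import Path

import pandas as pd

from seascapegen.pipeline import run_pipeline

spec = importlib.util.spec_from_file_location(
    "qc_driver", Path(__file__).parent / "02_quality_control.py"
)
qc_driver = importlib.util.module_from_spec(spec)
spec.loader.exec_module(qc_driver)

OUT = Path("results/pipeline")


def main() -> None:
    run_pipeline(qc_driver.config(), stages=["qc", "structure"])
    fst = pd.read_csv(OUT / "pairwise_fst.csv", index_col=0)
    padj = pd.read_csv(OUT / "pairwise_fst_padj.csv", index_col=0)
    k = json.loads((OUT / "chosen_k.json").read_text())["K"]
    anc = pd.read_csv(OUT / "ancestry_by_location.csv", index_col=0)
    print("pairwise FST:")
    print(fst.round(4))
    n_sig = int((padj.to_numpy() <= 0.05).sum() // 2)
    print(f"significant pairs after FDR (q<=0.05): {n_sig} "
          f"of {fst.shape[0]*(fst.shape[0]-1)//2}")
    print(f"cross-entropy selected K = {k}; mean ancestry by location:")
    print(anc.round(3))


if __name__ == "__main__":
    main()
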