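#!/usr/bin/env python
"""Generate the synthetic multi-tissue PA-seq study.

Writes the full input bundle (genome FASTA, BED12 gene models, gene map,
BED6 cleavage records, ground-truth table) to scratch/sim/ and a small
summary of what was planted to results/simulation_summary.json.
"""

import json
from collections import Counter
from pathlib import Path

from paseq import SimulationConfig, simulate_dataset

ROOT = Path(__file__).resolve().parents[1]
SIM_DIR = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = SimulationConfig(seed=1)
    ds = simulate_dataset(cfg, out_dir=SIM_DIR)

    genuine = [t for t in ds.truth if not t.is_artifact]
    shapes = Counter(t.shape for t in genuine)
    summary = {
        "seed": cfg.seed,
        "n_genes": cfg.n_genes,
        "n_tissues": cfg.n_tissues,
        "n_truth_sites": len(genuine),
        "n_artifact_sites": sum(t.is_artifact for t in ds.truth),
        "n_tissue_specific_sites": sum(t.is_tissue_specific for t in genuine),
        "n_usi_coupled_genes": len(ds.usi_coupled),
        "shape_counts": dict(shapes),
        "tags_per_tissue": ds.profile.library_sizes(),
    }
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "simulation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    print(f"simulated {len(genuine)} genuine PA sites "
          f"({dict(shapes)}) across {cfg.n_genes} genes and "
          f"{cfg.n_tissues} tissues, plus "
          f"{summary['n_artifact_sites']} A-rich priming artifacts")
    print(f"{summary['n_tissue_specific_sites']} sites are tissue-specific "
          f"(90% dominant share); {summary['n_usi_coupled_genes']} genes "
          f"carry the planted 3' UTR shortening coupling")
    print(f"bundle written to {SIM_DIR}")


if __name__ == "__main__":
    main()
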