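#!/usr/bin/env python
"""Call PA clusters from the pooled cleavage profile and score them
against the planted truth.

Reads scratch/sim/, writes results/clusters.tsv and
results/recovery.json.  The caller pools all 13 tissues, resizes each
candidate to its 95% core, drops clusters under 50 tags or with >= 15 A
in the 20 nt downstream of the mode, and classifies NP/BP/WP shapes.
"""

import json
from collections import Counter
from pathlib import Path

from paseq import (CallerParams, GenomeSequence, call_pa_clusters,
                   read_cleavage_sites, truth_recovery_report,
                   write_cluster_table)
from paseq.simulate import read_truth_table

ROOT = Path(__file__).resolve().parents[1]
SIM_DIR = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main() -> None:
    genome = GenomeSequence.from_fasta(SIM_DIR / "genome.fa")
    profile = read_cleavage_sites(SIM_DIR / "cleavage.bed6")
    truth = read_truth_table(SIM_DIR / "truth.tsv")

    clusters = call_pa_clusters(profile, CallerParams(), genome)
    write_cluster_table(clusters, profile.tissues, RESULTS / "clusters.tsv")

    rep = truth_recovery_report(truth, clusters, match_radius=5)
    shapes = Counter(c.shape for c in clusters)
    recovery = {
        "n_clusters": len(clusters),
        "shape_counts": dict(shapes),
        "sensitivity": rep.sensitivity,
        "mean_abs_mode_error_nt": rep.mean_abs_mode_error,
        "max_abs_mode_error_nt": rep.max_abs_mode_error,
        "n_false_clusters": rep.n_false_clusters,
        "shape_agreement": rep.shape_agreement,
        "artifacts_planted": rep.n_artifacts,
        "artifacts_surviving_filter": rep.n_artifacts_surviving,
    }
    with open(RESULTS / "recovery.json", "w") as fh:
        json.dump(recovery, fh, indent=2, sort_keys=True)

    n = len(clusters)
    print(f"called {n} clusters: "
          + ", ".join(f"{k} {v} ({v / n:.1%})" for k, v in shapes.items()))
    print(f"recovery vs truth: sensitivity {rep.sensitivity:.3f}, "
          f"mean |mode error| {rep.mean_abs_mode_error:.2f} nt, "
          f"{rep.n_false_clusters} false clusters")
    print(f"internal-priming filter removed "
          f"{rep.n_artifacts - rep.n_artifacts_surviving}/{rep.n_artifacts} "
          f"planted A-rich artifacts")


if __name__ == "__main__":
    main()
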