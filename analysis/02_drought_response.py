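#!/usr/bin/env python
"""Classify drought-responsive genes from the stress meta-expression panel.

Log2-normalizes the simulated intensities, computes per-replicate
stress/MOCK log2 fold changes, clusters the fold-change profiles with
K-means (k=10), and labels whole clusters up / down / unresponsive at
the 2-fold (|log2FC| >= 1) cluster-mean cutoff.  Reports recovery
against the planted truth.
"""

from pathlib import Path

import pandas as pd

import stressdiel as sd
from stressdiel.expression import read_sample_metadata

SEED = 1
SIM = Path("results/sim")
OUT = Path("results/drought")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = sd.read_expression_matrix(SIM / "stress_matrix.tsv")
    meta = read_sample_metadata(SIM / "stress_metadata.tsv")
    truth = pd.read_csv(SIM / "truth.tsv", sep="\t")

    fcp = sd.fold_change(sd.log2_normalize(matrix), meta)
    fcp.log2fc.to_csv(OUT / "fold_changes.tsv", sep="\t", float_format="%.4f")

    km = sd.kmeans(fcp.log2fc, k=10, seed=SEED)
    labels = sd.label_clusters(km, fcp, up_threshold=1.0, down_threshold=1.0)
    labels.to_csv(OUT / "response_labels.tsv", sep="\t", index=False,
                  float_format="%.4f")
    counts = sd.response_counts(labels)

    merged = labels.merge(truth, on="gene_id")
    up = merged[merged["true_drought_class"] == "up"]
    down = merged[merged["true_drought_class"] == "down"]
    none = merged[merged["true_drought_class"] == "none"]
    print(f"fold changes: {fcp.log2fc.shape[1]} stress/MOCK pairs "
          f"({(fcp.pair_meta['stress_type'] == 'drought').sum()} drought)")
    print(f"K-means k=10 converged, WCSS {km.wcss:.1f}")
    print(f"labels: {counts['n_up']} up, {counts['n_down']} down, "
          f"{counts['n_none']} unresponsive")
    print(f"recovery vs truth: up recall "
          f"{(up['drought_class'] == 'up').mean():.3f}, down recall "
          f"{(down['drought_class'] == 'down').mean():.3f}, false-positive rate "
          f"{(none['drought_class'] != 'none').mean():.3f}")


if __name__ == "__main__":
    main()
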