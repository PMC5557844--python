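#!/usr/bin/env python
"""Generate the synthetic study: stress meta-expression panel, diurnal
leaf time-course, annotations, and interaction tables with ground truth.

Writes everything under results/sim/.  The stress panel has nine series
(six drought, one each cold/heat/submergence) with three stress/MOCK
replicate pairs per series; the diurnal course samples every 2 h over
2 days across nine developmental stages.
"""

from pathlib import Path

import stressdiel as sd
from stressdiel.expression import write_expression_matrix, write_sample_metadata
from stressdiel.simulate import write_annotations, write_interactions, write_truth

SEED = 1
OUT = Path("results/sim")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = sd.SimConfig(n_genes=1000, seed=SEED)

    stress, stress_meta, truth = sd.generate_stress_series(cfg)
    diurnal, diurnal_meta, _ = sd.generate_diurnal_course(cfg)
    annotations = sd.generate_annotations(cfg, n_terms=50, planted_term_fold=10.0)
    interactions, anatomy = sd.generate_interactions(
        cfg, n_pathway_genes=11, n_partners=69
    )

    write_expression_matrix(stress, OUT / "stress_matrix.tsv")
    write_sample_metadata(stress_meta, OUT / "stress_metadata.tsv")
    write_expression_matrix(diurnal, OUT / "diurnal_matrix.tsv")
    write_sample_metadata(diurnal_meta, OUT / "diurnal_metadata.tsv")
    write_truth(truth, OUT / "truth.tsv")
    write_annotations(annotations, OUT / "annotations.tsv")
    write_interactions(interactions, OUT / "interactions.tsv")
    write_expression_matrix(anatomy, OUT / "anatomy_matrix.tsv")
    (OUT / "pathway_genes.txt").write_text("\n".join(cfg.gene_ids[:11]) + "\n")

    n_up = (truth["true_drought_class"] == "up").sum()
    n_down = (truth["true_drought_class"] == "down").sum()
    n_rhythmic = truth["true_rhythmic"].sum()
    print(f"simulated {cfg.n_genes} genes (seed {SEED}) -> {OUT}")
    print(f"  stress panel: {stress.shape[1]} samples in {cfg.n_series} series")
    print(f"  diurnal course: {diurnal.shape[1]} samples")
    print(f"  planted truth: {n_up} up, {n_down} down, {n_rhythmic} rhythmic")
    print(f"  annotations: {annotations['term_id'].nunique()} terms, "
          f"planted {annotations.attrs['planted_terms']}")
    print(f"  interactions: {len(interactions)} edges around 11 pathway genes")


if __name__ == "__main__":
    main()
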