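#!/usr/bin/env python
"""Call diurnally rhythmic genes and assign their peak phase window.

Clusters the median-centered log2 time-courses into seven groups,
scores each cluster centroid with a fixed-period 24-h cosinor fit
(rhythmic iff R2 >= 0.3), and assigns each rhythmic gene the phase
window (predawn / midday / lateday / midnight) with the highest mean
expression.  Reports phase recovery against the planted truth.
"""

from pathlib import Path

import pandas as pd

import stressdiel as sd
from stressdiel.expression import read_sample_metadata
from stressdiel.phases import PHASE_ORDER

SEED = 1
SIM = Path("results/sim")
OUT = Path("results/diurnal")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = sd.read_expression_matrix(SIM / "diurnal_matrix.tsv")
    meta = read_sample_metadata(SIM / "diurnal_metadata.tsv")
    truth = pd.read_csv(SIM / "truth.tsv", sep="\t")

    calls = sd.call_diurnal(
        sd.log2_normalize(matrix), meta, k=7, seed=SEED, r2_threshold=0.3
    )
    calls.to_csv(OUT / "diurnal_calls.tsv", sep="\t", index=False, na_rep="NA",
                 float_format="%.4f")

    merged = calls.merge(truth, on="gene_id")
    true_r = merged["true_rhythmic"]
    recovered = merged[true_r & merged["rhythmic"]]
    print(f"diurnal clustering: k=7 over {matrix.shape[1]} samples")
    print(f"rhythmic calls: {int(calls['rhythmic'].sum())} of {len(calls)} genes")
    print(f"sensitivity {merged.loc[true_r, 'rhythmic'].mean():.3f}, "
          f"specificity {(~merged.loc[~true_r, 'rhythmic']).mean():.3f}, "
          f"phase accuracy {(recovered['phase'] == recovered['true_phase']).mean():.3f}")
    dist = calls.loc[calls["rhythmic"], "phase"].value_counts(normalize=True)
    print("peak-window distribution:",
          ", ".join(f"{nm} {100 * dist.get(nm, 0):.1f}%" for nm in PHASE_ORDER))


if __name__ == "__main__":
    main()
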