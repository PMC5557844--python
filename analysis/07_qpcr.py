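#!/usr/bin/env python
"""Relative quantification of a drought-marker transcript by 2^-ddCt.

A worked qRT-PCR example: target and housekeeping-reference Ct values
for three biological replicates per group (drought-treated vs control).
dCt = Ct(target) - Ct(reference); ddCt = mean treated dCt - mean
control dCt; relative expression = 2^-ddCt.  Significance between the
two groups' dCt values uses Welch's two-tailed unequal-variance t-test
with star annotation.
"""

from pathlib import Path

import pandas as pd

import stressdiel as sd

OUT = Path("results/qpcr")

# three replicates per group; reference gene stable at ~Ct 18
CT_RECORDS = [
    ("treatment", 1, "target", 22.1), ("treatment", 1, "reference", 18.0),
    ("treatment", 2, "target", 22.4), ("treatment", 2, "reference", 18.2),
    ("treatment", 3, "target", 21.9), ("treatment", 3, "reference", 17.9),
    ("control", 1, "target", 25.3), ("control", 1, "reference", 18.1),
    ("control", 2, "target", 25.6), ("control", 2, "reference", 18.0),
    ("control", 3, "target", 25.1), ("control", 3, "reference", 18.2),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        CT_RECORDS, columns=["sample_group", "replicate", "gene", "ct"]
    )
    table.to_csv(OUT / "ct_values.tsv", sep="\t", index=False)
    result = sd.ddct_fold(table)
    result.delta_ct.to_csv(OUT / "delta_ct.tsv", sep="\t", index=False,
                           float_format="%.4f")
    pd.DataFrame([{
        "ddct": result.ddct, "fold": result.fold, "se": result.se,
        "welch_t": result.welch_t, "welch_df": result.welch_df,
        "p_two_tailed": result.p_two_tailed, "stars": result.stars,
    }]).to_csv(OUT / "relative_quantification.tsv", sep="\t", index=False,
               float_format="%.6g")

    print(f"ddCt = {result.ddct:.3f} -> relative expression "
          f"{result.fold:.2f}-fold (SE {result.se:.2f})")
    print(f"Welch t = {result.welch_t:.2f}, df = {result.welch_df:.2f}, "
          f"two-tailed P = {result.p_two_tailed:.2e} {result.stars}")


if __name__ == "__main__":
    main()
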