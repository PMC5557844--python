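"""Comparative-Ct (2^-ddCt) relative quantification and significance stars.

dCt = Ct(target) - Ct(reference housekeeping gene), per replicate;
ddCt = mean dCt(treatment) - mean dCt(control); relative expression
fold = 2^-ddCt.  Significance between the two groups' dCt values uses
Welch's unequal-variance two-tailed t-test, annotated with stars at
P <= 0.05 (*), 0.01 (**), 0.001 (***), and 0.0001 (****), thresholds
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, PairingError

SAMPLE_GROUPS = ("treatment", "control")
GENE_ROLES = ("target", "reference")

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*"))


@dataclass
class RelQuantResult:
    delta_ct: pd.DataFrame  # columns: sample_group, replicate, delta_ct, rel_fold
    ddct: float
    fold: float
    se: float
    welch_t: float | None
    welch_df: float | None
    p_two_tailed: float | None
    stars: str


def read_ct_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return validate_ct_table(table)


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    req = {"sample_group", "replicate", "gene", "ct"}
    if not req <= set(table.columns):
        raise FormatError(f"Ct table needs columns {sorted(req)}")
    if (set(table["sample_group"]) - set(SAMPLE_GROUPS)) or (
        set(table["gene"]) - set(GENE_ROLES)
    ):
        raise FormatError(
            f"sample_group must be in {SAMPLE_GROUPS} and gene in {GENE_ROLES}"
        )
    if (table["ct"] <= 0).any():
        raise FormatError("Ct values must be positive cycle counts")
    return table


def ddct_fold(ct_table: pd.DataFrame, se_scale: str = "linear") -> RelQuantResult:
    """Relative quantification by the comparative Ct method.

    Per-replicate relative folds 2^-(dCt - mean control dCt) are
    retained for error bars; their standard error over replicates is
    reported on the linear scale by default (``se_scale="log2"`` gives
    the SE of the per-replicate -dCt values instead).  Welch's test
    compares the two groups' dCt values when both have >= 2 replicates.
    """
    table = validate_ct_table(ct_table)
    wide = table.pivot_table(
        index=["sample_group", "replicate"], columns="gene", values="ct",
        aggfunc="first",
    )
    for role in GENE_ROLES:
        if role not in wide.columns:
            raise PairingError(f"no {role} Ct values present")
    missing = wide[wide.isna().any(axis=1)]
    if len(missing):
        raise PairingError(
            f"replicates lacking target or reference Ct: {list(missing.index)}"
        )
    dct = (wide["target"] - wide["reference"]).rename("delta_ct").reset_index()
    groups = {g: grp["delta_ct"].to_numpy() for g, grp in dct.groupby("sample_group")}
    for g in SAMPLE_GROUPS:
        if g not in groups or len(groups[g]) < 1:
            raise PairingError(f"no replicates in group {g!r}")

    control_mean = groups["control"].mean()
    ddct = float(groups["treatment"].mean() - control_mean)
    fold = float(2.0 ** (-ddct))
    dct["rel_fold"] = 2.0 ** (-(dct["delta_ct"] - control_mean))

    treat_folds = dct.loc[dct["sample_group"] == "treatment", "rel_fold"].to_numpy()
    if len(treat_folds) > 1:
        if se_scale == "linear":
            se = float(treat_folds.std(ddof=1) / np.sqrt(len(treat_folds)))
        elif se_scale == "log2":
            lg = -(groups["treatment"] - control_mean)
            se = float(lg.std(ddof=1) / np.sqrt(len(lg)))
        else:
            raise ValueError("se_scale must be 'linear' or 'log2'")
    else:
        se = float("nan")

    if len(groups["treatment"]) >= 2 and len(groups["control"]) >= 2:
        t, df, p = welch_test(groups["treatment"], groups["control"])
        star = stars(p)
    else:
        t = df = p = None
        star = ""
    return RelQuantResult(
        delta_ct=dct, ddct=ddct, fold=fold, se=se,
        welch_t=t, welch_df=df, p_two_tailed=p, stars=star,
    )


def welch_test(values_a, values_b) -> tuple[float, float, float]:
    """Welch's two-sample unequal-variance t-test, two-tailed.

    Returns (t, Welch-Satterthwaite df, p).  Each group needs >= 2
    finite values.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb == 0:
        return 0.0, float(len(a) + len(b) - 2), 1.0
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def stars(p: float) -> str:
    """Significance label: '****' at P<=1e-4 down to '*' at P<=0.05."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    for threshold, label in STAR_THRESHOLDS:
        if p <= threshold:
            return label
    return ""
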