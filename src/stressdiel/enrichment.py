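"""Term enrichment: fold enrichment (observed/expected) and hypergeometric P.

For a query of n genes from a background of N, a term annotating K
background genes and k query genes has expected count n*K/N, fold
enrichment k/(n*K/N), and upper-tail probability P(X >= k) for
X ~ Hypergeometric(N, K, n).  A term passes at >= 2-fold enrichment and
P <= 0.05 by default; no multiple-testing correction is applied unless
requested (Benjamini-Hochberg behind ``bh=True``).

The background is the set of genes on the platform (all genes present
in the annotation table's universe), not the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError


@dataclass
class AnnotationTable:
    """Gene -> term annotation with an explicit background universe."""

    pairs: pd.DataFrame  # columns gene_id, term_id; unique pairs
    background: frozenset[str]

    def __post_init__(self) -> None:
        if self.pairs.duplicated(["gene_id", "term_id"]).any():
            raise FormatError("duplicate (gene, term) annotation pairs")
        annotated = set(self.pairs["gene_id"])
        stray = annotated - self.background
        if stray:
            raise FormatError(
                f"annotated genes missing from background: {sorted(stray)[:5]}"
            )

    @property
    def n_background(self) -> int:
        return len(self.background)

    def term_sets(self) -> dict[str, set[str]]:
        return {
            term: set(grp["gene_id"])
            for term, grp in self.pairs.groupby("term_id", sort=True)
        }

    @classmethod
    def from_pairs(
        cls, pairs: pd.DataFrame, background: Collection[str] | None = None
    ) -> "AnnotationTable":
        pairs = pairs[["gene_id", "term_id"]].drop_duplicates()
        if background is None:
            background = set(pairs["gene_id"])
        return cls(pairs=pairs.reset_index(drop=True), background=frozenset(background))


def read_annotations(path, background: Collection[str] | None = None) -> AnnotationTable:
    """Read a two-column (gene_id, term_id) TSV; '#' lines are comments."""
    pairs = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"gene_id", "term_id"} <= set(pairs.columns):
        raise FormatError("annotation TSV needs gene_id and term_id columns")
    return AnnotationTable.from_pairs(pairs, background)


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(n, K) <= N and n <= N and K <= N and N >= 1):
        raise ValueError(
            f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}"
        )


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Evaluated through the survival function, which works in log space,
    so tiny tail probabilities do not underflow to 0 prematurely.
    Returns 1.0 at k = 0.
    """
    _check_counts(k, K, n, N)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fold_enrichment(k: int, K: int, n: int, N: int) -> float:
    """Observed over expected query count: k / (n*K/N)."""
    _check_counts(k, K, n, N)
    if K == 0 or n == 0:
        raise ValueError("fold enrichment undefined for K=0 or n=0")
    return k / (n * K / N)


def enrich(
    query_genes: Collection[str],
    annotations: AnnotationTable,
    min_fold: float = 2.0,
    alpha: float = 0.05,
    min_term_size: int = 2,
    max_term_size: int | None = None,
    bh: bool = False,
) -> pd.DataFrame:
    """Score every term with >= 1 query gene; flag passes at the thresholds.

    Results are sorted by fold enrichment descending.  Terms smaller
    than ``min_term_size`` or larger than ``max_term_size`` (default
    N/2) are excluded before testing to avoid degenerate folds.
    """
    query = set(query_genes)
    if not query:
        raise ValueError("empty query")
    stray = query - annotations.background
    if stray:
        raise ValueError(
            f"query genes absent from background: {sorted(stray)[:5]}"
        )
    N = annotations.n_background
    n = len(query)
    if max_term_size is None:
        max_term_size = N // 2

    rows = []
    for term, members in annotations.term_sets().items():
        K = len(members)
        if K < min_term_size or K > max_term_size:
            continue
        k = len(query & members)
        if k < 1:
            continue
        expected = n * K / N
        fold = fold_enrichment(k, K, n, N)
        p = hypergeom_upper_tail(k, K, n, N)
        rows.append(
            {
                "term_id": term,
                "query_count": k,
                "term_size": K,
                "query_size": n,
                "background": N,
                "expected": expected,
                "fold": fold,
                "p_hyper": p,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "term_id", "query_count", "term_size", "query_size",
            "background", "expected", "fold", "p_hyper",
        ],
    )
    if bh and len(result):
        result["p_bh"] = _benjamini_hochberg(result["p_hyper"].to_numpy())
    p_col = "p_bh" if bh and len(result) else "p_hyper"
    if len(result):
        result["passes"] = (result["fold"] >= min_fold) & (result[p_col] <= alpha)
        result = result.sort_values(
            ["fold", "p_hyper", "term_id"], ascending=[False, True, True]
        ).reset_index(drop=True)
    else:
        result["passes"] = pd.Series(dtype=bool)
    return result


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up FDR-adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
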