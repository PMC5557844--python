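"""Diurnal clustering, cosinor rhythmicity scoring, and peak-phase calling.

A gene's diurnal behaviour is summarized three ways:

* cluster membership from K-means on median-centered log2 time-courses
  (default k=7 groups);
* a rhythmicity score: the fraction of variance explained by a fixed
  24-h cosinor fit ``y = m + a*cos(2*pi*t/24) + b*sin(2*pi*t/24)`` —
  evaluated on the cluster centroid by default, so whole shape-groups
  are called rhythmic or not;
* for rhythmic genes, a peak phase window: the mean of the gene's
  (centered) values inside each of the four clock windows, with the peak
  assigned to the argmax window (ties broken in the fixed order
  predawn, midday, lateday, midnight).

The crosstalk summary then intersects these calls with the drought
up/down labels, reporting counts, one-decimal percentages, and
per-direction phase proportions in percent to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import KmeansResult, kmeans
from .errors import ValidationError
from .expression import ExpressionMatrix
from .phases import PHASE_ORDER, PHASE_WINDOWS, validate_windows


def median_center(values: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's median so clusters group by shape, not level."""
    return values.sub(values.median(axis=1), axis=0)


def cluster_diurnal(
    diurnal_matrix: ExpressionMatrix | pd.DataFrame,
    k: int = 7,
    seed: int = 0,
    center: bool = True,
) -> KmeansResult:
    """K-means over median-centered log2 diurnal time-courses."""
    if isinstance(diurnal_matrix, ExpressionMatrix):
        if diurnal_matrix.scale != "log2":
            raise ValidationError("diurnal matrix must be log2-normalized")
        values = diurnal_matrix.values
    else:
        values = diurnal_matrix
    if center:
        values = median_center(values)
    return kmeans(values, k=k, seed=seed)


def rhythmicity_score(series: np.ndarray, times: np.ndarray) -> float:
    """Variance fraction explained by a fixed-period 24-h cosinor fit.

    Least-squares fit of ``y = m + a cos(2 pi t/24) + b sin(2 pi t/24)``;
    returns R-squared in [0, 1].  A constant series scores 0 by
    convention.  Requires >= 6 timepoints spanning >= 24 h.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValidationError("series and times must be equal-length 1-D arrays")
    if len(y) < 6 or (t.max() - t.min()) < 22:  # 2-h sampling: 0..22 spans a day
        raise ValidationError("need >= 6 timepoints spanning >= 24 h")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        return 0.0
    w = 2.0 * np.pi * t / 24.0
    design = np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    r2 = 1.0 - float((resid**2).sum()) / sst
    return min(max(r2, 0.0), 1.0)


def assign_phase(
    series: np.ndarray,
    hours: np.ndarray,
    windows: dict[str, frozenset[int]] | None = None,
) -> tuple[str, dict[str, float]]:
    """Peak phase window by argmax of the four window means.

    Means pool every sample whose clock hour falls in the window (both
    days, all stages).  Ties go to the first window in PHASE_ORDER.
    """
    windows = PHASE_WINDOWS if windows is None else windows
    validate_windows(windows)
    y = np.asarray(series, dtype=float)
    h = np.asarray(hours)
    means: dict[str, float] = {}
    for name in PHASE_ORDER:
        mask = np.isin(h, list(windows[name]))
        if not mask.any():
            raise ValueError(f"phase window {name!r} has no samples")
        means[name] = float(y[mask].mean())
    best = max(PHASE_ORDER, key=lambda nm: (means[nm], -PHASE_ORDER.index(nm)))
    return best, means


def call_diurnal(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    k: int = 7,
    seed: int = 0,
    r2_threshold: float = 0.3,
    per_gene: bool = False,
    stages: list[int] | None = None,
) -> pd.DataFrame:
    """Cluster the time-course, score rhythmicity, and assign peak phases.

    By default a gene is rhythmic iff its cluster centroid's cosinor R2
    reaches ``r2_threshold`` (``per_gene=True`` scores each gene
    individually instead).  ``stages`` restricts the analysis to a
    subset of developmental stages.
    """
    if matrix.scale != "log2":
        raise ValidationError("call_diurnal requires a log2-normalized matrix")
    meta = metadata.set_index("sample_id").loc[matrix.sample_ids]
    if stages is not None:
        keep = meta["stage"].isin(stages)
        meta = meta[keep]
    values = matrix.values[meta.index]
    hours = meta["hour"].to_numpy()

    centered = median_center(values)
    km = cluster_diurnal(centered, k=k, seed=seed, center=False)

    if per_gene:
        r2_by_gene = np.array(
            [rhythmicity_score(row, hours) for row in centered.to_numpy()]
        )
        gene_r2 = pd.Series(r2_by_gene, index=centered.index)
    else:
        centroid_r2 = {
            j: rhythmicity_score(km.centroids[j], hours) for j in range(k)
        }
        gene_r2 = km.assignments_series().map(centroid_r2)

    rhythmic = gene_r2 >= r2_threshold
    rows = []
    arr = centered.to_numpy()
    for i, gene in enumerate(centered.index):
        phase, means = assign_phase(arr[i], hours)
        rows.append(
            {
                "gene_id": gene,
                "cluster": int(km.assignments[i]),
                "rhythmic": bool(rhythmic.iloc[i]),
                "rhythmicity_r2": float(gene_r2.iloc[i]),
                "phase": phase if rhythmic.iloc[i] else None,
                **{f"mean_{nm}": means[nm] for nm in PHASE_ORDER},
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CrosstalkSummary:
    """Intersection of drought response with diurnal rhythmicity."""

    n_up: int
    n_up_diurnal: int
    pct_up_diurnal: float | None
    n_down: int
    n_down_diurnal: int
    pct_down_diurnal: float | None
    n_crosstalk: int
    phase_proportions_up: dict[str, float]
    phase_proportions_down: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "n_up", "value": self.n_up},
            {"metric": "n_up_diurnal", "value": self.n_up_diurnal},
            {"metric": "pct_up_diurnal", "value": self.pct_up_diurnal},
            {"metric": "n_down", "value": self.n_down},
            {"metric": "n_down_diurnal", "value": self.n_down_diurnal},
            {"metric": "pct_down_diurnal", "value": self.pct_down_diurnal},
            {"metric": "n_crosstalk", "value": self.n_crosstalk},
        ]
        for nm in PHASE_ORDER:
            rows.append({"metric": f"pct_up_{nm}", "value": self.phase_proportions_up.get(nm)})
        for nm in PHASE_ORDER:
            rows.append({"metric": f"pct_down_{nm}", "value": self.phase_proportions_down.get(nm)})
        return pd.DataFrame(rows)


def _phase_proportions(calls: pd.DataFrame) -> dict[str, float]:
    """Percent of rhythmic genes peaking in each window, two decimals."""
    rhythmic = calls[calls["rhythmic"]]
    total = len(rhythmic)
    if total == 0:
        return {nm: float("nan") for nm in PHASE_ORDER}
    return {
        nm: round(100.0 * (rhythmic["phase"] == nm).sum() / total, 2)
        for nm in PHASE_ORDER
    }


def crosstalk_summary(
    response_labels: pd.DataFrame, diurnal_calls: pd.DataFrame
) -> CrosstalkSummary:
    """How many drought up/down genes are also diurnally rhythmic.

    Percentages are 100 * n_both / n_direction rounded to one decimal;
    for an empty direction the percentage is reported absent (None), not
    zero.  Phase proportions per direction are in percent, two decimals.
    """
    merged = response_labels.merge(diurnal_calls, on="gene_id", how="left")
    merged["rhythmic"] = merged["rhythmic"].fillna(False).astype(bool)

    out: dict[str, object] = {}
    props: dict[str, dict[str, float]] = {}
    for direction in ("up", "down"):
        sub = merged[merged["drought_class"] == direction]
        n_dir = len(sub)
        n_both = int(sub["rhythmic"].sum())
        pct = round(100.0 * n_both / n_dir, 1) if n_dir else None
        out[f"n_{direction}"] = n_dir
        out[f"n_{direction}_diurnal"] = n_both
        out[f"pct_{direction}_diurnal"] = pct
        props[direction] = _phase_proportions(sub)

    return CrosstalkSummary(
        n_up=out["n_up"],
        n_up_diurnal=out["n_up_diurnal"],
        pct_up_diurnal=out["pct_up_diurnal"],
        n_down=out["n_down"],
        n_down_diurnal=out["n_down_diurnal"],
        pct_down_diurnal=out["pct_down_diurnal"],
        n_crosstalk=out["n_up_diurnal"] + out["n_down_diurnal"],
        phase_proportions_up=props["up"],
        phase_proportions_down=props["down"],
    )
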