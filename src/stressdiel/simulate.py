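"""Synthetic stress-series and diurnal-course expression data with ground truth.

The generators emulate the statistical structure the pipeline assumes of
its inputs: a meta-expression panel of stress series with paired
stress/MOCK replicates and planted log2 effects for drought-responsive
genes, and a field-grown diurnal leaf time-course sampled every 2 h over
2 days across nine developmental stages, in which rhythmic genes follow
a 24-h cosine peaking inside one of four clock windows.  All generators
emit *linear-scale* intensities (2**log2-value) so the normalization
stage is exercised, and return a truth table for recovery tests.

A single :func:`draw_truth` call (seeded from the config) fixes each
gene's drought class, rhythmicity, phase window and peak hour, so the
stress series, the diurnal course and the annotation/interaction tables
generated from the same config share one consistent ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .expression import ExpressionMatrix
from .phases import PHASE_ORDER, PHASE_SPANS

#: Stress type of each series, cycled over n_series.  Six drought series
#: among nine mirrors the composition of the meta-expression panel.
DEFAULT_SERIES_TYPES = (
    "drought", "drought", "drought", "drought", "drought", "drought",
    "cold", "heat", "submergence",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Fractions are over all genes; effect sizes, amplitudes, baselines and
    noise are in log2 units.  ``phase_mix`` gives the probabilities of
    the four peak windows in the order predawn, midday, lateday, midnight
    and defaults to the observed phase proportions of drought-upregulated
    diurnal genes.
    """

    n_genes: int = 1000
    n_series: int = 9
    replicates_per_series: int = 3
    frac_up: float = 0.1
    frac_down: float = 0.1
    effect_size: float = 2.0
    frac_rhythmic: float = 0.5
    amplitude: float = 1.0
    phase_mix: tuple[float, float, float, float] = (0.35, 0.30, 0.17, 0.18)
    n_stages: int = 9
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    stage_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_series < 1 or self.replicates_per_series < 1:
            raise ConfigurationError("n_series and replicates_per_series must be >= 1")
        if self.n_stages < 1:
            raise ConfigurationError("n_stages must be >= 1")
        for name in ("frac_up", "frac_down", "frac_rhythmic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_up + self.frac_down > 1.0 + 1e-12:
            raise ConfigurationError("frac_up + frac_down must not exceed 1")
        if len(self.phase_mix) != 4:
            raise ConfigurationError("phase_mix needs four probabilities")
        if any(p < 0 for p in self.phase_mix) or abs(sum(self.phase_mix) - 1) > 1e-9:
            raise ConfigurationError("phase_mix must be nonnegative and sum to 1")
        if self.noise_sd < 0 or self.baseline_sd < 0 or self.stage_sd < 0:
            raise ConfigurationError("standard deviations must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        width = max(5, len(str(self.n_genes)))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    """Independent deterministic stream per generator, all rooted at config.seed."""
    key = zlib.crc32(stream.encode("ascii"))  # stable across processes
    ss = np.random.SeedSequence(config.seed, spawn_key=(key,))
    return np.random.default_rng(ss)


def draw_truth(config: SimConfig) -> pd.DataFrame:
    """Assign each gene its planted drought class, rhythmicity and peak.

    ``true_phase``/``true_peak_hour`` are present iff the gene is
    rhythmic; the peak hour is drawn uniformly within the continuous
    clock span of the chosen window (wrapping across midnight).
    """
    rng = _rng(config, "truth")
    n = config.n_genes
    classes = np.array(["none"] * n, dtype=object)
    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))
    order = rng.permutation(n)
    classes[order[:n_up]] = "up"
    classes[order[n_up : n_up + n_down]] = "down"

    rhythmic = rng.random(n) < config.frac_rhythmic
    phase_idx = rng.choice(4, size=n, p=list(config.phase_mix))
    phases = np.array([PHASE_ORDER[i] for i in phase_idx], dtype=object)
    peak = np.empty(n)
    for i, ph in enumerate(phases):
        lo, hi = PHASE_SPANS[ph]
        peak[i] = rng.uniform(lo, hi) % 24.0
    phases[~rhythmic] = None
    peak_col = np.where(rhythmic, peak, np.nan)

    return pd.DataFrame(
        {
            "gene_id": config.gene_ids,
            "true_drought_class": classes,
            "true_rhythmic": rhythmic,
            "true_phase": phases,
            "true_peak_hour": peak_col,
        }
    ).set_index("gene_id")


def generate_stress_series(
    config: SimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Stress meta-expression panel with paired stress/MOCK replicates.

    Each series contributes ``replicates_per_series`` stress/MOCK sample
    pairs.  Drought-series stressed samples of a truth-up (truth-down)
    gene carry a +effect_size (-effect_size) log2 shift; series of other
    stress types carry no planted effect.  Intensities are linear scale.
    """
    truth = draw_truth(config)
    rng = _rng(config, "stress")
    n = config.n_genes
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    effect = np.where(
        truth["true_drought_class"] == "up", config.effect_size,
        np.where(truth["true_drought_class"] == "down", -config.effect_size, 0.0),
    )

    sample_ids, meta_rows, cols = [], [], []
    for s in range(config.n_series):
        stype = DEFAULT_SERIES_TYPES[s % len(DEFAULT_SERIES_TYPES)]
        series_id = f"S{s + 1:02d}_{stype}"
        for rep in range(1, config.replicates_per_series + 1):
            for cond in ("stress", "mock"):
                sid = f"{series_id}_{cond}_r{rep}"
                is_effective = (cond == "stress") and (stype == "drought")
                log2_vals = (
                    baseline
                    + (effect if is_effective else 0.0)
                    + rng.normal(0.0, config.noise_sd, size=n)
                )
                sample_ids.append(sid)
                cols.append(log2_vals)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "series_id": series_id,
                        "stress_type": stype,
                        "condition": cond,
                        "replicate": rep,
                        "stage": np.nan,
                        "day": np.nan,
                        "hour": np.nan,
                    }
                )
    values = pd.DataFrame(
        np.power(2.0, np.column_stack(cols)),
        index=pd.Index(config.gene_ids, name="gene_id"),
        columns=sample_ids,
    )
    matrix = ExpressionMatrix(values=values, scale="linear")
    return matrix, pd.DataFrame(meta_rows), truth.reset_index()


def generate_diurnal_course(
    config: SimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Diurnal leaf time-course: 2-h sampling, 2 days, ``n_stages`` stages.

    Rhythmic genes follow baseline + amplitude * cos(2*pi*(t - peak)/24)
    plus a per-gene-per-stage offset and noise; non-rhythmic genes have
    amplitude 0.  One sample per (stage, day, even hour), linear scale.
    """
    truth = draw_truth(config)
    rng = _rng(config, "diurnal")
    n = config.n_genes
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    stage_offsets = rng.normal(0.0, config.stage_sd, size=(n, config.n_stages))
    amp = np.where(truth["true_rhythmic"], config.amplitude, 0.0)
    peak = np.nan_to_num(truth["true_peak_hour"].to_numpy(), nan=0.0)

    sample_ids, meta_rows, cols = [], [], []
    for stage in range(1, config.n_stages + 1):
        for day in (1, 2):
            for hour in range(0, 24, 2):
                sid = f"T{stage:02d}_d{day}_h{hour:02d}"
                rhythm = amp * np.cos(2.0 * np.pi * (hour - peak) / 24.0)
                log2_vals = (
                    baseline
                    + stage_offsets[:, stage - 1]
                    + rhythm
                    + rng.normal(0.0, config.noise_sd, size=n)
                )
                sample_ids.append(sid)
                cols.append(log2_vals)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "series_id": "RXP_diurnal",
                        "stress_type": "none",
                        "condition": "mock",
                        "replicate": 1,
                        "stage": stage,
                        "day": day,
                        "hour": hour,
                    }
                )
    values = pd.DataFrame(
        np.power(2.0, np.column_stack(cols)),
        index=pd.Index(config.gene_ids, name="gene_id"),
        columns=sample_ids,
    )
    matrix = ExpressionMatrix(values=values, scale="linear")
    return matrix, pd.DataFrame(meta_rows), truth.reset_index()


# Term sizes are drawn log-uniformly between these bounds (as a fraction
# of n_genes for the upper bound); recorded in the table attrs.  Planted
# terms use a higher floor so their signal is large enough to detect.
_TERM_SIZE_MIN = 5
_PLANTED_SIZE_MIN = 30
_TERM_SIZE_MAX_FRAC = 0.1


def generate_annotations(
    config: SimConfig,
    n_terms: int,
    planted_term_fold: float,
    n_planted_terms: int = 3,
) -> pd.DataFrame:
    """Gene -> term annotation table with terms enriched in the target set.

    The target set is the truth genes that are both drought-up and
    rhythmic.  For each planted term the per-gene membership probability
    inside the target set is ``planted_term_fold`` times the background
    rate, with the outside rate lowered so the expected term size is
    unchanged; background term sizes are drawn log-uniformly from
    [5, n_genes/10] (recorded in ``attrs``), with planted terms floored
    at 30 members so the planted signal is detectable.
    """
    if n_terms < 1:
        raise ConfigurationError("n_terms must be >= 1")
    if planted_term_fold < 1:
        raise ConfigurationError("planted_term_fold must be >= 1")
    truth = draw_truth(config)
    rng = _rng(config, "annotations")
    genes = np.array(config.gene_ids)
    n = config.n_genes
    target = ((truth["true_drought_class"] == "up") & truth["true_rhythmic"]).to_numpy()
    n_target = int(target.sum())

    size_max = max(_TERM_SIZE_MIN + 1, int(n * _TERM_SIZE_MAX_FRAC))
    sizes = np.exp(
        rng.uniform(np.log(_TERM_SIZE_MIN), np.log(size_max), size=n_terms)
    ).astype(int)
    n_planted = min(n_planted_terms, n_terms)
    planted_min = min(_PLANTED_SIZE_MIN, size_max)
    sizes[:n_planted] = np.maximum(sizes[:n_planted], planted_min)
    records = []
    planted_ids = []
    for j in range(n_terms):
        term = f"TERM:{j + 1:04d}"
        base_p = sizes[j] / n
        if j < n_planted and n_target > 0:
            p_in = planted_term_fold * base_p
            if p_in > 1.0:
                raise ConfigurationError(
                    f"planted fold {planted_term_fold} infeasible: in-target "
                    f"membership probability {p_in:.3f} exceeds 1 for term size "
                    f"{sizes[j]}"
                )
            p_out = base_p * (n - planted_term_fold * n_target) / (n - n_target)
            if p_out < 0:
                raise ConfigurationError(
                    f"planted fold {planted_term_fold} infeasible for target set "
                    f"of {n_target} genes at term size {sizes[j]}"
                )
            p = np.where(target, p_in, p_out)
            planted_ids.append(term)
        else:
            p = np.full(n, base_p)
        member = rng.random(n) < p
        for g in genes[member]:
            records.append({"gene_id": g, "term_id": term})

    table = pd.DataFrame(records, columns=["gene_id", "term_id"])
    table.attrs["term_size_range"] = (int(_TERM_SIZE_MIN), int(size_max))
    table.attrs["planted_terms"] = planted_ids
    table.attrs["planted_term_fold"] = planted_term_fold
    return table


def generate_interactions(
    config: SimConfig,
    n_pathway_genes: int,
    n_partners: int,
    target_pcc: float = 0.9,
    planted_frac: float = 0.5,
    n_anatomy_samples: int = 24,
) -> tuple[pd.DataFrame, ExpressionMatrix]:
    """Interaction records plus an anatomical-style expression matrix.

    Returns ``n_partners`` undirected (gene_a, gene_b, confidence) edges
    from pathway genes to partner genes, confidences uniform on (0, 1].
    A ``planted_frac`` subset of edges is given correlated expression
    profiles (Pearson ~ ``target_pcc`` on the log2 scale, recorded in the
    ``target_pcc`` column; NaN for unplanted edges); the companion matrix
    is linear scale over ``n_anatomy_samples`` pseudo-anatomy samples.
    """
    if n_pathway_genes < 1 or n_partners < 1:
        raise ConfigurationError("n_pathway_genes and n_partners must be >= 1")
    if n_pathway_genes + n_partners > config.n_genes:
        raise ConfigurationError(
            "n_pathway_genes + n_partners exceeds n_genes; enlarge the gene pool"
        )
    if not -1.0 <= target_pcc <= 1.0:
        raise ConfigurationError("target_pcc must lie in [-1, 1]")
    rng = _rng(config, "interactions")
    genes = config.gene_ids
    pathway = genes[:n_pathway_genes]
    partners = list(
        rng.choice(genes[n_pathway_genes:], size=n_partners, replace=False)
    )

    m = n_anatomy_samples
    profiles: dict[str, np.ndarray] = {
        g: rng.normal(config.baseline_mean, 1.0, size=m) for g in pathway
    }
    rows = []
    n_planted = int(round(planted_frac * n_partners))
    for i, partner in enumerate(partners):
        hub = pathway[int(rng.integers(0, n_pathway_genes))]
        confidence = float(rng.uniform(0.0, 1.0))
        confidence = confidence if confidence > 0 else 1.0  # open at 0
        planted = i < n_planted
        if planted:
            x = profiles[hub]
            z = (x - x.mean()) / x.std()
            eps = rng.normal(0.0, 1.0, size=m)
            eps -= eps.mean() + z * (eps @ z) / (z @ z)  # orthogonalize
            eps /= eps.std()
            y = target_pcc * z + np.sqrt(1 - target_pcc**2) * eps
            profiles[partner] = config.baseline_mean + y
        else:
            profiles[partner] = rng.normal(config.baseline_mean, 1.0, size=m)
        rows.append(
            {
                "gene_a": hub,
                "gene_b": partner,
                "confidence": confidence,
                "target_pcc": target_pcc if planted else np.nan,
            }
        )

    table = pd.DataFrame(rows)
    sample_ids = [f"anat_{i + 1:02d}" for i in range(m)]
    values = pd.DataFrame(
        np.power(2.0, np.array([profiles[g] for g in profiles])),
        index=pd.Index(list(profiles), name="gene_id"),
        columns=sample_ids,
    )
    return table, ExpressionMatrix(values=values, scale="linear")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_annotations(table: pd.DataFrame, path: str | Path) -> None:
    """Write the annotation TSV; the header comment records the size range."""
    lo, hi = table.attrs.get("term_size_range", (None, None))
    with open(path, "w") as fh:
        if lo is not None:
            fh.write(f"# term sizes log-uniform in [{lo}, {hi}]\n")
        table.to_csv(fh, sep="\t", index=False)


def write_interactions(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
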