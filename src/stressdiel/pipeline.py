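"""End-to-end orchestration: simulate -> normalize -> classify -> call
diurnal -> crosstalk -> enrich -> network, from one structured config.

The config is a nested mapping (usually loaded from YAML) with one
section per stage plus a global seed; every stage can be toggled with
``enabled``.  Each stage writes its tables under the run directory, and
a ``manifest.json`` records parameter values, seeds, and a SHA-256
checksum of every output, so a rerun with the same config is verifiably
identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import simulate as sim
from .cluster import kmeans, label_clusters, response_counts
from .diurnal import call_diurnal, crosstalk_summary
from .enrichment import AnnotationTable, enrich
from .expression import (
    ExpressionMatrix,
    filter_missing,
    fold_change,
    log2_normalize,
    read_expression_matrix,
    read_sample_metadata,
    write_expression_matrix,
    write_sample_metadata,
)
from .network import build_network, export_network, overlay_regulator

log = logging.getLogger("stressdiel")

DEFAULT_CONFIG: dict = {
    "out_dir": "run",
    "seed": 0,
    "simulate": {
        "enabled": True,
        "n_genes": 1000,
        "annotations": {"n_terms": 50, "planted_term_fold": 10.0},
        "interactions": {"n_pathway_genes": 11, "n_partners": 69},
    },
    "inputs": {},
    "drought": {"enabled": True, "k": 10, "up_threshold": 1.0, "down_threshold": 1.0},
    "diurnal": {"enabled": True, "k": 7, "r2_threshold": 0.3},
    "crosstalk": {"enabled": True},
    "enrichment": {"enabled": True, "min_fold": 2.0, "alpha": 0.05},
    "network": {"enabled": True, "pcc_threshold": 0.5},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    config = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_inputs(config: dict) -> list[dict]:
    """Pre-flight consistency report; returns machine-readable issues."""
    issues: list[dict] = []
    config = merge_config(config)
    inputs = config.get("inputs", {})
    if not config["simulate"].get("enabled", True):
        for key in ("stress_matrix", "stress_metadata", "diurnal_matrix", "diurnal_metadata"):
            p = inputs.get(key)
            if not p:
                issues.append({"issue": "missing_input", "key": key})
            elif not Path(p).exists():
                issues.append({"issue": "path_not_found", "key": key, "path": str(p)})
        for mkey, dkey in (
            ("stress_matrix", "stress_metadata"),
            ("diurnal_matrix", "diurnal_metadata"),
        ):
            mp, dp = inputs.get(mkey), inputs.get(dkey)
            if mp and dp and Path(mp).exists() and Path(dp).exists():
                try:
                    matrix = read_expression_matrix(mp)
                    meta = read_sample_metadata(dp)
                except Exception as exc:  # report, don't abort
                    issues.append({"issue": "unreadable", "key": mkey, "error": str(exc)})
                    continue
                missing = set(matrix.sample_ids) - set(meta["sample_id"])
                if missing:
                    issues.append(
                        {
                            "issue": "samples_without_metadata",
                            "key": mkey,
                            "samples": sorted(missing)[:10],
                        }
                    )
    return issues


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the enabled stages in dependency order.

    Returns the run directory.  A stage failure raises, naming the
    stage; outputs of completed stages are retained.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        config = merge_config(config)
    run_dir = Path(out_dir if out_dir is not None else config["out_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict = {"config": config, "outputs": {}, "stages": []}

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(run_dir)),
            "sha256": _sha256(path),
        }

    seed = int(config["seed"])
    state: dict = {}
    try:
        if config["simulate"].get("enabled", True):
            _stage_simulate(config, seed, run_dir, state, record)
            manifest["stages"].append("simulate")
        else:
            _stage_load_inputs(config, state)

        if config["drought"].get("enabled", True):
            _stage_drought(config, seed, run_dir, state, record)
            manifest["stages"].append("drought")
        if config["diurnal"].get("enabled", True):
            _stage_diurnal(config, seed, run_dir, state, record)
            manifest["stages"].append("diurnal")
        if (
            config["crosstalk"].get("enabled", True)
            and "labels" in state
            and "calls" in state
        ):
            summary = crosstalk_summary(state["labels"], state["calls"])
            path = run_dir / "crosstalk_summary.tsv"
            summary.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")
            record("crosstalk_summary", path)
            state["crosstalk"] = summary
            manifest["stages"].append("crosstalk")
        if config["enrichment"].get("enabled", True) and "annotations" in state:
            _stage_enrichment(config, run_dir, state, record)
            manifest["stages"].append("enrichment")
        if config["network"].get("enabled", True) and "interactions" in state:
            _stage_network(config, run_dir, state, record)
            manifest["stages"].append("network")
    except Exception as exc:
        stage = manifest["stages"][-1] if manifest["stages"] else "setup"
        log.error("pipeline failed after stage %s: %s", stage, exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return run_dir


def _sim_config(config: dict, seed: int) -> sim.SimConfig:
    params = {
        k: v
        for k, v in config["simulate"].items()
        if k in sim.SimConfig.__dataclass_fields__
    }
    params.setdefault("seed", seed)
    if isinstance(params.get("phase_mix"), list):
        params["phase_mix"] = tuple(params["phase_mix"])
    return sim.SimConfig(**params)


def _stage_simulate(config, seed, run_dir, state, record) -> None:
    sc = _sim_config(config, seed)
    log.info("simulating with %s", asdict(sc))
    stress, stress_meta, truth = sim.generate_stress_series(sc)
    diurnal, diurnal_meta, _ = sim.generate_diurnal_course(sc)
    ann_cfg = config["simulate"].get("annotations", {})
    annotations = sim.generate_annotations(
        sc,
        n_terms=int(ann_cfg.get("n_terms", 50)),
        planted_term_fold=float(ann_cfg.get("planted_term_fold", 10.0)),
    )
    int_cfg = config["simulate"].get("interactions", {})
    interactions, anatomy = sim.generate_interactions(
        sc,
        n_pathway_genes=int(int_cfg.get("n_pathway_genes", 11)),
        n_partners=int(int_cfg.get("n_partners", 69)),
    )
    for name, obj in (
        ("stress_matrix", stress),
        ("diurnal_matrix", diurnal),
        ("anatomy_matrix", anatomy),
    ):
        path = run_dir / f"{name}.tsv"
        write_expression_matrix(obj, path)
        record(name, path)
    for name, df in (
        ("stress_metadata", stress_meta),
        ("diurnal_metadata", diurnal_meta),
        ("truth", truth),
        ("interactions", interactions),
    ):
        path = run_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
        record(name, path)
    ann_path = run_dir / "annotations.tsv"
    sim.write_annotations(annotations, ann_path)
    record("annotations", ann_path)
    state.update(
        stress=stress,
        stress_meta=stress_meta,
        diurnal=diurnal,
        diurnal_meta=diurnal_meta,
        truth=truth,
        annotations=AnnotationTable.from_pairs(annotations, background=sc.gene_ids),
        interactions=interactions,
        anatomy=anatomy,
        pathway=sc.gene_ids[: int(int_cfg.get("n_pathway_genes", 11))],
    )


def _stage_load_inputs(config, state) -> None:
    inputs = config["inputs"]
    state["stress"] = read_expression_matrix(inputs["stress_matrix"])
    state["stress_meta"] = read_sample_metadata(inputs["stress_metadata"])
    state["diurnal"] = read_expression_matrix(inputs["diurnal_matrix"])
    state["diurnal_meta"] = read_sample_metadata(inputs["diurnal_metadata"])
    if inputs.get("annotations"):
        from .enrichment import read_annotations

        state["annotations"] = read_annotations(inputs["annotations"])
    if inputs.get("interactions"):
        from .network import read_interactions

        state["interactions"] = read_interactions(inputs["interactions"])
    if inputs.get("pathway"):
        state["pathway"] = [
            line.strip()
            for line in Path(inputs["pathway"]).read_text().splitlines()
            if line.strip()
        ]
    if inputs.get("anatomy_matrix"):
        state["anatomy"] = read_expression_matrix(inputs["anatomy_matrix"])


def _stage_drought(config, seed, run_dir, state, record) -> None:
    cfg = config["drought"]
    stress_log2 = log2_normalize(state["stress"])
    fcp = fold_change(stress_log2, state["stress_meta"])
    fc_path = run_dir / "fold_changes.tsv"
    out = fcp.log2fc.copy()
    out.index.name = "gene_id"
    out.to_csv(fc_path, sep="\t", na_rep="NA", float_format="%.6g")
    record("fold_changes", fc_path)

    complete = filter_missing(fcp.log2fc)
    km = kmeans(complete, k=int(cfg.get("k", 10)), seed=seed)
    labels = label_clusters(
        km,
        fcp,
        up_threshold=float(cfg.get("up_threshold", 1.0)),
        down_threshold=float(cfg.get("down_threshold", 1.0)),
    )
    path = run_dir / "response_labels.tsv"
    labels.to_csv(path, sep="\t", index=False, float_format="%.6g")
    record("response_labels", path)
    counts = response_counts(labels)
    log.info("drought response counts: %s", counts)
    state["fold_changes"] = fcp
    state["labels"] = labels
    state["response_counts"] = counts


def _stage_diurnal(config, seed, run_dir, state, record) -> None:
    cfg = config["diurnal"]
    diurnal_log2 = log2_normalize(state["diurnal"])
    calls = call_diurnal(
        diurnal_log2,
        state["diurnal_meta"],
        k=int(cfg.get("k", 7)),
        seed=seed,
        r2_threshold=float(cfg.get("r2_threshold", 0.3)),
    )
    path = run_dir / "diurnal_calls.tsv"
    calls.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    record("diurnal_calls", path)
    state["calls"] = calls


def _stage_enrichment(config, run_dir, state, record) -> None:
    cfg = config["enrichment"]
    labels, calls = state.get("labels"), state.get("calls")
    if labels is None or calls is None:
        log.info("enrichment skipped: needs drought labels and diurnal calls")
        return
    merged = labels.merge(calls[["gene_id", "rhythmic"]], on="gene_id", how="left")
    query = merged.loc[
        (merged["drought_class"] == "up") & merged["rhythmic"].fillna(False),
        "gene_id",
    ]
    if query.empty:
        log.info("enrichment skipped: empty up-and-rhythmic query")
        return
    result = enrich(
        query,
        state["annotations"],
        min_fold=float(cfg.get("min_fold", 2.0)),
        alpha=float(cfg.get("alpha", 0.05)),
    )
    path = run_dir / "enrichment.tsv"
    result.to_csv(path, sep="\t", index=False, float_format="%.6g")
    record("enrichment", path)
    state["enrichment"] = result


def _stage_network(config, run_dir, state, record) -> None:
    cfg = config["network"]
    anatomy = state.get("anatomy")
    anatomy_log2 = log2_normalize(anatomy) if anatomy is not None else None
    net = build_network(
        state["pathway"],
        state["interactions"],
        expression=anatomy_log2,
        labels=state.get("labels"),
        calls=state.get("calls"),
        pcc_threshold=float(cfg.get("pcc_threshold", 0.5)),
    )
    if "regulators" in state:
        net = overlay_regulator(net, state["regulators"])
    written = export_network(net, run_dir, fmt="SIF")
    for name, path in written.items():
        record(f"network_{name}", path)
    written = export_network(net, run_dir, fmt="GraphML")
    record("network_graphml", written["graphml"])
    state["network"] = net
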