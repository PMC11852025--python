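"""End-to-end pipeline driver with a reproducibility manifest.

Wires the stages in order — ingest → differential expression → detection →
annotation + topology → target selection — from a single configuration,
writing each stage's output as plain text plus a manifest recording the
effective parameter values and SHA-256 checksums of every input, so a run
can be reproduced and audited.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import detection as det
from . import diffexpr as de
from . import ingest
from . import targets as tg
from . import topology as topo

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    protein_groups: str
    uniprot_annotation: str
    eggnog_annotation: str
    topology: str
    out_dir: str
    topology_format: str = "3line"      # or "tsv"
    min_valid: int = 2
    downshift: float = 1.8
    width: float = 0.3
    alpha: float = 0.05
    lfc_threshold: float = 2.0
    min_reps: int = 2
    direction: str = "BX"
    seed: int = 0
    contrasts: tuple[tuple[str, str], ...] = (
        ("BU", "BX"), ("BU", "BY"), ("BX", "BY"),
    )
    control_condition: str = "BC"


@dataclass
class PipelineResult:
    matrix: ingest.IntensityMatrix
    filter_report: dict
    contrast_results: dict
    profiles: list
    venn: dict
    exclusive: dict
    heatmap: det.HeatmapSet
    target_calls: list
    report: list[dict]
    manifest: dict = field(default_factory=dict)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "contrasts" in raw:
        raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ValueError(f"invalid run configuration: {exc}") from exc


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute every stage; identical config and inputs give identical outputs."""
    excl = (config.control_condition,)

    # ingest
    raw = ingest.read_protein_groups(config.protein_groups)
    filtered, decoy_report = ingest.remove_decoys_and_contaminants(raw)
    matrix = ingest.matrix_from_table(filtered)
    matrix, valid_report = ingest.valid_value_filter(
        matrix, min_valid=config.min_valid, exclude_conditions=excl)
    matrix = ingest.impute_missing(
        matrix, downshift=config.downshift, width=config.width,
        seed=config.seed, exclude_conditions=excl)
    filter_report = {
        "n_input": decoy_report.n_input,
        "n_reverse_removed": decoy_report.n_reverse_removed,
        "n_contaminant_removed": decoy_report.n_contaminant_removed,
        "n_failed_valid_filter": valid_report.n_failed_valid_filter,
        "n_retained": valid_report.n_retained,
    }

    # differential expression
    contrast_results = de.run_contrasts(
        matrix, contrasts=list(config.contrasts),
        alpha=config.alpha, lfc_threshold=config.lfc_threshold)

    # detection
    profiles = det.detection_profiles(matrix)
    venn = det.venn_partition(profiles)
    exclusive = det.exclusive_sets(profiles)
    heatmap = det.build_heatmap_set(matrix, contrast_results, profiles,
                                    exclude_conditions=excl)

    # annotation + topology
    uni = ann.read_annotation_table(config.uniprot_annotation, "uniprot")
    egg = ann.read_annotation_table(config.eggnog_annotation, "eggnog")
    majority = [m.split(";") for m in matrix.majority_ids] \
        if matrix.majority_ids else [[p] for p in matrix.protein_ids]
    records = ann.build_annotation_records(majority, uni, egg)
    interest = {r.unique_protein_id: ann.classify_interest(r) for r in records}
    ann_by_id = {r.unique_protein_id: r for r in records}
    # re-key detection profiles by the representative annotation ID
    rep_of = {pid: rec.unique_protein_id
              for pid, rec in zip(matrix.protein_ids, records)}
    for p in profiles:
        p.protein_id = rep_of.get(p.protein_id, p.protein_id)

    if config.topology_format == "3line":
        topo_records = topo.parse_3line(config.topology)
    else:
        topo_records = topo.parse_topology_table(config.topology)
    topo_by_id = {t.protein_id: t for t in topo_records}

    # target selection
    calls = tg.call_targets(profiles, interest, topo_by_id,
                            min_reps=config.min_reps,
                            direction=config.direction)
    report = tg.selection_report(calls, ann_by_id)

    manifest = {
        "parameters": asdict(config),
        "inputs": {
            name: {"path": str(getattr(config, name)),
                   "sha256": _sha256(getattr(config, name))}
            for name in ("protein_groups", "uniprot_annotation",
                         "eggnog_annotation", "topology")
        },
        "filter_report": filter_report,
        "n_significant": {
            f"{a}-{b}": sum(r.significant for r in res)
            for (a, b), res in contrast_results.items()
        },
        "n_prioritized": sum(1 for c in calls if c.tier == "prioritized"),
        "n_accessible": sum(1 for c in calls if c.tier != "none"),
    }

    result = PipelineResult(
        matrix=matrix, filter_report=filter_report,
        contrast_results=contrast_results, profiles=profiles, venn=venn,
        exclusive=exclusive, heatmap=heatmap, target_calls=calls,
        report=report, manifest=manifest,
    )
    if write_outputs:
        _write_outputs(result, config)
    return result


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    m = result.matrix
    mat = pd.DataFrame(m.values, index=m.protein_ids, columns=m.sample_ids)
    mat.to_csv(out / "matrix_log2.tsv", sep="\t", float_format="%.6f",
               index_label="protein_id")
    masks = pd.DataFrame(
        {"protein_id": [pid for pid in m.protein_ids for _ in m.sample_ids],
         "sample": m.sample_ids * len(m.protein_ids),
         "observed": m.observed_mask.ravel(),
         "imputed": m.imputed_mask.ravel()})
    masks.to_csv(out / "masks.tsv", sep="\t", index=False)

    rows = []
    for res in result.contrast_results.values():
        rows.extend(de.results_to_records(res))
    pd.DataFrame(rows).to_csv(out / "contrasts.tsv", sep="\t", index=False,
                              float_format="%.6g")

    with open(out / "venn.json", "w") as fh:
        json.dump(result.venn, fh, indent=2, default=_json_default)
    pd.DataFrame(result.report).to_csv(out / "target_report.tsv", sep="\t",
                                       index=False)
    if len(result.heatmap.protein_ids):
        hm = pd.DataFrame(result.heatmap.z_values,
                          index=result.heatmap.protein_ids,
                          columns=result.heatmap.sample_ids)
        hm.to_csv(out / "heatmap_z.tsv", sep="\t", float_format="%.6f",
                  index_label="protein_id")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True,
                  default=_json_default)
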