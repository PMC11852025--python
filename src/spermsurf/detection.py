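"""Per-condition detection calls, Venn partition and heatmap-set building.

"Detected" means the protein has an observed (measured, non-imputed) LFQ
value in at least one replicate of a condition — detection never looks at
imputed cells. The Venn partition over three conditions, the
exclusive/absent sets, and the heatmap membership rule (significantly
regulated in any contrast, or completely absent from the X-sorted or
Y-sorted condition) all derive from these detection counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .diffexpr import ContrastResult
from .ingest import IntensityMatrix

__all__ = [
    "DetectionProfile",
    "HeatmapSet",
    "detection_profiles",
    "venn_partition",
    "exclusive_sets",
    "build_heatmap_set",
]


@dataclass
class DetectionProfile:
    protein_id: str
    n_detected: dict[str, int]          # condition -> replicates with observed value

    def detected_any(self, condition: str) -> bool:
        return self.n_detected.get(condition, 0) >= 1


@dataclass
class HeatmapSet:
    """Proteins selected for the clustered expression heatmap."""

    protein_ids: list[str]              # in clustered row order
    reasons: dict[str, list[str]]       # member -> why it is in the set
    z_values: np.ndarray                # rows follow protein_ids
    sample_ids: list[str] = field(default_factory=list)
    missing_mask: np.ndarray | None = None   # non-observed, non-imputed cells


def detection_profiles(matrix: IntensityMatrix) -> list[DetectionProfile]:
    """Count observed replicates per protein per condition."""
    cond_idx = {c: matrix.sample_indices(c) for c in matrix.conditions}
    profiles = []
    for i, pid in enumerate(matrix.protein_ids):
        counts = {c: int(matrix.observed_mask[i, idx].sum())
                  for c, idx in cond_idx.items()}
        profiles.append(DetectionProfile(protein_id=pid, n_detected=counts))
    return profiles


def venn_partition(
    profiles: list[DetectionProfile],
    conditions: tuple[str, str, str] = ("BU", "BX", "BY"),
) -> dict[str, int]:
    """Disjoint region counts of the three-condition Venn diagram.

    Region keys name the conditions a protein is detected in, joined by
    ``&`` in the given order; ``none`` counts proteins detected in no
    listed condition. Regions sum to the number of profiles.
    """
    a, b, c = conditions
    counts = {f"{a}": 0, f"{b}": 0, f"{c}": 0,
              f"{a}&{b}": 0, f"{a}&{c}": 0, f"{b}&{c}": 0,
              f"{a}&{b}&{c}": 0, "none": 0}
    for p in profiles:
        hits = [cond for cond in conditions if p.detected_any(cond)]
        counts["&".join(hits) if hits else "none"] += 1
    return counts


def exclusive_sets(
    profiles: list[DetectionProfile],
    x_condition: str = "BX",
    y_condition: str = "BY",
    u_condition: str = "BU",
) -> dict[str, set[str]]:
    """Detection-based protein sets used for target screening.

    ``absent_in_BY`` — detected in the X-sorted or unsexed condition,
    never in the Y-sorted one (and symmetric for ``absent_in_BX``);
    ``bx_only`` / ``bu_only`` / ``bx_and_bu`` partition the
    absent-in-BY set by which of BX/BU carries the detections.
    """
    out: dict[str, set[str]] = {
        "absent_in_BY": set(), "absent_in_BX": set(),
        "bx_only": set(), "bu_only": set(), "bx_and_bu": set(),
    }
    for p in profiles:
        in_x = p.detected_any(x_condition)
        in_y = p.detected_any(y_condition)
        in_u = p.detected_any(u_condition)
        if (in_x or in_u) and not in_y:
            out["absent_in_BY"].add(p.protein_id)
            if in_x and in_u:
                out["bx_and_bu"].add(p.protein_id)
            elif in_x:
                out["bx_only"].add(p.protein_id)
            else:
                out["bu_only"].add(p.protein_id)
        if (in_y or in_u) and not in_x:
            out["absent_in_BX"].add(p.protein_id)
    return out


def build_heatmap_set(
    matrix: IntensityMatrix,
    contrast_results: dict[tuple[str, str], list[ContrastResult]],
    profiles: list[DetectionProfile],
    exclude_conditions: tuple[str, ...] = ("BC",),
) -> HeatmapSet:
    """Assemble the clustered, z-scored heatmap set.

    Members are proteins significant in any contrast, plus proteins
    completely absent from BX or BY. Rows are z-scored over their finite
    (observed or imputed) values and ordered by agglomerative clustering
    (Euclidean distance, average linkage).
    """
    reasons: dict[str, list[str]] = {}
    for contrast, results in contrast_results.items():
        tag = f"significant-{contrast[0]}-{contrast[1]}"
        for r in results:
            if r.significant:
                reasons.setdefault(r.protein_id, []).append(tag)
    excl = exclusive_sets(profiles)
    for pid in sorted(excl["absent_in_BX"]):
        reasons.setdefault(pid, []).append("absent-in-BX")
    for pid in sorted(excl["absent_in_BY"]):
        reasons.setdefault(pid, []).append("absent-in-BY")

    row_of = {pid: i for i, pid in enumerate(matrix.protein_ids)}
    keep_cols = [j for j, s in enumerate(matrix.sample_ids)
                 if matrix.condition_of[s] not in exclude_conditions]
    members = [pid for pid in matrix.protein_ids if pid in reasons]

    usable, z_rows = [], []
    for pid in members:
        i = row_of[pid]
        vals = matrix.values[i, keep_cols]
        finite = np.isfinite(vals)
        if finite.sum() < 2 or np.nanstd(vals, ddof=1) == 0:
            warnings.warn(
                f"heatmap member {pid} has <2 finite values or zero spread; excluded"
            )
            continue
        mu = np.nanmean(vals)
        sd = np.nanstd(vals, ddof=1)
        z_rows.append((vals - mu) / sd)
        usable.append(pid)

    if not usable:
        return HeatmapSet(protein_ids=[], reasons=reasons,
                          z_values=np.empty((0, len(keep_cols))),
                          sample_ids=[matrix.sample_ids[j] for j in keep_cols])

    z = np.vstack(z_rows)
    if len(usable) > 2:
        zc = np.nan_to_num(z, nan=0.0)  # missing cells contribute zero distance
        order = leaves_list(linkage(pdist(zc), method="average"))
    elif len(usable) == 2:
        order = np.array([0, 1])
    else:
        order = np.array([0])

    obs_or_imp = matrix.observed_mask | matrix.imputed_mask
    missing = np.vstack([~obs_or_imp[row_of[pid]][keep_cols] for pid in usable])
    return HeatmapSet(
        protein_ids=[usable[i] for i in order],
        reasons=reasons,
        z_values=z[order],
        sample_ids=[matrix.sample_ids[j] for j in keep_cols],
        missing_mask=missing[order],
    )
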