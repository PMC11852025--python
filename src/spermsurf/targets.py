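"""Target-selection rule engine for sex-specific surface markers.

Joins three evidence layers per protein — GO localization categories,
predicted membrane topology, and per-condition detection counts — into a
candidate tier:

``accessible``
    surface-accessible by the GO/topology disjunction below, detected in at
    least one replicate of the sorted condition of interest (default BX)
    and in zero replicates of the opposite sorted condition (default BY).

``prioritized``
    additionally transmembrane with ≥1 membrane-spanning region and
    detected in at least ``min_reps`` (default 2) replicates of the sorted
    condition of interest — the proteins one would raise an antibody
    against for immunological sperm sexing.

Surface accessibility is the disjunction:
  1. any of the categories CS, ESPM, ECESPM, ACESPM, ICESPM, ESCW, ESCOM
     (these denote the external face or the cell surface outright);
  2. PM, ACPM or ICPM combined with a transmembrane prediction or at least
     one sequence segment predicted outside the membrane;
  3. extracellular space (ES) combined with a transmembrane prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .annotation import AnnotationRecord, InterestCall
from .detection import DetectionProfile
from .topology import TopologyRecord, is_transmembrane

__all__ = [
    "SURFACE_DIRECT_CATEGORIES",
    "SURFACE_TOPOLOGY_CATEGORIES",
    "TargetCall",
    "surface_accessible",
    "call_targets",
    "selection_report",
]

# Disjunct 1: categories sufficient on their own.
SURFACE_DIRECT_CATEGORIES = frozenset(
    {"CS", "ESPM", "ECESPM", "ACESPM", "ICESPM", "ESCW", "ESCOM"}
)
# Disjunct 2: categories needing topology support (TM or an outside segment).
SURFACE_TOPOLOGY_CATEGORIES = frozenset({"PM", "ACPM", "ICPM"})

_TIER_ORDER = {"prioritized": 0, "accessible": 1, "none": 2}


@dataclass
class TargetCall:
    protein_id: str
    of_interest: bool
    surface_accessible: bool
    bx_replicates_detected: int
    by_replicates_detected: int
    is_transmembrane: bool
    tier: str                      # none | accessible | prioritized
    evidence: list[str] = field(default_factory=list)


def surface_accessible(interest: InterestCall, topo: TopologyRecord) -> tuple[bool, list[str]]:
    """Evaluate the three-part surface-accessibility disjunction.

    Returns the flag together with the list of satisfied disjuncts.
    """
    if interest.protein_id != topo.protein_id:
        raise ValueError(
            f"join mismatch: {interest.protein_id!r} vs {topo.protein_id!r}"
        )
    cats = interest.categories_hit
    tm = is_transmembrane(topo)
    evidence = []
    if cats & SURFACE_DIRECT_CATEGORIES:
        evidence.append(
            "surface-GO:" + ",".join(sorted(cats & SURFACE_DIRECT_CATEGORIES))
        )
    if cats & SURFACE_TOPOLOGY_CATEGORIES and (tm or topo.has_outside_region):
        via = "transmembrane" if tm else "outside-segment"
        evidence.append(
            "membrane-GO+" + via + ":"
            + ",".join(sorted(cats & SURFACE_TOPOLOGY_CATEGORIES))
        )
    if "ES" in cats and tm:
        evidence.append("extracellular-GO+transmembrane")
    return bool(evidence), evidence


def call_targets(
    profiles: list[DetectionProfile],
    interest_calls: dict[str, InterestCall],
    topo_records: dict[str, TopologyRecord],
    min_reps: int = 2,
    direction: str = "BX",
) -> list[TargetCall]:
    """Assign a candidate tier to every profiled protein.

    ``direction`` names the sorted condition whose specific proteins are
    sought; the opposite sorted condition must show zero detections. A
    protein missing from the topology input is treated as globular with a
    warning (never dropped).
    """
    if direction not in {"BX", "BY"}:
        raise ValueError("direction must be 'BX' or 'BY'")
    other = "BY" if direction == "BX" else "BX"
    calls = []
    for p in profiles:
        pid = p.protein_id
        interest = interest_calls.get(pid)
        if interest is None:
            interest = InterestCall(pid, frozenset(), False, False)
        topo = topo_records.get(pid)
        if topo is None:
            warnings.warn(f"{pid}: no topology prediction; treating as globular")
            topo = TopologyRecord(pid, "GLOB", 0, False)
        tm = is_transmembrane(topo)
        accessible, evidence = surface_accessible(interest, topo)
        n_dir = p.n_detected.get(direction, 0)
        n_other = p.n_detected.get(other, 0)
        tier = "none"
        if accessible and n_dir >= 1 and n_other == 0:
            tier = "accessible"
            evidence.append(f"detected-{direction}:{n_dir}")
            evidence.append(f"absent-{other}")
            if n_dir >= min_reps and tm:
                tier = "prioritized"
                evidence.append(f"detected-{direction}>= {min_reps}".replace(" ", ""))
                evidence.append("transmembrane")
        bx = p.n_detected.get("BX", 0)
        by = p.n_detected.get("BY", 0)
        calls.append(TargetCall(
            protein_id=pid,
            of_interest=interest.resolve_of_interest(tm),
            surface_accessible=accessible,
            bx_replicates_detected=bx,
            by_replicates_detected=by,
            is_transmembrane=tm,
            tier=tier,
            evidence=evidence,
        ))
    return calls


def selection_report(
    calls: list[TargetCall],
    annotations: dict[str, AnnotationRecord] | None = None,
) -> list[dict]:
    """Tabular candidate report, sorted by tier then gene name.

    X-chromosome-encoded candidates are flagged, since X-linkage makes a
    copy-number difference between X- and Y-sperm plausible.
    """
    annotations = annotations or {}

    def row(call: TargetCall) -> dict:
        ann = annotations.get(call.protein_id)
        gene = ann.gene_name if ann else ""
        chrom = ann.chromosome if ann else ""
        return {
            "protein_id": call.protein_id,
            "gene_name": gene,
            "chromosome": chrom,
            "x_linked": chrom.upper() == "X",
            "tier": call.tier,
            "surface_accessible": call.surface_accessible,
            "is_transmembrane": call.is_transmembrane,
            "bx_replicates_detected": call.bx_replicates_detected,
            "by_replicates_detected": call.by_replicates_detected,
            "evidence": ";".join(call.evidence),
        }

    rows = [row(c) for c in calls]
    rows.sort(key=lambda r: (_TIER_ORDER[r["tier"]],
                             r["gene_name"] or "~", r["protein_id"]))
    return rows
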