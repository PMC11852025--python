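"""Bundled worked example: a 19-protein bovine sperm surface-candidate panel.

A curated panel of 19 bovine sperm proteins that passed a
surface-accessibility screen, each detected in at least one X-sorted (BX)
replicate and in no Y-sorted (BY) replicate, with its predicted membrane
topology class and the number of BX replicates it was detected in. Running
the target-selection rule engine on this panel is the package's canonical
worked example: seven of the proteins are transmembrane, and five —
ADAM2, ATP11C, PMCA4 (ATP2B4), DSG1 and MCT1 (SLC16A1) — reach the
prioritized tier (transmembrane and detected in ≥2 BX replicates).

Every panel protein carries the cell-surface GO category (CS), which
satisfies the accessibility rule regardless of topology; the panel is an
input to the tier logic, not to the GO screen itself.
"""

from __future__ import annotations

from .annotation import InterestCall
from .detection import DetectionProfile
from .topology import TopologyRecord

__all__ = ["EXAMPLE_CANDIDATES", "example_engine_inputs"]

# protein_id, gene, chromosome, topology class, transmembrane regions,
# BX replicates detected
EXAMPLE_CANDIDATES: tuple[tuple[str, str, str, str, int, int], ...] = (
    ("A0A3Q1LK79", "Adam1b", "17", "SP", 0, 2),
    ("O77780", "ADAM2", "Unplaced", "SP+TM", 1, 3),
    ("P09487", "ALPL", "2", "SP", 0, 1),
    ("F1N3G6", "ATP11C", "X", "TM", 10, 2),
    ("Q3T0C6", "ATP1B3", "1", "TM", 1, 1),
    ("D3K0R6", "ATP2B4", "16", "TM", 10, 2),
    ("P00829", "ATP5F1B", "Unplaced", "GLOB", 0, 2),
    ("Q03763", "DSG1", "Unplaced", "SP+TM", 1, 2),
    ("Q32LB5", "GLIPR1L1", "5", "SP", 0, 3),
    ("Q27975", "HSPA1A", "23", "GLOB", 0, 2),
    ("P0CB32", "HSPA1L", "23", "GLOB", 0, 2),
    ("P34933", "HSPA2", "Unplaced", "GLOB", 0, 2),
    ("Q0VCX2", "HSPA5", "11", "SP", 0, 2),
    ("P19120", "HSPA8", "15", "GLOB", 0, 2),
    ("P31081", "HSPD1", "22", "GLOB", 0, 3),
    ("Q3MHW6", "SLC16A1", "3", "TM", 12, 3),
    ("Q32PB3", "SPACA4", "18", "SP", 0, 2),
    ("F1MTV1", "SPAM1", "4", "SP", 0, 2),
    ("A0A3Q1MQE3", "-", "Unplaced", "SP+TM", 1, 1),
)


def example_engine_inputs() -> tuple[
    list[DetectionProfile], dict[str, InterestCall], dict[str, TopologyRecord]
]:
    """Encode the candidate panel as rule-engine inputs.

    All panel members are surface-accessible by construction (CS
    category); BY detections are zero by the panel's definition.
    """
    profiles, interest, topo = [], {}, {}
    for pid, _gene, _chrom, cls, tmr, bx in EXAMPLE_CANDIDATES:
        profiles.append(DetectionProfile(
            protein_id=pid,
            n_detected={"BU": 0, "BX": bx, "BY": 0},
        ))
        interest[pid] = InterestCall(
            protein_id=pid,
            categories_hit=frozenset({"CS"}),
            of_interest=True,
            needs_tm_for_interest=False,
        )
        topo[pid] = TopologyRecord(
            protein_id=pid,
            predicted_class=cls,
            tmr_count=tmr,
            has_signal_peptide=cls.startswith("SP"),
        ).validate()
    return profiles, interest, topo
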