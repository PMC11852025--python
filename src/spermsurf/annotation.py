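"""Protein-group annotation: unique-ID selection, GO merging, interest calls.

Each MaxQuant protein group lists several "majority protein IDs"; downstream
joins need a single representative, chosen as the first reviewed
(curator-verified) entry or, failing that, simply the first entry.

GO annotations come from two sources — a UniProt-style export and an
eggNOG-mapper-style orthology transfer — and are merged by set union.
Proteins are then screened against a fixed panel of fourteen GO IDs that
denote plasma-membrane, cell-surface or extracellular localization. A
protein is "of interest" when it carries any plasma-membrane/cell-surface
term outright, or the extracellular-space term combined with a
transmembrane topology prediction (resolved downstream once topology is
joined in).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GO_CATEGORY_OF_ID",
    "INTEREST_CATEGORIES",
    "DIRECT_INTEREST_CATEGORIES",
    "AnnotationRecord",
    "InterestCall",
    "select_unique_id",
    "merge_go",
    "classify_interest",
    "read_annotation_table",
    "build_annotation_records",
]

# Fixed panel: GO ID -> localization category. Literal IDs, no ontology
# traversal — the screen matches annotations as printed, not GO descendants.
GO_CATEGORY_OF_ID: dict[str, str] = {
    "GO:0005886": "PM",      # plasma membrane
    "GO:0005904": "PM",
    "GO:0009986": "CS",      # cell surface
    "GO:0009928": "CS",
    "GO:0009929": "CS",
    "GO:0009897": "ESPM",    # external side of plasma membrane
    "GO:0031232": "ECESPM",  # extrinsic component of external side of PM
    "GO:0046658": "ACPM",    # anchored component of plasma membrane
    "GO:0031362": "ACESPM",  # anchored component of external side of PM
    "GO:0071575": "ICESPM",  # integral component of external side of PM
    "GO:0005887": "ICPM",    # integral component of plasma membrane
    "GO:0010339": "ESCW",    # external side of cell wall
    "GO:0031240": "ESCOM",   # external side of cell outer membrane
    "GO:0005615": "ES",      # extracellular space
}

INTEREST_CATEGORIES: tuple[str, ...] = (
    "PM", "CS", "ESPM", "ECESPM", "ACPM", "ACESPM",
    "ICESPM", "ICPM", "ESCW", "ESCOM", "ES",
)

# Categories that make a protein "of interest" regardless of topology; the
# remaining category (ES) additionally requires a transmembrane prediction.
DIRECT_INTEREST_CATEGORIES: frozenset[str] = frozenset(
    c for c in INTEREST_CATEGORIES if c != "ES"
)

_GO_RE = re.compile(r"^GO:\d{7}$")


@dataclass
class AnnotationRecord:
    """Unified annotation for one protein group."""

    unique_protein_id: str
    majority_ids: list[str]
    reviewed: list[bool]
    gene_name: str = ""
    chromosome: str = ""
    go_uniprot: frozenset[str] = field(default_factory=frozenset)
    go_eggnog: frozenset[str] = field(default_factory=frozenset)

    @property
    def go_union(self) -> frozenset[str]:
        return self.go_uniprot | self.go_eggnog


@dataclass
class InterestCall:
    """Result of screening a protein's GO set against the interest panel.

    ``of_interest`` covers the topology-independent rule only;
    ``needs_tm_for_interest`` marks proteins whose sole qualifying category
    is extracellular space (ES), which count as "of interest" only when a
    transmembrane topology is confirmed downstream.
    """

    protein_id: str
    categories_hit: frozenset[str]
    of_interest: bool
    needs_tm_for_interest: bool

    def resolve_of_interest(self, is_transmembrane: bool) -> bool:
        """Final interest flag once topology is known."""
        return self.of_interest or (self.needs_tm_for_interest and is_transmembrane)


def select_unique_id(majority_ids: list[str], reviewed_flags: list[bool]) -> str:
    """Pick the representative ID: first reviewed entry, else the first.

    Raises ``ValueError`` on an empty ID list or mismatched flag length.
    """
    if not majority_ids:
        raise ValueError("majority_ids must be nonempty")
    if len(majority_ids) != len(reviewed_flags):
        raise ValueError(
            f"got {len(majority_ids)} IDs but {len(reviewed_flags)} reviewed flags"
        )
    for pid, rev in zip(majority_ids, reviewed_flags):
        if rev:
            return pid
    return majority_ids[0]


def merge_go(uniprot_set: set[str] | frozenset[str],
             eggnog_set: set[str] | frozenset[str]) -> frozenset[str]:
    """Union of the two source GO sets; validates GO ID syntax."""
    union = frozenset(uniprot_set) | frozenset(eggnog_set)
    for go in union:
        if not _GO_RE.match(go):
            raise ValueError(f"malformed GO ID: {go!r}")
    return union


def classify_interest(record: AnnotationRecord) -> InterestCall:
    """Screen one protein's merged GO set against the fourteen-ID panel."""
    cats = frozenset(
        GO_CATEGORY_OF_ID[go] for go in record.go_union if go in GO_CATEGORY_OF_ID
    )
    direct = bool(cats & DIRECT_INTEREST_CATEGORIES)
    return InterestCall(
        protein_id=record.unique_protein_id,
        categories_hit=cats,
        of_interest=direct,
        needs_tm_for_interest=(not direct and "ES" in cats),
    )


def _parse_go_field(raw: object) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return frozenset()
    text = str(raw).strip()
    if not text:
        return frozenset()
    tokens = [t.strip() for t in re.split(r"[;,]", text) if t.strip()]
    return merge_go(set(tokens), set())


def read_annotation_table(path, source: str) -> pd.DataFrame:
    """Read a UniProt-style or eggNOG-style annotation TSV.

    UniProt style needs columns ``id, reviewed, gene, chromosome, go_ids``;
    eggNOG style needs ``id, go_ids``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"uniprot": ["id", "reviewed", "gene", "chromosome", "go_ids"],
                "eggnog": ["id", "go_ids"]}[source]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{source} annotation table missing columns: {missing}")
    return df


def build_annotation_records(
    majority_ids_per_group: list[list[str]],
    uniprot_table: pd.DataFrame,
    eggnog_table: pd.DataFrame,
) -> list[AnnotationRecord]:
    """Join the two annotation sources onto protein groups.

    Reviewed status, gene name and chromosome come from the UniProt-style
    table; a protein absent from a source contributes an empty GO set for
    that source.
    """
    uni = uniprot_table.set_index("id")
    egg = eggnog_table.set_index("id")
    records = []
    for ids in majority_ids_per_group:
        reviewed = [
            pid in uni.index and str(uni.at[pid, "reviewed"]).lower()
            in {"1", "true", "yes", "reviewed"}
            for pid in ids
        ]
        uid = select_unique_id(ids, reviewed)
        go_uni = _parse_go_field(uni.at[uid, "go_ids"]) if uid in uni.index else frozenset()
        go_egg = _parse_go_field(egg.at[uid, "go_ids"]) if uid in egg.index else frozenset()
        records.append(AnnotationRecord(
            unique_protein_id=uid,
            majority_ids=list(ids),
            reviewed=reviewed,
            gene_name=str(uni.at[uid, "gene"]) if uid in uni.index else "",
            chromosome=str(uni.at[uid, "chromosome"]) if uid in uni.index else "",
            go_uniprot=go_uni,
            go_eggnog=go_egg,
        ))
    return records
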