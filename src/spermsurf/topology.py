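"""Transmembrane topology records and parsers.

Deep-learning topology predictors classify each protein as alpha-helical
transmembrane (TM), beta-barrel transmembrane (BETA) or globular (GLOB),
optionally preceded by a signal peptide (SP), and label every residue as
signal (S), inside (I), outside (O), membrane helix (M) or beta strand (B).
This module parses the common "3line" dialect (header / sequence /
per-residue labels) and a flat TSV summary dialect, and derives the fields
the target-selection rules need: transmembrane-region count, signal-peptide
flag and whether any part of the chain is predicted outside the membrane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TOPOLOGY_CLASSES",
    "Segment",
    "TopologyRecord",
    "parse_3line",
    "write_3line",
    "parse_topology_table",
    "write_topology_table",
    "is_transmembrane",
]

TOPOLOGY_CLASSES = ("TM", "SP+TM", "GLOB", "SP", "BETA", "SP+BETA")

_CHAR_LABEL = {"S": "signal", "I": "inside", "O": "outside",
               "M": "TMhelix", "B": "Beta"}
_LABEL_CHAR = {v: k for k, v in _CHAR_LABEL.items()}


@dataclass(frozen=True)
class Segment:
    """One run of identically labeled residues; 1-based inclusive coords."""

    start: int
    end: int
    label: str  # signal | inside | outside | TMhelix | Beta


@dataclass
class TopologyRecord:
    protein_id: str
    predicted_class: str
    tmr_count: int
    has_signal_peptide: bool
    segments: list[Segment] = field(default_factory=list)
    has_outside_region: bool = False
    sequence: str = ""

    def validate(self) -> "TopologyRecord":
        if self.predicted_class not in TOPOLOGY_CLASSES:
            raise ValueError(f"unknown topology class {self.predicted_class!r}")
        sp_class = self.predicted_class.startswith("SP")
        if self.has_signal_peptide != sp_class:
            raise ValueError(
                f"{self.protein_id}: signal-peptide flag inconsistent with "
                f"class {self.predicted_class}"
            )
        membranous = self.predicted_class in {"TM", "SP+TM", "BETA", "SP+BETA"}
        if membranous and self.tmr_count < 1:
            raise ValueError(
                f"{self.protein_id}: class {self.predicted_class} requires "
                f"tmr_count >= 1, got {self.tmr_count}"
            )
        if not membranous and self.tmr_count != 0:
            raise ValueError(
                f"{self.protein_id}: class {self.predicted_class} requires "
                f"tmr_count == 0, got {self.tmr_count}"
            )
        if self.segments:
            pos = 1
            for seg in self.segments:
                if seg.start != pos or seg.end < seg.start:
                    raise ValueError(
                        f"{self.protein_id}: segments do not tile the sequence"
                    )
                pos = seg.end + 1
        return self


def is_transmembrane(record: TopologyRecord) -> bool:
    """Membrane-embedded with at least one membrane-spanning region."""
    return (record.predicted_class in {"TM", "SP+TM", "BETA", "SP+BETA"}
            and record.tmr_count >= 1)


def _segments_from_string(topo: str, protein_id: str) -> list[Segment]:
    segments: list[Segment] = []
    start = 0
    for i in range(1, len(topo) + 1):
        if i == len(topo) or topo[i] != topo[start]:
            ch = topo[start]
            if ch not in _CHAR_LABEL:
                raise ValueError(
                    f"{protein_id}: unknown topology character {ch!r}"
                )
            segments.append(Segment(start + 1, i, _CHAR_LABEL[ch]))
            start = i
    return segments


def _record_from_segments(protein_id: str, cls: str, segments: list[Segment],
                          sequence: str = "") -> TopologyRecord:
    if cls in {"BETA", "SP+BETA"}:
        tmr = sum(1 for s in segments if s.label == "Beta")
    else:
        tmr = sum(1 for s in segments if s.label == "TMhelix")
    rec = TopologyRecord(
        protein_id=protein_id,
        predicted_class=cls,
        tmr_count=tmr,
        has_signal_peptide=any(s.label == "signal" for s in segments),
        segments=segments,
        has_outside_region=any(s.label == "outside" for s in segments),
        sequence=sequence,
    )
    return rec.validate()


def parse_3line(path) -> list[TopologyRecord]:
    """Parse a 3line topology file.

    The format repeats three lines per protein::

        >P12345 | SP+TM
        MKL...            (amino-acid sequence)
        SSSOOMMMII...     (per-residue topology string)
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) % 3:
        raise ValueError("3line file length is not a multiple of three lines")
    records = []
    for i in range(0, len(lines), 3):
        header, seq, topo = lines[i], lines[i + 1], lines[i + 2]
        if not header.startswith(">") or "|" not in header:
            raise ValueError(f"malformed 3line header: {header!r}")
        pid, cls = (part.strip() for part in header[1:].split("|", 1))
        if cls not in TOPOLOGY_CLASSES:
            raise ValueError(f"{pid}: unknown class token {cls!r}")
        if len(topo) != len(seq):
            raise ValueError(
                f"{pid}: topology string length {len(topo)} != sequence "
                f"length {len(seq)}"
            )
        segments = _segments_from_string(topo, pid)
        records.append(_record_from_segments(pid, cls, segments, sequence=seq))
    return records


def write_3line(records: list[TopologyRecord], path) -> None:
    """Inverse of :func:`parse_3line` for records carrying sequences."""
    with open(path, "w") as fh:
        for rec in records:
            if not rec.sequence or not rec.segments:
                raise ValueError(
                    f"{rec.protein_id}: 3line output needs sequence and segments"
                )
            topo = "".join(
                _LABEL_CHAR[s.label] * (s.end - s.start + 1) for s in rec.segments
            )
            fh.write(f">{rec.protein_id} | {rec.predicted_class}\n")
            fh.write(rec.sequence + "\n")
            fh.write(topo + "\n")


def parse_topology_table(path) -> list[TopologyRecord]:
    """Parse the flat TSV dialect: ``id<TAB>class<TAB>tmr_count[<TAB>segments]``.

    The optional segments column encodes runs as ``label:start-end`` joined
    by ``;``. Rows without segments cannot establish an outside region, so
    ``has_outside_region`` defaults to False (conservative).
    """
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            return records
        cols = header.rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(cols)}
        for c in ("id", "class", "tmr_count"):
            if c not in idx:
                raise ValueError(f"topology table missing column {c!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            pid = parts[idx["id"]]
            cls = parts[idx["class"]]
            tmr = int(parts[idx["tmr_count"]])
            segments: list[Segment] = []
            if "segments" in idx and len(parts) > idx["segments"] and parts[idx["segments"]]:
                for token in parts[idx["segments"]].split(";"):
                    label, span = token.split(":")
                    start, end = span.split("-")
                    segments.append(Segment(int(start), int(end), label))
            rec = TopologyRecord(
                protein_id=pid,
                predicted_class=cls,
                tmr_count=tmr,
                has_signal_peptide=cls.startswith("SP"),
                segments=segments,
                has_outside_region=any(s.label == "outside" for s in segments),
            )
            records.append(rec.validate())
    return records


def write_topology_table(records: list[TopologyRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tclass\ttmr_count\tsegments\n")
        for rec in records:
            segs = ";".join(f"{s.label}:{s.start}-{s.end}" for s in rec.segments)
            fh.write(f"{rec.protein_id}\t{rec.predicted_class}\t{rec.tmr_count}\t{segs}\n")
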