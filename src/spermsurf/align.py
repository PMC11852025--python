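"""Global pairwise protein alignment and percent identity.

Candidate markers are only useful across breeds and species if their
surface-exposed sequence is conserved, so orthologs are compared by global
(Needleman–Wunsch) alignment with affine gap costs and, optionally,
per-segment identity restricted to the regions a topology predictor places
outside the membrane.

Scoring convention: substitution scores from a standard matrix (default
BLOSUM62); a gap of length L costs ``gap_open + (L−1)·gap_extend``.
Percent identity is identical aligned columns over total alignment
columns, ×100. Traceback ties are broken deterministically: prefer a
substitution column, then a gap in the first sequence, then a gap in the
second.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import substitution_matrices

from .topology import Segment

__all__ = [
    "AlignmentResult",
    "global_align",
    "segment_similarity",
    "read_fasta",
]

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")
_NEG_INF = float("-inf")


@dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    alignment_length: int
    n_identical: int
    percent_identity: float
    score: float
    aligned_query: str
    aligned_subject: str


def _load_matrix(matrix):
    if isinstance(matrix, str):
        return substitution_matrices.load(matrix)
    return matrix


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    for i, ch in enumerate(seq):
        if ch not in _VALID_AA:
            raise ValueError(f"{name}: invalid amino-acid {ch!r} at position {i + 1}")


def global_align(
    seq_a: str,
    seq_b: str,
    matrix="BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Optimal global alignment of two amino-acid sequences (Gotoh).

    Three-state affine-gap dynamic programming; ``gap_open`` is the cost of
    the first residue of a gap and ``gap_extend`` of each further residue.
    """
    _check_sequence(seq_a, query_id)
    _check_sequence(seq_b, subject_id)
    sub = _load_matrix(matrix)
    n, m = len(seq_a), len(seq_b)

    # D: column consumes both; P: gap in seq_b (consumes a); Q: gap in seq_a.
    D = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    P = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Q = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    D[0][0] = 0.0
    for i in range(1, n + 1):
        P[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Q[0][j] = -gap_open - (j - 1) * gap_extend

    for i in range(1, n + 1):
        row_d, row_p, row_q = D[i], P[i], Q[i]
        prev_d, prev_p, prev_q = D[i - 1], P[i - 1], Q[i - 1]
        ai = seq_a[i - 1]
        for j in range(1, m + 1):
            s = sub[ai, seq_b[j - 1]]
            row_d[j] = max(prev_d[j - 1], prev_q[j - 1], prev_p[j - 1]) + s
            row_p[j] = max(prev_d[j] - gap_open,
                           prev_q[j] - gap_open,
                           prev_p[j] - gap_extend)
            row_q[j] = max(row_d[j - 1] - gap_open,
                           row_p[j - 1] - gap_open,
                           row_q[j - 1] - gap_extend)

    # Traceback with the documented tie preference: D, then Q (gap in a),
    # then P (gap in b).
    i, j = n, m
    finals = {"D": D[n][m], "Q": Q[n][m], "P": P[n][m]}
    state = max(("D", "Q", "P"), key=lambda k: finals[k])
    score = finals[state]
    out_a: list[str] = []
    out_b: list[str] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "D":
            s = sub[seq_a[i - 1], seq_b[j - 1]]
            target = D[i][j] - s
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i, j = i - 1, j - 1
            for cand in ("D", "Q", "P"):
                if abs({"D": D, "Q": Q, "P": P}[cand][i][j] - target) < tol:
                    state = cand
                    break
        elif state == "Q":
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            target = Q[i][j]
            j -= 1
            if abs(D[i][j] - gap_open - target) < tol:
                state = "D"
            elif abs(P[i][j] - gap_open - target) < tol:
                state = "P"
            else:
                state = "Q"
        else:  # P
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            target = P[i][j]
            i -= 1
            if abs(D[i][j] - gap_open - target) < tol:
                state = "D"
            elif abs(Q[i][j] - gap_open - target) < tol:
                state = "Q"
            else:
                state = "P"
        if i == 0 and j == 0:
            break

    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    n_id = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    length = len(aligned_a)
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        alignment_length=length,
        n_identical=n_id,
        percent_identity=100.0 * n_id / length,
        score=float(score),
        aligned_query=aligned_a,
        aligned_subject=aligned_b,
    )


def segment_similarity(
    seq_a: str,
    seq_b: str,
    segments_a: list[Segment],
    labels: tuple[str, ...] = ("outside",),
    **align_kwargs,
) -> list[AlignmentResult]:
    """Per-segment identity between a query and a subject sequence.

    The whole sequences are aligned once; each query segment with a label
    in ``labels`` is projected onto alignment columns (gap-in-query columns
    strictly inside the segment's span count as columns) and identity is
    computed over that span.
    """
    whole = global_align(seq_a, seq_b, **align_kwargs)
    sub = _load_matrix(align_kwargs.get("matrix", "BLOSUM62"))
    gap_open = align_kwargs.get("gap_open", 10.0)
    gap_extend = align_kwargs.get("gap_extend", 0.5)
    col_of_query_pos: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(whole.aligned_query):
        if ch != "-":
            pos += 1
            col_of_query_pos[pos] = col
    results = []
    for seg in segments_a:
        if seg.label not in labels:
            continue
        if seg.start < 1 or seg.end > len(seq_a):
            raise ValueError(
                f"segment {seg.start}-{seg.end} out of bounds for query of "
                f"length {len(seq_a)}"
            )
        c0, c1 = col_of_query_pos[seg.start], col_of_query_pos[seg.end]
        sub_a = whole.aligned_query[c0:c1 + 1]
        sub_b = whole.aligned_subject[c0:c1 + 1]
        n_id = sum(1 for x, y in zip(sub_a, sub_b) if x == y and x != "-")
        length = len(sub_a)
        # segment score: substitution columns scored by the matrix; each gap
        # run inside the span charged open + (L-1)*extend
        score = 0.0
        in_gap = False
        for x, y in zip(sub_a, sub_b):
            if x == "-" or y == "-":
                score -= gap_extend if in_gap else gap_open
                in_gap = True
            else:
                score += float(sub[x, y])
                in_gap = False
        results.append(AlignmentResult(
            query_id=f"{whole.query_id}:{seg.start}-{seg.end}",
            subject_id=whole.subject_id,
            alignment_length=length,
            n_identical=n_id,
            percent_identity=100.0 * n_id / length,
            score=score,
            aligned_query=sub_a,
            aligned_subject=sub_b,
        ))
    return results


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-record) FASTA into an ordered id → sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
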