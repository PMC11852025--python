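"""Generic term-overrepresentation statistic for protein sets.

For each annotation term, a 2×2 contingency table (in sample / not in
sample × carries term / does not) is tested with a two-sided Fisher exact
test, corrected by Bonferroni over the number of terms actually tested.
Fold enrichment is observed over expected under the background annotation
rate:

    FE = k / (n · K / N)

with N background proteins, K of them term-annotated, n sample proteins
and k term-annotated sample proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "overrepresentation",
    "bonferroni",
    "read_background_annotation",
]


@dataclass
class EnrichmentResult:
    term_id: str
    n_background: int
    n_background_with_term: int
    n_sample: int
    n_sample_with_term: int
    fold_enrichment: float
    p_raw: float
    p_bonferroni: float
    direction: str          # "over" | "under"


def bonferroni(p_values) -> np.ndarray:
    """Multiply each p by the number of tests, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def overrepresentation(
    sample_ids,
    background_annotation: dict[str, set[str]],
    alpha: float | None = None,
) -> list[EnrichmentResult]:
    """Test every background term for over/underrepresentation in the sample.

    ``background_annotation`` maps protein ID → set of term IDs; the sample
    must be a subset of the background. With ``alpha`` set, only results
    with ``p_bonferroni <= alpha`` are returned.
    """
    sample = set(sample_ids)
    background = set(background_annotation)
    offenders = sorted(sample - background)
    if offenders:
        raise ValueError(f"sample proteins missing from background: {offenders}")
    terms: dict[str, set[str]] = {}
    for pid, term_set in background_annotation.items():
        for term in term_set:
            terms.setdefault(term, set()).add(pid)

    n_bg, n_s = len(background), len(sample)
    results = []
    raw_ps = []
    for term, carriers in sorted(terms.items()):
        k_bg = len(carriers)
        k_s = len(carriers & sample)
        table = [[k_s, n_s - k_s],
                 [k_bg - k_s, (n_bg - n_s) - (k_bg - k_s)]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        expected = n_s * k_bg / n_bg
        fe = k_s / expected if expected > 0 else float("nan")
        results.append(EnrichmentResult(
            term_id=term,
            n_background=n_bg,
            n_background_with_term=k_bg,
            n_sample=n_s,
            n_sample_with_term=k_s,
            fold_enrichment=fe,
            p_raw=p,
            p_bonferroni=1.0,
            direction="over" if k_s >= expected else "under",
        ))
        raw_ps.append(p)
    if results:
        for r, q in zip(results, bonferroni(raw_ps)):
            r.p_bonferroni = float(q)
    if alpha is not None:
        results = [r for r in results if r.p_bonferroni <= alpha]
    return results


def read_background_annotation(path) -> dict[str, set[str]]:
    """Read a TSV mapping ``id`` to a ``;``/``,``-separated term list."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "id" not in df.columns:
        raise ValueError("background annotation table needs an 'id' column")
    term_col = next((c for c in df.columns if c != "id"), None)
    if term_col is None:
        raise ValueError("background annotation table needs a term column")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        toks = [t.strip() for t in str(row[term_col]).replace(",", ";").split(";")
                if t.strip()]
        out[row["id"]] = set(toks)
    return out
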