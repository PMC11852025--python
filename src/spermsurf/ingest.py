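"""Protein-groups ingestion: filtering, log2 transform, MNAR imputation.

The quantification table follows the MaxQuant ``proteinGroups`` convention:
one row per protein group, an ``LFQ intensity <sample>`` column per
replicate, a ``0`` wherever a protein was not quantified in a sample, and
``+`` flags marking reverse-database decoys and potential contaminants.

Missingness in label-free proteomics is predominantly
missing-not-at-random: low-abundance proteins fall below the instrument's
detection limit. Imputation therefore draws replacements from a normal
distribution shifted below each sample's observed intensity distribution
(the Perseus/DEP-style "downshifted normal"): centre ``mean_s −
downshift·sd_s`` and spread ``width·sd_s``, per sample ``s``.

The no-biotin negative control condition (default ``BC``) carries no signal
by design; it is excluded from the valid-value filter groups and never
imputed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LFQ_PREFIX",
    "REQUIRED_COLUMNS",
    "IntensityMatrix",
    "FilterReport",
    "read_protein_groups",
    "remove_decoys_and_contaminants",
    "matrix_from_table",
    "valid_value_filter",
    "impute_missing",
]

LFQ_PREFIX = "LFQ intensity "
REQUIRED_COLUMNS = ("Majority protein IDs", "Reverse", "Potential contaminant")


@dataclass
class FilterReport:
    """Bookkeeping for row removals across the ingest stages."""

    n_input: int = 0
    n_reverse_removed: int = 0
    n_contaminant_removed: int = 0
    n_failed_valid_filter: int = 0
    n_retained: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class IntensityMatrix:
    """Proteins × samples log2 LFQ intensities with missingness masks.

    ``values`` holds log2 intensities (NaN where neither observed nor
    imputed); ``observed_mask`` marks measured cells, ``imputed_mask``
    marks cells filled in by :func:`impute_missing`. The two masks are
    disjoint. ``condition_of`` maps each sample to its condition label.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    condition_of: dict[str, str]
    values: np.ndarray
    observed_mask: np.ndarray
    imputed_mask: np.ndarray
    majority_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n, m = len(self.protein_ids), len(self.sample_ids)
        if self.values.shape != (n, m):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {m})")
        if np.any(self.observed_mask & self.imputed_mask):
            raise ValueError("observed and imputed masks overlap")
        for s in self.sample_ids:
            if s not in self.condition_of:
                raise ValueError(f"sample {s!r} has no condition mapping")

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.condition_of[s], None)
        return list(seen)

    def sample_indices(self, condition: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids)
               if self.condition_of[s] == condition]
        if not idx:
            raise ValueError(f"unknown condition {condition!r}")
        return np.asarray(idx)

    def subset(self, row_keep: np.ndarray) -> "IntensityMatrix":
        return replace(
            self,
            protein_ids=[p for p, k in zip(self.protein_ids, row_keep) if k],
            values=self.values[row_keep].copy(),
            observed_mask=self.observed_mask[row_keep].copy(),
            imputed_mask=self.imputed_mask[row_keep].copy(),
            majority_ids=[m for m, k in zip(self.majority_ids, row_keep) if k]
            if self.majority_ids else [],
        )


def read_protein_groups(path) -> pd.DataFrame:
    """Read a protein-groups TSV; zero/blank LFQ cells become NaN."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"protein-groups table missing column {col!r}")
    lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    if not lfq_cols:
        raise ValueError(f"no {LFQ_PREFIX!r}* columns found")
    for col in lfq_cols:
        raw = df[col].str.strip().replace("", "0")
        try:
            num = raw.astype(float)
        except ValueError as exc:
            bad = raw[pd.to_numeric(raw, errors="coerce").isna()]
            raise ValueError(
                f"unreadable intensity in column {col!r}, row index "
                f"{bad.index[0]}"
            ) from exc
        df[col] = num.where(num > 0, np.nan)
    return df


def remove_decoys_and_contaminants(df: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop reverse-database decoys and potential contaminants.

    A row flagged as both counts once, under reverse.
    """
    flagged = df[["Reverse", "Potential contaminant"]].apply(
        lambda s: s.astype(str).str.strip() == "+"
    )
    is_rev = flagged["Reverse"].to_numpy()
    is_con = flagged["Potential contaminant"].to_numpy() & ~is_rev
    keep = ~(is_rev | is_con)
    report = FilterReport(
        n_input=len(df),
        n_reverse_removed=int(is_rev.sum()),
        n_contaminant_removed=int(is_con.sum()),
        n_retained=int(keep.sum()),
    )
    return df.loc[keep].reset_index(drop=True), report


def _condition_from_sample(sample: str) -> str:
    m = re.match(r"([A-Za-z]+)", sample)
    if not m:
        raise ValueError(f"cannot infer condition from sample name {sample!r}")
    return m.group(1)


def matrix_from_table(df: pd.DataFrame,
                      condition_of: dict[str, str] | None = None) -> IntensityMatrix:
    """Log2-transform LFQ columns and assemble an :class:`IntensityMatrix`.

    Sample names are the LFQ column suffixes; unless an explicit mapping is
    given, the condition is the sample name's leading alphabetic run (so
    ``BX_1`` and ``BX2`` both map to ``BX``).
    """
    lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    sample_ids = [c[len(LFQ_PREFIX):] for c in lfq_cols]
    if condition_of is None:
        condition_of = {s: _condition_from_sample(s) for s in sample_ids}
    raw = df[lfq_cols].to_numpy(dtype=float)
    observed = np.isfinite(raw) & (raw > 0)
    values = np.full(raw.shape, np.nan)
    values[observed] = np.log2(raw[observed])
    majority = df["Majority protein IDs"].astype(str).tolist()
    protein_ids = [m.split(";")[0] for m in majority]
    return IntensityMatrix(
        protein_ids=protein_ids,
        sample_ids=sample_ids,
        condition_of=dict(condition_of),
        values=values,
        observed_mask=observed,
        imputed_mask=np.zeros_like(observed),
        majority_ids=majority,
    )


def valid_value_filter(
    matrix: IntensityMatrix,
    min_valid: int = 2,
    exclude_conditions: tuple[str, ...] = ("BC",),
) -> tuple[IntensityMatrix, FilterReport]:
    """Keep proteins with ≥ ``min_valid`` observed values in some condition.

    Conditions in ``exclude_conditions`` (the negative control) do not count
    toward validity.
    """
    groups = [c for c in matrix.conditions if c not in exclude_conditions]
    if not groups:
        raise ValueError("no conditions left after exclusions")
    max_reps = max(len(matrix.sample_indices(c)) for c in groups)
    if min_valid > max_reps:
        raise ValueError(
            f"min_valid={min_valid} exceeds the largest replicate count {max_reps}"
        )
    keep = np.zeros(len(matrix.protein_ids), dtype=bool)
    for cond in groups:
        idx = matrix.sample_indices(cond)
        keep |= matrix.observed_mask[:, idx].sum(axis=1) >= min_valid
    report = FilterReport(
        n_input=len(matrix.protein_ids),
        n_failed_valid_filter=int((~keep).sum()),
        n_retained=int(keep.sum()),
    )
    return matrix.subset(keep), report


def impute_missing(
    matrix: IntensityMatrix,
    downshift: float = 1.8,
    width: float = 0.3,
    seed: int | None = None,
    exclude_conditions: tuple[str, ...] = ("BC",),
) -> IntensityMatrix:
    """Fill missing cells from a per-sample downshifted normal.

    For sample ``s`` with observed mean ``m_s`` and SD ``sd_s``, missing
    cells are drawn from ``Normal(m_s − downshift·sd_s, (width·sd_s)²)``.
    Observed cells are never modified. Samples belonging to excluded
    conditions are left untouched.
    """
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    imputed = matrix.imputed_mask.copy()
    for j, sample in enumerate(matrix.sample_ids):
        if matrix.condition_of[sample] in exclude_conditions:
            continue
        obs = matrix.observed_mask[:, j]
        if obs.sum() < 2:
            raise ValueError(
                f"sample {sample!r} has fewer than two observed values; "
                "cannot estimate its detection limit"
            )
        m_s = float(values[obs, j].mean())
        sd_s = float(values[obs, j].std(ddof=1))
        missing = ~obs
        n_missing = int(missing.sum())
        if n_missing:
            draws = rng.normal(m_s - downshift * sd_s, width * sd_s, size=n_missing)
            values[missing, j] = draws
            imputed[missing, j] = True
    return replace(matrix, values=values, imputed_mask=imputed)
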