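"""Synthetic surface-proteome data with known ground truth.

Emulates the statistical structure of a biotinylation/LFQ experiment on
sorted bovine semen: four conditions — no-biotin control (BC), unsexed
(BU), X-sorted (BX), Y-sorted (BY) — with three replicates each,
log-normal LFQ intensities, intensity-dependent (detection-limit)
missingness, contaminant and reverse-decoy rows, and a configurable number
of planted X-sperm-specific proteins, a subset of which are transmembrane
with cell-surface GO annotation (the proteins the pipeline should
prioritize).

Hierarchical intensity model (log2 scale)
-----------------------------------------
    protein mean      ~ Normal(base_log2_mean, between_protein_sd²)
    group variance σ² ~ scaled-inverse-chi-square(d0, s0²)
    replicate value   ~ Normal(group mean, σ²)

A cell is recorded missing with probability
``logistic((detection_limit − value) / censor_softness)`` (a hard
threshold when ``censor_softness = 0``), optionally plus a small
missing-completely-at-random rate. BC cells are always missing — the
control carries no biotinylated protein. Raw intensities are written as
``2^(log2 value)`` with 0 denoting a missing cell, following the MaxQuant
convention.

Planted X-specific proteins receive ``effect_log2fc`` on top of their mean
in the conditions named by ``effect_conditions`` and have their BY group
mean pushed far below the detection limit, so they are
absent-by-construction in the Y-sorted replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .annotation import GO_CATEGORY_OF_ID
from .topology import Segment, TopologyRecord, write_3line

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "planted_target_set",
    "write_dataset",
    "DECOY_GO_IDS",
]

INTEREST_GO_IDS = tuple(sorted(GO_CATEGORY_OF_ID))

# Syntactically valid GO IDs outside the interest panel, used as background
# annotation noise.
DECOY_GO_IDS = tuple(
    f"GO:11000{i:02d}" for i in range(20)
)

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationConfig:
    n_proteins: int = 500
    conditions: tuple[tuple[str, int], ...] = (
        ("BC", 3), ("BU", 3), ("BX", 3), ("BY", 3),
    )
    frac_contaminant: float = 0.05
    frac_reverse: float = 0.05
    n_bx_specific: int = 8
    n_bx_specific_tm_surface: int = 5
    base_log2_mean: float = 25.0
    between_protein_sd: float = 2.0
    within_group_sd_prior: tuple[float, float] = (4.0, 0.5)  # (d0, s0)
    effect_log2fc: float = 4.0
    effect_conditions: tuple[str, ...] = ("BX",)
    detection_limit: float = 22.0
    censor_softness: float = 0.5
    mcar_rate: float = 0.0
    go_leak_rate: float = 0.05
    frac_background_tm: float = 0.2
    control_condition: str = "BC"
    suppressed_condition: str = "BY"
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        for name in ("frac_contaminant", "frac_reverse", "mcar_rate",
                     "go_leak_rate", "frac_background_tm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"configuration error: {name}={v} not in [0, 1]")
        if self.n_proteins < 0:
            raise ValueError("configuration error: n_proteins must be >= 0")
        for label, reps in self.conditions:
            if reps < 2:
                raise ValueError(
                    f"configuration error: conditions[{label}] has {reps} "
                    "replicates; need >= 2"
                )
        d0, s0 = self.within_group_sd_prior
        if d0 <= 0 or s0 <= 0:
            raise ValueError(
                "configuration error: within_group_sd_prior requires d0 > 0, s0 > 0"
            )
        if not (0 <= self.n_bx_specific_tm_surface <= self.n_bx_specific
                <= self.n_proteins):
            raise ValueError(
                "configuration error: need n_bx_specific_tm_surface <= "
                "n_bx_specific <= n_proteins"
            )
        if self.censor_softness < 0:
            raise ValueError("configuration error: censor_softness must be >= 0")
        return self


@dataclass
class SimulatedDataset:
    protein_groups: pd.DataFrame
    uniprot_annotation: pd.DataFrame
    eggnog_annotation: pd.DataFrame
    topology: list[TopologyRecord]
    ledger: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


def _missing_probability(values: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    if cfg.censor_softness == 0:
        p = (values < cfg.detection_limit).astype(float)
    else:
        z = (cfg.detection_limit - values) / cfg.censor_softness
        p = special.expit(z)
    if cfg.mcar_rate > 0:
        p = p + cfg.mcar_rate * (1.0 - p)
    return p


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AMINO_ACIDS, size=length))


def _topology_record(rng: np.random.Generator, pid: str, cls: str,
                     tmr: int) -> TopologyRecord:
    """Build a plausible segment layout for the requested class."""
    segs: list[tuple[str, int]] = []          # (label, length)
    if cls.startswith("SP"):
        segs.append(("signal", int(rng.integers(15, 26))))
    base_cls = cls.removeprefix("SP+")
    if base_cls == "GLOB" or base_cls == "SP":
        segs.append(("inside" if cls == "GLOB" else "outside",
                     int(rng.integers(40, 81))))
    else:
        label = "TMhelix" if base_cls == "TM" else "Beta"
        side = "outside"
        segs.append((side, int(rng.integers(8, 21))))
        for _ in range(tmr):
            segs.append((label, int(rng.integers(15, 24)) if label == "TMhelix"
                         else int(rng.integers(8, 13))))
            side = "inside" if side == "outside" else "outside"
            segs.append((side, int(rng.integers(5, 16))))
    pos = 1
    segments = []
    for label, length in segs:
        segments.append(Segment(pos, pos + length - 1, label))
        pos += length
    seq = _random_sequence(rng, pos - 1)
    return TopologyRecord(
        protein_id=pid,
        predicted_class=cls,
        tmr_count=tmr if base_cls in {"TM", "BETA"} else 0,
        has_signal_peptide=cls.startswith("SP"),
        segments=segments,
        has_outside_region=any(s.label == "outside" for s in segments),
        sequence=seq,
    ).validate()


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one complete synthetic dataset from the hierarchical model."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    d0, s0 = cfg.within_group_sd_prior

    protein_ids = [f"SYNP{i:04d}" for i in range(n)]
    cond_labels = [c for c, _ in cfg.conditions]
    samples = [(f"{c}_{r + 1}", c) for c, reps in cfg.conditions
               for r in range(reps)]
    sample_names = [s for s, _ in samples]
    sample_cond = np.array([c for _, c in samples])

    # --- intensity model -------------------------------------------------
    base_means = rng.normal(cfg.base_log2_mean, cfg.between_protein_sd, size=n)
    group_var = d0 * s0 ** 2 / rng.chisquare(d0, size=n)
    group_sd = np.sqrt(group_var)

    planted_idx = np.arange(cfg.n_bx_specific)       # first rows are planted
    tm_surface_idx = planted_idx[:cfg.n_bx_specific_tm_surface]
    is_planted = np.zeros(n, dtype=bool)
    is_planted[planted_idx] = True
    is_tm_surface = np.zeros(n, dtype=bool)
    is_tm_surface[tm_surface_idx] = True

    suppressed_mean = (cfg.detection_limit - 8.0 * max(cfg.censor_softness, 0.25)
                       - 2.0)
    cond_means = {}
    for cond in cond_labels:
        mu = base_means.copy()
        if cond in cfg.effect_conditions:
            mu[is_planted] += cfg.effect_log2fc
        if cond == cfg.suppressed_condition:
            mu[is_planted] = suppressed_mean
        cond_means[cond] = mu

    n_samples = len(sample_names)
    values = np.empty((n, n_samples))
    for j, (_, cond) in enumerate(samples):
        values[:, j] = rng.normal(cond_means[cond], group_sd)

    # Common random numbers for censoring: one uniform per cell, so that
    # lowering the detection limit can only unhide cells.
    u = rng.uniform(size=(n, n_samples))
    missing = u < _missing_probability(values, cfg)
    missing[:, sample_cond == cfg.control_condition] = True

    raw = np.where(missing, 0.0, np.exp2(values))

    # --- contaminant / reverse rows --------------------------------------
    n_cont = int(round(cfg.frac_contaminant * n))
    n_rev = int(round(cfg.frac_reverse * n))
    extra_rows = []
    for i in range(n_cont):
        vals = rng.normal(cfg.base_log2_mean, cfg.between_protein_sd)
        reps = np.exp2(rng.normal(vals, s0, size=n_samples))
        reps[sample_cond == cfg.control_condition] = 0.0
        extra_rows.append((f"CONT{i:03d}", "", "+", reps))
    for i in range(n_rev):
        reps = np.zeros(n_samples)
        extra_rows.append((f"REV{i:03d}", "+", "", reps))

    table = {
        "Majority protein IDs": protein_ids + [r[0] for r in extra_rows],
        "Reverse": [""] * n + [r[1] for r in extra_rows],
        "Potential contaminant": [""] * n + [r[2] for r in extra_rows],
        "Razor + unique peptides": [2] * (n + len(extra_rows)),
    }
    all_raw = np.vstack([raw] + [r[3][None, :] for r in extra_rows]) \
        if extra_rows else raw
    for j, name in enumerate(sample_names):
        table[f"LFQ intensity {name}"] = all_raw[:, j]
    protein_groups = pd.DataFrame(table)

    # --- topology ---------------------------------------------------------
    topo_records = []
    classes = np.empty(n, dtype=object)
    class_draw = rng.uniform(size=n)
    for i, pid in enumerate(protein_ids):
        if is_tm_surface[i]:
            cls, tmr = ("SP+TM" if rng.uniform() < 0.3 else "TM"), int(rng.integers(1, 4))
        else:
            x = class_draw[i]
            if x < cfg.frac_background_tm:
                cls, tmr = "TM", int(rng.integers(1, 4))
            elif x < cfg.frac_background_tm + 0.15:
                cls, tmr = "SP", 0
            elif x < cfg.frac_background_tm + 0.20:
                cls, tmr = "SP+TM", int(rng.integers(1, 3))
            else:
                cls, tmr = "GLOB", 0
        classes[i] = cls
        topo_records.append(_topology_record(rng, pid, cls, tmr))

    # --- GO annotation ----------------------------------------------------
    reviewed = rng.uniform(size=n) < 0.5
    chromosomes = rng.choice([str(c) for c in range(1, 30)] + ["X"], size=n)
    go_uni, go_egg, surface_go = [], [], np.zeros(n, dtype=bool)
    for i in range(n):
        decoys = list(rng.choice(DECOY_GO_IDS, size=rng.integers(1, 4),
                                 replace=False))
        interest: list[str] = []
        if is_tm_surface[i]:
            interest = [str(rng.choice(INTEREST_GO_IDS))]
        elif rng.uniform() < cfg.go_leak_rate:
            interest = [str(rng.choice(INTEREST_GO_IDS))]
        surface_go[i] = bool(interest)
        pool = decoys + interest
        rng.shuffle(pool)
        # split the union across the two sources, with overlap allowed
        take_uni = rng.uniform(size=len(pool)) < 0.7
        take_egg = rng.uniform(size=len(pool)) < 0.7
        uni = [g for g, t in zip(pool, take_uni) if t] or pool[:1]
        egg = [g for g, t in zip(pool, take_egg) if t]
        if interest and interest[0] not in uni and interest[0] not in egg:
            uni.append(interest[0])
        go_uni.append(";".join(sorted(set(uni))))
        go_egg.append(";".join(sorted(set(egg))))

    uniprot_annotation = pd.DataFrame({
        "id": protein_ids,
        "reviewed": np.where(reviewed, "true", "false"),
        "gene": [f"GENE{i:04d}" for i in range(n)],
        "chromosome": chromosomes,
        "go_ids": go_uni,
    })
    eggnog_annotation = pd.DataFrame({"id": protein_ids, "go_ids": go_egg})

    # --- truth ledger ------------------------------------------------------
    ledger_cols = {
        "protein_id": protein_ids,
        "is_planted_target": is_planted,
        "is_planted_tm_surface": is_tm_surface,
        "true_topology_class": classes,
        "true_surface_go": surface_go,
        "true_group_sd": group_sd,
    }
    for cond in cond_labels:
        ledger_cols[f"true_mean_{cond}"] = cond_means[cond]
    ledger = pd.DataFrame(ledger_cols)

    return SimulatedDataset(
        protein_groups=protein_groups,
        uniprot_annotation=uniprot_annotation,
        eggnog_annotation=eggnog_annotation,
        topology=topo_records,
        ledger=ledger,
        config=cfg,
    )


def planted_target_set(ledger: pd.DataFrame, tm_surface_only: bool = True) -> set[str]:
    """IDs of planted X-specific proteins (default: the TM+surface subset)."""
    if ledger.empty:
        return set()
    col = "is_planted_tm_surface" if tm_surface_only else "is_planted_target"
    return set(ledger.loc[ledger[col].astype(bool), "protein_id"])


def write_dataset(dataset: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Write every artifact as TSV/3line text; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein_groups": out / "protein_groups.tsv",
        "uniprot_annotation": out / "annotation_uniprot.tsv",
        "eggnog_annotation": out / "annotation_eggnog.tsv",
        "topology": out / "topology.3line",
        "ledger": out / "truth_ledger.tsv",
    }
    dataset.protein_groups.to_csv(paths["protein_groups"], sep="\t",
                                  index=False, float_format="%.6f")
    dataset.uniprot_annotation.to_csv(paths["uniprot_annotation"], sep="\t",
                                      index=False)
    dataset.eggnog_annotation.to_csv(paths["eggnog_annotation"], sep="\t",
                                     index=False)
    write_3line(dataset.topology, paths["topology"])
    dataset.ledger.to_csv(paths["ledger"], sep="\t", index=False,
                          float_format="%.6f")
    return paths
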