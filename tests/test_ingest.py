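"""Ingestion: parsing, decoy removal, valid-value filter, imputation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spermsurf import ingest
from spermsurf.simulate import SimulationConfig, simulate_dataset, write_dataset


def write_pg(tmp_path, rows, samples=("BU_1", "BU_2")):
    cols = {"Majority protein IDs": [r[0] for r in rows],
            "Reverse": [r[1] for r in rows],
            "Potential contaminant": [r[2] for r in rows]}
    for j, s in enumerate(samples):
        cols[f"LFQ intensity {s}"] = [r[3][j] for r in rows]
    path = tmp_path / "pg.tsv"
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    return path


class TestReadProteinGroups:
    def test_zero_lfq_cell_becomes_missing(self, tmp_path):
        path = write_pg(tmp_path, [("P1", "", "", ("0", "1024"))])
        df = ingest.read_protein_groups(path)
        assert np.isnan(df["LFQ intensity BU_1"][0])
        assert df["LFQ intensity BU_2"][0] == 1024.0

    def test_missing_required_column_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"Reverse": [""], "Potential contaminant": [""],
                      "LFQ intensity BU_1": [1.0]}).to_csv(path, sep="\t",
                                                           index=False)
        with pytest.raises(ValueError, match="Majority protein IDs"):
            ingest.read_protein_groups(path)

    def test_unreadable_numeric_names_row(self, tmp_path):
        path = write_pg(tmp_path, [("P1", "", "", ("abc", "1"))])
        with pytest.raises(ValueError, match="row index"):
            ingest.read_protein_groups(path)

    def test_synthetic_roundtrip_preserves_values_and_masks(self, tmp_path):
        ds = simulate_dataset(SimulationConfig(n_proteins=40, seed=9))
        paths = write_dataset(ds, tmp_path)
        df = ingest.read_protein_groups(paths["protein_groups"])
        matrix = ingest.matrix_from_table(df)
        lfq_cols = [c for c in ds.protein_groups.columns
                    if c.startswith(ingest.LFQ_PREFIX)]
        raw = ds.protein_groups[lfq_cols].to_numpy(dtype=float)
        expected_mask = raw > 0
        assert np.array_equal(matrix.observed_mask, expected_mask)
        np.testing.assert_allclose(
            matrix.values[expected_mask], np.log2(raw[expected_mask]),
            rtol=1e-5)


class TestDecoyRemoval:
    def test_counts_and_precedence(self, tmp_path):
        rows = [("P1", "", "", ("1", "1")), ("P2", "+", "", ("1", "1")),
                ("P3", "+", "+", ("1", "1")), ("P4", "", "+", ("1", "1")),
                ("P5", "", "", ("1", "1"))]
        df = ingest.read_protein_groups(write_pg(tmp_path, rows))
        out, rep = ingest.remove_decoys_and_contaminants(df)
        # the doubly flagged row counts once, under reverse
        assert rep.n_reverse_removed == 2
        assert rep.n_contaminant_removed == 1
        assert rep.n_retained == 2
        assert rep.n_input == rep.n_reverse_removed + rep.n_contaminant_removed \
            + rep.n_retained
        assert list(out["Majority protein IDs"]) == ["P1", "P5"]

    def test_no_flags_is_identity(self, tmp_path):
        rows = [("P1", "", "", ("1", "2")), ("P2", "", "", ("3", "4"))]
        df = ingest.read_protein_groups(write_pg(tmp_path, rows))
        out, rep = ingest.remove_decoys_and_contaminants(df)
        assert len(out) == 2 and rep.n_reverse_removed == 0


class TestValidValueFilter:
    def test_rule_application(self, small_matrix):
        filtered, rep = ingest.valid_value_filter(small_matrix, min_valid=2)
        # P1: 3 valid everywhere -> keep; P2: 2 in BU -> keep;
        # P3: one per condition -> drop; P4: none -> drop
        assert filtered.protein_ids == ["P1", "P2"]
        assert rep.n_failed_valid_filter == 2

    def test_min_valid_above_replicates_raises(self, small_matrix):
        with pytest.raises(ValueError, match="min_valid"):
            ingest.valid_value_filter(small_matrix, min_valid=4)

    def test_matches_brute_force_recount(self):
        ds = simulate_dataset(SimulationConfig(n_proteins=300, seed=7))
        df, _ = ingest.remove_decoys_and_contaminants(ds.protein_groups)
        matrix = ingest.matrix_from_table(df)
        filtered, _ = ingest.valid_value_filter(matrix, min_valid=2)
        expected = set()
        for i, pid in enumerate(matrix.protein_ids):
            counts = {}
            for j, s in enumerate(matrix.sample_ids):
                cond = matrix.condition_of[s]
                if cond != "BC" and matrix.observed_mask[i, j]:
                    counts[cond] = counts.get(cond, 0) + 1
            if any(v >= 2 for v in counts.values()):
                expected.add(pid)
        assert set(filtered.protein_ids) == expected


class TestImputation:
    def test_no_missing_is_identity(self):
        values = np.arange(12.0).reshape(3, 4) + 10
        samples = ["BU_1", "BU_2", "BX_1", "BX_2"]
        m = ingest.IntensityMatrix(
            protein_ids=["A", "B", "C"], sample_ids=samples,
            condition_of={s: s.split("_")[0] for s in samples},
            values=values, observed_mask=np.ones((3, 4), bool),
            imputed_mask=np.zeros((3, 4), bool))
        out = ingest.impute_missing(m, seed=0)
        assert np.array_equal(out.values, values)
        assert not out.imputed_mask.any()

    @staticmethod
    def dense_matrix():
        rng = np.random.default_rng(0)
        values = rng.normal(20, 2, size=(6, 6))
        observed = np.ones((6, 6), bool)
        observed[0, 1] = observed[2, 4] = observed[5, 0] = observed[5, 3] = False
        values[~observed] = np.nan
        samples = [f"{c}_{r}" for c in ("BU", "BX") for r in (1, 2, 3)]
        return ingest.IntensityMatrix(
            protein_ids=[f"P{i}" for i in range(6)], sample_ids=samples,
            condition_of={s: s.split("_")[0] for s in samples},
            values=values, observed_mask=observed,
            imputed_mask=np.zeros_like(observed))

    def test_same_seed_identical_and_observed_untouched(self):
        m = self.dense_matrix()
        a = ingest.impute_missing(m, seed=42)
        b = ingest.impute_missing(m, seed=42)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.values[m.observed_mask],
                              m.values[m.observed_mask])
        assert np.array_equal(a.imputed_mask, ~m.observed_mask)

    def test_zero_width_hits_closed_form(self):
        m = self.dense_matrix()
        out = ingest.impute_missing(m, downshift=1.8, width=0.0, seed=1)
        for j in range(len(m.sample_ids)):
            obs = m.observed_mask[:, j]
            mu = m.values[obs, j].mean()
            sd = m.values[obs, j].std(ddof=1)
            imputed = out.values[out.imputed_mask[:, j], j]
            np.testing.assert_allclose(imputed, mu - 1.8 * sd)

    def test_sample_with_too_few_observed_raises(self, small_matrix):
        with pytest.raises(ValueError, match="BX_2"):
            ingest.impute_missing(small_matrix, seed=0)

    def test_imputed_mean_below_observed_mean_across_seeds(self):
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            ds = simulate_dataset(SimulationConfig(n_proteins=300, seed=seed))
            df, _ = ingest.remove_decoys_and_contaminants(ds.protein_groups)
            m, _ = ingest.valid_value_filter(ingest.matrix_from_table(df))
            out = ingest.impute_missing(m, seed=seed)
            imp, obs = out.imputed_mask, out.observed_mask
            if out.values[imp].mean() < out.values[obs].mean():
                wins += 1
        assert stats.binomtest(wins, n_seeds, 0.5,
                               alternative="greater").pvalue < 0.01

    def test_filter_order_independent_on_flag_disjoint_data(self, tmp_path):
        ds = simulate_dataset(SimulationConfig(n_proteins=100, seed=4))
        df = ds.protein_groups
        # order A: decoys first, then valid-value filter
        clean, _ = ingest.remove_decoys_and_contaminants(df)
        a, _ = ingest.valid_value_filter(ingest.matrix_from_table(clean))
        # order B: valid-value filter first, then drop flagged rows
        m = ingest.matrix_from_table(df)
        b, _ = ingest.valid_value_filter(m)
        flagged = set(df.loc[(df["Reverse"] == "+")
                             | (df["Potential contaminant"] == "+"),
                             "Majority protein IDs"])
        b_ids = [p for p in b.protein_ids if p not in flagged]
        assert a.protein_ids == b_ids
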