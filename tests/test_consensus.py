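"""Merged consensus table: column algebra, ordering, set identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condeseq.consensus import (
    MERGED_COLUMNS,
    merge_results,
    multi_de_pairs,
    significant_sets,
)
from condeseq.de_engines import EngineResult, bh_adjust
from condeseq.errors import MergeError
from condeseq.experiment_io import ContrastPair
from scipy.stats import rankdata


def fake_results(p_matrix, logfc=None, ave=None, ids=None):
    """Build three EngineResult objects from a (G, 3) raw p matrix."""
    p_matrix = np.asarray(p_matrix, dtype=float)
    g = p_matrix.shape[0]
    ids = ids if ids is not None else [f"g{i}" for i in range(g)]
    logfc = np.asarray(logfc, float) if logfc is not None else np.zeros((g, 3))
    ave = np.asarray(ave, float) if ave is not None else np.zeros((g, 3))
    pair = ContrastPair("A", "B")
    out = []
    for j, engine in enumerate(("nb_eb_lrt", "nb_wald", "precision_weights")):
        p = p_matrix[:, j]
        table = pd.DataFrame(
            {
                "logFC": logfc[:, j],
                "AveExpr": ave[:, j],
                "p_raw": p,
                "p_adj": bh_adjust(p),
                "rank": rankdata(p, method="average", nan_policy="omit"),
            },
            index=pd.Index(ids, name="ID"),
        )
        out.append(EngineResult(engine=engine, pair=pair, table=table))
    return out


class TestMergeResults:
    def test_table1_column_order(self):
        merged = merge_results(*fake_results(np.random.default_rng(0).uniform(size=(5, 3))))
        assert list(merged.columns[: len(MERGED_COLUMNS)]) == MERGED_COLUMNS

    def test_intersect_union_are_max_min(self):
        r = fake_results([[0.01, 0.02, 0.03]])
        merged = merge_results(*r)
        # raw p equal adjusted for a single gene
        assert merged.loc[0, "p_intersect"] == pytest.approx(0.03)
        assert merged.loc[0, "p_union"] == pytest.approx(0.01)

    def test_rank_sum(self):
        p = np.array([[0.001, 0.2, 0.001], [0.5, 0.001, 0.5]])
        merged = merge_results(*fake_results(p))
        first = merged.set_index("ID").loc["g0"]
        assert first["rank_sum"] == pytest.approx(1 + 2 + 1)

    def test_logfc_mean_and_sd(self):
        lfc = np.array([[1.0, 1.1, 1.2]])
        merged = merge_results(*fake_results([[0.1, 0.1, 0.1]], logfc=lfc))
        assert merged.loc[0, "LogFC"] == pytest.approx(1.1)
        assert merged.loc[0, "LogFC_sd"] == pytest.approx(0.1)

    def test_na_flag_and_propagation(self):
        p = np.array([[0.01, np.nan, 0.03], [0.2, 0.3, 0.4]])
        merged = merge_results(*fake_results(p)).set_index("ID")
        assert bool(merged.loc["g0", "na_flag"])
        assert np.isnan(merged.loc["g0", "p_intersect"])
        assert np.isfinite(merged.loc["g0", "p_union"])
        assert not bool(merged.loc["g1", "na_flag"])

    def test_mismatched_gene_sets_rejected(self):
        r1, r2, r3 = fake_results(np.random.default_rng(0).uniform(size=(4, 3)))
        r3.table = r3.table.rename(index={"g0": "other"})
        with pytest.raises(MergeError, match="other"):
            merge_results(r1, r2, r3)

    def test_sorted_by_rank_sum_with_id_tiebreak(self):
        rng = np.random.default_rng(3)
        merged = merge_results(*fake_results(rng.uniform(size=(50, 3))))
        rs = merged["rank_sum"].to_numpy()
        assert (np.diff(rs) >= 0).all()
        ties = merged.groupby("rank_sum")["ID"].apply(list)
        for ids in ties:
            assert ids == sorted(ids)

    def test_annotations_joined_not_dropped(self):
        annot = pd.DataFrame(
            {"symbol": ["S0"], "genename": ["gene zero"]},
            index=pd.Index(["g0"], name="ID"),
        )
        merged = merge_results(
            *fake_results(np.full((2, 3), 0.5)), annotations=annot
        ).set_index("ID")
        assert merged.loc["g0", "symbol"] == "S0"
        assert merged.loc["g1", "symbol"] == ""  # missing -> empty, row kept


class TestSignificantSets:
    def test_union_not_intersect_example(self):
        merged = merge_results(*fake_results([[0.01, 0.04, 0.06]]))
        sets = significant_sets(merged, alpha=0.05)
        assert "g0" in sets["union"] and "g0" not in sets["intersect"]

    def test_all_below_alpha_in_both(self):
        merged = merge_results(*fake_results([[0.01, 0.02, 0.03]]))
        sets = significant_sets(merged, alpha=0.05)
        assert "g0" in sets["union"] and "g0" in sets["intersect"]

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1), st.floats(0.01, 0.5))
    def test_set_identities_match_brute_force(self, seed, alpha):
        """Thresholding p_intersect/p_union equals explicit set algebra on
        the per-engine sets, for any alpha."""
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=(100, 3)) ** 2
        merged = merge_results(*fake_results(p))
        sets = significant_sets(merged, alpha=alpha)
        engines = [sets["edger"], sets["deseq"], sets["voom"]]
        assert sets["intersect"] == engines[0] & engines[1] & engines[2]
        assert sets["union"] == engines[0] | engines[1] | engines[2]
        # per-gene max/min identity
        stacked = np.column_stack(
            [merged["edger_adj_p"], merged["deseq_adj_p"], merged["voom_adj_p"]]
        )
        np.testing.assert_allclose(merged["p_intersect"], stacked.max(axis=1))
        np.testing.assert_allclose(merged["p_union"], stacked.min(axis=1))


class TestMultiDePairs:
    def test_two_groups_single_merged_table(self, small_sim):
        res = multi_de_pairs(small_sim.experiment, ruv=False)
        assert list(res) == ["A_vs_B"]
        assert res["A_vs_B"].merged is not None
        assert res["A_vs_B"].merged_ruv is None

    def test_three_groups_with_ruv_six_tables(self, nb_params, tmp_path):
        from condeseq.simulate import SimConfig, simulate_experiment
        from condeseq.experiment_io import CountExperiment

        cfg = SimConfig(n_genes=300, n_de=20, replicates=3, seed=2)
        sim = simulate_experiment(cfg, nb_params, seed=2)
        counts = sim.experiment.counts.copy()
        rng = np.random.default_rng(0)
        extra = rng.poisson(counts.iloc[:, :3].to_numpy())
        for j in range(3):
            counts[f"C_{j + 1}"] = extra[:, j]
        meta = sim.experiment.sample_meta
        meta = pd.concat(
            [
                meta,
                pd.DataFrame(
                    {"file": [f"C_{j + 1}" for j in range(3)], "group": "C"},
                    index=[f"C_{j + 1}" for j in range(3)],
                ),
            ]
        )
        exp = CountExperiment(counts=counts, sample_meta=meta)
        res = multi_de_pairs(exp, ruv=True, output_dir=tmp_path)
        tables = sorted(p.name for p in tmp_path.glob("*.tsv"))
        assert len(res) == 3
        assert len(tables) == 6  # 3 pairs x (plain, ruv)

    def test_intersect_subset_engines_subset_union(self, small_sim):
        res = multi_de_pairs(small_sim.experiment, ruv=False)["A_vs_B"]
        sets = significant_sets(res.merged, alpha=0.05)
        for role in ("edger", "deseq", "voom"):
            assert sets["intersect"] <= sets[role] <= sets["union"]
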