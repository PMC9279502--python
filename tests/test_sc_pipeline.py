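"""QC, normalization, CLR, gating, Wilcoxon DE, signatures, HLA sums."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from icbmm.sc_pipeline import (GatingConfig, GeneSignature, derive_signature,
                               differential_expression, gate_t_compartments,
                               normalize_protein_clr, normalize_rna,
                               qc_filter_cells, score_signature,
                               sum_hla_expression)


class TestQC:
    def test_boundary_rules(self, toy_adata):
        out = qc_filter_cells(toy_adata, min_genes=2, max_genes=2500,
                              min_cells_per_gene=3)
        rep = out.uns["qc_report"]
        # c1: 11% mito immune cell removed; c3: 1 detected gene removed;
        # c2: 10% mito but CD45neg (20% rule) retained
        assert set(out.obs_names) == {"c0", "c2", "c4", "c5"}
        assert rep["cells_removed_mito"] == 1
        assert rep["cells_removed_min_genes"] == 1
        # genes detected in exactly 3 remaining cells are retained ("<3" rule)
        assert "g1" in out.var_names and "g2" in out.var_names
        assert "g3" not in out.var_names

    def test_cell_detected_in_150_genes_removed(self):
        rng = np.random.default_rng(0)
        n_genes = 400
        X = np.zeros((2, n_genes), dtype=int)
        X[0, :150] = 1          # 150 detected genes -> below 200 -> removed
        X[1, :250] = 1          # 250 detected -> kept
        adata = ad.AnnData(
            X=X,
            obs=pd.DataFrame({"fraction": ["CD45pos", "CD45pos"]},
                             index=["a", "b"]),
            var=pd.DataFrame({"mito": np.zeros(n_genes, bool)},
                             index=[f"g{i}" for i in range(n_genes)]))
        out = qc_filter_cells(adata, min_cells_per_gene=1)
        assert list(out.obs_names) == ["b"]

    def test_immune_seven_percent_mito_removed(self):
        X = np.array([[93, 7], [97, 3]])
        adata = ad.AnnData(
            X=X, obs=pd.DataFrame({"fraction": ["CD45pos", "CD45pos"]},
                                  index=["a", "b"]),
            var=pd.DataFrame({"mito": [False, True]}, index=["g", "MT-g"]))
        out = qc_filter_cells(adata, min_genes=1, min_cells_per_gene=1)
        assert list(out.obs_names) == ["b"]  # 7% > 6% immune rule

    def test_all_cells_removed_is_an_error(self, toy_adata):
        with pytest.raises(ValueError, match="every cell"):
            qc_filter_cells(toy_adata, min_genes=100)

    def test_idempotent_on_generated_data(self, small_sim):
        _, adata, _, _ = small_sim
        once = qc_filter_cells(adata)
        twice = qc_filter_cells(once)
        assert once.shape == twice.shape
        assert list(once.obs_names) == list(twice.obs_names)
        np.testing.assert_array_equal(np.asarray(once.X), np.asarray(twice.X))


class TestNormalizeRNA:
    def test_scaled_row_sums_are_target(self, small_sim):
        _, adata, _, _ = small_sim
        q = qc_filter_cells(adata)
        norm = normalize_rna(q)
        pre_log = np.expm1(np.asarray(norm.X))
        np.testing.assert_allclose(pre_log.sum(axis=1), 1e4, rtol=1e-9)

    def test_single_values(self):
        adata = ad.AnnData(X=np.array([[2, 19998], [5000, 5000]]),
                           obs=pd.DataFrame(index=["a", "b"]),
                           var=pd.DataFrame(index=["g1", "g2"]))
        norm = normalize_rna(adata)
        # count 2 in a 20,000-count cell scales to 1.0 -> log(2) after log1p
        assert norm.X[0, 0] == pytest.approx(np.log(2), abs=1e-12)
        # a 10,000-count cell is unchanged by scaling
        assert norm.X[1, 0] == pytest.approx(np.log1p(5000), abs=1e-12)

    def test_all_zero_cell_error_names_cell(self):
        adata = ad.AnnData(X=np.array([[1, 2], [0, 0]]),
                           obs=pd.DataFrame(index=["ok", "empty"]),
                           var=pd.DataFrame(index=["g1", "g2"]))
        with pytest.raises(ValueError, match="empty"):
            normalize_rna(adata)


class TestCLR:
    def test_equal_markers_give_zero(self):
        df = pd.DataFrame([[5, 5, 5]], columns=list("abc"))
        np.testing.assert_allclose(normalize_protein_clr(df), 0.0, atol=1e-12)

    def test_single_marker_is_zero(self):
        df = pd.DataFrame([[7], [0]], columns=["a"])
        np.testing.assert_allclose(normalize_protein_clr(df), 0.0, atol=1e-12)

    def test_rows_sum_to_zero(self, small_sim):
        _, adata, _, _ = small_sim
        clr = normalize_protein_clr(adata.obsm["protein"])
        np.testing.assert_allclose(clr.sum(axis=1), 0.0, atol=1e-12)


def _gating_inputs(clr_rows, cd68=None):
    cells = [f"c{i}" for i in range(len(clr_rows))]
    clr = pd.DataFrame(clr_rows, index=cells,
                       columns=["CD45", "CD3", "CD4", "CD8", "CD20"])
    X = np.zeros((len(cells), 1)) if cd68 is None else np.array(cd68)[:, None]
    adata = ad.AnnData(X=X, obs=pd.DataFrame(index=cells),
                       var=pd.DataFrame(index=["CD68"]))
    return adata, clr


class TestGating:
    def test_cd4_cell_assigned(self):
        adata, clr = _gating_inputs([[2.0, 1.5, 1.2, -0.8, -1.0]], cd68=[0.0])
        out = gate_t_compartments(adata, clr)
        assert list(out.obs["compartment"]) == ["CD4"]

    def test_cd20_positive_excluded(self):
        adata, clr = _gating_inputs([[2.0, 1.5, 1.2, -0.8, 0.5]])
        out = gate_t_compartments(adata, clr)
        assert list(out.obs["compartment"]) == ["excluded"]

    def test_double_positive_and_negative_excluded(self):
        adata, clr = _gating_inputs([
            [2.0, 1.5, 1.2, 1.1, -1.0],    # CD4+CD8+ double positive
            [2.0, 1.5, -0.5, -0.5, -1.0],  # double negative
        ])
        out = gate_t_compartments(adata, clr)
        assert list(out.obs["compartment"]) == ["excluded", "excluded"]

    def test_cd68_high_rna_excluded(self):
        adata, clr = _gating_inputs([[2.0, 1.5, 1.2, -0.8, -1.0]], cd68=[2.5])
        out = gate_t_compartments(adata, clr)
        assert list(out.obs["compartment"]) == ["excluded"]

    def test_missing_marker_is_an_error(self):
        adata, clr = _gating_inputs([[2.0, 1.5, 1.2, -0.8, -1.0]])
        with pytest.raises(ValueError, match="CD20"):
            gate_t_compartments(adata, clr.drop(columns=["CD20"]))

    def test_gating_partitions_all_cells(self, small_sim):
        _, adata, _, _ = small_sim
        norm = normalize_rna(qc_filter_cells(adata))
        clr = normalize_protein_clr(norm.obsm["protein"])
        out = gate_t_compartments(norm, clr)
        counts = out.obs["compartment"].value_counts()
        assert counts.sum() == out.n_obs  # every cell in exactly one class
        assert out.uns["gating"]["thresholds"]["CD45"] == 0.0


def _exact_rank_sum_p(x, y):
    """Exhaustive enumeration of all rank assignments (no ties)."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(x)
    r1_obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        r = ranks[list(comb)].sum()
        total += 1
        if abs(r - mean) >= abs(r1_obs - mean) - 1e-9:
            count += 1
    return count / total


class TestDifferentialExpression:
    def test_constant_gene_null(self):
        expr = pd.DataFrame({"flat": np.ones(30), "var": np.arange(30.0)})
        labels = np.array(["a"] * 15 + ["b"] * 15)
        de = differential_expression(expr, labels, "a")
        assert de.loc["flat", "z"] == 0.0
        assert de.loc["flat", "p"] == pytest.approx(1.0)

    def test_five_vs_five_matches_exact_enumeration(self):
        rng = np.random.default_rng(3)
        x = rng.normal(2.0, 1.0, 5)
        y = rng.normal(0.0, 1.0, 5)
        expr = pd.DataFrame({"g": np.concatenate([x, y]),
                             "noise": rng.normal(size=10)})
        labels = np.array(["a"] * 5 + ["b"] * 5)
        de = differential_expression(expr, labels, "a")
        assert de.loc["g", "p"] == pytest.approx(_exact_rank_sum_p(x, y), abs=1e-12)
        assert de.loc["noise", "p"] == pytest.approx(
            _exact_rank_sum_p(expr["noise"][:5], expr["noise"][5:]), abs=1e-12)

    def test_permuted_labels_yield_no_bonferroni_hits(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(60, 2000)))
        expr.columns = [f"g{i}" for i in expr.columns]
        labels = rng.permutation(np.array(["a"] * 30 + ["b"] * 30))
        de = differential_expression(expr, labels, "a")
        assert (de["p_adj"] < 0.05).sum() <= 1

    def test_group_absent_is_an_error(self):
        expr = pd.DataFrame(np.ones((4, 2)))
        with pytest.raises(ValueError, match="absent"):
            differential_expression(expr, np.array(["a", "a", "b", "b"]), "c")

    def test_signed_z_orients_toward_group(self):
        expr = pd.DataFrame({"up": [5.0, 6, 7, 0, 0, 1], "dn": [0.0, 0, 1, 5, 6, 7]})
        labels = np.array(["a"] * 3 + ["b"] * 3)
        de = differential_expression(expr, labels, "a")
        assert de.loc["up", "z"] > 0 > de.loc["dn", "z"]


class TestSignatures:
    def test_positive_z_genes_selected(self):
        rng = np.random.default_rng(1)
        z = np.concatenate([rng.uniform(1, 5, 25), np.zeros(5)])
        de = pd.DataFrame({"z": z, "lfc": z / 2, "p": 0.01, "p_adj": 0.05,
                           "u": 0.0},
                          index=pd.Index([f"g{i:02d}" for i in range(30)],
                                         name="gene"))
        de.attrs["group"] = "clusterX"
        sig = derive_signature(de, k=25)
        assert set(sig.genes) == {f"g{i:02d}" for i in range(25)}
        assert sig.source_cluster == "clusterX"

    def test_tie_break_is_lexicographic(self):
        de = pd.DataFrame({"z": [1.0, 1.0, 0.5], "lfc": [1.0, 1.0, 1.0],
                           "p": 0.1, "p_adj": 0.1, "u": 0.0},
                          index=pd.Index(["gb", "ga", "gc"], name="gene"))
        sig = derive_signature(de, k=2)
        assert sig.genes == ("ga", "gb")

    def test_too_few_genes_is_an_error(self):
        de = pd.DataFrame({"z": [1.0], "lfc": [1.0], "p": 0.1, "p_adj": 0.1,
                           "u": 0.0}, index=pd.Index(["g"], name="gene"))
        with pytest.raises(ValueError, match="testable"):
            derive_signature(de, k=25)

    def test_planted_markers_recovered_across_seeds(self):
        # an 8-fold marker program should top the DE ranking nearly always
        from icbmm.synthetic_data import ClusterSpec, SimConfig, generate_sc_dataset
        markers = tuple(f"FILL{i:05d}" for i in range(10))
        spec = (
            ClusterSpec("planted", 0.3, "CD8", markers, 8.0, 10.0, True),
            ClusterSpec("rest", 0.7, "CD8", (), 8.0, 10.0, False),
        )
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimConfig(seed=seed, n_cells=400, n_genes=300,
                            cluster_spec=spec)
            adata, _, truth = generate_sc_dataset(cfg)
            norm = normalize_rna(adata)
            de = differential_expression(
                pd.DataFrame(np.asarray(norm.X), columns=norm.var_names),
                truth["cluster"].to_numpy(), "planted")
            top = set(de.head(len(markers)).index)
            if top == set(markers):
                hits += 1
        assert hits >= n_seeds - 1


class TestScoreSignature:
    def test_constant_log_values(self):
        sig = GeneSignature("s", ("a", "b"))
        expr = pd.DataFrame({"a": [2.0, 2.0], "b": [2.0, 2.0], "c": [9.0, 1.0]})
        assert (score_signature(expr, sig) == 2.0).all()

    def test_standardized_moments(self):
        rng = np.random.default_rng(2)
        sig = GeneSignature("s", ("a", "b", "c"))
        expr = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        s = score_signature(expr, sig, standardize=True)
        assert s.mean() == pytest.approx(0.0, abs=1e-12)
        assert s.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        sig = GeneSignature("s", tuple(genes[:25]))
        expr = pd.DataFrame(rng.normal(size=(15, 30)), columns=genes)
        s = score_signature(expr, sig)
        oracle = np.array([[expr.iloc[i][g] for g in sig.genes]
                           for i in range(15)]).mean(axis=1)
        np.testing.assert_allclose(s, oracle, atol=1e-12)

    def test_invariant_to_gene_order_and_extra_genes(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(10)]
        sig = GeneSignature("s", tuple(genes[:5]))
        expr = pd.DataFrame(rng.normal(size=(8, 10)), columns=genes)
        base = score_signature(expr, sig)
        shuffled = expr[rng.permutation(genes)]
        np.testing.assert_allclose(score_signature(shuffled, sig), base,
                                   atol=1e-12)
        np.testing.assert_allclose(score_signature(expr[genes[:5]], sig), base,
                                   atol=1e-12)

    def test_missing_gene_error_lists_gene(self):
        sig = GeneSignature("s", ("a", "zz"))
        expr = pd.DataFrame({"a": [1.0]})
        with pytest.raises(KeyError, match="zz"):
            score_signature(expr, sig)


class TestHLASums:
    def test_single_gene_locus_equals_gene(self):
        expr = pd.DataFrame({"HLA-A": [1.0, 2.0], "HLA-DRA": [3.0, 0.0]})
        totals, per_gene = sum_hla_expression(expr, {"I": ["HLA-A"]})
        np.testing.assert_allclose(totals["I"], expr["HLA-A"])

    def test_totals_equal_row_sums(self):
        rng = np.random.default_rng(5)
        genes = ["HLA-A", "HLA-B", "HLA-C", "HLA-DRA", "HLA-DRB1"]
        expr = pd.DataFrame(rng.uniform(0, 5, size=(20, 5)), columns=genes)
        totals, per_gene = sum_hla_expression(
            expr, {"I": genes[:3], "II": genes[3:]})
        np.testing.assert_allclose(totals["I"], expr[genes[:3]].sum(axis=1),
                                   atol=1e-12)
        np.testing.assert_allclose(totals["II"], expr[genes[3:]].sum(axis=1),
                                   atol=1e-12)
        assert list(per_gene.columns) == genes

    def test_all_zero_cell_total_zero(self):
        expr = pd.DataFrame({"HLA-A": [0.0], "HLA-B": [0.0]})
        totals, _ = sum_hla_expression(expr, {"I": ["HLA-A", "HLA-B"]})
        assert totals["I"].iloc[0] == 0.0

    def test_empty_gene_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            sum_hla_expression(pd.DataFrame({"a": [1.0]}), {"I": []})
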