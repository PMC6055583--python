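import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import triomix as tm
from triomix.diffstats import DifferentialResults

from conftest import make_layer


def binom_tail_oracle(k, n):
    """Exact P(X >= k), X ~ Binomial(n, 1/2), in rational arithmetic."""
    total = sum(math.comb(n, i) for i in range(k, n + 1))
    return Fraction(total, 2**n)


def results_from_logfc(logfc, q=None, ci_halfwidth=1.0):
    logfc = pd.Series(logfc)
    table = pd.DataFrame({
        "logFC": logfc,
        "q": 0.0 if q is None else pd.Series(q),
        "p": 0.0,
        "t": 0.0,
        "ci_lo": logfc - ci_halfwidth,
        "ci_hi": logfc + ci_halfwidth,
    })
    return DifferentialResults(table, "rna", "O_vs_L", 9, 0.0)


class TestMapGeneIds:
    def test_all_unique_kept(self):
        df = pd.DataFrame({"ensembl_id": ["E1", "E2"], "gene_name": ["A", "B"]})
        assert len(tm.map_gene_ids(df)) == 2

    def test_duplicate_name_drops_both(self):
        df = pd.DataFrame({"ensembl_id": ["E1", "E2"], "gene_name": ["A", "A"]})
        assert tm.map_gene_ids(df).empty

    def test_duplicate_id_drops_only_those(self):
        df = pd.DataFrame({"ensembl_id": ["E1", "E1", "E2"],
                           "gene_name": ["A", "B", "C"]})
        out = tm.map_gene_ids(df)
        assert out.to_records(index=False).tolist() == [("E2", "C")]


class TestBinomialConcordance:
    def test_52_of_56_exact_tail(self):
        p = tm.binomial_concordance(52, 56)
        assert p == pytest.approx(float(binom_tail_oracle(52, 56)), rel=1e-12)
        assert p == pytest.approx(5.50e-12, rel=0.01)
        assert p <= 1e-10

    def test_18_of_18_closed_form(self):
        p = tm.binomial_concordance(18, 18)
        assert p == pytest.approx(2.0**-18, rel=1e-12)
        assert p <= 1e-5

    def test_zero_successes_full_tail(self):
        assert tm.binomial_concordance(0, 10) == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 25), st.data())
    def test_matches_exact_enumeration(self, n, data):
        k = data.draw(st.integers(0, n))
        assert tm.binomial_concordance(k, n) == pytest.approx(
            float(binom_tail_oracle(k, n)), rel=1e-12)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            tm.binomial_concordance(5, 0)
        with pytest.raises(ValueError):
            tm.binomial_concordance(7, 6)


class TestTripleOverlap:
    def dmr_summary(self, genes, prop=1.0):
        return pd.DataFrame({"regions": [[0]] * len(genes),
                             "n_dmps_in_dmrs": 3, "prop_pos_beta": prop},
                            index=pd.Index(genes, name="gene"))

    def test_disjoint_sets_empty(self):
        rna = results_from_logfc({"A": 1.0}, q={"A": 0.0001})
        prot = results_from_logfc({"B": 1.0}, q={"B": 0.0001})
        out = tm.triple_overlap(rna, prot, self.dmr_summary(["C"]))
        assert out.empty

    def test_single_gene_everywhere(self):
        rna = results_from_logfc({"A": 1.5}, q={"A": 1e-5})
        prot = results_from_logfc({"A": -0.5}, q={"A": 1e-4})
        out = tm.triple_overlap(rna, prot, self.dmr_summary(["A"], prop=0.25))
        assert list(out.index) == ["A"]
        row = out.loc["A"]
        assert row["rna_direction"] == 1
        assert row["protein_direction"] == -1
        assert row["methylation_direction"] == -1  # prop_pos_beta < 0.5
        assert not row["rna_protein_concordant"]

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(30)]
        rna = results_from_logfc(pd.Series(rng.normal(size=30), index=genes),
                                 q=pd.Series(rng.random(30) * 0.1, index=genes))
        prot = results_from_logfc(pd.Series(rng.normal(size=30), index=genes[::-1]),
                                  q=pd.Series(rng.random(30) * 0.1,
                                              index=genes[::-1]))
        summary = self.dmr_summary(genes[5:25])
        once = tm.triple_overlap(rna, prot, summary, fdr=0.05)
        again = tm.triple_overlap(rna, prot, summary.iloc[::-1], fdr=0.05)
        pd.testing.assert_frame_equal(once, again)

    def test_planted_genes_recovered(self):
        # ~60 genes carry effects on all three layers (0.2 x 300 proteins)
        data = tm.generate_dataset(tm.SimConfig(
            n_genes=600, n_proteins=300, probes_per_gene=2,
            n_decoy_sets=0, planted_sets=[], seed=21))
        rna_results = tm.PairedDifferential(data.layers["rna"], "O_vs_L").fit()
        prot = tm.normalize_protein(tm.filter_complete(data.layers["protein"]))
        prot_res = tm.PairedDifferential(prot, "O_vs_L").fit()
        meth_res = tm.PairedDifferential(data.layers["methylation"], "O_vs_L").fit()
        regions = tm.call_dmrs(meth_res, data.probe_annotation, probe_fdr=0.05)
        summary = tm.overlap_genes(regions, data.gene_intervals,
                                   data.probe_annotation, meth_res,
                                   probe_fdr=0.05)
        out = tm.triple_overlap(rna_results, prot_res, summary, fdr=0.05)
        truth = data.truth.effects
        expected = set(truth.index[truth["affected"] & truth["on_protein_layer"]])
        got = set(out.index)
        jaccard = len(got & expected) / len(got | expected)
        assert jaccard >= 0.7


class TestContrastCorrelation:
    def test_self_correlation(self):
        rng = np.random.default_rng(4)
        res = results_from_logfc(pd.Series(rng.normal(size=20)))
        rep = tm.contrast_correlation(res, res)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.proportion == 1.0
        assert rep.ci_overlap_fraction == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        lfc = pd.Series(rng.normal(size=20))
        a = results_from_logfc(lfc)
        b = results_from_logfc(-lfc)
        rep = tm.contrast_correlation(a, b)
        assert rep.spearman_rho == pytest.approx(-1.0)
        assert rep.n_concordant == 0

    def test_too_few_shared_features(self):
        a = results_from_logfc({"A": 1.0, "B": 2.0})
        b = results_from_logfc({"A": 1.0, "C": 2.0})
        with pytest.raises(ValueError, match="3 shared"):
            tm.contrast_correlation(a, b)

    def test_rna_protein_concordance_excess(self):
        """With rna_protein_corr=0.6 the concordant fraction among
        triple-significant genes exceeds 1/2 (one-sided binomial P < 0.05)
        in most runs."""
        hits = 0
        for seed in range(5):
            data = tm.generate_dataset(tm.SimConfig(
                n_genes=600, n_proteins=300, probes_per_gene=2,
                rna_protein_corr=0.6, n_decoy_sets=0, planted_sets=[],
                seed=100 + seed))
            rna = tm.PairedDifferential(data.layers["rna"], "O_vs_L").fit()
            prot = tm.normalize_protein(tm.filter_complete(data.layers["protein"]))
            prot_res = tm.PairedDifferential(prot, "O_vs_L").fit()
            rep = tm.contrast_correlation(rna, prot_res,
                                          features=set(rna.significant(0.05))
                                          & set(prot_res.significant(0.05)))
            if tm.binomial_concordance(rep.n_concordant, rep.n_total) < 0.05:
                hits += 1
        assert hits >= 4


class TestPcaSeparation:
    def test_planted_axis_separates(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(20, 27))
        layer = make_layer(vals)
        shift = (layer.sample_design["grade"] == "osteophytic").to_numpy() * 6.0
        layer = layer.with_values(layer.values + shift)
        out = tm.pca_separation(layer, set(layer.features))
        assert out.separated
        assert out.method == "pc1-threshold"

    def test_pure_noise_rarely_separates(self):
        separated = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            layer = make_layer(rng.normal(size=(30, 27)))
            if tm.pca_separation(layer, set(layer.features)).separated:
                separated += 1
        assert separated <= 2

    def test_feature_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(9)
        layer = make_layer(rng.normal(size=(15, 27)))
        a = tm.pca_separation(layer, set(layer.features))
        perm = rng.permutation(15)
        shuffled = layer.with_values(layer.values.iloc[perm])
        b = tm.pca_separation(shuffled, set(layer.features))
        for pc in ("PC1", "PC2"):
            x, y = a.scores[pc].to_numpy(), b.scores[pc].to_numpy()
            assert np.allclose(x, y, atol=1e-8) or np.allclose(x, -y, atol=1e-8)

    def test_empty_subset_rejected(self):
        layer = make_layer(np.zeros((3, 27)))
        with pytest.raises(ValueError):
            tm.pca_separation(layer, set())
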