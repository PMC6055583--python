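import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import triomix as tm
from triomix.simulate import SimConfigError


QUICK = dict(n_genes=300, n_proteins=100, probes_per_gene=2,
             n_decoy_sets=10, decoy_set_size=15)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("frac_affected_genes", 1.2),
        ("effect_ratio_hvl", 1.0),
        ("effect_ratio_ovh", 0.0),
        ("n_genes", 0),
        ("rna_protein_corr", -0.1),
        ("effect_scale_ovl", 0.0),
    ])
    def test_invalid_field_named(self, field, value):
        cfg = dataclasses.replace(tm.SimConfig(), **{field: value})
        with pytest.raises(SimConfigError, match=field.split("_")[0]):
            tm.generate_dataset(cfg)

    def test_proteins_must_be_subset(self):
        with pytest.raises(SimConfigError, match="n_proteins"):
            tm.generate_dataset(tm.SimConfig(n_genes=10, n_proteins=11))


class TestDeterminism:
    def test_same_seed_identical_output(self):
        cfg = tm.SimConfig(seed=1, **QUICK)
        a = tm.generate_dataset(cfg)
        b = tm.generate_dataset(cfg)
        for name in a.layers:
            pd.testing.assert_frame_equal(a.layers[name].values,
                                          b.layers[name].values)
        pd.testing.assert_frame_equal(a.probe_annotation, b.probe_annotation)
        pd.testing.assert_frame_equal(a.truth.effects, b.truth.effects)
        assert a.gene_sets == b.gene_sets

    def test_written_files_byte_identical(self, tmp_path):
        cfg = tm.SimConfig(seed=5, **QUICK)
        tm.generate_dataset(cfg).write(tmp_path / "a")
        tm.generate_dataset(cfg).write(tmp_path / "b")
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_different_seeds_differ(self):
        a = tm.generate_dataset(tm.SimConfig(seed=1, **QUICK))
        b = tm.generate_dataset(tm.SimConfig(seed=2, **QUICK))
        assert not a.layers["rna"].values.equals(b.layers["rna"].values)


class TestGroundTruth:
    def test_affected_flags_match_effects(self):
        data = tm.generate_dataset(tm.SimConfig(seed=3, **QUICK))
        eff = data.truth.effects
        unaffected = eff[~eff["affected"]]
        cols = [c for c in eff.columns if "_O_vs_L" in c]
        assert (unaffected[cols].fillna(0.0) == 0.0).all().all()
        affected = eff[eff["affected"]]
        assert (affected[cols].abs().max(axis=1) > 0).all()

    def test_contrast_additivity(self):
        eff = tm.generate_dataset(tm.SimConfig(seed=4, **QUICK)).truth.effects
        for layer in ("rna", "methylation"):
            total = eff[f"{layer}_O_vs_H"] + eff[f"{layer}_H_vs_L"]
            assert np.allclose(total, eff[f"{layer}_O_vs_L"])

    def test_null_config_has_no_affected_genes(self):
        data = tm.generate_dataset(tm.null_config(seed=0, **QUICK))
        assert not data.truth.affected_genes
        res = tm.PairedDifferential(data.layers["rna"], "O_vs_L").fit()
        # raw false-positive rate near nominal alpha
        assert 0.01 <= (res.table["p"] < 0.05).mean() <= 0.12


class TestStructure:
    def test_probe_layout_within_gene_bodies(self):
        data = tm.generate_dataset(tm.SimConfig(seed=6, **QUICK))
        ann = data.probe_annotation.merge(data.gene_intervals, on="gene",
                                          suffixes=("", "_gene"))
        assert (ann["start"] >= ann["start_gene"]).all()
        assert (ann["start"] <= ann["end_gene"]).all()
        assert (data.probe_annotation.groupby("gene").size() >= 2).all()

    def test_protein_features_subset_of_genes(self):
        data = tm.generate_dataset(tm.SimConfig(seed=6, **QUICK))
        assert set(data.layers["protein"].features) <= \
            set(data.layers["rna"].features)

    def test_planted_sets_drawn_from_affected(self):
        cfg = tm.SimConfig(seed=7, planted_sets=[tm.PlantedSet("p", 20, 1.0)],
                           **QUICK)
        data = tm.generate_dataset(cfg)
        assert data.gene_sets["p"] <= data.truth.affected_genes
        assert data.truth.planted_sets["p"]

    def test_ovl_vs_hvl_correlation_matches_generator_oracle(self):
        """Estimated OvL/HvL RNA logFC Spearman correlation agrees with a
        direct Monte-Carlo of the generative model run outside the pipeline."""
        cfg = tm.SimConfig(n_genes=2000, frac_affected_genes=0.2,
                           effect_ratio_hvl=0.3, seed=42)
        data = tm.generate_dataset(cfg)
        rna = data.layers["rna"]
        ovl = tm.paired_fit(rna, "O_vs_L")["logFC"]
        hvl = tm.paired_fit(rna, "H_vs_L")["logFC"]
        rho = stats.spearmanr(ovl, hvl).statistic

        # independent oracle: draw true effects and paired-mean noise directly
        rng = np.random.default_rng(2024)
        n, n_pat = 100_000, cfg.n_patients
        sd = cfg.noise_sd["rna"]
        affected = rng.random(n) < cfg.frac_affected_genes
        delta = np.where(
            affected,
            rng.choice([-1.0, 1.0], n) * cfg.effect_scale_ovl
            * (1 + 0.5 * np.abs(rng.standard_normal(n))), 0.0)
        h = cfg.high_grade_fraction
        # both contrasts share the low-grade samples, so their estimation
        # noises are correlated; draw one mean-noise per grade
        se = sd / np.sqrt(n_pat)
        e_o, e_h, e_l = (se * rng.standard_normal(n) for _ in range(3))
        est_ovl = delta + e_o - e_l
        est_hvl = h * delta + e_h - e_l
        rho_oracle = stats.spearmanr(est_ovl, est_hvl).statistic

        assert rho > 0
        assert abs(rho - rho_oracle) <= 0.15

    def test_effect_scale_monotonicity(self):
        """Doubling the effect scale does not decrease the number of
        OvL-significant genes (majority vote over seeds)."""
        wins = 0
        for seed in range(3):
            base = tm.generate_dataset(tm.SimConfig(seed=seed, **QUICK))
            boosted = tm.generate_dataset(
                tm.SimConfig(seed=seed, effect_scale_ovl=3.0, **QUICK))
            n_base = len(tm.PairedDifferential(base.layers["rna"],
                                               "O_vs_L").fit().significant(0.05))
            n_boost = len(tm.PairedDifferential(boosted.layers["rna"],
                                                "O_vs_L").fit().significant(0.05))
            wins += n_boost >= n_base
        assert wins >= 2

    def test_planted_set_ranks_first_by_combined_p(self):
        """A fully affected 50-gene planted set tops the combined-enrichment
        ranking in nearly all seeds."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = tm.SimConfig(n_genes=800, n_proteins=400, probes_per_gene=2,
                               planted_sets=[tm.PlantedSet("planted", 50, 1.0)],
                               n_decoy_sets=40, decoy_set_size=40, seed=seed)
            data = tm.generate_dataset(cfg)
            rna = tm.PairedDifferential(data.layers["rna"], "O_vs_L").fit()
            prot_layer = tm.normalize_protein(
                tm.filter_complete(data.layers["protein"]))
            prot = tm.PairedDifferential(prot_layer, "O_vs_L").fit()
            meth = tm.PairedDifferential(data.layers["methylation"],
                                         "O_vs_L").fit()
            sig = {
                "rna": set(rna.significant(0.05)),
                "protein": set(prot.significant(0.05)),
                "methylation": tm.dmr_gene_set(meth, data.probe_annotation,
                                               data.gene_intervals,
                                               probe_fdr=0.05),
            }
            universes = {
                "rna": set(data.layers["rna"].features),
                "protein": set(prot_layer.features),
                "methylation": set(data.gene_intervals["gene"]),
            }
            coll = tm.GeneSetCollection(dict(data.gene_sets), universes)
            combined = {}
            for name, members in coll.sets.items():
                ps = []
                for layer in ("methylation", "rna", "protein"):
                    u = universes[layer]
                    _, _, p = tm.hypergeom_enrich(sig[layer] & u,
                                                  members & u, u)
                    ps.append(p)
                combined[name] = tm.combine_levels(ps)[1]
            best = min(combined, key=combined.get)
            hits += best == "planted"
        assert hits >= round(0.95 * n_seeds)
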