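"""Synthetic-data generator: determinism, moments, planted structure."""

import numpy as np
import pandas as pd
import pytest

from eggimmune.simulate import (
    ConfigurationError,
    SimulationConfig,
    design_table,
    simulate_annotation,
    simulate_cfu,
    simulate_counts,
    simulate_ct,
    simulate_peptides,
)


def null_config(**kw):
    base = dict(
        n_genes=200,
        gene_class_fractions={"null": 1.0},
        nb_dispersion=0.0,
        seed=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(gene_class_fractions={"null": 0.5}).validate()

    def test_dimensions_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_genes=0).validate()

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(nb_dispersion=-0.1).validate()


class TestCounts:
    def test_shape_and_sample_names(self):
        cfg = null_config()
        cm, truth = simulate_counts(cfg)
        assert cm.counts.shape == (200, 27)
        assert "wildtype.septic.rep2" in cm.counts.columns
        assert design_table(cfg).shape == (27, 3)
        assert (truth.gene_class == "null").all()

    def test_same_seed_is_bit_identical(self):
        a, _ = simulate_counts(null_config())
        b, _ = simulate_counts(null_config())
        assert a.counts.equals(b.counts)

    def test_different_seeds_differ(self):
        a, _ = simulate_counts(null_config(seed=1))
        b, _ = simulate_counts(null_config(seed=2))
        assert not a.counts.equals(b.counts)

    def test_null_poisson_means_match_truth_within_three_se(self):
        cfg = null_config()
        cm, truth = simulate_counts(cfg)
        mu = truth.true_means.iloc[:, 0]
        emp = cm.counts.mean(axis=1)
        se = np.sqrt(mu / 27)  # Poisson SE of the mean over 27 samples
        frac_in = (np.abs(emp - mu) <= 3 * se).mean()
        assert frac_in > 0.95

    def test_nb_variance_tracks_mu_plus_alpha_mu_squared(self):
        cfg = null_config(n_genes=300, nb_dispersion=0.3, seed=4)
        cm, truth = simulate_counts(cfg)
        mu = truth.true_means.iloc[:, 0].to_numpy()
        big = mu > 100
        var = cm.counts.to_numpy()[big].var(axis=1, ddof=1)
        implied_alpha = np.median((var - mu[big]) / mu[big] ** 2)
        assert 0.15 <= implied_alpha <= 0.45

    def test_planted_classes_shape_the_condition_means(self):
        cfg = SimulationConfig(n_genes=400, seed=3)
        cm, truth = simulate_counts(cfg)
        means = truth.true_means
        sd = truth.genes_of_class("serosa_dependent_inducible")
        assert (means.loc[sd, "wildtype.septic.rep1"]
                > means.loc[sd, "wildtype.naive.rep1"]).all()
        assert (means.loc[sd, "zen1_rnai.septic.rep1"]
                == means.loc[sd, "zen1_rnai.naive.rep1"]).all()
        assert (means.loc[sd, "wildtype.sterile.rep1"]
                == means.loc[sd, "wildtype.naive.rep1"]).all()
        wr = truth.genes_of_class("wound_responsive")
        assert (means.loc[wr, "zen1_rnai.sterile.rep1"]
                > means.loc[wr, "zen1_rnai.naive.rep1"]).all()
        cs = truth.genes_of_class("constitutive_serosal")
        assert (means.loc[cs, "wildtype.naive.rep1"]
                > means.loc[cs, "zen1_rnai.naive.rep1"]).all()
        nul = truth.genes_of_class("null")
        assert means.loc[nul].nunique(axis=1).eq(1).all()

    def test_sterile_induction_option(self):
        cfg = SimulationConfig(n_genes=100, seed=3,
                               sterile_induces_serosa_genes=True)
        _, truth = simulate_counts(cfg)
        sd = truth.genes_of_class("serosa_dependent_inducible")
        m = truth.true_means
        assert (m.loc[sd, "wildtype.sterile.rep1"]
                > m.loc[sd, "wildtype.naive.rep1"]).all()


class TestPeptides:
    def test_planted_amps_satisfy_the_screen_by_construction(self):
        records, labels = simulate_peptides(30, 0.5, seed=9)
        for gid, seq in records:
            if not labels[gid]:
                continue
            charge = sum(seq.count(c) for c in "KR") - sum(
                seq.count(c) for c in "DE")
            hydro = 100 * sum(seq.count(c) for c in "AVILMFWC") / len(seq)
            assert len(seq) < 200 and charge >= 1 and hydro >= 30

    def test_decoys_violate_at_least_one_criterion(self):
        records, labels = simulate_peptides(30, 0.0, seed=9)
        for gid, seq in records:
            charge = sum(seq.count(c) for c in "KR") - sum(
                seq.count(c) for c in "DE")
            hydro = 100 * sum(seq.count(c) for c in "AVILMFWC") / len(seq)
            assert len(seq) >= 200 or charge < 1 or hydro < 30

    def test_seeded_reproducibility(self):
        a, _ = simulate_peptides(20, 0.5, seed=4)
        b, _ = simulate_peptides(20, 0.5, seed=4)
        assert a == b

    def test_invalid_arguments(self):
        with pytest.raises(ConfigurationError):
            simulate_peptides(0, 0.5, seed=1)
        with pytest.raises(ConfigurationError):
            simulate_peptides(5, 1.5, seed=1)


class TestCfu:
    def test_reproducible_and_well_formed(self):
        a = simulate_cfu({"wt": 0.44}, 53.0, plates=5, seed=1)
        b = simulate_cfu({"wt": 0.44}, 53.0, plates=5, seed=1)
        pd.testing.assert_frame_equal(a, b)
        assert (a["colonies"] >= 0).all()
        assert set(a["time_h"]) == {0.0, 6.0}

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_cfu({"wt": -0.1}, 53.0, plates=5, seed=1)

    def test_negative_inoculum_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_cfu({"wt": 0.1}, -1.0, plates=5, seed=1)


class TestCtAndAnnotation:
    def test_ct_table_realises_requested_folds(self):
        ct = simulate_ct({"tgt": {"septic": 64.0}}, seed=1, noise_sd=0.0)
        from eggimmune.qpcr import livak_fold_change

        r = livak_fold_change(ct, "tgt", "septic")
        assert r.fold_change == pytest.approx(64.0, rel=1e-6)

    def test_annotation_plants_the_defense_category(self):
        cfg = SimulationConfig(n_genes=500, seed=5)
        _, truth = simulate_counts(cfg)
        ann = simulate_annotation(truth, seed=5)
        sd = set(truth.genes_of_class("serosa_dependent_inducible"))
        defense = set(ann.loc[ann["category_id"] == "GO:0006952", "gene_id"])
        frac_sd = len(defense & sd) / len(sd)
        frac_bg = len(defense - sd) / (500 - len(sd))
        assert frac_sd > 0.5 > frac_bg
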