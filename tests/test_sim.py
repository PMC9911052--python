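import numpy as np
import pytest

from conftest import tiny_config
from ghatpy.sim import (SimConfig, desk_scale, run_table1_group,
                        simulate_founders, simulate_pair, simulate_study)


class TestConfig:
    def test_defaults_match_baseline_design(self):
        cfg = SimConfig()
        assert cfg.n_chrom == 30
        assert cfg.chrom_length_cm == 100.0
        assert cfg.n_hist_generations == 100
        assert cfg.n_breeding_generations == 20

    def test_desk_scale_preset(self):
        cfg = desk_scale()
        assert (cfg.n_chrom, cfg.n_markers, cfg.n) == (5, 2000, 400)
        assert (cfg.h2, cfg.n_qtl) == (0.5, 150)
        assert desk_scale(n=100).n == 100

    @pytest.mark.parametrize("bad", [
        dict(h2=0.0), dict(h2=1.5), dict(selected_fraction=0.0),
        dict(selection="directional"), dict(n_qtl=0),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad)


class TestFounders:
    def test_zero_hist_generations_equal_init_draw(self):
        cfg = tiny_config(n_hist_generations=0, hist_n=500)
        rng = np.random.default_rng(0)
        pop = simulate_founders(cfg, rng)
        # no reproduction happened: haplotypes are the Bernoulli(p_init)
        # draw itself, so frequencies track p_init at binomial precision
        se = np.sqrt(pop.p_init * (1 - pop.p_init) / (2 * cfg.hist_n))
        inside = np.abs(pop.freqs - pop.p_init) <= 4 * se + 1e-12
        assert inside.mean() > 0.99

    def test_heterozygosity_decays_at_wright_fisher_rate(self):
        """Expected heterozygosity declines by (1 - 1/(2N)) per drift
        generation."""
        ratios = []
        for seed in range(3):
            cfg = tiny_config(n_hist_generations=0, hist_n=40,
                              n_markers=300, n_qtl=10, seed=seed)
            rng = np.random.default_rng(seed)
            pop0 = simulate_founders(cfg, rng)
            h0 = np.mean(2 * pop0.freqs * (1 - pop0.freqs))
            t = 30
            cfg_t = tiny_config(n_hist_generations=t, hist_n=40,
                                n_markers=300, n_qtl=10, seed=seed)
            pop_t = simulate_founders(cfg_t, np.random.default_rng(seed))
            h_t = np.mean(2 * pop_t.freqs * (1 - pop_t.freqs))
            ratios.append(h_t / h0)
        expected = (1 - 1 / (2 * 40)) ** 30
        assert np.mean(ratios) == pytest.approx(expected, rel=0.12)

    def test_drift_only_mean_change_near_zero(self):
        cfg = tiny_config(hist_n=80, n_hist_generations=30)
        rng = np.random.default_rng(5)
        pop = simulate_founders(cfg, rng)
        drift = pop.freqs - pop.p_init
        # each locus drifts, but the average change across many loci is 0
        assert abs(drift.mean()) < 4 * drift.std() / np.sqrt(len(drift))


class TestEvolve:
    def test_h2_one_phenotype_equals_breeding_value(self):
        study = simulate_study(tiny_config(h2=1.0, seed=3))
        for g in (0, 5, 20):
            np.testing.assert_allclose(study.phenotypes[g],
                                       study.breeding_values[g], atol=1e-5)

    def test_truncation_selection_raises_breeding_values(self, tiny_pair):
        _, sel = tiny_pair
        bv = [b.mean() for b in sel.breeding_values]
        sd0 = sel.breeding_values[0].std()
        assert bv[-1] - bv[0] > 3 * sd0
        # response accumulates: late generations above early ones
        assert np.all(np.diff([bv[0], bv[5], bv[10], bv[20]]) > 0)

    def test_unselected_breeding_values_stay_flat(self, tiny_pair):
        neu, _ = tiny_pair
        bv = [b.mean() for b in neu.breeding_values]
        sd0 = neu.breeding_values[0].std()
        assert abs(bv[-1] - bv[0]) < 2.5 * sd0

    def test_seed_pairing_shares_generation_zero(self, tiny_pair):
        neu, sel = tiny_pair
        np.testing.assert_array_equal(neu.dosages[0], sel.dosages[0])
        np.testing.assert_array_equal(neu.phenotypes[0], sel.phenotypes[0])
        assert not np.array_equal(neu.dosages[-1], sel.dosages[-1])

    def test_realized_heritability_matches_target(self):
        """var(BV)/var(phenotype) in the founder generation stays close to
        the configured h2, averaged over replicates."""
        vals = []
        for seed in range(10):
            study = simulate_study(tiny_config(n=400, seed=100 + seed))
            h2 = (study.breeding_values[0].var()
                  / study.phenotypes[0].var())
            vals.append(h2)
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_neutral_qtl_frequency_change_unrelated_to_effects(self):
        """Under random mating the recent frequency change at QTL has no
        linear association with the QTL effects; under selection it
        does."""
        slopes_neutral, slopes_sel = [], []
        for seed in range(8):
            neu, sel = simulate_pair(tiny_config(n_qtl=40,
                                                 seed=200 + seed))
            for study, out in ((neu, slopes_neutral), (sel, slopes_sel)):
                dq = study.qtl_freqs[20] - study.qtl_freqs[15]
                eff = study.qtl_effects
                out.append(np.polyfit(eff, dq, 1)[0])
        t_neu = np.mean(slopes_neutral) / (np.std(slopes_neutral)
                                           / np.sqrt(len(slopes_neutral)))
        assert abs(t_neu) < 4
        assert np.mean(slopes_sel) > 3 * np.std(slopes_sel) / np.sqrt(8)

    def test_marker_drift_variance_matches_wright_fisher(self):
        """Across neutral loci, var(delta over t generations) tracks
        p(1-p)(1 - (1 - 1/(2N))^t)."""
        obs, exp = [], []
        for seed in range(4):
            study = simulate_study(tiny_config(n=150, n_markers=300,
                                               seed=300 + seed))
            f15 = study.dosages[15].mean(axis=0) / 2.0
            f20 = study.dosages[20].mean(axis=0) / 2.0
            keep = (f15 > 0.05) & (f15 < 0.95)
            factor = 1 - (1 - 1 / (2 * 150)) ** 5
            obs.append(np.mean((f20 - f15)[keep] ** 2))
            exp.append(np.mean((f15 * (1 - f15))[keep]) * factor)
        ratio = np.sum(obs) / np.sum(exp)
        assert 0.75 < ratio < 1.35

    def test_too_strong_truncation_errors(self):
        cfg = tiny_config(n=8, selected_fraction=0.05,
                          selection="truncation")
        # a 5% fraction of 8 individuals rounds below 2 parents, which the
        # simulator clamps; 1-of-n would error in parent drawing
        study = simulate_study(cfg)
        assert study.n_generations == 21


class TestSweepHarness:
    def test_reproducible_and_shaped(self):
        cfg = tiny_config()
        df1 = run_table1_group("heritability", [0.5], reps=1, seed=9,
                               base_config=cfg)
        df2 = run_table1_group("heritability", [0.5], reps=1, seed=9,
                               base_config=cfg)
        assert len(df1) == 2          # both populations, one replicate
        assert (df1["p_value"] == df2["p_value"]).all()
        assert set(df1["population"]) == {"A_unselected", "B_selected"}

    def test_population_filter(self):
        df = run_table1_group("n_qtl", [20], reps=1, seed=4,
                              base_config=tiny_config(),
                              populations=("B_selected",))
        assert set(df["population"]) == {"B_selected"}

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown sweep group"):
            run_table1_group("mutation_rate", [1], reps=1)
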