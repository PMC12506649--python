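"""Recurrent-selection simulator: founders, architecture, cycle mechanics."""

import numpy as np
import pytest

from ordselect.ordinal import McmcSettings
from ordselect.simulate import (
    SCENARIOS,
    CycleSummary,
    Population,
    ScenarioConfig,
    build_architecture,
    category_proportions,
    phenotype_and_discretize,
    run_cycle,
    run_scenario,
    simulate_founders,
    summaries_to_frame,
    _discretize,
    _distinct_pairs,
)


def small_cfg(**kw):
    base = dict(
        scenario="E2", n_loci=60, pop_size=120, burn_in_generations=5,
        n_replicates=2, n_cycles=2, mcmc=McmcSettings(300, 100, 2),
        seed=7,
    )
    base.update(kw)
    return ScenarioConfig(**base)


def true_value_ranker(trait=0, sign=-1.0):
    """Oracle ranker: score candidates by (negated) true genetic value."""

    def _rank(y_train, X_train, X_cand, cfg, arch_holder={}):
        arch = _rank.arch
        g = (X_cand - arch.dosage_center) @ arch.effects
        return sign * g[:, trait]

    return _rank


def random_ranker(seed=0):
    rng = np.random.default_rng(seed)

    def _rank(y_train, X_train, X_cand, cfg):
        return rng.random(X_cand.shape[0])

    return _rank


class TestConfig:
    def test_scenarios_resolve(self):
        assert set(SCENARIOS) == {"E1", "E2", "E3", "E4", "E5", "E6"}
        cfg = ScenarioConfig(scenario="E4")
        assert cfg.h2 == 0.6
        assert cfg.structure[0, 1] == -0.3

    def test_invalid_scenario_and_fractions(self):
        with pytest.raises(ValueError, match="scenario"):
            ScenarioConfig(scenario="E9")
        with pytest.raises(ValueError, match="train_fraction"):
            small_cfg(train_fraction=1.0)
        with pytest.raises(ValueError, match="target"):
            small_cfg(target=((0.5, 0.5),) * 3)  # wrong category count vs default 3? len ok, validates pmf
        with pytest.raises(ValueError, match="one target"):
            small_cfg(target=((0.1, 0.2, 0.7),))

    def test_reduced_scale_defaults(self):
        cfg = ScenarioConfig.reduced_scale("E2")
        assert (cfg.n_loci, cfg.pop_size, cfg.n_replicates) == (500, 400, 3)
        assert (cfg.mcmc.n_iter, cfg.mcmc.burn_in, cfg.mcmc.thin) == (4000, 1500, 5)


class TestFounders:
    def test_no_burnin_frequencies_near_half(self):
        cfg = small_cfg(n_loci=4, pop_size=4000, burn_in_generations=0)
        pop = simulate_founders(cfg, seed=1)
        f = pop.allele_frequencies()
        assert np.all(np.abs(f - 0.5) < 0.03)  # binomial error at n=4000

    def test_drift_bounded_at_reduced_scale(self):
        cfg = small_cfg(n_loci=500, pop_size=400, burn_in_generations=100)
        pop = simulate_founders(cfg, seed=2)
        assert 0.45 < pop.allele_frequencies().mean() < 0.55

    def test_deterministic_under_seed(self):
        cfg = small_cfg()
        p1 = simulate_founders(cfg, seed=5)
        p2 = simulate_founders(cfg, seed=5)
        np.testing.assert_array_equal(p1.genotypes, p2.genotypes)

    def test_dosage_alphabet(self):
        pop = simulate_founders(small_cfg(), seed=0)
        assert set(np.unique(pop.genotypes)) <= {0, 1, 2}


class TestDistinctPairs:
    def test_never_selfed_and_uniform_support(self, rng):
        pairs = _distinct_pairs(6, 5000, rng)
        assert np.all(pairs[:, 0] != pairs[:, 1])
        counts = np.bincount(pairs.ravel(), minlength=6)
        assert counts.min() > 0.8 * counts.mean()


class TestArchitecture:
    def test_genetic_correlations_recovered(self):
        """Realised F0 genetic correlations track the requested structure
        (S1 positives and, via an override, the identity null case)."""
        cfg = small_cfg(pop_size=1200, n_loci=800)
        pop = simulate_founders(cfg, seed=13)
        arch = build_architecture(cfg, pop, seed=14)
        corr = np.corrcoef(arch.genetic_values(pop).T)
        assert abs(corr[0, 1] - 0.3) < 0.1
        assert abs(corr[0, 2] - 0.3) < 0.1
        assert abs(corr[1, 2] - 0.2) < 0.1

        import ordselect.simulate as sim

        orig = sim.CORRELATION_STRUCTURES["S1"]
        sim.CORRELATION_STRUCTURES["S1"] = np.eye(3)
        try:
            arch0 = build_architecture(cfg, pop, seed=14)
        finally:
            sim.CORRELATION_STRUCTURES["S1"] = orig
        corr0 = np.corrcoef(arch0.genetic_values(pop).T)
        off = corr0[np.triu_indices(3, k=1)]
        assert np.all(np.abs(off) < 0.1)

    def test_realized_heritability_exact_at_f0(self):
        cfg = small_cfg(pop_size=300, n_loci=200)
        pop = simulate_founders(cfg, seed=5)
        arch = build_architecture(cfg, pop, seed=6)
        g = arch.genetic_values(pop)
        h2 = g.var(axis=0) / (g.var(axis=0) + arch.env_sd**2)
        np.testing.assert_allclose(h2, cfg.h2, atol=1e-12)

    def test_f0_proportions_near_terciles(self):
        cfg = small_cfg(pop_size=2000, n_loci=300)
        pop = simulate_founders(cfg, seed=7)
        arch = build_architecture(cfg, pop, seed=8)
        props = category_proportions(arch.f0_categories, cfg.n_categories)
        assert np.all(np.abs(props - 1 / 3) < 0.02)

    def test_non_pd_structure_rejected(self):
        cfg = small_cfg()
        pop = simulate_founders(cfg, seed=0)
        bad = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        import ordselect.simulate as sim

        orig = sim.CORRELATION_STRUCTURES["S1"]
        sim.CORRELATION_STRUCTURES["S1"] = bad
        try:
            with pytest.raises(ValueError, match="positive-definite"):
                build_architecture(cfg, pop, seed=1)
        finally:
            sim.CORRELATION_STRUCTURES["S1"] = orig


class TestDiscretize:
    def test_half_open_intervals_scalar_oracle(self):
        cuts = np.array([[0.0, 1.0]])
        pheno = np.array([[-0.5], [0.0], [0.5], [1.0], [1.5]])
        cats = _discretize(pheno, cuts)
        np.testing.assert_array_equal(cats.ravel(), [1, 1, 2, 2, 3])

    def test_zero_noise_limit_deterministic(self):
        cfg = small_cfg()
        pop = simulate_founders(cfg, seed=1)
        arch = build_architecture(cfg, pop, seed=2)
        arch.env_sd = np.zeros_like(arch.env_sd)
        c1 = phenotype_and_discretize(pop, arch, seed=10)
        c2 = phenotype_and_discretize(pop, arch, seed=99)
        np.testing.assert_array_equal(c1, c2)

    def test_zero_effects_pure_noise_terciles(self):
        cfg = small_cfg(pop_size=3000, n_loci=50)
        pop = simulate_founders(cfg, seed=1)
        arch = build_architecture(cfg, pop, seed=2)
        arch.effects = np.zeros_like(arch.effects)
        arch.env_sd = np.ones_like(arch.env_sd)
        # cutpoints recomputed for the noise-only model at terciles of N(0,1)
        from scipy.stats import norm

        arch.cutpoints = np.tile(norm.ppf([1 / 3, 2 / 3]), (3, 1))
        cats = phenotype_and_discretize(pop, arch, seed=3)
        props = category_proportions(cats, 3)
        assert np.all(np.abs(props - 1 / 3) < 0.04)


class TestRunCycle:
    def test_dh_offspring_fully_homozygous(self):
        cfg = small_cfg()
        pop = simulate_founders(cfg, seed=1)
        arch = build_architecture(cfg, pop, seed=2)
        nxt, summ = run_cycle(pop, arch, cfg, seed=3, ranker=random_ranker(0))
        assert nxt.is_dh
        assert nxt.n_lines == cfg.pop_size
        assert isinstance(summ, CycleSummary)
        assert np.allclose(summ.proportions.sum(axis=1), 1.0)

    def test_positive_control_oracle_ranker(self):
        """Ranking by true genetic value of trait 1 increases its top
        category's proportion over a few cycles."""
        cfg = small_cfg(pop_size=300, n_loci=120, n_cycles=3, seed=21)
        pop = simulate_founders(cfg, seed=21)
        arch = build_architecture(cfg, pop, seed=22)
        ranker = true_value_ranker(trait=0)
        ranker.arch = arch
        p3 = []
        for c in range(3):
            cats = phenotype_and_discretize(pop, arch, seed=100 + c)
            p3.append(np.mean(cats[:, 0] == 3))
            pop, _ = run_cycle(pop, arch, cfg, seed=200 + c, ranker=ranker)
        cats = phenotype_and_discretize(pop, arch, seed=999)
        p3.append(np.mean(cats[:, 0] == 3))
        assert p3[-1] > p3[0] + 0.1  # strong, directed gain

    def test_no_selection_control_proportions_stable(self):
        """selection_fraction=1 (all candidates become parents): proportions
        unchanged across one cycle within sampling error.  Compared between
        two DH generations — the diploid-founder -> DH step itself doubles
        the genic variance and legitimately shifts mass outward."""
        cfg = small_cfg(pop_size=1500, n_loci=200, selection_fraction=1.0, seed=31)
        pop = simulate_founders(cfg, seed=31)
        arch = build_architecture(cfg, pop, seed=32)
        pop, _ = run_cycle(pop, arch, cfg, seed=9, ranker=random_ranker(0))  # to DH
        before = category_proportions(phenotype_and_discretize(pop, arch, seed=1), 3)
        nxt, _ = run_cycle(pop, arch, cfg, seed=2, ranker=random_ranker(1))
        after = category_proportions(phenotype_and_discretize(nxt, arch, seed=3), 3)
        assert np.all(np.abs(after - before) < 0.06)

    def test_deterministic_under_seed(self):
        cfg = small_cfg()
        pop = simulate_founders(cfg, seed=1)
        arch = build_architecture(cfg, pop, seed=2)
        n1, s1 = run_cycle(pop, arch, cfg, seed=3, ranker=random_ranker(5))
        n2, s2 = run_cycle(pop, arch, cfg, seed=3, ranker=random_ranker(5))
        np.testing.assert_array_equal(n1.genotypes, n2.genotypes)
        np.testing.assert_allclose(s1.proportions, s2.proportions, atol=0)

    def test_model_based_cycle_runs(self):
        """End-to-end single cycle with the real Bayesian fits (tiny chain)."""
        cfg = small_cfg(pop_size=150, n_loci=50)
        pop = simulate_founders(cfg, seed=41)
        arch = build_architecture(cfg, pop, seed=42)
        nxt, summ = run_cycle(pop, arch, cfg, loss_method="kl", seed=43)
        assert nxt.n_lines == cfg.pop_size
        assert np.isfinite(summ.mean_loss_selected)
        assert summ.mean_loss_selected >= 0


class TestRunScenario:
    def test_smoke_counts_and_schema(self):
        cfg = small_cfg(n_replicates=2, n_cycles=2)
        summaries = run_scenario(cfg, ranker=random_ranker(3))
        # cycles 0..n_cycles recorded per replicate
        assert len(summaries) == 2 * 3
        df = summaries_to_frame(summaries)
        assert set(df.columns) >= {
            "scenario", "replicate", "cycle", "method", "trait", "category", "proportion",
        }
        assert df.groupby(["replicate", "cycle", "trait"])["proportion"].sum().round(9).eq(1).all()

    def test_replicate_average_bookkeeping(self):
        cfg = small_cfg(n_replicates=2, n_cycles=1)
        df = summaries_to_frame(run_scenario(cfg, ranker=random_ranker(4)))
        sub = df[(df.cycle == 1) & (df.trait == 1) & (df.category == 3)]
        by_hand = sub["proportion"].to_numpy().mean()
        from ordselect.simulate import mean_trajectory

        m = mean_trajectory(df, category=3)
        got = m[(m.cycle == 1) & (m.trait == 1)]["proportion"].iloc[0]
        assert got == pytest.approx(by_hand, abs=1e-12)

    def test_no_selection_trend_absent_across_seeds(self):
        """No-selection control: no systematic trend in category-3 proportion
        (slope CI across seeds contains 0)."""
        slopes = []
        for seed in range(5):
            cfg = small_cfg(
                pop_size=500, n_loci=100, selection_fraction=1.0,
                n_replicates=1, n_cycles=4, seed=seed,
            )
            df = summaries_to_frame(run_scenario(cfg, ranker=random_ranker(seed)))
            sub = df[(df.category == 3)].groupby("cycle")["proportion"].mean()
            slopes.append(np.polyfit(sub.index, sub.to_numpy(), 1)[0])
        slopes = np.asarray(slopes)
        ci = slopes.mean() + np.array([-1, 1]) * 2.78 * slopes.std(ddof=1) / np.sqrt(5)
        assert ci[0] < 0 < ci[1]
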