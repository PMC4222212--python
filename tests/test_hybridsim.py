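"""Gamete-level crosses, scenario resampling and synthetic panel generation."""

import numpy as np
import pytest
from scipy import stats

import introquant as iq
from introquant.genotype_io import MISSING


class TestScenarioSpec:
    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            iq.ScenarioSpec({"F2": 1.0})

    def test_negative_proportion_rejected(self):
        with pytest.raises(ValueError):
            iq.ScenarioSpec({"H": -0.5, "pure_wild": 1.5})

    def test_renormalized_with_warning(self):
        with pytest.warns(UserWarning, match="renormalizing"):
            spec = iq.ScenarioSpec({"pure_wild": 2.0, "H": 2.0})
        assert spec.proportions == pytest.approx({"pure_wild": 0.5, "H": 0.5})


class TestScenarioExpectation:
    def test_two_generation_escapee_scenario(self):
        # proportions from a two-generation 20%-escapee projection -> 89%
        spec = iq.ScenarioSpec(
            {
                "pure_wild": 0.706, "H": 0.107, "BCW": 0.167,
                "BCF": 0.007, "2GH": 0.009, "pure_farm": 0.004,
            }
        )
        frac = iq.scenario_expected_wild_fraction(spec)
        assert frac == pytest.approx(0.891, abs=1e-12)
        assert round(100 * frac) == 89

    def test_pure_groups(self):
        assert iq.scenario_expected_wild_fraction(
            iq.ScenarioSpec({"pure_wild": 1.0})
        ) == 1.0
        assert iq.scenario_expected_wild_fraction(
            iq.ScenarioSpec({"H": 1.0})
        ) == 0.5


class TestCrossPopulations:
    def test_forced_gametes_make_heterozygotes(self, diagnostic_panel):
        wild, farm = diagnostic_panel
        off = iq.cross_populations(wild, farm, 20, pairing="random", seed=0)
        assert (off.genotypes == 1).all()

    def test_population_pairs_times_offspring(self):
        # 20 wild x 13 farm populations x 5 offspring each = 1300
        rng = np.random.default_rng(0)
        L = 5

        def group(prefix, n_pops):
            ids, pops, rows = [], [], []
            for p in range(n_pops):
                for i in range(3):
                    ids.append(f"{prefix}{p}_{i}")
                    pops.append(f"{prefix}{p}")
                    rows.append(rng.integers(0, 3, L))
            return iq.GenotypeMatrix(
                ids, pops, [f"l{j}" for j in range(L)], np.array(rows)
            )

        off = iq.cross_populations(group("w", 20), group("f", 13), 5, seed=1)
        assert off.n_individuals == 1300

    def test_gamete_from_heterozygote_is_fair_coin(self):
        L = 200
        het = iq.GenotypeMatrix(
            ["h"], ["p"], [f"l{j}" for j in range(L)], [[1] * L]
        )
        homo = iq.GenotypeMatrix(
            ["o"], ["p"], [f"l{j}" for j in range(L)], [[0] * L]
        )
        off = iq.cross_populations(het, homo, 10, pairing="random", seed=2)
        n_a = int((off.genotypes == 1).sum())  # A gametes from the het parent
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 10 * L, 0.5)
        assert lo <= n_a <= hi

    def test_missing_parent_allele_propagates(self):
        a = iq.GenotypeMatrix(["a"], ["p"], ["l1", "l2"], [[MISSING, 2]])
        b = iq.GenotypeMatrix(["b"], ["q"], ["l1", "l2"], [[2, 2]])
        off = iq.cross_populations(a, b, 5, pairing="random", seed=3)
        assert (off.genotypes[:, 0] == MISSING).all()
        assert (off.genotypes[:, 1] == 2).all()

    def test_allele_conservation(self):
        # offspring alleles must exist in the contributing parents
        a = iq.GenotypeMatrix(["a"], ["p"], ["l"], [[2]])
        b = iq.GenotypeMatrix(["b"], ["q"], ["l"], [[2]])
        off = iq.cross_populations(a, b, 10, pairing="random", seed=4)
        assert (off.genotypes == 2).all()

    def test_empty_pool_rejected(self):
        a = iq.GenotypeMatrix([], [], ["l"], np.empty((0, 1)))
        b = iq.GenotypeMatrix(["b"], ["q"], ["l"], [[1]])
        with pytest.raises(ValueError):
            iq.cross_populations(a, b, 1, seed=0)


class TestCrossGroups:
    def test_group_sizes_and_labels(self, diagnostic_panel):
        wild, farm = diagnostic_panel
        off = iq.build_cross_groups(wild, farm, n_per_group=30, seed=0)
        assert off.n_individuals == 180
        assert set(off.population_labels) == set(iq.GROUP_WILD_FRACTIONS)

    def test_pedigree_dosage_expectations_on_diagnostic_panel(
        self, diagnostic_panel
    ):
        wild, farm = diagnostic_panel
        off = iq.build_cross_groups(wild, farm, n_per_group=60, seed=1)
        for group, frac in iq.GROUP_WILD_FRACTIONS.items():
            rows = off.population_indices(group)
            g = off.genotypes[rows]
            n_copies = g.size * 2
            lo, hi = stats.binom.ppf([0.0005, 0.9995], n_copies, frac)
            assert lo <= g.sum() <= hi, group
            if group == "BCW":
                assert set(np.unique(g)) <= {1, 2}

    def test_expected_fractions_are_pedigree_constants(self):
        assert iq.GROUP_WILD_FRACTIONS == {
            "pure_wild": 1.0, "H": 0.5, "BCW": 0.75,
            "BCF": 0.25, "2GH": 0.5, "pure_farm": 0.0,
        }


class TestResampleScenario:
    def test_degenerate_pools_hit_expectation_exactly(self):
        spec = iq.ScenarioSpec(
            {"pure_wild": 0.7, "H": 0.2, "BCW": 0.1}, sample_size=30,
            n_reps=200, seed=0,
        )
        pools = {g: [iq.GROUP_WILD_FRACTIONS[g]] for g in spec.proportions}
        est = iq.resample_scenario(pools, spec, wild_ref=1.0, farm_ref=0.0)
        assert est.mean == pytest.approx(est.expected, abs=0.01)
        # each replicate is itself unbiased only on average; with pools
        # degenerate at the group expectation and exact anchors the only
        # spread left is the multinomial composition
        assert est.ci_low <= est.expected <= est.ci_high

    def test_single_group_degenerate_is_zero_width(self):
        spec = iq.ScenarioSpec({"H": 1.0}, sample_size=10, n_reps=100, seed=1)
        est = iq.resample_scenario({"H": [0.5]}, spec, 1.0, 0.0)
        assert est.ci_low == est.ci_high == est.mean == pytest.approx(0.5)

    def test_unbiased_with_noisy_pools(self):
        rng = np.random.default_rng(2)
        spec = iq.ScenarioSpec(
            {
                "pure_wild": 0.706, "H": 0.107, "BCW": 0.167,
                "BCF": 0.007, "2GH": 0.009, "pure_farm": 0.004,
            },
            sample_size=100, n_reps=1000, seed=3,
        )
        pools = {
            g: np.clip(rng.normal(f, 0.08, 30), 0, 1)
            for g, f in iq.GROUP_WILD_FRACTIONS.items()
        }
        est = iq.resample_scenario(pools, spec, wild_ref=1.0, farm_ref=0.0)
        assert abs(est.mean - est.expected) < 0.03

    def test_smaller_sample_gives_wider_interval(self):
        rng = np.random.default_rng(4)
        pools = {
            g: np.clip(rng.normal(f, 0.1, 30), 0, 1)
            for g, f in iq.GROUP_WILD_FRACTIONS.items()
        }
        props = {
            "pure_wild": 0.706, "H": 0.107, "BCW": 0.167,
            "BCF": 0.007, "2GH": 0.009, "pure_farm": 0.004,
        }
        est30 = iq.resample_scenario(
            pools, iq.ScenarioSpec(props, sample_size=30, n_reps=800, seed=5),
            1.0, 0.0,
        )
        est100 = iq.resample_scenario(
            pools, iq.ScenarioSpec(props, sample_size=100, n_reps=800, seed=5),
            1.0, 0.0,
        )
        assert (est30.ci_high - est30.ci_low) > (est100.ci_high - est100.ci_low)

    def test_missing_pool_named_in_error(self):
        spec = iq.ScenarioSpec({"H": 1.0}, seed=0)
        with pytest.raises(ValueError, match="'H'"):
            iq.resample_scenario({}, spec, 1.0, 0.0)


class TestSyntheticPanel:
    def test_zero_divergence_shares_frequencies(self):
        _, freqs = iq.simulate_reference_populations(
            iq.SyntheticPanelSpec(fst=0.0, seed=5)
        )
        np.testing.assert_array_equal(freqs["wild"], freqs["farm"])

    def test_deterministic_given_seed(self):
        a, fa = iq.simulate_reference_populations(iq.SyntheticPanelSpec(seed=9))
        b, fb = iq.simulate_reference_populations(iq.SyntheticPanelSpec(seed=9))
        assert a == b
        np.testing.assert_array_equal(fa["wild"], fb["wild"])

    def test_multiple_populations_per_group(self):
        m, _ = iq.simulate_reference_populations(
            iq.SyntheticPanelSpec(n_wild=30, n_farm=20, n_wild_pops=3,
                                  n_farm_pops=2, seed=6)
        )
        assert set(m.populations) == {
            "wild_1", "wild_2", "wild_3", "farm_1", "farm_2"
        }
        assert m.n_individuals == 50

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            iq.SyntheticPanelSpec(fst=1.0)
        with pytest.raises(ValueError):
            iq.SyntheticPanelSpec(ancestral_low=0.9, ancestral_high=0.1)


class TestSimulateAdmixed:
    def test_diagnostic_half_admixture_expected_dosage_one(self):
        L = 500
        loci = [f"l{j}" for j in range(L)]
        wf = iq.AlleleFrequencies(loci, np.ones(L), np.full(L, 100))
        ff = iq.AlleleFrequencies(loci, np.zeros(L), np.full(L, 100))
        ind = iq.simulate_admixed_individual(0.5, wf, ff, seed=0)
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 2 * L, 0.5)
        assert lo <= ind.genotypes.sum() <= hi

    def test_pure_wild_draw_matches_wild_frequencies(self, true_freqs):
        wf, ff = true_freqs
        cohort = iq.simulate_admixed_cohort(1.0, wf, ff, n=200, seed=1)
        emp = iq.allele_frequencies(cohort).freq_A
        lo = stats.binom.ppf(0.0005, 400, wf.freq_A) / 400
        hi = stats.binom.ppf(0.9995, 400, wf.freq_A) / 400
        assert ((emp >= lo) & (emp <= hi)).all()

    def test_recovery_is_unbiased_at_strong_divergence(self, strong_true_freqs):
        wf, ff = strong_true_freqs
        for q in (0.25, 0.5, 0.75):
            est = [
                iq.ml_admixture(
                    iq.simulate_admixed_individual(q, wf, ff, seed=1000 * int(q * 4) + r),
                    wf, ff,
                )
                for r in range(200)
            ]
            assert abs(np.mean(est) - q) < 0.02

    def test_invalid_q_rejected(self, true_freqs):
        with pytest.raises(ValueError):
            iq.simulate_admixed_individual(1.5, *true_freqs)


class TestEndToEnd:
    def test_bootstrap_interval_covers_known_wild_fraction(self):
        """Full pipeline on synthetic panels recovers an F1 cohort's wild
        fraction within the bootstrap CI for >= 90% of seeds (ML engine)."""
        hits = 0
        n_seeds = 10
        for s in range(n_seeds):
            panel, _ = iq.simulate_reference_populations(
                iq.SyntheticPanelSpec(seed=300 + s)
            )
            wild = panel.select_populations(["wild"])
            farm = panel.select_populations(["farm"])
            wcp = iq.synthesize_centerpoint(wild, "wild", 100, seed=2 * s)
            fcp = iq.synthesize_centerpoint(farm, "farm", 100, seed=2 * s + 1)
            est = iq.AdmixtureAssigner(mode="ml").fit(
                np.vstack([wcp.genotypes.genotypes, fcp.genotypes.genotypes]),
                ["wild"] * 100 + ["farm"] * 100,
            )
            wild_ref = est.membership(wild.genotypes[:30])[0].mean()
            farm_ref = est.membership(farm.genotypes[:30])[0].mean()
            f1 = iq.cross_populations(wild, farm, 30, pairing="random",
                                      seed=900 + s)
            p_f1 = est.membership(f1.genotypes)[0]
            ci = iq.bootstrap_ci(p_f1, wild_ref, farm_ref, n_boot=500, seed=s)
            hits += ci.ci_low <= 0.5 <= ci.ci_high
        assert hits >= 0.9 * n_seeds
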