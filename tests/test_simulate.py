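"""Synthetic-data generators: fixed-S conditioning, neutral SFS shape,
four-gamete consistency, sweep erosion, the decay oracle and cohorts."""

import numpy as np
import pytest

import hapselect as hs
from hapselect.haplotypes import (ancestral_haplotype_fraction,
                                  derived_carrier_spectrum,
                                  enumerate_haplotypes)
from hapselect.simulate import (CohortModel, DemographyModel, SweepModel,
                                haplotype_decay_forward, simulate_cohort,
                                simulate_neutral_haplotypes,
                                simulate_sweep_haplotypes)


class TestNeutralHaplotypes:
    @pytest.mark.parametrize("engine,rho", [("kingman", 0.0),
                                            ("msprime", 0.0),
                                            ("msprime", 20.0)])
    def test_deterministic_under_seed(self, engine, rho):
        a = simulate_neutral_haplotypes(20, 15, rho=rho, seed=5, engine=engine)
        b = simulate_neutral_haplotypes(20, 15, rho=rho, seed=5, engine=engine)
        np.testing.assert_array_equal(a.alleles, b.alleles)
        assert [v.position for v in a.variants] == [v.position for v in b.variants]

    @pytest.mark.parametrize("engine,rho", [("kingman", 0.0), ("msprime", 15.0)])
    def test_exactly_s_polymorphic_columns(self, engine, rho):
        for s in (1, 7, 40):
            m = simulate_neutral_haplotypes(24, s, rho=rho, seed=s, engine=engine)
            assert m.n_var == s
            counts = m.alleles.sum(axis=0)
            assert ((counts > 0) & (counts < 24)).all()

    def test_positions_strictly_increasing_within_region(self):
        m = simulate_neutral_haplotypes(10, 50, seed=2, sequence_length=10_000)
        pos = m.positions
        assert (np.diff(pos) > 0).all()
        assert pos[0] >= 1 and pos[-1] <= 10_000

    @pytest.mark.parametrize("engine", ["kingman", "msprime"])
    def test_four_gamete_rule_without_recombination(self, engine):
        """A single genealogy admits at most 3 of the 4 gametes per pair."""
        for seed in range(10):
            m = simulate_neutral_haplotypes(16, 12, rho=0.0, seed=seed,
                                            engine=engine)
            a = m.alleles
            for i in range(m.n_var):
                for j in range(i + 1, m.n_var):
                    g = {(int(x), int(y)) for x, y in zip(a[:, i], a[:, j])}
                    assert len(g) <= 3

    def test_neutral_sfs_shape(self):
        """Mean folded SFS tracks the neutral 1/i law; fixed-S conditioning
        admits only a small (percent-level) distortion."""
        n, s, reps = 20, 30, 2000
        rng = np.random.default_rng(17)
        counts = np.zeros(n + 1)
        for _ in range(reps):
            m = simulate_neutral_haplotypes(
                n, s, seed=int(rng.integers(2**31)))
            counts += np.bincount(m.alleles.sum(axis=0), minlength=n + 1)
        unfolded = counts[1:n] / counts[1:n].sum()
        q = (1 / np.arange(1, n)) / (1 / np.arange(1, n)).sum()
        folded_obs = unfolded[: n // 2 - 1] + unfolded[: n // 2 - 1 : -1]
        folded_q = q[: n // 2 - 1] + q[: n // 2 - 1 : -1]
        # fixed-S conditioning distorts class shares at the few-percent
        # level (ratio of expectations vs expectation of the per-tree
        # ratio), so compare shapes by total variation: a non-neutral
        # spectrum sits far above this bound
        tv = 0.5 * np.abs(folded_obs - folded_q).sum()
        assert tv < 0.04

    def test_engines_agree_on_sfs(self):
        """The built-in Kingman sampler and msprime produce the same
        singleton proportion within Monte-Carlo tolerance."""
        def singleton_fraction(engine, seed0):
            rng = np.random.default_rng(seed0)
            fracs = []
            for _ in range(600):
                m = simulate_neutral_haplotypes(
                    15, 20, seed=int(rng.integers(2**31)), engine=engine)
                fracs.append((m.alleles.sum(axis=0) == 1).mean())
            return float(np.mean(fracs))

        # mutations within a replicate share one genealogy, so compare at
        # replicate level with a tolerance covering that correlation
        f_k = singleton_fraction("kingman", 23)
        f_m = singleton_fraction("msprime", 24)
        assert f_k == pytest.approx(f_m, abs=0.025)

    def test_bottleneck_demography_runs(self):
        demog = DemographyModel(n1=10_000, n2=1_000, n3=20_000, t1=100, t2=1500)
        m = simulate_neutral_haplotypes(20, 10, rho=5.0, demography=demog,
                                        seed=3, engine="msprime")
        assert m.n_var == 10

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_neutral_haplotypes(2, 5, seed=0)
        with pytest.raises(ValueError):
            simulate_neutral_haplotypes(10, 0, seed=0)
        with pytest.raises(ValueError):
            DemographyModel(n1=0, n2=1, n3=1, t1=1, t2=2)


class TestSweepHaplotypes:
    def _background(self, seed=0, n=60, s=30):
        return simulate_neutral_haplotypes(n, s, seed=seed,
                                           sequence_length=100_000)

    def test_zero_age_gives_intact_founders(self):
        bg = self._background()
        sweep = SweepModel(core_position=50_000, target_freq=0.4, age=0.0,
                           r=1e-3, mu=1e-6)
        m = simulate_sweep_haplotypes(bg, sweep, seed=1)
        core = m.index_of("core")
        sp = enumerate_haplotypes(m, (0, m.n_var - 1))
        sub = derived_carrier_spectrum(sp, core)
        assert ancestral_haplotype_fraction(sub) == 1.0

    def test_core_frequency_matches_target(self):
        bg = self._background()
        sweep = SweepModel(core_position=50_000, target_freq=0.4, age=100,
                           r=1e-3, mu=1e-6)
        m = simulate_sweep_haplotypes(bg, sweep, seed=1)
        assert m.derived_allele_frequency(m.index_of("core")) == pytest.approx(0.4)

    def test_old_sweep_fully_eroded(self):
        bg = self._background(seed=5)
        sweep = SweepModel(core_position=50_000, target_freq=0.4,
                           age=20_000, r=1e-3, mu=1e-6)  # age >> 1/(r+mu)
        m = simulate_sweep_haplotypes(bg, sweep, seed=2)
        core = m.index_of("core")
        sub = derived_carrier_spectrum(
            enumerate_haplotypes(m, (0, m.n_var - 1)), core)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert ancestral_haplotype_fraction(sub) < 0.35

    def test_deterministic_under_seed(self):
        bg = self._background()
        sweep = SweepModel(core_position=50_000, target_freq=0.3, age=300,
                           r=1e-3, mu=1e-6)
        a = simulate_sweep_haplotypes(bg, sweep, seed=9)
        b = simulate_sweep_haplotypes(bg, sweep, seed=9)
        np.testing.assert_array_equal(a.alleles, b.alleles)

    def test_infeasible_frequency(self):
        bg = self._background(n=10)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_sweep_haplotypes(
                bg, SweepModel(core_position=50_000, target_freq=0.01,
                               age=10, r=1e-3, mu=1e-6), seed=0)

    def test_swept_site_shows_negative_uihs_vs_null(self):
        """Direction-of-effect: uiHS at a recently swept site (frequency
        ~0.4) is negative and beats the matched null's 95th percentile in
        at least 80% of replicates.

        The region simulated is wider than the swept block itself (600 kb
        at the same SNP density and per-bp recombination rate) so the
        derived allele's long haplotypes are not truncated at the matrix
        edge, as in a real scan with flanking markers.
        """
        from hapselect.ehh import ihs_null, unstandardized_ihs

        length, s = 600_000, 280
        r_region = 9.46e-4 * (length / 151_000)
        rho = 4 * 10_000 * r_region
        null = ihs_null(120, s + 1, rho, 0.4, n_reps=100, seed=77,
                        sequence_length=length)
        thresh = np.quantile(np.abs(null.values), 0.95)
        hits = 0
        n_reps = 20
        for seed in range(n_reps):
            bg = simulate_neutral_haplotypes(120, s, rho=rho, seed=500 + seed,
                                             sequence_length=length)
            sweep = SweepModel(core_position=length // 2, target_freq=0.4,
                               age=300, r=r_region, mu=1.66e-6)
            m = simulate_sweep_haplotypes(bg, sweep, seed=900 + seed)
            res = unstandardized_ihs(m, m.index_of("core"))
            if res.uihs < 0 and abs(res.uihs) > thresh:
                hits += 1
        assert hits >= 0.8 * n_reps


class TestDecayForward:
    def test_zero_generations(self):
        assert haplotype_decay_forward(100, 0, 1e-3, 1e-6, seed=0) == 1.0

    def test_zero_rates(self):
        assert haplotype_decay_forward(100, 1e9, 0.0, 0.0, seed=0) == 1.0

    def test_matches_exponential_decay_law(self):
        g, r, mu = 276, 9.46e-4, 1.66e-6
        expected = np.exp(-g * (r + mu))
        frac = haplotype_decay_forward(10_000, g, r, mu, seed=11)
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(frac - expected) < 3 * se

    def test_convergence_rate(self):
        """Error shrinks roughly as 1/sqrt(n)."""
        g, r, mu = 200, 1e-3, 1e-6
        expected = np.exp(-g * (r + mu))
        errs = {}
        for n in (500, 50_000):
            vals = [haplotype_decay_forward(n, g, r, mu, seed=s)
                    for s in range(20)]
            errs[n] = np.std(vals)
        assert errs[50_000] < errs[500] / 5


class TestCohortGenerator:
    def test_deterministic_under_seed(self):
        from hapselect.simulate import STUDY_COHORT

        a = simulate_cohort(STUDY_COHORT, seed=3)
        b = simulate_cohort(STUDY_COHORT, seed=3)
        assert a.data.equals(b.data)

    def test_hwe_holds_at_nominal_rate_under_null(self):
        from hapselect.association import hwe_test

        model = CohortModel(n_subjects=131, derived_freq=0.331)
        rng = np.random.default_rng(31)
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            cohort = simulate_cohort(model, seed=int(rng.integers(2**31)))
            if hwe_test(cohort.genotype_counts("rs7754840")).p < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_reps <= 0.09

    def test_truncation_keeps_hormones_non_negative(self):
        model = CohortModel(n_subjects=200, derived_freq=0.3,
                            hormones={"h": ((5.0, 5.0, 5.0), (10.0, 10.0, 10.0))})
        cohort = simulate_cohort(model, seed=1)
        vals = cohort.data["h"].dropna()
        assert (vals >= 0).all()

    def test_missingness_rate_applied(self):
        model = CohortModel(n_subjects=2000, derived_freq=0.3,
                            hormones={"h": ((10, 10, 10), (1, 1, 1))},
                            missing_rate=0.25)
        cohort = simulate_cohort(model, seed=2)
        frac = cohort.data["h"].isna().mean()
        assert frac == pytest.approx(0.25, abs=0.04)

    def test_single_subject_cohort(self):
        model = CohortModel(n_subjects=1, derived_freq=0.5,
                            hormones={"h": ((1, 1, 1), (0.1, 0.1, 0.1))})
        cohort = simulate_cohort(model, seed=4)
        assert cohort.n_subjects == 1
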