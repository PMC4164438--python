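"""EHH decay, integrated EHH, uiHS and the simulation-based significance."""

import numpy as np
import pytest

from hapselect.ehh import (EHHPoint, EHHProfile, IHSUndetermined, ehh_at,
                           ehh_profile, ihs_null, ihs_significance,
                           integrated_ehh, unstandardized_ihs)
from hapselect.io import RecombinationMap


def brute_force_ehh(alleles, core, code, target):
    """All-pairs identity counting straight from the definition."""
    lo, hi = min(core, target), max(core, target)
    rows = [tuple(r[lo:hi + 1]) for r in alleles
            if r[core] == code and all(x != -1 for x in r[lo:hi + 1])]
    c = len(rows)
    pairs = sum(1 for i in range(c) for j in range(i + 1, c)
                if rows[i] == rows[j])
    return pairs / (c * (c - 1) / 2)


class TestEhhAt:
    def test_core_is_one(self, build_matrix):
        m = build_matrix(["0101", "0110", "0011"])
        assert ehh_at(m, 1, "derived", 1) == 1.0

    def test_all_distinct_is_zero(self, build_matrix):
        m = build_matrix(["100", "110", "101", "111"])
        assert ehh_at(m, 0, "derived", 2) == 0.0

    def test_partition_counting_oracle(self, build_matrix):
        # 6 derived carriers partitioned 3/2/1 over the interval
        rows = ["100"] * 3 + ["110"] * 2 + ["111"] + ["000"] * 2
        m = build_matrix(rows)
        assert ehh_at(m, 0, "derived", 2) == pytest.approx(4 / 15)

    def test_too_few_carriers(self, build_matrix):
        m = build_matrix(["100", "000", "000"])
        with pytest.raises(ValueError, match="fewer than 2"):
            ehh_at(m, 0, "derived", 2)

    def test_matches_bruteforce_on_random_matrices(self, build_matrix):
        rng = np.random.default_rng(3)
        for _ in range(40):
            n, w = rng.integers(4, 16), rng.integers(3, 12)
            arr = (rng.random((n, w)) < rng.uniform(0.3, 0.7)).astype(np.int8)
            m = build_matrix(["".join(map(str, r)) for r in arr])
            core = int(rng.integers(w))
            for code in (0, 1):
                if (arr[:, core] == code).sum() < 2:
                    continue
                target = int(rng.integers(w))
                assert ehh_at(m, core, code, target) == brute_force_ehh(
                    arr, core, code, target)


class TestEhhProfile:
    def test_identical_haplotypes_constant_one(self, build_matrix):
        m = build_matrix(["0110"] * 5)
        prof = ehh_profile(m, 1, "derived")
        assert [p.ehh for p in prof.points] == [1.0] * 4
        assert [p.index for p in prof.points] == [0, 1, 2, 3]

    def test_degenerate_threshold_keeps_core_only(self, build_matrix):
        m = build_matrix(["110", "101", "111", "100"])
        prof = ehh_profile(m, 0, "derived", threshold=1.0 + 1e-12)
        assert [p.index for p in prof.points] == [0]

    def test_profile_equals_pointwise_ehh(self, build_matrix):
        rng = np.random.default_rng(21)
        arr = (rng.random((12, 9)) < 0.5).astype(np.int8)
        arr[:, 4] = rng.permutation([1] * 6 + [0] * 6)
        m = build_matrix(["".join(map(str, r)) for r in arr])
        for allele in (0, 1):
            prof = ehh_profile(m, 4, allele, threshold=0.0)
            for p in prof.points:
                assert p.ehh == ehh_at(m, 4, allele, p.index)

    def test_monotone_non_increasing_outward(self, build_matrix):
        import hapselect as hs

        for seed in range(5):
            m = hs.simulate_neutral_haplotypes(40, 25, seed=seed)
            core = 12
            for allele in (0, 1):
                if (m.alleles[:, core] == allele).sum() < 2:
                    continue
                prof = ehh_profile(m, core, allele, threshold=0.0)
                left = [p.ehh for p in prof.side("left")]
                right = [p.ehh for p in prof.side("right")]
                assert all(np.diff(left) >= -1e-12)        # increasing toward core
                assert all(np.diff(right) <= 1e-12)        # decreasing away

    def test_missing_fallback_matches_ehh_at(self, build_matrix):
        m = build_matrix(["11010", "110.0", "01101", "01100", "11011"])
        prof = ehh_profile(m, 2, "derived", threshold=0.0)
        for p in prof.points:
            assert p.ehh == ehh_at(m, 2, 1, p.index)

    def test_genetic_distances_attached(self, build_matrix):
        rmap = RecombinationMap([1000, 5000], [1, 1], [0.0, 0.004])
        m = build_matrix(["11"] * 4, positions=[1000, 5000])
        prof = ehh_profile(m, 0, "derived", rmap=rmap)
        assert prof.points[-1].distance_cm == pytest.approx(0.004)


class TestIntegratedEhh:
    def _profile(self, pts):
        points = [EHHPoint(index=i, position=1000 + 100 * i, ehh=e,
                           distance_cm=d) for i, (d, e) in enumerate(pts)]
        core = min(range(len(pts)), key=lambda i: pts[i][0])
        return EHHProfile(core=core, allele="derived", points=points,
                          n_carriers=10)

    def test_rectangle(self):
        # constant EHH=1 over 0.05 cM on each side -> area 0.1 cM
        prof = EHHProfile(core=1, allele="derived", n_carriers=10, points=[
            EHHPoint(0, 900, 1.0, 0.05), EHHPoint(1, 1000, 1.0, 0.0),
            EHHPoint(2, 1100, 1.0, 0.05)])
        assert integrated_ehh(prof) == pytest.approx(0.1)

    def test_triangle_one_side(self):
        prof = EHHProfile(core=0, allele="derived", n_carriers=10, points=[
            EHHPoint(0, 1000, 1.0, 0.0), EHHPoint(1, 1100, 0.0, 0.1)])
        assert integrated_ehh(prof) == pytest.approx(0.05)

    def test_uneven_trapezoid_oracle(self):
        d = [0.0, 0.01, 0.03, 0.07, 0.08]
        e = [1.0, 0.8, 0.5, 0.2, 0.1]
        prof = EHHProfile(core=0, allele="derived", n_carriers=10, points=[
            EHHPoint(i, 1000 + i, ee, dd) for i, (dd, ee) in enumerate(zip(d, e))])
        expected = sum((e[i] + e[i + 1]) / 2 * (d[i + 1] - d[i])
                       for i in range(4))
        assert integrated_ehh(prof) == pytest.approx(expected)

    def test_single_point_profile_rejected(self):
        prof = EHHProfile(core=0, allele="derived", n_carriers=10,
                          points=[EHHPoint(0, 1000, 1.0, 0.0)])
        with pytest.raises(ValueError, match="at least two points"):
            integrated_ehh(prof)

    def test_physical_distance_fallback(self, build_matrix):
        m = build_matrix(["111", "111", "000", "000"])
        prof = ehh_profile(m, 1, "derived")
        # EHH constant 1 over 1000 bp each side
        assert integrated_ehh(prof) == pytest.approx(2000.0)


class TestUnstandardizedIhs:
    def test_mirror_decay_is_zero(self, build_matrix):
        rows = ["111", "111", "000", "000"]
        m = build_matrix(rows)
        res = unstandardized_ihs(m, 1)
        assert res.uihs == pytest.approx(0.0)
        assert res.ihh_ancestral == res.ihh_derived

    def test_swept_derived_is_negative(self, build_matrix):
        # derived carriers identical across the region; ancestral diverse
        m = build_matrix(["11111"] * 6 + ["00000", "01000", "00001", "10000"])
        res = unstandardized_ihs(m, 2)
        assert res.uihs < 0

    def test_undetermined_when_side_degenerate(self, build_matrix):
        # ancestral carriers all distinct immediately: zero area
        m = build_matrix(["100", "010", "001", "111", "111", "110"])
        with pytest.raises(IHSUndetermined):
            unstandardized_ihs(m, 1, threshold=0.5)


class TestIhsNullAndSignificance:
    def test_null_deterministic_under_seed(self):
        a = ihs_null(20, 12, 0.0, 0.5, n_reps=100, seed=42)
        b = ihs_null(20, 12, 0.0, 0.5, n_reps=100, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_null_center_reflects_derived_allele_age(self):
        """Unstandardized iHS is not zero-mean under neutrality: at a given
        frequency the derived allele is younger and its carriers form a
        clade, so iHH_derived exceeds iHH_ancestral on average and the
        null mean is modestly negative. (This frequency-dependent shift is
        why genome scans standardize iHS; the empirical-null comparison
        used here absorbs it instead.)"""
        null = ihs_null(30, 20, 0.0, 0.5, n_reps=300, seed=9)
        mean = null.values.mean()
        assert -1.0 < mean < 0.0

    def test_observed_at_median_not_significant(self):
        null = ihs_null(20, 12, 0.0, 0.5, n_reps=100, seed=3)
        p, sig = ihs_significance(float(np.median(null.values)), null)
        assert p > 0.4 and not sig

    def test_counting_oracle(self):
        null = np.array([0.1] * 18 + [2.0])
        p, sig = ihs_significance(1.5, null)
        assert p == pytest.approx(2 / 20)
        assert not sig

    def test_extreme_observation(self):
        null = np.linspace(-1, 1, 999)
        p, sig = ihs_significance(5.0, null)
        assert p == pytest.approx(1 / 1000)
        assert sig

    def test_zero_observation_p_one(self):
        null = np.linspace(-1, 1, 99)
        p, _ = ihs_significance(0.0, null)
        assert p == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            ihs_significance(1.0, np.array([]))

    def test_min_reps_enforced(self):
        with pytest.raises(ValueError, match="at least 100"):
            ihs_null(20, 12, 0.0, 0.5, n_reps=10, seed=1)
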