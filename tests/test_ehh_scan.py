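"""EHH-family statistics against worked examples and enumeration oracles."""

import numpy as np
import pytest
from scipy.stats import norm

import sweepscan as sw
from sweepscan.ehh_scan import (Arm, EHHProfile, ehh_profile, ies_profile,
                                ihs_raw, integrate_profile, nsl_raw, rsb_raw,
                                scores_to_p, standardize, xpehh_raw, _sl_mean)
from conftest import (ehh_oracle, ehhs_oracle, make_matrix, nsl_tract_oracle,
                      random_matrix)


def _profile_values(m, core, allele):
    p = ehh_profile(m, core, allele)
    return p


class TestEHHProfile:
    def test_identical_carriers_full_homozygosity(self):
        a = np.zeros((8, 5), dtype=np.int8)
        a[:4, 2] = 1  # 4 derived carriers, identical elsewhere
        m = make_matrix(a)
        p = ehh_profile(m, 2, "derived")
        assert np.all(p.left.values == 1.0)
        assert np.all(p.right.values == 1.0)

    def test_split_into_two_pairs_gives_one_third(self):
        a = np.zeros((8, 3), dtype=np.int8)
        a[:4, 1] = 1  # core, 4 carriers
        a[0:2, 2] = 1  # split (2,2) at first right flank
        m = make_matrix(a)
        p = ehh_profile(m, 1, "derived")
        assert p.right.values[1] == pytest.approx(1 / 3)

    def test_all_distinct_gives_zero(self):
        # 4 carriers pairwise distinct after two right flanks
        m = make_matrix(np.array([
            [1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]], dtype=np.int8))
        p = ehh_profile(m, 0, "derived")
        assert p.right.values[-1] == 0.0

    def test_fewer_than_two_carriers_raises(self):
        a = np.zeros((4, 3), dtype=np.int8)
        a[0, 1] = 1
        with pytest.raises(ValueError, match="fewer than 2"):
            ehh_profile(make_matrix(a), 1, "derived")

    def test_monotone_nonincreasing_in_unit_interval(self):
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 40:
            m = random_matrix(rng, miss_p=0.05)
            core = int(rng.integers(0, m.n_sites))
            for allele in ("ancestral", "derived"):
                try:
                    p = ehh_profile(m, core, allele)
                except ValueError:
                    continue
                for arm in (p.left, p.right):
                    assert arm.values[0] == 1.0
                    assert np.all(np.diff(arm.values) <= 1e-12)
                    assert np.all((arm.values >= 0) & (arm.values <= 1))
                checked += 1


class TestIntegrateProfile:
    def _profile(self, offsets, values):
        arm = Arm(np.asarray(offsets, float), np.arange(len(values)),
                  np.asarray(values, float), reached_edge=False)
        empty = Arm(np.array([0.0]), np.array([0]), np.array([1.0]), False)
        return EHHProfile(0, "derived", empty, arm, 4)

    def test_linear_decay_cutoff_zero(self):
        p = self._profile([0, 1000, 2000], [1, 0.5, 0])
        area, truncated = integrate_profile(p, cutoff=0.0)
        assert area == pytest.approx(1000.0)  # 750 + 250
        assert not truncated

    def test_constant_one_rectangle(self):
        p = self._profile([0, 2500, 5000], [1, 1, 1])
        p.right.reached_edge = True
        area, truncated = integrate_profile(p, cutoff=0.05)
        assert area == pytest.approx(5000.0)
        assert truncated

    def test_interpolated_crossing(self):
        p = self._profile([0, 1000], [1, 0.04])
        area, _ = integrate_profile(p, cutoff=0.05)
        x_cross = (1 - 0.05) / (1 - 0.04) * 1000
        assert area == pytest.approx((1 + 0.05) / 2 * x_cross)


class TestRawStatistics:
    def _mirror_matrix(self):
        # derived and ancestral carrier sets with identical structure
        a = np.array([
            [0, 1, 0, 0], [0, 1, 1, 0], [1, 0, 0, 1], [1, 0, 1, 1]],
            dtype=np.int8)[:, [0, 1, 2]]
        a = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 1]],
                     dtype=np.int8)
        # build explicitly: 2 ancestral, 2 derived at core col 1, mirrored flanks
        a = np.array([
            [0, 0, 0],
            [1, 0, 1],
            [0, 1, 0],
            [1, 1, 1],
        ], dtype=np.int8)
        return make_matrix(a)

    def test_symmetric_configuration_zero(self):
        m = self._mirror_matrix()
        assert ihs_raw(m, 1, cutoff=0.0) == pytest.approx(0.0)
        assert nsl_raw(m, 1) == pytest.approx(0.0)

    def test_polarity_swap_antisymmetry(self):
        rng = np.random.default_rng(31)
        checked = 0
        while checked < 25:
            m = random_matrix(rng, n_hap=10, n_sites=12)
            core = int(rng.integers(1, m.n_sites - 1))
            r = ihs_raw(m, core, cutoff=0.0)
            rn = nsl_raw(m, core)
            flipped = make_matrix((1 - m.alleles).astype(np.int8),
                                  positions=m.positions)
            if np.isfinite(r):
                assert ihs_raw(flipped, core, cutoff=0.0) == pytest.approx(-r)
                checked += 1
            if np.isfinite(rn):
                assert nsl_raw(flipped, core) == pytest.approx(-rn)

    def test_population_swap_antisymmetry_and_identity(self):
        rng = np.random.default_rng(37)
        checked = 0
        while checked < 15:
            m1 = random_matrix(rng, n_hap=8, n_sites=10)
            m2 = random_matrix(rng, n_hap=8, n_sites=10)
            m2 = make_matrix(m2.alleles, positions=m1.positions)
            core = int(rng.integers(1, 9))
            for fn in (xpehh_raw, rsb_raw):
                assert fn(m1, m1, core) == pytest.approx(0.0) or \
                    np.isnan(fn(m1, m1, core))
                v = fn(m1, m2, core)
                if np.isfinite(v):
                    assert fn(m2, m1, core) == pytest.approx(-v)
                    checked += 1


class TestOracleEquivalence:
    """Group-refinement engine vs exhaustive pair enumeration, exactly."""

    def test_ehh_and_ehhs_and_nsl_match_enumeration(self):
        rng = np.random.default_rng(1234)
        n_checked = 0
        while n_checked < 60:
            m = random_matrix(rng, n_hap=int(rng.integers(2, 7)) * 2,
                              n_sites=int(rng.integers(4, 16)),
                              miss_p=float(rng.choice([0.0, 0.1])))
            core = int(rng.integers(0, m.n_sites))
            for allele, code in (("ancestral", 0), ("derived", 1)):
                try:
                    p = ehh_profile(m, core, allele)
                except ValueError:
                    continue
                for arm, step in ((p.left, -1), (p.right, +1)):
                    for k in range(1, len(arm.values)):
                        j = core + step * k
                        assert arm.values[k] == pytest.approx(
                            ehh_oracle(m, core, code, j), abs=1e-12)
                assert _sl_mean(m, core, code) == pytest.approx(
                    nsl_tract_oracle(m, core, code), abs=1e-12)
            for norm_mode in ("sabeti", "tang"):
                try:
                    ps = ies_profile(m, core, norm_mode)
                except ValueError:
                    continue
                for arm, step in ((ps.left, -1), (ps.right, +1)):
                    for k in range(1, len(arm.values)):
                        j = core + step * k
                        assert arm.values[k] == pytest.approx(
                            ehhs_oracle(m, core, j, norm_mode), abs=1e-12)
            n_checked += 1


class TestStandardize:
    def test_single_bin_two_values(self):
        z = standardize(np.array([-1.0, 1.0]), np.array([0.5, 0.5]),
                        mode="binned", min_bin_size=1)
        np.testing.assert_allclose(z, [-0.70710678, 0.70710678])

    def test_degenerate_bin_raises(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            standardize(np.array([2.0, 2.0, 2.0]), np.array([0.5] * 3),
                        mode="binned", min_bin_size=1)

    def test_two_bins_each_centered(self):
        raw = np.array([1.0, 2.0, 3.0, 11.0, 12.0, 13.0])
        freq = np.array([0.1] * 3 + [0.9] * 3)
        z = standardize(raw, freq, mode="binned", min_bin_size=2)
        assert z[:3].mean() == pytest.approx(0.0, abs=1e-12)
        assert z[3:].mean() == pytest.approx(0.0, abs=1e-12)

    def test_small_bins_merge_with_neighbor(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(size=30)
        freq = np.concatenate([np.full(5, 0.02), np.full(25, 0.52)])
        z = standardize(raw, freq, mode="binned", min_bin_size=20)
        assert np.isfinite(z).all()

    def test_global_mode(self):
        rng = np.random.default_rng(3)
        raw = rng.normal(2.0, 3.0, size=100)
        z = standardize(raw, mode="global")
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestScoresToP:
    @pytest.mark.parametrize("z, sided, expect", [
        (0.0, "two", 1.0),
        (1.959964, "two", 0.05),
        (-2.5, "one", float(norm.cdf(2.5))),
    ])
    def test_tail_values(self, z, sided, expect):
        assert scores_to_p(np.array([z]), sided)[0] == pytest.approx(
            expect, abs=1e-4)


class TestSweepPower:
    def test_ongoing_hard_sweep_shifts_ihs(self):
        """A planted ongoing hard sweep (derived freq 0.2-0.3, s=0.05,
        N=500) drives z_iHS at the swept site negative — long derived
        haplotypes — in far more replicates than the neutral half, and
        |z| there above the typical neutral site.

        Per replicate, standardization is frequency-binned over the pooled
        raw scores of neutral background panels plus the sweep panel,
        mirroring a genome-wide scan where the bulk of sites is neutral.
        Panels use a deep burn-in so neutral standing alleles carry
        equilibrated ages.
        """
        from sweepscan.ehh_scan import ihs_raw, standardize

        L, burnin, n_hap = 300_000, 2000, 100

        def raw_table(params):
            m, truth = sw.simulate_panel(params, burnin=burnin)
            daf = m.derived_frequency()
            keep = np.minimum(daf, 1 - daf) >= 0.05
            raws = np.array([ihs_raw(m, i) if keep[i] else np.nan
                             for i in range(m.n_sites)])
            return m.positions, raws, daf, truth

        neutral_raw, neutral_daf = [], []
        for seed in range(6):
            p = sw.ScenarioParams(kind="neutral", s=0, e=0, f=0, tau=0,
                                  seed=7000 + seed, L=L, n_hap=n_hap)
            _, raws, daf, _ = raw_table(p)
            neutral_raw.append(raws)
            neutral_daf.append(daf)

        rng = np.random.default_rng(555)
        z_focal = []
        z_neutral = None
        for seed in range(20):
            f = float(rng.uniform(0.2, 0.3))
            p = sw.ScenarioParams(kind="hard", s=0.05, e=0.0, f=f, tau=0.0,
                                  seed=7100 + seed, L=L, n_hap=n_hap)
            positions, raws, daf, truth = raw_table(p)
            pooled_raw = np.concatenate(neutral_raw + [raws])
            pooled_daf = np.concatenate(neutral_daf + [daf])
            z = standardize(pooled_raw, pooled_daf, mode="binned")
            if z_neutral is None:
                z_neutral = z[:-len(raws)]
                z_neutral = z_neutral[np.isfinite(z_neutral)]
            idx = np.flatnonzero(positions == truth.focal_position)
            if idx.size:
                v = z[len(pooled_raw) - len(raws) + idx[0]]
                if np.isfinite(v):
                    z_focal.append(float(v))
        z_focal = np.asarray(z_focal)
        assert len(z_focal) >= 16
        # sign consistency: >= 15 of 20 negative rejects symmetry at 2%
        assert (z_focal < 0).sum() >= 15
        assert np.median(np.abs(z_focal)) > np.median(np.abs(z_neutral))
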