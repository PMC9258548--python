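"""Forward Wright–Fisher generator: priors, determinism and population
genetics sanity checks."""

import json

import numpy as np
import pytest

import sweepscan as sw
from sweepscan.haplo_io import MISSING
from sweepscan.synthetic_sim import (CohortConfig, PlantedSweep,
                                     ScenarioParams, build_cohort_fixture,
                                     design_grid, design_total_simulations,
                                     draw_scenario, simulate_panel)


class TestDrawScenario:
    def test_hard_always_e_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            assert draw_scenario("hard", rng).e == 0.0

    def test_soft_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(2000):
            p = draw_scenario("soft", rng)
            assert 0 <= p.e <= 0.2
            assert p.e <= p.f <= 1
            assert 0 <= p.s <= 1
            assert 0 <= p.tau <= 0.005

    def test_seed_determinism(self):
        p1 = draw_scenario("soft", np.random.default_rng(7), seed=3)
        p2 = draw_scenario("soft", np.random.default_rng(7), seed=3)
        assert p1 == p2

    def test_invalid_kind(self):
        with pytest.raises(ValueError, match="kind"):
            draw_scenario("wrong", np.random.default_rng(0))

    def test_hard_with_nonzero_e_rejected(self):
        with pytest.raises(ValueError, match="e = 0"):
            ScenarioParams(kind="hard", s=0.5, e=0.1, f=0.5, tau=0.0)


class TestSimulatePanel:
    def test_strong_hard_sweep_fixes_focal(self):
        p = ScenarioParams(kind="hard", s=0.9, e=0, f=1.0, tau=0.0, seed=21)
        m, truth = simulate_panel(p)
        assert truth.sample_focal_freq == 1.0
        assert not truth.focal_in_matrix  # fixed alleles do not segregate

    def test_neutral_focal_frequency_martingale(self):
        """With s = 0 the focal allele drifts: mean sampled frequency over
        many seeds stays within 3 standard errors of the realized starting
        frequency."""
        diffs = []
        for seed in range(200):
            p = ScenarioParams(kind="soft", s=0.0, e=0.15, f=0.15,
                               tau=0.005, seed=3000 + seed, L=20_000,
                               n_hap=40)
            _, truth = simulate_panel(p)
            diffs.append(truth.sample_focal_freq - truth.realized_e)
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se + 1e-9

    def test_matrix_invariants_and_truth(self):
        p = ScenarioParams(kind="soft", s=0.6, e=0.1, f=0.8, tau=0.001,
                           seed=5)
        m, truth = simulate_panel(p)
        assert np.all(np.diff(m.positions) > 0)
        assert set(np.unique(m.alleles)) <= {0, 1}
        freqs = m.derived_frequency()
        assert np.all((freqs > 0) & (freqs < 1))  # only segregating sites
        if truth.focal_in_matrix:
            i = np.flatnonzero(m.positions == truth.focal_position)[0]
            assert freqs[i] == pytest.approx(truth.sample_focal_freq)

    def test_neutral_diversity_matches_theta(self):
        """Median pairwise diversity over 20 seeds within 20% of 4N·mu."""
        pis = []
        for seed in range(20):
            p = ScenarioParams(kind="neutral", s=0, e=0, f=0, tau=0,
                               seed=400 + seed)
            m, _ = simulate_panel(p)
            f = m.derived_frequency()
            n = m.n_hap
            pi = float((2 * f * (1 - f) * n / (n - 1)).sum()) / p.L
            pis.append(pi)
        theta = 4 * p.N * p.mu
        assert abs(np.median(pis) - theta) / theta < 0.20

    def test_neutral_diversity_against_coalescent_oracle(self):
        """Sampled segregating-site counts are consistent with an msprime
        neutral coalescent at the same theta (independent oracle)."""
        msprime = pytest.importorskip("msprime")
        p = ScenarioParams(kind="neutral", s=0, e=0, f=0, tau=0)
        s_forward = []
        for seed in range(12):
            m, _ = simulate_panel(ScenarioParams(kind="neutral", s=0, e=0,
                                                 f=0, tau=0, seed=500 + seed))
            s_forward.append(m.n_sites)
        s_coal = []
        for seed in range(12):
            ts = msprime.sim_ancestry(
                samples=p.n_hap // 2, population_size=p.N,
                sequence_length=p.L, recombination_rate=p.r,
                random_seed=seed + 1)
            mts = msprime.sim_mutations(ts, rate=p.mu, random_seed=seed + 1,
                                        model=msprime.BinaryMutationModel())
            s_coal.append(mts.num_sites)
        # medians agree within 25% (both ~ Watterson's expectation)
        med_f, med_c = np.median(s_forward), np.median(s_coal)
        assert abs(med_f - med_c) / med_c < 0.25

    def test_hard_sweep_raises_h12_over_neutral(self):
        """Completed hard sweeps (s >= 0.5, f = 1) leave higher window H12
        than neutral panels, 50 seeds each."""
        from sweepscan.sweep_classify import h_statistics, window_spectrum

        def h12(m, center_pos):
            c = int(np.argmin(np.abs(m.positions - center_pos)))
            return h_statistics(window_spectrum(m, c, 201)[0]).h12

        rng = np.random.default_rng(9)
        hard, neut = [], []
        for seed in range(50):
            s = float(rng.uniform(0.5, 1.0))
            ph = ScenarioParams(kind="hard", s=s, e=0, f=1.0,
                                tau=float(rng.uniform(0, 0.005)),
                                seed=6000 + seed)
            mh, th = simulate_panel(ph)
            hard.append(h12(mh, ph.L // 2))
            pn = ScenarioParams(kind="neutral", s=0, e=0, f=0, tau=0,
                                seed=6500 + seed)
            mn, _ = simulate_panel(pn)
            neut.append(h12(mn, pn.L // 2))
        assert np.median(hard) > np.median(neut)

    def test_soft_h2h1_stochastically_dominates_hard(
            self, hard_training_points, soft_training_points):
        """Soft-sweep H2/H1 stochastically dominates hard-sweep H2/H1
        (Mann-Whitney, s >= 0.1 draws)."""
        from scipy.stats import mannwhitneyu

        res = mannwhitneyu(soft_training_points[:200, 1],
                           hard_training_points[:200, 1],
                           alternative="greater")
        assert res.pvalue < 0.01


@pytest.fixture(scope="module")
def small_cfg():
    return CohortConfig(wild_samples=12, cultivated={"EastAsian": 12},
                        planted={"EastAsian": PlantedSweep(s=0.5)},
                        L=60_000, seed=77)


class TestCohortFixture:
    def test_files_parse_through_every_reader(self, small_cfg, tmp_path):
        import sweepscan.ancestral as anc
        import sweepscan.genome_annotate as ga
        import sweepscan.haplo_io as hio

        fx = build_cohort_fixture(small_cfg, outdir=tmp_path)
        mats = hio.read_haplotypes(fx.paths["vcf"], fx.paths["populations"])
        m = mats["chr1"]
        assert m.n_hap == 48
        np.testing.assert_array_equal(m.alleles, fx.vcf_matrix.alleles)
        states = anc.read_state_table(fx.paths["states"])
        assert len(states) == m.n_sites
        genes = ga.load_gene_models(fx.paths["gff"])
        assert len(genes) == 3
        truth = json.load(open(fx.paths["truth"]))
        assert "EastAsian" in truth["planted"]

    def test_polarization_recovers_truth_coding(self, small_cfg):
        """Inferring ancestral states from the emitted outgroup table and
        polarizing recovers the generator's ancestral/derived coding at
        almost all resolvable sites."""
        import pandas as pd

        import sweepscan.ancestral as anc

        fx = build_cohort_fixture(small_cfg)
        ra = pd.DataFrame({
            "chrom": "chr1", "pos": fx.vcf_matrix.positions,
            "ref": [fx.ref_alt[("chr1", int(p))][0]
                    for p in fx.vcf_matrix.positions],
            "alt": [fx.ref_alt[("chr1", int(p))][1]
                    for p in fx.vcf_matrix.positions]})
        table = anc.infer_ancestral_table(ra, fx.states)
        calls = [anc.AncestralState(s) for s in table["ancestral_state"]]
        pol = anc.polarize(fx.vcf_matrix, calls)
        known = pol.known
        assert known.mean() > 0.8  # most sites resolvable
        agree = (pol.matrix.alleles[:, known] == fx.matrix.alleles[:, known])
        miss = fx.vcf_matrix.alleles[:, known] == MISSING
        assert agree[~miss].mean() > 0.95

    def test_no_missingness_config_passes_qc_untouched(self):
        from sweepscan.haplo_io import qc_filter

        cfg = CohortConfig(wild_samples=10, cultivated={"EastAsian": 10},
                           planted={}, missingness=0.0, L=40_000, seed=3)
        fx = build_cohort_fixture(cfg)
        out, report = qc_filter(fx.vcf_matrix, drop_singletons=False)
        assert report.n_individuals_removed == 0
        assert report.n_sites_missingness == 0
        assert out.n_sites == fx.vcf_matrix.n_sites

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = CohortConfig(wild_samples=8, cultivated={"EastAsian": 8},
                           planted={"EastAsian": PlantedSweep()},
                           L=40_000, seed=55)
        a = build_cohort_fixture(cfg, outdir=tmp_path / "a")
        b = build_cohort_fixture(cfg, outdir=tmp_path / "b")
        for key in a.paths:
            assert (open(a.paths[key], "rb").read()
                    == open(b.paths[key], "rb").read()), key


class TestDesignGrid:
    def test_grid_structure(self):
        grid = design_grid()
        assert len(grid) == 6  # 3 cultivated populations x {hard, soft}
        assert all(n == 100_000 for _, _, n in grid)

    def test_total(self):
        assert design_total_simulations() == 600_000
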