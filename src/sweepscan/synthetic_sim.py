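"""Forward Wright–Fisher simulation of neutral and sweep-bearing panels.

The generator stands in for a resequencing cohort: it produces phased diploid
haplotype panels with mutation, recombination and drift, plants hard or soft
selective sweeps under the scenario priors of the analysis (selection
coefficient s ~ U[0,1]; time since selection ended tau ~ U[0, 0.005] in units
of 4N generations; soft sweeps start from a standing neutral variant at
frequency e ~ U[0, 0.2], hard sweeps from a de-novo mutation, e = 0; the
sweep runs until the beneficial allele reaches f ~ U[e, 1]), and can emit a
complete multi-population cohort — phased VCF, sample→population table,
outgroup allele-state table, toy gene models and a ground-truth manifest —
whose wild/cultivated split mimics a domestication design.

Populations are diploid of constant size N (an optional founder bottleneck is
available for cohort populations).  A panel starts at the neutral
mutation–drift equilibrium frequency spectrum (sites initially in linkage
equilibrium) and burns in for ``burnin`` further generations of full forward
simulation to build linkage before any sweep is planted; see docs/methods.md
for what this emulates and what it does not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .haplo_io import MISSING, HaplotypeMatrix, write_vcf

# Scenario grid of the full study design this generator emulates: one hard
# and one soft sweep scenario per cultivated population, at the full
# replicate count.  Desk-scale runs use DEFAULT_REPLICATES instead.
DESIGN_CULTIVATED_POPULATIONS = ("EastAsian", "Eurasian", "Xishuangbanna")
DESIGN_SCENARIO_KINDS = ("hard", "soft")
DESIGN_REPLICATES_PER_SCENARIO = 100_000
DEFAULT_REPLICATES = 1_000

DEFAULT_N = 500
DEFAULT_L = 50_000
DEFAULT_MU = 1e-7
DEFAULT_N_HAP = 60
_BASES = np.array(["A", "C", "G", "T"])


def design_grid(populations=DESIGN_CULTIVATED_POPULATIONS,
                kinds=DESIGN_SCENARIO_KINDS,
                replicates_per_scenario=DESIGN_REPLICATES_PER_SCENARIO):
    """Enumerate the full simulation design: one entry per scenario.

    Returns a list of (population, kind, n_replicates); the grid total is
    the number of simulated datasets the design prescribes.
    """
    return [(p, k, replicates_per_scenario) for p in populations for k in kinds]


def design_total_simulations(**kwargs) -> int:
    return sum(n for _, _, n in design_grid(**kwargs))


@dataclass(frozen=True)
class ScenarioParams:
    """One sweep-simulation draw."""

    kind: str  # "hard" | "soft" | "neutral"
    s: float
    e: float
    f: float
    tau: float  # in units of 4N generations
    mu: float = DEFAULT_MU
    r: float = DEFAULT_MU
    N: int = DEFAULT_N
    L: int = DEFAULT_L
    n_hap: int = DEFAULT_N_HAP
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("hard", "soft", "neutral"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "hard" and self.e != 0:
            raise ValueError("hard sweeps require e = 0")
        if not (0 <= self.e <= self.f <= 1):
            raise ValueError("require 0 <= e <= f <= 1")
        if not (0 <= self.s <= 1 and 0 <= self.tau):
            raise ValueError("require s in [0,1] and tau >= 0")


def draw_scenario(kind: str, rng: np.random.Generator,
                  s_range=(0.0, 1.0), e_range=(0.0, 0.2),
                  tau_range=(0.0, 0.005), seed: int | None = None,
                  **fixed) -> ScenarioParams:
    """Draw scenario parameters from the study priors.

    s ~ U[s_range]; tau ~ U[tau_range]; e = 0 (hard) or ~ U[e_range] (soft);
    f ~ U[e, 1].  ``fixed`` overrides structural fields (N, L, mu, r, n_hap).
    """
    if kind == "neutral":
        return ScenarioParams(kind="neutral", s=0.0, e=0.0, f=0.0, tau=0.0,
                              seed=seed if seed is not None else 0, **fixed)
    s = rng.uniform(*s_range)
    tau = rng.uniform(*tau_range)
    e = 0.0 if kind == "hard" else rng.uniform(*e_range)
    f = rng.uniform(e, 1.0)
    return ScenarioParams(kind=kind, s=s, e=e, f=f, tau=tau,
                          seed=seed if seed is not None else 0, **fixed)


# ---------------------------------------------------------------------------
# Wright–Fisher engine
# ---------------------------------------------------------------------------

class WrightFisherPopulation:
    """Diploid Wright–Fisher population with infinite-sites mutation and
    (at most one per transmitted gamete) crossover recombination.

    Haplotypes are rows of an int8 matrix over the currently segregating
    sites; columns fixed or lost are pruned periodically.  A single focal
    site may be under additive selection (fitness 1, 1+s/2, 1+s).
    """

    PRUNE_EVERY = 25

    def __init__(self, N: int, L: int, mu: float, r: float,
                 rng: np.random.Generator,
                 used_positions: set | None = None):
        self.N, self.L, self.mu, self.r = N, L, mu, r
        self.rng = rng
        self.used_positions = used_positions if used_positions is not None else set()
        self.positions = np.empty(0, dtype=np.int64)
        self.haps = np.empty((2 * N, 0), dtype=np.int8)
        self.focal_pos: int | None = None
        self._gen = 0

    # -- setup -------------------------------------------------------------
    def _new_positions(self, k: int) -> np.ndarray:
        out = []
        while len(out) < k:
            cand = int(self.rng.integers(1, self.L + 1))
            if cand not in self.used_positions:
                self.used_positions.add(cand)
                out.append(cand)
        return np.asarray(out, dtype=np.int64)

    def init_equilibrium(self) -> None:
        """Seed the population at the neutral mutation–drift equilibrium SFS
        expectation (E[# sites with i copies] = 4NµL / i), carriers assigned
        at linkage equilibrium."""
        two_n = 2 * self.N
        theta = 4 * self.N * self.mu * self.L
        copies = []
        for i in range(1, two_n):
            copies.extend([i] * int(self.rng.poisson(theta / i)))
        pos = self._new_positions(len(copies))
        order = np.argsort(pos)
        self.positions = pos[order]
        haps = np.zeros((two_n, len(copies)), dtype=np.int8)
        for j, i_copies in enumerate(np.asarray(copies)[order]):
            rows = self.rng.choice(two_n, size=i_copies, replace=False)
            haps[rows, j] = 1
        self.haps = haps

    # -- accessors -----------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.haps.shape[1]

    def _focal_col(self) -> int | None:
        if self.focal_pos is None:
            return None
        hits = np.flatnonzero(self.positions == self.focal_pos)
        return int(hits[0]) if hits.size else None

    def focal_frequency(self) -> float:
        col = self._focal_col()
        if col is None:
            # pruned: fixed counts as 1, lost as 0
            return self._focal_fate
        return float(self.haps[:, col].mean())

    # -- dynamics ------------------------------------------------------------
    def step(self, s: float = 0.0) -> None:
        """Advance one non-overlapping Wright–Fisher generation."""
        two_n = 2 * self.N
        rng = self.rng
        col = self._focal_col()
        if s > 0 and col is not None:
            g = (self.haps[0::2, col].astype(np.float64)
                 + self.haps[1::2, col])
            w = 1.0 + (s / 2.0) * g
            parents = rng.choice(self.N, size=two_n, p=w / w.sum())
        else:
            parents = rng.integers(0, self.N, size=two_n)
        hap_choice = rng.integers(0, 2, size=two_n)
        rows = 2 * parents + hap_choice
        new = self.haps[rows]
        # single-crossover recombinants (rL is small)
        rec = np.flatnonzero(rng.random(two_n) < self.r * (self.L - 1))
        for i in rec:
            b = rng.uniform(0, self.L)
            other = self.haps[2 * parents[i] + 1 - hap_choice[i]]
            right = self.positions >= b
            new[i, right] = other[right]
        self.haps = new
        # infinite-sites mutation
        n_mut = rng.poisson(two_n * self.mu * self.L)
        if n_mut:
            pos = self._new_positions(n_mut)
            cols = np.zeros((two_n, n_mut), dtype=np.int8)
            cols[rng.integers(0, two_n, size=n_mut), np.arange(n_mut)] = 1
            self.positions = np.concatenate([self.positions, pos])
            self.haps = np.concatenate([self.haps, cols], axis=1)
            order = np.argsort(self.positions)
            self.positions = self.positions[order]
            self.haps = self.haps[:, order]
        self._gen += 1
        if self._gen % self.PRUNE_EVERY == 0:
            self.prune()

    def prune(self) -> None:
        counts = self.haps.sum(axis=0)
        keep = (counts > 0) & (counts < 2 * self.N)
        col = self._focal_col()
        if col is not None and not keep[col]:
            self._focal_fate = 1.0 if counts[col] == 2 * self.N else 0.0
        self.positions = self.positions[keep]
        self.haps = self.haps[:, keep]

    _focal_fate: float = 0.0

    def run(self, generations: int, s: float = 0.0) -> None:
        for _ in range(generations):
            self.step(s)

    # -- focal-site management -----------------------------------------------
    def inject_focal(self, position: int | None = None) -> None:
        """Place a de-novo mutation on one random haplotype (hard sweeps)."""
        if position is None:
            position = self.L // 2
            while position in self.used_positions:
                position += 1
        self.used_positions.add(position)
        col = np.zeros((2 * self.N, 1), dtype=np.int8)
        col[self.rng.integers(0, 2 * self.N), 0] = 1
        j = int(np.searchsorted(self.positions, position))
        self.positions = np.insert(self.positions, j, position)
        self.haps = np.concatenate(
            [self.haps[:, :j], col, self.haps[:, j:]], axis=1)
        self.focal_pos = int(position)
        self._focal_fate = 0.0

    def choose_standing_focal(self, e: float,
                              center_window: float = 0.5) -> float:
        """Make the standing variant nearest the region centre with frequency
        closest to ``e`` the beneficial focal allele (soft sweeps).

        Returns the realized starting frequency.  Falls back to a de-novo
        injection when no segregating candidate exists.
        """
        lo = self.L * (0.5 - center_window / 2)
        hi = self.L * (0.5 + center_window / 2)
        freqs = self.haps.mean(axis=0)
        cand = np.flatnonzero((self.positions >= lo) & (self.positions <= hi)
                              & (freqs > 0) & (freqs < 1))
        if cand.size == 0:
            cand = np.flatnonzero((freqs > 0) & (freqs < 1))
        if cand.size == 0:
            self.inject_focal()
            return 1.0 / (2 * self.N)
        j = cand[np.argmin(np.abs(freqs[cand] - e))]
        self.focal_pos = int(self.positions[j])
        self._focal_fate = 0.0
        return float(freqs[j])

    # -- snapshots and sampling ------------------------------------------------
    def snapshot(self) -> tuple:
        return (self.positions.copy(), self.haps.copy(),
                set(self.used_positions), self.focal_pos, self._gen)

    def restore(self, snap: tuple) -> None:
        self.positions, self.haps = snap[0].copy(), snap[1].copy()
        self.used_positions = set(snap[2])
        self.focal_pos = snap[3]
        self._gen = snap[4]
        self._focal_fate = 0.0

    def sample_raw(self, n_hap: int, rng: np.random.Generator | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
        """Sample ``n_hap`` haplotype rows (without replacement, whole
        individuals first) over the currently segregating sites."""
        rng = rng or self.rng
        if n_hap > 2 * self.N:
            raise ValueError("cannot sample more haplotypes than exist")
        n_ind = n_hap // 2
        ind = rng.choice(self.N, size=n_ind, replace=False)
        rows = np.stack([2 * ind, 2 * ind + 1], axis=1).ravel()
        if n_hap % 2:
            extra = rng.integers(0, self.N)
            rows = np.append(rows, 2 * extra)
        return self.positions.copy(), self.haps[rows].copy()


# ---------------------------------------------------------------------------
# Single-panel simulation
# ---------------------------------------------------------------------------

@dataclass
class PanelTruth:
    """Ground truth accompanying one simulated panel."""

    params: ScenarioParams
    focal_position: int | None
    realized_e: float
    final_population_freq: float
    sample_focal_freq: float
    focal_in_matrix: bool
    n_attempts: int = 1


def _sweep_phase(pop: WrightFisherPopulation, params: ScenarioParams,
                 max_attempts: int, snap) -> tuple[float, int]:
    """Run selection until the focal allele reaches frequency f, rejecting
    and restarting trajectories that lose the allele.

    With s = 0 there is no selection phase: the focal allele is chosen
    (or injected) and left to drift, unconditioned.
    """
    max_gens = 40 * pop.N
    for attempt in range(1, max_attempts + 1):
        pop.restore(snap)
        if params.kind == "hard":
            pop.inject_focal()
            realized_e = 1.0 / (2 * pop.N)
        else:
            realized_e = pop.choose_standing_focal(params.e)
        if params.s == 0:
            return realized_e, attempt
        gens = 0
        while True:
            freq = pop.focal_frequency()
            if freq >= params.f:
                return realized_e, attempt
            if freq == 0.0 or gens >= max_gens:
                break
            pop.step(s=params.s)
            gens += 1
    raise RuntimeError(
        f"sweep failed to reach f={params.f} after {max_attempts} attempts "
        f"({params})")


def simulate_panel(params: ScenarioParams, burnin: int | None = None,
                   max_attempts: int = 200,
                   ) -> tuple[HaplotypeMatrix, PanelTruth]:
    """Simulate one phased haplotype panel under a scenario draw.

    Neutral panels are sampled right after equilibration; sweep panels run
    selection at the focal site from frequency e to f (rejection-resampled
    on loss), then drift neutrally for tau·4N generations before sampling
    ``n_hap`` haplotypes.
    """
    if params.N > 2000:
        raise ValueError(
            "N > 2000 exceeds the supported forward-simulation scale")
    rng = np.random.default_rng(params.seed)
    pop = WrightFisherPopulation(params.N, params.L, params.mu, params.r, rng)
    pop.init_equilibrium()
    pop.run(burnin if burnin is not None else params.N)

    realized_e, attempts = 0.0, 1
    if params.kind != "neutral":
        snap = pop.snapshot()
        realized_e, attempts = _sweep_phase(pop, params, max_attempts, snap)
        pop.run(int(round(params.tau * 4 * params.N)))

    final_freq = pop.focal_frequency() if params.kind != "neutral" else 0.0
    positions, alleles = pop.sample_raw(params.n_hap)
    seg = (alleles.sum(axis=0) > 0) & (alleles.sum(axis=0) < alleles.shape[0])
    focal_pos = pop.focal_pos
    sample_freq = 0.0
    if focal_pos is not None:
        hit = np.flatnonzero(positions == focal_pos)
        if hit.size:
            sample_freq = float(alleles[:, hit[0]].mean())
        elif pop._focal_fate == 1.0 or final_freq == 1.0:
            sample_freq = 1.0
    keep = np.flatnonzero(seg)
    n_samples = alleles.shape[0] // 2
    m = HaplotypeMatrix(
        chrom="chr1", positions=positions[keep], alleles=alleles[:, keep],
        sample_ids=[f"s{i}" for i in range(n_samples)],
        sample_pops=["sim"] * n_samples)
    focal_in = focal_pos is not None and bool(np.isin(focal_pos, m.positions))
    truth = PanelTruth(params=params, focal_position=focal_pos,
                       realized_e=realized_e,
                       final_population_freq=final_freq,
                       sample_focal_freq=sample_freq,
                       focal_in_matrix=focal_in, n_attempts=attempts)
    return m, truth


def simulate_h_points(kind: str, n: int, seed: int,
                      s_range=(0.1, 1.0), e_range=(0.0, 0.2),
                      window_snps: int = 201,
                      **fixed) -> np.ndarray:
    """(H12, H2/H1) points from ``n`` scenario draws of one kind.

    The observed window is centred on the focal site (or the site nearest
    the region centre when the focal allele is fixed in the sample).
    """
    from .sweep_classify import h_statistics, window_spectrum

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n, dtype=np.uint32) >> np.uint32(1)
    rng = np.random.default_rng(ss.spawn(1)[0])
    pts = np.empty((n, 2))
    for i in range(n):
        params = draw_scenario(kind, rng, s_range=s_range, e_range=e_range,
                               seed=int(child_seeds[i]), **fixed)
        m, truth = simulate_panel(params)
        if truth.focal_in_matrix:
            center = int(np.flatnonzero(m.positions == truth.focal_position)[0])
        else:
            center = int(np.argmin(np.abs(m.positions - params.L // 2)))
        spec, _ = window_spectrum(m, center, window_snps)
        hs = h_statistics(spec)
        pts[i] = (hs.h12, hs.h2_over_h1)
    return pts


# ---------------------------------------------------------------------------
# Cohort fixture: multi-population files for the whole pipeline
# ---------------------------------------------------------------------------

@dataclass
class PlantedSweep:
    """A domestication sweep planted in one cultivated population.

    Defaults describe a moderately strong, recently completed partial
    sweep (s = 0.15, swept to 90%, selection ending at sampling time)
    whose footprint ~1/(r·T_sweep) occupies a minority of the swept
    chromosome — see docs/methods.md for the sizing argument.
    """

    kind: str = "hard"
    s: float = 0.15
    f: float = 0.9
    tau: float = 0.0
    e: float = 0.0
    chrom: str = "chr1"


@dataclass
class CohortConfig:
    """Study conditions of one synthetic wild/cultivated cohort.

    The genome is a set of independently simulated chromosomes; sweeps are
    planted on ``PlantedSweep.chrom`` (default the first chromosome), the
    others provide the neutral background a genome-wide scan standardizes
    against.  ``L`` is a single-chromosome shorthand.
    """

    wild_name: str = "Indian"
    wild_samples: int = 30
    cultivated: dict = field(
        default_factory=lambda: {"EastAsian": 37})
    planted: dict = field(
        default_factory=lambda: {"EastAsian": PlantedSweep()})
    chromosomes: dict = field(
        default_factory=lambda: {"chr1": 250_000, "chr2": 250_000,
                                 "chr3": 250_000})
    L: int | None = None
    N: int = DEFAULT_N
    mu: float = DEFAULT_MU
    r: float = DEFAULT_MU
    burnin: int = DEFAULT_N
    split_generations: int = 400
    bottleneck_N: int | None = None
    bottleneck_generations: int = 0
    missingness: float = 0.02
    ref_swap_fraction: float = 0.2
    outgroup_error_rate: float = 0.05
    outgroup_absent_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.L is not None:
            self.chromosomes = {"chr1": int(self.L)}
        if not self.cultivated:
            raise ValueError("cohort needs at least one cultivated population")
        for pop, sweep in self.planted.items():
            if sweep is None:
                raise ValueError("conflicting planted sweep entries")
            if isinstance(sweep, PlantedSweep) and \
                    sweep.chrom not in self.chromosomes:
                raise ValueError(
                    f"planted sweep for {pop!r} names unknown chromosome "
                    f"{sweep.chrom!r}")


@dataclass
class CohortFixture:
    matrices: dict  # chrom -> HaplotypeMatrix, 0 = ancestral coding
    vcf_matrices: dict  # chrom -> HaplotypeMatrix, REF/ALT coding as emitted
    ref_alt: dict
    states: "object"  # pandas DataFrame
    genes: "object"
    truth: dict
    paths: dict = field(default_factory=dict)

    @property
    def matrix(self) -> HaplotypeMatrix:
        """The sole chromosome's ancestral-coded matrix (single-chrom runs)."""
        if len(self.matrices) != 1:
            raise ValueError("cohort has multiple chromosomes")
        return next(iter(self.matrices.values()))

    @property
    def vcf_matrix(self) -> HaplotypeMatrix:
        if len(self.vcf_matrices) != 1:
            raise ValueError("cohort has multiple chromosomes")
        return next(iter(self.vcf_matrices.values()))


def _derive_population(ancestor: WrightFisherPopulation, config: CohortConfig,
                       rng: np.random.Generator) -> WrightFisherPopulation:
    """Found a descendant population from the ancestral gene pool."""
    pop = WrightFisherPopulation(config.N, ancestor.L, config.mu, config.r,
                                 rng, used_positions=ancestor.used_positions)
    founders = rng.integers(0, ancestor.N, size=config.N)
    rows = np.stack([2 * founders, 2 * founders + 1], axis=1).ravel()
    pop.positions = ancestor.positions.copy()
    pop.haps = ancestor.haps[rows].copy()
    if config.bottleneck_N:
        keep = rng.choice(config.N, size=config.bottleneck_N, replace=False)
        bn_rows = np.stack([2 * keep, 2 * keep + 1], axis=1).ravel()
        expand = rng.choice(config.bottleneck_N, size=config.N, replace=True)
        rows2 = np.stack([bn_rows[2 * expand], bn_rows[2 * expand + 1]],
                         axis=1).ravel()
        pop.haps = pop.haps[rows2].copy()
        pop.run(config.bottleneck_generations)
    return pop


def _simulate_cohort_chromosome(chrom: str, length: int,
                                config: CohortConfig,
                                rng: np.random.Generator,
                                truth: dict) -> HaplotypeMatrix:
    """One chromosome: equilibrate, split wild/cultivated, plant sweeps."""
    anc = WrightFisherPopulation(config.N, length, config.mu, config.r, rng)
    anc.init_equilibrium()
    anc.run(config.burnin)

    pops: dict[str, WrightFisherPopulation] = {}
    max_gens_run = config.split_generations
    for name in config.cultivated:
        pop = _derive_population(anc, config, rng)
        sweep = config.planted.get(name)
        if sweep is not None and sweep.chrom == chrom:
            # diverge neutrally first, then sweep, so that selection ends
            # tau·4N generations before sampling
            pop.run(config.split_generations)
            params = ScenarioParams(kind=sweep.kind, s=sweep.s, e=sweep.e,
                                    f=sweep.f, tau=sweep.tau, mu=config.mu,
                                    r=config.r, N=config.N, L=length,
                                    n_hap=2 * config.cultivated[name],
                                    seed=config.seed)
            snap = pop.snapshot()
            realized_e, attempts = _sweep_phase(pop, params, 200, snap)
            pop.run(int(round(sweep.tau * 4 * config.N)))
            truth["planted"][name] = {
                "chrom": chrom, "position": pop.focal_pos,
                "kind": sweep.kind, "s": sweep.s, "f": sweep.f,
                "tau": sweep.tau, "realized_e": realized_e,
                "final_population_freq": pop.focal_frequency(),
                "n_attempts": attempts,
            }
        max_gens_run = max(max_gens_run, pop._gen)
        pops[name] = pop
    wild = _derive_population(anc, config, rng)
    pops = {config.wild_name: wild, **pops}
    for pop in pops.values():
        if pop._gen < max_gens_run:
            pop.run(max_gens_run - pop._gen)

    # union site grid over sampled haplotypes, all populations
    pops_order = [config.wild_name] + list(config.cultivated)
    sampled = {}
    for name, pop in pops.items():
        n_samples = (config.wild_samples if name == config.wild_name
                     else config.cultivated[name])
        sampled[name] = pop.sample_raw(2 * n_samples)
        truth["populations"][name] = {"n_samples": n_samples}
    union = np.unique(np.concatenate([p for p, _ in sampled.values()]))
    blocks, sample_ids, sample_pops = [], [], []
    for name in pops_order:
        positions, alleles = sampled[name]
        block = np.zeros((alleles.shape[0], union.size), dtype=np.int8)
        block[:, np.searchsorted(union, positions)] = alleles
        blocks.append(block)
        n_samples = alleles.shape[0] // 2
        sample_ids += [f"{name}_{i}" for i in range(n_samples)]
        sample_pops += [name] * n_samples
    big = np.concatenate(blocks, axis=0)
    seg = (big.sum(axis=0) > 0) & (big.sum(axis=0) < big.shape[0])
    return HaplotypeMatrix(chrom=chrom, positions=union[seg],
                           alleles=big[:, seg], sample_ids=sample_ids,
                           sample_pops=sample_pops)


def build_cohort_fixture(config: CohortConfig | None = None,
                         outdir=None) -> CohortFixture:
    """Generate end-to-end testable inputs for the whole pipeline.

    Per chromosome, an ancestral population equilibrates and splits into one
    wild and the configured cultivated populations; cultivated populations
    carry their planted sweeps on the designated chromosome while the other
    chromosomes evolve neutrally.  Emits (when ``outdir`` is given) a phased
    VCF with missingness, a population table, an outgroup allele-state table
    consistent with the true ancestral alleles up to the configured error
    rate, a toy GFF3 with genes flanking the planted sweeps, and a JSON
    truth manifest.
    """
    import pandas as pd

    config = config or CohortConfig()
    truth: dict = {"seed": config.seed, "populations": {}, "planted": {}}
    matrices: dict[str, HaplotypeMatrix] = {}
    ss = np.random.SeedSequence(config.seed)
    for child, (chrom, length) in zip(ss.spawn(len(config.chromosomes)),
                                      config.chromosomes.items()):
        rng = np.random.default_rng(child)
        matrices[chrom] = _simulate_cohort_chromosome(chrom, length, config,
                                                      rng, truth)

    # missingness (per genotype), REF/ALT bases, coding swaps, outgroups —
    # one rng stream, applied chromosome by chromosome
    rng = np.random.default_rng(ss.spawn(1)[0])
    species = ["cucumber", "melo", "lanatus", "siceraria",
               "moschata", "maxima", "pepo"]
    vcf_matrices: dict[str, HaplotypeMatrix] = {}
    ref_alt: dict = {}
    state_frames = []
    for chrom, matrix in matrices.items():
        n_sites = matrix.n_sites
        vcf_alleles = matrix.alleles.copy()
        if config.missingness > 0:
            miss_gt = rng.random((len(matrix.sample_ids), n_sites)) \
                < config.missingness
            vcf_alleles[np.repeat(miss_gt, 2, axis=0)] = MISSING
        base_idx = rng.integers(0, 4, size=n_sites)
        anc_base = _BASES[base_idx]
        der_base = _BASES[(base_idx + 1 + rng.integers(0, 3, n_sites)) % 4]
        swap = rng.random(n_sites) < config.ref_swap_fraction
        ref = np.where(swap, der_base, anc_base)
        alt = np.where(swap, anc_base, der_base)
        flip_cols = np.flatnonzero(swap)
        sub = vcf_alleles[:, flip_cols]
        nm = sub != MISSING
        sub[nm] = 1 - sub[nm]
        vcf_alleles[:, flip_cols] = sub
        vcf_matrices[chrom] = HaplotypeMatrix(
            chrom=chrom, positions=matrix.positions, alleles=vcf_alleles,
            sample_ids=matrix.sample_ids, sample_pops=matrix.sample_pops)
        for p, r_, a_ in zip(matrix.positions, ref, alt):
            ref_alt[(chrom, int(p))] = (r_, a_)
        states = {"chrom": [chrom] * n_sites, "pos": matrix.positions,
                  "cucumber": ref}  # focal-species reference base
        for sp in species[1:]:
            absent = rng.random(n_sites) < config.outgroup_absent_rate
            err = rng.random(n_sites) < config.outgroup_error_rate
            wrong = _BASES[(base_idx + 1 + rng.integers(0, 3, n_sites)) % 4]
            col = np.where(err, wrong, anc_base)
            states[sp] = np.where(absent, "", col)
        state_frames.append(pd.DataFrame(states))
    states = pd.concat(state_frames, ignore_index=True)

    # toy gene models flanking the planted sweeps
    gff_rows = []
    gi = 1
    for name, info in truth["planted"].items():
        chrom, p = info["chrom"], info["position"]
        length = config.chromosomes[chrom]
        gff_rows.append((chrom, p + 1000, min(p + 3000, length), "+",
                         f"gene{gi:03d}"))  # promoter covers the sweep site
        gi += 1
        gff_rows.append((chrom, max(1, p - 6000), max(2, p - 4000), "-",
                         f"gene{gi:03d}"))
        gi += 1
    first_chrom, first_len = next(iter(config.chromosomes.items()))
    gff_rows.append((first_chrom, int(first_len * 0.05),
                     int(first_len * 0.08), "+", f"gene{gi:03d}"))
    genes = pd.DataFrame(gff_rows, columns=["chrom", "start", "end", "strand",
                                            "gene_id"])

    fixture = CohortFixture(matrices=matrices, vcf_matrices=vcf_matrices,
                            ref_alt=ref_alt, states=states, genes=genes,
                            truth=truth)
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "populations": outdir / "populations.tsv",
            "states": outdir / "states.tsv",
            "gff": outdir / "genes.gff3",
            "truth": outdir / "truth.json",
        }
        write_vcf(vcf_matrices, paths["vcf"], ref_alt=ref_alt)
        first = next(iter(matrices.values()))
        with open(paths["populations"], "w") as fh:
            for s, p in zip(first.sample_ids, first.sample_pops):
                fh.write(f"{s}\t{p}\n")
        states.to_csv(paths["states"], sep="\t", index=False)
        with open(paths["gff"], "w") as fh:
            fh.write("##gff-version 3\n")
            for row in genes.itertuples(index=False):
                fh.write(f"{row.chrom}\tsweepscan\tgene\t{row.start}\t"
                         f"{row.end}\t.\t{row.strand}\t.\tID={row.gene_id}\n")
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        fixture.paths = {k: str(v) for k, v in paths.items()}
    return fixture
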