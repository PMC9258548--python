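"""Shared fixtures and independent brute-force oracles.

The oracles enumerate haplotype pairs directly and never touch the
group-refinement engine they are used to check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from hypothesis import settings

from sweepscan.haplo_io import MISSING, HaplotypeMatrix
import sweepscan as sw

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


def make_matrix(alleles, positions=None, pops=None, chrom="chr1"):
    """HaplotypeMatrix from a plain (n_hap, n_sites) array."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_hap, n_sites = alleles.shape
    assert n_hap % 2 == 0
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    n_samp = n_hap // 2
    if pops is None:
        pops = ["pop1"] * n_samp
    return HaplotypeMatrix(chrom=chrom, positions=positions, alleles=alleles,
                           sample_ids=[f"s{i}" for i in range(n_samp)],
                           sample_pops=list(pops))


def random_matrix(rng, n_hap=None, n_sites=None, miss_p=0.0):
    n_hap = n_hap or int(rng.integers(2, 7)) * 2
    n_sites = n_sites or int(rng.integers(3, 16))
    a = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.int8)
    if miss_p:
        a[rng.random(a.shape) < miss_p] = MISSING
    pos = np.sort(rng.choice(np.arange(1, 100_000), size=n_sites,
                             replace=False))
    return make_matrix(a, positions=pos)


# ---------------------------------------------------------------------------
# Pair-enumeration oracles
# ---------------------------------------------------------------------------

def _pair_identical(alleles, i, k, lo, hi):
    """Both non-missing and equal over columns lo..hi inclusive."""
    for j in range(lo, hi + 1):
        a, b = alleles[i, j], alleles[k, j]
        if a == MISSING or b == MISSING or a != b:
            return False
    return True


def ehh_oracle(m, core, allele_code, offset_index):
    """EHH at a site offset by exhaustive pair enumeration.

    ``offset_index`` is the absolute column index of the far end; the
    interval runs from core to it (inclusive).
    """
    carriers = [h for h in range(m.n_hap) if m.alleles[h, core] == allele_code]
    n0 = len(carriers)
    if n0 < 2:
        raise ValueError("fewer than 2 carriers")
    lo, hi = min(core, offset_index), max(core, offset_index)
    good = sum(_pair_identical(m.alleles, i, k, lo, hi)
               for i, k in combinations(carriers, 2))
    return good / (n0 * (n0 - 1) / 2)


def ehhs_oracle(m, core, offset_index, normalization="sabeti"):
    """Pooled (site) EHH by enumeration, normalized to 1 at the core."""
    members = [h for h in range(m.n_hap) if m.alleles[h, core] != MISSING]
    n0 = len(members)
    lo, hi = min(core, offset_index), max(core, offset_index)

    def hom(a, b):  # unnormalized homozygosity over interval [a, b]
        if normalization == "sabeti":
            good = sum(_pair_identical(m.alleles, i, k, a, b)
                       for i, k in combinations(members, 2))
            return good / (n0 * (n0 - 1) / 2)
        # biased: group alive members by their string over [a, b]
        groups: dict[tuple, int] = {}
        for h in members:
            row = tuple(m.alleles[h, a:b + 1])
            if MISSING in row:
                continue
            groups[row] = groups.get(row, 0) + 1
        return sum((c / n0) ** 2 for c in groups.values())

    return hom(lo, hi) / hom(core, core)


def nsl_tract_oracle(m, core, allele_code):
    """Mean pair identity-tract length (in segregating sites) by pair scan."""
    carriers = [h for h in range(m.n_hap) if m.alleles[h, core] == allele_code]
    if len(carriers) < 2:
        raise ValueError("fewer than 2 carriers")
    lengths = []
    for i, k in combinations(carriers, 2):
        left = 0
        j = core - 1
        while j >= 0 and _pair_identical(m.alleles, i, k, j, j):
            left += 1
            j -= 1
        right = 0
        j = core + 1
        while j < m.n_sites and _pair_identical(m.alleles, i, k, j, j):
            right += 1
            j += 1
        lengths.append(left + right + 1)
    return float(np.mean(lengths))


# ---------------------------------------------------------------------------
# Expensive shared simulations (session scope)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def neutral_cohort():
    """One neutral two-population cohort without missingness."""
    cfg = sw.CohortConfig(cultivated={"EastAsian": 30}, planted={},
                          wild_samples=30, missingness=0.0, L=150_000,
                          seed=4242)
    return sw.build_cohort_fixture(cfg)


@pytest.fixture(scope="session")
def hard_training_points():
    """1,000 hard-sweep (H12, H2/H1) training draws at s >= 0.1."""
    return sw.simulate_h_points("hard", 1000, seed=910, s_range=(0.1, 1.0))


@pytest.fixture(scope="session")
def soft_training_points():
    """1,000 soft-sweep training draws, e in [0.05, 0.2], s >= 0.1."""
    return sw.simulate_h_points("soft", 1000, seed=911, s_range=(0.1, 1.0),
                                e_range=(0.05, 0.2))
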