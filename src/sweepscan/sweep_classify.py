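"""Hard/soft sweep classification via Garud's H-statistics and Bayes factors.

In a window of SNPs around each selective site, distinct haplotype strings
are counted and their sorted frequency spectrum summarized by H1 = Σ pᵢ²,
H2 = H1 − p₁² and H12 = (p₁+p₂)² + Σ_{i≥3} pᵢ².  A hard sweep leaves one
dominant haplotype (high H12, low H2/H1); a soft sweep carries several
(high H12 with elevated H2/H1).  The observed (H12, H2/H1) point is compared
with simulated hard- and soft-sweep scenario sets: support for each class is
the number of simulated datasets within Euclidean distance eps (< 0.1) of
the observation, and the Bayes factor is the hard/soft support ratio —
BF > 1 labels the site hard, BF < 1 soft, BF = 1 or no support at all
unknown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplo_io import MISSING, HaplotypeMatrix

DEFAULT_WINDOW_SNPS = 201
DEFAULT_EPS = 0.1


def window_spectrum(m: HaplotypeMatrix, center: int,
                    window_snps: int = DEFAULT_WINDOW_SNPS,
                    ) -> tuple[np.ndarray, bool]:
    """Sorted haplotype frequency spectrum in a SNP-count window.

    The window covers ``window_snps`` sites centred on ``center`` (truncated
    at chromosome ends; the second return value flags truncation).
    Haplotypes with any missing genotype inside the window are dropped.
    """
    half = window_snps // 2
    lo, hi = center - half, center + half + 1
    truncated = lo < 0 or hi > m.n_sites
    lo, hi = max(lo, 0), min(hi, m.n_sites)
    block = m.alleles[:, lo:hi]
    keep = ~(block == MISSING).any(axis=1)
    block = block[keep]
    if block.shape[0] < 2:
        raise ValueError("fewer than 2 complete haplotypes in window")
    _, counts = np.unique(block, axis=0, return_counts=True)
    freqs = np.sort(counts / counts.sum())[::-1]
    return freqs, truncated


@dataclass(frozen=True)
class HStatistics:
    h1: float
    h2: float
    h12: float
    h2_over_h1: float


def h_statistics(spectrum) -> HStatistics:
    """H1, H2, H12 and H2/H1 from a sorted haplotype frequency spectrum."""
    p = np.asarray(spectrum, dtype=float)
    if p.size == 0:
        raise ValueError("empty haplotype spectrum")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("spectrum frequencies must sum to 1")
    p = np.sort(p)[::-1]
    h1 = float(np.sum(p ** 2))
    h2 = h1 - float(p[0] ** 2)
    if p.size >= 2:
        h12 = float((p[0] + p[1]) ** 2 + np.sum(p[2:] ** 2))
    else:
        h12 = h1
    h2_over_h1 = h2 / h1 if h1 > 0 else 0.0
    return HStatistics(h1=h1, h2=h2, h12=h12, h2_over_h1=h2_over_h1)


@dataclass(frozen=True)
class SweepVerdict:
    h12: float
    h2_over_h1: float
    support_hard: int
    support_soft: int
    bayes_factor: float
    label: str  # "hard" | "soft" | "unknown"


def bayes_factor_classify(observed: tuple[float, float],
                          hard_set: np.ndarray, soft_set: np.ndarray,
                          eps: float = DEFAULT_EPS) -> SweepVerdict:
    """Classify one observed (H12, H2/H1) point against simulated scenarios.

    ``hard_set`` and ``soft_set`` are (n, 2) arrays of simulated
    (H12, H2/H1) points.  Support is counted with strict ``< eps``.
    """
    hard_set = np.atleast_2d(np.asarray(hard_set, dtype=float))
    soft_set = np.atleast_2d(np.asarray(soft_set, dtype=float))
    if hard_set.size == 0 or soft_set.size == 0:
        raise ValueError("simulated scenario sets must be nonempty")
    obs = np.asarray(observed, dtype=float)
    nh = int(np.sum(np.linalg.norm(hard_set - obs, axis=1) < eps))
    ns = int(np.sum(np.linalg.norm(soft_set - obs, axis=1) < eps))
    if nh == 0 and ns == 0:
        bf, label = np.nan, "unknown"
    elif ns == 0:
        bf, label = np.inf, "hard"
    else:
        bf = nh / ns
        label = "hard" if bf > 1 else ("soft" if bf < 1 else "unknown")
    return SweepVerdict(h12=float(obs[0]), h2_over_h1=float(obs[1]),
                        support_hard=nh, support_soft=ns,
                        bayes_factor=bf, label=label)


def classify_selected_sites(m: HaplotypeMatrix, positions,
                            hard_set: np.ndarray, soft_set: np.ndarray,
                            window_snps: int = DEFAULT_WINDOW_SNPS,
                            eps: float = DEFAULT_EPS) -> pd.DataFrame:
    """Verdict table for selective sites (1-based positions) on one matrix."""
    rows = []
    pos_index = {int(p): i for i, p in enumerate(m.positions)}
    for pos in positions:
        i = pos_index.get(int(pos))
        if i is None:
            raise ValueError(f"position {pos} not present in matrix")
        spec, truncated = window_spectrum(m, i, window_snps)
        hs = h_statistics(spec)
        v = bayes_factor_classify((hs.h12, hs.h2_over_h1), hard_set,
                                  soft_set, eps)
        rows.append((m.chrom, int(pos), hs.h12, hs.h2_over_h1,
                     v.support_hard, v.support_soft, v.bayes_factor,
                     v.label, truncated))
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "h12", "h2_over_h1", "support_hard", "support_soft",
        "bayes_factor", "label", "window_truncated"])
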