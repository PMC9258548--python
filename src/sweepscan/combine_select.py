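"""Fisher combination of per-method P values, FDR control and set partition.

Per SNP, the available method P values (1–4 of iHS, nSL, XP-EHH, Rsb) are
combined with Fisher's statistic T = -2 Σ ln Pᵢ, chi-squared with 2n degrees
of freedom under the independent null; combined P values are corrected
genome-wide per population by Benjamini–Hochberg, and sites with q below the
FDR threshold (default 0.01) are called selective.  Selected sets from
several populations are partitioned into population-unique, pairwise-shared
and shared-by-all groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

METHODS = ("ihs", "nsl", "xpehh", "rsb")


def fisher_combine(p_values) -> tuple[float, int, float]:
    """Fisher's method for 1–4 P values: returns (T, df, combined P).

    P values must lie in (0, 1]; exact zeros are clipped to the smallest
    positive float with a warning.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("fisher_combine requires at least one P value")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("P values must lie in (0, 1]")
    if np.any(p == 0):
        warnings.warn("P value of 0 clipped to smallest positive float")
        p = np.maximum(p, np.finfo(float).tiny)
    t = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return t, df, float(chi2.sf(t, df))


def bh_adjust(p_vector) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (q), input order preserved."""
    p = np.asarray(list(p_vector), dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("P values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def combine_methods(score_tables, alpha: float = 0.01,
                    strict: bool = False) -> pd.DataFrame:
    """Merge per-method score tables into a combined-call table.

    ``score_tables`` is an iterable of scan outputs (chrom, pos, method, p).
    Sites missing some methods (e.g. no ancestral call for iHS/nSL) are
    combined over the available evidence with df = 2·n_available; with
    ``strict`` only sites scored by all four methods are kept.
    """
    frames = [t[["chrom", "pos", "method", "p"]] for t in score_tables]
    long = pd.concat(frames, ignore_index=True)
    if long.duplicated(["chrom", "pos", "method"]).any():
        raise ValueError("duplicate (chrom, pos) within a method table")
    wide = long.pivot_table(index=["chrom", "pos"], columns="method",
                            values="p", aggfunc="first")
    wide = wide.reindex(columns=[m for m in METHODS if m in wide.columns])
    n_methods = wide.notna().sum(axis=1)
    if strict:
        wide = wide[n_methods == len(wide.columns)]
        n_methods = n_methods[n_methods == len(wide.columns)]
    rows = []
    for (chrom, pos), ps in wide.iterrows():
        avail = ps.dropna()
        t, df, pc = fisher_combine(avail.to_numpy())
        rows.append((chrom, pos, t, df, pc))
    out = pd.DataFrame(rows, columns=["chrom", "pos", "T", "df", "p_combined"])
    for meth in wide.columns:
        out[f"p_{meth}"] = wide[meth].to_numpy()
    out["n_methods"] = (out["df"] // 2).astype(int)
    out["q"] = bh_adjust(out["p_combined"].to_numpy())
    out["selected"] = out["q"] < alpha
    return out


@dataclass
class VennPartition:
    """Selected-site sets and their exact partition across populations."""

    selected: dict[str, set] = field(default_factory=dict)
    unique: dict[str, set] = field(default_factory=dict)
    pairwise: dict[frozenset, set] = field(default_factory=dict)
    shared_by_all: set = field(default_factory=set)


def call_and_partition(calls_per_population: dict[str, pd.DataFrame],
                       alpha: float = 0.01) -> VennPartition:
    """Call selective sites per population (q < alpha) and partition them.

    ``unique[pop]`` holds sites selected in that population only;
    ``pairwise[{a, b}]`` sites selected in exactly populations a and b;
    ``shared_by_all`` sites selected in every population.
    """
    selected: dict[str, set] = {}
    for pop, df in calls_per_population.items():
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError(f"duplicate site keys in population {pop!r}")
        sel = df[df["q"] < alpha]
        selected[pop] = set(zip(sel["chrom"], sel["pos"]))
    pops = list(selected)
    part = VennPartition(selected=selected)
    for pop in pops:
        others = set().union(*(selected[q] for q in pops if q != pop)) if len(pops) > 1 else set()
        part.unique[pop] = selected[pop] - others
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            both = selected[a] & selected[b]
            rest = set().union(*(selected[q] for q in pops if q not in (a, b))) \
                if len(pops) > 2 else set()
            part.pairwise[frozenset((a, b))] = both - rest
    part.shared_by_all = set.intersection(*selected.values()) if pops else set()
    return part


def selected_to_bed(calls: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Selective sites as BED (0-based half-open) from 1-based positions."""
    sel = calls[calls["q"] < alpha]
    return pd.DataFrame({
        "chrom": sel["chrom"],
        "start": sel["pos"].astype(np.int64) - 1,
        "end": sel["pos"].astype(np.int64),
    }).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
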