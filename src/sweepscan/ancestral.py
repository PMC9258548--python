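"""Ancestral-allele inference by clade-consistency parsimony and polarization.

The focal species' alleles are polarized against a panel of related species
from a reference-based multiple alignment: a 4-species inner clade (the focal
species plus its 3 closest relatives) and a 7-species outer clade.  A site's
ancestral allele is the allele shared by at least 3 of the 4 inner-clade
species or, failing that, by at least 4 of the 7 outer-clade species; sites
where neither rule resolves are left missing and are later excluded from the
statistics that require polarity (iHS, nSL) while remaining available to
XP-EHH and Rsb.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .haplo_io import MISSING, HaplotypeMatrix

FOURWAY_MIN = 3  # "more than 2 species in the 4-way clade"
SEVENWAY_MIN = 4  # "4 species in the 7-way clade"

_BASES = ("A", "C", "G", "T")


class AncestralState(Enum):
    ANCESTRAL_IS_REF = "ref"
    ANCESTRAL_IS_ALT = "alt"
    MISSING = "missing"


@dataclass(frozen=True)
class AncestralCall:
    state: AncestralState
    clade: str  # "4way" | "7way" | "none"
    allele: str | None = None  # the inferred ancestral base, if any

    def __post_init__(self):
        if (self.state is AncestralState.MISSING) != (self.clade == "none"):
            raise ValueError("state MISSING iff supporting clade is none")


def _consensus(states: list[str | None], minimum: int) -> str | None:
    """Allele reaching ``minimum`` copies among present states, else None."""
    counts: dict[str, int] = {}
    for s in states:
        if s:
            counts[s] = counts.get(s, 0) + 1
    best = [a for a, c in counts.items() if c >= minimum]
    return best[0] if len(best) == 1 else None


def infer_ancestral_state(species_states, ref: str, alt: str,
                          include_focal: bool = True) -> AncestralCall:
    """Infer the ancestral allele of one biallelic site.

    Parameters
    ----------
    species_states
        Length-7 sequence of single bases (or None/'' for unaligned species).
        The first entry is the focal species (its reference base); entries
        0–3 form the 4-way clade and 0–6 the 7-way clade.
    ref, alt
        The two segregating alleles in the focal species.
    include_focal
        Whether the focal species itself counts toward the consensus
        (default, since it is a member of both clades).
    """
    if ref == alt:
        raise ValueError("ref and alt must differ")
    states = [s if s else None for s in species_states]
    if len(states) != 7:
        raise ValueError("expected 7 species states")
    start = 0 if include_focal else 1
    anc = _consensus(states[start:4], FOURWAY_MIN)
    clade = "4way"
    if anc is None:
        anc = _consensus(states[start:7], SEVENWAY_MIN)
        clade = "7way"
    if anc is None or anc not in (ref, alt):
        return AncestralCall(AncestralState.MISSING, "none")
    state = (AncestralState.ANCESTRAL_IS_REF if anc == ref
             else AncestralState.ANCESTRAL_IS_ALT)
    return AncestralCall(state, clade, anc)


def read_state_table(path) -> pd.DataFrame:
    """Per-site species allele states as TSV: chrom, pos, 7 species columns.

    Empty / '.' / '-' cells denote an unaligned (absent) species.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 9:
        raise ValueError(f"{path}: expected chrom, pos and 7 species columns")
    df["pos"] = df["pos"].astype(np.int64)
    species = list(df.columns[2:9])
    for c in species:
        df[c] = df[c].replace({".": "", "-": ""})
    return df


def infer_ancestral_table(ref_alt: pd.DataFrame, states: pd.DataFrame,
                          include_focal: bool = True) -> pd.DataFrame:
    """Vector version over a state table.

    ``ref_alt`` carries columns chrom, pos, ref, alt; ``states`` is a
    state table (chrom, pos, 7 species columns).  The result adds
    ancestral_state / clade / ancestral_allele columns aligned on (chrom, pos).
    """
    species = list(states.columns[2:9])
    merged = ref_alt.merge(states, on=["chrom", "pos"], how="left")
    calls = []
    for row in merged.itertuples(index=False):
        st = [getattr(row, c, "") for c in species]
        if all(not s for s in st):
            calls.append(AncestralCall(AncestralState.MISSING, "none"))
        else:
            calls.append(infer_ancestral_state(st, row.ref, row.alt,
                                               include_focal=include_focal))
    out = ref_alt.copy()
    out["ancestral_state"] = [c.state.value for c in calls]
    out["clade"] = [c.clade for c in calls]
    out["ancestral_allele"] = [c.allele or "." for c in calls]
    return out


@dataclass
class PolarizedMatrix:
    """Haplotype matrix recoded to 0 = ancestral / 1 = derived.

    ``known`` flags sites with a resolved ancestral call; unresolved sites
    keep their REF/ALT coding and must be excluded from polarity-dependent
    statistics.  ``daf`` is the derived allele frequency over non-missing
    haplotypes (NaN where the call is missing).
    """

    matrix: HaplotypeMatrix
    known: np.ndarray
    daf: np.ndarray


def polarize(m: HaplotypeMatrix, calls) -> PolarizedMatrix:
    """Recode a matrix so allele 1 is the derived allele at every called site.

    ``calls`` is a sequence of :class:`AncestralCall` (or their state values)
    aligned with ``m``'s sites.  Columns whose ancestral allele is ALT are
    flipped; missing genotype entries are preserved.
    """
    states = [c.state if isinstance(c, AncestralCall) else AncestralState(c)
              for c in calls]
    if len(states) != m.n_sites:
        raise ValueError(
            f"{len(states)} ancestral calls for {m.n_sites} sites")
    alleles = m.alleles.copy()
    known = np.array([s is not AncestralState.MISSING for s in states])
    flip = np.array([s is AncestralState.ANCESTRAL_IS_ALT for s in states])
    cols = np.flatnonzero(flip)
    sub = alleles[:, cols]
    nonmiss = sub != MISSING
    sub[nonmiss] = 1 - sub[nonmiss]
    alleles[:, cols] = sub
    out = HaplotypeMatrix(chrom=m.chrom, positions=m.positions.copy(),
                          alleles=alleles, sample_ids=list(m.sample_ids),
                          sample_pops=list(m.sample_pops))
    daf = out.derived_frequency()
    daf[~known] = np.nan
    return PolarizedMatrix(matrix=out, known=known, daf=daf)
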