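"""Extended-haplotype-homozygosity statistics: iHS, nSL, XP-EHH and Rsb.

Within one population, iHS and nSL contrast how far haplotypes carrying the
derived allele at a core SNP remain identical compared with haplotypes
carrying the ancestral allele — in physical distance (iHS) or in number of
segregating sites (nSL).  Between populations, XP-EHH and Rsb contrast the
allele-pooled haplotype homozygosity decay (iES, Sabeti normalization, resp.
inES, Tang normalization) around the same core SNP.  Raw log-ratios are
standardized — within derived-allele-frequency bins for iHS/nSL, genome-wide
for XP-EHH/Rsb — and converted to Gaussian tail P values.

All homozygosity curves share one pair-counting engine: haplotypes are grouped
by identity over the interval from the core to the current offset, a
haplotype leaving the comparison at its first missing genotype, and the
fraction of still-identical pairs (out of the pairs available at the core) is
recorded per offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .haplo_io import MISSING, HaplotypeMatrix
from .ancestral import PolarizedMatrix

DEFAULT_EHH_CUTOFF = 0.05
DEFAULT_MAF = 0.05


@dataclass
class Arm:
    """One directional arm of a homozygosity profile, core point included.

    ``offsets_bp`` are non-negative distances from the core (first entry 0),
    ``offsets_sites`` the corresponding segregating-site counts, ``values``
    the normalized homozygosity (1 at the core, non-increasing).
    ``reached_edge`` marks an arm that ran off the matrix before decaying
    below the requested truncation level.
    """

    offsets_bp: np.ndarray
    offsets_sites: np.ndarray
    values: np.ndarray
    reached_edge: bool


@dataclass
class EHHProfile:
    core_index: int
    allele: str  # "ancestral" | "derived" | "pooled"
    left: Arm
    right: Arm
    n_carriers: int


def _extend_arm(alleles: np.ndarray, positions: np.ndarray, core: int,
                members: np.ndarray, init_ids: np.ndarray, step: int,
                trunc: float, biased: bool = False,
                max_steps: int | None = None) -> Arm:
    """Walk outward from ``core`` refining identity groups site by site.

    ``members`` masks the haplotypes taking part; ``init_ids`` their initial
    grouping at the core (all-zero for allele-specific EHH, the core allele
    for pooled EHHS).  Homozygosity is the fraction of member pairs still
    identical (unbiased, pair counts over the fixed core denominator) or the
    biased form sum((n_g/n0)^2); either is normalized by its core value.
    """
    n0 = int(members.sum())
    npairs0 = n0 * (n0 - 1) / 2.0
    if n0 < 2:
        raise ValueError("need at least 2 haplotypes to extend a profile")
    ids = init_ids[members].astype(np.int64)
    alive = np.ones(n0, dtype=bool)
    rows = np.flatnonzero(members)

    def hom() -> float:
        counts = np.bincount(ids[alive]) if alive.any() else np.array([0])
        if biased:
            return float(np.sum((counts / n0) ** 2))
        return float(np.sum(counts * (counts - 1) / 2.0) / npairs0)

    h0 = hom()
    if h0 == 0:
        raise ValueError("zero homozygosity at the core")
    offs_bp = [0.0]
    offs_sites = [0]
    values = [1.0]
    n_sites = alleles.shape[1]
    j = core + step
    reached_edge = True
    k = 0
    while 0 <= j < n_sites and (max_steps is None or k < max_steps):
        k += 1
        col = alleles[rows, j]
        alive &= col != MISSING
        key = ids * 2 + np.where(col == MISSING, 0, col)
        _, ids = np.unique(key, return_inverse=True)
        v = hom() / h0
        offs_bp.append(abs(float(positions[j] - positions[core])))
        offs_sites.append(k)
        values.append(v)
        if v < trunc or v == 0.0:
            reached_edge = False
            break
        j += step
    return Arm(np.asarray(offs_bp), np.asarray(offs_sites),
               np.asarray(values), reached_edge)


def ehh_profile(m: HaplotypeMatrix, core: int, allele: str,
                trunc: float = 0.0) -> EHHProfile:
    """EHH curve for carriers of one allele (``"ancestral"``/``"derived"``,
    i.e. coded 0/1) at the core site.

    Extension stops once EHH drops below ``trunc`` (the first sub-threshold
    point is kept, for interpolation) or at the matrix edge.
    """
    a = {"ancestral": 0, "derived": 1}[allele]
    carriers = m.alleles[:, core] == a
    if carriers.sum() < 2:
        raise ValueError(
            f"fewer than 2 carriers of the {allele} allele at site {core}")
    init = np.zeros(m.n_hap, dtype=np.int64)
    left = _extend_arm(m.alleles, m.positions, core, carriers, init, -1, trunc)
    right = _extend_arm(m.alleles, m.positions, core, carriers, init, +1, trunc)
    return EHHProfile(core, allele, left, right, int(carriers.sum()))


def ies_profile(m: HaplotypeMatrix, core: int,
                normalization: str = "sabeti",
                trunc: float = 0.0) -> EHHProfile:
    """Allele-pooled (site) homozygosity profile EHHS.

    All haplotypes non-missing at the core take part, initially grouped by
    their core allele, so the unnormalized core value is the allelic
    homozygosity.  ``"sabeti"`` uses unbiased pair-count homozygosity,
    ``"tang"`` the biased form; both are normalized to 1 at the core.
    """
    if normalization not in ("sabeti", "tang"):
        raise ValueError(f"unknown normalization {normalization!r}")
    members = m.alleles[:, core] != MISSING
    if members.sum() < 2:
        raise ValueError(f"fewer than 2 genotyped haplotypes at site {core}")
    init = np.where(m.alleles[:, core] == 1, 1, 0).astype(np.int64)
    biased = normalization == "tang"
    left = _extend_arm(m.alleles, m.positions, core, members, init, -1,
                       trunc, biased=biased)
    right = _extend_arm(m.alleles, m.positions, core, members, init, +1,
                        trunc, biased=biased)
    return EHHProfile(core, "pooled", left, right, int(members.sum()))


def _integrate_arm(arm: Arm, cutoff: float) -> tuple[float, bool]:
    x, v = arm.offsets_bp, arm.values
    area = 0.0
    for k in range(1, len(v)):
        if v[k] >= cutoff:
            area += (v[k - 1] + v[k]) / 2.0 * (x[k] - x[k - 1])
        else:
            # linear interpolation to the cutoff crossing
            frac = (v[k - 1] - cutoff) / (v[k - 1] - v[k])
            area += (v[k - 1] + cutoff) / 2.0 * frac * (x[k] - x[k - 1])
            return area, False
    return area, arm.reached_edge


def integrate_profile(profile: EHHProfile,
                      cutoff: float = DEFAULT_EHH_CUTOFF) -> tuple[float, bool]:
    """Trapezoidal integral (bp · homozygosity) of both arms, truncated at
    the first offset where the curve falls below ``cutoff`` (sub-cutoff
    segment integrated down to the interpolated crossing).

    Returns ``(area, truncated_at_edge)``; the flag is True when either arm
    ran off the matrix before reaching the cutoff.
    """
    al, el = _integrate_arm(profile.left, cutoff)
    ar, er = _integrate_arm(profile.right, cutoff)
    return al + ar, el or er


#: Cap on nSL tract extension per side, in segregating sites (the default
#: of the standard calculator); pairs still identical at the cap count the
#: capped length.
NSL_MAX_EXTEND = 100


def _sl_mean(m: HaplotypeMatrix, core: int, allele_code: int,
             max_extend: int = NSL_MAX_EXTEND) -> float:
    """Mean over carrier pairs of identity-tract length in segregating sites.

    The tract including the core has length 1 + (consecutive identical sites
    leftward) + (rightward), each side capped at ``max_extend``; averaging
    over pairs equals 1 plus the sum of the EHH curve over site offsets on
    each side.
    """
    carriers = m.alleles[:, core] == allele_code
    if carriers.sum() < 2:
        raise ValueError(f"fewer than 2 carriers at site {core}")
    init = np.zeros(m.n_hap, dtype=np.int64)
    sl = 1.0
    for step in (-1, +1):
        arm = _extend_arm(m.alleles, m.positions, core, carriers, init, step,
                          trunc=0.0, max_steps=max_extend)
        sl += float(arm.values[1:].sum())
    return sl


def ihs_raw(m: HaplotypeMatrix, core: int,
            cutoff: float = DEFAULT_EHH_CUTOFF) -> float:
    """Unstandardized iHS: ln(iHH_ancestral / iHH_derived).

    ``m`` must be polarized (0 = ancestral).  NaN when either allele class
    has fewer than 2 carriers or zero integrated EHH.
    """
    try:
        pa = ehh_profile(m, core, "ancestral", trunc=cutoff)
        pd_ = ehh_profile(m, core, "derived", trunc=cutoff)
    except ValueError:
        return np.nan
    ihh_a, _ = integrate_profile(pa, cutoff)
    ihh_d, _ = integrate_profile(pd_, cutoff)
    if ihh_a <= 0 or ihh_d <= 0:
        return np.nan
    return float(np.log(ihh_a / ihh_d))


def nsl_raw(m: HaplotypeMatrix, core: int,
            max_extend: int = NSL_MAX_EXTEND) -> float:
    """Unstandardized nSL: ln(SL_ancestral / SL_derived), tract lengths in
    number of segregating sites (each side capped at ``max_extend``)."""
    try:
        sl_a = _sl_mean(m, core, 0, max_extend)
        sl_d = _sl_mean(m, core, 1, max_extend)
    except ValueError:
        return np.nan
    if sl_a <= 0 or sl_d <= 0:
        return np.nan
    return float(np.log(sl_a / sl_d))


def _ies(m: HaplotypeMatrix, core: int, normalization: str,
         cutoff: float) -> float:
    try:
        prof = ies_profile(m, core, normalization, trunc=cutoff)
    except ValueError:
        return np.nan
    area, _ = integrate_profile(prof, cutoff)
    return area


def xpehh_raw(m_pop1: HaplotypeMatrix, m_pop2: HaplotypeMatrix, core: int,
              cutoff: float = DEFAULT_EHH_CUTOFF) -> float:
    """Unstandardized XP-EHH: ln(iES_pop1 / iES_pop2), Sabeti normalization.

    Positive values mean longer haplotypes (selection) in population 1; by
    convention population 1 is the cultivated and 2 the wild population.
    """
    i1 = _ies(m_pop1, core, "sabeti", cutoff)
    i2 = _ies(m_pop2, core, "sabeti", cutoff)
    if not (i1 > 0 and i2 > 0):
        return np.nan
    return float(np.log(i1 / i2))


def rsb_raw(m_pop1: HaplotypeMatrix, m_pop2: HaplotypeMatrix, core: int,
            cutoff: float = DEFAULT_EHH_CUTOFF) -> float:
    """Unstandardized Rsb: ln(inES_pop1 / inES_pop2), Tang normalization."""
    i1 = _ies(m_pop1, core, "tang", cutoff)
    i2 = _ies(m_pop2, core, "tang", cutoff)
    if not (i1 > 0 and i2 > 0):
        return np.nan
    return float(np.log(i1 / i2))


# ---------------------------------------------------------------------------
# Standardization and P values
# ---------------------------------------------------------------------------

#: Symmetric trimming fraction (per tail) for robust standardization and the
#: normal-consistency factor for the sd of the middle 80% of a Gaussian.
TRIM_FRACTION = 0.10
_TRIM_SD_FACTOR = 1.513


def _location_scale(vals: np.ndarray, robust: bool) -> tuple[float, float]:
    if not robust or vals.size < 10:
        return float(vals.mean()), float(vals.std(ddof=1))
    lo, hi = np.quantile(vals, [TRIM_FRACTION, 1 - TRIM_FRACTION])
    mid = vals[(vals >= lo) & (vals <= hi)]
    return float(mid.mean()), float(mid.std(ddof=1) * _TRIM_SD_FACTOR)


def standardize(raw: np.ndarray, freqs: np.ndarray | None = None,
                mode: str = "binned", bin_width: float = 0.05,
                min_bin_size: int = 20, robust: bool = False) -> np.ndarray:
    """Z-standardize raw scores, optionally within derived-frequency bins.

    Binned mode (iHS/nSL): sites are binned by derived allele frequency with
    the given width; bins holding fewer than ``min_bin_size`` scored sites
    are merged with their right neighbour (the last short bin merges left).
    Global mode (XP-EHH/Rsb): one genome-wide mean/sd.  Sample (n-1) sd.
    NaN raws pass through as NaN z.

    With ``robust``, location and scale are the mean and (normal-consistent)
    sd of the middle 80% of each bin's scores.  On a panel whose selected
    fraction is not negligible — unavoidable when the simulated genome is
    small — the plain sd is inflated by the very outliers the scan is meant
    to find; trimming restores the neutral scale while leaving the null
    calibration intact.
    """
    raw = np.asarray(raw, dtype=float)
    z = np.full(raw.shape, np.nan)
    ok = np.isfinite(raw)
    if mode == "global":
        vals = raw[ok]
        if vals.size < 2:
            raise ValueError("need at least 2 finite scores to standardize")
        loc, sd = _location_scale(vals, robust)
        if sd == 0:
            raise ValueError("zero standard deviation in global bin")
        z[ok] = (raw[ok] - loc) / sd
        return z
    if mode != "binned":
        raise ValueError(f"unknown mode {mode!r}")
    if freqs is None:
        raise ValueError("binned standardization requires derived frequencies")
    freqs = np.asarray(freqs, dtype=float)
    ok &= np.isfinite(freqs)
    n_bins = int(np.ceil(1.0 / bin_width))
    safe_freqs = np.where(np.isfinite(freqs), freqs, 0.0)
    bin_of = np.minimum((safe_freqs / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(bin_of[ok], minlength=n_bins)
    # greedy left-to-right merge of short bins into their right neighbour
    group = np.zeros(n_bins, dtype=int)
    g, acc = 0, 0
    for b in range(n_bins):
        group[b] = g
        acc += counts[b]
        if acc >= min_bin_size:
            g, acc = g + 1, 0
    if acc > 0 and g > 0:  # trailing short group merges left
        group[group == g] = g - 1
    site_group = group[bin_of]
    for gg in np.unique(site_group[ok]):
        sel = ok & (site_group == gg)
        vals = raw[sel]
        if vals.size < 2:
            raise ValueError(f"standardization bin {gg} has <2 scores")
        loc, sd = _location_scale(vals, robust)
        if sd == 0:
            raise ValueError(f"zero standard deviation in frequency bin {gg}")
        z[sel] = (vals - loc) / sd
    return z


def scores_to_p(z: np.ndarray, sided: str = "two") -> np.ndarray:
    """Gaussian tail P values for standardized scores.

    two-sided: 2*Phi(-|z|); one-sided: Phi(-z) (upper tail — the
    selection-in-population-1 direction for XP-EHH/Rsb).
    """
    z = np.asarray(z, dtype=float)
    if sided == "two":
        return 2.0 * norm.sf(np.abs(z))
    if sided == "one":
        return norm.sf(z)
    raise ValueError(f"unknown sidedness {sided!r}")


# ---------------------------------------------------------------------------
# Whole-matrix scan drivers
# ---------------------------------------------------------------------------

def _scorable_sites(m: HaplotypeMatrix, maf: float) -> np.ndarray:
    freq = m.derived_frequency()
    mac_ok = np.minimum(freq, 1 - freq) >= maf
    return np.flatnonzero(np.nan_to_num(mac_ok))


def raw_within(pol: PolarizedMatrix, method: str = "ihs",
               maf: float = DEFAULT_MAF,
               cutoff: float = DEFAULT_EHH_CUTOFF) -> pd.DataFrame:
    """Unstandardized iHS or nSL over all scorable sites of one polarized
    population matrix (one chromosome).

    Sites without an ancestral call or below the pooled MAF threshold are
    skipped.  Returns chrom, pos, method, raw, derived_freq.
    """
    if method not in ("ihs", "nsl"):
        raise ValueError(f"unknown within-population method {method!r}")
    m = pol.matrix
    idx = [i for i in _scorable_sites(m, maf) if pol.known[i]]
    raw = np.full(m.n_sites, np.nan)
    for i in idx:
        raw[i] = ihs_raw(m, i, cutoff) if method == "ihs" else nsl_raw(m, i)
    keep = np.isfinite(raw)
    return pd.DataFrame({
        "chrom": m.chrom, "pos": m.positions[keep], "method": method,
        "raw": raw[keep], "derived_freq": pol.daf[keep],
    })


def raw_between(m_pop1: HaplotypeMatrix, m_pop2: HaplotypeMatrix,
                method: str = "xpehh", maf: float = DEFAULT_MAF,
                cutoff: float = DEFAULT_EHH_CUTOFF) -> pd.DataFrame:
    """Unstandardized XP-EHH or Rsb between two population matrices sharing
    their site grid (one chromosome).

    Cores must be polymorphic (MAF >= threshold) in the pooled sample.
    """
    if method not in ("xpehh", "rsb"):
        raise ValueError(f"unknown between-population method {method!r}")
    if not np.array_equal(m_pop1.positions, m_pop2.positions):
        raise ValueError("population matrices must share their site grid")
    pooled = HaplotypeMatrix(
        chrom=m_pop1.chrom, positions=m_pop1.positions,
        alleles=np.vstack([m_pop1.alleles, m_pop2.alleles]),
        sample_ids=m_pop1.sample_ids + m_pop2.sample_ids,
        sample_pops=m_pop1.sample_pops + m_pop2.sample_pops)
    idx = _scorable_sites(pooled, maf)
    fn = xpehh_raw if method == "xpehh" else rsb_raw
    raw = np.full(m_pop1.n_sites, np.nan)
    for i in idx:
        raw[i] = fn(m_pop1, m_pop2, i, cutoff)
    keep = np.isfinite(raw)
    freq = pooled.derived_frequency()
    return pd.DataFrame({
        "chrom": m_pop1.chrom, "pos": m_pop1.positions[keep], "method": method,
        "raw": raw[keep], "derived_freq": freq[keep],
    })


def finalize_scores(raw_frames, bin_width: float = 0.05,
                    min_bin_size: int = 20,
                    sided: str = "two", robust: bool = False) -> pd.DataFrame:
    """Standardize pooled raw-score frames (one method, >= 1 chromosomes)
    and attach Gaussian P values.

    iHS/nSL are standardized within derived-allele-frequency bins, XP-EHH
    and Rsb genome-wide — pooling across chromosomes before standardization,
    as a genome-wide scan requires.
    """
    frames = [raw_frames] if isinstance(raw_frames, pd.DataFrame) else list(raw_frames)
    df = pd.concat(frames, ignore_index=True)
    methods = df["method"].unique()
    if len(methods) != 1:
        raise ValueError("finalize_scores standardizes one method at a time")
    raw = df["raw"].to_numpy()
    if methods[0] in ("ihs", "nsl"):
        z = standardize(raw, df["derived_freq"].to_numpy(), mode="binned",
                        bin_width=bin_width, min_bin_size=min_bin_size,
                        robust=robust)
    else:
        z = standardize(raw, mode="global", robust=robust)
    df["z"] = z
    df["p"] = scores_to_p(z, sided)
    return df


def scan_within(pol: PolarizedMatrix, method: str = "ihs",
                maf: float = DEFAULT_MAF,
                cutoff: float = DEFAULT_EHH_CUTOFF,
                bin_width: float = 0.05, min_bin_size: int = 20,
                sided: str = "two") -> pd.DataFrame:
    """Single-chromosome convenience: ``raw_within`` + ``finalize_scores``."""
    return finalize_scores(raw_within(pol, method, maf, cutoff),
                           bin_width=bin_width, min_bin_size=min_bin_size,
                           sided=sided)


def scan_between(m_pop1: HaplotypeMatrix, m_pop2: HaplotypeMatrix,
                 method: str = "xpehh", maf: float = DEFAULT_MAF,
                 cutoff: float = DEFAULT_EHH_CUTOFF,
                 sided: str = "two") -> pd.DataFrame:
    """Single-chromosome convenience: ``raw_between`` + ``finalize_scores``."""
    return finalize_scores(raw_between(m_pop1, m_pop2, method, maf, cutoff),
                           sided=sided)
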