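"""Phased haplotype matrices: VCF input, quality control and LD decay.

The central container is :class:`HaplotypeMatrix` — a ``(2·n_samples, n_sites)``
int8 array of 0/1/missing haplotype alleles for one chromosome, carrying the
physical positions and a population label per sample.  Every scan statistic in
this package operates on this substrate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing haplotype allele.
MISSING: int = -1


@dataclass
class HaplotypeMatrix:
    """Binary phased haplotypes × ordered biallelic sites for one chromosome.

    Parameters
    ----------
    chrom
        Chromosome identifier.
    positions
        Strictly increasing 1-based physical coordinates (bp), one per site.
    alleles
        ``(n_hap, n_sites)`` int8 array with entries 0 (REF), 1 (ALT) or
        :data:`MISSING`.  Rows ``2*i`` and ``2*i + 1`` are the two phased
        haplotypes of sample ``i``.
    sample_ids
        One identifier per diploid sample (``n_hap = 2 * len(sample_ids)``).
    sample_pops
        Population label per sample, aligned with ``sample_ids``.
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    sample_ids: list[str]
    sample_pops: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.int8)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        n_hap, n_sites = self.alleles.shape
        if n_hap != 2 * len(self.sample_ids):
            raise ValueError(
                f"{n_hap} haplotype rows for {len(self.sample_ids)} samples; "
                "every sample must contribute exactly 2 haplotypes"
            )
        if len(self.sample_pops) != len(self.sample_ids):
            raise ValueError("sample_pops must align with sample_ids")
        if len(self.positions) != n_sites:
            raise ValueError("positions must align with allele columns")
        if n_sites and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("allele entries must be 0, 1 or MISSING")

    # -- conveniences -------------------------------------------------------
    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def haplotype_ids(self) -> list[str]:
        return [f"{s}_{k}" for s in self.sample_ids for k in (1, 2)]

    @property
    def hap_pops(self) -> np.ndarray:
        """Population label per haplotype row."""
        return np.repeat(np.asarray(self.sample_pops, dtype=object), 2)

    def take_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        idx = np.asarray(idx)
        return replace(self, positions=self.positions[idx],
                       alleles=self.alleles[:, idx])

    def take_samples(self, idx: np.ndarray) -> "HaplotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        rows = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
        return replace(
            self,
            alleles=self.alleles[rows],
            sample_ids=[self.sample_ids[i] for i in idx],
            sample_pops=[self.sample_pops[i] for i in idx],
        )

    def subset_population(self, pop: str) -> "HaplotypeMatrix":
        idx = np.flatnonzero(np.asarray(self.sample_pops, dtype=object) == pop)
        if idx.size == 0:
            raise ValueError(f"no samples in population {pop!r}")
        return self.take_samples(idx)

    def derived_frequency(self) -> np.ndarray:
        """Frequency of allele 1 per site over non-missing haplotypes."""
        a = self.alleles
        obs = (a != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(obs > 0, (a == 1).sum(axis=0) / obs, np.nan)


def read_population_table(path) -> dict[str, str]:
    """Read a 2-column TSV (sample, population) into a mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (sample, population)")
    # Tolerate a header row naming the columns.
    if df.iloc[0, 0].lower() in {"sample", "sample_id", "id"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_haplotypes(vcf_path, pop_table, region: str | None = None,
                    ) -> dict[str, HaplotypeMatrix]:
    """Read phased biallelic SNPs from a VCF into one matrix per chromosome.

    ``pop_table`` maps sample → population; it may cover a subset of the VCF
    samples, in which case only those samples are loaded.  Multiallelic and
    non-SNP records are skipped (counted in the log).  Any unphased genotype
    raises, naming the record: every statistic downstream assumes phase.
    """
    from cyvcf2 import VCF

    if isinstance(pop_table, (str, bytes)) or hasattr(pop_table, "__fspath__"):
        pop_table = read_population_table(pop_table)
    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    missing_samples = [s for s in pop_table if s not in vcf_samples]
    if missing_samples:
        raise ValueError(
            f"samples in population table absent from VCF: {missing_samples}"
        )
    keep = [s for s in vcf_samples if s in pop_table]
    vcf.set_samples(keep)
    keep = list(vcf.samples)  # cyvcf2 preserves VCF order
    pops = [pop_table[s] for s in keep]

    per_chrom: dict[str, tuple[list[int], list[np.ndarray]]] = {}
    n_skipped = 0
    it = vcf(region) if region else vcf
    for var in it:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gt = np.asarray(var.genotypes)  # (n_samples, 3): a0, a1, phased
        col = np.empty(2 * len(keep), dtype=np.int8)
        a = gt[:, :2].astype(np.int8)
        miss = a < 0
        phased = gt[:, 2].astype(bool)
        unphased_het = ~phased & ~miss.all(axis=1)
        if unphased_het.any():
            s = keep[int(np.flatnonzero(unphased_het)[0])]
            raise ValueError(
                f"unphased genotype at {var.CHROM}:{var.POS} (sample {s}); "
                "phased input is required"
            )
        a[miss] = MISSING
        col[0::2] = a[:, 0]
        col[1::2] = a[:, 1]
        positions, cols = per_chrom.setdefault(var.CHROM, ([], []))
        positions.append(var.POS)
        cols.append(col)
    if n_skipped:
        logger.info("skipped %d multiallelic/non-SNP records", n_skipped)

    out = {}
    for chrom, (positions, cols) in per_chrom.items():
        out[chrom] = HaplotypeMatrix(
            chrom=chrom,
            positions=np.asarray(positions, dtype=np.int64),
            alleles=np.stack(cols, axis=1),
            sample_ids=keep,
            sample_pops=pops,
        )
    return out


def write_vcf(matrices, path, ref_alt: dict | None = None) -> None:
    """Write matrices back to a minimal phased VCF 4.2 (deterministic output).

    ``ref_alt`` optionally maps ``(chrom, pos) -> (REF, ALT)`` bases; sites
    without an entry are written as A/T placeholders.
    """
    if isinstance(matrices, HaplotypeMatrix):
        matrices = {matrices.chrom: matrices}
    first = next(iter(matrices.values()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for chrom in matrices:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(first.sample_ids) + "\n")
        for chrom, m in matrices.items():
            code = {0: "0", 1: "1", MISSING: "."}
            for j in range(m.n_sites):
                pos = int(m.positions[j])
                ref, alt = (ref_alt or {}).get((chrom, pos), ("A", "T"))
                col = m.alleles[:, j]
                gts = "\t".join(
                    f"{code[int(col[2 * i])]}|{code[int(col[2 * i + 1])]}"
                    for i in range(len(m.sample_ids))
                )
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Counts removed by each sequential QC rule."""

    n_individuals_removed: int
    n_sites_missingness: int
    n_sites_singleton: int
    individuals_removed: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["individual_missingness", "site_missingness", "singleton"],
                "removed": [self.n_individuals_removed, self.n_sites_missingness,
                            self.n_sites_singleton],
            }
        )


def qc_filter(m: HaplotypeMatrix, max_indiv_missing: float = 0.15,
              max_site_missing: float = 0.10, drop_singletons: bool = True,
              ) -> tuple[HaplotypeMatrix, QCReport]:
    """Apply sequential panel QC.

    Individuals whose missing fraction (over both haplotypes) exceeds
    ``max_indiv_missing`` are removed first; then sites with missing fraction
    above ``max_site_missing`` or carrying a singleton minor allele (minor
    allele count exactly 1, computed after individual removal) are removed.
    """
    for thr in (max_indiv_missing, max_site_missing):
        if not 0 <= thr <= 1:
            raise ValueError("missingness thresholds must be in [0, 1]")
    miss = m.alleles == MISSING
    # fraction over both haplotype rows of each individual
    ind_miss = miss.reshape(len(m.sample_ids), 2, -1).mean(axis=(1, 2))
    keep_ind = np.flatnonzero(ind_miss <= max_indiv_missing)
    removed_ids = [m.sample_ids[i] for i in np.flatnonzero(ind_miss > max_indiv_missing)]
    m2 = m.take_samples(keep_ind) if len(keep_ind) < len(m.sample_ids) else m

    miss2 = m2.alleles == MISSING
    site_miss_frac = miss2.mean(axis=0)
    bad_missing = site_miss_frac > max_site_missing
    n_alt = (m2.alleles == 1).sum(axis=0)
    n_obs = (~miss2).sum(axis=0)
    mac = np.minimum(n_alt, n_obs - n_alt)
    singleton = (mac == 1) if drop_singletons else np.zeros(m2.n_sites, bool)
    keep_sites = ~(bad_missing | singleton)
    report = QCReport(
        n_individuals_removed=len(removed_ids),
        n_sites_missingness=int(bad_missing.sum()),
        n_sites_singleton=int((singleton & ~bad_missing).sum()),
        individuals_removed=removed_ids,
    )
    out = m2.take_sites(np.flatnonzero(keep_sites))
    if out.n_sites == 0 or out.n_hap == 0:
        raise ValueError("QC filtering removed all data")
    return out, report


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

@dataclass
class LDDecayCurve:
    """Mean r² per physical-distance bin, with the half-maximum distance used
    for haplotype-block sizing."""

    bin_upper_bp: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    max_mean_r2: float
    half_max_distance_bp: float
    n_skipped_monomorphic: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_upper_bp": self.bin_upper_bp,
                             "mean_r2": self.mean_r2, "n_pairs": self.n_pairs})


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """r² between two haplotype allele vectors, pairwise-complete.

    Returns NaN when either site is monomorphic among complete haplotypes.
    """
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok].astype(float), y[ok].astype(float)
    n = x.size
    if n < 2:
        return np.nan
    p_a, p_b = x.mean(), y.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return np.nan
    d = (x * y).mean() - p_a * p_b
    return d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))


def half_max_distance(bin_upper_bp: np.ndarray, mean_r2: np.ndarray) -> float:
    """Smallest bin distance at which mean r² has decayed to half its maximum."""
    valid = ~np.isnan(mean_r2)
    if not valid.any():
        return float("nan")
    max_r2 = np.nanmax(mean_r2)
    hit = valid & (mean_r2 <= max_r2 / 2)
    return float(bin_upper_bp[np.flatnonzero(hit)[0]]) if hit.any() else float("nan")


def ld_decay(m: HaplotypeMatrix, max_dist_bp: int, bin_bp: int) -> LDDecayCurve:
    """LD decay curve: mean r² of site pairs binned by physical distance.

    r² is computed on haplotype alleles with pairwise-complete observations;
    pairs where either site is monomorphic among the complete haplotypes are
    skipped (r² undefined) and counted.
    """
    if m.n_sites < 2:
        raise ValueError("ld_decay requires at least 2 sites")
    pos = m.positions
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    skipped = 0
    for i in range(m.n_sites - 1):
        j_hi = np.searchsorted(pos, pos[i] + max_dist_bp, side="right")
        for j in range(i + 1, j_hi):
            r2 = pairwise_r2(m.alleles[:, i], m.alleles[:, j])
            if np.isnan(r2):
                skipped += 1
                continue
            b = min(int((pos[j] - pos[i] - 1) // bin_bp), n_bins - 1)
            sums[b] += r2
            counts[b] += 1
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    uppers = (np.arange(1, n_bins + 1) * bin_bp).astype(np.int64)
    return LDDecayCurve(
        bin_upper_bp=uppers,
        mean_r2=mean_r2,
        n_pairs=counts,
        max_mean_r2=float(np.nanmax(mean_r2)) if counts.any() else float("nan"),
        half_max_distance_bp=half_max_distance(uppers, mean_r2),
        n_skipped_monomorphic=skipped,
    )
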