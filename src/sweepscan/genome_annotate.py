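"""Genomic context of selective SNPs: gene body, promoter or intergenic.

Gene models come from a GFF3; the promoter is the 2-kb stretch immediately
5' of the transcription start site (upstream of ``start`` on the + strand,
downstream of ``end`` on the - strand), clipped at chromosome bounds.
Following the convention used for the counts this mirrors, promoter sites
are a subset of the intergenic total: a site is genic, or intergenic
(possibly flagged as promoter).  A disjoint three-way labelling is offered.
Overlap with externally supplied sweep regions (BED) is a plain half-open
containment test.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    def promoter(self, length: int = 2000,
                 chrom_len: int | None = None) -> tuple[int, int] | None:
        """1-based inclusive promoter interval, or None if fully clipped."""
        if self.strand == "+":
            lo, hi = self.start - length, self.start - 1
        else:
            lo, hi = self.end + 1, self.end + length
        lo = max(lo, 1)
        if chrom_len is not None:
            hi = min(hi, chrom_len)
        return (lo, hi) if lo <= hi else None


def load_gene_models(gff_path) -> list[GeneModel]:
    """Parse gene features from a GFF3 file.

    Lines are pre-validated so a malformed record raises with its line
    number; parsing proper is delegated to gffutils.
    """
    import gffutils

    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{gff_path}:{lineno}: expected 9 columns")
            try:
                s, e = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(
                    f"{gff_path}:{lineno}: non-integer coordinates") from None
            if s > e:
                raise ValueError(f"{gff_path}:{lineno}: start > end")
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene"):
        genes.append(GeneModel(gene_id=feat.id, chrom=feat.seqid,
                               start=feat.start, end=feat.end,
                               strand=feat.strand))
    return genes


def classify_sites(sites: pd.DataFrame, genes: list[GeneModel],
                   promoter_len: int = 2000, disjoint: bool = False,
                   chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Label each site (chrom, pos 1-based) genic / promoter / intergenic.

    Genic wins over promoter.  By default promoter sites also count as
    intergenic (column ``intergenic`` is True for them); with ``disjoint``
    the three labels are exclusive.  Unknown chromosomes (absent from every
    gene model) are an error listing the offenders, unless there are no
    gene models at all.
    """
    known_chroms = {g.chrom for g in genes}
    if known_chroms:
        offenders = sorted(set(sites["chrom"]) - known_chroms)
        if offenders:
            raise ValueError(f"sites on chromosomes without gene models: {offenders}")
    labels = []
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        genic = any(g.chrom == chrom and g.start <= pos <= g.end for g in genes)
        prom = False
        if not genic:
            for g in genes:
                if g.chrom != chrom:
                    continue
                iv = g.promoter(promoter_len,
                                (chrom_lengths or {}).get(chrom))
                if iv and iv[0] <= pos <= iv[1]:
                    prom = True
                    break
        if genic:
            label = "genic"
        elif prom:
            label = "promoter"
        else:
            label = "intergenic"
        labels.append(label)
    out = sites.copy()
    out["label"] = labels
    out["genic"] = out["label"] == "genic"
    out["promoter"] = out["label"] == "promoter"
    if disjoint:
        out["intergenic"] = out["label"] == "intergenic"
    else:
        out["intergenic"] = out["label"].isin(("promoter", "intergenic"))
    return out


def count_labels(classified: pd.DataFrame) -> dict[str, int]:
    return {
        "genic": int(classified["genic"].sum()),
        "promoter": int(classified["promoter"].sum()),
        "intergenic": int(classified["intergenic"].sum()),
        "total": len(classified),
    }


def read_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return bed


def region_overlap(sites: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Sites (1-based pos) falling inside BED regions (0-based half-open).

    A site at 1-based position p occupies 0-based coordinate p-1; it is
    inside [start, end) iff start <= p-1 < end.  Returns the subset of
    ``sites`` that overlap, with the matching region's coordinates.
    """
    rows = []
    for idx, (chrom, pos) in enumerate(zip(sites["chrom"], sites["pos"])):
        p0 = pos - 1
        for r in regions.itertuples(index=False):
            if r.chrom == chrom and r.start <= p0 < r.end:
                rows.append((chrom, pos, r.start, r.end))
                break
    return pd.DataFrame(rows, columns=["chrom", "pos", "region_start",
                                       "region_end"])
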