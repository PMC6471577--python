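"""File I/O: FASTA, GTF, VCF 4.x and the pipeline's TSV tables.

Coordinates are 0-based half-open in memory and 1-based inclusive on disk
(GTF, VCF); conversion happens here and nowhere else.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cascade import VariantSite
from .context import GeneModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gtf",
    "write_gtf",
    "read_vcf",
    "write_vcf",
    "read_junction_counts",
    "write_junction_counts",
    "read_known_sites",
    "write_known_sites",
    "read_groups",
    "write_groups",
    "write_bed",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GTF (1-based inclusive on disk)
# ---------------------------------------------------------------------------

def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    lines = []
    for gene in genes:
        attrs = (
            f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1"; '
            f'gene_biotype "{"protein_coding" if gene.biotype == "coding" else "ncRNA"}";'
        )
        for s, e in gene.exons:
            lines.append(
                "\t".join(
                    [gene.chrom, "editome", "exon", str(s + 1), str(e),
                     ".", gene.strand, ".", attrs]
                )
            )
        if gene.cds is not None:
            cs, ce = gene.cds
            for s, e in gene.exons:
                os_, oe = max(s, cs), min(e, ce)
                if os_ < oe:
                    lines.append(
                        "\t".join(
                            [gene.chrom, "editome", "CDS", str(os_ + 1), str(oe),
                             ".", gene.strand, "0", attrs]
                        )
                    )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF (exon + CDS features, one transcript per
    gene)."""
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    genes: list[GeneModel] = []
    for gene_id, sub in df.groupby("gene_id", sort=True):
        chrom = str(sub["Chromosome"].iloc[0])
        strand = str(sub["Strand"].iloc[0])
        biotype_col = sub["gene_biotype"] if "gene_biotype" in sub else None
        biotype = "coding"
        if biotype_col is not None and str(biotype_col.iloc[0]) == "ncRNA":
            biotype = "ncRNA"
        exons = sorted(
            (int(r.Start), int(r.End))  # pyranges is already 0-based half-open
            for r in sub[sub["Feature"] == "exon"].itertuples()
        )
        cds_rows = sub[sub["Feature"] == "CDS"]
        cds = None
        if len(cds_rows):
            cds = (int(cds_rows["Start"].min()), int(cds_rows["End"].max()))
        genes.append(
            GeneModel(
                gene_id=str(gene_id), chrom=chrom, strand=strand,
                exons=tuple(exons), cds=cds, biotype=biotype,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth of base coverage">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank-sum">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank-sum">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Sample read depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">',
]


def write_vcf(
    variants: Sequence[VariantSite],
    samples: Sequence[str],
    path: str | Path,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write per-sample variant calls as uncompressed VCF 4.2."""
    import pysam

    header = pysam.VariantHeader()
    if contigs is None:
        lengths: dict[str, int] = {}
        for v in variants:
            lengths[v.chrom] = max(lengths.get(v.chrom, 0), v.pos + 1000)
        contigs = lengths
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos,
                alleles=(v.ref, v.alt), id=v.known_id,
            )
            rec.info["DP"] = int(round(v.total_depth))
            rec.info["MQ"] = float(v.mq)
            rec.info["QD"] = float(v.qd)
            if v.mq_rank_sum is not None:
                rec.info["MQRankSum"] = float(v.mq_rank_sum)
            if v.read_pos_rank_sum is not None:
                rec.info["ReadPosRankSum"] = float(v.read_pos_rank_sum)
            for i, s in enumerate(samples):
                rec.samples[s]["DP"] = int(v.depths[i])
                rec.samples[s]["AD"] = (
                    int(v.depths[i] - v.alt_counts[i]),
                    int(v.alt_counts[i]),
                )
            vcf.write(rec)


def read_vcf(path: str | Path) -> tuple[list[VariantSite], list[str]]:
    """Read variant calls back into :class:`VariantSite` objects.

    Returns the sites and the sample order.  Multi-allelic records are
    kept (with comma-joined ALT) so the cascade can drop and ledger them.
    """
    import pysam

    sites: list[VariantSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            alt = ",".join(alts)
            depths = np.zeros(len(samples), dtype=np.int64)
            alt_counts = np.zeros(len(samples), dtype=np.int64)
            for i, s in enumerate(samples):
                fmt = rec.samples[s]
                ad = fmt.get("AD")
                dp = fmt.get("DP")
                if dp is not None:
                    depths[i] = int(dp)
                if ad is not None and len(ad) >= 2 and ad[1] is not None:
                    alt_counts[i] = int(ad[1])
            info = rec.info
            sites.append(
                VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt if alt else ".",
                    depths=depths,
                    alt_counts=np.minimum(alt_counts, depths),
                    total_depth=float(info.get("DP", 0.0)),
                    mq=float(info.get("MQ", 60.0)),
                    qd=float(info.get("QD", 20.0)),
                    mq_rank_sum=(
                        float(info["MQRankSum"]) if "MQRankSum" in info else None
                    ),
                    read_pos_rank_sum=(
                        float(info["ReadPosRankSum"])
                        if "ReadPosRankSum" in info
                        else None
                    ),
                    known_id=rec.id,
                )
            )
    return sites, samples


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

_JUNCTION_COLUMNS = [
    "event_id", "event_type", "gene", "sample", "inclusion_count", "skipping_count",
]


def write_junction_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts[_JUNCTION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_junction_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str, "sample": str})
    missing = set(_JUNCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"junction count table missing columns: {sorted(missing)}")
    return df


def write_known_sites(catalog: Mapping[tuple[str, int], str], path: str | Path) -> None:
    rows = [
        {"chrom": c, "pos": p, "identifier": rsid}
        for (c, p), rsid in sorted(catalog.items())
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "identifier"]).to_csv(
        path, sep="\t", index=False
    )


def read_known_sites(path: str | Path) -> dict[tuple[str, int], str]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "identifier": str})
    return {
        (str(r.chrom), int(r.pos)): str(r.identifier) for r in df.itertuples()
    }


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        [{"sample": s, "group": g} for s, g in sorted(groups.items())]
    ).to_csv(path, sep="\t", index=False)


def read_groups(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    groups = {str(r.sample): str(r.group) for r in df.itertuples()}
    bad = set(groups.values()) - {"case", "control"}
    if bad:
        raise ValueError(f"group labels must be 'case'/'control', found {sorted(bad)}")
    return groups


def write_bed(
    intervals: Mapping[str, Sequence[tuple[int, int]]], path: str | Path, name: str = ""
) -> None:
    """Write 0-based half-open intervals (e.g. SSR or multi-mapping masks)."""
    lines = []
    for chrom in sorted(intervals):
        for s, e in intervals[chrom]:
            lines.append(f"{chrom}\t{s}\t{e}" + (f"\t{name}" if name else ""))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
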