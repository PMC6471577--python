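"""Partition significant variants into RNA-editing candidates vs SNVs.

A variant with a significant group difference in alternative allele
frequency qualifies as an RNA-editing candidate when, and only when:

1. the substitution is canonical editing chemistry on the transcript
   strand — A-to-I (read as A>G) or C-to-U (read as C>T);
2. its alternative allele frequency stays strictly below 0.7 in every
   sample (a fixed allele, as at a genomic SNP, tends to 0.5 or 1.0);
3. it carries no known-variant catalog identifier (dbSNP-style rs id);
4. it does not fall in a coding exon, and it lies within a gene (so the
   transcript strand is defined) — UTRs and introns qualify.

Everything else goes to the known/SNV pool, with the failed conditions
recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import math

import pandas as pd

__all__ = [
    "EditingClassification",
    "is_canonical_editing",
    "classify_variant",
    "classify_variants",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Canonical editing substitutions on the transcript strand.
CANONICAL = {("A", "G"), ("C", "T")}

EDITING_CANDIDATE = "editing_candidate"
KNOWN_OR_SNV = "known_or_snv_pool"


def is_canonical_editing(ref: str, alt: str, strand: str | None) -> bool:
    """True iff the substitution, oriented to the transcript strand, is
    A>G (A-to-I) or C>T (C-to-U).

    ``ref`` and ``alt`` are genome-strand bases.  With ``strand=None``
    (site outside any gene) the orientation is ambiguous; both are tried
    and the call is flagged upstream by the gene-membership condition.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("canonical-editing test requires single-base alleles")
    if strand == "+":
        return (ref, alt) in CANONICAL
    if strand == "-":
        return (_COMP[ref], _COMP[alt]) in CANONICAL
    if strand is None:
        return (ref, alt) in CANONICAL or (_COMP[ref], _COMP[alt]) in CANONICAL
    raise ValueError(f"strand must be '+', '-' or None, got {strand!r}")


@dataclass
class EditingClassification:
    """Outcome of the four-condition editing qualification for one site."""

    chrom: str
    pos: int
    classification: str
    canonical: bool
    max_aaf: float
    catalogued: bool
    in_cds: bool
    intergenic: bool
    strand_ambiguous: bool = False
    failed: list[str] = field(default_factory=list)

    @property
    def is_editing_candidate(self) -> bool:
        return self.classification == EDITING_CANDIDATE


def classify_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    aafs: Sequence[float],
    region_labels: Iterable[str],
    strand: str | None,
    known_id: str | None,
    max_aaf_threshold: float = 0.7,
) -> EditingClassification:
    """Apply the editing qualification rule to one significant variant.

    Parameters
    ----------
    aafs:
        Per-sample alternative allele frequencies (NaN for uncovered
        samples, which are ignored).
    region_labels:
        Region annotations of the site (one per overlapping gene);
        ``"EXON"`` denotes a coding-exon (CDS) position.
    strand:
        Transcript strand of the host gene, or ``None`` if the site lies
        in no gene (such sites go to the SNV pool: the editing chemistry
        is strand-defined).
    known_id:
        Known-variant catalog identifier, if any.
    """
    labels = set(region_labels)
    intergenic = strand is None or labels == {"INTERGENIC"}
    canonical = is_canonical_editing(ref, alt, strand)
    finite = [a for a in aafs if not math.isnan(a)]
    max_aaf = max(finite) if finite else float("nan")
    catalogued = known_id is not None and str(known_id) not in ("", ".")
    in_cds = "EXON" in labels
    failed = []
    if not canonical:
        failed.append("noncanonical")
    if not (max_aaf < max_aaf_threshold):
        failed.append("high_aaf")
    if catalogued:
        failed.append("catalogued")
    if in_cds:
        failed.append("coding")
    if intergenic:
        failed.append("intergenic")
    cls = EDITING_CANDIDATE if not failed else KNOWN_OR_SNV
    return EditingClassification(
        chrom=chrom,
        pos=pos,
        classification=cls,
        canonical=canonical,
        max_aaf=max_aaf,
        catalogued=catalogued,
        in_cds=in_cds,
        intergenic=intergenic,
        strand_ambiguous=strand is None,
        failed=failed,
    )


def classify_variants(
    records: pd.DataFrame,
    aaf_columns: Sequence[str],
    max_aaf_threshold: float = 0.7,
) -> pd.DataFrame:
    """Classify a table of significant variants.

    ``records`` needs columns ``chrom, pos, ref, alt, strand, region,
    known_id`` (``region`` may hold one label or a comma-separated list;
    ``strand`` empty/NaN for gene-less sites) plus the per-sample AAF
    columns named in ``aaf_columns``.  Returns the table with
    ``classification`` and ``failed_conditions`` columns appended.
    """
    classes = []
    reasons = []
    for _, row in records.iterrows():
        labels = str(row["region"]).split(",") if pd.notna(row["region"]) else []
        strand = row["strand"] if row.get("strand") in ("+", "-") else None
        known = row["known_id"] if pd.notna(row["known_id"]) else None
        aafs = [float(row[c]) for c in aaf_columns]
        cls = classify_variant(
            row["chrom"], int(row["pos"]), row["ref"], row["alt"],
            aafs, labels, strand, known, max_aaf_threshold,
        )
        classes.append(cls.classification)
        reasons.append(",".join(cls.failed))
    out = records.copy()
    out["classification"] = classes
    out["failed_conditions"] = reasons
    return out
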