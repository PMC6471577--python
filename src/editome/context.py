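"""Genomic context predicates used by the variant filter cascade.

Everything in this module works on a simple in-memory representation:
reference sequences as a ``{chrom: str}`` mapping and gene structures as
:class:`GeneModel` objects.  All coordinates are 0-based half-open
internally; conversion from/to 1-based inclusive (VCF, GTF) happens at the
I/O boundary.

Provided predicates / annotators:

* :func:`annotate_site` — region label(s) of a site relative to gene models
  (UTRs, CDS exon, intron, splice-site windows, up/downstream, intergenic);
* :func:`detect_ssr` — perfect tandem-repeat (microsatellite) intervals;
* :func:`is_bidirectional` — overlapping sense/antisense gene bodies;
* :func:`near_splice_boundary` — intronic positions close to a junction;
* :func:`flank_multimaps` — flank-uniqueness surrogate for multi-alignment.

:class:`GenomeContext` bundles all of them behind the interface the cascade
consumes; :class:`MaskContext` is the same interface backed by explicit
position sets (used for planted fixtures).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "REGION_LABELS",
    "GeneModel",
    "RegionAnnotation",
    "SsrParams",
    "annotate_site",
    "detect_ssr",
    "is_bidirectional",
    "near_splice_boundary",
    "flank_multimaps",
    "UniquenessIndex",
    "GenomeContext",
    "MaskContext",
]

Interval = tuple[int, int]

#: Region labels emitted by :func:`annotate_site`.
REGION_LABELS = (
    "UPSTREAM",
    "UTR_5_PRIME",
    "EXON",
    "SPLICE_SITE_ACCEPTOR",
    "SPLICE_SITE_REGION",
    "INTRON",
    "UTR_3_PRIME",
    "DOWNSTREAM",
    "INTERGENIC",
    "NCRNA",
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One gene with a single (representative) transcript model.

    Parameters
    ----------
    gene_id:
        Gene identifier / symbol.
    chrom:
        Chromosome name.
    strand:
        ``"+"`` or ``"-"``.
    exons:
        Sorted, non-overlapping exon intervals, 0-based half-open.
    cds:
        Genomic span ``(start, end)`` of the coding sequence, or ``None``
        for non-coding genes.  Must lie within the exon union's span.
    biotype:
        ``"coding"`` or ``"ncRNA"``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds: Interval | None = None
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in ("coding", "ncRNA"):
            raise ValueError(f"unknown biotype {self.biotype!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        for s, e in exons:
            if not 0 <= s < e:
                raise ValueError(f"gene {self.gene_id}: bad exon interval ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted")
        object.__setattr__(self, "exons", exons)
        if self.cds is not None:
            cs, ce = self.cds
            if not (exons[0][0] <= cs < ce <= exons[-1][1]):
                raise ValueError(f"gene {self.gene_id}: CDS outside exon span")
            object.__setattr__(self, "cds", (int(cs), int(ce)))
        if self.biotype == "ncRNA" and self.cds is not None:
            raise ValueError(f"gene {self.gene_id}: ncRNA gene cannot carry a CDS")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def exon_containing(self, pos: int) -> Interval | None:
        for s, e in self.exons:
            if s <= pos < e:
                return (s, e)
        return None

    def intron_containing(self, pos: int) -> Interval | None:
        for s, e in self.introns:
            if s <= pos < e:
                return (s, e)
        return None


@dataclass(frozen=True)
class RegionAnnotation:
    """Region label of one site relative to one gene (or intergenic)."""

    chrom: str
    pos: int  # 0-based
    gene_id: str | None
    label: str

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.label!r}")
        if self.label == "INTERGENIC" and self.gene_id is not None:
            raise ValueError("INTERGENIC annotations carry no gene_id")


def annotate_site(
    chrom: str,
    pos: int,
    genes: Sequence[GeneModel],
    extent: int = 5000,
    splice_region_intron: int = 8,
    splice_acceptor_bases: int = 2,
) -> list[RegionAnnotation]:
    """Annotate a genomic site against a set of gene models.

    One annotation is returned per gene whose body or ``extent``-base flank
    covers the site; a site covered by no gene yields a single INTERGENIC
    annotation.  Within a gene, labels follow the precedence
    SPLICE_SITE_ACCEPTOR > SPLICE_SITE_REGION > EXON/UTR > INTRON >
    UPSTREAM/DOWNSTREAM.  The splice-site window is intronic: the last
    ``splice_acceptor_bases`` bases of an intron (transcript orientation)
    are the acceptor; other intronic bases within ``splice_region_intron``
    of a boundary are SPLICE_SITE_REGION.

    Parameters
    ----------
    chrom, pos:
        Site position, 0-based.
    genes:
        Gene models; only those on ``chrom`` are considered.
    extent:
        Up/downstream flank size in bases (default 5000, the conventional
        "within 5 kb" promoter/downstream window).
    """
    if pos < 0:
        raise ValueError(f"position must be >= 0, got {pos}")
    chroms = {g.chrom for g in genes}
    if chrom not in chroms:
        raise ValueError(f"unknown chromosome {chrom!r}")
    out: list[RegionAnnotation] = []
    for gene in genes:
        if gene.chrom != chrom:
            continue
        label = _label_for_gene(pos, gene, extent, splice_region_intron, splice_acceptor_bases)
        if label is not None:
            out.append(RegionAnnotation(chrom, pos, gene.gene_id, label))
    if not out:
        out.append(RegionAnnotation(chrom, pos, None, "INTERGENIC"))
    return out


def _label_for_gene(
    pos: int,
    gene: GeneModel,
    extent: int,
    splice_region_intron: int,
    splice_acceptor_bases: int,
) -> str | None:
    if pos < gene.start:
        if gene.start - pos <= extent:
            return "UPSTREAM" if gene.strand == "+" else "DOWNSTREAM"
        return None
    if pos >= gene.end:
        if pos - gene.end < extent:
            return "DOWNSTREAM" if gene.strand == "+" else "UPSTREAM"
        return None
    exon = gene.exon_containing(pos)
    if exon is not None:
        if gene.biotype == "ncRNA":
            return "NCRNA"
        cs, ce = gene.cds  # coding genes always carry a CDS (validated)
        if cs <= pos < ce:
            return "EXON"
        if pos < cs:
            return "UTR_5_PRIME" if gene.strand == "+" else "UTR_3_PRIME"
        return "UTR_3_PRIME" if gene.strand == "+" else "UTR_5_PRIME"
    intron = gene.intron_containing(pos)
    istart, iend = intron
    # acceptor side = intron end adjacent to the downstream exon in
    # transcript orientation
    if gene.strand == "+":
        in_acceptor = pos >= iend - splice_acceptor_bases
    else:
        in_acceptor = pos < istart + splice_acceptor_bases
    if in_acceptor:
        return "SPLICE_SITE_ACCEPTOR"
    if min(pos - istart, iend - 1 - pos) < splice_region_intron:
        return "SPLICE_SITE_REGION"
    return "INTRON"


# ---------------------------------------------------------------------------
# Simple sequence repeats
# ---------------------------------------------------------------------------

#: Minimum number of motif copies per motif length (1-6) for a tract to
#: count as an SSR; standard microsatellite-survey defaults.
DEFAULT_MIN_REPEATS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 4}


@dataclass(frozen=True)
class SsrParams:
    """Microsatellite detection parameters.

    ``min_repeats`` maps motif length (1-6 bases) to the minimum number of
    perfect copies; ``flank`` is the exclusion margin added to each side of
    a detected tract (default 3 bases).
    """

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    flank: int = 3

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        for k, n in self.min_repeats.items():
            if not (1 <= k <= 6):
                raise ValueError(f"motif length {k} outside 1-6")
            if n < 2:
                raise ValueError(f"min repeat count must be >= 2, got {n}")


def _is_primitive(motif: str) -> bool:
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def detect_ssr(sequence: str, params: SsrParams | None = None) -> list[Interval]:
    """Find perfect tandem repeats (microsatellites) in ``sequence``.

    Returns sorted, merged 0-based half-open intervals.  Each reported
    tract is a maximal run with period 1-6 containing at least the
    configured number of exact motif copies (partial trailing copies are
    included in the interval), extended by ``params.flank`` bases on each
    side and clipped to the sequence bounds.
    """
    params = params or SsrParams()
    seq = sequence.upper()
    n = len(seq)
    raw: list[Interval] = []
    for k, min_copies in sorted(params.min_repeats.items()):
        i = 0
        while i + k * 2 <= n:
            motif = seq[i : i + k]
            if "N" in motif or not _is_primitive(motif):
                i += 1
                continue
            j = i + k
            while j < n and seq[j] == seq[j - k]:
                j += 1
            if (j - i) // k >= min_copies:
                raw.append((i, j))
                i = j - k + 1
            else:
                i += 1
    if not raw:
        return []
    # flank-extend, clip, merge
    ext = sorted((max(0, s - params.flank), min(n, e + params.flank)) for s, e in raw)
    merged = [ext[0]]
    for s, e in ext[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# Strand / junction predicates
# ---------------------------------------------------------------------------

def is_bidirectional(chrom: str, pos: int, genes: Sequence[GeneModel]) -> bool:
    """True iff the site lies inside gene bodies on both strands."""
    strands = {
        g.strand for g in genes if g.chrom == chrom and g.contains(pos)
    }
    return "+" in strands and "-" in strands


def near_splice_boundary(
    chrom: str, pos: int, genes: Sequence[GeneModel], flank: int = 5
) -> bool:
    """True iff the site is intronic and within ``flank`` bases of either
    intron boundary of any gene (the "5 bp intronic flanking region" rule).
    Exonic positions never qualify."""
    for gene in genes:
        if gene.chrom != chrom or not gene.contains(pos):
            continue
        intron = gene.intron_containing(pos)
        if intron is None:
            continue
        istart, iend = intron
        if pos - istart < flank or iend - 1 - pos < flank:
            return True
    return False


# ---------------------------------------------------------------------------
# Flank uniqueness (multi-mapping surrogate)
# ---------------------------------------------------------------------------

class UniquenessIndex:
    """Exact k-mer index over a reference used to seed flank-window matches.

    With the default window identity threshold of 0.90 over a 101-base
    window (at most 10 mismatches), a seed length of 8 guarantees that any
    qualifying second copy shares at least one exact 8-mer with the window,
    so seeding never misses a true hit at that threshold.
    """

    def __init__(self, reference: Mapping[str, str], k: int = 8) -> None:
        self.reference = {c: s.upper() for c, s in reference.items()}
        self.k = k
        index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.reference.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((chrom, i))
        self._index = index

    def occurrences(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def flank_multimaps(
    chrom: str,
    pos: int,
    reference: Mapping[str, str],
    flank: int = 50,
    min_identity: float = 0.90,
    index: UniquenessIndex | None = None,
) -> bool:
    """True iff the site's flank window occurs a second time in the reference.

    The window is the site plus ``flank`` bases on each side (clipped at
    sequence ends).  A second occurrence counts when a full window-length
    segment elsewhere matches at >= ``min_identity`` (either strand is not
    considered; duplications are modelled as direct repeats).  This is a
    seeded exact-k-mer + full-window-identity surrogate for aligning the
    flank back to the genome and finding multiple hits.
    """
    if index is None:
        index = UniquenessIndex(reference)
    seq = index.reference[chrom]
    start = max(0, pos - flank)
    end = min(len(seq), pos + flank + 1)
    window = seq[start:end]
    length = end - start
    k = index.k
    seen: set[tuple[str, int]] = set()
    for s in range(0, length - k + 1):
        for occ_chrom, occ_pos in index.occurrences(window[s : s + k]):
            cand = occ_pos - s
            if (occ_chrom, cand) in seen:
                continue
            seen.add((occ_chrom, cand))
            if occ_chrom == chrom and cand == start:
                continue  # self-match
            other = index.reference[occ_chrom]
            if cand < 0 or cand + length > len(other):
                continue
            if _identity(window, other[cand : cand + length]) >= min_identity:
                return True
    return False


# ---------------------------------------------------------------------------
# Bundled context interface for the cascade
# ---------------------------------------------------------------------------

class GenomeContext:
    """All positional predicates the filter cascade needs, precomputed from a
    reference and its gene models.

    The SSR mask is computed eagerly per chromosome; flank uniqueness is
    evaluated lazily per site through a shared k-mer index.
    """

    def __init__(
        self,
        reference: Mapping[str, str],
        genes: Sequence[GeneModel],
        ssr_params: SsrParams | None = None,
        flank: int = 50,
        min_identity: float = 0.90,
        splice_flank: int = 5,
    ) -> None:
        self.reference = dict(reference)
        self.genes = list(genes)
        self.ssr_params = ssr_params or SsrParams()
        self.flank = flank
        self.min_identity = min_identity
        self.splice_flank = splice_flank
        self._genes_by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self._genes_by_chrom.setdefault(g.chrom, []).append(g)
        self._ssr_mask = {
            chrom: detect_ssr(seq, self.ssr_params)
            for chrom, seq in self.reference.items()
        }
        self._ssr_starts = {
            chrom: [s for s, _ in ivals] for chrom, ivals in self._ssr_mask.items()
        }
        self._uindex: UniquenessIndex | None = None

    def ssr_intervals(self, chrom: str) -> list[Interval]:
        return self._ssr_mask.get(chrom, [])

    def _chrom_genes(self, chrom: str) -> list[GeneModel]:
        return self._genes_by_chrom.get(chrom, [])

    def is_bidirectional(self, chrom: str, pos: int) -> bool:
        return is_bidirectional(chrom, pos, self._chrom_genes(chrom))

    def in_ssr(self, chrom: str, pos: int) -> bool:
        ivals = self._ssr_mask.get(chrom)
        if not ivals:
            return False
        i = bisect_right(self._ssr_starts[chrom], pos) - 1
        return i >= 0 and ivals[i][0] <= pos < ivals[i][1]

    def flank_multimaps(self, chrom: str, pos: int) -> bool:
        if self._uindex is None:
            self._uindex = UniquenessIndex(self.reference)
        return flank_multimaps(
            chrom, pos, self.reference, self.flank, self.min_identity, self._uindex
        )

    def near_splice_boundary(self, chrom: str, pos: int) -> bool:
        return near_splice_boundary(
            chrom, pos, self._chrom_genes(chrom), self.splice_flank
        )

    def annotate(self, chrom: str, pos: int, extent: int = 5000) -> list[RegionAnnotation]:
        return annotate_site(chrom, pos, self.genes, extent)


class MaskContext:
    """Cascade context backed by explicit position sets.

    Used for planted fixtures where each site's context category is chosen
    directly rather than derived from sequence; positions are (chrom, pos)
    tuples with 0-based positions.
    """

    def __init__(
        self,
        bidirectional: Iterable[tuple[str, int]] = (),
        multimapping: Iterable[tuple[str, int]] = (),
        ssr: Iterable[tuple[str, int]] = (),
        splice_proximal: Iterable[tuple[str, int]] = (),
    ) -> None:
        self._bidirectional = set(bidirectional)
        self._multimapping = set(multimapping)
        self._ssr = set(ssr)
        self._splice = set(splice_proximal)

    def is_bidirectional(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self._bidirectional

    def flank_multimaps(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self._multimapping

    def in_ssr(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self._ssr

    def near_splice_boundary(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self._splice
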