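"""Synthetic data generator for the variant/splicing pipeline.

Emulates a small case-control bulk RNA-seq design — by default five
growth-restricted (IUGR) and five control placental libraries — at the
level the pipeline consumes: a reference sequence with planted genomic
features (microsatellite tracts, duplicated segments, an overlapping
sense/antisense gene pair), gene models, per-sample variant calls with
binomial allele counts, and per-sample junction counts for cassette-exon
events with group-specific true PSI.

Planted truth (which sites are editing sites, which are catalogued SNPs,
which cascade stage should remove each noise site, and the true PSI of
each event) is recorded in :class:`SyntheticTruth` so parameter-recovery
tests can compare pipeline output against it.

All randomness derives from ``SimulationConfig.seed`` through independent
child streams, so identical configurations produce byte-identical
fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cascade import CascadeConfig, VariantSite
from .context import GeneModel, MaskContext

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "build_gene_models",
    "generate_reference",
    "build_truth",
    "simulate_variant_calls",
    "simulate_junction_counts",
    "simulate",
    "write_fixtures",
    "PRINTED_LEDGER",
    "planted_cascade_fixture",
]

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ConfigurationError(ValueError):
    """Planted features conflict or fall outside the genome."""


@dataclass(frozen=True)
class PlantedEditingSite:
    """A canonical editing site: ``baseline_aaf`` in controls,
    ``baseline_aaf + fraction_difference`` in cases."""

    gene_id: str
    pos: int  # 0-based genomic position
    baseline_aaf: float
    fraction_difference: float

    @property
    def case_aaf(self) -> float:
        return self.baseline_aaf + self.fraction_difference


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the generator.

    Defaults emulate the pipeline's reference design: 5 cases vs 5
    controls, moderate sequencing depth, canonical editing sites whose
    case/control allele-fraction differences (0.047-0.178) bracket the
    range reported for placental A-to-I candidates, a handful of
    catalogued SNPs, and noise sites planted to exercise every cascade
    stage.  Use :meth:`default` for a fully populated instance.
    """

    seed: int
    n_cases: int = 5
    n_controls: int = 5
    chrom: str = "chr1"
    genome_length: int = 60_000
    n_genes: int = 6
    ssr_tracts: tuple[tuple[str, int, int], ...] = ()  # (motif, copies, pos)
    duplicated_segments: tuple[tuple[tuple[int, int], int, float], ...] = ()
    planted_editing_sites: tuple[PlantedEditingSite, ...] = ()
    planted_known_snps: tuple[tuple[int, str, float], ...] = ()  # (pos, id, aaf)
    noise_sites: Mapping[str, int] = field(
        default_factory=lambda: {
            "quality": 6,
            "bidirectional": 4,
            "paralog": 3,
            "repeat": 3,
            "splice_proximity": 3,
            "replicate_support": 4,
            "null_survivor": 12,
        }
    )
    null_aaf: float = 0.3
    read_depth_mean: float = 50.0
    junction_coverage_mean: float = 100.0
    true_psi: tuple[tuple[str, float, float], ...] = ()  # (gene, psi_case, psi_ctrl)
    l_inclusion: float = 2.0
    l_skipping: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cases + self.n_controls < 2:
            raise ConfigurationError("at least two samples are required")
        for site in self.planted_editing_sites:
            for frac in (site.baseline_aaf, site.case_aaf):
                if not 0.0 <= frac <= 1.0:
                    raise ConfigurationError(
                        f"editing site at {site.pos}: allele fraction {frac} "
                        "outside [0, 1]"
                    )
        for pos, _, af in self.planted_known_snps:
            if not 0.0 <= af <= 1.0:
                raise ConfigurationError(f"SNP at {pos}: frequency outside [0, 1]")
        for gene, pc, pk in self.true_psi:
            if not (0.0 <= pc <= 1.0 and 0.0 <= pk <= 1.0):
                raise ConfigurationError(f"event in {gene}: PSI outside [0, 1]")
        if self.read_depth_mean < 1:
            raise ConfigurationError("read_depth_mean must be >= 1")

    @property
    def samples(self) -> list[str]:
        return [f"CTR{i + 1}" for i in range(self.n_controls)] + [
            f"IUGR{i + 1}" for i in range(self.n_cases)
        ]

    @property
    def group_labels(self) -> np.ndarray:
        return np.array([0] * self.n_controls + [1] * self.n_cases)

    @property
    def groups(self) -> dict[str, str]:
        labels = self.group_labels
        return {
            s: ("case" if g else "control") for s, g in zip(self.samples, labels)
        }

    @classmethod
    def default(cls, seed: int) -> "SimulationConfig":
        """Reference configuration used throughout the test suite.

        Six genes of three exons each on a 60 kb chromosome, one antisense
        partner overlapping gene g1 (a bidirectional locus), two
        microsatellite tracts, one 200 bp duplicated segment, four
        canonical editing sites in UTR/intron positions, and three
        catalogued SNPs.
        """
        # editing sites: 3'UTR of g2 (-) and g4 (-) (genomic start side on
        # the minus strand), intron middles of g3 (+) and g5 (+); fraction
        # differences bracket 0.047-0.178
        editing = (
            PlantedEditingSite("g2", _gene_start(1) + 100, 0.15, 0.047),
            PlantedEditingSite("g3", _gene_start(2) + 900, 0.15, 0.106),
            PlantedEditingSite("g4", _gene_start(3) + 100, 0.15, 0.122),
            PlantedEditingSite("g5", _gene_start(4) + 2100, 0.15, 0.178),
        )
        known = (
            (_gene_start(2) + 400, "rs100001", 0.5),
            (_gene_start(4) + 450, "rs100002", 0.5),
            (_gene_start(5) + 500, "rs100003", 0.4),
        )
        events = (("g1", 0.7, 0.98), ("g2", 0.5, 0.5), ("g3", 0.9, 0.6),
                  ("g4", 0.3, 0.3), ("g5", 0.45, 0.45), ("g6", 0.2, 0.55))
        return cls(
            seed=seed,
            ssr_tracts=(("GCA", 7, 47_000), ("A", 12, 48_000)),
            duplicated_segments=(((50_000, 50_200), 55_000, 0.0),),
            planted_editing_sites=editing,
            planted_known_snps=known,
            true_psi=events,
        )


def _gene_start(i: int) -> int:
    return 2_000 + i * 7_000


def _default_gene_layout(chrom: str = "chr1") -> list[GeneModel]:
    """Six spaced three-exon genes plus one antisense ncRNA overlapping g1."""
    genes = []
    for i in range(6):
        g = _gene_start(i)
        strand = "+" if i % 2 == 0 else "-"
        genes.append(
            GeneModel(
                gene_id=f"g{i + 1}",
                chrom=chrom,
                strand=strand,
                exons=((g, g + 600), (g + 1200, g + 1800), (g + 2400, g + 3000)),
                cds=(g + 300, g + 2700),
                biotype="coding",
            )
        )
    # antisense partner overlapping g1's body -> bidirectional locus
    g = _gene_start(0)
    genes.append(
        GeneModel(
            gene_id="g1_as",
            chrom=chrom,
            strand="-",
            exons=((g + 1400, g + 1700), (g + 2500, g + 2900)),
            cds=None,
            biotype="ncRNA",
        )
    )
    return genes


def build_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Gene models for the configured genome (deterministic, no RNG)."""
    layout = _default_gene_layout(config.chrom)
    genes = layout[: config.n_genes]
    genes.append(layout[-1])  # antisense partner
    for g in genes:
        if g.end > config.genome_length:
            raise ConfigurationError(
                f"gene {g.gene_id} extends past the genome end "
                f"({g.end} > {config.genome_length})"
            )
    return genes


def generate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Generate the reference sequence and gene models.

    Plants the configured SSR tracts and duplicated segments, and fixes
    the reference base at each planted editing site to adenosine on the
    transcript strand.  Raises :class:`ConfigurationError` when planted
    features overlap or fall outside the genome.
    """
    genes = build_gene_models(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    seq = rng.choice(_BASES, size=config.genome_length)

    written: list[tuple[int, int, str]] = []
    for motif, copies, pos in config.ssr_tracts:
        end = pos + len(motif) * copies
        written.append((pos, end, f"SSR tract {motif}x{copies} at {pos}"))
    for (src_s, src_e), target, _ in config.duplicated_segments:
        written.append((target, target + (src_e - src_s), f"duplicated segment at {target}"))
    for s, e, name in written:
        if not (0 <= s < e <= config.genome_length):
            raise ConfigurationError(f"{name} falls outside the genome")
    for i, (s1, e1, n1) in enumerate(written):
        for s2, e2, n2 in written[i + 1:]:
            if s1 < e2 and s2 < e1:
                raise ConfigurationError(f"planted features overlap: {n1} vs {n2}")

    for motif, copies, pos in config.ssr_tracts:
        tract = (motif.upper() * copies)
        seq[pos : pos + len(tract)] = list(tract)

    strand_of = {g.gene_id: g.strand for g in genes}
    for site in config.planted_editing_sites:
        if site.gene_id not in strand_of:
            raise ConfigurationError(f"editing site gene {site.gene_id!r} not in layout")
        gene = next(g for g in genes if g.gene_id == site.gene_id)
        if not gene.contains(site.pos):
            raise ConfigurationError(
                f"editing site at {site.pos} lies outside gene {site.gene_id}"
            )
        seq[site.pos] = "A" if strand_of[site.gene_id] == "+" else "T"

    # duplications copied last so both copies share planted content
    for (src_s, src_e), target, divergence in config.duplicated_segments:
        segment = seq[src_s:src_e].copy()
        if divergence > 0:
            n_mut = int(round(divergence * len(segment)))
            idx = rng.choice(len(segment), size=n_mut, replace=False)
            for i in idx:
                others = [b for b in "ACGT" if b != segment[i]]
                segment[i] = others[rng.integers(len(others))]
        seq[target : target + len(segment)] = segment

    return {config.chrom: "".join(seq)}, genes


@dataclass
class SyntheticTruth:
    """Planted ground truth backing recovery tests.

    ``removal_category`` maps each planted variant position (0-based) to
    the first cascade stage expected to remove it, or ``"survivor"``;
    categories are mutually exclusive by construction.
    """

    editing_sites: dict[int, tuple[float, float]]  # pos -> (case, control) AAF
    known_snps: dict[int, str]
    true_psi: dict[str, tuple[float, float]]  # event_id -> (case, control)
    removal_category: dict[int, str]
    event_genes: dict[str, str] = field(default_factory=dict)

    def positions(self) -> list[int]:
        return sorted(self.removal_category)


def _se_event_id(gene: GeneModel) -> str:
    """Cassette-exon (SE) coordinate string for a three-exon gene."""
    (s1, e1), (s2, e2), (s3, e3) = gene.exons[:3]
    return f"{gene.chrom}:{e1}-{s2 + 1}:{e2}-{s3 + 1}:{gene.strand}"


def build_truth(config: SimulationConfig, genes: Sequence[GeneModel]) -> SyntheticTruth:
    """Lay out planted and noise variant sites and record their expected fate.

    Noise positions are deterministic functions of the layout (no RNG):
    each category is placed inside the genomic feature that its cascade
    stage tests, and away from every other feature, so the expected
    removal stage is unambiguous.
    """
    by_id = {g.gene_id: g for g in genes}
    removal: dict[int, str] = {}
    editing: dict[int, tuple[float, float]] = {}
    for site in config.planted_editing_sites:
        editing[site.pos] = (site.case_aaf, site.baseline_aaf)
        removal[site.pos] = "survivor"
    known = {pos: rsid for pos, rsid, _ in config.planted_known_snps}
    for pos in known:
        removal[pos] = "survivor"

    counts = dict(config.noise_sites)
    spans = _category_spans(config, genes)
    for category, n in counts.items():
        start, stride = spans[category]
        placed = 0
        pos = start
        while placed < n:
            if pos not in removal:
                removal[pos] = (
                    "survivor" if category == "null_survivor" else category
                )
                placed += 1
            pos += stride

    true_psi: dict[str, tuple[float, float]] = {}
    event_genes: dict[str, str] = {}
    for gene_id, psi_case, psi_ctrl in config.true_psi:
        gene = by_id.get(gene_id)
        if gene is None or len(gene.exons) < 3:
            raise ConfigurationError(f"no three-exon gene {gene_id!r} for PSI event")
        eid = _se_event_id(gene)
        true_psi[eid] = (psi_case, psi_ctrl)
        event_genes[eid] = gene_id
    return SyntheticTruth(editing, known, true_psi, removal, event_genes)


def _category_spans(
    config: SimulationConfig, genes: Sequence[GeneModel]
) -> dict[str, tuple[int, int]]:
    """(start, stride) placement rule per noise category."""
    by_id = {g.gene_id: g for g in genes}
    g1, g1_as = by_id["g1"], by_id["g1_as"]
    # inside both bodies, mid-exon of g1 (away from g1's intron boundaries)
    bidir_start = g1_as.exons[0][0] + 50
    ssr_motif, ssr_copies, ssr_pos = config.ssr_tracts[0] if config.ssr_tracts else ("A", 0, 0)
    (dup_s, dup_e), dup_target, _ = (
        config.duplicated_segments[0]
        if config.duplicated_segments
        else ((0, 0), 0, 0.0)
    )
    g3 = by_id.get("g3", by_id["g1"])
    splice_start = g3.introns[0][0] + 1  # 2nd intronic base: within 5 bp
    clear = 20_000  # intergenic, feature-free stretch of the default layout
    g6 = by_id.get("g6", g1)
    return {
        "quality": (clear, 7),
        "bidirectional": (bidir_start, 11),
        # >= 60 bases inside the duplicated copy so the full 101-base flank
        # window of each site lies within the duplication
        "paralog": (dup_target + 60, 13),
        "repeat": (ssr_pos + 2, 3),
        "splice_proximity": (splice_start, 1),
        "replicate_support": (clear + 1_000, 7),
        "null_survivor": (g6.exons[0][0] + 20, 17),
    }


def simulate_variant_calls(
    config: SimulationConfig,
    truth: SyntheticTruth,
    genes: Sequence[GeneModel],
    reference: Mapping[str, str],
) -> list[VariantSite]:
    """Draw per-sample depths and binomial alternative-allele counts.

    Depth per sample is Poisson around ``read_depth_mean`` floored at 1;
    the alternative count is binomial with the group's true AAF.  Sites in
    the ``quality`` category violate one hard-filter threshold each
    (cycled); ``replicate_support`` sites carry the alternative allele in
    exactly half the samples.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    seq = reference[config.chrom]
    genes_by_chrom = [g for g in genes if g.chrom == config.chrom]
    n = config.n_cases + config.n_controls
    labels = config.group_labels.astype(bool)
    quality_violations = [
        {"total_depth": 5.0},
        {"mq": 30.0},
        {"qd": 1.0},
        {"mq_rank_sum": -13.0},
        {"read_pos_rank_sum": -9.0},
    ]
    sites: list[VariantSite] = []
    q_idx = 0
    for pos in truth.positions():
        category = truth.removal_category[pos]
        ref = seq[pos]
        if pos in truth.editing_sites:
            case_aaf, ctrl_aaf = truth.editing_sites[pos]
            host = next((g for g in genes_by_chrom if g.contains(pos)), None)
            alt = "G" if (host is None or host.strand == "+") else "C"
        else:
            if pos in truth.known_snps:
                af = next(
                    a for p, _, a in config.planted_known_snps if p == pos
                )
                case_aaf = ctrl_aaf = af
            else:
                case_aaf = ctrl_aaf = config.null_aaf
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        depths = np.maximum(rng.poisson(config.read_depth_mean, size=n), 1)
        aaf = np.where(labels, case_aaf, ctrl_aaf)
        alts = rng.binomial(depths, aaf)
        extra: dict[str, float] = {}
        if category == "quality":
            extra = dict(quality_violations[q_idx % len(quality_violations)])
            q_idx += 1
        elif category == "replicate_support":
            carriers = np.zeros(n, dtype=bool)
            carriers[: n // 2] = True
            alts = np.where(carriers, np.maximum(alts, 1), 0)
        site = VariantSite(
            chrom=config.chrom,
            pos=pos + 1,
            ref=ref,
            alt=alt,
            depths=depths,
            alt_counts=np.minimum(alts, depths),
            total_depth=float(depths.sum()),
            mq=60.0,
            qd=25.0,
            mq_rank_sum=0.0,
            read_pos_rank_sum=0.0,
            known_id=truth.known_snps.get(pos),
        )
        for attr, value in extra.items():
            setattr(site, attr, value)
        sites.append(site)
    return sites


def simulate_junction_counts(
    config: SimulationConfig, truth: SyntheticTruth
) -> pd.DataFrame:
    """Draw per-sample inclusion/skipping junction counts for each event.

    Total junction coverage per sample is Poisson around
    ``junction_coverage_mean``; the inclusion count is binomial with
    success probability equal to the length-adjusted inclusion fraction,
    so the effective-length-corrected PSI estimator is consistent for the
    planted truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    labels = config.group_labels.astype(bool)
    samples = config.samples
    l_i, l_s = config.l_inclusion, config.l_skipping
    rows = []
    for event_id in sorted(truth.true_psi):
        psi_case, psi_ctrl = truth.true_psi[event_id]
        gene = truth.event_genes.get(event_id, "")
        for i, sample in enumerate(samples):
            psi = psi_case if labels[i] else psi_ctrl
            coverage = int(rng.poisson(config.junction_coverage_mean))
            denom = psi * l_i + (1 - psi) * l_s
            p_incl = (psi * l_i / denom) if denom > 0 else 0.0
            incl = int(rng.binomial(coverage, p_incl)) if coverage > 0 else 0
            rows.append(
                {
                    "event_id": event_id,
                    "event_type": "SE",
                    "gene": gene,
                    "sample": sample,
                    "inclusion_count": incl,
                    "skipping_count": coverage - incl,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "event_type", "gene", "sample",
            "inclusion_count", "skipping_count",
        ],
    )


@dataclass
class SyntheticDataset:
    """Everything one simulation run produces."""

    config: SimulationConfig
    reference: dict[str, str]
    genes: list[GeneModel]
    truth: SyntheticTruth
    variants: list[VariantSite]
    junction_counts: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return self.config.samples

    @property
    def group_labels(self) -> np.ndarray:
        return self.config.group_labels

    def catalog(self) -> dict[tuple[str, int], str]:
        return {
            (self.config.chrom, pos + 1): rsid
            for pos, rsid in self.truth.known_snps.items()
        }


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generator: reference, truth, variants, junction counts."""
    reference, genes = generate_reference(config)
    truth = build_truth(config, genes)
    variants = simulate_variant_calls(config, truth, genes, reference)
    junctions = simulate_junction_counts(config, truth)
    return SyntheticDataset(config, reference, genes, truth, variants, junctions)


def write_fixtures(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as FASTA/GTF/VCF/TSV files; returns the paths."""
    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "genes": outdir / "genes.gtf",
        "variants": outdir / "variants.vcf",
        "junctions": outdir / "junction_counts.tsv",
        "known": outdir / "known_sites.tsv",
        "groups": outdir / "groups.tsv",
    }
    io.write_fasta(dataset.reference, paths["reference"])
    io.write_gtf(dataset.genes, paths["genes"])
    contigs = {c: len(s) for c, s in dataset.reference.items()}
    io.write_vcf(dataset.variants, dataset.samples, paths["variants"], contigs)
    io.write_junction_counts(dataset.junction_counts, paths["junctions"])
    io.write_known_sites(dataset.catalog(), paths["known"])
    io.write_groups(dataset.config.groups, paths["groups"])
    return paths


# ---------------------------------------------------------------------------
# Planted-ledger fixture
# ---------------------------------------------------------------------------

#: Per-stage removal counts of the reference filter cascade: 88,859 input
#: variants, 16,584 failing hard quality filters, then positional and
#: replicate-support removals leaving 7,652 survivors.
PRINTED_LEDGER = {
    "input": 88_859,
    "quality": 16_584,
    "bidirectional": 24_877,
    "paralog": 13_310,
    "repeat": 2_529,
    "splice_proximity": 723,
    "replicate_support": 23_184,
}


def planted_cascade_fixture(
    stage_counts: Mapping[str, int] | None = None,
    n_samples: int = 10,
    seed: int = 0,
) -> tuple[list[VariantSite], MaskContext, CascadeConfig]:
    """Build a variant set whose cascade ledger is fixed by construction.

    Each stage's quota of sites is planted to fail exactly that stage and
    no earlier one, so running :func:`editome.cascade.run_cascade` on the
    result reproduces ``stage_counts`` exactly (default: the reference
    ledger of :data:`PRINTED_LEDGER`).
    """
    counts = dict(stage_counts or PRINTED_LEDGER)
    total = counts.pop("input")
    if sum(counts.values()) > total:
        raise ValueError("stage removals exceed the input count")
    chrom = "chrL"
    half = n_samples // 2
    depth = np.full(n_samples, 30, dtype=np.int64)
    alt_pass = np.full(n_samples, 9, dtype=np.int64)
    alt_fail = np.concatenate(
        [np.full(half, 12, dtype=np.int64), np.zeros(n_samples - half, dtype=np.int64)]
    )
    order = [
        "quality", "bidirectional", "paralog", "repeat",
        "splice_proximity", "replicate_support",
    ]
    masks: dict[str, list[tuple[str, int]]] = {k: [] for k in order}
    variants: list[VariantSite] = []
    pos = 1
    rng = np.random.default_rng(seed)
    for stage in order:
        for _ in range(counts.get(stage, 0)):
            site = VariantSite(
                chrom=chrom, pos=pos, ref="A", alt="G",
                depths=depth, alt_counts=alt_fail if stage == "replicate_support" else alt_pass,
                total_depth=5.0 if stage == "quality" else 300.0,
            )
            if stage in ("bidirectional", "paralog", "repeat", "splice_proximity"):
                masks[stage].append((chrom, pos - 1))
            variants.append(site)
            pos += 1
    n_survivors = total - sum(counts.values())
    survivor_alts = rng.binomial(30, 0.3, size=(n_survivors, n_samples)).astype(np.int64)
    survivor_alts = np.maximum(survivor_alts, 1)  # guarantee replicate support
    for i in range(n_survivors):
        variants.append(
            VariantSite(
                chrom=chrom, pos=pos, ref="A", alt="G",
                depths=depth, alt_counts=survivor_alts[i], total_depth=300.0,
            )
        )
        pos += 1
    context = MaskContext(
        bidirectional=masks["bidirectional"],
        multimapping=masks["paralog"],
        ssr=masks["repeat"],
        splice_proximal=masks["splice_proximity"],
    )
    config = CascadeConfig(group_labels=[0] * half + [1] * (n_samples - half))
    return variants, context, config
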