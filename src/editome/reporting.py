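"""Summary reports and end-to-end pipeline orchestration.

Aggregates cascade/classifier/splicing output into the pipeline's summary
artifacts: the region-distribution table of significant variants, the
filter ledger report, per-type splicing-event tallies, and the
up/down-regulated sign tally over an externally produced differential
expression table.  :func:`run_all` wires the whole pipeline together on
simulated or on-disk inputs.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import io
from .cascade import CascadeConfig, FilterLedger, run_cascade
from .context import GenomeContext, RegionAnnotation
from .editing import classify_variants
from .splicing import analyze_junction_counts

logger = logging.getLogger("editome")

__all__ = [
    "region_distribution",
    "deg_sign_tally",
    "ledger_report",
    "run_all",
]


def region_distribution(
    annotations: Iterable[RegionAnnotation] | Mapping[str, int],
) -> pd.DataFrame:
    """Per-label annotation counts and percentage shares.

    Accepts either region annotations (one site may contribute several,
    via multiple overlapping transcripts) or a ready label -> count
    mapping.  Percentages are of total annotations and recompute exactly
    from the counts; rounding is left to presentation.
    """
    if isinstance(annotations, Mapping):
        counts = Counter(dict(annotations))
    else:
        counts = Counter(a.label for a in annotations)
    total = sum(counts.values())
    rows = [
        {
            "label": label,
            "count": n,
            "percent": (100.0 * n / total) if total else 0.0,
        }
        for label, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["label", "count", "percent"])


def deg_sign_tally(deg_table: pd.DataFrame, log2fc_column: str = "log2FC") -> tuple[int, int]:
    """Count strictly up- and down-regulated genes by log2 fold change."""
    fc = pd.to_numeric(deg_table[log2fc_column], errors="raise")
    return int((fc > 0).sum()), int((fc < 0).sum())


def ledger_report(ledger: FilterLedger) -> str:
    """Human-readable stage/removed/remaining table; re-checks conservation."""
    ledger.validate()
    frame = ledger.as_frame()
    lines = [f"input variants\t{ledger.input_count}"]
    for row in frame.itertuples():
        lines.append(f"{row.stage}\t-{row.removed}\t{row.remaining}")
    lines.append(f"survivors\t{ledger.survivor_count}")
    return "\n".join(lines)


def annotated_results_frame(result, context, genes, samples):
    """Cascade results as a flat table with region labels, host-gene
    strand and per-sample AAF columns appended."""
    frame = result.as_frame()
    by_id = {g.gene_id: g for g in genes}
    regions, strands = [], []
    for r in result.results:
        anns = context.annotate(r.site.chrom, r.site.pos - 1)
        regions.append(",".join(a.label for a in anns))
        with_gene = [a for a in anns if a.gene_id is not None]
        strands.append(by_id[with_gene[0].gene_id].strand if with_gene else "")
    frame["region"] = regions
    frame["strand"] = strands
    for i, s in enumerate(samples):
        frame[f"aaf_{s}"] = [r.site.aaf()[i] for r in result.results]
    return frame


def run_all(
    outdir: str | Path,
    seed: int | None = None,
    simulate: bool = False,
    vcf: str | Path | None = None,
    gtf: str | Path | None = None,
    fasta: str | Path | None = None,
    known: str | Path | None = None,
    junctions: str | Path | None = None,
    groups: str | Path | None = None,
    fdr_alpha: float = 0.001,
    psi_fdr_alpha: float = 0.05,
) -> Path:
    """Execute the full pipeline and write all outputs under ``outdir``.

    With ``simulate=True`` the inputs are generated from ``seed`` and
    written alongside the results; otherwise every input path must be
    supplied (checked up front, before any stage runs).
    """
    outdir = Path(outdir)
    if simulate:
        if seed is None:
            raise ValueError("simulation requires a seed")
        from .synthetic import SimulationConfig, simulate as _simulate, write_fixtures

        dataset = _simulate(SimulationConfig.default(seed))
        fixture_dir = outdir / "fixtures"
        paths = write_fixtures(dataset, fixture_dir)
        vcf, gtf, fasta = paths["variants"], paths["genes"], paths["reference"]
        known, junctions, groups = paths["known"], paths["junctions"], paths["groups"]
    else:
        required = {
            "vcf": vcf, "gtf": gtf, "fasta": fasta,
            "known": known, "junctions": junctions, "groups": groups,
        }
        missing = [name for name, p in required.items() if p is None or not Path(p).exists()]
        if missing:
            raise FileNotFoundError(
                f"missing pipeline inputs: {', '.join(sorted(missing))}"
            )
    outdir.mkdir(parents=True, exist_ok=True)

    reference = io.read_fasta(fasta)
    genes = io.read_gtf(gtf)
    variants, samples = io.read_vcf(vcf)
    catalog = io.read_known_sites(known)
    group_map = io.read_groups(groups)
    labels = [1 if group_map[s] == "case" else 0 for s in samples]
    for v in variants:
        rsid = catalog.get((v.chrom, v.pos))
        if rsid is not None:
            v.known_id = rsid

    context = GenomeContext(reference, genes)
    result = run_cascade(variants, context, CascadeConfig(labels, fdr_alpha=fdr_alpha))
    for name, removed in result.ledger.stages:
        logger.info("cascade stage %s removed %d", name, removed)
    logger.info("cascade survivors: %d", result.ledger.survivor_count)
    (outdir / "ledger.txt").write_text(ledger_report(result.ledger) + "\n")

    frame = annotated_results_frame(result, context, genes, samples)
    all_annotations: list[RegionAnnotation] = []
    for r in result.results:
        if r.significant:
            all_annotations.extend(context.annotate(r.site.chrom, r.site.pos - 1))
    aaf_cols = [f"aaf_{s}" for s in samples]
    frame.to_csv(outdir / "cascade_results.tsv", sep="\t", index=False)

    significant = frame[frame["significant"]].reset_index(drop=True)
    classified = classify_variants(significant, aaf_cols)
    classified.to_csv(outdir / "editing_classification.tsv", sep="\t", index=False)
    region_distribution(all_annotations).to_csv(
        outdir / "region_distribution.tsv", sep="\t", index=False,
        float_format="%.2f",
    )

    counts = io.read_junction_counts(junctions)
    psi = analyze_junction_counts(
        counts, group_map, seed=seed, fdr_alpha=psi_fdr_alpha
    )
    psi.to_csv(outdir / "splicing_psi.tsv", sep="\t", index=False)

    with open(outdir / "run_log.txt", "w") as fh:
        from . import __version__

        fh.write(f"editome {__version__}\n")
        fh.write(f"seed: {seed}\n")
        fh.write(f"samples: {','.join(samples)}\n")
        fh.write(f"variants in: {len(variants)}\n")
        fh.write(f"survivors: {result.ledger.survivor_count}\n")
        fh.write(f"significant: {int(frame['significant'].sum())}\n")
        n_edit = int((classified["classification"] == "editing_candidate").sum()) if len(classified) else 0
        fh.write(f"editing candidates: {n_edit}\n")
        n_das = int(psi["significant"].sum()) if len(psi) else 0
        fh.write(f"significant splicing events: {n_das}\n")
    return outdir
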