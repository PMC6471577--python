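"""Bundled worked-example tables from a placental IUGR case-control study.

Four small summary tables ship with the package and back the worked
examples and the acceptance checks:

* ``das_events.tsv`` — 20 differential alternative-splicing events (gene,
  type, dPSI, p, coordinate string);
* ``deg_table.tsv`` — 28 differentially expressed genes with log2 fold
  changes and adjusted p-values;
* ``snv_region_counts.tsv`` — region-annotation counts of significant
  variant sites;
* ``editing_candidates.tsv`` — the four qualified A-to-I editing
  candidates (site, quality, FDR, fraction difference, gene, strand,
  region, substitution).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .splicing import SpliceEvent, parse_event_id

__all__ = [
    "load_das_events",
    "load_deg_table",
    "load_region_counts",
    "load_editing_candidates",
    "das_event_objects",
    "editing_example_records",
]


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("editome.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", **kwargs)


def load_das_events() -> pd.DataFrame:
    """Differential alternative-splicing events (20 rows)."""
    return _read("das_events.tsv", dtype={"event_id": str})


def load_deg_table() -> pd.DataFrame:
    """Differentially expressed genes (28 rows)."""
    return _read("deg_table.tsv", keep_default_na=False, na_values=[""])


def load_region_counts() -> dict[str, int]:
    """Region-annotation counts of significant variant sites."""
    df = _read("snv_region_counts.tsv")
    return dict(zip(df["label"], df["count"].astype(int)))


def load_editing_candidates() -> pd.DataFrame:
    """The four qualified RNA-editing candidate sites."""
    return _read("editing_candidates.tsv", dtype={"chrom": str})


def das_event_objects() -> list[SpliceEvent]:
    """Bundled splicing events parsed into :class:`SpliceEvent` objects."""
    events = []
    for row in load_das_events().itertuples():
        ev = parse_event_id(row.event_id, row.event_type, gene=row.gene)
        ev.delta_psi = float(row.delta_psi)
        ev.p_value = float(row.p_value)
        events.append(ev)
    return events


_REGION_ALIASES = {"Intron": "INTRON", "3UTR": "UTR_3_PRIME", "5UTR": "UTR_5_PRIME"}


def editing_example_records(n_samples: int = 10) -> pd.DataFrame:
    """Editing-classifier input built from the bundled candidate table plus
    two decoy records.

    The four candidate rows are converted to genome-strand alleles and
    per-sample allele frequencies consistent with their reported fraction
    differences (controls at 0.2, cases shifted; all below the 0.7
    qualification bound).  The two decoys are synthetic reconstructions of
    the catalogued variants the qualification rule must reject: a
    synonymous coding-exon SNP (rs4575, PSME2) and a downstream catalogued
    SNP (rs3817, PINLYP); only their failing attributes (rs identifier,
    region) are meaningful.

    Returns a frame ready for :func:`editome.editing.classify_variants`
    with AAF columns ``aaf_1 .. aaf_<n>`` (first half controls, second
    half cases).
    """
    half = n_samples // 2
    aaf_cols = [f"aaf_{i + 1}" for i in range(n_samples)]
    rows = []
    for row in load_editing_candidates().itertuples():
        if row.strand == "+":
            ref, alt = "A", "G"
        else:
            ref, alt = "T", "C"
        base = 0.2
        aafs = [base] * half + [base + float(row.fraction_difference)] * (
            n_samples - half
        )
        rec = {
            "chrom": row.chrom,
            "pos": int(row.pos),
            "ref": ref,
            "alt": alt,
            "gene": row.gene,
            "strand": row.strand,
            "region": _REGION_ALIASES[row.region],
            "known_id": np.nan,
        }
        rec.update(dict(zip(aaf_cols, aafs)))
        rows.append(rec)
    decoys = [
        # synthetic stand-in: synonymous coding SNP, catalogued
        {
            "chrom": "14", "pos": 24_146_300, "ref": "A", "alt": "G",
            "gene": "PSME2", "strand": "+", "region": "EXON",
            "known_id": "rs4575",
        },
        # synthetic stand-in: downstream catalogued SNP
        {
            "chrom": "19", "pos": 44_591_000, "ref": "A", "alt": "G",
            "gene": "PINLYP", "strand": "+", "region": "DOWNSTREAM",
            "known_id": "rs3817",
        },
    ]
    for rec in decoys:
        rec.update(dict(zip(aaf_cols, [0.5] * n_samples)))
        rows.append(rec)
    return pd.DataFrame(rows)
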