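"""Percent-spliced-in (PSI) quantification of alternative-splicing events.

Seven event types are handled — skipped exon (SE), alternative 5'/3'
splice sites (A5SS, A3SS), mutually exclusive exons (MXE), retained
intron (RI) and alternative first/last exons (AF, AL) — identified by
colon/dash-delimited coordinate strings of the form
``chrom:field:...:strand`` where each middle field is either a single
coordinate or a ``start-end`` junction pair (the convention of
transcript-based event catalogs).

PSI is computed from junction counts with effective-length correction,

    psi = (I / l_I) / (I / l_I + S / l_S),

or directly from isoform abundances (inclusion / total).  Group
differences (dPSI = mean case PSI - mean control PSI) are tested with a
two-sided label-permutation test, exact at small sample sizes, and
adjusted by Benjamini-Hochberg across events.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .cascade import bh_fdr

__all__ = [
    "EVENT_TYPES",
    "SpliceEvent",
    "parse_event_id",
    "format_event_id",
    "psi_from_junctions",
    "psi_from_isoforms",
    "delta_psi",
    "test_delta_psi",
    "intersect_events",
    "tally_event_types",
    "analyze_junction_counts",
]

EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI", "AF", "AL")

#: Aliases used in printed tables.
_TYPE_ALIASES = {"MX": "MXE", "A5": "A5SS", "A3": "A3SS"}

#: Expected middle-field shapes per event type: 'p' = start-end pair,
#: 's' = single coordinate, '*' = mixed singles/pairs (first/last-exon
#: events alternate shape with strand).
_SHAPES = {
    "SE": "pp",
    "A5SS": "pp",
    "A3SS": "pp",
    "MXE": "pppp",
    "RI": "sps",
    "AF": "****",
    "AL": "****",
}

Coord = int
Junction = tuple[int, int]
Field = Coord | Junction


def normalize_event_type(event_type: str) -> str:
    t = _TYPE_ALIASES.get(event_type.upper(), event_type.upper())
    if t not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    return t


@dataclass
class SpliceEvent:
    """One alternative-splicing event with optional quantification results."""

    gene: str
    event_type: str
    chrom: str
    strand: str
    coords: tuple[Field, ...]
    psi: dict[str, float] = field(default_factory=dict)  # sample -> psi
    delta_psi: float | None = None
    p_value: float | None = None
    fdr: float | None = None

    @property
    def event_id(self) -> str:
        return format_event_id(self)

    @property
    def interval(self) -> tuple[int, int]:
        """Genomic footprint (min, max) over all coordinates, 1-based."""
        flat = [c for f in self.coords for c in (f if isinstance(f, tuple) else (f,))]
        return (min(flat), max(flat))


_PAIR_RE = re.compile(r"^(\d+)-(\d+)$")
_SINGLE_RE = re.compile(r"^(\d+)$")


def parse_event_id(text: str, event_type: str, gene: str = "") -> SpliceEvent:
    """Parse a coordinate-string event identifier.

    The string is ``chrom:field:...:strand``; fields are single
    coordinates or ``start-end`` pairs.  The field shape is validated
    against the event type.  Formatting the result reproduces the input
    byte-for-byte.
    """
    etype = normalize_event_type(event_type)
    parts = text.split(":")
    if len(parts) < 3:
        raise ValueError(f"event string {text!r}: expected chrom:fields:strand")
    chrom, strand = parts[0], parts[-1]
    if strand not in ("+", "-"):
        raise ValueError(f"event string {text!r}: bad strand field {strand!r}")
    coords: list[Field] = []
    shape = []
    for i, token in enumerate(parts[1:-1], start=1):
        m = _PAIR_RE.match(token)
        if m:
            a, b = int(m.group(1)), int(m.group(2))
            if b < a:
                raise ValueError(
                    f"event string {text!r}: junction field {i} ({token!r}) "
                    "has end before start"
                )
            coords.append((a, b))
            shape.append("p")
            continue
        m = _SINGLE_RE.match(token)
        if m:
            coords.append(int(m.group(1)))
            shape.append("s")
            continue
        raise ValueError(f"event string {text!r}: malformed field {i} ({token!r})")
    expected = _SHAPES[etype]
    if len(shape) != len(expected) or any(
        e != "*" and e != s for e, s in zip(expected, shape)
    ):
        raise ValueError(
            f"event string {text!r}: field shape {''.join(shape)} does not "
            f"match event type {etype} (expected {expected})"
        )
    return SpliceEvent(gene=gene, event_type=etype, chrom=chrom, strand=strand,
                       coords=tuple(coords))


def format_event_id(event: SpliceEvent) -> str:
    fields = [
        f"{f[0]}-{f[1]}" if isinstance(f, tuple) else str(f) for f in event.coords
    ]
    return ":".join([event.chrom, *fields, event.strand])


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

def psi_from_junctions(
    inclusion: float, skipping: float, l_inclusion: float = 2.0, l_skipping: float = 1.0
) -> float:
    """Effective-length-corrected PSI from junction read counts.

    ``l_inclusion``/``l_skipping`` are the junction-position counts of the
    two forms (an included cassette exon is supported by two junctions,
    its skipped form by one — hence the 2:1 default).  Returns NaN when
    both counts are zero (no evidence, not zero inclusion).
    """
    if inclusion < 0 or skipping < 0:
        raise ValueError("junction counts must be >= 0")
    if l_inclusion < 1 or l_skipping < 1:
        raise ValueError("effective lengths must be >= 1")
    if inclusion == 0 and skipping == 0:
        return float("nan")
    i = inclusion / l_inclusion
    s = skipping / l_skipping
    return i / (i + s)


def psi_from_isoforms(inclusion_abundance: float, total_abundance: float) -> float:
    """PSI from isoform abundances: inclusion / total; NaN when total is 0."""
    if inclusion_abundance < 0 or total_abundance < 0:
        raise ValueError("abundances must be >= 0")
    if total_abundance == 0:
        return float("nan")
    if inclusion_abundance > total_abundance:
        raise ValueError("inclusion abundance exceeds total abundance")
    return inclusion_abundance / total_abundance


def delta_psi(case_psi: Sequence[float], control_psi: Sequence[float]) -> float:
    """dPSI = mean(case) - mean(control), ignoring missing (NaN) samples.

    A group with no defined PSI yields NaN (undefined, to be flagged by
    the caller)."""
    case = np.asarray(case_psi, dtype=float)
    ctrl = np.asarray(control_psi, dtype=float)
    if np.all(np.isnan(case)) or np.all(np.isnan(ctrl)):
        return float("nan")
    return float(np.nanmean(case) - np.nanmean(ctrl))


_SPLIT_MASK_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _split_masks(n: int, n_case: int) -> np.ndarray:
    """Boolean (n_splits, n) matrix of all C(n, n_case) case-label splits."""
    key = (n, n_case)
    if key not in _SPLIT_MASK_CACHE:
        masks = np.zeros((math.comb(n, n_case), n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n_case)):
            masks[i, list(idx)] = True
        _SPLIT_MASK_CACHE[key] = masks
    return _SPLIT_MASK_CACHE[key]


def test_delta_psi(
    psi: Sequence[float],
    group_labels: Sequence[int],
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-sided label-permutation p-value for a group difference in PSI.

    The statistic is |mean case - mean control| (NaN samples ignored
    within each permuted group).  All C(n, n_case) label splits are
    enumerated exactly when their number is at most ``n_permutations``;
    otherwise Monte-Carlo with the given seed.  Constant PSI across
    samples gives p = 1.
    """
    values = np.asarray(psi, dtype=float)
    labels = np.asarray(group_labels, dtype=bool)
    if labels.shape != values.shape:
        raise ValueError("group_labels length must match psi length")
    n_case = int(labels.sum())
    n_ctrl = int((~labels).sum())
    if n_case < 2 or n_ctrl < 2:
        raise ValueError("at least two samples per group are required")
    with np.errstate(invalid="ignore"):
        observed = abs(np.nanmean(values[labels]) - np.nanmean(values[~labels]))
    if np.isnan(observed):
        return 1.0
    tol = 1e-12
    n = len(values)
    if math.comb(n, n_case) <= n_permutations:
        masks = _split_masks(n, n_case)
        if not np.any(np.isnan(values)):
            case_means = masks @ values / n_case
            ctrl_means = (~masks) @ values / n_ctrl
            d = np.abs(case_means - ctrl_means)
            return int((d >= observed - tol).sum()) / len(masks)
        count = total = 0
        for mask in masks:
            with np.errstate(invalid="ignore"):
                d = abs(np.nanmean(values[mask]) - np.nanmean(values[~mask]))
            total += 1
            if np.isnan(d) or d >= observed - tol:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n_case, replace=False)] = True
        with np.errstate(invalid="ignore"):
            d = abs(np.nanmean(values[mask]) - np.nanmean(values[~mask]))
        if np.isnan(d) or d >= observed - tol:
            count += 1
    return (count + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# Event-set operations
# ---------------------------------------------------------------------------

def intersect_events(
    events_a: Sequence[SpliceEvent],
    events_b: Sequence[SpliceEvent],
    mode: str = "by-overlap",
) -> list[tuple[SpliceEvent, SpliceEvent]]:
    """Match events between two sets (e.g. two quantification methods).

    ``by-overlap`` pairs events whose genomic footprints overlap by at
    least one base on the same chromosome and strand; ``by-gene`` pairs
    events sharing a gene assignment.
    """
    pairs: list[tuple[SpliceEvent, SpliceEvent]] = []
    if mode == "by-gene":
        by_gene: dict[str, list[SpliceEvent]] = {}
        for b in events_b:
            by_gene.setdefault(b.gene, []).append(b)
        for a in events_a:
            for b in by_gene.get(a.gene, []):
                pairs.append((a, b))
        return pairs
    if mode != "by-overlap":
        raise ValueError(f"unknown mode {mode!r}")
    trees: dict[tuple[str, str], IntervalTree] = {}
    for j, b in enumerate(events_b):
        s, e = b.interval
        trees.setdefault((b.chrom, b.strand), IntervalTree()).addi(s, e + 1, j)
    for a in events_a:
        tree = trees.get((a.chrom, a.strand))
        if tree is None:
            continue
        s, e = a.interval
        hits = sorted(iv.data for iv in tree.overlap(s, e + 1))
        for j in hits:
            pairs.append((a, events_b[j]))
    return pairs


def tally_event_types(events: Iterable[SpliceEvent]) -> dict[str, int]:
    """Per-type event counts, with zeros for absent types."""
    counts = {t: 0 for t in EVENT_TYPES}
    for ev in events:
        counts[normalize_event_type(ev.event_type)] += 1
    return counts


# ---------------------------------------------------------------------------
# Batch quantification
# ---------------------------------------------------------------------------

def analyze_junction_counts(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    l_inclusion: float = 2.0,
    l_skipping: float = 1.0,
    n_permutations: int = 10_000,
    seed: int | None = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Quantify PSI, dPSI, permutation p and BH-FDR for a count table.

    ``counts`` needs columns ``event_id, event_type, gene, sample,
    inclusion_count, skipping_count``; ``groups`` maps sample name to
    ``"case"`` or ``"control"``.  Returns one row per event with
    per-sample PSI columns, ``delta_psi``, ``p_value``, ``fdr`` and a
    ``significant`` flag (FDR below ``fdr_alpha``).
    """
    samples = sorted(groups)
    labels = np.array([groups[s] == "case" for s in samples])
    if not labels.any() or labels.all():
        raise ValueError("both a case and a control group are required")
    rows = []
    for (event_id, etype, gene), sub in counts.groupby(
        ["event_id", "event_type", "gene"], sort=True
    ):
        by_sample = sub.set_index("sample")
        psi = np.array(
            [
                psi_from_junctions(
                    float(by_sample.loc[s, "inclusion_count"]),
                    float(by_sample.loc[s, "skipping_count"]),
                    l_inclusion,
                    l_skipping,
                )
                if s in by_sample.index
                else float("nan")
                for s in samples
            ]
        )
        dpsi = delta_psi(psi[labels], psi[~labels])
        p = test_delta_psi(psi, labels, n_permutations, seed)
        row = {
            "event_id": event_id,
            "event_type": normalize_event_type(etype),
            "gene": gene,
            "delta_psi": dpsi,
            "p_value": p,
        }
        row.update({f"psi_{s}": psi[i] for i, s in enumerate(samples)})
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = out["fdr"] < fdr_alpha
    return out
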