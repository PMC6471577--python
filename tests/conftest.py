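"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import editome as e

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset() -> e.SyntheticDataset:
    """Reference synthetic dataset (5 cases vs 5 controls, fixed seed)."""
    return e.simulate(e.SimulationConfig.default(1))


@pytest.fixture(scope="session")
def default_cascade(default_dataset):
    """Full cascade run on the reference dataset."""
    ctx = e.GenomeContext(default_dataset.reference, default_dataset.genes)
    result = e.run_cascade(
        default_dataset.variants, ctx, e.CascadeConfig(default_dataset.group_labels)
    )
    return ctx, result


@pytest.fixture(scope="session")
def planted_ledger_run():
    """Cascade run on the fixture planted to the reference ledger counts."""
    variants, context, config = e.planted_cascade_fixture(seed=3)
    return e.run_cascade(variants, context, config)


@pytest.fixture
def labels_5v5() -> np.ndarray:
    return np.array([0] * 5 + [1] * 5)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately written as plain position-set / sliding
# window arithmetic, separate from the package's implementations)
# ---------------------------------------------------------------------------

def brute_force_region_label(pos, gene, extent=5000, region_w=8, acceptor_w=2):
    """Per-base region classifier over one gene model; returns a label or
    None when the site is out of range.  Position sets are enumerated
    explicitly rather than via interval logic."""
    exonic = set()
    for s, e_ in gene.exons:
        exonic.update(range(s, e_))
    body = set(range(gene.start, gene.end))
    intronic = body - exonic
    acceptor, region = set(), set()
    for istart, iend in gene.introns:
        if gene.strand == "+":
            acc = set(range(iend - acceptor_w, iend))
        else:
            acc = set(range(istart, istart + acceptor_w))
        near = set(range(istart, istart + region_w)) | set(
            range(iend - region_w, iend)
        )
        acceptor |= acc
        region |= near - acc
    if pos in acceptor:
        return "SPLICE_SITE_ACCEPTOR"
    if pos in region:
        return "SPLICE_SITE_REGION"
    if pos in exonic:
        if gene.biotype == "ncRNA":
            return "NCRNA"
        cs, ce = gene.cds
        if pos in range(cs, ce):
            return "EXON"
        before = pos < cs
        if gene.strand == "+":
            return "UTR_5_PRIME" if before else "UTR_3_PRIME"
        return "UTR_3_PRIME" if before else "UTR_5_PRIME"
    if pos in intronic:
        return "INTRON"
    if pos in range(gene.start - extent, gene.start):
        return "UPSTREAM" if gene.strand == "+" else "DOWNSTREAM"
    if pos in range(gene.end, gene.end + extent):
        return "DOWNSTREAM" if gene.strand == "+" else "UPSTREAM"
    return None


def brute_force_ssr_positions(seq, min_repeats, flank):
    """Exhaustive tandem-repeat scan: every start x motif length, no
    skipping; returns the set of masked positions."""
    seq = seq.upper()
    n = len(seq)
    masked = set()
    for k, thr in min_repeats.items():
        for i in range(n - k):
            motif = seq[i : i + k]
            if "N" in motif:
                continue
            if any(k % d == 0 and motif == motif[:d] * (k // d) for d in range(1, k)):
                continue
            j = i + k
            while j < n and seq[j] == seq[j - k]:
                j += 1
            if (j - i) // k >= thr:
                masked.update(range(max(0, i - flank), min(n, j + flank)))
    return masked


def brute_force_window_multimap(seq, pos, flank=50, min_identity=0.90):
    """All-offset sliding comparison of the site's flank window against the
    whole sequence (quadratic oracle for the seeded uniqueness check)."""
    start = max(0, pos - flank)
    end = min(len(seq), pos + flank + 1)
    window = seq[start:end]
    length = end - start
    for cand in range(0, len(seq) - length + 1):
        if cand == start:
            continue
        other = seq[cand : cand + length]
        ident = sum(a == b for a, b in zip(window, other)) / length
        if ident >= min_identity:
            return True
    return False
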