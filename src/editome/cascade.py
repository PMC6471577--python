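"""Hard-filter cascade for RNA-seq variant calls, with ledger accounting.

The cascade takes per-sample variant calls (depth + alternative-allele
count per sample, plus site-level quality metrics) from a small
case-control design and applies, in order:

1. biallelic-SNV restriction (multi-allelic or non-SNV records dropped);
2. site-quality hard filters (DP, MQ, QD, MQRankSum, ReadPosRankSum);
3. bidirectional-transcription removal (overlapping sense/antisense genes);
4. paralog removal (flank window maps to a second genomic location);
5. repeat removal (site inside a microsatellite mask);
6. splice-proximity removal (intronic, within 5 bp of a junction);
7. replicate-support filter (alternative allele absent in too many
   libraries, or present in too few).

Each variant is charged to the first stage it fails; a
:class:`FilterLedger` records per-stage removals and conserves counts.
Survivors are tested for differential alternative-allele frequency (AAF)
between the two groups with a pooled-count G-test (optionally an exact
label-permutation test), and p-values are adjusted by Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .context import GeneModel, reverse_complement

__all__ = [
    "VariantSite",
    "QualityThresholds",
    "FilterLedger",
    "DifferentialAafResult",
    "CascadeConfig",
    "CascadeResult",
    "apply_quality_filters",
    "apply_positional_filters",
    "apply_replicate_filters",
    "differential_aaf_test",
    "differential_aaf_tests",
    "bh_fdr",
    "coding_effect",
    "run_cascade",
]


@dataclass
class VariantSite:
    """One candidate substitution with per-sample read support.

    ``pos`` is 1-based (as printed in VCF).  ``depths`` and ``alt_counts``
    are per-sample read counts in a fixed sample order.  Site-level quality
    metrics mirror the conventional variant-caller INFO fields: total depth
    ``total_depth`` (DP), RMS mapping quality ``mq`` (MQ), quality-by-depth
    ``qd`` (QD) and the two rank-sum statistics (may be missing).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depths: np.ndarray
    alt_counts: np.ndarray
    total_depth: float = 0.0
    mq: float = 60.0
    qd: float = 20.0
    mq_rank_sum: float | None = None
    read_pos_rank_sum: float | None = None
    known_id: str | None = None

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        if self.depths.shape != self.alt_counts.shape:
            raise ValueError("depths and alt_counts must have the same length")
        if np.any(self.alt_counts > self.depths) or np.any(self.alt_counts < 0):
            raise ValueError(
                f"{self.chrom}:{self.pos}: alt counts must satisfy 0 <= alt <= depth"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_biallelic_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and "," not in self.alt
            and self.ref != self.alt
        )

    def aaf(self) -> np.ndarray:
        """Per-sample alternative allele frequency; NaN where depth is 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.depths > 0, self.alt_counts / self.depths, np.nan)


@dataclass(frozen=True)
class QualityThresholds:
    """Hard-filter bounds; a variant is removed iff any metric falls
    strictly below its bound (missing rank-sums pass)."""

    min_total_depth: float = 10.0
    min_mq: float = 40.0
    min_qd: float = 2.0
    min_mq_rank_sum: float = -12.5
    min_read_pos_rank_sum: float = -8.0


def fails_quality(site: VariantSite, thresholds: QualityThresholds) -> bool:
    t = thresholds
    if site.total_depth < t.min_total_depth:
        return True
    if site.mq < t.min_mq:
        return True
    if site.qd < t.min_qd:
        return True
    if site.mq_rank_sum is not None and site.mq_rank_sum < t.min_mq_rank_sum:
        return True
    if (
        site.read_pos_rank_sum is not None
        and site.read_pos_rank_sum < t.min_read_pos_rank_sum
    ):
        return True
    return False


@dataclass
class FilterLedger:
    """Ordered per-stage removal accounting for one cascade run."""

    input_count: int
    stages: list[tuple[str, int]] = field(default_factory=list)

    @property
    def removed_total(self) -> int:
        return sum(n for _, n in self.stages)

    @property
    def survivor_count(self) -> int:
        return self.input_count - self.removed_total

    def add_stage(self, name: str, removed: int) -> None:
        if removed < 0:
            raise ValueError("removed count cannot be negative")
        self.stages.append((name, removed))
        if self.survivor_count < 0:
            raise ValueError("ledger removed more variants than were input")

    def validate(self) -> None:
        if self.input_count != self.survivor_count + self.removed_total:
            raise ValueError("ledger does not conserve counts")

    def as_frame(self) -> pd.DataFrame:
        rows = []
        remaining = self.input_count
        for name, removed in self.stages:
            remaining -= removed
            rows.append({"stage": name, "removed": removed, "remaining": remaining})
        return pd.DataFrame(rows, columns=["stage", "removed", "remaining"])


class CascadeContext(Protocol):
    """Positional predicates consumed by the cascade (0-based positions)."""

    def is_bidirectional(self, chrom: str, pos: int) -> bool: ...

    def flank_multimaps(self, chrom: str, pos: int) -> bool: ...

    def in_ssr(self, chrom: str, pos: int) -> bool: ...

    def near_splice_boundary(self, chrom: str, pos: int) -> bool: ...


# ---------------------------------------------------------------------------
# Filter stages
# ---------------------------------------------------------------------------

def apply_quality_filters(
    variants: Sequence[VariantSite], thresholds: QualityThresholds | None = None
) -> tuple[list[VariantSite], tuple[str, int]]:
    """Remove variants failing any site-quality hard filter.

    Returns the survivors and a ``("quality", n_removed)`` ledger stage.
    """
    thresholds = thresholds or QualityThresholds()
    survivors = [v for v in variants if not fails_quality(v, thresholds)]
    return survivors, ("quality", len(variants) - len(survivors))


def apply_positional_filters(
    variants: Sequence[VariantSite], context: CascadeContext
) -> tuple[list[VariantSite], list[tuple[str, int]]]:
    """Remove variants in flagged genomic contexts, charging each to the
    first failing stage: bidirectional, then paralog (flank multi-mapping),
    then repeat (SSR mask), then splice proximity."""
    stages: list[tuple[str, Callable[[str, int], bool]]] = [
        ("bidirectional", context.is_bidirectional),
        ("paralog", context.flank_multimaps),
        ("repeat", context.in_ssr),
        ("splice_proximity", context.near_splice_boundary),
    ]
    current = list(variants)
    ledger_stages: list[tuple[str, int]] = []
    for name, predicate in stages:
        survivors = [v for v in current if not predicate(v.chrom, v.pos - 1)]
        ledger_stages.append((name, len(current) - len(survivors)))
        current = survivors
    return current, ledger_stages


def fails_replicate_support(
    site: VariantSite,
    min_zero_aaf: int | None = None,
    min_supporting: int | None = None,
) -> bool:
    """Replicate-support rule.

    A site fails when the alternative allele is absent (AAF = 0, counting
    depth-0 samples as absent) in at least ``min_zero_aaf`` libraries, or
    is observed in no more than ``min_supporting`` samples.  Defaults scale
    with sample count n as ceil(n/2) and floor(n/2) respectively, matching
    the 10-sample rules "absent in at least five libraries" and "observed
    in more than half the samples".
    """
    n = len(site.depths)
    if min_zero_aaf is None:
        min_zero_aaf = math.ceil(n / 2)
    if min_supporting is None:
        min_supporting = n // 2
    zero_aaf = int(np.sum((site.alt_counts == 0) | (site.depths == 0)))
    supporting = int(np.sum((site.alt_counts > 0) & (site.depths > 0)))
    return zero_aaf >= min_zero_aaf or supporting <= min_supporting


def apply_replicate_filters(
    variants: Sequence[VariantSite],
    min_zero_aaf: int | None = None,
    min_supporting: int | None = None,
) -> tuple[list[VariantSite], tuple[str, int]]:
    survivors = [
        v
        for v in variants
        if not fails_replicate_support(v, min_zero_aaf, min_supporting)
    ]
    return survivors, ("replicate_support", len(variants) - len(survivors))


# ---------------------------------------------------------------------------
# Differential AAF testing
# ---------------------------------------------------------------------------

@dataclass
class DifferentialAafResult:
    """Between-group comparison of alternative allele frequency at one site."""

    site: VariantSite
    case_aaf: float
    control_aaf: float
    fraction_difference: float
    p_value: float
    q_value: float | None = None
    undefined: bool = False
    fdr_alpha: float = 0.001

    @property
    def significant(self) -> bool:
        return self.q_value is not None and self.q_value < self.fdr_alpha


def _g_statistic(table: np.ndarray) -> float:
    """Likelihood-ratio (G) statistic of independence for a 2x2 count table."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2.0 * terms.sum())


def differential_aaf_test(
    site: VariantSite,
    group_labels: Sequence[int],
    method: str = "g-test",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> DifferentialAafResult:
    """Two-sided test for a group difference in alternative allele frequency.

    ``group_labels`` marks each sample as case (1) or control (0).  The
    default pools per-group (alt, ref) read counts into a 2x2 table and
    computes a binomial likelihood-ratio (G) statistic with a chi-square
    (df = 1) p-value.  ``method="permutation"`` instead permutes sample
    labels and compares mean per-sample AAF differences (exact enumeration
    whenever the number of label splits is at most ``n_permutations``).

    The reported ``fraction_difference`` is mean(case AAF) - mean(control
    AAF) over samples with nonzero depth.  A group with no covered sample
    yields an undefined (flagged, NaN) result.
    """
    labels = np.asarray(group_labels, dtype=bool)
    if labels.shape != site.depths.shape:
        raise ValueError("group_labels length must match sample count")
    aaf = site.aaf()
    case_ok = site.depths[labels] > 0
    ctrl_ok = site.depths[~labels] > 0
    if not case_ok.any() or not ctrl_ok.any():
        return DifferentialAafResult(
            site, float("nan"), float("nan"), float("nan"), float("nan"),
            undefined=True,
        )
    case_aaf = float(np.nanmean(aaf[labels]))
    ctrl_aaf = float(np.nanmean(aaf[~labels]))
    delta = case_aaf - ctrl_aaf
    if method == "g-test":
        case_alt = int(site.alt_counts[labels].sum())
        case_ref = int(site.depths[labels].sum()) - case_alt
        ctrl_alt = int(site.alt_counts[~labels].sum())
        ctrl_ref = int(site.depths[~labels].sum()) - ctrl_alt
        g = _g_statistic([[case_alt, case_ref], [ctrl_alt, ctrl_ref]])
        p = float(stats.chi2.sf(g, df=1)) if g > 0 else 1.0
    elif method == "permutation":
        p = _permutation_mean_diff_p(aaf, labels, n_permutations, seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    return DifferentialAafResult(site, case_aaf, ctrl_aaf, delta, p)


def _permutation_mean_diff_p(
    values: np.ndarray,
    labels: np.ndarray,
    n_permutations: int,
    seed: int | None,
) -> float:
    """Two-sided label-permutation p-value for a difference in group means.

    NaN values (uncovered samples) are ignored within each permuted group.
    Exact enumeration over all C(n, n_case) label splits when feasible,
    Monte-Carlo otherwise.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    n_case = int(labels.sum())
    observed = abs(np.nanmean(values[labels]) - np.nanmean(values[~labels]))
    if np.isnan(observed):
        return 1.0
    tol = 1e-12
    if math.comb(n, n_case) <= n_permutations:
        count = 0
        total = 0
        for idx in combinations(range(n), n_case):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
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


def differential_aaf_tests(
    variants: Sequence[VariantSite], group_labels: Sequence[int]
) -> list[DifferentialAafResult]:
    """Vectorised pooled-count G-test over many sites (same sample order)."""
    if not variants:
        return []
    labels = np.asarray(group_labels, dtype=bool)
    depths = np.stack([v.depths for v in variants])
    alts = np.stack([v.alt_counts for v in variants])
    with np.errstate(invalid="ignore", divide="ignore"):
        aaf = np.where(depths > 0, alts / depths, np.nan)
    case_alt = alts[:, labels].sum(axis=1).astype(float)
    case_dp = depths[:, labels].sum(axis=1).astype(float)
    ctrl_alt = alts[:, ~labels].sum(axis=1).astype(float)
    ctrl_dp = depths[:, ~labels].sum(axis=1).astype(float)
    g = _g_statistic_vec(case_alt, case_dp - case_alt, ctrl_alt, ctrl_dp - ctrl_alt)
    p = stats.chi2.sf(g, df=1)
    p = np.where(g > 0, p, 1.0)
    undefined = (case_dp == 0) | (ctrl_dp == 0)
    with np.errstate(invalid="ignore"):
        case_mean = np.nanmean(np.where(labels, aaf, np.nan), axis=1)
        ctrl_mean = np.nanmean(np.where(~labels, aaf, np.nan), axis=1)
    results = []
    for i, v in enumerate(variants):
        if undefined[i]:
            results.append(
                DifferentialAafResult(
                    v, float("nan"), float("nan"), float("nan"), float("nan"),
                    undefined=True,
                )
            )
        else:
            results.append(
                DifferentialAafResult(
                    v,
                    float(case_mean[i]),
                    float(ctrl_mean[i]),
                    float(case_mean[i] - ctrl_mean[i]),
                    float(p[i]),
                )
            )
    return results


def _g_statistic_vec(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    # 2x2 tables [[a, b], [c, d]] per site
    total = a + b + c + d
    total = np.where(total == 0, 1.0, total)

    def term(obs: np.ndarray, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        expected = row * col / total
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
        return t

    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    g = 2.0 * (term(a, r1, c1) + term(b, r1, c2) + term(c, r2, c1) + term(d, r2, c2))
    return np.maximum(g, 0.0)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN inputs are ignored for ranking and returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[mask] = out
    return q


# ---------------------------------------------------------------------------
# Coding effect
# ---------------------------------------------------------------------------

def coding_effect(
    site: VariantSite, gene: GeneModel, reference: Mapping[str, str]
) -> str:
    """Classify a substitution's effect on the gene's protein.

    Returns ``"synonymous"``, ``"missense"``, ``"nonsense"`` or
    ``"noncoding"``.  The coding sequence is assembled from the exonic
    portions of the CDS span, reverse-complemented for minus-strand genes,
    and the codon containing the site is translated before and after the
    substitution.  Raises ``ValueError`` if the CDS length is not a
    multiple of 3.
    """
    from Bio.Seq import Seq

    if gene.cds is None or gene.biotype != "coding":
        return "noncoding"
    pos0 = site.pos - 1
    cs, ce = gene.cds
    seq = reference[gene.chrom]
    pieces: list[tuple[int, int]] = []
    for es, ee in gene.exons:
        s, e = max(es, cs), min(ee, ce)
        if s < e:
            pieces.append((s, e))
    cds_len = sum(e - s for s, e in pieces)
    if cds_len % 3 != 0:
        raise ValueError(
            f"gene {gene.gene_id}: CDS length {cds_len} not divisible by 3"
        )
    offset = None
    acc = 0
    for s, e in pieces:
        if s <= pos0 < e:
            offset = acc + (pos0 - s)
            break
        acc += e - s
    if offset is None:
        return "noncoding"
    cds_seq = "".join(seq[s:e] for s, e in pieces).upper()
    ref_base, alt_base = site.ref.upper(), site.alt.upper()
    if gene.strand == "-":
        cds_seq = reverse_complement(cds_seq)
        offset = cds_len - 1 - offset
        ref_base = reverse_complement(ref_base)
        alt_base = reverse_complement(alt_base)
    if cds_seq[offset] != ref_base:
        raise ValueError(
            f"{site.chrom}:{site.pos}: reference allele {site.ref!r} does not "
            "match the transcript sequence"
        )
    codon_start = (offset // 3) * 3
    codon = cds_seq[codon_start : codon_start + 3]
    mutated = codon[: offset % 3] + alt_base + codon[offset % 3 + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeConfig:
    """Run parameters for :func:`run_cascade`.

    ``group_labels`` marks each sample (in VCF sample order) as case (1)
    or control (0); ``fdr_alpha`` is the q-value cut used for the
    ``significant`` flag (default 0.001).
    """

    group_labels: Sequence[int]
    thresholds: QualityThresholds = field(default_factory=QualityThresholds)
    fdr_alpha: float = 0.001
    min_zero_aaf: int | None = None
    min_supporting: int | None = None


@dataclass
class CascadeResult:
    survivors: list[VariantSite]
    ledger: FilterLedger
    results: list[DifferentialAafResult]
    removal_reasons: dict[tuple[str, int, str, str], str]

    def significant(self) -> list[DifferentialAafResult]:
        return [r for r in self.results if r.significant]

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "chrom": r.site.chrom,
                    "pos": r.site.pos,
                    "ref": r.site.ref,
                    "alt": r.site.alt,
                    "known_id": r.site.known_id,
                    "case_aaf": r.case_aaf,
                    "control_aaf": r.control_aaf,
                    "fraction_difference": r.fraction_difference,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                    "significant": r.significant,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "chrom", "pos", "ref", "alt", "known_id", "case_aaf",
                "control_aaf", "fraction_difference", "p_value", "q_value",
                "significant",
            ],
        )


def run_cascade(
    variants: Sequence[VariantSite],
    context: CascadeContext,
    config: CascadeConfig,
) -> CascadeResult:
    """Apply the full filter cascade and differential AAF test.

    Stages run in order (biallelic restriction, quality, bidirectional,
    paralog, repeat, splice proximity, replicate support); each variant is
    charged to the first stage it fails.  Survivors are tested with the
    pooled-count G-test and BH-adjusted; ``significant`` flags sites with
    q below ``config.fdr_alpha``.
    """
    ledger = FilterLedger(input_count=len(variants))
    reasons: dict[tuple[str, int, str, str], str] = {}

    def charge(removed: Sequence[VariantSite], stage: str) -> None:
        for v in removed:
            reasons[v.key] = stage

    current = [v for v in variants if v.is_biallelic_snv]
    charge([v for v in variants if not v.is_biallelic_snv], "multiallelic")
    ledger.add_stage("multiallelic", len(variants) - len(current))

    survivors, (name, removed) = apply_quality_filters(current, config.thresholds)
    charge([v for v in current if fails_quality(v, config.thresholds)], name)
    ledger.add_stage(name, removed)
    current = survivors

    survivors, stages = apply_positional_filters(current, context)
    kept = {v.key for v in survivors}
    # re-derive per-variant first-failing positional stage for the reasons map
    for v in current:
        if v.key in kept:
            continue
        p = v.pos - 1
        if context.is_bidirectional(v.chrom, p):
            reasons[v.key] = "bidirectional"
        elif context.flank_multimaps(v.chrom, p):
            reasons[v.key] = "paralog"
        elif context.in_ssr(v.chrom, p):
            reasons[v.key] = "repeat"
        else:
            reasons[v.key] = "splice_proximity"
    for name, removed in stages:
        ledger.add_stage(name, removed)
    current = survivors

    survivors, (name, removed) = apply_replicate_filters(
        current, config.min_zero_aaf, config.min_supporting
    )
    kept = {v.key for v in survivors}
    charge([v for v in current if v.key not in kept], name)
    ledger.add_stage(name, removed)
    current = survivors

    ledger.validate()
    results = differential_aaf_tests(current, config.group_labels)
    q = bh_fdr([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = None if np.isnan(qv) else float(qv)
        r.fdr_alpha = config.fdr_alpha
    return CascadeResult(current, ledger, results, reasons)
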