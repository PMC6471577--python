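# Methods

This note documents the models, rules and numerical choices behind
`editome`, and what the synthetic data do and do not establish.

## The filter cascade

Variant calls from RNA-seq are filtered in a fixed order; each variant
is removed at the **first** stage it fails, so per-stage removal counts
are disjoint and the ledger conserves counts exactly
(`input = survivors + Σ removed`).  The order is:

1. **biallelic restriction** — only single-base, biallelic substitutions
   proceed; anything else is ledgered as `multiallelic`;
2. **quality** — a variant is removed iff any site metric falls strictly
   below its bound: total depth DP < 10, RMS mapping quality MQ < 40,
   quality-by-depth QD < 2, MQRankSum < −12.5, ReadPosRankSum < −8.
   The comparisons are strict, so a variant sitting exactly on every
   bound survives.  Missing rank-sum statistics pass (they are undefined
   for homozygous-like sites);
3. **bidirectional** — the site lies inside gene bodies on both strands.
   Antisense transcription makes strand-specific artifact modes (and
   true antisense editing) indistinguishable, so these loci are dropped
   wholesale;
4. **paralog** — the site's flank window (site ± 50 bp) occurs a second
   time in the reference at ≥ 90% identity.  This is a seeded
   exact-8-mer + full-window-identity scan: with ≤ 10 mismatches allowed
   over a 101-base window, the pigeonhole bound guarantees any
   qualifying second copy shares an exact 8-mer with the window, so
   seeding cannot miss a hit at the default threshold.  Reverse-strand
   copies are not searched; duplications are modelled as direct repeats;
5. **repeat** — the site falls in a microsatellite mask: maximal perfect
   tandem repeats of 1–6-base primitive motifs meeting per-length
   minimum copy numbers (1-mer: 10, 2-mer: 6, 3-mer: 5, 4-mer: 5,
   5-mer: 5, 6-mer: 4), each tract extended by ± 3 bp.  The copy-number
   defaults are the conventional microsatellite-survey settings and are
   configurable (`SsrParams`);
6. **splice proximity** — intronic positions within 5 bp of either
   intron boundary.  The rule is intronic-only: exonic bases adjacent to
   a junction are kept;
7. **replicate support** — with n samples, a site is removed when the
   alternative allele is absent (AAF = 0) in ≥ ⌈n/2⌉ libraries **or**
   observed in ≤ ⌊n/2⌋ samples.  At n = 10 these are the "absent in at
   least five libraries" and "present in more than half" rules; they are
   not redundant because a depth-0 sample counts as absent (absence of
   evidence for the alternative allele) while contributing no
   observation.

Positional predicates are evaluated in the order bidirectional →
paralog → repeat → splice proximity, mirroring the narrative order of
the reference workflow; a site in several flagged contexts is charged to
the earliest.

## Differential allele-frequency test

The between-group test pools reads: per group, alternative and
reference read counts are summed over samples and compared in a 2×2
table with the binomial likelihood-ratio (G) statistic,
p from χ²(1).  The G-test was chosen over an opaque tool-internal
statistic because it is transparent and oracle-checkable (it equals
scipy's log-likelihood-ratio contingency test).  An exact
label-permutation alternative (statistic: difference of group mean
per-sample AAF) is available for small n; at 5 vs 5 it enumerates all
252 splits.  Pooling weights samples by depth and assumes read-level
binomial sampling within groups; with ~50× depth and equal designs this
calibrates to nominal type-I error (measured at 0.05 ± 0.01 over 10⁴
null sites by the acceptance script).  ΔAAF is reported as
mean(case AAF) − mean(control AAF) over covered samples — an unweighted
mean, deliberately matching how fraction differences are usually
reported rather than the pooled estimate.  FDR control is
Benjamini–Hochberg step-up; the significance cut for variant selection
is q < 0.001.

A group with no covered sample yields an undefined, flagged result that
is excluded from FDR ranking.

## Editing qualification

A significant site is an RNA-editing candidate iff all of:

* canonical chemistry on the transcript strand: A→G (A-to-I) or C→T
  (C-to-U) after reverse-complementing minus-strand genes.  Orientation
  happens before the canonicality test, so a genome-strand T>C in a
  minus-strand gene qualifies;
* max per-sample AAF strictly < 0.7 — a genomic heterozygote or
  homozygote drifts to 0.5/1.0, while editing is typically partial;
* no known-variant catalog identifier;
* inside a gene but outside the CDS (UTRs and introns qualify —
  documented candidate sets include both 3′UTR and intronic sites).

Sites in no gene are sent to the SNV pool: the transcript strand, and
hence the chemistry, is undefined (both orientations are evaluated and
the ambiguity flagged).  Classes are disjoint and exhaustive; failed
conditions are listed per site.

## Region annotation

One annotation per overlapping or flanking gene (one transcript model
per gene), with precedence SPLICE_SITE_ACCEPTOR > SPLICE_SITE_REGION >
EXON/UTR > INTRON > UPSTREAM/DOWNSTREAM inside a gene.  `EXON` means
coding-exon (CDS) positions; exonic positions outside the CDS are
UTR_5_PRIME/UTR_3_PRIME strand-aware; ncRNA exons are NCRNA.  The
splice-site window is intronic: the last 2 intron bases on the acceptor
side (transcript orientation), and other intronic bases within 8 bases
of a boundary as SPLICE_SITE_REGION.  Up/downstream extends 5,000 bases
beyond the gene, symmetrically on both sides.  A site with no gene
within the extent is INTERGENIC.  Internally all coordinates are
0-based half-open; VCF/GTF conversion happens only in `editome.io`.

## PSI and ΔPSI

From junction counts, ψ = (I/l_I) / (I/l_I + S/l_S) with effective
lengths defaulting to l_I = 2, l_S = 1 for cassette exons (an included
exon is supported by two junctions, the skipped form by one); both are
configurable per event type.  I = S = 0 yields a missing value, never
zero.  From isoform abundances, ψ = inclusion / total.  ΔPSI =
mean(case ψ) − mean(control ψ) with missing samples excluded, so
positive ΔPSI means higher inclusion in cases.  Significance is an
exact two-sided label-permutation test on |mean difference| (all
C(n, n_case) splits when ≤ 10,000, Monte-Carlo with a caller-supplied
seed otherwise; ties at the observed statistic count as extreme, with a
10⁻¹² tolerance), BH-adjusted across events at FDR 0.05.  At 5 vs 5
the smallest attainable p is 2/252 ≈ 0.0079, which bounds per-event
resolution; the test is assumption-free and exactly calibrated at this
design size.  Event identifiers are colon/dash coordinate strings;
parsing validates the field shape per event type and formatting
reproduces the input byte-for-byte.  Alternative first/last-exon
families with more than two variants are encoded as one event per
alternative variant.  Only junction-count quantification is
implemented; read-on-target counting is out of scope.

## Synthetic data

The generator emulates the study conditions the pipeline targets: two
groups of five libraries, per-site per-sample depths Poisson around a
mean of 50 (floored at 1 — a called site has at least one read), and
binomial alternative counts at the group's true allele fraction.  The
default layout plants, on a 60 kb chromosome: six three-exon coding
genes, one antisense ncRNA overlapping the first gene (the
bidirectional locus), a GCA×7 and an A×12 microsatellite, a 200 bp
zero-divergence duplication, four canonical editing sites whose
case–control fraction differences (0.047, 0.106, 0.122, 0.178) span
the range reported for placental A-to-I candidates over a 0.15
baseline, three catalogued SNPs at fixed allele fractions, and
per-stage noise sites placed deterministically inside the feature each
cascade stage tests (quality-failing sites violate one threshold each,
cycling through the five).  Junction counts are binomial out of a
Poisson total with success probability equal to the length-adjusted
inclusion fraction, making the effective-length-corrected estimator
consistent; the planted PSI pairs include a (0.7, 0.98)
inclusion-deficit event reproducing a ΔPSI ≈ −0.28 exon-skipping
pattern.  All randomness derives from the config seed through three
independent child streams (reference, variants, junctions), so a config
determines its fixtures byte-for-byte.

Background noise rates for non-editing SNVs are free parameters of the
generator (no reference noise model exists for them); the defaults
plant a known count per cascade stage so ledger tests are exact.  What
the generator does **not** emulate: read-level errors and mapping
artifacts, indels and structural variants, multi-allelic sites,
overdispersion beyond binomial sampling, correlated samples, and
isoform-level coverage biases.  Passing recovery tests therefore
demonstrates correctness of the filtering/testing machinery under the
assumed sampling model, not robustness to alignment artifacts in real
data.

A separate planted-ledger fixture builds 88,859 minimal variant records
whose context flags and read patterns are chosen so the cascade
reproduces a reference per-stage ledger (16,584 quality; 24,877
bidirectional; 13,310 paralog; 2,529 repeat; 723 splice-proximal;
23,184 replicate-support; 7,652 survivors) by construction — it
validates the accounting, not the predicates, which the simulated
dataset exercises through the real genome context.

## Numerical choices and degenerate inputs

* BH q-values: step-up with monotone enforcement from the largest p;
  NaN p-values are excluded from ranking and returned NaN.
* G statistic: 0·log 0 terms are zero; an all-equal table gives G = 0,
  p = 1 exactly.
* Depth-0 samples: AAF undefined (NaN), excluded from means; counted as
  "absent" by the replicate rule.
* `psi_from_junctions(0, 0)` and `psi_from_isoforms(·, 0)` are missing,
  and missing values propagate through ΔPSI by exclusion.
* Coding effects translate the affected codon before/after substitution
  (stop gained = nonsense); a CDS whose spliced length is not a multiple
  of 3 is an error, as is a reference-allele mismatch.
* Ledger arithmetic is validated at construction and again before report
  emission.

## Problem sizes

The test suite and acceptance script run, on one CPU in well under a
minute of compute each: the 88,859-variant planted ledger (~3 s),
10,000-replicate null calibrations for both tests, a 2,200-site
recovery experiment, and 10,000× coverage PSI accuracy checks — sizes
chosen to make binomial concentration bounds (± 0.02) and calibration
windows (± 0.015 around α = 0.05) comfortably testable.

## Known limitations

* One transcript model per gene; isoform-resolved annotation is out of
  scope.
* The flank-uniqueness surrogate searches direct repeats only and is not
  a local aligner; diverged paralogs below seed/identity limits escape
  it.
* The pooled G-test treats reads within a group as exchangeable;
  strong per-sample overdispersion would inflate its type-I error
  (the permutation variant is the robust fallback).
* Exact permutation granularity (min p = 2/252) caps per-event evidence
  at 5 vs 5; FDR across many events inherits that discreteness.
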