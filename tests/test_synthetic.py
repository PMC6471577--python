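"""Synthetic data generator: determinism, planted features, moment
recovery and truth bookkeeping."""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import pytest

import editome as e
from editome import io
from editome.synthetic import (
    ConfigurationError,
    PlantedEditingSite,
    SimulationConfig,
    build_gene_models,
    build_truth,
    generate_reference,
    simulate_junction_counts,
    simulate_variant_calls,
)
from editome.splicing import psi_from_junctions


class TestGenerateReference:
    def test_same_seed_byte_identical(self, tmp_path):
        for sub in ("a", "b"):
            ds = e.simulate(SimulationConfig.default(5))
            e.write_fixtures(ds, tmp_path / sub)
        files = [p.name for p in (tmp_path / "a").iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", files, shallow=False
        )
        assert sorted(match) == sorted(files) and not mismatch and not errors

    def test_different_seeds_differ(self):
        ref1, _ = generate_reference(SimulationConfig.default(1))
        ref2, _ = generate_reference(SimulationConfig.default(2))
        assert ref1 != ref2

    def test_zero_divergence_duplication_identical(self):
        cfg = SimulationConfig.default(3)
        ref, _ = generate_reference(cfg)
        (src_s, src_e), target, div = cfg.duplicated_segments[0]
        assert div == 0.0
        seq = ref[cfg.chrom]
        assert seq[src_s:src_e] == seq[target : target + (src_e - src_s)]

    def test_ssr_tract_planted_verbatim(self):
        cfg = SimulationConfig.default(4)
        ref, _ = generate_reference(cfg)
        seq = ref[cfg.chrom]
        motif, copies, pos = cfg.ssr_tracts[0]
        # direct string scan
        assert seq[pos : pos + len(motif) * copies] == motif * copies

    def test_editing_reference_base_is_adenosine_on_transcript_strand(self):
        cfg = SimulationConfig.default(6)
        ref, genes = generate_reference(cfg)
        seq = ref[cfg.chrom]
        strand = {g.gene_id: g.strand for g in genes}
        for site in cfg.planted_editing_sites:
            expected = "A" if strand[site.gene_id] == "+" else "T"
            assert seq[site.pos] == expected

    def test_bidirectional_pair_present(self):
        _, genes = generate_reference(SimulationConfig.default(1))
        from editome.context import is_bidirectional

        g1 = next(g for g in genes if g.gene_id == "g1")
        anti = next(g for g in genes if g.gene_id == "g1_as")
        overlap = max(g1.start, anti.start)
        assert is_bidirectional(g1.chrom, overlap + 60, genes)

    def test_conflicting_features_rejected(self):
        with pytest.raises(ConfigurationError, match="overlap"):
            cfg = SimulationConfig(
                seed=1,
                ssr_tracts=(("GCA", 7, 47_000),),
                duplicated_segments=(((46_990, 47_100), 47_005, 0.0),),
            )
            generate_reference(cfg)

    def test_out_of_bounds_feature_rejected(self):
        with pytest.raises(ConfigurationError, match="outside"):
            generate_reference(
                SimulationConfig(seed=1, ssr_tracts=(("A", 20, 59_995),))
            )

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(
                seed=1,
                planted_editing_sites=(
                    PlantedEditingSite("g1", 2100, 0.9, 0.2),
                ),
            )


class TestSimulateVariantCalls:
    def test_zero_aaf_gives_zero_alt_everywhere(self):
        cfg = SimulationConfig(
            seed=2, planted_known_snps=((40_000, "rs0", 0.0),),
            noise_sites={},
        )
        ref, genes = generate_reference(cfg)
        truth = build_truth(cfg, genes)
        sites = simulate_variant_calls(cfg, truth, genes, ref)
        snp = next(s for s in sites if s.pos == 40_001)
        assert (snp.alt_counts == 0).all()

    def test_aaf_concentrates_at_high_depth(self):
        """At depth 10,000 the observed AAF is within 0.02 of truth and
        the group-mean difference recovers the planted fraction
        difference."""
        cfg = SimulationConfig(
            seed=3,
            read_depth_mean=10_000,
            planted_editing_sites=(
                PlantedEditingSite("g3", _g3_intron_mid(), 0.35, 0.15),
            ),
            planted_known_snps=((40_000, "rs1", 0.5),),
            noise_sites={},
        )
        ref, genes = generate_reference(cfg)
        truth = build_truth(cfg, genes)
        sites = simulate_variant_calls(cfg, truth, genes, ref)
        snp = next(s for s in sites if s.pos == 40_001)
        assert abs(float(snp.aaf().mean()) - 0.5) < 0.02
        edit = next(s for s in sites if s.pos == _g3_intron_mid() + 1)
        labels = cfg.group_labels.astype(bool)
        diff = float(edit.aaf()[labels].mean() - edit.aaf()[~labels].mean())
        assert abs(diff - 0.15) < 0.02

    def test_determinism(self):
        cfg = SimulationConfig.default(9)
        a = e.simulate(cfg)
        b = e.simulate(cfg)
        assert [v.key for v in a.variants] == [v.key for v in b.variants]
        for va, vb in zip(a.variants, b.variants):
            assert (va.depths == vb.depths).all()
            assert (va.alt_counts == vb.alt_counts).all()


def _g3_intron_mid() -> int:
    from editome.synthetic import _gene_start

    return _gene_start(2) + 900


class TestSimulateJunctionCounts:
    def test_pure_inclusion_truth(self):
        cfg = SimulationConfig(seed=4, true_psi=(("g1", 1.0, 1.0),), noise_sites={})
        _, genes = generate_reference(cfg)
        truth = build_truth(cfg, genes)
        counts = simulate_junction_counts(cfg, truth)
        assert (counts["skipping_count"] == 0).all()

    def test_psi_estimate_concentrates_at_high_coverage(self):
        cfg = SimulationConfig(
            seed=5, junction_coverage_mean=10_000,
            true_psi=(("g1", 0.5, 0.5),), noise_sites={},
        )
        _, genes = generate_reference(cfg)
        truth = build_truth(cfg, genes)
        counts = simulate_junction_counts(cfg, truth)
        psi = counts.apply(
            lambda r: psi_from_junctions(
                r.inclusion_count, r.skipping_count,
                cfg.l_inclusion, cfg.l_skipping,
            ),
            axis=1,
        )
        assert (psi - 0.5).abs().max() < 0.02

    def test_same_seed_identical_tables(self):
        cfg = SimulationConfig.default(6)
        _, genes = generate_reference(cfg)
        truth = build_truth(cfg, genes)
        a = simulate_junction_counts(cfg, truth)
        b = simulate_junction_counts(cfg, truth)
        assert a.equals(b)


class TestTruthBookkeeping:
    def test_categories_mutually_exclusive(self, default_dataset):
        truth = default_dataset.truth
        assert len(truth.positions()) == len(set(truth.positions()))
        planted = set(truth.editing_sites) | set(truth.known_snps)
        for pos in planted:
            assert truth.removal_category[pos] == "survivor"

    def test_removal_category_matches_cascade(self, default_dataset, default_cascade):
        """Every planted site is removed at exactly the stage the truth
        records (or survives)."""
        _, result = default_cascade
        by_pos = {v.pos - 1: v for v in default_dataset.variants}
        for pos, expected in default_dataset.truth.removal_category.items():
            actual = result.removal_reasons.get(by_pos[pos].key, "survivor")
            assert actual == expected, f"position {pos}"


class TestRoundTrips:
    def test_vcf_round_trip(self, default_dataset, tmp_path):
        path = tmp_path / "v.vcf"
        contigs = {c: len(s) for c, s in default_dataset.reference.items()}
        io.write_vcf(default_dataset.variants, default_dataset.samples, path, contigs)
        back, samples = io.read_vcf(path)
        assert samples == default_dataset.samples
        assert len(back) == len(default_dataset.variants)
        orig = {v.key: v for v in default_dataset.variants}
        for v in back:
            o = orig[v.key]
            assert (v.depths == o.depths).all()
            assert (v.alt_counts == o.alt_counts).all()
            assert v.known_id == o.known_id
            assert v.total_depth == pytest.approx(o.total_depth)

    def test_gtf_round_trip(self, default_dataset, tmp_path):
        path = tmp_path / "g.gtf"
        io.write_gtf(default_dataset.genes, path)
        back = {g.gene_id: g for g in io.read_gtf(path)}
        for g in default_dataset.genes:
            r = back[g.gene_id]
            assert (r.exons, r.cds, r.strand, r.biotype) == (
                g.exons, g.cds, g.strand, g.biotype
            )

    def test_empty_variant_set_valid_vcf(self, tmp_path):
        path = tmp_path / "empty.vcf"
        io.write_vcf([], ["s1", "s2"], path, {"chr1": 1000})
        back, samples = io.read_vcf(path)
        assert back == [] and samples == ["s1", "s2"]
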