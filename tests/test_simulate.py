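import json

import numpy as np
import pandas as pd
import pytest

from enhancerkit.core import ChromSizes
from enhancerkit.simulate import (
    SyntheticConfig,
    child_rng,
    generate_annotation,
    plant_enhancers,
    simulate_bundle,
    simulate_tags,
    write_fixture_bundle,
)

from conftest import SMALL_SYNTH


class TestChildRng:
    def test_streams_independent(self):
        a = child_rng(1, "tags", "k27ac", "treated", "rep1").integers(0, 1 << 30, 10)
        b = child_rng(1, "tags", "k27ac", "treated", "rep2").integers(0, 1 << 30, 10)
        a2 = child_rng(1, "tags", "k27ac", "treated", "rep1").integers(0, 1 << 30, 10)
        assert list(a) == list(a2)
        assert list(a) != list(b)


class TestGenerateAnnotation:
    def test_zero_genes(self):
        cfg = SyntheticConfig(n_genes=0)
        _sizes, tss = generate_annotation(cfg)
        assert tss == []

    def test_deterministic(self, small_config):
        _s1, t1 = generate_annotation(small_config)
        _s2, t2 = generate_annotation(small_config)
        assert t1 == t2

    def test_gene_geometry_valid(self, small_config):
        sizes, tss = generate_annotation(small_config)
        assert len(tss) == small_config.n_genes
        spans = []
        for rec in tss:
            lo, hi = sorted((rec.tss, rec.gene_end))
            assert 0 <= lo < hi <= sizes[rec.chrom]
            assert 5000 <= rec.length <= 50_000
            spans.append((lo, hi))
        spans.sort()
        for (l1, h1), (l2, h2) in zip(spans, spans[1:]):
            assert h1 <= l2, "gene bodies overlap"

    def test_too_small_genome(self):
        cfg = SyntheticConfig(genome={"c": 50_000}, n_genes=30)
        with pytest.raises(ValueError):
            generate_annotation(cfg)


class TestPlantEnhancers:
    def test_class_counts_match_config(self, small_config):
        truth = plant_enhancers(small_config)
        counts = truth.class_counts()
        assert counts["megatrans"] == small_config.n_megatrans
        assert counts["eralpha_other_active"] == small_config.n_eralpha_other
        assert counts["other_active"] == small_config.n_other_active
        assert counts["decoy_tss"] == small_config.n_decoy_tss

    def test_decoy_design(self, small_config):
        truth = plant_enhancers(small_config)
        loci = truth.loci
        k27_decoys = loci[loci.label == "decoy_k27ac"]
        assert (k27_decoys["mass_k27ac_treated"] == 0).all()
        assert (k27_decoys["mass_nascent_control"] > 0).all()
        nas_decoys = loci[loci.label == "decoy_nascent"]
        assert (nas_decoys["mass_nascent_control"] == 0).all()
        assert (nas_decoys["mass_k27ac_treated"] > 0).all()
        tss_decoys = loci[loci.label == "decoy_tss"]
        for row in tss_decoys.itertuples():
            d = min(abs(row.center - t.tss) for t in truth.tss if t.chrom == row.chrom)
            assert d < 3000

    def test_real_loci_distal(self, small_config):
        truth = plant_enhancers(small_config)
        real = truth.loci[~truth.loci.label.str.startswith("decoy")]
        for row in real.itertuples():
            d = min(abs(row.center - t.tss) for t in truth.tss if t.chrom == row.chrom)
            assert d >= 3000

    def test_band_fc_range(self, small_config):
        truth = plant_enhancers(small_config)
        band = truth.loci[truth.loci.label.isin(["eralpha_other_active", "other_active"])]
        assert band["nascent_target_fc"].between(
            small_config.band_fc_low, small_config.band_fc_high
        ).all()

    def test_balanced_masses_hit_normalized_fc_targets(self, small_config):
        """Expected normalized fold-change equals the target exactly."""
        truth = plant_enhancers(small_config)
        bg = small_config.background_rate["nascent"] * ChromSizes(
            small_config.genome
        ).genome_length
        tot_c = truth.loci["mass_nascent_control"].sum() + \
            truth.genes["nascent_mass_control"].sum() + bg
        tot_t = truth.loci["mass_nascent_treated"].sum() + \
            truth.genes["nascent_mass_treated"].sum() + bg
        planted = truth.loci[truth.loci["mass_nascent_control"] > 0]
        for row in planted.itertuples():
            norm_fc = (row.mass_nascent_treated / tot_t) / (
                row.mass_nascent_control / tot_c
            )
            assert norm_fc == pytest.approx(row.nascent_target_fc, rel=1e-9)

    def test_insufficient_space_errors(self):
        cfg = SyntheticConfig(
            genome={"c": 400_000}, n_genes=4, n_megatrans=500,
        )
        with pytest.raises(ValueError, match="insufficient intergenic space"):
            plant_enhancers(cfg)

    def test_excess_beyond_ballast_errors(self):
        cfg = SyntheticConfig(
            **{**SMALL_SYNTH, "erna_fc": 500.0, "nascent_base_mass": 5000.0}, seed=1
        )
        with pytest.raises(ValueError, match="exceeds shared library mass"):
            plant_enhancers(cfg)


class TestSimulateTags:
    def test_unknown_assay(self, small_config):
        truth = plant_enhancers(small_config)
        with pytest.raises(ValueError, match="unknown assay"):
            simulate_tags(truth, "atac", "treated", "rep1", small_config)

    def test_empty_when_no_mass(self):
        cfg = SyntheticConfig(
            genome={"c": 500_000}, n_genes=0, n_megatrans=0, n_eralpha_other=0,
            n_other_active=0, n_decoy_tss=0, n_decoy_k27ac=0, n_decoy_nascent=0,
            background_rate={a: 0.0 for a in ("k27ac", "nascent", "polii", "tf", "top1cc")},
        )
        truth = plant_enhancers(cfg)
        recs = simulate_tags(truth, "k27ac", "treated", "rep1", cfg)
        assert len(recs) == 0

    def test_replicates_differ_same_expectation(self, small_config):
        truth = plant_enhancers(small_config)
        r1 = simulate_tags(truth, "tf", "treated", "rep1", small_config)
        r2 = simulate_tags(truth, "tf", "treated", "rep2", small_config)
        assert not r1.equals(r2)
        assert abs(len(r1) - len(r2)) < 6 * np.sqrt(max(len(r1), 1))

    def test_reproducible(self, small_config):
        truth = plant_enhancers(small_config)
        r1 = simulate_tags(truth, "nascent", "treated", "rep1", small_config)
        r2 = simulate_tags(truth, "nascent", "treated", "rep1", small_config)
        pd.testing.assert_frame_equal(r1, r2)

    def test_poisson_concentration_at_locus(self, small_config):
        truth = plant_enhancers(small_config)
        row = truth.loci[truth.loci.label == "megatrans"].iloc[0]
        mass = row["mass_k27ac_treated"]
        recs = simulate_tags(truth, "k27ac", "treated", "rep1", small_config)
        near = recs[
            (recs["chrom"] == row["chrom"])
            & (recs["position"] - row["center"]).abs().le(2000)
        ]
        assert abs(len(near) - mass) < 4 * np.sqrt(mass)

    def test_divergent_erna_geometry(self):
        # zero background so every tag near the locus is a planted eRNA tag
        cfg = SyntheticConfig(**{**SMALL_SYNTH, "background_rate": {
            a: 0.0 for a in ("k27ac", "nascent", "polii", "tf", "top1cc")}}, seed=7)
        truth = plant_enhancers(cfg)
        row = truth.loci[truth.loci.label == "eralpha_other_active"].iloc[0]
        recs = simulate_tags(truth, "nascent", "treated", "rep1", cfg)
        near = recs[
            (recs["chrom"] == row["chrom"])
            & (recs["position"] - row["center"]).abs().le(1000)
        ]
        plus = near[near.strand == "+"]
        minus = near[near.strand == "-"]
        # offsets round to the nearest bp, so a tag may land exactly on center
        assert (plus["position"] >= row["center"]).all()
        assert (minus["position"] <= row["center"]).all()

    def test_expected_window_count_over_seeds(self):
        """Mean simulated tag count at a locus matches the planted mass."""
        base = dict(SMALL_SYNTH)
        totals = []
        mass = None
        for seed in range(50):
            cfg = SyntheticConfig(**base, seed=seed)
            truth = plant_enhancers(cfg)
            row = truth.loci[truth.loci.label == "megatrans"].iloc[0]
            mass = row["mass_k27ac_treated"]
            recs = simulate_tags(truth, "k27ac", "treated", "rep1", cfg)
            near = recs[
                (recs["chrom"] == row["chrom"])
                & (recs["position"] - row["center"]).abs().le(2500)
            ]
            totals.append(len(near))
        # window +/-2500 captures essentially the whole Normal(sd=450) mass
        mc_err = 4 * np.sqrt(mass / 50)
        assert abs(np.mean(totals) - mass) < mc_err + 0.01 * mass


class TestWriteFixtureBundle:
    def test_bundle_contents_and_checksums(self, tmp_path, small_config):
        truth = plant_enhancers(small_config)
        _bundle, records = simulate_bundle(truth, small_config)
        manifest = write_fixture_bundle(truth, records, tmp_path / "fx", small_config)
        fx = tmp_path / "fx"
        for name in ("genome.chrom.sizes", "tss.tsv", "truth_loci.tsv", "manifest.yaml"):
            assert (fx / name).exists()
        checksums = json.loads((fx / "checksums.json").read_text())
        assert "manifest.yaml" in checksums
        # every tag directory file listed and present
        import yaml

        m = yaml.safe_load(manifest.read_text())
        for entry in m["tags"]:
            assert (fx / entry["path"]).exists()
            assert entry["path"] in checksums

    def test_refuses_nonempty_dir(self, tmp_path, small_config):
        truth = plant_enhancers(small_config)
        _bundle, records = simulate_bundle(truth, small_config)
        out = tmp_path / "fx"
        write_fixture_bundle(truth, records, out, small_config)
        with pytest.raises(FileExistsError):
            write_fixture_bundle(truth, records, out, small_config)
        write_fixture_bundle(truth, records, out, small_config, force=True)

    def test_checksums_reproducible(self, tmp_path, small_config):
        truth = plant_enhancers(small_config)
        _bundle, records = simulate_bundle(truth, small_config)
        write_fixture_bundle(truth, records, tmp_path / "a", small_config)
        write_fixture_bundle(truth, records, tmp_path / "b", small_config)
        ca = json.loads((tmp_path / "a" / "checksums.json").read_text())
        cb = json.loads((tmp_path / "b" / "checksums.json").read_text())
        assert ca == cb


class TestTop1ccErnaCoupling:
    def test_planted_coupling_positive(self, default_truth_bundle):
        _cfg, truth, _bundle = default_truth_bundle
        loci = truth.loci[truth.loci["mass_nascent_control"] > 0]
        mass = loci["mass_top1cc_treated"].to_numpy()
        fc = loci["nascent_target_fc"].to_numpy()
        r = np.corrcoef(mass, fc)[0, 1]
        assert r > 0.5

    def test_measured_coupling_positive(self, default_truth_bundle):
        from enhancerkit.core import GenomicInterval
        from enhancerkit.overlap import region_tag_correlation

        _cfg, truth, bundle = default_truth_bundle
        regions = [
            GenomicInterval(row.chrom, row.center - 1000, row.center + 1000)
            for row in truth.loci.itertuples()
            if not row.label.startswith("decoy")
        ]
        r, p = region_tag_correlation(
            bundle.pooled("top1cc", "treated"),
            bundle.pooled("nascent", "treated"),
            regions,
            alternative="greater",
        )
        assert r > 0
        assert p < 0.01
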