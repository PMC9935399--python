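import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from enhancerkit.core import ChromSizes, TssRecord
from enhancerkit.tags import (
    AssayBundle,
    TagDirectory,
    build_tag_directory,
    count_range,
    count_window,
    merge_directories,
    normalized_count,
    profile_matrix,
    quantify_gene_body,
    read_tagalign,
    write_tagalign,
)

from conftest import make_directory, random_tags


class TestBuildTagDirectory:
    def test_cap_two_retains_two(self, sizes):
        d = make_directory([("chr1", 100, "+")] * 5, sizes, cap=2)
        assert d.raw_total == 5
        assert d.capped_total == 2

    def test_cap_three_nascent_mode(self, sizes):
        d = make_directory([("chr1", 100, "+")] * 5, sizes, cap=3)
        assert d.capped_total == 3

    def test_cap_oracle_random(self, sizes, rng):
        tags = random_tags(rng, sizes, 500)
        # force collisions by quantizing positions
        tags["position"] = (tags["position"] // 10_000) * 10_000
        for cap in (1, 2, 3):
            d = make_directory(tags, sizes, cap=cap)
            expected = (
                tags.groupby(["chrom", "position", "strand"])
                .size()
                .clip(upper=cap)
                .sum()
            )
            assert d.capped_total == expected

    def test_strand_blind_cap(self, sizes):
        tags = [("chr1", 100, "+")] * 3 + [("chr1", 100, "-")] * 3
        d_aware = make_directory(tags, sizes, cap=2)
        assert d_aware.capped_total == 4
        df = pd.DataFrame(tags, columns=["chrom", "position", "strand"])
        d_blind = build_tag_directory(
            df, "chip", "t", "r1", 2, sizes, strand_aware_cap=False
        )
        assert d_blind.capped_total == 2

    def test_empty_errors(self, sizes):
        with pytest.raises(ValueError, match="no tags"):
            make_directory([], sizes)

    def test_out_of_bounds_position(self, sizes):
        with pytest.raises(ValueError, match="out of bounds"):
            make_directory([("chr2", 500_000, "+")], sizes)

    def test_unknown_chrom(self, sizes):
        with pytest.raises(ValueError, match="unknown chromosome"):
            make_directory([("chr9", 10, "+")], sizes)

    def test_norm_factor(self, sizes):
        d = make_directory([("chr1", i, "+") for i in range(100)], sizes)
        assert d.norm_factor == pytest.approx(10_000_000 / 100)


class TestNormalizedCount:
    def test_ratio_formula(self, sizes):
        # same ratio as the reference case: 8 raw at depth 5e6 -> 16.0
        d = make_directory(
            [("chr1", i, "+") for i in range(5)], sizes, norm_target=10
        )
        assert normalized_count(d, 8) == pytest.approx(16.0)

    def test_zero(self, sizes):
        d = make_directory([("chr1", 1, "+")], sizes)
        assert normalized_count(d, 0) == 0.0

    def test_identity_at_target_depth(self, sizes):
        d = make_directory([("chr1", i, "+") for i in range(10)], sizes, norm_target=10)
        assert normalized_count(d, 10) == pytest.approx(10.0)

    @given(st.integers(0, 1000), st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_linearity(self, a, b):
        sizes = ChromSizes({"chr1": 1000})
        d = build_tag_directory(
            pd.DataFrame({"chrom": "chr1", "position": range(20), "strand": "+"}),
            "chip", "t", "r1", 2, sizes,
        )
        assert normalized_count(d, a + b) == pytest.approx(
            normalized_count(d, a) + normalized_count(d, b)
        )


class TestCountWindow:
    def test_empty_window(self, sizes):
        d = make_directory([("chr1", 100, "+")], sizes)
        assert count_window(d, "chr1", 500_000, 100) == 0.0

    def test_inclusive_boundaries(self, sizes):
        d = make_directory(
            [("chr1", 900, "+"), ("chr1", 1100, "-"), ("chr1", 899, "+"), ("chr1", 1101, "-")],
            sizes,
        )
        # window [900, 1100] inclusive catches exactly the two boundary tags
        assert count_window(d, "chr1", 1000, 100) == pytest.approx(
            2 * d.norm_factor
        )

    def test_unknown_chrom_errors(self, sizes):
        d = make_directory([("chr1", 100, "+")], sizes)
        with pytest.raises(ValueError, match="unknown chromosome"):
            count_window(d, "chrV", 100, 50)

    def test_strand_modes(self, sizes):
        d = make_directory(
            [("chr1", 100, "+"), ("chr1", 101, "-"), ("chr1", 102, "-")], sizes
        )
        f = d.norm_factor
        assert count_window(d, "chr1", 100, 10) == pytest.approx(3 * f)
        assert count_window(d, "chr1", 100, 10, "sense", "+") == pytest.approx(1 * f)
        assert count_window(d, "chr1", 100, 10, "antisense", "+") == pytest.approx(2 * f)
        assert count_window(d, "chr1", 100, 10, "sense", "-") == pytest.approx(2 * f)

    def test_scan_oracle(self, sizes, rng):
        tags = random_tags(rng, sizes, 2000)
        d = make_directory(tags, sizes, cap=3)
        expanded = d.to_records()
        for _ in range(100):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            center = int(rng.integers(0, sizes[chrom]))
            hw = int(rng.integers(1, 20_000))
            sub = expanded[
                (expanded["chrom"] == chrom)
                & (expanded["position"] >= center - hw)
                & (expanded["position"] <= center + hw)
            ]
            expected = sub["count"].sum() * d.norm_factor
            assert count_window(d, chrom, center, hw) == pytest.approx(expected)

    def test_depth_doubling_invariance(self, sizes, rng):
        tags = random_tags(rng, sizes, 1000)
        tags = tags.drop_duplicates(["chrom", "position", "strand"])
        d1 = make_directory(tags, sizes, cap=2)
        d2 = make_directory(pd.concat([tags, tags]), sizes, cap=2)
        for center in (1000, 250_000, 800_000):
            assert count_window(d1, "chr1", center, 5000) == pytest.approx(
                count_window(d2, "chr1", center, 5000)
            )


class TestProfileMatrix:
    def test_uniform_tags_flat_profile(self, sizes):
        tags = [("chr1", p, "+") for p in range(100_000, 110_000)]
        d = make_directory(tags, sizes)
        prof = profile_matrix(d, [("chr1", 105_000, "+")], flank=3000, binsize=100)
        inner = prof.matrix[0]
        assert np.allclose(inner, inner[0])

    def test_single_tag_central_bin(self, sizes):
        d = make_directory([("chr1", 100_000, "+")], sizes)
        prof = profile_matrix(d, [("chr1", 100_000, "+")], flank=1000, binsize=100)
        assert np.count_nonzero(prof.matrix[0]) == 1
        assert prof.matrix[0][10] > 0  # bin [100_000, 100_100)

    def test_minus_strand_reversed(self, sizes):
        d = make_directory([("chr1", 100_500, "+")], sizes)  # 500 bp downstream
        plus = profile_matrix(d, [("chr1", 100_000, "+")], flank=1000, binsize=100)
        minus = profile_matrix(d, [("chr1", 100_000, "-")], flank=1000, binsize=100)
        assert np.argmax(plus.matrix[0]) == 15
        assert np.argmax(minus.matrix[0]) == 4  # mirrored position

    def test_edge_rows_flagged(self, sizes):
        d = make_directory([("chr1", 100, "+")], sizes)
        prof = profile_matrix(
            d, [("chr1", 500, "."), ("chr1", 100_000, ".")], flank=3000, binsize=100
        )
        assert list(prof.valid) == [False, True]

    def test_per_bin_oracle(self, sizes, rng):
        tags = random_tags(rng, sizes, 3000, chroms=["chr1"])
        d = make_directory(tags, sizes, cap=3)
        centers = [("chr1", int(c), ".") for c in rng.integers(10_000, 900_000, size=20)]
        prof = profile_matrix(d, centers, flank=2000, binsize=100)
        for i, (chrom, c, _s) in enumerate(centers):
            for j in range(prof.matrix.shape[1]):
                lo = c - 2000 + j * 100
                expected = count_range(d, chrom, lo, lo + 100)
                assert prof.matrix[i, j] == pytest.approx(expected)

    def test_row_sum_equals_window(self, sizes, rng):
        tags = random_tags(rng, sizes, 2000, chroms=["chr1"])
        d = make_directory(tags, sizes)
        centers = [("chr1", 300_000, "."), ("chr1", 500_001, ".")]
        prof = profile_matrix(d, centers, flank=3000, binsize=100)
        for i, (chrom, c, _s) in enumerate(centers):
            assert prof.matrix[i].sum() == pytest.approx(
                count_range(d, chrom, c - 3000, c + 3000)
            )

    def test_flank_binsize_mismatch(self, sizes):
        d = make_directory([("chr1", 100, "+")], sizes)
        with pytest.raises(ValueError, match="multiple"):
            profile_matrix(d, [("chr1", 500, ".")], flank=1050, binsize=100)


class TestQuantifyGeneBody:
    def test_promoter_exclusion_zone(self, sizes):
        gene = TssRecord("g", "chr1", 100_000, "+", 120_000)
        tags = [("chr1", p, "+") for p in range(100_000, 100_500, 7)]
        d = make_directory(tags, sizes)
        assert quantify_gene_body(d, gene) == 0.0

    def test_short_gene_window(self, sizes):
        gene = TssRecord("g", "chr1", 100_000, "+", 108_000)  # 8 kb
        inside = [("chr1", 100_500, "+"), ("chr1", 107_999, "+")]
        outside = [("chr1", 108_000, "+"), ("chr1", 100_499, "+")]
        d = make_directory(inside + outside, sizes)
        assert quantify_gene_body(d, gene, normalized=False) == 2

    def test_sense_strand_only(self, sizes):
        gene = TssRecord("g", "chr1", 100_000, "+", 120_000)
        d = make_directory([("chr1", 105_000, "+"), ("chr1", 105_001, "-")], sizes)
        assert quantify_gene_body(d, gene, normalized=False) == 1

    def test_minus_strand_gene(self, sizes):
        gene = TssRecord("g", "chr1", 120_000, "-", 100_000)  # 20 kb, minus
        # sense tags are '-' strand; offsets in [500, 13000)
        inside = [("chr1", 119_500, "-"), ("chr1", 107_001, "-")]
        outside = [("chr1", 119_501, "-"), ("chr1", 107_000, "-"), ("chr1", 110_000, "+")]
        d = make_directory(inside + outside, sizes)
        assert quantify_gene_body(d, gene, normalized=False) == 2

    def test_gene_shorter_than_exclusion_errors(self, sizes):
        gene = TssRecord("g", "chr1", 100_000, "+", 100_400)
        d = make_directory([("chr1", 1, "+")], sizes)
        with pytest.raises(ValueError, match="promoter exclusion"):
            quantify_gene_body(d, gene)

    def test_uniform_scan_oracle(self, sizes, rng):
        gene = TssRecord("g", "chr1", 200_000, "+", 230_000)
        pos = rng.integers(195_000, 235_000, size=4000)
        tags = pd.DataFrame(
            {"chrom": "chr1", "position": pos,
             "strand": np.where(rng.random(4000) < 0.7, "+", "-")}
        )
        d = make_directory(tags, sizes, cap=3)
        recs = d.to_records()
        sub = recs[
            (recs["strand"] == "+")
            & (recs["position"] >= 200_500)
            & (recs["position"] < 213_000)
        ]
        assert quantify_gene_body(d, gene, normalized=False) == sub["count"].sum()


class TestTagAlignIO:
    def test_roundtrip_five_prime_ends(self, tmp_path, sizes, rng):
        records = random_tags(rng, sizes, 200)
        p = tmp_path / "tags.bed"
        write_tagalign(records, p, read_length=36)
        back = read_tagalign(p)
        pd.testing.assert_frame_equal(
            back.sort_values(["chrom", "position", "strand"]).reset_index(drop=True),
            records.sort_values(["chrom", "position", "strand"]).reset_index(drop=True),
            check_dtype=False,
        )

    def test_directory_save_load(self, tmp_path, sizes, rng):
        d = make_directory(random_tags(rng, sizes, 500), sizes, cap=3)
        d.save(tmp_path / "dir")
        d2 = TagDirectory.load(tmp_path / "dir")
        assert d2.capped_total == d.capped_total
        assert d2.raw_total == d.raw_total
        pd.testing.assert_frame_equal(d.to_records(), d2.to_records())


class TestNormalizationTiling:
    def test_tiled_counts_sum_to_target(self, sizes, rng):
        d = make_directory(random_tags(rng, sizes, 5000), sizes, cap=3)
        total = 0.0
        for chrom in sizes:
            for lo in range(0, sizes[chrom], 100_000):
                total += count_range(d, chrom, lo, min(lo + 100_000, sizes[chrom]))
        assert total == pytest.approx(d.norm_target)


class TestMergeAndBundle:
    def test_merge_pools_counts(self, sizes):
        d1 = make_directory([("chr1", 100, "+")], sizes, condition="t", replicate="r1")
        d2 = make_directory([("chr1", 100, "+"), ("chr1", 200, "-")], sizes,
                            condition="t", replicate="r2")
        m = merge_directories([d1, d2])
        assert m.capped_total == 3  # 100+ capped at 2, plus one at 200-

    def test_merge_mixed_pairs_rejected(self, sizes):
        d1 = make_directory([("chr1", 1, "+")], sizes, condition="a")
        d2 = make_directory([("chr1", 1, "+")], sizes, condition="b")
        with pytest.raises(ValueError):
            merge_directories([d1, d2])

    def test_bundle_pooling(self, sizes):
        d1 = make_directory([("chr1", 1, "+")], sizes, condition="t", replicate="r1")
        d2 = make_directory([("chr1", 2, "+")], sizes, condition="t", replicate="r2")
        b = AssayBundle([d1, d2])
        assert b.pooled("chip", "t").capped_total == 2
        with pytest.raises(KeyError):
            b.pooled("chip", "missing")

    def test_bundle_duplicate_key(self, sizes):
        d = make_directory([("chr1", 1, "+")], sizes)
        b = AssayBundle([d])
        with pytest.raises(ValueError, match="duplicate"):
            b.add(d)
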