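"""Interval-overlap counting, Venn partitions, enrichment against random
genomic background, and per-region tag correlations.

Overlap semantics are half-open (BED convention): abutting intervals do not
overlap. Each query interval is counted at most once regardless of how many
subject intervals it touches.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import ChromSizes, GenomicInterval
from .tags import TagDirectory, count_window

__all__ = [
    "overlap_count",
    "overlap_mask",
    "venn_partition",
    "random_regions",
    "enrichment_profile",
    "region_tag_correlation",
]


def _index_by_chrom(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) sorted by start."""
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by.items():
        pairs.sort()
        arr = np.asarray(pairs, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def overlap_mask(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    min_bp: int = 1,
) -> np.ndarray:
    """Boolean per-query flag: overlaps some subject interval by >= min_bp."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    idx = _index_by_chrom(subject)
    mask = np.zeros(len(query), dtype=bool)
    for i, q in enumerate(query):
        entry = idx.get(q.chrom)
        if entry is None:
            continue
        starts, ends = entry
        # candidates must start before the query end
        j = np.searchsorted(starts, q.end, side="left")
        if j == 0:
            continue
        ov = np.minimum(ends[:j], q.end) - np.maximum(starts[:j], q.start)
        if (ov >= min_bp).any():
            mask[i] = True
    return mask


def overlap_count(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    min_bp: int = 1,
) -> int:
    """Number of query intervals overlapping >= ``min_bp`` with the subject
    set; each query interval counted at most once."""
    return int(overlap_mask(query, subject, min_bp).sum())


def venn_partition(
    sets: Mapping[str, Sequence[GenomicInterval]], min_bp: int = 1
) -> dict[str, dict[str, int]]:
    """Per-set membership-pattern counts for 2-3 named interval sets.

    Each interval of each set is assigned a pattern: the sorted names of all
    sets it overlaps (always including its own). Counting is per-set — the
    same genomic locus may contribute one count to each set it appears in —
    so pattern counts for a set sum to that set's size.
    """
    names = list(sets)
    if not (2 <= len(names) <= 3):
        raise ValueError("venn_partition supports 2 or 3 sets")
    result: dict[str, dict[str, int]] = {}
    for name in names:
        own = sets[name]
        member_masks = {}
        for other in names:
            if other == name:
                continue
            member_masks[other] = overlap_mask(own, sets[other], min_bp)
        patterns: dict[str, int] = {}
        for i in range(len(own)):
            members = sorted([name] + [o for o, m in member_masks.items() if m[i]])
            key = "&".join(members)
            patterns[key] = patterns.get(key, 0) + 1
        result[name] = patterns
    return result


def random_regions(
    chrom_sizes: ChromSizes,
    n: int,
    length: int | None = None,
    matched_to: Sequence[GenomicInterval] | None = None,
    seed: int | np.random.Generator = 0,
) -> list[GenomicInterval]:
    """Uniformly placed random regions (placement probability proportional to
    chromosome length); lengths fixed or resampled from ``matched_to``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if (length is None) == (matched_to is None):
        raise ValueError("supply exactly one of length / matched_to")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    lengths_arr = np.asarray([chrom_sizes[c] for c in chroms], dtype=float)
    if matched_to is not None:
        pool = np.asarray([len(iv) for iv in matched_to], dtype=np.int64)
        if len(pool) == 0:
            raise ValueError("matched_to is empty")
        region_lengths = rng.choice(pool, size=n, replace=True)
    else:
        region_lengths = np.full(n, length, dtype=np.int64)
    if region_lengths.max() > lengths_arr.max():
        raise ValueError("region length exceeds the longest chromosome")
    probs = lengths_arr / lengths_arr.sum()
    out: list[GenomicInterval] = []
    for i in range(n):
        L = int(region_lengths[i])
        while True:
            ci = rng.choice(len(chroms), p=probs)
            cl = int(lengths_arr[ci])
            if cl >= L:
                break
        start = int(rng.integers(0, cl - L + 1))
        out.append(GenomicInterval(chroms[ci], start, start + L, name=f"rand_{i}"))
    return out


def enrichment_profile(
    query_peaks: Sequence[GenomicInterval],
    feature_sets: Mapping[str, Sequence[GenomicInterval]],
    chrom_sizes: ChromSizes,
    n_random: int,
    seed: int = 0,
    min_bp: int = 1,
) -> dict[str, dict[str, float]]:
    """Observed query-overlap count per feature set versus a random
    background of ``n_random`` query-length-matched regions.

    Returns feature -> {observed, background, enrichment}; enrichment is the
    observed/expected ratio after scaling the background count to the query
    set size.
    """
    if not feature_sets:
        raise ValueError("feature_sets must be non-empty")
    background = random_regions(
        chrom_sizes, n_random, matched_to=list(query_peaks) or None,
        length=None if query_peaks else 1000, seed=seed,
    )
    table: dict[str, dict[str, float]] = {}
    for name, features in feature_sets.items():
        observed = overlap_count(query_peaks, features, min_bp)
        bg = overlap_count(background, features, min_bp)
        expected = bg * len(query_peaks) / n_random if n_random else float("nan")
        table[name] = {
            "observed": float(observed),
            "background": float(bg),
            "n_query": float(len(query_peaks)),
            "n_random": float(n_random),
            "enrichment": float(observed / expected) if expected > 0 else float("inf"),
        }
    return table


def region_tag_correlation(
    dir_a: TagDirectory,
    dir_b: TagDirectory,
    regions: Sequence[GenomicInterval],
    halfwidth: int = 1000,
    log2: bool = True,
    pc: float = 1.0,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Pearson correlation of per-region normalized tag counts between two
    directories, optionally on a log2(x + pc) scale.

    Returns (r, p-value); ``alternative`` may be "two-sided", "greater" or
    "less" (one-tailed). Raises if either count vector has zero variance.
    """
    if len(regions) < 3:
        raise ValueError("need at least 3 regions")
    xs, ys = [], []
    for region in regions:
        c = region.center
        xs.append(count_window(dir_a, region.chrom, c, halfwidth))
        ys.append(count_window(dir_b, region.chrom, c, halfwidth))
    x = np.asarray(xs)
    y = np.asarray(ys)
    if log2:
        x = np.log2(x + pc)
        y = np.log2(y + pc)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in region counts; correlation undefined")
    res = stats.pearsonr(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
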