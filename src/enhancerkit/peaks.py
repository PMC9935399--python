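"""Poisson-background peak calling, replicate-concordance filtering, and
putative-enhancer anchoring.

The caller slides fixed windows across each chromosome and tests the window
count against a Poisson background whose rate is the maximum of the
genome-wide rate and a local rate estimated over a larger span (MACS-style
local lambda). It is deliberately simple and pluggable: every consumer of
peaks also accepts externally supplied peak BEDs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import GenomicInterval, Peak, TssRecord, distance_to_nearest_tss
from .tags import TagDirectory, count_window, normalized_count

__all__ = [
    "PeakCallConfig",
    "call_peaks",
    "scan_windows",
    "concordant_peaks",
    "define_putative_enhancers",
]


@dataclass(frozen=True)
class PeakCallConfig:
    window: int = 200
    step: int = 50
    pvalue_max: float = 1e-5
    fold_over_genome_min: float = 4.0
    local_bg_span: int = 10_000
    merge_gap: int | None = None  # defaults to window

    def __post_init__(self) -> None:
        if not (self.window >= self.step > 0):
            raise ValueError("require window >= step > 0")
        if not (0 < self.pvalue_max < 1):
            raise ValueError("pvalue_max must be in (0, 1)")

    @property
    def gap(self) -> int:
        return self.window if self.merge_gap is None else self.merge_gap


def _window_counts(track_pairs, starts: np.ndarray, width: int) -> np.ndarray:
    """Summed raw counts (both strands) in [s, s+width) for each start."""
    counts = np.zeros(len(starts), dtype=np.int64)
    for track in track_pairs:
        lo = np.searchsorted(track.pos, starts, side="left")
        hi = np.searchsorted(track.pos, starts + width, side="left")
        counts += track.cum[hi] - track.cum[lo]
    return counts


def scan_windows(
    directory: TagDirectory, config: PeakCallConfig, chrom: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window (start, count, upper-tail p-value) for one chromosome.

    lambda = max(genome-wide rate, local rate over ``local_bg_span``) x window;
    p = P(X >= k | lambda) for Poisson X.
    """
    length = directory.chrom_sizes.get(chrom)
    if length is None:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if config.window > length:
        raise ValueError(f"window {config.window} exceeds chromosome {chrom!r} length")
    tracks = [
        t for (c, _), t in directory.tracks.items() if c == chrom
    ]
    starts = np.arange(0, length - config.window + 1, config.step, dtype=np.int64)
    k = _window_counts(tracks, starts, config.window)

    genome_rate = directory.capped_total / directory.chrom_sizes.genome_length
    span = config.local_bg_span
    centers = starts + config.window // 2
    lo = np.clip(centers - span // 2, 0, length)
    hi = np.clip(centers + span // 2, 0, length)
    local_counts = np.zeros(len(starts), dtype=np.int64)
    for track in tracks:
        i = np.searchsorted(track.pos, lo, side="left")
        j = np.searchsorted(track.pos, hi, side="left")
        local_counts += track.cum[j] - track.cum[i]
    local_rate = local_counts / np.maximum(hi - lo, 1)
    lam = np.maximum(genome_rate, local_rate) * config.window
    pvals = stats.poisson.sf(k - 1, lam)
    return starts, k, pvals


def call_peaks(
    directory: TagDirectory,
    config: PeakCallConfig | None = None,
    chroms: Sequence[str] | None = None,
) -> list[Peak]:
    """Call enriched regions on a tag directory.

    A window is significant iff its Poisson upper-tail p-value is at most
    ``pvalue_max`` and its count is at least ``fold_over_genome_min`` times
    the genome-wide expectation. Significant windows closer than ``merge_gap``
    are merged; the summit is the (leftmost) position of maximum tag count in
    the merged region and the score is its normalized tag count.
    """
    config = config or PeakCallConfig()
    peaks: list[Peak] = []
    genome_rate = directory.capped_total / directory.chrom_sizes.genome_length
    lam_genome = genome_rate * config.window
    for chrom in chroms if chroms is not None else sorted(directory.chrom_sizes):
        starts, k, pvals = scan_windows(directory, config, chrom)
        sig = (pvals <= config.pvalue_max) & (k >= config.fold_over_genome_min * lam_genome)
        if not sig.any():
            continue
        for lo, hi in _merge_windows(starts[sig], config.window, config.gap):
            raw = directory.raw_count(chrom, lo, hi)
            summit = _summit(directory, chrom, lo, hi)
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, lo, hi, name=f"peak_{chrom}_{lo}"),
                    summit=summit,
                    score=normalized_count(directory, raw),
                )
            )
    return peaks


def _merge_windows(starts: np.ndarray, width: int, gap: int):
    """Merge sorted window starts into (lo, hi) regions; windows whose
    intervals are within ``gap`` bp are joined."""
    lo = int(starts[0])
    hi = lo + width
    for s in starts[1:]:
        s = int(s)
        if s - hi <= gap:
            hi = s + width
        else:
            yield lo, hi
            lo, hi = s, s + width
    yield lo, hi


def _summit(directory: TagDirectory, chrom: str, lo: int, hi: int) -> int:
    """Leftmost position of maximum per-bp tag count (strands summed)."""
    best_pos, best_count = lo, -1
    combined: dict[int, int] = {}
    for s in ("+", "-"):
        track = directory.tracks.get((chrom, s))
        if track is None:
            continue
        i = np.searchsorted(track.pos, lo, side="left")
        j = np.searchsorted(track.pos, hi, side="left")
        for p, c in zip(track.pos[i:j], track.counts[i:j]):
            combined[int(p)] = combined.get(int(p), 0) + int(c)
    for p in sorted(combined):
        if combined[p] > best_count:
            best_pos, best_count = p, combined[p]
    return best_pos


def concordant_peaks(
    peak_sets: Sequence[Sequence[Peak]],
    min_replicates: int = 2,
    max_center_dist: int = 200,
) -> list[Peak]:
    """Replicate-concordance filter (summit-distance substitute for IDR).

    Retains peaks from the first set whose summit lies within
    ``max_center_dist`` of a summit in at least ``min_replicates - 1`` of the
    other sets. Deterministic given its inputs.
    """
    if len(peak_sets) < 2:
        raise ValueError("need at least two peak sets")
    if min_replicates > len(peak_sets):
        raise ValueError("min_replicates exceeds the number of peak sets")
    summit_index: list[dict[str, np.ndarray]] = []
    for pset in peak_sets[1:]:
        idx: dict[str, list[int]] = {}
        for p in pset:
            idx.setdefault(p.chrom, []).append(p.summit)
        summit_index.append({c: np.sort(np.asarray(v)) for c, v in idx.items()})
    kept = []
    for p in peak_sets[0]:
        support = 1
        for idx in summit_index:
            summits = idx.get(p.chrom)
            if summits is None or len(summits) == 0:
                continue
            i = np.searchsorted(summits, p.summit)
            near = []
            if i < len(summits):
                near.append(abs(int(summits[i]) - p.summit))
            if i > 0:
                near.append(abs(int(summits[i - 1]) - p.summit))
            if near and min(near) <= max_center_dist:
                support += 1
        if support >= min_replicates:
            kept.append(p)
    return kept


def define_putative_enhancers(
    anchor_peaks: Sequence[Peak],
    k27ac_dir: TagDirectory,
    flank: int = 1000,
    tss_set: Sequence[TssRecord] | None = None,
    tss_min_dist: int = 3000,
) -> list[Peak]:
    """Anchor candidate enhancer windows on peak summits.

    For each anchor summit ``c`` emits [c - flank, c + flank) scored with the
    normalized tag count of ``k27ac_dir`` over the window. Regions
    whose center lies within ``tss_min_dist`` of a TSS are dropped when a
    ``tss_set`` is supplied. Windows truncated by a chromosome edge are
    clipped to bounds.
    """
    out: list[Peak] = []
    for i, anchor in enumerate(anchor_peaks):
        c = anchor.summit
        length = k27ac_dir.chrom_sizes.get(anchor.chrom)
        if length is None:
            raise ValueError(f"unknown chromosome {anchor.chrom!r}")
        lo, hi = max(0, c - flank), min(length, c + flank)
        iv = GenomicInterval(anchor.chrom, lo, hi, name=f"enh_{i}")
        if tss_set:
            if distance_to_nearest_tss(iv, tss_set) < tss_min_dist:
                continue
        score = count_window(k27ac_dir, anchor.chrom, c, flank)
        out.append(Peak(interval=iv, summit=c, score=score))
    return out
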