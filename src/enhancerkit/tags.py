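"""HOMER-style tag directories: clonal capping, depth normalization, and
windowed/gene-body/profile quantification.

A tag is a (chrom, 5'-end position, strand) triple. Directories cap the
number of tags retained per unique position (default 2 for ChIP-style data,
3 for nascent-transcription data) and normalize counts to a fixed library
size (default 10^7 tags) so samples of different depth are comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ChromSizes, TssRecord

__all__ = [
    "TagDirectory",
    "build_tag_directory",
    "merge_directories",
    "normalized_count",
    "count_window",
    "count_range",
    "profile_matrix",
    "ProfileMatrix",
    "quantify_gene_body",
    "read_tagalign",
    "write_tagalign",
    "AssayBundle",
]

NORM_TARGET_DEFAULT = 10_000_000


@dataclass
class _StrandTrack:
    """Sorted unique positions with per-position (capped) counts and a cumsum."""

    pos: np.ndarray  # int64, sorted, unique
    counts: np.ndarray  # int64, same length
    cum: np.ndarray  # int64, len+1 prefix sums of counts

    @classmethod
    def from_counts(cls, pos: np.ndarray, counts: np.ndarray) -> "_StrandTrack":
        cum = np.zeros(len(counts) + 1, dtype=np.int64)
        np.cumsum(counts, out=cum[1:])
        return cls(pos=pos, counts=counts, cum=cum)

    def count_in(self, lo: int, hi: int) -> int:
        """Raw tag count with position in half-open [lo, hi)."""
        i = np.searchsorted(self.pos, lo, side="left")
        j = np.searchsorted(self.pos, hi, side="left")
        return int(self.cum[j] - self.cum[i])


@dataclass
class TagDirectory:
    """Deduplicated (capped) tag collection for one sample.

    ``capped_total`` is the library size after clonal capping; the
    normalization factor is ``norm_target / capped_total``.
    """

    assay: str
    condition: str
    replicate: str
    per_position_cap: int
    chrom_sizes: ChromSizes
    raw_total: int
    capped_total: int
    norm_target: int = NORM_TARGET_DEFAULT
    tracks: dict[tuple[str, str], _StrandTrack] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.capped_total <= 0:
            raise ValueError(
                "tag directory is empty after capping; normalization undefined"
            )
        if self.per_position_cap < 1:
            raise ValueError("per_position_cap must be >= 1")

    @property
    def norm_factor(self) -> float:
        return self.norm_target / self.capped_total

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.assay, self.condition, self.replicate)

    # -- raw access -----------------------------------------------------

    def raw_count(self, chrom: str, lo: int, hi: int, strands: Sequence[str] = ("+", "-")) -> int:
        """Raw capped tags on ``chrom`` with position in half-open [lo, hi)."""
        if chrom not in self.chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        total = 0
        for s in strands:
            track = self.tracks.get((chrom, s))
            if track is not None:
                total += track.count_in(lo, hi)
        return total

    def to_records(self) -> pd.DataFrame:
        """All tags as a DataFrame (chrom, position, strand, count)."""
        frames = []
        for (chrom, strand), track in sorted(self.tracks.items()):
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "position": track.pos,
                        "strand": strand,
                        "count": track.counts,
                    }
                )
            )
        if not frames:
            return pd.DataFrame(columns=["chrom", "position", "strand", "count"])
        return pd.concat(frames, ignore_index=True)

    # -- serialization --------------------------------------------------

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.tags.tsv`` plus a ``<prefix>.json`` sidecar."""
        prefix = Path(prefix)
        self.to_records().to_csv(prefix.with_suffix(".tags.tsv"), sep="\t", index=False)
        meta = {
            "assay": self.assay,
            "condition": self.condition,
            "replicate": self.replicate,
            "per_position_cap": self.per_position_cap,
            "raw_total": self.raw_total,
            "capped_total": self.capped_total,
            "norm_target": self.norm_target,
            "chrom_sizes": dict(self.chrom_sizes),
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, prefix: str | Path) -> "TagDirectory":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        df = pd.read_csv(prefix.with_suffix(".tags.tsv"), sep="\t")
        tracks: dict[tuple[str, str], _StrandTrack] = {}
        for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
            order = np.argsort(grp["position"].to_numpy())
            tracks[(str(chrom), str(strand))] = _StrandTrack.from_counts(
                grp["position"].to_numpy(dtype=np.int64)[order],
                grp["count"].to_numpy(dtype=np.int64)[order],
            )
        return cls(
            assay=meta["assay"],
            condition=meta["condition"],
            replicate=meta["replicate"],
            per_position_cap=meta["per_position_cap"],
            chrom_sizes=ChromSizes(meta["chrom_sizes"]),
            raw_total=meta["raw_total"],
            capped_total=meta["capped_total"],
            norm_target=meta["norm_target"],
            tracks=tracks,
        )


def _cap_counts(
    df: pd.DataFrame, cap: int, strand_aware: bool
) -> pd.DataFrame:
    """Collapse raw tag records to per-position counts clipped at ``cap``.

    With ``strand_aware=False`` the cap applies to the (chrom, position)
    total; the retained count is split across strands proportionally
    (deterministic: remainder goes to '+').
    """
    counts = (
        df.groupby(["chrom", "position", "strand"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    if strand_aware:
        counts["count"] = counts["count"].clip(upper=cap)
        return counts
    totals = counts.groupby(["chrom", "position"])["count"].transform("sum")
    over = totals > cap
    if over.any():
        kept = np.floor(counts.loc[over, "count"] * cap / totals[over]).astype(np.int64)
        counts.loc[over, "count"] = kept
        # distribute rounding remainder to '+' rows
        sub = counts.loc[over].copy()
        got = sub.groupby(["chrom", "position"])["count"].transform("sum")
        deficit = cap - got
        bump = (sub["strand"] == "+") & (deficit > 0)
        counts.loc[sub.index[bump], "count"] += deficit[bump]
        counts = counts[counts["count"] > 0].reset_index(drop=True)
    return counts


def build_tag_directory(
    tag_records: pd.DataFrame | Iterable[tuple[str, int, str]],
    assay: str,
    condition: str,
    replicate: str,
    per_position_cap: int,
    chrom_sizes: ChromSizes,
    norm_target: int = NORM_TARGET_DEFAULT,
    strand_aware_cap: bool = True,
) -> TagDirectory:
    """Build a capped tag directory from raw tag records.

    ``tag_records`` is a DataFrame with columns (chrom, position, strand) or
    an iterable of such triples. Positions must lie within chromosome bounds.
    Occurrences of each unique position beyond ``per_position_cap`` are
    discarded before totals are computed.
    """
    if per_position_cap < 1:
        raise ValueError("per_position_cap must be >= 1")
    if not isinstance(tag_records, pd.DataFrame):
        tag_records = pd.DataFrame(
            list(tag_records), columns=["chrom", "position", "strand"]
        )
    raw_total = len(tag_records)
    if raw_total == 0:
        raise ValueError("no tags supplied; normalization undefined")

    for chrom, grp in tag_records.groupby("chrom", sort=False):
        length = chrom_sizes.get(str(chrom))
        if length is None:
            raise ValueError(f"unknown chromosome {chrom!r} in tag records")
        pos = grp["position"].to_numpy()
        if pos.min() < 0 or pos.max() >= length:
            raise ValueError(f"tag position out of bounds on {chrom!r}")

    counts = _cap_counts(tag_records, per_position_cap, strand_aware_cap)
    tracks: dict[tuple[str, str], _StrandTrack] = {}
    for (chrom, strand), grp in counts.groupby(["chrom", "strand"], sort=True):
        tracks[(str(chrom), str(strand))] = _StrandTrack.from_counts(
            grp["position"].to_numpy(dtype=np.int64),
            grp["count"].to_numpy(dtype=np.int64),
        )
    capped_total = int(counts["count"].sum())
    return TagDirectory(
        assay=assay,
        condition=condition,
        replicate=replicate,
        per_position_cap=per_position_cap,
        chrom_sizes=chrom_sizes,
        raw_total=raw_total,
        capped_total=capped_total,
        norm_target=norm_target,
        tracks=tracks,
    )


def merge_directories(
    dirs: Sequence[TagDirectory],
    replicate: str = "pooled",
    per_position_cap: int | None = None,
) -> TagDirectory:
    """Pool replicate directories into one, re-applying the clonal cap.

    Mirrors building a combined directory from the pooled raw tags: per-
    position counts are summed across inputs and clipped at the cap (the
    first directory's cap unless overridden).
    """
    if not dirs:
        raise ValueError("need at least one directory")
    if len({(d.assay, d.condition) for d in dirs}) != 1:
        raise ValueError("can only merge replicates of one (assay, condition)")
    cap = per_position_cap if per_position_cap is not None else dirs[0].per_position_cap
    frames = [d.to_records() for d in dirs]
    merged = (
        pd.concat(frames, ignore_index=True)
        .groupby(["chrom", "position", "strand"], sort=True)["count"]
        .sum()
        .clip(upper=cap)
        .reset_index()
    )
    tracks: dict[tuple[str, str], _StrandTrack] = {}
    for (chrom, strand), grp in merged.groupby(["chrom", "strand"], sort=True):
        tracks[(str(chrom), str(strand))] = _StrandTrack.from_counts(
            grp["position"].to_numpy(dtype=np.int64),
            grp["count"].to_numpy(dtype=np.int64),
        )
    return TagDirectory(
        assay=dirs[0].assay,
        condition=dirs[0].condition,
        replicate=replicate,
        per_position_cap=cap,
        chrom_sizes=dirs[0].chrom_sizes,
        raw_total=sum(d.raw_total for d in dirs),
        capped_total=int(merged["count"].sum()),
        norm_target=dirs[0].norm_target,
        tracks=tracks,
    )


# ---------------------------------------------------------------------------
# Quantification


def normalized_count(directory: TagDirectory, raw: float) -> float:
    """Scale a raw tag count to tags-per-norm_target (default tags-per-10M)."""
    return raw * directory.norm_target / directory.capped_total


def _resolve_strands(strand_mode: str, ref_strand: str | None) -> tuple[str, ...]:
    if strand_mode == "both":
        return ("+", "-")
    if ref_strand not in ("+", "-"):
        raise ValueError("sense/antisense counting requires ref_strand '+' or '-'")
    if strand_mode == "sense":
        return (ref_strand,)
    if strand_mode == "antisense":
        return ("-" if ref_strand == "+" else "+",)
    raise ValueError(f"unknown strand_mode {strand_mode!r}")


def count_window(
    directory: TagDirectory,
    chrom: str,
    center: int,
    halfwidth: int,
    strand_mode: str = "both",
    ref_strand: str | None = None,
) -> float:
    """Normalized tag count in the inclusive window [center-hw, center+hw]."""
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    strands = _resolve_strands(strand_mode, ref_strand)
    raw = directory.raw_count(chrom, center - halfwidth, center + halfwidth + 1, strands)
    return normalized_count(directory, raw)


def count_range(
    directory: TagDirectory,
    chrom: str,
    start: int,
    end: int,
    strand_mode: str = "both",
    ref_strand: str | None = None,
) -> float:
    """Normalized tag count in the half-open range [start, end)."""
    strands = _resolve_strands(strand_mode, ref_strand)
    return normalized_count(directory, directory.raw_count(chrom, start, end, strands))


@dataclass
class ProfileMatrix:
    """Per-region binned tag-density matrix; columns read 5'->3'.

    Rows whose window falls off a chromosome edge are zero-filled, flagged
    invalid, and excluded from :attr:`mean_profile`.
    """

    matrix: np.ndarray  # (n_regions, n_bins), normalized tags
    valid: np.ndarray  # (n_regions,), bool
    flank: int
    binsize: int

    @property
    def mean_profile(self) -> np.ndarray:
        if not self.valid.any():
            return np.zeros(self.matrix.shape[1])
        return self.matrix[self.valid].mean(axis=0)

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin midpoints relative to the region center (5'->3')."""
        n = self.matrix.shape[1]
        return -self.flank + self.binsize * (np.arange(n) + 0.5)


def profile_matrix(
    directory: TagDirectory,
    centers: Sequence[tuple[str, int, str]],
    flank: int = 3000,
    binsize: int = 100,
    strand_mode: str = "both",
) -> ProfileMatrix:
    """Tabulate normalized tags in half-open bins of ``binsize`` bp over
    [center-flank, center+flank) around each (chrom, bp, strand) center.

    Rows for '-' strand centers are reversed so columns read 5'->3'.
    """
    if flank % binsize != 0:
        raise ValueError("flank must be a multiple of binsize")
    nbins = 2 * flank // binsize
    mat = np.zeros((len(centers), nbins))
    valid = np.ones(len(centers), dtype=bool)
    factor = directory.norm_factor
    for i, (chrom, center, strand) in enumerate(centers):
        length = directory.chrom_sizes.get(chrom)
        if length is None:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if center - flank < 0 or center + flank > length:
            valid[i] = False
            continue
        edges = center - flank + binsize * np.arange(nbins + 1)
        row = np.zeros(nbins)
        strands = _resolve_strands(strand_mode, strand if strand in ("+", "-") else None) \
            if strand_mode != "both" else ("+", "-")
        for s in strands:
            track = directory.tracks.get((chrom, s))
            if track is None:
                continue
            idx = np.searchsorted(track.pos, edges, side="left")
            row += np.diff(track.cum[idx])
        if strand == "-":
            row = row[::-1]
        mat[i] = row * factor
    return ProfileMatrix(matrix=mat, valid=valid, flank=flank, binsize=binsize)


def quantify_gene_body(
    directory: TagDirectory,
    gene: TssRecord,
    body_cap: int = 13_000,
    promoter_exclusion: int = 500,
    strand_mode: str = "sense",
    normalized: bool = True,
) -> float:
    """Tag count over the first ``body_cap`` bp of the gene body, excluding
    the promoter-proximal ``promoter_exclusion`` bp, oriented 5'->3'.

    Counts positions at sense-strand offset d from the TSS with
    ``promoter_exclusion <= d < min(body_cap, gene length)``.
    """
    length = gene.length
    if length <= promoter_exclusion:
        raise ValueError(
            f"gene {gene.gene} length {length} <= promoter exclusion {promoter_exclusion}"
        )
    span = min(body_cap, length)
    strands = _resolve_strands(strand_mode, gene.strand)
    if gene.strand == "+":
        lo, hi = gene.tss + promoter_exclusion, gene.tss + span
    else:
        # offsets d = tss - pos in [promoter_exclusion, span)
        lo, hi = gene.tss - span + 1, gene.tss - promoter_exclusion + 1
    raw = directory.raw_count(gene.chrom, lo, hi, strands)
    return normalized_count(directory, raw) if normalized else float(raw)


# ---------------------------------------------------------------------------
# tagAlign I/O


def read_tagalign(path: str | Path) -> pd.DataFrame:
    """Read BED6/tagAlign into 5'-end tag records (chrom, position, strand).

    The 5' end is ``start`` for '+' tags and ``end - 1`` for '-' tags.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{path}: tag records must be stranded (+/-)")
    position = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return pd.DataFrame(
        {"chrom": df["chrom"], "position": position, "strand": df["strand"]}
    )


def write_tagalign(
    records: pd.DataFrame, path: str | Path, read_length: int = 1
) -> None:
    """Write tag records as minimal BED6 (one line per tag occurrence)."""
    plus = records["strand"].to_numpy() == "+"
    pos = records["position"].to_numpy()
    start = np.where(plus, pos, pos - read_length + 1)
    out = pd.DataFrame(
        {
            "chrom": records["chrom"],
            "start": start,
            "end": start + read_length,
            "name": "tag",
            "score": 0,
            "strand": records["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Bundles


class AssayBundle:
    """Keyed map (assay, condition, replicate) -> TagDirectory.

    ``pooled(assay, condition)`` merges all replicates of a pair (cached).
    """

    def __init__(self, directories: Iterable[TagDirectory] = ()):
        self._dirs: dict[tuple[str, str, str], TagDirectory] = {}
        self._pooled: dict[tuple[str, str], TagDirectory] = {}
        for d in directories:
            self.add(d)

    def add(self, directory: TagDirectory) -> None:
        if directory.key in self._dirs:
            raise ValueError(f"duplicate directory key {directory.key}")
        self._dirs[directory.key] = directory
        self._pooled.pop((directory.assay, directory.condition), None)

    def __getitem__(self, key: tuple[str, str, str]) -> TagDirectory:
        return self._dirs[key]

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        return key in self._dirs

    def keys(self):
        return self._dirs.keys()

    def replicates(self, assay: str, condition: str) -> list[TagDirectory]:
        return [
            d for (a, c, _), d in sorted(self._dirs.items()) if a == assay and c == condition
        ]

    def has(self, assay: str, condition: str) -> bool:
        return bool(self.replicates(assay, condition))

    def pooled(self, assay: str, condition: str) -> TagDirectory:
        key = (assay, condition)
        if key not in self._pooled:
            reps = self.replicates(assay, condition)
            if not reps:
                raise KeyError(f"no directories for (assay={assay!r}, condition={condition!r})")
            self._pooled[key] = reps[0] if len(reps) == 1 else merge_directories(reps)
        return self._pooled[key]
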