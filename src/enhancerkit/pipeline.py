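"""End-to-end orchestration: simulate/load tags -> tag directories -> peak
calls -> putative enhancers -> classification -> feature annotation ->
differential -> overlap enrichment -> profiles, with a machine-readable run
log and deterministic plain-text outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .classify import ClassifyConfig, EnhancerCall, annotate_feature_enrichment, classify_all
from .core import ChromSizes, GenomicInterval, Peak, read_chrom_sizes, read_tss_table
from .differential import differential_ernas, differential_genes
from .overlap import enrichment_profile, venn_partition
from .peaks import PeakCallConfig, call_peaks, define_putative_enhancers
from .simulate import (
    SyntheticConfig,
    TruthTable,
    plant_enhancers,
    simulate_bundle,
)
from .tags import AssayBundle, build_tag_directory, profile_matrix, read_tagalign

__all__ = ["run_pipeline", "load_manifest", "RunResult"]

FLOAT_FMT = "%.6g"


@dataclasses.dataclass
class RunResult:
    outdir: Path
    calls: list[EnhancerCall]
    peaks: dict[str, list[Peak]]
    recovery: dict[str, Any] | None


def load_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        manifest = yaml.safe_load(fh) or {}
    manifest.setdefault("_basedir", str(Path(path).parent))
    return manifest


def _resolve(manifest: Mapping, key: str) -> Path:
    return Path(manifest.get("_basedir", ".")) / manifest[key]


def _log(fh, stage: str, **params) -> None:
    fh.write(json.dumps({"stage": stage, **params}, sort_keys=True, default=str) + "\n")
    fh.flush()


def _peaks_to_bed(peaks: Sequence[Peak], path: Path) -> None:
    """BED6+ with an extra summit-offset column."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            name = iv.name or "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{FLOAT_FMT % p.score}\t.\t"
                f"{p.summit - iv.start}\n"
            )


def _calls_to_frame(calls: Sequence[EnhancerCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "chrom": c.region.chrom,
            "start": c.region.start,
            "end": c.region.end,
            "name": c.region.name or ".",
            "label": c.label,
        }
        row.update({f"tf_{k}": v for k, v in sorted(c.tf_marked.items())})
        row.update({k: v for k, v in sorted(c.flags.items())})
        row.update(c.metrics)
        rows.append(row)
    return pd.DataFrame(rows)


def _load_real_inputs(manifest: Mapping) -> tuple[ChromSizes, list, AssayBundle]:
    sizes = read_chrom_sizes(_resolve(manifest, "chrom_sizes"))
    tss = read_tss_table(_resolve(manifest, "tss"))
    bundle = AssayBundle()
    base = Path(manifest.get("_basedir", "."))
    for entry in manifest["tags"]:
        records = read_tagalign(base / entry["path"])
        bundle.add(
            build_tag_directory(
                records,
                assay=entry["assay"],
                condition=entry["condition"],
                replicate=entry.get("replicate", "rep1"),
                per_position_cap=int(entry.get("per_position_cap", 2)),
                chrom_sizes=sizes,
            )
        )
    return sizes, tss, bundle


def run_pipeline(manifest: Mapping | str | Path, outdir: str | Path) -> RunResult:
    """Execute the full analysis graph described by ``manifest``.

    Manifest keys: ``mode`` (synthetic|real), ``seed``, ``scheme``
    (hormone only for the built-in graph), ``synthetic`` (SyntheticConfig
    overrides) or real-mode input paths (``chrom_sizes``, ``tss``, ``tags``),
    plus optional ``classify`` / ``peaks`` config overrides.
    """
    if not isinstance(manifest, Mapping):
        manifest = load_manifest(manifest)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_fh = open(outdir / "runlog.jsonl", "w")

    seed = int(manifest.get("seed", 0))
    classify_cfg = ClassifyConfig(**manifest.get("classify", {}))
    peak_cfg = PeakCallConfig(**manifest.get("peaks", {}))
    mode = manifest.get("mode", "synthetic")
    _log(log_fh, "config", seed=seed, mode=mode,
         classify=dataclasses.asdict(classify_cfg), peaks=dataclasses.asdict(peak_cfg))

    truth: TruthTable | None = None
    if mode == "synthetic":
        syn = SyntheticConfig(**{**manifest.get("synthetic", {}), "seed": seed})
        truth = plant_enhancers(syn)
        bundle, _records = simulate_bundle(truth, syn)
        sizes, tss = truth.chrom_sizes, truth.tss
        _log(log_fh, "simulate", synthetic=dataclasses.asdict(syn),
             n_loci=len(truth.loci), n_genes=len(truth.genes))
    elif mode == "real":
        sizes, tss, bundle = _load_real_inputs(manifest)
        _log(log_fh, "load", n_directories=len(list(bundle.keys())))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    for key in (("k27ac", "treated"), ("nascent", "treated"), ("nascent", "control")):
        if not bundle.has(*key):
            raise KeyError(f"manifest provides no tags for (assay, condition) = {key}")

    # --- peak calling ---------------------------------------------------
    peak_sets: dict[str, list[Peak]] = {}
    for name, assay in (("era", "tf"), ("k27ac", "k27ac"), ("top1cc", "top1cc")):
        if bundle.has(assay, "treated"):
            pk = call_peaks(bundle.pooled(assay, "treated"), peak_cfg)
            peak_sets[name] = pk
            _peaks_to_bed(pk, outdir / f"peaks_{name}.bed")
            _log(log_fh, "call_peaks", assay=assay, n_peaks=len(pk))
    era_peaks = peak_sets.get("era", [])
    top1_peaks = peak_sets.get("top1cc", [])

    # --- putative enhancers --------------------------------------------
    anchors = list(era_peaks)
    era_summits = {}
    for p in era_peaks:
        era_summits.setdefault(p.chrom, []).append(p.summit)
    era_sorted = {c: np.sort(np.asarray(v)) for c, v in era_summits.items()}
    for p in peak_sets.get("k27ac", []):
        summits = era_sorted.get(p.chrom)
        if summits is not None and len(summits):
            i = np.searchsorted(summits, p.summit)
            near = min(
                abs(int(summits[j]) - p.summit)
                for j in (max(i - 1, 0), min(i, len(summits) - 1))
            )
            if near <= 1000:
                continue
        anchors.append(p)
    k27_dir = bundle.pooled("k27ac", "treated")
    putative = define_putative_enhancers(
        anchors, k27_dir, flank=1000, tss_set=tss, tss_min_dist=classify_cfg.tss_min_dist
    )
    regions = [
        GenomicInterval(p.chrom, p.interval.start, p.interval.end, name=f"enh_{i}")
        for i, p in enumerate(putative)
    ]
    _log(log_fh, "putative_enhancers", n_anchors=len(anchors), n_regions=len(regions))

    # --- classification -------------------------------------------------
    calls = classify_all(
        regions, bundle, tss, scheme=manifest.get("scheme", "hormone"),
        config=classify_cfg, era_peaks=era_peaks,
    )
    annotate_feature_enrichment(calls, top1_peaks, max_center_dist=1000)
    frame = _calls_to_frame(calls)
    frame.to_csv(outdir / "classification.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    _log(log_fh, "classify", n_calls=len(calls),
         labels=frame["label"].value_counts().to_dict() if len(frame) else {})

    # --- differential ---------------------------------------------------
    nas_c = bundle.pooled("nascent", "control")
    nas_t = bundle.pooled("nascent", "treated")
    centers = [(r.chrom, r.center) for r in regions]
    ernas = differential_ernas(nas_c, nas_t, centers)
    pd.DataFrame([dataclasses.asdict(r) for r in ernas]).to_csv(
        outdir / "differential_ernas.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    genes_diff = differential_genes(nas_c, nas_t, tss, test="poisson_exact")
    pd.DataFrame([dataclasses.asdict(r) for r in genes_diff]).to_csv(
        outdir / "differential_genes.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    _log(log_fh, "differential", n_ernas=len(ernas), n_genes=len(genes_diff))

    # --- overlap enrichment & Venn -------------------------------------
    if top1_peaks:
        query = [p.interval for p in top1_peaks]
        features = {
            name: [p.interval for p in pk]
            for name, pk in peak_sets.items()
            if name != "top1cc" and pk
        }
        if features:
            table = enrichment_profile(
                query, features, sizes, n_random=max(5 * len(query), 1000), seed=seed
            )
            pd.DataFrame(table).T.to_csv(
                outdir / "enrichment.tsv", sep="\t", float_format=FLOAT_FMT
            )
        sets = {"top1cc": query, **features}
        if 2 <= len(sets) <= 3:
            venn = venn_partition(sets)
            (outdir / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True))
        _log(log_fh, "overlap", n_query=len(query))

    # --- profile around classified enhancers ----------------------------
    mega_centers = [
        (c.region.chrom, c.region.center, ".")
        for c in calls
        if c.label == "megatrans"
    ]
    if mega_centers and bundle.has("top1cc", "treated"):
        prof = profile_matrix(bundle.pooled("top1cc", "treated"), mega_centers, flank=3000, binsize=100)
        pd.DataFrame(
            {"bin_center": prof.bin_centers, "mean_tags": prof.mean_profile}
        ).to_csv(outdir / "profile_top1cc_megatrans.tsv", sep="\t", index=False,
                 float_format=FLOAT_FMT)
        _log(log_fh, "profile", n_regions=int(prof.valid.sum()))

    # --- recovery vs truth ---------------------------------------------
    recovery = None
    if truth is not None:
        recovery = evaluate_recovery(truth, calls)
        (outdir / "recovery.json").write_text(json.dumps(recovery, indent=2, sort_keys=True))
        _log(log_fh, "recovery", **{k: v for k, v in recovery.items() if np.isscalar(v)})

    log_fh.close()
    return RunResult(outdir=outdir, calls=calls, peaks=peak_sets, recovery=recovery)


def evaluate_recovery(
    truth: TruthTable,
    calls: Sequence[EnhancerCall],
    max_match_dist: int = 1000,
) -> dict[str, Any]:
    """Compare classified regions against the planted truth.

    A truth locus matches the nearest call center within ``max_match_dist``.
    Decoys count as rejected when they are unmatched (dropped at a gate
    upstream) or matched to an unclassified call.
    """
    call_centers: dict[str, list[tuple[int, int]]] = {}
    for i, c in enumerate(calls):
        call_centers.setdefault(c.region.chrom, []).append((c.region.center, i))
    for v in call_centers.values():
        v.sort()

    def nearest_call(chrom: str, center: int) -> EnhancerCall | None:
        entries = call_centers.get(chrom)
        if not entries:
            return None
        centers = [e[0] for e in entries]
        i = int(np.searchsorted(centers, center))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(entries):
                d = abs(entries[j][0] - center)
                if d <= max_match_dist and (best is None or d < best[0]):
                    best = (d, entries[j][1])
        return calls[best[1]] if best else None

    real_classes = {"megatrans", "eralpha_other_active", "other_active"}
    n_real = n_matched = n_correct = 0
    n_decoy = n_decoy_rejected = 0
    n_top1_true = n_top1_flagged = 0
    n_top1_false = n_top1_misflagged = 0
    per_class: dict[str, dict[str, int]] = {}

    for row in truth.loci.itertuples(index=False):
        call = nearest_call(row.chrom, row.center)
        stats = per_class.setdefault(row.label, {"n": 0, "matched": 0, "correct": 0})
        stats["n"] += 1
        if row.label in real_classes:
            n_real += 1
            if call is not None:
                n_matched += 1
                stats["matched"] += 1
                if call.label == row.label:
                    n_correct += 1
                    stats["correct"] += 1
            if call is not None and call.flags.get("top1cc_enriched") is not None:
                if row.top1cc:
                    n_top1_true += 1
                    n_top1_flagged += int(call.flags["top1cc_enriched"])
                else:
                    n_top1_false += 1
                    n_top1_misflagged += int(call.flags["top1cc_enriched"])
        elif row.label.startswith("decoy"):
            n_decoy += 1
            rejected = call is None or call.label == "unclassified"
            n_decoy_rejected += int(rejected)
            stats["matched"] += int(call is not None)
            stats["correct"] += int(rejected)

    return {
        "n_planted": n_real,
        "n_matched": n_matched,
        "n_correct_label": n_correct,
        "label_recovery": n_correct / n_real if n_real else float("nan"),
        "n_decoys": n_decoy,
        "decoy_rejection": n_decoy_rejected / n_decoy if n_decoy else float("nan"),
        "n_top1cc_planted": n_top1_true,
        "top1cc_recovery": n_top1_flagged / n_top1_true if n_top1_true else float("nan"),
        "top1cc_false_flag_rate": n_top1_misflagged / n_top1_false if n_top1_false else 0.0,
        "per_class": per_class,
    }
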