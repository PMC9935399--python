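"""Synthetic genome, annotation, and tag-data generator with ground truth.

Generates a toy genome with non-overlapping genes, plants enhancer loci of
every supported class (plus decoys that each violate exactly one
classification gate), and simulates per-assay tag records: uniform Poisson
background, Poisson tag masses with Gaussian positional spread at planted
loci, divergent strand geometry for nascent (eRNA) tags, and uniform
sense-strand gene-body tags.

Because every directory is depth-normalized to a common total, a planted
raw-mass ratio is not the observed normalized fold-change: both libraries
are forced to the same normalized total, so condition-specific signal gains
are partially absorbed by the rest of the library. The generator therefore
specifies control masses plus *target normalized fold-changes* and solves
for the treated raw masses exactly:

    alpha = G / (G - sum_i (f_i - 1) m_i)

where m_i are control masses of fold-change-targeted units, f_i their
targets, and G the mass shared equally by both conditions (background +
ballast genes). Treated mass is then f_i * m_i * alpha, which makes the
expected normalized fold-change of unit i equal f_i.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    ChromSizes,
    TssRecord,
    write_chrom_sizes,
    write_tss_table,
)
from .tags import AssayBundle, build_tag_directory, write_tagalign

__all__ = [
    "SyntheticConfig",
    "TruthTable",
    "generate_annotation",
    "plant_enhancers",
    "simulate_tags",
    "simulate_bundle",
    "write_fixture_bundle",
    "child_rng",
]

ASSAYS = ("k27ac", "nascent", "polii", "tf", "top1cc")

#: condition label pairs used throughout the synthetic pipeline
CONTROL, TREATED = "control", "treated"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic genome and tag model.

    Masses are expected raw tag counts per locus (Poisson); background rates
    are raw tags per bp genome-wide.
    """

    genome: Mapping[str, int] = field(default_factory=lambda: {"chrS": 10_000_000})
    n_genes: int = 40

    # enhancer class counts
    n_megatrans: int = 70
    n_eralpha_other: int = 70
    n_other_active: int = 60
    n_proinflammatory: int = 0
    n_androgen: int = 0
    n_neuronal: int = 0
    n_decoy_tss: int = 10
    n_decoy_k27ac: int = 10
    n_decoy_nascent: int = 10

    # intensity parameters
    # Background is kept sparse and library mass is dominated by planted
    # loci plus gene-body "ballast" so that (a) an empty window normalizes
    # well below the 10/16 tag floors and (b) the one-tag quantum
    # (norm_target / library size) also stays below those floors.
    background_rate: Mapping[str, float] = field(
        default_factory=lambda: {
            "k27ac": 1e-5,
            "nascent": 1e-5,
            "polii": 1e-5,
            "tf": 1e-5,
            "top1cc": 1e-5,
        }
    )
    k27ac_mass: float = 8000.0
    nascent_base_mass: float = 800.0
    band_base_mass: float = 800.0
    tf_mass: float = 400.0
    polii_base_mass: float = 800.0
    top1cc_mass: float = 300.0
    gene_nascent_mass: float = 30000.0
    gene_polii_mass: float = 15000.0
    positional_sd: float = 150.0
    k27ac_positional_sd: float = 450.0  # broad nucleosomal mark

    # condition effects
    erna_fc: float = 3.0
    band_fc_low: float = 0.75
    band_fc_high: float = 1.33
    induced_fc: float = 3.0
    gene_fc: float = 1.6
    n_genes_up: int = 3
    n_genes_down: int = 3

    # TOP1cc coupling
    top1cc_coupling_acute: float = 1.0
    top1cc_coupling_other: float = 0.05

    # geometry
    tss_clearance: int = 5000
    gene_clearance: int = 2000
    locus_spacing: int = 4000
    decoy_tss_offset: int = 1500

    # directory construction
    chip_cap: int = 2
    nascent_cap: int = 3
    n_replicates: int = 1

    seed: int = 0

    def cap_for(self, assay: str) -> int:
        return self.nascent_cap if assay == "nascent" else self.chip_cap

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        return cls(**dict(d))


@dataclass
class TruthTable:
    """Planted ground truth: one row per locus plus the gene-level masses.

    ``loci`` columns: locus_id, chrom, center, label, era_marked, top1cc,
    and mass_<assay>_<condition> for every assay/condition pair.
    ``genes`` columns: gene, chrom, tss, strand, gene_end,
    nascent_mass_control/treated, nascent_target_fc, polii_mass.
    """

    loci: pd.DataFrame
    genes: pd.DataFrame
    chrom_sizes: ChromSizes
    tss: list[TssRecord]

    def class_counts(self) -> dict[str, int]:
        return self.loci["label"].value_counts().to_dict()


def child_rng(seed: int, *labels: str) -> np.random.Generator:
    """Deterministic per-stream generator: adding a stream never perturbs
    others because each (seed, labels...) pair seeds independently."""
    entropy = [seed] + [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng(entropy)


# ---------------------------------------------------------------------------
# Annotation


def generate_annotation(
    config: SyntheticConfig,
) -> tuple[ChromSizes, list[TssRecord]]:
    """Place ``n_genes`` non-overlapping genes with log-uniform lengths in
    [5 kb, 50 kb]; strands random; deterministic under config.seed."""
    sizes = ChromSizes(config.genome)
    rng = child_rng(config.seed, "annotation")
    records: list[TssRecord] = []
    chroms = sorted(sizes)
    lengths = np.asarray([sizes[c] for c in chroms], dtype=float)
    per_chrom = np.maximum(
        np.round(config.n_genes * lengths / lengths.sum()).astype(int), 0
    )
    # fix rounding so the total is exact
    while per_chrom.sum() > config.n_genes:
        per_chrom[np.argmax(per_chrom)] -= 1
    while per_chrom.sum() < config.n_genes:
        per_chrom[np.argmax(lengths)] += 1
    gi = 0
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        L = sizes[chrom]
        gene_lens = np.exp(rng.uniform(np.log(5000), np.log(50000), size=n_here)).astype(int)
        slack = L - int(gene_lens.sum()) - 2 * (n_here + 1)
        if slack <= 0:
            raise ValueError(f"chromosome {chrom!r} too small for {n_here} genes")
        gaps = rng.dirichlet(np.ones(n_here + 1)) * slack
        pos = 1
        for i in range(n_here):
            pos += int(gaps[i]) + 1
            start, end = pos, pos + int(gene_lens[i])
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                records.append(TssRecord(f"gene_{gi}", chrom, start, "+", end))
            else:
                records.append(TssRecord(f"gene_{gi}", chrom, end - 1, "-", start - 1))
            pos = end + 1
            gi += 1
    return sizes, records


# ---------------------------------------------------------------------------
# Enhancer planting


_CLASS_ORDER = (
    "megatrans",
    "eralpha_other_active",
    "other_active",
    "proinflammatory",
    "androgen_induced",
    "neuronal_induced",
    "decoy_k27ac",
    "decoy_nascent",
)


def _intergenic_slots(
    sizes: ChromSizes, tss: Sequence[TssRecord], config: SyntheticConfig
) -> list[tuple[str, int]]:
    """Candidate locus centers spaced ``locus_spacing`` apart, clear of gene
    bodies (+clearance) and of TSSs (+tss_clearance)."""
    slots: list[tuple[str, int]] = []
    for chrom in sorted(sizes):
        L = sizes[chrom]
        blocked = np.zeros(L // 100 + 1, dtype=bool)  # 100-bp resolution
        for rec in tss:
            if rec.chrom != chrom:
                continue
            lo, hi = sorted((rec.tss, rec.gene_end))
            lo = max(0, lo - config.gene_clearance)
            hi = min(L, hi + config.gene_clearance)
            blocked[lo // 100 : hi // 100 + 1] = True
            t_lo = max(0, rec.tss - config.tss_clearance)
            t_hi = min(L, rec.tss + config.tss_clearance)
            blocked[t_lo // 100 : t_hi // 100 + 1] = True
        margin = 6000  # keep profile windows clear of chromosome edges
        for center in range(margin, L - margin, config.locus_spacing):
            if not blocked[center // 100]:
                slots.append((chrom, center))
    return slots


def _balance_treated_masses(
    control: np.ndarray, targets: np.ndarray, shared_mass: float
) -> tuple[np.ndarray, float]:
    """Solve treated masses so expected normalized fold-changes equal targets.

    Returns (treated_masses, alpha). Raises when the requested excess signal
    cannot be absorbed by the shared (ballast + background) mass.
    """
    if control.size == 0:
        return control.astype(float).copy(), 1.0
    excess = float(np.sum((targets - 1.0) * control))
    if shared_mass <= 0:
        if abs(excess) > 1e-9:
            raise ValueError(
                "fold-change targets need shared (ballast/background) mass to absorb"
            )
        return targets * control, 1.0
    if excess >= shared_mass:
        raise ValueError(
            "requested fold-change excess exceeds shared library mass; "
            "increase ballast (gene mass / background) or lower targets"
        )
    alpha = shared_mass / (shared_mass - excess)
    return targets * control * alpha, alpha


def plant_enhancers(
    config: SyntheticConfig,
    sizes: ChromSizes | None = None,
    tss: Sequence[TssRecord] | None = None,
) -> TruthTable:
    """Plant enhancer loci of every configured class plus gate decoys.

    Decoy classes each violate exactly one gate: ``decoy_tss`` sits
    ``decoy_tss_offset`` bp from a TSS, ``decoy_k27ac`` has no H3K27Ac mass,
    ``decoy_nascent`` has no nascent mass; all other criteria are set to pass.
    """
    if sizes is None or tss is None:
        sizes, tss = generate_annotation(config)
    rng = child_rng(config.seed, "plant")

    n_by_class = {
        "megatrans": config.n_megatrans,
        "eralpha_other_active": config.n_eralpha_other,
        "other_active": config.n_other_active,
        "proinflammatory": config.n_proinflammatory,
        "androgen_induced": config.n_androgen,
        "neuronal_induced": config.n_neuronal,
        "decoy_k27ac": config.n_decoy_k27ac,
        "decoy_nascent": config.n_decoy_nascent,
    }
    n_slots_needed = sum(n_by_class.values())
    slots = _intergenic_slots(sizes, tss, config)
    if len(slots) < n_slots_needed:
        raise ValueError(
            f"insufficient intergenic space: need {n_slots_needed} loci, "
            f"have {len(slots)} candidate slots"
        )
    chosen = [slots[i] for i in rng.choice(len(slots), size=n_slots_needed, replace=False)]
    rng.shuffle(chosen)

    rows: list[dict] = []
    i = 0
    for label in _CLASS_ORDER:
        for _ in range(n_by_class[label]):
            chrom, center = chosen[i]
            i += 1
            rows.append(_locus_row(label, chrom, center, config, rng))

    # TSS-gate decoys sit just upstream of a random TSS
    genes_by_chrom = list(tss)
    for _ in range(config.n_decoy_tss):
        for _attempt in range(100):
            rec = genes_by_chrom[int(rng.integers(0, len(genes_by_chrom)))]
            offset = config.decoy_tss_offset
            center = rec.tss - offset if rec.strand == "+" else rec.tss + offset
            if 6000 <= center < sizes[rec.chrom] - 6000:
                break
        else:
            raise ValueError("could not place decoy_tss locus")
        rows.append(_locus_row("decoy_tss", rec.chrom, center, config, rng))

    locus_columns = [
        "chrom", "center", "label", "era_marked", "top1cc",
        "mass_k27ac_control", "mass_k27ac_treated",
        "mass_nascent_control", "nascent_target_fc", "mass_nascent_treated",
        "mass_polii_control", "polii_target_fc", "mass_polii_treated",
        "mass_tf_control", "mass_tf_treated",
        "mass_top1cc_control", "mass_top1cc_treated",
    ]
    loci = pd.DataFrame(rows, columns=locus_columns)
    loci.insert(0, "locus_id", [f"locus_{j}" for j in range(len(loci))])

    genes = _gene_truth(config, tss, rng)

    _balance_assay(loci, genes, config, assay="nascent")
    if (config.n_proinflammatory + config.n_androgen + config.n_neuronal) > 0:
        _balance_assay(loci, genes, config, assay="polii")
    else:
        loci["mass_polii_treated"] = loci["mass_polii_control"]
        genes["polii_mass_treated"] = genes["polii_mass_control"]
    return TruthTable(loci=loci, genes=genes, chrom_sizes=sizes, tss=list(tss))


def _locus_row(
    label: str, chrom: str, center: int, config: SyntheticConfig, rng: np.random.Generator
) -> dict:
    era = label in (
        "megatrans", "eralpha_other_active", "decoy_tss", "decoy_k27ac", "decoy_nascent",
    )
    induced = label in ("proinflammatory", "androgen_induced", "neuronal_induced")
    acute = label in ("megatrans",) or induced
    coupling = config.top1cc_coupling_acute if acute else config.top1cc_coupling_other
    top1cc = bool(rng.random() < coupling)

    k27 = 0.0 if label == "decoy_k27ac" else config.k27ac_mass
    if label in ("eralpha_other_active", "other_active"):
        nascent_c = config.band_base_mass
        nascent_fc = float(rng.uniform(config.band_fc_low, config.band_fc_high))
    elif label in ("megatrans", "decoy_tss", "decoy_k27ac"):
        nascent_c = config.nascent_base_mass
        nascent_fc = config.erna_fc
    else:  # decoy_nascent and induced classes carry no eRNA signal
        nascent_c, nascent_fc = 0.0, 1.0

    polii_c = config.polii_base_mass if induced else 0.0
    polii_fc = config.induced_fc if induced else 1.0
    tf = config.tf_mass if (era or label in ("proinflammatory", "androgen_induced")) else 0.0

    return {
        "chrom": chrom,
        "center": int(center),
        "label": label,
        "era_marked": era,
        "top1cc": top1cc,
        "mass_k27ac_control": k27,
        "mass_k27ac_treated": k27,
        "mass_nascent_control": nascent_c,
        "nascent_target_fc": nascent_fc,
        "mass_nascent_treated": np.nan,  # filled by balancing
        "mass_polii_control": polii_c,
        "polii_target_fc": polii_fc,
        "mass_polii_treated": np.nan,
        "mass_tf_control": 0.0,
        "mass_tf_treated": tf,
        "mass_top1cc_control": 0.0,
        "mass_top1cc_treated": config.top1cc_mass if top1cc else 0.0,
    }


def _gene_truth(
    config: SyntheticConfig, tss: Sequence[TssRecord], rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    n = len(tss)
    n_up = min(config.n_genes_up, n)
    n_down = min(config.n_genes_down, max(0, n - n_up))
    diff_idx = rng.choice(n, size=n_up + n_down, replace=False) if n else np.array([], dtype=int)
    up_set = set(diff_idx[:n_up].tolist())
    down_set = set(diff_idx[n_up:].tolist())
    for i, rec in enumerate(tss):
        fc = config.gene_fc if i in up_set else (1.0 / config.gene_fc if i in down_set else 1.0)
        rows.append(
            {
                "gene": rec.gene,
                "chrom": rec.chrom,
                "tss": rec.tss,
                "strand": rec.strand,
                "gene_end": rec.gene_end,
                "nascent_mass_control": config.gene_nascent_mass,
                "nascent_target_fc": fc,
                "nascent_mass_treated": np.nan,
                "polii_mass_control": config.gene_polii_mass,
                "polii_mass_treated": np.nan,
            }
        )
    columns = [
        "gene", "chrom", "tss", "strand", "gene_end",
        "nascent_mass_control", "nascent_target_fc", "nascent_mass_treated",
        "polii_mass_control", "polii_mass_treated",
    ]
    return pd.DataFrame(rows, columns=columns)


def _balance_assay(
    loci: pd.DataFrame, genes: pd.DataFrame, config: SyntheticConfig, assay: str
) -> None:
    """Fill treated masses for one fold-change assay in place.

    Fold-change-targeted units are loci with positive control mass plus
    genes with a non-unit target; ballast is the background plus genes at
    fc 1 (whose raw mass is equal in both conditions)."""
    bg = config.background_rate[assay] * ChromSizes(config.genome).genome_length
    mass_c = f"mass_{assay}_control"
    mass_t = f"mass_{assay}_treated"
    fc_col = f"{assay}_target_fc"
    l_mask = loci[mass_c] > 0
    if assay == "nascent":
        g_ball = genes["nascent_target_fc"] == 1.0
        g_diff = ~g_ball
        ballast = bg + float(genes.loc[g_ball, "nascent_mass_control"].sum())
        control = np.concatenate(
            [loci.loc[l_mask, mass_c].to_numpy(), genes.loc[g_diff, "nascent_mass_control"].to_numpy()]
        )
        targets = np.concatenate(
            [loci.loc[l_mask, fc_col].to_numpy(), genes.loc[g_diff, "nascent_target_fc"].to_numpy()]
        )
        treated, _alpha = _balance_treated_masses(control, targets, ballast)
        k = int(l_mask.sum())
        loci.loc[~l_mask, mass_t] = 0.0
        loci.loc[l_mask, mass_t] = treated[:k]
        genes.loc[g_ball, "nascent_mass_treated"] = genes.loc[g_ball, "nascent_mass_control"]
        genes.loc[g_diff, "nascent_mass_treated"] = treated[k:]
    else:  # polii: genes are all ballast
        ballast = bg + float(genes["polii_mass_control"].sum())
        control = loci.loc[l_mask, mass_c].to_numpy()
        targets = loci.loc[l_mask, fc_col].to_numpy()
        treated, _alpha = _balance_treated_masses(control, targets, ballast)
        loci.loc[~l_mask, mass_t] = 0.0
        loci.loc[l_mask, mass_t] = treated
        genes["polii_mass_treated"] = genes["polii_mass_control"]


# ---------------------------------------------------------------------------
# Tag simulation


def simulate_tags(
    truth: TruthTable,
    assay: str,
    condition: str,
    replicate: str,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Simulate raw tag records (chrom, position, strand) for one directory.

    Background ~ Poisson(rate x genome length), uniform positions, random
    strand. Per locus, tag count ~ Poisson(planted mass) with positions
    ~ Normal(center, sd) clipped to the chromosome; nascent tags use
    divergent eRNA geometry ('+' downstream of center, '-' upstream).
    Nascent and Pol II tags additionally include uniform sense-strand
    gene-body tags. Reproducible under (seed, assay, condition, replicate).
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    if condition not in (CONTROL, TREATED):
        raise ValueError(f"unknown condition {condition!r}")
    rng = child_rng(config.seed, "tags", assay, condition, replicate)
    sizes = truth.chrom_sizes
    chroms = sorted(sizes)
    parts: list[pd.DataFrame] = []

    # background
    rate = config.background_rate[assay]
    for chrom in chroms:
        L = sizes[chrom]
        n_bg = rng.poisson(rate * L)
        if n_bg:
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "position": rng.integers(0, L, size=n_bg),
                        "strand": np.where(rng.random(n_bg) < 0.5, "+", "-"),
                    }
                )
            )

    # planted locus masses
    mass_col = f"mass_{assay}_{condition}"
    sd = config.k27ac_positional_sd if assay == "k27ac" else config.positional_sd
    for row in truth.loci.itertuples(index=False):
        mass = getattr(row, mass_col)
        if mass <= 0:
            continue
        n = rng.poisson(mass)
        if n == 0:
            continue
        L = sizes[row.chrom]
        if assay == "nascent":
            offsets = rng.normal(0.0, sd, size=n)
            strand = np.where(offsets >= 0, "+", "-")
            pos = np.clip(np.round(row.center + offsets), 0, L - 1).astype(np.int64)
        else:
            pos = np.clip(np.round(rng.normal(row.center, sd, size=n)), 0, L - 1).astype(np.int64)
            strand = np.where(rng.random(n) < 0.5, "+", "-")
        parts.append(pd.DataFrame({"chrom": row.chrom, "position": pos, "strand": strand}))

    # gene-body transcription for nascent / polii
    if assay in ("nascent", "polii"):
        gmass_col = f"nascent_mass_{condition}" if assay == "nascent" else f"polii_mass_{condition}"
        for g in truth.genes.itertuples(index=False):
            mass = getattr(g, gmass_col)
            n = rng.poisson(mass)
            if n == 0:
                continue
            L = sizes[g.chrom]
            glen = abs(g.gene_end - g.tss)
            offs = rng.integers(0, glen, size=n)
            pos = g.tss + offs if g.strand == "+" else g.tss - offs
            pos = np.clip(pos, 0, L - 1).astype(np.int64)
            if assay == "nascent":
                strand = np.full(n, g.strand)  # sense-strand nascent tags
            else:
                strand = np.where(rng.random(n) < 0.5, "+", "-")
            parts.append(pd.DataFrame({"chrom": g.chrom, "position": pos, "strand": strand}))

    if not parts:
        return pd.DataFrame(columns=["chrom", "position", "strand"])
    return pd.concat(parts, ignore_index=True)


def default_directory_keys(config: SyntheticConfig) -> list[tuple[str, str]]:
    keys = [
        ("k27ac", TREATED),
        ("nascent", TREATED),
        ("nascent", CONTROL),
        ("tf", TREATED),
        ("top1cc", TREATED),
    ]
    if (config.n_proinflammatory + config.n_androgen + config.n_neuronal) > 0:
        keys += [("polii", TREATED), ("polii", CONTROL)]
    return keys


def simulate_bundle(
    truth: TruthTable, config: SyntheticConfig
) -> tuple[AssayBundle, dict[tuple[str, str, str], pd.DataFrame]]:
    """Simulate and build tag directories for the standard assay/condition
    grid; returns the bundle plus the raw (uncapped) tag records."""
    bundle = AssayBundle()
    records: dict[tuple[str, str, str], pd.DataFrame] = {}
    for assay, condition in default_directory_keys(config):
        for r in range(config.n_replicates):
            rep = f"rep{r + 1}"
            recs = simulate_tags(truth, assay, condition, rep, config)
            records[(assay, condition, rep)] = recs
            bundle.add(
                build_tag_directory(
                    recs,
                    assay=assay,
                    condition=condition,
                    replicate=rep,
                    per_position_cap=config.cap_for(assay),
                    chrom_sizes=truth.chrom_sizes,
                )
            )
    return bundle, records


# ---------------------------------------------------------------------------
# Fixture bundles on disk


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(
    truth: TruthTable,
    tag_records: Mapping[tuple[str, str, str], pd.DataFrame],
    outdir: str | Path,
    config: SyntheticConfig,
    force: bool = False,
) -> Path:
    """Write a self-contained plain-text fixture: chrom.sizes, TSS table,
    per-directory tagAlign BED, truth TSVs, and a YAML manifest (with file
    checksums) sufficient to rerun the pipeline without this module."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is non-empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)

    write_chrom_sizes(truth.chrom_sizes, outdir / "genome.chrom.sizes")
    write_tss_table(truth.tss, outdir / "tss.tsv")
    truth.loci.to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)

    tag_entries = []
    for (assay, condition, rep), recs in sorted(tag_records.items()):
        fname = f"tags_{assay}_{condition}_{rep}.tagalign.bed"
        write_tagalign(recs, outdir / fname)
        tag_entries.append(
            {
                "assay": assay,
                "condition": condition,
                "replicate": rep,
                "path": fname,
                "per_position_cap": config.cap_for(assay),
            }
        )

    manifest = {
        "mode": "real",
        "seed": config.seed,
        "scheme": "hormone",
        "chrom_sizes": "genome.chrom.sizes",
        "tss": "tss.tsv",
        "truth_loci": "truth_loci.tsv",
        "truth_genes": "truth_genes.tsv",
        "tags": tag_entries,
        "synthetic_config": {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in asdict(config).items()},
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    checksums = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.name != "checksums.json"
    }
    (outdir / "checksums.json").write_text(json.dumps(checksums, indent=2, sort_keys=True))
    return outdir / "manifest.yaml"
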