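"""Signal-dependent enhancer group definitions.

Six enhancer groups are supported, all sharing a common distal + H3K27Ac
gate: hormone-responsive groups classified from nascent-transcription
(eRNA) fold-change between treated and control conditions, and acutely
induced groups classified from Pol II (and TF) ChIP tag floors with or
without a Pol II fold-change criterion.

Threshold semantics (inclusive/exclusive) follow the published definitions:
tag floors and fold-inductions are inclusive (>= 16, >= 10, >= 1.5); the
"unchanged" fold-change band is the open interval (0.67, 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml

from .core import GenomicInterval, Peak, TssRecord, distance_to_nearest_tss
from .tags import AssayBundle, count_window

__all__ = [
    "ClassifyConfig",
    "EnhancerCall",
    "classify_hormone_enhancer",
    "classify_induced_enhancer",
    "classify_all",
    "annotate_feature_enrichment",
    "HORMONE_LABELS",
    "INDUCED_SCHEMES",
]

HORMONE_LABELS = ("megatrans", "eralpha_other_active", "other_active")
INDUCED_SCHEMES = {
    "proinflammatory": "proinflammatory",
    "androgen": "androgen_induced",
    "neuronal": "neuronal_induced",
}
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassifyConfig:
    """Thresholds for the enhancer-group definitions (tags-per-10M units)."""

    tss_min_dist: int = 3000
    k27ac_min: float = 16.0
    nascent_min: float = 10.0
    fc_up: float = 1.5
    fc_band_low: float = 0.67
    polii_min: float = 10.0
    polii_tf_min: float = 16.0
    fc_pseudocount: float = 1.0
    # The published band definition reads "at least 10 tags ... when treated
    # with either ethanol or E2": with "either" (default) one condition at
    # the floor suffices; "both" demands expression in both conditions.
    band_floor_mode: str = "either"

    def __post_init__(self) -> None:
        for name in ("k27ac_min", "nascent_min", "fc_up", "fc_band_low", "polii_min", "polii_tf_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.fc_band_low < self.fc_up:
            raise ValueError("fc_band_low must be < fc_up")
        if self.band_floor_mode not in ("either", "both"):
            raise ValueError("band_floor_mode must be 'either' or 'both'")

    def fold_change(self, treated: float, control: float) -> float:
        pc = self.fc_pseudocount
        return (treated + pc) / (control + pc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ClassifyConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class EnhancerCall:
    """A candidate region, its assigned group label, and the metric values
    that justified the label."""

    region: GenomicInterval
    label: str
    metrics: dict[str, float] = field(default_factory=dict)
    tf_marked: dict[str, bool] = field(default_factory=dict)
    flags: dict[str, bool] = field(default_factory=dict)


def _common_gate(tss_dist: float, k27ac: float, config: ClassifyConfig) -> bool:
    return tss_dist >= config.tss_min_dist and k27ac >= config.k27ac_min


def classify_hormone_enhancer(
    region: GenomicInterval,
    k27ac: float,
    nascent_treated: float,
    nascent_control: float,
    tss_dist: float,
    era_marked: bool,
    config: ClassifyConfig | None = None,
) -> EnhancerCall:
    """Classify a candidate region into the hormone-responsive groups.

    Gate: distal (tss_dist >= 3 kb) and H3K27Ac floor (>= 16). Then with
    fc = (treated + pc) / (control + pc):

    - megatrans: ER-marked, treated nascent >= 10, fc >= 1.5
    - eralpha_other_active: ER-marked, nascent floor met per
      ``band_floor_mode``, fc in the open band (0.67, 1.5)
    - other_active: same band criteria but not ER-marked
    - otherwise unclassified
    """
    config = config or ClassifyConfig()
    for name, v in (("k27ac", k27ac), ("nascent_treated", nascent_treated),
                    ("nascent_control", nascent_control)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    fc = config.fold_change(nascent_treated, nascent_control)
    metrics = {
        "tss_dist": float(tss_dist),
        "k27ac": float(k27ac),
        "nascent_treated": float(nascent_treated),
        "nascent_control": float(nascent_control),
        "fc": float(fc),
    }
    label = UNCLASSIFIED
    if _common_gate(tss_dist, k27ac, config):
        in_band = config.fc_band_low < fc < config.fc_up
        floor_stat = min if config.band_floor_mode == "both" else max
        expressed = floor_stat(nascent_treated, nascent_control) >= config.nascent_min
        if era_marked and nascent_treated >= config.nascent_min and fc >= config.fc_up:
            label = "megatrans"
        elif era_marked and expressed and in_band:
            label = "eralpha_other_active"
        elif not era_marked and expressed and in_band:
            label = "other_active"
    return EnhancerCall(
        region=region, label=label, metrics=metrics, tf_marked={"era": bool(era_marked)}
    )


def classify_induced_enhancer(
    region: GenomicInterval,
    k27ac: float,
    polii_treated: float,
    polii_control: float,
    tf_treated: float,
    tss_dist: float,
    scheme: str,
    config: ClassifyConfig | None = None,
) -> EnhancerCall:
    """Classify a candidate region under one of the acute-induction schemes.

    Common gate: distal and H3K27Ac floor. Then:

    - proinflammatory: Pol II >= 16 and TF (p65) >= 16 in the treated
      condition; no fold-change criterion.
    - androgen: Pol II >= 10 and TF (AR) >= 10 treated, Pol II fc >= 1.5.
    - neuronal: Pol II >= 10 treated and Pol II fc >= 1.5; TF ignored.
    """
    config = config or ClassifyConfig()
    if scheme not in INDUCED_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {sorted(INDUCED_SCHEMES)}")
    for name, v in (("k27ac", k27ac), ("polii_treated", polii_treated),
                    ("polii_control", polii_control), ("tf_treated", tf_treated)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    fc = config.fold_change(polii_treated, polii_control)
    metrics = {
        "tss_dist": float(tss_dist),
        "k27ac": float(k27ac),
        "polii_treated": float(polii_treated),
        "polii_control": float(polii_control),
        "tf_treated": float(tf_treated),
        "polii_fc": float(fc),
    }
    label = UNCLASSIFIED
    if _common_gate(tss_dist, k27ac, config):
        if scheme == "proinflammatory":
            if polii_treated >= config.polii_tf_min and tf_treated >= config.polii_tf_min:
                label = INDUCED_SCHEMES[scheme]
        elif scheme == "androgen":
            if (
                polii_treated >= config.polii_min
                and tf_treated >= config.polii_min
                and fc >= config.fc_up
            ):
                label = INDUCED_SCHEMES[scheme]
        else:  # neuronal
            if polii_treated >= config.polii_min and fc >= config.fc_up:
                label = INDUCED_SCHEMES[scheme]
    return EnhancerCall(region=region, label=label, metrics=metrics, tf_marked={})


def annotate_feature_enrichment(
    calls: Sequence[EnhancerCall],
    feature_peaks: Sequence[Peak],
    max_center_dist: int = 1000,
    flag_name: str = "top1cc_enriched",
) -> list[EnhancerCall]:
    """Flag calls whose region center lies within ``max_center_dist`` of a
    feature-peak summit (inclusive); mutates and returns ``calls``."""
    by_chrom: dict[str, list[int]] = {}
    for p in feature_peaks:
        by_chrom.setdefault(p.chrom, []).append(p.summit)
    sorted_summits = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}
    for call in calls:
        center = call.region.center
        summits = sorted_summits.get(call.region.chrom)
        hit = False
        if summits is not None and len(summits):
            i = np.searchsorted(summits, center)
            for j in (i - 1, i):
                if 0 <= j < len(summits) and abs(int(summits[j]) - center) <= max_center_dist:
                    hit = True
                    break
        call.flags[flag_name] = hit
    return list(calls)


_SCHEME_ASSAYS: Mapping[str, tuple[tuple[str, str], ...]] = {
    "hormone": (("k27ac", "treated"), ("nascent", "treated"), ("nascent", "control")),
    "proinflammatory": (("k27ac", "treated"), ("polii", "treated"), ("polii", "control"), ("tf", "treated")),
    "androgen": (("k27ac", "treated"), ("polii", "treated"), ("polii", "control"), ("tf", "treated")),
    "neuronal": (("k27ac", "treated"), ("polii", "treated"), ("polii", "control")),
}


def classify_all(
    regions: Sequence[GenomicInterval],
    bundle: AssayBundle,
    tss_set: Sequence[TssRecord],
    scheme: str = "hormone",
    config: ClassifyConfig | None = None,
    era_peaks: Sequence[Peak] | None = None,
    era_marked: Sequence[bool] | None = None,
    halfwidth: int = 1000,
) -> list[EnhancerCall]:
    """Classify every region by quantifying the scheme's assays in
    +/- ``halfwidth`` windows around region centers.

    ER-marking for the hormone scheme comes from ``era_marked`` booleans, or
    from ``era_peaks`` (marked iff a peak summit lies within ``halfwidth`` of
    the region center); with neither supplied every region counts as marked
    (regions anchored on ER peaks).
    """
    config = config or ClassifyConfig()
    if scheme not in _SCHEME_ASSAYS:
        raise ValueError(f"unknown scheme {scheme!r}")
    missing = [key for key in _SCHEME_ASSAYS[scheme] if not bundle.has(*key)]
    if missing:
        raise KeyError(f"bundle missing required (assay, condition) keys: {missing}")

    if scheme == "hormone" and era_marked is None:
        if era_peaks is not None:
            marks = _mark_by_summits(regions, era_peaks, halfwidth)
        else:
            marks = [True] * len(regions)
    elif era_marked is not None:
        marks = list(era_marked)
    else:
        marks = [True] * len(regions)

    k27 = bundle.pooled("k27ac", "treated")
    calls: list[EnhancerCall] = []
    if scheme == "hormone":
        tr = bundle.pooled("nascent", "treated")
        ct = bundle.pooled("nascent", "control")
        for region, marked in zip(regions, marks):
            c = region.center
            calls.append(
                classify_hormone_enhancer(
                    region,
                    k27ac=count_window(k27, region.chrom, c, halfwidth),
                    nascent_treated=count_window(tr, region.chrom, c, halfwidth),
                    nascent_control=count_window(ct, region.chrom, c, halfwidth),
                    tss_dist=distance_to_nearest_tss(region, tss_set),
                    era_marked=marked,
                    config=config,
                )
            )
    else:
        tr = bundle.pooled("polii", "treated")
        ct = bundle.pooled("polii", "control")
        tf = bundle.pooled("tf", "treated") if bundle.has("tf", "treated") else None
        for region in regions:
            c = region.center
            calls.append(
                classify_induced_enhancer(
                    region,
                    k27ac=count_window(k27, region.chrom, c, halfwidth),
                    polii_treated=count_window(tr, region.chrom, c, halfwidth),
                    polii_control=count_window(ct, region.chrom, c, halfwidth),
                    tf_treated=count_window(tf, region.chrom, c, halfwidth) if tf else 0.0,
                    tss_dist=distance_to_nearest_tss(region, tss_set),
                    scheme=scheme,
                    config=config,
                )
            )
    return calls


def _mark_by_summits(
    regions: Sequence[GenomicInterval], peaks: Sequence[Peak], max_dist: int
) -> list[bool]:
    by_chrom: dict[str, list[int]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p.summit)
    idx = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}
    marks = []
    for region in regions:
        summits = idx.get(region.chrom)
        hit = False
        if summits is not None and len(summits):
            center = region.center
            i = np.searchsorted(summits, center)
            for j in (i - 1, i):
                if 0 <= j < len(summits) and abs(int(summits[j]) - center) <= max_dist:
                    hit = True
                    break
        marks.append(hit)
    return marks
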