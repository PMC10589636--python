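"""Copy-number topography: segment states, arm-level events, HRD indices.

Segment states are derived from the ploidy-normalized log2 ratio
log2((cn_major + cn_minor) / ploidy): gain above +0.3, loss below -0.3,
amplification above 1.25 combined with a total-copy-number criterion
((ploidy <= 2.7 and total >= 5) or (ploidy > 2.7 and total >= 9)),
homozygous deletion at total 0.  LOH (cn_minor = 0 with total >= 1) is an
orthogonal flag.  The HRD-LOH index counts long (> 15 Mb) LOH segments not
spanning a whole chromosome.  HRDetect-style scoring combines six features
through a configurable standardized logistic model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogs import ID83_CHANNELS
from .variant_io import CnaSegment

log = logging.getLogger(__name__)

STATE_ORDER = ("homozygous_deletion", "loss", "neutral", "gain", "amplification")


@dataclass(frozen=True)
class CnaState:
    segment: CnaSegment
    state: str
    loh: bool
    log2_ratio: float


def classify_segment(segment: CnaSegment, ploidy: float,
                     gain_thresh: float = 0.3, amp_thresh: float = 1.25,
                     amp_low_ploidy_total: int = 5, amp_high_ploidy_total: int = 9,
                     amp_ploidy_cut: float = 2.7) -> CnaState:
    """Assign a copy-number state from the ploidy-normalized log2 ratio."""
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    total = segment.total_cn
    ratio = math.log2(total / ploidy) if total > 0 else float("-inf")
    loh = segment.cn_minor == 0 and segment.cn_major >= 1
    if total == 0:
        state = "homozygous_deletion"
    elif ratio > amp_thresh and (
            (ploidy <= amp_ploidy_cut and total >= amp_low_ploidy_total)
            or (ploidy > amp_ploidy_cut and total >= amp_high_ploidy_total)):
        state = "amplification"
    elif ratio > gain_thresh:
        state = "gain"
    elif ratio < -gain_thresh:
        state = "loss"
    else:
        state = "neutral"
    return CnaState(segment=segment, state=state, loh=loh, log2_ratio=ratio)


def call_arm_events(states: Sequence[CnaState],
                    arms: Mapping[str, tuple[str, int, int]],
                    min_arm_fraction: float = 0.60,
                    mode: str = "arm_fraction") -> dict[str, str]:
    """Per-arm {gain, loss, none} calls for one sample.

    ``arms`` maps arm name -> (chrom, start, end) in 0-based half-open
    coordinates.  An arm is called when a single gain/loss/amplification
    segment's intersection covers >= ``min_arm_fraction`` of the arm
    (``mode="arm_fraction"``); ``mode="cna_fraction"`` additionally requires
    the whole segment to lie inside the arm.  Conflicts resolve by larger
    covered fraction.
    """
    calls: dict[str, str] = {}
    for arm, (chrom, a_start, a_end) in arms.items():
        arm_len = a_end - a_start
        best: tuple[float, str] | None = None
        for st in states:
            seg = st.segment
            if seg.chrom != chrom:
                continue
            direction = ("gain" if st.state in ("gain", "amplification")
                         else "loss" if st.state in ("loss", "homozygous_deletion")
                         else None)
            if direction is None:
                continue
            inter = min(seg.end, a_end) - max(seg.start, a_start)
            if inter <= 0:
                continue
            frac = inter / arm_len
            if frac < min_arm_fraction:
                continue
            if mode == "cna_fraction" and inter < seg.length:
                continue
            if best is None or frac > best[0]:
                best = (frac, direction)
        calls[arm] = best[1] if best else "none"
    return calls


def merge_loh_segments(segments: Sequence[CnaSegment]) -> list[tuple[str, int, int]]:
    """Contiguous runs of LOH segments (cn_minor = 0, total >= 1), merged
    across book-ended boundaries, as (chrom, start, end)."""
    loh = sorted((s for s in segments if s.cn_minor == 0 and s.total_cn >= 1),
                 key=lambda s: (s.chrom, s.start))
    merged: list[tuple[str, int, int]] = []
    for s in loh:
        if merged and merged[-1][0] == s.chrom and merged[-1][2] == s.start:
            merged[-1] = (s.chrom, merged[-1][1], s.end)
        else:
            merged.append((s.chrom, s.start, s.end))
    return merged


def hrd_loh_index(segments: Sequence[CnaSegment],
                  chromosome_lengths: Mapping[str, int],
                  min_length: int = 15_000_000) -> int:
    """Count LOH runs longer than ``min_length`` that do not span a whole
    chromosome (the standard HRD-LOH index)."""
    count = 0
    for chrom, start, end in merge_loh_segments(segments):
        if end - start <= min_length:
            continue
        if start <= 0 and end >= chromosome_lengths.get(chrom, end):
            continue
        count += 1
    return count


# ---------------------------------------------------------------------------
# HRDetect-style feature vector and logistic score
# ---------------------------------------------------------------------------

MH_DELETION_CHANNELS = tuple(c for c in ID83_CHANNELS if ":Del:M:" in c)
DELETION_CHANNELS = tuple(c for c in ID83_CHANNELS if ":Del:" in c)

HRD_FEATURES = ("proportion_mh_deletions", "exposure_sbs3", "exposure_r3",
                "exposure_sbs5", "hrd_loh_index", "exposure_sbs8")


@dataclass(frozen=True)
class HrdFeatureVector:
    proportion_mh_deletions: float
    exposure_sbs3: float
    exposure_r3: float
    exposure_sbs5: float
    hrd_loh_index: int
    exposure_sbs8: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in HRD_FEATURES], dtype=float)


@dataclass
class HrdetectConfig:
    """Logistic-model configuration.

    The shipped default (zero weights) is a structural placeholder for
    pipeline testing; the published model's weights are not distributed with
    this package and should be supplied by the user.
    """

    weights: np.ndarray = field(default_factory=lambda: np.zeros(6))
    intercept: float = 0.0
    means: np.ndarray = field(default_factory=lambda: np.zeros(6))
    scales: np.ndarray = field(default_factory=lambda: np.ones(6))
    log_transform: np.ndarray = field(
        default_factory=lambda: np.array([False, True, True, True, False, True]))


def hrdetect_features(indel_counts: pd.Series,
                      exposures: Mapping[str, float],
                      hrd_loh: int) -> HrdFeatureVector:
    """Assemble the six-feature vector from an ID-83 catalog row, named
    signature exposures (absent signatures contribute 0, logged) and the
    HRD-LOH index."""
    dels = float(indel_counts[list(DELETION_CHANNELS)].sum())
    mh = float(indel_counts[list(MH_DELETION_CHANNELS)].sum())
    if dels == 0:
        log.info("hrdetect_features: sample has no deletions; proportion set to 0")
        prop = 0.0
    else:
        prop = mh / dels
    def expo(name: str) -> float:
        if name not in exposures:
            log.info("hrdetect_features: exposure %s absent, using 0", name)
            return 0.0
        return float(exposures[name])
    return HrdFeatureVector(
        proportion_mh_deletions=prop,
        exposure_sbs3=expo("SBS3"), exposure_r3=expo("R3"),
        exposure_sbs5=expo("SBS5"), hrd_loh_index=int(hrd_loh),
        exposure_sbs8=expo("SBS8"))


def hrdetect_score(features: HrdFeatureVector,
                   config: HrdetectConfig | None = None) -> float:
    """logistic(intercept + w . standardized features) in [0, 1]."""
    cfg = config or HrdetectConfig()
    x = features.as_array()
    x = np.where(cfg.log_transform, np.log(x + 1.0), x)
    z = (x - cfg.means) / cfg.scales
    lin = cfg.intercept + float(np.dot(cfg.weights, z))
    return float(1.0 / (1.0 + math.exp(-lin)))
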