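"""Rearrangement topography.

Kataegis: maximal runs of >= 6 consecutive SNVs with every inter-mutation
distance strictly below 1 kb, per chromosome.  Clustered rearrangements:
regions where >= 10 SV breakpoints fall within a 10 Mb window, with regions
overlapping known complex events removed.  Chromothripsis candidates follow
interleaved-SV and oscillating-copy-number filters with simplified
statistical tests.  Complex-event calls from several sources are merged by
reciprocal interval overlap with a class-precedence survivor rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cna_topography import CnaState
from .variant_io import GeneAnnotation, SnvRecord, SvRecord

log = logging.getLogger(__name__)

EVENT_CLASSES = ("ecDNA", "BFB", "chromothripsis", "CnC", "chromoplexy",
                 "TIC", "rigma", "pyrgo", "clustered")
_CLASS_RANK = {c: i for i, c in enumerate(EVENT_CLASSES)}


@dataclass(frozen=True)
class KataegisCluster:
    sample_id: str
    chrom: str
    start: int  # 1-based position of the first SNV
    end: int    # 1-based position of the last SNV
    n_snvs: int
    max_imd: int


@dataclass(frozen=True)
class ComplexEvent:
    sample_id: str
    event_class: str
    intervals: tuple[tuple[str, int, int], ...]  # (chrom, start, end) 0-based half-open
    source: str = ""
    sv_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown complex-event class {self.event_class!r}")
        if not self.intervals:
            raise ValueError("complex event requires at least one interval")


@dataclass(frozen=True)
class ChromothripsisCandidate:
    sample_id: str
    chrom: str
    region: tuple[int, int]
    n_interleaved_svs: int
    n_oscillating_segments: int
    fragment_join_p: float
    exp_breakpoint_p: float
    confidence: str  # high / low / none
    needs_review: bool = False  # amplified low-confidence candidates flagged for inspection


# ---------------------------------------------------------------------------
# kataegis
# ---------------------------------------------------------------------------

def detect_kataegis(snvs: Sequence[SnvRecord], min_run: int = 6,
                    max_imd: int = 1000) -> list[KataegisCluster]:
    """Maximal per-chromosome runs of consecutive SNVs with inter-mutation
    distance strictly below ``max_imd``; runs of >= ``min_run`` emitted."""
    by_key: dict[tuple[str, str], list[int]] = {}
    for s in snvs:
        by_key.setdefault((s.sample_id, s.chrom), []).append(s.pos)
    clusters = []
    for (sample, chrom), positions in sorted(by_key.items()):
        positions.sort()
        i = 0
        n = len(positions)
        while i < n:
            j = i
            while j + 1 < n and positions[j + 1] - positions[j] < max_imd:
                j += 1
            if j - i + 1 >= min_run:
                run = positions[i:j + 1]
                clusters.append(KataegisCluster(
                    sample_id=sample, chrom=chrom, start=run[0], end=run[-1],
                    n_snvs=len(run),
                    max_imd=max(b - a for a, b in zip(run, run[1:]))))
            i = j + 1
    return clusters


# ---------------------------------------------------------------------------
# clustered rearrangements
# ---------------------------------------------------------------------------

def _intervals_overlap(a: tuple[str, int, int], b: tuple[str, int, int]) -> bool:
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def detect_clustered_rearrangements(svs: Sequence[SvRecord],
                                    window: int = 10_000_000,
                                    min_breakpoints: int = 10,
                                    known_events: Sequence[ComplexEvent] = (),
                                    ) -> list[ComplexEvent]:
    """Per-sample regions with >= ``min_breakpoints`` SV breakpoints inside a
    ``window``-base window; overlapping qualifying windows merged; regions
    overlapping a known complex event of the same sample are removed."""
    by_key: dict[tuple[str, str], list[int]] = {}
    for sv in svs:
        rec = sv.record if hasattr(sv, "record") else sv
        for chrom, pos in rec.breakpoints():
            by_key.setdefault((rec.sample_id, chrom), []).append(pos)
    events = []
    for (sample, chrom), pos in sorted(by_key.items()):
        pos.sort()
        n = len(pos)
        spans = []  # qualifying anchored windows as (start pos, end pos) inclusive
        j = 0
        for i in range(n):
            if j < i:
                j = i
            while j + 1 < n and pos[j + 1] - pos[i] <= window:
                j += 1
            if j - i + 1 >= min_breakpoints:
                spans.append((pos[i], pos[j]))
        if not spans:
            continue
        merged = [spans[0]]
        for s, e in spans[1:]:
            if s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        known = [iv for ev in known_events if ev.sample_id == sample
                 for iv in ev.intervals]
        for s, e in merged:
            region = (chrom, s - 1, e)  # 1-based inclusive span -> 0-based half-open
            if any(_intervals_overlap(region, iv) for iv in known):
                continue
            events.append(ComplexEvent(sample_id=sample, event_class="clustered",
                                       intervals=(region,), source="mutscenarios"))
    return events


# ---------------------------------------------------------------------------
# chromothripsis filters
# ---------------------------------------------------------------------------

def _interleaved_component(intervals: list[tuple[int, int]]) -> int:
    """Largest connected set of pairwise partially-overlapping (interleaving,
    not nested, not disjoint) intervals."""
    n = len(intervals)
    if n == 0:
        return 0
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        a1, a2 = intervals[i]
        for j in range(i + 1, n):
            b1, b2 = intervals[j]
            if (a1 < b1 < a2 < b2) or (b1 < a1 < b2 < a2):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    sizes: dict[int, int] = {}
    for i in range(n):
        r = find(i)
        sizes[r] = sizes.get(r, 0) + 1
    return max(sizes.values())


def longest_oscillating_run(totals: Sequence[int]) -> int:
    """Longest run of contiguous segments alternating between exactly two
    total-copy-number values."""
    n = len(totals)
    best = min(n, 1)
    for i in range(n - 1):
        if totals[i + 1] == totals[i]:
            continue
        a, b = totals[i], totals[i + 1]
        length = 2
        expect = a
        for j in range(i + 2, n):
            if totals[j] == expect:
                length += 1
                expect = b if expect == a else a
            else:
                break
        best = max(best, length)
    return best


def chromothripsis_filters(svs: Sequence[SvRecord],
                           cna_states: Sequence[CnaState],
                           sample_id: str,
                           min_interleaved: int = 6,
                           min_oscillating: int = 7,
                           alpha: float = 0.05,
                           enrichment_p: Mapping[str, float] | None = None,
                           ) -> list[ChromothripsisCandidate]:
    """Per-chromosome chromothripsis candidate calling.

    High confidence: >= ``min_interleaved`` interleaved intrachromosomal SVs,
    >= ``min_oscillating`` segments oscillating between two CN states, a
    fragment-join chi-square consistent with equal class proportions
    (p > alpha), and either a non-significant exponential-breakpoint KS test
    or significant chromosomal enrichment.  Low confidence: the two counts
    only.  Low-confidence candidates overlapping amplified segments are
    flagged for review rather than silently accepted.
    """
    recs = [sv.record if hasattr(sv, "record") else sv for sv in svs]
    recs = [r for r in recs if r.sample_id == sample_id]
    states = [st for st in cna_states if st.segment.sample_id == sample_id]
    chroms = sorted({r.chrom1 for r in recs if r.chrom1 == r.chrom2})
    out = []
    for chrom in chroms:
        intra = [r for r in recs if r.chrom1 == chrom and r.chrom2 == chrom
                 and r.svclass in ("DEL", "DUP", "INV")]
        if not intra:
            continue
        chrom_states = sorted((st for st in states if st.segment.chrom == chrom),
                              key=lambda st: st.segment.start)
        if not chrom_states:
            log.info("chromothripsis: no CNA states for %s %s; skipped", sample_id, chrom)
            continue
        n_inter = _interleaved_component([(r.pos1, r.pos2) for r in intra])
        n_osc = longest_oscillating_run([st.segment.total_cn for st in chrom_states])
        class_counts = [sum(1 for r in intra if r.svclass == c)
                        for c in ("DEL", "DUP", "INV")]
        join_p = float(stats.chisquare(class_counts).pvalue) if sum(class_counts) else 1.0
        bps = sorted(p for r in intra for _, p in r.breakpoints())
        gaps = np.diff(bps)
        gaps = gaps[gaps > 0]
        if len(gaps) >= 3:
            exp_p = float(stats.kstest(gaps, "expon",
                                       args=(0, float(gaps.mean()))).pvalue)
        else:
            exp_p = 1.0
        enr_p = (enrichment_p or {}).get(chrom, 1.0)
        counts_ok = n_inter >= min_interleaved and n_osc >= min_oscillating
        if counts_ok and join_p > alpha and (exp_p > alpha or enr_p < alpha):
            confidence = "high"
        elif counts_ok:
            confidence = "low"
        else:
            confidence = "none"
        amplified = any(st.state == "amplification" for st in chrom_states)
        out.append(ChromothripsisCandidate(
            sample_id=sample_id, chrom=chrom,
            region=(min(bps), max(bps)),
            n_interleaved_svs=n_inter, n_oscillating_segments=n_osc,
            fragment_join_p=join_p, exp_breakpoint_p=exp_p,
            confidence=confidence,
            needs_review=(confidence == "low" and amplified)))
    return out


# ---------------------------------------------------------------------------
# complex-event merging, annotation, statistics
# ---------------------------------------------------------------------------

def _interval_set_overlap(a: ComplexEvent, b: ComplexEvent) -> float:
    """Reciprocal overlap fraction: intersection length over the larger of
    the two events' total interval lengths."""
    inter = 0
    for ia in a.intervals:
        for ib in b.intervals:
            if ia[0] == ib[0]:
                inter += max(0, min(ia[2], ib[2]) - max(ia[1], ib[1]))
    len_a = sum(e - s for _, s, e in a.intervals)
    len_b = sum(e - s for _, s, e in b.intervals)
    if len_a == 0 or len_b == 0:
        return 0.0
    return min(inter / len_a, inter / len_b)


def merge_complex_calls(events: Sequence[ComplexEvent],
                        min_reciprocal_overlap: float = 0.5) -> list[ComplexEvent]:
    """Collapse same-sample events whose interval sets reciprocally overlap
    by >= ``min_reciprocal_overlap``; the survivor carries the most
    informative class (fixed precedence) and the union of sources/SV ids."""
    events = list(events)
    n = len(events)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if events[i].sample_id != events[j].sample_id:
                continue
            if _interval_set_overlap(events[i], events[j]) >= min_reciprocal_overlap:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[ComplexEvent]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(events[i])
    merged = []
    for members in groups.values():
        members.sort(key=lambda e: (_CLASS_RANK[e.event_class], e.intervals))
        survivor = members[0]
        sources = ";".join(sorted({s for e in members for s in e.source.split(";") if s}))
        sv_ids = tuple(sorted({i for e in members for i in e.sv_ids}))
        merged.append(ComplexEvent(sample_id=survivor.sample_id,
                                   event_class=survivor.event_class,
                                   intervals=survivor.intervals,
                                   source=sources, sv_ids=sv_ids))
    merged.sort(key=lambda e: (e.sample_id, e.intervals, e.event_class))
    return merged


HIT_TYPES = ("sv_within", "sv_close", "amp", "homdel", "coding_snv_indel")
_CODING_CONSEQUENCES = {"missense", "stop_gained"}


def annotate_gene_overlap(svs: Sequence[SvRecord],
                          cna_states: Sequence[CnaState],
                          small_variants: Sequence,
                          genes: Sequence[GeneAnnotation],
                          pad: int = 20_000) -> pd.DataFrame:
    """Per-sample per-gene hit table.

    sv_within: an SV breakpoint inside the gene body; sv_close: within
    ``pad`` bases of the body but not inside; amp/homdel: gene overlaps a
    segment of that state; coding_snv_indel: a missense/stop-gained record
    inside the gene.
    """
    rows = []
    recs = [sv.record if hasattr(sv, "record") else sv for sv in svs]
    for gene in genes:
        for r in recs:
            for chrom, pos in r.breakpoints():
                if chrom != gene.chrom:
                    continue
                pos0 = pos - 1
                if gene.start <= pos0 < gene.end:
                    rows.append((r.sample_id, gene.gene, "sv_within"))
                elif gene.start - pad <= pos0 < gene.end + pad:
                    rows.append((r.sample_id, gene.gene, "sv_close"))
        for st in cna_states:
            seg = st.segment
            if seg.chrom != gene.chrom:
                continue
            if min(seg.end, gene.end) > max(seg.start, gene.start):
                if st.state == "amplification":
                    rows.append((seg.sample_id, gene.gene, "amp"))
                elif st.state == "homozygous_deletion":
                    rows.append((seg.sample_id, gene.gene, "homdel"))
        for v in small_variants:
            if v.consequence not in _CODING_CONSEQUENCES or v.chrom != gene.chrom:
                continue
            if gene.start <= v.pos - 1 < gene.end:
                rows.append((v.sample_id, gene.gene, "coding_snv_indel"))
    df = pd.DataFrame(sorted(set(rows)), columns=["sample_id", "gene", "hit_type"])
    return df


def sv_id(record: SvRecord) -> str:
    """Canonical identifier used to link SVs to complex-event support lists."""
    return (f"{record.sample_id}:{record.chrom1}:{record.pos1}-"
            f"{record.chrom2}:{record.pos2}:{record.svclass}")


def complex_sv_fraction(svs: Sequence, events: Sequence[ComplexEvent],
                        ) -> tuple[dict[str, float | None], float | None]:
    """Fraction of SVs with a breakpoint inside any complex-event interval of
    their sample (or listed among the event's supporting SV ids)."""
    recs = [sv.record if hasattr(sv, "record") else sv for sv in svs]
    by_sample: dict[str, list[SvRecord]] = {}
    for r in recs:
        by_sample.setdefault(r.sample_id, []).append(r)
    ev_by_sample: dict[str, list[ComplexEvent]] = {}
    for e in events:
        ev_by_sample.setdefault(e.sample_id, []).append(e)
    per_sample: dict[str, float | None] = {}
    tot_complex = tot_all = 0
    for sample, recs_s in by_sample.items():
        evs = ev_by_sample.get(sample, [])
        ids = {i for e in evs for i in e.sv_ids}
        n_complex = 0
        for r in recs_s:
            key = sv_id(r)
            inside = any(
                iv[0] == chrom and iv[1] <= pos - 1 < iv[2]
                for e in evs for iv in e.intervals
                for chrom, pos in r.breakpoints())
            if inside or key in ids:
                n_complex += 1
        per_sample[sample] = n_complex / len(recs_s) if recs_s else None
        tot_complex += n_complex
        tot_all += len(recs_s)
    cohort = tot_complex / tot_all if tot_all else None
    return per_sample, cohort


def read_complex_events(path) -> list[ComplexEvent]:
    """Adapter for externally produced complex-rearrangement calls.

    TSV columns: sample_id, event_class, intervals ("chrom:start-end[;...]",
    0-based half-open), source, optional sv_ids (";"-separated).
    """
    df = pd.read_csv(path, sep="\t")
    events = []
    for row in df.itertuples(index=False):
        intervals = []
        for token in str(row.intervals).split(";"):
            chrom, span = token.rsplit(":", 1)
            start, end = span.split("-")
            intervals.append((chrom, int(start), int(end)))
        sv_ids = tuple(str(getattr(row, "sv_ids", "")).split(";")) \
            if getattr(row, "sv_ids", "") not in ("", "nan") else ()
        events.append(ComplexEvent(sample_id=str(row.sample_id),
                                   event_class=str(row.event_class),
                                   intervals=tuple(intervals),
                                   source=str(getattr(row, "source", "")),
                                   sv_ids=sv_ids))
    return events


def write_complex_events(events: Sequence[ComplexEvent], path) -> None:
    rows = [{
        "sample_id": e.sample_id, "event_class": e.event_class,
        "intervals": ";".join(f"{c}:{s}-{t}" for c, s, t in e.intervals),
        "source": e.source, "sv_ids": ";".join(e.sv_ids),
    } for e in events]
    pd.DataFrame(rows, columns=["sample_id", "event_class", "intervals",
                                "source", "sv_ids"]).to_csv(path, sep="\t", index=False)


def genome_density(events: Sequence[ComplexEvent],
                   chromosome_lengths: Mapping[str, int],
                   bin_size: int = 1_000_000) -> pd.DataFrame:
    """Per-class counts of events intersecting fixed genome bins.

    Returns a long-format frame (event_class, chrom, bin_start, count).
    """
    counts: dict[tuple[str, str, int], int] = {}
    for ev in events:
        seen: set[tuple[str, str, int]] = set()
        for chrom, start, end in ev.intervals:
            clen = chromosome_lengths.get(chrom)
            if clen is None:
                continue
            b0 = start // bin_size
            b1 = min((end - 1) // bin_size, (clen - 1) // bin_size)
            for b in range(b0, b1 + 1):
                seen.add((ev.event_class, chrom, b * bin_size))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    rows = [{"event_class": c, "chrom": ch, "bin_start": b, "count": n}
            for (c, ch, b), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["event_class", "chrom", "bin_start", "count"])
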