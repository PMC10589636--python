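"""Multi-caller structural-variant consensus.

Per-caller call sets are merged by collapsing breakpoint pairs that agree in
class and lie within a fixed window (default 500 bp) at both ends.  A merged
component is kept when it is supported by at least ``min_callers`` distinct
callers and at least one supporting record passed its caller's filters;
insertions, which only one caller reports reliably, are exempted from the
multi-caller requirement for that designated caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median
from typing import Mapping, Sequence

from .variant_io import SvRecord

log = logging.getLogger(__name__)


def match_breakpoint_pairs(a: SvRecord, b: SvRecord, window: int = 500) -> bool:
    """True iff two same-sample SVs agree in class/chromosomes and both
    breakpoints lie within ``window`` bases (inclusive)."""
    return (a.svclass == b.svclass
            and a.chrom1 == b.chrom1 and a.chrom2 == b.chrom2
            and abs(a.pos1 - b.pos1) <= window
            and abs(a.pos2 - b.pos2) <= window)


@dataclass(frozen=True)
class ConsensusSv:
    """A merged SV with the callers that support it."""

    record: SvRecord
    callers: tuple[str, ...]
    n_records: int
    pass_any: bool

    @property
    def sample_id(self) -> str:
        return self.record.sample_id


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _components(records: list[SvRecord], window: int) -> list[list[int]]:
    """Connected components of the breakpoint-match relation."""
    n = len(records)
    uf = _UnionFind(n)
    order = sorted(range(n), key=lambda i: (records[i].chrom1, records[i].chrom2,
                                            records[i].svclass, records[i].pos1))
    for ii, i in enumerate(order):
        ri = records[i]
        for j in order[ii + 1:]:
            rj = records[j]
            if (rj.chrom1, rj.chrom2, rj.svclass) != (ri.chrom1, ri.chrom2, ri.svclass):
                break
            if rj.pos1 - ri.pos1 > window:
                break
            if abs(rj.pos2 - ri.pos2) <= window:
                uf.union(i, j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)
    return list(comps.values())


def _dedup_within_caller(records: Sequence[SvRecord], window: int) -> list[SvRecord]:
    """Collapse within-caller duplicates, preferring PASS then lowest pos1."""
    recs = list(records)
    out = []
    for comp in _components(recs, window):
        members = sorted((recs[i] for i in comp),
                         key=lambda r: (not r.pass_filter, r.pos1, r.pos2))
        out.append(members[0])
    return out


def consensus_merge(callsets: Mapping[str, Sequence[SvRecord]],
                    min_callers: int = 2, window: int = 500,
                    insertion_exception: str | None = None) -> list[ConsensusSv]:
    """Merge per-caller call sets into one consensus set.

    Matching components are built jointly across callers (the relation may
    chain); a component is emitted when it spans >= ``min_callers`` distinct
    callers and has at least one PASS record.  INS components supported only
    by ``insertion_exception`` are kept with single-caller support.
    Representative coordinates come from the first PASS record under the
    deterministic (caller, pos1, pos2) order.
    """
    # group by sample; caller order fixed alphabetically for determinism
    by_sample: dict[str, list[SvRecord]] = {}
    for caller in sorted(callsets):
        tagged = [r if r.caller == caller else
                  SvRecord(r.sample_id, r.chrom1, r.pos1, r.chrom2, r.pos2,
                           r.svclass, caller=caller, pass_filter=r.pass_filter)
                  for r in callsets[caller]]
        for rec in _dedup_within_caller(tagged, window):
            by_sample.setdefault(rec.sample_id, []).append(rec)

    out: list[ConsensusSv] = []
    for sample in sorted(by_sample):
        recs = sorted(by_sample[sample],
                      key=lambda r: (r.caller, r.chrom1, r.chrom2, r.svclass, r.pos1, r.pos2))
        for comp in _components(recs, window):
            members = sorted((recs[i] for i in comp),
                             key=lambda r: (r.caller, r.pos1, r.pos2))
            callers = tuple(sorted({m.caller for m in members}))
            pass_any = any(m.pass_filter for m in members)
            is_ins_exception = (members[0].svclass == "INS"
                                and insertion_exception is not None
                                and callers == (insertion_exception,))
            if not pass_any:
                continue
            if len(callers) < min_callers and not is_ins_exception:
                continue
            rep = next(m for m in members if m.pass_filter)
            out.append(ConsensusSv(record=rep, callers=callers,
                                   n_records=len(members), pass_any=pass_any))
    out.sort(key=lambda c: (c.sample_id, c.record.chrom1, c.record.pos1,
                            c.record.chrom2, c.record.pos2, c.record.svclass))
    return out


def qc_exclude_hypermutated(per_sample_sv_counts: Mapping[str, int],
                            fold: float = 5.0) -> tuple[list[str], float]:
    """Iteratively flag samples whose SV count exceeds ``fold`` times the
    median count of the retained samples.

    Returns (sorted flagged sample ids, final reference median).  Requires
    at least 3 samples to be meaningful; with fewer, nothing is flagged.
    """
    counts = dict(per_sample_sv_counts)
    if len(counts) < 3:
        return [], float(median(counts.values())) if counts else 0.0
    excluded: set[str] = set()
    while True:
        retained = {s: c for s, c in counts.items() if s not in excluded}
        ref = float(median(retained.values()))
        newly = {s for s, c in retained.items() if c > fold * ref}
        if not newly:
            return sorted(excluded), ref
        excluded |= newly
        if len(counts) - len(excluded) == 0:  # degenerate: refuse to empty cohort
            log.warning("qc_exclude_hypermutated flagged every sample; keeping none excluded")
            return sorted(excluded), ref
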