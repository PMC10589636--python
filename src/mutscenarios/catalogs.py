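"""Mutation-catalog construction: SBS-96, ID-83 and SV-38 feature schemes.

Each scheme maps a variant to one of a fixed, canonically ordered set of
channels; a catalog is the samples x channels count matrix.

SBS-96: pyrimidine-normalized single-base substitutions in trinucleotide
context (6 substitution types x 16 contexts).  ID-83: the COSMIC v3 indel
scheme (1-bp events by homopolymer length, longer events by length x repeat
count, microhomology deletions by length x homology length).  SV-38:
rearrangement type x six size bins x clustered status (plus translocations
x clustered status).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_io import IndelRecord, SnvRecord, SvRecord, ValidationError

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# canonical channel orders
# ---------------------------------------------------------------------------

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

SBS96_CHANNELS: tuple[str, ...] = tuple(
    f"{l}[{sub}]{r}" for sub in SUBSTITUTIONS for l in "ACGT" for r in "ACGT"
)


def _id83_channels() -> tuple[str, ...]:
    ch: list[str] = []
    for base in "CT":  # 1-bp deletions by homopolymer length 1..6+ (encoded 0..5)
        ch += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in "CT":  # 1-bp insertions by existing copies 0..5+
        ch += [f"1:Ins:{base}:{i}" for i in range(6)]
    for length in (2, 3, 4, 5):  # >=2-bp deletions in repeats, unit copies 1..6+ (0..5)
        ch += [f"{length}:Del:R:{i}" for i in range(6)]
    for length in (2, 3, 4, 5):  # >=2-bp insertions, existing copies 0..5+
        ch += [f"{length}:Ins:R:{i}" for i in range(6)]
    for length, max_mh in ((2, 1), (3, 2), (4, 3), (5, 5)):  # microhomology deletions
        ch += [f"{length}:Del:M:{i}" for i in range(1, max_mh + 1)]
    return tuple(ch)


ID83_CHANNELS: tuple[str, ...] = _id83_channels()
assert len(ID83_CHANNELS) == 83

SV_SIZE_BINS = ("<1kb", "1-10kb", "10-100kb", "100kb-1Mb", "1-10Mb", ">10Mb")
_SV_SIZE_EDGES = (1_000, 10_000, 100_000, 1_000_000, 10_000_000)

SV38_CHANNELS: tuple[str, ...] = tuple(
    f"{cl}:{typ}:{sz}"
    for cl in ("nonclust", "clust")
    for typ in ("DEL", "DUP", "INV")
    for sz in SV_SIZE_BINS
) + ("nonclust:TRA", "clust:TRA")
assert len(SV38_CHANNELS) == 38

SCHEMES: dict[str, tuple[str, ...]] = {
    "SBS96": SBS96_CHANNELS,
    "ID83": ID83_CHANNELS,
    "SV38": SV38_CHANNELS,
}


# ---------------------------------------------------------------------------
# reference access helper
# ---------------------------------------------------------------------------

def fetch_seq(reference, chrom: str, start0: int, end0: int) -> str:
    """Fetch [start0, end0) uppercase sequence from a GenomeSequence-like
    object (``.fetch``) or a pyfaidx.Fasta."""
    if hasattr(reference, "fetch"):
        return reference.fetch(chrom, start0, end0)
    return str(reference[chrom][start0:end0]).upper()


def contig_length(reference, chrom: str) -> int:
    if hasattr(reference, "lengths"):
        return reference.lengths[chrom]
    return len(reference[chrom])


class ReferenceMismatch(ValidationError):
    """Reference base at a variant position disagrees with the record."""


# ---------------------------------------------------------------------------
# SBS-96
# ---------------------------------------------------------------------------

def classify_sbs(snv: SnvRecord, reference) -> str:
    """SBS-96 channel "X[R>A]Y" with pyrimidine-normalized reference base."""
    pos0 = snv.pos - 1
    if pos0 < 1 or pos0 + 1 >= contig_length(reference, snv.chrom):
        raise ValueError(f"SNV at {snv.chrom}:{snv.pos} lacks a flanking base")
    tri = fetch_seq(reference, snv.chrom, pos0 - 1, pos0 + 2)
    if tri[1] != snv.ref:
        raise ReferenceMismatch(
            f"{snv.chrom}:{snv.pos} reference base {tri[1]} != record ref {snv.ref}")
    if snv.ref in "CT":
        left, right, ref, alt = tri[0], tri[2], snv.ref, snv.alt
    else:  # purine: reverse-complement substitution together with context
        rc = revcomp(tri)
        left, right, ref, alt = rc[0], rc[2], COMPLEMENT[snv.ref], COMPLEMENT[snv.alt]
    return f"{left}[{ref}>{alt}]{right}"


# ---------------------------------------------------------------------------
# ID-83
# ---------------------------------------------------------------------------

def _run_length(reference, chrom: str, pos0: int, base: str,
                lo: int, hi: int) -> tuple[int, int]:
    """Count contiguous ``base`` copies left of pos0 (exclusive) and right of
    pos0 (inclusive) within contig bounds [lo, hi)."""
    left = 0
    i = pos0 - 1
    while i >= lo and fetch_seq(reference, chrom, i, i + 1) == base:
        left += 1
        i -= 1
    right = 0
    i = pos0
    while i < hi and fetch_seq(reference, chrom, i, i + 1) == base:
        right += 1
        i += 1
    return left, right


def _unit_copies(reference, chrom: str, start0: int, unit: str,
                 lo: int, hi: int, max_count: int = 12) -> int:
    """Number of consecutive copies of ``unit`` in the reference around the
    copy occupying [start0, start0+len(unit)), counted in both directions."""
    L = len(unit)
    count = 1
    i = start0 + L
    while i + L <= hi and count < max_count and fetch_seq(reference, chrom, i, i + L) == unit:
        count += 1
        i += L
    i = start0 - L
    while i >= lo and count < max_count and fetch_seq(reference, chrom, i, i + L) == unit:
        count += 1
        i -= L
    return count


def classify_indel(indel: IndelRecord, reference,
                   flank_5p: int = 60, flank_3p: int = 10) -> str:
    """COSMIC ID-83 channel for an anchored indel.

    1-bp events are complemented to a C/T reference base; repeat counting is
    done on the + strand in both directions; an event that is not a
    whole-number repeat of its flanks is tested for microhomology (>=2-bp
    deletions only).  Context windows truncated by contig edges are used as
    available and logged.
    """
    change = indel.change
    L = len(change)
    event0 = indel.pos  # 0-based start of the changed bases (pos is the 1-based anchor)
    hi = contig_length(reference, indel.chrom)
    lo = 0
    if event0 - flank_5p < 0 or event0 + L + flank_3p > hi:
        log.info("indel %s:%d context window truncated by contig edge",
                 indel.chrom, indel.pos)
    if indel.is_deletion:
        observed = fetch_seq(reference, indel.chrom, event0, event0 + L)
        if observed != change:
            raise ReferenceMismatch(
                f"{indel.chrom}:{indel.pos} deleted sequence {change} != reference {observed}")

    if L == 1:
        base = change
        if indel.is_deletion:
            left, right = _run_length(reference, indel.chrom, event0, base, lo, hi)
            run = left + right  # includes the deleted base itself
            bin_idx = min(run, 6) - 1
        else:
            left, right = _run_length(reference, indel.chrom, event0, base, lo, hi)
            run = left + right  # existing copies adjacent to the insertion point
            bin_idx = min(run, 5)
        norm = base if base in "CT" else COMPLEMENT[base]
        kind = "Del" if indel.is_deletion else "Ins"
        return f"1:{kind}:{norm}:{bin_idx}"

    len_label = min(L, 5)
    if indel.is_deletion:
        copies = _unit_copies(reference, indel.chrom, event0, change, lo, hi)
        if copies >= 2:
            return f"{len_label}:Del:R:{min(copies, 6) - 1}"
        # microhomology: shared prefix with the 3' flank or suffix with the 5' flank
        flank3 = fetch_seq(reference, indel.chrom, event0 + L, min(event0 + 2 * L, hi))
        flank5 = fetch_seq(reference, indel.chrom, max(event0 - L, lo), event0)
        mh = 0
        for k in range(min(L - 1, len(flank3)), 0, -1):
            if change[:k] == flank3[:k]:
                mh = k
                break
        for k in range(min(L - 1, len(flank5)), 0, -1):
            if change[-k:] == flank5[-k:]:
                mh = max(mh, k)
                break
        if mh >= 1:
            max_mh = 5 if len_label == 5 else len_label - 1
            return f"{len_label}:Del:M:{min(mh, max_mh)}"
        return f"{len_label}:Del:R:0"
    # insertion: count existing copies of the inserted unit adjacent in the reference
    copies = 0
    i = event0
    while i + L <= hi and copies < 12 and fetch_seq(reference, indel.chrom, i, i + L) == change:
        copies += 1
        i += L
    i = event0 - L
    while i >= lo and copies < 12 and fetch_seq(reference, indel.chrom, i, i + L) == change:
        copies += 1
        i -= L
    return f"{len_label}:Ins:R:{min(copies, 5)}"


# ---------------------------------------------------------------------------
# SV-38
# ---------------------------------------------------------------------------

def flag_clustered_sv_breakpoints(svs: Sequence[SvRecord], window: int = 1_000_000,
                                  min_breakpoints: int = 10) -> list[bool]:
    """Per-record clustered flag for one sample's SVs.

    Each SV contributes both breakpoints (one per chromosome for TRA).  A
    breakpoint is clustered when some interval of ``window`` bases containing
    it holds >= ``min_breakpoints`` of the sample's breakpoints; an SV is
    clustered iff at least one of its breakpoints is.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}  # chrom -> [(pos, sv index)]
    for idx, sv in enumerate(svs):
        for chrom, pos in sv.breakpoints():
            by_chrom.setdefault(chrom, []).append((pos, idx))
    flags = [False] * len(svs)
    for chrom, bps in by_chrom.items():
        bps.sort()
        pos = [p for p, _ in bps]
        n = len(pos)
        clustered = [False] * n
        j = 0
        for i in range(n):
            if j < i:
                j = i
            while j + 1 < n and pos[j + 1] - pos[i] <= window:
                j += 1
            if j - i + 1 >= min_breakpoints:
                for t in range(i, j + 1):
                    clustered[t] = True
        for (p, idx), cl in zip(bps, clustered):
            if cl:
                flags[idx] = True
    return flags


def sv_size_bin(size: int) -> str:
    """Half-open size bins with inclusive lower edges at 1 kb/10 kb/100 kb/1 Mb/10 Mb."""
    for edge, label in zip(_SV_SIZE_EDGES, SV_SIZE_BINS):
        if size < edge:
            return label
    return SV_SIZE_BINS[-1]


def classify_sv(sv: SvRecord, clustered: bool) -> str | None:
    """SV-38 channel label; None for insertions (excluded from the catalog)."""
    prefix = "clust" if clustered else "nonclust"
    if sv.svclass == "INS":
        return None
    if sv.svclass == "TRA":
        return f"{prefix}:TRA"
    return f"{prefix}:{sv.svclass}:{sv_size_bin(sv.size)}"


# ---------------------------------------------------------------------------
# catalog assembly
# ---------------------------------------------------------------------------

@dataclass
class MutationCatalog:
    """Samples x feature-channel count matrix under a named scheme."""

    scheme: str
    counts: pd.DataFrame  # index: samples, columns: canonical channel order

    def __post_init__(self) -> None:
        channels = SCHEMES.get(self.scheme)
        if channels is None:
            raise ValueError(f"unknown catalog scheme {self.scheme!r}")
        self.counts = self.counts.reindex(columns=list(channels), fill_value=0)

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return SCHEMES[self.scheme]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def to_tsv(self, path: str | Path) -> None:
        """Write channels as rows (canonical order), samples as columns."""
        self.counts.T.rename_axis("channel").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, scheme: str) -> "MutationCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(scheme=scheme, counts=df.T)


def build_catalog(variants: Iterable, scheme: str, reference=None,
                  samples: Sequence[str] | None = None,
                  clustered_window: int = 1_000_000,
                  clustered_min_breakpoints: int = 10) -> MutationCatalog:
    """Classify variants under ``scheme`` and count them per sample.

    ``samples`` fixes the row set (zero-variant samples keep all-zero rows);
    otherwise rows are the samples observed in the input, sorted.
    """
    channels = SCHEMES.get(scheme)
    if channels is None:
        raise ValueError(f"unknown catalog scheme {scheme!r}")
    variants = list(variants)
    counts: dict[str, dict[str, int]] = {}
    skipped = 0

    if scheme == "SV38":
        recs = [v.record if hasattr(v, "record") else v for v in variants]
        by_sample: dict[str, list[SvRecord]] = {}
        for r in recs:
            by_sample.setdefault(r.sample_id, []).append(r)
        for sample, svs in by_sample.items():
            flags = flag_clustered_sv_breakpoints(svs, clustered_window,
                                                  clustered_min_breakpoints)
            row = counts.setdefault(sample, {})
            for sv, cl in zip(svs, flags):
                label = classify_sv(sv, cl)
                if label is None:
                    skipped += 1
                    continue
                row[label] = row.get(label, 0) + 1
    else:
        if reference is None:
            raise ValueError(f"scheme {scheme} requires a reference sequence")
        classify = classify_sbs if scheme == "SBS96" else classify_indel
        for v in variants:
            try:
                label = classify(v, reference)
            except ValueError as exc:
                if isinstance(exc, ReferenceMismatch):
                    raise
                skipped += 1
                continue
            row = counts.setdefault(v.sample_id, {})
            row[label] = row.get(label, 0) + 1

    if skipped:
        log.info("build_catalog(%s): %d variants not classifiable", scheme, skipped)
    index = list(samples) if samples is not None else sorted(counts)
    mat = pd.DataFrame(0, index=pd.Index(index, name="sample"),
                       columns=list(channels), dtype=np.int64)
    for sample, row in counts.items():
        if sample not in mat.index:
            continue
        for label, c in row.items():
            mat.loc[sample, label] = c
    return MutationCatalog(scheme=scheme, counts=mat)
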