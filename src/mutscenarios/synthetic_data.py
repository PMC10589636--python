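"""Synthetic cohorts with known ground truth.

Everything the pipeline consumes can be generated here: a small reference
genome seeded with homopolymers and tandem repeats (so indel channels are
reachable), context-consistent SNV and indel placement under planted
signature exposures, jittered multi-caller SV call sets with planted
breakpoint clusters, CNA profiles realizing requested states, planted
kataegis loci, CCF structure with clonal/subclonal exposure switches, and
three risk-group-like profiles for end-to-end scenario recovery.  The
generated cohort stands in for the consortium WGS call sets the real
analysis starts from; it is synthetic by construction and labelled as such.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import variant_io
from .catalogs import (COMPLEMENT, ID83_CHANNELS, SBS96_CHANNELS, SV38_CHANNELS,
                       classify_indel, revcomp)
from .rearrangement_topography import ComplexEvent, write_complex_events
from .signature_inference import SignatureMatrix
from .variant_io import (CnaSegment, IndelRecord, SampleProfile, SnvRecord,
                         SvRecord)

log = logging.getLogger(__name__)

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def _child_rng(seed: int, *stream: int) -> np.random.Generator:
    """Named substream: reproducible under partial re-runs."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *stream]))


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------

class GenomeSequence:
    """Small in-memory genome with pyfaidx-compatible FASTA round-trip."""

    def __init__(self, sequences: dict[str, str]) -> None:
        self.sequences = {c: s.upper() for c, s in sequences.items()}
        self.lengths = {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        return self.sequences[chrom][max(start0, 0):end0]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        from pyfaidx import Fasta

        fa = Fasta(str(path), rebuild=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})


DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 5_000_000, "chr2": 4_000_000, "chr3": 4_000_000, "chr4": 3_000_000,
    "chr5": 3_000_000, "chr6": 2_000_000, "chr7": 2_000_000, "chr8": 12_000_000,
}


def make_reference(chrom_lengths: Mapping[str, int] | None = None,
                   homopolymer_density: float = 0.5,
                   repeat_density: float = 0.2,
                   seed: int = 0) -> tuple[GenomeSequence, dict]:
    """Random genome with planted homopolymers (runs 4-9) and tandem repeats
    (units 2-5 bases, 2-6 copies); densities are events per kb.

    Returns (genome, composition report).  Densities that cannot fit the
    requested length raise a parameter error.
    """
    lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    if min(lengths.values()) < 10_000:
        raise ValueError("chromosomes must be at least 10 kb")
    rng = _child_rng(seed, 0)
    report = {"homopolymers": 0, "tandem_repeats": 0, "length": sum(lengths.values())}
    seqs: dict[str, str] = {}
    for chrom in lengths:
        L = lengths[chrom]
        arr = _BASE_ARR[rng.integers(0, 4, size=L)].copy()
        n_homo = int(L / 1000 * homopolymer_density)
        n_rep = int(L / 1000 * repeat_density)
        if (n_homo * 9 + n_rep * 30) > L // 2:
            raise ValueError("requested homopolymer/repeat densities infeasible for length")
        for _ in range(n_homo):
            run = int(rng.integers(4, 10))
            start = int(rng.integers(0, L - run))
            arr[start:start + run] = _BASE_ARR[rng.integers(0, 4)]
            report["homopolymers"] += 1
        for _ in range(n_rep):
            unit_len = int(rng.integers(2, 6))
            copies = int(rng.integers(2, 7))
            start = int(rng.integers(0, L - unit_len * copies))
            unit = _BASE_ARR[rng.integers(0, 4, size=unit_len)]
            arr[start:start + unit_len * copies] = np.tile(unit, copies)
            report["tandem_repeats"] += 1
        seqs[chrom] = arr.tobytes().decode()
    return GenomeSequence(seqs), report


# ---------------------------------------------------------------------------
# SNV placement
# ---------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i


def build_context_index(genome: GenomeSequence) -> dict[str, list]:
    """Map each pyrimidine-centered trinucleotide to its genomic positions.

    Returns {context (e.g. "ACA"): [(chrom, positions array (1-based),
    purine_strand bool), ...]}; purine_strand means the reference center base
    is the purine complement and substitutions must be reverse-complemented.
    """
    parts: dict[str, list] = {}
    chrom_names = list(genome.sequences)
    for c_i, chrom in enumerate(chrom_names):
        seq = genome.sequences[chrom]
        codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        tri = codes[:-2].astype(np.int32) * 16 + codes[1:-1] * 4 + codes[2:]
        order = np.argsort(tri, kind="stable")
        sorted_tri = tri[order]
        bounds = np.searchsorted(sorted_tri, np.arange(65))
        for code in range(64):
            lo, hi = bounds[code], bounds[code + 1]
            if lo == hi:
                continue
            pos = order[lo:hi] + 2  # 1-based center position
            ctx = "ACGT"[code // 16] + "ACGT"[(code // 4) % 4] + "ACGT"[code % 4]
            purine = ctx[1] not in "CT"
            key = revcomp(ctx) if purine else ctx
            parts.setdefault(key, []).append((c_i, pos, purine))
    index: dict[str, dict] = {}
    for ctx, chunks in parts.items():
        pos = np.concatenate([p for _, p, _ in chunks])
        chrom_idx = np.concatenate([np.full(len(p), c_i, dtype=np.int32)
                                    for c_i, p, _ in chunks])
        purine = np.concatenate([np.full(len(p), pur, dtype=bool)
                                 for _, p, pur in chunks])
        index[ctx] = {"chroms": chrom_names, "pos": pos.astype(np.int64),
                      "chrom_idx": chrom_idx, "purine": purine}
    return index


def _channel_context(channel: str) -> tuple[str, str, str]:
    """("ACA", "C", "A") from "A[C>A]A"."""
    left, rest = channel[0], channel[2:]
    ref, alt, right = rest[0], rest[2], rest[4]
    return left + ref + right, ref, alt


def simulate_snvs(genome: GenomeSequence, signatures: SignatureMatrix,
                  exposures: pd.DataFrame, seed: int = 0,
                  context_index: dict | None = None,
                  ) -> tuple[list[SnvRecord], pd.DataFrame]:
    """Place SNVs for each sample by drawing channel counts from a
    multinomial over W @ e and choosing uniform positions with the matching
    trinucleotide context (positions unique per sample).

    ``exposures``: samples x signature absolute counts.  Returns (records,
    per-sample drawn channel counts) — the truth catalog.
    """
    if list(exposures.columns) != signatures.names:
        exposures = exposures[signatures.names]
    W = signatures.W.to_numpy(dtype=float)
    index = context_index if context_index is not None else build_context_index(genome)
    pools: dict[str, tuple[np.ndarray, list]] = {}
    records: list[SnvRecord] = []
    truth = pd.DataFrame(0, index=exposures.index, columns=list(SBS96_CHANNELS))
    for s_i, (sample, e) in enumerate(exposures.iterrows()):
        rng = _child_rng(seed, 1, s_i)
        ev = e.to_numpy(dtype=float)
        total = int(round(ev.sum()))
        if total == 0:
            continue
        p = W @ (ev / ev.sum())
        p = p / p.sum()
        counts = rng.multinomial(total, p)
        # group channels by context: channels sharing a trinucleotide pool
        # must draw positions jointly to keep them unique within the sample
        by_ctx: dict[str, list[tuple[str, int, str, str]]] = {}
        for ch_i, n in enumerate(counts):
            if n == 0:
                continue
            channel = SBS96_CHANNELS[ch_i]
            ctx, ref, alt = _channel_context(channel)
            if ctx not in index:
                raise ValueError(f"no eligible reference positions for channel {channel}")
            by_ctx.setdefault(ctx, []).append((channel, int(n), ref, alt))
        for ctx, wanted in by_ctx.items():
            entry = index[ctx]
            allpos = entry["pos"]
            n_total = sum(n for _, n, _, _ in wanted)
            n_eff = min(n_total, len(allpos))
            if n_eff < n_total:
                log.warning("context %s: only %d eligible positions for %d draws",
                            ctx, len(allpos), n_total)
            pick = rng.choice(len(allpos), size=n_eff, replace=False)
            offset = 0
            for channel, n, ref, alt in wanted:
                take = pick[offset:offset + n]
                offset += len(take)
                truth.loc[sample, channel] += len(take)
                for t in take:
                    chrom = entry["chroms"][int(entry["chrom_idx"][t])]
                    pos = int(allpos[t])
                    if entry["purine"][t]:
                        records.append(SnvRecord(sample, chrom, pos,
                                                 COMPLEMENT[ref], COMPLEMENT[alt]))
                    else:
                        records.append(SnvRecord(sample, chrom, pos, ref, alt))
    # deduplicate within sample (distinct channels can collide only never: contexts
    # are disjoint, but repeated draws across channels cannot share positions)
    return records, truth


# ---------------------------------------------------------------------------
# indel placement (rejection-sampled eligible sites)
# ---------------------------------------------------------------------------

def build_indel_pools(genome: GenomeSequence, n_proposals: int = 30_000,
                      seed: int = 0) -> dict[str, list[tuple[str, int, str, str]]]:
    """Propose random candidate indels, classify each, and pool by ID-83
    channel.  Candidates are anchored VCF-style (chrom, pos, ref, alt)."""
    rng = _child_rng(seed, 2)
    chroms = list(genome.sequences)
    weights = np.array([genome.lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    pools: dict[str, list[tuple[str, int, str, str]]] = {}
    for _ in range(n_proposals):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        L = int(rng.choice([1, 1, 1, 2, 3, 4, 5]))
        clen = genome.lengths[chrom]
        anchor0 = int(rng.integers(100, clen - 100 - L))
        anchor = genome.fetch(chrom, anchor0, anchor0 + 1)
        if rng.random() < 0.5:  # deletion of the next L bases
            deleted = genome.fetch(chrom, anchor0 + 1, anchor0 + 1 + L)
            ref, alt = anchor + deleted, anchor
        else:  # insertion after the anchor: copy the following bases or random
            if rng.random() < 0.5:
                inserted = genome.fetch(chrom, anchor0 + 1, anchor0 + 1 + L)
            else:
                inserted = "".join("ACGT"[i] for i in rng.integers(0, 4, size=L))
            ref, alt = anchor, anchor + inserted
        try:
            rec = IndelRecord("pool", chrom, anchor0 + 1, ref, alt)
            channel = classify_indel(rec, genome)
        except ValueError:
            continue
        pools.setdefault(channel, []).append((chrom, anchor0 + 1, ref, alt))
    return pools


def simulate_indels(genome: GenomeSequence, exposures: pd.DataFrame,
                    seed: int = 0, pools: dict | None = None,
                    ) -> tuple[list[IndelRecord], pd.DataFrame]:
    """Place indels per sample by drawing ID-83 channel counts from the
    exposure-weighted signature mix and sampling eligible sites.

    ``exposures``: samples x channels expected counts (already W @ e).
    A requested channel with no eligible site raises a parameter error.
    """
    pools = pools if pools is not None else build_indel_pools(genome, seed=seed)
    records: list[IndelRecord] = []
    truth = pd.DataFrame(0, index=exposures.index, columns=list(ID83_CHANNELS))
    for s_i, (sample, e) in enumerate(exposures.iterrows()):
        rng = _child_rng(seed, 3, s_i)
        ev = e.reindex(list(ID83_CHANNELS)).fillna(0.0).to_numpy(dtype=float)
        total = int(round(ev.sum()))
        if total == 0:
            continue
        counts = rng.multinomial(total, ev / ev.sum())
        for ch_i, n in enumerate(counts):
            if n == 0:
                continue
            channel = ID83_CHANNELS[ch_i]
            pool = pools.get(channel)
            if not pool:
                raise ValueError(f"no eligible reference site for indel channel {channel}")
            pick = rng.choice(len(pool), size=n, replace=n > len(pool))
            truth.loc[sample, channel] += int(n)
            for t in pick:
                chrom, pos, ref, alt = pool[int(t)]
                records.append(IndelRecord(sample, chrom, pos, ref, alt))
    return records, truth


# ---------------------------------------------------------------------------
# SVs, CNA, kataegis
# ---------------------------------------------------------------------------

DEFAULT_CALLERS = ("delly", "novobreak", "svaba")


@dataclass
class SvSimConfig:
    n_background: float = 14.0        # cohort-median-scale SV burden per sample
    class_mix: dict = field(default_factory=lambda: {
        "DEL": 0.35, "DUP": 0.25, "INV": 0.2, "TRA": 0.15, "INS": 0.05})
    size_log10_range: tuple[float, float] = (3.3, 6.5)
    channel_weights: object = None    # optional length-38 SV38 channel law;
                                      # overrides class_mix/size sampling
    caller_dropout: dict = field(default_factory=lambda: {
        "delly": 0.15, "novobreak": 0.2, "svaba": 0.15})
    jitter: int = 150
    pass_prob: float = 0.92


# realized size ranges per SV38 size bin (half-open, bases)
_SIZE_BIN_SPAN = {
    "<1kb": (300, 1_000), "1-10kb": (1_000, 10_000),
    "10-100kb": (10_000, 100_000), "100kb-1Mb": (100_000, 1_000_000),
    "1-10Mb": (1_000_000, 10_000_000), ">10Mb": (10_000_000, 20_000_000),
}


def _sv_from_channel(sample: str, channel: str,
                     chrom_lengths: Mapping[str, int],
                     rng: np.random.Generator,
                     dense_window: tuple[str, int, int]) -> SvRecord:
    """Realize one SV drawn as an SV38 channel; clustered channels place at
    least one breakpoint inside the sample's dense window so the clustered
    flag re-emerges from breakpoint density."""
    parts = channel.split(":")
    clustered = parts[0] == "clust"
    svclass = parts[1]
    chroms = list(chrom_lengths)
    if svclass == "TRA":
        if clustered:
            chrom1 = dense_window[0]
            p1 = int(rng.integers(dense_window[1], dense_window[2]))
        else:
            chrom1 = chroms[int(rng.integers(len(chroms)))]
            p1 = int(rng.integers(1000, chrom_lengths[chrom1] - 1000))
        others = [c for c in chroms if c != chrom1]
        chrom2 = others[int(rng.integers(len(others)))]
        p2 = int(rng.integers(1000, chrom_lengths[chrom2] - 1000))
        return SvRecord(sample, chrom1, p1, chrom2, p2, "TRA")
    lo, hi = _SIZE_BIN_SPAN[parts[2]]
    if clustered:
        chrom = dense_window[0]
    else:
        eligible = [c for c in chroms if chrom_lengths[c] >= lo + 2000]
        if not eligible:
            eligible = [max(chroms, key=lambda c: chrom_lengths[c])]
        w = np.array([chrom_lengths[c] for c in eligible], dtype=float)
        chrom = eligible[int(rng.choice(len(eligible), p=w / w.sum()))]
    cap = max(chrom_lengths[chrom] - 2000, 301)
    hi_eff = min(hi, cap)
    lo_eff = min(lo, hi_eff - 1)
    size = int(10 ** rng.uniform(np.log10(lo_eff), np.log10(hi_eff)))
    if clustered:
        p1 = int(rng.integers(dense_window[1], dense_window[2]))
        if p1 + size > chrom_lengths[chrom] - 1000:
            p1 = max(1000, chrom_lengths[chrom] - 1000 - size)
    else:
        p1 = int(rng.integers(1000, max(1001, chrom_lengths[chrom] - size - 1000)))
    return SvRecord(sample, chrom, p1, chrom, p1 + size, svclass)


def _random_sv(sample: str, chrom_lengths: Mapping[str, int],
               rng: np.random.Generator, cfg: SvSimConfig,
               svclass: str | None = None,
               region: tuple[str, int, int] | None = None) -> SvRecord:
    chroms = list(chrom_lengths)
    if svclass is None:
        classes = list(cfg.class_mix)
        svclass = classes[int(rng.choice(len(classes),
                                         p=np.array(list(cfg.class_mix.values()))
                                         / sum(cfg.class_mix.values())))]
    if svclass == "TRA" and region is None:
        c1, c2 = rng.choice(len(chroms), size=2, replace=False)
        p1 = int(rng.integers(1000, chrom_lengths[chroms[c1]] - 1000))
        p2 = int(rng.integers(1000, chrom_lengths[chroms[c2]] - 1000))
        return SvRecord(sample, chroms[c1], p1, chroms[c2], p2, "TRA")
    if region is not None:
        chrom, lo, hi = region
        if svclass == "TRA":
            svclass = "DEL"
        p1 = int(rng.integers(lo + 1, hi - 1000))
        p2 = int(p1 + rng.integers(1000, max(1001, (hi - p1))))
        p2 = min(p2, hi)
    else:
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = int(10 ** rng.uniform(*cfg.size_log10_range))
        size = min(size, chrom_lengths[chrom] - 2000)
        p1 = int(rng.integers(1000, chrom_lengths[chrom] - size - 1))
        p2 = p1 + size
    if svclass == "INS":
        p2 = p1
    return SvRecord(sample, chrom, min(p1, p2), chrom, max(p1, p2), svclass)


def simulate_svs(chrom_lengths: Mapping[str, int],
                 sample_ids: Sequence[str],
                 cfg: SvSimConfig | None = None,
                 planted_clusters: Mapping[str, Sequence[tuple[str, int, int, int]]] | None = None,
                 seed: int = 0,
                 callers: Sequence[str] = DEFAULT_CALLERS,
                 ) -> tuple[dict[str, list[SvRecord]], dict]:
    """Per-caller jittered SV call sets with planted breakpoint clusters.

    ``planted_clusters``: sample -> [(chrom, start, end, n_breakpoints)].
    Returns ({caller: records}, truth with true SVs and cluster regions).
    """
    cfg = cfg or SvSimConfig()
    truth: dict = {"true_svs": {}, "clusters": dict(planted_clusters or {})}
    callsets: dict[str, list[SvRecord]] = {c: [] for c in callers}
    ins_caller = "svaba" if "svaba" in callers else list(callers)[-1]
    for s_i, sample in enumerate(sample_ids):
        rng = _child_rng(seed, 4, s_i)
        true_svs: list[SvRecord] = []
        n_bg = int(rng.poisson(cfg.n_background))
        if cfg.channel_weights is not None:
            from .catalogs import SV38_CHANNELS

            big = max(chrom_lengths, key=lambda c: chrom_lengths[c])
            span = min(1_000_000, chrom_lengths[big] // 3)
            w0 = int(rng.integers(1000, chrom_lengths[big] - span - 1000))
            dense = (big, w0, w0 + span)
            p = np.asarray(cfg.channel_weights, dtype=float)
            counts = rng.multinomial(n_bg, p / p.sum())
            for ch_i, n in enumerate(counts):
                for _ in range(n):
                    true_svs.append(_sv_from_channel(sample, SV38_CHANNELS[ch_i],
                                                     chrom_lengths, rng, dense))
        else:
            for _ in range(n_bg):
                true_svs.append(_random_sv(sample, chrom_lengths, rng, cfg))
        for chrom, lo, hi, n_bp in (planted_clusters or {}).get(sample, []):
            for _ in range((n_bp + 1) // 2):
                true_svs.append(_random_sv(sample, chrom_lengths, rng, cfg,
                                           svclass="DEL", region=(chrom, lo, hi)))
        truth["true_svs"][sample] = [
            (r.chrom1, r.pos1, r.chrom2, r.pos2, r.svclass) for r in true_svs]
        for sv in true_svs:
            eligible = [ins_caller] if sv.svclass == "INS" else list(callers)
            kept = [c for c in eligible
                    if rng.random() >= cfg.caller_dropout.get(c, 0.0)]
            if not kept and eligible:  # every true SV observed by at least one caller
                kept = [eligible[int(rng.integers(len(eligible)))]]
            first_pass = int(rng.integers(len(kept)))
            for c_i, caller in enumerate(kept):
                j1 = int(rng.integers(-cfg.jitter, cfg.jitter + 1))
                j2 = int(rng.integers(-cfg.jitter, cfg.jitter + 1))
                p1, p2 = sv.pos1 + j1, sv.pos2 + j2
                if sv.chrom1 == sv.chrom2:
                    p1, p2 = min(p1, p2), max(p1, p2)
                p1, p2 = max(p1, 1), max(p2, 1)
                passed = True if c_i == first_pass else rng.random() < cfg.pass_prob
                callsets[caller].append(SvRecord(
                    sample, sv.chrom1, p1, sv.chrom2, p2, sv.svclass,
                    caller=caller, pass_filter=passed))
    return callsets, truth


# state -> (cn_major, cn_minor) realizations at diploid baseline
_STATE_CN = {
    "neutral": (1, 1), "gain": (2, 1), "loss": (1, 0),
    "amplification": (9, 1), "homozygous_deletion": (0, 0), "loh": (2, 0),
}


def simulate_cna(chrom_lengths: Mapping[str, int],
                 planted: Mapping[str, Sequence[tuple[str, int, int, str]]],
                 ploidy: float = 2.0, seed: int = 0,
                 ) -> tuple[list[CnaSegment], dict]:
    """Whole-genome diploid baseline with planted state intervals.

    ``planted``: sample -> [(chrom, start, end, state)] with state from
    {gain, loss, amplification, homozygous_deletion, loh}; states are
    realized exactly under the default classification thresholds.
    """
    segments: list[CnaSegment] = []
    truth: dict = {}
    for sample, plants in planted.items():
        truth[sample] = list(plants)
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, state in plants:
            by_chrom.setdefault(chrom, []).append((start, end, state))
        for chrom, length in chrom_lengths.items():
            cursor = 0
            for start, end, state in sorted(by_chrom.get(chrom, [])):
                if start < cursor:
                    raise ValueError(f"overlapping planted CNA states on {chrom}")
                if start > cursor:
                    segments.append(CnaSegment(sample, chrom, cursor, start, 1, 1))
                cn_major, cn_minor = _STATE_CN[state]
                segments.append(CnaSegment(sample, chrom, start, end, cn_major, cn_minor))
                cursor = end
            if cursor < length:
                segments.append(CnaSegment(sample, chrom, cursor, length, 1, 1))
    return segments, truth


def simulate_kataegis(genome: GenomeSequence, sample: str,
                      rng: np.random.Generator, n_snvs: int | None = None,
                      ) -> tuple[list[SnvRecord], tuple[str, int, int]]:
    """One kataegis cluster: >= 6 SNVs spaced < 1 kb on a random chromosome."""
    chroms = list(genome.sequences)
    chrom = chroms[int(rng.integers(len(chroms)))]
    n = int(n_snvs or rng.integers(6, 13))
    start = int(rng.integers(2000, genome.lengths[chrom] - 2000 - n * 999))
    pos = start
    records = []
    while len(records) < n:
        ref = genome.fetch(chrom, pos - 1, pos)
        if ref in "ACGT":
            # APOBEC-like bias toward C>T / C>G on cytosines
            if ref == "C":
                alt = ["T", "G", "A"][int(rng.choice(3, p=[0.5, 0.4, 0.1]))]
            elif ref == "G":
                alt = ["A", "C", "T"][int(rng.choice(3, p=[0.5, 0.4, 0.1]))]
            else:
                alts = [b for b in "ACGT" if b != ref]
                alt = alts[int(rng.integers(3))]
            records.append(SnvRecord(sample, chrom, pos, ref, alt))
        pos += int(rng.integers(50, 999))
    return records, (chrom, records[0].pos, records[-1].pos)


# ---------------------------------------------------------------------------
# bundled synthetic reference signatures
# ---------------------------------------------------------------------------

# indel channels whose eligible sites are abundant in random-plus-planted
# sequence; bundled ID signatures put their mass here
_ID_SUPPORT = (
    [f"1:Del:{b}:{i}" for b in "CT" for i in range(5)]
    + [f"1:Ins:{b}:{i}" for b in "CT" for i in range(4)]
    + [f"{n}:Del:R:0" for n in (2, 3, 4, 5)]
    + [f"{n}:Ins:R:0" for n in (2, 3)]
    + [f"{n}:Del:M:1" for n in (2, 3, 4, 5)]
)

_BUNDLED_SPECS = {
    "SBS96": ("SYN-SBS", 4, None),
    "ID83": ("SYN-ID", 3, _ID_SUPPORT),
    "SV38": ("SYN-SV", 3, None),
}


def bundled_reference_signatures(scheme: str) -> SignatureMatrix:
    """Deterministic synthetic reference signatures for tests and demos.

    Near-orthogonal profiles (each concentrated on its own channel block
    with a small shared floor); these are synthetic stand-ins, not any
    published catalog.
    """
    prefix, k, support = _BUNDLED_SPECS[scheme]
    channels = {"SBS96": SBS96_CHANNELS, "ID83": ID83_CHANNELS,
                "SV38": SV38_CHANNELS}[scheme]
    support = list(support if support is not None else channels)
    rng = np.random.default_rng(20240601)
    blocks = np.array_split(np.arange(len(support)), k)
    W = np.zeros((len(channels), k))
    idx = {c: i for i, c in enumerate(channels)}
    for j, block in enumerate(blocks):
        profile = np.zeros(len(support))
        profile[block] = rng.dirichlet(np.full(len(block), 0.8))
        profile = 0.92 * profile + 0.08 / len(support)
        for s_i, c in enumerate(support):
            W[idx[c], j] = profile[s_i]
    W /= W.sum(axis=0)
    names = [f"{prefix}{j + 1}" for j in range(k)]
    return SignatureMatrix(
        scheme=scheme,
        W=pd.DataFrame(W, index=pd.Index(list(channels)), columns=names))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class GroupProfile:
    """Expected mutational profile of one clinical-risk-like group."""

    name: str
    risk_group: str
    n_snvs: float = 600.0
    sbs_weights: tuple = (0.25, 0.25, 0.25, 0.25)
    n_indels: float = 120.0
    id_weights: tuple = (1 / 3, 1 / 3, 1 / 3)
    n_svs: float = 14.0
    sv_sig_weights: tuple = (1 / 3, 1 / 3, 1 / 3)  # mix over bundled SV38 signatures
    cluster_rate: float = 0.0           # planted clustered-SV regions per sample
    event_rates: dict = field(default_factory=dict)  # class -> per-sample rate
    cna_states: tuple = ()              # (chrom_index, frac_start, frac_end, state)
    kataegis_rate: float = 0.2
    subclonal_switch: tuple | None = None  # (clonal sig idx, subclonal sig idx)
    dirichlet_conc: float = 15.0
    subclonal_fraction: float = 0.25


def default_group_profiles() -> list[GroupProfile]:
    """Three well-separated profiles emulating the high-risk amplified,
    high-risk non-amplified and non-high-risk group structure."""
    return [
        GroupProfile(
            name="HR_MNA", risk_group="HR_MNA",
            n_snvs=800, sbs_weights=(0.62, 0.06, 0.12, 0.20),
            n_indels=150, id_weights=(0.70, 0.15, 0.15),
            n_svs=28, sv_sig_weights=(0.15, 0.20, 0.65), cluster_rate=0.0,
            event_rates={"ecDNA": 1.0},
            cna_states=((0, 0.10, 0.12, "amplification"), (1, 0.55, 0.95, "gain")),
            kataegis_rate=0.8),
        GroupProfile(
            name="HR_nonMNA", risk_group="HR_nonMNA",
            n_snvs=700, sbs_weights=(0.08, 0.62, 0.10, 0.20),
            n_indels=160, id_weights=(0.15, 0.70, 0.15),
            n_svs=35, sv_sig_weights=(0.20, 0.65, 0.15), cluster_rate=0.0,
            event_rates={"CnC": 1.0, "TIC": 1.0},
            cna_states=((2, 0.10, 0.45, "loss"), (3, 0.30, 0.80, "loh"),
                        (4, 0.50, 0.90, "gain")),
            kataegis_rate=0.4, subclonal_switch=(1, 3)),
        GroupProfile(
            name="nonHR", risk_group="nonHR",
            n_snvs=450, sbs_weights=(0.08, 0.08, 0.64, 0.20),
            n_indels=90, id_weights=(0.15, 0.15, 0.70),
            n_svs=8, sv_sig_weights=(0.70, 0.15, 0.15), cluster_rate=0.0,
            event_rates={},
            cna_states=((5, 0.02, 0.98, "gain"),),
            kataegis_rate=0.1),
    ]


@dataclass
class CohortTruth:
    """Ground truth sufficient to score every recovery test."""

    seed: int
    labels: dict[str, str]
    sbs_exposures: pd.DataFrame          # planted absolute exposures (samples x sigs)
    sbs_channel_counts: pd.DataFrame     # channel counts actually drawn
    id_channel_counts: pd.DataFrame
    sv_truth: dict
    planted_events: list
    kataegis_loci: dict[str, list]
    cna_truth: dict
    subclonal_switch_groups: dict[str, tuple | None]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "labels": self.labels,
            "sbs_exposures": self.sbs_exposures.round(6).to_dict(orient="index"),
            "sbs_channel_counts": {s: {c: int(v) for c, v in row.items() if v}
                                   for s, row in
                                   self.sbs_channel_counts.to_dict(orient="index").items()},
            "id_channel_counts": {s: {c: int(v) for c, v in row.items() if v}
                                  for s, row in
                                  self.id_channel_counts.to_dict(orient="index").items()},
            "sv_truth": self.sv_truth,
            "planted_events": self.planted_events,
            "kataegis_loci": self.kataegis_loci,
            "cna_truth": self.cna_truth,
            "subclonal_switch_groups": {k: list(v) if v else None
                                        for k, v in self.subclonal_switch_groups.items()},
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


@dataclass
class Cohort:
    genome: GenomeSequence
    chrom_lengths: dict[str, int]
    samples: list[SampleProfile]
    snvs: list[SnvRecord]
    indels: list[IndelRecord]
    sv_callsets: dict[str, list[SvRecord]]
    cna_segments: list[CnaSegment]
    external_events: list[ComplexEvent]
    truth: CohortTruth

    def snvs_of(self, sample_id: str) -> list[SnvRecord]:
        return [s for s in self.snvs if s.sample_id == sample_id]

    def write(self, outdir: str | Path) -> None:
        """Emit the exact formats the pipeline consumes, plus truth JSON."""
        out = Path(outdir)
        (out / "vcf").mkdir(parents=True, exist_ok=True)
        (out / "sv").mkdir(exist_ok=True)
        self.genome.write_fasta(out / "reference.fa")
        by_sample: dict[str, list] = {s.sample_id: [] for s in self.samples}
        for rec in self.snvs + self.indels:
            by_sample.setdefault(rec.sample_id, []).append(rec)
        for sample, recs in sorted(by_sample.items()):
            variant_io.write_vcf(recs, out / "vcf" / f"{sample}.vcf",
                                 contigs=self.chrom_lengths)
        for caller, recs in sorted(self.sv_callsets.items()):
            variant_io.write_sv_bedpe(recs, out / "sv" / f"{caller}.bedpe")
        variant_io.write_cna_segments(self.cna_segments, out / "cna.tsv")
        variant_io.write_sample_table(self.samples, out / "samples.tsv")
        write_complex_events(self.external_events, out / "events.tsv")
        self.truth.to_json(out / "truth.json")


def _planted_intervals(profile: GroupProfile, chroms: list[str],
                       lengths: Mapping[str, int]) -> list[tuple[str, int, int, str]]:
    plants = []
    for chrom_idx, f0, f1, state in profile.cna_states:
        chrom = chroms[chrom_idx % len(chroms)]
        L = lengths[chrom]
        plants.append((chrom, int(f0 * L), int(f1 * L), state))
    return plants


def simulate_cohort(profiles: Sequence[GroupProfile] | None = None,
                    n_per_group: int = 20, seed: int = 7,
                    chrom_lengths: Mapping[str, int] | None = None,
                    indel_pool_proposals: int = 30_000) -> Cohort:
    """Full synthetic cohort with group-specific exposures and topography.

    Per sample the group's expected relative exposures receive Dirichlet
    jitter; SNVs/indels are placed context-consistently on the generated
    reference; SVs are emitted as three jittered per-caller call sets; CCFs
    carry a planted clonal/subclonal signature switch for designated groups.
    """
    profiles = list(profiles) if profiles is not None else default_group_profiles()
    if len(profiles) < 2:
        raise ValueError("need at least two groups")
    lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    genome, _ = make_reference(lengths, seed=seed)
    ctx_index = build_context_index(genome)
    pools = build_indel_pools(genome, n_proposals=indel_pool_proposals, seed=seed)
    sbs_sigs = bundled_reference_signatures("SBS96")
    id_sigs = bundled_reference_signatures("ID83")
    chroms = list(lengths)

    sample_profiles: list[SampleProfile] = []
    labels: dict[str, str] = {}
    clonal_expo_rows: dict[str, np.ndarray] = {}
    subclonal_expo_rows: dict[str, np.ndarray] = {}
    id_expo_rows: dict[str, np.ndarray] = {}
    planted_clusters: dict[str, list] = {}
    cna_plants: dict[str, list] = {}
    kataegis_loci: dict[str, list] = {}
    external_events: list[ComplexEvent] = []
    planted_events_truth: list = []
    switch_by_group: dict[str, tuple | None] = {}
    group_of: dict[str, GroupProfile] = {}

    s_idx = 0
    for g_i, prof in enumerate(profiles):
        switch_by_group[prof.name] = prof.subclonal_switch
        for _ in range(n_per_group):
            sample = f"S{s_idx:03d}"
            rng = _child_rng(seed, 10, s_idx)
            group_of[sample] = prof
            labels[sample] = prof.name
            # SNV exposures with per-sample Dirichlet jitter
            w = rng.dirichlet(np.asarray(prof.sbs_weights) * prof.dirichlet_conc)
            total = max(50, int(rng.normal(prof.n_snvs, 0.08 * prof.n_snvs)))
            expo = w * total
            if prof.subclonal_switch is not None:
                ci, si = prof.subclonal_switch
                clonal = expo.copy()
                sub = np.zeros_like(expo)
                sub[si] = clonal[si] * 0.9 + 0.1 * prof.subclonal_fraction * total
                clonal[si] *= 0.1
                clonal_expo_rows[sample] = clonal
                subclonal_expo_rows[sample] = sub
            else:
                clonal_expo_rows[sample] = expo * (1 - prof.subclonal_fraction)
                subclonal_expo_rows[sample] = expo * prof.subclonal_fraction
            # indel channel expectations
            wi = rng.dirichlet(np.asarray(prof.id_weights) * prof.dirichlet_conc)
            n_id = max(20, int(rng.normal(prof.n_indels, 0.08 * prof.n_indels)))
            id_expo_rows[sample] = id_sigs.W.to_numpy() @ wi * n_id
            # SV clusters
            if rng.random() < prof.cluster_rate:
                chrom = chroms[int(rng.integers(len(chroms)))]
                span = min(5_000_000, int(lengths[chrom] * 0.6))
                lo = int(rng.integers(0, lengths[chrom] - span))
                planted_clusters[sample] = [(chrom, lo, lo + span, 12)]
            # external complex events: a group-defining class (rate >= 1) is
            # always present with Poisson-distributed multiplicity; rates < 1
            # are per-sample presence probabilities
            for cls, rate in sorted(prof.event_rates.items()):
                if rate >= 1.0:
                    n_events = 1 + int(rng.poisson(rate - 1.0))
                else:
                    n_events = int(rng.random() < rate)
                for _ in range(n_events):
                    chrom = chroms[int(rng.integers(len(chroms)))]
                    span = int(rng.integers(200_000, 2_000_000))
                    span = min(span, lengths[chrom] // 2)
                    lo = int(rng.integers(0, lengths[chrom] - span))
                    ev = ComplexEvent(sample_id=sample, event_class=cls,
                                      intervals=((chrom, lo, lo + span),),
                                      source="synthetic-adapter")
                    external_events.append(ev)
                    planted_events_truth.append(
                        {"sample_id": sample, "event_class": cls,
                         "chrom": chrom, "start": lo, "end": lo + span})
            cna_plants[sample] = _planted_intervals(prof, chroms, lengths)
            purity = float(np.clip(rng.normal(0.75, 0.08), 0.4, 0.99))
            sample_profiles.append(SampleProfile(
                sample_id=sample, purity=purity, ploidy=2.0,
                risk_group=prof.risk_group,
                sex="F" if rng.random() < 0.5 else "M",
                age_group="<18m" if rng.random() < 0.5 else ">=18m",
                os_time=float(np.round(rng.exponential(48.0), 1)),
                os_event=bool(rng.random() < 0.4)))
            s_idx += 1

    sample_ids = [s.sample_id for s in sample_profiles]
    sig_names = sbs_sigs.names
    clonal_df = pd.DataFrame([clonal_expo_rows[s] for s in sample_ids],
                             index=sample_ids, columns=sig_names)
    subclonal_df = pd.DataFrame([subclonal_expo_rows[s] for s in sample_ids],
                                index=sample_ids, columns=sig_names)
    snv_clonal, truth_clonal = simulate_snvs(genome, sbs_sigs, clonal_df,
                                             seed=seed, context_index=ctx_index)
    snv_sub, truth_sub = simulate_snvs(genome, sbs_sigs, subclonal_df,
                                       seed=seed + 1, context_index=ctx_index)
    snvs: list[SnvRecord] = []
    for rec_list, lo, hi in ((snv_clonal, 0.75, 1.0), (snv_sub, 0.15, 0.5)):
        for i, r in enumerate(rec_list):
            rng = _child_rng(seed, 20, i, int(lo * 100))
            ccf = float(np.clip(rng.uniform(lo, hi), 0.01, 1.0))
            snvs.append(SnvRecord(r.sample_id, r.chrom, r.pos, r.ref, r.alt, ccf=ccf))

    id_expo_df = pd.DataFrame([id_expo_rows[s] for s in sample_ids],
                              index=sample_ids, columns=list(ID83_CHANNELS))
    indels, id_truth = simulate_indels(genome, id_expo_df, seed=seed, pools=pools)

    # kataegis
    for s_i, sample in enumerate(sample_ids):
        rng = _child_rng(seed, 30, s_i)
        loci = []
        if rng.random() < group_of[sample].kataegis_rate:
            recs, locus = simulate_kataegis(genome, sample, rng)
            snvs.extend(SnvRecord(r.sample_id, r.chrom, r.pos, r.ref, r.alt,
                                  ccf=float(np.clip(rng.uniform(0.75, 1.0), 0, 1)))
                        for r in recs)
            loci.append({"chrom": locus[0], "start": locus[1], "end": locus[2],
                         "positions": [r.pos for r in recs]})
        kataegis_loci[sample] = loci

    sv_sigs = bundled_reference_signatures("SV38")
    Wsv = sv_sigs.W.to_numpy()
    sv_weight_truth = {}
    sv_cfgs = {}
    for s_j, s in enumerate(sample_ids):
        prof = group_of[s]
        rng_sv = _child_rng(seed, 40, s_j)
        w_sv = rng_sv.dirichlet(np.asarray(prof.sv_sig_weights) * prof.dirichlet_conc)
        sv_weight_truth[s] = [round(float(x), 4) for x in w_sv]
        sv_cfgs[s] = SvSimConfig(n_background=prof.n_svs,
                                 channel_weights=Wsv @ w_sv)
    callsets: dict[str, list[SvRecord]] = {c: [] for c in DEFAULT_CALLERS}
    sv_truth_all: dict = {"true_svs": {}, "clusters": planted_clusters,
                          "sv_sig_weights": sv_weight_truth}
    for s_i, sample in enumerate(sample_ids):
        cs, tr = simulate_svs(lengths, [sample], cfg=sv_cfgs[sample],
                              planted_clusters={sample: planted_clusters.get(sample, [])},
                              seed=seed + 100 + s_i)
        for caller, recs in cs.items():
            callsets[caller].extend(recs)
        sv_truth_all["true_svs"].update(tr["true_svs"])

    cna_segments, cna_truth = simulate_cna(lengths, cna_plants, ploidy=2.0, seed=seed)

    truth = CohortTruth(
        seed=seed, labels=labels,
        sbs_exposures=clonal_df + subclonal_df,
        sbs_channel_counts=truth_clonal + truth_sub,
        id_channel_counts=id_truth,
        sv_truth=sv_truth_all,
        planted_events=planted_events_truth,
        kataegis_loci=kataegis_loci,
        cna_truth=cna_truth,
        subclonal_switch_groups=switch_by_group)
    return Cohort(genome=genome, chrom_lengths=lengths, samples=sample_profiles,
                  snvs=snvs, indels=indels, sv_callsets=callsets,
                  cna_segments=cna_segments, external_events=external_events,
                  truth=truth)
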