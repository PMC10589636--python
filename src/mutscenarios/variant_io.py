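"""Parsing, validation and serialization of somatic variant collections.

All interval types (CNA segments, genes, arms, event intervals) use 0-based
half-open coordinates; point variants (SNVs, indels, SV breakpoints) are
stored 1-based following VCF convention.  Conversions are confined to the
readers and writers in this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

BASES = frozenset("ACGT")
SV_CLASSES = ("DEL", "DUP", "INV", "TRA", "INS")
RISK_GROUPS = ("HR_MNA", "HR_nonMNA", "nonHR", "unknown")
GENE_CATEGORIES = ("nb_driver", "dna_repair", "hrr", "hrr_profound")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Well-formed input violating a semantic invariant."""


def _require(cond: bool, exc: type[ValueError], msg: str) -> None:
    if not cond:
        raise exc(msg)


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class SnvRecord:
    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ccf: float | None = None
    consequence: str | None = None

    def __post_init__(self) -> None:
        _require(self.pos >= 1, ValidationError, f"SNV pos must be >= 1, got {self.pos}")
        _require(self.ref in BASES and self.alt in BASES,
                 ValidationError, f"SNV alleles must be single A/C/G/T: {self.ref}>{self.alt}")
        _require(self.ref != self.alt, ValidationError, "SNV ref == alt")
        if self.ccf is not None:
            _require(0.0 <= self.ccf <= 1.0, ValidationError, f"CCF out of [0,1]: {self.ccf}")


@dataclass(frozen=True, slots=True)
class IndelRecord:
    """Anchored (VCF-style) insertion or deletion shorter than 50 bp net."""

    sample_id: str
    chrom: str
    pos: int  # 1-based anchor position
    ref: str
    alt: str
    ccf: float | None = None
    consequence: str | None = None

    def __post_init__(self) -> None:
        _require(self.pos >= 1, ValidationError, f"indel pos must be >= 1, got {self.pos}")
        net = abs(len(self.ref) - len(self.alt))
        _require(len(self.ref) != len(self.alt), ValidationError,
                 "indel alleles of equal length")
        _require(0 < net < 50, ValidationError, f"net indel length {net} not in (0, 50)")
        _require(self.ref[0] == self.alt[0], ValidationError,
                 f"indel alleles must share the anchor base: {self.ref}>{self.alt}")

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) > len(self.alt)

    @property
    def change(self) -> str:
        """The inserted or deleted sequence (anchor stripped)."""
        longer = self.ref if self.is_deletion else self.alt
        shorter = self.alt if self.is_deletion else self.ref
        return longer[len(shorter):]


@dataclass(frozen=True, slots=True)
class SvRecord:
    sample_id: str
    chrom1: str
    pos1: int  # 1-based
    chrom2: str
    pos2: int  # 1-based
    svclass: str
    caller: str = ""
    pass_filter: bool = True

    def __post_init__(self) -> None:
        _require(self.svclass in SV_CLASSES, ValidationError,
                 f"unknown svclass {self.svclass!r}")
        if self.svclass == "TRA":
            _require(self.chrom1 != self.chrom2, ValidationError,
                     "TRA requires chrom1 != chrom2")
        else:
            _require(self.chrom1 == self.chrom2, ValidationError,
                     f"{self.svclass} requires chrom1 == chrom2")
            _require(self.pos1 <= self.pos2, ValidationError,
                     "intrachromosomal SV requires pos1 <= pos2")
        _require(self.pos1 >= 1 and self.pos2 >= 1, ValidationError, "SV pos must be >= 1")

    @property
    def size(self) -> int | None:
        """Span in bases for intrachromosomal classes; None for TRA."""
        if self.svclass == "TRA":
            return None
        return abs(self.pos2 - self.pos1)

    def breakpoints(self) -> list[tuple[str, int]]:
        return [(self.chrom1, self.pos1), (self.chrom2, self.pos2)]


@dataclass(frozen=True, slots=True)
class CnaSegment:
    sample_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    cn_major: int
    cn_minor: int

    def __post_init__(self) -> None:
        _require(self.end > self.start, ValidationError,
                 f"segment end {self.end} <= start {self.start}")
        _require(self.cn_major >= self.cn_minor >= 0, ValidationError,
                 f"require cn_major >= cn_minor >= 0, got ({self.cn_major},{self.cn_minor})")

    @property
    def total_cn(self) -> int:
        return self.cn_major + self.cn_minor

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class SampleProfile:
    sample_id: str
    purity: float = 1.0
    ploidy: float = 2.0
    risk_group: str = "unknown"
    sex: str = "unknown"
    age_group: str = "unknown"
    os_time: float = 0.0
    os_event: bool = False

    def __post_init__(self) -> None:
        _require(self.ploidy > 0, ValidationError, f"ploidy must be > 0, got {self.ploidy}")
        _require(0 < self.purity <= 1, ValidationError, f"purity out of (0,1]: {self.purity}")
        _require(self.risk_group in RISK_GROUPS, ValidationError,
                 f"unknown risk group {self.risk_group!r}")


@dataclass(frozen=True, slots=True)
class GeneAnnotation:
    gene: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    category: str

    def __post_init__(self) -> None:
        _require(self.end > self.start, ValidationError, "gene end <= start")
        _require(self.category in GENE_CATEGORIES, ValidationError,
                 f"unknown gene category {self.category!r}")


# ---------------------------------------------------------------------------
# chromosome naming
# ---------------------------------------------------------------------------

def normalize_chrom(name: str, known: Iterable[str] | None = None) -> str | None:
    """Match ``name`` against the reference contig set by adding/stripping 'chr'.

    Returns the matching reference name, or None when the contig is absent
    (caller decides whether that is an error or a logged drop).
    """
    if known is None:
        return name
    known = set(known)
    if name in known:
        return name
    alt = name[3:] if name.startswith("chr") else "chr" + name
    if alt in known:
        return alt
    return None


# ---------------------------------------------------------------------------
# VCF reading (SNVs / indels)
# ---------------------------------------------------------------------------

def _vcf_ccf(variant, ccf_key: str) -> float | None:
    val = variant.INFO.get(ccf_key)
    if val is None and ccf_key in (variant.FORMAT or []):
        arr = variant.format(ccf_key)
        if arr is not None and len(arr):
            val = float(arr[0][0])
    if val is None:
        return None
    try:
        v = float(val)
    except (TypeError, ValueError):
        return None
    return min(max(v, 0.0), 1.0)


def read_snv_vcf(path: str | Path, sample_id: str, *, ccf_key: str = "CCF",
                 known_chroms: Iterable[str] | None = None,
                 consequence_key: str = "CSQ_LABEL") -> list[SnvRecord]:
    """Read single-base substitutions from a VCF; non-SNV alleles are skipped.

    Multi-allelic rows are split into one record per alternate allele.
    """
    from cyvcf2 import VCF

    known = set(known_chroms) if known_chroms is not None else None
    records: list[SnvRecord] = []
    skipped = 0
    bad_chroms: set[str] = set()
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    for variant in vcf:
        chrom = normalize_chrom(variant.CHROM, known)
        if chrom is None:
            bad_chroms.add(variant.CHROM)
            continue
        ccf = _vcf_ccf(variant, ccf_key)
        csq = variant.INFO.get(consequence_key)
        for alt in variant.ALT:
            if len(variant.REF) == 1 and len(alt) == 1 and \
                    variant.REF in BASES and alt in BASES and alt != variant.REF:
                records.append(SnvRecord(sample_id, chrom, variant.POS,
                                         variant.REF, alt, ccf=ccf, consequence=csq))
            else:
                skipped += 1
    if bad_chroms:
        raise ValidationError(
            f"{path}: chromosomes absent from reference index: {sorted(bad_chroms)}")
    if skipped:
        log.info("read_snv_vcf(%s): skipped %d non-SNV alleles", path, skipped)
    return records


def read_indel_vcf(path: str | Path, sample_id: str, *, ccf_key: str = "CCF",
                   known_chroms: Iterable[str] | None = None,
                   consequence_key: str = "CSQ_LABEL") -> list[IndelRecord]:
    """Read anchored insertions/deletions (<50 bp net) from a VCF."""
    from cyvcf2 import VCF

    known = set(known_chroms) if known_chroms is not None else None
    records: list[IndelRecord] = []
    skipped = 0
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    for variant in vcf:
        chrom = normalize_chrom(variant.CHROM, known)
        if chrom is None:
            continue
        ccf = _vcf_ccf(variant, ccf_key)
        csq = variant.INFO.get(consequence_key)
        for alt in variant.ALT:
            net = abs(len(variant.REF) - len(alt))
            if net == 0 or net >= 50 or not alt or variant.REF[0] != alt[0]:
                skipped += 1
                continue
            records.append(IndelRecord(sample_id, chrom, variant.POS,
                                       variant.REF, alt, ccf=ccf, consequence=csq))
    if skipped:
        log.info("read_indel_vcf(%s): skipped %d non-indel alleles", path, skipped)
    return records


def write_vcf(records: Sequence[SnvRecord | IndelRecord], path: str | Path,
              contigs: dict[str, int] | None = None, *, ccf_key: str = "CCF",
              consequence_key: str = "CSQ_LABEL") -> None:
    """Write SNV/indel records of one sample as a minimal sorted VCF 4.2."""
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(f'##INFO=<ID={ccf_key},Number=1,Type=Float,Description="Cancer cell fraction">')
    lines.append(f'##INFO=<ID={consequence_key},Number=1,Type=String,Description="Consequence label">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    order = {c: i for i, c in enumerate(contigs)} if contigs else {}
    for rec in sorted(records, key=lambda r: (order.get(r.chrom, 0), r.chrom, r.pos, r.ref, r.alt)):
        info = []
        if rec.ccf is not None:
            info.append(f"{ccf_key}={rec.ccf:.4f}")
        if rec.consequence:
            info.append(f"{consequence_key}={rec.consequence}")
        lines.append(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t"
                     + (";".join(info) or "."))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SV tables
# ---------------------------------------------------------------------------

_BEDPE_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
               "name", "score", "strand1", "strand2", "sample_id", "svclass", "filter"]


def read_sv_table(path: str | Path, dialect: str = "bedpe", caller: str = "",
                  known_chroms: Iterable[str] | None = None) -> list[SvRecord]:
    """Read SV breakpoint pairs from BEDPE (0-based half-open) or VCF-BND."""
    if dialect == "bedpe":
        return _read_bedpe(path, caller, known_chroms)
    if dialect == "vcf_bnd":
        return _read_vcf_bnd(path, caller, known_chroms)
    raise FormatError(f"unknown SV dialect {dialect!r}")


def _read_bedpe(path, caller, known_chroms) -> list[SvRecord]:
    try:
        df = pd.read_csv(path, sep="\t", comment=None)
    except Exception as exc:
        raise FormatError(f"cannot parse BEDPE {path}: {exc}") from exc
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [c for c in ("chrom1", "start1", "chrom2", "start2", "svclass") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: BEDPE lacks required columns {missing}")
    known = set(known_chroms) if known_chroms is not None else None
    records = []
    for row in df.itertuples(index=False):
        c1 = normalize_chrom(str(row.chrom1), known)
        c2 = normalize_chrom(str(row.chrom2), known)
        if c1 is None or c2 is None:
            raise ValidationError(f"{path}: unknown chromosome in row {row}")
        pos1 = int(row.start1) + 1  # 0-based BEDPE start -> 1-based breakpoint
        pos2 = int(row.start2) + 1
        svclass = str(row.svclass)
        if svclass != "TRA" and pos2 < pos1:
            raise ValidationError(f"{path}: negative size for {row}")
        filt = str(getattr(row, "filter", "PASS"))
        records.append(SvRecord(
            sample_id=str(getattr(row, "sample_id", "")),
            chrom1=c1, pos1=pos1, chrom2=c2, pos2=pos2, svclass=svclass,
            caller=caller or str(getattr(row, "caller", "")),
            pass_filter=filt in ("PASS", "."),
        ))
    return records


_BND_CLASS = {("+", "-"): "DEL", ("-", "+"): "DUP", ("+", "+"): "INV", ("-", "-"): "INV"}


def _parse_bnd_alt(alt: str) -> tuple[str, int, str, str] | None:
    """Return (mate_chrom, mate_pos, this_orient, mate_orient) from a BND ALT."""
    import re

    m = re.match(r"^([ACGTN]*)(\[|\])([^:]+):(\d+)(\[|\])([ACGTN]*)$", alt)
    if not m:
        return None
    left_seq, b1, chrom, pos, _b2, _right = m.groups()
    this_orient = "+" if left_seq else "-"
    mate_orient = "-" if b1 == "[" else "+"
    return chrom, int(pos), this_orient, mate_orient


def _read_vcf_bnd(path, caller, known_chroms) -> list[SvRecord]:
    from cyvcf2 import VCF

    known = set(known_chroms) if known_chroms is not None else None
    mates: dict[str, tuple] = {}
    records: list[SvRecord] = []
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = vcf.samples
    for variant in vcf:
        vid = variant.ID
        mate_id = variant.INFO.get("MATEID")
        parsed = _parse_bnd_alt(variant.ALT[0]) if variant.ALT else None
        if parsed is None:
            continue
        sample = samples[0] if samples else str(variant.INFO.get("SAMPLE") or "")
        entry = (variant.CHROM, variant.POS, parsed, variant.FILTER, sample)
        if mate_id in mates:
            other = mates.pop(mate_id)
            c1, p1, (mc, mp, o1, _), filt1, samp = other
            _c2, p2, (_mc2, _mp2, o2, _), filt2, _ = entry
            chrom1 = normalize_chrom(c1, known)
            chrom2 = normalize_chrom(mc, known)
            if chrom1 is None or chrom2 is None:
                raise ValidationError(f"{path}: unknown chromosome in BND pair {vid}")
            if chrom1 == chrom2 and p1 > p2:
                (p1, p2), (o1, o2) = (p2, p1), (o2, o1)
            svclass = "TRA" if chrom1 != chrom2 else _BND_CLASS.get((o1, o2), "INV")
            pass_filter = (filt1 is None) or (filt2 is None)  # cyvcf2: PASS -> None
            records.append(SvRecord(samp, chrom1, p1, chrom2, p2, svclass,
                                    caller=caller, pass_filter=pass_filter))
        else:
            mates[vid] = entry
    if mates:
        raise ValidationError(f"{path}: unmatched BND mates: {sorted(mates)}")
    return records


def write_sv_bedpe(records: Sequence[SvRecord], path: str | Path,
                   extra: dict[str, Sequence] | None = None) -> None:
    """Write SVs as BEDPE (0-based half-open single-base breakpoint intervals)."""
    rows = []
    for i, r in enumerate(records):
        rows.append({
            "chrom1": r.chrom1, "start1": r.pos1 - 1, "end1": r.pos1,
            "chrom2": r.chrom2, "start2": r.pos2 - 1, "end2": r.pos2,
            "name": f"sv{i}", "score": ".", "strand1": ".", "strand2": ".",
            "sample_id": r.sample_id, "svclass": r.svclass, "caller": r.caller,
            "filter": "PASS" if r.pass_filter else "FAIL",
        })
    cols = _BEDPE_COLS[:10] + ["sample_id", "svclass", "caller", "filter"]
    cols = list(dict.fromkeys(cols))
    df = pd.DataFrame(rows, columns=cols)
    if extra:
        for k, v in extra.items():
            df[k] = list(v)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CNA segments / sample table / genes
# ---------------------------------------------------------------------------

def merge_equal_segments(segments: Sequence[CnaSegment]) -> list[CnaSegment]:
    """Merge book-ended segments with identical (cn_major, cn_minor)."""
    out: list[CnaSegment] = []
    for seg in sorted(segments, key=lambda s: (s.sample_id, s.chrom, s.start)):
        if (out and out[-1].sample_id == seg.sample_id and out[-1].chrom == seg.chrom
                and out[-1].end == seg.start
                and (out[-1].cn_major, out[-1].cn_minor) == (seg.cn_major, seg.cn_minor)):
            out[-1] = replace(out[-1], end=seg.end)
        else:
            out.append(seg)
    return out


def read_cna_segments(path: str | Path, *, merge: bool = True,
                      known_chroms: Iterable[str] | None = None) -> list[CnaSegment]:
    required = ["sample_id", "chrom", "start", "end", "cn_major", "cn_minor"]
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot parse CNA table {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    known = set(known_chroms) if known_chroms is not None else None
    segments = []
    for row in df.itertuples(index=False):
        chrom = normalize_chrom(str(row.chrom), known)
        if chrom is None:
            raise ValidationError(f"{path}: unknown chromosome {row.chrom!r}")
        segments.append(CnaSegment(str(row.sample_id), chrom, int(row.start),
                                   int(row.end), int(row.cn_major), int(row.cn_minor)))
    segments.sort(key=lambda s: (s.sample_id, s.chrom, s.start))
    for a, b in zip(segments, segments[1:]):
        if a.sample_id == b.sample_id and a.chrom == b.chrom and b.start < a.end:
            raise ValidationError(
                f"{path}: overlapping segments in {a.sample_id} {a.chrom}: "
                f"[{a.start},{a.end}) and [{b.start},{b.end})")
    return merge_equal_segments(segments) if merge else segments


def write_cna_segments(segments: Sequence[CnaSegment], path: str | Path) -> None:
    df = pd.DataFrame([{"sample_id": s.sample_id, "chrom": s.chrom, "start": s.start,
                        "end": s.end, "cn_major": s.cn_major, "cn_minor": s.cn_minor}
                       for s in segments],
                      columns=["sample_id", "chrom", "start", "end", "cn_major", "cn_minor"])
    df.to_csv(path, sep="\t", index=False)


def read_sample_table(path: str | Path) -> list[SampleProfile]:
    required = ["sample_id", "purity", "ploidy", "risk_group"]
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot parse sample table {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return [SampleProfile(
        sample_id=str(r.sample_id), purity=float(r.purity), ploidy=float(r.ploidy),
        risk_group=str(r.risk_group), sex=str(getattr(r, "sex", "unknown")),
        age_group=str(getattr(r, "age_group", "unknown")),
        os_time=float(getattr(r, "os_time", 0.0)),
        os_event=bool(getattr(r, "os_event", False)),
    ) for r in df.itertuples(index=False)]


def write_sample_table(samples: Sequence[SampleProfile], path: str | Path) -> None:
    df = pd.DataFrame([{
        "sample_id": s.sample_id, "purity": s.purity, "ploidy": s.ploidy,
        "risk_group": s.risk_group, "sex": s.sex, "age_group": s.age_group,
        "os_time": s.os_time, "os_event": s.os_event} for s in samples])
    df.to_csv(path, sep="\t", index=False)


def read_gene_bed(path: str | Path,
                  known_chroms: Iterable[str] | None = None) -> list[GeneAnnotation]:
    """BED: chrom, start, end, gene, category (0-based half-open)."""
    known = set(known_chroms) if known_chroms is not None else None
    genes = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 5:
            raise FormatError(f"{path}:{ln}: expected 5 BED columns, got {len(parts)}")
        chrom = normalize_chrom(parts[0], known)
        if chrom is None:
            raise ValidationError(f"{path}:{ln}: unknown chromosome {parts[0]!r}")
        genes.append(GeneAnnotation(gene=parts[3], chrom=chrom,
                                    start=int(parts[1]), end=int(parts[2]),
                                    category=parts[4]))
    return genes


def write_gene_bed(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    lines = [f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene}\t{g.category}" for g in genes]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
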