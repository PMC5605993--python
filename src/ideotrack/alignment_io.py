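"""SAM/BAM input, the properly-paired read filter, and assembly detection.

The counting pipeline only keeps reads whose SAM flag marks them as part of
a properly aligned pair (both mates mapped in the expected orientation and
insert-size range), drops unmapped, secondary and supplementary records, and
applies a mapping-quality floor (default 10, the usual counting default).

SAM text is the primary format and is parsed directly so that malformed
records can be reported by line number; BAM is read through pysam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST_IN_PAIR = 0x40
FLAG_SECOND_IN_PAIR = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

DEFAULT_MIN_MAPQ = 10

#: CIGAR operations that consume reference bases.
_REF_CONSUMING = set("MDN=X")
#: Reference-consuming ops that are part of an aligned block (N splits).
_BLOCK_OPS = set("MD=X")


class SAMFormatError(ValueError):
    """Malformed SAM content; the message names the offending line."""


def cigar_to_blocks(cigar: str, pos: int) -> list[tuple[int, int]]:
    """Reference intervals (1-based inclusive) covered by an alignment.

    ``M``/``=``/``X``/``D`` extend the current block; ``N`` (intron skip)
    closes it and opens a new one after the gap; ``I``/``S``/``H``/``P``
    consume no reference. Returns blocks sorted ascending.
    """
    if cigar == "*":
        return []
    blocks: list[tuple[int, int]] = []
    ref = pos
    block_start: int | None = None
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        if not num:
            raise ValueError(f"bad CIGAR {cigar!r}: op {ch!r} without length")
        length, num = int(num), ""
        if ch in _BLOCK_OPS:
            if block_start is None:
                block_start = ref
            ref += length
        elif ch == "N":
            if block_start is not None:
                blocks.append((block_start, ref - 1))
                block_start = None
            ref += length
        elif ch in "ISHP":
            pass
        else:
            raise ValueError(f"bad CIGAR {cigar!r}: unknown op {ch!r}")
    if num:
        raise ValueError(f"bad CIGAR {cigar!r}: trailing length")
    if block_start is not None:
        blocks.append((block_start, ref - 1))
    return blocks


@dataclass
class AlignmentRecord:
    """The SAM fields the filter and counter need."""

    qname: str
    flag: int
    rname: str
    pos: int  # 1-based leftmost mapped base
    mapq: int
    cigar: str

    @property
    def aligned_blocks(self) -> list[tuple[int, int]]:
        return cigar_to_blocks(self.cigar, self.pos)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_first_in_pair(self) -> bool:
        return bool(self.flag & FLAG_FIRST_IN_PAIR)


@dataclass
class FilterStats:
    """Audit trail of the properly-paired filter.

    Categories are assigned in priority order: unmapped, then secondary or
    supplementary, then not properly paired, then low mapping quality; so
    the totals always conserve.
    """

    total: int = 0
    kept: int = 0
    not_proper_pair: int = 0
    unmapped: int = 0
    secondary_or_supplementary: int = 0
    low_mapq: int = 0

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def check_conservation(self) -> bool:
        return self.total == (self.kept + self.not_proper_pair + self.unmapped
                              + self.secondary_or_supplementary + self.low_mapq)


@dataclass
class SamHeader:
    """Reference sequence dictionary from ``@SQ`` lines."""

    references: list[tuple[str, int]] = field(default_factory=list)  # (SN, LN)


def _parse_sam_text(path: str | Path) -> tuple[SamHeader, Iterator[AlignmentRecord]]:
    header = SamHeader()
    fh = open(path, "rt", encoding="utf-8")
    line_no = 0
    first_record_line: str | None = None
    for line in fh:
        line_no += 1
        if line.startswith("@"):
            if line.startswith("@SQ"):
                tags = dict(
                    t.split(":", 1) for t in line.rstrip("\n").split("\t")[1:]
                    if ":" in t
                )
                if "SN" in tags and "LN" in tags:
                    try:
                        header.references.append((tags["SN"], int(tags["LN"])))
                    except ValueError as exc:
                        raise SAMFormatError(
                            f"line {line_no}: bad LN in @SQ"
                        ) from exc
            continue
        first_record_line = line
        break

    def parse_record(raw: str, n: int) -> AlignmentRecord | None:
        raw = raw.rstrip("\n")
        if not raw:
            return None
        cols = raw.split("\t")
        if len(cols) < 11:
            raise SAMFormatError(f"line {n}: expected ≥11 fields, got {len(cols)}")
        try:
            return AlignmentRecord(
                qname=cols[0], flag=int(cols[1]), rname=cols[2],
                pos=int(cols[3]), mapq=int(cols[4]), cigar=cols[5],
            )
        except ValueError as exc:
            raise SAMFormatError(f"line {n}: {exc}") from exc

    def records() -> Iterator[AlignmentRecord]:
        n = line_no
        try:
            if first_record_line is not None:
                rec = parse_record(first_record_line, n)
                if rec is not None:
                    yield rec
            for raw in fh:
                n += 1
                rec = parse_record(raw, n)
                if rec is not None:
                    yield rec
        finally:
            fh.close()

    return header, records()


def _parse_bam(path: str | Path) -> tuple[SamHeader, Iterator[AlignmentRecord]]:
    import pysam

    af = pysam.AlignmentFile(str(path), "rb", check_sq=False)
    header = SamHeader(references=[
        (name, length) for name, length in zip(af.references, af.lengths)
    ])

    def records() -> Iterator[AlignmentRecord]:
        with af:
            for rec in af.fetch(until_eof=True):
                yield AlignmentRecord(
                    qname=rec.query_name or "",
                    flag=rec.flag,
                    rname=rec.reference_name or "*",
                    pos=(rec.reference_start or 0) + 1,
                    mapq=rec.mapping_quality,
                    cigar=rec.cigarstring or "*",
                )

    return header, records()


def read_sam(path: str | Path) -> tuple[SamHeader, Iterator[AlignmentRecord]]:
    """Open a SAM (or BAM) file; returns the header and a record stream."""
    if str(path).endswith(".bam"):
        return _parse_bam(path)
    return _parse_sam_text(path)


def filter_properly_paired(
    records: Iterable[AlignmentRecord],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    stats: FilterStats | None = None,
) -> Iterator[AlignmentRecord]:
    """Keep records that are properly paired, primary, mapped, and at or
    above the mapping-quality floor.

    Pass a :class:`FilterStats` to collect the audit counters; it is filled
    in as the returned stream is consumed.
    """
    if stats is None:
        stats = FilterStats()

    def gen() -> Iterator[AlignmentRecord]:
        for rec in records:
            stats.total += 1
            if rec.flag & FLAG_UNMAPPED:
                stats.unmapped += 1
            elif rec.flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
                stats.secondary_or_supplementary += 1
            elif not rec.flag & FLAG_PROPER_PAIR:
                stats.not_proper_pair += 1
            elif rec.mapq < min_mapq:
                stats.low_mapq += 1
            else:
                stats.kept += 1
                yield rec

    return gen()


def load_assembly_fingerprints() -> dict[str, dict[str, int]]:
    """Shipped chromosome-length fingerprints for GRCh37 and GRCh38."""
    table: dict[str, dict[str, int]] = {}
    text = resources.files("ideotrack.data").joinpath(
        "assembly_fingerprints.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        assembly, label, length = line.split("\t")
        table.setdefault(assembly, {})[label] = int(length)
    return table


def detect_assembly(
    references: Iterable[tuple[str, int]],
    fingerprints: Mapping[str, Mapping[str, int]] | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> str:
    """Identify the reference assembly from header (SN, LN) pairs.

    A candidate assembly matches when at least one canonical chromosome in
    the header has the fingerprint length and none contradicts it. Returns
    the label only when exactly one assembly matches; otherwise ``"unknown"``
    — never a guess.
    """
    from .gff_annotation import load_human_alias_map, normalize_chromosome_name

    if fingerprints is None:
        fingerprints = load_assembly_fingerprints()
    if alias_map is None:
        alias_map = load_human_alias_map()

    refs = [(normalize_chromosome_name(sn, alias_map), ln)
            for sn, ln in references]
    candidates = []
    for assembly, chrom_lengths in fingerprints.items():
        matched = 0
        contradicted = False
        for label, length in refs:
            expected = chrom_lengths.get(label)
            if expected is None:
                continue
            if expected == length:
                matched += 1
            else:
                contradicted = True
                break
        if matched and not contradicted:
            candidates.append(assembly)
    if len(candidates) == 1:
        return candidates[0]
    return "unknown"
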