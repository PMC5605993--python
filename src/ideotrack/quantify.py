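"""Union-mode gene-level fragment counting and TPM normalization.

Counting follows union-mode overlap resolution: per fragment (all records
sharing a query name, i.e. both mates of a pair), take the union of genes
whose exonic intervals overlap any aligned block of any mate. Exactly one
gene in the union assigns the fragment to that gene; an empty union counts
as ``no_feature``; more than one counts as ``ambiguous``. Fragments are
never split fractionally, so counts stay integral and the conservation
invariant ``assigned + no_feature + ambiguous = fragments`` holds exactly.

TPM (transcripts per million) divides each gene's count by its length
(the longest transcript's mature length, in bp), then rescales the rates
so all genes sum to 10^6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from intervaltree import IntervalTree

from .alignment_io import AlignmentRecord
from .gff_annotation import GeneModel, GenomeLayout, gene_length

logger = logging.getLogger(__name__)

NO_FEATURE_KEY = "__no_feature"
AMBIGUOUS_KEY = "__ambiguous"

TPM_SCALE = 1_000_000.0


@dataclass
class CountTable:
    """Per-gene fragment counts plus union-mode diagnostic counters."""

    counts: dict[str, int] = field(default_factory=dict)
    no_feature: int = 0
    ambiguous: int = 0
    unknown_chromosome: int = 0  # subset of no_feature, for the audit log

    @property
    def assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def fragments_considered(self) -> int:
        return self.assigned + self.no_feature + self.ambiguous

    def check_conservation(self, fragments: int) -> bool:
        return self.fragments_considered == fragments


@dataclass
class ExpressionTable:
    """Per-gene TPM values and the gene lengths used to compute them."""

    tpm: dict[str, float] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)


class GeneIndex:
    """Per-chromosome interval index over genes' exonic intervals."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        for gene in genes:
            tree = self._trees.setdefault(gene.chromosome, IntervalTree())
            for start, stop in gene.exonic_intervals():
                # intervaltree is half-open; store [start, stop+1).
                tree.addi(start, stop + 1, (gene.symbol, gene.strand))

    def overlapping(
        self, chromosome: str, start: int, stop: int,
        strand: str | None = None,
    ) -> set[str] | None:
        """Gene symbols whose exons overlap [start, stop] (1-based incl.).

        Returns None when the chromosome is not indexed at all.
        """
        tree = self._trees.get(chromosome)
        if tree is None:
            return None
        hits = set()
        for iv in tree.overlap(start, stop + 1):
            symbol, gene_strand = iv.data
            if strand is not None and gene_strand in "+-" and gene_strand != strand:
                continue
            hits.add(symbol)
        return hits

    def has_chromosome(self, chromosome: str) -> bool:
        return chromosome in self._trees


def _fragment_strand(rec: AlignmentRecord, stranded: str) -> str | None:
    """Strand the fragment is assigned to under the given protocol.

    'no' disables strand matching. 'yes': the first mate's strand is the
    transcript strand; 'reverse': the opposite (dUTP-style protocols).
    """
    if stranded == "no":
        return None
    read_strand = "-" if rec.is_reverse else "+"
    first = rec.is_first_in_pair or not rec.flag & 0x1
    if stranded == "yes":
        same = first
    elif stranded == "reverse":
        same = not first
    else:
        raise ValueError(f"stranded must be 'yes', 'no' or 'reverse', got {stranded!r}")
    if same:
        return read_strand
    return "+" if read_strand == "-" else "-"


def count_fragments(
    records: Iterable[AlignmentRecord],
    genes: list[GeneModel],
    layout: GenomeLayout | None = None,
    stranded: str = "no",
) -> CountTable:
    """Union-mode fragment counting over a filtered alignment stream.

    Mates are pooled by query name regardless of file order (unsorted input
    is buffered; memory is bounded by the number of unmatched mates), and
    each fragment contributes one unit to exactly one of: a single gene,
    ``no_feature``, or ``ambiguous``.
    """
    index = GeneIndex(genes)
    table = CountTable()

    # qname -> (gene symbol union or None-for-unknown-chrom marker, mates seen)
    pending: dict[str, tuple[set[str], bool, int]] = {}
    # (union, saw_known_chromosome, mates_seen)

    def resolve(union: set[str], saw_known: bool) -> None:
        if not saw_known:
            table.unknown_chromosome += 1
            logger.debug("fragment on unindexed chromosome counted as no_feature")
        if len(union) == 1:
            symbol = next(iter(union))
            table.counts[symbol] = table.counts.get(symbol, 0) + 1
        elif not union:
            table.no_feature += 1
        else:
            table.ambiguous += 1

    for rec in records:
        strand = _fragment_strand(rec, stranded)
        rec_union: set[str] = set()
        saw_known = False
        for start, stop in rec.aligned_blocks:
            hits = index.overlapping(rec.rname, start, stop, strand)
            if hits is None:
                continue
            saw_known = True
            rec_union |= hits
        if not rec.flag & 0x1:
            # Unpaired read: a fragment on its own.
            resolve(rec_union, saw_known)
            continue
        if rec.qname in pending:
            union, known, seen = pending.pop(rec.qname)
            union |= rec_union
            known = known or saw_known
            if seen + 1 >= 2:
                resolve(union, known)
            else:
                pending[rec.qname] = (union, known, seen + 1)
        else:
            pending[rec.qname] = (rec_union, saw_known, 1)

    # Mates whose partner never appeared still form one fragment each.
    for union, known, _seen in pending.values():
        resolve(union, known)

    # Zero-initialize every annotated gene so the count table is total.
    for gene in genes:
        table.counts.setdefault(gene.symbol, 0)

    return table


def gene_lengths_map(genes: Iterable[GeneModel]) -> dict[str, int]:
    """Per-gene length used for TPM: the longest transcript's mature length."""
    return {g.symbol: gene_length(g) for g in genes}


def tpm(counts: CountTable | Mapping[str, int],
        lengths: Mapping[str, int]) -> ExpressionTable:
    """Normalize counts to TPM using per-gene lengths in bp.

    rate_i = count_i / length_i; tpm_i = 10^6 * rate_i / sum(rates).
    All-zero counts yield all-zero TPM.
    """
    count_map = counts.counts if isinstance(counts, CountTable) else dict(counts)
    missing = sorted(sym for sym in count_map if sym not in lengths)
    if missing:
        raise KeyError(
            "no length for counted gene(s): " + ", ".join(missing)
        )
    bad = sorted(sym for sym in count_map if lengths[sym] < 1)
    if bad:
        raise ValueError("non-positive length for gene(s): " + ", ".join(bad))

    # Iterate in sorted symbol order so the floating-point total (and hence
    # every TPM value) is independent of the counts' insertion order.
    rates = {sym: count_map[sym] / lengths[sym] for sym in sorted(count_map)}
    total = sum(rates.values())
    if total == 0:
        values = {sym: 0.0 for sym in count_map}
    else:
        values = {sym: TPM_SCALE * rate / total for sym, rate in rates.items()}
    return ExpressionTable(tpm=values,
                           lengths={sym: lengths[sym] for sym in count_map})


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Two-column TSV: gene symbol, fragment count; genes in lexicographic
    order; diagnostics as trailing ``__no_feature`` / ``__ambiguous`` rows."""
    with open(path, "wt", encoding="utf-8") as fh:
        for symbol in sorted(table.counts):
            fh.write(f"{symbol}\t{table.counts[symbol]}\n")
        fh.write(f"{NO_FEATURE_KEY}\t{table.no_feature}\n")
        fh.write(f"{AMBIGUOUS_KEY}\t{table.ambiguous}\n")


def read_count_table(path: str | Path) -> CountTable:
    """Inverse of :func:`write_count_table`; integer counts are enforced."""
    table = CountTable()
    with open(path, "rt", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {line_no}: expected 2 columns")
            symbol, value = parts
            try:
                count = int(value)
            except ValueError as exc:
                raise ValueError(
                    f"line {line_no}: non-integer count {value!r}"
                ) from exc
            if count < 0:
                raise ValueError(f"line {line_no}: negative count {count}")
            if symbol == NO_FEATURE_KEY:
                table.no_feature = count
            elif symbol == AMBIGUOUS_KEY:
                table.ambiguous = count
            else:
                table.counts[symbol] = count
    return table
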