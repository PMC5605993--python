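"""Gene models from GFF3 annotation.

Parses GFF3 (NCBI dialect: ``gene``/``pseudogene`` records with child
transcript and ``exon`` features linked by ``ID``/``Parent``) into a flat
gene model carrying, per gene: symbol, chromosome, genomic span, strand, a
gene type drawn from a small closed vocabulary, and the mature length of
each transcript (sum of exon lengths, introns excluded).

All coordinates are 1-based inclusive throughout, matching GFF3; conversion
to other conventions happens only at serialization boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping
from urllib.parse import unquote

logger = logging.getLogger(__name__)

#: Closed gene-type vocabulary used throughout the package.
GENE_TYPES = ("mRNA", "ncRNA", "pseudogene", "other")

#: GFF3 feature types treated as top-level gene records.
_GENE_FEATURE_TYPES = {"gene", "pseudogene"}

#: Child feature types treated as transcripts when linked to a gene.
_TRANSCRIPT_FEATURE_TYPES = {
    "mRNA", "transcript", "primary_transcript", "ncRNA", "lnc_RNA",
    "antisense_RNA", "miRNA", "snoRNA", "snRNA", "scRNA", "rRNA", "tRNA",
    "misc_RNA", "guide_RNA", "RNase_P_RNA", "RNase_MRP_RNA", "Y_RNA",
    "telomerase_RNA", "vault_RNA", "V_gene_segment", "C_gene_segment",
    "D_gene_segment", "J_gene_segment",
}


class GFF3ParseError(ValueError):
    """Malformed GFF3 content; the message names the offending line."""


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent 1-based inclusive intervals, sorted output."""
    merged: list[tuple[int, int]] = []
    for start, stop in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            prev_start, prev_stop = merged[-1]
            merged[-1] = (prev_start, max(prev_stop, stop))
        else:
            merged.append((start, stop))
    return merged


@dataclass
class TranscriptModel:
    """One transcript: its exon intervals and derived mature length."""

    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        # Overlapping exons on malformed records are merged so that the
        # mature length never double-counts a base.
        self.exons = merge_intervals(self.exons)

    @property
    def mature_length(self) -> int:
        return sum(stop - start + 1 for start, stop in self.exons)


@dataclass
class GeneModel:
    """One gene: location, type, and its transcripts."""

    symbol: str
    chromosome: str
    start: int
    stop: int
    strand: str = "."
    gene_type: str = "other"
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def mature_length(self) -> int:
        return gene_length(self)

    def exonic_intervals(self) -> list[tuple[int, int]]:
        """Union of exon intervals across all transcripts (merged, sorted)."""
        if not self.transcripts:
            return [(self.start, self.stop)]
        return merge_intervals(
            iv for tx in self.transcripts for iv in tx.exons
        )


@dataclass
class GenomeLayout:
    """Ordered chromosome labels with lengths, plus a seqid alias map."""

    chromosomes: list[tuple[str, int]] = field(default_factory=list)
    alias_map: dict[str, str] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.chromosomes]

    def length_of(self, label: str) -> int:
        for lab, length in self.chromosomes:
            if lab == label:
                return length
        raise KeyError(label)


def gene_length(gene: GeneModel) -> int:
    """Gene size: the longest transcript's mature length.

    Genes without annotated transcripts fall back to the genomic span.
    """
    if gene.transcripts:
        return max(tx.mature_length for tx in gene.transcripts)
    return gene.stop - gene.start + 1


def normalize_chromosome_name(seqid: str, alias_map: Mapping[str, str]) -> str:
    """Map an accession-style seqid to its plain label; identity if unknown."""
    return alias_map.get(seqid, seqid)


def _load_tsv_pairs(name: str) -> list[tuple[str, ...]]:
    rows = []
    text = resources.files("ideotrack.data").joinpath(name).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(tuple(line.split("\t")))
    return rows


def load_human_alias_map() -> dict[str, str]:
    """Shipped seqid→label table for human assemblies (GRCh37/GRCh38)."""
    return {seqid: label for seqid, label in _load_tsv_pairs("chr_aliases_human.tsv")}


def load_biotype_map() -> dict[str, str]:
    """Shipped ``gene_biotype`` → closed gene-type vocabulary table."""
    return {bt: gt for bt, gt in _load_tsv_pairs("gene_biotype_map.tsv")}


def classify_gene_type(
    biotype: str | None,
    child_feature_types: Iterable[str] = (),
    biotype_map: Mapping[str, str] | None = None,
) -> str:
    """Collapse a ``gene_biotype`` (preferred) or child feature type into
    {mRNA, ncRNA, pseudogene, other}."""
    table = load_biotype_map() if biotype_map is None else biotype_map
    if biotype is not None:
        return table.get(biotype, "other")
    for ft in child_feature_types:
        if ft == "mRNA":
            return "mRNA"
        if ft in _TRANSCRIPT_FEATURE_TYPES:
            return "ncRNA"
    return "other"


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.rstrip(";").split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = unquote(value)
    return attrs


@dataclass
class _RawFeature:
    seqid: str
    ftype: str
    start: int
    stop: int
    strand: str
    attrs: dict[str, str]
    line_no: int


def parse_gff3(
    path: str | Path,
    alias_map: Mapping[str, str] | None = None,
    biotype_map: Mapping[str, str] | None = None,
) -> tuple[list[GeneModel], GenomeLayout]:
    """Parse a GFF3 file into gene models and a genome layout.

    Parameters
    ----------
    path
        GFF3 file. ``##sequence-region seqid start end`` pragmas supply
        chromosome lengths when present.
    alias_map
        Optional seqid→label map. When given it also acts as a whitelist:
        genes on seqids absent from it are dropped (with a logged count),
        which is how accession-style NCBI seqids are restricted to the
        canonical chromosomes.
    biotype_map
        Optional override of the shipped ``gene_biotype`` mapping table.

    Returns
    -------
    (genes, layout)
        Genes in file order; layout chromosomes in order of first appearance
        in pragmas (or in features when pragmas are absent).

    Raises
    ------
    GFF3ParseError
        On a malformed feature line, naming the line number.
    """
    biotypes = load_biotype_map() if biotype_map is None else biotype_map
    aliases = dict(alias_map) if alias_map is not None else {}

    pragma_regions: list[tuple[str, int]] = []  # (label, length)
    genes_raw: dict[str, _RawFeature] = {}  # gene ID -> feature
    gene_order: list[str] = []
    transcripts_raw: dict[str, tuple[str, _RawFeature]] = {}  # tx ID -> (gene ID, feat)
    exons_by_parent: dict[str, list[tuple[int, int]]] = {}
    child_types: dict[str, list[str]] = {}  # gene ID -> child feature types
    orphan_exons = 0
    dropped_seqids = 0

    with open(path, "rt", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    seqid = parts[1]
                    if alias_map is not None and seqid not in aliases:
                        continue
                    label = normalize_chromosome_name(seqid, aliases)
                    try:
                        length = int(parts[3])
                    except ValueError as exc:
                        raise GFF3ParseError(
                            f"line {line_no}: bad sequence-region pragma"
                        ) from exc
                    pragma_regions.append((label, length))
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFF3ParseError(
                    f"line {line_no}: expected 9 tab-separated columns, got {len(cols)}"
                )
            seqid, _source, ftype, start_s, stop_s, _score, strand, _phase, attr_s = cols
            try:
                start, stop = int(start_s), int(stop_s)
            except ValueError as exc:
                raise GFF3ParseError(
                    f"line {line_no}: non-integer coordinates {start_s!r}/{stop_s!r}"
                ) from exc
            if start > stop:
                raise GFF3ParseError(f"line {line_no}: start {start} > stop {stop}")
            attrs = _parse_attributes(attr_s)
            feat = _RawFeature(seqid, ftype, start, stop, strand, attrs, line_no)

            if ftype in _GENE_FEATURE_TYPES:
                fid = attrs.get("ID", f"__line{line_no}")
                genes_raw[fid] = feat
                gene_order.append(fid)
            elif ftype == "exon":
                parent = attrs.get("Parent")
                exons_by_parent.setdefault(parent, []).append((start, stop))
            else:
                parent = attrs.get("Parent")
                if parent is not None and "ID" in attrs:
                    transcripts_raw[attrs["ID"]] = (parent, feat)
                    child_types.setdefault(parent, []).append(ftype)

    # Attach exons to transcripts; exons whose Parent matches no transcript
    # (nor a gene) are counted and skipped.
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    for parent, exons in exons_by_parent.items():
        if parent in transcripts_raw:
            tx_exons.setdefault(parent, []).extend(exons)
        elif parent in genes_raw:
            # NCBI annotates some single-exon genes with exons parented
            # directly on the gene; model them as one implicit transcript.
            tx_exons.setdefault(f"{parent}__implicit", []).extend(exons)
            transcripts_raw.setdefault(
                f"{parent}__implicit", (parent, genes_raw[parent])
            )
        else:
            orphan_exons += len(exons)

    if orphan_exons:
        logger.warning("skipped %d exon(s) with unresolvable Parent", orphan_exons)

    tx_by_gene: dict[str, list[TranscriptModel]] = {}
    for tx_id, (gene_id, _feat) in transcripts_raw.items():
        exons = tx_exons.get(tx_id)
        if not exons:
            continue
        tx_by_gene.setdefault(gene_id, []).append(TranscriptModel(tx_id, exons))

    seen_symbols: dict[str, int] = {}
    genes: list[GeneModel] = []
    feature_seqid_order: list[str] = []
    for gene_id in gene_order:
        feat = genes_raw[gene_id]
        if alias_map is not None and feat.seqid not in aliases:
            dropped_seqids += 1
            continue
        chrom = normalize_chromosome_name(feat.seqid, aliases)
        if chrom not in feature_seqid_order:
            feature_seqid_order.append(chrom)
        symbol = feat.attrs.get("gene") or feat.attrs.get("Name") or gene_id
        n_seen = seen_symbols.get(symbol, 0)
        seen_symbols[symbol] = n_seen + 1
        if n_seen:
            logger.warning("duplicate gene symbol %r; keeping as %s_%d",
                           symbol, symbol, n_seen + 1)
            symbol = f"{symbol}_{n_seen + 1}"
        biotype = feat.attrs.get("gene_biotype")
        if biotype is None and feat.ftype == "pseudogene":
            biotype = "pseudogene"
        gene_type = classify_gene_type(
            biotype, child_types.get(gene_id, ()), biotypes
        )
        genes.append(GeneModel(
            symbol=symbol,
            chromosome=chrom,
            start=feat.start,
            stop=feat.stop,
            strand=feat.strand if feat.strand in "+-" else ".",
            gene_type=gene_type,
            transcripts=sorted(tx_by_gene.get(gene_id, []),
                               key=lambda tx: tx.transcript_id),
        ))

    if dropped_seqids:
        logger.info("dropped %d gene(s) on seqids absent from alias map",
                    dropped_seqids)

    if pragma_regions:
        chromosomes = pragma_regions
    else:
        # No pragmas: infer minimal lengths from gene extents.
        maxstop: dict[str, int] = {}
        for g in genes:
            maxstop[g.chromosome] = max(maxstop.get(g.chromosome, 0), g.stop)
        chromosomes = [(label, maxstop[label]) for label in feature_seqid_order]

    layout = GenomeLayout(chromosomes=chromosomes, alias_map=aliases)
    return genes, layout


def read_chrom_sizes(path: str | Path) -> list[tuple[str, int]]:
    """Read a plain two-column (label, length) chromosome-sizes file."""
    out = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"line {line_no}: expected 'label<TAB>length'")
            out.append((parts[0], int(parts[1])))
    return out
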