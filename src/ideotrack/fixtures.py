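"""Deterministic toy genomes, GFF3 annotations, and SAM alignments with a
known ground-truth count table.

The generator emulates exactly the structures the pipeline consumes: a
small multi-chromosome genome with genes carrying 1-3 transcripts of
distinct mature lengths, a fraction of gene pairs planted with overlapping
exons (to exercise union-mode ambiguity), and paired-end alignments placed
wholly inside single-gene exonic sequence (assigned), inside two-gene
overlap regions (ambiguous), or outside all exons (no_feature), plus decoy
records for every filter category. Running the real pipeline on the output
must reproduce the truth table exactly.

All randomness flows through a single numpy Generator so identical seeds
give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .gff_annotation import (
    GeneModel,
    GenomeLayout,
    TranscriptModel,
    merge_intervals,
)

#: Representative NCBI-style biotype per closed gene-type class; used when
#: writing fixture GFF3 so that re-parsing recovers the same gene_type.
_BIOTYPE_FOR_TYPE = {
    "mRNA": "protein_coding",
    "ncRNA": "lncRNA",
    "pseudogene": "pseudogene",
    "other": "misc_feature",
}

_GENE_TYPE_WEIGHTS = (("mRNA", 0.6), ("ncRNA", 0.2),
                      ("pseudogene", 0.1), ("other", 0.1))

#: Overlap planted between paired genes' exons (bp); large enough to hold
#: a read of the default length.
_PAIR_OVERLAP = 80


class FixtureError(ValueError):
    """Requested fixture is geometrically infeasible."""


@dataclass
class TruthTable:
    """Ground truth for one generated alignment file."""

    counts: dict[str, int] = field(default_factory=dict)
    no_feature: int = 0
    ambiguous: int = 0
    unmapped: int = 0
    secondary_or_supplementary: int = 0
    not_proper_pair: int = 0
    low_mapq: int = 0
    gene_types: dict[str, str] = field(default_factory=dict)


def _intersect(a: Sequence[tuple[int, int]],
               b: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if s <= e:
                out.append((s, e))
    return merge_intervals(out) if out else []


def _subtract(a: Sequence[tuple[int, int]],
              b: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intervals of ``a`` minus every interval of ``b`` (1-based inclusive)."""
    pieces = list(a)
    for bs, be in b:
        nxt = []
        for s, e in pieces:
            if be < s or bs > e:
                nxt.append((s, e))
                continue
            if s < bs:
                nxt.append((s, bs - 1))
            if e > be:
                nxt.append((be + 1, e))
        pieces = nxt
        if not pieces:
            break
    return pieces


def _random_transcripts(
    rng: np.random.Generator, n_tx: int, min_exon: int, max_exon: int,
) -> list[list[tuple[int, int]]]:
    """Exon layouts (gene-relative, 1-based) with distinct mature lengths."""
    layouts: list[list[tuple[int, int]]] = []
    seen_lengths: set[int] = set()
    attempts = 0
    while len(layouts) < n_tx:
        attempts += 1
        if attempts > 200:
            raise FixtureError("cannot draw transcripts with distinct lengths")
        n_exons = int(rng.integers(1, 5))
        pos = 1
        exons = []
        for i in range(n_exons):
            if i:
                pos += int(rng.integers(50, 301))  # intron
            length = int(rng.integers(min_exon, max_exon + 1))
            exons.append((pos, pos + length - 1))
            pos += length
        mature = sum(e - s + 1 for s, e in exons)
        if mature in seen_lengths:
            continue
        seen_lengths.add(mature)
        layouts.append(exons)
    return layouts


def random_genes(
    rng: np.random.Generator,
    n_chroms: int,
    n_genes: int,
    chrom_length: int = 300_000,
    overlap_fraction: float = 0.0,
) -> tuple[list[GeneModel], GenomeLayout]:
    """Place genes on toy chromosomes; a fraction of genes form pairs with
    overlapping exons (the second member overlaps the first by a fixed
    exonic window)."""
    if n_chroms < 1:
        raise FixtureError("need at least one chromosome")
    labels = [str(i + 1) for i in range(n_chroms)]
    layout = GenomeLayout(chromosomes=[(lab, chrom_length) for lab in labels])
    if n_genes == 0:
        return [], layout

    n_pairs = int(round(overlap_fraction * n_genes / 2))
    # Genes that start an overlapping pair (the partner follows immediately).
    pair_leaders: set[int] = set()
    i = 0
    while len(pair_leaders) < n_pairs and i < n_genes - 1:
        pair_leaders.add(i)
        i += 2

    genes: list[GeneModel] = []
    cursors = {lab: 1 for lab in labels}
    chrom_i = 0
    gi = 0
    while gi < n_genes:
        paired = gi in pair_leaders and gi + 1 < n_genes
        lab = labels[chrom_i % n_chroms]
        chrom_i += 1
        # Pair members get wide terminal exons so that, after carving out
        # the shared window, enough exclusive sequence remains for reads.
        min_exon = 200 if paired else 80
        members = 2 if paired else 1
        built: list[GeneModel] = []
        for m in range(members):
            sym = f"G{gi + 1:04d}"
            gtype = _weighted_choice(rng, _GENE_TYPE_WEIGHTS)
            n_tx = int(rng.integers(1, 4))
            layouts = _random_transcripts(rng, n_tx, min_exon, 400)
            if m == 0:
                offset = cursors[lab] + int(rng.integers(100, 1001))
            else:
                # Overlap the leader's last exon by a fixed window.
                leader = built[0]
                first_exon_start = min(s for lay in layouts for s, _ in [lay[0]])
                offset = leader.stop - _PAIR_OVERLAP + 2 - first_exon_start
            txs = [
                TranscriptModel(f"{sym}.t{k + 1}",
                                [(offset + s - 1, offset + e - 1)
                                 for s, e in lay])
                for k, lay in enumerate(layouts)
            ]
            exonic = merge_intervals(iv for tx in txs for iv in tx.exons)
            gene = GeneModel(
                symbol=sym, chromosome=lab,
                start=exonic[0][0], stop=exonic[-1][1],
                strand="+" if rng.random() < 0.5 else "-",
                gene_type=gtype, transcripts=txs,
            )
            if gene.stop > chrom_length:
                raise FixtureError(
                    f"gene {sym} does not fit on chromosome {lab} "
                    f"(stop {gene.stop} > {chrom_length}); too many genes"
                )
            built.append(gene)
            gi += 1
        genes.extend(built)
        cursors[lab] = max(g.stop for g in built) + 1
    return genes, layout


def _weighted_choice(rng: np.random.Generator,
                     weighted: Sequence[tuple[str, float]]) -> str:
    r = rng.random()
    acc = 0.0
    for value, w in weighted:
        acc += w
        if r < acc:
            return value
    return weighted[-1][0]


def write_gff3(genes: Sequence[GeneModel], layout: GenomeLayout,
               path: str | Path) -> None:
    """Serialize gene models as NCBI-dialect GFF3 (the parser's input)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for label, length in layout.chromosomes:
            fh.write(f"##sequence-region {label} 1 {length}\n")
        for gene in genes:
            gid = f"gene-{gene.symbol}"
            biotype = _BIOTYPE_FOR_TYPE[gene.gene_type]
            fh.write("\t".join([
                gene.chromosome, "fixture", "gene",
                str(gene.start), str(gene.stop), ".", gene.strand, ".",
                f"ID={gid};Name={gene.symbol};gene={gene.symbol};"
                f"gene_biotype={biotype}",
            ]) + "\n")
            tx_type = "mRNA" if gene.gene_type == "mRNA" else "transcript"
            for tx in gene.transcripts:
                tid = tx.transcript_id
                fh.write("\t".join([
                    gene.chromosome, "fixture", tx_type,
                    str(tx.exons[0][0]), str(tx.exons[-1][1]),
                    ".", gene.strand, ".",
                    f"ID={tid};Parent={gid}",
                ]) + "\n")
                for k, (s, e) in enumerate(tx.exons):
                    fh.write("\t".join([
                        gene.chromosome, "fixture", "exon",
                        str(s), str(e), ".", gene.strand, ".",
                        f"ID={tid}.e{k + 1};Parent={tid}",
                    ]) + "\n")


def write_layout(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for label, length in layout.chromosomes:
            fh.write(f"{label}\t{length}\n")


def make_genome(
    n_chroms: int,
    n_genes: int,
    seed: int,
    out_dir: str | Path,
    chrom_length: int = 300_000,
    overlap_fraction: float = 0.0,
) -> tuple[Path, Path, list[GeneModel]]:
    """Generate a toy genome; returns (gff3 path, layout path, gene models)."""
    rng = np.random.default_rng(seed)
    genes, layout = random_genes(rng, n_chroms, n_genes,
                                 chrom_length, overlap_fraction)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gff_path = out_dir / "annotation.gff3"
    layout_path = out_dir / "chrom.sizes"
    write_gff3(genes, layout, gff_path)
    write_layout(layout, layout_path)
    return gff_path, layout_path, genes


def _exclusive_regions(genes: Sequence[GeneModel]) -> dict[str, list[tuple[int, int]]]:
    """Per gene: exonic intervals overlapped by no other gene's exons."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom_genes in by_chrom.values():
        for g in chrom_genes:
            others = [iv for o in chrom_genes if o is not g
                      for iv in o.exonic_intervals()]
            out[g.symbol] = _subtract(g.exonic_intervals(), others)
    return out


def _overlap_regions(genes: Sequence[GeneModel]) -> list[tuple[str, int, int]]:
    """(chrom, start, stop) windows where exactly two genes' exons overlap."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    regions = []
    for chrom, chrom_genes in by_chrom.items():
        for i, a in enumerate(chrom_genes):
            for b in chrom_genes[i + 1:]:
                shared = _intersect(a.exonic_intervals(), b.exonic_intervals())
                # Exclude windows a third gene also touches: they would
                # produce a 3-way union, still ambiguous but harder to audit.
                others = [iv for o in chrom_genes if o is not a and o is not b
                          for iv in o.exonic_intervals()]
                for s, e in _subtract(shared, others):
                    regions.append((chrom, s, e))
    return regions


def _sam_pair(qname: str, chrom: str, p1: int, c1: str, p2: int, c2: str,
              mapq: int = 60) -> list[str]:
    f1, f2 = 99, 147  # paired, proper, mate-reverse / reverse, first / second
    tlen = p2 - p1 + 1
    return [
        f"{qname}\t{f1}\t{chrom}\t{p1}\t{mapq}\t{c1}\t=\t{p2}\t{tlen}\t*\t*",
        f"{qname}\t{f2}\t{chrom}\t{p2}\t{mapq}\t{c2}\t=\t{p1}\t{-tlen}\t*\t*",
    ]


def _place_pair(rng: np.random.Generator, regions: list[tuple[int, int]],
                read_len: int, chrom: str, qname: str,
                gapped_ok: bool = True) -> list[str] | None:
    """Both mates inside the given 1-based regions; occasional N-gapped CIGAR."""
    fits = [(s, e) for s, e in regions if e - s + 1 >= read_len]
    if not fits:
        return None
    lines = []
    positions = []
    cigars = []
    for _mate in range(2):
        s, e = fits[int(rng.integers(0, len(fits)))]
        span = e - s + 1
        gap = 20
        if gapped_ok and span >= read_len + gap and rng.random() < 0.2:
            a = read_len // 2
            b = read_len - a
            pos = s + int(rng.integers(0, span - read_len - gap + 1))
            cig = f"{a}M{gap}N{b}M"
        else:
            pos = s + int(rng.integers(0, span - read_len + 1))
            cig = f"{read_len}M"
        positions.append(pos)
        cigars.append(cig)
    p1, p2 = positions
    c1, c2 = cigars
    if p2 < p1:
        p1, p2, c1, c2 = p2, p1, c2, c1
    return _sam_pair(qname, chrom, p1, c1, p2, c2)


def make_alignments(
    genes: Sequence[GeneModel],
    layout: GenomeLayout,
    truth_counts: Mapping[str, int],
    n_no_feature: int = 0,
    n_ambiguous: int = 0,
    read_len: int = 50,
    seed: int = 0,
    path: str | Path = "reads.sam",
    n_unmapped: int = 0,
    n_secondary: int = 0,
    n_not_proper: int = 0,
    n_low_mapq: int = 0,
    shuffle: bool = True,
) -> tuple[Path, TruthTable]:
    """Write a SAM file whose union-mode counts are known by construction."""
    rng = np.random.default_rng(seed)
    path = Path(path)
    gene_by_symbol = {g.symbol: g for g in genes}
    exclusive = _exclusive_regions(genes)
    truth = TruthTable(gene_types={g.symbol: g.gene_type for g in genes})
    for g in genes:
        truth.counts[g.symbol] = 0

    records: list[list[str]] = []  # each item: the line(s) of one fragment
    frag_i = 0

    for symbol in truth_counts:
        if symbol not in gene_by_symbol:
            raise FixtureError(f"unknown gene symbol {symbol!r} in truth counts")
    for symbol, want in truth_counts.items():
        gene = gene_by_symbol[symbol]
        for _ in range(int(want)):
            frag_i += 1
            pair = _place_pair(rng, exclusive.get(symbol, []), read_len,
                               gene.chromosome, f"frag{frag_i:06d}")
            if pair is None:
                raise FixtureError(
                    f"no exclusive exonic window of >= {read_len} bp for "
                    f"gene {symbol}; cannot plant an assigned fragment"
                )
            records.append(pair)
            truth.counts[symbol] += 1

    if n_ambiguous:
        overlaps = [(c, s, e) for c, s, e in _overlap_regions(genes)
                    if e - s + 1 >= read_len]
        if not overlaps:
            raise FixtureError(
                f"no two-gene exonic overlap of >= {read_len} bp; cannot "
                "plant ambiguous fragments"
            )
        for _ in range(int(n_ambiguous)):
            frag_i += 1
            chrom, s, e = overlaps[int(rng.integers(0, len(overlaps)))]
            pair = _place_pair(rng, [(s, e)], read_len, chrom,
                               f"frag{frag_i:06d}", gapped_ok=False)
            records.append(pair)
            truth.ambiguous += 1

    if n_no_feature:
        all_exonic: dict[str, list[tuple[int, int]]] = {}
        for g in genes:
            all_exonic.setdefault(g.chromosome, []).extend(g.exonic_intervals())
        deserts = []
        for label, length in layout.chromosomes:
            free = _subtract([(1, length)],
                             merge_intervals(all_exonic.get(label, [(0, 0)]))
                             if all_exonic.get(label) else [])
            deserts.extend((label, s, e) for s, e in free
                           if e - s + 1 >= read_len)
        if not deserts:
            raise FixtureError("no exon-free window large enough for "
                               "no_feature fragments")
        for _ in range(int(n_no_feature)):
            frag_i += 1
            chrom, s, e = deserts[int(rng.integers(0, len(deserts)))]
            pair = _place_pair(rng, [(s, e)], read_len, chrom,
                               f"frag{frag_i:06d}", gapped_ok=False)
            records.append(pair)
            truth.no_feature += 1

    # Decoy records exercising every filter category (dropped upstream of
    # counting, so they never touch the truth counts).
    first_chrom = layout.chromosomes[0][0]
    for _ in range(int(n_unmapped)):
        frag_i += 1
        records.append([f"decoy{frag_i:06d}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*"])
        truth.unmapped += 1
    for _ in range(int(n_secondary)):
        frag_i += 1
        records.append([
            f"decoy{frag_i:06d}\t355\t{first_chrom}\t1\t60\t{read_len}M\t=\t1\t0\t*\t*"
        ])
        truth.secondary_or_supplementary += 1
    for _ in range(int(n_not_proper)):
        frag_i += 1
        records.append([
            f"decoy{frag_i:06d}\t65\t{first_chrom}\t1\t60\t{read_len}M\t=\t1\t0\t*\t*"
        ])
        truth.not_proper_pair += 1
    for _ in range(int(n_low_mapq)):
        frag_i += 1
        records.append([
            f"decoy{frag_i:06d}\t99\t{first_chrom}\t1\t0\t{read_len}M\t=\t1\t0\t*\t*"
        ])
        truth.low_mapq += 1

    if shuffle and records:
        order = rng.permutation(len(records))
        records = [records[i] for i in order]

    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for label, length in layout.chromosomes:
            fh.write(f"@SQ\tSN:{label}\tLN:{length}\n")
        for lines in records:
            for line in lines:
                fh.write(line + "\n")
    return path, truth


def random_truth_counts(
    rng: np.random.Generator,
    genes: Sequence[GeneModel],
    max_count: int = 10,
    zero_fraction: float = 0.2,
) -> dict[str, int]:
    """Draw a plausible truth table: some silent genes, the rest small counts."""
    out = {}
    for g in genes:
        if rng.random() < zero_fraction:
            out[g.symbol] = 0
        else:
            out[g.symbol] = int(rng.integers(1, max_count + 1))
    return out
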