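"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the implementation's data paths: the CIGAR
oracle walks the string base by base, the counting oracle tests every
fragment block against every exon interval of every gene, and the facet
oracle is a plain predicate scan.
"""

from __future__ import annotations

import re

import numpy as np
import pytest

from ideotrack.annot_document import DOCUMENT_KEYS, AnnotationDocument, GENE_TYPE_CODES
from ideotrack.gff_annotation import GenomeLayout


# ---------------------------------------------------------------- oracles

def cigar_blocks_oracle(cigar: str, pos: int) -> list[tuple[int, int]]:
    """Reference blocks via per-base walking, grouped afterwards."""
    if cigar == "*":
        return []
    covered: list[int] = []
    ref = pos
    for length_s, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        length = int(length_s)
        if op in "M=XD":
            covered.extend(range(ref, ref + length))
            ref += length
        elif op == "N":
            ref += length
    blocks: list[tuple[int, int]] = []
    for base in covered:
        if blocks and base == blocks[-1][1] + 1:
            blocks[-1] = (blocks[-1][0], base)
        else:
            blocks.append((base, base))
    return blocks


def count_fragments_oracle(fragments, genes):
    """All-pairs union-mode counter.

    ``fragments``: iterable of (rname, [(start, stop), ...]) with all blocks
    of both mates pooled. Returns (counts dict incl. zeros, no_feature,
    ambiguous).
    """
    counts = {g.symbol: 0 for g in genes}
    no_feature = ambiguous = 0
    for rname, blocks in fragments:
        hits = set()
        for g in genes:
            if g.chromosome != rname:
                continue
            for bs, be in blocks:
                if any(bs <= ge and be >= gs for gs, ge in g.exonic_intervals()):
                    hits.add(g.symbol)
                    break
        if len(hits) == 1:
            counts[hits.pop()] += 1
        elif not hits:
            no_feature += 1
        else:
            ambiguous += 1
    return counts, no_feature, ambiguous


def facet_filter_oracle(doc: AnnotationDocument, state) -> list[tuple[str, list]]:
    """Predicate scan returning surviving (chrom, row) pairs."""
    tier_idx = doc.keys.index("expression-level")
    type_idx = doc.keys.index("gene-type")
    out = []
    for block in doc.annots:
        for row in block["annots"]:
            if state.gene_type is not None and row[type_idx] not in state.gene_type:
                continue
            if (state.expression_level is not None
                    and row[tier_idx] not in state.expression_level):
                continue
            if state.chromosome is not None and block["chr"] not in state.chromosome:
                continue
            out.append((block["chr"], row))
    return out


# ------------------------------------------------------------- generators

def random_document(
    rng: np.random.Generator,
    n_rows: int,
    n_chroms: int = 2,
    chrom_len: int = 50_000,
    n_tiers: int = 7,
) -> tuple[AnnotationDocument, GenomeLayout]:
    """A schema-valid random document plus its matching layout."""
    labels = [str(i + 1) for i in range(n_chroms)]
    rows_by_chrom: dict[str, list] = {lab: [] for lab in labels}
    for i in range(n_rows):
        lab = labels[int(rng.integers(0, n_chroms))]
        start = int(rng.integers(1, chrom_len + 1))
        length = int(rng.integers(1, 501))
        tier = int(rng.integers(0, n_tiers + 1))
        code = int(rng.integers(0, 4))
        rows_by_chrom[lab].append([f"G{i + 1:05d}", start, length, tier, code])
    annots = [{"chr": lab, "annots": sorted(rows_by_chrom[lab],
                                            key=lambda r: (r[1], r[0]))}
              for lab in labels]
    doc = AnnotationDocument(
        keys=list(DOCUMENT_KEYS),
        annots=annots,
        metadata={
            "assembly": "unknown",
            "gene-type-legend": {str(c): n for n, c in GENE_TYPE_CODES.items()},
            "tier-count": n_tiers,
            "tier-thresholds": [],
            "chromosome-lengths": {lab: chrom_len for lab in labels},
        },
    )
    layout = GenomeLayout(chromosomes=[(lab, chrom_len) for lab in labels])
    return doc, layout


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170428)


@pytest.fixture
def toy_gff3(tmp_path):
    """One protein-coding gene, one mRNA, exons 1001-1100 and 2001-2200."""
    text = "\n".join([
        "##gff-version 3",
        "##sequence-region 1 1 50000",
        "1\ttest\tgene\t1001\t2200\t.\t+\t.\t"
        "ID=gene-ALPHA;Name=ALPHA;gene=ALPHA;gene_biotype=protein_coding",
        "1\ttest\tmRNA\t1001\t2200\t.\t+\t.\tID=rna-A1;Parent=gene-ALPHA",
        "1\ttest\texon\t1001\t1100\t.\t+\t.\tID=e1;Parent=rna-A1",
        "1\ttest\texon\t2001\t2200\t.\t+\t.\tID=e2;Parent=rna-A1",
        "",
    ])
    path = tmp_path / "toy.gff3"
    path.write_text(text)
    return path
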