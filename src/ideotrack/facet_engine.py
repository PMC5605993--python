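"""Crossfilter-style faceted filtering and windowed histogram binning.

A facet state holds, per dimension (gene type, expression tier,
chromosome), either the full set ("all") or an explicit allowed subset —
possibly empty, which selects nothing. A row survives when it satisfies
every dimension (conjunction). Facet counts follow the crossfilter
convention: each dimension's per-value tallies are computed under the
OTHER dimensions' filters only, so the UI can show what selecting a value
would yield.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

from .annot_document import AnnotationDocument
from .gff_annotation import GenomeLayout

_ALL = None  # sentinel: dimension unfiltered

DEFAULT_WINDOW_BP = 3_000_000


@dataclass
class FacetState:
    """Active filters; ``None`` means "all" for that dimension.

    An empty set is a real filter that selects nothing — distinct from all.
    """

    gene_type: set[int] | None = _ALL  # gene-type codes
    expression_level: set[int] | None = _ALL  # tiers
    chromosome: set[str] | None = _ALL  # labels

    def dimensions(self) -> dict[str, set | None]:
        return {
            "gene-type": self.gene_type,
            "expression-level": self.expression_level,
            "chromosome": self.chromosome,
        }


@dataclass
class HistogramTrack:
    """Fixed-window bin counts per chromosome (bins of ``window_bp``)."""

    window_bp: int
    bins: dict[str, list[int]] = field(default_factory=dict)
    clamped: int = 0  # rows whose start lay beyond the chromosome length

    @property
    def total(self) -> int:
        return sum(sum(b) for b in self.bins.values())


def _row_values(doc: AnnotationDocument):
    """Yield (chrom, tier, type_code, row) for every row."""
    tier_idx = doc.keys.index("expression-level")
    type_idx = doc.keys.index("gene-type")
    for block in doc.annots:
        chrom = block["chr"]
        for row in block["annots"]:
            yield chrom, row[tier_idx], row[type_idx], row


def _validate_state(doc: AnnotationDocument, state: FacetState) -> None:
    legend = doc.metadata.get("gene-type-legend", {})
    n_tiers = doc.metadata.get("tier-count")
    labels = {block["chr"] for block in doc.annots}
    if state.gene_type is not _ALL and legend:
        for code in state.gene_type:
            if str(code) not in legend:
                raise ValueError(f"dimension gene-type: unknown code {code!r}")
    if state.expression_level is not _ALL and n_tiers is not None:
        for tier in state.expression_level:
            if not 0 <= tier <= n_tiers:
                raise ValueError(
                    f"dimension expression-level: unknown tier {tier!r}")
    if state.chromosome is not _ALL:
        for label in state.chromosome:
            if label not in labels:
                raise ValueError(f"dimension chromosome: unknown label {label!r}")


def apply_filters(
    doc: AnnotationDocument, state: FacetState,
) -> tuple[AnnotationDocument, dict[str, dict]]:
    """Filter a document and compute crossfilter facet counts.

    Returns a new document (the input is never modified) whose rows satisfy
    all active dimensions, plus per-dimension value tallies computed under
    the other dimensions' filters.
    """
    _validate_state(doc, state)
    dims = state.dimensions()

    def passes(chrom, tier, code, skip: str | None = None) -> bool:
        checks = {
            "gene-type": (dims["gene-type"], code),
            "expression-level": (dims["expression-level"], tier),
            "chromosome": (dims["chromosome"], chrom),
        }
        for name, (allowed, value) in checks.items():
            if name == skip or allowed is _ALL:
                continue
            if value not in allowed:
                return False
        return True

    facet_counts: dict[str, dict] = {
        "gene-type": {}, "expression-level": {}, "chromosome": {},
    }
    filtered_blocks = []
    for block in doc.annots:
        filtered_blocks.append({"chr": block["chr"], "annots": []})

    tier_idx = doc.keys.index("expression-level")
    type_idx = doc.keys.index("gene-type")
    block_index = {block["chr"]: i for i, block in enumerate(doc.annots)}

    for chrom, tier, code, row in _row_values(doc):
        if passes(chrom, tier, code):
            filtered_blocks[block_index[chrom]]["annots"].append(list(row))
        # Crossfilter tallies: exclude each dimension's own filter.
        if passes(chrom, tier, code, skip="gene-type"):
            facet_counts["gene-type"][code] = facet_counts["gene-type"].get(code, 0) + 1
        if passes(chrom, tier, code, skip="expression-level"):
            facet_counts["expression-level"][tier] = (
                facet_counts["expression-level"].get(tier, 0) + 1)
        if passes(chrom, tier, code, skip="chromosome"):
            facet_counts["chromosome"][chrom] = (
                facet_counts["chromosome"].get(chrom, 0) + 1)

    out = AnnotationDocument(
        keys=list(doc.keys),
        annots=filtered_blocks,
        metadata=copy.deepcopy(doc.metadata),
    )
    return out, facet_counts


def histogram(
    doc: AnnotationDocument,
    layout: GenomeLayout,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> HistogramTrack:
    """Bin every row once by start position into fixed windows.

    Bin index is ``floor((start - 1) / window_bp)``; a start beyond the
    chromosome length is clamped into the last bin and counted.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    lengths = dict(layout.chromosomes)
    start_idx = doc.keys.index("start")
    track = HistogramTrack(window_bp=window_bp)
    for block in doc.annots:
        chrom = block["chr"]
        if chrom not in lengths:
            raise ValueError(f"chromosome {chrom!r} absent from layout")
        n_bins = max(1, math.ceil(lengths[chrom] / window_bp))
        bins = track.bins.setdefault(chrom, [0] * n_bins)
        for row in block["annots"]:
            idx = (row[start_idx] - 1) // window_bp
            if idx >= n_bins:
                idx = n_bins - 1
                track.clamped += 1
            bins[idx] += 1
    return track
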