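"""The compact per-chromosome annotation document.

This is the JSON structure the chromosome-ideogram visualization consumes:
field names are declared once in ``keys`` and every gene is a bare value
array, grouped into per-chromosome blocks, which compresses well and keeps
genome-wide documents small. Expression is carried as a small integer tier
(0 = not expressed; 1..n quantile bins over nonzero TPM) so that the
consumer can facet on it directly.
"""

from __future__ import annotations

import gzip
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .gff_annotation import GENE_TYPES, GeneModel, GenomeLayout
from .quantify import ExpressionTable

logger = logging.getLogger(__name__)

#: Declared row schema: [symbol, start, length, expression tier, type code].
DOCUMENT_KEYS = ["name", "start", "length", "expression-level", "gene-type"]

#: Stable gene-type codes; the legend is always embedded in metadata.
GENE_TYPE_CODES = {name: code for code, name in enumerate(GENE_TYPES)}

DEFAULT_N_TIERS = 7


class DocumentSchemaError(ValueError):
    """The parsed JSON violates the annotation-document schema."""


@dataclass
class TierScheme:
    """Quantile binning of nonzero TPM into ``n_tiers`` expression levels.

    ``thresholds[i]`` is the upper-inclusive TPM bound of tier ``i+1``;
    zero TPM is always tier 0.
    """

    n_tiers: int
    thresholds: list[float] = field(default_factory=list)


@dataclass
class AnnotationDocument:
    keys: list[str] = field(default_factory=lambda: list(DOCUMENT_KEYS))
    annots: list[dict] = field(default_factory=list)  # {"chr": label, "annots": rows}
    metadata: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return sum(len(block["annots"]) for block in self.annots)

    def iter_rows(self):
        """Yield (chromosome label, row) pairs in document order."""
        for block in self.annots:
            for row in block["annots"]:
                yield block["chr"], row


def assign_tiers(
    expr: ExpressionTable | Mapping[str, float],
    n_tiers: int = DEFAULT_N_TIERS,
) -> tuple[dict[str, int], TierScheme]:
    """Assign each gene an expression tier.

    Zero TPM maps to tier 0. Nonzero TPM values are split into quantile
    bins 1..n_tiers, upper-inclusive: a gene's tier is ``ceil(F(v) *
    n_tiers)`` where ``F`` is the empirical CDF over nonzero values. Ties
    share a tier, assignment is monotone in TPM, and the gene(s) with the
    largest TPM always land in the top tier.
    """
    if n_tiers < 1:
        raise ValueError("n_tiers must be >= 1")
    values = expr.tpm if isinstance(expr, ExpressionTable) else dict(expr)
    nonzero = sorted(v for v in values.values() if v > 0)
    tiers: dict[str, int] = {}
    if not nonzero:
        return {sym: 0 for sym in values}, TierScheme(n_tiers, [])

    import bisect

    n = len(nonzero)
    for sym, v in values.items():
        if v <= 0:
            tiers[sym] = 0
        else:
            rank = bisect.bisect_right(nonzero, v)  # values <= v
            tiers[sym] = max(1, math.ceil(rank / n * n_tiers))

    # Upper-inclusive tier bounds; empty tiers inherit the previous bound.
    thresholds: list[float] = []
    upper = nonzero[0]
    for i in range(1, n_tiers):
        in_tier = [v for v in nonzero if math.ceil(
            bisect.bisect_right(nonzero, v) / n * n_tiers) <= i]
        if in_tier:
            upper = max(in_tier)
        thresholds.append(upper)
    return tiers, TierScheme(n_tiers, thresholds)


def build_document(
    genes: list[GeneModel],
    expr: ExpressionTable | None,
    tiers: Mapping[str, int],
    layout: GenomeLayout,
    scheme: TierScheme | None = None,
    metadata: Mapping | None = None,
) -> AnnotationDocument:
    """Assemble the per-chromosome document from gene models and tiers.

    One row per gene: ``[symbol, start, stop - start + 1, tier, type code]``,
    sorted by start within each chromosome; chromosomes follow layout order.
    Genes on chromosomes absent from the layout are dropped (logged count);
    genes without an expression record get tier 0.
    """
    labels = layout.labels
    by_chrom: dict[str, list[list]] = {label: [] for label in labels}
    dropped = 0
    for gene in genes:
        if gene.chromosome not in by_chrom:
            dropped += 1
            continue
        tier = int(tiers.get(gene.symbol, 0))
        row = [
            gene.symbol,
            gene.start,
            gene.stop - gene.start + 1,
            tier,
            GENE_TYPE_CODES.get(gene.gene_type, GENE_TYPE_CODES["other"]),
        ]
        by_chrom[gene.chromosome].append(row)
    if dropped:
        logger.warning("dropped %d gene(s) on chromosomes absent from layout",
                       dropped)

    n_tiers = scheme.n_tiers if scheme is not None else DEFAULT_N_TIERS
    meta = {
        "assembly": "unknown",
        "gene-type-legend": {str(code): name for name, code in GENE_TYPE_CODES.items()},
        "tier-count": n_tiers,
        "tier-thresholds": list(scheme.thresholds) if scheme is not None else [],
        "coordinates": "1-based-start, length = stop - start + 1",
        "chromosome-lengths": {label: layout.length_of(label) for label in labels},
    }
    if metadata:
        meta.update(metadata)

    annots = []
    for label in labels:
        rows = sorted(by_chrom[label], key=lambda r: (r[1], r[0]))
        annots.append({"chr": label, "annots": rows})
    return AnnotationDocument(keys=list(DOCUMENT_KEYS), annots=annots,
                              metadata=meta)


def serialize(doc: AnnotationDocument, path: str | Path,
              compress: bool | None = None) -> None:
    """Write the document as compact JSON, gzip-compressed on request
    (or when the path ends in ``.gz``). Output is deterministic."""
    path = Path(path)
    if compress is None:
        compress = path.suffix == ".gz"
    payload = {"keys": doc.keys, "annots": doc.annots, "metadata": doc.metadata}
    text = json.dumps(payload, separators=(",", ":"), sort_keys=False)
    data = text.encode("utf-8")
    if compress:
        # mtime=0 and an empty embedded filename keep the gzip bytes
        # identical across runs and paths.
        with open(path, "wb") as fh:
            with gzip.GzipFile(filename="", fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(data)
    else:
        path.write_bytes(data)


def parse(path: str | Path) -> AnnotationDocument:
    """Read a serialized document back, validating the schema."""
    path = Path(path)
    raw = path.read_bytes()
    if raw[:2] == b"\x1f\x8b":
        raw = gzip.decompress(raw)
    payload = json.loads(raw.decode("utf-8"))
    for key in ("keys", "annots", "metadata"):
        if key not in payload:
            raise DocumentSchemaError(f"missing top-level field {key!r}")
    keys = payload["keys"]
    if not isinstance(keys, list) or not keys:
        raise DocumentSchemaError("'keys' must be a non-empty list")
    width = len(keys)
    legend = payload["metadata"].get("gene-type-legend", {})
    n_tiers = payload["metadata"].get("tier-count")
    try:
        start_idx = keys.index("start")
        length_idx = keys.index("length")
        tier_idx = keys.index("expression-level")
        type_idx = keys.index("gene-type")
    except ValueError as exc:
        raise DocumentSchemaError(f"required key missing from 'keys': {exc}")
    for b, block in enumerate(payload["annots"]):
        if "chr" not in block or "annots" not in block:
            raise DocumentSchemaError(f"block {b}: missing 'chr' or 'annots'")
        for r, row in enumerate(block["annots"]):
            if len(row) != width:
                raise DocumentSchemaError(
                    f"block {b} row {r}: {len(row)} values for {width} keys")
            if row[start_idx] < 1:
                raise DocumentSchemaError(f"block {b} row {r}: start < 1")
            if row[length_idx] < 1:
                raise DocumentSchemaError(f"block {b} row {r}: length < 1")
            if n_tiers is not None and not (0 <= row[tier_idx] <= n_tiers):
                raise DocumentSchemaError(
                    f"block {b} row {r}: tier {row[tier_idx]} outside 0..{n_tiers}")
            if legend and str(row[type_idx]) not in legend:
                raise DocumentSchemaError(
                    f"block {b} row {r}: gene-type code {row[type_idx]} not in legend")
    return AnnotationDocument(keys=keys, annots=payload["annots"],
                              metadata=payload["metadata"])
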