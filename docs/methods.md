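# Methods

## Gene model

Genes are read from GFF3 (NCBI dialect: `gene`/`pseudogene` records with
child transcript features and `exon` children linked by `ID`/`Parent`).
All coordinates are kept 1-based inclusive end to end — the GFF3
convention — with conversions only at serialization boundaries, so there is
a single place where off-by-one errors could occur rather than many.

A transcript's **mature length** is the sum of its exon lengths after
merging overlapping exon records (a malformed annotation must not
double-count a base). A gene's length, used for TPM normalization, is the
**longest transcript's mature length**; the exon sum includes UTRs, the
standard choice for TPM, since restricting to CDS would bias short-UTR
genes. Genes without annotated transcripts fall back to their genomic span.

Gene types collapse to a closed four-class vocabulary — `mRNA`, `ncRNA`,
`pseudogene`, `other` — via a shipped, editable `gene_biotype` mapping
table (child feature type as fallback when the attribute is absent). A
closed set keeps the document's integer type codes stable across
annotation releases. Duplicate gene symbols are kept and suffixed
(`SYM`, `SYM_2`, …) at parse time so counts, TPM and document rows share
one key space; a silent overwrite would lose data.

Chromosome naming: accession-style seqids (e.g. RefSeq `NC_...`) are
mapped to plain labels through an alias table; the shipped human table
covers GRCh37 and GRCh38. When an alias map is supplied it doubles as a
whitelist — genes on unlisted scaffolds are dropped with a logged count.

## Alignment filtering

Only properly paired (flag `0x2`), primary, mapped records with MAPQ ≥ 10
are counted. The MAPQ floor of 10 is the common default of gene-level
counting tools; it removes multi-mapping reads that would otherwise inflate
ambiguity. Filter drops are attributed to exactly one category in the
fixed priority order *unmapped → secondary/supplementary → not properly
paired → low MAPQ*, making the conservation identity
`total = kept + drops` deterministic. Input need not be coordinate- or
name-sorted: correctness comes from interval lookup and qname buffering,
not record order.

Assembly detection fingerprints the `@SQ` (name, length) pairs against
shipped canonical chromosome lengths for GRCh37/GRCh38. An assembly is
reported only when at least one canonical chromosome matches and none
contradicts, and only when exactly one assembly satisfies that — e.g. a
header containing only the mitochondrial chromosome (identical length in
both builds) yields `unknown`, never a guess.

## Union-mode counting

The counting unit is the **fragment**: all records sharing a query name
(both mates of a pair) pooled, because filtering to properly paired reads
implies pair semantics — counting mates separately would double-count.
Aligned reference blocks come from the CIGAR string (`M/=/X/D` extend a
block, `N` splits it, `I/S/H/P` consume no reference), so spliced reads
overlap only their exonic landing sites. Overlap is evaluated against each
gene's **exonic interval union** (not its genomic span), matching
union-mode counting against exon features; an interval tree per chromosome
makes lookup independent of position sorting.

Per fragment, the set of overlapped genes decides the outcome: exactly one
→ that gene; none → `no_feature`; several → `ambiguous`. No fractional
rescue of ties — counts stay integral and
`assigned + no_feature + ambiguous = fragments` holds exactly on every
input. Fragments on chromosomes absent from the annotation count as
`no_feature` with a separate audit counter. Strandedness defaults to
unstranded (`--stranded {yes,no,reverse}` available), the safe choice when
the library protocol is unknown.

## TPM

`rate_i = count_i / length_i`; `TPM_i = 1e6 · rate_i / Σ rates`; all-zero
counts give all-zero TPM rather than NaN. Rates are accumulated in sorted
symbol order so the floating-point total — and hence every TPM value and
downstream byte of the document — is independent of count-table insertion
order. Σ TPM = 10⁶ holds to ~1e-9 relative (double-precision summation
over ≤ tens of thousands of genes).

## Expression tiers

The document stores a small integer tier rather than a raw TPM: zero TPM
is tier 0, and nonzero values are split into `n_tiers` (default 7)
quantile bins, assigned as `tier = ceil(F(v) · n_tiers)` with `F` the
empirical CDF over nonzero values. This rank-based rule is upper-inclusive
(the maximum always lands in the top tier, a single expressed gene gets
tier `n_tiers`), monotone in TPM, gives equal tiers to ties, and reduces to
the rank permutation when `n_tiers` equals the number of distinct values.
Reported thresholds are each tier's largest member (empty tiers inherit
the previous bound), so they are non-decreasing by construction. Seven
tiers keep the color palette of the downstream track readable; the value
is a display choice, not a statistical one.

## Annotation document

Keyed-array JSON: `keys` declared once, one block per chromosome in layout
order, one row per gene `[symbol, start, length, tier, type code]` sorted
by start (symbol as tie-break). `start` is 1-based and
`length = stop − start + 1`, stated in the embedded metadata so consumers
can adapt. Metadata also carries the assembly label, the gene-type legend,
tier count and thresholds, and chromosome lengths — parsing needs nothing
positional beyond `keys`. Serialization is compact (no insignificant
whitespace), and gzip output pins mtime 0 and an empty embedded filename,
so identical inputs give byte-identical files; the pipeline as a whole is
deterministic (no timestamps anywhere in the output).

## Faceting and histogram

Filtering is conjunctive over three dimensions (gene-type codes, tiers,
chromosome labels); an explicitly empty allowed-set selects nothing and is
distinct from "all". Facet counts follow the crossfilter convention — each
dimension's per-value tallies are computed under the *other* dimensions'
filters — which is what an interactive facet UI needs to show "what would
I get if I clicked this". Histogram binning keys each row by its **start
position** only (`bin = floor((start − 1) / window)`): one row, one bin,
so bin totals equal the filtered row count exactly; midpoint or
span-overlap binning would break that conservation. Starts beyond the
chromosome length are clamped into the last bin and counted. The default
window of 3 Mbp yields a few dozen bars on a large human chromosome.

## Synthetic data generator

`ideotrack simulate` (module `ideotrack.fixtures`) builds what the tests
and the acceptance script run on: toy chromosomes (default 300 kbp) with
non-overlapping genes of 1–3 transcripts with distinct mature lengths,
plus a configurable fraction of gene *pairs* planted with an 80 bp exonic
overlap; paired-end fragments (50 bp mates, flags 99/147, occasional
`N`-gapped CIGARs) placed wholly inside single-gene exclusive exonic
sequence (assigned), inside two-gene overlap windows (ambiguous), or in
exon-free sequence (no_feature); and decoy records for every filter
category. All randomness flows through one numpy generator, so a seed
fixes every output byte. Requests that are geometrically impossible (a
gene that cannot fit, an ambiguous fragment without any overlap window)
raise rather than degrade.

What the generator does **not** emulate: sequencing errors and quality
strings, realistic insert-size and coverage distributions, multi-mapping,
splice-aware alignment artifacts, or duplicate reads. Passing the
recovery tests therefore shows the bookkeeping — filtering, pairing,
overlap resolution, normalization, serialization — is exact; it does not
validate behavior under aligner noise or annotation errors on real data.

## Problem sizes

The default verification sizes — fixtures of up to 50 genes and ~500
fragments, 200 counting fixtures against a brute-force all-pairs oracle,
25 end-to-end seeds, 100 random documents of up to 10,000 rows — were
chosen so the complete suite exercises every code path in well under a
minute on one core while keeping the brute-force oracles (quadratic by
design) tractable.

## Known limitations

- GFF3 only (no GTF); exons parented directly on a gene are modeled as one
  implicit transcript, other orphan exons are skipped with a counter.
- BAM input requires pysam; SAM text is the contract.
- Assembly fingerprints ship for GRCh37/GRCh38 only; other genomes report
  `unknown` (counting is unaffected).
- No transcript-level quantification, EM multi-mapper resolution, or
  duplicate marking; ambiguous fragments are reported, never rescued.
- The tier scheme is a visualization binning, not a normalization across
  samples; documents from different runs share tier *semantics* but not
  comparable thresholds.
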