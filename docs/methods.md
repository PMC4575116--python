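# Methods

## Scope and data model

`annoweave` reconciles two gene annotations of the same assembly — a legacy
set ("v1") and a candidate set — into an updated annotation, then accounts
for every change.  Everything operates on a three-level hierarchy
(`AnnotationSet` → `GeneModel` → `Transcript` → exon/CDS intervals).
Coordinates are 1-based inclusive on disk (GFF3) and 0-based half-open in
memory; the conversion happens only at the I/O boundary, so all interval
arithmetic is free of inclusive-endpoint corner cases.  A gene's span is
always the exact extent of its transcript exons, and genes written in older
GFF dialects without mRNA lines receive one implicit transcript.

Protein length is `floor(total CDS nt / 3)` with no special treatment of
stop codons.  Whether a published protein length includes the stop codon is
rarely stated; this floor rule is the package's convention, applied
consistently on both sides of every comparison, so arbitration decisions
depend only on length *differences* and are insensitive to the convention.

## Pipeline stages and their parameters

| parameter | default | meaning |
|---|---|---|
| `overlap_threshold` | 0.30 | minimum overlap as a fraction of the shorter model |
| `min_support_reads` | 5 | reads needed to call a model expressed |
| `rbh_max_e` | 0.001 | e-value cutoff for reciprocal best hits |
| `sd_multiplier` | 1.0 | width of the length-difference outlier band |
| `same_strand_overlap` | on | whether overlap requires matching strands |
| `overlap_mode` | span | gene extent vs exon-union overlap length |
| `id_start`, `id_step`, `id_pad_width` | 10, 10, 5 | locus numbering convention |
| `n_anchored_scaffolds` | 8 | scaffolds named with G rather than U |
| `arbitration_species` | A. thaliana, C. rubella | the two outgroups used in arbitration |

The 30 % / 5-read / e ≤ 0.001 / ±1 SD defaults are the published update
procedure's stated thresholds; the rest are conventions chosen here.

**Overlap** is measured on gene genomic extents by default.  The source
procedure says only "overlap with respect to the shorter gene model"; span
overlap is the weaker (more inclusive) reading and the cheaper one, and an
exon-union mode is available behind `overlap_mode` for intron-dominated
loci.  Overlap across strands is off by default — annotation merges are
normally strand-aware — with a flag to disable, and unstranded features
match either strand.

**Arbitration** pairs legacy and updated proteins through overlap
components with exactly one updated member (this covers one-to-one loci
and merges, where several legacy models oppose a single updated model, so
one replaced model can re-introduce several legacy models).  The outlier
band is `mean(d) ± 1·SD(d)` over signed differences `d = len_v2 − len_v1`
with the sample SD (n−1); the band is *not* centred at zero, which is the
literal reading of "outside ± SD of the difference distribution".
"Outside" is strict, so a degenerate distribution (SD = 0) flags nothing,
and fewer than two pairs is an error.  Replacement requires both outgroup
lengths to be *strictly* closer to the legacy length; exact ties keep the
updated model (conservative: prefer the newer annotation).  Re-introduced
legacy models carry a `.r` id suffix internally so the change graph never
sees one identifier on both sides; systematic renaming erases the suffix.

**Deduplication** calls two models redundant when they share scaffold and
strand and the exon-chain set of the model with fewer transcripts is
contained (at exact coordinates) in the other's.  Published procedures
typically remove "redundant models" without defining the rule;
exact-structure containment is the only reading that cannot delete genuine
information.  The keeper is chosen by source priority
(version2 > version1 > augustus > cufflinks), ties by smaller id.

**Change accounting** takes connected components of the bipartite overlap
graph (union-find, deterministic ordering).  `split` means one legacy
model vs ≥ 2 updated models, `merge` the reverse, `complex` both sides ≥ 2;
single-sided components are removed/added models.  A one-to-one pair is
"unchanged" only when span and all exon chains agree exactly — any
coordinate difference counts as "updated", so UTR-only changes are updates.

**Identifier assignment** numbers genes per scaffold in positional order
(ties: earlier end, then source id) with a stride of 10, zero-padded to
five digits; the stride leaves identifier space for genes missed by the
update.

**TE classification** reads "coding region" as the genomic interval from
first to last CDS base of a transcript (any transcript qualifies); only
TEs flagged complete can trigger the containment rule, while spanning by
any TE interval, or a similarity hit to a declared TE-gene set at
e ≤ 0.001 (configurable; no published cutoff exists for this step),
also qualifies.  TE status labels genes; it does not delete them.

## Expression and differential tests

A read supports a model when its alignment interval overlaps at least one
exonic nucleotide of any transcript, counted once per model and
strand-agnostically (the emulated libraries are strand-unspecific).
FPKM is `count · 10⁹ / (library_size · exon_union_length)`.

The differential-expression caller is a deliberate stand-in for
isoform-deconvolution methods: per gene, a two-sided Fisher exact test on
pooled counts (gene vs rest of library, condition vs condition), with the
fold change computed on pseudocounted (+1 read) library-normalized means —
exon length cancels from the within-gene ratio.  Significance requires
p < 0.01 and |log2FC| strictly greater than 2.  Because the stand-in does
not model replicate dispersion, its gene lists are not comparable to
count-model callers and are not treated as benchmarks anywhere in the
package.

## Splicing

Events are enumerated by pairwise isoform comparison: SE (internal exon
absent from the partner with both flanking outer splice sites shared), RI
(intron strictly interior to a partner exon), A5SS/A3SS (intron pairs
sharing one boundary, with overlapping exons at the differing boundary —
the overlap requirement keeps SE patterns from double-counting as
alternative sites), MXE (non-overlapping private internal exons sharing
both outer flanks).  Donor/acceptor naming follows the transcribed strand.
Events are deduplicated by coordinates across isoform pairs.

Differential splicing pools replicates within condition (two replicates in
the emulated design; no dispersion model is attempted), applies a
two-sided Fisher exact test to the inclusion/exclusion × condition table,
controls FDR with Benjamini–Hochberg across tested events, and requires
p < 0.01, FDR < 1 % and |Δψ| > `min_delta_psi`.  The default
`min_delta_psi` is 0.0001 — the literal reading of a "0.01 % splicing
difference" criterion.  That figure looks like a typo for 1 % (0.01), so
the parameter is exposed rather than hard-coded.  Genes whose pseudocounted
expression differs ≥ 10,000-fold between the conditions are excluded before
testing; events with zero reads in a condition are skipped with a log
entry (ψ undefined).

## The synthetic scenarios

The generator emulates the *inputs* of an annotation update, not genome
evolution.  Per scaffold it lays out well-separated genes (150–400 nt
exons, 60–250 nt introns, 300–900 nt gaps, UTRs of 10–60 nt), plants a
second isoform (exon-skipping or intron-retention) in a fraction of
multi-exon genes, then derives the legacy annotation by perturbing truth:

* **fused** neighbours (one legacy model spanning two truth genes — the
  update must *split* it);
* **cut** genes (a truth gene broken at an intron into two legacy models —
  the update must *merge* them);
* **truncated** candidates (the updated model's CDS cut to 30 %, while the
  legacy copy and the outgroup orthologs retain the true length — the
  arbitration stage must swap the legacy model back in);
* **dropped** genes (absent from the legacy set; always expressed, so the
  update can discover them);
* **orphan** genes (present only in the legacy set and unexpressed, with
  at least one ortholog — only the orthology clause can rescue them);
* spurious short (< 500 nt) unexpressed models on both sides, placed in
  intergenic space;
* UTR loss on a fraction of intact legacy copies (these become "updated",
  not "unchanged").

Legacy models carry only the primary isoform, reflecting pre-isoform-era
annotations.  Default rates are 10 % fused/cut/truncated, 5 % dropped and
orphan, 10 % spurious, on 2 × 100 genes — the package's standard study
conditions.  Read evidence is Poisson (mean 60 reads per expressed gene
across six samples: WT/HS/REC in duplicate, with an 8-fold heat response
in 10 % of genes); expressed genes are guaranteed ≥ 5 reads so that
"clean evidence" scenarios are exactly recoverable.  Ortholog protein
lengths are truth ± N(0, 3) amino acids over up to five relative species
(presence 0.8 per species), with toy protein sequences whose shared-k-mer
scores drive the RBH structure; TE genes are marked by planted complete
TEs (in-CDS or spanning) plus incomplete decoys that trigger no rule.
Splice-event counts are binomial draws from planted per-condition ψ
(500 reads per event and sample; 30 % of events shift ψ by 0.35 under
heat stress).

Every sub-stage draws from its own seed-derived stream in a fixed order,
so scenarios are byte-reproducible and adding a stage cannot silently
reshuffle earlier draws.  The truth ledger records fates, TE status,
expression, ortholog lengths and planted ψ, and `ledger_score` turns a
pipeline report into per-category precision/recall.

What the scenarios do **not** emulate — and hence what passing tests do
not show about real data: alignment artefacts and multi-mapping reads,
overlapping or nested genes, strand-ambiguous loci, fragmented assemblies,
sequence-level homology noise (orthology is planted, not inferred from
real divergence), replicate overdispersion, and annotation errors other
than the planted classes.  Exact precision/recall of 1.0 under the
standard conditions demonstrates correctness of the bookkeeping and the
decision rules, not expected field performance.

## Numerical conventions

* Fisher exact p-values come from `scipy.stats.fisher_exact` (two-sided);
  tests cross-check them against an explicit hypergeometric pmf summation
  to 1e-10.  FDR is Benjamini–Hochberg via `statsmodels`.
* The k-mer stand-in scorer reports the multiset intersection of k-mer
  spectra (k = 4) and pseudo e-value `exp(−score)`: monotone in the score,
  1.0 at score 0, and far below any cutoff for genuinely similar toy
  proteins.  It is plumbing for synthetic data, not an aligner.
* All iteration orders (annotation sets, components, edges, reports) are
  sorted, so identical inputs give byte-identical outputs.
* RBH ties break by higher score, then lexicographically smaller subject
  id.  Identifier-assignment ties break by earlier end, then source id.
* Degenerate inputs: empty CDS → protein length 0; SD = 0 → no outliers;
  single-isoform genes → no events (not an error); ψ with zero reads on
  both forms → event skipped and logged; empty annotation → header-only
  GFF3.

## Known limitations

* The differential expression and splicing tests are pooled Fisher
  stand-ins; counts of significant genes/events are scenario quantities,
  not reproductions of any published tool's output.
* Redundancy detection is exact-structure containment only; it will not
  collapse near-identical models that differ by a single nucleotide.
* Arbitration compares one protein length per gene (the longest isoform);
  per-isoform arbitration is out of scope.
* The overlap graph is quadratic per locus neighbourhood; genomes with
  thousands of stacked models at one locus would need batching.
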