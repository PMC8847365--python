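# Methods

This note documents the models and procedures `lncquarry` implements,
the defaults it ships, the design choices made where the design was
genuinely open, and what the synthetic tests do and do not show about
real data.

## Coordinates and formats

All internal coordinates are 1-based inclusive (GTF-native); BED input
is converted at the I/O boundary and nowhere else.  Distance between
intervals is defined as the number of bases strictly between them,
`max(0, other.start − self.end − 1)`, so a rule like "distance < 1 kb"
is unambiguous: touching features have distance 0.  Chromosome names
are taken verbatim; a synonym map can be supplied at read time because
silently mixing Ensembl and UCSC styles is a classic failure mode.
Unstranded features are permitted and flagged; operations that need
strand state their fallback (class-code matching treats an unstranded
query as compatible with either strand; ORF scanning covers all six
frames for unstranded transcripts).

## Transcript classification

A reduced, gffcompare-style vocabulary is used: `=` requires an
identical intron chain (for mono-exon transcripts, where an intron
chain is undefined, ≥ 80% reciprocal exon overlap on a compatible
strand); `i` requires every exon strictly inside introns of a single
reference transcript; `u` requires zero overlap with any reference gene
body; everything else is `o`.  Intron containment deliberately ignores
the reference strand — the host relation is positional — while the
strand relation is still recorded.  All reference gene bodies count
when deciding "intergenic", including annotated lncRNA genes: a
transcript inside another lncRNA is not intergenic.  The nearest-gene
search reports the closest protein-coding gene body on each side;
overlapping genes count on both sides with distance 0, and equidistant
candidates resolve to the lexicographically smaller gene id so results
are reproducible.

## Coding potential

Three internal scorers are provided rather than re-implementations of
the five published tools whose names appear in real pipelines; external
per-tool score tables can be ingested alongside them, and the decision
rule — coding if at least `min_votes = 3` scorers call coding — is
preserved, since the vote is the scientifically meaningful part.

* **ORF fraction.** The longest complete (ATG…stop) ORF over the three
  sense frames; a transcript votes coding when that ORF covers > 0.5 of
  its length.  ORFs must be complete; `aa_length` excludes the stop
  codon, so the "> 300 aa" removal threshold excludes a transcript whose
  longest ORF has 301 translated codons.  Codons containing N never
  match ATG or a stop.
* **Fickett TESTCODE.** The classic statistic from the published
  position-asymmetry and composition lookup tables.  The vote boundary
  is 0.74, the published upper bound of the "non-coding" call — i.e. a
  transcript votes coding whenever TESTCODE does *not* call it
  non-coding.  (The published "coding" bound, 0.95, is also exported.)
* **Hexamer log-ratio.** Mean over in-frame hexamers of
  log(coding/noncoding frequency) under add-one-smoothed hexamer tables.
  Both tables are estimated from the input reference annotation itself —
  coding from the longest ORFs of protein-coding transcripts, noncoding
  from annotated lncRNAs — so the pipeline needs no external training
  corpus.  If the reference has no annotated lncRNAs the noncoding model
  falls back to uniform, with a warning.

The positional scorers (Fickett, hexamer) evaluate the longest-ORF
region when the transcript has a complete ORF of ≥ 200 nt, else the
whole transcript.  TESTCODE is a windowed statistic; scoring the
candidate coding region rather than UTR-diluted full transcripts is
standard practice and makes the vote depend on what the transcript
could encode, not on its UTR fraction.

## Homology search

Exclusion filters and catalogue lookups use a built-in nucleotide
search: exact k-mer seeding (word size 11), ungapped bidirectional
X-drop extension (match +1 / mismatch −2, X-drop 20), raw scores
converted through fixed Karlin–Altschul constants λ = 1.33, K = 0.621,
and `E = m·n·2^(−bitscore)` with m the query length and n the total
subject length.  The cutoff is E < 1e-5 throughout.  At the scale these
filters operate (rank/threshold behaviour on catalogue-sized subject
sets) an ungapped scorer is sufficient; externally produced 12-column
blast-tabular hit tables can replace any database wholesale.  One test
cross-checks the built-in search against NCBI blastn on a planted
homolog and skips silently where blastn is unavailable.

## The cascade

Stage order follows the canonical top-to-bottom reading of the
published filter sequence; the repeat filter sits beside the mono-exon
length filter as in the prose that joins them.  "Overlapping a repeat"
means ≥ 1 exonic base inside a repeat interval by default (the
overlap-fraction threshold is configurable; the sources are silent on
it).  The < 1 kb gene-distance rule applies only to intergenic ('u')
candidates and runs last; its position is configurable because the
prose ("in the last step") does not fully determine whether it preceded
the coding filters.  Expression values are taken as provided — the
pipeline never recomputes FPKM.  A transcript missing from the
expression matrix fails the expression stage with metric `absent`
rather than crashing the run.  When several catalogue entries pass the
known-lncRNA cutoff, the best (lowest-E) hit is kept.

Every transcript receives a `FilterTrace`; traces are append-only and
refuse to record anything after a terminal failure, which makes the
conservation invariant (entering = passing + failing at every stage)
and the short-circuit contract directly checkable.

## Expression statistics

Upper-quartile normalization divides each sample by its 75th percentile
of non-zero values (linear-interpolation quantile) and rescales by the
mean of those percentiles.  The differential-expression test is a
deliberate stand-in for heavier count-model tools whose internals are
out of scope here: Welch's t on log2(FPKM+1), BH adjustment over all
tested features, significance at q ≤ 0.05, with log2 fold change
computed on group means with pseudo-count 1.  Externally produced DE
tables can be ingested instead, bypassing the internal test.  Trans
targets use Pearson correlation on FPKM as provided (a `log1p` option
exists but the default mirrors the literal published description), with
assignments at |r| > 0.95 and the signed r recorded; constant vectors
are skipped with a logged reason because r is undefined for them.  With
only two samples per group — the real study's pooled design — |r| > 0.95
between independent features occurs at a measurable rate; the test
suite documents this false-positive floor rather than hiding it, and
the generator defaults to 8 samples per group (with a `paper_design`
flag for 2) precisely so that trans-target recovery is a testable
claim.  lncRNAs are clustered on Jaccard similarity of their target
sets with single linkage at ≥ 0.5 — a documented stand-in, since the
clustering behind published "clusters of lincRNAs with similar targets"
is unspecified.  The 10/100 kb cis windows are interpreted as nested:
the small window is tried first on each side and the large one only
where the small found nothing, with the satisfying window recorded per
assignment.  RT-qPCR relative expression is 2^(−ΔCt) with
ΔCt = Ct_target − Ct_reference.

## Synteny and conservation

A lincRNA flanked by protein-coding genes X (upstream) and Y
(downstream) is syntenic in a foreign species when a foreign lncRNA
lies strictly in the open interval between the ortholog gene bodies X′
and Y′ on one foreign chromosome.  "Strictly between" means the foreign
lncRNA may not overlap either gene body; the test is
orientation-agnostic (swapping which flank is called X changes
nothing).  No maximum flanking distance is imposed — the nearest
protein-coding genes qualify at any distance — but the search bound is
a config knob.  Failure reasons are explicit: missing flanking pair,
missing orthologs, orthologs on different chromosomes ("split pair"),
overlapping orthologs, or simply no foreign lncRNA between.  Sequence
conservation reuses the homology search per species and reports the
per-species best hit and the multi-species intersection.

## QTL co-localization

QTL input is a flat TSV (id, trait, chrom, start, end) extracted
upstream from whatever database dialect applies; ids are opaque
strings.  Overlap is ≥ 1 shared base under inclusive arithmetic, on the
transcript interval (QTL intervals are coarse, so exon-restricted
overlap would be false precision).  The multi-QTL report lists lncRNAs
in ≥ 2 QTLs, sorted by count then id, plus per-trait totals.

## Network modules and enrichment

The module detector re-implements the ClusterONE objective rather than
wrapping the tool: greedy growth from unvisited highest-degree seeds,
each step applying the single add/remove that most increases
cohesiveness f(V) = w_in / (w_in + w_bound + p·|V|), stopping at a
local maximum; groups below the minimum size (default 5, as published)
are discarded and pairs with overlap score ω(A,B) = |A∩B|²/(|A|·|B|) ≥
0.8 merge.  Penalty p = 2 and ω = 0.8 follow the tool's published
defaults since only the size thresholds are stated in the motivating
analyses.  All ties break on lexicographic node id, so output is
deterministic.  Because published module p-values come from an
undefined test, significance here is explicitly empirical: a
degree-preserving double-edge-swap null (10·|E| swaps per replicate,
edge weights permuted onto the rewired edges), with
p = (1 + #{f_null ≥ f_obs}) / (n_null + 1).  Enrichment is the
one-sided hypergeometric upper tail per gene set (sets intersected with
the background; the query must be inside the background), BH-adjusted,
significant at q < 0.1.

## The synthetic world

The generator emulates the study's input structure, not its raw reads:
no FASTQ, no splice-isoform complexity, no sequencing error model.
Each chromosome is a left-to-right concatenation of protein-coding gene
bodies and intergenic gaps; each gap carries at most one planted
intergenic feature with ≥ 2 kb margins (near-gene decoys: 300–700 nt),
so nearest-neighbour, QTL-containment and flanking-pair truths are
exact by construction.  This sequential placement replaces rejection
sampling: it has the same single-stream seed determinism (one PCG64
stream; identical seed ⇒ byte-identical emitted files) and cannot fail
to place a feature, at the cost of chromosome length being derived
rather than fixed.

Composition targets follow the real catalogue contrasts: novel lncRNAs
are lognormal around 733 nt (clipped to 203–3,000), 42% GC, 1–2 exons;
mRNAs carry complete ORFs of 350–1,000 aa from a positionally biased
codon model (~50% GC, strong codon-position asymmetry so the Fickett
and hexamer scorers see realistic coding signal) with UTRs totalling
30–60% of the ORF — which keeps the ORF fraction above the 0.5 vote
threshold and mean spliced length near 3.2 kb.  mRNA exon counts
default to 4–8: fewer than real chicken mRNAs average, a deliberate
scale-down that keeps the genome near 2 Mb while preserving the
direction contrast (mRNA exons ≫ lncRNA exons) that the checks assert.
Planted lncRNA sequences are scrubbed of chance ORFs longer than 120 aa
by in-frame stop insertion.

One decoy family per cascade stage is planted, ≥ 5 each by default,
each engineered to pass every stage before its own: >10 kb mono-exon
transcripts; repeat-overlapping transcripts (their repeat interval is
emitted to the BED); all-samples-sub-FPKM-1 transcripts; transcripts
embedding an exclusion-database fragment; coding-vote decoys (a 250 aa
biased ORF covering ~80% of the transcript — coding by all three
scorers yet under the 300 aa ORF cap); long-ORF decoys (a 340 aa ORF of
compositionally unbiased codons inside a transcript long enough that
ORF fraction, Fickett and hexamer all stay quiet); and intergenic
transcripts 300–700 nt from a gene.

Expression is multiplicative-lognormal (sd 0.25 on the log scale)
around per-feature baselines; baselines of planted non-decoy features
are floored at 1.8 FPKM so the FPKM ≥ 1 in ≥ 2 samples filter tests the
decoys, not sampling noise.  Planted DE features multiply one group's
mean by a fold of 3–6, so the expected group ratio equals the fold
exactly (and exactly at zero noise).  Planted trans pairs are
constructed by Gram–Schmidt so the sample Pearson r equals the target
(0.99) exactly up to non-negativity clipping — the ±0.05 contract holds
at any seed, not just in expectation.  QTLs either contain a planted
novel lncRNA (with margins small enough that no neighbouring feature is
swept in) or sit in feature-free gaps; synteny roles (syntenic,
ortholog-but-no-lncRNA, split-pair, no-orthologs) are assigned to
novel lincRNAs with disjoint flanking pairs so zero spurious calls is a
provable property; a subset of syntenic lincRNAs get sequence-identical
foreign partners, so planted synteny count ≥ planted homology count —
the positional-conservation-exceeds-sequence-conservation observation —
holds by construction.  The PPI background avoids planted module nodes
except for two boundary edges per module, which is what makes exact
module recovery a fair test: real complexes are cohesive with sparse
attachment, and a planted "module" whose nodes are saturated with
random background edges has no defensible boundary.

**What passing these tests shows** is that every filter, oracle and
annotation operation implements its stated contract and recovers truth
planted under its own assumptions.  **What it does not show** is
robustness to real-data pathologies — fragmentary assemblies,
mono-exonic artefacts near expression thresholds, correlated noise
between samples, incomplete ortholog maps — which the contracts expose
as configuration (thresholds, windows, overlap fractions) but the
synthetic defaults do not stress.

## Numerical and degenerate-input choices

Quantiles use linear interpolation; Pearson r is the closed-form
covariance ratio (vectorized); BH uses the step-up definition (verified
against an independent re-implementation in tests); the hypergeometric
tail is `sf(k−1)`.  Zero-variance DE features get p = 1 when group
means coincide and p = 0 otherwise.  Cohesiveness of an isolated set
with zero penalty is defined as 0.  An empty network yields no modules;
an empty catalogue yields an empty (not missing) distribution table;
empty characterization classes are emitted with zero counts.  Module
growth uses strict improvement (tolerance 1e-12), so it terminates and
is relabeling-invariant up to the documented id tie-break.
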