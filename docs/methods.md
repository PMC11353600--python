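# Methods

## Scope and model

`utrsurvey` reimplements a genome-wide untranslated-region (UTR) survey of
the kind run on plant genomes (maize B73 RefGen_v4 is the motivating
genome; the same code runs on any GTF/GFF3): per-gene 5′/3′ UTR lengths
from annotation geometry, their distribution over four length gradients,
GO over-representation per gradient, cross-species best-hit homolog
mapping from tabular alignment output, and IUPAC cis-element scanning of
5′ UTR sequences. Wet-lab stages of such studies (cloning, reporter
assays), RNA-seq mining, tree building and plotting are out of scope; the
pipeline ends at tidy TSV/JSON tables.

## UTR inference

A transcript is a set of non-overlapping exons plus a (possibly empty)
set of CDS intervals contained in them, all on one strand, held as
0-based half-open coordinates (converted from the 1-based inclusive
GTF/GFF3 convention at exactly one read point and one write point).
Conventions:

* **Representative transcript** = largest summed exon length (mature
  transcript length), not genomic span; ties break to the
  lexicographically smallest transcript id, so selection is deterministic
  and order-invariant.
* **Derived UTRs** are the exonic bases outside the genomic span
  `[min CDS start, max CDS end)`; on the + strand the low-coordinate side
  is 5′, on the − strand the high-coordinate side is. This yields the
  additivity identity `five_len + cds_len + three_len = exonic_length`
  for every coding transcript, which the test suite checks on 5000
  synthetic transcripts.
* GTF `stop_codon` features are merged into the CDS before inference, so
  Ensembl-style annotations (CDS excludes the stop) do not inflate every
  3′ UTR by 3 nt.
* Non-coding transcripts are retained in the model but excluded from UTR
  analysis; UTRs are defined relative to a CDS.
* Annotations that carry explicit `five_prime_utr`/`three_prime_utr`
  features can be analyzed in `explicit` or `prefer_explicit` mode; on
  the generator's matched fixture pair both modes give identical
  summaries.

**Length gradients**: closed bins 1–500, 501–1000, 1001–2000 and
≥2001 nt. **Means** are over UTR-containing transcripts only
(length > 0); zero-length UTRs contribute their CDS to the base-fraction
denominator but enter no bin and no mean. The genome-wide UTR base
fraction is `(utr5 + utr3) / (utr5 + utr3 + cds)` over coding
representative transcripts; whether a real survey's denominator includes
non-coding transcripts is usually unstated, and "coding representative
transcripts only" is this package's documented choice.

## GO over-representation

For a length class of `n` genes inside a universe of `N`, a term
annotating `K` universe genes and `k` class genes scores
`p = P(X ≥ k)`, `X ~ Hypergeometric(N, K, n)`. The tail is computed from
scratch: log-binomial coefficients via `lgamma` and a log-sum-exp
reduction, exact to enumeration for all `(k, K, n, N)` with `N ≤ 12`
(tested to 1e−12 relative error) and stable at genome scale
(cross-checked against an independent library implementation at
`N = 40 000`).

Decisions that matter:

* **Universe** = genes possessing a UTR on the analyzed side and at least
  one GO annotation (class/background symmetry); overridable.
* **Adjustment family**: Benjamini–Hochberg (default) is applied per
  class over *all testable terms* — every term with `K ≥ 1` in the
  universe — with unobserved terms (`k = 0`) entering at `p = 1` and
  dropped from the report afterwards. Adjusting only the `k ≥ 1` subset
  is selection before correction and measurably inflates the
  false-discovery rate in small classes (the >2000 gradient often holds
  only a couple of genes); with the full family the replicated null
  false-alarm rate (any class, q < 0.05) is ~5–6%.
* Ranking uses the raw p (ties by term id); reports carry both p and q.
* `is_a` ancestor propagation closes each gene's term set before counting
  and defaults to on exactly when an OBO is supplied.
* One-sided over-representation only.

## Best-hit homolog mapping

Standard outfmt-6 rows are reduced to one subject per query: maximal
bitscore, ties by smaller e-value, then lexicographic subject id — so the
map is invariant under row order. Reciprocal-best-hit filtering is
available but off by default (the one-directional "unique gene with the
highest score" convention). The mapper is agnostic to which aligner
produced the table.

## Cis-element scanning

The motif dictionary is a bundled, editable TSV of
(name, IUPAC consensus, functional category, description) covering the
standard plant stress / phytohormone / development / light element set
(STRE, ABRE, ARE, LTR, MBS, the CGTCA/TGACG MeJA pair, G-box, Box-4,
GT1-motif, GATA, TCT, …). It stands in for interactive promoter-element
web services, whose proprietary element definitions cannot be
redistributed: counts are analogous, not identical, and no exact
replication is promised. Matching semantics: a consensus position
accepts exactly its IUPAC base set; an `N` in the *sequence* matches only
an `N` consensus position. Both strands are scanned by default; a minus
hit is a match of the reverse-complemented consensus reported at its
start on the forward sequence, 1-based. All overlapping occurrences are
counted (no de-overlap rule). The scanner is regex-based with
lookahead; the tests hold it to exact agreement with a per-offset brute
force on 1000 random sequences × 20 motifs.

## ZmLAZ1 worked example

The package ships the seven cloned ZmLAZ1 5′ UTR lengths (1391, 1237,
493, 376, 355, 162, 149 bp; the family members lacking a 5′ UTR or
suspected pseudogenic are excluded). The family-level grouping is long
(> 1000 bp: 2 genes), medium (300–1000 bp: 3) and short (< 300 bp: 2);
note this qualitative grouping is coarser than the genome-wide gradients,
under which the family falls 5/0/2/0. The thresholds are chosen as the
natural gaps in the family's length gradient (1237 → 493 and 355 → 162).
The cis-element demo runs on *synthetic* stand-in sequences of the cloned
lengths (uniform ACGT with implanted STRE/TGACG words, files and
functions labelled synthetic); the real sequences live in MaizeGDB and
are not redistributed.

## Synthetic-data generator

`simulate.generate_annotation` emits a single-chromosome multi-gene
annotation (readable intergenic spacing of 200 nt), both as plain
exon/CDS GTF and as a variant with explicit UTR features, plus
transcript/5′ UTR/genome FASTA and a ground-truth JSON. Per gene: strand
Bernoulli(0.5); each UTR side absent with probability 0.10, otherwise a
gradient is drawn from the side's bin probabilities and the length
uniformly within the bin (the open last bin uses 2001–4000 nt, a cap
kept small for fixture size and exposed as a parameter); CDS length
uniform over 200–3800 nt (multiples of 3); 0–2 introns of 60–500 nt at
uniform positions; with probability 0.3 a strictly shorter secondary
isoform (same CDS, UTRs halved) so representative-transcript selection is
actually exercised.

Defaults are the survey conditions the package emulates: the bin
probabilities are the published maize proportions (87.64/9.87/2.30/0.19%
for 5′, 78.46/17.03/4.04/0.47% for 3′), and the CDS range was chosen so
the expected UTR base fraction comes out at that survey's ≈24.7%:
expected UTR nt per gene ≈ 0.9·(334 + 399) ≈ 660 against a mean CDS of
2000 nt gives 660/2660 ≈ 0.248. What uniform-within-bin sampling does
*not* reproduce is the strong within-bin skew of real UTR lengths, so the
synthetic mean 5′ UTR (~330 bp) sits below the real survey's 430 bp while
all bin proportions match; passing tests therefore validate the
accounting, not the shape of the real length distribution. Codon
structure, splice signals, base composition and GO DAG depth are likewise
not modelled.

The GO arm annotates every gene with every term independently at base
rate 0.08 over 30 terms; a planted (class, term, odds) triple multiplies
the odds of that term for genes of that 5′ UTR class. The motif arm
writes exact consensus words (concrete letters sampled for degenerate
positions) at non-overlapping uniform positions, Poisson counts per
sequence, random strand, over a uniform ACGT background — so scanner
recall of implants and the analytic background hit rate
`(L − w + 1)/4^w` per strand are both checkable. Everything is
deterministic given (params, seed).

## Calibration

`calibration.py` fixes one 500-gene genome and resamples the GO
annotation per replicate (the annotation draw is the randomness under
study). Null arm: 200 replicates at odds 1; the rate of any class
reporting BH q < 0.05 is ~5.5%. Power arm: 100 replicates with one term
planted at odds 20 into the 1–500 bp class; that term ranks first by p in
its class in 100% of replicates. Sizes (500 genes, 30 terms, 200/100
replicates) keep the whole calibration under ~3 s while leaving the
binomial error on the null rate at ~1.6 percentage points.

## Numerical and degenerate-input conventions

* Hypergeometric `k = 0` returns exactly 1; impossible tails return 0;
  results are clamped to [0, 1] against rounding.
* Empty length collections, empty universes, empty sequences, non-coding
  transcripts in derive mode, malformed annotation/alignment rows all
  raise typed errors naming the offending line/transcript/row rather
  than degrading silently.
* All tie-breaks (transcript selection, enrichment ordering, best-hit
  subjects, hit sorting) are lexicographic and documented, so every
  stage is reproducible bit-for-bit; CLI reports embed version, config
  hash and input checksums and contain no timestamps.

## Known limitations

* Trans-splicing, fuzzy coordinates and GFF3 multi-parent CDS are not
  handled; one genome dialect convention (gene/mRNA/exon parent chains or
  gene_id/transcript_id attributes) is assumed per file.
* The real-genome reproduction (maize B73 RefGen_v4) requires the
  Ensembl Plants/Gramene annotation to be present locally
  (`scratch/external/Zea_mays.AGPv4.gtf`); it is not bundled, and the
  corresponding check fails with an explanatory message when the file is
  absent. Published genome-wide numbers also depend on undocumented
  conventions (longest-transcript definition, explicit vs derived UTRs);
  both are exposed as run parameters here.
* Isoform-aware UTR accounting, uORFs, PWM scoring and
  topology-weighted enrichment are deliberately absent.
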