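# utrsurvey

Genome-wide surveys of mRNA untranslated regions (UTRs) for plant
genomes: infer 5′/3′ UTRs from a GTF/GFF3 annotation, profile their
lengths over the four standard gradients (1–500, 501–1000, 1001–2000,
>2000 nt), test GO-term over-representation per length class, map
cross-species best-hit homologs from BLAST-style tables, and scan 5′ UTR
sequences for IUPAC cis-acting elements (STRE, ABRE, MeJA motifs, …).
It targets the kind of question asked of maize, rice and arabidopsis
annotations — what fraction of the transcribed sequence is regulatory
UTR, how are UTR lengths distributed, and do genes with short, medium or
long UTRs carry distinct functions and elements?

For each gene the longest transcript (largest summed exon length) is the
representative; its UTRs are the exonic bases outside the CDS span, so
that

    five_len + cds_len + three_len = exonic_length

holds exactly. A class of n genes in a universe of N, with a term on K
universe genes and k class genes, is scored by the exact upper-tail
hypergeometric probability

    p = P(X ≥ k),  X ~ Hypergeometric(N, K, n)

computed in log space, with per-class Benjamini–Hochberg q-values over
the full testable-term family. A synthetic-data generator emits
annotation + sequence + GO + motif fixtures with stored ground truth, so
the whole pipeline is testable without downloading a genome.

## Worked example

Simulate a 1000-gene genome with maize-like UTR gradients, survey it,
and check the survey against the generator's truth (this is
`analysis/01_simulate.py` + `analysis/02_survey.py`, also available as
`utrsurvey simulate` / `utrsurvey survey`):

```bash
python analysis/01_simulate.py
python analysis/02_survey.py
```

```
surveyed 1000 genes
UTR base fraction: 24.6% (5' 296466 nt, 3' 342669 nt, CDS 1957266 nt)
mean 5' UTR 329 bp, mean 3' UTR 382 bp
5' gradient proportions: 87.46%, 10.43%, 2.00%, 0.11%
bin recovery vs truth: [788, 94, 18, 1] vs [788, 94, 18, 1] (exact)
```

Reading: about a quarter of the transcribed bases of this synthetic
genome are UTR, ~87% of 5′-UTR-containing genes carry a short (≤500 nt)
5′ UTR, and the four gradient counts recomputed from the emitted GTF
match the generator's stored truth integer-for-integer. Downstream
drivers continue the analysis: `03_enrichment.py` recovers a GO term
planted into the short-5′-UTR class at odds 20 as the top-ranked term of
that class (p ≈ 1e−25) with zero significant terms elsewhere;
`04_orthologs.py` recovers 1000/1000 planted best-hit orthologs;
`05_cis_elements.py` profiles implanted stress/MeJA elements; and
`06_laz1_case_study.py` runs the ZmLAZ1 worked example, whose seven
cloned 5′ UTR lengths (1391…149 bp) group into 2 long / 3 medium / 2
short members.

The same `survey` command runs on a real annotation (e.g. the maize B73
RefGen_v4 GTF) and prints the analogous genome-wide numbers.

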