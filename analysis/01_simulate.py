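#!/usr/bin/env python
"""Generate the synthetic study genome used by the downstream analyses.

Emits a 1000-gene single-chromosome annotation whose UTR-length gradient
proportions follow the maize B73 survey statistics, together with
transcript/UTR/genome FASTA, a GO universe with one stress term planted
into the short-5'-UTR class, and the ground-truth JSON.  Sequence files
(large) go to scratch/fixtures/; the annotation, GO files and truth go to
results/fixtures/.
"""

from pathlib import Path

from utrsurvey.simulate import (GeneratorParams, GOParams,
                                generate_annotation, generate_go_universe)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "fixtures"
SCRATCH = ROOT / "scratch" / "fixtures"

PARAMS = GeneratorParams(
    n_genes=1000,
    seed=42,
    go=GOParams(planted=[("1-500", "GO:1000003", 20.0)]),
    motif_implants=[("STRE", "AGGGG", 1.0), ("TGACG-motif", "TGACG", 0.5)],
)


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    bundle = generate_annotation(PARAMS)
    go_tsv, obo = generate_go_universe(PARAMS, bundle.truth)

    (SCRATCH / "annotation.gtf").write_text(bundle.gtf)
    (SCRATCH / "gene2go.tsv").write_text(go_tsv)
    (RESULTS / "ontology.obo").write_text(obo)
    (SCRATCH / "truth.json").write_text(bundle.truth.to_json())
    (SCRATCH / "annotation_explicit_utr.gtf").write_text(bundle.gtf_explicit)
    (SCRATCH / "transcripts.fa").write_text(bundle.mrna_fasta)
    (SCRATCH / "utr5.fa").write_text(bundle.utr5_fasta)
    (SCRATCH / "genome.fa").write_text(bundle.genome_fasta)

    n_with_utr5 = sum(1 for g in bundle.truth.genes.values() if g["bin_5"])
    print(f"wrote {PARAMS.n_genes}-gene fixture (seed {PARAMS.seed}): "
          f"{n_with_utr5} genes with a 5' UTR, "
          f"bin counts {bundle.truth.bin_counts('5')}")
    print(f"ontology -> {RESULTS}; annotation, GO map, truth, sequences -> {SCRATCH}")


if __name__ == "__main__":
    main()
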