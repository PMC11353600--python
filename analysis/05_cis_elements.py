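#!/usr/bin/env python
"""Cis-element scan of the synthetic 5' UTR sequences.

Scans the fixture's 5' UTR FASTA (with STRE and TGACG-motif words
implanted by 01_simulate.py) against the bundled element dictionary on
both strands and aggregates per-gene counts into functional categories.
"""

from pathlib import Path

from utrsurvey.cisscan import read_motif_table, scan_fasta

ROOT = Path(__file__).resolve().parent.parent
UTR_FASTA = ROOT / "scratch" / "fixtures" / "utr5.fa"
OUT = ROOT / "results" / "cis_elements"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    if not UTR_FASTA.exists():
        raise SystemExit("run analysis/01_simulate.py first (utr5.fa missing)")
    motifs = read_motif_table()
    hits, profiles = scan_fasta(UTR_FASTA.read_text(), motifs)

    hits.to_csv(ROOT / "scratch" / "cis_hits.tsv", sep="\t", index=False)
    profiles.to_csv(OUT / "category_profile.tsv", sep="\t", index=False)

    n_seq = len(profiles)
    print(f"scanned {n_seq} 5' UTR sequences with {len(motifs)} motifs: "
          f"{len(hits)} hits")
    totals = profiles.drop(columns="sequence_id").sum().sort_values(
        ascending=False)
    for category, count in totals.items():
        print(f"  {category}: {int(count)}")
    stre = hits[hits.motif == "STRE"]
    print(f"STRE occurrences: {len(stre)} in "
          f"{stre.sequence_id.nunique()} sequences")


if __name__ == "__main__":
    main()
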