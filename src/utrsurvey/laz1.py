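"""The ZmLAZ1 worked example: seven cloned 5' UTR lengths and their
long / medium / short grouping, used to drive the cis-element demo.

The family's 5' UTRs form a length gradient: two long members (1391 and
1237 bp), three medium ones (493, 376, 355 bp) and two short ones (162 and
149 bp).  The grouping thresholds are >1000 bp (long) and <300 bp (short);
everything between is medium.  This qualitative family-level grouping is
coarser than the four genome-wide gradients, under which the family falls
5 / 0 / 2 / 0.
"""

from __future__ import annotations

import io
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .utr import BIN_LABELS, bin_index

LONG_MIN = 1001   # nt; lengths >= this are "long"
SHORT_MAX = 299   # nt; lengths <= this are "short"

CLASS_LABELS = ("long", "medium", "short")


def load_lengths() -> pd.DataFrame:
    """The packaged table of the seven cloned ZmLAZ1 5' UTR lengths."""
    text = (
        resources.files("utrsurvey.data")
        .joinpath("zmlaz1_5utr_lengths.tsv")
        .read_text()
    )
    return pd.read_csv(io.StringIO(text), sep="\t", comment="#")


def classify_length(length: int) -> str:
    if length >= LONG_MIN:
        return "long"
    if length <= SHORT_MAX:
        return "short"
    return "medium"


def family_classes(table: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-gene long/medium/short class and genome-gradient bin."""
    if table is None:
        table = load_lengths()
    out = table.copy()
    out["length_class"] = [classify_length(v) for v in out["utr5_len"]]
    out["gradient_bin"] = [BIN_LABELS[bin_index(int(v))] for v in out["utr5_len"]]
    return out


def class_counts(table: Optional[pd.DataFrame] = None) -> dict[str, int]:
    """Counts per long/medium/short class (expected 2 / 3 / 2)."""
    classes = family_classes(table)["length_class"]
    return {label: int((classes == label).sum()) for label in CLASS_LABELS}


def demo_utr_fasta(seed: int = 0) -> str:
    """Synthetic stand-in 5' UTR sequences for the seven family members.

    The real sequences live in MaizeGDB and are not redistributed here;
    these are uniform-composition random sequences of the cloned lengths
    with stress (STRE) and MeJA (TGACG) element words implanted, mirroring
    the family's element profile qualitatively.  Synthetic: for
    demonstration and tests only.
    """
    from .simulate import GeneratorParams, implant_motifs

    rng = np.random.default_rng(seed)
    chunks = []
    for _, row in load_lengths().iterrows():
        seq = "".join(rng.choice(list("ACGT"), size=int(row.utr5_len)))
        chunks.append(f">{row.gene}\n{seq}")
    fasta = "\n".join(chunks) + "\n"

    params = GeneratorParams(
        motif_implants=[("STRE", "AGGGG", 2.0), ("TGACG-motif", "TGACG", 1.0)],
        seed=seed,
    )
    fasta, _truth = implant_motifs(fasta, params, seed=seed + 7)
    return fasta


def demo_element_profiles(seed: int = 0) -> pd.DataFrame:
    """Scan the synthetic family UTR set against the bundled dictionary."""
    from .cisscan import scan_fasta

    fasta = demo_utr_fasta(seed)
    _hits, profiles = scan_fasta(fasta)
    return profiles
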