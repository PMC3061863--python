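"""Packaged worked-example data and synthetic reference sequences.

Two kinds of content live here:

* small tables transcribed from the published study — the per-contig
  crowded/isolated tag counts used for the phase screen and the seven
  peptides encoded by the periviscerokinin (PVK / capability-like)
  precursor, with their amidation state and whether each had been known
  before that study;
* synthetic stand-ins for reference sequences the pipeline needs but that
  cannot be shipped (cloning-vector backbone, rRNA-like and bacterial-like
  contaminant decoys).  These are generated from fixed seeds and are
  synthetic: they exercise masking/screening, they are not the real
  pBluescript or E. coli sequences.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "selected_contig_tag_counts",
    "pvk_precursor_peptides",
    "GENERIC_SIGNAL",
    "VECTOR_STUB",
    "contaminant_refs",
]


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.files("estpipe.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def selected_contig_tag_counts() -> pd.DataFrame:
    """Per-contig counts of crowded- (C) and isolated-reared (I) library tags
    for the 16 contigs selected by the tag-based screen in the study.

    Columns: contig_id, n_crowded, n_isolated, annotation.
    """
    return _read_tsv("selected_contig_tag_counts.tsv")


def pvk_precursor_peptides() -> pd.DataFrame:
    """The seven peptides carried by the PVK (capability-like) precursor.

    ``sequence`` is the mature peptide (amidation glycine and flanking basic
    residues removed), ``amidated`` marks a C-terminal amide, and
    ``previously_known`` marks peptides already demonstrated in the desert
    locust before the precursor was sequenced (PVK-2, PVK-3, MT-2).
    """
    df = _read_tsv("pvk_precursor_peptides.tsv")
    df["amidated"] = df["amidated"].astype(bool)
    df["previously_known"] = df["previously_known"].astype(bool)
    return df


#: 19-residue generic secretory signal peptide used for synthetic precursors:
#: Met + a basic residue + a 14-residue hydrophobic core + an Ala-Ser-Ala cap,
#: built so the (-3,-1) small-residue rule cleaves exactly after the last Ala.
GENERIC_SIGNAL = "MKLLVLLLVLLVLLVLASA"

#: Fixed 80 nt synthetic "vector" stub flanking simulated inserts.  Not a real
#: cloning vector; it exists so vector masking has something to find.
VECTOR_STUB = (
    "TGCACTGGCCGTCGTTTTACAACGTCGTGACTGGGAAAACCCTGGCGTTACCCAACTTAATCGCCTTGCAGCACATCCCC"
)


def _random_dna(n: int, seed: int, gc: float = 0.5) -> str:
    rng = np.random.default_rng(seed)
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    return "".join(rng.choice(list("ACGT"), size=n, p=[p_at, p_gc, p_gc, p_at]))


def masking_refs(schemes=None) -> dict[str, str]:
    """Vector stub plus the library-primer anchors, for vector-style masking.

    The synthesis-primer anchors are cloning artefacts exactly like vector
    sequence: leaving them in the clean region would join unrelated reads
    in the assembler through their shared primer prefix.
    """
    from .tags import BUILTIN_SCHEMES

    refs = {"vector_stub": VECTOR_STUB}
    for scheme in (schemes if schemes is not None else BUILTIN_SCHEMES.values()):
        refs[f"primer_anchor_{scheme.scheme_id}"] = scheme.anchor
    return refs


def contaminant_refs() -> dict[str, str]:
    """Synthetic contaminant decoy references (deterministic).

    ``rrna_decoy`` stands in for ribosomal RNA and ``bacterial_decoy`` for
    genomic DNA of the cloning host; both are fixed-seed random sequences.
    """
    return {
        "rrna_decoy": _random_dna(1800, seed=777, gc=0.55),
        "bacterial_decoy": _random_dna(2400, seed=778, gc=0.50),
    }
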