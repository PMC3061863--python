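"""Shared pairwise local-alignment engine.

One Smith-Waterman engine backs read cleanup (vector/contaminant hits),
overlap detection in the assembler and the translated homology searches:

* DNA: match +1 / mismatch -2 / gap open -5 / gap extend -1
* protein: BLOSUM62 with gap open -11 / extend -1

Alignments are computed with :class:`Bio.Align.PairwiseAligner` (exact local
alignment in C); this module only normalises its output into a small record
with 0-based half-open coordinates, column count and identity.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "LocalAlignment",
    "dna_aligner",
    "protein_aligner",
    "align_dna",
    "align_protein",
    "revcomp",
]


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment of ``query`` against ``target``."""

    score: float
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    length: int  # alignment columns, gaps included
    matches: int
    identity: float  # matches / columns, in [0, 1]


def dna_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    # N never rewards a match (used to blank out already-masked regions)
    return aligner


def protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


_DNA = dna_aligner()
_PROT = protein_aligner()

_RC = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _summarise(alignment, query: str, target: str, ignore: str = "") -> LocalAlignment:
    coords = alignment.coordinates
    qstart, qend = int(coords[0, 0]), int(coords[0, -1])
    tstart, tend = int(coords[1, 0]), int(coords[1, -1])
    columns = 0
    matches = 0
    for i in range(coords.shape[1] - 1):
        q0, q1 = int(coords[0, i]), int(coords[0, i + 1])
        t0, t1 = int(coords[1, i]), int(coords[1, i + 1])
        dq, dt = q1 - q0, t1 - t0
        columns += max(dq, dt)
        if dq and dt:  # aligned block (no gap)
            for a, b in zip(query[q0:q1], target[t0:t1]):
                if a == b and a not in ignore:
                    matches += 1
    identity = matches / columns if columns else 0.0
    return LocalAlignment(
        score=float(alignment.score),
        query_start=qstart,
        query_end=qend,
        target_start=tstart,
        target_end=tend,
        length=columns,
        matches=matches,
        identity=identity,
    )


def _best(aligner: Align.PairwiseAligner, query: str, target: str, ignore: str = "") -> LocalAlignment | None:
    if not query or not target:
        return None
    score = aligner.score(query, target)
    if score <= 0:
        return None
    alignment = next(iter(aligner.align(query, target)))
    return _summarise(alignment, query, target, ignore)


def align_dna(query: str, target: str) -> LocalAlignment | None:
    """Best local DNA alignment, or None when nothing scores above zero."""
    # masked bases (N) never count as matches
    return _best(_DNA, query.upper(), target.upper(), ignore="N")


def align_protein(query: str, target: str) -> LocalAlignment | None:
    """Best local protein alignment under BLOSUM62."""
    q = str(Seq(query)).upper().replace("*", "X").replace("U", "X").replace("O", "X")
    t = str(Seq(target)).upper().replace("*", "X").replace("U", "X").replace("O", "X")
    q = q.replace("B", "X").replace("Z", "X").replace("J", "X")
    t = t.replace("B", "X").replace("Z", "X").replace("J", "X")
    return _best(_PROT, q, t, ignore="X")
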