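"""Neuropeptide precursor mining and cleavage prediction.

Insect neuropeptides are carved out of larger precursor proteins: a
secretory signal peptide is removed, prohormone convertases of the
subtilisin family cleave at dibasic (Lys-Arg, Arg-Arg and, in practice,
Lys-Lys / Arg-Lys) or monobasic (Arg) sites, furin cleaves at
Arg-Xaa-[Arg/Lys]-Arg, carboxypeptidase removes the exposed basic
residues, and a C-terminal glycine left behind is converted into an amide.

This module finds candidate precursor reading frames by a translated
homology scan with known short peptides, applies a simplified signal
peptide heuristic (hydrophobic-core plus (-3,-1) small-residue rule — a
low-confidence stand-in for a dedicated predictor), predicts the primary
peptide set from dibasic/furin cleavage, enumerates alternative
tissue-dependent cleavage forms around internal basic residues, and
classifies peptides into families by their C-terminal motifs
(periviscerokinin positional rule, myotropin -FXPRLamide, tachykinin
-FXGXRamide, AKH-like).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .align import align_protein
from .annotate import six_frame_segments

__all__ = [
    "CleavageSite",
    "PredictedPeptide",
    "PrecursorModel",
    "scan_for_precursors",
    "predict_signal",
    "find_sites",
    "release_peptides",
    "enumerate_forms",
    "classify_family",
    "analyze_precursor",
]

DIBASIC_MOTIFS = ("KR", "RR", "KK", "RK")
_FURIN = re.compile(r"(?=R.[RK]R)")

# Kyte-Doolittle hydropathy
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
_SMALL = set("AGSCT")  # allowed at -3 and -1 of the signal cleavage site


@dataclass(frozen=True)
class CleavageSite:
    position: int  # 1-based index of the LAST residue of the basic motif
    site_class: str  # dibasic | monobasic | furin
    motif: str


@dataclass(frozen=True)
class PredictedPeptide:
    sequence: str  # mature: basic flank and amidation Gly removed
    amidated: bool
    start: int = 0  # 1-based, within the mature (post-signal) protein
    end: int = 0
    families: tuple[str, ...] = ()


@dataclass
class PrecursorModel:
    protein: str
    signal: tuple[int, int] | None  # 1-based inclusive interval, starts at 1
    sites: list[CleavageSite]
    primary_peptides: list[PredictedPeptide]
    alternative_forms: dict[str, tuple[PredictedPeptide, ...]] = field(default_factory=dict)


def scan_for_precursors(
    transcripts: dict[str, str],
    queries: dict[str, str],
    score_threshold: float = 35.0,
    min_orf: int = 60,
) -> list[tuple[str, str]]:
    """Candidate precursor ORFs from a translated short-peptide scan.

    Each transcript is translated in six frames; open reading frames
    (Met to stop, >= ``min_orf`` residues) containing a Smith-Waterman hit
    of any query peptide at or above the score threshold are reported as
    (transcript_id, orf_protein).  Low thresholds are intentional: the
    queries are 5-40 residue peptides.
    """
    candidates: list[tuple[str, str]] = []
    for tid in sorted(transcripts):
        seen: set[str] = set()
        for _frame, seg in six_frame_segments(transcripts[tid], min_len=min_orf):
            for orf in _orfs(seg, min_orf):
                if orf in seen:
                    continue
                for q in queries.values():
                    aln = align_protein(q, orf)
                    if aln is not None and aln.score >= score_threshold:
                        seen.add(orf)
                        candidates.append((tid, orf))
                        break
    return candidates


def _orfs(segment: str, min_orf: int, max_starts: int = 8) -> list[str]:
    """Met-to-segment-end reading frames within a stop-free translation.
    Several start codons may be plausible; the first few are all offered."""
    out = []
    idx = segment.find("M")
    while idx != -1 and len(out) < max_starts:
        orf = segment[idx:]
        if len(orf) >= min_orf:
            out.append(orf)
        idx = segment.find("M", idx + 1)
    return out


def predict_signal(
    protein: str,
    max_search: int = 35,
    h_window: int = 8,
    h_threshold: float = 1.6,
    min_len: int = 10,
) -> tuple[int, int] | None:
    """Heuristic secretory signal peptide call (1-based interval), or None.

    Requires, within the first ``max_search`` residues, an 8-residue window
    of mean Kyte-Doolittle hydropathy >= ``h_threshold`` (the hydrophobic
    core), and cleaves after the first position >= ``min_len`` where the
    residues at -1 and -3 are small (A/G/S/C/T) — the classical (-3,-1)
    rule.  This is a deliberately simple stand-in for a dedicated signal
    peptide predictor; calls on real sequences are low-confidence.
    """
    if not protein.startswith("M"):
        raise ValueError("precursor proteins must start with Met")
    head = protein[:max_search]
    core_ok = False
    for i in range(len(head) - h_window + 1):
        window = head[i : i + h_window]
        mean_h = sum(_KD.get(a, 0.0) for a in window) / h_window
        if mean_h >= h_threshold:
            core_ok = True
            break
    if not core_ok:
        return None
    for p in range(min_len, min(len(protein), max_search) + 1):
        minus1 = protein[p - 1]
        minus3 = protein[p - 3] if p >= 3 else ""
        if minus1 in _SMALL and minus3 in _SMALL:
            return (1, p)
    return None


def find_sites(mature: str, dibasic_motifs: tuple[str, ...] = DIBASIC_MOTIFS) -> list[CleavageSite]:
    """All convertase site positions in a mature (signal-less) protein.

    Every site is reported at the last residue of its motif; where motifs
    of different classes claim the same position, furin beats dibasic
    beats monobasic.
    """
    sites: dict[int, CleavageSite] = {}
    for m in _FURIN.finditer(mature):
        pos = m.start() + 4  # last residue of R-X-[RK]-R
        sites[pos] = CleavageSite(pos, "furin", mature[m.start() : m.start() + 4])
    for i in range(len(mature) - 1):
        pair = mature[i : i + 2]
        if pair in dibasic_motifs:
            pos = i + 2
            if pos not in sites:
                sites[pos] = CleavageSite(pos, "dibasic", pair)
    for i, aa in enumerate(mature):
        if aa == "R":
            pos = i + 1
            if pos not in sites:
                sites[pos] = CleavageSite(pos, "monobasic", "R")
    return [sites[p] for p in sorted(sites)]


#: motif preference for overlapping primary sites: furin beats any dibasic,
#: Lys-Arg is the canonical convertase signal, Arg-Lys the weakest
_MOTIF_RANK = {"KR": 1, "RR": 2, "KK": 3, "RK": 4}


def _site_rank(s: CleavageSite) -> int:
    return 0 if s.site_class == "furin" else _MOTIF_RANK.get(s.motif, 5)


def _select_primary_sites(
    sites: list[CleavageSite], primary_classes: frozenset[str]
) -> list[CleavageSite]:
    """Primary cut sites with overlaps resolved by motif preference.

    Overlapping motifs compete (in K-K-R the Lys-Arg pair wins over
    Lys-Lys; in K-R-K it wins over Arg-Lys); equally ranked overlapping
    motifs keep the rightmost (R-R-R cleaves after the last Arg).
    """
    primary = [s for s in sites if s.site_class in primary_classes]
    keep: list[CleavageSite] = []
    for s in primary:
        take = True
        while keep and s.position - len(s.motif) + 1 <= keep[-1].position:
            prev = keep[-1]
            if (_site_rank(s), -s.position) < (_site_rank(prev), -prev.position):
                keep.pop()
            else:
                take = False
                break
        if take:
            keep.append(s)
    return keep


def release_peptides(
    mature: str,
    sites: list[CleavageSite] | None = None,
    primary_classes: frozenset[str] = frozenset({"dibasic", "furin"}),
) -> list[PredictedPeptide]:
    """Primary peptide set from convertase cleavage of a mature precursor.

    The chain is cut after each primary-class site; each fragment then
    loses the basic residues of its own cleavage motif (carboxypeptidase
    action on the site — peptide-internal C-terminal basics such as the
    Lys of a Lys-ending peptide are preserved), and a fragment then ending
    in Gly is amidated.  Empty fragments are dropped.
    """
    if sites is None:
        sites = find_sites(mature)
    cuts = _select_primary_sites(sites, primary_classes)
    peptides: list[PredictedPeptide] = []
    prev = 0
    bounds = [(s.position, len(s.motif)) for s in cuts]
    if not bounds or bounds[-1][0] != len(mature):
        bounds.append((len(mature), 0))
    for pos, motif_len in bounds:
        frag = mature[prev:pos]
        start = prev + 1
        prev = pos
        if not frag:
            continue
        if motif_len:
            trimmed = frag[: len(frag) - _motif_basic_tail(frag, motif_len)]
        else:
            # precursor end without a site: plain carboxypeptidase trim
            trimmed = frag.rstrip("KR")
        amidated = False
        if trimmed.endswith("G") and len(trimmed) > 1:
            trimmed = trimmed[:-1]
            amidated = True
        if not trimmed:
            continue
        peptides.append(
            PredictedPeptide(trimmed, amidated, start=start, end=start + len(trimmed) - 1)
        )
    return peptides


def _motif_basic_tail(frag: str, motif_len: int) -> int:
    """Number of trailing residues of ``frag`` that are basic residues of
    the terminal cleavage motif (the X of a furin site is kept)."""
    n = 0
    for aa in reversed(frag[-motif_len:]):
        if aa in "KR":
            n += 1
        else:
            break
    return n


def enumerate_forms(fragment: str, internal_sites: list[int] | None = None) -> set[PredictedPeptide]:
    """Alternative cleavage forms of one released fragment.

    ``fragment`` is the pre-amidation fragment (cleavage motif removed,
    amidation Gly still attached).  Cleavage may additionally occur, in a
    tissue-dependent manner, after any internal basic residue; every
    contiguous stretch delimited by {fragment start, internal basic
    positions, fragment end} is emitted.  Stretches ending inside the
    fragment get full trailing-basic trimming; only stretches reaching the
    original fragment end can carry the amidation signal.
    """
    if internal_sites is None:
        internal_sites = [i + 1 for i, aa in enumerate(fragment[:-1]) if aa in "KR"]
    bad = [p for p in internal_sites if not 1 <= p < len(fragment)]
    if bad:
        raise ValueError(f"internal sites out of range: {bad}")
    bounds = [0] + sorted(set(internal_sites)) + [len(fragment)]
    forms: dict[tuple[str, bool], PredictedPeptide] = {}
    for bi in range(len(bounds) - 1):
        for bj in range(bi + 1, len(bounds)):
            sub = fragment[bounds[bi] : bounds[bj]]
            at_end = bounds[bj] == len(fragment)
            amidated = False
            if at_end:
                if sub.endswith("G") and len(sub) > 1:
                    sub = sub[:-1]
                    amidated = True
            else:
                sub = sub.rstrip("KR")
            if not sub:
                continue
            key = (sub, amidated)
            if key not in forms:
                forms[key] = PredictedPeptide(sub, amidated, start=bounds[bi] + 1, end=bounds[bi] + len(sub))
    return set(forms.values())


_TK_RE = re.compile(r"F.G.R$")
_TK_RE_TOLERANT = re.compile(r"F.[GT].R$")
_MT_RE = re.compile(r"F.PRL$")


def classify_family(peptide: PredictedPeptide, tachykinin_gt_tolerance: bool = False) -> tuple[str, ...]:
    """C-terminal family motifs for one predicted peptide.

    * periviscerokinin (PVK): counted on the Gly-extended sequence
      (peptide + amidation G, last residue = n): Leu at n-7, Arg at n-2,
      and a C-terminal amide;
    * myotropin: amidated -FXPRL end;
    * tachykinin: amidated -FXGXR end (optionally tolerating G<->T);
    * AKH-like: amidated, 8-10 residues, N-terminal Gln (pyroGlu candidate).
    """
    labels: list[str] = []
    seq = peptide.sequence
    if peptide.amidated:
        ext = seq + "G"
        n = len(ext)
        if n >= 8 and ext[n - 8] == "L" and ext[n - 3] == "R":
            labels.append("PVK")
        if _MT_RE.search(seq):
            labels.append("myotropin")
        tk = _TK_RE_TOLERANT if tachykinin_gt_tolerance else _TK_RE
        if tk.search(seq):
            labels.append("tachykinin")
        if seq.startswith("Q") and 8 <= len(seq) <= 10:
            labels.append("AKH-like")
    return tuple(labels)


def analyze_precursor(protein: str) -> PrecursorModel:
    """Full precursor work-up: signal call, sites, primary peptides with
    family labels, and alternative forms per primary peptide."""
    signal = predict_signal(protein)
    mature = protein[signal[1] :] if signal else protein
    sites = find_sites(mature)
    primaries = release_peptides(mature, sites)
    labelled = [
        PredictedPeptide(p.sequence, p.amidated, p.start, p.end, classify_family(p))
        for p in primaries
    ]
    # recover each primary's pre-amidation fragment for form enumeration
    forms: dict[str, tuple[PredictedPeptide, ...]] = {}
    for p in labelled:
        frag = p.sequence + ("G" if p.amidated else "")
        forms[p.sequence] = tuple(sorted(enumerate_forms(frag), key=lambda f: (f.start, f.sequence)))
    return PrecursorModel(protein, signal, sites, labelled, forms)
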