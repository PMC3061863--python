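"""Raw EST cleanup: quality trimming, masking and contaminant exclusion.

The disposition vocabulary follows the classical EST-processing convention:
a read is ``clean`` when, after quality trimming and vector/low-complexity
masking, at least ``min_clean_length`` unmasked bases remain and the region
matches no contaminant reference; reads failing the high-quality-window
requirement are ``low_quality``; reads whose surviving insert is too short
are ``short_insert``; contaminant matches are ``contaminant``.

All reported intervals are 1-based and inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import align_dna, revcomp

__all__ = [
    "TrimPolicy",
    "MaskedInterval",
    "ReadDisposition",
    "ReferenceSet",
    "quality_trim",
    "mask_vector",
    "mask_low_complexity",
    "screen_contaminants",
    "dispose",
    "dispose_batch",
]

WINDOW = 50  # quality window width, bases


class ReferenceSet:
    """Reference sequences prepared for repeated screening.

    Holds both strands of every reference plus a k-mer index used as a
    cheap prefilter: a read is only aligned against references it shares
    at least one k-mer with (k = 11 keeps minimal 20-base vector hits
    findable at 90% identity while skipping almost all unrelated reads).
    """

    def __init__(self, refs: dict[str, str], k: int = 11):
        if not refs:
            raise ValueError("reference set must be non-empty")
        self.k = k
        self.targets: list[str] = []
        self._kmers: list[set[str]] = []
        for name in sorted(refs):
            seq = refs[name].upper()
            for s in (seq, revcomp(seq)):
                self.targets.append(s)
                self._kmers.append({s[i : i + k] for i in range(len(s) - k + 1)})

    def candidates(self, seq: str) -> list[str]:
        qk = {seq[i : i + self.k] for i in range(len(seq) - self.k + 1)}
        return [t for t, ks in zip(self.targets, self._kmers) if qk & ks]


def _as_refset(refs) -> "ReferenceSet":
    return refs if isinstance(refs, ReferenceSet) else ReferenceSet(refs)


@dataclass(frozen=True)
class TrimPolicy:
    """Quality/length thresholds for read cleanup.

    ``tolerance`` is the number of sub-threshold bases allowed in any
    50-base window of the trimmed region — the concession that maximises
    sequence length while keeping the region essentially >=Q20.
    """

    high_quality_threshold: int = 20
    min_high_quality_length: int = 200
    min_clean_length: int = 200
    tolerance: int = 2

    def __post_init__(self) -> None:
        if self.high_quality_threshold <= 0:
            raise ValueError("high_quality_threshold must be positive")
        if self.min_high_quality_length < 1 or self.min_clean_length < 1:
            raise ValueError("minimum lengths must be >= 1")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass(frozen=True)
class MaskedInterval:
    start: int  # 1-based inclusive
    end: int
    mask_class: str  # vector | repeat | low_complexity


@dataclass
class ReadDisposition:
    read_id: str
    status: str  # clean | short_insert | low_quality | contaminant
    clean_start: int | None = None
    clean_end: int | None = None
    masks: list[MaskedInterval] = field(default_factory=list)


def quality_trim(
    bases: str, quals: list[int] | np.ndarray, policy: TrimPolicy = TrimPolicy()
) -> tuple[int, int] | None:
    """Maximal high-quality interval (1-based inclusive), or None.

    An interval qualifies when every 50-base window inside it contains at
    most ``policy.tolerance`` bases below the Phred threshold (for intervals
    shorter than 50 bases the interval itself is the window).  Among
    qualifying intervals the longest is returned (leftmost on ties); None
    when the longest is shorter than ``min_high_quality_length``.
    """
    quals = np.asarray(quals)
    if len(bases) != len(quals):
        raise ValueError("bases and qualities differ in length")
    n = len(quals)
    if n == 0:
        return None
    low = (quals < policy.high_quality_threshold).astype(int)
    tol = policy.tolerance

    best_start, best_len = 0, 0
    if n >= WINDOW:
        csum = np.concatenate([[0], np.cumsum(low)])
        win = csum[WINDOW:] - csum[:-WINDOW]  # low count of window starting p
        ok = win <= tol
        p = 0
        while p < len(ok):
            if ok[p]:
                q = p
                while q + 1 < len(ok) and ok[q + 1]:
                    q += 1
                run_len = (q - p) + WINDOW
                if run_len > best_len:
                    best_start, best_len = p, run_len
                p = q + 1
            else:
                p += 1
    if best_len == 0:
        # no qualifying 50-base window: longest sub-50 stretch with <= tol lows
        left = 0
        bad = 0
        for right in range(n):
            bad += low[right]
            while bad > tol:
                bad -= low[left]
                left += 1
            if right - left + 1 > best_len:
                best_start, best_len = left, right - left + 1
        best_len = min(best_len, WINDOW - 1)
    if best_len < policy.min_high_quality_length:
        return None
    return best_start + 1, best_start + best_len


def _alignment_hits(
    seq: str, refs: "ReferenceSet", min_identity: float, min_len: int, max_hits: int = 10
) -> list[tuple[int, int]]:
    """Qualifying local-alignment intervals of ``seq`` against refs (both
    strands), found iteratively by masking out each accepted hit."""
    work = seq.upper()
    hits: list[tuple[int, int]] = []
    for _ in range(max_hits):
        found = None
        for target in refs.candidates(work):
            aln = align_dna(work, target)
            if aln is None:
                continue
            if aln.length >= min_len and aln.identity >= min_identity:
                if found is None or aln.score > found.score:
                    found = aln
        if found is None:
            break
        hits.append((found.query_start + 1, found.query_end))
        work = work[: found.query_start] + "N" * (found.query_end - found.query_start) + work[found.query_end:]
    hits.sort()
    return hits


def mask_vector(
    seq: str,
    vector_refs: dict[str, str] | ReferenceSet,
    min_identity: float = 0.9,
    min_len: int = 20,
) -> list[MaskedInterval]:
    """Mask read segments aligning to any vector reference (either strand).

    Cloning-primer anchors can be supplied alongside the vector backbone;
    they are masked with the same mechanism.
    """
    refset = _as_refset(vector_refs)
    return [MaskedInterval(s, e, "vector") for s, e in _alignment_hits(seq, refset, min_identity, min_len)]


def mask_low_complexity(
    seq: str, window: int = 64, threshold: float = 2.0, step: int = 8
) -> list[MaskedInterval]:
    """DUST-like low-complexity masking.

    Each window is scored by its trinucleotide repetitiveness
    ``sum c*(c-1)/2 / (T-1)`` (T = triplet count); windows above the
    threshold are masked and overlapping masks merged.  A homopolymer
    scores ~w/2, random sequence ~1.
    """
    if window < 12:
        raise ValueError("window must be >= 12")
    seq = seq.upper()
    n = len(seq)
    flagged: list[tuple[int, int]] = []
    if n < 12:
        return []
    starts = list(range(0, max(n - window, 0) + 1, step))
    if starts[-1] != max(n - window, 0):
        starts.append(max(n - window, 0))
    for s in starts:
        w = seq[s : s + window]
        triplets: dict[str, int] = {}
        for i in range(len(w) - 2):
            t = w[i : i + 3]
            triplets[t] = triplets.get(t, 0) + 1
        total = len(w) - 2
        if total < 2:
            continue
        score = sum(c * (c - 1) / 2 for c in triplets.values()) / (total - 1)
        if score > threshold:
            flagged.append((s + 1, min(s + window, n)))
    merged: list[list[int]] = []
    for s, e in flagged:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [MaskedInterval(s, e, "low_complexity") for s, e in merged]


def screen_contaminants(
    seq: str,
    contaminant_refs: dict[str, str] | ReferenceSet,
    min_identity: float = 0.95,
    min_len: int = 100,
) -> bool:
    """True when the sequence locally aligns to any contaminant reference
    (either strand) with >= min_identity over >= min_len bases."""
    refset = _as_refset(contaminant_refs)
    for target in refset.candidates(seq.upper()):
        aln = align_dna(seq, target)
        if aln is not None and aln.length >= min_len and aln.identity >= min_identity:
            return True
    return False


def _subtract_masks(start: int, end: int, masks: list[MaskedInterval]) -> tuple[int, int] | None:
    """Longest unmasked stretch within [start, end] (1-based inclusive)."""
    covered = np.zeros(end - start + 1, dtype=bool)
    for m in masks:
        lo = max(m.start, start) - start
        hi = min(m.end, end) - start
        if lo <= hi:
            covered[lo : hi + 1] = True
    best = None
    run_start = None
    for i in range(len(covered) + 1):
        free = i < len(covered) and not covered[i]
        if free and run_start is None:
            run_start = i
        elif not free and run_start is not None:
            if best is None or i - run_start > best[1] - best[0] + 1:
                best = (run_start + start, i - 1 + start)
            run_start = None
    return best


def dispose(
    read_id: str,
    seq: str,
    quals: list[int] | np.ndarray,
    policy: TrimPolicy = TrimPolicy(),
    vector_refs: dict[str, str] | None = None,
    contaminant_refs: dict[str, str] | None = None,
) -> ReadDisposition:
    """Full cleanup of one read: quality trim, then vector and
    low-complexity masking inside the trimmed region, then a contaminant
    screen on the surviving clean stretch."""
    hq = quality_trim(seq, quals, policy)
    if hq is None:
        return ReadDisposition(read_id, "low_quality")
    hq_start, hq_end = hq
    region = seq[hq_start - 1 : hq_end]

    masks: list[MaskedInterval] = []
    if vector_refs:
        for m in mask_vector(region, vector_refs):
            masks.append(MaskedInterval(m.start + hq_start - 1, m.end + hq_start - 1, m.mask_class))
    for m in mask_low_complexity(region):
        masks.append(MaskedInterval(m.start + hq_start - 1, m.end + hq_start - 1, m.mask_class))

    clean = _subtract_masks(hq_start, hq_end, masks)
    if clean is None or clean[1] - clean[0] + 1 < policy.min_clean_length:
        return ReadDisposition(read_id, "short_insert", masks=masks)
    if contaminant_refs and screen_contaminants(seq[clean[0] - 1 : clean[1]], contaminant_refs):
        return ReadDisposition(read_id, "contaminant", masks=masks)
    return ReadDisposition(read_id, "clean", clean_start=clean[0], clean_end=clean[1], masks=masks)


def dispose_batch(records, policy: TrimPolicy = TrimPolicy(), vector_refs=None, contaminant_refs=None):
    """Dispose a list of Biopython SeqRecords carrying phred qualities."""
    vec = ReferenceSet(vector_refs) if vector_refs else None
    cont = ReferenceSet(contaminant_refs) if contaminant_refs else None
    out = []
    for rec in records:
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None:
            quals = [40] * len(rec.seq)
        out.append(dispose(rec.id, str(rec.seq), quals, policy, vector_refs=vec, contaminant_refs=cont))
    return out
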