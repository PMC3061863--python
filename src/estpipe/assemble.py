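"""Greedy overlap assembly of cleaned ESTs into contigs.

Overlaps are found by 16-mer seeding plus local alignment (both strands),
then reads are laid out best-overlap-first; edges whose implied placement
contradicts an existing one by more than a small tolerance are dropped, so
inconsistent (chimeric) joins split into separate contigs instead of
producing a silent misassembly.  The consensus is a per-column
quality-weighted majority.  The summary applies the classical uniques /
redundancy accounting: uniques = contigs + singletons and
``redundancy% = 100 * (reads - uniques) / reads``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .align import align_dna, revcomp

__all__ = [
    "Overlap",
    "Contig",
    "AssemblySummary",
    "find_overlaps",
    "cluster_and_consense",
    "assemble_reads",
    "summarize",
]

KMER = 16


@dataclass(frozen=True)
class Overlap:
    read_a: str
    read_b: str
    orientation: str  # forward | reverse-complement (of read_b relative to read_a)
    offset: int  # start of oriented read_b in read_a coordinates
    length: int  # alignment columns
    identity: float

    def inverted(self, len_a: int, len_b: int) -> "Overlap":
        """The same overlap expressed with read_b as the reference."""
        if self.orientation == "forward":
            off = -self.offset
        else:
            off = len_b - len_a + self.offset
        return Overlap(self.read_b, self.read_a, self.orientation, off, self.length, self.identity)


@dataclass
class Contig:
    contig_id: str
    members: list[tuple[str, int, str]]  # (read_id, offset, +|-)
    consensus: str
    depth: list[int]


@dataclass(frozen=True)
class AssemblySummary:
    total_reads: int
    n_contigs: int
    n_singletons: int
    n_uniques: int
    redundancy_pct: float


def _kmers(seq: str, k: int = KMER):
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if len(set(km)) > 2:  # skip homopolymer-ish seeds (poly-A tails)
            yield km


def find_overlaps(
    reads: dict[str, str], min_overlap: int = 40, min_identity: float = 0.95, k: int = KMER
) -> list[Overlap]:
    """All qualifying pairwise overlaps, k-mer seeded, both strands."""
    ids = sorted(reads)
    index: dict[str, set[str]] = defaultdict(set)
    for rid in ids:
        for km in set(_kmers(reads[rid].upper(), k)):
            index[km].add(rid)

    candidates: dict[tuple[str, str], set[str]] = defaultdict(set)
    for rid in ids:
        seq = reads[rid].upper()
        for km in set(_kmers(seq, k)):
            for other in index[km]:
                if other < rid:
                    candidates[(other, rid)].add("forward")
        for km in set(_kmers(revcomp(seq), k)):
            for other in index.get(km, ()):
                if other != rid:
                    pair = (other, rid) if other < rid else (rid, other)
                    candidates[pair].add("reverse-complement")

    overlaps: list[Overlap] = []
    for (a, b), orients in sorted(candidates.items()):
        best = None
        for orient in sorted(orients):
            target = reads[b].upper() if orient == "forward" else revcomp(reads[b].upper())
            aln = align_dna(reads[a].upper(), target)
            if aln is None or aln.length < min_overlap or aln.identity < min_identity:
                continue
            ov = Overlap(a, b, orient, aln.query_start - aln.target_start, aln.length, aln.identity)
            if best is None or aln.score > best[0]:
                best = (aln.score, ov)
        if best is not None:
            overlaps.append(best[1])
    return overlaps


def _place_from(placed_pos: int, placed_ori: str, ov: Overlap, len_ref: int, len_other: int):
    """Placement of ov.read_b given the placement of ov.read_a."""
    if placed_ori == "+":
        ori = "+" if ov.orientation == "forward" else "-"
        pos = placed_pos + ov.offset
    else:
        ori = "-" if ov.orientation == "forward" else "+"
        pos = placed_pos + len_ref - ov.offset - len_other
    return pos, ori


def cluster_and_consense(
    reads: dict[str, str],
    overlaps: list[Overlap],
    quals: dict[str, list[int]] | None = None,
    offset_tolerance: int = 5,
    default_qual: int = 15,
) -> tuple[list[Contig], list[str], list[Overlap]]:
    """Lay out reads into contigs; returns (contigs, singleton ids, dropped).

    Edges are taken best-first (identity, then length).  An edge joining two
    already-laid-out groups merges them after translating one group's
    coordinates; an edge internal to a group is checked against the existing
    placement and dropped when it disagrees by more than the tolerance
    (these dropped edges are returned for logging; the split shows up as
    separate contigs).
    """
    quals = quals or {}
    lens = {rid: len(seq) for rid, seq in reads.items()}
    placement: dict[str, tuple[int, str]] = {}
    comp_of: dict[str, int] = {}
    members: dict[int, list[str]] = {}
    next_comp = 0
    dropped: list[Overlap] = []

    def ensure(rid: str) -> None:
        nonlocal next_comp
        if rid not in comp_of:
            comp_of[rid] = next_comp
            members[next_comp] = [rid]
            placement[rid] = (0, "+")
            next_comp += 1

    for ov in sorted(overlaps, key=lambda o: (-o.identity, -o.length, o.read_a, o.read_b)):
        a, b = ov.read_a, ov.read_b
        ensure(a)
        ensure(b)
        pos_b, ori_b = _place_from(*placement[a], ov, lens[a], lens[b])
        if comp_of[a] == comp_of[b]:
            cur_pos, cur_ori = placement[b]
            if cur_ori != ori_b or abs(cur_pos - pos_b) > offset_tolerance:
                dropped.append(ov)
            continue
        # merge b's component into a's frame with one rigid transform
        cur_pos, cur_ori = placement[b]
        ca, cb = comp_of[a], comp_of[b]
        if cur_ori == ori_b:
            delta = pos_b - cur_pos
            for rid in members[cb]:
                p, o = placement[rid]
                placement[rid] = (p + delta, o)
        else:
            # reverse-complement cb's frame: [p, p+L) maps to [S-p-L, S-p),
            # with S chosen so read b lands at its required placement
            s = pos_b + cur_pos + lens[b]
            for rid in members[cb]:
                p, o = placement[rid]
                placement[rid] = (s - p - lens[rid], "+" if o == "-" else "-")
        for rid in members[cb]:
            comp_of[rid] = ca
        members[ca].extend(members[cb])
        del members[cb]

    # components of size >= 2 become contigs
    comps = [sorted(m) for m in members.values() if len(m) >= 2]
    comps.sort(key=lambda m: m[0])
    singles = sorted(set(reads) - {rid for m in comps for rid in m})

    contigs: list[Contig] = []
    for i, comp in enumerate(comps, start=1):
        shift = min(placement[rid][0] for rid in comp)
        placed = [(rid, placement[rid][0] - shift, placement[rid][1]) for rid in comp]
        consensus, depth = _consensus(placed, reads, quals, default_qual)
        contigs.append(Contig(f"C{i}", placed, consensus, depth))
    return contigs, singles, dropped


def _consensus(placed, reads, quals, default_qual):
    """Per-column weighted majority: depth first, summed quality, then base."""
    length = max(pos + len(reads[rid]) for rid, pos, _ in placed)
    counts: list[dict[str, list[int]]] = [dict() for _ in range(length)]
    for rid, pos, ori in placed:
        seq = reads[rid].upper()
        q = list(quals.get(rid, [default_qual] * len(seq)))
        if ori == "-":
            seq = revcomp(seq)
            q = q[::-1]
        for j, base in enumerate(seq):
            col = counts[pos + j]
            if base not in col:
                col[base] = [0, 0]
            col[base][0] += 1
            col[base][1] += q[j]
    consensus = []
    depth = []
    for col in counts:
        if not col:
            consensus.append("N")
            depth.append(0)
            continue
        base = sorted(col.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))[0][0]
        consensus.append(base)
        depth.append(sum(v[0] for v in col.values()))
    return "".join(consensus), depth


def assemble_reads(
    reads: dict[str, str],
    quals: dict[str, list[int]] | None = None,
    min_overlap: int = 40,
    min_identity: float = 0.95,
) -> tuple[list[Contig], list[str], AssemblySummary]:
    """Convenience: overlaps + clustering + summary in one call."""
    overlaps = find_overlaps(reads, min_overlap=min_overlap, min_identity=min_identity)
    contigs, singles, _ = cluster_and_consense(reads, overlaps, quals=quals)
    return contigs, singles, summarize(len(reads), len(contigs), len(singles))


def summarize(total_reads: int, n_contigs: int, n_singletons: int) -> AssemblySummary:
    """Uniques and redundancy accounting from raw counts."""
    if min(total_reads, n_contigs, n_singletons) < 0:
        raise ValueError("counts must be non-negative")
    n_uniques = n_contigs + n_singletons
    if total_reads < n_uniques:
        raise ValueError("total reads cannot be fewer than unique sequences")
    if total_reads == 0:
        raise ValueError("total_reads must be positive")
    redundancy = 100.0 * (total_reads - n_uniques) / total_reads
    return AssemblySummary(total_reads, n_contigs, n_singletons, n_uniques, redundancy)
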