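"""GO annotation transfer by translated homology search.

Contig/singleton nucleotide sequences are compared against a GO-labelled
reference protein set by six-frame translation plus Smith-Waterman under
BLOSUM62; candidate GO terms collected from the hits are scored with a
Blast2GO-style annotation score combining hit identity, the evidence code
of the reference annotation, the number of supporting hits and a decaying
weight for parent terms.  Terms scoring above the threshold (default >45)
are assigned, then pruned to the lowest node per namespace so only the most
specific qualifying term survives.

E-values use the Karlin-Altschul formula with ungapped BLOSUM62 constants
(lambda = 0.3176, K = 0.134) applied to the gapped scores — a self-contained
approximation, adequate for ranking and thresholding at these scales.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import obonet

from .align import align_protein, revcomp

__all__ = [
    "SearchPolicy",
    "Hit",
    "GOAssignment",
    "GODag",
    "six_frame_segments",
    "translated_search",
    "score_terms",
    "level_distribution",
    "top_terms",
    "EC_WEIGHTS",
]

KA_LAMBDA = 0.3176
KA_K = 0.134

#: evidence-code weights: experimental/curated full weight, other
#: computational evidence slightly down-weighted, IEA lowest
EC_WEIGHTS: dict[str, float] = {
    **{ec: 1.0 for ec in ("EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC")},
    **{ec: 0.8 for ec in ("ISS", "ISO", "ISA", "ISM", "IGC", "IBA", "RCA", "NAS")},
    "IEA": 0.7,
}
DEFAULT_EC_WEIGHT = 0.8


@dataclass(frozen=True)
class SearchPolicy:
    mode: str = "translated_query"  # protein_query | translated_query
    evalue_cutoff: float = 1e-3  # 1e-7 for orthology calls, 1e-3 for GO transfer
    min_alignment_length: int = 33  # residues

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.min_alignment_length < 1:
            raise ValueError("min_alignment_length must be >= 1")


@dataclass(frozen=True)
class Hit:
    query_id: str
    subject_id: str
    length: int  # alignment columns (residues)
    pident: float  # percent identity, 0-100
    score: float  # raw Smith-Waterman score
    evalue: float
    frame: int  # +1..+3 / -1..-3 (0 for protein queries)
    go_terms: tuple[tuple[str, str], ...] = ()  # (term id, evidence code)


@dataclass(frozen=True)
class GOAssignment:
    sequence_id: str
    term: str
    score: float  # annotation score, 0-100
    supporting_hits: tuple[str, ...] = ()


class GODag:
    """Minimal is_a ontology: term metadata, ancestors and min-path depth."""

    def __init__(self, graph: nx.DiGraph):
        # edges run child -> parent
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology graph must be acyclic")
        for child, parent in graph.edges():
            if parent not in graph:
                raise ValueError(f"parent {parent} missing from graph")
        self.graph = graph
        self._depth: dict[str, int] = {}
        roots = [n for n in graph if graph.out_degree(n) == 0]
        for root in roots:
            ns = graph.nodes[root].get("namespace", root)
            for term, d in nx.single_source_shortest_path_length(graph.reverse(copy=False), root).items():
                cur = self._depth.get(term)
                if cur is None or d < cur:
                    self._depth[term] = d
                self.graph.nodes[term].setdefault("namespace", ns)
        self.roots = roots

    @classmethod
    def from_obo(cls, path) -> "GODag":
        g = obonet.read_obo(str(path))
        dag = nx.DiGraph()
        for node, data in g.nodes(data=True):
            dag.add_node(node, name=data.get("name", node), namespace=data.get("namespace"))
        for child, parent, key in g.edges(keys=True):
            if key == "is_a":
                dag.add_edge(child, parent)
        return cls(dag)

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str]], namespaces: dict[str, str] | None = None) -> "GODag":
        """Build from (child, parent) pairs — handy for synthetic ontologies."""
        dag = nx.DiGraph()
        for child, parent in edges:
            dag.add_edge(child, parent)
        if namespaces:
            nx.set_node_attributes(dag, namespaces, "namespace")
        return cls(dag)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def depth(self, term: str) -> int:
        return self._depth[term]

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        return nx.descendants(self.graph, term)  # edges point child -> parent

    def descendants(self, term: str) -> set[str]:
        return nx.ancestors(self.graph, term)


_STOP = "*"


def six_frame_segments(dna: str, min_len: int = 11) -> list[tuple[int, str]]:
    """Translate all six frames; stop codons break the translation into
    segments, segments shorter than ``min_len`` residues are discarded.
    Returns (frame, peptide) pairs; frames are +1..+3 and -1..-3."""
    from Bio.Seq import Seq

    out: list[tuple[int, str]] = []
    seq = dna.upper().replace("U", "T")
    for strand, s in ((1, seq), (-1, revcomp(seq))):
        for off in range(3):
            sub = s[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) < 3:
                continue
            prot = str(Seq(sub).translate())
            for seg in prot.split(_STOP):
                if len(seg) >= min_len:
                    out.append((strand * (off + 1), seg))
    return out


def translated_search(
    query_id: str,
    query_dna: str,
    reference: dict[str, str],
    policy: SearchPolicy = SearchPolicy(),
    reference_go: dict[str, list[tuple[str, str]]] | None = None,
) -> list[Hit]:
    """Best hit per reference protein for one nucleotide query.

    Queries shorter than 33 nt cannot produce a qualifying alignment and
    return an empty list.
    """
    if not reference:
        raise ValueError("reference protein set must be non-empty")
    if len(query_dna) < 33:
        return []
    reference_go = reference_go or {}
    segments = six_frame_segments(query_dna)
    if not segments:
        return []
    m = len(query_dna) / 3.0
    n_total = sum(len(s) for s in reference.values())
    hits: list[Hit] = []
    for sid in sorted(reference):
        sseq = reference[sid]
        best = None
        for frame, seg in segments:
            aln = align_protein(seg, sseq)
            if aln is None:
                continue
            if best is None or aln.score > best[0].score:
                best = (aln, frame)
        if best is None:
            continue
        aln, frame = best
        evalue = KA_K * m * n_total * math.exp(-KA_LAMBDA * aln.score)
        if evalue > policy.evalue_cutoff or aln.length < policy.min_alignment_length:
            continue
        hits.append(
            Hit(
                query_id=query_id,
                subject_id=sid,
                length=aln.length,
                pident=100.0 * aln.identity,
                score=aln.score,
                evalue=evalue,
                frame=frame,
                go_terms=tuple(reference_go.get(sid, ())),
            )
        )
    hits.sort(key=lambda h: (h.evalue, h.subject_id))
    return hits


def score_terms(
    hits: list[Hit],
    dag: GODag,
    ec_weights: dict[str, float] | None = None,
    parent_weight: float = 0.5,
    hit_bonus: float = 5.0,
    threshold: float = 45.0,
) -> list[GOAssignment]:
    """Blast2GO-style annotation scoring for one query's hits.

    direct(t) = max over hits annotated with t of (%identity x EC weight);
    an ancestor inherits parent_weight x its best child's score (decaying
    with distance); the total adds ``hit_bonus`` per extra supporting hit
    and is capped at 100.  Terms with total > threshold are kept, then
    pruned to the lowest node per namespace.
    """
    ec_weights = ec_weights or EC_WEIGHTS
    if not hits:
        return []
    seq_id = hits[0].query_id
    direct: dict[str, float] = {}
    supporters: dict[str, set[str]] = {}
    for h in hits:
        for term, ec in h.go_terms:
            if term not in dag:
                continue
            w = ec_weights.get(ec)
            if w is None:
                warnings.warn(f"unknown evidence code {ec!r}; using default weight", stacklevel=2)
                w = DEFAULT_EC_WEIGHT
            s = h.pident * w
            if s > direct.get(term, -1.0):
                direct[term] = s
            supporters.setdefault(term, set()).add(h.subject_id)

    # propagate scores and supporters upward through the DAG
    base: dict[str, float] = dict(direct)
    sup_all: dict[str, set[str]] = {t: set(s) for t, s in supporters.items()}
    # iterative relaxation child -> parent with geometric decay, deepest first
    pending = sorted(direct, key=dag.depth, reverse=True)
    while pending:
        nxt = []
        for t in pending:
            for p in dag.parents(t):
                cand = parent_weight * base[t]
                if cand > base.get(p, 0.0):
                    base[p] = cand
                    nxt.append(p)
                sup_all.setdefault(p, set()).update(sup_all.get(t, set()))
        pending = nxt

    totals = {}
    for t, s in base.items():
        bonus = hit_bonus * (len(sup_all.get(t, set())) - 1)
        totals[t] = min(s + max(bonus, 0.0), 100.0)

    kept = {t for t, s in totals.items() if s > threshold}
    # lowest-node rule within each namespace
    pruned = set(kept)
    for t in kept:
        if dag.descendants(t) & kept:
            pruned.discard(t)
    return [
        GOAssignment(seq_id, t, totals[t], tuple(sorted(sup_all.get(t, ()))))
        for t in sorted(pruned)
    ]


def level_distribution(
    assignments: list[GOAssignment], dag: GODag, namespace: str, level: int
) -> list[tuple[str, int]]:
    """Sequence counts per ancestor term at the requested depth.

    Each assigned term maps up to every ancestor whose minimum is_a depth
    equals ``level`` (the term itself included when its depth matches); a
    sequence is counted once per such ancestor.  Sorted by descending count,
    then term id.
    """
    counts: dict[str, set[str]] = {}
    for a in assignments:
        if a.term not in dag or dag.namespace(a.term) != namespace:
            continue
        lineage = dag.ancestors(a.term) | {a.term}
        for t in lineage:
            if dag.depth(t) == level:
                counts.setdefault(t, set()).add(a.sequence_id)
    table = [(t, len(s)) for t, s in counts.items()]
    table.sort(key=lambda kv: (-kv[1], kv[0]))
    return table


def top_terms(assignments: list[GOAssignment], dag: GODag, n: int) -> list[tuple[str, int]]:
    """Top-n terms ranked by number of distinct sequences (ties: term id)."""
    seqs: dict[str, set[str]] = {}
    for a in assignments:
        seqs.setdefault(a.term, set()).add(a.sequence_id)
    ranked = sorted(((t, len(s)) for t, s in seqs.items()), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]
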