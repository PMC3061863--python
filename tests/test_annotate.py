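"""Annotation-transfer tests: translated search, scoring, DAG operations."""

import numpy as np
import pytest

from estpipe import annotate as an
from estpipe.align import revcomp
from estpipe.synthio import _backtranslate

from conftest import random_dag

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _random_protein(n, rng):
    return "".join(rng.choice(AA, size=n))


@pytest.fixture(scope="module")
def toy_dag():
    edges = [
        ("GO:2", "GO:1"),
        ("GO:3", "GO:1"),
        ("GO:4", "GO:2"),
        ("GO:5", "GO:2"),
        ("GO:5", "GO:3"),
        ("GO:6", "GO:4"),
    ]
    return an.GODag.from_edges(edges, namespaces={"GO:1": "biological_process"})


def test_exact_backtranslation_hits_its_protein_at_full_identity():
    rng = np.random.default_rng(0)
    prot = _random_protein(120, rng)
    ref = {"target": prot, "decoy": _random_protein(110, rng)}
    hits = an.translated_search("q", _backtranslate(prot), ref)
    assert hits and hits[0].subject_id == "target"
    assert hits[0].pident == pytest.approx(100.0)
    assert hits[0].frame == 1


def test_reverse_complement_query_scores_identically_via_minus_frame():
    rng = np.random.default_rng(1)
    prot = _random_protein(100, rng)
    dna = _backtranslate(prot)
    ref = {"t": prot}
    fwd = an.translated_search("q", dna, ref)
    rev = an.translated_search("q", revcomp(dna), ref)
    assert fwd and rev
    assert fwd[0].score == rev[0].score
    assert rev[0].frame < 0


def test_too_short_query_returns_nothing():
    assert an.translated_search("q", "ATGGCT", {"t": "MAMAMAMAMAMA"}) == []
    with pytest.raises(ValueError):
        an.translated_search("q", "ATG" * 20, {})


def test_scrambled_queries_rarely_pass_the_evalue_cutoff():
    """Null calibration: random queries against a small reference set should
    almost never reach E <= 1e-3."""
    rng = np.random.default_rng(2)
    ref = {f"p{i}": _random_protein(250, rng) for i in range(3)}
    policy = an.SearchPolicy(evalue_cutoff=1e-3)
    n_pass = 0
    n_queries = 200
    for _ in range(n_queries):
        dna = "".join(rng.choice(list("ACGT"), size=300))
        if an.translated_search("q", dna, ref, policy):
            n_pass += 1
    assert n_pass / n_queries <= 0.05


def test_single_perfect_experimental_hit_scores_100(toy_dag):
    h = an.Hit("s1", "p1", 50, 100.0, 250.0, 1e-30, 1, (("GO:6", "IDA"),))
    assigns = an.score_terms([h], toy_dag)
    assert [(a.term, a.score) for a in assigns] == [("GO:6", 100.0)]


def test_half_identity_iea_hit_scores_35_and_is_rejected(toy_dag):
    h = an.Hit("s1", "p1", 50, 50.0, 80.0, 1e-9, 1, (("GO:6", "IEA"),))
    assert an.score_terms([h], toy_dag) == []


def test_lowest_node_rule_keeps_only_the_child(toy_dag):
    hits = [
        an.Hit("s1", "p1", 50, 60.0, 120.0, 1e-12, 1, (("GO:4", "IDA"),)),
        an.Hit("s1", "p2", 50, 50.0, 100.0, 1e-10, 1, (("GO:6", "IDA"),)),
    ]
    assigns = an.score_terms(hits, toy_dag)
    terms = {a.term for a in assigns}
    assert "GO:6" in terms and "GO:4" not in terms


def test_extra_supporting_hits_add_bonus(toy_dag):
    hits = [
        an.Hit("s1", f"p{i}", 50, 42.0, 90.0, 1e-9, 1, (("GO:6", "IDA"),))
        for i in range(3)
    ]
    assigns = an.score_terms(hits, toy_dag)
    assert assigns and assigns[0].score == pytest.approx(52.0)
    assert len(assigns[0].supporting_hits) == 3


def test_unknown_evidence_code_warns_and_uses_default(toy_dag):
    h = an.Hit("s1", "p1", 50, 90.0, 200.0, 1e-20, 1, (("GO:6", "XXX"),))
    with pytest.warns(UserWarning):
        assigns = an.score_terms([h], toy_dag)
    assert assigns and assigns[0].score == pytest.approx(72.0)


def test_score_is_monotone_in_identity(toy_dag):
    rng = np.random.default_rng(3)
    for _ in range(20):
        pid = float(rng.uniform(30, 95))
        h_lo = an.Hit("s", "p", 50, pid, 100.0, 1e-9, 1, (("GO:5", "IDA"),))
        h_hi = an.Hit("s", "p", 50, pid + 5.0, 100.0, 1e-9, 1, (("GO:5", "IDA"),))
        lo_terms = {a.term for a in an.score_terms([h_lo], toy_dag)}
        hi_terms = {a.term for a in an.score_terms([h_hi], toy_dag)}
        assert lo_terms <= hi_terms


def test_no_retained_pair_in_ancestor_relation_on_random_inputs():
    dag = random_dag(60, seed=4)
    rng = np.random.default_rng(5)
    ids = sorted(dag.graph)
    for trial in range(15):
        hits = [
            an.Hit(
                "s", f"p{j}", 50, float(rng.uniform(40, 100)), 100.0, 1e-9, 1,
                tuple((ids[int(t)], "IEA") for t in rng.integers(0, len(ids), size=2)),
            )
            for j in range(4)
        ]
        assigns = an.score_terms(hits, dag)
        terms = {a.term for a in assigns}
        for t in terms:
            assert not (dag.ancestors(t) & terms)


def test_level_distribution_simple_and_multi_parent(toy_dag):
    deep = an.GOAssignment("s1", "GO:6", 90.0)
    assert an.level_distribution([deep], toy_dag, "biological_process", 1) == [("GO:2", 1)]
    multi = an.GOAssignment("s2", "GO:5", 80.0)
    table = an.level_distribution([multi], toy_dag, "biological_process", 1)
    assert sorted(table) == [("GO:2", 1), ("GO:3", 1)]
    assert an.level_distribution([deep], toy_dag, "biological_process", 9) == []


def test_level_distribution_matches_path_enumeration_oracle():
    dag = random_dag(40, seed=6)
    rng = np.random.default_rng(7)
    ids = sorted(dag.graph)
    assigns = [
        an.GOAssignment(f"s{i % 7}", ids[int(rng.integers(0, len(ids)))], 60.0)
        for i in range(30)
    ]

    def oracle_depth(term, memo={}):
        if dag.graph.out_degree(term) == 0:
            return 0
        if term not in memo:
            memo[term] = 1 + min(oracle_depth(p) for p in dag.parents(term))
        return memo[term]

    def oracle_lineage(term):
        out = {term}
        for p in dag.parents(term):
            out |= oracle_lineage(p)
        return out

    for level in (1, 2, 3):
        got = dict(an.level_distribution(assigns, dag, "biological_process", level))
        expected = {}
        for a in assigns:
            for t in oracle_lineage(a.term):
                if oracle_depth(t) == level:
                    expected.setdefault(t, set()).add(a.sequence_id)
        assert got == {t: len(s) for t, s in expected.items()}


def test_top_terms_ranking_and_ties(toy_dag):
    assigns = [
        an.GOAssignment("s1", "GO:4", 50.0),
        an.GOAssignment("s2", "GO:4", 50.0),
        an.GOAssignment("s3", "GO:4", 50.0),
        an.GOAssignment("s4", "GO:6", 50.0),
    ]
    assert an.top_terms(assigns, toy_dag, 1) == [("GO:4", 3)]
    tied = [
        an.GOAssignment("s1", "GO:5", 50.0),
        an.GOAssignment("s2", "GO:4", 50.0),
    ]
    assert an.top_terms(tied, toy_dag, 2) == [("GO:4", 1), ("GO:5", 1)]


def test_obo_round_trip(tmp_path):
    obo = tmp_path / "mini.obo"
    obo.write_text(
        "format-version: 1.2\n\n"
        "[Term]\nid: GO:0000001\nname: root\nnamespace: biological_process\n\n"
        "[Term]\nid: GO:0000002\nname: child\nnamespace: biological_process\n"
        "is_a: GO:0000001 ! root\n\n"
        "[Term]\nid: GO:0000003\nname: grandchild\nnamespace: biological_process\n"
        "is_a: GO:0000002 ! child\n"
    )
    dag = an.GODag.from_obo(obo)
    assert dag.depth("GO:0000003") == 2
    assert dag.ancestors("GO:0000003") == {"GO:0000001", "GO:0000002"}
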