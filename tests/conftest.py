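"""Shared fixtures: small simulated studies and a synthetic ontology."""

from __future__ import annotations

import numpy as np
import pytest

from estpipe import annotate as an
from estpipe import datasets, synthio


@pytest.fixture(scope="session")
def small_study():
    """A small error-free tagged study with two planted phase-biased
    transcripts and a few contaminant reads."""
    cfg = synthio.SimConfig(
        seed=11,
        n_transcripts=10,
        n_reads=100,
        error_scale=0.0,
        phase_bias=((9, 0), (0, 9)),
        contaminant_fraction=0.05,
        start_jitter=250,
    )
    transcripts, reads, ledger, table = synthio.simulate_study(cfg)
    return cfg, transcripts, reads, ledger, table


@pytest.fixture(scope="session")
def pvk_model():
    from estpipe import peptidemine

    return peptidemine.analyze_precursor(synthio.pvk_fixture_precursor())


def random_dag(n_terms: int, seed: int) -> an.GODag:
    """Random single-namespace is_a DAG with 1-2 parents per term."""
    rng = np.random.default_rng(seed)
    edges = []
    ids = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.3)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            edges.append((ids[i], ids[int(p)]))
    return an.GODag.from_edges(edges, namespaces={ids[0]: "biological_process"})


@pytest.fixture(scope="session")
def masking_refs():
    return datasets.masking_refs()


@pytest.fixture(scope="session")
def contaminant_refs():
    return datasets.contaminant_refs()
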