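"""Read-cleanup tests, including the exhaustive quality-window oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estpipe import datasets, readqc
from estpipe.align import revcomp
from estpipe.readqc import TrimPolicy, quality_trim


def brute_force_quality_interval(low: np.ndarray, tol: int):
    """Independent oracle: enumerate every interval and check the 50-base
    window rule directly; returns the longest qualifying (start, end),
    1-based, leftmost on ties, or None."""
    n = len(low)
    csum = np.concatenate([[0], np.cumsum(low)])
    if n >= 50:
        win = csum[50:] - csum[:-50]
    best = None
    for i in range(n):
        for j in range(i, n):
            length = j - i + 1
            if length < 50:
                ok = csum[j + 1] - csum[i] <= tol
            else:
                ok = win[i : j - 48].max() <= tol
            if ok and (best is None or length > best[1] - best[0] + 1):
                best = (i + 1, j + 1)
    return best


def _oracle_check(quals, tol):
    low = (np.asarray(quals) < 20).astype(int)
    policy = TrimPolicy(min_high_quality_length=1, tolerance=tol)
    got = quality_trim("A" * len(quals), quals, policy)
    expected = brute_force_quality_interval(low, tol)
    if expected is None:
        assert got is None
    else:
        # the interval must be a longest qualifying one
        assert got is not None
        assert got[1] - got[0] == expected[1] - expected[0]
        assert brute_force_quality_interval(low, tol)[1] - expected[0] >= 0
        span = low[got[0] - 1 : got[1]]
        n = len(span)
        if n < 50:
            assert span.sum() <= tol
        else:
            c = np.convolve(span, np.ones(50, dtype=int), mode="valid")
            assert c.max() <= tol


def test_quality_trim_all_high_quality():
    assert quality_trim("A" * 300, [40] * 300) == (1, 300)


def test_quality_trim_high_then_low_is_cut_at_the_boundary():
    quals = [40] * 150 + [10] * 150
    policy = TrimPolicy(min_high_quality_length=100, tolerance=0)
    assert quality_trim("A" * 300, quals, policy) == (1, 150)
    # with the default 200-base requirement the read is low quality
    assert quality_trim("A" * 300, quals) is None


def test_quality_trim_length_mismatch_rejected():
    with pytest.raises(ValueError):
        quality_trim("AAA", [40, 40])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.sampled_from([10, 19, 20, 40]), min_size=1, max_size=130),
    st.integers(min_value=0, max_value=3),
)
def test_quality_trim_equals_exhaustive_interval_search(quals, tol):
    _oracle_check(quals, tol)


def test_pure_vector_read_is_short_insert(masking_refs):
    seq = datasets.VECTOR_STUB * 3
    d = readqc.dispose("r", seq, [40] * len(seq), vector_refs=masking_refs)
    assert d.status == "short_insert"
    covered = set()
    for m in d.masks:
        if m.mask_class == "vector":
            covered.update(range(m.start, m.end + 1))
    assert len(covered) >= 0.95 * len(seq)


def test_vector_prefix_masked_and_clean_interval_follows(masking_refs):
    rng = np.random.default_rng(0)
    insert = "".join(rng.choice(list("ACGT"), size=300))
    seq = datasets.VECTOR_STUB[:40] + insert
    masks = readqc.mask_vector(seq, masking_refs)
    assert any(m.start == 1 and m.end >= 38 for m in masks)
    d = readqc.dispose(
        "r", seq, [40] * len(seq), TrimPolicy(min_clean_length=200), vector_refs=masking_refs
    )
    assert d.status == "clean" and d.clean_start > 38


def test_unrelated_sequence_gets_no_vector_masks(masking_refs):
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    assert readqc.mask_vector(seq, masking_refs) == []


@pytest.mark.parametrize("seq", ["A" * 100, "AT" * 40])
def test_low_complexity_repeats_fully_masked(seq):
    masks = readqc.mask_low_complexity(seq)
    assert masks and masks[0].start == 1 and masks[-1].end == len(seq)


def test_random_sequence_rarely_masked():
    rng = np.random.default_rng(2)
    total = masked = 0
    for _ in range(20):
        p = [0.2, 0.3, 0.3, 0.2]  # 60% GC
        seq = "".join(rng.choice(list("ACGT"), size=500, p=p))
        for m in readqc.mask_low_complexity(seq):
            masked += m.end - m.start + 1
        total += 500
    assert masked / total < 0.05


def test_contaminant_screen_detects_decoys_and_chimeras(contaminant_refs):
    decoy = contaminant_refs["rrna_decoy"]
    rng = np.random.default_rng(3)
    transcript = "".join(rng.choice(list("ACGT"), size=300))
    assert readqc.screen_contaminants(decoy[100:600], contaminant_refs)
    assert readqc.screen_contaminants(revcomp(decoy[100:600]), contaminant_refs)
    assert not readqc.screen_contaminants(transcript, contaminant_refs)
    chimera = transcript[:150] + decoy[500:620]
    assert readqc.screen_contaminants(chimera, contaminant_refs)


def test_all_low_quality_read_is_low_quality():
    d = readqc.dispose("r", "ACGT" * 100, [10] * 400)
    assert d.status == "low_quality"


def test_clean_read_with_vector_suffix_keeps_insert_only(masking_refs):
    rng = np.random.default_rng(4)
    insert = "".join(rng.choice(list("ACGT"), size=250))
    seq = insert + datasets.VECTOR_STUB[:60]
    d = readqc.dispose("r", seq, [40] * len(seq), vector_refs=masking_refs)
    assert d.status == "clean"
    assert d.clean_start == 1 and d.clean_end <= 250


def test_disposition_agrees_with_ledger_for_error_free_reads(
    small_study, masking_refs, contaminant_refs
):
    cfg, transcripts, reads, ledger, _ = small_study
    disp = readqc.dispose_batch(
        reads, vector_refs=masking_refs, contaminant_refs=contaminant_refs
    )
    led = ledger.set_index("read_id")
    agree = 0
    for d in disp:
        truth_contaminant = bool(led.loc[d.read_id, "contaminant"])
        expected = "contaminant" if truth_contaminant else "clean"
        agree += d.status == expected
    assert agree / len(disp) >= 0.99


def test_cleanup_is_idempotent(small_study, masking_refs, contaminant_refs):
    _, _, reads, _, _ = small_study
    rec = reads[0]
    d1 = readqc.dispose(
        rec.id, str(rec.seq), rec.letter_annotations["phred_quality"],
        vector_refs=masking_refs, contaminant_refs=contaminant_refs,
    )
    assert d1.status == "clean"
    sub = str(rec.seq)[d1.clean_start - 1 : d1.clean_end]
    subq = rec.letter_annotations["phred_quality"][d1.clean_start - 1 : d1.clean_end]
    d2 = readqc.dispose(rec.id, sub, subq, vector_refs=masking_refs, contaminant_refs=contaminant_refs)
    assert d2.status == "clean"
    assert (d2.clean_start, d2.clean_end) == (1, len(sub))
    assert d2.masks == []
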