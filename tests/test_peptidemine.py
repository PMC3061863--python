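"""Precursor mining: signal heuristic, cleavage grammar, family motifs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estpipe import datasets, peptidemine as pm, synthio
from estpipe.align import revcomp
from estpipe.synthio import _backtranslate


def test_scan_finds_planted_precursor_orf():
    cfg = synthio.SimConfig(seed=9, n_transcripts=4, n_precursor_transcripts=1)
    transcripts, _ = synthio.simulate_transcriptome(cfg)
    tmap = {t.transcript_id: t.seq for t in transcripts}
    hits = pm.scan_for_precursors(tmap, {"pvk2": "GLLAFPRV"})
    assert any(tid == "T1" and synthio.pvk_fixture_precursor() in orf for tid, orf in hits)


def test_scan_on_minus_strand():
    protein = synthio.pvk_fixture_precursor()
    dna = "ACGTAC" + _backtranslate(protein) + "TAAGGCATC"
    hits = pm.scan_for_precursors({"t": revcomp(dna)}, {"pvk2": "GLLAFPRV"})
    assert any(protein in orf for _, orf in hits)


def test_scan_random_transcript_with_stringent_threshold_finds_nothing():
    rng = np.random.default_rng(10)
    dna = "".join(rng.choice(list("ACGT"), size=900))
    assert pm.scan_for_precursors({"t": dna}, {"q": "GLLAFPRV"}, score_threshold=45.0) == []


def test_signal_cleaved_exactly_after_fixture_signal():
    protein = synthio.pvk_fixture_precursor()
    assert pm.predict_signal(protein) == (1, len(datasets.GENERIC_SIGNAL))


def test_poly_asp_n_terminus_has_no_signal():
    assert pm.predict_signal("M" + "D" * 40 + "KR") is None


def test_non_met_start_rejected():
    with pytest.raises(ValueError):
        pm.predict_signal("KLLVLLLVLLVLLVLASA")


def test_find_sites_classes():
    sites = pm.find_sites("AAKRVV")
    assert [(s.position, s.site_class, s.motif) for s in sites] == [(4, "dibasic", "KR")]
    [furin] = [s for s in pm.find_sites("ARSKRA") if s.site_class == "furin"]
    assert furin.position == 5 and furin.motif == "RSKR"
    assert pm.find_sites("AGSTVQNML") == []
    mono = [s for s in pm.find_sites("AARVA") if s.site_class == "monobasic"]
    assert [(s.position, s.motif) for s in mono] == [(3, "R")]


def test_release_single_amidated_peptide():
    peps = pm.release_peptides("TSSLFPHPRIGKR")
    assert [(p.sequence, p.amidated) for p in peps] == [("TSSLFPHPRI", True)]


def test_release_trims_basic_without_amidation():
    # at a siteless precursor end trailing basics are trimmed, no amide
    peps = pm.release_peptides("ADEFNQTMK")
    assert [(p.sequence, p.amidated) for p in peps] == [("ADEFNQTM", False)]
    # before a Lys-Arg site only the site's own pair is removed, so a
    # genuine peptide-terminal Lys survives (as in the PVKDP peptide)
    peps = pm.release_peptides("ADEFNQTMKKR")
    assert [(p.sequence, p.amidated) for p in peps] == [("ADEFNQTMK", False)]


def test_release_reproduces_all_seven_printed_pvk_precursor_peptides(pvk_model):
    table = datasets.pvk_precursor_peptides()
    got = [(p.sequence, p.amidated) for p in pvk_model.primary_peptides]
    expected = [(r.sequence, bool(r.amidated)) for r in table.itertuples()]
    assert got == expected


def test_enumerate_forms_reproduces_tachykinin_footnote_pair():
    forms = {(f.sequence, f.amidated) for f in pm.enumerate_forms("GNTKKAPVGFYGTRG")}
    assert ("GNTKKAPVGFYGTR", True) in forms
    assert ("APVGFYGTR", True) in forms


def test_enumerate_forms_reproduces_myotropin_footnote_triple(pvk_model):
    mt3 = "SLRLRLPAAAWLAAGDVGNGKGDFTPRL"
    forms = {(f.sequence, f.amidated) for f in pvk_model.alternative_forms[mt3]}
    assert {(mt3, True), ("LPAAAWLAAGDVGNGKGDFTPRL", True), ("GDFTPRL", True)} <= forms


def test_enumerate_forms_without_internal_sites_is_singleton():
    forms = pm.enumerate_forms("ADQEFNTG")
    assert {(f.sequence, f.amidated) for f in forms} == {("ADQEFNT", True)}


def test_enumerate_forms_size_bound_and_substring_property():
    rng = np.random.default_rng(11)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(20):
        frag = "".join(rng.choice(aa, size=int(rng.integers(5, 25))))
        internal = [i + 1 for i, c in enumerate(frag[:-1]) if c in "KR"]
        forms = pm.enumerate_forms(frag)
        k = len(internal)
        assert len(forms) <= (k + 2) * (k + 1) // 2
        for f in forms:
            assert f.sequence in frag


@pytest.mark.parametrize(
    "seq, amidated, expected",
    [
        ("KGLVANARV", True, ("PVK",)),
        ("DSLWFGPRV", True, ("PVK",)),
        ("SLRLRLPAAAWLAAGDVGNGKGDFTPRL", True, ("myotropin",)),
        ("AGLGQDETRAGTK", False, ()),
        ("APLSGFYGVR", True, ("tachykinin",)),
        ("QVTFSRDWSP", False, ()),  # pyroGlu candidate but not amidated
        ("QLNFTPNWGT", True, ("AKH-like",)),
    ],
)
def test_family_motifs(seq, amidated, expected):
    got = pm.classify_family(pm.PredictedPeptide(seq, amidated))
    assert got == expected


def test_pvk_rule_marks_exactly_the_two_new_pvks(pvk_model):
    table = datasets.pvk_precursor_peptides()
    new = set(table.loc[~table["previously_known"], "sequence"])
    labelled = {p.sequence: p.families for p in pvk_model.primary_peptides}
    pvk_new = {s for s in new if "PVK" in labelled[s]}
    assert pvk_new == {"KGLVANARV", "DSLWFGPRV"}


_SAFE_AA = "ADEFHINPQSTVWY"  # no basics, no G/L/M edge cases needed


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.text(_SAFE_AA, min_size=4, max_size=20), st.booleans()),
        min_size=1,
        max_size=6,
    )
)
def test_roundtrip_release_recovers_built_precursor(segments):
    """Peptides without internal cleavage motifs survive the build -> signal
    -> release round trip exactly, amidation flags included."""
    protein = synthio.build_precursor(datasets.GENERIC_SIGNAL, segments)
    signal = pm.predict_signal(protein)
    assert signal == (1, len(datasets.GENERIC_SIGNAL))
    peps = pm.release_peptides(protein[signal[1] :])
    assert [(p.sequence, p.amidated) for p in peps] == [(s, a) for s, a in segments]
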