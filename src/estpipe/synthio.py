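"""Synthetic EST study generator with full ground truth.

Emulates the raw material of a 5'-sequenced, tagged, normalized cDNA library
from locust CNS: transcripts (optionally carrying planted neuropeptide
precursor reading frames and phase-biased copy numbers), vector-flanked
tagged reads with Phred-style quality decay and quality-dependent
substitution errors, contaminant reads copied from decoy references, and
Cq tables for the qRT-PCR module.  Every emitted read has a ground-truth
ledger row, so downstream stages can be scored exactly.

All randomness flows from one :class:`numpy.random.Generator` seeded by
``SimConfig.seed``; a fixed seed reproduces byte-identical FASTA/FASTQ/TSV
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import datasets
from .align import revcomp
from .tags import LIB2, LibraryTagScheme

__all__ = [
    "SimConfig",
    "Transcript",
    "build_precursor",
    "pvk_fixture_precursor",
    "simulate_transcriptome",
    "emit_reads",
    "simulate_study",
    "simulate_cq",
    "write_fasta",
    "write_fastq",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")

# one fixed codon per residue for back-translating planted precursors
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Read lengths follow a truncated normal (mode near the 600-900 nt
    high-quality range of the original chromatograms); per-base substitution
    probability is ``error_scale * 10**(-Q/10)`` with a flat high-quality
    plateau decaying linearly towards the read end.
    """

    seed: int = 0
    n_transcripts: int = 50
    n_reads: int = 500
    transcript_len_min: int = 900
    transcript_len_max: int = 2000
    polya_len: int = 18
    # planted structure
    n_precursor_transcripts: int = 0
    #: per biased transcript, (crowded, isolated) copy numbers
    phase_bias: tuple[tuple[int, int], ...] = ()
    # read geometry
    read_len_mean: float = 750.0
    read_len_sd: float = 150.0
    read_len_min: int = 200
    read_len_max: int = 1100
    vector_prefix_len: int = 30
    insert_min_len: int = 600  # size selection of inserts
    start_jitter: int = 0  # max 5' truncation of the insert, bases
    # quality / error model
    q_high: float = 40.0
    q_low: float = 10.0
    decay_start: int = 450
    error_scale: float = 1.0
    contaminant_fraction: float = 0.0

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.n_transcripts < 1 or self.n_reads < 0:
            raise ValueError("n_transcripts must be >=1 and n_reads >=0")
        if not (0 < self.transcript_len_min <= self.transcript_len_max):
            raise ValueError("bad transcript length range")
        if not (0 < self.read_len_min <= self.read_len_max):
            raise ValueError("bad read length range")
        if self.read_len_sd <= 0:
            raise ValueError("read_len_sd must be positive")
        if not 0.0 <= self.contaminant_fraction <= 1.0:
            raise ValueError("contaminant_fraction must be in [0,1]")
        if self.error_scale < 0:
            raise ValueError("error_scale must be >=0")
        if not (0 < self.q_low <= self.q_high):
            raise ValueError("need 0 < q_low <= q_high")
        if self.n_precursor_transcripts > self.n_transcripts:
            raise ValueError("more precursor transcripts than transcripts")
        if len(self.phase_bias) > self.n_transcripts - self.n_precursor_transcripts:
            raise ValueError("more phase-biased transcripts than transcripts")
        for c, i in self.phase_bias:
            if c < 0 or i < 0 or (c == 0 and i == 0):
                raise ValueError("phase bias copies must be >=0 and not both 0")


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    seq: str  # sense strand, poly(A) tail included
    copy_crowded: int = 1
    copy_isolated: int = 1
    precursor_protein: str | None = None


def build_precursor(signal: str, segments: list[tuple[str, bool]]) -> str:
    """Assemble a neuropeptide precursor protein.

    Each ``(peptide, amidated)`` segment is appended after the signal
    peptide; amidated peptides gain the C-terminal amidation glycine and
    every segment is closed with a Lys-Arg dibasic convertase site, the
    canonical flanking arrangement of insect neuropeptide precursors.
    """
    if not segments:
        raise ValueError("a precursor needs at least one peptide segment")
    for pep, _ in segments:
        if not pep or set(pep) - _AA:
            raise ValueError(f"non-standard residues in peptide {pep!r}")
    if not signal or set(signal) - _AA:
        raise ValueError("non-standard residues in signal peptide")
    parts = [signal]
    for pep, amidated in segments:
        parts.append(pep + ("G" if amidated else "") + "KR")
    return "".join(parts)


def pvk_fixture_precursor() -> str:
    """The synthetic PVK (capability-like) precursor: the generic signal
    followed by the seven peptides the precursor encodes, in table order."""
    peps = datasets.pvk_precursor_peptides()
    segments = [(r.sequence, bool(r.amidated)) for r in peps.itertuples()]
    return build_precursor(datasets.GENERIC_SIGNAL, segments)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, size=n)])


def _backtranslate(protein: str) -> str:
    return "".join(_CODON[aa] for aa in protein)


def simulate_transcriptome(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    precursor_proteins: list[str] | None = None,
) -> tuple[list[Transcript], pd.DataFrame]:
    """Generate the transcript set and its ground-truth table.

    The first ``n_precursor_transcripts`` transcripts carry a back-translated
    precursor reading frame (default: the PVK fixture precursor) inside a
    random-UTR context; the next ``len(phase_bias)`` transcripts get the
    configured (crowded, isolated) copy numbers; all others are balanced 1:1.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if precursor_proteins is None:
        precursor_proteins = [pvk_fixture_precursor()] * cfg.n_precursor_transcripts
    if len(precursor_proteins) != cfg.n_precursor_transcripts:
        raise ValueError("precursor_proteins length must match n_precursor_transcripts")

    transcripts: list[Transcript] = []
    width = len(str(cfg.n_transcripts))
    for i in range(cfg.n_transcripts):
        tid = f"T{i + 1:0{width}d}"
        protein = None
        if i < cfg.n_precursor_transcripts:
            protein = precursor_proteins[i]
            orf = _backtranslate(protein) + "TAA"
            utr5 = _random_dna(rng, 60)
            utr3 = _random_dna(rng, 120)
            seq = utr5 + orf + utr3
        else:
            n = int(rng.integers(cfg.transcript_len_min, cfg.transcript_len_max + 1))
            seq = _random_dna(rng, n)
        seq = seq + "A" * cfg.polya_len
        copy_c, copy_i = 1, 1
        j = i - cfg.n_precursor_transcripts
        if 0 <= j < len(cfg.phase_bias):
            copy_c, copy_i = cfg.phase_bias[j]
        transcripts.append(
            Transcript(tid, seq, copy_crowded=copy_c, copy_isolated=copy_i, precursor_protein=protein)
        )

    table = pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in transcripts],
            "length": [len(t.seq) for t in transcripts],
            "copy_crowded": [t.copy_crowded for t in transcripts],
            "copy_isolated": [t.copy_isolated for t in transcripts],
            "is_precursor": [t.precursor_protein is not None for t in transcripts],
        }
    )
    return transcripts, table


def _read_length(cfg: SimConfig, rng: np.random.Generator) -> int:
    for _ in range(1000):
        n = rng.normal(cfg.read_len_mean, cfg.read_len_sd)
        if cfg.read_len_min <= n <= cfg.read_len_max:
            return int(round(n))
    return int(cfg.read_len_mean)


def _quality_profile(cfg: SimConfig, n: int) -> np.ndarray:
    pos = np.arange(n, dtype=float)
    q = np.full(n, cfg.q_high)
    if n > cfg.decay_start:
        tail = pos >= cfg.decay_start
        frac = (pos[tail] - cfg.decay_start) / max(n - cfg.decay_start, 1)
        q[tail] = cfg.q_high - (cfg.q_high - cfg.q_low) * frac
    return np.clip(np.round(q), 2, 60).astype(int)


_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def _inject_errors(seq: str, quals: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> tuple[str, int]:
    if cfg.error_scale == 0:
        return seq, 0
    p = cfg.error_scale * np.power(10.0, -quals / 10.0)
    hit = rng.random(len(seq)) < p
    if not hit.any():
        return seq, 0
    chars = list(seq)
    n_err = 0
    for i in np.flatnonzero(hit):
        base = chars[i]
        if base in _OTHER:
            chars[i] = _OTHER[base][rng.integers(0, 3)]
            n_err += 1
    return "".join(chars), n_err


def emit_reads(
    transcripts: list[Transcript],
    cfg: SimConfig,
    scheme: LibraryTagScheme = LIB2,
    rng: np.random.Generator | None = None,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Emit 5' reads as FASTQ-style records plus the ground-truth ledger.

    Read layout for a 5'-tagged library (lib2): vector stub, anchor, tag,
    then the insert from its 5' end; reads that run past the insert continue
    into downstream vector.  For the 3'-tagged lib1 the tag is only visible
    (as its reverse complement, after the poly(A)) on reads that reach the
    insert's 3' end, mirroring why only a minority of first-library reads
    were phase-assignable.  Contaminant reads are fragments of the decoy
    references behind a vector stub, with no anchor or tag.
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)

    decoys = datasets.contaminant_refs()
    decoy_ids = sorted(decoys)
    vec = datasets.VECTOR_STUB
    vec_pfx = vec[-cfg.vector_prefix_len:]

    weights_c = np.array([t.copy_crowded for t in transcripts], dtype=float)
    weights_i = np.array([t.copy_isolated for t in transcripts], dtype=float)

    records: list[SeqRecord] = []
    rows: list[dict] = []
    width = len(str(max(cfg.n_reads, 1)))
    for r in range(cfg.n_reads):
        rid = f"R{r + 1:0{width}d}"
        length = _read_length(cfg, rng)
        is_cont = rng.random() < cfg.contaminant_fraction
        if is_cont:
            did = decoy_ids[int(rng.integers(0, len(decoy_ids)))]
            ref = decoys[did]
            start = int(rng.integers(0, max(len(ref) - 200, 1)))
            insert = ref[start : start + length]
            seq = vec_pfx + insert
            seq = seq[:length]
            row_src, tissue, phase, tag = did, "", "", ""
            clean_start, clean_end = len(vec_pfx) + 1, len(seq)
            insert_start = start + 1
        else:
            tissue = ("HG", "VNC")[int(rng.integers(0, 2))]
            phase = ("I", "C")[int(rng.integers(0, 2))]
            w = weights_c if phase == "C" else weights_i
            if w.sum() == 0:
                w = np.ones_like(w)
            t = transcripts[int(rng.choice(len(transcripts), p=w / w.sum()))]
            entry = next(e for e in scheme.entries if (e.tissue, e.phase) == (tissue, phase))
            tag = entry.tag
            jitter = int(rng.integers(0, cfg.start_jitter + 1)) if cfg.start_jitter else 0
            jitter = min(jitter, max(len(t.seq) - cfg.read_len_min, 0))
            insert = t.seq[jitter:]
            if scheme.tag_side == "5p":
                head = vec_pfx + scheme.anchor + tag
                body = insert
                tail_extra = vec  # downstream vector if the read runs out of insert
            else:
                head = vec_pfx
                body = insert + revcomp(tag) + revcomp(scheme.anchor)
                tail_extra = vec
            seq = (head + body + tail_extra)[:length]
            row_src = t.transcript_id
            clean_start = len(head) - (len(tag) + len(scheme.anchor) if scheme.tag_side == "5p" else 0) + 1
            insert_end = min(length, len(head) + len(body))
            clean_end = insert_end
            insert_start = jitter + 1
        quals = _quality_profile(cfg, len(seq))
        seq, n_err = _inject_errors(seq, quals, cfg, rng)
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = quals.tolist()
        records.append(rec)
        rows.append(
            {
                "read_id": rid,
                "source_id": row_src,
                "tissue": tissue,
                "phase": phase,
                "scheme_id": scheme.scheme_id,
                "tag": tag,
                "clean_start": clean_start,
                "clean_end": clean_end,
                "insert_start": insert_start,
                "contaminant": is_cont,
                "n_errors": n_err,
            }
        )
    ledger = pd.DataFrame(rows)
    return records, ledger


def simulate_study(
    cfg: SimConfig, scheme: LibraryTagScheme = LIB2
) -> tuple[list[Transcript], list[SeqRecord], pd.DataFrame, pd.DataFrame]:
    """Transcriptome + reads in one call.

    Returns (transcripts, reads, read_ledger, transcript_table).
    """
    rng = np.random.default_rng(cfg.seed)
    transcripts, table = simulate_transcriptome(cfg, rng=rng)
    reads, ledger = emit_reads(transcripts, cfg, scheme=scheme, rng=rng)
    return transcripts, reads, ledger, table


# ---------------------------------------------------------------------------
# qRT-PCR simulation


def simulate_cq(
    genes: list[str],
    reference_genes: list[str],
    groups: list[str],
    n_replicates: int = 4,
    fold_changes: dict[str, dict[str, float]] | None = None,
    efficiency: float = 2.0,
    sigma: float = 0.2,
    sigma_technical: float = 0.0,
    loading_sd: float = 0.3,
    n_technical: int = 2,
    calibrator_group: str | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a Cq table for groups x genes x biological replicates.

    Expression is log-normal on the Cq scale: each sample gets a shared
    loading offset (cancelled later by reference normalization) and each
    (sample, gene) a Gaussian Cq deviation ``sigma``; a gene at fold change
    ``f`` in a group sits ``log_E(f)`` cycles below the calibrator group.
    Returns ``(cq_table, truth)`` where truth holds the simulated fold
    change per (gene, group).
    """
    if len(reference_genes) < 2:
        raise ValueError("at least two reference genes are required")
    if not set(reference_genes) <= set(genes):
        raise ValueError("reference_genes must be a subset of genes")
    if n_replicates < 1 or n_technical < 1:
        raise ValueError("replicate counts must be >=1")
    if not 1.0 < efficiency <= 2.2:
        raise ValueError("efficiency must be in (1, 2.2]")
    fold_changes = fold_changes or {}
    calibrator_group = calibrator_group or groups[0]
    if calibrator_group not in groups:
        raise ValueError("calibrator_group not in groups")

    rng = np.random.default_rng(seed)
    base_cq = {g: float(rng.uniform(20.0, 26.0)) for g in genes}
    log_e = np.log2(efficiency)

    rows = []
    truth_rows = []
    for gene in genes:
        for group in groups:
            fold = 1.0 if gene in reference_genes else fold_changes.get(gene, {}).get(group, 1.0)
            truth_rows.append({"gene": gene, "group": group, "fold": fold})

    calibrator_sample = f"{calibrator_group}_r1"
    for group in groups:
        for rep in range(1, n_replicates + 1):
            sample = f"{group}_r{rep}"
            loading = float(rng.normal(0.0, loading_sd)) if loading_sd > 0 else 0.0
            for gene in genes:
                fold = 1.0 if gene in reference_genes else fold_changes.get(gene, {}).get(group, 1.0)
                bio = float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
                cq_true = base_cq[gene] - np.log2(fold) / log_e - loading + bio
                for tech in range(1, n_technical + 1):
                    tech_noise = float(rng.normal(0.0, sigma_technical)) if sigma_technical > 0 else 0.0
                    rows.append(
                        {
                            "sample_id": sample,
                            "group": group,
                            "gene": gene,
                            "replicate": tech,
                            "cq": cq_true + tech_noise,
                            "efficiency": efficiency,
                            "is_reference": gene in reference_genes,
                            "is_calibrator": sample == calibrator_sample,
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# IO helpers


def write_fasta(records, path) -> None:
    recs = [
        r if isinstance(r, SeqRecord) else SeqRecord(Seq(r[1]), id=r[0], description="")
        for r in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(records: list[SeqRecord], path) -> None:
    SeqIO.write(records, str(path), "fastq")


def transcripts_as_records(transcripts: list[Transcript]) -> list[SeqRecord]:
    return [SeqRecord(Seq(t.seq), id=t.transcript_id, description="") for t in transcripts]
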