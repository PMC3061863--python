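"""Calibrator-relative, multi-reference-normalized qRT-PCR quantification.

Relative quantities follow the classical efficiency-corrected calibrator
model: for gene g in sample s, ``RQ = E_g ** (Cq_cal(g) - Cq_s(g))`` with
technical replicates averaged on the Cq (log) scale, so the calibrator
sample is exactly 1 for every gene.  Normalized quantities divide by the
geometric mean of the reference genes' RQ in the same sample, cancelling
loading differences.  Reference-gene stability is ranked by the geNorm
M-value (mean pairwise SD of log2 expression ratios), and phase
differences are tested with a two-sample Student's t-test (pooled
variance, as in the original analysis; Welch available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "validate_cq_table",
    "relative_quantity",
    "stability",
    "phase_test",
    "group_tests",
    "RQResult",
    "StabilityRank",
]

REQUIRED_COLUMNS = [
    "sample_id",
    "group",
    "gene",
    "replicate",
    "cq",
    "efficiency",
    "is_reference",
    "is_calibrator",
]


@dataclass(frozen=True)
class RQResult:
    gene: str
    sample_id: str
    relative_quantity: float
    normalized_quantity: float


@dataclass(frozen=True)
class StabilityRank:
    gene: str
    m_value: float
    rank: int


def validate_cq_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Cq table missing columns: {missing}")
    if (table["cq"] <= 0).any():
        raise ValueError("Cq values must be positive")
    eff = table["efficiency"].fillna(2.0)
    if ((eff <= 1.0) | (eff > 2.2)).any():
        raise ValueError("efficiencies must be in (1, 2.2]")
    cal_samples = table.loc[table["is_calibrator"], "sample_id"].unique()
    if len(cal_samples) != 1:
        raise ValueError("exactly one calibrator sample must be designated")
    if table.loc[table["is_reference"], "gene"].nunique() < 2:
        raise ValueError("at least two reference genes are required")
    out = table.copy()
    out["efficiency"] = eff
    return out


def relative_quantity(table: pd.DataFrame) -> pd.DataFrame:
    """Per (gene, sample) calibrator-relative and reference-normalized
    quantities.  Returns a frame with columns gene, sample_id, group,
    is_reference, relative_quantity, normalized_quantity."""
    table = validate_cq_table(table)
    cal_sample = table.loc[table["is_calibrator"], "sample_id"].iloc[0]

    # technical replicates averaged on the Cq scale
    agg = (
        table.groupby(["gene", "sample_id"], sort=True)
        .agg(
            cq=("cq", "mean"),
            efficiency=("efficiency", "mean"),
            group=("group", "first"),
            is_reference=("is_reference", "first"),
        )
        .reset_index()
    )
    cal_cq = agg.loc[agg["sample_id"] == cal_sample].set_index("gene")["cq"]
    missing_cal = set(agg["gene"]) - set(cal_cq.index)
    if missing_cal:
        raise ValueError(f"calibrator sample lacks measurements for genes: {sorted(missing_cal)}")
    agg["relative_quantity"] = agg["efficiency"] ** (agg["gene"].map(cal_cq) - agg["cq"])

    ref = agg[agg["is_reference"]]
    norm: dict[str, float] = {}
    for sample, grp in ref.groupby("sample_id"):
        norm[sample] = float(np.exp(np.mean(np.log(grp["relative_quantity"]))))
    missing = set(agg["sample_id"]) - set(norm)
    if missing:
        raise ValueError(f"samples lacking reference-gene measurements: {sorted(missing)}")
    agg["normalized_quantity"] = agg["relative_quantity"] / agg["sample_id"].map(norm)
    return agg[["gene", "sample_id", "group", "is_reference", "relative_quantity", "normalized_quantity"]]


def stability(table: pd.DataFrame, candidates: list[str] | None = None) -> list[StabilityRank]:
    """geNorm reference stability: M(g) = mean over other candidates h of
    the SD across samples of log2(RQ_g / RQ_h); lower M = more stable."""
    rq = relative_quantity(table)
    if candidates is None:
        candidates = sorted(rq.loc[rq["is_reference"], "gene"].unique())
    if len(candidates) < 3:
        raise ValueError("stability ranking needs at least three candidate genes")
    pivot = rq.pivot_table(index="sample_id", columns="gene", values="relative_quantity")
    if pivot.shape[0] < 2:
        raise ValueError("stability ranking needs at least two samples")
    log_rq = np.log2(pivot[candidates])
    m_values = {}
    for g in candidates:
        sds = [
            float(np.std(log_rq[g] - log_rq[h], ddof=1))
            for h in candidates
            if h != g
        ]
        m_values[g] = float(np.mean(sds))
    ranked = sorted(candidates, key=lambda g: (m_values[g], g))
    return [StabilityRank(g, m_values[g], i + 1) for i, g in enumerate(ranked)]


def phase_test(
    values_a, values_b, alpha: float = 0.05, welch: bool = False
) -> tuple[float, float, bool]:
    """Two-sample Student's t-test on normalized quantities.

    Pooled-variance by default (``welch=True`` switches to unequal
    variances).  Returns (t, p, significant at alpha).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two replicates")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    if np.isnan(t):  # zero variance in both groups with equal means
        t, p = 0.0, 1.0
    return float(t), float(p), bool(p < alpha)


def group_tests(
    rq: pd.DataFrame,
    group_a: str,
    group_b: str,
    genes: list[str] | None = None,
    alpha: float = 0.05,
    welch: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-gene comparisons of normalized quantities between two groups.

    ``rq`` is the output of :func:`relative_quantity`.  Benjamini-Hochberg
    correction is available behind ``fdr`` but off by default (each gene
    is tested at alpha, matching the original single-test convention).
    """
    if genes is None:
        genes = sorted(rq.loc[~rq["is_reference"], "gene"].unique())
    rows = []
    for gene in genes:
        sub = rq[rq["gene"] == gene]
        a = sub.loc[sub["group"] == group_a, "normalized_quantity"].to_numpy()
        b = sub.loc[sub["group"] == group_b, "normalized_quantity"].to_numpy()
        t, p, sig = phase_test(a, b, alpha=alpha, welch=welch)
        rows.append(
            {
                "gene": gene,
                "mean_a": float(np.mean(a)),
                "mean_b": float(np.mean(b)),
                "t": t,
                "p": p,
                "significant": sig,
            }
        )
    out = pd.DataFrame(rows)
    if fdr and len(out):
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            val = out["p"].iloc[i] * m / (rank_idx + 1)
            prev = min(prev, val)
            adj[i] = prev
        out["p_adj"] = adj
        out["significant"] = out["p_adj"] < alpha
    return out
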