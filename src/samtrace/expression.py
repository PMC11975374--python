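"""Expression summaries: TPM, threshold fractions, delta-delta-Ct, and
dual-timepoint significance counting on a consumed DE results table.

The RNA-seq libraries behind these summaries are 3'-end tag libraries, so
TPM carries no gene-length term by default (one tag per transcript); a
length-aware mode is provided for conventional libraries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def tpm(counts: pd.DataFrame, lengths: pd.Series | None = None) -> pd.DataFrame:
    """Transcripts-per-million normalization of a genes x samples matrix.

    Without ``lengths`` (3'-end-seq mode): ``TPM = count / colsum * 1e6``.
    With per-gene lengths: counts are divided by length first, then scaled
    so every column sums to 1e6.
    """
    mat = counts.astype(float)
    if (mat.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if lengths is not None:
        lengths = lengths.reindex(mat.index)
        if lengths.isna().any() or (lengths <= 0).any():
            raise ValueError("every gene needs a positive length")
        mat = mat.div(lengths, axis=0)
    colsums = mat.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"zero-count sample(s): {list(zero.index)}")
    return mat.div(colsums, axis=1) * 1e6


def threshold_summary(
    tpm_matrix: pd.DataFrame, threshold: float = 15.0, strict: bool = True,
) -> dict:
    """Fraction of genes expressed above a TPM threshold.

    The default mirrors the reference comparison used for expression heat
    maps: a strict "higher than 15 TPM" cut.  Returns per-sample fractions
    and their pooled mean.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if tpm_matrix.empty:
        raise ValueError("empty TPM matrix")
    above = (tpm_matrix > threshold) if strict else (tpm_matrix >= threshold)
    per_sample = above.mean(axis=0)
    return {"per_sample": per_sample,
            "overall": float(per_sample.mean()),
            "threshold": float(threshold),
            "strict": strict}


def ddct(
    ct: pd.DataFrame,
    reference_gene: str = "RpL32",
    calibrator: str | None = None,
    calibrator_column: str = "condition",
) -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method.

    ``dCt = Ct_gene - Ct_reference`` within each sample; ``ddCt`` subtracts
    the mean dCt of the calibrator condition's replicates (arithmetic mean);
    fold change is ``2**(-ddCt)``.  Samples lacking a reference-gene Ct are
    excluded with a warning.

    ``ct`` columns: ``sample_id, gene, ct`` plus a condition column naming
    the calibrator level.
    """
    required = {"sample_id", "gene", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if calibrator is None:
        raise ValueError("a calibrator condition is required")
    if calibrator_column not in ct.columns:
        raise ValueError(f"Ct table lacks the {calibrator_column!r} column")
    if not np.isfinite(ct["ct"]).all():
        raise ValueError("non-finite Ct values")

    ref = (ct[ct["gene"] == reference_gene]
           .set_index("sample_id")["ct"])
    df = ct[ct["gene"] != reference_gene].copy()
    have_ref = df["sample_id"].isin(ref.index)
    if (~have_ref).any():
        dropped = sorted(df.loc[~have_ref, "sample_id"].unique())
        logger.warning("samples excluded (no %s Ct): %s", reference_gene, dropped)
        df = df[have_ref]
    df["dct"] = df["ct"] - df["sample_id"].map(ref)

    cal = df[df[calibrator_column] == calibrator]
    if cal.empty:
        raise ValueError(f"calibrator condition {calibrator!r} not present")
    cal_mean = cal.groupby("gene")["dct"].mean()
    df["ddct"] = df["dct"] - df["gene"].map(cal_mean)
    df["fold_change"] = 2.0 ** (-df["ddct"])
    return df.reset_index(drop=True)


def count_significant_in_both(
    de9: pd.DataFrame,
    de18: pd.DataFrame,
    gene_set: list[str],
    alpha: float = 0.05,
) -> dict:
    """Genes from ``gene_set`` significantly up-regulated at both timepoints.

    A gene counts if ``log2fc > 0`` and adjusted p < alpha in *both* DE
    tables (columns ``gene, log2fc, padj``).  Genes absent from a table are
    treated as not significant and logged.
    """
    if not gene_set:
        return {"count": 0, "genes": []}
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    hits = []
    tables = {"9": de9.set_index("gene"), "18": de18.set_index("gene")}
    for t in tables.values():
        if not ((t["padj"] >= 0) & (t["padj"] <= 1)).all():
            raise ValueError("adjusted p-values must lie in [0, 1]")
    for gene in gene_set:
        ok = True
        for label, t in tables.items():
            if gene not in t.index:
                logger.warning("gene %s absent from the %s hpi table; "
                               "treated as not significant", gene, label)
                ok = False
                break
            row = t.loc[gene]
            if not (row["log2fc"] > 0 and row["padj"] < alpha):
                ok = False
                break
        if ok:
            hits.append(gene)
    return {"count": len(hits), "genes": hits}
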