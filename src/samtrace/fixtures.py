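"""Small seeded synthetic datasets for the non-tracer analyses.

These emulate the shapes of the study's auxiliary tables -- an RT-qPCR Ct
table for the adenosine/adenylate kinases, a 3'-end-seq count matrix whose
TPM distribution leaves roughly 20% of genes above 15 TPM, and a pair of
differential-expression result tables in which 43 of 200 methyltransferase
genes are up-regulated at both timepoints.  Everything is regenerated
bit-identically from a seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

QPCR_GENES = ("Adk2", "Adk3", "Ak1", "Ak2")

#: mean Ct shifts relative to the 0 hpi calibrator; negative = induced.
#: Adk3 and Ak1 rise strongly with infection, Adk2/Ak2 barely move.
_QPCR_EFFECTS = {
    ("Adk2", 9): -0.2, ("Adk2", 18): -0.3,
    ("Adk3", 9): -2.0, ("Adk3", 18): -3.0,
    ("Ak1", 9): -1.5, ("Ak1", 18): -2.2,
    ("Ak2", 9): -0.1, ("Ak2", 18): -0.2,
}


def synth_ct_table(seed: int = 0, n_replicates: int = 3,
                   ct_sd: float = 0.2) -> pd.DataFrame:
    """qPCR Ct table with an RpL32 reference row in every sample."""
    rng = np.random.default_rng(seed)
    rows = []
    base_ct = {"Adk2": 22.0, "Adk3": 27.0, "Ak1": 24.0, "Ak2": 22.5}
    for tp in (0, 9, 18):
        for infected in ((False,) if tp == 0 else (False, True)):
            cond = f"{tp}hpi" + ("_INF" if infected else "")
            for rep in range(n_replicates):
                sample = f"{cond}_r{rep + 1}"
                ref_ct = 16.0 + rng.normal(0, ct_sd)
                rows.append((sample, cond, tp, infected, "RpL32", ref_ct))
                for gene in QPCR_GENES:
                    shift = _QPCR_EFFECTS.get((gene, tp), 0.0) if infected else 0.0
                    ct = base_ct[gene] + shift + rng.normal(0, ct_sd)
                    # Ct values move with the same loading as the reference
                    rows.append((sample, cond, tp, infected, gene,
                                 ct + (ref_ct - 16.0)))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "timepoint",
                                       "infected", "gene", "ct"])


def synth_counts(seed: int = 0, n_genes: int = 2000,
                 n_samples: int = 6, depth: int = 2_000_000) -> pd.DataFrame:
    """3'-end-seq-like count matrix.

    Gene abundances are log-normal with parameters chosen so that about 20%
    of genes land above 15 TPM, mirroring a typical hemocyte library.
    """
    rng = np.random.default_rng(seed)
    # lognormal(mu, sigma) scaled to TPM: exceedance P(TPM > 15) ~ 0.2
    log_abund = rng.normal(0.0, 2.6, size=n_genes)
    abund = np.exp(log_abund)
    p = abund / abund.sum()
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    cols = {}
    for s in range(n_samples):
        cols[f"sample{s + 1}"] = rng.multinomial(depth, p)
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))


def synth_de_tables(seed: int = 0, n_genes: int = 200,
                    n_both: int = 43) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """DE result tables at 9 and 18 hpi for a methyltransferase-like panel.

    Exactly ``n_both`` genes are significantly up-regulated at both
    timepoints; the remainder are null, down-regulated, or significant at
    one timepoint only.  Returns (de9, de18, gene_set).
    """
    rng = np.random.default_rng(seed)
    genes = [f"Mt{i:03d}" for i in range(n_genes)]
    both = set(rng.choice(genes, size=n_both, replace=False))
    rest = [g for g in genes if g not in both]
    one_tp_only = set(rest[: len(rest) // 4])

    def table(tp: int) -> pd.DataFrame:
        rows = []
        for g in genes:
            if g in both:
                lfc = rng.uniform(0.5, 3.0)
                padj = rng.uniform(1e-8, 0.01)
            elif g in one_tp_only and tp == 9:
                lfc = rng.uniform(0.5, 2.0)
                padj = rng.uniform(1e-4, 0.04)
            else:
                lfc = rng.normal(0.0, 0.3)
                padj = rng.uniform(0.1, 1.0)
            rows.append((g, lfc, padj))
        return pd.DataFrame(rows, columns=["gene", "log2fc", "padj"])

    return table(9), table(18), genes
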