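"""Metabolomics computations on peak-area tables.

Implements the readouts taken from LC-MS isotopologue tables:
reference-sample normalization, isotopologue fractions, the methylation
index (SAM:SAH), the remethylation threshold test against the tracer-stock
impurity, the adenosine-recycling fraction, per-protein extracellular purine
summaries, and the group statistics used in the figures (unpaired t test,
one-way ANOVA with Tukey's pairwise adjustment).

Peak tables are tidy DataFrames with columns ``sample_id, group,
metabolite, isotopologue, peak_area, detected``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: internal extraction standard, excluded from the normalization panel
INTERNAL_STANDARD = "4-fluorophenylalanine"

REQUIRED_COLUMNS = ("sample_id", "metabolite", "isotopologue", "peak_area")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    key = table[["sample_id", "metabolite", "isotopologue"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate (sample, metabolite, class) row: {dup}")


def normalization_factors(
    table: pd.DataFrame,
    reference: str,
    panel: list[str] | None = None,
) -> pd.Series:
    """Per-sample normalization factors from unlabeled (m+0) peak areas.

    For each panel metabolite, the m+0 area in a sample is divided by the
    m+0 area of the same metabolite in the reference sample; these ratios
    are averaged (arithmetic mean) over the panel to give that sample's
    factor.  The reference sample's factor is exactly 1.

    The default panel is every detected metabolite with an m+0 measurement
    in all samples; metabolites missing anywhere are dropped with a logged
    warning, and the internal extraction standard is always excluded.
    """
    _check_table(table)
    m0 = table[(table["isotopologue"] == "m+0")
               & table.get("detected", True)].copy()
    if reference not in set(table["sample_id"]):
        raise ValueError(f"reference sample {reference!r} not in table")
    samples = sorted(set(table["sample_id"]))
    wide = m0.pivot(index="metabolite", columns="sample_id", values="peak_area")
    wide = wide.reindex(columns=samples)

    if panel is None:
        complete = wide.dropna().index
        dropped = sorted(set(wide.index) - set(complete) - {INTERNAL_STANDARD})
        if dropped:
            logger.warning("normalization panel drops metabolites measured "
                           "incompletely: %s", dropped)
        panel = [m for m in complete if m != INTERNAL_STANDARD]
    if not panel:
        raise ValueError("empty normalization panel")
    missing = [m for m in panel if m not in wide.index]
    if missing:
        raise ValueError(f"panel metabolites absent from table: {missing}")

    ref = wide.loc[panel, reference]
    zero = ref[~(ref > 0)]
    if len(zero):
        raise ValueError(
            f"zero reference area for panel metabolite {zero.index[0]!r}")
    ratios = wide.loc[panel].div(ref, axis=0)
    nf = ratios.mean(axis=0)
    nf[reference] = 1.0
    nf.name = "normalization_factor"
    return nf


def normalize(table: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's peak areas by its normalization factor."""
    _check_table(table)
    missing = sorted(set(table["sample_id"]) - set(factors.index))
    if missing:
        raise ValueError(f"no normalization factor for samples: {missing}")
    out = table.copy()
    out["peak_area"] = out["peak_area"] / out["sample_id"].map(factors)
    out.attrs["normalized"] = True
    return out


def isotopologue_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, metabolite) class fractions f_{m+k} = area_k / sum_j area_j.

    Metabolites with zero total signal in a sample are flagged missing
    (NaN fractions) rather than producing 0/0.
    Returns a tidy DataFrame with columns ``sample_id, group, metabolite,
    isotopologue, fraction, total_area``.
    """
    _check_table(table)
    df = table.copy()
    if "detected" in df.columns:
        df = df[df["detected"]]
    group_cols = ["sample_id", "metabolite"]
    totals = df.groupby(group_cols)["peak_area"].transform("sum")
    df = df.assign(total_area=totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        df["fraction"] = np.where(totals > 0, df["peak_area"] / totals, np.nan)
    zero = df.loc[~(df["total_area"] > 0), group_cols].drop_duplicates()
    for _, row in zero.iterrows():
        logger.warning("all-zero metabolite flagged missing: %s / %s",
                       row["sample_id"], row["metabolite"])
    cols = [c for c in ("sample_id", "group", "metabolite", "isotopologue",
                        "fraction", "total_area") if c in df.columns]
    return df[cols].reset_index(drop=True)


def labeled_fraction(
    fractions: pd.DataFrame, metabolite: str,
    classes: tuple[str, ...] | None = None,
) -> pd.Series:
    """Per-sample labeled share of a metabolite (all classes but m+0)."""
    sub = fractions[fractions["metabolite"] == metabolite]
    if classes is not None:
        sub = sub[sub["isotopologue"].isin(classes)]
    else:
        sub = sub[sub["isotopologue"] != "m+0"]
    return sub.groupby("sample_id")["fraction"].sum()


def methylation_index(table: pd.DataFrame) -> pd.DataFrame:
    """SAM:SAH level ratio per sample, with a group mean and 95% CI.

    Levels are total peak areas summed over isotopologue classes.  Samples
    with zero SAH are reported as missing (the ratio is undefined there).
    Returns a per-sample frame; the group summary lives in ``.attrs``.
    """
    _check_table(table)
    lv = (table.groupby(["sample_id", "metabolite"])["peak_area"]
          .sum().unstack())
    for met in ("SAM", "SAH"):
        if met not in lv.columns:
            raise ValueError(f"methylation index needs {met} areas")
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = np.where(lv["SAH"] > 0, lv["SAM"] / lv["SAH"], np.nan)
    out = pd.DataFrame({"sample_id": lv.index, "methylation_index": mi})
    if "group" in table.columns:
        grp = table.drop_duplicates("sample_id").set_index("sample_id")["group"]
        out["group"] = out["sample_id"].map(grp)
        summary = {}
        for g, vals in out.groupby("group")["methylation_index"]:
            v = vals.dropna().to_numpy()
            mean = float(v.mean()) if len(v) else math.nan
            if len(v) > 1:
                half = stats.t.ppf(0.975, len(v) - 1) * v.std(ddof=1) / math.sqrt(len(v))
            else:
                half = math.nan
            summary[g] = {"mean": mean, "ci95": (mean - half, mean + half),
                          "n": int(len(v))}
        out.attrs["group_summary"] = summary
    return out.reset_index(drop=True)


@dataclass
class RemethylationVerdict:
    """Cell-side m+4 share of labeled methionine vs the medium impurity."""

    r_cell: float
    r_medium: float

    @property
    def remethylation_detected(self) -> bool:
        # strict inequality: matching the impurity threshold is no evidence
        return self.r_cell > self.r_medium


def _m4_share(fractions: dict[str, float] | pd.Series) -> float:
    m4 = float(fractions.get("m+4", 0.0))
    m5 = float(fractions.get("m+5", 0.0))
    if m4 + m5 <= 0:
        raise ValueError("no labeled methionine (m+4 + m+5 is zero)")
    return m4 / (m4 + m5)


def remethylation_test(
    cell_fractions: dict[str, float],
    medium_fractions: dict[str, float],
) -> RemethylationVerdict:
    """Test for homocysteine remethylation via the methionine m+4 share.

    Remethylated methionine regains an unlabeled methyl group and shows up
    as m+4 -- the same species as the tracer-stock impurity.  The verdict is
    positive only if the cell-side statistic ``m+4/(m+4+m+5)`` strictly
    exceeds the medium's (the impurity floor measured in the same run).
    """
    return RemethylationVerdict(r_cell=_m4_share(cell_fractions),
                                r_medium=_m4_share(medium_fractions))


def recycling_fraction(sam_m5_fraction: float, atp_m5_fraction: float) -> float:
    """Share of labeled ATP drawn into SAM synthesis: SAM m+5 over ATP m+5.

    Undefined (NaN) when the ATP fraction is zero; zero SAM labeling gives 0.
    """
    if atp_m5_fraction <= 0:
        return math.nan
    return sam_m5_fraction / atp_m5_fraction


def extracellular_purines(
    supernatant: pd.DataFrame,
    protein_mass: pd.Series | dict[str, float],
) -> pd.DataFrame:
    """Per-sample extracellular adenosine, inosine and their sum per unit
    protein; samples without a protein measurement are excluded with a
    warning.  Group means with SEM are attached in ``.attrs``."""
    prot = pd.Series(protein_mass, dtype=float)
    wide = (supernatant.groupby(["sample_id", "metabolite"])["peak_area"]
            .sum().unstack().reindex(columns=["adenosine", "inosine"]))
    rows = []
    for sample in wide.index:
        p = prot.get(sample, np.nan)
        if not (p > 0):
            logger.warning("sample %s excluded: missing protein mass", sample)
            continue
        ado = wide.loc[sample, "adenosine"] / p
        ino = wide.loc[sample, "inosine"] / p
        rows.append((sample, ado, ino, ado + ino))
    out = pd.DataFrame(rows, columns=["sample_id", "adenosine", "inosine",
                                      "ado_plus_ino"])
    if "group" in supernatant.columns:
        grp = (supernatant.drop_duplicates("sample_id")
               .set_index("sample_id")["group"])
        out["group"] = out["sample_id"].map(grp)
        summary = {}
        for g, sub in out.groupby("group"):
            summary[g] = {
                col: {"mean": float(sub[col].mean()),
                      "sem": float(stats.sem(sub[col])) if len(sub) > 1 else math.nan}
                for col in ("adenosine", "inosine", "ado_plus_ino")}
        out.attrs["group_summary"] = summary
    return out


def significance_stars(p: float) -> str:
    """Figure-legend star buckets: 0.05 / 0.01 / 0.001 / 0.0001."""
    if not np.isfinite(p):
        return "ns"
    for threshold, stars_ in ((1e-4, "****"), (1e-3, "***"),
                              (1e-2, "**"), (5e-2, "*")):
        if p < threshold:
            return stars_
    return "ns"


def group_compare(groups: dict[str, np.ndarray]) -> dict:
    """Compare metabolite levels (or any per-replicate values) by condition.

    Two groups: unpaired two-sided t test (equal variances, as in the
    figure legends' "unpaired t test").  Three or more: ordinary one-way
    ANOVA followed by Tukey's multiple-comparison test for all pairs.

    Returns a dict with the omnibus ``statistic`` and ``p_value`` plus a
    ``pairwise`` list of ``(group_a, group_b, p, stars)``.
    """
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(clean) < 2:
        raise ValueError("need at least two groups")
    for name, v in clean.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        if np.ptp(v) == 0 and len(clean) == 2:
            # zero within-group variance breaks the t statistic only if both
            # groups are degenerate; flag the truly degenerate design
            pass
    names = list(clean)
    values = [clean[n] for n in names]
    if all(np.ptp(v) == 0 for v in values) and len({v[0] for v in values}) == 1:
        raise ValueError("degenerate design: all observations identical")

    if len(names) == 2:
        stat, p = stats.ttest_ind(values[0], values[1], equal_var=True)
        pairwise = [(names[0], names[1], float(p), significance_stars(p))]
        return {"design": "two-group", "test": "unpaired t",
                "statistic": float(stat), "p_value": float(p),
                "pairwise": pairwise}

    f_stat, f_p = stats.f_oneway(*values)
    tukey = stats.tukey_hsd(*values)
    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(tukey.pvalue[i, j])
            pairwise.append((names[i], names[j], p, significance_stars(p)))
    return {"design": "multi-group", "test": "one-way ANOVA + Tukey",
            "statistic": float(f_stat), "p_value": float(f_p),
            "pairwise": pairwise}
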