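"""Methylation-extent classification relative to transcript level.

Each methylated transcript's MFPKM (m6A-seq) is compared with its FPKM
(mRNA-seq) by a two-cell goodness-of-fit chi-square against a 50/50 split of
the two values expressed as percentages:

    chi2 = (MFPKM*100/(MFPKM+FPKM) - 50)^2/50 + (FPKM*100/(MFPKM+FPKM) - 50)^2/50

with 1 degree of freedom.  Significant transcripts are 'High' (MFPKM > FPKM)
or 'Low'; the rest are 'Equivalent'.  Unmethylated transcripts are excluded.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


def ratio_chi_square(mfpkm: float, fpkm: float) -> tuple[float, float]:
    """Chi-square statistic and upper-tail p (df=1) for a value pair."""
    total = mfpkm + fpkm
    if total <= 0:
        raise ValueError("MFPKM + FPKM must be positive")
    pm = mfpkm * 100.0 / total
    pf = fpkm * 100.0 / total
    chi2 = (pm - 50.0) ** 2 / 50.0 + (pf - 50.0) ** 2 / 50.0
    return chi2, float(stats.chi2.sf(chi2, df=1))


def classify_extent(mfpkm: float, fpkm: float, alpha: float = DEFAULT_ALPHA
                    ) -> tuple[str, float, float]:
    """Category, chi2 and p for one methylated transcript."""
    chi2, p = ratio_chi_square(mfpkm, fpkm)
    if p >= alpha:
        cat = "Equivalent"
    elif mfpkm > fpkm:
        cat = "High"
    else:
        cat = "Low"
    return cat, chi2, p


def extent_calls(quant: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """ExtentCall table for the methylated transcripts of one or more
    organ/replicate quantifications; unmethylated transcripts are excluded.

    FDR is Benjamini-Hochberg within each organ/replicate (used downstream by
    the extensive-methylation filter).
    """
    meth = quant[quant["m6a_count"] > 0].copy()
    if len(meth) == 0:
        raise ValueError("no methylated transcripts to classify")
    res = [classify_extent(m, f, alpha)
           for m, f in zip(meth["mfpkm"], meth["fpkm"])]
    meth["category"] = [r[0] for r in res]
    meth["chi2"] = [r[1] for r in res]
    meth["p_value"] = [r[2] for r in res]
    meth["fdr"] = np.nan
    for _, idx in meth.groupby(["organ", "replicate"]).groups.items():
        meth.loc[idx, "fdr"] = multipletests(
            meth.loc[idx, "p_value"], method="fdr_bh")[1]
    return meth.reset_index(drop=True)


def tabulate_extent(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per category per organ/replicate, with
    cross-organ average rows per replicate (percentages rounded to 1 decimal,
    averages as unweighted means of the per-organ percentages)."""
    rows = []
    for (rep, organ), grp in calls.groupby(["replicate", "organ"], sort=True):
        total = len(grp)
        row = {"replicate": rep, "organ": organ, "total": total}
        for cat in ("High", "Low", "Equivalent"):
            n = int((grp["category"] == cat).sum())
            row[f"{cat}_n"] = n
            row[f"{cat}_pct"] = round(100.0 * n / total, 1)
        rows.append(row)
    out = pd.DataFrame(rows)
    avg_rows = []
    for rep, grp in out.groupby("replicate"):
        row = {"replicate": rep, "organ": "Average", "total": int(grp["total"].sum())}
        for cat in ("High", "Low", "Equivalent"):
            row[f"{cat}_n"] = int(grp[f"{cat}_n"].sum())
            row[f"{cat}_pct"] = round(float(grp[f"{cat}_pct"].mean()), 1)
        avg_rows.append(row)
    return pd.concat([out, pd.DataFrame(avg_rows)], ignore_index=True)


@dataclass
class GroupingSummary:
    grouping: str            # 'High-expr', 'Moderate-expr', 'Low-expr'
    n: int
    mean_mfpkm: float
    mean_fpkm: float
    ratio: float


def grouping_summary(quant: pd.DataFrame
                     ) -> tuple[list[GroupingSummary], dict[tuple[str, str], float]]:
    """Expression-tertile summary of the methylated set.

    Methylated transcripts are ranked by FPKM descending (ties broken by
    transcript_id) and split into thirds, remainder to the earlier groups.
    Returns the three summaries and Welch t-test p-values on the
    per-transcript MFPKM/FPKM ratios between groupings.
    """
    meth = quant[quant["m6a_count"] > 0].copy()
    if len(meth) < 3:
        raise ValueError("need at least 3 methylated transcripts")
    meth = meth.sort_values(["fpkm", "transcript_id"],
                            ascending=[False, True], kind="mergesort")
    n = len(meth)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    names = ["High-expr", "Moderate-expr", "Low-expr"]
    summaries, ratio_vectors = [], {}
    start = 0
    for name, size in zip(names, sizes):
        grp = meth.iloc[start : start + size]
        start += size
        mean_m = float(grp["mfpkm"].mean())
        mean_f = float(grp["fpkm"].mean())
        summaries.append(GroupingSummary(
            grouping=name, n=size, mean_mfpkm=mean_m, mean_fpkm=mean_f,
            ratio=mean_m / mean_f,
        ))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio_vectors[name] = (grp["mfpkm"] / grp["fpkm"]).to_numpy()
    pvals = {}
    for a, b in combinations(names, 2):
        x, y = ratio_vectors[a], ratio_vectors[b]
        if np.std(x) == 0 and np.std(y) == 0 and np.mean(x) == np.mean(y):
            pvals[(a, b)] = 1.0  # degenerate: identical constant ratios
        else:
            pvals[(a, b)] = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    return summaries, pvals


def call_extensively_methylated(
    calls: pd.DataFrame,
    fold: float = 10.0,
    fdr_max: float = 1e-12,
    min_reads: int = 30,
) -> dict[tuple[str, int], set[str]]:
    """Per-(organ, replicate) sets of extensively methylated transcripts:
    MFPKM/FPKM >= fold, BH-FDR < fdr_max and m6A read count >= min_reads."""
    out: dict[tuple[str, int], set[str]] = {}
    with np.errstate(divide="ignore"):
        ratio = calls["mfpkm"] / calls["fpkm"].replace(0.0, np.nan)
    passing = calls[
        (ratio >= fold)
        & (calls["fdr"] < fdr_max)
        & (calls["m6a_count"] >= min_reads)
        & (calls["mfpkm"] > calls["fpkm"])
    ]
    for (organ, rep), grp in passing.groupby(["organ", "replicate"]):
        out[(organ, int(rep))] = set(grp["transcript_id"])
    for (organ, rep), _ in calls.groupby(["organ", "replicate"]).groups.items():
        out.setdefault((organ, int(rep)), set())
    return out


def intersect_organs(sets: dict[tuple[str, int], set[str]] | list[set[str]]
                     ) -> set[str]:
    """Transcripts common to every provided set."""
    values = list(sets.values()) if isinstance(sets, dict) else list(sets)
    if not values:
        return set()
    out = set(values[0])
    for s in values[1:]:
        out &= s
    return out
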