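"""Between-organ differential methylation and differential expression.

Differential methylation uses NFPKM = MFPKM / log2(FPKM), which damps the
influence of transcript level on the methylation signal; transcripts with
FPKM <= 1 are excluded (their log2 is non-positive).  A transcript is called
differential between two organs when the fold change passes the threshold and
the BH-FDR of the same percentage chi-square used for extent classification
falls below the cutoff.  Differential expression applies the identical
machinery to FPKM directly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .extent import ratio_chi_square


@dataclass(frozen=True)
class DMThresholds:
    fold_hi: float = 2.0
    fold_lo: float = 0.5
    fdr_max: float = 0.05
    min_reads: int = 0

    def __post_init__(self):
        if not (self.fold_hi > 1.0 > self.fold_lo > 0.0):
            raise ValueError("need fold_hi > 1 > fold_lo > 0")
        if not 0.0 < self.fdr_max < 1.0:
            raise ValueError("fdr_max must be in (0,1)")


#: Headline thresholds for differential summaries.
DEFAULT_THRESHOLDS = DMThresholds()
#: Organ-specific extensively-methylated variant.
EXTREME_THRESHOLDS = DMThresholds(fold_hi=10.0, fold_lo=0.1, fdr_max=1e-10,
                                  min_reads=20)
#: Alternative presets from the original protocol's methods text.
METHODS_EXPRESSION = DMThresholds(fdr_max=0.02)
METHODS_METHYLATION = DMThresholds(fdr_max=0.005)


def compute_nfpkm(mfpkm: float, fpkm: float) -> float | None:
    """MFPKM / log2(FPKM); None marks exclusion (FPKM <= 1)."""
    if fpkm <= 1.0:
        return None
    return mfpkm / math.log2(fpkm)


def nfpkm_table(quant: pd.DataFrame) -> pd.DataFrame:
    """Adds 'nfpkm' and boolean 'nfpkm_excluded' columns; excluded transcripts
    are kept with an explicit reason, never silently dropped."""
    out = quant.copy()
    vals = [compute_nfpkm(m, f) for m, f in zip(out["mfpkm"], out["fpkm"])]
    out["nfpkm"] = [np.nan if v is None else v for v in vals]
    out["nfpkm_excluded"] = [v is None for v in vals]
    out["exclusion_reason"] = ["FPKM<=1" if v is None else "" for v in vals]
    return out


def differential_test(
    values_a: pd.Series,
    values_b: pd.Series,
    thresholds: DMThresholds = DEFAULT_THRESHOLDS,
    metric: str = "NFPKM",
    reads_a: pd.Series | None = None,
    reads_b: pd.Series | None = None,
) -> pd.DataFrame:
    """DifferentialCall table for one organ pair.

    ``values_a``/``values_b`` are per-transcript metric values indexed by
    transcript_id; only the shared, strictly positive, finite set is tested.
    fold = value_a / value_b; chi2/p from the percentage formula; BH-FDR over
    all tested transcripts of the pair.
    """
    shared = values_a.index.intersection(values_b.index)
    a = values_a.loc[shared].astype(float)
    b = values_b.loc[shared].astype(float)
    ok = np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0)
    a, b = a[ok], b[ok]
    if len(a) == 0:
        raise ValueError("empty shared transcript set")
    stats_ = [ratio_chi_square(x, y) for x, y in zip(a, b)]
    chi2 = np.array([s[0] for s in stats_])
    pval = np.array([s[1] for s in stats_])
    fdr = multipletests(pval, method="fdr_bh")[1]
    fold = (a / b).to_numpy()
    direction = np.where(
        (fold > thresholds.fold_hi) & (fdr < thresholds.fdr_max), "higher_in_a",
        np.where((fold < thresholds.fold_lo) & (fdr < thresholds.fdr_max),
                 "higher_in_b", "not_significant"),
    )
    out = pd.DataFrame({
        "transcript_id": a.index,
        "metric": metric,
        "value_a": a.to_numpy(),
        "value_b": b.to_numpy(),
        "fold_change": fold,
        "chi2": chi2,
        "p_value": pval,
        "fdr": fdr,
        "direction": direction,
    })
    if reads_a is not None and reads_b is not None and thresholds.min_reads > 0:
        r = np.minimum(
            reads_a.reindex(out["transcript_id"]).fillna(0).to_numpy(),
            reads_b.reindex(out["transcript_id"]).fillna(0).to_numpy(),
        )
        out.loc[r < thresholds.min_reads, "direction"] = "not_significant"
    return out.reset_index(drop=True)


def summarize_differential(calls: pd.DataFrame) -> dict:
    """Per-direction counts and percentages for one organ pair; the total is
    the sum of the two direction percentages."""
    n = len(calls)
    n_a = int((calls["direction"] == "higher_in_a").sum())
    n_b = int((calls["direction"] == "higher_in_b").sum())
    pct_a = 100.0 * n_a / n if n else 0.0
    pct_b = 100.0 * n_b / n if n else 0.0
    return {
        "n_tested": n,
        "higher_in_a_n": n_a,
        "higher_in_b_n": n_b,
        "higher_in_a_pct": pct_a,
        "higher_in_b_pct": pct_b,
        "total_pct": pct_a + pct_b,
    }


def organ_specific_sets(
    calls: dict[tuple[tuple[str, str], int], pd.DataFrame],
    organs: list[str],
    thresholds: DMThresholds = DEFAULT_THRESHOLDS,
) -> dict[str, set[str]]:
    """Transcripts higher in a focal organ than BOTH other organs in BOTH
    replicates (common-elements rule across replicate sets).

    ``calls`` maps ((organ_a, organ_b), replicate) to a DifferentialCall table
    computed at ``thresholds``.
    """
    replicates = sorted({rep for (_, rep) in calls})
    out: dict[str, set[str]] = {}
    for focal in organs:
        per_rep: list[set[str]] = []
        for rep in replicates:
            sets_vs_others = []
            for other in organs:
                if other == focal:
                    continue
                if ((focal, other), rep) in calls:
                    df = calls[((focal, other), rep)]
                    s = set(df.loc[df["direction"] == "higher_in_a",
                                   "transcript_id"])
                elif ((other, focal), rep) in calls:
                    df = calls[((other, focal), rep)]
                    s = set(df.loc[df["direction"] == "higher_in_b",
                                   "transcript_id"])
                else:
                    raise KeyError(f"no calls for pair ({focal},{other}) rep {rep}")
                sets_vs_others.append(s)
            per_rep.append(set.intersection(*sets_vs_others))
        out[focal] = set.intersection(*per_rep) if per_rep else set()
    return out


def replicate_agreement(set_a: set[str], set_b: set[str]
                        ) -> tuple[float, float, float]:
    """(overlap/|A| %, overlap/|B| %, overlap/|A u B| %); NaN when both empty.
    The headline replicate-agreement statistic is the minimum of the first two."""
    union = set_a | set_b
    if not union:
        return (float("nan"),) * 3
    ov = len(set_a & set_b)
    pa = 100.0 * ov / len(set_a) if set_a else 0.0
    pb = 100.0 * ov / len(set_b) if set_b else 0.0
    return pa, pb, 100.0 * ov / len(union)


def fold_change_matrix(calls_by_pair: dict[tuple[str, str], pd.DataFrame]
                       ) -> pd.DataFrame:
    """log2 fold-change matrix (transcripts x organ pairs), rows in gene-ID
    alphabetic order (the chromosome 1->5 proxy); missing values are NaN."""
    cols = {}
    for (a, b), df in calls_by_pair.items():
        s = pd.Series(np.log2(df["fold_change"].to_numpy()),
                      index=df["transcript_id"])
        cols[f"{a}|{b}"] = s
    out = pd.DataFrame(cols)
    return out.sort_index()
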