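"""qRT-PCR validation arithmetic for capture-seq abundance estimates.

Relative abundance from threshold cycles against a housekeeping reference
(Actin2 in the original protocol):

    RA = 100 x 2^-(Ct_target - Ct_reference)

and the sequencing-side expected abundance from region-restricted fragment
counts:

    EA = 100 x (m6A fragments of the test gene in the amplicon region /
                mRNA fragments of the reference gene in its amplicon region)

Agreement between RA and EA over genes x organs is measured by Pearson
correlation with a Fisher-z 95% confidence interval.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


def relative_abundance(ct_target: float, ct_reference: float) -> float:
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 100.0 * 2.0 ** (-(ct_target - ct_reference))


def expected_abundance(m6a_reads_in_amplicon: int,
                       reference_mrna_reads_in_amplicon: int) -> float:
    if reference_mrna_reads_in_amplicon <= 0:
        raise ValueError("reference read count must be positive")
    return 100.0 * m6a_reads_in_amplicon / reference_mrna_reads_in_amplicon


@dataclass(frozen=True)
class QPCRRecord:
    gene_id: str
    organ: str
    ct_target: float
    ct_reference: float
    amplicon: tuple[int, int]      # transcript coordinates
    ra: float
    ea: float

    def __post_init__(self):
        length = self.amplicon[1] - self.amplicon[0]
        if not 50 <= length <= 150:
            raise ValueError(
                f"{self.gene_id}: amplicon length {length} outside 50-150 nt")


def make_record(gene_id: str, organ: str, ct_target: float,
                ct_reference: float, amplicon: tuple[int, int],
                m6a_reads: int, reference_reads: int) -> QPCRRecord:
    return QPCRRecord(
        gene_id=gene_id, organ=organ, ct_target=ct_target,
        ct_reference=ct_reference, amplicon=amplicon,
        ra=relative_abundance(ct_target, ct_reference),
        ea=expected_abundance(m6a_reads, reference_reads),
    )


def validate_correlation(
    records: Sequence[QPCRRecord] | tuple[np.ndarray, np.ndarray],
    log_transform: bool = False,
) -> tuple[Optional[float], int, tuple[float, float]]:
    """Pearson r between RA and EA with a Fisher-z 95% CI.

    Returns (r, n, (ci_lo, ci_hi)); r is None (undefined-flagged) when either
    vector has zero variance.  ``log_transform`` correlates log-scaled values.
    """
    if isinstance(records, tuple):
        ra, ea = np.asarray(records[0], float), np.asarray(records[1], float)
    else:
        ra = np.array([r.ra for r in records], dtype=float)
        ea = np.array([r.ea for r in records], dtype=float)
    n = len(ra)
    if n < 3:
        raise ValueError("need at least 3 paired records")
    if log_transform:
        ra, ea = np.log10(ra), np.log10(np.maximum(ea, 1e-12))
    if np.std(ra) == 0 or np.std(ea) == 0:
        return None, n, (float("nan"), float("nan"))
    r = float(stats.pearsonr(ra, ea).statistic)
    if abs(r) >= 1.0:
        return r, n, (r, r)
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    lo, hi = math.tanh(z - 1.959964 * se), math.tanh(z + 1.959964 * se)
    return r, n, (lo, hi)
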