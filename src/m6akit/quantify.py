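"""Per-transcript abundance and methylation-extent quantification.

Expression from mRNA-seq is normalized as FPKM.  The m6A-seq signal is
normalized as MFPKM, an FPKM variant that replaces the transcript length with
the *covered length* — the union length of transcript bases covered by m6A
fragments — because a capture library samples only fragments that carry a
site, not the whole transcript:

    FPKM  = count x 1e9 / (spliced length x total mapped fragments)
    MFPKM = count x 1e9 / (covered length x total mapped m6A fragments)

Site numbers are estimated from the covered length divided by the typical
~150-nt peak footprint.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import (
    FragmentLibrary,
    GenomeSequence,
    TranscriptModel,
    project_intervals_vectorized,
)

PEAK_FOOTPRINT = 150  # nt of coverage per estimated m6A peak


def union_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def covered_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Length of the union of transcript-coordinate intervals."""
    return sum(b - a for a, b in union_intervals(intervals))


def compute_fpkm(count: int, transcript_length: int, total_mapped: int) -> float:
    if transcript_length <= 0:
        raise ValueError("transcript length must be positive")
    if total_mapped <= 0:
        raise ValueError("library total must be positive")
    return count * 1e9 / (transcript_length * total_mapped)


def compute_mfpkm(count: int, covered: int, total_m6a_mapped: int) -> float:
    if total_m6a_mapped <= 0:
        raise ValueError("m6A library total must be positive")
    if count == 0:
        return 0.0
    if covered <= 0:
        raise ValueError("positive m6A count with zero covered length")
    return count * 1e9 / (covered * total_m6a_mapped)


def estimate_peak_count(covered: int) -> int:
    """Covered length / 150, rounded, with a floor of one for any coverage."""
    if covered < 0:
        raise ValueError("covered length must be >= 0")
    if covered == 0:
        return 0
    return max(1, int(round(covered / PEAK_FOOTPRINT)))


# ---------------------------------------------------------------------------
# fragment -> transcript assignment
# ---------------------------------------------------------------------------

class TranscriptAssignment:
    """Projected fragment intervals of one library on a set of transcripts.

    A fragment overlapping several transcripts is counted for each; fragments
    with no exonic overlap still count in the library total.
    """

    def __init__(self, library: FragmentLibrary, models: Sequence[TranscriptModel]):
        self.library = library
        self.models = {m.transcript_id: m for m in models}
        trees: dict[str, IntervalTree] = {}
        for idx, m in enumerate(models):
            tree = trees.setdefault(m.chrom, IntervalTree())
            for a, b in m.exons:
                tree.addi(a, b, idx)
        hits: dict[int, list[int]] = {}
        starts = np.array([f.start for f in library.fragments], dtype=np.int64)
        ends = np.array([f.end for f in library.fragments], dtype=np.int64)
        for i, f in enumerate(library.fragments):
            tree = trees.get(f.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(f.start, f.end):
                hits.setdefault(iv.data, []).append(i)
        self.intervals: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for idx, frag_idx in hits.items():
            m = models[idx]
            fi = np.array(sorted(set(frag_idx)), dtype=np.int64)
            ts, te, mask = project_intervals_vectorized(starts[fi], ends[fi], m)
            self.intervals[m.transcript_id] = (ts[mask], te[mask])

    def count(self, transcript_id: str) -> int:
        iv = self.intervals.get(transcript_id)
        return 0 if iv is None else len(iv[0])

    def projected(self, transcript_id: str) -> list[tuple[int, int]]:
        iv = self.intervals.get(transcript_id)
        if iv is None:
            return []
        return list(zip(iv[0].tolist(), iv[1].tolist()))

    def depth(self, transcript_id: str) -> np.ndarray:
        """Per-base depth along the transcript (zeros if uncovered)."""
        m = self.models[transcript_id]
        d = np.zeros(m.spliced_length + 1, dtype=np.int64)
        iv = self.intervals.get(transcript_id)
        if iv is not None:
            ts, te = iv
            np.add.at(d, ts, 1)
            np.add.at(d, te, -1)
        return np.cumsum(d)[:-1]

    def count_in_region(self, transcript_id: str, region: tuple[int, int]) -> int:
        """Fragments whose projection overlaps a transcript-coordinate region."""
        iv = self.intervals.get(transcript_id)
        if iv is None:
            return 0
        ts, te = iv
        a, b = region
        return int(np.count_nonzero((ts < b) & (te > a)))


def quantify(
    m6a: TranscriptAssignment,
    mrna: TranscriptAssignment,
    models: Sequence[TranscriptModel],
) -> pd.DataFrame:
    """Per-transcript QuantRecord table for one organ/replicate.

    Columns: transcript_id, organ, replicate, mrna_count, m6a_count, fpkm,
    covered_length, mfpkm, peak_count.
    """
    total_mrna = mrna.library.total_mapped
    total_m6a = m6a.library.total_mapped
    rows = []
    for m in models:
        tid = m.transcript_id
        mc = mrna.count(tid)
        ac = m6a.count(tid)
        cov = covered_length(m6a.projected(tid)) if ac else 0
        rows.append({
            "transcript_id": tid,
            "organ": m6a.library.organ,
            "replicate": m6a.library.replicate,
            "mrna_count": mc,
            "m6a_count": ac,
            "fpkm": compute_fpkm(mc, m.spliced_length, total_mrna),
            "covered_length": cov,
            "mfpkm": compute_mfpkm(ac, cov, total_m6a),
            "peak_count": estimate_peak_count(cov),
        })
    return pd.DataFrame(rows)


@dataclass
class TranscriptomeSummary:
    n_methylated: int
    n_transcribed: int
    proportion_methylated: float            # % of transcribed set
    total_peaks: int
    sites_per_methylated_transcript: float
    sites_per_transcript: float
    m6a_to_A_ratio_methylated: float        # %
    m6a_to_A_ratio_all: float               # %


def summarize_transcriptome(
    quant: pd.DataFrame,
    models: Sequence[TranscriptModel],
    genome: Optional[GenomeSequence] = None,
    denominator: str = "transcribed",
) -> TranscriptomeSummary:
    """Transcriptome-wide methylation summary for one organ/replicate.

    A transcript is methylated when it has any m6A fragment and transcribed
    when it has any mRNA fragment.  Site counts use the estimated peak count;
    the m6A/A ratio divides total estimated sites by the adenosine content of
    the spliced sequences of the respective transcript set (requires
    ``genome``).  ``denominator`` selects whether per-transcript site means
    divide by the transcribed set (default) or all annotated transcripts.
    """
    if denominator not in ("transcribed", "all"):
        raise ValueError("denominator must be 'transcribed' or 'all'")
    meth = quant[quant["m6a_count"] > 0]
    trans = quant[quant["mrna_count"] > 0]
    if len(trans) == 0:
        raise ValueError("no transcribed transcripts")
    denom = trans if denominator == "transcribed" else quant
    total_peaks = int(meth["peak_count"].sum())
    by_id = {m.transcript_id: m for m in models}

    def a_count(tids) -> int:
        if genome is None:
            return 0
        return sum(by_id[t].spliced_sequence(genome).count("A") for t in tids)

    a_meth = a_count(meth["transcript_id"])
    a_denom = a_count(denom["transcript_id"])
    # proportion methylated is a fraction OF the transcribed set, so the
    # numerator is the methylated-and-transcribed intersection
    n_meth_trans = int(((quant["m6a_count"] > 0)
                        & (quant["mrna_count"] > 0)).sum())
    return TranscriptomeSummary(
        n_methylated=len(meth),
        n_transcribed=len(trans),
        proportion_methylated=100.0 * n_meth_trans / len(trans),
        total_peaks=total_peaks,
        sites_per_methylated_transcript=(total_peaks / len(meth)) if len(meth) else 0.0,
        sites_per_transcript=total_peaks / len(denom),
        m6a_to_A_ratio_methylated=(100.0 * total_peaks / a_meth) if a_meth else 0.0,
        m6a_to_A_ratio_all=(100.0 * total_peaks / a_denom) if a_denom else 0.0,
    )
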