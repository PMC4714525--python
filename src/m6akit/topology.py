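"""Metagene profiles, peak extraction, topology typing and motif analysis.

The metagene profile rescales every covered transcript to 60 bins from the
TSS (bin 0) to the 3' end (bin 59) so that, for typical gene architecture,
bins 49-59 hold the stop codon and proximal 3'UTR.  Bin values are
fragment-base counts normalized per kb of bin and per million library
fragments, then averaged over transcripts.

Peaks are maximal covered runs of the per-base transcript depth; the motif
step scans a ~100-nt window around the summit of the highest peaks for the
m6A consensus RRACH (R in {A,G}, H in {A,C,T}; the methylated A is position 3).
Motifs are handled in DNA space; ``display`` renders T as U.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import GenomeSequence, TranscriptModel
from .quantify import TranscriptAssignment

logger = logging.getLogger(__name__)

N_BINS = 60
RRACH_R = set("AG")
RRACH_H = set("ACT")


def is_rrach(kmer: str) -> bool:
    return (len(kmer) == 5 and kmer[0] in RRACH_R and kmer[1] in RRACH_R
            and kmer[2] == "A" and kmer[3] == "C" and kmer[4] in RRACH_H)


def display_motif(kmer: str) -> str:
    """DNA-space 5-mer rendered in RNA alphabet (T -> U)."""
    return kmer.replace("T", "U")


# ---------------------------------------------------------------------------
# metagene
# ---------------------------------------------------------------------------

def metagene_profile(
    assignment: TranscriptAssignment,
    models: Sequence[TranscriptModel],
    n_bins: int = N_BINS,
) -> np.ndarray:
    """Average normalized-depth profile of one library over transcripts.

    Each covered transcript of length >= n_bins contributes a profile of
    fragment bases per bin scaled by (1e3 / bin width) * (1e6 / library
    total); transcripts shorter than n_bins are skipped with a log entry.
    """
    total = assignment.library.total_mapped
    profiles = []
    for m in models:
        tid = m.transcript_id
        if assignment.count(tid) == 0:
            continue
        L = m.spliced_length
        if L < n_bins:
            logger.info("metagene: skipping %s (length %d < %d bins)",
                        tid, L, n_bins)
            continue
        depth = assignment.depth(tid)
        edges = np.linspace(0, L, n_bins + 1).astype(np.int64)
        bases = np.add.reduceat(depth, edges[:-1]).astype(float)
        widths = np.diff(edges).astype(float)
        profiles.append(bases * (1e3 / widths) * (1e6 / total))
    if not profiles:
        return np.zeros(n_bins)  # no covered transcript: flat zero profile
    return np.mean(profiles, axis=0)


def compare_profiles(profiles_by_group: dict[str, list[np.ndarray]]) -> float:
    """One-way ANOVA p-value across groups, bins as observations.

    Each profile contributes its bin values as observations of its group.
    Zero overall variance (identical flat profiles) returns p = 1.
    """
    groups = [np.concatenate([np.asarray(p) for p in plist])
              for plist in profiles_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(groups)
    if np.allclose(pooled, pooled[0]):
        return 1.0
    with np.errstate(invalid="ignore"):
        res = stats.f_oneway(*groups)
    return 1.0 if np.isnan(res.pvalue) else float(res.pvalue)


# ---------------------------------------------------------------------------
# peaks and topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    transcript_id: str
    summit: int          # transcript coordinate, leftmost position of max depth
    height: int
    span: tuple[int, int]


def call_peaks(depth: np.ndarray, transcript_id: str = "",
               min_depth: int = 1) -> list[Peak]:
    """Maximal runs with depth >= min_depth; summit is the leftmost maximum."""
    covered = depth >= min_depth
    if not covered.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[False], covered, [False]])))
    peaks = []
    for s, e in zip(edges[::2], edges[1::2]):
        seg = depth[s:e]
        summit = int(s + np.argmax(seg))
        peaks.append(Peak(transcript_id=transcript_id, summit=summit,
                          height=int(seg.max()), span=(int(s), int(e))))
    return peaks


def peaks_for_library(assignment: TranscriptAssignment,
                      models: Sequence[TranscriptModel],
                      min_depth: int = 1) -> list[Peak]:
    out = []
    for m in models:
        if assignment.count(m.transcript_id) == 0:
            continue
        out.extend(call_peaks(assignment.depth(m.transcript_id),
                              m.transcript_id, min_depth))
    return out


@dataclass(frozen=True)
class TopologyCall:
    transcript_id: str
    type: Optional[str]          # 'Type1', 'Type2' or None (no CDS)
    dominance_ratio: float       # stop-region max depth / CDS-region max depth

STOP_REGION_NT = 100  # stop-region window reaches this far back into the CDS


def classify_topology(peaks: list[Peak], model: TranscriptModel,
                      dominance_threshold: float = 2.0) -> TopologyCall:
    """Type 1 when the stop-codon/3'UTR signal dominates the CDS signal.

    The stop region spans [stop codon - 100 nt, 3' end]; a transcript is
    Type 1 when its maximum peak height there is at least
    ``dominance_threshold`` times the maximum in the upstream CDS (a covered
    stop region with a silent CDS is Type 1 by convention).
    """
    stop = model.stop_codon_tpos
    if stop is None:
        return TopologyCall(model.transcript_id, None, float("nan"))
    L = model.spliced_length
    cds_start = model.cds_start_tpos or 0
    region_lo = max(0, stop - STOP_REGION_NT)
    stop_max = max((p.height for p in peaks if region_lo <= p.summit < L),
                   default=0)
    cds_max = max((p.height for p in peaks
                   if cds_start <= p.summit < region_lo), default=0)
    if stop_max == 0:
        return TopologyCall(model.transcript_id, "Type2",
                            0.0 if cds_max else float("nan"))
    if cds_max == 0:
        return TopologyCall(model.transcript_id, "Type1", float("inf"))
    ratio = stop_max / cds_max
    t = "Type1" if ratio >= dominance_threshold else "Type2"
    return TopologyCall(model.transcript_id, t, ratio)


# ---------------------------------------------------------------------------
# motif analysis
# ---------------------------------------------------------------------------

@dataclass
class MotifTable:
    n_peaks_examined: int
    n_with_consensus: int
    fraction_with_consensus: float       # %
    counts: dict[str, int]               # per-5-mer instance counts (DNA space)

    @property
    def frequencies(self) -> dict[str, float]:
        """Per-5-mer % among consensus instances (sums to 100)."""
        total = sum(self.counts.values())
        if total == 0:
            return {}
        return {k: 100.0 * v / total for k, v in self.counts.items()}

    def frame(self) -> pd.DataFrame:
        freqs = self.frequencies
        rows = [{"motif": display_motif(k), "count": v,
                 "frequency_pct": freqs[k]}
                for k, v in sorted(self.counts.items(),
                                   key=lambda kv: (-kv[1], kv[0]))]
        return pd.DataFrame(rows)


def motif_table(
    peaks: list[Peak],
    genome: GenomeSequence,
    models: Sequence[TranscriptModel],
    top_n: int = 1000,
    window: int = 100,
    per_instance: bool = False,
) -> MotifTable:
    """RRACH content of the windows around the highest peak summits.

    Peaks are ranked by height (ties by transcript then summit for
    determinism); for each of the ``top_n`` a ``window``-nt stretch of the
    spliced sense sequence centered on the summit is scanned.  One instance —
    the match nearest the summit — is tallied per peak unless
    ``per_instance`` counts them all.  Windows running past a transcript end
    are truncated and logged.
    """
    by_id = {m.transcript_id: m for m in models}
    ranked = sorted(peaks, key=lambda p: (-p.height, p.transcript_id, p.summit))
    ranked = ranked[:top_n]
    seq_cache: dict[str, str] = {}
    half = window // 2
    n_with = 0
    counts: dict[str, int] = {}
    for p in ranked:
        m = by_id[p.transcript_id]
        seq = seq_cache.get(p.transcript_id)
        if seq is None:
            seq = m.spliced_sequence(genome)
            seq_cache[p.transcript_id] = seq
        lo, hi = p.summit - half, p.summit + half
        if lo < 0 or hi > len(seq):
            logger.info("motif: window truncated for %s summit %d",
                        p.transcript_id, p.summit)
            lo, hi = max(0, lo), min(len(seq), hi)
        win = seq[lo:hi]
        matches = [lo + i for i in range(len(win) - 4) if is_rrach(win[i:i + 5])]
        if not matches:
            continue
        n_with += 1
        if per_instance:
            for i in matches:
                counts[seq[i:i + 5]] = counts.get(seq[i:i + 5], 0) + 1
        else:
            i = min(matches, key=lambda i: (abs(i + 2 - p.summit), i))
            counts[seq[i:i + 5]] = counts.get(seq[i:i + 5], 0) + 1
    n_ex = len(ranked)
    return MotifTable(
        n_peaks_examined=n_ex,
        n_with_consensus=n_with,
        fraction_with_consensus=100.0 * n_with / n_ex if n_ex else 0.0,
        counts=counts,
    )
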