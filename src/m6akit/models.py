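"""Coordinate model for spliced transcripts and deduplicated fragment libraries.

All coordinates are 0-based half-open genomic intervals; GFF3's 1-based
inclusive convention is converted at the I/O boundary only.  Transcript
("spliced") coordinates run 5'->3' along the mature RNA, so position 0 is the
TSS-proximal base regardless of genomic strand.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

BIOTYPES = {
    "mRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "TE", "pseudogene", "other_ncRNA",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FragmentRecord:
    """One deduplicated mapped fragment (genomic span of the alignment)."""

    chrom: str
    start: int
    end: int
    strand: str = "unknown"  # '+', '-' or 'unknown'; RIP libraries are unstranded

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"invalid fragment interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """Exon-structured transcript with optional CDS landmarks.

    exons: non-overlapping genomic intervals sorted by start.
    cds_span: genomic (start, end) of the coding region including the stop codon.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: Sequence[tuple[int, int]]
    cds_span: Optional[tuple[int, int]] = None
    biotype: str = "mRNA"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in exons:
            if b <= a:
                raise ValueError(f"{self.transcript_id}: empty exon ({a},{b})")
        for (_, b), (a2, _) in zip(exons, exons[1:]):
            if a2 < b:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        self.exons = exons
        if self.spliced_length <= 0:
            raise ValueError(f"{self.transcript_id}: zero spliced length")
        if self.cds_span is not None:
            c0, c1 = self.cds_span
            if not (self.exons[0][0] <= c0 < c1 <= self.exons[-1][1]):
                raise ValueError(f"{self.transcript_id}: CDS outside exon span")

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    # -- genomic <-> transcript projection ---------------------------------

    def _cumlens(self) -> list[int]:
        out, c = [], 0
        for a, b in self.exons:
            out.append(c)
            c += b - a
        return out

    def genomic_to_transcript(self, gpos: int) -> Optional[int]:
        """Transcript coordinate of a genomic base, or None if intronic/outside."""
        cum = self._cumlens()
        for (a, b), c in zip(self.exons, cum):
            if a <= gpos < b:
                plus = c + (gpos - a)
                if self.strand == "+":
                    return plus
                return self.spliced_length - 1 - plus
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        """Genomic coordinate of a transcript base (inverse of the above)."""
        L = self.spliced_length
        if not 0 <= tpos < L:
            raise ValueError(f"transcript position {tpos} outside [0,{L})")
        plus = tpos if self.strand == "+" else L - 1 - tpos
        for (a, b), c in zip(self.exons, self._cumlens()):
            if c <= plus < c + (b - a):
                return a + (plus - c)
        raise AssertionError("unreachable")

    @property
    def stop_codon_tpos(self) -> Optional[int]:
        """Transcript coordinate of the last coding base (3' end of the stop codon)."""
        if self.cds_span is None:
            return None
        c0, c1 = self.cds_span
        glast = c1 - 1 if self.strand == "+" else c0
        return self.genomic_to_transcript(glast)

    @property
    def cds_start_tpos(self) -> Optional[int]:
        if self.cds_span is None:
            return None
        c0, c1 = self.cds_span
        gfirst = c0 if self.strand == "+" else c1 - 1
        return self.genomic_to_transcript(gfirst)

    def spliced_sequence(self, genome: "GenomeSequence") -> str:
        """Mature (spliced) RNA sequence in DNA alphabet, 5'->3'."""
        parts = [genome.fetch(self.chrom, a, b) for a, b in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)


class GenomeSequence:
    """Per-chromosome nucleotide strings over {A,C,G,T,N}."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {str(k): str(v).upper() for k, v in sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self._seqs[chrom][start:end]
        return seq if strand == "+" else reverse_complement(seq)

    def items(self):
        return self._seqs.items()


@dataclass
class FragmentLibrary:
    """All deduplicated fragments of one {organ, replicate, assay} library."""

    organ: str
    replicate: int
    assay: str  # 'm6A', 'mRNA' or 'input'
    fragments: list[FragmentRecord] = field(default_factory=list)
    total_mapped: Optional[int] = None

    def __post_init__(self):
        if self.assay not in ("m6A", "mRNA", "input"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.total_mapped is None:
            self.total_mapped = len(self.fragments)

    @property
    def label(self) -> str:
        return f"{self.organ}.rep{self.replicate}.{self.assay}"


def project_fragment(
    frag: FragmentRecord, model: TranscriptModel
) -> Optional[tuple[int, int]]:
    """Project a genomic fragment onto spliced transcript coordinates.

    Returns the (contiguous) transcript-coordinate interval of the fragment's
    overlap with the exon union, or None when there is no overlap.  Because a
    fragment is one genomic interval, the exonic pieces are always adjacent in
    transcript space.  Unknown-strand fragments follow the transcript's strand.
    """
    pieces = []
    for a, b in model.exons:
        lo, hi = max(frag.start, a), min(frag.end, b)
        if hi > lo:
            pieces.append((lo, hi))
    if not pieces:
        return None
    t_edges = []
    for lo, hi in pieces:
        t0 = model.genomic_to_transcript(lo)
        t1 = model.genomic_to_transcript(hi - 1)
        t_edges.extend((t0, t1))
    start, end = min(t_edges), max(t_edges) + 1
    return (start, end)


def project_intervals_vectorized(
    starts: np.ndarray, ends: np.ndarray, model: TranscriptModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized projection of many genomic intervals onto one transcript.

    Returns (t_starts, t_ends, mask) where mask marks intervals with exonic
    overlap; entries outside the mask are undefined.
    """
    exs = np.array([a for a, _ in model.exons])
    exe = np.array([b for _, b in model.exons])
    cum = np.concatenate([[0], np.cumsum(exe - exs)])[:-1]
    n = len(starts)
    tlo = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    thi = np.full(n, -1, dtype=np.int64)
    L = model.spliced_length
    for a, b, c in zip(exs, exe, cum):
        lo = np.maximum(starts, a)
        hi = np.minimum(ends, b)
        ok = hi > lo
        if not ok.any():
            continue
        p0 = c + (lo[ok] - a)
        p1 = c + (hi[ok] - 1 - a)
        if model.strand == "-":
            p0, p1 = L - 1 - p1, L - 1 - p0
        tlo[ok] = np.minimum(tlo[ok], p0)
        thi[ok] = np.maximum(thi[ok], p1)
    mask = thi >= 0
    return tlo, thi + 1, mask
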