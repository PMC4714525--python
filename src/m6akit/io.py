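"""Readers and writers for the standard formats the pipeline touches.

GFF3 (annotation), FASTA (genome), BED3 (fragments), bedGraph (coverage) and
headered TSV tables.  All internal coordinates are 0-based half-open; GFF3's
1-based inclusive coordinates are converted here and nowhere else.
"""
from __future__ import annotations

import os
from typing import Iterable, Optional

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .models import (
    FragmentLibrary,
    FragmentRecord,
    GenomeSequence,
    TranscriptModel,
)

# Feature types mapped onto the transcript biotypes we track.
_FEATURE_BIOTYPE = {
    "mRNA": "mRNA",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "transposable_element_gene": "TE",
    "transposon_fragment": "TE",
    "pseudogenic_transcript": "pseudogene",
    "ncRNA": "other_ncRNA",
    "lnc_RNA": "other_ncRNA",
    "miRNA": "other_ncRNA",
}
_TRANSCRIPT_FEATURES = set(_FEATURE_BIOTYPE)


def read_genome(path: str) -> GenomeSequence:
    fa = Fasta(path, rebuild=True, build_index=True)
    return GenomeSequence({name: str(fa[name][:]) for name in fa.keys()})


def write_genome(genome: GenomeSequence, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_annotation(path: str) -> list[TranscriptModel]:
    """Parse a GFF3 annotation into transcript models.

    One model per transcript-level feature (mRNA, rRNA, ... see
    ``_FEATURE_BIOTYPE``); biotype defaults to mRNA for unrecognized transcript
    types carrying exons.  Raises ``ValueError`` on malformed lines (with the
    line number) and on exons outside their declared transcript span.
    """
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # surface the offending line if we can find it
        raise ValueError(_diagnose_gff(path, exc)) from exc

    models = []
    for ftype in sorted(_TRANSCRIPT_FEATURES | {"transcript"}):
        try:
            feats = list(db.features_of_type(ftype))
        except Exception:
            continue
        for feat in feats:
            exons = [
                (e.start - 1, e.end)
                for e in db.children(feat, featuretype="exon", order_by="start")
            ]
            if not exons:
                exons = [(feat.start - 1, feat.end)]
            for a, b in exons:
                if a < feat.start - 1 or b > feat.end:
                    raise ValueError(
                        f"{feat.id}: exon ({a},{b}) outside transcript span "
                        f"({feat.start - 1},{feat.end})"
                    )
            cds = [
                (c.start - 1, c.end)
                for c in db.children(feat, featuretype="CDS", order_by="start")
            ]
            cds_span = (min(a for a, _ in cds), max(b for _, b in cds)) if cds else None
            biotype = _FEATURE_BIOTYPE.get(ftype, "mRNA")
            models.append(
                TranscriptModel(
                    transcript_id=feat.id,
                    chrom=feat.seqid,
                    strand=feat.strand if feat.strand in "+-" else "+",
                    exons=exons,
                    cds_span=cds_span,
                    biotype=biotype,
                )
            )
    models.sort(key=lambda m: m.transcript_id)
    return models


def _diagnose_gff(path: str, exc: Exception) -> str:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                return f"malformed GFF3 line {lineno} in {path}: {line.strip()!r}"
    return f"failed to parse GFF3 {path}: {exc}"


def write_annotation(models: Iterable[TranscriptModel], path: str) -> None:
    """Write transcript models as GFF3 (gene + transcript + exon [+ CDS] rows)."""
    inverse = {v: k for k, v in _FEATURE_BIOTYPE.items()}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.chrom, m.span[0], m.transcript_id)):
            g0, g1 = m.span
            ftype = inverse.get(m.biotype, "mRNA") if m.biotype != "mRNA" else "mRNA"
            gene_id = f"{m.transcript_id}.gene"
            fh.write(
                f"{m.chrom}\tm6akit\tgene\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\t"
                f"ID={gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\tm6akit\t{ftype}\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={gene_id}\n"
            )
            for i, (a, b) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\tm6akit\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}\n"
                )
            if m.cds_span is not None:
                c0, c1 = m.cds_span
                for a, b in m.exons:
                    lo, hi = max(a, c0), min(b, c1)
                    if hi > lo:
                        fh.write(
                            f"{m.chrom}\tm6akit\tCDS\t{lo + 1}\t{hi}\t.\t{m.strand}"
                            f"\t0\tID={m.transcript_id}.cds;Parent={m.transcript_id}\n"
                        )


def read_fragments(
    path: str, organ: str, replicate: int, assay: str
) -> FragmentLibrary:
    """Read a BED3+ file of deduplicated fragments into a library."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        i = int(bad[0])
        raise ValueError(
            f"{path}: record {i + 1} has end <= start "
            f"({df.loc[i, 'chrom']}:{df.loc[i, 'start']}-{df.loc[i, 'end']})"
        )
    frags = [
        FragmentRecord(c, int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]
    return FragmentLibrary(organ=organ, replicate=replicate, assay=assay,
                           fragments=frags)


def write_fragments(library: FragmentLibrary, path: str) -> None:
    rows = sorted((f.chrom, f.start, f.end) for f in library.fragments)
    with open(path, "w") as fh:
        for chrom, start, end in rows:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def coverage_steps(fragments: Iterable[FragmentRecord]):
    """Per-base depth of a fragment set as (chrom, start, end, depth) steps."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    for chrom in sorted(by_chrom):
        ivs = by_chrom[chrom]
        edges = sorted({p for iv in ivs for p in iv})
        edge_idx = {p: i for i, p in enumerate(edges)}
        delta = np.zeros(len(edges), dtype=np.int64)
        for s, e in ivs:
            delta[edge_idx[s]] += 1
            delta[edge_idx[e]] -= 1
        depth = np.cumsum(delta)
        for i in range(len(edges) - 1):
            yield chrom, edges[i], edges[i + 1], int(depth[i])


def write_coverage(libraries: Iterable[FragmentLibrary], path: str) -> None:
    """Write pooled per-base depth as bedGraph (zero-depth runs omitted)."""
    frags = [f for lib in libraries for f in lib.fragments]
    with open(path, "w") as fh:
        for chrom, start, end, depth in coverage_steps(frags):
            if depth > 0:
                fh.write(f"{chrom}\t{start}\t{end}\t{depth}\n")


def read_coverage(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "depth"]
    )


def write_table(records: pd.DataFrame, path: str, sort_by: Optional[str] = None) -> None:
    """Write a tabular result as headered TSV with deterministic row order."""
    df = records
    if sort_by is None and "transcript_id" in df.columns:
        sort_by = "transcript_id"
    if sort_by is not None:
        df = df.sort_values(sort_by, kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
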