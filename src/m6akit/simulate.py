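"""Synthetic m6A-seq / mRNA-seq / input experiments with known ground truth.

The generator emulates the data-generating process of an antibody-capture m6A
experiment in a compact plant transcriptome: transcripts with 5'UTR/CDS/3'UTR
architecture laid out on a random genome, methylation sites planted at RRACH
5-mers (predominantly at the stop codon / proximal 3'UTR), ~100-nt chemical
fragmentation, and per-fragment antibody capture with a high specific rate and
a sub-1% non-specific background.  Expression and methylation effects are
organ- and replicate-structured and recorded in a truth table so every
downstream statistic can be checked for recovery.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    FragmentLibrary,
    FragmentRecord,
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
)

_BASES = np.array(list("ACGT"))

#: The 12 RRACH 5-mers (R in {A,G}, H in {A,C,T}; DNA sense strand).
RRACH_5MERS = tuple(
    r1 + r2 + "AC" + h for r1 in "AG" for r2 in "AG" for h in "ACT"
)

#: Default planted-motif frequencies: the two most frequent consensus 5-mers
#: observed in plant m6A peaks, remainder spread uniformly.
DEFAULT_MOTIF_FREQS = {"AAACT": 0.193, "AAACA": 0.190}
_rest = (1.0 - sum(DEFAULT_MOTIF_FREQS.values())) / (len(RRACH_5MERS) - 2)
for _m in RRACH_5MERS:
    DEFAULT_MOTIF_FREQS.setdefault(_m, _rest)


@dataclass
class SimulationParams:
    """All knobs of the synthetic experiment (desk-scale defaults).

    Lengths are in nucleotides.  ``depth`` is fragments per library; capture
    probabilities are per-fragment Bernoulli rates.
    """

    n_transcripts: int = 500
    organs: Sequence[str] = ("leaves", "flowers", "roots")
    replicates: int = 2
    # transcript architecture (truncated-normal means / sds)
    utr5_mean: float = 120.0
    utr5_sd: float = 40.0
    cds_mean: float = 1200.0
    cds_sd: float = 300.0
    utr3_mean: float = 230.0
    utr3_sd: float = 60.0
    te_fraction: float = 0.04          # TE transcripts expressed in fragments
    # expression model
    expression_sigma: float = 1.0      # log-normal spread of expression weights
    de_fraction: float = 0.10          # transcripts with organ-differential expression
    de_fold: float = 4.0
    # methylation design
    extent_probs: dict = field(
        default_factory=lambda: {"High": 0.85, "Low": 0.04, "Equivalent": 0.11}
    )
    high_mult_range: tuple[float, float] = (3.0, 10.0)
    low_mult: float = 0.1
    dm_fraction: float = 0.10          # transcripts with organ-differential methylation
    dm_fold: float = 4.0
    # site placement
    placement_mass: dict = field(
        default_factory=lambda: {"stop": 0.75, "cds": 0.15, "five_prime": 0.10}
    )
    sites_probs: dict = field(
        default_factory=lambda: {1: 0.40, 2: 0.30, 3: 0.17, 4: 0.13}
    )
    motif_freqs: dict = field(default_factory=lambda: dict(DEFAULT_MOTIF_FREQS))
    # fragmentation and capture
    fragment_mean: float = 100.0
    fragment_sd: float = 20.0
    fragment_min: int = 30
    # Per-candidate-fragment rates.  With ~2 sites per transcript and ~100-nt
    # fragments, a non-specific rate of 0.001 against a specific rate of 0.9
    # leaves under 1% of the *retained* (precipitated) pool non-specific,
    # which is the background level the assay reports.
    p_specific: float = 0.90
    p_nonspecific: float = 0.001
    depth: int = 200_000
    edge_model: str = "inside"         # 'inside' or 'padded' (uniform-coverage control)
    genome_length: Optional[int] = None  # cap; layout larger than this errors
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_specific", "p_nonspecific", "de_fraction", "dm_fraction",
                     "te_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.p_nonspecific >= self.p_specific:
            raise ValueError("non-specific rate must be below specific capture")
        if self.depth <= 0:
            raise ValueError("library depth must be positive")
        if abs(sum(self.placement_mass.values()) - 1.0) > 1e-9:
            raise ValueError("placement_mass must sum to 1")
        if abs(sum(self.motif_freqs.values()) - 1.0) > 1e-9:
            raise ValueError("motif_freqs must sum to 1")
        if self.edge_model not in ("inside", "padded"):
            raise ValueError("edge_model must be 'inside' or 'padded'")


@dataclass
class TruthTable:
    """Planted ground truth for recovery tests.

    ``sites`` are transcript coordinates of the methylated adenosine (position
    3 of the planted RRACH 5-mer).  ``meth_mult`` is the per-organ methylation
    intensity multiplier realized in the m6A-library sampling weights; the
    planted MFPKM:FPKM fold between organs equals the multiplier ratio.
    """

    transcript_ids: list[str]
    sites: dict[str, list[int]]
    site_motifs: dict[str, list[str]]
    expression: pd.DataFrame          # transcripts x organs, sampling weights
    meth_mult: pd.DataFrame           # transcripts x organs
    extent_category: dict[str, str]   # target category per transcript
    dm_status: pd.DataFrame           # transcripts x organ pairs: higher_in_a/b/none
    te_windows: dict[str, list[tuple[int, int]]]
    biotype: dict[str, str]

    def frame(self) -> pd.DataFrame:
        """Flat per-transcript summary (one row per transcript)."""
        rows = []
        for tid in self.transcript_ids:
            rows.append({
                "transcript_id": tid,
                "biotype": self.biotype[tid],
                "n_sites": len(self.sites[tid]),
                "site_positions": ",".join(map(str, self.sites[tid])),
                "extent_category": self.extent_category[tid],
                **{f"expr_{o}": self.expression.loc[tid, o]
                   for o in self.expression.columns},
                **{f"mult_{o}": self.meth_mult.loc[tid, o]
                   for o in self.meth_mult.columns},
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def _trunc_normal(rng, mean, sd, lo, n):
    x = rng.normal(mean, sd, size=n)
    return np.maximum(np.round(x), lo).astype(np.int64)


def _random_seq(rng, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _place_sites(rng, params: SimulationParams, L: int, cds_start: int,
                 stop: Optional[int], n_sites: int) -> list[int]:
    """Sample ``n_sites`` site coordinates in [2, L-3] honoring placement mass."""
    regions = list(params.placement_mass.items())
    labels = [r for r, _ in regions]
    probs = np.array([p for _, p in regions])
    out: list[int] = []
    tries = 0
    while len(out) < n_sites and tries < 200 * n_sites:
        tries += 1
        region = labels[rng.choice(len(labels), p=probs)]
        if stop is None:
            pos = int(rng.integers(2, max(3, L - 3)))
        elif region == "stop":
            pos = stop + int(round(rng.normal(0.0, 40.0)))
            pos = int(np.clip(pos, max(2, stop - 60), L - 3))
        elif region == "cds":
            hi = max(cds_start + 12, stop - 120)
            pos = int(rng.integers(max(2, cds_start + 10), hi))
        else:  # five_prime
            pos = int(rng.integers(2, max(3, cds_start + 30)))
        pos = int(np.clip(pos, 2, L - 3))
        if all(abs(pos - q) >= 10 for q in out):
            out.append(pos)
    return sorted(out)


def generate_reference(
    params: SimulationParams,
) -> tuple[GenomeSequence, list[TranscriptModel], TruthTable]:
    """Build a random genome, transcript models and the planted truth.

    Every true site carries an RRACH 5-mer in the spliced sense sequence; all
    output is reproducible from ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_transcripts
    width = len(str(max(n, 1)))
    tids = [f"SYN{i + 1:0{width}d}" for i in range(n)]

    utr5 = _trunc_normal(rng, params.utr5_mean, params.utr5_sd, 30, n)
    cds = _trunc_normal(rng, params.cds_mean, params.cds_sd, 300, n)
    cds -= cds % 3
    utr3 = _trunc_normal(rng, params.utr3_mean, params.utr3_sd, 60, n)
    is_te = rng.random(n) < params.te_fraction

    cats = list(params.extent_probs)
    cat_p = np.array([params.extent_probs[c] for c in cats], dtype=float)
    cat_p = cat_p / cat_p.sum()
    categories = [cats[i] for i in rng.choice(len(cats), size=n, p=cat_p)]

    site_counts_vals = np.array(list(params.sites_probs))
    site_counts_p = np.array(list(params.sites_probs.values()), dtype=float)
    site_counts_p /= site_counts_p.sum()
    motif_names = list(params.motif_freqs)
    motif_p = np.array([params.motif_freqs[m] for m in motif_names], dtype=float)
    motif_p /= motif_p.sum()

    # expression: log-normal base weights shared across organs, plus
    # organ-differential effects on a random subset
    organs = list(params.organs)
    base_w = rng.lognormal(mean=0.0, sigma=params.expression_sigma, size=n)
    expr = pd.DataFrame({o: base_w.copy() for o in organs}, index=tids)
    mult = pd.DataFrame(np.ones((n, len(organs))), index=tids, columns=organs)

    high_lo, high_hi = params.high_mult_range
    for i, tid in enumerate(tids):
        if categories[i] == "High":
            mult.loc[tid, :] = rng.uniform(high_lo, high_hi)
        elif categories[i] == "Low":
            mult.loc[tid, :] = params.low_mult

    n_de = int(round(params.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], int)
    for k, i in enumerate(de_idx):
        organ = organs[k % len(organs)]
        expr.iloc[i, expr.columns.get_loc(organ)] *= params.de_fold

    pairs = [(a, b) for i, a in enumerate(organs) for b in organs[i + 1:]]
    dm_status = pd.DataFrame(
        "none", index=tids, columns=[f"{a}|{b}" for a, b in pairs]
    )
    n_dm = int(round(params.dm_fraction * n))
    pool = np.setdiff1d(np.arange(n), de_idx)
    n_dm = min(n_dm, len(pool))
    dm_idx = rng.choice(pool, size=n_dm, replace=False) if n_dm else np.array([], int)
    for k, i in enumerate(dm_idx):
        organ = organs[k % len(organs)]
        mult.iloc[i, mult.columns.get_loc(organ)] *= params.dm_fold
        for a, b in pairs:
            if a == organ:
                dm_status.iloc[i, dm_status.columns.get_loc(f"{a}|{b}")] = "higher_in_a"
            elif b == organ:
                dm_status.iloc[i, dm_status.columns.get_loc(f"{a}|{b}")] = "higher_in_b"

    # build sequences and genomic layout
    chrom = "chr1"
    parts: list[str] = []
    cursor = 0
    gap = 200
    models: list[TranscriptModel] = []
    sites: dict[str, list[int]] = {}
    site_motifs: dict[str, list[str]] = {}
    te_windows: dict[str, list[tuple[int, int]]] = {}
    biotype: dict[str, str] = {}

    for i, tid in enumerate(tids):
        L = int(utr5[i] + cds[i] + utr3[i])
        seq = _random_seq(rng, L)
        cds_start_t = int(utr5[i])
        stop_t = int(utr5[i] + cds[i] - 1)  # last coding base, transcript coords

        k_sites = int(site_counts_vals[rng.choice(len(site_counts_vals),
                                                  p=site_counts_p)])
        bt = "TE" if is_te[i] else "mRNA"
        pos_list = _place_sites(
            rng, params, L, cds_start_t, None if bt == "TE" else stop_t, k_sites
        )
        motifs = []
        for pos in pos_list:
            m = motif_names[rng.choice(len(motif_names), p=motif_p)]
            seq[pos - 2 : pos + 3] = list(m)
            motifs.append(m)
        sites[tid] = pos_list
        site_motifs[tid] = motifs
        biotype[tid] = bt

        # exon structure: split the spliced sequence, insert intron filler
        n_exons = int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))
        cuts = sorted(rng.choice(np.arange(50, L - 50), size=n_exons - 1,
                                 replace=False)) if n_exons > 1 else []
        bounds = [0, *map(int, cuts), L]
        strand = "+" if rng.random() < 0.5 else "-"
        spliced = "".join(seq)
        t_pieces = [spliced[a:b] for a, b in zip(bounds, bounds[1:])]
        introns = [
            "".join(_random_seq(rng, int(rng.integers(80, 300))))
            for _ in range(n_exons - 1)
        ]
        if strand == "+":
            genomic_pieces = t_pieces
        else:
            genomic_pieces = [reverse_complement(p) for p in reversed(t_pieces)]
        locus_parts = []
        exon_coords = []
        pos0 = cursor
        for j, piece in enumerate(genomic_pieces):
            exon_coords.append((pos0, pos0 + len(piece)))
            locus_parts.append(piece)
            pos0 += len(piece)
            if j < len(introns):
                locus_parts.append(introns[j])
                pos0 += len(introns[j])
        locus = "".join(locus_parts)

        model = TranscriptModel(
            transcript_id=tid, chrom=chrom, strand=strand, exons=exon_coords,
            biotype=bt,
        )
        if bt != "TE":
            g_cds_first = model.transcript_to_genomic(cds_start_t)
            g_cds_last = model.transcript_to_genomic(stop_t)
            model.cds_span = (min(g_cds_first, g_cds_last),
                              max(g_cds_first, g_cds_last) + 1)
            model.__post_init__()
        models.append(model)

        if bt == "TE":
            k_win = int(rng.integers(2, 5))
            edges = np.sort(rng.choice(np.arange(40, L - 40), size=2 * k_win,
                                       replace=False))
            te_windows[tid] = [
                (int(edges[2 * j]), int(edges[2 * j + 1])) for j in range(k_win)
                if edges[2 * j + 1] - edges[2 * j] >= params.fragment_min
            ] or [(0, L)]

        parts.append(locus)
        cursor += len(locus) + gap
        parts.append("".join(_random_seq(rng, gap)))

    genome_seq = "".join(parts)
    if params.genome_length is not None and len(genome_seq) > params.genome_length:
        raise ValueError(
            f"layout needs {len(genome_seq)} nt but genome_length is "
            f"{params.genome_length}"
        )
    genome = GenomeSequence({chrom: genome_seq})
    truth = TruthTable(
        transcript_ids=tids, sites=sites, site_motifs=site_motifs,
        expression=expr, meth_mult=mult,
        extent_category=dict(zip(tids, categories)),
        dm_status=dm_status, te_windows=te_windows, biotype=biotype,
    )
    return genome, models, truth


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def _t2g_span(model: TranscriptModel, tstart: np.ndarray,
              tend: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Genomic span (min start, max end) of transcript-coordinate intervals."""
    exs = np.array([a for a, _ in model.exons], dtype=np.int64)
    exe = np.array([b for _, b in model.exons], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(exe - exs)])
    L = model.spliced_length

    def map_pos(tpos):
        plus = tpos if model.strand == "+" else L - 1 - tpos
        idx = np.searchsorted(cum, plus, side="right") - 1
        return exs[idx] + (plus - cum[idx])

    g1 = map_pos(tstart)
    g2 = map_pos(tend - 1)
    return np.minimum(g1, g2), np.maximum(g1, g2) + 1


def _draw_on_transcript(rng, params: SimulationParams, model: TranscriptModel,
                        windows, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Fragment transcript-coordinate intervals for one transcript."""
    L = model.spliced_length
    flen = np.round(rng.normal(params.fragment_mean, params.fragment_sd, size=n))
    flen = np.clip(flen, params.fragment_min, L).astype(np.int64)
    if windows is not None:
        wlens = np.array([b - a for a, b in windows], dtype=float)
        widx = rng.choice(len(windows), size=n, p=wlens / wlens.sum())
        ws = np.array([windows[i][0] for i in widx])
        we = np.array([windows[i][1] for i in widx])
        flen = np.minimum(flen, we - ws)
        span = np.maximum(we - ws - flen, 1)
        starts = ws + (rng.random(n) * span).astype(np.int64)
    elif params.edge_model == "padded":
        # starts drawn from a fragment-length pad beyond both ends, clipped:
        # expected depth is exactly uniform along the transcript
        raw = (rng.random(n) * (L + flen - 1)).astype(np.int64) - (flen - 1)
        starts = raw
        ends = np.minimum(raw + flen, L)
        starts = np.maximum(starts, 0)
        return starts, np.maximum(ends, starts + 1)
    else:
        span = np.maximum(L - flen, 1)
        starts = (rng.random(n) * span).astype(np.int64)
    return starts, starts + flen


def _covers_site(truth: TruthTable, tid: str, tstart: np.ndarray,
                 tend: np.ndarray) -> np.ndarray:
    s = np.asarray(truth.sites[tid], dtype=np.int64)
    if len(s) == 0:
        return np.zeros(len(tstart), dtype=bool)
    idx = np.searchsorted(s, tstart, side="left")
    idx = np.minimum(idx, len(s) - 1)
    return (s[idx] >= tstart) & (s[idx] < tend)


def _emit(truth, params, rng, tids, models, m6a: bool,
          target: int, weights: np.ndarray) -> list[FragmentRecord]:
    """Draw ``target`` retained fragments from the weighted transcript pool.

    Candidates are allocated multinomially across transcripts; the m6A assay
    filters them through the capture model, so batches are oversized from the
    running retention rate and any overshoot is subsampled uniformly at the
    end — never truncated in transcript order, which would bias counts.
    """
    spans: list[tuple[np.ndarray, np.ndarray]] = []
    chroms: list[str] = []
    p = weights / weights.sum()
    rate = 0.25 if m6a else 1.0  # running retention-rate estimate
    kept = 0
    for _ in range(200):
        remaining = target - kept
        if remaining <= 0:
            break
        if m6a:
            batch = int(min(max(remaining / rate * 1.2, 1000), 4_000_000))
        else:
            batch = remaining  # every candidate is retained
        counts = rng.multinomial(batch, p)
        batch_kept = 0
        for i in np.nonzero(counts)[0]:
            tid = tids[i]
            model = models[i]
            n_i = int(counts[i])
            windows = truth.te_windows.get(tid)
            ts, te = _draw_on_transcript(rng, params, model, windows, n_i)
            if m6a:
                cov = _covers_site(truth, tid, ts, te)
                keep_p = np.where(cov, params.p_specific, params.p_nonspecific)
                keep = rng.random(n_i) < keep_p
                ts, te = ts[keep], te[keep]
            if len(ts) == 0:
                continue
            gs, ge = _t2g_span(model, ts, te)
            spans.append((gs, ge))
            chroms.extend([model.chrom] * len(gs))
            batch_kept += len(gs)
        if m6a and batch > 0:
            rate = max(batch_kept / batch, 1e-4)
        kept += batch_kept
    if kept < target:
        raise RuntimeError("could not reach requested library depth")
    starts = np.concatenate([s for s, _ in spans])
    ends = np.concatenate([e for _, e in spans])
    chrom_arr = np.array(chroms)
    if kept > target:
        sel = np.sort(rng.choice(kept, size=target, replace=False))
        starts, ends, chrom_arr = starts[sel], ends[sel], chrom_arr[sel]
    return [FragmentRecord(c, int(a), int(b))
            for c, a, b in zip(chrom_arr, starts, ends)]


def simulate_libraries(
    genome: GenomeSequence,
    models: list[TranscriptModel],
    truth: TruthTable,
    params: SimulationParams,
    assays: Sequence[str] = ("m6A", "mRNA", "input"),
) -> list[FragmentLibrary]:
    """Simulate fragment libraries for every organ x replicate x assay.

    mRNA/input fragments are drawn in proportion to expression weights and
    placed uniformly along the transcript (TE transcripts sample only their
    expressed sub-windows); the m6A assay draws from the methylation-weighted
    pool and retains a fragment with probability ``p_specific`` when it covers
    a true site, ``p_nonspecific`` otherwise.  Reproducible from
    ``params.seed``.
    """
    params.validate()
    if params.depth <= 0:
        raise ValueError("zero-depth request")
    tids = truth.transcript_ids
    by_id = {m.transcript_id: m for m in models}
    ordered_models = [by_id[t] for t in tids]
    libs: list[FragmentLibrary] = []
    root = np.random.SeedSequence(params.seed)
    children = root.spawn(len(params.organs) * params.replicates * len(assays))
    k = 0
    for organ in params.organs:
        w_expr = truth.expression[organ].to_numpy(dtype=float)
        w_m6a = w_expr * truth.meth_mult[organ].to_numpy(dtype=float)
        for rep in range(1, params.replicates + 1):
            for assay in assays:
                rng = np.random.default_rng(children[k])
                k += 1
                weights = w_m6a if assay == "m6A" else w_expr
                frags = _emit(truth, params, rng, tids, ordered_models,
                              assay == "m6A", params.depth, weights)
                libs.append(FragmentLibrary(organ=organ, replicate=rep,
                                            assay=assay, fragments=frags))
    return libs


def save_reference(genome, models, truth, outdir: str) -> None:
    """Write FASTA + GFF3 + truth TSV for the generated reference."""
    import os

    from .io import write_annotation, write_genome, write_table

    os.makedirs(outdir, exist_ok=True)
    write_genome(genome, os.path.join(outdir, "genome.fa"))
    write_annotation(models, os.path.join(outdir, "annotation.gff3"))
    write_table(truth.frame(), os.path.join(outdir, "truth.tsv"))
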