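# Methods

`m6akit` implements the post-alignment arithmetic of an antibody-capture
m6A-seq experiment read against a parallel mRNA-seq library, together with a
ground-truthed simulator of that experiment.  This note records the models,
the defaults and why they hold, the numerical choices, and the limitations
that the test suite itself exposes.

## Quantification model

Expression uses the standard FPKM,

    FPKM = count x 1e9 / (spliced length x total mapped fragments),

where *spliced length* is the exon-union length (not the genomic span) and
library totals are library-wide — fragments with no exonic overlap still
count in the denominator.  The m6A-seq signal cannot be normalized by
transcript length, because a capture library samples only fragments carrying
a site; it is instead normalized by the **covered length**, the union length
of transcript bases covered by m6A fragments:

    MFPKM = count x 1e9 / (covered length x total mapped m6A fragments).

Covered length is computed in spliced transcript coordinates after
projecting each genomic fragment through the exon map (a contiguous genomic
interval always projects to a contiguous transcript interval).  Fragments
overlapping several transcripts are counted for each; no multi-mapping
rescue is attempted.  Unknown-strand fragments adopt the transcript's strand
— capture libraries are effectively unstranded.

The m6A **site count** of a transcript is estimated as
`round(covered_length / 150)` with a floor of one for any positive coverage
(a methylated transcript must report at least one site); 150 nt is the
typical peak footprint of a ~100-nt-fragment capture assay.  Two properties
of this estimator matter and are verified by the tests rather than hidden:

* At saturating depth the footprint of a single site is
  2 x fragment length − 1.  With constant 100-nt fragments that is 199 nt,
  which `/150` correctly reads as one site; with a spread of fragment
  lengths (default sd 20 nt) the max-length tail widens the footprint to
  ~300 nt and the estimator reads about two per site.  The single-site
  recovery test therefore uses constant-length fragments; under the default
  spread, per-transcript site counts should be read as relative, not
  absolute.
* Non-specific (background) fragments land anywhere on a transcript, so
  covered length — and with it MFPKM — keeps growing with depth even after
  site regions saturate.  At very high depth this stabilizes (covered length
  approaches the transcript length); at desk-scale depth it is the dominant
  noise term in MFPKM (see *Limitations*).

## Extent classification

Each methylated transcript's (MFPKM, FPKM) pair is rescaled to percentages
of its sum and tested against a 50/50 split with a two-cell goodness-of-fit
chi-square:

    chi2 = (pM − 50)^2/50 + (pF − 50)^2/50,   pM = 100·MFPKM/(MFPKM+FPKM).

The statistic depends only on the MFPKM:FPKM ratio, not the magnitudes.  A
two-cell goodness-of-fit has one degree of freedom, so p-values use
chi-square(df=1).  Significant transcripts are High (MFPKM > FPKM) or Low;
everything else is Equivalent (p >= alpha, default alpha = 0.05 — the only
self-consistent reading, since a test cannot positively conclude a 1:1 fit).
Unmethylated transcripts are excluded, never classified.

Because covered length <= spliced length, a transcript sampled at equal
rates in both assays already has MFPKM >= FPKM; a preponderance of High
calls is therefore built into the definition, and the simulator reproduces
it without any planted asymmetry.

The expression-tertile summary ranks the methylated set by FPKM descending
(ties broken by transcript id for determinism), splits it into thirds with
the remainder assigned to earlier groups, and reports each third's mean
MFPKM, mean FPKM and their ratio.  Between-grouping tests are Welch t-tests
on the per-transcript MFPKM/FPKM ratios — a t-test on the two grouping means
alone would have no degrees of freedom.  "Extensively methylated" transcripts
pass MFPKM/FPKM >= 10, BH-FDR < 1e-12 (BH within organ/replicate over the
extent p-values) and m6A read count >= 30; organ sets are intersected for
the common core.

## Differential methylation

NFPKM = MFPKM / log2(FPKM) damps the influence of expression level on the
methylation signal.  Transcripts with FPKM <= 1 have a non-positive log and
are excluded with an explicit reason, never silently dropped.  Between-organ
calls apply the same percentage chi-square to the two NFPKM values, BH-FDR
across all tested transcripts of the pair, and a fold-change gate; defaults
are fold > 2 (or < 0.5) at FDR < 0.05, with named presets for the stricter
variants (organ-specific extreme sets: fold >= 10 / < 0.1, FDR < 1e-10,
reads >= 20; and the alternative 0.02 / 0.005 FDR cutoffs of the original
protocol's methods text).  Differential expression uses the identical
machinery on FPKM.  Organ-specific sets require a transcript to be higher in
the focal organ than *both* other organs in *both* replicates (set
intersection).  No between-library scaling beyond the per-million factors
inside FPKM/MFPKM is applied.

## Metagene, peaks, motifs

Metagene profiles rescale every covered transcript (length >= 60 nt) to 60
bins from TSS to 3' end; the per-bin value is fragment bases in the bin
scaled per kb of bin width and per million library fragments, and transcript
profiles are averaged with equal weight.  Binning is over spliced
coordinates, which places stop codons of typical gene architecture
(5'UTR ~120 nt, CDS ~1.2 kb, 3'UTR ~230 nt) near bins 49–59.  Cross-organ
profile comparison is a one-way ANOVA treating bins as observations and
organs as groups; identical flat profiles return p = 1 rather than a
zero-variance NaN.

Peaks are maximal runs of per-base transcript depth >= min_depth (default 1),
with the summit at the leftmost maximum; at min_depth 1 peak spans tile the
covered union exactly, which ties peak calling to the covered length used by
MFPKM.  Topology: the stop region spans [stop codon − 100 nt, 3' end]; a
transcript is Type 1 when its maximum peak height there is at least 2x the
maximum in the upstream CDS (threshold configurable; a covered stop region
with a silent CDS is Type 1 by convention), Type 2 otherwise; transcripts
without a CDS are flagged not-applicable.

Motif analysis ranks peaks by height (ties by transcript then position),
takes a 100-nt window of the spliced sense sequence around each of the top
1,000 summits, and scans every position for RRACH (R in {A,G}, H in
{A,C,T}; the methylated A is position 3).  One instance per peak — the match
nearest the summit — enters the frequency table, so frequencies are
peak-weighted; counting all instances is available behind a flag.  Motifs
live in DNA space internally and render with T→U for display.  Because the
summit of an empirical peak jitters a few nucleotides around the true site,
windows containing several sites or chance background RRACH instances dilute
planted-frequency recovery; the clean measurement design is one site per
transcript.

## The simulator

`generate_reference` lays non-overlapping transcripts (1–3 exons, random
strand, 80–300-nt introns, 200-nt intergenic gaps) on a random-base
chromosome and **writes** an RRACH 5-mer at every planted site — recovery
tests therefore have exact truth, with no dependence on motif discovery.
Defaults emulate the assayed system: ~2 planted sites per transcript
(distribution 1–4), 75% of sites within the stop-codon/3'UTR window
(Gaussian offset, sd 40 nt, around the last coding base), 15% in the CDS,
10% near the 5' end; planted 5-mer frequencies put AAACT at 19.3% and AAACA
at 19.0% with the remaining ten consensus 5-mers uniform.  Expression
weights are log-normal (sigma = 1); 4% of transcripts are
transposable-element-like, transcribed only in 2–4 disjoint sub-windows
(the "fragmented" TE pattern) and carrying no CDS.

`simulate_libraries` draws ~100-nt fragments (sd 20, minimum 30) uniformly
along expression-weighted transcripts.  The m6A assay samples candidates
from the methylation-weighted pool (expression x per-organ methylation
multiplier) and retains a fragment with probability p_specific = 0.9 if it
covers a site, p_nonspecific = 0.001 otherwise — per-fragment Bernoulli,
independent across fragments.  With ~2 sites per transcript this leaves
just under 1% of the retained pool non-specific, the background level the
assay design targets.  Batch overshoot is subsampled uniformly, never
truncated in transcript order (which would bias per-transcript counts).
Planted organ effects are multiplicative: differential expression (default
10% of transcripts at 4-fold) and differential methylation (default 10% at
4-fold, disjoint from the expression set), recorded per organ pair in the
truth table.  All outputs are bit-reproducible from the seed.

Two deliberate control modes exist for calibration experiments:

* `edge_model="padded"` draws fragment starts from a fragment-length pad
  beyond both transcript ends (clipped), giving exactly uniform expected
  coverage; the default `"inside"` mode provably ramps coverage over the
  terminal ~100 nt, so a flatness check against the default would measure
  geometry, not estimator error.
* `p_nonspecific=0` (capture-clean) makes the covered length equal the site
  footprint in both organs, so a planted k-fold methylation multiplier is
  realized as a k-fold MFPKM/NFPKM difference.  With background on, covered
  length grows with signal and compresses a planted 4-fold multiplier to a
  realized NFPKM fold of ~1.5–2.5; the differential-recovery test uses the
  clean mode and verifies the realized fold before asserting sensitivity.

What the simulator does **not** model: sequencing errors and quality,
isoform complexity, positional fragmentation bias, amplification artifacts,
or overlapping gene models.  Passing recovery tests show the estimators are
faithful to their own definitions under this generative model, not that the
biology of a real tissue is captured.

## qPCR validation arithmetic

RA = 100 x 2^-(Ct_target − Ct_reference) with the standard dCt convention
against a housekeeping reference; EA = 100 x (m6A fragments of the test gene
in its amplicon region / mRNA fragments of the reference gene in its
amplicon region), amplicons constrained to 50–150 nt.  Agreement is Pearson
r over pooled gene x organ pairs with a Fisher-z 95% CI; zero-variance
inputs return an undefined flag rather than a spurious value.  Raw values
are correlated by default, with a log option.

## Numerical choices and degenerate inputs

All internal coordinates are 0-based half-open; GFF3 converts at the I/O
boundary only.  MFPKM of a zero-count transcript is 0 by convention; a
positive count with zero covered length is an inconsistency error.  BH-FDR
comes from statsmodels; chi-square tails from scipy.  Tabulated percentages
round to one decimal and cross-organ averages are unweighted means of
per-organ percentages (so they inherit that rounding).  Identical constant
inputs short-circuit to p = 1 in the profile ANOVA and the tertile t-tests.
Tertile remainders go to earlier (higher-expression) groups.

## Limitations

* **Null calibration of the differential test is depth-dependent.**  The
  percentage chi-square has no sampling model, and MFPKM's covered-length
  denominator is hypersensitive to the Poisson-variable handful of
  background fragments a transcript retains at desk-scale depth (a 0-vs-5
  background split between organs moves covered length 2–3x).  In a
  no-effect two-organ simulation at the default preset, 7–8% of transcripts
  fall below FDR 0.05 — above the nominal 5% — and this is a property of the
  statistic at this depth, not a seed artifact.  Libraries deep enough to
  saturate covered length (as in the assayed datasets, ~100x deeper) escape
  the effect.
* Site counts from covered length inherit the footprint bias described
  above and should be compared within, not across, fragment-length regimes.
* The metagene ANOVA treats bins as independent observations, which they
  are not; its p-value is a descriptive summary, not a calibrated test.
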