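# Methods

This note documents the statistical procedures, the synthetic-data model,
the parameter defaults and the numerical choices in `riboshift`, and what
the simulation-based tests do and do not demonstrate about real data.

## Coordinate conventions

All internal coordinates are 0-based half-open; GTF and SAF (both 1-based
inclusive) are converted at the I/O boundary, BED is native. Exon lists are
stored in transcript orientation (descending genomic start on the minus
strand) so transcript-space arithmetic is strand-free. The CDS interval
spans the start codon **through the stop codon**, so its length is divisible
by three; annotations that exclude the stop codon from CDS features (e.g.
GENCODE) would need the stop codon appended before use.

One representative isoform per gene is chosen by a fixed hierarchy: (1) has
a CDS with non-empty 5′ and 3′ UTRs, (2) longest CDS, (3) longest
transcript, (4) lexicographically smallest transcript id. The hierarchy is a
deterministic convention of this package — reproducibility demands *some*
total order, and published pipelines rarely state theirs.

## P-sites, occupancy and the metagene estimator

P-sites are assigned at the footprint 5′ end + a length-dependent offset;
the default table maps lengths 28–32 nt to +12 nt and drops other lengths
(drop counts are reported, never fatal). Fixed offsets keep the stage
transparent; the table is fully configurable for libraries calibrated
differently.

Per transcript, P-site counts are partitioned into 5′UTR/CDS/3′UTR;
transcripts with fewer than 50 P-sites are excluded from metagene and
ratio analyses. The metagene estimator interpolates each region onto fixed
sub-grids of 250/1500/250 points (2000 total) so region boundaries align
across transcripts, normalises each transcript profile to unit mean (deep
transcripts must not dominate), averages with equal weight, and smooths with
a Gaussian kernel (default sd 5 grid points, truncated at 4 sd,
nearest-value boundary handling). Per-region grids, the 2000-point total,
and the 50-read filter are fixed study conventions; the smoothing bandwidth
is a free parameter with a conservative default.

The redistribution statistic uses **pooled** library-level fractions per
replicate (sum of region counts over qualifying transcripts divided by the
summed totals) rather than means of per-transcript fractions, so low-count
transcripts do not dominate; the per-transcript-mean variant is available
via `pooled=False`. The test is a classic equal-variance two-tailed unpaired
t-test on per-replicate 5′UTR fractions; the point estimate is the ratio of
mean per-replicate 5′UTR:3′UTR ratios (arrested over proliferating). At the
default simulation scale the estimator shows a small (≈ +2–5%) positive
bias relative to the generator's expectation target, driven by the ≥50-read
filter and footprint edge effects near the cap; this is well inside the
±10% recovery band the tests assert.

## ORF discovery

Candidates are every occurrence of a start-set codon (default: ATG plus the
nine single-mismatch near-cognates CTG, GTG, TTG, ACG, AGG, AAG, ATA, ATT,
ATC) extended in frame to the first stop; candidates without an in-frame
stop are discarded, and among nested candidates sharing a stop only the
5′-most start per class (ATG vs near-cognate) is kept.

The translation test is a deliberately transparent substitute for EM-based
codon-activity inference, with the same downstream contract (a scored,
categorised ORF table filtered at p ≤ 0.05): a one-sided binomial test on
triplet periodicity, k in-frame P-sites out of n in the candidate, null
success probability 1/3. Candidates with n below `min_psites` (default 10)
are uninformative and receive p = 1. No multiple-testing correction is
applied by default, mirroring the raw p ≤ 0.05 convention of this analysis
style; BH is available behind a flag. Consequence: the false-discovery
proportion among calls scales with the number of background candidates that
clear `min_psites`. In recovery experiments run at the ≥30 P-sites/ORF
regime the caller is evaluated with `min_psites=30`, where measured FDR is
≤ 0.05; at `min_psites=10` the uncorrected filter admits roughly 5% of the
several hundred low-coverage background candidates and the FDR rises to
≈ 0.1, which users should weigh when lowering the floor.

Categories are assigned in a fixed decision order: ncRNA (no CDS), CDS
(identical), truncation (same frame and stop, start inside the CDS), uORF
(entirely upstream), uoORF (start upstream, overlaps the CDS start,
different frame), dORF (entirely downstream), iORF (inside the CDS,
different frame), variant, orphan. *Variant* is defined here as any
remaining candidate overlapping the CDS **in the same frame** (the canonical
example being an N-terminal extension sharing the CDS stop); *orphan* is
everything else (e.g. a frame-shifted ORF running from the CDS into the
3′UTR). Same-frame 5′ extensions are therefore variants, not uoORFs.

Harringtonine run-off scoring: score(site, t) = P-sites within ±1 codon of
the site divided by the track total at time t; trajectories and the
uTIS:annotated-TIS ratio per time point are reported. The one-sided Fisher
exact test is provided as a primitive on user-supplied 2×2 count tables;
the package does not impose a particular contingency layout.

## Counting, normalisation, TE

Counting follows the SAF contract (1-based inclusive; multi-interval
features summed). The ≥5-read filter requires the threshold in **every**
sample by default (`mode="any"` is available; the source wording of such
rules is usually ambiguous). TMM is implemented from its definition —
reference sample by the 75th-percentile rule, genes with zeros dropped,
log-ratios doubly trimmed (30% on M, 5% on A), inverse-asymptotic-variance
weighted mean, factors rescaled to geometric mean 1 — and is tested to
1e-9 against both an independently coded step-by-step reference and factors
frozen from `edgeR::calcNormFactors`. Grubbs outlier screening is two-sided,
single-pass (at most one point flagged), with the closed-form Student-t
critical value; with n < 3 or zero variance no test is performed.

TE is the library-size-normalised ribo/RNA ratio over the same coordinates;
features with zero RNA (or zero ribosome) counts in a condition are reported
as excluded rather than tested. Differential TE uses a 2×2 chi-square on
(ribo, rna) × (condition A, B) counts without continuity correction,
falling back to the Fisher exact test when any expected cell is below 5,
then BH across features. This count-based test replaces dispersion-modelling
GLMs: it requires aggregate counts per condition (true replicate columns
can be summed), is exactly calibrated at small counts, and mildly
anticonservative at large counts — the null-calibration suite bounds its
type-I error at ≤ 7% at α = 0.05 under Poisson sampling.

## Peptide database

ORFs at p ≤ 0.05 are projected to BED12 (splice-aware blocks; thickStart/
thickEnd span the ORF), their spliced nucleotide sequence extracted and
translated with the standard nuclear code. The initiator codon is decoded
as methionine regardless of identity — the initiator-tRNA convention for
near-cognate starts — with literal decoding behind a flag, since a naive
translation of the nucleotide sequence would decode it literally; both modes
are tested. Internal stops truncate the product (counted and logged) rather
than discarding it, keeping partial products searchable. Products longer
than seven amino acids are kept; exact duplicates are collapsed with their
headers joined by ";". Output order is deterministic (proteome first, then
ORF entries sorted by header); FASTA is wrapped at 60 columns with
"|"-separated, space-free headers for search-engine compatibility.

## Differential immunopeptides

Per peptide, a pooled two-group variance s² with d = nA + nB − 2 degrees of
freedom; the scaled-F prior (d0, s0²) is fitted by moment matching on
log s² (the trigamma term inverted by bisection), the posterior variance is
(d0·s0² + d·s²)/(d0 + d), and the moderated t is referred to Student-t with
d0 + d df (normal when d0 = ∞, i.e. when the observed spread of log s² does
not exceed its sampling spread). The implementation agrees with statistics
frozen from `limma::eBayes` to 1e-8 on a fixed fixture. Missing intensities
are deleted pairwise with ≥2 valid values per group required; there is no
imputation, and no cross-run normalisation is applied by default
(median-centering is available but off). If fewer than two informative
variances exist the test falls back to the unmoderated pooled-variance t.

Classification applies the printed inequalities literally to the absolute
fold change FC = 2^|log2FC|: hits require FC **strictly greater than 2**
and BH-FDR ≤ 0.05; candidates FC ≥ 1.5 and FDR ≤ 0.2; the sign of log2FC
gives the up/down label. A peptide with FC exactly 2.0 is therefore a
candidate, not a hit.

## The synthetic-data model

The generator defines the study conditions; its defaults are chosen once
and are the conditions under which all recovery tests run.

* **Transcriptome** — one transcript per gene (1–3 exons, random strand),
  mean region lengths 180/900/240 nt (5′UTR/CDS/3′UTR); at most one uORF
  (8–20 codons, entirely upstream) or uoORF (8–25 codons, stop within 10
  codons of the CDS start, frame ≠ CDS) planted per gene (p = 0.35/0.20),
  30% initiating at ATG and the rest at near-cognate codons. The planted
  frame is scrubbed of competing start-set codons so the planted start is
  the candidate the scanner reports; planted ORFs carry no internal stops.
  Transcript abundances are log-normal (σ = 0.75) and shared between
  footprint and RNA simulations.
* **Footprint libraries** — mixtures over read classes. Proliferating:
  CDS-uniform occupancy with 3% diffuse leakage into each UTR (real
  libraries place only a few percent of reads in UTRs). Arrested: plus 3%
  of the library on planted upstream ORFs (periodic) and a 5′ front-load
  component with exponential decay from the cap (scale 120 nt, support
  5′UTR + 150 nt of CDS) whose weight is solved numerically so that the
  expected library-level 5′UTR:3′UTR ratio equals `front_load_ratio` times
  the proliferating ratio — the single interpretable knob behind the
  two-fold redistribution. Within any ORF, P-sites land in frame 0 with
  probability `periodicity` (default 0.9). Footprint lengths are drawn from
  {28..32} with mass centred at 29–30 nt; reads whose 12-nt offset would
  fall off the transcript are resampled (a cap-proximal edge effect).
  Feasibility constraint: `uorf_occupancy × (5′UTR share of planted ORFs)`
  must stay below `(front_load_ratio − 1) × utr5_leak`, otherwise the
  mixture weight has no non-negative solution and the configuration is
  rejected.
* **Harringtonine(t)** — initiation piles (±1 codon) persist at active
  starts (uTIS share 8% proliferating / 50% arrested of pile reads);
  elongating ribosomes initiated uniformly and advanced by `rate × t`
  codons (default 3 codons/s), so the 5′ CDS empties first and ribosomes
  reaching the stop leave the library (the library is resampled to fixed
  depth, as real size-selected libraries are). As t → ∞ only piles remain.
* **RNA-seq** — negative-binomial counts (dispersion 0.1; 0 gives Poisson)
  with expectation ∝ abundance × feature length, identical across
  conditions (the premise that RNA levels do not change).
* **Peptide intensities** — log2 intensities Normal(baseline ± effect/2,
  s²) with per-peptide s² from a scaled inverse-chi-square (d0 = 4,
  s0² = 0.09), baseline N(23, 2²), missing completely at random.

What passing recovery tests shows: the estimators correctly invert the
generative model they assume — unbiased ratio recovery, calibrated null
behaviour, high recall/low FDR on planted signals. What it does not show:
robustness to the features of real data the generator deliberately omits —
sequence-dependent ligation bias, codon-level pausing, offset
mis-calibration across footprint lengths, isoform mixtures, overlapping
ORFs sharing P-sites, intensity-dependent missingness in MS, and batch
structure. Conclusions about real libraries need the usual QC on those
axes.

## Numerical choices and degenerate inputs

Ties in isoform selection fall through to the transcript-id rule; the
binomial test uses the exact survival function (no normal approximation);
BH is the step-up procedure with monotonicity enforcement, reported in
input order; the trigamma inversion brackets geometrically before
bisection (200 iterations); TMM returns factor 1 for a sample whose
trimmed M-set is empty or identically zero; empty ORF sets produce a
proteome-only database with a warning; an all-zero Fisher table, a config
without a seed, and a missing-everywhere peptide matrix are errors, not
silent passes. Pipeline stage seeds derive from the master seed by stable
CRC32 hashing, so reruns with an identical config are byte-identical
(verified by manifest checksums).

## Problem sizes used in validation

Recovery experiments use 200 genes × 2×10⁵ footprints per library (3 + 3
replicates) for redistribution, the same scale for caller recovery
(evaluated over planted ORFs that received ≥30 P-sites), 300 null
simulations at 25 genes × 1.5×10⁴ reads for t-test calibration, 500
simulated feature sets for differential-TE calibration, and 100 × 1000
peptides for the null hit rate — sizes at which Monte-Carlo error is small
relative to every asserted tolerance while the whole suite runs in well
under a minute per property.
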