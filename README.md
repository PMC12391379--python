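# riboshift

Ribosome-profiling analysis of translational remodelling in mitotically
arrested cells: metagene redistribution statistics, upstream open reading
frame (uORF/uoORF) discovery, translation efficiency, immunopeptidomics
search-database construction and differential immunopeptide quantification —
with a first-class synthetic-data module, so the whole pipeline is testable
without any sequencing or mass-spectrometry downloads.

## The scientific problem

Cells arrested in mitosis (for example by Taxol or nocodazole) redistribute
ribosomes away from uniform CDS coverage toward the 5′ UTR and the start of
the CDS. This "front-loading" drives translation of upstream ORFs — uORFs
(start and stop entirely inside the 5′ UTR) and uoORFs (start in the 5′ UTR,
stop inside the CDS in a shifted reading frame) — whose peptide products can
be presented on HLA class I and recognised by T cells. `riboshift` implements
the computational path from aligned ribosome footprints (transcript
coordinates) to that biology:

1. **Region occupancy and metagene profiles.** For one representative
   isoform per gene, per-nucleotide P-site occupancy (5′ end + 12 nt offset
   for 28–32 nt footprints) is split into 5′UTR/CDS/3′UTR, transcripts with
   < 50 P-sites are excluded, each region is linearly interpolated onto a
   fixed grid (250/1500/250 of 2000 points), normalised to unit mean,
   averaged and Gaussian-smoothed. The redistribution statistic is the
   arrested:proliferating ratio of library-level 5′UTR:3′UTR occupancy
   ratios, with a two-tailed unpaired t-test on per-replicate 5′UTR
   fractions.
2. **ORF discovery.** Candidate ORFs are scanned from every ATG or
   near-cognate start codon to the first in-frame stop and scored with a
   one-sided binomial triplet-periodicity test: with *n* P-sites in the
   candidate and *k* of them in frame 0, `p = P(X ≥ k), X ~ Bin(n, 1/3)`.
   Candidates at `p ≤ 0.05` are classified into the standard taxonomy
   (CDS, truncation, uORF, uoORF, dORF, iORF, ncRNA, variant, orphan).
3. **Quantification.** featureCounts-style counting over SAF intervals, a
   ≥ 5 reads-per-sample filter, TMM normalisation (numerically equivalent to
   `edgeR::calcNormFactors`), CPM, Grubbs outlier screening, and translation
   efficiency `TE = (ribo/ribo_lib)/(rna/rna_lib)` with a count-based 2×2
   test and Benjamini–Hochberg adjustment for differential TE.
4. **Peptide database.** Scored ORFs are projected to genomic BED12,
   spliced nucleotide sequences extracted and translated (initiator codon
   decoded as Met), products longer than 7 aa deduplicated and appended to a
   reference proteome as an immunopeptidomics search FASTA.
5. **Differential immunopeptides.** An empirical-Bayes moderated t-test
   (variance prior fitted by moment matching on log variances; numerically
   equivalent to `limma::eBayes`), BH adjustment, and classification into
   hits (fold change > 2, FDR ≤ 0.05) and candidates (fold change ≥ 1.5,
   FDR ≤ 0.2).

The synthetic-data module generates transcriptomes with planted uORF/uoORFs,
footprint libraries in proliferating / arrested / harringtonine-run-off
regimes (20–34 nt lengths, 3-nt periodicity, configurable 5′UTR
front-loading), negative-binomial RNA-seq counts and log-normal peptide
intensity matrices with planted fold changes — all pure functions of a seed.

## Worked example

```bash
cat > demo.yaml <<EOF
seed: 7
n_genes: 50
library_size: 20000
n_replicates: 3
n_peptides: 200
outdir: demo_out
EOF
riboshift run --config demo.yaml
```

This simulates a 50-gene transcriptome (31 planted uORF/uoORFs), six
footprint libraries (3 proliferating + 3 arrested, 20 000 footprints each),
and runs every stage. The run prints per-stage counters, including:

```
"callorfs": { "n_candidates": 2501, "n_called": 137,
              "by_category": { "CDS": 42, "uORF": 18, "uoORF": 13, ... } },
"builddb":  { "n_orf_entries": 29, "n_proteome_entries": 50 },
"quant":    { "classes": { "hit_up": 8, "candidate_up": 3, "ns": 189 } }
```

and `demo_out/utr_ratio.json` holds the recovered redistribution:

```json
{
  "ratio_arrested_vs_proliferating": 1.896,
  "t_stat": 23.45,
  "p_value": 1.96e-05
}
```

i.e. the arrested libraries place ~1.9× more occupancy in the 5′UTR relative
to the 3′UTR than proliferating libraries (ground truth 2.0), the 137
p ≤ 0.05 ORFs include the planted uORFs/uoORFs, the search database gains 29
unique upstream-ORF peptides on top of the 50 proteome entries, and 8 of the
10 peptides simulated with a four-fold abundance increase are recovered as
hits. Individual stages are also available as subcommands
(`riboshift simulate|metagene|callorfs|count|te|builddb|quant|validate`) and
as plain library calls (`riboshift.profiles.metagene_profile`,
`riboshift.orfs.call_orfs`, `riboshift.immuno.differential_peptides`, ...).

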