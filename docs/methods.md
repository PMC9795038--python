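# Methods

## Problem setting

Mutation-agnostic RNAi gene therapy pairs a suppressor (an artificial miRNA
that silences *both* wild-type and mutant endogenous transcripts) with a
replacement cDNA that escapes suppression because its RNAi target site has
been rewritten with synonymous codons. Two computational problems follow:

1. **Design** — rewrite the target site so the guide no longer matches while
   the encoded protein is untouched, and prove it.
2. **Quantification** — after treatment, measure how much of the transcript
   pool comes from the endogenous gene vs. the delivered construct, and how
   strongly the endogenous allele was knocked down, using single-cell
   RNA-seq reads that span the (recoded) site.

`alleleq` implements both, plus the QC and statistics around them, and a
synthetic-data generator that makes every estimator testable against known
ground truth without any external download.

## Site recoding

The recoding engine works on the codon grid of a declared frame and
orientation. For every codon fully contained in the target site it
substitutes the synonymous codon with the most nucleotide mismatches; ties
are broken by the lexicographically smallest codon so output is
deterministic. Codons are disjoint, so per-codon maximisation is globally
optimal — verified in tests against exhaustive enumeration over all
synonymous codon assignments for sites of up to 7 codons. Codons that
straddle a site edge, stop codons, and codons containing ambiguous bases are
preserved verbatim: protein safety is prioritised over divergence.

Because published site pairs do not always state their strand,
`infer_matching_frame` searches all 3 frame offsets × 2 orientations
(applied jointly to both sequences) and returns the first candidate with
identical peptides. Synonymy additionally requires every nucleotide
difference to fall inside a fully covered codon — a difference in an
untranslated overhang cannot be certified synonymous. On the worked-example
21-mer pair this finds synonymy only on the reverse-complement strand in
frame 0 (peptide PVLYMIV, six differences, all at wobble positions); the
engine's own maximiser achieves 7 substitutions on that site (per-codon
1+1+2+1+0+1+1), one more than the published design, which is why a
"match a provided engineered sequence" mode exists alongside "maximise".

`verify_resistance` operationalises "escapes RNAi" as threshold counts:
total mismatches ≥ 6 and mismatches in the seed-pairing window (default
site positions 1–7, 0-based half-open) ≥ 1 by default. These are
configurable heuristics, not a thermodynamic model.

## Allele counting and expression split

A read is assigned to an allele iff the full-length site sequence, or its
reverse complement, occurs as an exact substring. Exactness is deliberate:
with 21-nt sites at Hamming distance 6, single sequencing errors void a
match (the read is simply not counted) but cannot flip a read's allele, so
the estimator loses depth symmetrically and stays unbiased. Mates sharing a
read id count once per fragment; a fragment matching both alleles is counted
as neither and logged. Reads with N in the matched window never match.

Allele fractions are **pooled at the group level**: counts are summed over
all cells with ≥ 1 site-spanning read, and the resulting percentages are
applied to every cell of the group. A per-cell-fraction mode was considered
and rejected as the default because per-cell site-read counts are small and
noisy; pooling matches how such fractions are normally reported.

Expression is depth-normalised as counts per million (CPM = raw count /
total mapped reads × 10⁶) — the simplest defensible normalisation when only
a count table is available. Each cell's CPM is split as
`exo = cpm × pct_exo/100`, `endo = cpm − exo` (with one re-subtraction so
the two components reproduce the total bit-for-bit).

Knockdown efficiency is

    100 × (1 − mean(treated endogenous CPM) / mean(control total CPM)),

with the untreated control assumed fully endogenous. Negative values
(treated endogenous above control) are returned and flagged rather than
clipped. Note this estimator is a group-mean ratio: it is *not* in general
reconstructible from an exogenous percentage and a fold-change alone, since
those can combine into different per-group values.

## QC filters

Genes are filtered first (detected in ≥ 3 cells by default); the per-cell
expressed-gene tally then counts only surviving genes, and cells need
≥ 3000 such genes and a mitochondrial read fraction ≤ 7%. The mitochondrial
fraction is read-based and computed on the unfiltered table; mitochondrial
genes are identified by a configurable id prefix (default `mt-`). Order
matters — a cell can fail the gene tally only because a private gene was
removed — and a dedicated test pins that ordering. The filter is a single
pass (gene filter, then cell filter), which is idempotent whenever surviving
cells support the surviving genes; it is not iterated to a fixed point.

## qPCR ΔΔCt

Ct triplicates are aggregated by arithmetic mean (no outlier rejection).
ΔCt = mean(target) − mean(reference) per sample, ΔΔCt = ΔCt(test) −
ΔCt(control), relative expression = 2^(−ΔΔCt), knockdown% = 100 × (1 −
2^(−ΔΔCt)). The headline knockdown is computed from mean Cts; per-replicate
knockdown values are reported alongside as spread.

## Statistical battery

* Two groups: Welch's t (scipy), two-sided; both-constant equal-mean input
  returns p = 1 by convention.
* ≥ 3 groups: Bartlett's test at α = 0.05 (configurable) routes to one-way
  ANOVA + Tukey HSD (scipy) or, when variances differ or any group is
  constant, Welch's ANOVA (statsmodels `anova_oneway`, unequal variances)
  with Dunnett's T3. T3 p-values use the studentized maximum modulus
  distribution, computed by numerically integrating
  ∫ (2Φ(ms) − 1)^k f_χ(s) ds over the scaled chi density with the pair's
  Welch–Satterthwaite df; for k = 1 this reduces to the two-sided t tail
  (asserted in tests to 1e−8).
* Nonparametric: Kruskal–Wallis (scipy, tie-corrected) with Dunn's z tests —
  z = (R̄ᵢ − R̄ⱼ)/√((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ)) — adjusted
  by Benjamini–Hochberg across all pairs of one endpoint.

Dunn and Dunnett T3 are implemented in-package; everything else delegates to
scipy/statsmodels and is cross-checked in tests against independent
hand-formula oracles (and pingouin for Welch's ANOVA) to 1e−8.

## Synthetic data: what it emulates, and what it does not

The generator is the test harness for the whole pipeline. Defaults describe
a small full-length single-cell experiment:

| parameter | default | meaning |
|---|---|---|
| `n_cells` | 12/group | outer-hair-cell scale experiment |
| `site_reads_per_cell` | 200 | site-spanning reads per cell |
| `read_length` | 100 nt | site (21 nt) + random flanks |
| `per_base_error_rate` | 0.005 | uniform substitution error |
| `mean_tmc1_cpm` | 300 (control) | gene-of-interest expression |
| `nb_dispersion` | 0.2 | var = μ + 0.2μ² (overdispersed counts) |
| `mean_depth` / `depth_sigma` | 10⁶ / 0.35 | lognormal per-cell depth |
| `mito_fraction` | 0.03 | share of depth in `mt-*` pseudo-genes |

Per-cell counts of the gene of interest are negative binomial
(`dispersion = 0` degenerates to `round(mean)`); group means encode
fold-changes vs. control. The `paper_groups_preset` ships four groups —
two fully endogenous controls and two treated groups with exogenous
fractions 0.764/0.965 and fold-changes 1.836/3.48 — as data, not code.
Reads are single-end (the counting contract is fragment-level, so pairing
only affects dedup, which is tested separately with explicit mate ids).

Not emulated: transcriptome-wide structure, splicing, UMIs, ambient RNA,
mapping artefacts, or any correlation between a cell's depth and its allele
mixture. Passing recovery tests therefore shows the estimators are correct
and unbiased under exact-match-with-error sampling — not that real libraries
are free of alignment- or chemistry-induced biases.

All generators are pure functions of (config, seed); the same seed yields
byte-identical FASTQ. Recovery checks average over 25 replicate seeds:
pooled allele fractions on 12 cells × 200 reads at 0.5% error are recovered
within 1 percentage point, the 85%-knockdown setup within 3 points, and
group-mean percent increases of 83.6%/248% (50 cells/group, dispersion 0.15)
within 5% relative. These problem sizes keep the whole suite and the
reproduction script in the seconds range.

## Numerical and interface choices

* Coordinates are 0-based half-open everywhere, including CLI flags and BED
  input.
* Allocation uses a compensated subtraction so `endo + exo == total`
  exactly in floating point.
* Reports isolate the timestamp in one `generated_at` provenance field;
  everything else is byte-reproducible given the same inputs.
* Degenerate inputs (all-identical samples, zero-variance groups, cells
  with no site reads, zero sequencing depth) either take documented
  conventions (p = 1) or raise typed errors (`DesignError`, `QuantError`,
  `QCError`); they are never silently coerced.

## Known limitations

* Exact matching cannot use reads that span the site only partially, and
  discards ~10% of reads at 0.5% error over a 21-nt site; it trades depth
  for zero allele-misassignment.
* The knockdown estimator assumes the control group is fully endogenous and
  that treated and control cells are comparable in depth normalisation.
* Off-target scoring, hairpin thermodynamics, and alignment/pseudo-alignment
  are out of scope; the pipeline consumes a gene-count table.
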