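# Methods

## Model of the data

A bulk tumour expression profile is treated as a convex mixture of three
component profiles on the linear (TPM) scale:

    x_tumour = f_mal * M_s + f_str * S + f_imm * I,   f_mal + f_str + f_imm = 1

where `M_s` is the malignant profile of the tumour's subtype `s` (luminal or
basal), and `S` and `I` are shared stromal and immune profiles. A cell line
is `M_s` alone, with multiplicative culture-adaptation fold changes on
designated gene blocks. Tumour purity is `f_mal`. All analyses run on
log2(TPM+1); scores and correlations that drive the purity correction are
rank- or Pearson-based on that scale.

## Synthetic cohort generator

The generator (`purecell.cohort`) draws cohorts with full ground truth. Its
defaults are the reference study conditions used by the analysis drivers,
the acceptance script and the recovery tests; they are fixed once:

| parameter | default | meaning |
|---|---|---|
| n_tumours / n_cell_lines / n_genes | 200 / 50 / 2000 | cohort dimensions |
| frac_stromal_genes / frac_immune_genes | 0.10 / 0.10 | signature block sizes |
| frac_culture_up / frac_culture_down | 0.05 / 0.05 | culture-adaptation blocks |
| stromal_effect / immune_effect | 8 | compartment specificity fold |
| culture_effect | 4 | culture fold change (up: x4, down: /4) |
| purity_alpha, purity_beta | 5, 2 | malignant fraction ~ Beta(5, 2), mean 0.71 |
| stromal_immune_split (± jitter) | 0.5 ± N(0, 0.05) | stroma share of non-malignant mass |
| frac_subtype_genes / subtype_effect | 0.10 / 4 | subtype-discriminating markers |
| base_log2_mean / base_log2_sd | 5 / 2 | log-normal baseline expression |
| noise_sd | 0.3 | Gaussian noise on the log2 scale |

Construction, in order: a log-normal baseline profile is drawn for all genes;
disjoint gene blocks are assigned (stromal, immune, culture-up, culture-down,
remainder null, with subtype markers carved from the null block). Component
profiles then apply multiplicative factors: each signature block is elevated
by its effect in its own compartment and attenuated by the same factor in the
other two; each subtype's markers are elevated in its malignant profile.
Tumour fractions are drawn per sample, mixtures formed, log2-scale Gaussian
noise added, and every column renormalised to TPM (sum 10^6). One
`numpy.random.Generator` seeded from the config drives all randomness, so
equal configurations give byte-identical cohorts.

Two compartment-realism choices matter and were fixed a priori:

1. **Signature genes are compartment-restricted.** Stromal/immune signature
   genes are not baseline-expressed in malignant cells (the defining property
   of such signatures — stromal markers are essentially absent from
   carcinoma monocultures). Hence the attenuation of each block outside its
   own compartment. Without it, purity dilution caps the tumour-vs-line fold
   of a stromal gene at 1 + (effect−1)·E[f_str] ≈ 2, the culture genes (fold
   4) dominate the top of the DE ranking, and the analysis' central
   phenomenon — top DE genes being microenvironment transcripts — cannot
   occur at realistic purity.
2. **Compartments spend equal total mRNA.** Signature and marker blocks draw
   their baseline a factor of their own fold change below the global
   log-normal, and each component profile is TPM-normalised before mixing.
   Mixing weights are then true mRNA fractions and purity does not shift the
   relative abundance of unrelated genes. Without this balance the ~20 %
   signature mass at 8-fold specificity makes essentially every gene
   correlate with purity (|r| ≈ 0.4–0.6), and the |r| > 0.2 filter removes
   ~90 % of the transcriptome — including the culture genes it exists to
   reveal.

What the generator does **not** emulate: gene–gene correlation beyond the
block structure, count noise or library-size variation, between-line
heterogeneity of malignant profiles (all lines of a subtype share one `M_s`,
so fidelity differences between lines are noise-driven and the
average-of-lines profile beats the best line only narrowly), claudin-low
biology, and any coupling between expression and genomic alterations.
Passing recovery tests therefore show that the procedures recover this
mixture structure — not that they would behave identically on real cohorts,
where effect sizes are heterogeneous and signatures imperfect.

## Purity scoring

The single-sample enrichment score walks the genes of one sample in
descending abundance (average ranks for ties; ties in walk order broken by
gene id, so scores are permutation-invariant and invariant under strictly
increasing transforms). Signature genes contribute increments proportional
to rank^alpha normalised to sum to 1; background genes contribute 1/(G−m);
the score is the summed difference of the two cumulative distributions. The
exponent defaults to 0.25, the convention of the ESTIMATE family of methods;
it is configurable. Composite = stromal + immune, and the purity proxy is
the negated composite — a monotone proxy, not a calibrated purity fraction
(no copy-number calibration is attempted).

## Statistical choices

- **Welch t per gene** with Satterthwaite degrees of freedom, two-sided p.
  Genes with zero variance in both groups: t = 0, p = 1 when means are
  equal, p = 0 otherwise. Implemented directly (vectorised) and
  cross-checked against closed-form and scipy routes in tests.
- **BH adjustment** via statsmodels; top-fraction selection takes
  ceil(fraction·n) genes ordered by (q, p, −|t|, gene id) — the ceiling
  convention gives 163 genes at 1 % of a 16,282-gene universe.
- **Purity filter**: genes with |stromal r| > tau or |immune r| > tau
  removed, tau = 0.2; undefined (zero-variance) correlations are retained
  and flagged — absence of evidence of a stromal association is not
  evidence of one. The filter runs on the full table before re-selection,
  so the filtered ranking is a subsequence of the unfiltered one. The
  r > 0.5 "highly stromal" threshold is a reporting flag, not a filter.
- **Clustering**: distance 1 − Pearson r over the selected genes; Ward.D2
  (squared-dissimilarity Lance–Williams update) via scipy, verified against
  an exhaustive re-computing oracle; dendrograms exported as Newick with
  branch lengths equal to merge-height differences.
- **PCA**: samples as observations, gene features centred but not scaled
  (keeps PC1's purity interpretation); component signs fixed by making each
  component's largest-magnitude loading positive.
- **Gene-set test**: the per-set statistic is the arithmetic mean of member
  Welch t values; significance is a two-sample Welch test of member versus
  non-member t values, a deliberate simplification of per-pair statistics
  with Stouffer combination — it reproduces the reported mean-t by
  construction. Sets with fewer than 2 or at least 200 present members are
  excluded (strict "fewer than 200"). Essential genes — the members driving
  a call — are defined as individually significant (q < 0.05) members whose
  t sign matches the set direction; the definition is a declared substitute
  where the upstream convention is unspecified, and both thresholds are
  configurable. The reporting significance cutoff is q < 0.0001.
- **Exact tests**: two-sidedness by the minimum-likelihood rule for both the
  binomial and Fisher tests (the default of the common statistical
  environments); the copy-number threshold is a strict inequality at
  |log2 ratio| > 0.2.
- **Ranking**: mean Pearson r of each line against all tumours of its
  comparison subtype over the selected genes, log scale; claudin-low lines
  are compared with basal tumours; ranks are per comparison group with ties
  broken by line id. Subtype separation is summarised as the AUC over each
  line's mean correlation to matched versus mismatched tumour subtypes —
  the quantity the ranking actually uses (a pooled per-pair AUC would mix
  tumour-level purity noise into the statistic).

## Numerical and engineering notes

- Degenerate inputs raise typed errors (all-zero samples, empty gene
  intersections, signatures spanning the universe, zero-variance samples in
  clustering — named in the message).
- Gene matching is exact string identity; duplicate gene ids are rejected
  rather than resolved.
- Scaled-estimate columns must sum to 1 ± 0.01; a strictness flag downgrades
  the violation to a warning for files with rounding drift.
- The pipeline writes deterministic text tables (fixed float format, sorted
  YAML manifest, no timestamps); two runs with the same config+seed are
  byte-identical, and the manifest alone reconstructs the run. Problem sizes
  used by the shipped drivers and the acceptance script (2000-gene reference
  cohort; a 16,282-gene cohort only for the top-1 % count; an 800-gene
  cohort for the determinism check) keep any run in the seconds-to-a-minute
  range on one CPU.

## Known limitations

Cohort-dependent numbers from real data (particular correlation values or
cell-line rankings) require the actual tumour and cell-line cohorts
(TCGA-scale RNA-seq, CCLE genomics) and published signature lists, none of
which are bundled or downloaded; the synthetic recovery results demonstrate
the machinery, not those numbers. The purity
proxy is uncalibrated; ssGSEA normalisation variants (e.g. dividing by the
score range) are not implemented; and the gene-set test's background is all
non-member genes rather than a permutation null.
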