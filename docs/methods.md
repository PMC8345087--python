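# Methods

## Reporter model

A DiR-seq library couples each SNP allele to a fixed sequencing identity:
a 6-nt sub-library tag followed by a 2-nt dinucleotide barcode inside the
transcribed reporter region. The measured quantity is barcode abundance in
cDNA relative to the plasmid input pool. We model the readout per sample
`s` and construct `c` as

    activity_raw(c, s) = cpm_cdna(c, s) / cpm_plasmid(c)
    activity(c, s)     = activity_raw(c, s) / activity_raw(control, s)

with cpm the counts-per-million within a sample. Depth normalization
before the ratio is our choice (ratios of within-sample proportions are
the standard MPRA treatment); it buys exact scale invariance — multiplying
any sample's counts by a constant leaves activities unchanged — and is
recorded in the run report. The insert-free negative control defines the
unit of activity and is pinned at exactly 1.0 in every column, immune to
floating-point round-off in the division chain.

Constructs whose raw plasmid count falls below `min_input_count`
(default 10) are flagged `low_input` and excluded rather than smoothed: a
pseudocount (available as a knob, default 0) would bias fold changes
exactly where the data are weakest.

## The regulatory call

Per SNP and cell line, `fc = mean(risk)/mean(protective)` over replicate
activities on the linear scale, and a two-tailed two-sample t-test on the
same linear activities. The default pools variances (Student); Welch is a
config option and is the default for genotype–expression (eQTL) group
comparisons, where group sizes and variances genuinely differ. The call is

    down  if fc < 0.8 and p < 0.05
    up    if fc > 1.2 and p < 0.05
    none  otherwise.

The fold-change gate makes the rule conservative relative to its nominal
alpha: under the null both conditions must fail jointly, so the empirical
call rate on null simulations sits well below 5%. No multiple-testing
correction is applied across the SNP × cell-line grid; the summary reports
the number of tests so users can apply their own. Zero-variance degenerate
groups are resolved by exact separation (p = 1 if the constant groups are
equal, p = 0 otherwise) instead of propagating a 0/0 t statistic.

## Library design conventions

* Oligos are 55 nt with the allele at 0-based index 27 — a 55-mer has a
  unique central base, so "SNP-centered" forces this choice. Flanks are
  copied verbatim from the genomic context, which must provide at least
  27 nt on each side.
* Identity assignment is deterministic and seed-free: the negative control
  takes the first slot (it anchors the activity scale), then allele
  constructs in sorted (rsid, allele role) order fill each sub-library's
  16 dinucleotide barcodes alphabetically (AA, AC, …, TT) before the next
  tag opens. A 22-SNP library therefore spans ⌈45/16⌉ = 3 sub-libraries
  and is byte-identical across runs.
* The sub-library tag scheme (8 fixed 6-nt tags immediately upstream of
  the barcode) is this package's own convention, chosen so demultiplexing
  is self-contained; vendor vector architectures can be mapped onto it via
  `AnchorConfig`.

## Synthetic data

The generator's defaults encode the study design they emulate: 22 SNPs ×
2 alleles + 1 control mixed equimolar, triplicate cDNA samples per cell
line, and a per-sample depth of 1e5 reads.

* **Plasmid pool** — equimolar with mild lognormal jitter (sigma 0.05 on
  the log scale) for cloning/pipetting variation, then Poisson sampling at
  depth.
* **cDNA counts** — negative binomial with mean ∝ plasmid proportion ×
  activity multiplier × depth and variance m + φm². Reporter replicates
  are overdispersed relative to Poisson; the default φ = 0.002 models
  tight technical triplicates from a single transfection (≈5% extra CV at
  this depth), and φ → 0 recovers Poisson. Biological replicates across
  independent transfections would warrant a larger φ.
* **Reads** — each counted molecule becomes one fully-overlapping mate
  pair: constant upstream anchor + tag + barcode + downstream anchor (the
  reverse complement of the BarP6 RT primer), with independent per-base
  substitution errors; indels and quality-score profiles are out of scope.
  Fully-overlapping mates are realistic here because the true fragment
  (51 nt) is shorter than any Illumina read.
* **Ct tables** — Ct = baseline − log_e(quantity) + N(0, sd) with
  technical triplicates; efficiency e defaults to 2.
* **Traces** — Gaussian peaks of unit amplitude at fixed spacing
  (12 samples/base, sigma 2); at the heterozygous site the two allele
  channels carry amplitudes equal to the allele fractions. Channel noise
  is i.i.d. Gaussian, floored at zero because physical trace intensities
  are nonnegative.

All randomness derives from a single integer seed through named
per-artifact streams (counts, reads per sample, Ct, traces), so each stage
regenerates independently and bit-identically.

What the simulator does **not** emulate — PCR amplification bias and
jackpotting, cross-talk between barcodes during cluster calling,
transfection batch effects, trace mobility shifts and dye blobs — bounds
what green tests mean: they demonstrate the estimators are correct and
well-calibrated under the declared noise model, not that real libraries
are free of these artifacts.

## Read processing

* **Merging** re-implements overlap assembly for this fixed read
  structure: mate 2 is reverse-complemented and aligned to mate 1 at every
  offset with ≥ `min_overlap` (20) overlapping bases; the pair merges at
  the unique best-scoring offset if it has ≤ `max_mismatch` (2)
  substitutions, and a score tie between offsets discards the pair rather
  than guessing. Within the overlap the mate-1 base is kept — the
  simulator emits flat qualities, so there is no signal to arbitrate with.
* **Demultiplexing** finds the upstream anchor at the unique best position
  with ≤ `max_anchor_mismatch` (1) substitutions, then requires the
  following 8 nt to match a (tag, barcode) identity *exactly*: a
  dinucleotide barcode is one substitution away from another valid
  barcode, so tolerating mismatches there would silently reassign reads.
  Assigned + unassigned always equals the merged total.

## Ct arithmetic

All formulas use amplification efficiency e (default 2.0; no standard
curves are fitted, and e is exposed everywhere so calibrated efficiencies
drop in). Technical replicates are averaged on the Ct scale and their SD
propagated in quadrature. The getPCR remaining-allele fraction is
reconstructed as a double delta of the allele-specific amplicon against a
non-allelic reference amplicon between edited and control pools — the
natural normalization for that assay's design, documented here as this
package's reconstruction.

## Under-peak quantification

Allele abundance at a heterozygous call is the trapezoidal integral of the
channel over ± `window_frac` (0.5) of the local inter-peak spacing, after
subtracting a baseline: the channel's 10th-percentile intensity over a 5×
window neighborhood, floored at zero (intensities are nonnegative, so a
negative percentile is a noise artifact, and subtracting it would inflate
both alleles toward 0.5). Area, not height, matches what "under-peak"
denotes; height mode exists as a sensitivity check. Ratios are normalized
over the two designated alleles and sum to 1 exactly; allele-specific
expression is the cDNA/gDNA odds ratio, undefined when the gDNA ratio is
degenerate (0 or 1). Significance calling on trace ratios is deliberately
left to the caller — a single trace carries no replicate structure.

## Problem sizes and determinism

The test suite and acceptance checks run the full library (45 constructs)
at depth 1e5 per sample with triplicates — the design the defaults encode —
plus a 50-SNP × 10-cell-line null grid (500 comparisons) for type-I
control and 200 re-simulated libraries for power; the whole suite completes
in well under a minute. Fixed seeds make every simulated artifact
bit-reproducible; single-trace recovery bands at high noise are asserted
distributionally over seeds, since one draw of a ~2σ band is
uninformative.

## Known limitations

* The bundled 22-SNP manifest names two real variants (rs10514231,
  rs2089222); the remaining rows are synthetic placeholders with the same
  shape, as the full published SNP list is not redistributed here.
* Substitution-only error model; merging is not quality-aware and no
  UMI/duplicate handling exists (the assay design has none).
* The eQTL Welch test treats genotype groups as independent samples; no
  covariate adjustment or ancestry correction is attempted.
* Vendor binary chromatograms must be converted to the columnar text
  format by external tools before use.
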