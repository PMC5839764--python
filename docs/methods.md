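# Methods

## The measurement model

The pipeline's input currency is a per-base count table over captured
regions: at every position, the sequencing depth and the number of calls of
each base. All frequency statistics are *depth-weighted*: the "sequenced
length" of a set of positions is the sum of their depths, so a mutation
frequency is events per sequenced base. This matches what deep sequencing
of a polyclonal germinal-center B-cell population observes — a mutant-allele
*fraction* per site, not per-cell lineages. A clone-style denominator
(clones × length) can be emulated by supplying uniform-depth counts.

Mutation events are read-level: a site with 4 T calls over reference C at
depth 1,000 contributes 4 events and 1,000 to the denominators. Reference-N
positions are excluded from all denominators; positions annotated as
germline SNPs are removed before anything else is computed (an optional
variant-allele-fraction threshold can additionally drop unannotated
near-heterozygous sites, default off — the genotype contrast, not a caller
threshold, is what controls sequencing error).

Three summary frequencies per region: total (all events / all bases), C/G
(events at C or G / bases at C or G), and hotspot C/G (restricted to
cytosines carrying a plus-frame hotspot instance and guanines carrying a
minus-frame instance). A position inside several overlapping hotspot
instances is counted once — the formulas are per-nucleotide, so a base
cannot contribute twice to a denominator.

## Hotspot motifs and the deaminated-C frame

Motifs are IUPAC strings with a designated deaminated cytosine (e.g. WRCY
with the C at offset 2; AGCTNT with the C at offset 2). Scanning reports
plus-strand matches at the C itself, and minus-strand matches by scanning
the reverse-complemented pattern on the plus strand and reporting the G
paired with the deaminated minus-strand C. Overlapping and nested matches
are all reported. An `N` in a sequence is an unknown base: it matches only
the motif letter `N`. All context analysis (logo matrices, per-position
enrichment) reverse-complements minus-frame windows so the mutated cytosine
is always central and read 5'→3'.

The context window is 5 bases per side (positions −5..+5). The literature
phrase "a window of 10 nucleotides" is ambiguous between total width and
per-side width; we read it as 10 flanking nucleotides (5 per side), which is
also what the window must span to cover the +3 position with margin. The
width is a parameter.

## Statistics

* **Target calling.** Per region, the number of C>T-at-C plus G>A-at-G
  events (m) and the depth-weighted C/G length (n) are compared between the
  repair-deficient case and the AID-null control with the one-tailed Fisher
  exact test (upper hypergeometric tail, computed via
  `scipy.stats.hypergeom`), then Benjamini–Hochberg adjusted across regions
  (via `statsmodels`); targets are q ≤ 0.05. Events could alternatively be
  counted as distinct mutated positions; read-level events use all the
  information deep coverage provides and are the default.
* **Context enrichment.** For each non-center window position and base, a
  one-tailed Fisher test of foreground (mutated-C contexts, adjusted
  frequency ≥ 4×10⁻³) against the context of *all* cytosines in the
  analyzed regions, Bonferroni-corrected over the 4 × 2w tests, called at
  adjusted p ≤ 10⁻³.
* **Motif mutability.** Every strand-resolved instance of a motif
  contributes its site's control-subtracted transition frequency (zero if
  unmutated); motifs are ranked by the unweighted per-site mean. Two-tailed
  Mann–Whitney compares motif site-frequency vectors: exact by full
  enumeration of label reassignments (midranks, so ties are handled) for
  combined n ≤ 12, tie-corrected normal approximation with continuity
  correction otherwise.
* **Genotype contrasts.** The AID-null frequency is subtracted per region
  (floored at zero) before comparison; replicate means form the genotype ×
  region matrix, and pairs of genotypes are compared per region with a
  two-tailed Student t test on replicate values. Pooled variance is used
  deliberately: with two replicates per genotype, Welch's correction leaves
  ~1 degree of freedom and no power.

## The synthetic-data generator

The generator emulates the observables of a targeted capture experiment,
and defines the conditions under which every pipeline property is tested.

* Regions: random uniform-GC sequences (default 200 regions × 500 bp,
  GC 0.5, mirroring TSS-proximal capture windows). A fraction (default 5%)
  are genuine AID targets; the rest get no deamination in any genotype.
* Deamination: at each C (or G, minus frame) the expected mutant-allele
  fraction is `d0 ×` the largest motif multiplier covering the site in the
  matching frame. Defaults: `d0 = 2×10⁻⁴`, WRCY ×10, AGCTNT ×25 — giving
  the hotspot ordering AGCTNT > WRCY > background. `hotspot_only` restricts
  deamination to listed-motif sites (used for the AGCTNT-signature
  experiments).
* Genotypes: an escape fraction (share of deaminations not faithfully
  repaired) times a substitution spectrum at the deaminated C, plus a
  collateral A/T-phase mass spread uniformly over A/T sites. Defaults:
  AID-null 0; double knockout 1.0 with a pure C>T spectrum (unprocessed U:G
  replicates into transitions) and no A/T phase (MSH2 absent); single
  knockouts 0.10; double heterozygote 0.04. Escape fractions are
  qualitative calibrations — no quantitative values exist to copy — chosen
  to produce the observed ordering: one intact pathway repairs most
  lesions, the double knockout exposes everything. Spectra follow the known
  division of labour (UNG loss → transitions dominate; UNG active on an
  MSH2-null background → more abasic-site transversions; MSH2 drives the
  A/T phase).
* Counts: depth ~ Poisson(500 by default); base calls multinomial with
  probabilities = truth fractions + `error_rate/3` per non-reference base
  (+0.5 toward the alternate allele at heterozygous SNP positions, planted
  at 10⁻³/bp). The default substitution error of 10⁻⁴/base represents
  quality-filtered targeted deep sequencing; raw Illumina error is ~10×
  higher, but mutation pipelines operate on quality-trimmed calls.
* Features: gene-level continuous features are lognormal around a shared
  latent "activity" (coupling 0.5, unit log-noise), binary marks are
  Bernoulli with activity-linked probabilities, and the target label is
  logistic: baseline logit −3 plus +4.2 when both PolII and Spt5 densities
  exceed their 75th percentiles — so the high-PolII∧Spt5 stratum is a
  target with probability logistic(1.2) ≈ 0.77.
* Randomness: a single seed feeds per-region/per-genotype child streams
  (numpy `SeedSequence` keys), so any genotype subset reproduces bit-for-bit
  and replicates (independent cohorts) redraw counts over identical
  regions, SNPs and truth.

What the generator does **not** model: read-level artifacts (PCR
duplicates, strand bias, quality decay), capture-efficiency variation,
clonal lineage structure, positional A/T-phase preference (spread uniformly
for want of a positional model), indels, and correlated features beyond one
latent axis. Passing tests therefore demonstrate that the statistics
recover what their models assume — planted motif concentration, genotype
ordering, a feature interaction — not that they are robust to every
artifact of real libraries.

## The conditional-inference tree

At each node, every covariate is tested for association with the class
label: continuous covariates by the two-sample Wilcoxon rank-sum test
(asymptotic, tie-corrected; Kruskal–Wallis for ≥3 classes), binary
covariates by the exact two-sided Fisher test (chi-square for ≥3 classes —
exactness matters in small nodes). P-values are Bonferroni-adjusted across
covariates; the node becomes a leaf if the best adjusted p exceeds
`alpha = 0.05` (the conventional 0.95 criterion) or fewer than
`minsplit = 20` samples remain. Continuous splits go at the candidate
midpoint (between consecutive distinct values) maximizing the chi-square
statistic of the left/right × class table — for two classes this is the
squared standardized two-sample statistic, so the argmax is the classical
standardized cutpoint; binary covariates split by level. Both children must
hold at least `minbucket = 7` samples; when no candidate qualifies the node
stays a leaf. Prediction routes rows to a leaf and reports the leaf's class
proportions; ties break toward the globally more frequent class. There is
no missing-value handling and no surrogate splits; fitting is fully
deterministic.

This is a rank-based approximation of the conditional-inference framework
(asymptotic rather than permutation p-values, Bonferroni rather than
min-p-resampling). Bit-exact agreement with other implementations is a
non-goal; the properties that matter — type-I control of the any-split rate
under independence, recovery of planted effects, leaf proportions matching
generative rates — are what the test suite measures.

The default response is the binary target/nontarget label from the calling
step (genes aggregate by "any region significant"); a three-tier mode
(highly mutated = top 20% of target C>T frequencies above 3×10⁻⁴, mutated,
nonmutated) is available since outcome codings differ between analyses.
The top-20% cut takes the ceiling of 0.2 × the target count, ranked by
frequency descending. Genes with AID-null background frequency strictly
above 5×10⁻⁴ are excluded before fitting as likely artifacts.

The convergent-transcription flag merges plus- and minus-strand transcribed
intervals per chromosome, intersects them, and flags a gene when some
contiguous overlap stretch within the gene body is strictly longer than
100 bp.

## Problem sizes in the acceptance script

`scripts/acceptance.py` recomputes everything at sizes chosen to keep a
full from-scratch run near half a minute on one core while leaving the
measured rates stable: 40 planted-target and 60 null calling experiments
(200 regions × 500 bp, depth 500 each), 25 AGCTNT-ranking seeds (40 regions
each) plus one 100-region run for the enrichment and Mann–Whitney
statistics, one 60-region genotype panel, 100 null tables and 50 planted
tables for the tree, and one 5,000-gene table for the leaf-purity readout.
The pytest acceptance suite runs the same analyses at larger seed counts
(100 planted / 200 null calling seeds, 50 ranking seeds).

## Numerical notes and edge cases

* Fisher p-values are hypergeometric survival functions; the test suite
  pins them to integer-exact tail enumeration for every table with total
  exposure ≤ 60 (|Δ| < 10⁻¹⁰).
* Zero-denominator frequencies are reported as 0 and flagged on the
  summary rather than raising.
* `subtract_control` keeps case sites missing from the control (control
  treated as 0, warning logged); sites only in the control are dropped.
* Context windows truncated by a region edge are dropped and logged, not
  padded.
* Motifs with zero instances report an undefined (NaN) mean and are ranked
  last, flagged.
* Identical replicate vectors in genotype contrasts short-circuit to
  p = 1 (the t statistic is 0/0 there).
* BED name columns carry region ids (column 4) and, optionally, gene names
  (column 6); SNP masks are accepted as BED or VCF (positions only).
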