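# Methods

## Biological model

A CpG dinucleotide carries a cytosine on each strand, and the two can be
methylated asymmetrically (hemimethylation). The region modeled here —
the *APC* promoter and first exon, a CpG island with 30 numbered sites —
shows, in adult human liver, a benign methylation background confined to
the **antisense** strand, while HCC-associated hypermethylation is dense
on **both** strands. Non-liver tissue, fetal liver and mouse liver carry
no methylation on either strand. Everything downstream follows from this
structure: an antisense-reading assay detects normal liver and loses
specificity; a sense-reading assay stays tumor-specific.

Coordinates are 1-based inclusive throughout, and CpG sites are always
indexed by their sense-strand 5′→3′ order, on both strands. Antisense
conversion is modeled as conversion of the reverse complement, with
calls re-indexed to sense-strand site numbers, keeping a single
canonical site map. N bases are excluded from CpG enumeration and pass
through conversion unchanged.

## Bisulfite conversion and read truncation

Conversion deaminates every unmethylated C to U (read T) and leaves 5mC
intact, independently on each strand. Molecule-level conversion requires
binary flags; population mixtures are handled by the simulator. After
conversion, long poly-T homopolymers defeat Sanger chemistry: every site
read after the start of a T-run of ≥16 bp is flagged unreadable. The
sequencing read is taken to traverse the region in ascending
sense-coordinate order for both strands (this reproduces the observed
truncation of the antisense read after site 20, which fixes the default
analyzed window at sites 1–20). The 575-bp analysis window itself is a
configuration parameter, not hard-coded.

## The chromatogram reference index

Classification of a CpG from a direct-sequencing trace uses only
peak-comparison rules: a channel is *detected* when its height exceeds
the noise floor (default: 5% of the taller channel, with an optional
absolute floor — sequencer detection limits are not published, so this
is an explicit, configurable choice); then

| call | rule | calibrated band |
|---|---|---|
| T only | C undetected | 0% methylated |
| C ≤ T | both detected, C ≤ T (ties here) | <10% |
| C > T | both detected, C > T | ~10–25% |
| C only | T undetected | ≥25% |

The bands are calibration metadata, not part of the rule. They were
established against reconstituted standards, and they imply the
chromatogram response is strongly **biased toward the C signal**: a 25%
methylated mixture already reads "C only". Bisulfite PCR preferentially
amplifies methylated (unconverted, GC-richer) templates and the
sequencer normalizes peak heights, so the observed C-share is not the
molar fraction. The simulator models this with the transfer

    f' = b·f / (b·f + 1 − f),    b = 70 by default,

mapping molecule fraction f to C-signal share f'. b = 70 was fixed once
so that the five standards {0, 10, 25, 50, 100}% reproduce the index
categories {T only, C>T, C only, C only, C only}: f'(0.10) = 0.886
(both peaks visible, C taller) and f'(0.25) = 0.959 (T below the 5%
relative floor). A linear signal (f' = f) cannot reproduce that
calibration under the peak-comparison rules — at f = 0.25 it would give
C < T — so the bias transfer is part of the measurement model, not a
tuning knob.

**Conversion QC.** The fraction of non-CpG cytosines reading fully as T
estimates conversion efficiency; samples at ≤0.95 are dropped (strict
">95%" gate), not corrected, since incomplete conversion mimics
methylation. In the population signal model a residual failure rate of
5% puts a C peak right at the detection floor at *every* non-CpG
position, so the gate rejects such samples almost surely; the default
simulated failure rate (0.5%) reflects modern conversion kits and
passes the gate.

## Clone analysis

Each clone derives from one molecule, so entries are binary; missing
calls are excluded from numerator and denominator (the per-sample call
is absent, not 0, if all clones miss a site). The group contrast pools
methylated/unmethylated site-calls over clones and samples into one 2×2
Pearson χ² (no per-site testing), matching how cloning data are
summarized. Clone counts are drawn uniformly on [7, 19].

## Quantitative MSP

The standard curve Cq = b + m·log₁₀(copies) is fitted by ordinary least
squares to a 10-fold dilution series (≥3 points); the amplification
efficiency is E = 10^(−1/m) (E = 2 ⇒ m = −3.32 cycles per decade).
Quantification inverts the curve; copies below the 6-copy limit of
detection are censored to 0 (a relative tolerance of 1e−9 at the LOD
comparison absorbs round-trip floating-point error of the log/power
inversion). Cq values beyond the calibrated range warn but are
extrapolated, since near-LOD samples sit below the lowest standard by
design. Input is normalized to 150 copies via the BS-actin estimate
(methylation-independent total converted DNA); the mass↔copies
conversion assumes 6 pg per cell, 2 genome copies per cell by default
(configurable, since "copies" per haploid or diploid genome is
ambiguous). Duplicates are averaged arithmetically, with not-detected
replicates contributing 0; the sample is called *detected* when **either**
replicate reaches the LOD ("any detectable methylation" read as
either-replicate; configurable).

## Biomarker evaluation

* BSP positivity: methylation detected (any non-T-only call, i.e., any
  visible C; configurable) in ≥50% of readable sites. Samples with no
  readable site are excluded.
* MSP positivity: the detected flag (cutoff at the LOD).
* Specificity pools adjacent non-HCC, normal, hepatitis and cirrhosis.
* ROC: empirical curve over all thresholds, ties as simultaneous steps,
  AUROC by trapezoid — exactly the Mann–Whitney all-pairs statistic.
  Constant markers yield 0.5 with a warning.
* Paired ROC comparison: DeLong's method (structural components from
  midranks; two-sided normal p). Implemented here directly since no
  dependency provides it; degenerate zero-variance comparisons of a
  marker with itself return p = 1.
* Combined marker: AFP positivity at ≥20 ng/mL (inclusive), quadrant
  counts and the derived percentages on the 0–100 scale.
* Group tests: Kruskal–Wallis of sense-MSP values across stage (1 vs 2–4
  pooled), grade (1 vs 2–3 pooled), HBV, HCV and AFP group; Spearman of
  mAPC vs AFP; Student t (age) and Fisher exact (sex) for HCC vs
  non-HCC. Degenerate groups skip the test with a warning. No
  multiple-testing correction is applied, and χ² is uncorrected Pearson
  (no Yates continuity correction).

## Synthetic-data generator

Defaults are the study conditions; all randomness flows from one seed
through named `SeedSequence` children spawned in a fixed order (region,
samples, traces, clones, msp, dilutions), so a config+seed pair is
bit-reproducible.

* **Cohort sizes**: HCC 58, adjacent 58, cirrhosis 41, hepatitis 39,
  normal 6 (the MSP study population). The shipped example fixture is a
  24-sample scaled-down cohort so it stays a small text file.
* **Biology** (sample-level methylated-molecule fraction per strand;
  per-site profiles default to uniform): HCC sense = 70% prevalence ×
  U(0.10, 0.60), HCC antisense = 72% × U(0.10, 0.70); all non-HCC adult
  liver carries the antisense background 85% × U(0, 0.12); adjacent
  tissue adds a sense field effect 30% × U(0.02, 0.10); cirrhosis is a
  mixture of antisense-biased (35%), unmethylated (45%) and symmetric
  (20%, both strands U(0.05, 0.30)) subtypes, mirroring the observed
  heterogeneity of cirrhotic tissue; non-liver, fetal and mouse liver
  are clean negative controls. Background magnitudes were chosen once
  as order-of-magnitude realistic: U(0, 0.12) of 150 input copies spans
  0–18 methylated copies, straddling the 6-copy LOD, which is what makes
  antisense specificity collapse under an end-point cutoff while both
  strands keep similar AUROCs.
* **Traces**: heights on a unit scale, truncated-Gaussian noise
  (sd 0.02), conversion failure 0.005, signal bias b = 70.
* **qPCR**: efficiency 2.0 (slope −3.32), single-copy intercept 38
  cycles, Cq noise sd 0.15, Poisson sampling of template molecules
  (0 templates ⇒ not detected), LOD 6 copies, true input per sample
  U(120, 180) copies measured by the BS-actin assay.
* **AFP**: log-normal; HCC μ = ln 14, σ = 1.8 (≈42% exceed the 20 ng/mL
  cutoff), non-HCC μ = ln 3, σ = 1.2.
* **Truth records** store each sample's strand fractions and the implied
  BSP/MSP positivity, enabling exact recovery tests at zero noise.

What the generator does **not** emulate: sequence-dependent PCR bias,
bisulfite degradation, primer/probe thermodynamics, chromatogram shape
(only peak heights), within-region density gradients (available via
per-site profiles but off by default), and correlated demographics
(e.g., matched adjacent pairs are drawn independently). Passing tests
therefore show internal consistency of the pipeline under the assumed
statistical structure, not fidelity to any particular real dataset.

## Published-count worked examples

Per-sample calls behind the published summary tallies were only shown
graphically, so `strandmeth.reference_data` expands the printed counts
(C-only calls, readable totals, missing counts; combined-marker
quadrants) into count-exact synthetic call vectors and records. Only
quantities that depend on those counts — C-only percentages, the 2×2 χ²
contrast, quadrant percentages — are meaningful on this fixture; the
split of the unpublished remainder across the other categories is an
arbitrary deterministic fill. The per-sample operating characteristics
of the original cohort (MSP specificity 84%/43% etc.) are consequently
not desk-reproducible; the test suite instead verifies the qualitative
recovery — sense specificity dominating antisense with high antisense
detection of the liver background — across 50 seeded replicate cohorts,
plus exact numerical identities (AUROC vs all-pairs statistic, χ² vs the
direct formula, standard-curve round trip) against independent oracles.

## Numerical and design notes

* Tie C = T classifies as C ≤ T; both channels undetected is a missing
  call, written "x" in TSVs.
* χ² with identical pooled proportions returns exactly (0, 1) rather
  than relying on floating-point cancellation.
* The AFP table header ambiguity (">20" vs "≥20") is resolved in favor
  of the ≥20 ng/mL definition; the cutoff is configurable.
* Problem sizes in tests (replicate counts, clone counts, cohort sizes)
  are chosen so the full suite runs in seconds while keeping binomial /
  simulation bounds conservative (e.g., Bonferroni-corrected 99%
  family-wise CIs across jointly tested sites).
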