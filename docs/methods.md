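# Methods

## Cluster geometry and the genotype caller

KASP allelic discrimination is read out as one endpoint RFU pair per
well. The instrument's viewer presents these as a scatter plot and the
genotype is inferred visually from clustering with controls; this
package formalizes that judgement so it is reproducible and flaggable.

After per-channel NTC baseline subtraction (x = max(rfu_wt − m̄_wt, 0),
y = max(rfu_mut − m̄_mut, 0)), each well is reduced to

* magnitude m = x + y — how much template amplified, and
* angle θ = atan2(y, x) in degrees — which alleles amplified.

The two coordinates carry orthogonal information: NHEJ alleles remove
template from *both* allele-specific primers (magnitude), while the
allelic composition of whatever does amplify moves only the angle.
Design choices, in the order the caller applies them:

* **Amplification threshold.** m ≤ mean + k·sd of the NTC magnitudes,
  default k = 5, computed on baseline-subtracted NTC magnitudes *before*
  clamping at zero (clamping halves the apparent NTC noise and would
  bias the band low). Wells below it are NO_AMP. The instrument gives no
  threshold; k = 5 keeps the false-amplification rate of true NTC wells
  below 10⁻³ with ≥ 12 NTC anchor wells under the default noise model.
* **Control anchoring.** Per genotype class, centroid = mean control
  angle, dispersion = sample sd floored at 0.75°, magnitude scale =
  median control magnitude. Centroid ordering WT/WT < WT/Mut < Mut/Mut
  is enforced; a violation means mislabelled controls. The floor exists
  because tight or noise-free control sets would otherwise make every
  clone unclassifiable; 0.75° places the confident boundary
  (z_max · floor = 2.25° at z_max = 3) *below* the 3.01° angle of the
  smallest designed mixed-population signal — one heterozygous cell in a
  ten-cell well, a 5 % mutant-allele fraction — while wells with no
  mutant allele (angle ≈ 0.3° ± 0.5° at default noise) stay inside the
  confident band with ~10⁻⁵ escape probability. A larger floor (e.g.
  1.5°) silently swallows the 5 % mixed-population signal into WT/WT,
  defeating multi-cell screening.
* **Classification.** Nearest centroid by z = |θ − centroid| / sd;
  confident if z ≤ z_max (default 3). Ties break toward the lower-mutant
  class — the conservative direction, fewer false HDR positives.
  Unconfident wells strictly between adjacent centroids are
  INTERMEDIATE (mixed population); off-axis wells are AMBIGUOUS, never
  INTERMEDIATE, because an angle beyond the homozygous centroids cannot
  arise from any mixture of the three genotypes.
* **Half-signal flag.** A confident call with m < 0.6 × class median
  magnitude. A compound edited/NHEJ clone presents the correct angle at
  roughly half magnitude; 0.6 splits 0.5 from 1.0 with margin for the
  default multiplicative magnitude noise (cv 0.08).

`detect_intermediate_wells` orders INTERMEDIATE wells by standardized
angular distance to the heterozygous centroid, most HDR-like first —
the screening priority for picking multi-cell wells to subclone.

## ChIPnQASO quantitation

The assay description fixes only that input DNA is "set to 50 %"; the
unique linear correction with that property is per-channel division by
the input means followed by renormalization:
frac_mut = (y/f_mut) / (y/f_mut + x/f_wt). It is scale-invariant and
cancels any channel-efficiency asymmetry applied identically to input
and IP wells (verified exactly for efficiency ratios 0.25–4). Multiple
input wells are pooled by per-channel means before the division, so the
*pooled* input maps to exactly 0.5; the mean of per-well input
fractions equals 0.5 exactly only for a single input well or noise-free
data, and within sampling error otherwise. IgG wells are never used for
normalization; they are reported descriptively and flagged
``low_signal`` when below the amplification threshold. No significance
test is attached to preference ratios — replicate means ± sd are the
deliverable, testing is the caller's choice.

## Titration LOD

Each nonzero level's replicate mutant-allele fractions are compared to
the 0 % replicates with a two-sided pooled-variance Student's t-test
(Welch available behind a flag); LOD = smallest level with p < α,
default α = 0.001, no multiple-testing correction (the single stringent
α plays that role). The test statistic is computed on derived allelic
fractions, which are scale-free and comparable across plates, not raw
RFU. A 10⁻¹² variance floor makes noise-free fixtures significant
rather than undefined; two degenerate groups with equal means report
p = 1. The statistic matches `scipy.stats.ttest_ind` to 10⁻¹² away from
the floor.

## Noise model of the simulators

No instrument noise figures are published for this assay family; the
generator's defaults are calibration choices, stated as such:

| parameter | default | meaning |
|---|---|---|
| gain | 2000 RFU | magnitude of a fully amplified well |
| fraction_noise_sd | 0.008 | additive noise on the measured mutant fraction |
| background_fraction | 0.005 | spurious mutant signal at 0 % mutant |
| magnitude_cv | 0.08 | multiplicative magnitude noise |
| ntc_mean / ntc_sd | 60 / 12 RFU | per-channel no-template baseline |
| channel_efficiency | 1.0 | FAM/HEX gain asymmetry |

Noise is placed on the measured allele *fraction* plus a multiplicative
magnitude term (cluster plots show angular tightness with magnitude
spread), rather than additive-only per-channel noise.
`fraction_noise_sd` and `background_fraction` are calibrated so the
nine-level, four-replicate titration detects 5 % but not 2.5 % at
p < 0.001: the 5 % level sits ≈ 0.050 above control against a detection
margin t₀.₉₉₉₅,₆ · σ · √(2/4) ≈ 0.034–0.042, while 2.5 % (≈ 0.025)
falls short. NHEJ alleles are completely non-amplifiable; partial
primer tolerance is not modelled. Simulated panels carry 4 genotype
controls per class and 12 NTC wells (a realistic anchor block for a
384-well run); titration panels add 4 input wells at a true 50 %.

**Stability caveat.** That margin calculation treats σ as known. With
n = 4 per group the t statistic has only 6 degrees of freedom, so the
*realized* LOD of a single simulated series is a random draw: across
seeds, ~65 % of series give LOD = 5 %, ~20–25 % give 2.5 % (the sample
sd underestimates σ often enough to push the 2.5 % level past the
stringent α), ~10 % give 10 %. The acceptance script therefore reports
the modal LOD over a 100-series ensemble alongside the pinned
calibration seed; a single-seed LOD should not be over-read, for
simulated or real plates.

What the generators deliberately do not emulate: PCR saturation and
competition kinetics, plate-position effects, cross-contamination,
partial NHEJ primer tolerance, mosaicism arising after plating, and
base-quality structure in reads. Passing tests show the *analysis* is
correct under the stated noise model, not that real instruments obey it.

## Amplicon-read classifier

A deliberately minimal re-implementation of indel scoring (the
full-featured external tools do much more):

1. trim 20 bp from each read end; an exact substring match of the core
   to the expected HDR amplicon (either orientation) → HDR. Exact-match
   precedence means a read can never be both HDR and NHEJ.
2. an exact substring match to the reference → WT (fast path; implies
   full identity, no indel).
3. otherwise global alignment to the reference (match +1, mismatch −1,
   gap open −2, gap extend −0.5 — fixed, configurable, not fitted);
   an insertion or deletion overlapping cut_site ± 10 bp → NHEJ; else
   ≥ 98 % identity → WT; else UNCLASSIFIED. Reads shorter than
   2·trim + 1 are UNCLASSIFIED, flagged ``short``. End gaps are read-
   length artefacts of merging and are not scored as indels.

The cut-site offset comes from assay configuration, not from PAM
arithmetic. On simulated read sets (10 000 reads, indels 1–10 bp,
deletion:insertion 3:1, half the reads reverse-complemented) the
classifier reproduces the generating HDR/NHEJ/WT frequencies within
3 binomial sds and agrees with per-read truth labels exactly.

## Display arithmetic

Genotype percentages and allelic efficiency are rounded half-up to one
decimal for display (the convention of published screen tables);
unrounded values are retained on the same objects. Allelic efficiency
counts one edited allele per heterozygote and ploidy per homozygote
over all screened alleles: 4 + 2·2 of 96 → 8.3 %, 3 + 4·2 of 114 →
9.6 %.

## Problem sizes

Stochastic tests use 200–5000 simulated wells or clones per property,
200-seed ensembles for recovery rates, and 10 000-read sets for
classifier frequencies — sizes at which binomial 3-sd bands are tight
enough to detect real defects while the full suite stays fast.
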