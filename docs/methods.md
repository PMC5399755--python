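# Methods

`osmodrop` quantifies the behavioral and imaging readouts of the
*C. elegans* droplet swimming assay used to study aversive responses to
osmotic upshifts.  This note documents the models behind each stage,
the parameters that matter, and what the synthetic-data generator does
and does not emulate.

## The droplet assay and its readouts

An adult worm swims in a 6 µl droplet while a camera records it at
10 Hz.  Swimming consists of continuous rhythmic body thrashes,
occasionally interrupted by *turns* — reversals and large Ω-shaped body
bends, pooled into one event class because both are reorienting
maneuvers.  The assay's primary statistic is the number of turns per
minute, and in particular the rate in the 5th minute of exposure
([240, 300) s), by which time the response to a hyperosmotic solution
has reached its plateau.

### Equivalent-ellipse eccentricity

Each frame is segmented (Otsu threshold by default; the largest
8-connected component is kept and holes are filled, since a
self-overlapping Ω posture can enclose background).  From the binary
silhouette the normalized second central moment matrix
C = [[μ20, μ11], [μ11, μ02]]/μ00 is computed over (row, col) pixel
centers; with eigenvalues λ1 ≥ λ2 the equivalent ellipse has semi-axes
a = 2√λ1, b = 2√λ2 and eccentricity e = √(1 − λ2/λ1).  Under this
convention a solid disk has e = 0 and a thin rod e → 1.  A swimming
(elongated, S-shaped) worm sits near e ≈ 0.95–0.98; curled turning
postures collapse e below ≈ 0.7.  Whether moments should be binary or
grayscale-weighted is not fixed by the assay; binary is the default and
intensity weighting is available via the `weights` argument.

### Turn calling

A turn is called where e stays below a threshold:

| parameter | default | meaning |
|---|---|---|
| `threshold` | 0.85 | eccentricity cutoff |
| `min_duration_s` | 0.2 s (2 frames at 10 Hz) | shortest credible event |
| `merge_gap_s` | 0.3 s | events closer than this are fused |

The threshold is an empirical constant: `calibrate_threshold` scans a
grid (step 0.01 over [0.50, 0.99]) and maximizes event-level F1 against
annotated turns, with one-to-one interval matching (so one over-merged
mega-event cannot claim every annotation) and ties broken toward the
higher threshold.  Calibrated on the generator's default appearance the
procedure returns ≈ 0.96; 0.85 is kept as the shipped default because it
sits in the middle of the wide F1 = 1 plateau and is robust to noisier
real footage.  Flagged (lost-worm) frames are treated as missing: they
neither join nor break sub-threshold runs.  Maximal sub-threshold runs
of at least `min_duration_s` become events, then events separated by
less than `merge_gap_s` are merged, in that order — that operational
order means a stricter duration cutoff is only guaranteed monotone in
event count when merging is disabled.  Events are assigned to half-open
minute bins [60(m−1), 60m) by start time.

### Thrash counting

The bend signal is the signed angle between the major axes of the
anterior and posterior half-silhouettes (split at the centroid along the
whole-body axis, with the axis direction kept continuous across frames).
One thrash is one curving of the body toward either side, counted by a
Schmitt trigger with hysteresis 0.2 rad: each entry into the
+hysteresis or −hysteresis band from the opposite (or unknown) state
counts once, i.e. two counts per undulation cycle.  Note that a
perfectly point-symmetric S posture has bend exactly 0 (the two halves
share an axial orientation); the signal oscillates because the traveling
body wave passes through mirror-symmetric (C-like) phases.

## The synthetic generator

The generator is the test bed for every stage.  A worm is a
constant-arclength midline with curvature
κ(s, t) = (A/L)·sin(2πf·t − 2πs/L), one wavelength along the body,
dilated to a half-width and rasterized (a pixel is foreground when its
center is within the half-width of the midline; distances are exact via
a KD-tree over a densely resampled midline).  Defaults: 96×96 px crop
of a single droplet, body length 56 px, half-width 2.5 px, undulation
1 Hz, dimensionless curvature amplitude A = 4 (swim eccentricity then
stays ≥ 0.95, matching the elongated look of real swimmers), worm at
gray level 200 on background 20 with additive Gaussian noise (SD 5).
Appearance constants are not measured from real footage; they are
chosen for segmentability and are config-exposed.

During a turn the swim curvature is cross-faded (trapezoidal ramp, 20%
of the event each side) into either a uniform arc of 5.2 rad ≈ 300°
(`omega`) or a deep focal mid-body fold of 5.8 rad (`reversal-bend`);
both depress eccentricity below ≈ 0.7 at event center.  Body shrinkage
from dehydration is modeled by scaling linear dimensions with
√`area_scale`, so silhouette area scales exactly with `area_scale`.

### The turn point process

Turn onsets are sampled by Ogata thinning from a *refractory,
rate-compensated* renewal process: each episode occupies
`turn_duration_s` (default 0.8 s) plus a refractory gap (0.6 s), and
the post-refractory waiting time is exponential with intensity
μ(t) = λ(t)/(1 − λ(t)·D), D the total dead time.  This compensation
makes the long-run episode rate equal λ(t) exactly, so `turn_rate_fn`
(turns/min) is directly the rate a downstream counter should recover —
a naive Poisson draw with overlap-merging would systematically
undercount by ≈ exp(−λ·D).  The construction requires λmax·D < 1,
which is also the physical feasibility bound ("a turn must be shorter
than the mean inter-turn gap"); parameter sets violating it are
rejected.  The refractory gap additionally guarantees that generated
inter-event gaps exceed the detector's `merge_gap_s`, so merging never
fuses two distinct true events.  The ramp profile
λ(t) = λ0 + (λend − λ0)·min(t/240, 1) plateaus at 240 s by default, so
the expected 5th-minute rate equals λend — the convention under which a
cohort's generating parameter is its minute-5 ground truth.

### What the generator does not emulate

No hydrodynamics, no photorealism, no multi-worm occlusion, no
head/tail asymmetry, no camera vignetting or focus drift, and the
worm is re-centered every frame (translation within the droplet is not
modeled; eccentricity is translation-invariant so turn calling is
unaffected).  Passing recovery tests therefore demonstrates that the
*computations* are correct and unbiased under the assay's nominal
conditions, not that segmentation is robust to every artifact of real
footage.

## Dehydration measurement

Pre/post image pairs are generated at 256×256 px with a 150 px worm
(half-width 6 px) in varying gentle crawling postures; the post image
scales linear dimensions by √(area ratio).  Measurement is the same
segmentation plus pixel counting used elsewhere; at this size the
rasterized area ratio is accurate to well under 1%.  The study-design
condition replicated in the acceptance run is 7 worms × 3 image pairs
per osmolarity, at shrinkage ratios 97.5% (200 mOsm) and 77.6%
(400 mOsm).  Blinded manual measurement is supported by
`blind_rename`, a seeded permutation to condition-free names with a
sealed JSON mapping for later unblinding.

## Osmolarity arithmetic

Osmolarity is additive over solutes: Σ concentration (mM) × particles
per formula unit (NaCl fully ionized → 2; glycerol, sorbitol → 1).
Solute–solute interactions are ignored; the bundled osmometer
validation table shows the worst deviation of measurement from
calculation is 7.75% (all-NaCl 400 mOsm), within the 10% reconciliation
tolerance.

## Calcium ΔF/F

For a single-ROI trace, F_base is the mean corrected fluorescence over
the first 60 s and ΔF/F(t) = (F − F_base)/F_base × 100% over the first
120 s; the per-animal response summary is the mean ΔF/F over
[60, 120) s, i.e. after the solution switch at 60 s.

Photobleaching is corrected by fitting F̂(t) = a·e^(−bt) + c (b ≥ 0)
and dividing: corrected = F/F̂ × F̂(0).  The correction is ratiometric
because ΔF/F is a ratio statistic — dividing preserves fractional
responses exactly, whereas subtraction would distort them as the
baseline decays.  The fit uses only the 60 s baseline window by
default, extrapolating over the response period: fitting the whole
trace lets a sustained response leak into the decay estimate (on a
simulated 20% step the whole-trace fit recovers well under 15% while
the baseline fit recovers 20.0%, as the test suite demonstrates);
`fit_window="full"` reproduces the whole-trace behaviour when wanted.
A non-convergent fit falls back to a linear detrend with a warning.
The imaging sample rate is not dictated by the hardware model; 10 Hz is
the configurable default.

Normality is checked with both Kolmogorov–Smirnov (against a normal
with the sample's own mean/SD, so approximate in the Lilliefors sense)
and Shapiro–Wilk; group comparisons use Student's t.

## Group statistics

Per-cell summaries are mean ± SEM (n), SEM = SD/√n (ddof = 1), with
single-observation cells reporting SEM as missing.  Two-group
comparisons default to the pooled-variance Student's t (the form named
in the assay's reporting; Welch via a flag), accepting either raw
per-animal rates or printed summary statistics — the two are exactly
equivalent.  The genotype × osmolarity analysis is a two-way
fixed-effects ANOVA with interaction, using Type II sums of squares
because cell sizes are routinely unbalanced; on balanced designs Type
II equals Type I (verified numerically).  Missing design cells are an
error, not an imputation target.  No multiple-testing correction is
applied across candidate-gene screens, mirroring the original analysis
style; Benjamini–Hochberg can be layered on by the caller.

## Problem sizes used in validation

Scales were chosen to exercise the statistics at realistic power:
Poisson/rate-recovery properties use 100–300 independent seeds of the
event sampler at 300 s; full-render recovery uses cohorts of 32
five-minute videos at 96×96 px (the reduced single-droplet crop);
type-I-error calibrations use 1000 null replicates at n = 16 per cell;
the calcium power check uses 100 replicate two-cohort experiments at
n = 15 vs 13.  All are seeded and reproducible.

## Known limitations

* The refractory, rate-compensated turn process is *underdispersed*
  relative to a Poisson process at high rates (per-animal minute-5
  count SD ≈ 1.4 at 33 turns/min, vs √33 ≈ 5.7 for Poisson): dead time
  regularizes the event train.  Real cohorts are, if anything,
  overdispersed because animals differ in responsiveness.  Synthetic
  cohort means are therefore far more precise than equally sized real
  cohorts, and power estimates on synthetic cohorts overstate the power
  of a real experiment of the same n.
* Straight, bend-free backing (a reversal without body curl) would not
  depress eccentricity and would be missed by any threshold; the
  generator renders reversal events with a deep bend, so this failure
  mode is not exercised.
* The bend-signal sign convention is continuous within a recording but
  arbitrary at the first frame; only alternation counts, so thrash
  counts are unaffected.
* Otsu segmentation assumes a bright worm on a darker, roughly uniform
  background; textured backgrounds need the fixed-threshold policy or
  upstream flat-fielding.
* The KS normality p value is anti-conservative when the null
  parameters are estimated from the sample; Shapiro–Wilk is the more
  reliable of the pair and both are reported.
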