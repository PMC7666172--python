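# Methods

## Sleep-like inactivity from actigraphy

Voluntary movement is recorded by an implanted 3-axis accelerometer that
reports a movement count per 12-s epoch (300 epochs per hour). An epoch is
scored *sleep-like inactive* iff it lies inside a run of at least two
consecutive zero-count epochs; equivalently, epoch *i* is inactive iff
`counts[i] == 0` and a neighbouring epoch is also zero. Neighbours outside
the recording are treated as nonzero: an inactive run cannot be asserted
without context, so an isolated zero at a recording edge is scored active
(conservative). The minimum detectable inactive period is therefore 24 s,
consistent with the 30–40 s immobility windows used by EEG-validated
immobility-defined sleep scoring (~90 % concordance with EEG); this is a
behavioral proxy and cannot distinguish REM from non-REM sleep.

Runs may span hourly-bin boundaries; scoring is per epoch, so each epoch
simply contributes to the bin containing its start. Bins with < 90 % of
their 300 epochs present are flagged invalid and excluded from window
means (sensor-dropout tolerance without imputation); missing epochs never
form part of a zero run. ZT 0 is lights-on; bin labels are bin starts;
window means are epoch-weighted and support windows crossing ZT 24.

The epoch-count path is canonical. When raw 25 Hz acceleration is
supplied, counts are derived as threshold up-crossings (from ≤ θ to > θ)
of the norm of the sample-to-sample change of the acceleration vector,
with θ = 0.05 g by default. This waveform is insensitive to the static
gravity offset, and the default is scale-free relative to typical murine
locomotor transients; the vendor's on-board waveform synthesis is
undocumented, so this path is an explicit approximation and every analysis
in the package consumes epoch counts.

## Temperature coupling and the hypothermia rule

Core temperature is logged per minute. Each mouse contributes one
(window-mean active %, window-mean T_b) point; the coupling is an ordinary
least-squares fit with Pearson r and two-sided p from the t distribution
with n − 2 df, plus point-wise 95 % confidence (mean response) and
prediction (single new observation) bands. Temperatures outside 25–45 °C
are flagged, never dropped — the hypothermic animal is real data.

A candidate outlier is assessed by leave-one-out: the regression is refit
on all other mice (control + stressed pooled) and the candidate is flagged
iff its temperature falls *strictly below* the lower 95 % prediction band
at its activity level. The prediction interval, not the confidence
interval, is the correct envelope for one animal's value; the confidence
band would over-flag. Ties (exactly on the band) do not flag. The pipeline
nominates the stressed mouse with the lowest window temperature as the
candidate and excludes a flagged mouse from the group temperature
comparison and the per-group regressions, mirroring the exclusion rule of
the analyses this pipeline implements.

## Social-interaction test

The arena is 30 × 40 cm with the mesh enclosure at one short wall. Zone
depths are not part of the assay's published geometry, so the default
makes each zone the third of the arena length nearest/farthest from the
mesh (13.33 cm); both depths are configurable. Zone membership uses the
body centroid (matching commercial-tracker behavior); the nose is reserved
for sniffing. Pose frames with likelihood < 0.9 are bridged by linear
interpolation for centroid analyses (standard pose-estimator hygiene;
threshold configurable) but are treated as *undefined* for nose-to-mesh
distances, because an interpolated nose must not fabricate a sniffing
bout.

Classification uses percent-of-session zone times and the control group's
sample SD (ddof = 1): avoidance criterion `avoid% > mean + 1·SD`, strict;
interaction criterion `interact% < mean − 1·SD`, strict. Both →
susceptible, neither → resilient, exactly one → intermediate (kept as its
own label by default; a `nearest` policy collapses it by the avoidance
criterion). The high-social-interest set applies the same two criteria to
*every* mouse, controls included, so a control beyond its own cohort's
thresholds is excluded — this is what makes the 2×2 high/low-interest
tables well defined for Fisher tests.

## Sniffing bouts

A bout is a maximal run of frames with nose-to-mesh distance ≤ 2 cm
lasting at least 500 ms. The frame threshold is `ceil(0.5 · fps)`, which
makes the rule inclusive ("500 ms or more") for non-integer products: at
25 fps, 13 frames (520 ms) qualify and 12 (480 ms) do not. Distance is
measured to the mesh *front-face segment*, not the wall plane, so
approaches from the side are scored by true proximity. Undefined
(low-likelihood) frames break runs; a `max_gap_frames` parameter (default
0, i.e. the continuous-stay rule) can bridge short gaps. The video frame
rate is a required input — it is never assumed.

Intensity is the mean bout duration per mouse (undefined at zero bouts,
propagated as an explicit missing marker, never a silent zero). Automatic
totals are validated against manual annotation totals by Pearson/OLS.

## Statistics layer

All tests return a uniform record (method, statistic, df, two-sided p,
adjusted p, group sizes). Engines: scipy.stats for Pearson, t, KS,
one-way ANOVA, Tukey HSD (studentized-range distribution,
Tukey–Kramer for unequal n) and Fisher exact; pingouin for the
mixed-design ANOVA. Choices that matter:

* **Fisher exact, two-sided** uses the probability method (sum of all
  tables with the observed margins whose probability does not exceed the
  observed table's). On the reconstructed high-interest tables
  [[5,1],[2,7]] and [[5,1],[7,6]] it yields p = 0.0406 and 0.3331. The
  tables themselves are an inference: they assume one of six control mice
  fell outside its own cohort's thresholds, which the natural spread of
  the criteria makes the expected outcome (≈ 0.8 high-interest probability
  per control), but the control counts are not directly published.
* **KS** is exact (lattice enumeration) when `m·n ≤ 10⁴`, asymptotic
  above. The exact statistic is discrete: with equal small samples the
  attainable level nearest 5 % can be far below 5 % (e.g. ≈ 1.2 % at
  n = 10 vs 10), so calibration checks use unequal sample sizes, where the
  D lattice is fine — the study's own three-group comparisons are unequal
  anyway.
* **Mixed ANOVA** (between-group × two-level within) needs no sphericity
  correction: with two within levels sphericity holds trivially. Follow-up
  families are Sidak-adjusted, `p_adj = 1 − (1 − p)^m`, either within-group
  paired t across levels (m = number of groups) or between-group unpaired
  t per level.
* **ANCOVA** fits `y ~ x + group + x:group` by least squares; slope
  homogeneity is the F test on the interaction block; when it is not
  rejected at α (default 0.05) intercepts are compared under the common
  slope model. When slopes differ the intercept test is suppressed (group
  offsets are not comparable at a single slope). One group degenerates to
  plain OLS.
* **Degenerate inputs** (zero within-variance, noiseless fits) return
  flagged degenerate results rather than raising, so pipelines over
  pathological synthetic data keep running; noiseless ANCOVA reports exact
  coefficient estimates with p ∈ {0, 1} by the sign of the residual
  comparison.
* **Multiplicity** mirrors the original analyses exactly — Tukey within
  ANOVA families, Sidak within the repeated-measures family, no correction
  across the c-Fos regions or elsewhere. No global FDR is imposed;
  fidelity over reformation.

## c-Fos spot counting

The local background is a running median of radius 50 µm (configurable),
computed with a histogram-based rank filter on an 8-bit quantisation of
the image's own intensity range and mapped back to intensity units; the
≤ 1/255-range quantisation error is negligible against the `k·σ` margin,
and quantising relative to the image range keeps detection invariant to
constant offsets. The noise scale σ is the MAD (× 1.4826) of the in-ROI
background residuals. Foreground pixels exceed background + `k·σ`
(k = 3 default); 8-connected components become objects; an object is kept
when its equivalent circular diameter lies in 9–30 µm, computed on the raw
component. Counts are reported per mm² of ROI and hemispheres averaged per
mouse (single-hemisphere values pass through flagged). Touching cells are
not split — no watershed — so dense tissue undercounts; on well-separated
somata recovery is exact.

## Synthetic cohort: what it emulates, and what it does not

The generator's defaults are the study conditions: group sizes 6/13/9;
dark-phase active fraction 0.694 and stressed ZT 13–15 fraction 0.401 with
between-mouse SD 0.12 (back-computed from the printed SEMs at n = 6 and
13); light-phase fraction 0.30; temperature line
`T_b = 35.86 + 2.32·(active fraction)` °C — which places the two group
means at 37.47 and 36.79 °C — with 0.25 °C between-mouse residual SD and
AR(1) minute noise (σ = 0.08, ρ = 0.8); a transient handling-induced
temperature bump at ZT 11.75 in all groups; an optional hypothermic
stressed mouse dipping to 31.1 °C at ZT 17 (Gaussian excursion, σ = 2 h)
and recovering within the day; sleep deprivation as enforced 95 % activity
over ZT 12–18.

Activity is a two-state semi-Markov chain per ZT phase. Inactive dwells
are `2 + geometric` epochs (mean 4), so *every* planted inactive run is
long enough for the ≥ 2-epoch scoring rule — with this choice the planted
active fraction equals the expected scored active fraction, which is what
makes parameter recovery a sharp test (a per-epoch Bernoulli model would
not have this property). Active dwells are geometric with the mean set by
the target fraction; active epochs draw counts `1 + Poisson(7)`.
Temperature couples to the *realised* hourly active fraction, so the
per-mouse (active %, T_b) scatter has the configured residual SD without
errors-in-variables attenuation.

Social sessions realise drawn zone-occupancy targets exactly (up to frame
quantisation) by constructing a zone-visit schedule and confining a
reflected random walk to each zone band, with corridors through the middle
band between visits. Phenotype targets (percent of a 150-s, 30-fps
session): control 45/26 (interaction/avoidance, SD 3), resilient 55/18,
susceptible 8/62, post-sleep-deprivation social 50/22 and avoidant 28/40.
The susceptible–control separation is many control-SDs, reflecting the
non-overlap of the source distributions; it also makes exact label
recovery the correct expectation. Sniffing bouts are injected during
interaction-zone visits: counts Poisson (rates 15.33 control, 11
resilient, 5.5 susceptible, 13/12 sleep-deprived), log-normal durations
(σ = 0.25) around a mouse-level mean that is linearly coupled to realised
interaction time in high-interest phenotypes (slope 0.03 s/s, targeting
r ≈ 0.7) and uncoupled in susceptible mice; two sub-500-ms approaches per
session exercise the duration threshold; manual annotations are the true
bouts with Gaussian boundary jitter (SD 50 ms), mimicking human scoring
latency. Because bouts must fit inside realised interaction time,
low-interaction phenotypes realise fewer bouts than their nominal rate
(susceptible mice saturate near 4–5); ground truth always records the
*realised* bouts. Within-mouse bout-duration distributions are a stated
assumption (log-normal), not a measured quantity.

Fluorescence images are 256 × 256 px at 2 µm/px: planar illumination
gradient + Gaussian noise (σ = 4 at background 100), non-overlapping hard
disks of 12–24 µm diameter at 10 σ contrast, plus two undersized (6 µm)
and two oversized (40 µm) distractors per image; stressed images of the
DMH- and VLPAG-like regions double the planted count.

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about real data: EEG-defined sleep architecture,
gradual (non-piecewise) circadian modulation, sensor drift and epoch loss
beyond random masking, body-pose kinematics (trajectories are schedule-
constrained walks, not locomotion), tracker identity swaps, anisotropic
optics, out-of-focus or touching somata, and any between-modality
correlation beyond those explicitly planted.

## Problem sizes and determinism

Recovery checks use 100 cohorts for classification, 100 replicate
two-group comparisons for the activity window, 200 replicates for
temperature-coupling coverage and outlier flagging, 100 images for spot
counting, and 10,000 Monte-Carlo replicates per test for type-I
calibration — sizes at which the binomial uncertainty of each pass
criterion is small relative to its margin. All randomness flows from
`numpy.random.default_rng` seeds; identical seed and configuration give
byte-identical cohorts, reports and acceptance JSON.

## Known limitations

* The inactivity proxy cannot stage sleep; 12-s epochs quantise bout
  boundaries.
* The raw-acceleration crossing counter approximates an undocumented
  on-board algorithm; epoch counts are authoritative.
* Zone depths and the centroid-vs-nose convention are configurable
  defaults, not published constants of the assay.
* No watershed splitting of touching somata; dense c-Fos fields
  undercount.
* The mixed ANOVA follows pingouin's unweighted-cell-means conventions for
  unbalanced groups.
* Fisher-table control counts are inferred (5 : 1), as documented above.
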