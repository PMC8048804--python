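# Methods

## Scope and model

`lamegait` studies the compensatory gait adaptations of horses with a
moderate, reversible supporting-limb lameness of one forelimb, measured on
an instrumented treadmill at walk and trot.  Because raw recordings of such
experiments are not publicly deposited, the package pairs its analysis
pipeline with a synthetic-trial generator whose defaults reproduce the
study conditions: 10 Warmblood-sized horses (body mass drawn uniformly from
480–640 kg), 20 s trials, preferred belt speed drawn from 1.57–1.79 m/s at
walk and 3.78–3.94 m/s at trot, forces sampled at 512 Hz and optical
markers at 256 Hz.  Every stage of the pipeline is therefore testable
against exact ground truth.

### Gait model

Walk is a four-beat lateral-sequence gait: footfalls LH → LF → RH → RF at
quarter-stride phases, stride duration 1.25 s, duty factor 0.625 per limb.
These defaults produce the canonical eight-phase support cycle
(tripedal/bipedal alternation) and ~15 strides per 20 s trial (the study
range is 11–17).  Trot is a two-beat diagonal gait: LF+RH and RF+LH offset
by half a stride, stride duration 0.75 s, duty factor 0.45, giving
suspension phases and ~26 strides per trial (study range 15–29).  A signed
`diagonal_dissociation` (forelimb-first positive) offsets the hindlimb of
each diagonal pair.

Stance duration is the duty factor times the limb's own stride interval,
so under stride-to-stride timing jitter stance and swing scale together —
as in steady-state locomotion, where cycle phases co-vary with cycle
duration.

### Force waveforms

Walk GRFz (N/kg) over a stance is a monotone piecewise-cubic interpolant
through (0,0) → (t_peak1, peak1) → (t_dip, dip) → (t_peak2, peak2) → (1,0)
with zero node derivatives.  The initial/terminal ramps are linear up to
85 % of the adjacent peak over 75 % of the rise time before a cubic cap.
Two properties follow: the 20–80 % band of each rise/fall is exactly
linear, so the slope-intercept event detector and the chord loading rates
are exact on noise-free data; and the stance integral is affine in the dip
height, which the effect realization uses.  Default control points
(fore: 6.3 / 4.5 / 6.6 N/kg at stance fractions 0.28 / 0.50 / 0.75, hinds
scaled ×0.8) are design defaults for the qualitative double-peaked shape;
the absolute level is rescaled per horse so the mean total normalised
force over a stride equals g = 9.81 N/kg exactly (weight support).

Trot GRFz is the single-peaked `peak·sin(πs)^q`.  The default exponent
q = 1.12 was chosen so that the chord-based event detector is consistent
with the true onset for this shape family (the chord's zero intercept
crosses zero bias near q ≈ 1.125; at q = 1.12 the residual bias is
≈ −0.2 ms, far below one force sample).

### Upper body and limbs

Each landmark (poll, withers, sternum, L3) moves vertically as
`z = mean + a2·sin(2θ + φ2) + a1·sin(θ + φ1)` with θ the stride phase; a2
is the symmetric twice-per-stride component and a1 the once-per-stride
asymmetry injected under lameness (a1 = 0 gives MinDiff = RUD = RDD = 0
and ROMz = 2·a2).  Defaults: poll a2 = 20 mm (walk) / 30 mm (trot),
withers 12 / 25 mm, with sternum/L3 carrying the lateral sway that
dominates the walk COM translation (25–30 mm amplitudes) and a smaller
trot sway.  The asymmetry phase 3π/4 maximally differentiates the two
half-cycle minima relative to the default a2 phase.

Each limb is reduced to four markers: hoof, fetlock, proximal joint and an
upper-limb pivot.  During stance the hoof moves caudally at belt speed
(slip-free, so stance length StL = belt speed × stance duration); during
swing it returns along a displacement profile whose velocity is
`v(u) ∝ (u(1−u))^p` — the regularised incomplete beta function gives the
position, p = 1 reproduces a smoothstep and larger p a sharper mid-swing
speed peak.  The fetlock extension angle during stance is driven
proportionally to the normalised force (default gain 3° per N/kg), and the
fetlock/proximal markers are constructed so that 180° minus the marker
vertex angle equals that extension exactly.

### Lameness effect profiles

A profile maps (parameter, limb role ∈ {lame fore, contralateral fore,
ipsilateral hind, diagonal hind, global}) to a multiplicative factor.  The
`walk_moderate` and `trot_moderate` presets encode the group-level
percentage changes measured for moderate forelimb lameness — walk: stride
duration ×0.9795, lame-fore duty ×1.004 (also ipsilateral hind), first
force-peak timing ×1.084 (lame fore and both hinds), lame-fore Fz_peak1
×0.981 and Fz_peak2 ×0.939, diagonal-hind Fz_peak1 ×1.048, lame-fore Iz
×0.949, contralateral ΔFz_load ×1.165 and ΔFz_unload ×1.15, lame-fore
fetlock hyperextension ×0.967, swing speed ×0.954 (hinds ×1.024 / ×1.027),
retraction ×0.974, contralateral protraction height ×1.025; trot: front
duty ×1.055, lame-fore Fz_peak ×0.823 and Iz ×0.857, poll ROMz ×1.505,
lame-fore protraction ×1.016, retraction ×0.972, protraction height
×0.832.  Directions that the source reports without a number are left at
identity rather than invented.

Encoding is by calibration: `apply_profile` solves the generator's free
knobs so the *noise-free analytic measurement* of each targeted parameter
changes by exactly its factor — the dip height for Iz (a linear solve,
since the stance integral is affine in the dip), t_peak1 / t_peak2 for the
chord rates (closed-form time scaling), the trot exponent q for trot Iz
(Brent solve on the stance integral), the swing exponent p for peak swing
speed (solved against the pipeline's own sampled central-difference
estimator), the fetlock gain for A_fetlock, the hoof home position (and,
when protraction and retraction are both targeted, the effective limb
length) for the limb angles, and the poll a1 for ROMz.  Head/withers
asymmetry at walk is injected as fixed a1 amplitudes (6 mm poll, 1.5 mm
withers — plausible magnitudes; the source reports walk head asymmetry as
significant but does not print millimetres).

Because only the printed per-limb changes are encoded, the lame condition
does not conserve weight support exactly (at trot the quantified lame-limb
impulse reduction is not offset by quantified compensations, leaving the
cohort mean ≈ 4 % below g); the conservation invariant is therefore a
property of baseline trials, which are calibrated to g exactly.

### Noise model

Additive white Gaussian measurement noise: σ = 0.05 N/kg on forces and
1 mm on markers.  Stride-to-stride variability: multiplicative unit-mean
lognormal jitter with CV 2 % on stride duration and on stance force
amplitude.  Inter-horse spread: CV 3 % on timing, force level, motion
amplitudes, fetlock gain and swing lift.  What the generator does **not**
emulate: soft-tissue artefact and marker occlusion, baseline drift of the
treadmill cells, within-trial fatigue or drift, autocorrelated
physiological variability beyond the shared stride boundaries, and
individual differences in compensation *strategy* (every synthetic horse
compensates with the same encoded pattern).  Passing tests therefore
demonstrate correctness of the estimators under realistic noise levels,
not robustness to every artefact of real capture data.

## Extraction pipeline

* **Events.**  Candidate stances are threshold crossings (50 N) of the
  30 Hz zero-phase-filtered trace, with gaps < 20 ms merged and candidates
  < 100 ms discarded with a log entry.  Hoof-on is the zero intercept of
  the chord through the 20 % and 80 % crossings of the first local force
  maximum (hoof-off symmetrically from the last); event times are
  real-valued seconds, and all durations are computed from them rather
  than from sample indices (512 Hz quantisation is 2 ms, the order of some
  effects).  The threshold, band fractions and minimum stance are config
  keys; the source method does not state them.
* **Stride assignment.**  Strides run between consecutive LF hoof-ons; a
  limb's stance belongs to the stride containing its hoof-on, with a 10 %
  pre-window tolerance because limbs whose footfall phase is ≈ 0 (the trot
  diagonal partner) jitter across the boundary.  Support phases are
  classified from the exact event times; intervals shorter than 2 ms
  (detection jitter around simultaneous diagonal contacts) are absorbed
  into their predecessor.
* **Kinetics.**  Peaks/dip are located on the filtered stance and refined
  with one-sided local cubic fits of the raw trace re-centred on the raw
  extremum — the waveform is piecewise-cubic with a node at each extremum,
  so one-sided fits recover the node exactly (noise-free peaks match the
  control points to ≈ 1e-6 N/kg).  Iz is the trapezoidal integral over
  the sub-sample-clipped stance; rates are least-squares slopes of the raw
  trace over the 20–80 % band; walk stances without two maxima are flagged
  monophasic.
* **Kinematics.**  Landmark signals are low-pass filtered (4th-order
  zero-phase Butterworth, 10 Hz) before extremum search; extrema are
  refined by local parabolic fits and indexed per stride with half-cycles
  delimited by the two forelimb hoof-ons.  The trailing maximum after the
  right-half minimum may fall in the next stride, so extrema are taken
  from a whole-trial extremum list; strides without the full pattern are
  excluded.  Swing peak speed uses unsmoothed central differences at the
  marker rate (a low-pass is available as a config key); robust peak
  values are obtained by locating the peak on a 21-frame moving average
  and fitting a parabola to ±11 raw frames — averaging the noise instead
  of selecting its maximum, which would bias max-based estimates upward in
  both conditions and shrink recovered percent changes.  The fetlock-peak
  stance phase is fixed per trial from the stride-ensemble mean curve
  because the lame walk condition has two nearly equal extension maxima
  and a per-stride argmax would select between two noisy candidates.
  A_fetlock is computed from raw (unfiltered) markers: the locate-then-fit
  estimator handles white noise well, whereas pre-filtered noise is
  correlated across the fit window and defeats it.
* **COM/COF.**  COM proxy = 0.6·sternum + 0.4·L3 (config key; the segment
  weighting of the underlying trunk model is approximate, weighted toward
  the thorax).  Markers are linearly resampled onto the force timeline.
  COF is the force-weighted mean of stance-gated hoof ground positions,
  undefined when total force is zero (trot suspension), and checked
  frame-by-frame against the support bounding box.  The per-side metric is
  the maximum of COF_y − COM_y during the tripedal phase preceding that
  side's ipsilateral bipedal support plus the bipedal phase itself; the
  asymmetry left − right is flipped when mirroring right-side inductions.
  This numeric operationalisation quantifies what the source assessed
  visually.
* **Mirroring.**  Limb-suffixed variables are mapped to lame / contra /
  ipsi / diag roles, side-suffixed variables to lame/contra, support
  phases mirrored (1↔5, 2↔6, 3↔7, 4↔8), and signed symmetry indices
  (MinDiff, RUD, RDD, COF asymmetry) negated for right-side inductions.

## Statistics

Youden cells use all strides of one horse: candidate cutoffs are midpoints
of consecutive sorted unique pooled values, both classification directions
are scored, and ties are broken toward the cutoff nearest the pooled
median, then toward direction "greater".  The resulting J equals the
two-sample Kolmogorov distance, which fixes its null behaviour: with n
strides per condition the attainable values are multiples of 1/n and the
null median is ≈ 0.83/√(n/2).  At trot stride counts (~25 per condition)
the null median is ≈ 0.24; at walk counts (~15) it is ≈ 0.30 for *any*
implementation — a property of the statistic worth remembering when
comparing heat maps across gaits.  Null-specificity checks therefore run
at trot.

Mixed models: one model per variable and gait, `value ~ condition` with a
horse random intercept, REML.  LS means are the fixed-effect intercept
(baseline) and intercept + effect (lame); percent change is their ratio.
Degenerate fits (no within-condition variance, implausible intercepts from
singular optimisations) fall back to a paired per-horse t-test on
condition differences, flagged in the output.  Bonferroni m is the number
of variables actually modelled per gait.  Significance is 0.05.

## Problem sizes

The standard experiment is 10 horses × 2 conditions × 20 s per gait
(~290 walk strides, ~510 trot strides per cohort); the null-specificity
suite uses 20 such trot cohorts.  These match the study design and keep
the full test suite and the acceptance script within a few minutes on one
CPU.

## Known limitations

* The generator encodes one common compensation pattern; inter-individual
  strategy differences appear only through parameter jitter, so heat maps
  are more homogeneous than real cohorts.
* Force-shape magnitudes, marker geometry, COM weighting and the RUD/RDD
  formulas follow equine-gait conventions but stand in for unavailable
  source tables; each is isolated behind one function or config key for
  substitution.
* Lame-condition trials do not exactly conserve weight support (see
  above); only baseline trials are calibrated to g.
* The trot waveform family sin^q couples its onset curvature to the
  impulse, so the slope-intercept detector carries a small (≤ ~2 ms)
  shape-dependent bias for lame-condition exponents.
* Horizontal forces, pelvis/croup symmetry and marker-based event
  detection are out of scope.
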