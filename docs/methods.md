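# Methods

This note documents the models, parameter choices and numerical conventions
behind spindlepipe, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Synthetic recordings

A recording is generated in four layers, each with explicit ground truth.

**Hypnogram.** A first-order Markov chain over {WAKE, NREM, REM} at one step
per 5-s epoch, started in WAKE. The default transition matrix

|        | →WAKE | →NREM | →REM |
|--------|------|------|------|
| WAKE   | 0.95 | 0.05 | 0.00 |
| NREM   | 0.03 | 0.94 | 0.03 |
| REM    | 0.08 | 0.02 | 0.90 |

gives mean bout lengths of ~100 s (wake), ~83 s (NREM) and ~50 s (REM) and a
stationary mix of roughly 45/42/13% — light-phase rodent sleep architecture.
Direct WAKE→REM transitions are excluded. Group/session effects multiply the
NREM/REM *leave* rates (a dwell multiplier m maps 1−p_ii to (1−p_ii)/m, with
the off-diagonal entries rescaled proportionally), so effect knobs change
bout lengths without breaking row-stochasticity.

**EEG.** Per state, a sum of sinusoidal components over a shared 1/f
background: wake 7 Hz/20 µV, NREM 1.5 Hz/60 µV + 3 Hz/20 µV, REM
7.5 Hz/45 µV; background RMS 15/20/10 µV respectively. The 1/f noise is
white noise shaped to 1/f power in the frequency domain, flattened below
0.5 Hz so the delta band stays finite and the trace does not drift.
Component phases are drawn once per recording, so oscillations are
continuous across same-state epochs.

**Spindles.** Homogeneous Poisson process within NREM bouts at 2 events per
NREM minute (a realistic rodent density), rejecting overlaps with a 0.1-s
guard gap. Each burst is a raised-cosine (Hann) enveloped sinusoid —
"waxing and waning", zero at both edges, with closed-form energy
3/16·A²·d·fs — with frequency uniform on 9–15 Hz, duration uniform on
0.5–3 s, and a fixed 50 µV envelope peak. These injection defaults describe
the spindle *phenomenon*; they deliberately straddle the *detection*
criteria (12–20 Hz band, 0.5–2 s duration), as in real data, where the
detection band and duration window clip the underlying event population.

**EMG.** White noise scaled per state to RMS 30/10/5 µV (wake/NREM/REM) —
high tone awake, atonia in REM.

Group/session effect directions follow the study design being modelled:
Valerian-treated animals get a higher spindle rate (×1.5–1.6), higher
baseline REM dwell declining by day 6, and longer NREM dwell under
neuropathy; magnitudes are qualitative stand-ins (the design reports only
directions) and fully configurable. Behaviour: per-trial withdrawal
probabilities (sham 0/0, neuropathic 0.75/0.85, treated 0.35/0 on
days 3/6) and an alternating center↔arm EPM walk with exponential dwells
(center mean 8 s, arm mean 25 s) and a group/day-specific closed-arm
preference.

What the generator does *not* emulate: real EEG morphology (K-complexes,
artifacts, electrode drift), non-stationary spindle shapes, circadian
structure, or inter-animal spectral variability. Recovery tests therefore
demonstrate the *internal consistency* of the pipeline — that each stage
inverts the generative process it assumes — not field performance on real
recordings.

## Staging

Features per 5-s epoch: log10 band powers from the plain (boxcar)
periodogram over δ 0.5–4, θ 4–9, σ 12–20, β 20–30 Hz (half-open bins so
adjacent bands never double-count), the log θ/δ ratio, and log EMG RMS.
Log powers are floored at 1e-12 so silent epochs stay finite. Features are
z-scored by the training statistics because the units are heterogeneous.

The classifier is k-nearest-neighbour (default k = 5) over the 5-s training
epochs cut from ≥ 30-s labelled exemplars of all three states. Neighbours
are ordered by (distance, state) lexicographically and votes tie-break by
the fixed order WAKE < NREM < REM, which makes predictions invariant to
exemplar ordering and makes k = 1 self-classification exactly reproduce the
training labels. No hypnogram smoothing is applied.

Exemplars are taken from ground truth as the first contiguous ≥ 30-s
same-state bout; when a short recording has no such bout, same-state epochs
are concatenated (band-power features are insensitive to the splice
boundaries). The study pipeline trains one stager per animal, falling back
to a dedicated balanced-bout reference recording for the rare animal whose
short sessions lack 30 s of REM.

## Spindle detection

Detection trace: short-time PSD (Hann window 1.0 s, step 0.1 s, zero-padded
to ≥ 1 Hz frequency spacing, density scaling, Parseval-consistent within
5%), band-integrated over 12–20 Hz with both edges inclusive. Threshold:
mean + 2.5·SD (population) over NREM-aligned bins; the multiplier and an
explicit `--threshold` override are exposed because any such threshold is a
calibration choice.

Event timing cannot be read off the 1-s-window trace (window smearing biases
run lengths by up to ±1 s), so events are refined on a 0.15-s/0.02-s trace
by iterative peak extraction:

1. while the largest remaining fine-trace value inside the coarse candidate
   zones exceeds both the detection threshold and the fine-trace background
   mean + 2.5·SD (computed from NREM bins away from candidates): take the
   peak, re-estimate its height as the corrected average over the profile
   top (the single-bin maximum rides on the noise);
2. measure widths at relative levels r = 0.15–0.4 of the background-corrected
   peak; for a raised-cosine envelope the width above level r is exactly
   d·(1 − (2/π)·asin r^¼), so each level yields an unbiased duration
   estimate and their mean suppresses single-crossing noise. The key choice
   of *relative* (fraction-of-peak) rather than absolute levels makes the
   measured duration independent of burst amplitude, which an absolute
   threshold crossing is not for any tapered envelope;
3. suppress the event's bins and repeat; merge adjacent bursts closer than
   0.3 s if their peaks are within a factor 4 (an envelope dip splits one
   spindle into comparable halves; a noise bump next to a strong burst must
   not stretch it).

Durations are resolved no finer than ~0.05 s (refinement window and step);
estimates within 0.05 s of a duration-criterion edge are snapped to the
edge before the inclusive [0.5, 2] s filter. Events are kept only if their
midpoint lies in a NREM epoch (spindles are a NREM phenomenon) and if the
peak of the event's own Hann-windowed, zero-padded periodogram — searched
over the band widened by half a bandwidth, so the slow-wave background
cannot mask it — lies within 12–20 Hz ± 0.4 Hz. The 0.4 Hz edge tolerance
is well under the ~2 Hz spectral resolution of the shortest admissible
event; the spectral check is what gives the detector exact band edges at
1 Hz granularity, since window leakage alone cannot separate an 11 Hz from
a 12 Hz oscillation on the power trace.

Characterization: RMS over the event samples; mean frequency as the
power-weighted periodogram average over the detection band (full-spectrum
optional), NaN when the in-band power is zero; peak sigma power from the
fine trace; density as events per NREM minute.

Recovery conditions: because the injected population (9–15 Hz, 0.5–3 s)
intentionally straddles the detection criteria, recall/precision and
density-recovery are evaluated on a configuration whose injected events all
satisfy the criteria with margin — 12.5–15 Hz, 0.7–1.8 s, 300 µV amplitude
("high SNR"), 40-min sessions at 250 Hz. Under those conditions recall and
precision exceed 0.9 (≥ 50%-overlap matching) and detected density is
within a few percent of the injected rate. Sweep measurements (duration and
band acceptance) inject 500 µV bursts at the quietest background stretch of
each of five independent 60-s NREM backgrounds and take the majority
verdict per sweep point; the quiet-site rule (calibration against a
pre-screened baseline) and the majority vote keep the measured acceptance
ranges stable under arbitrary seeds.

## Behaviour and statistics

Acetone scoring is the sum of five binary withdrawals; EPM scoring holds
each zone from its entry event to the next (the last to 300 s), so zone
times partition the session exactly; percent closed-arm time uses the
session length as denominator (the natural reading when no other is
stated). The all-four-paws entry criterion is the upstream annotator's job.

The statistics module wraps scipy.stats behind the study's decision scheme.
Conventions chosen where the scheme is silent: Shapiro–Wilk at α = 0.05 as
the normality gate (constant samples count as non-normal); two-sided tests;
exact rank distributions for n ≤ 12 without ties (Wilcoxon drops zero
differences), normal approximation with continuity and tie corrections
otherwise; all-zero paired differences give p = 1 by convention; identical
groups give F = 0, p = 1; SEM uses the n−1 standard deviation. No
multiple-testing correction is applied, matching the modelled design; the
report states this.

## Problem sizes and determinism

Full scale is 150-min sessions at 3,000 Hz (27 M samples per channel); the
`quick` profile (15-min sessions at 250 Hz) preserves every analysis band
below Nyquist and runs the 24-animal, 72-recording study in about a minute,
which is the scale the test suite and the acceptance script use. All
randomness flows from `SimConfig.seed` through per-(group, animal, session)
`numpy` generators, so identical seeds give bit-identical recordings and
byte-identical report tables; the run log's timings are the only
non-deterministic output.

## Known limitations

- The duration estimator's level calibration assumes a raised-cosine-like
  envelope; strongly asymmetric real spindles would bias durations by order
  10%.
- Staging features carry no temporal context (no smoothing, no transition
  prior), so isolated misclassified epochs pass through unchanged.
- The detector restricts events to NREM by the midpoint rule; events
  straddling a stage boundary are kept or dropped wholesale.
- EDF support writes 16-bit samples with one-second records (amplitudes are
  exact only to that quantization) and reads through mne; CSV round trips
  are exact to six decimals.
- Group-effect magnitudes in the generator are qualitative: the pipeline
  reproduces directions of group differences, not effect sizes.
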