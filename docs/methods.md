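# Methods

## Signals and preprocessing

A trial is five synchronized series at a common sampling rate (default
100 Hz, 60 s): forces Fx, Fy, Fz in N and COP excursions COPx
(anteroposterior), COPy (mediolateral). When a file ships moments instead
of COP, the moment balance gives COPx = −My/Fz and COPy = Mx/Fz; if the
support surface sits a height h above the plate origin (e.g. a 6 cm foam
pad), shear corrections −Fx·h/Fz and −Fy·h/Fz apply. The correction is
off by default because public datasets do not state whether their vendor
software already applied it; `CsvDialect.pad_height` switches it on.

Preprocessing is a low-pass Butterworth filter (default 10 Hz cutoff,
4th-order design) applied forward and backward (`sosfiltfilt`), so the
net phase shift is zero and the effective magnitude response is the
square of the one-pass design. "Order" here names the one-pass design
order — the common biomechanics reading of "fourth-order zero-lag".
Filtering is **opt-in** at the pipeline level (`filter_enabled`, default
off) because open posturography datasets are typically distributed
already filtered and re-filtering would double the smoothing.

## Decomposition

Plain EMD by envelope sifting:

1. locate strict interior extrema (a plateau bounded by opposite slopes
   counts once, at its midpoint — a deterministic tie-break);
2. extend extrema by symmetric reflection of the two end-nearest extrema
   about each end sample (curbs envelope end-swing; configurable via
   `boundary_rule`, and logged, since reference implementations differ
   here and the choice is the main source of cross-implementation
   disagreement);
3. cubic splines through the extended maxima/minima; with fewer than 4
   knots, linear interpolation;
4. subtract the envelope mean, and stop sifting when the Cauchy criterion
   `SD = Σ m(t)² / Σ x(t)² < stop_threshold` (default 0.05) holds *and*
   the candidate satisfies the IMF counting condition (|#extrema −
   #zero-crossings| ≤ 1), or after `max_sift_iterations` (default 50,
   logged when hit);
5. peel the IMF off and repeat on the remainder until it has no interior
   extrema of both kinds or the depth cap `max_imf` (default 7, the
   conventional depth for 100 Hz stabilograms) is reached.

The decomposition is complete by construction: IMFs + residue telescope
back to the input, and the test suite asserts the reconstruction at
1e−6·max|input| for every decomposition it performs. Series shorter than
16 samples are refused (spline envelopes are unreliable). A signal with
no interior extrema returns k = 0 with the input as residue.

Because "number of IMFs" for a given signal is boundary-rule dependent in
its low-energy tail (every EMD variant keeps decomposing its own end
artifacts for a few extra modes), cross-implementation agreement is
checked on the *significant-mode count* — IMFs carrying ≥ 1% of the
input energy — plus IMF1 correlation, against an independently written
textbook sifting variant with naive extrema and constant-extension
boundaries.

## Features

Per series: mean(|x|), sample SD (n−1), CV = SD/mean(|x|), ApEn and
SampEn. Using mean(|x|) in the CV keeps it well-defined on zero-centered
IMFs; `mean_mode="signed"` is available because published tables
sometimes report signed raw-COP means. Entropies use the canonical
definitions (ApEn with self-matches, SampEn without; Chebyshev distance)
with m = 2, lag 1, and r = 0.2 × SD **of the analyzed series** — each IMF
is compared at its own scale, which makes both entropies invariant to
channel gain. Which SD to use (raw vs per-series) is genuinely open in
the posturography literature; per-series is the convention of the COP
entropy-parameter studies this package follows, and it is configurable.

Degenerate rules: zero-variance series → both entropies 0 with a warning
(constant IMFs must not abort a cohort run); SampEn with no matched pairs
(A = 0 or B = 0) → missing (NaN), not 0; CV with mean(|x|) = 0 → missing.
Missing values propagate into the screening by pairwise deletion.

The counting kernel is a fused O(n²) pass (numba-compiled) returning
per-template counts at lengths m and m+1 plus the SampEn pair counts; it
is checked to 1e−12 against a brute-force pure-Python oracle.

## Screening

One Welch t-test per feature (pooled-variance Student's optional — the
source analyses rarely state which; Welch is the safer default), strict
p < α with α = 0.05, stars at 0.05/0.01, and no multiplicity correction
by default to mirror the screening convention of the field;
Benjamini–Hochberg is available behind a flag. Features with fewer than
two values in a group, or zero variance in both groups, report a missing
p with a warning. Significant rows are listed time-domain features first,
then entropies.

## Synthetic cohorts

`SyntheticCohortSpec` defaults encode the emulated study conditions: 27
fall / 49 non-fall subjects, 60 s at 100 Hz. Each channel is a sum of
three band oscillators — 8 Hz (fast, tremor-range), 1.2 Hz (mid band),
0.3 Hz (slow sway) — each with random phase, slow amplitude modulation
(5 s knots, depth 0.25) and Wiener phase noise, plus 1/f broadband noise,
around channel-typical operating points (≈700 N on Fz, ~cm-scale COP).
Group contrasts, chosen to produce the two finding types such screenings
report and fixed as the package's study conditions:

* **regularity**: the fall group's mid-band phase-jitter is reduced by
  `regularity_effect` (default 0.5) on COPx — more regular
  anteroposterior sway, hence lower mid-IMF entropies;
* **amplitude**: the fall group's slow band is amplified by `amp_delta`
  (default +30%) on COPy and Fz — larger slow sway, hence larger deep-IMF
  mean/SD.

All draws derive from `SeedSequence([seed, subject_seed, channel])`;
group effects are deterministic multipliers applied after the draws, so
a zero-effect spec produces bit-identically distributed groups (the same
subject seed gives the same recording under either label). Fall subjects
use seeds 0…n−1, non-fall 100000…, so groups never share streams.

What the generator does **not** emulate: biomechanics (no inverted
pendulum), real stabilogram spectra, inter-trial variability within
subject, or demographic covariates. Passing tests therefore demonstrate
that the pipeline recovers contrasts of the assumed kind at realistic
sample sizes — not that real fallers differ this way.

## Problem sizes in the test and acceptance runs

Simulation-heavy checks run at reduced sizes chosen to keep the suite
quick while leaving the checked properties intact: effect recovery uses
20 cohorts of 27 + 49 subjects with 10 s trials (the mid-band contrast
lands in IMF3–5 regardless of trial length; entropy estimates are merely
noisier), null calibration uses 500 replicates × 200 simulated features
through the same screening code, and the acceptance script runs one full
60 s default cohort plus 10 scaled cohorts. At these sizes the observed
effect-recovery rate is ~0.9 and the null flag rate ~0.050.

## Known limitations

* EMD end effects: reflection boundaries tame but do not eliminate
  envelope end-swing; the first/last ~1 s of deep IMFs is least reliable.
* Sifting depth is a fixed cap (7), not an adaptive stop; short trials
  (< ~15 s) often support only 5–6 IMFs, and deeper levels are recorded
  as missing rather than extrapolated.
* SampEn is undefined (missing) when no template pairs match; at n ≲ 100
  with r = 0.2·SD this is common for broadband series.
* The t-test screening assumes independent subjects and roughly normal
  feature distributions; no effect-size or power output beyond the
  simulation tests.
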