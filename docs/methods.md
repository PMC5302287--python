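# Methods

`tempopred` models and analyses an EEG experiment that dissociates
rhythm-based from memory-based temporal prediction.  Participants watch a
stream of visual stimuli, a warning signal (WS), and a target; reaction
times and EEG are the measures.  Three stream structures are compared:

* **Rhythmic** — a perfectly periodic stream (SOA 700 ms, "short cue", or
  1300 ms, "long cue"); the target follows the WS on-beat in 75% of trials
  (valid), at the other SOA in 12.5% (invalid), and 12.5% are catch trials
  (no target, 1500 ms blank after the WS).
* **Repeated-Interval** — black/red stimulus pairs whose within-pair
  interval equals the cue SOA while between-pair intervals are jittered
  (short: 1500–1900 ms in 50 ms steps; long: 1900–2700 ms in 100 ms steps,
  discrete uniform).  The stream is aperiodic yet the WS→target interval is
  as predictable as in the rhythmic stream (memory-based prediction).
* **Random** — all stream intervals jittered around the cue SOA
  (±200 ms in 50 ms steps) and the target SOA drawn independently; no
  temporal prediction is possible.  Blocks contain 32 trials with exact
  validity counts (predictive: 24/4/4; Random: 14/14/4); a session is two
  Random blocks followed by four alternating blocks of each predictive
  condition, yielding 48 valid trials per predictive condition per cue SOA.

The stepped jitter grids give the Repeated-Interval "meta-stream" (every
second stimulus) a mean interval of 2400 ms (short cue) with a CV of 5.38%
(discrete-uniform closed form; continuous-uniform sampling would give
~4.8%), and 3600 ms (CV 7.2%) for the long cue.

## Phase-oscillator entrainment model

Each oscillator in an array with natural periods 5000…200 ms (50 ms steps,
i.e. 0.2–5 Hz) follows

    dφ/dt = 2πF − s(t)·c·sin(φ),

where s(t) is the 1 kHz binary impulse train of a trial's stimulus onsets
and c the coupling strength.  Amplitude dynamics and period correction are
deliberately absent — the model isolates phase alignment.  φ = 0 is the
optimal phase, aligned with the external stream.  The system is integrated
with fourth-order Runge–Kutta at 1 ms steps, s(t) held constant within a
step (zero-order hold).  Impulses occupy a single sample, so the effective
per-impulse correction is ≈ c·sin(φ)·dt and useful couplings are in the
hundreds; `calibrate_coupling` bisection-tunes c so that the short-SOA
rhythmic stream entrains its matching oscillator to a target ITPC (default
0.6, a mid-range empirically plausible coherence).  The impulse width is
exposed; calibration makes the outcome insensitive to this choice.

Per trial, the initial phase is drawn without replacement from n equally
spaced angles (n = trial count), identical across oscillators, so the
initial resultant is exactly zero and any inter-trial phase coherence
(ITPC = resultant length of the per-trial target-time phasors) is
attributable to stimulus-driven phase correction.  Chance ITPC is the mean
resultant of matching numbers of uniform angles (≈ √π/(2√n), with surrogate
quantiles as a confidence band).

Two model facts discovered during implementation and handled explicitly:

* **Harmonic ties.**  For a perfectly periodic stream, every harmonic of
  the stimulation frequency experiences identical phase-correction
  dynamics (the free rotation between stimuli is a whole number of cycles),
  so their ITPCs tie up to ~1e-4 integration differences.  Peak-frequency
  reports resolve ties (tolerance 1e-3) to the lowest member — the
  fundamental; genuinely distinct peaks differ by ≫ 1e-2.
* **Zero-coupling invariance** (resultant stays exactly zero) holds at a
  fixed time point, or across trials of equal length; with 4–6 pre-WS
  stimuli per trial the per-trial rotations to target time differ, leaving
  a small non-zero resultant even without coupling.

The frequency grid is linear in period (50 ms steps), which is what the
stated period range implies; it is approximately logarithmic in frequency.

## Synthetic EEG generator

The generator plants every effect the pipeline measures, with known
parameters, in a 20-channel layout (9 central, 6 occipital, 3 parietal,
2 mastoids; default 256 Hz — all analysis windows are in physical units so
the rate is transparent; 1024 Hz is available):

* **CNV** (central): the piecewise waveform 0 → linear buildup (T0→T1) →
  plateau (T1→T2) → linear resolution, peaking (−5 µV) at the expected
  target time; the resolution delay T2−T1 is 0 ms for the Rhythmic
  condition and 400 ms for the Repeated-Interval condition (immediate vs
  delayed resolution).  The default resolution slope (0.007 µV/ms) keeps
  the waveform inside the model family over the whole 0–1400 ms fit
  window; a steeper slope would cross baseline inside the window, where
  the generator clips at baseline, and bias recovery.
* **Alpha** (occipital): a 10 Hz oscillation whose envelope dips by a
  fractional depth (default 0.3, Gaussian σ 150 ms) at the expected target
  time.
* **Delta** (occipital): a 1.5 Hz cosine under a Gaussian envelope
  (5 µV peak, σ 600 ms) positioned backward from the target so its Hilbert
  phase at target time equals a draw from von Mises(subject's optimal
  angle, κ); κ defaults to 2 in predictive conditions, 0.3 in Random.
  This construction is a generator convenience, not a mechanistic claim.
* **P3** (parietal): a Gaussian bump (8 µV, σ 70 ms) peaking 350 ms after
  the target, 40 ms later on invalid trials.
* **RT**: base (330 ms predictive, 365 ms Random) + validity penalty
  (45/25/10 ms for Rhythmic/Repeated-Interval/Random) − a·cos(φ − optimal
  angle) with a = 20 ms, plus Gaussian noise (SD 50 ms), floored at 50 ms.
  The equal predictive-condition base encodes the equal-benefit /
  unequal-cost structure of the behavioural findings.
* **Noise**: spectrally shaped 1/f (exponent 1, SD 8 µV) plus white noise
  (SD 5 µV) per channel, independent across channels — against the −5 µV
  CNV peak this is realistic single-trial SNR.

What the generator does **not** emulate: volume conduction and channel
covariance, eye/muscle artifacts, evoked responses to the stream stimuli,
non-stationary noise, or any mechanistic link between the delta component
and the CNV.  Passing recovery tests therefore validates the analysis
chain, not claims about real-data effect sizes.

Known measurement attenuation: at this SNR the delta-phase estimator
(per-electrode Hilbert phase, then unweighted circular averaging — the
convention of the original analysis) attenuates ITPC by roughly 20–25%,
because unit phasors weight noisy electrodes equally.  Inverting measured
ITPC through the von Mises Bessel ratio therefore *underestimates* κ; the
recovery test divides the measured ITPC by the measurement-kernel
concentration ρ = |E exp(i(measured−drawn))| (available from the
ground-truth sidecar) before inversion.  Amplitude-weighted averaging
would reduce the attenuation but is not the convention implemented.

## Analysis pipeline

* Preprocessing: linked-mastoid re-referencing (nose reference supported);
  zero-phase Butterworth filters, 4th order per pass ("24 dB/octave" read
  as the one-pass slope; order exposed); delta band-pass 0.5–3 Hz applied
  to unsegmented data before epoching; artifact rejection at |x| > 100 µV
  or >100 µV max−min inside any sliding 200 ms window; RT cleaning at
  <50 ms or beyond 3 SD of the subject's condition × validity cell
  (single pass).
* CNV: buildup = mean amplitude 400–700 ms post-WS (baseline −200–0 ms);
  resolution = least-squares fit of the five-parameter piecewise model to
  the group-average waveform (Nelder–Mead from a grid of ≥ 27 restarts;
  ordering enforced by fitting nonnegative segment lengths), compared to
  the four-parameter (T1 = T2) variant by Gaussian BIC
  n·ln(SSE/n) + k·ln n, with ΔBIC > 6 labelled strong evidence.
* P3: fractional-peak latency (mean of the 30/50/70% rising-flank
  crossings, linear interpolation) in 200–550 ms post-target, baseline
  200 ms pre-WS, cells split by the SOA at which the target appeared.
  Before estimation the average is low-passed at 20 Hz (zero-phase): on
  noisy averages the raw in-window maximum overestimates the peak and
  drags the fractional crossings later, more so in low-trial cells, which
  biases latency *contrasts*; the smoothing removes this bias (verified by
  simulation at grand-average noise levels) without shifting a slow
  positive component.  Group inference uses leave-one-subject-out grand
  averages with the standard (n−1) jackknife correction of the t
  statistic (exact for linear statistics).
* Delta phase: ITPC and circular means at target time; each subject's
  optimal phase from the circular mean of the fastest third of Random
  trials (per SOA); group alignment tested with the V test
  (V = Σcos(θᵢ−θ₀), u = V√(2/n), one-sided normal p).
* Time–frequency: complex Morlet family, 1–30 Hz in 1 Hz steps, σ_f = f/8
  (ratio 8), normalised to unit gain for a sinusoid at the centre
  frequency (under this normalisation white noise rises as √f — a
  property, not a bug); 1000 ms edges discarded.  Alpha statistic: mean
  8–13 Hz amplitude at 700–900 ms post-WS, baseline 0–100 ms post-WS
  (subtraction by default, ratio mode available), long-SOA-target trials
  only.
* Group statistics: within-subject ANOVA via orthonormal effect
  contrasts with Greenhouse–Geisser ε and partial ω²
  (ω²ₚ = df·(F−1)/(df·(F−1) + n·cells-of-effect)); permutation ANOVA
  permuting cell labels within subject (synchronised), 10 000 default
  permutations, p = (1+#{F* ≥ F})/(1+n);
  circular–linear mixed model RT ~ sin φ + cos φ + SOA with by-subject
  random intercepts and sin/cos slopes (full covariance), ML-fitted for
  LRTs — fixed phase (2 df), random slopes (5 df = full 3×3 covariance vs
  intercept-only), and an SOA × phase-angle shift tested with the 1-df
  local term sin(φ − θ̂)·SOA, the first-order parametrisation of an angle
  difference.  The optimal angle is the RT-minimising direction
  atan2(−β_sin, −β_cos).  Optimizers: Powell first, with lbfgs/Nelder–Mead
  fallbacks (each fails differently on boundary fits).

## Numerical and design choices

* All times are integer milliseconds, trial start = 0, onsets mark the
  first sample of the 100 ms stimulus.
* Concatenated impulse trains place 500 ms fixation before each trial and
  a configurable inter-trial gap after it.  A *fixed* gap imprints a comb
  periodicity that systematically cancels or boosts energy at the
  stimulation frequency, so the spectral/autocorrelation summaries use
  jittered gaps and per-sample-normalised spectra; per-trial simulation is
  unaffected.
* RK4 step-halving (1 vs 0.25 ms) agrees within 1e-3 rad on smooth
  segments; fits floor SSE at 1e-12 before the BIC log.
* Degenerate inputs: catch trials are skipped (with a warning) by the
  entrainment simulation; zero-variance jackknife inputs are flagged;
  all-zero waveforms fit with S1 ≈ 0 and a degeneracy flag; groups with
  fewer than three RTs skip the SD rule.

## Problem sizes in the default test run

Chosen to exercise every claim at meaningful power: the end-to-end
recovery study uses 19 subjects × a full 10-block session at 256 Hz;
entrainment acceptance uses 48 trials × 97 oscillators per cell; type-I
checks use 200–300 replicates (permutation ANOVA; binomial 99% acceptance
bands), 120/60 replicates for the mixed model, and 15–30 noisy replicates
for BIC model-selection consistency.  The full suite runs in ~8 minutes on
one CPU.
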