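# Methods

This note documents the models, estimators and design decisions behind
`optotheta`, in the spirit of a methods section: what each procedure
assumes, which knobs matter, and what the synthetic validation does and
does not establish.

## Conventions

Time is in seconds (float64), intervals are half-open `[start, end)`,
sample indices are 0-based, LFP values are microvolts.  Every stochastic
routine takes a seed (or `numpy.random.Generator`); all session-level
randomness derives from `SynthConfig.seed` through a single
`SeedSequence`, so a seed fixes the session exactly, across platforms up
to floating-point reproducibility of NumPy/SciPy kernels.

## The synthetic session generator

The generator (`optotheta.synth`) emulates a 10-minute urethane-state
optogenetic session: 5-s light pulses every 20 s (onsets 15, 35, …,
595 s), a CA1 laminar probe (default 8 contacts spanning stratum oriens
to stratum radiatum, pyramidale in the middle) and septal channels, and
40 sorted units per region.

**LFP composition.** Each hippocampal channel is the sum of

* a **1/f background** (one-sided PSD `66/f` µV²/Hz, flattened below
  0.5 Hz), independent per channel;
* a **slow oscillation** (0.5–3 Hz band-limited noise with order-4
  Butterworth skirts, so it stays out of the theta measurement band; 80 µV
  sinusoid-equivalent amplitude) shared across hippocampal channels, with
  a per-20-s-block amplitude factor (below);
* a **theta drive** (50 µV) shared with the septal channels;
* **gamma** components (20–40 Hz at 10 µV, 60–140 Hz at 5 µV),
  independent per channel;
* **sharp-wave ripple events**: Poisson at 0.3 events/s, thinned by the
  factor 0.827 inside light pulses; each event is a Gaussian-windowed
  140–160 Hz burst of 50–80 ms riding a sharp wave whose polarity is
  positive above the pyramidal layer, negative below, and whose ripple
  amplitude decays away from pyramidale.

**Theta drive.** The drive is a slowly drifting sinusoid (4.7–6.3 Hz,
centred on 5.5 Hz, ~1 min drift coherence so the frequency is stable
across an off/on epoch pair and the peak ± the 0.6 Hz analysis
half-bandwidth stays inside 4–7 Hz) plus a *causally driven* AR(2)
resonance at the same centre (~3 Hz bandwidth) holding 10 % of the power
(`theta_stochastic_share`).  Both ingredients are necessary: the
deterministic part keeps the theta power of a 5-s window stable enough
for the paired on/off power contrast to be detectable at 30 trials, while
the stochastic part carries *innovations*.  The hippocampal copy of the
drive is the septal drive delayed by 20 ms (`ms_to_hp_lag`), so septal
innovations genuinely improve the prediction of the hippocampal signal —
the substrate of the Wiener–Granger directionality.  A purely
deterministic (or anticausally smoothed) drive is self-predictable and
makes the measured causality *decrease* with coupling strength; this is a
property of the measure, not a bug, and is why the stochastic component
is filtered causally (`scipy.signal.lfilter`).

During light pulses the hippocampal theta amplitude is multiplied by
√1.148 (+14.8 % power, `theta_power_gain_on`); in the cholinergic
blockade mode (`blockade_time_s`) the gain collapses to 1 from the given
time onward, reproducing a null contrast table.

**Slow-wave/causality coupling.**  Each 20-s block draws one standard
normal z; the MS→HP theta transfer factor is `exp(0.5 z)` and the
slow-oscillation amplitude is `exp(−|delta_gc_coupling| z)` (default
coupling −0.3).  High slow-wave power therefore co-occurs with weak theta
transfer, which the trial-wise Spearman contrast recovers as a negative
correlation.  Setting the coupling to 0 makes slow amplitude constant and
the correlation null.

**Ripple amplitude calibration.**  "Burst amplitude z" is defined in the
detector's own units: the whole-trace z-score of the smoothed ripple-band
envelope.  Because the events themselves inflate the normalizing SD, the
calibration is self-consistent (two passes): amplitudes are set against
the background-only envelope statistics, provisionally injected, and
rescaled against the statistics of the composed trace.  The default peak
is 6 z, and the per-duration envelope response is measured with a probe
burst (short bursts are attenuated more by the 20 Hz smoother).

**Spikes.**  Units are inhomogeneous Poisson processes (thinning) with
log-normal baseline rates (hippocampal excited-class units are low-rate
"putative pyramidal" cells that double their rate inside ripple events;
inhibited-class units are high-rate "putative interneurons"), von Mises
theta phase modulation (κ = 1, normalized so the mean rate is
phase-independent), a class gain inside light pulses, and a κ multiplier
of 1.5 during light (`kappa_gain_on`).  Class fractions and gains default
to the emulated study conditions: MS 21.5 % excited (×1.532) / 7.3 %
inhibited (×0.545), HP 20.2 % excited (×1.341) / 4.7 % inhibited
(×0.806); class counts are deterministic (`round(frac·n)`), per-unit
gains are log-normal with 10 % CV around the class gain.  The κ
multiplier exists because the emulated experiment reports increased
spike-field coherence and PPC during light; an LFP amplitude gain alone
cannot produce a measurable PPC change (PPC is independent of signal
amplitude up to phase-estimation noise).

**What the generator does not emulate.**  Conduction/volume effects,
anesthesia depth drift, non-Poisson spike history (bursting ISI
structure beyond the ripple boost), electrode drift and unit instability,
and the empirical *decrease* of septo-hippocampal causality during light
reported for the real preparation — in the generator, boosting theta
drive during pulses slightly *raises* measured MS→HP causality.  Passing
recoveries therefore certify the estimators against their own model
class, not against biological confounds.

## Estimator notes

**Multitaper spectra.**  Thomson's estimator with unit-energy DPSS
tapers; one-sided density scaled so the integral over [0, Nyquist] equals
the variance (checked against Parseval on white noise).  TW = 3 with
K = 5 tapers is the default; a 5-s epoch is a single window
(half-bandwidth 0.6 Hz).  Band power is reported as mean density over the
band (µV²/Hz), not the integral.  Spike-train spectra bin spikes at
1 kHz per epoch, subtract the epoch mean, and divide by the Poisson floor
`2·mean_count·dt` so a homogeneous Poisson train is flat at 1.

**Band contrast statistics.**  The normality of paired differences is
gated by the Lilliefors-corrected Kolmogorov–Smirnov test (mean and SD
are estimated, so the plain KS null is wrong); normal → paired *t*,
otherwise Wilcoxon signed-rank; Benjamini–Hochberg across the band
registry at α = 0.05.  Identical columns return p = 1 by convention.

**Ripple detection.**  The stages are all zero-phase (the FIR is applied
forward-backward via FFT convolution with reflection padding; the
Butterworth forward-backward, chosen for phase fidelity of the envelope —
the one-pass alternative would skew event timing).  The FIR targets a
0.5 Hz transition width (~3·rate/0.5 taps) capped at one third of the
signal length with a warning.  On Gaussian background the 3.5 SD
threshold admits noise events at ~0.07–0.11/s (the rectified-and-smoothed
envelope has only ~7 effective independent samples under the 20 Hz
smoother, hence a right-skewed tail); usable precision comes from the
variance the true events add to the whole-trace normalization, which
lifts the effective threshold.  Detection is gain-invariant by
construction (z-scoring).  The refractory rule *merges* a detection
starting within 50 ms of the previous end (one event, not a dropped
event).  Event peak time is the envelope maximum inside the event.

**Layer assignment.**  Stratum pyramidale is the channel with maximal
*induced* ripple-band RMS (event-span RMS of the 100–250 Hz signal,
averaged over events) — ripple cycles are not phase-locked to the
detected envelope peak, so they cancel in the evoked average and the
evoked profile's band RMS is uninformative.  The sharp-wave deflection
(mean over ±50 ms of the evoked profile) gives polarity; probe
orientation is inferred from the polarity itself (the positive side of
the reversal is oriens), so a flipped probe labels correctly.  The
ambiguity guard (no channel exceeding 1.5× the median RMS) returns
all-unknown with a warning.

**Sliding sweeps and shuffle null.**  Templates use 60 bins of 500 ms
over ±15 s; each trial is normalized to its own total spike count
(zero-spike trials are excluded from the average but counted), and the
test statistic is the mean mass of the ten bins covering [0, 5) s.  The
null exchanges inter-spike intervals and inter-onset intervals
independently (the interval from the session start participates, so count
and span are conserved exactly) and rebuilds timestamps from zero; 1000
shuffles, two-sided 95 % percentile band.  Per-unit effect size is the
percent change of the on-epoch rate over the off (non-pulse) rate.

**PPC.**  Computed via the exact incoherent-sum identity
`(|Σe^{iθ}|² − N)/(N(N−1))` (equal to the O(N²) pairwise mean cosine to
~1e−16).  The phase at each grid frequency f comes from the Hilbert
transform of the LFP band-passed to f ± 0.5 Hz (the narrowest band that
resolves the 0.25 Hz grid without empty passbands); phase 0 is the cosine
peak.

**Coherence.**  Magnitude-squared multitaper coherence with cross- and
auto-spectra summed over tapers and trials; a single segment is rejected
(the estimator degenerates to 1).  The spike channel is the
mean-subtracted 2 ms-binned count sequence.

**Granger causality.**  Two-channel VAR by stacked OLS (mean-subtracted,
residual covariance with df correction, companion-matrix stability
check), then Geweke's spectral measure on an `n_freq = 1000` grid over
[0, Nyquist).  The measure is invariant to common rescaling and exactly
zero for block-diagonal models (clamped at 0 against rounding).  The
pipeline default fit is order 20 on 5-s epochs at 500 Hz: the 40 ms
history covers the 20 ms septo-hippocampal lag while limiting
self-prediction of the narrowband theta drive; order 50 (the classical
choice for this preparation) is available as a knob but is
variance-heavy on 2500-sample trials and, on this generator, lets the
target's own history absorb the drive, inverting the coupling–causality
relation.  Trials are pooled by averaging causality spectra per
condition, not by concatenating data.  The slow-wave contrast correlates
trial-wise theta-band causality with slow-band (0.5–3 Hz) power
(Spearman) and extracts the 5th-percentile trial subsets; for it the
3–7 Hz band is used (the generator's theta wanders up to ~6.8 Hz and the
LFP–MUA variant of the analysis is defined on 3–7 Hz), while tabulated
LFP–LFP contrasts use 3–6 Hz.  The contrast requires ≥ 40 trials so the
5 % subsets hold at least two; validation uses ~34-minute sessions
(~100 trials).

**MUA signal.**  Pooled 2 ms spike counts, Gaussian-smoothed (σ = 10 ms),
mean-subtracted, at 500 Hz.

## Validation problem sizes

Parameter recoveries run on 20 generator seeds each: 600-s one-channel
sessions for the power contrast and ripple density, 120-s traces for
detector recall/precision (~36 events each) plus 20 isolated 60-ms bursts
per trace for onset accuracy, full 80-unit sessions for classification
(1000 shuffles/unit), and ~2020-s two-channel sessions for the
slow-wave/causality contrast.  Theta-band significance is assessed on the
600 pooled trials (a single 30-trial session has roughly 50 % power for a
+14.8 % change under this generator — comparable to a single real
recording — while the null bands are checked per session against their
FDR false-positive budget).  These sizes keep the whole validation suite
in the tens of minutes on one core while leaving each recovery's sampling
error well inside its tolerance, except where noted: the pooled density
contrast carries ~±4 percentage points of Poisson noise against a ±6
point tolerance.

## Known limitations

* The detector's noise false-positive rate on burst-free Gaussian traces
  (~0.1/s at a literal 3.5 SD) means precision is only meaningful on
  traces that contain events at a realistic rate; on nearly-empty traces
  most detections are envelope noise.
* Layer assignment assumes one contiguous laminar span per shank and a
  single polarity reversal.
* The VAR/Geweke chain assumes linear-Gaussian dynamics; the measured
  causality magnitudes depend on generator SNR and are not calibrated to
  any particular tissue value — only signs, directions and injected
  contrasts are validated.
* Per-trial normalized PPC/coherence changes during light reflect the
  injected κ gain; nothing is claimed about mechanism.
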