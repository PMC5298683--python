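# Methods

## Signal model

A transit of duration `T` (drawn uniformly from the species'
`transit_ms_range`, default 60–140 ms, mean 100 ms — the average dwell time
of a fruit fly in the sensor's field of view) is modelled as

    x(t) = e(t) · [ A_body + A_wing · Σ_k a_k sin(2π k f0 (1+δ_k) t + φ_k) ]

* `e(t)` — a raised-cosine bell over the transit. The true envelope shape
  is not constrained by the hardware; a raised cosine reproduces the smooth
  rise and fall seen in recorded transits.
* `A_body` — the near-DC body-occlusion amplitude. Its spectrum is
  confined well below 50 Hz for ~100 ms transits.
* `a_k = decay^(k-1)` — geometric harmonic decay, default 0.6 over five
  partials, chosen so the fifth partial stays resolvable above a −75 dB
  noise floor at 50 dB SNR. Partials at or above the 2 kHz Nyquist
  frequency are dropped rather than aliased.
* `δ_k` — fractional detuning of partials k ≥ 3, uniform in ±1 % by
  default; real higher partials are slightly detuned from exact harmonic
  positions.
* Phases `φ_k` are uniform.

White Gaussian noise is added and rescaled so that the realised
`20·log10(clean_rms/noise_rms)` equals the requested SNR exactly (default
50 dB, the level observed in operational recordings). The stream generator
instead lays a constant −75 dB RMS white noise floor (the acquisition
system's measured noise level) and inserts clean transits additively;
whiteness is an assumption, as only the floor level is known.

Species presets: *B. oleae* 170–230 Hz (the span its wingbeat covers over
the 15–35 °C activity range; `f0_at_temperature` maps temperature linearly
onto it); *C. capitata* and *L. aristella* use the same band — their
spectra overlap the target's almost completely — and differ only in
harmonic decay (0.55 / 0.65) and body amplitude, which is what makes the
"overlapping" classification task genuinely hard; *Drosophila* 260–310 Hz
at half the optical modulation amplitude (smaller insect); mosquitoes
350–700 Hz at roughly one-sixth amplitude. The mosquito band is a design
choice — only "higher than *Drosophila*" is known — placed safely above
the 170–230 Hz rule band.

What the generator does **not** emulate: optics (light-guide response, LED
intensity maps, polariser gain), amplitude statistics of real species
(unpublished; rule limits are therefore *calibrated* on synthetic
positives, not copied), overlapping transits, temperature drift within a
recording, and non-white interference. Passing tests demonstrate the
correctness of the processing chain under this model, not field-level
classification accuracy.

## Trigger

A sliding 128-sample RMS window (16 ms) advances one sample at a time (a
`hop` parameter trades fidelity for speed); the trigger index is the last
sample of the first window whose RMS reaches the threshold, and the
snippet spans indices `[t−199, t+824]` inclusive — 50 ms before and up to
the trigger, 206 ms after. Extraction goes through an explicit 16 K-sample
circular buffer with an overrun error if the span has been overwritten.
Triggers earlier than 199 samples into a stream are head-padded with
zeros (the hardware never faces this case because its buffer is
pre-filled).

The hardware stores its threshold on an SD card without publishing the
value; the default here is 12 dB above the noise-floor RMS
(`default_threshold()`), and `calibrate_noise_threshold()` estimates the
floor from the first second of a signal-free stream. A refractory interval
equal to the 824-sample post-window suppresses re-triggering on the tail
of the transit that caused the event — the physical trap relies on shields
around the sensor for the same purpose.

## Spectral estimation

PSD: average of Hamming-windowed (symmetric taper), 256-point modified
periodograms, one-sided density scaling (interior bins doubled, DC and
Nyquist not), log-transformed as `10·log10`. Two overlaps are meaningful
for a 1024-sample snippet: 0 (4 segments, the descriptive worked example)
and 192 (13 segments, the setting the classifier features use). The
129-bin grid spans 0–2000 Hz in 15.625 Hz steps; the 170–230 Hz rule band
covers bins 11–14 (171.875–218.75 Hz), band edges inclusive on bin
centres. The estimate keeps both the dB values and the linear powers so
band energies sum exactly (an all-zero snippet has band energy exactly 0).

SNR uses the `20·log10` RMS-ratio convention; the theoretical ADC bound is
`6.02·bits + 1.76` dB (86.04 dB at 14 bits). `estimate_f0` picks the
strongest bin in a search band, optionally refined by up to half a bin via
a parabola through the three surrounding log-powers, and flags the
estimate low-confidence when the peak rises less than 10 dB above the
spectrum's median level (near-DC bins excluded).

## Rule-based verifier

Rule 1 bounds the peak absolute amplitude of the mean-removed snippet
(peak chosen because amplitude limits are naturally drawn on waveform
extremes); Rule 2 requires the linear 170–230 Hz band energy to reach a
calibrated floor. Both must hold.

Calibration needs ≥ 50 single-species positives. Amplitude limits are the
1st/99th percentiles of per-snippet peak amplitude widened by ±10 %; the
band floor is the 5th percentile of the positives' band energy relaxed by
3 dB (linear factor 0.5). The relaxation mirrors the widening of the
amplitude limits: an un-relaxed 5th-percentile floor would, by
construction, reject ~5 % of held-out positives from the same population,
and the verifier is meant to pass ≥ 95 % of genuine targets after both
rules. All percentile and margin choices are module constants
(`AMP_PCT`, `AMP_WIDEN`, `BAND_PCT`, `BAND_MARGIN`).

By construction the verifier cannot separate the target from fruit flies
with overlapping spectra (*C. capitata*, *L. aristella*); it rejects all
synthetic mosquitoes and (through the amplitude rule and the band rule
jointly) well over 80 % of synthetic *Drosophila*, and is immune to
"walking" insects whose snippets carry only a body pulse.

## ML evaluation

Features are the 129 log-PSD bins at overlap 192, near-DC bins included
(body size is species-discriminative). Evaluation repeats a shuffled,
stratified 80/20 split 10 times (the repeated-holdout reading of the
published protocol; per-repeat seeds are spawned from one seed sequence,
so results are bit-reproducible); reported are per-repeat accuracies,
their mean/std, and the final repeat's confusion matrix with
precision/recall/F1 applied literally — metrics with zero denominators are
flagged undefined (NaN), never coerced to 0. Classifier presets ship the
published hyperparameters (linear SVC C=0.01; RBF SVM γ=0.009, C=0.2;
650-tree random forest and extra-trees; gradient boosting with
max_depth=4), plus a 100-tree `rf_small` used where runtime matters; any
fit/predict estimator can be passed instead.

The published field accuracies (88–92 % on 2473 undeposited recordings)
are not reproducible from synthetic data; the synthetic analogue asserts
only the structural ordering — the separable task (target vs
*Drosophila*) scores strictly above the overlapping task (target vs
*C. capitata* + *L. aristella*) under the default corpus composition
(913/623/166/771).

## Event log

Events are append-only JSON Lines records (timestamp ISO-8601 UTC,
latitude/longitude, temperature, humidity, verification decision, snippet
file reference, trigger RMS) — the payload a trap would queue for its
nightly uplink; transmission itself is out of scope. Snippets are stored
as mono 16-bit PCM WAV at 4 kHz, with out-of-range samples clipped under a
warning; quantisation changes a 50 dB snippet's measured SNR by well under
0.1 dB. Daily reports aggregate trigger/verified counts and environment
extremes per UTC date; night-time report scheduling is a configuration
concern, not enforced.

## Problem sizes and determinism

Defaults throughout are sized for a desk run: SNR calibration is checked
over 100 snippets per level, rule rejection rates over 200–500 snippets
per species, the end-to-end check on 60 s streams with 10 transits, and
the ML analogue on the full 2473-snippet composition with the 100-tree
forest. Every stochastic path takes an explicit seed or
`numpy.random.Generator`; there is no global random state, and identical
seeds give bit-identical corpora, splits and scores.
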