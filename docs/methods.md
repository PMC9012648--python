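# Methods

This note documents the models, numerical choices and limitations behind
`abrreref`: what is simulated, how the three reference reconstructions are
computed, how waves are scored, and what the synthetic benchmark can and
cannot establish about real recordings.

## The problem

The auditory brainstem response (ABR) is a far-field evoked potential in
the first ~10 ms after a click, with clinically scored positive peaks
(waves I, III, V) of a few tenths of a microvolt. All scalp EEG is a
potential difference against a reference, and the reference choice changes
ABR amplitude and morphology — but, being a fixed spatial linear map,
cannot change peak times. The package compares three reconstructions of a
recording acquired against a physical cap reference:

* **AR** — subtract the instantaneous mean of all channels;
* **MM** — subtract the mean of the left/right mastoid electrodes;
* **REST** — reference electrode standardization: approximately restore
  the potential against a point at infinity using a head-model lead field.

## Forward model

Head: three concentric spherical shells (brain / skull / scalp) with outer
radii 0.87 / 0.92 / 1.0 of the scalp radius (0.09 m) and relative
conductivities 1 / 0.0125 / 1 (skull 1/80) — the standard three-shell
configuration. The potential of a current dipole is expanded in solid
harmonics; each degree `n` is propagated through the shells by solving the
five boundary conditions (continuity of potential and radial current at
both interfaces, zero radial current at the scalp), and the series is
summed at the electrode directions. The expansion carries no `n = 0` term,
so potentials are infinity-referenced by construction. Truncation at
`n_terms = 60` leaves a relative tail below 1e-6 for sources out to the
equivalent-layer radius (the tail scales as `(r_src/R)^n`; at the layer
radius `r_src/R = 0.75`, `0.75^60 ~ 3e-8`). A closed-form homogeneous-
sphere solution (image form) serves as an independent oracle: with equal
conductivities the shell series matches it to better than 1e-6.

Electrode geometry is the idealised spherical 10/20 layout (Cz at the
vertex, circumferential electrodes on the equator at their 10% azimuth
spacings, intermediate electrodes midway along great-circle arcs), with
M1/M2 at 115 degrees inclination below the T7/T8 meridian and the
physical reference REF on the midline between Cz and CPz. Positions load
from and save to plain `label x y z` text.

## REST

Given the infinity lead field `G` (channels x 3-orientations x 500
equivalent-layer sources, layer at 0.86 of the brain radius on a Fibonacci
lattice) and its column-centred version `G_avg`, the transfer matrix is
`T = G G_avg^+`. The pseudo-inverse is a truncated SVD with relative
cutoff 1e-6 so conditioning is reproducible; centring removes exactly one
rank. Data are centred across channels before applying `T`, which makes
the operation invariant to whatever common-mode reference the input
carries and makes `T` idempotent.

A property worth knowing: for any source in the span of the layer, the
REST reconstruction error is *exactly* a channel-constant offset (the
unresolved common mode of partial scalp coverage). With 30 scalp + 2
mastoid electrodes that offset amounts to a relative RMS error of roughly
4-10% depending on source position (a few percent for superior sources,
worst for sources under the uncovered base of the head), shrinking as the
montage densifies — in line with published REST simulations at comparable
channel counts. For the deep midline brainstem generator used here, the Cz
waveform survives standardisation to within ~3.5%. Claims of sub-percent
recovery at 32 channels are not achievable with an overcomplete source
layer and upper-head coverage, and the test suite records that expectation
honestly rather than relaxing it.

## Synthetic sessions

The generator reproduces the acquisition this analysis assumes: 30 scalp
channels plus M1/M2 at 20 kHz, recorded against REF, click trains at
10/25/50/100 per s and 45-80 dB nHL in 5 dB steps, 4000 stimuli per trial,
two trials per condition, ten subjects.

**Sources.** Waves I-V ride a single deep equivalent dipole at
(0, 0.02, 0.01) m oriented superior-anterior — one deep midline source
reproduces the vertex-positive / mastoid-negative far field that makes
MM amplitudes exceed AR (measured MM:AR gain ratio ~1.9 at Cz). The
middle latency response (MLR) rides a separate, more superficial dipole
at (0, 0.03, 0.05) m.

**Waveform.** Each component is a derivative-of-Gaussian biphasic wavelet
whose positive peak sits at the component latency. Defaults: wave I at
1.60 ms, III at 3.65 ms, V at 5.60 ms (interwave I-III 2.05 ms, III-V
1.95 ms), II/IV midway between neighbours at half their mean amplitude,
widths 0.35 ms (I-IV) and 0.6 ms (V); relative amplitudes I : III : V =
0.28 : 0.33 : 1. The MLR is an 8 ms-wide wavelet peaking at 28 ms — late
enough that the 0-10 ms epoch of an isolated stimulus is MLR-free, while
at 100/s (10 ms interval) it superimposes on the following epochs, which
is exactly the contamination mechanism that degrades 100/s recordings.
Because wavelet tails overlap, the composite peak would sit tens of
microseconds off the nominal latencies; a short fixed-point calibration
offsets each scored component's centre so the *composite* brainstem
waveform peaks exactly at the nominal times. The calibration is
condition-invariant because the stimulus laws below scale or shift all
components together.

**Stimulus laws.** Latencies shift +0.3 ms per 10 dB below 80 dB nHL and
+0.2 ms per doubling of rate above 10/s; amplitudes halve per 20 dB below
80. The rate shift is applied to the whole response rather than to wave V
alone: interwave intervals are conduction-time proxies that the published
interwave tables report as stable at the base condition, so the default
template keeps them rate-invariant while wave V latency still grows
monotonically with rate.

**Scaling.** The source moment is calibrated once so the noiseless
infinity-referenced wave V peak-to-trough at Cz is 3.0 uV at 80 dB / 10
per s. The absolute scale is nominal: a three-shell sphere without real
anatomy cannot reproduce absolute microvolt amplitudes (the benchmark's
amplitude claims are therefore ordering and ratio claims, which are
scale-invariant). The value is chosen so that, with the default noise,
the post-average residual (~0.07 uV) sits 4-5x below wave I — the
signal-to-residual regime in which clinical peak scoring operates.

**Noise.** Background activity: 20 random equivalent-layer dipoles with
independent 1/f time courses band-limited to the amplifier band (AC
coupling below 1 Hz, low-pass 3 kHz), projected through the lead field and
scaled to a channel-average RMS of 8 uV, plus 1 uV white sensor noise per
channel. About 4.7 uV of the background falls inside the 100-1500 Hz
analysis band, so single-epoch SNR is ~0.05 and 4000-epoch averaging is
genuinely required. Per-subject variability: component amplitudes jittered
+-15%, source depth +-10%, orientations tilted up to 10 degrees. All
randomness derives from one seed via spawned generator streams;
identical configurations are bit-identical.

## Processing chain

3rd-order Butterworth band-pass 100-1500 Hz applied forward-backward
(zero phase, squared magnitude response): offline latency scoring must not
be biased by filter delay, and the commutation of the filter with the
(spatial) re-referencing operators is exact and tested. Clinical online
filtering is causal and shifts peaks; that difference is deliberate and
documented. Epochs are half-open 10 ms windows starting exactly at each
stimulus onset (200 samples at 20 kHz); windows that do not fit are
dropped with a warning; no artifact rejection. Averaging is the plain
arithmetic mean.

Alongside the average, the chain computes the plus-minus waveform (half
the difference of odd- and even-epoch sub-averages), the standard clinical
estimator of post-average residual noise: stimulus-locked signal cancels
in it exactly, and it passes through any linear re-referencing operator
the same way the data do. It replaces a late-window (8.5-10 ms) RMS as
the detectability floor because the late window contains stimulus-locked
energy (chiefly the wave V rebound of the zero-phase high-pass, ~11% of
wave V amplitude) that averaging does not reduce — a threshold built on
it flags clearly present waves as undetected even in noiseless data. The
late-window RMS remains the fallback for externally supplied averages.

## Wave scoring

Waves I/III/V are the largest positive local maxima inside search windows
anchored at 80 dB / 10 per s — I: [1.0, 2.4] ms, III: [3.0, 4.4] ms,
V: [4.8, 7.2] ms — shifted by the same rate/level laws the template uses.
Latency is parabolic-interpolated through the three samples around the
peak (one sample is 0.05 ms at 20 kHz, the same order as the tolerances of
interest). Amplitude is peak-to-following-trough within 1.5 ms (offset-
invariant, the dominant clinical convention); baseline-to-peak is
available as an option. A wave is `found` when its peak exceeds twice the
residual-noise RMS. Summaries report cross-subject mean and sample SD
(n-1), excluding unfound waves and reporting contribution counts.

## Problem sizes

The cross-subject benchmark runs 10 subjects x 4000 epochs x 32 channels
at 20 kHz (~4 minutes on one core). The rate/level series uses 1000-epoch
averages over 5 subjects and reports the across-subject *median* latency
per condition: at the lowest levels a 1000-epoch average leaves wave V
only a few residual-noise SDs above the floor, so a single subject's peak
pick can occasionally land on a noise excursion; the median states the
cohort's central tendency without letting one gross mis-pick corrupt the
series, while epoch counts, search windows and noise stay untouched.

## What passing does and does not show

The generator shares its forward model with the REST transform, so REST's
accuracy here reflects sampling (montage coverage), not head-model error;
on real heads REST inherits the mismatch between the template sphere and
the subject's anatomy, and its advantage over AR is accordingly smaller
and subject-dependent. Absolute amplitudes are nominal (see Scaling).
Background noise is stationary and Gaussian — no blinks, EMG bursts or
alpha; artifact-rejection behaviour is untested by design. Electrode
positions are idealised; digitised-cap deviations enter only through the
`label x y z` loader. Latency findings (interwave stability across
references, rate/level monotonicity) are the transferable results: they
depend on linearity and timing, not on the head model.

## Known limitations

* Spherical three-shell geometry only; no BEM/FEM or individual MRI models.
* The equivalent layer is fixed (500 triplets at 0.86 of the brain
  radius); no regularised or depth-weighted REST variants.
* Wave II/IV are rendered but not scored; no threshold-estimation logic.
* EDF export is 16-bit EDF+C with annotation-based events; proprietary
  acquisition formats are out of scope.
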