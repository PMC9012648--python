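# abrreref

EEG re-referencing for auditory brainstem response (ABR) extraction:
average reference (AR), mean mastoid (MM), and REST infinity
standardisation, compared end to end on multichannel click-evoked
recordings — with a three-shell spherical forward model, a synthetic
session generator, the full filter/epoch/average chain, and clinical-style
wave I/III/V scoring.

**Who it is for.** Auditory electrophysiologists and EEG methodologists who
want to quantify how the reference choice changes ABR amplitude and
morphology — and to verify that it cannot change latency — without waiting
on human recordings; and anyone needing a clean, tested REST implementation
for high-rate (20 kHz) evoked-potential data.

## The science in brief

Every scalp potential is measured against a reference. For a 32-channel
cap the three standard reconstructions of a recording `v` (channels x
time, acquired against a cap electrode) are

* **AR** `v_c - mean_c(v)` — unbiased only with dense whole-head coverage;
* **MM** `v_c - (v_M1 + v_M2)/2` — for the ABR's vertex-positive /
  mastoid-negative far field this *adds* signal at Cz;
* **REST** `T (v - mean_c(v))` with `T = G G_avg^+`, where `G` is the
  infinity-referenced lead field of an equivalent source layer in a
  three-shell sphere and `G_avg` its average-referenced version: because
  recorded data and lead field are linked by the same sources, `T`
  approximately restores potentials against a point at infinity.

All three are fixed spatial linear maps, so wave latencies — the
quantities clinical diagnosis rests on — are invariant, while amplitudes
order as MM > REST > AR at the vertex. The package demonstrates both on
simulated ten-subject sessions (4000-epoch averages, 25/s clicks at
75 dB nHL) and quantifies waves I/III/V per method.

## Worked example

```python
from abrreref import (SessionConfig, Session, bandpass, extract_epochs,
                      average_epochs, build_rest_transform,
                      rereference_waveform, detect_waves, interwave_latencies)

session = Session(SessionConfig(
    n_subjects=1, conditions=((25.0, 75.0),), n_stimuli=4000,
    n_trials=1, seed=0))
recording = session.simulate_trial(0, rate=25.0, level=75.0)     # 32 ch @ 20 kHz
avg = average_epochs(extract_epochs(bandpass(recording)))        # 0-10 ms mean
rest = build_rest_transform(session.leadfield.subset(list(avg.channel_names)))

for method in ("AR", "REST", "MM"):
    wave = rereference_waveform(avg, method, rest)
    peaks = detect_waves(wave, "Cz", rate_per_s=25.0, level_dB_nHL=75.0)
    iwl = interwave_latencies(peaks)
    print(f"{method:>4}: " + "  ".join(
        f"{w} {peaks[w].latency_ms:5.2f} ms / {peaks[w].amplitude_uV:4.2f} uV"
        for w in ("I", "III", "V"))
        + f"   I-III {iwl['I-III']:.2f}  III-V {iwl['III-V']:.2f}")
```

prints

```
  AR: I  2.00 ms / 0.64 uV  III  4.06 ms / 0.39 uV  V  6.00 ms / 2.07 uV   I-III 2.05  III-V 1.94
REST: I  2.00 ms / 0.81 uV  III  4.05 ms / 0.51 uV  V  5.99 ms / 2.62 uV   I-III 2.06  III-V 1.94
  MM: I  1.98 ms / 1.21 uV  III  4.06 ms / 0.81 uV  V  6.01 ms / 3.87 uV   I-III 2.08  III-V 1.95
```

Read it as: the three references disagree about *amplitude* (MM largest,
AR smallest, here nearly 2:1 at wave V) but agree about *latency* — the
interwave intervals I-III ~ 2.05 ms and III-V ~ 1.95 ms are the same to
within one 0.05 ms sample, which is the clinically decisive result.

The same chain runs from a shell: `abrreref run --out report/` reproduces
the whole rate (10-100/s) and level (45-80 dB nHL) grid with CSV/JSON
reports and figures; `abrreref simulate` exports sessions as EDF+ with
stimulus annotations; `abrreref reref --method rest ...` re-references an
existing EDF; `abrreref real` processes a recorded EDF plus a
`label x y z` electrode file.

The re-referencing operators are also exposed as scikit-learn
transformers (`AverageReference`, `MeanMastoidReference`, `RESTReference`,
`ButterworthBandpass`) over `(n_times, n_channels)` arrays and compose in
sklearn pipelines.

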