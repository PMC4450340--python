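# stresspcg

Segmentation and S1/S2 classification of heart sounds in stress-test
phonocardiograms — **without an ECG reference and without systolic/diastolic
interval timing**.

Classical heart-sound pipelines first locate candidate sounds and then
label them S1 or S2 by exploiting the fact that diastole (S2→S1) is longer
than systole (S1→S2).  Under a cardiac stress test — or in severe
tachycardia — the two intervals converge and that criterion collapses.
`stresspcg` is for biomedical-signal researchers and auscultation-tool
builders who need beat labelling in exactly that regime: every statistic it
computes is a property of a single sound's own time–frequency content.

## Method in brief

Sounds are localized with the Shannon-energy envelope of the Stockwell
transform (S-transform) S_x(t, f) = ∫ x(τ) w(τ−t, f) e^{−2πifτ} dτ, whose
Gaussian window has frequency-dependent width σ(f) = α/f.  Per time
column, with magnitudes normalized to [0, 1],

    SSE(τ) = − Σ_f |S(τ,f)|ⁿ log |S(τ,f)|ⁿ Δf ,   n = 1.5,

where the sub-classical exponent keeps faint sounds (typically S2 at high
heart rate) above threshold.  Each detected sound then receives four
scalar features:

| feature | definition | direction |
|---|---|---|
| α_opt | Gaussian width maximizing the energy-concentration measure CM(α) = 1/Σ\|S̄\|ΔtΔf over α ∈ {0.5 … 2.0} | S1 higher |
| β | time average of the peak-normalized SSE envelope, ∈ (0, 1] | S1 higher |
| γ | non-excess kurtosis of the SSE envelope of the unit-mass ST-spectrogram \|S\|² | S2 higher |
| hfs | wavelet (Daubechies-6 detail) Shannon-energy baseline | S2 higher |

S1 is booming, long and multi-component, so its sharpest representation
needs a wide window (large α_opt) and its envelope fills its analysis
window (large β); S2 is a short high-pitched snap, so its envelope is
peaky (large γ).  Classification is a single threshold on a single
feature — no training, no beat-interval logic.

Because no stress-test PCG corpus with beat-level verified labels is
publicly deposited, the package ships a first-class synthetic generator
(`stresspcg.synthpcg`) producing annotated recordings across 60–198 bpm
with the physiological couplings that make the problem hard (systole/
diastole convergence, sound compression and S2 treble loss at high heart
rate, beat-to-beat and between-subject morphological variability), plus an
evaluation harness (`stresspcg.evaluation`) with ROC/AUC, Mann–Whitney
tests, a noise-robustness sweep and segmentation scoring.
`docs/methods.md` documents every model assumption and default.

## Worked example

```python
from stresspcg import (SyntheticBeatConfig, generate_recording,
                       segment_recording, extract_features, classify_segments)

rec = generate_recording(duration=10.0,
                         config=SyntheticBeatConfig(hr=120.0),
                         snr_db=10.0, seed=42)
sounds = segment_recording(rec.signal)
extract_features(rec.signal, sounds)
classify_segments(sounds, feature_name="gamma", threshold=4.5,
                  direction="above_is_s2")
```

Printing the first detections against the generator's ground truth:

```
onset    dur    alpha  beta   gamma  label  truth
 0.032s   61ms  0.80  0.623  2.75  S1     S1
 0.211s   78ms  0.50  0.418  7.18  S2     S2
 0.547s   84ms  0.90  0.540  3.34  S1     S1
 0.708s   83ms  0.50  0.375  6.84  S2     S2
 1.006s   84ms  0.80  0.519  4.20  S1     S1
 1.156s   79ms  0.50  0.389  6.49  S2     S2
32/37 sounds labelled correctly at 120 bpm
```

Each row is one detected sound: its onset and duration, the three proposed
features and the γ-threshold label.  S1 rows show the expected signature —
wider optimal window (α_opt ≈ 0.8–0.9), envelope filling more of its
window (β ≈ 0.5–0.6), low kurtosis — while S2 rows pin α_opt near the grid
floor with γ ≈ 6–7.  A fixed threshold chosen once labels 86% of the
sounds of this noisy 120 bpm recording correctly; sweeping the threshold
(see the evaluation harness) puts γ's AUC near 0.97 across the whole
60–198 bpm ladder.

The same pipeline is scriptable from the shell:

```bash
stresspcg simulate --hr 150 --duration 10 --snr-db 10 --seed 7 --out rec.wav
stresspcg segment rec.wav --out sounds.csv
stresspcg features rec.wav sounds.csv --out features.csv
stresspcg evaluate --seed 1 --out report.json
```

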