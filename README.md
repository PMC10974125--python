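# mmgmotion

Estimation of upper-limb joint rotational acceleration from fused wearable
biosignals: mechanomyography (MMG) isolated from raw accelerometer traces by
differential-evolution-tuned variational mode decomposition (DE-VMD), a
six-stage sEMG/MMG conditioning pipeline, and an encoder-only transformer
sequence estimator with RNN/LSTM baselines.

## Who this is for

Researchers in neuromuscular signal processing and wearable human-motion
estimation who need (a) a reproducible DE-VMD implementation for separating
muscle vibration (10–50 Hz) from gross limb motion (< 10 Hz) and sensor
noise in accelerometer recordings, and (b) a windowed sequence-to-sequence
estimation stack from activation envelopes to joint kinematics. Human
recordings are not bundled; a synthetic generator reproduces the signal
structure with known ground truth, so every stage is testable end to end.

## The method in brief

**MMG isolation.** VMD decomposes a channel into K band-limited intrinsic
mode functions by ADMM in the frequency domain (Wiener-filter mode updates,
power-centroid frequency updates, bandwidth penalty α). K and α are tuned
per channel by differential evolution (DE/rand/1/bin) minimising the mean
envelope entropy

    E_e = −Σ_j e_j · lg e_j,   e_j = a(j) / Σ_j a(j),

where `a` is the Hilbert envelope: sparse, structured modes score low.
Modes are labelled by marginal-Hilbert-spectrum energy centroid —
pseudo-acceleration (< 10 Hz), MMG (10–50 Hz), noise (> 50 Hz) — and each
label group is summed. An EMD baseline decomposer is included.

**Conditioning.** DC removal → 10–450 Hz zero-phase Butterworth bandpass →
full-wave rectification → 5 Hz linear envelope → per-trial min–max
normalisation, applied identically to extracted MMG and raw sEMG.

**Estimation.** 1000 ms windows advance every 200 ms; each window is
summarised as a length-20 sequence of 8 envelope means (4 MMG + 4 sEMG).
An encoder-only transformer (d_model = 8, 2 heads, 1 layer, sinusoidal
position embeddings, padding masks, flatten-and-project head) maps the
input sequence to the length-20 target sequence of 3-axis rotational
acceleration. RNN and LSTM baselines share the head and the training
protocol (Adam on MSE, seeded, deterministic). Evaluation reports per-trial
R² as highest / lowest / mean over block-held-out test spans.

See `docs/methods.md` for assumptions, parameter tables and limitations.

## Worked example

```python
import numpy as np
from mmgmotion import (DEConfig, SyntheticConfig, assemble_recording,
                       extract_mmg)

sr = assemble_recording(SyntheticConfig(duration_s=20.0, seed=21))
raw = sr.recording.raw_accel.samples[0]      # one accelerometer axis
res = extract_mmg(raw, 1000.0, DEConfig(seed=4))
print("chosen K =", res.chosen_K, " alpha = %.0f" % res.chosen_alpha)
print("IMF labels:", [l.value for l in res.imf_labels])
print("recovery r = %.3f" % np.corrcoef(res.mmg, sr.true_mmg[0])[0, 1])
```

prints

```
chosen K = 6  alpha = 4667
IMF labels: ['PSEUDO_ACCELERATION', 'MMG', 'NOISE', 'NOISE', 'NOISE', 'NOISE']
recovery r = 0.840
```

The DE search settled on a six-mode decomposition; the lowest-frequency
mode is the limb-motion pseudo-acceleration, one mode carries the 10–50 Hz
muscle vibration, and the rest are rejected as noise. The recovered MMG
correlates at r = 0.84 with the generator's ground-truth vibration (an
ideal 10–50 Hz bandpass with oracle knowledge reaches ≈ 0.94 at the default
15 dB sensor SNR).

The full study — simulate 3 exercises × 5 trials × 60 s, extract all 60
channels, condition, window, train the three estimators and evaluate on
held-out blocks — runs from one call:

```python
from mmgmotion.pipeline import run_study
results = run_study(n_trials=5, duration_s=60.0, seed=1)
print(results["fusion"].reports["transformer"].mean)
```

A command-line interface exposes the stages individually
(`mmgmotion simulate | extract | preprocess | train | evaluate`), each
writing bundle/CSV artifacts plus a JSON run summary; see `--help`.

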