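# clicktypes

Discovery, classification and seasonal mapping of odontocete (toothed
whale) echolocation click types in long-term passive acoustic monitoring
data — exercised end-to-end on synthetic, calibrated soundscapes.

Autonomous seafloor recorders (HARP-style: 200 kHz sampling, 16-bit)
collect years of audio containing millions of biosonar clicks from
dolphins, beaked whales, *Kogia* and sperm whales, mixed with sonar and
snapping-shrimp noise. This package implements the analysis chain that
turns such recordings into species-level seasonal presence maps, for
bioacousticians and ecologists who need objective, repeatable click-type
analysis:

1. **Synthetic soundscapes** (`clicktypes.soundscape`) — Gabor-click
   trains from 14 parameterized type templates (peak frequency *f_p*,
   −3 dB bandwidth, modal inter-click interval; multi-peaked types as
   sums of quadrature Gabor components), lognormal ICI jitter, calibrated
   received levels, plus sonar-ping and random-impulse confounders, with
   a ground-truth table per click.
2. **Two-step detection** (`clicktypes.detector`) — 5-pole Butterworth
   bandpass 5–100 kHz; events where the 1 ms windowed peak-to-peak level
   exceeds 118 dB re 1 µPa, padded ±2.5 ms and merged below 2.5 ms
   separation; impulse segmentation at the 70th percentile of envelope
   energy with <100 µs merging and clipped-signal rejection; per-click
   features from 400-point Hann FFTs (500 Hz bins): *f_p*, −3 dB
   bandwidth, p2p level, duration, envelope.
3. **Two-phase unsupervised discovery** (`clicktypes.clustering`) —
   Chinese whispers label propagation on pruned similarity graphs
   (*p_e* = 0.95 within 5-minute bins on spectral shape, clicks
   ≥ 120 dB only; *p_e* = 0.98 across ≤ 40,000 bin-level summaries on
   spectral + envelope shape), pruning clusters under 25 bins / 50
   detections.
4. **Type catalog** (`clicktypes.catalog`) — median [p10, p90] statistics
   over 2,000 representative clicks and the ICI median-of-modes over
   1,000 bins (mass below 0.02 s suppressed), with four-panel review
   figures.
5. **Bin classification** (`clicktypes.classifier`) — balanced training
   sets (5,500 examples/class; 5,000/500 train/test, 80/20
   train/validation) on concatenated spectrum + ICI histogram + envelope
   features; a four-layer 512-unit ReLU softmax network; peak-sorted
   review artifacts; stratified false-positive-rate estimation and
   RL/clicks-per-bin threshold sweeps.
6. **Presence & sightings** (`clicktypes.presence`) — hours of acoustic
   presence summed per season, normalized by recording effort, averaged
   across years and scaled by (1 − FPR); visual sightings pooled per
   season inside 63–82° W / 24–46° N and matched to moorings within the
   ~2 km recording radius.

## Worked example

The numbered drivers under `analysis/` run a miniature two-site study
(`python analysis/01_synthesize_deployment.py 1`, then 02…06). With seed
1 they print:

```
GS: 180/180 planted clicks recovered (100.0%), 9 impulsive noise detections
NFC: 400/400 planted clicks recovered (100.0%), 0 impulsive noise detections
NFC: 6 bin summaries -> 2 type clusters (peaks [28.5, 32.5] kHz)
GS: 10 bin summaries -> 1 type clusters (peaks [99.5] kHz)
Gg: peak 32.5 kHz [32.5, 32.5], bw 4.5 kHz, modal ICI 0.135 s
NFC: 6/6 bins labeled with their planted type
GS: 10/10 bins labeled with their planted type
NFC  Spring Gg        1.0 h (FPR-scaled: True)
1 sighting(s) within the 2 km recording radius
```

Reading this: every planted click was redetected; the nine extra GS
detections are snapping-shrimp impulses, which the classifier routes to
its noise outgroup class rather than a click type. Unsupervised
clustering recovers one type cluster per planted type, with summary-peak
frequencies at the generating template values (28.5 kHz
common-dolphin-like, 32.5 kHz Risso's, 99.5 kHz *Kogia*, the latter
truncated at the 100 kHz Nyquist limit). The catalog stage reports the
median [10th, 90th percentile] statistics per type, and the presence
stage converts retained labels into effort-normalized seasonal hours; a
Risso's sighting 0.4 km from the NFC mooring is matched within the
recording radius. Tables land under `results/`, figures and WAVs under
`scratch/analysis/`.

A quick library-level session:

```python
import numpy as np
from clicktypes import *

cal = Calibration()                      # 140 dB re 1 µPa p2p at full scale
spec = SceneSpec(duration_s=8.0, bouts=(Bout("Gg", 0.5, 40, 125.0),), seed=7)
x, truth = synth_scene(spec, cal)
clicks = detect_clicks(x, spec.fs_hz, cal)
print(len(clicks), np.median([c.peak_freq_khz for c in clicks]))
# 40 32.5
```

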