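# Methods

This note documents the models, conventions and numerical choices behind
the `clicktypes` pipeline, and what its synthetic-data results do and do
not demonstrate about real recordings.

## Click synthesis model

Echolocation clicks are modeled as Gabor impulses: a Gaussian envelope
modulating a sinusoid. For envelope standard deviation σ_t the magnitude
spectrum is Gaussian with σ_f = 1/(2π σ_t), so peak frequency, −3 dB
bandwidth (BW = 2 σ_f √(0.3 ln 10) ≈ 1.66 σ_f) and duration are
independently controllable — the three quantities the catalog stage
measures. Multi-peaked types (Risso's dolphin, Cuvier's beaked whale,
several unidentified-delphinid types) are sums of Gabor components. Two
conventions matter there:

- component amplitudes are specified on the *spectral* scale (a
  narrowband component persists longer in time, so its time-domain
  amplitude is scaled by the bandwidth ratio to make the quoted relative
  amplitude appear in the spectrum);
- auxiliary components carry a 90° phase offset so their spectral tails
  add incoherently with the main peak instead of widening its −3 dB
  region.

Each template stores the type's median peak frequency, −3 dB bandwidth
and modal inter-click interval; auxiliary peaks follow the published
per-type descriptions (e.g. Risso's lower-amplitude peaks at 23.5 and
27 kHz). Snippet duration defaults to 8 σ_t of the narrowest component
(clamped to 100–1500 µs), keeping envelope truncation below −70 dB.
Real clicks are not Gabor impulses — they carry source/propagation
distortions, off-axis lowpass filtering and spectral notches the
generator does not emulate; parameter-recovery results on synthetic
corpora therefore validate the *measurement chain*, not detector
performance on real oceans.

The *Kogia* template (99.5 kHz peak at a 100 kHz Nyquist limit) is the
deliberate near-Nyquist case: its upper spectral tail is truncated, its
measured bandwidth is narrower than the generating value, and its
analytic-signal envelope beats at the 0.5 kHz fold frequency, stretching
measured durations. This mirrors the partial capture of these clicks at
a 200 kHz sampling rate and is why the candidate duration ceiling
defaults to a permissive 2 ms.

Inter-click intervals are lognormal with the distribution *mode* pinned
at the template's modal ICI (μ = ln m + σ², σ² = ln(1+CV²)), CV 0.15 by
default — the catalog summarizes ICI by histogram mode, so the generator
is parameterized in the same statistic. Received levels are specified as
peak-to-peak dB re 1 µPa through a single scalar calibration (full-scale
excursion ↔ 140 dB p2p by default); frequency-dependent hydrophone
response is out of scope. Background noise is white Gaussian whose 1 ms
windowed p2p excursion sits near the scene's noise-floor parameter
(σ = p2p/6.6). Confounders: long (20 ms) narrowband Hann-windowed sonar
pings at regular intervals, and snapping-shrimp-like impulses (short
wideband Gabors, random center frequency 20–80 kHz) at Poisson times.

## Detection conventions

The recording is bandpassed with a 5-pole Butterworth (5–100 kHz)
applied forward–backward, so click times are not skewed by filter delay
(the effective order doubles; Butterworth passbands are monotone so no
ripple is introduced). An upper edge exactly at Nyquist — the nominal
configuration at 200 kHz — degrades to the equivalent highpass.

"Peak-to-peak level at a sample" means the max-minus-min excursion of a
sliding 1 ms window. Samples at or above 118 dB re 1 µPa p2p seed
high-amplitude peaks; peaks closer than 2.5 ms belong to one event
(separation measured between peak times — padding-to-padding separation
would make the effective merge distance ~5 ms larger than the stated
one); events are padded ±2.5 ms, with overlapping padded extents of
distinct events clipped at their midpoint so the event list is sorted
and non-overlapping. All dB threshold comparisons carry a 0.01 dB guard
so a signal synthesized exactly at threshold survives 16-bit
quantization and filter round-off.

Within an event, impulses are located by samples whose amplitude
(doubled, as a p2p equivalent) reaches the detection threshold;
boundaries extend from each impulse peak through samples whose squared
analytic-signal envelope exceeds the event's 70th energy percentile,
stopping at the first sample below it. The envelope (rather than raw
squared samples) is used because oscillation nulls inside a click dip
below any percentile of raw energy, while ~30% of background samples
exceed the event's 70th percentile by construction — raw-energy
expansion either splits clicks or swallows the whole event. Impulses
closer than 100 µs merge; impulses touching 99.9% of full scale are
discarded as clipped.

Features per click: 400-point Hann FFT (500 Hz bins, 0–99.5 kHz grid of
200 bins; snippets shorter than one frame are centered and zero-padded,
Welch averaging at 50% overlap once a snippet spans ≥1.5 frames); peak
frequency = argmax bin; −3 dB bandwidth = width of the contiguous bin
run around the peak within 3 dB; p2p level from the calibrated
max-minus-min; envelope = |analytic signal| on a fixed 1 ms window
centered at the main peak (fixed *absolute* time axis, so envelope-shape
comparisons across clicks are meaningful). Candidate screening is
deliberately permissive (peak 5–100 kHz, duration 10–2000 µs; envelope
and bandwidth floors off by default): the goal is to catch undescribed
click types and let clustering/classification absorb non-click events.
The 5 ms sonar ping is rejected here by duration.

## Clustering conventions

Phase 1 bins a deployment into half-open 5-minute windows and clusters
each bin's clicks (≥120 dB p2p only) with Chinese whispers; phase 2
clusters up to 40,000 bin-level summaries per deployment (seeded uniform
subsample when more exist) and discards clusters with fewer than 25 bins
or 50 total detections.

Similarity: dB spectra restricted to 5–100 kHz are referenced to their
own noise floor (median level subtracted, negative excursions clipped),
min-max normalized and Pearson-correlated. Without the floor reference,
background-bin fluctuations dominate the correlation for narrowband
types. Phase 2 uses the arithmetic mean of this spectral similarity and
the correlation of normalized mean envelopes.

Edge pruning: the parameter *p_e* is a minimum-similarity cutoff —
edges with similarity below *p_e* are removed (0.95 in phase 1, 0.98 in
phase 2). The alternative reading of *p_e* as a quantile of the edge
weight distribution was implemented and rejected: it always removes 95%
of edges regardless of how similar the clicks are, which at desk-scale
bin sizes (tens of clicks) leaves mean degree ~2 and shatters
single-type bins into a dozen clusters. With the cutoff semantics a
homogeneous bin yields one cluster, spectrally distinct mixtures split
cleanly, and three planted types are recovered as three pure clusters.

Chinese whispers itself: every node starts with its own label; in a
fresh seeded random order per iteration, each node adopts the label with
the largest summed edge weight among its neighbors (ties broken by the
seeded RNG); stop on a pass with no changes or after 20 iterations. The
algorithm is order-dependent, which is why a fixed seed is part of every
clustering call.

## Catalog statistics

ICI histograms use 0.01 s bins with edges at multiples of 0.01 s over
[0, 1] s, so bin centers fall on x.xx5 values and every cataloged modal
ICI is representable as a center. The modal ICI of a histogram is the
center of its maximal bin after zeroing bins centered below 0.02 s
(suppressing the near-zero intervals produced when many animals click
simultaneously); ties go to the lowest center, and a histogram with all
mass suppressed returns an undefined-mode sentinel (`None`), never a
number. A consequence of the center convention: the smallest mode the
statistic can return is 0.025 s, the center of the first unsuppressed
bin. The per-type statistic is the median of per-bin modes, over up to
1,000 bins; spectral/bandwidth statistics are medians with 10th/90th
percentiles over up to 2,000 representative clicks (seeded uniform
subsamples; when fewer are available all are used and the counts
recorded).

## Classifier

Features concatenate three blocks, each min-max normalized to [0, 1]:
mean bin spectrum (200), ICI histogram (100 — the click-rate
information), mean envelope (200). Balancing draws exactly 5,500
examples per class: uniform subsampling for larger classes, Gaussian
noise augmentation (σ = 5% of the unit feature range, re-clipped) for
smaller ones; 5,000/500 train/test per class, with an 80/20
train/validation subdivision driving early stopping. The reference
architecture is four 512-unit fully connected ReLU layers with a softmax
output; the scikit-learn MLP backend realizes that stack with Adam
(batch 128, ≤100 epochs, patience 10) and uses early stopping as the
regularizer — the 50% dropout and batch-normalization layers of the
reference design are recorded in `NetworkSpec` but have no sklearn
equivalent. Analysis-scale runs use smaller hidden layers; the planted
synthetic classes are far easier than real inter-type variability, so
accuracy here bounds the plumbing, not field performance.

Review is modeled reproducibly: the package emits the peak-frequency-
sorted concatenated-spectra artifact an analyst would scan and applies
an externally supplied removal mask; the judgment itself is out of
scope. FPR is estimated per (class, site, deployment) stratum from up to
n seeded labels each, optionally averaged across repeated deployments at
a site; an empty stratum is reported as absent, never as zero. The
threshold sweep reports exhaustive FPR and retention over a grid of
received-level and clicks-per-bin floors; retention is monotonically
non-increasing in both by construction.

## Presence and sightings

An hour counts as present for a class if at least one retained bin of
that class starts in it (the bin-to-hour rule is a declared convention).
Seasons: Spring Mar–May, Summer Jun–Aug, Fall Sep–Nov, Winter Dec–Feb,
with December assigned to the following winter's season-year. Seasonal
presence-hour sums are divided by the recorded fraction of the season
(so normalized hours can never exceed the season's span), averaged
across years, and multiplied by (1 − FPR) — the declared scaling
convention for classifier error. Seasons with zero recording effort are
flagged as missing rather than zero. Sightings are pooled (not averaged)
per season across years inside 63–82° W / 24–46° N (longitudes stored
signed, negative west); the two *Kogia* species merge by genus.
Great-circle distances use the haversine formula (R = 6371.0088 km);
sightings within 2 km of a mooring are matched. Bubble-map area is
proportional to mean hours; zero-presence cells draw no bubble.

## Verification strategy and problem sizes

Oracle tests pin the parts with room for implementation error: a 16×
zero-padded dense-FFT bandwidth oracle, a literal-rule brute-force
segmenter scan, an independently coded Chinese whispers propagation
oracle on ≤8-node graphs (partition agreement on ≥95/100 random
instances — the algorithm is order-dependent), a spherical-law-of-
cosines distance oracle, and exhaustive-count FPR comparisons.
Behavioral recovery tests find the operating constants by sweeping
(amplitude in 1 dB steps, separation in 0.1 ms steps) rather than
reading configuration. Type-statistic recoveries run the full
detect-and-characterize chain over 2,000-click corpora (50 bins × 120
clicks for the ICI case); unit-test corpora use 500 clicks and
scaled-down cluster/classifier sizes, chosen so the whole suite runs in
a few minutes on one CPU while leaving every tolerance at the width of
one measurement grid cell (one 500 Hz spectral bin, one 0.01 s ICI bin).

## Known limitations

- No propagation, absorption, directivity or duty-cycle modeling; bouts
  specify received level directly.
- Single scalar calibration; no frequency-dependent sensitivity.
- Per-type click duration and amplitude distributions are declared
  defaults, not field-derived.
- The analyst steps (cross-site cluster merging into named types, label
  review) are represented by their input artifacts and mask interfaces,
  not by automated judgment.
- Phase-2 clustering materializes the full similarity matrix; at the
  40,000-bin cap this is memory-hungry (the cap exists for exactly that
  reason) — desk-scale runs stay far below it.
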