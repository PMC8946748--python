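"""Synthetic HARP-like soundscape generator.

Produces calibrated single-channel recordings (nominally 200 kHz, 16-bit)
containing odontocete-like click trains built from the click type
templates, plus background noise and impulsive/tonal confounders (sonar
pings, snapping-shrimp-like random impulses), together with a ground-truth
table of every synthesized click. Clicks are Gabor impulses: Gaussian
envelopes modulating sinusoids, the simplest waveform with independently
controllable peak frequency, -3 dB bandwidth and duration. Inter-click
intervals are drawn from a lognormal distribution whose mode is the
template's modal ICI.

Propagation, absorption, directivity and duty-cycle effects are not
modeled; received level is specified directly per bout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .calibration import Calibration, CalibrationError, FULL_SCALE_PP
from .templates import TYPE_TEMPLATES, TypeTemplate, get_template

__all__ = [
    "Bout",
    "SonarPingTrain",
    "ImpulseNoise",
    "SceneSpec",
    "make_click_template",
    "synth_click_train",
    "synth_scene",
    "write_scene",
    "read_wav",
]

TRUTH_COLUMNS = ["click_time_s", "template", "rl_db_pp", "bout_id"]


@dataclass(frozen=True)
class Bout:
    """A click train of one type: ``n_clicks`` clicks starting at ``start_s``."""

    template: str | TypeTemplate
    start_s: float
    n_clicks: int
    rl_db_pp: float

    def resolve(self) -> TypeTemplate:
        t = self.template
        return t if isinstance(t, TypeTemplate) else get_template(t)


@dataclass(frozen=True)
class SonarPingTrain:
    """Long-duration narrowband pings at a regular ping interval."""

    start_s: float
    freq_khz: float = 35.0
    ping_ms: float = 20.0
    interval_s: float = 1.0
    n_pings: int = 5
    rl_db_pp: float = 130.0


@dataclass(frozen=True)
class ImpulseNoise:
    """Snapping-shrimp-like broadband impulses at Poisson random times."""

    rate_hz: float = 0.5
    rl_db_pp_lo: float = 118.0
    rl_db_pp_hi: float = 128.0


@dataclass(frozen=True)
class SceneSpec:
    fs_hz: int = 200_000
    duration_s: float = 10.0
    noise_floor_db: float = 95.0
    bouts: tuple[Bout, ...] = field(default_factory=tuple)
    confounders: tuple[SonarPingTrain | ImpulseNoise, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        for b in self.bouts:
            if not (0.0 <= b.start_s < self.duration_s):
                raise ValueError(f"bout start {b.start_s} outside [0, {self.duration_s})")
            if not np.isfinite(b.rl_db_pp):
                raise ValueError("bout rl_db_pp must be finite")


def make_click_template(template: TypeTemplate, fs_hz: float) -> np.ndarray:
    """Synthesize one unit-peak-amplitude click waveform for a template.

    The waveform is a sum of Gaussian-enveloped cosines (one per spectral
    component) sampled at ``fs_hz``. Components may extend past the Nyquist
    frequency only in the near-Nyquist case (peak at or below Nyquist with
    the upper spectral tail truncated, as for Kogia at 200 kHz); a peak
    frequency above Nyquist is rejected.
    """
    nyq_khz = fs_hz / 2000.0
    if template.peak_freq_khz > nyq_khz:
        raise ValueError(
            f"peak frequency {template.peak_freq_khz} kHz above Nyquist {nyq_khz} kHz"
        )
    if template.duration_us <= 0:
        raise ValueError("duration_us must be positive")
    n = int(round(template.duration_us * 1e-6 * fs_hz))
    n = max(n | 1, 5)  # odd length so the envelope peak falls on a sample
    t = (np.arange(n) - n // 2) / fs_hz
    x = np.zeros(n)
    comps = template.all_components
    sigma_ref = comps[0].sigma_t_s
    for c in comps:
        env = np.exp(-(t**2) / (2.0 * c.sigma_t_s**2))
        # spectral peak ~ amp * sigma_t: rescale so rel_amp is spectral
        amp = c.rel_amp * sigma_ref / c.sigma_t_s
        x += amp * env * np.cos(2.0 * np.pi * c.freq_khz * 1e3 * t + c.phase_rad)
    return x / np.max(np.abs(x))


def _draw_icis(template: TypeTemplate, n: int, rng: np.random.Generator) -> np.ndarray:
    """Lognormal ICIs whose distribution mode equals the modal ICI."""
    cv = template.ici_jitter_cv
    if n <= 0:
        return np.zeros(0)
    if cv == 0.0:
        return np.full(n, template.modal_ici_s)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(template.modal_ici_s) + sigma2  # mode = exp(mu - sigma^2)
    return np.exp(rng.normal(mu, np.sqrt(sigma2), size=n))


def synth_click_train(
    template: TypeTemplate | str,
    n_clicks: int,
    rl_db_pp: float,
    start_s: float,
    cal: Calibration,
    seed: int | np.random.Generator = 0,
    fs_hz: float = 200_000.0,
    bout_id: int = 0,
    allow_clipping: bool = False,
) -> tuple[np.ndarray, float, pd.DataFrame]:
    """Synthesize one click train.

    Returns ``(waveform, segment_start_s, truth)`` where ``waveform`` is a
    float array covering the train (zero baseline), ``segment_start_s`` the
    scene time of its first sample, and ``truth`` one row per click. Each
    click's peak-to-peak excursion maps to ``rl_db_pp`` through ``cal``;
    levels beyond full scale raise :class:`CalibrationError` unless clipping
    is explicitly requested.
    """
    if n_clicks < 1:
        raise ValueError("n_clicks must be >= 1")
    tmpl = get_template(template) if isinstance(template, str) else template
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    snippet = make_click_template(tmpl, fs_hz)
    target_pp = cal.db_to_pp(rl_db_pp)
    scale = target_pp / (snippet.max() - snippet.min())
    if scale * np.max(np.abs(snippet)) > FULL_SCALE_PP / 2 and not allow_clipping:
        raise CalibrationError(
            f"rl_db_pp={rl_db_pp} dB clips at full scale "
            f"({cal.db_pp_at_fullscale} dB p2p); pass allow_clipping=True to force"
        )
    click = scale * snippet

    icis = _draw_icis(tmpl, n_clicks - 1, rng)
    onsets = np.concatenate([[0.0], np.cumsum(icis)])  # click-center times in train
    half = len(snippet) // 2
    n_total = int(round(onsets[-1] * fs_hz)) + len(snippet)
    x = np.zeros(n_total)
    centers = np.round(onsets * fs_hz).astype(int) + half
    for c in centers:
        x[c - half : c - half + len(snippet)] += click
    if allow_clipping:
        np.clip(x, -FULL_SCALE_PP / 2, FULL_SCALE_PP / 2, out=x)

    seg_start = start_s - half / fs_hz
    truth = pd.DataFrame(
        {
            "click_time_s": start_s + centers / fs_hz - half / fs_hz,
            "template": tmpl.name,
            "rl_db_pp": rl_db_pp,
            "bout_id": bout_id,
        }
    )
    return x, seg_start, truth


def _add_segment(scene: np.ndarray, seg: np.ndarray, start_idx: int) -> None:
    lo = max(start_idx, 0)
    hi = min(start_idx + len(seg), len(scene))
    if hi > lo:
        scene[lo:hi] += seg[lo - start_idx : hi - start_idx]


def _synth_sonar(ping: SonarPingTrain, fs: float, cal: Calibration) -> tuple[np.ndarray, int]:
    n_ping = int(round(ping.ping_ms * 1e-3 * fs))
    t = np.arange(n_ping) / fs
    w = np.hanning(n_ping)
    tone = w * np.sin(2 * np.pi * ping.freq_khz * 1e3 * t)
    tone *= cal.db_to_pp(ping.rl_db_pp) / (tone.max() - tone.min())
    hop = int(round(ping.interval_s * fs))
    out = np.zeros(hop * (ping.n_pings - 1) + n_ping)
    for k in range(ping.n_pings):
        out[k * hop : k * hop + n_ping] += tone
    return out, int(round(ping.start_s * fs))


def synth_scene(
    spec: SceneSpec, cal: Calibration | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a scene to a float waveform plus its ground-truth click table.

    Deterministic for a given ``spec`` (including its seed). Background is
    Gaussian noise whose 1 ms windowed peak-to-peak excursion sits near
    ``noise_floor_db``; confounders are added on top. The truth table lists
    only genuine clicks (confounders are, by construction, not clicks).
    """
    cal = cal or Calibration()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs_hz))
    # a 1 ms window of N(0, s) spans ~6.6 s peak-to-peak; map that to the floor
    sigma = cal.db_to_pp(spec.noise_floor_db) / 6.6
    scene = rng.normal(0.0, sigma, size=n)

    truths = []
    for bout_id, bout in enumerate(spec.bouts):
        seg, seg_start, truth = synth_click_train(
            bout.resolve(),
            bout.n_clicks,
            bout.rl_db_pp,
            bout.start_s,
            cal,
            seed=rng,
            fs_hz=spec.fs_hz,
            bout_id=bout_id,
        )
        start_idx = int(round(seg_start * spec.fs_hz))
        if start_idx + len(seg) > n:
            warnings.warn(f"bout {bout_id} extends past scene end; truncated")
            truth = truth[truth.click_time_s < spec.duration_s]
        _add_segment(scene, seg, start_idx)
        truths.append(truth)

    for conf in spec.confounders:
        if isinstance(conf, SonarPingTrain):
            seg, idx = _synth_sonar(conf, spec.fs_hz, cal)
            _add_segment(scene, seg, idx)
        elif isinstance(conf, ImpulseNoise):
            n_imp = rng.poisson(conf.rate_hz * spec.duration_s)
            times = rng.uniform(0, spec.duration_s, size=n_imp)
            for t0 in times:
                f = rng.uniform(20.0, 80.0)
                tmpl = TypeTemplate(
                    name="shrimp", peak_freq_khz=f, bw3db_khz=25.0, modal_ici_s=1.0
                )
                imp = make_click_template(tmpl, spec.fs_hz)
                rl = rng.uniform(conf.rl_db_pp_lo, conf.rl_db_pp_hi)
                imp = imp * cal.db_to_pp(rl) / (imp.max() - imp.min())
                _add_segment(scene, imp, int(round(t0 * spec.fs_hz)))
        else:  # pragma: no cover
            raise TypeError(f"unknown confounder {conf!r}")

    if truths:
        truth = pd.concat(truths, ignore_index=True).sort_values("click_time_s")
        truth = truth.reset_index(drop=True)
    else:
        truth = pd.DataFrame(columns=TRUTH_COLUMNS)
    half_fs = FULL_SCALE_PP / 2
    np.clip(scene, -half_fs, half_fs, out=scene)
    return scene, truth


def write_scene(
    spec: SceneSpec,
    wav_path: str | Path,
    truth_path: str | Path | None = None,
    cal: Calibration | None = None,
) -> tuple[Path, pd.DataFrame]:
    """Render a scene and write it as 16-bit PCM WAV (+ truth CSV)."""
    scene, truth = synth_scene(spec, cal)
    pcm = np.clip(np.round(scene * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(wav_path), int(spec.fs_hz), pcm)
    if truth_path is not None:
        truth.to_csv(truth_path, index=False)
    return Path(wav_path), truth


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a 16-bit PCM WAV into float samples in [-1, 1] and its rate."""
    fs, data = wavfile.read(str(path))
    if data.dtype != np.int16:
        raise ValueError(f"expected 16-bit PCM, got {data.dtype}")
    if data.ndim != 1:
        raise ValueError("expected mono recording")
    return data.astype(np.float64) / 32767.0, float(fs)
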