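"""Two-step echolocation click detector and per-click feature extraction.

Step 1 bandpasses the recording (5-pole Butterworth, 5-100 kHz) and finds
high-amplitude events: regions where the 1 ms windowed peak-to-peak level
exceeds 118 dB re 1 uPa, padded to include all samples within 2.5 ms of
each high-amplitude peak, with events whose peaks are separated by less
than 2.5 ms merged. Step 2 segments individual impulses inside each event
at the outermost samples around the main peak whose energy exceeds the
70th percentile of energy over the event, merges impulses separated by
less than 100 us, and discards clipped signals. Each retained impulse is
characterized (400-point Hann FFT at 50% overlap giving a 500 Hz grid,
peak frequency, -3 dB bandwidth, peak-to-peak level, analytic-signal
envelope) and screened against permissive thresholds spanning the
variability of known odontocete click types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import butter, hilbert, sosfiltfilt

from .calibration import Calibration, FULL_SCALE_PP

__all__ = [
    "DetectorConfig",
    "Event",
    "ClickRecord",
    "bandpass",
    "detect_events",
    "segment_clicks",
    "click_features",
    "filter_candidates",
    "detect_clicks",
    "records_to_frame",
]

N_FFT = 400  # 500 Hz resolution at fs = 200 kHz
N_SPEC_BINS = 200  # one-sided grid 0-100 kHz, Nyquist bin dropped
N_ENV = 200  # envelopes resampled to a fixed length for comparability

#: numerical guard on dB threshold comparisons, so a click synthesized
#: exactly at threshold survives 16-bit quantization and filter round-off
DB_GUARD = 0.01


@dataclass(frozen=True)
class DetectorConfig:
    band_low_khz: float = 5.0
    band_high_khz: float = 100.0
    filter_poles: int = 5
    pp_threshold_db: float = 118.0
    pp_window_ms: float = 1.0
    event_pad_ms: float = 2.5
    event_merge_ms: float = 2.5
    energy_percentile: float = 70.0
    click_merge_us: float = 100.0
    clip_level: float = 0.999 * FULL_SCALE_PP / 2
    # candidate screening; defaults span known odontocete click variability
    min_peak_freq_khz: float = 5.0
    max_peak_freq_khz: float = 100.0
    min_duration_us: float = 10.0
    max_duration_us: float = 2000.0  # permissive: near-Nyquist types beat-stretch
    min_bw3db_khz: float = 0.0
    max_envelope_spread: float | None = None  # fraction of snippet; None = off

    def __post_init__(self) -> None:
        if not (0 < self.band_low_khz < self.band_high_khz):
            raise ValueError("require 0 < band_low < band_high")
        if not (0 < self.energy_percentile < 100):
            raise ValueError("energy_percentile must be in (0, 100)")
        for name in ("pp_window_ms", "event_pad_ms", "event_merge_ms", "click_merge_us"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Event:
    """One high-amplitude event: sample extent plus its amplitude peaks."""

    start_idx: int
    end_idx: int  # exclusive
    peak_idxs: tuple[int, ...]

    def start_s(self, fs: float) -> float:
        return self.start_idx / fs

    def end_s(self, fs: float) -> float:
        return self.end_idx / fs


@dataclass
class ClickRecord:
    """A detected impulse with its waveform snippet and scalar features."""

    start_s: float
    end_s: float
    peak_time_s: float
    waveform: np.ndarray
    envelope: np.ndarray
    spectrum_db: np.ndarray
    peak_freq_khz: float
    pp_level_db: float
    bw3db_khz: float
    duration_us: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("require start_s < end_s")
        if len(self.spectrum_db) != N_SPEC_BINS:
            raise ValueError(f"spectrum must have {N_SPEC_BINS} bins")


def bandpass(x: np.ndarray, fs: float, cfg: DetectorConfig | None = None) -> np.ndarray:
    """5-pole Butterworth bandpass, applied forward-backward (zero phase).

    An upper edge exactly at Nyquist (the nominal 100 kHz band at 200 kHz
    sampling) degrades to a highpass at the lower edge, matching the
    effective response of the nominal recorder configuration.
    """
    cfg = cfg or DetectorConfig()
    nyq = fs / 2.0
    lo, hi = cfg.band_low_khz * 1e3, cfg.band_high_khz * 1e3
    if lo >= nyq or hi > nyq:
        raise ValueError(
            f"filter band {cfg.band_low_khz}-{cfg.band_high_khz} kHz invalid for fs={fs}"
        )
    if hi == nyq:
        sos = butter(cfg.filter_poles, lo, btype="highpass", fs=fs, output="sos")
    else:
        sos = butter(cfg.filter_poles, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, end_exclusive)."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [len(mask)]])
    return list(zip(starts.tolist(), ends.tolist()))


def detect_events(
    x_filt: np.ndarray, fs: float, cal: Calibration, cfg: DetectorConfig | None = None
) -> list[Event]:
    """Stage-1 high-amplitude event detection on a calibrated filtered signal.

    The peak-to-peak level at each sample is the max-minus-min excursion in
    a sliding window (default 1 ms). Threshold crossings are grouped into
    peaks; peaks separated by less than ``event_merge_ms`` belong to one
    event; each event is padded by ``event_pad_ms`` on both sides. The
    returned list is sorted and non-overlapping (padding of adjacent
    distinct events is clipped at their midpoint).
    """
    cfg = cfg or DetectorConfig()
    if len(x_filt) == 0:
        return []
    w = max(int(round(cfg.pp_window_ms * 1e-3 * fs)), 1)
    pp = maximum_filter1d(x_filt, w) - minimum_filter1d(x_filt, w)
    thr_pp = cal.db_to_pp(cfg.pp_threshold_db - DB_GUARD)
    mask = pp >= thr_pp
    runs = _runs_of(mask)
    if not runs:
        return []

    # one amplitude peak per threshold-crossing run
    peaks = [s + int(np.argmax(np.abs(x_filt[s:e]))) for s, e in runs]
    merge = cfg.event_merge_ms * 1e-3 * fs
    groups: list[list[int]] = [[peaks[0]]]
    for p in peaks[1:]:
        if p - groups[-1][-1] < merge:
            groups[-1].append(p)
        else:
            groups.append([p])

    pad = int(round(cfg.event_pad_ms * 1e-3 * fs))
    events = []
    for g in groups:
        events.append([max(g[0] - pad, 0), min(g[-1] + pad + 1, len(x_filt)), tuple(g)])
    # clip overlapping padded extents of distinct events at the midpoint
    for a, b in zip(events, events[1:]):
        if a[1] > b[0]:
            mid = (a[2][-1] + b[2][0]) // 2
            a[1] = mid
            b[0] = mid + 1
    return [Event(s, e, p) for s, e, p in events]


def segment_clicks(
    event_x: np.ndarray,
    fs: float,
    cal: Calibration | None = None,
    cfg: DetectorConfig | None = None,
) -> list[tuple[int, int]]:
    """Stage-2 impulse segmentation within one event waveform.

    Impulses are located by samples exceeding the amplitude threshold
    (a sample's amplitude counts peak-to-peak as twice its magnitude).
    Each impulse's boundaries are then the outermost samples reachable
    from its main peak through energy contiguously exceeding the event's
    70th energy percentile, where energy is the squared magnitude of the
    analytic signal (the envelope, so within-click oscillation nulls do
    not split an impulse while event noise still bounds it). Impulses
    closer than ``click_merge_us`` are merged, and any impulse touching
    full scale (clipped) is discarded. Returns (start, end_exclusive)
    sample boundaries.
    """
    cfg = cfg or DetectorConfig()
    cal = cal or Calibration()
    n = len(event_x)
    if n == 0 or np.ptp(event_x) == 0:
        return []
    env2 = np.abs(hilbert(event_x)) ** 2
    p = np.percentile(env2, cfg.energy_percentile)
    amp_thr = cal.db_to_pp(cfg.pp_threshold_db - DB_GUARD) / 2.0
    seeds = [
        s + int(np.argmax(np.abs(event_x[s:e])))
        for s, e in _runs_of(np.abs(event_x) >= amp_thr)
    ]
    if not seeds:
        return []
    intervals = []
    for pk in seeds:
        s = pk
        while s > 0 and env2[s - 1] > p:
            s -= 1
        e = pk
        while e < n - 1 and env2[e + 1] > p:
            e += 1
        intervals.append([s, e + 1])
    intervals.sort()
    gap = cfg.click_merge_us * 1e-6 * fs
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        if np.max(np.abs(event_x[s:e])) >= cfg.clip_level:
            continue  # clipped signals are discarded
        out.append((s, e))
    return out


def _spectrum_db(snippet: np.ndarray) -> np.ndarray:
    """Mean Hann-windowed 400-point FFT magnitude spectrum, in dB (relative).

    Snippets shorter than one frame are centered and zero-padded to a
    single frame; Welch-style averaging over 50%-overlapping frames is used
    once the snippet spans at least 1.5 frames.
    """
    n = len(snippet)
    win = np.hanning(N_FFT)
    if n < 3 * N_FFT // 2:
        frame = np.zeros(N_FFT)
        lo = (N_FFT - min(n, N_FFT)) // 2
        use = snippet[:N_FFT] if n > N_FFT else snippet
        frame[lo : lo + len(use)] = use
        mag = np.abs(np.fft.rfft(frame * win))
    else:
        hop = N_FFT // 2
        mags = []
        for s in range(0, n - N_FFT + 1, hop):
            mags.append(np.abs(np.fft.rfft(snippet[s : s + N_FFT] * win)))
        mag = np.mean(mags, axis=0)
    return 20.0 * np.log10(mag[:N_SPEC_BINS] + 1e-12)


def _bw3db_from_spectrum(spec_db: np.ndarray, peak_bin: int, df_khz: float = 0.5) -> float:
    """Width of the contiguous region around the peak within 3 dB of it."""
    level = spec_db[peak_bin] - 3.0
    lo = peak_bin
    while lo > 0 and spec_db[lo - 1] >= level:
        lo -= 1
    hi = peak_bin
    while hi < len(spec_db) - 1 and spec_db[hi + 1] >= level:
        hi += 1
    return (hi - lo + 1) * df_khz


def click_features(
    snippet: np.ndarray,
    fs: float,
    cal: Calibration,
    t0_s: float = 0.0,
) -> ClickRecord:
    """Compute a full ClickRecord from a raw impulse snippet.

    ``t0_s`` is the recording time of the snippet's first sample; the
    click time convention is the main-peak sample time.
    """
    snippet = np.asarray(snippet, dtype=float)
    if len(snippet) == 0:
        raise ValueError("empty snippet")
    spec = _spectrum_db(snippet)
    peak_bin = int(np.argmax(spec))
    env = np.abs(hilbert(snippet))
    peak_idx = int(np.argmax(np.abs(snippet)))
    # fixed absolute-time window (N_ENV samples) centered on the main peak,
    # so envelope shape comparisons across clicks share a time axis
    env200 = np.zeros(N_ENV)
    lo = peak_idx - N_ENV // 2
    src_lo, src_hi = max(lo, 0), min(lo + N_ENV, len(env))
    env200[src_lo - lo : src_hi - lo] = env[src_lo:src_hi]
    return ClickRecord(
        start_s=t0_s,
        end_s=t0_s + len(snippet) / fs,
        peak_time_s=t0_s + peak_idx / fs,
        waveform=snippet,
        envelope=env200,
        spectrum_db=spec,
        peak_freq_khz=peak_bin * 0.5,
        pp_level_db=float(cal.pp_to_db(snippet.max() - snippet.min())),
        bw3db_khz=_bw3db_from_spectrum(spec, peak_bin),
        duration_us=len(snippet) / fs * 1e6,
    )


def filter_candidates(
    record: ClickRecord, cfg: DetectorConfig | None = None
) -> tuple[bool, str]:
    """Retain-or-discard decision for a candidate click, with reason code."""
    cfg = cfg or DetectorConfig()
    if record.peak_freq_khz < cfg.min_peak_freq_khz:
        return False, "low_peak_freq"
    if record.peak_freq_khz > cfg.max_peak_freq_khz:
        return False, "high_peak_freq"
    if record.duration_us > cfg.max_duration_us or record.duration_us < cfg.min_duration_us:
        return False, "duration"
    if record.bw3db_khz < cfg.min_bw3db_khz:
        return False, "narrow_bandwidth"
    if cfg.max_envelope_spread is not None:
        env = record.envelope / (record.envelope.max() + 1e-12)
        spread = float(np.mean(env > 0.5))
        if spread > cfg.max_envelope_spread:
            return False, "envelope"
    return True, "keep"


def detect_clicks(
    x: np.ndarray,
    fs: float,
    cal: Calibration,
    cfg: DetectorConfig | None = None,
    t_offset_s: float = 0.0,
    return_discarded: bool = False,
):
    """Full detection pipeline: filter, find events, segment, characterize.

    ``t_offset_s`` shifts all reported times (recording start time of this
    waveform chunk within a longer deployment). Returns retained
    ClickRecords sorted by time; with ``return_discarded`` also a list of
    (record, reason) for screened-out candidates.
    """
    cfg = cfg or DetectorConfig()
    xf = bandpass(x, fs, cfg)
    records, discarded = [], []
    for ev in detect_events(xf, fs, cal, cfg):
        ex = xf[ev.start_idx : ev.end_idx]
        for s, e in segment_clicks(ex, fs, cal, cfg):
            rec = click_features(
                ex[s:e], fs, cal, t0_s=t_offset_s + (ev.start_idx + s) / fs
            )
            keep, reason = filter_candidates(rec, cfg)
            (records if keep else discarded).append(rec if keep else (rec, reason))
    records.sort(key=lambda r: r.peak_time_s)
    if return_discarded:
        return records, discarded
    return records


def records_to_frame(records: list[ClickRecord]) -> pd.DataFrame:
    """Scalar fields of ClickRecords as a table (one row per click)."""
    return pd.DataFrame(
        {
            "start_s": [r.start_s for r in records],
            "end_s": [r.end_s for r in records],
            "peak_time_s": [r.peak_time_s for r in records],
            "peak_freq_khz": [r.peak_freq_khz for r in records],
            "pp_level_db": [r.pp_level_db for r in records],
            "bw3db_khz": [r.bw3db_khz for r in records],
            "duration_us": [r.duration_us for r in records],
        }
    )


def save_detections(records: list[ClickRecord], out_dir: str | Path) -> Path:
    """Write detections as a CSV of scalars plus an NPZ spectra/envelope sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(out / "clicks.csv", index=False)
    np.savez(
        out / "clicks_arrays.npz",
        spectra_db=np.array([r.spectrum_db for r in records]),
        envelopes=np.array([r.envelope for r in records]),
    )
    return out
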