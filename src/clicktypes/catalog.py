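"""Per-type descriptive statistics and review figures.

Characterizes a click type by the median (with 10th/90th percentiles) of
peak frequency and -3 dB bandwidth over up to 2,000 representative
clicks, and by the median of per-bin modal inter-click intervals over up
to 1,000 five-minute bins. ICI histogram mass below 0.02 s is suppressed
before taking the mode, to reduce the contribution of high-density
encounters where interleaved click trains from many individuals saturate
the distribution with near-zero intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clustering import BinSummary, ICI_HIST_EDGES
from .detector import ClickRecord

__all__ = ["ICIConfig", "TypeProfile", "modal_ici", "characterize_type", "render_type_panel"]

ICI_CENTERS = (ICI_HIST_EDGES[:-1] + ICI_HIST_EDGES[1:]) / 2.0


@dataclass(frozen=True)
class ICIConfig:
    suppress_below_s: float = 0.02
    hist_bin_s: float = 0.01
    hist_max_s: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.suppress_below_s < self.hist_max_s):
            raise ValueError("require 0 < suppress_below_s < hist_max_s")


@dataclass
class TypeProfile:
    """One click type's descriptive statistics (a catalog row)."""

    name: str
    peak_freq_khz: tuple[float, float, float]  # (median, p10, p90)
    bw3db_khz: tuple[float, float, float]
    modal_ici_s: tuple[float, float, float] | None
    n_clicks_used: int
    n_bins_used: int
    median_spectrum: np.ndarray = field(repr=False, default=None)
    p10_spectrum: np.ndarray = field(repr=False, default=None)
    p90_spectrum: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        for triple in (self.peak_freq_khz, self.bw3db_khz, self.modal_ici_s):
            if triple is None:
                continue
            med, p10, p90 = triple
            if not (p10 <= med <= p90):
                raise ValueError(f"percentile ordering violated: {triple}")

    def suggest_name(self) -> str:
        """Suggested 'UD' name from the median peak frequency."""
        return f"UD{self.peak_freq_khz[0]:.0f}"

    def to_json(self, path: str | Path) -> None:
        d = {
            "name": self.name,
            "peak_freq_khz": self.peak_freq_khz,
            "bw3db_khz": self.bw3db_khz,
            "modal_ici_s": self.modal_ici_s,
            "n_clicks_used": self.n_clicks_used,
            "n_bins_used": self.n_bins_used,
            "median_spectrum": None
            if self.median_spectrum is None
            else np.asarray(self.median_spectrum).tolist(),
        }
        Path(path).write_text(json.dumps(d, indent=2))


def modal_ici(ici_hist: np.ndarray, cfg: ICIConfig | None = None) -> float | None:
    """Mode of an ICI histogram after suppressing mass below 0.02 s.

    ``ici_hist`` is counts on the standard 0.01 s grid over [0, 1] s.
    Returns the center of the maximal bin; ties go to the lowest bin
    center. If all mass lies below the suppression floor the mode is
    undefined and ``None`` is returned.
    """
    cfg = cfg or ICIConfig()
    hist = np.asarray(ici_hist, dtype=float)
    if hist.shape != (len(ICI_CENTERS),):
        raise ValueError(f"histogram must have {len(ICI_CENTERS)} bins")
    keep = hist * (ICI_CENTERS >= cfg.suppress_below_s)
    if keep.sum() == 0:
        return None
    return float(ICI_CENTERS[int(np.argmax(keep))])  # argmax: lowest tied bin


def _triple(values: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.median(values)),
        float(np.percentile(values, 10)),
        float(np.percentile(values, 90)),
    )


def characterize_type(
    clicks: list[ClickRecord],
    bins: list[BinSummary],
    cfg: ICIConfig | None = None,
    n_clicks: int = 2000,
    n_bins: int = 1000,
    seed: int = 0,
) -> TypeProfile:
    """Descriptive statistics for one type from representative samples.

    When more clicks/bins are available than the representative sample
    sizes (2,000 clicks, 1,000 bins), seeded uniform subsamples of exactly
    those sizes are used; otherwise all available are used and the counts
    recorded. The modal ICI statistic is the median of per-bin modes.
    """
    if not clicks:
        raise ValueError("need at least one click")
    cfg = cfg or ICIConfig()
    rng = np.random.default_rng(seed)
    if len(clicks) > n_clicks:
        idx = np.sort(rng.choice(len(clicks), size=n_clicks, replace=False))
        clicks = [clicks[i] for i in idx]
    if len(bins) > n_bins:
        idx = np.sort(rng.choice(len(bins), size=n_bins, replace=False))
        bins = [bins[i] for i in idx]

    spectra = np.array([c.spectrum_db for c in clicks])
    modes = [m for b in bins if (m := modal_ici(b.ici_hist, cfg)) is not None]
    return TypeProfile(
        name="",
        peak_freq_khz=_triple(np.array([c.peak_freq_khz for c in clicks])),
        bw3db_khz=_triple(np.array([c.bw3db_khz for c in clicks])),
        modal_ici_s=_triple(np.array(modes)) if modes else None,
        n_clicks_used=len(clicks),
        n_bins_used=len(bins),
        median_spectrum=np.median(spectra, axis=0),
        p10_spectrum=np.percentile(spectra, 10, axis=0),
        p90_spectrum=np.percentile(spectra, 90, axis=0),
    )


def render_type_panel(
    profile: TypeProfile,
    clicks: list[ClickRecord],
    bins: list[BinSummary],
    out_path: str | Path,
    cfg: ICIConfig | None = None,
) -> Path:
    """Four-panel summary figure for one click type.

    Panels: median spectrum with 10th/90th percentile envelopes; modal-ICI
    histogram over bins; concatenated normalized click spectra sorted by
    received level; concatenated normalized envelopes sorted by received
    level. The sorted concatenations are the artifacts an analyst scans
    when judging cluster quality.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cfg = cfg or ICIConfig()
    freqs = np.arange(200) * 0.5
    order = np.argsort([c.pp_level_db for c in clicks])
    spec_img = np.array([clicks[i].spectrum_db for i in order])
    spec_img = (spec_img - spec_img.min(axis=1, keepdims=True)) / (
        np.ptp(spec_img, axis=1, keepdims=True) + 1e-12
    )
    env_img = np.array([clicks[i].envelope for i in order])
    env_img = env_img / (env_img.max(axis=1, keepdims=True) + 1e-12)
    modes = [m for b in bins if (m := modal_ici(b.ici_hist, cfg)) is not None]

    fig, axes = plt.subplots(1, 4, figsize=(16, 3.5))
    axes[0].plot(freqs, profile.median_spectrum, "k-")
    axes[0].plot(freqs, profile.p10_spectrum, "k--", lw=0.8)
    axes[0].plot(freqs, profile.p90_spectrum, "k--", lw=0.8)
    axes[0].set(xlabel="Frequency (kHz)", ylabel="dB", title=profile.name or "type")
    axes[1].hist(modes, bins=ICI_HIST_EDGES, color="0.3")
    axes[1].set(xlabel="Modal ICI (s)", ylabel="bins", xlim=(0, 1))
    axes[2].imshow(spec_img, aspect="auto", origin="lower", cmap="viridis",
                   extent=[0, 100, 0, len(order)])
    axes[2].set(xlabel="Frequency (kHz)", ylabel="click (RL-sorted)")
    axes[3].imshow(env_img, aspect="auto", origin="lower", cmap="viridis")
    axes[3].set(xlabel="Envelope sample", ylabel="click (RL-sorted)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return Path(out_path)
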