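"""Echolocation click type templates.

Each template parameterizes a species-specific (or unidentified-delphinid)
click type by its median peak frequency, -3 dB bandwidth, and modal
inter-click interval, the three signal parameters that differentiate the
click types of western North Atlantic odontocetes. Multi-peaked types
(e.g. Risso's dolphin, Cuvier's beaked whale) additionally carry auxiliary
spectral components with relative amplitudes taken from the published
per-type descriptions.

Known-species codes: Gg Grampus griseus (Risso's dolphin); Mb Mesoplodon
bidens (Sowerby's); Md M. densirostris (Blainville's); Me M. europaeus
(Gervais'); Mm M. mirus (True's); Zc Ziphius cavirostris (Cuvier's);
Kogia Kogia spp.; Pm Physeter macrocephalus (sperm whale). "UD" types are
unidentified delphinid types named by median peak frequency in kHz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["SpectralComponent", "TypeTemplate", "TYPE_TEMPLATES", "get_template"]

#: -3 dB full width of a Gaussian magnitude spectrum in units of its sigma:
#: |S(f)| = exp(-(f-f0)^2 / (2 s^2)) drops 3 dB at delta = s*sqrt(0.3*ln 10).
_BW3DB_PER_SIGMA = 2.0 * math.sqrt(2.0 * (3.0 / 20.0) * math.log(10.0))


@dataclass(frozen=True)
class SpectralComponent:
    """One Gabor component of a (possibly multi-peaked) click template.

    ``rel_amp`` is the component's *spectral* peak amplitude relative to
    the main peak (narrowband components last longer in time, so their
    time-domain amplitude is scaled down accordingly at synthesis).
    Auxiliary components carry a quadrature phase so their spectral tails
    add incoherently with the main peak rather than inflating it.
    """

    freq_khz: float
    rel_amp: float
    bw3db_khz: float
    phase_rad: float = 0.0

    @property
    def sigma_f_hz(self) -> float:
        return self.bw3db_khz * 1e3 / _BW3DB_PER_SIGMA

    @property
    def sigma_t_s(self) -> float:
        # Fourier pair of the Gaussian envelope: sigma_t = 1 / (2 pi sigma_f)
        return 1.0 / (2.0 * math.pi * self.sigma_f_hz)


@dataclass(frozen=True)
class TypeTemplate:
    """A click type's generating parameters.

    ``peak_freq_khz``, ``bw3db_khz`` and ``modal_ici_s`` are the medians
    of the type's measured distributions; ``components`` lists auxiliary
    spectral peaks (the main peak is always included). ``duration_us`` is
    the synthesized snippet length; by default it is derived from the
    narrowest component so the Gaussian envelope is not truncated.
    """

    name: str
    peak_freq_khz: float
    bw3db_khz: float
    modal_ici_s: float
    duration_us: float = 0.0  # 0 -> derived from bandwidth
    ici_jitter_cv: float = 0.15
    components: tuple[SpectralComponent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (5.0 <= self.peak_freq_khz <= 100.0):
            raise ValueError(f"peak_freq_khz out of range: {self.peak_freq_khz}")
        if self.bw3db_khz <= 0:
            raise ValueError("bw3db_khz must be positive")
        if self.modal_ici_s < 0.02:
            raise ValueError("modal_ici_s must be >= 0.02 s")
        if self.duration_us == 0.0:
            longest = max(c.sigma_t_s for c in self.all_components)
            # 8 sigma keeps envelope truncation below -70 dB
            dur = min(max(8e6 * longest, 100.0), 1500.0)
            object.__setattr__(self, "duration_us", dur)
        if self.duration_us <= 0:
            raise ValueError("duration_us must be positive")

    @property
    def all_components(self) -> tuple[SpectralComponent, ...]:
        main = SpectralComponent(self.peak_freq_khz, 1.0, self.bw3db_khz)
        return (main,) + tuple(self.components)


def _t(name, pf, bw, ici, comps=()):
    return TypeTemplate(
        name=name,
        peak_freq_khz=pf,
        bw3db_khz=bw,
        modal_ici_s=ici,
        components=tuple(
            SpectralComponent(*c, phase_rad=math.pi / 2) for c in comps
        ),
    )


# Auxiliary-peak amplitudes follow the published type descriptions: Gg has
# lower-amplitude peaks at 23.5 and 27 kHz; Zc auxiliary peaks of
# successively decreasing amplitude at ~23.5, ~19 and ~72 kHz; UD26 a
# narrow lower peak near 19 kHz separated from the main peak by a deep
# notch; UD36 a lower peak at 26 kHz and shoulder at 23 kHz; UD47
# low-amplitude peaks at 20 and 28 kHz; UD38 auxiliary peaks at 16 and
# 19 kHz; Me/Mm a much lower-amplitude peak near 23.5/24.5 kHz.
TYPE_TEMPLATES: dict[str, TypeTemplate] = {
    t.name: t
    for t in [
        _t("Gg", 32.5, 4.5, 0.145, [(23.5, 0.30, 3.0), (27.0, 0.35, 3.0)]),
        _t("Mb", 67.0, 13.5, 0.135),
        _t("Md", 31.5, 7.5, 0.325),
        _t("Me", 46.5, 11.5, 0.285, [(23.5, 0.30, 4.0)]),
        _t("Mm", 47.5, 11.3, 0.185, [(24.5, 0.30, 4.0)]),
        _t("Zc", 38.5, 7.0, 0.465, [(23.5, 0.50, 4.0), (19.0, 0.35, 3.0), (72.0, 0.20, 6.0)]),
        _t("Kogia", 99.5, 7.0, 0.085),
        _t("Pm", 8.5, 3.0, 0.475),
        _t("UD36", 36.5, 5.5, 0.155, [(26.0, 0.45, 3.0), (23.0, 0.30, 3.0)]),
        _t("UD26", 26.5, 4.0, 0.165, [(19.0, 0.70, 2.5)]),
        _t("UD28", 28.5, 9.0, 0.075),
        _t("UD19", 19.0, 9.0, 0.135),
        _t("UD47", 47.0, 6.5, 0.065, [(20.0, 0.35, 3.0), (28.0, 0.35, 3.0)]),
        _t("UD38", 38.5, 8.0, 0.065, [(16.0, 0.30, 3.0), (19.0, 0.30, 3.0)]),
    ]
}


def get_template(name: str) -> TypeTemplate:
    try:
        return TYPE_TEMPLATES[name]
    except KeyError:
        raise KeyError(
            f"unknown click type {name!r}; known: {sorted(TYPE_TEMPLATES)}"
        ) from None
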