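"""Scalar calibration between waveform sample units and sound pressure.

Recorders here are modeled with a single full-scale mapping: a waveform
whose peak-to-peak excursion spans the full digitization range (+1 to -1
in float units) corresponds to ``db_pp_at_fullscale`` dB re 1 uPa
peak-to-peak. Frequency-dependent hydrophone sensitivity is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Calibration", "CalibrationError", "FULL_SCALE_PP"]

#: full-scale peak-to-peak excursion in float sample units (-1 .. +1)
FULL_SCALE_PP = 2.0


class CalibrationError(ValueError):
    """Raised when a requested level cannot be represented without clipping."""


@dataclass(frozen=True)
class Calibration:
    """Full-scale peak-to-peak level in dB re 1 uPa. Default 140 dB."""

    db_pp_at_fullscale: float = 140.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.db_pp_at_fullscale):
            raise ValueError("db_pp_at_fullscale must be finite")

    def pp_to_db(self, pp_samples: float | np.ndarray) -> float | np.ndarray:
        """Peak-to-peak sample excursion -> dB re 1 uPa p2p."""
        with np.errstate(divide="ignore"):
            return self.db_pp_at_fullscale + 20.0 * np.log10(
                np.asarray(pp_samples, dtype=float) / FULL_SCALE_PP
            )

    def db_to_pp(self, db: float | np.ndarray) -> float | np.ndarray:
        """dB re 1 uPa p2p -> peak-to-peak sample excursion."""
        return FULL_SCALE_PP * 10.0 ** ((np.asarray(db, dtype=float) - self.db_pp_at_fullscale) / 20.0)
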