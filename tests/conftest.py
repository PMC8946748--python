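"""Shared fixtures: calibrated synthetic corpora reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from clicktypes import Calibration, cluster_bin
from clicktypes.study import detected_bins, detected_corpus

FS = 200_000.0


@pytest.fixture(scope="session")
def cal() -> Calibration:
    return Calibration()


@pytest.fixture(scope="session")
def gg_records():
    """A detected corpus of Risso's-dolphin-template clicks."""
    return detected_corpus("Gg", 500, seed=11)


@pytest.fixture(scope="session")
def kogia_records():
    """A detected corpus of near-Nyquist Kogia-template clicks."""
    return detected_corpus("Kogia", 500, seed=12)


@pytest.fixture(scope="session")
def planted_summaries():
    """Bin summaries planted from three spectrally distinct types.

    Returns (summaries, true_type_per_summary): 8 single-type bins per
    type, each of 30 clicks, run through detection and phase-1 clustering.
    """
    summaries, truth = [], []
    for name, seed0 in [("Gg", 1000), ("UD28", 2000), ("Kogia", 3000)]:
        for i in range(8):
            recs = detected_bins(name, 1, 30, seed=seed0 + i)
            for s in cluster_bin(recs, float(i * 300), seed=1):
                summaries.append(s)
                truth.append(name)
    return summaries, truth
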