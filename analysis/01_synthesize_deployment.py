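"""Synthesize a miniature two-site deployment.

Renders calibrated 16-bit recordings for two notional mooring sites:
"NFC" carries alternating UD28 (common-dolphin-like) and Gg (Risso's)
click-train bins plus a sonar ping train, "GS" carries Kogia bins plus
snapping-shrimp-like impulses. Each chunk is one 5-minute bin's worth of
clicks with a known calendar start time. Writes WAVs and truth CSVs under
scratch/analysis/scenes/ and a chunk manifest under results/.
"""

import sys
from pathlib import Path

import pandas as pd

from clicktypes import Bout, Calibration, ImpulseNoise, SceneSpec, SonarPingTrain, write_scene
from clicktypes.templates import get_template

SCENES = Path("scratch/analysis/scenes")
RESULTS = Path("results")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

# site -> list of (type, clicks, calendar start); bins land in distinct
# 5-minute windows across three seasons of 2017
PLAN = {
    "NFC": [
        ("UD28", 80, "2017-03-05 06:00"), ("UD28", 80, "2017-03-05 06:05"),
        ("Gg", 40, "2017-03-06 11:00"), ("UD28", 80, "2017-07-12 02:00"),
        ("Gg", 40, "2017-07-12 02:05"), ("UD28", 80, "2017-10-20 23:00"),
    ],
    "GS": [
        ("Kogia", 60, "2017-01-15 04:00"), ("Kogia", 60, "2017-01-15 04:05"),
        ("Kogia", 60, "2017-07-02 13:00"),
    ],
}


def main() -> None:
    SCENES.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cal = Calibration()
    rows = []
    for site, chunks in PLAN.items():
        for k, (name, n, start) in enumerate(chunks):
            dur = n * get_template(name).modal_ici_s * 1.3 + 2.0
            confounders = ()
            if site == "NFC" and k == 2:
                confounders = (SonarPingTrain(start_s=dur - 4.0, n_pings=3),)
            if site == "GS":
                confounders = (ImpulseNoise(rate_hz=0.3),)
            spec = SceneSpec(
                duration_s=dur,
                bouts=(Bout(name, 0.5, n, 125.0),),
                confounders=confounders,
                seed=SEED + 97 * len(rows),
            )
            wav = SCENES / f"{site}_{k:02d}.wav"
            _, truth = write_scene(spec, wav, wav.with_suffix(".truth.csv"), cal)
            rows.append(
                dict(site=site, chunk=k, wav=str(wav), type=name,
                     n_clicks=len(truth), start=start, duration_s=dur)
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(RESULTS / "scene_manifest.csv", index=False)
    print(f"wrote {len(manifest)} chunks, "
          f"{manifest.n_clicks.sum()} truth clicks, "
          f"{manifest.duration_s.sum():.0f} s of audio")


if __name__ == "__main__":
    main()
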