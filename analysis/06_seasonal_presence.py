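"""Seasonal effort-normalized FPR-scaled presence, with sighting overlay.

Aggregates the retained bin labels from step 05 into per-site, per-season
presence hours, scales them by (1 - FPR), pools a small synthetic
sighting table per species, matches sightings to mooring sites within the
2 km recording radius, and renders seasonal bubble maps. Writes
results/presence_cells.csv and results/site_matches.csv.
"""

from pathlib import Path

import pandas as pd

from clicktypes import match_sightings_to_sites, pool_sightings, presence_hours
from clicktypes.presence import render_presence_map

RESULTS = Path("results")
FIGS = Path("scratch/analysis/figures")

SITES = pd.DataFrame(
    [
        {"site": "NFC", "lat": 37.1665, "lon": -74.3333},
        {"site": "GS", "lat": 33.6657, "lon": -76.0013},
    ]
)

# a small synthetic sighting record: Risso's near NFC in spring (one
# within the recording radius), Kogia offshore of GS in winter
SIGHTINGS = pd.DataFrame(
    [
        {"species": "Grampus griseus", "lat": 37.170, "lon": -74.335,
         "datetime": "2017-03-06 10:40", "group_size": 12},
        {"species": "Grampus griseus", "lat": 38.2, "lon": -73.4,
         "datetime": "2017-04-02 08:00", "group_size": 8},
        {"species": "Grampus griseus", "lat": 39.5, "lon": -72.1,
         "datetime": "2016-07-19 12:00", "group_size": None},
        {"species": "Kogia breviceps", "lat": 33.1, "lon": -76.4,
         "datetime": "2017-01-22 09:30", "group_size": 2},
        {"species": "Kogia sima", "lat": 32.8, "lon": -76.9,
         "datetime": "2018-02-03 14:00", "group_size": 1},
    ]
)

EFFORT = pd.DataFrame(
    [
        {"site": "NFC", "start": "2017-01-01", "end": "2017-12-31"},
        {"site": "GS", "start": "2017-01-01", "end": "2017-12-31"},
    ]
)

SPECIES_OF = {"Gg": "Grampus griseus", "Kogia": "Kogia spp.", "UD28": "Delphinus delphis"}


def main() -> None:
    FIGS.mkdir(parents=True, exist_ok=True)
    labels = pd.read_csv(RESULTS / "bin_labels.csv", parse_dates=["bin_start"])
    labels = labels.rename(columns={"predicted": "class"})
    labels = labels[labels["class"] != "noise"]  # presence maps click types only
    fpr = pd.read_csv(RESULTS / "fpr.csv")
    cells = presence_hours(labels[["site", "class", "bin_start"]], EFFORT, fpr)
    cells.to_csv(RESULTS / "presence_cells.csv", index=False)
    present = cells[(~cells.no_effort) & (cells.mean_hours > 0)]
    for _, r in present.iterrows():
        print(f"{r['site']:4} {r['season']:6} {r['class']:6} "
              f"{r['mean_hours']:6.1f} h (FPR-scaled: {r['fpr_scaled']})")

    matches = match_sightings_to_sites(SIGHTINGS, SITES)
    matches.to_csv(RESULTS / "site_matches.csv", index=False)
    print(f"{len(matches)} sighting(s) within the 2 km recording radius")

    for cls, species in SPECIES_OF.items():
        if cls not in set(cells["class"]):
            continue
        pooled = pool_sightings(SIGHTINGS, species)
        render_presence_map(cells, SITES, cls, FIGS / f"presence_{cls}.png",
                            sightings=pooled)


if __name__ == "__main__":
    main()
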