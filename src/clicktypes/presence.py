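"""Seasonal acoustic presence aggregation and sighting correlation.

Hours of acoustic presence (an hour counts as present for a class when at
least one retained bin of that class starts in it) are summed within each
season, normalized by recording effort to account for gaps between
deployments, averaged across years, and scaled by the classifier's false
positive rate as (1 - FPR). Visual sighting records are pooled per season
across years inside the study bounding box (63-82 degrees W, 24-46
degrees N) and matched to mooring sites when they fall within the ~2 km
estimated recording radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeoConfig",
    "SEASONS",
    "season_of",
    "season_year_of",
    "haversine_km",
    "presence_hours",
    "pool_sightings",
    "match_sightings_to_sites",
    "render_presence_map",
]

logger = logging.getLogger(__name__)

SEASONS = {
    "Spring": (3, 4, 5),
    "Summer": (6, 7, 8),
    "Fall": (9, 10, 11),
    "Winter": (12, 1, 2),
}
_MONTH_TO_SEASON = {m: s for s, months in SEASONS.items() for m in months}

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class GeoConfig:
    """Study-area geometry. Longitudes are expressed in degrees West at
    this interface (internally stored signed, negative west)."""

    bbox_lon_w: tuple[float, float] = (63.0, 82.0)
    bbox_lat_n: tuple[float, float] = (24.0, 46.0)
    match_radius_km: float = 2.0

    def __post_init__(self) -> None:
        if self.match_radius_km <= 0:
            raise ValueError("match_radius_km must be positive")

    def in_bbox(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        """Membership test for signed decimal-degree coordinates."""
        lon_lo, lon_hi = -self.bbox_lon_w[1], -self.bbox_lon_w[0]
        lat_lo, lat_hi = self.bbox_lat_n
        return (lat >= lat_lo) & (lat <= lat_hi) & (lon >= lon_lo) & (lon <= lon_hi)


def season_of(date) -> str:
    """Season label of a date: Spring Mar-May, Summer Jun-Aug, Fall
    Sep-Nov, Winter Dec-Feb."""
    return _MONTH_TO_SEASON[pd.Timestamp(date).month]


def season_year_of(date) -> tuple[str, int]:
    """(season, season-year); December belongs to the following winter."""
    ts = pd.Timestamp(date)
    season = season_of(ts)
    year = ts.year + 1 if ts.month == 12 else ts.year
    return season, year


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between decimal-degree coordinates."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _season_window(season: str, year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    months = SEASONS[season]
    start_year = year - 1 if season == "Winter" else year
    start = pd.Timestamp(year=start_year, month=months[0], day=1)
    end = start + pd.DateOffset(months=3)
    return start, end


def _effort_hours(effort: pd.DataFrame, site: str, season: str, year: int) -> float:
    """Recorded hours of a site overlapping one season window."""
    w0, w1 = _season_window(season, year)
    rows = effort[effort["site"] == site]
    total = 0.0
    for _, r in rows.iterrows():
        lo = max(pd.Timestamp(r["start"]), w0)
        hi = min(pd.Timestamp(r["end"]), w1)
        if hi > lo:
            total += (hi - lo).total_seconds() / 3600.0
    return total


def presence_hours(
    labels: pd.DataFrame,
    effort: pd.DataFrame,
    fpr: pd.DataFrame | None = None,
    cfg: GeoConfig | None = None,
) -> pd.DataFrame:
    """Seasonal effort-normalized FPR-scaled presence per site and class.

    ``labels``: retained bin labels with columns (site, class, bin_start
    [datetime]). ``effort``: recording intervals (site, start, end).
    ``fpr``: optional per (site, class) false positive rates. Seasonal
    presence-hour sums are divided by the recorded fraction of each
    season, averaged across years, then multiplied by (1 - FPR). Seasons
    with zero recording effort are flagged ``no_effort`` (missing, not
    zero presence).
    """
    cfg = cfg or GeoConfig()
    labels = labels.copy()
    ts = pd.to_datetime(labels["bin_start"])
    labels["hour"] = ts.dt.floor("h")
    sy = ts.map(season_year_of)
    labels["season"] = [s for s, _ in sy]
    labels["season_year"] = [y for _, y in sy]

    fpr_map: dict[tuple[str, str], float] = {}
    if fpr is not None:
        fpr_map = {
            (r["site"], r["class"]): float(r["fpr"]) for _, r in fpr.iterrows()
        }

    rows = []
    for site in sorted(labels["site"].unique()):
        site_labels = labels[labels["site"] == site]
        years = sorted(site_labels["season_year"].unique())
        for cls in sorted(site_labels["class"].unique()):
            cl = site_labels[site_labels["class"] == cls]
            for season in SEASONS:
                per_year = []
                no_effort_years = 0
                for year in years:
                    season_hours = (_season_window(season, year)[1]
                                    - _season_window(season, year)[0]).total_seconds() / 3600.0
                    rec_hours = _effort_hours(effort, site, season, year)
                    if rec_hours == 0.0:
                        no_effort_years += 1
                        continue
                    sel = cl[(cl["season"] == season) & (cl["season_year"] == year)]
                    present = sel["hour"].nunique()
                    per_year.append(present / (rec_hours / season_hours))
                if not per_year:
                    rows.append(
                        dict(site=site, season=season, **{"class": cls},
                             mean_hours=float("nan"), fpr_scaled=False, no_effort=True)
                    )
                    continue
                mean_hours = float(np.mean(per_year))
                f = fpr_map.get((site, cls))
                rows.append(
                    dict(
                        site=site,
                        season=season,
                        **{"class": cls},
                        mean_hours=mean_hours * (1.0 - f if f is not None else 1.0),
                        fpr_scaled=f is not None,
                        no_effort=False,
                    )
                )
    return pd.DataFrame(rows)


_KOGIA = {"kogia breviceps", "kogia sima", "kogia spp.", "kogia spp"}


def normalize_species(name: str) -> str:
    """Canonical species label; the two Kogia species merge by genus."""
    if str(name).strip().lower() in _KOGIA:
        return "Kogia spp."
    return str(name).strip()


def pool_sightings(
    sightings: pd.DataFrame, species: str, cfg: GeoConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Seasonal pooled sightings of one species across all years.

    Records outside the study bounding box are excluded; unparseable rows
    are logged and skipped. Pooled (not averaged) per season because of
    large interannual differences in survey effort. Each season's frame
    carries ``n_sightings`` and ``n_individuals`` attrs, the latter summed
    over sightings with group-size data.
    """
    cfg = cfg or GeoConfig()
    df = sightings.copy()
    df["species"] = df["species"].map(normalize_species)
    df = df[df["species"] == normalize_species(species)]
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    dt = pd.to_datetime(df["datetime"], errors="coerce")
    bad = lat.isna() | lon.isna() | dt.isna()
    if bad.any():
        logger.warning("skipping %d unparseable sighting rows", int(bad.sum()))
    df, lat, lon, dt = df[~bad], lat[~bad], lon[~bad], dt[~bad]
    inside = cfg.in_bbox(lat.to_numpy(), lon.to_numpy())
    df = df[inside]
    dt = dt[inside]
    df = df.assign(season=[season_of(d) for d in dt])

    out = {}
    for season in SEASONS:
        s = df[df["season"] == season].copy()
        gs = pd.to_numeric(s.get("group_size"), errors="coerce")
        s.attrs["n_sightings"] = len(s)
        s.attrs["n_individuals"] = int(gs.dropna().sum()) if len(s) else 0
        out[season] = s
    return out


def match_sightings_to_sites(
    sightings: pd.DataFrame, sites: pd.DataFrame, cfg: GeoConfig | None = None
) -> pd.DataFrame:
    """Sightings within the estimated recording radius of any mooring site.

    Returns one row per (sighting, site) pair within ``match_radius_km``,
    carrying the sighting time for acoustic cross-reference.
    """
    cfg = cfg or GeoConfig()
    rows = []
    for _, site in sites.iterrows():
        d = haversine_km(
            pd.to_numeric(sightings["lat"]).to_numpy(),
            pd.to_numeric(sightings["lon"]).to_numpy(),
            float(site["lat"]),
            float(site["lon"]),
        )
        close = np.flatnonzero(d <= cfg.match_radius_km)
        for i in close:
            r = sightings.iloc[i]
            rows.append(
                {
                    "site": site["site"],
                    "species": r.get("species", ""),
                    "datetime": r.get("datetime"),
                    "distance_km": float(d[i]),
                }
            )
    return pd.DataFrame(rows, columns=["site", "species", "datetime", "distance_km"])


def render_presence_map(
    cells: pd.DataFrame,
    sites: pd.DataFrame,
    class_name: str,
    out_path: str | Path,
    sightings: dict[str, pd.DataFrame] | None = None,
    cfg: GeoConfig | None = None,
) -> Path:
    """Four seasonal bubble-map panels for one class.

    Bubble area is proportional to mean presence hours (zero-presence
    cells draw no bubble); sighting positions overlay as dots.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cfg = cfg or GeoConfig()
    cl = cells[cells["class"] == class_name]
    finite = cl["mean_hours"].dropna()
    max_h = max(float(finite.max()) if len(finite) else 0.0, 1e-9)
    fig, axes = plt.subplots(1, 4, figsize=(18, 4.5), sharex=True, sharey=True)
    for ax, season in zip(axes, SEASONS):
        sub = cl[cl["season"] == season].merge(sites, on="site")
        if sightings is not None and season in sightings:
            s = sightings[season]
            ax.plot(pd.to_numeric(s["lon"]), pd.to_numeric(s["lat"]), ".",
                    color="steelblue", ms=3, alpha=0.5, zorder=1)
        ax.plot(sites["lon"], sites["lat"], "r*", ms=8, zorder=2)
        drawn = sub[(~sub["no_effort"]) & (sub["mean_hours"] > 0)]
        if len(drawn):
            ax.scatter(
                drawn["lon"], drawn["lat"],
                s=600.0 * drawn["mean_hours"] / max_h,  # area ~ hours
                facecolors="none", edgecolors="k", zorder=3,
            )
        ax.set(title=f"{class_name} — {season}",
               xlim=(-cfg.bbox_lon_w[1], -cfg.bbox_lon_w[0]), ylim=cfg.bbox_lat_n)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return Path(out_path)
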