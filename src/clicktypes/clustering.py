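"""Two-phase unsupervised discovery of dominant click types.

Phase 1 partitions a deployment into 5-minute bins and clusters the
clicks of each bin with the Chinese whispers graph algorithm on pairwise
spectral similarity, keeping only clicks at or above 120 dB re 1 uPa
peak-to-peak; each within-bin cluster is summarized by its mean spectrum,
inter-click-interval histogram and mean waveform envelope. Phase 2
clusters (a subsample of at most 40,000 of) those bin-level summaries
across the deployment on combined spectral and envelope similarity, and
prunes clusters backed by fewer than 25 bin-level averages or fewer than
50 individual detections.

Edge pruning semantics: before label propagation, edges whose similarity
falls below the ``p_e`` quantile of all off-diagonal similarities are
removed, so ``p_e = 0.98`` keeps only the top 2% most-similar pairs. This
single parameter controls cluster granularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detector import DB_GUARD, ClickRecord, N_SPEC_BINS

__all__ = [
    "ClusterConfig",
    "BinSummary",
    "TypeCluster",
    "assign_bins",
    "chinese_whispers",
    "cluster_bin",
    "cluster_types",
    "subsample_summaries",
    "spectral_similarity",
    "ici_histogram",
    "ICI_HIST_EDGES",
]

#: ICI histogram grid: 0.01 s bins over [0, 1] s. Bin centers fall on
#: x.xx5 values so every published modal ICI is representable.
ICI_HIST_EDGES = np.round(np.arange(0.0, 1.0 + 0.01, 0.01), 10)


@dataclass(frozen=True)
class ClusterConfig:
    bin_minutes: float = 5.0
    min_cluster_rl_db: float = 120.0
    pe_phase1: float = 0.95
    pe_phase2: float = 0.98
    max_bins_phase2: int = 40_000
    min_bins_per_cluster: int = 25
    min_clicks_per_cluster: int = 50
    cw_iterations: int = 20
    band_low_khz: float = 5.0
    band_high_khz: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for pe in (self.pe_phase1, self.pe_phase2):
            if not (0 < pe < 1):
                raise ValueError("edge pruning parameter must be in (0, 1)")
        for name in ("max_bins_phase2", "min_bins_per_cluster", "min_clicks_per_cluster"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BinSummary:
    """Per-5-minute-bin cluster summary."""

    bin_start: float  # seconds from deployment start
    mean_spectrum_db: np.ndarray
    ici_hist: np.ndarray
    mean_envelope: np.ndarray
    n_clicks: int
    source_cluster: int = 0
    mean_rl_db: float = float("nan")
    member_indices: np.ndarray | None = None  # indices into the bin's records

    def __post_init__(self) -> None:
        if self.n_clicks < 1:
            raise ValueError("n_clicks must be >= 1")


@dataclass
class TypeCluster:
    """A phase-2 cluster: a candidate recurring click type."""

    id: int
    member_bins: list[BinSummary]
    summary_spectrum: np.ndarray
    ici_distribution: np.ndarray
    n_total_clicks: int


def ici_histogram(times_s: np.ndarray) -> np.ndarray:
    """Histogram of intervals between consecutive click times, 0.01 s bins."""
    times_s = np.sort(np.asarray(times_s, dtype=float))
    if len(times_s) < 2:
        return np.zeros(len(ICI_HIST_EDGES) - 1)
    icis = np.diff(times_s)
    hist, _ = np.histogram(icis, bins=ICI_HIST_EDGES)
    return hist.astype(float)


def assign_bins(
    records: list[ClickRecord], cfg: ClusterConfig | None = None
) -> dict[float, list[ClickRecord]]:
    """Group clicks into half-open 5-minute bins [t, t + 5 min).

    Clicks below the 120 dB clustering floor are excluded. Returns a
    mapping from bin start time (s) to the bin's records, in time order.
    """
    cfg = cfg or ClusterConfig()
    width = cfg.bin_minutes * 60.0
    bins: dict[float, list[ClickRecord]] = {}
    for r in sorted(records, key=lambda r: r.peak_time_s):
        if r.pp_level_db < cfg.min_cluster_rl_db - DB_GUARD:
            continue
        key = float(np.floor(r.peak_time_s / width) * width)
        bins.setdefault(key, []).append(r)
    return bins


def _minmax_rows(a: np.ndarray) -> np.ndarray:
    lo = a.min(axis=1, keepdims=True)
    rng = a.max(axis=1, keepdims=True) - lo
    rng[rng == 0] = 1.0
    return (a - lo) / rng


def _corr_matrix(a: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation, safe for zero-variance rows."""
    a = a - a.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(a, axis=1)
    norm[norm == 0] = 1.0
    c = (a / norm[:, None]) @ (a / norm[:, None]).T
    return np.clip(c, -1.0, 1.0)


def spectral_similarity(
    spectra_db: np.ndarray, cfg: ClusterConfig | None = None
) -> np.ndarray:
    """Pearson correlation of normalized spectral shapes in 5-100 kHz.

    Each dB spectrum is referenced to its own noise floor (the median
    level), negative excursions are clipped, and the result min-max
    normalized before correlating. This makes the similarity sensitive to
    the shape of the spectral peak region, invariant to absolute level,
    and robust to background-bin fluctuations that would otherwise
    dominate narrowband types. Used for phase-1 within-bin clustering.
    """
    cfg = cfg or ClusterConfig()
    lo = int(cfg.band_low_khz * 2)  # 500 Hz grid
    hi = min(int(cfg.band_high_khz * 2), N_SPEC_BINS)
    s = np.asarray(spectra_db, float)[:, lo:hi]
    s = np.clip(s - np.median(s, axis=1, keepdims=True), 0.0, None)
    sim = _corr_matrix(_minmax_rows(s))
    np.fill_diagonal(sim, 1.0)
    return sim


def chinese_whispers(
    similarity: np.ndarray,
    p_e: float,
    iterations: int = 20,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Chinese whispers label propagation on a pruned similarity graph.

    Edges with similarity below the pruning parameter ``p_e`` are removed
    (``p_e`` acts as a minimum-similarity cutoff on the correlation-based
    similarity scale); every node starts with its own label and, visiting
    nodes in a fresh random order each iteration, adopts the label with
    the largest summed edge weight among its neighbors (ties broken by
    the seeded RNG), until no label changes or the iteration cap is
    reached.
    """
    sim = np.asarray(similarity, dtype=float)
    n = sim.shape[0]
    if n == 0:
        return np.zeros(0, dtype=int)
    if sim.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    adj = sim.copy()
    adj[sim < p_e] = 0.0
    np.fill_diagonal(adj, 0.0)

    labels = np.arange(n)
    for _ in range(iterations):
        changed = False
        for i in rng.permutation(n):
            nbrs = np.flatnonzero(adj[i] > 0)
            if len(nbrs) == 0:
                continue
            weights: dict[int, float] = {}
            for j in nbrs:
                weights[labels[j]] = weights.get(labels[j], 0.0) + adj[i, j]
            best = max(weights.values())
            tied = sorted(k for k, v in weights.items() if v == best)
            new = tied[0] if len(tied) == 1 else tied[rng.integers(len(tied))]
            if new != labels[i]:
                labels[i] = new
                changed = True
        if not changed:
            break
    return labels


def _summarize_cluster(
    members: list[ClickRecord],
    bin_start: float,
    source_cluster: int,
    member_indices: np.ndarray | None = None,
) -> BinSummary:
    return BinSummary(
        bin_start=bin_start,
        mean_spectrum_db=np.mean([r.spectrum_db for r in members], axis=0),
        ici_hist=ici_histogram(np.array([r.peak_time_s for r in members])),
        mean_envelope=np.mean([r.envelope for r in members], axis=0),
        n_clicks=len(members),
        source_cluster=source_cluster,
        mean_rl_db=float(np.mean([r.pp_level_db for r in members])),
        member_indices=member_indices,
    )


def cluster_bin(
    records: list[ClickRecord],
    bin_start: float,
    cfg: ClusterConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> list[BinSummary]:
    """Phase-1 within-bin clustering; one BinSummary per resulting cluster.

    Bins with fewer than two clicks produce a single trivial summary.
    Multiple clusters form only when the bin mixes distinctly different
    signal types.
    """
    cfg = cfg or ClusterConfig()
    if len(records) == 0:
        return []
    if len(records) < 2:
        return [_summarize_cluster(records, bin_start, 0, np.array([0]))]
    spectra = np.array([r.spectrum_db for r in records])
    sim = spectral_similarity(spectra, cfg)
    labels = chinese_whispers(sim, cfg.pe_phase1, cfg.cw_iterations, seed)
    out = []
    for k, lab in enumerate(np.unique(labels)):
        idx = np.flatnonzero(labels == lab)
        out.append(
            _summarize_cluster([records[i] for i in idx], bin_start, k, idx)
        )
    return out


def subsample_summaries(
    summaries: list[BinSummary],
    cfg: ClusterConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> list[BinSummary]:
    """Seeded uniform subsample (without replacement) to the phase-2 cap.

    When more than ``max_bins_phase2`` summaries are supplied, exactly
    that many are admitted to graph construction; otherwise all are.
    """
    cfg = cfg or ClusterConfig()
    if len(summaries) <= cfg.max_bins_phase2:
        return list(summaries)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(summaries), size=cfg.max_bins_phase2, replace=False))
    return [summaries[i] for i in idx]


def cluster_types(
    summaries: list[BinSummary],
    cfg: ClusterConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> list[TypeCluster]:
    """Phase-2 cross-bin clustering of bin-level summaries into type clusters.

    Similarity is the arithmetic mean of spectral-shape and mean-envelope
    correlations; pruning uses ``pe_phase2``. Clusters with fewer than
    ``min_bins_per_cluster`` bin-level averages or fewer than
    ``min_clicks_per_cluster`` total detections are discarded.
    """
    cfg = cfg or ClusterConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    admitted = subsample_summaries(summaries, cfg, rng)
    if not admitted:
        return []
    spectra = np.array([s.mean_spectrum_db for s in admitted])
    envs = np.array([s.mean_envelope for s in admitted])
    sim = 0.5 * (
        spectral_similarity(spectra, cfg) + _corr_matrix(_minmax_rows(envs))
    )
    np.fill_diagonal(sim, 1.0)
    labels = chinese_whispers(sim, cfg.pe_phase2, cfg.cw_iterations, rng)

    clusters = []
    for lab in np.unique(labels):
        members = [s for s, l in zip(admitted, labels) if l == lab]
        n_clicks = int(sum(s.n_clicks for s in members))
        if len(members) < cfg.min_bins_per_cluster or n_clicks < cfg.min_clicks_per_cluster:
            continue
        clusters.append(
            TypeCluster(
                id=len(clusters),
                member_bins=members,
                summary_spectrum=np.mean([s.mean_spectrum_db for s in members], axis=0),
                ici_distribution=np.sum([s.ici_hist for s in members], axis=0),
                n_total_clicks=n_clicks,
            )
        )
    return clusters
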