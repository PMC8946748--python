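"""Two-phase unsupervised type discovery per site.

Reconstructs detections from step 02, bins them on calendar time,
clusters within bins (Chinese whispers, p_e = 0.95), then clusters the
bin-level summaries across each site (p_e = 0.98 with pruning). Writes
the surviving type clusters to results/type_clusters.csv and the bin
summaries (with majority truth types for later scoring) to NPZ.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from clicktypes import ClickRecord, ClusterConfig, assign_bins, cluster_bin, cluster_types

RESULTS = Path("results")
SIDE = Path("scratch/analysis")

# desk-scale pruning floors: the study deployment has a handful of bins
CFG = ClusterConfig(min_bins_per_cluster=2, min_clicks_per_cluster=20)


def load_records(site: str):
    frame = pd.read_csv(RESULTS / f"clicks_{site}.csv")
    arrays = np.load(SIDE / f"clicks_{site}.npz")
    epoch = pd.to_datetime(frame.start).astype("int64") / 1e9
    records, truth = [], []
    for i, row in frame.iterrows():
        t = float(epoch.iloc[i]) + row.peak_time_s
        records.append(
            ClickRecord(
                start_s=t, end_s=t + row.duration_us * 1e-6, peak_time_s=t,
                waveform=np.zeros(1), envelope=arrays["envelopes"][i],
                spectrum_db=arrays["spectra_db"][i],
                peak_freq_khz=row.peak_freq_khz, pp_level_db=row.pp_level_db,
                bw3db_khz=row.bw3db_khz, duration_us=row.duration_us,
            )
        )
        truth.append(row.true_type)
    return records, dict(zip((r.peak_time_s for r in records), truth))


def main() -> None:
    rows, summary_store = [], []
    for site in ("NFC", "GS"):
        records, truth_of = load_records(site)
        summaries, majorities = [], []
        for bin_start, recs in assign_bins(records).items():
            for s in cluster_bin(recs, bin_start, CFG, seed=1):
                summaries.append(s)
                members = [recs[i] for i in s.member_indices]
                types = [truth_of[r.peak_time_s] for r in members]
                majorities.append(max(set(types), key=types.count))
        clusters = cluster_types(summaries, CFG, seed=1)
        for c in clusters:
            peak_khz = float(np.argmax(c.summary_spectrum)) * 0.5
            rows.append(
                dict(site=site, cluster=c.id, n_bins=len(c.member_bins),
                     n_clicks=c.n_total_clicks, peak_freq_khz=peak_khz)
            )
        print(f"{site}: {len(summaries)} bin summaries -> "
              f"{len(clusters)} type clusters "
              f"(peaks {[r['peak_freq_khz'] for r in rows if r['site'] == site]} kHz)")
        summary_store.append(
            dict(
                site=site,
                spectra=np.array([s.mean_spectrum_db for s in summaries]),
                ici=np.array([s.ici_hist for s in summaries]),
                env=np.array([s.mean_envelope for s in summaries]),
                n_clicks=np.array([s.n_clicks for s in summaries]),
                rl=np.array([s.mean_rl_db for s in summaries]),
                bin_start=np.array([s.bin_start for s in summaries]),
                truth=np.array(majorities),
            )
        )
    pd.DataFrame(rows).to_csv(RESULTS / "type_clusters.csv", index=False)
    np.savez(SIDE / "bin_summaries.npz",
             **{f"{d['site']}_{k}": v for d in summary_store
                for k, v in d.items() if k != "site"})


if __name__ == "__main__":
    main()
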