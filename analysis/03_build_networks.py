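"""Build SRI social networks per site and period; summarise centrality.

From the detected events (02_detect_flocks.py) this derives, per site and
period, the Simple-Ratio-Index weighted network, its density (percentage
of realized dyads), and the per-bird centrality metrics used as model
predictors. Writes scratch/study/metrics.csv plus edge lists, and
results/network_summary.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from flocknet.flocks import build_gbi
from flocknet.network import (network_density, node_metrics, sri_network,
                              write_edge_list)
from flocknet.simulate import read_detections

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser().parse_args()
    study = ROOT / "scratch" / "study"
    events = pd.read_csv(study / "events.csv")
    stream = read_detections(study / "detections.csv")
    events = events.merge(
        stream.groupby(["site_id", "day"])["period"].first().reset_index(),
        on=["site_id", "day"], how="left")
    counts = stream.groupby(["period", "tag_id"]).size()

    rows, metric_frames = [], []
    for (period, site), ev in events.groupby(["period", "site_id"]):
        gbi = build_gbi(ev)
        net = sri_network(gbi, period=period)
        write_edge_list(net, study / f"edges_{period}_{site}.csv")
        m = node_metrics(net, gbi, detections=counts.loc[period])
        m["site_id"] = site
        metric_frames.append(m)
        rows.append({
            "period": period, "site_id": site, "n_nodes": net.n_nodes,
            "n_edges": int((net.weights > 0).sum() // 2),
            "density_pct": round(network_density(net), 1),
            "mean_strength": round(m["strength"].mean(), 3),
        })
    metrics = pd.concat(metric_frames)
    metrics.to_csv(study / "metrics.csv")
    summary = pd.DataFrame(rows).sort_values(["period", "site_id"])
    summary.to_csv(ROOT / "results" / "network_summary.csv", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
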