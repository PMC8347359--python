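#!/usr/bin/env python
"""Persistence-weighted interaction networks and hub/domain statistics.

Two parts:

1. The natural hydrophobic packing network of each synthetic system is
   built from its trajectory, thresholded with the
   largest-hydrophobic-cluster knee, and its hubs (toy-scale connection
   cutoff) are split between the core and gate domains.  The inward-state
   analogues are then compared hub-by-hub.
2. The published hub tables of the four prestin TMD systems are run
   through the same domain statistics, reproducing the reported core/gate
   percentages from the printed rows.

Writes results/network_hubs.tsv, results/network_summary.tsv and
results/published_hub_fractions.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common
from tmdkit import network
from tmdkit.published_hubs import SYSTEMS as PUBLISHED_SYSTEMS
from tmdkit.published_hubs import hub_table


def main() -> None:
    common.RESULTS.mkdir(parents=True, exist_ok=True)
    dm = common.domain_map()
    hub_rows, summary_rows, hub_sets = [], [], {}
    for system in common.SYSTEMS:
        ens, _ = common.network_input(system)
        g = network.persistence_graph(
            ens, ens.topology, network.ContactCriteria.ca_proxy(), dm=dm
        )
        threshold = network.select_persistence_threshold(g)
        tab = network.hubs(g, threshold, hub_min_degree=common.HUB_MIN_DEGREE)
        frac = (
            network.domain_hub_fractions(tab, dm) if len(tab) else (0, 0)
        )
        hub_sets[system] = set(tab["residue_index"])
        summary_rows.append(
            {
                "system": system,
                "n_edges": len(g.edges),
                "threshold_pct": threshold,
                "n_hubs": len(tab),
                "core_pct": frac[0],
                "gate_pct": frac[1],
            }
        )
        for _, row in tab.iterrows():
            hub_rows.append({"system": system, **row.to_dict()})
        print(
            f"{system}: {len(g.edges)} edges, knee threshold "
            f"{threshold:.1f}%, {len(tab)} hubs "
            f"({frac[0]}% core / {frac[1]}% gate)"
        )

    common_inward = sorted(hub_sets["rI"] & hub_sets["zI"])
    print(f"hubs common to the two inward analogues: {common_inward}")

    pd.DataFrame(hub_rows).to_csv(
        common.RESULTS / "network_hubs.tsv", sep="\t", index=False
    )
    pd.DataFrame(summary_rows).to_csv(
        common.RESULTS / "network_summary.tsv", sep="\t", index=False
    )

    pub_rows = []
    for system in PUBLISHED_SYSTEMS:
        tab = hub_table(system)
        core_pct, gate_pct = network.domain_hub_fractions(tab)
        pub_rows.append(
            {"system": system, "n_hubs": len(tab),
             "core_pct": core_pct, "gate_pct": gate_pct}
        )
        print(
            f"published {system}: {len(tab)} hubs -> "
            f"{core_pct}% core / {gate_pct}% gate"
        )
    pd.DataFrame(pub_rows).to_csv(
        common.RESULTS / "published_hub_fractions.tsv", sep="\t", index=False
    )
    print(f"wrote {common.RESULTS / 'published_hub_fractions.tsv'}")


if __name__ == "__main__":
    main()
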