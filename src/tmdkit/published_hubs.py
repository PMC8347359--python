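"""Reported interaction-network hubs of the prestin transmembrane domain.

Published hub tables for the four simulated prestin systems — rat (rPres)
and zebrafish (zPres) orthologs, each in the inward-open (I) and
outward-open (O) conformation.  Each entry is a residue whose number of
persistent typed interactions (H-bonds, salt bridges and hydrophobic
contacts) reached the hub cutoff, with its connection count and the helix
bundle (core or gate) it belongs to.  These rows serve as worked-example
inputs for the domain-fraction statistics.
"""

from __future__ import annotations

import pandas as pd

from .core_model import ONE_TO_THREE

SYSTEMS = ("rI", "rO", "zI", "zO")

#: (one-letter residue, residue index, degree, domain)
PRESTIN_HUBS: dict[str, list[tuple[str, int, int, str]]] = {
    "rI": [
        ("L", 95, 8, "core"), ("A", 100, 7, "core"), ("A", 102, 7, "core"),
        ("L", 104, 7, "core"), ("V", 107, 7, "core"), ("C", 124, 7, "core"),
        ("M", 143, 7, "core"), ("V", 147, 7, "core"), ("V", 182, 7, "core"),
        ("E", 374, 7, "core"), ("Q", 403, 7, "core"),
        ("V", 444, 8, "gate"), ("A", 218, 7, "gate"), ("M", 225, 7, "gate"),
        ("L", 257, 7, "gate"), ("L", 435, 7, "gate"), ("A", 442, 7, "gate"),
        ("I", 443, 7, "gate"), ("L", 488, 7, "gate"),
    ],
    "rO": [
        ("V", 92, 7, "core"), ("M", 143, 7, "core"), ("F", 351, 7, "core"),
        ("A", 217, 8, "gate"), ("A", 218, 8, "gate"), ("V", 221, 7, "gate"),
        ("L", 292, 7, "gate"),
    ],
    "zI": [
        ("L", 100, 8, "core"), ("I", 145, 8, "core"), ("A", 346, 8, "core"),
        ("L", 96, 7, "core"), ("A", 103, 7, "core"), ("M", 104, 7, "core"),
        ("V", 108, 7, "core"), ("A", 139, 7, "core"), ("L", 342, 7, "core"),
        ("I", 349, 7, "core"),
        ("L", 443, 7, "gate"), ("L", 451, 7, "gate"),
    ],
    "zO": [
        ("V", 93, 8, "core"), ("V", 108, 7, "core"), ("F", 138, 7, "core"),
        ("M", 144, 7, "core"), ("A", 149, 7, "core"), ("L", 342, 7, "core"),
        ("A", 220, 7, "gate"), ("A", 221, 7, "gate"),
    ],
}


def hub_table(system: str) -> pd.DataFrame:
    """Published hub table of one system in the package's hub-table layout
    (residue_index, residue_name, degree, domain)."""
    if system not in PRESTIN_HUBS:
        raise ValueError(f"unknown system {system!r}; expected one of {SYSTEMS}")
    rows = [
        (idx, ONE_TO_THREE[one], degree, domain)
        for (one, idx, degree, domain) in PRESTIN_HUBS[system]
    ]
    rows.sort(key=lambda r: (-r[2], r[0]))
    return pd.DataFrame(
        rows, columns=["residue_index", "residue_name", "degree", "domain"]
    )
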