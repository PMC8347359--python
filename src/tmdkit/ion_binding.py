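"""Ion binding-event detection and anchor-residue ranking.

An ion is "in contact" with a residue when it lies within a cutoff of the
residue's nearest heavy atom (Cα proxy on Cα-only systems).  A *binding
event* is a sustained residence at a declared binding site: a maximal run
of frames in which the ion contacts at least one site residue, with short
interruptions (up to ``gap_tolerance`` frames) bridged and runs shorter
than ``min_duration`` discarded.  Residues are ranked as *anchors* by the
total number of ion-contact frames they accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core_model import Topology, TrajectoryEnsemble

DEFAULT_CONTACT_CUTOFF = 4.0  # Å, ion to nearest heavy atom


@dataclass
class ContactSeries:
    """Boolean per-frame contact record for every (ion, residue) pair."""

    ion_ids: list[int]
    residue_indices: list[int]
    contacts: np.ndarray  # n_ions x n_residues x F, bool
    times: np.ndarray | None = None

    def __post_init__(self):
        self.contacts = np.asarray(self.contacts, dtype=bool)
        expected = (len(self.ion_ids), len(self.residue_indices))
        if self.contacts.shape[:2] != expected:
            raise ValueError(
                f"contacts shape {self.contacts.shape} does not match "
                f"{expected} (ions, residues)"
            )

    @property
    def n_frames(self) -> int:
        return self.contacts.shape[2]

    def any_site_contact(self, ion_id: int, site: Sequence[int] | None = None) -> np.ndarray:
        """Per-frame bool: does this ion contact any (site) residue?"""
        i = self.ion_ids.index(ion_id)
        if site is None:
            mask = np.ones(len(self.residue_indices), dtype=bool)
        else:
            site = set(site)
            mask = np.array([r in site for r in self.residue_indices])
        return self.contacts[i, mask, :].any(axis=0)


@dataclass
class BindingEvent:
    """One sustained residence of an ion at the binding site."""

    ion_id: int
    start_frame: int
    end_frame: int
    coordinating_residues: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.end_frame < self.start_frame:
            raise ValueError("event end before start")

    @property
    def duration(self) -> int:
        return self.end_frame - self.start_frame + 1


def find_ion_residues(top: Topology, resname: str = "CLA") -> list[int]:
    """Residue indices of ion pseudo-residues by residue name."""
    return [r.index for r in top.residues if r.name == resname]


def ion_contact_series(
    ens: TrajectoryEnsemble,
    top: Topology,
    ion_selection: Sequence[int],
    residue_set: Sequence[int],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactSeries:
    """Contact record of each ion against each residue of interest.

    ``ion_selection`` lists the *residue indices* of the ion pseudo-residues
    (one atom each); ``residue_set`` lists protein residues.  The distance
    is ion to nearest heavy (non-hydrogen) atom of the residue, which is the
    Cα on Cα-only synthetic systems.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ion_selection = list(ion_selection)
    residue_set = list(residue_set)
    if not ion_selection:
        raise ValueError("empty ion selection")
    if not residue_set:
        raise ValueError("empty residue set")
    ion_atoms = []
    for r in ion_selection:
        atoms = top.atoms_of_residue(r)
        if len(atoms) != 1:
            raise ValueError(f"ion residue {r} should have exactly one atom")
        ion_atoms.append(atoms[0])
    res_atoms = {
        r: [
            i
            for i in top.atoms_of_residue(r)
            if not top.atoms[i].name.startswith("H")
        ]
        for r in residue_set
    }
    F = ens.n_frames
    contacts = np.zeros((len(ion_selection), len(residue_set), F), dtype=bool)
    for f in range(F):
        frame = ens.coords[f]
        ion_pos = frame[ion_atoms]
        for j, r in enumerate(residue_set):
            d = cdist(ion_pos, frame[res_atoms[r]]).min(axis=1)
            contacts[:, j, f] = d <= cutoff
    return ContactSeries(
        ion_ids=ion_selection,
        residue_indices=residue_set,
        contacts=contacts,
        times=ens.times.copy(),
    )


def detect_binding_events(
    cs: ContactSeries,
    site: Sequence[int] | None = None,
    min_duration: int = 1,
    gap_tolerance: int = 0,
) -> list[BindingEvent]:
    """Segment each ion's site-contact series into binding events.

    Maximal contact runs separated by at most ``gap_tolerance`` frames are
    merged; merged runs shorter than ``min_duration`` frames are dropped.
    Events are returned sorted by (start frame, ion id).
    """
    if min_duration < 1:
        raise ValueError("min_duration must be >= 1")
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    events: list[BindingEvent] = []
    for ion in cs.ion_ids:
        series = cs.any_site_contact(ion, site)
        runs = _contact_runs(series)
        merged = _merge_runs(runs, gap_tolerance)
        for (lo, hi) in merged:
            if hi - lo + 1 < min_duration:
                continue
            events.append(
                BindingEvent(
                    ion_id=ion,
                    start_frame=lo,
                    end_frame=hi,
                    coordinating_residues=_coordination(cs, ion, lo, hi, site),
                )
            )
    events.sort(key=lambda e: (e.start_frame, e.ion_id))
    return events


def _contact_runs(series: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, end) frame pairs."""
    padded = np.concatenate(([False], series, [False])).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_runs(
    runs: list[tuple[int, int]], gap_tolerance: int
) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for (lo, hi) in runs[1:]:
        plo, phi = merged[-1]
        if lo - phi - 1 <= gap_tolerance:
            merged[-1] = (plo, hi)
        else:
            merged.append((lo, hi))
    return merged


def _coordination(
    cs: ContactSeries,
    ion_id: int,
    lo: int,
    hi: int,
    site: Sequence[int] | None,
) -> dict[int, float]:
    """Per-residue contact fraction within one event window."""
    i = cs.ion_ids.index(ion_id)
    residues = cs.residue_indices if site is None else [
        r for r in cs.residue_indices if r in set(site)
    ]
    out = {}
    span = hi - lo + 1
    for r in residues:
        j = cs.residue_indices.index(r)
        frac = float(cs.contacts[i, j, lo : hi + 1].sum()) / span
        if frac > 0:
            out[r] = frac
    return out


def anchor_ranking(cs: ContactSeries) -> pd.DataFrame:
    """Residues ranked by total ion-contact frame count (descending; ties
    broken by residue index).  Residues with zero contacts are omitted."""
    totals = cs.contacts.sum(axis=(0, 2))
    rows = [
        (r, int(c))
        for r, c in zip(cs.residue_indices, totals)
        if c > 0
    ]
    rows.sort(key=lambda rc: (-rc[1], rc[0]))
    return pd.DataFrame(rows, columns=["residue_index", "contact_frames"])


def events_to_frame(events: list[BindingEvent], times: np.ndarray | None = None) -> pd.DataFrame:
    """Tabulate events; with frame times given, durations are also in ns."""
    rows = []
    for e in events:
        row = {
            "ion_id": e.ion_id,
            "start_frame": e.start_frame,
            "end_frame": e.end_frame,
            "duration_frames": e.duration,
            "top_residues": ",".join(
                str(r)
                for r, _ in sorted(
                    e.coordinating_residues.items(), key=lambda kv: -kv[1]
                )[:4]
            ),
        }
        if times is not None:
            row["start_ns"] = float(times[e.start_frame])
            row["end_ns"] = float(times[e.end_frame])
            row["duration_ns"] = row["end_ns"] - row["start_ns"]
        rows.append(row)
    return pd.DataFrame(rows)
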