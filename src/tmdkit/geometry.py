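"""Helix-axis geometry and core/gate shift-tilt descriptors.

For an elevator-type transporter, the functionally informative comparison
between two states is made after superposing every frame of one state onto
a representative structure of the other using the *gate* helices only: any
rigid-body z-translation (shift) or reorientation (tilt) that survives the
alignment is then attributable to motion of the *core* relative to the
gate.  Helix axes follow the half-centre-of-mass convention (vector from
the COM of the N-terminal half of the helix Cα trace to the COM of the
C-terminal half); the tilt is the angle between that axis and the membrane
normal (+z).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import DomainMap, TrajectoryEnsemble, kabsch_superpose
from .landscape import ClusterModel

logger = logging.getLogger(__name__)


def helix_axis(coords: np.ndarray) -> np.ndarray:
    """Unit axis of a helix Cα trace, oriented N→C.

    Half-COM rule: the normalised vector from the centre of mass of the
    N-terminal half of the residues to that of the C-terminal half; with an
    odd residue count the middle residue belongs to both halves.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 6:
        raise ValueError(f"helix axis needs at least 6 residues, got {n}")
    half = n // 2
    if n % 2 == 0:
        first, second = coords[:half], coords[half:]
    else:
        first, second = coords[: half + 1], coords[half:]
    axis = second.mean(axis=0) - first.mean(axis=0)
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("degenerate (zero-length) helix axis")
    return axis / norm


def principal_axis(coords: np.ndarray) -> np.ndarray:
    """Helix axis from the leading principal component of the Cα trace,
    oriented N→C.  Alternative to the half-COM rule; the two agree to a
    couple of degrees on ideal helices."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis @ (coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def tilt_angle(axis: np.ndarray) -> float:
    """Angle (degrees, in [0, 180]) between a helix axis and +z."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if abs(norm - 1.0) > 1e-9:
        warnings.warn("tilt_angle input not unit length; normalising", stacklevel=2)
        axis = axis / norm
    return float(np.degrees(np.arccos(np.clip(axis[2], -1.0, 1.0))))


@dataclass
class HelixGeometry:
    """Axis, centre of mass and tilt of each TM helix in one structure."""

    axis: dict[int, np.ndarray]
    com: dict[int, np.ndarray]
    tilt: dict[int, float]


def helix_geometry(
    coords: np.ndarray,
    top,
    dm: DomainMap,
) -> HelixGeometry:
    """Per-TM axis/COM/tilt of a single structure (full-atom A × 3 coords)."""
    axes, coms, tilts = {}, {}, {}
    for tm in dm.tm_ids:
        idx = top.ca_indices(dm.residues_of_tm(tm))
        x = coords[idx]
        axes[tm] = helix_axis(x)
        coms[tm] = x.mean(axis=0)
        tilts[tm] = tilt_angle(axes[tm])
    return HelixGeometry(axis=axes, com=coms, tilt=tilts)


# ---------------------------------------------------------------------------
# Shift/tilt report
# ---------------------------------------------------------------------------


@dataclass
class ShiftTiltReport:
    """Per-core-TM Δz (Å) and Δtilt (degrees), outward state vs a
    representative inward structure, after gate alignment.

    Positive Δz means an upward (extracellular-directed) movement of the
    helix centre of mass; Δtilt is signed, outward minus inward.
    """

    table: pd.DataFrame  # columns: tm_id, domain, dz_mean, dz_sd, dtilt_mean, dtilt_sd

    def dz(self, tm) -> float:
        return float(self.table.set_index("tm_id").loc[tm, "dz_mean"])

    def dtilt(self, tm) -> float:
        return float(self.table.set_index("tm_id").loc[tm, "dtilt_mean"])


def shift_tilt_report(
    ens_O: TrajectoryEnsemble,
    ref_I: np.ndarray,
    dm: DomainMap,
    include_regions: bool = True,
) -> ShiftTiltReport:
    """Core-helix z-shift and tilt change between two states.

    Every frame of the outward ensemble is superposed onto the inward
    reference using the gate Cα only; per core TM, Δz is the mean over
    frames of COM_z(O frame) − COM_z(ref I) and Δtilt the mean of
    tilt(O frame) − tilt(ref I).  Extra regions declared in the domain map
    (e.g. the binding-site β-sheet, "BS") are reported as their own rows.
    """
    top = ens_O.topology
    gate_residues = dm.residues_of_domain("gate")
    gate_idx = top.ca_indices(gate_residues)
    if len(gate_idx) < 3:
        raise ValueError("gate selection must contain at least 3 residues")
    ref_I = np.asarray(ref_I, dtype=float)

    targets: list[tuple[object, str, list[int]]] = [
        (tm, "core", dm.residues_of_tm(tm)) for tm in dm.core_tms
    ]
    if include_regions:
        targets += [
            (name, "region", dm.residues_of_region(name))
            for name in dm.extra_regions
        ]

    ref_vals = {}
    for key, _, residues in targets:
        idx = top.ca_indices(residues)
        x = ref_I[idx]
        ref_vals[key] = (x[:, 2].mean(), tilt_angle(helix_axis(x)))

    rows = {key: ([], []) for key, _, _ in targets}
    for f in range(ens_O.n_frames):
        frame = ens_O.coords[f]
        sup = kabsch_superpose(frame[gate_idx], ref_I[gate_idx])
        aligned = sup.apply(frame)
        for key, _, residues in targets:
            idx = top.ca_indices(residues)
            x = aligned[idx]
            dz_list, dt_list = rows[key]
            dz_list.append(x[:, 2].mean() - ref_vals[key][0])
            dt_list.append(tilt_angle(helix_axis(x)) - ref_vals[key][1])

    records = []
    for key, kind, _ in targets:
        dz_arr = np.asarray(rows[key][0])
        dt_arr = np.asarray(rows[key][1])
        records.append(
            {
                "tm_id": key,
                "domain": kind if kind == "region" else dm.domain_of_tm[key],
                "dz_mean": dz_arr.mean(),
                "dz_sd": dz_arr.std(ddof=0),
                "dtilt_mean": dt_arr.mean(),
                "dtilt_sd": dt_arr.std(ddof=0),
            }
        )
    return ShiftTiltReport(table=pd.DataFrame(records))


# ---------------------------------------------------------------------------
# Representative structure
# ---------------------------------------------------------------------------


def representative_structure(
    ens: TrajectoryEnsemble,
    model: ClusterModel,
    selection: Sequence[int] | None = None,
) -> tuple[int, np.ndarray]:
    """Most representative frame of an ensemble: the medoid of the most
    populated cluster (the member with minimal mean Cα RMSD to the other
    members; first frame on ties).  Returns (frame index, coordinates)."""
    labels = np.asarray(model.labels)
    if len(labels) != ens.n_frames:
        raise ValueError("cluster model does not match ensemble frame count")
    counts = np.bincount(labels, minlength=model.K)
    biggest = int(np.argmax(counts))
    members = np.flatnonzero(labels == biggest)
    if selection is None:
        selection = ens.topology.protein_residues
    x = ens.ca_coords(selection)
    if len(members) == 1:
        f = int(members[0])
        return f, ens.coords[f].copy()
    mean_rmsd = np.zeros(len(members))
    for a, fa in enumerate(members):
        total = 0.0
        for fb in members:
            if fb == fa:
                continue
            total += kabsch_superpose(x[fa], x[fb]).rmsd
        mean_rmsd[a] = total / (len(members) - 1)
    f = int(members[int(np.argmin(mean_rmsd))])
    return f, ens.coords[f].copy()
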