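"""Synthetic helical-bundle topologies and trajectories with planted truth.

Real production trajectories of a 14-TM transporter run to hundreds of
nanoseconds and are far too large for a test suite, so every analysis stage
in this package is exercised against miniature Cα-only helix bundles whose
statistical structure is *planted* and therefore exactly known:

* multi-basin conformational ensembles (a chosen helix displaced between
  metastable offsets, plus isotropic Gaussian noise),
* typed residue contacts held at prescribed occurrence fractions,
* a rigid-body z-translation and tilt of the core helices relative to a
  statistically identical gate (the elevator motif),
* diffusing ions with scripted residence episodes at a binding site.

Each generator returns the trajectory together with a :class:`PlantedTruth`
record sufficient to score the downstream recovery.  All generators are
deterministic under a fixed seed.  The noise model is iid isotropic
Gaussian per atom per frame — it emulates thermal fluctuation amplitudes,
not kinetics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_model import (
    Atom,
    DomainMap,
    Residue,
    Topology,
    TrajectoryEnsemble,
    default_domain_of_tm,
)
from .network import ContactCriteria

# ideal α-helix backbone geometry (Cα trace)
HELIX_RADIUS = 2.3  # Å
HELIX_TWIST_DEG = 100.0  # per residue
DEFAULT_HELIX_RISE = 1.5  # Å per residue

#: Residue-name palette cycled along each helix; mixes hydrophobic, polar
#: and charged names so that every interaction type is plantable.
DEFAULT_PALETTE = ("LEU", "ALA", "SER", "VAL", "LYS", "ILE", "GLU", "THR")


@dataclass(frozen=True)
class BundleSpec:
    """Geometry of a toy Cα-only helix bundle standing in for a TMD."""

    n_helices: int
    residues_per_helix: int
    helix_rise: float = DEFAULT_HELIX_RISE  # Å per residue
    bundle_radius: float = 12.0  # Å, helix axes on this circle
    domain_split: Mapping[int, str] | None = None  # helix id -> core/gate
    palette: Sequence[str] = DEFAULT_PALETTE

    def __post_init__(self):
        if self.n_helices < 2:
            raise ValueError("bundle needs at least 2 helices")
        if self.residues_per_helix < 6:
            raise ValueError("helices need at least 6 residues")

    def helix_range(self, helix_id: int) -> tuple[int, int]:
        """Inclusive 1-based residue range of a helix (1-based helix id)."""
        lo = (helix_id - 1) * self.residues_per_helix + 1
        return (lo, lo + self.residues_per_helix - 1)

    def helix_residues(self, helix_id: int) -> list[int]:
        lo, hi = self.helix_range(helix_id)
        return list(range(lo, hi + 1))

    def domain_map(self, binding_site_residues: set[int] | None = None) -> DomainMap:
        """DomainMap over the bundle's helices.

        Uses the supplied ``domain_split`` if given; a 14-helix bundle falls
        back to the canonical inverted-repeat split, any other size assigns
        the first half of the helices to the core and the rest to the gate.
        """
        ids = range(1, self.n_helices + 1)
        if self.domain_split is not None:
            split = dict(self.domain_split)
        elif self.n_helices == 14:
            split = default_domain_of_tm(ids)
        else:
            half = self.n_helices // 2
            split = {h: ("core" if h <= half else "gate") for h in ids}
        return DomainMap(
            tm_ranges={h: self.helix_range(h) for h in ids},
            domain_of_tm=split,
            binding_site_residues=binding_site_residues or set(),
        )


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside a synthetic trajectory."""

    cluster_labels: np.ndarray | None = None
    planted_edges: list[tuple[int, int, str, float]] = field(default_factory=list)
    planted_shift_z: dict[int, float] = field(default_factory=dict)  # Å per helix
    planted_tilt_deg: dict[int, float] = field(default_factory=dict)
    ion_schedule: list[tuple[int, int, int]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        d = {
            "cluster_labels": None
            if self.cluster_labels is None
            else [int(v) for v in self.cluster_labels],
            "planted_edges": [list(e) for e in self.planted_edges],
            "planted_shift_z": {str(k): v for k, v in self.planted_shift_z.items()},
            "planted_tilt_deg": {str(k): v for k, v in self.planted_tilt_deg.items()},
            "ion_schedule": [list(s) for s in self.ion_schedule],
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            cluster_labels=None
            if d["cluster_labels"] is None
            else np.asarray(d["cluster_labels"], dtype=int),
            planted_edges=[tuple(e) for e in d["planted_edges"]],
            planted_shift_z={int(k): v for k, v in d["planted_shift_z"].items()},
            planted_tilt_deg={int(k): v for k, v in d["planted_tilt_deg"].items()},
            ion_schedule=[tuple(s) for s in d["ion_schedule"]],
        )


# ---------------------------------------------------------------------------
# Bundle construction
# ---------------------------------------------------------------------------


def build_bundle(spec: BundleSpec, seed: int = 0) -> tuple[Topology, np.ndarray]:
    """Build an ideal Cα-only helix bundle.

    Helices are ideal α-helical Cα traces (2.3 Å radius, 100°/residue twist,
    ``helix_rise`` per residue) with axes along +z, placed on a circle of
    ``bundle_radius`` in the xy-plane.  The seed only randomises the helical
    phase of each helix; the construction is otherwise deterministic.
    """
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    residues: list[Residue] = []
    ca_of: dict[int, int] = {}
    coords = np.zeros((spec.n_helices * spec.residues_per_helix, 3))
    atom_index = 0
    for h in range(1, spec.n_helices + 1):
        angle = 2.0 * np.pi * (h - 1) / spec.n_helices
        center = spec.bundle_radius * np.array([np.cos(angle), np.sin(angle), 0.0])
        phase = rng.uniform(0.0, 2.0 * np.pi)
        for k, resid in enumerate(spec.helix_residues(h)):
            theta = phase + np.deg2rad(HELIX_TWIST_DEG) * k
            coords[atom_index] = center + np.array(
                [
                    HELIX_RADIUS * np.cos(theta),
                    HELIX_RADIUS * np.sin(theta),
                    spec.helix_rise * k,
                ]
            )
            name = spec.palette[k % len(spec.palette)]
            residues.append(Residue(resid, name, "A"))
            atoms.append(Atom(atom_index, "CA", "C", resid))
            ca_of[resid] = atom_index
            atom_index += 1
    top = Topology(atoms=atoms, residues=residues, ca_index_of_residue=ca_of)
    return top, coords


def _noisy_frames(
    ref: np.ndarray, n_frames: int, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    frames = np.repeat(ref[None, :, :], n_frames, axis=0)
    if sigma > 0:
        frames = frames + rng.normal(scale=sigma, size=frames.shape)
    return frames


# ---------------------------------------------------------------------------
# Multi-basin ensembles
# ---------------------------------------------------------------------------


def generate_basin_trajectory(
    top: Topology,
    ref_coords: np.ndarray,
    basin_offsets: Sequence[Sequence[float]],
    frames_per_basin: int,
    noise_sigma: float,
    seed: int,
    moving_residues: Sequence[int],
) -> tuple[TrajectoryEnsemble, PlantedTruth]:
    """Sample a multi-basin ensemble: for each basin, the reference with
    ``moving_residues`` rigidly displaced by the basin's offset vector, plus
    iid Gaussian noise on every atom.  Frames are ordered basin-by-basin and
    the per-frame basin labels are recorded as planted truth."""
    if len(basin_offsets) < 1:
        raise ValueError("need at least one basin")
    if frames_per_basin < 1:
        raise ValueError("frames_per_basin must be >= 1")
    rng = np.random.default_rng(seed)
    move_idx = top.ca_indices(moving_residues)
    all_frames = []
    labels = []
    for b, offset in enumerate(basin_offsets):
        basin_ref = ref_coords.copy()
        basin_ref[move_idx] += np.asarray(offset, dtype=float)
        all_frames.append(_noisy_frames(basin_ref, frames_per_basin, noise_sigma, rng))
        labels.extend([b] * frames_per_basin)
    coords = np.concatenate(all_frames, axis=0)
    times = np.arange(len(coords), dtype=float)
    ens = TrajectoryEnsemble(coords, times, top)
    return ens, PlantedTruth(cluster_labels=np.asarray(labels, dtype=int))


# ---------------------------------------------------------------------------
# Elevator-style shift + tilt pairs
# ---------------------------------------------------------------------------


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()


def generate_shift_tilt_trajectory(
    top: Topology,
    ref_coords: np.ndarray,
    dm: DomainMap,
    dz: float,
    dtilt_deg: float,
    n_frames: int,
    noise_sigma: float,
    seed: int,
    tilt_axis: Sequence[float] | None = None,
) -> tuple[TrajectoryEnsemble, TrajectoryEnsemble, PlantedTruth]:
    """Generate paired "inward" (I) and "outward" (O) ensembles.

    State O is state I with each core helix rigidly translated by ``dz``
    along z and tilted by ``dtilt_deg`` about a membrane-plane axis through
    the helix's own centre of mass.  By default the rotation axis is the
    horizontal direction perpendicular to the plane spanned by the helix
    axis and z, so the helix tilt angle changes by exactly ``dtilt_deg``;
    a fixed ``tilt_axis`` may be supplied instead.  Gate helices are
    statistically identical between the two states.
    """
    from .geometry import helix_axis

    core = dm.core_tms
    if not core:
        raise ValueError("domain map defines no core helices")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    ref_O = ref_coords.copy()
    for tm in core:
        idx = top.ca_indices(dm.residues_of_tm(tm))
        if tilt_axis is None:
            # ẑ × axis: positive dtilt rotates the helix *away* from z,
            # so tilt(O) − tilt(I) = +dtilt as long as the result stays
            # within [0°, 180°]
            a0 = helix_axis(ref_coords[idx])
            axis = np.cross([0.0, 0.0, 1.0], a0)
            if np.linalg.norm(axis) < 1e-12:
                axis = np.array([1.0, 0.0, 0.0])
        else:
            axis = np.asarray(tilt_axis, dtype=float)
        R = _rotation_about_axis(axis, dtilt_deg)
        com = ref_coords[idx].mean(axis=0)
        moved = (ref_coords[idx] - com) @ R.T + com
        moved[:, 2] += dz
        ref_O[idx] = moved
    ens_I = TrajectoryEnsemble(
        _noisy_frames(ref_coords, n_frames, noise_sigma, rng),
        np.arange(n_frames, dtype=float),
        top,
    )
    ens_O = TrajectoryEnsemble(
        _noisy_frames(ref_O, n_frames, noise_sigma, rng),
        np.arange(n_frames, dtype=float),
        top,
    )
    truth = PlantedTruth(
        planted_shift_z={tm: float(dz) for tm in core},
        planted_tilt_deg={tm: float(dtilt_deg) for tm in core},
    )
    return ens_I, ens_O, truth


# ---------------------------------------------------------------------------
# Planted persistent contacts
# ---------------------------------------------------------------------------


def plant_contact_trajectory(
    top: Topology,
    ref_coords: np.ndarray,
    planted_edges: Sequence[tuple[int, int, str, float]],
    n_frames: int,
    seed: int,
    criteria: ContactCriteria | None = None,
) -> tuple[TrajectoryEnsemble, PlantedTruth]:
    """Plant typed residue contacts at exact occurrence fractions.

    For each planted edge ``(res_a, res_b, type, persistence_fraction)`` the
    Cα of ``res_b`` is pulled inside the type's contact cutoff in
    ``round(persistence_fraction * n_frames)`` randomly chosen "on" frames
    and pushed beyond cutoff + 2 Å otherwise.  ``res_a`` stays put, so a
    residue may anchor several edges (a star/hub motif) but may be the
    *moved* partner of at most one, and may not be both moved and an
    anchor; violations are conflicting geometric constraints.  The pair's
    residue names must be eligible for the requested type.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    crit = criteria or ContactCriteria.ca_proxy()
    rng = np.random.default_rng(seed)

    moved: set[int] = set()
    anchors: set[int] = set()
    for (ra, rb, kind, frac) in planted_edges:
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"persistence fraction {frac} outside [0, 1]")
        if abs(ra - rb) <= 1:
            raise ValueError(f"cannot plant sequence-adjacent edge {ra}-{rb}")
        if rb in moved or rb in anchors or ra in moved:
            clash = rb if (rb in moved or rb in anchors) else ra
            raise ValueError(
                f"conflicting geometric constraints: residue {clash} cannot "
                "be moved for more than one planted edge (or both moved and "
                "used as an anchor)"
            )
        moved.add(rb)
        anchors.add(ra)
        name_a = top.residue(ra).name
        name_b = top.residue(rb).name
        if not crit.pair_eligible(name_a, name_b, kind):
            raise ValueError(
                f"residues {ra} ({name_a}) and {rb} ({name_b}) cannot form a "
                f"{kind} interaction"
            )

    coords = np.repeat(ref_coords[None, :, :], n_frames, axis=0)
    for (ra, rb, kind, frac) in planted_edges:
        cutoff = crit.cutoff_of(kind)
        ia = top.ca_index_of_residue[ra]
        ib = top.ca_index_of_residue[rb]
        direction = ref_coords[ib] - ref_coords[ia]
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        n_on = int(round(frac * n_frames))
        on_frames = rng.choice(n_frames, size=n_on, replace=False)
        on_mask = np.zeros(n_frames, dtype=bool)
        on_mask[on_frames] = True
        pos_on = ref_coords[ia] + direction * (0.8 * cutoff)
        pos_off = ref_coords[ia] + direction * (cutoff + 3.0)
        coords[on_mask, ib] = pos_on
        coords[~on_mask, ib] = pos_off
    ens = TrajectoryEnsemble(coords, np.arange(n_frames, dtype=float), top)
    return ens, PlantedTruth(planted_edges=[tuple(e) for e in planted_edges])


# ---------------------------------------------------------------------------
# Scripted ion trajectories
# ---------------------------------------------------------------------------

ION_RESNAME = "CLA"
ION_ATOM_NAME = "CL"
ION_CONTACT_MARGIN = 0.4  # Å of jitter around the scheduled bound position


def generate_ion_trajectory(
    top: Topology,
    ref_coords: np.ndarray,
    binding_site_residues: Sequence[int],
    ion_schedule: Sequence[tuple[int, int, int]],
    n_ions: int,
    n_frames: int,
    box: float = 80.0,
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> tuple[TrajectoryEnsemble, PlantedTruth]:
    """Protein frames plus diffusing ion pseudo-atoms with scripted visits.

    The schedule lists ``(ion_id, start_frame, end_frame)`` residence
    episodes (inclusive, disjoint per ion).  During an episode the ion sits
    within 3 Å of the binding-site Cα centroid (and within contact distance
    of at least one site residue); outside episodes it random-walks in the
    box, kept at least 8 Å from the site centroid and clear of contact with
    the site residues.  The returned ensemble's topology is the input
    topology extended with the ion pseudo-atoms.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n_ions < 0:
        raise ValueError("n_ions must be >= 0")
    binding_site_residues = list(binding_site_residues)
    if not binding_site_residues:
        raise ValueError("binding_site_residues must be non-empty")

    per_ion: dict[int, list[tuple[int, int]]] = {}
    for (ion, lo, hi) in ion_schedule:
        if not (0 <= lo <= hi < n_frames):
            raise ValueError(f"episode ({ion}, {lo}, {hi}) outside [0, {n_frames})")
        if not (0 <= ion < n_ions):
            raise ValueError(f"ion id {ion} outside 0..{n_ions - 1}")
        per_ion.setdefault(ion, []).append((lo, hi))
    for ion, eps in per_ion.items():
        eps = sorted(eps)
        for (a_lo, a_hi), (b_lo, b_hi) in zip(eps, eps[1:]):
            if b_lo <= a_hi:
                raise ValueError(
                    f"overlapping episodes for ion {ion}: "
                    f"({a_lo}, {a_hi}) and ({b_lo}, {b_hi})"
                )

    rng = np.random.default_rng(seed)
    site_idx = top.ca_indices(binding_site_residues)
    site_ca = ref_coords[site_idx]
    centroid = site_ca.mean(axis=0)
    d_near = np.linalg.norm(site_ca - centroid, axis=1).min()
    nearest = site_ca[np.argmin(np.linalg.norm(site_ca - centroid, axis=1))]
    if d_near > 6.0:
        raise ValueError(
            "binding site too diffuse: nearest site residue is "
            f"{d_near:.1f} Å from the centroid (> 6 Å)"
        )
    # bound anchor: on the segment nearest-CA -> centroid, within 2.5 Å of
    # the centroid and 3.5 Å of the nearest CA, so a 4 Å contact cutoff and
    # the 3 Å-from-centroid contract both hold after jitter.
    if d_near <= 3.5:
        anchor = centroid
    else:
        anchor = nearest + 3.5 * (centroid - nearest) / d_near

    # extended topology with ion pseudo-atoms
    max_resid = max(r.index for r in top.residues)
    atoms = list(top.atoms)
    residues = list(top.residues)
    ca_of = dict(top.ca_index_of_residue)
    ion_atom_idx = []
    for i in range(n_ions):
        resid = max_resid + 1 + i
        idx = top.n_atoms + i
        residues.append(Residue(resid, ION_RESNAME, "I"))
        atoms.append(Atom(idx, ION_ATOM_NAME, "Cl", resid))
        ion_atom_idx.append(idx)
    ext_top = Topology(atoms=atoms, residues=residues, ca_index_of_residue=ca_of)

    protein_frames = _noisy_frames(ref_coords, n_frames, noise_sigma, rng)
    coords = np.zeros((n_frames, ext_top.n_atoms, 3))
    coords[:, : top.n_atoms, :] = protein_frames

    half = box / 2.0
    for i in range(n_ions):
        bound = np.zeros(n_frames, dtype=bool)
        for (lo, hi) in per_ion.get(i, ()):
            bound[lo : hi + 1] = True
        pos = _far_position(centroid, site_ca, half, rng)
        for f in range(n_frames):
            if bound[f]:
                jitter = rng.normal(size=3)
                jitter *= ION_CONTACT_MARGIN * rng.uniform() / np.linalg.norm(jitter)
                coords[f, ion_atom_idx[i]] = anchor + jitter
            else:
                pos = pos + rng.normal(scale=1.0, size=3)
                pos = np.clip(pos, -half, half)
                if (
                    np.linalg.norm(pos - centroid) < 8.0
                    or np.linalg.norm(site_ca - pos, axis=1).min() < 5.0
                ):
                    pos = _far_position(centroid, site_ca, half, rng)
                coords[f, ion_atom_idx[i]] = pos
    ens = TrajectoryEnsemble(coords, np.arange(n_frames, dtype=float), ext_top)
    truth = PlantedTruth(ion_schedule=[tuple(s) for s in ion_schedule])
    return ens, truth


def _far_position(
    centroid: np.ndarray,
    site_ca: np.ndarray,
    half: float,
    rng: np.random.Generator,
    min_dist: float = 8.0,
) -> np.ndarray:
    """A random position >= ``min_dist`` from the centroid and clear of the
    site residues."""
    for _ in range(200):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        r = min_dist + 0.5 + rng.exponential(4.0)
        pos = centroid + r * direction
        pos = np.clip(pos, -half, half)
        if (
            np.linalg.norm(pos - centroid) >= min_dist
            and np.linalg.norm(site_ca - pos, axis=1).min() >= 5.0
        ):
            return pos
    raise RuntimeError("could not place ion away from the binding site")
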