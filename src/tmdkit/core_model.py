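"""Topology/trajectory data model, standard-format I/O and Kabsch superposition.

Everything downstream (fluctuation profiles, landscapes, interaction
networks, helix geometry, ion analysis) operates on the two containers
defined here: a :class:`Topology` describing atoms and residues, and a
:class:`TrajectoryEnsemble` holding an ``F x A x 3`` coordinate array in
Angstrom.  File I/O goes through MDAnalysis (PDB topologies, DCD/XTC
trajectories); the containers themselves are plain NumPy so that synthetic
ensembles can be built without touching disk.

Conventions: right-handed axes with z along the membrane normal (positive z
pointing to the extracellular side); all lengths in Angstrom; residue
indices are 1-based as in PDB files.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

#: Three-letter codes treated as protein residues.
STANDARD_AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE HSP ILE LEU LYS MET
    PHE PRO SER THR TRP TYR VAL""".split()
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class Atom:
    index: int
    name: str
    element: str
    residue_index: int


@dataclass(frozen=True)
class Residue:
    index: int
    name: str
    chain: str


@dataclass
class Topology:
    """Atoms, residues and the Cα bookkeeping used by every selection."""

    atoms: list[Atom]
    residues: list[Residue]
    ca_index_of_residue: dict[int, int]
    source: Path | None = None

    def __post_init__(self) -> None:
        self._residue_by_index = {r.index: r for r in self.residues}
        self._atoms_of_residue: dict[int, list[int]] = {}
        for a in self.atoms:
            self._atoms_of_residue.setdefault(a.residue_index, []).append(a.index)
        self.validate()

    # -- accessors ---------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue(self, residue_index: int) -> Residue:
        return self._residue_by_index[residue_index]

    def has_residue(self, residue_index: int) -> bool:
        return residue_index in self._residue_by_index

    def atoms_of_residue(self, residue_index: int) -> list[int]:
        return self._atoms_of_residue[residue_index]

    def is_protein(self, residue_index: int) -> bool:
        return self._residue_by_index[residue_index].name in STANDARD_AMINO_ACIDS

    @property
    def protein_residues(self) -> list[int]:
        return [r.index for r in self.residues if r.name in STANDARD_AMINO_ACIDS]

    def ca_indices(self, residue_indices: Iterable[int] | None = None) -> np.ndarray:
        """Atom indices of the Cα of the given residues (all protein residues
        by default), in residue order."""
        if residue_indices is None:
            residue_indices = self.protein_residues
        return np.asarray(
            [self.ca_index_of_residue[r] for r in residue_indices], dtype=int
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        indices = [a.index for a in self.atoms]
        if len(set(indices)) != len(indices):
            raise ValueError("atom indices are not unique")
        per_chain: dict[str, int] = {}
        for r in self.residues:
            prev = per_chain.get(r.chain)
            if prev is not None and r.index <= prev:
                raise ValueError(
                    f"residue indices not strictly increasing in chain {r.chain!r}"
                    f" (residue {r.index} after {prev})"
                )
            per_chain[r.chain] = r.index
        for r in self.residues:
            if r.name in STANDARD_AMINO_ACIDS and r.index not in self.ca_index_of_residue:
                raise ValueError(f"residue {r.index} has no CA")


@dataclass
class TrajectoryEnsemble:
    """F frames × A atoms Cartesian coordinates (Å) with timestamps (ns)."""

    coords: np.ndarray
    times: np.ndarray
    topology: Topology

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be F x A x 3, got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in trajectory")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"trajectory has {self.coords.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if len(self.times) != len(self.coords):
            raise ValueError("times and coords disagree on frame count")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("frame times must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def ca_coords(self, residue_indices: Iterable[int] | None = None) -> np.ndarray:
        """F × R × 3 Cα coordinates for the selected residues."""
        return self.coords[:, self.topology.ca_indices(residue_indices), :]

    def subset_frames(self, frame_indices: Sequence[int]) -> "TrajectoryEnsemble":
        idx = np.asarray(frame_indices, dtype=int)
        return TrajectoryEnsemble(self.coords[idx], self.times[idx], self.topology)


# ---------------------------------------------------------------------------
# Domain bookkeeping
# ---------------------------------------------------------------------------

DEFAULT_CORE_TMS = frozenset({1, 2, 3, 4, 8, 9, 10, 11})
DEFAULT_GATE_TMS = frozenset({5, 6, 7, 12, 13, 14})


def default_domain_of_tm(tm_ids: Iterable[int]) -> dict[int, str]:
    """Core/gate split of a 14-helix bundle following the inverted-repeat
    transporter convention (core = TM1-4, TM8-11; gate = TM5-7, TM12-14)."""
    out = {}
    for tm in tm_ids:
        out[tm] = "core" if tm in DEFAULT_CORE_TMS else "gate"
    return out


@dataclass
class DomainMap:
    """TM helix residue ranges, the core/gate split, and binding-site residues."""

    tm_ranges: dict[int, tuple[int, int]]
    domain_of_tm: dict[int, str] = field(default_factory=dict)
    inner_shell: set[int] | None = None
    binding_site_residues: set[int] = field(default_factory=set)
    extra_regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.domain_of_tm:
            self.domain_of_tm = default_domain_of_tm(self.tm_ranges)
        self.validate()

    def validate(self) -> None:
        spans = sorted(
            (int(lo), int(hi), tm) for tm, (lo, hi) in self.tm_ranges.items()
        )
        for (lo, hi, tm) in spans:
            if hi < lo:
                raise ValueError(f"TM{tm} range ({lo}, {hi}) is inverted")
        for (_, hi_a, tm_a), (lo_b, _, tm_b) in zip(spans, spans[1:]):
            if lo_b <= hi_a:
                raise ValueError(f"TM{tm_a} and TM{tm_b} residue ranges overlap")
        for tm in self.tm_ranges:
            dom = self.domain_of_tm.get(tm)
            if dom not in ("core", "gate"):
                raise ValueError(f"TM{tm} not assigned to core or gate")

    # -- queries -----------------------------------------------------------

    @property
    def tm_ids(self) -> list[int]:
        return sorted(self.tm_ranges)

    def tms_of_domain(self, domain: str) -> list[int]:
        return [tm for tm in self.tm_ids if self.domain_of_tm[tm] == domain]

    @property
    def core_tms(self) -> list[int]:
        return self.tms_of_domain("core")

    @property
    def gate_tms(self) -> list[int]:
        return self.tms_of_domain("gate")

    def residues_of_tm(self, tm: int) -> list[int]:
        lo, hi = self.tm_ranges[tm]
        return list(range(lo, hi + 1))

    def residues_of_domain(self, domain: str) -> list[int]:
        out: list[int] = []
        for tm in self.tms_of_domain(domain):
            out.extend(self.residues_of_tm(tm))
        return out

    def residues_of_region(self, region: str) -> list[int]:
        lo, hi = self.extra_regions[region]
        return list(range(lo, hi + 1))

    def tm_of_residue(self, residue_index: int) -> int | None:
        for tm, (lo, hi) in self.tm_ranges.items():
            if lo <= residue_index <= hi:
                return tm
        return None

    def domain_of_residue(self, residue_index: int) -> str | None:
        tm = self.tm_of_residue(residue_index)
        return None if tm is None else self.domain_of_tm[tm]

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tm_ranges": {int(k): list(v) for k, v in self.tm_ranges.items()},
            "domain_of_tm": {int(k): v for k, v in self.domain_of_tm.items()},
            "inner_shell": sorted(self.inner_shell) if self.inner_shell else None,
            "binding_site_residues": sorted(self.binding_site_residues),
            "extra_regions": {k: list(v) for k, v in self.extra_regions.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DomainMap":
        return cls(
            tm_ranges={int(k): tuple(v) for k, v in d["tm_ranges"].items()},
            domain_of_tm={int(k): v for k, v in d.get("domain_of_tm", {}).items()},
            inner_shell=set(d["inner_shell"]) if d.get("inner_shell") else None,
            binding_site_residues=set(d.get("binding_site_residues", ())),
            extra_regions={
                k: tuple(v) for k, v in d.get("extra_regions", {}).items()
            },
        )


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


from contextlib import contextmanager


@contextmanager
def _suppress_mda_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        warnings.filterwarnings("ignore", category=DeprecationWarning)
        yield


def load_topology(path: str | Path) -> Topology:
    """Parse ATOM/HETATM records of a PDB file into a :class:`Topology`.

    Only standard amino acids are treated as protein residues; alternate
    locations are resolved by keeping the highest-occupancy copy (first on a
    tie).  A protein residue without a Cα atom is an error.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _precheck_pdb(path)
    with _suppress_mda_warnings():
        u = mda.Universe(str(path))
        try:
            elements = list(u.atoms.elements)
        except Exception:
            from MDAnalysis.topology.guessers import guess_types

            elements = list(guess_types(u.atoms.names))
        occupancies = getattr(u.atoms, "occupancies", np.ones(len(u.atoms)))
        altlocs = getattr(u.atoms, "altLocs", [""] * len(u.atoms))

        # resolve alternate locations: keep highest occupancy, first on tie
        keep: dict[tuple, int] = {}
        for i, atom in enumerate(u.atoms):
            key = (atom.segid, atom.resid, atom.name)
            if altlocs[i] in ("", " "):
                keep.setdefault(key, i)
                continue
            j = keep.get(key)
            if j is None or occupancies[i] > occupancies[j] + 1e-12:
                keep[key] = i
        kept = sorted(keep.values())

        atoms: list[Atom] = []
        residues: list[Residue] = []
        ca_of: dict[int, int] = {}
        seen_res: dict[int, str] = {}
        for i in kept:
            atom = u.atoms[i]
            resid = int(atom.resid)
            chain = str(getattr(atom, "chainID", "") or atom.segid or "A")
            if resid not in seen_res:
                seen_res[resid] = chain
                residues.append(Residue(resid, str(atom.resname), chain))
            elif seen_res[resid] != chain:
                # residue indices are the global keys of every downstream
                # selection; duplicate numbering across chains is ambiguous
                raise ValueError(
                    f"residue index {resid} appears in chains "
                    f"{seen_res[resid]!r} and {chain!r}; renumber to make "
                    "residue indices unique"
                )
            atoms.append(Atom(int(atom.ix), str(atom.name), str(elements[i]).capitalize() or "X", resid))
            if atom.name == "CA":
                ca_of.setdefault(resid, int(atom.ix))
    top = Topology(atoms=atoms, residues=residues, ca_index_of_residue=ca_of, source=path)
    return top


def _precheck_pdb(path: Path) -> None:
    """Cheap line-level sanity check so parse failures carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                raise ValueError(
                    f"{path}: unparseable coordinate fields on line {lineno}: "
                    f"{line.rstrip()!r}"
                ) from None


def reference_coords(path: str | Path) -> np.ndarray:
    """Coordinates (A × 3, Å) of the single model stored in a PDB file."""
    import MDAnalysis as mda

    with _suppress_mda_warnings():
        u = mda.Universe(str(path))
        return u.atoms.positions.astype(float).copy()


def load_trajectory(
    top: Topology,
    path: str | Path,
    frame_spacing_ns: float | None = None,
) -> TrajectoryEnsemble:
    """Load a DCD or XTC trajectory against an existing topology.

    Frame times come from the file metadata (converted ps → ns) unless
    ``frame_spacing_ns`` overrides them or the metadata is degenerate.
    """
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.XTC import XTCReader

    path = Path(path)
    suffix = path.suffix.lower()
    readers = {".dcd": DCDReader, ".xtc": XTCReader}
    if suffix not in readers:
        raise ValueError(f"unsupported trajectory format {suffix!r} (use .dcd/.xtc)")
    with _suppress_mda_warnings():
        reader = readers[suffix](str(path))
        if reader.n_atoms != top.n_atoms:
            raise ValueError(
                f"trajectory has {reader.n_atoms} atoms but topology has "
                f"{top.n_atoms}"
            )
        coords = []
        times = []
        for ts in reader:
            coords.append(ts.positions.astype(float).copy())
            times.append(float(ts.time) / 1000.0)  # ps → ns
        reader.close()
    coords = np.asarray(coords)
    times = np.asarray(times)
    if frame_spacing_ns is not None:
        times = np.arange(len(coords)) * float(frame_spacing_ns)
    elif len(times) > 1 and (np.any(np.diff(times) < 0) or np.allclose(times, times[0])):
        logger.warning("degenerate frame times in %s; using 1 ns spacing", path)
        times = np.arange(len(coords), dtype=float)
    return TrajectoryEnsemble(coords, times, top)


def write_trajectory(ens: TrajectoryEnsemble, path: str | Path) -> None:
    """Write an ensemble to DCD or XTC (XTC at 1e-3 Å precision)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDWriter
    from MDAnalysis.coordinates.XTC import XTCWriter

    path = Path(path)
    suffix = path.suffix.lower()
    n = ens.coords.shape[1]
    with _suppress_mda_warnings():
        u = mda.Universe.empty(n, trajectory=True)
        if suffix == ".xtc":
            # 4 decimal places in nm → 5e-4 Å round-trip error at most
            writer = XTCWriter(str(path), n, precision=4)
        elif suffix == ".dcd":
            writer = DCDWriter(str(path), n)
        else:
            raise ValueError(f"unsupported trajectory format {suffix!r}")
        with writer:
            for i in range(ens.n_frames):
                u.atoms.positions = ens.coords[i].astype(np.float32)
                u.trajectory.ts.frame = i
                u.trajectory.ts.time = float(ens.times[i]) * 1000.0  # ns → ps
                writer.write(u.atoms)


def write_pdb(top: Topology, coords: np.ndarray, path: str | Path) -> None:
    """Write a topology + one coordinate set as a PDB file."""
    import MDAnalysis as mda

    coords = np.asarray(coords, dtype=float)
    if coords.shape != (top.n_atoms, 3):
        raise ValueError(f"coords shape {coords.shape} != ({top.n_atoms}, 3)")
    res_order = [r.index for r in top.residues]
    res_pos = {r: i for i, r in enumerate(res_order)}
    atom_resindex = [res_pos[a.residue_index] for a in top.atoms]
    with _suppress_mda_warnings():
        u = mda.Universe.empty(
            top.n_atoms,
            n_residues=top.n_residues,
            atom_resindex=atom_resindex,
            trajectory=True,
        )
        u.add_TopologyAttr("name", [a.name for a in top.atoms])
        u.add_TopologyAttr("element", [a.element for a in top.atoms])
        u.add_TopologyAttr("resname", [r.name for r in top.residues])
        u.add_TopologyAttr("resid", [r.index for r in top.residues])
        u.add_TopologyAttr("chainID", [top.residue(a.residue_index).chain for a in top.atoms])
        u.atoms.positions = coords.astype(np.float32)
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


@dataclass
class Superposition:
    """A proper rigid-body transform mapping a mobile selection onto a
    reference, with the residual RMSD of the fit."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the transform to an M × 3 coordinate array."""
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Uses the Kabsch/Umeyama solution (via scipy's rotation fitting), with
    reflections excluded so the returned matrix is a proper rotation.
    Collinear inputs degrade gracefully: the component of the rotation about
    the degenerate axis is arbitrary but the RMSD is still minimised.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"shape mismatch {mobile.shape} vs {reference.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points for superposition, got {n}")
    mob_com = mobile.mean(axis=0)
    ref_com = reference.mean(axis=0)
    a = reference - ref_com
    b = mobile - mob_com
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        rot, rssd = Rotation.align_vectors(a, b)
    R = rot.as_matrix()
    t = ref_com - R @ mob_com
    rmsd = float(rssd) / np.sqrt(n)
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def _batched_kabsch_rotations(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Proper Kabsch rotations for a stack of centred mobile frames
    (F × N × 3) onto one centred reference (N × 3); returns F × 3 × 3."""
    C = np.einsum("fni,nj->fij", mobile, reference)  # covariance per frame
    U, _, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", U, Vt)))
    Vt[:, -1, :] *= d[:, None]
    # R = V · diag(1,1,d) · Uᵀ maps mobile onto reference (x' = R x)
    return np.einsum("fji,fkj->fik", Vt, U)


def superpose_frames(
    coords: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Superpose every frame of ``coords`` (F × A × 3) onto ``reference``
    (A × 3), fitting on ``fit_indices`` (all atoms by default) and applying
    the transform to the whole frame."""
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is None:
        fit_indices = np.arange(coords.shape[1])
    fit = coords[:, fit_indices, :]
    mob_com = fit.mean(axis=1)
    ref_fit = reference[fit_indices]
    ref_com = ref_fit.mean(axis=0)
    R = _batched_kabsch_rotations(fit - mob_com[:, None, :], ref_fit - ref_com)
    centered = coords - mob_com[:, None, :]
    return np.einsum("fni,fji->fnj", centered, R) + ref_com
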