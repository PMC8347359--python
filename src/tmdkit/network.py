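"""Persistence-weighted residue interaction networks.

A protein is represented as an undirected graph whose nodes are residues and
whose edges are typed non-bonded interactions (hydrophobic contacts,
hydrogen bonds, salt bridges) weighted by *persistence*: the percentage of
trajectory frames in which the interaction's geometric criterion holds.
Thresholding the graph by persistence and counting surviving connections
identifies *hubs* — residues that anchor the packing of the helix bundle —
and the largest-hydrophobic-cluster criterion picks the persistence
threshold at which the hydrophobic network disaggregates.

Full-atom criteria follow the PyInteraph conventions (side-chain-COM
distance for hydrophobic contacts, donor-acceptor heavy-atom distance plus
D-H-A angle for H-bonds, charged-group minimum distance for salt bridges).
Cα-only ensembles (the synthetic bundles) use Cα-proxy criteria with the
same cutoffs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core_model import DomainMap, Topology, TrajectoryEnsemble

logger = logging.getLogger(__name__)

INTERACTION_TYPES = ("hydrophobic", "hbond", "saltbridge")

#: Default PyInteraph-style hydrophobic residue set.
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}
)
#: Residues with polar side chains able to donate/accept hydrogen bonds.
POLAR_RESIDUES = frozenset(
    {"SER", "THR", "TYR", "ASN", "GLN", "HIS", "TRP", "LYS", "ARG", "ASP", "GLU"}
)
ACIDIC_RESIDUES = frozenset({"ASP", "GLU"})
BASIC_RESIDUES = frozenset({"LYS", "ARG"})

#: Charged-group side-chain atoms used for salt-bridge distances.
CHARGED_GROUP_ATOMS = {
    "ASP": ("CG", "OD1", "OD2"),
    "GLU": ("CD", "OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("CZ", "NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}

#: Heavy-atom H-bond donors/acceptors per residue (side chains).
HBOND_SIDECHAIN_ATOMS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("OD1", "ND2"), "GLN": ("OE1", "NE2"),
    "HIS": ("ND1", "NE2"), "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"),
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "TRP": ("NE1",),
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "H", "HA", "HN", "OXT"})


@dataclass(frozen=True)
class HydrophobicCriterion:
    residues: frozenset = HYDROPHOBIC_RESIDUES
    distance_cutoff: float = 5.0  # Å, side-chain COM (or Cα proxy)

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("hydrophobic cutoff must be positive")


@dataclass(frozen=True)
class HBondCriterion:
    distance_cutoff: float = 3.5  # Å, donor-acceptor heavy atoms
    angle_min: float = 120.0  # degrees, D-H-A, when hydrogens are present

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("hbond cutoff must be positive")
        if not (0.0 < self.angle_min <= 180.0):
            raise ValueError("hbond angle must lie in (0, 180]")


@dataclass(frozen=True)
class SaltBridgeCriterion:
    distance_cutoff: float = 4.5  # Å, min distance between charged groups
    protonated_his: bool = False  # treat His as basic when True

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("salt-bridge cutoff must be positive")


@dataclass(frozen=True)
class ContactCriteria:
    """Bundle of the three typed interaction criteria.

    ``site`` selects how residue positions are measured: ``sidechain_com``
    for full-atom systems, ``ca`` for Cα-only (synthetic) systems, where
    every criterion falls back to the Cα-Cα distance with its own cutoff.
    """

    hydrophobic: HydrophobicCriterion = field(default_factory=HydrophobicCriterion)
    hbond: HBondCriterion = field(default_factory=HBondCriterion)
    saltbridge: SaltBridgeCriterion = field(default_factory=SaltBridgeCriterion)
    site: Literal["sidechain_com", "ca"] = "sidechain_com"

    @classmethod
    def ca_proxy(cls, **kwargs) -> "ContactCriteria":
        """Criteria for Cα-only ensembles (synthetic bundles)."""
        return cls(site="ca", **kwargs)

    def cutoff_of(self, kind: str) -> float:
        return {
            "hydrophobic": self.hydrophobic.distance_cutoff,
            "hbond": self.hbond.distance_cutoff,
            "saltbridge": self.saltbridge.distance_cutoff,
        }[kind]

    def pair_eligible(self, name_a: str, name_b: str, kind: str) -> bool:
        """Can residues with these names form an interaction of this type?"""
        if kind == "hydrophobic":
            hs = self.hydrophobic.residues
            return name_a in hs and name_b in hs
        if kind == "hbond":
            return name_a in POLAR_RESIDUES and name_b in POLAR_RESIDUES
        if kind == "saltbridge":
            acidic, basic = set(ACIDIC_RESIDUES), set(BASIC_RESIDUES)
            if self.saltbridge.protonated_his:
                basic.add("HIS")
            return (name_a in acidic and name_b in basic) or (
                name_a in basic and name_b in acidic
            )
        raise ValueError(f"unknown interaction type {kind!r}")


@dataclass(frozen=True)
class Edge:
    res_a: int
    res_b: int
    kind: str
    persistence: float  # % of frames, in [0, 100]


@dataclass
class InteractionGraph:
    """Residue graph with typed, persistence-weighted edges."""

    edges: list[Edge]
    residue_names: dict[int, str]
    domain_of_residue: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        for e in self.edges:
            if e.res_a == e.res_b:
                raise ValueError(f"self-edge on residue {e.res_a}")
            if abs(e.res_a - e.res_b) <= 1:
                raise ValueError(
                    f"sequence-adjacent edge {e.res_a}-{e.res_b} not allowed"
                )
            if not (0.0 <= e.persistence <= 100.0):
                raise ValueError(f"persistence {e.persistence} outside [0, 100]")

    @property
    def nodes(self) -> set[int]:
        return set(self.residue_names)

    def edges_of_type(self, kind: str) -> list[Edge]:
        return [e for e in self.edges if e.kind == kind]

    def thresholded(self, threshold: float, kinds: Iterable[str] | None = None) -> list[Edge]:
        """Edges with persistence >= threshold (optionally of given types)."""
        kinds = set(kinds) if kinds is not None else set(INTERACTION_TYPES)
        return [e for e in self.edges if e.kind in kinds and e.persistence >= threshold]

    def to_networkx(self, threshold: float = 0.0) -> nx.Graph:
        """Simple graph of the thresholded network (parallel typed edges
        between the same residue pair collapse to one)."""
        g = nx.Graph()
        g.add_nodes_from(self.residue_names)
        for e in self.thresholded(threshold):
            g.add_edge(e.res_a, e.res_b)
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.res_a, e.res_b, e.kind, e.persistence) for e in self.edges],
            columns=["res_a", "res_b", "type", "persistence"],
        )


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def _sidechain_indices(top: Topology, residue_index: int) -> list[int]:
    return [
        i
        for i in top.atoms_of_residue(residue_index)
        if _atom_name(top, i) not in BACKBONE_ATOMS
        and not _atom_name(top, i).startswith("H")
    ]


def _atom_name(top: Topology, atom_index: int) -> str:
    # atoms list is indexed by position; atom_index values are positions in file order
    return top.atoms[atom_index].name


def _named_atom_indices(top: Topology, residue_index: int, names: Sequence[str]) -> list[int]:
    wanted = set(names)
    return [i for i in top.atoms_of_residue(residue_index) if _atom_name(top, i) in wanted]


def persistence_graph(
    ens: TrajectoryEnsemble,
    top: Topology,
    crit: ContactCriteria,
    dm: DomainMap | None = None,
) -> InteractionGraph:
    """Build the typed residue interaction graph over the ensemble.

    For each eligible residue pair (non-adjacent in sequence) and each
    interaction type, persistence is the percentage of frames in which the
    pair satisfies the type's geometric criterion; only positive
    persistences become edges.
    """
    protein = top.protein_residues
    F = ens.n_frames
    names = {r: top.residue(r).name for r in protein}

    # positions per kind (R x 3 per frame)
    counts: dict[tuple[int, int, str], int] = {}
    eligible: dict[str, list[tuple[int, int]]] = {k: [] for k in INTERACTION_TYPES}
    pos_of = {r: i for i, r in enumerate(protein)}
    for i, ra in enumerate(protein):
        for rb in protein[i + 1:]:
            if abs(ra - rb) <= 1:
                continue
            for kind in INTERACTION_TYPES:
                if crit.pair_eligible(names[ra], names[rb], kind):
                    eligible[kind].append((ra, rb))

    if crit.site == "ca":
        coords = ens.ca_coords(protein)  # F x R x 3
        for kind in INTERACTION_TYPES:
            pairs = eligible[kind]
            if not pairs:
                continue
            ia = np.array([pos_of[ra] for ra, _ in pairs])
            ib = np.array([pos_of[rb] for _, rb in pairs])
            # F x P distances for the eligible pairs only
            d = np.linalg.norm(coords[:, ia, :] - coords[:, ib, :], axis=2)
            n_hit = (d <= crit.cutoff_of(kind)).sum(axis=0)
            for (ra, rb), c in zip(pairs, n_hit):
                if c > 0:
                    counts[(ra, rb, kind)] = int(c)
    else:
        _count_fullatom(ens, top, crit, eligible, counts)

    edges = [
        Edge(ra, rb, kind, 100.0 * c / F)
        for (ra, rb, kind), c in sorted(counts.items())
        if c > 0
    ]
    domains = {}
    if dm is not None:
        domains = {
            r: d for r in protein if (d := dm.domain_of_residue(r)) is not None
        }
    return InteractionGraph(edges=edges, residue_names=names, domain_of_residue=domains)


def _count_fullatom(ens, top, crit, eligible, counts) -> None:
    """Full-atom criterion evaluation (side-chain COM / atom groups)."""
    F = ens.n_frames
    protein = top.protein_residues
    names = {r: top.residue(r).name for r in protein}

    sc_atoms = {}
    hb_atoms = {}
    sb_atoms = {}
    for r in protein:
        nm = names[r]
        sc = _sidechain_indices(top, r)
        sc_atoms[r] = sc if sc else list(top.atoms_of_residue(r))
        hb = list(_named_atom_indices(top, r, HBOND_SIDECHAIN_ATOMS.get(nm, ())))
        # backbone N and O can donate/accept as well
        hb += _named_atom_indices(top, r, ("N", "O"))
        hb_atoms[r] = hb
        sb_atoms[r] = _named_atom_indices(top, r, CHARGED_GROUP_ATOMS.get(nm, ()))

    warned: set[tuple[int, int, str]] = set()
    for f in range(F):
        x = ens.coords[f]
        sc_com = {r: x[sc_atoms[r]].mean(axis=0) for r in protein}
        for (ra, rb) in eligible["hydrophobic"]:
            if np.linalg.norm(sc_com[ra] - sc_com[rb]) <= crit.hydrophobic.distance_cutoff:
                counts[(ra, rb, "hydrophobic")] = counts.get((ra, rb, "hydrophobic"), 0) + 1
        for (ra, rb) in eligible["hbond"]:
            ia, ib = hb_atoms[ra], hb_atoms[rb]
            if not ia or not ib:
                if (ra, rb, "hbond") not in warned:
                    warned.add((ra, rb, "hbond"))
                    logger.warning("missing H-bond atoms for pair %s-%s; skipped", ra, rb)
                continue
            if cdist(x[ia], x[ib]).min() <= crit.hbond.distance_cutoff:
                counts[(ra, rb, "hbond")] = counts.get((ra, rb, "hbond"), 0) + 1
        for (ra, rb) in eligible["saltbridge"]:
            ia, ib = sb_atoms[ra], sb_atoms[rb]
            if not ia or not ib:
                if (ra, rb, "saltbridge") not in warned:
                    warned.add((ra, rb, "saltbridge"))
                    logger.warning("missing charged-group atoms for pair %s-%s; skipped", ra, rb)
                continue
            if cdist(x[ia], x[ib]).min() <= crit.saltbridge.distance_cutoff:
                counts[(ra, rb, "saltbridge")] = counts.get((ra, rb, "saltbridge"), 0) + 1


# ---------------------------------------------------------------------------
# Threshold selection, hubs, domain statistics
# ---------------------------------------------------------------------------


def largest_hydrophobic_cluster_sizes(
    g: InteractionGraph, scan: np.ndarray
) -> np.ndarray:
    """Size of the largest connected component of the hydrophobic subgraph
    at each scanned persistence threshold."""
    sizes = np.zeros(len(scan), dtype=int)
    for k, t in enumerate(scan):
        edges = g.thresholded(t, kinds=("hydrophobic",))
        if not edges:
            sizes[k] = 0
            continue
        sub = nx.Graph()
        for e in edges:
            sub.add_edge(e.res_a, e.res_b)
        sizes[k] = max(len(c) for c in nx.connected_components(sub))
    return sizes


def select_persistence_threshold(
    g: InteractionGraph,
    scan: np.ndarray | None = None,
) -> float:
    """Persistence threshold by the largest-hydrophobic-cluster criterion.

    The size of the largest connected hydrophobic component is scanned as a
    function of threshold; the selected threshold is the first scan point
    after the steepest single-step drop of that size (ties broken toward the
    lowest threshold).  A flat curve yields the scan midpoint with a warning.
    """
    if scan is None:
        scan = np.arange(0.0, 100.5, 0.5)
    scan = np.asarray(scan, dtype=float)
    if not g.edges_of_type("hydrophobic"):
        raise ValueError("graph has no hydrophobic edges to scan")
    sizes = largest_hydrophobic_cluster_sizes(g, scan)
    drops = sizes[:-1] - sizes[1:]
    if np.all(drops <= 0):
        mid = float(scan[len(scan) // 2])
        warnings.warn(
            "largest-hydrophobic-cluster size curve is flat; "
            f"returning scan midpoint {mid}",
            stacklevel=2,
        )
        return mid
    k = int(np.argmax(drops))  # argmax takes the first (lowest) on ties
    return float(scan[k + 1])


def hubs(
    g: InteractionGraph,
    threshold: float,
    hub_min_degree: int = 7,
) -> pd.DataFrame:
    """Hub table: residues whose degree in the thresholded graph (counting
    each pair-and-type edge separately) reaches ``hub_min_degree``.

    Returns a DataFrame with columns residue_index, residue_name, degree,
    domain — sorted by degree descending, then residue index.
    """
    if not (0.0 <= threshold <= 100.0):
        raise ValueError("threshold must lie in [0, 100]")
    degree: dict[int, int] = {}
    for e in g.thresholded(threshold):
        degree[e.res_a] = degree.get(e.res_a, 0) + 1
        degree[e.res_b] = degree.get(e.res_b, 0) + 1
    rows = [
        (r, g.residue_names.get(r, "UNK"), d, g.domain_of_residue.get(r))
        for r, d in degree.items()
        if d >= hub_min_degree
    ]
    rows.sort(key=lambda row: (-row[2], row[0]))
    return pd.DataFrame(rows, columns=["residue_index", "residue_name", "degree", "domain"])


def domain_hub_fractions(
    tab: pd.DataFrame,
    dm: DomainMap | None = None,
) -> tuple[int, int]:
    """Percentage of hubs in the core and gate domains.

    Domains come from ``dm`` when given, falling back to the table's own
    ``domain`` column.  Percentages are rounded with the largest-remainder
    rule so they sum to exactly 100.
    """
    if len(tab) == 0:
        warnings.warn("empty hub table; returning (0, 0)", stacklevel=2)
        return (0, 0)
    domains = []
    for _, row in tab.iterrows():
        dom = None
        if dm is not None:
            dom = dm.domain_of_residue(int(row["residue_index"]))
        if dom is None and "domain" in tab.columns:
            dom = row["domain"]
        if dom not in ("core", "gate"):
            raise ValueError(
                f"residue {int(row['residue_index'])} is not mapped to a domain"
            )
        domains.append(dom)
    n = len(domains)
    n_core = sum(d == "core" for d in domains)
    exact = (100.0 * n_core / n, 100.0 * (n - n_core) / n)
    floors = [int(np.floor(v)) for v in exact]
    short = 100 - sum(floors)
    remainders = [v - f for v, f in zip(exact, floors)]
    order = sorted(range(2), key=lambda i: -remainders[i])
    for i in order[:short]:
        floors[i] += 1
    return (floors[0], floors[1])


def shortest_path(
    g: InteractionGraph,
    threshold: float,
    res_a: int,
    res_b: int,
) -> list[list[int]]:
    """All unweighted shortest paths between two residues on the thresholded
    graph.  Disconnected pairs yield an empty list (with a log diagnostic)."""
    if res_a not in g.nodes or res_b not in g.nodes:
        raise ValueError(f"residue {res_a if res_a not in g.nodes else res_b} not in graph")
    if res_a == res_b:
        return [[res_a]]
    nxg = g.to_networkx(threshold)
    try:
        return [list(p) for p in nx.all_shortest_paths(nxg, res_a, res_b)]
    except nx.NetworkXNoPath:
        logger.warning(
            "residues %s and %s are disconnected at threshold %.1f",
            res_a, res_b, threshold,
        )
        return []


# ---------------------------------------------------------------------------
# Residue-pair distance series
# ---------------------------------------------------------------------------


def residue_pair_distance(
    ens: TrajectoryEnsemble,
    top: Topology,
    res_a: int,
    res_b: int,
    scheme: Literal["ca", "min_heavy", "charged_group"] = "ca",
) -> np.ndarray:
    """Per-frame distance (Å) between two residues under the given scheme:
    Cα-Cα, minimum heavy-atom, or minimum charged-group distance."""
    for r in (res_a, res_b):
        if not top.has_residue(r):
            raise ValueError(f"residue {r} not in topology")
    if res_a == res_b:
        return np.zeros(ens.n_frames)
    if scheme == "ca":
        ia = [top.ca_index_of_residue[res_a]]
        ib = [top.ca_index_of_residue[res_b]]
    elif scheme == "min_heavy":
        ia = [i for i in top.atoms_of_residue(res_a) if not _atom_name(top, i).startswith("H")]
        ib = [i for i in top.atoms_of_residue(res_b) if not _atom_name(top, i).startswith("H")]
    elif scheme == "charged_group":
        ia = _named_atom_indices(top, res_a, CHARGED_GROUP_ATOMS.get(top.residue(res_a).name, ()))
        ib = _named_atom_indices(top, res_b, CHARGED_GROUP_ATOMS.get(top.residue(res_b).name, ()))
        if not ia or not ib:
            raise ValueError(
                f"charged-group scheme needs charged side chains "
                f"({top.residue(res_a).name}, {top.residue(res_b).name})"
            )
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if not ia or not ib:
        raise ValueError(f"no atoms available for scheme {scheme!r}")
    out = np.empty(ens.n_frames)
    for f in range(ens.n_frames):
        out[f] = cdist(ens.coords[f, ia], ens.coords[f, ib]).min()
    return out
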