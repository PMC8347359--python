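"""Orchestration of the comparative multi-system analysis workflow.

One configuration file declares, per system, a topology, a trajectory, the
TM-helix domain map and analysis parameters; the pipeline then runs the
stages in a fixed order — equilibration detection, RMSF filtering,
conformational landscape (RMSD matrix → MDS → GMM/BIC), interaction
network with hub statistics, gate-aligned core shift/tilt against a paired
inward system, and ion binding events — writing each stage's table plus a
machine-readable summary.  Runs are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import fluctuation, geometry, ion_binding, landscape, network
from .core_model import (
    DomainMap,
    Topology,
    TrajectoryEnsemble,
    load_config,
    load_topology,
    load_trajectory,
)

logger = logging.getLogger(__name__)


@dataclass
class SystemConfig:
    name: str
    topology: Path
    trajectory: Path
    domain_map: DomainMap
    frame_spacing_ns: float | None = None
    inward_reference: str | None = None  # name of the paired inward system
    # analysis parameters (module defaults unless overridden)
    equil_window: int = 25
    equil_tol: float = 0.1
    rmsf_percentile: float = fluctuation.DEFAULT_RMSF_PERCENTILE
    stride: int = 1
    k_range: tuple = tuple(range(1, 9))
    n_starts: int = 3
    hub_min_degree: int = 7
    ion_resname: str = "CLA"
    ion_cutoff: float = ion_binding.DEFAULT_CONTACT_CUTOFF
    ion_min_duration: int = 5
    ion_gap_tolerance: int = 1

    @classmethod
    def from_dict(cls, name: str, d: Mapping) -> "SystemConfig":
        known = {
            k: d[k]
            for k in (
                "frame_spacing_ns", "inward_reference", "equil_window",
                "equil_tol", "rmsf_percentile", "stride", "n_starts",
                "hub_min_degree", "ion_resname", "ion_cutoff",
                "ion_min_duration", "ion_gap_tolerance",
            )
            if k in d
        }
        if "k_range" in d:
            known["k_range"] = tuple(d["k_range"])
        return cls(
            name=name,
            topology=Path(d["topology"]),
            trajectory=Path(d["trajectory"]),
            domain_map=DomainMap.from_dict(d["domain_map"]),
            **known,
        )


@dataclass
class RunConfig:
    systems: dict[str, SystemConfig]
    seed: int = 0
    output_dir: Path = Path("results")
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        d = load_config(path)
        systems = {
            name: SystemConfig.from_dict(name, sd)
            for name, sd in d["systems"].items()
        }
        cfg = cls(
            systems=systems,
            seed=int(d.get("seed", 0)),
            output_dir=Path(d.get("output_dir", "results")),
            log_level=d.get("log_level", "INFO"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.systems:
            raise ValueError("configuration declares no systems")
        for name, sc in self.systems.items():
            for p in (sc.topology, sc.trajectory):
                if not Path(p).exists():
                    raise ValueError(f"system {name!r}: missing file {p}")
            if sc.inward_reference is not None and sc.inward_reference not in self.systems:
                raise ValueError(
                    f"system {name!r}: inward reference "
                    f"{sc.inward_reference!r} is not a configured system"
                )


def _is_ca_only(top: Topology) -> bool:
    return all(a.name == "CA" for a in top.atoms if top.is_protein(a.residue_index))


def analyse_system(
    sc: SystemConfig,
    ens: TrajectoryEnsemble,
    top: Topology,
    seed: int,
    ref_inward: np.ndarray | None = None,
    out_dir: Path | None = None,
) -> dict:
    """Run the per-system stage sequence on an already-loaded ensemble."""
    summary: dict = {"system": sc.name, "seed": seed}
    protein = top.protein_residues

    # 1. equilibration (RMSD to the first frame)
    eq = fluctuation.detect_equilibration(
        ens, ens.coords[0], selection=protein,
        window=sc.equil_window, tol=sc.equil_tol,
    )
    eq_frame = 0 if eq is None else eq
    summary["equilibration_frame"] = None if eq is None else int(eq)
    post = ens.subset_frames(np.arange(eq_frame, ens.n_frames))

    # 2. RMSF + loop filter
    profile = fluctuation.compute_rmsf(post, protein)
    cutoff = fluctuation.rmsf_percentile_cutoff(profile, sc.rmsf_percentile)
    kept = fluctuation.filter_by_rmsf(profile, cutoff)
    summary["rmsf_cutoff_A"] = float(cutoff)
    summary["n_residues_kept"] = len(kept)

    # 3. landscape
    D = landscape.rmsd_matrix(post, kept, stride=sc.stride)
    emb = landscape.classical_mds(D, dims=2)
    model = landscape.select_k_bic(
        emb, k_range=sc.k_range, n_starts=sc.n_starts, seed=seed
    )
    summary["n_clusters"] = int(model.K)
    summary["bic"] = float(model.bic)

    # 4. interaction network
    crit = (
        network.ContactCriteria.ca_proxy()
        if _is_ca_only(top)
        else network.ContactCriteria()
    )
    graph = network.persistence_graph(post, top, crit, dm=sc.domain_map)
    try:
        threshold = network.select_persistence_threshold(graph)
    except ValueError:
        threshold = 0.0
    hub_tab = network.hubs(graph, threshold, hub_min_degree=sc.hub_min_degree)
    summary["persistence_threshold"] = float(threshold)
    summary["n_hubs"] = int(len(hub_tab))
    if len(hub_tab) and hub_tab["domain"].notna().all():
        core_pct, gate_pct = network.domain_hub_fractions(hub_tab, sc.domain_map)
        summary["hub_fractions"] = {"core": core_pct, "gate": gate_pct}
    else:
        summary["hub_fractions"] = None

    # 5. geometry vs the paired inward reference
    if ref_inward is not None:
        report = geometry.shift_tilt_report(post, ref_inward, sc.domain_map)
        summary["shift_tilt"] = {
            str(row["tm_id"]): {
                "dz_A": float(row["dz_mean"]),
                "dtilt_deg": float(row["dtilt_mean"]),
            }
            for _, row in report.table.iterrows()
        }
    else:
        report = None
        summary["shift_tilt"] = None

    # 6. ion binding events
    ion_res = ion_binding.find_ion_residues(top, sc.ion_resname)
    if ion_res and sc.domain_map.binding_site_residues:
        cs = ion_binding.ion_contact_series(
            ens, top, ion_res,
            sorted(sc.domain_map.binding_site_residues),
            cutoff=sc.ion_cutoff,
        )
        events = ion_binding.detect_binding_events(
            cs,
            min_duration=sc.ion_min_duration,
            gap_tolerance=sc.ion_gap_tolerance,
        )
        summary["n_binding_events"] = len(events)
        ranking = ion_binding.anchor_ranking(cs)
    else:
        events, ranking, cs = [], None, None
        summary["n_binding_events"] = None

    summary["hub_table"] = hub_tab.to_dict(orient="records")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"residue_index": profile.residue_indices, "rmsf_A": profile.rmsf}
        ).to_csv(out_dir / "rmsf.tsv", sep="\t", index=False)
        np.savetxt(out_dir / "rmsd_matrix.tsv", D.values, fmt="%.4f", delimiter="\t")
        pd.DataFrame(
            {
                "frame": np.arange(emb.n),
                "x": emb.points[:, 0],
                "y": emb.points[:, 1],
                "label": model.labels,
            }
        ).to_csv(out_dir / "embedding.tsv", sep="\t", index=False)
        graph.to_frame().to_csv(out_dir / "network_edges.tsv", sep="\t", index=False)
        hub_tab.to_csv(out_dir / "hubs.tsv", sep="\t", index=False)
        if report is not None:
            report.table.to_csv(out_dir / "shift_tilt.tsv", sep="\t", index=False)
        if events:
            ion_binding.events_to_frame(events, ens.times).to_csv(
                out_dir / "binding_events.tsv", sep="\t", index=False
            )
        if ranking is not None:
            ranking.to_csv(out_dir / "anchor_ranking.tsv", sep="\t", index=False)
    return summary


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every configured system and write the summary bundle.

    Systems with an ``inward_reference`` are analysed after their reference
    so that the gate-aligned shift/tilt stage can use the reference's
    most-representative structure.
    """
    cfg.validate()
    out_root = Path(cfg.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    order = sorted(
        cfg.systems, key=lambda n: cfg.systems[n].inward_reference is not None
    )
    referenced = {
        sc.inward_reference
        for sc in cfg.systems.values()
        if sc.inward_reference is not None
    }
    loaded: dict[str, tuple[Topology, TrajectoryEnsemble]] = {}
    representatives: dict[str, np.ndarray] = {}
    summaries: dict[str, dict] = {}
    for name in order:
        sc = cfg.systems[name]
        logger.info("analysing system %s", name)
        try:
            top = load_topology(sc.topology)
            ens = load_trajectory(top, sc.trajectory, sc.frame_spacing_ns)
            loaded[name] = (top, ens)
            ref = None
            if sc.inward_reference is not None:
                ref = representatives.get(sc.inward_reference)
            summary = analyse_system(
                sc, ens, top, cfg.seed, ref_inward=ref, out_dir=out_root / name
            )
            if name in referenced:
                representatives[name] = _representative(sc, ens, top, cfg.seed)
            summaries[name] = summary
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed for system {name!r}: {exc}") from exc
    bundle = {"seed": cfg.seed, "systems": summaries}
    (out_root / "summary.json").write_text(json.dumps(bundle, indent=1, default=_json_default))
    return bundle


def _representative(sc: SystemConfig, ens, top, seed: int) -> np.ndarray:
    protein = top.protein_residues
    D = landscape.rmsd_matrix(ens, protein, stride=max(1, sc.stride))
    emb = landscape.classical_mds(D, dims=2)
    model = landscape.select_k_bic(
        emb, k_range=sc.k_range, n_starts=sc.n_starts, seed=seed
    )
    _, coords = geometry.representative_structure(ens, model, protein)
    return coords


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def compare_systems(
    report_a: dict,
    report_b: dict,
    correspondence: Mapping[int, int] | None = None,
) -> dict:
    """Compare two per-system summaries.

    Hub residues of system A are mapped through ``correspondence``
    (A-residue → B-residue; identity when omitted) and intersected with
    system B's hubs; residues without a mapping are listed as unmatched.
    Domain hub fractions and shift/tilt tables are placed side by side.
    """
    hubs_a = {int(r["residue_index"]) for r in report_a.get("hub_table", [])}
    hubs_b = {int(r["residue_index"]) for r in report_b.get("hub_table", [])}
    correspondence = dict(correspondence) if correspondence else {}
    mapped = {}
    unmatched = []
    for r in sorted(hubs_a):
        if correspondence:
            if r in correspondence:
                mapped[r] = correspondence[r]
            else:
                unmatched.append(r)
        else:
            mapped[r] = r
    common = sorted(r for r, rb in mapped.items() if rb in hubs_b)
    only_a = sorted(set(mapped) - set(common))
    only_b = sorted(hubs_b - {mapped[r] for r in common})
    return {
        "common_hubs": common,
        "only_a": only_a,
        "only_b": only_b,
        "unmatched_a": unmatched,
        "hub_fractions": {
            "a": report_a.get("hub_fractions"),
            "b": report_b.get("hub_fractions"),
        },
        "shift_tilt": {
            "a": report_a.get("shift_tilt"),
            "b": report_b.get("shift_tilt"),
        },
    }
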