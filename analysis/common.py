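"""Shared definition of the four-system synthetic comparative study.

The study mirrors the design of a comparative MD investigation of an
elevator-type 14-TM transporter in two orthologs (r*, z*) and two states
(I = inward-open, O = outward-open), at desk scale: each system is a
6-helix Cα bundle (3 core + 3 gate helices) with planted conformational
basins, interaction networks, core shift/tilt and ion-visit schedules.
Everything is deterministic under the seeds fixed here, so each numbered
analysis script can regenerate its inputs independently.

Planted study conditions
------------------------
* conformational basins: rI 4, rO 5, zI 7, zO 5 (the I-state counts follow
  the reported range endpoints; the O-state counts are an intermediate
  choice, see docs/methods.md)
* elevator motion: the z pair plants a +3 Å core shift with a 12° tilt,
  the r pair a mixed ±1 Å shift with a 4° tilt — a clear vs marginal
  elevator signature
* ion schedules: 3 episodes for the r system, 22 for the z system, each
  10 frames long with 20 clean frames between consecutive episodes
* interaction networks: the natural hydrophobic packing network of the
  bundle (helix axes 8.5 Å apart puts neighbouring Cα within the 5 Å
  contact cutoff), thresholded by the largest-hydrophobic-cluster knee;
  hubs at the toy-scale connection cutoff of 3 (a 6-helix Cα bundle cannot
  reach the 7-contact degrees of a full side-chain TMD)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from tmdkit.synthetic import (
    BundleSpec,
    build_bundle,
    generate_basin_trajectory,
    generate_ion_trajectory,
    generate_shift_tilt_trajectory,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "synthetic"

SYSTEMS = ("rI", "rO", "zI", "zO")

#: planted conformational-basin counts per system
BASIN_COUNTS = {"rI": 4, "rO": 5, "zI": 7, "zO": 5}
FRAMES_PER_BASIN = 30
BASIN_NOISE = 0.15  # Å
BASIN_OFFSET = 8.0  # Å, displacement magnitude between basins

#: planted elevator parameters (dz in Å, dtilt in degrees) per ortholog
ELEVATOR = {"r": (1.0, 4.0), "z": (3.0, 12.0)}
ELEVATOR_FRAMES = 60
ELEVATOR_NOISE = 0.15

#: ion residence episodes per ortholog (the applied-field analyses)
ION_EPISODES = {"r": 3, "z": 22}
EPISODE_LENGTH = 10  # frames
EPISODE_SPACING = 30  # frames between episode starts, per ion
ION_MIN_DURATION = 5
ION_GAP_TOLERANCE = 1

SPEC = BundleSpec(n_helices=6, residues_per_helix=10, bundle_radius=8.5)

#: hub cutoff for the toy bundle's packing network (see module docstring)
HUB_MIN_DEGREE = 3

SEEDS = {"bundle": 2024, "rI": 11, "rO": 12, "zI": 13, "zO": 14,
         "elevator_r": 21, "elevator_z": 22, "ions_r": 31, "ions_z": 32,
         "network_r": 41, "network_z": 42}


def bundle():
    top, ref = build_bundle(SPEC, seed=SEEDS["bundle"])
    return SPEC, top, ref


def domain_map():
    spec, top, ref = bundle()
    site = spec.helix_residues(1)[3:6]
    return spec.domain_map(binding_site_residues=set(site))


def basin_offsets(n_basins: int) -> list[tuple[float, float, float]]:
    return [
        (BASIN_OFFSET * np.cos(2 * np.pi * b / n_basins), 0.0,
         BASIN_OFFSET * np.sin(2 * np.pi * b / n_basins))
        for b in range(n_basins)
    ]


def basin_trajectory(system: str):
    """Multi-basin ensemble + truth for one of the four systems.

    The basin motion is a rigid displacement of the whole core domain
    (helices 1-3) between metastable offsets: intra-domain packing is
    preserved across basins while the core/gate interface rearranges,
    and the RMSF-based loop filter cannot silently remove the moving
    part wholesale.
    """
    spec, top, ref = bundle()
    n = BASIN_COUNTS[system]
    movers = [r for h in (1, 2, 3) for r in spec.helix_residues(h)]
    return generate_basin_trajectory(
        top, ref, basin_offsets(n), FRAMES_PER_BASIN, BASIN_NOISE,
        SEEDS[system], moving_residues=movers,
    )


def elevator_pair(ortholog: str):
    """(inward, outward) ensembles + truth for one ortholog's state pair."""
    spec, top, ref = bundle()
    dz, dtilt = ELEVATOR[ortholog]
    return generate_shift_tilt_trajectory(
        top, ref, domain_map(), dz=dz, dtilt_deg=dtilt,
        n_frames=ELEVATOR_FRAMES, noise_sigma=ELEVATOR_NOISE,
        seed=SEEDS[f"elevator_{ortholog}"],
    )


def ion_trajectory(ortholog: str):
    """Scripted-ion ensemble + truth for one ortholog's field analysis."""
    spec, top, ref = bundle()
    dm = domain_map()
    n_episodes = ION_EPISODES[ortholog]
    n_ions = min(5, n_episodes)
    schedule = [
        (k % n_ions, (k // n_ions) * EPISODE_SPACING,
         (k // n_ions) * EPISODE_SPACING + EPISODE_LENGTH - 1)
        for k in range(n_episodes)
    ]
    n_frames = EPISODE_SPACING * ((n_episodes + n_ions - 1) // n_ions)
    return generate_ion_trajectory(
        top, ref, sorted(dm.binding_site_residues), schedule,
        n_ions=n_ions, n_frames=n_frames, seed=SEEDS[f"ions_{ortholog}"],
    )


def network_input(system: str):
    """The basin ensemble of a system, reused as the network-stage input
    (its packing contacts are the natural interaction network)."""
    return basin_trajectory(system)
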