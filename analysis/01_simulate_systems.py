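#!/usr/bin/env python
"""Generate the four-system synthetic study and write its inputs to disk.

Builds the shared 6-helix bundle and, for each of the four systems
(rI/rO/zI/zO analogues), the multi-basin trajectory with its planted
truth; also the elevator state pairs and the scripted-ion trajectories.
Trajectory files (PDB + XTC + truth JSON) go under scratch/synthetic/ for
inspection with standard MD tools; a small manifest table summarising the
planted conditions goes to results/systems.tsv.

The later analysis scripts regenerate their inputs in memory from the same
seeds, so this script is a convenience, not a dependency.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common
from tmdkit.core_model import write_pdb, write_trajectory


def main() -> None:
    common.SCRATCH.mkdir(parents=True, exist_ok=True)
    common.RESULTS.mkdir(parents=True, exist_ok=True)
    spec, top, ref = common.bundle()
    write_pdb(top, ref, common.SCRATCH / "bundle.pdb")

    rows = []
    for system in common.SYSTEMS:
        ens, truth = common.basin_trajectory(system)
        write_trajectory(ens, common.SCRATCH / f"{system}_basins.xtc")
        truth.to_json(common.SCRATCH / f"{system}_basins.truth.json")
        rows.append(
            {
                "system": system,
                "n_basins_planted": common.BASIN_COUNTS[system],
                "n_frames": ens.n_frames,
                "noise_A": common.BASIN_NOISE,
            }
        )
        print(
            f"{system}: {ens.n_frames} frames, "
            f"{common.BASIN_COUNTS[system]} planted basins"
        )

    for ortholog in ("r", "z"):
        ens_I, ens_O, truth = common.elevator_pair(ortholog)
        write_trajectory(ens_I, common.SCRATCH / f"{ortholog}_elevator_I.xtc")
        write_trajectory(ens_O, common.SCRATCH / f"{ortholog}_elevator_O.xtc")
        truth.to_json(common.SCRATCH / f"{ortholog}_elevator.truth.json")
        ion_ens, ion_truth = common.ion_trajectory(ortholog)
        write_pdb(
            ion_ens.topology, ion_ens.coords[0],
            common.SCRATCH / f"{ortholog}_ions.pdb",
        )
        write_trajectory(ion_ens, common.SCRATCH / f"{ortholog}_ions.xtc")
        ion_truth.to_json(common.SCRATCH / f"{ortholog}_ions.truth.json")
        dz, dtilt = common.ELEVATOR[ortholog]
        print(
            f"{ortholog}: elevator pair (dz {dz:+.1f} Å, dtilt {dtilt:.0f}°), "
            f"{common.ION_EPISODES[ortholog]} scripted ion episodes"
        )

    manifest = pd.DataFrame(rows)
    manifest.to_csv(common.RESULTS / "systems.tsv", sep="\t", index=False)
    print(f"wrote {common.RESULTS / 'systems.tsv'} and trajectories under "
          f"{common.SCRATCH}")


if __name__ == "__main__":
    main()
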