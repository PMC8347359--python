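import numpy as np
import pytest

from tmdkit.core_model import Topology, TrajectoryEnsemble
from tmdkit.synthetic import BundleSpec, build_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """4-helix, 10-residue Cα bundle used across module tests."""
    spec = BundleSpec(n_helices=4, residues_per_helix=10)
    top, ref = build_bundle(spec, seed=7)
    return spec, top, ref


@pytest.fixture()
def static_ensemble(small_bundle):
    _, top, ref = small_bundle
    coords = np.repeat(ref[None, :, :], 5, axis=0)
    return TrajectoryEnsemble(coords, np.arange(5.0), top)


def toy_pdb_text(drop_gly_ca: bool = False) -> str:
    """Three-residue ALA-GLY-ALA peptide with full backbone."""
    lines = []
    serial = 1
    residues = [("ALA", 1), ("GLY", 2), ("ALA", 3)]
    for resname, resid in residues:
        for name in ("N", "CA", "C", "O"):
            if drop_gly_ca and resname == "GLY" and name == "CA":
                continue
            x, y, z = serial * 1.1, resid * 2.0, 0.5 * serial
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} A{resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           "
                f"{name[0]}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def two_chain_pdb_text() -> str:
    """Two chains A and B of 5 Cα-only residues each."""
    lines = []
    serial = 1
    for ci, chain in enumerate(("A", "B")):
        for resid in range(5 * ci + 1, 5 * ci + 6):
            x = serial * 1.5
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA {chain}{resid:4d}    "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
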