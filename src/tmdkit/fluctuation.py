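"""RMSF profiles, fluctuation-based residue filtering and equilibration
detection.

Per-residue Cα root-mean-square fluctuations are computed about the
iteratively superposed ensemble mean; residues in highly mobile loops can
then be filtered out before any RMSD-based analysis, and an RMSD plateau
rule picks the first equilibrated frame of a trajectory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_model import TrajectoryEnsemble, kabsch_superpose, superpose_frames

logger = logging.getLogger(__name__)

#: Default loop-filter rule: retain residues below this RMSF percentile.
DEFAULT_RMSF_PERCENTILE = 80.0


@dataclass
class RMSFProfile:
    """Per-residue Cα RMSF (Å) after superposition to the ensemble mean."""

    residue_indices: list[int]
    rmsf: np.ndarray

    def __post_init__(self):
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if len(self.rmsf) != len(self.residue_indices):
            raise ValueError("rmsf length != number of residues")
        if np.any(self.rmsf < 0):
            raise ValueError("negative RMSF value")

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.residue_indices, self.rmsf))


def compute_rmsf(
    ens: TrajectoryEnsemble,
    selection: Sequence[int] | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> RMSFProfile:
    """Cα RMSF about the superposed ensemble mean.

    Frames are superposed onto the running mean structure, the mean is
    recomputed, and the loop repeats until the mean moves by less than
    ``tol`` Å; rmsf_i = sqrt(mean_f |x_i(f) − ⟨x_i⟩|²) on the converged
    alignment.
    """
    if ens.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if selection is None:
        selection = ens.topology.protein_residues
    else:
        selection = list(selection)
    x = ens.ca_coords(selection)  # F x R x 3
    mean = x[0].copy()
    for _ in range(max_iter):
        aligned = superpose_frames(x, mean)
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean()))
        mean = new_mean
        x = aligned
        if shift < tol:
            break
    rmsf = np.sqrt(((x - mean) ** 2).sum(axis=2).mean(axis=0))
    return RMSFProfile(residue_indices=list(selection), rmsf=rmsf)


def filter_by_rmsf(profile: RMSFProfile, cutoff: float) -> list[int]:
    """Residues with RMSF <= cutoff (Å).  An empty result warns, it is not
    an error — downstream stages will fail loudly on an empty selection."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    kept = [
        r for r, v in zip(profile.residue_indices, profile.rmsf) if v <= cutoff
    ]
    if not kept:
        warnings.warn(
            f"RMSF filter at {cutoff} Å retains no residues", stacklevel=2
        )
    return kept


def rmsf_percentile_cutoff(
    profile: RMSFProfile, percentile: float = DEFAULT_RMSF_PERCENTILE
) -> float:
    """Cutoff at a percentile of the profile (the default loop-filter rule)."""
    return float(np.percentile(profile.rmsf, percentile))


def rmsd_to_reference(
    ens: TrajectoryEnsemble,
    reference: np.ndarray,
    selection: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-frame Cα RMSD to a reference structure after superposition."""
    if selection is None:
        selection = ens.topology.protein_residues
    idx = ens.topology.ca_indices(selection)
    ref = np.asarray(reference, dtype=float)
    ref_sel = ref[idx] if ref.shape[0] == ens.coords.shape[1] else ref
    out = np.empty(ens.n_frames)
    for f in range(ens.n_frames):
        out[f] = kabsch_superpose(ens.coords[f, idx], ref_sel).rmsd
    return out


def detect_equilibration(
    ens: TrajectoryEnsemble,
    reference: np.ndarray,
    selection: Sequence[int] | None = None,
    window: int = 25,
    tol: float = 0.1,
) -> int | None:
    """First equilibrated frame by a sliding-window RMSD plateau rule.

    The RMSD-to-reference series is averaged over windows of ``window``
    frames starting at each frame; the trajectory counts as equilibrated
    from the first index where consecutive window means differ by less than
    ``tol`` Å *and keep doing so to the end of the series*.  Returns ``None``
    (with a logged diagnostic) if the rule never fires.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    series = rmsd_to_reference(ens, reference, selection)
    return equilibration_from_series(series, window=window, tol=tol)


def equilibration_from_series(
    series: np.ndarray, window: int = 25, tol: float = 0.1
) -> int | None:
    """Plateau rule on a precomputed RMSD series (see
    :func:`detect_equilibration`)."""
    if window < 2:
        raise ValueError("window must be >= 2")
    series = np.asarray(series, dtype=float)
    n_windows = len(series) - window + 1
    if n_windows < 2:
        raise ValueError(
            f"series of {len(series)} frames too short for window {window}"
        )
    kernel = np.ones(window) / window
    means = np.convolve(series, kernel, mode="valid")
    diffs = np.abs(np.diff(means))
    ok = diffs < tol
    # first index from which every subsequent consecutive-window change is small
    idx = None
    for t in range(len(ok) - 1, -1, -1):
        if ok[t]:
            idx = t
        else:
            break
    if idx is None:
        logger.warning(
            "no equilibration plateau found (window=%d, tol=%.3g, "
            "final window change=%.3g)",
            window, tol, diffs[-1] if len(diffs) else float("nan"),
        )
        return None
    return int(idx)
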