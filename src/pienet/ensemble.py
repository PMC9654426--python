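"""Trajectory bookkeeping: snapshot selection, RMSD, and ensemble statistics.

The analysis convention is the one used for the MutS-DNA study system:
frames saved every 10 ps over a 50 ns trajectory, the stable window
20-50 ns selected at a 300 ps stride (exactly 100 snapshots with the
half-open window [start, end)), heavy-atom RMSD against the first frame
to confirm stability, and mean +/- standard deviation over the selected
snapshots for every per-snapshot quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.spatial.transform import Rotation

from .system import MolecularSystem, SnapshotSet

__all__ = [
    "SelectionPolicy",
    "select_snapshots",
    "rmsd_series",
    "rmsd_histogram",
    "ensemble_mean_std",
]


@dataclass(frozen=True)
class SelectionPolicy:
    """Half-open time window [t_start, t_end) in ps with a stride in ps."""

    t_start: float
    t_end: float
    stride: float

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")
        if self.stride <= 0:
            raise ValueError("stride must be positive")


def select_snapshots(times: Sequence[float], policy: SelectionPolicy) -> np.ndarray:
    """Indices of frames at t_start, t_start+stride, ... within [t_start, t_end).

    Each target time is matched to the nearest frame; a match is accepted
    only within half the typical frame spacing.  Raises if nothing matches.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty time series")
    spacing = float(np.median(np.diff(times))) if times.size > 1 else np.inf
    targets = np.arange(policy.t_start, policy.t_end, policy.stride)
    indices = []
    for t in targets:
        k = int(np.argmin(np.abs(times - t)))
        if abs(times[k] - t) <= spacing / 2 and policy.t_start <= times[k] < policy.t_end:
            indices.append(k)
    indices = sorted(set(indices))
    if not indices:
        raise ValueError(
            f"no frames selected in [{policy.t_start}, {policy.t_end}) "
            f"at stride {policy.stride}"
        )
    return np.asarray(indices, dtype=int)


def _kabsch_rmsd(ref: np.ndarray, mobile: np.ndarray) -> float:
    """RMSD after optimal rigid-body superposition (Kabsch via SVD)."""
    ref_c = ref - ref.mean(axis=0)
    mob_c = mobile - mobile.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    diff = ref_c - rot.apply(mob_c)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def rmsd_series(
    snapshots: SnapshotSet,
    reference_index: int = 0,
    heavy_only: bool = True,
    superpose: bool = True,
    system: Optional[MolecularSystem] = None,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-frame RMSD (Å) of selected atoms relative to a reference frame.

    ``heavy_only`` needs either an explicit boolean ``mask`` or a ``system``
    to identify hydrogens.  With ``superpose`` (default) an optimal
    rigid-body fit removes global rotation/translation first.
    """
    coords = snapshots.coords
    if mask is None:
        if heavy_only:
            if system is None:
                raise ValueError("heavy_only requires a system or an explicit mask")
            mask = system.heavy_mask
        else:
            mask = np.ones(snapshots.n_atoms, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != snapshots.n_atoms:
        raise ValueError("mask length does not match atom count")
    if not mask.any():
        raise ValueError("no atoms selected for RMSD")

    ref = coords[reference_index][mask]
    out = np.empty(snapshots.n_frames)
    for f in range(snapshots.n_frames):
        mob = coords[f][mask]
        if superpose:
            out[f] = _kabsch_rmsd(ref, mob)
        else:
            out[f] = float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
    return out


def rmsd_histogram(
    series: Sequence[float],
    n_bins: int = 50,
    count_threshold: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Histogram of an RMSD series plus a modality flag.

    Returns ``(bin_edges, counts, n_modes)`` where ``n_modes`` is the number
    of local maxima whose count and prominence both exceed
    ``count_threshold`` (default: 25% of the tallest bin), so shot noise on
    a single broad peak does not register as extra modes.  A unimodal
    distribution — the signature of a single conformational basin — gives
    ``n_modes == 1``.
    """
    series = np.asarray(series, dtype=float)
    counts, edges = np.histogram(series, bins=n_bins)
    if count_threshold is None:
        count_threshold = 0.25 * counts.max()
    threshold = max(count_threshold, 1e-12)
    padded = np.concatenate([[0], counts, [0]])
    peaks, _ = find_peaks(padded, height=threshold, prominence=threshold)
    return edges, counts, int(len(peaks))


def ensemble_mean_std(
    frame: pd.DataFrame,
    group_keys: Sequence[str],
    value_cols: Sequence[str],
    population: bool = True,
) -> pd.DataFrame:
    """Mean and standard deviation of per-snapshot values, per group key.

    Population (ddof=0) standard deviation by default.  Output columns are
    ``<col>_mean`` / ``<col>_std`` plus ``n`` (the snapshot count per group).
    """
    ddof = 0 if population else 1
    grouped = frame.groupby(list(group_keys), sort=True)
    pieces = {}
    for col in value_cols:
        pieces[f"{col}_mean"] = grouped[col].mean()
        pieces[f"{col}_std"] = grouped[col].std(ddof=ddof).fillna(0.0)
    out = pd.DataFrame(pieces)
    out["n"] = grouped.size()
    return out.reset_index()
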