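"""Coarse-grained helix axis and per-step rise/twist/bend extraction.

Each frame is reduced to (i) per-residue quinoline ring centers, (ii)
per-unit ring centers (mean of the unit's two ring centers), and (iii)
helical-axis centers, each the unweighted geometric center of the selected
heavy atoms of four consecutive residues, with windows advancing by two
residues. For a chain of n residues this yields n/2 - 1 axis centers.

From the axis polyline the three observables of the analysis are:

* rise_i  = |a_{i+1} - a_i|                       (Å, per axis step)
* twist_i = signed dihedral (v_i, a_i, a_{i+1}, v_{i+1})  (degrees), where
  v_i is the ring center of unit i; positive for a right-handed helix
* bend_j  = angle between consecutive axis segments  (degrees, [0, 180])

Degenerate twist steps (ring center on the axis) are flagged as NaN rather
than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geom import angle_between_deg, dihedral_deg, unit
from .topology import FoldamerTopology

__all__ = ["CoarseGrainFrame", "HelixSeries", "coarse_grain_frame",
           "coarse_grain_coords", "helix_series"]


@dataclass
class CoarseGrainFrame:
    """Coarse-grained geometry of a single frame."""

    ring_centers: np.ndarray       # (n_residues, 3)
    unit_ring_centers: np.ndarray  # (n_units, 3)
    axis_centers: np.ndarray       # (n_axis, 3), n_axis = n_res/2 - 1


@dataclass
class HelixSeries:
    """Per-frame, per-step helix parameter series.

    ``seg_tangents`` (unit vectors of the axis segments) are retained so
    that persistence-length estimators can be computed without re-reading
    the trajectory.
    """

    rise: np.ndarray          # (n_frames, n_axis - 1), Å
    twist: np.ndarray         # (n_frames, n_axis - 1), degrees in (-180, 180]
    bend: np.ndarray          # (n_frames, n_axis - 2), degrees in [0, 180]
    frame_times: np.ndarray   # ns
    seg_tangents: np.ndarray = field(default=None, repr=False)  # (F, S, 3)

    @property
    def n_frames(self) -> int:
        return self.rise.shape[0]

    @property
    def n_steps(self) -> int:
        return self.rise.shape[1]


def _window_centroids(coords, per_residue_idx):
    """Axis centers: unweighted means over atoms of residues [2i, 2i+4)."""
    n_res = len(per_residue_idx)
    n_axis = n_res // 2 - 1
    out = np.empty(coords.shape[:-2] + (n_axis, 3))
    for i in range(n_axis):
        idx = np.concatenate(per_residue_idx[2 * i : 2 * i + 4])
        out[..., i, :] = coords[..., idx, :].mean(axis=-2)
    return out


def coarse_grain_coords(coords: np.ndarray, topology: FoldamerTopology,
                        axis_selection: str = "backbone+ring"):
    """Vectorized coarse-graining of coordinates (..., n_atoms, 3).

    Returns (ring_centers, unit_ring_centers, axis_centers) with matching
    leading dimensions.
    """
    if topology.n_units < 2:
        raise ValueError("coarse graining needs at least 2 units (4 residues)")
    coords = np.asarray(coords, dtype=float)
    ring_idx = topology.ring_indices()
    ring_centers = np.stack(
        [coords[..., idx, :].mean(axis=-2) for idx in ring_idx], axis=-2
    )
    unit_rc = np.stack(
        [
            0.5 * (ring_centers[..., i, :] + ring_centers[..., j, :])
            for i, j in topology.units
        ],
        axis=-2,
    )
    axis_centers = _window_centroids(
        coords, topology.axis_selection_indices(axis_selection)
    )
    return ring_centers, unit_rc, axis_centers


def coarse_grain_frame(frame, topology: FoldamerTopology,
                       axis_selection: str = "backbone+ring") -> CoarseGrainFrame:
    """Coarse-grain a single :class:`~foldhelix.trajio.Frame`."""
    coords = frame.coords if hasattr(frame, "coords") else np.asarray(frame)
    rc, urc, ac = coarse_grain_coords(coords, topology, axis_selection)
    return CoarseGrainFrame(ring_centers=rc, unit_ring_centers=urc, axis_centers=ac)


def helix_series(traj, topology: FoldamerTopology | None = None,
                 axis_selection: str = "backbone+ring") -> HelixSeries:
    """Extract rise/twist/bend series for every frame of ``traj``."""
    topology = topology or traj.topology
    if topology is None:
        raise ValueError("helix_series needs a FoldamerTopology")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    _, urc, ac = coarse_grain_coords(traj.coords, topology, axis_selection)
    # segments between consecutive axis centers
    seg = ac[:, 1:, :] - ac[:, :-1, :]
    rise = np.linalg.norm(seg, axis=-1)
    n_steps = seg.shape[1]
    # twist step i pairs axis segment (a_i -> a_{i+1}) with unit ring
    # centers v_i, v_{i+1}; trailing unit ring centers beyond n_steps + 1
    # are unused by convention.
    v = urc[:, : n_steps + 1, :]
    twist = dihedral_deg(v[:, :-1, :], ac[:, :-1, :], ac[:, 1:, :], v[:, 1:, :])
    bend = angle_between_deg(seg[:, :-1, :], seg[:, 1:, :])
    if ac.shape[1] < 2:
        rise = np.empty((traj.n_frames, 0))
        twist = np.empty((traj.n_frames, 0))
        bend = np.empty((traj.n_frames, 0))
        seg = np.empty((traj.n_frames, 0, 3))
    return HelixSeries(
        rise=rise,
        twist=twist,
        bend=bend,
        frame_times=np.asarray(traj.times, dtype=float),
        seg_tangents=unit(seg),
    )
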