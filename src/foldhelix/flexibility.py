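"""Global flexibility of the foldamer helix: persistence lengths, rise
fluctuations, exo-helix periodicity, fluctuation covariance, RMSD/RMSF.

The helix is treated as a discrete worm-like chain sampled at one mQQ unit
per step. From the per-frame axis series the summary reports:

* mean twist and mean rise (grand means over unmasked frames and steps);
* bending persistence length from the end-to-end tangent scalar product,
  L_b = -L / ln<u_start . u_end>, with u_start/u_end the unit vectors of
  the first and last axis segments and L the mean contour length between
  them ((n_axis - 2) * <rise>);
* twist persistence length L_t = <rise> / var(dphi) with dphi the per-step
  twist fluctuation in radians — the standard discrete torsional-stiffness
  relation (the quantity is reported in simulation studies without a
  printed definition, so the estimator choice is flagged in reports); an
  alternative cumulative-twist-decay estimator is available behind a flag;
* pooled per-step rise variance (Å² per step).

Frames with large structural transitions (RMSD above a threshold, 6 Å by
convention) are excluded from these ensemble statistics — they are the
kinking events analyzed separately — via :func:`exclusion_mask`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._geom import kabsch_align
from .coarse_grain import HelixSeries

__all__ = [
    "FlexibilitySummary",
    "CovarianceProfile",
    "ExoPeriodicity",
    "exclusion_mask",
    "excluded_ranges",
    "flexibility_summary",
    "bending_persistence_per_step",
    "exo_periodicity",
    "fluctuation_covariance",
    "rmsd_series",
    "rmsf",
]


@dataclass
class FlexibilitySummary:
    mean_twist: float            # degrees
    mean_rise: float             # Å
    bending_persistence: float   # Å (inf if no measurable decay)
    twist_persistence: float     # Å
    rise_variance: float         # Å² per step
    n_frames_used: int
    exclusion: list = field(default_factory=list)   # [(start, stop), ...)
    flags: list = field(default_factory=list)

    def as_dict(self):
        return dict(
            mean_twist=self.mean_twist,
            mean_rise=self.mean_rise,
            bending_persistence=self.bending_persistence,
            twist_persistence=self.twist_persistence,
            rise_variance=self.rise_variance,
            n_frames_used=self.n_frames_used,
            exclusion=[list(r) for r in self.exclusion],
            flags=list(self.flags),
        )


@dataclass
class CovarianceProfile:
    offsets: np.ndarray     # signed step offsets
    twist_cov: np.ndarray   # degrees²
    bend_cov: np.ndarray    # degrees²
    center_step: int


@dataclass(frozen=True)
class ExoPeriodicity:
    """Units per exo-helical turn: 360 / (per-unit twist)."""

    units: float
    rounded: float          # nearest 0.5 unit


def exclusion_mask(rmsd_series: np.ndarray, threshold: float = 6.0) -> np.ndarray:
    """Frame mask that is False exactly where RMSD exceeds ``threshold``."""
    r = np.asarray(rmsd_series, dtype=float)
    return ~(r > threshold)


def excluded_ranges(mask: np.ndarray):
    """Contiguous half-open [start, stop) ranges of excluded (False) frames."""
    bad = ~np.asarray(mask, dtype=bool)
    padded = np.concatenate(([False], bad, [False]))
    d = np.diff(padded.astype(int))
    return list(zip(np.flatnonzero(d == 1).tolist(),
                    np.flatnonzero(d == -1).tolist()))


def _pooled_var(x: np.ndarray) -> float:
    """Pooled variance of per-column fluctuations (per-step means removed)."""
    resid = x - np.nanmean(x, axis=0, keepdims=True)
    resid = resid[np.isfinite(resid)]
    return float(np.var(resid, ddof=1)) if resid.size > 1 else 0.0


def flexibility_summary(series: HelixSeries, mask: np.ndarray | None = None
                        ) -> FlexibilitySummary:
    """Table-1-style global flexibility summary over unmasked frames."""
    keep = (np.ones(series.n_frames, dtype=bool)
            if mask is None else np.asarray(mask, dtype=bool))
    if keep.sum() < 2:
        raise ValueError("need at least 2 usable frames")
    if series.n_steps < 2 or series.seg_tangents.shape[1] < 2:
        raise ValueError("need at least 3 axis centers")
    rise = series.rise[keep]
    twist = series.twist[keep]
    tang = series.seg_tangents[keep]
    flags = []
    mean_rise = float(np.nanmean(rise))
    mean_twist = float(np.nanmean(twist))
    rise_var = _pooled_var(rise)
    # twist persistence: per-step estimator
    twist_var_rad = _pooled_var(np.radians(twist))
    if twist_var_rad > 0:
        twist_persistence = mean_rise / twist_var_rad
    else:
        twist_persistence = math.inf
        flags.append("twist_persistence_infinite")
    # bending persistence: end-to-end scalar product
    dot = float(np.mean(np.sum(tang[:, 0, :] * tang[:, -1, :], axis=-1)))
    n_axis = series.n_steps + 1
    L = (n_axis - 2) * mean_rise
    if dot >= 1.0:
        bending = math.inf
        flags.append("bending_persistence_infinite")
    elif dot <= 0.0:
        bending = math.nan
        flags.append("bending_persistence_unreliable_chain_too_flexible")
    else:
        bending = -L / math.log(dot)
    return FlexibilitySummary(
        mean_twist=mean_twist,
        mean_rise=mean_rise,
        bending_persistence=bending,
        twist_persistence=float(twist_persistence),
        rise_variance=rise_var,
        n_frames_used=int(keep.sum()),
        exclusion=excluded_ranges(keep),
        flags=flags,
    )


def bending_persistence_per_step(series: HelixSeries,
                                 mask: np.ndarray | None = None) -> float:
    """Independent per-step estimator: L_b = -<rise> / ln<cos(bend)>."""
    keep = (np.ones(series.n_frames, dtype=bool)
            if mask is None else np.asarray(mask, dtype=bool))
    mean_rise = float(np.nanmean(series.rise[keep]))
    c = float(np.nanmean(np.cos(np.radians(series.bend[keep]))))
    if c >= 1.0:
        return math.inf
    if c <= 0.0:
        return math.nan
    return -mean_rise / math.log(c)


def twist_persistence_decay(series: HelixSeries,
                            mask: np.ndarray | None = None,
                            max_sep: int = 5) -> float:
    """Alternative twist-persistence estimator from the decay of
    <cos(cumulative twist fluctuation)> with step separation."""
    keep = (np.ones(series.n_frames, dtype=bool)
            if mask is None else np.asarray(mask, dtype=bool))
    phi = np.radians(series.twist[keep])
    dphi = phi - np.nanmean(phi, axis=0, keepdims=True)
    mean_rise = float(np.nanmean(series.rise[keep]))
    seps, logs = [], []
    for j in range(1, min(max_sep, dphi.shape[1]) + 1):
        cum = np.nansum(
            np.stack([dphi[:, s : s + j] for s in range(dphi.shape[1] - j + 1)],
                     axis=1),
            axis=-1,
        )
        c = float(np.mean(np.cos(cum)))
        if c <= 0:
            break
        seps.append(j)
        logs.append(math.log(c))
    if len(seps) < 1:
        return math.nan
    slope = np.polyfit(seps, logs, 1)[0] if len(seps) > 1 else logs[0] / seps[0]
    if slope >= 0:
        return math.inf
    # <cos(sum dphi)> = exp(-j sigma^2 / 2) for Gaussian steps
    return mean_rise / (-2.0 * slope)


def exo_periodicity(mean_twist: float) -> ExoPeriodicity:
    """Units per exo-helix turn from the mean per-unit twist (degrees).

    36 degrees (the crystal-like twist) gives 10 units per turn; the
    partially unwound simulated helices give ~14 (mQQ4) and 12.5 (mQQ5).
    """
    if not 0 < mean_twist < 360:
        raise ValueError(f"mean twist must be in (0, 360), got {mean_twist}")
    units = 360.0 / mean_twist
    return ExoPeriodicity(units=units, rounded=round(units * 2.0) / 2.0)


def fluctuation_covariance(series: HelixSeries, center_step: int,
                           max_offset: int,
                           mask: np.ndarray | None = None) -> CovarianceProfile:
    """Covariance of twist (and bend) fluctuations between the center step
    and its neighbours; offset 0 equals the sample variance at the center."""
    keep = (np.ones(series.n_frames, dtype=bool)
            if mask is None else np.asarray(mask, dtype=bool))
    if keep.sum() < 2:
        raise ValueError("covariance needs at least 2 frames")
    if not (0 <= center_step - max_offset
            and center_step + max_offset < series.n_steps):
        raise ValueError("center_step +/- max_offset outside twist series")
    offsets = np.arange(-max_offset, max_offset + 1)

    def _cov(x):
        xc = x[keep] - np.nanmean(x[keep], axis=0, keepdims=True)
        n_cols = xc.shape[1]
        out = np.full(len(offsets), np.nan)
        for m, o in enumerate(offsets):
            j = center_step + o
            if 0 <= j < n_cols:
                a, b = xc[:, center_step], xc[:, j]
                ok = np.isfinite(a) & np.isfinite(b)
                if ok.sum() > 1:
                    out[m] = float(np.sum(a[ok] * b[ok]) / (ok.sum() - 1))
        return out

    return CovarianceProfile(
        offsets=offsets,
        twist_cov=_cov(series.twist),
        bend_cov=_cov(series.bend),
        center_step=center_step,
    )


def rmsd_series(traj, reference=0, atom_mask: np.ndarray | None = None
                ) -> np.ndarray:
    """Per-frame optimal-superposition RMSD (Å) to a reference structure.

    ``reference`` is a frame index or an (n_atoms, 3) array; ``atom_mask``
    defaults to all heavy atoms when a topology is attached, else all atoms.
    The Kabsch superposition runs in double precision throughout.
    """
    if atom_mask is None:
        atom_mask = (traj.topology.heavy_atom_mask
                     if traj.topology is not None
                     else np.ones(traj.n_atoms, dtype=bool))
    atom_mask = np.asarray(atom_mask, dtype=bool)
    if not atom_mask.any():
        raise ValueError("empty atom mask")
    ref = (traj.coords[reference] if np.isscalar(reference)
           else np.asarray(reference, dtype=float))
    if ref.shape != (traj.n_atoms, 3):
        raise ValueError("reference atom count does not match trajectory")
    ref_sel = ref[atom_mask]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        aligned = kabsch_align(traj.coords[f][atom_mask], ref_sel)
        out[f] = np.sqrt(np.mean(np.sum((aligned - ref_sel) ** 2, axis=-1)))
    return out


def rmsf(traj, atom_mask: np.ndarray | None = None,
         frame_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (Å) about the ensemble mean.

    Frames are superposed onto a provisional mean (computed after aligning
    everything to the first usable frame), the mean is recomputed once, and
    fluctuations are measured about it.
    """
    if atom_mask is None:
        atom_mask = (traj.topology.heavy_atom_mask
                     if traj.topology is not None
                     else np.ones(traj.n_atoms, dtype=bool))
    atom_mask = np.asarray(atom_mask, dtype=bool)
    keep = (np.ones(traj.n_frames, dtype=bool)
            if frame_mask is None else np.asarray(frame_mask, dtype=bool))
    frames = traj.coords[keep][:, atom_mask, :]
    if frames.shape[0] < 2:
        raise ValueError("RMSF needs at least 2 usable frames")
    aligned = np.stack([kabsch_align(f, frames[0]) for f in frames])
    mean0 = aligned.mean(axis=0)
    aligned = np.stack([kabsch_align(f, mean0) for f in frames])
    mean1 = aligned.mean(axis=0)
    out = np.zeros(traj.n_atoms)
    out[atom_mask] = np.sqrt(
        np.mean(np.sum((aligned - mean1) ** 2, axis=-1), axis=0)
    )
    return out
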