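"""Synthetic foldamer-helix conformers, ensembles, kinks and kinetic traces.

This module generates every input the analysis pipeline consumes, with known
ground truth, so that all estimators can be validated without
molecular-dynamics runs:

* an idealized straight (mQQ)_n helix with prescribed per-unit twist
  (36 degrees and 3.5 Å rise reproduce the crystal-like start geometry of
  the simulated 18-unit chains);
* fluctuating ensembles with prescribed per-step twist/rise variance and a
  prescribed worm-like-chain bending persistence length;
* transient kinks injected at a chosen unit and frame window with a
  prescribed axis-kink angle and gamma/delta dihedral offsets;
* single-exponential CD decay traces with noise and an instrument-lag
  plateau.

Pseudo-atom chemistry
---------------------
Residues are built from pseudo-atoms, not real quinoline geometry: a planar
"ring" polygon of ``atoms_per_ring`` carbons whose centroid plays the role
of the quinoline ring center, a matching "backbone" polygon of nitrogens on
the opposite side of the helix axis, and an optional 5-atom phosphonate
group (P, 3 O, 1 donor H) further out. The backbone polygon mirrors the
ring so that each residue's backbone+ring centroid lies exactly on the
helix axis; the 4-residue-window axis centers of the analyzer are then
exactly on the axis and the ideal-helix rise/twist/bend are exact by
construction. The analysis depends only on geometric centers, distances and
dihedral quadruples, all of which pseudo-atoms express.

Ensembles are built by generating the coarse-grained axis path itself
(per-step twist and rise noise; a fixed-magnitude tangent tilt with uniform
random azimuth, with cos(tilt) = exp(-rise0/lp) so the tangent
autocorrelation is exactly exp(-j*rise0/lp)) and then solving for residue
centers whose analyzer window means reproduce the generated axis nodes
exactly. Frames are temporally independent by default (ensemble statistics
need no memory); an optional AR(1) frame-memory parameter exists for
event-lifetime studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._geom import minimal_rotation
from .kinetics import KineticTrace
from .kinks import KinkEvent, KinkParams
from .topology import builtin_registry, build_topology
from .trajio import Frame, Trajectory

__all__ = [
    "HelixSpec",
    "EnsembleSpec",
    "KinkSpec",
    "build_ideal_helix",
    "generate_ensemble",
    "inject_kink",
    "make_cd_trace",
]


@dataclass(frozen=True)
class HelixSpec:
    """Geometry of the idealized straight helix."""

    n_units: int = 18
    twist_per_unit: float = 36.0   # degrees
    rise_per_unit: float = 3.5     # Å
    ring_radius: float = 2.5       # Å, ring center from axis
    side_radius: float = 9.5       # Å, phosphonate P from axis (B-DNA-like)
    atoms_per_ring: int = 6
    include_phosphonate: bool = True

    def __post_init__(self):
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2")
        if not self.rise_per_unit > 0:
            raise ValueError("rise_per_unit must be > 0")
        if not 0 < self.twist_per_unit < 360:
            raise ValueError("twist_per_unit must be in (0, 360)")
        if self.atoms_per_ring < 6:
            raise ValueError("atoms_per_ring must be >= 6")


@dataclass(frozen=True)
class EnsembleSpec:
    """Fluctuation parameters of a synthetic conformer ensemble."""

    n_frames: int
    sigma_twist: float = 0.0       # degrees, per-step sd
    lp_bend: float = math.inf      # Å, target bending persistence length
    sigma_rise: float = 0.0        # Å, per-step sd
    seed: int = 0
    ar1: float = 0.0               # frame-to-frame noise memory (0 = none)

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for name in ("sigma_twist", "sigma_rise"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not self.lp_bend > 0:
            raise ValueError("lp_bend must be > 0 (use inf for a rigid axis)")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must be in [0, 1)")


@dataclass(frozen=True)
class KinkSpec:
    """A transient kink to inject: location, window, magnitudes."""

    unit_index: int
    frame_start: int
    frame_end: int
    bend_angle: float = 40.0       # degrees
    gamma_offset: float = 0.0      # degrees
    delta_offset: float = 0.0      # degrees

    def __post_init__(self):
        if not self.frame_start < self.frame_end:
            raise ValueError("frame_start must be < frame_end")
        if not 0 <= self.bend_angle < 180:
            raise ValueError("bend_angle must be in [0, 180)")


# --------------------------------------------------------------------------
# residue-local pseudo-atom geometry
# --------------------------------------------------------------------------

_RING_RHO = 0.7      # Å, radius of the pseudo-ring polygon
_BACK_Z = 0.3        # Å, alternating z offset of backbone atoms
_BACK_PHASE = 25.0   # degrees, backbone polygon phase offset


def _residue_local(spec: HelixSpec):
    """Local atom coordinates and names for one residue.

    Local frame: x = outward normal (away from the helix axis), z = local
    helix tangent; the residue's backbone+ring centroid is the origin.
    """
    m = spec.atoms_per_ring
    names, coords = [], []
    ang = 2 * np.pi * np.arange(m) / m
    for k in range(m):
        names.append(f"C{k + 1}")
        coords.append([
            spec.ring_radius + _RING_RHO * np.cos(ang[k]),
            _RING_RHO * np.sin(ang[k]),
            0.0,
        ])
    ph = np.radians(_BACK_PHASE)
    for k in range(m):
        names.append(f"N{k + 1}")
        coords.append([
            -spec.ring_radius - _RING_RHO * np.cos(ang[k] + ph),
            -_RING_RHO * np.sin(ang[k] + ph),
            _BACK_Z * (1 if k % 2 else -1),
        ])
    if spec.include_phosphonate:
        s = spec.side_radius
        names += ["P", "O1", "O2", "O3", "H1"]
        coords += [
            [s, 0.0, 0.0],
            [s + 1.2, 0.0, 0.9],
            [s + 0.4, 1.3, -0.6],
            [s + 0.4, -1.3, -0.6],
            [s + 2.0, 0.0, 1.5],
        ]
    return names, np.asarray(coords, dtype=float)


# --------------------------------------------------------------------------
# axis-path sampling and frame construction
# --------------------------------------------------------------------------


def _window_matrix(n_res: int):
    n_axis = n_res // 2 - 1
    W = np.zeros((n_axis, n_res))
    for i in range(n_axis):
        W[i, 2 * i : 2 * i + 4] = 0.25
    return W, np.linalg.pinv(W)


def _ar1_normal(rng, rho: float, shape):
    """Standard-normal field with AR(1) memory along the first (frame) axis."""
    z = rng.standard_normal(shape)
    if rho == 0.0 or shape[0] == 1:
        return z
    out = np.empty_like(z)
    out[0] = z[0]
    c = math.sqrt(1.0 - rho * rho)
    for f in range(1, shape[0]):
        out[f] = rho * out[f - 1] + c * z[f]
    return out


def _sample_paths(hspec: HelixSpec, espec: EnsembleSpec, rng):
    """Generate per-frame coarse-grained axis paths.

    Returns a dict of arrays: axis nodes ``a`` (F, n_axis, 3), per-segment
    frames ``T``/``e1``/``e2`` (F, n_seg_pad, 3), unit azimuths ``Psi``
    (F, n_units) in degrees, and segment lengths ``rises`` (F, n_seg).
    """
    F = espec.n_frames
    n_units = hspec.n_units
    n_axis = n_units - 1
    n_seg = n_axis - 1
    tau = hspec.twist_per_unit + espec.sigma_twist * _ar1_normal(
        rng, espec.ar1, (F, n_units - 1)
    )
    Psi = np.concatenate([np.zeros((F, 1)), np.cumsum(tau, axis=1)], axis=1)
    rises = hspec.rise_per_unit + espec.sigma_rise * _ar1_normal(
        rng, espec.ar1, (F, max(n_seg, 1))
    )[:, :n_seg]
    n_pad = max(n_seg, 1)
    T = np.zeros((F, n_pad, 3))
    e1 = np.zeros((F, n_pad, 3))
    e2 = np.zeros((F, n_pad, 3))
    T[:, 0] = (0.0, 0.0, 1.0)
    e1[:, 0] = (1.0, 0.0, 0.0)
    e2[:, 0] = (0.0, 1.0, 0.0)
    if np.isinf(espec.lp_bend):
        cos_t, sin_t = 1.0, 0.0
    else:
        cos_t = math.exp(-hspec.rise_per_unit / espec.lp_bend)
        sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    if n_seg > 1:
        az = 2 * np.pi * rng.random((F, n_seg - 1))
        if espec.ar1 > 0.0:
            gx = _ar1_normal(rng, espec.ar1, (F, n_seg - 1))
            gy = _ar1_normal(rng, espec.ar1, (F, n_seg - 1))
            az = np.arctan2(gy, gx)
        for j in range(n_seg - 1):
            if sin_t == 0.0:
                T[:, j + 1] = T[:, j]
                e1[:, j + 1] = e1[:, j]
                e2[:, j + 1] = e2[:, j]
                continue
            tilt_dir = (np.cos(az[:, j])[:, None] * e1[:, j]
                        + np.sin(az[:, j])[:, None] * e2[:, j])
            T[:, j + 1] = cos_t * T[:, j] + sin_t * tilt_dir
            R = minimal_rotation(T[:, j], T[:, j + 1])
            e1[:, j + 1] = np.einsum("fij,fj->fi", R, e1[:, j])
            e2[:, j + 1] = np.cross(T[:, j + 1], e1[:, j + 1])
    a = np.zeros((F, n_axis, 3))
    for i in range(n_seg):
        a[:, i + 1] = a[:, i] + rises[:, i, None] * T[:, i]
    return dict(a=a, T=T, e1=e1, e2=e2, Psi=Psi, rises=rises)


def _point_on_path(path, hspec: HelixSpec, arclens):
    """Points at signed arclengths along each frame's axis polyline,
    linearly extended beyond both ends."""
    a, T, rises = path["a"], path["T"], path["rises"]
    F, n_axis = a.shape[:2]
    s = np.concatenate([np.zeros((F, 1)), np.cumsum(rises, axis=1)], axis=1)
    n_seg = rises.shape[1]
    pts = np.empty((F, len(arclens), 3))
    for r, ell in enumerate(arclens):
        if n_seg == 0:
            pts[:, r] = a[:, 0] + ell * T[:, 0]
            continue
        j = np.clip(
            (s[:, :-1] <= ell).sum(axis=1) - 1, 0, n_seg - 1
        )
        rows = np.arange(F)
        pts[:, r] = a[rows, j] + (ell - s[rows, j])[:, None] * T[rows, j]
    return pts


def _frames_from_paths(path, hspec: HelixSpec, local_coords, pinv_data):
    """Build atomic coordinates (F, n_atoms, 3) whose analyzer axis centers
    reproduce the path nodes exactly."""
    F = path["a"].shape[0]
    n_units = hspec.n_units
    n_res = 2 * n_units
    W, Wp = pinv_data
    h = hspec.rise_per_unit / 2.0
    arclens = (np.arange(n_res) - 1.5) * h
    c0 = _point_on_path(path, hspec, arclens)          # (F, n_res, 3)
    target = path["a"]
    resid = target - np.einsum("ar,frk->fak", W, c0)
    c = c0 + np.einsum("ra,fak->frk", Wp, resid)
    # residue orientation frames
    eps = hspec.twist_per_unit / 4.0
    n_seg_pad = path["T"].shape[1]
    n_atoms_res = local_coords.shape[0]
    coords = np.empty((F, n_res * n_atoms_res, 3))
    for r in range(n_res):
        u = r // 2
        j = min(u, n_seg_pad - 1)
        psi = np.radians(path["Psi"][:, u] + (eps if r % 2 else -eps))
        nhat = (np.cos(psi)[:, None] * path["e1"][:, j]
                + np.sin(psi)[:, None] * path["e2"][:, j])
        that = path["T"][:, j]
        bhat = np.cross(that, nhat)
        M = np.stack([nhat, bhat, that], axis=-1)       # (F, 3, 3) columns
        coords[:, r * n_atoms_res : (r + 1) * n_atoms_res] = (
            c[:, r, None, :] + np.einsum("ak,fjk->faj", local_coords, M)
        )
    return coords


def _chain_labels(hspec: HelixSpec, local_names, q_residue: str):
    n_res = 2 * hspec.n_units
    atom_names, resids, resnames, sequence = [], [], [], []
    for r in range(n_res):
        name = "mQ" if r % 2 == 0 else q_residue
        sequence.append(name)
        for an in local_names:
            atom_names.append(an)
            resids.append(r)
            resnames.append(name)
    return atom_names, np.array(resids, dtype=np.intp), resnames, sequence


def build_ideal_helix(spec: HelixSpec = HelixSpec(), q_residue: str = "Q4",
                      registry=None):
    """Build the idealized straight helix and its topology.

    Residue r sits at azimuth r*(twist/2) and height r*(rise/2); the chain
    alternates mQ and Q-type residues, one mQQ unit per residue pair. The
    coarse-grained analyzer returns exactly ``rise_per_unit``,
    ``twist_per_unit`` and zero bend on this frame.
    """
    registry = registry or builtin_registry(spec.atoms_per_ring)
    local_names, local_coords = _residue_local(spec)
    espec = EnsembleSpec(n_frames=1, seed=0)
    path = _sample_paths(spec, espec, np.random.default_rng(0))
    W_Wp = _window_matrix(2 * spec.n_units)
    coords = _frames_from_paths(path, spec, local_coords, W_Wp)[0]
    atom_names, resids, resnames, sequence = _chain_labels(
        spec, local_names, q_residue
    )
    frame = Frame(coords=coords, atom_names=atom_names, resids=resids,
                  resnames=resnames, time=0.0)
    topo = build_topology(sequence, registry, frame)
    topo.metadata["helix_spec"] = spec
    topo.metadata["q_residue"] = q_residue
    return frame, topo


def generate_ensemble(base, spec: EnsembleSpec, timestep: float = 1.0) -> Trajectory:
    """Re-grow the chain each frame with independent per-step perturbations.

    ``base`` is the (frame, topology) pair from :func:`build_ideal_helix`.
    Twist and rise steps receive independent Gaussian noise; the axis
    tangent is tilted per step by a fixed angle with uniform random azimuth,
    calibrated so the tangent autocorrelation is exp(-j*rise0/lp_bend).
    Reproducible given ``spec.seed``.
    """
    frame, topo = base
    hspec = topo.metadata.get("helix_spec")
    if hspec is None:
        raise ValueError("base topology lacks helix_spec metadata; "
                         "build it with build_ideal_helix")
    local_names, local_coords = _residue_local(hspec)
    ref, _ = build_ideal_helix(hspec, q_residue=topo.metadata.get("q_residue", "Q4"))
    if not np.allclose(ref.coords, frame.coords, atol=1e-6):
        raise ValueError("base frame is not the ideal helix of its spec")
    rng = np.random.default_rng(spec.seed)
    path = _sample_paths(hspec, spec, rng)
    W_Wp = _window_matrix(2 * hspec.n_units)
    coords = _frames_from_paths(path, hspec, local_coords, W_Wp)
    traj = Trajectory(
        coords=coords,
        atom_names=list(frame.atom_names),
        resids=frame.resids.copy(),
        resnames=list(frame.resnames),
        timestep=timestep,
        topology=topo,
        metadata=dict(path=path, ensemble_spec=spec, injections=[]),
    )
    return traj


def _axis_angle_matrices(axes: np.ndarray, angle_deg: float) -> np.ndarray:
    """Batched Rodrigues rotation matrices about unit axes (N, 3)."""
    k = axes / np.linalg.norm(axes, axis=-1, keepdims=True)
    t = math.radians(angle_deg)
    K = np.zeros(k.shape[:-1] + (3, 3))
    K[..., 0, 1], K[..., 0, 2] = -k[..., 2], k[..., 1]
    K[..., 1, 0], K[..., 1, 2] = k[..., 2], -k[..., 0]
    K[..., 2, 0], K[..., 2, 1] = -k[..., 1], k[..., 0]
    eye = np.broadcast_to(np.eye(3), K.shape).copy()
    return eye + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)


def _rotate_probe(coords, quad_idx, angle_deg):
    """Rotate the terminal atom of a dihedral quadruple about its b-c bond
    axis, changing that dihedral by exactly ``angle_deg``."""
    ia, ib, ic, id_ = (int(i) for i in quad_idx)
    axis = coords[:, ic] - coords[:, ib]
    R = _axis_angle_matrices(axis, angle_deg)
    p = coords[:, id_] - coords[:, ic]
    coords[:, id_] = np.einsum("fij,fj->fi", R, p) + coords[:, ic]


def inject_kink(traj: Trajectory, spec: KinkSpec):
    """Inject a transient kink into a generator-produced trajectory.

    Within [frame_start, frame_end) the axis path downstream of the chosen
    unit is rotated by ``bend_angle`` about a transverse axis through the
    corner node, the frames are rebuilt from the modified path (so the
    analyzer sees the full bend at a single junction), and the unit's gamma
    and delta dihedrals are offset by rotating their dedicated probe atoms.
    Frames outside the window are bit-identical to the input. Returns the
    new trajectory and a ground-truth :class:`KinkEvent`.
    """
    topo = traj.topology
    hspec = topo.metadata.get("helix_spec")
    path = traj.metadata.get("path")
    if hspec is None or path is None:
        raise ValueError("inject_kink requires a generate_ensemble trajectory "
                         "(path metadata missing)")
    n_units = hspec.n_units
    n_axis = n_units - 1
    if not 0 <= spec.unit_index < n_units:
        raise ValueError(f"unit_index {spec.unit_index} out of range")
    if spec.bend_angle > 0 and not 1 <= spec.unit_index <= n_axis - 2:
        raise ValueError(
            f"a bent kink needs an interior unit (1..{n_axis - 2}), "
            f"got {spec.unit_index}"
        )
    if not (0 <= spec.frame_start and spec.frame_end <= traj.n_frames):
        raise ValueError("kink frame window outside trajectory")
    for prev in traj.metadata.get("injections", []):
        if (prev.unit_index == spec.unit_index
                and prev.frame_start < spec.frame_end
                and spec.frame_start < prev.frame_end):
            raise ValueError("overlapping kink injection at the same unit")
    w = slice(spec.frame_start, spec.frame_end)
    new_path = {k: v.copy() for k, v in path.items()}
    coords = traj.coords.copy()
    if spec.bend_angle > 0:
        i0 = spec.unit_index
        axes = path["e1"][w, min(i0, path["e1"].shape[1] - 1)]
        R = _axis_angle_matrices(axes, spec.bend_angle)
        pivot = path["a"][w, i0]

        def _rot_pts(pts):
            return np.einsum("fij,f...j->f...i", R, pts - pivot[:, None, :]) \
                + pivot[:, None, :]

        def _rot_dirs(dirs):
            return np.einsum("fij,f...j->f...i", R, dirs)

        new_path["a"][w, i0 + 1 :] = _rot_pts(path["a"][w, i0 + 1 :])
        for key in ("T", "e1", "e2"):
            new_path[key][w, i0:] = _rot_dirs(path[key][w, i0:])
        sub = {k: new_path[k][w] for k in new_path}
        local_names, local_coords = _residue_local(hspec)
        coords[w] = _frames_from_paths(
            sub, hspec, local_coords, _window_matrix(2 * n_units)
        )
    labels, table = topo.dihedral_index_table()
    if spec.bend_angle > 0:
        # rebuilding the window regenerates all atoms; re-apply the probe
        # rotations of earlier injections whose windows overlap this one
        for prev in traj.metadata.get("injections", []):
            lo = max(prev.frame_start, spec.frame_start)
            hi = min(prev.frame_end, spec.frame_end)
            if lo >= hi:
                continue
            for label, offset in (("gamma", prev.gamma_offset),
                                  ("delta", prev.delta_offset)):
                if offset:
                    quad = table[prev.unit_index, labels.index(label)]
                    _rotate_probe(coords[lo:hi], quad, offset)
    deltas = {}
    for label, offset in (("gamma", spec.gamma_offset),
                          ("delta", spec.delta_offset)):
        if offset:
            li = labels.index(label)
            quad = table[spec.unit_index, li]
            if np.any(quad < 0):
                raise ValueError(f"{label} dihedral unresolvable at unit "
                                 f"{spec.unit_index}")
            _rotate_probe(coords[w], quad, offset)
            deltas[label] = abs(offset)
    lifetime = (spec.frame_end - spec.frame_start) * traj.timestep
    defaults = KinkParams()
    span = traj.n_frames * traj.timestep
    coupled = (abs(spec.delta_offset) > defaults.delta_threshold
               or spec.bend_angle > defaults.bend_threshold)
    truth = KinkEvent(
        unit_index=spec.unit_index,
        frame_start=spec.frame_start,
        frame_end=spec.frame_end,
        lifetime=float(lifetime),
        kink_class="major" if coupled and lifetime >= 0.1 * span else "minor",
        max_bend=float(spec.bend_angle),
        dihedral_deltas={"gamma": abs(spec.gamma_offset), **deltas},
    )
    out = Trajectory(
        coords=coords,
        atom_names=list(traj.atom_names),
        resids=traj.resids.copy(),
        resnames=list(traj.resnames),
        timestep=traj.timestep,
        topology=topo,
        metadata=dict(
            path=new_path,
            ensemble_spec=traj.metadata.get("ensemble_spec"),
            injections=list(traj.metadata.get("injections", [])) + [spec],
        ),
    )
    return out, truth


def make_cd_trace(y_inf: float, amplitude: float, k: float, t_max: float,
                  n_points: int, noise_sigma: float = 0.0, lag: float = 0.0,
                  seed: int = 0, metadata: dict | None = None) -> KineticTrace:
    """Synthesize a CD re-equilibration trace.

    ``y(t) = y_inf + amplitude * exp(-k (t - lag))`` for t >= lag; before
    the lag a flat plateau at the initial signal is emitted, simulating the
    sample-temperature equilibration period that is trimmed before fitting.
    Gaussian noise of sd ``noise_sigma`` is added; reproducible given seed.
    """
    if not k > 0:
        raise ValueError("rate constant k must be > 0")
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    t = np.linspace(0.0, t_max, n_points)
    y = np.where(
        t < lag,
        y_inf + amplitude,
        y_inf + amplitude * np.exp(-k * np.maximum(t - lag, 0.0)),
    )
    if noise_sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sigma, n_points)
    return KineticTrace(time=t, signal=y, metadata=dict(metadata or {}))
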