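"""Backbone-dihedral kink detection, unstacking events and phosphonate contacts.

Transient kinks in the aromatic helix are local unstacking events in which
the helical axis is temporarily redirected. They are read out from the
backbone dihedrals along each repeat unit (labels alpha..zeta): an event
opens when the gamma dihedral of a unit leaves its circular mode by more
than a threshold for a minimum dwell, and is classified *major* when the
excursion is accompanied by a delta flip or a large local axis bend and
lives long enough, *minor* otherwise. This mirrors the phenomenology of
microsecond simulations of (mQQ)18 chains: frequent sub-ns minor kinks with
small (<60 deg) dihedral shifts, and rare >100 ns major kinks with coupled
gamma/delta transitions and a ~40 deg axis break. The thresholds are
parameters, not constants of nature, and are logged into reports.

Phosphonate hydrogen bonds use the distance-only criterion d(H..O) < 2.5 Å
between different phosphonate groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import circmean

from ._geom import dihedral_deg, wrap_deg
from .topology import FoldamerTopology

__all__ = [
    "DihedralSeries",
    "KinkEvent",
    "UnstackingEvent",
    "ContactStats",
    "KinkParams",
    "dihedral_series",
    "detect_kinks",
    "kink_rate",
    "detect_unstacking",
    "phosphonate_contacts",
    "circular_mode",
]


@dataclass
class DihedralSeries:
    """Per-frame, per-unit backbone dihedrals in degrees, (-180, 180]."""

    values: np.ndarray            # (n_frames, n_units, n_labels); NaN = unresolved
    labels: tuple[str, ...]
    frame_times: np.ndarray       # ns

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def label_index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def timestep(self) -> float:
        t = self.frame_times
        return float(t[1] - t[0]) if len(t) > 1 else 1.0


@dataclass
class KinkEvent:
    """A detected (or injected ground-truth) kinking event."""

    unit_index: int
    frame_start: int
    frame_end: int                # half-open
    lifetime: float               # ns
    kink_class: str               # "minor" | "major"
    max_bend: float               # degrees
    dihedral_deltas: dict = field(default_factory=dict)  # label -> max |excursion|


@dataclass
class UnstackingEvent:
    pair_index: int               # between units pair_index and pair_index + 1
    frame_start: int
    frame_end: int
    lifetime: float               # ns
    max_ratio: float              # peak distance / per-pair median


@dataclass
class ContactStats:
    pp_distances: np.ndarray      # (n_frames, n_adjacent_pairs), Å
    hbond_fraction: np.ndarray    # per frame, fraction of groups in >= 1 bond
    cutoff: float                 # Å


@dataclass
class KinkParams:
    """Detection thresholds (degrees / frames / ns); all CLI-exposed."""

    gamma_threshold: float = 45.0
    delta_threshold: float = 90.0
    bend_threshold: float = 30.0
    min_dwell_frames: int = 2
    major_min_lifetime_ns: float | None = None  # default: 10% of span

    def validate(self):
        for name in ("gamma_threshold", "delta_threshold", "bend_threshold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_dwell_frames < 1:
            raise ValueError("min_dwell_frames must be >= 1")


def dihedral_series(traj, topology: FoldamerTopology | None = None) -> DihedralSeries:
    """Compute the alpha..zeta series for every unit and frame.

    Quadruples that do not resolve (missing template/atom/offset) yield NaN
    columns for that unit.
    """
    import warnings as _warnings

    topology = topology or traj.topology
    labels, table = topology.dihedral_index_table()
    n_frames = traj.n_frames
    n_units, n_labels = table.shape[:2]
    values = np.full((n_frames, n_units, n_labels), np.nan)
    ok = np.all(table >= 0, axis=-1)          # (n_units, n_labels)
    if not np.all(ok):
        bad = [(u, labels[li]) for u, li in zip(*np.nonzero(~ok))]
        _warnings.warn(
            f"{len(bad)} dihedral(s) unresolvable and omitted "
            f"(first: unit {bad[0][0]}, label {bad[0][1]})",
            stacklevel=2,
        )
    idx = table[ok]                            # (n_ok, 4)
    if idx.size:
        p = traj.coords[:, idx, :]             # (F, n_ok, 4, 3)
        vals = dihedral_deg(p[..., 0, :], p[..., 1, :], p[..., 2, :], p[..., 3, :])
        values[:, ok] = vals
    return DihedralSeries(values=values, labels=tuple(labels),
                          frame_times=np.asarray(traj.times, dtype=float))


def circular_mode(angles_deg: np.ndarray, bin_width: float = 10.0) -> float:
    """Mode of a circular sample: densest histogram bin refined by a local
    circular mean (+/- 2 bins). Deterministic; NaNs ignored."""
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        return np.nan
    nbins = max(int(round(360.0 / bin_width)), 4)
    hist, edges = np.histogram(np.mod(a, 360.0), bins=nbins, range=(0.0, 360.0))
    center = edges[np.argmax(hist)] + 180.0 / nbins
    local = a[np.abs(wrap_deg(a - center)) <= 2 * bin_width]
    if local.size == 0:
        local = a
    return float(wrap_deg(np.degrees(circmean(np.radians(local)))))


def _runs(mask_1d: np.ndarray):
    """Start/stop (half-open) of True runs in a boolean vector."""
    padded = np.concatenate(([False], mask_1d, [False]))
    d = np.diff(padded.astype(int))
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def _merge_runs(runs, gap: int):
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _bend_junctions_for_unit(u: int, n_junctions: int):
    # bend junction j involves axis centers j..j+2, i.e. residues
    # [2j, 2j+6) = units j..j+2, so unit u touches junctions u-2..u
    lo, hi = max(0, u - 2), min(n_junctions - 1, u)
    return range(lo, hi + 1)


def detect_kinks(dihedrals: DihedralSeries, bends: np.ndarray | None = None,
                 params: KinkParams | None = None,
                 frame_mask: np.ndarray | None = None) -> list[KinkEvent]:
    """Detect and classify kinking events from gamma/delta excursions.

    The reference value per unit is the circular mode of gamma over the
    (unmasked) trajectory, which is robust to slow drift. ``bends`` is the
    (n_frames, n_junctions) bend matrix from :func:`helix_series`, used both
    for the major-kink bend criterion and to report ``max_bend``.
    """
    params = params or KinkParams()
    params.validate()
    dt = dihedrals.timestep
    span_ns = dihedrals.n_frames * dt
    major_min = (params.major_min_lifetime_ns
                 if params.major_min_lifetime_ns is not None else 0.1 * span_ns)
    gi = dihedrals.label_index("gamma")
    di = dihedrals.label_index("delta") if "delta" in dihedrals.labels else None
    keep = (np.ones(dihedrals.n_frames, dtype=bool)
            if frame_mask is None else np.asarray(frame_mask, dtype=bool))
    n_junctions = bends.shape[1] if bends is not None else 0
    events: list[KinkEvent] = []
    for u in range(dihedrals.n_units):
        gamma = dihedrals.values[:, u, gi]
        if not np.any(np.isfinite(gamma)):
            continue
        ref_g = circular_mode(gamma[keep])
        exc_g = np.abs(wrap_deg(gamma - ref_g))
        above = np.nan_to_num(exc_g) > params.gamma_threshold
        runs = [
            (s, e)
            for s, e in _merge_runs(_runs(above), params.min_dwell_frames)
            if e - s >= params.min_dwell_frames
        ]
        if di is not None:
            delta = dihedrals.values[:, u, di]
            ref_d = circular_mode(delta[keep])
            exc_d = np.abs(wrap_deg(delta - ref_d))
        for s, e in runs:
            lifetime = (e - s) * dt
            deltas = {"gamma": float(np.nanmax(exc_g[s:e]))}
            if di is not None:
                deltas["delta"] = float(np.nanmax(np.nan_to_num(exc_d[s:e])))
            max_bend = 0.0
            if bends is not None and n_junctions:
                js = list(_bend_junctions_for_unit(u, n_junctions))
                max_bend = float(np.nanmax(bends[s:e][:, js]))
            coupled = (deltas.get("delta", 0.0) > params.delta_threshold
                       or max_bend > params.bend_threshold)
            kink_class = ("major"
                          if coupled and lifetime >= major_min else "minor")
            events.append(KinkEvent(
                unit_index=u, frame_start=int(s), frame_end=int(e),
                lifetime=float(lifetime), kink_class=kink_class,
                max_bend=max_bend, dihedral_deltas=deltas,
            ))
    events.sort(key=lambda ev: (ev.frame_start, ev.unit_index))
    return events


def kink_rate(events, total_time_ns: float) -> float:
    """Event rate in kinks per microsecond of trajectory."""
    if not total_time_ns > 0:
        raise ValueError("total_time_ns must be > 0")
    return len(list(events)) * 1000.0 / total_time_ns


def detect_unstacking(unit_ring_centers: np.ndarray, factor: float = 1.8,
                      min_dwell_frames: int = 1, timestep: float = 1.0,
                      frame_mask: np.ndarray | None = None) -> list[UnstackingEvent]:
    """Detect unstacking: a neighbor-unit ring-center distance exceeding
    ``factor`` times its per-pair median (an unstacked step roughly doubles
    the spacing, hence the 1.8 default)."""
    if not factor > 1.0:
        raise ValueError("unstacking factor must be > 1")
    v = np.asarray(unit_ring_centers, dtype=float)
    if v.ndim != 3 or v.shape[1] < 2:
        raise ValueError("need (n_frames, n_units >= 2, 3) ring centers")
    d = np.linalg.norm(v[:, 1:, :] - v[:, :-1, :], axis=-1)  # (F, U-1)
    keep = (np.ones(d.shape[0], dtype=bool)
            if frame_mask is None else np.asarray(frame_mask, dtype=bool))
    med = np.median(d[keep], axis=0)
    events = []
    for pair in range(d.shape[1]):
        above = d[:, pair] > factor * med[pair]
        for s, e in _runs(above):
            if e - s >= min_dwell_frames:
                events.append(UnstackingEvent(
                    pair_index=pair, frame_start=int(s), frame_end=int(e),
                    lifetime=float((e - s) * timestep),
                    max_ratio=float(np.max(d[s:e, pair]) / med[pair]),
                ))
    events.sort(key=lambda ev: (ev.frame_start, ev.pair_index))
    return events


def phosphonate_contacts(traj, topology: FoldamerTopology | None = None,
                         hbond_cutoff: float = 2.5,
                         chunk: int = 512) -> ContactStats:
    """Inter-phosphonate hydrogen-bond statistics and adjacent P-P distances.

    A bond is counted when a donor H of one phosphonate lies within
    ``hbond_cutoff`` of an acceptor O of a *different* phosphonate
    (intra-group pairs are excluded); ``hbond_fraction`` counts groups in at
    least one bond, as donor or acceptor, per frame.
    """
    import warnings as _warnings

    topology = topology or traj.topology
    groups = topology.phosphonate_groups()
    n_frames = traj.n_frames
    if not groups:
        _warnings.warn("no phosphonate groups in topology; empty contact stats",
                       stacklevel=2)
        return ContactStats(
            pp_distances=np.empty((n_frames, 0)),
            hbond_fraction=np.zeros(n_frames),
            cutoff=hbond_cutoff,
        )
    donors = np.array([h for g in groups for h in g["donors"]], dtype=np.intp)
    donor_grp = np.array([gi for gi, g in enumerate(groups) for _ in g["donors"]])
    accs = np.array([o for g in groups for o in g["acceptors"]], dtype=np.intp)
    acc_grp = np.array([gi for gi, g in enumerate(groups) for _ in g["acceptors"]])
    same = donor_grp[:, None] == acc_grp[None, :]
    p_idx = np.array([g["P"] for g in groups], dtype=np.intp)
    residues = [g["residue"] for g in groups]
    adjacent = [i for i in range(len(groups) - 1)
                if residues[i + 1] == residues[i] + 1]
    frac = np.zeros(n_frames)
    ppd = np.zeros((n_frames, len(adjacent)))
    for start in range(0, n_frames, chunk):
        sl = slice(start, min(start + chunk, n_frames))
        c = traj.coords[sl]
        hd = c[:, donors, :]
        oa = c[:, accs, :]
        dist = np.linalg.norm(hd[:, :, None, :] - oa[:, None, :, :], axis=-1)
        bonded = (dist < hbond_cutoff) & ~same
        in_bond = np.zeros((c.shape[0], len(groups)), dtype=bool)
        for gi in range(len(groups)):
            as_donor = bonded[:, donor_grp == gi, :].any(axis=(1, 2))
            as_acc = bonded[:, :, acc_grp == gi].any(axis=(1, 2))
            in_bond[:, gi] = as_donor | as_acc
        frac[sl] = in_bond.mean(axis=1)
        pp = c[:, p_idx, :]
        if adjacent:
            a = np.array(adjacent)
            ppd[sl] = np.linalg.norm(pp[:, a + 1, :] - pp[:, a, :], axis=-1)
    return ContactStats(pp_distances=ppd, hbond_fraction=frac, cutoff=hbond_cutoff)
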