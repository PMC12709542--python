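"""Trajectory, series-table and report I/O.

Coordinate formats are plain-text only: multi-model PDB (MODEL/ENDMDL per
frame) and multi-frame XYZ, both read and written through MDAnalysis behind
the package's :class:`Frame`/:class:`Trajectory` contract. Coordinates are
assumed pre-imaged/unwrapped — the analysis is single-molecule geometry and
periodic-boundary handling is the producer's job; box records in input are
ignored with a logged warning.

Time metadata is in nanoseconds throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Frame",
    "Trajectory",
    "TrajectoryFormatError",
    "read_trajectory",
    "write_trajectory",
    "write_series_table",
    "read_series_table",
]


class TrajectoryFormatError(ValueError):
    """Raised for malformed or internally inconsistent coordinate files."""


@dataclass
class Frame:
    """A single conformation: per-atom coordinates (Å) plus labelling."""

    coords: np.ndarray
    atom_names: list[str]
    resids: np.ndarray
    resnames: list[str]
    time: float | None = None  # ns

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.resids = np.asarray(self.resids, dtype=np.intp)
        n = len(self.atom_names)
        if self.coords.shape != (n, 3) or len(self.resids) != n or len(self.resnames) != n:
            raise ValueError("Frame: atom_names/resids/resnames/coords lengths differ")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("Frame: non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def residue_labels(self) -> list[str]:
        return [f"{rn}{ri + 1}" for rn, ri in zip(self.resnames, self.resids)]


@dataclass
class Trajectory:
    """Time-ordered conformations with identical atom ordering.

    ``coords`` is a (n_frames, n_atoms, 3) array in Å; ``timestep`` is the
    inter-frame interval in ns.
    """

    coords: np.ndarray
    atom_names: list[str]
    resids: np.ndarray
    resnames: list[str]
    timestep: float = 1.0
    topology: object | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.resids = np.asarray(self.resids, dtype=np.intp)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("Trajectory: coords must be (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atom_names):
            raise ValueError("Trajectory: coords second axis must match atom count")
        if not self.timestep > 0:
            raise ValueError("Trajectory: timestep must be > 0")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.timestep

    def frame(self, i: int) -> Frame:
        return Frame(
            coords=self.coords[i],
            atom_names=self.atom_names,
            resids=self.resids,
            resnames=self.resnames,
            time=float(i * self.timestep),
        )

    def frames(self):
        for i in range(self.n_frames):
            yield self.frame(i)


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
        if f not in ("pdb", "xyz"):
            raise ValueError(f"unknown trajectory format {fmt!r} (use 'pdb' or 'xyz')")
        return f
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("pdb", "xyz"):
        return suffix
    raise ValueError(f"cannot infer trajectory format from {path!r}")


def _validate_pdb_models(path):
    counts, n, in_model, model_i = [], 0, False, 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model, n = True, 0
            elif rec == "ENDMDL":
                counts.append(n)
                in_model = False
                model_i += 1
            elif rec in ("ATOM", "HETATM"):
                n += 1
            elif rec == "CRYST1":
                log.warning("%s: box record (CRYST1) present; ignored", path)
    if in_model:
        counts.append(n)
    if not counts:  # single-model file without MODEL records
        return
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise TrajectoryFormatError(
            f"{path}: inconsistent atom count in MODEL {bad + 1} "
            f"({counts[bad]} vs {counts[0]})"
        )


def _validate_xyz_frames(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, counts, frame = 0, [], 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"{path}: frame {frame}: expected atom count, got {lines[i]!r}"
            ) from exc
        body = lines[i + 2 : i + 2 + n]
        short = [ln for ln in body if len(ln.split()) < 4]
        if len(body) < n or short:
            raise TrajectoryFormatError(
                f"{path}: frame {frame}: expected {n} atom lines"
            )
        counts.append(n)
        i += 2 + n
        frame += 1
    if counts and len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise TrajectoryFormatError(
            f"{path}: inconsistent atom count in frame {bad} "
            f"({counts[bad]} vs {counts[0]})"
        )


def read_trajectory(path, fmt: str | None = None, timestep: float = 1.0,
                    topology=None) -> Trajectory:
    """Read a multi-model PDB or multi-frame XYZ file into a Trajectory."""
    import MDAnalysis as mda

    f = _infer_format(path, fmt)
    if f == "pdb":
        _validate_pdb_models(path)
    else:
        _validate_xyz_frames(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        coords = np.stack([u.atoms.positions.copy() for _ in u.trajectory]).astype(float)
        names = [str(n) for n in u.atoms.names]
        try:
            resids = u.atoms.resindices.astype(np.intp)
            resnames = [str(r) for r in u.atoms.resnames]
        except Exception:
            resids = np.zeros(len(names), dtype=np.intp)
            resnames = ["UNK"] * len(names)
    return Trajectory(
        coords=coords,
        atom_names=names,
        resids=resids,
        resnames=resnames,
        timestep=timestep,
        topology=topology,
    )


def _guess_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def write_trajectory(traj: Trajectory, path, fmt: str | None = None):
    """Write a Trajectory as multi-model PDB or multi-frame XYZ."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    if traj.n_frames == 0:
        raise ValueError("refusing to write a 0-frame trajectory")
    f = _infer_format(path, fmt)
    n_res = int(traj.resids.max()) + 1
    resnames_per_res = [None] * n_res
    for rn, ri in zip(traj.resnames, traj.resids):
        resnames_per_res[ri] = rn
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            traj.n_atoms,
            n_residues=n_res,
            atom_resindex=traj.resids,
            residue_segindex=np.zeros(n_res, dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", traj.atom_names)
        u.add_TopologyAttr("resnames", resnames_per_res)
        u.add_TopologyAttr("resids", np.arange(n_res) + 1)
        if f == "pdb":
            # XYZ keeps full atom names; PDB element columns want symbols
            u.add_TopologyAttr(
                "elements", [_guess_element(n) for n in traj.atom_names]
            )
        u.load_new(traj.coords.astype(np.float32), format=MemoryReader)
        with mda.Writer(str(path), n_atoms=traj.n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
    return Path(path)


def write_series_table(matrix, labels, path):
    """Write a per-frame (or per-step) series matrix as CSV.

    Header row carries the column labels; decimal point is always ``.``
    regardless of locale (pandas C writer).
    """
    arr = np.asarray(matrix, dtype=object)
    if arr.ndim == 1 and len(arr) and isinstance(arr[0], (list, np.ndarray)):
        raise ValueError("ragged series matrix")
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        arr = arr.reshape(0, len(labels)) if arr.size == 0 else arr
    if arr.ndim != 2 or (arr.size and arr.shape[1] != len(labels)):
        raise ValueError(
            f"labels length {len(labels)} does not match column count"
        )
    df = pd.DataFrame(arr, columns=list(labels))
    df.to_csv(path, index=False)
    return Path(path)


def read_series_table(path):
    """Read a series CSV back into (matrix, labels)."""
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float), list(df.columns)
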