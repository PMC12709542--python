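"""Cosine-series torsion-coefficient fitting.

The force-field parameterization step: given a target torsional profile
(a QM profile minus the force field's own non-bonded contribution, both
computed externally), fit the truncated Fourier form used by GAFF-style
force fields,

    E(phi) = offset + sum_{n=1..n_max} c_n cos(n phi),

by ordinary linear least squares. A negative coefficient is reported in
force-field convention as a positive barrier V_n with a 180-degree phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TorsionProfile", "TorsionParams", "fit_torsion",
           "read_profile", "write_params"]


@dataclass
class TorsionProfile:
    """Target torsion energies on an angle grid (degrees, kcal/mol)."""

    angles: np.ndarray
    target_energy: np.ndarray

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.target_energy = np.asarray(self.target_energy, dtype=float)
        if self.angles.shape != self.target_energy.shape or self.angles.ndim != 1:
            raise ValueError("angles and target_energy must be matching 1-D arrays")
        if len(np.unique(np.round(self.angles, 9))) != len(self.angles):
            raise ValueError("torsion profile angles must be unique")


@dataclass
class TorsionParams:
    """Fitted amplitudes V_n (kcal/mol) with phases in {0, 180} degrees."""

    amplitudes: np.ndarray   # V_n >= 0 for n = 1..n_max
    phases: np.ndarray       # 0 or 180 degrees per n
    offset: float
    rss: float
    signed: np.ndarray = field(repr=False, default=None)  # raw c_n

    @property
    def n_max(self) -> int:
        return len(self.amplitudes)

    def predict(self, angles_deg) -> np.ndarray:
        phi = np.radians(np.asarray(angles_deg, dtype=float))
        n = np.arange(1, self.n_max + 1)
        return self.offset + np.cos(np.outer(phi, n)) @ self.signed

    def to_text(self) -> str:
        """Force-field-modification-style text block (one term per line)."""
        lines = ["# periodicity  barrier_kcal_mol  phase_deg"]
        for i, (v, ph) in enumerate(zip(self.amplitudes, self.phases), start=1):
            lines.append(f"{i:>2d}  {v: .6f}  {ph:6.1f}")
        lines.append(f"# offset {self.offset:.6f} kcal/mol, rss {self.rss:.3e}")
        return "\n".join(lines)


def fit_torsion(profile: TorsionProfile, n_max: int = 4) -> TorsionParams:
    """Linear least squares on the basis {1, cos(n phi), n = 1..n_max}.

    Raises on a rank-deficient grid (too few or degenerate angles for the
    requested number of periodicities).
    """
    if not 1 <= n_max <= 6:
        raise ValueError("n_max must be between 1 and 6")
    phi = np.radians(profile.angles)
    if len(phi) < n_max + 1:
        raise ValueError(
            f"profile has {len(phi)} points but the fit needs at least "
            f"{n_max + 1}; sample the torsion more densely"
        )
    design = np.column_stack(
        [np.ones_like(phi)] + [np.cos(n * phi) for n in range(1, n_max + 1)]
    )
    coeffs, _, rank, _ = np.linalg.lstsq(design, profile.target_energy, rcond=None)
    if rank < design.shape[1]:
        raise ValueError(
            "rank-deficient angle grid for the requested periodicities; "
            "sample the torsion more densely"
        )
    resid = design @ coeffs - profile.target_energy
    signed = coeffs[1:]
    return TorsionParams(
        amplitudes=np.abs(signed),
        phases=np.where(signed < 0, 180.0, 0.0),
        offset=float(coeffs[0]),
        rss=float(resid @ resid),
        signed=signed,
    )


def read_profile(path) -> TorsionProfile:
    """Read a 2-column delimited (angle_deg, energy) torsion profile."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (angle_deg, energy)")
    arr = df.to_numpy(dtype=float)
    return TorsionProfile(angles=arr[:, 0], target_energy=arr[:, 1])


def write_params(params: TorsionParams, path):
    with open(path, "w") as fh:
        fh.write(params.to_text() + "\n")
    return path
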