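"""Helix handedness-inversion kinetics: single-exponential CD-decay fitting.

A foldamer carrying one chiral unit equilibrates between P and M helical
diastereomers; after a solvent jump the CD signal re-equilibrates and its
time course follows a single exponential

    y(t) = y_inf + A * exp(-k t),        t_1/2 = ln 2 / k

with A of either sign (enrichment raises or lowers |CD| depending on the
jump direction). Instrumental lag — the time for the sample to reach the
measurement temperature — is handled by trimming points from the start of
the trace until the remainder is exponential; the automatic criterion is a
runs-style sign-randomness test on fit residuals, a reproducible surrogate
for the visual "until an exponential decay was observed" rule.

Times are minutes throughout; rate constants per minute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import norm

__all__ = [
    "KineticTrace",
    "DecayFit",
    "FitError",
    "read_trace",
    "write_trace",
    "trim_lag",
    "fit_decay",
    "half_life",
    "batch_halflives",
]

LN2 = math.log(2.0)


class FitError(RuntimeError):
    """Raised when the exponential fit fails or yields a non-decay."""


@dataclass
class KineticTrace:
    """A CD-vs-time trace (time in minutes, signal in instrument units)."""

    time: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise ValueError("time and signal must be matching 1-D arrays")
        if len(self.time) < 4:
            raise ValueError("a kinetic trace needs at least 4 points")
        if not np.all(np.isfinite(self.time)):
            raise ValueError("non-finite times")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self):
        return len(self.time)


@dataclass
class DecayFit:
    """Fitted single-exponential parameters; ``t_half * k == ln 2`` exactly."""

    y_inf: float
    amplitude: float
    k: float            # per minute
    t_half: float       # minutes
    rss: float
    n_used: int
    trim_start: float = 0.0  # minutes removed from the head of the trace


def read_trace(path) -> KineticTrace:
    """Read a 2-column delimited trace; ``# key=value`` lines are metadata."""
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    meta[key.strip()] = val.strip()
                continue
            rows.append(line.replace(",", " ").replace(";", " ").split())
    data = np.array(rows, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_min, signal)")
    return KineticTrace(time=data[:, 0], signal=data[:, 1], metadata=meta)


def write_trace(trace: KineticTrace, path):
    with open(path, "w") as fh:
        for key, val in trace.metadata.items():
            fh.write(f"# {key}={val}\n")
        for t, y in zip(trace.time, trace.signal):
            fh.write(f"{float(t)!r},{float(y)!r}\n")
    return path


def half_life(k: float) -> float:
    """t_1/2 = ln 2 / k (minutes) for a first-order rate constant k > 0."""
    if not k > 0:
        raise ValueError(f"rate constant must be > 0, got {k}")
    return LN2 / k


def _model(t, y_inf, a, k):
    return y_inf + a * np.exp(-k * t)


def _initial_guess(t, y):
    tail = max(3, len(y) // 10)
    y_inf = float(np.mean(y[-tail:]))
    a = float(y[0] - y_inf)
    resid = y - y_inf
    # log-linear slope on the portion with the sign of the initial amplitude
    usable = resid * np.sign(a if a != 0 else 1.0) > abs(a) * 1e-3
    if usable.sum() >= 2:
        slope = np.polyfit(t[usable], np.log(np.abs(resid[usable])), 1)[0]
        k0 = max(-slope, 1e-8)
    else:
        k0 = 1.0 / max(t[-1] - t[0], 1e-9)
    if a == 0.0:
        a = float(np.ptp(y)) or 1.0
    return y_inf, a, k0


def fit_decay(trace: KineticTrace) -> DecayFit:
    """Nonlinear least-squares fit of y(t) = y_inf + A exp(-k t).

    Initial guesses come from the endpoints (tail mean for y_inf, first
    point for A, log-linear regression for k). Raises :class:`FitError`
    on non-convergence, k <= 0, or a constant signal.
    """
    t = trace.time - trace.time[0]
    y = trace.signal
    if np.allclose(y, y[0]):
        raise FitError("constant signal: no decay to fit")
    p0 = _initial_guess(t, y)
    try:
        popt, _ = curve_fit(_model, t, y, p0=p0, maxfev=20000)
    except Exception as exc:  # noqa: BLE001 - carry diagnostics upward
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    y_inf, a, k = (float(p) for p in popt)
    if not np.isfinite(k) or k <= 0:
        raise FitError(f"fit returned non-decaying rate constant k={k:.4g}")
    rss = float(np.sum((_model(t, *popt) - y) ** 2))
    return DecayFit(
        y_inf=y_inf,
        amplitude=a,
        k=k,
        t_half=half_life(k),
        rss=rss,
        n_used=len(y),
    )


def _runs_test_p(signs: np.ndarray) -> float:
    """Wald-Wolfowitz runs test p-value for sign randomness."""
    signs = signs[signs != 0]
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    n = n1 + n2
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mu) / math.sqrt(var)
    return 2.0 * norm.sf(abs(z))


def _suffix(trace: KineticTrace, start_idx: int) -> KineticTrace:
    return KineticTrace(
        time=trace.time[start_idx:],
        signal=trace.signal[start_idx:],
        metadata=dict(trace.metadata),
    )


def trim_lag(trace: KineticTrace, method: str = "auto",
             fixed_time: float | None = None, alpha: float = 0.05):
    """Remove the pre-exponential instrument-lag head of a trace.

    ``auto`` tries suffixes starting at each of the first third of points
    and keeps the longest one whose fit residuals pass a runs-style
    sign-randomness check (numerically perfect fits pass outright). Returns
    ``(trimmed_trace, trim_start_minutes)``.
    """
    if method == "none":
        return trace, 0.0
    if method == "fixed_time":
        if fixed_time is None:
            raise ValueError("fixed_time trimming needs a time value")
        keep = trace.time >= trace.time[0] + fixed_time
        if keep.sum() < 4:
            raise ValueError("fewer than 4 points remain after trimming")
        start = int(np.argmax(keep))
        return _suffix(trace, start), float(trace.time[start] - trace.time[0])
    if method != "auto":
        raise ValueError(f"unknown trim method {method!r}")

    best = None
    for start in range(0, max(1, len(trace) // 3)):
        if len(trace) - start < 4:
            break
        sub = _suffix(trace, start)
        try:
            fit = fit_decay(sub)
        except FitError:
            continue
        scale = max(abs(fit.amplitude), float(np.ptp(sub.signal)), 1e-300)
        resid = sub.signal - _model(sub.time - sub.time[0], fit.y_inf,
                                    fit.amplitude, fit.k)
        if np.sqrt(fit.rss / len(sub)) < 1e-8 * scale:
            p = 1.0  # numerically exact fit
        else:
            p = _runs_test_p(np.sign(resid))
        if p > alpha:
            return sub, float(sub.time[0] - trace.time[0])
        if best is None or p > best[0]:
            best = (p, start)
    if best is None:
        raise FitError("no suffix of the trace admits an exponential fit")
    start = best[1]
    return _suffix(trace, start), float(trace.time[start] - trace.time[0])


def batch_halflives(traces, trim: str = "auto") -> pd.DataFrame:
    """Fit a collection of traces; one row per trace, failures flagged.

    Metadata keys of each trace become columns (compound, temperature, pH,
    salt, ...), alongside ``t_half``, ``k``, ``rss``, ``n_used``,
    ``trim_start`` and an ``ok`` flag.
    """
    rows = []
    for trace in traces:
        row = dict(trace.metadata)
        try:
            trimmed, start = trim_lag(trace, method=trim)
            fit = fit_decay(trimmed)
            row.update(
                t_half=fit.t_half, k=fit.k, rss=fit.rss,
                n_used=fit.n_used, trim_start=start, ok=True, error="",
            )
        except (FitError, ValueError) as exc:
            row.update(
                t_half=np.nan, k=np.nan, rss=np.nan, n_used=0,
                trim_start=np.nan, ok=False, error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)
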