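"""Mechanical performance: force integrals, muscle volume, specific force.

Force output of the electrically stimulated muscle is summarised as the
tension-time integral (TTI, N*s) of the baseline-corrected isometric force
trace.  Muscle size comes from serial axial MR images: per-slice
cross-sectional areas are turned into a volume by summing slice slabs plus
the inter-slice gaps (the slices are non-contiguous: 1 mm thick, spaced
0.5 mm).  Specific force is TTI normalised by that volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ForceTrace",
    "MuscleGeometry",
    "baseline_correct",
    "tension_time_integral",
    "muscle_volume",
    "specific_force",
    "read_force_csv",
    "read_csa_csv",
]


@dataclass(frozen=True)
class ForceTrace:
    """Sampled isometric force (N) on a strictly increasing time grid (s)."""

    t: np.ndarray
    force: np.ndarray
    stim_frequency_hz: float = 3.3
    pulse_width_ms: float = 1.0
    pulse_amplitude_ma: float = 7.0  # informational; 6-8 mA supramaximal

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("t and force must be 1-D arrays of equal length")
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "force", f)


@dataclass(frozen=True)
class MuscleGeometry:
    """Serial-slice muscle geometry: per-slice CSA (cm^2), slab and gap (cm)."""

    csa: np.ndarray
    slice_thickness: float = 0.1   # 1 mm
    gap: float = 0.05              # 0.5 mm spacing between slices
    gap_mode: str = "trapezoid"    # or "nearest" (half-slab extension)

    def __post_init__(self) -> None:
        csa = np.asarray(self.csa, dtype=float)
        if np.any(csa < 0):
            raise ValueError("cross-sectional areas must be >= 0")
        object.__setattr__(self, "csa", csa)


def baseline_correct(trace: ForceTrace, window_s: float = 1.0) -> ForceTrace:
    """Subtract passive tension (mean force over the first ``window_s`` s).

    Negative excursions after subtraction are clipped to zero.
    """
    sel = trace.t <= trace.t[0] + window_s
    base = float(np.mean(trace.force[sel]))
    return ForceTrace(trace.t, np.clip(trace.force - base, 0.0, None),
                      trace.stim_frequency_hz, trace.pulse_width_ms,
                      trace.pulse_amplitude_ma)


def tension_time_integral(trace: ForceTrace, window: tuple[float, float] | None = None) -> float:
    """Tension-time integral (N*s): trapezoid integral of force over a window.

    ``window`` defaults to the whole trace; its endpoints must lie within
    the sampled time range.  Additive over adjacent windows.
    """
    t, f = trace.t, trace.force
    if window is not None:
        t0, t1 = window
        if t1 <= t0:
            raise ValueError("empty integration window")
        if t0 < t[0] - 1e-12 or t1 > t[-1] + 1e-12:
            raise ValueError("window extends beyond the force trace")
        # interpolated endpoint samples keep the integral exactly additive
        inside = (t > t0) & (t < t1)
        tt = np.concatenate([[t0], t[inside], [t1]])
        ff = np.interp(tt, t, f)
        t, f = tt, ff
    return float(np.trapezoid(f, t))


def muscle_volume(geom: MuscleGeometry) -> float:
    """Muscle volume (cm^3) from serial non-contiguous slices.

    Sum of slice slabs (CSA x thickness) plus the inter-slice gap volumes.
    Gaps are filled by trapezoidal interpolation between adjacent CSAs
    (``gap_mode="trapezoid"``) or by extending each neighbouring slab half a
    gap (``"nearest"``); for a single gap between two slices the two rules
    integrate to the same mean-CSA volume, so the switch is kept for
    interface clarity.
    """
    csa = geom.csa
    if len(csa) < 2:
        raise ValueError("need >= 2 slices to form a volume")
    slabs = float(np.sum(csa) * geom.slice_thickness)
    pair_mean = 0.5 * (csa[:-1] + csa[1:])  # same for trapezoid and nearest
    if geom.gap_mode not in ("trapezoid", "nearest"):
        raise ValueError("gap_mode must be 'trapezoid' or 'nearest'")
    gaps = float(np.sum(pair_mean) * geom.gap)
    return slabs + gaps


def specific_force(tti: float, volume: float) -> float:
    """Force output normalised by muscle volume (N*s/cm^3)."""
    if volume <= 0:
        raise ZeroDivisionError("muscle volume must be > 0")
    return tti / volume


def read_force_csv(path, **kwargs) -> ForceTrace:
    """Read a force trace CSV with columns ``t_s, force_n``."""
    df = pd.read_csv(path)
    return ForceTrace(df["t_s"].to_numpy(), df["force_n"].to_numpy(), **kwargs)


def read_csa_csv(path, **kwargs) -> MuscleGeometry:
    """Read a per-slice CSA CSV with columns ``slice_index, csa_cm2``."""
    df = pd.read_csv(path).sort_values("slice_index")
    return MuscleGeometry(df["csa_cm2"].to_numpy(), **kwargs)
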