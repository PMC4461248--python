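"""Absolute quantification of dynamic in vivo 31P-MRS data.

Converts fitted peak areas and Pi-PCr chemical shifts into absolute,
saturation-corrected metabolite concentrations, intracellular pH and free
cytosolic ADP, on the acquisition time base of a gated
rest / electrostimulation / recovery protocol.

The processing chain is:

1. :func:`bin_midpoints` — place each summed FID packet at the midpoint of
   its acquisition interval, on a single clock starting at the onset of the
   saturated acquisition.
2. :func:`absolute_concentrations` — correct each metabolite for magnetic
   saturation against a fully relaxed rest spectrum, then anchor all areas
   to a resting beta-ATP concentration measured biochemically.
3. :func:`ph_from_shift` — intracellular pH from the Pi chemical shift
   relative to PCr (Henderson–Hasselbalch titration of the Pi resonance).
4. :func:`adp_from_ck` — free ADP from the creatine-kinase equilibrium.

Series are plain pandas DataFrames with the column schema documented in
:data:`PHOS_COLUMNS`; parameter bundles are small frozen dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionProtocol",
    "PhCalibration",
    "CKParams",
    "PHOS_COLUMNS",
    "PEAK_COLUMNS",
    "bin_midpoints",
    "bin_durations",
    "bin_phases",
    "absolute_concentrations",
    "ph_from_shift",
    "shift_from_ph",
    "adp_from_ck",
    "calibrate_tcr",
    "build_series",
    "ProtocolError",
    "read_peak_table",
    "write_series",
    "read_series",
]

#: Column schema of a metabolite time series ("PhosTimeSeries").
PHOS_COLUMNS = ("t_s", "phase", "pcr", "pi", "atp", "adp", "ph")

#: Column schema of a fitted peak table (one row per acquisition bin).
PEAK_COLUMNS = (
    "bin_index", "phase", "pme", "pi", "pcr",
    "atp_gamma", "atp_alpha", "atp_beta", "pi_shift_ppm",
)

#: Metabolite area columns that undergo saturation correction and anchoring.
_AREA_COLUMNS = ("pme", "pi", "pcr", "atp_gamma", "atp_alpha", "atp_beta")

PHASES = ("rest", "stim", "recovery")


class ProtocolError(ValueError):
    """Raised when an acquisition protocol is internally inconsistent."""


class CalibrationError(ValueError):
    """Raised when a chemical shift falls outside the pH calibration range."""


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Gated 31P-MRS acquisition scheme for a rest/stimulation/recovery bout.

    Defaults describe the standard protocol: 768 saturated FIDs at a
    repetition time of 1.875 s — 64 at rest summed into one bin, 192 during
    6 min of electrostimulation summed by packets of 32 (~60 s temporal
    resolution), and 512 during recovery summed as 7x32, 3x64 and 1x96.
    A fully relaxed spectrum (20 s repetition time) is acquired at rest for
    saturation correction.

    Parameters
    ----------
    repetition_time_saturated : float
        Repetition time of the saturated FIDs, seconds.
    repetition_time_relaxed : float
        Repetition time of the fully relaxed rest spectrum, seconds.
    rest_packets, stim_packets, recovery_packets : tuple of int
        Number of FIDs summed into each bin, per phase, in acquisition
        order.
    """

    repetition_time_saturated: float = 1.875
    repetition_time_relaxed: float = 20.0
    rest_packets: tuple[int, ...] = (64,)
    stim_packets: tuple[int, ...] = (32,) * 6
    recovery_packets: tuple[int, ...] = ((32,) * 7 + (64,) * 3 + (96,))

    def __post_init__(self) -> None:
        for name in ("rest_packets", "stim_packets", "recovery_packets"):
            packets = getattr(self, name)
            if len(packets) == 0 or any(int(c) <= 0 for c in packets):
                raise ProtocolError(f"{name} must be non-empty positive counts")
        if self.repetition_time_saturated <= 0:
            raise ProtocolError("repetition_time_saturated must be > 0")

    @property
    def packets(self) -> tuple[int, ...]:
        return self.rest_packets + self.stim_packets + self.recovery_packets

    @property
    def n_bins(self) -> int:
        return len(self.packets)

    @property
    def total_fids(self) -> int:
        return int(sum(self.packets))

    def phase_of_bin(self) -> np.ndarray:
        """Phase label of each bin, in acquisition order."""
        return np.asarray(
            ["rest"] * len(self.rest_packets)
            + ["stim"] * len(self.stim_packets)
            + ["recovery"] * len(self.recovery_packets)
        )

    def phase_onset(self, phase: str) -> float:
        """Clock time (s) at which *phase* begins.

        The clock starts at the onset of the saturated acquisition (start of
        the rest bin); stimulation starts when the rest FIDs end.
        """
        tr = self.repetition_time_saturated
        if phase == "rest":
            return 0.0
        if phase == "stim":
            return sum(self.rest_packets) * tr
        if phase == "recovery":
            return (sum(self.rest_packets) + sum(self.stim_packets)) * tr
        raise ValueError(f"unknown phase {phase!r}")

    def phase_duration(self, phase: str) -> float:
        tr = self.repetition_time_saturated
        packets = {
            "rest": self.rest_packets,
            "stim": self.stim_packets,
            "recovery": self.recovery_packets,
        }[phase]
        return sum(packets) * tr

    def validate_totals(self, rest: int = 64, stim: int = 192,
                        recovery: int = 512) -> None:
        """Check packet sums against declared per-phase FID totals."""
        got = (sum(self.rest_packets), sum(self.stim_packets),
               sum(self.recovery_packets))
        if got != (rest, stim, recovery):
            raise ProtocolError(
                f"packet counts sum to {got}, expected {(rest, stim, recovery)}"
            )


def bin_durations(protocol: AcquisitionProtocol) -> np.ndarray:
    """Duration of each acquisition bin in seconds."""
    return np.asarray(protocol.packets, dtype=float) * protocol.repetition_time_saturated


def bin_midpoints(protocol: AcquisitionProtocol) -> np.ndarray:
    """Midpoint time (s) of every acquisition bin on the common clock.

    Each metabolite/pH value is assigned to the midpoint of the interval
    over which its FIDs were summed.  With the default protocol the first
    stimulation bin spans 60 s, so its value sits 30 s after stimulation
    onset.
    """
    durations = bin_durations(protocol)
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    return edges[:-1] + durations / 2.0


def bin_phases(protocol: AcquisitionProtocol) -> np.ndarray:
    return protocol.phase_of_bin()


@dataclass(frozen=True)
class PhCalibration:
    """Pi titration calibration: pH = pk + log10((d - da)/(db - d)).

    The acid/base endpoint shifts (ppm, relative to PCr) and pK default to
    the conventional phosphate titration constants for skeletal muscle.
    """

    pk: float = 6.75
    delta_acid: float = 3.27
    delta_base: float = 5.69

    def __post_init__(self) -> None:
        if not self.delta_acid < self.delta_base:
            raise ValueError("delta_acid must be < delta_base")


@dataclass(frozen=True)
class CKParams:
    """Creatine-kinase equilibrium parameters.

    ``k_ck`` is the apparent CK equilibrium constant (1/M).  ``tcr`` is the
    total creatine pool (PCr + free Cr, umol/g wet wt); if ``None`` it must
    be supplied or calibrated (:func:`calibrate_tcr`) before ADP can be
    computed.  ``density_factor`` converts per-gram-wet-weight contents to
    cytosolic molarities ((g wet wt)/(mL cell water)); the default of 1
    treats umol/g as numerically equal to mM (hence nmol/g == uM), making
    the convention explicit and adjustable.
    """

    k_ck: float = 1.67e9
    tcr: float | None = None
    density_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.k_ck <= 0:
            raise ValueError("k_ck must be > 0")
        if self.density_factor <= 0:
            raise ValueError("density_factor must be > 0")

    def with_tcr(self, tcr: float) -> "CKParams":
        return replace(self, tcr=tcr)


def ph_from_shift(pi_shift, cal: PhCalibration = PhCalibration()):
    """Intracellular pH from the Pi chemical shift relative to PCr (ppm).

    Henderson–Hasselbalch form of the HPO4^2-/H2PO4^- titration:
    ``pH = pk + log10((d - delta_acid) / (delta_base - d))``.
    Strictly increasing in the shift; defined only on the open interval
    (delta_acid, delta_base).
    """
    d = np.asarray(pi_shift, dtype=float)
    if np.any(d <= cal.delta_acid):
        raise CalibrationError(
            f"pi shift <= acid endpoint {cal.delta_acid} ppm: pH undefined"
        )
    if np.any(d >= cal.delta_base):
        raise CalibrationError(
            f"pi shift >= base endpoint {cal.delta_base} ppm: pH undefined"
        )
    ph = cal.pk + np.log10((d - cal.delta_acid) / (cal.delta_base - d))
    return float(ph) if np.isscalar(pi_shift) else ph


def shift_from_ph(ph, cal: PhCalibration = PhCalibration()):
    """Inverse of :func:`ph_from_shift`: Pi-PCr shift (ppm) at a given pH."""
    p = np.asarray(ph, dtype=float)
    r = np.power(10.0, p - cal.pk)
    d = (cal.delta_acid + cal.delta_base * r) / (1.0 + r)
    return float(d) if np.isscalar(ph) else d


def adp_from_ck(pcr, atp, ph, ck: CKParams):
    """Free cytosolic ADP (nmol/g) from the creatine-kinase equilibrium.

    CK reaction: PCr + ADP + H+ <-> ATP + Cr, with equilibrium constant
    ``K = [ATP][Cr] / ([PCr][ADP][H+])`` so

        [ADP] = [ATP][Cr] / ([PCr] * K * [H+]),   [Cr] = tcr - [PCr].

    ``pcr`` and ``atp`` are umol/g wet wt; contents enter the equilibrium as
    molarities through ``ck.density_factor`` (1 by default, i.e. umol/g ~ mM).
    Returns nmol/g.
    """
    if ck.tcr is None:
        raise ValueError("CKParams.tcr is unset; supply or calibrate it first")
    pcr_a = np.asarray(pcr, dtype=float)
    atp_a = np.asarray(atp, dtype=float)
    ph_a = np.asarray(ph, dtype=float)
    if np.any(pcr_a <= 0):
        raise ZeroDivisionError("pcr must be > 0 for the CK equilibrium")
    cr = ck.tcr - pcr_a
    if np.any(cr < 0):
        raise ValueError("tcr <= pcr: nonpositive free creatine")
    # ATP/PCr is unitless and K*[H+] is dimensionless, so density_factor
    # cancels inside the equilibrium; it only matters when the nmol/g result
    # is read as a uM molarity (e.g. against Km downstream).
    h = np.power(10.0, -ph_a)
    adp = atp_a * cr / (pcr_a * ck.k_ck * h) * 1e3
    if all(np.isscalar(x) for x in (pcr, atp, ph)):
        return float(adp)
    return adp


def calibrate_tcr(pcr_rest: float, atp_rest: float, ph_rest: float,
                  adp_rest: float, ck_k: float = 1.67e9,
                  density_factor: float = 1.0) -> float:
    """Total creatine pool (umol/g) that reproduces a resting ADP.

    Algebraic inversion of the CK equilibrium at rest: given resting PCr,
    ATP (umol/g), pH and free ADP (nmol/g), the unique tcr is

        tcr = pcr_rest + adp_rest * pcr_rest * K * [H+] / atp_rest.
    """
    if min(pcr_rest, atp_rest, ph_rest) <= 0 or adp_rest < 0:
        raise ValueError("all calibration inputs must be positive (adp >= 0)")
    h = 10.0 ** (-ph_rest)
    cr = (adp_rest * 1e-3) * pcr_rest * ck_k * h / atp_rest
    return pcr_rest + cr


def default_tcr(pcr_rest: float, pcr_fraction: float = 0.85) -> float:
    """Fallback total creatine pool when no resting ADP is available.

    Assumes resting PCr is a fixed fraction (default 85%) of the total
    creatine pool, a typical value for resting skeletal muscle.
    """
    if not 0 < pcr_fraction < 1:
        raise ValueError("pcr_fraction must lie in (0, 1)")
    return pcr_rest / pcr_fraction


def _rest_mean(peaks: pd.DataFrame, column: str) -> float:
    rest = peaks.loc[peaks["phase"] == "rest", column]
    if rest.empty:
        raise ValueError("peak table has no rest bins")
    return float(rest.mean())


def absolute_concentrations(
    peaks: pd.DataFrame,
    relaxed: pd.DataFrame,
    atp_ref: float,
    protocol: AcquisitionProtocol = AcquisitionProtocol(),
) -> pd.DataFrame:
    """Saturation-corrected absolute concentrations on the bin time base.

    Each metabolite's saturation factor is the ratio of its fully relaxed
    area to its saturated rest-bin area; factors are computed once at rest
    and applied to every bin (saturation depends on T1 and repetition time,
    not on phase).  Corrected areas are then anchored linearly so that the
    resting beta-ATP equals ``atp_ref`` (umol/g, from a biochemical assay);
    the anchoring is scale-invariant in the raw areas.

    Returns a series DataFrame with columns ``t_s, phase, pcr, pi, atp``
    (``atp`` is the beta-ATP resonance, the standard single-phosphate ATP
    reporter); ``adp`` and ``ph`` are left for downstream steps.
    """
    if atp_ref <= 0:
        raise ValueError("atp_ref must be > 0")
    if len(peaks) != protocol.n_bins:
        raise ProtocolError(
            f"peak table has {len(peaks)} rows, protocol defines {protocol.n_bins} bins"
        )
    factors = {}
    for col in _AREA_COLUMNS:
        sat_rest = _rest_mean(peaks, col)
        rel_rest = float(relaxed[col].mean())
        if sat_rest == 0.0:
            if rel_rest == 0.0:
                factors[col] = 1.0  # absent resonance: nothing to correct
                continue
            raise ZeroDivisionError(
                f"zero saturated rest area for {col}: saturation factor undefined"
            )
        factors[col] = rel_rest / sat_rest

    corrected = peaks.copy()
    for col in _AREA_COLUMNS:
        corrected[col] = peaks[col].to_numpy(dtype=float) * factors[col]

    beta_rest = _rest_mean(corrected, "atp_beta")
    if beta_rest == 0.0:
        raise ZeroDivisionError("resting beta-ATP area is zero: cannot anchor")
    scale = atp_ref / beta_rest

    out = pd.DataFrame(
        {
            "t_s": bin_midpoints(protocol),
            "phase": bin_phases(protocol),
            "pcr": corrected["pcr"].to_numpy(dtype=float) * scale,
            "pi": corrected["pi"].to_numpy(dtype=float) * scale,
            "atp": corrected["atp_beta"].to_numpy(dtype=float) * scale,
        }
    )
    return out


def build_series(
    peaks: pd.DataFrame,
    relaxed: pd.DataFrame,
    atp_ref: float,
    protocol: AcquisitionProtocol = AcquisitionProtocol(),
    cal: PhCalibration = PhCalibration(),
    ck: CKParams = CKParams(),
    adp_rest: float | None = None,
) -> tuple[pd.DataFrame, CKParams]:
    """Full quantification: peak table -> concentration/pH/ADP series.

    If ``ck.tcr`` is unset it is calibrated against ``adp_rest`` (nmol/g)
    when given, else falls back to :func:`default_tcr`.  Returns the series
    (all :data:`PHOS_COLUMNS`) and the CKParams actually used.
    """
    series = absolute_concentrations(peaks, relaxed, atp_ref, protocol)
    series["ph"] = ph_from_shift(peaks["pi_shift_ppm"].to_numpy(dtype=float), cal)
    if ck.tcr is None:
        rest = series["phase"] == "rest"
        pcr_rest = float(series.loc[rest, "pcr"].mean())
        if adp_rest is not None:
            atp_rest = float(series.loc[rest, "atp"].mean())
            ph_rest = float(series.loc[rest, "ph"].mean())
            ck = ck.with_tcr(
                calibrate_tcr(pcr_rest, atp_rest, ph_rest, adp_rest,
                              ck.k_ck, ck.density_factor)
            )
        else:
            ck = ck.with_tcr(default_tcr(pcr_rest))
    series["adp"] = adp_from_ck(
        series["pcr"].to_numpy(), series["atp"].to_numpy(),
        series["ph"].to_numpy(), ck,
    )
    return series[list(PHOS_COLUMNS)], ck


# ---------------------------------------------------------------------------
# I/O

def read_peak_table(path) -> pd.DataFrame:
    """Read a fitted-peak CSV (one row per bin, :data:`PEAK_COLUMNS`)."""
    df = pd.read_csv(path)
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    return df.sort_values("bin_index").reset_index(drop=True)


def write_series(series: pd.DataFrame, path) -> None:
    series.to_csv(path, index=False)


def read_series(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHOS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"series missing columns: {sorted(missing)}")
    return df
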