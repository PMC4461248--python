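"""PCr time-course kinetics and oxidative ATP flux.

Fits the mono-exponential PCr depletion at stimulation onset and the
mono-exponential PCr resynthesis during post-stimulation recovery, and
derives from them:

* ``D(t)``     — ATP production by net PCr breakdown through the creatine
  kinase reaction, ``D = -dPCr/dt``;
* ``Q(t)``     — oxidative ATP synthesis under hyperbolic ADP control,
  ``Q = Qmax / (1 + Km/[ADP])``;
* ``Qmax``     — maximal oxidative capacity from the initial PCr resynthesis
  rate and end-of-stimulation ADP, ``Qmax = VPCr_rec * (1 + Km/[ADP]_end)``.

All rate constants are per minute; series time is in seconds and re-zeroed
at the relevant phase onset before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Model

__all__ = [
    "RecoveryFit",
    "OnsetFit",
    "OxParams",
    "FitError",
    "DegenerateSeriesError",
    "fit_recovery",
    "fit_onset",
    "ck_flux",
    "ck_flux_finite_difference",
    "ox_flux",
    "compute_qmax",
    "pcr_consumption_pct",
    "adp_end_of_stim",
]

K_BOUNDS = (1e-6, 20.0)  # 1/min; physiological PCr kinetics live well inside


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or produced unusable estimates."""


class DegenerateSeriesError(FitError):
    """The series carries no exponential signal (e.g. constant PCr)."""


@dataclass(frozen=True)
class RecoveryFit:
    """Mono-exponential recovery [PCr](t) = pcr_rest - pcr_cons * exp(-k t).

    ``k_rec`` (1/min) is the pseudo-first-order resynthesis rate constant,
    ``pcr_cons`` the PCr consumed at end of stimulation (umol/g), and
    ``vpcr_rec = k_rec * pcr_cons`` the initial resynthesis rate
    (umol/g/min).  Standard errors are from the fit covariance; the one for
    ``vpcr_rec`` is first-order propagated ignoring parameter correlation.
    """

    k_rec: float
    pcr_rest: float
    pcr_cons: float
    k_rec_se: float
    pcr_rest_se: float
    pcr_cons_se: float
    residuals: np.ndarray

    @property
    def vpcr_rec(self) -> float:
        return self.k_rec * self.pcr_cons

    @property
    def vpcr_rec_se(self) -> float:
        return float(np.hypot(self.pcr_cons * self.k_rec_se,
                              self.k_rec * self.pcr_cons_se))

    def predict(self, t_min) -> np.ndarray:
        """PCr (umol/g) at time t (minutes after recovery onset)."""
        return self.pcr_rest - self.pcr_cons * np.exp(-self.k_rec * np.asarray(t_min, float))


@dataclass(frozen=True)
class OnsetFit:
    """Mono-exponential depletion [PCr](t) = pcr_ss + (pcr_rest - pcr_ss) e^(-k t).

    ``vpcr_stim = k_stim * (pcr_rest - pcr_ss)`` is the initial breakdown
    rate at stimulation onset.  ``nonphysical`` flags a fitted amplitude of
    the wrong sign (PCr rising during stimulation).
    """

    k_stim: float
    pcr_rest: float
    pcr_ss: float
    k_stim_se: float
    pcr_rest_se: float
    pcr_ss_se: float
    residuals: np.ndarray
    nonphysical: bool = False

    @property
    def amplitude(self) -> float:
        return self.pcr_rest - self.pcr_ss

    @property
    def vpcr_stim(self) -> float:
        return self.k_stim * self.amplitude

    def predict(self, t_min) -> np.ndarray:
        return self.pcr_ss + self.amplitude * np.exp(-self.k_stim * np.asarray(t_min, float))

    def dpcr_dt(self, t_min) -> np.ndarray:
        """Analytic -D(t): signed dPCr/dt (umol/g/min) during stimulation."""
        return -self.k_stim * self.amplitude * np.exp(-self.k_stim * np.asarray(t_min, float))


@dataclass(frozen=True)
class OxParams:
    """Hyperbolic ADP control of oxidative ATP synthesis."""

    qmax: float
    km: float = 50.0  # uM, rat gastrocnemius

    def __post_init__(self) -> None:
        if self.qmax <= 0 or self.km <= 0:
            raise ValueError("qmax and km must be > 0")


def _phase_time(series: pd.DataFrame, phase: str, min_bins: int):
    sel = series[series["phase"] == phase]
    if len(sel) < min_bins:
        raise ValueError(f"need >= {min_bins} {phase} bins, got {len(sel)}")
    t_s = sel["t_s"].to_numpy(dtype=float)
    onset = _phase_onset_s(series, phase)
    return (t_s - onset) / 60.0, sel["pcr"].to_numpy(dtype=float), sel


def _phase_onset_s(series: pd.DataFrame, phase: str) -> float:
    """Phase onset on the series clock, from bin midpoints.

    Bins are contiguous from t = 0, so edges follow from midpoints by the
    recursion edge[i+1] = 2*mid[i] - edge[i]; the onset is the leading edge
    of the phase's first bin.  Exact even when adjacent bins differ in
    duration (e.g. a 120 s rest bin followed by 60 s stimulation bins).
    """
    phases = series["phase"].to_numpy()
    t = series["t_s"].to_numpy(dtype=float)
    first = int(np.flatnonzero(phases == phase)[0])
    edge = 0.0
    for i in range(first):
        edge = 2.0 * t[i] - edge
    return edge


def _exp_recovery(t, pcr_rest, pcr_cons, k):
    return pcr_rest - pcr_cons * np.exp(-k * t)


def _exp_onset(t, pcr_ss, amplitude, k):
    return pcr_ss + amplitude * np.exp(-k * t)


def fit_recovery(series: pd.DataFrame) -> RecoveryFit:
    """Fit the post-stimulation PCr resynthesis time course.

    Nonlinear least squares of ``pcr_rest - pcr_cons * exp(-k t)`` with t in
    minutes after recovery onset.  Initialisation: pcr_rest from the rest
    bins (last bin if none), pcr_cons from the phase range, k = 1/min;
    k bounded in (0, 20].  Deterministic (no random restarts).
    """
    t_min, pcr, _ = _phase_time(series, "recovery", 4)
    rest = series.loc[series["phase"] == "rest", "pcr"]
    rest0 = float(rest.mean()) if len(rest) else float(pcr[-1])
    span = float(pcr.max() - pcr.min())
    if span <= 0 or np.ptp(pcr) < 1e-12 * max(1.0, abs(pcr[0])):
        raise DegenerateSeriesError("constant PCr series: no recovery signal")

    model = Model(_exp_recovery)
    params = model.make_params(
        pcr_rest={"value": rest0},
        pcr_cons={"value": max(span, 1e-6), "min": 0.0},
        k={"value": 1.0, "min": K_BOUNDS[0], "max": K_BOUNDS[1]},
    )
    result = _run_fit(model, pcr, params, t_min, "recovery")
    p = result.params
    if p["pcr_cons"].value <= 0:
        raise DegenerateSeriesError("fitted pcr_cons <= 0: degenerate recovery")
    return RecoveryFit(
        k_rec=p["k"].value,
        pcr_rest=p["pcr_rest"].value,
        pcr_cons=p["pcr_cons"].value,
        k_rec_se=_se(p["k"]),
        pcr_rest_se=_se(p["pcr_rest"]),
        pcr_cons_se=_se(p["pcr_cons"]),
        residuals=np.asarray(result.residual, dtype=float),
    )


def fit_onset(series: pd.DataFrame) -> OnsetFit:
    """Fit the PCr depletion at the start of the stimulation period.

    Mono-exponential decline toward the stimulation steady state; the rest
    bins pin the pre-stimulation level through the fitted curve's t=0 value.
    A rising-PCr series yields a negative amplitude: the fit is returned
    with ``nonphysical=True`` rather than raising.
    """
    t_min, pcr, _ = _phase_time(series, "stim", 4)
    rest = series.loc[series["phase"] == "rest", "pcr"]
    rest0 = float(rest.mean()) if len(rest) else float(pcr[0])
    if np.ptp(pcr) < 1e-12 * max(1.0, abs(pcr[0])):
        raise DegenerateSeriesError("constant PCr series: no onset signal")

    model = Model(_exp_onset)
    params = model.make_params(
        pcr_ss={"value": float(pcr[-1])},
        amplitude={"value": rest0 - float(pcr[-1])},
        k={"value": 2.0, "min": K_BOUNDS[0], "max": K_BOUNDS[1]},
    )
    result = _run_fit(model, pcr, params, t_min, "onset")
    p = result.params
    amp = p["amplitude"].value
    nonphysical = amp <= 0
    if nonphysical:
        warnings.warn("PCr rises during stimulation: onset fit amplitude <= 0",
                      RuntimeWarning, stacklevel=2)
    return OnsetFit(
        k_stim=p["k"].value,
        pcr_rest=p["pcr_ss"].value + amp,
        pcr_ss=p["pcr_ss"].value,
        k_stim_se=_se(p["k"]),
        pcr_rest_se=float(np.hypot(_se(p["pcr_ss"]), _se(p["amplitude"]))),
        pcr_ss_se=_se(p["pcr_ss"]),
        residuals=np.asarray(result.residual, dtype=float),
        nonphysical=nonphysical,
    )


def _run_fit(model, y, params, t_min, label):
    """Levenberg-Marquardt at tight tolerance, retrying at the solver's
    defaults when the tight request is below what the data support."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(y, params, t=t_min, method="leastsq",
                           fit_kws={"xtol": 1e-10, "ftol": 1e-10})
        if not result.success:
            result = model.fit(y, params, t=t_min, method="leastsq")
    if not result.success:
        raise FitError(f"{label} fit did not converge: {result.message}")
    return result


def _se(param) -> float:
    return float(param.stderr) if param.stderr is not None else float("nan")


def ck_flux(onset: OnsetFit, t_min) -> np.ndarray:
    """CK-mediated ATP production D(t) = -dPCr/dt (umol/g/min).

    Evaluated from the analytic derivative of the onset fit; positive while
    PCr falls, tending to zero at the stimulation steady state.
    """
    d = -onset.dpcr_dt(t_min)
    return d if np.ndim(t_min) else float(d)


def ck_flux_finite_difference(series: pd.DataFrame) -> pd.DataFrame:
    """D(t) by centred finite differences on the stimulation bins.

    One-sided stencils at the phase edges.  Noisier than the analytic
    derivative at coarse binning; retained for sensitivity analysis.
    """
    sel = series[series["phase"] == "stim"]
    t_min = sel["t_s"].to_numpy(dtype=float) / 60.0
    pcr = sel["pcr"].to_numpy(dtype=float)
    d = -np.gradient(pcr, t_min)
    return pd.DataFrame({"t_s": sel["t_s"].to_numpy(), "d_ck": d})


def ox_flux(adp, ox: OxParams):
    """Oxidative ATP synthesis Q = Qmax / (1 + Km/[ADP]) (umol/g/min).

    ``adp`` in uM (nmol/g with a unit density factor).  Hyperbolic in ADP:
    zero at zero ADP, half-maximal at Km, saturating at Qmax.
    """
    adp_a = np.asarray(adp, dtype=float)
    if np.any(adp_a < 0):
        raise ValueError("adp must be >= 0")
    with np.errstate(divide="ignore"):
        q = np.where(adp_a > 0, ox.qmax / (1.0 + ox.km / adp_a), 0.0)
    return float(q) if np.isscalar(adp) else q


def compute_qmax(vpcr_rec: float, adp_end: float, km: float = 50.0) -> float:
    """Maximal oxidative capacity Qmax = VPCr_rec * (1 + Km/[ADP]_end).

    ``vpcr_rec`` in umol/g/min, ``adp_end`` (end-of-stimulation free ADP)
    and ``km`` in uM.
    """
    if adp_end == 0:
        raise ZeroDivisionError("adp_end must be nonzero")
    if vpcr_rec <= 0 or adp_end < 0 or km <= 0:
        raise ValueError("inputs must be positive")
    return vpcr_rec * (1.0 + km / adp_end)


def pcr_consumption_pct(pcr_rest: float, pcr_end: float) -> float:
    """PCr consumed at end of stimulation, percent of the resting level."""
    if pcr_rest <= 0:
        raise ValueError("pcr_rest must be > 0")
    return 100.0 * (pcr_rest - pcr_end) / pcr_rest


def adp_end_of_stim(series: pd.DataFrame, density_factor: float = 1.0) -> float:
    """Free ADP (uM) in the final stimulation bin.

    The end-of-stimulation value is the last stimulation bin itself, not an
    average over the plateau.
    """
    stim = series[series["phase"] == "stim"]
    if stim.empty:
        raise ValueError("series has no stimulation bins")
    return float(stim["adp"].iloc[-1]) * density_factor
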