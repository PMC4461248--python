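"""Cytosolic proton balance and glycolytic ATP flux.

During stimulated contractions the intracellular pH trace reflects the sum
of proton loads and sinks: glycolytic proton production (H_Gly), protons
handled by the creatine-kinase reaction through Pi protonation (H_CK),
passive cytosolic buffering (H_beta), net membrane efflux (H_Efflux) and
protons coupled to oxidative ATP synthesis (H_Ox).  Because every term but
H_Gly is measurable from the 31P-MRS time courses, glycolytic proton
production — and through the 1.5 ATP/H+ coupling stoichiometry the
glycolytic ATP production rate L — falls out of the closure

    H_Gly = H_CK + H_beta + H_Efflux - H_Ox.

Sign convention: proton fluxes are positive as proton load into the
cytosol.  H_CK = phi * D is positive while PCr is consumed (protons of Pi
production) and negative during resynthesis; the buffering term is used in
rate form, H_beta = -beta_total * d(dpH)/dt, so that the closure balances
per-bin rates dimensionally (the level form -beta_total * dpH is available
for cumulative bookkeeping).

The efflux constant lambda (umol/g/min per pH unit) is estimated at the
start of recovery, where glycolysis is silent and pH recovers purely by
efflux against the proton loads of aerobic PCr resynthesis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import OnsetFit, OxParams, RecoveryFit, ck_flux, ox_flux

__all__ = [
    "BufferModel",
    "beta_pi",
    "beta_tissue",
    "beta_total",
    "proton_stoich",
    "phi_stoich",
    "m_stoich",
    "h_ck_flux",
    "lambda_from_recovery",
    "glycolytic_flux",
    "total_atp_and_cost",
    "LEDGER_COLUMNS",
]

#: Column schema of the per-bin proton ledger.
LEDGER_COLUMNS = ("t_s", "h_ck", "h_beta", "h_efflux", "h_ox",
                  "h_gly", "h_gly_raw", "l_gly", "d_ck", "q_ox")


@dataclass(frozen=True)
class BufferModel:
    """Cytosolic buffering and proton-stoichiometry constants.

    ``pk_pi`` — pK of the HPO4^2-/H2PO4^- couple used in the Pi buffering
    and phi stoichiometry.  ``tissue_slope``/``tissue_intercept`` — linear
    non-phosphate tissue buffer capacity, beta_tissue = slope*pH + intercept
    (Slykes; 16 at pH 7, 37 at pH 6 in murine gastrocnemius).  ``m_amp``,
    ``m_pk`` — protons per unit oxidative ATP synthesis,
    m = m_amp / (1 + 10^(m_pk - pH)).
    """

    pk_pi: float = 6.75
    tissue_slope: float = -21.0
    tissue_intercept: float = 163.0
    m_amp: float = 0.16
    m_pk: float = 6.1


def beta_pi(pi, ph, buf: BufferModel = BufferModel()):
    """Phosphate buffering capacity (Slykes).

    beta_Pi = 2.3 [Pi] / ((1 + 10^(pH-pK)) (1 + 10^(pK-pH))); maximal at
    pH = pK for fixed [Pi] and symmetric about it.
    """
    pi_a = np.asarray(pi, dtype=float)
    ph_a = np.asarray(ph, dtype=float)
    b = 2.3 * pi_a / ((1.0 + 10.0 ** (ph_a - buf.pk_pi))
                      * (1.0 + 10.0 ** (buf.pk_pi - ph_a)))
    return float(b) if (np.isscalar(pi) and np.isscalar(ph)) else b


def beta_tissue(ph, buf: BufferModel = BufferModel()):
    """Non-phosphate tissue buffering capacity (Slykes), linear in pH."""
    b = buf.tissue_slope * np.asarray(ph, dtype=float) + buf.tissue_intercept
    return float(b) if np.isscalar(ph) else b


def beta_total(pi, ph, buf: BufferModel = BufferModel()):
    """Apparent total buffering capacity beta_Pi + beta_tissue (Slykes)."""
    return beta_pi(pi, ph, buf) + beta_tissue(ph, buf)


def phi_stoich(ph, buf: BufferModel = BufferModel()):
    """Protons per PCr split, phi = 1/(1 + 10^(pH - pK)); in (0, 1)."""
    p = 1.0 / (1.0 + 10.0 ** (np.asarray(ph, dtype=float) - buf.pk_pi))
    return float(p) if np.isscalar(ph) else p


def m_stoich(ph, buf: BufferModel = BufferModel()):
    """Protons per unit oxidative ATP synthesis, m = m_amp/(1+10^(m_pk-pH))."""
    m = buf.m_amp / (1.0 + 10.0 ** (buf.m_pk - np.asarray(ph, dtype=float)))
    return float(m) if np.isscalar(ph) else m


def proton_stoich(ph, buf: BufferModel = BufferModel()):
    """Both stoichiometric coefficients (phi, m) at a given pH."""
    return phi_stoich(ph, buf), m_stoich(ph, buf)


def h_ck_flux(dpcr_dt, ph, buf: BufferModel = BufferModel()):
    """CK-coupled proton flux H_CK = phi * dPCr/dt (umol/g/min).

    ``dpcr_dt`` is the PCr *consumption* rate D (positive while PCr falls),
    so H_CK is positive during stimulation (protons released with Pi
    production) and negative during recovery (resynthesis consumes them).
    """
    h = phi_stoich(ph, buf) * np.asarray(dpcr_dt, dtype=float)
    return float(h) if (np.isscalar(dpcr_dt) and np.isscalar(ph)) else h


def _dph_dt_per_min(t_s: np.ndarray, ph: np.ndarray) -> np.ndarray:
    """d(pH)/dt in 1/min: centred differences, one-sided at the edges."""
    return np.gradient(ph, t_s / 60.0)


def lambda_from_recovery(
    recovery: pd.DataFrame,
    rec_fit: RecoveryFit,
    buf: BufferModel = BufferModel(),
    ph_rest: float | None = None,
) -> float:
    """Proton-efflux proportionality constant lambda (umol/g/min per pH unit).

    At the start of recovery glycolysis has stopped, yet pH returns to
    basal: the net efflux V_eff must absorb the proton loads of CK-mediated
    PCr resynthesis (phi * V) and of oxidative ATP synthesis (m * V), plus
    whatever the buffers release as pH moves,

        V_eff = (phi + m) * V + beta_total * dpH/dt,        lambda = -V_eff / dpH.

    All terms are discretised at a single instant — the midpoint between
    the first two recovery bins — so that the finite-difference dpH/dt, the
    pH deviation and the resynthesis rate V (the recovery fit's rate
    ``vpcr_rec * exp(-k t)`` evaluated there) refer to the same time.  An
    inconsistent pairing (initial-rate V against a 60 s-later derivative)
    biases lambda far beyond discretisation error at coarse binning.
    """
    rec = recovery[recovery["phase"] == "recovery"]
    if len(rec) < 2:
        raise ValueError("need >= 2 recovery bins to estimate lambda")
    t_s = rec["t_s"].to_numpy(dtype=float)
    ph = rec["ph"].to_numpy(dtype=float)
    pi = rec["pi"].to_numpy(dtype=float)
    if ph_rest is None:
        rest = recovery.loc[recovery["phase"] == "rest", "ph"]
        if rest.empty:
            raise ValueError("ph_rest not given and series has no rest bins")
        ph_rest = float(rest.mean())
    if ph[0] - ph_rest == 0.0:
        raise ZeroDivisionError("delta pH = 0 at recovery onset: lambda undefined")
    # recovery onset from the first two bins alone (leading edge of bin 0,
    # assuming equal widths): invariant to a uniform shift of the clock
    onset_s = t_s[0] - 0.5 * (t_s[1] - t_s[0])
    t_star_s = 0.5 * (t_s[0] + t_s[1])
    ph_star = 0.5 * (ph[0] + ph[1])
    pi_star = 0.5 * (pi[0] + pi[1])
    delta_ph = ph_star - ph_rest
    if delta_ph == 0.0:
        raise ZeroDivisionError("delta pH = 0 at recovery onset: lambda undefined")
    dph_dt = (ph[1] - ph[0]) / ((t_s[1] - t_s[0]) / 60.0)
    v_star = rec_fit.vpcr_rec * np.exp(-rec_fit.k_rec * (t_star_s - onset_s) / 60.0)
    phi_s = phi_stoich(ph_star, buf)
    m_s = m_stoich(ph_star, buf)
    beta_s = beta_total(pi_star, ph_star, buf)
    v_eff = (phi_s + m_s) * v_star + beta_s * dph_dt
    return -v_eff / delta_ph


def glycolytic_flux(
    series: pd.DataFrame,
    onset: OnsetFit,
    rec_fit: RecoveryFit,
    lambda_: float,
    ox: OxParams,
    buf: BufferModel = BufferModel(),
    ph_rest: float | None = None,
    d_mode: str = "analytic",
) -> pd.DataFrame:
    """Per-bin proton ledger and glycolytic ATP flux over stimulation.

    For each stimulation bin:

    * ``d_ck``     D(t) from the onset fit's analytic derivative
      (``d_mode="analytic"``) or centred finite differences on the binned
      PCr (``d_mode="fd"``);
    * ``h_ck``     phi(pH) * D;
    * ``h_beta``   -beta_total(Pi, pH) * d(dpH)/dt (buffer release rate);
    * ``h_efflux`` -lambda * dpH;
    * ``q_ox``     Q from the per-bin ADP and the hyperbolic model;
      ``h_ox`` = m(pH) * Q (per-bin oxidative rate — the recovery-onset
      form m * VPCr_rec applies only where Q has relaxed to VPCr_rec);
    * ``h_gly``    by the closure identity, floored at zero for the ATP
      rate ``l_gly = 1.5 * h_gly`` with the raw value kept in
      ``h_gly_raw``.

    Returns a DataFrame with :data:`LEDGER_COLUMNS`.
    """
    if lambda_ is None or not np.isfinite(lambda_):
        raise ValueError("lambda_ is required for the efflux term")
    stim = series[series["phase"] == "stim"]
    if stim.empty:
        raise ValueError("series has no stimulation bins")
    t_s = stim["t_s"].to_numpy(dtype=float)
    ph = stim["ph"].to_numpy(dtype=float)
    pi = stim["pi"].to_numpy(dtype=float)
    adp = stim["adp"].to_numpy(dtype=float)
    if ph_rest is None:
        rest = series.loc[series["phase"] == "rest", "ph"]
        if rest.empty:
            raise ValueError("ph_rest not given and series has no rest bins")
        ph_rest = float(rest.mean())

    onset_s = _stim_onset_s(series)
    t_min = (t_s - onset_s) / 60.0
    if d_mode == "analytic":
        d = ck_flux(onset, t_min)
    elif d_mode == "fd":
        pcr = stim["pcr"].to_numpy(dtype=float)
        d = -np.gradient(pcr, t_min)
    else:
        raise ValueError("d_mode must be 'analytic' or 'fd'")

    delta_ph = ph - ph_rest
    dph_dt = _dph_dt_per_min(t_s, delta_ph)
    betat = beta_total(pi, ph, buf)

    h_ck = phi_stoich(ph, buf) * d
    h_beta = -betat * dph_dt
    h_efflux = -lambda_ * delta_ph
    q = ox_flux(adp, ox)
    h_ox = m_stoich(ph, buf) * q
    h_gly_raw = h_ck + h_beta + h_efflux - h_ox
    h_gly = np.maximum(h_gly_raw, 0.0)

    return pd.DataFrame({
        "t_s": t_s,
        "h_ck": h_ck,
        "h_beta": h_beta,
        "h_efflux": h_efflux,
        "h_ox": h_ox,
        "h_gly": h_gly,
        "h_gly_raw": h_gly_raw,
        "l_gly": 1.5 * h_gly,
        "d_ck": d,
        "q_ox": q,
    })


def _stim_onset_s(series: pd.DataFrame) -> float:
    from .kinetics import _phase_onset_s
    return _phase_onset_s(series, "stim")


def total_atp_and_cost(
    fluxes: pd.DataFrame,
    tti: float | None = None,
    bin_durations_s: np.ndarray | None = None,
) -> tuple[float, float | None]:
    """Total ATP turnover over the stimulation window and its force cost.

    ``total = integral of (D + Q + L) dt`` over the full window.  Fluxes are
    bin values, so the integral is the bin-duration-weighted sum (trapezoid
    on the piecewise-constant extension over the bin edges); when durations
    are not given they are reconstructed from consecutive midpoints assuming
    contiguous bins.  ``cost = total / tti`` (umol/g per N*s) when a
    tension-time integral over the same window is supplied.
    """
    t_s = fluxes["t_s"].to_numpy(dtype=float)
    total_rate = (fluxes["d_ck"] + fluxes["q_ox"] + fluxes["l_gly"]).to_numpy(dtype=float)
    if bin_durations_s is None:
        if len(t_s) < 2:
            raise ValueError("cannot infer bin durations from a single bin")
        # contiguous bins: width_i = 2*(mid_i - left_i), left_{i+1} = left_i + width_i
        widths = np.empty_like(t_s)
        left = t_s[0] - 0.5 * (t_s[1] - t_s[0])  # assume first two bins equal
        for i, mid in enumerate(t_s):
            widths[i] = 2.0 * (mid - left)
            left += widths[i]
        bin_durations_s = widths
    total = float(np.sum(total_rate * np.asarray(bin_durations_s, float) / 60.0))
    if tti is None:
        return total, None
    if tti == 0:
        raise ZeroDivisionError("tension-time integral is zero: cost undefined")
    return total, total / tti
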