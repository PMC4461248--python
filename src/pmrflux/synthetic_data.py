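"""Forward simulation of rest / stimulation / recovery 31P-MRS experiments.

Generates complete synthetic bouts — metabolite, pH and force time courses
with MR time-binning and additive Gaussian noise — from known ground-truth
parameters, so that every stage of the analysis (quantification, kinetics,
proton balance, statistics) can be tested by parameter recovery and closure
rather than against inaccessible in vivo data.

Model (explicit Euler on a fine grid, default 1 s):

* free ADP from the creatine-kinase equilibrium at every step;
* oxidative ATP synthesis ``Q = Qmax/(1 + Km/[ADP])``;
* an ATP demand profile ``U(t)``: basal at rest and during recovery,
  a decaying-exponential contraction demand during stimulation;
* a glycolytic partition ``g(t) in [0, 1]`` (input, not emergent): the
  non-oxidative demand splits into glycolysis ``L = g (U - Q)`` and net PCr
  breakdown ``D = U - Q - L``, so ``D + Q + L = U`` holds exactly and
  ``dPCr/dt = -D`` (PCr rebuilds whenever Q exceeds demand, which is what
  drives the post-stimulation recovery);
* pH integrated from the proton ledger run forward: the buffering term is
  whatever closes ``H_Gly = H_CK + H_beta + H_Efflux - H_Ox``, and
  ``dpH/dt = -H_beta / beta_total``.  The simulated efflux carries a
  constant basal offset ``m(pH_rest) * U_basal`` on top of ``-lambda dpH``
  so that the resting state is an exact fixed point of both the metabolite
  and the proton dynamics.

The resting state is self-consistent by construction: basal demand is set
to the resting oxidative rate ``Q([ADP]_rest)``, with ``[ADP]_rest``
implied by ``tcr``.  The default total creatine pool keeps resting free ADP
low (~0.5 uM) so that resting oxidative flux is a small fraction of Qmax —
the regime the recovery-based capacity estimator assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .quantify import (
    AcquisitionProtocol, CKParams, PhCalibration, PHOS_COLUMNS,
    adp_from_ck, bin_durations, bin_midpoints, bin_phases, shift_from_ph,
)
from .proton_balance import BufferModel, beta_total, m_stoich, phi_stoich
from .mechanics import ForceTrace

__all__ = [
    "SimParams",
    "SimOutput",
    "simulate_bout",
    "simulate_group",
    "exponential_series",
    "twitch_train",
    "to_peak_table",
]

#: Default per-channel additive Gaussian noise SD (applied after binning).
DEFAULT_NOISE_SD = {"pcr": 1.0, "pi": 0.5, "atp": 0.2, "ph": 0.02}


@dataclass(frozen=True)
class SimParams:
    """Ground-truth parameters of a simulated electrostimulation bout.

    Rates in umol/g/min, concentrations in umol/g wet wt, times in seconds.

    Demand during stimulation decays exponentially from ``u_start`` to
    ``u_ss`` with time constant ``tau_u_s`` (contractile demand falls as the
    muscle fatigues); outside stimulation demand is basal, derived from the
    resting fixed point.  The glycolytic fraction rises along a logistic
    from ``g_early`` to ``g_late`` (glycolysis takes over as the PCr store
    empties), midpoint ``g_mid_s`` and width ``g_width_s`` after onset.
    """

    qmax: float = 26.0
    km: float = 50.0                 # uM
    lambda_: float = 12.0            # umol/g/min per pH unit
    tcr: float = 32.12               # total creatine; resting ADP ~0.2 uM
    pcr_rest: float = 32.0
    atp_rest: float = 7.22
    ph_rest: float = 7.06
    pi_rest: float = 4.0
    k_ck: float = 1.67e9
    density_factor: float = 1.0
    u_start: float = 55.0
    u_ss: float = 22.0
    tau_u_s: float = 22.0
    g_early: float = 0.05
    g_late: float = 0.95
    g_mid_s: float = 60.0
    g_width_s: float = 25.0
    buffer: BufferModel = field(default_factory=BufferModel)
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    dt_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.g_early <= 1.0 and 0.0 <= self.g_late <= 1.0):
            raise ValueError("glycolytic fractions must lie in [0, 1]")
        for name in ("qmax", "km", "tcr", "pcr_rest", "atp_rest", "dt_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.tcr <= self.pcr_rest:
            raise ValueError("tcr must exceed pcr_rest")

    @property
    def ck(self) -> CKParams:
        return CKParams(k_ck=self.k_ck, tcr=self.tcr,
                        density_factor=self.density_factor)

    @property
    def adp_rest(self) -> float:
        """Resting free ADP (uM) implied by the CK equilibrium and tcr."""
        return adp_from_ck(self.pcr_rest, self.atp_rest, self.ph_rest,
                           self.ck) * self.density_factor

    @property
    def u_basal(self) -> float:
        """Basal ATP demand: the resting oxidative rate (fixed point)."""
        return self.qmax / (1.0 + self.km / self.adp_rest)

    def demand(self, t_since_stim_s) -> np.ndarray:
        """Stimulation ATP demand U(t) (umol/g/min), t since stim onset."""
        t = np.asarray(t_since_stim_s, dtype=float)
        return self.u_ss + (self.u_start - self.u_ss) * np.exp(-t / self.tau_u_s)

    def gly_fraction(self, t_since_stim_s) -> np.ndarray:
        """Glycolytic partition g(t) in [0, 1], t since stim onset."""
        t = np.asarray(t_since_stim_s, dtype=float)
        return self.g_early + (self.g_late - self.g_early) / (
            1.0 + np.exp(-(t - self.g_mid_s) / self.g_width_s))

    @classmethod
    def validation(cls, **overrides) -> "SimParams":
        """Mild-exercise bout for estimator validation.

        The default bout mimics the fatiguing in vivo protocol (deep PCr
        depletion, substantial acidosis); there the recovery-based capacity
        estimator carries a known pH-coupling bias of order -20% (see the
        methods note).  This configuration — moderate depletion (~30%),
        near-neutral pH throughout, fast proton efflux — is the regime
        where the estimator's assumptions (supra-basal resynthesis, small
        pH excursion) hold, and is used to verify closure and parameter
        recovery of the inversion chain itself.
        """
        base = dict(lambda_=60.0, tcr=32.06, u_start=30.0, tau_u_s=25.0,
                    u_ss=8.0, g_late=0.9, g_mid_s=75.0, g_width_s=30.0)
        base.update(overrides)
        return cls(**base)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimParams":
        d = json.loads(text)
        if "buffer" in d and isinstance(d["buffer"], dict):
            d["buffer"] = BufferModel(**d["buffer"])
        return cls(**d)


@dataclass
class SimOutput:
    """Simulated bout: fine-grid truth, binned noisy series, force, truth fluxes.

    ``fine`` has one row per integration step (t_s, phase, pcr, pi, atp, ph,
    adp, u, d, q, l, h_gly, h_ck, h_beta, h_efflux, h_ox); the ATP balance
    D + Q + L = U and the proton-ledger closure hold exactly row by row.
    ``series`` is the MR-binned measurement (within-bin means plus noise)
    with the standard series columns; ``truth_bins`` carries the noise-free
    bin means of the fluxes.
    """

    params: SimParams
    protocol: AcquisitionProtocol
    fine: pd.DataFrame
    series: pd.DataFrame
    truth_bins: pd.DataFrame
    force: ForceTrace
    tti: float


def simulate_bout(params: SimParams,
                  protocol: AcquisitionProtocol = AcquisitionProtocol(),
                  rng: np.random.Generator | None = None) -> SimOutput:
    """Run one forward bout and bin it like the MR acquisition.

    Explicit Euler at ``params.dt_s`` (state sampled at cell centres so bin
    means are plain averages); Gaussian noise per channel is added after
    binning; the ADP column of the noisy series is recomputed from the
    noisy PCr/ATP/pH through the CK equilibrium, exactly as the analysis
    pipeline would.  A demand that would exhaust PCr is floored at zero PCr
    with an infeasibility warning.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    buf = params.buffer
    ck = params.ck
    dt_min = params.dt_s / 60.0
    stim_on = protocol.phase_onset("stim")
    rec_on = protocol.phase_onset("recovery")
    t_end = rec_on + protocol.phase_duration("recovery")
    n = int(round(t_end / params.dt_s))
    t = (np.arange(n) + 0.5) * params.dt_s

    basal = params.u_basal
    h_ox_rest = m_stoich(params.ph_rest, buf) * basal  # basal efflux offset

    pcr = params.pcr_rest
    ph = params.ph_rest
    cols = {k: np.empty(n) for k in
            ("pcr", "pi", "ph", "adp", "u", "d", "q", "l",
             "h_gly", "h_ck", "h_beta", "h_efflux", "h_ox")}
    infeasible = False
    # hot loop: plain-float physics (the CK equilibrium, hyperbola and
    # buffer formulas inlined) — identical maths to the module functions,
    # which the test suite cross-checks row by row
    from math import exp
    tcr, atp, kck = params.tcr, params.atp_rest, params.k_ck
    qmax, km, lam = params.qmax, params.km, params.lambda_
    ph_rest, pcr_rest, pi_rest = params.ph_rest, params.pcr_rest, params.pi_rest
    df = params.density_factor
    pk, m_amp, m_pk = buf.pk_pi, buf.m_amp, buf.m_pk
    b_slope, b_icpt = buf.tissue_slope, buf.tissue_intercept
    u0, uss, tau = params.u_start, params.u_ss, params.tau_u_s
    g0, g1, gmid, gw = (params.g_early, params.g_late, params.g_mid_s,
                        params.g_width_s)
    (a_pcr, a_pi, a_ph, a_adp, a_u, a_d, a_q, a_l, a_hg, a_hc, a_hb,
     a_he, a_ho) = (cols[k] for k in
                    ("pcr", "pi", "ph", "adp", "u", "d", "q", "l",
                     "h_gly", "h_ck", "h_beta", "h_efflux", "h_ox"))

    def rates(pcr_s: float, ph_s: float, ti: float):
        """State derivatives and fluxes at (pcr, ph, t)."""
        pi_c = pi_rest + (pcr_rest - pcr_s)
        adp = atp * (tcr - pcr_s) / (pcr_s * kck * 10.0 ** (-ph_s)) * 1e3 * df
        q = qmax / (1.0 + km / adp) if adp > 0 else 0.0
        if stim_on <= ti < rec_on:
            ts = ti - stim_on
            u = uss + (u0 - uss) * exp(-ts / tau)
            g = g0 + (g1 - g0) / (1.0 + exp(-(ts - gmid) / gw))
            gap = u - q
            l = min(max(g * gap, 0.0), max(gap, 0.0))
        else:
            u = basal
            l = 0.0
        d = u - q - l  # exact ATP balance: d + q + l = u
        h_gly = l / 1.5
        h_ck = d / (1.0 + 10.0 ** (ph_s - pk))
        h_efflux = -lam * (ph_s - ph_rest) + h_ox_rest
        h_ox = q * m_amp / (1.0 + 10.0 ** (m_pk - ph_s))
        h_beta = h_gly - h_ck - h_efflux + h_ox  # ledger closure, exact
        bt = (2.3 * pi_c / ((1.0 + 10.0 ** (ph_s - pk))
                            * (1.0 + 10.0 ** (pk - ph_s)))
              + b_slope * ph_s + b_icpt)
        return (pi_c, adp, u, d, q, l, h_gly, h_ck, h_beta, h_efflux,
                h_ox, -d, -h_beta / bt)

    for i, ti in enumerate(t):
        r1 = rates(pcr, ph, ti)
        (a_pi[i], a_adp[i], a_u[i], a_d[i], a_q[i], a_l[i], a_hg[i],
         a_hc[i], a_hb[i], a_he[i], a_ho[i], dpcr1, dph1) = r1
        a_pcr[i] = pcr
        a_ph[i] = ph
        # Heun step: predictor at t+dt, then trapezoidal corrector
        pcr_p = max(pcr + dpcr1 * dt_min, 1e-9)
        ph_p = ph + dph1 * dt_min
        *_, dpcr2, dph2 = rates(pcr_p, ph_p, ti + params.dt_s)
        pcr_next = pcr + 0.5 * (dpcr1 + dpcr2) * dt_min
        if pcr_next <= 0.0:
            infeasible = True
            pcr_next = min(pcr, 1e-9)
        pcr = pcr_next
        ph = ph + 0.5 * (dph1 + dph2) * dt_min
    if infeasible:
        import warnings
        warnings.warn("demand exhausted the PCr store: PCr floored at 0",
                      RuntimeWarning, stacklevel=2)

    fine = pd.DataFrame({"t_s": t, **cols})
    fine["atp"] = params.atp_rest
    edges_idx = _bin_edges_idx(protocol, params.dt_s)
    fine["phase"] = _phase_of_t(t, stim_on, rec_on)

    # within-bin means of the fine grid
    def bin_mean(col: str) -> np.ndarray:
        x = fine[col].to_numpy()
        return np.array([x[a:b].mean() for a, b in edges_idx])

    mid = bin_midpoints(protocol)
    series = pd.DataFrame({
        "t_s": mid,
        "phase": bin_phases(protocol),
        "pcr": bin_mean("pcr"),
        "pi": bin_mean("pi"),
        "atp": bin_mean("atp"),
        "ph": bin_mean("ph"),
    })
    truth_bins = pd.DataFrame({
        "t_s": mid,
        "phase": bin_phases(protocol),
        **{k: bin_mean(k) for k in ("u", "d", "q", "l", "h_gly", "h_ck",
                                    "h_beta", "h_efflux", "h_ox", "adp")},
    })

    sd = params.noise_sd
    for ch in ("pcr", "pi", "atp", "ph"):
        s = float(sd.get(ch, 0.0))
        if s > 0:
            series[ch] = series[ch] + rng.normal(0.0, s, len(series))
    series["pcr"] = series["pcr"].clip(lower=1e-6)
    series["pi"] = series["pi"].clip(lower=0.0)
    series["atp"] = series["atp"].clip(lower=1e-6)
    series["adp"] = adp_from_ck(
        np.minimum(series["pcr"].to_numpy(), params.tcr * (1 - 1e-9)),
        series["atp"].to_numpy(), series["ph"].to_numpy(), ck)
    series = series[list(PHOS_COLUMNS)]

    force = _force_trace(params, protocol, rng)
    tti = float(np.trapezoid(force.force, force.t))
    return SimOutput(params=params, protocol=protocol, fine=fine,
                     series=series, truth_bins=truth_bins, force=force, tti=tti)


def _bin_edges_idx(protocol: AcquisitionProtocol, dt_s: float):
    edges = np.concatenate([[0.0], np.cumsum(bin_durations(protocol))])
    idx = np.round(edges / dt_s).astype(int)
    return list(zip(idx[:-1], idx[1:]))


def _phase_of_t(t: np.ndarray, stim_on: float, rec_on: float) -> np.ndarray:
    phase = np.where(t < stim_on, "rest",
                     np.where(t < rec_on, "stim", "recovery"))
    return phase


# ---------------------------------------------------------------------------
# Force synthesis

def twitch_train(duration_s: float, freq_hz: float = 3.3,
                 twitch_width_s: float = 0.12, sample_hz: float = 1000.0,
                 peak_n: float | np.ndarray = 1.0) -> ForceTrace:
    """Train of triangular isometric twitches.

    Each stimulus at ``1/freq_hz`` spacing produces a symmetric triangular
    twitch of base width ``twitch_width_s`` whose analytic area is
    ``0.5 * width * peak`` N*s; ``peak_n`` may be a scalar or a per-twitch
    array (fatigue envelope).
    """
    t = np.arange(0.0, duration_s, 1.0 / sample_hz)
    f = np.zeros_like(t)
    onsets = np.arange(0.0, duration_s - twitch_width_s, 1.0 / freq_hz)
    peaks = np.broadcast_to(np.asarray(peak_n, dtype=float), onsets.shape)
    half = twitch_width_s / 2.0
    n_tw = int(np.ceil(twitch_width_s * sample_hz)) + 1
    for t0, pk in zip(onsets, peaks):
        i0 = int(np.ceil(t0 * sample_hz))
        sl = slice(i0, min(i0 + n_tw, len(t)))
        x = t[sl] - t0
        tri = np.where(x < half, x / half, 2.0 - x / half)
        f[sl] += pk * np.clip(tri, 0.0, 1.0)
    return ForceTrace(t, f, stim_frequency_hz=freq_hz)


def _force_trace(params: SimParams, protocol: AcquisitionProtocol,
                 rng: np.random.Generator) -> ForceTrace:
    """Force over the stimulation window, proportional to contractile demand.

    Twitch peaks follow the supra-basal demand envelope (force costs ATP),
    scaled so the first twitch peaks near 6 N, with 2% multiplicative
    jitter per twitch.
    """
    dur = protocol.phase_duration("stim")
    freq = 3.3
    onsets = np.arange(0.0, dur - 0.12, 1.0 / freq)
    env = params.demand(onsets) - params.u_basal
    peaks = 6.0 * env / max(env[0], 1e-9)
    peaks = peaks * rng.normal(1.0, 0.02, len(peaks)).clip(0.5, 1.5)
    return twitch_train(dur, freq_hz=freq, peak_n=peaks)


# ---------------------------------------------------------------------------
# Idealised series and group designs

def exponential_series(pcr_rest: float = 32.0, pcr_cons: float = 25.0,
                       k_rec: float = 0.38, k_stim: float = 2.4,
                       pcr_ss: float | None = None,
                       ph_rest: float = 7.06, ph_end: float = 6.34,
                       pi_rest: float = 4.0, atp: float = 7.22,
                       tcr: float = 37.7,
                       protocol: AcquisitionProtocol = AcquisitionProtocol(),
                       noise_sd: float = 0.0,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Series sampled exactly from the mono-exponential fit models.

    PCr falls as ``pcr_ss + (pcr_rest - pcr_ss) e^(-k_stim t)`` during
    stimulation and recovers as ``pcr_rest - pcr_cons e^(-k_rec t)``; pH
    falls linearly to ``ph_end`` over the first half of stimulation and
    recovers exponentially.  Values are the model evaluated at the bin
    midpoints (no bin-averaging), so fits must reproduce the generating
    parameters to numerical precision on noiseless output.
    """
    if pcr_ss is None:
        pcr_ss = pcr_rest - pcr_cons
    t = bin_midpoints(protocol)
    phase = bin_phases(protocol)
    stim_on = protocol.phase_onset("stim")
    rec_on = protocol.phase_onset("recovery")
    pcr = np.empty_like(t)
    ph = np.empty_like(t)
    for i, (ti, phs) in enumerate(zip(t, phase)):
        if phs == "rest":
            pcr[i] = pcr_rest
            ph[i] = ph_rest
        elif phs == "stim":
            tm = (ti - stim_on) / 60.0
            pcr[i] = pcr_ss + (pcr_rest - pcr_ss) * np.exp(-k_stim * tm)
            half = (rec_on - stim_on) / 2.0
            frac = min((ti - stim_on) / half, 1.0)
            ph[i] = ph_rest + (ph_end - ph_rest) * frac
        else:
            tm = (ti - rec_on) / 60.0
            pcr[i] = pcr_rest - pcr_cons * np.exp(-k_rec * tm)
            ph[i] = ph_rest + (ph_end - ph_rest) * np.exp(-k_rec * tm)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        pcr = pcr + rng.normal(0.0, noise_sd, len(pcr))
    pi = pi_rest + (pcr_rest - pcr)
    ck = CKParams(tcr=tcr)
    adp = adp_from_ck(np.clip(pcr, 1e-6, tcr * (1 - 1e-9)), atp, ph, ck)
    return pd.DataFrame({
        "t_s": t, "phase": phase, "pcr": pcr, "pi": pi,
        "atp": np.full_like(t, atp), "adp": adp, "ph": ph,
    })


def simulate_group(params_a: SimParams, params_b: SimParams,
                   n_a: int = 8, n_b: int = 10, seed: int = 0,
                   cv: float = 0.10,
                   protocol: AcquisitionProtocol = AcquisitionProtocol(),
                   jitter_fields: tuple[str, ...] = (
                       "qmax", "lambda_", "u_start", "u_ss", "pcr_rest"),
                   ) -> list[tuple[str, int, SimOutput]]:
    """Simulate two groups of subjects with log-normal parameter jitter.

    Each subject's rate parameters are drawn log-normally around the group
    values with coefficient of variation ``cv`` (log-normal keeps rates
    positive), then a full bout is simulated.  Deterministic under
    ``seed``.  Returns ``(group_label, subject_index, SimOutput)`` tuples.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 subjects per group")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1.0 + cv ** 2))
    out = []
    for label, base, n in (("A", params_a, n_a), ("B", params_b, n_b)):
        for i in range(n):
            updates = {}
            for f_name in jitter_fields:
                val = getattr(base, f_name)
                updates[f_name] = val * rng.lognormal(-0.5 * sigma ** 2, sigma)
            if "pcr_rest" in updates:
                # keep the creatine pool consistent with the jittered PCr
                updates["tcr"] = base.tcr * updates["pcr_rest"] / base.pcr_rest
            subj = replace(base, **updates,
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
            out.append((label, i, simulate_bout(subj, protocol, rng=rng)))
    return out


def to_peak_table(series: pd.DataFrame, atp_ref: float,
                  saturation: dict | None = None,
                  area_scale: float = 10.0,
                  cal: PhCalibration = PhCalibration()):
    """Convert a concentration series back into fitted-peak CSV inputs.

    Inverse of the quantification stage: areas proportional to
    concentration divided by the per-metabolite saturation factor, and the
    Pi shift from the pH calibration.  Returns ``(peaks, relaxed)``
    DataFrames in the peak-table schema, for end-to-end round trips.
    """
    sat = {"pcr": 0.7, "pi": 0.85, "atp": 0.95}
    if saturation:
        sat.update(saturation)
    n = len(series)
    rest = series["phase"] == "rest"
    peaks = pd.DataFrame({
        "bin_index": np.arange(n),
        "phase": series["phase"].to_numpy(),
        "pme": np.zeros(n),
        "pi": series["pi"].to_numpy() * area_scale * sat["pi"],
        "pcr": series["pcr"].to_numpy() * area_scale * sat["pcr"],
        "atp_gamma": series["atp"].to_numpy() * area_scale * sat["atp"],
        "atp_alpha": series["atp"].to_numpy() * area_scale * sat["atp"],
        "atp_beta": series["atp"].to_numpy() * area_scale * sat["atp"],
        "pi_shift_ppm": shift_from_ph(series["ph"].to_numpy(), cal),
    })
    relaxed = pd.DataFrame({
        "bin_index": [0], "phase": ["rest"], "pme": [0.0],
        "pi": [float(series.loc[rest, "pi"].mean()) * area_scale],
        "pcr": [float(series.loc[rest, "pcr"].mean()) * area_scale],
        "atp_gamma": [float(series.loc[rest, "atp"].mean()) * area_scale],
        "atp_alpha": [float(series.loc[rest, "atp"].mean()) * area_scale],
        "atp_beta": [float(series.loc[rest, "atp"].mean()) * area_scale],
        "pi_shift_ppm": [shift_from_ph(float(series.loc[rest, "ph"].mean()), cal)],
    })
    return peaks, relaxed
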