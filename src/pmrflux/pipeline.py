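"""End-to-end analysis of one bout: series in, energetic endpoints out.

Chains the analysis stages in acquisition order — onset and recovery fits,
end-of-stimulation ADP, maximal oxidative capacity, efflux constant, per-bin
proton ledger and flux partition, total ATP turnover and (when force data
are present) the ATP cost of contraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import (
    OnsetFit, OxParams, RecoveryFit, adp_end_of_stim, compute_qmax,
    fit_onset, fit_recovery, pcr_consumption_pct,
)
from .proton_balance import (
    BufferModel, glycolytic_flux, lambda_from_recovery, total_atp_and_cost,
)

__all__ = ["BoutResult", "analyze_bout"]


@dataclass
class BoutResult:
    """Derived energetics of one bout; ``fluxes`` is the per-bin ledger."""

    onset: OnsetFit
    recovery: RecoveryFit
    adp_end: float
    qmax: float
    lambda_: float
    fluxes: pd.DataFrame
    total_atp: float
    atp_cost: float | None
    pcr_cons_pct: float

    def endpoints(self) -> dict:
        """Flat scalar endpoints for group tables."""
        d = {
            "k_stim": self.onset.k_stim,
            "vpcr_stim": self.onset.vpcr_stim,
            "k_rec": self.recovery.k_rec,
            "vpcr_rec": self.recovery.vpcr_rec,
            "pcr_rest": self.recovery.pcr_rest,
            "pcr_cons": self.recovery.pcr_cons,
            "pcr_cons_pct": self.pcr_cons_pct,
            "adp_end": self.adp_end,
            "qmax": self.qmax,
            "lambda": self.lambda_,
            "total_atp": self.total_atp,
        }
        if self.atp_cost is not None:
            d["atp_cost"] = self.atp_cost
        return d


def analyze_bout(series: pd.DataFrame, km: float = 50.0,
                 buf: BufferModel = BufferModel(),
                 density_factor: float = 1.0,
                 tti: float | None = None,
                 d_mode: str = "analytic") -> BoutResult:
    """Full flux analysis of a quantified series.

    ``series`` must carry the standard columns (t_s, phase, pcr, pi, atp,
    adp, ph) with rest, stim and recovery phases.  ``tti`` (N*s over the
    stimulation window) enables the ATP cost of contraction.
    """
    onset = fit_onset(series)
    recovery = fit_recovery(series)
    adp_end = adp_end_of_stim(series, density_factor)
    qmax = compute_qmax(recovery.vpcr_rec, adp_end, km)
    lam = lambda_from_recovery(series, recovery, buf)
    ox = OxParams(qmax=qmax, km=km)
    fluxes = glycolytic_flux(series, onset, recovery, lam, ox, buf,
                             d_mode=d_mode)
    stim = series[series["phase"] == "stim"]
    durations = _stim_bin_durations(series)
    total, cost = total_atp_and_cost(fluxes, tti, bin_durations_s=durations)
    pcr_end = float(stim["pcr"].iloc[-1])
    rest_pcr = float(series.loc[series["phase"] == "rest", "pcr"].mean())
    return BoutResult(
        onset=onset, recovery=recovery, adp_end=adp_end, qmax=qmax,
        lambda_=lam, fluxes=fluxes, total_atp=total, atp_cost=cost,
        pcr_cons_pct=pcr_consumption_pct(rest_pcr, pcr_end),
    )


def _stim_bin_durations(series: pd.DataFrame) -> np.ndarray:
    """Bin widths (s) of the stimulation bins, from contiguous midpoints."""
    t = series["t_s"].to_numpy(dtype=float)
    phases = series["phase"].to_numpy()
    widths = np.empty(len(t))
    left = 0.0
    for i, mid in enumerate(t):
        widths[i] = 2.0 * (mid - left)
        left += widths[i]
    return widths[phases == "stim"]
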