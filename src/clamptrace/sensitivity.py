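"""Steady-state summaries and insulin-sensitivity indices.

The clamp's steady state is the final 30 minutes of the study, over which
glucose, insulin and the tracer-derived fluxes are time-averaged.  The two
indices separate insulin action on muscle/periphery from action on the
liver:

    SI_P = 1e4 * (Rd_SS - Rd_basal) / ((Ins_SS - Ins_basal) * Gluc_SS)
    SI_H = 1e4 * (EGP_basal - EGP_SS) / ((Ins_SS - Ins_basal) * Gluc_SS)

both in dl/kg/min per uU/ml x 1e4.  Delta-EGP is suppression-positive
(basal minus clamp), so a healthy liver has SI_H > 0 and a paradoxical
insulin-driven *rise* of glucose production shows up as SI_H < 0 — which is
how a between-condition "reduction" of hepatic sensitivity can exceed 100%.
Insulin MCR is the raw ratio of the insulin infusion rate to steady-state
insulin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import BasalSummary, ClampRecord, FluxSeries

__all__ = [
    "SteadyStateSummary",
    "SensitivityResult",
    "steady_state_summary",
    "compute_sensitivity",
    "percent_reduction",
]


@dataclass
class SteadyStateSummary:
    """Time-averages over the final-30-minute steady-state window."""

    Gluc_SS: float   # mg/dl
    Ins_SS: float    # uU/ml
    Rd_SS: float     # mg/kg/min
    EGP_SS: float    # mg/kg/min
    window: tuple[float, float]  # (start, end], min


@dataclass
class SensitivityResult:
    """Per-animal insulin-sensitivity endpoints."""

    dRd: float     # Rd_SS - Rd_basal, mg/kg/min
    dEGP: float    # EGP_basal - EGP_SS (suppression-positive), mg/kg/min
    dIns: float    # Ins_SS - Ins_basal, uU/ml
    SI_P: float    # dl/kg/min per uU/ml x 1e4
    SI_H: float    # dl/kg/min per uU/ml x 1e4
    MCR: float     # insulin_rate / Ins_SS, (mU/kg/min)/(uU/ml)
    basal: BasalSummary
    steady_state: SteadyStateSummary
    insulin_rate: float


def steady_state_summary(series: FluxSeries, record: ClampRecord,
                         window: float = 30.0) -> SteadyStateSummary:
    """Average G, I, Rd and EGP over the final ``window`` minutes.

    The window is half-open ``(t_end - window, t_end]``; boundary samples
    belong to the right edge.
    """
    t_end = float(record.time[-1])
    if t_end - record.insulin_start < window:
        raise ValueError("record does not extend far enough past insulin start")
    start = t_end - window
    mask = (record.time > start) & (record.time <= t_end)
    if int(mask.sum()) < 2:
        raise ValueError("steady-state window underpopulated (< 2 samples)")
    return SteadyStateSummary(
        Gluc_SS=float(np.mean(record.G[mask])),
        Ins_SS=float(np.mean(record.I[mask])),
        Rd_SS=float(np.mean(series.Rd[mask])),
        EGP_SS=float(np.mean(series.EGP[mask])),
        window=(start, t_end),
    )


def compute_sensitivity(ss: SteadyStateSummary, basal: BasalSummary,
                        insulin_rate: float) -> SensitivityResult:
    """Derive SI_P, SI_H and insulin MCR from basal and steady-state summaries."""
    dIns = ss.Ins_SS - basal.I_basal
    if dIns <= 0:
        raise ValueError("no insulin elevation; SI undefined")
    if ss.Gluc_SS <= 0:
        raise ValueError("steady-state glucose must be positive")
    dRd = ss.Rd_SS - basal.Rd_basal
    dEGP = basal.EGP_basal - ss.EGP_SS
    denom = dIns * ss.Gluc_SS
    return SensitivityResult(
        dRd=dRd,
        dEGP=dEGP,
        dIns=dIns,
        SI_P=1e4 * dRd / denom,
        SI_H=1e4 * dEGP / denom,
        MCR=insulin_rate / ss.Ins_SS,
        basal=basal,
        steady_state=ss,
        insulin_rate=insulin_rate,
    )


def percent_reduction(si_reference: float, si_test: float) -> float:
    """Percent reduction of ``si_test`` relative to ``si_reference``.

    Values above 100% mean the test value crossed zero (sign flip).
    """
    if si_reference == 0:
        raise ValueError("undefined reduction: reference sensitivity is zero")
    return 100.0 * (si_reference - si_test) / si_reference
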