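"""Tracer-dilution glucose kinetics: Steele's equation for labeled infusates.

A primed-continuous [3-3H]glucose infusion labels the plasma glucose pool;
during the clamp the exogenous glucose infusate is itself labeled ("hot
GINF") so that plasma specific activity stays nearly constant and the
single-pool non-steady-state correction stays small.  With

* ``G``   plasma glucose (mg/dl),
* ``SA``  plasma specific activity (dpm/mg) = 100 * Gstar / G
  (Gstar in dpm/ml; x100 converts ml -> dl),
* ``F*``  total label delivery = tracer pump + GINF * SA_inf (dpm/kg/min),
* ``p``   Steele pool fraction, ``V`` glucose distribution volume (dl/kg),

the total rate of glucose appearance is

    Ra_total(t) = [F*(t) - p * V * G(t) * dSA/dt] / SA(t)      (mg/kg/min)

and the derived fluxes are ``EGP = Ra_total - GINF`` (endogenous glucose
production) and ``Rd = Ra_total - p * V * dG/dt`` (whole-body disposal).
Derivatives always come from the optimal-segments smoother, never from raw
finite differences of noisy samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .smoothing import OptimalSegmentsSmoother

__all__ = [
    "DPM_PER_UCI",
    "ClampRecord",
    "KineticConstants",
    "FluxSeries",
    "BasalSummary",
    "compute_fluxes",
    "basal_flux",
]

#: disintegrations per minute per microcurie
DPM_PER_UCI = 2.22e6


@dataclass
class ClampRecord:
    """One animal's sampled clamp time series plus protocol metadata.

    Concentration series are plasma measurements at ``time`` (min since
    tracer start); ``GINF`` and ``Fstar`` are the pump rates in effect at
    each sample.  ``SA_inf`` is the specific activity of the labeled
    exogenous glucose infusate (dpm/mg); it must be given explicitly (0 for
    a deliberately unlabeled "cold" infusate) whenever GINF is nonzero.
    """

    time: np.ndarray          # min
    G: np.ndarray             # plasma glucose, mg/dl
    Gstar: np.ndarray         # plasma tracer, dpm/ml
    I: np.ndarray             # plasma insulin, uU/ml
    GINF: np.ndarray          # exogenous glucose infusion, mg/kg/min
    Fstar: np.ndarray         # tracer pump rate, dpm/kg/min
    SA_inf: float | None      # infusate specific activity, dpm/mg
    weight: float             # kg
    insulin_rate: float       # mU/kg/min
    insulin_start: float      # min
    diet: str = "lean"        # {"lean", "fat_fed"}
    state: str = "conscious"  # {"conscious", "anesthetized"}
    animal_id: str = "animal"

    def __post_init__(self) -> None:
        for name in ("time", "G", "Gstar", "I", "GINF", "Fstar"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.time)
        for name in ("G", "Gstar", "I", "GINF", "Fstar"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column '{name}' length differs from time")
        bad = np.flatnonzero(np.diff(self.time) <= 0)
        if bad.size:
            raise ValueError(f"unsorted input: time not increasing at row {bad[0] + 1}")
        neg = np.flatnonzero(self.G <= 0)
        if neg.size:
            raise ValueError(f"non-positive glucose at rows {neg.tolist()}")
        if np.any(self.Gstar < 0):
            raise ValueError("negative tracer activity")
        if np.any(self.GINF < 0):
            raise ValueError("negative GINF")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if not (self.time[0] <= self.insulin_start <= self.time[-1]):
            raise ValueError("insulin_start outside the record's time range")


@dataclass
class KineticConstants:
    """Steele single-pool constants.

    The conventional canine/human values p = 0.65 and V = 2.2 dl/kg are the
    defaults; analyses of the matched single-pool simulator set p = 1 with
    the simulator's V so that the model is exact.
    """

    p: float = 0.65   # pool fraction, dimensionless
    V: float = 2.2    # glucose distribution volume, dl/kg

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError("pool fraction p must be in (0, 1]")
        if self.V <= 0:
            raise ValueError("distribution volume V must be positive")


@dataclass
class FluxSeries:
    """Time-resolved specific activity and glucose fluxes for one animal."""

    time: np.ndarray        # min
    SA: np.ndarray          # dpm/mg
    Ra_total: np.ndarray    # mg/kg/min
    EGP: np.ndarray         # mg/kg/min
    Rd: np.ndarray          # mg/kg/min
    negative_egp: np.ndarray = field(default=None)  # per-sample warning flags

    def __post_init__(self) -> None:
        if self.negative_egp is None:
            self.negative_egp = self.EGP < 0


@dataclass
class BasalSummary:
    """Time-averaged fluxes and concentrations over the basal window."""

    Rd_basal: float    # mg/kg/min
    EGP_basal: float   # mg/kg/min
    G_basal: float     # mg/dl
    I_basal: float     # uU/ml

    def __iter__(self):
        yield from (self.Rd_basal, self.EGP_basal, self.G_basal, self.I_basal)


def _smoother(settings: OptimalSegmentsSmoother | dict | None) -> OptimalSegmentsSmoother:
    if settings is None:
        return OptimalSegmentsSmoother()
    if isinstance(settings, OptimalSegmentsSmoother):
        return settings
    return OptimalSegmentsSmoother(**settings)


def compute_fluxes(record: ClampRecord,
                   constants: KineticConstants | None = None,
                   smoother: OptimalSegmentsSmoother | dict | None = None,
                   ginf_convention: str = "midpoint",
                   ) -> FluxSeries:
    """Compute SA(t), Ra_total(t), EGP(t) and Rd(t) at the sample times.

    Glucose and tracer activity are smoothed separately by optimal
    segments; SA and dSA/dt follow analytically from the two smooth curves
    via the quotient rule, so the derivative entering Steele's equation is
    the derivative of a fitted curve rather than of noisy samples.

    The glucose infusion is piecewise-constant and conventionally recorded
    as the rate in effect while each sample was drawn, so a sampling
    instant at which the pump was adjusted carries two rates (before and
    after).  The smoothed derivatives are two-sided, and the consistent
    instantaneous GINF is the mean of the adjacent recorded rates
    (``ginf_convention="midpoint"``, the default — for a stepwise infusion
    this cancels the pump-step half-jump in the smoothed dG/dt and dSA/dt
    exactly); ``"left"`` uses the recorded rates as-is.
    """
    constants = constants or KineticConstants()
    if record.SA_inf is None and np.any(record.GINF > 0):
        raise ValueError(
            "unlabeled infusate requires SA_inf = 0 explicitly "
            "(set SA_inf to the infusate specific activity, or 0 for cold glucose)"
        )
    if np.all(record.Gstar == 0):
        raise ValueError("tracer activity identically zero; was the pool primed?")

    sm_G = _smoother(smoother).fit(record.time, record.G)
    sm_T = _smoother(smoother).fit(record.time, record.Gstar)

    t = record.time
    G = sm_G.predict(t)
    dG = sm_G.predict_derivative(t)
    C = sm_T.predict(t)               # dpm/ml, smoothed
    dC = sm_T.predict_derivative(t)

    SA = 100.0 * C / G                                  # dpm/mg
    if np.any(SA <= 0):
        raise ValueError("specific activity nonpositive at an evaluation point")
    dSA = 100.0 * (dC * G - C * dG) / G**2              # dpm/mg/min

    sa_inf = 0.0 if record.SA_inf is None else float(record.SA_inf)
    if ginf_convention == "midpoint":
        ginf = record.GINF.copy()
        ginf[:-1] = 0.5 * (record.GINF[:-1] + record.GINF[1:])
    elif ginf_convention == "left":
        ginf = record.GINF
    else:
        raise ValueError("ginf_convention must be 'midpoint' or 'left'")
    F_total = record.Fstar + ginf * sa_inf              # dpm/kg/min
    pV = constants.p * constants.V
    Ra_total = (F_total - pV * G * dSA) / SA            # mg/kg/min
    EGP = Ra_total - ginf
    Rd = Ra_total - pV * dG

    flags = EGP < 0
    if np.any(flags):
        warnings.warn(
            f"negative EGP at {int(flags.sum())} sample(s); reported as computed",
            RuntimeWarning,
            stacklevel=2,
        )
    return FluxSeries(time=t.copy(), SA=SA, Ra_total=Ra_total, EGP=EGP, Rd=Rd,
                      negative_egp=flags)


def basal_flux(series: FluxSeries, record: ClampRecord,
               window: float = 30.0, end: float | None = None) -> BasalSummary:
    """Average fluxes and concentrations over the final ``window`` minutes
    of the basal (pre-insulin) period.

    The window is half-open, ``(end - window, end]``, with ``end`` defaulting
    to the insulin start time.
    """
    if end is None:
        end = record.insulin_start
    if end > record.insulin_start:
        raise ValueError("basal window overlaps clamp")
    if window <= 0:
        raise ValueError("window must be positive")
    start = end - window
    mask = (record.time > start) & (record.time <= end)
    if not np.any(mask):
        raise ValueError("no samples in basal window")
    return BasalSummary(
        Rd_basal=float(np.mean(series.Rd[mask])),
        EGP_basal=float(np.mean(series.EGP[mask])),
        G_basal=float(np.mean(record.G[mask])),
        I_basal=float(np.mean(record.I[mask])),
    )
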