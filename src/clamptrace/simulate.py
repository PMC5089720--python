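"""Mechanistic synthetic hyperinsulinemic-euglycemic clamp generator.

Simulates the full protocol on which the analysis pipeline operates, with
known ground truth: a primed-continuous [3-3H]glucose infusion (prime
25 uCi, pump 0.25 uCi/min), somatostatin-suppressed endogenous insulin,
exogenous insulin at 0.75-1.0 mU/kg/min starting after 120-180 min of
tracer equilibration, and a variable glucose infusion — labeled at
2.7 uCi/g ("hot GINF") — adjusted every sampling interval by a
proportional-integral rule standing in for the human operator, clamping
plasma glucose at its basal level.  Samples are drawn every 10-15 min with
multiplicative assay noise on glucose and insulin and square-root counting
noise on the tracer.

Model (per kg; G mg/dl, concentrations per dl, t min):

    dX/dt  = -p2 * (X - (I - I_b))                    remote insulin action
    EGP    = max(0, EGP_b * (1 - s_H * X))            hepatic production
    Rd     = (k_b + s_P * X) * G,  k_b = EGP_b / G_b  peripheral disposal
    V dG/dt  = EGP + GINF - Rd
    V dC*/dt = F*_pump + GINF * SA_inf - Rd * C*/G    tracer (C* dpm/dl)
    dI/dt  = 1000 * insulin_rate / V_I - n_I * I      (V_I in ml/kg)

Basal is a fixed point by construction; the tracer pool is primed at
C*(0) = prime / (V * weight).  ``s_H`` may be zero or negative
(anesthetized presets), making EGP insensitive to — or paradoxically
raised by — insulin.

Single-pool glucose kinetics are deliberate: analyzing with p = 1 and the
simulator's V makes Steele's equation exact, separating pipeline
correctness from model-mismatch bias (which can be studied by analyzing
with p = 0.65).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import DPM_PER_UCI, ClampRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PRESETS",
    "preset_config",
    "simulate_clamp",
    "generate_cohort",
    "DEFAULT_GROUP_SIZES",
]


@dataclass
class SimulationConfig:
    """Full parameterization of one virtual clamp experiment."""

    # physiology
    G_b: float = 95.0          # basal glucose, mg/dl
    EGP_b: float = 2.5         # basal endogenous glucose production, mg/kg/min
    I_b: float = 0.0           # basal insulin under somatostatin, uU/ml
    V: float = 2.2             # glucose distribution volume, dl/kg
    s_P: float = 4.7e-4        # peripheral insulin action, per (uU/ml)
    s_H: float = 5.4e-3        # hepatic insulin action, per (uU/ml); may be <= 0
    p2: float = 0.05           # remote-insulin equilibration rate, 1/min
    n_I: float = 0.10          # insulin clearance, 1/min
    V_I: float = 150.0         # insulin distribution volume, ml/kg
    # protocol
    tracer_prime_uCi: float = 25.0
    tracer_rate_uCi_min: float = 0.25
    sa_inf_uCi_g: float = 2.7       # infusate label, uCi per g glucose
    insulin_rate: float = 1.0       # mU/kg/min
    basal_duration: float = 120.0   # min of tracer equilibration before insulin
    clamp_duration: float = 180.0   # min of hyperinsulinemia
    sampling_interval: float = 10.0  # min
    weight: float = 28.5            # kg
    # controller (operator emulation): a positional PI law applied in
    # increment form at each sample, dGINF = Kp*(e_n - e_{n-1}) + Ki*e_n,
    # i.e. GINF_n = Kp*e_n + Ki*sum(e); gains chosen so default presets hold
    # the final-30-min glucose excursion well inside 5% despite assay noise
    Kp: float = 0.15    # mg/kg/min of GINF per mg/dl of glucose error
    Ki: float = 0.05    # mg/kg/min per mg/dl of accumulated error, per update
    update_interval: float = 10.0   # min between GINF adjustments
    controller_on: bool = True
    # assay noise
    cv_G: float = 0.02
    cv_I: float = 0.05
    tracer_count_sd: float = 1.0    # dpm/ml noise per sqrt(dpm/ml) counted
    # bookkeeping
    seed: int | None = None
    diet: str = "lean"
    state: str = "conscious"
    animal_id: str = "sim"
    enforce_protocol: bool = True   # range-check protocol fields

    def __post_init__(self) -> None:
        for name in ("G_b", "EGP_b", "V", "V_I", "n_I", "p2", "weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("tracer_prime_uCi", "tracer_rate_uCi_min", "sa_inf_uCi_g",
                     "insulin_rate", "cv_G", "cv_I", "tracer_count_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.enforce_protocol:
            if not 10.0 <= self.sampling_interval <= 15.0:
                raise ValueError("sampling_interval must be within [10, 15] min")
            if not 120.0 <= self.basal_duration <= 180.0:
                raise ValueError("basal_duration must be within [120, 180] min")

    # derived protocol quantities -------------------------------------------

    @property
    def sa_inf_dpm_mg(self) -> float:
        """Infusate specific activity in dpm/mg (2.7 uCi/g -> 5994 dpm/mg)."""
        return self.sa_inf_uCi_g * DPM_PER_UCI / 1000.0

    @property
    def fstar_pump(self) -> float:
        """Tracer pump rate per kg, dpm/kg/min."""
        return self.tracer_rate_uCi_min * DPM_PER_UCI / self.weight

    @property
    def total_duration(self) -> float:
        return self.basal_duration + self.clamp_duration

    @property
    def i_ss_analytic(self) -> float:
        """Closed-form steady-state insulin, 1000*rate/(n_I*V_I), uU/ml."""
        return 1000.0 * self.insulin_rate / (self.n_I * self.V_I)


@dataclass
class GroundTruth:
    """Noise-free simulator state and fluxes on a fine grid, plus the
    sensitivity endpoints the generator implies (computed with the same
    basal / final-30-min windowing conventions the analysis uses)."""

    time: np.ndarray       # min, fine grid
    G: np.ndarray          # mg/dl
    Cstar: np.ndarray      # dpm/dl
    I: np.ndarray          # uU/ml
    X: np.ndarray          # remote insulin, uU/ml
    GINF: np.ndarray       # mg/kg/min (right-continuous steps)
    EGP: np.ndarray        # mg/kg/min
    Rd: np.ndarray         # mg/kg/min
    Ra_total: np.ndarray   # mg/kg/min
    SA: np.ndarray         # dpm/mg
    glucose_balance: np.ndarray   # mass-balance residual, mg/kg
    tracer_balance: np.ndarray    # label-balance residual, dpm/kg
    Rd_basal: float
    EGP_basal: float
    Rd_SS: float
    EGP_SS: float
    G_SS: float
    I_SS: float
    dIns: float
    SI_P: float
    SI_H: float
    MCR: float


PRESETS: dict[str, dict[str, float | str]] = {
    # Conscious insulin action values put SI_P near 4-5 and SI_H near 0.8-1.4
    # (x1e-4 dl/kg/min per uU/ml); anesthetized presets halve s_P and push s_H
    # toward zero (lean) or below it (fat-fed), reproducing the direction of
    # the anesthesia effect with a near-total loss of hepatic insulin action.
    "lean_conscious": dict(s_P=4.7e-4, s_H=5.4e-3, diet="lean", state="conscious"),
    "lean_anesthetized": dict(s_P=2.3e-4, s_H=1.35e-3, diet="lean", state="anesthetized"),
    "fat_conscious": dict(s_P=4.0e-4, s_H=3.1e-3, diet="fat_fed", state="conscious"),
    "fat_anesthetized": dict(s_P=2.1e-4, s_H=-4.9e-4, diet="fat_fed", state="anesthetized"),
}

#: cohort structure: 16 lean conscious, 16 lean anesthetized,
#: 16 fat-fed conscious, 8 fat-fed anesthetized
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "lean_conscious": 16,
    "lean_anesthetized": 16,
    "fat_conscious": 16,
    "fat_anesthetized": 8,
}


def preset_config(name: str, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a named condition preset."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset '{name}' (choose from {sorted(PRESETS)})")
    params = dict(PRESETS[name])
    params.update(overrides)
    return SimulationConfig(animal_id=name, **params)


def _windowed_mean(t: np.ndarray, y: np.ndarray, start: float, end: float) -> float:
    mask = (t > start) & (t <= end)
    return float(np.mean(y[mask]))


def simulate_clamp(config: SimulationConfig,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[ClampRecord, GroundTruth]:
    """Integrate one virtual clamp; returns the sampled record and truth.

    Deterministic given ``config.seed`` (or an explicit ``rng``).  The
    controller adjusts GINF at each sample time from ``insulin_start`` on,
    acting on the *measured* (noisy) glucose value, exactly as a human
    operator would; the measured value it used is the one stored in the
    record.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    k_b = cfg.EGP_b / cfg.G_b
    fstar = cfg.fstar_pump
    sa_inf = cfg.sa_inf_dpm_mg
    t_ins = cfg.basal_duration
    T = cfg.total_duration

    # boundaries: every sample time, plus insulin start if off-grid
    sample_times = np.arange(0.0, T + 1e-9, cfg.sampling_interval)
    bounds = np.union1d(sample_times, [t_ins, T])

    def rhs(t, y, ginf, ins_on):
        G, C, I, X = y[:4]
        egp = max(0.0, cfg.EGP_b * (1.0 - cfg.s_H * X))
        rd = (k_b + cfg.s_P * X) * G
        dG = (egp + ginf - rd) / cfg.V
        dC = (fstar + ginf * sa_inf - rd * C / G) / cfg.V
        dI = (1000.0 * cfg.insulin_rate / cfg.V_I if ins_on else 0.0) - cfg.n_I * I
        dX = -cfg.p2 * (X - (I - cfg.I_b))
        # cumulative throughputs for mass-balance audits
        return (dG, dC, dI, dX,
                ginf, egp, rd,                       # glucose in/out, mg/kg
                fstar + ginf * sa_inf, rd * C / G)   # label in/out, dpm/kg

    C0 = cfg.tracer_prime_uCi * DPM_PER_UCI / (cfg.V * cfg.weight)
    y = np.array([cfg.G_b, C0, cfg.I_b, 0.0, 0, 0, 0, 0, 0], dtype=float)

    ginf = 0.0
    err_prev = 0.0
    fine_t: list[np.ndarray] = []
    fine_y: list[np.ndarray] = []
    fine_ginf: list[np.ndarray] = []
    rec_rows: list[tuple] = []

    def measure_and_control(t_now: float) -> None:
        nonlocal ginf, err_prev
        G_true, C_true, I_true = y[0], y[1], y[2]
        if abs(G_true - cfg.G_b) / cfg.G_b > 0.5:
            raise RuntimeError(
                f"clamp failed: |G - G_b|/G_b > 50% at t = {t_now:.0f} min "
                f"(G = {G_true:.1f} mg/dl)"
            )
        G_meas = G_true * (1.0 + cfg.cv_G * rng.standard_normal())
        I_meas = I_true * (1.0 + cfg.cv_I * rng.standard_normal())
        gstar_true = C_true / 100.0  # dpm/ml
        gstar_meas = gstar_true + cfg.tracer_count_sd * math.sqrt(max(gstar_true, 0.0)) \
            * rng.standard_normal()
        # record the infusion rate in effect while the sample was drawn;
        # the operator's adjustment applies from this instant onward
        rec_rows.append((t_now, G_meas, gstar_meas, I_meas, ginf))
        on_update_grid = (abs((t_now - t_ins) / cfg.update_interval
                              - round((t_now - t_ins) / cfg.update_interval)) < 1e-6)
        if cfg.controller_on and on_update_grid \
                and t_now >= t_ins - 1e-9 and t_now < T - 1e-9:
            err = cfg.G_b - G_meas
            ginf = max(0.0, ginf + cfg.Kp * (err - err_prev) + cfg.Ki * err)
            err_prev = err

    is_sample = np.isclose(bounds[:, None], sample_times[None, :]).any(axis=1)
    for i in range(len(bounds) - 1):
        t0, t1 = bounds[i], bounds[i + 1]
        if is_sample[i]:
            measure_and_control(t0)
        ins_on = t0 >= t_ins - 1e-9
        t_eval = np.append(np.arange(t0, t1, 1.0), t1)
        sol = solve_ivp(rhs, (t0, t1), y, t_eval=t_eval, args=(ginf, ins_on),
                        method="RK45", rtol=1e-9, atol=1e-9, dense_output=False)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"integrator error: {sol.message}")
        fine_t.append(sol.t[:-1])       # chunk end belongs to the next chunk
        fine_y.append(sol.y[:, :-1])
        fine_ginf.append(np.full(len(sol.t) - 1, ginf))
        y = sol.y[:, -1]
        if y[0] <= 0 or y[1] < 0:  # pragma: no cover
            raise RuntimeError("integrator error: negative state")
    # final sample at T
    if is_sample[-1]:
        measure_and_control(T)
    fine_t.append(np.array([T]))
    fine_y.append(y[:, None])
    fine_ginf.append(np.array([ginf]))

    tt = np.concatenate(fine_t)
    yy = np.concatenate(fine_y, axis=1)
    gg = np.concatenate(fine_ginf)

    G, C, I, X = yy[0], yy[1], yy[2], yy[3]
    EGP = np.maximum(0.0, cfg.EGP_b * (1.0 - cfg.s_H * X))
    Rd = (k_b + cfg.s_P * X) * G
    Ra = EGP + gg
    SA = C / G  # (dpm/dl)/(mg/dl) = dpm/mg
    glucose_balance = cfg.V * (G - cfg.G_b) - (yy[5] + yy[4] - yy[6])
    tracer_balance = cfg.V * (C - C0) - (yy[7] - yy[8])

    b0, b1 = t_ins - 30.0, t_ins
    s0, s1 = T - 30.0, T
    Rd_basal = _windowed_mean(tt, Rd, b0, b1)
    EGP_basal = _windowed_mean(tt, EGP, b0, b1)
    I_basal = _windowed_mean(tt, I, b0, b1)
    Rd_SS = _windowed_mean(tt, Rd, s0, s1)
    EGP_SS = _windowed_mean(tt, EGP, s0, s1)
    G_SS = _windowed_mean(tt, G, s0, s1)
    I_SS = _windowed_mean(tt, I, s0, s1)
    dIns = I_SS - I_basal
    # without insulin elevation the implied SI is undefined, not infinite
    denom = dIns * G_SS if dIns > 0 else np.nan
    truth = GroundTruth(
        time=tt, G=G, Cstar=C, I=I, X=X, GINF=gg, EGP=EGP, Rd=Rd, Ra_total=Ra,
        SA=SA, glucose_balance=glucose_balance, tracer_balance=tracer_balance,
        Rd_basal=Rd_basal, EGP_basal=EGP_basal, Rd_SS=Rd_SS, EGP_SS=EGP_SS,
        G_SS=G_SS, I_SS=I_SS, dIns=dIns,
        SI_P=1e4 * (Rd_SS - Rd_basal) / denom,
        SI_H=1e4 * (EGP_basal - EGP_SS) / denom,
        MCR=cfg.insulin_rate / I_SS if I_SS > 0 else np.nan,
    )

    rows = np.array(rec_rows)
    record = ClampRecord(
        time=rows[:, 0], G=rows[:, 1], Gstar=rows[:, 2], I=rows[:, 3],
        GINF=rows[:, 4], Fstar=np.full(len(rows), fstar),
        SA_inf=cfg.sa_inf_dpm_mg, weight=cfg.weight,
        insulin_rate=cfg.insulin_rate, insulin_start=t_ins,
        diet=cfg.diet, state=cfg.state, animal_id=cfg.animal_id,
    )
    return record, truth


def generate_cohort(n_per_group: int | dict[str, int] | None = None,
                    conditions: list[str] | None = None,
                    dispersion: float = 0.15,
                    seed: int | None = None,
                    **config_overrides,
                    ) -> list[tuple[ClampRecord, GroundTruth]]:
    """Simulate a cohort across condition presets with between-animal spread.

    Physiological parameters (EGP_b, s_P, s_H, n_I, and — at a quarter of
    the CV — G_b) vary log-normally around the preset means with coefficient
    of variation ``dispersion`` (sign-preserving for s_H); body weight is
    drawn normally around 28.5 kg (SD 2).  ``dispersion = 0`` disables all
    between-animal variation, body weight included.  ``n_per_group`` may be a single
    integer or a per-condition mapping; the default mirrors a 16/16/16/8
    design.  Fully reproducible per ``seed``.
    """
    if conditions is None:
        conditions = list(PRESETS)
    for c in conditions:
        if c not in PRESETS:
            raise ValueError(f"unknown preset '{c}'")
    if n_per_group is None:
        sizes = {c: DEFAULT_GROUP_SIZES[c] for c in conditions}
    elif isinstance(n_per_group, dict):
        sizes = {c: int(n_per_group[c]) for c in conditions}
    else:
        sizes = {c: int(n_per_group) for c in conditions}
    if any(n < 1 for n in sizes.values()):
        raise ValueError("n_per_group must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")

    ss = np.random.SeedSequence(seed)
    out: list[tuple[ClampRecord, GroundTruth]] = []
    for cond in conditions:
        children = ss.spawn(sizes[cond])
        for i, child in enumerate(children):
            rng = np.random.default_rng(child)
            base = preset_config(cond, **config_overrides)
            pert = replace(
                base,
                EGP_b=base.EGP_b * _lognormal_factor(rng, dispersion),
                s_P=base.s_P * _lognormal_factor(rng, dispersion),
                s_H=base.s_H * _lognormal_factor(rng, dispersion),
                n_I=base.n_I * _lognormal_factor(rng, dispersion),
                G_b=base.G_b * _lognormal_factor(rng, dispersion / 4.0),
                weight=(float(np.clip(28.5 + 2.0 * rng.standard_normal(), 15.0, 45.0))
                        if dispersion > 0 else 28.5),
                animal_id=f"{cond}_{i:03d}",
            )
            out.append(simulate_clamp(pert, rng=rng))
    return out


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean log-normal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0
    s = math.sqrt(math.log1p(cv * cv))
    return float(np.exp(s * rng.standard_normal() - 0.5 * s * s))
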