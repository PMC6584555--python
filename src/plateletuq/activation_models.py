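"""Platelet activation state (PAS) models along scalar stress histories.

Two model families are implemented, both phenomenological power laws in the
scalar stress τ (dyn/cm²) and exposure time (s), calibrated in
constant-shear devices:

* the three-parameter model (here "nobili"),

      dPAS/dt = c·a·τ^{b/a}·D^{a−1},   dD/dt = τ^{b/a},

  whose constant-stress solution is the classic power law
  PAS = c·τ^b·t^a;

* the seven-parameter additive-rate model ("soares", and its re-calibrated
  "consolo" variant),

      dPAS/dt = (S + F + G)·(1 − PAS),

  where S = S_r·PAS·H accounts for the accumulated stress H = ∫τ dt,
  F = C^{1/β}·β·PAS^{(β−1)/β}·τ^{α/β} for the instantaneous stress, and
  G = C_r^{1/δ}·δ·PAS^{(δ−1)/δ}·SR^{γ/δ} for the mean stress rate SR
  (running mean of |dτ/dt| from the path start, not the instantaneous
  derivative).

Integration is explicit Heun (trapezoidal) on the history's own grid.
PAS = 0 is a degenerate equilibrium of the F- and G-terms (and singular for
the exponents < 0 of the consolo set), so a start from PAS0 = 0 takes its
first step from the exact constant-input power-law increment instead of the
generic stepper; see the methods note.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .stress_signals import ScalarStressHistory, stress_accumulation, stress_rate

__all__ = [
    "NobiliParameters",
    "SoaresParameters",
    "ActivationTrajectory",
    "builtin_parameters",
    "integrate_nobili",
    "soares_terms",
    "integrate_soares",
    "integrate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NobiliParameters:
    """Exponents a (time), b (stress) and rate constant c.

    c absorbs (dyn/cm²)^{-b}·s^{-a} so PAS is dimensionless.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError("a, b and c must all be strictly positive")

    def asdict(self) -> dict[str, float]:
        return {"a": self.a, "b": self.b, "c": self.c}

    def replace(self, **kw) -> "NobiliParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class SoaresParameters:
    """Parameters of the additive S/F/G rate model.

    S_r drives the stress-history term, (C, alpha, beta) the instantaneous
    power law, (C_r, gamma, delta) the stress-rate power law.
    """

    S_r: float
    C: float
    alpha: float
    beta: float
    C_r: float
    gamma: float
    delta: float

    def __post_init__(self) -> None:
        for name in ("S_r", "C", "alpha", "beta", "C_r", "gamma", "delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def asdict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("S_r", "C", "alpha", "beta", "C_r", "gamma", "delta")}

    def replace(self, **kw) -> "SoaresParameters":
        return replace(self, **kw)


_BUILTIN = {
    "nobili": NobiliParameters(a=1.3198, b=0.6256, c=1e-5),
    "soares": SoaresParameters(
        S_r=1.5701e-7, C=1.4854e-7, alpha=1.4854, beta=1.4401,
        C_r=1.3889e-4, gamma=0.5720, delta=0.5125,
    ),
    "consolo": SoaresParameters(
        S_r=1.5701e-7, C=1.4854e-7, alpha=0.71825, beta=0.72005,
        C_r=2.78e-5, gamma=0.75, delta=0.5125,
    ),
}


def builtin_parameters(name: str):
    """Return one of the published calibrated parameter sets."""
    try:
        return _BUILTIN[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown parameter set {name!r}; choose from {sorted(_BUILTIN)}"
        ) from None


@dataclass(frozen=True)
class ActivationTrajectory:
    """PAS(t) with the model's history integral and per-term rates.

    ``history_integral`` is D for the nobili model ((dyn/cm²)^{b/a}·s) and
    H = ∫τ dt (dyn·s/cm²) for the soares family.  ``term_S/F/G`` (1/s) are
    the instantaneous additive rates along the trajectory (soares family
    only; 0 at the initial point where PAS = 0 by convention).
    """

    times: np.ndarray
    pas: np.ndarray
    history_integral: np.ndarray
    model: str
    term_S: np.ndarray | None = None
    term_F: np.ndarray | None = None
    term_G: np.ndarray | None = None

    @property
    def final_pas(self) -> float:
        return float(self.pas[-1])


def integrate_nobili(
    h: ScalarStressHistory,
    p: NobiliParameters,
    pas0: float = 0.0,
    d0: float = 0.0,
) -> ActivationTrajectory:
    """March the three-parameter model along a stress history.

    D is advanced with the trapezoidal rule (exact Heun step: its rate does
    not depend on the state).  The PAS rate c·a·τ^{b/a}·D^{a−1} is likewise
    trapezoidal, except that any interval starting at D = 0 uses the exact
    increment c·(D₁^a − D₀^a) valid when τ is constant over the step, which
    removes the D^{a−1} kink at the origin.  PAS is clamped at 1 with a
    logged warning if the power law exceeds the admissible range.
    """
    if pas0 < 0 or d0 < 0:
        raise ValueError("pas0 and d0 must be non-negative")
    k = h.tau ** (p.b / p.a)
    D = d0 + cumulative_trapezoid(k, h.times, initial=0.0)
    rate = p.c * p.a * k * D ** (p.a - 1.0)
    dts = np.diff(h.times)
    incr = 0.5 * dts * (rate[:-1] + rate[1:])
    zero_start = D[:-1] == 0.0
    if np.any(zero_start):
        incr[zero_start] = p.c * (D[1:][zero_start] ** p.a - D[:-1][zero_start] ** p.a)
    pas = pas0 + np.concatenate([[0.0], np.cumsum(incr)])
    if pas[-1] > 1.0:
        logger.warning(
            "nobili PAS exceeded 1 (%.3g) and was clamped; the power law is "
            "outside its admissible range", pas[-1],
        )
        pas = np.minimum(pas, 1.0)
    return ActivationTrajectory(h.times, pas, D, model="nobili")


def soares_terms(
    pas: float,
    tau: float,
    H: float,
    SR: float,
    p: SoaresParameters,
) -> tuple[float, float, float]:
    """Instantaneous additive rates (S, F, G) in 1/s.

    τ = 0 gives F = 0 and SR = 0 gives G = 0 (continuous limits).  When a
    PAS exponent (β−1)/β or (δ−1)/δ is negative and PAS = 0 the term is
    singular; the limit +inf is returned and the integrators avoid this
    state via the first-step bootstrap.
    """
    if pas < 0 or pas > 1 or tau < 0 or H < 0 or SR < 0:
        raise ValueError("soares_terms inputs must be non-negative with PAS in [0, 1]")
    S = p.S_r * pas * H
    F = _power_term(pas, tau, p.C, p.alpha, p.beta)
    G = _power_term(pas, SR, p.C_r, p.gamma, p.delta)
    return S, F, G


def _power_term(pas: float, x: float, coeff: float, num_exp: float, den_exp: float) -> float:
    """C^{1/β}·β·PAS^{(β−1)/β}·x^{α/β} with the PAS = 0 limits."""
    if x == 0.0:
        return 0.0
    e = (den_exp - 1.0) / den_exp
    if pas == 0.0:
        return 0.0 if e > 0 else (math.inf if e < 0 else
                                  coeff ** (1.0 / den_exp) * den_exp * x ** (num_exp / den_exp))
    return coeff ** (1.0 / den_exp) * den_exp * pas ** e * x ** (num_exp / den_exp)


def integrate_soares(
    h: ScalarStressHistory,
    p: SoaresParameters,
    include: Iterable[str] = ("S", "F", "G"),
    pas0: float = 0.0,
) -> ActivationTrajectory:
    """March dPAS/dt = (S + F + G)(1 − PAS) along a stress history.

    ``include`` selects which additive terms are active (e.g. ("S", "F")
    when the stress-rate contribution is to be excluded).  H(t) is the
    trapezoidal stress accumulation; SR(t) is the running cumulative mean
    of |Δτ|/Δt from the path start, recomputed each step.

    A start from PAS0 = 0 bootstraps the first step with the closed-form
    power-law increment PAS(Δt) = C·τ^α·Δt^β (+ C_r·SR^γ·Δt^δ when G is
    active): PAS = 0 is a degenerate equilibrium of the F/G terms for β > 1
    and a singular state for β < 1, and the closed form is the exact
    constant-input solution either way, making the result robust to the
    bootstrap step size.
    """
    include = frozenset(include)
    if not include:
        raise ValueError("include must name at least one of S, F, G")
    if not include <= {"S", "F", "G"}:
        raise ValueError(f"include must be a subset of {{'S','F','G'}}, got {sorted(include)}")
    if not 0 <= pas0 <= 1:
        raise ValueError("pas0 must lie in [0, 1]")

    _, H = stress_accumulation(h)
    _, SR = stress_rate(h, mode="cumulative_mean")
    tau = h.tau
    times = h.times
    n = times.size

    use_S, use_F, use_G = ("S" in include), ("F" in include), ("G" in include)

    def rate(pas, i):
        S = p.S_r * pas * H[i] if use_S else 0.0
        F = _power_term(pas, tau[i], p.C, p.alpha, p.beta) if use_F else 0.0
        G = _power_term(pas, SR[i], p.C_r, p.gamma, p.delta) if use_G else 0.0
        return (S + F + G) * (1.0 - pas), S, F, G

    pas = np.empty(n)
    tS = np.zeros(n)
    tF = np.zeros(n)
    tG = np.zeros(n)
    pas[0] = pas0
    if pas0 > 0:
        _, tS[0], tF[0], tG[0] = rate(pas0, 0)

    for i in range(n - 1):
        dt = times[i + 1] - times[i]
        if pas[i] == 0.0:
            # PAS = 0 is a degenerate equilibrium (β > 1) or singular state
            # (β < 1) of the F/G power laws; step off it with the exact
            # constant-input closed form instead of the generic stepper.
            tau_b = tau[i] if tau[i] > 0 else tau[i + 1]
            boot = 0.0
            if use_F and tau_b > 0:
                boot += p.C * tau_b ** p.alpha * dt ** p.beta
            if use_G and SR[i + 1] > 0:
                boot += p.C_r * SR[i + 1] ** p.gamma * dt ** p.delta
            pas[i + 1] = min(boot, 1.0)
            if pas[i + 1] > 0:
                _, tS[i + 1], tF[i + 1], tG[i + 1] = rate(pas[i + 1], i + 1)
            continue
        f0, *_ = rate(pas[i], i)
        pred = min(pas[i] + dt * f0, 1.0)
        f1, S1, F1, G1 = rate(pred, i + 1)
        new = pas[i] + 0.5 * dt * (f0 + f1)
        if new > 1.0 + 1e-9:
            if new > 1.5:
                raise RuntimeError(
                    f"divergent step at t = {times[i + 1]:.6g}: PAS = {new:.3g}; "
                    "refine the sampling grid"
                )
            new = 1.0
        pas[i + 1] = min(new, 1.0)
        _, tS[i + 1], tF[i + 1], tG[i + 1] = rate(pas[i + 1], i + 1)

    return ActivationTrajectory(
        times, pas, H, model="soares",
        term_S=tS if use_S else np.zeros(n),
        term_F=tF if use_F else np.zeros(n),
        term_G=tG if use_G else np.zeros(n),
    )


def integrate(h: ScalarStressHistory, params, **kw) -> ActivationTrajectory:
    """Dispatch on the parameter type (NobiliParameters vs SoaresParameters)."""
    if isinstance(params, NobiliParameters):
        return integrate_nobili(h, params, **kw)
    if isinstance(params, SoaresParameters):
        return integrate_soares(h, params, **kw)
    raise TypeError(f"unsupported parameter type {type(params).__name__}")
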