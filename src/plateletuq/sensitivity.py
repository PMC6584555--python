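"""Linearized (local) sensitivities of the three-parameter PAS model.

The sensitivity system is obtained by differentiating the model ODEs

    dPAS/dt = c·a·τ^{b/a}·D^{a−1},   dD/dt = τ^{b/a}

with respect to each parameter ζ ∈ {a, b, c} and to a multiplicative
rescaling of the whole stress history, and co-integrating the resulting
linear ODEs along the same path.  With P = c·τ^{b/a}·D^{a−1} the rates are

    d(∂PAS/∂a)/dt = P·[1 − (b·ln τ)/a + a·ln D + a(a−1)(∂D/∂a)/D]
    d(∂PAS/∂b)/dt = P·[ln τ + a(a−1)(∂D/∂b)/D]
    d(∂PAS/∂c)/dt = a·τ^{b/a}·D^{a−1}
    d(∂D/∂a)/dt   = −(b/a²)·τ^{b/a}·ln τ
    d(∂D/∂b)/dt   = (1/a)·τ^{b/a}·ln τ

and, for the stress-scale direction τ(t) → s·τ(t) evaluated at s = 1,

    d(∂PAS/∂s)/dt = P·a·[(b/a) + (a−1)(∂D/∂s)/D]
    d(∂D/∂s)/dt   = (b/a)·τ^{b/a}.

Every rate is independent of the PAS-sensitivities themselves, so the whole
system integrates by cumulative trapezoids (identical to a Heun march).
Terms of the form x^p·ln x are evaluated as their continuous limit 0 at
x = 0.  Under constant stress the closed forms of PAS = c·τ^b·t^a are
recovered: ∂PAS/∂a = PAS·ln t, ∂PAS/∂b = PAS·ln τ, ∂PAS/∂c = PAS/c,
∂PAS/∂s = b·PAS.

For the seven-parameter model family no analytic sensitivity system is
provided; use :func:`finite_difference_sensitivity`, which works for both
families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .activation_models import (
    NobiliParameters,
    SoaresParameters,
    integrate,
    integrate_nobili,
)
from .stress_signals import ScalarStressHistory

__all__ = [
    "SensitivityTrajectory",
    "integrate_nobili_sensitivities",
    "finite_difference_sensitivity",
    "perturbation_for_relative_error",
]


@dataclass(frozen=True)
class SensitivityTrajectory:
    """Parameter sensitivities of PAS (and D) along one stress history.

    ``dpas_dscale`` is the derivative with respect to a multiplicative
    rescaling s of the whole stress history at s = 1 (dimensionless
    direction); ``dpas_dtau`` expresses the same direction per unit stress,
    dividing by the time-mean of τ, so that under constant stress it equals
    the pointwise derivative c·b·τ^{b−1}·t^a.
    """

    times: np.ndarray
    pas: np.ndarray
    d: np.ndarray
    dpas_da: np.ndarray
    dpas_db: np.ndarray
    dpas_dc: np.ndarray
    dpas_dscale: np.ndarray
    dd_da: np.ndarray
    dd_db: np.ndarray
    dd_dscale: np.ndarray
    tau_ref: float

    @property
    def dpas_dtau(self) -> np.ndarray:
        return self.dpas_dscale / self.tau_ref

    @property
    def dd_dtau(self) -> np.ndarray:
        return self.dd_dscale / self.tau_ref

    def final(self) -> dict[str, float]:
        return {
            "pas": float(self.pas[-1]),
            "dpas_da": float(self.dpas_da[-1]),
            "dpas_db": float(self.dpas_db[-1]),
            "dpas_dc": float(self.dpas_dc[-1]),
            "dpas_dtau": float(self.dpas_dtau[-1]),
            "dpas_dscale": float(self.dpas_dscale[-1]),
        }


def _xlogx_factor(x: np.ndarray, power: float) -> np.ndarray:
    """x^power·ln x with the limit 0 at x = 0 (requires power > 0)."""
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] ** power * np.log(x[pos])
    return out


def integrate_nobili_sensitivities(
    h: ScalarStressHistory,
    p: NobiliParameters,
) -> SensitivityTrajectory:
    """Co-integrate PAS, D and their parameter sensitivities.

    The first interval (D = 0) is bootstrapped with the constant-stress
    closed forms evaluated at the elapsed step, removing the ln D
    singularity; thereafter trapezoidal cumulation applies.  If the stress
    is identically zero all sensitivities stay 0.
    """
    a, b, c = p.a, p.b, p.c
    tau = h.tau
    t = h.times
    if np.all(tau == 0):
        z = np.zeros_like(t)
        return SensitivityTrajectory(t, z, z, z, z, z, z, z, z, z, tau_ref=1.0)

    k = tau ** (b / a)                      # dD/dt
    klogtau = _xlogx_factor(tau, b / a)     # τ^{b/a}·ln τ, 0 at τ = 0
    D = cumulative_trapezoid(k, t, initial=0.0)

    dD_da = cumulative_trapezoid(-(b / a**2) * klogtau, t, initial=0.0)
    dD_db = cumulative_trapezoid(klogtau / a, t, initial=0.0)
    dD_ds = cumulative_trapezoid((b / a) * k, t, initial=0.0)

    Dpow = np.where(D > 0, D, 1.0) ** (a - 1.0)
    Dpow[D == 0] = 0.0
    P = c * k * Dpow                        # c·τ^{b/a}·D^{a−1}
    with np.errstate(divide="ignore", invalid="ignore"):
        logD = np.where(D > 0, np.log(np.where(D > 0, D, 1.0)), 0.0)
        rat_a = np.where(D > 0, dD_da / np.where(D > 0, D, 1.0), 0.0)
        rat_b = np.where(D > 0, dD_db / np.where(D > 0, D, 1.0), 0.0)
        rat_s = np.where(D > 0, dD_ds / np.where(D > 0, D, 1.0), 0.0)
    logtau = np.where(tau > 0, np.log(np.where(tau > 0, tau, 1.0)), 0.0)

    r_pa = P * (1.0 - (b / a) * logtau + a * logD + a * (a - 1.0) * rat_a)
    r_pb = P * (logtau + a * (a - 1.0) * rat_b)
    r_pc = a * k * Dpow
    r_ps = P * a * ((b / a) + (a - 1.0) * rat_s)
    # P·a·ln D → 0 as D → 0 (power beats log), but the grid value at the
    # first positive D is finite and the t = 0 node is exactly 0, so the
    # plain trapezoid under-resolves the first interval; replace it with the
    # constant-stress closed forms at the elapsed time below.
    dpas_da = cumulative_trapezoid(r_pa, t, initial=0.0)
    dpas_db = cumulative_trapezoid(r_pb, t, initial=0.0)
    dpas_dc = cumulative_trapezoid(r_pc, t, initial=0.0)
    dpas_ds = cumulative_trapezoid(r_ps, t, initial=0.0)

    i1 = int(np.argmax(D > 0))  # first node with D > 0
    if i1 > 0 and tau[i1 - 1] > 0:
        dt0 = t[i1] - t[i1 - 1]
        tau0 = tau[i1 - 1]
        pas_b = c * tau0**b * dt0**a
        corr = {
            "a": pas_b * math.log(dt0) - dpas_da[i1],
            "b": pas_b * math.log(tau0) - dpas_db[i1],
            "c": pas_b / c - dpas_dc[i1],
            "s": pas_b * b - dpas_ds[i1],
        }
        dpas_da[i1:] += corr["a"]
        dpas_db[i1:] += corr["b"]
        dpas_dc[i1:] += corr["c"]
        dpas_ds[i1:] += corr["s"]

    pas = integrate_nobili(h, p).pas
    tau_ref = float(np.trapezoid(tau, t) / (t[-1] - t[0]))
    return SensitivityTrajectory(
        t, pas, D, dpas_da, dpas_db, dpas_dc, dpas_ds,
        dD_da, dD_db, dD_ds, tau_ref=tau_ref,
    )


def finite_difference_sensitivity(
    h: ScalarStressHistory,
    p,
    which: str,
    rel_step: float = 1e-5,
    **integrate_kw,
) -> np.ndarray:
    """Central-difference sensitivity of the PAS trajectory.

    ``which`` names a parameter of ``p`` (e.g. ``"a"`` or ``"beta"``) or
    ``"tau"``, in which case the whole stress series is scaled by
    (1 ± rel_step) and the result is expressed per unit stress (divided by
    the time-mean of τ), matching ``SensitivityTrajectory.dpas_dtau``.
    Works for both model families; returns the full trajectory series.
    """
    if rel_step <= 0:
        raise ValueError("rel_step must be positive")
    if which == "tau":
        if np.all(h.tau == 0):
            return np.zeros_like(h.times)
        hi = integrate(h.scaled(1.0 + rel_step), p, **integrate_kw).pas
        lo = integrate(h.scaled(1.0 - rel_step), p, **integrate_kw).pas
        tau_ref = float(np.trapezoid(h.tau, h.times) / (h.times[-1] - h.times[0]))
        return (hi - lo) / (2.0 * rel_step) / tau_ref
    value = getattr(p, which, None)
    if value is None:
        raise ValueError(f"{type(p).__name__} has no parameter {which!r}")
    if value == 0:
        raise ValueError(f"cannot take a relative step on {which} = 0")
    hi = integrate(h, p.replace(**{which: value * (1.0 + rel_step)}), **integrate_kw).pas
    lo = integrate(h, p.replace(**{which: value * (1.0 - rel_step)}), **integrate_kw).pas
    return (hi - lo) / (2.0 * rel_step * value)


def perturbation_for_relative_error(
    s: SensitivityTrajectory,
    p: NobiliParameters,
    target_rel_error: float = 1.0,
) -> dict[str, float]:
    """First-order relative parameter errors producing a target PAS error.

    For each parameter ζ returns (target·PAS_final / |∂PAS/∂ζ|) / |ζ| — the
    relative perturbation of ζ that, to first order, changes the final PAS
    by ``target_rel_error`` of itself.  The key ``"tau"`` refers to the
    multiplicative stress-scale direction (|ζ| = 1).  A zero derivative is
    reported as ``inf`` (unbounded: PAS is first-order insensitive).
    """
    pas_final = float(s.pas[-1])
    if pas_final <= 0:
        raise ValueError("final PAS must be positive")
    if target_rel_error < 0:
        raise ValueError("target_rel_error must be non-negative")
    finals = {
        "a": (float(s.dpas_da[-1]), p.a),
        "b": (float(s.dpas_db[-1]), p.b),
        "c": (float(s.dpas_dc[-1]), p.c),
        "tau": (float(s.dpas_dscale[-1]), 1.0),
    }
    out = {}
    for name, (deriv, scale) in finals.items():
        if target_rel_error == 0:
            out[name] = 0.0
        elif deriv == 0:
            out[name] = math.inf
        else:
            out[name] = target_rel_error * pas_final / abs(deriv) / abs(scale)
    return out
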