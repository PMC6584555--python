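"""Tracer advection through canonical analytic velocity fields.

Stand-ins for a resolved pump flow: each field provides an analytic
velocity and velocity gradient, so the Newtonian viscous stress tensor
τ_ij = μ(∂u_i/∂x_j + ∂u_j/∂x_i) along a platelet path is exact.  Platelets
(≈2 μm) have Stokes numbers of order 1e-4–1e-2 in such devices, so the
default advection mode is a passive tracer (u_p = u_fluid); an inertial
mode integrating Stokes drag with relaxation time ρ_p·d²/(18μ) is kept for
checking that asymptotics.

Fields are 3-D Cartesian; axisymmetric profiles are evaluated by rotation.
Defaults ρ = 998 kg/m³ and ν = 0.9e-6 m²/s give μ = 8.982e-4 Pa·s
(blood-analog fluid).  Stress tensors are reported in dyn/cm² (1 Pa = 10
dyn/cm²) so they feed directly into the stress-history machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stress_signals import PA_TO_DYN_CM2, TensorStressHistory

__all__ = [
    "RHO_DEFAULT",
    "NU_DEFAULT",
    "PlateletProperties",
    "AnalyticField",
    "UniformField",
    "CouetteField",
    "SolidRotationField",
    "TaylorCouetteAnnulusField",
    "LambOseenField",
    "analytic_field",
    "TracerPath",
    "advect",
    "stress_along_path",
    "relaxation_time",
    "stokes_number",
    "check_gradient",
]

RHO_DEFAULT = 998.0       # kg/m³
NU_DEFAULT = 0.9e-6       # m²/s


@dataclass(frozen=True)
class PlateletProperties:
    """Rigid-sphere platelet: diameter 2 μm, density slightly above plasma."""

    diameter: float = 2e-6   # m
    density: float = 1040.0  # kg/m³


class AnalyticField:
    """Base class: velocity/velocity-gradient evaluators plus viscosity."""

    def __init__(self, rho: float = RHO_DEFAULT, nu: float = NU_DEFAULT) -> None:
        if rho <= 0 or nu <= 0:
            raise ValueError("density and kinematic viscosity must be positive")
        self.rho = rho
        self.nu = nu

    @property
    def mu(self) -> float:
        """Dynamic viscosity μ = ρ·ν in Pa·s."""
        return self.rho * self.nu

    def velocity(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def velocity_gradient(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        """∂u_i/∂x_j as a (3, 3) array."""
        raise NotImplementedError

    def in_domain(self, x: np.ndarray) -> bool:
        return True


class UniformField(AnalyticField):
    def __init__(self, u0=(1.0, 0.0, 0.0), **kw) -> None:
        super().__init__(**kw)
        self.u0 = np.asarray(u0, dtype=float)

    def velocity(self, x):
        return self.u0.copy()

    def velocity_gradient(self, x):
        return np.zeros((3, 3))


class CouetteField(AnalyticField):
    """Plane Couette flow u = (γ̇·y, 0, 0) with constant shear rate γ̇ (1/s)."""

    def __init__(self, shear_rate: float, **kw) -> None:
        super().__init__(**kw)
        self.shear_rate = float(shear_rate)

    def velocity(self, x):
        return np.array([self.shear_rate * x[1], 0.0, 0.0])

    def velocity_gradient(self, x):
        g = np.zeros((3, 3))
        g[0, 1] = self.shear_rate
        return g


class _AzimuthalField(AnalyticField):
    """u = f(r)·e_θ around the z axis; subclasses provide f and f'.

    With g(r) = f(r)/r the Cartesian gradient is
    ∂u_x/∂x = −x·y·g'/r, ∂u_x/∂y = −g − y²·g'/r,
    ∂u_y/∂x =  g + x²·g'/r, ∂u_y/∂y =  x·y·g'/r.
    """

    def _f(self, r: float) -> float:  # pragma: no cover
        raise NotImplementedError

    def _g_gprime(self, r: float) -> tuple[float, float]:  # pragma: no cover
        raise NotImplementedError

    def velocity(self, x):
        r = float(np.hypot(x[0], x[1]))
        if r == 0.0:
            return np.zeros(3)
        f = self._f(r)
        return np.array([-f * x[1] / r, f * x[0] / r, 0.0])

    def velocity_gradient(self, x):
        r = float(np.hypot(x[0], x[1]))
        grad = np.zeros((3, 3))
        if r == 0.0:
            g, _ = self._g_gprime(1e-300)
            grad[0, 1], grad[1, 0] = -g, g
            return grad
        g, gp = self._g_gprime(r)
        xx, yy = x[0], x[1]
        grad[0, 0] = -xx * yy * gp / r
        grad[0, 1] = -g - yy**2 * gp / r
        grad[1, 0] = g + xx**2 * gp / r
        grad[1, 1] = xx * yy * gp / r
        return grad


class SolidRotationField(_AzimuthalField):
    """Rigid-body rotation u_θ = Ω·r: zero strain rate, zero viscous stress."""

    def __init__(self, omega: float, **kw) -> None:
        super().__init__(**kw)
        self.omega = float(omega)

    def _f(self, r):
        return self.omega * r

    def _g_gprime(self, r):
        return self.omega, 0.0


class TaylorCouetteAnnulusField(_AzimuthalField):
    """Laminar annulus profile u_θ = A·r + B/r between rotating cylinders.

    A = (Ω_o·R_o² − Ω_i·R_i²)/(R_o² − R_i²),
    B = (Ω_i − Ω_o)·R_i²·R_o²/(R_o² − R_i²).
    Used as a stand-in for the narrow gap between a levitated rotating
    magnet house and the pump housing.
    """

    def __init__(self, omega_inner: float, r_inner: float, r_outer: float,
                 omega_outer: float = 0.0, **kw) -> None:
        super().__init__(**kw)
        if not 0 < r_inner < r_outer:
            raise ValueError("need 0 < r_inner < r_outer")
        self.r_inner, self.r_outer = float(r_inner), float(r_outer)
        self.omega_inner, self.omega_outer = float(omega_inner), float(omega_outer)
        d = r_outer**2 - r_inner**2
        self.A = (omega_outer * r_outer**2 - omega_inner * r_inner**2) / d
        self.B = (omega_inner - omega_outer) * r_inner**2 * r_outer**2 / d

    def _f(self, r):
        return self.A * r + self.B / r

    def _g_gprime(self, r):
        return self.A + self.B / r**2, -2.0 * self.B / r**3

    def in_domain(self, x):
        r = float(np.hypot(x[0], x[1]))
        return self.r_inner - 1e-12 <= r <= self.r_outer + 1e-12


class LambOseenField(_AzimuthalField):
    """Lamb–Oseen vortex u_θ = Γ/(2πr)·(1 − e^{−r²/r_c²})."""

    def __init__(self, circulation: float, core_radius: float, **kw) -> None:
        super().__init__(**kw)
        if core_radius <= 0:
            raise ValueError("core_radius must be positive")
        self.circulation = float(circulation)
        self.core_radius = float(core_radius)

    def _f(self, r):
        return self.circulation / (2 * np.pi * r) * (1.0 - np.exp(-(r / self.core_radius) ** 2))

    def _g_gprime(self, r):
        E = np.exp(-(r / self.core_radius) ** 2)
        g = self.circulation / (2 * np.pi) * (1.0 - E) / r**2
        gp = self.circulation / np.pi * ((r**2 / self.core_radius**2) * E - (1.0 - E)) / r**3
        return g, gp


_FIELDS = {
    "uniform": UniformField,
    "couette": CouetteField,
    "solid_rotation": SolidRotationField,
    "taylor_couette_annulus": TaylorCouetteAnnulusField,
    "lamb_oseen": LambOseenField,
}


def analytic_field(name: str, **params) -> AnalyticField:
    """Construct a field by name (see :data:`_FIELDS` keys)."""
    try:
        cls = _FIELDS[name]
    except KeyError:
        raise ValueError(f"unknown field {name!r}; choose from {sorted(_FIELDS)}") from None
    return cls(**params)


@dataclass(frozen=True)
class TracerPath:
    """Particle path: times (s), positions (n, 3) m, velocities (n, 3) m/s."""

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    truncated: bool = False


def relaxation_time(platelet: PlateletProperties, mu: float) -> float:
    """Stokes relaxation time ρ_p·d²/(18μ) in seconds."""
    return platelet.density * platelet.diameter**2 / (18.0 * mu)


def stokes_number(relaxation: float, flow_time: float) -> float:
    """St = particle relaxation time / flow time scale."""
    if relaxation <= 0 or flow_time <= 0:
        raise ValueError("both time scales must be positive")
    return relaxation / flow_time


def advect(
    field: AnalyticField,
    x0,
    duration: float,
    dt: float,
    inertial: bool = False,
    platelet: PlateletProperties = PlateletProperties(),
) -> TracerPath:
    """Integrate a tracer through the field with the trapezoidal (Heun) rule.

    Passive mode sets u_p = u_fluid(x_p); inertial mode integrates Stokes
    drag du_p/dt = (u_fluid − u_p)/τ_p.  If the tracer exits the field's
    domain the path is truncated there and flagged.
    """
    x = np.asarray(x0, dtype=float)
    if x.shape != (3,):
        raise ValueError("x0 must be a 3-vector")
    if not field.in_domain(x):
        raise ValueError("x0 is outside the field's domain")
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n = int(round(duration / dt))
    times = np.linspace(0.0, n * dt, n + 1)
    pos = np.empty((n + 1, 3))
    vel = np.empty((n + 1, 3))
    pos[0] = x
    tau_p = relaxation_time(platelet, field.mu)
    u_p = field.velocity(x)
    vel[0] = u_p
    truncated = False
    for i in range(n):
        if inertial:
            a0 = (field.velocity(pos[i]) - u_p) / tau_p
            x_pred = pos[i] + dt * u_p
            u_pred = u_p + dt * a0
            a1 = (field.velocity(x_pred) - u_pred) / tau_p
            x_new = pos[i] + 0.5 * dt * (u_p + u_pred)
            u_p = u_p + 0.5 * dt * (a0 + a1)
        else:
            v0 = field.velocity(pos[i])
            v1 = field.velocity(pos[i] + dt * v0)
            x_new = pos[i] + 0.5 * dt * (v0 + v1)
            u_p = field.velocity(x_new)
        if not field.in_domain(x_new):
            warnings.warn("tracer left the field domain; path truncated", stacklevel=2)
            times = times[: i + 1]
            pos = pos[: i + 1]
            vel = vel[: i + 1]
            truncated = True
            break
        pos[i + 1] = x_new
        vel[i + 1] = u_p
    return TracerPath(times, pos, vel, truncated=truncated)


def stress_along_path(field: AnalyticField, path: TracerPath) -> TensorStressHistory:
    """Newtonian viscous stress τ_ij = μ(∂u_i/∂x_j + ∂u_j/∂x_i) along a path.

    Returned in dyn/cm², ordered (xx, yy, zz, xy, xz, yz).
    """
    mu = field.mu
    comp = np.empty((path.times.size, 6))
    for i, x in enumerate(path.positions):
        g = field.velocity_gradient(x)
        s = mu * (g + g.T) * PA_TO_DYN_CM2
        comp[i] = (s[0, 0], s[1, 1], s[2, 2], s[0, 1], s[0, 2], s[1, 2])
    return TensorStressHistory(path.times, comp)


def check_gradient(field: AnalyticField, x, h: float = 1e-6) -> float:
    """Max relative mismatch between analytic and central-difference ∇u.

    Used to assert that a field's velocity and gradient evaluators are
    mutually consistent.
    """
    x = np.asarray(x, dtype=float)
    g = field.velocity_gradient(x)
    num = np.zeros((3, 3))
    for j in range(3):
        e = np.zeros(3)
        e[j] = h
        num[:, j] = (field.velocity(x + e) - field.velocity(x - e)) / (2 * h)
    scale = max(np.abs(g).max(), np.abs(num).max(), 1e-300)
    return float(np.abs(g - num).max() / scale)
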