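"""Lagrangian scalar/tensor stress histories and their summary statistics.

All stresses are carried in dyn/cm² internally (the unit system in which the
activation-model parameters are calibrated); Pa appears only at I/O
boundaries and is converted by the factor 10.

The scalar contractions of the symmetric viscous stress tensor, the stress
accumulation SA = ∫ τ dt and the stress rate SR (mean absolute Lagrangian
time derivative of τ) defined here are the inputs consumed by the activation
models.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "TENSOR_COMPONENTS",
    "PA_TO_DYN_CM2",
    "ScalarStressHistory",
    "TensorStressHistory",
    "StressSummary",
    "contract_tensor",
    "generate_uniform_stress",
    "generate_pump_like_stress",
    "stress_accumulation",
    "stress_rate",
    "summarize_stress",
    "read_stress_history",
    "write_stress_history",
]

#: order of the six unique components of the symmetric stress tensor
TENSOR_COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")

#: 1 Pa = 10 dyn/cm²
PA_TO_DYN_CM2 = 10.0


def _validate_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("a stress history needs at least 2 samples")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    return times


@dataclass(frozen=True)
class ScalarStressHistory:
    """Scalar stress τ(t) ≥ 0 in dyn/cm² sampled along one platelet path."""

    times: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        times = _validate_times(self.times)
        tau = np.asarray(self.tau, dtype=float)
        if tau.shape != times.shape:
            raise ValueError("tau must have the same length as times")
        if np.any(np.isnan(tau)):
            raise ValueError("stress history contains NaN")
        if np.any(tau < 0):
            raise ValueError("scalar stress must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "tau", tau)

    @property
    def residence_time(self) -> float:
        return float(self.times[-1] - self.times[0])

    def scaled(self, factor: float) -> "ScalarStressHistory":
        """Same history with the whole stress series multiplied by ``factor``."""
        return ScalarStressHistory(self.times, self.tau * factor)


@dataclass(frozen=True)
class TensorStressHistory:
    """Six unique components of the symmetric stress tensor vs. time.

    ``components`` has shape (n, 6) ordered as :data:`TENSOR_COMPONENTS`,
    in dyn/cm².
    """

    times: np.ndarray
    components: np.ndarray

    def __post_init__(self) -> None:
        times = _validate_times(self.times)
        comp = np.asarray(self.components, dtype=float)
        if comp.shape != (times.size, 6):
            raise ValueError(
                "components must have shape (len(times), 6) "
                f"ordered {TENSOR_COMPONENTS}"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "components", comp)

    def component(self, name: str) -> np.ndarray:
        return self.components[:, TENSOR_COMPONENTS.index(name)]


@dataclass(frozen=True)
class StressSummary:
    """SA / SR statistics of a scalar stress history."""

    sa: float  # dyn·s/cm²
    sr: float  # dyn/(cm²·s)
    residence_time: float  # s
    tau_min: float  # dyn/cm²
    tau_max: float  # dyn/cm²


def contract_tensor(history: TensorStressHistory, variant: str = "a") -> ScalarStressHistory:
    """Contract a stress-tensor history to a scalar stress series.

    Variants (all non-negative, positively homogeneous of degree one):

    ``"a"``
        von-Mises-like form,
        √[(1/6)((τxx−τyy)² + (τyy−τzz)² + (τzz−τxx)²) + τxy² + τxz² + τyz²].
        Returns exactly the applied shear for a single-shear-component
        tensor, which is the loading state of the shearing devices the
        activation models were calibrated in.
    ``"b"``
        shear-only RMS, √[(1/3) Σ_{i≠j} τij τji] with each unordered shear
        pair counted twice (ordered-pair sum).
    ``"b_single"``
        literal single count of each unordered shear pair,
        √[(1/3)(τxy² + τxz² + τyz²)].
    ``"c"``
        normal-only RMS, √[(1/3)(τxx² + τyy² + τzz²)].
    """
    xx, yy, zz, xy, xz, yz = (history.component(k) for k in TENSOR_COMPONENTS)
    if variant == "a":
        tau = np.sqrt(
            ((xx - yy) ** 2 + (yy - zz) ** 2 + (zz - xx) ** 2) / 6.0
            + xy**2 + xz**2 + yz**2
        )
    elif variant == "b":
        tau = np.sqrt(2.0 * (xy**2 + xz**2 + yz**2) / 3.0)
    elif variant == "b_single":
        tau = np.sqrt((xy**2 + xz**2 + yz**2) / 3.0)
    elif variant == "c":
        tau = np.sqrt((xx**2 + yy**2 + zz**2) / 3.0)
    else:
        raise ValueError(f"unknown contraction variant {variant!r}")
    return ScalarStressHistory(history.times, tau)


def generate_uniform_stress(
    tau0: float,
    amp_frac: float = 0.0,
    freq: float = 50.0,
    duration: float = 1.0,
    dt: float = 1e-4,
) -> ScalarStressHistory:
    """Uniform stress with a sinusoidal modulation.

    τ(t) = tau0 · (1 + amp_frac · sin(2π·freq·t)) on a uniform grid that
    includes both endpoints.  ``tau0`` in dyn/cm².
    """
    if tau0 < 0:
        raise ValueError("tau0 must be non-negative")
    if not 0 <= amp_frac < 1:
        raise ValueError("amp_frac must lie in [0, 1) so the stress stays positive")
    if dt <= 0 or duration <= 0:
        raise ValueError("duration and dt must be positive")
    n = int(round(duration / dt))
    times = np.linspace(0.0, n * dt, n + 1)
    tau = tau0 * (1.0 + amp_frac * np.sin(2.0 * np.pi * freq * times))
    return ScalarStressHistory(times, tau)


def generate_pump_like_stress(
    schedule,
    dt: float = 1e-4,
    seed: int | None = None,
) -> ScalarStressHistory:
    """Piecewise stress schedule emulating a platelet path through a pump.

    ``schedule`` is a list of regions ``(duration_s, mean_tau)`` or
    ``(duration_s, mean_tau, fluctuation_frac, fluctuation_freq)``.  Within
    each region the mean stress is modulated by a seeded band-limited
    fluctuation (random-phase harmonics up to ``fluctuation_freq``) whose
    standard deviation is ``fluctuation_frac · mean_tau``.  Region
    boundaries may jump abruptly, e.g. by two orders of magnitude when a
    platelet enters the narrow rotating gap.  Deterministic for a fixed
    seed; the result is clipped at zero.
    """
    if not schedule:
        raise ValueError("schedule must contain at least one region")
    rng = np.random.default_rng(seed)
    pieces_t, pieces_tau = [], []
    t0 = 0.0
    for region in schedule:
        if len(region) == 2:
            dur, mean_tau = region
            fluct_frac, fluct_freq = 0.0, 0.0
        else:
            dur, mean_tau, fluct_frac, fluct_freq = region
        if dur <= 0:
            raise ValueError("region durations must be positive")
        if mean_tau < 0:
            raise ValueError("region mean stresses must be non-negative")
        n = max(int(round(dur / dt)), 1)
        t = t0 + dt * np.arange(n)
        tau = np.full(n, float(mean_tau))
        if fluct_frac > 0 and fluct_freq > 0:
            n_harm = 8
            freqs = rng.uniform(0.1 * fluct_freq, fluct_freq, n_harm)
            phases = rng.uniform(0, 2 * np.pi, n_harm)
            amps = rng.uniform(0.5, 1.0, n_harm)
            w = np.zeros(n)
            for f, ph, am in zip(freqs, phases, amps):
                w += am * np.sin(2 * np.pi * f * t + ph)
            w_std = w.std()
            if w_std > 0:
                tau += mean_tau * fluct_frac * w / w_std
        pieces_t.append(t)
        pieces_tau.append(tau)
        t0 += n * dt
    times = np.concatenate(pieces_t + [[t0]])
    tau = np.concatenate(pieces_tau + [[pieces_tau[-1][-1]]])
    return ScalarStressHistory(times, np.clip(tau, 0.0, None))


def stress_accumulation(h: ScalarStressHistory) -> tuple[float, np.ndarray]:
    """Stress accumulation SA = ∫ τ dt (trapezoidal) and the running H(t).

    Returns ``(SA, H)`` with ``H`` the cumulative integral on the history
    grid (``H[0] = 0``); SA is the final value of H.  Units dyn·s/cm².
    """
    H = cumulative_trapezoid(h.tau, h.times, initial=0.0)
    return float(H[-1]), H


def stress_rate(h: ScalarStressHistory, mode: str = "final_mean") -> tuple[float, np.ndarray]:
    """Stress rate SR: mean of |Δτ|/Δt over the intervals of the path.

    ``mode="final_mean"`` returns the whole-path scalar; the series is then
    the per-interval |Δτ|/Δt aligned to interval right edges (0 at t0).
    ``mode="cumulative_mean"`` returns the running mean from the path start
    up to each time (the form fed to the stress-rate activation term), and
    the scalar is its final value.  Non-uniform grids use per-interval Δt.
    """
    dt = np.diff(h.times)
    rates = np.abs(np.diff(h.tau)) / dt
    if mode == "final_mean":
        series = np.concatenate([[0.0], rates])
        return float(rates.mean()), series
    if mode == "cumulative_mean":
        running = np.concatenate([[0.0], np.cumsum(rates) / np.arange(1, rates.size + 1)])
        return float(running[-1]), running
    raise ValueError(f"unknown stress_rate mode {mode!r}")


def summarize_stress(h: ScalarStressHistory) -> StressSummary:
    sa, _ = stress_accumulation(h)
    sr, _ = stress_rate(h, mode="final_mean")
    return StressSummary(
        sa=sa,
        sr=sr,
        residence_time=h.residence_time,
        tau_min=float(h.tau.min()),
        tau_max=float(h.tau.max()),
    )


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

_SCALAR_COLS = ["time", "tau"]
_TENSOR_COLS = ["time", *TENSOR_COMPONENTS]


def write_stress_history(h, path, units: str = "dyn/cm2", seed=None) -> None:
    """Write a scalar or tensor history as commented CSV (always dyn/cm²)."""
    if units not in ("dyn/cm2",):
        raise ValueError("histories are written in dyn/cm2")
    with open(path, "w") as fh:
        fh.write("# units: dyn/cm2\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if isinstance(h, ScalarStressHistory):
            df = pd.DataFrame({"time": h.times, "tau": h.tau})
        elif isinstance(h, TensorStressHistory):
            df = pd.DataFrame({"time": h.times})
            for i, k in enumerate(TENSOR_COMPONENTS):
                df[k] = h.components[:, i]
        else:
            raise TypeError("expected a ScalarStressHistory or TensorStressHistory")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_stress_history(path):
    """Read a history written by :func:`write_stress_history` or compatible.

    The file must carry a ``time`` column plus either ``tau`` (scalar) or
    the six tensor components.  A ``# units: Pa`` header comment triggers
    conversion to dyn/cm² (×10); the default is dyn/cm².
    """
    units = "dyn/cm2"
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        if "units:" in line:
            units = line.split("units:")[1].strip()
    factor = PA_TO_DYN_CM2 if units.lower() in ("pa", "pascal") else 1.0
    df = pd.read_csv(io.StringIO(text), comment="#")
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if set(_TENSOR_COLS) <= set(cols):
        comp = np.column_stack([df[k].to_numpy(float) for k in TENSOR_COMPONENTS])
        return TensorStressHistory(df["time"].to_numpy(float), comp * factor)
    if set(_SCALAR_COLS) <= set(cols):
        return ScalarStressHistory(df["time"].to_numpy(float), df["tau"].to_numpy(float) * factor)
    raise ValueError(
        f"file must contain columns {_SCALAR_COLS} or {_TENSOR_COLS}, got {cols}"
    )
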