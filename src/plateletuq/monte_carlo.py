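"""Monte-Carlo uncertainty quantification of the PAS models.

Model parameters (and optionally a multiplicative stress scale) are
perturbed by factors (1 + amplitude·z), z ~ N(0, 1), and the activation ODE
is re-integrated for every sample.  Two perturbation modes are offered:

``per_timestep``
    all targeted quantities are redrawn at every integration step
    (default), emulating uncorrelated model error along the path;
``per_sample``
    one static draw per sample, emulating calibration uncertainty.

Draws that would make an intrinsically positive quantity non-positive are
rejected and redrawn (clamping would bias the ensemble mean at large
amplitudes).  Everything is reproducible from the integer seed.

The ensembles report mean/variance/standard error and, because extreme
activations matter more for thrombosis risk than the population mean,
median, quartiles, 2.5/97.5% quantiles and extremes as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .activation_models import NobiliParameters, SoaresParameters
from .stress_signals import ScalarStressHistory, stress_accumulation, stress_rate

__all__ = [
    "PerturbationSpec",
    "MCEnsemble",
    "PopulationSummary",
    "perturb",
    "run_mc",
    "required_sample_size",
    "population_statistics",
]

STRESS_TARGET = "stress_scale"

_NOBILI_PARAMS = ("a", "b", "c")
_SOARES_PARAMS = ("S_r", "C", "alpha", "beta", "C_r", "gamma", "delta")


@dataclass(frozen=True)
class PerturbationSpec:
    """What to perturb, how strongly, and how often.

    ``targets = None`` means every model parameter (the stress scale is
    only perturbed when named explicitly).  ``amplitude`` is the relative
    standard deviation of the normal perturbation factor.
    """

    amplitude: float
    targets: tuple[str, ...] | None = None
    mode: str = "per_timestep"
    n_samples: int = 250
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        if self.mode not in ("per_timestep", "per_sample"):
            raise ValueError("mode must be 'per_timestep' or 'per_sample'")


@dataclass(frozen=True)
class MCEnsemble:
    """Per-sample final PAS values with summary statistics."""

    samples: np.ndarray
    spec: PerturbationSpec
    unperturbed: float
    draws: dict[str, np.ndarray] = field(default_factory=dict)
    n_truncated: int = 0

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def variance(self) -> float:
        return float(self.samples.var(ddof=1)) if self.samples.size > 1 else 0.0

    @property
    def std_error(self) -> float:
        return math.sqrt(self.variance / self.samples.size)

    @property
    def median(self) -> float:
        return float(np.median(self.samples))

    def quantile(self, q) -> float:
        return float(np.quantile(self.samples, q))

    def summary(self) -> dict[str, float]:
        return {
            "n": int(self.samples.size),
            "mean": self.mean,
            "variance": self.variance,
            "std_error": self.std_error,
            "median": self.median,
            "q2.5": self.quantile(0.025),
            "q25": self.quantile(0.25),
            "q75": self.quantile(0.75),
            "q97.5": self.quantile(0.975),
            "min": float(self.samples.min()),
            "max": float(self.samples.max()),
            "unperturbed": self.unperturbed,
            "n_truncated_draws": self.n_truncated,
        }


@dataclass(frozen=True)
class PopulationSummary:
    """Pooled statistics over a collection of per-platelet ensembles."""

    pooled_mean: float
    pooled_variance: float
    per_platelet_median: np.ndarray
    per_platelet_min: np.ndarray
    per_platelet_max: np.ndarray

    @property
    def envelope(self) -> tuple[float, float]:
        return float(self.per_platelet_min.min()), float(self.per_platelet_max.max())


class _TruncationCounter:
    def __init__(self) -> None:
        self.count = 0


def _positive_factors(rng, amplitude, shape, counter=None):
    """(1 + amplitude·z) factors, redrawing any non-positive result."""
    f = 1.0 + amplitude * rng.standard_normal(shape)
    while True:
        bad = f <= 0
        n_bad = int(bad.sum())
        if n_bad == 0:
            return f
        if counter is not None:
            counter.count += n_bad
        f[bad] = 1.0 + amplitude * rng.standard_normal(n_bad)


def perturb(value, amplitude, rng):
    """value·(1 + amplitude·z) with rejection of non-positive factors."""
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    value = np.asarray(value, dtype=float)
    f = _positive_factors(rng, amplitude, value.shape if value.shape else (1,))
    out = value * (f if value.shape else f[0])
    return out if value.shape else float(out)


def required_sample_size(sigma: float, epsilon: float) -> int:
    """Samples needed for a standard error ε given spread σ: ⌈(σ/ε)²⌉."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return math.ceil((sigma / epsilon) ** 2)


def run_mc(h: ScalarStressHistory, params, spec: PerturbationSpec) -> MCEnsemble:
    """Ensemble of PAS integrations under random parameter perturbations.

    ``params`` selects the model (NobiliParameters or SoaresParameters; for
    the latter an ``include`` restriction can be baked in by passing a
    tuple ``(params, include)``).  Integration marches on the history grid
    with the same Heun scheme and PAS = 0 bootstrap as the deterministic
    integrators, vectorized across samples.
    """
    include = ("S", "F", "G")
    if isinstance(params, tuple):
        params, include = params
    if isinstance(params, NobiliParameters):
        names = _NOBILI_PARAMS
        runner = _run_nobili_ensemble
    elif isinstance(params, SoaresParameters):
        names = _SOARES_PARAMS
        runner = _run_soares_ensemble
    else:
        raise TypeError(f"unsupported parameter type {type(params).__name__}")

    targets = tuple(spec.targets) if spec.targets is not None else names
    allowed = set(names) | {STRESS_TARGET}
    unknown = set(targets) - allowed
    if unknown:
        raise ValueError(
            f"targets {sorted(unknown)} are not parameters of "
            f"{type(params).__name__} (allowed: {sorted(allowed)})"
        )

    rng = np.random.default_rng(spec.seed)
    counter = _TruncationCounter()
    samples, draws = runner(h, params, include, spec, targets, rng, counter)
    unperturbed, _ = runner(
        h, params, include,
        PerturbationSpec(0.0, mode=spec.mode, n_samples=1),
        targets, np.random.default_rng(0), None,
    )
    return MCEnsemble(
        samples=samples, spec=spec, unperturbed=float(unperturbed[0]),
        draws=draws, n_truncated=counter.count,
    )


def _factors(rng, spec, targets, counter, n):
    """Static per-sample factors for every target (per_sample mode)."""
    return {
        t: _positive_factors(rng, spec.amplitude, (n,), counter) for t in targets
    }


def _step_factors(rng, spec, targets, counter, n, static):
    if spec.mode == "per_sample":
        return static
    return {t: _positive_factors(rng, spec.amplitude, (n,), counter) for t in targets}


def _run_nobili_ensemble(h, p, include, spec, targets, rng, counter):
    n = spec.n_samples
    t, tau = h.times, h.tau
    static = _factors(rng, spec, targets, counter, n)
    draws = {k: p.asdict().get(k, 1.0) * v for k, v in static.items()} \
        if spec.mode == "per_sample" else {}

    D = np.zeros(n)
    pas = np.zeros(n)
    ones = np.ones(n)
    # extreme exponent draws at large amplitudes can overflow τ^{b/a}; the
    # physical limit of an astronomically large increment is saturation at 1
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(t.size - 1):
            dt = t[i + 1] - t[i]
            f = _step_factors(rng, spec, targets, counter, n, static)
            a = p.a * f.get("a", ones)
            b = p.b * f.get("b", ones)
            c = p.c * f.get("c", ones)
            s = f.get(STRESS_TARGET, ones)
            tau0, tau1 = tau[i] * s, tau[i + 1] * s
            k0 = tau0 ** (b / a)
            k1 = tau1 ** (b / a)
            D1 = D + 0.5 * dt * (k0 + k1)
            zero = D == 0
            r0 = c * a * k0 * np.where(zero, 0.0, np.where(D > 0, D, 1.0) ** (a - 1.0))
            r1 = c * a * k1 * np.where(D1 > 0, D1, 1.0) ** (a - 1.0)
            r1[D1 == 0] = 0.0
            incr = 0.5 * dt * (r0 + r1)
            if zero.any():
                incr[zero] = c[zero] * (D1[zero] ** a[zero] - 0.0)
            incr = np.where(np.isfinite(incr), incr, 1.0)
            pas = np.minimum(pas + incr, 1.0)
            D = D1
    return pas, draws


def _run_soares_ensemble(h, p, include, spec, targets, rng, counter):
    n = spec.n_samples
    t, tau = h.times, h.tau
    use_S, use_F, use_G = ("S" in include), ("F" in include), ("G" in include)
    static = _factors(rng, spec, targets, counter, n)
    draws = {k: p.asdict().get(k, 1.0) * v for k, v in static.items()} \
        if spec.mode == "per_sample" else {}

    stress_perturbed = STRESS_TARGET in targets
    if not stress_perturbed:
        _, H_base = stress_accumulation(h)
        _, SR_base = stress_rate(h, mode="cumulative_mean")

    pas = np.zeros(n)
    ones = np.ones(n)
    # per-sample Lagrangian stress statistics when the stress is perturbed
    H = np.zeros(n)
    sr_sum = np.zeros(n)
    tau_prev = None

    def term(pas_arr, x, coeff, num_exp, den_exp):
        e = (den_exp - 1.0) / den_exp
        safe = np.where(pas_arr > 0, pas_arr, 1.0)
        with np.errstate(over="ignore", invalid="ignore"):
            out = coeff ** (1.0 / den_exp) * den_exp * safe**e * x ** (num_exp / den_exp)
        return np.where((pas_arr > 0) & (x > 0), out, 0.0)

    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        f = _step_factors(rng, spec, targets, counter, n, static)
        # pathological exponent draws (large amplitudes) can overflow the
        # power laws; a diverging increment saturates PAS at 1 below
        S_r = p.S_r * f.get("S_r", ones)
        C = p.C * f.get("C", ones)
        al = p.alpha * f.get("alpha", ones)
        be = p.beta * f.get("beta", ones)
        C_r = p.C_r * f.get("C_r", ones)
        ga = p.gamma * f.get("gamma", ones)
        de = p.delta * f.get("delta", ones)
        s = f.get(STRESS_TARGET, ones)

        tau0 = tau[i] * s
        tau1 = tau[i + 1] * s
        if stress_perturbed:
            if tau_prev is not None:
                tau0 = tau_prev  # keep the per-sample path continuous
            H0, H1 = H, H + 0.5 * dt * (tau0 + tau1)
            SR0 = sr_sum / i if i > 0 else np.zeros(n)
            sr_sum = sr_sum + np.abs(tau1 - tau0) / dt
            SR1 = sr_sum / (i + 1)
            tau_prev = tau1
            H = H1
        else:
            H0, H1 = H_base[i] * ones, H_base[i + 1] * ones
            SR0, SR1 = SR_base[i] * ones, SR_base[i + 1] * ones

        with np.errstate(over="ignore", invalid="ignore"):
            zero = pas == 0
            S0 = S_r * pas * H0 if use_S else 0.0
            F0 = term(pas, tau0, C, al, be) if use_F else 0.0
            G0 = term(pas, SR0, C_r, ga, de) if use_G else 0.0
            f0 = (S0 + F0 + G0) * (1.0 - pas)
            pred = np.minimum(pas + dt * f0, 1.0)
            S1 = S_r * pred * H1 if use_S else 0.0
            F1 = term(pred, tau1, C, al, be) if use_F else 0.0
            G1 = term(pred, SR1, C_r, ga, de) if use_G else 0.0
            f1 = (S1 + F1 + G1) * (1.0 - pred)
            new = np.minimum(pas + 0.5 * dt * (f0 + f1), 1.0)

            if zero.any():
                boot = np.zeros(n)
                tau_b = np.where(tau0 > 0, tau0, tau1)
                if use_F:
                    boot = boot + np.where(tau_b > 0, C * tau_b**al * dt**be, 0.0)
                if use_G:
                    boot = boot + np.where(
                        SR1 > 0, C_r * np.where(SR1 > 0, SR1, 1.0)**ga * dt**de, 0.0)
                new = np.where(zero, np.minimum(boot, 1.0), new)
        pas = np.where(np.isfinite(new), new, 1.0)
    return pas, draws


def population_statistics(ensembles) -> PopulationSummary:
    """Pooled mean/variance plus per-platelet medians and extremes."""
    ensembles = list(ensembles)
    if not ensembles:
        raise ValueError("need at least one ensemble")
    pooled = np.concatenate([e.samples for e in ensembles])
    return PopulationSummary(
        pooled_mean=float(pooled.mean()),
        pooled_variance=float(pooled.var(ddof=1)) if pooled.size > 1 else 0.0,
        per_platelet_median=np.array([e.median for e in ensembles]),
        per_platelet_min=np.array([float(e.samples.min()) for e in ensembles]),
        per_platelet_max=np.array([float(e.samples.max()) for e in ensembles]),
    )
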