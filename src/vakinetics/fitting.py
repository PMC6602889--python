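"""Weighted nonlinear least-squares estimation of the kinetic parameters.

The estimator minimises the fractional-SD-weighted sum of squares

    wss = sum_i [ (y_i - yhat_i) / (fsd_plasma * y_i) ]^2
          (+ [ (u_obs - uhat) / (fsd_diet * u_obs) ]^2  for a diet-constrained fit)

over the adjustable fractional transfer coefficients and the delay time.
y_i are the observed plasma fraction-of-dose values, u_obs an observed (or
assumed) dietary vitamin A intake in µmol/d, and uhat the steady-state intake
implied by the current parameters and the measured plasma pool.  Weights use
the observed values, so residuals are relative errors and the objective is
invariant to rescaling the dose normalisation.

Parameters are optimised on the natural-log scale, which enforces positivity
and makes the reported standard errors fractional SDs directly.

Usage follows the model/results convention::

    model = TracerKineticsModel(obs, spec)
    res = model.fit()
    print(res.summary())
    res.steady_state()          # masses, TBS, DR, days of stores
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kinetics import (
    PARAM_NAMES,
    KineticParameters,
    ModelSpec,
    TracerCurve,
    simulate_fdp,
)
from .steady_state import SteadyStateSolution, predicted_intake, solve_steady_state

__all__ = [
    "IntakeObservation",
    "ObservationSet",
    "KineticsFitResults",
    "TracerKineticsModel",
    "weighted_residuals",
    "fit",
    "f_test",
    "DEFAULT_START",
    "DEFAULT_BOUNDS",
]

#: Default starting values (order-of-magnitude guesses; /d except DT_3 in d).
DEFAULT_START: dict[str, float] = {
    "L_2_1": 1.5,
    "L_3_2": 6.0,
    "DT_3": 0.1,
    "L_5_4": 3.0,
    "L_6_5": 2.0,
    "L_5_6": 0.05,
    "L_10_6": 0.01,
    "L_7_5": 0.5,
    "L_5_7": 0.2,
}

#: Default box bounds on the natural scale.  The second extravascular pool
#: (compartment 7) is by construction the smaller, faster-exchanging pool —
#: slow storage belongs to compartment 6 — so its return rate L(5,7) is kept
#: above 0.02/d (transit <= 50 d, resolvable within a ~52-d study); without
#: this floor the pool's mass is unidentifiable from short studies.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    name: ((1e-5, 20.0) if name == "DT_3" else (1e-7, 1e3))
    for name in DEFAULT_START
}
DEFAULT_BOUNDS["L_5_7"] = (0.02, 1e3)

#: Multi-start perturbation seeds (fixed list; best wss wins).
MULTISTART_SEEDS = (101, 202, 303, 404, 505, 606, 707, 808)


@dataclass(frozen=True)
class IntakeObservation:
    """Observed or assumed dietary vitamin A intake, µmol/d."""

    value: float
    fsd: float = 0.1

    def __post_init__(self):
        if self.value <= 0 or self.fsd <= 0:
            raise ValueError("intake value and fsd must be positive")


@dataclass(frozen=True)
class ObservationSet:
    """Data entering one fit: the tracer curve and optional intake.

    plasma_pool_M5 (µmol) is the measured plasma retinol pool; it is held
    fixed during fitting and is required when an intake observation is
    present (the steady-state intake prediction needs it).
    """

    tracer: TracerCurve
    fsd_plasma: float = 0.05
    intake_obs: Optional[IntakeObservation] = None
    plasma_pool_M5: Optional[float] = None

    def __post_init__(self):
        if self.fsd_plasma <= 0:
            raise ValueError("fsd_plasma must be positive")
        if self.intake_obs is not None and (
            self.plasma_pool_M5 is None or self.plasma_pool_M5 <= 0
        ):
            raise ValueError("an intake observation requires plasma_pool_M5 > 0")

    @property
    def n_obs(self) -> int:
        return len(self.tracer) + (1 if self.intake_obs is not None else 0)


def weighted_residuals(
    obs: ObservationSet,
    params: KineticParameters,
    spec: ModelSpec,
    on_nonpositive: str = "error",
) -> np.ndarray:
    """Fractional-SD-weighted residual vector (tracer points, then intake).

    on_nonpositive: 'error' rejects observed fdp <= 0 (weights undefined);
    'drop' removes those points with a warning.
    """
    y = obs.tracer.fdp
    t = obs.tracer.times
    bad = y <= 0
    if np.any(bad):
        if on_nonpositive == "drop":
            warnings.warn(
                f"dropping {int(bad.sum())} non-positive fdp observation(s)",
                stacklevel=2,
            )
            y, t = y[~bad], t[~bad]
        else:
            raise ValueError("observed fdp <= 0: fractional weights undefined")
    yhat = simulate_fdp(params, spec, t).fdp
    resid = (y - yhat) / (obs.fsd_plasma * y)
    if spec.include_diet_constraint and obs.intake_obs is not None:
        uhat = predicted_intake(params, spec, obs.plasma_pool_M5)
        u = obs.intake_obs.value
        resid = np.append(resid, (u - uhat) / (obs.intake_obs.fsd * u))
    return resid


@dataclass
class KineticsFitResults:
    """Parameter estimates with uncertainties and fit diagnostics.

    param_fsd holds the fractional SD of each adjustable parameter (the
    standard error on the log scale, from the Jacobian at the optimum).
    """

    params: KineticParameters
    spec: ModelSpec
    obs: ObservationSet
    wss: float
    n_obs: int
    n_free: int
    param_fsd: dict[str, float]
    converged: bool
    message: str
    n_iterations: int
    identifiable: bool = True
    trace: list = field(default_factory=list)

    @property
    def dof(self) -> int:
        return self.n_obs - self.n_free

    def predict(self, times) -> TracerCurve:
        return simulate_fdp(self.params, self.spec, times)

    def steady_state(self, M5: Optional[float] = None) -> SteadyStateSolution:
        """Steady-state solution at the fitted kinetics and a plasma pool."""
        if M5 is None:
            M5 = self.obs.plasma_pool_M5
        if M5 is None:
            raise ValueError("no plasma pool M5 available")
        return solve_steady_state(self.params, self.spec, M5)

    def plot(self, ax=None, t_max: Optional[float] = None):
        """Observed points and the fitted curve on log-scaled fdp axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t, y = self.obs.tracer.times, self.obs.tracer.fdp
        tt = np.linspace(t[0], t_max or t[-1], 400)
        ax.plot(t, y, "o", label="observed", color="k", ms=4)
        ax.plot(tt, self.predict(tt).fdp, "-",
                label=f"{self.spec.variant.value} fit")
        ax.set_yscale("log")
        ax.set_xlabel("time (d)")
        ax.set_ylabel("fraction of dose in plasma")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "variant": self.spec.variant.value,
            "diet_constraint": self.spec.include_diet_constraint,
            "params": self.params.to_dict(),
            "param_fsd": dict(self.param_fsd),
            "wss": self.wss,
            "n_obs": self.n_obs,
            "n_free": self.n_free,
            "converged": self.converged,
            "identifiable": self.identifiable,
            "n_iterations": self.n_iterations,
        }

    def summary(self) -> str:
        lines = [
            "Tracer kinetics fit",
            "=" * 58,
            f"model variant:    {self.spec.variant.value}"
            + ("  (diet-constrained)" if self.spec.include_diet_constraint else ""),
            f"observations:     {self.n_obs}   free parameters: {self.n_free}",
            f"weighted SS:      {self.wss:.6g}   wss/dof: {self.wss / self.dof:.4g}",
            f"converged:        {self.converged}   iterations: {self.n_iterations}",
            "-" * 58,
            f"{'parameter':<10}{'estimate':>14}{'fract. SD':>14}",
        ]
        est = self.params.to_dict()
        for name in PARAM_NAMES[self.spec.variant]:
            fsd = self.param_fsd.get(name)
            fsd_s = f"{fsd:>14.4g}" if fsd is not None else f"{'(fixed)':>14}"
            lines.append(f"{name:<10}{est.get(name, 0.0):>14.6g}{fsd_s}")
        lines.append("=" * 58)
        return "\n".join(lines)


def _pack(values: Mapping[str, float], names) -> np.ndarray:
    return np.log(np.array([values[n] for n in names], dtype=float))


def _unpack(theta: np.ndarray, names, fixed: Mapping[str, float]) -> KineticParameters:
    vals = dict(fixed)
    vals.update({n: float(np.exp(v)) for n, v in zip(names, theta)})
    return KineticParameters.from_dict(vals)


def fit(
    obs: ObservationSet,
    spec: ModelSpec,
    start: Optional[Mapping[str, float] | KineticParameters] = None,
    n_starts: int = 1,
    seed: Optional[int] = None,
    bounds: Optional[Mapping[str, tuple[float, float]]] = None,
    max_nfev: int = 4000,
    on_nonpositive: str = "error",
) -> KineticsFitResults:
    """Minimise the weighted sum of squares over the adjustable parameters.

    Trust-region least squares on log-transformed parameters; deterministic
    given ``start``, ``n_starts`` and ``seed``.  With n_starts > 1 the start
    is additionally perturbed log-normally (seeded); the lowest wss wins,
    ties broken by fewer function evaluations.
    """
    names = list(spec.adjustable)
    if isinstance(start, KineticParameters):
        start = start.to_dict()
    start_full = {**DEFAULT_START, **(dict(start) if start else {})}
    missing = [n for n in names if n not in start_full]
    if missing:
        raise ValueError(f"no starting value for {missing}")
    if obs.n_obs <= len(names):
        raise ValueError("need more observations than free parameters")
    bnds = {**DEFAULT_BOUNDS, **(dict(bounds) if bounds else {})}
    lo = np.log([bnds[n][0] for n in names])
    hi = np.log([bnds[n][1] for n in names])

    def residual(theta: np.ndarray) -> np.ndarray:
        params = _unpack(theta, names, spec.fixed)
        return weighted_residuals(obs, params, spec, on_nonpositive=on_nonpositive)

    theta0 = np.clip(_pack(start_full, names), lo, hi)
    starts = [theta0]
    if n_starts > 1:
        rng = np.random.default_rng(
            seed if seed is not None else MULTISTART_SEEDS[0]
        )
        for k in range(n_starts - 1):
            jitter = rng.uniform(-np.log(10), np.log(10), size=theta0.size)
            starts.append(np.clip(theta0 + jitter, lo, hi))

    best = None
    trace = []
    for t0 in starts:
        sol = optimize.least_squares(
            residual, t0, bounds=(lo, hi), method="trf",
            ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=max_nfev,
        )
        wss = float(2.0 * sol.cost)
        trace.append({"start": np.exp(t0).tolist(), "wss": wss,
                      "nfev": int(sol.nfev), "status": int(sol.status)})
        key = (wss, sol.nfev)
        if best is None or key < (best[0], best[1].nfev):
            best = (wss, sol)
    wss, sol = best

    n_obs = obs.n_obs
    n_free = len(names)
    dof = n_obs - n_free
    s2 = wss / dof if dof > 0 else np.nan
    J = sol.jac
    identifiable = True
    try:
        JtJ = J.T @ J
        cond = np.linalg.cond(JtJ)
        if not np.isfinite(cond) or cond > 1e12:
            identifiable = False
        cov = np.linalg.pinv(JtJ) * s2
        fsd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        identifiable = False
        fsd = np.full(n_free, np.nan)

    converged = bool(sol.status > 0)
    if not converged:
        warnings.warn("fit did not converge; returning best point found",
                      stacklevel=2)

    return KineticsFitResults(
        params=_unpack(sol.x, names, spec.fixed),
        spec=spec,
        obs=obs,
        wss=wss,
        n_obs=n_obs,
        n_free=n_free,
        param_fsd={n: float(s) for n, s in zip(names, fsd)},
        converged=converged,
        message=str(sol.message),
        n_iterations=int(sol.nfev),
        identifiable=identifiable,
        trace=trace,
    )


class TracerKineticsModel:
    """Whole-body vitamin A kinetics model bound to one observation set.

    Parameters
    ----------
    obs : ObservationSet
        Plasma tracer curve, weighting factors, optional intake observation
        and the measured plasma pool.
    spec : ModelSpec
        Topology variant (1 EV / 2 EV), diet-constraint flag, absorption
        efficiency and the adjustable/fixed parameter split.
    """

    def __init__(self, obs: ObservationSet, spec: ModelSpec):
        self.obs = obs
        self.spec = spec

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        spec: ModelSpec,
        time_col: str = "time_d",
        fdp_col: str = "fdp",
        **obs_kwargs,
    ) -> "TracerKineticsModel":
        curve = TracerCurve(
            times=data[time_col].to_numpy(float),
            fdp=data[fdp_col].to_numpy(float),
        )
        return cls(ObservationSet(tracer=curve, **obs_kwargs), spec)

    def residuals(self, params: KineticParameters, **kw) -> np.ndarray:
        return weighted_residuals(self.obs, params, self.spec, **kw)

    def fit(self, **kwargs) -> KineticsFitResults:
        return fit(self.obs, self.spec, **kwargs)


def f_test(simple: KineticsFitResults, complex: KineticsFitResults) -> dict:
    """Compare nested fits: does the extra complexity reduce wss significantly?

        F = [(wss_s - wss_c) / (p_c - p_s)] / [wss_c / (n - p_c)]

    with p from the F distribution on (p_c - p_s, n - p_c) degrees of
    freedom.  Both fits must use the same observation set.
    """
    if complex.n_obs != simple.n_obs:
        raise ValueError("fits must share the same observation set")
    df1 = complex.n_free - simple.n_free
    df2 = complex.n_obs - complex.n_free
    if df1 <= 0 or df2 <= 0:
        raise ValueError("models are not nested with positive degrees of freedom")
    F = ((simple.wss - complex.wss) / df1) / (complex.wss / df2)
    p = float(stats.f.sf(F, df1, df2)) if F > 0 else 1.0
    return {"F": float(F), "p": p, "df1": df1, "df2": df2}
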