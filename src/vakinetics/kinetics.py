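"""Compartmental model of whole-body vitamin A kinetics.

The model tracks an oral bolus of labelled retinol through a chain of
absorptive compartments into plasma, where retinol exchanges with one or two
extravascular storage pools:

    1 (gut) --L(2,1)--> 2 --L(3,2)--> [delay 3, DT(3) days] --> 4
      |                                                        |
      L(10,1) unabsorbed loss                              L(5,4)
                                                               v
                     6 (stores) <--L(6,5)-- 5 (plasma) --L(7,5)--> 7
                       |  ^                    ^                    |
                 L(10,6)  +----L(5,6)----------+--------L(5,7)------+

Compartment numbering follows the convention of whole-body vitamin A
modelling: L(I,J) is the fraction of compartment J's content transferred to
compartment I per day, with I = 10 denoting irreversible loss outside the
system.  The delay element 3 is a pure time shift of DT(3) days.  The 1 EV
("one extravascular pool") variant omits compartment 7; the 2 EV variant
includes it.  Compartment 6 is the sole site of irreversible systemic loss;
compartment 5 (plasma) is the sampling site.

Unabsorbed dose leaves compartment 1 via L(10,1), which is tied to L(2,1) so
that the absorbed fraction equals the configured absorption efficiency
(default 0.75): L(10,1) = L(2,1)*(1-a)/a.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import linalg

__all__ = [
    "Variant",
    "ModelSpec",
    "KineticParameters",
    "TracerCurve",
    "StructuralError",
    "build_system_matrix",
    "simulate_fdp",
    "simulate_state",
    "terminal_slope",
    "PARAM_NAMES",
    "DEFAULT_SAMPLING_GRID",
]


class StructuralError(ValueError):
    """A parameter set is inconsistent with the requested model topology."""


class Variant(str, enum.Enum):
    ONE_EV = "1EV"
    TWO_EV = "2EV"


# Edges allowed in each variant, (destination, source).  10 = outside.
_EDGES_ONE_EV = (
    (2, 1), (10, 1), (3, 2), (5, 4), (6, 5), (5, 6), (10, 6),
)
_EDGES_TWO_EV = _EDGES_ONE_EV + ((7, 5), (5, 7))

# Parameter naming used in configs and fit reports: "L_I_J" and "DT_3".
PARAM_NAMES = {
    Variant.ONE_EV: ("L_2_1", "L_3_2", "DT_3", "L_5_4", "L_6_5", "L_5_6", "L_10_6"),
    Variant.TWO_EV: (
        "L_2_1", "L_3_2", "DT_3", "L_5_4", "L_6_5", "L_5_6", "L_10_6",
        "L_7_5", "L_5_7",
    ),
}

# Non-delay compartments, in matrix order.
_COMPARTMENTS = {
    Variant.ONE_EV: (1, 2, 4, 5, 6),
    Variant.TWO_EV: (1, 2, 4, 5, 6, 7),
}

#: Default plasma sampling schedule, days (3 h to 52 d, 19 samples).
DEFAULT_SAMPLING_GRID = np.array(
    [0.125, 0.177, 0.25, 0.5, 1, 2, 3, 5, 7, 9, 11, 14, 17, 21,
     28, 35, 42, 46, 52],
    dtype=float,
)


def _edge_key(name: str) -> tuple[int, int]:
    _, i, j = name.split("_")
    return int(i), int(j)


@dataclass(frozen=True)
class ModelSpec:
    """Topology variant and fitting configuration for the kinetic model.

    Parameters
    ----------
    variant : Variant
        ONE_EV (compartments 1,2,delay 3,4,5,6) or TWO_EV (adds 7).
    include_diet_constraint : bool
        If True, the steady-state dietary intake U(1) predicted by the
        parameters is matched against an observed intake during fitting
        (the "2 EV DI" treatment).
    absorption_efficiency : float
        Fraction of ingested vitamin A absorbed; fixes L(10,1) relative to
        L(2,1).  Default 0.75.
    adjustable : tuple of str
        Parameter names estimated during fitting.  Defaults to every
        parameter of the variant.
    fixed : mapping
        Parameter name -> value held fixed during fitting.  Disjoint from
        ``adjustable``; together they must cover the variant's parameters.
    """

    variant: Variant = Variant.TWO_EV
    include_diet_constraint: bool = False
    absorption_efficiency: float = 0.75
    adjustable: tuple[str, ...] = ()
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.absorption_efficiency <= 1.0:
            raise ValueError("absorption_efficiency must be in (0, 1]")
        names = PARAM_NAMES[self.variant]
        adjustable = self.adjustable or tuple(
            n for n in names if n not in self.fixed
        )
        object.__setattr__(self, "adjustable", adjustable)
        overlap = set(self.adjustable) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both adjustable and fixed: {overlap}")
        covered = set(self.adjustable) | set(self.fixed)
        if covered != set(names):
            raise ValueError(
                f"adjustable+fixed must cover {names}, got {sorted(covered)}"
            )

    @property
    def compartments(self) -> tuple[int, ...]:
        return _COMPARTMENTS[self.variant]

    @property
    def edges(self) -> tuple[tuple[int, int], ...]:
        return _EDGES_ONE_EV if self.variant is Variant.ONE_EV else _EDGES_TWO_EV


@dataclass(frozen=True)
class KineticParameters:
    """Fractional transfer coefficients L(I,J) (per day) and delay DT(3) (days).

    ``L`` maps (destination, source) pairs; destination 10 is irreversible
    loss outside the system.  L(10,1), the unabsorbed fraction of the dose,
    is not stored: it is derived from L(2,1) and the absorption efficiency.
    """

    L: Mapping[tuple[int, int], float]
    dt3: float

    def __post_init__(self):
        object.__setattr__(self, "L", dict(self.L))
        for (i, j), v in self.L.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"L({i},{j}) must be finite and >= 0, got {v}")
        if not np.isfinite(self.dt3) or self.dt3 < 0:
            raise ValueError(f"DT(3) must be finite and >= 0, got {self.dt3}")

    def get(self, i: int, j: int) -> float:
        return self.L.get((i, j), 0.0)

    def loss_from_gut(self, absorption_efficiency: float) -> float:
        """L(10,1) implied by the absorption efficiency."""
        a = absorption_efficiency
        return self.get(2, 1) * (1.0 - a) / a

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "KineticParameters":
        """Build from flat names: ``L_2_1`` ... ``L_5_7`` and ``DT_3``."""
        L = {}
        dt3 = 0.0
        for name, v in values.items():
            if name == "DT_3":
                dt3 = float(v)
            elif name.startswith("L_"):
                L[_edge_key(name)] = float(v)
            else:
                raise KeyError(f"unknown parameter {name!r}")
        return cls(L=L, dt3=dt3)

    def to_dict(self) -> dict[str, float]:
        out = {f"L_{i}_{j}": v for (i, j), v in sorted(self.L.items())}
        out["DT_3"] = self.dt3
        return out

    def validate_for(self, spec: ModelSpec) -> None:
        allowed = set(spec.edges) - {(10, 1)}
        unknown = set(self.L) - allowed
        if unknown:
            raise StructuralError(
                f"edges {sorted(unknown)} not allowed for variant {spec.variant.value}"
            )


@dataclass(frozen=True)
class TracerCurve:
    """Plasma tracer observations: fraction of the oral dose in compartment 5."""

    times: np.ndarray  # days
    fdp: np.ndarray    # dimensionless fraction of dose

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.fdp, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValueError("times and fdp must be 1-D and of equal length")
        if t.size and t[0] < 0:
            raise ValueError("times must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0) or np.any(y > 1):
            raise ValueError("fdp values must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fdp", y)

    def __len__(self) -> int:
        return self.times.size


def build_system_matrix(params: KineticParameters, spec: ModelSpec) -> np.ndarray:
    """Assemble the rate matrix over the non-delay compartments.

    Entry (i, j) holds L(i, j); the diagonal holds minus each compartment's
    total fractional outflow, including losses to the outside and, for
    compartment 2, the flow into the delay element.  The delay itself is not
    part of the matrix.  Row/column order follows ``spec.compartments``.
    """
    params.validate_for(spec)
    comps = spec.compartments
    idx = {c: k for k, c in enumerate(comps)}
    n = len(comps)
    A = np.zeros((n, n))
    l_10_1 = params.loss_from_gut(spec.absorption_efficiency)
    for (i, j) in spec.edges:
        rate = l_10_1 if (i, j) == (10, 1) else params.get(i, j)
        if rate == 0.0:
            continue
        A[idx[j], idx[j]] -= rate
        if i in idx:  # 10 and the delay element 3 are outside the matrix
            A[idx[i], idx[j]] += rate
    return A


def _undelayed_matrix(
    params: KineticParameters, spec: ModelSpec, track_losses: bool
) -> tuple[np.ndarray, tuple, dict]:
    """Rate matrix with the delay collapsed (2 feeds 4 directly).

    With ``track_losses`` two absorbing states are appended: cumulative
    unabsorbed loss from 1 and cumulative systemic loss from 6.
    """
    comps = list(spec.compartments)
    states = comps + (["loss_gut", "loss_sys"] if track_losses else [])
    idx = {c: k for k, c in enumerate(states)}
    n = len(states)
    M = np.zeros((n, n))
    l_10_1 = params.loss_from_gut(spec.absorption_efficiency)

    def flow(j, i, rate):
        M[idx[j], idx[j]] -= rate
        if i in idx:
            M[idx[i], idx[j]] += rate

    flow(1, 2, params.get(2, 1))
    flow(1, "loss_gut", l_10_1)
    flow(2, 4, params.get(3, 2))  # delay applied as a time shift afterwards
    flow(4, 5, params.get(5, 4))
    flow(5, 6, params.get(6, 5))
    flow(6, 5, params.get(5, 6))
    flow(6, "loss_sys", params.get(10, 6))
    if spec.variant is Variant.TWO_EV:
        flow(5, 7, params.get(7, 5))
        flow(7, 5, params.get(5, 7))
    return M, tuple(states), idx


def _propagate(M: np.ndarray, x0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Evaluate exp(M t) @ x0 at each time; rows = states, cols = times.

    Uses the eigen-decomposition when well conditioned, otherwise a per-time
    matrix exponential (handles defective matrices from coincident rates).
    """
    times = np.asarray(times, dtype=float)
    try:
        lam, V = linalg.eig(M)
        cond = np.linalg.cond(V)
        if not np.isfinite(cond) or cond > 1e8:
            raise linalg.LinAlgError("ill-conditioned eigenbasis")
        c = linalg.solve(V, x0.astype(complex))
        E = np.exp(np.outer(lam, times))  # (n_states, n_times)
        X = (V @ (E * c[:, None])).real
    except linalg.LinAlgError:
        X = np.column_stack([linalg.expm(M * t) @ x0 for t in times])
    return X


def _solve_undelayed(
    params: KineticParameters, spec: ModelSpec, times: np.ndarray,
    track_losses: bool = False,
):
    M, states, idx = _undelayed_matrix(params, spec, track_losses)
    x0 = np.zeros(len(states))
    x0[idx[1]] = 1.0
    return _propagate(M, x0, times), states, idx


def simulate_fdp(
    params: KineticParameters, spec: ModelSpec, times: Iterable[float]
) -> TracerCurve:
    """Fraction of a unit oral dose in plasma (compartment 5) at each time.

    The bolus enters compartment 1 at t = 0.  The upstream chain 1 -> 2 and
    the downstream subsystem {4, 5, 6[, 7]} are linear; the delay element is
    a pure time shift, so the downstream response with delay DT(3) equals the
    undelayed response evaluated at t - DT(3) (zero before the delay elapses).
    """
    times = np.asarray(list(times), dtype=float)
    if times.size and np.any(times < 0):
        raise ValueError("times must be >= 0")
    params.validate_for(spec)
    shifted = times - params.dt3
    live = shifted > 0
    fdp = np.zeros_like(times)
    if np.any(live):
        X, _, idx = _solve_undelayed(params, spec, shifted[live])
        fdp[live] = np.clip(X[idx[5]], 0.0, None)
    order = np.argsort(times)
    return TracerCurve(times=times[order], fdp=fdp[order])


def simulate_state(
    params: KineticParameters, spec: ModelSpec, times: Iterable[float]
):
    """Full tracer state: every compartment, the delay content, and losses.

    Returns a pandas DataFrame indexed by time with one column per
    compartment (``comp1`` ...), ``delay``, ``loss_gut`` and ``loss_sys``.
    Compartments 1 and 2 evolve independently of the delay; compartments
    4-7 and the systemic loss are the undelayed response shifted by DT(3).
    The delay content is the material that has left compartment 2 but not
    yet entered 4.
    """
    import pandas as pd

    times = np.asarray(list(times), dtype=float)
    params.validate_for(spec)
    X_now, states, idx = _solve_undelayed(params, spec, times, track_losses=True)

    shifted = np.clip(times - params.dt3, 0.0, None)
    X_shift, _, _ = _solve_undelayed(params, spec, shifted, track_losses=True)

    data = {
        "comp1": X_now[idx[1]],
        "comp2": X_now[idx[2]],
        "loss_gut": X_now[idx["loss_gut"]],
    }
    downstream = [c for c in spec.compartments if c not in (1, 2)]
    for c in downstream:
        data[f"comp{c}"] = X_shift[idx[c]]
    data["loss_sys"] = X_shift[idx["loss_sys"]]

    # exited-upstream(t) minus entered-downstream(t) = content of the delay
    def exited_upstream(X):
        return 1.0 - X[idx[1]] - X[idx[2]] - X[idx["loss_gut"]]

    entered_down = sum(X_shift[idx[c]] for c in downstream) + X_shift[idx["loss_sys"]]
    data["delay"] = np.clip(exited_upstream(X_now) - entered_down, 0.0, None)

    cols = ["comp1", "comp2", "delay"] + [f"comp{c}" for c in downstream] + [
        "loss_gut", "loss_sys",
    ]
    return pd.DataFrame(data, index=pd.Index(times, name="time_d"))[cols]


def terminal_slope(curve: TracerCurve, window: tuple[float, float]) -> float:
    """Least-squares slope of ln(fdp) versus time inside ``window`` (per day).

    Used to characterise the terminal decay of the plasma tracer curve: when
    a study is too short to define this slope, the disposal rate is
    overestimated and total body stores underestimated.
    """
    lo, hi = window
    mask = (curve.times >= lo) & (curve.times <= hi)
    if mask.sum() < 3:
        raise ValueError("terminal_slope needs at least 3 points in the window")
    y = curve.fdp[mask]
    if np.any(y <= 0):
        raise ValueError("fdp must be positive throughout the window")
    slope, _ = np.polyfit(curve.times[mask], np.log(y), 1)
    return float(slope)
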