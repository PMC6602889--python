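"""Steady-state mass balance and tracer-theory quantities.

Given fitted fractional transfer coefficients and the measured plasma retinol
pool M(5), the steady-state solution yields the compartment masses, the
dietary input rate U(1), the disposal rate DR = M(6) * L(10,6), total body
stores TBS (sum of the extravascular masses), days of stores TBS/DR, and the
liver vitamin A concentration under the assumption that 90% of total body
vitamin A resides in the liver.

Closed forms (plasma pool M(5) given, compartment 6 the loss site):

    M(6) = M(5) * L(6,5) / (L(5,6) + L(10,6))
    M(7) = M(5) * L(7,5) / L(5,7)                  (2 EV only)
    DR   = M(6) * L(10,6)
    U(1) = DR / absorption_efficiency

The tracer-theory quantities (transit times, the mean residence-time matrix
-A^{-1}, plasma recycling number and recycling time) summarise how long
vitamin A spends in each pool and how often it revisits plasma before
irreversible loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .kinetics import (
    KineticParameters,
    ModelSpec,
    StructuralError,
    Variant,
    build_system_matrix,
)

__all__ = [
    "SteadyStateSolution",
    "DerivedKinetics",
    "solve_steady_state",
    "predicted_intake",
    "plasma_pool_size",
    "liver_weight_from_bsa",
    "liver_va_concentration",
    "derived_kinetics",
    "fold_increase",
    "DEFAULT_PLASMA_VOLUME_PER_KG",
    "LIVER_FRACTION_OF_STORES",
    "LIVER_WEIGHT_PER_BSA",
]

#: Estimated plasma volume per kg body weight (L/kg).
DEFAULT_PLASMA_VOLUME_PER_KG = 0.0435
#: Fraction of total body vitamin A assumed to reside in the liver.
LIVER_FRACTION_OF_STORES = 0.9
#: Estimated liver weight per unit body surface area (g/m^2).
LIVER_WEIGHT_PER_BSA = 772.0


@dataclass(frozen=True)
class SteadyStateSolution:
    """Steady-state masses (µmol) and turnover of the vitamin A system."""

    M5: float
    M6: float
    M7: float
    TBS: float
    U1: float               # dietary input, µmol/d
    DR: float               # disposal rate, µmol/d
    days_of_stores: float   # TBS/DR; nan when DR == 0
    masses: dict = field(default_factory=dict)  # all compartments incl. delay

    def liver_concentration(self, liver_weight_g: float) -> float:
        return liver_va_concentration(self.TBS, liver_weight_g)

    def as_dict(self) -> dict[str, float]:
        return {
            "U1_umol_per_d": self.U1,
            "M5_umol": self.M5,
            "M6_umol": self.M6,
            "M7_umol": self.M7,
            "TBS_umol": self.TBS,
            "DR_umol_per_d": self.DR,
            "days_of_stores": self.days_of_stores,
        }


def solve_steady_state(
    params: KineticParameters, spec: ModelSpec, M5: float
) -> SteadyStateSolution:
    """Steady-state compartment masses and flows for a measured plasma pool.

    M5 is the plasma retinol pool in µmol.  Raises StructuralError when an
    exchange coefficient needed by the closed form is zero.
    """
    if M5 <= 0:
        raise ValueError("M5 must be positive")
    params.validate_for(spec)

    denom6 = params.get(5, 6) + params.get(10, 6)
    if params.get(6, 5) > 0 and denom6 == 0:
        raise StructuralError("L(5,6) + L(10,6) is zero: compartment 6 has no outflow")
    M6 = M5 * params.get(6, 5) / denom6 if denom6 > 0 else 0.0

    M7 = 0.0
    if spec.variant is Variant.TWO_EV and params.get(7, 5) > 0:
        if params.get(5, 7) == 0:
            raise StructuralError("L(5,7) is zero: compartment 7 has no outflow")
        M7 = M5 * params.get(7, 5) / params.get(5, 7)

    DR = M6 * params.get(10, 6)
    U1 = DR / spec.absorption_efficiency
    TBS = M6 + M7
    days = TBS / DR if DR > 0 else math.nan

    # Upstream masses carried by the absorbed flux a*U1 = DR.
    masses = {"M5": M5, "M6": M6, "M7": M7}
    total_out_1 = params.get(2, 1) + params.loss_from_gut(spec.absorption_efficiency)
    masses["M1"] = U1 / total_out_1 if total_out_1 > 0 else 0.0
    masses["M2"] = DR / params.get(3, 2) if params.get(3, 2) > 0 else 0.0
    masses["M_delay"] = DR * params.dt3
    masses["M4"] = DR / params.get(5, 4) if params.get(5, 4) > 0 else 0.0

    return SteadyStateSolution(
        M5=M5, M6=M6, M7=M7, TBS=TBS, U1=U1, DR=DR, days_of_stores=days,
        masses=masses,
    )


def predicted_intake(params: KineticParameters, spec: ModelSpec, M5: float) -> float:
    """Steady-state dietary intake U(1), µmol/d, implied by the kinetics.

    This is the quantity matched against the dietary-intake observation in
    the diet-constrained ("2 EV DI") fit.
    """
    return solve_steady_state(params, spec, M5).U1


def plasma_pool_size(
    mean_retinol: float,
    body_weight: float,
    plasma_volume_per_kg: float = DEFAULT_PLASMA_VOLUME_PER_KG,
) -> float:
    """Plasma retinol pool (µmol) = serum retinol (µmol/L) x plasma volume (L)."""
    if mean_retinol < 0 or body_weight <= 0 or plasma_volume_per_kg <= 0:
        raise ValueError("inputs must be positive")
    return mean_retinol * plasma_volume_per_kg * body_weight


def liver_weight_from_bsa(bsa: float) -> float:
    """Estimated liver weight (g) from body surface area (m^2)."""
    if bsa <= 0:
        raise ValueError("bsa must be positive")
    return bsa * LIVER_WEIGHT_PER_BSA


def liver_va_concentration(tbs: float, liver_weight: float) -> float:
    """Liver vitamin A concentration (µmol/g): 90% of TBS in the liver."""
    if liver_weight <= 0:
        raise ValueError("liver_weight must be positive")
    if tbs < 0:
        raise ValueError("tbs must be >= 0")
    return tbs * LIVER_FRACTION_OF_STORES / liver_weight


def fold_increase(new: float, old: float) -> float:
    """Relative increase (new - old)/old, the 'x-fold increase' convention."""
    return (new - old) / old


@dataclass(frozen=True)
class DerivedKinetics:
    """Tracer-theory summary of the fitted system.

    transit_time
        Mean time (d) a molecule spends in a compartment per visit,
        1 / (total fractional outflow); the delay contributes DT(3).
    residence
        DataFrame, entry (i, j) = mean total time (d) spent in compartment i
        per unit introduced into compartment j (the matrix -A^{-1}).
    plasma_recycling_number
        Mean number of returns to plasma before irreversible loss.
    plasma_recycling_time
        Mean time (d) spent in the extravascular pools per plasma re-entry.
    system_residence_time
        Mean total time (d) in the system per unit of dietary input,
        including the absorption delay traversed by the absorbed fraction.
    """

    transit_time: dict
    residence: pd.DataFrame
    plasma_recycling_number: float
    plasma_recycling_time: float
    system_residence_time: float


def derived_kinetics(params: KineticParameters, spec: ModelSpec) -> DerivedKinetics:
    """Transit/residence/recycling parameters from the fitted coefficients."""
    params.validate_for(spec)
    A = build_system_matrix(params, spec)
    comps = spec.compartments
    # Reroute the delay edge so the matrix is the full connected system
    # (the delay's time contribution is added separately below).
    idx = {c: k for k, c in enumerate(comps)}
    A = A.copy()
    A[idx[4], idx[2]] += params.get(3, 2)
    try:
        R = -linalg.inv(A)
    except linalg.LinAlgError as exc:
        raise StructuralError("system has no loss path: singular matrix") from exc
    if not np.all(np.isfinite(R)) or np.any(R < -1e-9):
        raise StructuralError("system has no loss path: infinite residence time")
    residence = pd.DataFrame(R, index=list(comps), columns=list(comps))

    transit = {}
    l_10_1 = params.loss_from_gut(spec.absorption_efficiency)
    outflow = {
        1: params.get(2, 1) + l_10_1,
        2: params.get(3, 2),
        4: params.get(5, 4),
        5: params.get(6, 5) + params.get(7, 5),
        6: params.get(5, 6) + params.get(10, 6),
    }
    if spec.variant is Variant.TWO_EV:
        outflow[7] = params.get(5, 7)
    for c, rate in outflow.items():
        transit[c] = 1.0 / rate if rate > 0 else math.inf
    transit["delay"] = params.dt3

    # Recycling: probability that a molecule leaving plasma returns to plasma.
    out5 = params.get(6, 5) + params.get(7, 5)
    if out5 <= 0:
        raise StructuralError("plasma has no outflow; recycling undefined")
    f6 = params.get(6, 5) / out5
    out6 = params.get(5, 6) + params.get(10, 6)
    r6 = params.get(5, 6) / out6 if out6 > 0 else 0.0
    p_return = f6 * r6
    if spec.variant is Variant.TWO_EV:
        f7 = params.get(7, 5) / out5
        p_return += f7 * 1.0  # compartment 7 always returns to plasma
    if p_return >= 1.0:
        raise StructuralError("no loss path from plasma: recycling diverges")
    recycling_number = p_return / (1.0 - p_return)

    ev = [c for c in (6, 7) if c in idx]
    t_extravascular = float(sum(R[idx[c], idx[5]] for c in ev))
    recycling_time = (
        t_extravascular / recycling_number if recycling_number > 0 else math.nan
    )

    alpha = spec.absorption_efficiency
    system_rt = float(R[:, idx[1]].sum()) + alpha * params.dt3

    return DerivedKinetics(
        transit_time=transit,
        residence=residence,
        plasma_recycling_number=float(recycling_number),
        plasma_recycling_time=float(recycling_time),
        system_residence_time=system_rt,
    )
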