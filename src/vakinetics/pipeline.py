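"""Group-level analysis: composite (population) and per-subject model fits.

The analysis mirrors the two tracks used in whole-body vitamin A kinetic
studies: (a) fit the geometric-mean ("composite") plasma tracer curve of a
group, using the group's geometric-mean plasma pool in the steady-state
solution, and (b) fit each subject individually and summarise the outputs as
geometric means.  Each track can be run under three treatments: the
one-extravascular-pool model (1EV), the two-pool model (2EV), and the
two-pool model with a dietary-intake observation in the objective (2EV_DI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import RDA_INTAKE_UMOL_PER_DAY
from .fitting import (
    IntakeObservation,
    KineticsFitResults,
    ObservationSet,
    f_test,
    fit,
)
from .kinetics import ModelSpec, TracerCurve, Variant
from .steady_state import (
    DEFAULT_PLASMA_VOLUME_PER_KG,
    SteadyStateSolution,
    liver_va_concentration,
    plasma_pool_size,
)

__all__ = [
    "SubjectRecord",
    "GroupConfig",
    "GroupAnalysis",
    "TREATMENTS",
    "geometric_mean_curve",
    "group_summary",
    "arithmetic_summary",
    "run_group",
    "intake_sensitivity",
]

TREATMENTS = ("1EV", "2EV", "2EV_DI")


@dataclass
class SubjectRecord:
    """One study participant: covariates plus the plasma tracer curve."""

    id: str
    sex: str
    age_y: float
    body_weight_kg: float
    bmi_kg_m2: float
    mean_serum_retinol_umol_l: float
    tracer: TracerCurve
    liver_weight_g: Optional[float] = None
    group: Optional[str] = None
    ground_truth: Optional[dict] = None

    def __post_init__(self):
        for name in ("age_y", "body_weight_kg", "bmi_kg_m2",
                     "mean_serum_retinol_umol_l"):
            v = getattr(self, name)
            if v is None or v <= 0:
                raise ValueError(f"{self.id}: {name} must be positive, got {v}")
        if self.liver_weight_g is not None and self.liver_weight_g <= 0:
            raise ValueError(f"{self.id}: liver_weight_g must be positive")

    def plasma_pool(self, plasma_volume_per_kg: float = DEFAULT_PLASMA_VOLUME_PER_KG) -> float:
        return plasma_pool_size(
            self.mean_serum_retinol_umol_l, self.body_weight_kg, plasma_volume_per_kg
        )


@dataclass
class GroupConfig:
    """Settings for a group analysis run."""

    treatments: tuple[str, ...] = TREATMENTS
    intake_umol_per_d: float = RDA_INTAKE_UMOL_PER_DAY
    fsd_plasma: float = 0.05
    fsd_diet: float = 0.1
    absorption_efficiency: float = 0.75
    plasma_volume_per_kg: float = DEFAULT_PLASMA_VOLUME_PER_KG
    per_subject: bool = True
    grid_tolerance: float = 1e-9     # sampling grids must agree to this
    # inclusion filter: tracer identifiable in the late window
    late_window_start_d: float = 20.0
    min_late_points: int = 4
    detection_floor: float = 1e-6
    # per-subject fits enter the group summaries only when every parameter's
    # fractional SD is below this (single 52-d curves often leave the storage
    # pool unidentified; fits with ~100%+ uncertainty are reported but not
    # averaged)
    max_param_fsd: float = 1.0
    n_starts: int = 1
    seed: Optional[int] = None
    start: Optional[dict] = None

    def __post_init__(self):
        unknown = set(self.treatments) - set(TREATMENTS)
        if unknown:
            raise ValueError(f"unknown treatments: {sorted(unknown)}")
        if not self.treatments:
            raise ValueError("at least one treatment required")


@dataclass
class GroupAnalysis:
    """Results of one group run: composite fits, per-subject fits, summaries."""

    label: str
    config: GroupConfig
    subjects_included: list[str]
    subjects_excluded: list[str]
    composite_M5: float
    liver_weight_gm: Optional[float]
    composite_fit: dict[str, KineticsFitResults]
    composite_steady_state: dict[str, SteadyStateSolution]
    f_tests: dict[str, dict]
    per_subject: dict[str, dict] = field(default_factory=dict)
    per_subject_errors: dict[str, str] = field(default_factory=dict)
    group_geometric_means: dict[str, dict] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    def steady_state_table(self) -> pd.DataFrame:
        """Population steady-state outputs, one column per treatment."""
        rows = ["U1_umol_per_d", "M5_umol", "M6_umol", "M7_umol", "TBS_umol",
                "DR_umol_per_d", "days_of_stores", "liver_va_umol_per_g"]
        out = {}
        for tr, ss in self.composite_steady_state.items():
            col = ss.as_dict()
            col["liver_va_umol_per_g"] = (
                liver_va_concentration(ss.TBS, self.liver_weight_gm)
                if self.liver_weight_gm else math.nan
            )
            out[tr] = [col[r] for r in rows]
        return pd.DataFrame(out, index=rows)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "subjects_included": self.subjects_included,
            "subjects_excluded": self.subjects_excluded,
            "composite_M5_umol": self.composite_M5,
            "liver_weight_gm_g": self.liver_weight_gm,
            "composite_fit": {t: r.to_dict() for t, r in self.composite_fit.items()},
            "composite_steady_state": {
                t: s.as_dict() for t, s in self.composite_steady_state.items()
            },
            "f_tests": self.f_tests,
            "per_subject": {
                sid: {
                    t: {"fit": r["fit"].to_dict(),
                        "steady_state": r["steady_state"].as_dict()}
                    for t, r in res.items()
                }
                for sid, res in self.per_subject.items()
            },
            "per_subject_errors": self.per_subject_errors,
            "group_geometric_means": self.group_geometric_means,
            "log": self.log,
        }


def geometric_mean_curve(
    subjects: Sequence[SubjectRecord] | Sequence[TracerCurve],
    grid_tolerance: float = 1e-9,
) -> TracerCurve:
    """Pointwise geometric-mean tracer curve over subjects sharing one grid."""
    curves = [s.tracer if isinstance(s, SubjectRecord) else s for s in subjects]
    if not curves:
        raise ValueError("no subjects")
    t0 = curves[0].times
    for c in curves[1:]:
        if len(c) != len(curves[0]) or np.any(np.abs(c.times - t0) > grid_tolerance):
            raise ValueError("subjects do not share a common sampling grid")
    Y = np.array([c.fdp for c in curves])
    if np.any(Y <= 0):
        raise ValueError("geometric mean requires positive fdp values")
    return TracerCurve(times=t0, fdp=np.exp(np.log(Y).mean(axis=0)))


def group_summary(values: Sequence[float], dispersion: bool = True) -> dict:
    """Geometric mean (and geometric SD factor) of positive values."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("no values")
    if np.any(x <= 0):
        raise ValueError("geometric mean requires positive values")
    logs = np.log(x)
    out = {"geometric_mean": float(np.exp(logs.mean())), "n": int(x.size)}
    if dispersion:
        out["gsd_factor"] = (
            float(np.exp(logs.std(ddof=1))) if x.size > 1 else math.nan
        )
    return out


def arithmetic_summary(values: Sequence[float]) -> dict:
    """Arithmetic mean and SD, for covariates reported on the natural scale."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("no values")
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else math.nan,
        "n": int(x.size),
    }


def _treatment_spec(treatment: str, cfg: GroupConfig) -> ModelSpec:
    variant = Variant.ONE_EV if treatment == "1EV" else Variant.TWO_EV
    return ModelSpec(
        variant=variant,
        include_diet_constraint=treatment.endswith("_DI"),
        absorption_efficiency=cfg.absorption_efficiency,
    )


def _observation_set(
    curve: TracerCurve, M5: float, treatment: str, cfg: GroupConfig,
    intake: Optional[float] = None,
) -> ObservationSet:
    intake_obs = None
    if treatment.endswith("_DI"):
        intake_obs = IntakeObservation(
            value=intake if intake is not None else cfg.intake_umol_per_d,
            fsd=cfg.fsd_diet,
        )
    return ObservationSet(
        tracer=curve, fsd_plasma=cfg.fsd_plasma,
        intake_obs=intake_obs, plasma_pool_M5=M5,
    )


def _fit_treatment(curve, M5, treatment, cfg, intake=None) -> KineticsFitResults:
    spec = _treatment_spec(treatment, cfg)
    obs = _observation_set(curve, M5, treatment, cfg, intake=intake)
    return fit(obs, spec, start=cfg.start, n_starts=cfg.n_starts, seed=cfg.seed)


def identifiable_late(subject: SubjectRecord, cfg: GroupConfig) -> bool:
    """Inclusion filter: enough late-window points above the detection floor."""
    t, y = subject.tracer.times, subject.tracer.fdp
    late = (t >= cfg.late_window_start_d) & (y > cfg.detection_floor)
    return int(late.sum()) >= cfg.min_late_points


def run_group(
    subjects: Sequence[SubjectRecord],
    config: Optional[GroupConfig] = None,
    label: str = "group",
) -> GroupAnalysis:
    """Run the composite and per-subject analyses for one group.

    The composite track fits the geometric-mean tracer curve with the group's
    geometric-mean plasma pool; model treatments are compared with F-tests
    (the diet-constrained comparison refits the simpler model on the same
    augmented observation set so the objectives are commensurable).
    Per-subject failures are recorded without aborting the group.
    """
    cfg = config or GroupConfig()
    if len(subjects) < 2:
        raise ValueError("composite mode requires at least 2 subjects")
    log: list[str] = []

    included = [s for s in subjects if identifiable_late(s, cfg)]
    excluded = [s.id for s in subjects if not identifiable_late(s, cfg)]
    if excluded:
        log.append(f"excluded (late tracer not identifiable): {excluded}")
    if len(included) < 2:
        raise ValueError("fewer than 2 subjects pass the inclusion filter")

    pools = [s.plasma_pool(cfg.plasma_volume_per_kg) for s in included]
    composite_M5 = group_summary(pools, dispersion=False)["geometric_mean"]
    log.append(f"composite plasma pool M5 = {composite_M5:.4g} umol")

    liver_weights = [s.liver_weight_g for s in included if s.liver_weight_g]
    liver_gm = (
        group_summary(liver_weights, dispersion=False)["geometric_mean"]
        if liver_weights else None
    )

    composite = geometric_mean_curve(included, cfg.grid_tolerance)
    composite_fit: dict[str, KineticsFitResults] = {}
    composite_ss: dict[str, SteadyStateSolution] = {}
    for tr in cfg.treatments:
        res = _fit_treatment(composite, composite_M5, tr, cfg)
        composite_fit[tr] = res
        composite_ss[tr] = res.steady_state()
        log.append(f"composite {tr}: wss={res.wss:.4g} converged={res.converged}")

    f_tests: dict[str, dict] = {}
    if "1EV" in composite_fit and "2EV" in composite_fit:
        f_tests["1EV_vs_2EV"] = f_test(composite_fit["1EV"], composite_fit["2EV"])
    if "2EV_DI" in composite_fit:
        # same observation set (tracer + intake) for both models
        simple_spec = ModelSpec(
            variant=Variant.ONE_EV, include_diet_constraint=True,
            absorption_efficiency=cfg.absorption_efficiency,
        )
        obs_di = _observation_set(composite, composite_M5, "2EV_DI", cfg)
        simple_di = fit(obs_di, simple_spec, start=cfg.start,
                        n_starts=cfg.n_starts, seed=cfg.seed)
        f_tests["1EV_vs_2EV_DI"] = f_test(simple_di, composite_fit["2EV_DI"])

    analysis = GroupAnalysis(
        label=label, config=cfg,
        subjects_included=[s.id for s in included],
        subjects_excluded=excluded,
        composite_M5=composite_M5,
        liver_weight_gm=liver_gm,
        composite_fit=composite_fit,
        composite_steady_state=composite_ss,
        f_tests=f_tests,
        log=log,
    )

    if cfg.per_subject:
        for s in included:
            try:
                M5 = s.plasma_pool(cfg.plasma_volume_per_kg)
                res_by_tr = {}
                for tr in cfg.treatments:
                    r = _fit_treatment(s.tracer, M5, tr, cfg)
                    res_by_tr[tr] = {"fit": r, "steady_state": r.steady_state()}
                analysis.per_subject[s.id] = res_by_tr
            except Exception as exc:  # keep the group running
                analysis.per_subject_errors[s.id] = f"{type(exc).__name__}: {exc}"
                log.append(f"subject {s.id} failed: {exc}")

        for tr in cfg.treatments:
            vals: dict[str, list[float]] = {}
            screened = []
            for sid, res in analysis.per_subject.items():
                if tr not in res:
                    continue
                f = res[tr]["fit"]
                if not f.identifiable or (
                    f.param_fsd and max(f.param_fsd.values()) > cfg.max_param_fsd
                ):
                    screened.append(sid)
                    continue
                for k, v in res[tr]["steady_state"].as_dict().items():
                    if np.isfinite(v) and v > 0:
                        vals.setdefault(k, []).append(v)
            if screened:
                log.append(
                    f"{tr}: per-subject fits excluded from summaries "
                    f"(parameter fsd > {cfg.max_param_fsd}): {screened}"
                )
            analysis.group_geometric_means[tr] = {
                k: group_summary(v)["geometric_mean"] for k, v in vals.items() if v
            }

    return analysis


def intake_sensitivity(
    subjects: Sequence[SubjectRecord],
    config: Optional[GroupConfig] = None,
    multipliers: Sequence[float] = (0.5, 1.0, 1.5),
) -> pd.DataFrame:
    """Sensitivity of composite TBS to the assumed dietary intake.

    Refits the diet-constrained model with the intake observation scaled by
    each multiplier; percent change in TBS is relative to the multiplier-1.0
    run.  Columns: multiplier, intake_umol_per_d, TBS_umol, pct_change_TBS.
    """
    cfg = config or GroupConfig()
    if "2EV_DI" not in cfg.treatments:
        raise ValueError("intake sensitivity requires the 2EV_DI treatment")
    included = [s for s in subjects if identifiable_late(s, cfg)]
    pools = [s.plasma_pool(cfg.plasma_volume_per_kg) for s in included]
    M5 = group_summary(pools, dispersion=False)["geometric_mean"]
    composite = geometric_mean_curve(included, cfg.grid_tolerance)

    mults = sorted(set(float(m) for m in multipliers) | {1.0})
    rows = []
    tbs = {}
    for m in mults:
        intake = m * cfg.intake_umol_per_d
        res = _fit_treatment(composite, M5, "2EV_DI", cfg, intake=intake)
        tbs[m] = res.steady_state().TBS
        rows.append({"multiplier": m, "intake_umol_per_d": intake,
                     "TBS_umol": tbs[m]})
    base = tbs[1.0]
    for r in rows:
        r["pct_change_TBS"] = 100.0 * (r["TBS_umol"] - base) / base
    df = pd.DataFrame(rows)
    return df[df["multiplier"].isin([float(m) for m in multipliers])].reset_index(drop=True)
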