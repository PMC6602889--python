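"""Readers, writers and configuration for the analysis pipeline.

File formats (comma-separated, '.' decimal, UTF-8, header required; times in
days):

* tracer CSV: columns ``time_d, fdp`` — one plasma observation per row;
* subjects CSV: one row per subject with covariates and the path (relative
  to the CSV) of the subject's tracer CSV;
* parameter config (YAML or JSON): flat keys ``L_2_1`` ... ``DT_3`` plus
  ``variant`` ("1EV"/"2EV") and ``absorption_efficiency``;
* group report: result JSON, a subjects table, a steady-state table with one
  column per model treatment, and a plain-text run log.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .kinetics import KineticParameters, ModelSpec, TracerCurve, Variant
from .pipeline import GroupAnalysis, GroupConfig, SubjectRecord

__all__ = [
    "ValidationError",
    "read_tracer_csv",
    "write_tracer_csv",
    "read_subjects",
    "write_subjects",
    "load_params_config",
    "save_params_config",
    "load_group_config",
    "write_report",
]

SUBJECT_COLUMNS = [
    "id", "sex", "age_y", "body_weight_kg", "bmi_kg_m2",
    "mean_serum_retinol_umol_l", "liver_weight_g", "group", "tracer_csv",
]


class ValidationError(ValueError):
    """Malformed or inconsistent input data (message names the location)."""


def read_tracer_csv(path) -> TracerCurve:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(f"{path}: cannot parse CSV ({exc})") from exc
    for col in ("time_d", "fdp"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise ValidationError(f"{path}: non-numeric {col} at line {row}")
    t = df["time_d"].to_numpy(float)
    y = df["fdp"].to_numpy(float)
    dup = np.nonzero(np.diff(t) == 0)[0]
    if dup.size:
        raise ValidationError(f"{path}: duplicated time at line {int(dup[0]) + 3}")
    order = np.nonzero(np.diff(t) < 0)[0]
    if order.size:
        raise ValidationError(f"{path}: times out of order at line {int(order[0]) + 3}")
    neg = np.nonzero((y < 0) | (y > 1))[0]
    if neg.size:
        raise ValidationError(f"{path}: fdp outside [0, 1] at line {int(neg[0]) + 2}")
    try:
        return TracerCurve(times=t, fdp=y)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_tracer_csv(curve: TracerCurve, path) -> None:
    pd.DataFrame({"time_d": curve.times, "fdp": curve.fdp}).to_csv(
        path, index=False
    )


def read_subjects(path) -> list[SubjectRecord]:
    """Read a subjects CSV; tracer paths resolve relative to the CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(f"{path}: cannot parse CSV ({exc})") from exc
    required = [c for c in SUBJECT_COLUMNS if c not in ("liver_weight_g", "group")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    subjects = []
    for k, row in df.iterrows():
        line = int(k) + 2
        tracer_path = path.parent / str(row["tracer_csv"])
        if not tracer_path.exists():
            raise ValidationError(
                f"{path} line {line}: tracer file {tracer_path} not found"
            )
        tracer = read_tracer_csv(tracer_path)
        liver = row.get("liver_weight_g")
        group = row.get("group")
        try:
            subjects.append(
                SubjectRecord(
                    id=str(row["id"]),
                    sex=str(row["sex"]),
                    age_y=float(row["age_y"]),
                    body_weight_kg=float(row["body_weight_kg"]),
                    bmi_kg_m2=float(row["bmi_kg_m2"]),
                    mean_serum_retinol_umol_l=float(row["mean_serum_retinol_umol_l"]),
                    liver_weight_g=float(liver) if pd.notna(liver) else None,
                    group=str(group) if pd.notna(group) else None,
                    tracer=tracer,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path} line {line}: {exc}") from exc
    return subjects


def write_subjects(subjects: Sequence[SubjectRecord], outdir) -> Path:
    """Write subjects.csv plus per-subject tracer CSVs (and any ground truth).

    Returns the path of the subjects CSV.  Synthetic subjects carry their
    generating parameters and true steady state; these are written to a
    ``ground_truth.json`` sidecar.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows, truths = [], {}
    for s in subjects:
        tracer_name = f"tracer_{s.id}.csv"
        write_tracer_csv(s.tracer, outdir / tracer_name)
        rows.append({
            "id": s.id, "sex": s.sex, "age_y": s.age_y,
            "body_weight_kg": s.body_weight_kg, "bmi_kg_m2": s.bmi_kg_m2,
            "mean_serum_retinol_umol_l": s.mean_serum_retinol_umol_l,
            "liver_weight_g": s.liver_weight_g, "group": s.group,
            "tracer_csv": tracer_name,
        })
        if s.ground_truth is not None:
            truths[s.id] = s.ground_truth
    csv_path = outdir / "subjects.csv"
    pd.DataFrame(rows, columns=SUBJECT_COLUMNS).to_csv(csv_path, index=False)
    if truths:
        (outdir / "ground_truth.json").write_text(json.dumps(truths, indent=1))
    return csv_path


def load_params_config(path) -> tuple[KineticParameters, ModelSpec]:
    """Read a flat parameter config (YAML or JSON by extension)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping")
    variant = Variant(str(data.pop("variant", "2EV")))
    absorption = float(data.pop("absorption_efficiency", 0.75))
    spec = ModelSpec(variant=variant, absorption_efficiency=absorption)
    try:
        params = KineticParameters.from_dict(data)
        params.validate_for(spec)
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    return params, spec


def save_params_config(params: KineticParameters, spec: ModelSpec, path) -> None:
    data = {"variant": spec.variant.value,
            "absorption_efficiency": spec.absorption_efficiency}
    data.update(params.to_dict())
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=1))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_group_config(path) -> GroupConfig:
    """Read a group-analysis config (YAML/JSON) into a GroupConfig."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping")
    known = {f.name for f in dataclasses.fields(GroupConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    if "treatments" in data:
        data["treatments"] = tuple(data["treatments"])
    try:
        return GroupConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_report(analysis: GroupAnalysis, outdir) -> dict[str, Path]:
    """Write result JSON, steady-state table, and the run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["results"] = outdir / f"{analysis.label}_results.json"
    paths["results"].write_text(
        json.dumps(analysis.to_dict(), indent=1, default=_json_default)
    )

    paths["steady_state"] = outdir / f"{analysis.label}_steady_state.csv"
    analysis.steady_state_table().to_csv(paths["steady_state"])

    paths["log"] = outdir / f"{analysis.label}_run.log"
    paths["log"].write_text("\n".join(analysis.log) + "\n")
    return paths


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
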