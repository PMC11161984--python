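"""Case-file formats, pipeline orchestration and report assembly.

Cases are stored one per JSON file (schema version 1) in a cohort
directory, alongside a ``cohort.csv`` covariate table.  Coordinates are
written in anatomical coordinates: left-sided cases are mirrored across
the midsagittal plane on write and mirrored back into the canonical
measurement frame (x lateral toward the measured side) on read.
Measurements are emitted as a fixed-column CSV; the stats report is JSON
with the active configuration embedded so any report is regenerable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__ as _version
from .errors import KambinError, MeasurementError, ValidationError
from .geometry import PlanePatch
from .measure import (
    FACET_LANDMARK_NAMES,
    CaseMeasurements,
    LumbarCase,
    MeasurementConfig,
    measure_case,
    mirror_case,
)
from .stats import cohort_report

log = logging.getLogger("kambin")

SCHEMA_VERSION = 1

#: stable machine-readable contract for the measurements CSV
MEASUREMENT_COLUMNS = (
    "case_id", "side", "sex", "age", "bmi",
    "d_mm", "beta_deg",
    "J_x_mm", "J_y_mm", "J_z_mm",
    "quadrant", "L1_mm", "L2_mm", "safe_L1", "safe_L2",
)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; lengths mm, alpha in (0, 1)."""

    trephine_diameter: float = 8.0
    comparison_diameter: float = 10.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.trephine_diameter > 0 and self.comparison_diameter > 0):
            raise ValidationError("diameters must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")

    def measurement(self) -> MeasurementConfig:
        return MeasurementConfig(trephine_diameter=self.trephine_diameter)


# ---------------------------------------------------------------------------
# case serialization
# ---------------------------------------------------------------------------


def _point(v) -> List[float]:
    return [float(x) for x in v]


def case_to_record(case: LumbarCase) -> Dict[str, object]:
    """Serializable record in anatomical coordinates (units: mm)."""
    stored = mirror_case(case, flip_side=False) if case.side == "left" else case
    patch = stored.facet_patch
    return {
        "schema_version": SCHEMA_VERSION,
        "case_id": stored.case_id,
        "side": stored.side,
        "units": "mm",
        "landmarks": {
            "A": _point(stored.A),
            "B": _point(stored.B),
            "C": _point(stored.C),
            "E": _point(stored.E),
        },
        "disc_corners": [_point(c) for c in stored.disc_corners],
        "facet_landmarks": {
            k: _point(v) for k, v in stored.facet_landmarks.items()
        },
        "facet_patch": {
            "origin": _point(patch.origin),
            "u_axis": _point(patch.u_axis),
            "v_axis": _point(patch.v_axis),
            "u_range": list(patch.u_range),
            "v_range": list(patch.v_range),
        },
        "wire_offset": list(case.wire_offset),
        "covariates": {"sex": stored.sex, "age": stored.age, "bmi": stored.bmi},
    }


def _require(record: Dict, key: str, case_id: str):
    if key not in record:
        raise ValidationError(f"case {case_id!r}: missing field {key!r}")
    return record[key]


def record_to_case(record: Dict[str, object]) -> LumbarCase:
    """Parse and validate one case record; mirrors left cases to canonical."""
    case_id = str(record.get("case_id", "<unknown>"))
    version = record.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValidationError(
            f"case {case_id!r}: unknown schema version {version!r} "
            f"(expected {SCHEMA_VERSION})"
        )
    if record.get("units", "mm") != "mm":
        raise ValidationError(f"case {case_id!r}: units must be mm")
    landmarks = _require(record, "landmarks", case_id)
    for name in ("A", "B", "C", "E"):
        if name not in landmarks:
            raise ValidationError(f"case {case_id!r}: missing landmark {name!r}")
    facet = _require(record, "facet_landmarks", case_id)
    for name in FACET_LANDMARK_NAMES:
        if name not in facet:
            raise ValidationError(f"case {case_id!r}: missing facet landmark {name!r}")
    patch_rec = _require(record, "facet_patch", case_id)
    for name in ("origin", "u_axis", "v_axis", "u_range", "v_range"):
        if name not in patch_rec:
            raise ValidationError(f"case {case_id!r}: facet_patch missing {name!r}")
    cov = _require(record, "covariates", case_id)
    for name in ("sex", "age", "bmi"):
        if name not in cov:
            raise ValidationError(f"case {case_id!r}: missing covariate {name!r}")
    try:
        case = LumbarCase(
            case_id=case_id,
            side=str(_require(record, "side", case_id)),
            A=landmarks["A"],
            B=landmarks["B"],
            C=landmarks["C"],
            E=landmarks["E"],
            disc_corners=np.asarray(_require(record, "disc_corners", case_id), float),
            facet_landmarks={k: facet[k] for k in FACET_LANDMARK_NAMES},
            facet_patch=PlanePatch(
                origin=patch_rec["origin"],
                u_axis=patch_rec["u_axis"],
                v_axis=patch_rec["v_axis"],
                u_range=tuple(patch_rec["u_range"]),
                v_range=tuple(patch_rec["v_range"]),
            ),
            sex=str(cov["sex"]),
            age=float(cov["age"]),
            bmi=float(cov["bmi"]),
            wire_offset=tuple(record.get("wire_offset", (0.0, 0.0))),
        )
    except KambinError:
        raise
    except Exception as exc:
        raise ValidationError(f"case {case_id!r}: malformed record: {exc}") from exc
    # files hold anatomical coordinates; measure in the canonical frame
    return mirror_case(case, flip_side=False) if case.side == "left" else case


def write_cases(cases: Sequence[LumbarCase], path: Union[str, Path]) -> Path:
    """Write one JSON file per case plus a covariate table ``cohort.csv``."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        record = case_to_record(case)
        (out / f"{case.case_id}.json").write_text(
            json.dumps(record, indent=1, sort_keys=True) + "\n"
        )
        rows.append(
            {"case_id": case.case_id, "side": case.side, "sex": case.sex,
             "age": case.age, "bmi": case.bmi}
        )
    pd.DataFrame(rows).to_csv(out / "cohort.csv", index=False)
    log.info("wrote %d cases to %s", len(cases), out)
    return out


def read_cases(
    path: Union[str, Path]
) -> Tuple[List[LumbarCase], List[Tuple[str, Exception]]]:
    """Load a cohort directory (or a single case file).

    Returns the successfully parsed cases plus a list of (filename, error)
    for files that failed validation; valid files are always loaded.
    """
    p = Path(path)
    files = sorted(p.glob("*.json")) if p.is_dir() else [p]
    files = [f for f in files if f.name != "cohort.csv"]
    if not files:
        raise ValidationError(f"no case files found under {p}")
    cases: List[LumbarCase] = []
    errors: List[Tuple[str, Exception]] = []
    for f in files:
        try:
            record = json.loads(f.read_text())
            cases.append(record_to_case(record))
        except (KambinError, json.JSONDecodeError, OSError) as exc:
            log.error("failed to load %s: %s", f.name, exc)
            errors.append((f.name, exc))
    return cases, errors


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def measurements_to_frame(
    cases: Sequence[LumbarCase], results: Sequence[CaseMeasurements]
) -> pd.DataFrame:
    rows = []
    for case, m in zip(cases, results):
        rows.append({
            "case_id": m.case_id, "side": m.side, "sex": case.sex,
            "age": case.age, "bmi": case.bmi,
            "d_mm": m.d, "beta_deg": m.beta,
            "J_x_mm": float(m.J[0]), "J_y_mm": float(m.J[1]),
            "J_z_mm": float(m.J[2]),
            "quadrant": m.quadrant, "L1_mm": m.L1, "L2_mm": m.L2,
            "safe_L1": m.safe_L1, "safe_L2": m.safe_L2,
        })
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def run_pipeline(
    cases: Sequence[LumbarCase],
    config: Optional[RunConfig] = None,
) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Measure a cohort and assemble the statistics report.

    Per-case failures are collected into the report's errors section
    without aborting the cohort; an empty (or fully failing) cohort raises.
    """
    cfg = config or RunConfig()
    if len(cases) == 0:
        raise ValidationError("empty cohort: nothing to measure")
    mcfg = cfg.measurement()
    measured_cases: List[LumbarCase] = []
    results: List[CaseMeasurements] = []
    errors: List[Dict[str, str]] = []
    for case in cases:
        try:
            results.append(measure_case(case, mcfg))
            measured_cases.append(case)
        except MeasurementError as exc:
            log.error("%s", exc)
            errors.append(
                {"case_id": exc.case_id, "stage": exc.stage, "error": str(exc.cause)}
            )
    if not results:
        raise ValidationError("all cases failed measurement")
    frame = measurements_to_frame(measured_cases, results)
    report: Dict[str, object] = {
        "header": {
            "package": "kambin",
            "version": _version,
            "config": asdict(cfg),
            "n_cases": len(results),
            "n_errors": len(errors),
            "conventions": {
                "frame": "x lateral (measured side), y posterior, z superior; mm",
                "beta": "transverse-plane projection of lines OD and DE, degrees",
                "axis": "through O + wire_offset, parallel to the disc plane",
                "L2": "shortest distance rule (same as L1)",
                "quadrant_ties": "half-open, favouring upper/outer",
                "roots": "zero-radius segments (clearances are upper bounds)",
            },
        },
        "statistics": cohort_report(
            frame,
            trephine_diameter=cfg.trephine_diameter,
            comparison_diameter=cfg.comparison_diameter,
            alpha=cfg.alpha,
        ),
        "errors": errors,
    }
    return frame, report


def write_report(report: Dict[str, object], path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
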