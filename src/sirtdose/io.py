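"""Cohort schema readers/writers, run configuration, and the pipeline driver.

Cohort files are plain text in two equivalent dialects:

* **CSV** — UTF-8, comma-separated, one lesion per row with the
  treatment-level fields repeated, preceded by a version comment line
  (``# sirtdose-cohort-v1``).
* **JSON** — nested: ``{"schema_version": 1, "treatments": [...]}`` with a
  ``lesions`` list inside each treatment.

Doses are Gy, activities GBq, masses kg, volumes ml; these are the only
accepted units and are enforced at parse time through the domain-type
invariants.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

import sirtdose
from sirtdose.cohort import CohortConfig, generate_cohort
from sirtdose.dosimetry import Lesion, Treatment
from sirtdose.ntcp_planning import ntcp_cohort_summary
from sirtdose.parameterization import (
    DEFAULT_PM_AXIS,
    DEFAULT_SM_AXIS,
    build_chart,
    delta_tcp_histogram,
    equivalence_line,
    volume_stratified_concordance,
)
from sirtdose.response import NTCPParams, TCPModel

__all__ = [
    "SCHEMA_VERSION",
    "CohortSchemaError",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_cohort_json",
    "read_cohort_json",
    "read_cohort",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
_CSV_MAGIC = "# sirtdose-cohort-v1"

_TREATMENT_COLUMNS = [
    "treatment_id",
    "patient_id",
    "lobe_mass_kg",
    "normal_liver_mass_kg",
    "whole_liver_mass_kg",
    "lung_shunt_fraction",
    "tnr",
    "targeted_volume_fraction",
    "normal_liver_dpa_delivered_gy_gbq",
    "normal_liver_dpa_planning_gy_gbq",
    "microsphere_specific_activity_kbq",
    "injected_activity_gbq",
]
_LESION_COLUMNS = [
    "lesion_id",
    "lesion_volume_ml",
    "lesion_dpa_delivered_gy_gbq",
    "lesion_dpa_planning_gy_gbq",
]


class CohortSchemaError(ValueError):
    """Cohort file does not match the documented schema."""


def _cohort_frame(cohort: list[Treatment]) -> pd.DataFrame:
    rows = []
    for t in cohort:
        base = {
            "treatment_id": t.treatment_id,
            "patient_id": t.patient_id if t.patient_id is not None else "",
            "lobe_mass_kg": t.lobe_mass,
            "normal_liver_mass_kg": t.normal_liver_mass,
            "whole_liver_mass_kg": t.whole_liver_mass,
            "lung_shunt_fraction": t.lung_shunt_fraction,
            "tnr": t.tnr,
            "targeted_volume_fraction": t.targeted_volume_fraction,
            "normal_liver_dpa_delivered_gy_gbq": t.normal_liver_dose_per_activity_delivered,
            "normal_liver_dpa_planning_gy_gbq": t.normal_liver_dose_per_activity_planning,
            "microsphere_specific_activity_kbq": (
                t.microsphere_specific_activity
                if t.microsphere_specific_activity is not None
                else ""
            ),
            "injected_activity_gbq": (
                t.injected_activity if t.injected_activity is not None else ""
            ),
        }
        for les in t.lesions:
            rows.append(
                {
                    **base,
                    "lesion_id": les.lesion_id,
                    "lesion_volume_ml": les.volume,
                    "lesion_dpa_delivered_gy_gbq": les.delivered_dose_per_activity,
                    "lesion_dpa_planning_gy_gbq": les.planning_dose_per_activity,
                }
            )
    return pd.DataFrame(rows, columns=_TREATMENT_COLUMNS + _LESION_COLUMNS)


def write_cohort_csv(cohort: list[Treatment], path: str | Path) -> None:
    """Write the cohort as versioned one-lesion-per-row CSV."""
    path = Path(path)
    frame = _cohort_frame(cohort)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_CSV_MAGIC + "\n")
        frame.to_csv(fh, index=False)


def _optional_float(value) -> float | None:
    if value is None or value == "" or pd.isna(value):
        return None
    return float(value)


def _treatments_from_frame(frame: pd.DataFrame) -> list[Treatment]:
    missing = [c for c in _TREATMENT_COLUMNS + _LESION_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"missing required columns: {missing}")
    treatments: list[Treatment] = []
    for tid, group in frame.groupby("treatment_id", sort=False):
        first = group.iloc[0]
        for col in _TREATMENT_COLUMNS:
            if group[col].nunique(dropna=False) > 1:
                raise CohortSchemaError(
                    f"treatment {tid}: inconsistent values in column {col!r}"
                )
        lesions = []
        for idx, row in group.iterrows():
            try:
                lesions.append(
                    Lesion(
                        lesion_id=str(row["lesion_id"]),
                        volume=float(row["lesion_volume_ml"]),
                        delivered_dose_per_activity=float(row["lesion_dpa_delivered_gy_gbq"]),
                        planning_dose_per_activity=float(row["lesion_dpa_planning_gy_gbq"]),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise CohortSchemaError(f"row {idx + 2}: {exc}") from exc
        patient = first["patient_id"]
        try:
            treatments.append(
                Treatment(
                    treatment_id=str(tid),
                    patient_id=str(patient) if patient not in ("", None) and not pd.isna(patient) else None,
                    lobe_mass=float(first["lobe_mass_kg"]),
                    normal_liver_mass=float(first["normal_liver_mass_kg"]),
                    whole_liver_mass=float(first["whole_liver_mass_kg"]),
                    lung_shunt_fraction=float(first["lung_shunt_fraction"]),
                    tnr=float(first["tnr"]),
                    lesions=lesions,
                    targeted_volume_fraction=float(first["targeted_volume_fraction"]),
                    normal_liver_dose_per_activity_delivered=float(
                        first["normal_liver_dpa_delivered_gy_gbq"]
                    ),
                    normal_liver_dose_per_activity_planning=float(
                        first["normal_liver_dpa_planning_gy_gbq"]
                    ),
                    microsphere_specific_activity=_optional_float(
                        first["microsphere_specific_activity_kbq"]
                    ),
                    injected_activity=_optional_float(first["injected_activity_gbq"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise CohortSchemaError(f"treatment {tid}: {exc}") from exc
    return treatments


def read_cohort_csv(path: str | Path) -> list[Treatment]:
    """Read and validate a versioned cohort CSV."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first_line = fh.readline().strip()
    if first_line != _CSV_MAGIC:
        raise CohortSchemaError(
            f"{path}: expected version header {_CSV_MAGIC!r}, found {first_line!r}"
        )
    frame = pd.read_csv(path, comment="#", dtype={"treatment_id": str, "patient_id": str, "lesion_id": str})
    return _treatments_from_frame(frame)


def write_cohort_json(cohort: list[Treatment], path: str | Path) -> None:
    """Write the cohort as nested JSON."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "treatments": [
            {
                "treatment_id": t.treatment_id,
                "patient_id": t.patient_id,
                "lobe_mass_kg": t.lobe_mass,
                "normal_liver_mass_kg": t.normal_liver_mass,
                "whole_liver_mass_kg": t.whole_liver_mass,
                "lung_shunt_fraction": t.lung_shunt_fraction,
                "tnr": t.tnr,
                "targeted_volume_fraction": t.targeted_volume_fraction,
                "normal_liver_dpa_delivered_gy_gbq": t.normal_liver_dose_per_activity_delivered,
                "normal_liver_dpa_planning_gy_gbq": t.normal_liver_dose_per_activity_planning,
                "microsphere_specific_activity_kbq": t.microsphere_specific_activity,
                "injected_activity_gbq": t.injected_activity,
                "lesions": [
                    {
                        "lesion_id": les.lesion_id,
                        "volume_ml": les.volume,
                        "dpa_delivered_gy_gbq": les.delivered_dose_per_activity,
                        "dpa_planning_gy_gbq": les.planning_dose_per_activity,
                    }
                    for les in t.lesions
                ],
            }
            for t in cohort
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_cohort_json(path: str | Path) -> list[Treatment]:
    """Read and validate a nested-JSON cohort."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise CohortSchemaError(
            f"{path}: schema_version {payload.get('schema_version')!r} "
            f"(expected {SCHEMA_VERSION})"
        )
    treatments = []
    for entry in payload.get("treatments", []):
        try:
            lesions = [
                Lesion(
                    lesion_id=les["lesion_id"],
                    volume=float(les["volume_ml"]),
                    delivered_dose_per_activity=float(les["dpa_delivered_gy_gbq"]),
                    planning_dose_per_activity=float(les["dpa_planning_gy_gbq"]),
                )
                for les in entry.get("lesions", [])
            ]
            treatments.append(
                Treatment(
                    treatment_id=entry["treatment_id"],
                    patient_id=entry.get("patient_id"),
                    lobe_mass=float(entry["lobe_mass_kg"]),
                    normal_liver_mass=float(entry["normal_liver_mass_kg"]),
                    whole_liver_mass=float(entry["whole_liver_mass_kg"]),
                    lung_shunt_fraction=float(entry["lung_shunt_fraction"]),
                    tnr=float(entry["tnr"]),
                    lesions=lesions,
                    targeted_volume_fraction=float(entry["targeted_volume_fraction"]),
                    normal_liver_dose_per_activity_delivered=float(
                        entry["normal_liver_dpa_delivered_gy_gbq"]
                    ),
                    normal_liver_dose_per_activity_planning=float(
                        entry["normal_liver_dpa_planning_gy_gbq"]
                    ),
                    microsphere_specific_activity=entry.get("microsphere_specific_activity_kbq"),
                    injected_activity=entry.get("injected_activity_gbq"),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise CohortSchemaError(
                f"treatment {entry.get('treatment_id', '?')}: {exc}"
            ) from exc
    return treatments


def read_cohort(path: str | Path) -> list[Treatment]:
    """Dispatch on extension: ``.json`` -> JSON, anything else -> CSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_cohort_json(path)
    return read_cohort_csv(path)


@dataclass
class RunConfig:
    """Reproducible description of a full pipeline run."""

    output_dir: str = "sirtdose_out"
    cohort_path: str | None = None  # load when set, otherwise generate
    seed: int = 0
    tcp_midpoint: float = 150.0  # Gy
    tcp_slope: float = 50.0  # Gy
    sm_axis: list[float] = field(default_factory=lambda: list(DEFAULT_SM_AXIS))
    pm_axis: list[float] = field(default_factory=lambda: list(DEFAULT_PM_AXIS))
    histogram_sm_dose: float = 120.0  # Gy
    histogram_pm_dose: float = 75.0  # Gy
    histogram_bin_width: float = 5.0  # percentage points
    ntcp_target_p: float = 0.15
    reference_sm_dose: float = 120.0  # Gy
    vf_threshold: float = 0.40
    make_plots: bool = True
    log_level: str = "INFO"


def _plot_chart(grid, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 6))
    matrix = grid.mean_matrix()
    im = ax.imshow(matrix, origin="lower", aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(grid.sm_axis)), [f"{d:g}" for d in grid.sm_axis])
    ax.set_yticks(range(len(grid.pm_axis)), [f"{d:g}" for d in grid.pm_axis])
    ax.set_xlabel("Standard model prescription to perfused volume (Gy)")
    ax.set_ylabel("Partition model prescription to normal liver (Gy)")
    fig.colorbar(im, ax=ax, label="Mean change in TCP (percentage points)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_histogram(hist, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    widths = hist.bin_edges[1:] - hist.bin_edges[:-1]
    ax.bar(hist.bin_edges[:-1], hist.counts, width=widths, align="edge", edgecolor="k")
    ax.set_xlabel("Change in TCP per lesion (percentage points)")
    ax.set_ylabel("Lesions")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis: cohort -> chart -> histogram ->
    equivalence line -> NTCP summary -> concordance.

    Writes long-format CSVs (plus optional images) and a machine-readable
    manifest into ``config.output_dir``; returns the manifest dict.
    Deterministic per seed.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    stage = "cohort"
    timings: dict[str, float] = {}
    try:
        t = time.time()
        if config.cohort_path:
            cohort = read_cohort(config.cohort_path)
        else:
            cohort = generate_cohort(CohortConfig(seed=config.seed))
            write_cohort_csv(cohort, out / "cohort.csv")
        if not cohort:
            raise ValueError("cohort is empty")
        timings[stage] = time.time() - t
        tcp_model = TCPModel(midpoint_dose=config.tcp_midpoint, slope=config.tcp_slope)

        stage = "chart"
        t = time.time()
        grid = build_chart(cohort, config.sm_axis, config.pm_axis, tcp_model)
        grid.to_frame().to_csv(out / "chart.csv", index=False)
        if config.make_plots:
            _plot_chart(grid, out / "chart.png")
        timings[stage] = time.time() - t

        stage = "histogram"
        t = time.time()
        hist = delta_tcp_histogram(
            cohort,
            config.histogram_sm_dose,
            config.histogram_pm_dose,
            tcp_model,
            config.histogram_bin_width,
        )
        hist.to_frame().to_csv(out / "histogram.csv", index=False)
        if config.make_plots:
            _plot_histogram(hist, out / "histogram.png")
        timings[stage] = time.time() - t

        stage = "equivalence"
        t = time.time()
        line = equivalence_line(cohort, config.sm_axis, tcp_model)
        pd.DataFrame(line, columns=["sm_dose", "pm_dose"]).to_csv(
            out / "equivalence.csv", index=False
        )
        timings[stage] = time.time() - t

        stage = "ntcp"
        t = time.time()
        table, summary = ntcp_cohort_summary(
            cohort,
            target_p=config.ntcp_target_p,
            reference_sm_dose=config.reference_sm_dose,
            params=NTCPParams(),
            vf_threshold=config.vf_threshold,
        )
        table.to_csv(out / "ntcp.csv", index=False)
        (out / "ntcp_summary.json").write_text(json.dumps(summary, indent=2))
        timings[stage] = time.time() - t

        stage = "concordance"
        t = time.time()
        concordance = volume_stratified_concordance(cohort)
        concordance.to_csv(out / "concordance.csv", index=False)
        timings[stage] = time.time() - t
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": sirtdose.__version__,
        "config": asdict(config),
        "n_treatments": len(cohort),
        "n_lesions": sum(t.n_lesions for t in cohort),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_runtime_s": round(time.time() - t0, 3),
        "ntcp_summary": summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
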