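"""Cohort data model, CSV I/O, lesion aggregation and pretreatment imputation.

Input schema (two comma-separated UTF-8 files, '.' decimal):

``lesions.csv`` — one row per contoured lesion per imaging timepoint:
    patient_id, timepoint (TP-1 | TP0 | TP+1 | TP+2), lesion_id,
    volume_cc (> 0), site (brain | liver | bone | lung | lymph_node | other)

``patients.csv`` — one row per patient:
    patient_id, de_novo (0/1), tp_minus1_offset_days (negative; empty for
    de-novo patients), primary_site, brain_met, liver_met, bone_met, lung_met
    (0/1 organ-involvement flags), os_days, os_event, pfs_days, pfs_event,
    pfs2_days, pfs2_event (event flags 0/1), best_response (CR | PR | SD | PD).
    Optional: tp_plus1_offset_days, tp_plus2_offset_days.

All internal times are day offsets relative to the treatment baseline TP0
(day 0); the pretreatment scan TP-1 has a strictly negative offset. De-novo
metastatic patients (no measurable disease before baseline) carry no TP-1
lesion rows; their TP-1 state is imputed as a small fixed volume at a fixed
offset (default 0.1 cc at -90 days, a typical surveillance-imaging interval).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .growth_models import (
    GrowthFit,
    InvalidInputError,
    fit_exponential_two_point,
    fit_growth_model,
    get_model,
)

logger = logging.getLogger(__name__)

TIMEPOINTS = ("TP-1", "TP0", "TP+1", "TP+2")
SITES = ("brain", "liver", "bone", "lung", "lymph_node", "other")
RESPONSE_LABELS = ("CR", "PR", "SD", "PD")

#: Observed pretreatment-interval range (days) of typical surveillance imaging;
#: intervals outside this range are admitted with a warning.
PLAUSIBLE_INTERVAL_RANGE = (-363.0, -6.0)

LESION_COLUMNS = ["patient_id", "timepoint", "lesion_id", "volume_cc", "site"]
PATIENT_COLUMNS = [
    "patient_id", "de_novo", "tp_minus1_offset_days", "primary_site",
    "brain_met", "liver_met", "bone_met", "lung_met",
    "os_days", "os_event", "pfs_days", "pfs_event",
    "pfs2_days", "pfs2_event", "best_response",
]


class CohortValidationError(ValueError):
    """Raised with the full list of schema violations found at load."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            "cohort validation failed with %d error(s):\n  " % len(errors)
            + "\n  ".join(errors)
        )


@dataclass(frozen=True)
class ImputationPolicy:
    """Assumed TP-1 state for de-novo patients: volume (cc) at offset (days < 0)."""

    volume: float = 0.1
    offset: float = -90.0

    def __post_init__(self) -> None:
        if not (self.volume > 0):
            raise InvalidInputError(f"imputation volume must be > 0, got {self.volume}")
        if not (self.offset < 0):
            raise InvalidInputError(f"imputation offset must be < 0, got {self.offset}")


@dataclass(frozen=True)
class PatientTimeline:
    """Per-patient cumulative-volume series with imputation provenance.

    ``offsets`` and ``total_volumes`` are keyed by timepoint label; volumes are
    exact sums over that patient's lesions. ``imputed`` marks timepoints whose
    values came from an imputation policy rather than imaging.
    """

    patient_id: str
    offsets: Mapping[str, float]
    total_volumes: Mapping[str, float]
    de_novo: bool
    n_met_baseline: int
    covariates: Mapping[str, object] = field(default_factory=dict)
    imputed: frozenset = frozenset()
    imputation_applied: bool = False

    def pretreatment_observations(self) -> list[tuple[float, float, bool]]:
        """(t, volume, imputed) for TP-1 and TP0, sorted by t."""
        out = []
        for tp in ("TP-1", "TP0"):
            if tp in self.total_volumes:
                out.append((self.offsets[tp], self.total_volumes[tp], tp in self.imputed))
        return sorted(out)


def aggregate_lesions(lesions: pd.DataFrame, timepoint: str) -> float | None:
    """Exact sum of one patient's lesion volumes at ``timepoint``.

    Returns None (absent-timepoint signal) when no lesion was contoured there.
    """
    if timepoint not in TIMEPOINTS:
        raise InvalidInputError(f"unknown timepoint {timepoint!r}")
    sub = lesions.loc[lesions["timepoint"] == timepoint, "volume_cc"]
    if sub.empty:
        return None
    return float(sub.sum())


@dataclass
class Cohort:
    """Validated cohort: lesion table, patient table, per-patient timelines."""

    lesions: pd.DataFrame
    patients: pd.DataFrame
    timelines: dict[str, PatientTimeline]

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patients["patient_id"])

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def met_counts(self) -> pd.Series:
        """Baseline (TP0) metastatic lesion count per patient."""
        return pd.Series(
            {pid: tl.n_met_baseline for pid, tl in self.timelines.items()},
            name="n_met_baseline",
        ).loc[self.patient_ids]

    def to_csv(self, lesions_path: str | Path, patients_path: str | Path) -> None:
        self.lesions.to_csv(lesions_path, index=False)
        self.patients.to_csv(patients_path, index=False)


def _validate_lesions(df: pd.DataFrame, errors: list[str]) -> None:
    missing = [c for c in LESION_COLUMNS if c not in df.columns]
    if missing:
        errors.append(f"lesions file: missing required column(s) {missing}")
        return
    # row numbers reported are 1-based file lines (header is line 1)
    bad_tp = ~df["timepoint"].isin(TIMEPOINTS)
    for idx in df.index[bad_tp]:
        errors.append(f"lesions row {idx + 2}: unknown timepoint "
                      f"{df.at[idx, 'timepoint']!r}")
    vol = pd.to_numeric(df["volume_cc"], errors="coerce")
    bad_vol = ~(vol > 0)
    for idx in df.index[bad_vol]:
        errors.append(f"lesions row {idx + 2}: non-positive volume "
                      f"{df.at[idx, 'volume_cc']!r}")
    bad_site = ~df["site"].isin(SITES)
    for idx in df.index[bad_site]:
        errors.append(f"lesions row {idx + 2}: unknown site {df.at[idx, 'site']!r}")
    dup = df.duplicated(subset=["patient_id", "timepoint", "lesion_id"])
    for idx in df.index[dup]:
        errors.append(
            f"lesions row {idx + 2}: duplicate lesion key "
            f"({df.at[idx, 'patient_id']}, {df.at[idx, 'timepoint']}, "
            f"{df.at[idx, 'lesion_id']})"
        )


def _validate_patients(df: pd.DataFrame, errors: list[str]) -> None:
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        errors.append(f"patients file: missing required column(s) {missing}")
        return
    dup = df.duplicated(subset=["patient_id"])
    for idx in df.index[dup]:
        errors.append(f"patients row {idx + 2}: duplicate patient_id "
                      f"{df.at[idx, 'patient_id']!r}")

    def report(mask: pd.Series, message: str) -> None:
        for idx in df.index[mask]:
            errors.append(f"patients row {idx + 2} "
                          f"({df.at[idx, 'patient_id']}): {message}")

    for ep in ("os", "pfs", "pfs2"):
        t = pd.to_numeric(df[f"{ep}_days"], errors="coerce")
        report(~(t >= 0), f"negative or missing {ep}_days")
        report(~df[f"{ep}_event"].isin((0, 1, 0.0, 1.0, True, False)),
               f"{ep}_event must be 0/1")
    pfs = pd.to_numeric(df["pfs_days"], errors="coerce")
    report(pfs > pd.to_numeric(df["os_days"], errors="coerce"),
           "pfs_days > os_days")
    report(pfs > pd.to_numeric(df["pfs2_days"], errors="coerce"),
           "pfs_days > pfs2_days")
    report(~df["best_response"].isin(RESPONSE_LABELS),
           f"best_response must be one of {RESPONSE_LABELS}")

    measured = ~df["de_novo"].astype(bool)
    off = pd.to_numeric(df["tp_minus1_offset_days"], errors="coerce")
    report(measured & ~(off < 0),
           "measured-TP-1 patient needs a strictly negative tp_minus1_offset_days")
    implausible = measured & (off < 0) & (
        (off < PLAUSIBLE_INTERVAL_RANGE[0]) | (off > PLAUSIBLE_INTERVAL_RANGE[1])
    )
    for idx in df.index[implausible]:
        warnings.warn(
            f"patient {df.at[idx, 'patient_id']}: TP-1 offset "
            f"{df.at[idx, 'tp_minus1_offset_days']} d outside the typical "
            f"surveillance range {PLAUSIBLE_INTERVAL_RANGE}",
            stacklevel=3,
        )


def build_timeline(
    patient_row: Mapping,
    lesions: pd.DataFrame,
    totals: Mapping[str, float] | None = None,
    n_met_baseline: int | None = None,
) -> PatientTimeline:
    """Assemble one patient's timeline from their lesion rows.

    ``totals``/``n_met_baseline`` may carry precomputed per-timepoint volume
    sums and the TP0 lesion count (exact sums, identical to
    :func:`aggregate_lesions`); they are derived from ``lesions`` otherwise.
    """
    pid = str(patient_row["patient_id"])
    de_novo = bool(patient_row["de_novo"])
    if totals is None:
        totals = {
            tp: total for tp in TIMEPOINTS
            if (total := aggregate_lesions(lesions, tp)) is not None
        }
    if n_met_baseline is None:
        n_met_baseline = int((lesions["timepoint"] == "TP0").sum())
    offsets: dict[str, float] = {}
    volumes: dict[str, float] = {}
    for tp in TIMEPOINTS:
        if tp not in totals:
            continue
        volumes[tp] = totals[tp]
        if tp == "TP0":
            offsets[tp] = 0.0
        elif tp == "TP-1":
            offsets[tp] = float(patient_row["tp_minus1_offset_days"])
        else:
            col = "tp_plus1_offset_days" if tp == "TP+1" else "tp_plus2_offset_days"
            default = 63.0 if tp == "TP+1" else 126.0
            val = patient_row.get(col, default) if hasattr(patient_row, "get") else default
            offsets[tp] = float(val) if pd.notna(val) else default
    covariates = {
        k: patient_row[k]
        for k in ("primary_site", "brain_met", "liver_met", "bone_met", "lung_met",
                  "best_response")
        if k in patient_row
    }
    return PatientTimeline(
        patient_id=pid, offsets=offsets, total_volumes=volumes,
        de_novo=de_novo, n_met_baseline=n_met_baseline, covariates=covariates,
    )


def load_cohort(lesions_path: str | Path, patients_path: str | Path) -> Cohort:
    """Load and validate the two-file cohort; all violations reported at once."""
    for p in (lesions_path, patients_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    lesions = pd.read_csv(lesions_path, dtype={"patient_id": str, "lesion_id": str})
    patients = pd.read_csv(patients_path, dtype={"patient_id": str})
    return build_cohort(lesions, patients)


def build_cohort(lesions: pd.DataFrame, patients: pd.DataFrame) -> Cohort:
    """Validate in-memory lesion/patient tables and assemble timelines."""
    errors: list[str] = []
    _validate_lesions(lesions, errors)
    _validate_patients(patients, errors)
    if not errors:
        sums = lesions.groupby(["patient_id", "timepoint"], sort=False)["volume_cc"].sum()
        counts = lesions.groupby(["patient_id", "timepoint"], sort=False).size()
        totals_by_patient: dict[str, dict[str, float]] = {}
        n_met_by_patient: dict[str, int] = {}
        for (pid, tp), total in sums.items():
            totals_by_patient.setdefault(pid, {})[tp] = float(total)
        for (pid, tp), cnt in counts.items():
            if tp == "TP0":
                n_met_by_patient[pid] = int(cnt)
        timelines: dict[str, PatientTimeline] = {}
        for row in patients.to_dict("records"):
            pid = str(row["patient_id"])
            totals = totals_by_patient.get(pid, {})
            if "TP0" not in totals:
                errors.append(f"patient {pid}: no TP0 lesion measurements (baseline "
                              f"is required for every patient)")
                continue
            if bool(row["de_novo"]) and "TP-1" in totals:
                errors.append(f"patient {pid}: flagged de_novo but has TP-1 lesions")
                continue
            if not bool(row["de_novo"]) and "TP-1" not in totals:
                errors.append(f"patient {pid}: measured-TP-1 patient has no TP-1 "
                              f"lesion rows (flag de_novo for imputation)")
                continue
            timelines[pid] = build_timeline(
                row, lesions, totals=totals,
                n_met_baseline=n_met_by_patient.get(pid, 0),
            )
        stray = set(lesions["patient_id"]) - set(patients["patient_id"])
        for pid in sorted(stray):
            errors.append(f"lesions file: patient {pid} absent from patients file")
    if errors:
        raise CohortValidationError(errors)
    logger.info("loaded cohort: %d patients, %d lesion rows, %d de-novo",
                len(patients), len(lesions), int(patients["de_novo"].sum()))
    return Cohort(lesions=lesions, patients=patients, timelines=timelines)


def impute_pretreatment(
    timeline: PatientTimeline, policy: ImputationPolicy = ImputationPolicy()
) -> PatientTimeline:
    """Insert the assumed TP-1 state for a de-novo patient; no-op otherwise.

    Idempotent: a timeline that already carries TP-1 data (measured or
    previously imputed) is returned unchanged.
    """
    if "TP0" not in timeline.total_volumes:
        raise InvalidInputError(f"patient {timeline.patient_id}: TP0 missing")
    if "TP-1" in timeline.total_volumes:
        return timeline
    smallest_tp0 = timeline.total_volumes["TP0"]
    if policy.volume > smallest_tp0:
        warnings.warn(
            f"patient {timeline.patient_id}: imputation volume {policy.volume} cc "
            f"exceeds the baseline volume {smallest_tp0} cc; alpha will be "
            f"negative by construction (imputed state above the minimal "
            f"detectable volume)",
            stacklevel=2,
        )
    return replace(
        timeline,
        offsets={**timeline.offsets, "TP-1": policy.offset},
        total_volumes={**timeline.total_volumes, "TP-1": policy.volume},
        imputed=timeline.imputed | {"TP-1"},
        imputation_applied=True,
    )


def compute_cohort_growth_rates(
    cohort: Cohort,
    model_name: str = "exponential",
    policy: ImputationPolicy = ImputationPolicy(),
    log_scale: bool = False,
) -> pd.DataFrame:
    """Fit the chosen growth law to every patient's pretreatment series.

    Only TP-1 and TP0 enter the fit (on-treatment scans never inform alpha).
    De-novo patients are imputed with ``policy`` first. Exponential fits to
    two points use the exact closed form; per-patient failures are returned as
    flagged rows (``converged = False``), never raised.

    Returns a DataFrame: patient_id, model, alpha, param columns, rss,
    converged, underdetermined, imputed, n_obs.
    """
    model = get_model(model_name)
    rows = []
    for pid in cohort.patient_ids:
        tl = impute_pretreatment(cohort.timelines[pid], policy)
        obs = tl.pretreatment_observations()
        imputed = any(flag for _, _, flag in obs)
        row: dict[str, object] = {"patient_id": pid, "model": model.name,
                                  "imputed": imputed}
        try:
            if model.name == "exponential" and len(obs) == 2:
                (t0, v0, _), (t1, v1, _) = obs
                fit = fit_exponential_two_point(v0, v1, t1 - t0)
            else:
                fit = fit_growth_model(model, [(t, v) for t, v, _ in obs],
                                       log_scale=log_scale)
        except InvalidInputError as exc:
            logger.warning("patient %s: growth fit failed (%s)", pid, exc)
            row.update(alpha=np.nan, rss=np.nan, converged=False,
                       underdetermined=False, n_obs=len(obs))
            for name in model.param_names[1:]:
                row[name] = np.nan
            rows.append(row)
            continue
        row["alpha"] = fit.params[0]
        for name, value in zip(model.param_names[1:], fit.params[1:]):
            row[name] = value
        row.update(rss=fit.rss, converged=fit.converged,
                   underdetermined=fit.underdetermined, n_obs=fit.n_obs)
        rows.append(row)
    fits = pd.DataFrame(rows)
    logger.info("fitted %s model for %d patients (%d imputed, %d converged)",
                model.name, len(fits), int(fits["imputed"].sum()),
                int(fits["converged"].sum()))
    return fits
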