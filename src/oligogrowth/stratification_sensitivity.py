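"""Quartile stratification of the growth rate and the imputation sensitivity grid.

Patients are split into quartiles of the fitted pretreatment growth rate
alpha; the upper quartile (Q3 threshold) dichotomizes the cohort into a
slow-paced group (alpha <= threshold, boundary inclusive) and a fast-paced
group (alpha > threshold). Survival endpoints are compared between groups
with the log-rank test, for the whole cohort, for every pair of quartiles,
and within metastasis-count subgroups (<= 5 lesions, the conventional
oligometastatic cutoff, versus > 5).

The sensitivity grid re-runs the slow/fast comparison under alternative
imputation assumptions for de-novo patients (imputed TP-1 volume x imputed
TP-1 offset), recomputing alpha for de-novo patients only and re-deriving
the quartile threshold per cell.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, ImputationPolicy, compute_cohort_growth_rates
from .endpoints_survival import ENDPOINTS, endpoint_arrays, logrank_test
from .growth_models import InvalidInputError

logger = logging.getLogger(__name__)

QUARTILES = ("Q1", "Q2", "Q3", "Q4")

#: Imputation axes of the default sensitivity grid: volumes in cc, offsets in
#: days before baseline at 30-day steps.
DEFAULT_VOLUME_AXIS = (0.01, 0.1, 1.0)
DEFAULT_OFFSET_AXIS = (-150.0, -120.0, -90.0, -60.0, -30.0)

#: Conventional oligometastatic lesion-count cutoff (<= 5 lesions).
OLIGO_CUTOFF = 5


def quartile_thresholds(
    alphas: Sequence[float], method: str = "linear"
) -> tuple[float, float, float]:
    """Sample quartiles (q1, q2, q3) of alpha.

    ``method`` is the quantile interpolation convention (numpy naming);
    the default linearly interpolates between order statistics.
    """
    a = np.asarray(alphas, dtype=float)
    if a.size < 4:
        raise InvalidInputError(
            f"quartile stratification needs >= 4 values, got {a.size}"
        )
    q1, q2, q3 = np.quantile(a, [0.25, 0.5, 0.75], method=method)
    return float(q1), float(q2), float(q3)


def assign_groups(
    patient_ids: Sequence[str],
    alphas: Sequence[float],
    threshold: float | None = None,
    method: str = "linear",
) -> pd.DataFrame:
    """Quartile labels and the slow/fast dichotomy for every patient.

    ``slow`` iff alpha <= threshold (the boundary belongs to slow); the
    default threshold is the cohort's upper quartile q3, in which case the
    fast group coincides with Q4.

    Returns a DataFrame: patient_id, alpha, quartile, group, threshold.
    """
    a = np.asarray(alphas, dtype=float)
    q1, q2, q3 = quartile_thresholds(a, method=method)
    if threshold is None:
        threshold = q3
    if not np.isfinite(threshold):
        raise InvalidInputError(f"threshold must be finite, got {threshold}")
    quart = np.where(a <= q1, "Q1", np.where(a <= q2, "Q2",
                     np.where(a <= q3, "Q3", "Q4")))
    group = np.where(a <= threshold, "slow", "fast")
    return pd.DataFrame(
        {
            "patient_id": list(patient_ids),
            "alpha": a,
            "quartile": quart,
            "group": group,
            "threshold": float(threshold),
        }
    )


def _logrank_between(patients: pd.DataFrame, ids_a, ids_b, endpoint: str):
    sub_a = patients[patients["patient_id"].isin(set(ids_a))]
    sub_b = patients[patients["patient_id"].isin(set(ids_b))]
    ta, ea = endpoint_arrays(sub_a, endpoint)
    tb, eb = endpoint_arrays(sub_b, endpoint)
    return logrank_test(ta, ea, tb, eb)


def compare_groups(
    patients: pd.DataFrame, strata: pd.DataFrame, endpoint: str
) -> pd.DataFrame:
    """Slow-vs-fast log-rank for one endpoint (single-row table)."""
    slow = strata.loc[strata["group"] == "slow", "patient_id"]
    fast = strata.loc[strata["group"] == "fast", "patient_id"]
    res = _logrank_between(patients, slow, fast, endpoint)
    return pd.DataFrame(
        [{"endpoint": endpoint, "comparison": "slow_vs_fast",
          "statistic": res.statistic, "p_value": res.p_value,
          "n_a": res.n_per_group[0], "n_b": res.n_per_group[1]}]
    )


def pairwise_quartile_comparisons(
    patients: pd.DataFrame, strata: pd.DataFrame, endpoint: str
) -> pd.DataFrame:
    """Log-rank for every quartile pair plus Q4 vs pooled Q1-3.

    Pairs with an empty quartile are flagged (NaN statistic), not computed.
    """
    ids = {q: strata.loc[strata["quartile"] == q, "patient_id"] for q in QUARTILES}
    ids["Q1-3"] = strata.loc[strata["quartile"] != "Q4", "patient_id"]
    pairs = list(itertools.combinations(QUARTILES, 2)) + [("Q1-3", "Q4")]
    rows = []
    for qa, qb in pairs:
        row = {"endpoint": endpoint, "comparison": f"{qa}_vs_{qb}",
               "n_a": len(ids[qa]), "n_b": len(ids[qb])}
        if len(ids[qa]) == 0 or len(ids[qb]) == 0:
            row.update(statistic=np.nan, p_value=np.nan, flagged=True)
        else:
            res = _logrank_between(patients, ids[qa], ids[qb], endpoint)
            row.update(statistic=res.statistic, p_value=res.p_value, flagged=False)
        rows.append(row)
    return pd.DataFrame(rows)


def subgroup_by_met_count(
    cohort: Cohort, cutoff: int = OLIGO_CUTOFF
) -> dict[str, list[str]]:
    """Partition patient ids by baseline metastasis count: oligo (<= cutoff) vs poly."""
    counts = cohort.met_counts()
    return {
        "oligo": list(counts.index[counts <= cutoff]),
        "poly": list(counts.index[counts > cutoff]),
    }


@dataclass(frozen=True)
class SensitivityGrid:
    """Log-rank p-values of the slow/fast comparison over imputation assumptions.

    ``table`` is long-format: volume_cc, offset_days, endpoint, p_value,
    statistic, threshold, n_slow, n_fast, flagged.
    """

    volume_axis: tuple[float, ...]
    offset_axis: tuple[float, ...]
    endpoints: tuple[str, ...]
    table: pd.DataFrame

    def cell(self, volume: float, offset: float, endpoint: str) -> pd.Series:
        m = self.table[
            (self.table["volume_cc"] == volume)
            & (self.table["offset_days"] == offset)
            & (self.table["endpoint"] == endpoint)
        ]
        if m.empty:
            raise KeyError((volume, offset, endpoint))
        return m.iloc[0]


def run_sensitivity_grid(
    cohort: Cohort,
    volume_axis: Sequence[float] = DEFAULT_VOLUME_AXIS,
    offset_axis: Sequence[float] = DEFAULT_OFFSET_AXIS,
    endpoints: Sequence[str] = ENDPOINTS,
    threshold: float | None = None,
    quantile_method: str = "linear",
) -> SensitivityGrid:
    """Re-impute, re-fit, re-stratify and re-test over the imputation grid.

    Per cell (volume, offset): de-novo patients' alpha is recomputed under
    that imputation, measured-TP-1 patients' alpha never changes, the upper
    quartile threshold is re-derived from the full re-imputed alpha
    distribution (unless a fixed ``threshold`` is given), and the slow/fast
    log-rank is run per endpoint. Cells where one group is empty are flagged.
    """
    base = compute_cohort_growth_rates(cohort, "exponential",
                                       ImputationPolicy()).set_index("patient_id")
    de_novo_ids = [pid for pid in cohort.patient_ids
                   if cohort.timelines[pid].de_novo]
    v0 = {pid: cohort.timelines[pid].total_volumes["TP0"] for pid in de_novo_ids}
    rows = []
    for vol in volume_axis:
        for off in offset_axis:
            alphas = base["alpha"].copy()
            for pid in de_novo_ids:
                alphas.loc[pid] = np.log(v0[pid] / vol) / abs(off)
            strata = assign_groups(alphas.index, alphas.values,
                                   threshold=threshold, method=quantile_method)
            n_slow = int((strata["group"] == "slow").sum())
            n_fast = int((strata["group"] == "fast").sum())
            for ep in endpoints:
                row = {"volume_cc": vol, "offset_days": off, "endpoint": ep,
                       "threshold": strata["threshold"].iloc[0],
                       "n_slow": n_slow, "n_fast": n_fast}
                if n_slow == 0 or n_fast == 0:
                    row.update(statistic=np.nan, p_value=np.nan, flagged=True)
                else:
                    res = compare_groups(cohort.patients, strata, ep).iloc[0]
                    row.update(statistic=res["statistic"],
                               p_value=res["p_value"], flagged=False)
                rows.append(row)
    table = pd.DataFrame(rows)
    logger.info("sensitivity grid: %d cells (%d x %d x %d endpoints), "
                "%d de-novo patients re-imputed per cell",
                len(table), len(volume_axis), len(offset_axis), len(endpoints),
                len(de_novo_ids))
    return SensitivityGrid(
        volume_axis=tuple(volume_axis), offset_axis=tuple(offset_axis),
        endpoints=tuple(endpoints), table=table,
    )
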