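"""Response metric, waterfall table, and correlation validation of alpha.

The volumetric treatment response at the first on-treatment evaluation is

    tumor volume change (%) = 100 * (V_tp1 - V_tp0) / V_tp0,

bounded below by -100% (complete disappearance). The fitted growth rate is
validated against clinical variables: Spearman rank correlation with
continuous variables (volume change, metastasis count) and Cramer's V with
categorical ones (organ involvement, primary site), alpha being discretized
into its cohort quartiles for the categorical cross-tabulations. Coefficient
magnitudes are mapped to interpretation labels through configurable bands
(defaults follow common correlation-strength guidelines).
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

from .cohort import Cohort
from .growth_models import InvalidInputError
from .stratification_sensitivity import assign_groups

logger = logging.getLogger(__name__)


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for this input (constant vector, single level)."""


#: (|coefficient| lower bound, label), first match wins.
SPEARMAN_BANDS = (
    (0.8, "very strong"),
    (0.6, "strong"),
    (0.4, "moderate"),
    (0.2, "weak"),
    (0.0, "negligible"),
)
CRAMERS_V_BANDS = (
    (0.25, "very strong"),
    (0.15, "strong"),
    (0.10, "moderate"),
    (0.05, "weak"),
    (0.0, "negligible"),
)


def tumor_volume_change(v_tp1: float, v_tp0: float) -> float:
    """Percent change of cumulative volume from baseline: 100*(V1 - V0)/V0."""
    if not (v_tp0 > 0):
        raise InvalidInputError(f"v_tp0 must be > 0, got {v_tp0}")
    if v_tp1 < 0:
        raise InvalidInputError(f"v_tp1 must be >= 0, got {v_tp1}")
    # clamp: complete disappearance is exactly -100%, never below by rounding
    return max(100.0 * (v_tp1 - v_tp0) / v_tp0, -100.0)


def _exact_spearman_p(rho_obs: float, n: int) -> float:
    """Two-sided exact permutation p for untied ranks (all n! assignments).

    Uses the rank-distance form rho = 1 - 6*sum(d^2)/(n(n^2-1)), so only the
    distribution of sum(d^2) over permutations is needed.
    """
    base = np.arange(1, n + 1)
    perms = np.array(list(itertools.permutations(base)))
    d2 = np.sum((perms - base) ** 2, axis=1)
    rhos = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties; two-sided p.

    The p-value is exact (full permutation enumeration) for n <= 9 with
    untied data, and uses the t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise InvalidInputError(f"spearman needs >= 3 pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("constant input vector")
    rx = rankdata(x)
    ry = rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    no_ties = np.unique(x).size == n and np.unique(y).size == n
    if n <= 9 and no_ties:
        p = _exact_spearman_p(rho, n)
    else:
        rho_c = min(max(rho, -1.0 + 1e-15), 1.0 - 1e-15)
        t_stat = rho_c * math.sqrt((n - 2) / (1.0 - rho_c**2))
        p = float(2.0 * t_dist.sf(abs(t_stat), n - 2))
        if abs(rho) >= 1.0:
            p = 0.0
    return rho, p


def contingency_chi2(table: np.ndarray) -> float:
    """Pearson chi-squared of a contingency table (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    mask = expected > 0
    return float(np.sum((table[mask] - expected[mask]) ** 2 / expected[mask]))


def cramers_v(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cramer's V between two categorical vectors.

    V = sqrt(chi2 / (n * (min(r, c) - 1))) from the r x c contingency table.
    """
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise InvalidInputError("label vectors must have equal length")
    table = pd.crosstab(a, b).to_numpy()
    r, c = table.shape
    if r < 2 or c < 2:
        raise UndefinedStatisticError(
            "Cramer's V needs >= 2 levels in each variable"
        )
    chi2 = contingency_chi2(table)
    n = table.sum()
    return float(math.sqrt(chi2 / (n * (min(r, c) - 1))))


def interpret_coefficient(
    value: float,
    method: str = "spearman",
    bands: Sequence[tuple[float, str]] | None = None,
) -> str:
    """Map |coefficient| to a strength label via ordered (threshold, label) bands."""
    if bands is None:
        bands = SPEARMAN_BANDS if method == "spearman" else CRAMERS_V_BANDS
    mag = abs(value)
    for threshold, label in bands:
        if mag >= threshold:
            return label
    return bands[-1][1]


def waterfall_table(cohort: Cohort, fits: pd.DataFrame) -> pd.DataFrame:
    """Per-patient percent volume change at TP+1, sorted for a waterfall plot.

    Patients without a TP+1 scan are excluded (logged). Rows are ordered by
    descending percent change, ties broken by patient_id, and annotated with
    the best-response label and the fitted alpha.
    """
    alpha = fits.set_index("patient_id")["alpha"]
    rows = []
    excluded = []
    for pid in cohort.patient_ids:
        tl = cohort.timelines[pid]
        if "TP+1" not in tl.total_volumes:
            excluded.append(pid)
            continue
        change = tumor_volume_change(tl.total_volumes["TP+1"],
                                     tl.total_volumes["TP0"])
        rows.append({
            "patient_id": pid,
            "pct_change_tp1": change,
            "best_response": tl.covariates.get("best_response"),
            "alpha": float(alpha.loc[pid]),
        })
    if excluded:
        logger.info("waterfall table: %d patient(s) without TP+1 excluded: %s",
                    len(excluded), ", ".join(excluded[:10]))
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    return table.sort_values(
        ["pct_change_tp1", "patient_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def validate_alpha(cohort: Cohort, fits: pd.DataFrame) -> pd.DataFrame:
    """Correlation panel of alpha against response and clinical covariates.

    Spearman: alpha vs percent volume change at TP+1 (patients with TP+1
    imaging) and alpha vs baseline metastasis count. Cramer's V: alpha
    quartile vs each organ-involvement flag and vs primary site.

    Returns a table: variable, method, coefficient, p_value, n, interpretation.
    """
    alpha = fits.set_index("patient_id")["alpha"]
    rows = []

    wf = waterfall_table(cohort, fits)
    if len(wf) >= 3:
        rho, p = spearman_correlation(wf["alpha"], wf["pct_change_tp1"])
        rows.append({"variable": "tumor_volume_change_tp1", "method": "spearman",
                     "coefficient": rho, "p_value": p, "n": len(wf),
                     "interpretation": interpret_coefficient(rho, "spearman")})

    counts = cohort.met_counts()
    rho, p = spearman_correlation(alpha.loc[counts.index], counts)
    rows.append({"variable": "n_metastases", "method": "spearman",
                 "coefficient": rho, "p_value": p, "n": len(counts),
                 "interpretation": interpret_coefficient(rho, "spearman")})

    strata = assign_groups(alpha.index, alpha.values)
    quart = strata.set_index("patient_id")["quartile"]
    categorical = {
        f"{organ}_met": cohort.patients.set_index("patient_id")[f"{organ}_met"]
        for organ in ("liver", "lung", "brain", "bone")
    }
    categorical["primary_site"] = cohort.patients.set_index("patient_id")["primary_site"]
    for name, series in categorical.items():
        series = series.loc[quart.index]
        try:
            v = cramers_v(quart, series)
        except UndefinedStatisticError:
            logger.info("validate_alpha: %s has a single level, skipped", name)
            continue
        rows.append({"variable": name, "method": "cramers_v",
                     "coefficient": v, "p_value": np.nan, "n": len(series),
                     "interpretation": interpret_coefficient(v, "cramers_v")})
    return pd.DataFrame(rows)
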