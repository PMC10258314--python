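"""Seeded synthetic cohorts with the statistical structure of a metastatic
melanoma ICB cohort, plus the per-patient ground truth for recovery tests.

The generator emulates the study conditions the pipeline was designed for:
86 patients, about half de-novo metastatic (no measurable disease at the
pretreatment scan, hence needing imputation), cumulative baseline volume
log-normally distributed around a 28.4 cc median within 0.4-1194.8 cc,
baseline lesion count around a median of 7 (1-73) rank-correlated with the
growth rate, pretreatment imaging interval around -90 days (-363 to -6), a
growth-rate distribution with median about 0.0471 d^-1 plus a small negative
tail, and exponential survival with a log-hazard linear in alpha and uniform
right censoring (median follow-up about 35 months).

True (noise-free) volumes follow V(t) = V0 * exp(alpha * t) exactly, so with
measurement noise switched off the fitted alpha recovers the truth to
machine precision for measured-TP-1 patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, build_cohort
from .growth_models import InvalidInputError

SITE_CHOICES = ("lung", "liver", "lymph_node", "bone", "brain", "other")
SITE_PROBS = (0.30, 0.18, 0.22, 0.12, 0.08, 0.10)
PRIMARY_CHOICES = ("cutaneous", "mucosal", "ocular", "unknown")
PRIMARY_PROBS = (0.55, 0.25, 0.12, 0.08)


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults are the emulated study conditions.

    Rates are per day, volumes in cc, times in days. ``alpha`` is drawn from a
    log-normal around ``alpha_median`` with probability ``1 - negative_prob``,
    and from a small uniform negative component otherwise (shrinking disease
    between the scans). The metastasis count shares a latent normal with
    alpha (Gaussian copula, rank correlation ~ ``met_alpha_rho``). Survival is
    exponential with patient rate ``hazard_baseline * exp(hazard_slope *
    alpha)``; progression runs at ``progression_multiplier`` times the death
    rate, and a second progression gap of the same scale yields PFS2.
    """

    n_patients: int = 86
    de_novo_fraction: float = 0.51
    alpha_median: float = 0.0471
    alpha_sigma: float = 1.0
    alpha_negative_prob: float = 0.05
    alpha_negative_low: float = -0.0062
    volume_median: float = 28.4
    volume_sigma: float = 1.2
    volume_range: tuple[float, float] = (0.4, 1194.8)
    interval_median: float = 90.0
    interval_sigma: float = 0.55
    interval_range: tuple[float, float] = (6.0, 363.0)
    met_count_median: float = 7.0
    met_count_sigma: float = 0.9
    met_count_range: tuple[int, int] = (1, 73)
    met_alpha_rho: float = 0.5
    volume_alpha_rho: float = 0.5
    hazard_baseline: float = 1.0 / 1500.0
    hazard_slope: float = 15.0
    progression_multiplier: float = 1.5
    censor_range: tuple[float, float] = (365.0, 1765.0)
    noise_sigma: float = 0.15
    tp1_fraction: float = 0.71
    tp2_fraction: float = 0.50
    treatment_effect_mean: float = 0.05
    treatment_effect_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.n_patients < 1:
            errors.append("n_patients must be >= 1")
        if not (0.0 <= self.de_novo_fraction <= 1.0):
            errors.append("de_novo_fraction must lie in [0, 1]")
        for name in ("alpha_sigma", "volume_sigma", "interval_sigma",
                     "met_count_sigma", "noise_sigma", "hazard_baseline"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        for name in ("volume_range", "interval_range", "met_count_range",
                     "censor_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                errors.append(f"{name} is empty: ({lo}, {hi})")
        if self.volume_range[0] <= 0:
            errors.append("volume_range lower bound must be > 0")
        if not (0.0 <= self.alpha_negative_prob <= 1.0):
            errors.append("alpha_negative_prob must lie in [0, 1]")
        if errors:
            raise InvalidInputError("invalid CohortConfig: " + "; ".join(errors))


@dataclass
class SyntheticCohort:
    """Generated tables plus ground truth, writable as the cohort CSV schema."""

    lesions: pd.DataFrame
    patients: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "lesions": out / "lesions.csv",
            "patients": out / "patients.csv",
            "truth": out / "truth.csv",
        }
        self.lesions.to_csv(paths["lesions"], index=False)
        self.patients.to_csv(paths["patients"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        return paths

    def to_cohort(self) -> Cohort:
        return build_cohort(self.lesions, self.patients)


def generate_lesion_split(
    total_volume: float, n_lesions: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Split a cumulative volume into positive lesion volumes summing to it.

    Dirichlet proportions, renormalized at full precision so the sum is exact
    to floating-point rounding.
    """
    if n_lesions < 1:
        raise InvalidInputError(f"n_lesions must be >= 1, got {n_lesions}")
    if not (total_volume > 0):
        raise InvalidInputError(f"total_volume must be > 0, got {total_volume}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if n_lesions == 1:
        return np.array([total_volume])
    w = rng.dirichlet(np.full(n_lesions, 1.2))
    vols = w * total_volume
    vols[-1] = total_volume - vols[:-1].sum()
    return vols


def _lognormal(rng, median, sigma):
    return median * math.exp(sigma * rng.standard_normal())


def _best_response_label(best_pct: float) -> str:
    if best_pct <= -95.0:
        return "CR"
    if best_pct <= -30.0:
        return "PR"
    if best_pct >= 20.0:
        return "PD"
    return "SD"


def generate_cohort(config: CohortConfig = CohortConfig()) -> SyntheticCohort:
    """Generate one cohort deterministically from ``config.seed``.

    The seed is expanded into independent per-patient substreams, so changing
    ``n_patients`` extends the cohort without reshuffling existing patients.
    De-novo patients carry no TP-1 lesion rows (their imputation happens
    downstream in the analysis); measured patients' TP-1 volume is
    ``V0 * exp(-alpha * interval)`` times multiplicative log-normal noise.
    """
    lesion_rows = []
    patient_rows = []
    truth_rows = []
    c = config
    for i in range(c.n_patients):
        rng = np.random.default_rng([c.seed, i])
        pid = f"P{i:03d}"

        z_alpha = rng.standard_normal()
        if rng.random() < c.alpha_negative_prob:
            alpha = rng.uniform(c.alpha_negative_low, 0.0)
        else:
            alpha = c.alpha_median * math.exp(c.alpha_sigma * z_alpha)
        # baseline volume shares the latent normal with alpha (faster tumors
        # are caught at larger burden, de-novo presentations especially)
        z_vol = (c.volume_alpha_rho * z_alpha
                 + math.sqrt(1.0 - c.volume_alpha_rho**2) * rng.standard_normal())
        v0_true = float(np.clip(
            c.volume_median * math.exp(c.volume_sigma * z_vol), *c.volume_range))
        de_novo = rng.random() < c.de_novo_fraction

        z_count = (c.met_alpha_rho * z_alpha
                   + math.sqrt(1.0 - c.met_alpha_rho**2) * rng.standard_normal())
        n_met = int(np.clip(round(c.met_count_median
                                  * math.exp(c.met_count_sigma * z_count)),
                            *c.met_count_range))

        def noisy(v):
            if c.noise_sigma == 0:
                return v
            return v * math.exp(c.noise_sigma * rng.standard_normal())

        interval = np.nan
        v_pre_true = np.nan
        v_pre_obs = np.nan
        if not de_novo:
            interval = float(np.clip(
                round(_lognormal(rng, c.interval_median, c.interval_sigma)),
                *c.interval_range))
            v_pre_true = v0_true * math.exp(-alpha * interval)
            v_pre_obs = noisy(v_pre_true)
        v0_obs = noisy(v0_true)

        # on-treatment trajectory: growth slowed (or reversed) by treatment
        effect = rng.normal(c.treatment_effect_mean, c.treatment_effect_sigma)
        alpha_post = alpha - effect
        v1_true = max(v0_true * math.exp(alpha_post * 63.0), 1e-3)
        v2_true = max(v0_true * math.exp(alpha_post * 126.0), 1e-3)
        best_pct = 100.0 * (min(v1_true, v2_true) - v0_true) / v0_true
        best_response = _best_response_label(best_pct)
        has_tp1 = rng.random() < c.tp1_fraction
        has_tp2 = has_tp1 and rng.random() < (c.tp2_fraction / max(c.tp1_fraction, 1e-9))

        # survival: exponential with log-hazard linear in alpha
        rate = c.hazard_baseline * math.exp(c.hazard_slope * alpha)
        t_os = rng.exponential(1.0 / rate)
        t_prog = rng.exponential(1.0 / (rate * c.progression_multiplier))
        gap = rng.exponential(1.0 / rate)
        censor = rng.uniform(*c.censor_range)
        t_pfs = min(t_prog, t_os)
        t_pfs2 = min(t_prog + gap, t_os)
        os_days = round(min(t_os, censor), 1)
        pfs_days = round(min(t_pfs, censor), 1)
        pfs2_days = round(min(t_pfs2, censor), 1)
        os_event = int(t_os <= censor)
        pfs_event = int(t_pfs <= censor)
        pfs2_event = int(t_pfs2 <= censor)

        # lesion-level rows
        sites = rng.choice(SITE_CHOICES, size=n_met, p=SITE_PROBS)
        timepoint_volumes = {"TP0": (v0_obs, n_met)}
        if not de_novo:
            n_pre = 1 + int(rng.binomial(max(n_met - 1, 0), 0.25))
            timepoint_volumes["TP-1"] = (v_pre_obs, n_pre)
        if has_tp1:
            timepoint_volumes["TP+1"] = (noisy(v1_true), n_met)
        if has_tp2:
            timepoint_volumes["TP+2"] = (noisy(v2_true), n_met)
        for tp, (total, count) in timepoint_volumes.items():
            vols = generate_lesion_split(total, count, rng)
            for j, vol in enumerate(vols):
                lesion_rows.append({
                    "patient_id": pid, "timepoint": tp, "lesion_id": f"L{j:03d}",
                    "volume_cc": float(vol), "site": sites[j % n_met],
                })

        organ_flags = {f"{o}_met": int(o in set(sites))
                       for o in ("brain", "liver", "bone", "lung")}
        patient_rows.append({
            "patient_id": pid,
            "de_novo": int(de_novo),
            "tp_minus1_offset_days": -interval if not de_novo else np.nan,
            "primary_site": rng.choice(PRIMARY_CHOICES, p=PRIMARY_PROBS),
            **organ_flags,
            "os_days": os_days, "os_event": os_event,
            "pfs_days": pfs_days, "pfs_event": pfs_event,
            "pfs2_days": pfs2_days, "pfs2_event": pfs2_event,
            "best_response": best_response,
            "tp_plus1_offset_days": 63.0 if has_tp1 else np.nan,
            "tp_plus2_offset_days": 126.0 if has_tp2 else np.nan,
        })
        truth_rows.append({
            "patient_id": pid, "alpha_true": alpha, "alpha_post_true": alpha_post,
            "v_pre_true": v_pre_true, "v0_true": v0_true,
            "v1_true": v1_true if has_tp1 else np.nan,
            "v2_true": v2_true if has_tp2 else np.nan,
            "t_os_true": t_os, "censor_time": censor,
        })

    return SyntheticCohort(
        lesions=pd.DataFrame(lesion_rows),
        patients=pd.DataFrame(patient_rows),
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def summarize_cohort(cohort: Cohort, fits: pd.DataFrame | None = None) -> dict:
    """Descriptive summary: medians and ranges of the cohort-defining quantities.

    When ``fits`` (from :func:`~oligogrowth.cohort.compute_cohort_growth_rates`)
    is given, the alpha distribution is summarized too.
    """
    v0 = np.array([tl.total_volumes["TP0"] for tl in cohort.timelines.values()])
    counts = cohort.met_counts().to_numpy()
    offsets = cohort.patients["tp_minus1_offset_days"].dropna().to_numpy(dtype=float)
    summary = {
        "n_patients": cohort.n_patients,
        "n_de_novo": int(cohort.patients["de_novo"].sum()),
        "baseline_volume_median_cc": float(np.median(v0)),
        "baseline_volume_range_cc": (float(v0.min()), float(v0.max())),
        "met_count_median": float(np.median(counts)),
        "met_count_range": (int(counts.min()), int(counts.max())),
    }
    if offsets.size:
        summary["interval_median_days"] = float(np.median(offsets))
        summary["interval_range_days"] = (float(offsets.min()), float(offsets.max()))
    if fits is not None:
        a = fits["alpha"].to_numpy(dtype=float)
        summary["alpha_median_per_day"] = float(np.median(a))
        summary["alpha_range_per_day"] = (float(a.min()), float(a.max()))
    return summary
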