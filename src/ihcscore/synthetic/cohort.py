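"""Synthetic patient cohorts with known statistical structure.

Each patient carries dichotomised clinicopathological covariates drawn from
configurable marginals, a correlated bivariate log-normal pair of true
(nuclear, cytoplasmic) autoscores, two replicate core measurements with
multiplicative log-normal noise, and survival outcomes from an exponential
proportional-hazards model whose log hazard ratios — including a true
changepoint on the cytoplasmic-to-nuclear ratio — are chosen by the caller.

Disease-specific and other-cause mortality are competing exponential clocks;
overall survival is their minimum, administratively censored at a fixed
horizon.  A disease death is by construction also an overall-survival event
at the same time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Covariates with their (level_low, level_high) codings; the marginal gives
#: the probability of the *second* (high) level.
COVARIATE_LEVELS = {
    "age_group": ("<=65", ">65"),
    "size_group": ("<=20mm", ">20mm"),
    "nodal": ("N0", "N1+"),
    "grade": ("I&II", "III"),
    "er": ("<10%", ">=10%"),
    "pr": ("<10%", ">=10%"),
    "ki67": ("<10%", ">=10%"),
    "her2": ("0-2+", "3+"),
}

#: Default marginal frequency of the high level of each covariate, loosely
#: matching a node-negative-dominant early breast cancer cohort.
DEFAULT_MARGINALS = {
    "age_group": 0.51,
    "size_group": 0.28,
    "nodal": 0.36,
    "grade": 0.34,
    "er": 0.77,
    "pr": 0.57,
    "ki67": 0.62,
    "her2": 0.20,
}

DEFAULT_TREATMENT = {"tamoxifen": 0.31, "chemotherapy": 0.045, "none": 0.39}


@dataclass(frozen=True)
class ScoreDistribution:
    """Bivariate log-scale law of the true (nuclear, cytoplasmic) autoscores."""

    nuclear_log_mean: float = 1.0
    cytoplasmic_log_mean: float = 2.6
    log_sd: float = 0.9
    correlation: float = 0.75

    def __post_init__(self) -> None:
        if not (-1.0 <= self.correlation <= 1.0):
            raise ValueError("correlation must lie in [-1, 1]")
        if self.log_sd < 0:
            raise ValueError("log_sd must be >= 0")


@dataclass
class CohortSimConfig:
    """Full parameterisation of one simulated cohort."""

    n_patients: int = 359
    covariate_marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    treatment_marginals: dict = field(default_factory=lambda: dict(DEFAULT_TREATMENT))
    score_distribution: ScoreDistribution = field(default_factory=ScoreDistribution)
    duplicate_noise_sd: float = 0.3
    log_hr: dict = field(default_factory=dict)
    true_threshold: float = 5.0
    baseline_hazard: float = 0.005  # disease events per month
    other_cause_rate: float = 0.002  # per month, modulated by age group
    admin_censor_month: float = 207.0
    assoc_logodds: dict = field(default_factory=dict)
    seed: int | None = None

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.baseline_hazard < 0 or self.other_cause_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.admin_censor_month <= 0:
            raise ValueError("admin_censor_month must be > 0")
        if self.duplicate_noise_sd < 0:
            raise ValueError("duplicate_noise_sd must be >= 0")
        if self.true_threshold <= 0:
            raise ValueError("true_threshold must be > 0")
        unknown = set(self.covariate_marginals) - set(COVARIATE_LEVELS)
        if unknown:
            raise ValueError(f"unknown covariates in marginals: {sorted(unknown)}")
        for name, p in self.covariate_marginals.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"marginal frequency for {name} out of [0, 1]: {p}")
        if sum(self.treatment_marginals.values()) > 1.0 + 1e-9:
            raise ValueError("treatment frequencies sum to more than 1")
        for name, lhr in self.log_hr.items():
            if name not in ("cnr_high", "snas", "snas_high") and name not in COVARIATE_LEVELS:
                raise ValueError(f"unknown log_hr predictor: {name}")


def _split_autoscore(autoscore: np.ndarray, z: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Factor an autoscore into (fraction, intensity) with product ~ score/100."""
    intensity = np.clip(0.25 + 0.08 * z + rng.normal(0, 0.03, z.shape), 0.05, 1.0)
    fraction = np.clip(autoscore / (100.0 * intensity), 0.0, 1.0)
    return fraction, intensity


def generate_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort.

    Returns ``(patients, cores)``: one row per patient carrying covariates,
    true scores and survival outcomes, and one row per core (two replicates
    per patient) carrying noisy percentage/intensity measurements in the
    per-core CSV column contract.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    sd = config.score_distribution

    # --- true correlated autoscores --------------------------------------
    cov = np.array([[1.0, sd.correlation], [sd.correlation, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    nuclear_true = np.minimum(np.exp(sd.nuclear_log_mean + sd.log_sd * z[:, 0]), 100.0)
    cyt_true = np.minimum(np.exp(sd.cytoplasmic_log_mean + sd.log_sd * z[:, 1]), 100.0)
    cnr_true = cyt_true / nuclear_true
    log_cnr_std = (np.log(cnr_true) - np.mean(np.log(cnr_true))) / (np.std(np.log(cnr_true)) or 1.0)

    # --- covariates -------------------------------------------------------
    patients = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)]})
    age = np.clip(np.round(rng.normal(65, 12, n)), 27, 96)
    patients["age"] = age.astype(int)
    for name, levels in COVARIATE_LEVELS.items():
        p_high = config.covariate_marginals.get(name, DEFAULT_MARGINALS[name])
        if name == "age_group":
            high = age > 65
        else:
            logit = math.log(p_high / (1 - p_high)) if 0 < p_high < 1 else math.inf * (1 if p_high else -1)
            shift = config.assoc_logodds.get(name, 0.0) * log_cnr_std
            prob = 1.0 / (1.0 + np.exp(-(logit + shift)))
            high = rng.random(n) < prob
        patients[name] = np.where(high, levels[1], levels[0])

    t_probs = config.treatment_marginals
    u = rng.random(n)
    tam = u < t_probs.get("tamoxifen", 0.0)
    chemo = (~tam) & (u < t_probs.get("tamoxifen", 0.0) + t_probs.get("chemotherapy", 0.0))
    patients["tamoxifen"] = tam
    patients["chemotherapy"] = chemo
    patients["no_adjuvant"] = ~tam & ~chemo

    patients["snas"] = nuclear_true
    patients["cytoplasmic_autoscore"] = cyt_true
    patients["cnr"] = cnr_true
    patients["cnr_high"] = cnr_true > config.true_threshold

    # --- proportional-hazards survival ------------------------------------
    lp = np.zeros(n)
    for name, beta in config.log_hr.items():
        if name == "cnr_high":
            x = patients["cnr_high"].to_numpy(float)
        elif name == "snas":
            x = nuclear_true
        elif name == "snas_high":
            raise ValueError("snas_high requires a threshold; use 'snas' or a covariate")
        else:
            x = (patients[name] == COVARIATE_LEVELS[name][1]).to_numpy(float)
        lp += beta * x
    hazard = config.baseline_hazard * np.exp(lp)

    with np.errstate(divide="ignore"):
        t_disease = rng.exponential(1.0, n) / np.where(hazard > 0, hazard, np.inf)
        age_mult = np.where(age > 65, 1.5, 0.7)
        oc = config.other_cause_rate * age_mult
        t_other = rng.exponential(1.0, n) / np.where(oc > 0, oc, np.inf)

    t_admin = config.admin_censor_month
    os_time = np.minimum.reduce([t_disease, t_other, np.full(n, t_admin)])
    patients["os_time"] = os_time
    patients["os_event"] = np.minimum(t_disease, t_other) < t_admin
    patients["bcss_time"] = os_time
    patients["bcss_event"] = (t_disease <= t_other) & (t_disease < t_admin)

    # --- replicate cores ---------------------------------------------------
    cores = _replicate_cores(patients, z, config, rng)
    return patients, cores


def _replicate_cores(patients: pd.DataFrame, z: np.ndarray, config: CohortSimConfig,
                     rng) -> pd.DataFrame:
    n = len(patients)
    nuc_frac, nuc_int = _split_autoscore(patients["snas"].to_numpy(), z[:, 0], rng)
    cyt_frac, cyt_int = _split_autoscore(
        patients["cytoplasmic_autoscore"].to_numpy(), z[:, 1], rng
    )
    sd = config.duplicate_noise_sd / math.sqrt(2.0)  # per-factor so score sd ~ config value
    rows = []
    for rep in (1, 2):
        if config.duplicate_noise_sd > 0:
            jitter = [np.exp(rng.normal(0, sd, n)) for _ in range(4)]
        else:
            jitter = [np.ones(n)] * 4
        nf = np.clip(nuc_frac * jitter[0], 0.0, 1.0)
        ni = np.clip(nuc_int * jitter[1], 0.0, 1.0)
        cf = np.clip(cyt_frac * jitter[2], 0.0, 1.0)
        ci = np.clip(cyt_int * jitter[3], 0.0, 1.0)
        nuc_auto = 100.0 * nf * ni
        cyt_auto = 100.0 * cf * ci
        rows.append(pd.DataFrame({
            "patient_id": patients["patient_id"],
            "replicate": rep,
            "nuclear_pct": nf,
            "nuclear_intensity": ni,
            "cyt_pct": cf,
            "cyt_intensity": ci,
            "nuclear_autoscore": nuc_auto,
            "cyt_autoscore": cyt_auto,
            "cnr": np.where(nuc_auto > 0, cyt_auto / np.where(nuc_auto > 0, nuc_auto, 1.0), np.nan),
            "evaluable": True,
        }))
    cores = pd.concat(rows, ignore_index=True)
    return cores.sort_values(["patient_id", "replicate"], kind="stable").reset_index(drop=True)
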