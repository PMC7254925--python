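"""Synthetic validation-study cohorts with the exact structure the model assumes.

The generator emulates the design of a biomarker validation study of an
online 24-hour dietary questionnaire: ~160 adults aged 18-65, three cycles
about two weeks apart, each cycle yielding one biomarker measurement
followed by the two self-report assessments in randomized order.  For every
nutrient it draws latent true log intake T_i, correlated person-specific
reporting biases (r_i, s_i), occasion drifts and within-person errors
exactly per the three-instrument model, then knocks out cells independently
(missing at random by construction).

Default nutrient scenarios are anchored to a published validation of such a
questionnaire: the error components are solved (``parameters_from_validity``)
so that each nutrient's implied single- and two-administration attenuation
factors and correlation with truth equal the published values, the latent
mean matches the published biomarker geometric mean, and the between-person
and biomarker-error variances are backed out of the published geometric-mean
confidence intervals.  PABA recoveries are drawn from a mixture placing
~45% of collections below 85% recovery, and ~4% of participants drift past
the 5% weight-change limit, matching the reported completeness profile.

``generate_raw_records`` inverts the biomarker conversions to produce the
raw urine and energy tables, so the preparation stage can be tested
end-to-end: running the prep pipeline on the raw records reproduces the
cohort's biomarker columns for complete records.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarkers import (
    CalibrationCoefficients,
    NITROGEN_RECOVERY,
    NITROGEN_TO_PROTEIN,
    POTASSIUM_RECOVERY,
    TEF_FRACTION,
)
from .estimation import CohortMeasurements
from .model import DesignSpec, ModelParameters, parameters_from_validity

__all__ = [
    "SimulationScenario",
    "SimulatedCohort",
    "default_nutrient_parameters",
    "generate_cohort",
    "generate_raw_records",
    "write_table",
]


# Published validity metrics and geometric means used to anchor the default
# scenarios: per nutrient, the questionnaire's (lambda1, lambda2, rho1), the
# interviewer recall's (lambda1, rho1), the chosen between-person variance of
# log intake, the biomarker within-person variance, and the geometric means
# (biomarker, webq, recall) on the natural scale.
_NUTRIENT_ANCHORS: dict[str, dict] = {
    "protein": dict(webq=(0.27, 0.37, 0.40), recall=(0.33, 0.46),
                    sigma2_T=0.090, sigma2_v=0.0875,
                    gm_biomarker=70.2, gm_webq=85.0, gm_recall=82.0),
    "potassium": dict(webq=(0.31, 0.42, 0.34), recall=(0.35, 0.37),
                      sigma2_T=0.115, sigma2_v=0.078,
                      gm_biomarker=2.1, gm_webq=3.3, gm_recall=3.1),
    "sugars": dict(webq=(0.31, 0.45, 0.33), recall=(0.16, 0.15),
                   sigma2_T=0.235, sigma2_v=0.517,
                   gm_biomarker=133.5, gm_webq=100.8, gm_recall=88.9),
    "energy": dict(webq=(0.22, 0.31, 0.32), recall=(0.30, 0.36),
                   sigma2_T=0.075, sigma2_v=0.025,
                   gm_biomarker=11.0, gm_webq=8.7, gm_recall=8.5),
}

_DEFAULT_RHO_RS = 0.3    # moderate positive correlation of person-specific biases


def _drift(J: int, scale: float = 0.02) -> tuple[float, ...]:
    """Small alternating occasion drift, anchored at zero on occasion 1."""
    return (0.0, *((scale if j % 2 else -scale) for j in range(1, J)))


def default_nutrient_parameters(n_occasions: int = 3) -> dict[str, ModelParameters]:
    """Per-nutrient model parameters reproducing the anchor validity metrics.

    For each nutrient the questionnaire components come from its
    (lambda1, lambda2, rho1) triple; the recall slope is rho1^2/lambda1 and
    its bias/error split uses the questionnaire's within-to-between variance
    ratio (only a single-administration pair is published for the recall).
    Intercepts place each tool's occasion-1 mean at its published geometric
    mean.
    """
    out = {}
    for name, a in _NUTRIENT_ANCHORS.items():
        l1, l2, r1 = a["webq"]
        mu_T = math.log(a["gm_biomarker"])
        p = parameters_from_validity(l1, l2, r1, a["sigma2_T"], mu_T=mu_T)
        x = (p.sigma2_eps) / (p.beta_Q1 ** 2 * p.sigma2_T + p.sigma2_r)

        lf, rf = a["recall"]
        beta_F1 = rf ** 2 / lf
        V1F = beta_F1 * a["sigma2_T"] / lf
        base = V1F / (1.0 + x)
        sigma2_s = max(base - beta_F1 ** 2 * a["sigma2_T"], 1e-6)
        sigma2_u = V1F - base

        out[name] = p.replace(
            mu_Q=_drift(n_occasions),
            mu_F=_drift(n_occasions),
            mu_M=(0.0,) * n_occasions,
            beta_Q0=math.log(a["gm_webq"]) - p.beta_Q1 * mu_T,
            beta_F0=math.log(a["gm_recall"]) - beta_F1 * mu_T,
            beta_F1=beta_F1,
            sigma2_s=sigma2_s,
            sigma2_u=sigma2_u,
            rho_rs=_DEFAULT_RHO_RS,
            sigma2_v=a["sigma2_v"],
        )
        out[name].validate()
    return out


@dataclass
class SimulationScenario:
    """Study conditions for a synthetic validation cohort.

    Defaults emulate the anchor study: 160 adults, 3 cycles, per-occasion
    completion rates of roughly 95/91/92% for the questionnaire, PABA
    recovery mixture putting ~45% of collections below 85%, and ~4% of
    participants exceeding the 5% weight-change limit.  ``seed`` is
    mandatory; every generated artefact is deterministic given the scenario.
    """

    seed: int
    n_participants: int = 160
    n_occasions: int = 3
    nutrients: dict[str, ModelParameters] | None = None
    missing_webq: tuple[float, ...] = (0.05, 0.0875, 0.08125)
    missing_recall: tuple[float, ...] = (0.0375, 0.0375, 0.0375)
    missing_biomarker: tuple[float, ...] = (0.05, 0.05, 0.05)
    female_fraction: float = 0.575
    age_mean: float = 43.0
    age_sd: float = 16.0
    age_range: tuple[float, float] = (18.0, 65.0)
    bmi_mean: float = 25.5
    bmi_sd: float = 4.2
    # PABA recovery (%): mixture of complete-collection and incomplete-collection
    # components; the incomplete weight puts ~45% of samples below 85%.
    paba_complete: tuple[float, float] = (95.0, 5.0)
    paba_incomplete: tuple[float, float] = (70.0, 10.0)
    paba_incomplete_weight: float = 0.4693
    missed_voids_probs: tuple[float, ...] = (0.90, 0.07, 0.03)
    weight_change_sd: float = 2.2
    order_effect: float = 0.0     # additive shift on the second assessment; off

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.nutrients is None:
            self.nutrients = default_nutrient_parameters(self.n_occasions)
        for name, p in self.nutrients.items():
            p.validate(DesignSpec(n_occasions=self.n_occasions))
        for rates in (self.missing_webq, self.missing_recall, self.missing_biomarker):
            if len(rates) != self.n_occasions:
                raise ValueError("one missingness rate per instrument-occasion required")
            if not all(0.0 <= r <= 1.0 for r in rates):
                raise ValueError("missingness probabilities must lie in [0, 1]")
        if not 0.0 <= self.paba_incomplete_weight <= 1.0:
            raise ValueError("paba_incomplete_weight must lie in [0, 1]")
        if abs(sum(self.missed_voids_probs) - 1.0) > 1e-9:
            raise ValueError("missed_voids_probs must sum to 1")

    @property
    def design(self) -> DesignSpec:
        return DesignSpec(n_occasions=self.n_occasions)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "nutrients"}
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
        d["nutrients"] = {n: p.to_dict() for n, p in self.nutrients.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationScenario":
        d = dict(d)
        nutrients = d.pop("nutrients", None)
        if nutrients is not None:
            nutrients = {n: ModelParameters.from_dict(p) for n, p in nutrients.items()}
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(nutrients=nutrients, **d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class SimulatedCohort:
    """Generated measurements plus the latent truth retained for testing."""

    scenario: SimulationScenario
    cohorts: dict[str, CohortMeasurements]
    true_intake: dict[str, np.ndarray]
    person_bias: dict[str, np.ndarray]      # (n, 2) columns r_i, s_i
    covariates: pd.DataFrame                # participant_id, sex, age, bmi
    assessment_order: np.ndarray            # (n, J), 0 = webq first

    def to_long(self) -> pd.DataFrame:
        return pd.concat([c.to_long() for c in self.cohorts.values()],
                         ignore_index=True)


def _truncated_normal(rng: np.random.Generator, mean, sd, low, high, size) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds are mild; cheap and exact)."""
    out = rng.normal(mean, sd, size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < low) | (out > high)
    return out


def generate_cohort(scenario: SimulationScenario) -> SimulatedCohort:
    """Draw a full synthetic cohort per the measurement-model equations.

    T_i ~ N(mu_T, sigma2_T) on the log scale; (r_i, s_i) bivariate normal
    with correlation rho_rs; Q, F, M assembled with occasion drifts and
    independent within-person errors; cells then set missing independently
    at the configured instrument-occasion rates.  Deterministic given the
    scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    n, J = scenario.n_participants, scenario.n_occasions

    sex = (rng.random(n) < scenario.female_fraction).astype(int)
    age = _truncated_normal(rng, scenario.age_mean, scenario.age_sd,
                            *scenario.age_range, n)
    bmi = np.maximum(rng.normal(scenario.bmi_mean, scenario.bmi_sd, n), 15.0)
    ids = np.array([f"P{i + 1:04d}" for i in range(n)])
    covariates = pd.DataFrame({"participant_id": ids, "sex": sex,
                               "age": age, "bmi": bmi})
    order = rng.integers(0, 2, size=(n, J))    # randomized within-cycle order

    cohorts: dict[str, CohortMeasurements] = {}
    truth: dict[str, np.ndarray] = {}
    biases: dict[str, np.ndarray] = {}
    for name in sorted(scenario.nutrients):
        p = scenario.nutrients[name]
        T = rng.normal(p.mu_T, math.sqrt(p.sigma2_T), n)
        c_rs = p.rho_rs * math.sqrt(p.sigma2_r * p.sigma2_s)
        cov_rs = np.array([[p.sigma2_r, c_rs], [c_rs, p.sigma2_s]])
        if not np.all(np.linalg.eigvalsh(cov_rs) >= -1e-12):
            raise ValueError(f"invalid (r, s) covariance for {name!r}")
        # eigh decomposition tolerates the singular (zero-variance) case
        rs = rng.multivariate_normal([0.0, 0.0], cov_rs, size=n, method="eigh")

        eps = rng.normal(0.0, math.sqrt(p.sigma2_eps), (n, J))
        u = rng.normal(0.0, math.sqrt(p.sigma2_u), (n, J))
        v = rng.normal(0.0, math.sqrt(p.sigma2_v), (n, J))

        Q = np.asarray(p.mu_Q) + p.beta_Q0 + p.beta_Q1 * T[:, None] + rs[:, [0]] + eps
        F = np.asarray(p.mu_F) + p.beta_F0 + p.beta_F1 * T[:, None] + rs[:, [1]] + u
        M = np.asarray(p.mu_M) + T[:, None] + v
        if scenario.order_effect:
            # order == 0: webq administered first, recall second
            Q += scenario.order_effect * (order == 1)
            F += scenario.order_effect * (order == 0)

        values = np.concatenate([Q, F, M], axis=1)
        for block, rates in ((0, scenario.missing_webq),
                             (1, scenario.missing_recall),
                             (2, scenario.missing_biomarker)):
            drop = rng.random((n, J)) < np.asarray(rates)
            values[:, block * J:(block + 1) * J][drop] = np.nan

        cohorts[name] = CohortMeasurements(
            nutrient=name, ids=ids, values=values,
            sex=sex.astype(float), age=age, bmi=bmi,
            design=scenario.design, log_scale=True,
        )
        truth[name] = T
        biases[name] = rs
    return SimulatedCohort(scenario=scenario, cohorts=cohorts,
                           true_intake=truth, person_bias=biases,
                           covariates=covariates, assessment_order=order)


def generate_raw_records(
    scenario: SimulationScenario,
    sim: SimulatedCohort,
    coeffs: CalibrationCoefficients | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Invert the biomarker conversions to raw urine and energy tables.

    nitrogen = protein * 0.81 / 6.25, potassium excreted = intake * 0.8,
    log sugar excretion inverts the calibration equation, and TEE is
    decomposed into resting and activity energy expenditure at a sampled
    resting share.  PABA recovery, missed voids and weight change are drawn
    per the scenario.  Running the preparation pipeline on these records
    reproduces the cohort's biomarker columns for records classified
    complete.
    """
    coeffs = coeffs or CalibrationCoefficients()
    rng = np.random.default_rng([scenario.seed, 7919])   # independent substream
    n, J = scenario.n_participants, scenario.n_occasions
    cov = sim.covariates

    def biomarker_block(name: str) -> np.ndarray:
        if name in sim.cohorts:
            return sim.cohorts[name].values[:, 2 * J:]
        return np.full((n, J), np.nan)

    prot = biomarker_block("protein")     # log g/day
    pot = biomarker_block("potassium")    # log g/day
    sug = biomarker_block("sugars")       # calibrated log excretion M*
    ene = biomarker_block("energy")       # log MJ/day

    pid = np.repeat(cov["participant_id"].to_numpy(), J)
    occ = np.tile(np.arange(1, J + 1), n)
    sex = np.repeat(cov["sex"].to_numpy(), J)
    age = np.repeat(cov["age"].to_numpy(), J)

    with np.errstate(invalid="ignore"):
        nitrogen = np.exp(prot).ravel() * NITROGEN_RECOVERY / NITROGEN_TO_PROTEIN
        potassium = np.exp(pot).ravel() * POTASSIUM_RECOVERY
        log_exc = (sug.ravel() - coeffs.intercept - coeffs.sex * sex
                   - coeffs.log_age * np.log(age))
        excretion = np.exp(log_exc)
    fructose_share = rng.uniform(0.3, 0.6, n * J)
    fructose = excretion * fructose_share
    sucrose = excretion - fructose

    comp = rng.random(n * J) >= scenario.paba_incomplete_weight
    paba = np.where(
        comp,
        rng.normal(*scenario.paba_complete, n * J),
        rng.normal(*scenario.paba_incomplete, n * J),
    )
    paba = np.maximum(paba, 0.0)
    voids = rng.choice(len(scenario.missed_voids_probs), size=n * J,
                       p=scenario.missed_voids_probs)
    volume = np.maximum(rng.normal(1.55, 0.45, n * J), 0.3)

    urine = pd.DataFrame({
        "participant_id": pid, "occasion": occ,
        "urine_volume": volume,
        "nitrogen": nitrogen, "potassium": potassium,
        "sucrose": sucrose, "fructose": fructose,
        "paba_recovery": paba, "missed_voids": voids,
        "sex": sex, "age": age,
    })

    tee = np.exp(ene).ravel()
    resting_share = rng.uniform(0.55, 0.70, n * J)
    ree = resting_share * (1.0 - TEF_FRACTION) * tee
    aee = (1.0 - resting_share) * (1.0 - TEF_FRACTION) * tee
    wchange = np.zeros((n, J))
    wchange[:, 1:] = rng.normal(0.0, scenario.weight_change_sd, (n, J - 1))
    energy = pd.DataFrame({
        "participant_id": pid, "occasion": occ,
        "ree": ree, "aee": aee,
        "weight_change": wchange.ravel(),
    })
    return urine, energy


def write_table(path, df: pd.DataFrame, scenario: SimulationScenario | None = None,
                sep: str = "\t") -> None:
    """Write a delimited table, embedding seed and scenario hash in a header comment."""
    with open(path, "w") as fh:
        if scenario is not None:
            fh.write(f"# seed={scenario.seed} scenario_hash={scenario.hash()}\n")
        df.to_csv(fh, sep=sep, index=False)
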