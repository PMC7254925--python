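"""Three-instrument measurement-error model for dietary validation studies.

A cohort completes, on each of ``J`` occasions, an online 24-hour dietary
questionnaire (``webq``), an interviewer-administered multiple-pass 24-hour
recall (``recall``), and provides an objective biomarker measurement
(``biomarker``).  All measures are analysed on the natural-log scale.  The
model relates each instrument linearly to a single person-level latent true
intake ``T_i ~ N(mu_T, sigma2_T)``:

    Q_ij = mu_Q[j] + beta_Q0 + beta_Q1 * T_i + r_i + eps_ij     (webq)
    F_ij = mu_F[j] + beta_F0 + beta_F1 * T_i + s_i + u_ij       (recall)
    M_ij = mu_M[j] +                    T_i        + v_ij       (biomarker)

``r_i`` and ``s_i`` are person-specific reporting biases, stable across
repeats of the same self-report tool and allowed to be correlated across
tools (``rho_rs``), because the same psychology can drive misreporting on
both.  The biomarker carries no person-specific bias and anchors the scale
of ``T`` (slope fixed at 1).  ``eps``, ``u``, ``v`` are independent
within-person errors.  Occasion intercepts ``mu_*[j]`` absorb drift over
the study; the occasion-1 intercepts are fixed at zero for identifiability
(they are absorbed into ``beta_Q0``, ``beta_F0`` and ``mu_T``).

From a fitted parameter set the module computes the two validity metrics of
regression calibration:

* the attenuation factor ``lambda_k`` — the slope of regressing true intake
  on the mean of ``k`` administrations of a self-report tool, i.e. the
  multiplicative bias applied to log relative risks in diet-disease models
  using that tool;
* the correlation ``rho_k`` between the k-administration mean and true
  intake, which governs power loss and the attenuation of estimates based
  on ranked or categorised intake.

Averaging ``k`` administrations divides only the within-person error
variance by ``k``; the person-specific bias does not average away.  The
same algebra lets both metrics be extrapolated to any ``k`` from the
printed ``(lambda_1, lambda_2, rho_1)`` of a published validation study
(`extrapolate_from_pair`).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "DesignSpec",
    "ExtrapolationInput",
    "InfeasibleRatioError",
    "implied_moments",
    "attenuation_factor",
    "correlation_with_truth",
    "extrapolate_from_pair",
    "parameters_from_validity",
]

SELF_REPORT_INSTRUMENTS = ("webq", "recall")
INSTRUMENTS = ("webq", "recall", "biomarker")


class InfeasibleRatioError(ValueError):
    """Raised when lambda2/lambda1 admits no nonnegative variance ratio."""


@dataclass(frozen=True)
class DesignSpec:
    """Layout of the repeated-measures validation design.

    ``n_occasions`` is the number of cycles J (each contributing one
    observation per instrument); ``reference_instrument`` is the tool whose
    slope on latent intake is fixed at 1, defining the units of T.
    """

    n_occasions: int = 3
    instruments: tuple[str, ...] = INSTRUMENTS
    reference_instrument: str = "biomarker"

    def __post_init__(self) -> None:
        if self.n_occasions < 2:
            raise ValueError(
                "n_occasions must be >= 2: a single occasion cannot separate "
                "within-person from between-person variance"
            )
        if self.reference_instrument not in self.instruments:
            raise ValueError("reference instrument missing from instrument list")

    @property
    def n_variables(self) -> int:
        return len(self.instruments) * self.n_occasions


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the three-instrument error model.

    All values refer to the natural-log intake scale.  ``mu_Q``, ``mu_F``,
    ``mu_M`` are occasion intercepts (drift), one per occasion, with the
    first fixed at zero.
    """

    mu_T: float
    sigma2_T: float
    mu_Q: tuple[float, ...] = (0.0, 0.0, 0.0)
    mu_F: tuple[float, ...] = (0.0, 0.0, 0.0)
    mu_M: tuple[float, ...] = (0.0, 0.0, 0.0)
    beta_Q0: float = 0.0
    beta_F0: float = 0.0
    beta_Q1: float = 1.0
    beta_F1: float = 1.0
    sigma2_r: float = 0.0
    sigma2_s: float = 0.0
    rho_rs: float = 0.0
    sigma2_eps: float = 0.0
    sigma2_u: float = 0.0
    sigma2_v: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu_Q", tuple(float(x) for x in self.mu_Q))
        object.__setattr__(self, "mu_F", tuple(float(x) for x in self.mu_F))
        object.__setattr__(self, "mu_M", tuple(float(x) for x in self.mu_M))

    # -- validation ------------------------------------------------------

    def validate(self, design: DesignSpec | None = None) -> None:
        """Raise ValueError naming the first violated invariant."""
        for name in ("sigma2_T", "sigma2_r", "sigma2_s",
                     "sigma2_eps", "sigma2_u", "sigma2_v"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be a finite nonnegative variance, got {value!r}")
        if not np.isfinite(self.rho_rs) or abs(self.rho_rs) > 1:
            raise ValueError(f"rho_rs must lie in [-1, 1], got {self.rho_rs!r}")
        for name in ("mu_T", "beta_Q0", "beta_F0", "beta_Q1", "beta_F1"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        J = design.n_occasions if design is not None else len(self.mu_Q)
        for name in ("mu_Q", "mu_F", "mu_M"):
            vec = getattr(self, name)
            if len(vec) != J:
                raise ValueError(f"{name} must have one intercept per occasion (J={J}), got {len(vec)}")
            if not all(np.isfinite(vec)):
                raise ValueError(f"{name} contains non-finite entries")
            if vec[0] != 0.0:
                raise ValueError(f"{name}[0] must be 0 (occasion-1 anchor for identifiability)")

    @property
    def n_occasions(self) -> int:
        return len(self.mu_Q)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mu_T": self.mu_T,
            "sigma2_T": self.sigma2_T,
            "mu_Q": list(self.mu_Q),
            "mu_F": list(self.mu_F),
            "mu_M": list(self.mu_M),
            "beta_Q0": self.beta_Q0,
            "beta_F0": self.beta_F0,
            "beta_Q1": self.beta_Q1,
            "beta_F1": self.beta_F1,
            "sigma2_r": self.sigma2_r,
            "sigma2_s": self.sigma2_s,
            "rho_rs": self.rho_rs,
            "sigma2_eps": self.sigma2_eps,
            "sigma2_u": self.sigma2_u,
            "sigma2_v": self.sigma2_v,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        for key in ("mu_Q", "mu_F", "mu_M"):
            d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        return cls.from_dict(json.loads(text))

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# implied moments
# ---------------------------------------------------------------------------

def implied_moments(params: ModelParameters,
                    design: DesignSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and covariance matrix of the stacked observation.

    The stacked vector is (Q_1..Q_J, F_1..F_J, M_1..M_J).  The covariance
    follows directly from the model equations, e.g.

        cov(Q_j, Q_j') = beta_Q1^2 sigma2_T + sigma2_r + 1{j=j'} sigma2_eps
        cov(Q_j, F_j') = beta_Q1 beta_F1 sigma2_T + rho_rs sigma_r sigma_s
        cov(Q_j, M_j') = beta_Q1 sigma2_T
        cov(M_j, M_j') = sigma2_T + 1{j=j'} sigma2_v

    Returns
    -------
    (mean, cov) : arrays of shape (3J,) and (3J, 3J).
    """
    if design is None:
        design = DesignSpec(n_occasions=params.n_occasions)
    params.validate(design)
    J = design.n_occasions

    p = params
    mean = np.concatenate([
        np.asarray(p.mu_Q) + p.beta_Q0 + p.beta_Q1 * p.mu_T,
        np.asarray(p.mu_F) + p.beta_F0 + p.beta_F1 * p.mu_T,
        np.asarray(p.mu_M) + p.mu_T,
    ])

    ones = np.ones((J, J))
    eye = np.eye(J)
    c_rs = p.rho_rs * math.sqrt(p.sigma2_r * p.sigma2_s)
    QQ = (p.beta_Q1 ** 2 * p.sigma2_T + p.sigma2_r) * ones + p.sigma2_eps * eye
    FF = (p.beta_F1 ** 2 * p.sigma2_T + p.sigma2_s) * ones + p.sigma2_u * eye
    MM = p.sigma2_T * ones + p.sigma2_v * eye
    QF = (p.beta_Q1 * p.beta_F1 * p.sigma2_T + c_rs) * ones
    QM = (p.beta_Q1 * p.sigma2_T) * ones
    FM = (p.beta_F1 * p.sigma2_T) * ones
    cov = np.block([[QQ, QF, QM], [QF.T, FF, FM], [QM.T, FM.T, MM]])
    return mean, cov


# ---------------------------------------------------------------------------
# validity metrics
# ---------------------------------------------------------------------------

def _instrument_components(params: ModelParameters, instrument: str) -> tuple[float, float, float]:
    """(slope, person-bias variance, within-person variance) for a tool."""
    if instrument == "webq":
        return params.beta_Q1, params.sigma2_r, params.sigma2_eps
    if instrument == "recall":
        return params.beta_F1, params.sigma2_s, params.sigma2_u
    raise ValueError(
        f"instrument must be one of {SELF_REPORT_INSTRUMENTS} (the biomarker "
        f"has no attenuation factor in this model), got {instrument!r}"
    )


def _check_k(k: int) -> int:
    if not float(k).is_integer() or k < 1:
        raise ValueError(f"k must be an integer >= 1, got {k!r}")
    return int(k)


def attenuation_factor(params: ModelParameters, instrument: str, k: int = 1) -> float:
    """Attenuation factor lambda_k for the mean of k administrations.

    lambda_k = beta1 * sigma2_T / (beta1^2 sigma2_T + sigma2_b + sigma2_w / k),

    the slope of regressing latent true intake on the k-administration mean:
    averaging replaces the within-person error variance sigma2_w by
    sigma2_w / k while the person-specific bias variance sigma2_b persists.
    """
    k = _check_k(k)
    params.validate()
    beta1, s2_b, s2_w = _instrument_components(params, instrument)
    if beta1 <= 0:
        warnings.warn(
            "intake slope beta1 <= 0: the attenuation-factor interpretation "
            "(shrinkage of log relative risks toward zero) breaks down",
            stacklevel=2,
        )
    denom = beta1 ** 2 * params.sigma2_T + s2_b + s2_w / k
    return beta1 * params.sigma2_T / denom


def correlation_with_truth(params: ModelParameters, instrument: str, k: int = 1) -> float:
    """Correlation rho_k between the mean of k administrations and true intake.

    rho_k = beta1 sigma_T / sqrt(beta1^2 sigma2_T + sigma2_b + sigma2_w / k).
    Satisfies (rho_k / rho_1)^2 = lambda_k / lambda_1.
    """
    k = _check_k(k)
    params.validate()
    beta1, s2_b, s2_w = _instrument_components(params, instrument)
    denom = beta1 ** 2 * params.sigma2_T + s2_b + s2_w / k
    return beta1 * math.sqrt(params.sigma2_T) / math.sqrt(denom)


# ---------------------------------------------------------------------------
# closed-form extrapolation from printed (lambda1, lambda2, rho1)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtrapolationInput:
    """Printed single- and two-administration metrics of one tool/nutrient.

    ``lambda1``/``lambda2`` are the attenuation factors for one and for the
    mean of two administrations; ``rho1`` the single-administration
    correlation with true intake.  These three numbers identify the ratio
    x = sigma2_w / (beta1^2 sigma2_T + sigma2_b), which is all the
    k-repeat algebra needs.
    """

    lambda1: float
    lambda2: float
    rho1: float

    def __post_init__(self) -> None:
        if not (0 < self.lambda1):
            raise ValueError(f"lambda1 must be positive, got {self.lambda1!r}")
        if self.lambda2 < self.lambda1:
            raise InfeasibleRatioError(
                f"lambda2 ({self.lambda2}) < lambda1 ({self.lambda1}): averaging "
                "cannot worsen attenuation in this model"
            )
        if self.lambda2 / self.lambda1 >= 2:
            raise InfeasibleRatioError(
                f"lambda2/lambda1 = {self.lambda2 / self.lambda1:.3f} >= 2: no "
                "nonnegative within-person variance ratio achieves this "
                "(the k=2 gain is bounded by a factor of 2)"
            )
        if not (0 < self.rho1 <= 1):
            raise ValueError(f"rho1 must lie in (0, 1], got {self.rho1!r}")

    @property
    def variance_ratio(self) -> float:
        """x = sigma2_w / (beta1^2 sigma2_T + sigma2_b), solved from lambda2/lambda1."""
        ratio = self.lambda2 / self.lambda1
        return 2.0 * (ratio - 1.0) / (2.0 - ratio)


def extrapolate_from_pair(inp: ExtrapolationInput, k: int) -> tuple[float, float]:
    """Predict (lambda_k, rho_k) for the mean of k administrations.

    Solving (1 + x) / (1 + x/2) = lambda2/lambda1 for the variance ratio x
    gives  lambda_k = lambda1 (1 + x) / (1 + x/k)  and, because the two
    metrics share a denominator,  rho_k = rho1 sqrt(lambda_k / lambda1).
    Both are nondecreasing in k with finite limits at k -> infinity.
    """
    k = _check_k(k)
    x = inp.variance_ratio
    lam_k = inp.lambda1 * (1.0 + x) / (1.0 + x / k)
    rho_k = inp.rho1 * math.sqrt(lam_k / inp.lambda1)
    return lam_k, rho_k


# ---------------------------------------------------------------------------
# constructing parameter sets that reproduce printed validity metrics
# ---------------------------------------------------------------------------

def parameters_from_validity(
    lambda1: float,
    lambda2: float,
    rho1: float,
    sigma2_T: float,
    *,
    mu_T: float = 0.0,
    instrument: str = "webq",
    base: ModelParameters | None = None,
) -> ModelParameters:
    """Solve an instrument's error components from its printed validity metrics.

    Given (lambda1, lambda2, rho1) and a chosen between-person variance
    sigma2_T, the model is exactly identified for one self-report tool:

        beta1   = rho1^2 / lambda1
        V1      = beta1 * sigma2_T / lambda1        (single-administration variance
                                                     explained + bias + error)
        x       = 2 (R - 1) / (2 - R),  R = lambda2/lambda1
        sigma2_b = V1 / (1 + x) - beta1^2 sigma2_T
        sigma2_w = V1 * x / (1 + x)

    Used by the synthetic-cohort generator to build scenarios whose implied
    metrics equal published values.  Raises if the implied person-bias
    variance is negative, which happens when rho1^2 > 1/(1 + x): the stated
    correlation is too high for the stated attenuation gain from k=1 to k=2.
    """
    inp = ExtrapolationInput(lambda1, lambda2, rho1)  # validates feasibility
    beta1 = rho1 ** 2 / lambda1
    V1 = beta1 * sigma2_T / lambda1
    x = inp.variance_ratio
    s2_base = V1 / (1.0 + x)
    s2_b = s2_base - beta1 ** 2 * sigma2_T
    s2_w = V1 - s2_base
    if s2_b < -1e-12:
        raise ValueError(
            f"metrics imply negative person-bias variance ({s2_b:.4g}): "
            f"rho1={rho1} is too high for the attenuation pair "
            f"({lambda1}, {lambda2})"
        )
    s2_b = max(s2_b, 0.0)
    if base is None:
        base = ModelParameters(mu_T=mu_T, sigma2_T=sigma2_T)
    out = base.replace(mu_T=mu_T, sigma2_T=sigma2_T)
    if instrument == "webq":
        return out.replace(beta_Q1=beta1, sigma2_r=s2_b, sigma2_eps=s2_w)
    if instrument == "recall":
        return out.replace(beta_F1=beta1, sigma2_s=s2_b, sigma2_u=s2_w)
    raise ValueError(f"instrument must be a self-report tool, got {instrument!r}")
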