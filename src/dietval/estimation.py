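"""Maximum-likelihood fitting of the three-instrument measurement-error model.

Each participant contributes a stacked vector (Q_1..Q_J, F_1..F_J, M_1..M_J)
of log-scale measurements, any subset of which may be missing.  Under the
model all components are jointly Gaussian, so the likelihood of a
participant is the multivariate-normal density of their *observed*
subvector under the implied moments restricted to the observed coordinates
— full-information maximum likelihood (FIML), valid when missingness is
missing-at-random.  Participants are grouped by missingness pattern and the
likelihood evaluated from per-pattern sufficient statistics (count, mean,
scatter), so an evaluation costs the same for 160 participants as for
500,000.

Variances are optimized on the log scale and the bias correlation via
arctanh, making the search unconstrained; gradients are analytic.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import eigh, pinvh

from .model import (
    DesignSpec,
    ModelParameters,
    attenuation_factor,
    correlation_with_truth,
)

__all__ = [
    "CohortMeasurements",
    "FitConfig",
    "FitResult",
    "MetricInterval",
    "log_likelihood",
    "fit_model",
    "metric_uncertainty",
    "fit_subgroups",
    "load_cohort",
]

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)
_VAR_FLOOR_LOG = math.log(1e-8)
_VAR_CEIL_LOG = math.log(1e6)
_BOUNDARY_VAR = 1e-6

_INSTRUMENT_ORDER = ("webq", "recall", "biomarker")


# ---------------------------------------------------------------------------
# cohort container and long-format I/O
# ---------------------------------------------------------------------------

@dataclass
class CohortMeasurements:
    """Wide per-participant measurement matrix for one nutrient.

    ``values`` has shape (n, 3J) with columns ordered Q_1..Q_J, F_1..F_J,
    M_1..M_J on the natural-log scale (``log_scale`` records that the
    transform has been applied); NaN marks a missing cell.  Covariates may
    themselves contain NaN where unrecorded.
    """

    nutrient: str
    ids: np.ndarray
    values: np.ndarray
    sex: np.ndarray
    age: np.ndarray
    bmi: np.ndarray
    design: DesignSpec = field(default_factory=DesignSpec)
    log_scale: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if m != self.design.n_variables:
            raise ValueError(
                f"values has {m} columns; design implies {self.design.n_variables}"
            )
        with np.errstate(invalid="ignore"):
            if np.isinf(self.values).any():
                raise ValueError("non-finite (infinite) measurement values")
        for name in ("ids", "sex", "age", "bmi"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n participants {n}")
            setattr(self, name, arr)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, mask: np.ndarray) -> "CohortMeasurements":
        return CohortMeasurements(
            nutrient=self.nutrient,
            ids=self.ids[mask],
            values=self.values[mask],
            sex=self.sex[mask],
            age=self.age[mask],
            bmi=self.bmi[mask],
            design=self.design,
            log_scale=self.log_scale,
        )

    # -- long-format interchange ----------------------------------------

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        nutrient: str | None = None,
        design: DesignSpec | None = None,
        log_transform: bool = True,
    ) -> "CohortMeasurements":
        """Build from long format: participant_id, occasion, instrument,
        nutrient, value, sex, age, bmi.  ``log_transform=True`` means values
        arrive in natural units and are logged on load."""
        required = {"participant_id", "occasion", "instrument", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long-format cohort missing columns: {sorted(missing)}")
        if nutrient is not None and "nutrient" in df.columns:
            df = df[df["nutrient"] == nutrient]
            if df.empty:
                raise ValueError(f"no rows for nutrient {nutrient!r}")
        elif nutrient is None:
            nutrient = str(df["nutrient"].iloc[0]) if "nutrient" in df.columns else "nutrient"
            if "nutrient" in df.columns:
                df = df[df["nutrient"] == nutrient]
        if design is None:
            design = DesignSpec(n_occasions=int(df["occasion"].max()))
        J = design.n_occasions

        vals = df["value"].to_numpy(dtype=float)
        if log_transform:
            if np.nanmin(vals) <= 0:
                raise ValueError("log transform requested but nonpositive values present")
            df = df.assign(value=np.log(vals))

        ids = pd.unique(df["participant_id"])
        row = pd.Series(np.arange(len(ids)), index=ids)
        values = np.full((len(ids), 3 * J), np.nan)
        inst_offset = {"webq": 0, "recall": J, "biomarker": 2 * J}
        bad = set(df["instrument"]) - set(inst_offset)
        if bad:
            raise ValueError(f"unknown instrument labels: {sorted(bad)}")
        occ = df["occasion"].to_numpy(dtype=int)
        if occ.min() < 1 or occ.max() > J:
            raise ValueError(f"occasions must lie in 1..{J}")
        cols = np.array([inst_offset[i] for i in df["instrument"]]) + occ - 1
        values[row[df["participant_id"]].to_numpy(), cols] = df["value"].to_numpy()

        def covariate(name: str) -> np.ndarray:
            if name not in df.columns:
                return np.full(len(ids), np.nan)
            return df.groupby("participant_id", sort=False)[name].first()[ids].to_numpy(dtype=float)

        return cls(
            nutrient=str(nutrient),
            ids=np.asarray(ids),
            values=values,
            sex=covariate("sex"),
            age=covariate("age"),
            bmi=covariate("bmi"),
            design=design,
            log_scale=True,
        )

    def to_long(self) -> pd.DataFrame:
        J = self.design.n_occasions
        frames = []
        for inst, off in (("webq", 0), ("recall", J), ("biomarker", 2 * J)):
            for j in range(J):
                frames.append(pd.DataFrame({
                    "participant_id": self.ids,
                    "occasion": j + 1,
                    "instrument": inst,
                    "nutrient": self.nutrient,
                    "value": self.values[:, off + j],
                    "sex": self.sex,
                    "age": self.age,
                    "bmi": self.bmi,
                }))
        out = pd.concat(frames, ignore_index=True)
        return out.dropna(subset=["value"]).reset_index(drop=True)


def load_cohort(
    path,
    nutrient: str | None = None,
    design: DesignSpec | None = None,
    log_transform: bool = True,
    sep: str = "\t",
) -> CohortMeasurements:
    """Read a long-format delimited cohort file (see CohortMeasurements.from_long)."""
    df = pd.read_csv(path, sep=sep, comment="#")
    return CohortMeasurements.from_long(df, nutrient=nutrient, design=design,
                                        log_transform=log_transform)


# ---------------------------------------------------------------------------
# parameter packing: natural <-> unconstrained ("free") vector
# ---------------------------------------------------------------------------

def _layout(J: int) -> dict:
    """Index layout of the packed parameter vector for J occasions."""
    names = ["mu_T"]
    names += [f"mu_Q{j}" for j in range(2, J + 1)]
    names += [f"mu_F{j}" for j in range(2, J + 1)]
    names += [f"mu_M{j}" for j in range(2, J + 1)]
    names += ["beta_Q0", "beta_F0", "beta_Q1", "beta_F1",
              "sigma2_T", "sigma2_r", "sigma2_s", "rho_rs",
              "sigma2_eps", "sigma2_u", "sigma2_v"]
    idx = {n: i for i, n in enumerate(names)}
    var_idx = np.array([idx[n] for n in
                        ("sigma2_T", "sigma2_r", "sigma2_s",
                         "sigma2_eps", "sigma2_u", "sigma2_v")])
    return {"names": names, "idx": idx, "var_idx": var_idx,
            "rho_idx": idx["rho_rs"], "n_params": len(names)}


def _pack(params: ModelParameters) -> np.ndarray:
    J = params.n_occasions
    theta = [params.mu_T]
    theta += list(params.mu_Q[1:]) + list(params.mu_F[1:]) + list(params.mu_M[1:])
    theta += [params.beta_Q0, params.beta_F0, params.beta_Q1, params.beta_F1,
              params.sigma2_T, params.sigma2_r, params.sigma2_s, params.rho_rs,
              params.sigma2_eps, params.sigma2_u, params.sigma2_v]
    return np.asarray(theta, dtype=float)


def _unpack(theta: np.ndarray, J: int) -> ModelParameters:
    k = 1 + 3 * (J - 1)
    muQ = (0.0, *theta[1:J])
    muF = (0.0, *theta[J:2 * J - 1])
    muM = (0.0, *theta[2 * J - 1:3 * J - 2])
    b = theta[k:]
    return ModelParameters(
        mu_T=theta[0], mu_Q=muQ, mu_F=muF, mu_M=muM,
        beta_Q0=b[0], beta_F0=b[1], beta_Q1=b[2], beta_F1=b[3],
        sigma2_T=b[4], sigma2_r=b[5], sigma2_s=b[6], rho_rs=b[7],
        sigma2_eps=b[8], sigma2_u=b[9], sigma2_v=b[10],
    )


def _to_free(theta: np.ndarray, lay: dict) -> np.ndarray:
    z = theta.copy()
    z[lay["var_idx"]] = np.log(np.maximum(theta[lay["var_idx"]], 1e-8))
    z[lay["rho_idx"]] = np.arctanh(np.clip(theta[lay["rho_idx"]], -0.999999, 0.999999))
    return z


def _from_free(z: np.ndarray, lay: dict) -> np.ndarray:
    theta = z.copy()
    theta[lay["var_idx"]] = np.exp(z[lay["var_idx"]])
    theta[lay["rho_idx"]] = np.tanh(z[lay["rho_idx"]])
    return theta


def _chain(theta: np.ndarray, lay: dict) -> np.ndarray:
    """d(natural)/d(free), diagonal."""
    jac = np.ones_like(theta)
    jac[lay["var_idx"]] = theta[lay["var_idx"]]
    jac[lay["rho_idx"]] = 1.0 - theta[lay["rho_idx"]] ** 2
    return jac


def _free_bounds(lay: dict) -> list:
    bounds = [(None, None)] * lay["n_params"]
    for i in lay["var_idx"]:
        bounds[i] = (_VAR_FLOOR_LOG, _VAR_CEIL_LOG)
    bounds[lay["rho_idx"]] = (-6.0, 6.0)
    return bounds


# ---------------------------------------------------------------------------
# covariance basis: Sigma(theta) = sum_k c_k(theta) B_k
# ---------------------------------------------------------------------------

def _basis(J: int) -> np.ndarray:
    """Nine constant 3J x 3J matrices spanning the implied covariance."""
    m = 3 * J
    ones = np.ones((J, J))
    eye = np.eye(J)
    B = np.zeros((9, m, m))
    blocks = [(0, 0, ones), (0, 0, eye),          # QQ shared / diag
              (1, 1, ones), (1, 1, eye),          # FF
              (2, 2, ones), (2, 2, eye),          # MM
              (0, 1, ones), (0, 2, ones), (1, 2, ones)]  # QF, QM, FM
    order = [0, 1, 2, 3, 4, 5, 6, 7, 8]
    for k, (bi, bj, blk) in zip(order, blocks):
        sl_i = slice(bi * J, (bi + 1) * J)
        sl_j = slice(bj * J, (bj + 1) * J)
        B[k][sl_i, sl_j] = blk
        if bi != bj:
            B[k][sl_j, sl_i] = blk.T
    return B


def _coeffs_and_jac(theta: np.ndarray, lay: dict) -> tuple[np.ndarray, np.ndarray]:
    """Basis coefficients c(theta) and Jacobian dc/dtheta (natural scale)."""
    ix = lay["idx"]
    bQ1, bF1 = theta[ix["beta_Q1"]], theta[ix["beta_F1"]]
    s2T, s2r, s2s = theta[ix["sigma2_T"]], theta[ix["sigma2_r"]], theta[ix["sigma2_s"]]
    rho = theta[ix["rho_rs"]]
    s2e, s2u, s2v = theta[ix["sigma2_eps"]], theta[ix["sigma2_u"]], theta[ix["sigma2_v"]]
    sr = math.sqrt(max(s2r, 1e-300))
    ss = math.sqrt(max(s2s, 1e-300))

    c = np.array([
        bQ1 ** 2 * s2T + s2r, s2e,
        bF1 ** 2 * s2T + s2s, s2u,
        s2T, s2v,
        bQ1 * bF1 * s2T + rho * sr * ss,
        bQ1 * s2T, bF1 * s2T,
    ])

    C = np.zeros((lay["n_params"], 9))
    C[ix["beta_Q1"], [0, 6, 7]] = [2 * bQ1 * s2T, bF1 * s2T, s2T]
    C[ix["beta_F1"], [2, 6, 8]] = [2 * bF1 * s2T, bQ1 * s2T, s2T]
    C[ix["sigma2_T"], [0, 2, 4, 6, 7, 8]] = [bQ1 ** 2, bF1 ** 2, 1.0,
                                             bQ1 * bF1, bQ1, bF1]
    C[ix["sigma2_r"], [0, 6]] = [1.0, rho * ss / (2 * sr)]
    C[ix["sigma2_s"], [2, 6]] = [1.0, rho * sr / (2 * ss)]
    C[ix["rho_rs"], 6] = sr * ss
    C[ix["sigma2_eps"], 1] = 1.0
    C[ix["sigma2_u"], 3] = 1.0
    C[ix["sigma2_v"], 5] = 1.0
    return c, C


def _mean_and_jac(theta: np.ndarray, lay: dict, J: int) -> tuple[np.ndarray, np.ndarray]:
    ix = lay["idx"]
    mu_T = theta[0]
    bQ0, bF0 = theta[ix["beta_Q0"]], theta[ix["beta_F0"]]
    bQ1, bF1 = theta[ix["beta_Q1"]], theta[ix["beta_F1"]]
    muQ = np.concatenate([[0.0], theta[1:J]])
    muF = np.concatenate([[0.0], theta[J:2 * J - 1]])
    muM = np.concatenate([[0.0], theta[2 * J - 1:3 * J - 2]])
    mu = np.concatenate([muQ + bQ0 + bQ1 * mu_T,
                         muF + bF0 + bF1 * mu_T,
                         muM + mu_T])

    D = np.zeros((lay["n_params"], 3 * J))
    D[0, :J] = bQ1
    D[0, J:2 * J] = bF1
    D[0, 2 * J:] = 1.0
    for j in range(J - 1):
        D[1 + j, 1 + j] = 1.0                      # mu_Q{j+2}
        D[J + j, J + 1 + j] = 1.0                  # mu_F{j+2}
        D[2 * J - 1 + j, 2 * J + 1 + j] = 1.0      # mu_M{j+2}
    D[ix["beta_Q0"], :J] = 1.0
    D[ix["beta_F0"], J:2 * J] = 1.0
    D[ix["beta_Q1"], :J] = mu_T
    D[ix["beta_F1"], J:2 * J] = mu_T
    return mu, D


# ---------------------------------------------------------------------------
# pattern-grouped FIML data
# ---------------------------------------------------------------------------

class _FimlData:
    """Participants grouped by missingness pattern, statistics stacked.

    Each pattern's observed-coordinate covariance is evaluated through the
    standard embedding: mask the full covariance to the observed rows and
    columns and put 1 on missing diagonal entries.  The log-determinant and
    the quadratic form of the embedded matrix equal those of the observed
    submatrix (the mean/scatter are embedded with zeros at missing
    coordinates), so all patterns evaluate in a few batched linalg calls.
    """

    def __init__(self, values: np.ndarray, J: int):
        self.J = J
        self.m = 3 * J
        mask = ~np.isnan(values)
        keep = mask.sum(axis=1) > 0
        self.n_excluded = int((~keep).sum())
        if self.n_excluded:
            logger.warning(
                "%d participant(s) with no observed measurements excluded "
                "from the likelihood", self.n_excluded)
        values = values[keep]
        mask = mask[keep]
        self.n = values.shape[0]
        if self.n == 0:
            raise ValueError("no participants with observed data")

        keys = mask @ (1 << np.arange(self.m, dtype=np.int64))
        uniq, inverse = np.unique(keys, return_inverse=True)
        P = len(uniq)
        self.obs = np.zeros((P, self.m), dtype=bool)
        self.rows = []
        self.X = []          # per pattern: raw rows embedded with 0 at missing
        for u in range(P):
            rows = np.flatnonzero(inverse == u)
            self.obs[u] = mask[rows[0]]
            self.rows.append(rows)
            Xp = np.where(mask[rows[0]], values[rows], 0.0)
            self.X.append(Xp)
        self.WW = self.obs[:, :, None] & self.obs[:, None, :]   # (P, m, m)
        diag = np.arange(self.m)
        self.miss_eye = np.zeros((P, self.m, self.m))
        self.miss_eye[:, diag, diag] = ~self.obs
        self.m_obs = self.obs.sum(axis=1).astype(float)         # (P,)
        self.n_pat, self.xbar, self.S = self._stats(None)

    def _stats(self, weights: np.ndarray | None):
        """Stacked (counts, embedded means, embedded scatters) per pattern."""
        P = len(self.rows)
        n_pat = np.zeros(P)
        xbar = np.zeros((P, self.m))
        S = np.zeros((P, self.m, self.m))
        for u, rows in enumerate(self.rows):
            X = self.X[u]
            if weights is None:
                n = float(len(rows))
                if n == 0:
                    continue
                mu = X.mean(axis=0)
                Xc = X - mu
                Sp = Xc.T @ Xc
            else:
                w = weights[rows].astype(float)
                n = w.sum()
                if n == 0:
                    continue
                mu = (w @ X) / n
                Xc = X - mu
                Sp = (Xc * w[:, None]).T @ Xc
            n_pat[u] = n
            xbar[u] = np.where(self.obs[u], mu, 0.0)
            S[u] = Sp * self.WW[u]
        return n_pat, xbar, S

    @property
    def missing_summary(self) -> dict:
        observed = float((self.n_pat * self.m_obs).sum())
        complete = int(self.n_pat[self.m_obs == self.m].sum())
        return {
            "n_participants": self.n,
            "n_excluded_empty": self.n_excluded,
            "n_patterns": int(len(self.rows)),
            "n_complete": complete,
            "fraction_cells_missing": 1.0 - observed / (self.n * self.m),
        }


def _nll_factory(data: _FimlData, lay: dict,
                 weights: np.ndarray | None = None) -> Callable:
    """Negative log-likelihood (free scale) with analytic gradient.

    Batched over missingness patterns; cost is independent of cohort size.
    """
    J = data.J
    m = data.m
    B2d = _basis(J).reshape(9, -1)
    if weights is None:
        n_pat, xbar, S = data.n_pat, data.xbar, data.S
    else:
        n_pat, xbar, S = data._stats(weights)
    active = n_pat > 0
    n_pat, xbar, S = n_pat[active], xbar[active], S[active]
    WW = data.WW[active]
    miss_eye = data.miss_eye[active]
    m_obs = data.m_obs[active]
    obs = data.obs[active]
    n_total_obs = float(n_pat @ m_obs)
    bad = (1e12, np.zeros(lay["n_params"]))

    def nll(z: np.ndarray) -> tuple[float, np.ndarray]:
        theta = _from_free(z, lay)
        c, C = _coeffs_and_jac(theta, lay)
        mu, D = _mean_and_jac(theta, lay, J)

        Sig = (c @ B2d).reshape(m, m)
        Sig_t = Sig * WW + miss_eye                      # (P, m, m)
        try:
            L = np.linalg.cholesky(Sig_t)
        except np.linalg.LinAlgError:
            return bad
        logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
        K = np.linalg.inv(Sig_t)                         # block diag: (K_oo, I)
        d = (xbar - mu) * obs                            # (P, m)
        Kd = np.einsum("pij,pj->pi", K, d)
        quad = np.einsum("pij,pij->", K, S) + n_pat @ np.einsum("pi,pi->p", d, Kd)
        ll = -0.5 * (n_total_obs * _LOG_2PI + n_pat @ logdet + quad)
        if not np.isfinite(ll):
            return bad

        # d(ll)/d(Sigma) summed over patterns, masked to observed coordinates
        G = S + n_pat[:, None, None] * np.einsum("pi,pj->pij", d, d)
        A = np.einsum("pij,pjk,pkl->il", K, G, K) - \
            np.einsum("p,pij->ij", n_pat, K * WW)
        grad = C @ (0.5 * (B2d @ A.ravel()))
        grad += D @ (n_pat @ Kd)
        grad *= _chain(theta, lay)                       # to free scale
        return -ll, -grad

    return nll


# ---------------------------------------------------------------------------
# public likelihood
# ---------------------------------------------------------------------------

def log_likelihood(params: ModelParameters, cohort: CohortMeasurements,
                   design: DesignSpec | None = None) -> float:
    """FIML log-likelihood of the cohort under ``params``.

    Sums, over participants, the multivariate-normal log-density of each
    participant's observed subvector under the implied moments restricted to
    the observed coordinates.  Equals the complete-data log-likelihood when
    nothing is missing.  Participants with no observed values are excluded
    with a logged warning.
    """
    design = design or cohort.design
    params.validate(design)
    if not cohort.log_scale:
        raise ValueError("cohort must be log-transformed before likelihood evaluation")
    lay = _layout(design.n_occasions)
    data = _FimlData(cohort.values, design.n_occasions)
    z = _to_free(_pack(params), lay)
    val, _ = _nll_factory(data, lay)(z)
    return -val


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Optimizer settings.

    ``n_starts > 1`` adds seeded jittered restarts around the deterministic
    method-of-moments start (robustness check); the best optimum is kept.
    ``gtol`` is the projected-gradient tolerance of the quasi-Newton search.
    """

    max_iter: int = 500
    gtol: float = 1e-8
    ftol: float = 1e-12
    n_starts: int = 1
    jitter: float = 0.25
    seed: int = 0
    compute_vcov: bool = True
    start: ModelParameters | None = None


@dataclass
class MetricInterval:
    """Point estimate with bootstrap-percentile and delta-method 95% intervals."""

    metric: str
    instrument: str
    k: int
    estimate: float
    ci_low: float
    ci_high: float
    delta_low: float
    delta_high: float
    n_boot: int
    n_boot_failed: int


@dataclass
class FitResult:
    """Converged ML fit with enough context to derive metrics and intervals."""

    params: ModelParameters
    loglik: float
    converged: bool
    message: str
    n_participants: int
    n_excluded: int
    design: DesignSpec
    param_names: list
    vcov: np.ndarray | None
    missing_summary: dict
    boundary_params: list
    nutrient: str = ""
    _free: np.ndarray | None = field(default=None, repr=False)
    _hessian: np.ndarray | None = field(default=None, repr=False)
    _data: object = field(default=None, repr=False)
    _cohort: object = field(default=None, repr=False)

    def attenuation(self, k: int = 1, instrument: str = "webq") -> float:
        return attenuation_factor(self.params, instrument, k)

    def correlation(self, k: int = 1, instrument: str = "webq") -> float:
        return correlation_with_truth(self.params, instrument, k)

    def to_dict(self, k_max: int = 5) -> dict:
        out = {
            "nutrient": self.nutrient,
            "converged": self.converged,
            "loglik": self.loglik,
            "n_participants": self.n_participants,
            "parameters": self.params.to_dict(),
            "missing_summary": self.missing_summary,
            "boundary_params": list(self.boundary_params),
            "metrics": {
                inst: {
                    str(k): {
                        "attenuation": self.attenuation(k, inst),
                        "correlation": self.correlation(k, inst),
                    } for k in range(1, k_max + 1)
                } for inst in ("webq", "recall")
            },
        }
        if self.vcov is not None:
            out["vcov_transformed"] = self.vcov.tolist()
            out["param_names"] = list(self.param_names)
        return out


def _moment_start(values: np.ndarray, J: int) -> ModelParameters:
    """Deterministic method-of-moments initialization.

    sigma2_T from the mean off-diagonal biomarker covariance; slopes from
    cross covariances with the biomarker; residual variances from sample
    variances minus explained parts, floored at 1e-4.
    """
    Vm = np.ma.masked_invalid(values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        C = np.asarray(np.ma.cov(Vm, rowvar=False, allow_masked=True))
        colmean = np.asarray(Vm.mean(axis=0))
    C = np.nan_to_num(C, nan=0.0)
    colmean = np.nan_to_num(colmean, nan=float(np.nan_to_num(Vm.mean())))
    q, f, mcol = slice(0, J), slice(J, 2 * J), slice(2 * J, 3 * J)
    off = ~np.eye(J, dtype=bool)

    floor = 1e-4
    s2T = max(float(C[mcol, mcol][off].mean()), floor)
    bQ1 = float(C[q, mcol].mean()) / s2T
    bF1 = float(C[f, mcol].mean()) / s2T
    s2r = max(float(C[q, q][off].mean()) - bQ1 ** 2 * s2T, floor)
    s2s = max(float(C[f, f][off].mean()) - bF1 ** 2 * s2T, floor)
    s2e = max(float(np.diag(C[q, q]).mean()) - bQ1 ** 2 * s2T - s2r, floor)
    s2u = max(float(np.diag(C[f, f]).mean()) - bF1 ** 2 * s2T - s2s, floor)
    s2v = max(float(np.diag(C[mcol, mcol]).mean()) - s2T, floor)
    c_rs = float(C[q, f].mean()) - bQ1 * bF1 * s2T
    rho = float(np.clip(c_rs / math.sqrt(s2r * s2s), -0.9, 0.9))

    mu_T = float(colmean[2 * J])
    mu_M = (0.0, *(float(colmean[2 * J + j] - mu_T) for j in range(1, J)))
    bQ0 = float(colmean[0] - bQ1 * mu_T)
    mu_Q = (0.0, *(float(colmean[j] - bQ0 - bQ1 * mu_T) for j in range(1, J)))
    bF0 = float(colmean[J] - bF1 * mu_T)
    mu_F = (0.0, *(float(colmean[J + j] - bF0 - bF1 * mu_T) for j in range(1, J)))

    return ModelParameters(
        mu_T=mu_T, sigma2_T=s2T, mu_Q=mu_Q, mu_F=mu_F, mu_M=mu_M,
        beta_Q0=bQ0, beta_F0=bF0, beta_Q1=bQ1, beta_F1=bF1,
        sigma2_r=s2r, sigma2_s=s2s, rho_rs=rho,
        sigma2_eps=s2e, sigma2_u=s2u, sigma2_v=s2v,
    )


def _minimize(nll: Callable, z0: np.ndarray, lay: dict, config: FitConfig):
    return optimize.minimize(
        nll, z0, jac=True, method="L-BFGS-B", bounds=_free_bounds(lay),
        options={"maxiter": config.max_iter, "gtol": config.gtol,
                 "ftol": config.ftol},
    )


def _minimize_preconditioned(nll: Callable, z0: np.ndarray, H: np.ndarray,
                             config: FitConfig):
    """Quasi-Newton search in coordinates whitened by a reference Hessian.

    With y defined by z = z0 + A y, A = U diag(w^-1/2) from H = U diag(w) U',
    the curvature near z0 is approximately the identity, so a warm-started
    search (bootstrap replicates, nearby strata) converges in few iterations.
    """
    w, U = eigh(0.5 * (H + H.T))
    w = np.clip(w, max(w.max(), 1.0) * 1e-8, None)
    A = U * (1.0 / np.sqrt(w))

    def f(y: np.ndarray) -> tuple[float, np.ndarray]:
        val, g = nll(z0 + A @ y)
        return val, A.T @ g

    res = optimize.minimize(
        f, np.zeros(len(z0)), jac=True, method="L-BFGS-B",
        options={"maxiter": config.max_iter, "gtol": config.gtol,
                 "ftol": config.ftol},
    )
    res.x = z0 + A @ res.x
    return res


def _numerical_hessian(nll: Callable, z: np.ndarray, h: float = 1e-5) -> np.ndarray:
    p = len(z)
    H = np.zeros((p, p))
    for i in range(p):
        zp, zm = z.copy(), z.copy()
        zp[i] += h
        zm[i] -= h
        H[i] = (nll(zp)[1] - nll(zm)[1]) / (2 * h)
    return 0.5 * (H + H.T)


def _psd_project(V: np.ndarray) -> np.ndarray:
    w, U = eigh(0.5 * (V + V.T))
    return (U * np.clip(w, 0.0, None)) @ U.T


def fit_model(cohort: CohortMeasurements, design: DesignSpec | None = None,
              config: FitConfig | None = None) -> FitResult:
    """Fit the measurement model to one nutrient's cohort by FIML.

    Starts from a deterministic method-of-moments initialization and runs a
    bounded quasi-Newton search on the transformed (unconstrained)
    parameters; the result is therefore reproducible for a given cohort.
    Variance estimates at the floor are reported in ``boundary_params``.
    """
    design = design or cohort.design
    config = config or FitConfig()
    if not cohort.log_scale:
        raise ValueError("cohort must be log-transformed before fitting")
    J = design.n_occasions
    lay = _layout(J)
    data = _FimlData(cohort.values, J)

    biom = cohort.values[:, 2 * J:]
    if not (np.isfinite(biom).sum(axis=1) >= 2).any():
        raise ValueError(
            "need biomarker replicates (>=2 occasions observed for some "
            "participant) to separate within- from between-person variance")

    start = config.start or _moment_start(cohort.values, J)
    start.validate(design)
    z0 = _to_free(_pack(start), lay)
    nll = _nll_factory(data, lay)

    starts = [z0]
    if config.n_starts > 1:
        rng = np.random.default_rng(config.seed)
        starts += [z0 + rng.normal(0.0, config.jitter, size=z0.size)
                   for _ in range(config.n_starts - 1)]

    best = None
    for z_init in starts:
        res = _minimize(nll, z_init, lay, config)
        if best is None or res.fun < best.fun:
            best = res
    res = best

    f0 = nll(z0)[0]
    if res.fun > f0 + 1e-9:      # never accept a point worse than the start
        res.x, res.fun = z0, f0

    theta = _from_free(res.x, lay)
    params = _unpack(theta, J)
    boundary = [name for i, name in enumerate(lay["names"])
                if i in set(lay["var_idx"]) and theta[i] <= _BOUNDARY_VAR]
    if boundary:
        logger.warning("variance estimate(s) at boundary: %s", boundary)

    vcov = H = None
    if config.compute_vcov:
        H = _numerical_hessian(nll, res.x)
        vcov = _psd_project(pinvh(H))

    return FitResult(
        params=params,
        loglik=-float(res.fun),
        converged=bool(res.success),
        message=str(res.message),
        n_participants=data.n,
        n_excluded=data.n_excluded,
        design=design,
        param_names=lay["names"],
        vcov=vcov,
        missing_summary=data.missing_summary,
        boundary_params=boundary,
        nutrient=cohort.nutrient,
        _free=res.x,
        _hessian=H,
        _data=data,
        _cohort=cohort,
    )


# ---------------------------------------------------------------------------
# uncertainty for derived metrics
# ---------------------------------------------------------------------------

_METRIC_FUN = {
    "attenuation": attenuation_factor,
    "correlation": correlation_with_truth,
}


def metric_uncertainty(
    fit: FitResult,
    metric: str = "attenuation",
    k: int = 1,
    instrument: str = "webq",
    n_boot: int = 500,
    seed: int = 0,
) -> MetricInterval:
    """95% interval for lambda_k or rho_k.

    Primary method: nonparametric bootstrap over participants (each
    replicate refits the model, warm-started at the full-data optimum;
    percentile interval).  A delta-method interval from the observed
    information is reported alongside.  Replicates that fail to converge are
    dropped and counted; more than 20% dropped triggers a warning.
    """
    if metric not in _METRIC_FUN:
        raise ValueError(f"metric must be one of {sorted(_METRIC_FUN)}")
    if not fit.converged:
        raise ValueError("metric_uncertainty requires a converged fit")
    fun = _METRIC_FUN[metric]
    point = fun(fit.params, instrument, k)
    J = fit.design.n_occasions
    lay = _layout(J)
    data: _FimlData = fit._data

    # delta method on the free scale
    if fit.vcov is not None:
        def metric_of_free(z):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return fun(_unpack(_from_free(z, lay), J), instrument, k)
        h = 1e-6
        g = np.zeros(lay["n_params"])
        for i in range(lay["n_params"]):
            zp, zm = fit._free.copy(), fit._free.copy()
            zp[i] += h
            zm[i] -= h
            g[i] = (metric_of_free(zp) - metric_of_free(zm)) / (2 * h)
        se = math.sqrt(max(g @ fit.vcov @ g, 0.0))
    else:
        se = float("nan")
    delta_low, delta_high = point - 1.96 * se, point + 1.96 * se

    rng = np.random.default_rng(seed)
    # replicate fits are warm-started at the full-data optimum in coordinates
    # whitened by its Hessian; the metric is only needed to ~1e-4, so
    # practical tolerances keep the bootstrap cheap
    boot_cfg = FitConfig(max_iter=300, gtol=1e-4, ftol=1e-10, compute_vcov=False)
    H = fit._hessian
    if H is None:
        H = _numerical_hessian(_nll_factory(data, lay), fit._free)
    estimates = []
    failed = 0
    for _ in range(n_boot):
        draw = rng.integers(0, data.n, size=data.n)
        weights = np.bincount(draw, minlength=data.n)
        nll_b = _nll_factory(data, lay, weights=weights)
        res = _minimize_preconditioned(nll_b, fit._free, H, boot_cfg)
        if not res.success:
            failed += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            estimates.append(fun(_unpack(_from_free(res.x, lay), J), instrument, k))
    if n_boot and failed > 0.2 * n_boot:
        warnings.warn(f"{failed}/{n_boot} bootstrap replicates failed to converge",
                      stacklevel=2)
    if estimates:
        lo, hi = np.percentile(estimates, [2.5, 97.5])
    else:
        lo, hi = delta_low, delta_high
    lo, hi = min(lo, point), max(hi, point)   # interval always brackets the estimate
    return MetricInterval(
        metric=metric, instrument=instrument, k=int(k), estimate=point,
        ci_low=float(lo), ci_high=float(hi),
        delta_low=float(delta_low), delta_high=float(delta_high),
        n_boot=len(estimates), n_boot_failed=failed,
    )


# ---------------------------------------------------------------------------
# subgroup fits
# ---------------------------------------------------------------------------

_STRATIFIERS = {
    "sex": (lambda c: c.sex == 0, "men", "women"),
    "age": (lambda c: c.age < 40, "age<40", "age>=40"),
    "bmi": (lambda c: c.bmi < 25, "bmi<25", "bmi>=25"),
}


def fit_subgroups(cohort: CohortMeasurements, stratifier: str,
                  min_size: int = 20,
                  config: FitConfig | None = None) -> dict[str, FitResult]:
    """Independent fits in the two strata of a binary stratifier.

    ``stratifier`` is one of ``sex`` (men vs women), ``age`` (<40 vs >=40
    years) or ``bmi`` (<25 vs >=25).  Strata partition the participants with
    a recorded stratifier value; strata below ``min_size`` are skipped with
    a warning.
    """
    if stratifier not in _STRATIFIERS:
        raise ValueError(f"stratifier must be one of {sorted(_STRATIFIERS)}")
    rule, name_low, name_high = _STRATIFIERS[stratifier]
    low = rule(cohort)
    covariate = {"sex": cohort.sex, "age": cohort.age, "bmi": cohort.bmi}[stratifier]
    known = np.isfinite(np.asarray(covariate, dtype=float))
    results: dict[str, FitResult] = {}
    for name, mask in ((name_low, low & known), (name_high, ~low & known)):
        n = int(mask.sum())
        if n < min_size:
            warnings.warn(
                f"stratum {name!r} has {n} participants (< {min_size}); skipped",
                stacklevel=2)
            continue
        results[name] = fit_model(cohort.subset(mask), cohort.design, config)
    return results
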