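"""End-to-end orchestration and publication-style tables.

Builds three kinds of output per nutrient:

* geometric-mean tables (tool vs biomarker, first occasion);
* single-administration validity: attenuation factor, correlation with true
  intake, 95% CIs, and the Bland-Altman mean percentage difference of each
  self-report tool against its biomarker;
* repeat-administration validity for the mean of k = 1..K administrations
  of the questionnaire.

Values are carried at full precision and rounded (half-up, two decimals,
the convention of published validity tables) only when rendered to disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomarkers
from .estimation import (
    CohortMeasurements,
    FitConfig,
    FitResult,
    fit_model,
    fit_subgroups,
    metric_uncertainty,
)
from .model import ExtrapolationInput, extrapolate_from_pair
from .simulate import SimulationScenario, generate_cohort, generate_raw_records, write_table

__all__ = [
    "ValidationMetrics",
    "round_half_up",
    "extrapolation_table",
    "geometric_means_table",
    "validity_tables",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.425 -> 0.43), matching printed tables."""
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ValidationMetrics:
    """One row of a validity table: metrics for (nutrient, instrument, k)."""

    nutrient: str
    instrument: str
    k: int
    attenuation: float
    attenuation_low: float
    attenuation_high: float
    correlation: float
    correlation_low: float
    correlation_high: float
    mean_pct_difference: float | None = None
    mean_pct_low: float | None = None
    mean_pct_high: float | None = None
    n: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for point, lo, hi in ((self.attenuation, self.attenuation_low, self.attenuation_high),
                              (self.correlation, self.correlation_low, self.correlation_high)):
            if np.isfinite(lo) and np.isfinite(hi) and not (lo <= point <= hi):
                raise ValueError("confidence interval must bracket the point estimate")


def extrapolation_table(lambda1: float, lambda2: float, rho1: float,
                        k_max: int = 5) -> pd.DataFrame:
    """Predicted (lambda_k, rho_k) for k = 1..k_max from printed inputs.

    Returns full-precision columns plus two-decimal rendered columns.
    """
    inp = ExtrapolationInput(lambda1, lambda2, rho1)
    rows = []
    for k in range(1, k_max + 1):
        lam, rho = extrapolate_from_pair(inp, k)
        rows.append({
            "k": k,
            "attenuation": lam,
            "correlation": rho,
            "attenuation_2dp": round_half_up(lam),
            "correlation_2dp": round_half_up(rho),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# table builders
# ---------------------------------------------------------------------------

def geometric_means_table(cohorts: dict[str, CohortMeasurements],
                          occasion: int = 1) -> pd.DataFrame:
    """Geometric mean (95% CI) of each instrument at one occasion per nutrient."""
    rows = []
    for nutrient in sorted(cohorts):
        c = cohorts[nutrient]
        J = c.design.n_occasions
        for inst, off in (("webq", 0), ("recall", J), ("biomarker", 2 * J)):
            col = c.values[:, off + occasion - 1]
            vals = np.exp(col[np.isfinite(col)])
            if vals.size == 0:
                continue
            gm, (lo, hi) = biomarkers.geometric_mean_ci(vals)
            rows.append({"nutrient": nutrient, "instrument": inst,
                         "n": int(vals.size), "geometric_mean": gm,
                         "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows, columns=["nutrient", "instrument", "n",
                                       "geometric_mean", "ci_low", "ci_high"])


def _bland_altman(cohort: CohortMeasurements, instrument: str) -> tuple[float, float, float]:
    """Mean % difference of a tool vs the biomarker with a t-based 95% CI."""
    J = cohort.design.n_occasions
    off = {"webq": 0, "recall": J}[instrument]
    with np.errstate(invalid="ignore"):
        tool = np.nanmean(cohort.values[:, off:off + J], axis=1)
        ref = np.nanmean(cohort.values[:, 2 * J:], axis=1)
    point = biomarkers.mean_percent_difference(tool, ref)
    ok = np.isfinite(tool) & np.isfinite(ref)
    d = tool[ok] - ref[ok]
    if d.size > 1:
        from scipy import stats
        se = d.std(ddof=1) / np.sqrt(d.size)
        t = stats.t.ppf(0.975, df=d.size - 1)
        lo = 100.0 * (np.exp(d.mean() - t * se) - 1.0)
        hi = 100.0 * (np.exp(d.mean() + t * se) - 1.0)
    else:
        lo = hi = point
    return point, lo, hi


def validity_tables(
    fits: dict[str, FitResult],
    k_max: int = 5,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single- and repeat-administration validity tables from fitted models.

    Returns (single, repeats): ``single`` has one row per nutrient and
    self-report tool at k = 1 including the Bland-Altman mean % difference;
    ``repeats`` covers the questionnaire for k = 1..k_max.  Bootstrap CIs
    when ``n_boot`` > 0, otherwise delta-method CIs.
    """
    single_rows, repeat_rows = [], []
    for nutrient in sorted(fits):
        fit = fits[nutrient]

        def interval(inst: str, k: int) -> tuple[tuple, tuple]:
            lam = metric_uncertainty(fit, "attenuation", k, inst,
                                     n_boot=n_boot, seed=seed)
            rho = metric_uncertainty(fit, "correlation", k, inst,
                                     n_boot=n_boot, seed=seed)
            return ((lam.estimate, lam.ci_low, lam.ci_high),
                    (rho.estimate, rho.ci_low, rho.ci_high))

        for inst in ("webq", "recall"):
            (lam, llo, lhi), (rho, rlo, rhi) = interval(inst, 1)
            diff, dlo, dhi = _bland_altman(fit._cohort, inst)
            single_rows.append(ValidationMetrics(
                nutrient=nutrient, instrument=inst, k=1,
                attenuation=lam, attenuation_low=llo, attenuation_high=lhi,
                correlation=rho, correlation_low=rlo, correlation_high=rhi,
                mean_pct_difference=diff, mean_pct_low=dlo, mean_pct_high=dhi,
                n=fit.n_participants))
        for k in range(1, k_max + 1):
            (lam, llo, lhi), (rho, rlo, rhi) = interval("webq", k)
            repeat_rows.append(ValidationMetrics(
                nutrient=nutrient, instrument="webq", k=k,
                attenuation=lam, attenuation_low=llo, attenuation_high=lhi,
                correlation=rho, correlation_low=rlo, correlation_high=rhi,
                n=fit.n_participants))
    cols = list(ValidationMetrics.__dataclass_fields__)
    single = pd.DataFrame([asdict(r) for r in single_rows], columns=cols)
    repeats = pd.DataFrame([asdict(r) for r in repeat_rows], columns=cols)
    repeats = repeats.drop(columns=["mean_pct_difference", "mean_pct_low", "mean_pct_high"])
    return single, repeats


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "seed": 0,
    "nutrients": ["protein", "potassium", "sugars", "energy"],
    "k_max": 5,
    "bootstrap_b": 200,
    "strata": [],
    "paba_mode": "main",
    "scenario": {},
    "out_dir": "dietval_run",
}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    out = dict(_DEFAULT_CONFIG)
    out.update(config or {})
    return out


def _render(df: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: round_half_up(v, ndigits))
    return out


def run_pipeline(config, out_dir=None, seed: int | None = None) -> dict:
    """Simulate (or load), prepare, fit, and render all validity tables.

    ``config`` is a mapping or a YAML path following the documented schema.
    Output is deterministic given the config and seed: tables are written as
    TSV with a seed/scenario header, fitted parameters as JSON, and a run
    manifest records the seed, config hash and package version.
    Partial fit failures skip the nutrient and are reported in the manifest.
    """
    cfg = _load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    out_path = Path(cfg["out_dir"])
    out_path.mkdir(parents=True, exist_ok=True)

    scenario_kwargs = dict(cfg.get("scenario") or {})
    scenario = SimulationScenario(seed=cfg["seed"], **scenario_kwargs)
    scenario.nutrients = {k: v for k, v in scenario.nutrients.items()
                          if k in set(cfg["nutrients"])}
    sim = generate_cohort(scenario)

    urine, energy = generate_raw_records(scenario, sim)
    prepared = biomarkers.prepare_records(urine, energy, mode=cfg["paba_mode"])

    fits: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    for nutrient, cohort in sim.cohorts.items():
        try:
            fit = fit_model(cohort)
            if not fit.converged:
                raise RuntimeError(f"optimizer did not converge: {fit.message}")
            fits[nutrient] = fit
        except Exception as exc:   # continue other nutrients
            logger.error("fit failed for %s: %s", nutrient, exc)
            failures[nutrient] = str(exc)

    table2 = geometric_means_table(sim.cohorts)
    single, repeats = validity_tables(fits, k_max=cfg["k_max"],
                                      n_boot=cfg["bootstrap_b"], seed=cfg["seed"])

    subgroup_tables: dict[str, pd.DataFrame] = {}
    for strat in cfg["strata"]:
        rows = []
        for nutrient, cohort in sim.cohorts.items():
            for name, sfit in fit_subgroups(cohort, strat).items():
                rows.append({
                    "nutrient": nutrient, "stratum": name,
                    "n": sfit.n_participants,
                    "attenuation": sfit.attenuation(1, "webq"),
                    "correlation": sfit.correlation(1, "webq"),
                })
        subgroup_tables[strat] = pd.DataFrame(
            rows, columns=["nutrient", "stratum", "n", "attenuation", "correlation"])

    outputs = {}
    tables = {
        "table2_geometric_means.tsv": _render(table2),
        "table3_single_administration.tsv": _render(single),
        "table4_repeat_administrations.tsv": _render(repeats),
        "prepared_biomarkers.tsv": prepared,
    }
    for strat, df in subgroup_tables.items():
        tables[f"subgroup_{strat}.tsv"] = _render(df)
    for fname, df in tables.items():
        write_table(out_path / fname, df, scenario)
        outputs[fname] = str(out_path / fname)

    params_file = out_path / "fitted_parameters.json"
    params_file.write_text(json.dumps(
        {n: f.to_dict(k_max=cfg["k_max"]) for n, f in fits.items()},
        indent=1, sort_keys=True))
    outputs["fitted_parameters.json"] = str(params_file)

    try:
        version = metadata.version("dietval")
    except metadata.PackageNotFoundError:
        version = "unknown"
    hashed_cfg = {k: v for k, v in cfg.items() if k != "out_dir"}
    manifest = {
        "seed": cfg["seed"],
        "config_hash": hashlib.sha256(
            json.dumps(hashed_cfg, sort_keys=True, default=str).encode()).hexdigest()[:16],
        "scenario_hash": scenario.hash(),
        "package_version": version,
        "outputs": sorted(outputs),
        "fit_failures": failures,
    }
    (out_path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return {"tables": {k.removesuffix('.tsv'): v for k, v in tables.items()},
            "fits": fits, "failures": failures, "manifest": manifest,
            "outputs": outputs, "simulated": sim}
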