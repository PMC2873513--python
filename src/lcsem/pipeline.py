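"""End-to-end orchestration of the sex-stratified analysis.

Per sex: the single-wave measurement models (baseline and follow-up), the
constrained latent-change measurement model, the longitudinal structural
model with fit indices, the effect decomposition with bootstrap intervals,
and the per-indicator regression comparison.  Results are emitted as a
machine-readable JSON bundle plus human-readable text tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import (
    ANALYSIS_VARIABLES,
    AnalysisDataset,
    CovarianceSummary,
    RecordTable,
    derive_analysis_dataset,
    ks_normality,
    load_records,
    sample_covariance,
)
from .effects import DEFAULT_BOOTSTRAP_B, bootstrap_effects, decompose
from .engine import FittedModel, OptimOptions, fit_ml, standardize
from .fit_indices import fit_report
from .models import (
    BASELINE_INDICATORS,
    CHANGE_INDICATORS,
    INDICATORS,
    latent_change_measurement_spec,
    longitudinal_structural_spec,
    single_wave_measurement_spec,
)
from .simulate import GeneratorParams, default_params, simulate

logger = logging.getLogger("lcsem")

__all__ = ["RunConfig", "RegressionComparison", "run_full_analysis", "ols_comparison"]


@dataclass
class RunConfig:
    input_path: str | None = None  # delimited records; None -> simulate
    column_map: dict[str, str] | None = None
    sep: str = ","
    sexes: tuple[str, ...] = ("male", "female")
    bootstrap_b: int = DEFAULT_BOOTSTRAP_B
    seed: int = 0
    ci_level: float = 0.95
    rmsea_ci_level: float = 0.95
    out_dir: str | None = None
    free_residual_cov: bool = False
    simulate_n: int | None = None  # override generator sample sizes

    def __post_init__(self) -> None:
        if self.input_path is not None and not Path(self.input_path).exists():
            raise FileNotFoundError(self.input_path)
        if self.bootstrap_b and self.bootstrap_b < 100:
            raise ValueError("bootstrap needs at least 100 replicates (0 disables)")


@dataclass
class RegressionComparison:
    """Per-indicator OLS rows plus the latent-model counterpart."""

    sex: str
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def ols_comparison(
    ds: AnalysisDataset, latent_fit: FittedModel | None = None
) -> RegressionComparison:
    """Regress restraint change on each baseline indicator separately.

    Each row is the OLS coefficient (and SE) of ``d_crs`` on one baseline
    indicator, adjusted for age and baseline restraint — all on the same
    transformed analysis scale the structural model uses, so the latent
    counterpart (the adiposity -> restraint-change coefficient) is directly
    comparable.
    """
    y = ds.column("d_crs")
    rows = []
    for ind in BASELINE_INDICATORS:
        X = np.column_stack([ds.column(ind), ds.column("age0"), ds.column("crs0")])
        Xc = sm.add_constant(X)
        rank = np.linalg.matrix_rank(Xc)
        if rank < Xc.shape[1]:
            raise ValueError(f"collinear design for indicator {ind}")
        res = sm.OLS(y, Xc).fit()
        rows.append(
            {
                "kind": "manifest",
                "variable": ind,
                "coefficient": float(res.params[1]),
                "se": float(res.bse[1]),
                "t": float(res.tvalues[1]),
                "intercept": float(res.params[0]),
            }
        )
    if latent_fit is not None:
        est = latent_fit.estimates.get("beta_dcrs_A0")
        se = latent_fit.se.get("beta_dcrs_A0")
        rows.append(
            {
                "kind": "latent",
                "variable": "A0",
                "coefficient": float(est),
                "se": float(se) if se else float("nan"),
                "t": float(est / se) if se else float("nan"),
                "intercept": 0.0,
            }
        )
    return RegressionComparison(sex=ds.sex, rows=rows)


def _subcov(cov: CovarianceSummary, names: list[str]) -> CovarianceSummary:
    idx = [cov.labels.index(v) for v in names]
    return CovarianceSummary(labels=list(names), S=cov.S[np.ix_(idx, idx)], n=cov.n)


def _wave1_covariance(ds: AnalysisDataset) -> CovarianceSummary:
    """Covariance of the follow-up indicators reconstructed as baseline + change."""
    base = np.column_stack([ds.column(v) for v in BASELINE_INDICATORS])
    chg = np.column_stack([ds.column(v) for v in CHANGE_INDICATORS])
    w1 = base + chg
    w1 = w1 - w1.mean(axis=0)
    S = np.cov(w1, rowvar=False, ddof=1)
    names = [v.replace("0", "1") if v == "pbf0" else v[:-1] + "1" for v in BASELINE_INDICATORS]
    return CovarianceSummary(labels=names, S=0.5 * (S + S.T), n=ds.n)


def _loading_table(fit: FittedModel) -> list[dict]:
    std = standardize(fit)
    rows = []
    for stem, b, c in zip(INDICATORS, BASELINE_INDICATORS, CHANGE_INDICATORS):
        lab = f"lambda_{stem}"
        est = 1.0 if stem == "pbf" else fit.estimates[lab]
        se = None if stem == "pbf" else fit.se.get(lab)
        rows.append(
            {
                "indicator": stem,
                "estimate": est,
                "se": se,
                "std_baseline": std.coefficients.get(("A0", b)),
                "std_change": std.coefficients.get(("A1", c)),
                "r2_baseline": std.r_squared.get(b),
                "r2_change": std.r_squared.get(c),
            }
        )
    return rows


def _coef_table(fit: FittedModel) -> list[dict]:
    from .models import STRUCTURAL_LABELS

    rows = []
    for (outcome, pred), lab in STRUCTURAL_LABELS.items():
        est = fit.estimates[lab]
        se = fit.se.get(lab, float("nan"))
        rows.append(
            {
                "outcome": outcome,
                "explanatory": pred,
                "estimate": est,
                "se": se,
                "t": est / se if se and se > 0 else float("nan"),
                "significant": bool(se and abs(est / se) > 1.96),
            }
        )
    return rows


def _analyze_sex(
    records: RecordTable, sex: str, config: RunConfig, seed: int
) -> dict:
    ds = derive_analysis_dataset(records, sex)
    cov = sample_covariance(ds)
    opts = OptimOptions(restart_seed=seed)
    out: dict = {"sex": sex, "n": ds.n, "seed": seed}

    # normality of the transformed analysis variables
    out["normality"] = {
        v: vars(ks_normality(ds.column(v), variable=v, transformed=v.startswith(("log", "d_log"))))
        for v in ANALYSIS_VARIABLES
        if ds.n >= 20
    }

    # 1. single-wave measurement models, baseline and follow-up
    spec0 = single_wave_measurement_spec()
    fit0 = fit_ml(spec0, _subcov(cov, BASELINE_INDICATORS), opts)
    out["measurement_baseline"] = {
        "fit": fit_report(fit0, _subcov(cov, BASELINE_INDICATORS), rmsea_ci_level=config.rmsea_ci_level).to_dict(),
        "r2": standardize(fit0).r_squared,
    }
    cov1 = _wave1_covariance(ds)
    fit1 = fit_ml(single_wave_measurement_spec(indicators=cov1.labels), cov1, opts)
    out["measurement_followup"] = {
        "fit": fit_report(fit1, cov1, rmsea_ci_level=config.rmsea_ci_level).to_dict(),
        "r2": standardize(fit1).r_squared,
    }

    # 2. constrained latent-change measurement model
    lc_spec = latent_change_measurement_spec(free_residual_cov=config.free_residual_cov)
    lc_cov = _subcov(cov, BASELINE_INDICATORS + CHANGE_INDICATORS)
    lc_fit = fit_ml(lc_spec, lc_cov, opts)
    out["latent_change"] = {
        "fit": fit_report(lc_fit, lc_cov, rmsea_ci_level=config.rmsea_ci_level).to_dict(),
        "loadings": _loading_table(lc_fit),
    }

    # 3. longitudinal structural model
    spec = longitudinal_structural_spec(free_residual_cov=config.free_residual_cov)
    fit = fit_ml(spec, cov, opts)
    out["longitudinal"] = {
        "fit": fit_report(fit, cov, rmsea_ci_level=config.rmsea_ci_level).to_dict(),
        "loadings": _loading_table(fit),
        "coefficients": _coef_table(fit),
        "converged": fit.converged,
    }

    # 4. effect decomposition (+ bootstrap)
    dec = decompose(fit, spec, "crs0", "A1")
    eff = {
        "direct": dec.direct,
        "indirects": dec.indirects,
        "extra_paths": dec.extra_paths,
        "partial": dec.partial,
        "total": dec.total,
        "total_all_paths": dec.total_all_paths,
    }
    if config.bootstrap_b:
        bs = bootstrap_effects(
            records,
            sex,
            spec,
            B=config.bootstrap_b,
            seed=seed + 1,
            ci_level=config.ci_level,
        )
        eff["bootstrap"] = {
            "B": bs.B,
            "n_failed": bs.n_failed,
            "se": bs.se,
            "ci_normal": {k: list(v) for k, v in bs.ci_normal.items()},
            "ci_percentile": {k: list(v) for k, v in bs.ci_percentile.items()},
            "normality_p": bs.normality,
        }
    out["effects"] = eff

    # 5. per-indicator regression comparison
    out["regression_comparison"] = ols_comparison(ds, latent_fit=fit).rows
    return out


def _render_text(bundle: dict) -> str:
    lines = []
    for sex, res in bundle["by_sex"].items():
        if "error" in res:
            lines.append(f"== {sex}: FAILED: {res['error']}")
            continue
        lines.append(f"== {sex} (n = {res['n']}) ==")
        fi = res["longitudinal"]["fit"]
        lo, hi = fi["rmsea_ci"]
        lo_s = "." if lo == 0 else f"{lo:.2f}"
        lines.append(
            f"longitudinal model: chi2({fi['df']}) = {fi['chi_square']:.1f}, "
            f"RMSEA {fi['rmsea']:.2f} [{lo_s} ; {hi:.2f}], NFI {fi['nfi']:.3f}"
        )
        lines.append("loadings (estimate [se] | std baseline / std change):")
        for r in res["longitudinal"]["loadings"]:
            se = f"{r['se']:.5f}" if r["se"] is not None else "fixed"
            lines.append(
                f"  {r['indicator']:<13} {r['estimate']:.3f} [{se}] | "
                f"{r['std_baseline']:.3f} / {r['std_change']:.3f}"
            )
        lines.append("structural coefficients (outcome <- explanatory):")
        for r in res["longitudinal"]["coefficients"]:
            star = "*" if r["significant"] else " "
            lines.append(
                f"  {r['outcome']:<6} <- {r['explanatory']:<6} "
                f"{r['estimate']:8.3f} ({r['se']:.3f}) t = {r['t']:.2f}{star}"
            )
        eff = res["effects"]
        lines.append("effects of baseline CRS on adiposity change:")
        lines.append(f"  direct            {eff['direct']:+.4f}")
        for k, v in eff["indirects"].items():
            lines.append(f"  {k:<17} {v:+.4f}")
        lines.append(f"  partial           {eff['partial']:+.4f}")
        lines.append(f"  total             {eff['total']:+.4f}")
        lines.append(f"  total (all paths) {eff['total_all_paths']:+.4f}")
        lines.append("")
    return "\n".join(lines)


def run_full_analysis(
    config: RunConfig, params: dict[str, GeneratorParams] | None = None
) -> dict:
    """Run the whole analysis for every configured sex; returns the bundle.

    Input records come from ``config.input_path`` or, when absent, from the
    synthetic generator (``params`` overrides the published-cohort defaults).
    A hard error in one sex's branch is recorded and the other sex continues.
    """
    if config.input_path is not None:
        records = load_records(config.input_path, config.column_map, sep=config.sep)
    else:
        frames = []
        for i, sex in enumerate(config.sexes):
            p = (params or {}).get(sex) or default_params(sex)
            tab = simulate(p, seed=config.seed + 1000 * i, n=config.simulate_n)
            frames.append(tab.frame)
        records = RecordTable(frame=pd.concat(frames, ignore_index=True))
    logger.info("analysis input: %d records (%d dropped)", len(records), records.n_dropped)

    bundle: dict = {"config": {k: v for k, v in vars(config).items()}, "by_sex": {}}
    for i, sex in enumerate(config.sexes):
        try:
            bundle["by_sex"][sex] = _analyze_sex(records, sex, config, config.seed + 10 * i)
        except Exception as err:
            logger.error("analysis failed for sex=%s: %s", sex, err)
            bundle["by_sex"][sex] = {"error": str(err)}
    bundle["text_report"] = _render_text(bundle)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(bundle, fh, indent=1, default=_jsonable)
        (out / "report.txt").write_text(bundle["text_report"])
    return bundle


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return list(obj)
    return str(obj)
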