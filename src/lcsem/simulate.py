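"""Synthetic two-wave cohorts generated from the longitudinal model itself.

The generator draws exogenous age and baseline restraint from a bivariate
normal, propagates them through the structural equations (baseline adiposity,
restraint change, adiposity change) with normal residuals, emits the eight
indicators through the shared-loading measurement model, and finally
un-centers and exponentiates the logged indicators to produce raw-scale
records in the same layout ``load_records`` consumes.

Default ground truth per sex reproduces the published cohort summaries: the
sample sizes, age and restraint means/SDs, the constrained loadings and the
nine structural coefficients.  Residual scales are *derived*, not invented:
baseline indicator residuals come from the printed indicator R-squared and
the raw-scale SDs (log-scale variances via lognormal moment matching),
latent residuals are solved so the implied latent variances hit documented
targets, and change-side indicator residuals are backed out of the printed
change-standardized loadings.  Each derived value carries a note in
``GeneratorParams.derivation`` for auditability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CANONICAL_COLUMNS, RecordTable
from .engine import implied_covariance
from .models import INDICATORS, STRUCTURAL_LABELS, longitudinal_structural_spec

__all__ = [
    "GeneratorParams",
    "default_params",
    "simulate",
    "recovery_study",
    "TABLE_MEANS_SDS",
    "LOADINGS",
    "STRUCTURAL_COEFFICIENTS",
]

# ---------------------------------------------------------------------------
# Published cohort constants (generative defaults)
# ---------------------------------------------------------------------------

#: baseline raw-scale mean (SD) per sex: age, the four indicators, restraint
TABLE_MEANS_SDS = {
    "male": {
        "n": 201,
        "age": (44.0, 4.9),
        "pbf": (23.0, 6.2),
        "bmi": (25.7, 3.4),
        "skinfold": (58.6, 25.2),
        "waist": (91.6, 10.4),
        "crs": (21.8, 18.2),
    },
    "female": {
        "n": 256,
        "age": (42.4, 4.5),
        "pbf": (33.2, 7.1),
        "bmi": (24.7, 4.6),
        "skinfold": (75.0, 32.2),
        "waist": (79.4, 11.7),
        "crs": (39.6, 21.4),
    },
}

#: constrained loadings (adiposity scale = percent body fat)
LOADINGS = {
    "male": {"pbf": 1.0, "log_bmi": 0.022, "log_skinfold": 0.061, "log_waist": 0.017},
    "female": {"pbf": 1.0, "log_bmi": 0.024, "log_skinfold": 0.055, "log_waist": 0.019},
}

#: structural coefficients, keyed by the model's parameter labels
STRUCTURAL_COEFFICIENTS = {
    "male": {
        "gamma_A0_age": 0.195,
        "gamma_A0_crs0": 0.084,
        "beta_dcrs_A0": 0.577,
        "gamma_dcrs_age": 0.392,
        "gamma_dcrs_crs0": -0.342,
        "beta_A1_A0": -0.044,
        "gamma_A1_age": -0.018,
        "gamma_A1_crs0": 0.012,
        "beta_A1_dcrs": -0.011,
    },
    "female": {
        "gamma_A0_age": 0.254,
        "gamma_A0_crs0": 0.051,
        "beta_dcrs_A0": 0.438,
        "gamma_dcrs_age": 0.023,
        "gamma_dcrs_crs0": -0.286,
        "beta_A1_A0": -0.024,
        "gamma_A1_age": 0.038,
        "gamma_A1_crs0": -0.010,
        "beta_A1_dcrs": -0.014,
    },
}

#: baseline indicator R-squared (share of variance explained by adiposity)
_R2_BASELINE = {
    "male": {"pbf": 0.90, "log_bmi": 0.96, "log_skinfold": 0.65, "log_waist": 0.83},
    "female": {"pbf": 0.95, "log_bmi": 0.96, "log_skinfold": 0.87, "log_waist": 0.94},
}

#: change-standardized loadings (correlation of each change indicator with
#: latent adiposity change)
_STD_CHANGE = {
    "male": {"pbf": 0.673, "log_bmi": 0.942, "log_skinfold": 0.357, "log_waist": 0.546},
    "female": {"pbf": 0.603, "log_bmi": 0.996, "log_skinfold": 0.558, "log_waist": 0.647},
}

#: target SD of latent adiposity change (percent-body-fat units over 2 years)
_SD_A1_TARGET = 2.0
#: target SD of the 2-year restraint-score change
_SD_DCRS_TARGET = 12.0


@dataclass
class GeneratorParams:
    """Ground truth for one sex group's synthetic cohort."""

    sex: str
    n: int
    age_mean: float
    age_sd: float
    crs0_mean: float
    crs0_sd: float
    age_crs_corr: float
    structural: dict[str, float]
    zeta0_sd: float
    zeta3_sd: float
    zeta1_sd: float
    loadings: dict[str, float]
    eps_sd_baseline: dict[str, float]
    eps_sd_change: dict[str, float]
    anchor_means: dict[str, float]  # analysis-scale location of each baseline indicator
    seed: int = 0
    derivation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sds = [self.age_sd, self.crs0_sd, self.zeta0_sd, self.zeta3_sd, self.zeta1_sd]
        sds += list(self.eps_sd_baseline.values()) + list(self.eps_sd_change.values())
        if any(s <= 0 for s in sds):
            raise ValueError("all SDs must be strictly positive")
        if not abs(self.age_crs_corr) < 1:
            raise ValueError("|correlation| must be < 1")
        if self.loadings["pbf"] != 1.0:
            raise ValueError("the percent-body-fat loading fixes the scale at 1")

    # -- mapping onto the longitudinal model's parameter labels ------------
    def to_theta(self) -> dict[str, float]:
        """Free-parameter values of the longitudinal spec implied by truth."""
        theta: dict[str, float] = {}
        for stem in INDICATORS[1:]:
            theta[f"lambda_{stem}"] = self.loadings[stem]
        theta.update(self.structural)
        base = ["pbf0", "log_bmi0", "log_skinfold0", "log_waist0"]
        chg = ["d_pbf", "d_log_bmi", "d_log_skinfold", "d_log_waist"]
        for v, stem in zip(base, INDICATORS):
            theta[f"eps_{v}"] = self.eps_sd_baseline[stem] ** 2
        for v, stem in zip(chg, INDICATORS):
            theta[f"eps_{v}"] = self.eps_sd_change[stem] ** 2
        theta["zeta0"] = self.zeta0_sd**2
        theta["zeta3"] = self.zeta3_sd**2
        theta["zeta1"] = self.zeta1_sd**2
        theta["var_age"] = self.age_sd**2
        theta["var_crs0"] = self.crs0_sd**2
        theta["cov_age_crs0"] = self.age_crs_corr * self.age_sd * self.crs0_sd
        return theta

    def implied_analysis_covariance(self) -> np.ndarray:
        """Model-implied covariance of the 11 analysis variables at truth."""
        return implied_covariance(longitudinal_structural_spec(), self.to_theta())

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        return cls(**d)

    @classmethod
    def load(cls, path) -> "GeneratorParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _log_scale_var(mean: float, sd: float) -> float:
    """Variance of ln X for a lognormal matched to raw mean/SD."""
    return math.log1p((sd / mean) ** 2)


def default_params(sex: str, *, age_crs_corr: float = 0.0, seed: int = 0) -> GeneratorParams:
    """Published-cohort defaults for one sex, residual scales derived in code.

    ``age_crs_corr`` defaults to 0 because no age-restraint covariance is
    published; it is configurable.
    """
    if sex not in TABLE_MEANS_SDS:
        raise ValueError("sex must be 'male' or 'female'")
    t1 = TABLE_MEANS_SDS[sex]
    lam = LOADINGS[sex]
    coef = STRUCTURAL_COEFFICIENTS[sex]
    r2 = _R2_BASELINE[sex]
    stdc = _STD_CHANGE[sex]
    notes: dict[str, str] = {}

    age_mean, age_sd = t1["age"]
    crs_mean, crs_sd = t1["crs"]

    # analysis-scale variance of each baseline indicator
    varlog = {"pbf": t1["pbf"][1] ** 2}
    for stem, key in (("log_bmi", "bmi"), ("log_skinfold", "skinfold"), ("log_waist", "waist")):
        varlog[stem] = _log_scale_var(*t1[key])
        notes[f"var_{stem}"] = (
            f"log-scale variance ln(1+(sd/mean)^2) from raw {key} mean/SD "
            f"{t1[key][0]}/{t1[key][1]}"
        )

    # latent baseline variance from the scaling indicator's R-squared
    var_a0 = r2["pbf"] * varlog["pbf"]
    notes["var_A0"] = (
        f"R2(pbf baseline) x var(pbf) = {r2['pbf']} x {varlog['pbf']:.4g} = {var_a0:.4g}"
    )

    # solve the latent residual variances sequentially so implied totals hit
    # their targets: exogenous block -> A0 -> d_crs -> A1
    cov_ac = age_crs_corr * age_sd * crs_sd
    sig = np.array([[age_sd**2, cov_ac], [cov_ac, crs_sd**2]])  # (age, crs0)

    def _extend(sig_in: np.ndarray, weights: np.ndarray, target_var: float, name: str) -> tuple[np.ndarray, float]:
        explained = float(weights @ sig_in @ weights)
        resid = target_var - explained
        if resid <= 0:
            raise ValueError(
                f"target variance for {name} ({target_var:.3g}) below the "
                f"explained part ({explained:.3g}); increase the target"
            )
        k = sig_in.shape[0]
        out = np.empty((k + 1, k + 1))
        out[:k, :k] = sig_in
        cross = sig_in @ weights
        out[:k, k] = cross
        out[k, :k] = cross
        out[k, k] = target_var
        notes[f"zeta_{name}"] = (
            f"residual var = target {target_var:.4g} - explained {explained:.4g}"
        )
        return out, math.sqrt(resid)

    # order grows as (age, crs0, A0, d_crs, A1)
    w_a0 = np.array([coef["gamma_A0_age"], coef["gamma_A0_crs0"]])
    sig, zeta0_sd = _extend(sig, w_a0, var_a0, "A0")
    w_dcrs = np.array([coef["gamma_dcrs_age"], coef["gamma_dcrs_crs0"], coef["beta_dcrs_A0"]])
    sig, zeta3_sd = _extend(sig, w_dcrs, _SD_DCRS_TARGET**2, "d_crs")
    w_a1 = np.array(
        [coef["gamma_A1_age"], coef["gamma_A1_crs0"], coef["beta_A1_A0"], coef["beta_A1_dcrs"]]
    )
    sig, zeta1_sd = _extend(sig, w_a1, _SD_A1_TARGET**2, "A1")
    var_a1 = _SD_A1_TARGET**2

    # indicator residuals
    eps_b = {}
    for stem in INDICATORS:
        eps_b[stem] = math.sqrt((1 - r2[stem]) * varlog[stem])
        notes[f"eps_{stem}_baseline"] = (
            f"(1 - R2 {r2[stem]}) x analysis-scale var {varlog[stem]:.4g}"
        )
    eps_c = {}
    for stem in INDICATORS:
        s = stdc[stem]
        eps_c[stem] = math.sqrt(lam[stem] ** 2 * var_a1 * (1 / s**2 - 1))
        notes[f"eps_{stem}_change"] = (
            f"lambda^2 var(A1) (1/std^2 - 1) with change-standardized loading {s}"
        )

    # analysis-scale anchors chosen so raw-scale means match the published
    # table: for a logged indicator E[X] = exp(mu + v/2), hence mu = ln m - v/2
    anchors = {"pbf": t1["pbf"][0]}
    for stem, key in (("log_bmi", "bmi"), ("log_skinfold", "skinfold"), ("log_waist", "waist")):
        v_implied = lam[stem] ** 2 * var_a0 + eps_b[stem] ** 2
        anchors[stem] = math.log(t1[key][0]) - 0.5 * v_implied
        notes[f"anchor_{stem}"] = (
            f"ln({t1[key][0]}) - implied log-scale var/2 so E[raw] matches the table"
        )

    return GeneratorParams(
        sex=sex,
        n=t1["n"],
        age_mean=age_mean,
        age_sd=age_sd,
        crs0_mean=crs_mean,
        crs0_sd=crs_sd,
        age_crs_corr=age_crs_corr,
        structural=dict(coef),
        zeta0_sd=zeta0_sd,
        zeta3_sd=zeta3_sd,
        zeta1_sd=zeta1_sd,
        loadings=dict(lam),
        eps_sd_baseline=eps_b,
        eps_sd_change=eps_c,
        anchor_means=anchors,
        seed=seed,
        derivation=notes,
    )


def simulate(params: GeneratorParams, seed: int | None = None, n: int | None = None) -> RecordTable:
    """Draw a raw-scale two-wave cohort of ``n`` subjects (default params.n).

    Out-of-range generated values (e.g. percent body fat above 100) are kept,
    not truncated, so the linear-normal model holds exactly; their count is
    recorded on the returned table as ``n_out_of_range``.
    """
    # fail early on inconsistent user-supplied parameters
    sig = params.implied_analysis_covariance()
    if np.linalg.eigvalsh(sig)[0] <= 0:
        raise ValueError("implied covariance not positive definite; check parameters")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = int(n if n is not None else params.n)

    cov_ac = params.age_crs_corr * params.age_sd * params.crs0_sd
    exo = rng.multivariate_normal(
        [0.0, 0.0], [[params.age_sd**2, cov_ac], [cov_ac, params.crs0_sd**2]], size=n
    )
    age_c, crs_c = exo[:, 0], exo[:, 1]
    c = params.structural
    a0 = c["gamma_A0_age"] * age_c + c["gamma_A0_crs0"] * crs_c + rng.normal(
        0, params.zeta0_sd, n
    )
    d_crs = (
        c["beta_dcrs_A0"] * a0
        + c["gamma_dcrs_age"] * age_c
        + c["gamma_dcrs_crs0"] * crs_c
        + rng.normal(0, params.zeta3_sd, n)
    )
    a1 = (
        c["beta_A1_A0"] * a0
        + c["gamma_A1_age"] * age_c
        + c["gamma_A1_crs0"] * crs_c
        + c["beta_A1_dcrs"] * d_crs
        + rng.normal(0, params.zeta1_sd, n)
    )

    base = {}
    change = {}
    for stem in INDICATORS:
        lam = params.loadings[stem]
        base[stem] = lam * a0 + rng.normal(0, params.eps_sd_baseline[stem], n)
        change[stem] = lam * a1 + rng.normal(0, params.eps_sd_change[stem], n)

    pbf0 = params.anchor_means["pbf"] + base["pbf"]
    pbf1 = pbf0 + change["pbf"]
    raw0 = {"pbf": pbf0}
    raw1 = {"pbf": pbf1}
    for stem, key in (("log_bmi", "bmi"), ("log_skinfold", "skinfold"), ("log_waist", "waist")):
        l0 = params.anchor_means[stem] + base[stem]
        raw0[key] = np.exp(l0)
        raw1[key] = np.exp(l0 + change[stem])
    crs0 = params.crs0_mean + crs_c
    df = pd.DataFrame(
        {
            "subject_id": [f"{params.sex[0]}{i:06d}" for i in range(n)],
            "sex": params.sex,
            "age0": params.age_mean + age_c,
            "pbf_0": raw0["pbf"],
            "bmi_0": raw0["bmi"],
            "skinfold_0": raw0["skinfold"],
            "waist_0": raw0["waist"],
            "crs_0": crs0,
            "pbf_1": raw1["pbf"],
            "bmi_1": raw1["bmi"],
            "skinfold_1": raw1["skinfold"],
            "waist_1": raw1["waist"],
            "crs_1": crs0 + d_crs,
        },
        columns=CANONICAL_COLUMNS,
    )
    table = RecordTable(frame=df)
    oob = int(
        ((df["pbf_0"] < 0) | (df["pbf_0"] > 100) | (df["pbf_1"] < 0) | (df["pbf_1"] > 100)).sum()
    )
    table.n_out_of_range = oob
    return table


def recovery_study(
    params: GeneratorParams,
    n_per_replicate: int,
    replicates: int,
    seed: int = 0,
    *,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Simulate -> preprocess -> fit, ``replicates`` times; summarize recovery.

    Returns one row per free parameter: truth, mean estimate, bias, median
    absolute error, empirical SD of the estimates, mean reported SE, and
    Wald-CI coverage of the truth.  Replicates whose fit fails are counted
    and tolerated up to 10%.
    """
    if replicates < 20:
        raise ValueError("need at least 20 replicates")
    from .data import derive_analysis_dataset, sample_covariance
    from .engine import OptimOptions, Z_95, fit_ml

    spec = longitudinal_structural_spec()
    truth = params.to_theta()
    z = Z_95 if abs(ci_level - 0.95) < 1e-12 else None
    if z is None:
        from scipy.stats import norm

        z = float(norm.ppf(0.5 + ci_level / 2))
    ests: dict[str, list[float]] = {k: [] for k in truth}
    ses: dict[str, list[float]] = {k: [] for k in truth}
    cover: dict[str, list[bool]] = {k: [] for k in truth}
    n_failed = 0
    child_seeds = np.random.SeedSequence(seed).spawn(replicates)
    for ss in child_seeds:
        rep_seed = int(ss.generate_state(1)[0] % (2**31))
        try:
            table = simulate(params, seed=rep_seed, n=n_per_replicate)
            ds = derive_analysis_dataset(table, params.sex)
            fit = fit_ml(spec, sample_covariance(ds), OptimOptions(n_restarts=2))
        except Exception:
            n_failed += 1
            continue
        if not fit.converged or not fit.se:
            n_failed += 1
            continue
        for k, v in truth.items():
            est, se = fit.estimates[k], fit.se.get(k, float("nan"))
            ests[k].append(est)
            ses[k].append(se)
            cover[k].append(abs(est - v) <= z * se)
    if n_failed > 0.10 * replicates:
        raise RuntimeError(f"{n_failed}/{replicates} replicates failed")
    rows = []
    for k, v in truth.items():
        e = np.asarray(ests[k])
        rows.append(
            {
                "parameter": k,
                "truth": v,
                "mean_estimate": e.mean(),
                "bias": e.mean() - v,
                "median_abs_error": float(np.median(np.abs(e - v))),
                "empirical_sd": e.std(ddof=1),
                "mean_se": float(np.mean(ses[k])),
                "coverage": float(np.mean(cover[k])),
                "n_converged": len(e),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_failed"] = n_failed
    out.attrs["replicates"] = replicates
    return out
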