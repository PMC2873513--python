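"""Loading, transforming and summarizing two-wave anthropometric records.

A record carries, per subject: sex, baseline age, and at two waves the four
adiposity indicators (percent body fat, BMI, sum of four skinfolds, waist
circumference) plus the cognitive restraint score (CRS, 0-100).  Analysis
works on eleven variables per sex group: the four baseline indicators (BMI,
skinfolds and waist on the log scale, percent body fat raw), their two-year
changes computed on the same analysis scale, baseline age, baseline CRS and
the CRS change.  All columns are centered within sex so the fitted models
need no intercepts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("lcsem")

__all__ = [
    "CANONICAL_COLUMNS",
    "ANALYSIS_VARIABLES",
    "RecordTable",
    "AnalysisDataset",
    "CovarianceSummary",
    "NormalityReport",
    "load_records",
    "derive_analysis_dataset",
    "sample_covariance",
    "ks_normality",
]

#: canonical raw-record columns, in order
CANONICAL_COLUMNS = [
    "subject_id",
    "sex",
    "age0",
    "pbf_0",
    "bmi_0",
    "skinfold_0",
    "waist_0",
    "crs_0",
    "pbf_1",
    "bmi_1",
    "skinfold_1",
    "waist_1",
    "crs_1",
]

_MEASUREMENTS = CANONICAL_COLUMNS[2:]

#: the eleven analysis variables, in fixed column order
ANALYSIS_VARIABLES = [
    "pbf0",
    "log_bmi0",
    "log_skinfold0",
    "log_waist0",
    "d_pbf",
    "d_log_bmi",
    "d_log_skinfold",
    "d_log_waist",
    "age0",
    "crs0",
    "d_crs",
]

#: indicators that are log-transformed before analysis
LOGGED = ("bmi", "skinfold", "waist")

_SEX_CODES = {
    "male": "male",
    "m": "male",
    "1": "male",
    "female": "female",
    "f": "female",
    "2": "female",
}


@dataclass
class RecordTable:
    """Validated per-subject records (one row per subject, both waves)."""

    frame: pd.DataFrame
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.frame)

    def by_sex(self, sex: str) -> pd.DataFrame:
        return self.frame[self.frame["sex"] == sex]


@dataclass
class AnalysisDataset:
    sex: str
    variable_names: list[str]
    data_matrix: np.ndarray  # n x 11, centered
    centering_means: dict[str, float]
    n: int
    subject_ids: list = field(default_factory=list)

    def column(self, name: str) -> np.ndarray:
        return self.data_matrix[:, self.variable_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data_matrix, columns=self.variable_names)

    def save(self, path) -> None:
        """Write the centered matrix as CSV plus a JSON sidecar of metadata."""
        path = str(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "sex": self.sex,
            "n": self.n,
            "variable_names": self.variable_names,
            "centering_means": self.centering_means,
        }
        with open(path + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)


@dataclass
class CovarianceSummary:
    labels: list[str]
    S: np.ndarray
    n: int

    def save(self, path) -> None:
        path = str(path)
        pd.DataFrame(self.S, index=self.labels, columns=self.labels).to_csv(path)
        with open(path + ".json", "w") as fh:
            json.dump({"labels": self.labels, "n": self.n}, fh, indent=1)


@dataclass
class NormalityReport:
    variable: str
    ks_statistic: float
    p_value: float
    transformed: bool = False


def _coerce_sex(value, row_label) -> str:
    key = str(value).strip().lower()
    if key not in _SEX_CODES:
        raise ValueError(f"unknown sex code {value!r} in row {row_label}")
    return _SEX_CODES[key]


def load_records(
    path,
    column_map: dict[str, str] | None = None,
    *,
    sep: str = ",",
) -> RecordTable:
    """Read a delimited text file of two-wave records.

    ``column_map`` binds canonical field names to the file's header names
    (canonical -> file column); omitted entries default to the canonical
    name itself.  Rows missing any analysis field are dropped listwise and
    counted; a malformed sex code or non-numeric measurement is a hard error
    naming the offending row.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    column_map = column_map or {}
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src not in raw.columns:
            if canon == "subject_id":
                continue  # synthesized below
            raise ValueError(f"required column {src!r} (for {canon!r}) not in file")
        rename[src] = canon
    df = raw.rename(columns=rename)
    if "subject_id" not in df.columns:
        df["subject_id"] = [f"s{i}" for i in range(len(df))]
    df = df[[c for c in CANONICAL_COLUMNS if c in df.columns]]

    # listwise deletion on missing fields, counted
    missing = df[_MEASUREMENTS + ["sex"]].isna() | (
        df[_MEASUREMENTS + ["sex"]].astype(str).apply(lambda s: s.str.strip() == "")
    )
    drop_mask = missing.any(axis=1)
    n_dropped = int(drop_mask.sum())
    if n_dropped:
        logger.info("load_records: dropped %d row(s) with missing fields", n_dropped)
    df = df[~drop_mask].copy()
    if df.empty:
        raise ValueError("no usable rows after listwise deletion")

    df["sex"] = [
        _coerce_sex(v, rid) for v, rid in zip(df["sex"], df["subject_id"])
    ]
    for col in _MEASUREMENTS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as err:
            raise ValueError(f"non-numeric value in column {col!r}: {err}") from err
    return RecordTable(frame=df.reset_index(drop=True), n_dropped=n_dropped)


def derive_analysis_dataset(
    records: RecordTable, sex: str, *, min_n: int = 12
) -> AnalysisDataset:
    """Build the centered 11-variable analysis matrix for one sex group.

    Percent body fat stays on the raw scale; BMI, skinfold sum and waist are
    log-transformed; change variables are differences on the analysis scale
    (so Delta log, not log of the difference); every column is centered
    within the sex group and the means are retained.
    """
    sub = records.by_sex(sex)
    if len(sub) < min_n:
        raise ValueError(f"need at least {min_n} records for sex={sex!r}, got {len(sub)}")
    cols = {}
    for name in LOGGED:
        for w in (0, 1):
            vals = sub[f"{name}_{w}"].to_numpy(dtype=float)
            bad = vals <= 0
            if bad.any():
                sid = sub["subject_id"].to_numpy()[bad][0]
                raise ValueError(
                    f"non-positive {name} at wave {w} for subject {sid!r}: cannot log-transform"
                )
    cols["pbf0"] = sub["pbf_0"].to_numpy(dtype=float)
    cols["log_bmi0"] = np.log(sub["bmi_0"].to_numpy(dtype=float))
    cols["log_skinfold0"] = np.log(sub["skinfold_0"].to_numpy(dtype=float))
    cols["log_waist0"] = np.log(sub["waist_0"].to_numpy(dtype=float))
    cols["d_pbf"] = sub["pbf_1"].to_numpy(dtype=float) - cols["pbf0"]
    cols["d_log_bmi"] = np.log(sub["bmi_1"].to_numpy(dtype=float)) - cols["log_bmi0"]
    cols["d_log_skinfold"] = (
        np.log(sub["skinfold_1"].to_numpy(dtype=float)) - cols["log_skinfold0"]
    )
    cols["d_log_waist"] = np.log(sub["waist_1"].to_numpy(dtype=float)) - cols["log_waist0"]
    cols["age0"] = sub["age0"].to_numpy(dtype=float)
    cols["crs0"] = sub["crs_0"].to_numpy(dtype=float)
    cols["d_crs"] = sub["crs_1"].to_numpy(dtype=float) - cols["crs0"]

    mat = np.column_stack([cols[v] for v in ANALYSIS_VARIABLES])
    means = mat.mean(axis=0)
    mat = mat - means
    return AnalysisDataset(
        sex=sex,
        variable_names=list(ANALYSIS_VARIABLES),
        data_matrix=mat,
        centering_means={v: float(m) for v, m in zip(ANALYSIS_VARIABLES, means)},
        n=mat.shape[0],
        subject_ids=list(sub["subject_id"]),
    )


def sample_covariance(ds: AnalysisDataset) -> CovarianceSummary:
    """Unbiased (n-1 divisor) covariance of the centered analysis columns."""
    if ds.n < 2:
        raise ValueError("need at least 2 rows for a covariance")
    S = np.cov(ds.data_matrix, rowvar=False, ddof=1)
    S = 0.5 * (S + S.T)
    w = np.linalg.eigvalsh(S)
    if w[0] <= 1e-12 * max(w[-1], 1.0):
        raise ValueError("singular covariance")
    return CovarianceSummary(labels=list(ds.variable_names), S=S, n=ds.n)


def ks_normality(
    values, *, variable: str = "", transformed: bool = False, lilliefors: bool = True
) -> NormalityReport:
    """One-sample Kolmogorov-Smirnov check against a fitted normal.

    Because the normal's mean and SD are estimated from the same data, the
    default p-value uses the Lilliefors correction; ``lilliefors=False``
    falls back to the plain asymptotic KS p-value (anti-conservative here).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant vector: normality test undefined")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm", pvalmethod="table")
    else:
        stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return NormalityReport(
        variable=variable,
        ks_statistic=float(stat),
        p_value=float(min(max(p, 0.0), 1.0)),
        transformed=transformed,
    )
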