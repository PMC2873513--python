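"""Direct/indirect effect decomposition and bootstrap inference.

Effects are read off the structural graph by path enumeration: the direct
effect of X on Y is the X -> Y edge coefficient, and the indirect effect
along a path is the product of its edge coefficients.  The headline
decomposition follows the reporting convention of mediation tables: the
named indirect effects are the single-mediator paths (X -> M -> Y), the
"partial" effect sums the direct effect with the indirect effect through
the behavioural mediator (CRS change) only, and "total" adds the remaining
single-mediator indirect.  The full path sum over ALL simple paths — which
in this graph also contains a two-mediator path — equals the (Y, X) entry
of the reduced-form total-effect matrix (I - A)^-1 and is reported
separately as ``total_all_paths``; see docs/methods.md for why the two
totals can differ.

Sampling variability of the composite effects is assessed by bootstrapping
subjects within sex (default 1,000 replicates): each replicate resamples the
records, reruns preprocessing, refits the structural model and recomputes
the decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .data import RecordTable, derive_analysis_dataset, ks_normality, sample_covariance
from .engine import Fixed, FittedModel, ModelSpec, OptimOptions, Z_95, fit_ml

__all__ = [
    "DEFAULT_BOOTSTRAP_B",
    "PathEffect",
    "EffectDecomposition",
    "BootstrapResult",
    "enumerate_paths",
    "path_product",
    "total_effect",
    "decompose",
    "bootstrap_effects",
    "expected_measurement_ratio",
]

#: bootstrap replicate count used throughout unless overridden
DEFAULT_BOOTSTRAP_B = 1000


@dataclass
class PathEffect:
    """One directed path and (optionally) its product-of-coefficients value."""

    edges: list[tuple[str, str]]
    coefficient_labels: list[str]
    value: float | None = None

    @property
    def mediators(self) -> tuple[str, ...]:
        return tuple(t for _, t in self.edges[:-1])

    def name(self) -> str:
        if not self.mediators:
            return "direct"
        return "via_" + "_".join(self.mediators)


def _structural_graph(spec: ModelSpec) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(spec.variables)
    for e in spec.edges:
        label = e.param.label if hasattr(e.param, "label") else None
        g.add_edge(e.source, e.target, label=label, fixed=(
            e.param.value if isinstance(e.param, Fixed) else None))
    return g


def enumerate_paths(spec: ModelSpec, source: str, target: str) -> list[PathEffect]:
    """All simple directed paths from source to target.

    Deterministic order: shortest first, ties broken lexicographically by
    node sequence.  ``source == target`` yields an empty list.
    """
    if source not in spec.variables or target not in spec.variables:
        raise KeyError(f"unknown variable: {source!r} or {target!r}")
    g = _structural_graph(spec)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("structural graph contains a cycle")
    if source == target:
        return []
    out = []
    for nodes in nx.all_simple_paths(g, source, target):
        edges = list(zip(nodes[:-1], nodes[1:]))
        labels = []
        for s, t in edges:
            d = g.edges[s, t]
            labels.append(d["label"] if d["label"] is not None else f"<fixed:{d['fixed']}>")
        out.append(PathEffect(edges=edges, coefficient_labels=labels))
    out.sort(key=lambda p: (len(p.edges), [n for e in p.edges for n in e]))
    return out


def path_product(path: PathEffect, estimates: dict[str, float]) -> float:
    """Product of the edge coefficients along one path."""
    value = 1.0
    for lab in path.coefficient_labels:
        if lab.startswith("<fixed:"):
            value *= float(lab[7:-1])
        elif lab in estimates:
            value *= estimates[lab]
        else:
            raise KeyError(f"estimate missing for parameter {lab!r}")
    path.value = value
    return value


def total_effect(spec: ModelSpec, estimates: dict[str, float], source: str, target: str) -> float:
    """Sum of the products over ALL simple paths (= reduced-form entry)."""
    return sum(path_product(p, estimates) for p in enumerate_paths(spec, source, target))


@dataclass
class EffectDecomposition:
    source: str
    target: str
    direct: float
    indirects: dict[str, float]  # single-mediator paths, keyed "via_<mediator>"
    extra_paths: dict[str, float]  # longer paths, excluded from the headline total
    partial: float  # direct + indirect through the behavioural mediator
    total: float  # direct + all single-mediator indirects
    total_all_paths: float  # direct + every simple path (reduced-form entry)
    se: dict[str, float] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    warning: str | None = None

    def as_rows(self) -> list[dict]:
        rows = [{"effect": "direct", "estimate": self.direct}]
        rows += [{"effect": k, "estimate": v} for k, v in self.indirects.items()]
        rows.append({"effect": "partial", "estimate": self.partial})
        rows.append({"effect": "total", "estimate": self.total})
        for r in rows:
            name = r["effect"]
            if name in self.se:
                r["se"] = self.se[name]
            if name in self.ci:
                r["ci_lower"], r["ci_upper"] = self.ci[name]
        return rows


def decompose(
    fit_or_estimates: FittedModel | dict[str, float],
    spec: ModelSpec | None,
    source: str,
    target: str,
    *,
    partial_mediator: str = "d_crs",
) -> EffectDecomposition:
    """Direct, indirect, partial and total effects of ``source`` on ``target``.

    ``partial`` excludes the indirect path through the cross-sectionally
    confounded mediator (here baseline adiposity), keeping the direct effect
    plus the indirect effect through ``partial_mediator``.
    """
    if isinstance(fit_or_estimates, FittedModel):
        estimates = fit_or_estimates.estimates
        spec = spec or fit_or_estimates.spec
    else:
        estimates = fit_or_estimates
        if spec is None:
            raise ValueError("spec required when passing raw estimates")
    paths = enumerate_paths(spec, source, target)
    warning = None
    if not paths:
        warning = f"no directed path from {source!r} to {target!r}"
        return EffectDecomposition(
            source, target, 0.0, {}, {}, 0.0, 0.0, 0.0, warning=warning
        )
    direct = 0.0
    indirects: dict[str, float] = {}
    extra: dict[str, float] = {}
    for p in paths:
        v = path_product(p, estimates)
        if not p.mediators:
            direct = v
        elif len(p.mediators) == 1:
            indirects[p.name()] = v
        else:
            extra[p.name()] = v
    partial = direct + indirects.get(f"via_{partial_mediator}", 0.0)
    total = direct + sum(indirects.values())
    return EffectDecomposition(
        source=source,
        target=target,
        direct=direct,
        indirects=indirects,
        extra_paths=extra,
        partial=partial,
        total=total,
        total_all_paths=total + sum(extra.values()),
        warning=warning,
    )


@dataclass
class BootstrapResult:
    B: int
    seed: int
    replicates: dict[str, np.ndarray]  # effect name -> converged replicate values
    se: dict[str, float]
    ci_normal: dict[str, tuple[float, float]]
    ci_percentile: dict[str, tuple[float, float]]
    point: dict[str, float]
    n_failed: int
    normality: dict[str, float] = field(default_factory=dict)  # KS p per effect
    warning: str | None = None


def bootstrap_effects(
    records: RecordTable,
    sex: str,
    spec: ModelSpec,
    *,
    source: str = "crs0",
    target: str = "A1",
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int = 0,
    ci_level: float = 0.95,
    options: OptimOptions | None = None,
) -> BootstrapResult:
    """Bootstrap SEs/CIs for the effect decomposition by resampling subjects.

    Resampling is with replacement within the sex group; each replicate is
    preprocessed and refitted from scratch.  Non-converged replicates are
    dropped and counted (warning above 5%, hard error above 50%).  The
    normal-approximation CI (point estimate ± z * bootstrap SD) is primary;
    percentile CIs are also reported, and a KS normality p-value per effect
    replicate distribution mirrors the usual visual check.
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    options = options or OptimOptions(n_restarts=2)
    rng = np.random.default_rng(seed)
    sub = records.by_sex(sex).reset_index(drop=True)
    n = len(sub)

    # point estimate on the original sample
    ds = derive_analysis_dataset(records, sex)
    fit = fit_ml(spec, sample_covariance(ds), options)
    point_dec = decompose(fit, spec, source, target)
    names = ["direct", *point_dec.indirects, "partial", "total"]
    point = {
        "direct": point_dec.direct,
        **point_dec.indirects,
        "partial": point_dec.partial,
        "total": point_dec.total,
    }

    reps: dict[str, list[float]] = {k: [] for k in names}
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = RecordTable(frame=sub.iloc[idx].reset_index(drop=True))
        try:
            bds = derive_analysis_dataset(boot, sex)
            bfit = fit_ml(spec, sample_covariance(bds), options)
        except Exception:
            n_failed += 1
            continue
        if not bfit.converged:
            n_failed += 1
            continue
        dec = decompose(bfit, spec, source, target)
        vals = {
            "direct": dec.direct,
            **dec.indirects,
            "partial": dec.partial,
            "total": dec.total,
        }
        for k in names:
            reps[k].append(vals.get(k, np.nan))
    if n_failed > B / 2:
        raise RuntimeError(f"bootstrap failed: {n_failed}/{B} replicates did not converge")
    warning = None
    if n_failed > 0.05 * B:
        warning = f"{n_failed}/{B} bootstrap replicates failed to converge"
        warnings.warn(warning, RuntimeWarning)

    z = Z_95 if abs(ci_level - 0.95) < 1e-12 else None
    if z is None:
        from scipy.stats import norm

        z = float(norm.ppf(0.5 + ci_level / 2))
    arrays = {k: np.asarray(v) for k, v in reps.items()}
    se = {k: float(a.std(ddof=1)) for k, a in arrays.items()}
    ci_normal = {k: (point[k] - z * se[k], point[k] + z * se[k]) for k in names}
    alpha = 1 - ci_level
    ci_pct = {
        k: tuple(np.quantile(a, [alpha / 2, 1 - alpha / 2])) for k, a in arrays.items()
    }
    normality = {}
    for k, a in arrays.items():
        if a.size >= 20 and a.std(ddof=1) > 0:
            normality[k] = ks_normality(a, variable=k).p_value
    return BootstrapResult(
        B=B,
        seed=seed,
        replicates=arrays,
        se=se,
        ci_normal=ci_normal,
        ci_percentile={k: (float(lo), float(hi)) for k, (lo, hi) in ci_pct.items()},
        point=point,
        n_failed=n_failed,
        normality=normality,
        warning=warning,
    )


def expected_measurement_ratio(
    effect_on_latent: float, loading: float, delta: float
) -> float:
    """Expected multiplicative change of a log-scale indicator.

    For a predictor ``delta`` units above its mean, a latent effect ``b`` and
    a log-indicator loading ``lam``, the indicator's expected raw-scale ratio
    is ``exp(delta * b * lam)`` — e.g. the expected BMI ratio implied by a
    restraint score 20 points above the mean.
    """
    return float(np.exp(delta * effect_on_latent * loading))
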