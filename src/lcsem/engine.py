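"""Covariance-structure estimation for path models with latent variables.

The engine works on a RAM-style specification: every variable (observed or
latent) is a node, directed edges carry regression coefficients/loadings, and
a symmetric residual matrix carries exogenous variances, residual variances
and residual covariances.  With ``A`` the directed-coefficient matrix and
``S0`` the residual matrix, the implied covariance of all variables is

    Sigma_all = (I - A)^-1  S0  (I - A)^-T

and the model-implied covariance of the observed variables is the observed
sub-block.  Free parameters may share a label, which encodes an equality
constraint: one optimization variable drives every tied position.

Estimation minimizes the normal-theory maximum-likelihood discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

whose minimizer is the ML estimate under multivariate normality; the model
chi-square is (N - 1) * F_ML.  Variance parameters are optimized on the log
scale to keep them positive, with delta-method back-transformed standard
errors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "Fixed",
    "Free",
    "Edge",
    "CovEdge",
    "ModelSpec",
    "ModelSpecError",
    "IdentificationError",
    "NotPositiveDefiniteError",
    "OptimOptions",
    "FittedModel",
    "StandardizedSolution",
    "implied_covariance",
    "ml_discrepancy",
    "fit_ml",
    "standard_errors",
    "wald_interval",
    "standardize",
    "Z_95",
]

#: two-sided 97.5% standard-normal quantile used for 95% Wald intervals
Z_95 = 1.959964


class ModelSpecError(ValueError):
    """Structural problem in a model specification."""


class IdentificationError(ModelSpecError):
    """The model's free parameters are not identified."""


class NotPositiveDefiniteError(ValueError):
    """A covariance matrix that must be positive definite is not."""


# ---------------------------------------------------------------------------
# Parameter references and specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fixed:
    """A parameter held at a constant value (e.g. the scaling loading 1)."""

    value: float


@dataclass(frozen=True)
class Free:
    """A free parameter; a shared label ties positions together (equality)."""

    label: str


Param = Fixed | Free


@dataclass(frozen=True)
class Edge:
    """Directed linear effect ``source -> target``."""

    source: str
    target: str
    param: Param


@dataclass(frozen=True)
class CovEdge:
    """Residual (co)variance between ``var_a`` and ``var_b`` (variance if equal)."""

    var_a: str
    var_b: str
    param: Param


@dataclass
class ModelSpec:
    """RAM-form model: nodes, directed edges, residual (co)variance edges.

    ``variables`` fixes node order; ``latents`` is the subset that is
    unobserved.  ``observed_order`` maps the spec onto the labels of a sample
    covariance matrix (defaults to the observed variables in node order).
    """

    variables: list[str]
    latents: set[str] = field(default_factory=set)
    edges: list[Edge] = field(default_factory=list)
    covs: list[CovEdge] = field(default_factory=list)
    observed_order: list[str] | None = None

    # -- derived ---------------------------------------------------------
    @property
    def observed(self) -> list[str]:
        if self.observed_order is not None:
            return list(self.observed_order)
        return [v for v in self.variables if v not in self.latents]

    @property
    def free_labels(self) -> list[str]:
        """Distinct free labels, path labels first, in first-appearance order."""
        seen: dict[str, None] = {}
        for e in self.edges:
            if isinstance(e.param, Free):
                seen.setdefault(e.param.label, None)
        for c in self.covs:
            if isinstance(c.param, Free):
                seen.setdefault(c.param.label, None)
        return list(seen)

    @property
    def variance_labels(self) -> set[str]:
        """Free labels that sit on a diagonal (variance) position."""
        return {
            c.param.label
            for c in self.covs
            if isinstance(c.param, Free) and c.var_a == c.var_b
        }

    def n_free(self) -> int:
        return len(self.free_labels)

    def df(self) -> int:
        p = len(self.observed)
        return p * (p + 1) // 2 - self.n_free()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        idx = {v: i for i, v in enumerate(self.variables)}
        if len(idx) != len(self.variables):
            raise ModelSpecError("duplicate variable names")
        unknown = self.latents - set(self.variables)
        if unknown:
            raise ModelSpecError(f"latents not in variables: {sorted(unknown)}")
        for e in self.edges:
            if e.source not in idx or e.target not in idx:
                raise ModelSpecError(f"edge uses unknown variable: {e}")
        for c in self.covs:
            if c.var_a not in idx or c.var_b not in idx:
                raise ModelSpecError(f"cov edge uses unknown variable: {c}")
        if self.observed_order is not None:
            expect = {v for v in self.variables if v not in self.latents}
            if set(self.observed_order) != expect:
                raise ModelSpecError("observed_order must list exactly the observed variables")
        # acyclicity of directed part
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from((e.source, e.target) for e in self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ModelSpecError("directed edges contain a cycle")
        # no label on both a variance and a non-variance position
        var_labels = self.variance_labels
        for c in self.covs:
            if isinstance(c.param, Free) and c.var_a != c.var_b and c.param.label in var_labels:
                raise ModelSpecError(
                    f"label {c.param.label!r} used for both a variance and a covariance"
                )
        for e in self.edges:
            if isinstance(e.param, Free) and e.param.label in var_labels:
                raise ModelSpecError(
                    f"label {e.param.label!r} used for both a variance and a path"
                )
        # every latent needs a scale: a fixed outgoing loading or a fixed variance
        for lv in sorted(self.latents):
            fixed_loading = any(
                e.source == lv and isinstance(e.param, Fixed) for e in self.edges
            )
            fixed_var = any(
                c.var_a == lv and c.var_b == lv and isinstance(c.param, Fixed)
                for c in self.covs
            )
            if not (fixed_loading or fixed_var):
                raise IdentificationError(
                    f"model not identified: latent {lv!r} has no fixed scale "
                    "(fix one loading or its variance)"
                )
        p = len(self.observed)
        if self.n_free() >= p * (p + 1) // 2 + 1:
            raise IdentificationError(
                f"model not identified: {self.n_free()} free parameters exceed "
                f"{p * (p + 1) // 2} observed moments"
            )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def pd(p: Param) -> dict:
            return {"fixed": p.value} if isinstance(p, Fixed) else {"free": p.label}

        return {
            "variables": list(self.variables),
            "latents": sorted(self.latents),
            "edges": [{"from": e.source, "to": e.target, "param": pd(e.param)} for e in self.edges],
            "covs": [{"a": c.var_a, "b": c.var_b, "param": pd(c.param)} for c in self.covs],
            "observed_order": self.observed_order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        def pp(pd: dict) -> Param:
            if "fixed" in pd:
                return Fixed(float(pd["fixed"]))
            return Free(str(pd["free"]))

        return cls(
            variables=list(d["variables"]),
            latents=set(d.get("latents", [])),
            edges=[Edge(e["from"], e["to"], pp(e["param"])) for e in d.get("edges", [])],
            covs=[CovEdge(c["a"], c["b"], pp(c["param"])) for c in d.get("covs", [])],
            observed_order=d.get("observed_order"),
        )

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Compiled structure: fast theta -> Sigma and analytic gradient
# ---------------------------------------------------------------------------


class _Compiled:
    """Index structure mapping free labels to matrix positions."""

    def __init__(self, spec: ModelSpec):
        spec.validate()
        self.spec = spec
        self.vars = spec.variables
        self.nv = len(self.vars)
        self.idx = {v: i for i, v in enumerate(self.vars)}
        self.obs = spec.observed
        self.obs_idx = np.array([self.idx[v] for v in self.obs])
        self.labels = spec.free_labels
        self.lab_pos = {lab: k for k, lab in enumerate(self.labels)}
        self.var_labels = spec.variance_labels
        self.is_var = np.array([lab in self.var_labels for lab in self.labels])

        # fixed skeletons and free position lists
        self.A_fixed = np.zeros((self.nv, self.nv))
        self.S0_fixed = np.zeros((self.nv, self.nv))
        # per label: list of (t, s) positions in A, list of (a, b) in S0
        self.A_pos: list[list[tuple[int, int]]] = [[] for _ in self.labels]
        self.S_pos: list[list[tuple[int, int]]] = [[] for _ in self.labels]
        for e in spec.edges:
            t, s = self.idx[e.target], self.idx[e.source]
            if isinstance(e.param, Fixed):
                self.A_fixed[t, s] += e.param.value
            else:
                self.A_pos[self.lab_pos[e.param.label]].append((t, s))
        for c in spec.covs:
            a, b = self.idx[c.var_a], self.idx[c.var_b]
            if isinstance(c.param, Fixed):
                self.S0_fixed[a, b] += c.param.value
                if a != b:
                    self.S0_fixed[b, a] += c.param.value
            else:
                self.S_pos[self.lab_pos[c.param.label]].append((a, b))

    # theta given on the NATURAL scale as an array ordered like self.labels
    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A = self.A_fixed.copy()
        S0 = self.S0_fixed.copy()
        for k, val in enumerate(theta):
            for (t, s) in self.A_pos[k]:
                A[t, s] += val
            for (a, b) in self.S_pos[k]:
                S0[a, b] += val
                if a != b:
                    S0[b, a] += val
        return A, S0

    def sigma_all(self, theta: np.ndarray) -> np.ndarray:
        A, S0 = self.matrices(theta)
        ima = np.eye(self.nv) - A
        try:
            B = np.linalg.inv(ima)
        except np.linalg.LinAlgError as err:
            raise ModelSpecError("(I - A) is singular") from err
        sig = B @ S0 @ B.T
        return 0.5 * (sig + sig.T)

    def sigma_obs(self, theta: np.ndarray) -> np.ndarray:
        return self.sigma_all(theta)[np.ix_(self.obs_idx, self.obs_idx)]

    # -- objective / gradient on the transformed scale -------------------
    def to_transformed(self, theta_nat: np.ndarray) -> np.ndarray:
        x = np.asarray(theta_nat, dtype=float).copy()
        x[self.is_var] = np.log(x[self.is_var])
        return x

    def to_natural(self, x: np.ndarray) -> np.ndarray:
        th = np.asarray(x, dtype=float).copy()
        th[self.is_var] = np.exp(th[self.is_var])
        return th

    def fml_grad(
        self, x: np.ndarray, S: np.ndarray, lndetS: float
    ) -> tuple[float, np.ndarray]:
        """F_ML and its gradient w.r.t. the transformed parameter vector."""
        theta = self.to_natural(x)
        A, S0 = self.matrices(theta)
        ima = np.eye(self.nv) - A
        try:
            B = np.linalg.inv(ima)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(x)
        sig_all = B @ S0 @ B.T
        sig = sig_all[np.ix_(self.obs_idx, self.obs_idx)]
        sig = 0.5 * (sig + sig.T)
        p = sig.shape[0]
        try:
            cf = sla.cho_factor(sig, check_finite=False)
        except (sla.LinAlgError, ValueError):
            return np.inf, np.zeros_like(x)
        lndet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        sig_inv = sla.cho_solve(cf, np.eye(p), check_finite=False)
        f = lndet + float(np.sum(sig_inv * S)) - lndetS - p
        # W = Sigma^-1 - Sigma^-1 S Sigma^-1, lifted to the full variable space
        W = sig_inv - sig_inv @ S @ sig_inv
        Wf = np.zeros((self.nv, self.nv))
        Wf[np.ix_(self.obs_idx, self.obs_idx)] = W
        G1 = sig_all @ Wf @ B  # gradient kernel for path parameters
        G2 = B.T @ Wf @ B  # gradient kernel for residual parameters
        g = np.zeros_like(x)
        for k in range(len(theta)):
            acc = 0.0
            for (t, s) in self.A_pos[k]:
                acc += 2.0 * G1[s, t]
            for (a, b) in self.S_pos[k]:
                acc += G2[a, b] if a == b else 2.0 * G2[a, b]
            if self.is_var[k]:
                acc *= theta[k]  # chain rule through log
            g[k] = acc
        return f, g


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def implied_covariance(spec: ModelSpec, theta: dict[str, float]) -> np.ndarray:
    """Model-implied covariance of the observed variables at ``theta``.

    ``theta`` maps every free label to its (natural-scale) value.
    """
    comp = _Compiled(spec)
    missing = [lab for lab in comp.labels if lab not in theta]
    if missing:
        raise ValueError(f"theta missing labels: {missing}")
    vec = np.array([theta[lab] for lab in comp.labels], dtype=float)
    return comp.sigma_obs(vec)


def _check_pd(M: np.ndarray, name: str) -> float:
    """Return ln|M|, raising if M is not symmetric positive definite."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=1e-8):
        raise NotPositiveDefiniteError(f"{name} is not symmetric")
    sign, lndet = np.linalg.slogdet(M)
    w = np.linalg.eigvalsh(M)
    if sign <= 0 or w[0] <= 0:
        raise NotPositiveDefiniteError(f"{name} is not positive definite")
    return lndet


def ml_discrepancy(S: np.ndarray, sigma: np.ndarray, p: int | None = None) -> float:
    """Normal-theory ML discrepancy F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p."""
    S = np.asarray(S, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if S.shape != sigma.shape:
        raise ValueError("S and Sigma must have the same shape")
    if p is None:
        p = S.shape[0]
    lndetS = _check_pd(S, "S")
    lndetSig = _check_pd(sigma, "Sigma")
    sig_inv = np.linalg.inv(sigma)
    return float(lndetSig + np.sum(sig_inv * S) - lndetS - p)


@dataclass
class OptimOptions:
    max_iter: int = 500
    gtol: float = 1e-6  # convergence: max-norm of the gradient
    ftol: float = 1e-10  # relative F change
    n_restarts: int = 5
    restart_seed: int = 0
    jitter: float = 0.25


@dataclass
class FittedModel:
    spec: ModelSpec
    estimates: dict[str, float]
    se: dict[str, float]
    vcov: np.ndarray | None
    F_ML: float
    chi_square: float
    df: int
    n: int
    implied_sigma: np.ndarray
    converged: bool
    n_iterations: int
    gradient_norm: float

    def tvalues(self) -> dict[str, float]:
        return {
            k: (self.estimates[k] / self.se[k]) if self.se.get(k, 0) > 0 else float("nan")
            for k in self.estimates
        }

    def parameter_table(self) -> "pandas.DataFrame":  # noqa: F821
        import pandas as pd

        rows = []
        for lab in self.estimates:
            se = self.se.get(lab, float("nan"))
            est = self.estimates[lab]
            rows.append(
                {
                    "parameter": lab,
                    "estimate": est,
                    "se": se,
                    "t": est / se if se and se > 0 else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    def to_report_dict(self) -> dict:
        return {
            "estimates": dict(self.estimates),
            "se": dict(self.se),
            "t": self.tvalues(),
            "F_ML": self.F_ML,
            "chi_square": self.chi_square,
            "df": self.df,
            "n": self.n,
            "converged": self.converged,
            "implied_sigma": np.asarray(self.implied_sigma).tolist(),
        }


def _start_values(comp: _Compiled, S: np.ndarray) -> np.ndarray:
    """Heuristic starts: loadings 1, paths 0, variances half the data scale."""
    spec = comp.spec
    obs_var = {v: S[i, i] for i, v in enumerate(comp.obs)}
    # loading = edge from a latent to an observed; structural path = anything else
    loading_labels: set[str] = set()
    for e in spec.edges:
        if isinstance(e.param, Free) and e.source in spec.latents and e.target not in spec.latents:
            loading_labels.add(e.param.label)
    # scaling indicator variance per latent (observed target of a fixed edge)
    latent_scale_var: dict[str, float] = {}
    for e in spec.edges:
        if isinstance(e.param, Fixed) and e.source in spec.latents and e.target in obs_var:
            latent_scale_var.setdefault(e.source, obs_var[e.target] / max(e.param.value**2, 1e-12))
    x0 = np.zeros(len(comp.labels))
    for k, lab in enumerate(comp.labels):
        if comp.is_var[k]:
            # variance parameter: half the relevant observed variance
            a, b = comp.S_pos[k][0]
            v = comp.vars[a]
            if v in obs_var:
                x0[k] = 0.5 * obs_var[v]
            elif v in latent_scale_var:
                x0[k] = 0.5 * latent_scale_var[v]
            else:
                x0[k] = 0.5
            x0[k] = max(x0[k], 1e-6)
        elif comp.S_pos[k]:
            x0[k] = 0.0  # free covariance
        elif lab in loading_labels:
            x0[k] = 1.0
        else:
            x0[k] = 0.0  # structural coefficient
    # free covariances: start at the observed covariance when both are observed
    for k, lab in enumerate(comp.labels):
        if comp.S_pos[k] and not comp.is_var[k]:
            a, b = comp.S_pos[k][0]
            va, vb = comp.vars[a], comp.vars[b]
            if va in obs_var and vb in obs_var:
                ia, ib = comp.obs.index(va), comp.obs.index(vb)
                x0[k] = S[ia, ib]
    return x0


def fit_ml(
    spec: ModelSpec,
    cov: "CovarianceSummary | tuple",  # noqa: F821
    options: OptimOptions | None = None,
) -> FittedModel:
    """Fit ``spec`` to a sample covariance by normal-theory maximum likelihood.

    ``cov`` is a ``CovarianceSummary`` (or any object with ``labels``, ``S``
    and ``n``).  Equality constraints are honoured by construction: tied
    positions share one optimization variable.  Variances are optimized on
    the log scale.  On non-convergence the fit is retried from jittered
    starting points; if all restarts fail the best result is returned with
    ``converged=False`` and a warning.
    """
    options = options or OptimOptions()
    comp = _Compiled(spec)
    labels = list(cov.labels)
    order = [labels.index(v) for v in comp.obs]
    S = np.asarray(cov.S, dtype=float)[np.ix_(order, order)]
    n = int(cov.n)
    lndetS = _check_pd(S, "S")

    x0_nat = _start_values(comp, S)
    x0 = comp.to_transformed(x0_nat)

    rng = np.random.default_rng(options.restart_seed)
    best = None
    for attempt in range(options.n_restarts + 1):
        xs = x0 if attempt == 0 else x0 + rng.normal(0, options.jitter, size=x0.shape)
        res = minimize(
            comp.fml_grad,
            xs,
            args=(S, lndetS),
            jac=True,
            method="BFGS",
            options={"maxiter": options.max_iter, "gtol": options.gtol / 10},
        )
        gnorm = float(np.max(np.abs(res.jac)))
        ok = np.isfinite(res.fun) and gnorm < options.gtol
        if best is None or (np.isfinite(res.fun) and res.fun < best[0].fun - 1e-12):
            best = (res, gnorm, ok)
        if ok:
            best = (res, gnorm, ok)
            break
    res, gnorm, converged = best
    if not converged:
        warnings.warn(
            f"fit_ml did not converge (gradient max-norm {gnorm:.2e})", RuntimeWarning
        )
    theta = comp.to_natural(res.x)
    estimates = {lab: float(v) for lab, v in zip(comp.labels, theta)}
    fml = float(max(res.fun, 0.0)) if res.fun > -1e-8 else float(res.fun)
    sigma = comp.sigma_obs(theta)

    fit = FittedModel(
        spec=spec,
        estimates=estimates,
        se={},
        vcov=None,
        F_ML=fml,
        chi_square=(n - 1) * fml,
        df=spec.df(),
        n=n,
        implied_sigma=sigma,
        converged=bool(converged),
        n_iterations=int(res.nit),
        gradient_norm=gnorm,
    )
    fit._comp, fit._S, fit._lndetS, fit._x = comp, S, lndetS, res.x
    if converged:
        try:
            standard_errors(fit, n, _comp=comp, _S=S, _lndetS=lndetS, _x=res.x)
        except IdentificationError:
            raise
        except Exception as err:  # pragma: no cover - defensive
            warnings.warn(f"standard errors unavailable: {err}", RuntimeWarning)
    return fit


def _hessian_fd(comp: _Compiled, x: np.ndarray, S: np.ndarray, lndetS: float) -> np.ndarray:
    """Hessian of F_ML (transformed scale) by central differences of the gradient."""
    k = len(x)
    H = np.zeros((k, k))
    h = 1e-5 * np.maximum(1.0, np.abs(x))
    for j in range(k):
        xp = x.copy()
        xp[j] += h[j]
        xm = x.copy()
        xm[j] -= h[j]
        _, gp = comp.fml_grad(xp, S, lndetS)
        _, gm = comp.fml_grad(xm, S, lndetS)
        H[:, j] = (gp - gm) / (2 * h[j])
    return 0.5 * (H + H.T)


def standard_errors(
    fit: FittedModel,
    n: int | None = None,
    *,
    _comp: _Compiled | None = None,
    _S: np.ndarray | None = None,
    _lndetS: float | None = None,
    _x: np.ndarray | None = None,
) -> FittedModel:
    """Wald standard errors from the information of the ML criterion.

    ``vcov = (2 / (N - 1)) H^-1`` with ``H`` the Hessian of F_ML at the
    solution; SEs therefore scale as 1/sqrt(N - 1).  Log-variance parameters
    are mapped back to the natural scale by the delta method.
    """
    if not fit.converged:
        raise ValueError("standard errors require a converged fit")
    n = int(n if n is not None else fit.n)
    comp = _comp or getattr(fit, "_comp", None) or _Compiled(fit.spec)
    if _S is None:
        _S, _lndetS, _x = fit._S, fit._lndetS, fit._x
    H = _hessian_fd(comp, _x, _S, _lndetS)
    # scale-invariant singularity check: eigenvalues of the correlation-form
    # Hessian (parameters live on wildly different scales)
    d = np.diag(H).copy()
    if np.any(d <= 0):
        bad_labels = [comp.labels[i] for i in np.where(d <= 0)[0]]
        raise IdentificationError(
            "model not identified: non-positive information for " + ", ".join(bad_labels)
        )
    Dinv = 1.0 / np.sqrt(d)
    w, V = np.linalg.eigh(H * np.outer(Dinv, Dinv))
    if w[0] <= 1e-8:
        labs: list[str] = []
        for j in np.where(w <= 1e-8)[0]:
            heavy = np.argsort(-np.abs(V[:, j]))[:3]
            labs.extend(comp.labels[i] for i in heavy if abs(V[i, j]) > 0.3)
        raise IdentificationError(
            "model not identified: singular information; null space involves "
            + ", ".join(sorted(set(labs)))
        )
    Hinv = np.outer(Dinv, Dinv) * ((V / w) @ V.T)
    vcov_t = (2.0 / (n - 1)) * Hinv
    theta = comp.to_natural(_x)
    jac = np.where(comp.is_var, theta, 1.0)
    vcov = vcov_t * np.outer(jac, jac)
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    fit.vcov = vcov
    fit.se = {lab: float(s) for lab, s in zip(comp.labels, se)}
    return fit


def wald_interval(
    estimate: float, se: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Normal-theory confidence interval ``estimate ± z * se`` and the t ratio."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = Z_95 if abs(level - 0.95) < 1e-12 else float(norm.ppf(0.5 + level / 2))
    return estimate - z * se, estimate + z * se, estimate / se


@dataclass
class StandardizedSolution:
    """Standardized path coefficients and indicator R-squared values.

    Each directed edge gets ``raw * sd(source) / sd(target)`` with SDs from
    the model-implied covariance of all variables, so a loading constrained
    equal across two latents yields two standardized values, one per edge.
    """

    coefficients: dict[tuple[str, str], float]
    r_squared: dict[str, float]


def standardize(fit: FittedModel) -> StandardizedSolution:
    """Standardized solution from the implied covariance of all variables."""
    if not fit.converged:
        raise ValueError("standardization requires a converged fit")
    comp = _Compiled(fit.spec)
    theta = np.array([fit.estimates[lab] for lab in comp.labels])
    sig_all = comp.sigma_all(theta)
    sd = np.sqrt(np.diag(sig_all))
    if np.any(sd <= 0):
        bad = [comp.vars[i] for i in np.where(sd <= 0)[0]]
        raise ValueError(f"zero implied variance for {bad}")
    A, S0 = comp.matrices(theta)
    coeffs: dict[tuple[str, str], float] = {}
    for e in fit.spec.edges:
        t, s = comp.idx[e.target], comp.idx[e.source]
        coeffs[(e.source, e.target)] = float(A[t, s] * sd[s] / sd[t])
    r2: dict[str, float] = {}
    for v in fit.spec.observed:
        i = comp.idx[v]
        if np.any(A[i, :] != 0):  # an indicator / endogenous observed variable
            r2[v] = float(1.0 - S0[i, i] / sig_all[i, i])
    return StandardizedSolution(coefficients=coeffs, r_squared=r2)
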