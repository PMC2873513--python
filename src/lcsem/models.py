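"""Builders for the three model families fitted in the analysis.

* ``single_wave_measurement_spec`` — one latent adiposity factor measured by
  the four indicators of a single wave (scale fixed by the percent-body-fat
  loading at 1).
* ``latent_change_measurement_spec`` — baseline adiposity and adiposity
  change as two latents, the four loadings constrained equal across the
  baseline indicators and their changes, with a directed baseline-to-change
  regression.
* ``longitudinal_structural_spec`` — the full longitudinal model: baseline
  adiposity regressed on age and baseline restraint (CRS), CRS change on
  baseline adiposity, age and baseline CRS, and adiposity change on baseline
  adiposity, age, baseline CRS and CRS change; age and baseline CRS covary
  freely as exogenous observed inputs.
"""

from __future__ import annotations

from .engine import CovEdge, Edge, Fixed, Free, ModelSpec

__all__ = [
    "INDICATORS",
    "BASELINE_INDICATORS",
    "CHANGE_INDICATORS",
    "STRUCTURAL_LABELS",
    "single_wave_measurement_spec",
    "latent_change_measurement_spec",
    "longitudinal_structural_spec",
    "builder_by_name",
]

#: short indicator stems, percent body fat first (it carries the fixed scale)
INDICATORS = ["pbf", "log_bmi", "log_skinfold", "log_waist"]
BASELINE_INDICATORS = ["pbf0", "log_bmi0", "log_skinfold0", "log_waist0"]
CHANGE_INDICATORS = ["d_pbf", "d_log_bmi", "d_log_skinfold", "d_log_waist"]

#: the nine structural regression coefficients, one per arrow of the
#: longitudinal diagram (outcome, predictor) -> label
STRUCTURAL_LABELS = {
    ("A0", "age0"): "gamma_A0_age",
    ("A0", "crs0"): "gamma_A0_crs0",
    ("d_crs", "A0"): "beta_dcrs_A0",
    ("d_crs", "age0"): "gamma_dcrs_age",
    ("d_crs", "crs0"): "gamma_dcrs_crs0",
    ("A1", "A0"): "beta_A1_A0",
    ("A1", "age0"): "gamma_A1_age",
    ("A1", "crs0"): "gamma_A1_crs0",
    ("A1", "d_crs"): "beta_A1_dcrs",
}


def _loading(stem: str) -> Free:
    return Free(f"lambda_{stem}")


def single_wave_measurement_spec(
    indicators: list[str] | None = None, latent: str = "A0"
) -> ModelSpec:
    """One-factor model for the four adiposity indicators of one wave.

    Free parameters (8): three loadings, four residual variances, the latent
    variance; the first indicator's loading is fixed at 1, so with 10
    observed moments the model has 2 degrees of freedom.
    """
    indicators = indicators or list(BASELINE_INDICATORS)
    if len(indicators) != 4:
        raise ValueError("expected exactly four indicators")
    edges = [Edge(latent, indicators[0], Fixed(1.0))]
    edges += [Edge(latent, ind, _loading(stem)) for ind, stem in zip(indicators[1:], INDICATORS[1:])]
    covs = [CovEdge(ind, ind, Free(f"eps_{ind}")) for ind in indicators]
    covs.append(CovEdge(latent, latent, Free(f"var_{latent}")))
    spec = ModelSpec(
        variables=indicators + [latent],
        latents={latent},
        edges=edges,
        covs=covs,
        observed_order=list(indicators),
    )
    spec.validate()
    return spec


def latent_change_measurement_spec(
    *, constrained: bool = True, free_residual_cov: bool = False
) -> ModelSpec:
    """Two-latent measurement model: baseline adiposity and its change.

    With ``constrained=True`` (the analysis model) each loading label is
    shared between a baseline indicator and its change, so the same four
    loadings describe both latents; the unconstrained variant gives the
    change indicators their own three free loadings.  The baseline-to-change
    link is a directed regression of the change latent on the baseline
    latent.  ``free_residual_cov`` additionally frees the four covariances
    between a baseline indicator's residual and its change's residual (the
    time-2 parameterization implies these; off by default).
    """
    edges = [Edge("A0", "pbf0", Fixed(1.0)), Edge("A1", "d_pbf", Fixed(1.0))]
    for b, c, stem in zip(BASELINE_INDICATORS[1:], CHANGE_INDICATORS[1:], INDICATORS[1:]):
        edges.append(Edge("A0", b, _loading(stem)))
        lam = _loading(stem) if constrained else Free(f"lambda_{stem}_chg")
        edges.append(Edge("A1", c, lam))
    edges.append(Edge("A0", "A1", Free("beta_A1_A0")))
    covs = [CovEdge(v, v, Free(f"eps_{v}")) for v in BASELINE_INDICATORS + CHANGE_INDICATORS]
    covs += [CovEdge("A0", "A0", Free("var_A0")), CovEdge("A1", "A1", Free("zeta1"))]
    if free_residual_cov:
        for b, c, stem in zip(BASELINE_INDICATORS, CHANGE_INDICATORS, INDICATORS):
            covs.append(CovEdge(b, c, Free(f"cov_eps_{stem}")))
    spec = ModelSpec(
        variables=BASELINE_INDICATORS + CHANGE_INDICATORS + ["A0", "A1"],
        latents={"A0", "A1"},
        edges=edges,
        covs=covs,
        observed_order=BASELINE_INDICATORS + CHANGE_INDICATORS,
    )
    spec.validate()
    return spec


def longitudinal_structural_spec(*, free_residual_cov: bool = False) -> ModelSpec:
    """Full longitudinal model: 11 observed variables, 2 latents, 26 free
    parameters, hence 66 - 26 = 40 degrees of freedom.

    Structural arrows: A0 <- age0, crs0; d_crs <- A0, age0, crs0;
    A1 <- A0, age0, crs0, d_crs; age0 and crs0 covary freely.
    """
    edges = [Edge("A0", "pbf0", Fixed(1.0)), Edge("A1", "d_pbf", Fixed(1.0))]
    for b, c, stem in zip(BASELINE_INDICATORS[1:], CHANGE_INDICATORS[1:], INDICATORS[1:]):
        edges.append(Edge("A0", b, _loading(stem)))
        edges.append(Edge("A1", c, _loading(stem)))
    for (outcome, pred), label in STRUCTURAL_LABELS.items():
        edges.append(Edge(pred, outcome, Free(label)))
    covs = [CovEdge(v, v, Free(f"eps_{v}")) for v in BASELINE_INDICATORS + CHANGE_INDICATORS]
    covs += [
        CovEdge("A0", "A0", Free("zeta0")),
        CovEdge("d_crs", "d_crs", Free("zeta3")),
        CovEdge("A1", "A1", Free("zeta1")),
        CovEdge("age0", "age0", Free("var_age")),
        CovEdge("crs0", "crs0", Free("var_crs0")),
        CovEdge("age0", "crs0", Free("cov_age_crs0")),
    ]
    if free_residual_cov:
        for b, c, stem in zip(BASELINE_INDICATORS, CHANGE_INDICATORS, INDICATORS):
            covs.append(CovEdge(b, c, Free(f"cov_eps_{stem}")))
    observed = (
        BASELINE_INDICATORS + CHANGE_INDICATORS + ["age0", "crs0", "d_crs"]
    )
    spec = ModelSpec(
        variables=observed + ["A0", "A1"],
        latents={"A0", "A1"},
        edges=edges,
        covs=covs,
        observed_order=observed,
    )
    spec.validate()
    return spec


_BUILDERS = {
    "single_wave": single_wave_measurement_spec,
    "latent_change": latent_change_measurement_spec,
    "longitudinal": longitudinal_structural_spec,
}


def builder_by_name(name: str):
    """Look up a model builder by its CLI/config name."""
    try:
        return _BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; choose from {sorted(_BUILDERS)}"
        ) from None
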