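"""Closed-form efficiency and privacy metrics for the six mechanisms.

Three quantities summarize a mechanism at a given parameter point:

* ``Var(mu_hat)`` — the design-based variance of the sample-mean estimator
  under simple random sampling with replacement; scales exactly as 1/n.
* ``nabla = E[(Z - Y)^2]`` — the respondent-privacy measure: the expected
  squared deviation of the reported from the true response.  Larger is
  better privacy.  Independent of n.
* ``delta = Var(mu_hat) / nabla`` — the joint efficiency–privacy measure
  (MSE = Var for these unbiased estimators).  Smaller is better.

Two privacy variants are exposed.  ``privacy_as_printed`` follows the
published closed forms verbatim.  ``privacy_first_principles`` applies the
definition E[(Z - Y)^2] directly to each mechanism; for five of the six
models the two coincide, but for the three-branch optional model the
published form omits the factor (1 - p) that the direct derivation
carries — the first-principles value is (1-p) * [var_S + (1-A) * var_T *
(var_Y + mu_Y^2)].  Both are first-class outputs; grid reproduction uses
the printed variant by default, and Monte-Carlo verification shows that
only the first-principles variant matches empirical E[(Z - Y)^2].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .models import Model, ModelParams, OPTIONAL_MODELS
from .samplers import PopulationSpec

__all__ = [
    "MetricsResult",
    "EfficiencyComparison",
    "variance_of_mean",
    "privacy_as_printed",
    "privacy_first_principles",
    "delta_measure",
    "compute_metrics",
    "efficiency_condition",
    "EFFICIENCY_PAIRS",
]

#: delta sentinel for Var > 0 at nabla = 0 (no privacy at all)
DELTA_INFINITE = math.inf
#: delta sentinel for the 0/0 corner (degenerate direct questioning)
DELTA_UNDEFINED = math.nan


@dataclass(frozen=True)
class MetricsResult:
    """Analytic Var(mu_hat), privacy nabla and joint delta for one cell."""

    model: Model
    variance: float
    privacy: float
    delta: float
    params: ModelParams
    pop: PopulationSpec
    var_S: float
    var_T: float
    n: int
    privacy_mode: str = "printed"


def _second_moment(pop: PopulationSpec) -> float:
    """E(Y^2) = var_Y + mu_Y^2."""
    return pop.var + pop.mu * pop.mu


def _check_variances(var_S: float, var_T: float) -> None:
    if var_S < 0 or var_T < 0:
        raise ValueError("scrambler variances must be >= 0")


def variance_of_mean(
    params: ModelParams,
    pop: PopulationSpec,
    var_S: float,
    var_T: float,
    n: int,
) -> float:
    """Design-based variance of the sample-mean estimator.

    Per-mechanism closed forms (g = var_T * (var_Y + mu_Y^2)):

    * warner:        (var_Y + var_S) / n
    * eichhorn:      (var_Y + g) / n
    * gupta add.:    (var_Y + (1-p) var_S) / n
    * bar-lev:       (var_Y + (1-p) g) / n
    * murtaza:       ((1-p) g + var_Y + alpha^2 var_S) / n
    * gupta mixed:   ((1-p)(1-A) g + var_Y + (1-p) var_S) / n

    The murtaza form follows its published statement, in which the
    alpha^2 var_S term is not attenuated by (1-p).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    _check_variances(var_S, var_T)
    g = var_T * _second_moment(pop)
    model = params.model
    if model is Model.WARNER_ADDITIVE:
        num = pop.var + var_S
    elif model is Model.EICHHORN_HAYRE:
        num = pop.var + g
    elif model is Model.GUPTA_OPTIONAL_ADDITIVE:
        num = pop.var + (1.0 - params.p) * var_S
    elif model is Model.BARLEV_OPTIONAL_MULTIPLICATIVE:
        num = pop.var + (1.0 - params.p) * g
    elif model is Model.MURTAZA_MIXED:
        num = (1.0 - params.p) * g + pop.var + params.alpha**2 * var_S
    else:  # GUPTA_MIXED_OPTIONAL
        q = 1.0 - params.p
        num = q * (1.0 - params.A) * g + pop.var + q * var_S
    return num / n


def privacy_as_printed(
    params: ModelParams,
    pop: PopulationSpec,
    var_S: float,
    var_T: float,
) -> float:
    """Privacy nabla following the published closed forms verbatim."""
    _check_variances(var_S, var_T)
    g = var_T * _second_moment(pop)
    model = params.model
    if model is Model.WARNER_ADDITIVE:
        return var_S
    if model is Model.EICHHORN_HAYRE:
        return g
    if model is Model.GUPTA_OPTIONAL_ADDITIVE:
        return (1.0 - params.p) * var_S
    if model is Model.BARLEV_OPTIONAL_MULTIPLICATIVE:
        return (1.0 - params.p) * g
    if model is Model.MURTAZA_MIXED:
        return (1.0 - params.p) * (g + params.alpha**2 * var_S)
    # GUPTA_MIXED_OPTIONAL: published form, constant in p
    return (1.0 - params.A) * g + var_S


def privacy_first_principles(
    params: ModelParams,
    pop: PopulationSpec,
    var_S: float,
    var_T: float,
) -> float:
    """Privacy nabla = E[(Z - Y)^2] derived directly from each mechanism.

    Assumes a centred additive scrambler (theta = 0) and E(T) = 1, so
    E[(S)^2] = var_S and E[(T-1)^2 Y^2] = var_T * (var_Y + mu_Y^2).
    Identical to :func:`privacy_as_printed` for all models except
    ``gupta_mixed_optional``, where the scrambled-branch probability
    (1 - p) multiplies the whole expression.
    """
    model = params.model
    if model is Model.GUPTA_MIXED_OPTIONAL:
        _check_variances(var_S, var_T)
        g = var_T * _second_moment(pop)
        return (1.0 - params.p) * (var_S + (1.0 - params.A) * g)
    return privacy_as_printed(params, pop, var_S, var_T)


def delta_measure(variance: float, privacy: float) -> float:
    """Joint measure delta = Var(mu_hat) / nabla.

    At nabla = 0 (e.g. p = 1 or all scrambler variances 0) the published
    definition is silent; a tagged sentinel is returned instead of raising
    so grid sweeps over the p endpoints do not abort: ``inf`` when the
    variance is positive, ``nan`` for the degenerate 0/0 corner.
    """
    if variance < 0 or privacy < 0:
        raise ValueError("variance and privacy must be >= 0")
    if privacy == 0.0:
        return DELTA_INFINITE if variance > 0.0 else DELTA_UNDEFINED
    return variance / privacy


def compute_metrics(
    params: ModelParams,
    pop: PopulationSpec,
    var_S: float,
    var_T: float,
    n: int,
    privacy_mode: str = "printed",
) -> MetricsResult:
    """Bundle Var(mu_hat), nabla and delta for one (model, parameter) cell."""
    if privacy_mode not in ("printed", "first_principles"):
        raise ValueError(f"unknown privacy_mode {privacy_mode!r}")
    variance = variance_of_mean(params, pop, var_S, var_T, n)
    privacy_fn = (
        privacy_as_printed if privacy_mode == "printed" else privacy_first_principles
    )
    privacy = privacy_fn(params, pop, var_S, var_T)
    return MetricsResult(
        model=params.model,
        variance=variance,
        privacy=privacy,
        delta=delta_measure(variance, privacy),
        params=params,
        pop=pop,
        var_S=var_S,
        var_T=var_T,
        n=n,
        privacy_mode=privacy_mode,
    )


@dataclass(frozen=True)
class EfficiencyComparison:
    """Outcome of a pairwise closed-form efficiency condition.

    ``first_more_efficient`` is True when the first-named model of the pair
    has the smaller estimator variance; ``margin`` is LHS - RHS of the
    inequality that decides it (positive means the condition holds).
    """

    pair: str
    first_more_efficient: bool
    margin: float
    lhs: float
    rhs: float


EFFICIENCY_PAIRS = (
    "warner_vs_eichhorn_hayre",
    "gupta_additive_vs_barlev",
    "gupta_mixed_vs_murtaza",
)


def efficiency_condition(
    pair: str,
    pop: PopulationSpec,
    var_S: float,
    var_T: float,
    p: float | None = None,
    A: float | None = None,
    alpha: float | None = None,
) -> EfficiencyComparison:
    """Evaluate a pairwise efficiency inequality in the moment parameters.

    The two non-optional-vs-optional pairs share the same condition
    var_T * (var_Y + mu_Y^2) > var_S, because each optional model is the
    truthful-option variant of its non-optional counterpart.  The mixed
    pair compares the three-branch optional model against the two-branch
    mixed model:  A (1-p) g + alpha^2 var_S > (1-p) var_S  with
    g = var_T * (var_Y + mu_Y^2).

    The boolean always agrees with direct comparison of the two
    :func:`variance_of_mean` values.
    """
    _check_variances(var_S, var_T)
    g = var_T * _second_moment(pop)
    if pair == "warner_vs_eichhorn_hayre":
        lhs, rhs = g, var_S
    elif pair == "gupta_additive_vs_barlev":
        if p is None:
            raise ValueError(f"{pair} requires p")
        # retains the (1-p) factor that cancels for p < 1 so the boolean
        # agrees with direct variance comparison at the p = 1 boundary too
        lhs, rhs = (1.0 - p) * g, (1.0 - p) * var_S
    elif pair == "gupta_mixed_vs_murtaza":
        if p is None or A is None or alpha is None:
            raise ValueError(f"{pair} requires p, A and alpha")
        lhs = A * (1.0 - p) * g + alpha**2 * var_S
        rhs = (1.0 - p) * var_S
    else:
        raise ValueError(f"unknown pair {pair!r}; choose from {EFFICIENCY_PAIRS}")
    return EfficiencyComparison(
        pair=pair,
        first_more_efficient=lhs > rhs,
        margin=lhs - rhs,
        lhs=lhs,
        rhs=rhs,
    )
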