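"""Replicate-level Monte-Carlo verification of the analytic formulas.

Each design simulates R independent surveys of size n, collects the
per-survey mean estimates, and compares

* the mean of the estimates against mu_Y (unbiasedness),
* the variance of the estimates against the closed-form Var(mu_hat),
* the grand mean of (Z - Y)^2 against the analytic privacy nabla,

each with a Monte-Carlo standard error.  The MC standard error of the
empirical variance is computed from the sample fourth central moment of
the replicate estimates rather than the normal-theory 2*sigma^4/(R-1)
shortcut, because reported responses are generally non-normal (e.g. under
gamma scramblers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .estimators import estimate_mean
from .metrics import MetricsResult, compute_metrics
from .models import (
    ADDITIVE_MODELS,
    MULTIPLICATIVE_MODELS,
    ModelParams,
    generate_responses,
)
from .samplers import (
    PopulationSpec,
    SamplerHandle,
    ScramblerSpec,
    draw,
    substream_seed,
)

__all__ = ["SimulationDesign", "SimulationResult", "run_replicates", "verify_against_analytic"]


@dataclass(frozen=True)
class SimulationDesign:
    """One Monte-Carlo verification cell: mechanism, moments, R and n."""

    model: ModelParams
    pop: PopulationSpec
    additive: ScramblerSpec | None = None
    multiplicative: ScramblerSpec | None = None
    n: int = 500
    replicates: int = 10_000
    seed: int = 0
    privacy_mode: str = "first_principles"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("per-survey sample size n must be >= 2")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")


@dataclass(frozen=True)
class SimulationResult:
    """Empirical moments with MC standard errors, plus the analytic reference."""

    design: SimulationDesign
    mean_of_estimates: float
    empirical_variance: float
    empirical_privacy: float
    mc_se_mean: float
    mc_se_variance: float
    mc_se_privacy: float
    analytic: MetricsResult


def _variance_se(estimates: np.ndarray) -> float:
    """MC standard error of the sample variance via the fourth central moment.

    Var(s^2) = (m4 - (R-3)/(R-1) * m2^2) / R with central moments m2, m4.
    """
    r = estimates.size
    centred = estimates - estimates.mean()
    m2 = float(np.mean(centred**2))
    m4 = float(np.mean(centred**4))
    var_s2 = (m4 - (r - 3) / (r - 1) * m2 * m2) / r
    return math.sqrt(max(var_s2, 0.0))


def run_replicates(design: SimulationDesign) -> SimulationResult:
    """Simulate R surveys of size n and summarize against the analytic values.

    All R*n draws per variable come from one vectorized substream, so the
    replicates are mutually independent; the per-survey estimator is the
    sample mean of each row.
    """
    model = design.model.model
    r, n = design.replicates, design.n
    total = r * n
    seed = design.seed
    y = draw(SamplerHandle(design.pop, substream_seed(seed, "population")), total)
    s = t = None
    var_S = var_T = 0.0
    if model in ADDITIVE_MODELS:
        if design.additive is None:
            raise ValueError(f"{model.value} requires an additive ScramblerSpec")
        s = draw(SamplerHandle(design.additive, substream_seed(seed, "additive")), total)
        var_S = design.additive.variance
    if model in MULTIPLICATIVE_MODELS:
        if design.multiplicative is None:
            raise ValueError(f"{model.value} requires a multiplicative ScramblerSpec")
        t = draw(
            SamplerHandle(design.multiplicative, substream_seed(seed, "multiplicative")),
            total,
        )
        var_T = design.multiplicative.variance
    u = np.random.default_rng(
        np.random.SeedSequence(substream_seed(seed, "branch"))
    ).random(total)
    u2 = np.random.default_rng(
        np.random.SeedSequence(substream_seed(seed, "subbranch"))
    ).random(total)

    draws = generate_responses(design.model, y, s=s, t=t, u=u, u2=u2)
    z = draws.z_reported
    mu_hats = z.reshape(r, n).mean(axis=1)

    sq_dev = (z - y) ** 2
    empirical_privacy = float(sq_dev.mean())
    mc_se_privacy = float(sq_dev.std(ddof=1) / math.sqrt(total)) if total > 1 else 0.0

    analytic = compute_metrics(
        design.model,
        design.pop,
        var_S,
        var_T,
        design.n,
        privacy_mode=design.privacy_mode,
    )
    return SimulationResult(
        design=design,
        mean_of_estimates=float(mu_hats.mean()),
        empirical_variance=float(mu_hats.var(ddof=1)),
        empirical_privacy=empirical_privacy,
        mc_se_mean=float(mu_hats.std(ddof=1) / math.sqrt(r)),
        mc_se_variance=_variance_se(mu_hats),
        mc_se_privacy=mc_se_privacy,
        analytic=analytic,
    )


def _zscore(observed: float, reference: float, se: float) -> float:
    if se == 0.0:
        return 0.0 if observed == reference else math.inf
    return (observed - reference) / se


def verify_against_analytic(result: SimulationResult, k_sigma: float = 5.0) -> dict:
    """Per-metric pass/fail report comparing empirical and analytic values.

    Returns a JSON-serializable dict with observed z-scores for the mean
    (against mu_Y), the variance of the estimates (against the closed-form
    Var(mu_hat)) and the empirical privacy (against the analytic nabla of
    the design's privacy mode), each passed when |z| <= k_sigma.
    """
    if not k_sigma > 0:
        raise ValueError("k_sigma must be positive")
    checks = {
        "mean": _zscore(result.mean_of_estimates, result.design.pop.mu, result.mc_se_mean),
        "variance": _zscore(
            result.empirical_variance, result.analytic.variance, result.mc_se_variance
        ),
        "privacy": _zscore(
            result.empirical_privacy, result.analytic.privacy, result.mc_se_privacy
        ),
    }
    report = {
        "model": result.design.model.model.value,
        "privacy_mode": result.design.privacy_mode,
        "k_sigma": k_sigma,
        "metrics": {
            name: {"z": z, "pass": bool(abs(z) <= k_sigma)} for name, z in checks.items()
        },
    }
    report["all_pass"] = all(m["pass"] for m in report["metrics"].values())
    return report
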