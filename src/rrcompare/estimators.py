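"""Mean estimation from reported responses.

All six mechanisms share the same estimator: the plain sample mean of the
reported responses, unbiased for mu_Y when the additive scrambler is
centred (theta = 0) and E(T) = 1.  A bias-aware mode subtracts the known
additive offset when theta != 0; this is an extension beyond the standard
design and is labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import Model, ModelParams

__all__ = ["EstimateRecord", "estimate_mean", "additive_bias"]


@dataclass(frozen=True)
class EstimateRecord:
    """Point estimate of mu_Y from one survey.

    ``se_plugin`` is the plug-in standard error sqrt(s_z^2 / n) from the
    sample variance of the reported responses — a convenience for interval
    reporting, not a design-based formula.
    """

    mu_hat: float
    n: int
    model: Model | None = None
    se_plugin: float | None = None


def additive_bias(params: ModelParams, theta: float) -> float:
    """Expected offset E(Z) - mu_Y contributed by an additive scrambler mean.

    Zero for purely multiplicative mechanisms; theta scaled by the
    probability (and weight) with which S enters the reported response.
    """
    model = params.model
    if model is Model.WARNER_ADDITIVE:
        return theta
    if model is Model.GUPTA_OPTIONAL_ADDITIVE:
        return (1.0 - params.p) * theta
    if model is Model.MURTAZA_MIXED:
        return (1.0 - params.p) * params.alpha * theta
    if model is Model.GUPTA_MIXED_OPTIONAL:
        return (1.0 - params.p) * theta
    return 0.0


def estimate_mean(
    z,
    model: Model | ModelParams | None = None,
    theta: float = 0.0,
) -> EstimateRecord:
    """Sample mean of the reported responses.

    Parameters
    ----------
    z : array-like
        Reported responses from one survey.
    model : Model or ModelParams, optional
        Recorded in the result; a ``ModelParams`` is required when
        ``theta != 0`` so the additive offset can be subtracted
        (bias-aware mode).
    theta : float
        Mean of the additive scrambler; non-zero activates the bias-aware
        correction.
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("cannot estimate a mean from an empty response vector")
    mu_hat = float(z.mean())
    if theta != 0.0:
        if not isinstance(model, ModelParams):
            raise ValueError("bias-aware mode (theta != 0) requires ModelParams")
        mu_hat -= additive_bias(model, theta)
    model_id = model.model if isinstance(model, ModelParams) else model
    se = float(np.sqrt(z.var(ddof=1) / z.size)) if z.size > 1 else None
    return EstimateRecord(mu_hat=mu_hat, n=int(z.size), model=model_id, se_plugin=se)
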