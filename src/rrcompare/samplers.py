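"""Samplers for the sensitive variable and the scrambling variables.

Randomized-response mechanisms for quantitative sensitive questions are
specified only through the first two moments of three mutually independent
random variables:

* the sensitive variable ``Y`` with mean ``mu_Y`` and variance ``var_Y``,
* an additive scrambler ``S`` with mean ``theta`` (0 by default) and
  variance ``var_S``,
* a multiplicative scrambler ``T`` with mean 1 and variance ``var_T``.

All closed-form efficiency and privacy results depend on these moments
only, so the concrete distribution family is a free choice.  This module
provides method-of-moments samplers for a small set of families (normal,
gamma, lognormal, symmetric two-point) so that Monte-Carlo checks can be
repeated under different shapes without touching the analytic code.

Seeding contract: every draw stream is a pure function of ``(spec, seed)``.
Per-role sub-streams are derived from one master seed by hashing the role
name, so adding a model or variable to a run never perturbs the draws of
the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidSpecError",
    "PopulationSpec",
    "ScramblerSpec",
    "SamplerHandle",
    "moments_to_family_params",
    "draw",
    "substream_seed_sequence",
]


class InvalidSpecError(ValueError):
    """A moment/family combination that cannot define a valid distribution."""


POPULATION_FAMILIES = ("normal", "gamma", "lognormal")
SCRAMBLER_FAMILIES = ("normal", "gamma", "two_point")


@dataclass(frozen=True)
class PopulationSpec:
    """Moments and distribution family of the sensitive variable Y.

    Parameters
    ----------
    mu : float
        Population mean of the sensitive variable.
    var : float
        Population variance; must be non-negative.
    family : str
        One of ``normal``, ``gamma``, ``lognormal``.  The strictly positive
        families require ``mu > 0``.
    """

    mu: float
    var: float
    family: str = "normal"

    def __post_init__(self) -> None:
        if self.family not in POPULATION_FAMILIES:
            raise InvalidSpecError(
                f"unknown population family {self.family!r}; "
                f"choose from {POPULATION_FAMILIES}"
            )
        if not math.isfinite(self.mu):
            raise InvalidSpecError("population mean must be finite")
        if not (self.var >= 0.0):
            raise InvalidSpecError("population variance must be >= 0")
        if self.family in ("gamma", "lognormal") and not self.mu > 0.0:
            raise InvalidSpecError(
                f"{self.family} population requires a positive mean, got {self.mu}"
            )


@dataclass(frozen=True)
class ScramblerSpec:
    """Moments and family of a scrambling variable.

    ``kind='additive'`` describes S (mean ``theta``, default 0); the mean
    estimator of every additive model is unbiased only at ``theta = 0``,
    so a non-zero mean is rejected unless ``allow_biased=True`` is set
    explicitly (see :func:`rrcompare.estimators.estimate_mean` for the
    bias-aware correction).  ``kind='multiplicative'`` describes T, whose
    mean is fixed at 1 by the model definitions.
    """

    kind: str
    variance: float
    mean: float | None = None
    family: str = "normal"
    allow_biased: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "multiplicative"):
            raise InvalidSpecError(
                f"scrambler kind must be 'additive' or 'multiplicative', got {self.kind!r}"
            )
        if self.family not in SCRAMBLER_FAMILIES:
            raise InvalidSpecError(
                f"unknown scrambler family {self.family!r}; "
                f"choose from {SCRAMBLER_FAMILIES}"
            )
        if not (self.variance >= 0.0):
            raise InvalidSpecError("scrambler variance must be >= 0")
        if self.kind == "multiplicative":
            if self.mean is None:
                object.__setattr__(self, "mean", 1.0)
            elif self.mean != 1.0:
                raise InvalidSpecError(
                    "multiplicative scrambler must have mean 1 "
                    f"(got {self.mean}); the estimators rely on E(T)=1"
                )
        else:
            if self.mean is None:
                object.__setattr__(self, "mean", 0.0)
            elif self.mean != 0.0 and not self.allow_biased:
                raise InvalidSpecError(
                    "additive scrambler mean theta != 0 biases the plain mean "
                    "estimator; pass allow_biased=True to opt into the "
                    "bias-aware workflow"
                )
        if self.family == "gamma" and self.variance > 0.0 and not self.mean > 0.0:
            raise InvalidSpecError(
                f"gamma scrambler requires a positive mean, got {self.mean}"
            )


@dataclass(frozen=True)
class SamplerHandle:
    """A (spec, seed) pair; identical handles yield bitwise-identical streams."""

    spec: PopulationSpec | ScramblerSpec
    seed: int


def _spec_moments(spec: PopulationSpec | ScramblerSpec) -> tuple[float, float]:
    if isinstance(spec, PopulationSpec):
        return float(spec.mu), float(spec.var)
    return float(spec.mean), float(spec.variance)


def moments_to_family_params(spec: PopulationSpec | ScramblerSpec) -> dict:
    """Invert (mean, variance) to the family's native parameters.

    Returns a dict of parameters such that the induced distribution has
    exactly the requested mean and variance (method of moments).  A zero
    variance is represented as ``{"constant": mean}`` for every family.

    Raises
    ------
    InvalidSpecError
        If the combination is unsatisfiable (e.g. gamma with mean <= 0).
    """
    mean, var = _spec_moments(spec)
    if var == 0.0:
        return {"family": "degenerate", "constant": mean}
    family = spec.family
    if family == "normal":
        return {"family": "normal", "loc": mean, "scale": math.sqrt(var)}
    if family == "gamma":
        if mean <= 0.0:
            raise InvalidSpecError("gamma family needs mean > 0")
        # mean = shape*scale, var = shape*scale^2
        return {"family": "gamma", "shape": mean * mean / var, "scale": var / mean}
    if family == "lognormal":
        if mean <= 0.0:
            raise InvalidSpecError("lognormal family needs mean > 0")
        sigma2 = math.log1p(var / (mean * mean))
        return {
            "family": "lognormal",
            "mu_log": math.log(mean) - 0.5 * sigma2,
            "sigma_log": math.sqrt(sigma2),
        }
    if family == "two_point":
        # equal mass on mean +/- sqrt(var): mean exact, variance exact
        half = math.sqrt(var)
        return {"family": "two_point", "low": mean - half, "high": mean + half}
    raise InvalidSpecError(f"unknown family {family!r}")  # pragma: no cover


def draw(handle: SamplerHandle, count: int) -> np.ndarray:
    """Draw ``count`` i.i.d. values from the distribution the handle specifies.

    Deterministic: the same ``(spec, seed, count)`` gives a bitwise-identical
    vector.  Degenerate (zero-variance) specs return a constant vector.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    params = moments_to_family_params(handle.spec)
    rng = np.random.default_rng(np.random.SeedSequence(handle.seed))
    fam = params["family"]
    if fam == "degenerate":
        return np.full(count, params["constant"], dtype=float)
    if fam == "normal":
        return rng.normal(params["loc"], params["scale"], size=count)
    if fam == "gamma":
        return rng.gamma(params["shape"], params["scale"], size=count)
    if fam == "lognormal":
        return rng.lognormal(params["mu_log"], params["sigma_log"], size=count)
    if fam == "two_point":
        picks = rng.integers(0, 2, size=count)
        return np.where(picks == 0, params["low"], params["high"]).astype(float)
    raise InvalidSpecError(f"unknown family {fam!r}")  # pragma: no cover


def substream_seed_sequence(master_seed: int, role: str) -> np.random.SeedSequence:
    """Derive a per-role seed sequence from one master seed.

    The role name is hashed with CRC-32 (stable across processes and
    platforms, unlike built-in ``hash``), so each named variable gets an
    independent stream and adding a role never shifts the others.
    """
    return np.random.SeedSequence(master_seed, spawn_key=(zlib.crc32(role.encode()),))


def substream_seed(master_seed: int, role: str) -> int:
    """A 32-bit integer seed for the given role, usable as ``SamplerHandle.seed``."""
    return int(substream_seed_sequence(master_seed, role).generate_state(1)[0])
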