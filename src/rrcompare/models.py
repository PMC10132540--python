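"""The six quantitative randomized-response mechanisms.

Each mechanism maps a respondent's true value Y (plus scrambling noise)
to the reported response Z:

================================  ==============================================
model id                          reported response Z
================================  ==============================================
``warner_additive``               Y + S
``eichhorn_hayre``                T * Y
``gupta_optional_additive``       Y w.p. p;  Y + S w.p. 1 - p
``barlev_optional_multiplicative``Y w.p. p;  T * Y w.p. 1 - p
``murtaza_mixed``                 Y w.p. p;  T * Y + alpha * S w.p. 1 - p
``gupta_mixed_optional``          Y w.p. p;  Y + S w.p. (1-p)A;
                                  T * Y + S w.p. (1-p)(1-A)
================================  ==============================================

Branch selection consumes pre-drawn uniforms passed in explicitly, so the
same respondent stream can be replayed across models (common random
numbers).  The three-branch model uses a second uniform vector: scramble
when ``u1 >= p``, then take the additive branch when ``u2 < A``, matching
branch probabilities p, (1-p)A and (1-p)(1-A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .samplers import (
    PopulationSpec,
    ScramblerSpec,
    SamplerHandle,
    draw,
    substream_seed,
)

__all__ = ["Model", "ModelParams", "ResponseDraws", "generate_responses", "simulate_survey"]


class Model(str, Enum):
    """Identifiers for the six mechanisms, in canonical comparison order."""

    WARNER_ADDITIVE = "warner_additive"
    EICHHORN_HAYRE = "eichhorn_hayre"
    GUPTA_OPTIONAL_ADDITIVE = "gupta_optional_additive"
    BARLEV_OPTIONAL_MULTIPLICATIVE = "barlev_optional_multiplicative"
    MURTAZA_MIXED = "murtaza_mixed"
    GUPTA_MIXED_OPTIONAL = "gupta_mixed_optional"


#: models with a truthful-response probability p
OPTIONAL_MODELS = frozenset(
    {
        Model.GUPTA_OPTIONAL_ADDITIVE,
        Model.BARLEV_OPTIONAL_MULTIPLICATIVE,
        Model.MURTAZA_MIXED,
        Model.GUPTA_MIXED_OPTIONAL,
    }
)
#: models whose mechanism involves the additive scrambler S
ADDITIVE_MODELS = frozenset(
    {
        Model.WARNER_ADDITIVE,
        Model.GUPTA_OPTIONAL_ADDITIVE,
        Model.MURTAZA_MIXED,
        Model.GUPTA_MIXED_OPTIONAL,
    }
)
#: models whose mechanism involves the multiplicative scrambler T
MULTIPLICATIVE_MODELS = frozenset(
    {
        Model.EICHHORN_HAYRE,
        Model.BARLEV_OPTIONAL_MULTIPLICATIVE,
        Model.MURTAZA_MIXED,
        Model.GUPTA_MIXED_OPTIONAL,
    }
)


@dataclass(frozen=True)
class ModelParams:
    """A mechanism identifier with its design constants.

    ``p`` is the probability of a truthful report (optional models only;
    accepted at the closed boundaries 0 and 1).  ``A`` in (0, 1) splits the
    scrambled branch of the three-branch optional model.  ``alpha`` weights
    the additive noise in the mixed two-branch model.
    """

    model: Model
    p: float | None = None
    A: float | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        model = Model(self.model)
        object.__setattr__(self, "model", model)
        if model in OPTIONAL_MODELS:
            if self.p is None:
                raise ValueError(f"{model.value} requires p")
            if not (0.0 <= self.p <= 1.0):
                raise ValueError(f"p must lie in [0, 1], got {self.p}")
        elif self.p is not None:
            warnings.warn(
                f"{model.value} has no truthful-response probability; p ignored",
                stacklevel=3,
            )
            object.__setattr__(self, "p", None)
        if model is Model.GUPTA_MIXED_OPTIONAL:
            if self.A is None:
                raise ValueError("gupta_mixed_optional requires A")
            if not (0.0 < self.A < 1.0):
                raise ValueError(f"A must lie in (0, 1), got {self.A}")
        if model is Model.MURTAZA_MIXED:
            if self.alpha is None:
                raise ValueError("murtaza_mixed requires alpha")
            if not np.isfinite(self.alpha):
                raise ValueError("alpha must be finite")


@dataclass(frozen=True)
class ResponseDraws:
    """Vectorized respondent-level outcomes of one simulated survey."""

    y_true: np.ndarray
    z_reported: np.ndarray
    branch: np.ndarray  # str labels: direct / additive / multiplicative / mixed

    def __len__(self) -> int:
        return self.y_true.size


def _as_float_array(name: str, v) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim == 0:
        arr = arr.reshape(1)
    return arr


def generate_responses(
    params: ModelParams,
    y,
    s=None,
    t=None,
    u=None,
    u2=None,
) -> ResponseDraws:
    """Apply the mechanism element-wise to pre-drawn variable streams.

    Parameters
    ----------
    y, s, t : array-like
        True values and scrambler draws; ``s``/``t`` are required only by
        mechanisms that use them.
    u, u2 : array-like of uniforms on [0, 1)
        ``u`` selects the truthful branch (``u < p``); ``u2`` selects the
        sub-branch of the three-branch model (``u2 < A`` -> additive).
    """
    model = params.model
    y = _as_float_array("y", y)
    n = y.size

    def need(name: str, vec) -> np.ndarray:
        if vec is None:
            raise ValueError(f"{model.value} requires the {name} stream")
        arr = _as_float_array(name, vec)
        if arr.size != n:
            raise ValueError(
                f"length mismatch: y has {n} elements, {name} has {arr.size}"
            )
        return arr

    branch = np.empty(n, dtype="<U14")
    if model is Model.WARNER_ADDITIVE:
        z = y + need("s", s)
        branch[:] = "additive"
    elif model is Model.EICHHORN_HAYRE:
        z = need("t", t) * y
        branch[:] = "multiplicative"
    else:
        truthful = need("u", u) < params.p
        branch[truthful] = "direct"
        if model is Model.GUPTA_OPTIONAL_ADDITIVE:
            z = np.where(truthful, y, y + need("s", s))
            branch[~truthful] = "additive"
        elif model is Model.BARLEV_OPTIONAL_MULTIPLICATIVE:
            z = np.where(truthful, y, need("t", t) * y)
            branch[~truthful] = "multiplicative"
        elif model is Model.MURTAZA_MIXED:
            z = np.where(truthful, y, need("t", t) * y + params.alpha * need("s", s))
            branch[~truthful] = "mixed"
        else:  # GUPTA_MIXED_OPTIONAL
            s_arr, t_arr = need("s", s), need("t", t)
            additive = ~truthful & (need("u2", u2) < params.A)
            mixed = ~truthful & ~additive
            z = np.where(truthful, y, np.where(additive, y + s_arr, t_arr * y + s_arr))
            branch[additive] = "additive"
            branch[mixed] = "mixed"
    return ResponseDraws(y_true=y, z_reported=z, branch=branch)


def simulate_survey(
    params: ModelParams,
    pop: PopulationSpec,
    additive: ScramblerSpec | None = None,
    multiplicative: ScramblerSpec | None = None,
    n: int = 500,
    seed: int = 0,
) -> ResponseDraws:
    """Simulate one with-replacement survey of size ``n`` under a mechanism.

    Draws Y, S, T and the branch-selection uniforms from independent
    per-role substreams of ``seed`` and composes them with
    :func:`generate_responses`.  Scrambler specs are required only when the
    mechanism uses the corresponding variable.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    model = params.model
    y = draw(SamplerHandle(pop, substream_seed(seed, "population")), n)
    s = t = None
    if model in ADDITIVE_MODELS:
        if additive is None:
            raise ValueError(f"{model.value} requires an additive ScramblerSpec")
        s = draw(SamplerHandle(additive, substream_seed(seed, "additive")), n)
    if model in MULTIPLICATIVE_MODELS:
        if multiplicative is None:
            raise ValueError(f"{model.value} requires a multiplicative ScramblerSpec")
        t = draw(
            SamplerHandle(multiplicative, substream_seed(seed, "multiplicative")), n
        )
    rng_u = np.random.default_rng(np.random.SeedSequence(substream_seed(seed, "branch")))
    rng_u2 = np.random.default_rng(
        np.random.SeedSequence(substream_seed(seed, "subbranch"))
    )
    u = rng_u.random(n)
    u2 = rng_u2.random(n)
    return generate_responses(params, y, s=s, t=t, u=u, u2=u2)
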