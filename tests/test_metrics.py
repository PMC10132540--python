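"""Closed-form metric values, identities, and efficiency conditions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rrcompare import (
    Model,
    ModelParams,
    PopulationSpec,
    compute_metrics,
    delta_measure,
    efficiency_condition,
    privacy_as_printed,
    privacy_first_principles,
    variance_of_mean,
)
from rrcompare.metrics import EFFICIENCY_PAIRS

from test_models import params_for

ALL_MODELS = list(Model)

# moderate, well-scaled parameter ranges for property checks
pos = st.floats(0.0, 50.0, allow_nan=False)
mu_s = st.floats(-20.0, 20.0, allow_nan=False)
var_y_s = st.floats(0.0, 50.0, allow_nan=False)
p_s = st.floats(0.0, 1.0, allow_nan=False)
A_s = st.floats(0.01, 0.99, allow_nan=False)
alpha_s = st.floats(-2.0, 2.0, allow_nan=False)
n_s = st.integers(1, 100_000)


class TestSpotValues:
    """Frozen values from the published parameter grid (mu_Y=10, var_Y=2)."""

    def test_warner_variance(self, pop):
        v = variance_of_mean(ModelParams(Model.WARNER_ADDITIVE), pop, 6.0, 0.0, 500)
        assert v == pytest.approx(0.016)

    def test_murtaza_variance(self, pop):
        v = variance_of_mean(
            ModelParams(Model.MURTAZA_MIXED, p=0.3, alpha=0.9), pop, 6.0, 8.0, 500
        )
        assert v == pytest.approx(1.15612)

    def test_eichhorn_hayre_privacy(self, pop):
        nabla = privacy_as_printed(ModelParams(Model.EICHHORN_HAYRE), pop, 0.0, 8.0)
        assert nabla == pytest.approx(816.0)

    def test_three_branch_printed_privacy_constant_in_p(self, pop):
        values = [
            privacy_as_printed(
                ModelParams(Model.GUPTA_MIXED_OPTIONAL, p=p, A=0.8), pop, 6.0, 8.0
            )
            for p in (0.3, 0.5, 0.7)
        ]
        assert values == pytest.approx([169.2] * 3)

    def test_three_branch_first_principles_privacy_carries_1mp(self, pop):
        params = ModelParams(Model.GUPTA_MIXED_OPTIONAL, p=0.7, A=0.8)
        nabla = privacy_first_principles(params, pop, 6.0, 8.0)
        assert nabla == pytest.approx(0.3 * (6.0 + 0.2 * 816.0))  # 50.76
        assert nabla != pytest.approx(privacy_as_printed(params, pop, 6.0, 8.0))

    def test_murtaza_first_principles_matches_printed(self, pop):
        params = ModelParams(Model.MURTAZA_MIXED, p=0.3, alpha=0.9)
        nabla = privacy_first_principles(params, pop, 6.0, 8.0)
        assert nabla == pytest.approx(0.7 * (816.0 + 0.81 * 6.0))  # 574.602
        assert nabla == pytest.approx(privacy_as_printed(params, pop, 6.0, 8.0))

    def test_optional_additive_privacy_vanishes_at_p_one(self, pop):
        params = ModelParams(Model.GUPTA_OPTIONAL_ADDITIVE, p=1.0)
        assert privacy_as_printed(params, pop, 6.0, 0.0) == 0.0

    def test_warner_delta(self, pop):
        m = compute_metrics(ModelParams(Model.WARNER_ADDITIVE), pop, 6.0, 0.0, 500)
        assert round(m.delta, 6) == pytest.approx(0.002667)

    def test_three_branch_delta(self, pop):
        m = compute_metrics(
            ModelParams(Model.GUPTA_MIXED_OPTIONAL, p=0.7, A=0.8), pop, 6.0, 8.0, 500
        )
        assert round(m.delta, 6) == pytest.approx(0.000624)


class TestDeltaSentinels:
    def test_zero_variance_gives_zero(self):
        assert delta_measure(0.0, 5.0) == 0.0

    def test_positive_variance_zero_privacy_is_infinite(self):
        assert math.isinf(delta_measure(0.3, 0.0))

    def test_zero_over_zero_is_undefined(self):
        assert math.isnan(delta_measure(0.0, 0.0))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            delta_measure(-1.0, 2.0)


class TestProperties:
    @pytest.mark.parametrize("model", ALL_MODELS, ids=lambda m: m.value)
    @given(mu=mu_s, var_y=var_y_s, var_s=pos, var_t=pos, p=p_s, A=A_s, alpha=alpha_s, n=n_s)
    def test_delta_times_privacy_equals_variance(
        self, model, mu, var_y, var_s, var_t, p, A, alpha, n
    ):
        pop = PopulationSpec(mu=mu, var=var_y)
        params = params_for(model, p=p, A=A, alpha=alpha)
        m = compute_metrics(params, pop, var_s, var_t, n)
        if m.privacy > 0:
            assert m.delta * m.privacy == pytest.approx(m.variance, rel=1e-12)

    @pytest.mark.parametrize("model", ALL_MODELS, ids=lambda m: m.value)
    def test_variance_and_delta_scale_as_one_over_n(self, model, pop):
        params = params_for(model, p=0.3)
        v500 = variance_of_mean(params, pop, 6.0, 8.0, 500)
        v5000 = variance_of_mean(params, pop, 6.0, 8.0, 5000)
        assert v5000 == pytest.approx(v500 / 10.0, rel=1e-12)
        m500 = compute_metrics(params, pop, 6.0, 8.0, 500)
        m5000 = compute_metrics(params, pop, 6.0, 8.0, 5000)
        assert m5000.delta == pytest.approx(m500.delta / 10.0, rel=1e-12)
        assert m5000.privacy == m500.privacy  # nabla independent of n

    @pytest.mark.parametrize("model", ALL_MODELS, ids=lambda m: m.value)
    def test_direct_questioning_limit(self, model, pop):
        """All scrambler variances 0: Var = var_Y / n and nabla = 0."""
        params = params_for(model, p=0.4)
        assert variance_of_mean(params, pop, 0.0, 0.0, 500) == pytest.approx(2.0 / 500)
        assert privacy_as_printed(params, pop, 0.0, 0.0) == 0.0
        assert privacy_first_principles(params, pop, 0.0, 0.0) == 0.0

    @pytest.mark.parametrize(
        "model",
        [m for m in ALL_MODELS if m is not Model.GUPTA_MIXED_OPTIONAL],
        ids=lambda m: m.value,
    )
    @given(mu=mu_s, var_y=var_y_s, var_s=pos, var_t=pos, p=p_s, alpha=alpha_s)
    def test_printed_privacy_equals_first_principles_except_three_branch(
        self, model, mu, var_y, var_s, var_t, p, alpha
    ):
        pop = PopulationSpec(mu=mu, var=var_y)
        params = params_for(model, p=p, alpha=alpha)
        assert privacy_as_printed(params, pop, var_s, var_t) == pytest.approx(
            privacy_first_principles(params, pop, var_s, var_t)
        )

    @given(mu=mu_s, var_y=var_y_s, var_s=pos, var_t=pos, p=p_s, A=A_s)
    def test_three_branch_privacy_variants_differ_by_1mp(
        self, mu, var_y, var_s, var_t, p, A
    ):
        pop = PopulationSpec(mu=mu, var=var_y)
        params = ModelParams(Model.GUPTA_MIXED_OPTIONAL, p=p, A=A)
        printed = privacy_as_printed(params, pop, var_s, var_t)
        fp = privacy_first_principles(params, pop, var_s, var_t)
        assert fp == pytest.approx((1 - p) * printed, rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize(
        "model",
        [m for m in ALL_MODELS if m not in (Model.WARNER_ADDITIVE, Model.EICHHORN_HAYRE)],
        ids=lambda m: m.value,
    )
    def test_variance_and_privacy_nonincreasing_in_p(self, model, pop):
        ps = np.linspace(0.0, 1.0, 11)
        variances = [
            variance_of_mean(params_for(model, p=p), pop, 6.0, 8.0, 500) for p in ps
        ]
        assert np.all(np.diff(variances) <= 1e-12)
        if model is not Model.GUPTA_MIXED_OPTIONAL:  # printed form constant in p there
            privacies = [
                privacy_as_printed(params_for(model, p=p), pop, 6.0, 8.0) for p in ps
            ]
            assert np.all(np.diff(privacies) <= 1e-12)


class TestEfficiencyConditions:
    def test_additive_vs_multiplicative_condition_block1(self, pop):
        cmp = efficiency_condition("warner_vs_eichhorn_hayre", pop, 6.0, 8.0)
        assert cmp.first_more_efficient
        assert cmp.margin == pytest.approx(816.0 - 6.0)

    def test_condition_fails_with_degenerate_multiplicative_noise(self, pop):
        cmp = efficiency_condition("warner_vs_eichhorn_hayre", pop, 6.0, 0.0)
        assert not cmp.first_more_efficient

    def test_mixed_pair_condition_block1(self, pop):
        cmp = efficiency_condition(
            "gupta_mixed_vs_murtaza", pop, 6.0, 8.0, p=0.3, A=0.8, alpha=0.9
        )
        assert cmp.lhs == pytest.approx(0.8 * 0.7 * 816.0 + 0.81 * 6.0)  # 461.82
        assert cmp.rhs == pytest.approx(0.7 * 6.0)
        assert cmp.first_more_efficient

    def test_unknown_pair_rejected(self, pop):
        with pytest.raises(ValueError):
            efficiency_condition("nope", pop, 1.0, 1.0)

    @pytest.mark.parametrize("pair", EFFICIENCY_PAIRS)
    @given(mu=mu_s, var_y=var_y_s, var_s=pos, var_t=pos, p=p_s, A=A_s, alpha=alpha_s)
    def test_condition_agrees_with_direct_variance_comparison(
        self, pair, mu, var_y, var_s, var_t, p, A, alpha
    ):
        pop = PopulationSpec(mu=mu, var=var_y)
        first, second = {
            "warner_vs_eichhorn_hayre": (Model.WARNER_ADDITIVE, Model.EICHHORN_HAYRE),
            "gupta_additive_vs_barlev": (
                Model.GUPTA_OPTIONAL_ADDITIVE,
                Model.BARLEV_OPTIONAL_MULTIPLICATIVE,
            ),
            "gupta_mixed_vs_murtaza": (Model.GUPTA_MIXED_OPTIONAL, Model.MURTAZA_MIXED),
        }[pair]
        cmp = efficiency_condition(pair, pop, var_s, var_t, p=p, A=A, alpha=alpha)
        v1 = variance_of_mean(params_for(first, p, A, alpha), pop, var_s, var_t, 500)
        v2 = variance_of_mean(params_for(second, p, A, alpha), pop, var_s, var_t, 500)
        assert cmp.first_more_efficient == (v1 < v2)
        # the margin is the variance gap rescaled by n
        assert cmp.margin / 500 == pytest.approx(v2 - v1, rel=1e-9, abs=1e-12)
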