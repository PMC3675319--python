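"""Unit and property tests for the kinetic core: Hill factors, the ODE
right-hand side (against an independently hand-coded per-equation oracle),
equilibration, and the conservation laws of the tracer bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tim2iron import (
    EquilibrationError,
    InvalidParameterError,
    ModelParameters,
    StateDomainError,
    StateVector,
    equilibrate,
    hill_inhibit,
    hill_promote,
    rhs,
)
from tim2iron.model import STATE_NAMES


# ---------------------------------------------------------------------------
# Hill factors
# ---------------------------------------------------------------------------

class TestHillFactors:
    def test_promotion_half_maximal_at_threshold(self):
        assert hill_promote(2.5, alpha=0.8, k=2.5) == pytest.approx(0.4)

    def test_inhibition_unsuppressed_at_zero(self):
        assert hill_inhibit(0.0, alpha=0.7, k=1.3) == pytest.approx(0.7)

    def test_endocytosis_halved_at_saturation_threshold(self):
        # at ferritin level K47 the endocytosis rate drops to gamma7 / 2
        assert hill_inhibit(0.11, alpha=0.118, k=0.11) == pytest.approx(0.059)

    @pytest.mark.parametrize("bad_k", [0.0, -1.0])
    def test_nonpositive_threshold_rejected(self, bad_k):
        with pytest.raises(InvalidParameterError):
            hill_promote(1.0, 1.0, bad_k)
        with pytest.raises(InvalidParameterError):
            hill_inhibit(1.0, 1.0, bad_k)

    @settings(derandomize=True, max_examples=50)
    @given(
        x=st.floats(0.0, 1e3),
        alpha=st.floats(0.0, 10.0),
        k=st.floats(1e-6, 1e3),
    )
    def test_both_factors_bounded_by_alpha(self, x, alpha, k):
        assert 0.0 <= hill_promote(x, alpha, k) <= alpha
        assert 0.0 <= hill_inhibit(x, alpha, k) <= alpha
        assert hill_promote(x, alpha, k) + hill_inhibit(x, alpha, k) == pytest.approx(alpha)


# ---------------------------------------------------------------------------
# Parameter validation
# ---------------------------------------------------------------------------

class TestModelParameters:
    def test_conservation_defaults(self, params):
        assert params.alpha10 == pytest.approx(1.0 - params.alpha9)
        assert params.alpha11 == 1.0

    @pytest.mark.parametrize(
        "changes",
        [
            {"gamma7": -0.1},
            {"K47": 0.0},
            {"alpha9": 1.4},
            {"alpha10": -0.2},
        ],
    )
    def test_invalid_values_rejected(self, changes):
        with pytest.raises(InvalidParameterError):
            ModelParameters(**changes)

    def test_unknown_name_rejected(self):
        with pytest.raises(InvalidParameterError):
            ModelParameters.from_dict({"gamma7": 0.1, "not_a_rate": 1.0})

    def test_storage_release_balance_is_four_to_one(self, params):
        # the preload partition 80%/20% requires storage/release ratio 4
        assert params.storage_coefficient() / params.gamma4 == pytest.approx(4.0)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def _rhs_oracle(y, p, tim2_present=True, media_reference=None, ferritin_media=True):
    """Straight per-equation transliteration of the governing equations,
    written independently of the packaged implementation: every flux is
    spelled out term by term and summed per state variable."""
    x1, x2, x3, x4, x5, x6, x7, x8, x9, mu, me = y
    d = dict.fromkeys(STATE_NAMES, 0.0)

    # media fraction scaling of the lumped combination coefficient
    if mu <= 0:
        frac = 0.0
    elif media_reference is None:
        frac = 1.0
    else:
        frac = min(mu / media_reference, 1.0) if media_reference > 0 else 0.0

    x2eq_x5 = p.alpha5 * p.k15 / (p.k15 + 0.0) / p.gamma5  # resting IRP level
    s4 = p.alpha4_storage * p.k54 / (p.k54 + (x2eq_x5 if p.frozen_core else x5))

    # LIP balance: direct uptake, ferritin release, export, storage
    d["x1"] += p.alpha1_Feex_x2 * max(mu, 0.0)
    d["media_unbound"] -= p.alpha1_Feex_x2 * max(mu, 0.0)
    d["x1"] += p.gamma4 * x4
    d["x4"] -= p.gamma4 * x4
    d["x1"] -= p.alpha6_x3_eff * x1
    d["media_exported"] += p.alpha6_x3_eff * x1
    d["x1"] -= s4 * x1
    d["x4"] += s4 * x1

    if tim2_present:
        binding = (p.alpha7_Ftex if ferritin_media else 0.0) * x6 * frac
        d["x6"] -= binding
        d["x7"] += binding
        d["media_unbound"] -= binding
        d["x6"] += p.gamma6 * x8
        d["x8"] -= p.gamma6 * x8
        suppressed = p.gamma7 * p.K47 / (p.K47 + x4 + x9) * x7
        d["x7"] -= suppressed
        d["x8"] += suppressed
        source = p.gamma7 * x7 if p.literal_processing else suppressed
        d["x9"] += p.alpha9 * source
        d["x1"] += p.alpha10 * source
    d["x9"] -= p.gamma9 * x9
    d["x1"] += p.alpha11 * p.gamma9 * x9

    if not p.frozen_core:
        d["x2"] = p.alpha2 * x5 / (p.k52 + x5) - p.gamma2 * x2
        d["x3"] = p.alpha3 * p.k53 / (p.k53 + x5) - (p.gamma3 + p.gammah_Hep) * x3
        d["x5"] = p.alpha5 * p.k15 / (p.k15 + x1) - p.gamma5 * x5
    return np.array([d[n] for n in STATE_NAMES])


class TestRightHandSide:
    def test_matches_per_equation_oracle(self, params):
        rng = np.random.default_rng(42)
        for frozen in (True, False):
            p = params.replace(frozen_core=frozen)
            for _ in range(25):
                y = rng.uniform(0.01, 10.0, size=11)
                expected = _rhs_oracle(y, p, media_reference=25.0)
                got = rhs(y, p, media_reference=25.0)
                np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-15)

    def test_surviving_hft_pure_decay(self, params):
        state = StateVector(x9=1.0)
        d = rhs(state, params)
        assert d[8] == pytest.approx(-0.00031)
        assert d[0] == pytest.approx(0.00031 * params.alpha11)

    def test_no_free_receptor_means_no_binding(self, params):
        state = StateVector(x6=0.0, x8=2.0, media_unbound=25.0)
        d = rhs(state, params, media_reference=25.0)
        assert d[5] == pytest.approx(params.gamma6 * 2.0)   # recycling only
        assert d[6] == pytest.approx(0.0)                   # no binding into x7

    def test_vector_cells_have_inert_receptor_dynamics(self, params):
        state = StateVector(x6=5.0, x7=1.0, x8=1.0, media_unbound=25.0)
        d = rhs(state, params, tim2_present=False, media_reference=25.0)
        assert d[5] == d[6] == d[7] == 0.0

    def test_negative_state_rejected(self, params):
        y = np.zeros(11)
        y[0] = -1.0
        with pytest.raises(StateDomainError):
            rhs(y, params)

    @settings(derandomize=True, max_examples=40)
    @given(data=st.lists(st.floats(0.0, 50.0), min_size=11, max_size=11))
    def test_tracer_and_receptor_conservation_pointwise(self, data, params):
        """With the conservation defaults, label and receptor capacity are
        conserved by construction at every state: the labelled-pool
        derivatives sum to zero, as do the x6/x7/x8 derivatives."""
        d = rhs(np.array(data), params, media_reference=25.0)
        label = d[0] + d[3] + d[6] + d[8] + d[9] + d[10]
        assert abs(label) < 1e-12 * (1.0 + np.max(np.abs(d)))
        assert abs(d[5] + d[6] + d[7]) < 1e-12 * (1.0 + np.max(np.abs(d)))


# ---------------------------------------------------------------------------
# Equilibration
# ---------------------------------------------------------------------------

class TestEquilibrate:
    def test_zero_label_environment_has_empty_pools(self, params):
        s = equilibrate(params, tim2_capacity=8.4)
        for name in ("x1", "x4", "x7", "x9", "media_unbound", "media_exported"):
            assert getattr(s, name) == 0.0
        assert s.x6 == 8.4 and s.x8 == 0.0

    @pytest.mark.parametrize("frozen", [True, False])
    def test_zero_label_residual_below_tolerance(self, params, frozen):
        p = params.replace(frozen_core=frozen)
        s = equilibrate(p, tim2_capacity=8.4)
        residual = np.max(np.abs(rhs(s, p)))
        assert residual < 1e-9

    def test_preload_splits_eighty_twenty(self, params):
        # storage/release balance at ratio 4 puts 80% of the preload in
        # endogenous ferritin and 20% in the LIP
        s = equilibrate(params, cell_preload=10.8)
        assert s.x4 == pytest.approx(0.8 * 10.8)
        assert s.x1 == pytest.approx(0.2 * 10.8)

    def test_negative_environment_rejected(self, params):
        with pytest.raises(InvalidParameterError):
            equilibrate(params, media_label=-1.0)
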