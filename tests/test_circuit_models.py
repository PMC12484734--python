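import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pev import circuit_models as cm

# Independent brute-force oracle: each cell's activity written out directly
# as a rectified weighted difference, one expression per (model, cell type).
# sigma2 multiplies the stimulus or divides the prediction as the model
# prescribes; nothing is shared with the implementation.
ORACLE = {
    ("P", "pPE"): lambda s, E, v, ws, wp: max(0.0, ws * s - wp * E / v),
    ("P", "nPE"): lambda s, E, v, ws, wp: max(0.0, wp * E / v - ws * s),
    ("S", "pPE"): lambda s, E, v, ws, wp: max(0.0, ws * v * s - wp * E),
    ("S", "nPE"): lambda s, E, v, ws, wp: max(0.0, wp * E - ws * v * s),
    ("I", "pPE"): lambda s, E, v, ws, wp: max(0.0, ws * s - wp * E / v),
    ("I", "nPE"): lambda s, E, v, ws, wp: max(0.0, wp * E - ws * v * s),
    ("D", "pPE"): lambda s, E, v, ws, wp: max(0.0, ws * v * s - wp * E),
    ("D", "nPE"): lambda s, E, v, ws, wp: max(0.0, wp * E / v - ws * s),
}

FIXED = cm.FIXED_CONDITION
VARIABLE = cm.VARIABLE_CONDITION


def test_sigma_s_matches_discrete_uniform_intensities():
    # SD of the 3/5/7 intensity representation of the 30/50/70% set
    assert cm.discrete_uniform_sd((3, 5, 7)) == pytest.approx(np.sqrt(8 / 3))
    assert round(cm.discrete_uniform_sd((3, 5, 7)), 1) == 1.6
    assert VARIABLE.sigma_sq == pytest.approx(1 + 1.6**2)


@pytest.mark.parametrize("model_id", cm.MODEL_IDS)
@pytest.mark.parametrize("cell_type", cm.CELL_TYPES)
@pytest.mark.parametrize("cond", [FIXED, VARIABLE], ids=["fixed", "variable"])
@pytest.mark.parametrize("s", [9.0, 1.0])
def test_equations_match_brute_force_oracle(model_id, cell_type, cond, s):
    rng = np.random.default_rng(17)
    weight_sets = [(1.0, 1.0)] + [tuple(rng.uniform(0.001, 0.05, 2)) for _ in range(5)]
    for ws, wp in weight_sets:
        expected = ORACLE[(model_id, cell_type)](s, cond.E_s, cond.sigma_sq, ws, wp)
        got = cm.pe_response(model_id, cell_type, cond, s, ws, wp)
        assert got == pytest.approx(expected, abs=1e-12)


def test_unweighted_hand_values():
    # fixed condition (sigma^2 = 1): every model reduces to max(0, 9 - 5) = 4
    for m in cm.MODEL_IDS:
        assert cm.pe_response(m, "pPE", FIXED, 9.0) == pytest.approx(4.0, abs=1e-12)
    # variable condition (sigma^2 = 3.56)
    assert cm.pe_response("P", "pPE", VARIABLE, 9.0) == pytest.approx(
        9.0 - 5.0 / 3.56, abs=1e-12
    )
    assert cm.pe_response("S", "pPE", VARIABLE, 9.0) == pytest.approx(
        3.56 * 9.0 - 5.0, abs=1e-12
    )
    # stimulus-modulated nPE drive exceeds the prediction: rectified to 0
    assert cm.pe_response("S", "nPE", VARIABLE, 9.0) == 0.0


def test_all_models_identical_when_variability_is_zero():
    rng = np.random.default_rng(3)
    w = rng.uniform(0.001, 0.05, (20, 2))
    for cell in cm.CELL_TYPES:
        s = 9.0 if cell == "pPE" else 1.0
        outs = [
            cm.pe_response(m, cell, FIXED, s, w[:, 0], w[:, 1]) for m in cm.MODEL_IDS
        ]
        for other in outs[1:]:
            np.testing.assert_array_equal(outs[0], other)


def test_monotonicity_in_variability_for_every_circuit():
    """pPE non-decreasing and (pre-modulation) nPE non-increasing in sigma_s."""
    w = cm.sample_weights(50, seed=11)
    sigmas = [0.0, 0.5, 1.0, 1.6, 2.5]
    for m in cm.MODEL_IDS:
        prev_p = prev_n = None
        for s_s in sigmas:
            cond = cm.ConditionParams(sigma_s=s_s)
            p = cm.pe_response(m, "pPE", cond, cond.s_pos, w[:, 0], w[:, 1])
            n = cm.pe_response(m, "nPE", cond, cond.s_neg, w[:, 0], w[:, 1])
            if prev_p is not None:
                assert np.all(p >= prev_p - 1e-12)
                assert np.all(n <= prev_n + 1e-12)
            prev_p, prev_n = p, n


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    c=st.floats(min_value=1e-3, max_value=1e3),
    ws=st.floats(min_value=1e-4, max_value=0.05),
    wp=st.floats(min_value=1e-4, max_value=0.05),
)
def test_scale_equivariance_of_weights(c, ws, wp):
    for m in cm.MODEL_IDS:
        for cell, s in (("pPE", 9.0), ("nPE", 1.0)):
            base = cm.pe_response(m, cell, VARIABLE, s, ws, wp)
            scaled = cm.pe_response(m, cell, VARIABLE, s, c * ws, c * wp)
            assert scaled == pytest.approx(c * base, rel=1e-9)


def test_rectification_nonnegative():
    rng = np.random.default_rng(9)
    for m in cm.MODEL_IDS:
        sim = cm.simulate_population(m, seed=int(rng.integers(2**31)), npe_modulation="none")
        assert (sim["activity"] >= 0).all()


class TestSampleWeights:
    def test_pooled_maximum_exactly_max_weight(self):
        for n in (1, 5, 50):
            w = cm.sample_weights(n, seed=n)
            assert w.max() == 0.05
            assert w.shape == (n, 2)

    def test_all_weights_positive_and_bounded(self):
        w = cm.sample_weights(200, seed=1)
        assert np.all(w > 0)
        assert np.all(w <= 0.05)

    def test_log_sd_matches_shape_parameter(self):
        # normalization shifts log-weights by a constant, so the log-SD of
        # the normalized draws equals the pre-normalization shape parameter
        w = cm.sample_weights(10_000, shape=1.0, seed=2)
        assert np.log(w).std() == pytest.approx(1.0, rel=0.03)

    def test_deterministic_given_seed(self):
        np.testing.assert_array_equal(
            cm.sample_weights(10, seed=7), cm.sample_weights(10, seed=7)
        )

    def test_invalid_parameters_error(self):
        with pytest.raises(ValueError):
            cm.sample_weights(0)
        with pytest.raises(ValueError):
            cm.sample_weights(5, max_weight=-1.0)
        with pytest.raises(ValueError):
            cm.sample_weights(5, shape=0.0)


class TestSimulatePopulation:
    def test_output_shape_and_labels(self):
        sim = cm.simulate_population("I", seed=0, npe_modulation="none")
        assert len(sim) == 4 * 50
        counts = sim.groupby(["cell_type", "condition"]).size()
        assert (counts == 50).all()

    def test_variability_direction_per_circuit(self):
        """Variability raises every pPE circuit's activity and lowers every
        nPE circuit's pre-modulation activity (weights shared across
        conditions)."""
        for m in cm.MODEL_IDS:
            sim = cm.simulate_population(m, seed=4, npe_modulation="none")
            wide = sim.pivot_table(
                index=["cell_type", "circuit_id"],
                columns="condition",
                values="activity_premod",
            )
            ppe = wide.loc["pPE"]
            npe = wide.loc["nPE"]
            assert np.all(ppe["variable"] >= ppe["fixed"] - 1e-12)
            assert np.all(npe["variable"] <= npe["fixed"] + 1e-12)

    def test_models_collapse_when_both_conditions_fixed(self):
        cond = cm.ConditionParams(sigma_s=0.0)
        sims = [
            cm.simulate_population(m, cond, cond, seed=5, npe_modulation="none")
            for m in cm.MODEL_IDS
        ]
        for other in sims[1:]:
            np.testing.assert_array_equal(
                sims[0]["activity"].to_numpy(), other["activity"].to_numpy()
            )

    def test_sigma_s_modulation_zeroes_fixed_npe_with_warning(self):
        with pytest.warns(UserWarning, match="sigma_s"):
            sim = cm.simulate_population("I", seed=6, npe_modulation="sigma_s")
        npe_fixed = sim[(sim.cell_type == "nPE") & (sim.condition == "fixed")]
        assert (npe_fixed["activity"] == 0).all()
        assert (npe_fixed["activity_premod"] > 0).any()

    def test_npe_modulation_factor_options(self):
        assert cm.npe_modulation_factor("none", VARIABLE) == 1.0
        assert cm.npe_modulation_factor("sigma_s", VARIABLE) == 1.6
        assert cm.npe_modulation_factor("sigma_total", VARIABLE) == pytest.approx(
            np.sqrt(3.56)
        )
        assert cm.npe_modulation_factor("sigma_s_floor1", FIXED) == 1.0

    def test_s_model_ppe_exceeds_i_model_by_variance_factor(self):
        # unweighted variable-condition ratio: (3.56*9-5)/(9-5/3.56) = 3.56
        s_val = cm.pe_response("S", "pPE", VARIABLE, 9.0)
        i_val = cm.pe_response("I", "pPE", VARIABLE, 9.0)
        assert s_val / i_val == pytest.approx(3.56, abs=1e-12)
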