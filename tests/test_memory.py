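import numpy as np
import pytest

from conceptdrift.events import EdgeEvent
from conceptdrift.memory import (
    ContextMessage,
    IntegrationCell,
    TimeEncoder,
    aggregate_messages,
    apply_graphlet,
    context_aggregate,
    contextual_integrate,
    encode_time,
    init_states,
)


def zero_cell(d_in, d):
    cell = IntegrationCell(d_in, d, np.random.default_rng(0))
    for p in cell.parameters():
        p.data = np.zeros_like(p.data)
    return cell


def zero_encoder(d_time):
    enc = TimeEncoder(d_time)
    enc.omega.data = np.zeros(d_time)
    enc.phase.data = np.zeros(d_time)
    return enc


class TestInitStates:
    def test_identity_when_dims_match(self):
        X = np.arange(12.0).reshape(3, 4)
        store = init_states(X, 4, projection="off")
        np.testing.assert_array_equal(store.states, X)

    def test_last_update_zero_after_init(self):
        store = init_states(np.ones((3, 4)), 4)
        assert (store.last_update == 0).all()

    def test_row_count_mismatch_fatal(self):
        store = init_states(np.ones((3, 4)), 4)
        # mismatch is caught at model level; here projection off + wrong d
        with pytest.raises(ValueError):
            init_states(np.ones((3, 4)), 8, projection="off")

    def test_projection_engaged_when_dims_differ(self):
        rng = np.random.default_rng(0)
        store = init_states(rng.normal(size=(5, 4)), 8)
        assert store.projection is not None
        assert store.states.shape == (5, 8)


class TestEncodeTime:
    def test_zero_params_give_linear_zero_and_cos_one(self):
        enc = zero_encoder(5)
        np.testing.assert_allclose(encode_time(enc, 3.7), [0, 1, 1, 1, 1])

    def test_pi_frequency_gives_minus_one(self):
        enc = zero_encoder(3)
        enc.omega.data = np.array([0.0, np.pi, 0.0])
        out = encode_time(enc, 1.0)
        np.testing.assert_allclose(out[1], -1.0, atol=1e-12)

    def test_deterministic(self):
        enc = TimeEncoder(8, np.random.default_rng(1))
        a = encode_time(enc, 2.5)
        b = encode_time(enc, 2.5)
        np.testing.assert_array_equal(a, b)

    def test_output_length(self):
        for d_time in (1, 2, 9):
            assert encode_time(TimeEncoder(d_time), 4.0).shape == (d_time,)


class TestContextAggregate:
    def test_concatenation_layout(self):
        store = init_states(np.array([[1.0, 2.0], [3.0, 4.0]]), 2, "off")
        enc = zero_encoder(2)
        enc.omega.data = np.array([0.0, 0.0])
        enc.phase.data = np.array([0.0, np.pi / 2])
        msg = context_aggregate(store, enc, 0, 1, 5)
        np.testing.assert_allclose(msg.vector, [1, 2, 3, 4, 0, np.cos(np.pi / 2)])

    def test_length_is_2d_plus_dtime(self):
        store = init_states(np.ones((4, 3)), 3, "off")
        enc = TimeEncoder(6)
        assert context_aggregate(store, enc, 0, 1, 2).vector.shape == (12,)

    def test_endpoint_views_swap_state_blocks(self):
        store = init_states(np.array([[1.0, 2.0], [3.0, 4.0]]), 2, "off")
        enc = zero_encoder(2)
        mi = context_aggregate(store, enc, 0, 1, 3)
        mj = context_aggregate(store, enc, 1, 0, 3)
        np.testing.assert_array_equal(mi.vector[:2], mj.vector[2:4])
        np.testing.assert_array_equal(mi.vector[2:4], mj.vector[:2])

    def test_stale_time_fatal(self):
        store = init_states(np.ones((2, 2)), 2, "off")
        store.last_update[0] = 5
        with pytest.raises(ValueError):
            context_aggregate(store, TimeEncoder(2), 0, 1, 3)


class TestAggregateMessages:
    def test_single_message_unchanged(self):
        m = ContextMessage(np.array([1.0, 2.0]), 0, 1)
        assert aggregate_messages([m]) is m

    def test_mean_of_two(self):
        a = ContextMessage(np.array([1.0, 1.0]), 0, 1)
        b = ContextMessage(np.array([3.0, 3.0]), 0, 1)
        np.testing.assert_allclose(aggregate_messages([a, b]).vector, [2, 2])

    def test_permutation_invariant(self):
        msgs = [
            ContextMessage(np.array([float(k), -float(k)]), 2, 3)
            for k in range(5)
        ]
        fwd = aggregate_messages(msgs).vector
        rev = aggregate_messages(msgs[::-1]).vector
        np.testing.assert_array_equal(fwd, rev)

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            aggregate_messages([])


class TestContextualIntegrate:
    def test_zero_parameters_halve_previous_state(self):
        # r = u = sigmoid(0) = 0.5, n = tanh(0) = 0 -> s' = 0.5 * s_prev
        cell = zero_cell(6, 2)
        msg = ContextMessage(np.ones(6), 0, 1)
        out = contextual_integrate(cell, msg, np.array([0.8, -0.4]))
        np.testing.assert_allclose(out, [0.4, -0.2])

    def test_finite_output_right_length(self):
        rng = np.random.default_rng(0)
        cell = IntegrationCell(10, 4, rng)
        msg = ContextMessage(rng.normal(size=10), 0, 1)
        out = contextual_integrate(cell, msg, rng.normal(size=4))
        assert out.shape == (4,) and np.isfinite(out).all()

    def test_update_gate_saturated_keeps_state(self):
        cell = zero_cell(6, 3)
        cell.bu.data = np.full(3, 1e3)  # u -> 1 => s' = s_prev
        msg = ContextMessage(np.ones(6), 0, 1)
        s = np.array([0.3, -0.2, 0.9])
        np.testing.assert_allclose(contextual_integrate(cell, msg, s), s)

    def test_hand_evaluated_gates_match(self):
        rng = np.random.default_rng(5)
        cell = IntegrationCell(4, 2, rng)
        x = rng.normal(size=4)
        h = rng.normal(size=2)

        def sig(v):
            return 1 / (1 + np.exp(-v))

        r = sig(x @ cell.Wr.data + h @ cell.Ur.data + cell.br.data)
        u = sig(x @ cell.Wu.data + h @ cell.Uu.data + cell.bu.data)
        n = np.tanh(x @ cell.Wn.data + r * (h @ cell.Un.data) + cell.bn.data)
        expected = (1 - u) * n + u * h
        out = contextual_integrate(cell, ContextMessage(x, 0, 1), h)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_dimension_mismatch_fatal(self):
        cell = zero_cell(6, 2)
        with pytest.raises(ValueError):
            contextual_integrate(cell, ContextMessage(np.ones(5), 0, 1), np.ones(2))


class TestApplyGraphlet:
    def setup_store(self, n=4, d=3, d_time=2, seed=0):
        rng = np.random.default_rng(seed)
        store = init_states(rng.normal(size=(n, d)), d, "off")
        cell = IntegrationCell(2 * d + d_time, d, rng)
        enc = TimeEncoder(d_time, rng)
        return store, cell, enc

    def test_touched_concepts_update_bookkeeping(self):
        store, cell, enc = self.setup_store()
        apply_graphlet(store, cell, enc, [EdgeEvent(2, 1, 2)], 2)
        assert store.last_update[1] == store.last_update[2] == 2
        assert store.last_update[0] == store.last_update[3] == 0

    def test_empty_graphlet_is_noop_on_states(self):
        store, cell, enc = self.setup_store()
        before = store.states.copy()
        apply_graphlet(store, cell, enc, [], 1)
        np.testing.assert_array_equal(store.states, before)

    def test_saturated_update_gate_preserves_states(self):
        store, cell, enc = self.setup_store()
        for p in cell.parameters():
            p.data = np.zeros_like(p.data)
        cell.bu.data = np.full(3, 1e3)
        before = store.states.copy()
        apply_graphlet(store, cell, enc, [EdgeEvent(1, 0, 1)], 1)
        np.testing.assert_allclose(store.states, before)
        assert store.last_update[0] == 1

    def test_locality_untouched_rows_bitwise_identical(self):
        store, cell, enc = self.setup_store()
        before = store.states.copy()
        apply_graphlet(store, cell, enc, [EdgeEvent(1, 0, 1)], 1)
        np.testing.assert_array_equal(store.states[2:], before[2:])

    def test_order_independence_within_step(self):
        events = [EdgeEvent(1, 0, 1), EdgeEvent(1, 1, 2), EdgeEvent(1, 0, 3)]
        store_a, cell, enc = self.setup_store(seed=3)
        store_b = store_a.copy()
        apply_graphlet(store_a, cell, enc, events, 1)
        apply_graphlet(store_b, cell, enc, events[::-1], 1)
        np.testing.assert_array_equal(store_a.states, store_b.states)

    def test_out_of_order_step_fatal(self):
        store, cell, enc = self.setup_store()
        apply_graphlet(store, cell, enc, [EdgeEvent(2, 0, 1)], 2)
        with pytest.raises(ValueError):
            apply_graphlet(store, cell, enc, [EdgeEvent(1, 0, 1)], 1)

    def test_states_stay_finite_and_shaped(self):
        store, cell, enc = self.setup_store()
        for t in range(1, 4):
            apply_graphlet(store, cell, enc, [EdgeEvent(t, 0, 1 + t % 3)], t)
        assert store.states.shape == (4, 3)
        assert np.isfinite(store.states).all()
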