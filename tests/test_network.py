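import numpy as np
import pytest

import skan
from skan import (NetParams, SkanParams, connection_count, inhibition_update,
                  init_network, network_step)
from skan.network import NetworkState, run_reference_network


def _network(dr_rows, theta, n_inputs=2):
    dr = np.asarray(dr_rows, dtype=np.int64)
    n = dr.shape[0]
    return NetworkState(
        p=np.zeros((n, n_inputs), np.int64),
        r=np.zeros((n, n_inputs), np.int64),
        dr=dr,
        theta=np.full(n, theta, np.int64),
        s=np.zeros(n, np.int64),
        inh=0,
    )


class TestInhibitionCounter:
    def test_reload_on_any_spike(self):
        assert inhibition_update(37, 1, NetParams(n_neurons=2)) == 100

    def test_decay_when_quiet(self):
        assert inhibition_update(50, 0, NetParams(n_neurons=2)) == 49

    def test_zero_is_absorbing(self):
        assert inhibition_update(0, 0, NetParams(n_neurons=2)) == 0

    def test_large_decay_clamped(self):
        assert inhibition_update(5, 0, NetParams(n_neurons=2, inh_decay=7)) == 0


class TestConnectionCount:
    @pytest.mark.parametrize("n_in,n_neu,expected", [(2, 2, 8), (4, 4, 24), (0, 0, 0)])
    def test_values(self, n_in, n_neu, expected):
        assert connection_count(n_in, n_neu) == expected

    def test_linear_in_neurons(self):
        base = connection_count(16, 1)
        assert all(connection_count(16, n) == n * base for n in range(1, 9))


class TestCompetition:
    def test_inhibition_blocks_late_riser(self, params2, net2):
        # A's kernels are steeper, so A crosses first; B's membrane crosses
        # B's threshold a few steps later while inh > 0: B stays silent and
        # B's threshold is untouched by the whole presentation
        state = _network([[400, 400], [200, 200]], theta=12000)
        raster = np.zeros((300, 2), dtype=np.uint8)
        raster[0] = 1
        s_out, mem, theta, _, inh = skan.run_network_traced(state, raster, params2, net2)
        assert s_out[:, 0].any() and not s_out[:, 1].any()
        b_crossings = np.flatnonzero(mem[:, 1] > 12000)
        assert b_crossings.size and np.all(inh[b_crossings - 1] > 0)
        assert np.all(theta[:, 1] == 12000)

    def test_ongoing_pulse_survives_inhibition(self, params2):
        # a spiking neuron reloads the counter itself yet keeps spiking:
        # the gate admits continuation (s_prev = 1), only initiations are vetoed
        net = NetParams(n_neurons=1)
        state = _network([[300, 300]], theta=4000)
        raster = np.zeros((200, 2), dtype=np.uint8)
        raster[0] = 1
        s_out, _, _, _, inh = skan.run_network_traced(state, raster, params2, net)
        widths = np.diff(np.flatnonzero(np.diff(
            np.concatenate([[0], s_out[:, 0], [0]]))).reshape(-1, 2), axis=1)
        assert widths.max() > 1
        during = np.flatnonzero(s_out[:, 0] == 1)
        assert np.all(inh[during] == net.inh_max)  # held for the whole pulse

    def test_exact_tie_both_spike_and_adapt(self, params2, net2):
        state = _network([[250, 250], [250, 250]], theta=9000)
        raster = np.zeros((250, 2), dtype=np.uint8)
        raster[0] = 1
        s_out = skan.run_network(state, raster, params2, net2)
        first = [np.flatnonzero(s_out[:, n])[0] for n in (0, 1)]
        assert first[0] == first[1]
        assert np.array_equal(state.dr[0], state.dr[1])
        assert state.dr[0, 0] != 250  # adaptation happened for both

    def test_winner_threshold_falls_at_own_falling_edge(self, params2):
        # with inhibition active at membrane return, the spiking neuron's
        # threshold takes its fall at the end of its own pulse instead
        net = NetParams(n_neurons=1)
        state = _network([[300, 300]], theta=4000)
        raster = np.zeros((300, 2), dtype=np.uint8)
        raster[0] = 1
        s_out, mem, theta, _, inh = skan.run_network_traced(state, raster, params2, net)
        edge = np.flatnonzero(np.diff(s_out[:, 0].astype(int)) == -1)[0] + 1
        assert theta[edge, 0] == theta[edge - 1, 0] - params2.theta_fall
        back = np.flatnonzero((mem[1:, 0] == 0) & (mem[:-1, 0] > 0))[0] + 1
        assert inh[back - 1] > 0                  # return-to-zero fall suppressed
        assert theta[back, 0] == theta[back - 1, 0]


class TestHiding:
    """Inhibition is the only coupling: freeze neuron A and delete its
    pattern, and B's trajectory is unchanged if B never answered A's
    pattern."""

    def test_loser_trajectory_independent_of_hidden_pattern(self):
        from skan.experiments import _edge_counts
        params = SkanParams(n_inputs=2)
        net = NetParams(n_neurons=2)
        rng = np.random.default_rng(42)
        x = skan.SpikePattern(np.array([0, 0]), 20)
        y = skan.SpikePattern(np.array([0, 10]), 20)
        stream = skan.build_sequence([x, y], (0.5, 0.5), 120, skan.NoiseSpec(),
                                     400, rng)
        # A pre-tuned to the simultaneous pattern, B to the ISI-10 one, with
        # thresholds close enough to the peaks that each answers only its own
        full = _network([[400, 400], [286, 400]], theta=19500)
        raster = stream.raster()
        lab = stream.pattern_ids
        probe = full.copy()
        s_out = skan.run_network(probe, raster, params, net)
        counts = _edge_counts(s_out, 120, 400)
        assert np.all((counts[:, 0] > 0) == (lab == 0))   # A answers exactly x
        assert np.all((counts[:, 1] > 0) == (lab == 1))   # B answers exactly y
        # delete A's pattern and drop A: B's trajectory is bit-identical
        masked = raster.copy()
        for k in np.flatnonzero(lab == 0):
            masked[k * 400:(k + 1) * 400] = 0
        b_alone = _network([[286, 400]], theta=19500)
        s_alone = skan.run_network(b_alone, masked, params, NetParams(n_neurons=1))
        assert np.array_equal(s_out[:, 1], s_alone[:, 0])
        assert np.array_equal(probe.dr[1], b_alone.dr[0])
        assert probe.theta[1] == b_alone.theta[0]


class TestReferenceStep:
    def test_step_matches_loop_engine(self, params2, net2, rng):
        raster = (rng.random((1200, 2)) < 0.02).astype(np.uint8)
        state = init_network(params2, net2, np.random.default_rng(5))
        ref, s_ref, inh_ref = run_reference_network(state.copy(), raster, params2, net2)
        eng = state.copy()
        s_eng = skan.run_network(eng, raster, params2, net2)
        assert np.array_equal(s_ref, s_eng)
        assert ref.state_hash() == eng.state_hash()
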