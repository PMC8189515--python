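import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from hierspread.engine import (
    STATE_I,
    STATE_R,
    STATE_S,
    DosageParams,
    _py_step,
    _spawn_streams,
    init_states,
    micro_step,
    run,
    run_ensemble,
    truncated_normal,
)
from hierspread.layered import LayeredGraph
from hierspread.seeding import SeedSpec

from .conftest import single_layer


def det_params(**kw):
    """Parameters with zero-variance thresholds/doses for exact oracles."""
    base = dict(
        T=1,
        r=0.2,
        threshold_mean=1.0,
        threshold_sd=0.0,
        dose_mean=10.0,
        dose_sd=0.0,
    )
    base.update(kw)
    return DosageParams(**base)


class TestInitStates:
    def test_threshold_moments_match_truncated_gaussian(self):
        # oracle: scipy truncnorm moments of N(1, 0.5) restricted to > 0
        g = nx.empty_graph(100_000)
        lg = single_layer(g)
        params = DosageParams()
        st = init_states(lg, params, set(), np.random.default_rng(0))
        a = (0.0 - 1.0) / 0.5
        expect_mean = stats.truncnorm.mean(a, np.inf, loc=1.0, scale=0.5)
        expect_sd = stats.truncnorm.std(a, np.inf, loc=1.0, scale=0.5)
        n = lg.n_nodes
        assert st.thresholds.min() > 0
        assert abs(st.thresholds.mean() - expect_mean) < 4 * expect_sd / np.sqrt(n)
        assert abs(st.thresholds.std() - expect_sd) < 0.01
        # headline parameters: mean about 1, sd about 0.5
        assert st.thresholds.mean() == pytest.approx(1.0, abs=0.05)
        assert st.thresholds.std() == pytest.approx(0.5, abs=0.05)

    def test_no_seeds_all_susceptible(self, path3):
        st = init_states(path3, DosageParams(), set(), np.random.default_rng(0))
        assert st.counts() == (3, 0, 0)
        assert st.memory.shape == (3, 5) and not st.memory.any()

    def test_same_stream_seed_identical_thresholds(self, path3):
        a = init_states(path3, DosageParams(), {0}, np.random.default_rng(7))
        b = init_states(path3, DosageParams(), {0}, np.random.default_rng(7))
        np.testing.assert_array_equal(a.thresholds, b.thresholds)

    def test_unknown_seed_rejected(self, path3):
        with pytest.raises(ValueError, match="subset"):
            init_states(path3, DosageParams(), {99}, np.random.default_rng(0))


class TestMicroStep:
    def test_removed_speaker_confers_zero_dose(self, path3):
        st = init_states(path3, det_params(), {1}, np.random.default_rng(0))
        st.state[1] = STATE_R
        indptr, indices, layer, _ = path3.csr()
        # listener 0 (u_l < 1/3) must pick neighbor 1, its only neighbor
        _, speaker, dose, transition = _py_step(
            indptr, indices, layer,
            st.thresholds, st.state, st.memory, st.mem_ptr,
            1, 0.0, True, 0.1, 0.5, 10.0, 0.9,
        )
        assert speaker == 1 and dose == 0.0 and transition is None

    def test_all_susceptible_is_frozen(self, path3):
        params = DosageParams(max_micro_steps=3000)
        res = run(path3, params, set(), rng_master_seed=1)
        assert res.peak_i == 0
        assert (res.i == 0).all() and (res.r == 0).all() and (res.s == 3).all()

    def test_manager_override_guarantees_switch(self, manager_staff_pair, rng):
        # property: an S listener hearing an infected higher-layer
        # speaker switches on that step, whatever its memory holds
        g = manager_staff_pair
        indptr, indices, layer, _ = g.csr()
        params = DosageParams()
        for _ in range(200):
            st = init_states(g, params, {1}, rng)
            st.memory[0] = rng.random(params.T)  # arbitrary prior doses
            _, speaker, dose, transition = _py_step(
                indptr, indices, layer,
                st.thresholds, st.state, st.memory, st.mem_ptr,
                params.T, params.r, True,
                0.2, 0.5, 0.0, 0.99,  # listener 0, dose variate unused
            )
            assert speaker == 1
            assert dose == pytest.approx(st.thresholds[0])
            assert transition == "S->I"

    def test_first_switch_time_is_geometric_mean_two(self, manager_staff_pair):
        # staff must be drawn as listener (p = 1/2); override then switches
        # it instantly, so the first-switch time is geometric with mean 2
        g = manager_staff_pair
        params = det_params(si_mode=True, max_micro_steps=500)
        times = []
        for seed in range(4000):
            res = run(g, params, {1}, rng_master_seed=seed, backend="python")
            times.append(res.steps)
        mean = np.mean(times)
        se = np.std(times) / np.sqrt(len(times))
        assert abs(mean - 2.0) < 3 * se + 1e-9

    def test_micro_step_api_runs(self, path3):
        streams = _spawn_streams(3)
        st = init_states(path3, DosageParams(), {0}, streams["thresholds"])
        st2, (l, s, dose, tr) = micro_step(st, path3, DosageParams(), streams)
        assert st2 is st and 0 <= l < 3


class TestRunInvariants:
    def test_conservation_and_monotone_removal(self, small_hierarchy):
        g, _ = small_hierarchy
        params = DosageParams(max_micro_steps=200_000)
        res = run(g, params, set(g.nodes_in_layer(2)[:5]), rng_master_seed=2)
        n = g.n_nodes
        np.testing.assert_array_equal(res.s + res.i + res.r, n)
        assert (np.diff(res.r) >= 0).all()

    def test_si_mode_monotone_and_consensus_absorbing(self, small_hierarchy):
        g, _ = small_hierarchy
        params = DosageParams(si_mode=True, max_micro_steps=2_000_000)
        res = run(g, params, {0}, rng_master_seed=3)
        assert (np.diff(res.i) >= 0).all()
        assert res.i[-1] == g.n_nodes  # connected graph reaches consensus

    def test_fully_seeded_si_run_is_instant_consensus(self, path3):
        params = DosageParams(si_mode=True)
        res = run(path3, params, {0, 1, 2}, rng_master_seed=4)
        assert res.i[0] == 3 and res.peak_i == 3 and res.peak_epoch == 0

    def test_absorption_with_positive_removal(self, path3):
        params = det_params(r=0.5, dose_mean=0.1, max_micro_steps=100_000)
        res = run(path3, params, {0}, rng_master_seed=5)
        assert res.extinction_epoch is not None
        assert res.i[-1] == 0

    def test_isolated_seed_removed_at_geometric_rate(self):
        # r=1: the lone seed is removed the first time it listens
        # (degree-0 listener logs a null dose); time ~ geometric(1/3)
        g = nx.empty_graph(3)
        lg = single_layer(g)
        params = det_params(r=1.0, max_micro_steps=10_000)
        times = [
            run(lg, params, {0}, rng_master_seed=s).steps for s in range(3000)
        ]
        mean, sd = np.mean(times), np.std(times)
        assert abs(mean - 3.0) < 3 * sd / np.sqrt(len(times))

    def test_seed_cap_binds(self, path3):
        params = DosageParams(si_mode=True, max_micro_steps=7)
        res = run(path3, params, {0}, rng_master_seed=6)
        assert res.steps <= 7

    def test_run_reproducible_from_master_seed(self, small_hierarchy):
        g, _ = small_hierarchy
        params = DosageParams(max_micro_steps=50_000)
        a = run(g, params, {0, 1}, rng_master_seed=11)
        b = run(g, params, {0, 1}, rng_master_seed=11)
        np.testing.assert_array_equal(a.i, b.i)
        assert a.peak_i == b.peak_i and a.steps == b.steps

    def test_python_and_numba_backends_agree(self, small_hierarchy):
        g, _ = small_hierarchy
        params = DosageParams(max_micro_steps=30_000)
        seeds = set(g.nodes_in_layer(2)[:3])
        a = run(g, params, seeds, rng_master_seed=13, backend="numba")
        b = run(g, params, seeds, rng_master_seed=13, backend="python")
        np.testing.assert_array_equal(a.i, b.i)
        np.testing.assert_array_equal(a.s, b.s)
        assert a.peak_i == b.peak_i and a.steps == b.steps

    def test_event_log_matches_trajectory(self, path3):
        params = det_params(si_mode=True, max_micro_steps=1000)
        res = run(path3, params, {0}, rng_master_seed=8, record_events=True)
        switches = [e for e in res.events if e[4] == "S->I"]
        assert len(switches) == 2  # nodes 1 and 2 adopt exactly once


def enumerate_si_path3_expected_steps():
    """Exact expected micro-steps to consensus on the 0-1-2 path.

    Seed {0}, T=1, deterministic dose above every threshold: node 1
    adopts when drawn as listener (p=1/3) with speaker 0 (p=1/2); then
    node 2 adopts when drawn as listener (p=1/3, speaker forced).
    Geometric stage means: 6 + 3.
    """
    return 6.0 + 3.0


class TestExactChainOracles:
    def test_si_consensus_time_matches_enumeration(self, path3):
        params = det_params(si_mode=True, max_micro_steps=5000)
        times = [
            run(path3, params, {0}, rng_master_seed=s).steps
            for s in range(3000)
        ]
        expect = enumerate_si_path3_expected_steps()
        se = np.std(times) / np.sqrt(len(times))
        assert abs(np.mean(times) - expect) < 3 * se

    def test_sir_absorption_statistics_match_enumeration(self, path3):
        # exact 27-state chain over {S,I,R}^3 for T=1, zero-variance doses:
        # transitions depend only on current states, so full enumeration
        # of the jump matrix is an independent oracle
        r = 0.2
        graph_neighbors = {0: [1], 1: [0, 2], 2: [1]}
        states = list(itertools.product([0, 1, 2], repeat=3))
        index = {s: k for k, s in enumerate(states)}
        P = np.zeros((27, 27))
        for s in states:
            k = index[s]
            for listener in range(3):
                p_l = 1 / 3
                nbrs = graph_neighbors[listener]
                for speaker in nbrs:
                    p = p_l / len(nbrs)
                    target = list(s)
                    if s[listener] == 0 and s[speaker] == 1:
                        target[listener] = 1
                        P[k, index[tuple(target)]] += p
                    elif s[listener] == 1 and s[speaker] != 1:
                        P[k, index[tuple(target)]] += p * (1 - r)
                        target[listener] = 2
                        P[k, index[tuple(target)]] += p * r
                    else:
                        P[k, k] += p
        start = index[(1, 0, 0)]
        # absorption distribution: iterate to the stationary point; the
        # all-infected pattern is absorbing too (every speaker infected
        # keeps D above threshold, so nobody can be removed)
        dist = np.zeros(27)
        dist[start] = 1.0
        for _ in range(20_000):
            dist = dist @ P
        absorbing = [s for s in states if 1 not in s] + [(1, 1, 1)]
        exact = {s: dist[index[s]] for s in absorbing}
        assert abs(sum(exact.values()) - 1.0) < 1e-9

        params = det_params(r=r, max_micro_steps=1500)
        n_mc = 2000
        counts = {s: 0 for s in absorbing}
        for seed in range(n_mc):
            # event recording recovers the node-level terminal pattern
            res = run(
                path3, params, {0}, rng_master_seed=seed, record_events=True
            )
            node_state = [1, 0, 0]  # node 0 seeded
            for _, l, _, _, tr in res.events:
                node_state[l] = 1 if tr == "S->I" else 2
            counts[tuple(node_state)] += 1
        for s in absorbing:
            p_exact = exact[s]
            p_mc = counts[s] / n_mc
            se = np.sqrt(max(p_exact * (1 - p_exact), 1e-12) / n_mc)
            assert abs(p_mc - p_exact) < max(3 * se, 0.01), (s, p_mc, p_exact)


class TestEnsemble:
    def test_identical_master_seeds_bit_identical_summary(self, path3):
        params = det_params(si_mode=True, max_micro_steps=2000)
        spec = SeedSpec(strategy="random", level=1, count=1)
        seeds = list(range(20))
        a = run_ensemble(path3, params, spec, 20, seeds)
        b = run_ensemble(path3, params, spec, 20, seeds)
        np.testing.assert_array_equal(a.i_max, b.i_max)
        np.testing.assert_array_equal(a.mean_i, b.mean_i)

    def test_duplicate_master_seeds_rejected(self, path3):
        params = DosageParams()
        spec = SeedSpec(strategy="random", level=1, count=1)
        with pytest.raises(ValueError, match="duplicate"):
            run_ensemble(path3, params, spec, 3, [1, 1, 2])

    def test_hierarchical_dominates_flat_under_crn(self, small_hierarchy):
        g, _ = small_hierarchy
        spec = SeedSpec(strategy="random", level=2, count=3)
        seeds = list(range(120))
        hier = run_ensemble(
            g, DosageParams(max_micro_steps=300_000), spec, 120, seeds
        )
        flat = run_ensemble(
            g,
            DosageParams(manager_override=False, max_micro_steps=300_000),
            spec,
            120,
            seeds,
        )
        diff = hier.i_max - flat.i_max
        assert diff.mean() > 0

    def test_seed_fragility_of_single_seeds(self, small_hierarchy):
        # seeds start with empty memories, so many single-seed runs die
        # before spreading: extinction must be common and often immediate
        g, _ = small_hierarchy
        spec = SeedSpec(strategy="random", level=1, count=1)
        summ = run_ensemble(
            g, DosageParams(max_micro_steps=200_000), spec, 100,
            list(range(100)),
        )
        assert np.isnan(summ.extinction_epoch).sum() == 0
        assert (summ.i_max <= 2 / g.n_nodes).mean() > 0.2


class TestTruncatedSampler:
    def test_zero_variance_returns_constant(self, rng):
        np.testing.assert_array_equal(
            truncated_normal(rng, 0.5, 0.0, 4), np.full(4, 0.5)
        )

    def test_strict_positive_truncation(self, rng):
        vals = truncated_normal(rng, 0.1, 1.0, 20_000, strict_positive=True)
        assert vals.min() > 0
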