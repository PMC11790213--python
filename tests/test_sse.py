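"""SSE framework: model space, band discretizer, likelihood, fitting."""

import math

import dendropy
import numpy as np
import pytest

from edgsim.sse import (DIVERSIFICATION_STRUCTURES, ElevationSSE,
                        SSEModelSpec, TreeData, aic_weights, assign_bands,
                        bd_loglik, enumerate_models, fit_model_set, mk_loglik,
                        simulate_sse_tree, sse_loglik)
from edgsim.sse.fit import ElevationSSEResults, ModelSetResults

from _sse_oracle import reference_sse_loglik


class TestModelSpace:
    def test_fifteen_models(self):
        models = enumerate_models()
        assert len(models) == 15
        assert len({m.model_id for m in models}) == 15

    @pytest.mark.parametrize("structure, n_trans", [
        ("a", 1), ("b", 2), ("c", 1), ("d", 2), ("e", 6)])
    def test_transition_parameter_counts(self, structure, n_trans):
        spec = SSEModelSpec(structure, "CR")
        assert spec.n_transition_params == n_trans

    def test_adjacent_symmetric_template_forbids_direct_low_high(self):
        spec = SSEModelSpec("a", "CR")
        lam, mu, Q = spec.build_rates([0.5, 0.1, 0.3])
        assert Q[0, 1] == Q[1, 0] == Q[1, 2] == Q[2, 1] == 0.3
        assert Q[0, 2] == Q[2, 0] == 0.0
        assert np.allclose(Q.sum(axis=1), 0.0)

    def test_any_band_asymmetric_uses_two_rates(self):
        spec = SSEModelSpec("d", "CR")
        _, _, Q = spec.build_rates([0.5, 0.1, 0.4, 0.2])
        assert Q[0, 1] == Q[1, 2] == Q[0, 2] == 0.4   # uphill
        assert Q[1, 0] == Q[2, 1] == Q[2, 0] == 0.2   # downhill

    def test_concealed_specs_expand_state_space(self):
        spec = SSEModelSpec("a", "CTD")
        lam, mu, Q = spec.build_rates([0.5, 0.8, 1.1, 0.1, 0.3])
        assert lam.shape == (9,) and Q.shape == (9, 9)
        # speciation depends only on the concealed state
        assert np.allclose(lam, np.repeat([0.5, 0.8, 1.1], 3))
        # no simultaneous observed+concealed jumps
        assert Q[0, 4] == 0.0

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            SSEModelSpec("a", "CR").build_rates([0.5, -0.1, 0.3])


class TestBandAssignment:
    def test_middle_third_is_midland(self):
        bands = assign_bands({"a": 0.0, "b": 1500.0, "c": 3000.0}).bands
        assert bands == {"a": 0, "b": 1, "c": 2}

    def test_extremes_are_lowland_and_highland(self):
        a = assign_bands({"lo": 120.0, "mid": 800.0, "hi": 2500.0})
        assert a.bands["lo"] == 0 and a.bands["hi"] == 2

    def test_boundary_species_assigned_to_lower_band(self):
        # span 600-1500 m: cut points at 900 and 1200
        a = assign_bands({"a": 600.0, "b": 900.0, "c": 1200.0, "d": 1500.0})
        assert a.bands["b"] == 0 and a.bands["c"] == 1
        assert a.boundaries == (900.0, 1200.0)

    def test_degenerate_elevations_rejected(self):
        with pytest.raises(ValueError):
            assign_bands({"a": 100.0, "b": 100.0})


@pytest.fixture(scope="module")
def small_tree():
    gen = SSEModelSpec("b", "ETD")
    sim = simulate_sse_tree(gen, [0.6, 0.9, 1.2, 0.15, 0.35, 0.2],
                            n_tips=10, seed=3)
    return TreeData.from_newick(sim.newick), sim.tip_states


class TestLikelihood:
    ORACLE_CASES = [
        (SSEModelSpec("a", "CR"), [0.7, 0.1, 0.3]),
        (SSEModelSpec("c", "CR"), [0.7, 0.1, 0.2]),
        (SSEModelSpec("e", "CR"), [0.7, 0.1, 0.1, 0.2, 0.3, 0.15, 0.25, 0.05]),
        (SSEModelSpec("b", "ETD"), [0.6, 0.9, 1.2, 0.15, 0.35, 0.2]),
        (SSEModelSpec("a", "CTD"), [0.5, 0.8, 1.1, 0.1, 0.3]),
        (SSEModelSpec("d", "CTD"), [0.5, 0.8, 1.1, 0.1, 0.3, 0.2]),
    ]

    @pytest.mark.parametrize("spec, params", ORACLE_CASES,
                             ids=[s.model_id for s, _ in ORACLE_CASES])
    def test_matches_independent_pruning_oracle(self, small_tree, spec,
                                                params):
        td, states = small_tree
        fast = sse_loglik(td, states, spec, params)
        slow = reference_sse_loglik(td, states, spec, params)
        assert fast == pytest.approx(slow, abs=1e-6)

    def test_constant_rates_factorize_into_bd_times_mk(self, small_tree):
        """With state-independent diversification the likelihood equals the
        closed-form birth-death term plus the Markov tip-state term."""
        td, states = small_tree
        spec = SSEModelSpec("a", "CR")
        params = [0.8, 0.2, 0.25]
        lam, mu, Q = spec.build_rates(params)
        full = sse_loglik(td, states, spec, params)
        split = bd_loglik(td, 0.8, 0.2) + mk_loglik(td, states, Q)
        assert full == pytest.approx(split, abs=1e-6)

    @pytest.mark.parametrize("n_tips, seed", [(10, 1), (25, 2), (50, 3)])
    def test_bd_limit_across_tree_sizes(self, n_tips, seed):
        spec = SSEModelSpec("c", "CR")
        sim = simulate_sse_tree(spec, [0.9, 0.3, 0.4], n_tips=n_tips,
                                seed=seed)
        td = TreeData.from_newick(sim.newick)
        params = [0.85, 0.25, 0.3]
        lam, mu, Q = spec.build_rates(params)
        full = sse_loglik(td, sim.tip_states, spec, params)
        split = bd_loglik(td, 0.85, 0.25) + mk_loglik(td, sim.tip_states, Q)
        assert full == pytest.approx(split, abs=1e-6)

    def test_state_relabeling_symmetry(self, small_tree):
        td, states = small_tree
        spec = SSEModelSpec("e", "ETD")
        params = np.array([0.6, 0.9, 1.2, 0.2,      # lam L, M, H, mu
                           0.1, 0.2, 0.3, 0.15, 0.25, 0.05])
        ll = sse_loglik(td, states, spec, params)
        # swap lowland <-> highland everywhere
        swapped_states = {k: {0: 2, 1: 1, 2: 0}[v] for k, v in states.items()}
        # q order: LM, LH, ML, MH, HL, HM  ->  HM, HL, MH, ML, LH, LM
        q = params[4:]
        swapped = np.array([1.2, 0.9, 0.6, 0.2,
                            q[5], q[4], q[3], q[2], q[1], q[0]])
        ll_swapped = sse_loglik(td, swapped_states, spec, swapped,
                                root_prior="uniform")
        ll_base = sse_loglik(td, states, spec, params, root_prior="uniform")
        assert ll_swapped == pytest.approx(ll_base, abs=1e-8)

    def test_zero_transition_rates_make_mixed_tips_impossible(self,
                                                              small_tree):
        td, states = small_tree
        assert len(set(states.values())) >= 2
        ll = sse_loglik(td, states, SSEModelSpec("a", "CR"), [0.7, 0.1, 0.0])
        assert ll == -math.inf

    def test_missing_tip_state_integrated_over(self, small_tree):
        td, states = small_tree
        spec = SSEModelSpec("a", "CR")
        params = [0.7, 0.1, 0.3]
        label = td.tip_labels[0]
        lls = []
        for s in (0, 1, 2):
            st2 = dict(states)
            st2[label] = s
            lls.append(sse_loglik(td, st2, spec, params))
        st2 = dict(states)
        st2[label] = None
        marginal = sse_loglik(td, st2, spec, params)
        assert marginal == pytest.approx(
            np.log(np.exp(lls).sum()), abs=1e-6)

    def test_non_ultrametric_tree_rejected(self):
        with pytest.raises(ValueError, match="ultrametric"):
            TreeData.from_newick("((a:1.0,b:2.0):1.0,c:3.0);")

    def test_non_binary_tree_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            TreeData.from_newick("((a:1,b:1,c:1):1,d:2);")


class TestSimulator:
    def test_tip_count_states_and_ultrametry(self):
        spec = SSEModelSpec("d", "ETD")
        sim = simulate_sse_tree(spec, [0.6, 0.8, 1.0, 0.1, 0.3, 0.2],
                                n_tips=30, seed=8)
        td = TreeData.from_newick(sim.newick)
        assert td.n_tips == 30
        assert set(sim.tip_states) == set(td.tip_labels)
        assert set(sim.tip_states.values()) <= {0, 1, 2}

    def test_seeded_reproducibility(self):
        spec = SSEModelSpec("a", "CR")
        s1 = simulate_sse_tree(spec, [0.7, 0.1, 0.3], n_tips=15, seed=5)
        s2 = simulate_sse_tree(spec, [0.7, 0.1, 0.3], n_tips=15, seed=5)
        assert s1.newick == s2.newick and s1.tip_states == s2.tip_states

    def test_concealed_simulation_reports_observed_band(self):
        spec = SSEModelSpec("a", "CTD")
        sim = simulate_sse_tree(spec, [0.4, 0.7, 1.0, 0.1, 0.3],
                                n_tips=20, seed=6)
        for label, full in sim.tip_full_states.items():
            assert sim.tip_states[label] == full % 3


class TestFitting:
    def test_aic_weights_normalize(self):
        w = aic_weights([10.0, 12.0, 30.0])
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert w[0] > w[1] > w[2]

    def test_single_model_weight_is_one(self):
        assert aic_weights([123.4]) == pytest.approx([1.0])

    def test_identical_aics_share_weight_equally(self):
        w = aic_weights([50.0] * 15)
        assert np.allclose(w, 1 / 15)

    def test_nested_structures_never_lose_likelihood(self, small_tree):
        """Structure b contains a (equal up/down rates), so its maximized
        log-likelihood cannot be smaller."""
        td, states = small_tree
        ra = ElevationSSE(td, states, "a", "CR").fit(n_starts=2, seed=0)
        embed = np.array([ra.params[0], ra.params[1],
                          ra.params[2], ra.params[2]])
        rb = ElevationSSE(td, states, "b", "CR").fit(
            n_starts=1, seed=0, extra_starts=[embed])
        assert rb.loglik >= ra.loglik - 1e-6

    def test_fit_recovers_local_optimum(self):
        """On simulated data the fitted likelihood is a local maximum:
        perturbing any parameter away decreases it."""
        gen = SSEModelSpec("a", "CR")
        sim = simulate_sse_tree(gen, [0.7, 0.15, 0.25], n_tips=40, seed=77)
        model = ElevationSSE(sim.newick, sim.tip_states, spec=gen)
        res = model.fit(n_starts=2, seed=1)
        assert res.converged
        for i in range(len(res.params)):
            for f in (0.7, 1.4):
                pert = res.params.copy()
                pert[i] *= f
                assert model.loglik(pert) <= res.loglik + 1e-6

    def test_summary_reports_estimates(self):
        gen = SSEModelSpec("a", "CR")
        sim = simulate_sse_tree(gen, [0.7, 0.15, 0.25], n_tips=25, seed=5)
        res = ElevationSSE(sim.newick, sim.tip_states, spec=gen).fit(
            n_starts=1, seed=0)
        text = res.summary()
        assert "log-likelihood" in text and "AIC" in text
        assert "lambda" in text and "q" in text

    def test_model_set_table_and_family_pooling(self, sse_recovery_runs):
        for row in sse_recovery_runs:
            assert row["weights_sum"] == pytest.approx(1.0, abs=1e-9)
            assert set(row["families"]) <= set(DIVERSIFICATION_STRUCTURES)

    def test_true_family_wins_on_simulated_data(self, sse_recovery_runs):
        """Data simulated under the constant-rate adjacent-symmetric model:
        the constant-rate family takes the largest pooled AIC weight in the
        majority of replicates."""
        wins = sum(max(r["families"], key=r["families"].get) == "CR"
                   for r in sse_recovery_runs)
        assert wins > len(sse_recovery_runs) / 2

    def test_elevations_to_bands_entry_point(self):
        gen = SSEModelSpec("a", "CR")
        sim = simulate_sse_tree(gen, [0.7, 0.15, 0.25], n_tips=12, seed=9)
        elev = {lab: 200.0 + 1000.0 * s + 50.0 * i
                for i, (lab, s) in enumerate(sim.tip_states.items())}
        m = ElevationSSE.from_elevations(sim.newick, elev)
        assert set(m.tip_states.values()) <= {0, 1, 2}
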