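import itertools
import math

import numpy as np
import pytest

from bicontrol import (
    BinomialNull,
    BipartiteNetwork,
    BooleanBipartiteModel,
    BooleanConfig,
    GeometricModel,
    PoissonNull,
    count_output_states,
    entropy_single_node,
    evaluate,
    expected_value,
    fig3_sweep,
    mean_entropy,
    mean_robustness,
    omega_estimate,
    p_fragile,
    robustness_closed_form,
    robustness_exhaustive,
    robustness_simulation,
)
from conftest import random_network


# ---------------------------------------------------------------------------
# independent oracles: pure-python dict/set implementations
# ---------------------------------------------------------------------------
def oracle_outputs(net, inputs: dict, rule: str) -> tuple:
    out = []
    for t in net.targets:
        ctrls = net.controllers_of(t)
        states = [inputs[c] for c in ctrls]
        if not states:
            out.append(0)
        elif rule == "OR":
            out.append(int(any(states)))
        elif rule == "AND":
            out.append(int(all(states)))
        else:  # MAJORITY: strictly more than half active
            out.append(int(sum(states) * 2 > len(states)))
    return tuple(out)


def oracle_count_states(net, rule: str) -> int:
    seen = set()
    for bits in itertools.product((0, 1), repeat=net.M):
        seen.add(oracle_outputs(net, dict(zip(net.controllers, bits)), rule))
    return len(seen)


def oracle_robustness(net, gamma: int, rule: str) -> float:
    """Exact expectation over inputs x gamma-subsets, fraction of
    signal-receiving targets unchanged."""
    links = sorted(net.links)
    alive = [t for t in net.targets if net.controllers_of(t)]
    if not alive or gamma == 0:
        return 1.0
    total, n = 0.0, 0
    for bits in itertools.product((0, 1), repeat=net.M):
        inp = dict(zip(net.controllers, bits))
        before = dict(zip(net.targets, oracle_outputs(net, inp, rule)))
        for sub in itertools.combinations(links, gamma):
            pruned = BipartiteNetwork(
                net.controllers, net.targets, set(links) - set(sub)
            )
            after = dict(zip(net.targets, oracle_outputs(pruned, inp, rule)))
            total += sum(before[t] == after[t] for t in alive) / len(alive)
            n += 1
    return total / n


# ---------------------------------------------------------------------------
# rule semantics
# ---------------------------------------------------------------------------
class TestEvaluate:
    @pytest.fixture
    def fan_in_3(self):
        return BipartiteNetwork(["a", "b", "c"], ["y"], [(c, "y") for c in "abc"])

    def test_one_of_three_active(self, fan_in_3):
        x = [1, 0, 0]
        assert evaluate(fan_in_3, x, "OR")[0] == 1
        assert evaluate(fan_in_3, x, "AND")[0] == 0
        assert evaluate(fan_in_3, x, "MAJORITY")[0] == 0

    def test_majority_tie_is_inactive(self):
        net = BipartiteNetwork(list("abcd"), ["y"], [(c, "y") for c in "abcd"])
        assert evaluate(net, [1, 1, 0, 0], "MAJORITY")[0] == 0
        assert evaluate(net, [1, 1, 1, 0], "MAJORITY")[0] == 1

    @pytest.mark.parametrize("rule", ["OR", "AND", "MAJORITY"])
    def test_all_zero_input_gives_all_zero_output(self, rule):
        net = random_network(5, 7, 0.4, seed=1)
        assert not evaluate(net, [0] * 5, rule).any()

    @pytest.mark.parametrize("rule", ["OR", "AND", "MAJORITY"])
    def test_unlinked_target_always_inactive(self, rule):
        net = BipartiteNetwork(["a"], ["y", "orphan"], [("a", "y")])
        assert evaluate(net, [1], rule)[1] == 0

    def test_input_length_checked(self):
        net = random_network(4, 4, 0.5, seed=0)
        with pytest.raises(ValueError):
            evaluate(net, [1, 0], "OR")


class TestCountOutputStates:
    @pytest.mark.parametrize("rule", ["OR", "AND", "MAJORITY"])
    def test_one_to_one_reaches_2_to_M(self, rule):
        n = 5
        net = BipartiteNetwork(
            [f"c{i}" for i in range(n)],
            [f"t{i}" for i in range(n)],
            [(f"c{i}", f"t{i}") for i in range(n)],
        )
        assert count_output_states(net, rule) == 2**n

    def test_single_fan_out_has_two_states(self):
        net = BipartiteNetwork(["c"], [f"t{j}" for j in range(6)],
                               [("c", f"t{j}") for j in range(6)])
        assert count_output_states(net, "OR") == 2

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("rule", ["OR", "AND", "MAJORITY"])
    def test_matches_enumeration_oracle(self, seed, rule):
        net = random_network(6, 6, 0.35, seed=seed)
        assert count_output_states(net, rule) == oracle_count_states(net, rule)

    def test_bounded_by_2_to_M(self):
        net = random_network(5, 9, 0.5, seed=3)
        assert count_output_states(net, "OR") <= 2**5

    def test_large_m_refused(self):
        net = random_network(4, 4, 0.5, seed=0)
        object.__setattr__(net, "controllers", tuple(f"c{i}" for i in range(23)))
        with pytest.raises(ValueError, match="omega_estimate"):
            count_output_states(net)


class TestRobustness:
    def test_gamma_zero_is_perfectly_robust(self):
        net = random_network(6, 6, 0.4, seed=1)
        cfg = BooleanConfig(mutation_fraction=0.0, n_trials=10, seed=0)
        assert robustness_simulation(net, cfg) == 1.0

    def test_single_link_network_half_robust(self):
        # one target, k_in = 1, delete its only link: flips iff input was 1
        net = BipartiteNetwork(["c"], ["t"], [("c", "t")])
        assert robustness_exhaustive(net, 1, "OR") == pytest.approx(0.5)
        cfg = BooleanConfig(mutation_fraction=1.0, n_trials=4000, seed=5)
        assert robustness_simulation(net, cfg) == pytest.approx(0.5, abs=0.03)

    def test_gamma_exceeding_L_rejected(self):
        net = BipartiteNetwork(["c"], ["t"], [("c", "t")])
        with pytest.raises(ValueError):
            robustness_simulation(net, BooleanConfig(mutation_fraction=5.0))

    @pytest.mark.parametrize("seed", range(4))
    def test_exhaustive_matches_oracle(self, seed):
        net = random_network(3, 3, 0.5, seed=seed)
        if net.L < 1:
            return
        got = robustness_exhaustive(net, 1, "OR")
        assert got == pytest.approx(oracle_robustness(net, 1, "OR"), abs=1e-12)

    def test_simulation_converges_to_exhaustive(self):
        net = random_network(4, 4, 0.5, seed=9)
        exact = robustness_exhaustive(net, 1, "OR")
        cfg = BooleanConfig(mutation_fraction=1 / net.N, n_trials=6000, seed=1)
        assert robustness_simulation(net, cfg) == pytest.approx(exact, abs=0.02)


class TestFragility:
    @pytest.mark.parametrize("k,expected", [(1, 0.5), (3, 0.125)])
    def test_matches_single_node_enumeration(self, k, expected):
        # enumerate all 2^k inputs of a single k-in target; deleting one
        # specific link flips the output only when that controller alone is on
        ctrl = [f"c{i}" for i in range(k)]
        net = BipartiteNetwork(ctrl, ["y"], [(c, "y") for c in ctrl])
        pruned = BipartiteNetwork(ctrl, ["y"], [(c, "y") for c in ctrl[1:]])
        flips = 0
        for bits in itertools.product((0, 1), repeat=k):
            inp = dict(zip(ctrl, bits))
            if oracle_outputs(net, inp, "OR") != oracle_outputs(pruned, inp, "OR"):
                flips += 1
        assert flips / 2**k == pytest.approx(expected)
        assert p_fragile(k, "OR") == pytest.approx(expected)

    def test_and_equals_or_by_symmetry(self):
        for k in range(1, 8):
            assert p_fragile(k, "AND") == p_fragile(k, "OR")

    def test_decreasing_to_zero(self):
        vals = [p_fragile(k) for k in range(1, 30)]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-8

    def test_majority_has_no_closed_form(self):
        with pytest.raises(ValueError):
            p_fragile(3, "MAJORITY")


class TestClosedForm:
    def test_gamma_zero(self):
        assert robustness_closed_form(5, 0, 10) == 1.0

    def test_k1_full_deletion_half(self):
        assert robustness_closed_form(1, 1, 1) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_first_order_matches_exhaustive_small_gamma(self, seed):
        """R(k) averaged over a small network's targets vs exact enumeration
        at gamma = 1 (first-order regime)."""
        net = random_network(5, 5, 0.4, seed=seed + 20)
        if net.L < 3:
            return
        kin = [len(net.controllers_of(t)) for t in net.targets]
        alive = [k for k in kin if k >= 1]
        pred = float(np.mean([robustness_closed_form(k, 1, net.L) for k in alive]))
        exact = robustness_exhaustive(net, 1, "OR")
        assert pred == pytest.approx(exact, abs=0.02)


class TestEntropy:
    def test_k1_is_one_bit(self):
        assert entropy_single_node(1) == pytest.approx(1.0)

    def test_k2_value(self):
        q0 = 0.25
        expect = -q0 * math.log2(q0) - 0.75 * math.log2(0.75)
        assert entropy_single_node(2) == pytest.approx(expect)
        assert expect == pytest.approx(0.8113, abs=1e-4)

    def test_strictly_decreasing_to_zero(self):
        vals = [entropy_single_node(k) for k in range(1, 40)]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-8

    def test_series_converges_to_exact(self):
        for k in (1, 2, 5):
            exact = entropy_single_node(k)
            assert entropy_single_node(k, eta=30) == pytest.approx(exact, abs=1e-8)
            assert entropy_single_node(k, eta=3) == pytest.approx(exact, abs=0.03)


class TestExpectedValues:
    def test_point_mass_k1(self):
        m = GeometricModel(1.0)
        assert expected_value("2^-nk", m, eta=1) == pytest.approx(0.5)

    def test_geometric_closed_form_vs_summation(self):
        m = GeometricModel(0.5)
        assert expected_value("2^-nk", m, eta=1) == pytest.approx(1 / 3)
        ks = np.arange(1, 200)
        for eta in (1, 2, 3):
            direct = float(np.sum(m.pmf(ks) * 2.0 ** (-eta * ks)))
            assert expected_value("2^-nk", m, eta=eta) == pytest.approx(direct, abs=1e-12)
            direct_k = float(np.sum(m.pmf(ks) * ks * 2.0 ** (-eta * ks)))
            assert expected_value("k*2^-nk", m, eta=eta) == pytest.approx(direct_k, abs=1e-12)

    def test_poisson_closed_form_vs_summation(self):
        m = PoissonNull(3.0)
        ks = np.arange(1, 200)
        for eta in (1, 2):
            direct = float(np.sum(m.pmf(ks) * 2.0 ** (-eta * ks)))
            assert expected_value("2^-nk", m, eta=eta) == pytest.approx(direct, abs=1e-12)
            direct_k = float(np.sum(m.pmf(ks) * ks * 2.0 ** (-eta * ks)))
            assert expected_value("k*2^-nk", m, eta=eta) == pytest.approx(direct_k, abs=1e-12)

    def test_poisson_truncated_vs_renormalized(self):
        ren = PoissonNull(2.0, renormalized=True)
        trunc = PoissonNull(2.0, renormalized=False)
        factor = 1 - math.exp(-2.0)
        assert expected_value("2^-nk", trunc, eta=1) == pytest.approx(
            factor * expected_value("2^-nk", ren, eta=1)
        )

    def test_geometric_and_poisson_curves_similar(self):
        """Mean robustness curves over <k_in> agree in shape for the two
        degree laws at equal mean."""
        for mean in (2.0, 4.0, 8.0):
            rg = mean_robustness(GeometricModel.from_mean(mean), 1, 10 * mean)
            lam = mean  # zero-excluded Poisson mean slightly exceeds lam
            rp = mean_robustness(PoissonNull(lam), 1, 10 * mean)
            assert rg == pytest.approx(rp, abs=0.02)

    def test_divergent_parameters_rejected(self):
        # eta < 0 turns the geometric series ratio (1-p) 2^-eta above 1
        with pytest.raises(ValueError):
            expected_value("2^-nk", GeometricModel(0.2), eta=-1)


class TestOmegaEstimate:
    def test_point_mass_k1_gives_2_to_N(self):
        assert omega_estimate(GeometricModel(1.0), 12, eta=None) == pytest.approx(12.0)

    def test_decreasing_in_mean_degree(self):
        vals = [omega_estimate(GeometricModel.from_mean(mu), 20) for mu in range(1, 10)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_close_to_enumeration_on_small_er(self):
        """log2 Omega estimate vs exhaustive enumeration, M=N=6 ER at
        <k_in> = 3 over 100 seeded networks."""
        logs = []
        for s in range(100):
            net = random_network(6, 6, 0.5, seed=4000 + s)
            logs.append(math.log2(count_output_states(net, "OR")))
        est = omega_estimate(BinomialNull(6, 0.5), 6, eta=3)
        assert abs(est - np.mean(logs)) / np.mean(logs) < 0.25


class TestSweep:
    def test_closed_form_independent_of_N(self):
        """With gamma/N and <k_in> fixed, gamma/L = mutation/k_in does not
        depend on N, so R-bar is identical across N."""
        for kin in (1.0, 3.0, 6.0):
            vals = []
            for N in (6, 8, 10):
                gamma = 0.1 * N  # fractional: the closed form needs only gamma/L
                model = BinomialNull(10, kin / 10)
                vals.append(mean_robustness(model, gamma, N * kin))
            assert vals[0] == pytest.approx(vals[1], abs=1e-12)
            assert vals[1] == pytest.approx(vals[2], abs=1e-12)

    def test_sweep_table_columns_and_trends(self):
        df = fig3_sweep(8, 8, 0.125, [1, 2, 4], n_trials=60, seed=2)
        assert {"k_in", "R_sim_OR", "R_closed", "log2_omega_closed"} <= set(df.columns)
        assert df["R_closed"].is_monotonic_increasing
        assert df["log2_omega_closed"].is_monotonic_decreasing

    def test_infeasible_grid_point_skipped(self):
        with pytest.warns(UserWarning, match="infeasible"):
            df = fig3_sweep(4, 4, 0.25, [2, 9], n_trials=5, count_states=False)
        assert list(df["k_in"]) == [2]


class TestAndOrSymmetry:
    @pytest.mark.parametrize("seed", range(5))
    def test_omega_and_robustness_equal(self, seed):
        """OR(x) = NOT AND(NOT x): state counts and exhaustive robustness
        coincide exactly on every network."""
        net = random_network(5, 5, 0.4, seed=seed + 50)
        assert count_output_states(net, "OR") == count_output_states(net, "AND")
        if 1 <= net.L:
            assert robustness_exhaustive(net, 1, "OR") == pytest.approx(
                robustness_exhaustive(net, 1, "AND"), abs=1e-12
            )


class TestModelFacade:
    def test_facade_delegates(self):
        net = random_network(5, 5, 0.4, seed=7)
        m = BooleanBipartiteModel(net, "OR")
        assert m.count_output_states() == count_output_states(net, "OR")
        r = m.simulate_robustness(mutation_fraction=0.2, n_trials=50, seed=1)
        assert 0 <= r <= 1
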