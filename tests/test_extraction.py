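"""Tensor module extraction: objective, solver ascent, oracle agreement."""

import numpy as np
import pytest

from cdmnet import (
    PlantedModuleSpec,
    SolverConfig,
    brute_force_heaviest,
    discretize,
    extract_all_cdms,
    generate_multilayer,
    mask_module,
    module_weight,
    solve_continuous,
)
from cdmnet.layers import MultilayerTensor


class TestModuleWeight:
    def test_all_zero_tensor(self):
        t = MultilayerTensor(["A", "B"], ["L"], np.zeros((2, 2, 1)))
        assert module_weight(np.ones(2), np.ones(1), t) == 0.0

    def test_binary_selection(self, two_layer_tensor):
        x = np.array([1.0, 1.0, 0.0])
        assert module_weight(x, np.array([1.0, 1.0]), two_layer_tensor) == pytest.approx(1.5)
        assert module_weight(x, np.array([1.0, 0.0]), two_layer_tensor) == pytest.approx(1.0)

    def test_dimension_mismatch(self, two_layer_tensor):
        with pytest.raises(ValueError):
            module_weight(np.ones(2), np.ones(2), two_layer_tensor)

    def test_scale_equivariance(self, planted_tensor):
        tensor, _ = planted_tensor
        scaled = MultilayerTensor(
            tensor.node_order, tensor.layer_order, tensor.values * 3.0
        )
        x = np.random.default_rng(0).random(tensor.n)
        y = np.ones(tensor.m)
        assert module_weight(x, y, scaled) == pytest.approx(
            3.0 * module_weight(x, y, tensor)
        )


class TestSolver:
    def test_all_zero_tensor_refused(self):
        t = MultilayerTensor(["A", "B"], ["L"], np.zeros((2, 2, 1)))
        with pytest.raises(ValueError):
            solve_continuous(t)

    def test_objective_history_non_decreasing(self, planted_tensor):
        tensor, _ = planted_tensor
        sol = solve_continuous(tensor, SolverConfig(seed=5, n_restarts=3))
        hist = np.asarray(sol.history)
        assert np.all(np.diff(hist) >= -1e-9)

    def test_mass_concentrates_on_planted_clique(self, planted_tensor):
        tensor, truth = planted_tensor
        sol = solve_continuous(tensor, SolverConfig(seed=1))
        top = {tensor.node_order[i] for i in np.argsort(-sol.x)[:6]}
        assert top == set(truth["planted"])
        assert np.all(sol.y > 0)

    def test_single_layer_y_forced_to_one(self):
        tensor, _ = generate_multilayer(
            n_nodes=15, m_layers=1, specs=[PlantedModuleSpec(members=5)], seed=2
        )
        sol = solve_continuous(tensor, SolverConfig(seed=0, n_restarts=2))
        assert sol.y == pytest.approx([1.0])

    def test_norm_constraints_hold(self, planted_tensor):
        tensor, _ = planted_tensor
        cfg = SolverConfig(seed=7, p=2.0, q=2.0)
        sol = solve_continuous(tensor, cfg)
        assert np.sum(sol.x**2) == pytest.approx(1.0)
        assert np.sum(sol.y**2) == pytest.approx(1.0)
        assert np.all(sol.x >= 0) and np.all(sol.y >= 0)


class TestDiscretize:
    def test_recovers_planted_members(self, planted_tensor):
        tensor, truth = planted_tensor
        cfg = SolverConfig(seed=1)
        sol = solve_continuous(tensor, cfg)
        module = discretize(sol.x, sol.y, tensor, cfg)
        assert module is not None
        assert set(module.members) == set(truth["planted"])

    def test_background_below_threshold_returns_none(self):
        tensor, _ = generate_multilayer(n_nodes=20, m_layers=2, seed=4)
        cfg = SolverConfig(seed=0, n_restarts=2, min_weight=5.0)
        sol = solve_continuous(tensor, cfg)
        assert discretize(sol.x, sol.y, tensor, cfg) is None

    def test_total_weight_equals_per_layer_sum(self, planted_tensor):
        tensor, _ = planted_tensor
        cfg = SolverConfig(seed=1)
        sol = solve_continuous(tensor, cfg)
        module = discretize(sol.x, sol.y, tensor, cfg)
        assert module.total_weight == pytest.approx(
            sum(module.per_layer_weight.values())
        )
        assert module.size >= cfg.min_size


class TestMask:
    def test_masked_module_weight_zero(self, planted_tensor):
        tensor, truth = planted_tensor
        cfg = SolverConfig(seed=1)
        sol = solve_continuous(tensor, cfg)
        module = discretize(sol.x, sol.y, tensor, cfg)
        masked = mask_module(tensor, module)
        ix = masked.indices(module.members)
        assert np.all(masked.values[np.ix_(ix, ix)] == 0)

    def test_mask_counts_and_idempotence(self, planted_tensor):
        tensor, truth = planted_tensor
        cfg = SolverConfig(seed=1)
        sol = solve_continuous(tensor, cfg)
        module = discretize(sol.x, sol.y, tensor, cfg)
        masked = mask_module(tensor, module)
        ix = masked.indices(module.members)
        outside = np.ones(tensor.n, dtype=bool)
        outside[ix] = False
        np.testing.assert_allclose(
            masked.values[outside][:, outside], tensor.values[outside][:, outside]
        )
        np.testing.assert_allclose(mask_module(masked, module).values, masked.values)


class TestExtractAll:
    def test_two_planted_modules_recovered_disjoint(self):
        tensor, truth = generate_multilayer(
            n_nodes=40,
            m_layers=3,
            specs=[
                PlantedModuleSpec(members=6, label="m1"),
                PlantedModuleSpec(members=5, label="m2"),
            ],
            seed=8,
        )
        modules = extract_all_cdms(tensor, SolverConfig(seed=0))
        assert len(modules) == 2
        found = [set(m.members) for m in modules]
        assert not (found[0] & found[1])
        assert {frozenset(s) for s in found} == {
            frozenset(truth["m1"]),
            frozenset(truth["m2"]),
        }

    def test_background_only_gives_empty_list(self):
        tensor, _ = generate_multilayer(n_nodes=40, m_layers=3, seed=9)
        assert extract_all_cdms(tensor, SolverConfig(seed=0, n_restarts=3)) == []

    def test_single_module_then_termination(self, planted_tensor):
        tensor, truth = planted_tensor
        modules = extract_all_cdms(tensor, SolverConfig(seed=0))
        assert len(modules) == 1
        assert set(modules[0].members) == set(truth["planted"])

    def test_seed_determinism(self, planted_tensor):
        tensor, _ = planted_tensor
        a = extract_all_cdms(tensor, SolverConfig(seed=42))
        b = extract_all_cdms(tensor, SolverConfig(seed=42))
        assert [m.members for m in a] == [m.members for m in b]
        assert [m.total_weight for m in a] == [m.total_weight for m in b]


class TestBruteForce:
    def test_planted_clique_in_ten_nodes(self):
        tensor, truth = generate_multilayer(
            n_nodes=10, m_layers=3, specs=[PlantedModuleSpec(members=5)], seed=3
        )
        members, weight = brute_force_heaviest(tensor, 5)
        assert set(members) == set(truth["planted"])
        assert weight > 0

    def test_tie_break_lexicographic(self):
        v = np.full((4, 4, 1), 1.0)
        v[np.arange(4), np.arange(4), :] = 0.0
        t = MultilayerTensor(["A", "B", "C", "D"], ["L"], v)
        members, _ = brute_force_heaviest(t, 2)
        assert members == ("A", "B")

    def test_size_equals_n(self, two_layer_tensor):
        members, weight = brute_force_heaviest(two_layer_tensor, 3)
        assert members == ("D1", "D2", "D3")
        assert weight == pytest.approx(1.5)

    def test_combinatorial_guard(self):
        tensor, _ = generate_multilayer(n_nodes=16, m_layers=2, seed=0)
        with pytest.raises(ValueError, match="n <= 15"):
            brute_force_heaviest(tensor, 5)

    @pytest.mark.parametrize("seed", range(6))
    def test_solver_matches_oracle_on_planted_instances(self, seed):
        tensor, truth = generate_multilayer(
            n_nodes=10,
            m_layers=3,
            specs=[PlantedModuleSpec(members=5, mean=0.5)],
            background_mean=0.05,
            background_density=0.3,
            seed=seed,
        )
        cfg = SolverConfig(seed=seed, min_size=5)
        sol = solve_continuous(tensor, cfg)
        module = discretize(sol.x, sol.y, tensor, cfg)
        oracle_members, _ = brute_force_heaviest(tensor, 5)
        assert module is not None
        assert set(module.members) >= set(oracle_members) or set(module.members) == set(
            truth["planted"]
        )
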