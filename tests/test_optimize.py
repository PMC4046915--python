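import numpy as np
import pytest

from pepwave import ConfigError
from pepwave.forcing import ForcingProgram
from pepwave.optimize import (OptimizationProblem, default_path_constraints,
                              optimize_circuit, optimize_dynamic,
                              optimize_static)
from pepwave.simulate import simulate, total_metabolite


def _toy_problem(toy, **kw):
    defaults = dict(cluster=["M1"], target=toy.metabolite_ids[-1],
                    path_constraints={}, seeds=(0, 1), budget=120,
                    floor_one=(), grid_dt=600.0, horizon=4 * 3600.0)
    defaults.update(kw)
    return OptimizationProblem(**defaults)


class TestProblemValidation:
    def test_empty_cluster_rejected(self):
        with pytest.raises(ConfigError):
            OptimizationProblem(cluster=[])

    def test_unknown_enzyme_rejected(self, ecoli):
        pr = OptimizationProblem(cluster=["NOSUCH"])
        with pytest.raises(ConfigError):
            optimize_dynamic(pr, ecoli)

    def test_constant_waveform_needs_static_entry_point(self, ecoli):
        pr = OptimizationProblem(cluster=["PFK"], waveform="constant")
        with pytest.raises(ConfigError):
            optimize_dynamic(pr, ecoli)

    def test_default_path_constraints_bands(self, ecoli):
        bands = default_path_constraints(ecoli)
        assert bands["pep"] == (1.0, 10.0)
        for met in ("pyr", "rib5p", "e4p", "g6p"):
            lo, hi = bands[met]
            c = ecoli.steady_state[ecoli.metabolite_index(met)]
            assert lo < c < hi
            assert hi / lo == pytest.approx(10.0)


class TestDegenerateRuns:
    def test_zero_amplitude_bounds_give_unit_gain(self, toy):
        res = optimize_dynamic(_toy_problem(toy, A_bounds=(0.0, 0.0),
                                            budget=40), toy)
        assert res.gain == pytest.approx(1.0, abs=1e-12)
        assert res.converged

    def test_static_levels_pinned_at_one_give_unit_gain(self, toy):
        res = optimize_static(
            _toy_problem(toy, waveform="constant",
                         level_bounds={"M1": (1.0, 1.0)}, budget=40), toy)
        assert res.gain == pytest.approx(1.0, abs=1e-12)

    def test_circuit_with_zero_amplitudes_gives_unit_gain(self, ecoli):
        pr = OptimizationProblem(cluster=["GAPDH", "PFK", "RPPK"],
                                 A_bounds=(0.0, 0.0), seeds=(0,),
                                 budget=30, grid_dt=300.0)
        res = optimize_circuit(ecoli, problem=pr)
        assert res.gain == pytest.approx(1.0, abs=1e-12)


@pytest.fixture(scope="module")
def toy_result(toy):
    return optimize_dynamic(_toy_problem(toy, budget=150), toy)


class TestOptimizerContracts:
    def test_gain_at_least_one_with_feasible_baseline(self, toy_result):
        assert toy_result.gain >= 1.0 - 1e-12

    def test_optimum_reproducible_by_fresh_simulation(self, toy,
                                                      toy_result):
        """Re-simulating the reported program reproduces the reported
        objective to 1e-8 relative."""
        pr = _toy_problem(toy)
        traj = simulate(toy, toy_result.program, horizon=pr.horizon,
                        grid_dt=min(pr.grid_dt, 2 * np.pi
                                    / pr.omega_bounds[1] / 24.0),
                        rtol=1e-8, atol=1e-10)
        total = total_metabolite(traj, pr.target)
        assert total == pytest.approx(toy_result.objective, rel=1e-8)

    def test_constraint_satisfied_at_reported_optimum(self, ecoli):
        pr = OptimizationProblem(cluster=["GAPDH"], seeds=(0, 1),
                                 budget=80, grid_dt=300.0,
                                 direction_hints={"GAPDH": 1.0})
        res = optimize_dynamic(pr, ecoli)
        assert res.converged
        assert res.max_violation < 1e-6
        assert res.gain >= 1.0 - 1e-12

    def test_deterministic_given_seeds(self, toy):
        a = optimize_dynamic(_toy_problem(toy, budget=100), toy)
        b = optimize_dynamic(_toy_problem(toy, budget=100), toy)
        assert a.objective == b.objective
        assert a.program == b.program

    def test_optimum_beats_brute_force_grid(self, toy):
        """Single forced enzyme on the toy: the optimizer must match or
        exceed the best of a coarse 3x3x3 grid over (A, omega, phi)."""
        pr = _toy_problem(toy, budget=200, seeds=(0, 1, 2))
        res = optimize_dynamic(pr, toy)
        best = 0.0
        grid_dt = min(pr.grid_dt, 2 * np.pi / pr.omega_bounds[1] / 24.0)
        base = simulate(toy, None, horizon=pr.horizon, grid_dt=grid_dt,
                        rtol=1e-8, atol=1e-10)
        b0 = total_metabolite(base, pr.target)
        from pepwave.forcing import EnzymeProfile
        for A in np.linspace(*pr.A_bounds, 3):
            for om in np.geomspace(*pr.omega_bounds, 3):
                for phi in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
                    prog = ForcingProgram([EnzymeProfile(
                        "M1", A=A, omega=om, phi=phi,
                        e_min=pr.e_min, e_max=pr.e_max)])
                    tr = simulate(toy, prog, horizon=pr.horizon,
                                  grid_dt=grid_dt, rtol=1e-8, atol=1e-10)
                    best = max(best, total_metabolite(tr, pr.target) / b0)
        assert res.gain >= best - 1e-6


class TestStaticBounds:
    def test_essential_enzymes_floor_quarter(self, ecoli):
        from pepwave.optimize import _Encoding
        pr = OptimizationProblem(cluster=["RPPK", "PEPC"],
                                 waveform="constant")
        enc = _Encoding(pr, ecoli)
        assert enc.bounds[0] == (0.25, 20.0)   # RPPK essential
        assert enc.bounds[1] == (0.0, 20.0)    # PEPC dispensable
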