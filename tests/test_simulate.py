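import numpy as np
import pytest
from scipy.integrate import simpson

from pepwave import ConfigError, DomainError
from pepwave.forcing import EnzymeProfile, ForcingProgram
from pepwave.simulate import Trajectory, gain_ratio, simulate, total_metabolite


def _synthetic_traj(t, values, name="pep"):
    n = len(t)
    return Trajectory(t=np.asarray(t, float),
                      C=np.asarray(values, float)[None, :],
                      E=np.ones((1, n)), horizon=float(t[-1]),
                      metabolite_ids=[name], reaction_ids=["R"])


@pytest.fixture(scope="module")
def forced_traj(ecoli):
    prog = ForcingProgram([EnzymeProfile(
        "GAPDH", A=5.0, omega=2 * np.pi / 7200, phi=0.0, e_min=1.0)])
    return prog, simulate(ecoli, prog, grid_dt=60.0)


@pytest.fixture(scope="module")
def fine_traj(ecoli):
    """A 2 h smoothly forced run (no clamping kinks) on the default 1 s
    reporting grid, where quadrature error drops below 1e-7 relative."""
    prog = ForcingProgram([EnzymeProfile(
        "GAPDH", A=0.8, omega=2 * np.pi / 7200, phi=0.0)])
    return prog, simulate(ecoli, prog, horizon=7200.0, grid_dt=1.0)


class TestSimulate:
    def test_steady_state_persists_unforced(self, ecoli, baseline_traj):
        """With no forcing the nominal state is stationary over 8 h."""
        rel = np.abs(baseline_traj.C / ecoli.steady_state[:, None] - 1.0)
        assert rel.max() < 1e-3

    def test_zero_amplitude_program_equals_empty_program(self, ecoli):
        prog = ForcingProgram([
            EnzymeProfile(e, A=0.0, omega=2 * np.pi / 3600, phi=0.5)
            for e in ("PFK", "GAPDH", "PK", "PEPC", "RPPK", "SER", "SYN1",
                      "DAHPS", "G6PDH")])
        a = simulate(ecoli, prog, horizon=3600.0, grid_dt=60.0)
        b = simulate(ecoli, None, horizon=3600.0, grid_dt=60.0)
        np.testing.assert_allclose(a.C, b.C, rtol=1e-9, atol=1e-12)

    def test_identical_inputs_bit_identical_output(self, ecoli, forced_traj):
        prog, traj = forced_traj
        again = simulate(ecoli, prog, grid_dt=60.0)
        np.testing.assert_array_equal(traj.C, again.C)
        np.testing.assert_array_equal(traj.t, again.t)

    def test_grid_refinement_leaves_total_pep(self, ecoli, fine_traj):
        """Halving the (default 1 s) reporting grid changes the PEP
        integral by <1e-6 relative: the grid is pure output, not the
        solver step."""
        prog, traj = fine_traj
        halved = simulate(ecoli, prog, horizon=7200.0, grid_dt=0.5)
        a = total_metabolite(traj, "pep")
        b = total_metabolite(halved, "pep")
        assert a == pytest.approx(b, rel=1e-6)

    def test_tolerance_sweep_stability(self, ecoli, forced_traj):
        prog, _ = forced_traj
        loose = simulate(ecoli, prog, grid_dt=120.0, rtol=1e-6, atol=1e-8)
        tight = simulate(ecoli, prog, grid_dt=120.0, rtol=1e-10, atol=1e-12)
        assert (total_metabolite(loose, "pep")
                == pytest.approx(total_metabolite(tight, "pep"), rel=1e-4))

    def test_trajectory_invariants(self, forced_traj):
        _, traj = forced_traj
        assert traj.t[0] == 0.0
        assert traj.t[-1] == traj.horizon
        assert np.all(np.diff(traj.t) > 0)
        assert traj.C.shape[1] == traj.t.size == traj.E.shape[1]

    def test_bad_horizon_rejected(self, ecoli):
        with pytest.raises(ConfigError):
            simulate(ecoli, None, horizon=0.0)

    def test_export_frame_has_unit_columns(self, forced_traj):
        _, traj = forced_traj
        df = traj.to_frame()
        assert "time_s" in df.columns and "pep_mM" in df.columns
        tidy = traj.to_frame(wide=False)
        assert set(tidy.columns) == {"time_s", "variable", "value"}


class TestTotalMetabolite:
    def test_constant_concentration_integrates_exactly(self):
        t = np.linspace(0.0, 100.0, 11)
        traj = _synthetic_traj(t, np.full(11, 3.5))
        assert total_metabolite(traj, "pep") == pytest.approx(350.0)

    def test_sin_squared_closed_form(self):
        t = np.linspace(0.0, 2 * np.pi, 20001)
        traj = _synthetic_traj(t, np.sin(t) ** 2)
        assert total_metabolite(traj, "pep") == pytest.approx(np.pi,
                                                              rel=1e-7)

    def test_matches_simpson_oracle_on_simulated_run(self, fine_traj):
        _, traj = fine_traj
        pep = traj.metabolite("pep")
        assert (total_metabolite(traj, "pep")
                == pytest.approx(simpson(pep, x=traj.t), rel=1e-6))

    def test_unknown_metabolite_rejected(self, forced_traj):
        with pytest.raises(ConfigError):
            total_metabolite(forced_traj[1], "atp")


class TestGainRatio:
    def test_self_ratio_is_one(self, baseline_traj):
        assert gain_ratio(baseline_traj, baseline_traj, "pep") == 1.0

    def test_doubled_concentration_gives_two(self):
        t = np.linspace(0, 10, 21)
        base = _synthetic_traj(t, 1.0 + np.sin(t) ** 2)
        test = _synthetic_traj(t, 2.0 * (1.0 + np.sin(t) ** 2))
        assert gain_ratio(test, base, "pep") == pytest.approx(2.0)

    def test_mismatched_horizons_rejected(self):
        a = _synthetic_traj(np.linspace(0, 10, 11), np.ones(11))
        b = _synthetic_traj(np.linspace(0, 20, 11), np.ones(11))
        with pytest.raises(ConfigError):
            gain_ratio(a, b, "pep")

    def test_zero_baseline_rejected(self):
        t = np.linspace(0, 10, 11)
        a = _synthetic_traj(t, np.ones(11))
        b = _synthetic_traj(t, np.zeros(11))
        with pytest.raises(DomainError):
            gain_ratio(a, b, "pep")
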