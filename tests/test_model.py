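"""Core model oracle tests: hand-evaluated derivatives, closed-form steady
states, solver accuracy against a fixed-step integrator, and structural
properties of the p53 network."""

import numpy as np
import pytest

from p53ddr.model import (
    RATE_PARAM_NAMES,
    SPECIES,
    KineticParameters,
    ModelState,
    ObservableMap,
    StimulusSchedule,
    Trajectory,
    disrupt_feedback,
    effective_stimulus,
    observe,
    rhs,
    simulate,
    steady_state,
)

class TestEffectiveStimulus:
    @pytest.mark.parametrize(
        "ec,tau,t,start,expected",
        [
            (2.0, 0.0, 100.0, 0.0, 2.0),  # zero decay
            (1.0, np.log(2), 1.0, 0.0, 0.5),  # closed-form half-life
            (3.7, 0.3, 5.0, 5.0, 3.7),  # identity at exposure onset
            (1.0, 0.5, 1.0, 2.0, 0.0),  # zero before exposure
        ],
    )
    def test_closed_form(self, ec, tau, t, start, expected):
        s = StimulusSchedule(EC=ec, tau=tau, exposure_start=start)
        assert effective_stimulus(s, t) == pytest.approx(expected, abs=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            StimulusSchedule(EC=-1.0, tau=0.1)
        with pytest.raises(ValueError):
            StimulusSchedule(EC=1.0, tau=-0.1)

    def test_vectorized(self):
        s = StimulusSchedule(EC=2.0, tau=0.1)
        t = np.array([0.0, 1.0, 10.0])
        np.testing.assert_allclose(
            effective_stimulus(s, t), 2.0 * np.exp(-0.1 * t)
        )


class TestRhs:
    def test_all_unit_inputs(self, unit_params, unit_state):
        """Hand evaluation of the ten equations at all-one species/rates."""
        deriv = rhs(unit_state, unit_params, 0.0)
        expected = np.array([0, 0, -1, -2, 0.5, 0, 0.5, 0, 0.5, 0], float)
        np.testing.assert_allclose(deriv, expected, atol=1e-12)

    def test_origin_only_synthesis(self, unit_params):
        """At zero state only synthesis terms survive; Hill term is zero."""
        deriv = rhs(ModelState(*([0.0] * 10)), unit_params, 0.0)
        expected = np.array([1, 1, 0, 0, 1, 0, 1, 0, 1, 0], float)
        np.testing.assert_allclose(deriv, expected, atol=1e-12)

    def test_zero_at_steady_state(self, base_params, base_steady):
        deriv = rhs(base_steady, base_params, 0.0)
        assert np.max(np.abs(deriv)) <= 1e-8

    def test_stimulus_enters_damage_only(self, unit_params, unit_state):
        d0 = rhs(unit_state, unit_params, 0.0)
        d5 = rhs(unit_state, unit_params, 5.0)
        assert d5[0] - d0[0] == pytest.approx(5.0)
        np.testing.assert_array_equal(d0[1:], d5[1:])

    @pytest.mark.parametrize("hill_n", [1, 4])
    def test_hill_midpoint(self, hill_n):
        """With P53p at Km the induced synthesis is exactly half-maximal."""
        p = KineticParameters(
            **{n: 1.0 for n in RATE_PARAM_NAMES}, hill_n=hill_n
        ).replace(Km_mdm2=0.7, ks_mdm2_RNA=0.0, kd_mdm2_RNA=0.0)
        state = ModelState(0, 0, 0, 0.7, 0, 0, 0, 0, 0, 0)
        deriv = rhs(state, p, 0.0)
        # dMDM2_RNA/dt = ks_mdm2_p53p * 1/2 with synthesis/degradation removed
        assert deriv[SPECIES.index("MDM2_RNA")] == pytest.approx(0.5)


class TestSimulate:
    def test_equilibrium_invariance(self, base_params, base_steady, no_stimulus):
        """72 h without stress keeps every species within 0.1 %."""
        grid = np.linspace(0.5, 72.0, 40)
        traj = simulate(base_params, base_steady, no_stimulus, grid)
        ref = base_steady.as_array()
        rel = np.abs(traj.states - ref) / np.abs(ref)
        assert rel.max() < 1e-3

    def test_p53_mrna_decoupled_from_dose(self, base_params, base_steady):
        """p53 mRNA is structurally independent of the stress amplitude."""
        grid = np.linspace(1.0, 48.0, 20)
        lo = simulate(base_params, base_steady,
                      StimulusSchedule(EC=1.0, tau=base_params.tau), grid)
        hi = simulate(base_params, base_steady,
                      StimulusSchedule(EC=4.0, tau=base_params.tau), grid)
        np.testing.assert_array_equal(lo.species("P53_RNA"), hi.species("P53_RNA"))

    def test_tolerance_refinement_contract(self, base_params, base_steady):
        """10x tighter tolerances move states by < 0.1 % relative."""
        grid = np.linspace(1.0, 65.0, 30)
        sched = StimulusSchedule(EC=base_params.EC3, tau=base_params.tau)
        a = simulate(base_params, base_steady, sched, grid, rtol=1e-8, atol=1e-10)
        b = simulate(base_params, base_steady, sched, grid, rtol=1e-9, atol=1e-11)
        rel = np.abs(a.states - b.states) / (np.abs(b.states) + 1e-12)
        assert rel.max() < 1e-3

    def test_agrees_with_fixed_step_rk4(self, base_params, base_steady):
        """Oracle: classic RK4 at a very small step over a 2 h window."""
        sched = StimulusSchedule(EC=base_params.EC2, tau=base_params.tau)
        from p53ddr.model import _rhs_raw, effective_stimulus

        h = 1e-3
        y = base_steady.as_array().copy()
        t = 0.0
        while t < 2.0 - h / 2:
            def f(ti, yi):
                return _rhs_raw(yi, base_params, effective_stimulus(sched, ti))
            k1 = f(t, y)
            k2 = f(t + h / 2, y + h / 2 * k1)
            k3 = f(t + h / 2, y + h / 2 * k2)
            k4 = f(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        traj = simulate(base_params, base_steady, sched, np.array([1.0, 2.0]))
        rel = np.abs(traj.states[-1] - y) / (np.abs(y) + 1e-12)
        assert rel.max() < 1e-4

    def test_non_negativity(self, base_params, base_steady):
        grid = np.linspace(0.5, 72.0, 48)
        traj = simulate(base_params, base_steady,
                        StimulusSchedule(EC=4.0, tau=base_params.tau), grid)
        assert traj.states.min() >= -1e-8

    def test_invalid_grid_rejected(self, base_params, base_steady, no_stimulus):
        with pytest.raises(ValueError):
            simulate(base_params, base_steady, no_stimulus, np.array([2.0, 1.0]))
        with pytest.raises(ValueError):
            simulate(base_params, base_steady, no_stimulus, np.array([-1.0, 1.0]))


class TestObserve:
    def test_p53_sums_both_forms(self):
        traj = Trajectory(np.array([0.0, 1.0]),
                          np.column_stack([np.zeros((2, 2)),
                                           np.full((2, 1), 2.0),  # P53
                                           np.full((2, 1), 3.0),  # P53p
                                           np.zeros((2, 6))]))
        omap = ObservableMap()
        obs = observe(traj, omap, reporters=("p53",))
        np.testing.assert_allclose(obs["p53"], 5.0)

    def test_affine_map(self):
        states = np.zeros((2, 10))
        states[:, 5] = 3.0  # MDM2
        traj = Trajectory(np.array([0.0, 1.0]), states)
        omap = ObservableMap(scaling={"p53": 1, "mdm2": 2, "p21": 1, "btg2": 1},
                             offset={"p53": 0, "mdm2": 1, "p21": 0, "btg2": 0})
        np.testing.assert_allclose(observe(traj, omap)["mdm2"], 7.0)

    def test_offsets_only_on_zero_state(self):
        traj = Trajectory(np.array([0.0, 1.0]), np.zeros((2, 10)))
        omap = ObservableMap(offset={r: 0.3 for r in ("p53", "mdm2", "p21", "btg2")})
        for rep, vals in observe(traj, omap).items():
            np.testing.assert_allclose(vals, 0.3)

    def test_unknown_reporter_rejected(self):
        traj = Trajectory(np.array([0.0, 1.0]), np.zeros((2, 10)))
        with pytest.raises(KeyError):
            observe(traj, ObservableMap(), reporters=("gfp",))

    def test_nonpositive_scaling_rejected(self):
        with pytest.raises(ValueError):
            ObservableMap(scaling={"p53": 0.0, "mdm2": 1, "p21": 1, "btg2": 1})


class TestSteadyState:
    def test_p53_mrna_closed_form(self, base_params):
        ss = steady_state(base_params.replace(ks_p53_RNA=4.0, kd_p53_RNA=2.0))
        assert ss.P53_RNA == pytest.approx(2.0, rel=1e-9)

    def test_damage_balance(self, base_params, base_steady):
        p = base_params
        assert p.ks_DD == pytest.approx(p.kd_DD * base_steady.DD * base_steady.P53p, rel=1e-8)

    def test_residual_tolerance(self, base_params, base_steady):
        from p53ddr.model import _rhs_raw

        assert np.max(np.abs(_rhs_raw(base_steady.as_array(), base_params, 0.0))) <= 1e-8

    def test_matches_long_time_integration_at_unit_params(self, unit_params):
        """Oracle: equilibrium of a long integration from the origin."""
        ss = steady_state(unit_params)
        start = ModelState(*([0.01] * 10))
        traj = simulate(unit_params, start, StimulusSchedule(EC=0.0, tau=0.0),
                        np.array([1.0, 1e4]))
        np.testing.assert_allclose(traj.states[-1], ss.as_array(), rtol=1e-6, atol=1e-8)

    def test_protein_closed_form(self, base_params, base_steady):
        p = base_params
        assert base_steady.P21 == pytest.approx(
            p.ks_p21 * base_steady.P21_RNA / p.kd_p21, rel=1e-8
        )


class TestDisruptFeedback:
    def test_identity(self, base_params):
        assert disrupt_feedback(base_params, 1.0) == base_params

    def test_scales_only_feedback_rates(self, base_params):
        p = disrupt_feedback(base_params, 0.2)
        assert p.kd_p53_mdm2 == pytest.approx(0.2 * base_params.kd_p53_mdm2)
        assert p.kd_p53p_mdm2 == pytest.approx(0.2 * base_params.kd_p53p_mdm2)
        for name in RATE_PARAM_NAMES:
            if name not in ("kd_p53_mdm2", "kd_p53p_mdm2"):
                assert getattr(p, name) == getattr(base_params, name)

    def test_invalid_efficiency(self, base_params):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                disrupt_feedback(base_params, bad)

    def test_total_p53_monotone_in_disruption(self, base_params):
        """Weaker MDM2 feedback never lowers total p53 at any time."""
        grid = np.linspace(1.0, 65.0, 30)
        totals = {}
        for eff in (1.0, 0.5, 0.2):
            p = disrupt_feedback(base_params, eff)
            ss = steady_state(p)
            traj = simulate(p, ss, StimulusSchedule(EC=p.EC2, tau=p.tau), grid)
            totals[eff] = traj.species("P53") + traj.species("P53p")
        assert np.all(totals[0.2] >= totals[0.5] - 1e-9)
        assert np.all(totals[0.5] >= totals[1.0] - 1e-9)


class TestTrajectoryExport:
    def test_tidy_tsv_round_trip(self, base_params, base_steady, no_stimulus, tmp_path):
        import pandas as pd

        traj = simulate(base_params, base_steady, no_stimulus, np.array([1.0, 2.0]))
        observe(traj, ObservableMap())
        path = tmp_path / "traj.tsv"
        traj.to_tsv(path)
        df = pd.read_csv(path, sep="\t")
        state_rows = df[df["species"].notna()]
        assert len(state_rows) == 2 * len(SPECIES)
        obs_rows = df[df["reporter"].notna()]
        assert set(obs_rows["reporter"]) == {"p53", "mdm2", "p21", "btg2"}


class TestParameterContainer:
    def test_json_round_trip(self, base_params, tmp_path):
        path = tmp_path / "params.json"
        base_params.to_json(path, fixed=["EC1"])
        loaded, fixed = KineticParameters.from_json(path)
        assert loaded == base_params
        assert fixed == ["EC1"]

    def test_invalid_hill_rejected(self):
        with pytest.raises(ValueError):
            KineticParameters(**{n: 1.0 for n in RATE_PARAM_NAMES}, hill_n=2)

    def test_non_finite_rejected(self):
        vals = {n: 1.0 for n in RATE_PARAM_NAMES}
        vals["kp"] = float("nan")
        with pytest.raises(ValueError):
            KineticParameters(**vals)
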