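"""Markov likelihood machinery: generators, probabilities, fitting, tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from strokemsm.msmm import (ConvergenceError, MsmmParams, MsmmSpec,
                            MultistateMarkovModel, build_Q, fit_msmm,
                            global_treatment_test, lrt, panel_loglik,
                            reduce_structure, transition_probability)
from strokemsm.panel import StateSpace, TrialPanel
from strokemsm.simulate import SimulationSpec, simulate_trajectory, \
    simulate_trial


def series_expm(A: np.ndarray) -> np.ndarray:
    """Independent scaled Taylor-series oracle for the matrix exponential."""
    s = max(int(np.ceil(np.log2(max(np.abs(A).sum(axis=1).max(), 1e-30)))) + 1,
            0)
    B = A / 2 ** s
    term = np.eye(A.shape[0])
    out = term.copy()
    for k in range(1, 60):
        term = term @ B / k
        out += term
        if np.abs(term).max() < 1e-18:
            break
    for _ in range(s):
        out = out @ out
    return out


def random_generator(rng, n=4):
    Q = rng.uniform(0.1, 1.0, size=(n, n))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def panel_from(rows, state_space):
    return TrialPanel(pd.DataFrame(rows, columns=["subject_id", "arm",
                                                  "time_days", "state"]),
                      state_space=state_space)


class TestBuildQ:
    def setup_method(self):
        self.spec = MsmmSpec(state_space=StateSpace.reduced(),
                             covariates=("treatment",))
        nfree = len(self.spec.free_transitions)
        self.params = MsmmParams(log_q=np.full((1, nfree), -4.0),
                                 beta=np.zeros(len(self.spec.beta_index)))

    def test_null_betas_ignore_covariates(self):
        Q0 = build_Q(self.params, self.spec, {"treatment": 0.0})
        Q1 = build_Q(self.params, self.spec, {"treatment": 1.0})
        assert np.allclose(Q0, Q1)
        assert np.allclose(Q0.sum(axis=1), 0.0)
        assert (Q0[6] == 0).all()

    def test_hazard_ratio_scales_single_intensity(self):
        k = self.spec.beta_index.index(((1, 2), "treatment"))
        beta = np.zeros(len(self.spec.beta_index))
        beta[k] = np.log(0.5)
        params = MsmmParams(log_q=self.params.log_q, beta=beta)
        Q0 = build_Q(params, self.spec, {"treatment": 0.0})
        Q1 = build_Q(params, self.spec, {"treatment": 1.0})
        assert Q1[1, 2] == pytest.approx(0.5 * Q0[1, 2], rel=1e-12)
        others = [(r, s) for (r, s) in self.spec.free_transitions
                  if (r, s) != (1, 2)]
        for r, s in others:
            assert Q1[r, s] == pytest.approx(Q0[r, s], rel=1e-12)

    def test_pinned_transition_is_zero(self):
        spec = MsmmSpec(state_space=StateSpace.general(),
                        pinned=frozenset({(0, 6)}))
        nfree = len(spec.free_transitions)
        params = MsmmParams(log_q=np.full((1, nfree), 1.0), beta=np.zeros(0))
        Q = build_Q(params, spec, {})
        assert Q[0, 6] == 0.0

    def test_missing_covariate_is_hard_error(self):
        with pytest.raises(ValueError, match="treatment"):
            build_Q(self.params, self.spec, {})


class TestTransitionProbability:
    def test_zero_dt_identity(self):
        Q = random_generator(np.random.default_rng(0))
        assert np.allclose(transition_probability(Q, 0.0), np.eye(4))

    def test_two_state_closed_form(self):
        Q = np.array([[-1.0, 1.0], [0.0, 0.0]])
        P = transition_probability(Q, np.log(2))
        assert P[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_matches_series_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            Q = random_generator(rng)
            P = transition_probability(Q, 1.0)
            assert np.abs(P - series_expm(Q)).max() < 1e-10
            assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
            assert (P >= 0).all() and (P <= 1).all()

    def test_chapman_kolmogorov(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            Q = random_generator(rng, n=5)
            s, t = rng.uniform(0.1, 2.0, size=2)
            lhs = transition_probability(Q, s + t)
            rhs = transition_probability(Q, s) @ transition_probability(Q, t)
            assert np.abs(lhs - rhs).max() < 1e-9

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            transition_probability(np.zeros((2, 2)), -1.0)


class TestPanelLoglik:
    def test_zero_generator_same_state_contributes_zero(self, ss3):
        spec = MsmmSpec(state_space=ss3, death_mode="panel")
        panel = panel_from([("a", "control", 1.0, 1), ("a", "control", 5.0, 1)],
                           ss3)
        nfree = len(spec.free_transitions)
        params = MsmmParams(log_q=np.full((1, nfree), -40.0),
                            beta=np.zeros(0))
        assert panel_loglik(panel, spec, params) == pytest.approx(0.0,
                                                                  abs=1e-12)

    def test_interval_additivity(self, ss3):
        spec = MsmmSpec(state_space=ss3, death_mode="panel")
        nfree = len(spec.free_transitions)
        params = MsmmParams(log_q=np.full((1, nfree), -2.0), beta=np.zeros(0))
        both = panel_loglik(panel_from(
            [("a", "control", 1.0, 0), ("a", "control", 4.0, 1),
             ("a", "control", 9.0, 2)], ss3), spec, params)
        first = panel_loglik(panel_from(
            [("a", "control", 1.0, 0), ("a", "control", 4.0, 1)], ss3),
            spec, params)
        second = panel_loglik(panel_from(
            [("a", "control", 4.0, 1), ("a", "control", 9.0, 2)], ss3),
            spec, params)
        assert both == pytest.approx(first + second, abs=1e-10)

    def test_exact_death_term_matches_density(self):
        """The exact-death likelihood equals the absorption-time density
        d/dt P_{y0,death}(t), computed by central finite differences."""
        ss = StateSpace(states=(0, 1, 2), absorbing=frozenset({2}),
                        allowed=frozenset({(0, 1), (1, 0), (1, 2), (0, 2)}))
        spec = MsmmSpec(state_space=ss, death_mode="exact")
        nfree = len(spec.free_transitions)
        rng = np.random.default_rng(3)
        log_q = rng.uniform(-2.0, 0.0, size=(1, nfree))
        params = MsmmParams(log_q=log_q, beta=np.zeros(0))
        Q = build_Q(params, spec, {})
        T = 1.7
        ll = panel_loglik(panel_from(
            [("a", "control", 0.5, 0), ("a", "control", 0.5 + T, 2)], ss),
            spec, params)
        h = 1e-4
        density = (linalg.expm(Q * (T + h))[0, 2]
                   - linalg.expm(Q * (T - h))[0, 2]) / (2 * h)
        assert np.exp(ll) == pytest.approx(density, abs=1e-6)

    def test_piecewise_interval_uses_epoch_product(self, ss3):
        spec = MsmmSpec(state_space=ss3, death_mode="panel",
                        breakpoints=(10.0,))
        nfree = len(spec.free_transitions)
        rng = np.random.default_rng(4)
        log_q = rng.uniform(-3.0, -1.0, size=(2, nfree))
        params = MsmmParams(log_q=log_q, beta=np.zeros(0))
        ll = panel_loglik(panel_from(
            [("a", "control", 6.0, 0), ("a", "control", 13.0, 2)], ss3),
            spec, params)
        Q1 = build_Q(params, spec, {}, epoch=0)
        Q2 = build_Q(params, spec, {}, epoch=1)
        P = linalg.expm(Q1 * 4.0) @ linalg.expm(Q2 * 3.0)
        assert ll == pytest.approx(np.log(P[0, 2]), abs=1e-10)

    def test_tied_times_rejected(self, ss3):
        from strokemsm.panel import PanelValidationError
        with pytest.raises(PanelValidationError):
            panel_from([("a", "control", 1.0, 0), ("a", "control", 1.0, 1)],
                       ss3)


class TestFit:
    def test_complete_data_mle_matches_count_over_exposure(self, ss3):
        """With every transition time observed, the MLE equals the
        closed-form transition count / exposure time."""
        Q = np.array([[-.5, .5, 0], [.3, -.7, .4], [0, .6, -.6]])
        rng = np.random.default_rng(5)
        rows = []
        for i in range(150):
            t, p = simulate_trajectory([Q], [], 0, 15.0, rng,
                                       states=[0, 1, 2])
            for tt, s in zip(t, p):
                rows.append((f"s{i}", "control", tt, s))
            if t[-1] < 15.0:
                rows.append((f"s{i}", "control", 15.0, p[-1]))
        panel = panel_from(rows, ss3)
        spec = MsmmSpec(state_space=ss3, observation="exact",
                        death_mode="panel")
        fit = MultistateMarkovModel(panel, spec).fit(se=False, gtol=1e-9)
        counts = {tr: 0 for tr in ss3.sorted_transitions()}
        exposure = {0: 0.0, 1: 0.0, 2: 0.0}
        for _, grp in panel.data.groupby("subject_id"):
            t = grp["time_days"].to_numpy()
            y = grp["state"].to_numpy()
            for j in range(len(t) - 1):
                exposure[y[j]] += t[j + 1] - t[j]
                if y[j + 1] != y[j]:
                    counts[(y[j], y[j + 1])] += 1
        for j, tr in enumerate(spec.free_transitions):
            closed = counts[tr] / exposure[tr[0]]
            assert np.exp(fit.params.log_q[0, j]) == pytest.approx(
                closed, abs=1e-6)

    def test_panel_mle_approaches_complete_data_mle_as_grid_refines(self, ss3):
        """Panel MLEs on ever finer visit grids converge to the completely
        observed count/exposure estimate."""
        Q = np.array([[-.4, .4, 0], [.3, -.6, .3], [0, .5, -.5]])
        rng = np.random.default_rng(6)
        trajs = [simulate_trajectory([Q], [], 0, 12.0, rng,
                                     states=[0, 1, 2]) for _ in range(300)]

        def grid_panel(step):
            rows = []
            for i, (t, p) in enumerate(trajs):
                for g in np.arange(0, 12.0 + step / 2, step):
                    j = np.searchsorted(t, g, side="right") - 1
                    rows.append((f"s{i}", "control", g, p[max(j, 0)]))
            return panel_from(rows, ss3)

        spec = MsmmSpec(state_space=ss3, death_mode="panel")
        target = np.zeros(len(spec.free_transitions))
        counts = {tr: 0 for tr in ss3.sorted_transitions()}
        exposure = {0: 0.0, 1: 0.0, 2: 0.0}
        for t, p in trajs:
            edges = list(t) + [12.0]
            for j in range(len(t)):
                exposure[p[j]] += edges[j + 1] - edges[j]
                if j + 1 < len(p):
                    counts[(p[j], p[j + 1])] += 1
        for j, tr in enumerate(spec.free_transitions):
            target[j] = np.log(counts[tr] / exposure[tr[0]])
        errs = []
        for step in (1.5, 0.25):
            fit = MultistateMarkovModel(grid_panel(step), spec).fit(se=False)
            errs.append(np.abs(fit.params.log_q[0] - target).max())
        assert errs[1] < errs[0]
        assert errs[1] < 0.1

    def test_boundary_flag_when_transition_unobserved(self, ss3):
        rows = []
        for i in range(30):
            rows += [(f"s{i}", "control", 1.0, i % 2),
                     (f"s{i}", "control", 5.0, (i + 1) % 2)]
        panel = panel_from(rows, ss3)   # nobody ever reaches state 2
        spec = MsmmSpec(state_space=ss3, death_mode="panel")
        fit = MultistateMarkovModel(panel, spec).fit(se=False)
        j12 = spec.free_transitions.index((1, 2))
        assert fit.boundary[j12]
        reduced = reduce_structure(fit, threshold=1e-4)
        assert (1, 2) in reduced.pinned
        assert (0, 1) not in reduced.pinned

    def test_reduce_structure_keeps_supported_transitions(self, effect_trial):
        spec = MsmmSpec(covariates=())
        fit = fit_msmm(effect_trial.panel, spec, se=False)
        reduced = reduce_structure(fit, threshold=1e-7)
        assert reduced.pinned == spec.pinned   # all rates well supported

    def test_fit_invariant_to_subject_order(self, ss3):
        sim = simulate_trial(SimulationSpec(
            n_per_arm=60, seed=18, state_space=ss3,
            intensities=({(0, 1): .03, (1, 0): .02, (1, 2): .03,
                          (2, 1): .02},),
            breakpoints=(), initial_state_dist=(0.4, 0.3, 0.3),
            visit_days=(15, 60, 120), jitter_days=(2, 5, 5),
            covariate_models=()))
        spec = MsmmSpec(state_space=ss3, covariates=("treatment",),
                        death_mode="panel")
        fit1 = MultistateMarkovModel(sim.panel, spec).fit(se=False)
        shuffled = TrialPanel(
            sim.panel.data.sample(frac=1, random_state=1),
            baseline=sim.panel.baseline, state_space=ss3)
        fit2 = MultistateMarkovModel(shuffled, spec).fit(se=False)
        assert fit1.llf == pytest.approx(fit2.llf, abs=1e-6)
        assert np.allclose(fit1.params.pack(), fit2.params.pack(), atol=1e-4)

    def test_time_rescaling_equivariance(self, ss3):
        """Measuring time in tenths of days rescales intensities by 10 and
        leaves hazard ratios unchanged."""
        sim = simulate_trial(SimulationSpec(
            n_per_arm=80, seed=19, state_space=ss3,
            intensities=({(0, 1): .03, (1, 0): .02, (1, 2): .03,
                          (2, 1): .02},),
            breakpoints=(), treatment_log_hr={(0, 1): np.log(0.6)},
            initial_state_dist=(0.4, 0.3, 0.3),
            visit_days=(15, 60, 120), jitter_days=(2, 5, 5),
            covariate_models=()))
        spec = MsmmSpec(state_space=ss3, covariates=("treatment",),
                        death_mode="panel")
        fit = MultistateMarkovModel(sim.panel, spec).fit(se=False)
        scaled_data = sim.panel.data.copy()
        scaled_data["time_days"] = scaled_data["time_days"] * 10.0
        scaled = TrialPanel(scaled_data, state_space=ss3)
        fit10 = MultistateMarkovModel(scaled, spec).fit(se=False)
        assert np.allclose(fit10.params.beta, fit.params.beta, atol=5e-3)
        assert np.allclose(fit10.params.log_q, fit.params.log_q - np.log(10),
                           atol=5e-3)


class TestLrtAndGlobalTest:
    def test_identical_models_give_zero_statistic(self, ss3, effect_trial):
        spec = MsmmSpec(covariates=())
        fit = fit_msmm(effect_trial.panel, spec, se=False)
        with pytest.raises(ValueError):
            lrt(fit, fit)          # equal param counts: not nested
        stat, df, p = lrt(fit, fit_msmm(
            effect_trial.panel, MsmmSpec(covariates=("treatment",)),
            se=False))
        assert stat >= 0 and df == 12 and 0 <= p <= 1

    def test_global_test_df_is_twelve_on_reduced_structure(self, null_trial):
        p, fit1, fit0 = global_treatment_test(
            null_trial.panel, MsmmSpec(covariates=("treatment",)), se=False)
        assert fit1.n_params - fit0.n_params == 12
        assert 0 <= p <= 1

    def test_detects_strong_single_transition_effect(self):
        """A strong protective effect on one transition is detected by the
        global LRT in most replicates (power direction)."""
        from conftest import dense_world
        hits = 0
        for rep in range(10):
            sim = simulate_trial(dense_world(
                600 + rep, n_per_arm=150,
                treatment_log_hr={(1, 2): np.log(0.25)}))
            p, _, _ = global_treatment_test(
                sim.panel, MsmmSpec(covariates=("treatment",)), se=False)
            hits += p < 0.05
        assert hits >= 6

    def test_piecewise_detected_when_dynamics_change(self):
        """Constant vs piecewise LRT prefers piecewise when the generator
        really changes at the breakpoint."""
        wins = 0
        for rep in range(6):
            sim = simulate_trial(SimulationSpec(n_per_arm=200,
                                                seed=700 + rep))
            fit_const = fit_msmm(sim.panel, MsmmSpec(covariates=()),
                                 se=False)
            fit_pw = fit_msmm(sim.panel,
                              MsmmSpec(covariates=(), breakpoints=(90.0,)),
                              se=False)
            stat, df, p = lrt(fit_const, fit_pw)
            assert df == 12
            wins += p < 0.05
        assert wins >= 4

    def test_nonconvergence_carries_best_iterate(self, effect_trial):
        with pytest.raises(ConvergenceError) as err:
            fit_msmm(effect_trial.panel, MsmmSpec(covariates=("treatment",)),
                     maxiter=2, se=False)
        assert err.value.best_params.shape == (24,)
        assert np.isfinite(err.value.grad_norm)


class TestHazardRatioTable:
    def test_closed_form_ci(self, ss3):
        sim = simulate_trial(SimulationSpec(
            n_per_arm=150, seed=20, state_space=ss3,
            intensities=({(0, 1): .03, (1, 0): .02, (1, 2): .03,
                          (2, 1): .02},),
            breakpoints=(), initial_state_dist=(0.4, 0.3, 0.3),
            visit_days=(15, 60, 120), jitter_days=(2, 5, 5),
            covariate_models=()))
        spec = MsmmSpec(state_space=ss3, covariates=("treatment",),
                        death_mode="panel")
        fit = MultistateMarkovModel(sim.panel, spec).fit(se=True)
        tab = fit.hazard_ratio_table()
        for _, row in tab.iterrows():
            if np.isfinite(row.se):
                assert row.ci_lo == pytest.approx(
                    np.exp(row.log_hr - 1.959963984540054 * row.se), rel=1e-9)
                assert row.ci_hi == pytest.approx(
                    np.exp(row.log_hr + 1.959963984540054 * row.se), rel=1e-9)
        assert "hazard ratios" in fit.summary()
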