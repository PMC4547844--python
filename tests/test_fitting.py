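"""Multi-start protocol, local descent, ablation and sensitivity machinery.

The expensive end-to-end recovery experiments (ranking, parameter recovery,
robustness) live in test_acceptance.py; here the machinery is exercised at
small budgets.
"""

import numpy as np
import pytest

import limbgrn as lg
from limbgrn.fitting import (DEFAULT_START_GRID, FitResult, Objective,
                             ParameterSet, _converged, ablation_study,
                             initial_parameter_sets, optimize, param_bounds,
                             sensitivity_analysis)
from limbgrn.solver import SeriesContext


@pytest.fixture(scope="module")
def tiny_fit_setup(tiny_series):
    """A 4-hour dataset: enough for descent smoke tests."""
    model = lg.make_model("C")
    truth = lg.truth_params("C")
    ctx = SeriesContext(tiny_series)
    traj = lg.generate_ground_truth(tiny_series, model, truth, hours=(0, 4),
                                    ctx=ctx)
    ds = lg.sample_observations(
        traj, counts={"M": 3, "H11": 4, "H13": 4}, noise_sd=0.0, seed=0,
        windows={"M": (0, 3), "H11": (1, 4), "H13": (2, 4)})
    return model, truth, ds, ctx


class TestParameterSet:
    def test_vector_round_trip(self):
        model = lg.make_model("C")
        ps = ParameterSet("C", lg.truth_params("C"))
        back = ParameterSet.from_vector("C", ps.names, ps.to_vector())
        for k, v in ps.values.items():
            assert back.values[k] == pytest.approx(v, rel=1e-12)

    def test_validation(self):
        model = lg.make_model("C")
        ps = ParameterSet("C", lg.truth_params("C"))
        ps.validate(model)
        with pytest.raises(KeyError):
            bad = ParameterSet("C", {"mu": 4.0})
            bad.validate(model)
        with pytest.raises(ValueError):
            out = ParameterSet("C", dict(lg.truth_params("C"), k1=99.0))
            out.validate(model)

    def test_log_transform_for_rates_and_thresholds(self):
        lo, hi, tr = param_bounds("k_FH11")
        assert tr == "log"
        assert param_bounds("mu")[2] == "lin"
        assert param_bounds("P_FGF4")[2] == "lin"


class TestInitialSets:
    def test_exactly_27_sets(self):
        sets = initial_parameter_sets(lg.make_model("C"), seed=0)
        assert len(sets) == 27

    def test_grid_combinatorics(self):
        sets = initial_parameter_sets(lg.make_model("C"), seed=0)
        for pname in ("lam_F", "lam_R", "c1"):
            values = [s.values[pname] for s in sets]
            for g in DEFAULT_START_GRID[pname]:
                assert values.count(g) == 9

    def test_seeded_determinism_and_bounds(self):
        a = initial_parameter_sets(lg.make_model("F"), seed=3)
        b = initial_parameter_sets(lg.make_model("F"), seed=3)
        assert all(x.values == y.values for x, y in zip(a, b))
        model = lg.make_model("F")
        for s in a:
            s.validate(model)


class TestOptimize:
    def test_truth_start_on_noiseless_data_is_fixed_point(self,
                                                          tiny_fit_setup):
        model, truth, ds, ctx = tiny_fit_setup
        init = ParameterSet("C", dict(truth))
        res = optimize(model, ds, ctx.series, init, budget=30, ctx=ctx,
                       sim_opts={"hours": (0, 4)})
        assert res.final_score <= 1e-9
        assert res.converged

    def test_descent_contract(self, tiny_fit_setup):
        model, truth, ds, ctx = tiny_fit_setup
        init = initial_parameter_sets(model, seed=2)[0]
        res = optimize(model, ds, ctx.series, init, budget=25, ctx=ctx,
                       sim_opts={"hours": (0, 4)})
        assert res.final_score <= res.score_trajectory[0] + 1e-12
        assert np.all(np.diff(res.score_trajectory) <= 1e-12)
        assert res.n_evals <= 25 + 1

    def test_budget_must_be_positive(self, tiny_fit_setup):
        model, truth, ds, ctx = tiny_fit_setup
        with pytest.raises(ValueError):
            optimize(model, ds, ctx.series,
                     ParameterSet("C", dict(truth)), budget=0)


class TestConvergenceFlag:
    def test_plateau_after_descent_detected(self):
        assert _converged(list(np.linspace(5, 1, 30)) + [1.0] * 45)
        assert _converged(list(np.geomspace(40, 1e-6, 30)) + [1e-6] * 45)

    def test_stalls_and_active_descent_not_converged(self):
        # flat from the very start = stalled on a plateau, not converged
        assert not _converged([1.0] * 60)
        assert not _converged(list(np.geomspace(100, 1, 60)))
        assert not _converged([5.0, 4.0])
        assert not _converged([np.inf] * 60)


class TestAblation:
    def test_link_counting_and_scores(self, tiny_fit_setup):
        model, truth, ds, ctx = tiny_fit_setup
        # a fitted super-model standing in for the optimizer output: truth
        # values plus near-neutral extra links
        x0 = lg.make_model("X0")
        params = dict(truth, k_RH11=2.0, k_FH13=2.0)
        pset = ParameterSet("X0", params)
        fit = FitResult(model_name="X0", init=pset, final=pset,
                        score_trajectory=[0.0], final_score=None,
                        report=None, converged=True, n_evals=0)
        obj = Objective(x0, ds, ctx.series, ctx=ctx,
                        sim_opts={"hours": (0, 4)})
        fit.final_score = obj.score(params)
        table = ablation_study(ds, ctx.series, x0_fit=fit, refit_budget=30,
                               sim_opts={"hours": (0, 4)})
        # one row per RA/FGF->Hox link; a short refit never scores worse
        # than the unrefit ablation (the link-importance ordering itself is
        # an acceptance-level check on the fitted super-model)
        assert len(table) == 4
        assert set(table.index) == {"R->H11", "R->H13", "F->H11", "F->H13"}
        assert (table["refit_score"]
                <= table["unrefit_score"] * (1 + 1e-6) + 1e-9).all()
        assert table.attrs["x0_score"] == pytest.approx(fit.final_score)


class TestSensitivity:
    def test_fitted_point_is_scan_minimum(self, tiny_fit_setup):
        model, truth, ds, ctx = tiny_fit_setup
        table = sensitivity_analysis(model, ParameterSet("C", dict(truth)),
                                     ds, ctx.series,
                                     factors=(0.25, 1.0, 4.0),
                                     sim_opts={"hours": (0, 4)})
        assert table.attrs["fitted_score"] == pytest.approx(0.0, abs=1e-12)
        assert (table["min_scan_score"] >= -1e-12).all()
        assert (table["normalized_curvature"] >= 0).all()
        assert table["flat"].dtype == bool
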