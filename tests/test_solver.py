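"""Finite-volume operator, integrators, closed forms, conservation, remesh."""

import numpy as np
import pytest

import limbgrn as lg
from limbgrn import models as mo
from limbgrn.models import FIXED_PARAMS
from limbgrn.solver import (FieldState, SeriesContext, SolverError,
                            assemble_diffusion_operator, concat_trajectories,
                            presimulate_gradients, simulate, stable_dt, step,
                            transect_profile)


@pytest.fixture(scope="module")
def mesh0(tiny_series):
    return tiny_series.meshes[0]


class TestDiffusionOperator:
    def test_laplacian_of_constant_is_zero(self, mesh0):
        L, _ = assemble_diffusion_operator(mesh0)
        c = np.full(mesh0.n_elements, 3.7)
        assert np.abs(L @ c).max() < 1e-12

    def test_flux_matrix_conserves_amount(self, mesh0):
        _, K = assemble_diffusion_operator(mesh0)
        rng = np.random.default_rng(0)
        c = rng.uniform(0, 1, mesh0.n_elements)
        # column sums of K vanish, so total amount A*(L c) sums to zero
        assert abs((K @ c).sum()) < 1e-9

    def test_explicit_diffusion_step_conserves_mass(self, mesh0):
        L, _ = assemble_diffusion_operator(mesh0)
        rng = np.random.default_rng(1)
        c = rng.uniform(0, 1, mesh0.n_elements)
        dt = stable_dt(mesh0)
        total0 = (c * mesh0.element_area).sum()
        for _ in range(int(60 / dt)):  # one simulated hour
            c = c + dt * FIXED_PARAMS["D_R"] * (L @ c)
        total = (c * mesh0.element_area).sum()
        assert total == pytest.approx(total0, rel=1e-9)

    def test_implicit_diffusion_solve_conserves_mass(self, tiny_series):
        ctx = SeriesContext(tiny_series).at(0)
        mesh = tiny_series.meshes[0]
        lu = ctx.lu(FIXED_PARAMS["D_R"], 2.0)
        rng = np.random.default_rng(2)
        c = rng.uniform(0, 1, mesh.n_elements)
        total0 = (c * mesh.element_area).sum()
        for _ in range(30):  # one hour at dt=2
            c = lu.solve(mesh.element_area * c)
        assert (c * mesh.element_area).sum() == pytest.approx(total0, rel=1e-9)
        assert np.all(c >= 0)


class TestClosedForms:
    """Single-element kinetics against the analytic solutions."""

    def _single_element_run(self, scheme, dt, t_end, params, c0=0.0):
        # a non-diffusible species with saturating drive: Meis under a large
        # uniform RA pool (act(R, k2) ~ 1 throughout, R decays very slowly)
        from limbgrn.solver import _MeshContext, _run_hour
        mesh = lg.triangulate(
            lg.build_limb_outline(0), 60.0, hour=0, params=lg.GeometryParams())
        mctx = _MeshContext(mesh)
        state = FieldState(0, 0.0, np.zeros((6, mesh.n_elements)))
        state.values[mo.M] = c0
        state.values[mo.R] = 50.0
        active = np.zeros(6, dtype=bool)
        active[[mo.M, mo.R]] = True
        return _run_hour(mctx, state, lg.make_model("C"), params, t_end, dt,
                         scheme, active)

    @pytest.mark.parametrize("scheme,dt", [("imex", 2.0), ("euler", 0.5)])
    def test_saturated_production_reaches_unit_steady_state(self, scheme, dt):
        # P = lambda = 0.05/min => c(t) = 1 - exp(-0.05 t) -> 1.0
        params = dict(lg.truth_params("C"), lam_R=1e-3, c1=1e-2)
        out = self._single_element_run(scheme, dt, 500.0, params)
        assert out.values[mo.M].max() == pytest.approx(1.0, abs=1e-3)

    def test_imex_decay_is_exact(self):
        # no RA drive: Meis decays as c0 * exp(-lambda t), which the
        # exponential reaction update reproduces to round-off
        from limbgrn.solver import _MeshContext, _run_hour
        mesh = lg.triangulate(lg.build_limb_outline(0), 60.0, hour=0,
                              params=lg.GeometryParams())
        mctx = _MeshContext(mesh)
        state = FieldState(0, 0.0, np.zeros((6, mesh.n_elements)))
        state.values[mo.M] = 0.8
        active = np.zeros(6, dtype=bool)
        active[mo.M] = True
        out = _run_hour(mctx, state, lg.make_model("C"), lg.truth_params("C"),
                        240.0, 2.0, "imex", active)
        expected = 0.8 * np.exp(-FIXED_PARAMS["lam_M"] * 240.0)
        assert out.values[mo.M].max() == pytest.approx(expected, rel=1e-12)

    def test_euler_decay_matches_theory_at_small_dt(self):
        # explicit steps approach the exponential with O(dt) error
        from limbgrn.solver import _MeshContext, _run_hour
        mesh = lg.triangulate(lg.build_limb_outline(0), 60.0, hour=0,
                              params=lg.GeometryParams())
        mctx = _MeshContext(mesh)
        state = FieldState(0, 0.0, np.zeros((6, mesh.n_elements)))
        state.values[mo.M] = 0.8
        active = np.zeros(6, dtype=bool)
        active[mo.M] = True
        out = _run_hour(mctx, state, lg.make_model("C"), lg.truth_params("C"),
                        120.0, 0.05, "euler", active)
        expected = 0.8 * np.exp(-FIXED_PARAMS["lam_M"] * 120.0)
        assert out.values[mo.M].max() == pytest.approx(expected, rel=1e-2)


class TestStepAndSimulate:
    def test_zero_state_production_structure(self, mesh0):
        # from the all-zero state, one step creates morphogen only in the
        # source elements, leaves the activator-driven genes (M, H11) at
        # zero, and derepresses H13 everywhere (its only regulator is an
        # inhibitor, so zero RA means full production)
        params = lg.truth_params("C")
        state = FieldState(0, 0.0, np.zeros((6, mesh0.n_elements)))
        out = step(state, lg.make_model("C"), mesh0, 1.0, params)
        labels = mesh0.region_labels
        assert np.all(out.values[mo.F][labels <= 1] == 0.0)
        assert np.all(out.values[mo.F][labels >= 2] > 0.0)
        assert np.all(out.values[mo.R][labels != 1] == 0.0)
        assert np.all(out.values[mo.R][labels == 1] > 0.0)
        assert np.all(out.values[[mo.M, mo.H11]] == 0.0)
        assert np.all(out.values[mo.H13] > 0.0)

    def test_step_detects_nonfinite(self, mesh0):
        params = dict(lg.truth_params("C"), c1=1e300)
        state = FieldState(0, 0.0, np.full((6, mesh0.n_elements), 1e300))
        with pytest.raises(SolverError, match="species"):
            out = state
            for _ in range(4):
                out = step(out, lg.make_model("C"), mesh0, 1e3, params)

    def test_presimulation_geometry(self, tiny_series):
        mesh = tiny_series.meshes[0]
        params = lg.truth_params("C")
        state = presimulate_gradients(mesh, lg.make_model("C"), params)
        assert np.all(state.values[[mo.M, mo.H11, mo.H13]] == 0.0)
        # RA maximal near the flank, monotone non-increasing along the PD
        # transect; FGF maximal near the AER
        x, r_prof = transect_profile(mesh, state.values[mo.R])
        sm = np.convolve(r_prof, np.ones(3) / 3, mode="valid")
        assert np.argmax(r_prof) <= 2  # peak at/near the flank
        assert np.all(np.diff(sm) <= 1e-9)
        f = state.values[mo.F]
        aer = np.isin(mesh.region_labels, (2, 3))
        assert f[aer].max() == f.max()

    def test_presimulation_zero_duration_and_modes(self, tiny_series):
        mesh = tiny_series.meshes[0]
        params = lg.truth_params("C")
        z = presimulate_gradients(mesh, lg.make_model("C"), params, duration=0)
        assert np.all(z.values == 0.0)
        d = presimulate_gradients(mesh, lg.make_model("C"), params,
                                  mode="diffusion_only")
        assert np.all(d.values[mo.C] == 0.0)
        u = presimulate_gradients(mesh, lg.make_model("C"), params,
                                  mode="upstream")
        assert u.values[mo.C].max() > 0.0

    def test_empty_window_returns_presimulated_state(self, tiny_series):
        params = lg.truth_params("C")
        traj = simulate(tiny_series, lg.make_model("C"), params, hours=(0, 0))
        assert len(traj.fields) == 1
        ref = presimulate_gradients(tiny_series.meshes[0],
                                    lg.make_model("C"), params)
        assert np.allclose(traj.fields[0], ref.values)

    def test_trajectory_bookkeeping(self, tiny_series):
        params = lg.truth_params("C")
        traj = simulate(tiny_series, lg.make_model("C"), params, hours=(0, 3),
                        output_every=30.0)
        assert np.all(np.diff(traj.times_min) > 0)
        # element counts follow the mesh of each recorded hour
        for mh, f in zip(traj.mesh_hours, traj.fields):
            assert f.shape == (6, tiny_series.meshes[mh].n_elements)
        with pytest.raises(KeyError):
            traj.index_at_hour(2.37)

    def test_schemes_agree_on_smooth_dynamics(self, tiny_series):
        params = lg.truth_params("C")
        a = simulate(tiny_series, lg.make_model("C"), params, hours=(0, 2),
                     scheme="imex", dt=1.0)
        b = simulate(tiny_series, lg.make_model("C"), params, hours=(0, 2),
                     scheme="euler")
        rms = np.sqrt(np.mean((a.fields[-1] - b.fields[-1]) ** 2))
        assert rms < 0.02

    def test_concat_trajectories_matches_single_run(self, tiny_series):
        params = lg.truth_params("C")
        whole = simulate(tiny_series, lg.make_model("C"), params, hours=(0, 3))
        first = simulate(tiny_series, lg.make_model("C"), params, hours=(0, 2))
        second = simulate(tiny_series, lg.make_model("C"), params,
                          hours=(2, 3),
                          initial_state=FieldState(2, 0.0, first.fields[-1]))
        joined = concat_trajectories(first, second)
        assert joined.times_min == pytest.approx(whole.times_min)
        assert np.allclose(joined.fields[-1], whole.fields[-1], atol=1e-12)


class TestRefinement:
    def test_central_profile_converges_under_refinement(self):
        """Halving the default target edge changes the central RA profile
        by well under 5% RMS (discretization convergence)."""
        from scipy.interpolate import griddata
        params = lg.truth_params("C")
        gp = lg.GeometryParams()
        fields = {}
        for edge in (65.0, 32.5):
            series = lg.build_growth_series(n_hours=3, params=gp,
                                            target_edge=edge)
            traj = simulate(series, lg.make_model("C"), params, hours=(0, 3))
            mesh = series.meshes[traj.mesh_hours[-1]]
            fields[edge] = (mesh.centroids, traj.fields[-1][mo.R])
        gx, gy = np.meshgrid(np.linspace(50, gp.pd_extent(3) - 50, 30),
                             np.linspace(-80, 80, 9))
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        a = griddata(*fields[65.0], pts, method="linear")
        b = griddata(*fields[32.5], pts, method="linear")
        m = np.isfinite(a) & np.isfinite(b)
        rms = np.sqrt(np.mean((a[m] - b[m]) ** 2))
        assert rms < 0.05 * np.abs(b[m]).max()
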