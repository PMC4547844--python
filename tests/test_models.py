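"""Hill functions, topology definitions, production terms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import limbgrn as lg
from limbgrn import models as mo
from limbgrn.models import (FIXED_PARAMS, HillDomainError, MODEL_NAMES,
                            ablate_link, hill_act, hill_inh, make_model,
                            make_production_fn, production_rates)


class TestHill:
    def test_half_saturation(self):
        for mu in (1.0, 2.0, 8.0):
            assert hill_act(0.37, 0.37, mu) == pytest.approx(0.5)
            assert hill_inh(0.37, 0.37, mu) == pytest.approx(0.5)

    def test_limits(self):
        assert hill_act(0.0, 0.5, 4) == 0.0
        assert hill_inh(0.0, 0.5, 4) == 1.0
        assert hill_act(1.0, 0.5, 4) == pytest.approx(0.9412, abs=5e-5)

    @given(x=st.floats(0.0, 10.0), k=st.floats(0.01, 5.0),
           mu=st.floats(0.5, 12.0))
    @settings(max_examples=200, deadline=None)
    def test_activation_inhibition_partition_unity(self, x, k, mu):
        assert hill_act(x, k, mu) + hill_inh(x, k, mu) == pytest.approx(1.0)

    def test_monotonicity(self):
        x = np.linspace(0, 3, 50)
        a = hill_act(x, 0.7, 6)
        assert np.all(np.diff(a) > 0)
        assert np.all(np.diff(hill_inh(x, 0.7, 6)) < 0)

    def test_domain_errors(self):
        with pytest.raises(HillDomainError):
            hill_act(-0.1, 0.5, 4)
        with pytest.raises(HillDomainError):
            hill_inh(1.0, 0.0, 4)


class TestTopologies:
    def test_upstream_circuit_common_to_all(self):
        for name in MODEL_NAMES:
            m = make_model(name)
            assert m.has_link("F", "C")
            assert m.has_link("R", "M")
            assert m.has_link("H13", "H11")

    def test_h13_h11_repression_uses_distinct_coefficient(self):
        m = make_model("C")
        (link,) = [l for l in m.links if l.key == ("H13", "H11")]
        assert link.hill == "mu_tilde"
        assert all(l.hill == "mu" for l in m.links if l.key != ("H13", "H11"))

    @pytest.mark.parametrize("name,hox", [
        ("A", {("R", "H11"), ("R", "H13")}),
        ("B", {("F", "H11"), ("F", "H13")}),
        ("C", {("F", "H11"), ("R", "H13")}),
        ("D", {("R", "H11"), ("F", "H13")}),
    ])
    def test_minimal_model_wiring(self, name, hox):
        m = make_model(name)
        assert {l.key for l in m.hox_links()} == hox

    def test_minimal_models_have_equal_free_parameter_counts(self):
        counts = {n: len(make_model(n).free_parameters) for n in "ABCD"}
        assert len(set(counts.values())) == 1

    def test_supermodel_and_intermediates(self):
        assert len(make_model("X0").hox_links()) == 4
        for i in range(1, 5):
            assert len(make_model(f"X{i}").hox_links()) == 3

    def test_double_ablation_of_x0_recreates_model_c(self):
        m = ablate_link(ablate_link(make_model("X0"), ("R", "H11")),
                        ("F", "H13"))
        assert {l.key for l in m.links} == {l.key
                                            for l in make_model("C").links}

    def test_ablating_absent_link_raises(self):
        m = ablate_link(make_model("X0"), ("R", "H11"))
        with pytest.raises(KeyError):
            ablate_link(m, ("R", "H11"))
        with pytest.raises(KeyError):
            ablate_link(make_model("C"), ("R", "H11"))

    def test_extended_models_add_meis_links(self):
        assert make_model("E").has_link("M", "H13")
        assert make_model("F").has_link("M", "C")

    def test_unknown_model_name(self):
        with pytest.raises(KeyError):
            make_model("Z")


def _masks(n):
    flank = np.zeros(n)
    flank[0] = 1.0
    aer = np.zeros(n)
    aer[-1] = 1.0
    return flank, aer, np.zeros(n)


class TestProduction:
    def test_model_c_limits(self):
        m = make_model("C")
        p = lg.truth_params("C")
        state = np.zeros((6, 3))
        state[mo.R] = 5.0  # high RA, no FGF, no H13
        prod = production_rates(state, m, p, *_masks(3))
        assert np.all(prod[mo.H11] == 0.0)  # no FGF activation
        assert prod[mo.M][0] == pytest.approx(FIXED_PARAMS["P_M"], rel=1e-3)
        assert np.all(prod[mo.H13] < 1e-5)  # repressed by RA

    def test_model_a_full_derepression(self):
        m = make_model("A")
        p = {**lg.truth_params("C"), "k_RH11": 0.5, "k_RH13": 0.1}
        for k in ("k_FH11",):
            p.pop(k)
        state = np.zeros((6, 2))
        prod = production_rates(state, m, p, *_masks(2))
        assert np.allclose(prod[mo.H11], FIXED_PARAMS["P_H11"])
        assert np.allclose(prod[mo.H13], FIXED_PARAMS["P_H13"])

    def test_model_f_meis_suppresses_cyp26b1(self):
        m = make_model("F")
        p = lg.truth_params("F")
        state = np.zeros((6, 1))
        state[mo.F] = 5.0
        base = production_rates(state, m, p, *_masks(1))[mo.C][0]
        state[mo.M] = 3.0 * p["k_MC"]
        suppressed = production_rates(state, m, p, *_masks(1))[mo.C][0]
        assert suppressed < 0.5 * base

    def test_production_bounded_by_max_rates(self):
        rng = np.random.default_rng(3)
        state = np.abs(rng.normal(0.5, 0.5, (6, 20)))
        for name in ("A", "C", "F", "X0"):
            m = make_model(name)
            p = dict(lg.truth_params("C"), k_RH11=0.5, k_FH13=1.0,
                     k_MC=1.0, k_MH13=1.1)
            prod = production_rates(state, m, p, *_masks(20))
            for gene, pmax in (("C", "P_C"), ("M", "P_M"),
                               ("H11", "P_H11"), ("H13", "P_H13")):
                assert np.all(prod[mo.SPECIES_INDEX[gene]]
                              <= FIXED_PARAMS[pmax] + 1e-12)

    def test_missing_link_parameter_names_the_link(self):
        m = make_model("C")
        p = lg.truth_params("C")
        p.pop("k_RH13")
        with pytest.raises(KeyError, match="k_RH13"):
            production_rates(np.zeros((6, 2)), m, p, *_masks(2))

    @pytest.mark.parametrize("name", ["A", "B", "C", "D", "E", "F", "X0"])
    def test_compiled_production_matches_reference(self, name):
        m = make_model(name)
        p = dict(lg.truth_params("C"), k_RH11=0.5, k_FH13=1.0,
                 k_MC=1.0, k_MH13=1.1)
        rng = np.random.default_rng(11)
        state = np.abs(rng.normal(0.4, 0.4, (6, 40)))
        masks = _masks(40)
        ref = production_rates(state, m, p, *masks)
        fast = np.empty_like(state)
        make_production_fn(m, p, *masks)(state, fast)
        assert np.allclose(ref, fast, atol=1e-14)


class TestMutualExclusionMechanism:
    def test_h13_h11_repression_enforces_exclusive_domains(
            self, coarse_series, coarse_ctx):
        """Deleting the Hoxa13 -| Hoxa11 link makes the two marker domains
        overlap distally; with the link they are mutually exclusive."""
        import dataclasses
        base = make_model("C")
        stripped = dataclasses.replace(
            base, links=tuple(l for l in base.links
                              if l.key != ("H13", "H11")))
        params = lg.truth_params("C")
        with_link = lg.simulate(coarse_series, base, params, hours=(0, 14),
                                ctx=coarse_ctx)
        without = lg.simulate(coarse_series, stripped, params, hours=(0, 14),
                              ctx=coarse_ctx)

        def coexpression(traj):
            v = traj.fields[-1]
            return np.mean((v[mo.H11] > 0.5) & (v[mo.H13] > 0.5))

        assert coexpression(with_link) < 0.05
        assert coexpression(without) > 0.15
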