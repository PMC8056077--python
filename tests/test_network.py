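"""Network reconstruction, rate laws, stoichiometry and growth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import seedflux as sf
from seedflux.expression import ConfigurationError
from seedflux.network import (
    COFACTOR_PAIRS,
    CompiledModel,
    GrowthModel,
    Metabolite,
    ParameterSet,
    RateLawSpec,
    Reaction,
    hill_inhibition,
)


class TestDefaultReconstruction:
    def test_dimensions(self, default_model):
        assert len(default_model.metabolites) == 34
        assert len(default_model.reactions) == 40
        s = default_model.stoichiometric_matrix()
        assert s.shape == (34, 40)

    def test_parameter_count_near_125(self, default_model):
        assert 110 <= len(default_model.parameters) <= 140

    def test_every_enzymatic_reaction_has_turnover_class(self, default_model):
        for rxn in default_model.reactions:
            if rxn.enzyme_id is not None:
                assert rxn.enzyme_id in default_model.enzyme_turnover

    def test_validation_passes(self, default_model):
        default_model.validate()

    def test_no_gluconeogenic_route(self, default_model):
        # glycolytic mode only: no reaction produces hexose-P from triose-P
        for rxn in default_model.reactions:
            coeff = rxn.stoichiometry
            assert not (
                coeff.get("TP_c", 0) < 0 and coeff.get("HP_c", 0) > 0
            ), f"{rxn.id} runs gluconeogenic"

    def test_parameters_within_bounds(self, default_model):
        for name, prm in default_model.parameters.items():
            lo, hi = prm.bounds
            assert lo <= prm.value <= hi, name

    def test_irreversible_fluxes_nonnegative_in_random_states(
        self, default_model
    ):
        compiled = CompiledModel(default_model)
        rng = np.random.default_rng(42)
        for _ in range(20):
            y = rng.uniform(0, 3, size=compiled.n_met)
            e = rng.uniform(0, 5, size=len(compiled.enzyme_ids))
            v = compiled.fluxes(y, e, mu=0.01, mrna={"SPRT": 1.0})
            assert np.all(v[compiled.irreversible] >= 0)


def _toy_reaction():
    p = ParameterSet()
    p.add("k", 2.0)
    p.add("Km", 0.5)
    p.add("Ki", 0.3)
    p.add("n", 2.0, bounds=(1.0, 4.0))
    rxn = Reaction(
        "R", {"S": -1, "P": 1},
        RateLawSpec(
            "michaelis_menten", k="k",
            substrates=(("S", "Km", 1.0),),
            inhibitors=(("I", "Ki", "n"),),
        ),
        "E",
    )
    return rxn, p


class TestRateLaws:
    @pytest.fixture()
    def toy(self):
        p = ParameterSet()
        p.add("k", 2.0)
        p.add("Km", 0.5)
        p.add("Ki", 0.3)
        p.add("n", 2.0, bounds=(1.0, 4.0))
        rxn = Reaction(
            "R", {"S": -1, "P": 1},
            RateLawSpec(
                "michaelis_menten", k="k",
                substrates=(("S", "Km", 1.0),),
                inhibitors=(("I", "Ki", "n"),),
            ),
            "E",
        )
        return rxn, p

    def test_half_saturation(self, toy):
        rxn, p = toy
        v = sf.eval_flux(rxn, {"S": 0.5, "P": 0.0, "I": 0.0}, 1.0, p)
        assert v == pytest.approx(0.5 * 1.0 * 2.0)

    def test_hill_midpoint(self, toy):
        rxn, p = toy
        v0 = sf.eval_flux(rxn, {"S": 10.0, "P": 0, "I": 0.0}, 1.0, p)
        v1 = sf.eval_flux(rxn, {"S": 10.0, "P": 0, "I": 0.3}, 1.0, p)
        assert v1 / v0 == pytest.approx(0.5)

    def test_flux_proportional_to_enzyme(self, toy):
        rxn, p = toy
        v1 = sf.eval_flux(rxn, {"S": 1.0, "P": 0, "I": 0.0}, 1.0, p)
        v2 = sf.eval_flux(rxn, {"S": 1.0, "P": 0, "I": 0.0}, 2.0, p)
        assert v2 == pytest.approx(2.0 * v1)

    @given(s=st.floats(0.0, 10.0), s2=st.floats(0.0, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_substrate(self, s, s2):
        rxn, p = _toy_reaction()
        lo, hi = sorted((s, s2))
        v_lo = sf.eval_flux(rxn, {"S": lo, "I": 0.0}, 1.0, p)
        v_hi = sf.eval_flux(rxn, {"S": hi, "I": 0.0}, 1.0, p)
        assert v_hi >= v_lo - 1e-12

    @given(i=st.floats(0.0, 10.0), i2=st.floats(0.0, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_decreasing_in_inhibitor(self, i, i2):
        rxn, p = _toy_reaction()
        lo, hi = sorted((i, i2))
        v_lo = sf.eval_flux(rxn, {"S": 1.0, "I": lo}, 1.0, p)
        v_hi = sf.eval_flux(rxn, {"S": 1.0, "I": hi}, 1.0, p)
        assert v_hi <= v_lo + 1e-12

    def test_zero_substrate_zero_flux_every_irreversible_reaction(
        self, default_model
    ):
        zero = {m.id: 0.0 for m in default_model.metabolites}
        for rxn in default_model.reactions:
            if rxn.reversible or not rxn.rate_law.substrates:
                continue
            v = sf.eval_flux(
                rxn, zero, 1.0, default_model.parameters, mu=0.01, mrna=1.0
            )
            assert v == pytest.approx(0.0, abs=1e-12), rxn.id

    def test_reversible_rate_changes_sign_at_equilibrium(self):
        # two-metabolite sucrose-synthase-like toy: 2 G <-> S, Keq = 4
        p = ParameterSet()
        p.add("k", 1.0)
        p.add("Ka", 1.0)
        p.add("Kp", 1.0)
        p.add("Keq", 4.0)
        rxn = Reaction(
            "SUS", {"G": -2, "S": 1},
            RateLawSpec(
                "reversible_mm", k="k",
                substrates=(("G", "Ka", 2.0),),
                products=(("S", "Kp", 1.0),),
                keq="Keq",
            ),
            "E", reversible=True,
        )
        # at equilibrium S = Keq * G^2
        g = 0.8
        s_eq = 4.0 * g**2
        v_eq = sf.eval_flux(rxn, {"G": g, "S": s_eq}, 1.0, p)
        v_fwd = sf.eval_flux(rxn, {"G": g, "S": 0.5 * s_eq}, 1.0, p)
        v_rev = sf.eval_flux(rxn, {"G": g, "S": 2.0 * s_eq}, 1.0, p)
        assert v_eq == pytest.approx(0.0, abs=1e-12)
        assert v_fwd > 0 > v_rev

    def test_scfa_feedback_multiplier_limits(self):
        assert sf.scfa_feedback_multiplier(0.0, 0.05) == 1.0
        assert sf.scfa_feedback_multiplier(0.05, 0.05) == pytest.approx(0.5)
        assert sf.scfa_feedback_multiplier(100.0, 0.05) < 1e-4
        # strictly decreasing
        xs = np.linspace(0, 1, 50)
        ys = [sf.scfa_feedback_multiplier(x, 0.05) for x in xs]
        assert np.all(np.diff(ys) < 0)

    def test_maintenance_flux_reduces_to_beta_without_growth(
        self, default_model
    ):
        rxn = default_model.reaction("ATPM")
        p = default_model.parameters
        state = {"ATP": 1e9}  # saturate the MM guard
        v = sf.eval_flux(rxn, state, 1.0, p, mu=0.0)
        assert v == pytest.approx(p.value("beta_maint"), rel=1e-6)

    def test_storage_protein_flux_proportional_to_mrna(self, default_model):
        rxn = default_model.reaction("SPRTS")
        p = default_model.parameters
        state = {"GLT_c": 5.0, "ATP": 5.0}
        v0 = sf.eval_flux(rxn, state, 1.0, p, mrna=0.0)
        v2 = sf.eval_flux(rxn, state, 1.0, p, mrna=2.0)
        v4 = sf.eval_flux(rxn, state, 1.0, p, mrna=4.0)
        assert v0 == 0.0
        assert v4 == pytest.approx(2.0 * v2)


class TestStoichiometry:
    def test_unit_flux_reproduces_each_stoichiometric_column(
        self, default_model
    ):
        # reaction-by-reaction oracle: S . e_j == the reaction's own
        # stoichiometry dict, independently reassembled
        compiled = CompiledModel(default_model)
        met_index = compiled.met_index
        for j, rxn in enumerate(default_model.reactions):
            unit = np.zeros(compiled.n_rxn)
            unit[j] = 1.0
            dy = compiled.s_matrix @ unit
            expected = np.zeros(compiled.n_met)
            for met, coeff in rxn.stoichiometry.items():
                expected[met_index[met]] = coeff
            np.testing.assert_allclose(dy, expected, atol=1e-12, err_msg=rxn.id)

    def test_cofactor_pairs_conserved_by_every_reaction(self, default_model):
        s = default_model.stoichiometric_matrix()
        ids = default_model.metabolite_ids
        for pair, members in COFACTOR_PAIRS.items():
            rows = s[[ids.index(m) for m in members], :]
            np.testing.assert_allclose(
                rows.sum(axis=0), 0.0, atol=1e-12, err_msg=pair
            )

    def test_rhs_pure_dilution_when_fluxes_vanish(self, default_model):
        compiled = CompiledModel(default_model)
        zero_e = np.zeros(len(compiled.enzyme_ids))
        mu = 0.02
        rhs = compiled.rhs(lambda t: zero_e, lambda t: mu, {"SPRT": lambda t: 0.0})
        y = default_model.initial_state()
        # suppress non-enzymatic background fluxes by zeroing their rates
        compiled.k_vec[:] = 0.0
        compiled.alpha = compiled.beta = 0.0
        dy = rhs(0.0, y)
        for i, met in enumerate(default_model.metabolites):
            if met.clamped:
                assert dy[i] == 0.0
            elif met.cofactor_pair_id is not None:
                assert dy[i] == pytest.approx(0.0, abs=1e-12)
            else:
                assert dy[i] == pytest.approx(-mu * y[i], rel=1e-9)

    def test_single_reaction_bookkeeping(self):
        # A -> B with flux f: dA/dt = -f, dB/dt = +f at mu = 0
        p = ParameterSet()
        p.add("k", 1.0)
        p.add("Km", 0.5)
        model = sf.MetabolicModel(
            metabolites=[
                Metabolite("A", "cytosol", 1.0),
                Metabolite("B", "cytosol", 0.0),
            ],
            reactions=[
                Reaction("R", {"A": -1, "B": 1},
                         RateLawSpec("michaelis_menten", k="k",
                                     substrates=(("A", "Km", 1.0),)), "E"),
            ],
            parameters=p,
            growth=GrowthModel(),
            enzyme_turnover={"E": "average"},
        )
        compiled = CompiledModel(model)
        rhs = compiled.rhs(lambda t: np.ones(1), lambda t: 0.0)
        dy = rhs(0.0, np.array([1.0, 0.0]))
        f = 1.0 * 1.0 / (0.5 + 1.0)
        np.testing.assert_allclose(dy, [-f, f])


class TestGrowthModel:
    def test_growth_rate_endpoints(self, default_model):
        g = default_model.growth
        assert g.mu(0.0) == pytest.approx(0.025, rel=1e-9)
        assert g.mu(g.t_mature_daf * 24.0) == pytest.approx(0.0025, rel=1e-9)

    def test_mass_nondecreasing_and_bounded(self, default_model):
        g = default_model.growth
        ts = np.linspace(0, 21 * 24, 500)
        mass = g.mass(ts)
        assert np.all(np.diff(mass) >= 0)
        assert np.all(mass < g.m_max)

    def test_mu_is_logarithmic_mass_derivative(self, default_model):
        g = default_model.growth
        ts = np.linspace(10, 500, 200)
        mass = np.asarray(g.mass(ts))
        dlogm = np.gradient(np.log(mass), ts)
        # one-sided end stencils are first-order; compare the interior
        np.testing.assert_allclose(
            dlogm[1:-1], np.asarray(g.mu(ts))[1:-1], rtol=5e-3
        )

    def test_invalid_rates_rejected(self):
        with pytest.raises(ConfigurationError):
            GrowthModel(mu_early=0.001, mu_mature=0.01)


class TestConfigRoundTrip:
    def test_yaml_round_trip_is_lossless(self, default_model, tmp_path):
        path = tmp_path / "model.yaml"
        sf.save_model(default_model, path)
        loaded = sf.load_model(path)
        assert loaded.metabolite_ids == default_model.metabolite_ids
        assert loaded.reaction_ids == default_model.reaction_ids
        for name, prm in default_model.parameters.items():
            assert loaded.parameters[name].value == prm.value
            assert loaded.parameters[name].provenance == prm.provenance
        np.testing.assert_allclose(
            loaded.stoichiometric_matrix(),
            default_model.stoichiometric_matrix(),
        )
        # kinetics evaluate identically
        c0, c1 = CompiledModel(default_model), CompiledModel(loaded)
        y = default_model.initial_state() + 0.1
        e = np.ones(len(c0.enzyme_ids))
        np.testing.assert_allclose(
            c0.fluxes(y, e, mu=0.01, mrna={"SPRT": 1.0}),
            c1.fluxes(y, e, mu=0.01, mrna={"SPRT": 1.0}),
        )


def test_hill_inhibition_bounds():
    xs = np.linspace(0, 5, 50)
    vals = np.array([hill_inhibition(x, 0.5, 2.0) for x in xs])
    assert np.all((vals > 0) & (vals <= 1.0))
    assert vals[0] == 1.0
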