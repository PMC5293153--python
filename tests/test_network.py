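"""Structural and dynamical tests of the signaling network module."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given
from hypothesis import strategies as st
from scipy.linalg import expm

from eposignal.contexts import copy_number_to_concentration, surface_density
from eposignal.network import (
    N_GLOBAL_PARAMETERS,
    Perturbation,
    TopologyError,
    apply_cell_context,
    apply_perturbation,
    build_signaling_model,
    catalytic_rate,
    full_topology,
    receptor_input,
    receptor_topology,
    simulate,
)


# ---------------------------------------------------------------------------
# receptor Hill input
# ---------------------------------------------------------------------------

class TestReceptorInput:
    def test_zero_dose_gives_zero(self):
        assert receptor_input(0.0, v_max=2.0, K=1.0, n=2.0) == 0.0

    @given(st.floats(0.3, 5.0), st.floats(0.05, 50.0), st.floats(0.1, 10.0))
    def test_half_saturation_identity(self, n, K, v_max):
        """At epo = K the term equals v_max/2 for any Hill exponent."""
        assert receptor_input(K, v_max, K, n) == pytest.approx(v_max / 2)

    def test_closed_form_n1_triple_K(self):
        # epo = 3K with n = 1: 3/(1+3) of v_max
        assert receptor_input(3.0, 1.0, 1.0, 1.0) == pytest.approx(0.75)

    @given(st.floats(0.5, 4.0))
    def test_monotone_in_dose(self, n):
        doses = np.linspace(0.0, 20.0, 50)
        vals = [receptor_input(d, 1.0, 1.0, n) for d in doses]
        assert np.all(np.diff(vals) >= 0)
        assert vals[-1] < 1.0  # approaches but never exceeds v_max

    @pytest.mark.parametrize("kw", [dict(K=0.0), dict(K=-1.0), dict(n=0.0)])
    def test_domain_errors(self, kw):
        args = dict(epo=1.0, v_max=1.0, K=1.0, n=1.0)
        args.update(kw)
        with pytest.raises(ValueError):
            receptor_input(**args)


# ---------------------------------------------------------------------------
# catalytic decomposition
# ---------------------------------------------------------------------------

def _one_step_toy():
    """X decays catalyzed by an enzyme whose total comes from the context
    (PTEN stands in as the enzyme)."""
    return dict(
        name="toy_catalytic",
        species=["Epo", "X"],
        reactions=[dict(name="decay", reactants={"X": 1}, products={},
                        kind="catalytic", rate="k*PTEN_total*X"),
                   dict(name="epo_sink", reactants={"Epo": 1}, products={},
                        kind="mass_action", rate="kz*Epo")],
        parameters=["k", "kz"],
        moieties={},
        observables={"X": "X"},
        theta_default={"k": 0.001, "kz": 1.0},
    )


class TestCatalyticRate:
    def test_product(self):
        assert catalytic_rate(0.5, 100.0) == 50.0

    def test_absent_enzyme_silences(self):
        assert catalytic_rate(0.5, 0.0) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            catalytic_rate(-1.0, 10.0)
        with pytest.raises(ValueError):
            catalytic_rate(1.0, -10.0)

    def test_doubling_enzyme_doubles_flux(self, contexts):
        """Simulated decay rate scales linearly with enzyme concentration."""
        model = build_signaling_model(_one_step_toy())
        t = np.array([0.0, 1.0])
        vals = {}
        for pten in (10.4, 20.8):
            ctx = contexts["mCFU-E"].with_abundance("PTEN", pten)
            inst = apply_cell_context(model, ctx)
            # decay exponent over 1 min equals the effective rate constant
            traj = simulate(inst, 0.0, t, pre_equilibrate=False, y0=np.array(
                [0.0, 100.0]))
            vals[pten] = -np.log(traj.states["X"][1] / 100.0)
        assert vals[20.8] == pytest.approx(2 * vals[10.4], rel=1e-5)


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

class TestUnitConversions:
    def test_receptor_copy_number_worked_example(self):
        # 1,000 receptors in a 399 um^3 cytoplasm
        assert copy_number_to_concentration(1000, 399.0) == pytest.approx(
            4.16, abs=0.005)

    def test_zero_copies(self):
        assert copy_number_to_concentration(0, 399.0) == 0.0

    def test_millimolar_unit_check(self):
        # 6.022e8 molecules in 1000 um^3 = 1 mM = 1e6 nM
        got = copy_number_to_concentration(6.02214076e8, 1000.0)
        assert got == pytest.approx(1.0e6, rel=1e-6)

    def test_surface_density_worked_example(self):
        assert surface_density(1000, 378.5) == 2.6

    def test_surface_density_zero(self):
        assert surface_density(0, 100.0) == 0.0

    def test_surface_density_cell_line(self):
        # straight division gives 25.8 (a published table rounds to 26.1)
        assert surface_density(15500, 600.3) == 25.8

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            copy_number_to_concentration(10, 0.0)
        with pytest.raises(ValueError):
            surface_density(10, -1.0)


# ---------------------------------------------------------------------------
# model assembly and validation
# ---------------------------------------------------------------------------

class TestBuildModel:
    def test_full_model_parameter_count(self, full_model):
        assert full_model.n_parameters == N_GLOBAL_PARAMETERS

    def test_quoted_couplings_present(self, full_model):
        """The eight qualitative couplings of the network wiring."""
        m = full_model
        # PI3K (receptor-bound) generates PIP3
        assert m.coupling_exists("pEpoR_PI3K", "PIP2")
        # SHIP1 (via receptor complex) and PTEN dephosphorylate PIP3
        assert m.coupling_exists("pEpoR_SHIP1", "PIP3")
        assert any("PTEN_total" in r.rate and "PIP3" in r.reactants
                   for r in m.reactions)
        # pEpoR-Sos complex loads Ras; GTP-Ras drives Raf
        assert m.coupling_exists("pEpoR_Sos", "Ras")
        assert m.coupling_exists("GTP_Ras", "Raf")
        # DUSP dephosphorylates ppERK
        assert any("DUSP_total" in r.rate and "ppERK" in r.reactants
                   for r in m.reactions)
        # S6 phosphorylation integrates TORC1 (mTOR arm) and RSK (ERK arm)
        assert m.coupling_exists("TORC1", "S6")
        assert m.coupling_exists("pRSK", "S6")
        # SHP1 and a constitutive phosphatase deactivate pEpoR
        assert m.coupling_exists("aSHP1", "pEpoR")
        assert any(r.name == "pepor_dephos_const" for r in m.reactions)
        # pAKT activates mTOR; transcripts respond to pAKT and ppERK
        assert m.coupling_exists("pAKT", "mTOR")
        assert all(any(g in r.rate for r in m.reactions if "syn" in r.name)
                   for g in ("pAKT", "ppERK"))

    def test_undeclared_species_named_in_error(self):
        topo = _one_step_toy()
        topo["reactions"].append(dict(name="bad", reactants={"X": 1},
                                      products={"Q": 1}, kind="mass_action",
                                      rate="k*X"))
        with pytest.raises(TopologyError, match="'Q'"):
            build_signaling_model(topo)

    def test_duplicate_reaction_rejected(self):
        topo = _one_step_toy()
        topo["reactions"].append(dict(topo["reactions"][0]))
        with pytest.raises(TopologyError, match="duplicate"):
            build_signaling_model(topo)

    def test_unknown_rate_symbol_rejected(self):
        topo = _one_step_toy()
        topo["reactions"][0] = dict(topo["reactions"][0], rate="k_undeclared*X")
        with pytest.raises(TopologyError, match="k_undeclared"):
            build_signaling_model(topo)

    def test_receptor_submodel(self):
        m = build_signaling_model(receptor_topology())
        assert {"pEpoR", "SHP1", "aSHP1"} <= set(m.species)
        dephos = [r for r in m.reactions
                  if r.reactants == {"pEpoR": 1} and r.products == {"EpoR": 1}]
        assert len(dephos) == 2  # SHP1-catalyzed + constitutive


# ---------------------------------------------------------------------------
# contexts applied to the model
# ---------------------------------------------------------------------------

class TestApplyCellContext:
    def test_measured_totals(self, full_model, contexts):
        inst = apply_cell_context(full_model, contexts["mCFU-E"])
        assert inst.total("ERK") == 1140.0
        assert inst.total("AKT") == 407.0

    def test_pure_function(self, full_model, contexts):
        a = apply_cell_context(full_model, contexts["BaF3-EpoR"])
        b = apply_cell_context(full_model, contexts["BaF3-EpoR"])
        assert a.abundances == b.abundances and a.theta == b.theta

    def test_absent_protein_is_zero(self, full_model, contexts):
        assert contexts["BaF3-EpoR"].concentration("Gab1") == 0.0
        assert contexts["mCFU-E"].concentration("Gab2") == 0.0

    def test_missing_protein_keyed_error(self, full_model, contexts):
        ctx = contexts["mCFU-E"]
        broken = ctx.abundances_nM.copy()
        del broken["PTEN"]
        from eposignal.contexts import CellTypeContext
        ctx2 = CellTypeContext(ctx.name, 399.0, 378.5, broken, ctx.ratios,
                               frozenset())
        with pytest.raises(KeyError, match="PTEN"):
            apply_cell_context(full_model, ctx2)

    def test_zero_enzyme_silences_rate_symbolically(self, full_model):
        """Setting an enzyme's abundance to 0 removes its flux entirely."""
        rate = next(r.rate for r in full_model.reactions
                    if r.name == "pip3_pten")
        expr = sp.sympify(rate)
        assert expr.subs(sp.Symbol("PTEN_total"), 0) == 0


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

class TestPerturbations:
    def _inst(self, truth):
        return truth.instance("mCFU-E")

    def test_zero_dose_identity(self, truth):
        inst = self._inst(truth)
        out = apply_perturbation(inst, Perturbation("inhibitor", "AKTVIII", 0.0))
        assert out.inhibition_factors == inst.inhibition_factors

    def test_half_inhibition_at_strength(self, truth):
        inst = self._inst(truth)
        s = inst.inhibitor_strengths["AKTVIII"]
        out = apply_perturbation(inst, Perturbation("inhibitor", "AKTVIII", s))
        assert out.inhibition_factors["inh_akt"] == pytest.approx(0.5)

    def test_perturbations_commute(self, truth):
        inst = self._inst(truth)
        p1 = Perturbation("inhibitor", "AKTVIII", 0.5)
        p2 = Perturbation("inhibitor", "U0126", 5.0)
        a = apply_perturbation(apply_perturbation(inst, p1), p2)
        b = apply_perturbation(apply_perturbation(inst, p2), p1)
        assert a.inhibition_factors == b.inhibition_factors

    def test_unknown_agent_keyed_error(self):
        with pytest.raises(KeyError):
            Perturbation("inhibitor", "mystery-drug", 1.0)

    def test_pten_overexpression_lowers_pakt_peak(self, truth, t_grid):
        """More lipid phosphatase, less AKT activation."""
        inst = truth.instance("mCFU-E")
        oe = apply_perturbation(inst, Perturbation("overexpression", "PTEN", 4.0))
        wt = simulate(inst, 5.0, t_grid).observables["pAKT"].max()
        pert = simulate(oe, 5.0, t_grid).observables["pAKT"].max()
        assert pert < wt

    def test_knockdown_sets_total(self, truth):
        inst = truth.instance("BaF3-EpoR")
        kd = apply_perturbation(inst, Perturbation("knockdown", "SHIP1", 15.4))
        assert kd.abundances["SHIP1"] == 15.4


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_unstimulated_steady_state_is_flat(self, truth, t_grid):
        traj = simulate(truth.instance("mCFU-E"), 0.0, t_grid)
        for ob in ("pEpoR", "pAKT", "ppERK", "pS6"):
            v = traj.observables[ob]
            assert np.max(np.abs(v - v[0])) <= 1e-6 * max(abs(v[0]), 1.0)

    def test_conservation_and_nonnegativity(self, truth, t_grid):
        traj = simulate(truth.instance("BaF3-EpoR"), 50.0, t_grid)
        assert traj.conserved_drift < 1e-6
        for name, v in traj.states.items():
            assert v.min() >= -1e-9, name

    def test_pepor_transient(self, truth):
        """Single interior maximum followed by decline at saturating Epo."""
        t = np.linspace(0.0, 60.0, 121)
        traj = simulate(truth.instance("mCFU-E"), 50.0, t)
        v = traj.observables["pEpoR"]
        i_max = int(np.argmax(v))
        assert 0 < i_max < len(v) - 1
        assert v[-1] < v[i_max]
        # single interior maximum: rises before, declines after
        assert np.all(np.diff(v[: i_max + 1]) >= -1e-9)

    def test_toy_decay_matches_analytic(self):
        model = build_signaling_model(dict(
            name="decay", species=["Epo", "X"],
            reactions=[dict(name="d", reactants={"X": 1}, products={},
                            kind="mass_action", rate="k*X"),
                       dict(name="ez", reactants={"Epo": 1}, products={},
                            kind="mass_action", rate="kz*Epo")],
            parameters=["k", "kz"], moieties={}, observables={"X": "X"},
            theta_default={"k": 1.0, "kz": 1.0}))
        from eposignal.network import ModelInstance
        inst = ModelInstance(model, "toy", {"PTEN": 0, "DUSP": 0, "EpoR": 0},
                             {"k": 1.0, "kz": 1.0})
        traj = simulate(inst, 0.0, np.linspace(0, 10, 11),
                        pre_equilibrate=False, y0=np.array([0.0, 1.0]))
        assert traj.states["X"][-1] == pytest.approx(np.exp(-10.0), rel=1e-6)

    def test_linear_chain_matches_matrix_exponential(self):
        """Three-step linear chain vs expm of its rate matrix."""
        model = build_signaling_model(dict(
            name="chain", species=["Epo", "A", "B", "C"],
            reactions=[
                dict(name="ab", reactants={"A": 1}, products={"B": 1},
                     kind="mass_action", rate="k1*A"),
                dict(name="bc", reactants={"B": 1}, products={"C": 1},
                     kind="mass_action", rate="k2*B"),
                dict(name="ez", reactants={"Epo": 1}, products={},
                     kind="mass_action", rate="kz*Epo"),
            ],
            parameters=["k1", "k2", "kz"], moieties={},
            observables={"C": "C"},
            theta_default={"k1": 0.3, "k2": 0.07, "kz": 1.0}))
        from eposignal.network import ModelInstance
        inst = ModelInstance(model, "toy", {"PTEN": 0, "DUSP": 0, "EpoR": 0},
                             model.theta_default)
        t_grid = np.linspace(0, 30, 7)
        traj = simulate(inst, 0.0, t_grid, pre_equilibrate=False,
                        y0=np.array([0.0, 1.0, 0.0, 0.0]))
        A = np.array([[-0.3, 0, 0], [0.3, -0.07, 0], [0, 0.07, 0]])
        for i, t in enumerate(t_grid):
            exact = expm(A * t) @ np.array([1.0, 0.0, 0.0])
            got = np.array([traj.states[s][i] for s in ("A", "B", "C")])
            assert np.allclose(got, exact, rtol=1e-6, atol=1e-10)

    def test_bad_time_grid_rejected(self, truth):
        with pytest.raises(ValueError):
            simulate(truth.instance("mCFU-E"), 5.0, [0.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            simulate(truth.instance("mCFU-E"), -1.0, [0.0, 10.0])
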