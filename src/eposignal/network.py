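"""Kinetic model of Epo-induced EpoR -> AKT/ERK -> S6 signaling.

The model is a mass-action ODE network with a phenomenological Hill term at
the receptor.  Its defining structural idea is the split between *global*
kinetic parameters (binding and catalytic rate constants, shared across cell
types) and *cell-type-specific* protein abundances: every enzymatic rate is
decomposed as ``k_cat x [enzyme] x [substrate]``, so transplanting the model
to a new cell type only requires a new abundance context.

Network outline (receptor module / PI3K-AKT / Ras-MEK-ERK / S6 integration):

* Preformed EpoR dimers are phosphorylated upon Epo binding (Hill input);
  pEpoR is dephosphorylated by the pEpoR-activated phosphatase SHP1 and a
  constitutive phosphatase.  pEpoR forms complexes with Sos, PI3K, GTP-Ras,
  and SHIP1.
* PI3K in complex with pEpoR converts PIP2 to PIP3; SHIP1 and PTEN
  dephosphorylate PIP3.  PIP3 recruits AKT and PDK1 to the membrane, where
  PDK1 phosphorylates AKT (Thr308) and TORC2 completes activation (Ser473).
* pAKT activates mTOR; active mTOR assembles TORC1 with Raptor (inactive
  mTOR assembles TORC2 with Rictor).
* The pEpoR-Sos complex loads Ras with GTP; GTP-Ras drives the dual
  phosphorylation cascade Raf -> MEK -> ERK; DUSP dephosphorylates ERK.
* TORC1 and ERK-activated RSK jointly phosphorylate S6 (two sites) -- the
  integration point of the two pathways.
* pAKT and ppERK modulate transcription of cyclinD2 (induced) and of
  cyclinG2 and p27 (repressed), tracked as fold-change variables.

Gab1/Gab2 adaptors are omitted from the fast receptor binding equilibrium
(their binding is either too fast or too slow to shape it); their abundances
remain in the contexts for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .contexts import CellTypeContext

__all__ = [
    "Reaction",
    "Perturbation",
    "SignalingModel",
    "ModelInstance",
    "Trajectory",
    "TopologyError",
    "IntegrationError",
    "build_signaling_model",
    "full_topology",
    "reduced_topology",
    "receptor_topology",
    "catalytic_rate",
    "receptor_input",
    "apply_cell_context",
    "apply_perturbation",
    "simulate",
    "N_GLOBAL_PARAMETERS",
    "INHIBITOR_TARGETS",
]

#: Expected size of the global kinetic parameter vector of the full model.
N_GLOBAL_PARAMETERS = 82

#: Inhibitor agent -> (inhibition-factor symbol, targeted process).
INHIBITOR_TARGETS = {
    "AKTVIII": ("inh_akt", "AKT phosphorylation"),
    "U0126": ("inh_mek", "MEK kinase activity toward ERK"),
    "BID1870": ("inh_rsk", "RSK phosphorylation"),
    "rapamycin": ("inh_mtor", "TORC1 (mTOR) activity toward S6"),
}

_INH_SYMBOLS = tuple(sym for sym, _ in INHIBITOR_TARGETS.values())
_CELLTYPE_SYMBOLS = ("ct_act", "ct_deact")
_RATE_ABUNDANCE_SYMBOLS = ("PTEN_total", "DUSP_total", "EpoR_total")

REACTION_KINDS = ("mass_action", "catalytic", "hill_input", "regulatory")


class TopologyError(ValueError):
    """Structural validation failure when assembling a model."""


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the last successfully integrated time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


def catalytic_rate(k_cat: float, enzyme_total: float) -> float:
    """Effective first-order rate constant ``k_cat * [enzyme]``.

    Decomposing enzymatic rate constants into a cell-type-independent
    catalytic efficiency and a cell-type-specific enzyme concentration is what
    lets the kinetic parameters be shared across cell types.
    """
    if k_cat < 0:
        raise ValueError(f"k_cat must be >= 0, got {k_cat}")
    if enzyme_total < 0:
        raise ValueError(f"enzyme concentration must be >= 0, got {enzyme_total}")
    return k_cat * enzyme_total


def receptor_input(epo: float, v_max: float, K: float, n: float) -> float:
    """Hill-type receptor activation term ``v_max * epo^n / (K^n + epo^n)``.

    ``epo`` is in U/ml (no conversion to molarity); ``K`` is the
    half-saturating dose and ``n`` the Hill exponent.
    """
    if K <= 0:
        raise ValueError(f"K must be > 0, got {K}")
    if n <= 0:
        raise ValueError(f"n must be > 0, got {n}")
    if epo < 0:
        raise ValueError(f"epo dose must be >= 0, got {epo}")
    if epo == 0.0:
        return 0.0
    return v_max * epo**n / (K**n + epo**n)


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry plus a symbolic rate law.

    ``kind`` is one of ``mass_action`` (rate constant times reactant
    concentrations), ``catalytic`` (k_cat times enzyme times substrate),
    ``hill_input`` (receptor only), or ``regulatory`` (the saturating
    transcript-synthesis terms).  ``modifiers`` name species that shape the
    rate without being consumed (enzymes, scaffolds).
    """

    name: str
    reactants: dict[str, int]
    products: dict[str, int]
    kind: str
    rate: str
    modifiers: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in REACTION_KINDS:
            raise TopologyError(f"reaction {self.name!r}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class Perturbation:
    """An inhibitor dose, an overexpression fold, or a knockdown target level."""

    kind: str  # "inhibitor" | "overexpression" | "knockdown"
    agent: str  # inhibitor name or protein name
    dose: float  # uM (inhibitor), fold (overexpression), nM (knockdown)

    def __post_init__(self):
        if self.kind not in ("inhibitor", "overexpression", "knockdown"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "inhibitor":
            if self.agent not in INHIBITOR_TARGETS:
                raise KeyError(f"unknown inhibitor agent {self.agent!r}")
            if self.dose < 0:
                raise ValueError("inhibitor dose must be >= 0 uM")
        elif self.kind == "overexpression" and self.dose <= 0:
            raise ValueError("overexpression fold must be > 0")
        elif self.kind == "knockdown" and self.dose < 0:
            raise ValueError("knockdown target level must be >= 0 nM")

    @property
    def label(self) -> str:
        return f"{self.agent}:{self.kind}:{self.dose:g}"


class SignalingModel:
    """Validated, compiled reaction network with global kinetic parameters."""

    _serial_counter = 0

    def __init__(
        self,
        species: list[str],
        reactions: list[Reaction],
        parameters: list[str],
        moieties: dict[str, list[str]],
        observables: dict[str, str],
        theta_default: dict[str, float],
        name: str = "model",
    ):
        self.name = name
        self.species = list(species)
        self.reactions = list(reactions)
        self.parameters = list(parameters)
        self.moieties = dict(moieties)
        self.observables = dict(observables)
        self.theta_default = dict(theta_default)
        SignalingModel._serial_counter += 1
        self._serial = SignalingModel._serial_counter  # stable cache identity
        self._validate()
        self._compiled = None

    # -- validation ---------------------------------------------------------

    def _allowed_symbols(self) -> set[str]:
        return (
            set(self.species)
            | set(self.parameters)
            | set(_RATE_ABUNDANCE_SYMBOLS)
            | set(_CELLTYPE_SYMBOLS)
            | set(_INH_SYMBOLS)
        )

    def _validate(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise TopologyError("duplicate species declared")
        names = [r.name for r in self.reactions]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise TopologyError(f"duplicate reactions: {dup}")
        allowed = self._allowed_symbols()
        # explicit symbol table so species named like sympy builtins (S, E,
        # I, N...) parse as plain symbols
        local = {name: sp.Symbol(name) for name in allowed}
        local["Max"] = sp.Max
        spset = set(self.species)
        for rxn in self.reactions:
            for s in list(rxn.reactants) + list(rxn.products) + list(rxn.modifiers):
                if s not in spset:
                    raise TopologyError(
                        f"reaction {rxn.name!r} references undeclared species {s!r}"
                    )
            for sym in sp.sympify(rxn.rate, locals=local).free_symbols:
                if str(sym) not in allowed:
                    raise TopologyError(
                        f"reaction {rxn.name!r} rate references unknown symbol "
                        f"{sym!s}"
                    )
            if rxn.kind == "hill_input" and "Epo" not in rxn.rate:
                raise TopologyError(
                    f"hill_input reaction {rxn.name!r} must involve Epo"
                )
        for moiety, members in self.moieties.items():
            if not members:
                raise TopologyError(f"moiety {moiety!r} has no member species")
            for s in members:
                if s not in spset:
                    raise TopologyError(
                        f"moiety {moiety!r} lists undeclared species {s!r}"
                    )
        missing = set(self.parameters) - set(self.theta_default)
        if missing:
            raise TopologyError(f"no default value for parameters {sorted(missing)}")

    # -- structure queries --------------------------------------------------

    @property
    def n_parameters(self) -> int:
        """Number of global kinetic parameters."""
        return len(self.parameters)

    def coupling_exists(self, catalyst: str, target_reaction_substrate: str) -> bool:
        """True if some reaction converts ``target_reaction_substrate`` with
        ``catalyst`` as modifier -- used to audit the network wiring."""
        for rxn in self.reactions:
            if catalyst in rxn.modifiers and target_reaction_substrate in rxn.reactants:
                return True
        return False

    def conservation_matrix(self) -> tuple[list[str], np.ndarray]:
        """(moiety names, 0/1 matrix of moiety membership over species)."""
        idx = {s: i for i, s in enumerate(self.species)}
        names = list(self.moieties)
        mat = np.zeros((len(names), len(self.species)))
        for r, moiety in enumerate(names):
            for s in self.moieties[moiety]:
                mat[r, idx[s]] = 1.0
        return names, mat

    # -- compilation --------------------------------------------------------

    def _compile(self):
        if self._compiled is not None:
            return self._compiled
        sp_syms = sp.symbols(self.species)
        th_syms = sp.symbols(self.parameters)
        ab_syms = sp.symbols(list(_RATE_ABUNDANCE_SYMBOLS))
        ct_syms = sp.symbols(list(_CELLTYPE_SYMBOLS))
        inh_syms = sp.symbols(list(_INH_SYMBOLS))
        local = {str(s): s for group in (sp_syms, th_syms, ab_syms, ct_syms, inh_syms)
                 for s in group}
        local["Max"] = sp.Max
        idx = {s: i for i, s in enumerate(self.species)}
        dydt = [sp.Integer(0)] * len(self.species)
        for rxn in self.reactions:
            rate = sp.sympify(rxn.rate, locals=local)
            for s, nu in rxn.reactants.items():
                dydt[idx[s]] -= nu * rate
            for s, nu in rxn.products.items():
                dydt[idx[s]] += nu * rate
        f_mat = sp.Matrix(dydt)
        y = sp.Matrix(sp_syms)
        jac = f_mat.jacobian(y)
        args = (list(sp_syms), list(th_syms), list(ab_syms), list(ct_syms),
                list(inh_syms))
        f_fn = sp.lambdify(args, list(f_mat), modules="numpy", cse=True)
        j_fn = sp.lambdify(args, jac, modules="numpy", cse=True)
        obs_fns = {}
        for oname, expr in self.observables.items():
            obs_fns[oname] = sp.lambdify((list(sp_syms),), sp.sympify(expr, locals=local),
                                         modules="numpy")
        self._compiled = (f_fn, j_fn, obs_fns)
        return self._compiled

    def instantiate(
        self,
        context: CellTypeContext,
        theta: dict[str, float] | None = None,
        inhibitor_strengths: dict[str, float] | None = None,
        receptor_scaling: tuple[float, float] = (1.0, 1.0),
        observable_scales: dict[str, float] | None = None,
    ) -> "ModelInstance":
        return apply_cell_context(
            self, context, theta=theta, inhibitor_strengths=inhibitor_strengths,
            receptor_scaling=receptor_scaling, observable_scales=observable_scales,
        )

    def theta_vector(self, theta: dict[str, float] | None = None) -> np.ndarray:
        merged = dict(self.theta_default)
        if theta:
            unknown = set(theta) - set(self.parameters)
            if unknown:
                raise KeyError(f"unknown parameters {sorted(unknown)}")
            merged.update(theta)
        return np.array([merged[p] for p in self.parameters], dtype=float)


@dataclass(frozen=True)
class ModelInstance:
    """A model joined with one cell-type context (and optional perturbations).

    The instance is immutable; perturbations and parameter updates return new
    instances, so identical inputs always produce identical simulations.
    """

    model: SignalingModel
    context_name: str
    abundances: dict[str, float]
    theta: dict[str, float]
    inhibitor_strengths: dict[str, float] = field(default_factory=dict)
    receptor_scaling: tuple[float, float] = (1.0, 1.0)
    observable_scales: dict[str, float] = field(default_factory=dict)
    inhibition_factors: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in _INH_SYMBOLS}
    )
    perturbations: tuple[Perturbation, ...] = ()

    def with_theta(self, theta: dict[str, float]) -> "ModelInstance":
        merged = dict(self.theta)
        merged.update(theta)
        return replace(self, theta=merged)

    def with_observable_scales(self, scales: dict[str, float]) -> "ModelInstance":
        merged = dict(self.observable_scales)
        merged.update(scales)
        return replace(self, observable_scales=merged)

    def total(self, protein: str) -> float:
        """Conserved total (nM) of a context protein in this instance."""
        return self.abundances[protein]


@dataclass
class Trajectory:
    """Simulated time course on a fixed grid (concentrations in nM)."""

    time: np.ndarray  # minutes, strictly increasing, starts at 0
    states: dict[str, np.ndarray]
    observables: dict[str, np.ndarray]
    context_name: str
    epo_dose: float
    perturbations: tuple[Perturbation, ...]
    conserved_drift: float  # max relative drift over all conserved totals
    dense: object | None = None  # scipy OdeSolution over [0, t_end], if kept
    _obs_eval: dict | None = None  # observable name -> callable(t) when dense

    def observable(self, name: str) -> np.ndarray:
        return self.observables[name]

    def observable_at(self, name: str, t: float) -> float:
        """Evaluate an observable at arbitrary time via the dense solution."""
        if self._obs_eval is None:
            raise ValueError("trajectory was not simulated with keep_dense")
        return float(self._obs_eval[name](t))


# ---------------------------------------------------------------------------
# Topology definitions
# ---------------------------------------------------------------------------

def _rxn(name, reactants, products, kind, rate, modifiers=()):
    return dict(name=name, reactants=reactants, products=products, kind=kind,
                rate=rate, modifiers=tuple(modifiers))


def full_topology() -> dict:
    """Canonical full network; 82 global kinetic parameters.

    Returns a plain-data topology specification consumed by
    :func:`build_signaling_model`.
    """
    species = [
        "Epo",
        "EpoR", "pEpoR", "pEpoR_Sos", "pEpoR_PI3K", "pEpoR_SHIP1",
        "pEpoR_GTPRas",
        "Sos", "PI3K", "SHIP1", "SHP1", "aSHP1",
        "PIP2", "PIP3",
        "AKT", "AKT_mem", "pAKT_mem", "pAKT",
        "PDK1", "PDK1_mem",
        "mTOR", "amTOR", "Raptor", "TORC1", "Rictor", "TORC2",
        "Ras", "GTP_Ras",
        "Raf", "pRaf",
        "MEK", "pMEK", "ppMEK",
        "ERK", "pERK", "ppERK",
        "RSK", "pRSK",
        "S6", "pS6", "ppS6",
        "mCCND2", "mCCNG2", "mCDKN1B",
    ]

    hill = "(Max(Epo,0) + 1e-12)**n_epo/(K_epo**n_epo + (Max(Epo,0) + 1e-12)**n_epo)"
    reactions = [
        # --- receptor module ---------------------------------------------
        _rxn("epor_act_basal", {"EpoR": 1}, {"pEpoR": 1}, "mass_action",
             "k_act_basal*ct_act*EpoR"),
        _rxn("epor_act_epo", {"EpoR": 1}, {"pEpoR": 1}, "hill_input",
             f"k_act_epo*ct_act*EpoR*{hill}"),
        _rxn("epo_depletion", {"Epo": 1}, {}, "catalytic",
             "k_epo_deg*EpoR_total*Epo"),
        _rxn("shp1_act", {"SHP1": 1}, {"aSHP1": 1}, "catalytic",
             "k_shp1_act*pEpoR*SHP1", modifiers=("pEpoR",)),
        _rxn("shp1_act_basal", {"SHP1": 1}, {"aSHP1": 1}, "mass_action",
             "k_shp1_basal*SHP1"),
        _rxn("shp1_deact", {"aSHP1": 1}, {"SHP1": 1}, "mass_action",
             "k_shp1_deact*aSHP1"),
        _rxn("pepor_dephos_shp1", {"pEpoR": 1}, {"EpoR": 1}, "catalytic",
             "kcat_shp1_pepor*ct_deact*aSHP1*pEpoR", modifiers=("aSHP1",)),
        _rxn("pepor_dephos_const", {"pEpoR": 1}, {"EpoR": 1}, "mass_action",
             "k_dephos_pepor*pEpoR"),
        # receptor complexes (reversible binding)
        _rxn("sos_bind", {"pEpoR": 1, "Sos": 1}, {"pEpoR_Sos": 1}, "mass_action",
             "kon_sos*pEpoR*Sos"),
        _rxn("sos_unbind", {"pEpoR_Sos": 1}, {"pEpoR": 1, "Sos": 1}, "mass_action",
             "koff_sos*pEpoR_Sos"),
        _rxn("pi3k_bind", {"pEpoR": 1, "PI3K": 1}, {"pEpoR_PI3K": 1}, "mass_action",
             "kon_pi3k*pEpoR*PI3K"),
        _rxn("pi3k_unbind", {"pEpoR_PI3K": 1}, {"pEpoR": 1, "PI3K": 1},
             "mass_action", "koff_pi3k*pEpoR_PI3K"),
        _rxn("ship1_bind", {"pEpoR": 1, "SHIP1": 1}, {"pEpoR_SHIP1": 1},
             "mass_action", "kon_ship1*pEpoR*SHIP1"),
        _rxn("ship1_unbind", {"pEpoR_SHIP1": 1}, {"pEpoR": 1, "SHIP1": 1},
             "mass_action", "koff_ship1*pEpoR_SHIP1"),
        _rxn("rasgtp_bind", {"pEpoR": 1, "GTP_Ras": 1}, {"pEpoR_GTPRas": 1},
             "mass_action", "kon_rasgtp*pEpoR*GTP_Ras"),
        _rxn("rasgtp_unbind", {"pEpoR_GTPRas": 1}, {"pEpoR": 1, "GTP_Ras": 1},
             "mass_action", "koff_rasgtp*pEpoR_GTPRas"),
        # dephosphorylation of complexed receptor (SHP1-catalyzed and
        # constitutive); the partner is released
        _rxn("cplx_sos_dephos_shp1", {"pEpoR_Sos": 1}, {"EpoR": 1, "Sos": 1},
             "catalytic", "kcat_shp1_sos*ct_deact*aSHP1*pEpoR_Sos",
             modifiers=("aSHP1",)),
        _rxn("cplx_pi3k_dephos_shp1", {"pEpoR_PI3K": 1}, {"EpoR": 1, "PI3K": 1},
             "catalytic", "kcat_shp1_pi3k*ct_deact*aSHP1*pEpoR_PI3K",
             modifiers=("aSHP1",)),
        _rxn("cplx_ship1_dephos_shp1", {"pEpoR_SHIP1": 1}, {"EpoR": 1, "SHIP1": 1},
             "catalytic", "kcat_shp1_ship1*ct_deact*aSHP1*pEpoR_SHIP1",
             modifiers=("aSHP1",)),
        _rxn("cplx_rasgtp_dephos_shp1", {"pEpoR_GTPRas": 1},
             {"EpoR": 1, "GTP_Ras": 1}, "catalytic",
             "kcat_shp1_rasgtp*ct_deact*aSHP1*pEpoR_GTPRas", modifiers=("aSHP1",)),
        _rxn("cplx_sos_dephos_const", {"pEpoR_Sos": 1}, {"EpoR": 1, "Sos": 1},
             "mass_action", "k_dephos_sos_cplx*pEpoR_Sos"),
        _rxn("cplx_pi3k_dephos_const", {"pEpoR_PI3K": 1}, {"EpoR": 1, "PI3K": 1},
             "mass_action", "k_dephos_pi3k_cplx*pEpoR_PI3K"),
        _rxn("cplx_ship1_dephos_const", {"pEpoR_SHIP1": 1},
             {"EpoR": 1, "SHIP1": 1}, "mass_action",
             "k_dephos_ship1_cplx*pEpoR_SHIP1"),
        _rxn("cplx_rasgtp_dephos_const", {"pEpoR_GTPRas": 1},
             {"EpoR": 1, "GTP_Ras": 1}, "mass_action",
             "k_dephos_rasgtp_cplx*pEpoR_GTPRas"),
        # --- PIP3 / membrane ----------------------------------------------
        _rxn("pip3_synthesis", {"PIP2": 1}, {"PIP3": 1}, "catalytic",
             "kcat_pip3*pEpoR_PI3K*PIP2", modifiers=("pEpoR_PI3K",)),
        _rxn("pip3_synthesis_basal", {"PIP2": 1}, {"PIP3": 1}, "catalytic",
             "k_pip3_basal*PI3K*PIP2", modifiers=("PI3K",)),
        _rxn("pip3_ship1_membrane", {"PIP3": 1}, {"PIP2": 1}, "catalytic",
             "kcat_ship1_m*pEpoR_SHIP1*PIP3", modifiers=("pEpoR_SHIP1",)),
        _rxn("pip3_ship1_cytosolic", {"PIP3": 1}, {"PIP2": 1}, "catalytic",
             "kcat_ship1_c*SHIP1*PIP3", modifiers=("SHIP1",)),
        _rxn("pip3_pten", {"PIP3": 1}, {"PIP2": 1}, "catalytic",
             "kcat_pten*PTEN_total*PIP3"),
        _rxn("akt_membrane_on", {"AKT": 1}, {"AKT_mem": 1}, "catalytic",
             "kon_akt_mem*PIP3*AKT", modifiers=("PIP3",)),
        _rxn("akt_membrane_off", {"AKT_mem": 1}, {"AKT": 1}, "mass_action",
             "koff_akt_mem*AKT_mem"),
        _rxn("pdk1_membrane_on", {"PDK1": 1}, {"PDK1_mem": 1}, "catalytic",
             "kon_pdk1_mem*PIP3*PDK1", modifiers=("PIP3",)),
        _rxn("pdk1_membrane_off", {"PDK1_mem": 1}, {"PDK1": 1}, "mass_action",
             "koff_pdk1_mem*PDK1_mem"),
        # --- AKT activation -------------------------------------------------
        _rxn("akt_phos_thr308", {"AKT_mem": 1}, {"pAKT_mem": 1}, "catalytic",
             "kcat_akt_308*inh_akt*PDK1_mem*AKT_mem", modifiers=("PDK1_mem",)),
        _rxn("akt_phos_ser473", {"pAKT_mem": 1}, {"pAKT": 1}, "catalytic",
             "kcat_akt_473*inh_akt*TORC2*pAKT_mem", modifiers=("TORC2",)),
        _rxn("pakt_mem_dephos", {"pAKT_mem": 1}, {"AKT_mem": 1}, "mass_action",
             "k_dephos_pakt_mem*pAKT_mem"),
        _rxn("pakt_dephos", {"pAKT": 1}, {"AKT": 1}, "mass_action",
             "k_dephos_pakt*pAKT"),
        # --- mTOR / TORC assembly -------------------------------------------
        _rxn("mtor_act", {"mTOR": 1}, {"amTOR": 1}, "catalytic",
             "kcat_mtor_act*pAKT*mTOR", modifiers=("pAKT",)),
        _rxn("mtor_deact", {"amTOR": 1}, {"mTOR": 1}, "mass_action",
             "k_mtor_deact*amTOR"),
        _rxn("torc1_bind", {"amTOR": 1, "Raptor": 1}, {"TORC1": 1}, "mass_action",
             "kon_torc1*amTOR*Raptor"),
        _rxn("torc1_unbind", {"TORC1": 1}, {"amTOR": 1, "Raptor": 1},
             "mass_action", "koff_torc1*TORC1"),
        _rxn("torc2_bind", {"mTOR": 1, "Rictor": 1}, {"TORC2": 1}, "mass_action",
             "kon_torc2*mTOR*Rictor"),
        _rxn("torc2_unbind", {"TORC2": 1}, {"mTOR": 1, "Rictor": 1},
             "mass_action", "koff_torc2*TORC2"),
        # --- Ras / Raf / MEK / ERK ------------------------------------------
        _rxn("ras_act", {"Ras": 1}, {"GTP_Ras": 1}, "catalytic",
             "kcat_ras_act*pEpoR_Sos*Ras", modifiers=("pEpoR_Sos",)),
        _rxn("ras_act_basal", {"Ras": 1}, {"GTP_Ras": 1}, "mass_action",
             "k_ras_basal*Ras"),
        _rxn("ras_gap", {"GTP_Ras": 1}, {"Ras": 1}, "mass_action",
             "k_ras_gap*GTP_Ras"),
        _rxn("ras_gap_receptor", {"pEpoR_GTPRas": 1}, {"pEpoR": 1, "Ras": 1},
             "mass_action", "kcat_ras_gap_rec*pEpoR_GTPRas"),
        _rxn("raf_act", {"Raf": 1}, {"pRaf": 1}, "catalytic",
             "kcat_raf_act*GTP_Ras*Raf", modifiers=("GTP_Ras",)),
        _rxn("raf_deact", {"pRaf": 1}, {"Raf": 1}, "mass_action",
             "k_raf_deact*pRaf"),
        _rxn("mek_phos_1", {"MEK": 1}, {"pMEK": 1}, "catalytic",
             "kcat_mek_p1*pRaf*MEK", modifiers=("pRaf",)),
        _rxn("mek_phos_2", {"pMEK": 1}, {"ppMEK": 1}, "catalytic",
             "kcat_mek_p2*pRaf*pMEK", modifiers=("pRaf",)),
        _rxn("mek_dephos_2", {"ppMEK": 1}, {"pMEK": 1}, "mass_action",
             "k_mek_dp2*ppMEK"),
        _rxn("mek_dephos_1", {"pMEK": 1}, {"MEK": 1}, "mass_action",
             "k_mek_dp1*pMEK"),
        _rxn("erk_phos_1", {"ERK": 1}, {"pERK": 1}, "catalytic",
             "kcat_erk_p1*inh_mek*ppMEK*ERK", modifiers=("ppMEK",)),
        _rxn("erk_phos_2", {"pERK": 1}, {"ppERK": 1}, "catalytic",
             "kcat_erk_p2*inh_mek*ppMEK*pERK", modifiers=("ppMEK",)),
        _rxn("erk_dephos_2", {"ppERK": 1}, {"pERK": 1}, "catalytic",
             "kcat_dusp_pp*DUSP_total*ppERK"),
        _rxn("erk_dephos_1", {"pERK": 1}, {"ERK": 1}, "catalytic",
             "kcat_dusp_p*DUSP_total*pERK"),
        # --- RSK / S6 integration -------------------------------------------
        _rxn("rsk_act", {"RSK": 1}, {"pRSK": 1}, "catalytic",
             "kcat_rsk_act*inh_rsk*ppERK*RSK", modifiers=("ppERK",)),
        _rxn("rsk_deact", {"pRSK": 1}, {"RSK": 1}, "mass_action",
             "k_rsk_deact*pRSK"),
        _rxn("s6_phos_torc1_a", {"S6": 1}, {"pS6": 1}, "catalytic",
             "kcat_s6_torc1_a*inh_mtor*TORC1*S6", modifiers=("TORC1",)),
        _rxn("s6_phos_torc1_b", {"pS6": 1}, {"ppS6": 1}, "catalytic",
             "kcat_s6_torc1_b*inh_mtor*TORC1*pS6", modifiers=("TORC1",)),
        _rxn("s6_phos_rsk_a", {"S6": 1}, {"pS6": 1}, "catalytic",
             "kcat_s6_rsk_a*pRSK*S6", modifiers=("pRSK",)),
        _rxn("s6_phos_rsk_b", {"pS6": 1}, {"ppS6": 1}, "catalytic",
             "kcat_s6_rsk_b*pRSK*pS6", modifiers=("pRSK",)),
        _rxn("s6_dephos_b", {"ppS6": 1}, {"pS6": 1}, "mass_action",
             "k_s6_dp_b*ppS6"),
        _rxn("s6_dephos_a", {"pS6": 1}, {"S6": 1}, "mass_action",
             "k_s6_dp_a*pS6"),
        # --- cell-cycle transcripts (fold-change units; basal steady state
        # equals the basal synthesis/degradation balance) ---------------------
        _rxn("ccnd2_syn", {}, {"mCCND2": 1}, "regulatory",
             "k_deg_ccnd2*(1 + w_akt_ccnd2*pAKT/(K_akt_ccnd2 + pAKT)"
             " + w_erk_ccnd2*ppERK/(K_erk_ccnd2 + ppERK))",
             modifiers=("pAKT", "ppERK")),
        _rxn("ccnd2_deg", {"mCCND2": 1}, {}, "mass_action",
             "k_deg_ccnd2*mCCND2"),
        _rxn("ccng2_syn", {}, {"mCCNG2": 1}, "regulatory",
             "k_deg_ccng2/(1 + w_akt_ccng2*pAKT/(K_akt_ccng2 + pAKT)"
             " + w_erk_ccng2*ppERK/(K_erk_ccng2 + ppERK))",
             modifiers=("pAKT", "ppERK")),
        _rxn("ccng2_deg", {"mCCNG2": 1}, {}, "mass_action",
             "k_deg_ccng2*mCCNG2"),
        _rxn("cdkn1b_syn", {}, {"mCDKN1B": 1}, "regulatory",
             "k_deg_cdkn1b/(1 + w_akt_cdkn1b*pAKT/(K_akt_cdkn1b + pAKT)"
             " + w_erk_cdkn1b*ppERK/(K_erk_cdkn1b + ppERK))",
             modifiers=("pAKT", "ppERK")),
        _rxn("cdkn1b_deg", {"mCDKN1B": 1}, {}, "mass_action",
             "k_deg_cdkn1b*mCDKN1B"),
    ]

    parameters = [
        # receptor
        "k_act_basal", "k_act_epo", "K_epo", "n_epo",
        "k_shp1_act", "k_shp1_basal", "k_shp1_deact",
        "kcat_shp1_pepor", "k_dephos_pepor",
        "kon_sos", "koff_sos", "kon_pi3k", "koff_pi3k",
        "kon_ship1", "koff_ship1", "kon_rasgtp", "koff_rasgtp",
        "kcat_shp1_sos", "kcat_shp1_pi3k", "kcat_shp1_ship1", "kcat_shp1_rasgtp",
        "k_dephos_sos_cplx", "k_dephos_pi3k_cplx", "k_dephos_ship1_cplx",
        "k_dephos_rasgtp_cplx",
        "k_epo_deg",
        # PIP3 / membrane
        "kcat_pip3", "k_pip3_basal", "kcat_ship1_m", "kcat_ship1_c", "kcat_pten",
        "kon_akt_mem", "koff_akt_mem", "kon_pdk1_mem", "koff_pdk1_mem",
        # AKT
        "kcat_akt_308", "kcat_akt_473", "k_dephos_pakt_mem", "k_dephos_pakt",
        # mTOR / TORC
        "kcat_mtor_act", "k_mtor_deact", "kon_torc1", "koff_torc1",
        "kon_torc2", "koff_torc2",
        # Ras / Raf / MEK / ERK
        "kcat_ras_act", "k_ras_basal", "k_ras_gap", "kcat_ras_gap_rec",
        "kcat_raf_act", "k_raf_deact",
        "kcat_mek_p1", "kcat_mek_p2", "k_mek_dp2", "k_mek_dp1",
        "kcat_erk_p1", "kcat_erk_p2", "kcat_dusp_pp", "kcat_dusp_p",
        # RSK / S6
        "kcat_rsk_act", "k_rsk_deact",
        "kcat_s6_torc1_a", "kcat_s6_torc1_b", "kcat_s6_rsk_a", "kcat_s6_rsk_b",
        "k_s6_dp_b", "k_s6_dp_a",
        # transcripts
        "k_deg_ccnd2", "w_akt_ccnd2", "w_erk_ccnd2", "K_akt_ccnd2", "K_erk_ccnd2",
        "k_deg_ccng2", "w_akt_ccng2", "w_erk_ccng2", "K_akt_ccng2", "K_erk_ccng2",
        "k_deg_cdkn1b", "w_akt_cdkn1b", "w_erk_cdkn1b", "K_akt_cdkn1b",
        "K_erk_cdkn1b",
    ]

    moieties = {
        "EpoR": ["EpoR", "pEpoR", "pEpoR_Sos", "pEpoR_PI3K", "pEpoR_SHIP1",
                 "pEpoR_GTPRas"],
        "Sos": ["Sos", "pEpoR_Sos"],
        "PI3K": ["PI3K", "pEpoR_PI3K"],
        "SHIP1": ["SHIP1", "pEpoR_SHIP1"],
        "SHP1": ["SHP1", "aSHP1"],
        "PIP2": ["PIP2", "PIP3"],
        "AKT": ["AKT", "AKT_mem", "pAKT_mem", "pAKT"],
        "PDK1": ["PDK1", "PDK1_mem"],
        "mTOR": ["mTOR", "amTOR", "TORC1", "TORC2"],
        "Raptor": ["Raptor", "TORC1"],
        "Rictor": ["Rictor", "TORC2"],
        "Ras": ["Ras", "GTP_Ras", "pEpoR_GTPRas"],
        "Raf": ["Raf", "pRaf"],
        "MEK": ["MEK", "pMEK", "ppMEK"],
        "ERK": ["ERK", "pERK", "ppERK"],
        "RSK": ["RSK", "pRSK"],
        "S6": ["S6", "pS6", "ppS6"],
    }

    observables = {
        "pEpoR": "pEpoR + pEpoR_Sos + pEpoR_PI3K + pEpoR_SHIP1 + pEpoR_GTPRas",
        "pAKT": "pAKT",
        "ppERK": "ppERK",
        "pS6": "pS6 + ppS6",
        "GTPRas": "GTP_Ras + pEpoR_GTPRas",
        "pRSK": "pRSK",
        "fc_ccnd2": "mCCND2",
        "fc_ccng2": "mCCNG2",
        "fc_cdkn1b": "mCDKN1B",
    }

    return dict(
        name="epo_akt_erk_s6_full",
        species=species,
        reactions=reactions,
        parameters=parameters,
        moieties=moieties,
        observables=observables,
        theta_default=dict(DEFAULT_THETA),
    )


def receptor_topology() -> dict:
    """Receptor-only subnetwork: pEpoR with its two dephosphorylation routes."""
    species = ["Epo", "EpoR", "pEpoR", "SHP1", "aSHP1"]
    hill = "(Max(Epo,0) + 1e-12)**n_epo/(K_epo**n_epo + (Max(Epo,0) + 1e-12)**n_epo)"
    reactions = [
        _rxn("epor_act_epo", {"EpoR": 1}, {"pEpoR": 1}, "hill_input",
             f"k_act_epo*ct_act*EpoR*{hill}"),
        _rxn("pepor_dephos_shp1", {"pEpoR": 1}, {"EpoR": 1}, "catalytic",
             "kcat_shp1_pepor*ct_deact*aSHP1*pEpoR", modifiers=("aSHP1",)),
        _rxn("pepor_dephos_const", {"pEpoR": 1}, {"EpoR": 1}, "mass_action",
             "k_dephos_pepor*pEpoR"),
        _rxn("shp1_act", {"SHP1": 1}, {"aSHP1": 1}, "catalytic",
             "k_shp1_act*pEpoR*SHP1", modifiers=("pEpoR",)),
        _rxn("shp1_deact", {"aSHP1": 1}, {"SHP1": 1}, "mass_action",
             "k_shp1_deact*aSHP1"),
        _rxn("epo_depletion", {"Epo": 1}, {}, "catalytic",
             "k_epo_deg*EpoR_total*Epo"),
    ]
    parameters = ["k_act_epo", "K_epo", "n_epo", "kcat_shp1_pepor",
                  "k_dephos_pepor", "k_shp1_act", "k_shp1_deact", "k_epo_deg"]
    theta = {p: DEFAULT_THETA[p] for p in parameters}
    return dict(
        name="epo_receptor_module",
        species=species,
        reactions=reactions,
        parameters=parameters,
        moieties={"EpoR": ["EpoR", "pEpoR"], "SHP1": ["SHP1", "aSHP1"]},
        observables={"pEpoR": "pEpoR"},
        theta_default=theta,
    )


def reduced_topology() -> dict:
    """Reduced 10-parameter single-route cascade Epo -> pR -> pA -> pS.

    A fast-simulating surrogate used for parameter-recovery and end-to-end
    studies: receptor activation with a Hill input and first-order decay, one
    lumped AKT-like activation step, one lumped S6-like step.
    """
    species = ["Epo", "R", "pR", "A", "pA", "S", "pS"]
    hill = "(Max(Epo,0) + 1e-12)**n_epo/(K_epo**n_epo + (Max(Epo,0) + 1e-12)**n_epo)"
    reactions = [
        _rxn("r_act_basal", {"R": 1}, {"pR": 1}, "mass_action", "k_act_basal*R"),
        _rxn("r_act_epo", {"R": 1}, {"pR": 1}, "hill_input",
             f"k_act_epo*R*{hill}"),
        _rxn("r_deact", {"pR": 1}, {"R": 1}, "mass_action", "k_deact_r*pR"),
        _rxn("epo_depletion", {"Epo": 1}, {}, "catalytic",
             "k_epo_deg*EpoR_total*Epo"),
        _rxn("a_act", {"A": 1}, {"pA": 1}, "catalytic",
             "kcat_a*inh_akt*pR*A", modifiers=("pR",)),
        _rxn("a_deact", {"pA": 1}, {"A": 1}, "mass_action", "k_deact_a*pA"),
        _rxn("s_act", {"S": 1}, {"pS": 1}, "catalytic",
             "kcat_s*pA*S", modifiers=("pA",)),
        _rxn("s_deact", {"pS": 1}, {"S": 1}, "mass_action", "k_deact_s*pS"),
    ]
    parameters = ["k_act_basal", "k_act_epo", "K_epo", "n_epo", "k_deact_r",
                  "k_epo_deg", "kcat_a", "k_deact_a", "kcat_s", "k_deact_s"]
    theta = {
        "k_act_basal": 1e-3, "k_act_epo": 0.5, "K_epo": 1.0, "n_epo": 1.0,
        "k_deact_r": 0.15, "k_epo_deg": 5e-3, "kcat_a": 5e-3,
        "k_deact_a": 0.12, "kcat_s": 2e-3, "k_deact_s": 0.08,
    }
    return dict(
        name="epo_cascade_reduced",
        species=species,
        reactions=reactions,
        parameters=parameters,
        moieties={"R": ["R", "pR"], "A": ["A", "pA"], "S": ["S", "pS"]},
        observables={"pR": "pR", "pA": "pA", "pS": "pS"},
        theta_default=theta,
    )


#: Moiety -> context protein supplying the conserved total; the unmodified
#: member of the moiety receives the total as initial condition.
_MOIETY_PROTEIN = {
    # full model
    "EpoR": "EpoR", "Sos": "Sos", "PI3K": "PI3K", "SHIP1": "SHIP1",
    "SHP1": "SHP1", "PIP2": "PIP2", "AKT": "AKT", "PDK1": "PDK1",
    "mTOR": "mTOR", "Raptor": "Raptor", "Rictor": "Rictor", "Ras": "Ras",
    "Raf": "Raf", "MEK": "MEK", "ERK": "ERK", "RSK": "RSK", "S6": "S6",
    # reduced model
    "R": "EpoR", "A": "AKT", "S": "S6",
}

#: States initialized at 1.0 (transcript fold-change variables).
_UNIT_INITIAL_STATES = ("mCCND2", "mCCNG2", "mCDKN1B")


def build_signaling_model(topology_spec: dict) -> SignalingModel:
    """Assemble and validate a :class:`SignalingModel` from a topology spec.

    The spec is plain data: species, reactions (name/stoichiometry/kind/rate),
    an ordered global parameter list with defaults, conserved moieties, and
    observable expressions.  Structural errors (dangling species, duplicate
    reactions, missing conservation members, unknown rate symbols) raise
    :class:`TopologyError` naming the offending element.
    """
    reactions = [
        r if isinstance(r, Reaction) else Reaction(**r)
        for r in topology_spec["reactions"]
    ]
    return SignalingModel(
        species=topology_spec["species"],
        reactions=reactions,
        parameters=topology_spec["parameters"],
        moieties=topology_spec["moieties"],
        observables=topology_spec["observables"],
        theta_default=topology_spec["theta_default"],
        name=topology_spec.get("name", "model"),
    )


def apply_cell_context(
    model: SignalingModel,
    context: CellTypeContext,
    theta: dict[str, float] | None = None,
    inhibitor_strengths: dict[str, float] | None = None,
    receptor_scaling: tuple[float, float] = (1.0, 1.0),
    observable_scales: dict[str, float] | None = None,
) -> ModelInstance:
    """Parametrize a model with one cell type's protein abundances.

    Conservation totals and enzyme concentrations come from the context
    (absent proteins as exactly 0); global kinetics stay untouched.
    Ratio-scale entries are resolved against the declared reference levels.
    """
    resolved = context.resolved_abundances()
    needed = {_MOIETY_PROTEIN[m] for m in model.moieties}
    needed |= {"PTEN", "DUSP", "EpoR"}
    missing = sorted(needed - set(resolved))
    if missing:
        raise KeyError(
            f"context {context.name!r} missing proteins required by the model: "
            f"{missing}"
        )
    for prot in needed:
        if resolved[prot] < 0:
            raise ValueError(f"negative abundance for {prot!r}")
    theta_full = dict(model.theta_default)
    if theta:
        unknown = set(theta) - set(model.parameters)
        if unknown:
            raise KeyError(f"unknown parameters {sorted(unknown)}")
        theta_full.update(theta)
    return ModelInstance(
        model=model,
        context_name=context.name,
        abundances={p: resolved[p] for p in sorted(needed)},
        theta=theta_full,
        inhibitor_strengths=dict(inhibitor_strengths or {}),
        receptor_scaling=receptor_scaling,
        observable_scales=dict(observable_scales or {}),
    )


def apply_perturbation(
    instance: ModelInstance, perturbations: list[Perturbation] | Perturbation
) -> ModelInstance:
    """Apply inhibitors / overexpression / knockdown; returns a new instance.

    An inhibitor at dose ``d`` scales its target process by ``1/(1 + d/s)``
    where ``s`` is the cell-type-specific strength (the dose producing
    half-inhibition).  Overexpression multiplies the protein's conserved
    total by the fold; knockdown sets it.  Perturbations compose
    multiplicatively and commute.
    """
    if isinstance(perturbations, Perturbation):
        perturbations = [perturbations]
    factors = dict(instance.inhibition_factors)
    abund = dict(instance.abundances)
    for pert in perturbations:
        if pert.kind == "inhibitor":
            sym, _ = INHIBITOR_TARGETS[pert.agent]
            try:
                strength = instance.inhibitor_strengths[pert.agent]
            except KeyError:
                raise KeyError(
                    f"no inhibitor strength configured for {pert.agent!r} in "
                    f"context {instance.context_name!r}"
                ) from None
            factors[sym] = factors.get(sym, 1.0) / (1.0 + pert.dose / strength)
        else:
            if pert.agent not in abund:
                raise KeyError(
                    f"unknown protein {pert.agent!r} for {pert.kind} in "
                    f"context {instance.context_name!r}"
                )
            if pert.kind == "overexpression":
                abund[pert.agent] *= pert.dose
            else:  # knockdown to target level
                abund[pert.agent] = pert.dose
    return replace(
        instance,
        inhibition_factors=factors,
        abundances=abund,
        perturbations=instance.perturbations + tuple(perturbations),
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_EPO_STATE = "Epo"
_SS_TOL = 1e-8  # nM/min sup-norm for pre-equilibration
_PRE_EQ_TMAX = 1e4  # minutes


def _initial_state(instance: ModelInstance) -> np.ndarray:
    model = instance.model
    y0 = np.zeros(len(model.species))
    idx = {s: i for i, s in enumerate(model.species)}
    for moiety, members in model.moieties.items():
        prot = _MOIETY_PROTEIN[moiety]
        y0[idx[members[0]]] = instance.abundances[prot]
    for s in _UNIT_INITIAL_STATES:
        if s in idx:
            y0[idx[s]] = 1.0
    return y0


def _rhs_functions(instance: ModelInstance):
    f_fn, j_fn, obs_fns = instance.model._compile()
    theta = np.array([instance.theta[p] for p in instance.model.parameters])
    ab = np.array([
        instance.abundances.get("PTEN", 0.0),
        instance.abundances.get("DUSP", 0.0),
        instance.abundances.get("EpoR", 0.0),
    ])
    ct = np.array(instance.receptor_scaling, dtype=float)
    inh = np.array([instance.inhibition_factors.get(s, 1.0)
                    for s in _INH_SYMBOLS])

    def f(t, y):
        return np.asarray(f_fn(y, theta, ab, ct, inh), dtype=float)

    def jac(t, y):
        return np.asarray(j_fn(y, theta, ab, ct, inh), dtype=float)

    return f, jac, obs_fns


def _solve(f, jac, y0, t_span, t_eval=None, rtol=1e-8, atol=1e-10,
           dense_output=False):
    sol = solve_ivp(
        f, t_span, y0, method="LSODA", jac=jac, t_eval=t_eval,
        rtol=rtol, atol=atol, dense_output=dense_output,
    )
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else t_span[0]
        raise IntegrationError(f"ODE solver failed: {sol.message}", last_t)
    return sol


#: Cache of pre-equilibration steady states.  The key captures everything
#: the unstimulated steady state depends on (inhibitors are applied only
#: after pre-equilibration and are deliberately not part of the key).
_EQUILIBRIUM_CACHE: dict[tuple, np.ndarray] = {}


def _equilibrium_key(instance: ModelInstance) -> tuple:
    return (
        instance.model._serial,
        tuple(sorted(instance.abundances.items())),
        tuple(sorted(instance.theta.items())),
        instance.receptor_scaling,
    )


def equilibrate_cached(instance: ModelInstance) -> np.ndarray:
    key = _equilibrium_key(instance)
    if key not in _EQUILIBRIUM_CACHE:
        if len(_EQUILIBRIUM_CACHE) > 512:
            _EQUILIBRIUM_CACHE.clear()
        _EQUILIBRIUM_CACHE[key] = equilibrate(instance)
    return _EQUILIBRIUM_CACHE[key].copy()


def equilibrate(instance: ModelInstance, y0: np.ndarray | None = None,
                with_inhibitors: bool = False) -> np.ndarray:
    """Relax the unstimulated (epo = 0) system to steady state.

    Growth-factor-deprived cells define the initial condition of every
    stimulation experiment.  Integration proceeds in windows up to 1e4 min
    until the derivative sup-norm drops below 1e-8 nM/min.
    """
    inst = instance
    if not with_inhibitors:
        inst = replace(instance,
                       inhibition_factors={s: 1.0 for s in _INH_SYMBOLS})
    f, jac, _ = _rhs_functions(inst)
    y = _initial_state(inst) if y0 is None else y0.copy()
    i_epo = inst.model.species.index(_EPO_STATE)
    y[i_epo] = 0.0
    t, window = 0.0, 500.0
    while t < _PRE_EQ_TMAX:
        sol = _solve(f, jac, y, (0.0, window))
        y = sol.y[:, -1]
        t += window
        window = min(window * 2, _PRE_EQ_TMAX - t) or window
        if np.max(np.abs(f(0.0, y))) < _SS_TOL:
            break
    return y


def simulate(
    instance: ModelInstance,
    epo_dose: float,
    t_grid: np.ndarray | list[float] | None = None,
    pre_equilibrate: bool = True,
    pretreat_min: float = 30.0,
    keep_dense: bool = False,
    y0: np.ndarray | None = None,
) -> Trajectory:
    """Simulate an Epo stimulation time course.

    With ``pre_equilibrate`` the deprived system is first relaxed to steady
    state without inhibitors; if the instance carries inhibitor perturbations
    these are then applied as a constant factor for ``pretreat_min`` minutes
    before stimulation (t = 0), matching a 30-min pretreatment protocol.
    """
    if epo_dose < 0:
        raise ValueError("epo dose must be >= 0 U/ml")
    t_grid = np.asarray([0.0, 10.0, 30.0, 60.0] if t_grid is None else t_grid,
                        dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0) or t_grid[0] != 0.0:
        raise ValueError("t_grid must be strictly increasing and start at 0")

    model = instance.model
    i_epo = model.species.index(_EPO_STATE)
    has_inhibitor = any(v != 1.0 for v in instance.inhibition_factors.values())

    if y0 is not None:
        y_start = y0.copy()
    elif pre_equilibrate:
        y_start = equilibrate_cached(instance)
        if has_inhibitor and pretreat_min > 0:
            f, jac, _ = _rhs_functions(instance)
            sol = _solve(f, jac, y_start, (-pretreat_min, 0.0))
            y_start = sol.y[:, -1]
    else:
        y_start = _initial_state(instance)

    f, jac, obs_fns = _rhs_functions(instance)
    y_start = y_start.copy()
    y_start[i_epo] = epo_dose
    sol = _solve(f, jac, y_start, (0.0, t_grid[-1]), t_eval=t_grid,
                 dense_output=keep_dense)

    states = {s: sol.y[i] for i, s in enumerate(model.species)}
    observables = {}
    for oname, fn in obs_fns.items():
        scale = instance.observable_scales.get(oname, 1.0)
        observables[oname] = scale * np.asarray(fn(sol.y), dtype=float)

    _, cons = model.conservation_matrix()
    totals = cons @ sol.y
    ref = totals[:, :1]
    with np.errstate(divide="ignore", invalid="ignore"):
        drift = np.abs(totals - ref) / np.where(ref != 0, ref, 1.0)
    conserved_drift = float(np.max(drift)) if drift.size else 0.0

    obs_eval = None
    if keep_dense:
        def _make(fn, scale):
            return lambda tt: scale * np.asarray(fn(sol.sol(tt)), dtype=float)
        obs_eval = {
            oname: _make(fn, instance.observable_scales.get(oname, 1.0))
            for oname, fn in obs_fns.items()
        }
    return Trajectory(
        time=t_grid,
        states=states,
        observables=observables,
        context_name=instance.context_name,
        epo_dose=epo_dose,
        perturbations=instance.perturbations,
        conserved_drift=conserved_drift,
        dense=sol.sol if keep_dense else None,
        _obs_eval=obs_eval,
    )


# ---------------------------------------------------------------------------
# Default global kinetic parameters (synthetic ground truth)
# ---------------------------------------------------------------------------

#: Default values of the 82 global kinetic parameters.  This parametrization
#: is a reduced, fast-simulating synthetic truth tuned to satisfy the
#: phospho-degree anchors and the qualitative cell-type-specific signal-flow
#: pattern; it is not a claim about fitted values from experimental data.
#: Units: /min for first-order constants, /(nM min) for second-order ones,
#: U/ml for K_epo; weights and Hill exponents dimensionless.
DEFAULT_THETA: dict[str, float] = {
    # receptor
    "k_act_basal": 2e-4, "k_act_epo": 1.0, "K_epo": 1.0, "n_epo": 1.0,
    "k_shp1_act": 5e-3, "k_shp1_basal": 1e-3, "k_shp1_deact": 0.05,
    "kcat_shp1_pepor": 0.02, "k_dephos_pepor": 0.05,
    "kon_sos": 5e-3, "koff_sos": 0.5,
    "kon_pi3k": 5e-3, "koff_pi3k": 0.5,
    "kon_ship1": 2e-3, "koff_ship1": 0.5,
    "kon_rasgtp": 1e-4, "koff_rasgtp": 1.0,
    "kcat_shp1_sos": 0.02, "kcat_shp1_pi3k": 0.02,
    "kcat_shp1_ship1": 0.02, "kcat_shp1_rasgtp": 0.02,
    "k_dephos_sos_cplx": 0.02, "k_dephos_pi3k_cplx": 0.02,
    "k_dephos_ship1_cplx": 0.02, "k_dephos_rasgtp_cplx": 0.02,
    "k_epo_deg": 1e-3,
    # PIP3 / membrane
    "kcat_pip3": 0.05, "k_pip3_basal": 2e-6,
    "kcat_ship1_m": 2.5, "kcat_ship1_c": 0.005, "kcat_pten": 0.01,
    "kon_akt_mem": 2e-3, "koff_akt_mem": 0.5,
    "kon_pdk1_mem": 2e-3, "koff_pdk1_mem": 0.5,
    # AKT
    "kcat_akt_308": 1e-3, "kcat_akt_473": 5e-3,
    "k_dephos_pakt_mem": 0.1, "k_dephos_pakt": 0.15,
    # mTOR / TORC
    "kcat_mtor_act": 2e-3, "k_mtor_deact": 0.1,
    "kon_torc1": 5e-3, "koff_torc1": 0.2,
    "kon_torc2": 5e-4, "koff_torc2": 0.1,
    # Ras / Raf / MEK / ERK
    "kcat_ras_act": 0.02, "k_ras_basal": 1e-5, "k_ras_gap": 0.3,
    "kcat_ras_gap_rec": 0.5,
    "kcat_raf_act": 2e-4, "k_raf_deact": 0.3,
    "kcat_mek_p1": 3e-4, "kcat_mek_p2": 3e-4,
    "k_mek_dp2": 0.5, "k_mek_dp1": 0.5,
    "kcat_erk_p1": 5e-3, "kcat_erk_p2": 5e-3,
    "kcat_dusp_pp": 0.02, "kcat_dusp_p": 0.02,
    # RSK / S6
    "kcat_rsk_act": 1e-3, "k_rsk_deact": 0.2,
    "kcat_s6_torc1_a": 2e-4, "kcat_s6_torc1_b": 2e-4,
    "kcat_s6_rsk_a": 5e-5, "kcat_s6_rsk_b": 5e-5,
    "k_s6_dp_b": 0.1, "k_s6_dp_a": 0.1,
    # transcripts (degradation /min; weights and half-saturations)
    "k_deg_ccnd2": 0.02, "w_akt_ccnd2": 3.0, "w_erk_ccnd2": 2.0,
    "K_akt_ccnd2": 100.0, "K_erk_ccnd2": 50.0,
    "k_deg_ccng2": 0.02, "w_akt_ccng2": 2.0, "w_erk_ccng2": 2.0,
    "K_akt_ccng2": 100.0, "K_erk_ccng2": 50.0,
    "k_deg_cdkn1b": 0.02, "w_akt_cdkn1b": 2.5, "w_erk_cdkn1b": 1.5,
    "K_akt_cdkn1b": 100.0, "K_erk_cdkn1b": 50.0,
}
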