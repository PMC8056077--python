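"""Compartmented kinetic model of embryo carbon/energy metabolism.

The default reconstruction covers the pathways that dominate carbon and
energy flow in an oilseed embryo between fertilization and maturity:

* sucrose unloading and hexose uptake (cell-wall invertase CWI, glucose
  transporter GLCT) and sucrose/starch turnover (SUS, STAS, STAD);
* a five-step lumped glycolysis (HK, PFK, PGK, the non-phosphorylating
  NADPH-producing bypass NPG, cytosolic pyruvate kinase PKc);
* the oxidative pentose-phosphate pathway with the epimerase return route
  (EPI) and a carbon-conserving Rubisco bypass (RUB) feeding the plastid;
* plastidial glycolysis and fatty-acid (FA) synthesis: PEP/pyruvate
  transporters (PEPT, PYRT), plastidial pyruvate kinase (PKp), plastidial
  pyruvate dehydrogenase (PDHp), acetyl-CoA carboxylase (ACCp) and the FA
  synthase complex (FAS), both feedback-inhibited by the short-chain
  acyl-ACP pool (SCFA), and acyl export (FAX);
* cytosolic FA handling: cytosolic ACCase (ACCc), FA elongation (FAE),
  triacylglycerol assembly (TAGS) and oxidation (TAGOX) with the glyoxylate
  shunt (ICL);
* a lumped mitochondrial TCA cycle (PDHm, CS, IDH, AKGDH) with anaplerotic
  and exchange reactions (PEPC, ME, GDH, AAT, citrate export CITT, ATP
  citrate lyase ACL);
* storage-protein synthesis (SPRTS, driven directly by storage-protein
  mRNA) and maintenance (oxidative phosphorylation OXP, mitochondrial
  proton leak LEAK, endogenous oxidative stress OX, and mixed
  growth/non-growth ATP maintenance ATPM).

Mass balances follow dM/dt = S.v - mu.M, i.e. production/consumption by the
stoichiometric matrix plus first-order dilution of intracellular pools by
growth.  Cofactor pairs (ATP/ADP, NAD(H), NADP(H)) are treated as
homeostatically maintained conserved moieties and are exempt from dilution;
clamped external pools (maternal sucrose and alanine) are constant.

Flux kinetics follow v_i = E_i * k_i * f(M, p) where E_i is the (relative)
enzyme level from the expression layer, k_i a reaction constant lumping the
absolute enzyme abundance, and f combines Michaelis-Menten saturation,
Hill-type feedback inhibition, reversible Michaelis-Menten (for sucrose
synthase, GDH and AAT) and the special maintenance forms.

The ~125 default parameters are literature-plausible affinities plus rate
constants anchored to a mid-filling reference flux map (see
``REFERENCE_FLUXES``); growth follows a logistic curve matching the early
(0.025 hr^-1) and mature (0.0025 hr^-1) specific growth rates.

All times are hours internally; concentrations are model-relative units.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from .expression import HOURS_PER_DAY, ConfigurationError, InputError

COMPARTMENTS = ("cytosol", "plastid", "mitochondrion", "external")

COFACTOR_PAIRS = {
    "adenylate": ("ATP", "ADP"),
    "nad_pool": ("NADH", "NAD"),
    "nadp_pool": ("NADPH", "NADP"),
}

LAW_TYPES = (
    "michaelis_menten",
    "reversible_mm",
    "mass_action",
    "hill_inhibited",  # alias: michaelis_menten with inhibitors
    "mrna_proportional",
    "logistic_growth",
    "constant_maintenance",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Parameter:
    value: float
    bounds: tuple[float, float] = (0.0, np.inf)
    provenance: str = "default"  # literature | fitted | default

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (lo <= self.value <= hi):
            raise ConfigurationError(
                f"parameter value {self.value} outside bounds {self.bounds}"
            )


class ParameterSet(dict):
    """Named parameters with values, bounds and provenance tags."""

    def add(
        self,
        name: str,
        value: float,
        bounds: tuple[float, float] | None = None,
        provenance: str = "default",
    ) -> None:
        if bounds is None:
            bounds = (value / 100.0 if value > 0 else 0.0, max(value * 100.0, 1.0))
        self[name] = Parameter(float(value), bounds, provenance)

    def value(self, name: str) -> float:
        try:
            return self[name].value
        except KeyError:
            raise ConfigurationError(f"missing parameter {name!r}") from None

    def values_dict(self) -> dict[str, float]:
        return {k: p.value for k, p in self.items()}


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    initial_concentration: float
    cofactor_pair_id: str | None = None
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ConfigurationError(f"unknown compartment {self.compartment!r}")
        if self.initial_concentration < 0:
            raise ConfigurationError(
                f"negative initial concentration for {self.id}"
            )


@dataclass(frozen=True)
class RateLawSpec:
    """Declarative kinetic law for one reaction.

    ``substrates``/``products`` are (metabolite_id, K_param_name, exponent)
    triples; ``inhibitors`` are (metabolite_id, Ki_param_name, n_param_name)
    Hill-inhibition terms.  Parameter *names* are stored; values live in the
    model's ParameterSet so calibration can rebind them.
    """

    law_type: str
    k: str | None = None
    substrates: tuple[tuple[str, str, float], ...] = ()
    products: tuple[tuple[str, str, float], ...] = ()
    keq: str | None = None
    inhibitors: tuple[tuple[str, str, str], ...] = ()
    mrna_key: str | None = None

    def __post_init__(self) -> None:
        if self.law_type not in LAW_TYPES:
            raise ConfigurationError(f"unknown law type {self.law_type!r}")


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    rate_law: RateLawSpec
    enzyme_id: str | None = None
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ConfigurationError(f"reaction {self.id} has empty stoichiometry")


@dataclass
class GrowthModel:
    """Logistic seed growth; mu(t) = (dm/dt)/m.

    Parametrized by the early and mature specific growth rates and the time
    at which the mature rate is reached; the logistic rate r and initial
    mass fraction are solved from those constraints, so mu(0) == mu_early
    and mu(t_mature) == mu_mature exactly.
    """

    mu_early: float = 0.025  # hr^-1
    mu_mature: float = 0.0025  # hr^-1
    t_mature_daf: float = 13.0
    m_max: float = 1.0
    _r: float = dc_field(init=False, repr=False)
    _c: float = dc_field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (0 < self.mu_mature < self.mu_early):
            raise ConfigurationError("need 0 < mu_mature < mu_early")
        tm = self.t_mature_daf * HOURS_PER_DAY

        # mu(t) = r / (1 + c*exp(r t)); mu(0)=mu_early fixes c = r/mu_early - 1.
        def resid(r: float) -> float:
            c = r / self.mu_early - 1.0
            return r / (1.0 + c * np.exp(r * tm)) - self.mu_mature

        r = brentq(resid, self.mu_early * (1.0 + 1e-12), self.mu_early * 2.0)
        self._r = float(r)
        self._c = float(r / self.mu_early - 1.0)

    def mu(self, t_hr: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_hr, dtype=float)
        out = self._r / (1.0 + self._c * np.exp(self._r * t))
        return out if out.ndim else float(out)

    def mass(self, t_hr: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_hr, dtype=float)
        a = 1.0 / self._c  # m(t) = m_max / (1 + A exp(-r t)), A = 1/c
        out = self.m_max / (1.0 + a * np.exp(-self._r * t))
        return out if out.ndim else float(out)


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    parameters: ParameterSet
    growth: GrowthModel
    enzyme_turnover: dict[str, str]  # enzyme_id -> turnover class label
    name: str = "seedflux-default"

    # -- indexing helpers ---------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def enzyme_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.reactions:
            if r.enzyme_id and r.enzyme_id not in seen:
                seen.append(r.enzyme_id)
        return seen

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions)."""
        idx = {m: i for i, m in enumerate(self.metabolite_ids)}
        s = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coeff in rxn.stoichiometry.items():
                s[idx[met], j] = coeff
        return s

    def initial_state(self) -> np.ndarray:
        return np.array([m.initial_concentration for m in self.metabolites])

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        met_ids = self.metabolite_ids
        if len(set(met_ids)) != len(met_ids):
            raise ConfigurationError("duplicate metabolite ids")
        rxn_ids = self.reaction_ids
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ConfigurationError("duplicate reaction ids")
        met_set = set(met_ids)
        for rxn in self.reactions:
            for met in rxn.stoichiometry:
                if met not in met_set:
                    raise ConfigurationError(
                        f"reaction {rxn.id} references unknown metabolite {met}"
                    )
            law = rxn.rate_law
            for met, km, _ in law.substrates + law.products:
                if met not in met_set:
                    raise ConfigurationError(
                        f"rate law of {rxn.id} references unknown metabolite {met}"
                    )
                self.parameters.value(km)
            for met, ki, n in law.inhibitors:
                if met not in met_set:
                    raise ConfigurationError(
                        f"inhibitor of {rxn.id} references unknown metabolite {met}"
                    )
                self.parameters.value(ki)
                self.parameters.value(n)
            if law.k is not None:
                self.parameters.value(law.k)
            if law.keq is not None:
                self.parameters.value(law.keq)
            if rxn.enzyme_id is not None and rxn.enzyme_id not in self.enzyme_turnover:
                raise ConfigurationError(
                    f"enzyme {rxn.enzyme_id} of reaction {rxn.id} has no "
                    "turnover-class assignment"
                )
        # every cofactor-paired reaction must conserve its pair
        s = self.stoichiometric_matrix()
        idx = {m: i for i, m in enumerate(met_ids)}
        for pair, members in COFACTOR_PAIRS.items():
            if all(m in idx for m in members):
                rows = s[[idx[m] for m in members], :]
                if not np.allclose(rows.sum(axis=0), 0.0, atol=1e-12):
                    bad = [
                        self.reactions[j].id
                        for j in np.nonzero(~np.isclose(rows.sum(axis=0), 0.0))[0]
                    ]
                    raise ConfigurationError(
                        f"cofactor pair {pair} not conserved by reactions {bad}"
                    )


# ---------------------------------------------------------------------------
# Kinetic-law evaluation
# ---------------------------------------------------------------------------


def hill_inhibition(conc: float, ki: float, n: float) -> float:
    """Hill-type inhibition multiplier Ki^n / (Ki^n + I^n), in (0, 1]."""
    if conc <= 0:
        return 1.0
    kin = ki**n
    return kin / (kin + conc**n)


def scfa_feedback_multiplier(scfa: float, ki: float, n: float = 2.0) -> float:
    """Feedback inhibition of ACCase / FA synthase by the acyl-ACP pool."""
    return hill_inhibition(scfa, ki, n)


def eval_flux(
    reaction: Reaction,
    state: Mapping[str, float],
    enzyme_level: float,
    params: ParameterSet,
    *,
    mu: float = 0.0,
    mrna: float = 1.0,
) -> float:
    """Evaluate one reaction's flux at a (metabolite -> concentration) state.

    Reference implementation used for tests and single-point queries; the
    simulator uses the vectorized ``CompiledModel`` path.
    """
    law = reaction.rate_law
    conc = lambda met: max(float(state[met]), 0.0)  # noqa: E731

    inh = 1.0
    for met, ki, n in law.inhibitors:
        inh *= hill_inhibition(conc(met), params.value(ki), params.value(n))

    if law.law_type == "constant_maintenance":
        rate = params.value("alpha_maint") * mu + params.value("beta_maint")
        for met, km, _ in law.substrates:
            s = conc(met)
            rate *= s / (params.value(km) + s)
        return rate * inh

    if law.law_type == "mrna_proportional":
        rate = params.value(law.k) * max(mrna, 0.0)
        for met, km, _ in law.substrates:
            s = conc(met)
            rate *= s / (params.value(km) + s)
        return rate * inh

    if law.law_type == "mass_action":
        rate = params.value(law.k) * enzyme_level
        for met, _, expo in law.substrates:
            rate *= conc(met) ** expo
        return rate * inh

    if law.law_type == "reversible_mm":
        fwd = 1.0
        for met, km, expo in law.substrates:
            fwd *= (conc(met) / params.value(km)) ** expo
        rev = 1.0
        for met, km, expo in law.products:
            rev *= (conc(met) / params.value(km)) ** expo
        rev /= params.value(law.keq)
        return (
            params.value(law.k)
            * enzyme_level
            * (fwd - rev)
            / (1.0 + fwd + rev)
            * inh
        )

    # michaelis_menten / hill_inhibited
    rate = params.value(law.k) * enzyme_level
    for met, km, _ in law.substrates:
        s = conc(met)
        rate *= s / (params.value(km) + s)
    return rate * inh


class CompiledModel:
    """Vectorized flux/RHS evaluator compiled from a MetabolicModel.

    Parameter values are frozen at compile time; recompile after editing the
    ParameterSet.  Enzyme levels are supplied per call as a vector aligned
    with ``enzyme_ids``.
    """

    def __init__(self, model: MetabolicModel):
        model.validate()
        self.model = model
        self.met_ids = model.metabolite_ids
        self.rxn_ids = model.reaction_ids
        self.met_index = {m: i for i, m in enumerate(self.met_ids)}
        self.rxn_index = {r: i for i, r in enumerate(self.rxn_ids)}
        self.enzyme_ids = model.enzyme_ids
        enz_index = {e: i for i, e in enumerate(self.enzyme_ids)}
        self.n_met = len(self.met_ids)
        self.n_rxn = len(self.rxn_ids)
        self.s_matrix = model.stoichiometric_matrix()
        p = model.parameters

        self.rxn_enz = np.array(
            [
                enz_index[r.enzyme_id] if r.enzyme_id is not None else -1
                for r in model.reactions
            ]
        )
        self.clamped = np.array([m.clamped for m in model.metabolites])
        self.dilute = np.array(
            [
                not m.clamped and m.cofactor_pair_id is None
                for m in model.metabolites
            ]
        )
        self.k_vec = np.array(
            [
                p.value(r.rate_law.k) if r.rate_law.k is not None else 0.0
                for r in model.reactions
            ]
        )
        self.irreversible = np.array([not r.reversible for r in model.reactions])

        # flattened simple-MM substrate terms for irreversible MM-type laws
        t_rxn, t_met, t_km = [], [], []
        # flattened Hill inhibition terms
        i_rxn, i_met, i_ki, i_n = [], [], [], []
        # special-law bookkeeping
        self.special: list[tuple[int, Reaction]] = []
        for j, r in enumerate(model.reactions):
            law = r.rate_law
            for met, ki, n in law.inhibitors:
                i_rxn.append(j)
                i_met.append(self.met_index[met])
                i_ki.append(p.value(ki))
                i_n.append(p.value(n))
            if law.law_type in ("michaelis_menten", "hill_inhibited"):
                for met, km, _ in law.substrates:
                    t_rxn.append(j)
                    t_met.append(self.met_index[met])
                    t_km.append(p.value(km))
            else:
                self.special.append((j, r))
        self.t_rxn = np.array(t_rxn, dtype=int)
        self.t_met = np.array(t_met, dtype=int)
        self.t_km = np.array(t_km)
        self.i_rxn = np.array(i_rxn, dtype=int)
        self.i_met = np.array(i_met, dtype=int)
        self.i_ki = np.array(i_ki)
        self.i_n = np.array(i_n)
        # terms are appended in reaction order, so groups are contiguous and
        # per-reaction products can use multiply.reduceat
        self.t_groups, self.t_starts = np.unique(self.t_rxn, return_index=True)
        self.i_groups, self.i_starts = np.unique(self.i_rxn, return_index=True)

        self.alpha = p.value("alpha_maint") if "alpha_maint" in p else 0.0
        self.beta = p.value("beta_maint") if "beta_maint" in p else 0.0

        # pre-resolve special-law parameters
        self._special_data = []
        for j, r in self.special:
            law = r.rate_law
            subs = [(self.met_index[m], p.value(km), e) for m, km, e in law.substrates]
            prods = [(self.met_index[m], p.value(km), e) for m, km, e in law.products]
            keq = p.value(law.keq) if law.keq else 1.0
            self._special_data.append((j, law.law_type, subs, prods, keq, law.mrna_key))

    def fluxes(
        self,
        y: np.ndarray,
        enzyme_levels: np.ndarray,
        *,
        mu: float = 0.0,
        mrna: Mapping[str, float] | None = None,
    ) -> np.ndarray:
        """Flux vector at state y (negative concentrations treated as 0)."""
        yc = np.maximum(y, 0.0)
        e_full = np.ones(self.n_rxn)
        has_enz = self.rxn_enz >= 0
        e_full[has_enz] = np.maximum(enzyme_levels[self.rxn_enz[has_enz]], 0.0)

        f = np.ones(self.n_rxn)
        if len(self.t_rxn):
            s = yc[self.t_met]
            f[self.t_groups] = np.multiply.reduceat(
                s / (self.t_km + s), self.t_starts
            )
        if len(self.i_rxn):
            i_conc = yc[self.i_met]
            kin = self.i_ki**self.i_n
            f[self.i_groups] *= np.multiply.reduceat(
                kin / (kin + i_conc**self.i_n), self.i_starts
            )

        v = self.k_vec * e_full * f

        for j, law_type, subs, prods, keq, mrna_key in self._special_data:
            inh = f[j]  # only inhibition factors were folded into f for special laws
            if law_type == "reversible_mm":
                fwd = 1.0
                for m, km, expo in subs:
                    fwd *= (yc[m] / km) ** expo
                rev = 1.0
                for m, km, expo in prods:
                    rev *= (yc[m] / km) ** expo
                rev /= keq
                v[j] = self.k_vec[j] * e_full[j] * (fwd - rev) / (1.0 + fwd + rev) * inh
            elif law_type == "mass_action":
                rate = self.k_vec[j] * e_full[j]
                for m, _, expo in subs:
                    rate *= yc[m] ** expo
                v[j] = rate * inh
            elif law_type == "mrna_proportional":
                rate = self.k_vec[j] * max((mrna or {}).get(mrna_key, 0.0), 0.0)
                for m, km, _ in subs:
                    rate *= yc[m] / (km + yc[m])
                v[j] = rate * inh
            elif law_type == "constant_maintenance":
                rate = self.alpha * mu + self.beta
                for m, km, _ in subs:
                    rate *= yc[m] / (km + yc[m])
                v[j] = rate * inh
        v[self.irreversible] = np.maximum(v[self.irreversible], 0.0)
        return v

    def rhs(
        self,
        enzyme_fn: Callable[[float], np.ndarray],
        mu_fn: Callable[[float], float],
        mrna_fns: Mapping[str, Callable[[float], float]] | None = None,
    ) -> Callable[[float, np.ndarray], np.ndarray]:
        """Time-derivative function dM/dt = S.v(M, E(t)) - mu(t).M.

        ``enzyme_fn(t)`` must return levels aligned with ``enzyme_ids``;
        ``mrna_fns`` supplies mRNA-driven rates (storage-protein synthesis).
        Clamped external metabolites are held constant; cofactor pools are
        not diluted.
        """
        mrna_fns = mrna_fns or {}

        def f(t: float, y: np.ndarray) -> np.ndarray:
            mu = float(mu_fn(t))
            mrna = {k: float(fn(t)) for k, fn in mrna_fns.items()}
            v = self.fluxes(y, enzyme_fn(t), mu=mu, mrna=mrna)
            dy = self.s_matrix @ v
            dy[self.dilute] -= mu * y[self.dilute]
            dy[self.clamped] = 0.0
            return dy

        return f


# ---------------------------------------------------------------------------
# Default reconstruction
# ---------------------------------------------------------------------------

#: Clamped maternal-supply concentrations (model units).
BOUNDARY_CONCENTRATIONS = {"SUC_x": 2.0, "ALA_x": 1.0}

#: Typical mid-seed-filling state used to anchor rate constants (model units).
REFERENCE_STATE = {
    "SUC_x": 2.0, "ALA_x": 1.0, "GLC_x": 0.5,
    "SUC_c": 1.0, "GLC_c": 1.0, "HP_c": 0.5, "TP_c": 0.2, "PEP_c": 0.3,
    "PYR_c": 0.3, "R5P_c": 0.2, "CIT_c": 0.2, "ACA_c": 0.1, "MALCOA_c": 0.05,
    "GLT_c": 1.0, "STA_c": 1.0, "SPRT_c": 0.1, "FFA_c": 0.1, "VLCFA_c": 0.05,
    "TAG_c": 0.5,
    "PEP_p": 0.2, "PYR_p": 0.2, "ACA_p": 0.1, "MALACP_p": 0.05, "SCFA_p": 0.03,
    "ACA_m": 0.1, "CIT_m": 0.3, "AKG_m": 0.3, "MAL_m": 0.5,
    "ATP": 1.0, "ADP": 0.5, "NAD": 0.5, "NADH": 0.1, "NADP": 0.1, "NADPH": 0.3,
}

#: Mid-filling reference flux map (model units / hr) used to anchor the rate
#: constants of the irreversible reactions; loosely patterned on embryo flux
#: estimates (glycolytic mode, plastid-dominated pyruvate kinase flux, a
#: minor Rubisco bypass, and FA synthesis as the dominant carbon sink).
REFERENCE_FLUXES = {
    "CWI": 0.16, "GLCT": 0.32, "HK": 0.30, "STAS": 0.01, "STAD": 0.01,
    "PFK": 0.12, "PGK": 0.24, "NPG": 0.03, "PKc": 0.06,
    "PPP": 0.10, "EPI": 0.01, "RUB": 0.07,
    "PEPT": 0.18, "PYRT": 0.03, "PKp": 0.29, "PDHp": 0.32,
    "ACCp": 0.26, "FAS": 0.032, "FAX": 0.032,
    "ACCc": 0.008, "FAE": 0.006, "TAGS": 0.01, "TAGOX": 0.0042,
    "PDHm": 0.09, "CS": 0.085, "IDH": 0.07, "AKGDH": 0.07,
    "PEPC": 0.03, "ME": 0.05, "ICL": 0.004, "CITT": 0.012, "ACL": 0.01,
    "OXP": 0.63, "LEAK": 0.08, "OX": 0.15, "SPRTS": 0.005,
}

#: Reference enzyme level per reaction when solving k from the flux map
#: (mid-peak expression program enzymes sit well above their initial level
#: at mid filling).
REFERENCE_ENZYME_LEVEL = 3.0

#: Enzymes following the mid-window (oil-filling) expression program.
MID_PEAK_ENZYMES = (
    "CWI", "GLCT", "NPG", "RUB", "PPP",
    "PEPT", "PYRT", "PKp", "PDHp", "ACCp", "FAS", "FAX",
    "ACCc", "FAE", "TAGS", "ACL",
)

#: Turnover-class assignment for the default model (fall-back is 'average').
DEFAULT_TURNOVER = {
    "HK": "fast", "PFK": "fast", "PKc": "fast", "PKp": "fast",
    "FAS": "fast", "ACCp": "fast", "FAX": "fast",
    "RUB": "slow", "FAE": "slow", "TAGS": "slow",
    "ACCc": "slow", "TAGOX": "average",
}

#: Weights of the total-FA read-out: free FA + short-chain acyl-ACP +
#: elongated FA + 3 acyl chains per TAG (glycerol backbone excluded).
FA_POOLS = {"FFA_c": 1.0, "SCFA_p": 1.0, "VLCFA_c": 1.0, "TAG_c": 3.0}


def _default_metabolites() -> list[Metabolite]:
    m = []

    def add(mid, comp, conc, pair=None, clamped=False):
        m.append(Metabolite(mid, comp, conc, pair, clamped))

    ref = REFERENCE_STATE
    add("SUC_x", "external", ref["SUC_x"], clamped=True)
    add("ALA_x", "external", ref["ALA_x"], clamped=True)
    add("GLC_x", "external", 0.2)
    initial_cytosol = {
        "SUC_c": 0.1, "GLC_c": 0.2, "HP_c": 0.3, "TP_c": 0.2, "PEP_c": 0.3,
        "PYR_c": 0.3, "R5P_c": 0.2, "CIT_c": 0.2, "ACA_c": 0.1,
        "MALCOA_c": 0.05, "GLT_c": 1.0,
    }
    for mid, conc in initial_cytosol.items():
        add(mid, "cytosol", conc)
    # storage pools start near zero at fertilization
    add("STA_c", "cytosol", 0.02)
    add("SPRT_c", "cytosol", 0.001)
    add("FFA_c", "cytosol", 0.005)
    add("VLCFA_c", "cytosol", 0.002)
    add("TAG_c", "cytosol", 0.002)
    for mid in ("PEP_p", "PYR_p", "ACA_p", "MALACP_p", "SCFA_p"):
        add(mid, "plastid", 0.05)
    for mid in ("ACA_m", "CIT_m", "AKG_m", "MAL_m"):
        add(mid, "mitochondrion", ref[mid])
    add("ATP", "cytosol", ref["ATP"], "adenylate")
    add("ADP", "cytosol", ref["ADP"], "adenylate")
    add("NAD", "cytosol", ref["NAD"], "nad_pool")
    add("NADH", "cytosol", ref["NADH"], "nad_pool")
    add("NADP", "cytosol", ref["NADP"], "nadp_pool")
    add("NADPH", "cytosol", ref["NADPH"], "nadp_pool")
    return m


def _mm(k, subs, inhibitors=()):
    return RateLawSpec(
        "michaelis_menten",
        k=k,
        substrates=tuple((m, km, 1.0) for m, km in subs),
        inhibitors=tuple(inhibitors),
    )


def build_default_model() -> MetabolicModel:
    """The reference embryo reconstruction: 34 metabolites, 40 reactions.

    Rate constants of irreversible reactions are solved from
    ``REFERENCE_FLUXES`` at ``REFERENCE_STATE`` so that the model's
    mid-filling operating point matches the documented flux map; affinity
    and inhibition constants carry literature-plausible defaults.
    """
    p = ParameterSet()

    # affinities (model-relative Km); provenance 'literature' marks values in
    # the plausible range for the corresponding enzyme class
    km_defaults = {
        "Km_CWI_SUC": 1.0, "Km_GLCT_GLC": 0.3,
        "Ka_SUS_GLC": 1.0, "Kp_SUS_SUC": 1.0,
        "Km_HK_GLC": 0.3, "Km_ATP": 0.3,
        "Km_STAS_HP": 0.5, "Km_ATP": 0.3,
        "Km_STAD_STA": 1.0,
        "Km_PFK_HP": 0.3, "Km_ATP": 0.2,
        "Km_PGK_TP": 0.2, "Km_ADP": 0.05, "Km_NAD": 0.05,
        "Km_NPG_TP": 0.3, "Km_NADP": 0.05,
        "Km_PKc_PEP": 0.3, "Km_ADP": 0.05,
        "Km_PPP_HP": 0.2, "Km_NADP": 0.05,
        "Km_EPI_R5P": 0.2,
        "Km_RUB_R5P": 0.3, "Km_ATP": 0.3,
        "Km_PEPT_PEP": 0.3, "Km_PYRT_PYR": 0.3,
        "Km_PKp_PEP": 0.2, "Km_ADP": 0.05,
        "Km_PDHp_PYR": 0.2, "Km_NAD": 0.05,
        "Km_ACCp_ACA": 0.1, "Km_ATP": 0.3,
        "Km_FAS_MALACP": 0.15, "Km_NADPH": 0.1,
        "Km_FAX_SCFA": 0.05,
        "Km_ACCc_ACA": 0.1, "Km_ATP": 0.3,
        "Km_FAE_FFA": 0.1, "Km_FAE_MALCOA": 0.05, "Km_NADPH": 0.1,
        "Km_TAGS_TP": 0.005, "Km_TAGS_FFA": 0.1, "Km_TAGS_VLCFA": 0.01,
        "Km_ATP": 0.3,
        "Km_TAGOX_TAG": 0.7, "Km_NAD": 0.05,
        "Km_PDHm_PYR": 0.2, "Km_NAD": 0.05,
        "Km_CS_ACA": 0.1, "Km_CS_MAL": 0.3, "Km_NAD": 0.05,
        "Km_IDH_CIT": 0.3, "Km_NAD": 0.05,
        "Km_AKGDH_AKG": 0.3, "Km_NAD": 0.05, "Km_ADP": 0.05,
        "Km_PEPC_PEP": 0.3, "Km_rNADH": 0.05,
        "Km_ME_MAL": 0.5, "Km_NADP": 0.05,
        "Ka_GDH_GLT": 1.0, "Ka_GDH_NAD": 0.1, "Kp_GDH_AKG": 0.5,
        "Kp_GDH_NADH": 0.1,
        "Ka_AAT_ALA": 0.5, "Ka_AAT_AKG": 0.3, "Kp_AAT_PYR": 0.5,
        "Kp_AAT_GLT": 1.0,
        "Km_ICL_CIT": 0.5, "Km_ICL_ACA": 0.2,
        "Km_CITT_CIT": 0.3,
        "Km_ACL_CIT": 0.3, "Km_ATP": 0.3, "Km_rNADH": 0.1,
        "Km_rNADH": 0.1, "Km_ADP": 0.05,
        "Km_rNADH": 0.2, "Km_rNADPH": 0.3,
        "Km_ATP": 0.3,
        "Km_SPRTS_GLT": 0.5, "Km_ATP": 0.3,
    }
    for name, val in km_defaults.items():
        p.add(name, val, provenance="literature")

    # feedback inhibition: acyl-ACP on ACCase and FA synthase; PEP on PFK;
    # NADPH on the oxidative PPP
    p.add("Ki_ACCp_SCFA", 0.02, provenance="literature")
    p.add("n_ACCp_SCFA", 3.0, bounds=(1.0, 4.0), provenance="default")
    p.add("Ki_FAS_SCFA", 0.02, provenance="literature")
    p.add("n_FAS_SCFA", 3.0, bounds=(1.0, 4.0), provenance="default")
    p.add("Ki_HK_HP", 0.5, provenance="literature")
    p.add("n_HK_HP", 2.0, bounds=(1.0, 4.0), provenance="default")
    p.add("Ki_PFK_PEP", 1.0, provenance="literature")
    p.add("n_PFK_PEP", 2.0, bounds=(1.0, 4.0), provenance="default")
    p.add("Ki_PPP_NADPH", 0.15, provenance="literature")
    p.add("Ki_FAX_FFA", 0.15, provenance="default")
    p.add("n_FAX_FFA", 1.0, bounds=(1.0, 4.0), provenance="default")
    p.add("Ki_PKp_PYR", 0.1, provenance="default")
    p.add("n_PKp_PYR", 1.0, bounds=(1.0, 4.0), provenance="default")
    p.add("Ki_PDHp_ACA", 0.1, provenance="default")
    p.add("n_PDHp_ACA", 1.0, bounds=(1.0, 4.0), provenance="default")
    p.add("Ki_PEPT_PEP", 1.0, provenance="default")
    p.add("n_PEPT_PEP", 1.0, bounds=(1.0, 4.0), provenance="default")
    p.add("Ki_PYRT_PYR", 0.2, provenance="default")
    p.add("n_PYRT_PYR", 1.0, bounds=(1.0, 4.0), provenance="default")
    p.add("Ki_RUB_PEP", 10.0, provenance="default")
    p.add("n_RUB_PEP", 1.0, bounds=(1.0, 4.0), provenance="default")
    p.add("Ki_PDHm_ACA", 0.2, provenance="default")
    p.add("n_PDHm_ACA", 1.0, bounds=(1.0, 4.0), provenance="default")
    p.add("Ki_ACCp_MALACP", 0.2, provenance="default")
    p.add("n_ACCp_MALACP", 1.0, bounds=(1.0, 4.0), provenance="default")
    p.add("Ki_CITT_CIT", 0.1, provenance="default")
    p.add("n_CITT_CIT", 1.0, bounds=(1.0, 4.0), provenance="default")
    p.add("n_PYRT_PYR", 1.0, bounds=(1.0, 4.0), provenance="default")
    p.add("n_PPP_NADPH", 2.0, bounds=(1.0, 4.0), provenance="default")

    # reversible equilibria and rates
    p.add("Keq_SUS", 4.0, provenance="default")
    p.add("k_SUS", 0.03, provenance="fitted")
    p.add("Keq_GDH", 2.0, provenance="default")
    p.add("k_GDH", 0.05, provenance="fitted")
    p.add("Keq_AAT", 4.0, provenance="default")
    p.add("k_AAT", 0.02, provenance="fitted")

    # maintenance
    p.add("alpha_maint", 15.0, provenance="fitted")
    p.add("beta_maint", 0.2, provenance="fitted")

    # boundary / growth / pools
    p.add("conc_SUC_x", BOUNDARY_CONCENTRATIONS["SUC_x"], provenance="default")
    p.add("conc_ALA_x", BOUNDARY_CONCENTRATIONS["ALA_x"], provenance="default")
    p.add("mu_early", 0.025, provenance="literature")
    p.add("mu_mature", 0.0025, provenance="literature")
    p.add("t_mature_daf", 13.0, provenance="default")
    p.add("m_max", 1.0, provenance="default")
    p.add("total_adenylate", 1.5, provenance="default")
    p.add("total_nad", 0.6, provenance="default")
    p.add("total_nadp", 0.4, provenance="default")

    inh_accp = (("SCFA_p", "Ki_ACCp_SCFA", "n_ACCp_SCFA"),)
    inh_fas = (("SCFA_p", "Ki_FAS_SCFA", "n_FAS_SCFA"),)
    inh_pfk = (("PEP_c", "Ki_PFK_PEP", "n_PFK_PEP"),)
    inh_hk = (("HP_c", "Ki_HK_HP", "n_HK_HP"),)
    inh_ppp = (("NADPH", "Ki_PPP_NADPH", "n_PPP_NADPH"),)

    reactions = [
        Reaction("CWI", {"SUC_x": -1, "GLC_x": 2},
                 _mm("k_CWI", [("SUC_x", "Km_CWI_SUC")]), "CWI"),
        Reaction("GLCT", {"GLC_x": -1, "GLC_c": 1},
                 _mm("k_GLCT", [("GLC_x", "Km_GLCT_GLC")]), "GLCT"),
        Reaction(
            "SUS", {"GLC_c": -2, "SUC_c": 1},
            RateLawSpec(
                "reversible_mm", k="k_SUS",
                substrates=(("GLC_c", "Ka_SUS_GLC", 2.0),),
                products=(("SUC_c", "Kp_SUS_SUC", 1.0),),
                keq="Keq_SUS",
            ),
            "SUS", reversible=True,
        ),
        Reaction("HK", {"GLC_c": -1, "ATP": -1, "HP_c": 1, "ADP": 1},
                 RateLawSpec(
                     "michaelis_menten", k="k_HK",
                     substrates=(("GLC_c", "Km_HK_GLC", 1.0), ("ATP", "Km_ATP", 1.0)),
                     inhibitors=inh_hk,
                 ), "HK"),
        Reaction("STAS", {"HP_c": -1, "ATP": -1, "STA_c": 1, "ADP": 1},
                 _mm("k_STAS", [("HP_c", "Km_STAS_HP"), ("ATP", "Km_ATP")]),
                 "STAS"),
        Reaction("STAD", {"STA_c": -1, "GLC_c": 1},
                 _mm("k_STAD", [("STA_c", "Km_STAD_STA")]), "STAD"),
        Reaction("PFK", {"HP_c": -1, "ATP": -1, "TP_c": 2, "ADP": 1},
                 RateLawSpec(
                     "michaelis_menten", k="k_PFK",
                     substrates=(("HP_c", "Km_PFK_HP", 1.0), ("ATP", "Km_ATP", 1.0)),
                     inhibitors=inh_pfk,
                 ), "PFK"),
        Reaction("PGK", {"TP_c": -1, "ADP": -1, "NAD": -1,
                         "PEP_c": 1, "ATP": 1, "NADH": 1},
                 _mm("k_PGK", [("TP_c", "Km_PGK_TP"), ("ADP", "Km_ADP"),
                               ("NAD", "Km_NAD")]), "PGK"),
        Reaction("NPG", {"TP_c": -1, "NADP": -1, "PEP_c": 1, "NADPH": 1},
                 _mm("k_NPG", [("TP_c", "Km_NPG_TP"), ("NADP", "Km_NADP")]),
                 "NPG"),
        Reaction("PKc", {"PEP_c": -1, "ADP": -1, "PYR_c": 1, "ATP": 1},
                 _mm("k_PKc", [("PEP_c", "Km_PKc_PEP"), ("ADP", "Km_ADP")]),
                 "PKc"),
        Reaction("PPP", {"HP_c": -1, "NADP": -2, "R5P_c": 1, "NADPH": 2},
                 RateLawSpec(
                     "michaelis_menten", k="k_PPP",
                     substrates=(("HP_c", "Km_PPP_HP", 1.0), ("NADP", "Km_NADP", 1.0)),
                     inhibitors=inh_ppp,
                 ), "PPP"),
        Reaction("EPI", {"R5P_c": -3, "TP_c": 5},
                 _mm("k_EPI", [("R5P_c", "Km_EPI_R5P")]), "EPI"),
        Reaction("RUB", {"R5P_c": -1, "ATP": -1, "PEP_p": 2, "ADP": 1},
                 RateLawSpec(
                     "michaelis_menten", k="k_RUB",
                     substrates=(("R5P_c", "Km_RUB_R5P", 1.0), ("ATP", "Km_ATP", 1.0)),
                     inhibitors=(("PEP_p", "Ki_RUB_PEP", "n_RUB_PEP"),),
                 ), "RUB"),
        Reaction("PEPT", {"PEP_c": -1, "PEP_p": 1},
                 RateLawSpec(
                     "michaelis_menten", k="k_PEPT",
                     substrates=(("PEP_c", "Km_PEPT_PEP", 1.0),),
                     inhibitors=(("PEP_p", "Ki_PEPT_PEP", "n_PEPT_PEP"),),
                 ), "PEPT"),
        Reaction("PYRT", {"PYR_c": -1, "PYR_p": 1},
                 RateLawSpec(
                     "michaelis_menten", k="k_PYRT",
                     substrates=(("PYR_c", "Km_PYRT_PYR", 1.0),),
                     inhibitors=(("PYR_p", "Ki_PYRT_PYR", "n_PYRT_PYR"),),
                 ), "PYRT"),
        Reaction("PKp", {"PEP_p": -1, "ADP": -1, "PYR_p": 1, "ATP": 1},
                 RateLawSpec(
                     "michaelis_menten", k="k_PKp",
                     substrates=(("PEP_p", "Km_PKp_PEP", 1.0), ("ADP", "Km_ADP", 1.0)),
                     inhibitors=(("PYR_p", "Ki_PKp_PYR", "n_PKp_PYR"),),
                 ), "PKp"),
        Reaction("PDHp", {"PYR_p": -1, "NAD": -1, "ACA_p": 1, "NADH": 1},
                 RateLawSpec(
                     "michaelis_menten", k="k_PDHp",
                     substrates=(("PYR_p", "Km_PDHp_PYR", 1.0), ("NAD", "Km_NAD", 1.0)),
                     inhibitors=(("ACA_p", "Ki_PDHp_ACA", "n_PDHp_ACA"),),
                 ), "PDHp"),
        Reaction("ACCp", {"ACA_p": -1, "ATP": -1, "MALACP_p": 1, "ADP": 1},
                 RateLawSpec(
                     "michaelis_menten", k="k_ACCp",
                     substrates=(("ACA_p", "Km_ACCp_ACA", 1.0), ("ATP", "Km_ATP", 1.0)),
                     inhibitors=inh_accp
                     + (("MALACP_p", "Ki_ACCp_MALACP", "n_ACCp_MALACP"),),
                 ), "ACCp"),
        Reaction("FAS", {"MALACP_p": -8, "NADPH": -7, "NADH": -7,
                         "SCFA_p": 1, "NADP": 7, "NAD": 7},
                 RateLawSpec(
                     "michaelis_menten", k="k_FAS",
                     substrates=(("MALACP_p", "Km_FAS_MALACP", 1.0),
                                 ("NADPH", "Km_NADPH", 1.0),
                                 ("NADH", "Km_rNADH", 1.0)),
                     inhibitors=inh_fas,
                 ), "FAS"),
        Reaction("FAX", {"SCFA_p": -1, "FFA_c": 1},
                 RateLawSpec(
                     "michaelis_menten", k="k_FAX",
                     substrates=(("SCFA_p", "Km_FAX_SCFA", 1.0),),
                     inhibitors=(("FFA_c", "Ki_FAX_FFA", "n_FAX_FFA"),),
                 ), "FAX"),
        Reaction("ACCc", {"ACA_c": -1, "ATP": -1, "MALCOA_c": 1, "ADP": 1},
                 _mm("k_ACCc", [("ACA_c", "Km_ACCc_ACA"), ("ATP", "Km_ATP")]),
                 "ACCc"),
        Reaction("FAE", {"FFA_c": -1, "MALCOA_c": -1, "NADPH": -2,
                         "VLCFA_c": 1, "NADP": 2},
                 _mm("k_FAE", [("FFA_c", "Km_FAE_FFA"),
                               ("MALCOA_c", "Km_FAE_MALCOA"),
                               ("NADPH", "Km_NADPH")]), "FAE"),
        Reaction("TAGS", {"TP_c": -1, "FFA_c": -3, "ATP": -1,
                          "TAG_c": 1, "ADP": 1},
                 _mm("k_TAGS", [("TP_c", "Km_TAGS_TP"), ("FFA_c", "Km_TAGS_FFA"),
                                ("VLCFA_c", "Km_TAGS_VLCFA"),
                                ("ATP", "Km_ATP")]), "TAGS"),
        Reaction("TAGOX", {"TAG_c": -1, "NAD": -12, "ACA_m": 12, "NADH": 12,
                           "TP_c": 1},
                 _mm("k_TAGOX", [("TAG_c", "Km_TAGOX_TAG"),
                                 ("NAD", "Km_NAD")]), "TAGOX"),
        Reaction("PDHm", {"PYR_c": -1, "NAD": -1, "ACA_m": 1, "NADH": 1},
                 RateLawSpec(
                     "michaelis_menten", k="k_PDHm",
                     substrates=(("PYR_c", "Km_PDHm_PYR", 1.0), ("NAD", "Km_NAD", 1.0)),
                     inhibitors=(("ACA_m", "Ki_PDHm_ACA", "n_PDHm_ACA"),),
                 ), "PDHm"),
        Reaction("CS", {"ACA_m": -1, "MAL_m": -1, "NAD": -1, "CIT_m": 1, "NADH": 1},
                 _mm("k_CS", [("ACA_m", "Km_CS_ACA"), ("MAL_m", "Km_CS_MAL"),
                              ("NAD", "Km_NAD")]), "CS"),
        Reaction("IDH", {"CIT_m": -1, "NAD": -1, "AKG_m": 1, "NADH": 1},
                 _mm("k_IDH", [("CIT_m", "Km_IDH_CIT"), ("NAD", "Km_NAD")]),
                 "IDH"),
        Reaction("AKGDH", {"AKG_m": -1, "NAD": -2, "ADP": -1,
                           "MAL_m": 1, "NADH": 2, "ATP": 1},
                 _mm("k_AKGDH", [("AKG_m", "Km_AKGDH_AKG"),
                                 ("NAD", "Km_NAD"),
                                 ("ADP", "Km_ADP")]), "AKGDH"),
        Reaction("PEPC", {"PEP_c": -1, "NADH": -1, "MAL_m": 1, "NAD": 1},
                 _mm("k_PEPC", [("PEP_c", "Km_PEPC_PEP"), ("NADH", "Km_rNADH")]),
                 "PEPC"),
        Reaction("ME", {"MAL_m": -1, "NADP": -1, "PYR_c": 1, "NADPH": 1},
                 _mm("k_ME", [("MAL_m", "Km_ME_MAL"), ("NADP", "Km_NADP")]),
                 "ME"),
        Reaction(
            "GDH", {"GLT_c": -1, "NAD": -1, "AKG_m": 1, "NADH": 1},
            RateLawSpec(
                "reversible_mm", k="k_GDH",
                substrates=(("GLT_c", "Ka_GDH_GLT", 1.0), ("NAD", "Ka_GDH_NAD", 1.0)),
                products=(("AKG_m", "Kp_GDH_AKG", 1.0), ("NADH", "Kp_GDH_NADH", 1.0)),
                keq="Keq_GDH",
            ),
            "GDH", reversible=True,
        ),
        Reaction(
            "AAT", {"ALA_x": -1, "AKG_m": -1, "PYR_c": 1, "GLT_c": 1},
            RateLawSpec(
                "reversible_mm", k="k_AAT",
                substrates=(("ALA_x", "Ka_AAT_ALA", 1.0), ("AKG_m", "Ka_AAT_AKG", 1.0)),
                products=(("PYR_c", "Kp_AAT_PYR", 1.0), ("GLT_c", "Kp_AAT_GLT", 1.0)),
                keq="Keq_AAT",
            ),
            "AAT", reversible=True,
        ),
        Reaction("ICL", {"CIT_m": -1, "ACA_m": -1, "MAL_m": 2},
                 _mm("k_ICL", [("CIT_m", "Km_ICL_CIT"), ("ACA_m", "Km_ICL_ACA")]),
                 "ICL"),
        Reaction("CITT", {"CIT_m": -1, "CIT_c": 1},
                 RateLawSpec(
                     "michaelis_menten", k="k_CITT",
                     substrates=(("CIT_m", "Km_CITT_CIT", 1.0),),
                     inhibitors=(("CIT_c", "Ki_CITT_CIT", "n_CITT_CIT"),),
                 ), "CITT"),
        Reaction("ACL", {"CIT_c": -1, "ATP": -1, "NADH": -1,
                         "ACA_c": 1, "MAL_m": 1, "ADP": 1, "NAD": 1},
                 _mm("k_ACL", [("CIT_c", "Km_ACL_CIT"), ("ATP", "Km_ATP"),
                               ("NADH", "Km_rNADH")]), "ACL"),
        Reaction("OXP", {"NADH": -1, "ADP": -2.5, "NAD": 1, "ATP": 2.5},
                 _mm("k_OXP", [("NADH", "Km_rNADH"), ("ADP", "Km_ADP")])),
        Reaction("LEAK", {"NADH": -1, "NAD": 1},
                 _mm("k_LEAK", [("NADH", "Km_rNADH")])),
        Reaction("OX", {"NADPH": -1, "NADP": 1},
                 _mm("k_OX", [("NADPH", "Km_rNADPH")])),
        Reaction("ATPM", {"ATP": -1, "ADP": 1},
                 RateLawSpec(
                     "constant_maintenance",
                     substrates=(("ATP", "Km_ATP", 1.0),),
                 )),
        Reaction("SPRTS", {"GLT_c": -2, "ATP": -4, "SPRT_c": 1, "ADP": 4},
                 RateLawSpec(
                     "mrna_proportional", k="k_SPRTS",
                     substrates=(("GLT_c", "Km_SPRTS_GLT", 1.0),
                                 ("ATP", "Km_ATP", 1.0)),
                     mrna_key="SPRT",
                 )),
    ]

    # solve rate constants from the reference flux map: k = v_ref / (E_ref * f)
    ref = REFERENCE_STATE
    for rxn in reactions:
        law = rxn.rate_law
        if law.k is not None and law.k in p:
            continue  # reversible rates set explicitly above
        if law.law_type == "constant_maintenance":
            continue
        v_ref = REFERENCE_FLUXES[rxn.id]
        f = 1.0
        for met, km, _ in law.substrates:
            s = ref[met]
            f *= s / (p.value(km) + s)
        for met, ki, n in law.inhibitors:
            f *= hill_inhibition(ref[met], p.value(ki), p.value(n))
        e_ref = REFERENCE_ENZYME_LEVEL if rxn.enzyme_id in MID_PEAK_ENZYMES else 1.0
        if rxn.enzyme_id is None and law.law_type != "mrna_proportional":
            e_ref = 1.0
        if law.law_type == "mrna_proportional":
            e_ref = REFERENCE_ENZYME_LEVEL  # reference mRNA level mid filling
        p.add(law.k, v_ref / (e_ref * f), provenance="fitted")

    growth = GrowthModel(
        mu_early=p.value("mu_early"),
        mu_mature=p.value("mu_mature"),
        t_mature_daf=p.value("t_mature_daf"),
        m_max=p.value("m_max"),
    )
    turnover = {e: DEFAULT_TURNOVER.get(e, "average")
                for r in reactions if r.enzyme_id for e in [r.enzyme_id]}
    model = MetabolicModel(
        metabolites=_default_metabolites(),
        reactions=reactions,
        parameters=p,
        growth=growth,
        enzyme_turnover=turnover,
    )
    model.validate()
    return model


def total_fa(state: Mapping[str, float] | np.ndarray,
             met_ids: Sequence[str] | None = None) -> float:
    """Total FA read-out: FFA + SCFA + elongated FA + 3*TAG."""
    if isinstance(state, np.ndarray):
        if met_ids is None:
            raise InputError("met_ids required with array state")
        state = dict(zip(met_ids, state))
    return float(sum(w * state[m] for m, w in FA_POOLS.items()))


# ---------------------------------------------------------------------------
# Config round-trip (YAML)
# ---------------------------------------------------------------------------


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "name": model.name,
        "metabolites": [
            {
                "id": m.id,
                "compartment": m.compartment,
                "initial_concentration": m.initial_concentration,
                "cofactor_pair_id": m.cofactor_pair_id,
                "clamped": m.clamped,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "enzyme_id": r.enzyme_id,
                "reversible": r.reversible,
                "rate_law": {
                    "law_type": r.rate_law.law_type,
                    "k": r.rate_law.k,
                    "substrates": [list(t) for t in r.rate_law.substrates],
                    "products": [list(t) for t in r.rate_law.products],
                    "keq": r.rate_law.keq,
                    "inhibitors": [list(t) for t in r.rate_law.inhibitors],
                    "mrna_key": r.rate_law.mrna_key,
                },
            }
            for r in model.reactions
        ],
        "parameters": {
            name: {
                "value": prm.value,
                "bounds": list(prm.bounds),
                "provenance": prm.provenance,
            }
            for name, prm in model.parameters.items()
        },
        "growth": {
            "mu_early": model.growth.mu_early,
            "mu_mature": model.growth.mu_mature,
            "t_mature_daf": model.growth.t_mature_daf,
            "m_max": model.growth.m_max,
        },
        "enzyme_turnover": dict(model.enzyme_turnover),
    }


def model_from_dict(data: dict) -> MetabolicModel:
    params = ParameterSet()
    for name, d in data["parameters"].items():
        params[name] = Parameter(
            float(d["value"]),
            (float(d["bounds"][0]), float(d["bounds"][1])),
            d.get("provenance", "default"),
        )
    model = MetabolicModel(
        metabolites=[
            Metabolite(
                m["id"], m["compartment"], float(m["initial_concentration"]),
                m.get("cofactor_pair_id"), bool(m.get("clamped", False)),
            )
            for m in data["metabolites"]
        ],
        reactions=[
            Reaction(
                r["id"], {k: float(v) for k, v in r["stoichiometry"].items()},
                RateLawSpec(
                    r["rate_law"]["law_type"],
                    k=r["rate_law"].get("k"),
                    substrates=tuple(
                        (s[0], s[1], float(s[2]))
                        for s in r["rate_law"].get("substrates", [])
                    ),
                    products=tuple(
                        (s[0], s[1], float(s[2]))
                        for s in r["rate_law"].get("products", [])
                    ),
                    keq=r["rate_law"].get("keq"),
                    inhibitors=tuple(
                        (s[0], s[1], s[2])
                        for s in r["rate_law"].get("inhibitors", [])
                    ),
                    mrna_key=r["rate_law"].get("mrna_key"),
                ),
                enzyme_id=r.get("enzyme_id"),
                reversible=bool(r.get("reversible", False)),
            )
            for r in data["reactions"]
        ],
        parameters=params,
        growth=GrowthModel(**data["growth"]),
        enzyme_turnover=dict(data["enzyme_turnover"]),
        name=data.get("name", "unnamed"),
    )
    model.validate()
    return model


def save_model(model: MetabolicModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> MetabolicModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
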