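"""Coupled expression + metabolism simulation over 0-21 DAF.

The enzyme layer is integrated first (each enzyme equation is linear in the
enzyme level and independent of the metabolic state), then the metabolic
ODE system dM/dt = S.v(M, E(t)) - mu(t).M is integrated with a stiff solver
and the physiological read-outs of interest are computed from the dense
trajectory: storage-product time courses, the hexose/sucrose ratio, the
plastidial vs cytosolic pyruvate-kinase flux split, the Rubisco-bypass
contribution to FA synthesis, the ATP/ADP energy charge, and the FA
turnover rate at maturity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .expression import (
    DEFAULT_STAGE_GRID,
    EnzymeTrajectories,
    HOURS_PER_DAY,
    InputError,
    StageGrid,
    enzyme_trajectories,
    interpolate_stage_profile,
    normalize_mrna,
    ribosome_signal,
)
from .network import CompiledModel, FA_POOLS, MetabolicModel

#: Default integration horizon, hours (21 days after fertilization).
T_END_HR = 21.0 * HOURS_PER_DAY

#: Denominator floor used when forming physiological ratios.
RATIO_FLOOR = 1e-9


class SimulationError(RuntimeError):
    """Stiff integration failed or produced out-of-range states."""


@dataclass
class ExpressionInputs:
    """Bundled expression-layer inputs for a simulation.

    ``normalized_profiles`` holds per-enzyme stage profiles (rows scaled to
    1 at stage one); ``sprt_profile`` is the storage-protein transcript
    pool driving v_sprt; ``rb_profile`` the ribosome proxy.
    """

    normalized_profiles: pd.DataFrame
    rb_profile: np.ndarray
    sprt_profile: np.ndarray
    grid: StageGrid = field(default_factory=lambda: DEFAULT_STAGE_GRID)
    #: multiplicative rate-scale overrides for reactions without an enzyme
    #: (used by the perturbation layer for maintenance reactions)
    rate_scales: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_atlas(
        cls,
        raw_intensities: pd.DataFrame,
        gene_to_enzyme: Mapping[str, str],
        ribosomal_gene_ids: list[str],
        grid: StageGrid = DEFAULT_STAGE_GRID,
        *,
        sprt_key: str = "SPRT",
    ) -> "ExpressionInputs":
        """Normalize a gene-level atlas into per-enzyme simulation inputs."""
        profiles = normalize_mrna(raw_intensities, gene_to_enzyme)
        rb = ribosome_signal(raw_intensities, ribosomal_gene_ids)
        if sprt_key in profiles.index:
            sprt = profiles.loc[sprt_key].to_numpy(dtype=float)
            profiles = profiles.drop(index=sprt_key)
        else:
            sprt = np.ones(7)
        return cls(profiles, rb.profile, sprt, grid)

    def copy(self) -> "ExpressionInputs":
        return ExpressionInputs(
            self.normalized_profiles.copy(),
            self.rb_profile.copy(),
            self.sprt_profile.copy(),
            self.grid,
            dict(self.rate_scales),
        )


@dataclass
class Trajectory:
    """Dense simulation output on an aligned time grid."""

    times_hr: np.ndarray
    met_ids: list[str]
    states: np.ndarray  # metabolites x times
    rxn_ids: list[str]
    fluxes: np.ndarray  # reactions x times
    enzyme_ids: list[str]
    enzymes: np.ndarray  # enzymes x times
    seed_mass: np.ndarray
    mu: np.ndarray

    @property
    def times_daf(self) -> np.ndarray:
        return self.times_hr / HOURS_PER_DAY

    def state(self, met_id: str) -> np.ndarray:
        return self.states[self.met_ids.index(met_id)]

    def flux(self, rxn_id: str) -> np.ndarray:
        return self.fluxes[self.rxn_ids.index(rxn_id)]

    def total_fa_series(self) -> np.ndarray:
        out = np.zeros_like(self.times_hr)
        for met, w in FA_POOLS.items():
            if met in self.met_ids:  # reduced models may lack some pools
                out += w * self.state(met)
        return out

    def at_daf(self, series: np.ndarray, t_daf: float) -> float:
        """Linear interpolation of any aligned series at a DAF time point."""
        return float(np.interp(t_daf, self.times_daf, series))

    def window_mask(self, lo_daf: float, hi_daf: float) -> np.ndarray:
        d = self.times_daf
        return (d >= lo_daf) & (d <= hi_daf)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame (time_daf, variable, value)."""
        daf = self.times_daf
        parts = []
        for ids, block, kind in (
            (self.met_ids, self.states, "state"),
            (self.rxn_ids, self.fluxes, "flux"),
            (self.enzyme_ids, self.enzymes, "enzyme"),
        ):
            for i, name in enumerate(ids):
                parts.append(
                    pd.DataFrame(
                        {
                            "time_daf": daf,
                            "variable": f"{kind}:{name}",
                            "value": block[i],
                        }
                    )
                )
        parts.append(
            pd.DataFrame(
                {"time_daf": daf, "variable": "seed_mass", "value": self.seed_mass}
            )
        )
        return pd.concat(parts, ignore_index=True)


def reference_expression(model: MetabolicModel) -> ExpressionInputs:
    """The canonical (noise-free) wild-type expression program for a model.

    Every enzyme follows its default shape class; the storage-protein
    transcript pool follows the late-up program.
    """
    from .synth import RB_PROFILE, reference_profiles

    profiles = reference_profiles(model.enzyme_ids + ["SPRT"])
    return ExpressionInputs(
        profiles.drop(index="SPRT"),
        RB_PROFILE.copy(),
        profiles.loc["SPRT"].to_numpy(dtype=float),
    )


def constant_enzymes(model: MetabolicModel, level: float = 1.0,
                     t_end_hr: float = T_END_HR) -> EnzymeTrajectories:
    """Flat enzyme inputs (useful for fixtures and analytic checks)."""
    ids = tuple(model.enzyme_ids)
    times = np.array([0.0, t_end_hr])
    return EnzymeTrajectories(ids, times, np.full((len(ids), 2), float(level)))


def simulate(
    model: MetabolicModel,
    expression: ExpressionInputs | EnzymeTrajectories,
    *,
    t_end_hr: float = T_END_HR,
    dt_out_daf: float = 0.1,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "LSODA",
    neg_floor: float = 1e-6,
    sprt_mrna_fn=None,
) -> Trajectory:
    """Integrate the coupled system and return a dense trajectory.

    ``expression`` may be full expression inputs (enzyme trajectories are
    derived via the enzyme ODE) or precomputed enzyme trajectories (then
    ``sprt_mrna_fn`` may supply the storage-protein transcript input).
    States dipping below ``-neg_floor`` abort with a diagnostic naming the
    first failing metabolite; smaller excursions are clamped inside the
    rate laws.
    """
    mu_fn = model.growth.mu

    if isinstance(expression, ExpressionInputs):
        profiles = expression.normalized_profiles
        missing = [e for e in model.enzyme_ids if e not in profiles.index]
        if missing:
            raise InputError(f"no expression profile for enzymes: {missing}")
        enz = enzyme_trajectories(
            profiles.loc[model.enzyme_ids],
            expression.rb_profile,
            model.enzyme_turnover,
            mu_fn,
            expression.grid,
            t_end_hr=t_end_hr,
        )
        sprt_pchip = interpolate_stage_profile(
            expression.sprt_profile, expression.grid
        )
        # dense linear lookup: the smooth interpolant is far too slow to
        # evaluate inside the ODE right-hand side
        sprt_t = np.linspace(0.0, t_end_hr, 512)
        sprt_v = np.asarray(sprt_pchip(sprt_t), dtype=float)

        def sprt_fn(t: float) -> float:
            return float(np.interp(t, sprt_t, sprt_v))

        rate_scales = expression.rate_scales
    else:
        enz = expression
        sprt_fn = sprt_mrna_fn or (lambda t: 1.0)
        rate_scales = {}

    compiled = CompiledModel(model)
    if rate_scales:
        for rxn_id, factor in rate_scales.items():
            compiled.k_vec[compiled.rxn_index[rxn_id]] *= factor
    order = [enz.enzyme_ids.index(e) for e in compiled.enzyme_ids]

    def enzyme_fn(t: float) -> np.ndarray:
        return enz(t)[order]

    rhs = compiled.rhs(enzyme_fn, mu_fn, {"SPRT": sprt_fn})
    y0 = model.initial_state()
    n_out = int(round(t_end_hr / (dt_out_daf * HOURS_PER_DAY))) + 1
    t_eval = np.linspace(0.0, t_end_hr, n_out)
    sol = solve_ivp(
        rhs, (0.0, t_end_hr), y0, method=method, t_eval=t_eval,
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"integration failed: {sol.message}")
    ymin = sol.y.min(axis=1)
    bad = np.nonzero(ymin < -neg_floor)[0]
    if len(bad):
        names = [model.metabolite_ids[i] for i in bad]
        raise SimulationError(
            f"negative excursion beyond -{neg_floor:g} for states {names} "
            f"(min {ymin[bad].min():.3g})"
        )
    states = np.maximum(sol.y, 0.0)

    mu_series = np.asarray(mu_fn(sol.t), dtype=float)
    enz_block = np.stack([enzyme_fn(t) for t in sol.t], axis=1)
    fluxes = np.stack(
        [
            compiled.fluxes(
                states[:, i], enz_block[:, i], mu=mu_series[i],
                mrna={"SPRT": float(sprt_fn(sol.t[i]))},
            )
            for i in range(len(sol.t))
        ],
        axis=1,
    )
    return Trajectory(
        times_hr=sol.t,
        met_ids=model.metabolite_ids,
        states=states,
        rxn_ids=compiled.rxn_ids,
        fluxes=fluxes,
        enzyme_ids=list(compiled.enzyme_ids),
        enzymes=enz_block,
        seed_mass=np.asarray(model.growth.mass(sol.t), dtype=float),
        mu=mu_series,
    )


# ---------------------------------------------------------------------------
# Physiological read-outs
# ---------------------------------------------------------------------------


@dataclass
class RatioReport:
    """Pointwise physiological ratios plus their peak locations (DAF)."""

    times_daf: np.ndarray
    hex_suc: np.ndarray
    pk_plastid_over_cytosol: np.ndarray
    rub_over_fab: np.ndarray
    atp_adp: np.ndarray
    hex_suc_peak_daf: float
    fab_window: tuple[float, float] = (7.0, 14.0)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    return num / np.maximum(den, RATIO_FLOOR)


def physiological_ratios(traj: Trajectory) -> RatioReport:
    """Hexose/sucrose, PKp/PKc flux, RUB/FA-synthesis flux and ATP/ADP.

    The hexose and sucrose pools are totals over the tissue, i.e. they
    include the apoplastic/maternal supply pools alongside the cytosolic
    ones (what a whole-embryo metabolite measurement reports).  Ratios
    whose species/reactions are absent (reduced models) come back as NaN
    series.
    """
    n = len(traj.times_hr)
    nan = np.full(n, np.nan)

    def state_sum(*mets):
        if all(m in traj.met_ids for m in mets):
            return sum(traj.state(m) for m in mets)
        return None

    def flux_ratio(num, den):
        if num in traj.rxn_ids and den in traj.rxn_ids:
            return _safe_ratio(traj.flux(num), traj.flux(den))
        return nan

    hexose = state_sum("GLC_c", "GLC_x")
    sucrose = state_sum("SUC_c", "SUC_x")
    hex_suc = _safe_ratio(hexose, sucrose) if hexose is not None and sucrose is not None else nan
    pk = flux_ratio("PKp", "PKc")
    rub_fab = flux_ratio("RUB", "FAS")
    adenylate = state_sum("ATP") , state_sum("ADP")
    atp_adp = (
        _safe_ratio(adenylate[0], adenylate[1])
        if adenylate[0] is not None and adenylate[1] is not None
        else nan
    )
    peak = (
        float(traj.times_daf[int(np.nanargmax(hex_suc))])
        if np.isfinite(hex_suc).any()
        else float("nan")
    )
    return RatioReport(
        times_daf=traj.times_daf,
        hex_suc=hex_suc,
        pk_plastid_over_cytosol=pk,
        rub_over_fab=rub_fab,
        atp_adp=atp_adp,
        hex_suc_peak_daf=peak,
    )


def fa_accumulation_peak_daf(traj: Trajectory) -> float:
    """DAF at which d(total FA)/dt is maximal."""
    fa = traj.total_fa_series()
    rate = np.gradient(fa, traj.times_hr)
    return float(traj.times_daf[int(np.argmax(rate))])


def fa_plateau_drift(traj: Trajectory, window: tuple[float, float] = (16.0, 19.0)
                     ) -> float:
    """Net relative drift of total FA across a window, fraction per day.

    Computed as |ln(FA(t1)/FA(t0))| / (t1 - t0): the pool is 'stable' over
    the window when its net change is small, even though synthesis,
    oxidation and growth dilution individually remain active.
    """
    t0, t1 = window
    if t1 <= t0:
        raise InputError("window must satisfy t0 < t1")
    if t0 < traj.times_daf[0] or t1 > traj.times_daf[-1]:
        raise InputError(f"window {window} outside the simulated span")
    fa = traj.total_fa_series()
    fa0 = max(traj.at_daf(fa, t0), RATIO_FLOOR)
    fa1 = max(traj.at_daf(fa, t1), RATIO_FLOOR)
    return float(abs(np.log(fa1 / fa0)) / (t1 - t0))


def fa_turnover(traj: Trajectory, window: tuple[float, float] = (16.0, 19.0)
                ) -> float:
    """FA turnover rate (d^-1) over a maturity window.

    Turnover = mean FA-degradation flux / mean total-FA pool.  TAG oxidation
    removes three acyl chains per TAG consumed, so the degradation flux in
    FA units is 3 * v_TAGOX.
    """
    mask = traj.window_mask(*window)
    if not mask.any():
        raise InputError(f"window {window} outside the simulated span")
    degradation = 3.0 * traj.flux("TAGOX")[mask]
    pool = traj.total_fa_series()[mask]
    return float(degradation.mean() / max(pool.mean(), RATIO_FLOOR) * HOURS_PER_DAY)


def cofactor_drift(traj: Trajectory) -> dict[str, float]:
    """Max relative drift of each conserved cofactor pair over the run."""
    out = {}
    for pair, members in (
        ("adenylate", ("ATP", "ADP")),
        ("nad_pool", ("NAD", "NADH")),
        ("nadp_pool", ("NADP", "NADPH")),
    ):
        if all(m in traj.met_ids for m in members):
            series = sum(traj.state(m) for m in members)
            out[pair] = float(np.abs(series / series[0] - 1.0).max())
    return out
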