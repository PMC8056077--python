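"""Transcript-to-enzyme dynamics.

Stage-resolved microarray intensities are turned into continuous enzyme-level
inputs for the kinetic metabolic model in three steps:

1.  Per-enzyme mRNA profiles: the intensities of all genes mapped to an enzyme
    are summed per stage and scaled by the first-stage sum, so every profile
    starts at 1 (relative units).
2.  A ribosome proxy ``Rb(t)``: the scaled weighted sum of ribosomal-gene
    intensities, Rb(0) = 1.
3.  One linear ODE per enzyme,

        dE/dt = k_syn * mRNA(t) * Rb(t) - (k_deg + mu(t)) * E,

    where synthesis tracks transcript abundance times translational capacity
    and the pool is lost to degradation (k_deg, = ln 2 / t_half) and to
    dilution by growth (mu).  Enzymes fall into three turnover classes
    (fast / average / slow); synthesis constants are balanced so that
    production and removal are at equilibrium early in development
    (k_syn = k_deg + mu0 with mu0 = 0.025 hr^-1).

Internal time unit is hours; stage positions are given in days after
fertilization (DAF, 1 DAF = 24 h).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator, interp1d

HOURS_PER_DAY = 24.0

#: Growth rate early in development (hr^-1), used to balance k_syn.
MU_EARLY = 0.025

#: Degradation rate constant (hr^-1) per turnover class.
TURNOVER_KDEG = {"fast": 0.03, "average": 0.02, "slow": 0.01}

#: Default intensity threshold above which a ribosomal gene gets weight 1.
RIBOSOME_INTENSITY_THRESHOLD = 2000.0

#: Pseudo-intensity added to every stage when a first-stage gene sum is zero.
ZERO_GUARD_EPSILON = 1.0

STAGE_NAMES = (
    "zygote",
    "octant",
    "globular",
    "heart",
    "torpedo",
    "bent",
    "mature",
)

#: Default stage -> DAF assignment (user-overridable through StageGrid).
DEFAULT_STAGE_DAF = (0.0, 1.0, 2.0, 4.0, 6.0, 10.0, 18.0)


class MappingError(ValueError):
    """An enzyme has no mapped genes (or a gene maps to no enzyme)."""


class InputError(ValueError):
    """Malformed numeric input (negative intensity, bad query time...)."""


class ConfigurationError(ValueError):
    """Unknown turnover class or otherwise inconsistent configuration."""


@dataclass(frozen=True)
class StageGrid:
    """The seven-stage developmental sampling grid.

    ``stage_times`` are in DAF; they must start at 0, increase strictly and
    stay within the 0-21 DAF simulation horizon.
    """

    stage_names: tuple[str, ...] = STAGE_NAMES
    stage_times: tuple[float, ...] = DEFAULT_STAGE_DAF

    def __post_init__(self) -> None:
        if len(self.stage_names) != 7 or len(self.stage_times) != 7:
            raise ConfigurationError(
                f"expected exactly 7 stages, got {len(self.stage_names)} names "
                f"and {len(self.stage_times)} times"
            )
        times = np.asarray(self.stage_times, dtype=float)
        if not np.all(np.diff(times) > 0):
            raise ConfigurationError("stage_times must be strictly increasing")
        if times[0] != 0.0:
            raise ConfigurationError("first stage time must be 0 DAF")
        if times[-1] > 21.0:
            raise ConfigurationError("last stage time must be <= 21 DAF")

    @property
    def times_hr(self) -> np.ndarray:
        return np.asarray(self.stage_times, dtype=float) * HOURS_PER_DAY

    @property
    def times_daf(self) -> np.ndarray:
        return np.asarray(self.stage_times, dtype=float)


DEFAULT_STAGE_GRID = StageGrid()


@dataclass(frozen=True)
class TurnoverClass:
    """A fast/average/slow enzyme turnover class with its rate constants."""

    label: str
    k_deg: float  # hr^-1
    k_syn: float  # hr^-1


def derive_rate_constants(class_label: str, mu0: float = MU_EARLY) -> TurnoverClass:
    """Return (k_deg, k_syn) for a turnover class.

    k_syn is balanced against removal at the early growth rate,
    k_syn = k_deg + mu0, so that a constitutively expressed enzyme sits at a
    steady level of 1 at the start of development.
    """
    if class_label not in TURNOVER_KDEG:
        raise ConfigurationError(
            f"unknown turnover class {class_label!r}; "
            f"expected one of {sorted(TURNOVER_KDEG)}"
        )
    if mu0 <= 0:
        raise ConfigurationError(f"mu0 must be > 0, got {mu0}")
    k_deg = TURNOVER_KDEG[class_label]
    return TurnoverClass(class_label, k_deg, k_deg + mu0)


def kdeg_from_half_life(t_half_hr: float) -> float:
    """Degradation rate constant from protein half-life, k_deg = ln2 / t_half."""
    if t_half_hr <= 0:
        raise InputError(f"half-life must be > 0, got {t_half_hr}")
    return float(np.log(2.0) / t_half_hr)


# ---------------------------------------------------------------------------
# mRNA normalization and the ribosome proxy
# ---------------------------------------------------------------------------


def normalize_mrna(
    raw_intensities: pd.DataFrame,
    gene_to_enzyme: Mapping[str, str],
    *,
    zero_guard: float = ZERO_GUARD_EPSILON,
) -> pd.DataFrame:
    """Per-enzyme normalized expression profiles (enzymes x stages).

    For each enzyme the intensities of its genes are summed stage-wise and the
    series is divided by its first-stage value, so profiles are dimensionless
    and equal 1 at the first stage.  If a first-stage sum is zero, a
    pseudo-intensity ``zero_guard`` is added at every stage and a warning is
    emitted.

    Parameters
    ----------
    raw_intensities
        Genes x stages matrix of nonnegative microarray intensities.
    gene_to_enzyme
        Many-to-one map from gene IDs (rows of ``raw_intensities``) to enzyme
        IDs.  Genes absent from the matrix raise a mapping error; matrix rows
        without a mapping are ignored (e.g. ribosomal genes).
    """
    values = raw_intensities.to_numpy(dtype=float)
    if np.any(values < 0):
        bad = raw_intensities.index[np.any(values < 0, axis=1)].tolist()
        raise InputError(f"negative intensities for genes: {bad[:5]}")

    enzyme_genes: dict[str, list[str]] = {}
    for gene, enzyme in gene_to_enzyme.items():
        if gene not in raw_intensities.index:
            raise MappingError(f"mapped gene {gene!r} not present in the matrix")
        enzyme_genes.setdefault(enzyme, []).append(gene)
    if not enzyme_genes:
        raise MappingError("gene_to_enzyme mapping is empty")

    profiles = {}
    for enzyme, genes in enzyme_genes.items():
        total = raw_intensities.loc[genes].sum(axis=0).to_numpy(dtype=float)
        if total[0] == 0.0:
            warnings.warn(
                f"enzyme {enzyme!r} has a zero first-stage intensity sum; "
                f"adding pseudo-intensity {zero_guard} to all stages",
                UserWarning,
                stacklevel=2,
            )
            total = total + zero_guard
        profiles[enzyme] = total / total[0]
    out = pd.DataFrame.from_dict(profiles, orient="index", dtype=float)
    out.columns = raw_intensities.columns
    return out.sort_index()


@dataclass(frozen=True)
class RibosomeSignal:
    """Scaled weighted ribosomal-gene signal; profile[0] == 1."""

    profile: np.ndarray
    gene_weights: Mapping[str, float]


def ribosome_signal(
    raw_intensities: pd.DataFrame,
    ribosomal_gene_ids: Sequence[str],
    weights: Sequence[float] | None = None,
    *,
    intensity_threshold: float = RIBOSOME_INTENSITY_THRESHOLD,
) -> RibosomeSignal:
    """Ribosome abundance proxy Rb over stages, scaled so Rb(stage 1) = 1.

    With ``weights=None`` each ribosomal gene whose mean intensity is at or
    above ``intensity_threshold`` gets weight 1 and the rest get 0 (the bulk
    of ribosomal transcripts sit above that level on the microarray scale
    used here; the weighting is fully overridable).
    """
    ids = list(ribosomal_gene_ids)
    if not ids:
        raise InputError("ribosomal gene list is empty")
    missing = [g for g in ids if g not in raw_intensities.index]
    if missing:
        raise MappingError(f"ribosomal genes not in matrix: {missing[:5]}")
    sub = raw_intensities.loc[ids].to_numpy(dtype=float)
    if np.any(sub < 0):
        raise InputError("negative ribosomal intensities")

    if weights is None:
        w = (sub.mean(axis=1) >= intensity_threshold).astype(float)
        if w.sum() == 0:  # fall back to equal weights rather than a 0/0 signal
            warnings.warn(
                "no ribosomal gene reaches the intensity threshold; "
                "using equal weights",
                UserWarning,
                stacklevel=2,
            )
            w = np.ones(len(ids))
    else:
        w = np.asarray(list(weights), dtype=float)
        if len(w) != len(ids):
            raise InputError("weights must match the ribosomal gene list")
        if np.any(w < 0):
            raise InputError("ribosome weights must be nonnegative")
        if w.sum() == 0:
            raise InputError("at least one ribosome weight must be positive")

    series = w @ sub
    if series[0] == 0:
        raise InputError("weighted ribosomal signal is zero at the first stage")
    return RibosomeSignal(profile=series / series[0], gene_weights=dict(zip(ids, w)))


# ---------------------------------------------------------------------------
# Stage-profile interpolation
# ---------------------------------------------------------------------------


def interpolate_stage_profile(
    profile: Sequence[float],
    grid: StageGrid = DEFAULT_STAGE_GRID,
    *,
    kind: str = "pchip",
) -> Callable[[np.ndarray], np.ndarray]:
    """Continuous-time input function from a 7-stage profile.

    Shape-preserving monotone piecewise-cubic interpolation by default
    (``kind="pchip"``; never overshoots below 0 for nonnegative knots),
    ``kind="linear"`` as an option.  Constant extrapolation beyond the last
    stage; query times must be >= 0 (hours).
    """
    y = np.asarray(profile, dtype=float)
    if y.shape != (7,):
        raise InputError(f"profile must have 7 stage values, got shape {y.shape}")
    t = grid.times_hr
    if kind == "pchip":
        interp = PchipInterpolator(t, y, extrapolate=False)
    elif kind == "linear":
        interp = interp1d(t, y, kind="linear", bounds_error=False)
    else:
        raise ConfigurationError(f"unknown interpolation kind {kind!r}")
    t_last, y_last = t[-1], y[-1]

    def fn(query: np.ndarray | float) -> np.ndarray | float:
        q = np.asarray(query, dtype=float)
        if np.any(q < 0):
            raise InputError("query times must be >= 0")
        out = np.asarray(interp(np.minimum(q, t_last)), dtype=float)
        out = np.where(q > t_last, y_last, out)
        out = np.maximum(out, 0.0)
        return out if out.ndim else float(out)

    return fn


# ---------------------------------------------------------------------------
# Enzyme ODE
# ---------------------------------------------------------------------------


def simulate_enzyme(
    e0: float,
    mrna_fn: Callable[[float], float],
    rb_fn: Callable[[float], float],
    k_syn: float,
    k_deg: float,
    mu_fn: Callable[[float], float],
    t_span: tuple[float, float],
    t_eval: np.ndarray | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate dE/dt = k_syn*mRNA(t)*Rb(t) - (k_deg + mu(t))*E.

    Returns ``(t, E)``.  Times in hours.
    """
    if k_syn <= 0 or k_deg <= 0:
        raise ConfigurationError("rate constants must be > 0")

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return k_syn * mrna_fn(t) * rb_fn(t) - (k_deg + mu_fn(t)) * y

    sol = solve_ivp(
        rhs, t_span, [float(e0)], method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise RuntimeError(f"enzyme ODE integration failed: {sol.message}")
    return sol.t, np.maximum(sol.y[0], 0.0)


@dataclass
class EnzymeTrajectories:
    """Dense enzyme levels for a set of enzymes on a shared time grid (hours).

    ``__call__`` evaluates all enzyme levels at one time point by linear
    interpolation on the dense grid (constant beyond the last point), in the
    row order of ``enzyme_ids``.
    """

    enzyme_ids: tuple[str, ...]
    times_hr: np.ndarray
    levels: np.ndarray  # enzymes x times
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.levels.shape != (len(self.enzyme_ids), len(self.times_hr)):
            raise ConfigurationError("levels must be enzymes x times")
        self._index = {e: i for i, e in enumerate(self.enzyme_ids)}

    def __call__(self, t: float) -> np.ndarray:
        ts = self.times_hr
        t = min(max(t, ts[0]), ts[-1])
        j = int(np.searchsorted(ts, t, side="right") - 1)
        j = min(j, len(ts) - 2)
        w = (t - ts[j]) / (ts[j + 1] - ts[j])
        return (1.0 - w) * self.levels[:, j] + w * self.levels[:, j + 1]

    def level(self, enzyme_id: str) -> np.ndarray:
        return self.levels[self._index[enzyme_id]]

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame (time_hr, enzyme_id, level)."""
        frames = []
        for i, enz in enumerate(self.enzyme_ids):
            frames.append(
                pd.DataFrame(
                    {
                        "time_hr": self.times_hr,
                        "enzyme_id": enz,
                        "level": self.levels[i],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def enzyme_trajectories(
    normalized_profiles: pd.DataFrame,
    rb_profile: np.ndarray,
    turnover: Mapping[str, str],
    mu_fn: Callable[[float], float],
    grid: StageGrid = DEFAULT_STAGE_GRID,
    *,
    t_end_hr: float = 21.0 * HOURS_PER_DAY,
    dt_hr: float = 1.0,
    mu0: float = MU_EARLY,
    interp_kind: str = "pchip",
) -> EnzymeTrajectories:
    """Solve the enzyme ODE for every enzyme in ``normalized_profiles``.

    All enzyme equations share the dense output grid; because each equation is
    linear and scalar they are integrated together as one diagonal system.
    Initial levels are the steady states under first-stage inputs,
    E(0) = k_syn*mRNA(0)*Rb(0) / (k_deg + mu0) (production and removal are at
    equilibrium at the start of development).

    ``turnover`` maps enzyme IDs to class labels; enzymes without an entry
    fall back to the ``average`` class.
    """
    enzymes = tuple(normalized_profiles.index)
    mrna_fns = [
        interpolate_stage_profile(normalized_profiles.loc[e], grid, kind=interp_kind)
        for e in enzymes
    ]
    rb_fn = interpolate_stage_profile(rb_profile, grid, kind=interp_kind)
    classes = [derive_rate_constants(turnover.get(e, "average"), mu0) for e in enzymes]
    k_syn = np.array([c.k_syn for c in classes])
    k_deg = np.array([c.k_deg for c in classes])

    e0 = k_syn * np.array([fn(0.0) for fn in mrna_fns]) * rb_fn(0.0) / (k_deg + mu0)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        mrna = np.array([fn(t) for fn in mrna_fns])
        return k_syn * mrna * rb_fn(t) - (k_deg + mu_fn(t)) * y

    t_eval = np.arange(0.0, t_end_hr + 0.5 * dt_hr, dt_hr)
    sol = solve_ivp(
        rhs, (0.0, t_end_hr), e0, method="LSODA", t_eval=t_eval, rtol=1e-8, atol=1e-10
    )
    if not sol.success:
        raise RuntimeError(f"enzyme ODE integration failed: {sol.message}")
    return EnzymeTrajectories(
        enzyme_ids=enzymes, times_hr=sol.t, levels=np.maximum(sol.y, 0.0)
    )
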