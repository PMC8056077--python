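"""Synthetic expression atlases, observations and a desk-scale fixture.

The real study conditions pair a 7-stage embryo microarray atlas with
metabolite time courses.  This module generates structurally equivalent
stand-ins so the whole pipeline is testable offline:

* a shape library of stage profiles (early transient, mid-window peak for
  the oil-filling program active ~7-14 DAF, late up/down, flat);
* a gene-level mRNA atlas (1-3 genes per enzyme plus a ~200-gene ribosomal
  block, most of it above the expression threshold);
* noisy pseudo-observations of the storage products (4 biological
  replicates, multiplicative log-normal noise);
* a reduced fixture network used as an analytically tractable oracle for
  integrator and parameter-recovery tests.

All generators take explicit integer seeds and are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import (
    DEFAULT_STAGE_GRID,
    StageGrid,
    ConfigurationError,
)
from .network import (
    GrowthModel,
    MetabolicModel,
    Metabolite,
    ParameterSet,
    RateLawSpec,
    Reaction,
    MID_PEAK_ENZYMES,
)

#: Stage-profile templates (multiplicative, relative to the first stage).
#: Stages sit at 0, 1, 2, 4, 6, 10, 18 DAF on the default grid, so the
#: mid_peak template (maximum at the bent stage, 10 DAF) interpolates to a
#: peak inside the 7-14 DAF oil-filling window.
SHAPE_TEMPLATES = {
    "flat": np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]),
    "early_transient": np.array([1.0, 2.5, 3.0, 2.0, 1.0, 0.5, 0.3]),
    "mid_peak": np.array([1.0, 1.0, 1.5, 3.0, 5.0, 6.0, 0.1]),
    "late_up": np.array([1.0, 1.0, 1.0, 1.2, 1.8, 5.0, 8.0]),
    "late_down": np.array([1.0, 1.0, 0.9, 0.8, 0.6, 0.4, 0.2]),
}

#: Canonical ribosome-proxy profile (translation capacity eases off late).
RB_PROFILE = np.array([1.0, 1.0, 1.05, 1.1, 1.0, 0.9, 0.7])

#: Default expression-program assignment for the reference model's enzymes
#: and the storage-protein transcript pool.  Enzymes not listed are 'flat'.
DEFAULT_SHAPE_ASSIGNMENT = {
    **{e: "mid_peak" for e in MID_PEAK_ENZYMES},
    "STAS": "early_transient",
    "STAD": "late_up",
    "SUS": "late_up",
    "SPRT": "late_up",
}

N_RIBOSOMAL_GENES = 200
RIBOSOMAL_MEDIAN_INTENSITY = 6000.0
RIBOSOMAL_LOG_SIGMA = 1.6


def shape_profile(name: str) -> np.ndarray:
    try:
        return SHAPE_TEMPLATES[name].copy()
    except KeyError:
        raise ConfigurationError(f"unknown shape {name!r}") from None


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal noise with a given coefficient of variation."""

    cv: float = 0.15
    replicates: int = 4

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ConfigurationError("CV must be >= 0")
        if self.replicates < 1:
            raise ConfigurationError("need >= 1 replicate")

    def sample(self, truth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Replicates x truth.shape draws with E[sample] = truth."""
        truth = np.asarray(truth, dtype=float)
        if self.cv == 0:
            return np.broadcast_to(truth, (self.replicates, *truth.shape)).copy()
        sigma = np.sqrt(np.log1p(self.cv**2))
        factors = rng.lognormal(
            mean=-0.5 * sigma**2, sigma=sigma, size=(self.replicates, *truth.shape)
        )
        return truth * factors


def generate_mrna_atlas(
    seed: int,
    enzyme_list: list[str],
    shape_assignment: dict[str, str] | None = None,
    *,
    grid: StageGrid = DEFAULT_STAGE_GRID,
    gene_noise_cv: float = 0.1,
    basal_median: float = 1000.0,
) -> tuple[pd.DataFrame, dict[str, str], list[str]]:
    """Gene-level intensity matrix emulating the embryo microarray atlas.

    Each enzyme gets 1-3 genes whose stage profiles follow the enzyme's
    assigned shape times gene-specific basal intensity and multiplicative
    noise, plus a ribosomal block of ~200 genes (flat-ish, most above the
    2000-intensity threshold).

    Returns ``(raw_intensities, gene_to_enzyme, ribosomal_gene_ids)``.
    """
    shapes = dict(DEFAULT_SHAPE_ASSIGNMENT)
    if shape_assignment:
        shapes.update(shape_assignment)
    missing = [e for e in enzyme_list if e not in shapes]
    for e in missing:  # unlisted enzymes default to the flat program
        shapes[e] = "flat"

    rng = np.random.default_rng(seed)
    noise = NoiseModel(cv=gene_noise_cv, replicates=1)
    rows: dict[str, np.ndarray] = {}
    gene_to_enzyme: dict[str, str] = {}
    for enz in enzyme_list:
        template = shape_profile(shapes[enz])
        n_genes = int(rng.integers(1, 4))
        for g in range(n_genes):
            basal = rng.lognormal(np.log(basal_median), 0.5)
            profile = noise.sample(basal * template, rng)[0]
            gene = f"{enz}_g{g + 1}"
            rows[gene] = np.maximum(profile, 0.0)
            gene_to_enzyme[gene] = enz

    ribosomal: list[str] = []
    for i in range(N_RIBOSOMAL_GENES):
        basal = rng.lognormal(
            np.log(RIBOSOMAL_MEDIAN_INTENSITY), RIBOSOMAL_LOG_SIGMA
        )
        profile = noise.sample(basal * RB_PROFILE, rng)[0]
        gene = f"RPG{i + 1:03d}"
        rows[gene] = np.maximum(profile, 0.0)
        ribosomal.append(gene)

    atlas = pd.DataFrame.from_dict(rows, orient="index")
    atlas.columns = list(grid.stage_names)
    return atlas, gene_to_enzyme, ribosomal


def reference_profiles(
    enzyme_list: list[str],
    shape_assignment: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Noise-free canonical normalized profiles (enzymes x 7 stages).

    This is the deterministic wild-type expression program used for the
    reference simulation; templates are already scaled to 1 at stage 1.
    """
    shapes = dict(DEFAULT_SHAPE_ASSIGNMENT)
    if shape_assignment:
        shapes.update(shape_assignment)
    data = {e: shape_profile(shapes.get(e, "flat")) for e in enzyme_list}
    out = pd.DataFrame.from_dict(data, orient="index")
    out.columns = list(DEFAULT_STAGE_GRID.stage_names)
    return out


def generate_observations(
    truth: pd.DataFrame,
    noise_model: NoiseModel,
    seed: int,
    *,
    grid: StageGrid = DEFAULT_STAGE_GRID,
) -> pd.DataFrame:
    """Noisy stage-sampled pseudo-observations from a truth table.

    ``truth`` is observables x stages (values at the 7 stage times).
    Returns a tidy frame (observable, time_daf, replicate, value).
    """
    rng = np.random.default_rng(seed)
    records = []
    times = grid.times_daf
    for obs in truth.index:
        samples = noise_model.sample(truth.loc[obs].to_numpy(dtype=float), rng)
        for rep in range(noise_model.replicates):
            for t, val in zip(times, samples[rep]):
                records.append(
                    {
                        "observable": obs,
                        "time_daf": float(t),
                        "replicate": rep + 1,
                        "value": float(val),
                    }
                )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Fixture network
# ---------------------------------------------------------------------------


def fixture_model() -> MetabolicModel:
    """Reduced oracle network: 8 metabolites, 10 reactions.

    A substrate-uptake chain A -> B -> C -> P with one branch (B -> Q), one
    Hill feedback (P inhibits B -> C), an adenylate pair and simple sinks.
    Steady states are tractable by hand, which makes the fixture the
    reference for integrator cross-checks and parameter-recovery tests.
    """
    p = ParameterSet()
    p.add("k_UPT", 0.2, provenance="default")
    p.add("Km_UPT_S", 1.0)
    p.add("k_OVF", 0.02)
    p.add("k_R1", 0.5)
    p.add("Km_R1_A", 0.5)
    p.add("Km_R1_ATP", 0.2)
    p.add("k_R2", 0.6)
    p.add("Km_R2_B", 0.5)
    p.add("Ki_R2_P", 1.0)
    p.add("n_R2_P", 2.0, bounds=(1.0, 4.0))
    p.add("k_R3", 0.8)
    p.add("Km_R3_C", 0.5)
    p.add("k_R4", 0.1)
    p.add("Km_R4_B", 0.5)
    p.add("k_QS", 0.3)
    p.add("Km_QS_Q", 0.5)
    p.add("k_PS", 0.15)
    p.add("Km_PS_P", 0.5)
    p.add("k_REG", 1.0)
    p.add("alpha_maint", 1.0)
    p.add("beta_maint", 0.05)
    p.add("Km_PM_ATP", 0.2)

    mets = [
        Metabolite("S_x", "external", 2.0, clamped=True),
        Metabolite("A", "cytosol", 0.5),
        Metabolite("B", "cytosol", 0.3),
        Metabolite("C", "cytosol", 0.2),
        Metabolite("P", "cytosol", 0.1),
        Metabolite("Q", "cytosol", 0.1),
        Metabolite("ATP", "cytosol", 1.0, "adenylate"),
        Metabolite("ADP", "cytosol", 0.5, "adenylate"),
    ]

    def mm(k, subs, inhibitors=()):
        return RateLawSpec(
            "michaelis_menten",
            k=k,
            substrates=tuple((m, km, 1.0) for m, km in subs),
            inhibitors=tuple(inhibitors),
        )

    rxns = [
        Reaction("UPT", {"S_x": -1, "A": 1}, mm("k_UPT", [("S_x", "Km_UPT_S")]),
                 "UPT"),
        Reaction("OVF", {"A": -1},
                 RateLawSpec("mass_action", k="k_OVF",
                             substrates=(("A", "Km_UPT_S", 1.0),)), "OVF"),
        Reaction("R1", {"A": -1, "ATP": -1, "B": 1, "ADP": 1},
                 mm("k_R1", [("A", "Km_R1_A"), ("ATP", "Km_R1_ATP")]), "E1"),
        Reaction("R2", {"B": -1, "C": 1},
                 mm("k_R2", [("B", "Km_R2_B")],
                    inhibitors=(("P", "Ki_R2_P", "n_R2_P"),)), "E2"),
        Reaction("R3", {"C": -1, "P": 1}, mm("k_R3", [("C", "Km_R3_C")]), "E3"),
        Reaction("R4", {"B": -1, "Q": 1}, mm("k_R4", [("B", "Km_R4_B")]), "E4"),
        Reaction("QS", {"Q": -1}, mm("k_QS", [("Q", "Km_QS_Q")]), "E5"),
        Reaction("PS", {"P": -1}, mm("k_PS", [("P", "Km_PS_P")]), "E6"),
        Reaction("REG", {"ADP": -1, "ATP": 1},
                 RateLawSpec("mass_action", k="k_REG",
                             substrates=(("ADP", "Km_PM_ATP", 1.0),))),
        Reaction("PM", {"ATP": -1, "ADP": 1},
                 RateLawSpec("constant_maintenance",
                             substrates=(("ATP", "Km_PM_ATP", 1.0),))),
    ]
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        parameters=p,
        growth=GrowthModel(),
        enzyme_turnover={e: "average" for e in ("UPT", "OVF", "E1", "E2", "E3",
                                                "E4", "E5", "E6")},
        name="seedflux-fixture",
    )
    model.validate()
    return model
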