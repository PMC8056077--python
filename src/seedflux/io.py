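"""File readers/writers, run configuration and the pipeline driver.

Formats are plain text and pinned: expression matrices are tab-separated
(UTF-8, '.' decimal), everything else comma-separated; numbers are written
with 9 significant digits so write -> read round-trips are lossless at
output precision.  Every pipeline run writes a JSON manifest recording the
package version, seeds, inputs and SHA-256 checksums of the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import DEFAULT_STAGE_GRID, InputError, StageGrid
from .network import MetabolicModel, build_default_model, load_model
from .perturb import SCAN_FOLDS, prediction_table, scan_all
from .simulate import ExpressionInputs, physiological_ratios, simulate
from . import synth

log = logging.getLogger("seedflux")

FLOAT_FORMAT = "%.9g"


@dataclasses.dataclass
class RunConfig:
    """Paths, seeds and options for a full pipeline run."""

    out_dir: Path
    model_path: Path | None = None  # None -> built-in default reconstruction
    expression_path: Path | None = None  # None -> canonical synthetic program
    mapping_path: Path | None = None
    stage_grid: StageGrid = dataclasses.field(
        default_factory=lambda: DEFAULT_STAGE_GRID
    )
    seed: int = 0
    scan_folds: tuple[float, ...] = SCAN_FOLDS
    run_scan: bool = True
    solver_options: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = {"rtol", "atol", "method", "dt_out_daf", "neg_floor"}
        unknown = set(self.solver_options) - allowed
        if unknown:
            raise InputError(f"unknown solver options: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_expression(
    path, grid: StageGrid = DEFAULT_STAGE_GRID
) -> pd.DataFrame:
    """Read a gene x stage intensity matrix from TSV.

    First column: gene ID; header row: the 7 stage names, validated against
    the configured grid.  Parse errors carry 1-based line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    expected = list(grid.stage_names)
    if list(df.columns) != expected:
        missing = [s for s in expected if s not in df.columns]
        raise InputError(
            f"{path}: stage columns {list(df.columns)} do not match the "
            f"grid {expected}" + (f"; missing {missing}" if missing else "")
        )
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        lines = [int(np.nonzero(df.index == g)[0][-1]) + 2 for g in dup]
        raise InputError(f"{path}: duplicate gene IDs {dup} (lines {lines})")
    for j, col in enumerate(df.columns):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2
            raise InputError(
                f"{path}:{line}: non-numeric value in column {col!r}"
            )
    out = df.astype(float)
    if (out < 0).any().any():
        gene = out.index[(out < 0).any(axis=1)][0]
        raise InputError(f"{path}: negative intensity for gene {gene!r}")
    return out


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_mapping(path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a gene -> enzyme (+ optional turnover class) table from TSV.

    Columns: gene, enzyme[, turnover].  Returns ``(gene_to_enzyme,
    enzyme_turnover)``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "gene" not in cols or "enzyme" not in cols:
        raise InputError(f"{path}: expected columns gene, enzyme[, turnover]")
    gene_to_enzyme = dict(zip(df["gene"].astype(str), df["enzyme"].astype(str)))
    turnover: dict[str, str] = {}
    if "turnover" in cols:
        for enzyme, cls in zip(df["enzyme"], df["turnover"]):
            if isinstance(cls, str) and cls:
                turnover[str(enzyme)] = cls
    return gene_to_enzyme, turnover


def write_mapping(gene_to_enzyme: dict, turnover: dict, path) -> None:
    rows = [
        {"gene": g, "enzyme": e, "turnover": turnover.get(e, "average")}
        for g, e in gene_to_enzyme.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_targets(path) -> pd.DataFrame:
    """Read calibration targets (observable, time_daf, value[, weight, replicate])."""
    df = pd.read_csv(path)
    required = {"observable", "time_daf", "value"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: expected columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_tidy(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: Path, config: RunConfig, outputs: list[Path]) -> Path:
    from . import __version__

    manifest = {
        "package": "seedflux",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "solver_options": config.solver_options,
        "inputs": {
            "model": str(config.model_path) if config.model_path else "builtin",
            "expression": str(config.expression_path)
            if config.expression_path
            else "synthetic-reference",
        },
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def load_inputs(
    config: RunConfig,
) -> tuple[MetabolicModel, ExpressionInputs]:
    """Resolve the model and expression inputs for a run."""
    model = (
        load_model(config.model_path) if config.model_path else build_default_model()
    )
    if config.expression_path:
        if not config.mapping_path:
            raise InputError("expression input requires a gene mapping file")
        raw = read_expression(config.expression_path, config.stage_grid)
        gene_to_enzyme, turnover = read_mapping(config.mapping_path)
        if turnover:
            model.enzyme_turnover.update(turnover)
        ribosomal = [g for g in raw.index if g not in gene_to_enzyme]
        expr = ExpressionInputs.from_atlas(
            raw, gene_to_enzyme, ribosomal, config.stage_grid
        )
    else:
        profiles = synth.reference_profiles(model.enzyme_ids + ["SPRT"])
        expr = ExpressionInputs(
            profiles.drop(index="SPRT"),
            synth.RB_PROFILE.copy(),
            profiles.loc["SPRT"].to_numpy(dtype=float),
            config.stage_grid,
        )
    return model, expr


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """simulate -> ratios -> scan -> prediction table, with manifest.

    Each stage logs on entry; a failure aborts with the stage name while
    earlier outputs stay on disk.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model, expr = load_inputs(config)
    outputs: dict[str, Path] = {}

    stage = "simulate"
    try:
        log.info("stage %s", stage)
        traj = simulate(model, expr, **config.solver_options)
        p = out_dir / "trajectory.csv"
        write_tidy(traj.to_frame(), p)
        outputs["trajectory"] = p

        stage = "ratios"
        log.info("stage %s", stage)
        ratios = physiological_ratios(traj)
        ratio_df = pd.DataFrame(
            {
                "time_daf": ratios.times_daf,
                "hex_suc": ratios.hex_suc,
                "pk_plastid_over_cytosol": ratios.pk_plastid_over_cytosol,
                "rub_over_fab": ratios.rub_over_fab,
                "atp_adp": ratios.atp_adp,
            }
        )
        p = out_dir / "ratios.csv"
        write_tidy(ratio_df, p)
        outputs["ratios"] = p

        if config.run_scan:
            stage = "scan"
            log.info("stage %s", stage)
            scan = scan_all(model, expr, config.scan_folds)
            p = out_dir / "scan.csv"
            write_tidy(scan.to_frame(), p)
            outputs["scan"] = p

        stage = "prediction_table"
        log.info("stage %s", stage)
        table = prediction_table(model, expr, wt_traj=traj)
        p = out_dir / "prediction_table.csv"
        write_tidy(table, p)
        outputs["prediction_table"] = p
        p_md = out_dir / "prediction_table.md"
        p_md.write_text(table.to_markdown(index=False) + "\n")
        outputs["prediction_table_md"] = p_md
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {exc}; partial outputs kept in "
            f"{out_dir}"
        ) from exc

    outputs["manifest"] = write_manifest(
        out_dir, config, list(outputs.values())
    )
    return outputs
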