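"""Pipeline shell: input validation, end-to-end orchestration, reports.

``run_all`` chains simulate (optional) -> preprocess -> candidate-set fits
-> AICc selection with nesting rule and model averaging -> Bayesian refit of
the top model with a prediction grid, writing every artifact as CSV/JSON
plus a manifest (config, seed, package version, SHA-256 digests of all
inputs and outputs) so a run is self-describing and reruns are verifiable.

Exit codes used by the CLI: 0 success, 2 validation failure, 3 convergence
failure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import MCMCControl, make_prediction_grid, mcmc_top_model, predict_grid
from .glmm import GLMMControl, fit_candidate_set
from .preprocess import preprocess_dataset
from .selection import apply_nesting_rule, marginal_r2, model_average, rank_and_weight
from .synthetic import (
    RESIGHT_COLUMNS,
    SimConfig,
    generate_dataset,
    generate_resightings,
    write_csvs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ValidationReport",
    "validate_inputs",
    "run_all",
    "load_config",
]

BIRDS_SCHEMA = {
    "bird_id": object,
    "year": "int",
    "day_of_cycle": "int",
    "mass_g": "float",
    "skull_mm": "float",
    "n_offspring_next_winter": "int",
    "adult_associate_flag": "bool",
}
NAO_SCHEMA = {"year": "int", "june_nao": "float"}


@dataclass
class PipelineConfig:
    """Everything a full run needs; serialisable to/from YAML."""

    out_dir: str = "results"
    birds_path: str | None = None
    nao_path: str | None = None
    resightings_path: str | None = None
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    delta_threshold: float = 6.0
    seed: int = 0
    mcmc_iters: int = 20000
    mcmc_burn_in: int = 5000
    mcmc_thin: int = 15
    run_bayes: bool = True


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimConfig(**raw.pop("sim", {}))
    return PipelineConfig(sim=sim, **raw)


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    row_counts: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def _check_table(df: pd.DataFrame, schema: dict, name: str, report: ValidationReport):
    for col in schema:
        if col not in df.columns:
            report.errors.append(f"{name}: missing column '{col}'")
    report.row_counts[name] = len(df)


def validate_inputs(
    birds_path, nao_path, resightings_path=None
) -> ValidationReport:
    """Schema and consistency checks on the input CSVs."""
    report = ValidationReport()
    try:
        birds = pd.read_csv(birds_path)
    except Exception as exc:  # unreadable file is a validation failure
        report.errors.append(f"birds: cannot read ({exc})")
        return report
    try:
        nao = pd.read_csv(nao_path)
    except Exception as exc:
        report.errors.append(f"nao: cannot read ({exc})")
        return report

    _check_table(birds, BIRDS_SCHEMA, "birds", report)
    _check_table(nao, NAO_SCHEMA, "nao", report)
    if report.errors:
        return report

    dup = birds.duplicated(subset=["bird_id", "year"]).sum()
    if dup:
        report.errors.append(f"birds: {dup} duplicate (bird_id, year) rows")
    if (birds["n_offspring_next_winter"] < 0).any():
        report.errors.append("birds: negative offspring counts")
    missing_years = set(birds["year"]) - set(nao["year"])
    if missing_years:
        report.errors.append(f"nao: missing years {sorted(missing_years)}")
    extra_years = set(nao["year"]) - set(birds["year"])
    if extra_years:
        report.warnings.append(
            f"nao: years {sorted(extra_years)} absent from birds (tolerated)"
        )
    if resightings_path is not None:
        rs = pd.read_csv(resightings_path)
        for col in RESIGHT_COLUMNS:
            if col not in rs.columns:
                report.errors.append(f"resightings: missing column '{col}'")
        report.row_counts["resightings"] = len(rs)
        if report.ok:
            unmatched = set(birds["bird_id"]) - set(rs["bird_id"])
            if unmatched:
                report.errors.append(
                    f"resightings: {len(unmatched)} birds without records"
                )
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _fit_to_dict(fit) -> dict:
    return {
        "name": fit.spec.name,
        "terms": list(fit.spec.terms),
        "k": fit.spec.k,
        "beta": dict(zip(fit.spec.coef_names, np.asarray(fit.beta).tolist())),
        "se": None if fit.se is None else dict(zip(fit.spec.coef_names, np.asarray(fit.se).tolist())),
        "sigma_u": fit.sigma_u,
        "loglik": fit.loglik,
        "converged": bool(fit.converged),
        "n_obs": fit.n_obs,
        "n_groups": fit.n_groups,
    }


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns a manifest dict (also written to
    ``<out_dir>/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "inputs": {},
        "outputs": {},
        "log": [],
    }

    try:
        if config.simulate:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            ds = generate_dataset(sim)
            rs = generate_resightings(ds, sim)
            write_csvs(ds, out, resightings=rs)
            birds_path, nao_path = out / "birds.csv", out / "nao.csv"
            resight_path = out / "resightings.csv"
            manifest["log"].append(f"simulated {len(ds.birds)} birds over {sim.n_years} years")
        else:
            birds_path = Path(config.birds_path)
            nao_path = Path(config.nao_path)
            resight_path = (
                Path(config.resightings_path) if config.resightings_path else None
            )

        report = validate_inputs(birds_path, nao_path, resight_path)
        if not report.ok:
            raise PipelineValidationError("; ".join(report.errors))
        manifest["log"].append(f"validated inputs: rows {report.row_counts}")
        for p in filter(None, [birds_path, nao_path, resight_path]):
            manifest["inputs"][p.name] = _sha256(Path(p))

        birds = pd.read_csv(birds_path)
        nao = pd.read_csv(nao_path)
        resight = pd.read_csv(resight_path) if resight_path else None
        prep = preprocess_dataset(birds, nao, resight)
        prep.data.to_csv(out / "preprocessed.csv", index=False)
        manifest["log"].append(
            f"preprocessed: {len(prep.data)} analysis rows, "
            f"{prep.n_dropped_missing} dropped (missing), {prep.n_excluded} excluded (resighting rule)"
        )

        fits = fit_candidate_set(prep.data, GLMMControl())
        bad = [f.spec.name for f in fits if not f.converged]
        if bad:
            raise PipelineConvergenceError(f"non-converged models: {bad}")
        with open(out / "fits.json", "w") as fh:
            json.dump([_fit_to_dict(f) for f in fits], fh, indent=1)

        table = apply_nesting_rule(
            rank_and_weight(fits, n=len(prep.data), delta_threshold=config.delta_threshold)
        )
        avg = model_average(table)
        top = table.retained[0]
        sel = {
            "n": table.n,
            "delta_threshold": table.delta_threshold,
            "table": table.table.to_dict(orient="records"),
            "averaged": avg.table.reset_index(names="term").to_dict(orient="records"),
            "marginal_r2_top": marginal_r2(top, prep.data),
        }
        with open(out / "selection.json", "w") as fh:
            json.dump(sel, fh, indent=1)
        table.table.to_csv(out / "selection_table.csv", index=False)
        avg.table.to_csv(out / "averaged_estimates.csv")
        manifest["log"].append(
            f"selection: top model '{top.spec.name}', "
            f"{int(table.table['retained'].sum())} retained of "
            f"{int(table.table['in_delta6'].sum())} in the delta set"
        )

        if config.run_bayes:
            control = MCMCControl(
                n_iter=config.mcmc_iters,
                burn_in=config.mcmc_burn_in,
                thin=config.mcmc_thin,
            )
            chain = mcmc_top_model(prep.data, top.spec, control, seed=config.seed)
            long = chain.samples.reset_index(names="iteration").melt(
                id_vars="iteration", var_name="parameter", value_name="value"
            )
            long.to_csv(out / "chain.csv", index=False)
            year_nao_z = (
                prep.data.groupby("year")["nao_z"].first().to_numpy()
            )
            grid = predict_grid(chain, make_prediction_grid(year_nao_z))
            grid.table.to_csv(out / "prediction_grid.csv", index=False)
            manifest["log"].append(
                f"bayes: {chain.n_stored} stored samples for '{top.spec.name}'"
            )
    except (PipelineValidationError, PipelineConvergenceError):
        raise
    except Exception as exc:
        raise PipelineStageError(f"pipeline failed: {exc}") from exc

    for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sim"]["capture_window"] = list(d["sim"]["capture_window"])
    return d


class PipelineValidationError(RuntimeError):
    """Input validation failed (CLI exit code 2)."""


class PipelineConvergenceError(RuntimeError):
    """A model failed to converge (CLI exit code 3)."""


class PipelineStageError(RuntimeError):
    """Any other stage failure, with the stage and cause in the message."""
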