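"""Config-driven end-to-end pipeline producing a machine-readable report bundle.

One call runs: parse or simulate a cohort -> apply exclusions -> fit the
incidence model (per-group risks + relative risk + prior sensitivity) -> build
the risk table and fit the time-to-event model (hazards + cumulative-incidence
curves) -> case-series descriptives -> convergence diagnostics -> manifest.
Everything is written as JSON/CSV with deterministic content for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import yaml

from . import __version__
from .cohort import (
    DEFAULT_CUTOFF_DAYS,
    Group,
    Outcome,
    apply_exclusions,
    parse_cohort,
    write_cohort,
)
from .incidence import build_incidence_counts, fit_incidence, prior_sensitivity, relative_risk
from .inference import INCIDENCE_PRIOR, HAZARD_PRIOR, McmcConfig, PriorSpec
from .simulate import SimulationParams, simulate_cohort
from .surveillance import ProtocolSpec, descriptive_report
from .tte import build_risk_table, cumulative_incidence, fit_interval_hazards

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; exactly one input source.

    ``cohort_csv`` reads a cohort file; ``simulate`` generates one in-package.
    """

    outdir: Union[str, Path]
    seed: int = 0
    cohort_csv: Optional[str] = None
    simulate: Optional[SimulationParams] = None
    incidence_prior: PriorSpec = INCIDENCE_PRIOR
    hazard_prior: PriorSpec = HAZARD_PRIOR
    mcmc: McmcConfig = McmcConfig()
    interval_months: float = 3.0
    horizon_months: float = 90.0
    cutoff_days: int = DEFAULT_CUTOFF_DAYS
    protocol: ProtocolSpec = ProtocolSpec()
    run_sensitivity: bool = True
    run_tte: bool = True
    run_models: bool = True

    def __post_init__(self):
        if (self.cohort_csv is None) == (self.simulate is None):
            raise ValueError("exactly one of cohort_csv / simulate must be given")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulationParams(**raw["simulate"])
        for key, factory in (
            ("incidence_prior", PriorSpec),
            ("hazard_prior", PriorSpec),
            ("mcmc", McmcConfig),
            ("protocol", ProtocolSpec),
        ):
            if key in raw and raw[key] is not None:
                raw[key] = factory(**raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValueError(f"invalid run config: {exc}") from exc

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = asdict(self)
        data["outdir"] = str(data["outdir"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _write_json(path: Path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and write the report bundle to ``outdir``.

    Returns the manifest.  Deterministic given the seed: re-running with the
    same config yields byte-identical files (no timestamps are recorded).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "molarisk",
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    # --- input -----------------------------------------------------------
    try:
        if config.cohort_csv is not None:
            records = parse_cohort(config.cohort_csv)
            manifest["stages"]["input"] = {
                "module": "cohort",
                "operation": "parse_cohort",
                "source": str(config.cohort_csv),
                "n_records": len(records),
            }
        else:
            sim = replace(config.simulate, seed=config.seed)
            records, truth = simulate_cohort(sim)
            write_cohort(records, outdir / "cohort.csv")
            _write_json(
                outdir / "truth.json",
                {
                    "n": {g.value: truth.n[g] for g in truth.n},
                    "events": {g.value: truth.events[g] for g in truth.events},
                    "n_flagged": truth.n_flagged,
                },
            )
            manifest["stages"]["input"] = {
                "module": "synthetic_data",
                "operation": "simulate_cohort",
                "seed": sim.seed,
                "n_records": len(records),
            }
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc

    # --- exclusions ------------------------------------------------------
    try:
        cohort, exclusion_log = apply_exclusions(records)
        _write_json(outdir / "exclusions.json", exclusion_log)
        manifest["stages"]["exclusions"] = {
            "module": "cohort",
            "operation": "apply_exclusions",
            "retained": exclusion_log["retained"],
        }
    except Exception as exc:
        raise PipelineError("exclusions", str(exc)) from exc

    rhat_report = {}

    # --- incidence model -------------------------------------------------
    if config.run_models:
        try:
            counts = build_incidence_counts(cohort, config.cutoff_days)
            fit = fit_incidence(counts, config.incidence_prior, replace(config.mcmc, seed=config.seed))
            rr = relative_risk(fit.draws[Group.EARLY], fit.draws[Group.LATE])
            _write_json(
                outdir / "incidence.json",
                {
                    "counts": {
                        g.value: {"y": counts[g].y, "n": counts[g].n} for g in counts.counts
                    },
                    "prior": {"mean": config.incidence_prior.mean, "sd": config.incidence_prior.sd},
                    "posterior_p": {g.value: fit.summaries[g].as_dict() for g in fit.summaries},
                    "relative_risk_early_vs_late": rr.summary.as_dict(),
                },
            )
            for g, v in fit.rhat.items():
                rhat_report[f"incidence.alpha[{g.value}]"] = v
            manifest["stages"]["incidence"] = {
                "module": "incidence_model",
                "operation": "fit_incidence",
                "seed": config.seed,
            }
        except Exception as exc:
            raise PipelineError("incidence", str(exc)) from exc

        if config.run_sensitivity:
            try:
                table = prior_sensitivity(counts)
                table.to_csv(outdir / "sensitivity.csv", index=False)
                manifest["stages"]["sensitivity"] = {
                    "module": "incidence_model",
                    "operation": "prior_sensitivity",
                    "n_priors": int(table[["prior_mean", "prior_sd"]].drop_duplicates().shape[0]),
                }
            except Exception as exc:
                raise PipelineError("sensitivity", str(exc)) from exc

    # --- time-to-event model --------------------------------------------
    if config.run_models and config.run_tte:
        try:
            risk_table = build_risk_table(
                cohort, config.interval_months, config.horizon_months, config.cutoff_days
            )
            risk_table.to_frame().to_csv(outdir / "risk_table.csv", index=False)
            hfit = fit_interval_hazards(
                risk_table, config.hazard_prior, replace(config.mcmc, seed=config.seed + 1000)
            )
            hfit.hazard_summary().to_csv(outdir / "hazards.csv", index=False)
            curves = [cumulative_incidence(hfit, g) for g in (Group.EARLY, Group.LATE)]
            import pandas as pd

            pd.concat([c.to_frame() for c in curves]).to_csv(
                outdir / "cumulative_incidence.csv", index=False
            )
            for g in (Group.EARLY, Group.LATE):
                for k, v in enumerate(hfit.rhat[g]):
                    rhat_report[f"tte.alpha[{g.value},{k}]"] = float(v)
            manifest["stages"]["tte"] = {
                "module": "tte_model",
                "operation": "fit_interval_hazards",
                "seed": config.seed + 1000,
                "interval_months": config.interval_months,
                "horizon_months": config.horizon_months,
            }
        except Exception as exc:
            raise PipelineError("tte", str(exc)) from exc

    # --- descriptives ----------------------------------------------------
    try:
        cases = [r for r in cohort if r.outcome is Outcome.GTN]
        _write_json(outdir / "descriptives.json", descriptive_report(cases, config.protocol))
        manifest["stages"]["descriptives"] = {
            "module": "surveillance",
            "operation": "descriptive_report",
            "n_cases": len(cases),
        }
    except Exception as exc:
        raise PipelineError("descriptives", str(exc)) from exc

    if rhat_report:
        _write_json(outdir / "rhat.json", rhat_report)

    _write_json(outdir / "manifest.json", manifest)
    return manifest
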