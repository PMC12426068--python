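"""End-to-end pipeline: read or simulate -> fit -> checks -> contrasts.

A single config (YAML file or dict) drives a reproducible run and writes four
artifacts plus a run log into the output directory:

* ``summary.json`` — group-level posterior summaries, priors, seed, R-hat;
* ``posterior_group.csv`` — group-level probability-scale draws;
* ``ppc.json`` — posterior-predictive T1/T2 report;
* ``contrasts.json`` / ``contrasts.csv`` — the standard contrast battery.

Config layout (all blocks optional except one of ``input``/``simulation``)::

    seed: 7
    simulation:
      design: {n_participants: 82, items_per_source: 9, n_distractors: 18}
      medians: {d_TI: 0.42, d_TU: 0.06, d_FI: 0.05, d_FU: 0.04,
                e_ver: 0.80, e_imp: 0.16}   # omitted parameters: 0.5
      probit_sd: 0.5
    input:
      trials: path/to/trials.csv        # or frequencies: path/to/freq.csv
      coding: remember_only             # or remember_plus_know
      dialect: {participant: subj}      # our-name -> their-name
    inference: {n_chains: 2, n_iterations: 2000, n_burnin: 500, thinning: 2}
    checks: {n_rep: 300}
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .contrasts import battery_frame, standard_contrast_battery
from .design import DesignSpec
from .checks import ppc_T1, ppc_T2
from .inference import InferenceConfig, PosteriorSamples, fit, summarize
from .io import (
    CodingRule,
    build_frequency_tables,
    read_frequency_tables,
    read_trials,
    write_frequency_tables,
)
from .model import FrequencyTable, paper_constraints
from .simulate import GroupDistribution, draw_participants, simulate_frequencies

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    tables: list[FrequencyTable]
    samples: PosteriorSamples
    summary: "object"
    ppc: dict[str, object]
    contrasts: "object"
    out_dir: Path | None


def _load_config(config: Mapping | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _design_from(cfg: Mapping) -> DesignSpec:
    block = cfg.get("design", {}) or {}
    return DesignSpec(
        n_participants=int(block.get("n_participants", 82)),
        items_per_source=int(block.get("items_per_source", 9)),
        n_distractors=int(block.get("n_distractors", 18)),
    )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("data")
def _obtain_tables(cfg: dict, seed: int, design: DesignSpec) -> list[FrequencyTable]:
    constraints = paper_constraints()
    if "simulation" in cfg:
        sim = cfg["simulation"] or {}
        medians = {n: 0.5 for n in constraints.free_names}
        medians.update(sim.get("medians", {}) or {})
        group = GroupDistribution.from_medians(
            medians, constraints, sd=float(sim.get("probit_sd", 0.5))
        )
        params = draw_participants(group, constraints, design.n_participants, seed)
        return simulate_frequencies(params, design, seed + 1)
    inp = cfg.get("input")
    if not inp:
        raise ValueError("config needs an 'input' or 'simulation' block")
    if "frequencies" in inp:
        return read_frequency_tables(inp["frequencies"])
    records = read_trials(inp["trials"], dialect=inp.get("dialect"))
    rule = CodingRule(inp.get("coding", "remember_only"))
    return build_frequency_tables(records, rule, design)


def run_pipeline(
    config: Mapping | str | Path, out_dir: str | Path | None = None
) -> PipelineResult:
    """Run the full analysis described by ``config``; write artifacts to ``out_dir``."""
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    design = _design_from(cfg.get("simulation", cfg) or {})
    constraints = paper_constraints()

    out_path: Path | None = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_path / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logging.getLogger("mptsource").addHandler(handler)
        logging.getLogger("mptsource").setLevel(logging.INFO)

    try:
        logger.info("mptsource %s, seed=%d", __version__, seed)
        tables = _obtain_tables(cfg, seed, design)
        logger.info("data: %d participants", len(tables))

        inf = cfg.get("inference", {}) or {}
        icfg = InferenceConfig(
            n_chains=int(inf.get("n_chains", 2)),
            n_iterations=int(inf.get("n_iterations", 2000)),
            n_burnin=inf.get("n_burnin"),
            thinning=int(inf.get("thinning", 2)),
            seed=seed + 2,
        )
        logger.info("priors: %s", icfg.prior_description())
        samples = _stage("fit")(fit)(tables, constraints, design, icfg)
        logger.info("convergence: max R-hat %.3f (converged=%s)",
                    max(samples.diagnostics.values()), samples.converged)

        summary = summarize(samples)
        n_rep = int((cfg.get("checks", {}) or {}).get("n_rep", 300))
        t1 = _stage("checks")(ppc_T1)(samples, tables, design, n_rep=n_rep, seed=seed + 3)
        t2 = _stage("checks")(ppc_T2)(samples, tables, design, n_rep=n_rep, seed=seed + 4)
        logger.info("PPC: T1 p=%.3f, T2 p=%.3f", t1.p_value, t2.p_value)
        battery = _stage("contrasts")(standard_contrast_battery)(samples)
        ppc_report = {"T1": t1.to_dict(), "T2": t2.to_dict()}

        if out_path is not None:
            write_frequency_tables(tables, out_path / "frequencies.csv")
            samples.to_frame().to_csv(out_path / "posterior_group.csv", index=False)
            summary_payload = {
                "version": __version__,
                "seed": seed,
                "priors": samples.priors,
                "inference": {
                    "n_chains": icfg.n_chains,
                    "n_iterations": icfg.n_iterations,
                    "n_burnin": icfg.burnin,
                    "thinning": icfg.thinning,
                },
                "diagnostics": samples.diagnostics,
                "converged": samples.converged,
                "group_summary": summary.round(6).to_dict(orient="index"),
            }
            (out_path / "summary.json").write_text(
                json.dumps(summary_payload, indent=2, sort_keys=True)
            )
            (out_path / "ppc.json").write_text(json.dumps(ppc_report, indent=2))
            scatter = t1.scatter_frame().join(t2.scatter_frame())
            scatter.to_csv(out_path / "ppc_scatter.csv", index=False)
            frame = battery_frame(battery)
            frame.to_csv(out_path / "contrasts.csv")
            (out_path / "contrasts.json").write_text(
                json.dumps(
                    {
                        "contrasts": [c.to_dict() for c in battery],
                        "note": "no multiplicity correction applied across the battery",
                    },
                    indent=2,
                )
            )

        return PipelineResult(
            tables=tables,
            samples=samples,
            summary=summary,
            ppc=ppc_report,
            contrasts=battery,
            out_dir=out_path,
        )
    finally:
        if out_path is not None:
            logging.getLogger("mptsource").removeHandler(handler)
            handler.close()
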