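"""End-to-end orchestration: genetics -> divergence -> canonical -> correlation.

A single RunConfig (YAML-loadable) drives the whole chain on either a
phenotype CSV or a simulation block — exactly one of the two. Every
stage's tables are written under the output directory, every file is
listed in a MANIFEST, and a JSON run summary records seeds, the chosen
group count and headline parameters, so identical configs reproduce
byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import seedpheno
from seedpheno import anova as anova_mod
from seedpheno import canonical as canonical_mod
from seedpheno import correlation as correlation_mod
from seedpheno import divergence as div_mod
from seedpheno import simulate as sim_mod
from seedpheno.io import read_phenotype_table, write_results
from seedpheno.traits import DEFAULT_CORRELATION_TRAITS, DEFAULT_SCHEMA

logger = logging.getLogger(__name__)

STAGES = ("load", "genetics", "divergence", "canonical", "correlation", "write")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.exit_code = 10 + STAGES.index(stage)


@dataclass
class RunConfig:
    input_path: str | None = None
    simulation: dict | None = None
    sep: str = ","
    decimal: str = "."
    correlation_traits: list[str] = field(default_factory=lambda: list(DEFAULT_CORRELATION_TRAITS))
    alpha: float = 0.01
    kmax: int | None = None
    seed: int = 0
    output_dir: str = "results/run"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path or simulation must be set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _simulation_config(block: dict, seed: int) -> sim_mod.SimulationConfig:
    block = dict(block or {})
    block.setdefault("seed", seed)
    if "traits" in block:
        block["traits"] = [
            t if isinstance(t, sim_mod.TraitSim) else sim_mod.TraitSim(**t)
            for t in block["traits"]
        ]
        return sim_mod.SimulationConfig(**block)
    return sim_mod.default_config(
        g=block.get("g", 43),
        r=block.get("r", 4),
        n_groups=block.get("n_groups", 0),
        delta=block.get("delta", 0.0),
        seed=block["seed"],
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run summary dict.

    Any stage failure raises StageError with a stage-specific exit
    code; tables produced before the failure are retained and the
    MANIFEST flags the run as incomplete.
    """
    out = Path(config.output_dir)
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {
        "package": "seedpheno",
        "version": seedpheno.__version__,
        "seed": config.seed,
        "alpha": config.alpha,
    }
    timers: dict[str, float] = {}

    def _manifest(complete: bool) -> None:
        out.mkdir(parents=True, exist_ok=True)
        lines = [f"{name}.csv" for name in tables] + ["run_summary.json"]
        status = "complete" if complete else "INCOMPLETE"
        (out / "MANIFEST").write_text("\n".join([f"# status: {status}", *lines]) + "\n")

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)

            def __exit__(self, exc_type, exc, tb):
                timers[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    _manifest(complete=False)
                    raise StageError(name, exc) from exc
                return False

        return _Timer()

    with stage("load"):
        if config.input_path is not None:
            table = read_phenotype_table(
                config.input_path, sep=config.sep, decimal=config.decimal
            )
            summary["input"] = str(config.input_path)
        else:
            sim_config = _simulation_config(config.simulation, config.seed)
            table, truth = sim_mod.simulate_phenotypes(sim_config)
            tables["simulated_phenotypes"] = table.data
            summary["simulation"] = {
                "g": sim_config.g,
                "r": sim_config.r,
                "n_groups": sim_config.n_groups,
                "delta": sim_config.delta,
                "seed": sim_config.seed,
            }
            if truth.group_labels is not None:
                tables["true_groups"] = truth.group_labels.rename_axis("genotype").reset_index()
        summary["n_genotypes"] = len(table.genotypes)
        summary["n_blocks"] = len(table.blocks)
        summary["n_traits"] = len(table.traits)

    with stage("genetics"):
        anova = anova_mod.anova_table(table)
        params = anova_mod.genetic_parameters_table(anova)
        tables["anova"] = anova
        tables["genetic_parameters"] = params
        summary["h2_range"] = [
            round(float(params["h2"].min()), 4),
            round(float(params["h2"].max()), 4),
        ]

    with stage("divergence"):
        profiles = table.genotype_means()
        d = div_mod.gower_matrix(profiles)
        tree = div_mod.ward_linkage(d)
        criteria = div_mod.cluster_criteria(profiles, tree, config.kmax)
        k_star = div_mod.select_group_count(criteria)
        solution = criteria.solutions[k_star]
        tables["gower"] = d.to_frame()
        tables["cluster_criteria"] = criteria.table
        tables["likelihood_profile"] = criteria.table[["k", "log_likelihood"]]
        tables["assignments"] = solution.assignments.rename_axis("genotype").reset_index()
        tables["group_distances"] = div_mod.intergroup_distances(solution)
        summary["chosen_k"] = k_star
        summary["group_sizes"] = solution.group_sizes

    with stage("canonical"):
        can = canonical_mod.canonical_analysis(profiles, solution.assignments)
        tables["canonical_coefficients"] = can.coefficients
        tables["canonical_scores"] = can.scores.rename_axis("genotype")
        tables["canonical_group_means"] = can.group_means
        tables["canonical_proportions"] = pd.DataFrame(
            {
                "axis": can.coefficients.columns,
                "eigenvalue": can.eigenvalues,
                "proportion": can.proportions,
                "cumulative": can.cumulative,
            }
        )
        summary["canonical_first_two_pct"] = round(100.0 * float(can.cumulative[min(1, can.n_axes - 1)]), 2)

    with stage("correlation"):
        sel = [t for t in config.correlation_traits if t in profiles.columns]
        corr = correlation_mod.correlation_matrix(profiles[sel], alpha=config.alpha)
        tables["correlation_r"] = corr.r
        tables["correlation_pairs"] = corr.pair_table()
        summary["correlation"] = {
            "n_pairs": corr.n_pairs,
            "n_significant": int(corr.pair_table()["significant"].sum()),
            "class_counts": corr.counts,
        }

    with stage("write"):
        # timers are logged but kept out of the summary so identical
        # configs reproduce byte-identical summary files
        logger.info("stage timers: %s", timers)
        write_results(tables, out, summary=summary)
        _manifest(complete=True)
    return summary


# organ-split helper used by the CLI `genetics` subcommand
def split_by_organ(df: pd.DataFrame, column: str = "trait_id") -> dict[str, pd.DataFrame]:
    out = {}
    for organ in ("bean", "cherry"):
        ids = set(DEFAULT_SCHEMA.organ_ids(organ))
        sub = df[df[column].isin(ids)]
        if not sub.empty:
            out[organ] = sub
    return out
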