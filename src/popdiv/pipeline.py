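"""End-to-end workflow orchestration.

A :class:`PipelineConfig` (strict YAML schema) drives the stage sequence
simulate -> filter -> diversity -> differentiation -> cascade ->
contributions -> prioritize.  Each stage writes its TSV outputs into the run
directory and the run ends with a machine-readable manifest (parameters,
seed, input digests) sufficient to reproduce the run byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cascade import complete_snp_subset, diversity_cascade
from .contributions import (
    diversity_partition,
    leave_one_out_contributions,
    optimal_pool_contributions,
    subsample_average,
)
from .coverage import prioritization_protocol
from .differentiation import mantel_ibd, pairwise_matrix
from .diversity import population_diversity
from .filtering import run_cascade
from .io import (
    GenotypeDataset,
    PopulationMap,
    allele_counts,
    read_population_map,
    read_vcf,
    write_population_map,
    write_vcf,
)
from .simulate import SimulationConfig, PopulationSpec, default_config, simulate_dataset

ALL_STAGES = [
    "simulate",
    "filter",
    "diversity",
    "differentiation",
    "cascade",
    "contributions",
    "prioritize",
]

_KNOWN_KEYS = {
    "seed", "output_dir", "stages", "input",
    "simulate", "filter", "diversity", "differentiation",
    "cascade", "contributions", "prioritize",
}


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "popdiv_run"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    input: dict = field(default_factory=dict)  # vcf / popmap paths
    simulate: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    diversity: dict = field(default_factory=dict)
    differentiation: dict = field(default_factory=dict)
    cascade: dict = field(default_factory=dict)
    contributions: dict = field(default_factory=dict)
    prioritize: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = [s for s in cfg.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build_sim_config(params: dict, seed: int) -> SimulationConfig:
    params = dict(params)
    pops = params.pop("populations", None)
    if pops is not None:
        params["populations"] = [PopulationSpec(**p) for p in pops]
        return SimulationConfig(seed=seed, **params)
    return default_config(seed=seed, **params)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "outputs": {},
        "inputs": {},
        "warnings": [],
    }

    def save(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest["outputs"][name] = _digest(path)

    dataset: GenotypeDataset | None = None
    popmap: PopulationMap | None = None

    try:
        if "simulate" in config.stages:
            sim_cfg = _build_sim_config(config.simulate, config.seed)
            dataset, popmap, truth = simulate_dataset(config=sim_cfg)
            write_vcf(dataset, out / "simulated.vcf")
            write_population_map(popmap, out / "simulated_popmap.tsv")
            manifest["outputs"]["simulated.vcf"] = _digest(out / "simulated.vcf")
            manifest["outputs"]["simulated_popmap.tsv"] = _digest(
                out / "simulated_popmap.tsv"
            )
        else:
            vcf_path = config.input.get("vcf")
            popmap_path = config.input.get("popmap")
            if not vcf_path or not popmap_path:
                raise ValueError(
                    "config must provide input.vcf and input.popmap when the "
                    "simulate stage is disabled"
                )
            for p in (vcf_path, popmap_path):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
                manifest["inputs"][str(p)] = _digest(Path(p))
            dataset = read_vcf(vcf_path)
            popmap = read_population_map(popmap_path)
            dataset.replicate_pairs = popmap.replicate_pairs()

        filtered = dataset
        if "filter" in config.stages:
            filtered, report = run_cascade(dataset, popmap, **config.filter)
            save("filter_report.tsv", report.to_frame())
            write_vcf(filtered, out / "filtered.vcf")
            manifest["outputs"]["filtered.vcf"] = _digest(out / "filtered.vcf")
        fmap = popmap.restrict_to(filtered.individual_ids)

        if "diversity" in config.stages:
            div = population_diversity(
                filtered, fmap, seed=config.seed, **config.diversity
            )
            save("diversity_table.tsv", div)

        if "differentiation" in config.stages:
            params = dict(config.differentiation)
            permutations = params.pop("permutations", 999)
            min_n = params.pop("min_n", 6)
            estimator = params.pop("estimator", "wc84")
            fst = pairwise_matrix(
                filtered, fmap, metric="fst", min_n=min_n, estimator=estimator
            )
            dxy = pairwise_matrix(filtered, fmap, metric="dxy", min_n=min_n)
            save("pairwise_fst.tsv", fst.to_frame().reset_index(names="population"))
            save("pairwise_dxy.tsv", dxy.to_frame().reset_index(names="population"))
            try:
                ibd = mantel_ibd(
                    fst, fmap.coordinates(), permutations=permutations,
                    seed=config.seed,
                )
                save("mantel_ibd.tsv", pd.DataFrame([ibd]))
            except ValueError as exc:
                manifest["warnings"].append(f"ibd skipped: {exc}")

        if "cascade" in config.stages:
            complete = complete_snp_subset(filtered)
            if complete.n_sites == 0:
                manifest["warnings"].append(
                    "cascade skipped: no sites with 100% call rate"
                )
            else:
                cmap = fmap.restrict_to(complete.individual_ids)
                casc = diversity_cascade(complete, cmap, **config.cascade)
                save("diversity_cascade.tsv", casc.to_frame(cmap))

        if "contributions" in config.stages:
            params = dict(config.contributions)
            n = params.pop("subsample_n", 6)
            reps = params.pop("reps", 50)
            mean, sd = subsample_average(
                lambda t: leave_one_out_contributions(t, **params),
                filtered, fmap, n=n, reps=reps, seed=config.seed,
            )
            save("contributions_mean.tsv", mean)
            save("contributions_sd.tsv", sd)
            table = allele_counts(filtered, fmap)
            for objective in ("H", "k"):
                pool = optimal_pool_contributions(
                    table, objective=objective, seed=config.seed
                )
                save(f"optimal_pool_{objective}.tsv", pool)

        if "prioritize" in config.stages:
            params = dict(config.prioritize)
            summary, tallies = prioritization_protocol(
                filtered, fmap, seed=config.seed, **params
            )
            save("coverage_summary.tsv", summary)
            save("coverage_tallies.tsv", tallies)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def render_reports(output_dir) -> dict[str, Path]:
    """Markdown mirrors of the main stage tables for human consumption."""
    out = Path(output_dir)
    rendered = {}
    mapping = {
        "diversity_table.tsv": "table_diversity.md",
        "diversity_cascade.tsv": "table_cascade.md",
        "contributions_mean.tsv": "table_contributions.md",
        "coverage_summary.tsv": "table_coverage.md",
    }
    for src, dst in mapping.items():
        path = out / src
        target = out / dst
        if not path.exists():
            target.write_text(f"Stage output `{src}` missing: stage skipped.\n")
        else:
            frame = pd.read_csv(path, sep="\t")
            target.write_text(frame.to_markdown(index=False, floatfmt=".4g") + "\n")
        rendered[dst] = target
    return rendered
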