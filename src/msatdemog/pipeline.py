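"""End-to-end study pipeline: QC, diversity, differentiation, the
bottleneck battery (pooled and per-deme), size-change MCMC per group,
and posterior summaries, with all outputs as TSV/JSON."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import coalsim
from .bottleneck import bottleneck_battery
from .dataset import GenotypeDataset
from .demographic_mcmc import PriorSpec, run_replicated
from .io import attach_metadata, filter_individuals, read_genepop, write_genepop, write_metadata
from .posterior_analysis import PosteriorSummary, summarize, summary_table
from .stats import diversity_table, differentiation_matrix

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Serializable settings for a full run.

    Every stochastic stage derives its own stream from ``seed``;
    ``generation_years`` and ``sample_age_years`` feed time calibration.
    """

    seed: int = 1
    min_loci: int = 7
    rarefaction_genes: int = 8
    tpm_variants: tuple = (0.05, 0.20)
    theta_grid: tuple = (1.0, 2.0, 5.0, 10.0)
    het_reps: int = 5000
    mc_reps: int = 10_000
    mcmc_iterations: int = 50_000
    mcmc_thinning: int = 50
    mcmc_chains: int = 3
    mcmc_shapes: tuple = ("exponential",)
    generation_years: float = 5.0
    sample_age_years: dict = field(default_factory=dict)  # group -> years
    exact_reps: int = 20_000
    mcmc_groups: Optional[tuple] = None  # default: all groups

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("tpm_variants", "theta_grid", "mcmc_shapes", "mcmc_groups"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def load_dataset(
    genepop_path, metadata_path=None, min_loci: int = 0
) -> GenotypeDataset:
    """Read Genepop (+ optional sidecar TSV), then apply the typed-loci QC."""
    ds = read_genepop(genepop_path)
    if metadata_path is not None:
        ds = attach_metadata(ds, metadata_path)
    if min_loci:
        ds = filter_individuals(ds, min_loci)
    return ds


def run_full_study(
    datasets: dict[str, GenotypeDataset],
    config: AnalysisConfig,
    out_dir,
    deme_groups: Sequence[str] = (),
) -> dict:
    """Run every stage on a dict of group-name -> dataset.

    Writes diversity/differentiation/bottleneck/posterior tables plus a
    JSON log with per-stage timings and seeds; stages fail soft (the
    error is recorded and later stages still run).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    log: dict = {"seed": config.seed, "stages": {}}
    report: dict = {}

    def stage(name, fn):
        t0 = time.time()
        try:
            report[name] = fn()
            log["stages"][name] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
        except Exception as e:  # noqa: BLE001 - fail soft per stage
            logger.exception("stage %s failed", name)
            log["stages"][name] = {"status": "error", "error": str(e)}

    # QC
    def qc():
        filtered = {}
        for name, ds in datasets.items():
            filtered[name] = filter_individuals(ds, config.min_loci)
        return filtered

    stage("qc", qc)
    data = report.get("qc", datasets)

    # pooled container for differentiation
    def pooled() -> GenotypeDataset:
        parts = list(data.values())
        base = parts[0]
        calls = np.concatenate([p.calls for p in parts])
        return GenotypeDataset(
            individuals=[i for p in parts for i in p.individuals],
            loci=base.loci,
            calls=calls,
            population=np.concatenate([p.population for p in parts]),
        )

    def diversity():
        tab = diversity_table(pooled(), rarefaction_genes=config.rarefaction_genes)
        tab.to_csv(out / "diversity.tsv", sep="\t")
        return tab

    stage("diversity", diversity)

    def differentiation():
        mat = differentiation_matrix(
            pooled(), reps=config.exact_reps, seed=int(rng.integers(2**31))
        )
        mat.to_csv(out / "differentiation.tsv", sep="\t")
        mat.attrs["genic_p"].to_csv(out / "genic_diff_p.tsv", sep="\t")
        return mat

    stage("differentiation", differentiation)

    def bottlenecks():
        frames = []
        mc_cache: dict = {}
        for name, ds in data.items():
            rep = bottleneck_battery(
                ds,
                deme_partition=name in deme_groups and ds.deme is not None,
                tpm_variants=config.tpm_variants,
                theta_grid=config.theta_grid,
                het_reps=config.het_reps,
                mc_reps=config.mc_reps,
                seed=int(rng.integers(2**31)),
                label=name,
                _mc_cache=mc_cache,
            )
            frames.append(rep.rows)
        tab = pd.concat(frames)
        tab.to_csv(out / "bottleneck.tsv", sep="\t")
        return tab

    stage("bottleneck", bottlenecks)

    def demographic():
        priors = PriorSpec.default()
        summaries: list[PosteriorSummary] = []
        groups = config.mcmc_groups or tuple(data)
        for name in groups:
            ds = data[name]
            for shape in config.mcmc_shapes:
                chains = run_replicated(
                    ds,
                    priors=priors,
                    shape=shape,
                    n_chains=config.mcmc_chains,
                    iterations=config.mcmc_iterations,
                    thinning=config.mcmc_thinning,
                    seed=int(rng.integers(2**31)),
                )
                summaries.append(
                    summarize(
                        chains,
                        priors=priors,
                        label=name,
                        generation_years=config.generation_years,
                        sample_age_years=config.sample_age_years.get(name, 0.0),
                        seed=int(rng.integers(2**31)),
                        shape=shape,
                    )
                )
        tab = summary_table(summaries)
        tab.to_csv(out / "demographic.tsv", sep="\t")
        return tab

    stage("demographic", demographic)

    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return report


def simulate_study(seed: int, out_dir, n_loci: int = 10) -> dict[str, GenotypeDataset]:
    """Generate the four-sample synthetic scenario and write Genepop +
    sidecar metadata files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = coalsim.study_scenario(seed, n_loci=n_loci)
    for name, ds in bundle.items():
        write_genepop(ds, out / f"{name}.gen", title=f"synthetic {name}")
        write_metadata(ds, out / f"{name}.meta.tsv")
    return bundle
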