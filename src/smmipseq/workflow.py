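"""End-to-end orchestration: count -> bias -> fit -> differential expression.

A run is driven by a single :class:`RunConfig` (loadable from YAML); every
run writes its resolved configuration, per-stage outputs and a JSON
manifest with input checksums and seeds next to the results, so that a
re-run with unchanged inputs is reproducible: identical count tables
always, and identical posterior summaries under a fixed MCMC seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expr_model import (
    CountMatrix,
    MCMCConfig,
    differential_expression,
    estimate_bias,
    fit_condition,
    gene_summary,
    relative_expression,
)
from .panel import load_panel
from .readproc import ReadLayout, count_samples, read_sample_sheet

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and stage parameters for one pipeline run."""

    panel: str
    samples: str
    outdir: str
    umi_fraction: float = 0.95
    max_arm_mismatches: int = 2
    umi_length: int = 9
    conditions: list[str] = field(default_factory=list)  # empty: use sheet order
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        mcmc = MCMCConfig(**raw.pop("mcmc", {}))
        return cls(mcmc=mcmc, **raw)

    def validate(self) -> None:
        for p in (self.panel, self.samples):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and return the output manifest.

    Stages: (1) probe assignment and dimer removal, (2) UMI tallying and
    error correction (both inside molecule counting), (3) bias-covariate
    estimation, (4) per-condition posterior fits, (5) differential
    expression with gene aggregation.  Aborts with :class:`PipelineError`
    naming the failed stage; outputs written so far remain on disk.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "mcmc_seed": config.mcmc.seed,
        "inputs": {},
        "outputs": {},
    }
    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)

    stage = "load"
    try:
        panel = load_panel(config.panel)
        sheet = read_sample_sheet(config.samples)
        manifest["inputs"] = {
            "panel": _sha256(config.panel),
            "samples": _sha256(config.samples),
            "fastq": {row["sample"]: [_sha256(row["fastq1"]), _sha256(row["fastq2"])] for _, row in sheet.iterrows()},
        }

        stage = "count"
        layout = ReadLayout(umi_length=config.umi_length, max_arm_mismatches=config.max_arm_mismatches)
        counts, qc = count_samples(sheet, panel, layout, fraction=config.umi_fraction)
        counts.table.to_csv(outdir / "molecule_counts.tsv", sep="\t", index=False)
        qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
        manifest["outputs"]["counts"] = "molecule_counts.tsv"
        manifest["outputs"]["qc"] = "qc.tsv"

        stage = "bias"
        cm = CountMatrix.from_tidy(counts.table, sheet)
        bias = estimate_bias(cm)
        bias.x.rename("bias").to_csv(outdir / "probe_bias.tsv", sep="\t")
        manifest["outputs"]["bias"] = "probe_bias.tsv"

        stage = "fit"
        conditions = config.conditions or cm.conditions()
        fits = {}
        summaries = []
        rng = np.random.default_rng(config.mcmc.seed)
        for cond in conditions:
            fits[cond] = fit_condition(cm, cond, bias, config.mcmc, rng=rng)
            summaries.append(fits[cond].summary())
        pd.concat(summaries, ignore_index=True).to_csv(outdir / "posterior_summary.tsv", sep="\t", index=False)
        manifest["outputs"]["posterior"] = "posterior_summary.tsv"

        stage = "de"
        if len(conditions) >= 2:
            a, b = conditions[:2]
            de = differential_expression(fits[a], fits[b])
            de.table.to_csv(outdir / "de_probes.tsv", sep="\t", index=False)
            gene_map = {p.name: (p.gene or p.target_id) for p in panel}
            genes = gene_summary(de, gene_map)
            genes.table.to_csv(outdir / "de_genes.tsv", sep="\t", index=False)
            rel = pd.concat([relative_expression(fits[c], gene_map) for c in (a, b)], ignore_index=True)
            rel.to_csv(outdir / "expression_genes.tsv", sep="\t", index=False)
            manifest["outputs"]["de_probes"] = "de_probes.tsv"
            manifest["outputs"]["de_genes"] = "de_genes.tsv"
            manifest["outputs"]["expression"] = "expression_genes.tsv"
    except PipelineError:
        raise
    except Exception as exc:  # abort with the failing stage recorded
        manifest["failed_stage"] = stage
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise PipelineError(stage, str(exc)) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
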