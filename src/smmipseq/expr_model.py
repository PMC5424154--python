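"""Bayesian hierarchical negative-binomial expression model.

Replicate molecule counts for one condition are modeled as

    y[p, r] ~ NegBin(mean = m[p, r], dispersion = phi[e(r)])
    log m[p, r] = log N[r] + mu[p] + alpha[k(r)] + lambda[k(r)] * x[p]

where ``N[r]`` is replicate depth (total molecules), ``mu[p]`` is the
probe's log mean normalized expression, ``x[p]`` a centered per-probe
bias covariate shared by all conditions, ``alpha[k]``/``lambda[k]`` the
per-replicate-class depth offset and bias loading (e.g. per cDNA input
amount; the first class is the reference with alpha = 0) and ``phi[e]``
a per-experiment overdispersion (Var = m + m^2/phi), shared across
probes.  Conditions are fit independently; differential expression is
the cross-condition contrast of ``mu`` computed sample-wise on the
posterior draws.

The bias covariate captures the empirical observation that the
between-replicate-class deviation of a probe's normalized counts is
systematic: it correlates across unrelated conditions.  It is estimated
once from the full data set and passed to every per-condition fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._mcmc import MCMCConfig, NBModelData, NBPosterior, sample_posterior

__all__ = [
    "CountMatrix",
    "BiasCovariate",
    "PosteriorFit",
    "DeEstimate",
    "MCMCConfig",
    "normalize_mpm",
    "estimate_bias",
    "fit_condition",
    "differential_expression",
    "gene_summary",
    "relative_expression",
]

LOG2 = np.log(2.0)


@dataclass
class CountMatrix:
    """Molecule counts (probes x samples) plus per-sample design metadata.

    ``samples`` is indexed by sample name with columns ``condition``,
    ``replicate_class`` and ``experiment``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for: {sorted(missing)}")
        for col, default in (("condition", "cond"), ("replicate_class", "A"), ("experiment", "exp")):
            if col not in self.samples.columns:
                self.samples[col] = default
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @classmethod
    def from_tidy(cls, table: pd.DataFrame, samples: pd.DataFrame) -> "CountMatrix":
        """Build from the tidy readproc table (sample, probe, molecules)."""
        mat = table.pivot(index="probe", columns="sample", values="molecules").fillna(0)
        if "sample" in samples.columns:
            samples = samples.set_index("sample")
        return cls(mat, samples.loc[mat.columns].copy())

    @property
    def depth(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def condition_samples(self, condition: str) -> list[str]:
        sel = self.samples.index[self.samples["condition"] == condition]
        return [s for s in self.counts.columns if s in set(sel)]

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))


@dataclass
class BiasCovariate:
    """Centered per-probe bias values, aligned with a probe index."""

    x: pd.Series

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.x.values)):
            raise ValueError("bias covariate contains non-finite values")

    def aligned(self, probes: Sequence[str]) -> np.ndarray:
        return self.x.reindex(probes).fillna(0.0).values


@dataclass
class PosteriorFit:
    """Posterior draws for one condition."""

    condition: str
    probes: list[str]
    classes: list[str]
    experiments: list[str]
    posterior: NBPosterior
    config: MCMCConfig

    @property
    def mu_samples(self) -> np.ndarray:  # (S, P)
        return self.posterior.mu

    def summary(self) -> pd.DataFrame:
        mu = self.posterior.mu
        return pd.DataFrame(
            {
                "probe": self.probes,
                "condition": self.condition,
                "mean": mu.mean(axis=0),
                "sd": mu.std(axis=0, ddof=1),
                "q2.5": np.percentile(mu, 2.5, axis=0),
                "q97.5": np.percentile(mu, 97.5, axis=0),
            }
        )


@dataclass
class DeEstimate:
    """Log2 fold-change point estimates and 95% credible intervals.

    ``samples`` holds the underlying posterior contrast draws (units x
    draws) so that estimates can be aggregated (probe -> gene) without
    losing uncertainty.
    """

    table: pd.DataFrame  # columns: unit, log2fc, q2.5, q97.5
    samples: np.ndarray
    units: list[str]
    level: str = "probe"


def normalize_mpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Molecules-per-million normalization: 1e6 * y[p,r] / N[r].

    Zero-depth samples are dropped with a warning; each retained column
    sums to exactly 1e6.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    depth = mat.sum(axis=0)
    zero = depth[depth == 0].index.tolist()
    if zero:
        warnings.warn(f"excluding zero-depth samples: {zero}")
        mat = mat.drop(columns=zero)
        depth = depth.drop(zero)
    return 1e6 * mat / depth


def estimate_bias(counts: CountMatrix) -> BiasCovariate:
    """Estimate the condition-independent probe-bias covariate.

    For every condition containing both replicate classes, compute per
    probe half the difference of class-mean log(1 + mpm); average the
    per-condition values and center to mean zero.  With fewer than two
    replicate classes the covariate is identically zero (the model then
    reduces to plain depth normalization).
    """
    mpm = normalize_mpm(counts)
    meta = counts.samples
    classes = sorted(meta["replicate_class"].unique())
    if len(classes) < 2:
        return BiasCovariate(pd.Series(0.0, index=counts.counts.index))
    a, b = classes[:2]
    diffs = []
    for cond in counts.conditions():
        cols = [c for c in mpm.columns if meta.loc[c, "condition"] == cond]
        cols_a = [c for c in cols if meta.loc[c, "replicate_class"] == a]
        cols_b = [c for c in cols if meta.loc[c, "replicate_class"] == b]
        if not cols_a or not cols_b:
            continue
        la = np.log1p(mpm[cols_a]).mean(axis=1)
        lb = np.log1p(mpm[cols_b]).mean(axis=1)
        diffs.append(0.5 * (la - lb))
    if not diffs:
        return BiasCovariate(pd.Series(0.0, index=counts.counts.index))
    x = pd.concat(diffs, axis=1).mean(axis=1)
    x = x - x.mean()
    return BiasCovariate(x)


def fit_condition(
    counts: CountMatrix,
    condition: str,
    bias: BiasCovariate | None = None,
    config: MCMCConfig = MCMCConfig(),
    *,
    rng: np.random.Generator | None = None,
) -> PosteriorFit:
    """Fit the negative-binomial model to one condition's replicates.

    Emits a warning when any split-chain scale-reduction statistic
    exceeds the configured threshold.
    """
    cols = counts.condition_samples(condition)
    if not cols:
        raise ValueError(f"no samples for condition {condition!r}")
    y = counts.counts[cols].values
    depth = y.sum(axis=0).astype(float)
    keep = depth > 0
    if not keep.all():
        warnings.warn(f"excluding zero-depth replicates: {[c for c, k in zip(cols, keep) if not k]}")
        cols = [c for c, k in zip(cols, keep) if k]
        y, depth = y[:, keep], depth[keep]
    probes = list(counts.counts.index)
    x = bias.aligned(probes) if bias is not None else np.zeros(len(probes))
    meta = counts.samples.loc[cols]
    classes = sorted(meta["replicate_class"].unique())
    experiments = sorted(meta["experiment"].unique())
    data = NBModelData(
        y=y,
        depth=depth,
        x=x,
        class_idx=np.array([classes.index(c) for c in meta["replicate_class"]]),
        exp_idx=np.array([experiments.index(e) for e in meta["experiment"]]),
    )
    post = sample_posterior(data, config, rng=rng)
    bad = {k: v for k, v in post.rhat.items() if np.isfinite(v) and v > config.rhat_threshold}
    if bad:
        worst = max(bad.values())
        warnings.warn(
            f"condition {condition!r}: {len(bad)} parameters with split-Rhat > "
            f"{config.rhat_threshold} (worst {worst:.3f}); increase warmup or draws"
        )
    return PosteriorFit(condition, probes, [str(c) for c in classes], [str(e) for e in experiments], post, config)


def differential_expression(fit_a: PosteriorFit, fit_b: PosteriorFit) -> DeEstimate:
    """Per-probe log2 fold change of condition A over condition B.

    The two fits are independent posteriors over the same probe set;
    contrast draws pair the s-th sample of each.
    """
    if fit_a.probes != fit_b.probes:
        raise ValueError("fits cover different probe sets")
    s = min(fit_a.posterior.n_samples, fit_b.posterior.n_samples)
    delta = (fit_a.mu_samples[:s] - fit_b.mu_samples[:s]).T / LOG2  # (P, S)
    return DeEstimate(_summarize(delta, fit_a.probes, "probe"), delta, list(fit_a.probes), "probe")


def _summarize(samples: np.ndarray, units: Sequence[str], level: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            level: list(units),
            "log2fc": samples.mean(axis=1),
            "q2.5": np.percentile(samples, 2.5, axis=1),
            "q97.5": np.percentile(samples, 97.5, axis=1),
        }
    )


def gene_summary(estimate: DeEstimate, gene_map: Mapping[str, str]) -> DeEstimate:
    """Aggregate probe-level estimates to genes by sample-wise averaging.

    Averaging the posterior draws of all probes targeting a gene (rather
    than the point estimates) propagates uncertainty into the gene-level
    credible interval.  Single-probe genes pass through unchanged.
    """
    unmapped = [p for p in estimate.units if p not in gene_map]
    if unmapped:
        raise ValueError(f"probes without gene mapping: {unmapped[:5]}")
    genes = list(dict.fromkeys(gene_map[p] for p in estimate.units))
    rows = []
    for g in genes:
        idx = [i for i, p in enumerate(estimate.units) if gene_map[p] == g]
        rows.append(estimate.samples[idx].mean(axis=0))
    samples = np.vstack(rows)
    return DeEstimate(_summarize(samples, genes, "gene"), samples, genes, "gene")


def relative_expression(fit: PosteriorFit, gene_map: Mapping[str, str]) -> pd.DataFrame:
    """Gene-level normalized expression on the log2(1 + mpm) scale.

    Posterior draws of each probe's mean molecules-per-million are
    averaged across the gene's probes draw-wise, then transformed.
    Values are comparable to external expression measures (e.g. RPKM)
    only up to an affine transform.
    """
    unmapped = [p for p in fit.probes if p not in gene_map]
    if unmapped:
        raise ValueError(f"probes without gene mapping: {unmapped[:5]}")
    mpm = 1e6 * np.exp(fit.mu_samples)  # (S, P)
    genes = list(dict.fromkeys(gene_map[p] for p in fit.probes))
    rows = []
    for g in genes:
        idx = [i for i, p in enumerate(fit.probes) if gene_map[p] == g]
        rows.append(np.log2(1.0 + mpm[:, idx].mean(axis=1)))
    samples = np.vstack(rows)  # (G, S)
    out = _summarize(samples, genes, "gene")
    out = out.rename(columns={"log2fc": "log2_expression"})
    out["condition"] = fit.condition
    return out
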