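"""Normalization, bias covariate, posterior fitting and differential expression."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from smmipseq._mcmc import MCMCConfig, NBModelData, sample_posterior, split_rhat
from smmipseq.expr_model import (
    BiasCovariate,
    CountMatrix,
    DeEstimate,
    differential_expression,
    estimate_bias,
    fit_condition,
    gene_summary,
    normalize_mpm,
    relative_expression,
)

QUICK = MCMCConfig(warmup=400, draws_per_chain=150, thin=2)


def make_cm(columns: dict, meta_rows: list[dict], probes=None) -> CountMatrix:
    probes = probes or [f"p{i}" for i in range(len(next(iter(columns.values()))))]
    counts = pd.DataFrame(columns, index=probes)
    return CountMatrix(counts, pd.DataFrame(meta_rows).set_index("sample"))


class TestNormalizeMpm:
    def test_single_probe_is_full_million(self):
        cm = make_cm({"s1": [7]}, [{"sample": "s1", "condition": "c", "replicate_class": "A", "experiment": "e"}])
        assert normalize_mpm(cm).iloc[0, 0] == 1e6

    def test_arithmetic(self):
        cm = make_cm({"s1": [1, 1, 2]}, [{"sample": "s1", "condition": "c", "replicate_class": "A", "experiment": "e"}])
        assert list(normalize_mpm(cm)["s1"]) == [250000, 250000, 500000]

    def test_columns_sum_to_million(self, rng):
        y = rng.integers(0, 500, size=(30, 4))
        cm = make_cm(
            {f"s{i}": y[:, i] for i in range(4)},
            [{"sample": f"s{i}", "condition": "c", "replicate_class": "A", "experiment": "e"} for i in range(4)],
        )
        assert np.allclose(normalize_mpm(cm).sum(axis=0), 1e6)

    def test_probe_permutation_equivariance(self, rng):
        y = list(rng.integers(1, 100, 10))
        meta = [{"sample": "s", "condition": "c", "replicate_class": "A", "experiment": "e"}]
        a = normalize_mpm(make_cm({"s": y}, meta))
        perm = list(reversed(range(10)))
        b = normalize_mpm(make_cm({"s": [y[i] for i in perm]}, meta))
        assert list(a["s"].values[perm]) == list(b["s"].values)

    def test_zero_depth_sample_excluded(self):
        cm = make_cm(
            {"s1": [1, 2], "s2": [0, 0]},
            [{"sample": s, "condition": "c", "replicate_class": "A", "experiment": "e"} for s in ("s1", "s2")],
        )
        with pytest.warns(UserWarning, match="zero-depth"):
            out = normalize_mpm(cm)
        assert list(out.columns) == ["s1"]


class TestEstimateBias:
    @staticmethod
    def _meta(cond, klass, i):
        return {"sample": f"{cond}{klass}{i}", "condition": cond, "replicate_class": klass, "experiment": "e"}

    def test_identical_replicates_zero(self):
        y = [10, 20, 30]
        cols = {"c1A": y, "c1B": y}
        meta = [self._meta("c1", "A", 0) | {"sample": "c1A"}, self._meta("c1", "B", 0) | {"sample": "c1B"}]
        x = estimate_bias(make_cm(cols, meta)).x
        assert np.allclose(x, 0)

    def test_systematic_two_fold_bias(self):
        base = np.array([1000, 2000, 4000, 8000])
        cols, meta = {}, []
        for cond in ("c1", "c2"):
            biased = base.copy()
            biased[0] *= 2  # probe 0 doubled in class A, both conditions
            cols[f"{cond}A"] = biased
            cols[f"{cond}B"] = base
            meta.append({"sample": f"{cond}A", "condition": cond, "replicate_class": "A", "experiment": "e"})
            meta.append({"sample": f"{cond}B", "condition": cond, "replicate_class": "B", "experiment": "e"})
        x = estimate_bias(make_cm(cols, meta)).x
        # probe 0 carries ~ +log(2)/2 relative to the panel mean, modulo
        # the depth renormalization and centering
        spread = x.iloc[0] - x.iloc[1:].mean()
        assert spread == pytest.approx(0.5 * np.log(2), rel=0.15)
        assert abs(x.mean()) < 1e-12

    def test_single_class_returns_zero(self):
        cols = {"s1": [1, 2, 3]}
        meta = [{"sample": "s1", "condition": "c", "replicate_class": "A", "experiment": "e"}]
        assert np.allclose(estimate_bias(make_cm(cols, meta)).x, 0)

    def test_condition_specific_difference_cancels(self, rng):
        base = rng.integers(500, 5000, 20).astype(float)
        cols, meta = {}, []
        for cond, sign in (("c1", +1), ("c2", -1)):
            fac = np.exp(sign * 0.5)
            cols[f"{cond}A"] = base * fac  # opposite class effect per condition
            cols[f"{cond}B"] = base
            meta.append({"sample": f"{cond}A", "condition": cond, "replicate_class": "A", "experiment": "e"})
            meta.append({"sample": f"{cond}B", "condition": cond, "replicate_class": "B", "experiment": "e"})
        x = estimate_bias(make_cm(cols, meta)).x
        assert np.abs(x).max() < 0.05


def grid_posterior_mean_exp_mu(ys, N, config=MCMCConfig()):
    """2-D grid integration of the single-probe posterior.

    Marginalizes the dispersion numerically; independent of the MCMC code
    path (direct quadrature of the unnormalized posterior).
    """
    mu = np.linspace(np.log(ys.mean() / N) - 4, np.log(ys.mean() / N) + 4, 2001)
    t = np.linspace(-5, 9, 701)  # log phi
    MU, T = np.meshgrid(mu, t, indexing="ij")
    PHI = np.exp(T)
    M = N * np.exp(MU)
    loglik = np.zeros_like(MU)
    for y in ys:
        loglik += gammaln(y + PHI) - gammaln(PHI) + PHI * np.log(PHI / (PHI + M)) + y * np.log(M / (PHI + M))
    logprior = -(MU**2) / (2 * config.mu_prior_sd**2)  # prior mean log(1/P) = 0 for P = 1
    logprior += -T - np.log1p(np.exp(-2 * T) / config.phi_cauchy_scale**2)
    logpost = loglik + logprior
    w = np.exp(logpost - logpost.max())
    return float((np.exp(MU) * w).sum() / w.sum())


class TestSampler:
    def test_single_probe_matches_grid_oracle(self):
        ys, N = np.array([37.0, 41, 29, 35, 44, 33]), 1000.0
        data = NBModelData(
            y=ys[None, :], depth=np.full(6, N), x=np.zeros(1), class_idx=np.zeros(6, int), exp_idx=np.zeros(6, int)
        )
        post = sample_posterior(data, MCMCConfig(seed=5))
        expected = grid_posterior_mean_exp_mu(ys, N)
        assert np.exp(post.mu).mean() == pytest.approx(expected, rel=0.05)
        assert expected == pytest.approx(ys.mean() / N, rel=0.1)

    def test_parameter_recovery(self, rng):
        P, R, phi = 60, 4, 40.0
        mu = np.log(rng.dirichlet(np.ones(P) * 2))
        N = np.full(R, 3e4)
        m = N[None, :] * np.exp(mu[:, None])
        y = rng.negative_binomial(phi, phi / (phi + m))
        data = NBModelData(
            y=y, depth=y.sum(axis=0).astype(float), x=np.zeros(P), class_idx=np.zeros(R, int), exp_idx=np.zeros(R, int)
        )
        post = sample_posterior(data, MCMCConfig(seed=6))
        assert max(post.rhat.values()) < 1.05
        # single-dataset frequentist coverage fluctuates; the calibrated
        # multi-dataset check lives in the acceptance suite
        lo, hi = np.percentile(post.mu, [2.5, 97.5], axis=0)
        assert ((mu >= lo) & (mu <= hi)).mean() >= 0.8
        est = post.mu.mean(axis=0)
        assert np.corrcoef(est, mu)[0, 1] > 0.99

    def test_poisson_limit_dispersion_diverges(self, rng):
        P, R = 50, 4
        mu = np.log(np.full(P, 1.0 / P))
        N = np.full(R, 2e4)
        y = rng.poisson(N[None, :] * np.exp(mu[:, None]))
        data = NBModelData(
            y=y, depth=y.sum(axis=0).astype(float), x=np.zeros(P), class_idx=np.zeros(R, int), exp_idx=np.zeros(R, int)
        )
        post = sample_posterior(data, QUICK)
        assert np.median(post.phi) > 100  # Var ~ m: overdispersion negligible
        lo, hi = np.percentile(post.mu, [2.5, 97.5], axis=0)
        assert ((mu >= lo) & (mu <= hi)).mean() >= 0.85

    def test_split_rhat_flags_divergent_chains(self, rng):
        good = rng.standard_normal((4, 200))
        assert split_rhat(good) < 1.05
        bad = good + np.arange(4)[:, None] * 3
        assert split_rhat(bad) > 1.5


def _fit_pair(cm, bias, seed=3):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fa = fit_condition(cm, "c1", bias, QUICK, rng=np.random.default_rng(seed))
        fb = fit_condition(cm, "c2", bias, QUICK, rng=np.random.default_rng(seed + 1))
    return fa, fb


@pytest.fixture(scope="module")
def two_condition_fit():
    rng = np.random.default_rng(99)
    P = 40
    props = rng.dirichlet(np.ones(P) * 3)
    fold = np.where(np.arange(P) % 2 == 0, 2.0, 1.0)
    w1 = props * fold
    cols, meta = {}, []
    for cond, w in (("c1", w1 / w1.sum()), ("c2", props)):
        for r in range(4):
            cols[f"{cond}_{r}"] = rng.multinomial(30000, w)
            meta.append({"sample": f"{cond}_{r}", "condition": cond, "replicate_class": "A", "experiment": "e"})
    counts = pd.DataFrame(cols, index=[f"p{i}" for i in range(P)])
    cm = CountMatrix(counts, pd.DataFrame(meta).set_index("sample"))
    bias = BiasCovariate(pd.Series(0.0, index=counts.index))
    fa, fb = _fit_pair(cm, bias)
    return cm, fa, fb, fold


class TestDifferentialExpression:
    def test_identical_fits_give_zero(self, two_condition_fit):
        _, fa, _, _ = two_condition_fit
        de = differential_expression(fa, fa)
        assert np.all(de.table["log2fc"] == 0)

    def test_contrast_is_linear_in_mu(self, two_condition_fit):
        _, fa, fb, _ = two_condition_fit
        de = differential_expression(fa, fb)
        shifted = fa
        shifted.posterior.mu = fa.posterior.mu + 1.0
        de2 = differential_expression(shifted, fb)
        assert np.allclose(de2.table["log2fc"] - de.table["log2fc"], 1 / np.log(2))
        shifted.posterior.mu = fa.posterior.mu - 1.0  # restore

    def test_recovers_two_fold_change(self, two_condition_fit):
        _, fa, fb, fold = two_condition_fit
        de = differential_expression(fa, fb)
        est = de.table["log2fc"].values
        up = est[fold == 2.0].mean() - est[fold == 1.0].mean()
        assert up == pytest.approx(1.0, abs=0.1)

    def test_probe_set_mismatch(self, two_condition_fit):
        _, fa, fb, _ = two_condition_fit
        import copy

        fb2 = copy.copy(fb)
        fb2.probes = list(fb.probes[:-1]) + ["other"]
        with pytest.raises(ValueError):
            differential_expression(fa, fb2)


class TestGeneSummary:
    def test_single_probe_gene_passthrough(self):
        samples = np.array([[1.0, 2.0, 3.0]])
        de = DeEstimate(pd.DataFrame({"probe": ["p0"], "log2fc": [2.0]}), samples, ["p0"])
        g = gene_summary(de, {"p0": "G"})
        assert np.allclose(g.samples, samples)

    def test_two_probe_average(self):
        samples = np.array([[1.0, 1.0], [3.0, 3.0]])
        de = DeEstimate(pd.DataFrame({"probe": ["a", "b"], "log2fc": [1, 3]}), samples, ["a", "b"])
        g = gene_summary(de, {"a": "G", "b": "G"})
        assert np.allclose(g.samples, 2.0)
        assert g.table["log2fc"].iloc[0] == pytest.approx(2.0)

    def test_unmapped_probe_rejected(self):
        de = DeEstimate(pd.DataFrame({"probe": ["a"], "log2fc": [1]}), np.ones((1, 2)), ["a"])
        with pytest.raises(ValueError, match="mapping"):
            gene_summary(de, {})

    def test_gene_interval_tighter_than_probe_median(self, two_condition_fit):
        _, fa, fb, _ = two_condition_fit
        de = differential_expression(fa, fb)
        gene_map = {p: f"G{i // 4}" for i, p in enumerate(de.units)}  # 4 probes per gene
        g = gene_summary(de, gene_map)
        probe_width = (de.table["q97.5"] - de.table["q2.5"]).median()
        gene_width = (g.table["q97.5"] - g.table["q2.5"]).median()
        assert gene_width < probe_width


class TestRelativeExpression:
    def test_uniform_gene_equals_probe_transform(self, two_condition_fit):
        _, fa, _, _ = two_condition_fit
        rel = relative_expression(fa, {p: p for p in fa.probes})  # one gene per probe
        expected = np.log2(1 + 1e6 * np.exp(fa.posterior.mu)).mean(axis=0)
        assert np.allclose(rel["log2_expression"].values, expected, atol=1e-9)

    def test_depth_scaling_invariance(self, two_condition_fit, rng):
        cm, fa, _, _ = two_condition_fit
        scaled = CountMatrix(cm.counts * 3, cm.samples.copy())
        bias = BiasCovariate(pd.Series(0.0, index=cm.counts.index))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fa3 = fit_condition(scaled, "c1", bias, QUICK, rng=np.random.default_rng(3))
        a = relative_expression(fa, {p: p for p in fa.probes})["log2_expression"].values
        b = relative_expression(fa3, {p: p for p in fa.probes})["log2_expression"].values
        assert np.abs(a - b).max() < 0.2
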