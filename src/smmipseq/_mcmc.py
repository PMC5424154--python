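"""Posterior sampling for the hierarchical negative-binomial count model.

The model for one condition, probe p and replicate r:

    y[p, r] ~ NegBin(mean = m[p, r], dispersion = phi[e(r)])
    log m[p, r] = log N[r] + mu[p] + alpha[k(r)] + lambda[k(r)] * x[p]

with Var = m + m^2/phi, depth N[r], centered probe-bias covariate x[p],
replicate class k(r) and experiment e(r).  alpha is a per-class depth
offset (first class fixed at zero): a multiplicative probe bias
redistributes capture but also shifts a class's effective depth by a
probe-independent constant that the centered slope term cannot absorb.
Priors: mu[p] ~ Normal(log(1/P), sd_mu^2), alpha[k], lambda[k] ~
Normal(0, sd_lambda^2), 1/phi[e] ~ Half-Cauchy(0, c).

Given (lambda, phi) the likelihood factorizes over probes, so a
Metropolis-within-Gibbs scheme with elementwise random-walk updates for
mu and scalar updates for lambda and log phi mixes well; proposal scales
are adapted toward 44% acceptance during warmup and frozen afterwards.
All chains are advanced simultaneously as a leading array axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = ["MCMCConfig", "NBModelData", "NBPosterior", "sample_posterior", "split_rhat"]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; defaults yield 1,000 posterior draws (4 x 250)."""

    chains: int = 4
    warmup: int = 1000
    draws_per_chain: int = 250
    thin: int = 4
    seed: int = 1
    mu_prior_sd: float = 5.0
    lambda_prior_sd: float = 1.0
    phi_cauchy_scale: float = 5.0
    target_accept: float = 0.44
    rhat_threshold: float = 1.05

    @property
    def total_draws(self) -> int:
        return self.chains * self.draws_per_chain


@dataclass
class NBModelData:
    """Arrays defining one condition's likelihood."""

    y: np.ndarray  # (P, R) counts
    depth: np.ndarray  # (R,) total molecules
    x: np.ndarray  # (P,) centered bias covariate
    class_idx: np.ndarray  # (R,) -> [0, K)
    exp_idx: np.ndarray  # (R,) -> [0, E)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.class_idx = np.asarray(self.class_idx, dtype=int)
        self.exp_idx = np.asarray(self.exp_idx, dtype=int)
        P, R = self.y.shape
        if self.depth.shape != (R,) or self.x.shape != (P,):
            raise ValueError("inconsistent shapes in model data")
        if np.any(self.depth <= 0):
            raise ValueError("replicate depths must be positive")

    @property
    def n_probes(self) -> int:
        return self.y.shape[0]

    @property
    def n_classes(self) -> int:
        return int(self.class_idx.max()) + 1 if len(self.class_idx) else 1

    @property
    def n_experiments(self) -> int:
        return int(self.exp_idx.max()) + 1 if len(self.exp_idx) else 1


@dataclass
class NBPosterior:
    """Post-warmup draws, flattened across chains, plus diagnostics."""

    mu: np.ndarray  # (S, P)
    lam: np.ndarray  # (S, K)
    phi: np.ndarray  # (S, E)
    alpha: np.ndarray | None = None  # (S, K); first class fixed at 0
    rhat: dict[str, float] = field(default_factory=dict)
    accept: dict[str, float] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.mu.shape[0]

    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential-scale-reduction statistic.

    ``chains`` has shape (n_chains, n_draws); each chain is split in half
    so within-chain drift also registers as non-convergence.
    """
    c, n = chains.shape
    half = n // 2
    if half < 2:
        return float("nan")
    parts = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = parts.shape
    means = parts.mean(axis=1)
    w = parts.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _loglik_probe_terms(y, m, phi_r):
    """Sum over replicates of the m-dependent NB log-likelihood terms, per probe.

    y, m: (..., P, R); phi_r: (..., 1, R) broadcastable.  Omits terms
    constant in m (used for mu and lambda updates).
    """
    return (-(y + phi_r) * np.log(phi_r + m) + y * np.log(m)).sum(axis=-1)


def _loglik_full(y, m, phi_r):
    """Full NB log-likelihood (up to y-only constants), summed over replicates."""
    return (
        gammaln(y + phi_r)
        - gammaln(phi_r)
        + phi_r * np.log(phi_r)
        - (y + phi_r) * np.log(phi_r + m)
        + y * np.log(m)
    ).sum(axis=-1)


def _log_prior_logphi(t: np.ndarray, scale: float) -> np.ndarray:
    # 1/phi ~ Half-Cauchy(0, scale), transformed to t = log(phi) with Jacobian
    return -t - np.log1p(np.exp(-2.0 * t) / scale**2)


def sample_posterior(
    data: NBModelData, config: MCMCConfig = MCMCConfig(), rng: np.random.Generator | None = None
) -> NBPosterior:
    """Draw from the posterior by adaptive Metropolis-within-Gibbs."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    y, x = data.y, data.x
    P, R = y.shape
    K, E = data.n_classes, data.n_experiments
    C = config.chains
    logN = np.log(data.depth)

    # initial values: moment estimates, jittered per chain
    props = (y / data.depth).mean(axis=1)
    mu0_hat = np.log(np.clip(props, 1e-9, None))
    mu = mu0_hat[None, :] + 0.1 * rng.standard_normal((C, P))
    # initialize lambda at its per-class least-squares estimate: the
    # conditional posterior can be orders of magnitude narrower than the
    # prior, and a random-walk started far away never reaches it
    lam0 = np.zeros(K)
    ssx = float((x**2).sum())
    if ssx > 0:
        logp = np.log(np.clip(y / data.depth, 1e-9, None))
        for k in range(K):
            cols = data.class_idx == k
            if cols.any():
                resid = (logp[:, cols].mean(axis=1)) - mu0_hat
                lam0[k] = float((resid * x).sum() / ssx)
    lam = np.tile(lam0, (C, 1)) + (0.05 * rng.standard_normal((C, K)) if ssx > 0 else 0.0)
    if ssx > 0:
        mu = mu - lam0[data.class_idx].mean() * x[None, :]
    # per-class depth offsets, class 0 as reference
    alpha0 = np.zeros(K)
    logp = np.log(np.clip(y / data.depth, 1e-9, None))
    gm = [float((logp[:, data.class_idx == k] - mu0_hat[:, None]).mean()) if (data.class_idx == k).any() else 0.0 for k in range(K)]
    for k in range(1, K):
        alpha0[k] = gm[k] - gm[0]
    alpha = alpha0[None, :] + 0.05 * rng.standard_normal((C, K))
    alpha[:, 0] = 0.0
    mhat = np.clip(props[:, None] * data.depth, 1e-9, None)
    excess = ((y - mhat) ** 2 - mhat).sum() / np.maximum((mhat**2).sum(), 1e-9)
    phi_init = 1.0 / np.clip(excess, 1e-3, 1e3)
    logphi = np.log(phi_init) + 0.1 * rng.standard_normal((C, E))

    mu_prior_mean = np.log(1.0 / P)
    sd_mu, sd_lam = config.mu_prior_sd, config.lambda_prior_sd

    step_mu = np.full((C, P), 0.2)
    step_lam = np.full((C, K), 0.2)
    step_phi = np.full((C, E), 0.3)
    step_ridge = np.full(C, 0.2)
    use_ridge = not np.allclose(x, 0)

    def make_m(mu, lam, alpha):
        lam_r = lam[:, data.class_idx]  # (C, R)
        off_r = alpha[:, data.class_idx]  # (C, R)
        return np.exp(
            logN[None, None, :] + off_r[:, None, :] + mu[:, :, None] + lam_r[:, None, :] * x[None, :, None]
        )

    def phi_rep(logphi):
        return np.exp(logphi)[:, data.exp_idx][:, None, :]  # (C, 1, R)

    n_keep = config.draws_per_chain
    total_iters = config.warmup + n_keep * config.thin
    keep_mu = np.empty((C, n_keep, P))
    keep_lam = np.empty((C, n_keep, K))
    keep_alpha = np.empty((C, n_keep, K))
    keep_phi = np.empty((C, n_keep, E))
    step_alpha = np.full((C, K), 0.1)
    acc_counts = {"mu": 0.0, "lambda": 0.0, "phi": 0.0}
    yb = y[None, :, :]  # (1, P, R) broadcast over chains

    kept = 0
    for it in range(total_iters):
        adapting = it < config.warmup
        gamma = 1.0 / (1.0 + it) ** 0.6 if adapting else 0.0
        phi_r = phi_rep(logphi)

        # --- mu: elementwise random walk (independent conditionals) -------
        m_cur = make_m(mu, lam, alpha)
        ll_cur = _loglik_probe_terms(yb, m_cur, phi_r)
        prop = mu + step_mu * rng.standard_normal((C, P))
        m_prop = make_m(prop, lam, alpha)
        ll_prop = _loglik_probe_terms(yb, m_prop, phi_r)
        dprior = ((mu - mu_prior_mean) ** 2 - (prop - mu_prior_mean) ** 2) / (2 * sd_mu**2)
        log_alpha = ll_prop - ll_cur + dprior
        acc = np.log(rng.random((C, P))) < log_alpha
        mu = np.where(acc, prop, mu)
        if adapting:
            step_mu = np.clip(step_mu * np.exp(gamma * (acc.astype(float) - config.target_accept)), 1e-5, 10.0)
        else:
            acc_counts["mu"] += acc.mean()

        # --- alpha: per-class depth offset (class 0 pinned at zero) -------
        for k in range(1, K):
            cols = data.class_idx == k
            if not cols.any():
                continue
            m_cur = make_m(mu, lam, alpha)[:, :, cols]
            ll_cur = _loglik_probe_terms(yb[:, :, cols], m_cur, phi_r[:, :, cols]).sum(axis=1)
            prop_a = alpha.copy()
            prop_a[:, k] += step_alpha[:, k] * rng.standard_normal(C)
            m_prop = make_m(mu, lam, prop_a)[:, :, cols]
            ll_prop = _loglik_probe_terms(yb[:, :, cols], m_prop, phi_r[:, :, cols]).sum(axis=1)
            dprior = (alpha[:, k] ** 2 - prop_a[:, k] ** 2) / (2 * sd_lam**2)
            acc = np.log(rng.random(C)) < ll_prop - ll_cur + dprior
            alpha[:, k] = np.where(acc, prop_a[:, k], alpha[:, k])
            if adapting:
                step_alpha[:, k] = np.clip(
                    step_alpha[:, k] * np.exp(gamma * (acc.astype(float) - config.target_accept)), 1e-5, 10.0
                )

        # --- lambda: scalar random walk per class -------------------------
        for k in range(K):
            cols = data.class_idx == k
            if not cols.any() or ssx == 0:
                continue
            m_cur = make_m(mu, lam, alpha)[:, :, cols]
            ll_cur = _loglik_probe_terms(yb[:, :, cols], m_cur, phi_r[:, :, cols]).sum(axis=1)
            prop_l = lam.copy()
            prop_l[:, k] += step_lam[:, k] * rng.standard_normal(C)
            m_prop = make_m(mu, prop_l, alpha)[:, :, cols]
            ll_prop = _loglik_probe_terms(yb[:, :, cols], m_prop, phi_r[:, :, cols]).sum(axis=1)
            dprior = (lam[:, k] ** 2 - prop_l[:, k] ** 2) / (2 * sd_lam**2)
            acc = np.log(rng.random(C)) < ll_prop - ll_cur + dprior
            lam[:, k] = np.where(acc, prop_l[:, k], lam[:, k])
            if adapting:
                step_lam[:, k] = np.clip(
                    step_lam[:, k] * np.exp(gamma * (acc.astype(float) - config.target_accept)), 1e-5, 10.0
                )
            else:
                acc_counts["lambda"] += acc.mean() / K

        # --- ridge move: mu -> mu - d*x, lambda -> lambda + d -------------
        # The likelihood is invariant under this shift (log m unchanged), so
        # the unidentified direction is sampled from the priors directly;
        # without it, tight mu conditionals freeze lambda's level.
        if use_ridge:
            d = step_ridge * rng.standard_normal(C)
            prop_mu = mu - d[:, None] * x[None, :]
            prop_lam = lam + d[:, None]
            dprior = ((mu - mu_prior_mean) ** 2 - (prop_mu - mu_prior_mean) ** 2).sum(axis=1) / (
                2 * sd_mu**2
            ) + (lam**2 - prop_lam**2).sum(axis=1) / (2 * sd_lam**2)
            acc = np.log(rng.random(C)) < dprior
            mu = np.where(acc[:, None], prop_mu, mu)
            lam = np.where(acc[:, None], prop_lam, lam)
            if adapting:
                step_ridge *= np.exp(gamma * (acc.astype(float) - config.target_accept))

        # --- log phi: scalar random walk per experiment -------------------
        m_cur = make_m(mu, lam, alpha)
        for e in range(E):
            cols = data.exp_idx == e
            if not cols.any():
                continue
            ysub, msub = yb[:, :, cols], m_cur[:, :, cols]
            phi_cur = np.exp(logphi[:, e])[:, None, None]
            ll_cur = _loglik_full(ysub, msub, phi_cur).sum(axis=1)
            prop_t = logphi[:, e] + step_phi[:, e] * rng.standard_normal(C)
            phi_new = np.exp(prop_t)[:, None, None]
            ll_prop = _loglik_full(ysub, msub, phi_new).sum(axis=1)
            dprior = _log_prior_logphi(prop_t, config.phi_cauchy_scale) - _log_prior_logphi(
                logphi[:, e], config.phi_cauchy_scale
            )
            acc = np.log(rng.random(C)) < ll_prop - ll_cur + dprior
            logphi[:, e] = np.where(acc, prop_t, logphi[:, e])
            if adapting:
                step_phi[:, e] *= np.exp(gamma * (acc.astype(float) - config.target_accept))
            else:
                acc_counts["phi"] += acc.mean() / E

        if not adapting and (it - config.warmup + 1) % config.thin == 0:
            keep_mu[:, kept] = mu
            keep_lam[:, kept] = lam
            keep_alpha[:, kept] = alpha
            keep_phi[:, kept] = np.exp(logphi)
            kept += 1

    n_sampling = max(total_iters - config.warmup, 1)
    rhat: dict[str, float] = {}
    for p in range(P):
        rhat[f"mu[{p}]"] = split_rhat(keep_mu[:, :, p])
    if ssx > 0:
        for k in range(K):
            rhat[f"lambda[{k}]"] = split_rhat(keep_lam[:, :, k])
    for k in range(1, K):
        rhat[f"alpha[{k}]"] = split_rhat(keep_alpha[:, :, k])
    for e in range(E):
        rhat[f"phi[{e}]"] = split_rhat(np.log(keep_phi[:, :, e]))

    return NBPosterior(
        mu=keep_mu.reshape(-1, P),
        lam=keep_lam.reshape(-1, K),
        phi=keep_phi.reshape(-1, E),
        alpha=keep_alpha.reshape(-1, K),
        rhat=rhat,
        accept={k: v / n_sampling for k, v in acc_counts.items()},
    )
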