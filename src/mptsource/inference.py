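"""Hierarchical Bayesian (latent-trait) fitting of the constrained tree model.

Each participant's free parameters live on the probit scale:
``theta_pk = Phi(zeta_pk)`` with ``zeta_p ~ MVN(mu, Sigma)``.  The group mean
``mu`` gets independent normal priors; ``Sigma`` a scaled inverse-Wishart
prior, ``Sigma = diag(xi) Q diag(xi)`` with ``Q ~ InvWishart(K+1, I)`` and
``xi_k ~ Uniform(0, 10)``.  This captures participant heterogeneity and
parameter correlations, and rules out stochastic dependence arising as an
aggregation artefact.

Sampling is Metropolis-within-Gibbs: componentwise adaptive random-walk
Metropolis on the ``zeta_p`` (vectorized across participants), conjugate Gibbs
draws for ``mu`` and ``Q``, and random-walk Metropolis on the scaling factors
``xi``.  The contract is the posterior, not the algorithm; convergence is
monitored with split R-hat on the group-level parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import invwishart

from .design import DesignSpec
from .model import ConstraintSet, FrequencyTable, log_likelihood_matrix

__all__ = ["InferenceConfig", "PosteriorSamples", "fit", "summarize"]

RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class InferenceConfig:
    """MCMC settings.

    Defaults follow the study's reported run length (50,000 iterations) with
    20% burn-in and thinning 10 to bound memory; at least two chains are used
    so that split R-hat is informative.  ``prior_mu_sd`` is the SD of the
    normal prior on probit-scale group means; ``xi_upper`` bounds the uniform
    prior on the covariance scaling factors.
    """

    n_chains: int = 2
    n_iterations: int = 50_000
    n_burnin: int | None = None
    thinning: int = 10
    seed: int = 0
    prior_mu_sd: float = 1.0
    xi_upper: float = 10.0
    target_accept: float = 0.44

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iterations < 1 or self.thinning < 1:
            raise ValueError("chains, iterations and thinning must be positive")
        burn = self.burnin
        if not 0 <= burn < self.n_iterations:
            raise ValueError("burn-in must lie in [0, n_iterations)")

    @property
    def burnin(self) -> int:
        return self.n_burnin if self.n_burnin is not None else self.n_iterations // 5

    @property
    def draws_per_chain(self) -> int:
        span = self.n_iterations - self.burnin
        return -(-span // self.thinning)  # ceil

    def prior_description(self) -> dict[str, object]:
        return {
            "group_mean": f"Normal(0, {self.prior_mu_sd}^2) on the probit scale",
            "group_covariance": (
                "scaled inverse-Wishart: Sigma = diag(xi) Q diag(xi), "
                f"Q ~ InvWishart(df=K+1, scale=I), xi_k ~ Uniform(0, {self.xi_upper})"
            ),
        }


@dataclass
class PosteriorSamples:
    """Posterior draws on the probability scale, plus convergence diagnostics.

    ``group_probability`` holds ``Phi(mu)`` per retained draw (rows) and free
    parameter (columns); ``participant_probability`` holds the participant
    level ``Phi(zeta_p)``.  ``diagnostics`` maps each free parameter to its
    split R-hat (across chains); ``converged`` is True when all R-hat are at
    most 1.05.
    """

    free_names: tuple[str, ...]
    group_probability: np.ndarray
    participant_probability: np.ndarray
    n_chains: int
    draws_per_chain: int
    diagnostics: dict[str, float] = field(default_factory=dict)
    priors: dict[str, object] = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return self.group_probability.shape[0]

    @property
    def n_participants(self) -> int:
        return self.participant_probability.shape[1]

    @property
    def converged(self) -> bool:
        return bool(
            self.diagnostics
            and all(r <= RHAT_THRESHOLD for r in self.diagnostics.values())
        )

    def group_draws(self, name: str) -> np.ndarray:
        try:
            k = self.free_names.index(name)
        except ValueError:
            raise KeyError(f"unknown free parameter {name!r}") from None
        return self.group_probability[:, k]

    def to_frame(self) -> pd.DataFrame:
        """Group-level probability-scale draws, one column per free parameter."""
        return pd.DataFrame(self.group_probability, columns=list(self.free_names))


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split R-hat per parameter for draws of shape (chain, draw, K)."""
    if chains.shape[0] == 1:
        # arviz needs >= 2 chains; halve the single chain (split R-hat anyway).
        half = chains.shape[1] // 2
        chains = np.stack([chains[0, :half], chains[0, half : 2 * half]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        ds = az.convert_to_dataset(chains)
        return np.atleast_1d(az.rhat(ds)["x"].values)


def _run_chain(
    seed_seq: np.random.SeedSequence,
    counts: np.ndarray,
    idx_map: np.ndarray,
    K: int,
    cfg: InferenceConfig,
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed_seq)
    P = counts.shape[0]

    def loglik(zeta: np.ndarray) -> np.ndarray:
        theta = ndtr(zeta)
        return log_likelihood_matrix(theta[:, idx_map], counts)

    zeta = rng.normal(0.0, 0.1, size=(P, K))
    mu = np.zeros(K)
    xi = np.ones(K)
    Q = np.eye(K)
    Sigma = Q.copy()
    Lam = np.eye(K)
    cur_ll = loglik(zeta)
    scales = np.full(K, 0.5)
    shift_scales = np.full(K, 0.1)
    prior_prec = 1.0 / cfg.prior_mu_sd**2
    burn = cfg.burnin

    group_out = np.empty((cfg.draws_per_chain, K))
    part_out = np.empty((cfg.draws_per_chain, P, K))
    n_stored = 0

    for it in range(cfg.n_iterations):
        # --- participant-level probit parameters, componentwise MH ---
        for k in range(K):
            prop_k = zeta[:, k] + scales[k] * rng.standard_normal(P)
            zprop = zeta.copy()
            zprop[:, k] = prop_k
            ll_prop = loglik(zprop)
            rk = zeta[:, k] - mu[k]
            rk_p = prop_k - mu[k]
            cross = (zeta - mu) @ Lam[:, k]
            dquad = Lam[k, k] * (rk_p**2 - rk**2) + 2.0 * (rk_p - rk) * (
                cross - Lam[k, k] * rk
            )
            log_acc = (ll_prop - cur_ll) - 0.5 * dquad
            accept = np.log(rng.random(P)) < log_acc
            zeta[accept, k] = prop_k[accept]
            cur_ll[accept] = ll_prop[accept]
            if it < burn:
                gamma = min(0.25, (it + 1.0) ** -0.6)
                scales[k] *= np.exp(gamma * (accept.mean() - cfg.target_accept))

        # --- joint translation of (mu_k, zeta_:k): decorrelates the group
        # mean from the participant effects (centered parameterization) ---
        for k in range(K):
            t = shift_scales[k] * rng.standard_normal()
            zprop = zeta.copy()
            zprop[:, k] += t
            ll_prop = loglik(zprop)
            mu_k_new = mu[k] + t
            dlogprior = -0.5 * prior_prec * (mu_k_new**2 - mu[k] ** 2)
            log_acc = (ll_prop - cur_ll).sum() + dlogprior
            accepted = np.log(rng.random()) < log_acc
            if accepted:
                zeta = zprop
                cur_ll = ll_prop
                mu[k] = mu_k_new
            if it < burn:
                gamma = min(0.25, (it + 1.0) ** -0.6)
                shift_scales[k] *= np.exp(gamma * (float(accepted) - 0.234))

        # --- group mean, conjugate normal ---
        prec = P * Lam + prior_prec * np.eye(K)
        cov_mu = np.linalg.inv(prec)
        mean_mu = cov_mu @ (Lam @ zeta.sum(axis=0))
        mu = rng.multivariate_normal(mean_mu, cov_mu, method="cholesky")

        # --- covariance: inverse-Wishart factor, conjugate ---
        delta = zeta - mu
        u = delta / xi
        S = u.T @ u
        Q = invwishart.rvs(df=K + 1 + P, scale=np.eye(K) + S, random_state=rng)
        Qinv = np.linalg.inv(Q)

        # --- scaling factors, log-normal random-walk MH ---
        for k in range(K):
            prop = xi[k] * np.exp(0.3 * rng.standard_normal())
            if not (1e-6 < prop < cfg.xi_upper):
                continue
            c = xi[k] / prop
            dquad = Qinv[k, k] * (c * c - 1.0) * S[k, k] + 2.0 * (c - 1.0) * (
                Qinv[k] @ S[:, k] - Qinv[k, k] * S[k, k]
            )
            log_ratio = np.log(prop / xi[k])
            log_acc = -P * log_ratio - 0.5 * dquad + log_ratio
            if np.log(rng.random()) < log_acc:
                xi[k] = prop
                S[k, :] *= c
                S[:, k] *= c

        Sigma = (xi[:, None] * Q) * xi[None, :]
        Lam = np.linalg.inv(Sigma)

        if it >= burn and (it - burn) % cfg.thinning == 0:
            group_out[n_stored] = ndtr(mu)
            part_out[n_stored] = ndtr(zeta)
            n_stored += 1

    return group_out[:n_stored], part_out[:n_stored]


def fit(
    tables: Sequence[FrequencyTable],
    constraints: ConstraintSet,
    design: DesignSpec,
    config: InferenceConfig | None = None,
) -> PosteriorSamples:
    """Sample the posterior of the latent-trait model for a cohort.

    Parameters
    ----------
    tables
        One frequency table per participant (at least two).
    constraints
        Equality constraints defining the free parameters.
    design
        Stimulus counts; each table's row totals must match.
    config
        MCMC settings; defaults to :class:`InferenceConfig`.
    """
    cfg = config or InferenceConfig()
    if len(tables) < 2:
        raise ValueError("hierarchical fitting needs at least 2 participants")
    items = design.items_per_type
    for t in tables:
        if not np.array_equal(t.items_per_type, items):
            raise ValueError(
                f"table {t.participant_id!r} is inconsistent with the design"
            )
    counts = np.stack([t.counts for t in tables])
    idx_map = constraints.index_map
    K = constraints.n_free

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    group_chains, part_chains = [], []
    for ss in seeds:
        g, p = _run_chain(ss, counts, idx_map, K, cfg)
        group_chains.append(g)
        part_chains.append(p)

    group_arr = np.stack(group_chains)  # (chains, draws, K)
    rhat = _split_rhat(group_arr)
    diagnostics = {
        name: float(r) for name, r in zip(constraints.free_names, rhat)
    }
    samples = PosteriorSamples(
        free_names=constraints.free_names,
        group_probability=group_arr.reshape(-1, K),
        participant_probability=np.concatenate(part_chains, axis=0),
        n_chains=cfg.n_chains,
        draws_per_chain=group_chains[0].shape[0],
        diagnostics=diagnostics,
        priors=cfg.prior_description(),
        seed=cfg.seed,
    )
    return samples


def summarize(samples: PosteriorSamples, credibility: float = 0.95) -> pd.DataFrame:
    """Posterior summaries of the group-level parameters.

    Returns a DataFrame indexed by free-parameter name with columns
    ``median``, ``mean``, ``lower``, ``upper`` (equal-tailed credibility
    interval) and ``rhat``.
    """
    if samples.n_draws < 1:
        raise ValueError("need at least one posterior draw")
    if not 0.0 < credibility < 1.0:
        raise ValueError("credibility must lie in (0, 1)")
    alpha = (1.0 - credibility) / 2.0
    g = samples.group_probability
    frame = pd.DataFrame(
        {
            "median": np.median(g, axis=0),
            "mean": g.mean(axis=0),
            "lower": np.quantile(g, alpha, axis=0),
            "upper": np.quantile(g, 1.0 - alpha, axis=0),
            "rhat": [samples.diagnostics.get(n, np.nan) for n in samples.free_names],
        },
        index=list(samples.free_names),
    )
    return frame
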