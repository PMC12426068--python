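"""Synthetic cohorts from the source-memory tree with latent-trait heterogeneity.

Participants differ: each participant's free parameters are probit-transformed
draws around group-level means, ``theta_p = Phi(mu + delta_p)`` with
``delta_p ~ MVN(0, Sigma)`` on the probit scale.  Trial-level simulation adds
a Remember/Know tag to "old" responses as an independent Bernoulli overlay —
a data-coding device, not a modelled memory state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .design import DesignSpec
from .model import (
    CATEGORY_LABELS,
    ITEM_TYPE_LABELS,
    ConstraintSet,
    FrequencyTable,
    ParameterVector,
    category_probability_matrix,
    paper_constraints,
)

__all__ = [
    "GroupDistribution",
    "published_regime",
    "draw_participants",
    "simulate_frequencies",
    "simulate_trials",
]

TRIAL_COLUMNS = (
    "participant",
    "item_id",
    "item_type",
    "old_new_response",
    "remember_know",
    "veracity_response",
    "importance_response",
)


@dataclass(frozen=True)
class GroupDistribution:
    """Group-level distribution of free parameters on the probit scale.

    ``mu`` holds probit-scale means (so ``Phi(mu)`` is the group median on the
    probability scale); ``sigma`` is the covariance of the participant-level
    deviations.
    """

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if mu.ndim != 1:
            raise ValueError("mu must be a vector")
        if sigma.shape != (mu.size, mu.size):
            raise ValueError("sigma must be square with dimension len(mu)")
        if not np.allclose(sigma, sigma.T):
            raise ValueError("sigma must be symmetric")
        eigvals = np.linalg.eigvalsh(sigma)
        if eigvals.min() < -1e-10:
            raise ValueError("sigma must be positive semi-definite")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @classmethod
    def from_medians(
        cls,
        medians: dict[str, float] | Sequence[float],
        constraints: ConstraintSet,
        sd: float = 0.5,
    ) -> "GroupDistribution":
        """Build from probability-scale group medians and a common probit SD."""
        names = constraints.free_names
        if isinstance(medians, dict):
            vals = np.array([medians[n] for n in names], dtype=float)
        else:
            vals = np.asarray(medians, dtype=float)
        if np.any(vals <= 0.0) or np.any(vals >= 1.0):
            raise ValueError("medians must lie strictly inside (0, 1)")
        mu = ndtri(vals)
        sigma = (sd**2) * np.eye(len(names))
        return cls(mu=mu, sigma=sigma)


def published_regime(
    constraints: ConstraintSet | None = None, sd: float = 0.5
) -> GroupDistribution:
    """The generating regime used for recovery and power runs.

    Joint-retrieval medians follow the observed pattern (strong binding only
    for true-important sources: d_TI=.42, d_TU=.06, d_FI=.05, d_FU=.04);
    dimension memory is much better for veracity than importance
    (e_ver=.80, e_imp=.16); detection and guessing parameters are neutral 0.5.
    Heterogeneity is sd=0.5 on the probit scale, independent across
    parameters.
    """
    cs = constraints or paper_constraints()
    medians = {n: 0.5 for n in cs.free_names}
    medians.update(
        {"d_TI": 0.42, "d_TU": 0.06, "d_FI": 0.05, "d_FU": 0.04,
         "e_ver": 0.80, "e_imp": 0.16}
    )
    return GroupDistribution.from_medians(medians, cs, sd=sd)


def draw_participants(
    group: GroupDistribution,
    constraints: ConstraintSet,
    n: int,
    seed: int,
) -> list[ParameterVector]:
    """Draw ``n`` participant parameter vectors from the latent-trait model.

    Free parameters are ``Phi(mu + delta_p)`` with ``delta_p ~ MVN(0, sigma)``;
    constraints expand each free vector to the full 24-entry vector.
    Seeded runs are bit-reproducible.
    """
    if group.mu.size != constraints.n_free:
        raise ValueError(
            f"group distribution has {group.mu.size} entries but the constraint "
            f"set has {constraints.n_free} free parameters"
        )
    rng = np.random.default_rng(seed)
    # "eigh" handles positive semi-definite sigma (including sigma = 0) exactly.
    delta = rng.multivariate_normal(
        np.zeros(group.mu.size), group.sigma, size=n, method="eigh"
    )
    theta = ndtr(group.mu[None, :] + delta)
    full = constraints.expand_matrix(theta)
    return [ParameterVector(row) for row in full]


def _category_draws(
    params_list: Sequence[ParameterVector], design: DesignSpec, rng: np.random.Generator
) -> np.ndarray:
    """Per-item category indices, shape (P, n_test_items), type-blocked."""
    values = np.stack([p.values for p in params_list])
    probs = category_probability_matrix(values)  # (P, 5, 5)
    items = design.items_per_type
    P = len(params_list)
    out = np.empty((P, items.sum()), dtype=np.int64)
    for p in range(P):
        pos = 0
        for t in range(5):
            n_t = int(items[t])
            out[p, pos : pos + n_t] = rng.choice(5, size=n_t, p=probs[p, t])
            pos += n_t
    return out


def _counts_from_draws(draws: np.ndarray, design: DesignSpec) -> np.ndarray:
    items = design.items_per_type
    P = draws.shape[0]
    counts = np.zeros((P, 5, 5), dtype=np.int64)
    pos = 0
    for t in range(5):
        n_t = int(items[t])
        block = draws[:, pos : pos + n_t]
        for c in range(5):
            counts[:, t, c] = (block == c).sum(axis=1)
        pos += n_t
    return counts


def simulate_frequencies(
    params_list: Sequence[ParameterVector], design: DesignSpec, seed: int
) -> list[FrequencyTable]:
    """Frequency tables sampled from the tree, one per participant.

    Uses the same per-item category stream as :func:`simulate_trials`, so
    collapsing trials under the Remember+Know coding reproduces these tables
    exactly for the same seed.
    """
    cat_ss, _ = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(cat_ss)
    draws = _category_draws(params_list, design, rng)
    counts = _counts_from_draws(draws, design)
    return [
        FrequencyTable(
            participant_id=f"p{p + 1:03d}",
            counts=counts[p],
            items_per_type=design.items_per_type,
        )
        for p in range(len(params_list))
    ]


def simulate_trials(
    params_list: Sequence[ParameterVector],
    design: DesignSpec,
    remember_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Trial-level records: one row per participant x test item.

    "Old" responses carry a Remember/Know tag drawn i.i.d. Bernoulli with
    ``remember_rate``; "new" responses carry no tag and no source attribution.
    """
    if not 0.0 <= remember_rate <= 1.0:
        raise ValueError("remember_rate must be in [0, 1]")
    cat_ss, rk_ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(cat_ss)
    rk_rng = np.random.default_rng(rk_ss)

    draws = _category_draws(params_list, design, rng)
    items = design.items_per_type
    type_of_item = np.repeat(np.arange(5), items)

    rows = []
    for p in range(len(params_list)):
        pid = f"p{p + 1:03d}"
        for i in range(items.sum()):
            cat = int(draws[p, i])
            t_label = ITEM_TYPE_LABELS[type_of_item[i]]
            if cat == 0:
                rows.append((pid, f"{t_label}_{i:03d}", t_label, "new", "", "", ""))
            else:
                key = CATEGORY_LABELS[cat].removeprefix("old_")  # e.g. "TI"
                ver = "true" if key[0] == "T" else "false"
                imp = "important" if key[1] == "I" else "unimportant"
                rk = "remember" if rk_rng.random() < remember_rate else "know"
                rows.append((pid, f"{t_label}_{i:03d}", t_label, "old", rk, ver, imp))
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
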