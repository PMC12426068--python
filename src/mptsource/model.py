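"""Core multidimensional source-memory MPT model.

The model is a two-high-threshold recognition tree extended with a
two-dimensional source attribution stage.  Studied statements come from one
of four sources crossing *veracity* (true/false feedback) with *importance*
(important/unimportant feedback).  At test, a participant first calls an item
old or new; for "old" calls she attributes the item to one of the four source
combinations.  The tree separates

* item detection (``D_ij`` per source combination, ``D_new`` for distractors),
* joint retrieval of both source features as a bound compound (``d_ij``),
* independent retrieval of each source dimension (``e_ij^ver``, ``e_ij^imp``),
* guessing: source guessing for recognized items (``a``), source guessing for
  unrecognized/undetected items (``g``), and old-guessing (``b``).

Joint retrieval produces stochastic dependence between the two attributions;
independent retrieval does not — this distinction is the scientific point of
the model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "SourceCombination",
    "ItemType",
    "ResponseCategory",
    "PARAM_NAMES",
    "PARAM_INDEX",
    "N_PARAMS",
    "ParameterVector",
    "ConstraintSet",
    "paper_constraints",
    "apply_constraints",
    "FrequencyTable",
    "category_probabilities",
    "category_probability_matrix",
    "log_likelihood",
    "log_likelihood_matrix",
]


class SourceCombination(enum.Enum):
    """The four study sources: veracity x importance. Order is fixed globally."""

    TI = ("true", "important")
    TU = ("true", "unimportant")
    FI = ("false", "important")
    FU = ("false", "unimportant")

    @property
    def veracity(self) -> str:
        return self.value[0]

    @property
    def importance(self) -> str:
        return self.value[1]

    @property
    def index(self) -> int:
        return list(SourceCombination).index(self)


class ItemType(enum.Enum):
    """Five test item types: one target type per source combination + distractor."""

    TARGET_TI = "TI"
    TARGET_TU = "TU"
    TARGET_FI = "FI"
    TARGET_FU = "FU"
    DISTRACTOR = "new"

    @property
    def source(self) -> SourceCombination | None:
        if self is ItemType.DISTRACTOR:
            return None
        return SourceCombination[self.value]

    @property
    def index(self) -> int:
        return list(ItemType).index(self)


class ResponseCategory(enum.Enum):
    """Response categories: "new", or "old" plus one of four source attributions."""

    NEW = "new"
    OLD_TI = "old_TI"
    OLD_TU = "old_TU"
    OLD_FI = "old_FI"
    OLD_FU = "old_FU"

    @property
    def index(self) -> int:
        return list(ResponseCategory).index(self)


ITEM_TYPE_LABELS = tuple(t.value for t in ItemType)
CATEGORY_LABELS = tuple(c.value for c in ResponseCategory)
COMBO_LABELS = tuple(c.name for c in SourceCombination)

# Canonical full-parameter order. All array code indexes into this.
PARAM_NAMES: tuple[str, ...] = (
    "D_TI", "D_TU", "D_FI", "D_FU",
    "D_new",
    "d_TI", "d_TU", "d_FI", "d_FU",
    "e_ver_TI", "e_ver_TU", "e_ver_FI", "e_ver_FU",
    "e_imp_TI", "e_imp_TU", "e_imp_FI", "e_imp_FU",
    "a_ver", "a_imp_true", "a_imp_false",
    "g_ver", "g_imp_true", "g_imp_false",
    "b",
)
PARAM_INDEX: dict[str, int] = {n: i for i, n in enumerate(PARAM_NAMES)}
N_PARAMS = len(PARAM_NAMES)  # 24

# Source indicators per combination in (TI, TU, FI, FU) order.
_IS_TRUE = np.array([1.0, 1.0, 0.0, 0.0])
_IS_IMPORTANT = np.array([1.0, 0.0, 1.0, 0.0])


def _check_unit_interval(values: np.ndarray) -> None:
    if not np.all(np.isfinite(values)) or np.any(values < 0.0) or np.any(values > 1.0):
        raise ValueError("all model parameters must lie in [0, 1]")


@dataclass(frozen=True)
class ParameterVector:
    """The full (unconstrained) 24-entry parameter vector of the tree.

    Entries follow :data:`PARAM_NAMES`. Values are probabilities in [0, 1].
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (N_PARAMS,):
            raise ValueError(f"expected {N_PARAMS} parameters, got shape {arr.shape}")
        _check_unit_interval(arr)
        object.__setattr__(self, "values", arr)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ParameterVector":
        missing = set(PARAM_NAMES) - set(mapping)
        if missing:
            raise KeyError(f"missing parameters: {sorted(missing)}")
        extra = set(mapping) - set(PARAM_NAMES)
        if extra:
            raise KeyError(f"unknown parameters: {sorted(extra)}")
        return cls(np.array([mapping[n] for n in PARAM_NAMES], dtype=float))

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(PARAM_NAMES, self.values)}

    def __getitem__(self, name: str) -> float:
        return float(self.values[PARAM_INDEX[name]])


@dataclass(frozen=True)
class ConstraintSet:
    """Named equality constraints mapping full parameters onto free parameters.

    ``groups`` is a sequence of ``(free_name, members)`` pairs; every member of
    a group is equated to that group's single free value.  Full parameters not
    named in any group are free under their own name.  The free-parameter
    order is the canonical full order, with each group placed at its first
    member's position.
    """

    groups: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def __post_init__(self) -> None:
        norm = tuple((str(f), tuple(m)) for f, m in self.groups)
        seen: set[str] = set()
        for free, members in norm:
            if not members:
                raise ValueError(f"constraint group {free!r} has no members")
            for m in members:
                if m not in PARAM_INDEX:
                    raise KeyError(f"unknown model parameter in constraints: {m!r}")
                if m in seen:
                    raise ValueError(f"parameter {m!r} appears in more than one group")
                seen.add(m)
        object.__setattr__(self, "groups", norm)

    @property
    def free_names(self) -> tuple[str, ...]:
        by_member = {m: f for f, members in self.groups for m in members}
        order: list[str] = []
        for name in PARAM_NAMES:
            free = by_member.get(name, name)
            if free not in order:
                order.append(free)
        return tuple(order)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    @property
    def index_map(self) -> np.ndarray:
        """For each of the 24 full parameters, the index of its free parameter."""
        free_pos = {f: i for i, f in enumerate(self.free_names)}
        by_member = {m: f for f, members in self.groups for m in members}
        return np.array([free_pos[by_member.get(n, n)] for n in PARAM_NAMES], dtype=int)

    def expand(self, free_values: Mapping[str, float]) -> "ParameterVector":
        names = self.free_names
        missing = set(names) - set(free_values)
        if missing:
            raise KeyError(f"missing free parameters: {sorted(missing)}")
        free = np.array([free_values[n] for n in names], dtype=float)
        _check_unit_interval(free)
        return ParameterVector(free[self.index_map])

    def expand_matrix(self, free: np.ndarray) -> np.ndarray:
        """Expand an ``(..., n_free)`` array of free values to ``(..., 24)``."""
        free = np.asarray(free, dtype=float)
        if free.shape[-1] != self.n_free:
            raise ValueError(f"expected last axis {self.n_free}, got {free.shape[-1]}")
        return free[..., self.index_map]

    def reduce(self, params: "ParameterVector") -> dict[str, float]:
        """Project a full vector onto the free parameters (first-member value)."""
        inv: dict[str, float] = {}
        by_member = {m: f for f, members in self.groups for m in members}
        for name, value in zip(PARAM_NAMES, params.values):
            free = by_member.get(name, name)
            inv.setdefault(free, float(value))
        return {n: inv[n] for n in self.free_names}


def paper_constraints() -> ConstraintSet:
    """The study's constraint set: 14 free parameters.

    Distractor detection is equated with detection of true-important targets
    (D_new = D_TI); source guessing does not depend on recognition state
    (g = a on all three guessing branches); independent retrieval is equated
    across source combinations within each dimension, leaving one memory
    parameter per dimension (e_ver, e_imp).
    """
    return ConstraintSet(
        groups=(
            ("D_TI", ("D_TI", "D_new")),
            ("e_ver", ("e_ver_TI", "e_ver_TU", "e_ver_FI", "e_ver_FU")),
            ("e_imp", ("e_imp_TI", "e_imp_TU", "e_imp_FI", "e_imp_FU")),
            ("a_ver", ("a_ver", "g_ver")),
            ("a_imp_true", ("a_imp_true", "g_imp_true")),
            ("a_imp_false", ("a_imp_false", "g_imp_false")),
        )
    )


def apply_constraints(
    free_values: Mapping[str, float], constraints: ConstraintSet
) -> ParameterVector:
    """Build the full 24-entry vector from free values under ``constraints``."""
    return constraints.expand(free_values)


@dataclass
class FrequencyTable:
    """Per-participant response counts: 5 item types x 5 response categories.

    Rows follow :class:`ItemType` order, columns :class:`ResponseCategory`
    order; each row sums to the number of test items of that type.
    """

    participant_id: str
    counts: np.ndarray
    items_per_type: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        items = np.asarray(self.items_per_type)
        if counts.shape != (5, 5):
            raise ValueError(f"counts must be 5x5, got {counts.shape}")
        if items.shape != (5,):
            raise ValueError(f"items_per_type must have 5 entries, got {items.shape}")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            counts = counts.astype(np.int64, casting="unsafe")
            if np.any(counts < 0):
                raise ValueError("counts must be non-negative integers")
        if not np.array_equal(counts.sum(axis=1), items):
            raise ValueError("each row of counts must sum to items_per_type")
        self.counts = counts.astype(np.int64)
        self.items_per_type = items.astype(np.int64)


def category_probability_matrix(values: np.ndarray) -> np.ndarray:
    """Category probabilities for every item type, vectorized.

    Parameters
    ----------
    values
        Array of shape ``(..., 24)`` in :data:`PARAM_NAMES` order.

    Returns
    -------
    Array of shape ``(..., 5, 5)``: item types (TI, TU, FI, FU, distractor) by
    response categories (new, old_TI, old_TU, old_FI, old_FU). Each row sums
    to 1.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[-1] != N_PARAMS:
        raise ValueError(f"expected last axis {N_PARAMS}, got {v.shape[-1]}")
    _check_unit_interval(v)

    D = v[..., 0:4]
    D_new = v[..., 4]
    d = v[..., 5:9]
    e_ver = v[..., 9:13]
    e_imp = v[..., 13:17]
    a_ver = v[..., 17:18]
    a_imp_t = v[..., 18:19]
    a_imp_f = v[..., 19:20]
    g_ver = v[..., 20]
    g_imp_t = v[..., 21]
    g_imp_f = v[..., 22]
    b = v[..., 23]

    # Independent-retrieval stage for a recognized target from source (i, j):
    # veracity response first (retrieved -> correct, else guess a_ver), then
    # importance (retrieved -> correct, else guess conditional on the
    # veracity *response*).
    A_true = e_ver * _IS_TRUE + (1.0 - e_ver) * a_ver          # P(respond "true")
    A_false = e_ver * (1.0 - _IS_TRUE) + (1.0 - e_ver) * (1.0 - a_ver)
    B_imp_true = e_imp * _IS_IMPORTANT + (1.0 - e_imp) * a_imp_t   # given "true"
    B_imp_false = e_imp * _IS_IMPORTANT + (1.0 - e_imp) * a_imp_f  # given "false"

    # P(attribution category c | independent route), per source combination.
    S = np.stack(
        [
            A_true * B_imp_true,
            A_true * (1.0 - B_imp_true),
            A_false * B_imp_false,
            A_false * (1.0 - B_imp_false),
        ],
        axis=-1,
    )  # (..., 4 sources, 4 categories)

    eye = np.eye(4)
    P_src = d[..., :, None] * eye + (1.0 - d[..., :, None]) * S

    # Source guessing for undetected items (and distractors guessed old).
    G = np.stack(
        [
            g_ver * g_imp_t,
            g_ver * (1.0 - g_imp_t),
            (1.0 - g_ver) * g_imp_f,
            (1.0 - g_ver) * (1.0 - g_imp_f),
        ],
        axis=-1,
    )  # (..., 4 categories)

    old_target = (
        D[..., :, None] * P_src
        + (1.0 - D[..., :, None]) * b[..., None, None] * G[..., None, :]
    )
    new_target = (1.0 - D) * (1.0 - b[..., None])
    target_block = np.concatenate([new_target[..., :, None], old_target], axis=-1)

    new_distractor = D_new + (1.0 - D_new) * (1.0 - b)
    old_distractor = ((1.0 - D_new) * b)[..., None] * G
    distractor_row = np.concatenate(
        [new_distractor[..., None], old_distractor], axis=-1
    )

    return np.concatenate([target_block, distractor_row[..., None, :]], axis=-2)


def category_probabilities(
    params: ParameterVector, item_type: ItemType
) -> np.ndarray:
    """Probability vector over the 5 response categories for one item type."""
    return category_probability_matrix(params.values)[item_type.index]


def log_likelihood_matrix(values: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Product-multinomial log-likelihood, vectorized over participants.

    ``values`` has shape ``(P, 24)``, ``counts`` shape ``(P, 5, 5)``; returns
    shape ``(P,)``.  A zero-probability category with a positive count yields
    ``-inf``; with a zero count it contributes 0 (the 0*log0 convention).
    """
    probs = category_probability_matrix(values)
    counts = np.asarray(counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(probs)
        term = np.where(counts > 0, counts * logp, 0.0)
    return term.sum(axis=(-2, -1))


def log_likelihood(params: ParameterVector, table: FrequencyTable) -> float:
    """Multinomial log-likelihood of one participant's frequency table."""
    return float(log_likelihood_matrix(params.values[None, :], table.counts[None])[0])
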