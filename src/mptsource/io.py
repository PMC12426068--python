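"""Readers, writers and response coding.

Frequency tables are plain delimited text: one row per participant, columns
``<itemtype>_<category>`` in the fixed item-type (TI, TU, FI, FU, new) and
category (new, old_TI, old_TU, old_FI, old_FU) orders.  Trial records carry
one row per test item.  The trial reader accepts a column-name mapping so
that externally deposited files with a different dialect can be ingested
without rewriting them.
"""

from __future__ import annotations

import enum
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DesignSpec
from .model import (
    CATEGORY_LABELS,
    ITEM_TYPE_LABELS,
    ConstraintSet,
    FrequencyTable,
    ItemType,
)
from .paths import enumerate_tree_paths
from .simulate import TRIAL_COLUMNS

__all__ = [
    "CodingRule",
    "build_frequency_tables",
    "read_frequency_tables",
    "write_frequency_tables",
    "read_trials",
    "write_trials",
    "write_eqn",
]

logger = logging.getLogger(__name__)

FREQ_COLUMNS = tuple(
    f"{t}_{c}" for t in ITEM_TYPE_LABELS for c in CATEGORY_LABELS
)


class CodingRule(enum.Enum):
    """How Remember/Know tags enter the frequency tables.

    ``REMEMBER_ONLY``: an "old" response tagged Know is recoded as "new"
    (keeping row totals fixed, as the multinomial likelihood requires).
    ``REMEMBER_PLUS_KNOW``: every "old" response counts.
    """

    REMEMBER_ONLY = "remember_only"
    REMEMBER_PLUS_KNOW = "remember_plus_know"


_CAT_INDEX = {c: i for i, c in enumerate(CATEGORY_LABELS)}
_TYPE_INDEX = {t: i for i, t in enumerate(ITEM_TYPE_LABELS)}


def _category_label(ver: str, imp: str) -> str:
    key = ("T" if ver == "true" else "F") + ("I" if imp == "important" else "U")
    return "old_" + key


def build_frequency_tables(
    records: pd.DataFrame,
    rule: CodingRule,
    design: DesignSpec,
    drop_know_trials: bool = False,
) -> list[FrequencyTable]:
    """Aggregate trial records into per-participant frequency tables.

    Under ``REMEMBER_ONLY`` an old-Know response is recoded as "new" by
    default; with ``drop_know_trials=True`` those trials are excluded instead
    (changing row totals, in which case each table's ``items_per_type`` is
    taken from the retained trials).  Participants with an incomplete trial
    set are excluded with a logged warning; duplicated (participant, item)
    pairs or unknown item types raise.
    """
    df = records
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial records are missing columns: {sorted(missing)}")
    if df.duplicated(subset=["participant", "item_id"]).any():
        raise ValueError("duplicate (participant, item_id) pairs in trial records")
    unknown = set(df["item_type"]) - set(ITEM_TYPE_LABELS)
    if unknown:
        raise ValueError(f"unknown item types: {sorted(unknown)}")

    expected_total = design.n_test_items
    tables: list[FrequencyTable] = []
    for pid, grp in df.groupby("participant", sort=True):
        if len(grp) != expected_total:
            logger.warning(
                "participant %s has %d trials (expected %d); excluded",
                pid, len(grp), expected_total,
            )
            continue
        grp = grp.copy()
        old = grp["old_new_response"].str.lower() == "old"
        know = grp["remember_know"].fillna("").str.lower() == "know"
        if rule is CodingRule.REMEMBER_ONLY:
            if drop_know_trials:
                grp = grp[~(old & know)]
                old = grp["old_new_response"].str.lower() == "old"
            else:
                old = old & ~know
        counts = np.zeros((5, 5), dtype=np.int64)
        t_idx = grp["item_type"].map(_TYPE_INDEX).to_numpy()
        cat = np.zeros(len(grp), dtype=np.int64)
        old_arr = old.to_numpy()
        ver = grp["veracity_response"].fillna("").str.lower().to_numpy()
        imp = grp["importance_response"].fillna("").str.lower().to_numpy()
        for i in np.flatnonzero(old_arr):
            cat[i] = _CAT_INDEX[_category_label(ver[i], imp[i])]
        np.add.at(counts, (t_idx, cat), 1)
        items = counts.sum(axis=1)
        tables.append(
            FrequencyTable(participant_id=str(pid), counts=counts, items_per_type=items)
        )
    return tables


def write_frequency_tables(
    tables: Sequence[FrequencyTable], path: str | Path
) -> None:
    rows = {t.participant_id: t.counts.ravel() for t in tables}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FREQ_COLUMNS))
    df.index.name = "participant"
    df.to_csv(path)


def read_frequency_tables(path: str | Path) -> list[FrequencyTable]:
    df = pd.read_csv(path, index_col="participant")
    missing = set(FREQ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"frequency file missing columns: {sorted(missing)}")
    tables = []
    for pid, row in df[list(FREQ_COLUMNS)].iterrows():
        counts = row.to_numpy(dtype=np.int64).reshape(5, 5)
        tables.append(
            FrequencyTable(
                participant_id=str(pid),
                counts=counts,
                items_per_type=counts.sum(axis=1),
            )
        )
    return tables


def write_trials(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_trials(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read trial-level records; ``dialect`` maps our column names to theirs."""
    df = pd.read_csv(path, dtype=str).fillna("")
    if dialect:
        rename = {v: k for k, v in dialect.items()}
        df = df.rename(columns=rename)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial file missing columns: {sorted(missing)}")
    return df[list(TRIAL_COLUMNS)]


_TREE_NAMES = {
    ItemType.TARGET_TI: "target_TI",
    ItemType.TARGET_TU: "target_TU",
    ItemType.TARGET_FI: "target_FI",
    ItemType.TARGET_FU: "target_FU",
    ItemType.DISTRACTOR: "distractor",
}


def write_eqn(path: str | Path, constraints: ConstraintSet | None = None) -> None:
    """Export the tree as a standard MPT ``.eqn`` file.

    One line per root-to-leaf path: tree name, response category, product of
    parameter terms using ``X`` / ``(1-X)`` notation.  If a constraint set is
    given, parameters are renamed to their free-parameter labels, yielding the
    constrained model.
    """
    rename: dict[str, str] = {}
    if constraints is not None:
        for free, members in constraints.groups:
            for m in members:
                rename[m] = free

    lines = []
    for item_type in ItemType:
        tree = _TREE_NAMES[item_type]
        for p in enumerate_tree_paths(item_type):
            factors = [(rename.get(n, n), comp) for n, comp in p.factors]
            term = "*".join(f"(1-{n})" if comp else n for n, comp in factors)
            lines.append(f"{tree} {p.category.value} {term}")
    text = f"{len(lines)}\n" + "\n".join(lines) + "\n"
    Path(path).write_text(text)
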