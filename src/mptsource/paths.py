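"""Explicit root-to-leaf enumeration of the source-memory processing tree.

This walks the tree branch by branch and is deliberately kept independent of
the closed-form algebra in :mod:`mptsource.model`: summing path products per
response category must reproduce ``category_probabilities`` exactly, which the
test suite uses as an oracle.  The same path lists drive the ``.eqn`` export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ItemType, ParameterVector, ResponseCategory

__all__ = ["Factor", "TreePath", "enumerate_tree_paths", "evaluate_paths", "path_term"]

# A branch factor: (parameter name, complement?). complement=True means (1 - x).
Factor = tuple[str, bool]


@dataclass(frozen=True)
class TreePath:
    """One root-to-leaf path: a product of branch factors and its outcome."""

    factors: tuple[Factor, ...]
    category: ResponseCategory

    def probability(self, params: ParameterVector) -> float:
        p = 1.0
        for name, complement in self.factors:
            x = params[name]
            p *= (1.0 - x) if complement else x
        return p


def _category(veracity_response: str, importance_response: str) -> ResponseCategory:
    key = ("T" if veracity_response == "true" else "F") + (
        "I" if importance_response == "important" else "U"
    )
    return ResponseCategory["OLD_" + key]


def _source_guess_paths(prefix: tuple[Factor, ...]) -> list[TreePath]:
    """Guessing branches for items judged old without source retrieval (g)."""
    out = []
    for ver, ver_comp in (("true", False), ("false", True)):
        g_imp = "g_imp_true" if ver == "true" else "g_imp_false"
        for imp, imp_comp in (("important", False), ("unimportant", True)):
            out.append(
                TreePath(
                    prefix + (("g_ver", ver_comp), (g_imp, imp_comp)),
                    _category(ver, imp),
                )
            )
    return out


def enumerate_tree_paths(item_type: ItemType) -> list[TreePath]:
    """All root-to-leaf paths of the tree for one item type.

    Targets from source (i, j) have 15 paths: joint retrieval (1); detection
    with independent retrieval/guessing of veracity then importance (9);
    non-detection with old-guessing plus source guessing (4) or new-guessing
    (1).  Distractors have 6.
    """
    if item_type is ItemType.DISTRACTOR:
        paths = [TreePath((("D_new", False),), ResponseCategory.NEW)]
        undetected: tuple[Factor, ...] = (("D_new", True),)
        paths.extend(_source_guess_paths(undetected + (("b", False),)))
        paths.append(TreePath(undetected + (("b", True),), ResponseCategory.NEW))
        return paths

    combo = item_type.source
    assert combo is not None
    key = combo.name
    D, d = f"D_{key}", f"d_{key}"
    e_ver, e_imp = f"e_ver_{key}", f"e_imp_{key}"

    paths = [TreePath(((D, False), (d, False)), _category(combo.veracity, combo.importance))]

    # Detected, joint retrieval failed: veracity stage then importance stage.
    base: tuple[Factor, ...] = ((D, False), (d, True))
    ver_branches: list[tuple[tuple[Factor, ...], str]] = [
        (base + ((e_ver, False),), combo.veracity),  # retrieved -> correct
        (base + ((e_ver, True), ("a_ver", False)), "true"),
        (base + ((e_ver, True), ("a_ver", True)), "false"),
    ]
    for prefix, ver in ver_branches:
        a_imp = "a_imp_true" if ver == "true" else "a_imp_false"
        paths.append(
            TreePath(prefix + ((e_imp, False),), _category(ver, combo.importance))
        )
        paths.append(TreePath(prefix + ((e_imp, True), (a_imp, False)), _category(ver, "important")))
        paths.append(TreePath(prefix + ((e_imp, True), (a_imp, True)), _category(ver, "unimportant")))

    # Not detected: guess old (with source guessing) or new.
    undetected = ((D, True),)
    paths.extend(_source_guess_paths(undetected + (("b", False),)))
    paths.append(TreePath(undetected + (("b", True),), ResponseCategory.NEW))
    return paths


def evaluate_paths(item_type: ItemType, params: ParameterVector) -> np.ndarray:
    """Category probabilities obtained purely by summing path products."""
    out = np.zeros(len(ResponseCategory))
    for path in enumerate_tree_paths(item_type):
        out[path.category.index] += path.probability(params)
    return out


def path_term(path: TreePath) -> str:
    """The path's product as an ``.eqn``-style term, e.g. ``D_TI*(1-d_TI)*a_ver``."""
    parts = [f"(1-{name})" if comp else name for name, comp in path.factors]
    return "*".join(parts)
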