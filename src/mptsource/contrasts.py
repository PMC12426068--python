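"""Posterior contrasts between group-level parameters.

Differences are computed draw by draw on the probability scale (the scale on
which the study reports them), summarized by the posterior median and an
equal-tailed 95% credibility interval; a contrast is credited as a difference
when its interval excludes zero.  No multiplicity correction is applied
across the battery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorSamples

__all__ = ["ContrastResult", "difference", "standard_contrast_battery"]

# The standard battery: joint retrieval of the true-important source vs the
# other combinations, the two dimension-memory parameters, and item memory.
BATTERY = (
    ("delta_d", "d_TI", "d_TU"),
    ("delta_d1", "d_TI", "d_FI"),
    ("delta_d2", "d_TI", "d_FU"),
    ("delta_e", "e_ver", "e_imp"),
    ("delta_D", "D_TI", "D_TU"),
    ("delta_D1", "D_TI", "D_FI"),
    ("delta_D2", "D_TI", "D_FU"),
)


@dataclass
class ContrastResult:
    """A sampled parameter difference with its credibility interval."""

    name: str
    delta_median: float
    bci: tuple[float, float]
    excludes_zero: bool
    draws: np.ndarray | None = None

    def to_dict(self) -> dict[str, object]:
        return {
            "name": self.name,
            "delta_median": self.delta_median,
            "lower": self.bci[0],
            "upper": self.bci[1],
            "excludes_zero": self.excludes_zero,
        }


def difference(
    samples: PosteriorSamples,
    param_a: str,
    param_b: str,
    credibility: float = 0.95,
    name: str | None = None,
) -> ContrastResult:
    """Posterior difference ``param_a - param_b`` on the probability scale."""
    delta = samples.group_draws(param_a) - samples.group_draws(param_b)
    alpha = (1.0 - credibility) / 2.0
    lower = float(np.quantile(delta, alpha))
    upper = float(np.quantile(delta, 1.0 - alpha))
    return ContrastResult(
        name=name or f"{param_a}-{param_b}",
        delta_median=float(np.median(delta)),
        bci=(lower, upper),
        excludes_zero=not (lower <= 0.0 <= upper),
        draws=delta,
    )


def standard_contrast_battery(
    samples: PosteriorSamples, credibility: float = 0.95
) -> list[ContrastResult]:
    """The study's seven contrasts: Δd, Δd1, Δd2, Δe, ΔD, ΔD1, ΔD2.

    Requires a fit under the standard constraint set (free parameters include
    ``d_*``, ``e_ver``, ``e_imp``, ``D_*``).
    """
    missing = {
        p for _, a, b in BATTERY for p in (a, b) if p not in samples.free_names
    }
    if missing:
        raise KeyError(
            f"contrast battery needs free parameters {sorted(missing)}; "
            "fit with the standard constraint set"
        )
    return [
        difference(samples, a, b, credibility=credibility, name=name)
        for name, a, b in BATTERY
    ]


def battery_frame(results: list[ContrastResult]) -> pd.DataFrame:
    """Tabular view of a contrast battery."""
    return pd.DataFrame([r.to_dict() for r in results]).set_index("name")
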