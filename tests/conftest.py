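import numpy as np
import pytest

from mptsource import DesignSpec, ParameterVector, paper_constraints
from mptsource.model import N_PARAMS, PARAM_NAMES


@pytest.fixture(scope="session")
def paper_cs():
    return paper_constraints()


@pytest.fixture(scope="session")
def design():
    return DesignSpec()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_parameter_vectors(n: int, seed: int = 0) -> np.ndarray:
    """Uniform random full parameter vectors, shape (n, 24)."""
    return np.random.default_rng(seed).random((n, N_PARAMS))


def params_with(overrides: dict[str, float], base: float = 0.5) -> ParameterVector:
    """Full parameter vector at ``base`` with selected entries overridden.

    Accepts full parameter names and the standard free names (``e_ver``,
    ``e_imp``), which expand to their equated members.
    """
    members = dict(paper_constraints().groups)
    values = {n: base for n in PARAM_NAMES}
    for key, val in overrides.items():
        if key in values:
            values[key] = val
        elif key in members:
            for m in members[key]:
                values[m] = val
        else:
            raise KeyError(key)
    return ParameterVector.from_dict(values)
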