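import numpy as np
import pandas as pd
import pytest

from metgblup.covstruct import ResidualStructure
from metgblup.grm import KinshipMatrix


def random_pd(l, rng, ridge=0.3):
    A = rng.standard_normal((l, l + 2))
    return A @ A.T / (l + 2) + ridge * np.eye(l)


def random_kinship(n, rng, ridge=0.2):
    """Small dense PD kinship with generic eigenstructure."""
    A = rng.standard_normal((n, n + 3))
    return KinshipMatrix(A @ A.T / (n + 3) + ridge * np.eye(n), [f"L{i}" for i in range(n)])


def random_structure(kind, l, rng):
    if kind == "US":
        return ResidualStructure("US", l, random_pd(l, rng)[np.tril_indices(l)])
    if kind == "IDH":
        return ResidualStructure("IDH", l, rng.uniform(0.5, 2.0, l))
    if kind == "IDV":
        return ResidualStructure("IDV", l, np.array([rng.uniform(0.5, 2.0)]))
    return ResidualStructure(
        "ANT1",
        l,
        np.concatenate([rng.uniform(0.7, 1.5, l), rng.uniform(-0.6, 0.6, l - 1)]),
    )


def long_phenotypes(y_cells, line_ids, env_ids, drop_frac=0.0, rng=None):
    """Long table from an n x l cell matrix, optionally dropping cells."""
    rows = []
    for e, env in enumerate(env_ids):
        for i, line in enumerate(line_ids):
            rows.append({"line": line, "env": env, "value": y_cells[i, e]})
    ph = pd.DataFrame(rows)
    if drop_frac:
        keep = rng.random(len(ph)) >= drop_frac
        ph = ph[keep].reset_index(drop=True)
    return ph


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
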