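"""Shared fixtures: small tables and panels built programmatically."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from conjfdr.ld import LDPanel


@pytest.fixture
def micro_pair():
    """The worked 5-SNP trait pair with known conditional/conjunction FDRs."""
    p1 = np.array([0.01, 0.2, 0.3, 0.05, 0.5])
    p2 = np.array([0.04, 0.03, 0.5, 0.02, 0.9])
    return p1, p2


def make_panel(pairs, n=None, ids=None):
    """Panel from a list of (i, j, r2) index pairs."""
    if ids is None:
        n = n or (max((max(i, j) for i, j, _ in pairs), default=-1) + 1)
        ids = [f"s{k}" for k in range(n)]
    n = len(ids)
    if pairs:
        rows = [p[0] for p in pairs] + [p[1] for p in pairs]
        cols = [p[1] for p in pairs] + [p[0] for p in pairs]
        vals = [p[2] for p in pairs] * 2
        mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    else:
        mat = sp.coo_matrix((n, n))
    return LDPanel(ids, mat)


@pytest.fixture
def chain_panel():
    """s0-s1 (0.9), s1-s2 (0.9), s0-s2 (0.1): pruning keeps {s1} or {s0, s2}."""
    return make_panel([(0, 1, 0.9), (1, 2, 0.9), (0, 2, 0.1)])


@pytest.fixture
def tiny_reference():
    return pd.DataFrame(
        {
            "SNP": ["rs1", "rs2", "rs3", "rs4", "rs5"],
            "CHR": [1, 1, 2, 2, 6],
            "BP": [100, 200, 100, 200, 30_000_000],
            "A1": ["A", "A", "C", "T", "A"],
            "A2": ["G", "C", "T", "G", "G"],
        }
    )
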