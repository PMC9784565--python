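"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (nested Python loops, direct
formula evaluation) and never call the implementation paths they audit.
"""

import math

import numpy as np
import pytest

from fodm import toy_fixture


# ---------------------------------------------------------------- oracles

def levitt_oracle(r: float, c: float) -> float:
    """Direct polynomial evaluation of the contact function."""
    if r > c:
        return 0.0
    x = r / c
    return 1.0 - 0.5 * (7 * x**2 - 9 * x**4 + 5 * x**6 - x**8)


def observed_oracle(positions, h, cutoff: float) -> np.ndarray:
    """O(N^2) double-loop observed profile, symmetric pair form with the
    i == j self term included; normalized."""
    n = len(h)
    raw = np.zeros(n)
    for j in range(n):
        for i in range(n):
            r = math.dist(positions[i], positions[j])
            raw[j] += (h[i] + h[j]) * levitt_oracle(r, cutoff)
    return raw / raw.sum()


def kl_oracle(p, q) -> float:
    """Term-by-term base-2 divergence."""
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            total += pi * math.log2(pi / qi)
    return total


def fit_k_oracle(o_vals, t_vals, grid) -> float:
    """Exhaustive scan with naive arithmetic: build M at every grid K,
    evaluate the divergence, take the first minimum."""
    k_min, k_max, step = grid
    n_pts = int(round((k_max - k_min) / step)) + 1
    tmax = max(t_vals)
    best_k, best_d = None, math.inf
    for idx in range(n_pts):
        k = round(k_min + idx * step, 10)
        raw = [t + k * (tmax - t) for t in t_vals]
        s = sum(raw)
        m = [max(v / s, 1e-12) for v in raw]
        d = kl_oracle(o_vals, m)
        if d < best_d - 1e-15:
            best_d, best_k = d, k
    return best_k


def random_rotation(rng) -> np.ndarray:
    """A proper rotation matrix from a QR decomposition of Gaussian noise."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# ---------------------------------------------------------------- fixtures

@pytest.fixture
def toy_cloud():
    return toy_fixture()


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   0.000   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.000   1.000   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.000  -1.000   0.500  1.00  0.00           C
ATOM      6  N   GLY A   2       3.000   0.500   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       4.000   0.500   1.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.000   0.500   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       5.000   1.500   0.000  1.00  0.00           O
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   5       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   5       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   SER A   5       2.000   0.000   0.000  1.00  0.00           C
ATOM      4  O   SER A   5       3.000   0.000   0.000  1.00  0.00           O
ATOM      5  CB ASER A   5       1.000   2.000   0.000  0.60  0.00           C
ATOM      6  CB BSER A   5       1.000  -2.000   0.000  0.40  0.00           C
ATOM      7  N   LEU A   6       4.000   0.000   0.000  1.00  0.00           N
ATOM      8  CA  LEU A   6       5.000   0.000   0.000  1.00  0.00           C
ATOM      9  C   LEU A   6       6.000   0.000   0.000  1.00  0.00           C
ATOM     10  O   LEU A   6       7.000   0.000   0.000  1.00  0.00           O
HETATM   11 FE    FE A 501       1.500   0.100   0.100  1.00  0.00          FE
HETATM   12  O   HOH A 601      20.000  20.000  20.000  1.00  0.00           O
TER
END
"""


@pytest.fixture
def minimal_pdb_text():
    return MINIMAL_PDB


@pytest.fixture
def altloc_pdb_text():
    return ALTLOC_PDB
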