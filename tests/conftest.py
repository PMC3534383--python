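"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own code paths:
exhaustive subset enumeration for GDT, brute-force Mann-Whitney pair
counting for AUC, and run enumeration for insertion trimming.
"""

from __future__ import annotations

from itertools import combinations, groupby

import numpy as np
import pytest

from mrprime import synthetic
from mrprime.accuracy import kabsch_superpose
from mrprime.structure_model import Atom, Residue, StructureModel


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def native50() -> StructureModel:
    return synthetic.make_native(50, seed=7)


@pytest.fixture(scope="session")
def native100() -> StructureModel:
    return synthetic.make_native(100, seed=11)


@pytest.fixture()
def tiny_model() -> StructureModel:
    """Three residues with full ideal-ish atom sets, built by hand."""
    residues = []
    for i, aa in enumerate("AGW", start=1):
        base = np.array([3.8 * i, 0.0, 0.0])
        atoms = [
            Atom("N", "N", base + [0.0, 1.4, 0.0]),
            Atom("CA", "C", base),
            Atom("C", "C", base + [1.5, 0.0, 0.0]),
            Atom("O", "O", base + [1.5, 1.2, 0.0]),
        ]
        if aa != "G":
            atoms.append(Atom("CB", "C", base + [0.0, -1.5, 0.0]))
        residues.append(Residue(i, aa, atoms))
    return StructureModel("tiny", residues)


def random_rigid_motion(rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a random translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=20.0, size=3)
    return Q, t


def rigidly_move(model: StructureModel, R: np.ndarray, t: np.ndarray
                 ) -> StructureModel:
    out = model.copy()
    for res in out.residues:
        for atom in res.atoms:
            atom.position = R @ atom.position + t
    return out


@pytest.fixture()
def rigid_motion():
    return random_rigid_motion, rigidly_move


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def gdt_oracle(X: np.ndarray, Y: np.ndarray,
               cutoffs=(1.0, 2.0, 4.0, 8.0)) -> float:
    """Exhaustive GDT: best inlier count over Kabsch fits on EVERY subset
    of size >= 3.  Exponential; use only on toy instances."""
    n = len(X)
    best = {c: 0 for c in cutoffs}
    for k in range(3, n + 1):
        for subset in combinations(range(n), k):
            S = np.array(subset)
            try:
                R, t, _ = kabsch_superpose(X[S], Y[S])
            except ValueError:
                continue
            d = np.linalg.norm(X @ R.T + t - Y, axis=1)
            for c in cutoffs:
                cnt = int(np.sum(d <= c + 1e-9))
                if cnt > best[c]:
                    best[c] = cnt
    return 100.0 * float(np.mean([best[c] / n for c in cutoffs]))


def auc_oracle(scores, labels) -> float:
    """Mann-Whitney AUC by explicit pair enumeration with tie half-credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (len(pos) * len(neg))


def trim_oracle(mapped_flags: list[bool], max_len: int) -> list[bool]:
    """Which positions survive trimming: brute-force run enumeration."""
    keep = []
    pos = 0
    for is_mapped, group in groupby(mapped_flags):
        run = len(list(group))
        survive = is_mapped or run <= max_len
        keep.extend([survive] * run)
        pos += run
    return keep
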