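"""Seeded synthetic fixtures with known ground truth.

Every generator is a pure function of its parameters and an integer seed.
The structural generators build a compact self-avoiding CA trace with
idealized local geometry (consecutive CA-CA = 3.8 A; N, C, O and, for
non-glycine residues, CB placed at fixed offsets in a local frame) — not
a physically realistic backbone, but geometrically sufficient for
superposition, GDT and consensus-distance arithmetic.  Decoys are natives
plus per-residue isotropic Gaussian coordinate noise, so the true local
deviation of every residue is known exactly.  The feature-table generator
draws alignment features in plausible ranges (cumulative column-count
invariant enforced by construction) and labels them from a known logistic
model, giving an exact parameter-recovery target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .accuracy import AccuracyProfile
from .amigomr import FEATURE_NAMES
from .consensus import DecoyEnsemble
from .structure_model import Atom, Residue, StructureModel, TargetAlignment

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
CA_CA = 3.8


@dataclass
class NoiseSpec:
    """Per-residue coordinate noise (A standard deviation) plus a seed."""

    per_residue_sigma: dict[int, float]
    seed: int

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.per_residue_sigma.values()):
            raise ValueError("sigma must be >= 0")


@dataclass
class LogisticSpec:
    """Generative logistic model for feature-table fixtures."""

    coefficients: dict[str, float]
    intercept: float
    n_rows: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ValueError("n_rows must be >= 1")
        unknown = set(self.coefficients) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def make_native(n_residues: int, seed: int, clash_distance: float = 3.5
                ) -> StructureModel:
    """A self-avoiding CA walk decorated with idealized backbone atoms.

    Consecutive CA-CA distances are exactly 3.8 A; non-adjacent CAs are
    kept at least ``clash_distance`` apart (relaxed stepwise if the walk
    gets stuck, which is rare below a few hundred residues).
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    ca = np.zeros((n_residues, 3))
    direction = _random_unit(rng)
    for i in range(1, n_residues):
        placed = False
        clash = clash_distance
        while not placed:
            for _ in range(100):
                # persistent walk: bias toward the previous direction
                proposal = _unit(direction + 0.9 * _random_unit(rng))
                candidate = ca[i - 1] + CA_CA * proposal
                if i < 2 or np.all(
                        np.linalg.norm(ca[:i - 1] - candidate, axis=1) >= clash):
                    ca[i] = candidate
                    direction = proposal
                    placed = True
                    break
            clash *= 0.9  # stuck: relax the clash criterion slightly

    seq = rng.choice(list(_AA20), size=n_residues)
    residues = []
    for i in range(n_residues):
        t = _unit(ca[min(i + 1, n_residues - 1)] - ca[max(i - 1, 0)])
        helper = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(t, helper)) > 0.9:
            helper = np.array([1.0, 0.0, 0.0])
        u = _unit(np.cross(t, helper))
        w = np.cross(t, u)
        pos = ca[i]
        atoms = [
            Atom("N", "N", pos - 1.46 * t + 0.40 * u),
            Atom("CA", "C", pos.copy()),
            Atom("C", "C", pos + 1.52 * t),
            Atom("O", "O", pos + 1.52 * t + 1.23 * u),
        ]
        aa = str(seq[i])
        if aa != "G":
            atoms.append(Atom("CB", "C", pos + 1.53 * (-0.43 * t + 0.9 * w)))
        residues.append(Residue(i + 1, aa, atoms))
    return StructureModel(f"native_s{seed}_n{n_residues}", residues)


def make_decoy(native: StructureModel, noise: NoiseSpec,
               model_id: str | None = None
               ) -> tuple[StructureModel, AccuracyProfile]:
    """Native plus isotropic Gaussian noise; returns the realized truth.

    The returned profile holds the actual displacement of each atom (and
    each residue's CA) *before* any superposition; measured deviations
    recover it up to superposition effects.
    """
    missing = [r.seq_index for r in native.residues
               if r.seq_index not in noise.per_residue_sigma]
    if missing:
        raise ValueError(f"sigma map missing residues {missing}")
    rng = np.random.default_rng(noise.seed)
    decoy = native.copy(model_id=model_id or f"{native.model_id}_decoy")
    per_residue: dict[int, float] = {}
    per_atom: dict[tuple[int, str], float] = {}
    for res in decoy.residues:
        sigma = noise.per_residue_sigma[res.seq_index]
        for atom in res.atoms:
            shift = rng.normal(0.0, sigma, size=3) if sigma > 0 else np.zeros(3)
            atom.position = atom.position + shift
            u = float(np.linalg.norm(shift))
            per_atom[(res.seq_index, atom.name)] = u
            if atom.name == "CA":
                per_residue[res.seq_index] = u
    return decoy, AccuracyProfile(per_residue, per_atom)


def make_ensemble(native: StructureModel, sigmas: list[float], seed: int
                  ) -> DecoyEnsemble:
    """One decoy per sigma, base-scored by -sigma (known ranking)."""
    if len(sigmas) < 2:
        raise ValueError("need at least 2 sigmas")
    models, scores = [], {}
    for i, sigma in enumerate(sigmas):
        spec = NoiseSpec({r.seq_index: float(sigma) for r in native.residues},
                         seed=seed * 100003 + i)
        decoy, _ = make_decoy(native, spec, model_id=f"m{i:02d}")
        models.append(decoy)
        scores[decoy.model_id] = -float(sigma)
    return DecoyEnsemble(native.model_id, models, scores)


def make_alignment_fixture(model_len: int, insertions: list[tuple[int, int]],
                           seed: int) -> TargetAlignment:
    """An alignment in which the stated model runs are unmapped insertions.

    ``insertions`` are (1-based start position, length) runs on the model
    sequence; they must not overlap.  All other model positions map to
    consecutive target positions.
    """
    occupied: set[int] = set()
    for start, length in insertions:
        run = set(range(start, start + length))
        if start < 1 or start + length - 1 > model_len:
            raise ValueError(f"insertion ({start}, {length}) out of bounds")
        if run & occupied:
            raise ValueError("insertions overlap")
        occupied |= run
    rng = np.random.default_rng(seed)
    model_seq = "".join(rng.choice(list(_AA20), size=model_len))
    mapping = []
    target_chars = []
    tpos = 0
    for m in range(1, model_len + 1):
        if m in occupied:
            target_chars.append("-")
        else:
            tpos += 1
            mapping.append((tpos, m))
            target_chars.append(model_seq[m - 1])
    return TargetAlignment("".join(target_chars), model_seq, mapping)


def make_feature_table(spec: LogisticSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table + Bernoulli labels from a known logistic structure."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rows
    aligned = rng.integers(60, 400, size=n)
    target_length = aligned + rng.integers(0, 80, size=n)
    fracs = np.sort(rng.random(size=(n, 4)), axis=1)  # cumulative by design
    ge_1_5 = np.floor(fracs[:, 0] * aligned).astype(int)
    ge_0_5 = np.floor(fracs[:, 1] * aligned).astype(int)
    ge_m0_5 = np.floor(fracs[:, 2] * aligned).astype(int)
    ge_m1_5 = np.floor(fracs[:, 3] * aligned).astype(int)
    X = pd.DataFrame({
        "global_score": rng.normal(50.0, 15.0, size=n),
        "aligned_columns": aligned,
        "seq_identity": rng.beta(2.0, 4.0, size=n),
        "gap_fraction": rng.beta(2.0, 8.0, size=n),
        "target_length": target_length,
        "ge_1_5": ge_1_5,
        "ge_0_5": ge_0_5,
        "ge_m0_5": ge_m0_5,
        "ge_m1_5": ge_m1_5,
        "below_m1_5": aligned - ge_m1_5,
    }, columns=list(FEATURE_NAMES))
    eta = np.full(n, spec.intercept, dtype=float)
    for name, coef in spec.coefficients.items():
        eta += coef * X[name].to_numpy(dtype=float)
    labels = (rng.random(n) < expit(eta)).astype(int)
    return X, labels
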