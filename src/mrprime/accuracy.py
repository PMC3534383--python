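"""Model accuracy against a reference structure.

Sequence-dependent superposition (Kabsch least-squares) and the measures
built on it:

* per-residue / per-atom positional deviation ``u`` (the quantity encoded
  into B-factors by :mod:`mrprime.structure_model`),
* CA RMSD after optimal superposition,
* GDT_TS — the mean over distance cutoffs {1, 2, 4, 8} A of the largest
  fraction of CA atoms that can be brought within the cutoff by a rigid
  fit, scaled to [0, 100],
* the geometric MR-success criterion: at least half of the target's
  C-alpha chain rebuilt.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_model import StructureModel

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)


class SuperpositionError(ValueError):
    """Raised for degenerate or mismatched coordinate sets."""


@dataclass
class ResidueMapping:
    """Aligned residue pairs (model_res_index, reference_res_index)."""

    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        a = [p[0] for p in self.pairs]
        b = [p[1] for p in self.pairs]
        if sorted(set(a)) != a or sorted(set(b)) != b:
            raise ValueError("mapping must be strictly increasing on both sides")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AccuracyProfile:
    """Per-residue (and optionally per-atom) positional deviations in A."""

    per_residue_u: dict[int, float]
    per_atom_u: dict[tuple[int, str], float] | None = None

    def __post_init__(self) -> None:
        vals = list(self.per_residue_u.values())
        if self.per_atom_u:
            vals += list(self.per_atom_u.values())
        arr = np.asarray(vals, dtype=float)
        if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr < 0)):
            raise ValueError("deviations must be finite and >= 0")


@dataclass
class GlobalQuality:
    ca_rmsd: float
    gdt_ts: float
    n_mapped: int

    def to_dict(self) -> dict:
        return {"ca_rmsd": self.ca_rmsd, "gdt_ts": self.gdt_ts,
                "n_mapped": self.n_mapped}


# --------------------------------------------------------------------------
# Kabsch engine
# --------------------------------------------------------------------------

def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns ``(R, t, rmsd)`` with the proper rotation R (det = +1) and
    translation t such that ``moving @ R.T + t`` minimizes the RMSD to
    ``fixed``.
    """
    X = np.asarray(moving, dtype=float)
    Y = np.asarray(fixed, dtype=float)
    if X.shape != Y.shape:
        raise SuperpositionError(
            f"coordinate sets differ in shape: {X.shape} vs {Y.shape}")
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise SuperpositionError("need at least 3 points of dimension 3")
    cx = X.mean(axis=0)
    cy = Y.mean(axis=0)
    H = (X - cx).T @ (Y - cy)
    U, s, Vt = np.linalg.svd(H)
    # all-collinear sets leave the rotation about the axis undetermined
    if s[0] > 0 and s[1] / s[0] <= 1e-12:
        raise SuperpositionError("degenerate (collinear) coordinate set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cy - R @ cx
    moved = X @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Y) ** 2, axis=1))))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray
                    ) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ R.T + t


# --------------------------------------------------------------------------
# Mapping helpers
# --------------------------------------------------------------------------

def mapping_from_seq_index(model: StructureModel, reference: StructureModel
                           ) -> ResidueMapping:
    """Pair residues sharing a seq_index, keeping those with CA on both sides."""
    ref_idx = {r.seq_index for r in reference.residues if r.has_ca}
    pairs = [(r.seq_index, r.seq_index)
             for r in model.residues if r.has_ca and r.seq_index in ref_idx]
    return ResidueMapping(pairs)


def mapping_from_alignment(aln, model: StructureModel,
                           reference: StructureModel) -> ResidueMapping:
    """Build a model->reference mapping from a target alignment.

    Alignment target positions are interpreted as reference seq_index
    values; only columns where both residues exist and carry a CA are kept.
    """
    model_ok = {r.seq_index for r in model.residues if r.has_ca}
    ref_ok = {r.seq_index for r in reference.residues if r.has_ca}
    pairs = [(m, t) for t, m in aln.mapping if m in model_ok and t in ref_ok]
    return ResidueMapping(pairs)


def _mapped_ca(model: StructureModel, reference: StructureModel,
               mapping: ResidueMapping) -> tuple[np.ndarray, np.ndarray]:
    if not mapping.pairs:
        raise ValueError("empty residue mapping")
    X, Y = [], []
    for mi, ri in mapping.pairs:
        mres = model.residue(mi)
        rres = reference.residue(ri)
        if mres is None or rres is None:
            raise ValueError(f"mapping pair ({mi}, {ri}) absent from structures")
        mca, rca = mres.get("CA"), rres.get("CA")
        if mca is None or rca is None:
            raise ValueError(f"missing CA for mapped pair ({mi}, {ri})")
        X.append(mca.position)
        Y.append(rca.position)
    return np.asarray(X), np.asarray(Y)


# --------------------------------------------------------------------------
# Local accuracy
# --------------------------------------------------------------------------

def per_residue_deviation(model: StructureModel, reference: StructureModel,
                          mapping: ResidueMapping) -> AccuracyProfile:
    """Measure per-residue (CA) and per-atom deviations after one global fit.

    The model is superposed onto the reference over all mapped CA atoms;
    deviations are Euclidean distances under that single transform.
    Atom-level deviations are recorded for atoms whose names match in both
    residues.
    """
    X, Y = _mapped_ca(model, reference, mapping)
    R, t, _ = kabsch_superpose(X, Y)
    per_residue: dict[int, float] = {}
    per_atom: dict[tuple[int, str], float] = {}
    for mi, ri in mapping.pairs:
        mres = model.residue(mi)
        rres = reference.residue(ri)
        for atom in mres.atoms:
            counterpart = rres.get(atom.name)
            if counterpart is None:
                continue
            moved = R @ atom.position + t
            u = float(np.linalg.norm(moved - counterpart.position))
            per_atom[(mi, atom.name)] = u
            if atom.name == "CA":
                per_residue[mi] = u
    return AccuracyProfile(per_residue, per_atom)


def ca_rmsd(model: StructureModel, reference: StructureModel,
            mapping: ResidueMapping) -> float:
    """RMSD of mapped CA pairs under the optimal superposition."""
    X, Y = _mapped_ca(model, reference, mapping)
    _, _, rmsd = kabsch_superpose(X, Y)
    return rmsd


# --------------------------------------------------------------------------
# GDT_TS
# --------------------------------------------------------------------------

#: Mapped-set size up to which the GDT subset search is exhaustive.
GDT_EXHAUSTIVE_LIMIT = 10


def _gdt_seeds(n: int) -> tuple[list[np.ndarray], int]:
    """Deterministic seed subsets and iteration budget for the GDT search.

    Up to ``GDT_EXHAUSTIVE_LIMIT`` mapped pairs, every subset of size >= 3
    is fitted directly (a few hundred 3x3 SVDs), making the search exact;
    larger sets are seeded with sliding windows of lengths 3, 5 and 7 plus
    the full set and refined by iterative re-selection.
    """
    if n <= GDT_EXHAUSTIVE_LIMIT:
        from itertools import combinations

        seeds: list[np.ndarray] = []
        for k in range(3, n + 1):
            seeds.extend(np.array(c) for c in combinations(range(n), k))
        return seeds, 1
    seeds = [np.arange(n)]
    for w in (3, 5, 7):
        for start in range(0, n - w + 1):
            seeds.append(np.arange(start, start + w))
    return seeds, 10


def _gdt_best_count(X: np.ndarray, Y: np.ndarray, cutoff: float,
                    seeds: list[np.ndarray], max_iter: int = 10) -> int:
    """Largest number of pairs within ``cutoff`` under any examined fit.

    Each seed subset is superposed by Kabsch; pairs within the cutoff are
    re-selected and the fit repeated to a fixed point.  The recorded score
    for a fit is the count of *all* mapped pairs within the cutoff, so the
    single global fit provides a guaranteed lower bound.
    """
    n = len(X)
    best = 0
    tol = 1e-9
    for seed in seeds:
        S = seed
        seen: set[frozenset] = set()
        for _ in range(max_iter):
            try:
                R, t, _ = kabsch_superpose(X[S], Y[S])
            except SuperpositionError:
                break
            d = np.linalg.norm(X @ R.T + t - Y, axis=1)
            within = d <= cutoff + tol
            count = int(within.sum())
            if count > best:
                best = count
                if best == n:
                    return best
            newS = np.flatnonzero(within)
            key = frozenset(newS.tolist())
            if len(newS) < 3 or key == frozenset(S.tolist()) or key in seen:
                break
            seen.add(frozenset(S.tolist()))
            S = newS
    return best


def gdt_ts(model: StructureModel, reference: StructureModel,
           mapping: ResidueMapping,
           cutoffs: tuple[float, ...] = GDT_CUTOFFS) -> float:
    """GDT total score in [0, 100] over the mapped CA pairs.

    For each cutoff the largest superposable fraction is searched with a
    deterministic iterative-refit heuristic (see :func:`_gdt_best_count`);
    the score is 100 times the mean fraction over the cutoffs.
    """
    X, Y = _mapped_ca(model, reference, mapping)
    n = len(X)
    if n < 3:
        raise ValueError("GDT needs at least 3 mapped pairs")
    seeds, max_iter = _gdt_seeds(n)
    fractions = [_gdt_best_count(X, Y, c, seeds, max_iter) / n
                 for c in cutoffs]
    return 100.0 * float(np.mean(fractions))


def global_quality(model: StructureModel, reference: StructureModel,
                   mapping: ResidueMapping) -> GlobalQuality:
    return GlobalQuality(ca_rmsd(model, reference, mapping),
                         gdt_ts(model, reference, mapping),
                         len(mapping))


# --------------------------------------------------------------------------
# MR success criterion
# --------------------------------------------------------------------------

def mr_success(rebuilt: StructureModel, target: StructureModel,
               cutoff: float = 3.0) -> tuple[bool, float]:
    """Did a rebuilt model trace at least half of the target CA chain?

    Residues sharing a seq_index anchor the superposition; the coverage
    fraction then counts target residues whose CA is matched one-to-one
    (greedy, nearest first) by a rebuilt CA within ``cutoff`` A.  Success
    is a fraction >= 0.5 ("at least half of the chain built").
    """
    t_idx, t_xyz = target.ca_coords()
    r_idx, r_xyz = rebuilt.ca_coords()
    if not t_idx or not r_idx:
        raise ValueError("both structures must contain CA atoms")
    common = sorted(set(t_idx) & set(r_idx))
    if len(common) < 3:
        raise SuperpositionError(
            "fewer than 3 shared residue numbers; cannot superpose")
    t_pos = {i: t_xyz[k] for k, i in enumerate(t_idx)}
    r_pos = {i: r_xyz[k] for k, i in enumerate(r_idx)}
    X = np.array([r_pos[i] for i in common])
    Y = np.array([t_pos[i] for i in common])
    R, t, _ = kabsch_superpose(X, Y)
    moved = r_xyz @ R.T + t

    dist = np.linalg.norm(moved[:, None, :] - t_xyz[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    used_r: set[int] = set()
    used_t: set[int] = set()
    matched = 0
    for ri, ti in order:
        if dist[ri, ti] > cutoff:
            break
        if ri in used_r or ti in used_t:
            continue
        used_r.add(int(ri))
        used_t.add(int(ti))
        matched += 1
    fraction = matched / len(target.residues)
    return fraction >= 0.5, fraction


# --------------------------------------------------------------------------
# Profile TSV I/O
# --------------------------------------------------------------------------

def write_profile_tsv(profile: AccuracyProfile, path: str | Path,
                      model: StructureModel | None = None) -> None:
    """Write a deviation profile as TSV (residue rows, then atom rows)."""
    aa = {r.seq_index: r.aa for r in model.residues} if model else {}
    rows = [{"residue_index": i, "atom_name": "", "aa": aa.get(i, "X"),
             "u_angstrom": u}
            for i, u in sorted(profile.per_residue_u.items())]
    for (i, name), u in sorted((profile.per_atom_u or {}).items()):
        rows.append({"residue_index": i, "atom_name": name,
                     "aa": aa.get(i, "X"), "u_angstrom": u})
    pd.DataFrame(rows, columns=["residue_index", "atom_name", "aa",
                                "u_angstrom"]).to_csv(
        path, sep="\t", index=False, float_format="%.4f")


def read_profile_tsv(path: str | Path) -> AccuracyProfile:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"atom_name": str})
    per_residue: dict[int, float] = {}
    per_atom: dict[tuple[int, str], float] = {}
    for row in df.itertuples(index=False):
        idx = int(row.residue_index)
        u = float(row.u_angstrom)
        if row.atom_name:
            per_atom[(idx, row.atom_name)] = u
            if row.atom_name == "CA":
                per_residue.setdefault(idx, u)
        else:
            per_residue[idx] = u
    return AccuracyProfile(per_residue, per_atom or None)
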