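"""Consensus (clustering) model-quality assessment.

Given an ensemble of alternative models of one target, the models are
ranked by a base score and a 3D-Jury-style consensus is computed over the
top-ranked 15%: the score of residue *i* in model *j* is the mean CA-CA
distance to the corresponding residue in every other top model after
pairwise global superposition,

    S_ij = 1/(N-1) * sum_{k != j} d_ijk .

Small S means the residue is placed consistently across models and is
therefore predicted accurate; S feeds straight into the B-factor encoding
as a per-residue deviation estimate.

The base scorer is a pluggable contract (model_id -> scalar, higher is
better).  The default ranks models by their negative mean consensus
distance from a preliminary all-against-all pass — a self-contained
structural consensus ranking usable when no external single-model quality
estimate is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .accuracy import AccuracyProfile, kabsch_superpose
from .structure_model import StructureModel


@dataclass
class DecoyEnsemble:
    """Alternative models of one target plus their base ranking scores."""

    target_id: str
    models: list[StructureModel]
    base_scores: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if len(self.models) < 2:
            raise ValueError("an ensemble needs at least 2 models")
        ids = [m.model_id for m in self.models]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate model ids in ensemble")
        if self.base_scores is not None:
            missing = set(ids) - set(self.base_scores)
            if missing:
                raise ValueError(f"base scores missing for {sorted(missing)}")

    def model(self, model_id: str) -> StructureModel:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(model_id)


@dataclass
class ConsensusScore:
    """Per-model, per-residue consensus distances S (A) over the top set."""

    per_model: dict[str, dict[int, float]]
    n_top: int


def pairwise_residue_distances(a: StructureModel, b: StructureModel
                               ) -> dict[int, float]:
    """CA-CA distance per common residue after global superposition of b on a.

    Residues are matched by seq_index; at least 3 common CA-bearing
    residues are required for the fit.
    """
    a_idx, a_xyz = a.ca_coords()
    b_idx, b_xyz = b.ca_coords()
    a_pos = {i: a_xyz[k] for k, i in enumerate(a_idx)}
    b_pos = {i: b_xyz[k] for k, i in enumerate(b_idx)}
    common = sorted(set(a_pos) & set(b_pos))
    if len(common) < 3:
        raise ValueError(
            f"models {a.model_id}/{b.model_id}: fewer than 3 common residues")
    X = np.array([b_pos[i] for i in common])
    Y = np.array([a_pos[i] for i in common])
    R, t, _ = kabsch_superpose(X, Y)
    moved = X @ R.T + t
    d = np.linalg.norm(moved - Y, axis=1)
    return {i: float(di) for i, di in zip(common, d)}


def default_base_scores(ensemble: DecoyEnsemble) -> dict[str, float]:
    """Structural consensus ranking: negative mean all-against-all distance."""
    ids = [m.model_id for m in ensemble.models]
    sums = {i: 0.0 for i in ids}
    counts = {i: 0 for i in ids}
    for i, a in enumerate(ensemble.models):
        for b in ensemble.models[i + 1:]:
            d = pairwise_residue_distances(a, b)
            mean_d = float(np.mean(list(d.values())))
            sums[a.model_id] += mean_d
            sums[b.model_id] += mean_d
            counts[a.model_id] += 1
            counts[b.model_id] += 1
    return {i: -sums[i] / counts[i] for i in ids}


def select_top(ensemble: DecoyEnsemble, fraction: float = 0.15,
               base_scores: dict[str, float] | None = None) -> list[str]:
    """Ids of the ceil(fraction * N) best-scoring models, at least 2.

    Ties are broken by model_id (lexicographic) for determinism.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scores = base_scores or ensemble.base_scores
    if scores is None:
        scores = default_base_scores(ensemble)
    n = len(ensemble.models)
    k = max(2, math.ceil(fraction * n))
    k = min(k, n)
    ranked = sorted((m.model_id for m in ensemble.models),
                    key=lambda mid: (-scores[mid], mid))
    return ranked[:k]


def clustering_score(ensemble: DecoyEnsemble, fraction: float = 0.15,
                     base_scores: dict[str, float] | None = None
                     ) -> ConsensusScore:
    """3D-Jury consensus distances over the top-ranked set.

    For each top model j and residue i, S_ij averages the pairwise CA
    distances d_ijk over the other top models k in which residue i exists
    (denominator = number of available pairs).
    """
    top = select_top(ensemble, fraction, base_scores)
    dist: dict[tuple[str, str], dict[int, float]] = {}
    for i, mid_a in enumerate(top):
        for mid_b in top[i + 1:]:
            d = pairwise_residue_distances(ensemble.model(mid_a),
                                           ensemble.model(mid_b))
            dist[(mid_a, mid_b)] = d
            dist[(mid_b, mid_a)] = d
    per_model: dict[str, dict[int, float]] = {}
    for mid in top:
        sums: dict[int, float] = {}
        counts: dict[int, int] = {}
        for other in top:
            if other == mid:
                continue
            for res_idx, d in dist[(mid, other)].items():
                sums[res_idx] = sums.get(res_idx, 0.0) + d
                counts[res_idx] = counts.get(res_idx, 0) + 1
        per_model[mid] = {i: sums[i] / counts[i] for i in sums}
    return ConsensusScore(per_model, len(top))


def consensus_to_profile(score: ConsensusScore, model_id: str,
                         model: StructureModel | None = None,
                         u_missing: float | None = None) -> AccuracyProfile:
    """Turn a model's consensus distances into an accuracy profile.

    Only models inside the scored top set can be converted.  If ``model``
    is given, residues it contains but the consensus did not score are
    filled with ``u_missing`` (default: the model's largest S — unscored
    residues are the least trusted).
    """
    if model_id not in score.per_model:
        raise KeyError(
            f"model {model_id!r} is outside the scored top set "
            f"({sorted(score.per_model)})")
    s = dict(score.per_model[model_id])
    if model is not None:
        fill = u_missing if u_missing is not None else (max(s.values()) if s else 0.0)
        for res in model.residues:
            s.setdefault(res.seq_index, fill)
    return AccuracyProfile(s)


def write_consensus_tsv(score: ConsensusScore, model_id: str,
                        path: str | Path) -> None:
    rows = sorted(score.per_model[model_id].items())
    pd.DataFrame(rows, columns=["residue_index", "S_angstrom"]).to_csv(
        path, sep="\t", index=False, float_format="%.4f")
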