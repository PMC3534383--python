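"""Protein search-model handling for Molecular Replacement.

A search model for MR is a single-chain protein structure whose per-atom
temperature factors (B-factors) can be repurposed to encode the *local
accuracy* of the model: an atom believed to sit ``u`` angstroms from its
true position is assigned

    B = 8 * pi**2 * u**2        [A^2]

so that MR programs which damp atoms by B (MOLREP, AMoRe) down-weight the
unreliable parts of the model.  This module provides PDB I/O, the
B-encoding transform, and the factory for the ten standard search-model
variants (all-atom / backbone-only / polyalanine, each with uniform B=20
or accuracy-derived B).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import gemmi
import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .accuracy import AccuracyProfile

logger = logging.getLogger(__name__)

#: Lower bound written to the PDB B column.  A zero B-factor makes an atom
#: infinitely sharp in the structure-factor calculation, which several MR
#: programs handle badly; 2.0 A^2 is a conservative crystallographic floor.
B_FLOOR = 2.00
#: Upper bound forced by the fixed-width (6.2f) PDB B-factor column.
B_CAP = 999.99

EIGHT_PI_SQUARED = 8.0 * math.pi**2

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})
POLYALA_ATOMS = frozenset({"N", "CA", "C", "O", "CB"})

#: The ten search-model variants, plus RAW (as-parsed model).
VARIANT_TAGS = (
    "ALL_20",
    "ALL_IDEAL",
    "BACKBONE_20",
    "BACKBONE_IDEAL",
    "ALL_CA_IDEAL",
    "BACKBONE_CA_IDEAL",
    "MQAP_EVAL",
    "MQAPCLUST_EVAL",
    "POLYALA",
    "POLYALA_20",
    "RAW",
)

#: Variants whose B-factors are derived from an accuracy profile.
PROFILE_VARIANTS = frozenset(
    {"ALL_IDEAL", "BACKBONE_IDEAL", "ALL_CA_IDEAL", "BACKBONE_CA_IDEAL",
     "MQAP_EVAL", "MQAPCLUST_EVAL"}
)

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
AA_1TO3["X"] = "UNK"


class PDBFormatError(ValueError):
    """Raised when a PDB file cannot be parsed into a usable model."""


class ProfileMismatchError(ValueError):
    """Raised when an accuracy profile does not cover the model."""


@dataclass
class Atom:
    """A heavy atom of a search model."""

    name: str
    element: str
    position: np.ndarray
    b_factor: float = 20.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(),
                    self.b_factor, self.occupancy)


@dataclass
class Residue:
    seq_index: int
    aa: str
    atoms: list[Atom] = field(default_factory=list)

    def get(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    @property
    def has_ca(self) -> bool:
        return self.get("CA") is not None

    def copy(self) -> "Residue":
        return Residue(self.seq_index, self.aa, [a.copy() for a in self.atoms])


@dataclass
class StructureModel:
    """A single-chain protein model: ordered residues of heavy atoms."""

    model_id: str
    residues: list[Residue]
    variant_tag: str = "RAW"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.residues:
            raise ValueError(f"model {self.model_id}: no residues")
        if self.variant_tag not in VARIANT_TAGS:
            raise ValueError(f"unknown variant tag {self.variant_tag!r}")
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                f"model {self.model_id}: residue numbers not strictly increasing")
        for res in self.residues:
            names = [a.name for a in res.atoms]
            if len(names) != len(set(names)):
                raise ValueError(
                    f"model {self.model_id}: duplicate atom names in residue "
                    f"{res.seq_index}")

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def residue(self, seq_index: int) -> Residue | None:
        for res in self.residues:
            if res.seq_index == seq_index:
                return res
        return None

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> tuple[list[int], np.ndarray]:
        """Residue indices and coordinates of all CA atoms, in chain order."""
        idx, xyz = [], []
        for res in self.residues:
            ca = res.get("CA")
            if ca is not None:
                idx.append(res.seq_index)
                xyz.append(ca.position)
        return idx, np.asarray(xyz, dtype=float).reshape(-1, 3)

    def copy(self, variant_tag: str | None = None, model_id: str | None = None
             ) -> "StructureModel":
        return StructureModel(
            model_id if model_id is not None else self.model_id,
            [r.copy() for r in self.residues],
            variant_tag if variant_tag is not None else self.variant_tag,
        )


@dataclass
class TargetAlignment:
    """A target-model alignment.

    ``aligned_target`` and ``aligned_model`` are equal-length strings over
    amino-acid letters and ``-``; ``mapping`` lists the aligned columns as
    ``(target_pos, model_res_index)`` pairs (both 1-based, model side given
    in residue seq_index numbering).
    """

    aligned_target: str
    aligned_model: str
    mapping: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.aligned_target) != len(self.aligned_model):
            raise ValueError("aligned strings differ in length")
        t = [p[0] for p in self.mapping]
        m = [p[1] for p in self.mapping]
        if sorted(set(t)) != t or sorted(set(m)) != m:
            raise ValueError("mapping must be strictly increasing on both sides")

    @property
    def mapped_model_indices(self) -> set[int]:
        return {m for _, m in self.mapping}


# --------------------------------------------------------------------------
# PDB I/O (gemmi does the format work; here we enforce the search-model
# contract: single chain, first model, heavy atoms, one conformer per atom)
# --------------------------------------------------------------------------

def _prevalidate_pdb_text(path: Path) -> int:
    """Cheap scan: count ATOM records and fail loudly on garbled coordinates."""
    n_atom = 0
    with open(path, "r", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("ATOM"):
                n_atom += 1
            if line.startswith(("ATOM", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fld = line[lo:hi].strip()
                    try:
                        float(fld)
                    except ValueError:
                        raise PDBFormatError(
                            f"{path}: unparseable coordinate field {fld!r} "
                            f"on line {lineno}") from None
    return n_atom


def read_pdb(path: str | Path, model_id: str | None = None) -> StructureModel:
    """Parse the first chain of the first model of a PDB file.

    Hydrogens are dropped, HETATM records are ignored, and for atoms with
    alternate conformers the highest-occupancy one is kept (ties: first
    encountered).  Additional chains trigger a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _prevalidate_pdb_text(path) == 0:
        raise PDBFormatError(f"{path}: no ATOM records")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBFormatError(f"{path}: {exc}") from exc

    model = st[0]
    if len(st) > 1:
        logger.warning("%s: %d models present, keeping the first", path, len(st))
    chains = [ch for ch in model]
    if len(chains) > 1:
        logger.warning("%s: %d chains present, keeping chain %s",
                       path, len(chains), chains[0].name)

    residues: list[Residue] = []
    last_idx: int | None = None
    for gres in chains[0]:
        if gres.het_flag == "H" or gres.name == "HOH":
            continue
        seq_index = gres.seqid.num
        if last_idx is not None and seq_index <= last_idx:
            logger.warning("%s: skipping residue %s %d (non-increasing numbering)",
                           path, gres.name, seq_index)
            continue
        best: dict[str, gemmi.Atom] = {}
        for ga in gres:
            if ga.element.is_hydrogen:
                continue
            prev = best.get(ga.name)
            if prev is None or ga.occ > prev.occ:
                best[ga.name] = ga
        if not best:
            continue
        atoms = [
            Atom(ga.name, ga.element.name,
                 np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                 float(ga.b_iso), float(ga.occ))
            for ga in best.values()
        ]
        residues.append(Residue(seq_index, AA_3TO1.get(gres.name, "X"), atoms))
        last_idx = seq_index

    if not residues:
        raise PDBFormatError(f"{path}: no ATOM records")
    return StructureModel(model_id or path.stem, residues)


def clamp_b(value: float, floor: float = B_FLOOR, cap: float = B_CAP) -> float:
    return float(min(max(value, floor), cap))


def write_pdb(model: StructureModel, path: str | Path,
              b_floor: float = B_FLOOR, b_cap: float = B_CAP) -> None:
    """Write the model as wwPDB v3.3 ATOM records.

    B-factors are clamped to ``[b_floor, b_cap]`` on output; coordinates
    round-trip to 3 decimals and B-factors to 2 (PDB column widths).
    """
    model.validate()
    st = gemmi.Structure()
    st.name = model.model_id
    gmodel = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for res in model.residues:
        gres = gemmi.Residue()
        gres.name = AA_1TO3.get(res.aa, "UNK")
        gres.seqid = gemmi.SeqId(res.seq_index, " ")
        gres.het_flag = "A"
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.position)
            ga.b_iso = clamp_b(atom.b_factor, b_floor, b_cap)
            ga.occ = atom.occupancy
            gres.add_atom(ga)
        chain.add_residue(gres)
    gmodel.add_chain(chain)
    st.add_model(gmodel)
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


# --------------------------------------------------------------------------
# Variant-building operations
# --------------------------------------------------------------------------

def strip_side_chains(model: StructureModel) -> StructureModel:
    """Keep only backbone atoms (N, CA, C, O) in every residue."""
    out = model.copy()
    for res in out.residues:
        res.atoms = [a for a in res.atoms if a.name in BACKBONE_ATOMS]
    return out


def to_polyalanine(model: StructureModel) -> StructureModel:
    """Rename every residue to ALA, keeping N, CA, C, O and any existing CB.

    Original B-factors are preserved; no CB is fabricated for residues
    (e.g. glycine) that lack one.
    """
    out = model.copy()
    for res in out.residues:
        res.aa = "A"
        res.atoms = [a for a in res.atoms if a.name in POLYALA_ATOMS]
    return out


def set_uniform_bfactor(model: StructureModel, value: float) -> StructureModel:
    if not (B_FLOOR <= value <= B_CAP):
        raise ValueError(
            f"uniform B {value} outside [{B_FLOOR}, {B_CAP}]")
    out = model.copy()
    for res in out.residues:
        for atom in res.atoms:
            atom.b_factor = float(value)
    return out


def deviation_to_bfactor(u, b_floor: float = B_FLOOR, b_cap: float = B_CAP):
    """Convert a positional deviation u [A] into a temperature factor [A^2].

    B = 8 * pi^2 * u^2, clamped to the writable PDB range.  Accepts scalars
    or arrays.
    """
    arr = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("deviation u must be finite and >= 0")
    b = np.clip(EIGHT_PI_SQUARED * arr**2, b_floor, b_cap)
    return float(b) if np.isscalar(u) or arr.ndim == 0 else b


def trim_insertions(model: StructureModel, aln: TargetAlignment,
                    max_len: int = 8) -> StructureModel:
    """Delete runs of unmapped (insertion) residues longer than ``max_len``.

    Insertions relative to the target alignment are the residues most likely
    to be mis-modelled; runs of up to ``max_len`` residues are retained,
    longer runs are removed wholesale.  Terminal overhangs count as runs.
    """
    mapped = aln.mapped_model_indices
    model_indices = {r.seq_index for r in model.residues}
    missing = sorted(mapped - model_indices)
    if missing:
        raise ValueError(
            f"alignment references residues absent from model: {missing}")
    keep: list[Residue] = []
    run: list[Residue] = []

    def flush() -> None:
        if len(run) <= max_len:
            keep.extend(run)
        run.clear()

    for res in model.residues:
        if res.seq_index in mapped:
            flush()
            keep.append(res)
        else:
            run.append(res)
    flush()
    if not keep:
        raise ValueError("trimming removed every residue")
    out = model.copy()
    out.residues = [r.copy() for r in keep]
    return out


def apply_accuracy_profile(model: StructureModel, profile: "AccuracyProfile",
                           mode: str = "per_atom",
                           b_floor: float = B_FLOOR,
                           b_cap: float = B_CAP) -> StructureModel:
    """Set every B-factor from a positional-deviation profile.

    mode='per_atom' uses the atom-level deviations; mode='per_residue_ca'
    transfers each residue's CA deviation to all of its atoms (the form
    needed when the accuracy estimator predicts CA deviations only).
    """
    if mode not in ("per_atom", "per_residue_ca"):
        raise ValueError(f"unknown mode {mode!r}")
    out = model.copy()
    missing: list[str] = []
    for res in out.residues:
        if mode == "per_residue_ca":
            u = profile.per_residue_u.get(res.seq_index)
            if u is None:
                missing.append(f"residue {res.seq_index}")
                continue
            b = deviation_to_bfactor(u, b_floor, b_cap)
            for atom in res.atoms:
                atom.b_factor = b
        else:
            per_atom = profile.per_atom_u or {}
            for atom in res.atoms:
                u = per_atom.get((res.seq_index, atom.name))
                if u is None:
                    missing.append(f"atom {res.seq_index}:{atom.name}")
                    continue
                atom.b_factor = deviation_to_bfactor(u, b_floor, b_cap)
    if missing:
        raise ProfileMismatchError(
            "profile does not cover model: " + ", ".join(missing[:20])
            + ("..." if len(missing) > 20 else ""))
    return out


def make_variant(model: StructureModel, tag: str,
                 profile: "AccuracyProfile | None" = None,
                 uniform_b: float = 20.0) -> StructureModel:
    """Build one of the ten search-model variants.

    ==================  ================================================
    tag                 construction
    ==================  ================================================
    ALL_20              all atoms, B = uniform_b
    ALL_IDEAL           all atoms, B from per-atom deviations
    BACKBONE_20         backbone only, B = uniform_b
    BACKBONE_IDEAL      backbone only, B from per-atom deviations
    ALL_CA_IDEAL        all atoms, B from the residue's CA deviation
    BACKBONE_CA_IDEAL   backbone only, B from the residue's CA deviation
    MQAP_EVAL           backbone only, B from predicted CA deviation
    MQAPCLUST_EVAL      backbone only, B from consensus-predicted CA dev.
    POLYALA             polyalanine, original (template) B-factors
    POLYALA_20          polyalanine, B = uniform_b
    ==================  ================================================

    Accuracy-derived tags require ``profile``; uniform-B and polyalanine
    tags forbid it.
    """
    if tag not in VARIANT_TAGS or tag == "RAW":
        raise ValueError(f"unknown variant tag {tag!r}")
    needs_profile = tag in PROFILE_VARIANTS
    if needs_profile and profile is None:
        raise ValueError(f"variant {tag} requires an accuracy profile")
    if not needs_profile and profile is not None:
        raise ValueError(f"variant {tag} does not take an accuracy profile")

    if tag == "ALL_20":
        out = set_uniform_bfactor(model, uniform_b)
    elif tag == "ALL_IDEAL":
        out = apply_accuracy_profile(model, profile, "per_atom")
    elif tag == "BACKBONE_20":
        out = set_uniform_bfactor(strip_side_chains(model), uniform_b)
    elif tag == "BACKBONE_IDEAL":
        out = apply_accuracy_profile(strip_side_chains(model), profile, "per_atom")
    elif tag == "ALL_CA_IDEAL":
        out = apply_accuracy_profile(model, profile, "per_residue_ca")
    elif tag in ("BACKBONE_CA_IDEAL", "MQAP_EVAL", "MQAPCLUST_EVAL"):
        out = apply_accuracy_profile(strip_side_chains(model), profile,
                                     "per_residue_ca")
    elif tag == "POLYALA":
        out = to_polyalanine(model)
    elif tag == "POLYALA_20":
        out = set_uniform_bfactor(to_polyalanine(model), uniform_b)
    out.variant_tag = tag
    return out


def completeness(model: StructureModel, target_seq: str) -> float:
    """Fraction of the target sequence covered by the model's residues."""
    if not target_seq:
        raise ValueError("empty target sequence")
    return len(model.residues) / len(target_seq)


# --------------------------------------------------------------------------
# Alignment input formats
# --------------------------------------------------------------------------

def _mapping_from_aligned(target: str, modelseq: str,
                          model_indices: Sequence[int] | None = None
                          ) -> list[tuple[int, int]]:
    if model_indices is None:
        model_indices = list(range(1, sum(c != "-" for c in modelseq) + 1))
    mapping = []
    tpos = mpos = 0
    for tc, mc in zip(target, modelseq):
        if tc != "-":
            tpos += 1
        if mc != "-":
            mpos += 1
        if tc != "-" and mc != "-":
            mapping.append((tpos, int(model_indices[mpos - 1])))
    return mapping


def read_alignment_fasta(path: str | Path,
                         model: StructureModel | None = None) -> TargetAlignment:
    """Read an aligned FASTA pair: first record target, second the model.

    If ``model`` is given, gapless model positions are translated to its
    residue seq_index numbering; otherwise 1..n ordinal numbering is used.
    """
    from Bio import SeqIO  # deferred: biopython is only needed for this reader

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValueError(f"{path}: need two aligned sequences, got {len(records)}")
    target = str(records[0].seq).upper()
    modelseq = str(records[1].seq).upper()
    indices = [r.seq_index for r in model.residues] if model is not None else None
    if indices is not None and len(indices) != sum(c != "-" for c in modelseq):
        raise ValueError("model length does not match ungapped alignment row")
    return TargetAlignment(target, modelseq,
                           _mapping_from_aligned(target, modelseq, indices))


def read_alignment_tsv(path: str | Path) -> TargetAlignment:
    """Read a 3-column TSV: target_pos, model_res_index, aligned_flag."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["target_pos", "model_res_index", "aligned_flag"])
    mapping = [(int(t), int(m))
               for t, m, f in df.itertuples(index=False) if int(f) == 1]
    n_t = int(df["target_pos"].max()) if len(df) else 0
    # aligned strings are not reconstructable from the TSV; synthesize
    # placeholders of the right mapped structure
    tset = {t for t, _ in mapping}
    mset = {m for _, m in mapping}
    tcols = "".join("X" if i in tset else "-" for i in range(1, n_t + 1))
    return TargetAlignment(tcols, tcols, sorted(mapping)) if mapping else \
        TargetAlignment("", "", [])
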