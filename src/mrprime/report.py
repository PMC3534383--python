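"""Outcome tables, success-ratio reporting, run configuration, pipeline.

The headline statistic of an MR benchmark is the *success ratio*: the
percentage of phasing attempts with a given search-model variant that
produced a correct solution, optionally stratified by global model
quality (GDT_TS bins >=80, 70-80, <70).  Relative changes between two
ratios are reported as integer percentages of the baseline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import accuracy, consensus, structure_model

logger = logging.getLogger(__name__)

GDT_BINS = ("ge80", "70to80", "lt70")


def bin_of_gdt(gdt: float) -> str:
    if gdt >= 80.0:
        return "ge80"
    if gdt >= 70.0:
        return "70to80"
    return "lt70"


@dataclass
class VariantOutcomeTable:
    """Rows of (model_id, variant_tag, gdt_bin, solved)."""

    df: pd.DataFrame

    COLUMNS = ("model_id", "variant_tag", "gdt_bin", "solved")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"outcome table missing columns {missing}")
        bad_bins = set(self.df["gdt_bin"]) - set(GDT_BINS)
        if bad_bins:
            raise ValueError(f"unknown gdt bins {sorted(bad_bins)}")
        if self.df.duplicated(["model_id", "variant_tag"]).any():
            raise ValueError("duplicate (model_id, variant_tag) rows")

    @classmethod
    def from_records(cls, records: list[dict]) -> "VariantOutcomeTable":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))


def success_ratio(table: VariantOutcomeTable, variant_tag: str,
                  gdt_bin: str | None = None) -> float:
    """Percentage of solved cases in the selected stratum, to 1 decimal."""
    df = table.df[table.df["variant_tag"] == variant_tag]
    if gdt_bin is not None:
        df = df[df["gdt_bin"] == gdt_bin]
    if df.empty:
        raise ValueError(f"no rows for variant {variant_tag!r}, bin {gdt_bin!r}")
    return round(100.0 * float(df["solved"].astype(bool).mean()), 1)


def relative_change(new: float, base: float) -> int:
    """Signed percentage change of ``new`` over ``base``, nearest integer."""
    if base <= 0:
        raise ValueError("baseline must be positive")
    return int(round(100.0 * (new - base) / base))


@dataclass
class RunConfig:
    """The pipeline's fixed constants."""

    trim_threshold: int = 8      # residues: longest insertion kept
    top_fraction: float = 0.15   # consensus top-ranked fraction
    uniform_b: float = 20.0      # A^2, for the *_20 variants
    b_floor: float = structure_model.B_FLOOR
    b_cap: float = structure_model.B_CAP
    mr_success_cutoff: float = 3.0  # A, CA-CA match tolerance
    alpha: float = 0.05          # significance level for elimination
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.trim_threshold < 1:
            raise ValueError("trim_threshold must be >= 1")
        if not self.b_floor < self.b_cap:
            raise ValueError("b_floor must be below b_cap")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Flat key = value text; CLI overrides win over file values."""
        values: dict = {}
        fields = {f for f in cls.__dataclass_fields__}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            caster = cls.__dataclass_fields__[key].type
            values[key] = int(raw) if caster == "int" else float(raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**values)
        for key, value in asdict(cfg).items():
            logger.info("config %s = %s", key, value)
        return cfg


def run_pipeline(config: RunConfig, manifest_path: str | Path,
                 out_dir: str | Path) -> dict:
    """Desk-scale preparation + evaluation pipeline.

    The JSON manifest lists targets, each with a reference structure
    (optional), models (each with optional alignment, rebuilt structure
    and externally supplied solved flag) and the variant tags to emit.
    Produces per-model variant PDBs, a quality report JSON, consensus
    TSVs (when >= 2 models share a target) and an outcome table TSV.
    Solved flags come from the manifest, or from the geometric chain-
    coverage proxy when a rebuilt model is given; crystallographic
    software is never invoked.
    """
    manifest_path = Path(manifest_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = json.loads(manifest_path.read_text())

    quality_report: dict = {}
    outcome_rows: list[dict] = []
    for target in manifest.get("targets", []):
        target_id = target["target_id"]
        reference = None
        if target.get("reference"):
            reference = structure_model.read_pdb(target["reference"])
        variants = target.get("variants", ["BACKBONE_20"])
        needs_profile = [v for v in variants
                         if v in structure_model.PROFILE_VARIANTS]
        models = []
        for entry in target.get("models", []):
            model = structure_model.read_pdb(entry["path"],
                                             model_id=entry.get("model_id"))
            if entry.get("alignment"):
                aln = structure_model.read_alignment_fasta(
                    entry["alignment"], model)
                model = structure_model.trim_insertions(
                    model, aln, config.trim_threshold)
            models.append((entry, model))

        cons_scores = None
        if len(models) >= 2:
            ensemble = consensus.DecoyEnsemble(
                target_id, [m for _, m in models])
            cons_scores = consensus.clustering_score(
                ensemble, config.top_fraction,
                consensus.default_base_scores(ensemble))
            for mid in cons_scores.per_model:
                consensus.write_consensus_tsv(
                    cons_scores, mid, out_dir / f"{target_id}_{mid}_S.tsv")

        for entry, model in models:
            mid = model.model_id
            profile = None
            quality = None
            if reference is not None:
                mapping = accuracy.mapping_from_seq_index(model, reference)
                profile = accuracy.per_residue_deviation(
                    model, reference, mapping)
                quality = accuracy.global_quality(model, reference, mapping)
                quality_report[f"{target_id}/{mid}"] = quality.to_dict()
            for tag in variants:
                if tag in structure_model.PROFILE_VARIANTS:
                    if tag == "MQAPCLUST_EVAL":
                        if cons_scores is None or mid not in cons_scores.per_model:
                            continue  # only top-ranked models get predictions
                        var_profile = consensus.consensus_to_profile(
                            cons_scores, mid, model)
                    elif profile is None:
                        raise ValueError(
                            f"variant {tag} for model {mid}: no reference "
                            f"given for target {target_id}")
                    else:
                        var_profile = profile
                else:
                    var_profile = None
                var = structure_model.make_variant(
                    model, tag, var_profile, config.uniform_b)
                structure_model.write_pdb(
                    var, out_dir / f"{target_id}_{mid}_{tag}.pdb",
                    config.b_floor, config.b_cap)

                solved = entry.get("solved")
                if solved is None and entry.get("rebuilt") and reference is not None:
                    rebuilt = structure_model.read_pdb(entry["rebuilt"])
                    solved, _ = accuracy.mr_success(
                        rebuilt, reference, config.mr_success_cutoff)
                if solved is not None and quality is not None:
                    outcome_rows.append({
                        "model_id": mid, "variant_tag": tag,
                        "gdt_bin": bin_of_gdt(quality.gdt_ts),
                        "solved": bool(solved)})

    (out_dir / "quality.json").write_text(
        json.dumps(quality_report, indent=2, sort_keys=True))
    outcome_path = out_dir / "outcomes.tsv"
    if outcome_rows:
        table = VariantOutcomeTable.from_records(outcome_rows)
        table.df.to_csv(outcome_path, sep="\t", index=False)
    report = {"n_quality": len(quality_report), "n_outcomes": len(outcome_rows),
              "out_dir": str(out_dir)}
    logger.info("pipeline done: %s", report)
    return report
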