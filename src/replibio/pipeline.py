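"""End-to-end orchestration: configuration, staging, provenance.

``run_all`` executes simulate (or load) -> row filters -> technical-replicate
averaging -> preprocessing -> SAINT-style scoring (NT and HU) -> HU
differential classification -> reports, writing every artifact plus a
manifest (config hash, seed, input checksums, per-stage row accounting) that
makes a rerun bit-for-bit comparable.  All numeric gates live in the nested
config dataclasses and default to the study's thresholds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import differential, io, preprocess, report, scoring, synthetic

FUNCTIONAL_GROUPS = ("CMG", "POL", "RPA", "CHR")


class StageError(RuntimeError):
    """Pipeline failure annotated with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")


@dataclass
class DifferentialConfig:
    log2fc_min: float = 1.0
    iqr_k: float = 1.5
    delta_mode: str = "delta"  # 'delta' or 'per_ratio'

    def __post_init__(self) -> None:
        if self.iqr_k <= 0:
            raise ValueError("iqr_k must be > 0")
        if self.delta_mode not in ("delta", "per_ratio"):
            raise ValueError(f"unknown delta_mode {self.delta_mode!r}")


@dataclass
class PipelineConfig:
    simulation: synthetic.SimulationConfig = field(default_factory=synthetic.SimulationConfig)
    preprocess: preprocess.PreprocessConfig = field(default_factory=preprocess.PreprocessConfig)
    scoring: scoring.ScoringConfig = field(default_factory=scoring.ScoringConfig)
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)
    dialect: io.Dialect = field(default_factory=io.Dialect)
    min_unique_peptides: int = 3
    seed: int = 42

    def __post_init__(self) -> None:
        self.simulation.seed = self.seed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "simulation": synthetic.SimulationConfig,
    "preprocess": preprocess.PreprocessConfig,
    "scoring": scoring.ScoringConfig,
    "differential": DifferentialConfig,
    "dialect": io.Dialect,
}


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a validated config; unknown keys are rejected."""
    data = dict(data or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.pop(name, {}) or {}
        allowed = {f.name for f in fields(cls)}
        unknown = set(section) - allowed
        if unknown:
            raise ValueError(f"unknown keys in {name!r}: {sorted(unknown)}")
        kwargs[name] = cls(**section)
    for scalar in ("min_unique_peptides", "seed"):
        if scalar in data:
            kwargs[scalar] = data.pop(scalar)
    if data:
        raise ValueError(f"unknown config keys: {sorted(data)}")
    return PipelineConfig(**kwargs)


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML/JSON config file, filling the study-default gates."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if not isinstance(data, dict) and data is not None:
        raise ValueError("config file must hold a mapping")
    return config_from_dict(data or {})


def _sha256(payload: bytes) -> str:
    return hashlib.sha256(payload).hexdigest()


def _file_checksum(path: Path) -> str:
    return _sha256(path.read_bytes())


def run_all(
    cfg: PipelineConfig,
    outdir: str | Path,
    design_path: str | Path | None = None,
    proteingroups_nt: str | Path | None = None,
    proteingroups_hu: str | Path | None = None,
) -> dict:
    """Run the full pipeline; returns the manifest (also written to disk).

    Without input paths, the synthetic generator provides the study; with
    them, the user-supplied design and NT/HU proteinGroups tables are loaded.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_sha256": _sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()),
        "seed": cfg.seed,
        "stages": {},
        "inputs": {},
    }

    truth = None
    if design_path is None:
        study = synthetic.simulate(cfg.simulation)
        design, q_nt, q_hu, truth = study.design, study.q_nt, study.q_hu, study.truth
        io.write_design(design, outdir / "design.tsv")
        io.write_proteingroups(q_nt, outdir / "proteinGroups_NT.tsv", cfg.dialect)
        io.write_proteingroups(q_hu, outdir / "proteinGroups_HU.tsv", cfg.dialect)
        synthetic.write_truth(truth, outdir / "truth.json")
        for name in ("design.tsv", "proteinGroups_NT.tsv", "proteinGroups_HU.tsv"):
            manifest["inputs"][name] = _file_checksum(outdir / name)
        manifest["stages"]["simulate"] = {
            "rows_in": 0,
            "rows_out": int(len(q_nt.proteins)),
            "rows_removed": 0,
        }
    else:
        try:
            design = io.read_design(design_path)
        except (OSError, ValueError) as exc:
            raise StageError("load", str(exc)) from exc
        if proteingroups_nt is None or proteingroups_hu is None:
            raise StageError("load", "NT and HU proteinGroups tables are both required")
        try:
            q_nt = io.read_proteingroups(proteingroups_nt, design, cfg.dialect)
            q_hu = io.read_proteingroups(proteingroups_hu, design, cfg.dialect)
        except (OSError, ValueError) as exc:
            raise StageError("load", str(exc)) from exc
        for name, p in (("design", design_path), ("proteinGroups_NT", proteingroups_nt),
                        ("proteinGroups_HU", proteingroups_hu)):
            manifest["inputs"][name] = _file_checksum(Path(p))

    # row-level quality filters
    try:
        rows_in = len(q_nt.proteins)
        q_nt, removal_log = io.filter_rows(q_nt, cfg.min_unique_peptides)
        q_hu, _ = io.filter_rows(q_hu, cfg.min_unique_peptides)
    except ValueError as exc:
        raise StageError("filter", str(exc)) from exc
    manifest["stages"]["filter"] = {
        "rows_in": rows_in,
        "rows_out": int(len(q_nt.proteins)),
        "rows_removed": len(removal_log),
        "reasons": removal_log,
    }
    pd.Series(removal_log, name="reason").rename_axis("group_id").to_csv(
        outdir / "removed_rows.tsv", sep="\t"
    )

    # technical replicates -> biological replicates
    q_nt_b, design_nt = io.average_tech_reps(q_nt, design)
    q_hu_b, design_hu = io.average_tech_reps(q_hu, design)
    design_bio = design_nt + design_hu
    manifest["stages"]["average_tech_reps"] = {
        "rows_in": int(len(q_nt.proteins)),
        "rows_out": int(len(q_nt_b.proteins)),
        "rows_removed": 0,
        "samples_nt": len(design_nt),
        "samples_hu": len(design_hu),
    }

    # preprocessing (per condition)
    try:
        proc_nt = preprocess.preprocess_matrix(q_nt_b, design_bio, cfg.preprocess)
        proc_hu = preprocess.preprocess_matrix(q_hu_b, design_bio, cfg.preprocess)
    except ValueError as exc:
        raise StageError("preprocess", str(exc)) from exc
    manifest["stages"]["preprocess"] = {
        "rows_in": int(len(q_nt_b.proteins)),
        "rows_out": int(len(proc_nt.q.proteins)),
        "rows_removed": 0,
        "nt": proc_nt.report,
        "hu": proc_hu.report,
    }
    proc_nt.q.intensity.to_csv(outdir / "processed_intensity_NT.tsv", sep="\t")
    proc_hu.q.intensity.to_csv(outdir / "processed_intensity_HU.tsv", sep="\t")
    with open(outdir / "preprocess_report.json", "w") as fh:
        json.dump({"NT": proc_nt.report, "HU": proc_hu.report}, fh, indent=1, sort_keys=True)

    # SAINT-style scoring, both conditions (the untreated screen defines the
    # proximity interactome; the HU pass supplies interactor status under treatment)
    try:
        calls_nt = scoring.call_interactions(q_nt_b, design_bio, cfg.scoring, condition="NT")
        calls_hu = scoring.call_interactions(q_hu_b, design_bio, cfg.scoring, condition="HU")
    except ValueError as exc:
        raise StageError("score", str(exc)) from exc
    scoring.saint_list_table(calls_nt).to_csv(outdir / "interactions_NT.tsv", sep="\t", index=False)
    scoring.saint_list_table(calls_hu).to_csv(outdir / "interactions_HU.tsv", sep="\t", index=False)
    calls_nt.to_csv(outdir / "calls_NT_full.tsv", sep="\t", index=False)
    interactors_nt = scoring.interactor_sets(calls_nt)
    interactors_hu = scoring.interactor_sets(calls_hu)
    manifest["stages"]["score"] = {
        "rows_in": int(len(calls_nt)),
        "rows_out": int(len(calls_nt)),
        "rows_removed": 0,
        "interactors_nt": {b: len(s) for b, s in interactors_nt.items()},
        "interactors_hu": {b: len(s) for b, s in interactors_hu.items()},
    }

    # per-bait prey universes: presence-passed in both conditions, bait-MEC removed
    prey_sets: dict[str, set] = {}
    for bait in io.baits(design_bio):
        key_nt = preprocess.group_key(bait, "NT")
        key_hu = preprocess.group_key(bait, "HU")
        ok = pd.Series(True, index=proc_nt.q.proteins.index)
        if key_nt in proc_nt.presence.columns:
            ok &= proc_nt.presence[key_nt]
        if key_hu in proc_hu.presence.columns:
            ok &= proc_hu.presence[key_hu]
        excluded = proc_nt.bait_mec.get(bait, set()) | proc_hu.bait_mec.get(bait, set())
        prey_sets[bait] = set(ok.index[ok]) - excluded

    # HU differential
    try:
        records = differential.enrichment_ratios(
            proc_nt.q, proc_hu.q, design_bio, cfg.differential.log2fc_min, prey_sets
        )
        records, thresholds = differential.classify_all(
            records, interactors_nt, interactors_hu, k=cfg.differential.iqr_k
        )
    except ValueError as exc:
        raise StageError("differential", str(exc)) from exc
    records.to_csv(outdir / "enrichment_records.tsv", sep="\t", index=False)
    records[["bait", "prey", "ratio_nt", "ratio_hu"]].to_csv(
        outdir / "scatter_data.tsv", sep="\t", index=False
    )
    with open(outdir / "iqr_thresholds.json", "w") as fh:
        json.dump({b: dataclasses.asdict(t) for b, t in thresholds.items()}, fh, indent=1, sort_keys=True)
    group_map = {
        bait: FUNCTIONAL_GROUPS[i % len(FUNCTIONAL_GROUPS)]
        for i, bait in enumerate(io.baits(design_bio))
    }
    summary, venn = differential.summarize_by_group(records, group_map)
    summary.to_csv(outdir / "gained_depleted_summary.tsv", sep="\t", index=False)
    with open(outdir / "venn_counts.json", "w") as fh:
        json.dump({"|".join(sorted(k)): v for k, v in venn.items()}, fh, indent=1, sort_keys=True)
    status_counts = records["status"].value_counts().to_dict() if not records.empty else {}
    manifest["stages"]["differential"] = {
        "rows_in": int(len(records)),
        "rows_out": int(len(records)),
        "rows_removed": 0,
        "status_counts": status_counts,
    }

    # reporting
    try:
        corr, order = report.bait_correlation(q_nt_b, design_bio, condition="NT")
        corr.to_csv(outdir / "bait_correlation.tsv", sep="\t")
        # concordance is a QC metric on observed intensities (imputation would
        # pair detection floors in one condition with real values in the other)
        concordance = report.control_concordance(q_nt_b, q_hu_b, design_bio)
        if not calls_nt.empty:
            report.dotplot_table(calls_nt).to_csv(outdir / "dotplot_NT.tsv", sep="\t", index=False)
        report.export_network(records, calls_nt, outdir / "network", group_map)
    except ValueError as exc:
        raise StageError("report", str(exc)) from exc
    manifest["stages"]["report"] = {
        "rows_in": int(len(records)),
        "rows_out": int(len(records)),
        "rows_removed": 0,
        "bait_order": order,
        "control_concordance_r": round(concordance, 6),
    }

    if truth is not None:
        manifest["metrics"] = {
            "scoring": synthetic.scoring_metrics(calls_nt, truth, io.baits(design_bio)),
            "differential": synthetic.differential_metrics(records, truth),
        }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
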