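"""Readers and writers for the pipeline's file dialects.

Handles three interchange formats:

* MaxQuant-style ``proteinGroups`` tables (tab-delimited, one row per protein
  group, per-sample ``MS/MS count`` and ``LFQ intensity`` columns, ``+`` flag
  convention for reverse/contaminant/site-only rows);
* sample-design tables mapping each quantitative column to
  (bait-or-control, condition, biological replicate, technical replicate);
* the classic SAINT three-file interchange (bait.dat / prey.dat /
  interaction.dat).

The in-memory model is :class:`QuantMatrix`, which keeps spectral counts and
label-free intensities as two aligned layers.  An intensity of 0 (or blank) in
a proteinGroups table denotes *non-quantification* and is stored as missing
(NaN); a spectral count of 0 is an observed zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONTROL_SOURCES = ("control_parental", "control_gfp", "control_gfp_nls")
CONDITIONS = ("NT", "HU")

DESIGN_COLUMNS = ("sample_id", "source", "condition", "bio_rep", "tech_rep")


@dataclass(frozen=True)
class SampleDesign:
    """One quantitative sample: who produced it and where it sits in the design."""

    sample_id: str
    source: str  # 'bait' or one of CONTROL_SOURCES
    bait: str | None
    condition: str  # 'NT' or 'HU'
    bio_rep: int
    tech_rep: int

    def __post_init__(self) -> None:
        if self.source == "bait" and not self.bait:
            raise ValueError(f"bait sample {self.sample_id!r} needs a bait name")
        if self.source not in ("bait",) + CONTROL_SOURCES:
            raise ValueError(f"unknown source token {self.source!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition token {self.condition!r}")
        if self.bio_rep < 1 or self.tech_rep < 1:
            raise ValueError("replicate indices start at 1")

    @property
    def label(self) -> str:
        """Group label: the bait name for baits, the control token for controls."""
        return self.bait if self.source == "bait" else self.source


def read_design(path: str | Path) -> list[SampleDesign]:
    """Parse a tab- or comma-delimited sample-design table.

    The ``source`` column holds either one of the control tokens
    (``control_parental``, ``control_gfp``, ``control_gfp_nls``,
    case-insensitive) or a bait name.  Conditions are ``NT``/``HU``
    (case-insensitive).
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"empty design file: {path}")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = set(DESIGN_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"design file missing columns: {sorted(missing)}")
    rows: list[SampleDesign] = []
    seen: set[str] = set()
    for rec in frame.itertuples(index=False):
        sample_id = str(rec.sample_id).strip()
        if sample_id in seen:
            raise ValueError(f"duplicate sample id {sample_id!r}")
        seen.add(sample_id)
        token = str(rec.source).strip()
        norm = token.lower()
        if norm in CONTROL_SOURCES:
            source, bait = norm, None
        elif norm in ("", "nan"):
            raise ValueError(f"unknown source token {token!r} for sample {sample_id!r}")
        else:
            source, bait = "bait", token
        condition = str(rec.condition).strip().upper()
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition token {rec.condition!r} for sample {sample_id!r}")
        rows.append(
            SampleDesign(
                sample_id=sample_id,
                source=source,
                bait=bait,
                condition=condition,
                bio_rep=int(rec.bio_rep),
                tech_rep=int(rec.tech_rep),
            )
        )
    return rows


def write_design(design: list[SampleDesign], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "sample_id": [d.sample_id for d in design],
            "source": [d.label for d in design],
            "condition": [d.condition for d in design],
            "bio_rep": [d.bio_rep for d in design],
            "tech_rep": [d.tech_rep for d in design],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def baits(design: list[SampleDesign]) -> list[str]:
    """Bait names in order of first appearance."""
    out: list[str] = []
    for d in design:
        if d.source == "bait" and d.bait not in out:
            out.append(d.bait)
    return out


def group_columns(
    design: list[SampleDesign],
    sample_ids: list[str] | None = None,
) -> dict[tuple[str, str], list[str]]:
    """Map (label, condition) -> ordered sample ids, restricted to ``sample_ids``."""
    keep = None if sample_ids is None else set(sample_ids)
    groups: dict[tuple[str, str], list[str]] = {}
    for d in sorted(design, key=lambda d: (d.bio_rep, d.tech_rep)):
        if keep is not None and d.sample_id not in keep:
            continue
        groups.setdefault((d.label, d.condition), []).append(d.sample_id)
    return groups


# ---------------------------------------------------------------------------
# QuantMatrix


PROTEIN_COLUMNS = (
    "gene_symbol",
    "is_reverse",
    "is_contaminant",
    "only_by_site",
    "unique_peptides",
)


@dataclass
class QuantMatrix:
    """Protein-group x sample matrix with a spectral-count and an intensity layer.

    ``proteins`` is indexed by the group id (first accession of the group) and
    carries the quality flags; ``counts`` holds observed spectral counts
    (zeros are real observations); ``intensity`` holds LFQ intensities with
    NaN marking missing (non-quantified) entries.  ``log_transformed`` is True
    once intensities are on the log2 scale.
    """

    proteins: pd.DataFrame
    counts: pd.DataFrame
    intensity: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if not self.proteins.index.is_unique:
            raise ValueError("protein group ids must be unique")
        if not (self.counts.index.equals(self.proteins.index) and self.intensity.index.equals(self.proteins.index)):
            raise ValueError("layers must share the protein index")
        if not self.counts.columns.equals(self.intensity.columns):
            raise ValueError("layers must share the sample columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative spectral counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.proteins.index)

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(
            self.proteins.copy(), self.counts.copy(), self.intensity.copy(), self.log_transformed
        )

    def subset_rows(self, ids) -> "QuantMatrix":
        ids = [i for i in self.proteins.index if i in set(ids)]
        return QuantMatrix(
            self.proteins.loc[ids].copy(),
            self.counts.loc[ids].copy(),
            self.intensity.loc[ids].copy(),
            self.log_transformed,
        )

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask of missing intensity entries."""
        return self.intensity.isna()


@dataclass(frozen=True)
class Dialect:
    """Column-name templates for a MaxQuant proteinGroups flavor (v1.6 default)."""

    count_template: str = "MS/MS count {sample}"
    intensity_template: str = "LFQ intensity {sample}"
    id_column: str = "Protein IDs"
    gene_column: str = "Gene names"
    unique_peptides_column: str = "Unique peptides"
    reverse_column: str = "Reverse"
    contaminant_column: str = "Potential contaminant"
    site_column: str = "Only identified by site"


def _first_token(value: object) -> str:
    return str(value).split(";")[0].strip()


def _flags(frame: pd.DataFrame, column: str) -> pd.Series:
    if column not in frame.columns:
        return pd.Series(False, index=frame.index)
    return frame[column].fillna("").astype(str).str.strip() == "+"


def read_proteingroups(
    path: str | Path,
    design: list[SampleDesign],
    dialect: Dialect = Dialect(),
) -> QuantMatrix:
    """Load a proteinGroups table into a QuantMatrix aligned to the design.

    A 0 (or blank) LFQ intensity becomes a missing entry; spectral counts are
    kept as observed values including zeros.
    """
    frame = pd.read_csv(path, sep="\t", dtype={dialect.id_column: str})
    if frame.empty:
        raise ValueError(f"empty proteinGroups table: {path}")
    sample_ids = [d.sample_id for d in design]
    count_cols, intensity_cols, used = {}, {}, []
    for sid in sample_ids:
        ccol = dialect.count_template.format(sample=sid)
        icol = dialect.intensity_template.format(sample=sid)
        if ccol not in frame.columns and icol not in frame.columns:
            continue
        if ccol not in frame.columns or icol not in frame.columns:
            raise ValueError(f"sample {sid!r}: need both count and intensity columns")
        count_cols[sid], intensity_cols[sid] = ccol, icol
        used.append(sid)
    if not used:
        raise ValueError("no quantitative columns matched the design")
    absent = [d.sample_id for d in design if d.sample_id not in used
              and d.condition in {dd.condition for dd in design if dd.sample_id in used}]
    # every design sample belonging to this table's condition(s) must resolve
    missing_design = set(absent)
    if missing_design and len(used) < len(sample_ids):
        all_conditions = {d.condition for d in design}
        used_conditions = {d.condition for d in design if d.sample_id in used}
        if used_conditions == all_conditions:
            raise ValueError(f"design samples without matching columns: {sorted(missing_design)}")

    group_ids = frame[dialect.id_column].map(_first_token)
    if group_ids.duplicated().any():
        dupes = sorted(group_ids[group_ids.duplicated()].unique())
        raise ValueError(f"duplicate protein group ids: {dupes[:5]}")
    genes = (
        frame[dialect.gene_column].map(_first_token)
        if dialect.gene_column in frame.columns
        else pd.Series("", index=frame.index)
    )
    unique_peptides = (
        pd.to_numeric(frame[dialect.unique_peptides_column], errors="coerce").fillna(0).astype(int)
        if dialect.unique_peptides_column in frame.columns
        else pd.Series(0, index=frame.index)
    )
    proteins = pd.DataFrame(
        {
            "accessions": frame[dialect.id_column].astype(str).to_numpy(),
            "gene_symbol": genes.to_numpy(),
            "is_reverse": _flags(frame, dialect.reverse_column).to_numpy(),
            "is_contaminant": _flags(frame, dialect.contaminant_column).to_numpy(),
            "only_by_site": _flags(frame, dialect.site_column).to_numpy(),
            "unique_peptides": unique_peptides.to_numpy(),
        },
        index=pd.Index(group_ids, name="group_id"),
    )
    counts = pd.DataFrame(
        {sid: pd.to_numeric(frame[count_cols[sid]], errors="coerce").fillna(0).to_numpy(dtype=float) for sid in used},
        index=proteins.index,
    )
    intensity = pd.DataFrame(
        {sid: pd.to_numeric(frame[intensity_cols[sid]], errors="coerce").to_numpy(dtype=float) for sid in used},
        index=proteins.index,
    )
    intensity = intensity.where(intensity > 0)  # 0/blank -> missing
    return QuantMatrix(proteins, counts, intensity)


def write_proteingroups(
    q: QuantMatrix,
    path: str | Path,
    dialect: Dialect = Dialect(),
) -> None:
    """Write a QuantMatrix back to the proteinGroups dialect (missing -> 0)."""
    out = pd.DataFrame(
        {
            dialect.id_column: q.proteins.get("accessions", pd.Series(q.proteins.index, index=q.proteins.index)),
            dialect.gene_column: q.proteins["gene_symbol"],
            dialect.unique_peptides_column: q.proteins["unique_peptides"],
            dialect.reverse_column: np.where(q.proteins["is_reverse"], "+", ""),
            dialect.contaminant_column: np.where(q.proteins["is_contaminant"], "+", ""),
            dialect.site_column: np.where(q.proteins["only_by_site"], "+", ""),
        }
    )
    for sid in q.sample_ids:
        out[dialect.count_template.format(sample=sid)] = q.counts[sid].to_numpy()
    for sid in q.sample_ids:
        out[dialect.intensity_template.format(sample=sid)] = q.intensity[sid].fillna(0.0).to_numpy()
    out.to_csv(path, sep="\t", index=False)


def filter_rows(
    q: QuantMatrix, min_unique_peptides: int = 3
) -> tuple[QuantMatrix, dict[str, str]]:
    """Apply the row-level quality filters.

    Removes reverse hits, contaminants, site-only identifications and protein
    groups with fewer than ``min_unique_peptides`` unique peptides (boundary
    inclusive: exactly the minimum is retained).  Returns the retained subset
    and a removal log mapping group id -> reason.
    """
    log: dict[str, str] = {}
    p = q.proteins
    for gid in p.index:
        row = p.loc[gid]
        if row["is_reverse"]:
            log[gid] = "reverse"
        elif row["is_contaminant"]:
            log[gid] = "contaminant"
        elif row["only_by_site"]:
            log[gid] = "only_identified_by_site"
        elif row["unique_peptides"] < min_unique_peptides:
            log[gid] = f"unique_peptides<{min_unique_peptides}"
    keep = [gid for gid in p.index if gid not in log]
    return q.subset_rows(keep), log


def average_tech_reps(
    q: QuantMatrix, design: list[SampleDesign]
) -> tuple[QuantMatrix, list[SampleDesign]]:
    """Collapse technical replicates into biological replicates.

    Observed values are averaged arithmetically; an intensity entry is missing
    in the collapsed column only when every technical replicate was missing.
    Downstream statistics operate at the biological-replicate level.
    """
    by_biorep: dict[tuple[str, str, int], list[SampleDesign]] = {}
    for d in design:
        if d.sample_id in q.counts.columns:
            by_biorep.setdefault((d.label, d.condition, d.bio_rep), []).append(d)
    new_design: list[SampleDesign] = []
    counts, intensity = {}, {}
    for (label, condition, bio_rep), members in by_biorep.items():
        sid = f"{label}.{condition}.b{bio_rep}"
        cols = [m.sample_id for m in members]
        counts[sid] = q.counts[cols].mean(axis=1)
        intensity[sid] = q.intensity[cols].mean(axis=1)  # NaN only if all missing
        new_design.append(
            SampleDesign(
                sample_id=sid,
                source=members[0].source,
                bait=members[0].bait,
                condition=condition,
                bio_rep=bio_rep,
                tech_rep=1,
            )
        )
    order = [d.sample_id for d in new_design]
    out = QuantMatrix(
        q.proteins.copy(),
        pd.DataFrame(counts)[order],
        pd.DataFrame(intensity)[order],
        q.log_transformed,
    )
    return out, new_design


# ---------------------------------------------------------------------------
# SAINT interchange


def write_saint_triples(
    q: QuantMatrix, design: list[SampleDesign], outdir: str | Path
) -> dict[str, Path]:
    """Emit the classic SAINT three-file interchange.

    ``bait.dat``: sample id, bait-or-control label, T (test) / C (control).
    ``prey.dat``: prey id, length placeholder, gene symbol.
    ``interaction.dat``: sample id, bait label, prey, spectral count — only
    nonzero counts are listed (zero-count pairs are unlisted by convention).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / f"{name}.dat" for name in ("bait", "prey", "interaction")}
    keep = [d for d in design if d.sample_id in q.counts.columns]
    with open(paths["bait"], "w") as fh:
        for d in keep:
            flag = "T" if d.source == "bait" else "C"
            fh.write(f"{d.sample_id}\t{d.label}\t{flag}\n")
    with open(paths["prey"], "w") as fh:
        for gid in q.protein_ids:
            gene = q.proteins.loc[gid, "gene_symbol"] or gid
            fh.write(f"{gid}\t0\t{gene}\n")
    with open(paths["interaction"], "w") as fh:
        for d in keep:
            col = q.counts[d.sample_id]
            for gid, value in col[col > 0].items():
                fh.write(f"{d.sample_id}\t{d.label}\t{gid}\t{value:g}\n")
    return paths
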