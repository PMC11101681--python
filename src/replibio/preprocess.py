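"""Normalization and two-regime missing-value treatment for log2 intensities.

Label-free intensities are log2-transformed, median-normalized per sample,
and missing entries are handled according to their missingness regime within
each (bait-or-control, condition) group of biological replicates:

* **FULL** — no missing replicate; left alone.
* **POV** — partially observed (at least one observed, at most
  ``max_missing_pov`` missing); imputed by structured least squares (SLSA):
  the missing entry is predicted from the protein's mean in the sibling
  replicate columns through an OLS regression fitted on fully observed
  proteins of the group.
* **MEC** — missing in the entire condition; either deterministically imputed
  at a low quantile of the column (``DetQuantile``, encoding "below
  detection") or, for a bait's own condition pair, excluded from that bait's
  downstream comparison.

A presence rule (observed, pre-imputation, in at least 2 of 3 biological
replicates) gates which proteins enter downstream per-bait results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONTROL_SOURCES, QuantMatrix, SampleDesign, group_columns

FULL, POV, MEC = "FULL", "POV", "MEC"


@dataclass
class PreprocessConfig:
    max_missing_pov: int = 2
    detquantile_q: float = 0.01
    detquantile_factor: float = 0.2
    presence_min_bioreps: int = 2
    presence_total_bioreps: int = 3
    quantile_method: str = "linear"  # numpy quantile interpolation rule
    center: str = "per_sample"  # mean centering unit within condition groups

    def __post_init__(self) -> None:
        if not 0 < self.detquantile_q < 1:
            raise ValueError("detquantile_q must be in (0, 1)")
        if not 0 < self.detquantile_factor <= 1:
            raise ValueError("detquantile_factor must be in (0, 1]")
        if self.presence_min_bioreps > self.presence_total_bioreps:
            raise ValueError("presence_min_bioreps exceeds presence_total_bioreps")
        if self.max_missing_pov < 1:
            raise ValueError("max_missing_pov must be >= 1")


def group_key(label: str, condition: str) -> str:
    return f"{label}|{condition}"


def log2_transform(q: QuantMatrix) -> QuantMatrix:
    """Put intensities on the log2 scale (missing stays missing)."""
    if q.log_transformed:
        return q.copy()
    out = q.copy()
    with np.errstate(divide="ignore"):
        out.intensity = np.log2(out.intensity)
    out.intensity = out.intensity.where(np.isfinite(out.intensity))
    out.log_transformed = True
    return out


def classify_missingness(
    q: QuantMatrix, design: list[SampleDesign], cfg: PreprocessConfig = PreprocessConfig()
) -> pd.DataFrame:
    """Label every (protein, condition-group) as FULL / POV / MEC.

    Groups are the biological replicates of one (bait-or-control, condition).
    POV requires at least one observed replicate and at most
    ``max_missing_pov`` missing; a group with more missing than that but not
    fully missing is treated as MEC (effectively below detection).
    """
    groups = group_columns(design, q.sample_ids)
    out = {}
    for (label, condition), cols in groups.items():
        if not cols:
            raise ValueError(f"group {label}/{condition} has zero samples")
        n_missing = q.intensity[cols].isna().sum(axis=1)
        n = len(cols)
        cls = np.where(
            n_missing == 0, FULL, np.where((n_missing < n) & (n_missing <= cfg.max_missing_pov), POV, MEC)
        )
        out[group_key(label, condition)] = pd.Series(cls, index=q.proteins.index)
    return pd.DataFrame(out)


def median_normalize(q: QuantMatrix) -> tuple[QuantMatrix, pd.Series]:
    """Shift each sample so its observed median equals the grand median.

    The grand median is the median of the original per-column medians, so a
    single-column matrix is left unchanged.  Purely additive: within-column
    differences are preserved exactly.  Counts are untouched.
    """
    medians = q.intensity.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValueError(f"all-missing columns: {bad}")
    grand = medians.median()
    shifts = grand - medians
    out = q.copy()
    out.intensity = out.intensity + shifts
    return out, shifts


def mean_center(
    q: QuantMatrix, design: list[SampleDesign]
) -> tuple[QuantMatrix, pd.Series]:
    """Within each condition-group, shift columns to the group's grand mean.

    Idempotent; additive, so within-column differences are preserved.
    """
    groups = group_columns(design, q.sample_ids)
    out = q.copy()
    shifts = {}
    for cols in groups.values():
        means = q.intensity[cols].mean(axis=0, skipna=True)
        if means.isna().any():
            bad = list(means.index[means.isna()])
            raise ValueError(f"all-missing columns: {bad}")
        grand = means.mean()
        for c in cols:
            shifts[c] = grand - means[c]
            out.intensity[c] = out.intensity[c] + shifts[c]
    return out, pd.Series(shifts)


def _slsa_impute_column(
    block: pd.DataFrame, col: str, target_rows: pd.Index
) -> pd.Series:
    """Predict ``col`` entries for ``target_rows`` from sibling columns.

    For each missing protein, the predictor is the mean of the protein's
    observed sibling columns; the regression (OLS, affine) is fitted on
    proteins fully observed in the group, using the same sibling set.
    Falls back to the sibling mean itself when too few complete rows exist.
    """
    others = [c for c in block.columns if c != col]
    full_rows = block.dropna().index
    predictions = {}
    # group target proteins by their observed sibling pattern
    observed = block.loc[target_rows, others].notna()
    for pattern, rows in observed.groupby(list(others)).groups.items():
        pattern = (pattern,) if not isinstance(pattern, tuple) else pattern
        siblings = [c for c, obs in zip(others, pattern) if obs]
        if not siblings:  # cannot happen for POV entries
            continue
        x_new = block.loc[rows, siblings].mean(axis=1)
        if len(full_rows) >= 3:
            x_fit = block.loc[full_rows, siblings].mean(axis=1)
            y_fit = block.loc[full_rows, col]
            if np.ptp(x_fit.to_numpy()) > 0:
                fit = stats.linregress(x_fit.to_numpy(), y_fit.to_numpy())
                predictions.update(dict(zip(rows, fit.intercept + fit.slope * x_new)))
                continue
        predictions.update(dict(zip(rows, x_new)))
    return pd.Series(predictions)


def impute_slsa(
    q: QuantMatrix,
    classes: pd.DataFrame,
    design: list[SampleDesign],
    cfg: PreprocessConfig = PreprocessConfig(),
) -> QuantMatrix:
    """Impute POV-missing entries by structured least squares; observed entries
    are untouched (bitwise).  FULL and MEC entries are left alone."""
    groups = group_columns(design, q.sample_ids)
    out = q.copy()
    for (label, condition), cols in groups.items():
        if len(cols) < 2:
            continue
        key = group_key(label, condition)
        pov_rows = classes.index[classes[key] == POV]
        if pov_rows.empty:
            continue
        block = q.intensity[cols]
        for col in cols:
            targets = pov_rows[block.loc[pov_rows, col].isna()]
            if targets.empty:
                continue
            preds = _slsa_impute_column(block, col, targets)
            out.intensity.loc[preds.index, col] = preds
    return out


def impute_detquantile(
    q: QuantMatrix,
    classes: pd.DataFrame,
    design: list[SampleDesign],
    cfg: PreprocessConfig = PreprocessConfig(),
    groups: list[tuple[str, str]] | None = None,
) -> QuantMatrix:
    """Deterministically impute MEC entries at a low column quantile.

    Every MEC entry of column ``c`` (within the selected groups) is set to
    ``factor * Q_q(observed values of c)``.  With factor < 1 and a small q the
    imputed value sits below the column's observed range, encoding "below
    detection".  Bitwise deterministic.
    """
    design_groups = group_columns(design, q.sample_ids)
    selected = set(groups) if groups is not None else set(design_groups)
    out = q.copy()
    for (label, condition), cols in design_groups.items():
        if (label, condition) not in selected:
            continue
        key = group_key(label, condition)
        mec_rows = classes.index[classes[key] == MEC]
        if mec_rows.empty:
            continue
        for col in cols:
            observed = q.intensity[col].dropna().to_numpy()
            if observed.size == 0:
                raise ValueError(f"column {col!r} has no observed values")
            value = cfg.detquantile_factor * np.quantile(
                observed, cfg.detquantile_q, method=cfg.quantile_method
            )
            out.intensity.loc[mec_rows, col] = value
    return out


def presence_filter(
    q: QuantMatrix, design: list[SampleDesign], cfg: PreprocessConfig = PreprocessConfig()
) -> pd.DataFrame:
    """Per (label, condition): proteins observed in >= presence_min bio-reps.

    Decisions depend only on the pre-imputation missingness mask, so this must
    be evaluated on (or with masks from) the un-imputed matrix.  Returns a
    boolean proteins x group frame.
    """
    groups = group_columns(design, q.sample_ids)
    out = {}
    for (label, condition), cols in groups.items():
        n_observed = q.intensity[cols].notna().sum(axis=1)
        out[group_key(label, condition)] = n_observed >= cfg.presence_min_bioreps
    return pd.DataFrame(out)


@dataclass
class ProcessedMatrix:
    """Result of the full preprocessing chain on one condition's matrix."""

    q: QuantMatrix
    classes: pd.DataFrame
    presence: pd.DataFrame
    bait_mec: dict[str, set]  # bait label -> proteins MEC in that bait's group
    report: dict = field(default_factory=dict)


def preprocess_matrix(
    q: QuantMatrix, design: list[SampleDesign], cfg: PreprocessConfig = PreprocessConfig()
) -> ProcessedMatrix:
    """classify -> median-normalize -> impute (SLSA then DetQuantile) ->
    presence filter -> mean center.

    DetQuantile is applied to control groups only: a prey never seen in a
    control is floored there so enrichment ratios stay computable, whereas a
    prey MEC in a bait's own condition is recorded in ``bait_mec`` and
    excluded from that bait's comparison (for both conditions) downstream.
    Presence decisions are taken on the pre-imputation masks.
    """
    q = log2_transform(q)
    classes = classify_missingness(q, design, cfg)
    presence = presence_filter(q, design, cfg)
    q, median_shifts = median_normalize(q)
    q = impute_slsa(q, classes, design, cfg)
    groups = group_columns(design, q.sample_ids)
    control_groups = [(label, cond) for (label, cond) in groups if label in CONTROL_SOURCES]
    q = impute_detquantile(q, classes, design, cfg, groups=control_groups)
    bait_mec: dict[str, set] = {}
    for (label, cond) in groups:
        if label in CONTROL_SOURCES:
            continue
        key = group_key(label, cond)
        bait_mec.setdefault(label, set()).update(classes.index[classes[key] == MEC])
    q, center_shifts = mean_center(q, design)
    report = {
        "class_counts": {k: classes[k].value_counts().to_dict() for k in classes.columns},
        "median_shifts": median_shifts.round(6).to_dict(),
        "center_shifts": center_shifts.round(6).to_dict(),
        "presence_survivors": {k: int(presence[k].sum()) for k in presence.columns},
    }
    return ProcessedMatrix(q, classes, presence, bait_mec, report)
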