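"""Hydroxyurea differential-interactome analysis.

For each bait-prey pair the enrichment ratio is the binary logarithm of the
bait's mean prey intensity (NT or HU, linear-scale mean over biological
replicates) over the *untreated* GFP-NLS control baseline — the same baseline
for both conditions, since HU leaves the nuclear background essentially
unchanged.  A pair is "enriched" in a condition when its log2 ratio is >= 1
(boundary inclusive).

The classified quantity is delta = ratio_HU - ratio_NT.  Per bait, Tukey
fences (Q1 - k*IQR, Q3 + k*IQR, k = 1.5, linear-interpolation quartiles) on
the bait's own delta distribution give two thresholds; a prey is

* ``gained``   when delta > upper fence, it is enriched under HU, and it is a
  scored interactor in at least one condition;
* ``depleted`` when delta < lower fence, enriched without HU, and likewise an
  interactor;
* ``unchanged`` for any other interactor;
* ``not_interactor`` when the prey passed no scoring gate in either condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import QuantMatrix, SampleDesign, baits as design_baits, group_columns

STATUSES = ("gained", "depleted", "unchanged", "not_interactor")


@dataclass(frozen=True)
class IqrThresholds:
    """Tukey fences of one bait's delta distribution."""

    bait: str
    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float
    k: float = 1.5


def linear_group_mean(q: QuantMatrix, cols: list[str]) -> pd.Series:
    """Mean over replicate columns on the linear intensity scale."""
    block = q.intensity[cols]
    if q.log_transformed:
        block = 2.0 ** block
    return block.mean(axis=1)


def enrichment_ratios(
    q_nt: QuantMatrix,
    q_hu: QuantMatrix,
    design: list[SampleDesign],
    log2fc_min: float = 1.0,
    prey_sets: dict[str, set] | None = None,
) -> pd.DataFrame:
    """log2 enrichment ratios of every bait against the untreated GFP-NLS baseline.

    ``prey_sets`` optionally restricts each bait to its admissible prey
    universe (presence-filtered, bait-MEC rows removed).  Both matrices must
    be preprocessed; the baseline must be strictly positive (guaranteed by
    the DetQuantile floor — a nonpositive or missing baseline raises).
    """
    groups_nt = group_columns(design, q_nt.sample_ids)
    baseline_cols = groups_nt.get(("control_gfp_nls", "NT"))
    if not baseline_cols:
        raise ValueError("no untreated GFP-NLS baseline samples")
    baseline = linear_group_mean(q_nt, baseline_cols)
    groups_hu = group_columns(design, q_hu.sample_ids)
    rows = []
    for bait in design_baits(design):
        nt_cols = groups_nt.get((bait, "NT"))
        hu_cols = groups_hu.get((bait, "HU"))
        if not nt_cols or not hu_cols:
            continue
        mean_nt = linear_group_mean(q_nt, nt_cols)
        mean_hu = linear_group_mean(q_hu, hu_cols)
        preys = q_nt.proteins.index
        if prey_sets is not None:
            preys = preys[preys.isin(prey_sets.get(bait, set()))]
        for prey in preys:
            b = baseline[prey]
            m_nt, m_hu = mean_nt[prey], mean_hu[prey]
            if np.isnan(m_nt) or np.isnan(m_hu):
                continue
            if not b > 0 or np.isnan(b):
                raise ValueError(f"nonpositive GFP-NLS baseline for prey {prey!r}")
            ratio_nt = float(np.log2(m_nt / b))
            ratio_hu = float(np.log2(m_hu / b))
            rows.append(
                {
                    "bait": bait,
                    "prey": prey,
                    "ratio_nt": ratio_nt,
                    "ratio_hu": ratio_hu,
                    "delta": ratio_hu - ratio_nt,
                    "enriched_nt": ratio_nt >= log2fc_min,
                    "enriched_hu": ratio_hu >= log2fc_min,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["bait", "prey", "ratio_nt", "ratio_hu", "delta", "enriched_nt", "enriched_hu"],
    )


def iqr_thresholds(deltas, k: float = 1.5, bait: str = "") -> IqrThresholds:
    """Tukey fences from linear-interpolation quartiles of the deltas."""
    values = np.asarray(pd.Series(deltas).dropna(), dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 4:
        raise ValueError("need at least 4 finite deltas for interquartile thresholds")
    q1, q3 = np.quantile(values, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    return IqrThresholds(
        bait=bait, q1=float(q1), q3=float(q3), iqr=float(iqr),
        lower=float(q1 - k * iqr), upper=float(q3 + k * iqr), k=k,
    )


def classify(
    records: pd.DataFrame,
    thr: IqrThresholds,
    interactors_nt: set,
    interactors_hu: set,
) -> pd.DataFrame:
    """Assign one status per record using the bait's own Tukey fences."""
    interactors = set(interactors_nt) | set(interactors_hu)
    out = records.copy()
    status = []
    for rec in out.itertuples(index=False):
        if rec.prey not in interactors:
            status.append("not_interactor")
        elif rec.delta > thr.upper and rec.enriched_hu:
            status.append("gained")
        elif rec.delta < thr.lower and rec.enriched_nt:
            status.append("depleted")
        else:
            status.append("unchanged")
    out["status"] = status
    return out


def classify_all(
    records: pd.DataFrame,
    interactors_nt: dict[str, set],
    interactors_hu: dict[str, set],
    k: float = 1.5,
) -> tuple[pd.DataFrame, dict[str, IqrThresholds]]:
    """Per-bait fences and classification for a multi-bait record table."""
    classified, thresholds = [], {}
    for bait, sub in records.groupby("bait", sort=False):
        thr = iqr_thresholds(sub["delta"], k=k, bait=str(bait))
        thresholds[str(bait)] = thr
        classified.append(
            classify(sub, thr, interactors_nt.get(bait, set()), interactors_hu.get(bait, set()))
        )
    out = pd.concat(classified, ignore_index=True) if classified else records.assign(status=[])
    return out, thresholds


def summarize_by_group(
    records: pd.DataFrame, group_map: dict[str, str]
) -> tuple[pd.DataFrame, dict[frozenset, int]]:
    """Union of gained/depleted preys per functional group, plus Venn counts.

    ``group_map`` maps each bait to its functional group (e.g. CMG, POL, RPA,
    CHR).  Venn counts are exclusive-region cardinalities over the groups'
    changed-prey sets (gained plus depleted), keyed by the frozenset of
    groups covering the region; they sum to the size of the union.
    """
    unassigned = sorted(set(records["bait"]) - set(group_map))
    if unassigned:
        raise ValueError(f"baits without functional group: {unassigned}")
    sets: dict[str, dict[str, set]] = {}
    for rec in records.itertuples(index=False):
        grp = group_map[rec.bait]
        entry = sets.setdefault(grp, {"gained": set(), "depleted": set()})
        if rec.status in ("gained", "depleted"):
            entry[rec.status].add(rec.prey)
    table = pd.DataFrame(
        [
            {
                "group": grp,
                "n_gained": len(v["gained"]),
                "n_depleted": len(v["depleted"]),
                "gained": ";".join(sorted(v["gained"])),
                "depleted": ";".join(sorted(v["depleted"])),
            }
            for grp, v in sorted(sets.items())
        ]
    )
    changed = {grp: v["gained"] | v["depleted"] for grp, v in sets.items()}
    venn: dict[frozenset, int] = {}
    names = sorted(changed)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(changed[g] for g in combo)) if combo else set()
            outside = set.union(set(), *(changed[g] for g in names if g not in combo))
            venn[frozenset(combo)] = len(inside - outside)
    return table, venn
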