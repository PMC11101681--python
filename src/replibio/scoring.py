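"""SAINT-style probabilistic interaction scoring on spectral counts.

Each bait-prey pair is scored against the parental negative control with a
transparent two-component, equal-prior likelihood-ratio posterior: the prey's
background rate lambda0 is the (floored) mean control count, the interaction
rate lambda1 is the bait's mean count (never below lambda0), and each
biological replicate contributes

    p_r = L(x_r | lambda1) / (L(x_r | lambda1) + L(x_r | lambda0))

under a Poisson (default) or negative-binomial count model.  The score is the
mean of the replicate probabilities, so it behaves like SAINT's AvgP at the
decision gates: score >= 0.95 with AvgSpec >= 5 calls a proximal association,
and fold changes over the GFP and GFP-NLS controls provide a secondary gate
(>= 1.5, boundary inclusive).

Counts are expected at the biological-replicate level (technical replicates
pre-averaged), so replicate values may be fractional; likelihoods are
evaluated continuously through the gamma function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import QuantMatrix, SampleDesign, baits as design_baits, group_columns

CONTROL_KEYS = {
    "control_parental": "fc_parental",
    "control_gfp": "fc_gfp",
    "control_gfp_nls": "fc_gfp_nls",
}


@dataclass
class ScoringConfig:
    saint_threshold: float = 0.95
    min_avgspec: float = 5.0
    fc_threshold: float = 1.5
    control_pseudocount: float = 0.1
    count_model: str = "poisson"  # 'poisson' or 'negbin'
    nb_size: float | None = None  # negbin size; estimated from controls if None
    fc_mode: str = "conjunctive"  # 'conjunctive' or 'disjunctive' GFP fold-change gate
    library_scaling: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.saint_threshold < 1:
            raise ValueError("saint_threshold must be in (0, 1)")
        if self.min_avgspec < 0:
            raise ValueError("min_avgspec must be >= 0")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.control_pseudocount <= 0:
            raise ValueError("control_pseudocount must be > 0")
        if self.count_model not in ("poisson", "negbin"):
            raise ValueError(f"unknown count model {self.count_model!r}")
        if self.fc_mode not in ("conjunctive", "disjunctive"):
            raise ValueError(f"unknown fc_mode {self.fc_mode!r}")


def _log_poisson(x: np.ndarray, lam: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * np.log(lam) - lam - gammaln(x + 1.0)


def _log_negbin(x: np.ndarray, mu: float, size: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return (
        gammaln(x + size)
        - gammaln(size)
        - gammaln(x + 1.0)
        + size * np.log(size / (size + mu))
        + x * np.log(mu / (size + mu))
    )


def estimate_nb_size(control_counts: pd.DataFrame) -> float:
    """Method-of-moments negative-binomial size from control replicates.

    Pools the per-prey moment estimates of the quadratic overdispersion
    coefficient (var = mu + mu^2/size) across preys with mean > 0.
    """
    m = control_counts.mean(axis=1)
    v = control_counts.var(axis=1, ddof=1)
    keep = m > 0
    if not keep.any():
        return 100.0
    alpha = ((v[keep] - m[keep]).clip(lower=0) / m[keep] ** 2).mean()
    if alpha <= 1e-6:
        return 100.0
    return float(np.clip(1.0 / alpha, 0.1, 100.0))


def estimate_background(
    q: QuantMatrix,
    design: list[SampleDesign],
    control: str = "control_parental",
    condition: str = "NT",
    cfg: ScoringConfig = ScoringConfig(),
) -> pd.Series:
    """Per-prey background rate: floored mean count over the control bio-reps."""
    groups = group_columns(design, q.sample_ids)
    cols = groups.get((control, condition), [])
    if not cols:
        raise ValueError(f"no control samples of type {control!r} in condition {condition!r}")
    lam0 = q.counts[cols].mean(axis=1).clip(lower=cfg.control_pseudocount)
    lam0.name = "lambda0"
    return lam0


def library_factors(
    q: QuantMatrix,
    bait_cols: list[str],
    control_cols: list[str],
) -> np.ndarray:
    """Total-count library-size factors: bait column sum / mean control column sum."""
    control_mean = float(q.counts[control_cols].sum(axis=0).mean())
    if control_mean <= 0:
        return np.ones(len(bait_cols))
    return q.counts[bait_cols].sum(axis=0).to_numpy() / control_mean


def saint_score(
    bait_counts: np.ndarray,
    lam0: float,
    cfg: ScoringConfig = ScoringConfig(),
    scale: np.ndarray | None = None,
    nb_size: float | None = None,
) -> tuple[np.ndarray, float]:
    """Replicate probabilities and their mean for one bait-prey pair.

    ``scale`` optionally carries per-replicate library-size factors applied to
    the background rate.  When the interaction rate collapses onto the
    background rate every replicate probability is exactly 0.5.
    """
    x = np.asarray(bait_counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    if lam0 <= 0:
        raise ValueError("lambda0 must be > 0")
    scale = np.ones_like(x) if scale is None else np.asarray(scale, dtype=float)
    lam0_r = lam0 * scale
    lam1 = max(float(x.mean()), lam0)
    lam1_r = np.maximum(lam1, lam0_r)
    if cfg.count_model == "poisson":
        log_l1 = _log_poisson(x, lam1_r)
        log_l0 = _log_poisson(x, lam0_r)
    else:
        size = nb_size if nb_size is not None else (cfg.nb_size or 10.0)
        log_l1 = _log_negbin(x, lam1_r, size)
        log_l0 = _log_negbin(x, lam0_r, size)
    with np.errstate(over="ignore"):
        probs = 1.0 / (1.0 + np.exp(log_l0 - log_l1))
    probs = np.where(np.isclose(lam1_r, lam0_r), 0.5, probs)
    return probs, float(probs.mean())


def fold_changes(
    bait_avg: float, control_avgs: dict[str, float], cfg: ScoringConfig = ScoringConfig()
) -> dict[str, float]:
    """Fold change of the bait average over each (floored) control average."""
    return {
        CONTROL_KEYS[src]: bait_avg / max(avg, cfg.control_pseudocount)
        for src, avg in control_avgs.items()
    }


def call_interactions(
    q: QuantMatrix,
    design: list[SampleDesign],
    cfg: ScoringConfig = ScoringConfig(),
    condition: str = "NT",
) -> pd.DataFrame:
    """Score every (bait, prey) pair with a nonzero bait count.

    Returns one row per pair with AvgSpec, the SAINT-style score, fold changes
    over all three controls, and the two pass flags:

    * ``passes_primary``: score >= threshold (parental control) and
      AvgSpec >= minimum — the interactor gate;
    * ``passes_fc``: fold change >= threshold over the GFP and GFP-NLS
      controls (conjunctive by default).

    Calls are sorted by bait, then descending score, then descending AvgSpec.
    """
    groups = group_columns(design, q.sample_ids)
    controls_present = {src for (src, cond) in groups if cond == condition and src in CONTROL_KEYS}
    missing_controls = set(CONTROL_KEYS) - controls_present
    if missing_controls:
        raise ValueError(f"missing control groups for {condition}: {sorted(missing_controls)}")
    lam0 = estimate_background(q, design, "control_parental", condition, cfg)
    parental_cols = groups[("control_parental", condition)]
    control_avg = {
        src: q.counts[groups[(src, condition)]].mean(axis=1) for src in CONTROL_KEYS
    }
    nb_size = None
    if cfg.count_model == "negbin" and cfg.nb_size is None:
        nb_size = estimate_nb_size(q.counts[parental_cols])
    rows = []
    for bait in design_baits(design):
        bait_cols = groups.get((bait, condition))
        if not bait_cols:
            continue
        scale = (
            library_factors(q, bait_cols, parental_cols)
            if cfg.library_scaling
            else np.ones(len(bait_cols))
        )
        counts = q.counts[bait_cols]
        nonzero = counts.sum(axis=1) > 0
        for prey in counts.index[nonzero]:
            x = counts.loc[prey].to_numpy()
            probs, score = saint_score(x, float(lam0[prey]), cfg, scale=scale, nb_size=nb_size)
            avg_spec = float(x.mean())
            fcs = fold_changes(avg_spec, {src: float(control_avg[src][prey]) for src in CONTROL_KEYS}, cfg)
            gfp_pass = fcs["fc_gfp"] >= cfg.fc_threshold
            nls_pass = fcs["fc_gfp_nls"] >= cfg.fc_threshold
            rows.append(
                {
                    "bait": bait,
                    "prey": prey,
                    "gene_symbol": q.proteins.loc[prey, "gene_symbol"],
                    "avg_spec": avg_spec,
                    "saint_score": score,
                    "rep_probs": ";".join(f"{p:.6f}" for p in probs),
                    **fcs,
                    "passes_primary": score >= cfg.saint_threshold and avg_spec >= cfg.min_avgspec,
                    "passes_fc": (gfp_pass and nls_pass) if cfg.fc_mode == "conjunctive" else (gfp_pass or nls_pass),
                }
            )
    calls = pd.DataFrame(
        rows,
        columns=[
            "bait", "prey", "gene_symbol", "avg_spec", "saint_score", "rep_probs",
            "fc_parental", "fc_gfp", "fc_gfp_nls", "passes_primary", "passes_fc",
        ],
    )
    if not calls.empty:
        calls = calls.sort_values(
            ["bait", "saint_score", "avg_spec"], ascending=[True, False, False]
        ).reset_index(drop=True)
    return calls


def interactor_sets(calls: pd.DataFrame) -> dict[str, set]:
    """Per bait, the preys passing the primary (score + AvgSpec) gate."""
    out: dict[str, set] = {}
    if calls.empty:
        return out
    for bait, sub in calls.groupby("bait"):
        out[str(bait)] = set(sub.loc[sub["passes_primary"], "prey"])
    return out


def saint_list_table(calls: pd.DataFrame) -> pd.DataFrame:
    """SAINT 'list.txt'-style view of the calls (Bait/Prey/AvgSpec/AvgP...)."""
    return calls.rename(
        columns={
            "bait": "Bait",
            "prey": "Prey",
            "gene_symbol": "PreyGene",
            "avg_spec": "AvgSpec",
            "saint_score": "AvgP",
            "fc_gfp": "FoldChange_GFP",
            "fc_gfp_nls": "FoldChange_GFP_NLS",
            "fc_parental": "FoldChange_Parental",
        }
    )[
        ["Bait", "Prey", "PreyGene", "AvgSpec", "AvgP",
         "FoldChange_Parental", "FoldChange_GFP", "FoldChange_GFP_NLS"]
    ]
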