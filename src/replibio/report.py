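"""Summary artifacts: correlation heatmap input, dot-plot tables, networks.

These mirror the standard AP-MS reporting toolkit: a bait-bait Pearson
correlation matrix over AvgSpec prey profiles (ProHits-viz style, absent
preys as zero) with an average-linkage dendrogram order, dot-plot tables of
per-prey relative abundance, and Cytoscape-compatible SIF/GraphML network
exports annotated with interaction scores and HU status.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .io import QuantMatrix, SampleDesign, baits as design_baits, group_columns


def avgspec_profiles(
    q: QuantMatrix, design: list[SampleDesign], condition: str = "NT"
) -> pd.DataFrame:
    """Prey x bait matrix of mean spectral counts (absent preys are 0)."""
    groups = group_columns(design, q.sample_ids)
    profiles = {}
    for bait in design_baits(design):
        cols = groups.get((bait, condition))
        if cols:
            profiles[bait] = q.counts[cols].mean(axis=1)
    return pd.DataFrame(profiles).fillna(0.0)


def bait_correlation(
    q: QuantMatrix, design: list[SampleDesign], condition: str = "NT"
) -> tuple[pd.DataFrame, list[str]]:
    """Bait-bait Pearson correlation of AvgSpec profiles + dendrogram order.

    Hierarchical clustering uses average linkage on the 1 - r distance.
    """
    profiles = avgspec_profiles(q, design, condition)
    zero = profiles.columns[(profiles == 0).all(axis=0) | (profiles.std(axis=0) == 0)]
    if len(zero):
        raise ValueError(f"baits with constant/all-zero profiles: {list(zero)}")
    corr = profiles.corr(method="pearson")
    order = list(corr.columns)
    if len(order) > 2:
        dist = squareform((1.0 - corr.to_numpy()).clip(min=0.0), checks=False)
        linkage = hierarchy.average(dist)
        order = [corr.columns[i] for i in hierarchy.leaves_list(linkage)]
    return corr, order


def control_concordance(
    q_nt: QuantMatrix,
    q_hu: QuantMatrix,
    design: list[SampleDesign],
    control: str = "control_gfp_nls",
    layer: str = "intensity",
) -> float:
    """Pearson r between a control's mean prey profiles in NT vs HU.

    Defaults to mean log2-intensity profiles over co-observed preys (the LFQ
    convention); ``layer='counts'`` correlates mean spectral counts instead.
    """
    groups_nt = group_columns(design, q_nt.sample_ids)
    groups_hu = group_columns(design, q_hu.sample_ids)
    cols_nt = groups_nt.get((control, "NT"))
    cols_hu = groups_hu.get((control, "HU"))
    if not cols_nt or not cols_hu:
        raise ValueError(f"control {control!r} missing in one of the conditions")
    if layer == "counts":
        prof_nt = q_nt.counts[cols_nt].mean(axis=1)
        prof_hu = q_hu.counts[cols_hu].mean(axis=1)
    else:
        def log_profile(q: QuantMatrix, cols: list[str]) -> pd.Series:
            block = q.intensity[cols]
            if not q.log_transformed:
                with np.errstate(divide="ignore"):
                    block = np.log2(block.where(block > 0))
            return block.mean(axis=1)

        prof_nt = log_profile(q_nt, cols_nt)
        prof_hu = log_profile(q_hu, cols_hu)
    shared = pd.concat({"nt": prof_nt, "hu": prof_hu}, axis=1, join="inner").dropna()
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared preys between conditions")
    r, _ = pearsonr(shared["nt"], shared["hu"])
    return float(r)


def dotplot_table(calls: pd.DataFrame, preys: list[str] | None = None) -> pd.DataFrame:
    """Per (prey, bait) relative abundance cells for ProHits-viz-style dot plots.

    relative_abundance = AvgSpec / max AvgSpec of that prey over all baits;
    the per-prey maximum is exactly 1 for any detected prey.  Cells carry the
    SAINT-style score for edge coloring.
    """
    if preys is not None:
        calls = calls[calls["prey"].isin(set(preys))]
        if calls.empty:
            raise ValueError("empty prey subset")
    if calls.empty:
        raise ValueError("no calls to plot")
    max_spec = calls.groupby("prey")["avg_spec"].transform("max")
    out = calls.loc[:, ["bait", "prey", "gene_symbol", "avg_spec", "saint_score"]].copy()
    out["relative_abundance"] = np.where(max_spec > 0, calls["avg_spec"] / max_spec, 0.0)
    return out.sort_values(["prey", "bait"]).reset_index(drop=True)


def build_network(
    records: pd.DataFrame,
    calls: pd.DataFrame,
    group_map: dict[str, str] | None = None,
) -> nx.DiGraph:
    """Bait -> prey graph with score/abundance/status edge attributes.

    Edge status comes from the HU classification when available
    (gained/depleted map to themselves, anything else to "stable").
    """
    graph = nx.DiGraph()
    group_map = group_map or {}
    status_lookup = {}
    if not records.empty and "status" in records.columns:
        status_lookup = {
            (r.bait, r.prey): r.status for r in records.itertuples(index=False)
        }
    for call in calls.itertuples(index=False):
        status = status_lookup.get((call.bait, call.prey), "stable")
        token = status if status in ("gained", "depleted") else "stable"
        graph.add_node(call.bait, kind="bait", functional_group=group_map.get(call.bait, ""))
        graph.add_node(call.prey, kind="prey", gene_symbol=str(call.gene_symbol))
        graph.add_edge(
            call.bait,
            call.prey,
            saint_score=float(call.saint_score),
            avg_spec=float(call.avg_spec),
            status=token,
        )
    return graph


def export_network(
    records: pd.DataFrame,
    calls: pd.DataFrame,
    outdir: str | Path,
    group_map: dict[str, str] | None = None,
) -> dict[str, Path]:
    """Write node/edge TSVs, a SIF file and GraphML for one interaction network."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph = build_network(records, calls, group_map)
    paths = {
        "nodes": outdir / "nodes.tsv",
        "edges": outdir / "edges.tsv",
        "sif": outdir / "network.sif",
        "graphml": outdir / "network.graphml",
    }
    nodes = pd.DataFrame(
        [{"node": n, **attrs} for n, attrs in sorted(graph.nodes(data=True))],
        columns=["node", "kind", "functional_group", "gene_symbol"],
    )
    edges = pd.DataFrame(
        [{"bait": u, "prey": v, **attrs} for u, v, attrs in sorted(graph.edges(data=True))],
        columns=["bait", "prey", "saint_score", "avg_spec", "status"],
    )
    nodes.to_csv(paths["nodes"], sep="\t", index=False)
    edges.to_csv(paths["edges"], sep="\t", index=False)
    with open(paths["sif"], "w") as fh:
        for u, v, attrs in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{attrs['status']}\t{v}\n")
    nx.write_graphml(graph, paths["graphml"])
    return paths


def correlation_heatmap_figure(corr: pd.DataFrame, order: list[str], path: str | Path) -> None:
    """Optional static rendering of the bait correlation heatmap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = corr.loc[order, order]
    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(order), 1 + 0.5 * len(order)))
    im = ax.imshow(data.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)), order, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
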