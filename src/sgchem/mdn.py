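"""Mass-difference networking.

Nodes are LC-MS features; an undirected edge joins two features whose m/z
difference matches a tabulated neutral loss (glycosylation, hydroxylation,
saturation, acetylation, malonylation) within tolerance AND whose retention
times lie within a co-elution window — in-source fragments of one compound
co-elute, so the window is tight by default (0.1 min).  Singleton nodes are
pruned, nodes are annotated with per-group intensity fractions and an
association label, and the network exports to standard GraphML.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .core import FeatureTable
from .masschem import ResidueTable, default_residue_table

DEFAULT_LOSSES = ("hexose", "deoxyhexose", "pentose", "malonylhexoside",
                  "hydroxylation", "saturation", "acetylation")


def build_mdn(
    features: FeatureTable,
    losses: ResidueTable | None = None,
    mz_tol: float = 0.02,
    rt_window: float = 0.1,
) -> nx.Graph:
    """Infer the mass-difference network from a feature table.

    Edge (i, j) exists iff ``||mz_i - mz_j| - loss mass| <= mz_tol`` for some
    loss and ``|rt_i - rt_j| <= rt_window``; when several losses match, the one
    with the smallest mass error is kept.
    """
    if features.n_features < 2:
        raise ValueError("need at least 2 features to build a network")
    if mz_tol <= 0 or rt_window <= 0:
        raise ValueError("tolerances must be > 0")
    table = losses or default_residue_table().subset(DEFAULT_LOSSES)
    loss_names = table.names
    loss_masses = np.array([table.mass(n) for n in loss_names])

    g = nx.Graph(mz_tol=mz_tol, rt_window=rt_window)
    ids = features.features.index.to_numpy()
    mz = features.features["mz"].to_numpy(float)
    rt = features.features["rt"].to_numpy(float)
    for fid, m, r in zip(ids, mz, rt):
        inten = features.intensities.loc[fid]
        g.add_node(fid, mz=float(m), rt=float(r),
                   total_intensity=float(inten.sum()))
    order = np.argsort(mz)
    mz_s, rt_s, ids_s = mz[order], rt[order], ids[order]
    max_loss = loss_masses.max() + mz_tol
    for i in range(len(mz_s)):
        j = i + 1
        while j < len(mz_s) and mz_s[j] - mz_s[i] <= max_loss:
            if abs(rt_s[i] - rt_s[j]) <= rt_window:
                errs = np.abs((mz_s[j] - mz_s[i]) - loss_masses)
                k = int(np.argmin(errs))
                if errs[k] <= mz_tol:
                    g.add_edge(ids_s[i], ids_s[j], loss=loss_names[k],
                               delta_mz=float(mz_s[j] - mz_s[i]),
                               mass_error=float(errs[k]))
            j += 1
    _assign_components(g)
    return g


def _assign_components(g: nx.Graph) -> None:
    for cid, comp in enumerate(nx.connected_components(g)):
        for n in comp:
            g.nodes[n]["component"] = cid


def prune_singletons(g: nx.Graph) -> nx.Graph:
    """Drop degree-0 nodes; edges are untouched."""
    out = g.copy()
    out.remove_nodes_from([n for n, d in g.degree() if d == 0])
    _assign_components(out)
    return out


def annotate_associations(
    g: nx.Graph,
    features: FeatureTable,
    grouping: str = "chemotype",
    threshold: float = 0.75,
) -> nx.Graph:
    """Per-node intensity fractions over the levels of one metadata factor.

    For the chemotype grouping a node is labelled S (or U) when that level
    carries at least ``threshold`` of its summed intensity, else ``neutral``;
    other groupings store the fractions and the dominant level the same way.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0.5, 1]")
    meta = features.metadata
    missing = [s for s in features.samples if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    if grouping not in meta.columns:
        raise ValueError(f"unknown grouping column: {grouping}")
    levels = sorted(meta[grouping].unique())
    group_of = meta[grouping]
    out = g.copy()
    for n in out.nodes:
        inten = features.intensities.loc[n]
        total = float(inten.sum())
        fractions = {}
        for lev in levels:
            cols = group_of[group_of == lev].index
            frac = float(inten[cols].sum()) / total if total > 0 else 0.0
            fractions[lev] = frac
            out.nodes[n][f"frac_{grouping}_{lev}"] = frac
        label = "neutral"
        for lev, frac in fractions.items():
            if frac >= threshold:
                label = lev
        out.nodes[n][f"association_{grouping}"] = label
    return out


def export_graphml(g: nx.Graph, path) -> None:
    """Write standard GraphML (losslessly re-importable via networkx)."""
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
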