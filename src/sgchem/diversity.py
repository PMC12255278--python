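"""Chemodiversity indices on glycoside count matrices.

Margalef's richness Dmg = (S - 1)/ln N and Pielou's evenness J = H'/ln S
(Shannon H' with natural logarithms), computed per sample from the counts of
glycosides per aglycone species, plus the summed network-feature intensity
TIC_SG (excluding designated artifact signals) and Pearson correlations
between intensity and diversity.

Degenerate cases: all-zero counts yield NaN (undefined); N = 1 yields
Dmg = 0 by continuity of the numerator; S = 1 leaves J undefined.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import FeatureTable


def margalef(counts: Sequence[float]) -> float:
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    N = c.sum()
    S = int((c > 0).sum())
    if N == 0:
        return float("nan")
    if N == 1 or S == 1:
        return 0.0
    return (S - 1) / np.log(N)


def shannon(counts: Sequence[float]) -> float:
    c = np.asarray(counts, dtype=float)
    N = c.sum()
    if N == 0:
        return float("nan")
    p = c[c > 0] / N
    return float(-(p * np.log(p)).sum())


def pielou(counts: Sequence[float]) -> tuple[float, float]:
    """(Shannon H', evenness J = H'/ln S); J is NaN when S <= 1."""
    c = np.asarray(counts, dtype=float)
    N = c.sum()
    if N == 0:
        return float("nan"), float("nan")
    S = int((c > 0).sum())
    H = shannon(c)
    if S <= 1:
        return H, float("nan")
    return H, H / np.log(S)


def tic_sg(
    features: FeatureTable,
    network_nodes: Iterable[str] | nx.Graph,
    exclude_mz: Sequence[float] = (329.32,),
    tol: float = 0.02,
) -> pd.Series:
    """Per-sample summed intensity over network features, minus exclusions."""
    if isinstance(network_nodes, nx.Graph):
        network_nodes = list(network_nodes.nodes)
    nodes = [n for n in network_nodes]
    unknown = [n for n in nodes if n not in features.features.index]
    if unknown:
        raise ValueError(f"network nodes not in feature table: {unknown[:5]}")
    mz = features.features.loc[nodes, "mz"]
    keep = [n for n in nodes
            if all(abs(mz[n] - x) > tol for x in exclude_mz)]
    return features.intensities.loc[keep].sum(axis=0)


def correlate(
    x: pd.Series,
    y: pd.Series,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson r with two-sided p, overall and (optionally) per group."""
    def one(xv, yv, label):
        xv, yv = np.asarray(xv, float), np.asarray(yv, float)
        ok = np.isfinite(xv) & np.isfinite(yv)
        xv, yv = xv[ok], yv[ok]
        if len(xv) < 3 or np.std(xv) == 0 or np.std(yv) == 0:
            return {"group": label, "n": len(xv), "r": float("nan"),
                    "p": float("nan")}
        r, p = stats.pearsonr(xv, yv)
        return {"group": label, "n": len(xv), "r": float(r), "p": float(p)}

    x, y = x.align(y, join="inner")
    rows = [one(x, y, "overall")]
    if groups is not None:
        for level, idx in x.groupby(groups.reindex(x.index)).groups.items():
            rows.append(one(x.loc[idx], y.loc[idx], str(level)))
    return pd.DataFrame(rows).set_index("group")


def diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-sample record of S, N, Dmg, H' and J."""
    rows = []
    for sample, row in counts.iterrows():
        c = row.to_numpy(float)
        H, J = pielou(c)
        rows.append({"sample": sample, "S": int((c > 0).sum()),
                     "N": int(c.sum()), "Dmg": margalef(c),
                     "H": H, "J": J})
    return pd.DataFrame(rows).set_index("sample")


def group_summaries(div: pd.DataFrame, metadata: pd.DataFrame,
                    factors: Sequence[str] = ("chemotype", "organ", "ontogeny"),
                    ) -> pd.DataFrame:
    """Mean +- sd of each index per factor combination (descriptive only)."""
    joined = div.join(metadata[list(factors)])
    agg = joined.groupby(list(factors))[["Dmg", "J", "H"]].agg(["mean", "std", "count"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg.reset_index()
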