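"""Compositional correlation networks and microbial hub detection.

Metagenomic profiles are compositions: closing each sample to sum 1 induces
spurious negative correlation between raw proportions, so pairwise analysis
runs on the centered log-ratio (CLR) transform — log of each component over
the row geometric mean. The estimator here is CLR + pairwise Pearson with
Benjamini–Hochberg FDR control across all pairs and a bootstrap edge-
stability fraction. The interface (abundance matrix in, network out) is
estimator-agnostic, so a latent-covariance estimator can be plugged in
behind it.

A *hub* is a connected component of the positive-edge subgraph with at least
``min_size`` members — the simplest reproducible formalization of a group of
mutually positively co-occurring taxa.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiling import RankProfile
from .taxonomy import TaxonomyTree


def relative_abundance_matrix(
    profiles_by_sample: Mapping[str, RankProfile],
    min_prevalence: float = 0.0,
) -> pd.DataFrame:
    """Samples x taxa matrix of mean-depth abundances closed to sum 1.

    Absent taxa are 0; taxa present in fewer than ``min_prevalence`` of the
    samples are dropped; samples with no classified reads are dropped with a
    warning.
    """
    if len(profiles_by_sample) < 2:
        raise ValueError("need at least 2 samples")
    rows = {}
    for sample, profile in profiles_by_sample.items():
        depths = {t: r.mean_depth for t, r in profile.rows.items()}
        if not depths:
            warnings.warn(f"sample {sample!r} has no classified reads: dropped")
            continue
        rows[sample] = depths
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    df = df.reindex(sorted(df.columns), axis=1)
    if min_prevalence > 0:
        prevalence = (df > 0).mean(axis=0)
        df = df.loc[:, prevalence >= min_prevalence]
    return close_composition(df)


def close_composition(df: pd.DataFrame) -> pd.DataFrame:
    return df.div(df.sum(axis=1), axis=0)


def clr_transform(matrix: pd.DataFrame, zero_policy: str = "half-min") -> pd.DataFrame:
    """Centered log-ratio transform with zero replacement.

    ``half-min`` replaces zeros with half the smallest nonzero value in the
    same sample; ``multiplicative`` uses a small uniform pseudo-proportion
    and rescales nonzero entries. Every output row sums to zero.
    """
    if matrix.shape[1] < 2:
        raise ValueError("CLR is undefined for a single-taxon composition")
    x = matrix.to_numpy(dtype=float).copy()
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    for i in range(x.shape[0]):
        row = x[i]
        zeros = row == 0
        if zeros.any():
            if not (~zeros).any():
                raise ValueError("row with all-zero abundances")
            if zero_policy == "half-min":
                row[zeros] = row[~zeros].min() / 2.0
            elif zero_policy == "multiplicative":
                delta = 0.65 * row[~zeros].min()
                row[~zeros] *= 1.0 - delta * zeros.sum()
                row[zeros] = delta
            else:
                raise ValueError(f"unknown zero policy {zero_policy!r}")
        x[i] = row / row.sum()
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=matrix.index, columns=matrix.columns)


@dataclass
class Edge:
    taxon_i: int
    taxon_j: int
    r: float
    q_value: float
    stability: float | None = None


@dataclass
class CorrelationNetwork:
    graph: nx.Graph
    hubs: dict[int, int] = field(default_factory=dict)  # node -> hub id

    @property
    def edges(self) -> list[Edge]:
        return [
            Edge(i, j, d["r"], d["q"], d.get("stability"))
            for i, j, d in self.graph.edges(data=True)
        ]


def _pearson_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise r and two-sided p-values (t-distribution) on columns."""
    n, p = x.shape
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pvals[np.isnan(pvals)] = 0.0  # |r| == 1 exactly
    return r, pvals


def correlation_network(
    clr_matrix: pd.DataFrame,
    r_min: float = 0.5,
    fdr: float = 0.05,
    n_boot: int = 100,
    seed: int | None = None,
) -> CorrelationNetwork:
    """Build the co-occurrence network from CLR-transformed abundances.

    Pairwise Pearson on CLR columns; Benjamini–Hochberg across all pairs;
    an edge is kept iff q <= fdr and |r| >= r_min. With ``n_boot > 0`` each
    edge carries a stability fraction: the share of sample-bootstrap
    resamples in which the pair's |r| still clears r_min with the same sign.
    Constant columns are excluded with a warning.
    """
    if clr_matrix.shape[0] < 10:
        warnings.warn("fewer than 10 samples: correlation estimates are unstable")
    x = clr_matrix.to_numpy(dtype=float)
    cols = np.asarray(clr_matrix.columns)
    keep = x.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} constant column(s)")
        x, cols = x[:, keep], cols[keep]
    n, p = x.shape
    graph = nx.Graph()
    graph.add_nodes_from(cols.tolist())
    if p < 2:
        return CorrelationNetwork(graph)
    r, pvals = _pearson_matrix(x)
    iu = np.triu_indices(p, k=1)
    flat_p = pvals[iu]
    _rej, qvals, _a, _b = multipletests(flat_p, alpha=fdr, method="fdr_bh")
    selected = (qvals <= fdr) & (np.abs(r[iu]) >= r_min)
    idx_pairs = [
        (iu[0][k], iu[1][k]) for k in np.nonzero(selected)[0]
    ]
    stability: dict[tuple[int, int], float] = {}
    if n_boot > 0 and idx_pairs:
        rng = np.random.default_rng(seed)
        counts = {pair: 0 for pair in idx_pairs}
        for _ in range(n_boot):
            resample = rng.integers(0, n, size=n)
            xb = x[resample]
            ok = xb.std(axis=0) > 0
            rb = np.corrcoef(xb, rowvar=False)
            for (i, j) in idx_pairs:
                if ok[i] and ok[j] and abs(rb[i, j]) >= r_min and np.sign(rb[i, j]) == np.sign(r[i, j]):
                    counts[(i, j)] += 1
        stability = {pair: c / n_boot for pair, c in counts.items()}
    for k in np.nonzero(selected)[0]:
        i, j = iu[0][k], iu[1][k]
        graph.add_edge(
            cols[i].item(), cols[j].item(),
            r=float(r[i, j]), q=float(qvals[k]),
            stability=stability.get((i, j)),
        )
    return CorrelationNetwork(graph)


def detect_hubs(network: CorrelationNetwork, min_size: int = 3) -> CorrelationNetwork:
    """Label hubs: connected components of the positive-edge subgraph.

    Adds a sign summary as graph attributes: fraction of within-hub edges
    that are positive and fraction of between-hub edges that are negative.
    """
    positive = nx.Graph(
        (u, v) for u, v, d in network.graph.edges(data=True) if d["r"] > 0
    )
    hubs: dict[int, int] = {}
    hub_id = 0
    for component in nx.connected_components(positive):
        if len(component) >= min_size:
            for node in component:
                hubs[node] = hub_id
            hub_id += 1
    network.hubs = hubs
    within = between = within_pos = between_neg = 0
    for u, v, d in network.graph.edges(data=True):
        if u in hubs and v in hubs and hubs[u] == hubs[v]:
            within += 1
            within_pos += d["r"] > 0
        elif u in hubs and v in hubs:
            between += 1
            between_neg += d["r"] < 0
    network.graph.graph["within_hub_positive_frac"] = (
        within_pos / within if within else None
    )
    network.graph.graph["between_hub_negative_frac"] = (
        between_neg / between if between else None
    )
    return network


def aggregate_to_rank(
    abundance: pd.DataFrame, tree: TaxonomyTree, rank: str
) -> pd.DataFrame:
    """Sum strain-level abundance columns by their ancestor at ``rank``.

    Columns whose lineage lacks the rank are dropped; rows are re-closed.
    """
    groups: dict[int, list] = {}
    for col in abundance.columns:
        ancestor = tree.lineage_of(int(col), rank)
        if ancestor is not None:
            groups.setdefault(ancestor, []).append(col)
    out = pd.DataFrame(
        {anc: abundance[cols].sum(axis=1) for anc, cols in groups.items()},
        index=abundance.index,
    )
    return close_composition(out)


def write_edges(network: CorrelationNetwork, path) -> None:
    with open(path, "w") as out:
        out.write("taxid_i\ttaxid_j\tr\tq\tstability\n")
        for e in sorted(network.edges, key=lambda e: (e.taxon_i, e.taxon_j)):
            stab = "" if e.stability is None else repr(e.stability)
            out.write(f"{e.taxon_i}\t{e.taxon_j}\t{e.r!r}\t{e.q_value!r}\t{stab}\n")


def write_hubs(network: CorrelationNetwork, path) -> None:
    with open(path, "w") as out:
        out.write("taxid\thub_id\n")
        for node, hub in sorted(network.hubs.items()):
            out.write(f"{node}\t{hub}\n")


def plot_correlogram(clr_matrix: pd.DataFrame, network: CorrelationNetwork, path) -> None:
    """Heatmap of the correlation matrix, columns ordered by hub membership."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = sorted(
        clr_matrix.columns, key=lambda c: (network.hubs.get(c, -1), c)
    )
    r = np.corrcoef(clr_matrix[order].to_numpy(), rowvar=False)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(r, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(order)))
    ax.set_yticks(range(len(order)))
    ax.set_xticklabels(order, rotation=90, fontsize=6)
    ax.set_yticklabels(order, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r (CLR)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
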