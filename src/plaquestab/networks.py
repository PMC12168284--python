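"""Sparse microbial association networks and core association networks.

Per group × visit, a signed association network is inferred from CLR data by
neighborhood selection (MB): every species is L1-regressed on all others,
an edge is kept when either neighborhood selects it (OR rule), and the
penalty is chosen by StARS-style stability selection. Per-visit networks are
then combined into a Core Association Network (CAN): the edges recurring in
at least ``ceil(set_size_frac × N)`` of the input networks (set size 1.0 =
exact intersection). CANs are clustered with Clauset–Newman–Moore greedy
modularity maximization on the unsigned skeleton; Q = Σ_c (e_cc − a_c²).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from .composition import ClrMatrix


@dataclass
class AssociationNetwork:
    """Signed weighted undirected graph over species (canonical source < target)."""

    nodes: list[str]
    edges: pd.DataFrame  # columns: source, target, sign, weight
    meta: dict = field(default_factory=dict)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(s, t) for s, t in zip(self.edges["source"], self.edges["target"])}


@dataclass
class ConsensusNetwork:
    nodes: list[str]
    edges: pd.DataFrame  # columns: source, target, occurrence_count, sign
    set_size_frac: float
    n_networks: int

    def edge_set(self) -> set[tuple[str, str]]:
        return {(s, t) for s, t in zip(self.edges["source"], self.edges["target"])}


@dataclass
class ClusterPartition:
    assignment: dict  # node -> cluster id (1-based)
    modularity: float
    sizes: dict  # cluster id -> member count


def _as_frame(clr) -> pd.DataFrame:
    return clr.data if isinstance(clr, ClrMatrix) else pd.DataFrame(clr)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _neighborhood_coefs(x: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """coefs[a, j, k] = coefficient of node k in the neighborhood of node j
    at penalty alphas[a] (coefs[a, j, j] = 0)."""
    n, p = x.shape
    out = np.zeros((len(alphas), p, p))
    idx = np.arange(p)
    for j in range(p):
        others = idx[idx != j]
        _, coefs, _ = lasso_path(x[:, others], x[:, j], alphas=alphas)
        out[:, j, others] = coefs.T  # lasso_path returns (n_features, n_alphas)
    return out


def _adjacency(coefs: np.ndarray) -> np.ndarray:
    """OR-rule symmetric boolean adjacency per alpha."""
    sel = coefs != 0
    return sel | sel.transpose(0, 2, 1)


def infer_network_mb(
    clr_subset,
    lambda_grid: np.ndarray | None = None,
    stars_subsample_frac: float = 0.8,
    stars_reps: int = 20,
    stability_threshold: float = 0.05,
    seed: int | None = None,
    min_samples: int = 20,
) -> AssociationNetwork:
    """Neighborhood-selection (MB) network with StARS penalty selection.

    Each species' CLR column is lasso-regressed on all others over a shared
    penalty grid; per subsample the OR-rule adjacency is recorded, the edge
    instability ``mean 2ξ(1−ξ)`` per penalty is monotonized from the sparse
    end, and the smallest penalty whose instability stays at or below
    ``stability_threshold`` is chosen. The final network is the full-data
    fit at that penalty; an edge's sign and weight come from the larger-
    magnitude of its two directional coefficients.
    """
    df = _as_frame(clr_subset)
    n = len(df)
    if n < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {n}")
    variances = df.var(axis=0)
    constant = variances.index[variances == 0].tolist()
    if constant:
        warnings.warn(f"dropping constant columns: {constant}")
        df = df.drop(columns=constant)
    nodes = sorted(df.columns)
    df = df[nodes]
    x_full = _standardize(df.to_numpy(dtype=float))
    p = len(nodes)

    if lambda_grid is None:
        amax = 0.0
        for j in range(p):
            others = np.delete(np.arange(p), j)
            amax = max(amax, np.abs(x_full[:, others].T @ x_full[:, j]).max() / n)
        lambda_grid = amax * np.logspace(0, -2, 20)
    alphas = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    rng = np.random.default_rng(seed)
    b = int(math.floor(stars_subsample_frac * n))
    freq = np.zeros((len(alphas), p, p))
    for _ in range(stars_reps):
        take = rng.choice(n, size=b, replace=False)
        xs = _standardize(df.to_numpy(dtype=float)[take])
        freq += _adjacency(_neighborhood_coefs(xs, alphas))
    xi = freq / stars_reps
    iu = np.triu_indices(p, 1)
    instab = np.array([(2 * xi[a][iu] * (1 - xi[a][iu])).mean() for a in range(len(alphas))])
    runmax = np.maximum.accumulate(instab)  # monotonized from the sparse end
    ok = np.where(runmax <= stability_threshold)[0]
    if len(ok):
        chosen = int(ok[-1])  # smallest penalty still within the threshold
    else:
        chosen = 0
        warnings.warn("no penalty met the stability threshold; using the sparsest")

    coefs = _neighborhood_coefs(x_full, alphas)[chosen]
    edges = []
    for i in range(p):
        for j in range(i + 1, p):
            c_ij, c_ji = coefs[i, j], coefs[j, i]
            if c_ij == 0 and c_ji == 0:
                continue
            w = c_ij if abs(c_ij) >= abs(c_ji) else c_ji
            edges.append(
                {"source": nodes[i], "target": nodes[j],
                 "sign": "+" if w > 0 else "-", "weight": float(w)}
            )
    edge_df = pd.DataFrame(edges, columns=["source", "target", "sign", "weight"])
    return AssociationNetwork(
        nodes=nodes,
        edges=edge_df,
        meta={
            "penalty": float(alphas[chosen]),
            "stability_threshold": stability_threshold,
            "stars_reps": stars_reps,
            "stars_subsample_frac": stars_subsample_frac,
            "seed": seed,
            "n_samples": n,
            "instability": float(instab[chosen]),
        },
    )


def build_can(
    networks: list[AssociationNetwork], set_size_frac: float
) -> ConsensusNetwork:
    """Consensus of edge sets across networks.

    An edge (canonical pair identity, weights ignored) is retained iff it
    appears in at least ``ceil(set_size_frac × N)`` of the N input networks;
    its consensus sign is the majority sign, and sign ties drop the edge.
    """
    if not networks:
        raise ValueError("empty network list")
    n = len(networks)
    needed = math.ceil(set_size_frac * n)
    counts: dict[tuple[str, str], int] = {}
    signs: dict[tuple[str, str], int] = {}
    for net in networks:
        for _, row in net.edges.iterrows():
            key = (row["source"], row["target"])
            counts[key] = counts.get(key, 0) + 1
            signs[key] = signs.get(key, 0) + (1 if row["sign"] == "+" else -1)
    rows = []
    for key in sorted(counts):
        if counts[key] < needed:
            continue
        if signs[key] == 0:
            continue  # sign tie: dropped
        rows.append(
            {"source": key[0], "target": key[1],
             "occurrence_count": counts[key],
             "sign": "+" if signs[key] > 0 else "-"}
        )
    nodes = sorted(set().union(*[set(net.nodes) for net in networks]))
    return ConsensusNetwork(
        nodes=nodes,
        edges=pd.DataFrame(rows, columns=["source", "target", "occurrence_count", "sign"]),
        set_size_frac=set_size_frac,
        n_networks=n,
    )


def _to_nx(obj) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(sorted(obj.nodes))
    for _, row in obj.edges.iterrows():
        g.add_edge(row["source"], row["target"])
    return g


def greedy_modularity(network) -> ClusterPartition:
    """Clauset–Newman–Moore greedy clustering of the unsigned skeleton.

    Q is computed on the returned partition as Σ_c (e_cc − a_c²) with edges
    unweighted. An edgeless graph yields singleton clusters and Q = 0.
    """
    g = _to_nx(network)
    if g.number_of_edges() == 0:
        warnings.warn("edgeless graph: every node its own cluster, Q = 0")
        assignment = {node: i + 1 for i, node in enumerate(sorted(g.nodes))}
        return ClusterPartition(assignment, 0.0, {c: 1 for c in assignment.values()})
    communities = nx.community.greedy_modularity_communities(g)
    communities = sorted(
        (sorted(c) for c in communities), key=lambda c: (-len(c), c[0])
    )
    assignment = {}
    for cid, members in enumerate(communities, start=1):
        for node in members:
            assignment[node] = cid
    q = nx.community.modularity(g, [set(c) for c in communities])
    sizes = {cid: len(c) for cid, c in enumerate(communities, start=1)}
    return ClusterPartition(assignment, float(q), sizes)


def filter_clusters(partition: ClusterPartition, min_size: int = 10) -> pd.DataFrame:
    """Flag clusters below the reporting size; Q is untouched (computed on
    the full partition before any exclusion)."""
    rows = [
        {
            "node": node,
            "cluster": cid,
            "in_reported_set": partition.sizes[cid] >= min_size,
        }
        for node, cid in sorted(partition.assignment.items())
    ]
    return pd.DataFrame(rows)


def cluster_overlay(global_partition: ClusterPartition, group_can) -> dict:
    """Label every node of a group CAN with its global-CAN cluster id, or
    ``"unique"`` when the node is absent from the global partition."""
    return {
        node: global_partition.assignment.get(node, "unique")
        for node in sorted(group_can.nodes)
    }


# -- export -----------------------------------------------------------------


def write_edgelist_tsv(obj, path) -> None:
    obj.edges.to_csv(path, sep="\t", index=False)


def write_graphml(obj, path) -> None:
    g = nx.Graph()
    g.add_nodes_from(sorted(obj.nodes))
    for _, row in obj.edges.iterrows():
        attrs = {k: row[k] for k in obj.edges.columns if k not in ("source", "target")}
        g.add_edge(row["source"], row["target"], **attrs)
    nx.write_graphml(g, path)


def write_partition_tsv(partition: ClusterPartition, path, min_size: int = 10) -> None:
    filter_clusters(partition, min_size).to_csv(path, sep="\t", index=False)
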