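"""NetView-style fine-scale population network.

An identity-by-state distance matrix is reduced to a mutual k-nearest
neighbour graph: an undirected edge joins i and j only when each is among
the other's k closest samples.  Ties among equal distances are broken by
sample order, which is logged; this keeps the construction deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import MISSING, ConfigError, GenotypeMatrix, InputError

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise InputError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise InputError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise InputError("distances must be nonnegative")
        self.values = v


def ibs_distance(genotypes: GenotypeMatrix, metric: str = "ibs") -> DistanceMatrix:
    """Pairwise genotype distance.

    ``metric='ibs'`` (default): d(i,j) = 1 - mean shared-allele count / 2,
    where a dose pair (a, b) shares 2 - |a - b| allele copies (so two
    heterozygotes share both copies).  ``metric='hamming'``: fraction of
    non-missing SNPs with unequal genotype codes.
    """
    if genotypes.n_samples < 2:
        raise InputError("need at least 2 samples for a distance matrix")
    if metric not in ("ibs", "hamming"):
        raise ConfigError(f"unknown distance metric {metric!r}")
    d = np.where(genotypes.doses == MISSING, np.nan, genotypes.doses).astype(float)
    n = genotypes.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(d[i] - d[i + 1 :])  # (n-i-1, m), nan where either missing
        valid = ~np.isnan(diff)
        n_valid = valid.sum(axis=1)
        if np.any(n_valid == 0):
            j = int(np.flatnonzero(n_valid == 0)[0]) + i + 1
            raise InputError(
                f"samples {genotypes.sample_ids[i]!r} and {genotypes.sample_ids[j]!r} "
                "share no non-missing SNPs"
            )
        if metric == "ibs":
            vals = np.nansum(diff, axis=1) / (2.0 * n_valid)
        else:
            vals = np.nansum(diff > 0, axis=1) / n_valid
        out[i, i + 1 :] = vals
        out[i + 1 :, i] = vals
    return DistanceMatrix(sample_ids=list(genotypes.sample_ids), values=out)


def kinship_to_distance(kinship: pd.DataFrame) -> DistanceMatrix:
    """Convert a kinship matrix to a distance as d = max(phi) - phi."""
    phi = kinship.to_numpy(dtype=float)
    d = phi.max() - phi
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(sample_ids=list(kinship.index), values=d)


def mutual_knn_network(
    dist: DistanceMatrix,
    k: int = 10,
    status: dict[str, str] | None = None,
) -> nx.Graph:
    """Mutual k-nearest-neighbour graph with component labels.

    Every node keeps attributes ``status`` (case/control/unknown) and
    ``component``; every edge carries its distance.  Node degree can never
    exceed k because an edge requires membership in both neighbour lists.
    """
    if k <= 0:
        raise ConfigError(f"k must be positive, got {k}")
    n = len(dist.sample_ids)
    if k >= n:
        raise ConfigError(f"k={k} must be smaller than the number of samples ({n})")
    v = dist.values
    neighbour_sets = []
    for i in range(n):
        order = np.lexsort((np.arange(n), v[i]))  # distance, then sample order
        order = order[order != i][:k]
        neighbour_sets.append(set(order.tolist()))
        logger.debug("node %s neighbours: %s", dist.sample_ids[i], order)
    g = nx.Graph()
    for i, sid in enumerate(dist.sample_ids):
        g.add_node(sid, status=(status or {}).get(sid, "unknown"))
    for i in range(n):
        for j in neighbour_sets[i]:
            if j > i and i in neighbour_sets[j]:
                g.add_edge(dist.sample_ids[i], dist.sample_ids[j], distance=float(v[i, j]))
    for comp_id, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            g.nodes[node]["component"] = comp_id
    return g


def write_network(edge_path, node_path, graph: nx.Graph) -> None:
    """Edge-list TSV (source, target, distance) and node-attribute TSV."""
    edges = pd.DataFrame(
        [(u, v, d["distance"]) for u, v, d in graph.edges(data=True)],
        columns=["source", "target", "distance"],
    )
    edges.to_csv(edge_path, sep="\t", index=False)
    nodes = pd.DataFrame(
        [(n, d.get("status", "unknown"), d.get("component", -1)) for n, d in graph.nodes(data=True)],
        columns=["id", "status", "component"],
    )
    nodes.to_csv(node_path, sep="\t", index=False)
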