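"""Unsupervised characterization of APSD spectra.

Covers the biomacromolecule-structure analyses: z-scoring, hierarchical
waveband partitioning (which chromophore dominates which optical
wavelengths), Shapiro-Wilk normality screening, Spearman correlation
heat-map construction, correlation-threshold wavelength networks, WalkTrap
community detection, betweenness centrality, and a PCA baseline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import igraph as ig
import networkx as nx
import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from sklearn.decomposition import PCA

from .absorption import CHROMOPHORES, AbsorptionModel, absorption_table
from .grid import wavelength_grid

LINKAGE_METHODS = ("single", "complete", "average", "ward")


def zscore(matrix: np.ndarray, axis: int = 0) -> np.ndarray:
    """Standardize along ``axis``: mean 0, SD 1 (n-1 denominator).

    Raises on any constant vector, naming its index.
    """
    x = np.asarray(matrix, dtype=float)
    mean = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=1, keepdims=True)
    flat_sd = np.moveaxis(sd, axis, -1).ravel() if x.ndim > 1 else sd.ravel()
    bad = np.flatnonzero(flat_sd == 0)
    if bad.size:
        raise ValueError(f"constant vector at index {bad[0]} cannot be z-scored")
    return (x - mean) / sd


@dataclass(frozen=True)
class WavebandPartition:
    """Assignment of each grid wavelength to a chromophore-dominated segment.

    ``segments`` maps wavelength -> integer segment id; ``chromophores`` maps
    segment id -> chromophore name. Collagen may own two disjoint segments
    (two separate collagen detection windows).
    """

    wavelengths: np.ndarray
    segments: np.ndarray
    chromophores: dict[int, str]

    def __post_init__(self) -> None:
        if self.segments.shape != self.wavelengths.shape:
            raise ValueError("one segment label per wavelength required")
        if set(np.unique(self.segments)) != set(self.chromophores):
            raise ValueError("chromophore map must cover exactly the segment ids")

    def chromophore_of(self, wavelength_nm: float) -> str:
        idx = np.flatnonzero(np.isclose(self.wavelengths, wavelength_nm))
        if idx.size == 0:
            raise ValueError(f"wavelength {wavelength_nm} nm not in the partition")
        return self.chromophores[int(self.segments[idx[0]])]

    def chromophore_labels(self) -> np.ndarray:
        return np.array([self.chromophores[int(s)] for s in self.segments])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["wavelength_nm", "segment", "chromophore"])
            for wl, seg in zip(self.wavelengths, self.segments):
                writer.writerow([f"{wl:g}", int(seg), self.chromophores[int(seg)]])


def reference_partition() -> WavebandPartition:
    """The canonical dominated-absorption waveband partition.

    Collagen: 1200-1400 and 1530-1630 nm (two detection windows), water:
    1410-1520 nm, lipid: 1640-1700 nm.
    """
    wl = wavelength_grid()
    segments = np.empty(wl.shape, dtype=int)
    segments[(wl >= 1200) & (wl <= 1400)] = 0
    segments[(wl >= 1410) & (wl <= 1520)] = 1
    segments[(wl >= 1530) & (wl <= 1630)] = 2
    segments[(wl >= 1640) & (wl <= 1700)] = 3
    return WavebandPartition(
        wl, segments, {0: "collagen", 1: "water", 2: "collagen", 3: "lipid"}
    )


def hierarchical_partition(
    apsd_matrix: np.ndarray,
    wavelengths: np.ndarray | None = None,
    k: int = 3,
    method: str = "complete",
    absorption: dict[str, AbsorptionModel] | None = None,
) -> WavebandPartition:
    """Partition the wavelength grid into chromophore-dominated segments.

    The samples x wavelengths APSD matrix is z-scored per wavelength, the
    wavelength profiles (rows = wavelengths, features = samples) are
    agglomeratively clustered under Euclidean distance, and the tree is cut
    into ``k`` clusters. Each cluster is assigned the chromophore whose mean
    normalized absorption over the cluster's wavelengths is maximal (ties
    broken toward collagen).
    """
    if k < 1:
        raise ValueError("cluster count k must be >= 1")
    if method not in LINKAGE_METHODS:
        raise ValueError(f"linkage method must be one of {LINKAGE_METHODS}")
    wl = wavelength_grid() if wavelengths is None else np.asarray(wavelengths, float)
    if k > len(wl):
        raise ValueError("k cannot exceed the number of wavelengths")
    profiles = zscore(apsd_matrix, axis=0).T  # rows = wavelengths
    if k == 1:
        clusters = np.ones(len(wl), dtype=int)
    else:
        tree = scipy_linkage(profiles, method=method, metric="euclidean")
        clusters = fcluster(tree, t=k, criterion="maxclust")
    table = absorption or absorption_table(wl)
    chrom_values = np.stack([table[name].values for name in CHROMOPHORES])
    segments = np.empty(len(wl), dtype=int)
    chromophores: dict[int, str] = {}
    # renumber segments by first occurrence along the grid for stable output
    seg_id = 0
    for cluster in dict.fromkeys(clusters):
        mask = clusters == cluster
        mean_abs = chrom_values[:, mask].mean(axis=1)
        best = np.flatnonzero(np.isclose(mean_abs, mean_abs.max()))
        chromophores[seg_id] = CHROMOPHORES[best[0]]  # index order favors collagen
        segments[mask] = seg_id
        seg_id += 1
    return WavebandPartition(wl, segments, chromophores)


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W statistic, p-value)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires a 1-D sample with 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    result = stats.shapiro(x)
    return float(result.statistic), float(result.pvalue)


def spearman_matrix(apsd_matrix: np.ndarray) -> np.ndarray:
    """Tie-corrected (average-rank) Spearman correlation of every column pair.

    Returns an exactly symmetric matrix with unit diagonal.
    """
    x = np.asarray(apsd_matrix, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("Spearman matrix requires >= 3 samples")
    constant = np.flatnonzero(np.ptp(x, axis=0) == 0)
    if constant.size:
        raise ValueError(f"column {constant[0]} is constant; correlation undefined")
    cm = stats.spearmanr(x).statistic
    if np.ndim(cm) == 0:  # scipy collapses the two-column case to a scalar
        r = float(cm)
        cm = np.array([[1.0, r], [r, 1.0]])
    cm = (cm + cm.T) / 2.0
    np.fill_diagonal(cm, 1.0)
    return cm


def threshold_network(
    correlation: np.ndarray,
    wavelengths: np.ndarray | None = None,
    tau: float = 0.9,
) -> nx.Graph:
    """Binary wavelength network: edge (i, j) iff correlation strictly > tau.

    The diagonal is ignored; nodes are the wavelengths themselves.
    """
    if not -1.0 <= tau <= 1.0:
        raise ValueError("threshold tau must lie in [-1, 1]")
    cm = np.asarray(correlation, dtype=float)
    n = cm.shape[0]
    wl = np.arange(n) if wavelengths is None else np.asarray(wavelengths, float)
    graph = nx.Graph()
    graph.add_nodes_from(float(w) for w in wl)
    rows, cols = np.nonzero(np.triu(cm, k=1) > tau)
    graph.add_edges_from((float(wl[i]), float(wl[j])) for i, j in zip(rows, cols))
    return graph


def walktrap_communities(graph: nx.Graph, steps: int = 4) -> dict:
    """WalkTrap community detection cut at the modularity-maximizing level.

    Isolated nodes become singleton communities. Community ids are ordered
    by descending size (ties by smallest member node).
    """
    nodes = list(graph.nodes)
    if not nodes:
        return {}
    index = {node: i for i, node in enumerate(nodes)}
    g = ig.Graph(
        n=len(nodes), edges=[(index[u], index[v]) for u, v in graph.edges]
    )
    membership = g.community_walktrap(steps=steps).as_clustering().membership
    groups: dict[int, list] = {}
    for node, comm in zip(nodes, membership):
        groups.setdefault(comm, []).append(node)
    ordered = sorted(groups.values(), key=lambda ns: (-len(ns), min(ns)))
    return {node: cid for cid, members in enumerate(ordered) for node in members}


def betweenness(graph: nx.Graph) -> dict:
    """Shortest-path betweenness centrality normalized to [0, 1].

    Normalization divisor is (n-1)(n-2)/2, so a star center scores 1.
    Graphs with fewer than 3 nodes score 0 everywhere.
    """
    if graph.number_of_nodes() < 3:
        return {node: 0.0 for node in graph.nodes}
    return nx.betweenness_centrality(graph, normalized=True)


def pca_scores(standardized: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """PCA of a z-scored matrix: (scores, eigenvalues, n_retained).

    Eigenvalues are component variances (n-1 denominator); components with
    eigenvalue > 1 are the retained baseline latent variables.
    """
    x = np.asarray(standardized, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("PCA requires >= 2 samples")
    pca = PCA(n_components=min(x.shape))
    scores = pca.fit_transform(x)
    eigenvalues = pca.explained_variance_
    return scores, eigenvalues, int(np.sum(eigenvalues > 1.0))


def write_network(
    graph: nx.Graph,
    communities: dict,
    centrality: dict,
    edges_path: str | Path,
    nodes_path: str | Path,
) -> None:
    """Write an edge-list text file plus a node-attribute CSV."""
    with open(edges_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavelength_a", "wavelength_b"])
        for u, v in sorted(graph.edges):
            writer.writerow([f"{u:g}", f"{v:g}"])
    with open(nodes_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavelength_nm", "community", "betweenness"])
        for node in sorted(graph.nodes):
            writer.writerow([f"{node:g}", communities[node], f"{centrality[node]:.10g}"])
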