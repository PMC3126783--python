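"""Thresholded Pearson coexpression networks and topology diagnostics.

Edges connect gene pairs whose Pearson correlation over the stage-median
profiles reaches the threshold (default r >= 0.90, positive correlations
only — negative correlation is treated as a different kind of interaction
and never forms an edge). Topology diagnostics follow the usual vocabulary
for biological networks: the mean clustering coefficient C, the scale-free
topology criterion R^2 (goodness of the log-log degree-distribution fit) and
the power-law exponent gamma.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

#: Degree-histogram bin edges: 1; 2-49; 50-99; ...; 250-299; >=300.
DEGREE_BINS: list[tuple[int, float]] = [
    (1, 1),
    (2, 49),
    (50, 99),
    (100, 149),
    (150, 199),
    (200, 249),
    (250, 299),
    (300, float("inf")),
]


def degree_bin_labels() -> list[str]:
    out = []
    for lo, hi in DEGREE_BINS:
        if hi == float("inf"):
            out.append(f">={lo}")
        elif lo == hi:
            out.append(str(lo))
        else:
            out.append(f"{lo}-{int(hi)}")
    return out


@dataclasses.dataclass
class TopologyStats:
    n_nodes: int
    n_edges: int
    mean_degree: float
    median_degree: float
    max_degree: int
    clustering_coefficient: float
    scale_free_r2: float
    gamma: float
    degree_histogram: dict[str, int]

    def to_tsv(self, path: str | Path) -> None:
        """Flat key/value TSV mirroring the usual network-characteristics table."""
        with open(path, "w") as fh:
            fh.write(f"total_genes\t{self.n_nodes}\n")
            fh.write(f"total_edges\t{self.n_edges}\n")
            fh.write(f"mean_degree\t{self.mean_degree:.4g}\n")
            fh.write(f"median_degree\t{self.median_degree:.4g}\n")
            fh.write(f"max_degree\t{self.max_degree}\n")
            fh.write(f"clustering_coefficient\t{self.clustering_coefficient:.4f}\n")
            fh.write(f"scale_free_criterion_r2\t{self.scale_free_r2:.4f}\n")
            fh.write(f"gamma\t{self.gamma:.4f}\n")
            for label, count in self.degree_histogram.items():
                fh.write(f"degree_bin_{label}\t{count}\n")


@dataclasses.dataclass
class FisherZResult:
    """Fisher Z significance of a Pearson correlation at sample size n."""

    r: float
    n: int
    z: float
    statistic: float
    p: float


def pairwise_correlation(sm: pd.DataFrame) -> pd.DataFrame:
    """Pearson r for every unordered pair of genes with nonzero variance.

    ``sm`` is a genes x stages stage-median matrix. Returns a DataFrame with
    columns ``gene_a``, ``gene_b``, ``r`` (gene_a < gene_b in input order).
    Intended for modest gene counts; use :func:`correlated_pairs` to stream
    only above-threshold pairs at scale.
    """
    if sm.shape[1] < 3:
        raise ValueError("need >= 3 stages for correlation")
    x = sm.to_numpy()
    keep = x.std(axis=1) > 0
    genes = np.asarray(sm.index)[keep]
    corr = np.corrcoef(x[keep])
    iu, ju = np.triu_indices(len(genes), k=1)
    return pd.DataFrame(
        {"gene_a": genes[iu], "gene_b": genes[ju], "r": corr[iu, ju]}
    )


def correlated_pairs(
    sm: pd.DataFrame, threshold: float, block: int = 2000
) -> Iterator[tuple[str, str, float]]:
    """Stream gene pairs with r >= threshold, block by block.

    Processes the gene list in blocks so only O(block * n_genes) memory is
    needed; suitable for matrices of 12,000+ genes.
    """
    if sm.shape[1] < 3:
        raise ValueError("need >= 3 stages for correlation")
    x = sm.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    x = x[keep]
    genes = np.asarray(sm.index)[keep]
    n = x.shape[0]
    z = (x - x.mean(axis=1, keepdims=True)) / (sd[keep, None] * np.sqrt(x.shape[1]))
    for a0 in range(0, n, block):
        a1 = min(a0 + block, n)
        corr = z[a0:a1] @ z[a0:].T  # rows a0..a1 against all later genes
        for i in range(a1 - a0):
            row = corr[i, i + 1 :]
            for j in np.flatnonzero(row >= threshold):
                gi = a0 + i
                gj = gi + 1 + int(j)
                yield str(genes[gi]), str(genes[gj]), float(row[j])


def build_network(
    corr: pd.DataFrame | Iterator[tuple[str, str, float]],
    threshold: float = 0.90,
) -> nx.Graph:
    """Coexpression graph: edge iff r >= threshold (positive r only).

    Node set is the genes incident to at least one edge.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    g = nx.Graph()
    if isinstance(corr, pd.DataFrame):
        rows = corr.itertuples(index=False)
        items = ((t.gene_a, t.gene_b, t.r) for t in rows)
    else:
        items = corr
    for a, b, r in items:
        if a != b and r >= threshold:
            g.add_edge(a, b, r=float(r))
    return g


def build_network_from_medians(
    sm: pd.DataFrame, threshold: float = 0.90, block: int = 2000
) -> nx.Graph:
    """Block-streamed construction straight from a stage-median matrix."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return build_network(correlated_pairs(sm, threshold, block), threshold)


def fisher_z_pvalue(r: float, n: int) -> FisherZResult:
    """One-sided significance of r via Fisher's Z: z = atanh(r),
    statistic = z * sqrt(n - 3), p = upper normal tail."""
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    if n < 4:
        raise ValueError("need n >= 4")
    z = float(np.arctanh(r))
    statistic = z * np.sqrt(n - 3)
    p = float(stats.norm.sf(statistic))
    return FisherZResult(r=r, n=n, z=z, statistic=float(statistic), p=p)


def fit_power_law(degrees: list[int] | np.ndarray, max_bins: int = 10) -> tuple[float, float]:
    """Power-law exponent gamma and fit R^2 from the degree distribution.

    Degrees are binned into at most ``max_bins`` logarithmically spaced bins;
    per-bin frequency is width-normalised to a density, and log10 density is
    regressed on log10 of the bin's geometric-centre degree by OLS.
    gamma = -slope; R^2 is the coefficient of determination (reported as 0
    when the slope is positive).
    """
    degrees = np.asarray(degrees, dtype=float)
    degrees = degrees[degrees > 0]
    if len(np.unique(degrees)) < 5:
        raise ValueError("need >= 5 distinct degree values")
    lo, hi = degrees.min(), degrees.max()
    edges = np.logspace(np.log10(lo), np.log10(hi), max_bins + 1)
    edges[-1] *= 1 + 1e-12  # include the max degree in the last bin
    counts, _ = np.histogram(degrees, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    nonzero = counts > 0
    density = counts[nonzero] / (len(degrees) * widths[nonzero])
    lx = np.log10(centers[nonzero])
    ly = np.log10(density)
    slope, intercept, r_value, _, _ = stats.linregress(lx, ly)
    r2 = 0.0 if slope > 0 else float(r_value**2)
    return float(-slope), r2


def topology_stats(net: nx.Graph) -> TopologyStats:
    """Node/edge counts, degree summaries, clustering coefficient, degree
    histogram over the standard bins, and the scale-free fit.

    The clustering coefficient averages 2*triangles/(k*(k-1)) over nodes of
    degree >= 2 only (it is undefined below that).
    """
    if net.number_of_edges() == 0:
        raise ValueError("empty network")
    degrees = np.array([d for _, d in net.degree()])
    local = nx.clustering(net)
    eligible = [v for v, d in net.degree() if d >= 2]
    c = float(np.mean([local[v] for v in eligible])) if eligible else 0.0
    hist = {label: 0 for label in degree_bin_labels()}
    for d in degrees:
        for (lo, hi), label in zip(DEGREE_BINS, degree_bin_labels()):
            if lo <= d <= hi:
                hist[label] += 1
                break
    try:
        gamma, r2 = fit_power_law(degrees)
    except ValueError:
        gamma, r2 = float("nan"), float("nan")
    return TopologyStats(
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
        mean_degree=float(degrees.mean()),
        median_degree=float(np.median(degrees)),
        max_degree=int(degrees.max()),
        clustering_coefficient=c,
        scale_free_r2=r2,
        gamma=gamma,
        degree_histogram=hist,
    )


def extract_subnetwork(
    net: nx.Graph, seeds: list[str], mode: str = "neighborhood"
) -> nx.Graph:
    """Subgraph around seed genes.

    ``neighborhood``: induced subgraph on the seeds plus their first
    neighbours. ``component``: union of the connected components containing
    any seed. Seeds absent from the network are ignored (reported via the
    return's graph attribute ``missing_seeds``); it is an error if none are
    present.
    """
    present = [s for s in seeds if s in net]
    missing = [s for s in seeds if s not in net]
    if not present:
        raise ValueError("no seed gene present in the network")
    if mode == "neighborhood":
        nodes = set(present)
        for s in present:
            nodes.update(net.neighbors(s))
        sub = net.subgraph(nodes).copy()
    elif mode == "component":
        nodes = set()
        for comp in nx.connected_components(net):
            if any(s in comp for s in present):
                nodes |= comp
        sub = net.subgraph(nodes).copy()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sub.graph["missing_seeds"] = missing
    return sub


def export_network(net: nx.Graph, path: str | Path, format: str = "edge_tsv") -> None:
    """Write the edge list in SIF (`a coexp b`) or TSV (`a b r`) form,
    one edge per line in stable lexicographic order."""
    edges = sorted(
        (min(a, b), max(a, b), data.get("r", float("nan")))
        for a, b, data in net.edges(data=True)
    )
    with open(path, "w") as fh:
        if format == "sif":
            for a, b, _ in edges:
                fh.write(f"{a}\tcoexp\t{b}\n")
        elif format == "edge_tsv":
            fh.write("gene_a\tgene_b\tr\n")
            for a, b, r in edges:
                fh.write(f"{a}\t{b}\t{r:.6f}\n")
        else:
            raise ValueError(f"unknown format {format!r}")


def read_network_tsv(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(str(row.gene_a), str(row.gene_b), r=float(row.r))
    return g
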