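"""Stage (B/C-prep): co-expression network construction on LFC profiles.

Similarity between two genes is the absolute Pearson correlation of their
log-fold-change profiles across genotypes, so strong negative co-regulation
counts as strongly as positive co-regulation.  Raising the similarity matrix
elementwise to a power ``beta > 1`` (soft thresholding) suppresses weak
correlations and pushes the weighted connectivity distribution towards a
power law; ``beta`` is chosen as the smallest integer whose scale-free
regression fit reaches a target R².  A hard cutoff on the soft-thresholded
weights then yields the unweighted network handed to link clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .data import LfcMatrix


@dataclass(frozen=True)
class SimilarityMatrix:
    """|Pearson correlation| between gene LFC profiles; symmetric, unit diagonal."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if v.shape != (n, n):
            raise ValueError("similarity matrix must be square over gene_ids")
        if v.size:
            if not np.allclose(v, v.T):
                raise ValueError("similarity matrix must be symmetric")
            if v.min() < -1e-12 or v.max() > 1 + 1e-12:
                raise ValueError("similarity values must lie in [0, 1]")


@dataclass(frozen=True)
class WeightedAdjacency:
    """Soft-thresholded similarity network: a_ij = s_ij ** beta."""

    gene_ids: list[str]
    beta: int
    values: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def connectivity(self) -> np.ndarray:
        """Soft connectivity k_i = sum_{j != i} a_ij."""
        v = np.asarray(self.values, dtype=float)
        return v.sum(axis=1) - np.diag(v)


@dataclass(frozen=True)
class ScaleFreeFit:
    """Log-log regression of the connectivity histogram for one beta."""

    beta: int
    r_squared: float
    slope: float
    bin_centers: np.ndarray  # log10 of mean connectivity per bin
    bin_frequencies: np.ndarray  # log10 of frequency fraction per bin


@dataclass(frozen=True)
class BetaSelection:
    beta: int
    fit: ScaleFreeFit
    warning: bool  # True when no beta reached the R² target and argmax was used
    scan: list[ScaleFreeFit] = field(default_factory=list)


@dataclass(frozen=True)
class CutoffScan:
    thresholds: np.ndarray
    node_counts: np.ndarray  # non-isolated nodes per threshold
    edge_counts: np.ndarray
    densities: np.ndarray
    n_genes: int


@dataclass(frozen=True)
class BinaryNetwork:
    """Unweighted co-expression network after cutoff; isolated nodes removed."""

    gene_ids: list[str]
    values: np.ndarray  # 0/1, symmetric, zero diagonal
    cutoff: float

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.values, k=1).sum())

    def edges(self) -> list[tuple[str, str]]:
        iu, ju = np.nonzero(np.triu(self.values, k=1))
        return [(self.gene_ids[i], self.gene_ids[j]) for i, j in zip(iu, ju)]


def similarity_matrix(l1: LfcMatrix) -> SimilarityMatrix:
    """Absolute Pearson correlation between every pair of gene LFC rows."""
    v = np.asarray(l1.values, dtype=float)
    sd = v.std(axis=1)
    if (sd == 0).any():
        bad = l1.gene_ids[int(np.argmax(sd == 0))]
        raise ValueError(
            f"gene {bad!r} has zero variance across genotypes; correlation is "
            "undefined (run the LFC variance filter first)"
        )
    s = np.abs(np.corrcoef(v))
    np.fill_diagonal(s, 1.0)
    s = np.clip((s + s.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(gene_ids=list(l1.gene_ids), values=s)


def soft_power(s: SimilarityMatrix, beta: int) -> WeightedAdjacency:
    if beta < 1:
        raise ValueError("beta must be >= 1")
    return WeightedAdjacency(
        gene_ids=list(s.gene_ids), beta=int(beta), values=np.asarray(s.values) ** beta
    )


def fit_degree_distribution(k: np.ndarray, n_bins: int = 20, beta: int = 0) -> ScaleFreeFit:
    """Scale-free topology fit from a vector of connectivities.

    Bins positive connectivities into ``n_bins`` equal-width bins on the log10
    scale, drops empty bins, and regresses log10(frequency fraction) on
    log10(mean connectivity per bin).  Needs at least three nonempty bins.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size == 0 or np.allclose(k, k[0]):
        raise ValueError("degenerate connectivity distribution: all connectivities equal")
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max(), n_bins + 1)
    # right-closed last bin so the maximum is not dropped
    idx = np.clip(np.digitize(logk, edges, right=False) - 1, 0, n_bins - 1)
    centers = []
    freqs = []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        centers.append(np.log10(k[mask].mean()))
        freqs.append(np.log10(mask.sum() / k.size))
    if len(centers) < 3:
        raise ValueError(
            f"only {len(centers)} nonempty connectivity bins; need >= 3 for the scale-free fit"
        )
    res = stats.linregress(centers, freqs)
    return ScaleFreeFit(
        beta=int(beta),
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        bin_centers=np.asarray(centers),
        bin_frequencies=np.asarray(freqs),
    )


def scale_free_r2(a: WeightedAdjacency, n_bins: int = 20) -> ScaleFreeFit:
    """Scale-free fit of the weighted network's connectivity distribution."""
    return fit_degree_distribution(a.connectivity(), n_bins=n_bins, beta=a.beta)


def select_beta(
    s: SimilarityMatrix,
    r2_min: float = 0.8,
    beta_grid: Iterable[int] = range(1, 21),
    n_bins: int = 20,
) -> BetaSelection:
    """Smallest beta > 1 whose scale-free fit reaches ``r2_min``.

    If no beta qualifies, falls back to the argmax-R² beta with a warning
    flag so callers can surface the weak fit.
    """
    grid = sorted(int(b) for b in beta_grid)
    if not grid:
        raise ValueError("beta grid must be nonempty")
    scan: list[ScaleFreeFit] = []
    chosen: ScaleFreeFit | None = None
    for beta in grid:
        try:
            fit = scale_free_r2(soft_power(s, beta), n_bins=n_bins)
        except ValueError:
            continue
        scan.append(fit)
        if chosen is None and beta > 1 and fit.r_squared >= r2_min:
            chosen = fit
    if not scan:
        raise ValueError("scale-free fit failed for every beta in the grid")
    if chosen is not None:
        return BetaSelection(beta=chosen.beta, fit=chosen, warning=False, scan=scan)
    best = max(scan, key=lambda f: f.r_squared)
    return BetaSelection(beta=best.beta, fit=best, warning=True, scan=scan)


def threshold_scan(a: WeightedAdjacency, grid: Sequence[float]) -> CutoffScan:
    """Node/edge/density counts of the binarized network over a cutoff grid.

    Edges are strict: a_ij > tau.  Density is 2E / (N(N-1)) over the
    non-isolated nodes N (0 when fewer than two nodes remain).
    """
    grid_arr = np.asarray(sorted(grid), dtype=float)
    if grid_arr.size and (grid_arr.min() <= 0 or grid_arr.max() >= 1):
        raise ValueError("cutoff grid values must lie strictly inside (0, 1)")
    v = np.asarray(a.values, dtype=float)
    n = v.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = v[iu, ju]
    nodes, edges, dens = [], [], []
    for tau in grid_arr:
        keep = w > tau
        e = int(keep.sum())
        deg = np.zeros(n, dtype=int)
        np.add.at(deg, iu[keep], 1)
        np.add.at(deg, ju[keep], 1)
        nn = int((deg > 0).sum())
        d = 2.0 * e / (nn * (nn - 1)) if nn >= 2 else 0.0
        nodes.append(nn)
        edges.append(e)
        dens.append(d)
    return CutoffScan(
        thresholds=grid_arr,
        node_counts=np.asarray(nodes),
        edge_counts=np.asarray(edges),
        densities=np.asarray(dens),
        n_genes=n,
    )


def select_cutoff(
    scan: CutoffScan, override: float | None = None, min_node_fraction: float = 0.05
) -> float:
    """Cutoff choice: explicit override, else the density-minimum rule.

    Without an override, returns the smallest grid threshold achieving the
    minimum network density among thresholds that keep at least
    ``min_node_fraction`` of all genes non-isolated.
    """
    if override is not None:
        return float(override)
    if scan.thresholds.size == 0:
        raise ValueError("empty cutoff scan")
    eligible = scan.node_counts >= max(1, min_node_fraction * scan.n_genes)
    if not eligible.any():
        raise ValueError("no cutoff in the grid retains any non-isolated nodes")
    dens = np.where(eligible, scan.densities, np.inf)
    best = int(np.argmin(dens))  # argmin returns the first (smallest tau) on ties
    return float(scan.thresholds[best])


def binarize(a: WeightedAdjacency, tau: float) -> BinaryNetwork:
    """Unweighted network: edge iff a_ij > tau (strict); isolated nodes dropped."""
    if not 0 < tau < 1:
        raise ValueError("cutoff must lie strictly inside (0, 1)")
    v = np.asarray(a.values, dtype=float)
    adj = (v > tau).astype(np.int8)
    np.fill_diagonal(adj, 0)
    degree = adj.sum(axis=1)
    keep = degree > 0
    if not keep.any():
        raise ValueError(f"no edges survive cutoff {tau}; the network is empty")
    return BinaryNetwork(
        gene_ids=[g for g, k in zip(a.gene_ids, keep) if k],
        values=adj[np.ix_(keep, keep)],
        cutoff=float(tau),
    )
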