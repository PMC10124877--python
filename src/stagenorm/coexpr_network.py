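"""Weighted gene co-expression network construction and module detection.

The classic workflow: raise absolute Pearson correlations to a soft
power chosen by a scale-free-topology fit, convert the adjacency to a
topological overlap matrix (TOM), cluster genes by average linkage on
1-TOM, slice the dendrogram into modules with a tree-based dynamic cut,
and merge modules whose eigengenes (first principal components) are
highly correlated.  The network is unsigned; modules carry colour-style
names that are cosmetic aliases of size-ranked labels, with ``grey``
reserved for unassigned genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

GREY = "grey"

#: colour names assigned to modules in decreasing size order
MODULE_COLOURS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta",
]


@dataclass
class NetworkParams:
    """Tunables of the network stage.

    ``beta`` is the soft-threshold power; when None it is picked from
    ``beta_grid`` as the smallest power whose degree distribution fits a
    scale-free law with R^2 above ``r2_threshold`` and negative slope.
    ``merge_cut`` is the eigengene dissimilarity (1 - correlation) below
    which two modules are merged; 0.25 corresponds to eigengene
    correlation 0.75.
    """

    beta: Optional[int] = None
    beta_grid: tuple[int, ...] = tuple(range(1, 31))
    r2_threshold: float = 0.8
    min_module_size: int = 30
    merge_cut: float = 0.25
    cut_height_fraction: float = 0.99
    correlation: str = "pearson"
    network_sign: str = "unsigned"

    def __post_init__(self) -> None:
        if self.beta is not None and self.beta not in self.beta_grid:
            raise ValueError(f"beta={self.beta} not in beta_grid")
        for name in ("r2_threshold", "merge_cut", "cut_height_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")


@dataclass
class ModuleAssignment:
    """Partition of genes into named modules plus module eigengenes."""

    labels: pd.Series  # gene_id -> module name, "grey" = unassigned
    eigengenes: Optional[pd.DataFrame] = None  # module x sample
    params: Optional[NetworkParams] = None

    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def modules(self) -> list[str]:
        return [m for m in self.labels.unique() if m != GREY]

    def genes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def _correlation_matrix(expr: pd.DataFrame) -> np.ndarray:
    """Pearson correlation between gene rows; constant rows raise."""
    arr = expr.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(expr.index, sd) if s == 0]
        raise ValueError(f"constant expression rows: {bad[:5]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cor = np.corrcoef(arr)
    return np.clip(cor, -1.0, 1.0)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free-topology fit of a connectivity vector.

    Bins genes into equal-width connectivity bins, regresses
    log10(frequency) on log10(mean connectivity) over nonempty bins, and
    returns (R^2, slope).  A scale-free network shows high R^2 with
    negative slope.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < 2 or k.max() == k.min():
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    log_freq, log_k = [], []
    for b in range(len(edges) - 1):
        mask = which == b
        if mask.sum() == 0:
            continue
        log_freq.append(np.log10(mask.mean()))
        log_k.append(np.log10(k[mask].mean()))
    if len(log_k) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(log_k, log_freq, 1)
    pred = slope * np.asarray(log_k) + intercept
    resid = np.asarray(log_freq) - pred
    ss_tot = float(np.var(log_freq) * len(log_freq))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    return r2, float(slope)


def pick_soft_threshold(
    expr: pd.DataFrame, params: Optional[NetworkParams] = None
) -> int:
    """Smallest power whose degree distribution passes the scale-free fit.

    For each candidate power the connectivity of gene i is the sum of
    |cor(i, j)|^beta over j != i.  If no candidate reaches the R^2
    threshold with negative slope, the power maximizing R^2 (among
    negative-slope fits, if any) is returned with a warning.
    """
    params = params or NetworkParams()
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    cor = np.abs(_correlation_matrix(expr))
    np.fill_diagonal(cor, 0.0)
    fits: list[tuple[int, float, float]] = []
    for beta in params.beta_grid:
        k = (cor**beta).sum(axis=1)
        r2, slope = scale_free_fit(k)
        fits.append((beta, r2, slope))
        if slope < 0 and r2 > params.r2_threshold:
            return beta
    negatives = [(b, r2) for b, r2, s in fits if s < 0]
    pool = negatives if negatives else [(b, r2) for b, r2, _ in fits]
    best = max(pool, key=lambda t: t[1])[0]
    logger.warning(
        "no power reached scale-free R^2 > %.2f; falling back to beta=%d",
        params.r2_threshold,
        best,
    )
    return best


def topological_overlap(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Topological overlap matrix of the unsigned weighted network.

    Adjacency a_ij = |cor(i,j)|^beta with zero diagonal; overlap
    combines direct adjacency with shared-neighbour strength:

        TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

    with TOM_ii = 1.  Symmetric, values in [0, 1].
    """
    adj = np.abs(_correlation_matrix(expr)) ** beta
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    shared = adj @ adj
    numer = shared + adj
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=expr.index, columns=expr.index)


def _colour_names(n: int) -> list[str]:
    names = list(MODULE_COLOURS)
    i = 2
    while len(names) < n:
        names.extend(f"{c}{i}" for c in MODULE_COLOURS)
        i += 1
    return names[:n]


def detect_modules(
    tom: pd.DataFrame, params: Optional[NetworkParams] = None
) -> ModuleAssignment:
    """Average-linkage tree on 1-TOM sliced by a tree-based dynamic cut.

    The tree is cut at ``cut_height_fraction`` of its tallest merge
    height, detaching the topmost joins; resulting branches with at
    least ``min_module_size`` members become modules (named by
    decreasing size), the remainder are grey.
    """
    params = params or NetworkParams()
    genes = list(tom.index)
    if len(genes) < params.min_module_size:
        logger.warning("fewer genes (%d) than min_module_size; all grey", len(genes))
        return ModuleAssignment(
            labels=pd.Series(GREY, index=genes), params=params
        )
    diss = 1.0 - tom.to_numpy()
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    Z = linkage(squareform(diss, checks=False), method="average")
    heights = Z[:, 2]
    cut_h = params.cut_height_fraction * float(heights.max())
    branch = fcluster(Z, t=cut_h, criterion="distance")
    labels = pd.Series(GREY, index=genes, dtype=object)
    sizes = pd.Series(branch).value_counts()
    kept = [b for b in sizes.index if sizes[b] >= params.min_module_size]
    # a single branch holding every gene means no structure was found
    if len(kept) == 1 and sizes[kept[0]] == len(genes):
        kept = []
    kept.sort(key=lambda b: (-sizes[b], b))
    names = _colour_names(len(kept))
    for name, b in zip(names, kept):
        labels[branch == b] = name
    return ModuleAssignment(labels=labels, params=params)


def module_eigengene(expr: pd.DataFrame, genes: list[str]) -> pd.Series:
    """First principal component of the standardized member rows.

    Sign-aligned so the eigengene correlates positively with the mean
    member profile.
    """
    sub = expr.loc[genes].to_numpy(dtype=float)
    sd = sub.std(axis=1)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns)


def merge_close_modules(
    expr: pd.DataFrame,
    assignment: ModuleAssignment,
    merge_cut: Optional[float] = None,
) -> ModuleAssignment:
    """Iteratively merge module pairs with eigengene dissimilarity < cut.

    At each pass the closest qualifying pair is merged (the larger
    module's name wins, ties broken alphabetically) and eigengenes are
    recomputed, until no pair of eigengenes has 1 - cor below the cut.
    """
    if merge_cut is None:
        merge_cut = assignment.params.merge_cut if assignment.params else 0.25
    labels = assignment.labels.copy()
    while True:
        modules = sorted(
            [m for m in labels.unique() if m != GREY],
            key=lambda m: (-int((labels == m).sum()), m),
        )
        if len(modules) < 2:
            break
        eigs = pd.DataFrame(
            {m: module_eigengene(expr, list(labels.index[labels == m])) for m in modules}
        )
        cor = eigs.corr().to_numpy()
        diss = 1.0 - cor
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut:
            break
        keep, drop = modules[min(i, j)], modules[max(i, j)]
        labels[labels == drop] = keep
    modules = sorted(
        [m for m in labels.unique() if m != GREY],
        key=lambda m: (-int((labels == m).sum()), m),
    )
    eigs = (
        pd.DataFrame(
            {m: module_eigengene(expr, list(labels.index[labels == m])) for m in modules}
        ).T
        if modules
        else None
    )
    return ModuleAssignment(labels=labels, eigengenes=eigs, params=assignment.params)


def build_network_modules(
    expr: pd.DataFrame, params: Optional[NetworkParams] = None
) -> tuple[ModuleAssignment, int]:
    """Convenience wrapper: pick beta, build TOM, detect and merge modules."""
    params = params or NetworkParams()
    beta = params.beta if params.beta is not None else pick_soft_threshold(expr, params)
    tom = topological_overlap(expr, beta)
    assignment = detect_modules(tom, params)
    if len(assignment.modules()) >= 2:
        assignment = merge_close_modules(expr, assignment)
    elif assignment.modules():
        assignment = ModuleAssignment(
            labels=assignment.labels,
            eigengenes=pd.DataFrame(
                {
                    m: module_eigengene(expr, assignment.genes_in(m))
                    for m in assignment.modules()
                }
            ).T,
            params=params,
        )
    return assignment, beta
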