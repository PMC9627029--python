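"""Alpha/beta diversity: Shannon, Bray-Curtis, weighted UniFrac, PCoA, ANOSIM.

Distances are computed on CSS-normalized counts by default in the pipeline;
every routine here accepts whatever abundances it is given.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from sympy.utilities.iterables import multiset_permutations

from .core_io import AsvTable, DistanceMatrix

logger = logging.getLogger("gutsampler")


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int


@dataclass
class PcoaResult:
    coordinates: np.ndarray       # samples x axes
    eigenvalues: np.ndarray       # descending, negatives included
    proportion_explained: np.ndarray
    sample_ids: list[str]


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i; natural log unless ``base`` set."""
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if (c < 0).any():
        raise ValueError("negative count")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / math.log(base) if base is not None else h


def bray_curtis(table: AsvTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y) between samples."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = table.counts.T  # samples x features
    totals = x.sum(axis=1)
    if (totals == 0).sum() >= 2:
        raise ValueError("more than one all-zero sample: Bray-Curtis undefined")
    return DistanceMatrix(squareform(pdist(x, metric="braycurtis")),
                          list(table.sample_ids))


def _branch_proportions(table: AsvTable, tree: TreeNode) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch descendant read proportions for every sample.

    Returns (lengths, P) with lengths shape (n_branches,) and P shape
    (n_branches, n_samples); branch b's row is the fraction of each sample's
    reads on leaves below b.
    """
    leaf_index = {}
    for tip in tree.tips():
        if tip.name in leaf_index:
            raise ValueError(f"duplicate leaf label {tip.name!r}")
        leaf_index[tip.name] = len(leaf_index)
    present = table.counts.sum(axis=1) > 0
    for fid, pres in zip(table.feature_ids, present):
        if pres and fid not in leaf_index:
            raise ValueError(f"feature {fid!r} missing from tree")

    totals = table.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = table.sample_ids[int(np.argmin(totals))]
        raise ValueError(f"sample {bad!r} has zero total count")
    # leaf x sample proportion matrix in tree leaf order
    leaf_props = np.zeros((len(leaf_index), table.n_samples))
    for i, fid in enumerate(table.feature_ids):
        if fid in leaf_index:
            leaf_props[leaf_index[fid]] = table.counts[i] / totals

    lengths, rows = [], []
    subtree: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            prop = leaf_props[leaf_index[node.name]]
        else:
            prop = np.sum([subtree.pop(id(c)) for c in node.children], axis=0)
        subtree[id(node)] = prop
        if node.parent is not None:
            if node.length is None:
                raise ValueError(
                    f"missing branch length above {node.name or '<internal>'}")
            lengths.append(float(node.length))
            rows.append(prop)
    return np.array(lengths), np.array(rows)


def weighted_unifrac(table: AsvTable, tree: TreeNode,
                     normalized: bool = False) -> DistanceMatrix:
    """Weighted UniFrac: d = sum_b l_b |p_A(b) - p_B(b)| over branches.

    The normalized variant divides each pair by sum_b l_b (p_A(b) + p_B(b)).
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    lengths, props = _branch_proportions(table, tree)
    coords = (props * lengths[:, None]).T  # samples x branches, l_b * p
    raw = squareform(pdist(coords, metric="cityblock"))
    if not normalized:
        return DistanceMatrix(raw, list(table.sample_ids))
    mass = coords.sum(axis=1)  # sum_b l_b p(b) per sample
    denom = mass[:, None] + mass[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, raw / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(table.sample_ids))


def pcoa(dm: DistanceMatrix, axes: int | None = None) -> PcoaResult:
    """Classical metric scaling of a distance matrix.

    Negative eigenvalues (non-Euclidean input) are reported, never silently
    dropped; coordinates are returned only for positive eigenvalues.
    """
    n = len(dm.sample_ids)
    d2 = dm.data ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    positive = eigvals > tol
    n_pos = int(positive.sum())
    if axes is None:
        axes = n_pos
    if axes > n_pos:
        logger.warning("requested %d axes but only %d positive eigenvalues; "
                       "truncating", axes, n_pos)
        axes = n_pos
    coords = eigvecs[:, :axes] * np.sqrt(eigvals[:axes])
    pos_sum = eigvals[positive].sum()
    prop = np.where(eigvals > tol, eigvals / pos_sum if pos_sum > 0 else 0.0, 0.0)
    return PcoaResult(coordinates=coords, eigenvalues=eigvals,
                      proportion_explained=prop[:axes],
                      sample_ids=list(dm.sample_ids))


def _anosim_r(rank_matrix: np.ndarray, labels: np.ndarray) -> float:
    n = rank_matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    ranks = rank_matrix[iu]
    m = n * (n - 1) // 2
    r_within = ranks[same].mean()
    r_between = ranks[~same].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim(dm: DistanceMatrix, groups, n_permutations: int = 999,
           seed: int = 0) -> AnosimResult:
    """ANOSIM: rank-based test of between-group vs within-group distances.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 and mid-ranks for ties.  The p-value permutes group labels;
    when ``n_permutations`` meets or exceeds the number of distinct label
    arrangements the null is enumerated exactly instead of sampled.
    """
    labels = np.asarray([str(g) for g in groups])
    if len(labels) != len(dm.sample_ids):
        raise ValueError("one group label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 members")

    n = len(labels)
    iu = np.triu_indices(n, k=1)
    rank_matrix = np.zeros((n, n))
    rank_matrix[iu] = stats.rankdata(dm.data[iu])  # mid-ranks for ties
    rank_matrix += rank_matrix.T
    r_obs = _anosim_r(rank_matrix, labels)

    n_distinct = math.factorial(n)
    for c in counts:
        n_distinct //= math.factorial(int(c))
    if n_permutations >= n_distinct:
        codes = np.searchsorted(uniq, labels)
        r_all = [_anosim_r(rank_matrix, np.asarray(perm))
                 for perm in multiset_permutations(list(codes))]
        p = float(np.mean(np.asarray(r_all) >= r_obs - 1e-12))
        return AnosimResult(R=r_obs, p=p, n_permutations=n_distinct)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(labels, (n_permutations, 1)), axis=1)
    # vectorized within-group mean rank per permutation
    m = n * (n - 1) // 2
    total_rank = rank_matrix[iu].sum()
    within_sums = np.zeros(n_permutations)
    within_counts = 0
    for g, c in zip(uniq, counts):
        ind = (perms == g).astype(float)           # perms x n
        quad = np.einsum("pi,ij,pj->p", ind, rank_matrix, ind) / 2.0
        within_sums += quad
        within_counts += int(c) * (int(c) - 1) // 2
    between_counts = m - within_counts
    r_within = within_sums / within_counts
    r_between = (total_rank - within_sums) / between_counts
    r_perm = (r_between - r_within) / (m / 2.0)
    p = float((1 + np.sum(r_perm >= r_obs - 1e-12)) / (n_permutations + 1))
    return AnosimResult(R=r_obs, p=p, n_permutations=n_permutations)


def nearest_neighbor(dm: DistanceMatrix, query: str) -> str:
    """The distinct sample nearest to ``query``; ties broken lexicographically."""
    if query not in dm.sample_ids:
        raise ValueError(f"sample {query!r} not in distance matrix")
    if len(dm.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    qi = dm.sample_ids.index(query)
    dists = dm.data[qi].copy()
    dists[qi] = np.inf
    best = np.min(dists)
    candidates = sorted(s for s, d in zip(dm.sample_ids, dists)
                        if d <= best + 1e-12 and s != query)
    if len(candidates) > 1:
        logger.warning("nearest_neighbor tie for %r among %s; returning %r",
                       query, candidates, candidates[0])
    return candidates[0]
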