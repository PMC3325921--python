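"""Average-linkage (UPGMA) hierarchical clustering of top-ranked genes.

Profiles are log2 treated/control ratios of the N highest-ranked genes
across all treatment conditions.  Genes are clustered with the classic
uncentered-Pearson correlation distance (1 - <x,y>/(|x||y|)), the historic
default of the Eisen clustering tools; conditions are clustered with
Euclidean distance by default, because near-null condition profiles (all
log-ratios ~ 0) have no meaningful direction and correlation distances
between them are dominated by noise.  Both metrics are selectable.

Linkage uses the unweighted pair-group method with arithmetic mean: the
distance between clusters is the mean of all cross-pair distances, which
guarantees monotone merge heights for metric inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .calls import UP
from .design import GTX
from .exceptions import ValidationError

RATIO_FLOOR = 1e-6  # ratios are clipped here before the log2 transform

UNCENTERED = "uncentered"
EUCLIDEAN = "euclidean"


def distance_matrix(profiles: pd.DataFrame, metric: str = UNCENTERED) -> pd.DataFrame:
    """Symmetric pairwise distance matrix over the rows of ``profiles``."""
    x = profiles.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("need at least two rows to cluster")
    if not np.isfinite(x).all():
        raise ValidationError("profiles contain non-finite values")
    if metric == UNCENTERED:
        norms = np.sqrt((x * x).sum(axis=1))
        zero = norms == 0
        if zero.any():
            rows = list(profiles.index[zero])
            raise ValidationError(
                f"rows with zero norm under uncentered-correlation distance: {rows}"
            )
        d = 1.0 - (x @ x.T) / np.outer(norms, norms)
    elif metric == EUCLIDEAN:
        sq = (x * x).sum(axis=1)
        d = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2.0 * (x @ x.T), 0.0))
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    d = np.maximum((d + d.T) / 2.0, 0.0)  # enforce exact symmetry
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def average_linkage(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    """UPGMA linkage matrix (scipy encoding) from a square distance matrix."""
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    heights = z[:, 2]
    assert (np.diff(heights) >= -1e-10).all(), "UPGMA merge heights must be monotone"
    return z


def leaf_order(linkage: np.ndarray, labels: list[str]) -> list[str]:
    return [labels[i] for i in hierarchy.leaves_list(linkage)]


def to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage matrix as a Newick string."""
    tree = TreeNode.from_linkage_matrix(linkage, labels)
    return str(tree).strip()


def root_bipartition(linkage: np.ndarray, labels: list[str]) -> tuple[set[str], set[str]]:
    """The two leaf sets joined by the final (root) merge."""
    n = len(labels)
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    for k, (a, b, _, _) in enumerate(linkage):
        members[n + k] = members[int(a)] | members[int(b)]
    a, b = int(linkage[-1, 0]), int(linkage[-1, 1])
    return {labels[i] for i in members[a]}, {labels[i] for i in members[b]}


@dataclass
class ClusterResult:
    """Gene and condition trees plus the leaf-ordered profile matrix.

    ``gene_labels``/``condition_labels`` give the leaf order the linkage
    matrices are encoded against (the pre-reordering input order).
    """

    profiles: pd.DataFrame  # reordered: gene rows, condition columns
    gene_linkage: np.ndarray
    condition_linkage: np.ndarray
    gene_labels: list[str]
    condition_labels: list[str]
    gene_newick: str
    condition_newick: str

    def condition_split(self) -> tuple[set[str], set[str]]:
        return root_bipartition(self.condition_linkage, self.condition_labels)


def log_ratio_profiles(calls: pd.DataFrame, gene_order: list[str]) -> pd.DataFrame:
    """log2 ratio matrix (genes x conditions) for the given genes."""
    ratio = calls.pivot(index="gene_id", columns="condition", values="ratio")
    cond_order = list(calls["condition"].drop_duplicates())
    prof = ratio.loc[gene_order, cond_order]
    return np.log2(prof.clip(lower=RATIO_FLOOR))


def cluster_top(
    scores: pd.DataFrame,
    calls: pd.DataFrame,
    n: int = 50,
    gene_metric: str = UNCENTERED,
    condition_metric: str = EUCLIDEAN,
) -> ClusterResult:
    """Cluster the top-``n`` ranked genes and the treatment conditions.

    ``scores`` is a ranked table from :func:`gtxscore.scoring.rank_genes`
    (index gene_id, sorted by rank); ``calls`` the long-form call matrix.
    If fewer than ``n`` genes were scored, all of them are used (warning).
    """
    avail = len(scores)
    if avail < n:
        warnings.warn(f"only {avail} scored genes available; clustering all of them")
        n = avail
    top = list(scores.index[:n])
    profiles = log_ratio_profiles(calls, top)

    gene_z = average_linkage(distance_matrix(profiles, gene_metric))
    cond_z = average_linkage(distance_matrix(profiles.T, condition_metric))
    ordered = profiles.loc[
        leaf_order(gene_z, list(profiles.index)),
        leaf_order(cond_z, list(profiles.columns)),
    ]
    return ClusterResult(
        profiles=ordered,
        gene_linkage=gene_z,
        condition_linkage=cond_z,
        gene_labels=list(profiles.index),
        condition_labels=list(profiles.columns),
        gene_newick=to_newick(gene_z, list(profiles.index)),
        condition_newick=to_newick(cond_z, list(profiles.columns)),
    )


def splits_by_class(result: ClusterResult, calls: pd.DataFrame) -> bool:
    """True if the condition tree's root bipartition separates GTX from NGTX."""
    klass = calls[["condition", "klass"]].drop_duplicates("condition").set_index("condition")["klass"]
    left, right = result.condition_split()
    gtx = {c for c in klass.index if klass[c] == GTX}
    ngtx = set(klass.index) - gtx
    return (left == gtx and right == ngtx) or (left == ngtx and right == gtx)
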