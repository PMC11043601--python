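"""Profile normalization, substrate-specificity clustering, and PCA.

Fatty-acid profiles are z-scored per species, enzymes are clustered by
Ward's variance-minimizing linkage on Euclidean distances, the dendrogram
is pruned with an adaptive tree cut (cluster count determined by tree
shape, not a fixed height), and a PCA summarizes how much profile
variation the leading components capture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .io import EnzymePanel
from .treecut import cut_tree_dynamic


@dataclass
class ScaledProfiles:
    """Column-wise z-scored profiles plus scaling provenance.

    ``constant`` flags species whose abundance was identical across all
    enzymes; those columns are set to zero (not dropped) so that column
    indices keep lining up with species labels.
    """

    values: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    constant: pd.Series  # bool per species

    @property
    def enzyme_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ClusterAssignment:
    """Enzyme -> specificity-cluster mapping with the linkage retained."""

    labels: pd.Series  # enzyme id -> 1..n_clusters
    n_clusters: int
    linkage: np.ndarray

    def label_of(self, enzyme_id: str) -> int:
        return int(self.labels.loc[enzyme_id])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"enzyme_id": self.labels.index, "cluster": self.labels.to_numpy()}
        )


@dataclass
class PCADecomposition:
    scores: np.ndarray  # (n_enzymes, k)
    loadings: np.ndarray  # (k, n_species)
    variance_explained: np.ndarray  # percent, per component


def normalize_profiles(panel: EnzymePanel) -> ScaledProfiles:
    """Z-score each fatty-acid species across enzymes.

    Uses the sample (n-1) standard deviation. Species with zero spread
    are flagged constant and set to all-zero rather than dropped.
    """
    if panel.n_enzymes < 2:
        raise ValueError("need at least 2 enzymes to scale profiles")
    raw = panel.profiles
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=1)
    constant = sds == 0
    safe_sds = sds.replace(0, 1.0)
    values = (raw - means) / safe_sds
    values.loc[:, constant] = 0.0
    return ScaledProfiles(values=values, means=means, sds=sds, constant=constant)


def cluster_enzymes(
    scaled: ScaledProfiles,
    min_cluster_size: int = 4,
    deep_split: int = 1,
) -> ClusterAssignment:
    """Ward clustering of scaled profiles with an adaptive tree cut.

    Deterministic for a fixed input: there is no randomness in the
    distance computation, the linkage, or the cut.
    """
    X = scaled.values.to_numpy(dtype=float)
    n = X.shape[0]
    Z = linkage(pdist(X, metric="euclidean"), method="ward")
    labels = cut_tree_dynamic(
        Z, X, min_cluster_size=min_cluster_size, deep_split=deep_split
    )
    n_clusters = int(labels.max())
    if n_clusters == 1 and n < 2 * min_cluster_size:
        warnings.warn(
            "panel smaller than two minimum-size clusters; single cluster returned",
            stacklevel=2,
        )
    return ClusterAssignment(
        labels=pd.Series(labels, index=scaled.enzyme_ids, name="cluster"),
        n_clusters=n_clusters,
        linkage=Z,
    )


def pca_variance(scaled: ScaledProfiles, k: int) -> PCADecomposition:
    """Centered PCA of the scaled profiles; variance fractions in percent.

    The matrix is already species-scaled, so no further scaling is
    applied (the solver still removes column means, which are ~0 apart
    from constant-flagged columns).
    """
    X = scaled.values.to_numpy(dtype=float)
    max_k = min(X.shape)
    if k > max_k:
        warnings.warn(f"k={k} exceeds rank bound {max_k}; truncating", stacklevel=2)
        k = max_k
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    return PCADecomposition(
        scores=scores,
        loadings=pca.components_,
        variance_explained=pca.explained_variance_ratio_ * 100.0,
    )


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a linkage matrix as a Newick string (branch lengths = height gaps)."""
    tree = to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
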