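"""Adaptive ("dynamic") cutting of a hierarchical clustering dendrogram.

A fixed-height cut cannot separate clusters that join the tree at very
different heights. The cut implemented here instead decides, merge by
merge, whether a join is *within* one cluster or *between* two clusters,
based on the shape of the tree:

* a branch qualifies as a cluster core when it has at least
  ``min_cluster_size`` leaves and the joining height sits well above the
  branch's own internal merge heights (a height *gap*);
* once two qualifying branches are kept apart, every later merge above
  them only records that distinct clusters are being glued together;
* leftover branches too small or too shallow to qualify are assigned to
  the nearest cluster centroid in the data space (a PAM-like mop-up
  stage), so every object receives a label.

``deep_split`` (0..4) controls how large the height gap must be relative
to the span of merge heights: higher values split more aggressively and
produce more, smaller clusters.
"""

from __future__ import annotations

import numpy as np

# required gap between a branch's top internal merge and its joining
# height, as a fraction of (root height - 5th percentile height)
_GAP_FRACTION = {0: 0.40, 1: 0.25, 2: 0.15, 3: 0.08, 4: 0.04}


def cut_tree_dynamic(
    linkage: np.ndarray,
    data: np.ndarray,
    min_cluster_size: int = 4,
    deep_split: int = 1,
) -> np.ndarray:
    """Cut a SciPy linkage matrix into shape-defined clusters.

    Parameters
    ----------
    linkage : (n-1, 4) array
        SciPy linkage matrix (e.g. Ward on Euclidean distances).
    data : (n, p) array
        The observations the tree was built from; used only in the
        mop-up stage to assign unqualified branches to the nearest
        cluster centroid.
    min_cluster_size : int
        Smallest branch size that may form a cluster core.
    deep_split : int
        Split sensitivity, 0 (coarse) .. 4 (fine).

    Returns
    -------
    labels : (n,) int array
        Cluster labels ``1..k``, numbered by decreasing cluster size
        (ties: smaller leaf index first). A tree with no qualifying
        split yields a single cluster.
    """
    if deep_split not in _GAP_FRACTION:
        raise ValueError(f"deep_split must be in 0..4, got {deep_split}")
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")

    n = linkage.shape[0] + 1
    heights = linkage[:, 2]
    root_h = heights[-1]
    ref_h = float(np.percentile(heights, 5))
    min_gap = _GAP_FRACTION[deep_split] * max(root_h - ref_h, 0.0)

    # per node (leaves 0..n-1, merges n..2n-2): leaf set, top internal
    # height, and whether the node already contains >1 committed cluster
    leaves: list[list[int]] = [[i] for i in range(n)] + [None] * (n - 1)
    top = np.zeros(2 * n - 1)
    composite = np.zeros(2 * n - 1, dtype=bool)
    cores: list[list[int]] = []  # committed cluster cores (leaf lists)
    # leaf sets of plain branches absorbed next to committed clusters
    unassigned: list[list[int]] = []

    def qualifies(node: int, h: float) -> bool:
        return len(leaves[node]) >= min_cluster_size and (h - top[node]) >= min_gap

    for m in range(n - 1):
        a, b = int(linkage[m, 0]), int(linkage[m, 1])
        node = n + m
        h = heights[m]
        leaves[node] = leaves[a] + leaves[b]
        top[node] = h
        if composite[a] or composite[b]:
            # distinct clusters already live below; any plain sibling
            # either qualifies as its own core or is mopped up later
            composite[node] = True
            for child in (a, b):
                if not composite[child]:
                    if qualifies(child, h):
                        cores.append(leaves[child])
                    else:
                        unassigned.append(leaves[child])
        elif qualifies(a, h) and qualifies(b, h):
            composite[node] = True
            cores.append(leaves[a])
            cores.append(leaves[b])
        # else: ordinary within-cluster merge

    if not cores:  # no qualifying split anywhere: one cluster
        return np.ones(n, dtype=int)

    labels = np.zeros(n, dtype=int)
    for ci, members in enumerate(cores, start=1):
        labels[members] = ci

    if unassigned:
        centroids = np.stack([data[np.asarray(c)].mean(axis=0) for c in cores])
        for branch in unassigned:
            for leaf in branch:
                d = np.linalg.norm(centroids - data[leaf], axis=1)
                labels[leaf] = int(np.argmin(d)) + 1

    return _relabel_by_size(labels)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..k by decreasing size, ties by first appearance."""
    ids, counts = np.unique(labels, return_counts=True)
    first = np.array([np.argmax(labels == i) for i in ids])
    order = sorted(range(len(ids)), key=lambda j: (-counts[j], first[j]))
    mapping = {ids[j]: rank + 1 for rank, j in enumerate(order)}
    return np.array([mapping[v] for v in labels], dtype=int)
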