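"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle recomputes a quantity along a different route from the
implementation it checks: sphere-exclusion by literal re-simulation over
explicit neighbour sets, cophenetic distances by root-path edge sums,
hierarchy cuts by exhaustive k-scan, and superposition by direct numeric
minimisation over rotation vectors.
"""

from __future__ import annotations

import numpy as np


def brute_force_sphere_exclusion(ids, values, cutoff):
    """Literal sphere-exclusion: sets and explicit max-degree selection.

    Returns a partition as a set of frozensets of ids.  Ties on the
    neighbour count break by lexicographically smallest id (the documented
    convention).  Independent of the package's implementation: operates on
    plain dicts of neighbour sets.
    """
    neigh = {
        a: {b for b in ids if b != a
            and values[ids.index(a), ids.index(b)] >= cutoff}
        for a in ids
    }
    remaining = set(ids)
    partition = []
    while remaining:
        degree = {a: len(neigh[a] & remaining) for a in remaining}
        top = max(degree.values())
        centroid = min(a for a in remaining if degree[a] == top)
        cluster = (neigh[centroid] & remaining) | {centroid}
        partition.append(frozenset(cluster))
        remaining -= cluster
    return set(partition)


def cophenetic_by_root_paths(tree):
    """Leaf distances via root-path edge sums (dendropy Tree input).

    For each leaf, record the edges on its path to the root; the distance
    between two leaves is the total length of the symmetric difference of
    their edge sets.
    """
    paths = {}
    for leaf in tree.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append(node.edge)
            node = node.parent_node
        paths[leaf.taxon.label] = edges
    ids = sorted(paths)
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = set(paths[ids[i]]), set(paths[ids[j]])
            d = sum(e.length for e in a.symmetric_difference(b))
            m[i, j] = m[j, i] = d
    return ids, m


def exhaustive_one_percent_scan(matrix, kmax, major_fraction=0.01):
    """For every k, the number of clusters holding >= 1% of leaves.

    Uses the same complete-linkage hierarchy definition (scipy) but scans
    every k independently; returns {k: n_major}.
    """
    from collections import Counter

    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    n = matrix.shape[0]
    z = linkage(squareform(matrix, checks=False), method="complete")
    out = {}
    for k in range(2, kmax + 1):
        assign = fcluster(z, t=k, criterion="maxclust")
        sizes = Counter(assign)
        out[k] = sum(1 for s in sizes.values() if s / n >= major_fraction)
    return out


def numeric_min_rmsd(mobile, reference, n_starts=12, seed=0):
    """Minimum RMSD over rigid motions by direct optimisation.

    Parameterises rotation as a rotation vector and minimises the RMSD
    (translation handled in closed form by centroid alignment) from several
    random starts — no SVD, independent of the Kabsch route.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    m = np.asarray(mobile, float)
    r = np.asarray(reference, float)
    m0 = m - m.mean(axis=0)
    r0 = r - r.mean(axis=0)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = m0 @ R.T - r0
        return np.sqrt(np.mean(np.sum(d * d, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        x0 = rng.uniform(-np.pi, np.pi, size=3)
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return float(best)


def random_similarity_matrix(rng, n):
    """A random symmetric TI-like matrix with unit diagonal."""
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    return v


def random_binary_tree_newick(rng, n_leaves, max_bl=2.0):
    """Random binary topology over labelled leaves with random branch lengths."""
    labels = [f"L{i}" for i in range(n_leaves)]

    def build(leaves):
        if len(leaves) == 1:
            return f"{leaves[0]}:{rng.uniform(0.01, max_bl):.6f}"
        k = int(rng.integers(1, len(leaves)))
        left, right = leaves[:k], leaves[k:]
        return (f"({build(left)},{build(right)})"
                f":{rng.uniform(0.01, max_bl):.6f}")

    order = list(labels)
    rng.shuffle(order)
    return f"({build(order[: len(order) // 2 or 1])},{build(order[len(order) // 2 or 1:])});"
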