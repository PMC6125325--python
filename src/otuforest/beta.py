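"""Phylogenetic beta diversity: generalized UniFrac, PCoA, PERMANOVA.

Generalized UniFrac weights every branch of a rooted phylogeny by its length
times a power ``alpha`` of the combined relative abundance descending
through it:

    d_alpha(A, B) = sum_i  b_i (pA_i + pB_i)^alpha * |pA_i - pB_i| / (pA_i + pB_i)
                    ------------------------------------------------------------
                    sum_i  b_i (pA_i + pB_i)^alpha

with ``b_i`` the branch length and ``p_i`` the fraction of a sample's reads
on leaves below branch ``i``.  ``alpha = 1`` is weighted-normalized UniFrac;
``alpha = 0`` weighs rare and abundant lineages equally; ``alpha = 0.5`` is
the usual compromise and the default here.

The ordination of a UniFrac matrix is classical metric scaling (principal
coordinates), and group structure is tested by one-factor PERMANOVA with
freely permuted labels and the add-one p-value convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree with branch lengths."""
    return TreeNode.read(str(path), format="newick")


def _branch_profile(
    table: pd.DataFrame, tree: TreeNode
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample branch mass: fraction of each sample's reads under each branch.

    Returns ``(P, b)`` where ``P`` is samples × branches and ``b`` the branch
    lengths, one entry per non-root node in postorder.
    """
    leaf_names = {leaf.name for leaf in tree.tips()}
    missing = [o for o in table.columns if o not in leaf_names]
    if missing:
        raise ValueError(f"OTUs absent from tree: {missing}")
    totals = table.sum(axis=1).to_numpy(dtype=float)
    if np.any(totals <= 0):
        bad = table.index[totals <= 0].tolist()
        raise ValueError(f"samples with non-positive totals: {bad}")
    rel = table.to_numpy(dtype=float) / totals[:, None]
    col_of = {o: j for j, o in enumerate(table.columns)}

    n = table.shape[0]
    profiles: list[np.ndarray] = []
    lengths: list[float] = []
    node_mass: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            j = col_of.get(node.name)
            mass = rel[:, j].copy() if j is not None else np.zeros(n)
        else:
            mass = np.zeros(n)
            for child in node.children:
                mass += node_mass.pop(id(child))
        node_mass[id(node)] = mass
        if node.parent is not None:  # root branch carries no information
            if node.length is None:
                raise ValueError("tree has a branch without a length")
            profiles.append(mass)
            lengths.append(float(node.length))
    return np.asarray(profiles).T, np.asarray(lengths)


def generalized_unifrac(
    table: pd.DataFrame, tree: TreeNode, alpha: float = 0.5
) -> DistanceMatrix:
    """Pairwise generalized UniFrac distances between all samples of ``table``.

    Branches carrying no mass in either sample of a pair contribute nothing
    to numerator or denominator.  Distances lie in [0, 1].
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    P, b = _branch_profile(table, tree)
    n = P.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        pi = P[i]
        for j in range(i + 1, n):
            pj = P[j]
            s = pi + pj
            mask = s > 0
            w = b[mask] * s[mask] ** alpha
            den = w.sum()
            if den == 0:
                d[i, j] = d[j, i] = 0.0
                continue
            num = (w * np.abs(pi[mask] - pj[mask]) / s[mask]).sum()
            d[i, j] = d[j, i] = num / den
    return DistanceMatrix(d, ids=list(table.index))


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of a distance matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples × k, axes by decreasing eigenvalue
    proportion_explained: np.ndarray  # fraction of positive-eigenvalue variance
    eigvals: np.ndarray  # all eigenvalues, descending (negatives included)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical metric scaling (principal coordinates) of a distance matrix.

    The squared-distance matrix is double-centred (Gower) and
    eigendecomposed; axes with non-positive eigenvalues are discarded (their
    eigenvalues are still reported).  When the matrix is Euclidean-embeddable
    the pairwise distances between returned coordinates reproduce it.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    D = dm.data
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(np.abs(eigvals).max(), 1.0) * 1e-12
    n_pos = int((eigvals > tol).sum())
    if k > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating k from {k}",
            UserWarning,
            stacklevel=2,
        )
        k = max(n_pos, 0)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    pos_sum = eigvals[:n_pos].sum()
    prop = eigvals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    return OrdinationResult(
        sample_ids=list(dm.ids),
        coordinates=coords,
        proportion_explained=prop,
        eigvals=eigvals,
    )


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int


def _pseudo_f(D2: np.ndarray, labels: np.ndarray) -> float:
    """One-factor PERMANOVA pseudo-F from squared distances and group labels."""
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss_within += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    a = len(groups)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    dm: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Labels are permuted freely (one factor, no strata);
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` so p is never 0.
    Deterministic for a fixed seed.
    """
    labels = np.asarray(labels)
    if len(labels) != dm.shape[0]:
        raise ValueError("labels length must match distance matrix size")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two distinct group labels")
    if n_permutations < 99:
        raise ValueError(f"n_permutations must be >= 99, got {n_permutations}")
    D2 = dm.data**2
    f_obs = _pseudo_f(D2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if _pseudo_f(D2, rng.permutation(labels)) >= f_obs:
            hits += 1
    return PermanovaResult(
        pseudo_F=float(f_obs),
        p_value=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations,
    )


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t", index_label="#SampleID"
    )
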