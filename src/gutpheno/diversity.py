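"""Beta diversity, principal coordinates, and PERMANOVA.

All three dissimilarity metrics operate on relative abundances (each sample's
counts divided by its library size), so uneven sequencing depth does not
dominate the comparison.  Distances are returned as `skbio.DistanceMatrix`
objects keyed by sample ID.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "relative_abundance",
    "bray_curtis",
    "jensen_shannon",
    "weighted_unifrac",
    "Ordination",
    "pcoa",
    "PermanovaResult",
    "permanova",
]


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize counts to relative abundances; errors on all-zero samples."""
    totals = counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return counts.div(totals, axis=0)


def bray_curtis(counts: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity on relative abundances."""
    rel = relative_abundance(counts)
    d = pdist(rel.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=list(counts.index))


def jensen_shannon(counts: pd.DataFrame, sqrt: bool = False) -> DistanceMatrix:
    """Pairwise Jensen-Shannon divergence (log base 2) on relative abundances.

    Returns the divergence itself by default (maximum 1 for disjoint
    supports); set ``sqrt=True`` for the metric square-root variant.
    """
    rel = relative_abundance(counts)
    # scipy's jensenshannon distance is sqrt(JSD) in nats; rescale to base 2.
    root_js_nats = pdist(rel.to_numpy(dtype=float), metric="jensenshannon")
    div = np.clip(root_js_nats**2 / np.log(2.0), 0.0, 1.0)
    d = np.sqrt(div) if sqrt else div
    return DistanceMatrix(squareform(d), ids=list(counts.index))


def weighted_unifrac(counts: pd.DataFrame, tree: TreeNode) -> DistanceMatrix:
    """Raw weighted UniFrac: sum over branches of length * |A_b - B_b|.

    A_b is the fraction of a sample's relative abundance descending from
    branch b.  The tree's leaf set must cover every taxon in the table
    (extra leaves simply carry zero abundance).
    """
    taxa = list(counts.columns)
    leaf_names = {t.name for t in tree.tips()}
    missing = [t for t in taxa if t not in leaf_names]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    rel = relative_abundance(counts).to_numpy(dtype=float)
    col = {t: i for i, t in enumerate(taxa)}
    n = rel.shape[0]

    # Postorder accumulation of per-branch descending abundance per sample.
    weighted_cols: list[np.ndarray] = []
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = (rel[:, col[node.name]] if node.name in col
                   else np.zeros(n))
        else:
            vec = np.zeros(n)
            for child in node.children:
                vec = vec + partial.pop(id(child))
        partial[id(node)] = vec
        if node.parent is not None and node.length:
            weighted_cols.append(node.length * vec)
    if weighted_cols:
        m = np.column_stack(weighted_cols)
        d = pdist(m, metric="cityblock")
    else:
        d = np.zeros(n * (n - 1) // 2)
    return DistanceMatrix(squareform(d), ids=list(counts.index))


@dataclass
class Ordination:
    """PCoA result: sample coordinates on positive-eigenvalue axes.

    ``proportion_explained`` is the percent of the positive-eigenvalue total
    attributed to each retained axis; ``eigenvalues`` keeps the full spectrum
    (negative eigenvalues included) for diagnostics.
    """

    coordinates: pd.DataFrame  # samples x axes, ordered by descending eigenvalue
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray  # percent, per retained (positive) axis

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Principal coordinates via Gower double-centering of -D^2/2."""
    d = dm.data
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    b = a - row - col + a.mean()
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-10 * abs(eigvals[0])) if eigvals.size else 0.0
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pct = eigvals[pos] / eigvals[pos].sum() * 100.0
    axes = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    return Ordination(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=eigvals,
        proportion_explained=pct,
    )


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int


def permanova(
    dm: DistanceMatrix,
    labels: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix (Anderson's construction).

    SS_total = sum of squared distances / N; SS_within sums the per-group
    analogue; pseudo-F = (SS_among/(a-1)) / (SS_within/(N-a)).  The p-value
    is (1 + #{permuted F >= observed}) / (n_perm + 1) under seeded free
    permutation of sample labels.
    """
    ids = list(dm.ids)
    grp = labels.loc[ids].to_numpy()
    names, codes = np.unique(grp, return_inverse=True)
    if len(names) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = names[sizes < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    d2 = dm.data**2
    n = d2.shape[0]
    a = len(names)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def ss_within(code_vec: np.ndarray) -> float:
        ss = 0.0
        for k in range(a):
            idx = np.flatnonzero(code_vec == k)
            block = d2[np.ix_(idx, idx)]
            ss += block.sum() / (2 * idx.size)
        return ss

    ss_w = ss_within(codes)
    ss_a = ss_total - ss_w
    f_obs = (ss_a / (a - 1)) / (ss_w / (n - a))
    r2 = ss_a / ss_total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        ss_w_p = ss_within(perm)
        ss_a_p = ss_total - ss_w_p
        f_p = (ss_a_p / (a - 1)) / (ss_w_p / (n - a))
        if f_p >= f_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermanovaResult(pseudo_f=float(f_obs), r2=float(r2),
                           p_value=float(p), n_permutations=n_perm)
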