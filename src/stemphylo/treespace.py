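"""Treespace embedding of tree samples.

Pairwise unweighted Robinson-Foulds distances (the size of the symmetric
difference between two trees' nontrivial split sets) are embedded by
classical metric multidimensional scaling: eigendecomposition of the
double-centred Gram matrix, coordinates scaled by the square roots of the
non-negative eigenvalues.  RF distance matrices are generally non-Euclidean;
negative eigenvalues are truncated to zero with a warning.  Range-overlap
summaries per axis quantify how much hypothesis-labelled tree groups (e.g.
monophyletic-proboscis vs paraphyletic-grade topologies) co-occupy the
embedded space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nexus_io import Tree, TreeRecord, as_tree

__all__ = [
    "DistanceMatrix",
    "Embedding",
    "OverlapReport",
    "rf_distance",
    "pairwise_distances",
    "classical_mds",
    "overlap_summary",
]


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Embedding:
    coordinates: np.ndarray  # (n_trees, n_axes)
    eigenvalues: np.ndarray  # descending, full spectrum
    labels: list = field(default_factory=list)
    group_labels: dict[int, str] | None = None

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            columns=[f"axis_{i + 1}" for i in range(self.n_axes)],
        )
        if self.labels:
            df.insert(0, "tree", self.labels)
        if self.group_labels is not None:
            df["group"] = [self.group_labels.get(i) for i in range(len(df))]
        return df


def rf_distance(t1: Tree | TreeRecord, t2: Tree | TreeRecord) -> int:
    """Unweighted Robinson-Foulds distance (symmetric split difference)."""
    a, b = as_tree(t1), as_tree(t2)
    if a.leaf_names != b.leaf_names:
        raise ValueError("leaf sets differ")
    return len(a.splits() ^ b.splits())


def pairwise_distances(trees: Sequence[TreeRecord | Tree]) -> DistanceMatrix:
    """Full symmetric RF distance matrix over a tree sample."""
    ts = [as_tree(t) for t in trees]
    if not ts:
        raise ValueError("empty tree list")
    leaves = ts[0].leaf_names
    splits = []
    for t in ts:
        if t.leaf_names != leaves:
            raise ValueError("leaf sets differ")
        splits.append(t.splits())
    n = len(ts)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = len(splits[i] ^ splits[j])
    labels = [
        t.provenance if isinstance(t, TreeRecord) else i
        for i, t in enumerate(trees)
    ]
    return DistanceMatrix(labels=labels, values=d)


def classical_mds(d: DistanceMatrix, n_axes: int = 3) -> Embedding:
    """Classical (metric) MDS / principal coordinates analysis.

    The Gram matrix ``B = -J D^2 J / 2`` (J the centring matrix) is
    eigendecomposed; axes are ordered by descending eigenvalue and each
    axis's sign is fixed so its largest-magnitude coordinate is positive.
    """
    n = d.n
    if n_axes > max(n - 1, 1):
        raise ValueError("n_axes must be <= n_trees - 1")
    D2 = d.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    if np.any(eigval < -1e-9 * max(1.0, abs(eigval[0]))):
        warnings.warn(
            "negative eigenvalues truncated to zero (non-Euclidean distances)",
            stacklevel=2,
        )
    lam = np.clip(eigval, 0.0, None)
    coords = eigvec[:, :n_axes] * np.sqrt(lam[:n_axes])
    for i in range(coords.shape[1]):
        col = coords[:, i]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, i] = -col
    return Embedding(coordinates=coords, eigenvalues=eigval, labels=list(d.labels))


@dataclass
class OverlapReport:
    """Per-axis group ranges, pairwise range-overlap fractions and centroids."""

    axes: list[int]
    ranges: dict[str, list[tuple[float, float]]]  # group -> per-axis (lo, hi)
    overlap: dict[tuple[str, str], list[float]]  # pair -> per-axis fraction
    centroids: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (g1, g2), fracs in self.overlap.items():
            for ax, f in zip(self.axes, fracs):
                rows.append({"group_a": g1, "group_b": g2, "axis": ax, "overlap": f})
        return pd.DataFrame(rows)


def overlap_summary(e: Embedding, groups: Mapping[int, str],
                    declared: Sequence[str] | None = None) -> OverlapReport:
    """Interval overlap of labelled tree groups on each MDS axis.

    For each axis and group pair the overlap fraction is the length of the
    intersection of the two coordinate ranges divided by the length of their
    union (0 = disjoint, 1 = identical ranges).  ``declared`` categories
    with no trees are dropped with a warning; at least two non-empty groups
    are required.
    """
    by_group: dict[str, list[int]] = {}
    for idx, g in groups.items():
        by_group.setdefault(g, []).append(idx)
    names = sorted(g for g, idxs in by_group.items() if idxs)
    for g in sorted(set(declared) if declared is not None else set()):
        if g not in names:
            warnings.warn(f"group {g!r} has no trees; excluded", stacklevel=2)
    if len(names) < 2:
        raise ValueError("need >= 2 non-empty groups")
    axes = list(range(e.n_axes))
    ranges: dict[str, list[tuple[float, float]]] = {}
    centroids: dict[str, np.ndarray] = {}
    for g in names:
        pts = e.coordinates[by_group[g]]
        ranges[g] = [(float(pts[:, a].min()), float(pts[:, a].max())) for a in axes]
        centroids[g] = pts.mean(axis=0)
    overlap: dict[tuple[str, str], list[float]] = {}
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            fracs = []
            for a in axes:
                lo1, hi1 = ranges[g1][a]
                lo2, hi2 = ranges[g2][a]
                inter = min(hi1, hi2) - max(lo1, lo2)
                union = max(hi1, hi2) - min(lo1, lo2)
                if union <= 0:  # all points identical on this axis
                    fracs.append(1.0)
                else:
                    fracs.append(max(inter, 0.0) / union)
            overlap[(g1, g2)] = fracs
    return OverlapReport(axes=[a + 1 for a in axes], ranges=ranges,
                         overlap=overlap, centroids=centroids)


def plot_embedding(e: Embedding, groups: Mapping[int, str] | None = None,
                   path: str | None = None):
    """Static scatter plots of axes 1-2 and 1-3 (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axs = plt.subplots(1, 2, figsize=(10, 4.5))
    pairs = [(0, 1), (0, 2)] if e.n_axes >= 3 else [(0, 1), (0, 1)]
    labels = (
        {i: groups.get(i, "unlabelled") for i in range(len(e.coordinates))}
        if groups
        else {i: "tree" for i in range(len(e.coordinates))}
    )
    cats = sorted(set(labels.values()))
    for ax, (i, j) in zip(axs, pairs):
        for cat in cats:
            idxs = [n for n, c in labels.items() if c == cat]
            ax.scatter(e.coordinates[idxs, i], e.coordinates[idxs, j],
                       s=12, alpha=0.6, label=cat)
        ax.set_xlabel(f"MDS axis {i + 1}")
        ax.set_ylabel(f"MDS axis {j + 1}")
    axs[0].legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
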