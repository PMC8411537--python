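"""Divergence of 2-D kinematic distributions and species clustering.

Each species' pooled per-frame (centroid speed, |bend angle|) points are
binned on a fixed 40 x 70 grid -- speed in 0.1 mm/s steps over [0, 4)
mm/s, angle in 2 degree steps over [0, 140) degrees, 2800 cells in all --
and normalised to a probability distribution.  Species are compared with
the Kullback-Leibler divergence

    KL(p, q) = sum_cells p * ln(p / q)

and its symmetrised form

    JS(p, q) = (KL(p, q) + KL(q, p)) / 2,

in nats, and hierarchically clustered on the resulting pairwise JS
matrix.  A small pseudocount keeps KL finite on empty cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

SPEED_EDGES = np.round(np.arange(0.0, 4.0 + 1e-9, 0.1), 10)  # 40 bins
ANGLE_EDGES = np.round(np.arange(0.0, 140.0 + 1e-9, 2.0), 10)  # 70 bins
N_CELLS = (len(SPEED_EDGES) - 1) * (len(ANGLE_EDGES) - 1)  # 2800
DEFAULT_PSEUDOCOUNT = 1e-9


class DegenerateGridError(ValueError):
    """All points fell outside the grid range."""


class DivergenceError(ValueError):
    """Invalid divergence input (shape mismatch or unsupported zeros)."""


@dataclass
class ProbabilityGrid:
    """Normalised 40 (speed) x 70 (angle) histogram of kinematic points."""

    probs: np.ndarray  # shape (40, 70), sums to 1
    counts_total: int
    dropped_out_of_range: int
    pseudocount: float

    def __post_init__(self) -> None:
        if self.probs.shape != (40, 70):
            raise ValueError(f"grid must be 40x70, got {self.probs.shape}")


def build_grid(points: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> ProbabilityGrid:
    """Bin (speed, |angle|) points into the 2800-cell probability grid.

    Bins are half-open [lo, lo + width); points with speed >= 4 mm/s or
    |angle| >= 140 deg fall outside and are dropped (counted in
    ``dropped_out_of_range``).  ``pseudocount`` is added to every cell
    before normalisation so that later divergences stay finite.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (speed, angle)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    speed = pts[:, 0]
    angle = np.abs(pts[:, 1])
    in_range = (speed >= 0) & (speed < 4.0) & (angle < 140.0)
    dropped = int(np.sum(~in_range))
    kept = pts[in_range]
    if kept.shape[0] == 0:
        raise DegenerateGridError(
            f"all {len(pts)} points fall outside the grid range "
            "(speed [0,4) mm/s, |angle| [0,140) deg)"
        )
    counts, _, _ = np.histogram2d(
        kept[:, 0], np.abs(kept[:, 1]), bins=[SPEED_EDGES, ANGLE_EDGES]
    )
    counts = counts + pseudocount
    probs = counts / counts.sum()
    return ProbabilityGrid(
        probs=probs,
        counts_total=int(kept.shape[0]),
        dropped_out_of_range=dropped,
        pseudocount=pseudocount,
    )


def _check_pair(p: ProbabilityGrid, q: ProbabilityGrid) -> tuple[np.ndarray, np.ndarray]:
    if p.probs.shape != q.probs.shape:
        raise DivergenceError(
            f"grid shape mismatch: {p.probs.shape} vs {q.probs.shape}"
        )
    return p.probs, q.probs


def kl_divergence(p: ProbabilityGrid, q: ProbabilityGrid) -> float:
    """Kullback-Leibler divergence KL(p, q) in nats (natural log).

    Cells with p = 0 contribute 0.  A cell with q = 0 where p > 0 makes
    KL infinite; that situation is rejected with advice to use a positive
    pseudocount when building the grids.
    """
    pp, qq = _check_pair(p, q)
    support = pp > 0
    if np.any(qq[support] == 0):
        raise DivergenceError(
            "KL(p, q) is infinite: q has zero cells on p's support; "
            "build the grids with a positive pseudocount"
        )
    return float(np.sum(pp[support] * np.log(pp[support] / qq[support])))


def js_divergence(p: ProbabilityGrid, q: ProbabilityGrid) -> float:
    """Symmetrised KL divergence, (KL(p,q) + KL(q,p)) / 2, in nats.

    Note this is the symmetrised-KL form, not the mixture-based
    Jensen-Shannon divergence; it is unbounded but symmetric and zero iff
    p = q.
    """
    return 0.5 * (kl_divergence(p, q) + kl_divergence(q, p))


@dataclass
class DivergenceMatrix:
    """Symmetric pairwise JS divergence matrix with species labels."""

    values: np.ndarray
    labels: list[str]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def divergence_matrix(grids, labels=None) -> DivergenceMatrix:
    """Pairwise JS divergences between species probability grids."""
    grids = list(grids)
    n = len(grids)
    if n < 2:
        raise ValueError("need at least two grids")
    if labels is None:
        labels = [f"species_{i}" for i in range(n)]
    labels = [str(l) for l in labels]
    if len(labels) != n:
        raise ValueError("labels must match the number of grids")
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = js_divergence(grids[i], grids[j])
            values[i, j] = values[j, i] = d
    return DivergenceMatrix(values=values, labels=labels)


@dataclass
class Dendrogram:
    """Agglomerative clustering of species on JS distances."""

    linkage_matrix: np.ndarray  # scipy linkage format
    labels: list[str]
    method: str

    def merge_order(self) -> list[tuple[frozenset, frozenset, float]]:
        """Merges as (left leaf set, right leaf set, height), in order."""
        n = len(self.labels)
        clusters: dict[int, frozenset] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        merges = []
        for step, (a, b, height, _size) in enumerate(self.linkage_matrix):
            left, right = clusters[int(a)], clusters[int(b)]
            merges.append((left, right, float(height)))
            clusters[n + step] = left | right
        return merges

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge-height differences."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def hierarchical_cluster(d: DivergenceMatrix, method: str = "average") -> Dendrogram:
    """Cluster species agglomeratively on the JS divergence matrix.

    ``method`` is one of single / average / complete; average (UPGMA) is
    the default.  Returns the scipy merge tree with heights.
    """
    if method not in ("single", "average", "complete"):
        raise ValueError("linkage must be single, average, or complete")
    n = d.values.shape[0]
    if n < 2:
        raise ValueError("need at least two species to cluster")
    if not np.allclose(d.values, d.values.T) or np.any(np.diag(d.values) != 0):
        raise ValueError("divergence matrix must be symmetric with zero diagonal")
    condensed = squareform(d.values, checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    return Dendrogram(linkage_matrix=Z, labels=list(d.labels), method=method)
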