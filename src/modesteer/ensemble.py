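"""Ensemble analysis: distance monitors, pairwise RMSD, single-link clustering.

The clustering follows the classic conformer-ensemble recipe: compute the
pairwise superposed-RMSD matrix over a binding-site selection, build the
agglomerative single-link hierarchy (equivalent to the minimum spanning
tree with edges taken in ascending weight order), score every clustering
level by its separation ratio — the shortest inter-cluster distance
divided by the characteristic threshold distance defining that level —
and keep the level with the highest ratio.  Each cluster is represented
by its medoid.

For single linkage the separation ratio at level j equals h_{j+1}/h_j,
the ratio of consecutive merge heights; :func:`separation_ratios` computes
the definitional quantity from the distance matrix and the identity is
cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structio import Selection, SelectionError, Structure, superpose

__all__ = [
    "MonitorSeries",
    "ClusterHierarchy",
    "monitor_distance",
    "pairwise_rmsd",
    "cluster_single_link",
    "separation_ratios",
    "choose_clustering",
    "B2AR_BINDING_SITE_RESIDUES",
]

#: Binding-site residue preset (β2AR author numbering): the experimentally
#: critical ligand-binding residues on H3, H5, H6 and H7.
B2AR_BINDING_SITE_RESIDUES: tuple[int, ...] = (
    109, 113, 114,            # Trp109, Asp113, Val114 (H3)
    203, 204, 207, 211,       # Ser203, Ser204, Ser207, Pro211 (H5)
    282, 286, 289, 290, 293, 294, 297,   # H6 aromatics + Asn pair
    308, 312, 316,            # Tyr308, Asn312, Tyr316 (H7)
)


@dataclass
class MonitorSeries:
    """Per-conformer inter-group distance (Å)."""

    keys: list[str]
    distances: np.ndarray
    description: str = ""


def _ensemble_models(ensemble: Sequence[Structure] | Structure
                     ) -> tuple[list[Structure], list[str]]:
    if isinstance(ensemble, Structure):
        models = [ensemble.model(i) for i in range(ensemble.n_models)]
        keys = [str(i) for i in range(ensemble.n_models)]
    else:
        models = list(ensemble)
        keys = [m.provenance or str(i) for i, m in enumerate(models)]
    if not models:
        raise ValueError("empty ensemble")
    return models, keys


def monitor_distance(ensemble: Sequence[Structure] | Structure,
                     group_a: Selection, group_b: Selection,
                     mode: str = "min") -> MonitorSeries:
    """Track the distance between two atom groups across an ensemble.

    ``mode='min'`` reports the minimum pairwise distance between the two
    groups in each conformer; ``mode='specific'`` requires each selection
    to resolve to exactly one atom and reports that atom–atom distance.
    """
    if mode not in ("min", "specific"):
        raise ValueError("mode must be 'min' or 'specific'")
    models, keys = _ensemble_models(ensemble)
    out = np.empty(len(models))
    for m, model in enumerate(models):
        ia = group_a.resolve(model)
        ib = group_b.resolve(model)
        if mode == "specific" and (ia.size != 1 or ib.size != 1):
            raise SelectionError(
                "mode='specific' requires single-atom selections "
                f"(got {ia.size} and {ib.size})")
        xa = model.coords[0][ia]
        xb = model.coords[0][ib]
        d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
        out[m] = float(d.min())
    return MonitorSeries(keys=keys, distances=out)


def pairwise_rmsd(ensemble: Sequence[Structure] | Structure,
                  selection: Selection | None = None,
                  superpose_on: str = "selection") -> np.ndarray:
    """Symmetric matrix of superposed RMSDs over a selection.

    Each pair is rigid-body superposed before measuring, either on the
    selection itself (default — local rearrangements are then measured
    in their own frame) or on all Cα atoms (``superpose_on='calpha'``).
    """
    models, _keys = _ensemble_models(ensemble)
    n = len(models)
    if n < 2:
        raise ValueError("need at least 2 conformers")
    if selection is None:
        selection = Selection.calpha()
    sel_idx = selection.resolve(models[0])
    if sel_idx.size < 3:
        raise SelectionError("selection resolves to fewer than 3 atoms")
    if superpose_on == "selection":
        fit_idx = sel_idx
    elif superpose_on == "calpha":
        fit_idx = Selection.calpha().resolve(models[0])
    else:
        raise ValueError("superpose_on must be 'selection' or 'calpha'")
    sel = [m.coords[0][sel_idx] for m in models]
    fit = [m.coords[0][fit_idx] for m in models]
    M = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            R, t, _ = superpose(fit[b], fit[a])
            moved = sel[b] @ R.T + t
            r = float(np.sqrt(np.mean(np.sum((moved - sel[a]) ** 2, axis=1))))
            M[a, b] = M[b, a] = r
    return M


@dataclass
class ClusterHierarchy:
    """Single-link merge sequence over n items.

    ``heights`` ascend; ``merges[j]`` is the (lower-index, higher-index)
    item pair whose edge performed merge j+1.  Level j (1 ≤ j ≤ n−1)
    denotes the partition after j merges, holding n−j clusters.
    """

    n: int
    heights: np.ndarray                  # (n-1,)
    merges: list[tuple[int, int]]
    keys: list[str] | None = None

    def clusters_at_level(self, level: int) -> list[list[int]]:
        """Partition after ``level`` merges (level 0 = all singletons)."""
        if not 0 <= level <= self.n - 1:
            raise ValueError(f"level must be in 0..{self.n - 1}")
        parent = list(range(self.n))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, j in self.merges[:level]:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
        groups: dict[int, list[int]] = {}
        for item in range(self.n):
            groups.setdefault(find(item), []).append(item)
        return [sorted(g) for g in sorted(groups.values(), key=lambda g: g[0])]


def _check_matrix(matrix: np.ndarray) -> np.ndarray:
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("distance matrix must be square")
    if M.shape[0] < 2:
        raise ValueError("need at least 2 items")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(M < 0):
        raise ValueError("distances must be non-negative")
    if np.any(np.abs(np.diag(M)) > 1e-12):
        raise ValueError("diagonal must be zero")
    return M


def cluster_single_link(matrix: np.ndarray,
                        keys: list[str] | None = None) -> ClusterHierarchy:
    """Agglomerative single-link hierarchy of a distance matrix.

    Implemented as Kruskal's minimum-spanning-tree construction: edges
    sorted ascending by (weight, i, j) — so ties break on the lowest
    item-index pair — joined when they bridge distinct clusters.  The
    accepted edge weights, in order, are the single-link merge heights.
    """
    M = _check_matrix(matrix)
    n = M.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, M[iu, ju]))
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    heights, merges = [], []
    for e in order:
        i, j = int(iu[e]), int(ju[e])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
            heights.append(float(M[i, j]))
            merges.append((i, j))
            if len(merges) == n - 1:
                break
    return ClusterHierarchy(n=n, heights=np.asarray(heights),
                            merges=merges, keys=keys)


def separation_ratios(hierarchy: ClusterHierarchy,
                      matrix: np.ndarray) -> np.ndarray:
    """Separation ratio per clustering level, from its definition.

    At level j the threshold distance is h_j, the largest merge height
    used, and the ratio is (shortest distance between items in different
    clusters) / h_j.  Levels with a zero threshold (duplicate conformers)
    and the single-cluster level are flagged NaN rather than silently
    infinite.  For single linkage the finite values equal h_{j+1}/h_j.
    """
    M = _check_matrix(matrix)
    n = hierarchy.n
    ratios = np.full(n - 1, np.nan)
    for level in range(1, n - 1):
        threshold = hierarchy.heights[level - 1]
        if threshold <= 0:
            continue
        clusters = hierarchy.clusters_at_level(level)
        label = np.empty(n, dtype=int)
        for c, members in enumerate(clusters):
            label[members] = c
        iu, ju = np.triu_indices(n, k=1)
        across = label[iu] != label[ju]
        ratios[level - 1] = float(M[iu[across], ju[across]].min()) / threshold
    return ratios


def choose_clustering(hierarchy: ClusterHierarchy, matrix: np.ndarray,
                      ) -> tuple[int, list[list[int]], list[int]]:
    """Pick the level with the highest separation ratio; medoid reps.

    Ties prefer fewer clusters (the deeper level).  Each cluster's
    representative is its medoid — the member minimizing summed
    intra-cluster distance, ties to the lowest index.  Returns
    (level, clusters as index lists, representative indices).
    """
    M = _check_matrix(matrix)
    ratios = separation_ratios(hierarchy, M)
    usable = np.flatnonzero(np.isfinite(ratios))
    if usable.size == 0:
        raise ValueError("no usable clustering level (all duplicates?)")
    best = max(usable, key=lambda i: (ratios[i], i))
    level = int(best) + 1
    clusters = hierarchy.clusters_at_level(level)
    reps = []
    for members in clusters:
        sub = M[np.ix_(members, members)]
        sums = sub.sum(axis=1)
        reps.append(members[int(np.argmin(sums))])
    return level, clusters, reps
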