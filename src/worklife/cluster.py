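"""Ward clustering of OM dissimilarities with stopping-rule diagnostics.

The sequence dissimilarity matrix is clustered with Ward's agglomerative
criterion (Ward.D2 convention by default: the Lance-Williams update applied
to squared dissimilarities).  Two classical stopping rules guide the choice
of the number of clusters: the Calinski-Harabasz pseudo-F (between/within
dispersion ratio) and the Duda-Hart Je(2)/Je(1) split ratio with its
pseudo-T².  Both are computed in their distance-based forms, which coincide
with the familiar variance-based definitions when the dissimilarities are
Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .sequences import DistanceMatrix, SequencePanel


@dataclass
class LinkageTree:
    """Agglomerative merge tree (scipy linkage encoding)."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    n: int
    variant: str = "d2"

    def __post_init__(self) -> None:
        if self.merges.shape != (self.n - 1, 4):
            raise ValueError("linkage matrix shape does not match leaf count")
        heights = self.merges[:, 2]
        if (np.diff(heights) < -1e-9).any():
            raise ValueError("merge heights must be nondecreasing (Ward monotonicity)")


@dataclass
class ClusterSolution:
    """Labels at the chosen k plus the per-k diagnostics table."""

    k: int
    labels: np.ndarray
    diagnostics: pd.DataFrame
    rationale: str = ""


def ward_linkage(dm: DistanceMatrix, variant: str = "d2") -> LinkageTree:
    """Ward agglomeration of a precomputed dissimilarity matrix.

    ``variant="d2"`` (default) is the Ward.D2 convention: the Lance-Williams
    Ward update runs on squared dissimilarities and merge heights are on the
    original distance scale.  ``variant="d"`` is the Ward.D convention
    (update applied to the dissimilarities as given); it is obtained from
    the D2 recursion on the square roots, with heights squared back.
    """
    if dm.n < 2:
        raise ValueError("need at least two observations")
    if variant == "d2":
        merges = hierarchy.linkage(dm.condensed, method="ward")
    elif variant == "d":
        merges = hierarchy.linkage(np.sqrt(dm.condensed), method="ward")
        merges = merges.copy()
        merges[:, 2] = merges[:, 2] ** 2
    else:
        raise ValueError("variant must be 'd2' or 'd'")
    return LinkageTree(merges=merges, n=dm.n, variant=variant)


def cut_tree(tree: LinkageTree, k: int) -> np.ndarray:
    """Labels ``1..k`` from removing the k-1 highest merges.

    Clusters are relabeled deterministically: by decreasing size, ties by
    the smallest member index.
    """
    if not 1 <= k <= tree.n:
        raise ValueError(f"k={k} outside [1, {tree.n}]")
    if k == tree.n:
        return np.arange(1, tree.n + 1)
    raw = hierarchy.fcluster(tree.merges, t=k, criterion="maxclust")
    return _relabel(raw)


def _relabel(raw: np.ndarray) -> np.ndarray:
    order = []
    for lab in pd.unique(raw):
        members = np.flatnonzero(raw == lab)
        order.append((-len(members), members[0], lab))
    order.sort()
    mapping = {lab: i + 1 for i, (_, _, lab) in enumerate(order)}
    return np.array([mapping[x] for x in raw])


# ---------------------------------------------------------------------------
# stopping-rule indices
# ---------------------------------------------------------------------------


def _within_ss(sq: np.ndarray, members: np.ndarray) -> float:
    """Distance-based within-cluster sum of squares.

    ``(1/n_c) * sum_{i<j in c} d(i,j)^2`` — equal to the sum of squared
    deviations from the centroid when d is Euclidean.
    """
    if len(members) < 2:
        return 0.0
    block = sq[np.ix_(members, members)]
    return float((block**2).sum() / (2.0 * len(members)))


def ch_pseudo_f(dm: DistanceMatrix | np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz pseudo-F in its distance-based form.

    ``F = (B/(k-1)) / (W/(n-k))`` with W the pooled within-cluster sum of
    squared distances (1/n_c-scaled) and ``B = T - W`` from the total.
    Returns ``+inf`` for a perfect partition (W = 0).
    """
    sq = dm.square() if isinstance(dm, DistanceMatrix) else np.asarray(dm)
    labels = np.asarray(labels)
    n = sq.shape[0]
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least two clusters")
    if n <= k:
        raise ValueError("need n > k")
    w = sum(_within_ss(sq, np.flatnonzero(labels == c)) for c in uniq)
    t = float((sq**2).sum() / (2.0 * n))
    b = t - w
    if w <= 1e-12:
        return float("inf")
    return (b / (k - 1)) / (w / (n - k))


def duda_hart(
    dm: DistanceMatrix | np.ndarray,
    parent: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
) -> tuple[float, float]:
    """Duda-Hart index for one candidate split.

    ``Je(1)`` is the within sum of squares of the parent cluster, ``Je(2)``
    the sum over the two children; returns ``(Je(2)/Je(1), pseudo-T²)``
    where ``T² = (Je(1) - Je(2)) / (Je(2) / (n1 + n2 - 2))``.  A perfect
    split (``Je(2) = 0``) gives ratio 0 and infinite T².
    """
    sq = dm.square() if isinstance(dm, DistanceMatrix) else np.asarray(dm)
    parent = np.asarray(parent)
    left = np.asarray(left)
    right = np.asarray(right)
    if len(parent) < 2:
        raise ValueError("parent must have at least two members")
    if len(left) == 0 or len(right) == 0:
        raise ValueError("degenerate split: empty child")
    if len(left) + len(right) != len(parent):
        raise ValueError("children do not partition the parent")
    je1 = _within_ss(sq, parent)
    je2 = _within_ss(sq, left) + _within_ss(sq, right)
    if je1 <= 1e-12:
        return float("nan"), float("nan")
    ratio = je2 / je1
    dof = len(left) + len(right) - 2
    if je2 <= 1e-12:
        return 0.0, float("inf")
    t2 = (je1 - je2) / (je2 / dof)
    return ratio, t2


def _split_members(tree: LinkageTree, labels_k: np.ndarray, labels_k1: np.ndarray):
    """Find the cluster of the k-solution that splits at k+1."""
    for c in np.unique(labels_k):
        members = np.flatnonzero(labels_k == c)
        children = np.unique(labels_k1[members])
        if len(children) == 2:
            left = members[labels_k1[members] == children[0]]
            right = members[labels_k1[members] == children[1]]
            return members, left, right
    return None


def diagnostics_table(
    tree: LinkageTree, dm: DistanceMatrix, k_range=range(2, 11)
) -> pd.DataFrame:
    """Per-k stopping-rule table: CH pseudo-F and next-split Duda-Hart.

    For each k the Duda-Hart columns describe the split that takes the
    solution to k+1 clusters (the hierarchical convention).
    """
    ks = [k for k in k_range if 2 <= k <= tree.n - 1]
    if not ks:
        raise ValueError("empty or out-of-range k_range")
    sq = dm.square()
    rows = []
    labels_by_k = {k: cut_tree(tree, k) for k in ks}
    for k in ks:
        lab = labels_by_k[k]
        ch = ch_pseudo_f(sq, lab)
        nxt = cut_tree(tree, k + 1) if k + 1 <= tree.n else None
        ratio = t2 = np.nan
        if nxt is not None:
            found = _split_members(tree, lab, nxt)
            if found is not None:
                parent, left, right = found
                if len(parent) >= 2:
                    ratio, t2 = duda_hart(sq, parent, left, right)
        rows.append({"k": k, "ch_pseudo_f": ch, "dh_ratio": ratio, "dh_pseudo_t2": t2})
    return pd.DataFrame(rows)


def recommend_k(diag: pd.DataFrame) -> tuple[int, str]:
    """Stopping-rule recommendation from the diagnostics table.

    The recommended k is the largest CH pseudo-F among local maxima of the
    CH curve (endpoints count when they beat their single neighbour); the
    Duda-Hart ratio at the preceding split is reported as corroboration.
    A curve with no interior local maximum is flagged low-confidence.
    """
    ch = diag["ch_pseudo_f"].to_numpy()
    ks = diag["k"].to_numpy()
    cand = []
    for i in range(len(ks)):
        left_ok = i == 0 or ch[i] >= ch[i - 1]
        right_ok = i == len(ks) - 1 or ch[i] >= ch[i + 1]
        if left_ok and right_ok:
            cand.append(i)
    best = max(cand, key=lambda i: ch[i])
    k = int(ks[best])
    interior = any(0 < i < len(ks) - 1 for i in cand)
    note = f"CH pseudo-F peaks at k={k} ({ch[best]:.1f})"
    prev = diag.loc[diag["k"] == k - 1]
    if len(prev) and np.isfinite(prev["dh_ratio"].iloc[0]):
        note += (
            f"; Duda-Hart ratio {prev['dh_ratio'].iloc[0]:.3f} "
            f"(pseudo-T2 {prev['dh_pseudo_t2'].iloc[0]:.1f}) at the split to k={k}"
        )
    if not interior:
        note += "; no interior CH peak - low confidence"
    return k, note


def cluster_solution(
    tree: LinkageTree,
    dm: DistanceMatrix,
    k: int | None = None,
    k_range=range(2, 11),
) -> ClusterSolution:
    """Diagnostics plus labels; a user-supplied k is never overridden."""
    diag = diagnostics_table(tree, dm, k_range)
    rec_k, note = recommend_k(diag)
    if k is None:
        k = rec_k
        rationale = f"recommended by stopping rules: {note}"
    else:
        rationale = f"user-specified k={k}; stopping rules: {note}"
    return ClusterSolution(k=k, labels=cut_tree(tree, k), diagnostics=diag, rationale=rationale)


# ---------------------------------------------------------------------------
# cluster description
# ---------------------------------------------------------------------------


def state_distribution(panel: SequencePanel, labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster, per-age state proportions (plot-ready long table)."""
    labels = np.asarray(labels)
    if len(labels) != panel.n:
        raise ValueError("labels do not align with the panel")
    rows = []
    for c in np.unique(labels):
        members = panel.codes[labels == c]
        for t, age in enumerate(panel.ages):
            col = members[:, t]
            col = col[col >= 0]
            total = max(len(col), 1)
            for s, tok in enumerate(panel.alphabet):
                rows.append(
                    {
                        "cluster": int(c),
                        "age": int(age),
                        "state": tok,
                        "proportion": float((col == s).sum() / total),
                    }
                )
    return pd.DataFrame(rows)


def plot_state_distribution(dist: pd.DataFrame, path=None):
    """Stacked-area plot of the per-cluster state distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    clusters = sorted(dist["cluster"].unique())
    states = list(dict.fromkeys(dist["state"]))
    fig, axes = plt.subplots(
        1, len(clusters), figsize=(3 * len(clusters), 3), sharey=True
    )
    if len(clusters) == 1:
        axes = [axes]
    for ax, c in zip(axes, clusters):
        sub = dist[dist["cluster"] == c].pivot(
            index="age", columns="state", values="proportion"
        )[states]
        ax.stackplot(sub.index, sub.T.to_numpy(), labels=states)
        ax.set_title(f"cluster {c}")
        ax.set_xlabel("age")
    axes[0].set_ylabel("proportion")
    axes[-1].legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
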