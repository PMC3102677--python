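"""Hierarchical clustering for heat-map export and term enrichment.

Clustering is agglomerative over a protein x sample RIA matrix that may
contain missing values; distances are computed pairwise-complete (only
positions present in both rows).  The default configuration is
Pearson-correlation distance (1 - r) with average linkage.  Merging is
deterministic: ties break on the lowest cluster index pair.

Enrichment is an upper-tail hypergeometric test per term with
Benjamini-Hochberg adjustment across the tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterResult",
    "pairwise_distances",
    "hcluster",
    "enrich",
    "bh_adjust",
    "heatmap_matrix",
    "render_heatmap",
    "HEATMAP_ORDER",
]

#: four-column layout: forward mixed, reverse mixed, resistant control,
#: parental control
HEATMAP_ORDER = ("mix_fwd", "mix_rev", "ctrl_cddp", "ctrl_hela")


@dataclass
class ClusterResult:
    """Agglomeration result.

    ``merges`` has one row per step: (cluster_a, cluster_b, height,
    size); original rows are clusters 0..n-1 and step k creates cluster
    n+k, scipy-linkage style.  ``order`` is the dendrogram leaf order.
    """

    order: np.ndarray
    merges: np.ndarray
    metric: str
    linkage: str


def pairwise_distances(matrix: np.ndarray, metric: str = "pearson") -> np.ndarray:
    """Square distance matrix with pairwise-complete missing handling.

    ``pearson`` gives 1 - r over the positions both rows share; rows
    sharing fewer than two positions, or with zero variance on the
    shared positions, get the neutral distance 1.  ``euclidean`` is
    rescaled by the fraction of shared positions.
    """
    x = np.asarray(matrix, dtype=float)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~(np.isnan(x[i]) | np.isnan(x[j]))
            xi, xj = x[i, both], x[j, both]
            if metric == "pearson":
                if xi.size < 2 or xi.std() == 0 or xj.std() == 0:
                    dist = 1.0
                else:
                    dist = 1.0 - float(np.corrcoef(xi, xj)[0, 1])
            elif metric == "euclidean":
                if xi.size == 0:
                    dist = np.nan
                else:
                    dist = float(np.sqrt(np.sum((xi - xj) ** 2) * x.shape[1] / xi.size))
            else:
                raise ValueError(f"unknown metric: {metric!r}")
            d[i, j] = d[j, i] = dist
    return d


def hcluster(
    matrix,
    metric: str = "pearson",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of matrix rows.

    Requires at least two rows and at least two non-missing values per
    row.  Supported linkages: average (UPGMA), single, complete.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    bad = np.flatnonzero((~np.isnan(x)).sum(axis=1) < 2)
    if bad.size:
        raise ValueError(f"rows with fewer than two non-missing values: {bad.tolist()}")
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unknown linkage: {linkage!r}")

    n = x.shape[0]
    d = pairwise_distances(x, metric).astype(float)
    np.fill_diagonal(d, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=int)
    ids = np.arange(n)  # current cluster id at each slot
    merges = np.zeros((n - 1, 4))

    work = d.copy()
    for step in range(n - 1):
        masked = np.where(np.outer(active, active), work, np.inf)
        np.fill_diagonal(masked, np.inf)
        flat = int(np.argmin(masked))  # row-major: lowest row, then column
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        height = masked[i, j]
        merges[step] = (ids[i], ids[j], height, sizes[i] + sizes[j])

        # Lance-Williams update into slot i
        if linkage == "average":
            new = (sizes[i] * work[i] + sizes[j] * work[j]) / (sizes[i] + sizes[j])
        elif linkage == "single":
            new = np.minimum(work[i], work[j])
        else:
            new = np.maximum(work[i], work[j])
        work[i, :] = new
        work[:, i] = new
        work[i, i] = np.inf
        active[j] = False
        sizes[i] += sizes[j]
        ids[i] = n + step

    order = _leaf_order(merges, n)
    return ClusterResult(order=order, merges=merges, metric=metric, linkage=linkage)


def _leaf_order(merges: np.ndarray, n: int) -> np.ndarray:
    children: dict[int, tuple[int, int]] = {
        n + k: (int(merges[k, 0]), int(merges[k, 1])) for k in range(len(merges))
    }
    out: list[int] = []
    stack = [n + len(merges) - 1]
    while stack:
        node = stack.pop()
        if node < n:
            out.append(node)
        else:
            a, b = children[node]
            stack.append(b)
            stack.append(a)
    return np.array(out)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, mapped
    back to the input order and capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich(
    target: set,
    annotation: dict[str, set],
    universe: set,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of ``target`` within ``universe``.

    Per term with K annotated members in the universe, the upper-tail
    probability P(X >= k) of observing k annotated members among the
    n = \\|target\\| draws.  Terms with no hit in the target are skipped.
    Benjamini-Hochberg q-values are computed across the tested terms;
    results are sorted by (q, p, term).

    Columns: term, k, n, K, N, p, q, significant (q <= alpha).
    """
    if not universe:
        raise ValueError("empty universe")
    target = set(target)
    if not target <= universe:
        raise ValueError("target must be a subset of the universe")
    N = len(universe)
    n = len(target)
    rows = []
    for term in sorted(annotation):
        members = set(annotation[term]) & universe
        k = len(members & target)
        if k == 0:
            continue
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "p": min(p, 1.0)})
    if not rows:
        return pd.DataFrame(columns=["term", "k", "n", "K", "N", "p", "q", "significant"])
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] <= alpha
    return out.sort_values(["q", "p", "term"]).reset_index(drop=True)


def heatmap_matrix(
    protein_table: pd.DataFrame,
    by_replicate: bool = False,
    sample_order: tuple[str, ...] = HEATMAP_ORDER,
) -> pd.DataFrame:
    """Protein x sample RIA matrix in the fixed display layout.

    Four columns (per-sample-type replicate means) by default, or the
    twelve per-biological-replicate columns with ``by_replicate``.
    Raw (unflipped) orientation is kept for display.
    """
    df = protein_table
    if by_replicate:
        wide = df.pivot_table(
            index="accession", columns=["sample_type", "bio_rep"], values="ria", aggfunc="mean"
        )
        cols = [
            (s, b)
            for s in sample_order
            for b in sorted({c[1] for c in wide.columns if c[0] == s})
        ]
        wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols))
        wide.columns = [f"{s}_b{b}" for s, b in wide.columns]
    else:
        wide = df.pivot_table(index="accession", columns="sample_type", values="ria", aggfunc="mean")
        wide = wide.reindex(columns=list(sample_order))
    return wide


def render_heatmap(matrix: pd.DataFrame, path, order: np.ndarray | None = None) -> None:
    """Write a simple heat-map image of the (optionally reordered) matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = matrix.iloc[order] if order is not None else matrix
    fig, ax = plt.subplots(figsize=(4, max(4, len(m) / 40)))
    im = ax.imshow(m.to_numpy(float), aspect="auto", cmap="RdYlGn_r", vmin=0, vmax=1)
    ax.set_xticks(range(m.shape[1]))
    ax.set_xticklabels(m.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="RIA")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
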