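"""Ordination and clustering of CLR-transformed samples.

The PCA biplot of a CLR matrix is the standard exploratory view of
compositional sequencing data: feature-wise centering followed by a
singular value decomposition, with sample scores and feature loadings
plotted together.  "Form" scaling (the default) puts the singular values
on the scores so inter-sample distances in the plot approximate Aitchison
distances; "covariance" scaling puts them on the loadings instead.

Hierarchical clustering uses Lance-Williams agglomeration with
deterministic tie-breaking (the candidate pair with the smallest
(row, column) cluster indices wins), so dendrograms are reproducible
across platforms.  Ward linkage follows the squared-distance (Ward.D2)
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib import colormaps, colors as mcolors
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import CountTable, MetadataTable
from .transform import ClrMatrix, clr

__all__ = [
    "PcaResult",
    "pca_clr",
    "CLRPCA",
    "colour_by_metadata",
    "metadata_histogram",
    "Dendrogram",
    "hierarchical_cluster",
    "sample_distance_matrix",
]

LINKAGES = ("single", "complete", "average", "ward")
DISTANCES = ("aitchison", "euclidean_clr", "jaccard_presence")

MISSING_COLOUR = "#bdbdbd"


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    """Scores, loadings and variance decomposition of a CLR-PCA.

    ``scores`` is samples x components, ``loadings`` features x
    components; ``variance_explained`` fractions sum to one over the
    retained components.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    singular_values: np.ndarray
    variance_explained: np.ndarray
    scaling: str = "form"

    @property
    def component_names(self) -> list[str]:
        return list(self.scores.columns)

    def axis_label(self, i: int) -> str:
        return f"PC{i + 1} ({self.variance_explained[i] * 100:.1f}% of variance)"


def pca_clr(clr_data, scaling: str = "form") -> PcaResult:
    """PCA of a CLR matrix via SVD of the feature-centered data.

    Each feature's mean across samples is subtracted, the centered
    samples x features matrix is decomposed as ``U S V^T``, and
    ``variance_explained_i = s_i^2 / sum s^2``.  With ``scaling="form"``
    scores are ``U S`` and loadings ``V``; with ``scaling="covariance"``
    scores are ``U`` and loadings ``V S``.  Singular-vector signs are fixed
    by making the largest-magnitude element of each loading vector
    positive, so results do not depend on the linear-algebra backend.
    """
    if scaling not in ("form", "covariance"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if isinstance(clr_data, ClrMatrix):
        values = clr_data.values
    elif isinstance(clr_data, pd.DataFrame):
        values = clr_data
    else:
        arr = np.asarray(clr_data, dtype=float)
        values = pd.DataFrame(
            arr,
            index=[f"F{i}" for i in range(arr.shape[0])],
            columns=[f"S{j}" for j in range(arr.shape[1])],
        )
    n_feat, n_samp = values.shape
    if n_samp < 2 or n_feat < 2:
        raise ValueError("PCA needs at least two samples and two features")

    x = values.to_numpy().T  # samples x features
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt.T
    # sign convention: largest-|.| loading element positive per component
    flip = np.sign(v[np.abs(v).argmax(axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    u = u * flip
    v = v * flip

    total = float((s**2).sum())
    var_exp = s**2 / total if total > 0 else np.zeros_like(s)
    if scaling == "form":
        scores, loadings = u * s, v
    else:
        scores, loadings = u, v * s
    comp = [f"PC{i + 1}" for i in range(s.size)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=values.columns, columns=comp),
        loadings=pd.DataFrame(loadings, index=values.index, columns=comp),
        singular_values=s,
        variance_explained=var_exp,
        scaling=scaling,
    )


class CLRPCA(TransformerMixin, BaseEstimator):
    """PCA for CLR data as a sklearn transformer (X = samples x features).

    Fitted attributes follow sklearn naming: ``components_`` (components x
    features), ``singular_values_``, ``explained_variance_ratio_``,
    ``mean_``.  ``transform`` returns form- or covariance-scaled scores
    according to ``scaling``.
    """

    def __init__(self, scaling: str = "form"):
        self.scaling = scaling

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        X = np.asarray(X, dtype=float)
        res = pca_clr(pd.DataFrame(X.T), scaling=self.scaling)
        self.mean_ = X.mean(axis=0)
        self.components_ = res.loadings.to_numpy().T
        self.singular_values_ = res.singular_values
        self.explained_variance_ratio_ = res.variance_explained
        self.n_features_in_ = X.shape[1]
        return res.scores.to_numpy()

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        scores = (X - self.mean_) @ self.components_.T
        if self.scaling == "covariance":
            with np.errstate(divide="ignore", invalid="ignore"):
                scores = np.where(
                    self.singular_values_ > 0, scores / self.singular_values_, 0.0
                )
        return scores


# ---------------------------------------------------------------------------
# metadata colouring and histograms
# ---------------------------------------------------------------------------

def colour_by_metadata(
    sample_ids,
    metadata: MetadataTable,
    variable: str,
    palette: str = "tab10",
    gradient: str = "viridis",
) -> dict[str, str]:
    """Hex colour per sample from a metadata variable.

    Discrete variables map levels to a categorical palette in order of
    first appearance; continuous variables map linearly onto a gradient
    over the observed range; missing values get a reserved grey.
    """
    if isinstance(sample_ids, PcaResult):
        sample_ids = list(sample_ids.scores.index)
    col = metadata.column(variable).reindex(list(sample_ids))
    kind = metadata.kind(variable)
    out: dict[str, str] = {}
    if col.dropna().empty:
        import warnings

        warnings.warn(
            f"variable {variable!r} has no observed values; all samples "
            "take the missing colour",
            UserWarning,
            stacklevel=2,
        )
        return {s: MISSING_COLOUR for s in sample_ids}
    if kind == "discrete":
        cmap = colormaps[palette]
        levels = list(dict.fromkeys(v for v in col if pd.notna(v)))
        level_colour = {
            lev: mcolors.to_hex(cmap(i % cmap.N)) for i, lev in enumerate(levels)
        }
        for s, v in col.items():
            out[s] = MISSING_COLOUR if pd.isna(v) else level_colour[v]
    else:
        numeric = pd.to_numeric(col, errors="coerce")
        lo, hi = numeric.min(), numeric.max()
        span = hi - lo if hi > lo else 1.0
        cmap = colormaps[gradient]
        for s, v in numeric.items():
            out[s] = (
                MISSING_COLOUR
                if pd.isna(v)
                else mcolors.to_hex(cmap(float((v - lo) / span)))
            )
    return out


def metadata_histogram(
    metadata: MetadataTable, variable: str, bins: int = 10
) -> pd.DataFrame:
    """Frequency table for one metadata variable.

    Discrete variables yield level counts (first-appearance order);
    continuous ones counts in ``bins`` equal-width bins over the observed
    range.  Missing values are counted in a separate ``missing`` row.
    """
    col = metadata.column(variable)
    kind = metadata.kind(variable)
    n_missing = int(col.isna().sum())
    rows: list[tuple[str, int]] = []
    observed = col.dropna()
    if kind == "discrete":
        levels = list(dict.fromkeys(observed))
        for lev in levels:
            rows.append((str(lev), int((observed == lev).sum())))
    elif not observed.empty:
        numeric = pd.to_numeric(observed, errors="coerce").dropna()
        lo, hi = float(numeric.min()), float(numeric.max())
        if lo == hi:
            rows.append((f"[{lo:g}, {hi:g}]", int(numeric.size)))
        else:
            counts, edges = np.histogram(numeric, bins=bins, range=(lo, hi))
            for c, (a, b) in zip(counts, zip(edges[:-1], edges[1:])):
                rows.append((f"[{a:g}, {b:g})", int(c)))
    rows.append(("missing", n_missing))
    return pd.DataFrame(rows, columns=["level", "count"])


# ---------------------------------------------------------------------------
# distances and hierarchical clustering
# ---------------------------------------------------------------------------

def sample_distance_matrix(data, metric: str = "aitchison") -> pd.DataFrame:
    """Pairwise sample distances.

    ``aitchison`` and ``euclidean_clr`` are identical by construction
    (Aitchison distance *is* the Euclidean distance between CLR vectors);
    ``aitchison`` additionally accepts a strictly positive features x
    samples matrix of zero-handled counts/compositions and CLR-transforms
    it first.  ``jaccard_presence`` operates on presence/absence of raw
    counts in a :class:`CountTable`.
    """
    if metric not in DISTANCES:
        raise ValueError(f"unknown metric {metric!r}; choose from {DISTANCES}")
    if metric == "jaccard_presence":
        if isinstance(data, CountTable):
            mat = data.counts.to_numpy() > 0
            ids = data.sample_ids
        elif isinstance(data, pd.DataFrame):
            mat = data.to_numpy() > 0
            ids = list(data.columns)
        else:
            raise TypeError("jaccard_presence needs a CountTable or DataFrame")
        d = pdist(mat.T, metric="jaccard")
        return pd.DataFrame(squareform(d), index=ids, columns=ids)

    if isinstance(data, ClrMatrix):
        vals = data.values.to_numpy()
        ids = data.sample_ids
    elif isinstance(data, CountTable):
        raise ValueError(
            "aitchison distance needs zero-handled data; apply CZM or a "
            "pseudocount, or pass a ClrMatrix"
        )
    elif isinstance(data, pd.DataFrame):
        arr = data.to_numpy(dtype=float)
        ids = list(data.columns)
        if metric == "aitchison":
            if (arr <= 0).any():
                raise ValueError(
                    "aitchison distance requires strictly positive values; "
                    "apply zero handling first"
                )
            vals = clr(arr, axis=0)
        else:
            vals = arr
    else:
        raise TypeError("expected ClrMatrix, CountTable or DataFrame")
    d = pdist(vals.T, metric="euclidean")
    return pd.DataFrame(squareform(d), index=ids, columns=ids)


@dataclass
class Dendrogram:
    """Agglomeration result: n-1 merges over n leaves.

    ``merges`` lists ``(node_i, node_j, height, size)`` with leaves
    numbered ``0..n-1`` and internal nodes ``n..2n-2`` in merge order.
    """

    merges: list[tuple[int, int, float, int]]
    leaf_ids: list[str]
    linkage: str
    distance: str = ""

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h, _ in self.merges]

    def to_scipy_linkage(self) -> np.ndarray:
        """The merge sequence as a scipy-style linkage matrix."""
        return np.array(
            [[i, j, h, sz] for i, j, h, sz in self.merges], dtype=float
        )

    def leaf_order(self) -> list[str]:
        """Leaves in dendrogram display order."""
        n = len(self.leaf_ids)
        children = {
            n + k: (i, j) for k, (i, j, _, _) in enumerate(self.merges)
        }

        def walk(node: int) -> list[int]:
            if node < n:
                return [node]
            i, j = children[node]
            return walk(i) + walk(j)

        root = n + len(self.merges) - 1
        return [self.leaf_ids[i] for i in walk(root)]

    def to_newick(self) -> str:
        """Newick string with merge heights as node heights.

        Branch lengths are the height differences between a node and its
        parent merge, so ultrametric inputs render with aligned leaves.
        """
        n = len(self.leaf_ids)
        height = {i: 0.0 for i in range(n)}
        children = {}
        for k, (i, j, h, _) in enumerate(self.merges):
            node = n + k
            height[node] = h
            children[node] = (i, j)

        def walk(node: int, parent_h: float) -> str:
            bl = parent_h - height[node]
            if node < n:
                return f"{_newick_escape(self.leaf_ids[node])}:{bl:.10g}"
            i, j = children[node]
            h = height[node]
            return f"({walk(i, h)},{walk(j, h)}):{bl:.10g}"

        root = n + len(self.merges) - 1
        i, j = children[root] if self.merges else (0, 0)
        if not self.merges:
            return f"{_newick_escape(self.leaf_ids[0])};"
        h = height[root]
        return f"({walk(i, h)},{walk(j, h)});"


def _newick_escape(label: str) -> str:
    if any(c in label for c in "(),:; \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def hierarchical_cluster(
    d: pd.DataFrame | np.ndarray,
    linkage: str = "average",
    leaf_ids: list[str] | None = None,
    distance_name: str = "",
) -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    Lance-Williams updates for single (min), complete (max), average
    (size-weighted mean) and Ward (Ward.D2, squared-distance) linkage.
    At every step the closest pair is merged; exact ties are broken by the
    smallest (row, column) index pair, so the merge sequence is fully
    deterministic.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if isinstance(d, pd.DataFrame):
        if leaf_ids is None:
            leaf_ids = [str(c) for c in d.columns]
        dm = d.to_numpy(dtype=float)
    else:
        dm = np.asarray(d, dtype=float)
    n = dm.shape[0]
    if dm.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if leaf_ids is None:
        leaf_ids = [f"S{i}" for i in range(n)]
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (dm < 0).any():
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(dm), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 2:
        raise ValueError("need at least two observations to cluster")

    work = dm.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    active = list(range(n))  # positions into `work`
    node_of = list(range(n))  # cluster node id at each active position
    sizes = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_node = n

    for _ in range(n - 1):
        sub = work[np.ix_(active, active)]
        # smallest distance; ties -> smallest (row, col) position pair
        flat = np.argmin(sub)
        r, c = divmod(int(flat), len(active))
        if r > c:
            r, c = c, r
        pi, pj = active[r], active[c]
        ni, nj = node_of[pi], node_of[pj]
        h = float(work[pi, pj])
        si, sj = sizes[ni], sizes[nj]
        new_size = si + sj

        # Lance-Williams update against every other active cluster
        for pk in active:
            if pk in (pi, pj):
                continue
            dik, djk = work[pi, pk], work[pj, pk]
            if linkage == "single":
                dnew = min(dik, djk)
            elif linkage == "complete":
                dnew = max(dik, djk)
            elif linkage == "average":
                dnew = (si * dik + sj * djk) / new_size
            else:  # ward (D2)
                sk = sizes[node_of[pk]]
                dnew = np.sqrt(
                    ((si + sk) * dik**2 + (sj + sk) * djk**2 - sk * h**2)
                    / (new_size + sk)
                )
            work[pi, pk] = work[pk, pi] = dnew

        merges.append((ni, nj, h, new_size))
        node_of[pi] = next_node
        sizes[next_node] = new_size
        next_node += 1
        active.remove(pj)

    return Dendrogram(
        merges=merges,
        leaf_ids=[str(s) for s in leaf_ids],
        linkage=linkage,
        distance=distance_name,
    )
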