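"""Age-band symptom profiles: heatmap matrix, dendrogram, PCA, k-means.

The cohort is grouped into the eight admission age bands used throughout
the analysis (18-24, then decades to >= 85). For each band the within-band
prevalence of the eleven presenting symptoms is computed; the heatmap view
standardises each band row (mean 0, SD 1 across symptoms), expressing how
common each symptom is relative to the other symptoms within that band.

Band profiles are then related by (a) agglomerative hierarchical
clustering on Euclidean distances between standardised rows, (b) PCA via
SVD of the centred matrix, and (c) k-means (Lloyd's algorithm with
k-means++ seeding and restarts) on the leading principal-component scores,
with the number of clusters chosen by mean silhouette score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .base import BaseEstimator
from .errors import ValidationError
from .scores import SYMPTOMS

#: (low, high, label) inclusive age bands; the open-ended last band is
#: capped at 100 to match the synthetic generator's truncation.
AGE_BANDS = (
    (18, 24, "18-24"),
    (25, 34, "25-34"),
    (35, 44, "35-44"),
    (45, 54, "45-54"),
    (55, 64, "55-64"),
    (65, 74, "65-74"),
    (75, 84, "75-84"),
    (85, 100, "85+"),
)

BAND_LABELS = tuple(b[2] for b in AGE_BANDS)


def age_band_index(age_years) -> np.ndarray:
    """Map ages to band indices 0..7 (>= 85 all map to the last band)."""
    age = np.asarray(age_years, dtype=float)
    edges = np.array([b[0] for b in AGE_BANDS[1:]], dtype=float)
    if np.any(age < 18):
        raise ValidationError("ages below 18 have no band")
    return np.searchsorted(edges, age, side="right")


@dataclass(frozen=True)
class AgeBandProfile:
    """Band x symptom prevalence matrix with its row-standardised view."""

    bands: tuple
    symptoms: tuple
    freq: pd.DataFrame
    zmat: pd.DataFrame
    band_counts: np.ndarray
    constant_rows: tuple = field(default_factory=tuple)
    empty_rows: tuple = field(default_factory=tuple)

    @property
    def usable_bands(self) -> list:
        """Bands that can enter clustering (non-empty, non-constant)."""
        drop = set(self.constant_rows) | set(self.empty_rows)
        return [b for b in self.bands if b not in drop]

    def usable_z(self) -> pd.DataFrame:
        return self.zmat.loc[self.usable_bands]


def band_frequency_matrix(cohort: pd.DataFrame) -> AgeBandProfile:
    """Within-band symptom prevalences (8 x 11) and their z-scored rows.

    Empty bands and bands with a constant symptom profile are flagged: they
    stay in ``freq`` (NaN for empty bands) but are excluded from
    ``usable_bands`` so clustering never sees undefined rows.
    """
    idx = age_band_index(cohort["age_years"])
    cols = []
    for s in SYMPTOMS:
        name = s if s in cohort.columns else f"sym_{s}"
        if name not in cohort.columns:
            raise ValidationError(f"missing symptom column for {s!r}")
        cols.append(cohort[name].to_numpy(dtype=float))
    mat = np.column_stack(cols)

    freq = np.full((len(AGE_BANDS), len(SYMPTOMS)), np.nan)
    counts = np.zeros(len(AGE_BANDS), dtype=int)
    for b in range(len(AGE_BANDS)):
        sel = idx == b
        counts[b] = int(sel.sum())
        if counts[b]:
            freq[b] = mat[sel].mean(axis=0)

    empty = tuple(BAND_LABELS[b] for b in range(len(AGE_BANDS)) if counts[b] == 0)
    filled = counts > 0
    sd = np.full(len(AGE_BANDS), np.nan)
    mean = np.full(len(AGE_BANDS), np.nan)
    sd[filled] = freq[filled].std(axis=1, ddof=1)
    mean[filled] = freq[filled].mean(axis=1)
    constant = tuple(
        BAND_LABELS[b]
        for b in range(len(AGE_BANDS))
        if counts[b] > 0 and sd[b] == 0
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (freq - mean[:, None]) / sd[:, None]

    freq_df = pd.DataFrame(freq, index=list(BAND_LABELS), columns=list(SYMPTOMS))
    z_df = pd.DataFrame(z, index=list(BAND_LABELS), columns=list(SYMPTOMS))
    return AgeBandProfile(
        bands=BAND_LABELS,
        symptoms=tuple(SYMPTOMS),
        freq=freq_df,
        zmat=z_df,
        band_counts=counts,
        constant_rows=constant,
        empty_rows=empty,
    )


# ---------------------------------------------------------------------------
# Agglomerative hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree.

    ``merges`` lists (cluster_a, cluster_b, height, size): original points
    are clusters 0..n-1, the merge in row k creates cluster n+k (the scipy
    linkage convention). ``tree`` is the equivalent nested dict.
    """

    labels: tuple
    merges: np.ndarray
    linkage_method: str

    @property
    def tree(self) -> dict:
        n = len(self.labels)
        nodes = {i: {"label": self.labels[i]} for i in range(n)}
        for k, (a, b, h, size) in enumerate(self.merges):
            nodes[n + k] = {
                "children": [nodes[int(a)], nodes[int(b)]],
                "height": float(h),
                "size": int(size),
            }
        return nodes[n + len(self.merges) - 1] if len(self.merges) else nodes[0]

    def cut(self, k: int) -> np.ndarray:
        """Labels 0..k-1 from cutting the tree into k clusters."""
        n = len(self.labels)
        if not 1 <= k <= n:
            raise ValidationError(f"k must be in [1, {n}]")
        members = {i: [i] for i in range(n)}
        active = set(range(n))
        for m, (a, b, _, _) in enumerate(self.merges[: n - k]):
            members[n + m] = members.pop(int(a)) + members.pop(int(b))
            active.discard(int(a))
            active.discard(int(b))
            active.add(n + m)
        out = np.empty(n, dtype=int)
        for lab, cid in enumerate(sorted(active)):
            out[members[cid]] = lab
        return out


_LINKAGES = ("complete", "single", "average", "ward")


def hierarchical_clustering(
    data, linkage: str = "complete", labels: Optional[Sequence[str]] = None
) -> Dendrogram:
    """Agglomerative clustering of rows with Euclidean distances.

    Accepts an :class:`AgeBandProfile` (clusters its usable z-scored rows)
    or any (n, p) array. Ties in the merge queue are broken toward the
    lowest index pair, making the tree deterministic.
    """
    if isinstance(data, AgeBandProfile):
        frame = data.usable_z()
        labels = tuple(frame.index)
        x = frame.to_numpy(dtype=float)
    else:
        x = np.asarray(data, dtype=float)
        labels = tuple(labels) if labels is not None else tuple(
            str(i) for i in range(len(x))
        )
    if x.ndim != 2 or len(x) < 2:
        raise ValidationError("need at least two rows to cluster")
    if linkage not in _LINKAGES:
        raise ValidationError(f"linkage must be one of {_LINKAGES}")

    n = len(x)
    # active cluster id -> (member point indices, centroid/size for ward)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    point_dist = np.sqrt(
        ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    )

    def cluster_distance(ca: int, cb: int) -> float:
        pa, pb = members[ca], members[cb]
        block = point_dist[np.ix_(pa, pb)]
        if linkage == "complete":
            return float(block.max())
        if linkage == "single":
            return float(block.min())
        if linkage == "average":
            return float(block.mean())
        # ward: sqrt of the increase in within-cluster sum of squares
        ma, mb = x[pa].mean(axis=0), x[pb].mean(axis=0)
        na, nb = len(pa), len(pb)
        return float(
            np.sqrt(2.0 * na * nb / (na + nb) * ((ma - mb) ** 2).sum())
        )

    merges = []
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for i_pos in range(len(active)):
            for j_pos in range(i_pos + 1, len(active)):
                ca, cb = active[i_pos], active[j_pos]
                d = cluster_distance(ca, cb)
                if best is None or d < best[0] - 1e-12:
                    best = (d, ca, cb)
        d, ca, cb = best
        merges.append([ca, cb, d, sizes[ca] + sizes[cb]])
        members[next_id] = members[ca] + members[cb]
        sizes[next_id] = sizes[ca] + sizes[cb]
        active = [c for c in active if c not in (ca, cb)] + [next_id]
        next_id += 1
    return Dendrogram(
        labels=tuple(labels), merges=np.array(merges), linkage_method=linkage
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PcaResult:
    """Loadings (components x symptoms), row scores, explained variance."""

    components: np.ndarray
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    row_labels: tuple
    column_labels: tuple

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=list(self.row_labels), columns=cols)


def pca(data, center: bool = True, use_z: bool = True) -> PcaResult:
    """PCA by SVD of the (optionally centred) matrix.

    For an :class:`AgeBandProfile`, rows are usable bands and columns are
    symptoms; ``use_z`` selects the row-standardised view (the heatmap
    semantics) over raw prevalences. Component signs are fixed so each
    loading's largest-magnitude entry is positive.
    """
    if isinstance(data, AgeBandProfile):
        frame = data.usable_z() if use_z else data.freq.loc[data.usable_bands]
        x = frame.to_numpy(dtype=float)
        row_labels = tuple(frame.index)
        col_labels = tuple(frame.columns)
    else:
        x = np.asarray(data, dtype=float)
        row_labels = tuple(str(i) for i in range(len(x)))
        col_labels = tuple(str(j) for j in range(x.shape[1]))
    if x.ndim != 2 or len(x) < 2:
        raise ValidationError("need at least two rows for PCA")
    mean = x.mean(axis=0) if center else np.zeros(x.shape[1])
    xc = x - mean
    if not np.any(xc):
        raise ValidationError("matrix has rank 0 after centring")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest |loading| entry of each component positive
    for k in range(len(s)):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    scores = u * s
    var = s**2
    return PcaResult(
        components=vt,
        scores=scores,
        explained_variance_ratio=var / var.sum(),
        mean=mean,
        row_labels=row_labels,
        column_labels=col_labels,
    )


class PrincipalComponents(BaseEstimator):
    """Transformer facade over :func:`pca` (fit stores loadings, transform projects)."""

    def __init__(self, n_components: Optional[int] = None, center: bool = True):
        self.n_components = n_components
        self.center = center

    def fit(self, X, y=None):
        res = pca(X, center=self.center)
        k = self.n_components or len(res.explained_variance_ratio)
        self.components_ = res.components[:k]
        self.mean_ = res.mean
        self.explained_variance_ratio_ = res.explained_variance_ratio[:k]
        self.result_ = res
        return self

    def transform(self, X) -> np.ndarray:
        self._check_fitted("components_")
        x = np.asarray(X, dtype=float)
        return (x - self.mean_) @ self.components_.T

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self.result_.scores[:, : self.components_.shape[0]]


# ---------------------------------------------------------------------------
# k-means with silhouette-based k selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterResult:
    """Chosen k, assignments, centroids, inertia and silhouette summary."""

    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float
    silhouette_values: np.ndarray
    mean_silhouette: float
    per_k_silhouette: dict
    row_labels: tuple

    def assignment_map(self) -> dict:
        return {lab: int(c) for lab, c in zip(self.row_labels, self.assignments)}


def _kmeans_pp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: iteratively sample centres far from existing ones."""
    n = len(x)
    centers = [x[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            ((x[:, None, :] - np.array(centers)[None, :, :]) ** 2).sum(axis=2),
            axis=1,
        )
        total = d2.sum()
        if total <= 0:
            centers.append(x[rng.integers(n)])
            continue
        centers.append(x[rng.choice(n, p=d2 / total)])
    return np.array(centers)


def _lloyd(x: np.ndarray, centers: np.ndarray, max_iter: int = 300):
    """Lloyd iterations until assignments stabilise; returns (labels, centers, inertia)."""
    k = len(centers)
    labels = None
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        for c in range(k):  # re-seed empty clusters with the farthest point
            if not np.any(new_labels == c):
                new_labels[d2.min(axis=1).argmax()] = c
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        centers = np.array(
            [x[labels == c].mean(axis=0) for c in range(k)]
        )
    inertia = float(((x - centers[labels]) ** 2).sum())
    return labels, centers, inertia


def kmeans(
    x: np.ndarray, k: int, n_restarts: int = 50, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-restarts k-means; deterministic for a given seed."""
    x = np.asarray(x, dtype=float)
    if k > len(x):
        raise ValidationError(f"k={k} exceeds the number of rows ({len(x)})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        centers0 = _kmeans_pp_init(x, k, rng)
        labels, centers, inertia = _lloyd(x, centers0)
        if best is None or inertia < best[2] - 1e-12:
            best = (labels, centers, inertia)
    return best


def silhouette_values(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette (b - a)/max(a, b); singleton clusters score 0."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("silhouette requires at least two clusters")
    if len(uniq) >= len(x):
        raise ValidationError("silhouette undefined when every point is its own cluster")
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    out = np.zeros(len(x))
    for i in range(len(x)):
        own = labels == labels[i]
        if own.sum() == 1:
            out[i] = 0.0
            continue
        a = dist[i, own & (np.arange(len(x)) != i)].mean()
        b = min(dist[i, labels == c].mean() for c in uniq if c != labels[i])
        out[i] = (b - a) / max(a, b)
    return out


def kmeans_with_silhouette(
    data,
    k_range: Sequence[int] = (2, 3, 4, 5, 6),
    n_restarts: int = 50,
    seed: int = 0,
) -> ClusterResult:
    """Cluster rows with k-means, choosing k by mean silhouette.

    Accepts a (rows x PC) score matrix, a DataFrame, or a
    :class:`PcaResult` (uses its scores). k values equal to or above the
    number of rows are skipped (the silhouette is undefined there); ties in
    mean silhouette resolve toward the smaller k.
    """
    if isinstance(data, PcaResult):
        x = data.scores
        row_labels = data.row_labels
    elif isinstance(data, pd.DataFrame):
        x = data.to_numpy(dtype=float)
        row_labels = tuple(data.index)
    else:
        x = np.asarray(data, dtype=float)
        row_labels = tuple(str(i) for i in range(len(x)))
    feasible = [k for k in sorted(set(int(k) for k in k_range)) if 2 <= k < len(x)]
    if not feasible:
        raise ValidationError(
            f"no feasible k in {list(k_range)} for {len(x)} rows"
        )
    per_k = {}
    fits = {}
    for k in feasible:
        labels, centers, inertia = kmeans(x, k, n_restarts=n_restarts, seed=seed)
        sil = silhouette_values(x, labels)
        per_k[k] = float(sil.mean())
        fits[k] = (labels, centers, inertia, sil)
    best_k = max(feasible, key=lambda k: (per_k[k], -k))
    labels, centers, inertia, sil = fits[best_k]
    return ClusterResult(
        k=best_k,
        assignments=labels,
        centroids=centers,
        inertia=inertia,
        silhouette_values=sil,
        mean_silhouette=float(sil.mean()),
        per_k_silhouette=per_k,
        row_labels=row_labels,
    )


class KMeansSilhouette(BaseEstimator):
    """Estimator facade: fit selects k by silhouette and stores the clustering."""

    def __init__(
        self,
        k_range: Sequence[int] = (2, 3, 4, 5, 6),
        n_restarts: int = 50,
        seed: int = 0,
    ):
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.seed = seed

    def fit(self, X, y=None):
        res = kmeans_with_silhouette(
            X, k_range=self.k_range, n_restarts=self.n_restarts, seed=self.seed
        )
        self.k_ = res.k
        self.labels_ = res.assignments
        self.cluster_centers_ = res.centroids
        self.inertia_ = res.inertia
        self.silhouette_ = res.mean_silhouette
        self.result_ = res
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
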