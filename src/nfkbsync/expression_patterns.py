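"""Expression time-course processing: deregulation calls, standardization,
fuzzy c-means clustering and target-set enrichment.

The stages mirror a standard microarray time-course workflow: an
optional detection-p filter, deregulation calls on |log2 fold change|
relative to the t = 0 sample, per-gene standardization of the log2
profile (so clustering sees shapes, not levels), soft c-means clustering
with fuzzifier m, membership "cores" at 0.5, and Fisher-exact enrichment
of cluster cores against a target gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "ExpressionMatrix", "ClusterResult", "filter_detected", "call_deregulated",
    "standardize", "fuzzy_cmeans", "select_cluster_count", "extract_cores",
    "overlap_coefficient", "enrichment_test",
]


@dataclass
class ExpressionMatrix:
    """Genes × timepoints expression values (intensities or fold changes)."""

    values: pd.DataFrame                       # index gene_id, columns time labels
    timepoints_min: np.ndarray
    detection_p: pd.DataFrame | None = None    # same shape as values
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timepoints_min = np.asarray(self.timepoints_min, dtype=float)
        if len(self.timepoints_min) != self.values.shape[1]:
            raise ValueError("timepoints and value columns mismatch")
        if np.any(np.diff(self.timepoints_min) <= 0):
            raise ValueError("timepoints must be increasing")
        if self.detection_p is not None and self.detection_p.shape != self.values.shape:
            raise ValueError("detection p-values shape mismatch")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def subset(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[genes],
            self.timepoints_min,
            self.detection_p.loc[genes] if self.detection_p is not None else None,
            dict(self.metadata),
        )


def filter_detected(matrix: ExpressionMatrix, p_threshold: float = 0.05,
                    allow_missing: bool = False) -> ExpressionMatrix:
    """Keep genes detected (p < threshold) in at least one condition."""
    if matrix.detection_p is None:
        if allow_missing:
            return matrix
        raise ValueError("detection p-values missing; pass allow_missing=True to skip")
    keep = (matrix.detection_p < p_threshold).any(axis=1)
    return matrix.subset(matrix.genes[keep])


def call_deregulated(matrix: ExpressionMatrix, threshold: float = 1.0) -> pd.DataFrame:
    """Deregulation flags from log2 fold change against the t = 0 column.

    A gene is deregulated when max over timepoints of |log2(v_t/v_0)|
    is strictly greater than ``threshold`` (default 1, i.e. a two-fold
    change); the direction is the sign of the extreme log2 fold change.
    """
    if matrix.timepoints_min[0] != 0:
        raise ValueError("first timepoint must be the t=0 reference")
    vals = matrix.values.to_numpy(float)
    if np.any(vals <= 0):
        raise ValueError("expression values must be positive for log2 fold change")
    l2fc = np.log2(vals / vals[:, [0]])
    extreme_idx = np.argmax(np.abs(l2fc), axis=1)
    extreme = l2fc[np.arange(len(l2fc)), extreme_idx]
    dereg = np.abs(extreme) > threshold
    direction = np.where(~dereg, "none", np.where(extreme > 0, "up", "down"))
    return pd.DataFrame({
        "deregulated": dereg,
        "direction": direction,
        "max_abs_log2fc": np.abs(extreme),
    }, index=matrix.genes)


def standardize(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, list]:
    """Per-gene z-scored log2 profiles (population sd): mean 0, sd 1.

    Returns the standardized frame and the list of excluded zero-variance
    genes.  Standardization removes level and fold-scale so that
    clustering groups genes by profile shape only.
    """
    vals = matrix.values.to_numpy(float)
    if np.any(vals <= 0):
        raise ValueError("expression values must be positive for log transform")
    logv = np.log2(vals)
    mean = logv.mean(axis=1, keepdims=True)
    sd = logv.std(axis=1, keepdims=True)   # population sd
    ok = sd[:, 0] > 0
    z = (logv[ok] - mean[ok]) / sd[ok]
    excluded = list(matrix.genes[~ok])
    return pd.DataFrame(z, index=matrix.genes[ok], columns=matrix.values.columns), excluded


@dataclass
class ClusterResult:
    centroids: np.ndarray        # c × T
    memberships: pd.DataFrame    # genes × c, rows sum to 1
    fuzzifier: float
    objective: float
    n_iter: int
    seed: int | None

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def min_intercentroid_distance(self) -> float:
        c = self.centroids
        d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
        iu = np.triu_indices(len(c), k=1)
        return float(d[iu].min())

    def cores(self, threshold: float = 0.5) -> dict[int, list]:
        return extract_cores(self.memberships, threshold)


def _farthest_point_init(X: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style farthest-point seeding of the centroids."""
    n = len(X)
    idx = [int(rng.integers(n))]
    for _ in range(c - 1):
        d2 = np.min(((X[:, None, :] - X[None, idx, :]) ** 2).sum(axis=2), axis=1)
        total = d2.sum()
        if total <= 0:
            idx.append(int(rng.integers(n)))
        else:
            idx.append(int(rng.choice(n, p=d2 / total)))
    return X[idx].copy()


def fuzzy_cmeans(standardized: pd.DataFrame, c: int, m: float = 1.5,
                 seed: int | None = 0, tol: float = 1e-6,
                 max_iter: int = 500, n_init: int = 5) -> ClusterResult:
    """Fuzzy c-means with Euclidean distance on standardized profiles.

    Memberships follow u_ij ∝ (1/d_ij²)^(1/(m−1)) normalized per gene;
    centroids are u^m-weighted means.  A gene coinciding with a centroid
    receives membership 1 there (the m→ limit convention).  The c-means
    objective Σ_ij u_ij^m d_ij² decreases monotonically; iteration stops
    when centroids move less than ``tol``.  ``n_init`` independent
    restarts (deterministically derived from ``seed``) guard against
    local minima; the solution with the lowest objective is returned.
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    children = np.random.SeedSequence(seed).generate_state(n_init) % (2 ** 31)
    best: ClusterResult | None = None
    for child in children:
        res = _fuzzy_cmeans_once(standardized, c, m, int(child), tol, max_iter)
        if best is None or res.objective < best.objective:
            best = res
    return ClusterResult(centroids=best.centroids, memberships=best.memberships,
                         fuzzifier=best.fuzzifier, objective=best.objective,
                         n_iter=best.n_iter, seed=seed)


def _fuzzy_cmeans_once(standardized: pd.DataFrame, c: int, m: float,
                       seed: int, tol: float, max_iter: int) -> ClusterResult:
    if c < 2:
        raise ValueError("need at least 2 clusters")
    X = standardized.to_numpy(float)
    if len(X) < c:
        raise ValueError("fewer genes than clusters")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    centroids = _farthest_point_init(X, c, rng)
    expo = 1.0 / (m - 1.0)
    prev_obj = np.inf
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        exact = d2 < 1e-300
        u = np.zeros_like(d2)
        any_exact = exact.any(axis=1)
        with np.errstate(divide="ignore"):
            w = d2[~any_exact] ** (-expo)
        u[~any_exact] = w / w.sum(axis=1, keepdims=True)
        u[any_exact] = exact[any_exact] / exact[any_exact].sum(axis=1, keepdims=True)
        um = u ** m
        new_centroids = (um.T @ X) / um.sum(axis=0)[:, None]
        obj = float((um * d2).sum())
        if obj > prev_obj + 1e-9 * max(1.0, abs(prev_obj)):
            raise RuntimeError("c-means objective increased; numerical failure")
        shift = np.linalg.norm(new_centroids - centroids, axis=1).max()
        centroids = new_centroids
        prev_obj = obj
        if shift < tol:
            break
    memberships = pd.DataFrame(u, index=standardized.index,
                               columns=list(range(c)))
    return ClusterResult(centroids=centroids, memberships=memberships,
                         fuzzifier=m, objective=prev_obj, n_iter=it, seed=seed)


def select_cluster_count(standardized: pd.DataFrame, c_range,
                         m: float = 1.5, seed: int | None = 0) -> pd.DataFrame:
    """Minimum inter-centroid distance as a function of cluster count.

    The elbow — the last c before the curve flattens — indicates the
    number of distinct profile shapes; the row with the largest relative
    drop from the previous c is flagged.
    """
    rows = []
    for c in c_range:
        res = fuzzy_cmeans(standardized, int(c), m=m, seed=seed)
        rows.append({"c": int(c), "min_intercentroid_distance": res.min_intercentroid_distance()})
    df = pd.DataFrame(rows)
    d = df["min_intercentroid_distance"].to_numpy()
    rel_drop = np.zeros(len(d))
    rel_drop[1:] = np.where(d[:-1] > 0, (d[:-1] - d[1:]) / d[:-1], 0.0)
    df["relative_drop"] = rel_drop
    df["largest_drop"] = False
    if len(df) > 1:
        df.loc[df["relative_drop"].idxmax(), "largest_drop"] = True
    return df


def extract_cores(memberships: pd.DataFrame, threshold: float = 0.5) -> dict[int, list]:
    """Cluster cores: genes with membership ≥ threshold (boundary included)."""
    cores: dict[int, list] = {}
    for j in memberships.columns:
        cores[int(j)] = list(memberships.index[memberships[j] >= threshold])
    return cores


def overlap_coefficient(X, Y) -> float:
    """Szymkiewicz–Simpson overlap |X∩Y| / min(|X|, |Y|)."""
    X, Y = set(X), set(Y)
    if not X or not Y:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(X & Y) / min(len(X), len(Y))


def enrichment_test(cluster_genes, target_set, universe) -> dict:
    """One-sided Fisher exact test for target enrichment of a cluster.

    The 2×2 table counts cluster/non-cluster × target/non-target within
    the universe; the p-value is the exact hypergeometric upper tail.
    Returns odds ratio, p and −log10 p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    cluster = set(cluster_genes) & universe
    target = set(target_set) & universe
    a = len(cluster & target)
    b = len(cluster - target)
    c = len(target - cluster)
    d = len(universe) - a - b - c
    odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return {"odds_ratio": float(odds), "p_value": float(p),
            "neg_log10_p": float(-np.log10(p)) if p > 0 else np.inf,
            "table": (a, b, c, d)}
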