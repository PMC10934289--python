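"""K-means physical-performance grouping and the linear performance score.

Participants are clustered on the seven raw-unit features with Lloyd's
algorithm (random initial centroids drawn from the data, Euclidean
assignment, centroid refinement to convergence, best of many restarts by
inertia).  The number of clusters is chosen by the maximum mean silhouette
coefficient over a small k range.  With k = 3 the clusters are ordered into
low / intermediate / high physical performance (LPP / IPP / HPP) by their
centroid six-minute-walk distance, and a continuous performance score is
obtained by ordinary least squares of the numeric level code (LPP=0, IPP=1,
HPP=2) on the seven features.

Features are NOT standardized by default: the published raw-unit score
equation and the walk-distance-dominated cluster geometry both presume raw
features.  A z-score option exists and its state is recorded on the model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FEATURE_COLUMNS

__all__ = [
    "ClusterModel",
    "PerformanceEquation",
    "kmeans_fit",
    "silhouette_mean",
    "select_k",
    "order_levels",
    "fit_performance_equation",
    "apply_equation",
    "reference_equation",
    "cluster_cohort",
]

LEVELS_3 = ("LPP", "IPP", "HPP")
LEVEL_CODES = {"LPP": 0, "IPP": 1, "HPP": 2}

#: feature used to rank k=3 centroids into performance levels (ascending)
DEFAULT_RANKING_FEATURE = "six_mwt_distance"

N_RESTARTS = 50
TOL = 1e-6
MAX_ITER = 300
LOW_CONFIDENCE_SILHOUETTE = 0.25


@dataclass
class PerformanceEquation:
    """Linear performance score: sum of per-feature weights plus intercept."""

    coefficients: dict
    intercept: float

    def __post_init__(self):
        missing = [c for c in FEATURE_COLUMNS if c not in self.coefficients]
        extra = [c for c in self.coefficients if c not in FEATURE_COLUMNS]
        if missing or extra:
            raise ValueError(
                f"equation must carry exactly one weight per feature; "
                f"missing {missing}, unexpected {extra}"
            )


@dataclass
class ClusterModel:
    """Fitted K-means model plus the derived performance structure."""

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    feature_names: tuple = tuple(FEATURE_COLUMNS)
    silhouette_by_k: dict = field(default_factory=dict)
    level_map: dict = field(default_factory=dict)
    equation: PerformanceEquation | None = None
    standardized: bool = False
    feature_loc: np.ndarray | None = None
    feature_scale: np.ndarray | None = None
    seed: int | None = None
    low_confidence: bool = False

    def levels(self) -> np.ndarray:
        """Per-participant performance labels."""
        if not self.level_map:
            raise ValueError("levels not assigned; call order_levels first")
        return np.array([self.level_map[int(c)] for c in self.assignments])

    def to_json(self) -> str:
        d = {
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "assignments": self.assignments.tolist(),
            "inertia": self.inertia,
            "feature_names": list(self.feature_names),
            "silhouette_by_k": {str(k): v for k, v in self.silhouette_by_k.items()},
            "level_map": {str(k): v for k, v in self.level_map.items()},
            "equation": (
                {"coefficients": self.equation.coefficients,
                 "intercept": self.equation.intercept}
                if self.equation else None
            ),
            "standardized": self.standardized,
            "feature_loc": None if self.feature_loc is None else self.feature_loc.tolist(),
            "feature_scale": None if self.feature_scale is None else self.feature_scale.tolist(),
            "seed": self.seed,
            "low_confidence": self.low_confidence,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ClusterModel":
        d = json.loads(text)
        eq = d.get("equation")
        return cls(
            k=d["k"],
            centroids=np.asarray(d["centroids"], dtype=float),
            assignments=np.asarray(d["assignments"], dtype=int),
            inertia=d["inertia"],
            feature_names=tuple(d["feature_names"]),
            silhouette_by_k={int(k): v for k, v in d["silhouette_by_k"].items()},
            level_map={int(k): v for k, v in d["level_map"].items()},
            equation=PerformanceEquation(eq["coefficients"], eq["intercept"]) if eq else None,
            standardized=d["standardized"],
            feature_loc=None if d["feature_loc"] is None else np.asarray(d["feature_loc"]),
            feature_scale=None if d["feature_scale"] is None else np.asarray(d["feature_scale"]),
            seed=d.get("seed"),
            low_confidence=d.get("low_confidence", False),
        )


# ---------------------------------------------------------------------------
# Lloyd's algorithm
# ---------------------------------------------------------------------------

def _assign(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    return labels, d2[np.arange(X.shape[0]), labels]


def _lloyd_once(X: np.ndarray, k: int, rng) -> tuple[np.ndarray, np.ndarray, float]:
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    inertia = np.inf
    for _ in range(MAX_ITER):
        new_labels, d2 = _assign(X, centroids)
        # empty-cluster repair: re-seed at the point farthest from its centroid
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(np.argmax(d2))
                centroids[c] = X[far]
                new_labels, d2 = _assign(X, centroids)
        new_inertia = float(d2.sum())
        if np.array_equal(new_labels, labels) or inertia - new_inertia < TOL:
            labels, inertia = new_labels, new_inertia
            break
        labels, inertia = new_labels, new_inertia
        for c in range(k):
            centroids[c] = X[labels == c].mean(axis=0)
    return centroids, labels, inertia


def kmeans_fit(
    X: np.ndarray,
    k: int,
    seed: int | None = None,
    n_restarts: int = N_RESTARTS,
    *,
    standardize: bool = False,
) -> ClusterModel:
    """Best-of-``n_restarts`` Lloyd K-means by within-cluster sum of squares.

    Initial centroids are k distinct data points drawn at random; assignment
    is by Euclidean distance; centroids are refined until the assignment is a
    fixed point (or the inertia improvement drops below tolerance).  Empty
    clusters are repaired by re-seeding at the farthest point.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (participants x features)")
    n = X.shape[0]
    if not n >= k or k < 2:
        raise ValueError("need n >= k >= 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"fewer than k={k} distinct points")

    loc = scale = None
    Xw = X
    if standardize:
        loc = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0
        Xw = (X - loc) / scale

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        centroids, labels, inertia = _lloyd_once(Xw, k, rng)
        if best is None or inertia < best[2]:
            best = (centroids, labels, inertia)
    centroids, labels, inertia = best
    return ClusterModel(
        k=k,
        centroids=centroids,
        assignments=labels,
        inertia=inertia,
        standardized=standardize,
        feature_loc=loc,
        feature_scale=scale,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# silhouette and model selection
# ---------------------------------------------------------------------------

def silhouette_mean(X: np.ndarray, assignments: np.ndarray) -> float:
    """Mean silhouette coefficient (b - a) / max(a, b) over all points.

    a is the mean distance to the point's own cluster (excluding itself), b
    the smallest mean distance to another cluster.  Points in singleton
    clusters score 0.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    n = X.shape[0]
    s = np.zeros(n)
    sizes = {c: int(np.count_nonzero(labels == c)) for c in uniq}
    for i in range(n):
        own = labels[i]
        if sizes[own] == 1:
            continue
        a = D[i, labels == own].sum() / (sizes[own] - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != own)
        m = max(a, b)
        s[i] = 0.0 if m == 0.0 else (b - a) / m
    return float(s.mean())


def select_k(
    X: np.ndarray,
    k_min: int = 2,
    k_max: int = 8,
    seed: int | None = None,
    n_restarts: int = N_RESTARTS,
    *,
    standardize: bool = False,
) -> tuple[int, dict]:
    """Silhouette-based choice of the number of clusters.

    Fits each k in [k_min, k_max] with a shared restart policy and returns the
    argmax of the mean silhouette (ties to the smaller k) plus the full
    silhouette-by-k map.  A warning is raised when even the best silhouette is
    weak (< 0.25), i.e. when no clear cluster structure exists.
    """
    X = np.asarray(X, dtype=float)
    if k_max >= X.shape[0]:
        raise ValueError("k_max must be smaller than the number of points")
    if k_min < 2 or k_min > k_max:
        raise ValueError("need 2 <= k_min <= k_max")
    sil = {}
    for k in range(k_min, k_max + 1):
        model = kmeans_fit(X, k, seed=seed, n_restarts=n_restarts, standardize=standardize)
        sil[k] = silhouette_mean(
            X if not standardize else (X - model.feature_loc) / model.feature_scale,
            model.assignments,
        )
    k_best = min(sil, key=lambda k: (-sil[k], k))
    if sil[k_best] < LOW_CONFIDENCE_SILHOUETTE:
        warnings.warn(
            f"weak cluster structure: best mean silhouette {sil[k_best]:.3f} < "
            f"{LOW_CONFIDENCE_SILHOUETTE}"
        )
    return k_best, sil


def order_levels(
    model: ClusterModel,
    ranking_feature: str = DEFAULT_RANKING_FEATURE,
) -> dict:
    """Rank clusters into performance levels by a centroid feature (ascending).

    With k = 3 the labels are LPP / IPP / HPP (low to high six-minute-walk
    distance by default); any other k gets generic ordered labels L1..Lk.
    The map is a pure function of centroid geometry, so it is invariant to
    cluster-id permutations.
    """
    names = list(model.feature_names)
    if ranking_feature not in names:
        raise ValueError(f"unknown ranking feature {ranking_feature!r}")
    col = names.index(ranking_feature)
    vals = model.centroids[:, col]
    if model.standardized and model.feature_loc is not None:
        vals = vals * model.feature_scale[col] + model.feature_loc[col]
    order = np.argsort(vals, kind="stable")
    labels = LEVELS_3 if model.k == 3 else tuple(f"L{i + 1}" for i in range(model.k))
    return {int(cid): labels[rank] for rank, cid in enumerate(order)}


# ---------------------------------------------------------------------------
# performance equation
# ---------------------------------------------------------------------------

def _level_codes(levels: np.ndarray) -> np.ndarray:
    if np.issubdtype(np.asarray(levels).dtype, np.number):
        return np.asarray(levels, dtype=float)
    try:
        return np.array([LEVEL_CODES[lv] if lv in LEVEL_CODES else int(lv[1:]) - 1
                         for lv in levels], dtype=float)
    except (KeyError, ValueError) as e:  # pragma: no cover - defensive
        raise ValueError(f"unrecognized level label: {e}")


def fit_performance_equation(
    X: np.ndarray, levels, feature_names=tuple(FEATURE_COLUMNS)
) -> PerformanceEquation:
    """OLS of the numeric level code (LPP=0, IPP=1, HPP=2) on raw features.

    Returns per-feature weights (score per feature unit) and an intercept.  A
    rank-deficient design is rejected, naming the features that are linearly
    dependent on the preceding ones.
    """
    X = np.asarray(X, dtype=float)
    y = _level_codes(np.asarray(levels))
    if X.shape[0] != y.size:
        raise ValueError("X and levels must align")
    design = np.column_stack([X, np.ones(X.shape[0])])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        collinear = []
        for j in range(1, X.shape[1] + 1):
            sub = np.column_stack([X[:, :j], np.ones(X.shape[0])])
            if np.linalg.matrix_rank(sub) < j + 1:
                collinear.append(feature_names[j - 1])
        raise ValueError(f"rank-deficient design; collinear features: {collinear}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    coefs = {name: float(b) for name, b in zip(feature_names, beta[:-1])}
    return PerformanceEquation(coefficients=coefs, intercept=float(beta[-1]))


def apply_equation(eq: PerformanceEquation, fv) -> float:
    """Evaluate the performance score for one feature vector (raw units)."""
    values = fv.as_dict() if hasattr(fv, "as_dict") else dict(fv)
    missing = [c for c in FEATURE_COLUMNS if c not in values or values[c] is None]
    if missing:
        raise ValueError(f"feature vector missing field(s): {missing}")
    return float(sum(eq.coefficients[c] * float(values[c]) for c in FEATURE_COLUMNS)
                 + eq.intercept)


def reference_equation() -> PerformanceEquation:
    """The published raw-unit performance equation for this test battery.

    Weights are score units per feature unit (count, m/s^2, m, m, s, s, s).
    """
    return PerformanceEquation(
        coefficients={
            "sts_count": -0.014,
            "sts_peak_accel_mean": 0.010,
            "six_mwt_distance": 0.009,
            "step_length_mean": -0.098,
            "step_duration_mean": 0.051,
            "tug_fast_s": 0.002,
            "tug_comfort_s": -0.045,
        },
        intercept=-2.265,
    )


# ---------------------------------------------------------------------------
# whole workflow
# ---------------------------------------------------------------------------

def cluster_cohort(
    X: np.ndarray,
    seed: int | None = None,
    k_min: int = 2,
    k_max: int = 8,
    n_restarts: int = N_RESTARTS,
    *,
    standardize: bool = False,
    ranking_feature: str = DEFAULT_RANKING_FEATURE,
) -> ClusterModel:
    """Select k by silhouette, fit, order levels, and fit the score equation."""
    X = np.asarray(X, dtype=float)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        k_best, sil = select_k(X, k_min, k_max, seed=seed, n_restarts=n_restarts,
                               standardize=standardize)
    low_conf = any("weak cluster structure" in str(w.message) for w in caught)
    model = kmeans_fit(X, k_best, seed=seed, n_restarts=n_restarts, standardize=standardize)
    model.silhouette_by_k = sil
    model.low_confidence = low_conf
    model.level_map = order_levels(model, ranking_feature)
    model.equation = fit_performance_equation(X, model.levels())
    return model
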