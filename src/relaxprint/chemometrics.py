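"""PCA, confidence ellipsoids, classification and the adulteration axis.

The discrimination machinery works in two spaces:

* PCA biplot space - correlation-matrix PCA (columns centred and scaled to
  unit variance, axes from SVD) of the samples-by-regions feature matrix,
  used to visualize and to screen discriminative regions.
* Identifier space - the raw 3D (B, E, G) coordinates, where each oil
  species forms a cluster summarized by its mean and covariance.  The 95%
  confidence ellipsoid of a cluster is the Mahalanobis ball of squared
  radius chi2(0.95, 3) = 7.8147 around the mean under a Gaussian cluster
  model (a tolerance region for new specimens of that species, not a
  confidence region for the mean).

Classification assigns a new identifier to the unique ellipsoid containing
it (nearest by Mahalanobis distance when several contain it) and flags it
"unassigned" - the adulteration/unknown signal - when no ellipsoid does.
For a binary adulteration series, identifiers travel along the straight
segment joining the two pure-species cluster centres; projecting onto that
axis yields a first, model-free estimate of the mixing ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .errors import DegenerateClusterError, DegenerateFeatureError, DomainError, SchemaError
from .features import Identifier

__all__ = [
    "PCAModel",
    "Ellipsoid",
    "ClusterModel",
    "ClassificationResult",
    "Axis",
    "fit_pca",
    "project",
    "fit_ellipsoid",
    "contains",
    "fit_clusters",
    "classify",
    "adulteration_axis",
    "project_ratio",
    "ellipsoids_disjoint",
]


# ---------------------------------------------------------------------------
# PCA (correlation-matrix, from scratch)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAModel:
    """Correlation-matrix PCA: centring/scaling constants, loadings, variance split."""

    columns: tuple[str, ...]
    column_means: np.ndarray
    column_scales: np.ndarray
    loadings: np.ndarray  # (n_features, n_axes); columns orthonormal
    explained_fraction: np.ndarray


def _as_matrix(X) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.index.astype(str)), list(X.columns.astype(str))
    arr = np.asarray(X, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])], [str(j) for j in range(arr.shape[1])]


def fit_pca(X, scale: bool = True) -> PCAModel:
    """Fit PCA to a samples-by-features matrix (DataFrame or array).

    With ``scale=True`` (default) columns are centred and scaled to unit
    variance, so the axes are the eigenvectors of the correlation matrix;
    with ``scale=False`` only centring is applied (covariance PCA).  Axes
    come from the SVD of the scaled matrix; ``explained_fraction[k]`` is
    sigma_k^2 / sum sigma^2.  Loading signs are fixed so that each axis's
    largest-magnitude entry is positive.
    """
    M, _, cols = _as_matrix(X)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise DomainError("PCA needs at least 2 rows and 2 columns")
    if not np.all(np.isfinite(M)):
        raise DomainError("PCA input must be finite (no missing values)")
    means = M.mean(axis=0)
    stds = M.std(axis=0, ddof=1)
    if np.any(stds == 0):
        bad = cols[int(np.argmin(stds))]
        raise DegenerateFeatureError(f"feature column {bad!r} is constant")
    scales = stds if scale else np.ones_like(stds)
    Z = (M - means) / scales
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt.T
    # Deterministic sign: largest-|entry| of each axis made positive.
    for k in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, k])), k] < 0:
            loadings[:, k] *= -1
    frac = s**2 / np.sum(s**2)
    return PCAModel(
        columns=tuple(cols),
        column_means=means,
        column_scales=scales,
        loadings=loadings,
        explained_fraction=frac,
    )


def project(model: PCAModel, X, k: int | None = None) -> pd.DataFrame:
    """Biplot scores: the scaled-centred matrix projected on the first k axes."""
    M, rows, cols = _as_matrix(X)
    if tuple(cols) != model.columns:
        raise SchemaError(
            f"columns {cols} do not match the fitted columns {list(model.columns)}"
        )
    k = model.loadings.shape[1] if k is None else int(k)
    if not (1 <= k <= model.loadings.shape[1]):
        raise DomainError(f"k must lie in [1, {model.loadings.shape[1]}]")
    Z = (M - model.column_means) / model.column_scales
    scores = Z @ model.loadings[:, :k]
    return pd.DataFrame(scores, index=rows, columns=[f"PC{i + 1}" for i in range(k)])


# ---------------------------------------------------------------------------
# Confidence ellipsoids in identifier space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """Gaussian cluster tolerance region: mean, covariance, chi-square radius."""

    center: np.ndarray
    covariance: np.ndarray
    level: float = 0.95
    radius2: float = field(default=0.0)

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        S = np.asarray(self.covariance, dtype=float)
        if c.shape != (3,) or S.shape != (3, 3):
            raise DomainError("ellipsoid lives in 3D identifier space")
        if not np.allclose(S, S.T):
            raise DomainError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(S) <= 0):
            raise DegenerateClusterError("covariance must be positive definite")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "covariance", S)
        if self.radius2 == 0.0:
            object.__setattr__(self, "radius2", float(stats.chi2.ppf(self.level, df=3)))
        if not (self.radius2 > 0):
            raise DomainError("radius2 must be positive")


def _points_array(points) -> np.ndarray:
    pts = [p.as_array() if isinstance(p, Identifier) else np.asarray(p, float) for p in points]
    return np.vstack(pts)


def fit_ellipsoid(points, level: float = 0.95, small_sample: bool = False) -> Ellipsoid:
    """Fit a confidence ellipsoid to >= 4 identifier points.

    Centre = sample mean, covariance = sample covariance (denominator n-1),
    squared Mahalanobis radius = chi2 quantile at ``level`` with 3 dof.  With
    ``small_sample=True`` the radius uses the scaled-F (prediction-region)
    quantile 3 (n-1)(n+1) / (n (n-3)) * F(level; 3, n-3) instead, which
    widens the region for the handful-of-brands regime.
    """
    P = _points_array(points)
    n = P.shape[0]
    if n < 4:
        raise DegenerateClusterError(
            f"need >= 4 points to estimate a 3D covariance, got {n}"
        )
    center = P.mean(axis=0)
    cov = np.cov(P, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(cov) < 3 or np.any(np.linalg.eigvalsh(cov) <= 0):
        raise DegenerateClusterError("cluster covariance is singular")
    if small_sample:
        if n <= 3:  # pragma: no cover - already excluded above
            raise DegenerateClusterError("small-sample radius needs n > 3")
        r2 = 3 * (n - 1) * (n + 1) / (n * (n - 3)) * stats.f.ppf(level, 3, n - 3)
    else:
        r2 = stats.chi2.ppf(level, df=3)
    return Ellipsoid(center=center, covariance=cov, level=level, radius2=float(r2))


def contains(e: Ellipsoid, p) -> tuple[bool, float]:
    """Membership test: inside iff squared Mahalanobis distance <= radius2.

    The boundary counts as inside.  Returns (inside, mahalanobis2).
    """
    x = p.as_array() if isinstance(p, Identifier) else np.asarray(p, float)
    d = x - e.center
    m2 = float(d @ np.linalg.solve(e.covariance, d))
    return m2 <= e.radius2, m2


@dataclass(frozen=True)
class ClusterModel:
    """One fitted ellipsoid per oil species, in raw (B, E, G) space."""

    ellipsoids: dict[str, Ellipsoid]

    def __post_init__(self):
        if not self.ellipsoids:
            raise DomainError("cluster model needs at least one cluster")


def fit_clusters(
    identifiers_by_species: dict[str, list[Identifier]],
    level: float = 0.95,
    small_sample: bool = False,
) -> ClusterModel:
    """Fit one ellipsoid per species from that species' training identifiers."""
    return ClusterModel(
        {
            sp: fit_ellipsoid(pts, level=level, small_sample=small_sample)
            for sp, pts in identifiers_by_species.items()
        }
    )


@dataclass(frozen=True)
class ClassificationResult:
    """Predicted label plus the full per-cluster squared-distance table."""

    label: str
    predicted: str
    mahalanobis2: dict[str, float]
    inside: dict[str, bool]


def classify(p: Identifier, clusters: ClusterModel) -> ClassificationResult:
    """Assign an identifier to a species, or flag it "unassigned".

    Inside exactly one ellipsoid: that species.  Inside several: the nearest
    by Mahalanobis distance.  Inside none: "unassigned" - the signature of an
    adulterated or out-of-library sample.
    """
    m2: dict[str, float] = {}
    inside: dict[str, bool] = {}
    for sp, e in clusters.ellipsoids.items():
        inside[sp], m2[sp] = contains(e, p)
    hits = [sp for sp, ok in inside.items() if ok]
    if not hits:
        predicted = "unassigned"
    else:
        predicted = min(hits, key=lambda sp: m2[sp])
    return ClassificationResult(
        label=p.label, predicted=predicted, mahalanobis2=m2, inside=inside
    )


# ---------------------------------------------------------------------------
# Adulteration axis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Axis:
    """The parameterized segment L(t) = origin + t * direction, t in R."""

    origin: np.ndarray
    direction: np.ndarray

    def at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


def adulteration_axis(a: Ellipsoid, b: Ellipsoid) -> Axis:
    """The line through the two cluster centres, parameterized so t=0 at a, t=1 at b."""
    d = b.center - a.center
    if np.allclose(d, 0):
        raise DomainError("cluster centres coincide; adulteration axis is degenerate")
    return Axis(origin=a.center.copy(), direction=d)


def project_ratio(p, axis: Axis) -> tuple[float, float]:
    """Orthogonal projection of an identifier onto the adulteration axis.

    Returns (t, off_axis): t is the projection coefficient (0 at the base
    cluster, 1 at the adulterant cluster - the model-free ratio estimate) and
    off_axis the Euclidean distance from the point to the line.
    """
    x = p.as_array() if isinstance(p, Identifier) else np.asarray(p, float)
    d = axis.direction
    t = float((x - axis.origin) @ d / (d @ d))
    perp = x - axis.at(t)
    return t, float(np.linalg.norm(perp))


def ellipsoids_disjoint(a: Ellipsoid, b: Ellipsoid) -> bool:
    """Whether two confidence ellipsoids have no common point.

    Minimizes the Mahalanobis distance to ``b`` over the (convex) region
    enclosed by ``a``; the sets are disjoint iff the minimum exceeds b's
    radius.  Convex problem, solved with SLSQP from a's centre.
    """
    La = np.linalg.cholesky(np.linalg.inv(a.covariance))
    Sb_inv = np.linalg.inv(b.covariance)

    def obj(x):
        d = x - b.center
        return d @ Sb_inv @ d

    def obj_grad(x):
        return 2 * Sb_inv @ (x - b.center)

    cons = {
        "type": "ineq",
        "fun": lambda x: a.radius2 - (x - a.center) @ La @ La.T @ (x - a.center),
        "jac": lambda x: -2 * La @ La.T @ (x - a.center),
    }
    res = minimize(
        obj,
        a.center,
        jac=obj_grad,
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    return bool(res.fun > b.radius2)
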