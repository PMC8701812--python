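"""Adulteration-ratio quantification: univariate calibration and PLS1 regression.

Two model families estimate the adulterant volume fraction v of a binary
oil mixture from fingerprint region intensities:

* Univariate straight lines per discriminative region (B, E or G):
  ordinary least squares of v on the region intensity x.  Because region
  features are affine in v for a noiseless binary mixture, the line is exact
  in the ideal limit.  The inverse parameterization (x as a function of v,
  the way calibration plots are usually drawn) is reported alongside.
* PLS1 on all eight regions A-H: columns autoscaled, response centred,
  factors extracted sequentially from the X'y cross-covariance (for a single
  response the dominant singular direction of X'y is its normalization),
  X deflated by the rank-one score-loading product after each factor.  The
  factor count is chosen by leave-one-out cross-validation, minimizing the
  predicted residual sum of squares (PRESS).

Errors are summarized as RMSEC (calibration residuals) and RMSEP (validation
residuals), both with plain 1/n denominators, plus the slope/intercept/R^2 of
the predicted-versus-actual line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .features import REGION_LABELS, FeatureVector

__all__ = [
    "CalibrationSplit",
    "UnivariateModel",
    "PLSRModel",
    "EvaluationResult",
    "fit_univariate",
    "predict_univariate",
    "evaluate",
    "fit_plsr",
    "predict_plsr",
    "loo_press",
    "QuantificationReport",
    "run_quantification",
]


@dataclass(frozen=True)
class CalibrationSplit:
    """Labelled (features, true ratio) pairs split into calibration/validation."""

    calibration: tuple[tuple[FeatureVector, float], ...]
    validation: tuple[tuple[FeatureVector, float], ...]

    def __post_init__(self):
        cal = {f.label for f, _ in self.calibration}
        val = {f.label for f, _ in self.validation}
        if cal & val:
            raise DomainError(f"calibration/validation labels overlap: {sorted(cal & val)}")
        for _, v in list(self.calibration) + list(self.validation):
            if not (0 <= v <= 1):
                raise DomainError(f"adulteration ratio {v} outside [0, 1]")

    def matrices(self, regions=REGION_LABELS) -> tuple[pd.DataFrame, pd.DataFrame]:
        """The calibration and validation design matrices (regions + ratio column)."""
        def _df(pairs):
            rows = {
                f.label: [f.region_means[r] for r in regions] + [v] for f, v in pairs
            }
            return pd.DataFrame.from_dict(
                rows, orient="index", columns=list(regions) + ["ratio"]
            )
        return _df(self.calibration), _df(self.validation)


@dataclass(frozen=True)
class UnivariateModel:
    """Straight-line calibration v = slope * x + intercept for one region."""

    region: str
    slope: float
    intercept: float
    r2: float
    rmsec: float
    # Inverse parameterization x = inv_slope * v + inv_intercept, the axis
    # convention of conventional calibration plots.
    inv_slope: float = float("nan")
    inv_intercept: float = float("nan")


def fit_univariate(pairs, region: str) -> UnivariateModel:
    """OLS of the ratio on one region's intensity.

    ``pairs`` is a sequence of (intensity, ratio).  Requires >= 3 pairs with
    non-constant intensity.
    """
    x = np.array([p[0] for p in pairs], dtype=float)
    v = np.array([p[1] for p in pairs], dtype=float)
    if x.size < 3:
        raise DomainError("need at least 3 calibration pairs")
    if np.ptp(x) == 0:
        raise DomainError(f"region {region!r} intensity is constant; singular design")
    slope, intercept = np.polyfit(x, v, 1)
    resid = v - (slope * x + intercept)
    sst = np.sum((v - v.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 1.0
    inv_slope, inv_intercept = np.polyfit(v, x, 1) if np.ptp(v) > 0 else (np.nan, np.nan)
    return UnivariateModel(
        region=region,
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r2),
        rmsec=float(np.sqrt(np.mean(resid**2))),
        inv_slope=float(inv_slope),
        inv_intercept=float(inv_intercept),
    )


def predict_univariate(model: UnivariateModel, x) -> np.ndarray | float:
    """Evaluate the calibration line; out-of-[0,1] estimates pass through as-is."""
    import warnings

    est = model.slope * np.asarray(x, dtype=float) + model.intercept
    if np.any(est < 0) or np.any(est > 1):
        warnings.warn(
            f"region {model.region}: predicted ratio outside [0, 1]; reported unclipped"
        )
    return est if np.ndim(x) else float(est)


@dataclass(frozen=True)
class EvaluationResult:
    """RMSE plus the predicted-versus-actual line for one dataset role."""

    role: str
    rmse: float
    slope: float
    intercept: float
    r2: float
    n: int


def evaluate(pairs, role: str = "validation") -> EvaluationResult:
    """Summarize (true v, predicted v_hat) pairs.

    rmse = sqrt(mean (v - v_hat)^2); slope/intercept/r2 come from OLS of the
    predictions on the true values (predicted regressed on actual).
    """
    v = np.array([p[0] for p in pairs], dtype=float)
    vh = np.array([p[1] for p in pairs], dtype=float)
    if v.size < 2:
        raise DomainError("need at least 2 (actual, predicted) pairs")
    rmse = float(np.sqrt(np.mean((v - vh) ** 2)))
    if np.ptp(v) == 0:
        slope, intercept, r2 = float("nan"), float("nan"), float("nan")
    else:
        slope, intercept = np.polyfit(v, vh, 1)
        resid = vh - (slope * v + intercept)
        sst = np.sum((vh - vh.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 1.0
    return EvaluationResult(
        role=role, rmse=rmse, slope=float(slope), intercept=float(intercept),
        r2=float(r2), n=int(v.size),
    )


# ---------------------------------------------------------------------------
# PLS1
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PLSRModel:
    """A fitted PLS1 model collapsed to one coefficient vector on the raw scale."""

    columns: tuple[str, ...]
    x_means: np.ndarray
    x_scales: np.ndarray
    y_mean: float
    weights: np.ndarray  # (n_features, n_factors), scaled space
    x_loadings: np.ndarray
    y_loadings: np.ndarray  # (n_factors,)
    n_factors: int
    coef: np.ndarray  # raw-scale coefficients
    intercept: float
    rmsec: float
    press_curve: np.ndarray = field(default=None)


def _pls1_core(Z: np.ndarray, yc: np.ndarray, n_factors: int):
    """Sequential PLS1 factor extraction on pre-scaled data (X deflated only)."""
    W, P, q = [], [], []
    Xd = Z.copy()
    for _ in range(n_factors):
        w = Xd.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            raise DomainError("cross-covariance vanished; too many factors requested")
        w /= norm
        t = Xd @ w
        tt = t @ t
        if tt < 1e-14:
            raise DomainError("degenerate score vector; too many factors requested")
        p = Xd.T @ t / tt
        q.append(yc @ t / tt)
        W.append(w)
        P.append(p)
        Xd = Xd - np.outer(t, p)
    W = np.column_stack(W)
    P = np.column_stack(P)
    q = np.array(q)
    beta_scaled = W @ np.linalg.solve(P.T @ W, q)
    return W, P, q, beta_scaled


def fit_plsr(X, y, n_factors: int) -> PLSRModel:
    """Fit PLS1 of the ratios y on the region features X with n_factors factors.

    X columns are centred and scaled to unit variance, y is centred.  With
    n_factors equal to the column rank the model reproduces multivariate OLS.
    """
    if isinstance(X, pd.DataFrame):
        cols, M = tuple(X.columns.astype(str)), X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        cols = tuple(str(i) for i in range(M.shape[1]))
    y = np.asarray(y, dtype=float)
    n, k = M.shape
    if not (1 <= n_factors <= min(n - 1, k)):
        raise DomainError(
            f"n_factors must lie in [1, {min(n - 1, k)}], got {n_factors}"
        )
    means = M.mean(axis=0)
    stds = M.std(axis=0, ddof=1)
    if np.any(stds == 0):
        bad = cols[int(np.argmin(stds))]
        raise DomainError(f"feature column {bad!r} is constant; cannot autoscale")
    Z = (M - means) / stds
    y_mean = float(y.mean())
    yc = y - y_mean
    W, P, q, beta_scaled = _pls1_core(Z, yc, n_factors)
    coef = beta_scaled / stds
    intercept = y_mean - means @ coef
    resid = y - (M @ coef + intercept)
    return PLSRModel(
        columns=cols,
        x_means=means,
        x_scales=stds,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        n_factors=n_factors,
        coef=coef,
        intercept=float(intercept),
        rmsec=float(np.sqrt(np.mean(resid**2))),
    )


def predict_plsr(model: PLSRModel, X) -> np.ndarray:
    """Predict ratios for new samples with a fitted PLS1 model."""
    M = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    return M @ model.coef + model.intercept


def loo_press(X, y, max_factors: int) -> tuple[np.ndarray, int]:
    """Leave-one-out PRESS curve and the selected factor count.

    For each candidate factor count a, PRESS(a) = sum_i (y_i - yhat_i^(-i))^2
    with the model refit on all samples but i.  The selected count is the
    PRESS minimizer (smallest count on ties - parsimony).
    """
    M = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, dtype=float)
    n, k = M.shape
    if not (1 <= max_factors <= min(n - 2, k)):
        raise DomainError(
            f"max_factors must lie in [1, {min(n - 2, k)}] for LOO on {n} samples"
        )
    press = np.zeros(max_factors)
    for i in range(n):
        keep = np.arange(n) != i
        for a in range(1, max_factors + 1):
            try:
                m = fit_plsr(M[keep], y[keep], a)
            except DomainError as exc:
                raise DomainError(
                    f"leave-one-out refit without sample {i} degenerate at "
                    f"{a} factor(s): {exc}"
                ) from exc
            yhat = float(M[i] @ m.coef + m.intercept)
            press[a - 1] += (y[i] - yhat) ** 2
    selected = int(np.argmin(press)) + 1
    return press, selected


# ---------------------------------------------------------------------------
# Study-level driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantificationReport:
    """All four fitted models with their calibration/validation metrics."""

    univariate: dict[str, UnivariateModel]
    univariate_metrics: dict[str, dict[str, EvaluationResult]]
    plsr: PLSRModel
    plsr_metrics: dict[str, EvaluationResult]
    press_curve: np.ndarray
    selected_factors: int
    predictions: pd.DataFrame


def run_quantification(
    split: CalibrationSplit,
    regions: tuple[str, ...] = ("B", "E", "G"),
    max_factors: int | None = None,
) -> QuantificationReport:
    """Fit the three univariate models and the PLS1 model on one split.

    The PLS1 factor count is selected by LOO PRESS on the calibration set
    (up to ``max_factors``, default the largest count LOO allows, capped at
    the eight regions).
    """
    cal, val = split.matrices()
    Xc, yc = cal[list(REGION_LABELS)], cal["ratio"].to_numpy()
    Xv, yv = val[list(REGION_LABELS)], val["ratio"].to_numpy()

    uni: dict[str, UnivariateModel] = {}
    uni_metrics: dict[str, dict[str, EvaluationResult]] = {}
    pred_cols: dict[str, np.ndarray] = {}
    for r in regions:
        m = fit_univariate(list(zip(cal[r], yc)), r)
        uni[r] = m
        cal_hat = predict_univariate(m, cal[r].to_numpy())
        val_hat = predict_univariate(m, val[r].to_numpy())
        uni_metrics[r] = {
            "calibration": evaluate(list(zip(yc, cal_hat)), "calibration"),
            "validation": evaluate(list(zip(yv, val_hat)), "validation"),
        }
        pred_cols[f"pred_{r}"] = np.concatenate([cal_hat, val_hat])

    if max_factors is None:
        # Candidate factor counts cannot exceed the numerical rank of the
        # autoscaled calibration matrix (noiseless mixture panels are exactly
        # rank 1 in the mixing fraction).
        Zc = (Xc - Xc.mean(axis=0)) / Xc.std(axis=0, ddof=1)
        rank = int(np.linalg.matrix_rank(Zc.to_numpy(), tol=1e-8 * Xc.shape[0]))
        max_factors = max(1, min(Xc.shape[0] - 2, Xc.shape[1], rank))
    press, n_sel = loo_press(Xc, yc, max_factors)
    plsr = fit_plsr(Xc, yc, n_sel)
    plsr = PLSRModel(**{**plsr.__dict__, "press_curve": press})
    cal_hat = predict_plsr(plsr, Xc)
    val_hat = predict_plsr(plsr, Xv)
    plsr_metrics = {
        "calibration": evaluate(list(zip(yc, cal_hat)), "calibration"),
        "validation": evaluate(list(zip(yv, val_hat)), "validation"),
    }
    pred_cols["pred_PLSR"] = np.concatenate([cal_hat, val_hat])

    predictions = pd.DataFrame(
        {
            "label": list(cal.index) + list(val.index),
            "role": ["calibration"] * len(cal) + ["validation"] * len(val),
            "actual": np.concatenate([yc, yv]),
            **pred_cols,
        }
    ).set_index("label")
    return QuantificationReport(
        univariate=uni,
        univariate_metrics=uni_metrics,
        plsr=plsr,
        plsr_metrics=plsr_metrics,
        press_curve=press,
        selected_factors=n_sel,
        predictions=predictions,
    )
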