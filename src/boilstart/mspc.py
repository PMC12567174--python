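"""PCA-based multivariate statistical process control (Hotelling's T2 / SPE).

A monitoring model is fitted on the feature matrix ``X`` (N acquisitions x K
sub-band PSD variables) of an in-control training window — here the quiet
subcooled-boiling stage.  Columns are autoscaled (training mean 0, SD 1), the
sample correlation matrix (divisor N-1) is eigendecomposed, and the principal
components whose explained-variance ratio exceeds a threshold (default 0.05)
are retained.

For a point x with scores t = x_std . P:

    T2  = (t - tbar) diag(lambda_1..lambda_A)^-1 (t - tbar)^T
    SPE = || x_std - t . P^T ||^2

with analytic control limits at significance alpha (default 0.01):

    T2_limit  = A (N - 1) / (N - A) * F_{1-alpha}(A, N - A)
    SPE_limit = theta1 [ z_alpha h0 sqrt(2 theta2) / theta1 + 1
                         + theta2 h0 (h0 - 1) / theta1^2 ]^{1/h0}

where ``theta_i = sum_{k>A} lambda_k^i`` and ``h0 = 1 - 2 theta1 theta3 /
(3 theta2^2)`` (the Jackson-Mudholkar weighted-chi-square construction) and
``z_alpha`` is the upper-alpha standard-normal quantile.

Usage follows the Model/Results convention: ``PCAMonitor(X).fit()`` returns a
:class:`PCAMonitorResults` carrying the loadings, eigenvalue spectrum, both
limits, and the scoring methods; ``results.monitor(X_new)`` produces the
control-chart records.  The module-level functions (``fit_pca``,
``hotelling_t2``, ``spe``, ...) are thin wrappers over these objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateModelError
from .spectral import FeatureVector

__all__ = [
    "PCAMonitor",
    "PCAMonitorResults",
    "MonitorRecord",
    "fit_pca",
    "hotelling_t2",
    "spe",
    "t2_control_limit",
    "spe_control_limit",
    "spe_limit_from_spectrum",
    "control_chart",
    "records_to_frame",
]

_EIG_TOL = 1e-12


@dataclass(frozen=True)
class MonitorRecord:
    """Both statistics and both fixed limits for one monitored acquisition."""

    index: int
    time_min: float
    t2: float
    t2_limit: float
    spe: float
    spe_limit: float

    @property
    def t2_exceeds(self) -> bool:
        return self.t2 > self.t2_limit

    @property
    def spe_exceeds(self) -> bool:
        return self.spe > self.spe_limit


def t2_control_limit(n_components: int, n_train: int, alpha: float) -> float:
    """F-distribution control limit for Hotelling's T2.

    ``A (N-1)/(N-A) * F_{1-alpha}(A, N-A)`` for A retained components and N
    training points.
    """
    a, n = n_components, n_train
    if not 1 <= a < n:
        raise ConfigError(f"need 1 <= A < N, got A={a}, N={n}")
    if not 0 < alpha < 1:
        raise ConfigError("alpha must lie in (0, 1)")
    return a * (n - 1) / (n - a) * stats.f.ppf(1 - alpha, a, n - a)


def spe_limit_from_spectrum(eigenvalues: np.ndarray, n_components: int,
                            alpha: float) -> float:
    """Weighted-chi-square SPE control limit from a full eigenvalue spectrum.

    Uses the residual eigenvalues ``eigenvalues[n_components:]``; returns 0
    when there is no residual variance left.
    """
    return _spe_limit_from_residual_eigenvalues(
        np.asarray(eigenvalues, dtype=np.float64)[n_components:], alpha)


def _spe_limit_from_residual_eigenvalues(residual: np.ndarray,
                                         alpha: float) -> float:
    theta1 = float(np.sum(residual))
    if theta1 <= _EIG_TOL:
        return 0.0  # no residual space: SPE is identically ~0
    theta2 = float(np.sum(residual ** 2))
    theta3 = float(np.sum(residual ** 3))
    if theta2 <= _EIG_TOL:
        raise DegenerateModelError(
            "residual eigenvalue spectrum degenerate (theta2 = 0)")
    h0 = 1.0 - 2.0 * theta1 * theta3 / (3.0 * theta2 ** 2)
    z = stats.norm.ppf(1 - alpha)
    return theta1 * (z * h0 * np.sqrt(2.0 * theta2) / theta1 + 1.0
                     + theta2 * h0 * (h0 - 1.0) / theta1 ** 2) ** (1.0 / h0)


class PCAMonitor:
    """PCA monitoring model specification for an in-control training window.

    Parameters
    ----------
    X:
        Training feature matrix, shape (N, K), N >= 4; rows are acquisitions
        of the in-control (subcooled) stage.
    variance_ratio_threshold:
        Retain components with eigenvalue ratio ``lambda_a / sum(lambda)``
        strictly greater than this (default 0.05), clamped to
        ``[1, min(N-2, K)]`` so the F-limit degrees of freedom stay positive.
    alpha:
        Significance level of both control limits (default 0.01).
    n_components:
        Optional explicit number of retained components, overriding the
        variance-ratio rule (still clamped).
    times, indices:
        Optional per-row timestamps/indices carried into monitoring records.
    """

    def __init__(self, X: np.ndarray, variance_ratio_threshold: float = 0.05,
                 alpha: float = 0.01, n_components: int | None = None,
                 times: np.ndarray | None = None,
                 indices: np.ndarray | None = None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ConfigError("X must be a 2-D feature matrix")
        n, k = X.shape
        if n < 4:
            raise ConfigError(f"need at least 4 training rows, got {n}")
        if not np.all(np.isfinite(X)):
            raise ConfigError("X contains non-finite entries")
        self.X = X
        self.variance_ratio_threshold = variance_ratio_threshold
        self.alpha = alpha
        self.n_components = n_components
        self.times = times
        self.indices = indices

    def fit(self) -> "PCAMonitorResults":
        X = self.X
        n, k = X.shape
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        # relative tolerance: a numerically-constant column (std at rounding
        # level of its mean) counts as zero-variance
        degenerate = scale <= np.abs(mean) * 1e-12
        if np.any(degenerate):
            warnings.warn(
                f"{int(degenerate.sum())} training column(s) have zero "
                "variance; their scale is set to 1 (degenerate-variance "
                "policy)", RuntimeWarning, stacklevel=2)
            scale = np.where(degenerate, 1.0, scale)
        Xs = (X - mean) / scale
        corr = Xs.T @ Xs / (n - 1)
        eigvals, eigvecs = np.linalg.eigh(corr)
        order = np.argsort(eigvals)[::-1]
        eigvals = np.clip(eigvals[order], 0.0, None)
        eigvecs = eigvecs[:, order]

        a_max = min(n - 2, k)
        if self.n_components is not None:
            a = int(self.n_components)
        else:
            total = eigvals.sum()
            ratios = eigvals / total if total > 0 else eigvals
            a = int(np.sum(ratios > self.variance_ratio_threshold))
        a = int(np.clip(a, 1, a_max))

        loadings = eigvecs[:, :a]
        scores = Xs @ loadings
        score_means = scores.mean(axis=0)

        t2_lim = t2_control_limit(a, n, self.alpha)
        spe_lim = _spe_limit_from_residual_eigenvalues(eigvals[a:], self.alpha)

        return PCAMonitorResults(
            mean=mean, scale=scale, loadings=loadings, eigenvalues=eigvals,
            score_means=score_means, n_components=a, n_train=n,
            alpha=self.alpha, t2_limit=float(t2_lim), spe_limit=float(spe_lim),
        )


@dataclass(frozen=True)
class PCAMonitorResults:
    """Fitted PCA monitoring model: estimates, limits, and scoring methods."""

    mean: np.ndarray          # (K,) training column means
    scale: np.ndarray         # (K,) training column SDs (zero-variance -> 1)
    loadings: np.ndarray      # (K, A) orthonormal columns
    eigenvalues: np.ndarray   # (K,) full non-increasing spectrum
    score_means: np.ndarray   # (A,) training score means (≈ 0)
    n_components: int         # A
    n_train: int              # N
    alpha: float
    t2_limit: float
    spe_limit: float

    # -- scoring ---------------------------------------------------------

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.shape[-1] != self.mean.size:
            raise ConfigError(
                f"point has {x.shape[-1]} variables, model expects "
                f"{self.mean.size}")
        return (x - self.mean) / self.scale

    def t2(self, x: np.ndarray | FeatureVector) -> float | np.ndarray:
        """Hotelling's T2 of one point (1-D) or many points (2-D, per row)."""
        lam = self.eigenvalues[:self.n_components]
        if np.any(lam <= _EIG_TOL):
            raise DegenerateModelError(
                "a retained eigenvalue is numerically zero")
        x = x.values if isinstance(x, FeatureVector) else x
        xs = self._standardize(x)
        dev = xs @ self.loadings - self.score_means
        out = np.sum(dev ** 2 / lam, axis=-1)
        return float(out) if out.ndim == 0 else out

    def spe(self, x: np.ndarray | FeatureVector) -> float | np.ndarray:
        """Squared prediction error (Q statistic) of one or many points."""
        x = x.values if isinstance(x, FeatureVector) else x
        xs = self._standardize(x)
        recon = (xs @ self.loadings) @ self.loadings.T
        out = np.sum((xs - recon) ** 2, axis=-1)
        return float(out) if out.ndim == 0 else out

    def monitor(self, X: np.ndarray, indices: np.ndarray | None = None,
                times: np.ndarray | None = None,
                period_min: float = 0.5) -> list[MonitorRecord]:
        """Score rows of ``X`` against the fixed fitted limits."""
        X = np.asarray(X, dtype=np.float64)
        if X.size == 0:
            return []
        X = np.atleast_2d(X)
        t2v = np.atleast_1d(self.t2(X))
        spev = np.atleast_1d(self.spe(X))
        if indices is None:
            indices = np.arange(1, X.shape[0] + 1)
        if times is None:
            times = np.asarray(indices, dtype=float) * period_min
        return [MonitorRecord(index=int(i), time_min=float(t),
                              t2=float(a), t2_limit=self.t2_limit,
                              spe=float(b), spe_limit=self.spe_limit)
                for i, t, a, b in zip(indices, times, t2v, spev)]

    # -- reporting -------------------------------------------------------

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues

    def summary(self) -> str:
        lines = [
            "PCA monitoring model",
            "====================",
            f"training rows (N):        {self.n_train}",
            f"variables (K):            {self.mean.size}",
            f"retained components (A):  {self.n_components}",
            f"alpha:                    {self.alpha}",
            f"T2 control limit:         {self.t2_limit:.4f}",
            f"SPE control limit:        {self.spe_limit:.4f}",
            "explained variance ratio: "
            + ", ".join(f"{r:.3f}"
                        for r in
                        self.explained_variance_ratio[:self.n_components]),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable snapshot for audit."""
        return {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "score_means": self.score_means.tolist(),
            "n_components": self.n_components,
            "n_train": self.n_train,
            "alpha": self.alpha,
            "t2_limit": self.t2_limit,
            "spe_limit": self.spe_limit,
        }


# ---------------------------------------------------------------------------
# functional surface


def fit_pca(X: np.ndarray, variance_ratio_threshold: float = 0.05,
            alpha: float = 0.01,
            n_components: int | None = None) -> PCAMonitorResults:
    """Fit a PCA monitoring model on a training feature matrix."""
    return PCAMonitor(X, variance_ratio_threshold=variance_ratio_threshold,
                      alpha=alpha, n_components=n_components).fit()


def hotelling_t2(model: PCAMonitorResults,
                 x: np.ndarray | FeatureVector) -> float | np.ndarray:
    return model.t2(x)


def spe(model: PCAMonitorResults,
        x: np.ndarray | FeatureVector) -> float | np.ndarray:
    return model.spe(x)


def spe_control_limit(model: PCAMonitorResults,
                      alpha: float | None = None) -> float:
    """SPE limit from the model's residual eigenvalue spectrum."""
    residual = model.eigenvalues[model.n_components:]
    return _spe_limit_from_residual_eigenvalues(
        residual, model.alpha if alpha is None else alpha)


def control_chart(train: np.ndarray, all_points: np.ndarray,
                  variance_ratio_threshold: float = 0.05, alpha: float = 0.01,
                  period_min: float = 0.5,
                  indices: np.ndarray | None = None) -> list[MonitorRecord]:
    """Offline control chart: one fixed model on the subcooled training prefix.

    Fits once on ``train`` and scores every row of ``all_points`` against the
    fixed limits.
    """
    model = fit_pca(train, variance_ratio_threshold, alpha)
    return model.monitor(np.asarray(all_points, dtype=np.float64),
                         indices=indices, period_min=period_min)


def records_to_frame(records: list[MonitorRecord]) -> pd.DataFrame:
    """MonitorRecords as a DataFrame (CSV-ready control-chart export)."""
    return pd.DataFrame([{
        "index": r.index, "time_min": r.time_min,
        "t2": r.t2, "t2_limit": r.t2_limit,
        "spe": r.spe, "spe_limit": r.spe_limit,
        "t2_exceeds": r.t2_exceeds, "spe_exceeds": r.spe_exceeds,
    } for r in records])
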