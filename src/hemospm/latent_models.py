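"""PCA and slow-feature-analysis latent-variable models.

Both models operate on the variable-wise unfolded matrix X of normalized
observations.  PCA eigendecomposes the sample covariance
B = Xc'Xc/(n-1) (Xc column-centered) as B = U L^2 U', and defines
variance-scaled scores S = Xc U L^{-1}, whose training covariance is the
identity — the scaling that makes the chi-square control-chart
distributions exact under the null.

SFA reuses the PCA factors to sphere the data, Z = Xc U L^{-1}, forms the
covariance A of the backward time-differences of Z (within each patient's
contiguous valid spans only — differencing across patients or gaps would
fabricate huge derivatives), and eigendecomposes A.  Ordering A's
eigenpairs by ascending eigenvalue (mean squared derivative = "slowness
value") yields slow features: the slowest features track operating-point
drift, the fastest track abrupt anomalies.  The combined transform is
W = U L^{-1} P with P orthonormal, so SFA scores keep identity training
covariance and preserve total score energy per observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, InsufficientDataError
from .unfold_normalize import UnfoldedMatrix, base_signal

#: Singular values below this fraction of the largest are treated as
#: numerically zero: excluded from sphering, their scores fixed at 0.
RANK_TOL = 1e-8


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (reproducible
    across SVD backends)."""
    k = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[k, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


@dataclass
class PCAModel:
    """Principal-component model of the unfolded cohort matrix."""

    mean: np.ndarray  # (J,) training column means
    U: np.ndarray  # (J, J) orthonormal loadings
    Lambda: np.ndarray  # (J,) singular values (sqrt eigenvalues), descending
    c: int  # retained components
    var_explained: np.ndarray  # (J,) fractions, sums to 1
    n_train: int
    signal_labels: list = field(default_factory=list)
    c_auto: bool = False

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.Lambda**2

    @property
    def inv_lambda(self) -> np.ndarray:
        active = self.Lambda > RANK_TOL * self.Lambda[0]
        return np.where(active, 1.0 / np.where(active, self.Lambda, 1.0), 0.0)

    @property
    def rank(self) -> int:
        return int((self.Lambda > RANK_TOL * self.Lambda[0]).sum())


@dataclass
class SFAModel:
    """Slow-feature model: PCA sphering + derivative-covariance rotation."""

    mean: np.ndarray
    U: np.ndarray
    Lambda: np.ndarray
    P: np.ndarray  # (J, J) orthonormal rotation, columns by ascending slowness
    Omega: np.ndarray  # (J,) slowness values, ascending
    d: int  # slow-feature count (default: the PCA c)
    n_train: int
    n_deriv: int = 0
    signal_labels: list = field(default_factory=list)

    @property
    def inv_lambda(self) -> np.ndarray:
        active = self.Lambda > RANK_TOL * self.Lambda[0]
        return np.where(active, 1.0 / np.where(active, self.Lambda, 1.0), 0.0)

    @property
    def J(self) -> int:
        return self.U.shape[0]


def select_components_lcurve(eigenvalues: np.ndarray,
                             coverage_fallback: float = 0.98) -> int:
    """Retained-component count at the knee of the scree curve.

    The knee is the index of maximum discrete curvature of the
    (component index, log eigenvalue) curve.  A monotone-flat spectrum has
    no knee; then the smallest c whose cumulative variance reaches
    ``coverage_fallback`` is returned instead.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if len(lam) < 3:
        raise ContractError("need at least 3 eigenvalues for the L-curve")
    if np.any(lam < 0):
        raise ContractError("eigenvalues must be non-negative")
    y = np.log(np.maximum(lam, 1e-300))
    d1 = (y[2:] - y[:-2]) / 2.0  # central first difference at 1..n-2
    d2 = y[2:] - 2.0 * y[1:-1] + y[:-2]
    curvature = np.abs(d2) / (1.0 + d1**2) ** 1.5
    if curvature.max() < 1e-9:  # flat/degenerate spectrum
        cum = np.cumsum(lam) / lam.sum()
        return int(np.searchsorted(cum, coverage_fallback) + 1)
    return int(np.argmax(curvature) + 2)  # knee at 1-based component index


def fit_pca(X, c: int | None = None, coverage: float = 0.98) -> PCAModel:
    """Fit the PCA model on an unfolded matrix (or plain 2-D array).

    ``c=None`` selects the retained count automatically by the L-curve
    knee, raised if necessary to the smallest count covering ``coverage``
    of the variance.  Columns are re-centered (the SpO2 anchor leaves a
    possibly nonzero mean) and the training mean is stored.
    """
    labels = []
    if isinstance(X, UnfoldedMatrix):
        labels = list(X.signal_labels)
        X = X.X
    X = np.asarray(X, dtype=float)
    n, J = X.shape
    if n <= J:
        raise InsufficientDataError(f"need more than J={J} training rows, got {n}")
    mean = X.mean(axis=0)
    Xc = X - mean
    B = Xc.T @ Xc / (n - 1)
    U, eigvals, _ = np.linalg.svd(B, hermitian=True)
    U = _fix_signs(U)
    Lambda = np.sqrt(np.maximum(eigvals, 0.0))
    var_explained = eigvals / eigvals.sum()
    c_auto = c is None
    if c_auto:
        c = select_components_lcurve(eigvals, coverage)
        cum = np.cumsum(var_explained)
        while c < J and cum[c - 1] < coverage:
            c += 1
    if not 1 <= c <= J:
        raise ContractError(f"c must be in [1, {J}]")
    return PCAModel(mean, U, Lambda, int(c), var_explained, n, labels, c_auto)


def pca_scores(x, model: PCAModel) -> np.ndarray:
    """Variance-scaled principal-component scores s = (x - mean) U L^{-1}.

    Accepts a single J-vector or an (n, J) matrix; returns all J scores so
    charts can split retained/residual blocks at ``model.c``.  Scores of
    numerically rank-deficient directions are 0.
    """
    x = np.asarray(x, dtype=float)
    return (x - model.mean) @ (model.U * model.inv_lambda[None, :])


def _deriv_rows(Z: np.ndarray, patient_index, minute_index) -> np.ndarray:
    """Backward differences of Z within each patient's contiguous minute runs."""
    if patient_index is None:
        return np.diff(Z, axis=0)
    keep = (patient_index[1:] == patient_index[:-1]) & \
           (np.diff(minute_index) == 1)
    if not keep.any():
        raise InsufficientDataError(
            "no patient contributes two consecutive valid minutes"
        )
    return Z[1:][keep] - Z[:-1][keep]


def fit_sfa(X, pca: PCAModel | None = None, d: int | None = None) -> SFAModel:
    """Fit the SFA model on an unfolded matrix.

    Rows must be time-ordered within each patient (guaranteed by
    :func:`~hemospm.unfold_normalize.variable_wise_unfold`).  ``d``
    defaults to the PCA retained-component count c.
    """
    patient_index = minute_index = None
    if isinstance(X, UnfoldedMatrix):
        patient_index, minute_index = X.patient_index, X.minute_index
    if pca is None:
        pca = fit_pca(X)
    Xarr = X.X if isinstance(X, UnfoldedMatrix) else np.asarray(X, dtype=float)
    Z = pca_scores(Xarr, pca)
    dZ = _deriv_rows(Z, patient_index, minute_index)
    A = dZ.T @ dZ / max(len(dZ) - 1, 1)
    P, omega, _ = np.linalg.svd(A, hermitian=True)
    P, omega = P[:, ::-1], omega[::-1]  # ascending slowness
    P = _fix_signs(P)
    if d is None:
        d = pca.c
    J = Z.shape[1]
    if not 1 <= d <= J:
        raise ContractError(f"d must be in [1, {J}]")
    return SFAModel(pca.mean, pca.U, pca.Lambda, P, omega, int(d),
                    pca.n_train, len(dZ), list(pca.signal_labels))


def sfa_scores(x, model: SFAModel) -> np.ndarray:
    """Slow-feature scores s = (x - mean) U L^{-1} P, slowest first.

    The slow block is columns ``:model.d``, the fast block ``model.d:``.
    """
    x = np.asarray(x, dtype=float)
    return (x - model.mean) @ (model.U * model.inv_lambda[None, :]) @ model.P


def slowness(series: np.ndarray) -> float:
    """Mean squared backward difference of a feature series.

    For a unit-variance sinusoid of period T (densely sampled) this is
    approximately (2*pi/T)^2.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 2:
        raise ContractError("need at least 2 samples")
    return float(np.mean(np.diff(series) ** 2))


def lag_weight_dispersion(loading: np.ndarray, signal_labels) -> float:
    """Mean within-signal variance of squared lag weights of one loading
    vector (unit-normalized).  Near zero when a component weights all lags
    of each signal equally — the static-model signature; dynamic features
    weight lags unequally."""
    v = np.asarray(loading, dtype=float)
    v = v / np.linalg.norm(v)
    groups = {}
    for w, lab in zip(v, signal_labels):
        groups.setdefault(base_signal(lab), []).append(w)
    return float(np.mean([np.var(np.square(g)) for g in groups.values()]))
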