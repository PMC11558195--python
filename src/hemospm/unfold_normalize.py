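"""Three-way cohort array, lag augmentation, batch-wise normalization and
variable-wise unfolding.

The cohort is arranged as an I x J x K array (patients x signals x
minutes), where J counts lag-augmented signal columns.  *Batch-wise*
normalization standardizes each (signal, minute) cell across patients —
removing the shared recovery trajectory and its variability — except the
SpO2 columns, which are anchored to a fixed clinical reference of 100%
with a 5% standard deviation at every minute (oxygen saturation has an
absolute ceiling; cohort standardization would turn a clinically trivial
0.5% dip into a large excursion).  The normalized array is then unfolded
*variable-wise* into an (I*K) x J matrix for latent-variable modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, InsufficientDataError
from .io_cohort import SIGNALS

SPO2_MU = 100.0
SPO2_SIGMA = 5.0


def lagged_label(signal: str, lag: int) -> str:
    return signal if lag == 0 else f"{signal}-{lag}"


def base_signal(label: str) -> str:
    return label.split("-")[0]


@dataclass
class CohortTensor:
    """I x J x K array of patients x (lag-augmented) signals x minutes.

    ``data`` is NaN wherever ``valid`` is False; a lagged cell is valid
    only if the contributing base sample is valid and inside the horizon.
    """

    data: np.ndarray
    valid: np.ndarray
    patient_ids: list
    signal_labels: list
    minutes: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.data.shape != self.valid.shape:
            raise ContractError("data/valid shape mismatch")
        I, J, K = self.data.shape
        if len(self.patient_ids) != I or len(self.signal_labels) != J \
                or len(self.minutes) != K:
            raise ContractError("tensor labels do not match data shape")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class NormalizationModel:
    """Per-(signal, minute) training mean/SD plus the fixed SpO2 anchor."""

    mu: np.ndarray  # (J, K)
    sigma: np.ndarray  # (J, K), floored > 0
    n_eff: np.ndarray  # (J, K) patients contributing to each cell
    signal_labels: list
    minutes: np.ndarray
    spo2_mu: float = SPO2_MU
    spo2_sigma: float = SPO2_SIGMA

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            raise ContractError("sigma must be positive everywhere after flooring")

    def to_frame(self) -> pd.DataFrame:
        J, K = self.mu.shape
        j, k = np.meshgrid(np.arange(J), np.arange(K), indexing="ij")
        return pd.DataFrame({
            "signal": np.repeat(self.signal_labels, K),
            "minute": np.tile(self.minutes, J),
            "mu": self.mu.ravel(),
            "sigma": self.sigma.ravel(),
            "n_eff": self.n_eff.ravel().astype(int),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NormalizationModel":
        labels = list(dict.fromkeys(df["signal"]))
        minutes = np.sort(df["minute"].unique())
        J, K = len(labels), len(minutes)
        piv = df.set_index(["signal", "minute"])
        mu = np.array([[piv.loc[(s, m), "mu"] for m in minutes] for s in labels])
        sigma = np.array([[piv.loc[(s, m), "sigma"] for m in minutes] for s in labels])
        n_eff = np.array([[piv.loc[(s, m), "n_eff"] for m in minutes] for s in labels])
        return cls(mu, sigma, n_eff, labels, minutes)


@dataclass
class UnfoldedMatrix:
    """Variable-wise unfolded (I*K_valid) x J matrix.

    Rows are (patient, minute) pairs whose J entries are all valid, in
    patient-major / time-minor order; ``patient_index`` and
    ``minute_index`` allow re-folding row statistics into per-patient
    chart series.
    """

    X: np.ndarray
    patient_index: np.ndarray
    minute_index: np.ndarray
    patient_ids: list
    signal_labels: list
    n_dropped: int = 0

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


def build_tensor(records) -> CohortTensor:
    """Stack patient records into the base I x 5 x K tensor."""
    horizons = {rec.horizon for rec in records}
    if len(horizons) != 1:
        raise ContractError(f"heterogeneous horizons: {sorted(horizons)}")
    K = horizons.pop()
    I, J = len(records), len(SIGNALS)
    data = np.full((I, J, K), np.nan)
    valid = np.zeros((I, J, K), dtype=bool)
    for i, rec in enumerate(records):
        for j, sig in enumerate(SIGNALS):
            tr = rec.traces[sig]
            data[i, j] = tr.value
            valid[i, j] = tr.valid
    data[~valid] = np.nan
    return CohortTensor(data, valid, [r.patient_id for r in records],
                        list(SIGNALS), np.arange(K))


def lag_augment(tensor: CohortTensor, n_lags: int = 2) -> CohortTensor:
    """Append time-lagged copies of each signal as extra columns.

    Column (signal, lag l) at minute k holds the signal at minute k-l;
    minutes k < l are invalid for that column (never padded — padding
    would fabricate pre-operative data).  Base-signal ordering is kept
    with lags adjacent: HR, HR-1, HR-2, ABP_SYS, ...
    """
    if n_lags < 0:
        raise ContractError("n_lags must be >= 0")
    I, J, K = tensor.shape
    if n_lags >= K:
        raise ContractError("n_lags must be smaller than the horizon")
    if n_lags == 0:
        return tensor
    labels, blocks_d, blocks_v = [], [], []
    for j, sig in enumerate(tensor.signal_labels):
        for lag in range(n_lags + 1):
            labels.append(lagged_label(sig, lag))
            d = np.full((I, K), np.nan)
            v = np.zeros((I, K), dtype=bool)
            if lag == 0:
                d[:] = tensor.data[:, j]
                v[:] = tensor.valid[:, j]
            else:
                d[:, lag:] = tensor.data[:, j, :-lag]
                v[:, lag:] = tensor.valid[:, j, :-lag]
            blocks_d.append(d)
            blocks_v.append(v)
    data = np.stack(blocks_d, axis=1)
    valid = np.stack(blocks_v, axis=1)
    data[~valid] = np.nan
    return CohortTensor(data, valid, tensor.patient_ids, labels, tensor.minutes)


def _is_spo2(label: str) -> bool:
    return base_signal(label) == "SPO2"


def fit_normalization(tensor: CohortTensor,
                      spo2_mu: float = SPO2_MU, spo2_sigma: float = SPO2_SIGMA,
                      sigma_floor_rel: float = 1e-3) -> NormalizationModel:
    """Learn the batch-wise trajectory normalization from a training cohort.

    Per (signal, minute) cell: mean and sample SD (ddof=1) across the
    patients valid there.  SpO2 columns (all lags) are overridden with the
    fixed (100, 5) anchor.  Cells with fewer than 2 valid patients inherit
    the statistics of the nearest valid minute of the same column; SDs are
    floored at ``sigma_floor_rel`` times the column's median SD so that a
    degenerate cell never divides by zero.
    """
    I, J, K = tensor.shape
    x = tensor.data
    n_eff = tensor.valid.sum(axis=0)  # (J, K)
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-invalid cells
        mu = np.nanmean(np.where(tensor.valid, x, np.nan), axis=0)
        sums = np.where(tensor.valid, x, 0.0)
        # sample SD with ddof=1 where n_eff >= 2
        mean_b = np.where(n_eff > 0, sums.sum(axis=0) / np.maximum(n_eff, 1), np.nan)
        ss = (np.where(tensor.valid, (x - mean_b[None]) ** 2, 0.0)).sum(axis=0)
        sigma = np.sqrt(ss / np.maximum(n_eff - 1, 1))
    ok = n_eff >= 2
    mu = np.where(ok, mu, np.nan)
    sigma = np.where(ok, sigma, np.nan)

    # nearest-valid-minute fallback, per column
    for j in range(J):
        bad = ~ok[j]
        if bad.all():
            raise InsufficientDataError(
                f"column {tensor.signal_labels[j]!r} has no minute with >= 2 valid patients"
            )
        if bad.any():
            good_idx = np.flatnonzero(~bad)
            nearest = good_idx[np.argmin(
                np.abs(np.arange(K)[:, None] - good_idx[None]), axis=1)]
            mu[j, bad] = mu[j, nearest[bad]]
            sigma[j, bad] = sigma[j, nearest[bad]]

    # SD floor, relative to each column's median SD
    for j in range(J):
        floor = sigma_floor_rel * np.median(sigma[j])
        if floor <= 0:
            floor = 1e-6
        sigma[j] = np.maximum(sigma[j], floor)

    for j, label in enumerate(tensor.signal_labels):
        if _is_spo2(label):
            mu[j] = spo2_mu
            sigma[j] = spo2_sigma

    return NormalizationModel(mu, sigma, n_eff, list(tensor.signal_labels),
                              tensor.minutes, spo2_mu, spo2_sigma)


def apply_normalization(tensor: CohortTensor,
                        model: NormalizationModel) -> CohortTensor:
    """z[i,j,k] = (x[i,j,k] - mu[j,k]) / sigma[j,k]; validity preserved."""
    I, J, K = tensor.shape
    if model.mu.shape != (J, K) or list(model.signal_labels) != list(tensor.signal_labels):
        raise ContractError("normalization model does not conform to the tensor")
    z = (tensor.data - model.mu[None]) / model.sigma[None]
    z[~tensor.valid] = np.nan
    return CohortTensor(z, tensor.valid.copy(), tensor.patient_ids,
                        list(tensor.signal_labels), tensor.minutes)


def denormalize(tensor: CohortTensor,
                model: NormalizationModel) -> CohortTensor:
    """Inverse of :func:`apply_normalization` at valid cells."""
    I, J, K = tensor.shape
    if model.mu.shape != (J, K):
        raise ContractError("normalization model does not conform to the tensor")
    x = tensor.data * model.sigma[None] + model.mu[None]
    x[~tensor.valid] = np.nan
    return CohortTensor(x, tensor.valid.copy(), tensor.patient_ids,
                        list(tensor.signal_labels), tensor.minutes)


def variable_wise_unfold(tensor: CohortTensor) -> UnfoldedMatrix:
    """Unfold the (normalized) tensor into an (I*K_valid) x J matrix.

    Rows with any invalid entry are excluded (their count is recorded);
    kept rows are in patient-major, time-minor order.
    """
    I, J, K = tensor.shape
    row_ok = tensor.valid.all(axis=1)  # (I, K)
    pi, ki = np.nonzero(row_ok)
    X = tensor.data[pi, :, ki]  # rows in patient-major, minute-minor order
    return UnfoldedMatrix(X, pi, ki, list(tensor.patient_ids),
                          list(tensor.signal_labels),
                          n_dropped=int(I * K - len(pi)))


def refold(values: np.ndarray, unfolded: UnfoldedMatrix, I: int, K: int,
           fill: float = np.nan) -> np.ndarray:
    """Scatter per-row statistics back onto the (I, K) patient/minute grid."""
    out = np.full((I, K) + np.shape(values)[1:], fill, dtype=float)
    out[unfolded.patient_index, unfolded.minute_index] = values
    return out
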