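"""Synthetic multi-patient hemodynamic cohort generator.

Stands in for a postoperative neonatal cohort after the arterial switch
operation, with known ground truth so every pipeline stage is testable:
a shared cohort baseline per signal (near-static heart rate, an arterial
blood pressure dip-and-recovery over the first day, a slow SpO2 decline
over the week), patient-level offsets scaled by a between-patient SD
curve, within-patient AR(1) noise with cross-signal correlated
innovations, sub-minute jittered emission to exercise the resampler, and
controlled injection of anomalies, dropouts and spike outliers.

The numeric template values are illustrative clinical magnitudes, not
fitted to any specific cohort; quantitative tests compare generated data
against the template's own declared parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import uniform_filter1d

from .errors import ContractError
from .io_cohort import SIGNALS, DEFAULT_HORIZON
from .preprocess import RawStream

ANOMALY_KINDS = ("mean_shift", "variance_inflation", "correlation_break",
                 "spike_train")


@dataclass
class TrajectoryTemplate:
    """Ground-truth generative description of one cohort.

    Per base signal: a piecewise-smooth baseline curve (monotone-cubic
    through knot points on the 7-day grid), a between-patient SD,
    an AR(1) coefficient with a within-patient marginal SD, and a shared
    cross-signal correlation matrix for both patient offsets and AR
    innovations.
    """

    baseline_knots: dict  # signal -> (times_minutes, values)
    between_sd: dict  # signal -> float (SD of patient-level offsets)
    within_sd: dict  # signal -> float (marginal SD of the AR(1) noise)
    ar_coeff: dict  # signal -> float in [0, 1)
    correlation: np.ndarray  # (5, 5) symmetric positive-definite
    horizon: int = DEFAULT_HORIZON

    def __post_init__(self) -> None:
        self.correlation = np.asarray(self.correlation, dtype=float)
        if not np.allclose(self.correlation, self.correlation.T):
            raise ContractError("correlation matrix must be symmetric")
        if np.any(np.linalg.eigvalsh(self.correlation) <= 0):
            raise ContractError("correlation matrix must be positive-definite")
        for sig in SIGNALS:
            if self.between_sd[sig] <= 0 or self.within_sd[sig] <= 0:
                raise ContractError("SD values must be positive")
            if not 0 <= self.ar_coeff[sig] < 1:
                raise ContractError("AR coefficients must be in [0, 1)")
        t, v = self.baseline_knots["SPO2"]
        if np.any(np.asarray(v) > 100):
            raise ContractError("SpO2 baseline cannot exceed 100%")

    def baseline(self, signal: str, minutes: np.ndarray) -> np.ndarray:
        t, v = self.baseline_knots[signal]
        return PchipInterpolator(np.asarray(t, float), np.asarray(v, float))(
            np.asarray(minutes, float))

    def between_sd_curve(self, signal: str, minutes: np.ndarray) -> np.ndarray:
        return np.full(len(minutes), float(self.between_sd[signal]))

    def to_dict(self) -> dict:
        return {
            "baseline_knots": {s: [list(map(float, t)), list(map(float, v))]
                               for s, (t, v) in self.baseline_knots.items()},
            "between_sd": {s: float(x) for s, x in self.between_sd.items()},
            "within_sd": {s: float(x) for s, x in self.within_sd.items()},
            "ar_coeff": {s: float(x) for s, x in self.ar_coeff.items()},
            "correlation": self.correlation.tolist(),
            "horizon": int(self.horizon),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectoryTemplate":
        return cls(
            baseline_knots={s: (np.array(t), np.array(v))
                            for s, (t, v) in d["baseline_knots"].items()},
            between_sd=dict(d["between_sd"]),
            within_sd=dict(d["within_sd"]),
            ar_coeff=dict(d["ar_coeff"]),
            correlation=np.array(d["correlation"]),
            horizon=int(d.get("horizon", DEFAULT_HORIZON)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "TrajectoryTemplate":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class AnomalySpec:
    """A controlled deviation injected into one or more signals."""

    kind: str
    signals: tuple
    start: int  # minute
    end: int  # minute, exclusive
    magnitude: float  # SD units (mean_shift, spike_train) or factor

    def __post_init__(self) -> None:
        if self.kind not in ANOMALY_KINDS:
            raise ContractError(f"unknown anomaly kind {self.kind!r}")
        if self.end <= self.start:
            raise ContractError("anomaly interval must be non-empty")
        if not np.isfinite(self.magnitude):
            raise ContractError("magnitude must be finite")
        self.signals = tuple(self.signals)
        for s in self.signals:
            if s not in SIGNALS:
                raise ContractError(f"unknown signal {s!r}")


_DAY = 1440.0


def default_template(horizon: int = DEFAULT_HORIZON) -> TrajectoryTemplate:
    """Illustrative post-arterial-switch cohort template.

    Heart rate near-constant with a mild decline; arterial pressures dip
    over the first postoperative day (bypass-related low cardiac output)
    and recover; SpO2 declines slowly from ~100% to ~97% over the week as
    oxygen demand rises during weaning.
    """
    knots = {
        "HR": ([0, 2 * _DAY, 7 * _DAY], [152.0, 148.0, 142.0]),
        "ABP_SYS": ([0, 0.5 * _DAY, 1.5 * _DAY, 3 * _DAY, 7 * _DAY],
                    [66.0, 58.0, 70.0, 74.0, 76.0]),
        "ABP_DIA": ([0, 0.5 * _DAY, 1.5 * _DAY, 3 * _DAY, 7 * _DAY],
                    [38.0, 33.0, 41.0, 43.0, 44.0]),
        "ABP_MEAN": ([0, 0.5 * _DAY, 1.5 * _DAY, 3 * _DAY, 7 * _DAY],
                     [48.0, 42.0, 52.0, 54.0, 55.0]),
        "SPO2": ([0, 3 * _DAY, 7 * _DAY], [99.5, 98.5, 97.0]),
    }
    corr = np.array([
        [1.00, 0.25, 0.25, 0.25, 0.10],
        [0.25, 1.00, 0.80, 0.90, 0.10],
        [0.25, 0.80, 1.00, 0.90, 0.10],
        [0.25, 0.90, 0.90, 1.00, 0.10],
        [0.10, 0.10, 0.10, 0.10, 1.00],
    ])
    return TrajectoryTemplate(
        baseline_knots=knots,
        between_sd={"HR": 6.0, "ABP_SYS": 5.0, "ABP_DIA": 4.0,
                    "ABP_MEAN": 4.0, "SPO2": 1.0},
        within_sd={"HR": 7.0, "ABP_SYS": 6.0, "ABP_DIA": 5.0,
                   "ABP_MEAN": 5.0, "SPO2": 1.2},
        ar_coeff={s: 0.95 for s in SIGNALS},
        correlation=corr,
        horizon=horizon,
    )


def _simulate_grid(template: TrajectoryTemplate, rng: np.random.Generator,
                   horizon: int):
    """One patient's latent process on the minute grid: (5, K) values."""
    K = horizon
    grid = np.arange(K)
    L = np.linalg.cholesky(template.correlation)
    a = L @ rng.standard_normal(5)  # correlated patient offsets
    eta = (L @ rng.standard_normal((5, K)))  # correlated innovations
    phi = np.array([template.ar_coeff[s] for s in SIGNALS])
    e = np.empty((5, K))
    e[:, 0] = eta[:, 0]
    innov_scale = np.sqrt(1.0 - phi**2)
    for k in range(1, K):
        e[:, k] = phi * e[:, k - 1] + innov_scale * eta[:, k]
    values = np.empty((5, K))
    for j, sig in enumerate(SIGNALS):
        values[j] = (template.baseline(sig, grid)
                     + a[j] * template.between_sd_curve(sig, grid)
                     + e[j] * template.within_sd[sig])
    spo2 = SIGNALS.index("SPO2")
    values[spo2] = np.clip(values[spo2], 0.0, 100.0)
    return values


def generate_cohort(template: TrajectoryTemplate, n_patients: int, seed: int,
                    horizon: int | None = None, sample_interval: float = 0.5,
                    jitter: float = 0.1):
    """Generate a cohort of raw (irregularly sampled) streams.

    Per patient: correlated patient-level offsets scaled by the
    between-patient SD, AR(1) within-patient noise with cross-signal
    correlated innovations, emitted every ``sample_interval`` minutes with
    uniform timestamp jitter.  Fully reproducible from ``seed``.

    Returns a list of ``{signal: RawStream}`` dicts (patients P001, ...).
    """
    if n_patients < 2:
        raise ContractError("need at least 2 patients")
    horizon = horizon or template.horizon
    rng = np.random.default_rng(seed)
    cohort = []
    base_times = np.arange(0.0, horizon - 1 + 1e-9, sample_interval)
    for i in range(n_patients):
        pid = f"P{i + 1:03d}"
        values = _simulate_grid(template, rng, horizon)
        times = base_times + rng.uniform(-jitter, jitter, len(base_times))
        times = np.sort(np.clip(times, 0.0, horizon - 1.0))
        streams = {}
        for j, sig in enumerate(SIGNALS):
            sampled = np.interp(times, np.arange(horizon), values[j])
            streams[sig] = RawStream(pid, sig, times.copy(), sampled)
        cohort.append(streams)
    return cohort


def _local_trend(values: np.ndarray, size: int = 61) -> np.ndarray:
    return uniform_filter1d(values, size=size, mode="nearest")


def inject(streams: dict, specs, template: TrajectoryTemplate, seed: int):
    """Inject anomalies into one patient's streams.

    ``mean_shift`` adds magnitude x (cohort marginal SD, between- and
    within-patient combined — the unit of the trajectory-map band);
    ``variance_inflation`` scales deviations from the local trend by the
    magnitude factor; ``correlation_break`` regenerates the window with
    independent AR(1) innovations around the local trend; ``spike_train``
    adds isolated spikes of magnitude x (within-patient SD), spaced
    >= 5 min apart.  Untouched samples are bit-identical to the input.

    Returns ``(modified streams, injection log)``.
    """
    rng = np.random.default_rng(seed)
    seen = {}
    for spec in specs:
        for s in spec.signals:
            for a, b in seen.get(s, []):
                if spec.start < b and a < spec.end:
                    raise ContractError(f"overlapping anomaly specs on {s}")
            seen.setdefault(s, []).append((spec.start, spec.end))
    out = {sig: RawStream(st.patient_id, sig, st.times.copy(), st.values.copy())
           for sig, st in streams.items()}
    log = []
    for spec in specs:
        for sig in spec.signals:
            st = out[sig]
            idx = np.flatnonzero((st.times >= spec.start) & (st.times < spec.end))
            if len(idx) == 0:
                continue
            sd = float(template.within_sd[sig])
            if spec.kind == "mean_shift":
                marginal = float(np.hypot(template.within_sd[sig],
                                          template.between_sd[sig]))
                st.values[idx] += spec.magnitude * marginal
            elif spec.kind == "variance_inflation":
                trend = _local_trend(st.values)[idx]
                st.values[idx] = trend + spec.magnitude * (st.values[idx] - trend)
            elif spec.kind == "correlation_break":
                trend = _local_trend(st.values)[idx]
                phi = template.ar_coeff[sig]
                e = np.empty(len(idx))
                e[0] = rng.standard_normal()
                scale = np.sqrt(1 - phi**2)
                for k in range(1, len(idx)):
                    e[k] = phi * e[k - 1] + scale * rng.standard_normal()
                st.values[idx] = trend + sd * e
            elif spec.kind == "spike_train":
                # isolated spikes at the sample closest to every 5th integer
                # minute: close enough (< 0.3 min) to survive linear
                # re-gridding near full amplitude, and sparse within an
                # 11-min Hampel window
                spike_idx = []
                for m in range(int(np.ceil(spec.start)), int(spec.end), 5):
                    k = int(np.argmin(np.abs(st.times - m)))
                    if abs(st.times[k] - m) > 0.3 or \
                            not spec.start <= st.times[k] < spec.end:
                        continue
                    if not spike_idx or st.times[k] - st.times[spike_idx[-1]] >= 4.0:
                        spike_idx.append(k)
                spike_idx = np.asarray(spike_idx)
                signs = rng.choice([-1.0, 1.0], len(spike_idx))
                st.values[spike_idx] += signs * spec.magnitude * sd
                log.append((sig, spec.kind, [float(st.times[k]) for k in spike_idx]))
                continue
            log.append((sig, spec.kind, (spec.start, spec.end)))
    return out, log


def inject_missingness(streams: dict, dropout_fraction: float,
                       outlier_fraction: float, seed: int,
                       min_gap: int = 3, spike_sd: float = 8.0):
    """Inject sensor dropouts and spike outliers into one patient's streams.

    Dropouts are silent gaps of ``min_gap``..10 minutes totaling about
    ``dropout_fraction`` of each signal's span; outliers are isolated
    spikes at about ``outlier_fraction`` of minutes, sized ``spike_sd``
    local (robust) SDs so a correctly configured Hampel identifier flags
    them.  Returns ``(modified streams, log)`` where the log records the
    injected gap intervals and spike times per signal.
    """
    if not (0 <= dropout_fraction <= 0.1 and 0 <= outlier_fraction <= 0.1):
        raise ContractError("fractions must be in [0, 0.1]")
    rng = np.random.default_rng(seed)
    out = {}
    log = {}
    for sig, st in streams.items():
        times, values = st.times.copy(), st.values.copy()
        t0, t1 = times[0], times[-1]
        span = t1 - t0
        gaps = []
        budget = dropout_fraction * span
        total = 0.0
        attempts = 0
        while total + min_gap <= budget and attempts < 1000:
            attempts += 1
            length = int(rng.integers(min_gap, 11))
            start = float(np.floor(rng.uniform(t0 + 1, t1 - length - 1)))
            # keep gaps separated by >= 2 min so they stay distinct
            if any(start < b + 2 and a - 2 < start + length for a, b in gaps):
                continue
            gaps.append((start, start + length))
            total += length
        keep = np.ones(len(times), dtype=bool)
        for a, b in gaps:
            keep &= ~((times >= a) & (times < b))
        times, values = times[keep], values[keep]

        n_spikes = int(round(outlier_fraction * span))
        scale = 1.4826 * np.median(np.abs(values - _local_trend(values)))
        if scale <= 0:
            scale = 1.0
        # snap spikes to the sample nearest an integer minute so the spike
        # survives linear re-gridding at full amplitude
        cand_minutes = rng.permutation(np.arange(int(t0) + 1, int(t1) - 1))
        spike_t, chosen = [], []
        for m in cand_minutes:
            if len(chosen) >= n_spikes:
                break
            k = int(np.argmin(np.abs(times - m)))
            t = times[k]
            if all(abs(t - u) >= 2.0 for u in spike_t) and \
               not any(a - 2 <= t < b + 2 for a, b in gaps):
                chosen.append(k)
                spike_t.append(t)
        chosen = np.asarray(sorted(chosen), dtype=int)
        signs = rng.choice([-1.0, 1.0], len(chosen))
        values[chosen] += signs * spike_sd * scale
        out[sig] = RawStream(st.patient_id, sig, times, values)
        log[sig] = {"gaps": sorted(gaps), "spike_times": sorted(spike_t)}
    return out, log
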