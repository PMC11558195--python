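"""Monitoring pipeline: model fitting, held-out scoring, leave-one-out
cross-validation, trajectory maps and the run-directory artifact writer.

A *model bundle* holds everything learned from a training cohort — the
batch-wise normalization, the PCA and SFA models, the flat chi-square T²
limits and the windowed SPE limit profile.  Monitoring a patient never
touches the bundle: leave-one-out folds are therefore strictly isolated,
and each patient is scored against charts built exclusively from the
other patients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import control_charts as cc
from . import io_cohort as io
from . import latent_models as lm
from . import preprocess as pp
from . import synthetic_cohort as sc
from . import unfold_normalize as un
from .errors import ContractError, DataError

log = logging.getLogger("hemospm")

DEFAULT_CONFIG = {
    "grid": {"horizon": io.DEFAULT_HORIZON},
    "io": {"exclusion_threshold": 0.1, "allow_excluded": False},
    "hampel": {"window": 11, "alpha": 0.05, "calibration": "simulated"},
    "dropout": {"min_gap": 3},
    "lags": {"n": 2},
    "normalization": {"spo2_mu": 100.0, "spo2_sigma": 5.0,
                      "sigma_floor_rel": 1e-3},
    "pca": {"c": 3, "coverage": 0.98},  # c: null -> L-curve per fold
    "sfa": {"d": None},  # null -> d = c
    "charts": {"alpha": 0.01},
    "spe": {"window": 5},
    "alarms": {"min_duration": 0},
}


def merge_config(overrides: dict | None) -> dict:
    """Deep-merge user overrides onto the defaults."""
    def deep(a, b):
        out = dict(a)
        for k, v in (b or {}).items():
            out[k] = deep(a[k], v) if isinstance(v, dict) and isinstance(a.get(k), dict) else v
        return out
    return deep(DEFAULT_CONFIG, overrides or {})


@dataclass
class TrajectoryMap:
    """Per-minute cross-patient mean and SD band of each raw signal.

    Defined (finite) only at minutes with at least 2 valid patients.
    """

    minutes: np.ndarray
    mean: dict  # signal -> (K,) array
    sd: dict  # signal -> (K,) array

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for sig, m in self.mean.items():
            parts.append(pd.DataFrame({
                "signal": sig, "minute": self.minutes,
                "mean": m, "sd": self.sd[sig],
            }))
        return pd.concat(parts, ignore_index=True)


@dataclass
class ModelBundle:
    """Everything learned from one training cohort."""

    normalization: un.NormalizationModel
    pca: lm.PCAModel
    sfa: lm.SFAModel
    spe_profile: cc.SPELimitProfile
    config: dict
    training_patients: list

    @property
    def c(self) -> int:
        return self.pca.c

    @property
    def d(self) -> int:
        return self.sfa.d

    def to_dict(self) -> dict:
        return {
            "training_patients": list(self.training_patients),
            "config": self.config,
            "c": self.c,
            "d": self.d,
            "signal_labels": list(self.pca.signal_labels),
            "normalization": {
                "mu": self.normalization.mu.tolist(),
                "sigma": self.normalization.sigma.tolist(),
                "n_eff": self.normalization.n_eff.tolist(),
            },
            "pca": {
                "mean": self.pca.mean.tolist(),
                "U": self.pca.U.tolist(),
                "Lambda": self.pca.Lambda.tolist(),
                "var_explained": self.pca.var_explained.tolist(),
                "n_train": self.pca.n_train,
            },
            "sfa": {
                "P": self.sfa.P.tolist(),
                "Omega": self.sfa.Omega.tolist(),
                "n_deriv": self.sfa.n_deriv,
            },
            "spe_profile": {
                "m": self.spe_profile.m.tolist(),
                "v": self.spe_profile.v.tolist(),
                "limit": self.spe_profile.limit.tolist(),
            },
        }


@dataclass
class MonitoringResult:
    """All monitoring outputs for one patient against one training fold."""

    patient_id: str
    charts: dict  # chart name -> ControlChart
    trajectory_map: TrajectoryMap
    record: io.PatientRecord
    dropout_intervals: list = field(default_factory=list)
    annotations: list = field(default_factory=list)

    def alarm_sparks(self, min_duration: int = 0) -> dict:
        return {name: cc.alarm_sparks(chart, min_duration)
                for name, chart in self.charts.items()}


def trajectory_map(records, signals=None) -> TrajectoryMap:
    """Cross-patient mean and sample SD of the raw signals per minute."""
    if len(records) < 2:
        raise ContractError("need at least 2 patients for a trajectory map")
    signals = signals or io.SIGNALS
    K = records[0].horizon
    mean, sd = {}, {}
    for sig in signals:
        vals = np.stack([r.traces[sig].value for r in records])  # NaN-invalid
        n = np.isfinite(vals).sum(axis=0)
        with np.errstate(invalid="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                m = np.nanmean(vals, axis=0)
                s = np.nanstd(vals, axis=0, ddof=1)
        m[n < 2] = np.nan
        s[n < 2] = np.nan
        mean[sig], sd[sig] = m, s
    return TrajectoryMap(np.arange(K), mean, sd)


def _prepared_tensor(records, config) -> un.CohortTensor:
    tensor = un.build_tensor(records)
    return un.lag_augment(tensor, config["lags"]["n"])


def fit_models(records, config: dict | None = None) -> ModelBundle:
    """Fit normalization, PCA, SFA and all control limits on a training cohort."""
    config = merge_config(config)
    if len(records) < 2:
        raise ContractError("need at least 2 training patients")
    excluded = [r.patient_id for r in records if r.excluded]
    if excluded and not config["io"]["allow_excluded"]:
        raise DataError(
            "training cohort contains excluded patients "
            f"({', '.join(excluded)}); set io.allow_excluded to override"
        )
    tensor = _prepared_tensor(records, config)
    norm = un.fit_normalization(
        tensor,
        spo2_mu=config["normalization"]["spo2_mu"],
        spo2_sigma=config["normalization"]["spo2_sigma"],
        sigma_floor_rel=config["normalization"]["sigma_floor_rel"],
    )
    z = un.apply_normalization(tensor, norm)
    unfolded = un.variable_wise_unfold(z)
    pca = lm.fit_pca(unfolded, c=config["pca"]["c"],
                     coverage=config["pca"]["coverage"])
    sfa = lm.fit_sfa(unfolded, pca=pca, d=config["sfa"]["d"])

    scores = lm.pca_scores(unfolded.X, pca)
    spe_rows = np.einsum("ij,ij->i", scores[:, pca.c:], scores[:, pca.c:])
    I, K = len(records), records[0].horizon
    training_spe = un.refold(spe_rows, unfolded, I, K)
    profile = cc.spe_limit_profile(training_spe, np.arange(K),
                                   window=config["spe"]["window"],
                                   alpha=config["charts"]["alpha"])
    return ModelBundle(norm, pca, sfa, profile, config,
                       [r.patient_id for r in records])


def _score_matrix(record, bundle: ModelBundle):
    """Per-minute PCA and SFA score matrices for one patient (NaN rows at
    minutes where any lag-augmented column is invalid)."""
    tensor = _prepared_tensor([record], bundle.config)
    if list(tensor.signal_labels) != list(bundle.normalization.signal_labels):
        raise ContractError("record does not conform to the bundle's signals")
    z = un.apply_normalization(tensor, bundle.normalization)
    unfolded = un.variable_wise_unfold(z)
    K = record.horizon
    J = len(tensor.signal_labels)
    pca_s = np.full((K, J), np.nan)
    sfa_s = np.full((K, J), np.nan)
    if unfolded.n_rows:
        pca_s[unfolded.minute_index] = lm.pca_scores(unfolded.X, bundle.pca)
        sfa_s[unfolded.minute_index] = lm.sfa_scores(unfolded.X, bundle.sfa)
    return pca_s, sfa_s


def monitor_patient(record, bundle: ModelBundle, reference_map: TrajectoryMap,
                    annotations=None) -> MonitoringResult:
    """Score one patient against a fitted bundle and emit the four charts."""
    config = bundle.config
    alpha = config["charts"]["alpha"]
    K = record.horizon
    minutes = np.arange(K)
    pca_s, sfa_s = _score_matrix(record, bundle)
    c, d = bundle.c, bundle.d
    charts = {}
    charts["PCA_T2"] = cc.t2_chart(pca_s, minutes, c, alpha)
    charts["PCA_SPE"] = cc.spe_chart(pca_s[:, c:], minutes, bundle.spe_profile)
    t2d, t2e = cc.sfa_t2_charts(sfa_s, minutes, d, alpha)
    charts["SFA_T2D"] = t2d
    charts["SFA_T2E"] = t2e

    gap = ~np.isfinite(pca_s[:, 0])
    dropout_intervals = _runs(gap, minutes)
    notes = [a for a in (annotations or []) if a.patient_id == record.patient_id]
    return MonitoringResult(record.patient_id, charts, reference_map, record,
                            dropout_intervals, notes)


def _runs(mask: np.ndarray, minutes: np.ndarray):
    edges = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if mask.size and mask[0]:
        starts.insert(0, 0)
    if mask.size and mask[-1]:
        ends.append(len(mask))
    return [(int(minutes[s]), int(minutes[e - 1]) + 1) for s, e in zip(starts, ends)]


def loo_monitor(records, config: dict | None = None, annotations=None,
                with_bundles: bool = False):
    """Leave-one-out monitoring: each patient is scored with models fitted
    on the other patients only.

    With ``with_bundles=True`` returns ``(results, bundles)`` so callers
    can serialize the per-fold models without refitting.
    """
    config = merge_config(config)
    if len(records) < 3:
        raise ContractError("leave-one-out monitoring needs at least 3 patients")
    results, bundles = [], []
    for i, held_out in enumerate(records):
        fold = [r for j, r in enumerate(records) if j != i]
        bundle = fit_models(fold, config)
        fold_map = trajectory_map(fold)
        results.append(monitor_patient(held_out, bundle, fold_map, annotations))
        bundles.append(bundle)
        log.info("fold %d/%d: monitored %s against %d peers",
                 i + 1, len(records), held_out.patient_id, len(fold))
    return (results, bundles) if with_bundles else results


def preprocess_cohort(raw_cohort: dict, config: dict | None = None):
    """Preprocess ``{patient_id: {signal: RawStream}}`` into records + reports."""
    config = merge_config(config)
    records, reports = [], {}
    for pid in sorted(raw_cohort):
        rec, rep = pp.preprocess_patient(
            raw_cohort[pid],
            horizon=config["grid"]["horizon"],
            min_gap=config["dropout"]["min_gap"],
            window=config["hampel"]["window"],
            alpha=config["hampel"]["alpha"],
            calibration=config["hampel"]["calibration"],
            exclusion_threshold=config["io"]["exclusion_threshold"],
        )
        records.append(rec)
        reports[pid] = rep
    return records, reports


def _report_dict(reports: dict) -> dict:
    pooled = pp.OutlierReport()
    per_patient = {}
    for pid, rep in reports.items():
        per_patient[pid] = {
            "dropout_pct": 100 * rep.dropout_fraction,
            "outlier_pct": 100 * rep.outlier_fraction,
            "prepost_pct": 100 * rep.prepost_fraction,
        }
        pooled.n_total += rep.n_total
        pooled.n_dropout += rep.n_dropout
        pooled.n_outlier += rep.n_outlier
        pooled.n_prepost += rep.n_prepost
        pooled.n_horizon += rep.n_horizon
    return {
        "pooled": {
            "dropout_pct": 100 * pooled.dropout_fraction,
            "outlier_pct": 100 * pooled.outlier_fraction,
            "prepost_pct": 100 * pooled.prepost_fraction,
        },
        "per_patient": per_patient,
    }


def run_pipeline(config, out_dir) -> Path:
    """Run the full pipeline from a config mapping (or YAML path).

    The config either names raw-stream input CSVs (``inputs: [paths]``) or
    a synthetic-generation block
    (``synthetic: {n_patients, seed, horizon, ...}``).  Writes per-patient
    chart tables, the per-fold trajectory maps, fold model bundles and a
    run log into ``out_dir``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    user = dict(config or {})
    synthetic = user.pop("synthetic", None)
    inputs = user.pop("inputs", None)
    annotations_path = user.pop("annotations", None)
    make_plots = user.pop("plots", False)
    cfg = merge_config(user)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if synthetic is not None:
        template = (sc.TrajectoryTemplate.from_dict(synthetic["template"])
                    if "template" in synthetic
                    else sc.default_template())
        horizon = int(synthetic.get("horizon", cfg["grid"]["horizon"]))
        cfg["grid"]["horizon"] = horizon
        cohort = sc.generate_cohort(template, int(synthetic["n_patients"]),
                                    int(synthetic["seed"]), horizon=horizon)
        seed = int(synthetic["seed"])
        if synthetic.get("dropout_fraction") or synthetic.get("outlier_fraction"):
            cohort = [
                sc.inject_missingness(
                    streams,
                    float(synthetic.get("dropout_fraction", 0.0)),
                    float(synthetic.get("outlier_fraction", 0.0)),
                    seed=seed + 1000 + i,
                )[0]
                for i, streams in enumerate(cohort)
            ]
        raw = {next(iter(s.values())).patient_id: s for s in cohort}
        io.write_raw_streams(raw, out / "raw_streams.csv")
    elif inputs:
        raw = io.read_raw_streams(inputs)
    else:
        raise DataError("config must provide either 'inputs' or a 'synthetic' block")

    records, reports = preprocess_cohort(raw, cfg)
    annotations = (io.read_annotations(annotations_path, cfg["grid"]["horizon"])
                   if annotations_path else [])

    usable = [r for r in records if not r.excluded or cfg["io"]["allow_excluded"]]
    skipped = [r.patient_id for r in records if r not in usable]
    results, bundles = loo_monitor(usable, cfg, annotations, with_bundles=True)

    charts_dir = out / "charts"
    charts_dir.mkdir(exist_ok=True)
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    for res, bundle in zip(results, bundles):
        io.write_chart_table(list(res.charts.values()),
                             charts_dir / f"{res.patient_id}.csv")
        res.trajectory_map.to_frame().to_csv(
            maps_dir / f"{res.patient_id}.csv", index=False)
        with open(models_dir / f"fold_{res.patient_id}.json", "w") as fh:
            json.dump(bundle.to_dict(), fh)
    trajectory_map(usable).to_frame().to_csv(out / "trajectory_map.csv",
                                             index=False)

    run_log = {
        "config": cfg,
        "patients": [r.patient_id for r in records],
        "excluded_skipped": skipped,
        "folds": {res.patient_id: [p for p in (r.patient_id for r in usable)
                                   if p != res.patient_id]
                  for res in results},
        "preprocessing": _report_dict(reports),
        "alarm_sparks": {res.patient_id: {k: v for k, v in
                                          res.alarm_sparks(cfg["alarms"]["min_duration"]).items()}
                         for res in results},
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)

    if make_plots:
        from .plotting import plot_monitoring
        plots_dir = out / "plots"
        plots_dir.mkdir(exist_ok=True)
        for res in results:
            plot_monitoring(res, plots_dir / f"{res.patient_id}.png")
    return out
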