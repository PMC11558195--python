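import numpy as np
import pytest

import hemospm as h

HORIZON_1D = 1440


@pytest.fixture(scope="session")
def config_1d():
    return {"grid": {"horizon": HORIZON_1D}}


@pytest.fixture(scope="session")
def template_1d():
    return h.default_template(HORIZON_1D)


@pytest.fixture(scope="session")
def cohort_records(template_1d, config_1d):
    """Eight preprocessed synthetic patients on a 1-day horizon."""
    cohort = h.generate_cohort(template_1d, 8, seed=11, horizon=HORIZON_1D)
    raw = {next(iter(s.values())).patient_id: s for s in cohort}
    records, _ = h.preprocess_cohort(raw, config_1d)
    return records


@pytest.fixture(scope="session")
def fitted_bundle(cohort_records, config_1d):
    """Models fitted on the first six patients of the session cohort."""
    return h.fit_models(cohort_records[:6], config_1d)


def make_constant_record(patient_id: str, values: dict, horizon: int = 100,
                         invalid: dict | None = None) -> h.PatientRecord:
    """A record with constant per-signal values; ``invalid`` maps signals to
    minute indices to invalidate."""
    grid = np.arange(horizon)
    traces = {}
    for sig in h.SIGNALS:
        v = np.full(horizon, float(values.get(sig, 80.0)))
        mask = np.ones(horizon, dtype=bool)
        for m in (invalid or {}).get(sig, []):
            mask[m] = False
            v[m] = np.nan
        traces[sig] = h.SignalTrace(patient_id, sig, grid, v, mask)
    return h.PatientRecord(patient_id, traces, horizon)
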