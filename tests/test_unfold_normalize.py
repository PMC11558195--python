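import numpy as np
import pytest

import hemospm as h
from hemospm.errors import ContractError
from hemospm.unfold_normalize import refold

from conftest import make_constant_record


@pytest.fixture()
def small_tensor(template_1d):
    cohort = h.generate_cohort(template_1d, 3, seed=2, horizon=200,
                               sample_interval=1.0, jitter=0.0)
    records = [h.preprocess_patient(s, horizon=200)[0] for s in cohort]
    return h.build_tensor(records)


class TestBuildTensor:
    def test_shape_and_labels(self, small_tensor):
        assert small_tensor.shape == (3, 5, 200)
        assert small_tensor.signal_labels == list(h.SIGNALS)

    def test_single_patient(self, template_1d):
        cohort = h.generate_cohort(template_1d, 2, seed=2, horizon=50)
        rec = h.preprocess_patient(cohort[0], horizon=50)[0]
        assert h.build_tensor([rec]).shape == (1, 5, 50)

    def test_invalid_minute_propagates(self):
        rec = make_constant_record("p", {"HR": 100.0}, horizon=30,
                                   invalid={"HR": [4]})
        t = h.build_tensor([rec])
        assert not t.valid[0, 0, 4]
        assert np.isnan(t.data[0, 0, 4])

    def test_heterogeneous_horizons_rejected(self):
        a = make_constant_record("a", {}, horizon=30)
        b = make_constant_record("b", {}, horizon=40)
        with pytest.raises(ContractError):
            h.build_tensor([a, b])


class TestLagAugment:
    def test_two_lags_give_fifteen_columns(self, small_tensor):
        aug = h.lag_augment(small_tensor, 2)
        assert aug.shape == (3, 15, 200)
        assert aug.signal_labels[:3] == ["HR", "HR-1", "HR-2"]
        assert aug.signal_labels[3] == "ABP_SYS"

    def test_zero_lags_identity(self, small_tensor):
        aug = h.lag_augment(small_tensor, 0)
        np.testing.assert_array_equal(aug.data, small_tensor.data)
        assert aug.signal_labels == small_tensor.signal_labels

    def test_lag_columns_are_shifted_copies(self, small_tensor):
        aug = h.lag_augment(small_tensor, 2)
        base = aug.signal_labels.index("ABP_SYS")
        for lag in (1, 2):
            j = aug.signal_labels.index(f"ABP_SYS-{lag}")
            both = aug.valid[:, base, :-lag] & aug.valid[:, j, lag:]
            np.testing.assert_array_equal(aug.data[:, j, lag:][both],
                                          aug.data[:, base, :-lag][both])

    def test_boundary_minutes_invalid(self, small_tensor):
        aug = h.lag_augment(small_tensor, 2)
        j1 = aug.signal_labels.index("HR-1")
        j2 = aug.signal_labels.index("HR-2")
        assert not aug.valid[:, j1, 0].any()
        assert not aug.valid[:, j2, :2].any()

    def test_excessive_lags_rejected(self, small_tensor):
        with pytest.raises(ContractError):
            h.lag_augment(small_tensor, 200)


class TestNormalization:
    def test_spo2_anchor_constants(self, small_tensor):
        model = h.fit_normalization(h.lag_augment(small_tensor, 2))
        for lag in ("SPO2", "SPO2-1", "SPO2-2"):
            j = model.signal_labels.index(lag)
            assert (model.mu[j] == 100.0).all()
            assert (model.sigma[j] == 5.0).all()

    def test_spo2_value_mapping(self, small_tensor):
        model = h.fit_normalization(small_tensor)
        z = h.apply_normalization(small_tensor, model)
        j = small_tensor.signal_labels.index("SPO2")
        x = small_tensor.data[0, j].copy()
        expected = (x - 100.0) / 5.0
        np.testing.assert_allclose(z.data[0, j], expected)
        # 100% -> 0, 95% -> -1 by the fixed anchor
        assert (95.0 - model.mu[j, 0]) / model.sigma[j, 0] == -1.0

    def test_training_mean_zero_sd_one_exact(self, small_tensor):
        model = h.fit_normalization(small_tensor)
        z = h.apply_normalization(small_tensor, model)
        for j, lab in enumerate(z.signal_labels):
            if lab.startswith("SPO2"):
                continue
            col = z.data[:, j, :]
            assert np.nanmax(np.abs(col.mean(axis=0))) < 1e-10
            assert np.nanmax(np.abs(col.std(axis=0, ddof=1) - 1)) < 1e-10

    def test_invertible(self, small_tensor):
        model = h.fit_normalization(small_tensor)
        z = h.apply_normalization(small_tensor, model)
        back = h.denormalize(z, model)
        np.testing.assert_allclose(back.data[small_tensor.valid],
                                   small_tensor.data[small_tensor.valid],
                                   rtol=1e-12, atol=1e-9)

    def test_identical_patients_hit_sigma_floor(self):
        recs = [make_constant_record(p, {"HR": 100.0, "ABP_SYS": 60.0},
                                     horizon=40) for p in "abc"]
        model = h.fit_normalization(h.build_tensor(recs))
        j = model.signal_labels.index("HR")
        assert (model.sigma[j] > 0).all()

    def test_sparse_cell_inherits_nearest_minute(self):
        recs = [make_constant_record(p, {"HR": v}, horizon=20,
                                     invalid={"HR": [5]})
                for p, v in zip("abc", (90.0, 100.0, 110.0))]
        recs[0].traces["HR"].valid[5] = True
        recs[0].traces["HR"].value[5] = 90.0
        # only 1 patient valid at minute 5 -> inherit neighbour stats
        model = h.fit_normalization(h.build_tensor(recs))
        j = model.signal_labels.index("HR")
        assert model.n_eff[j, 5] == 1
        assert model.mu[j, 5] == model.mu[j, 4]
        assert model.sigma[j, 5] == model.sigma[j, 4]

    def test_heldout_patient_scores_near_standard_normal(self, template_1d):
        cohort = h.generate_cohort(template_1d, 120, seed=9, horizon=120,
                                   sample_interval=1.0, jitter=0.0)
        records = [h.preprocess_patient(s, horizon=120)[0] for s in cohort]
        model = h.fit_normalization(h.build_tensor(records[:60]))
        z = h.apply_normalization(h.build_tensor(records[60:]), model)
        j = z.signal_labels.index("HR")
        vals = z.data[:, j, :][np.isfinite(z.data[:, j, :])]
        # patient offsets persist across the whole stay, so the effective
        # sample size is close to the number of held-out patients
        assert abs(vals.mean()) < 0.35
        assert abs(vals.std() - 1.0) < 0.15

    def test_recovers_template_baseline(self, template_1d):
        cohort = h.generate_cohort(template_1d, 150, seed=13, horizon=60,
                                   sample_interval=1.0, jitter=0.0)
        records = [h.preprocess_patient(s, horizon=60)[0] for s in cohort]
        model = h.fit_normalization(h.build_tensor(records))
        grid = np.arange(60)
        for sig in ("HR", "ABP_MEAN"):
            j = model.signal_labels.index(sig)
            truth = template_1d.baseline(sig, grid)
            total_sd = np.hypot(template_1d.between_sd[sig],
                                template_1d.within_sd[sig])
            se = total_sd / np.sqrt(150)
            assert np.max(np.abs(model.mu[j] - truth)) < 5 * se


class TestUnfold:
    def tensor(self, data, valid):
        I, J, K = data.shape
        return h.CohortTensor(data, valid, [f"p{i}" for i in range(I)],
                              ["HR", "ABP_SYS", "ABP_DIA"][:J], np.arange(K))

    def test_full_valid_cardinality(self):
        data = np.arange(24, dtype=float).reshape(2, 3, 4)
        t = self.tensor(data, np.ones((2, 3, 4), bool))
        unf = h.variable_wise_unfold(t)
        assert unf.X.shape == (8, 3)
        # patient-major, time-minor ordering
        np.testing.assert_array_equal(unf.patient_index,
                                      [0, 0, 0, 0, 1, 1, 1, 1])
        np.testing.assert_array_equal(unf.X[0], data[0, :, 0])

    def test_invalid_cell_drops_row(self):
        data = np.arange(24, dtype=float).reshape(2, 3, 4)
        valid = np.ones((2, 3, 4), bool)
        valid[1, 2, 3] = False
        unf = h.variable_wise_unfold(self.tensor(data, valid))
        assert unf.X.shape == (7, 3)
        assert unf.n_dropped == 1

    def test_refold_inverse(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(3, 2, 5))
        valid = rng.random((3, 2, 5)) > 0.2
        valid = np.broadcast_to(valid.all(axis=1, keepdims=True), valid.shape).copy()
        data = np.where(valid, data, np.nan)
        t = h.CohortTensor(data, valid, list("abc"), ["HR", "ABP_SYS"],
                           np.arange(5))
        unf = h.variable_wise_unfold(t)
        back = refold(unf.X, unf, 3, 5)  # (I, K, J)
        for j in range(2):
            np.testing.assert_array_equal(back[:, :, j][valid[:, j]],
                                          data[:, j][valid[:, j]])
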