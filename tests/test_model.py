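"""Regressor: splitting, R2, forward pass, training, sweep, serialization."""

import dataclasses

import numpy as np
import pytest

from malphot.dataset_io import PhotophysicsRecord, SubstitutionClass
from malphot.featurize import fingerprint_smiles
from malphot.model import (
    ModelConfig,
    TrainedSpectralModel,
    predict_wavelength,
    r_squared,
    solvatochromic_sweep,
    split_dataset,
    train_model,
)
from malphot.synthetic import all_enumerable_smiles

# small configuration keeps unit-test trainings fast; the full-size
# configuration is exercised by the acceptance suite
SMALL = dict(n_bits=256, radius=3, hidden_units=64)


def _record(smiles, eps, lam_em=None, lam_abs=None):
    return PhotophysicsRecord(
        smiles, "x", eps, lambda_abs=lam_abs, lambda_em=lam_em,
        substitution_class=SubstitutionClass.OTHER,
    )


def linear_target_records(n=500, seed=0, n_bits=256, radius=3):
    """Noiseless dataset whose target is linear in 20 bits plus 0.5 * eps."""
    rng = np.random.default_rng(seed)
    smis = all_enumerable_smiles()
    fps = {s: fingerprint_smiles(s, radius, n_bits).bits for s in smis}
    idx = rng.choice(n_bits, 20, replace=False)
    w = rng.uniform(1.0, 5.0, 20)
    eps_vals = np.array([1.88, 2.25, 4.33, 4.88, 32.7, 37.5])
    records = []
    while len(records) < n:
        s = smis[rng.integers(len(smis))]
        e = float(eps_vals[rng.integers(len(eps_vals))])
        lam = 300.0 + float(fps[s][idx] @ w) + 0.5 * e
        records.append(_record(s, e, lam_em=lam, lam_abs=lam - 50.0))
    return records


class TestSplit:
    def test_sizes_match_floor_rule(self):
        recs = list(range(258))
        train, test = split_dataset(recs, 0.9, seed=0)
        assert (len(train), len(test)) == (232, 26)

    def test_partition_is_disjoint_and_exhaustive(self):
        recs = list(range(37))
        train, test = split_dataset(recs, 0.8, seed=3)
        assert sorted(train + test) == recs

    def test_same_seed_same_partition(self):
        recs = list(range(50))
        assert split_dataset(recs, 0.9, 11) == split_dataset(recs, 0.9, 11)
        assert split_dataset(recs, 0.9, 11) != split_dataset(recs, 0.9, 12)

    def test_half_split_of_four(self):
        train, test = split_dataset([1, 2, 3, 4], 0.5, 0)
        assert len(train) == 2 and len(test) == 2

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2], 0.1, 0)


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction_is_zero(self):
        assert r_squared([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]) == 0.0

    def test_worked_value(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 2.0]) == pytest.approx(0.5)

    def test_zero_variance_convention(self):
        assert r_squared([5.0, 5.0], [4.0, 6.0]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            r_squared([1.0], [1.0, 2.0])

    def test_matches_sklearn_on_random_data(self):
        from sklearn.metrics import r2_score

        rng = np.random.default_rng(1)
        obs = rng.normal(400, 30, 50)
        pred = obs + rng.normal(0, 10, 50)
        assert r_squared(obs, pred) == pytest.approx(r2_score(obs, pred))


class TestForwardPass:
    def test_hand_set_toy_weights(self):
        # 3-bit input, 2 hidden units, identity scaling
        model = TrainedSpectralModel(
            w1=np.array([[1.0, -1.0], [0.0, 2.0], [1.0, 0.0], [0.5, 0.5]]),
            b1=np.array([0.0, -1.0]),
            w2=np.array([2.0, 3.0]),
            b2=1.0,
            x_mean=np.zeros(4),
            x_scale=np.ones(4),
            y_mean=0.0,
            y_scale=1.0,
            config=ModelConfig(n_bits=3, radius=1, hidden_units=2),
        )
        x = np.array([1.0, 0.0, 1.0, 2.0])  # bits 101, dielectric 2
        # hidden: relu([1+1+1, -1-1+1+1]) = [3, 0]; out = 2*3 + 1 = 7
        assert model.predict_features(x)[0] == pytest.approx(7.0)

    def test_equals_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        n_feat, hidden = 17, 9
        model = TrainedSpectralModel(
            w1=rng.normal(size=(n_feat, hidden)),
            b1=rng.normal(size=hidden),
            w2=rng.normal(size=hidden),
            b2=float(rng.normal()),
            x_mean=rng.normal(size=n_feat),
            x_scale=np.abs(rng.normal(size=n_feat)) + 0.5,
            y_mean=400.0,
            y_scale=25.0,
            config=ModelConfig(n_bits=16, radius=1, hidden_units=hidden),
        )
        for _ in range(20):
            x = rng.normal(size=n_feat)
            # independent element-wise computation
            z = [(x[k] - model.x_mean[k]) / model.x_scale[k] for k in range(n_feat)]
            out = model.b2
            for h in range(hidden):
                act = model.b1[h] + sum(z[k] * model.w1[k, h] for k in range(n_feat))
                out += model.w2[h] * max(act, 0.0)
            expect = out * model.y_scale + model.y_mean
            got = model.predict_features(x)[0]
            assert abs(got - expect) <= 1e-9 * max(1.0, abs(expect))


class TestTraining:
    def test_noiseless_linear_target_is_learned(self):
        records = linear_target_records(n=500, seed=0)
        cfg = ModelConfig(seed=0, **SMALL)
        model, metrics = train_model(records, cfg)
        assert metrics.r2_train >= 0.99
        # independent oracle: exact least squares on the same features
        from malphot.model import build_design_matrix

        X, y = build_design_matrix(records, cfg)
        coef, *_ = np.linalg.lstsq(np.c_[X, np.ones(len(y))], y, rcond=None)
        assert r_squared(y, np.c_[X, np.ones(len(y))] @ coef) >= 0.999

    def test_constant_target_predicts_constant(self):
        records = [
            _record(s, e, lam_em=450.0)
            for s in all_enumerable_smiles()[:30]
            for e in (1.88, 37.5)
        ]
        cfg = ModelConfig(seed=0, **SMALL, max_iterations=200)
        model, metrics = train_model(records, cfg)
        preds = [predict_wavelength(model, records[0].smiles, 4.33)]
        assert preds[0] == pytest.approx(450.0, abs=1.0)
        assert metrics.r2_train == 0.0  # zero-variance convention

    def test_seed_determinism(self, small_synthetic):
        _, _, records, _ = small_synthetic
        cfg = ModelConfig(seed=5, **SMALL, max_iterations=50)
        m1, k1 = train_model(records, cfg)
        m2, k2 = train_model(records, cfg)
        assert np.array_equal(m1.w1, m2.w1) and np.array_equal(m1.w2, m2.w2)
        assert k1.r2_test == k2.r2_test

    def test_records_missing_target_are_excluded(self, small_synthetic):
        _, _, records, _ = small_synthetic
        headless = [dataclasses.replace(r, lambda_em=None) for r in records[:5]]
        cfg = ModelConfig(seed=0, **SMALL, max_iterations=20)
        m1, _ = train_model(records[5:], cfg)
        m2, _ = train_model(headless + records[5:], cfg)
        assert np.array_equal(m1.w1, m2.w1)

    def test_all_missing_target_raises(self):
        records = [_record("O=C1NC(=O)C=C1NCC", 1.88, lam_abs=365.0)]
        with pytest.raises(ValueError, match="emission"):
            train_model(records * 20, ModelConfig(seed=0, **SMALL))

    def test_identical_query_identical_output(self, small_synthetic):
        _, _, records, _ = small_synthetic
        cfg = ModelConfig(seed=0, **SMALL, max_iterations=30)
        model, _ = train_model(records, cfg)
        smi = records[0].smiles
        assert predict_wavelength(model, smi, 4.33) == predict_wavelength(
            model, smi, 4.33
        )

    def test_capacity_one_hidden_unit_degrades_fit(self, small_synthetic):
        _, _, records, _ = small_synthetic
        cfg = ModelConfig(seed=0, **SMALL)
        m_full, k_full = train_model(records, cfg)
        cfg1 = dataclasses.replace(cfg, hidden_units=1)
        m_one, k_one = train_model(records, cfg1)
        assert k_one.r2_train < k_full.r2_train


class TestSweepAndSerialization:
    @pytest.fixture(scope="class")
    def trained(self, small_synthetic):
        _, _, records, _ = small_synthetic
        cfg = ModelConfig(seed=0, target="absorption", **SMALL)
        return train_model(records, cfg)

    def test_single_point_sweep_has_zero_delta(self, trained):
        model, _ = trained
        res = solvatochromic_sweep(model, "O=C1NC(=O)C=C1NCC", [4.33])
        assert res.delta_lambda == 0.0 and len(res.points) == 1

    def test_positive_solvatochromic_slope_recovered(self, trained, small_synthetic):
        model, _ = trained
        _, _, records, _ = small_synthetic
        am = next(r for r in records
                  if r.substitution_class is SubstitutionClass.AM)
        res = solvatochromic_sweep(model, am.smiles, [1.88, 4.33, 32.7, 37.5])
        assert res.delta_lambda > 0

    def test_unsorted_grid_rejected(self, trained):
        model, _ = trained
        with pytest.raises(ValueError):
            solvatochromic_sweep(model, "O=C1NC(=O)C=C1NCC", [4.33, 1.88])

    def test_json_roundtrip_bit_exact(self, trained, tmp_path):
        model, _ = trained
        path = tmp_path / "model.json"
        model.to_json(path)
        again = TrainedSpectralModel.from_json(path)
        x = np.r_[np.zeros(255), 1.0, 4.33]
        assert again.predict_features(x)[0] == model.predict_features(x)[0]
        assert np.array_equal(again.w1, model.w1)
        assert again.config == model.config

    def test_invalid_dielectric_rejected(self, trained):
        model, _ = trained
        with pytest.raises(ValueError):
            predict_wavelength(model, "O=C1NC(=O)C=C1NCC", 0.5)
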