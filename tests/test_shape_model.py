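import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteokit.errors import (
    ChecksumError,
    FormatVersionError,
    MinimumParameterError,
    MissingSubsetError,
    RankDeficientError,
    UnknownParameterError,
)
from osteokit.shape_model import (
    CorrespondedCloudSet,
    MorphometricVector,
    fit_full_model,
    fit_intercept_model,
    fit_subset_model,
    model_load,
    model_save,
    predict_cloud,
    residual_report,
)
from osteokit.synthetic_data import GeneratorConfig, TUBE_PARAMS, generate_population

from conftest import ols_oracle


def _random_cloudset(rng, S, P, k):
    names = [f"d{i+1}" for i in range(k)]
    D = rng.uniform(10.0, 100.0, size=(S, k))
    clouds = rng.normal(0.0, 30.0, size=(S, P, 3))
    params = [MorphometricVector(dict(zip(names, row))) for row in D]
    return CorrespondedCloudSet(
        specimen_ids=[f"s{i}" for i in range(S)], clouds=clouds,
        parameters=params)


class TestFitting:
    def test_design_matrix_is_ones_plus_parameters(self):
        train = _random_cloudset(np.random.default_rng(0), S=6, P=4, k=4)
        X = train.design_matrix(train.parameter_names)
        assert X.shape == (6, 5)
        assert np.all(X[:, 0] == 1.0)

    @pytest.mark.parametrize("S,P,k", [(6, 5, 4), (10, 40, 2), (30, 120, 3)])
    def test_fit_matches_normal_equations_oracle(self, S, P, k):
        rng = np.random.default_rng(42 + S)
        train = _random_cloudset(rng, S, P, k)
        model = fit_full_model(train)
        expected = ols_oracle(train.clouds,
                              train.design_matrix(train.parameter_names))
        got = model.full_fit.coefficients
        rel = np.abs(got - expected) / np.maximum(np.abs(expected), 1.0)
        assert rel.max() <= 1e-8

    def test_exact_recovery_zero_noise(self, tube_exact):
        pop, B_true = tube_exact
        model = fit_full_model(pop)
        assert np.abs(model.full_fit.coefficients - B_true).max() <= 1e-8

    def test_single_specimen_intercept_only_reproduces_cloud(self):
        rng = np.random.default_rng(1)
        train = _random_cloudset(rng, S=1, P=20, k=1)
        model = fit_intercept_model(train)
        cloud = predict_cloud(model, MorphometricVector({}))
        assert np.abs(cloud.points - train.clouds[0]).max() <= 1e-9
        report = residual_report(model, train)
        assert report.to_numpy().max() == 0.0

    def test_too_few_specimens_rejected(self):
        train = _random_cloudset(np.random.default_rng(2), S=4, P=5, k=4)
        with pytest.raises(RankDeficientError):
            fit_full_model(train)

    def test_collinear_parameters_rejected(self):
        rng = np.random.default_rng(3)
        train = _random_cloudset(rng, S=10, P=5, k=2)
        for pv in train.parameters:      # force exact collinearity d2 = 2 d1
            pv.values["d2"] = 2.0 * pv.values["d1"]
        with pytest.raises(RankDeficientError):
            fit_full_model(train)

    def test_parameter_recovery_improves_with_sample_size(self):
        errs = []
        for S in (10, 50, 200):
            cfg = GeneratorConfig(bone_family="tube", S=S, L=6, M=8,
                                  noise_sigma=1.0, seed=99)
            pop, B_true = generate_population(cfg)
            model = fit_full_model(pop)
            errs.append(np.sqrt(np.mean(
                (model.full_fit.coefficients - B_true) ** 2)))
        assert errs[0] > errs[1] > errs[2]


class TestSubsets:
    def test_full_subset_refit_is_identity(self, tube_noisy):
        pop, _ = tube_noisy
        model = fit_full_model(pop)
        before = model.full_fit.coefficients.copy()
        fit_subset_model(model, pop, list(pop.parameter_names))
        assert np.array_equal(model.full_fit.coefficients, before)

    def test_nested_sse_monotone_over_all_subsets(self, tube_noisy):
        pop, _ = tube_noisy
        model = fit_full_model(pop)
        names = pop.parameter_names
        sse = {}
        for r in range(1, 5):
            for sub in itertools.combinations(names, r):
                fit_subset_model(model, pop, list(sub))
                fit = model.get_fit(sub)
                sse[frozenset(sub)] = float(np.sum(fit.rmse ** 2)) * fit.S_used
        for small, big in itertools.permutations(sse, 2):
            if small < big:
                assert sse[big] <= sse[small] + 1e-9

    def test_subset_suffices_when_it_drives_shape(self):
        # only d1 has nonzero generating coefficients
        k, L, M = 4, 4, 6
        P = L * M
        rng = np.random.default_rng(10)
        B = np.zeros((P, 3, 1 + k))
        B[:, :, 0] = rng.normal(0, 5, size=(P, 3))
        B[:, :, 1] = rng.normal(0, 1, size=(P, 3))
        cfg = GeneratorConfig(bone_family="tube", S=10, L=L, M=M,
                              noise_sigma=0.0, seed=12, true_coefficients=B)
        pop, _ = generate_population(cfg)
        model = fit_full_model(pop)
        fit_subset_model(model, pop, [TUBE_PARAMS[0]])
        full_rmse = np.sqrt(np.sum(model.full_fit.rmse ** 2))
        sub_rmse = np.sqrt(np.sum(model.get_fit((TUBE_PARAMS[0],)).rmse ** 2))
        assert abs(full_rmse - sub_rmse) <= 1e-8

    def test_unknown_parameter_rejected(self, tube_noisy):
        pop, _ = tube_noisy
        model = fit_full_model(pop)
        with pytest.raises(UnknownParameterError):
            fit_subset_model(model, pop, ["femur_width"])


class TestPrediction:
    def test_prediction_at_training_point_zero_noise(self, tube_exact):
        pop, _ = tube_exact
        model = fit_full_model(pop)
        for j in (0, 3, 7):
            cloud = predict_cloud(model, pop.parameters[j])
            assert np.abs(cloud.points - pop.clouds[j]).max() <= 1e-6

    def test_partial_vector_matches_subset_oracle(self, tube_noisy):
        pop, _ = tube_noisy
        model = fit_full_model(pop)
        sub = [TUBE_PARAMS[0], TUBE_PARAMS[2]]
        patient = MorphometricVector(
            {n: pop.parameters[1].values[n] for n in sub})
        cloud = predict_cloud(model, patient)     # on-demand subset fit
        assert set(cloud.subset_used) == set(sub)
        B = ols_oracle(pop.clouds, pop.design_matrix(cloud.subset_used))
        x = np.concatenate([[1.0],
                            [patient.values[n] for n in cloud.subset_used]])
        assert np.abs(cloud.points - B @ x).max() <= 1e-6

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(alpha=st.floats(min_value=-1.0, max_value=2.0,
                           allow_nan=False, allow_infinity=False))
    def test_prediction_affine_in_patient_vector(self, tube_noisy, alpha):
        pop, _ = tube_noisy
        model = fit_full_model(pop)
        p, q = pop.parameters[0].values, pop.parameters[1].values
        mix = {n: alpha * p[n] + (1 - alpha) * q[n] for n in p}
        if any(v <= 0 for v in mix.values()):
            return
        lhs = predict_cloud(model, MorphometricVector(mix)).points
        rhs = (alpha * predict_cloud(model, MorphometricVector(p)).points
               + (1 - alpha) * predict_cloud(model, MorphometricVector(q)).points)
        assert np.abs(lhs - rhs).max() <= 1e-9 * max(1.0, np.abs(rhs).max())

    def test_missing_subset_without_training_set(self, tube_noisy):
        pop, _ = tube_noisy
        model = fit_full_model(pop, attach_training=False)
        patient = MorphometricVector({TUBE_PARAMS[0]: 350.0})
        with pytest.raises(MissingSubsetError):
            predict_cloud(model, patient)

    def test_minimum_parameter_count_enforced(self, tube_noisy):
        pop, _ = tube_noisy
        model = fit_full_model(pop, min_parameters=2)
        with pytest.raises(MinimumParameterError):
            predict_cloud(model, MorphometricVector({TUBE_PARAMS[0]: 350.0}))


class TestModelStore:
    def test_round_trip_is_bitwise_identity(self, tube_noisy, tmp_path):
        pop, _ = tube_noisy
        model = fit_full_model(pop)
        fit_subset_model(model, pop, [TUBE_PARAMS[1]])
        path = model_save(model, tmp_path / "m.json")
        loaded = model_load(path)
        assert loaded.parameter_names == model.parameter_names
        assert loaded.grid == model.grid
        for key, fit in model.coefficient_store.items():
            assert np.array_equal(loaded.coefficient_store[key].coefficients,
                                  fit.coefficients)

    def test_empty_store_rejected_at_save(self, tube_noisy, tmp_path):
        from osteokit.shape_model import ParametricBoneModel
        empty = ParametricBoneModel("b", ("d1",), P=2)
        with pytest.raises(ValueError):
            model_save(empty, tmp_path / "e.json")

    def test_hand_written_minimal_file_parses(self, tmp_path):
        # P=2, k=1 -> 2 x 3 x 2 coefficient tensor
        coeffs = [[[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
                  [[7.0, 8.0], [9.0, 10.0], [11.0, 12.0]]]
        payload = {
            "schema": "pbm-model/1", "bone_label": "toy",
            "parameter_names": ["d1"], "P": 2, "grid": None,
            "min_parameters": 1,
            "subsets": [{"params": ["d1"], "coefficients": coeffs,
                         "rmse": {"x": 0.0, "y": 0.0, "z": 0.0},
                         "S_used": 2, "cond": 1.0}],
        }
        path = tmp_path / "toy.json"
        path.write_text(json.dumps(payload))
        model = model_load(path)
        assert model.full_fit.coefficients.shape == (2, 3, 2)
        assert model.full_fit.coefficients[1, 2, 1] == 12.0

    def test_unknown_schema_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"schema": "pbm-model/99"}))
        with pytest.raises(FormatVersionError):
            model_load(path)

    def test_corrupted_file_fails_checksum(self, tube_noisy, tmp_path):
        pop, _ = tube_noisy
        path = model_save(fit_full_model(pop), tmp_path / "m.json")
        text = path.read_text().replace('"P": 192', '"P": 191')
        path.write_text(text)
        with pytest.raises((ChecksumError, Exception)):
            model_load(path)


class TestResidualReport:
    def test_zero_noise_rmse_vanishes(self, tube_exact):
        pop, _ = tube_exact
        model = fit_full_model(pop)
        report = residual_report(model, pop)
        assert report.to_numpy().max() <= 1e-8

    def test_full_column_dominates_subsets(self, tube_noisy):
        pop, _ = tube_noisy
        model = fit_full_model(pop)
        fit_subset_model(model, pop, [TUBE_PARAMS[0]])
        report = residual_report(model, pop)
        full_col = "+".join(model.full_fit.params)
        sums = (report ** 2).sum()
        assert sums[full_col] <= min(s for c, s in sums.items()
                                     if c != full_col) + 1e-12

    def test_noise_band_at_moderate_sample_size(self):
        cfg = GeneratorConfig(bone_family="tube", S=30, L=6, M=8,
                              noise_sigma=0.5, seed=21)
        pop, _ = generate_population(cfg)
        model = fit_full_model(pop)
        overall = np.sqrt(np.mean(residual_report(model, pop).to_numpy()
                                  [:, 0] ** 2))
        assert 0.25 <= overall <= 1.0
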