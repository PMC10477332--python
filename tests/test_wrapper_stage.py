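import numpy as np
import pytest

from miqfs import (FeatureMatrix, FitnessConfig, decode_particle, fitness,
                   phi_weight, select, svm_cv_accuracy, weighted_score)
from miqfs.wrapper_stage import EmptyMaskError, SvmParams


def _gaussian_table(n=200, n_features=4, gap=4.0, seed=0, n_noise=0):
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], n // 2)
    cols = [rng.normal(labels * gap, 1.0) for _ in range(n_features)]
    cols += [rng.standard_normal(n) for _ in range(n_noise)]
    names = [f"f{i}" for i in range(len(cols))]
    return FeatureMatrix(values=np.column_stack(cols), names=names,
                         labels=labels)


class TestDecodeParticle:
    def test_threshold_rule_and_parameter_slots(self):
        pos = [0.7, 0.2, 0.5, 0.49, 12.3, 0.8]
        mask, params = decode_particle(pos, 4)
        assert mask.tolist() == [True, False, True, False]
        assert params.C == 12.3 and params.sigma == 0.8

    def test_all_below_threshold_gives_empty_mask(self):
        mask, _ = decode_particle([0.49] * 3 + [1.0, 1.0], 3)
        assert mask.sum() == 0

    def test_boundary_half_counts_as_selected(self):
        mask, _ = decode_particle([0.5] * 3 + [1.0, 1.0], 3)
        assert mask.all()

    def test_wrong_length_errors(self):
        with pytest.raises(ValueError):
            decode_particle([0.5, 0.5], 3)

    def test_log_scale_mapping(self):
        _, params = decode_particle([0.9, 1.0, 0.0], 1,
                                    svm_bounds=(0.01, 100, 0.01, 100),
                                    log_scale=True)
        assert params.C == pytest.approx(10.0)
        assert params.sigma == pytest.approx(1.0)

    def test_invalid_svm_params(self):
        with pytest.raises(ValueError):
            SvmParams(C=-1.0, sigma=1.0)


class TestPhiWeight:
    def test_zero_dimension_weight_is_one(self):
        assert phi_weight(0) == 1.0

    def test_reference_value_at_100(self):
        assert phi_weight(100) == pytest.approx((9 + np.exp(-1)) / 10,
                                                abs=1e-5)

    def test_large_dimension_floor(self):
        v = phi_weight(10 ** 6)
        assert v >= 0.9
        assert v == pytest.approx(0.9, abs=1e-6)

    def test_decreasing_on_grid_with_floor(self):
        grid = np.arange(0, 100001, 100)
        vals = np.array([phi_weight(int(d)) for d in grid])
        assert np.all(np.diff(vals) <= 0)
        # strictly decreasing until float64 saturates at the 0.9 floor
        above = vals > 0.9
        assert np.all(np.diff(vals[above]) < 0)
        assert above[:10].all()
        assert np.all((vals >= 0.9) & (vals <= 1.0))

    def test_negative_dimension_errors(self):
        with pytest.raises(ValueError):
            phi_weight(-1)


class TestSvmCvAccuracy:
    def test_separable_classes_high_accuracy(self):
        F = _gaussian_table()
        mask = np.ones(4, dtype=bool)
        acc = svm_cv_accuracy(F, mask, SvmParams(1.0, 1.0), k=3, seed=0)
        assert acc >= 0.95

    def test_permuted_labels_chance_level(self):
        F = _gaussian_table()
        mask = np.ones(4, dtype=bool)
        accs = []
        for rep in range(20):
            rng = np.random.default_rng(rep)
            Fp = FeatureMatrix(values=F.values, names=F.names,
                               labels=rng.permutation(F.labels))
            accs.append(svm_cv_accuracy(Fp, mask, SvmParams(1.0, 1.0),
                                        k=3, seed=rep))
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_duplicated_column_changes_little(self):
        F = _gaussian_table(n_features=3)
        dup = FeatureMatrix(
            values=np.column_stack([F.values, F.values[:, 0]]),
            names=F.names + ["dup0"], labels=F.labels)
        base = svm_cv_accuracy(F, np.ones(3, bool), SvmParams(1.0, 1.0), 3, 0)
        with_dup = svm_cv_accuracy(dup, np.ones(4, bool),
                                   SvmParams(1.0, 1.0), 3, 0)
        assert abs(base - with_dup) <= 0.05

    def test_empty_mask_and_small_class_errors(self):
        F = _gaussian_table()
        with pytest.raises(EmptyMaskError):
            svm_cv_accuracy(F, np.zeros(4, bool), SvmParams(1.0, 1.0), 3, 0)
        tiny = _gaussian_table(n=4)
        with pytest.raises(ValueError):
            svm_cv_accuracy(tiny, np.ones(4, bool), SvmParams(1.0, 1.0),
                            k=3, seed=0)


class TestFitness:
    def test_weighted_combination_arithmetic(self):
        # CA=0.9, 20 of 100 selected (DR=0.8), d=665
        assert weighted_score(0.9, 0.8, 665) == pytest.approx(0.89001,
                                                              abs=1e-4)
        assert weighted_score(1.0, 1.0, 12345) == 1.0

    def test_empty_mask_policy_zero(self):
        F = _gaussian_table(n_features=3)
        pos = np.array([0.1, 0.1, 0.1, 1.0, 1.0])
        assert fitness(pos, F, FitnessConfig()) == 0.0
        with pytest.raises(EmptyMaskError):
            fitness(pos, F, FitnessConfig(empty_mask_policy="raise"))

    def test_fitness_increases_with_accuracy_weight(self):
        # same mask, better-separated table must not score lower
        easy = _gaussian_table(gap=6.0, seed=1)
        hard = _gaussian_table(gap=0.3, seed=1)
        pos = np.array([0.9, 0.9, 0.9, 0.9, 1.0, 1.0])
        cfg = FitnessConfig()
        assert fitness(pos, easy, cfg) >= fitness(pos, hard, cfg)


class TestSelect:
    def test_single_perfect_feature(self):
        labels = np.repeat([0, 1], 30)
        F = FeatureMatrix(values=labels[:, None].astype(float),
                          names=["perfect"], labels=labels)
        res = select(F, FitnessConfig(cv_seed=0), n_particles=10, t_max=15,
                     seed=0)
        assert res.mask.tolist() == [True]
        assert res.CA >= 0.95

    def test_result_internally_consistent(self):
        F = _gaussian_table(n_features=3, n_noise=3)
        cfg = FitnessConfig(d_original=6, cv_seed=1)
        res = select(F, cfg, n_particles=12, t_max=15, seed=1)
        phi = phi_weight(6)
        recomputed = phi * res.CA + (1 - phi) * res.DR
        assert abs(recomputed - res.fitness) <= 1e-12
        assert len(res.history) == 15
        assert np.all(np.diff(res.history) >= 0)

    def test_history_matches_final_fitness(self):
        F = _gaussian_table(n_features=2, n_noise=2)
        res = select(F, FitnessConfig(cv_seed=2), n_particles=10, t_max=12,
                     seed=2)
        assert res.history[-1] == pytest.approx(res.fitness, abs=1e-12)

    def test_reproducible(self):
        F = _gaussian_table(n_features=2, n_noise=2)
        a = select(F, FitnessConfig(cv_seed=3), n_particles=8, t_max=10,
                   seed=3)
        b = select(F, FitnessConfig(cv_seed=3), n_particles=8, t_max=10,
                   seed=3)
        assert a.mask.tolist() == b.mask.tolist()
        assert a.fitness == b.fitness
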