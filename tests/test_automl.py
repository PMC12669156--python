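import numpy as np
import pytest

from stentrisk import (
    AutoMLConfig,
    CVPlan,
    FeatureMask,
    Hyperparams,
    HyperparamSpace,
    cv_fitness,
    fit_automl,
    mask_from_position,
    smote,
    stage1_select,
    stage2_tune,
)
from stentrisk.automl import PARSIMONY_PENALTY

from conftest import make_toy_table


class TestMaskTransfer:
    def test_saturated_positions(self):
        rng = np.random.default_rng(0)
        mask = mask_from_position(np.array([10.0, 10.0, -10.0]), rng)
        assert mask.bits == (True, True, False)

    def test_all_negative_rescued_to_single_bit(self):
        rng = np.random.default_rng(1)
        mask = mask_from_position(np.array([-10.0, -12.0, -11.0]), rng)
        assert sum(mask.bits) == 1
        assert mask.bits[0]  # largest sigmoid activation

    def test_zero_position_bit_rate_is_half(self):
        # second saturated bit keeps the rescue rule out of the way
        rng = np.random.default_rng(2)
        draws = np.array(
            [mask_from_position(np.array([0.0, 10.0]), rng).bits[0]
             for _ in range(10_000)]
        )
        assert abs(draws.mean() - 0.5) < 0.02

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            mask_from_position(np.array([np.nan, 1.0]), np.random.default_rng(0))

    def test_empty_mask_construction_rejected(self):
        with pytest.raises(ValueError):
            FeatureMask((False, False))


class TestSmote:
    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = np.array([0] * 20 + [1] * 20)
        X2, y2 = smote(X, y, k=3, target_minority=20, seed=0)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(y2, y)

    def test_synthetic_points_lie_on_minority_segments(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(size=(50, 4)), rng.normal(3.0, 1.0, size=(12, 4))])
        y = np.array([0] * 50 + [1] * 12)
        X2, y2 = smote(X, y, k=5, target_minority=40, seed=2)
        Xm = X[y == 1]
        new = X2[len(X):]
        assert len(new) == 28
        for z in new:
            # z = a + u (b - a) for some minority pair: projection recovers
            # an affine coefficient in [0, 1] with negligible residual
            found = False
            for i in range(len(Xm)):
                d = z - Xm[i]
                for j in range(len(Xm)):
                    if i == j:
                        continue
                    seg = Xm[j] - Xm[i]
                    denom = seg @ seg
                    if denom == 0:
                        continue
                    u = (d @ seg) / denom
                    if -1e-10 <= u <= 1 + 1e-10 and np.linalg.norm(d - u * seg) < 1e-10:
                        found = True
                        break
                if found:
                    break
            assert found

    def test_study_scale_growth_counts(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(661, 5))
        y = np.array([1] * 103 + [0] * 558)
        X2, y2 = smote(X, y, k=5, target_minority=500, seed=4)
        assert (y2 == 1).sum() == 500
        assert (y2 == 0).sum() == 558
        np.testing.assert_array_equal(X2[:661], X)  # originals retained

    def test_tiny_minority_rejected_with_hint(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = np.array([1] * 4 + [0] * 16)
        with pytest.raises(ValueError, match="reduce k"):
            smote(X, y, k=5, target_minority=10, seed=0)


class TestCvFitness:
    plan = CVPlan(folds=3, seed=0)
    hp = Hyperparams(n_estimators=60)

    def test_noise_features_score_near_chance(self):
        fits = []
        for seed in range(3):
            tab = make_toy_table(240, 4, {}, seed=seed, intercept=-1.0)
            mask = FeatureMask((True,) * 4)
            fits.append(cv_fitness(tab, mask, self.hp, CVPlan(folds=3, seed=seed)))
        assert abs(np.mean(fits) - (0.5 - PARSIMONY_PENALTY)) < 0.06

    def test_signal_mask_beats_noise_mask(self, toy_signal_table):
        signal = FeatureMask((False, True, False, True, False, False))
        noise = FeatureMask((True, False, True, False, True, True))
        f_sig = cv_fitness(toy_signal_table, signal, self.hp, self.plan)
        f_noise = cv_fitness(toy_signal_table, noise, self.hp, self.plan)
        assert f_sig >= f_noise + 0.15

    def test_deterministic_given_seed(self, toy_signal_table):
        mask = FeatureMask((True,) * 6)
        f1 = cv_fitness(toy_signal_table, mask, self.hp, self.plan)
        f2 = cv_fitness(toy_signal_table, mask, self.hp, self.plan)
        assert f1 == f2

    def test_audit_hook_sees_disjoint_fit_and_validation_rows(self, toy_signal_table):
        seen = []

        def audit(fold, fit_rows, val_rows):
            seen.append((set(fit_rows.tolist()), set(val_rows.tolist())))

        cv_fitness(toy_signal_table, FeatureMask((True,) * 6), self.hp, self.plan,
                   audit=audit)
        assert len(seen) == 3
        covered = set()
        for fit_rows, val_rows in seen:
            assert fit_rows.isdisjoint(val_rows)
            covered |= val_rows
        assert covered == set(range(len(toy_signal_table)))

    def test_mask_length_mismatch_rejected(self, toy_signal_table):
        with pytest.raises(ValueError):
            cv_fitness(toy_signal_table, FeatureMask((True,) * 3), self.hp, self.plan)


class TestStages:
    config = AutoMLConfig(
        plan=CVPlan(folds=3, seed=0),
        stage1_pop=5, stage1_iters=4, stage2_pop=5, stage2_iters=4,
        hp_default=Hyperparams(n_estimators=60), seed=0,
    )

    def test_single_predictor_mask_is_identity(self):
        tab = make_toy_table(120, 1, {0: 2.0}, seed=5)
        mask, _ = stage1_select(tab, self.config.hp_default, self.config.plan, self.config)
        assert mask.bits == (True,)

    def test_stage1_budget_monotonicity(self, toy_signal_table):
        trace: list = []
        stage1_select(toy_signal_table, self.config.hp_default, self.config.plan,
                      self.config, record_trace=trace)
        assert all(a <= b for a, b in zip(trace, trace[1:]))

    def test_stage1_mask_at_least_as_fit_as_full_mask(self, toy_signal_table):
        mask, fit = stage1_select(toy_signal_table, self.config.hp_default,
                                  self.config.plan, self.config)
        full_fit = cv_fitness(toy_signal_table, FeatureMask((True,) * 6),
                              self.config.hp_default, self.config.plan)
        assert fit >= full_fit - 0.02

    def test_stage2_point_in_space_and_not_worse_than_default(self, toy_signal_table):
        space = HyperparamSpace()
        mask = FeatureMask((False, True, False, True, False, False))
        hp, fit = stage2_tune(toy_signal_table, mask, space, self.config.plan, self.config)
        assert space.contains(hp)
        default_fit = cv_fitness(toy_signal_table, mask, self.config.hp_default,
                                 self.config.plan)
        assert fit >= default_fit - 1e-9


class TestFitAutoml:
    def test_end_to_end_contract(self, toy_signal_table):
        cfg = AutoMLConfig(plan=CVPlan(folds=3, seed=1),
                           stage1_pop=4, stage1_iters=3, stage2_pop=4, stage2_iters=3,
                           hp_default=Hyperparams(n_estimators=60), seed=1)
        model = fit_automl(toy_signal_table, cfg)
        p = model.predict_proba(toy_signal_table)
        assert ((p >= 0) & (p <= 1)).all()
        assert model.mask.n_selected >= 1

        model2 = fit_automl(toy_signal_table, cfg)
        assert model2.mask.bits == model.mask.bits
        assert model2.hyperparams == model.hyperparams
        assert model2.cv_score == model.cv_score
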