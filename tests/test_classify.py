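"""Classification contracts: LOMO fold hygiene, AUROC oracle equivalence,
bootstrap coverage, variant aggregation, and calibration closed forms."""

import numpy as np
import pandas as pd
import pytest

from confvar.classify import (CvFold, aggregate_variant, auroc, bootstrap_ci,
                              calibration_report, fit_and_predict, lomo_split,
                              make_model)
from confvar.features import DESCRIPTOR_COLUMNS, FeatureMatrix


def toy_fm(rng, n_variants=4, frames=40, shift=6.0, labels=None):
    """Per-variant Gaussian features; pathogenic variants shifted in the
    first descriptor by ``shift`` standard deviations."""
    if labels is None:
        labels = [0, 0, 1, 1][:n_variants]
    rows = []
    for v in range(n_variants):
        X = rng.normal(size=(frames, 5))
        X[:, 0] += shift * labels[v]
        for f in range(frames):
            rows.append({"variant": f"V{v}", "label": labels[v], "depth": 0,
                         "seed": 0, "frame": f,
                         **dict(zip(DESCRIPTOR_COLUMNS, X[f]))})
    return FeatureMatrix(pd.DataFrame(rows))


class TestLomoSplit:
    def test_one_fold_per_variant_partition(self, rng):
        fm = toy_fm(rng, n_variants=6, labels=[0, 0, 0, 1, 1, 1])
        folds = lomo_split(fm)
        assert len(folds) == 6
        all_test = np.concatenate([f.test_idx for f in folds])
        assert sorted(all_test) == list(range(fm.n))

    def test_no_leakage_of_held_out_variant(self, rng):
        fm = toy_fm(rng)
        for fold in lomo_split(fm):
            train_variants = set(fm.variants[fold.train_idx])
            assert fold.held_out_variant not in train_variants

    def test_single_variant_rejected(self, rng):
        fm = toy_fm(rng, n_variants=2, labels=[0, 1])
        fm.data["variant"] = "ONLY"
        with pytest.raises(ValueError):
            lomo_split(fm)


class TestFitAndPredict:
    def test_separable_construction_perfect_auroc(self, rng):
        fm = toy_fm(rng, shift=6.0)
        res = fit_and_predict(lomo_split(fm), fm, "rf", rng_seed=0,
                              n_bootstrap=100)
        assert res.auroc == 1.0

    def test_permuted_labels_null_auroc(self, rng):
        """Frame-level permuted labels decouple features from class:
        pooled AUROC lands near chance."""
        fm = toy_fm(rng, n_variants=6, frames=840, shift=6.0,
                    labels=[0, 0, 0, 1, 1, 1])
        fm.data["label"] = rng.permutation(fm.data["label"].to_numpy())
        res = fit_and_predict(lomo_split(fm), fm, "lr", rng_seed=0,
                              n_bootstrap=100)
        assert abs(res.auroc - 0.5) < 0.05

    def test_seeded_determinism(self, rng):
        fm = toy_fm(rng)
        folds = lomo_split(fm)
        a = fit_and_predict(folds, fm, "rf", rng_seed=42, n_bootstrap=100)
        b = fit_and_predict(folds, fm, "rf", rng_seed=42, n_bootstrap=100)
        assert np.array_equal(a.oof_probs, b.oof_probs)
        assert a.ci == b.ci

    def test_single_class_training_fold_rejected(self, rng):
        fm = toy_fm(rng, n_variants=2, labels=[0, 1])
        with pytest.raises(ValueError, match="single-class"):
            fit_and_predict(lomo_split(fm), fm, "lr", n_bootstrap=100)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            make_model("gradient_descent_into_madness")

    def test_deliberate_leakage_inflates_auroc(self, rng):
        """Sanity check that the LOMO protocol is doing real work: on a task
        where labels are variant-specific but features carry no class signal,
        honest folds give chance AUROC while leaked folds (held-out frames
        present in training) inflate it."""
        labels = [0, 1, 0, 1, 0, 1]
        fm = toy_fm(rng, n_variants=6, frames=60, shift=0.0, labels=labels)
        # give each variant a distinct feature centroid (identity signal)
        for v in range(6):
            fm.data.loc[fm.data.variant == f"V{v}", DESCRIPTOR_COLUMNS] += 4 * v
        honest = fit_and_predict(lomo_split(fm), fm, "rf", rng_seed=0,
                                 n_bootstrap=100)
        leaked_folds = [CvFold(f.held_out_variant, np.arange(fm.n), f.test_idx)
                        for f in lomo_split(fm)]
        leaked = fit_and_predict(leaked_folds, fm, "rf", rng_seed=0,
                                 n_bootstrap=100)
        assert leaked.auroc > honest.auroc + 0.3


class TestAuroc:
    def test_perfect_ranking(self):
        assert auroc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_concordant(self):
        assert auroc([0.9, 0.3, 0.8, 0.2], [1, 1, 0, 0]) == 0.75

    def test_matches_pair_enumeration(self, rng):
        """O(n^2) oracle: concordant pairs + half ties."""
        scores = rng.choice(np.linspace(0, 1, 25), size=200)  # forces ties
        labels = rng.integers(0, 2, size=200)
        pos, neg = scores[labels == 1], scores[labels == 0]
        brute = np.mean((pos[:, None] > neg[None, :])
                        + 0.5 * (pos[:, None] == neg[None, :]))
        assert auroc(scores, labels) == pytest.approx(brute, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=300)
        labels = rng.integers(0, 2, size=300)
        a = auroc(scores, labels)
        assert auroc(np.exp(scores), labels) == pytest.approx(a, abs=1e-12)
        assert auroc(3 * scores - 7, labels) == pytest.approx(a, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.9], [1, 1])


class TestBootstrapCi:
    def test_constant_data_zero_width(self):
        df = pd.DataFrame({"v": np.full(50, 3.3)})
        lo, hi = bootstrap_ci(lambda d: float(d["v"].mean()), df,
                              n_replicates=200, rng_seed=0)
        assert lo == hi == pytest.approx(3.3)

    def test_coverage_of_the_mean(self):
        """~95% of intervals cover the true mean (tolerance 3%)."""
        rng = np.random.default_rng(0)
        covered = 0
        for rep in range(200):
            df = pd.DataFrame({"v": rng.normal(size=500)})
            lo, hi = bootstrap_ci(lambda d: float(d["v"].mean()), df,
                                  n_replicates=300, rng_seed=rep)
            covered += lo <= 0.0 <= hi
        assert abs(covered / 200 - 0.95) <= 0.03

    def test_replicate_count_convergence(self, rng):
        """1000 vs 2000 replicates agree within 0.01 per endpoint."""
        df = pd.DataFrame({"v": rng.normal(size=400)})
        a = bootstrap_ci(lambda d: float(d["v"].mean()), df,
                         n_replicates=1000, rng_seed=1)
        b = bootstrap_ci(lambda d: float(d["v"].mean()), df,
                         n_replicates=2000, rng_seed=2)
        assert abs(a[0] - b[0]) < 0.01 and abs(a[1] - b[1]) < 0.01

    def test_hierarchical_resamples_segments(self, rng):
        df = pd.DataFrame({
            "variant": np.repeat(["A", "B"], 50),
            "depth": 0, "seed": np.tile(np.repeat([0, 1], 25), 2),
            "v": rng.normal(size=100)})
        lo, hi = bootstrap_ci(lambda d: float(d["v"].mean()), df,
                              n_replicates=200, rng_seed=0,
                              scheme="hierarchical")
        assert lo < df["v"].mean() < hi

    def test_too_few_replicates_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_ci(lambda d: 0.0, pd.DataFrame({"v": [1.0]}),
                         n_replicates=10)


class TestAggregateVariant:
    def _table(self, probs):
        n = len(probs)
        return pd.DataFrame({"variant": "V", "depth": 0,
                             "seed": np.arange(n) % 2, "prob": probs})

    def test_constant_probabilities(self):
        s = aggregate_variant(self._table(np.full(20, 0.7)), n_bootstrap=100)
        assert s.mean_prob == pytest.approx(0.7)
        assert s.ci == (pytest.approx(0.7), pytest.approx(0.7))

    def test_arithmetic_mean(self):
        s = aggregate_variant(self._table([0.2, 0.4, 0.6, 0.8]), n_bootstrap=100)
        assert s.mean_prob == pytest.approx(0.5)

    def test_hierarchical_coverage_of_planted_mean(self):
        """CI covers the true Beta mean in roughly 95% of replications."""
        rng = np.random.default_rng(3)
        true_mean = 2 / (2 + 3)
        covered = 0
        for rep in range(100):
            probs = rng.beta(2, 3, size=200)
            s = aggregate_variant(self._table(probs), rng_seed=rep,
                                  n_bootstrap=300)
            covered += s.ci[0] <= true_mean <= s.ci[1]
        assert abs(covered / 100 - 0.95) <= 0.05


class TestCalibrationReport:
    def test_perfect_predictor(self):
        labels = np.array([0, 1, 0, 1, 1, 0])
        rep = calibration_report(labels.astype(float), labels)
        assert rep.brier == 0.0
        assert rep.ece == pytest.approx(0.0)
        assert rep.mcc == 1.0
        assert rep.balanced_accuracy == 1.0

    def test_constant_half_on_balanced_labels(self):
        labels = np.array([0, 1] * 50)
        rep = calibration_report(np.full(100, 0.5), labels)
        assert rep.brier == pytest.approx(0.25)

    def test_calibrated_by_construction_low_ece(self):
        """Predictor emitting true Bernoulli parameters: ECE below 0.02."""
        rng = np.random.default_rng(7)
        p = rng.uniform(size=20_000)
        y = rng.binomial(1, p)
        rep = calibration_report(p, y)
        assert rep.ece < 0.02

    def test_brier_bounds_calibration_term(self):
        """Brier >= its calibration component for any predictor."""
        rng = np.random.default_rng(11)
        p = rng.uniform(size=5000)
        y = rng.binomial(1, np.clip(p + rng.normal(0, 0.2, 5000), 0, 1))
        rep = calibration_report(p, y)
        cal_term = np.nansum(rep.bin_counts / len(p)
                             * (rep.bin_mean_pred - rep.bin_frac_pos) ** 2)
        assert rep.brier >= cal_term - 1e-12

    def test_bin_counts_sum_to_n(self, rng):
        p = rng.uniform(size=512)
        rep = calibration_report(p, rng.integers(0, 2, 512))
        assert rep.bin_counts.sum() == 512

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            calibration_report(np.array([]), np.array([]))
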