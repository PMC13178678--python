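import math

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.metrics import average_precision_score, roc_auc_score

from ecgkit.exceptions import (
    AlignmentError,
    InstabilityError,
    ParameterError,
    UndefinedMetricError,
)
from ecgkit.metrics import (
    auroc,
    auprc,
    auroc_variance,
    binary_rates,
    bootstrap_ci,
    continuous_nri,
    delong_test,
    optimize_thresholds,
    rank_metrics,
    regression_mae,
    weighted_brier,
)
from ecgkit.synth import AuditCohortSpec, simulate_audit_cohort

from conftest import make_prediction_set


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def pairwise_auroc(scores, truths):
    """Brute-force concordant-pair count with ties worth 1/2."""
    pos = [s for s, t in zip(scores, truths) if t == 1]
    neg = [s for s, t in zip(scores, truths) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def placement_covariance_oracle(scores, truths):
    """Explicit double-loop DeLong variance of one AUROC."""
    pos = [s for s, t in zip(scores, truths) if t == 1]
    neg = [s for s, t in zip(scores, truths) if t == 0]
    m, n = len(pos), len(neg)
    psi = lambda x, y: 1.0 if x > y else (0.5 if x == y else 0.0)
    v10 = [sum(psi(p, q) for q in neg) / n for p in pos]
    v01 = [sum(psi(p, q) for p in pos) / m for q in neg]
    s10 = sum((v - sum(v10) / m) ** 2 for v in v10) / (m - 1)
    s01 = sum((v - sum(v01) / n) ** 2 for v in v01) / (n - 1)
    return s10 / m + s01 / n


class TestAuroc:
    def test_hand_example(self):
        assert auroc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) == 0.75

    def test_all_ties_give_half(self):
        assert auroc([0.3] * 6, [1, 0, 1, 0, 0, 1]) == 0.5

    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        truths = [1, 1, 0, 0]
        assert auroc(scores, truths) == 1.0
        assert auprc(scores, truths) == 1.0

    @pytest.mark.parametrize("seed", range(40))
    def test_equals_bruteforce_pairwise_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = rng.choice(np.linspace(0, 1, 21), size=n)  # force ties
        truths = rng.integers(0, 2, size=n)
        if truths.min() == truths.max():
            truths[0] = 1 - truths[0]
        assert auroc(scores, truths) == pairwise_auroc(scores, truths)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_sklearn(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = rng.random(150)
        truths = rng.integers(0, 2, size=150)
        if truths.min() == truths.max():
            truths[0] = 1 - truths[0]
        assert auroc(scores, truths) == pytest.approx(
            roc_auc_score(truths, scores), abs=1e-12
        )

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.1, 0.2], [1, 1])


class TestRankMetrics:
    def test_micro_flattens_matrices(self):
        preds = make_prediction_set(
            [[0.9, 0.2], [0.1, 0.7], [0.8, 0.3]], [[1, 0], [0, 1], [1, 1]]
        )
        frame = rank_metrics(preds, "micro")
        assert frame.loc["micro", "auroc"] == pairwise_auroc(
            preds.scores.ravel(), preds.truths.ravel()
        )

    def test_micro_equals_per_label_on_single_label(self):
        preds = make_prediction_set([[0.9], [0.1], [0.4], [0.6]], [[1], [0], [0], [1]])
        micro = rank_metrics(preds, "micro").loc["micro"]
        per = rank_metrics(preds, "per_label").iloc[0]
        assert micro["auroc"] == per["auroc"]
        assert micro["auprc"] == per["auprc"]

    def test_macro_is_mean_of_labels(self):
        preds = make_prediction_set(
            [[0.9, 0.2], [0.1, 0.7], [0.8, 0.3], [0.2, 0.9]],
            [[1, 0], [0, 1], [1, 0], [0, 1]],
        )
        per = rank_metrics(preds, "per_label")
        macro = rank_metrics(preds, "macro")
        assert macro.loc["macro", "auroc"] == pytest.approx(per["auroc"].mean())

    def test_auprc_is_step_integral(self):
        scores = [0.9, 0.8, 0.7, 0.1]
        truths = [1, 0, 1, 0]
        # hand enumeration: precision at each positive, in rank order
        # rank 1 (0.9, +): P = 1/1; rank 3 (0.7, +): P = 2/3
        expected = (1.0 + 2.0 / 3.0) / 2.0
        assert auprc(scores, truths) == pytest.approx(expected)
        assert auprc(scores, truths) == average_precision_score(truths, scores)


class TestBootstrap:
    def test_constant_metric_gives_zero_width(self):
        preds = make_prediction_set([[1.0], [0.0]] * 10, [[1], [0]] * 10)
        result = bootstrap_ci(preds, "auroc", n_iter=50, seed=1)
        assert result.ci_low == result.ci_high == result.estimate == 1.0

    def test_seed_reproducible(self):
        preds, _, _ = simulate_audit_cohort(AuditCohortSpec(n_records=100, seed=3))
        a = bootstrap_ci(preds, "auroc", n_iter=100, seed=9)
        b = bootstrap_ci(preds, "auroc", n_iter=100, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_ci_contains_point_estimate(self):
        preds, _, _ = simulate_audit_cohort(AuditCohortSpec(n_records=150, seed=4))
        r = bootstrap_ci(preds, "auprc", n_iter=200, seed=2)
        assert r.ci_low <= r.estimate <= r.ci_high

    def test_width_contracts_with_n(self):
        widths = {}
        for n in (100, 10000):
            preds, _, _ = simulate_audit_cohort(AuditCohortSpec(n_records=n, seed=8))
            r = bootstrap_ci(preds, "auroc", n_iter=200, seed=5)
            widths[n] = r.ci_high - r.ci_low
        assert widths[10000] < widths[100]

    def test_instability_error_on_fragile_metric(self):
        # one positive record: most resamples lose it entirely
        scores = [[0.9]] + [[0.1]] * 20
        truths = [[1]] + [[0]] * 20
        preds = make_prediction_set(scores, truths)
        with pytest.raises(InstabilityError):
            bootstrap_ci(preds, "auroc", n_iter=100, fraction=0.3, seed=0, replace=False)


class TestDelong:
    def test_identical_scores_give_p_one(self):
        truths = [1, 0, 1, 0, 1]
        s = [0.9, 0.1, 0.7, 0.4, 0.6]
        result = delong_test(s, s, truths)
        assert result.delta == 0.0
        assert result.p_value == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_variance_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        scores = rng.choice(np.linspace(0, 1, 11), size=n)
        truths = rng.integers(0, 2, size=n)
        if truths.sum() < 2 or truths.sum() > n - 2:
            truths[:2] = [0, 1]
        assert auroc_variance(scores, truths) == pytest.approx(
            placement_covariance_oracle(scores, truths), abs=1e-10
        )

    def test_separated_vs_random_is_significant(self):
        rng = np.random.default_rng(0)
        truths = rng.integers(0, 2, size=2000)
        strong = np.clip(truths + rng.normal(0, 0.1, 2000), 0, 1)
        noise = rng.random(2000)
        assert delong_test(strong, noise, truths).p_value < 1e-6

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        truths = rng.integers(0, 2, size=300)
        a = rng.random(300)
        b = rng.random(300)
        base = delong_test(a, b, truths)
        mono = delong_test(np.exp(3 * a), np.exp(3 * b), truths)
        assert mono.p_value == pytest.approx(base.p_value, abs=1e-12)
        assert mono.delta == pytest.approx(base.delta, abs=1e-12)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            delong_test([0.1, 0.2], [0.3], [1, 0])


class TestThresholds:
    def test_scores_equal_truths_give_half(self):
        preds = make_prediction_set([[0.0], [1.0], [0.0], [1.0]], [[0], [1], [0], [1]])
        table = optimize_thresholds(preds)
        row = table.table.iloc[0]
        assert row["threshold"] == 0.5
        assert row["sensitivity"] == 1.0 and row["specificity"] == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_achieves_minimal_balance_gap_exhaustively(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        truths = np.concatenate([np.ones(30), np.zeros(30)]).astype(int)
        scores = np.clip(
            np.where(truths == 1, rng.normal(0.6, 0.15, n), rng.normal(0.4, 0.15, n)),
            0, 1,
        )
        preds = make_prediction_set(scores[:, None], truths[:, None])
        chosen = optimize_thresholds(preds).table.iloc[0]
        # exhaustive candidate scan oracle
        distinct = np.unique(scores)
        candidates = np.concatenate(([0.0], (distinct[:-1] + distinct[1:]) / 2, [1.0]))
        gaps = []
        for t in candidates:
            d = scores >= t
            sens = d[truths == 1].mean()
            spec = (~d[truths == 0]).mean()
            gaps.append(abs(sens - spec))
        assert abs(chosen["sensitivity"] - chosen["specificity"]) <= min(gaps) + 1e-12

    def test_label_polarity_swaps_operating_point(self):
        rng = np.random.default_rng(3)
        scores = rng.random(80)
        truths = (scores + rng.normal(0, 0.3, 80) > 0.5).astype(int)
        if truths.min() == truths.max():
            truths[:2] = [0, 1]
        fwd = optimize_thresholds(
            make_prediction_set(scores[:, None], truths[:, None])
        ).table.iloc[0]
        rev = optimize_thresholds(
            make_prediction_set(1 - scores[:, None], 1 - truths[:, None])
        ).table.iloc[0]
        # reversing polarity maps (sens, spec) onto (spec, sens) up to the
        # >=-vs-< asymmetry at tied scores; none are tied here
        assert rev["sensitivity"] == pytest.approx(fwd["specificity"], abs=1e-12)
        assert rev["specificity"] == pytest.approx(fwd["sensitivity"], abs=1e-12)

    def test_single_class_label_named_in_error(self):
        preds = make_prediction_set([[0.2], [0.4]], [[1], [1]], labels=["lonely"])
        with pytest.raises(UndefinedMetricError, match="lonely"):
            optimize_thresholds(preds)


class TestBinaryRates:
    def test_quoted_formulas(self):
        decisions = np.array([1] * 8 + [0] * 2 + [1] * 1 + [0] * 9)
        truths = np.array([1] * 10 + [0] * 10)
        rates = binary_rates(decisions, truths)
        assert rates.tpr == pytest.approx(0.8)
        assert rates.fpr == pytest.approx(0.1)
        assert (rates.tp, rates.fn, rates.fp, rates.tn) == (8, 2, 1, 9)

    def test_all_correct(self):
        rates = binary_rates([1, 0, 1, 0], [1, 0, 1, 0])
        assert rates.tpr == 1.0 and rates.fpr == 0.0

    def test_undefined_rates_flagged(self):
        rates = binary_rates([1, 0], [0, 0])
        assert not rates.tpr_defined and math.isnan(rates.tpr)
        rates = binary_rates([1, 0], [1, 1])
        assert not rates.fpr_defined and math.isnan(rates.fpr)


class TestNri:
    def test_equal_scores_give_zero(self):
        s = [0.1, 0.5, 0.9]
        assert continuous_nri(s, s, [1, 0, 1]) == 0.0

    def test_maximum_is_two(self):
        old = [0.5] * 6
        new = [0.9, 0.9, 0.9, 0.1, 0.1, 0.1]
        truths = [1, 1, 1, 0, 0, 0]
        assert continuous_nri(new, old, truths) == 2.0

    def test_ten_record_hand_case(self):
        # 3 events: 2 up, 1 down; 7 nonevents: 3 down, 4 up
        truths = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        old = [0.5] * 10
        new = [0.6, 0.7, 0.4, 0.4, 0.3, 0.2, 0.6, 0.7, 0.8, 0.9]
        expected = (2 / 3 - 1 / 3) + (3 / 7 - 4 / 7)
        assert continuous_nri(new, old, truths) == pytest.approx(expected)
        assert continuous_nri(new, old, truths) == pytest.approx(0.19047619, abs=1e-6)


class TestWeightedBrier:
    def test_perfect_probabilities_give_zero(self):
        preds = make_prediction_set([[1.0, 0.0], [0.0, 1.0]], [[1, 0], [0, 1]])
        assert weighted_brier(preds, np.array([1.0, 1.0])) == 0.0

    def test_uninformative_half_is_quarter_for_any_weights(self):
        preds = make_prediction_set([[0.5, 0.5]] * 4, [[1, 0], [0, 1], [1, 1], [0, 0]])
        for w in ([1.0, 1.0], [3.0, 1.0], [0.2, 5.0]):
            assert weighted_brier(preds, np.array(w)) == pytest.approx(0.25)

    def test_weighted_mean_of_per_label_briers(self):
        # Brier_1 = 0.1, Brier_2 = 0.3, weights 3:1 -> 0.15
        s1 = 1 - math.sqrt(0.1)
        s2 = 1 - math.sqrt(0.3)
        preds = make_prediction_set([[s1, s2]], [[1, 1]])
        assert weighted_brier(preds, np.array([3.0, 1.0])) == pytest.approx(0.15)

    def test_inverse_prevalence_default(self):
        preds = make_prediction_set(
            [[0.8, 0.5], [0.2, 0.5], [0.7, 0.5], [0.6, 0.5]],
            [[1, 1], [0, 0], [1, 0], [1, 0]],
        )
        briers = ((preds.scores - preds.truths) ** 2).mean(axis=0)
        prevalence = preds.truths.mean(axis=0)
        w = 1 / prevalence
        assert weighted_brier(preds) == pytest.approx(np.sum(w * briers) / w.sum())

    def test_zero_prevalence_with_inverse_weights_rejected(self):
        preds = make_prediction_set([[0.5, 0.5]] * 3, [[1, 0], [0, 0], [1, 0]])
        with pytest.raises(UndefinedMetricError):
            weighted_brier(preds)


class TestMae:
    def test_examples(self):
        assert regression_mae([1, 2, 3], [1, 2, 3]) == 0.0
        assert regression_mae([6, 7, 8], [1, 2, 3]) == 5.0
        assert regression_mae([1, 2, 3], [2, 0, 3]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            regression_mae([], [])


class TestBootstrapCoverage:
    def test_ci_covers_analytic_auroc(self):
        # small-scale version of the coverage experiment: 25 cohorts
        spec = AuditCohortSpec(n_records=300, label_prevalences=(0.5,),
                               pos_loc=1.0, neg_loc=0.0)
        target = spec.analytic_auroc()
        assert target == pytest.approx(norm.cdf(1 / math.sqrt(2)))
        covered = 0
        rng = np.random.default_rng(17)
        for _ in range(25):
            preds, _, _ = simulate_audit_cohort(
                AuditCohortSpec(
                    n_records=300, label_prevalences=(0.5,),
                    pos_loc=1.0, neg_loc=0.0, seed=int(rng.integers(2**31 - 1)),
                )
            )
            r = bootstrap_ci(preds, "auroc", n_iter=250, seed=int(rng.integers(2**31 - 1)))
            covered += r.ci_low <= target <= r.ci_high
        assert covered >= 21
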