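"""Confusion metrics, nonparametric ROC/AUC, majority voting, reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import ramanscreen as rs
from ramanscreen.datasets import REFERENCE_EXTERNAL_VOTES, load_reference_votes
from ramanscreen.evaluate_report import votes_to_frame


def mann_whitney_auc(scores, labels):
    """All-pairs counting oracle: P(pos > neg) + 0.5 P(pos == neg)."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "tp,fn,tn,fp,expected",
        [
            (9, 1, 8, 2, (0.9, 0.8, 0.85)),
            (10, 0, 10, 0, (1.0, 1.0, 1.0)),
            (10, 0, 0, 10, (1.0, 0.0, 0.5)),
        ],
    )
    def test_direct_from_definitions(self, tp, fn, tn, fp, expected):
        y_true = np.array(["cancer"] * (tp + fn) + ["healthy"] * (tn + fp))
        y_pred = np.array(
            ["cancer"] * tp + ["healthy"] * fn + ["healthy"] * tn + ["cancer"] * fp
        )
        out = rs.confusion_metrics(y_true, y_pred, positive="cancer")
        assert out == pytest.approx(expected)

    def test_absent_positive_class_rejected(self):
        y = np.array(["healthy", "healthy"])
        with pytest.raises(ValueError, match="absent"):
            rs.confusion_metrics(y, y, positive="cancer")


class TestRocAuc:
    def test_worked_example_auc_075(self):
        """Positives {0.9, 0.4} vs negatives {0.5, 0.1}: 3 of 4 pairs won."""
        scores = np.array([0.9, 0.4, 0.5, 0.1])
        labels = np.array([True, True, False, False])
        _, _, auc = rs.roc_auc(scores, labels)
        assert auc == pytest.approx(0.75)

    def test_all_tied_scores_give_half(self):
        scores = np.full(10, 3.3)
        labels = np.array([True] * 4 + [False] * 6)
        _, _, auc = rs.roc_auc(scores, labels)
        assert auc == pytest.approx(0.5)

    def test_perfect_ordering_gives_one(self):
        scores = np.concatenate([np.linspace(0.6, 1, 5), np.linspace(0, 0.4, 5)])
        labels = np.array([True] * 5 + [False] * 5)
        _, _, auc = rs.roc_auc(scores, labels)
        assert auc == 1.0

    @pytest.mark.parametrize("n,seed", [(20, 0), (57, 1), (200, 2), (150, 3)])
    def test_equals_all_pairs_mann_whitney_counting(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=n), 2)  # rounding forces ties
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        _, _, auc = rs.roc_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rs.roc_auc(np.array([1.0, 2.0]), np.array([True, True]))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(-20, 20), st.booleans()), min_size=4, max_size=60
        )
    )
    def test_mann_whitney_identity_holds_for_arbitrary_tied_scores(self, pairs):
        """AUC equals all-pairs counting on any score/label configuration."""
        scores = np.array([p for p, _ in pairs], dtype=float) / 4.0
        labels = np.array([b for _, b in pairs])
        assume(labels.any() and not labels.all())
        _, _, auc = rs.roc_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)


class TestMajorityVote:
    def test_reference_verification_table_all_15_samples_correct(self):
        """The published 15-sample external-verification count triplets all
        vote for their true class."""
        for sample, healthy, benign, cancer, true_class in REFERENCE_EXTERNAL_VOTES:
            predicted, tie = rs.majority_vote(
                {"healthy": healthy, "benign": benign, "cancer": cancer}
            )
            assert predicted == true_class, f"sample {sample}"
            assert not tie

    def test_tie_breaks_lexicographically_and_flags(self):
        predicted, tie = rs.majority_vote({"b": 5, "a": 5})
        assert predicted == "a"
        assert tie

    def test_invariant_to_positive_scaling(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            counts = {c: int(rng.integers(0, 50)) for c in ("healthy", "benign", "cancer")}
            if sum(counts.values()) == 0:
                counts["healthy"] = 1
            k = int(rng.integers(1, 9))
            scaled = {c: k * v for c, v in counts.items()}
            assert rs.majority_vote(counts) == rs.majority_vote(scaled)

    def test_empty_or_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            rs.majority_vote({})
        with pytest.raises(ValueError):
            rs.majority_vote({"healthy": 0, "cancer": 0})

    def test_reference_table_loads_as_frame(self):
        df = load_reference_votes()
        assert df.shape == (15, 5)
        assert (df[["healthy", "benign", "cancer"]].sum(axis=1) == 1500).all()


class TestMetricsSummary:
    def test_rejects_out_of_range_values(self):
        with pytest.raises(ValueError):
            rs.MetricsSummary("c", [1.1], [0.5], [0.5], [0.5])

    def test_mean_sd_and_formatting(self):
        m = rs.MetricsSummary("cancer_vs_healthy", [0.9, 1.0], [0.8, 0.9], [0.85, 0.95], [0.97, 0.99])
        assert m.mean("auc") == pytest.approx(0.98)
        assert m.sd("sensitivity") == pytest.approx(np.std([0.9, 1.0], ddof=1))
        assert "±" in m.summary_row()["auc"]


@pytest.fixture(scope="module")
def separable_external(coarse_grid):
    peaks = (
        rs.PeakSpec(800.0, 8.0, 400.0, {"benign": 1.6}),
        rs.PeakSpec(1200.0, 8.0, 600.0, {"cancer": 2.0}),
        rs.PeakSpec(1500.0, 8.0, 300.0),
    )
    cfg = rs.CohortConfig(
        n_per_group={"healthy": 4, "benign": 4, "cancer": 4},
        peaks=peaks, noise_sd=2.0, baseline_scale=0.0,
        background_amplitude=0.0, spike_rate=0.0, subject_effect_sd=0.02, seed=61,
    )
    cohort, _ = rs.generate_cohort(cfg, coarse_grid)
    external, truth = rs.generate_external_set(
        cfg, coarse_grid, {"healthy": 2, "benign": 2, "cancer": 2}
    )
    mask = rs.stability_select(
        cohort, ("healthy", "benign", "cancer"), n_repeats=20, min_hits=14, seed=1
    )
    x, y = rs.apply_mask(cohort, mask)
    model = rs.train_rbf_svm(
        x, y, rs.ClassifierSpec(C_grid=(1.0, 10.0), gamma_grid=(0.01, 0.1)), seed=0
    )
    return model, external, mask, truth


class TestExternalValidate:
    def test_blinded_separable_external_set_fully_correct(self, separable_external):
        model, external, mask, truth = separable_external
        votes = rs.external_validate(model, external, mask, truth.labels)
        assert len(votes) == 6
        assert all(v.correct for v in votes)
        assert all(sum(v.counts.values()) == 15 for v in votes)

    def test_vote_counts_scale_with_ensemble_size(self, separable_external):
        model, external, mask, truth = separable_external
        votes = rs.external_validate([model, model], external, mask, truth.labels)
        assert all(sum(v.counts.values()) == 30 for v in votes)

    def test_blinding_keeps_truth_unknown_without_unblinding_map(self, separable_external):
        model, external, mask, _ = separable_external
        votes = rs.external_validate(model, external, mask)
        assert all(v.true_class == "unknown" and v.correct is None for v in votes)


class TestRenderReport:
    def test_metrics_csv_roundtrip_and_vote_rows(self, tmp_path):
        m = rs.MetricsSummary(
            "cancer_vs_healthy",
            [0.9, 0.95], [0.8, 0.85], [0.85, 0.9], [0.97, 0.98],
        )
        votes = [
            rs.VoteRecord("s1", {"healthy": 12, "cancer": 3}, "healthy", "healthy"),
            rs.VoteRecord("s2", {"healthy": 2, "cancer": 13}, "cancer", "cancer"),
        ]
        fpr, tpr, auc = rs.roc_auc(
            np.array([0.9, 0.8, 0.3, 0.2]), np.array([True, True, False, False])
        )
        written = rs.render_report(
            tmp_path, metrics=[m], votes=votes, roc_curves={"cancer_vs_healthy": (fpr, tpr, auc)}
        )
        per_repeat = pd.read_csv(written["metrics_per_repeat"])
        np.testing.assert_allclose(per_repeat["auc"], [0.97, 0.98], atol=1e-9)
        vote_df = pd.read_csv(written["votes"])
        assert len(vote_df) == 2
        assert written["roc_overlay"].exists()

    def test_votes_frame_has_one_row_per_sample(self):
        votes = [
            rs.VoteRecord(f"s{i}", {"healthy": 10 + i, "cancer": 5 - i}, "healthy", "unknown")
            for i in range(5)
        ]
        assert len(votes_to_frame(votes)) == 5
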