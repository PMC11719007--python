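"""ROC/Youden/DeLong statistics, the frequency-threshold hierarchy, confusion
metrics and RECIST labelling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from riskpipe.aggregate import (
    ThresholdSet,
    classify_hierarchy,
    confusion,
    delong_ci,
    lesion_frequency_score,
    optimize_thresholds,
    recist_classify,
    roc_auc,
    youden_threshold,
)


class TestRocAuc:
    def test_scores_equal_labels_is_perfect(self):
        assert roc_auc(np.array([0, 0, 1, 1.0]), np.array([0, 0, 1, 1])).auc == 1.0

    def test_four_point_fixture_matches_pairwise_count(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        # exhaustive pairwise comparison oracle
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        )
        assert roc_auc(scores, labels).auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_ties_count_half(self):
        scores = np.array([0.5, 0.5, 0.5, 0.5])
        labels = np.array([0, 0, 1, 1])
        assert roc_auc(scores, labels).auc == 0.5

    @given(st.floats(0.1, 5.0), st.floats(-2.0, 2.0))
    def test_invariant_under_increasing_transform(self, scale, shift):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]  # both classes present
        base = roc_auc(scores, labels).auc
        transformed = roc_auc(np.exp(scale * scores) + shift, labels).auc
        assert transformed == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestYouden:
    def test_perfect_separation_lowest_separating_cutoff(self):
        scores = np.array([0.1, 0.2, 0.7, 0.9])
        labels = np.array([0, 0, 1, 1])
        # any cutoff in (0.2, 0.7] has J = 1; the lowest evaluated is 0.7
        assert youden_threshold(roc_auc(scores, labels)) == pytest.approx(0.7)

    def test_two_maximum_tie_breaks_low(self):
        # J is maximal (0.5) both at cutoff 0.8 and at cutoff 0.4
        scores = np.array([0.1, 0.4, 0.6, 0.8])
        labels = np.array([0, 1, 0, 1])
        roc = roc_auc(scores, labels)
        j = roc.sensitivities + roc.specificities - 1
        ties = roc.thresholds[j == j.max()]
        assert len(ties) > 1
        assert youden_threshold(roc) == ties.min()

    def test_returned_cutoff_maximizes_j_over_enumeration(self):
        rng = np.random.default_rng(1)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        roc = roc_auc(scores, labels)
        t = youden_threshold(roc)

        def j_at(c):
            sn = (scores[labels == 1] >= c).mean()
            sp = (scores[labels == 0] < c).mean()
            return sn + sp - 1

        assert all(j_at(t) >= j_at(c) - 1e-12 for c in np.unique(scores))


class TestDeLong:
    def test_perfect_separation_clips_to_one(self):
        scores = np.concatenate([np.zeros(10), np.ones(10)])
        labels = np.concatenate([np.zeros(10, int), np.ones(10, int)])
        auc, lo, hi = delong_ci(scores, labels)
        assert auc == 1.0 and hi == 1.0 and lo <= 1.0

    def test_ci_width_shrinks_with_n(self):
        def width(n, seed):
            rng = np.random.default_rng(seed)
            labels = np.repeat([0, 1], n // 2)
            scores = rng.normal(labels.astype(float), 1.0)
            _, lo, hi = delong_ci(scores, labels)
            return hi - lo

        assert width(500, 2) < width(50, 2)

    def test_degenerate_class_rejected(self):
        with pytest.raises(ValueError):
            delong_ci(np.array([0.1, 0.2, 0.3]), np.array([1, 0, 0]))


class TestFrequencyScore:
    def test_printed_cutoff_example(self):
        assert lesion_frequency_score([0.30, 0.25, 0.10, 0.05, 0.02], 0.22) == 2

    def test_all_below(self):
        assert lesion_frequency_score([0.1, 0.1], 0.22) == 0

    def test_zero_cutoff_counts_all(self):
        assert lesion_frequency_score([0.0, 0.5, 0.9], 0.0) == 3

    def test_inclusive_boundary(self):
        assert lesion_frequency_score([0.22], 0.22) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lesion_frequency_score([], 0.22)


def _hierarchy_oracle(df, X, Y, Z):
    """Straight-line reimplementation of the counting rules."""
    patient_pd = {}
    lesion_pd = {}
    for pid, pat in df.groupby("patient_id"):
        n_pd_lesions = 0
        for lid, les in pat.groupby("lesion_id"):
            count = sum(1 for s in les["score"] if s >= X)
            is_pd = count >= Y
            lesion_pd[(pid, lid)] = is_pd
            if is_pd:
                n_pd_lesions += 1
        patient_pd[pid] = n_pd_lesions >= Z
    return lesion_pd, patient_pd


def _random_score_set(rng):
    rows = []
    for pid in range(rng.integers(2, 8)):
        for lid in range(rng.integers(1, 4)):
            for s in range(rng.integers(1, 6)):
                rows.append({
                    "patient_id": f"P{pid}", "lesion_id": f"L{lid}",
                    "slice_index": s, "score": float(rng.random()),
                })
    return pd.DataFrame(rows)


class TestHierarchy:
    def test_printed_example_lesion_counts(self):
        df = pd.DataFrame({
            "patient_id": ["P0"] * 10,
            "lesion_id": ["L0"] * 5 + ["L1"] * 5,
            "score": [0.1] * 5 + [0.9, 0.9, 0.9, 0.1, 0.1],
        })
        lesions, pats = classify_hierarchy(df, ThresholdSet(0.22, 2, 1))
        by_lesion = lesions.set_index("lesion_id")
        assert by_lesion.loc["L0", "frequency_score"] == 0
        assert by_lesion.loc["L1", "frequency_score"] == 3
        assert not by_lesion.loc["L0", "lesion_pd"]
        assert by_lesion.loc["L1", "lesion_pd"]
        assert pats["patient_pd"].iloc[0]

    def test_all_slices_below_cutoff_patient_dc(self):
        df = pd.DataFrame({
            "patient_id": ["P0"] * 5, "lesion_id": ["L0"] * 5,
            "score": [0.1, 0.2, 0.15, 0.05, 0.21],
        })
        _, pats = classify_hierarchy(df, ThresholdSet(0.22, 2, 1))
        assert not pats["patient_pd"].iloc[0]

    def test_matches_straight_line_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            df = _random_score_set(rng)
            X = float(rng.random())
            thr = ThresholdSet(X, int(rng.integers(1, 6)), int(rng.integers(1, 3)))
            lesions, pats = classify_hierarchy(df, thr)
            o_les, o_pat = _hierarchy_oracle(
                df, thr.slice_cutoff, thr.slice_count_cutoff, thr.lesion_count_cutoff
            )
            got_les = {
                (r.patient_id, r.lesion_id): bool(r.lesion_pd) for r in lesions.itertuples()
            }
            got_pat = {r.patient_id: bool(r.patient_pd) for r in pats.itertuples()}
            assert got_les == o_les
            assert got_pat == o_pat

    def test_raising_cutoff_never_flips_dc_to_pd(self):
        rng = np.random.default_rng(7)
        df = _random_score_set(rng)
        previous = None
        for X in np.linspace(0, 1, 11):
            _, pats = classify_hierarchy(df, ThresholdSet(X, 2, 1))
            current = set(pats[pats["patient_pd"]]["patient_id"])
            if previous is not None:
                assert current <= previous  # PD set shrinks as X rises
            previous = current

    def test_patient_score_invariant_to_lesion_order(self):
        rng = np.random.default_rng(8)
        df = _random_score_set(rng)
        shuffled = df.sample(frac=1.0, random_state=1)
        _, a = classify_hierarchy(df, ThresholdSet(0.5, 2, 1))
        _, b = classify_hierarchy(shuffled, ThresholdSet(0.5, 2, 1))
        pd.testing.assert_frame_equal(
            a.sort_values("patient_id").reset_index(drop=True),
            b.sort_values("patient_id").reset_index(drop=True),
        )

    def test_short_lesion_warns(self):
        df = pd.DataFrame({
            "patient_id": ["P0"], "lesion_id": ["L0"], "score": [0.9],
        })
        with pytest.warns(UserWarning, match="fewer than"):
            classify_hierarchy(df, ThresholdSet(0.22, 2, 1))


class TestOptimizeThresholds:
    def _planted_scores(self, n_patients, seed):
        """Slice scores drawn so that PD patients' slices sit mostly above a
        known boundary; the generative patient labels are the target."""
        rng = np.random.default_rng(seed)
        rows, labels = [], {}
        for i in range(n_patients):
            pid = f"P{i:03d}"
            is_pd = rng.random() < 0.3
            labels[pid] = int(is_pd)
            for lid in range(rng.integers(1, 3)):
                mu = 0.65 if is_pd else 0.25
                for s in range(5):
                    rows.append({
                        "patient_id": pid, "lesion_id": f"L{lid}", "slice_index": s,
                        "score": float(np.clip(rng.normal(mu, 0.15), 0, 1)),
                    })
        return pd.DataFrame(rows), labels

    def test_recovers_planted_boundary_with_high_sensitivity(self):
        df, labels = self._planted_scores(120, seed=3)
        thr = optimize_thresholds(df, labels)
        _, pats = classify_hierarchy(df, thr)
        truth = pats["patient_id"].map(labels).to_numpy()
        stats = confusion(pats["patient_pd"].astype(int).to_numpy(), truth)
        assert stats.sn >= 0.85

    def test_output_ranges(self):
        df, labels = self._planted_scores(40, seed=4)
        thr = optimize_thresholds(df, labels)
        assert 1 <= thr.slice_count_cutoff <= 5
        assert thr.lesion_count_cutoff >= 1
        assert 0 <= thr.slice_cutoff <= 1

    def test_tie_prefers_smaller_y(self):
        # one PD patient with all slices hot, one DC with all cold: any Y works,
        # the smaller must be returned
        df = pd.DataFrame({
            "patient_id": ["A"] * 5 + ["B"] * 5,
            "lesion_id": ["L0"] * 10,
            "slice_index": list(range(5)) * 2,
            "score": [0.9] * 5 + [0.1] * 5,
        })
        thr = optimize_thresholds(df, {"A": 1, "B": 0})
        assert thr.slice_count_cutoff == 1
        assert thr.lesion_count_cutoff == 1

    def test_external_rows_refused(self):
        df, labels = self._planted_scores(20, seed=5)
        tags = pd.Series(["discovery"] * (len(df) - 1) + ["external"])
        with pytest.raises(ValueError, match="external"):
            optimize_thresholds(df, labels, split_tags=tags)


class TestConfusion:
    @pytest.mark.parametrize(
        "tp,fn,fp,tn,sn,sp",
        [
            (24, 3, 14, 56, 0.889, 0.800),   # discovery patient-level counts
            (9, 0, 3, 5, 1.000, 0.625),      # external patient-level counts
        ],
    )
    def test_patient_level_count_fixtures(self, tp, fn, fp, tn, sn, sp):
        preds = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        truth = [1] * (tp + fn) + [0] * (fp + tn)
        stats = confusion(np.array(preds), np.array(truth))
        assert (stats.tp, stats.fn, stats.fp, stats.tn) == (tp, fn, fp, tn)
        assert stats.sn == pytest.approx(sn, abs=5e-4)
        assert stats.sp == pytest.approx(sp, abs=5e-4)

    def test_perfect_prediction(self):
        stats = confusion(np.array([1, 0, 1]), np.array([1, 0, 1]))
        assert stats.sn == stats.sp == stats.f1 == 1.0

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_integer_identity(self, tp, fn, fp, tn):
        if tp + fn == 0 or fp + tn == 0:
            return
        preds = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn)
        truth = np.array([1] * (tp + fn) + [0] * (fp + tn))
        stats = confusion(preds, truth)
        assert stats.sn * (stats.tp + stats.fn) == pytest.approx(stats.tp)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([1]), np.array([1, 0]))


class TestRecist:
    @pytest.mark.parametrize(
        "baseline,followup,disappeared,expected",
        [
            (100, 120, False, "PD"),   # exactly +20% counts as progression
            (100, 119.9, False, "SD"),
            (100, 70, False, "PR"),    # exactly -30% counts as response
            (100, 70.1, False, "SD"),
            (100, 100, False, "SD"),
            (100, 0, True, "CR"),
            (100, 250, False, "PD"),
        ],
    )
    def test_categories(self, baseline, followup, disappeared, expected):
        assert recist_classify(baseline, followup, disappeared) == expected

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            recist_classify(0, 10)
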