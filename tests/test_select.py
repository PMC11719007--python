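"""Selection algorithms: forward search with the ΔAUC admission rule,
mRMR against a brute-force mutual-information oracle, ReliefF against a
hand-computed weight oracle, and the six-signature menu."""

import numpy as np
import pandas as pd
import pytest

from riskpipe.select import (
    SelectionConfig,
    best_signature,
    build_signature_menu,
    mrmr_select,
    relieff_select,
    relieff_weights,
    sfs_select,
)
from riskpipe.synthetic import generate_feature_table


def _groups(n):
    return np.array([f"P{i}" for i in range(n)])


class TestSFS:
    def test_perfect_predictor_picked_first(self):
        rng = np.random.default_rng(0)
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(rng.normal(size=(n, 21)), columns=[f"n{i:02d}" for i in range(21)])
        X["perfect"] = y + rng.normal(0, 0.01, n)
        sig = sfs_select(X, y, _groups(n), SelectionConfig(seed=1))
        assert sig.features[0] == "perfect"

    def test_stops_when_improvement_below_threshold(self):
        rng = np.random.default_rng(1)
        n = 120
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame({
            "strong": y + rng.normal(0, 0.05, n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        })
        sig = sfs_select(X, y, _groups(n), SelectionConfig(seed=2))
        assert sig.features == ["strong"]  # noise adds <= 0.03 AUC

    def test_max_features_honoured(self):
        X, y = generate_feature_table(150, 10, informative=10, delta=1.2, seed=5)
        sig = sfs_select(X, y, _groups(len(y)), SelectionConfig(seed=3, delta_auc_threshold=0.0))
        assert len(sig.features) == 5

    def test_trace_non_decreasing(self):
        X, y = generate_feature_table(100, 8, informative=4, delta=1.0, seed=6)
        sig = sfs_select(X, y, _groups(len(y)), SelectionConfig(seed=4, delta_auc_threshold=0.0))
        assert all(b >= a for a, b in zip(sig.auc_trace, sig.auc_trace[1:]))

    def test_degenerate_labels_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            sfs_select(X, np.array([1, 1]), _groups(2))


def _mi_discrete(a, b):
    """Brute-force mutual information on small discrete vectors (nats)."""
    mi = 0.0
    n = len(a)
    for va in set(a):
        for vb in set(b):
            pab = np.mean((np.asarray(a) == va) & (np.asarray(b) == vb))
            if pab > 0:
                pa = np.mean(np.asarray(a) == va)
                pb = np.mean(np.asarray(b) == vb)
                mi += pab * np.log(pab / (pa * pb))
    return mi


class TestMRMR:
    # printed 12-row fixture: three binary features with graded label agreement
    FIXTURE = pd.DataFrame({
        "a": [0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1],  # strongest single predictor
        "b": [0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 0, 1],  # nearly a copy of a
        "c": [0, 1, 0, 1, 0, 1, 0, 1, 1, 0, 1, 0],  # weak but independent
    })
    LABELS = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])

    def test_selection_order_matches_exhaustive_mi_oracle(self):
        """Greedy difference-form mRMR replayed by hand with brute-force MI."""
        sig = mrmr_select(self.FIXTURE, self.LABELS, k=3)

        cols = sorted(self.FIXTURE.columns)
        data = {c: self.FIXTURE[c].tolist() for c in cols}
        rel = {c: _mi_discrete(data[c], self.LABELS.tolist()) for c in cols}
        chosen = []
        while len(chosen) < 3:
            best, best_score = None, -np.inf
            for c in cols:
                if c in chosen:
                    continue
                red = np.mean([_mi_discrete(data[c], data[s]) for s in chosen]) if chosen else 0.0
                score = rel[c] - red
                if score > best_score + 1e-12:
                    best, best_score = c, score
            chosen.append(best)
        assert sig.features == chosen

    def test_redundant_copy_deferred(self):
        rng = np.random.default_rng(7)
        n = 200
        y = np.repeat([0, 1], n // 2)
        f1 = y + rng.normal(0, 0.3, n)
        X = pd.DataFrame({
            "f1": f1,
            "f2": f1.copy(),                      # exact copy
            "f3": y + rng.normal(0, 2.0, n),      # weak but independent
        })
        sig = mrmr_select(X, y, k=2)
        assert sig.features[0] == "f1"
        assert sig.features[1] == "f3"

    def test_k1_is_argmax_univariate_mi(self):
        sig = mrmr_select(self.FIXTURE, self.LABELS, k=1)
        rel = {c: _mi_discrete(self.FIXTURE[c].tolist(), self.LABELS.tolist())
               for c in self.FIXTURE.columns}
        assert sig.features == [max(sorted(rel), key=lambda c: rel[c])]

    def test_k_beyond_pool_rejected(self):
        with pytest.raises(ValueError):
            mrmr_select(self.FIXTURE, self.LABELS, k=4)


def _relieff_oracle(X, y, k):
    """Direct transliteration of the ReliefF update rule for a tiny fixture."""
    n, p = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    classes, counts = np.unique(y, return_counts=True)
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    W = np.zeros(p)
    for i in range(n):
        dists = np.abs(X - X[i]).sum(axis=1)
        dists[i] = np.inf
        for c in classes:
            idx = [j for j in np.argsort(dists, kind="stable") if y[j] == c and j != i][:k]
            diff = np.abs(X[idx] - X[i]) / span
            if c == y[i]:
                W -= diff.mean(axis=0) / n
            else:
                W += priors[c] / (1 - priors[y[i]]) * diff.mean(axis=0) / n
    return W


class TestReliefF:
    def test_weights_match_hand_oracle_on_ten_row_fixture(self):
        rng = np.random.default_rng(8)
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        X = rng.normal(size=(10, 4))
        X[:, 0] += 2.0 * y  # separating feature
        df = pd.DataFrame(X, columns=list("wxyz"))
        weights = relieff_weights(df, y, n_neighbors=2)
        oracle = _relieff_oracle(X, y, k=2)
        np.testing.assert_allclose(weights.to_numpy(), oracle, atol=1e-12)
        assert weights.idxmax() == "w"

    def test_constant_feature_weight_zero(self):
        rng = np.random.default_rng(9)
        y = np.repeat([0, 1], 10)
        df = pd.DataFrame({"const": np.ones(20), "f": rng.normal(size=20) + y})
        weights = relieff_weights(df, y, n_neighbors=3)
        assert weights["const"] == 0.0

    def test_deterministic(self):
        X, y = generate_feature_table(30, 6, informative=2, delta=1.0, seed=10)
        s1 = relieff_select(X, y, k=3)
        s2 = relieff_select(X, y, k=3)
        assert s1.features == s2.features

    def test_neighbors_must_fit_in_class(self):
        X, y = generate_feature_table(5, 3, informative=1, delta=1.0, seed=11)
        with pytest.raises(ValueError):
            relieff_select(X, y, k=1, config=SelectionConfig(relieff_neighbors=5))


@pytest.fixture(scope="module")
def menu_setup():
    X, y = generate_feature_table(80, 10, informative=3, delta=1.5, seed=12)
    X = X.rename(columns={"f009": "clin_age"})
    menu = build_signature_menu(X, ["clin_age"], y, _groups(len(y)), SelectionConfig(seed=5))
    return X, menu


class TestSignatureMenu:

    def test_six_signatures(self, menu_setup):
        _, menu = menu_setup
        assert len(menu) == 6

    def test_clinical_pool_membership(self, menu_setup):
        _, menu = menu_setup
        for sig in menu:
            if not sig.config.include_clinical:
                assert "clin_age" not in sig.features

    def test_winner_has_highest_mean_auc(self, menu_setup):
        _, menu = menu_setup
        winner = best_signature(menu)
        assert winner.cv_auc_mean == max(s.cv_auc_mean for s in menu)


def test_planted_features_found_before_noise():
    """All three selectors put the planted informative features first in
    the vast majority of replicate draws."""
    hits = {"sfs": 0, "mrmr": 0, "relieff": 0}
    n_seeds = 10
    informative = {"f000", "f001", "f002"}
    for seed in range(n_seeds):
        X, y = generate_feature_table(200, 30, informative=3, delta=1.5, seed=100 + seed)
        groups = _groups(len(y))
        cfg = SelectionConfig(seed=seed, delta_auc_threshold=0.0, max_features=3)
        if set(sfs_select(X, y, groups, cfg).features) == informative:
            hits["sfs"] += 1
        if set(mrmr_select(X, y, 3, cfg).features) == informative:
            hits["mrmr"] += 1
        if set(relieff_select(X, y, 3, cfg).features) == informative:
            hits["relieff"] += 1
    for algo, n_hit in hits.items():
        assert n_hit >= 9, f"{algo} recovered planted features in only {n_hit}/{n_seeds} runs"
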