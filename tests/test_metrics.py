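import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from itertools import permutations
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from mvgsc import acc, ari, evaluate, f_score, nmi, pair_confusion, precision, purity
from mvgsc.data_io import ValidationError
from mvgsc.metrics import recall


def loop_pair_confusion(truth, pred):
    """O(n^2) oracle over all unordered pairs."""
    n = len(truth)
    tp = tn = fp = fn = 0
    for i in range(n):
        for j in range(i + 1, n):
            st_, sp = truth[i] == truth[j], pred[i] == pred[j]
            if st_ and sp:
                tp += 1
            elif st_ and not sp:
                fn += 1
            elif not st_ and sp:
                fp += 1
            else:
                tn += 1
    return {"TP": tp, "TN": tn, "FP": fp, "FN": fn}


class TestPairConfusion:
    def test_perfect_partition(self):
        pc = pair_confusion(["a", "a", "b", "b"], [1, 1, 2, 2])
        assert pc == {"TP": 2, "TN": 4, "FP": 0, "FN": 0}

    def test_all_merged(self):
        pc = pair_confusion(["a", "a", "b", "b"], [1, 1, 1, 1])
        assert pc == {"TP": 2, "FP": 4, "FN": 0, "TN": 0}

    def test_random_matches_loop_oracle(self, rng):
        for _ in range(5):
            truth = rng.integers(0, 4, 30)
            pred = rng.integers(0, 3, 30)
            assert pair_confusion(truth, pred) == loop_pair_confusion(truth, pred)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            pair_confusion([1, 2], [1, 2, 3])


class TestARI:
    def test_identical_and_relabeled(self):
        assert ari([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert ari([0, 0, 1, 1], ["x", "x", "y", "y"]) == 1.0

    def test_checkerboard_hand_formula(self):
        # contingency [[1,1],[1,1]]: index=0, expected = 2*2/6 = 2/3, max=2
        expected = (0 - 2.0 / 3.0) / (2.0 - 2.0 / 3.0)
        assert ari(["a", "a", "b", "b"], [1, 2, 1, 2]) == pytest.approx(expected)

    def test_matches_sklearn_on_random(self, rng):
        for _ in range(10):
            t = rng.integers(0, 4, 25)
            p = rng.integers(0, 5, 25)
            assert ari(t, p) == pytest.approx(adjusted_rand_score(t, p), abs=1e-10)

    def test_single_cluster_both_convention(self):
        assert ari([0, 0, 0], [1, 1, 1]) == 1.0


class TestNMI:
    def test_identical(self):
        assert nmi([0, 1, 2, 0], [5, 6, 7, 5]) == pytest.approx(1.0)

    def test_independent_checkerboard_zero(self):
        assert nmi(["a", "a", "b", "b"], [1, 2, 1, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_joint_count_formula(self, rng):
        t = rng.integers(0, 3, 30)
        p = rng.integers(0, 4, 30)
        # explicit I / sqrt(H H) from joint counts
        n = 30
        mi = 0.0
        for a in np.unique(t):
            for b in np.unique(p):
                nij = np.sum((t == a) & (p == b))
                if nij:
                    mi += (nij / n) * math.log(nij * n / (np.sum(t == a) * np.sum(p == b)))
        hp = -sum(
            (np.sum(t == a) / n) * math.log(np.sum(t == a) / n) for a in np.unique(t)
        )
        hq = -sum(
            (np.sum(p == b) / n) * math.log(np.sum(p == b) / n) for b in np.unique(p)
        )
        assert nmi(t, p) == pytest.approx(mi / math.sqrt(hp * hq), abs=1e-10)

    @pytest.mark.parametrize("norm,sk", [("sqrt", "geometric"), ("mean", "arithmetic"), ("max", "max")])
    def test_matches_sklearn_variants(self, rng, norm, sk):
        t = rng.integers(0, 3, 40)
        p = rng.integers(0, 4, 40)
        assert nmi(t, p, norm=norm) == pytest.approx(
            normalized_mutual_info_score(t, p, average_method=sk), abs=1e-10
        )


class TestPairFScores:
    def test_perfect(self):
        t = [0, 0, 1, 1]
        assert precision(t, t) == recall(t, t) == f_score(t, t) == 1.0

    def test_all_merged_hand_values(self):
        t, p = ["a", "a", "b", "b"], [1, 1, 1, 1]
        assert precision(t, p) == pytest.approx(2.0 / 6.0)
        assert recall(t, p) == 1.0
        assert f_score(t, p) == pytest.approx(0.5)

    def test_no_false_pairs_gives_one(self):
        t = [0, 0, 1, 2]
        assert f_score(t, t) == 1.0


class TestACC:
    def test_relabeled_perfect(self):
        assert acc([0, 0, 1, 1], [7, 7, 3, 3]) == 1.0

    def test_hand_matching(self):
        assert acc(["a", "a", "b", "b"], [1, 1, 1, 2]) == pytest.approx(0.75)

    def test_matches_factorial_oracle(self, rng):
        """Optimal-assignment ACC equals brute force over all label permutations."""
        for _ in range(10):
            n = 8
            t = rng.integers(0, 3, n)
            p = rng.integers(0, 3, n)
            best = max(
                np.mean([perm[pi] == ti for pi, ti in zip(p, t)])
                for perm in permutations(range(3))
            )
            assert acc(t, p) == pytest.approx(best)

    def test_rectangular_contingency(self):
        # more predicted clusters than true classes
        assert acc([0, 0, 0, 1], [0, 1, 2, 3]) == pytest.approx(0.5)


class TestPurity:
    def test_perfect(self):
        assert purity([0, 1, 1], [2, 0, 0]) == 1.0

    def test_single_cluster_balanced(self):
        assert purity([0, 0, 1, 1], [5, 5, 5, 5]) == 0.5

    def test_purity_at_least_acc(self, rng):
        for _ in range(20):
            t = rng.integers(0, 4, 15)
            p = rng.integers(0, 4, 15)
            assert purity(t, p) >= acc(t, p) - 1e-12


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(0, 3), min_size=2, max_size=25),
    st.data(),
)
def test_metric_ranges_and_relabeling_invariance(truth, data):
    """All metrics bounded, invariant to relabeling, pair counts sum to C(n,2)."""
    n = len(truth)
    pred = data.draw(st.lists(st.integers(0, 3), min_size=n, max_size=n))
    rep = evaluate(truth, pred)
    assert -1 - 1e-12 <= rep.ari <= 1 + 1e-12
    for v in (rep.nmi, rep.f_score, rep.acc, rep.purity, rep.precision):
        assert -1e-12 <= v <= 1 + 1e-12
    pc = rep.pair_counts
    assert pc["TP"] + pc["TN"] + pc["FP"] + pc["FN"] == n * (n - 1) // 2
    # relabel predictions: every metric unchanged
    relabel = {v: 9 - v for v in set(pred)}
    rep2 = evaluate(truth, [relabel[v] for v in pred])
    for key in ("ari", "nmi", "f_score", "acc", "purity", "precision"):
        assert getattr(rep, key) == pytest.approx(getattr(rep2, key), abs=1e-12)
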