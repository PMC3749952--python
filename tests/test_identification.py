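import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import blindmix as bm
from blindmix.identification import NoCellTypesError
from oracles import assign_bruteforce, skld_bruteforce


def _panel(values, labels=None, classes=None):
    values = np.asarray(values, float)
    labels = labels or [f"t{j}" for j in range(values.shape[1])]
    return bm.ReferencePanel(
        values, [f"g{i}" for i in range(values.shape[0])], labels, classes or {}
    )


class TestSkld:
    def test_worked_value_against_definitional_sum(self):
        got = bm.skld([0.5, 0.5], [0.25, 0.75], epsilon=1e-300)
        assert got == pytest.approx(0.25 * math.log(3.0), abs=1e-12)
        assert got == pytest.approx(
            skld_bruteforce([0.5, 0.5], [0.25, 0.75], 1e-300), abs=1e-12
        )

    def test_zero_for_identical_and_for_rescaled_vectors(self, rng):
        w = rng.uniform(0.1, 5, 30)
        assert bm.skld(w, w) == 0.0
        assert bm.skld(w, 4.2 * w) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(
        arrays(float, 12, elements=st.floats(1e-3, 1e3)),
        arrays(float, 12, elements=st.floats(1e-3, 1e3)),
    )
    def test_symmetric_premetric_and_oracle_agreement(self, w, d):
        ab = bm.skld(w, d)
        ba = bm.skld(d, w)
        assert ab >= 0.0
        assert ab == pytest.approx(ba, abs=1e-12)
        assert ab == pytest.approx(skld_bruteforce(w, d), rel=1e-9, abs=1e-12)
        if not np.allclose(w / w.sum(), d / d.sum()):
            assert ab > 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero sum"):
            bm.skld([0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="length"):
            bm.skld([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="negative"):
            bm.skld([1.0, -1.0], [1.0, 1.0])


class TestAssignReferences:
    def test_self_panel_maps_every_label_to_its_own_column(self, rng):
        L = _panel(rng.uniform(0.1, 1, (20, 4)))
        W = L.values / L.values.sum(0)
        a = bm.assign_references(W, L)
        assert a.k_hat == 4
        assert a.chosen_columns == [0, 1, 2, 3]
        assert a.column_labels == L.labels
        assert all(a.nearest_column[lab] == j for j, lab in enumerate(L.labels))

    def test_duplicate_references_collapse_onto_one_column(self, rng):
        u = rng.uniform(0.1, 1, 15)
        v = rng.uniform(0.1, 1, 15)
        L = _panel(np.column_stack([u, u, v]), ["a1", "a2", "b"])
        W = np.column_stack([u, v, rng.uniform(0.1, 1, 15)])
        a = bm.assign_references(W / W.sum(0), L)
        assert a.k_hat == 2
        assert a.nearest_column["a1"] == a.nearest_column["a2"] == 0

    def test_shared_winner_labeled_by_smaller_divergence(self):
        # factors with exclusive markers; references A and B both nearest to
        # factor 1, A strictly closer -> factor 1 labeled A, B dropped
        W = np.array(
            [[10, 1, 1, 1], [1, 10, 1, 1], [1, 1, 10, 1], [1, 1, 1, 10]], float
        )
        W = W / W.sum(0)
        refs = np.column_stack(
            [W[:, 0], [1, 9, 1.5, 1], [2, 8, 1, 1.5], W[:, 2]]
        )
        L = _panel(refs, ["C", "A", "B", "D"])
        a = bm.assign_references(W, L)
        winners, chosen, col_labels = assign_bruteforce(refs, L.labels, W)
        assert a.nearest_column["A"] == a.nearest_column["B"] == 1
        assert a.distance["A"] < a.distance["B"]
        assert a.chosen_columns == chosen
        assert a.column_labels == col_labels
        assert "B" not in a.column_labels

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_ref = int(rng.integers(2, 11))
        n_col = int(rng.integers(2, 11))
        m = int(rng.integers(5, 15))
        L = _panel(rng.uniform(0.05, 1, (m, n_ref)))
        W = rng.uniform(0.05, 1, (m, n_col))
        a = bm.assign_references(W, L)
        winners, chosen, col_labels = assign_bruteforce(L.values, L.labels, W)
        assert {lab: a.nearest_column[lab] for lab in L.labels} == winners
        assert a.chosen_columns == chosen
        assert a.column_labels == col_labels


class TestCollapseClasses:
    def _assignment(self, W, L):
        return bm.assign_references(W / W.sum(0), L)

    def test_singleton_classes_pass_through(self, rng):
        L = _panel(rng.uniform(0.1, 1, (12, 3)))
        W = L.values / L.values.sum(0)
        G, labels = bm.collapse_classes(self._assignment(W, L), W, {})
        assert labels == L.labels
        np.testing.assert_allclose(G, W)

    def test_same_class_columns_averaged_and_renormalized(self, rng):
        L = _panel(
            rng.uniform(0.1, 1, (12, 3)), ["b1", "b2", "t"],
            {"b1": "B cells", "b2": "B cells"},
        )
        W = L.values / L.values.sum(0)
        a = self._assignment(W, L)
        G, labels = bm.collapse_classes(a, W, L.class_of)
        assert labels == ["B cells", "t"]
        expected = (W[:, 0] + W[:, 1]) / 2
        np.testing.assert_allclose(G[:, 0], expected / expected.sum())
        np.testing.assert_allclose(G.sum(0), 1.0, atol=1e-12)


class TestMajorityVote:
    def _runs(self, spec, m=6):
        """spec: list of label-lists, one per run; signatures are random
        but repeatable per label."""
        out = []
        for labels in spec:
            cols = []
            for lab in labels:
                r = np.random.default_rng(abs(hash(lab)) % 2 ** 31)
                c = r.uniform(0.1, 1, m)
                cols.append(c / c.sum())
            out.append((np.column_stack(cols), list(labels)))
        return out

    def test_always_chosen_label_retained_with_frequency_one(self):
        res = bm.majority_vote(self._runs([["a", "b"]] * 10), threshold=0.7)
        assert res.selection_frequency["a"] == 1.0
        assert set(res.labels) == {"a", "b"}
        assert res.k_t_hat == 2

    def test_rarely_chosen_label_dropped_but_frequency_recorded(self):
        spec = [["a", "grey"], ["a", "grey"]] + [["a"]] * 8
        res = bm.majority_vote(self._runs(spec), threshold=0.7)
        assert res.labels == ["a"]
        assert res.selection_frequency["grey"] == pytest.approx(0.2)

    def test_single_run_passes_any_threshold(self):
        res = bm.majority_vote(self._runs([["x", "y"]]), threshold=0.7)
        assert set(res.labels) == {"x", "y"}

    def test_boundary_threshold_retains_every_winner(self):
        spec = [["a"], ["b"], ["c"], ["a"], ["a"]]
        res = bm.majority_vote(self._runs(spec), threshold=1 / 5)
        assert set(res.labels) == {"a", "b", "c"}

    def test_signature_is_mean_over_chosen_runs(self):
        g1 = np.array([0.5, 0.3, 0.2])
        g2 = np.array([0.1, 0.6, 0.3])
        res = bm.majority_vote([(g1[:, None], ["a"]), (g2[:, None], ["a"])], 0.7)
        mean = (g1 + g2) / 2
        np.testing.assert_allclose(res.G_hat[:, 0], mean / mean.sum())

    def test_no_label_reaching_threshold_is_explicit_error(self):
        with pytest.raises(NoCellTypesError, match="threshold"):
            bm.majority_vote(self._runs([["a"], ["b"]]), threshold=0.9)

    def test_zero_runs_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            bm.majority_vote([], threshold=0.5)
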