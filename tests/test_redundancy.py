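from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import symptomnet as sn


def net_from_weights(W):
    return sn.Network(
        W, None, 0.0, tuple(f"n{i}" for i in range(W.shape[0]))
    )


class TestWeightedTopologicalOverlap:
    def test_empty_network_all_zero(self):
        wto = sn.weighted_topological_overlap(net_from_weights(np.zeros((4, 4))))
        assert np.all(wto == 0)

    def test_three_node_hand_value(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = 0.2
        W[1, 2] = W[2, 1] = 0.4
        wto = sn.weighted_topological_overlap(net_from_weights(W))
        # (a13*a23 + a12) / (min(k1,k2) + 1 - a12) = 0.58 / 1.2
        assert wto[0, 1] == pytest.approx(0.58 / 1.2, abs=1e-12)

    def test_identical_profiles_high_overlap(self):
        # nodes 0 and 1: strong mutual edge and identical profiles elsewhere
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 0.9
        for j in (2, 3, 4):
            W[0, j] = W[j, 0] = 0.3
            W[1, j] = W[j, 1] = 0.3
        wto = sn.weighted_topological_overlap(net_from_weights(W))
        # independent direct computation
        a = np.abs(W)
        k = a.sum(axis=1)
        num = sum(a[0, u] * a[1, u] for u in (2, 3, 4)) + a[0, 1]
        expected = num / (min(k[0], k[1]) + 1 - a[0, 1])
        assert wto[0, 1] == pytest.approx(expected, abs=1e-12)
        assert wto[0, 1] > 0.9 * wto.max()

    @given(
        arrays(
            float,
            (5, 5),
            elements=st.floats(0, 0.2),
        )
    )
    def test_bounded_in_unit_interval(self, raw):
        W = np.triu(raw, 1)
        W = W + W.T
        wto = sn.weighted_topological_overlap(net_from_weights(W))
        assert np.all(wto >= -1e-12) and np.all(wto <= 1 + 1e-12)


class TestDetectRedundant:
    def test_constant_matrix_flags_nothing(self):
        wto = np.full((6, 6), 0.3)
        np.fill_diagonal(wto, 0.0)
        codes = [f"n{i}" for i in range(6)]
        assert sn.detect_redundant(wto, codes) == []

    def test_quantile_rule_flags_top_pairs(self):
        wto = np.zeros((10, 10))
        wto[0, 1] = wto[1, 0] = 0.9
        wto[2, 3] = wto[3, 2] = 0.8
        codes = [f"n{i}" for i in range(10)]
        flagged = sn.detect_redundant(wto, codes, method="quantile", threshold=0.95)
        assert [(a, b) for a, b, _ in flagged] == [("n0", "n1"), ("n2", "n3")]

    def test_sd_rule(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.1, 0.2, size=(8, 8))
        wto = np.triu(base, 1)
        wto = wto + wto.T
        wto[0, 1] = wto[1, 0] = 0.95
        codes = [f"n{i}" for i in range(8)]
        flagged = sn.detect_redundant(wto, codes, method="sd", threshold=2.0)
        assert flagged[0][:2] == ("n0", "n1")

    def test_injected_pairs_detected_on_study_raw_data(self):
        spec = sn.default_raw_study_spec(n=1463, seed=21)
        m = sn.generate(spec)
        net = sn.ebic_glasso(sn.correlation(m))
        wto = sn.weighted_topological_overlap(net)
        flagged = sn.detect_redundant(wto, m.codes)
        flagged_pairs = {frozenset((a, b)) for a, b, _ in flagged}
        for s in sn.STUDY_COMPOSITES:
            assert frozenset(s.member_codes) in flagged_pairs


class TestCombineItems:
    def test_study_merge_reduces_25_to_22(self):
        m = sn.generate(sn.default_raw_study_spec(n=1000, seed=1))
        out = sn.combine_items(m, sn.STUDY_COMPOSITES)
        assert m.n_items == 25 and out.n_items == 22
        assert {s.new_code for s in sn.STUDY_COMPOSITES} <= set(out.codes)
        # node-count arithmetic: p_out = p_in - sum(members - 1)
        assert out.n_items == m.n_items - sum(
            len(s.member_codes) - 1 for s in sn.STUDY_COMPOSITES
        )

    def test_mean_combine_of_identical_columns(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 5, 60).astype(float)
        m = sn.ResponseMatrix(
            np.column_stack([col, col]),
            (sn.ItemMeta("a", sn.Scale.DS2, 0, 4), sn.ItemMeta("b", sn.Scale.DS2, 0, 4)),
        )
        out = sn.combine_items(
            m, [sn.CompositeSpec("ab", ("a", "b"), sn.CombineMethod.MEAN)]
        )
        z = (col - col.mean()) / col.std(ddof=1)
        assert np.allclose(out.values[:, 0], z)

    def test_latent_score_tracks_shared_component(self):
        rng = np.random.default_rng(3)
        n = 20_000
        f = rng.standard_normal(n)
        lam = np.sqrt(0.8)  # members correlate 0.8
        x = lam * f[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((n, 2))
        m = sn.ResponseMatrix(
            x,
            (sn.ItemMeta("a", sn.Scale.COMPOSITE, None, None),
             sn.ItemMeta("b", sn.Scale.COMPOSITE, None, None)),
        )
        out = sn.combine_items(
            m, [sn.CompositeSpec("ab", ("a", "b"), sn.CombineMethod.LATENT_SCORE)]
        )
        r = np.corrcoef(out.values[:, 0], f)[0, 1]
        assert abs(r) >= 0.94

    def test_zero_variance_member_fatal(self):
        m = sn.ResponseMatrix(
            np.column_stack([np.ones(10), np.arange(10, dtype=float)]),
            (sn.ItemMeta("a", sn.Scale.DS2, 0, 4),
             sn.ItemMeta("b", sn.Scale.COMPOSITE, None, None)),
        )
        with pytest.raises(ValueError, match="zero-variance"):
            sn.combine_items(
                m, [sn.CompositeSpec("ab", ("a", "b"), sn.CombineMethod.MEAN)]
            )

    def test_overlapping_specs_rejected(self):
        m = sn.generate(sn.default_raw_study_spec(n=500, seed=4))
        specs = [
            sn.CompositeSpec("x", ("ds_value", "ds_worth")),
            sn.CompositeSpec("y", ("ds_worth", "ds_nohelp")),
        ]
        with pytest.raises(ValueError, match="share member"):
            sn.combine_items(m, specs)
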