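from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import spearmanr

import symptomnet as sn

from conftest import two_clique_network


def net(W, codes=None):
    codes = codes or tuple(f"n{i}" for i in range(W.shape[0]))
    return sn.Network(W, None, 0.0, codes)


class TestNodeStrength:
    def test_isolated_node_zero(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.4
        s = sn.node_strength(net(W))
        assert s["n2"] == 0.0

    def test_star_centre(self):
        W = np.zeros((5, 5))
        for j in range(1, 5):
            W[0, j] = W[j, 0] = 0.2
        s = sn.node_strength(net(W))
        assert s["n0"] == pytest.approx(0.8)
        assert s["n1"] == pytest.approx(0.2)

    def test_equals_absolute_row_sums(self, study_ega):
        network = study_ega.network
        s = sn.node_strength(network)
        expected = np.abs(network.weights).sum(axis=1)  # direct oracle
        assert np.allclose(s.to_numpy(), expected)

    def test_removing_isolated_node_leaves_others_unchanged(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.3
        full = sn.node_strength(net(W))
        reduced = sn.node_strength(net(W[:3, :3]))
        assert np.allclose(full.iloc[:3].to_numpy(), reduced.to_numpy())


class TestNodeLoadings:
    def hand_fixture(self):
        # communities {0,1,2} and {3,4,5}; node 2 bridges into community 2
        W = np.zeros((6, 6))
        W[0, 1] = 0.5
        W[0, 2] = 0.3
        W[1, 2] = 0.4
        W[3, 4] = 0.6
        W[3, 5] = 0.2
        W[4, 5] = 0.3
        W[2, 3] = 0.15
        W = W + W.T
        network = net(W)
        partition = sn.Partition(
            {"n0": 1, "n1": 1, "n2": 1, "n3": 2, "n4": 2, "n5": 2}, 2, 0.0
        )
        return W, network, partition

    def test_matches_hand_computed_standardisation(self):
        W, network, partition = self.hand_fixture()
        L = sn.node_loadings(network, partition)
        # raw loadings computed by hand
        raw = np.zeros((6, 2))
        for i in range(6):
            for c, members in ((0, (0, 1, 2)), (1, (3, 4, 5))):
                raw[i, c] = sum(W[i, j] for j in members if j != i)
        denom1 = np.sqrt(sum(abs(raw[i, 0]) for i in (0, 1, 2)))
        denom2 = np.sqrt(sum(abs(raw[i, 1]) for i in (3, 4, 5)))
        assert L.loc["n0", "1"] == pytest.approx(raw[0, 0] / denom1, abs=1e-12)
        assert L.loc["n2", "2"] == pytest.approx(raw[2, 1] / denom2, abs=1e-12)

    def test_zero_loading_outside_own_community(self):
        network = two_clique_network(n_per=4, within=0.5)  # no bridge
        partition = sn.walktrap(network)
        L = sn.node_loadings(network, partition)
        assert np.all(L.loc["n0"].to_numpy()[1:] == 0)

    def test_strength_decomposes_into_loadings(self, study_ega):
        L = sn.node_loadings(study_ega.network, study_ega.partition)
        s = sn.node_strength(study_ega.network)
        # un-standardise: recompute raw column scales
        membership = study_ega.partition.membership(study_ega.network.node_codes)
        W = study_ega.network.weights
        for c in range(1, study_ega.partition.n_communities + 1):
            members = membership == c
            raw_own = [
                np.abs(W[i, members & (np.arange(len(s)) != i)]).sum()
                for i in np.flatnonzero(members)
            ]
            denom = np.sqrt(np.sum(np.abs(raw_own)))
            np.testing.assert_allclose(
                np.abs(L[str(c)].to_numpy()) * denom,
                [np.abs(W[i, members & (np.arange(len(s)) != i)]).sum()
                 for i in range(len(s))],
                atol=1e-10,
            )

    def test_central_items_crossload_more(self, study_ega):
        """More central nodes tend to have more non-trivial crossloadings."""
        L = sn.node_loadings(study_ega.network, study_ega.partition)
        s = sn.node_strength(study_ega.network)
        membership = study_ega.partition.membership(study_ega.network.node_codes)
        cross = []
        for idx, code in enumerate(study_ega.network.node_codes):
            own = membership[idx]
            others = [
                abs(L.loc[code, str(c)])
                for c in range(1, study_ega.partition.n_communities + 1)
                if c != own
            ]
            cross.append(sum(1 for v in others if v > 0.05))
        rho = spearmanr(s.to_numpy(), cross)[0]
        assert rho >= 0

    def test_empty_community_fatal(self):
        W = np.zeros((2, 2))
        with pytest.raises(ValueError, match="contiguous"):
            sn.Partition({"n0": 1, "n1": 3}, 3, 0.0)


@pytest.fixture(scope="module")
def matrix():
    return sn.generate(
        sn.community_spec((6, 6), n=1200, seed=9, loading=0.75, factor_corr=0.2)
    )


class TestStabilityCurves:
    def test_zero_drop_fraction_correlation_exactly_one(self, matrix):
        curve = sn.case_drop_stability(
            matrix, n_iter=5, drop_fractions=[0.0, 0.3], seed=1,
            config=sn.EGAConfig(n_lambda=30),
        )
        assert curve.mean_corr[0] == 1.0
        assert curve.q025[0] == 1.0

    def test_case_drop_mean_correlation_decreases(self, matrix):
        curve = sn.case_drop_stability(
            matrix, n_iter=20, drop_fractions=[0.0, 0.3, 0.6], seed=2,
            config=sn.EGAConfig(n_lambda=30),
        )
        assert curve.mean_corr[0] >= curve.mean_corr[1] - 0.02
        assert curve.mean_corr[1] >= curve.mean_corr[2] - 0.02

    def test_cs_coefficient_definition(self, matrix):
        curve = sn.case_drop_stability(
            matrix, n_iter=20, drop_fractions=[0.0, 0.3], seed=3,
            config=sn.EGAConfig(n_lambda=30),
        )
        for f, prop in zip(curve.drop_fractions, curve.prop_above):
            if f == curve.cs_coefficient:
                assert prop >= curve.certainty

    def test_small_subsample_fraction_skipped(self, matrix):
        with pytest.warns(UserWarning, match="skipped"):
            curve = sn.case_drop_stability(
                matrix, n_iter=3, drop_fractions=[0.0, 0.95], seed=4,
            )
        assert 0.95 not in curve.drop_fractions

    def test_node_drop_zero_fraction_one(self, matrix):
        curve = sn.node_drop_stability(
            matrix, n_iter=4, drop_fractions=[0.0, 0.4], seed=5,
            config=sn.EGAConfig(n_lambda=30),
        )
        assert curve.mean_corr[0] == 1.0
        assert np.all(curve.mean_corr[1] <= 1.0)

    def test_invalid_fraction_rejected(self, matrix):
        with pytest.raises(ValueError):
            sn.case_drop_stability(matrix, n_iter=2, drop_fractions=[1.0])
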