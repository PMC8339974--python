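"""Read-across engine: neighbor search, weighted vote, tiered domain."""

import pytest

from amesread import MUTAGENIC, NON_MUTAGENIC
from amesread.fingerprints import atom_environments
from amesread.lazar import (
    MP2D_TIERS,
    LazarModel,
    Neighbor,
    TierPolicy,
    weighted_vote,
)
from amesread.similarity import tanimoto


class TestWeightedVote:
    def test_single_class_gives_certainty(self):
        p = weighted_vote([Neighbor("k", 0.7, MUTAGENIC)])
        assert p == (1.0, 0.0)

    def test_two_class_split_is_similarity_proportional(self):
        p = weighted_vote(
            [Neighbor("a", 0.6, MUTAGENIC), Neighbor("b", 0.4, NON_MUTAGENIC)]
        )
        assert p == pytest.approx((0.6, 0.4))

    def test_three_neighbors(self):
        p = weighted_vote(
            [
                Neighbor("a", 0.5, MUTAGENIC),
                Neighbor("b", 0.5, MUTAGENIC),
                Neighbor("c", 0.5, NON_MUTAGENIC),
            ]
        )
        assert p == pytest.approx((2 / 3, 1 / 3))

    def test_probabilities_sum_to_one(self):
        p = weighted_vote(
            [Neighbor("a", 0.31, MUTAGENIC), Neighbor("b", 0.77, NON_MUTAGENIC)]
        )
        assert p[0] + p[1] == pytest.approx(1.0, abs=1e-15)

    def test_empty_neighbors_is_error(self):
        with pytest.raises(ValueError):
            weighted_vote([])


class TestTierPolicy:
    def test_thresholds_must_be_ordered(self):
        with pytest.raises(ValueError):
            TierPolicy(high=0.2, low=0.5)

    def test_defaults(self):
        assert (MP2D_TIERS.high, MP2D_TIERS.low) == (0.5, 0.2)


def _toy_model(tiers=None):
    smiles = {
        "q_like_1": "O=[N+]([O-])c1ccccc1C",
        "q_like_2": "O=[N+]([O-])c1ccccc1CC",
        "other": "C1CCCCC1",
        "mid": "Cc1ccccc1C",
    }
    fps = {k: atom_environments(s) for k, s in smiles.items()}
    measurements = [
        ("q_like_1", MUTAGENIC),
        ("q_like_2", MUTAGENIC),
        ("other", NON_MUTAGENIC),
        ("mid", NON_MUTAGENIC),
    ]
    return LazarModel(fps, measurements, kernel="tanimoto", tiers=tiers), fps


class TestFindNeighbors:
    def test_matches_bruteforce_scan(self, small_fixture, small_fingerprints):
        dataset, _ = small_fixture
        model = LazarModel.from_dataset(dataset, small_fingerprints)
        keys = dataset.keys()[:50]
        for query in keys[:10]:
            got = model.find_neighbors(small_fingerprints[query], 0.3, exclude_key=query)
            expected = sorted(
                (
                    (key, tanimoto(small_fingerprints[query], small_fingerprints[key]), m.outcome)
                    for key in dataset.keys()
                    if key != query
                    for m in dataset[key].measurements
                    if tanimoto(small_fingerprints[query], small_fingerprints[key]) >= 0.3
                ),
                key=lambda t: (-t[1], t[0], t[2]),
            )
            assert [(n.key, n.similarity, n.outcome) for n in got] == expected

    def test_query_structure_excluded_from_neighbors(self):
        model, fps = _toy_model()
        neighbors = model.find_neighbors(fps["q_like_1"], 0.1, exclude_key="q_like_1")
        assert all(n.key != "q_like_1" for n in neighbors)

    def test_impossible_threshold_gives_empty_list(self):
        model, fps = _toy_model()
        assert model.find_neighbors(fps["q_like_1"], 1.01) == []

    def test_sorted_by_descending_similarity(self):
        model, fps = _toy_model()
        sims = [n.similarity for n in model.find_neighbors(fps["q_like_1"], 0.05)]
        assert sims == sorted(sims, reverse=True)


class TestPredict:
    def test_high_confidence_when_close_neighbor_exists(self):
        model, fps = _toy_model()
        pred = model.predict(fps["q_like_1"], query_key="q_like_1")
        assert pred.confidence == "high"
        assert pred.tier_used == 0.5
        assert pred.predicted == MUTAGENIC

    def test_low_confidence_fallback(self):
        # thresholds chosen so only the low tier finds neighbors
        model, fps = _toy_model(tiers=TierPolicy(high=0.99, low=0.2))
        pred = model.predict(fps["q_like_1"], query_key="q_like_1")
        assert pred.confidence == "low"
        assert pred.predicted is not None

    def test_abstention_when_no_neighbors_at_either_tier(self):
        model, fps = _toy_model(tiers=TierPolicy(high=0.999, low=0.998))
        query = atom_environments("FC(F)(F)C(Br)(Cl)I")
        pred = model.predict(query)
        assert pred.predicted is None
        assert pred.confidence == "none"
        assert pred.p_mutagenic is None

    def test_probabilities_sum_to_one_when_predicted(self, small_fixture, small_fingerprints):
        dataset, _ = small_fixture
        model = LazarModel.from_dataset(dataset, small_fingerprints)
        for key in dataset.keys():
            pred = model.predict(small_fingerprints[key], query_key=key)
            if pred.predicted is not None:
                assert pred.p_mutagenic + pred.p_nonmutagenic == pytest.approx(1.0)
                expected = MUTAGENIC if pred.p_mutagenic > 0.5 else NON_MUTAGENIC
                assert pred.predicted == expected

    def test_tied_vote_abstains_with_reason(self):
        fps = {
            "a": {"f1", "f2"},
            "b": {"f1", "f3"},
            "q": {"f1", "f2", "f3"},
        }
        model = LazarModel(
            {"a": fps["a"], "b": fps["b"]},
            [("a", MUTAGENIC), ("b", NON_MUTAGENIC)],
            kernel="tanimoto",
            tiers=TierPolicy(high=0.6, low=0.3),
        )
        pred = model.predict(fps["q"], query_key="q")
        assert pred.predicted is None
        assert pred.reason == "tie"

    def test_contradictory_compound_votes_once_per_measurement(self):
        fps = {"n1": {"f1", "f2"}, "q": {"f1", "f2", "f3"}}
        model = LazarModel(
            {"n1": fps["n1"]},
            [("n1", MUTAGENIC), ("n1", NON_MUTAGENIC), ("n1", MUTAGENIC)],
            kernel="tanimoto",
            tiers=TierPolicy(high=0.5, low=0.2),
        )
        # deduplicated same-outcome entries are the caller's concern; here the
        # engine must weight each retained measurement equally
        pred = model.predict(fps["q"], query_key="q")
        assert pred.p_mutagenic == pytest.approx(2 / 3)

    def test_tier_monotonicity_low_superset_of_high(self, small_fixture, small_fingerprints):
        dataset, _ = small_fixture
        model_high = LazarModel.from_dataset(
            dataset, small_fingerprints, tiers=TierPolicy(0.5, 0.499)
        )
        model_low = LazarModel.from_dataset(
            dataset, small_fingerprints, tiers=TierPolicy(0.2, 0.199)
        )
        predicted_high = {
            k for k in dataset.keys()
            if model_high.predict(small_fingerprints[k], query_key=k).predicted
        }
        predicted_low = {
            k for k in dataset.keys()
            if model_low.predict(small_fingerprints[k], query_key=k).predicted
        }
        assert predicted_high <= predicted_low
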