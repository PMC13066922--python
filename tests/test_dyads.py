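"""Dyad construction: pairing rules, responses, covariates, status categories."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from socmix.dyads import (build_dyads, filter_within_group, nest_sharing_lump,
                          shared_nest_at_hatch, status_pair_category,
                          STATUS_PAIR_LEVELS)


def _meta(rows):
    defaults = {"group_id": "G1", "status": "Sub", "sex": "F", "age_years": 1.0,
                "day_in_season": 0, "minutes_after_sunrise": 0,
                "season": "major", "year": 2017, "period_id": "2017_major",
                "natal_nest_id": None, "present_at_nest_ids": ""}
    return pd.DataFrame([{**defaults, **r} for r in rows])


def _inputs(meta, seed=0):
    rng = np.random.default_rng(seed)
    ids = list(meta["sample_id"])
    clr = rng.normal(size=(len(ids), 4))
    from scipy.spatial.distance import pdist, squareform
    dm = DistanceMatrix(squareform(pdist(clr)), ids=ids)
    alpha = pd.DataFrame({"richness": rng.integers(5, 50, len(ids)),
                          "shannon": rng.uniform(0.5, 3.0, len(ids))},
                         index=pd.Index(ids, name="sample_id"))
    birds = sorted(meta["bird_id"].unique())
    r = np.full((len(birds), len(birds)), 0.1)
    np.fill_diagonal(r, 1.0)
    rel = pd.DataFrame(r, index=birds, columns=birds)
    return {"overall": dm}, alpha, rel


class TestBuildDyads:
    def test_four_birds_one_period_give_six_dyads(self):
        meta = _meta([{"sample_id": f"s{i}", "bird_id": f"b{i}"} for i in range(4)])
        d, a, r = _inputs(meta)
        out = build_dyads(meta, d, a, r)
        assert len(out) == 6

    def test_same_bird_pairs_excluded(self):
        meta = _meta([{"sample_id": "s1", "bird_id": "b1"},
                      {"sample_id": "s2", "bird_id": "b1"},
                      {"sample_id": "s3", "bird_id": "b2"}])
        out = build_dyads(meta, *_inputs(meta))
        pairs = set(map(tuple, out[["bird_a", "bird_b"]].to_numpy()))
        assert ("b1", "b1") not in pairs
        assert len(out) == 2  # s1-s3 and s2-s3

    def test_cross_period_pairs_never_emitted(self):
        meta = _meta([
            {"sample_id": "s1", "bird_id": "b1"},
            {"sample_id": "s2", "bird_id": "b2", "period_id": "2018_major",
             "year": 2018},
        ])
        with pytest.raises(ValueError, match="no dyads"):
            build_dyads(meta, *_inputs(meta))

    def test_duplicate_sample_ids_rejected(self):
        ok = _meta([{"sample_id": "s1", "bird_id": "b1"},
                    {"sample_id": "s2", "bird_id": "b2"}])
        d, a, r = _inputs(ok)
        dup = ok.assign(sample_id=["s1", "s1"])
        with pytest.raises(ValueError, match="duplicate"):
            build_dyads(dup, d, a, r)

    def test_counts_match_brute_force_per_period(self, small_bundle):
        meta = small_bundle.metadata
        expected = 0
        for _, grp in meta.groupby("period_id"):
            birds = grp["bird_id"].to_numpy()
            for i, j in itertools.combinations(range(len(grp)), 2):
                if birds[i] != birds[j]:
                    expected += 1
        assert len(small_bundle.dyads) == expected

    def test_identical_samples_have_zero_responses(self):
        # one sample duplicated under a different synthetic bird identity
        meta = _meta([{"sample_id": "s1", "bird_id": "b1"},
                      {"sample_id": "s2", "bird_id": "b2"}])
        d, a, r = _inputs(meta)
        dm = DistanceMatrix(np.zeros((2, 2)), ids=["s1", "s2"])
        a.loc["s2"] = a.loc["s1"]
        out = build_dyads(meta, {"overall": dm}, a, r)
        assert out["neg_distance_overall"].iloc[0] == 0.0
        assert out["neg_richness_diff"].iloc[0] == 0.0
        assert out["neg_shannon_diff"].iloc[0] == 0.0

    def test_responses_are_nonpositive_similarities(self, small_bundle):
        d = small_bundle.dyads
        for col in ("neg_distance_overall", "neg_distance_aerotolerant",
                    "neg_distance_anaerobic", "neg_richness_diff",
                    "neg_shannon_diff"):
            assert (d[col] <= 0).all()

    def test_missing_relatedness_rows_dropped(self, caplog):
        meta = _meta([{"sample_id": f"s{i}", "bird_id": f"b{i}"} for i in range(3)])
        d, a, r = _inputs(meta)
        r = r.drop(index="b2", columns="b2")  # b2 unknown
        with caplog.at_level("WARNING"):
            out = build_dyads(meta, d, a, r)
        assert len(out) == 1  # only b0-b1 remains
        assert "missing relatedness" in caplog.text

    def test_dyads_share_period_and_season(self, small_bundle):
        d = small_bundle.dyads
        meta = small_bundle.metadata.set_index("sample_id")
        assert (meta.loc[d["sample_a"], "period_id"].to_numpy()
                == meta.loc[d["sample_b"], "period_id"].to_numpy()).all()


class TestStatusCategories:
    @pytest.mark.parametrize("a,b,expected", [
        ("DomM", "DomF", "DomDom"),
        ("DomF", "Helper", "DomHelp"),
        ("DomM", "Sub", "DomSub"),
        ("Helper", "Sub", "HelpSub"),
        ("Sub", "Sub", "SubSub"),
        ("Helper", "Helper", "HelpHelp"),
    ])
    def test_mapping(self, a, b, expected):
        assert status_pair_category(a, b) == expected
        assert status_pair_category(b, a) == expected  # order invariance

    def test_cross_group_pairs_rejected(self):
        with pytest.raises(ValueError, match="within a group"):
            status_pair_category("DomM", "Sub", group_a="G1", group_b="G2")

    def test_lump_is_total_partition_of_the_five_levels(self):
        lumped = {c: nest_sharing_lump(c) for c in STATUS_PAIR_LEVELS}
        assert lumped["DomDom"] == lumped["DomHelp"] == "nest_sharing"
        assert all(lumped[c] == "non_nest_sharing"
                   for c in ("DomSub", "HelpSub", "SubSub"))
        with pytest.raises(ValueError):
            nest_sharing_lump("HelpHelp")


class TestSharedNest:
    def test_parent_attending_natal_nest(self):
        parent = pd.Series({"bird_id": "p", "natal_nest_id": "NX_p",
                            "present_at_nest_ids": "NX_p;N1"})
        chick = pd.Series({"bird_id": "c", "natal_nest_id": "N1",
                           "present_at_nest_ids": "N1"})
        assert shared_nest_at_hatch(parent, chick)
        assert shared_nest_at_hatch(chick, parent)  # symmetric

    def test_siblings_share_natal_nest(self):
        a = pd.Series({"natal_nest_id": "N1", "present_at_nest_ids": "N1"})
        b = pd.Series({"natal_nest_id": "N1", "present_at_nest_ids": "N1"})
        assert shared_nest_at_hatch(a, b)

    def test_immigrants_with_disjoint_histories(self):
        a = pd.Series({"natal_nest_id": "NX_a", "present_at_nest_ids": "NX_a"})
        b = pd.Series({"natal_nest_id": "NX_b", "present_at_nest_ids": "NX_b"})
        assert not shared_nest_at_hatch(a, b)

    def test_missing_record_is_false_with_warning(self, caplog):
        a = pd.Series({"bird_id": "a", "natal_nest_id": None,
                       "present_at_nest_ids": ""})
        b = pd.Series({"bird_id": "b", "natal_nest_id": "N1",
                       "present_at_nest_ids": "N1"})
        with caplog.at_level("WARNING"):
            assert not shared_nest_at_hatch(a, b)
        assert "missing natal nest" in caplog.text


class TestFilterWithinGroup:
    def test_within_rows_only_with_categories(self, small_bundle):
        within = filter_within_group(small_bundle.dyads)
        assert (within["same_group"] == 1).all()
        assert set(within["status_pair"]) <= set(STATUS_PAIR_LEVELS)
        assert set(within["nest_sharing"]) <= {"nest_sharing", "non_nest_sharing"}
        meta = small_bundle.metadata.set_index("sample_id")
        assert (meta.loc[within["sample_a"], "group_id"].to_numpy()
                == meta.loc[within["sample_b"], "group_id"].to_numpy()).all()

    def test_all_between_input_is_error(self):
        meta = _meta([{"sample_id": "s1", "bird_id": "b1", "group_id": "G1"},
                      {"sample_id": "s2", "bird_id": "b2", "group_id": "G2"}])
        dyads = build_dyads(meta, *_inputs(meta))
        with pytest.raises(ValueError, match="within-group"):
            filter_within_group(dyads)

    def test_helper_helper_rows_excluded(self, caplog):
        meta = _meta([{"sample_id": "s1", "bird_id": "b1", "status": "Helper"},
                      {"sample_id": "s2", "bird_id": "b2", "status": "Helper"},
                      {"sample_id": "s3", "bird_id": "b3", "status": "DomM"}])
        dyads = build_dyads(meta, *_inputs(meta))
        with caplog.at_level("WARNING"):
            within = filter_within_group(dyads)
        assert "Helper-Helper" in caplog.text
        assert len(within) == 2  # the two Dom-Help pairs survive
        assert set(within["status_pair"]) == {"DomHelp"}
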