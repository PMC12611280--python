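"""Classification, cluster calling against the brute-force oracle, statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutstem.labels import (
    call_clusters,
    class_counts,
    classify,
    cluster_stats,
    positional_profile,
)

from conftest import oracle_clusters, random_section


def _section_from_flags(isc_flags, unit_id=0):
    """Single-unit section with given ISC-class membership per row."""
    n = len(isc_flags)
    return pd.DataFrame(
        {
            "animal_id": "A1",
            "section_id": "S0",
            "unit_id": unit_id,
            "position_index": np.arange(n),
            "zone": "IFR",
            "dapi": 1,
            "brdu": np.asarray(isc_flags, dtype=int),
            "edu": 0,
            "pcna": 1,
        }
    )


class TestClassify:
    @pytest.mark.parametrize(
        "brdu,edu,expected",
        [
            (1, 0, "QUIESCENT_ISC"),
            (1, 1, "CYCLING_ISC"),
            (0, 1, "CYCLING_NON_LRC"),
            (0, 0, "UNLABELED"),
        ],
    )
    def test_four_way_mapping(self, brdu, edu, expected):
        df = _section_from_flags([0])
        df["brdu"], df["edu"] = brdu, edu
        assert classify(df)["cell_class"].iloc[0] == expected

    def test_counts_match_marginal_recount(self):
        rng = np.random.default_rng(0)
        df = _section_from_flags(rng.integers(0, 2, 10**4))
        df["edu"] = rng.integers(0, 2, 10**4)
        counts = class_counts(classify(df))
        b, e = df["brdu"].to_numpy(), df["edu"].to_numpy()
        assert counts["QUIESCENT_ISC"] == ((b == 1) & (e == 0)).sum()
        assert counts["CYCLING_ISC"] == ((b == 1) & (e == 1)).sum()
        assert counts["CYCLING_NON_LRC"] == ((b == 0) & (e == 1)).sum()
        assert counts["UNLABELED"] == ((b == 0) & (e == 0)).sum()
        assert counts.sum() == len(df)

    def test_missing_column_named_in_error(self):
        df = _section_from_flags([1]).drop(columns=["edu"])
        with pytest.raises(KeyError, match="edu"):
            classify(df)

    def test_nonbinary_label_rejected(self):
        df = _section_from_flags([1])
        df.loc[0, "brdu"] = 2
        with pytest.raises(ValueError, match="brdu"):
            classify(df)

    def test_invariant_to_row_permutation(self):
        rng = np.random.default_rng(3)
        df = classify(_section_from_flags(rng.integers(0, 2, 200)))
        shuffled = df.sample(frac=1.0, random_state=1).sort_values("position_index")
        assert (
            shuffled["cell_class"].to_numpy() == df["cell_class"].to_numpy()
        ).all()


class TestCallClusters:
    def test_gap_of_exactly_ten_joins(self):
        """Two ISC cells with 10 intervening nuclei form one cluster."""
        flags = np.zeros(20, dtype=int)
        flags[5] = flags[16] = 1
        calls = call_clusters(classify(_section_from_flags(flags)))
        assert len(calls) == 1
        assert calls.iloc[0]["isc_count"] == 2
        assert calls.iloc[0]["span_cell_count"] == 12

    def test_gap_of_eleven_splits(self):
        flags = np.zeros(25, dtype=int)
        flags[0] = flags[8] = flags[20] = 1  # gaps 7 and 11
        calls = call_clusters(classify(_section_from_flags(flags)))
        assert len(calls) == 1
        assert calls.iloc[0]["first_index"] == 0
        assert calls.iloc[0]["last_index"] == 8
        assert calls.iloc[0]["isc_count"] == 2

    def test_singleton_is_not_a_cluster(self):
        flags = np.zeros(10, dtype=int)
        flags[4] = 1
        assert len(call_clusters(classify(_section_from_flags(flags)))) == 0

    def test_unordered_input_raises(self):
        df = classify(_section_from_flags([1, 0, 1]))
        df["position_index"] = [2, 1, 0]
        with pytest.raises(ValueError, match="increasing"):
            call_clusters(df)

    def test_clusters_never_span_units(self):
        a = classify(_section_from_flags([1, 1], unit_id=0))
        b = classify(_section_from_flags([1, 1], unit_id=1))
        calls = call_clusters(pd.concat([a, b], ignore_index=True))
        assert len(calls) == 2
        assert set(calls["unit_id"]) == {0, 1}

    def test_matches_oracle_on_random_sections(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            df = classify(random_section(rng))
            max_gap = int(rng.integers(1, 21))
            got = call_clusters(df, max_gap=max_gap)
            got_t = sorted(
                (r.animal_id, r.section_id, r.unit_id, r.first_index,
                 r.last_index, r.span_cell_count, r.isc_count)
                for r in got.itertuples()
            )
            assert got_t == oracle_clusters(df, max_gap)

    @given(
        flags=st.lists(st.booleans(), min_size=2, max_size=60),
        gaps=st.tuples(st.integers(0, 12), st.integers(0, 12)),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_max_gap_monotonicity(self, flags, gaps):
        """Growing max_gap merges clusters: fewer calls, larger max span."""
        df = classify(_section_from_flags([int(f) for f in flags]))
        g1, g2 = min(gaps), max(gaps)
        c1, c2 = call_clusters(df, max_gap=g1), call_clusters(df, max_gap=g2)
        if len(c1) and len(c2):
            assert len(c2) <= len(c1)
            assert c2["span_cell_count"].max() >= c1["span_cell_count"].max()

    def test_output_clusters_disjoint_and_maximal(self):
        rng = np.random.default_rng(5)
        df = classify(random_section(rng, n_cells=150))
        calls = call_clusters(df, max_gap=6).sort_values("first_index")
        spans = list(zip(calls["first_index"], calls["last_index"]))
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 < b0  # disjoint, ordered
            # merging adjacent clusters would violate the gap rule
            between = df[(df["position_index"] > a1) & (df["position_index"] < b0)]
            assert len(between) > 6


class TestClusterStats:
    def test_span_and_member_counting(self):
        flags = np.zeros(20, dtype=int)
        flags[5] = flags[16] = 1
        calls = call_clusters(classify(_section_from_flags(flags)))
        st_ = cluster_stats(calls, {"A1": "g"})
        row = st_.per_group.set_index("metric")
        assert row.loc["span_cell_count", "mean"] == 12
        assert row.loc["isc_count", "mean"] == 2

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(1)
        frames = []
        for i, animal in enumerate(["A1", "A2", "B1", "B2"]):
            df = classify(random_section(rng, n_cells=100))
            df["animal_id"] = animal
            frames.append(call_clusters(df.iloc[: 50 + 0 * i]))
        # same cluster calls under both labels: paired test on identical means
        calls_a = pd.concat(frames[:2], ignore_index=True)
        calls_b = calls_a.copy()
        calls_b["animal_id"] = calls_b["animal_id"].map({"A1": "B1", "A2": "B2"})
        calls = pd.concat([calls_a, calls_b], ignore_index=True)
        groups = {"A1": "ga", "A2": "ga", "B1": "gb", "B2": "gb"}
        st_ = cluster_stats(calls, groups, paired=True)
        assert (st_.tests["p_value"] > 0.99).all()

    def test_empty_group_flagged(self):
        flags = np.zeros(20, dtype=int)
        flags[5] = flags[16] = 1
        calls = call_clusters(classify(_section_from_flags(flags)))
        st_ = cluster_stats(calls, {"A1": "ga", "ZZ": "gb"})
        assert st_.excluded_groups == ("gb",)


class TestPositionalProfile:
    def test_all_in_ifr(self):
        df = classify(_section_from_flags([1, 1, 0, 1]))
        prof = positional_profile(df, target="QUIESCENT_ISC")
        assert prof.loc["A1", "IFR"] == 1.0
        assert prof.loc["A1"].sum() == 1.0

    def test_uniform_over_equal_zones(self):
        df = classify(_section_from_flags([1, 1, 1, 1]))
        df["zone"] = ["IFR", "FOLD_LOWER", "FOLD_UPPER", "APEX"]
        prof = positional_profile(df, target="QUIESCENT_ISC")
        assert np.allclose(prof.loc["A1"].to_numpy(), 0.25)

    def test_unknown_zone_rejected(self):
        df = classify(_section_from_flags([1]))
        df["zone"] = "CRYPT"
        with pytest.raises(ValueError, match="zone"):
            positional_profile(df, target="QUIESCENT_ISC")

    def test_cluster_centroid_profile(self):
        flags = np.zeros(8, dtype=int)
        flags[2] = flags[4] = 1
        df = classify(_section_from_flags(flags))
        calls = call_clusters(df)
        prof = positional_profile(df, target="clusters", calls=calls)
        assert prof.loc["A1", "IFR"] == 1.0
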