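import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from treburden.calling import (
    NOISE,
    CallParams,
    LocusMotifProfile,
    call_expansion_carriers,
    call_expansions,
    canonical_motif,
    classify_cpg,
    clustered_ceiling,
    dbscan_1d,
    merge_regions,
    rarity_filter,
    sample_qc_mask,
    TRECall,
)
from treburden.exceptions import ConfigError

from oracles import canonical_motif_oracle, dbscan_oracle, merge_intervals_oracle, relabel_by_position

MOTIF_ST = st.text(alphabet="ACGT", min_size=2, max_size=20)


class TestCanonicalMotif:
    @pytest.mark.parametrize(
        "motif,expected",
        [("GCA", "AGC"), ("AT", "AT"), ("CGG", "CCG"), ("GGC", "CCG"), ("CG", "CG")],
    )
    def test_examples(self, motif, expected):
        assert canonical_motif(motif) == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(MOTIF_ST)
    def test_matches_enumeration_oracle_and_idempotent(self, motif):
        c = canonical_motif(motif)
        assert c == canonical_motif_oracle(motif)
        assert canonical_motif(c) == c

    def test_rejects_non_acgt(self):
        with pytest.raises(ConfigError):
            canonical_motif("ANT")


class TestClassifyCpg:
    @pytest.mark.parametrize(
        "motif", ["CG", "GC", "CGC", "CGG", "CCG", "GCC", "GGC", "GCG"]
    )
    def test_cpg_motifs_positive(self, motif):
        assert classify_cpg(motif)

    @pytest.mark.parametrize("motif", ["AT", "GA", "AAAG", "AGAT"])
    def test_non_cpg_negative(self, motif):
        # "GA" circularises to "GAGA": no CG/GC anywhere
        assert not classify_cpg(motif)

    def test_circular_scan_across_boundary(self):
        # "GAC" doubled is "GACGAC": the CG spans the junction
        assert classify_cpg("GAC")


class TestMergeRegions:
    @staticmethod
    def _df(ivs, motifs=None):
        motifs = motifs or ["AG"] * len(ivs)
        return pd.DataFrame(
            {
                "contig": ["chr1"] * len(ivs),
                "start": [s for s, _ in ivs],
                "end": [e for _, e in ivs],
                "motif": motifs,
            }
        )

    def test_one_bp_overlap_merges_with_motif_union(self):
        out = merge_regions(self._df([(100, 200), (150, 260)], ["AG", "AGG"]))
        assert len(out) == 1
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (100, 260)
        assert out.loc[0, "motifs"] == frozenset({"AG", "AGG"})

    def test_abutting_half_open_intervals_stay_separate(self):
        out = merge_regions(self._df([(100, 200), (200, 300)]))
        assert len(out) == 2

    def test_idempotent(self):
        first = merge_regions(self._df([(0, 10), (5, 20), (40, 50)]))
        again = merge_regions(
            first.assign(motif=[sorted(m)[0] for m in first["motifs"]])[
                ["contig", "start", "end", "motif"]
            ]
        )
        assert list(again["start"]) == list(first["start"])
        assert list(again["end"]) == list(first["end"])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 80), st.integers(1, 30)), min_size=1, max_size=12
        )
    )
    def test_matches_per_base_painting_oracle(self, raw):
        ivs = [(s, s + w) for s, w in raw]
        out = merge_regions(self._df(ivs))
        got = list(zip(out["start"], out["end"]))
        assert got == merge_intervals_oracle(ivs)


class TestDbscan1d:
    def test_small_example(self):
        labels = dbscan_1d([10, 11, 10, 12, 11, 55], eps=5, min_samples=3)
        assert list(labels[:5]) == [0] * 5
        assert labels[5] == NOISE

    def test_identical_values_single_cluster(self):
        labels = dbscan_1d([7.0] * 10, eps=1, min_samples=3)
        assert set(labels) == {0}

    def test_empty_input(self):
        assert dbscan_1d([], eps=1, min_samples=2).size == 0

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 21))
            v = np.round(rng.uniform(0, 50, n), 1)
            eps = float(rng.uniform(0.5, 10))
            ms = int(rng.integers(2, 6))
            got = relabel_by_position(dbscan_1d(v, eps, ms).tolist(), v.tolist())
            assert got == dbscan_oracle(v, eps, ms)

    def test_raising_eps_never_increases_noise(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            v = rng.uniform(0, 100, int(rng.integers(5, 30)))
            noise = [
                int(np.sum(dbscan_1d(v, eps, 3) == NOISE)) for eps in (2, 5, 10, 25)
            ]
            assert noise == sorted(noise, reverse=True)


class TestCallExpansions:
    def _profile(self, lengths):
        return LocusMotifProfile("chr1", 100, 160, "AGC", lengths)

    def test_right_tail_outlier_called(self):
        prof = self._profile(
            {"s1": 10, "s2": 11, "s3": 10, "s4": 12, "s5": 11, "s6": 55}
        )
        tre = call_expansions(prof, CallParams(eps=5, min_samples=3, min_cohort=5))
        assert tre is not None and tre.carriers == frozenset({"s6"})

    def test_left_tail_outlier_is_not_an_expansion(self):
        lengths = {f"s{i}": 10 + (i % 3) for i in range(10)}
        lengths["low"] = 1.0
        tre = call_expansions(self._profile(lengths), CallParams(eps=5, min_samples=3))
        assert tre is None

    def test_all_equal_yields_none(self):
        tre = call_expansions(
            self._profile({f"s{i}": 20.0 for i in range(12)}),
            CallParams(eps=5, min_samples=3),
        )
        assert tre is None

    def test_all_noise_yields_none(self):
        # pairwise gaps all exceed eps: no reference cluster
        lengths = {f"s{i}": 1000.0 * i for i in range(12)}
        tre = call_expansions(self._profile(lengths), CallParams(eps=5, min_samples=3))
        assert tre is None

    def test_below_min_cohort_yields_none(self):
        tre = call_expansions(
            self._profile({"a": 10, "b": 11, "c": 300}),
            CallParams(eps=5, min_samples=2, min_cohort=10),
        )
        assert tre is None

    def test_invariant_under_sample_permutation(self):
        rng = np.random.default_rng(3)
        base = {f"s{i}": float(x) for i, x in enumerate(rng.normal(60, 15, 40))}
        base["exp"] = 400.0
        params = CallParams(eps=50, min_samples=4)
        ref = call_expansions(self._profile(base), params)
        for seed in range(5):
            keys = list(base)
            np.random.default_rng(seed).shuffle(keys)
            tre = call_expansions(self._profile({k: base[k] for k in keys}), params)
            assert tre is not None and tre.carriers == ref.carriers

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1000, allow_nan=False), min_size=10, max_size=40),
        st.floats(1, 100),
        st.integers(2, 6),
    )
    def test_ceiling_shortcut_equals_dbscan_path(self, values, eps, min_samples):
        v = np.round(np.asarray(values), 1)
        params = CallParams(eps=eps, min_samples=min_samples)
        idx = call_expansion_carriers(v, params)
        via_dbscan = set() if idx is None else set(idx.tolist())
        t = clustered_ceiling(np.sort(v), eps, min_samples)
        via_ceiling = set() if t is None else set(np.flatnonzero(v > t).tolist())
        assert via_dbscan == via_ceiling


class TestRarityFilter:
    @staticmethod
    def _tre(carriers):
        return TRECall("chr1", 0, 60, "AGC", frozenset(carriers))

    def test_two_of_2504_panel_carriers_is_rare(self):
        panel = {f"p{i}" for i in range(2504)}
        tre = self._tre({"case1", "p0", "p1"})
        assert rarity_filter(tre, panel, 2504).is_rare
        assert tre.panel_carrier_count == 2

    def test_three_of_2504_panel_carriers_is_not_rare(self):
        panel = {f"p{i}" for i in range(2504)}
        tre = rarity_filter(self._tre({"p0", "p1", "p2"}), panel, 2504)
        assert not tre.is_rare

    def test_zero_panel_carriers_is_rare(self):
        assert rarity_filter(self._tre({"case1"}), {"p0"}, 2504).is_rare

    def test_monotone_in_threshold(self):
        panel = {f"p{i}" for i in range(1000)}
        tre = self._tre({"p0", "p1", "p2"})
        rare_at = [
            rarity_filter(tre, panel, 1000, threshold=t).is_rare
            for t in (0.001, 0.003, 0.0031, 0.01, 0.5)
        ]
        assert rare_at == sorted(rare_at)  # once rare, stays rare as t grows


def test_sample_qc_drops_only_high_outliers():
    counts = pd.Series([100, 101, 99, 102, 100, 100, 500], dtype=float)
    keep = sample_qc_mask(counts, k=3.0)
    assert keep.tolist() == [True] * 6 + [False]
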