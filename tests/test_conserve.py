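"""RBH orthology, tissue specificity, IoU, conservation scores, KS test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lncnet.conserve import (
    OUTFMT6_COLUMNS,
    OrthologPair,
    TissueProfile,
    collapse_to_genes,
    compare_distributions,
    conservation_score,
    ortholog_expression_correlation,
    read_bedgraph,
    read_hit_table,
    reciprocal_best_hits,
    tf_family_iou,
    tsi,
    write_hit_table,
)
from lncnet.synthetic import SyntheticConfig, generate_expression, generate_hit_tables


def hit_frame(rows):
    """rows: (qseqid, sseqid, evalue, bitscore)."""
    data = [
        {"qseqid": q, "sseqid": s, "pident": 90.0, "length": 100,
         "mismatch": 1, "gapopen": 0, "qstart": 1, "qend": 100,
         "sstart": 1, "send": 100, "evalue": e, "bitscore": b}
        for q, s, e, b in rows
    ]
    return pd.DataFrame(data, columns=OUTFMT6_COLUMNS)


class TestReciprocalBestHits:
    def test_synthetic_truth_recovered_without_decoys(self):
        cfg = SyntheticConfig(seed=3, n_decoy_hits=0)
        _, truth = generate_expression(cfg)
        fwd, rev = generate_hit_tables(truth, cfg)
        pairs = reciprocal_best_hits(fwd, rev)
        assert {(p.gene_a, p.gene_b) for p in pairs} == set(truth.ortholog_pairs)

    def test_decoys_above_threshold_change_nothing(self):
        cfg_clean = SyntheticConfig(seed=3, n_decoy_hits=0)
        cfg_noisy = SyntheticConfig(seed=3, n_decoy_hits=50)
        _, truth = generate_expression(cfg_clean)
        clean = reciprocal_best_hits(*generate_hit_tables(truth, cfg_clean))
        noisy = reciprocal_best_hits(*generate_hit_tables(truth, cfg_noisy))
        assert {(p.gene_a, p.gene_b) for p in clean} == {
            (p.gene_a, p.gene_b) for p in noisy
        }

    def test_one_directional_best_hit_excluded(self):
        # b1 is a's best hit, but b1's best hit is a2: no pair (a, b1)
        fwd = hit_frame([("a", "b1", 1e-30, 300), ("a2", "b1", 1e-20, 250)])
        rev = hit_frame([("b1", "a2", 1e-25, 280)])
        pairs = reciprocal_best_hits(fwd, rev)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a2", "b1")]

    def test_all_hits_above_threshold_gives_empty(self):
        fwd = hit_frame([("a", "b", 1e-4, 40)])
        rev = hit_frame([("b", "a", 1e-4, 40)])
        assert reciprocal_best_hits(fwd, rev) == []

    def test_evalue_tie_broken_by_bitscore_then_subject(self):
        fwd = hit_frame([("a", "b_low", 1e-20, 100), ("a", "b_hi", 1e-20, 200)])
        rev = hit_frame([("b_hi", "a", 1e-20, 200)])
        pairs = reciprocal_best_hits(fwd, rev)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a", "b_hi")]

    def test_symmetry_under_table_swap(self):
        cfg = SyntheticConfig(seed=9)
        _, truth = generate_expression(cfg)
        fwd, rev = generate_hit_tables(truth, cfg)
        ab = {(p.gene_a, p.gene_b) for p in reciprocal_best_hits(fwd, rev)}
        ba = {(p.gene_b, p.gene_a) for p in reciprocal_best_hits(rev, fwd)}
        assert ab == ba
        # one-to-one: no gene appears twice
        assert len({a for a, _ in ab}) == len(ab)
        assert len({b for _, b in ab}) == len(ab)

    def test_collapse_to_genes(self):
        pairs = [
            OrthologPair("gA.t1", "gB.t1", 1e-30, 1e-28),
            OrthologPair("gA.t2", "gB.t2", 1e-20, 1e-18),
        ]
        tx2g = {"gA.t1": "gA", "gA.t2": "gA"}
        tx2g_b = {"gB.t1": "gB", "gB.t2": "gB"}
        collapsed = collapse_to_genes(pairs, tx2g, tx2g_b)
        assert len(collapsed) == 1
        assert collapsed[0].gene_a == "gA" and collapsed[0].forward_evalue == 1e-30

    def test_round_trip_and_bad_evalue(self, tmp_path):
        fwd = hit_frame([("a", "b", 1e-20, 100)])
        write_hit_table(fwd, tmp_path / "h.tsv")
        back = read_hit_table(tmp_path / "h.tsv")
        pd.testing.assert_frame_equal(back, fwd)


class TestTsi:
    def test_single_tissue_is_one(self):
        assert tsi([0, 0, 7, 0]) == 1.0

    def test_uniform_is_reciprocal_n(self):
        assert tsi([2, 2, 2, 2]) == pytest.approx(0.25)

    def test_hand_example(self):
        assert tsi([1, 2, 3, 4]) == pytest.approx(0.4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            tsi([0.0, 0.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 10))
    def test_bounds_for_positive_profiles(self, seed, n):
        x = np.random.default_rng(seed).uniform(0.01, 10, size=n)
        assert 1 / n <= tsi(x) <= 1


class TestOrthologCorrelation:
    def profiles(self, values):
        tissues = [f"t{i}" for i in range(len(next(iter(values.values()))))]
        return TissueProfile(tissues, {g: np.asarray(v, float) for g, v in values.items()})

    def test_identical_profiles(self):
        pa = self.profiles({"a": [1, 2, 3, 4, 5]})
        pb = self.profiles({"b": [1, 2, 3, 4, 5]})
        out = ortholog_expression_correlation(
            [OrthologPair("a", "b", 0, 0)], pa, pb
        )
        assert out.rs.iloc[0] == pytest.approx(1.0)

    def test_reversed_profiles(self):
        pa = self.profiles({"a": [1, 2, 3, 4, 5]})
        pb = self.profiles({"b": [5, 4, 3, 2, 1]})
        out = ortholog_expression_correlation(
            [OrthologPair("a", "b", 0, 0)], pa, pb
        )
        assert out.rs.iloc[0] == pytest.approx(-1.0)

    def test_mismatched_tissue_lists_rejected(self):
        pa = TissueProfile(["t0", "t1", "t2", "t3"], {"a": np.arange(4.0)})
        pb = TissueProfile(["t0", "t1", "t3", "t2"], {"b": np.arange(4.0)})
        with pytest.raises(ValueError):
            ortholog_expression_correlation([OrthologPair("a", "b", 0, 0)], pa, pb)

    def test_constant_profile_skipped(self):
        pa = self.profiles({"a": [2, 2, 2, 2, 2]})
        pb = self.profiles({"b": [1, 2, 3, 4, 5]})
        out = ortholog_expression_correlation(
            [OrthologPair("a", "b", 0, 0)], pa, pb
        )
        assert out.empty

    def test_true_pairs_beat_shuffled_pairs(self):
        from lncnet.synthetic import generate_tissue_profiles
        cfg = SyntheticConfig(seed=4)
        matrix, truth = generate_expression(cfg)
        pa, pb = generate_tissue_profiles(matrix, truth, cfg)
        true_pairs = [OrthologPair(a, b, 0, 0) for a, b in truth.ortholog_pairs]
        rng = np.random.default_rng(0)
        bs = [b for _, b in truth.ortholog_pairs]
        shuffled = [
            OrthologPair(a, bs[j], 0, 0)
            for (a, _), j in zip(truth.ortholog_pairs,
                                 rng.permutation(len(bs)))
        ]
        rs_true = ortholog_expression_correlation(true_pairs, pa, pb).rs
        rs_rand = ortholog_expression_correlation(shuffled, pa, pb).rs
        assert rs_true.mean() > rs_rand.mean()


class TestTfFamilyIou:
    def test_identical_sets(self):
        assert tf_family_iou({"A", "B"}, {"A", "B"}) == 1.0

    def test_disjoint_sets(self):
        assert tf_family_iou({"A"}, {"B"}) == 0.0

    def test_partial_overlap(self):
        assert tf_family_iou({"A", "B"}, {"B", "C"}) == pytest.approx(1 / 3)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            tf_family_iou(set(), set())

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.sets(st.sampled_from("ABCDEFGH")),
        st.sets(st.sampled_from("ABCDEFGH")),
    )
    def test_bounds_and_equality(self, a, b):
        if not (a | b):
            return
        s = tf_family_iou(a, b)
        assert 0 <= s <= 1
        assert (s == 1) == (a == b)


class TestConservationScore:
    def test_uniform_track(self):
        track = {"chr1": [(0, 1000, 0.8)]}
        assert conservation_score([(10, 110)], "chr1", track) == pytest.approx(0.8)

    def test_outside_track_scores_zero(self):
        assert conservation_score([(10, 110)], "chr9", {"chr1": [(0, 10, 1.0)]}) == 0.0

    def test_length_weighted_mean(self):
        track = {"chr1": [(0, 100, 1.0), (100, 1000, 0.0)]}
        # exons of lengths 10 and 30 scoring 1.0 and 0.0 -> 0.25
        assert conservation_score(
            [(50, 60), (200, 230)], "chr1", track
        ) == pytest.approx(0.25)

    def test_invariant_to_exon_splitting(self):
        track = {"chr1": [(0, 50, 0.9), (50, 150, 0.3)]}
        whole = conservation_score([(20, 120)], "chr1", track)
        split = conservation_score([(20, 70), (70, 120)], "chr1", track)
        assert whole == pytest.approx(split, abs=1e-12)

    def test_bedgraph_round_trip(self, tmp_path):
        (tmp_path / "t.bedgraph").write_text("chr1\t0\t50\t0.9\nchr1\t50\t100\t0.1\n")
        track = read_bedgraph(tmp_path / "t.bedgraph")
        assert track["chr1"] == [(0, 50, 0.9), (50, 100, 0.1)]

    def test_negative_interval_rejected(self, tmp_path):
        (tmp_path / "bad.bedgraph").write_text("chr1\t50\t10\t0.9\n")
        with pytest.raises(ValueError):
            read_bedgraph(tmp_path / "bad.bedgraph")


class TestCompareDistributions:
    def test_identical_samples(self):
        a = np.arange(10.0)
        d, p = compare_distributions(a, a)
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = compare_distributions([0.1, 0.5, 0.9], [2.1, 2.5, 2.9])
        assert d == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([], [1.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_small_sample_brute_force_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=int(rng.integers(2, 9)))
        b = rng.normal(1.0, size=int(rng.integers(2, 9)))
        d, p = compare_distributions(a, b)
        # brute-force sup of |ECDF difference| over every data point
        points = np.concatenate([a, b])
        brute = max(
            abs((a <= x).mean() - (b <= x).mean()) for x in points
        )
        assert d == pytest.approx(brute, abs=1e-12)
        ref = stats.ks_2samp(a, b, method="asymp")
        assert d == pytest.approx(ref.statistic, abs=1e-12)
        # limiting-series p, re-derived term by term:
        # Q(x) = 2 * sum_{j>=1} (-1)^(j-1) exp(-2 j^2 x^2)
        x = np.sqrt(len(a) * len(b) / (len(a) + len(b))) * d
        series = 2 * sum(
            (-1) ** (j - 1) * np.exp(-2 * j**2 * x**2) for j in range(1, 101)
        )
        assert p == pytest.approx(min(1.0, max(0.0, series)), abs=1e-8)
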