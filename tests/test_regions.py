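"""Region extension, overlap counting, the permutation test and annotation."""

import numpy as np
import pandas as pd
import pytest

from methyltf import (
    RegionSet,
    annotate_regions,
    count_overlaps,
    extend_probes_to_regions,
    permutation_overlap_test,
)
from methyltf.regions import build_promoters

BOUNDS = {"chr1": 100_000}


def regions(rows, name="r", bounds=BOUNDS):
    df = pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])
    return RegionSet(name, df, dict(bounds))


class TestExtend:
    def test_coordinate_arithmetic(self):
        probes = pd.DataFrame({"probe_id": ["p"], "chrom": ["chr1"], "pos": [1000]})
        rs = extend_probes_to_regions(probes, 200, BOUNDS)
        assert (rs.df.loc[0, "Start"], rs.df.loc[0, "End"]) == (799, 1200)
        assert rs.df.loc[0, "End"] - rs.df.loc[0, "Start"] == 401

    def test_clamped_at_contig_start(self):
        probes = pd.DataFrame({"probe_id": ["p"], "chrom": ["chr1"], "pos": [50]})
        rs = extend_probes_to_regions(probes, 200, BOUNDS)
        assert (rs.df.loc[0, "Start"], rs.df.loc[0, "End"]) == (0, 250)

    def test_off_contig_probe_skipped(self):
        probes = pd.DataFrame(
            {"probe_id": ["p", "q"], "chrom": ["chr1", "chr9"], "pos": [500, 5]}
        )
        with pytest.warns(UserWarning, match="off-contig"):
            rs = extend_probes_to_regions(probes, 100, BOUNDS)
        assert len(rs) == 1


class TestCountOverlaps:
    def test_identity_and_disjoint(self):
        a = regions([("chr1", 10, 20), ("chr1", 50, 70)])
        n, frac = count_overlaps(a, a)
        assert (n, frac) == (2, 1.0)
        b = regions([("chr1", 1000, 1100)])
        assert count_overlaps(a, b) == (0, 0.0)

    def test_single_base_overlap_counts(self):
        a = regions([("chr1", 10, 20)])
        b = regions([("chr1", 19, 30)])
        assert count_overlaps(a, b)[0] == 1
        c = regions([("chr1", 20, 30)])  # half-open: adjacent, no shared base
        assert count_overlaps(a, c)[0] == 0

    def test_each_query_counts_once(self):
        a = regions([("chr1", 0, 100)])
        b = regions([("chr1", 10, 20), ("chr1", 30, 40)])
        assert count_overlaps(a, b) == (1, 1.0)

    def test_order_and_split_invariance(self):
        rs = np.random.default_rng(3)
        starts = rs.integers(0, 90_000, size=60)
        a = regions([("chr1", s, s + 500) for s in starts])
        bstarts = rs.integers(0, 90_000, size=40)
        brows = [("chr1", s, s + 300) for s in bstarts]
        b = regions(brows)
        shuffled = regions([brows[i] for i in rs.permutation(40)])
        assert count_overlaps(a, b) == count_overlaps(a, shuffled)
        b1, b2 = regions(brows[:17]), regions(brows[17:])
        n_union = count_overlaps(a, b)[0]
        n1 = {i for i in range(60)
              if count_overlaps(regions([("chr1", starts[i], starts[i]+500)]), b1)[0]}
        n2 = {i for i in range(60)
              if count_overlaps(regions([("chr1", starts[i], starts[i]+500)]), b2)[0]}
        assert len(n1 | n2) == n_union

    def test_empty_query_flagged(self):
        a = RegionSet("a", pd.DataFrame(columns=["Chromosome", "Start", "End"]),
                      dict(BOUNDS))
        with pytest.warns(UserWarning, match="empty"):
            n, frac = count_overlaps(a, regions([("chr1", 0, 10)]))
        assert n == 0 and np.isnan(frac)


def exact_overlap_tail(a_lengths, b_interval, genome_len, observed):
    """P(overlap count >= observed) under uniform independent placement,
    by exhaustive enumeration of every start position per region."""
    bs, be = b_interval
    probs = []
    for L in a_lengths:
        starts = np.arange(genome_len - L + 1)
        hit = (starts < be) & (starts + L > bs)
        probs.append(hit.mean())
    # distribution of sum of independent Bernoullis
    dist = np.array([1.0])
    for q in probs:
        dist = np.convolve(dist, [1 - q, q])
    return dist[observed:].sum()


class TestPermutation:
    def test_p_floor_when_observed_beats_all(self):
        bounds = {"chr1": 100_000}
        b = regions([("chr1", 0, 500)], bounds=bounds)
        a = regions([("chr1", i * 50, i * 50 + 40) for i in range(10)],
                    bounds=bounds)
        res = permutation_overlap_test(a, b, n_perms=1000, seed=1)
        assert res.observed == 10
        assert res.p_value == pytest.approx(1 / 1001)
        assert round(res.p_value, 3) == 0.001

    def test_p_is_one_when_b_covers_genome(self):
        bounds = {"chr1": 10_000}
        b = regions([("chr1", 0, 10_000)], bounds=bounds)
        a = regions([("chr1", 100, 200), ("chr1", 5_000, 5_100)], bounds=bounds)
        res = permutation_overlap_test(a, b, n_perms=200, seed=2)
        assert res.p_value == 1.0

    def test_matches_exact_enumeration_on_toy_genome(self):
        bounds = {"chr1": 1000}
        a = regions([("chr1", 100, 150), ("chr1", 300, 330)], bounds=bounds)
        b = regions([("chr1", 90, 200)], bounds=bounds)
        res = permutation_overlap_test(a, b, n_perms=10_000, seed=3)
        assert res.observed == 1
        p_exact = exact_overlap_tail([50, 30], (90, 200), 1000, res.observed)
        se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(res.p_value - p_exact) <= 3 * se + 1 / 10_001

    def test_interval_beyond_bounds_rejected(self):
        # an interval that does not fit its own chromosome is invalid
        with pytest.raises(ValueError):
            RegionSet("x", pd.DataFrame(
                [("chr1", 0, 200)], columns=["Chromosome", "Start", "End"]),
                {"chr1": 100})

    def test_p_bounds_and_permutation_count(self):
        bounds = {"chr1": 5000, "chr2": 3000}
        rs = np.random.default_rng(9)
        a = regions([("chr1", int(s), int(s) + 50)
                     for s in rs.integers(0, 4000, 5)], bounds=bounds)
        b = regions([("chr2", int(s), int(s) + 80)
                     for s in rs.integers(0, 2500, 5)], bounds=bounds)
        res = permutation_overlap_test(a, b, n_perms=99, seed=4)
        assert len(res.permuted) == 99
        assert 1 / 100 <= res.p_value <= 1.0

    def test_super_uniform_under_null(self):
        """With the query set itself placed at random, P(p <= a) <= a + MC tol."""
        bounds = {"chr1": 20_000}
        rs = np.random.default_rng(7)
        bstarts = rs.integers(0, 19_000, size=15)
        b = regions([("chr1", int(s), int(s) + 400) for s in bstarts],
                    bounds=bounds)
        pvals = []
        for i in range(200):
            astarts = rs.integers(0, 19_500, size=8)
            a = regions([("chr1", int(s), int(s) + 200) for s in astarts],
                        bounds=bounds)
            pvals.append(
                permutation_overlap_test(a, b, n_perms=49, seed=1000 + i).p_value)
        pvals = np.array(pvals)
        for alpha in (0.05, 0.1, 0.2):
            tol = 3 * np.sqrt(alpha * (1 - alpha) / 200)
            assert (pvals <= alpha).mean() <= alpha + tol


class TestAnnotate:
    def test_promoter_spans(self):
        genes = pd.DataFrame(
            {"Chromosome": ["chr1", "chr1"], "Start": [10_000, 5_000],
             "End": [12_000, 10_001], "Strand": ["+", "-"]}
        )
        prom = build_promoters(genes)
        # + strand TSS at 10,000: [9000, 10200] inclusive
        assert (prom.loc[0, "Start"], prom.loc[0, "End"]) == (9_000, 10_201)
        # - strand TSS at 10,000: [9800, 11000] inclusive
        assert (prom.loc[1, "Start"], prom.loc[1, "End"]) == (9_800, 11_001)

    def test_missing_strand_rejected(self):
        genes = pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [10], "End": [20], "Strand": [None]}
        )
        enh = regions([("chr1", 0, 10)])
        with pytest.raises(ValueError):
            annotate_regions(regions([("chr1", 0, 5)]), genes, enh)

    def test_promoter_precedence_and_counts(self):
        genes = pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [10_000], "End": [12_000],
             "Strand": ["+"]}
        )
        enh = regions([("chr1", 9_500, 10_500), ("chr1", 40_000, 41_000)])
        probes = pd.DataFrame(
            {"probe_id": ["in_both", "enh_only", "neither"],
             "chrom": ["chr1"] * 3, "pos": [10_001, 40_500, 70_000]}
        )
        target = extend_probes_to_regions(probes, 200, BOUNDS)
        classes, counts = annotate_regions(target, genes, enh)
        assert list(classes) == ["promoter", "enhancer", "unannotated"]
        assert sum(counts.values()) == len(target)


class TestRandomizePlacements:
    def test_lengths_preserved_and_bounds_respected(self):
        from methyltf.regions import randomize_placements

        bounds = {"chr1": 5000, "chr2": 900, "chr3": 12_000}
        lengths = np.array([1000, 50, 11_999, 200, 200])
        rng = np.random.default_rng(0)
        for _ in range(200):
            chroms, starts = randomize_placements(lengths, bounds, rng)
            ends = starts + lengths
            assert (starts >= 0).all()
            for c, s, e, L in zip(chroms, starts, ends, lengths):
                assert e - s == L
                assert e <= bounds[c]

    def test_unplaceable_length_rejected(self):
        from methyltf.regions import randomize_placements

        with pytest.raises(ValueError):
            randomize_placements(np.array([200]), {"chr1": 100},
                                 np.random.default_rng(1))
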