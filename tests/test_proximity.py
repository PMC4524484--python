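"""Nearest-site distances, HAS derivation, rank statistics, Fig.-4 profile."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from scdc.annotation import BindingSiteSet, GeneModel
from scdc.proximity import (
    colocalize_has,
    distances_to_nearest,
    magnitude_distance_profile,
    min_distance,
    spearman,
    wilcoxon_rank_sum,
)


def _gene(start, end, gid="g", chrom="X"):
    return GeneModel(gene_id=gid, chrom=chrom, start=start, end=end)


def _sites(*ivs, component="MLE"):
    return BindingSiteSet(component=component, intervals=[("X", s, e) for s, e in ivs])


class TestMinDistance:
    def test_overlap_is_zero(self):
        assert min_distance(_gene(100, 200), _sites((150, 400))) == 0

    def test_gap_to_right_site(self):
        assert min_distance(_gene(100, 200), _sites((300, 350))) == 100

    def test_nearest_of_two_sites(self):
        assert min_distance(_gene(100, 200), _sites((10, 20), (500, 600))) == 80

    def test_no_sites_on_chromosome_errors(self):
        sites = BindingSiteSet(component="MLE", intervals=[("2L", 5, 9)])
        with pytest.raises(ValueError, match="distance undefined"):
            min_distance(_gene(100, 200), sites)

    def test_equals_four_endpoint_minimum(self):
        # the edge-gap shortcut must equal the literal endpoint rule
        rng = np.random.default_rng(11)
        for _ in range(200):
            gs = int(rng.integers(1, 10_000))
            ge = gs + int(rng.integers(0, 500))
            ss = int(rng.integers(1, 10_000))
            se = ss + int(rng.integers(0, 300))
            gene, sites = _gene(gs, ge), _sites((ss, se))
            if ss <= ge and se >= gs:
                assert min_distance(gene, sites) == 0
            else:
                endpoint_min = min(
                    abs(p - q) for p in (ss, se) for q in (gs, ge)
                )
                assert min_distance(gene, sites) == endpoint_min

    def test_vectorised_matches_brute_force_oracle(self):
        # all-pairs scan over 1,000 genes x 1,000 sites
        rng = np.random.default_rng(12)
        site_starts = np.sort(rng.choice(2_000_000, size=1000, replace=False))
        site_ends = site_starts + rng.integers(1, 400, size=1000)
        sites = _sites(*zip(site_starts.tolist(), site_ends.tolist()))
        gene_starts = rng.integers(1, 2_000_000, size=1000)
        gene_ends = gene_starts + rng.integers(1, 3000, size=1000)
        genes = [
            _gene(int(s), int(e), gid=f"g{i}")
            for i, (s, e) in enumerate(zip(gene_starts, gene_ends))
        ]
        fast = distances_to_nearest(genes, sites)

        gs = gene_starts[:, None]
        ge = gene_ends[:, None]
        ss = site_starts[None, :]
        se = site_ends[None, :]
        overlap = (ss <= ge) & (se >= gs)
        gaps = np.minimum.reduce(
            [np.abs(ss - gs), np.abs(ss - ge), np.abs(se - gs), np.abs(se - ge)]
        )
        brute = np.where(overlap, 0, gaps).min(axis=1)
        assert np.array_equal(fast, brute)


class TestColocalizeHas:
    def test_intersection_span(self):
        has = colocalize_has(_sites((100, 200)), _sites((150, 250), component="MSL2"))
        assert has.intervals == [("X", 150, 200)]

    def test_disjoint_gives_no_has(self):
        has = colocalize_has(_sites((100, 200)), _sites((300, 400), component="MSL2"))
        assert len(has) == 0

    def test_one_mle_two_msl2_overlaps(self):
        has = colocalize_has(
            _sites((100, 300)),
            _sites((120, 140), (200, 220), component="MSL2"),
        )
        assert has.intervals == [("X", 120, 140), ("X", 200, 220)]

    def test_empty_input_warns_and_returns_empty(self, caplog):
        has = colocalize_has(
            BindingSiteSet(component="MLE", intervals=[]),
            _sites((1, 10), component="MSL2"),
        )
        assert len(has) == 0

    def test_has_distances_dominate_mle_distances(self):
        # HAS coverage is a subset of MLE coverage, so every gene is at
        # least as far from a HAS as from an MLE site
        rng = np.random.default_rng(13)
        starts = np.sort(rng.choice(500_000, size=60, replace=False))
        mle = _sites(*[(int(s), int(s) + 300) for s in starts])
        msl2_starts = np.sort(rng.choice(500_000, size=60, replace=False))
        msl2 = _sites(
            *[(int(s), int(s) + 300) for s in msl2_starts], component="MSL2"
        )
        has = colocalize_has(mle, msl2)
        if len(has) == 0:
            pytest.skip("random fixture produced no colocalization")
        genes = [
            _gene(int(s), int(s) + 1000, gid=f"g{i}")
            for i, s in enumerate(rng.integers(1, 500_000, size=200))
        ]
        d_mle = distances_to_nearest(genes, mle)
        d_has = distances_to_nearest(genes, has)
        assert np.all(d_has >= d_mle)


class TestSpearman:
    def test_perfectly_increasing(self):
        rho, _ = spearman([(i, 10 * i) for i in range(1, 6)])
        assert rho == pytest.approx(1.0)

    def test_perfectly_decreasing(self):
        rho, _ = spearman([(i, -3 * i) for i in range(1, 6)])
        assert rho == pytest.approx(-1.0)

    def test_tie_averaged_ranks_small_case(self):
        # pairs (1,10),(2,10),(3,30): ranks x=(1,2,3), y=(1.5,1.5,3)
        rho, _ = spearman([(1, 10), (2, 10), (3, 30)])
        rx = np.array([1.0, 2.0, 3.0])
        ry = np.array([1.5, 1.5, 3.0])
        brute = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(brute)

    def test_zero_variance_undefined(self):
        rho, p = spearman([(1, 5), (2, 5), (3, 5)])
        assert math.isnan(rho)
        assert p == 1.0

    def test_exact_permutation_p_matches_enumeration(self):
        pairs = [(1, 3), (2, 1), (3, 4), (4, 2), (5, 5)]
        rho, p = spearman(pairs)
        x = np.array([p_[0] for p_ in pairs], dtype=float)
        y = np.array([p_[1] for p_ in pairs], dtype=float)
        rx = np.argsort(np.argsort(x)) + 1.0
        count = total = 0
        for perm in itertools.permutations(np.argsort(np.argsort(y)) + 1.0):
            r = np.corrcoef(rx, np.array(perm))[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        assert p == pytest.approx(count / total)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        base, base_p = spearman(list(zip(x, y)))
        trans, trans_p = spearman(list(zip(np.exp(x), y**3 + 5 * y)))
        # y**3+5y is strictly increasing; exp is strictly increasing
        assert trans == pytest.approx(base)
        assert trans_p == pytest.approx(base_p)


class TestWilcoxonRankSum:
    def test_identical_groups_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_extreme_separation_exact(self):
        # most extreme of the C(6,3)=20 rank assignments, two-sided
        assert wilcoxon_rank_sum([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_shift_invariance(self):
        rng = np.random.default_rng(15)
        a = rng.normal(size=8)
        b = rng.normal(1.0, 1.0, size=9)
        assert wilcoxon_rank_sum(a, b) == pytest.approx(
            wilcoxon_rank_sum(a + 100, b + 100)
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestMagnitudeDistanceProfile:
    def test_single_bin_occupancy(self):
        rec = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "call": ["MBG", "MBG"],
                "log2_ratio": [0.5, 0.9],  # both <= 2-fold
                "distance_bp": [100, 300],
            }
        )
        prof = magnitude_distance_profile(rec).set_index("bin")
        assert prof.loc["<=2-fold", "n"] == 2
        assert prof["n"].sum() == 2

    def test_medians_match_groupby_oracle(self):
        rng = np.random.default_rng(16)
        n = 200
        rec = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "call": ["MBG"] * n,
                "log2_ratio": rng.uniform(0.1, 4.0, size=n),
                "distance_bp": rng.integers(0, 50_000, size=n),
            }
        )
        prof = magnitude_distance_profile(rec).set_index("bin")
        from scdc.sexbias import magnitude_bin

        oracle = rec.groupby(
            rec["log2_ratio"].map(lambda r: magnitude_bin(r).value)
        )["distance_bp"].median()
        for b, med in oracle.items():
            assert prof.loc[b, "median_distance_bp"] == pytest.approx(med)
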