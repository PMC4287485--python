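"""DMR calling: candidates, likelihood-ratio test, grouping, hDMRs."""

import itertools

import numpy as np
import pytest
from scipy import stats

from methylseg.dmr import (
    Dmr,
    StrainGrouping,
    build_candidates,
    classify_hdmrs,
    filter_candidates,
    group_level_test,
    group_strains,
    lrt_pairwise,
    resolve_overlaps,
)
from methylseg.hmm import MethylatedRegion
from methylseg.io import SamplePool

from conftest import make_pool, make_table


def mr(chrom, start, end):
    return MethylatedRegion(chrom, start, end, 1.0, 5)


class TestCandidates:
    def test_identical_mrs_give_spanning_candidate(self):
        cands = build_candidates({"A": [mr("chr1", 100, 200)],
                                  "B": [mr("chr1", 100, 200)]})
        assert [(c.start, c.end) for c in cands] == [(100, 200)]
        assert cands[0].high_strains == {"A", "B"}

    def test_breakpoint_enumeration_on_shifted_mrs(self):
        # A: [100,200], B: [150,250] -> breakpoints {100,150,200,250};
        # candidates are those pairs fully HIGH in >= 1 strain
        cands = build_candidates({"A": [mr("chr1", 100, 200)],
                                  "B": [mr("chr1", 150, 250)]})
        got = {(c.start, c.end): set(c.high_strains) for c in cands}
        expected = {
            (100, 150): {"A"}, (100, 200): {"A"},
            (150, 200): {"A", "B"}, (150, 250): {"B"}, (200, 250): {"B"},
        }
        assert got == expected  # (100, 250) covered fully by no strain

    def test_disjoint_components_never_combine(self):
        cands = build_candidates({"A": [mr("chr1", 100, 200)],
                                  "B": [mr("chr1", 500, 600)]})
        spans = [(c.start, c.end) for c in cands]
        assert (200, 500) not in spans and (100, 600) not in spans

    def test_needs_two_strains(self):
        with pytest.raises(ValueError):
            build_candidates({"A": [mr("chr1", 1, 2)]})


def _pool_with_sites(acc, n_sites, depth=5, rate=0.5, start=100, step=10):
    rows = [
        ("chr1", start + i * step, "+", "CG", int(round(rate * depth)), depth)
        for i in range(n_sites)
    ]
    return make_pool(acc, [make_table(rows, sample_id=acc)])


class TestCandidateFilters:
    def test_sparse_strain_excluded_by_half_max_rule(self):
        from methylseg.dmr import StrainData

        data = {
            "A": StrainData(_pool_with_sites("A", 12)),
            "B": StrainData(_pool_with_sites("B", 11)),
            "C": StrainData(_pool_with_sites("C", 3)),
        }
        from methylseg.dmr import CandidateSegment

        cand = CandidateSegment("chr1", 100, 220, frozenset({"A"}),
                                frozenset({"A", "B", "C"}))
        out = filter_candidates([cand], data)
        assert len(out) == 1
        assert out[0].admissible_strains == {"A", "B"}  # C: 3 < 12/2

    def test_reciprocal_overlap_discards_similar_region(self):
        from methylseg.dmr import CandidateSegment, StrainData

        data = {
            "A": StrainData(_pool_with_sites("A", 20)),
            "B": StrainData(_pool_with_sites("B", 20)),
        }
        c1 = CandidateSegment("chr1", 100, 200, frozenset({"A"}),
                              frozenset({"A", "B"}))
        c2 = CandidateSegment("chr1", 110, 210, frozenset({"A"}),
                              frozenset({"A", "B"}))  # reciprocal 91/101 > 0.7
        out = filter_candidates([c1, c2], data)
        assert [(c.start, c.end) for c in out] == [(100, 200)]

    def test_low_low_pairs_not_scheduled(self):
        from methylseg.dmr import CandidateSegment, StrainData

        data = {
            "A": StrainData(_pool_with_sites("A", 15)),
            "B": StrainData(_pool_with_sites("B", 15)),
            "C": StrainData(_pool_with_sites("C", 15)),
        }
        cand = CandidateSegment("chr1", 100, 250, frozenset({"A"}),
                                frozenset({"A"}))  # B, C fully LOW
        out = filter_candidates([cand], data)
        assert ("B", "C") not in out[0].admissible_pairs
        assert ("A", "B") in out[0].admissible_pairs


def _counts(rng, n_sites, depth, mu, nu=10.0):
    r = rng.beta(mu * nu, (1 - mu) * nu, n_sites)
    n = np.full(n_sites, depth, dtype=float)
    x = rng.binomial(depth, r).astype(float)
    return {"CG": (x, n)}


class TestPairwiseLrt:
    def test_identical_data_gives_null_result(self, rng):
        c = _counts(rng, 12, 20, 0.5)
        t = lrt_pairwise("chr1", 1, 100, "A", "B", c, c)
        assert t.lr == pytest.approx(0.0, abs=1e-6)
        assert t.p_value == pytest.approx(1.0, abs=1e-6)
        assert not t.prefilter_pass

    def test_chi2_quantile_reference(self):
        # LR = 12.592 on 6 df sits at p ~ 0.05
        assert stats.chi2.sf(12.592, 6) == pytest.approx(0.05, abs=1e-4)

    def test_strong_difference_detected_with_prefilter(self, rng):
        ca = _counts(rng, 15, 20, 0.85)
        cb = _counts(rng, 15, 20, 0.05)
        t = lrt_pairwise("chr1", 1, 100, "A", "B", ca, cb)
        assert t.p_value < 1e-6
        assert t.prefilter_pass
        assert t.lr >= 0

    def test_missing_context_reduces_df(self, rng):
        ca = _counts(rng, 10, 20, 0.8)
        cb = _counts(rng, 10, 20, 0.1)
        t = lrt_pairwise("chr1", 1, 100, "A", "B", ca, cb)
        assert t.df == 2  # only CG present
        ca["CHG"] = ca["CG"]
        cb["CHG"] = cb["CG"]
        t2 = lrt_pairwise("chr1", 1, 100, "A", "B", ca, cb)
        assert t2.df == 4

    def test_strain_likelihood_dominates_common(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            ca = _counts(r, 10, 15, r.uniform(0.2, 0.8))
            cb = _counts(r, 10, 15, r.uniform(0.2, 0.8))
            t = lrt_pairwise("chr1", 1, 100, "A", "B", ca, cb)
            assert t.lr >= 0  # nested models


def brute_force_chromatic_number(n, edges):
    if not edges:
        return 1 if n else 0
    for k in range(1, n + 1):
        for colors in itertools.product(range(k), repeat=n):
            if all(colors[a] != colors[b] for a, b in edges):
                return k
    return n


class TestGrouping:
    def test_worked_example_group_mean(self):
        blue = [0.89, 0.90, 0.90, 0.93, 0.87]
        grouping = group_strains(
            ["D", "F", "G", "J", "L"],
            [],
            {s: np.array([v]) for s, v in zip("DFGJL", blue)},
        )
        gm = list(grouping.group_means.values())[0]
        assert gm[0] * 100 == pytest.approx(89.8)

    def test_isolated_strain_joins_nearest_group(self):
        # blue group mean ~0.898, white ~0.52; strain with mean 0.81 -> blue
        means = {
            "D": np.array([0.89]), "F": np.array([0.93]), "G": np.array([0.90]),
            "J": np.array([0.90]), "X": np.array([0.87]),
            "a": np.array([0.52]), "b": np.array([0.52]),
            "L": np.array([0.81]),  # no edges
        }
        edges = [(h, l) for h in "DFGJX" for l in "ab"]
        grouping = group_strains(list(means), edges, means)
        assert grouping.assignment["L"] == grouping.assignment["D"]
        assert grouping.n_groups == 2

    def test_lowest_diversity_coloring_chosen(self):
        # path A-B-C is 2-colorable two ways: {A,C}|{B} fits the means
        means = {"A": np.array([0.8]), "B": np.array([0.1]),
                 "C": np.array([0.82])}
        grouping = group_strains(["A", "B", "C"], [("A", "B"), ("B", "C")], means)
        assert grouping.assignment["A"] == grouping.assignment["C"]
        assert grouping.assignment["A"] != grouping.assignment["B"]

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            group_strains(["A"], [("A", "A")], {"A": np.array([0.5])})

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_chromatic_number_matches_brute_force_sampled(self, n, rng):
        verts = [f"S{i}" for i in range(n)]
        means = {v: np.array([rng.uniform()]) for v in verts}
        all_edges = list(itertools.combinations(range(n), 2))
        for _ in range(40):
            mask = rng.random(len(all_edges)) < 0.5
            edges = [e for e, m in zip(all_edges, mask) if m]
            truth = brute_force_chromatic_number(n, edges)
            grouping = group_strains(
                verts, [(verts[a], verts[b]) for a, b in edges], means
            )
            assert grouping.n_groups == max(truth, 1)


class TestGroupTestAndHdmrs:
    def test_identical_groups_not_a_dmr(self, rng):
        c = _counts(rng, 12, 20, 0.5)
        grouping = StrainGrouping({"A": 0, "B": 1}, {}, 0.0, 2)
        d = group_level_test("chr1", 1, 100, grouping, {"A": c, "B": dict(c)})
        assert d.p_value > 0.5

    def test_separated_groups_detected(self, rng):
        # group A mu 0.8 vs group B mu 0.1, 15 CG sites depth 20
        ca1 = _counts(rng, 15, 20, 0.8)
        ca2 = _counts(rng, 15, 20, 0.8)
        cb1 = _counts(rng, 15, 20, 0.1)
        cb2 = _counts(rng, 15, 20, 0.1)
        grouping = StrainGrouping({"A1": 0, "A2": 0, "B1": 1, "B2": 1}, {}, 0.0, 2)
        d = group_level_test("chr1", 1, 100, grouping,
                             {"A1": ca1, "A2": ca2, "B1": cb1, "B2": cb2})
        assert d.p_value < 1e-8

    def _dmr(self, start, end, diversity, rates=None):
        g = StrainGrouping({"A": 0, "B": 1}, {}, diversity, 2)
        d = Dmr("chr1", start, end, g, 10.0, 6, 1e-5, 1e-4)
        if rates:
            d.group_rates = rates
        return d

    def test_overlap_resolution_keeps_lowest_diversity(self):
        d1 = self._dmr(100, 200, 1.2)
        d2 = self._dmr(150, 250, 3.4)
        kept = resolve_overlaps([d2, d1])
        assert [(d.start, d.end) for d in kept] == [(100, 200)]

    def test_disjoint_dmrs_all_kept_and_overlap_free(self, rng):
        dmrs = [self._dmr(int(s), int(s) + 40, float(rng.uniform()))
                for s in range(0, 1000, 100)]
        kept = resolve_overlaps(dmrs)
        assert len(kept) == len(dmrs)
        # sweep check
        spans = sorted((d.start, d.end) for d in kept)
        assert all(spans[i][1] < spans[i + 1][0] for i in range(len(spans) - 1))

    def test_random_overlap_resolution_is_overlap_free(self, rng):
        dmrs = [
            self._dmr(int(s), int(s + rng.integers(20, 120)),
                      float(rng.uniform()))
            for s in rng.integers(0, 800, size=30)
        ]
        kept = resolve_overlaps(dmrs)
        spans = sorted((d.start, d.end) for d in kept)
        assert all(spans[i][1] < spans[i + 1][0] for i in range(len(spans) - 1))

    def test_hdmr_rule_application(self):
        rates_pass = {0: {"CG": (54.0, 60.0, 6)}, 1: {"CG": (12.0, 60.0, 6)}}
        hd = classify_hdmrs([self._dmr(100, 159, 1.0, rates_pass)])
        assert len(hd) == 1
        assert hd[0].fold_change == pytest.approx((54 / 60) / (12 / 60))

    def test_short_dmr_not_hdmr(self):
        rates = {0: {"CG": (54.0, 60.0, 6)}, 1: {"CG": (6.0, 60.0, 6)}}
        assert classify_hdmrs([self._dmr(100, 144, 1.0, rates)]) == []

    def test_weak_fold_not_hdmr(self):
        rates = {0: {"CG": (15.0, 60.0, 6)}, 1: {"CG": (6.0, 60.0, 6)}}
        assert classify_hdmrs([self._dmr(100, 159, 1.0, rates)]) == []

    def test_low_max_rate_not_hdmr(self):
        rates = {0: {"CG": (9.0, 60.0, 6)}, 1: {"CG": (1.0, 60.0, 6)}}
        assert classify_hdmrs([self._dmr(100, 159, 1.0, rates)]) == []

    def test_zero_denominator_counts_as_infinite_fold(self):
        rates = {0: {"CG": (30.0, 60.0, 6)}, 1: {"CG": (0.0, 60.0, 6)}}
        hd = classify_hdmrs([self._dmr(100, 159, 1.0, rates)])
        assert len(hd) == 1 and np.isinf(hd[0].fold_change)

    def test_few_context_sites_not_hdmr(self):
        rates = {0: {"CG": (54.0, 60.0, 4)}, 1: {"CG": (6.0, 60.0, 4)}}
        assert classify_hdmrs([self._dmr(100, 159, 1.0, rates)]) == []
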