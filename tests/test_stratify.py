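import numpy as np
import pytest

from hergsar.chem import CompoundRecord
from hergsar.stratify import (
    HeteroatomEffectAnalysis,
    Stratum,
    build_strata,
    detect_effects,
    filter_strata,
    select_pair,
    trend_summary,
)
from hergsar.synthetic import gen_library

from conftest import make_stratum, records_from_compositions


def _recs(census_pic50s, prefix="C"):
    """Records from (formula, pIC50) pairs."""
    return [
        CompoundRecord(id=f"{prefix}{i}", pic50=p, formula=f)
        for i, (f, p) in enumerate(census_pic50s)
    ]


class TestBuildStrata:
    def test_direct_partition_example(self):
        recs = _recs(
            [("C9H13NO3", 5.0), ("C8H12N2O2", 6.0), ("C10H15NO3", 7.0)]
        )
        strata = build_strata(recs, "N")
        keys = {(s.focal_count, s.total_heteroatoms): s.size for s in strata}
        assert keys == {(1, 4): 2, (2, 4): 1}

    def test_partition_law_on_synthetic_library(self):
        recs = gen_library(300, seed=11)
        for focal in ("N", "O", "S", "Cl"):
            strata = build_strata(recs, focal)
            assert sum(s.size for s in strata) == 300
            all_ids = [i for s in strata for i in s.member_ids]
            assert len(all_ids) == len(set(all_ids))

    def test_central_values_within_member_range(self):
        recs = gen_library(200, seed=4)
        for s in build_strata(recs, "O"):
            lo, hi = min(s.member_pic50s), max(s.member_pic50s)
            assert lo <= s.median_pic50 <= hi
            assert lo <= s.mean_pic50 <= hi


class TestFilterStrata:
    def test_min_size_five(self):
        strata = [
            Stratum("O", i, 5, [f"X{i}{j}" for j in range(n)], [5.0 + 0.1 * j for j in range(n)])
            for i, n in enumerate((4, 5, 6))
        ]
        assert [s.size for s in filter_strata(strata, 5)] == [5, 6]

    def test_min_size_one_is_identity(self):
        recs = gen_library(150, seed=2)
        strata = build_strata(recs, "N")
        assert filter_strata(strata, 1) == strata

    def test_against_count_then_filter_oracle(self):
        recs = gen_library(1000, seed=9)
        strata = build_strata(recs, "Cl")
        survivors = filter_strata(strata, 5)
        # independent oracle: count key frequencies directly
        from collections import Counter

        counts = Counter(
            (r.census.get("Cl"), r.census.total) for r in recs
        )
        expected = {k for k, v in counts.items() if v >= 5}
        assert {(s.focal_count, s.total_heteroatoms) for s in survivors} == expected


class TestDetectEffects:
    def test_flags_printed_magnitude_pair(self, pair1_strata):
        weak, strong = pair1_strata
        pairs = detect_effects([weak, strong], threshold=0.9, central="mean")
        assert len(pairs) == 1
        assert pairs[0].delta == pytest.approx(1.03, abs=1e-9)

    def test_equal_centrals_no_pairs(self):
        a = make_stratum("O", 1, 6, 5.5, prefix="A")
        b = make_stratum("O", 2, 6, 5.5, prefix="B")
        assert detect_effects([a, b], threshold=0.9) == []

    def test_threshold_boundary_laws(self):
        a = make_stratum("O", 0, 6, 5.0, prefix="A")
        b = make_stratum("O", 2, 6, 5.4, prefix="B")
        c = make_stratum("O", 4, 6, 6.1, prefix="C")
        strata = [a, b, c]
        assert detect_effects(strata, threshold=np.inf) == []
        every = detect_effects(strata, threshold=0.0)
        assert len(every) == 3  # all unequal pairs at the shared total

    def test_invariant_under_input_permutation(self):
        recs = gen_library(400, seed=6)
        strata = filter_strata(build_strata(recs, "O"), 5)
        fwd = detect_effects(strata)
        rev = detect_effects(strata[::-1])
        assert [(p.delta, p.weak_compound, p.strong_compound) for p in fwd] == [
            (p.delta, p.weak_compound, p.strong_compound) for p in rev
        ]

    def test_delta_self_consistency(self):
        recs = gen_library(600, seed=13)
        for focal in ("O", "N"):
            strata = filter_strata(build_strata(recs, focal), 5)
            for p in detect_effects(strata, threshold=0.5):
                assert p.delta == pytest.approx(
                    p.strong_stratum.mean_pic50 - p.weak_stratum.mean_pic50
                )

    def test_mixed_focal_elements_rejected(self):
        a = make_stratum("O", 1, 6, 5.0)
        b = make_stratum("N", 2, 6, 6.0)
        with pytest.raises(ValueError, match="mix"):
            detect_effects([a, b])

    def test_other_constant_mode_compares_across_totals(self):
        # O=0 and O=2 with the same non-focal count 4: totals differ (4 vs 6)
        a = make_stratum("O", 0, 4, 4.8, prefix="A")
        b = make_stratum("O", 2, 6, 6.0, prefix="B")
        assert detect_effects([a, b], mode="total") == []
        pairs = detect_effects([a, b], mode="other")
        assert len(pairs) == 1 and pairs[0].delta == pytest.approx(1.2, abs=1e-9)

    def test_planted_effect_flagged_no_spurious(self):
        """A planted 1.2-log oxygen effect at fixed total is flagged, and
        null stratum pairs stay silent, in >=95 of 100 seeded replicates."""
        hits, spurious_free = 0, 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            comps, pics = [], []
            # planted contrast at total 6: O=0 (mean 6.0) vs O=4 (mean 4.8)
            for o, mu in ((0, 6.0), (1, 5.7), (2, 5.4), (3, 5.1), (4, 4.8)):
                for _ in range(12):
                    comps.append((0, o, 0, 0, 6 - o))
                    pics.append(mu + 0.4 * r.standard_normal())
            # null strata at total 8: equal planted means
            for o in (0, 1):
                for _ in range(12):
                    comps.append((0, o, 0, 0, 8 - o))
                    pics.append(5.5 + 0.4 * r.standard_normal())
            recs = records_from_compositions(comps, pics)
            strata = filter_strata(build_strata(recs, "O"), 5)
            pairs = detect_effects(strata, threshold=0.9)
            planted = [
                p for p in pairs
                if p.total_heteroatoms == 6
                and {p.weak_stratum.focal_count, p.strong_stratum.focal_count} == {0, 4}
            ]
            if planted:
                hits += 1
            if not any(p.total_heteroatoms == 8 for p in pairs):
                spurious_free += 1
        assert hits >= 95
        assert spurious_free >= 95


class TestSelectPair:
    def test_returns_documented_extremes(self, pair1_strata):
        weak, strong = pair1_strata
        w, s = select_pair(weak, strong)
        assert w == ("CHEMBL70", pytest.approx(3.00))
        assert s == ("CHEMBL1257821", pytest.approx(9.85))

    def test_single_member_strata(self):
        a = Stratum("O", 0, 4, ["solo1"], [4.0])
        b = Stratum("O", 1, 4, ["solo2"], [6.0])
        assert select_pair(a, b) == (("solo1", 4.0), ("solo2", 6.0))

    def test_tie_broken_lexicographically(self):
        a = Stratum("O", 0, 4, ["A2", "A10"], [3.0, 3.0])
        b = Stratum("O", 1, 4, ["B9", "B10"], [7.0, 7.0])
        w, s = select_pair(a, b)
        assert w[0] == "A10"  # "A10" < "A2" lexicographically
        assert s[0] == "B10"

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            Stratum("O", 0, 4, [], [])


class TestTrendSummary:
    def test_planted_negative_slope_gives_decreasing(self):
        comps, pics = [], []
        for o in range(5):
            for j in range(8):
                comps.append((1, o, 0, 0, 0))
                pics.append(6.0 - 0.3 * o + 0.01 * (j % 3))
        recs = records_from_compositions(comps, pics)
        t = trend_summary(recs, "O")
        assert t.verdict == "decreasing" and t.spearman_rho < 0

    def test_constant_curve_is_flat(self):
        comps = [(1, o, 0, 0, 0) for o in range(3) for _ in range(6)]
        recs = records_from_compositions(comps, [5.5] * len(comps))
        t = trend_summary(recs, "O")
        assert t.verdict == "flat"

    def test_u_shaped_nitrogen_curve(self):
        g = {1: 0.0, 2: -0.4, 3: -0.8, 4: -0.5, 5: -0.2}
        comps, pics = [], []
        for n, off in g.items():
            for _ in range(8):
                comps.append((n, 0, 0, 0, 3))
                pics.append(6.0 + off)
        t = trend_summary(records_from_compositions(comps, pics), "N")
        assert t.verdict == "non-monotone"
        assert t.turning_point == 3

    def test_too_few_counts_rejected(self):
        comps = [(1, 2, 0, 0, 0)] * 10
        recs = records_from_compositions(comps, [5.0] * 10)
        with pytest.raises(ValueError, match="distinct"):
            trend_summary(recs, "O")


class TestAnalysisEstimator:
    def test_fit_populates_all_elements(self):
        recs = gen_library(500, seed=21)
        ana = HeteroatomEffectAnalysis().fit(recs)
        for el in ("N", "O", "S", "Cl"):
            assert sum(s.size for s in ana.strata_[el]) == 500
            assert all(s.size >= 5 for s in ana.qualifying_strata_[el])

    def test_get_params_round_trip(self):
        ana = HeteroatomEffectAnalysis(threshold=1.1)
        params = ana.get_params()
        assert params["threshold"] == 1.1
        ana.set_params(min_size=7)
        assert ana.min_size == 7
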