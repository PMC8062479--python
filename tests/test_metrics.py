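import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from envcomplexity.metrics import (
    CommunityMeasurement,
    classify_outcome,
    distribution_stats,
    epistasis_over_tree,
    epistasis_richness,
    epistasis_shannon,
    epistasis_yield,
    records_to_frame,
    shannon_entropy,
    species_richness,
)


class TestDiversity:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([1.0], 0.0),
            ([0.25, 0.25, 0.25, 0.25], 2.0),
            ([0.5, 0.25, 0.25], 1.5),
        ],
    )
    def test_shannon_entropy_values(self, p, expected):
        assert shannon_entropy(p) == pytest.approx(expected)

    def test_entropy_rejects_negative_and_unnormalized(self):
        with pytest.raises(ValueError):
            shannon_entropy([-0.1, 1.1])
        with pytest.raises(ValueError):
            shannon_entropy([0.5, 0.4])

    def test_entropy_bounded_by_log_richness(self, rng):
        p = rng.dirichlet(np.ones(6))
        h = shannon_entropy(p, normalize=True)
        assert 0.0 <= h <= math.log2(6) + 1e-12

    @pytest.mark.parametrize(
        "p,thr,expected",
        [
            ([0.0, 0.0], 0.0, 0),
            ([0.9, 0.1, 0.0], 0.0, 2),
            ([0.99, 0.0099, 0.0001], 1e-3, 2),
        ],
    )
    def test_species_richness(self, p, thr, expected):
        assert species_richness(p, thr) == expected


class TestEpistasisScores:
    @pytest.mark.parametrize(
        "yab,ya,yb,expected",
        [(0.3, 0.3, 0.3, 0.0), (0.13, 0.0, 0.0, 0.13), (0.1, 0.4, 0.2, -0.2)],
    )
    def test_yield_epistasis(self, yab, ya, yb, expected):
        assert epistasis_yield(yab, ya, yb) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "sab,sa,sb,expected",
        [(3, 3, 2, 0.0), (5, 3, 2, 2.0), (1, 3, 2, -2.0)],
    )
    def test_richness_epistasis(self, sab, sa, sb, expected):
        assert epistasis_richness(sab, sa, sb) == expected

    @pytest.mark.parametrize(
        "hab,ha,hb,expected",
        [(1.0, 1.0, 0.5, 0.0), (1.0, 0.0, 0.0, 1.0), (0.0, 2.0, 1.0, -2.0)],
    )
    def test_shannon_epistasis(self, hab, ha, hb, expected):
        assert epistasis_shannon(hab, ha, hb) == expected

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(0, 10, allow_nan=False),
        b=st.floats(0, 10, allow_nan=False),
        ab=st.floats(0, 10, allow_nan=False),
    )
    def test_symmetry_under_constituent_exchange(self, a, b, ab):
        assert epistasis_yield(ab, a, b) == epistasis_yield(ab, b, a)
        assert epistasis_shannon(ab, a, b) == epistasis_shannon(ab, b, a)
        sa, sb, sab = int(a), int(b), int(ab)
        assert epistasis_richness(sab, sa, sb) == epistasis_richness(sab, sb, sa)


def uniform_measurement(eid, taxa, yield_=0.3):
    n = len(taxa)
    return CommunityMeasurement(
        eid,
        yield_=yield_,
        abundances={t: 1.0 / n for t in taxa} if n else {},
        growth_flag=True,
    )


class TestEpistasisOverTree:
    def test_hierarchical_scheme_gives_31_records(self, tree32):
        meas = {
            eid: uniform_measurement(eid, ["x", "y"]) for eid in tree32.environments
        }
        records = epistasis_over_tree(tree32, meas, "E_Y")
        assert len(records) == 31
        assert all(r.E == pytest.approx(0.0) for r in records)

    def test_identical_measurements_give_zero_epistasis(self, tree8):
        meas = {
            eid: uniform_measurement(eid, ["x", "y", "z"])
            for eid in tree8.environments
        }
        for metric in ("E_Y", "E_S", "E_H"):
            records = epistasis_over_tree(tree8, meas, metric)
            assert all(r.E == pytest.approx(0.0) for r in records)

    def test_exact_additivity(self, tree8):
        # two singletons at 0.2 / 0.4 and composite at 0.3 -> E_Y = 0
        meas = {eid: uniform_measurement(eid, ["x"]) for eid in tree8.environments}
        comp, a, b = tree8.edge_records()[0]
        meas[a] = uniform_measurement(a, ["x"], 0.2)
        meas[b] = uniform_measurement(b, ["x"], 0.4)
        meas[comp] = uniform_measurement(comp, ["x"], 0.3)
        records = {r.composite_id: r for r in epistasis_over_tree(tree8, meas, "E_Y")}
        assert records[comp].E == pytest.approx(0.0)

    def test_no_growth_contributes_zero(self, tree8):
        meas = {
            eid: uniform_measurement(eid, ["x", "y"], 0.3)
            for eid in tree8.environments
        }
        comp, a, b = tree8.edge_records()[0]
        meas[a] = CommunityMeasurement(
            a, yield_=0.02, abundances={"x": 1.0}, growth_flag=False
        )
        ey = {r.composite_id: r for r in epistasis_over_tree(tree8, meas, "E_Y")}
        assert ey[comp].expected == pytest.approx(0.15)  # (0 + 0.3) / 2
        es = {r.composite_id: r for r in epistasis_over_tree(tree8, meas, "E_S")}
        assert es[comp].expected == 2.0  # max(0, 2)

    def test_missing_composite_yields_nan_gap(self, tree8):
        meas = {
            eid: uniform_measurement(eid, ["x"]) for eid in tree8.environments
        }
        comp = "8-1"  # top composite: not a constituent of anything
        del meas[comp]
        records = epistasis_over_tree(tree8, meas, "E_Y")
        assert len(records) == tree8.n_edges
        gap = [r for r in records if r.composite_id == comp]
        assert len(gap) == 1 and math.isnan(gap[0].observed)

    def test_composite_without_constituents_is_structural_error(self, tree8):
        meas = {
            eid: uniform_measurement(eid, ["x"]) for eid in tree8.environments
        }
        comp, a, _ = tree8.edge_records()[0]
        del meas[a]
        with pytest.raises(ValueError, match=comp):
            epistasis_over_tree(tree8, meas, "E_Y")


class TestOutcomeClassification:
    @pytest.mark.parametrize(
        "A,B,AB,label",
        [
            ({"x"}, {"x", "y"}, {"x", "z"}, "I"),
            ({"x"}, {"y"}, {"x", "y"}, "II"),
            ({"x", "y", "z"}, {"x"}, {"x"}, "III"),
            ({"x", "y"}, {"x", "z"}, {"y"}, "IV"),
        ],
    )
    def test_documented_examples(self, A, B, AB, label):
        assert classify_outcome(A, B, AB).label == label

    def test_all_empty_sets_are_type_ii(self):
        assert classify_outcome(set(), set(), set()).label == "II"

    def test_tie_on_richness_matches_either_side(self):
        assert classify_outcome({"x"}, {"y"}, {"y"}).label == "III"
        assert classify_outcome({"x"}, {"y"}, {"x"}).label == "III"

    def test_exhaustive_and_exclusive_on_three_taxa(self):
        universe = ["a", "b", "c"]
        subsets = [
            frozenset(s)
            for r in range(4)
            for s in itertools.combinations(universe, r)
        ]
        for A, B, AB in itertools.product(subsets, repeat=3):
            out = classify_outcome(A, B, AB)
            # independent rule table, evaluated definitionally
            novel = bool(AB - (A | B))
            union = AB == (A | B)
            less_rich = [s for s in (A, B) if len(s) == min(len(A), len(B))]
            dominated = any(AB == s for s in less_rich)
            if novel:
                expected = "I"
            elif union:
                expected = "II"
            elif dominated:
                expected = "III"
            else:
                expected = "IV"
            assert out.label == expected


class TestDistributionStats:
    def test_identical_distributions_not_significant(self):
        x = [0.1, -0.2, 0.3, 0.0, -0.1]
        s = distribution_stats(x, baseline=x)
        assert s.p_vs_baseline == pytest.approx(0.5)
        assert s.paired is True

    def test_degenerate_zero_distribution(self):
        s = distribution_stats([0.0, 0.0, 0.0])
        assert s.mean == 0.0 and s.sd == 0.0

    def test_planted_negative_shift_is_significant(self, rng):
        x = rng.normal(-0.5, 0.1, size=31)
        s = distribution_stats(x, alternative="less")
        assert s.p_vs_zero < 1e-3

    def test_unpaired_fallback_flagged(self, rng):
        s = distribution_stats(
            rng.normal(0, 1, 10), baseline=rng.normal(0, 1, 12)
        )
        assert s.paired is False

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            distribution_stats([0.1])


def test_records_frame_columns(tree8):
    meas = {eid: uniform_measurement(eid, ["x"]) for eid in tree8.environments}
    df = records_to_frame(epistasis_over_tree(tree8, meas, "E_S"))
    assert list(df.columns) == [
        "composite_id", "a_id", "b_id", "metric", "observed", "expected", "E",
    ]
    assert (df["metric"] == "E_S").all()
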