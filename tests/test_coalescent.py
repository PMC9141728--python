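import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retrophylo.marker_matrix import ORDERS, OUTGROUP, PRESENT, UNKNOWN
from retrophylo.coalescent import (
    CoalescentError,
    LocalPPConfig,
    anomaly_boundary,
    branch_length_from_concordance,
    concordance_from_branch_length,
    in_anomaly_zone,
    local_pp,
    quartet_pattern_counts,
    species_tree_from_markers,
)
from conftest import make_order_matrix


def mpmath_local_pp(counts, lam=0.5):
    """High-precision closed-form oracle: expanding (1-2u/3)^k binomially
    turns each weight into an exact alternating series, evaluated at 300
    decimal digits to absorb the cancellation."""
    from mpmath import binomial, mp, mpf

    mp.dps = 300
    n = sum(counts)
    vals = []
    for k in counts:
        s = mpf(0)
        for j in range(int(k) + 1):
            s += binomial(int(k), j) * (mpf(-2) / 3) ** j / (mpf(lam) + n - k + j)
        vals.append(mpf(lam) * mpf(3) ** (-(n - k)) * s)
    total = sum(vals)
    return tuple(float(v / total) for v in vals)


class TestBranchLength:
    def test_saturation_boundary_maps_to_zero(self):
        assert branch_length_from_concordance(1 / 3) == 0.0
        assert branch_length_from_concordance(0.1) == 0.0

    def test_closed_form_value(self):
        assert branch_length_from_concordance(0.6) == pytest.approx(
            -math.log(0.6), abs=1e-12
        )

    def test_full_concordance_capped(self):
        assert branch_length_from_concordance(1.0) == 10.0
        assert branch_length_from_concordance(1.0, t_max=5.0) == 5.0

    @given(st.floats(min_value=0.0, max_value=5.0))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_identity(self, t):
        q = concordance_from_branch_length(t)
        assert branch_length_from_concordance(q) == pytest.approx(t, abs=1e-12)

    @given(st.floats(min_value=5.0, max_value=10.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_on_long_branches(self, t):
        # near saturation 1 - q underflows toward the double-precision eps,
        # so only ~1e-11 absolute accuracy is representable
        q = concordance_from_branch_length(t)
        assert branch_length_from_concordance(q) == pytest.approx(t, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(CoalescentError):
            branch_length_from_concordance(1.5)


class TestAnomalyBoundary:
    def test_independent_formula_evaluation(self):
        # direct evaluation with plain floats, written out independently
        x = 0.149
        expected = math.log(
            2 / 3
            + (3 * math.e ** (2 * x) - 2)
            / (18 * (math.e ** (3 * x) - math.e ** (2 * x)))
        )
        assert anomaly_boundary(0.149) == pytest.approx(expected, rel=1e-12)
        assert anomaly_boundary(0.149) == pytest.approx(0.1746, abs=5e-4)

    def test_zero_crossing_near_0p2655(self):
        # bisection oracle for the root of a(x)
        lo, hi = 0.1, 1.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if anomaly_boundary(mid) > 0:
                lo = mid
            else:
                hi = mid
        assert (lo + hi) / 2 == pytest.approx(0.2655, abs=5e-4)
        assert 0.26 < (lo + hi) / 2 < 0.27

    def test_long_branches_have_no_anomaly_zone(self):
        assert anomaly_boundary(5.0) < 0
        # the x -> infinity limit of the bracket is 2/3, so a(x) -> ln(2/3)
        assert anomaly_boundary(50.0) == pytest.approx(math.log(2 / 3), abs=1e-6)

    def test_strictly_decreasing_on_unit_range(self):
        xs = np.linspace(0.01, 2.0, 200)
        vals = [anomaly_boundary(x) for x in xs]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_domain_error(self):
        with pytest.raises(CoalescentError):
            anomaly_boundary(0.0)


class TestAnomalyZone:
    @pytest.mark.parametrize(
        "x,y,expected",
        [(0.149, 0.0615, True), (0.1151, 0.0551, True), (1.0, 0.5, False)],
    )
    def test_zone_membership(self, x, y, expected):
        result = in_anomaly_zone(x, y)
        assert result.in_zone is expected
        if result.in_zone:
            assert result.a_x > 0


class TestLocalPP:
    @pytest.mark.parametrize("counts", [(0, 0, 0), (5, 5, 5)])
    def test_symmetric_counts_give_equal_thirds(self, counts):
        pps = local_pp(counts)
        assert pps == pytest.approx((1 / 3, 1 / 3, 1 / 3), abs=1e-9)

    def test_matches_high_precision_oracle(self):
        grid = [
            (30, 5, 5), (1, 0, 0), (10, 10, 0), (100, 40, 30),
            (2, 1, 1), (7, 3, 2),
        ]
        for counts in grid:
            pps = local_pp(counts)
            oracle = mpmath_local_pp(counts)
            assert pps == pytest.approx(oracle, abs=1e-6)
            assert sum(pps) == pytest.approx(1.0, abs=1e-9)

    def test_dominant_count_gives_high_support(self):
        assert local_pp((30, 5, 5))[0] > 0.95

    def test_monotone_in_first_count(self):
        vals = [local_pp((n1, 4, 4))[0] for n1 in range(0, 30, 3)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_negative_counts_rejected(self):
        with pytest.raises(CoalescentError):
            local_pp((-1, 0, 0))


class TestQuartetCounts:
    def test_pair_marker_votes_concordant(self, make_matrix):
        m = make_matrix([{"Cetartiodactyla", "Ferae"}])
        clusters = (
            ("Cetartiodactyla",),
            ("Ferae",),
            ("Perissodactyla",),
            ("Chiroptera",),
        )
        sup = quartet_pattern_counts(m, clusters)
        assert (sup.n1, sup.n2, sup.n3) == (1, 0, 0)

    def test_triple_marker_votes_concordant_at_parent_branch(self, make_matrix):
        m = make_matrix([{"Perissodactyla", "Cetartiodactyla", "Ferae"}])
        clusters = (
            ("Perissodactyla",),
            ("Cetartiodactyla", "Ferae"),
            ("Chiroptera",),
            ("Eulipotyphla", OUTGROUP),
        )
        sup = quartet_pattern_counts(m, clusters)
        # quadruples: 1 (Per) x 2 (Cet|Fer) x 1 (Chi) x 2 (Eul|OG) resolved
        assert sup.n1 == 4
        assert sup.n2 == sup.n3 == 0

    def test_unknown_taxa_do_not_vote(self, make_matrix):
        m = make_matrix([{"Cetartiodactyla", "Ferae"}])
        m.states[0, m.taxa.index("Perissodactyla")] = UNKNOWN
        clusters = (
            ("Cetartiodactyla",),
            ("Ferae",),
            ("Perissodactyla",),
            ("Chiroptera",),
        )
        sup = quartet_pattern_counts(m, clusters)
        assert sup.n == 0

    def test_invariant_to_relabeling_within_clusters(self, make_matrix):
        m = make_matrix(
            [{"Cetartiodactyla", "Ferae"}, {"Cetartiodactyla", "Perissodactyla"}]
        )
        a = quartet_pattern_counts(
            m,
            (("Cetartiodactyla",), ("Ferae",),
             ("Perissodactyla", "Chiroptera"), ("Eulipotyphla", OUTGROUP)),
        )
        b = quartet_pattern_counts(
            m,
            (("Cetartiodactyla",), ("Ferae",),
             ("Chiroptera", "Perissodactyla"), (OUTGROUP, "Eulipotyphla")),
        )
        assert (a.n1, a.n2, a.n3) == (b.n1, b.n2, b.n3)

    def test_empty_cluster_rejected(self, make_matrix):
        m = make_matrix([{"Cetartiodactyla", "Ferae"}])
        with pytest.raises(CoalescentError):
            quartet_pattern_counts(
                m, (("Cetartiodactyla",), (), ("Ferae",), ("Chiroptera",))
            )


class TestSpeciesTree:
    def test_single_affiliation_resolves_toward_clade(self, make_matrix):
        m = make_matrix([{"Cetartiodactyla", "Ferae"}] * 30)
        sptree, ties = species_tree_from_markers(m, outgroup=OUTGROUP)
        clade = frozenset({"Cetartiodactyla", "Ferae"})
        assert clade in sptree.branches
        assert sptree.branches[clade].pp[0] > 0.99

    def test_too_many_lineages_rejected(self):
        from retrophylo.marker_matrix import PresenceAbsenceMatrix

        taxa = [f"t{i}" for i in range(8)]
        m = make_order_matrix([], taxa=taxa)
        m = PresenceAbsenceMatrix(
            ["m1"], taxa, np.ones((1, 8), dtype=np.int8)
        )
        with pytest.raises(CoalescentError):
            species_tree_from_markers(m)
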