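import numpy as np
import pytest

from retrophylo.marker_matrix import ABSENT, ORDERS, OUTGROUP, PRESENT, UNKNOWN, OrderMap
from retrophylo.marker_validation import (
    ElementAnnotation,
    LocusAlignment,
    ValidationConfig,
    call_state,
    check_tsd_orthology,
    detect_tsd,
    validate_marker,
)

FLANK = 60  # short flanks keep the constructed fixtures readable
TSD = "ACGTACGT"  # 8 nt
ELEM = "GGGGCCCCGGGGCCCCGGGGCCCC"  # 24 nt element


def build_locus(
    present,
    absent=(),
    unknown=(),
    family="LINE1",
    orientation="+",
    tsd_shift=None,
    truncate_3prime=0,
    scramble_flanks=(),
):
    """A locus with deterministic flanks: present species carry
    left+TSD+element+TSD+right, absent species a clean empty site."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    left = "".join(rng.choice(bases, FLANK))
    right = "".join(rng.choice(bases, FLANK))
    elem_cols = len(ELEM) + len(TSD)
    seqs = {}
    for sp in present:
        elem = ELEM
        if truncate_3prime:
            elem = ELEM[:-truncate_3prime] + "-" * truncate_3prime
        if tsd_shift and sp in tsd_shift:
            # move the insertion point left by k columns for this species
            k = tsd_shift[sp]
            seqs[sp] = left[:-k] + TSD + elem + TSD + left[-k:] + right
            continue
        seqs[sp] = left + TSD + elem + TSD + right
    for sp in absent:
        seqs[sp] = left + TSD + "-" * elem_cols + right
    for sp in scramble_flanks:
        shuffled = "".join(rng.permutation(list(left)))
        seqs[sp] = shuffled + TSD[::-1] + ELEM + "TTTTAAAA" + right
    span = (FLANK + len(TSD), FLANK + len(TSD) + len(ELEM))
    return LocusAlignment(
        "L1", seqs, ElementAnnotation(family, span, orientation)
    )


@pytest.fixture
def omap():
    assignments = {f"{o}_sp1": o for o in ORDERS}
    assignments[f"{OUTGROUP}_sp1"] = OUTGROUP
    return OrderMap(assignments)


SP = {o: f"{o}_sp1" for o in ORDERS}
OG = f"{OUTGROUP}_sp1"


class TestDetectTsd:
    def test_exact_flanking_repeat_found(self):
        locus = build_locus([SP["Cetartiodactyla"], SP["Ferae"]], [OG])
        exact = ValidationConfig(tsd_max_mismatches=0)
        pair = detect_tsd(locus, SP["Cetartiodactyla"], exact)
        assert pair is not None
        assert pair.length >= len(TSD)
        assert pair.mismatches == 0
        # copies sit at the element boundaries
        assert pair.left_span[1] == FLANK + len(TSD)
        assert pair.right_span[0] == FLANK + len(TSD) + len(ELEM)

    def test_scrambled_flanks_yield_none(self):
        locus = build_locus(
            [SP["Cetartiodactyla"]], [OG], scramble_flanks=[SP["Ferae"]]
        )
        assert detect_tsd(locus, SP["Ferae"]) is None

    def test_repeat_below_minimum_length_rejected(self):
        locus = build_locus([SP["Cetartiodactyla"]], [OG])
        config = ValidationConfig(min_tsd_len_nt=4)
        strict = ValidationConfig(
            min_tsd_len_nt=len(TSD) + 1,
            max_tsd_len_nt=len(TSD) + 1,
            tsd_max_mismatches=0,
        )
        assert detect_tsd(locus, SP["Cetartiodactyla"], config) is not None
        assert detect_tsd(locus, SP["Cetartiodactyla"], strict) is None

    def test_absent_species_raises(self):
        locus = build_locus([SP["Cetartiodactyla"]], [OG])
        with pytest.raises(ValueError):
            detect_tsd(locus, OG)


class TestTsdOrthology:
    def test_small_offsets_pass(self):
        shifts = {SP["Ferae"]: 2}
        locus = build_locus(
            [SP["Cetartiodactyla"], SP["Ferae"]], [OG], tsd_shift=shifts
        )
        tsds = {
            sp: detect_tsd(locus, sp)
            for sp in (SP["Cetartiodactyla"], SP["Ferae"])
        }
        assert all(t is not None for t in tsds.values())
        ok, reason = check_tsd_orthology(locus, tsds)
        assert ok and reason is None

    def test_offset_three_fails(self):
        shifts = {SP["Ferae"]: 3}
        locus = build_locus(
            [SP["Cetartiodactyla"], SP["Ferae"]], [OG], tsd_shift=shifts
        )
        tsds = {
            sp: detect_tsd(locus, sp)
            for sp in (SP["Cetartiodactyla"], SP["Ferae"])
        }
        ok, reason = check_tsd_orthology(locus, tsds)
        assert not ok and reason == "tsd_not_orthologous"

    def test_single_species_uncorroborated(self):
        locus = build_locus([SP["Cetartiodactyla"]], [OG])
        tsds = {SP["Cetartiodactyla"]: detect_tsd(locus, SP["Cetartiodactyla"])}
        ok, reason = check_tsd_orthology(locus, tsds)
        assert not ok


class TestCallState:
    def test_full_element_present(self):
        locus = build_locus([SP["Cetartiodactyla"]], [OG])
        assert call_state(locus, SP["Cetartiodactyla"]) == PRESENT

    def test_clean_empty_site_absent(self):
        locus = build_locus([SP["Cetartiodactyla"]], [OG])
        assert call_state(locus, OG) == ABSENT

    def test_half_gapped_span_ambiguous(self):
        locus = build_locus([SP["Cetartiodactyla"]], [OG])
        seq = locus.sequences[SP["Cetartiodactyla"]]
        s, e = locus.element.span
        half = (e - s) // 2
        locus.sequences["weird"] = seq[: s + half] + "-" * (e - s - half) + seq[e:]
        assert call_state(locus, "weird") == UNKNOWN


class TestValidateMarker:
    def test_clean_fixture_accepted(self, omap):
        locus = build_locus(
            [SP["Cetartiodactyla"], SP["Ferae"]],
            [SP["Perissodactyla"], SP["Chiroptera"], SP["Eulipotyphla"], OG],
        )
        report = validate_marker(locus, omap)
        assert report.accept, report.reasons
        assert report.states[SP["Cetartiodactyla"]] == PRESENT
        assert report.states[OG] == ABSENT

    def test_line1_excess_3prime_truncation_rejected(self, omap):
        # element long enough that a 60-nt truncation still leaves >= 80%
        # of the span aligned (the species remains present-state)
        long_elem = "GC" * 200
        left = "A" * FLANK
        right = "T" * FLANK
        trunc = 60
        seqs = {
            SP["Cetartiodactyla"]: left + TSD + long_elem + TSD + right,
            SP["Ferae"]: left + TSD + long_elem[:-trunc] + "-" * trunc + TSD + right,
            OG: left + TSD + "-" * (len(long_elem) + len(TSD)) + right,
        }
        span = (FLANK + len(TSD), FLANK + len(TSD) + len(long_elem))
        locus = LocusAlignment("L2", seqs, ElementAnnotation("LINE1", span))
        report = validate_marker(locus, omap)
        assert not report.accept
        assert "truncation" in report.reasons

    def test_line1_truncation_under_limit_tolerated(self, omap):
        long_elem = "GC" * 200
        left = "A" * FLANK
        right = "T" * FLANK
        trunc = 40  # < 50 nt limit
        seqs = {
            SP["Cetartiodactyla"]: left + TSD + long_elem + TSD + right,
            SP["Ferae"]: left + TSD + long_elem[:-trunc] + "-" * trunc + TSD + right,
            OG: left + TSD + "-" * (len(long_elem) + len(TSD)) + right,
        }
        span = (FLANK + len(TSD), FLANK + len(TSD) + len(long_elem))
        locus = LocusAlignment("L3", seqs, ElementAnnotation("LINE1", span))
        report = validate_marker(locus, omap)
        assert "truncation" not in report.reasons

    def test_outgroup_presence_rejected(self, omap):
        locus = build_locus(
            [SP["Cetartiodactyla"], SP["Ferae"], OG],
            [SP["Perissodactyla"], SP["Chiroptera"], SP["Eulipotyphla"]],
        )
        report = validate_marker(locus, omap)
        assert not report.accept
        assert "outgroup_presence" in report.reasons

    def test_orientation_mismatch_rejected(self, omap):
        locus = build_locus(
            [SP["Cetartiodactyla"], SP["Ferae"]],
            [SP["Perissodactyla"], OG],
        )
        locus.species_element[SP["Ferae"]] = ("LINE1", "-")
        report = validate_marker(locus, omap)
        assert "orientation_mismatch" in report.reasons

    def test_species_listing_order_irrelevant(self, omap):
        locus = build_locus(
            [SP["Cetartiodactyla"], SP["Ferae"]],
            [SP["Perissodactyla"], SP["Chiroptera"], SP["Eulipotyphla"], OG],
        )
        r1 = validate_marker(locus, omap)
        reversed_seqs = dict(reversed(list(locus.sequences.items())))
        locus2 = LocusAlignment("L1", reversed_seqs, locus.element)
        r2 = validate_marker(locus2, omap)
        assert r1.states == r2.states
        assert r1.reasons == r2.reasons

    def test_every_rejection_carries_reasons(self, omap):
        loci = [
            build_locus([SP["Cetartiodactyla"], SP["Ferae"], OG],
                        [SP["Perissodactyla"]]),
            build_locus([SP["Cetartiodactyla"]], [OG]),
            build_locus([SP["Cetartiodactyla"], SP["Ferae"]],
                        [SP["Perissodactyla"], OG]),
        ]
        for locus in loci:
            report = validate_marker(locus, omap)
            assert report.accept == (not report.reasons)
            if not report.accept:
                assert len(report.reasons) >= 1
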