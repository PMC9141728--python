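"""Validation of candidate insertion loci into presence/absence markers.

A candidate locus is a multi-species alignment of a retrotransposon with its
flanking sequence (nominally 500 nt each side).  A locus is accepted as a
phylogenetically informative marker only when it shows the hallmarks of a
single, orthologous insertion event:

* the element is flanked by a target site duplication (TSD) in every
  present-state species;
* the TSDs sit at the same alignment position across species (start offsets
  strictly below 3 nt), i.e. the insertions are positionally orthologous;
* all present species carry the same element family in the same orientation;
* truncation stays within family-specific limits — LINE1 3' truncation
  strictly below 50 nt (5' truncation is unconstrained, as expected for the
  target-primed reverse transcription mechanism), LTR truncation at most
  20 nt at either end;
* the outgroup shows a clear absence state;
* at least two orders have a definite (non-ambiguous) state, so the marker
  can corroborate an interordinal affiliation.

Rejected loci carry machine-readable failure reasons so that screening
statistics can be reported per rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .marker_matrix import ABSENT, PRESENT, UNKNOWN, OrderMap

__all__ = [
    "GAP",
    "ValidationError",
    "ElementAnnotation",
    "LocusAlignment",
    "ValidationConfig",
    "TSDPair",
    "ValidationReport",
    "detect_tsd",
    "check_tsd_orthology",
    "call_state",
    "validate_marker",
    "reports_to_matrix_rows",
]

GAP = "-"

#: Enumerated failure-reason identifiers attached to rejected loci.
REASONS = (
    "no_present_species",
    "family_mismatch",
    "orientation_mismatch",
    "truncation",
    "tsd_missing",
    "tsd_not_orthologous",
    "outgroup_presence",
    "outgroup_unclear",
    "insufficient_orders",
)


class ValidationError(ValueError):
    """Raised for structurally invalid loci or queries."""


@dataclass
class ElementAnnotation:
    """Annotation of the inserted element within a locus alignment.

    ``span`` is 0-based half-open in alignment columns; ``family`` is
    ``"LINE1"`` or ``"LTR"``; ``orientation`` is ``"+"`` or ``"-"``.
    """

    family: str
    span: tuple[int, int]
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.family not in ("LINE1", "LTR"):
            raise ValidationError(f"unknown element family {self.family!r}")
        if self.orientation not in ("+", "-"):
            raise ValidationError(f"unknown orientation {self.orientation!r}")
        if self.span[0] < 0 or self.span[1] <= self.span[0]:
            raise ValidationError(f"invalid element span {self.span}")


@dataclass
class LocusAlignment:
    """One candidate locus: aligned sequences (element plus flanks) for two
    or more species, with the element annotation.

    ``species_element`` optionally overrides family/orientation for single
    species (e.g. an independent insertion of a different family at a nearby
    position); species not listed inherit the locus-level annotation.
    """

    locus_id: str
    sequences: dict[str, str]
    element: ElementAnnotation
    species_element: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValidationError(f"{self.locus_id}: need >= 2 species")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValidationError(f"{self.locus_id}: unequal alignment lengths")
        (self.n_columns,) = lengths
        if self.element.span[1] > self.n_columns:
            raise ValidationError(
                f"{self.locus_id}: element span exceeds alignment bounds"
            )

    def ungapped(self, species: str) -> str:
        return self._seq(species).replace(GAP, "")

    def _seq(self, species: str) -> str:
        try:
            return self.sequences[species]
        except KeyError:
            raise ValidationError(
                f"{self.locus_id}: species {species!r} not in alignment"
            ) from None

    def column_to_position(self, species: str, column: int) -> int:
        """Ungapped sequence position of alignment ``column`` for ``species``
        (number of residues strictly before the column)."""
        seq = self._seq(species)
        return sum(1 for c in seq[:column] if c != GAP)

    def position_to_column(self, species: str, position: int) -> int:
        """Alignment column of ungapped ``position`` for ``species``."""
        seq = self._seq(species)
        count = 0
        for col, c in enumerate(seq):
            if c != GAP:
                if count == position:
                    return col
                count += 1
        if count == position:
            return len(seq)
        raise ValidationError(
            f"{self.locus_id}: position {position} beyond sequence of {species!r}"
        )

    def family_of(self, species: str) -> str:
        return self.species_element.get(species, (self.element.family, None))[0]

    def orientation_of(self, species: str) -> str:
        ov = self.species_element.get(species)
        return ov[1] if ov is not None else self.element.orientation


@dataclass
class ValidationConfig:
    """Thresholds for marker acceptance.

    ``max_tsd_shift_nt`` is an exclusive bound (offsets must be strictly
    smaller); ``line1_max_3prime_truncation_nt`` is exclusive (< 50 nt
    accepted); ``ltr_max_truncation_nt`` is inclusive (<= 20 nt accepted at
    each end).  TSD detection parameters (minimum length 4, at most one
    mismatch, 5-nt boundary window) are operational choices; the underlying
    screen relies on manual curation for them.
    """

    max_tsd_shift_nt: int = 3
    flank_len_nt: int = 500
    line1_max_3prime_truncation_nt: int = 50
    ltr_max_truncation_nt: int = 20
    min_tsd_len_nt: int = 4
    tsd_max_mismatches: int = 1
    tsd_boundary_window_nt: int = 5
    max_tsd_len_nt: int = 30
    presence_nongap_fraction: float = 0.8
    flank_window_nt: int = 25

    def __post_init__(self) -> None:
        for name in (
            "max_tsd_shift_nt",
            "flank_len_nt",
            "line1_max_3prime_truncation_nt",
            "ltr_max_truncation_nt",
            "min_tsd_len_nt",
            "tsd_max_mismatches",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class TSDPair:
    """A detected target site duplication for one species: the left and
    right copy spans in the species' ungapped coordinates (0-based
    half-open), the repeat length, and the number of mismatches."""

    species: str
    left_span: tuple[int, int]
    right_span: tuple[int, int]
    length: int
    mismatches: int


@dataclass
class ValidationReport:
    """Outcome of validating one locus: per-species state calls, the accept
    flag, and enumerated failure reasons (empty iff accepted)."""

    locus_id: str
    states: dict[str, int]
    accept: bool
    reasons: list[str]
    tsds: dict[str, TSDPair] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.accept != (len(self.reasons) == 0):
            raise ValidationError("accept flag inconsistent with reasons")


# ---------------------------------------------------------------------------
# TSD detection
# ---------------------------------------------------------------------------

def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == GAP)


def detect_tsd(
    locus: LocusAlignment, species: str, config: ValidationConfig | None = None
) -> TSDPair | None:
    """Find the best direct repeat flanking the element for ``species``.

    Searches, in the species' ungapped sequence, for the longest repeat with
    at most ``tsd_max_mismatches`` whose left copy ends and right copy starts
    within ``tsd_boundary_window_nt`` of the element boundaries.  Returns
    ``None`` when no repeat of at least ``min_tsd_len_nt`` exists.
    """
    config = config or ValidationConfig()
    seq = locus.ungapped(species)
    start = locus.column_to_position(species, locus.element.span[0])
    end = locus.column_to_position(species, locus.element.span[1])
    if end <= start:
        raise ValidationError(
            f"{locus.locus_id}: {species!r} has no element sequence "
            "(species is not in a present state)"
        )
    best: TSDPair | None = None
    w = config.tsd_boundary_window_nt
    # boundaries are searched within +/- w of the annotated element ends:
    # cross-species alignment jitter can shift the copies either way
    for length in range(config.max_tsd_len_nt, config.min_tsd_len_nt - 1, -1):
        for dl in range(-w, w + 1):
            l_end = start - dl
            l_start = l_end - length
            if l_start < 0 or l_end > len(seq):
                continue
            for dr in range(-w, w + 1):
                r_start = end + dr
                r_end = r_start + length
                if r_end > len(seq) or r_start < 0:
                    continue
                mm = _mismatches(seq[l_start:l_end], seq[r_start:r_end])
                if mm <= config.tsd_max_mismatches:
                    cand = TSDPair(
                        species, (l_start, l_end), (r_start, r_end), length, mm
                    )
                    if best is None or (cand.length, -cand.mismatches) > (
                        best.length,
                        -best.mismatches,
                    ):
                        best = cand
        if best is not None:
            break  # longest-first search: first hit is maximal
    return best


def check_tsd_orthology(
    locus: LocusAlignment,
    tsds: dict[str, TSDPair],
    config: ValidationConfig | None = None,
) -> tuple[bool, str | None]:
    """Check that TSD positions agree across present-state species.

    Pass iff at least two species carry a TSD and every pairwise difference
    of TSD start positions, measured in alignment columns, is strictly below
    ``max_tsd_shift_nt``.  Returns ``(ok, reason)``.
    """
    config = config or ValidationConfig()
    if len(tsds) < 2:
        return False, "tsd_missing" if not tsds else "tsd_not_orthologous"
    cols = [
        locus.position_to_column(sp, pair.left_span[0])
        for sp, pair in tsds.items()
    ]
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(cols[i] - cols[j]) >= config.max_tsd_shift_nt:
                return False, "tsd_not_orthologous"
    return True, None


# ---------------------------------------------------------------------------
# State calling
# ---------------------------------------------------------------------------

def call_state(
    locus: LocusAlignment, species: str, config: ValidationConfig | None = None
) -> int:
    """Call present / absent / ambiguous for one species.

    Present: at least ``presence_nongap_fraction`` (default 80%) of the
    element-span columns are non-gap.  Absent: the element span is fully
    gapped while both flanks align contiguously (non-gap fraction >= 80%
    within ``flank_window_nt`` columns on each side).  Anything else is
    ambiguous (returned as the UNKNOWN state code).
    """
    config = config or ValidationConfig()
    seq = locus._seq(species)
    s, e = locus.element.span
    span = seq[s:e]
    nongap = sum(1 for c in span if c != GAP)
    if nongap / len(span) >= config.presence_nongap_fraction:
        return PRESENT
    if nongap == 0:
        # an empty site may gap out one TSD copy next to the element span;
        # skip a short adjacent gap run (at most one TSD length) on each
        # side before judging flank contiguity
        slack = config.max_tsd_len_nt
        right_start = e
        while right_start < len(seq) and seq[right_start] == GAP:
            right_start += 1
            if right_start - e > slack:
                return UNKNOWN
        left_end = s
        while left_end > 0 and seq[left_end - 1] == GAP:
            left_end -= 1
            if s - left_end > slack:
                return UNKNOWN
        w = config.flank_window_nt
        left = seq[max(0, left_end - w): left_end]
        right = seq[right_start: right_start + w]
        if left and right:
            lf = sum(1 for c in left if c != GAP) / len(left)
            rf = sum(1 for c in right if c != GAP) / len(right)
            if lf >= 0.8 and rf >= 0.8:
                return ABSENT
    return UNKNOWN


# ---------------------------------------------------------------------------
# Full marker validation
# ---------------------------------------------------------------------------

def validate_marker(
    locus: LocusAlignment,
    order_map: OrderMap,
    config: ValidationConfig | None = None,
) -> ValidationReport:
    """Apply the full acceptance rule set to one locus.

    Species listed in the order map but missing from the alignment are
    recorded as unknown.  Validation is deterministic and does not depend on
    the listing order of species.
    """
    from .marker_matrix import OUTGROUP

    config = config or ValidationConfig()
    species = sorted(order_map.assignments)
    states = {
        sp: (call_state(locus, sp, config) if sp in locus.sequences else UNKNOWN)
        for sp in species
    }
    reasons: list[str] = []
    present = [sp for sp in species if states[sp] == PRESENT]
    if not present:
        reasons.append("no_present_species")

    # same family, same orientation across present species
    if present:
        if len({locus.family_of(sp) for sp in present}) > 1:
            reasons.append("family_mismatch")
        if len({locus.orientation_of(sp) for sp in present}) > 1:
            reasons.append("orientation_mismatch")

    # family-specific truncation limits, measured as terminal gap runs within
    # the element span (orientation-aware: for '-' elements the alignment
    # left end is the element 3' end)
    family = locus.element.family
    for sp in present:
        lead, trail = _terminal_gap_runs(locus, sp)
        if locus.orientation_of(sp) == "-":
            lead, trail = trail, lead
        # lead = 5' truncation, trail = 3' truncation
        if family == "LINE1":
            if trail >= config.line1_max_3prime_truncation_nt:
                reasons.append("truncation")
                break
        else:  # LTR
            if (
                lead > config.ltr_max_truncation_nt
                or trail > config.ltr_max_truncation_nt
            ):
                reasons.append("truncation")
                break

    # TSDs present and orthologous
    tsds: dict[str, TSDPair] = {}
    for sp in present:
        pair = detect_tsd(locus, sp, config)
        if pair is None:
            if "tsd_missing" not in reasons:
                reasons.append("tsd_missing")
        else:
            tsds[sp] = pair
    if present and "tsd_missing" not in reasons:
        ok, why = check_tsd_orthology(locus, tsds, config)
        if not ok:
            reasons.append(why)

    # clear absence in the outgroup: presence disqualifies outright, and an
    # outgroup with no definite absent member gives no clear absence state
    og_members = order_map.members(OUTGROUP)
    if og_members:
        if any(states[sp] == PRESENT for sp in og_members):
            reasons.append("outgroup_presence")
        elif not any(states[sp] == ABSENT for sp in og_members):
            reasons.append("outgroup_unclear")

    # at least two orders with a definite state
    definite_orders = {
        order_map.assignments[sp]
        for sp in species
        if states[sp] != UNKNOWN and order_map.assignments[sp] != OUTGROUP
    }
    if len(definite_orders) < 2:
        reasons.append("insufficient_orders")

    return ValidationReport(
        locus.locus_id, states, accept=not reasons, reasons=reasons, tsds=tsds
    )


def _terminal_gap_runs(locus: LocusAlignment, species: str) -> tuple[int, int]:
    """Leading and trailing gap-run lengths within the element span,
    i.e. the apparent truncation at each element end."""
    s, e = locus.element.span
    span = locus._seq(species)[s:e]
    lead = len(span) - len(span.lstrip(GAP))
    trail = len(span) - len(span.rstrip(GAP))
    if lead + trail >= len(span):
        return len(span), len(span)
    return lead, trail


def reports_to_matrix_rows(
    reports: list[ValidationReport],
) -> tuple[list[str], list[str], np.ndarray]:
    """Assemble accepted reports into matrix components
    ``(marker_ids, taxa, states)`` suitable for PresenceAbsenceMatrix."""
    accepted = [r for r in reports if r.accept]
    if not accepted:
        return [], [], np.zeros((0, 0), dtype=np.int8)
    taxa = sorted(accepted[0].states)
    states = np.array(
        [[r.states[t] for t in taxa] for r in accepted], dtype=np.int8
    )
    return [r.locus_id for r in accepted], taxa, states
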