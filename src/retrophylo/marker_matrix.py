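"""Presence/absence marker matrices: data model, I/O, merging, and the
interordinal affiliation census.

A retrotransposon presence/absence matrix records, for every validated
insertion locus (row) and every sampled taxon (column), whether the element
is present (``1``), absent (``0``), or unresolvable from the assembly
(``?``).  Because a retrotransposon inserts once and is essentially never
excised precisely, shared presence is near-homoplasy-free evidence of common
ancestry; conflicting presence patterns between lineages are the signature
of incomplete lineage sorting across a rapid radiation.

The census groups order-collapsed markers into *affiliation classes*: the
subsets of the five laurasiatherian orders of size 2, 3, or 4 — exactly
C(5,2) + C(5,3) + C(5,4) = 25 classes.  Markers present in 0, 1, or all 5
orders carry no interordinal signal and are tallied as uninformative;
markers whose class cannot be determined unambiguously (a ``?`` order, or a
non-absent outgroup) are tallied as conflicted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PRESENT",
    "ABSENT",
    "UNKNOWN",
    "ORDERS",
    "OUTGROUP",
    "MatrixFormatError",
    "PresenceAbsenceMatrix",
    "OrderMap",
    "PatternCensus",
    "read_matrix",
    "write_matrix",
    "collapse_to_orders",
    "census_patterns",
    "merge_matrices",
    "export_splits_nexus",
]

# Integer state codes used throughout the package.
PRESENT: int = 1
ABSENT: int = 0
UNKNOWN: int = -1

_SYMBOL_TO_STATE = {"1": PRESENT, "0": ABSENT, "?": UNKNOWN}
_STATE_TO_SYMBOL = {PRESENT: "1", ABSENT: "0", UNKNOWN: "?"}

#: The five laurasiatherian orders, in the fixed reference order used for
#: order-collapsed matrices and affiliation classes.
ORDERS: tuple[str, ...] = (
    "Eulipotyphla",
    "Chiroptera",
    "Perissodactyla",
    "Cetartiodactyla",
    "Ferae",
)

#: Group label used for the outgroup column of order-collapsed matrices.
OUTGROUP: str = "Outgroup"


class MatrixFormatError(ValueError):
    """Raised for malformed matrix files or inconsistent matrix operations."""


@dataclass
class PresenceAbsenceMatrix:
    """A markers x taxa matrix of insertion states.

    Parameters
    ----------
    marker_ids
        Locus identifiers, one per row; unique.
    taxa
        Taxon (or order) labels, one per column; unique.
    states
        ``(n_markers, n_taxa)`` int8 array over {PRESENT, ABSENT, UNKNOWN}.
    provenance
        Per-marker source tag, e.g. ``"new_screen"`` or ``"prior_study"``.
    """

    marker_ids: list[str]
    taxa: list[str]
    states: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.marker_ids), len(self.taxa)):
            raise MatrixFormatError(
                f"state array shape {self.states.shape} does not match "
                f"{len(self.marker_ids)} markers x {len(self.taxa)} taxa"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise MatrixFormatError("duplicated marker id(s) in matrix")
        if len(set(self.taxa)) != len(self.taxa):
            raise MatrixFormatError("duplicated taxon label(s) in matrix")
        if not self.provenance:
            self.provenance = ["new_screen"] * len(self.marker_ids)
        bad = ~np.isin(self.states, (PRESENT, ABSENT, UNKNOWN))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise MatrixFormatError(
                f"invalid state at marker {self.marker_ids[i]!r}, "
                f"taxon {self.taxa[j]!r}"
            )

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def column(self, taxon: str) -> np.ndarray:
        return self.states[:, self.taxa.index(taxon)]

    def row(self, marker_id: str) -> dict[str, int]:
        r = self.states[self.marker_ids.index(marker_id)]
        return dict(zip(self.taxa, (int(v) for v in r)))

    def presence_set(self, i: int) -> frozenset[str]:
        """Taxa with a definite present state for marker row ``i``."""
        return frozenset(
            t for t, s in zip(self.taxa, self.states[i]) if s == PRESENT
        )

    def reorder_taxa(self, taxa: list[str]) -> "PresenceAbsenceMatrix":
        if set(taxa) != set(self.taxa):
            raise MatrixFormatError("reorder_taxa requires the same taxon set")
        idx = [self.taxa.index(t) for t in taxa]
        return PresenceAbsenceMatrix(
            list(self.marker_ids), list(taxa), self.states[:, idx],
            list(self.provenance),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceAbsenceMatrix):
            return NotImplemented
        return (
            self.marker_ids == other.marker_ids
            and self.taxa == other.taxa
            and np.array_equal(self.states, other.states)
        )


@dataclass
class OrderMap:
    """Assignment of every matrix taxon to a laurasiatherian order or the
    outgroup.

    ``assignments`` maps taxon label -> group label, where group labels are
    drawn from :data:`ORDERS` plus :data:`OUTGROUP`.
    """

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for t, g in self.assignments.items():
            counts[g] = counts.get(g, 0) + 1
        for g in counts:
            if g not in ORDERS and g != OUTGROUP:
                raise MatrixFormatError(f"unknown group label {g!r}")

    def group_of(self, taxon: str) -> str:
        try:
            return self.assignments[taxon]
        except KeyError:
            raise MatrixFormatError(f"taxon {taxon!r} is not mapped") from None

    def members(self, group: str) -> list[str]:
        return [t for t, g in self.assignments.items() if g == group]

    @property
    def groups(self) -> list[str]:
        """Groups in canonical order: the five orders, then the outgroup."""
        present = set(self.assignments.values())
        out = [g for g in ORDERS if g in present]
        if OUTGROUP in present:
            out.append(OUTGROUP)
        return out


def affiliation_classes() -> list[frozenset[str]]:
    """The 25 interordinal affiliation classes: subsets of the five orders
    of size 2, 3, or 4, in deterministic order."""
    classes: list[frozenset[str]] = []
    for k in (2, 3, 4):
        for combo in itertools.combinations(ORDERS, k):
            classes.append(frozenset(combo))
    return classes


@dataclass
class PatternCensus:
    """Counts of markers per affiliation class plus the uninformative and
    conflicted tallies.  ``counts`` always contains all 25 classes."""

    counts: dict[frozenset[str], int]
    uninformative: int
    conflicted: int
    total: int

    def __post_init__(self) -> None:
        if len(self.counts) != 25:
            raise MatrixFormatError("census must contain exactly 25 classes")
        if sum(self.counts.values()) + self.uninformative + self.conflicted != self.total:
            raise MatrixFormatError("census counts do not sum to the total")

    @property
    def informative(self) -> int:
        return sum(self.counts.values())

    def count(self, *orders: str) -> int:
        return self.counts[frozenset(orders)]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_symbol(sym: str, marker: str, taxon: str) -> int:
    try:
        return _SYMBOL_TO_STATE[sym]
    except KeyError:
        raise MatrixFormatError(
            f"unknown state symbol {sym!r} at marker {marker!r}, taxon {taxon!r}"
        ) from None


def _read_tsv(path: str) -> PresenceAbsenceMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise MatrixFormatError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    if header[0] not in ("marker_id", "id", "locus"):
        raise MatrixFormatError(
            f"{path}: first header field must name the marker-id column"
        )
    taxa = header[1:]
    marker_ids: list[str] = []
    rows: list[list[int]] = []
    seen: set[str] = set()
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise MatrixFormatError(
                f"{path}: row {fields[0]!r} has {len(fields) - 1} states, "
                f"expected {len(taxa)}"
            )
        mid = fields[0]
        if mid in seen:
            raise MatrixFormatError(f"{path}: duplicated marker id {mid!r}")
        seen.add(mid)
        marker_ids.append(mid)
        rows.append([_parse_symbol(s, mid, t) for s, t in zip(fields[1:], taxa)])
    return PresenceAbsenceMatrix(
        marker_ids, taxa, np.array(rows, dtype=np.int8).reshape(len(rows), len(taxa))
    )


def _read_nexus(path: str) -> PresenceAbsenceMatrix:
    # dendropy owns the NEXUS grammar; we only map its standard-data matrix
    # onto our integer codes.
    import dendropy

    try:
        ds = dendropy.DataSet.get(path=path, schema="nexus")
    except Exception as exc:  # dendropy raises assorted parse errors
        raise MatrixFormatError(f"{path}: NEXUS parse failure: {exc}") from exc
    if not ds.char_matrices:
        raise MatrixFormatError(f"{path}: no character matrix in NEXUS file")
    cm = ds.char_matrices[0]
    taxa = [t.label for t in cm.taxon_namespace]
    n_char = max(len(cm[t]) for t in cm.taxon_namespace)
    states = np.full((n_char, len(taxa)), UNKNOWN, dtype=np.int8)
    for j, taxon in enumerate(cm.taxon_namespace):
        for i, cell in enumerate(cm[taxon]):
            sym = str(cell.symbol)
            states[i, j] = _parse_symbol(sym, f"char{i + 1}", taxon.label)
    marker_ids = [f"char{i + 1}" for i in range(n_char)]
    return PresenceAbsenceMatrix(marker_ids, taxa, states)


def read_matrix(path: str, format: str = "tsv") -> PresenceAbsenceMatrix:
    """Read a presence/absence matrix from ``path``.

    TSV layout: a header row ``marker_id<TAB>taxon1<TAB>...`` followed by one
    row per marker with states in {1,0,?}.  NEXUS: a ``data`` block with
    ``datatype=standard``, ``symbols="01"``, ``missing=?``.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "nexus":
        return _read_nexus(path)
    raise MatrixFormatError(f"unknown matrix format {format!r}")


def write_matrix(matrix: PresenceAbsenceMatrix, path: str, format: str = "tsv") -> None:
    """Write ``matrix`` to ``path``; inverse of :func:`read_matrix` (reading
    the written file reproduces the matrix, and re-writing that matrix
    reproduces the file byte for byte)."""
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("marker_id\t" + "\t".join(matrix.taxa) + "\n")
            for mid, row in zip(matrix.marker_ids, matrix.states):
                fh.write(
                    mid + "\t" + "\t".join(_STATE_TO_SYMBOL[int(s)] for s in row) + "\n"
                )
    elif format == "nexus":
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(
                f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_markers};\n"
            )
            fh.write(
                '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\n'
            )
            fh.write("    MATRIX\n")
            width = max(len(t) for t in matrix.taxa) + 2
            for j, taxon in enumerate(matrix.taxa):
                seq = "".join(
                    _STATE_TO_SYMBOL[int(s)] for s in matrix.states[:, j]
                )
                fh.write(f"    {taxon.replace(' ', '_'):<{width}}{seq}\n")
            fh.write("    ;\nEND;\n")
    else:
        raise MatrixFormatError(f"unknown matrix format {format!r}")


# ---------------------------------------------------------------------------
# Order collapse and census
# ---------------------------------------------------------------------------

def collapse_to_orders(
    matrix: PresenceAbsenceMatrix,
    order_map: OrderMap,
    policy: str = "strict",
) -> PresenceAbsenceMatrix:
    """Collapse species columns to one column per order (plus outgroup).

    ``strict`` (default): an order is present only if every member with a
    definite state is present, absent only if every such member is absent,
    and unknown otherwise (members with ``?`` do not vote; an intra-order
    conflict yields ``?``).  ``any``: present if at least one member is
    present, absent if no member is present and at least one is definitely
    absent.
    """
    if policy not in ("strict", "any"):
        raise MatrixFormatError(f"unknown collapse policy {policy!r}")
    for t in matrix.taxa:
        order_map.group_of(t)  # raises for unmapped taxa
    groups = order_map.groups
    out = np.full((matrix.n_markers, len(groups)), UNKNOWN, dtype=np.int8)
    for j, g in enumerate(groups):
        members = [t for t in matrix.taxa if order_map.assignments[t] == g]
        sub = matrix.states[:, [matrix.taxa.index(t) for t in members]]
        any_present = (sub == PRESENT).any(axis=1)
        any_absent = (sub == ABSENT).any(axis=1)
        if policy == "strict":
            out[:, j] = np.where(
                any_present & ~any_absent,
                PRESENT,
                np.where(any_absent & ~any_present, ABSENT, UNKNOWN),
            )
        else:
            out[:, j] = np.where(
                any_present, PRESENT, np.where(any_absent, ABSENT, UNKNOWN)
            )
    return PresenceAbsenceMatrix(
        list(matrix.marker_ids), list(groups), out, list(matrix.provenance)
    )


def census_patterns(matrix: PresenceAbsenceMatrix) -> PatternCensus:
    """Tally an order-collapsed matrix into the 25 affiliation classes.

    A marker is assigned to a class only when all five orders have a definite
    state, presence spans 2–4 orders, and the outgroup column (if present in
    the matrix) is definitely absent.  Markers present in 0, 1 or 5 orders
    are uninformative; everything else (a ``?`` order, or outgroup presence /
    outgroup ``?``) is conflicted.
    """
    order_cols = [o for o in ORDERS if o in matrix.taxa]
    if len(order_cols) != 5:
        raise MatrixFormatError(
            "census requires a matrix collapsed to the five orders; "
            f"found columns {matrix.taxa}"
        )
    has_og = OUTGROUP in matrix.taxa
    counts = {c: 0 for c in affiliation_classes()}
    uninformative = conflicted = 0
    oidx = [matrix.taxa.index(o) for o in order_cols]
    og = matrix.taxa.index(OUTGROUP) if has_og else None
    for i in range(matrix.n_markers):
        row = matrix.states[i]
        if has_og and row[og] != ABSENT:
            conflicted += 1
            continue
        vals = row[oidx]
        if (vals == UNKNOWN).any():
            conflicted += 1
            continue
        present = frozenset(o for o, v in zip(order_cols, vals) if v == PRESENT)
        if len(present) in (0, 1, 5):
            uninformative += 1
        else:
            counts[present] += 1
    return PatternCensus(counts, uninformative, conflicted, matrix.n_markers)


def merge_matrices(
    a: PresenceAbsenceMatrix, b: PresenceAbsenceMatrix
) -> PresenceAbsenceMatrix:
    """Union of two matrices over a shared taxon namespace, keyed on locus id.

    For loci present in both, ``a``'s copy is kept; the merge fails if the two
    copies disagree in any state.  ``|result| = |a| + |b| - |overlap|``.
    """
    if set(a.taxa) != set(b.taxa):
        raise MatrixFormatError(
            "matrices must share a taxon namespace before merging"
        )
    b = b.reorder_taxa(list(a.taxa))
    a_index = {m: i for i, m in enumerate(a.marker_ids)}
    conflicts = [
        m
        for m, j in ((m, j) for j, m in enumerate(b.marker_ids) if m in a_index)
        if not np.array_equal(a.states[a_index[m]], b.states[j])
    ]
    if conflicts:
        raise MatrixFormatError(
            "conflicting states for shared loci: " + ", ".join(sorted(conflicts))
        )
    new_rows = [j for j, m in enumerate(b.marker_ids) if m not in a_index]
    marker_ids = list(a.marker_ids) + [b.marker_ids[j] for j in new_rows]
    states = np.vstack([a.states, b.states[new_rows]]) if new_rows else a.states.copy()
    provenance = list(a.provenance) + [b.provenance[j] for j in new_rows]
    return PresenceAbsenceMatrix(marker_ids, list(a.taxa), states, provenance)


# ---------------------------------------------------------------------------
# Splits export
# ---------------------------------------------------------------------------

def export_splits_nexus(
    census: PatternCensus, taxa: list[str], path: str
) -> None:
    """Write the census as a SplitsTree-compatible NEXUS splits block.

    Each nonzero affiliation class becomes one split (the class orders on one
    side) weighted by its marker count, so a splits-network viewer displays
    the conflicting interordinal signal directly.
    """
    nonzero = [(c, n) for c, n in census.counts.items() if n > 0]
    # deterministic order: by class size then lexicographic member list
    nonzero.sort(key=lambda cn: (len(cn[0]), sorted(cn[0])))
    index = {t: i + 1 for i, t in enumerate(taxa)}
    for c, _ in nonzero:
        missing = [o for o in c if o not in index]
        if missing:
            raise MatrixFormatError(
                f"census class references taxa absent from the taxa list: {missing}"
            )
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN Taxa;\n")
        fh.write(f"DIMENSIONS ntax={len(taxa)};\n")
        fh.write("TAXLABELS\n")
        for i, t in enumerate(taxa, 1):
            fh.write(f"[{i}] '{t}'\n")
        fh.write(";\nEND;\n\nBEGIN Splits;\n")
        fh.write(f"DIMENSIONS ntax={len(taxa)} nsplits={len(nonzero)};\n")
        fh.write(
            "FORMAT labels=no weights=yes confidences=no intervals=no;\n"
        )
        fh.write("MATRIX\n")
        for k, (c, n) in enumerate(nonzero, 1):
            side = " ".join(str(index[o]) for o in sorted(c, key=index.get))
            fh.write(f"[{k}, size={len(c)}]\t{float(n)}\t{side},\n")
        fh.write(";\nEND;\n")
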