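"""Dollo parsimony on presence/absence markers.

Under the Dollo model a character (an insertion) is gained exactly once and
can subsequently only be lost.  For a marker on a rooted tree the gain is
placed on the branch to the most recent common ancestor (MRCA) of all
definitely-present taxa, and the score is the minimum number of loss (1->0)
branches below that gain needed to explain every definitely-absent taxon;
unknown (``?``) taxa are assigned whichever state avoids a loss.  Summing
over markers gives the tree score; by default only the reversions are
counted (``losses_only``), which is the convention under which a fully
compatible matrix scores zero.

Trees here are rooted binary topologies represented as nested tuples of
leaf labels, with an optional outgroup attached at the root.  Exhaustive
search enumerates all rooted topologies, which is feasible for order-level
analyses (105 topologies for 5 ingroup taxa, 945 for 6).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .marker_matrix import ABSENT, PRESENT, UNKNOWN, PresenceAbsenceMatrix

__all__ = [
    "RootedTree",
    "DolloScore",
    "BootstrapConfig",
    "dollo_losses",
    "dollo_score",
    "search_best_tree",
    "bootstrap_support",
    "enumerate_rooted_topologies",
]

_INF = float("inf")


class DolloError(ValueError):
    pass


@dataclass(frozen=True)
class RootedTree:
    """A rooted binary topology over ingroup taxa, optionally with an
    outgroup joined at the root."""

    root: object  # nested tuples of leaf labels
    outgroup: str | None = None

    @property
    def full_root(self) -> object:
        """Root including the outgroup (attached as the root's sister)."""
        return (self.root, self.outgroup) if self.outgroup else self.root

    def leaves(self) -> list[str]:
        return _leaves(self.full_root)

    def clades(self, include_outgroup: bool = False) -> list[frozenset[str]]:
        """Nontrivial ingroup clades (size >= 2, below the ingroup root)."""
        out: list[frozenset[str]] = []
        top = self.full_root if include_outgroup else self.root
        for node in _internal_nodes(top):
            if node is not top:
                out.append(frozenset(_leaves(node)))
        return out

    def newick(self) -> str:
        return _newick(_canonical(self.full_root)) + ";"

    def canonical(self) -> "RootedTree":
        return RootedTree(_canonical(self.root), self.outgroup)


def _leaves(node) -> list[str]:
    if isinstance(node, str):
        return [node]
    return _leaves(node[0]) + _leaves(node[1])


def _internal_nodes(node):
    if isinstance(node, str):
        return
    yield node
    yield from _internal_nodes(node[0])
    yield from _internal_nodes(node[1])


def _canonical(node):
    if isinstance(node, str):
        return node
    a, b = _canonical(node[0]), _canonical(node[1])
    return (a, b) if _newick(a) <= _newick(b) else (b, a)


def _newick(node) -> str:
    if isinstance(node, str):
        return node
    return f"({_newick(node[0])},{_newick(node[1])})"


def enumerate_rooted_topologies(taxa: list[str]):
    """All rooted binary topologies on ``taxa`` by stepwise addition
    ((2n-3)!! trees); deterministic order."""
    taxa = list(taxa)
    if not taxa:
        raise DolloError("no taxa")
    if len(taxa) == 1:
        yield taxa[0]
        return
    for sub in enumerate_rooted_topologies(taxa[:-1]):
        new = taxa[-1]
        for attached in _attach_everywhere(sub, new):
            yield attached


def _attach_everywhere(node, leaf):
    # attach above the current node (new root joining node and leaf)
    yield (node, leaf)
    if not isinstance(node, str):
        for left in _attach_everywhere(node[0], leaf):
            yield (left, node[1])
        for right in _attach_everywhere(node[1], leaf):
            yield (node[0], right)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def dollo_losses(tree: RootedTree, states: dict[str, int]) -> int:
    """Minimum number of loss branches for one marker on ``tree``.

    ``states`` maps taxon -> {PRESENT, ABSENT, UNKNOWN}; tree leaves missing
    from ``states`` are treated as unknown.  Raises if no taxon is
    definitely present.
    """
    present = {t for t, s in states.items() if s == PRESENT}
    if not present:
        raise DolloError("marker has no definitely present taxon")
    mrca = _mrca(tree.full_root, present)
    if isinstance(mrca, str):
        return 0  # single present leaf: gain on its terminal branch
    total = 0
    for child in mrca:
        total += _min_losses(child, states)
    if total >= _INF:  # pragma: no cover - cannot happen: present leaves score 0
        raise DolloError("infeasible marker")
    return int(total)


def _mrca(node, present: set[str]):
    """Smallest subtree containing every definitely-present taxon."""
    while not isinstance(node, str):
        left = set(_leaves(node[0]))
        if present <= left:
            node = node[0]
            continue
        right = set(_leaves(node[1]))
        if present <= right:
            node = node[1]
            continue
        return node
    return node


def _min_losses(node, states: dict[str, int]) -> float:
    """Minimum losses in the subtree of ``node`` given the lineage entering
    ``node`` carries the element.  A loss may be placed on the branch above
    ``node`` only when no definitely-present leaf lies below it."""
    if isinstance(node, str):
        s = states.get(node, UNKNOWN)
        if s == ABSENT:
            return 1.0  # must lose on this terminal branch
        return 0.0
    leaves = _leaves(node)
    no_loss = _min_losses(node[0], states) + _min_losses(node[1], states)
    if all(states.get(t, UNKNOWN) != PRESENT for t in leaves):
        return min(1.0, no_loss)
    return no_loss


@dataclass
class DolloScore:
    """Tree score: total steps and the per-marker loss counts.

    ``convention`` is ``"losses_only"`` (steps = reversions; a compatible
    matrix scores 0) or ``"gains_plus_losses"`` (adds one gain per marker).
    """

    total_steps: int
    per_marker: dict[str, int]
    convention: str = "losses_only"

    def __post_init__(self) -> None:
        if self.convention not in ("losses_only", "gains_plus_losses"):
            raise DolloError(f"unknown convention {self.convention!r}")


def dollo_score(
    tree: RootedTree,
    matrix: PresenceAbsenceMatrix,
    convention: str = "losses_only",
) -> DolloScore:
    """Sum :func:`dollo_losses` over every marker of ``matrix``."""
    leaves = set(tree.leaves())
    missing = [t for t in matrix.taxa if t not in leaves]
    if missing:
        raise DolloError(f"matrix taxa not on tree: {missing}")
    per: dict[str, int] = {}
    for i, mid in enumerate(matrix.marker_ids):
        states = dict(zip(matrix.taxa, (int(v) for v in matrix.states[i])))
        per[mid] = dollo_losses(tree, states)
    extra = len(per) if convention == "gains_plus_losses" else 0
    return DolloScore(sum(per.values()) + extra, per, convention)


# ---------------------------------------------------------------------------
# Exhaustive search and bootstrap
# ---------------------------------------------------------------------------

def _pattern_table(
    matrix: PresenceAbsenceMatrix,
) -> tuple[list[tuple[int, ...]], np.ndarray]:
    """Unique marker patterns and the pattern index of every marker."""
    patterns: dict[tuple[int, ...], int] = {}
    index = np.empty(matrix.n_markers, dtype=np.intp)
    for i in range(matrix.n_markers):
        pat = tuple(int(v) for v in matrix.states[i])
        index[i] = patterns.setdefault(pat, len(patterns))
    return list(patterns), index


def _score_table(
    trees: list[RootedTree],
    patterns: list[tuple[int, ...]],
    taxa: list[str],
) -> np.ndarray:
    """Loss counts, shape (n_trees, n_patterns)."""
    table = np.zeros((len(trees), len(patterns)), dtype=np.int64)
    for j, pat in enumerate(patterns):
        states = dict(zip(taxa, pat))
        for i, tree in enumerate(trees):
            table[i, j] = dollo_losses(tree, states)
    return table


def _candidate_trees(
    taxa: list[str], outgroup: str | None
) -> list[RootedTree]:
    ingroup = [t for t in taxa if t != outgroup]
    if len(ingroup) > 10:
        raise DolloError(
            f"{len(ingroup)} ingroup taxa: exhaustive search is limited to "
            "10; collapse to order-level taxa first"
        )
    trees = [
        RootedTree(_canonical(top), outgroup)
        for top in enumerate_rooted_topologies(ingroup)
    ]
    # deterministic canonical order, deduplicated
    uniq: dict[str, RootedTree] = {}
    for t in trees:
        uniq.setdefault(t.newick(), t)
    return [uniq[k] for k in sorted(uniq)]


def search_best_tree(
    matrix: PresenceAbsenceMatrix,
    taxa: list[str] | None = None,
    outgroup: str | None = None,
    convention: str = "losses_only",
) -> tuple[list[RootedTree], int]:
    """Exhaustive Dollo search: all optimal rooted topologies and the
    optimal step count, topologies sorted by canonical newick string."""
    taxa = list(taxa or matrix.taxa)
    trees = _candidate_trees(taxa, outgroup)
    patterns, index = _pattern_table(matrix)
    table = _score_table(trees, patterns, taxa)
    counts = np.bincount(index, minlength=len(patterns))
    scores = table @ counts
    if convention == "gains_plus_losses":
        scores = scores + matrix.n_markers
    best = int(scores.min())
    optima = [trees[i] for i in np.flatnonzero(scores == scores.min())]
    return optima, best


@dataclass
class BootstrapConfig:
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise DolloError("bootstrap requires >= 1 replicate")


def bootstrap_support(
    matrix: PresenceAbsenceMatrix,
    taxa: list[str] | None = None,
    outgroup: str | None = None,
    config: BootstrapConfig | None = None,
) -> dict[frozenset[str], float]:
    """Marker-resampling bootstrap support for ingroup clades.

    Markers are resampled with replacement ``replicates`` times; each
    replicate's optimal tree (the first in canonical order on ties) is
    recorded, and support is the percentage of replicates containing each
    clade.  Fully deterministic for a given seed.
    """
    config = config or BootstrapConfig()
    taxa = list(taxa or matrix.taxa)
    trees = _candidate_trees(taxa, outgroup)
    patterns, index = _pattern_table(matrix)
    table = _score_table(trees, patterns, taxa)
    clade_sets = [t.clades() for t in trees]
    rng = np.random.default_rng(config.seed)
    n = matrix.n_markers
    support: dict[frozenset[str], int] = {}
    for _ in range(config.replicates):
        draw = rng.integers(0, n, size=n)
        counts = np.bincount(index[draw], minlength=len(patterns))
        scores = table @ counts
        win = int(np.argmin(scores))  # first index == first in canonical order
        for clade in clade_sets[win]:
            support[clade] = support.get(clade, 0) + 1
    return {
        c: 100.0 * k / config.replicates for c, k in sorted(
            support.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
        )
    }
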