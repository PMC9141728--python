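"""Multispecies-coalescent quartet statistics on presence/absence markers.

Each marker is treated as a partial bipartition "gene tree": the set of taxa
carrying the insertion versus the set definitely lacking it.  Around any
internal branch of a candidate species tree, with the four surrounding
clusters (A, B, C, D) such that the branch separates A+B from C+D, a marker
votes for the resolution AB|CD through every quadruple (a, b, c, d) it
resolves — pairs inside the insertion, pairs outside it — and analogously
for the two alternative resolutions.  Under the multispecies coalescent the
expected concordant-quartet fraction for a branch of length ``t`` coalescent
units is ``1 - (2/3) e^{-t}``, which inverts to the branch-length estimator
``t = -ln(3/2 (1 - q))``.

Per-branch support is the local posterior probability: with quartet counts
(n1, n2, n3) and an exponential(lambda) branch-length prior, the posterior
weight of resolution i is proportional to

    I(n_i) = lambda * Int_0^1 u^{lambda-1} (1 - 2u/3)^{n_i} (u/3)^{n-n_i} du

(the substitution u = e^{-t} maps the prior onto the unit interval).

The anomaly zone: for a pectinate species tree with consecutive internal
branches x (deeper) and y, the most probable gene tree differs from the
species tree whenever y < a(x), with the boundary

    a(x) = ln[ 2/3 + (3 e^{2x} - 2) / (18 (e^{3x} - e^{2x})) ].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.special import logsumexp

from .marker_matrix import ABSENT, PRESENT, PresenceAbsenceMatrix
from .dollo import RootedTree, _candidate_trees, _leaves

__all__ = [
    "CoalescentError",
    "SpeciesTreeCU",
    "QuartetSupport",
    "LocalPPConfig",
    "AnomalyZoneResult",
    "quartet_pattern_counts",
    "branch_length_from_concordance",
    "concordance_from_branch_length",
    "local_pp",
    "anomaly_boundary",
    "in_anomaly_zone",
    "species_tree_from_markers",
]


class CoalescentError(ValueError):
    pass


@dataclass
class QuartetSupport:
    """Per-branch quartet tallies: ``n1`` concordant votes, ``n2``/``n3``
    the two alternatives, and the concordance fraction ``q_hat``."""

    branch: frozenset[str]
    clusters: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...], tuple[str, ...]]
    n1: float
    n2: float
    n3: float

    @property
    def n(self) -> float:
        return self.n1 + self.n2 + self.n3

    @property
    def q_hat(self) -> float:
        return self.n1 / self.n if self.n > 0 else float("nan")


@dataclass
class LocalPPConfig:
    """Local posterior probability settings: exponential prior rate
    ``lam`` (default 0.5, the convention of quartet-support methods),
    quadrature tolerance, and the branch-length cap ``t_max``."""

    lam: float = 0.5
    quad_tol: float = 1e-10
    t_max: float = 10.0

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.t_max <= 0:
            raise CoalescentError("lam and t_max must be positive")


@dataclass
class AnomalyZoneResult:
    x: float
    y: float
    a_x: float
    in_zone: bool


@dataclass
class SpeciesTreeCU:
    """A rooted species tree whose internal branches carry coalescent-unit
    lengths, quartet support, and local posterior probabilities."""

    tree: RootedTree
    branches: dict[frozenset[str], "BranchAnnotation"] = field(default_factory=dict)

    def newick(self) -> str:
        return _annotated_newick(self.tree, self.branches)


@dataclass
class BranchAnnotation:
    support: QuartetSupport
    length_cu: float
    saturated: bool
    pp: tuple[float, float, float]


# ---------------------------------------------------------------------------
# Quartet pattern counts
# ---------------------------------------------------------------------------

def quartet_pattern_counts(
    matrix: PresenceAbsenceMatrix,
    clusters: tuple,
    weighting: str = "quadruples",
) -> QuartetSupport:
    """Tally marker votes for the three resolutions of one internal branch.

    ``clusters`` is ``(A, B, C, D)``, four disjoint nonempty collections of
    matrix taxa such that the branch separates A+B from C+D.  In
    ``quadruples`` weighting (default) a marker contributes one vote per
    resolved quadruple; in ``single`` weighting a marker contributes at most
    one vote, determined by its order-level pattern across the clusters.
    Taxa with unknown state never take part in a vote.
    """
    A, B, C, D = (tuple(c) for c in clusters)
    for name, cl in zip("ABCD", (A, B, C, D)):
        if not cl:
            raise CoalescentError(f"cluster {name} is empty")
    if weighting not in ("quadruples", "single"):
        raise CoalescentError(f"unknown weighting {weighting!r}")
    idx = {t: matrix.taxa.index(t) for t in A + B + C + D}

    n1 = n2 = n3 = 0.0
    for i in range(matrix.n_markers):
        row = matrix.states[i]
        pres = {t for t in idx if row[idx[t]] == PRESENT}
        abst = {t for t in idx if row[idx[t]] == ABSENT}

        def pair_votes(x, y, u, v):
            # quadruples with {x,y} inside the marker and {u,v} outside,
            # plus the complementary assignment
            px, py = len(pres & set(x)), len(pres & set(y))
            au, av = len(abst & set(u)), len(abst & set(v))
            ax, ay = len(abst & set(x)), len(abst & set(y))
            pu, pv = len(pres & set(u)), len(pres & set(v))
            return px * py * au * av + ax * ay * pu * pv

        v1 = pair_votes(A, B, C, D)
        v2 = pair_votes(A, C, B, D)
        v3 = pair_votes(A, D, B, C)
        if weighting == "single":
            votes = [v1 > 0, v2 > 0, v3 > 0]
            if sum(votes) == 1:
                n1 += votes[0]
                n2 += votes[1]
                n3 += votes[2]
        else:
            n1 += v1
            n2 += v2
            n3 += v3
    return QuartetSupport(frozenset(A + B), (A, B, C, D), n1, n2, n3)


# ---------------------------------------------------------------------------
# Branch lengths and the anomaly zone
# ---------------------------------------------------------------------------

def concordance_from_branch_length(t: float) -> float:
    """Expected concordant-quartet fraction: ``1 - (2/3) e^{-t}``."""
    return 1.0 - (2.0 / 3.0) * math.exp(-t)


def branch_length_from_concordance(q: float, t_max: float = 10.0) -> float:
    """Invert the concordance fraction to coalescent units.

    ``q <= 1/3`` (ILS saturation) clamps to 0; values implying ``t > t_max``
    (including ``q = 1``) are capped at ``t_max``.
    """
    if not 0.0 <= q <= 1.0:
        raise CoalescentError(f"concordance fraction {q} outside [0, 1]")
    if q <= 1.0 / 3.0:
        return 0.0
    if q >= 1.0:
        return t_max
    t = -math.log(1.5 * (1.0 - q))
    return min(t, t_max)


def anomaly_boundary(x: float) -> float:
    """Degnan–Rosenberg anomaly-zone boundary ``a(x)`` for the descendant
    internal branch of a pectinate species tree; ``y < a(x)`` places the
    pair (x, y) in the anomaly zone.  Negative values mean no anomaly zone
    exists at this ``x``."""
    if x <= 0:
        raise CoalescentError("anomaly boundary requires x > 0")
    e2x = math.exp(2.0 * x)
    e3x = math.exp(3.0 * x)
    return math.log(2.0 / 3.0 + (3.0 * e2x - 2.0) / (18.0 * (e3x - e2x)))


def in_anomaly_zone(x: float, y: float) -> AnomalyZoneResult:
    """Is the pair of consecutive internal branch lengths (x, y) in the
    anomaly zone?"""
    if x <= 0 or y <= 0:
        raise CoalescentError("anomaly-zone test requires x, y > 0")
    a_x = anomaly_boundary(x)
    return AnomalyZoneResult(x, y, a_x, in_zone=(y < a_x and a_x > 0))


# ---------------------------------------------------------------------------
# Local posterior probability
# ---------------------------------------------------------------------------

def _log_weight(k: float, n: float, lam: float, tol: float) -> float:
    """log of lambda * Int_0^1 u^{lam-1} (1-2u/3)^k (u/3)^{n-k} du,
    computed by adaptive quadrature on the exp-shifted log-integrand."""

    def g(u: float) -> float:
        if u <= 0.0:
            return -math.inf
        return (
            (lam - 1.0 + (n - k)) * math.log(u)
            + k * math.log1p(-2.0 * u / 3.0)
            - (n - k) * math.log(3.0)
        )

    # locate the maximum of g on a grid to stabilise the shift
    grid = np.linspace(1e-12, 1.0 - 1e-12, 513)
    gvals = np.array([g(u) for u in grid])
    shift = float(gvals.max())
    val, _ = integrate.quad(
        lambda u: math.exp(g(u) - shift) if g(u) - shift > -745 else 0.0,
        0.0,
        1.0,
        epsabs=tol,
        epsrel=tol,
        limit=200,
    )
    return math.log(lam) + shift + math.log(val)


def local_pp(
    counts: tuple[float, float, float], config: LocalPPConfig | None = None
) -> tuple[float, float, float]:
    """Local posterior probabilities for the three resolutions of a branch
    given quartet counts ``(n1, n2, n3)``.  Sums to 1; symmetric counts give
    equal thirds."""
    config = config or LocalPPConfig()
    n1, n2, n3 = counts
    if min(n1, n2, n3) < 0:
        raise CoalescentError("quartet counts must be non-negative")
    n = n1 + n2 + n3
    logs = np.array(
        [_log_weight(k, n, config.lam, config.quad_tol) for k in (n1, n2, n3)]
    )
    pps = np.exp(logs - logsumexp(logs))
    pps = pps / pps.sum()
    return (float(pps[0]), float(pps[1]), float(pps[2]))


# ---------------------------------------------------------------------------
# Species-tree search
# ---------------------------------------------------------------------------

def _branch_clusters(tree: RootedTree) -> list[tuple[frozenset[str], tuple]]:
    """For each internal branch of the rooted ingroup tree, the four
    surrounding clusters (A, B: the child subtrees; C: the sibling side;
    D: everything else, outgroup included)."""
    full = tree.full_root
    all_leaves = set(_leaves(full))
    out = []

    def walk(node, sibling_leaves):
        if isinstance(node, str):
            return
        left, right = node
        l_leaves, r_leaves = _leaves(left), _leaves(right)
        here = set(l_leaves) | set(r_leaves)
        rest = all_leaves - here - set(sibling_leaves)
        if sibling_leaves and rest:
            clusters = (
                tuple(l_leaves),
                tuple(r_leaves),
                tuple(sibling_leaves),
                tuple(sorted(rest)),
            )
            out.append((frozenset(here), clusters))
        walk(left, r_leaves)
        walk(right, l_leaves)

    if not isinstance(full, str):
        walk(full[0], _leaves(full[1]))
        walk(full[1], _leaves(full[0]))
    return out


def quartet_score(matrix: PresenceAbsenceMatrix, tree: RootedTree) -> float:
    """Total quartet support of ``tree``: over every 4-taxon subset, the
    number of marker votes for the resolution the tree induces (each subset
    counted exactly once).  This is the species-tree optimality criterion
    for markers treated as partial bipartitions."""
    taxa = list(matrix.taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    P = matrix.states == PRESENT
    Z = matrix.states == ABSENT
    votes_cache: dict[tuple[int, int, int, int], int] = {}

    def votes(a: int, b: int, c: int, d: int) -> int:
        key = (*sorted((a, b)), *sorted((c, d)))
        if key not in votes_cache:
            ab_in = P[:, a] & P[:, b] & Z[:, c] & Z[:, d]
            cd_in = P[:, c] & P[:, d] & Z[:, a] & Z[:, b]
            votes_cache[key] = int((ab_in | cd_in).sum())
        return votes_cache[key]

    total = 0
    for quad, (a, b, c, d) in _induced_quartets(tree, idx):
        total += votes(a, b, c, d)
    return float(total)


def _induced_quartets(tree: RootedTree, idx: dict[str, int]):
    """Yield every 4-taxon subset with its tree-induced pairing, as column
    indices ((a,b) sisters against (c,d)).  The pairing of a subset S is
    read off any clade whose intersection with S has exactly two members."""
    import itertools

    from .dollo import _internal_nodes

    full = tree.full_root
    taxa = _leaves(full)
    clades = [
        frozenset(_leaves(node))
        for node in _internal_nodes(full)
        if node is not full
    ]
    for quad in itertools.combinations(taxa, 4):
        s = set(quad)
        for clade in clades:
            inter = clade & s
            if len(inter) == 2:
                a, b = sorted(inter)
                c, d = sorted(s - inter)
                yield frozenset(idx[t] for t in quad), (
                    idx[a], idx[b], idx[c], idx[d],
                )
                break


def species_tree_from_markers(
    matrix: PresenceAbsenceMatrix,
    outgroup: str | None = None,
    weighting: str = "quadruples",
    pp_config: LocalPPConfig | None = None,
    max_ingroup: int = 6,
) -> tuple[SpeciesTreeCU, list[RootedTree]]:
    """Exhaustive quartet-score species-tree estimate from an order-level
    matrix.

    Scores every rooted topology with :func:`quartet_score` and returns the
    winner annotated with per-branch quartet counts, coalescent-unit
    lengths, and local posterior probabilities, together with the list of
    co-optimal topologies (ties).
    """
    pp_config = pp_config or LocalPPConfig()
    taxa = list(matrix.taxa)
    ingroup = [t for t in taxa if t != outgroup]
    if len(ingroup) > max_ingroup:
        raise CoalescentError(
            f"{len(ingroup)} ingroup lineages exceed the exhaustive-search "
            f"limit of {max_ingroup}"
        )
    trees = _candidate_trees(taxa, outgroup)
    scores = [quartet_score(matrix, tree) for tree in trees]
    best = max(scores)
    winners = [i for i, s in enumerate(scores) if s == best]
    win = winners[0]
    ties = [trees[i] for i in winners[1:]]
    annotations: dict[frozenset[str], BranchAnnotation] = {}
    for _, clusters in _branch_clusters(trees[win]):
        sup = quartet_pattern_counts(matrix, clusters, weighting)
        t = branch_length_from_concordance(sup.q_hat, pp_config.t_max) if sup.n else 0.0
        saturated = sup.n > 0 and (sup.q_hat >= 1.0 or t >= pp_config.t_max)
        pp = local_pp((sup.n1, sup.n2, sup.n3), pp_config)
        annotations[sup.branch] = BranchAnnotation(sup, t, saturated, pp)
    return SpeciesTreeCU(trees[win], annotations), ties


def _annotated_newick(
    tree: RootedTree, branches: dict[frozenset[str], BranchAnnotation]
) -> str:
    def render(node) -> str:
        if isinstance(node, str):
            return node
        inner = ",".join(render(c) for c in node)
        clade = frozenset(_leaves(node))
        ann = branches.get(clade)
        if ann is None:
            return f"({inner})"
        sup = ann.support
        comment = (
            f"[&n1={sup.n1:g},n2={sup.n2:g},n3={sup.n3:g},pp={ann.pp[0]:.4f}]"
        )
        return f"({inner}){comment}:{ann.length_cu:.6f}"

    return render(tree.full_root) + ";"
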