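"""Seeded synthetic-data generator for retrotransposon presence/absence
matrices under the multispecies coalescent.

The generator emulates the statistical structure of an order-level
laurasiatherian marker matrix: five orders with two species each plus one
outgroup, gene trees drawn under the MSC on a pectinate species tree whose
two consecutive internal branches (x, y, in coalescent units) sit at
anomaly-zone scale, insertions dropped as a Poisson process along gene-tree
branches, and optional missingness, homoplasy (precise deletion or parallel
insertion), and an introgression pulse.

Two modes are provided.  ``branch_weighted`` is the mechanistic model: the
gene trees come from msprime on the full species demography and every
informative insertion becomes a marker.  ``multinomial`` is the reduced
statistical model used for calibration: each marker's class is drawn
directly from the focal-branch trinomial with concordance
``1 - (2/3) e^{-t}``, which makes closed-form checks of estimators
possible.

Within-order species splits are recent relative to a long (5 coalescent
unit) ordinal stem, so markers are effectively fixed per order and the
second species corroborates rather than conflicts — mirroring how real
screens use a second species per order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .marker_matrix import (
    ABSENT,
    ORDERS,
    OUTGROUP,
    PRESENT,
    UNKNOWN,
    OrderMap,
    PresenceAbsenceMatrix,
)
from .marker_validation import ElementAnnotation, LocusAlignment

__all__ = [
    "SimulationScenario",
    "SimulatedTruth",
    "laurasiatheria_preset",
    "scenario_order_map",
    "simulate_markers",
    "emit_locus_alignments",
]


class SimulationError(ValueError):
    pass


@dataclass
class SimulationScenario:
    """All knobs of one simulation run; fully reproducible given ``seed``.

    ``x`` and ``y`` are the two consecutive internal branches of the
    pectinate ingroup tree (Eul,(Chi,(Per,(Cet,Fer)))) in coalescent units;
    ``terminal_cu`` is the default length for the remaining internal and
    terminal branches; ``stem_gap_cu`` is the ordinal stem duration that
    fixes markers within orders.  ``introgression`` is ``None`` or a tuple
    ``(gamma, donor_order, recipient_order)``.
    """

    x: float = 0.1151
    y: float = 0.0551
    species_per_order: int = 2
    n_markers: int = 470
    insertion_rate: float = 0.1
    missing_rate: float = 0.0
    homoplasy_rate: float = 0.0
    introgression: tuple[float, str, str] | None = None
    mode: str = "branch_weighted"
    multinomial_focal: str = "both"
    seed: int = 0
    terminal_cu: float = 1.0
    stem_gap_cu: float = 5.0

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise SimulationError("marker count must be >= 1")
        for r in (self.missing_rate, self.homoplasy_rate):
            if not 0.0 <= r <= 1.0:
                raise SimulationError("rates must lie in [0, 1]")
        if self.mode not in ("branch_weighted", "multinomial"):
            raise SimulationError(f"unknown mode {self.mode!r}")
        if self.multinomial_focal not in ("x", "y", "both"):
            raise SimulationError(f"unknown focal {self.multinomial_focal!r}")
        if self.introgression is not None:
            g, donor, recipient = self.introgression
            if not 0.0 <= g <= 1.0:
                raise SimulationError(f"gamma {g} outside [0, 1]")
            if donor not in ORDERS or recipient not in ORDERS:
                raise SimulationError("introgression orders must be ingroup orders")

    @property
    def species(self) -> list[str]:
        out = [
            f"{order}_sp{i + 1}"
            for order in ORDERS
            for i in range(self.species_per_order)
        ]
        out.append(f"{OUTGROUP}_sp1")
        return out

    @property
    def topology_newick(self) -> str:
        return "(Eulipotyphla,(Chiroptera,(Perissodactyla,(Cetartiodactyla,Ferae))));"


@dataclass
class SimulatedTruth:
    """Ground truth for every emitted marker."""

    topology_newick: str
    x: float
    y: float
    mode: str
    generating_clade: list[frozenset[str]] = field(default_factory=list)
    focal_branch: list[str] = field(default_factory=list)
    homoplasy_flags: list[str | None] = field(default_factory=list)
    insertion_rate: float = 0.0


def laurasiatheria_preset(seed: int = 0) -> SimulationScenario:
    """The reference scenario: the published anomaly-zone branch lengths
    (x = 0.1151, y = 0.0551), five orders with two species each plus one
    outgroup (11 taxa), and 470 markers."""
    return SimulationScenario(seed=seed)


def scenario_order_map(scenario: SimulationScenario) -> OrderMap:
    assignments = {}
    for sp in scenario.species:
        group = sp.rsplit("_sp", 1)[0]
        assignments[sp] = group
    return OrderMap(assignments)


# ---------------------------------------------------------------------------
# Demography and branch-weighted simulation
# ---------------------------------------------------------------------------

def _demography(scenario: SimulationScenario):
    """msprime demography for the preset species tree; time in coalescent
    units (ploidy 1, all population sizes 1)."""
    import msprime

    dem = msprime.Demography()
    tips = scenario.species
    for sp in tips:
        dem.add_population(name=sp, initial_size=1.0)
    for order in ORDERS:
        dem.add_population(name=f"anc_{order}", initial_size=1.0)
    for name in ("anc_CetFer", "anc_Fereuungulata", "anc_Scrotifera",
                 "anc_Laurasiatheria", "anc_Root"):
        dem.add_population(name=name, initial_size=1.0)

    t_sp = scenario.terminal_cu
    t_cf = t_sp + scenario.stem_gap_cu
    t_fu = t_cf + scenario.y
    t_sc = t_fu + scenario.x
    t_la = t_sc + scenario.terminal_cu
    t_root = t_la + scenario.terminal_cu

    for order in ORDERS:
        members = [sp for sp in tips if sp.startswith(order + "_sp")]
        dem.add_population_split(
            time=t_sp, derived=members, ancestral=f"anc_{order}"
        )
    if scenario.introgression is not None:
        gamma, donor, recipient = scenario.introgression
        # a pulse just before the recipient's ordinal join lets a fraction
        # gamma of recipient lineages trace the donor's history
        join_time = {"Perissodactyla": t_fu, "Chiroptera": t_sc,
                     "Cetartiodactyla": t_cf, "Ferae": t_cf,
                     "Eulipotyphla": t_la}[recipient]
        dem.add_mass_migration(
            time=join_time - 1e-9,
            source=f"anc_{recipient}",
            dest=f"anc_{donor}",
            proportion=gamma,
        )
    dem.add_population_split(
        time=t_cf,
        derived=["anc_Cetartiodactyla", "anc_Ferae"],
        ancestral="anc_CetFer",
    )
    dem.add_population_split(
        time=t_fu,
        derived=["anc_CetFer", "anc_Perissodactyla"],
        ancestral="anc_Fereuungulata",
    )
    dem.add_population_split(
        time=t_sc,
        derived=["anc_Fereuungulata", "anc_Chiroptera"],
        ancestral="anc_Scrotifera",
    )
    dem.add_population_split(
        time=t_la,
        derived=["anc_Scrotifera", "anc_Eulipotyphla"],
        ancestral="anc_Laurasiatheria",
    )
    dem.add_population_split(
        time=t_root,
        derived=["anc_Laurasiatheria", f"{OUTGROUP}_sp1"],
        ancestral="anc_Root",
    )
    dem.sort_events()
    return dem


def _is_informative(pattern: frozenset[str], order_map: OrderMap) -> bool:
    """A species-level presence set is informative when no order is split
    (all-or-none membership), the outgroup is absent, and presence spans
    2-4 orders."""
    present_orders = set()
    for order in list(ORDERS) + [OUTGROUP]:
        members = set(order_map.members(order))
        inter = members & pattern
        if inter and inter != members:
            return False
        if inter:
            present_orders.add(order)
    if OUTGROUP in present_orders:
        return False
    return 2 <= len(present_orders) <= 4


def _branch_weighted(
    scenario: SimulationScenario, rng: np.random.Generator
) -> tuple[list[frozenset[str]], list[frozenset[str]]]:
    """Draw informative insertion patterns from msprime gene trees until
    the target marker count is reached."""
    import msprime

    if scenario.insertion_rate <= 0:
        raise SimulationError(
            "insertion rate must be positive to reach the target marker count"
        )
    dem = _demography(scenario)
    order_map = scenario_order_map(scenario)
    samples = {sp: 1 for sp in scenario.species}
    patterns: list[frozenset[str]] = []
    batch = max(500, int(scenario.n_markers / max(scenario.insertion_rate, 1e-6) / 4))
    guard = 0
    while len(patterns) < scenario.n_markers:
        guard += 1
        if guard > 200:
            raise SimulationError(
                "simulation failed to reach the target marker count; "
                "increase insertion_rate"
            )
        reps = msprime.sim_ancestry(
            samples=samples,
            demography=dem,
            ploidy=1,
            random_seed=int(rng.integers(1, 2**31 - 1)),
            num_replicates=batch,
        )
        for ts in reps:
            tree = ts.first()
            node_species = {}
            for node in ts.samples():
                pop = ts.node(node).population
                node_species[node] = ts.population(pop).metadata.get(
                    "name", None
                ) or dem.populations[pop].name
            for u in tree.nodes():
                parent = tree.parent(u)
                if parent == -1:
                    continue
                length = tree.branch_length(u)
                k = rng.poisson(scenario.insertion_rate * length)
                if k == 0:
                    continue
                clade = frozenset(
                    node_species[s] for s in tree.samples(u)
                )
                for _ in range(int(k)):
                    if _is_informative(clade, order_map):
                        patterns.append(clade)
            if len(patterns) >= scenario.n_markers:
                break
    return patterns[: scenario.n_markers], patterns[: scenario.n_markers]


_FOCAL_PATTERNS = {
    # focal branch x (Fereuungulata): clusters ({Per},{Cet,Fer},{Chi},{Eul,OG})
    "x": (
        frozenset({"Perissodactyla", "Cetartiodactyla", "Ferae"}),
        frozenset({"Perissodactyla", "Chiroptera"}),
        frozenset({"Cetartiodactyla", "Ferae", "Chiroptera"}),
    ),
    # focal branch y (Cetartioferae): clusters ({Cet},{Fer},{Per},{rest})
    "y": (
        frozenset({"Cetartiodactyla", "Ferae"}),
        frozenset({"Cetartiodactyla", "Perissodactyla"}),
        frozenset({"Ferae", "Perissodactyla"}),
    ),
}


def _multinomial(
    scenario: SimulationScenario, rng: np.random.Generator
) -> tuple[list[frozenset[str]], list[str]]:
    """Draw marker classes directly from the focal-branch trinomials."""
    focal = (
        ["x", "y"] if scenario.multinomial_focal == "both"
        else [scenario.multinomial_focal]
    )
    n = scenario.n_markers
    counts = {f: n // len(focal) for f in focal}
    counts[focal[0]] += n - sum(counts.values())
    order_patterns: list[frozenset[str]] = []
    branches: list[str] = []
    for f in focal:
        t = scenario.x if f == "x" else scenario.y
        theta = 1.0 - (2.0 / 3.0) * np.exp(-t)
        probs = [theta, (1 - theta) / 2, (1 - theta) / 2]
        draws = rng.choice(3, size=counts[f], p=probs)
        for d in draws:
            order_patterns.append(_FOCAL_PATTERNS[f][d])
            branches.append(f)
    return order_patterns, branches


def simulate_markers(
    scenario: SimulationScenario,
) -> tuple[PresenceAbsenceMatrix, SimulatedTruth]:
    """Generate a species-level presence/absence matrix plus ground truth.

    Fully deterministic for a given scenario (the seed drives msprime and
    all noise injection).  Homoplasy flips one random cell per affected
    marker — a precise deletion (present -> absent) or a parallel insertion
    (absent -> present) with equal probability; missingness then masks cells
    to unknown.
    """
    rng = np.random.default_rng(scenario.seed)
    order_map = scenario_order_map(scenario)
    species = scenario.species

    if scenario.mode == "branch_weighted":
        patterns, _ = _branch_weighted(scenario, rng)
        branches = [""] * len(patterns)
        clades = patterns
    else:
        order_patterns, branches = _multinomial(scenario, rng)
        # expand order-level classes to species-level presence sets
        clades = []
        for pat in order_patterns:
            clade = frozenset(
                sp for order in pat for sp in order_map.members(order)
            )
            clades.append(clade)

    n = len(clades)
    states = np.full((n, len(species)), ABSENT, dtype=np.int8)
    col = {sp: j for j, sp in enumerate(species)}
    for i, clade in enumerate(clades):
        for sp in clade:
            states[i, col[sp]] = PRESENT

    homoplasy_flags: list[str | None] = [None] * n
    if scenario.homoplasy_rate > 0:
        hits = rng.random(n) < scenario.homoplasy_rate
        for i in np.flatnonzero(hits):
            kind = "precise_deletion" if rng.random() < 0.5 else "parallel_insertion"
            if kind == "precise_deletion":
                cands = np.flatnonzero(states[i] == PRESENT)
            else:
                cands = np.flatnonzero(states[i] == ABSENT)
            if cands.size == 0:
                continue
            j = int(rng.choice(cands))
            states[i, j] = ABSENT if kind == "precise_deletion" else PRESENT
            homoplasy_flags[i] = kind

    if scenario.missing_rate > 0:
        mask = rng.random(states.shape) < scenario.missing_rate
        states[mask] = UNKNOWN

    marker_ids = [f"sim{i + 1:05d}" for i in range(n)]
    matrix = PresenceAbsenceMatrix(
        marker_ids, list(species), states, ["simulated"] * n
    )
    truth = SimulatedTruth(
        topology_newick=scenario.topology_newick,
        x=scenario.x,
        y=scenario.y,
        mode=scenario.mode,
        generating_clade=list(clades),
        focal_branch=branches,
        homoplasy_flags=homoplasy_flags,
        insertion_rate=scenario.insertion_rate,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Locus-alignment fixtures
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def emit_locus_alignments(
    matrix: PresenceAbsenceMatrix,
    seed: int = 0,
    flank_len: int = 500,
    tsd_len: int = 10,
) -> list[LocusAlignment]:
    """Build synthetic locus alignments that round-trip through marker
    validation.

    Present species carry the element with exact TSD copies on both sides;
    absent species show a clean empty site (the element plus one TSD copy
    gapped out, flanks contiguous); unknown species are omitted from the
    alignment.  With no injected noise, validating these fixtures reproduces
    the matrix states exactly.
    """
    rng = np.random.default_rng(seed)
    loci: list[LocusAlignment] = []
    for i, mid in enumerate(matrix.marker_ids):
        family = "LINE1" if rng.random() < 0.5 else "LTR"
        orientation = "+" if rng.random() < 0.5 else "-"
        elem_len = int(rng.integers(150, 400))
        left = _random_seq(rng, flank_len)
        right = _random_seq(rng, flank_len - tsd_len)
        tsd = _random_seq(rng, tsd_len)
        element = _random_seq(rng, elem_len)
        gap_block = "-" * (elem_len + tsd_len)
        sequences: dict[str, str] = {}
        for j, sp in enumerate(matrix.taxa):
            s = int(matrix.states[i, j])
            if s == PRESENT:
                sequences[sp] = left + tsd + element + tsd + right
            elif s == ABSENT:
                sequences[sp] = left + tsd + gap_block + right
            else:
                continue  # unknown: assembly gap, species missing
        if len(sequences) < 2:
            continue
        span = (flank_len + tsd_len, flank_len + tsd_len + elem_len)
        loci.append(
            LocusAlignment(
                mid,
                sequences,
                ElementAnnotation(family, span, orientation),
            )
        )
    return loci
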