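# Methods

`retrophylo` analyses retrotransposon presence/absence matrices for rapid
radiations whose species trees may sit in the anomaly zone, with the five
laurasiatherian orders (Eulipotyphla, Chiroptera, Perissodactyla,
Cetartiodactyla, Ferae) as the reference system.  This note documents the
models, the defaults and why they hold, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Marker model

A marker is one retrotransposon insertion at an orthologous locus, coded
per taxon as present (`1`), absent (`0`), or unresolvable (`?`).  Because
insertions are effectively irreversible and independent insertions at the
same position are vanishingly rare, a shared present state is near
homoplasy-free evidence for a clade, and conflicting markers predominantly
reflect incomplete lineage sorting (ILS) across short internodes.

**Validation rules** (module `marker_validation`) operationalize the
acceptance of a candidate locus: target site duplications (TSDs) detected in
every present species (default minimum length 4 nt, at most 1 mismatch,
boundary window ±5 nt — the screen literature leaves these to manual
curation, so they are configurable and logged); TSD start positions
orthologous across species (alignment-column offsets strictly below 3 nt);
one element family and orientation across present species; LINE1 3′
truncation strictly below 50 nt (5′ truncation free, as expected from
target-primed reverse transcription) and LTR truncations at most 20 nt per
end; a clear absence state in the outgroup; at least two orders with a
definite state.  Presence requires ≥80% of the element span aligned; absence
requires a fully gapped span with contiguous flanks, where a short gap run
(up to one TSD length) adjacent to the span is tolerated because an empty
site lacks one TSD copy relative to present species.  The 80% threshold and
the flank-contiguity window (25 columns, ≥80% non-gap) are our documented
operationalization of "clear" presence/absence.

**Census** (module `marker_matrix`): species columns are collapsed to
orders.  The default policy is strict — an order is present only if every
member with a definite state is present; a conflicted order becomes `?` and
excludes the marker from the census (the second species corroborates, never
rescues, a marker).  Affiliation classes are the subsets of the five orders
of size 2–4, exactly C(5,2)+C(5,3)+C(5,4) = 25 classes; markers present in
0, 1 or 5 orders are uninformative.  Outgroup presence (or an outgroup
without a definite absent member) disqualifies a marker.  The census can be
exported as a SplitsTree-compatible NEXUS splits block with one weighted
split per nonzero class.

## Dollo parsimony

Under Dollo parsimony a character is gained once and only lost thereafter.
For each marker the gain is placed on the branch to the MRCA of the
definitely-present taxa and the minimal set of loss branches below it is
found by dynamic programming; `?` taxa take whichever state avoids a loss.
The reported step count follows the `losses_only` convention (a marker
compatible with the tree contributes zero steps); the alternative
`gains_plus_losses` convention, which adds one step per marker, is available
for sensitivity checks.  With order-level taxa the search is exhaustive
(105 rooted topologies for 5 ingroup taxa), so heuristic search order and
input jumbling are irrelevant; ties are broken by canonical newick order,
which also makes the marker-resampling bootstrap (default 1000 replicates,
seeded) fully deterministic.

## Coalescent quartet statistics

Each marker acts as a partial bipartition "gene tree".  The species-tree
criterion is the quartet score: over every 4-taxon subset, the number of
marker votes for the resolution the candidate tree induces, where a marker
votes for ab|cd whenever it contains {a,b} and definitely excludes {c,d}
(or vice versa).  Each 4-subset is counted exactly once; the search is
exhaustive for up to 6 order-level lineages.

Per-branch annotation uses the counts (n1, n2, n3) of the three resolutions
around the branch, with:

* branch length `t = −ln(3/2 (1 − q̂))` from the concordance fraction
  `q̂ = n1/n`; `q̂ ≤ 1/3` clamps to 0 (ILS saturation) and `q̂ = 1` caps at
  `t_max = 10` coalescent units with a saturation flag, since the estimator
  diverges there;
* local posterior probability
  `pp_i ∝ λ ∫₀¹ u^{λ−1} (1 − 2u/3)^{n_i} (u/3)^{n−n_i} du` with an
  exponential(λ = 0.5) branch-length prior (the convention of quartet-support
  methods), evaluated by adaptive quadrature on the exp-shifted
  log-integrand (absolute tolerance 1e−10); the tests check it against an
  exact 300-digit series oracle to 1e−6.

Because markers are single insertions rather than full gene trees, votes
from insertions that arose on one internal branch also inform neighbouring
branches; pooled branch-length estimates on multi-branch matrices are
therefore convention-sensitive, and parameter-recovery checks use
single-focal-branch multinomial data.  An alternative `single` weighting
(one vote per marker) is provided for comparison.

**Anomaly zone.**  For consecutive internal branches x (deeper) and y of a
pectinate species tree, the pair lies in the anomaly zone when `y < a(x)`
with `a(x) = ln[2/3 + (3e^{2x} − 2)/(18(e^{3x} − e^{2x}))]`.  `a` is
strictly decreasing with its zero near x ≈ 0.2655; beyond that no anomaly
zone exists.

## ILS versus introgression

**Quartet-asymmetry test.**  Under the multispecies coalescent (MSC) alone
the two discordant resolutions of a quartet are exactly equiprobable, so the
discordant counts are tested by an exact two-sided binomial test at p = 1/2.
The test takes explicit counts; how markers are assigned to a quartet is the
caller's choice.

**4-lineage likelihood-ratio test.**  Markers on four lineages fall into ten
informative classes (six pairs, four triples).  Class probabilities under
the pectinate MSC `(((A,B):y,C):x,D)` are estimated by simulating gene
trees with a vectorized structured-coalescent sampler (cross-checked against
msprime) and dropping one marker per gene tree uniformly on its internal
branches weighted by length.  Introgression is a single lineage-replacement
pulse: with probability γ the recipient lineage C joins the donor D's
population at the base of the recipient stem represented in the model (the
A–B divergence), where it may coalesce with D anywhere in the x + y window
before the root.  The multinomial likelihood is maximized over (x, y) with
γ = 0 and over (x, y, γ); all likelihood evaluations share one fixed block
of uniforms (common random numbers), which nests the null exactly inside
the alternative and makes the Monte-Carlo surface optimizable (Nelder–Mead
with explicit wide initial simplexes, log-scale branch lengths, default
n_mc = 10⁵ per evaluation; the test suite uses 6 × 10³ to keep runtimes
short).  Because γ = 0 is a boundary point, the default p-value uses the
½χ²₀ + ½χ²₁ mixture reference; the plain χ²(1) p-value is reported
alongside and is conservative.

Calibration and power are assessed on a moderate-ILS quartet
(x = 0.5, y = 0.25 coalescent units, 1000 markers), where the test holds
its size (empirical type-I ≈ 0.05–0.06) and detects γ = 0.3 essentially
always.  A known limitation: the detectable effect of a single pulse scales
with γ(1 − e^{−(x+y)}), so at anomaly-zone-scale branches
(x + y ≈ 0.17) most of the introgression signal is erased by shared
ancestry and no test of this form retains high power — which is precisely
why published analyses of such radiations can disagree.

## Synthetic-data generator

The generator (module `retro_simulator`) emulates the statistical structure
of an order-level laurasiatherian marker matrix.  Defaults: pectinate
ingroup (Eul,(Chi,(Per,(Cet,Fer)))) with x = 0.1151 and y = 0.0551
coalescent units (anomaly-zone scale), two species per order plus one
outgroup (11 taxa), 470 markers.  Within-order splits sit 1 CU above the
tips with a 5 CU ordinal stem, so the two species of an order almost surely
share each marker state and the second species corroborates rather than
conflicts; remaining internal/terminal branches default to 1 CU.

* `branch_weighted` mode draws gene trees from msprime on the full
  demography (one haploid lineage per species, population sizes 1, times in
  coalescent units) and drops insertions as a Poisson process along
  branches (default rate 0.1 per CU — a free parameter, not an inference;
  gene trees are drawn until the target count of order-informative markers
  is reached, so the rate shifts compute cost, not the pattern
  distribution).  Markers are kept when their order-collapsed pattern is
  unambiguous, spans 2–4 orders, and excludes the outgroup.
* `multinomial` mode draws marker classes directly from the focal-branch
  trinomial with concordance `1 − (2/3)e^{−t}`, enabling closed-form checks
  of the estimators.

Noise injection: homoplasy flips one random cell per affected marker —
precise deletion or parallel insertion with equal probability (default rate
0 in tests that assert exact recovery; the preset documents 1% as a
realistic level) — and missingness masks cells to `?`.  Optional
introgression adds an msprime mass-migration pulse just before the
recipient order's join.  Locus-alignment fixtures embed exact TSDs and
500-nt flanks so that zero-noise fixtures round-trip through validation
with 100% state agreement; the generator does not simulate flank sequence
evolution (substitutions, indels) or population sampling, so passing tests
say nothing about alignment error or polymorphism in real screens.

## Exon supermatrix curation

The exon module reproduces the bookkeeping around an exon-level c-gene
analysis: per-group coverage minima (Primates ≥2, Rodentia ≥1, Lagomorpha
≥1, Afrotheria ≥2, Xenarthra ≥2, Pholidota ≥1, Cetartiodactyla ≥3,
Carnivora ≥3, Perissodactyla ≥1, Chiroptera ≥5, Eulipotyphla ≥1 — read
distributively per group, with the rule table configurable so the
alternative conjunctive reading can be tested), split-codon trimming to a
multiple of 3, concatenation with 1-based inclusive partitions and a paired
amino-acid matrix of exactly one third the columns, parsimony-informative
site counts (≥2 unambiguous states each in ≥2 sequences; gaps and ambiguity
codes never count — the standard convention, which deposited-data counts
may be mildly sensitive to), length statistics with a strict >500 nt
long-exon subset, collapsing of internal branches strictly shorter than
0.01 substitutions/site, and unrooted Robinson–Foulds distances on the
shared leaf set (via dendropy).  Maximum-likelihood and quartet tree
inference are external engines; this module prepares inputs and consumes
newick outputs only.

## Numerical and engineering choices

* All randomness flows through `numpy.random.default_rng` seeds carried in
  the configuration; identical config + seed reproduces every output byte
  for byte (reports carry a config hash and package version).
* Branch-length round trips are exact to 1e−12 for t ≤ 5 CU; near
  saturation (t → 10) double-precision cancellation in 1 − q limits
  accuracy to ~1e−11.
* Exhaustive tree enumeration is (2n−3)!! rooted topologies via stepwise
  addition; the Dollo search accepts at most 10 ingroup taxa and the
  quartet search at most 6 — both meant for order-level analyses.
* Degenerate inputs fail loudly: all-unknown markers, empty clusters,
  x ≤ 0 for the anomaly boundary, fewer than 4 shared taxa for RF.

## Known limitations

* The validation rule set approximates a manual curation protocol; real
  screens apply judgments (flank microhomology, nested elements) no fixed
  rule captures.
* Treating each insertion as an independent bipartition ignores linkage
  between insertions on the same gene-tree branch and makes pooled
  branch-length/pp values convention-sensitive.
* The 4-lineage LRT tests a single pulse between one donor/recipient pair;
  it is not a network-inference method, and its power collapses at
  anomaly-zone-scale branch lengths (see above).
* Order-level exhaustive searches do not scale beyond a handful of
  lineages by design.
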