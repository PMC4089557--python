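# Methods

This note records the models, algorithms, numerical conventions and
design decisions behind `elucid`, in the order the pipeline runs.

## Molecular model

Candidates are constitutions: hydrogen-suppressed connected multigraphs
of heavy atoms with integer bond orders 1–3, up to element- and
bond-order-preserving isomorphism.  Hydrogens are implicit; each atom's
implicit count is its fixed valence minus the sum of its incident bond
orders.  Valences are C 4, N 3, O 2, S 2, P 3, halogens 1.  Charges,
radicals, isotopes, stereochemistry and hypervalent S/P are out of
scope: the target chemistry is small neutral natural products, and
fixed valences keep the validity check decidable.

Aromatic rings are always represented in Kekulé form.  A consequence
worth stating: bond-order patterns that are genuinely non-isomorphic as
multigraphs (e.g. the central-double-bond Kekulé form of naphthalene
versus the others) count as distinct constitutions.  This keeps
canonicalization free of aromaticity-model ambiguity at the cost of
occasionally splitting one aromatic species across Kekulé variants.

Formula feasibility is checked via the degree of unsaturation
DBE = 1 + Σᵢ nᵢ(vᵢ − 2)/2 (over all atoms including H); formulas with
negative or fractional DBE are rejected.

**Canonical identity.**  The canonical key of a graph is its canonical
Kekulé SMILES (RDKit, no aromaticity perception).  Independently,
`is_same_constitution` answers the same question through VF2
isomorphism on the labelled graph (networkx).  The test suite checks
that the two notions agree with a brute-force enumeration oracle on
exhaustively enumerable formulas (C4H10, C3H8O, C2H4O).

## Random structures and mutation

`random_structure` builds a random spanning tree over the heavy atoms
(respecting residual valences), then distributes the remaining
bond-order units — new bonds or order increments up to 3 — until the
implicit-hydrogen total matches the formula, retrying dead ends up to
1000 times.

`mutate` applies one Faulon-style elementary move.  Conceptually the
move acts on the hydrogen-*explicit* graph: two bonds (a,b) and (c,d)
on four distinct atoms are each decremented and the cross pairs
(a,c)+(b,d) (or (a,d)+(b,c)) incremented, so every atom's total valence
is untouched.  On the hydrogen-suppressed representation this yields
two move types:

- **rewire** — both bonds heavy–heavy: transfers one order unit between
  two heavy-atom pairs and preserves every atom's heavy bond-order sum;
- **hshift** — one endpoint is a hydrogen: a heavy bond loses an order
  unit, the freed valence becomes an implicit H, and an H elsewhere is
  spent to create/strengthen a bond.

The hshift move is what lets the search change the hydrogen-placement
profile (n-butane → isobutane has different heavy-degree sequences, so
no heavy-bond-only move can connect them).  Moves that disconnect the
graph, exceed order 3 or drive an H count negative are rejected and
retried, 100 attempts at most, after which the input is returned
unchanged with a logged warning (so a whole-population mutation pass
always completes; methane, with no applicable move, simply passes
through).  Element counts, total hydrogen and total bond order are
conserved by every accepted move; the test suite drives 10⁴ moves per
fixture molecule to check conservation and connectivity, and verifies
that iterated mutation visits all three C5H12 isomers from any start.

## HOSE-style shift index

A carbon's environment code is a canonical rooted-tree string.  Grammar:

- root token `<El>H<n>` (element + attached-H count), e.g. `CH2`;
- each deeper node is `<bond><El>` with bond symbols `-`, `=`, `#`;
- a node's children (neighbours except the atom it was reached from)
  are parenthesised and comma-separated, expanded recursively to the
  requested height;
- siblings are ordered by (bond order descending, element priority
  C > O > N > S > P > F > Cl > Br > I, then recursive string), so the
  code is independent of atom numbering.

Only the root carries its hydrogen count.  Deeper nodes are
element-only: their hydrogens are implied by the unencoded remainder of
their valence, and encoding them would make low heights so specific
that the height-1 backoff table would rarely match anything.  Ring
atoms revisited along different branches are re-expanded as separate
subtrees (bounded by the height), which keeps the string a pure
function of the rooted neighbourhood.

**Index.**  For heights 1–4, every carbon of every reference molecule
contributes its observed shift to the entry of its code at that height.
An entry stores count, mean, standard deviation (ddof = 1) and a
confidence limit:

    CL = max(5 ppm, (sd/√n) · t((1+0.95)/2, n − 1))   for n ≥ 2,
    CL = 5 ppm                                        for n = 1,

the floor guarding against overconfident sparse entries; a singleton
has no defined standard error, so it takes the floor directly.  Because
lower heights pool more distinct contexts, per-entry spread grows as
height shrinks (asserted on the generated fixture set).  Heights are
stored as separate tables (behaviourally equivalent to a joint key
under longest-match backoff).  The index serializes to a sorted,
versioned TSV that reloads bit-identically.

**Prediction** tries the carbon's height-4 code, then 3, 2, 1; the
first hit supplies (mean, CL, height).  No hit at any height sets a
fallback flag and the carbon scores zero in the NMR judge.

## Judges

**Peak assignment.**  The scoring rule presupposes a pairing of
predicted and experimental shifts, so the pairing is made explicit and
deterministic: carbons and peak slots (a peak with multiplicity m
yields m slots) are grouped by attached-hydrogen class (DEPT); within
each class a linear-sum assignment maximizes the number of within-CL
matches, ties broken by minimal total |δ_pred − δ_exp| (mismatches cost
a constant ≫ any deviation, deviations are scaled to stay ≪ 1, so the
match count strictly dominates).  Carbons without a slot in their class
stay unmatched — the candidate is penalized, not rejected.  A greedy
pairing would make the score depend on atom order; the optimal
assignment does not.

**NMR judge.**  Each assigned carbon earns `P_max` (default 100,
cosmetic — it cancels) if its deviation is within the CL.
NMRcost_norm = matched/carbon_count ∈ [0, 1]; 1 iff every carbon
matches.

**NP-likeness judge.**  Atom signatures are the same environment
encoding at height 3.  Training counts signatures in a natural-product
corpus and a synthetic corpus; a signature's contribution is
ln(p̂_np/p̂_syn) with Laplace smoothing (+1 per signature, + vocabulary
size per total) so corpus-exclusive fragments stay finite.  A
molecule's raw score is the mean contribution over heavy atoms — the
mean (rather than sum) keeps scores size-independent and bounded, in
keeping with the small fixed range such scorers report.  The model
records the min/max raw scores over its training molecules;
normalization is (raw − min)/(max − min) clipped to [0, 1].  Raw scores
are not clamped to any literal range: the recorded extremes are
training-data-dependent, and a degenerate model (min = max) is an
error.  Unseen signatures contribute 0.

**Anti-Bredt judge.**  Bridgeheads are the endpoint atoms of a bridge —
a path of ≥ 2 bonds shared by two SSSR rings.  A violation is flagged
when a bridgehead bears a double bond and every ring through that bond
(through the bridgehead atom itself, for an exocyclic double bond) has
at most 7 atoms; ring sizes through a bond are found by exhaustive
simple-path search, fine at ≤ 15 heavy atoms.  A large (> 7) ring
through the double bond rescues the structure, matching the classical
trans-cycloalkene rationale.  The rule's penalty magnitude is a design
choice here: the default is a hard veto (total cost 0), since small-ring
bridgehead alkenes are not plausible candidates at this problem size;
`bredt_penalty` ∈ (0,1) switches to a multiplicative penalty.

**Combination.**  Cost_total = NMRcost_norm/1 + NPcost_norm/2 in
`nmr_np` mode (weights chosen so NMR agreement dominates: a candidate
matching all carbons with NP 0 still outranks one missing more than
half its carbons with NP 1), or NMRcost_norm alone in `nmr_only` mode.
Higher totals are fitter.  Re-evaluation is bit-deterministic, which
the search exploits by caching fitness per canonical key.

## Evolutionary search

Defaults: population 16, niche expansion to 24, stagnation and niche
windows of 5 generations, termination on a maximum generation count
(default 3000) — the one criterion enabled by default, so a run
traverses and archives isomers for the full budget; maximum fitness,
wall-clock and stagnation criteria are available but off.

Per generation: mutate every individual once (population doubles),
evaluate, round-robin tournament (all-pairs win counting; a strictly
higher total wins a pairing; survivors are the top-`target` by wins,
ties resolved by total then canonical key).  All-pairs comparison makes
the incumbent best a guaranteed survivor, so the best-so-far history is
non-decreasing.  Improvement is strict float inequality — no tolerance.

Niche search: after 5 stagnant generations, 4 single-mutation offspring
of each of the two fittest individuals join the population (16 → 24 —
the arithmetic is forced by the stated sizes).  The expanded population
runs for a 5-generation trial; if still no improvement it contracts
back to 16 by tournament.  Two points the scheme's prose leaves open
are resolved as follows: improvement during the trial ends niche mode
but keeps the expanded population until the next stagnation event; and
the niche trigger can re-fire any number of times in a run — if it
fires while the population is still expanded, the population is first
contracted to 16 so the injection again yields exactly 24.

Ranking: the archive of all distinct constitutions visited is sorted by
total cost descending; equal costs share the better (competition) rank,
ordered within the tie by canonical key for determinism.  If an answer
structure is supplied its rank (or absence) is reported; answer
detection by canonical key is cross-checked against VF2 isomorphism.
Duplicate constitutions may coexist in the population (dedup happens
only in the archive), matching a plain reading of the generational
scheme.  `aggregate_runs` merges archives of several runs of the same
problem, keeping each constitution's best cost, and re-ranks.

## Synthetic data

The fixtures module generates everything the pipeline consumes, so the
package builds and tests offline.

- **Reference shift sets**: hand-curated natural-product-like and
  synthetic-like scaffolds (≤ 15 heavy atoms — the small-metabolite
  regime the tool targets) topped up with random valid structures from
  biased formulas.  Per-carbon shifts are a deterministic base value
  from the carbon's one-sphere class (additive per neighbour
  element/bond-order, spreading methyls ~15 ppm to carbonyls
  ~170–200 ppm) plus Gaussian noise (default sd 2 ppm, a plausible
  within-environment spread).  An exclusion set keeps nominated answer
  structures out of the reference data, mirroring the practice of
  cross-checking test cases out of a shift database before benchmarking.
- **NP corpora**: O-heterocycle/polyol-rich vs halogen/amide-rich sets,
  deliberately skewed so trained log-odds are non-degenerate and
  NP-corpus members score higher on average.
- **Closed-loop problems**: the spectrum is the index's own prediction
  of a known answer (carbons with equal predicted shift and H count
  merge into one peak with multiplicity), so the answer attains
  NMRcost_norm = 1 exactly and whole-pipeline recovery is testable
  without external data.

What this does *not* emulate: real ¹³C shift physics (the additive
model has no ring-current, stereoelectronic or solvent effects), real
natural-product fragment statistics, and spectral artefacts
(overlapping peaks, impurities, wrong DEPT edits).  Passing tests
therefore demonstrate that the machinery — encoding, indexing, backoff,
assignment, scoring, search, ranking — is correct and reproducible, not
that elucidation accuracy on real spectra matches any benchmark; for
real use the reference SDF and corpora should come from a curated
shift database and real NP/synthetic collections.

## Problem file schema

```yaml
formula: C5H10O          # Hill notation, CHNOPS + halogens
peaks:                   # one entry per resonance
  - {shift: 59.0, h: 2, mult: 1}   # ppm, attached H (0-3), equivalent carbons
judges:                  # optional; defaults shown in JudgeConfig
  mode: nmr_np           # or nmr_only
  p_max: 100.0
  bredt_penalty: 0.0     # 0 = veto
ea:                      # optional; defaults in EAConfig
  max_generations: 3000
  seed: 7
answer: answer.mol       # optional V2000 molfile, for rank evaluation
```

Peak multiplicities must sum to the formula's carbon count, and total
attached hydrogens may not exceed the formula's hydrogen count.
Unknown keys are errors in strict mode, warnings otherwise.

## Test-scale choices

The stochastic suites run at sizes chosen to exercise the claimed
behaviour with comfortable margins on a single CPU: closed-loop
recovery uses a 6-heavy-atom answer, a 100-molecule reference set and
100 runs of 200 generations; oracle-agreement uses four exhaustively
enumerable formulas (≤ 5 constitutions) with 25 runs of 60 generations
each; mutation invariants use 10⁴ moves per fixture molecule.
Determinism everywhere is by explicit seeding; reports and model files
format floats with `repr` so reruns are byte-identical.

## Known limitations

- Kekulé-form identity can split aromatic species (above).
- The environment encoder re-expands ring revisits rather than marking
  ring closure, so very symmetric fused polycycles may receive longer
  codes than a closure-marking scheme would give; identity and
  determinism are unaffected.
- The mutation kernel proposes uniformly over applicable moves; it has
  no bias toward chemically sensible intermediates, which is the main
  cost of search efficiency at larger formulas.
- Proton spectra, 2D-NMR constraints (HMBC/HSQC/COSY) and charge- or
  stereo-bearing targets are out of scope.
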