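# Methods

## The search model

`tangoplan` hosts a value-guided best-first AND–OR search. Molecules are
OR nodes (solved by any one disconnection), reactions are AND nodes
(solved only when all precursors are solved). Each iteration selects the
unexpanded, non-purchasable molecule lying on the cheapest estimated
route through the current graph, asks the single-step policy for
disconnections, grafts them in, and re-estimates. A molecule node's value
is 0 if purchasable, the frontier cost if unexpanded, otherwise the
minimum over child reactions of (reaction cost + Σ precursor values).
Route estimates propagate top-down from the root: the estimate through a
reaction equals the parent's estimate with the parent's value replaced by
that reaction's branch cost; estimates only grow as they descend, so a
Dijkstra-style pass computes them exactly.

Guidance enters **only** at the frontier: an unexpanded molecule `m` is
priced `base(m) + k·(1 − TANGO(m, sm*))`. Expanded nodes take their value
from the graph, so guidance never distorts the cost of work already done.
An alternative would be to fold the similarity term into back-propagated
values as well; frontier-only guidance was chosen because it preserves the
semantics of a value function (an estimate of *remaining* cost) and makes
`k = 0` reduce bit-for-bit to unguided best-first search — a property the
test suite checks against an independent reimplementation.

The cost is combined additively, `base + k·(1 − score)`, rather than by
subtracting `k·score`: the two are ordinally equivalent for fixed `k`, and
the additive form keeps all node costs non-negative, which keeps route
costs monotone under extension and simplifies minimum-cost extraction.

Reaction cost is `−log(policy confidence)` clamped to `[1e−3, 10]`; with
uniform template priors route cost is then proportional to reaction count.

Termination: the search stops at the first *constrained* solve (a solved
route whose leaves are purchasable and include sm\*), or on budget
exhaustion; `stop_on_first_solve=False` exhausts the budget and extracts
the best route at the end (used for best-route and oracle-equivalence
studies). Every policy call — including ones returning no proposals —
consumes one unit of the expansion budget, since each is a real model
invocation. sm\* is always treated as purchasable.

Determinism: frontier ties break on (rounded estimate, insertion order,
canonical SMILES); route-cost ties break on the lexicographically smallest
serialized tree. Identical configuration and seed give byte-identical
outputs.

### Route extraction with a preference

Among solved subtrees the extractor returns the minimum-cost route whose
leaves include sm\* when one exists, otherwise the overall minimum-cost
route. The sm\*-carrying variant is computed by a second dynamic program
in which exactly one precursor branch per reaction must carry sm\*.

## The TANGO cost

* **Tanimoto term** — Jaccard similarity of binary Morgan (circular)
  fingerprints, radius 2, 2048 bits. These are the field-standard
  defaults; both are configurable.
* **FMS term** — heavy atoms in the maximum common substructure (MCS)
  of candidate and sm\*, divided by the heavy atoms of the *candidate*
  (the precursor being scored). The denominator choice makes the score 1
  exactly when the candidate is entirely contained in sm\*'s shared
  substructure — e.g. benzene scored against toluene gives 6/6 while
  toluene against benzene gives 6/7. A config switch (`candidate | sm |
  max`) exposes the other normalisations.
* **MCS settings** — element-sensitive atoms, order-sensitive bonds,
  ring bonds match only ring bonds, 1 s timeout per pair. The search is
  atom-maximizing (not RDKit's default bond-maximizing) because the score
  counts atoms. A timeout returns the best-so-far count flagged
  `timed_out` instead of raising, so a pathological pair can never stall
  a search. "Fuzzy" relaxations (element-insensitive atoms,
  order-insensitive bonds) are exposed as flags.
* **Weights** — `k ≥ 0` scales the starting-material pull against the
  base value function; default 25. `c ∈ [0,1]` is the FMS weight; default
  0 (pure Tanimoto), with 0.3 as the blended setting. With `c = 0` the
  expensive MCS is skipped entirely.
* **Caching** — breakdowns are cached per canonical-SMILES pair for the
  lifetime of one search object, so the MCS for a pair is computed at
  most once.

The cost object also exposes a pairwise signature `cost(m, sm)` so it can
be dropped into any framework expecting a molecule-pair distance.

## Single-step policies

The policy contract is minimal — product in, ordered scored precursor
sets out; one call is one budget unit. Two offline policies ship:

* **TemplatePolicy** applies retro SMARTS transformations with RDKit.
  Scores are template priors (uniform by default); proposals are
  deduplicated by canonical precursor set and ordered by (descending
  prior, lexicographic precursor SMILES) for bit-reproducibility.
  Fragments that fail sanitization invalidate the whole proposal;
  self-loop proposals are dropped.
* **TabularPolicy** looks reactions up in an explicit table — the policy
  used with synthetic networks.

## The synthetic network generator

The generator manufactures constrained problems with known answers. A
planted linear route is grown *forward* from a starting material chosen
from a small pool of 6–9-heavy-atom molecules: each step attaches a
small fragment (C/N/O chains) by a single bond at a random free valence.
Read backwards this is a retrosynthesis whose deepest, heaviest leaf is
sm\* — the same rule used to extract (target, sm\*) pairs from real route
datasets (longest root-to-leaf path, then the leaf with the most heavy
atoms). Each growth step must strictly *decrease* fingerprint similarity
to sm\* (steps that do not are resampled), so the planted route carries an
exactly monotone guidance signal; this is the regime in which
similarity-guided search should provably help, and the diagnostics tests
rely on it.

Decoy disconnections are grafted onto every planted intermediate:
`branching − 1` side chains of 1–3 reactions, ending with probability
`decoy_rate` in a dead end (non-purchasable, no reactions) and otherwise
in a purchasable decoy leaf drawn from a pool disjoint from the planted
leaves. Decoy routes are therefore solvable but never constrained —
the planted route is the unique route containing sm\* (verified by
exhaustive enumeration in the tests). Every reaction in a generated
network carries the same confidence (0.8), so neither search arm can read
the planted route off the scores; guided and unguided search differ only
through the node cost.

Defaults used by the benchmark and the acceptance script: depth 4,
branching 3, decoy rate 0.4, 20 networks — small enough to enumerate
exhaustively, large enough that the unguided baseline needs roughly twice
the expansions of the guided search. `mode="abstract"` produces
structure-less token molecules plus a planted-distance oracle cost, for
chemistry-free search-logic tests.

What the generator does *not* emulate: realistic reaction feasibility,
failure of the single-step model to propose the true disconnection,
convergent (branched) ground-truth routes, and the scale of real
building-block catalogues. Passing benchmarks here show the guidance
mechanics work when the similarity signal is informative; they do not
predict solve rates on real route datasets, where the signal is noisy.

## Metrics and diagnostics

* **Constrained solve rate** (%) per expansion-budget checkpoint. One
  search per (problem, cost setting) runs at the largest budget; the
  iteration of first solve gives the solve state at every smaller
  checkpoint (verified against independently capped runs).
* **N̄** — mean expansions per target; unsolved problems contribute their
  full budget.
* **Route length** — reactions on the longest root-to-leaf path; averaged
  over the subset solved by *all* compared settings.
* **Monotonicity** — Spearman ρ and Kendall τ-b (tie-corrected; distances
  are heavily tied) between ground-truth synthetic distance to sm\* and
  cost, along root→sm\* paths of ground-truth routes.
* **Consistency** — mean over distance groups of the coefficient of
  variation (population σ / mean). Groups with mean ≈ 0 (e.g. the TANGO
  cost at distance 0 is exactly 0) are excluded and the exclusion count
  reported, since CV is undefined there.
* **Granularity** — "mean distribution overlap" between adjacent distance
  groups, implemented as the separation ratio (σᵢ + σⱼ)/|μᵢ − μⱼ|
  averaged over adjacent pairs: below 1 the groups are about a standard
  deviation apart; larger values mean blur. This statistic is unbounded
  above, matching its use as a lower-is-better consistency measure. A
  classic [0,1] histogram overlap coefficient is available under
  `overlap_method="histogram"`.

## Numerical choices and degenerate inputs

* Frontier tie-breaks round estimates to 9 decimals before comparing, so
  float noise cannot reorder expansions across platforms.
* Cycle handling: a proposal whose precursor is an ancestor of the
  product is discarded at insertion; the value pass additionally guards
  against cycles arising through shared subgraphs.
* A purchasable target that is not sm\* is still expandable (a length-0
  "route" cannot satisfy the constraint); a target equal to sm\* returns
  a length-0 route with 0 expansions.
* Molecules with no heavy atoms are rejected by the FMS score
  (`DegenerateMoleculeError`); unparseable SMILES raise `ParseError` at
  the boundary so the search core never sees invalid structures.

## Known limitations

* The base value function is a constant or a heavy-atom heuristic, not a
  trained network; the seam accepts any callable.
* FMS "fuzziness" defaults to strict matching; the relaxed options are
  exposed but unvalidated against any external definition.
* Benchmark problem sizes are deliberately small (tens of molecules per
  network) so that exhaustive enumeration can serve as a ground-truth
  oracle in the test suite.
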