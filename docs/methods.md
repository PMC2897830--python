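# Methods

This note documents the procedure implemented in `domcons`, its
assumptions, the tunable parameters, the design choices made where the
procedure admitted more than one reading, and what the synthetic fixtures
do and do not emulate.

## Data model

A chain is a dense 1-based integer residue coordinate. Each method's
assignment partitions (part of) the chain into domains; a domain is one or
more non-overlapping contiguous fragments, so discontinuous domains are
first-class. Residues between domains may be unassigned — several real
parsers leave linkers out — and unassigned residues simply belong to no
domain. PDB author numbering (with insertion codes) is collapsed onto the
sequential coordinate at parse time; for DSSP input the full mapping is
retained on the annotation. For CATH Domall input only segment *endpoints*
are available, so the numeric author numbers are used directly as the
coordinate; this is exact for chains whose author numbering is sequential
(the vast majority) and the insertion-code columns are parsed and
tolerated. No minimum chain length is enforced; chains under 40 residues
log a warning.

## Pairwise agreement

Agreement between two assignments A, B of the same chain requires:

1. equal domain counts;
2. after sorting both by N-terminal fragment start, equal fragment counts
   in each positionally paired domain;
3. for every paired domain, `|A_i ∩ B_i| ≥ 0.8·|A_i|` **and**
   `≥ 0.8·|B_i|`;
4. the same bidirectional 80% test for every positionally paired fragment.

Choices made here, with rationale:

* **Bidirectional overlap.** Requiring the intersection to cover 80% of
  *each* partner keeps the relation symmetric and is the strictest
  consistent reading of "80% of the residues the same". A one-sided test
  would make agreement depend on comparison direction.
* **Both domain- and fragment-level tests.** Whether the 80% rule binds
  the domain's residue set, each fragment, or both is underdetermined; both
  are enforced by default (strictest), and the fragment-level test can be
  switched off (`Parameters.fragment_level_check=False`).
* **Positional pairing.** Domains are paired i-th to i-th after canonical
  ordering. Counts already match and domains are residue-disjoint, so
  positional pairing is deterministic and almost always what maximal
  overlap would choose; an optimal-overlap pairing is available behind
  `Parameters.optimal_domain_matching` for robustness studies.
* The threshold comparison is inclusive (`fraction ≥ 0.80`), so 79/100
  fails and 80/100 passes.

The relation is reflexive and symmetric but **not transitive**: boundary
drift can accumulate (A≈B, B≈C, A≉C; the test suite pins a witness).
Greedy grouping is therefore order-dependent on non-transitive instances;
the processing order is fixed (`Parameters.method_order`) to keep results
deterministic, and on instances where the relation *is* transitive the
groups provably equal the connected components of the agreement graph
(property-tested against a brute-force oracle).

## Consensus

Methods are processed in order; each joins the first existing group whose
*representative* (the group's founding method) it agrees with, else founds
a new group. Scoring:

* simple: `R(G) = 100·|G| / n_methods`;
* weighted: `R(G) = 100·Σ_{m∈G} w_m / Σ_{m present} w_m`.

The weighted combination formula is the minimal generalization of
"percentage of contributing methods": it reduces exactly to the simple
score under equal weights (tested), and group scores in both modes sum
to 100. Weights are renormalized over the methods actually present, so a
method that produced no output drops out of the denominator.

Decision rule: the top group wins if `R ≥ consensus_threshold` (40%). If
the runner-up is strictly within `near_tie_window` (10 points) of the top,
both are reported (`tied_consensus`); a runner-up below 40% can be
co-reported this way — the report flags this case — because the tie rule
is stated on the distance to the top score, not on the floor. At most two
groups are ever reported. Ties in reliability break by group creation
order.

## Weight rules

Base weights are prior per-method success rates (percent of correctly
assigned chains on a balanced, mostly multi-domain benchmark): PDP 84.4,
NCBI 81.9, DomainParser2 78.1, DDomain 76.5, PUU 74.0, DHcL 68.3,
Dodis 40.0. Nine context rules then adjust them, in fixed order, each at
most once, stacking multiplicatively:

| rule | condition | effect |
|------|-----------|--------|
| R1 | PDP and NCBI both predict ≥ 4 domains | DomainParser2 × 0.9 |
| R2 | PUU predicts more domains than PDP **and** NCBI | PUU × 0.9 |
| R3 | PDP predicts ≥ 5 domains | NCBI × 0.9 |
| R4 | ≥ 3 methods have a fragmented domain | each method without one × 0.9 |
| R5 | neither PDP nor NCBI has a fragmented domain | each method with one × 0.9 |
| R6 | all-α chain, PDP/NCBI domain counts differ | PDP × 1.1 |
| R7 | all-β chain, counts differ | PDP × 1.1 |
| R8 | all-β chain, counts equal | PDP and NCBI × 1.1 |
| R9 | α-β chain, counts equal | each method outside PDP's agreement group × 0.9 |

Interpretive choices: "reduced by 10%" is multiplicative (×0.9), not a
10-point subtraction — absolute subtraction could drive Dodis's weight
negative after stacked rules; "DP" in R1 denotes DomainParser2 (PDP is
always spelled out); R9's "disagree with PDP and NCBI" is operationalized
as *not in PDP's agreement group*, using the full agreement criterion
rather than bare counts, since the rule only fires when PDP and NCBI
already agree on the count. Rules referencing absent methods are skipped;
a method with no base weight gets 50 with a logged warning.

**Structure class.** Among residues inside helix/strand elements, the
chain is all-α if the strand share is ≤ `ss_class_minor_fraction`
(default 0.05), all-β if the helix share is, α-β otherwise, and irregular
with no elements at all. The 5% tolerance is a design choice: "all
alpha-helix" admits no explicit slack, but real DSSP output of α proteins
routinely contains an isolated bridge or short 3-10 turn.

## Boundary / secondary-structure analysis

Boundaries are the fragment start/end residues of each method's domains,
excluding the chain termini (an N-terminal domain start is not a
boundary). Residue-level boundaries were chosen (rather than inter-residue
gaps) because the cut rules are phrased in residues. Endpoints of one
method falling on the same residue are deduplicated per method
(configurable, `Parameters.dedupe_shared_boundaries`); abutting fragments
of the same domain are kept as given, never merged, since a parser may
deliberately report them.

Cut rules: a helix (maximal run of DSSP H/G/I, terminated at chain
breaks) is cut by a boundary at positions `start+2 … end−2`; a strand
(run of E; isolated bridges B excluded) at `start+1 … end−1`. Hence a
helix of length ≤ 4 and a strand of length ≤ 2 can never be cut. The
statistics count each boundary at most once per element kind; the
rendered context track shows *untrimmed* element spans, matching the
distinct purposes (measurement vs display).

## Synthetic fixtures

`domcons.simulate` plants a true partition (contiguous domains ≥ 20
residues; lengths 20 + a multinomial share of the excess) and perturbs it
per method: each internal boundary shifts uniformly in ±jitter; with the
given probabilities one adjacent pair merges, one domain splits at a
random interior point, or one domain is fragmented — its middle third is
donated to a neighbouring domain (or left unassigned for a single-domain
chain), mirroring how real parsers produce discontinuous domains and
unassigned linkers. Invalid draws are retried up to 100 times, then the
truth is returned with a warning. Per-method RNG streams are derived by
SHA-256 hashing of (seed, method name), so output is independent of dict
iteration order and byte-identical across runs of the same seed.

For randomized simulation studies the per-method specs draw jitter from
U{0..10} residues and merge/split/fragment probabilities from U(0, 0.4) —
moderate disagreement: enough to split the methods into several groups on
many chains while leaving a winning coalition on most. Randomized suites
use 500 runs of 7 methods on 300-residue chains with 1–4 true domains;
this exercises every grouping outcome (unanimity, ties, no consensus) in
seconds.

What the generator does **not** emulate: the error profile of any specific
published parser, correlated errors between methods (real parsers share
failure modes on complex topologies), boundary uncertainty that scales
with domain size, or disagreement concentrated at discontinuous domains.
Passing tests therefore demonstrate the correctness of the consensus
arithmetic and its invariants under controlled disagreement — not the
field accuracy of any consensus on real PDB chains, which depends on the
real methods' outputs.

## Numerical and degenerate-input choices

* Overlap fractions are exact small-integer ratios; comparisons use plain
  `≥` with no epsilon.
* Reliability sums are asserted to 1e-9; scores are reported unrounded and
  rounded to 1 decimal only for display.
* Validation (`validate_assignment`) never raises — it returns a list of
  named violations so file loaders can report all problems; operations
  that *require* validity (`canonical_order`, agreement) raise
  `ValidationError` carrying those violations. Unsorted fragments are the
  one violation `canonical_order` repairs rather than rejects.
* Empty residue sets, empty assignment sets, empty annotations and
  out-of-chain ranges are errors; a method with zero boundaries reports
  cut fractions of 0 with an explicit flag rather than NaN.
* The DSSP writer emits the classic fixed-column layout (zero-filled
  energy/angle fields) so fixtures round-trip through the same standard
  parser used for real files.

## Known limitations

* Domall input cannot be renumbered through insertion codes without the
  residue census; author numbers are used as-is (see Data model).
* Greedy grouping on non-transitive instances depends on the method
  order; this matches the deterministic fixed-order design but means the
  reported consensus can differ from a maximum-agreement clustering.
* Per-boundary (rather than per-chain) reliability is out of scope.
* Multi-chain/quaternary domains and alternate conformations are not
  modelled.
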