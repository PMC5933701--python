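# Methods

## Representation

An evidence map is a directed graph. A node is a biological phenomenon
identified by three free-text properties: What (the entity), Where
(location) and When (temporal context). Identity is the whitespace-
collapsed, case-folded triple; Where/When may be empty but still count,
so the same protein measured in two compartments is two nodes. No
ontology is enforced — the representation is meant for personal
curation, where users keep their own vocabularies consistent.

An empirical edge Agent → Target aggregates every experiment recorded
for that ordered pair (the opposite direction is a separate edge).
An experiment is (class, outcome) plus metadata: free-text method
descriptions, an optional statistical test and p-value (stored, never
scored — reporting conventions vary too much across fields for p-values
to be combined honestly), a source identifier, and optionally a second
Agent for two-Agent interventions. Two-Agent experiments count only
toward their primary Agent → Target edge; any mechanism among the three
entities is expressed by user-entered hypothetical edges, since no
formal multi-node experiment representation is defined here.
Hypothetical edges assert a relation (E, I or N) without evidence; they
carry no score and no experiment symbols.

## The evidence calculus

The four experiment classes C = {↑, ⌀↑, ⌀↓, ↓} and three relations
R = {E, N, I} define a 4×3 count table x[c, r], where each experiment's
supported relation follows from its class and outcome: no change in the
Target always supports N; otherwise agreement between the Agent's
direction and the Target's change supports E, disagreement supports I.

Per class, θ_c ~ Dirichlet(α_c) prior with Multinomial(x_c) likelihood
gives the posterior mean

    E[θ_{c,r}] = (α_{c,r} + x_{c,r}) / (Σ_r α_{c,r} + n_c),

implemented directly (no sampling — only the posterior expectation
enters the score). The default α ≡ 1 is Laplace add-one smoothing and
encodes the axiom that no experiment class is a priori preferred; a
field that trusts, say, interventions more may raise that row's weight.

The convergence vector θ̄ averages each relation's component over the
four classes. The edge's relation is θ̄'s unique argmax; its score is
(max θ̄ − θ₀)/(1 − θ₀) with baseline θ₀ = 1/3 at zero evidence. With
non-uniform priors θ₀ is generalised to the maximum component of the
zero-evidence θ̄, keeping the score exactly 0 before any experiment.
Scores live in (0, 1); each class can contribute at most 0.25, reached
in the limit of infinitely many agreeing results; convergent evidence
across classes therefore always outweighs repetition within one class.
The score measures evidential support, not effect size.

Ties in θ̄ assign neither relation nor score (the edge renders with a
diamond arrowhead). Components are compared with absolute tolerance
1e-9: with integer counts true ties are exact rationals, so the
tolerance only absorbs float noise; tests verify 1e-12 agreement with an
exact-fraction oracle.

## Merging, querying

Merging pools experiments per directed node-key pair and re-scores the
pooled table — scores are never averaged across sources, because the
calculus is count-based and pooling is exactly how independent reports
should combine. Every global edge keeps (map_id, experiment_id)
provenance, and hypothetical assertions attach with provenance without
touching the counts. Node keys are either the full What/Where/When
triple or What alone ("what_only"), which collapses context variants of
one entity into a single node for coarse overviews. Merging is
deterministic and order-independent; provenance lists are kept sorted.

Queries match a term as a case-insensitive substring of any node field,
then expand breadth-first up to a hop limit over edges passing an
inclusive [score_min, score_max] band. Unscored edges are outside the
band's domain: indeterminate empirical edges pass only with
include_unscored, hypothesis-only edges only with include_hypothetical.
Edges are filtered before traversal (an edge outside the band neither
appears nor carries the search onward); the alternative — bounding hops
first, filtering after — would surface filtered-out intermediaries and
was rejected. BFS order is fixed by sorted node keys so output is
reproducible. The connectivity profile counts nodes first reachable
within k undirected traversals from a seed set, seeds excluded.

## Conflict detection

A No-connection edge asserts independence of its endpoints; the stored
direction is ignored because independence is orientation-free. A simple
directed pathway of E/I edges between the same endpoints (either way,
length ≤ max_path_len, default 4) asserts dependence of determinate
sign — either polarity conflicts, since both imply dependence. Each such
pathway is reported with its sign (product of edge signs), its minimum
edge score and the N edge's score; the two are reported separately
rather than combined, as no principled severity weighting exists.
Defaults: min_score 0 (any scored edge qualifies), hypothetical edges
excluded; indeterminate edges never enter pathways. Conflicts are
purely structural — background conditions that might reconcile the
findings are not represented — so reports are leads for re-reading the
sources, not verdicts.

Forbidden causation inverts the same logic: (X, Y) is reported when
some B is independent of X while Y already reaches B through a signed
pathway (or Y is B), so any hypothesised cause X⇝Y would complete a
conflicting pathway. Template matching re-finds a conflict motif (≤ 6
nodes, relation-labelled edges, N edges matched in either orientation)
anywhere in a map via subgraph monomorphism; bindings are valid
regardless of node identities.

## Serialization

JSON with sorted keys and an explicit schema_version is canonical.
Documents embed a derived block (per-edge relation, score, symbols) for
human readers, but derived fields are never trusted on load: they are
recomputed, compared, and on mismatch a warning is emitted and the
recomputed value wins. Layout/coordinates are not serialized. DOT and
GraphML exports carry the three display lines per node and the edge
decorations (arrowhead by relation, score, class symbols; hypothetical
edges dashed and unlabelled). Class symbols appear in display fields;
machine fields use ASCII names.

## Synthetic maps

The fixture generator emulates a curated single-article map: a random
simple directed graph whose empirical edges each receive a designated
true relation, with experiment outcomes supporting that relation with
probability agreement_prob and one of the other two relations
otherwise. Defaults — 10 nodes, 13 empirical and 3 hypothetical edges,
experiments-per-edge distribution {1: 0.75, 2: 0.2, 3: 0.05} (mean
≈ 1.3), uniform class mix, agreement_prob 0.9, and a 0.15 chance a node
reuses an earlier What with a different Where — approximate observed
curation practice, where large collections average roughly 1.3
experiments per edge and 10–13 edges per article. Output is
byte-identical for a fixed seed, and all generation parameters are
recorded in the map's metadata.

What the generator does not emulate: real curation noise (ambiguous
class assignment, annotator disagreement), heavy-tailed node degree in
large literatures, correlated evidence (the same lab repeating its own
design), or meaningful free-text fields. Passing tests therefore
establish the calculus's arithmetic and the graph machinery, not the
fidelity of any particular curated corpus.

## Problem sizes and numerics

All scoring quantities are desk-scale and exact to double precision;
tests compare the incremental implementation against an exact-rational
brute-force oracle on 1,000 random evidence multisets, and round-trip /
merge-order properties run over 1,000 seeded fixtures of 5-node maps.
Scores are computed and stored unrounded; display rounds to 4 decimal
places (0.13125 prints as 0.1313).

## Known limitations

- Edges record experimental results, not a formal causal graph: no
  distinction between direct and ancestral relations, no d-separation
  reasoning.
- p-values and effect sizes never enter the score.
- Two-Agent experiments are first-class records but contribute to only
  one edge.
- What/Where/When free text means node identity is only as consistent
  as the curator's vocabulary.
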