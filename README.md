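# evimap

Causal evidence maps for biologists: directed graphs of experimental
findings and hypothetical assertions, with a Bayesian calculus that
scores how convergent and consistent the evidence for each causal
connection is.

## The problem

A biologist synthesising a literature must weigh many experiments of
different kinds that bear on the same putative connection — does CREB
activity in the lateral amygdala affect the number of Arc-expressing
neurons?  `evimap` represents each phenomenon as a node identified by
three free-text properties (*What* / *Where* / *When*) and each directed
Agent → Target edge as the accumulated evidence from four classes of
connection experiments:

| class | symbol | meaning |
|---|---|---|
| Positive Intervention | ↑ | Agent experimentally increased, Target measured |
| Negative Intervention | ↓ | Agent experimentally decreased, Target measured |
| Positive Non-intervention | ⌀↑ | Agent observed to increase, Target measured |
| Negative Non-intervention | ⌀↓ | Agent observed to decrease, Target measured |

Each result supports one of three relations — Excitatory (E, same-direction
change), Inhibitory (I, opposite-direction change) or No-connection (N,
no change in the Target).

## The scoring model

For each experiment class *c* the relation probabilities get a Dirichlet
prior (all ones by default — Laplace add-one smoothing) with a
multinomial likelihood over the observed counts *x<sub>c,r</sub>*, giving
posterior means

E[θ<sub>c,r</sub>] = (α<sub>c,r</sub> + x<sub>c,r</sub>) / (Σ<sub>r</sub> α<sub>c,r</sub> + n<sub>c</sub>).

Averaging each relation's component across the four classes yields the
convergence vector θ̄.  The edge's relation is θ̄'s unique argmax and its
score is

score = (max θ̄ − θ₀) / (1 − θ₀),  θ₀ = 1/3,

in (0, 1).  Repeating one class raises the score by diminishing amounts
(consistency); spreading agreeing results across classes raises it more
(convergence, which deliberately carries greater weight).  Ties assign
neither relation nor score.  Conflicting results lower the score of the
still-dominant relation.

On top of the per-source maps the package merges many maps into a global
graph (pooled counts re-scored, full provenance per edge), answers
term/pair/neighborhood queries with hop limits and score filters, and
detects structural conflicts: a signed (E/I) directed pathway between two
nodes that an independence (N) finding says are unconnected cannot
coexist with that finding, and the detected motif can be re-matched
anywhere as a template.

## Worked example

Two Positive Interventions of CREB and one Negative Intervention, all
producing no change in the number of Arc neurons:

```sh
$ evimap score --csv worked.csv
edge:     CREB -> number of Arc neurons
relation: NO_CONNECTION
score:    0.1625  (full precision 0.16249999999999998)
counts (pseudocount 1 included):
        B+   B0   B-
    ↑    1    3    1
   ⌀↑    1    1    1
   ⌀↓    1    1    1
    ↓    1    2    1

$ evimap trajectory --csv worked.csv
k       class             outcome    relation       score
1       POS_INTERVENTION  NO_CHANGE  NO_CONNECTION  0.0625
2       POS_INTERVENTION  NO_CHANGE  NO_CONNECTION  0.1000
3       NEG_INTERVENTION  NO_CHANGE  NO_CONNECTION  0.1625
```

The first experiment contributes 0.0625; the second, consistent one in
the same class adds only 0.0375; the third opens a new class and adds a
fresh 0.0625.  Adding a conflicting fourth result (a Positive
Non-intervention with an increase) drops the score to 0.1313 — the
evidence for No-connection still dominates, but less convincingly.

Other subcommands: `merge` (global map with provenance), `query`
(term/pair search with `--max-hops`, `--score-min/--score-max`),
`conflicts` (pathway-vs-independence report), `export` (DOT/GraphML),
`fixture` (seeded synthetic maps), `add`, `validate`.  The same
operations are available as library functions (`evimap.score_edge`,
`evimap.merge_maps`, `evimap.detect_conflicts`, ...).

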