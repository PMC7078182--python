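# Methods

## Model overview

The package simulates social-network formation in two stages: a demographic
stage that produces a kin network, and a behavioural stage that completes each
agent's contacts with chosen friends. The quantities of interest are the
friend ratio λ (share of edges that are non-kin) and the clustering
coefficient χ of the combined network, studied as fertility varies.

## Kin-network generator

The kin graph's defining rule is relational: two egos are adjacent iff their
grandparent sets intersect in at least two identifiers (full siblings share
four, first cousins exactly two). The pedigree that realises this rule is the
minimal three-generation structure:

1. **G0** — founder couples; couple *c* is the identifier pair (2c, 2c+1).
2. **G1** — each founder couple draws an offspring count from the family-size
   law; G1 individuals are paired into monogamous couples by a random greedy
   matching that excludes own siblings. Sex is not modelled: any two unpaired
   non-siblings may form a couple, since sex plays no role in the edge rule.
   Individuals left without a feasible partner (odd counts, all-sibling
   residues) remain childless.
3. **G2** — each G1 couple draws offspring; these are the egos. An ego's
   grandparent set is the union of its two parental couples' founder pairs.

Family-size laws (mean = fertility in every case): `binomial` —
Binomial(8, fertility/8), the default; `poisson` — Poisson(fertility); and
`fixed` — the constant integer, used by tests because it has closed-form
consequences (one child per couple ⇒ no siblings, no aunts/uncles, hence no
cousins and an edgeless kin network).

The founder pool is sized so the expected ego count is 1.2 × the requested
cohort (expected egos per founder couple ≈ f²/2), capped at 40 × n couples;
if a draw falls short the pool is enlarged by ×1.6 up to eight times before
the generator raises, so infeasible parameter combinations fail loudly in
bounded time. The surplus cohort is uniformly subsampled to exactly n egos,
keeping induced edges — the cross-section view of a larger population, which
preserves the fertility → kin-degree link. Edges are found by grouping egos
on shared grandparent identifiers, which is near-linear in cohort size.

What the generator does *not* emulate: mortality, divorce and remarriage,
overlapping generations, assortative mating, or kin beyond first cousins.
Passing tests therefore speak to the modelled mechanism — kin availability
scaling with fertility — not to the demography of any real population.

## Friend-choice stage

All three algorithms share the loop: find the eligible set X of agents with
degree < ν on the current combined adjacency; pick the minimum-degree member
xi (ties uniform at random, or lowest-id under `tiebreak="index"` for
hand-traceable runs); pick a partner xj from X, excluding xi and agents
already connected to xi; add the edge. The candidate restriction to
unconnected pairs is deliberate: ranking over all of X could make the argmin
an existing edge and deadlock the loop, while the termination condition
clearly intends unconnected pairs. Likewise the pair-ineligibility test uses
the *combined* adjacency b, not the kin matrix alone — a friend edge makes a
pair just as ineligible as a kin edge.

Costs: homophily uses |Δφ|; the weighted variant |Δφ|^p · d^q with defaults
p = 2, q = 0.5 — trait distance is punished with increasing intensity while
marginal graph distance matters less far from the ego. Graph distances are
recomputed by breadth-first search from xi at every selection, because the
network the distance is measured on grows during the run. Pairs in different
components get a sentinel distance of n (≥ any finite shortest path), keeping
cross-component friendships possible in the kin-fragmented (low-fertility)
regime; the sentinel is configurable via `CostParams.unreachable_distance`.

Termination bookkeeping: once an agent finds no partner, it never will —
degrees only grow, so the eligible set only shrinks and adjacency only gains
edges — hence exhausted agents are set aside permanently rather than
re-polled each pass. This bounds the loop by n·ν/2 edge additions plus n
exhaustions; the implementation guards at n·(ν+1) iterations and raises
beyond it, which would indicate a bookkeeping bug, not a hard instance.
Agents whose kin degree already meets ν never enter X and keep all kin edges
even though their degree exceeds the target.

## Metrics

λ = 1 − Σa/Σb on symmetric sums. χ comes in three variants because the
degree-target normalisation of the triple-sum statistic admits more than one
reading: the numerator ΣᵢΣⱼΣₖ b_ij b_ik b_jk (= 6 × triangle count, computed
as trace(b³)) over n²ν(ν−1) (`chi_nu_nsq`), over nν(ν−1) (`chi_nu`), and the
standard average local clustering coefficient over realised degrees
(`chi_local`, agents of degree < 2 contributing 0, via networkx). The single-n
variant is the interpretable per-agent normalisation — a ν-regular network of
closed cliques scores 1, whereas the n² form cannot exceed 1/n of that — so
`chi_nu` is the default reported χ while the n² form is retained for
fidelity. Shape claims (u-shape, lift, monotonicity) are stated on
`chi_local` because it is definition-independent: it uses realised degrees,
so agents ending below ν do not deflate it. An exhaustive triple-enumeration
triangle oracle (guarded to n ≤ 200) backs the identity tests.

## Sweep design and statistics

One sweep iterates a fertility grid × replicates; per replicate the kin
network and traits are drawn once and every algorithm runs on its own copy —
a paired design that removes kin-draw variance from algorithm contrasts.
Per-run seeds derive from the base seed through `numpy.random.SeedSequence`
spawn keys of (level, replicate, algorithm), so any subset of the sweep is
reproducible in isolation and streams are mutually independent.

Curve statistics bin records by λ into 10 equal-width bins over the realised
range. A curve is called u-shaped when the bin minimising mean χ is interior
and both end bins exceed it by more than 2 pooled standard errors (within-bin
variance pooled across bins, so sparse bins still get an error estimate).
The random baseline's monotone decline is measured by the Spearman
correlation of bin means against bin centres; the weighted-vs-homophily
"shifted up" comparison counts shared λ bins where the weighted mean χ is at
least the homophily mean.

## Default parameters and problem sizes

| parameter | default | meaning |
|---|---|---|
| n | 500 | egos per network (full scale) |
| ν | 60 | degree target, chosen so almost all egos have fewer relatives than contacts |
| φ bounds | [0, 100] | uniform trait support |
| trait/distance exponents | 2, 0.5 | weighted-cost shape |
| fertility grid | 12 levels, log-spaced [1, 8] | spans realised λ ≈ 0.3–1.0 at full scale |
| replicates | 10 per level | paired across algorithms |

The tests and the acceptance script run the desk-scale configuration
(`reduced_scale_config`): n = 200, ν = 20, 12 levels log-spaced on [0.5, 8],
10 paired replicates. The grid's lower bound drops below the full-scale 1
because λ ≈ 1 − (mean kin degree)/(2ν)·…; with the smaller ν the kin share of
edges is larger at any fertility, and sub-replacement levels are needed for
the realised λ range to reach ≈ 0.97 and populate the high-λ comparison, as
the full-scale grid does at ν = 60. The robustness runs use ν = 30 with cost
exponents (2, 0.5) and (1, 1) at 6 replicates per level. These sizes are the
package's desk-scale study conditions; the full n = 500, ν = 60 configuration
is the `SweepConfig` default and runs unchanged, just longer.

## Numerical and design notes

- Tie-breaking everywhere is uniform-random from the run's seeded stream;
  `tiebreak="index"` gives lowest-id determinism for worked examples. Cost
  ties are broken on exact float equality, which in practice only occurs in
  degenerate fixtures (equal traits), since traits are continuous.
- λ is undefined on an edgeless network and raises rather than returning a
  sentinel.
- `detect_ushape` requires ≥ 5 non-empty λ bins; fewer indicates the sweep
  did not span enough of the transition to classify a shape.
- External kin networks load from two-column edge-list CSV; their agents get
  synthetic placeholder grandparent sets (the edge rule is taken on trust),
  flagged as such in the loader's docstring.

## Known limitations

- The pedigree is a declared stand-in for a full population-history
  simulation: three generations, no mortality or migration mechanics. The
  fertility → λ mapping is therefore qualitative, not calibrated to any
  census.
- A single scalar trait; real homophily is multi-dimensional and partly
  categorical.
- No edge decay or maintenance dynamics: friendships, once formed, persist
  for the run.
- χ comparisons across ν values should use `chi_local`; the ν-normalised
  variants are not comparable across different degree targets by
  construction.
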