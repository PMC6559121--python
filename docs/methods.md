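# Methods

## The operational network

All statistics run on an undirected, unweighted, simple, connected graph of
opaque protein identifiers. `build_network` fixes the order of operations:
self-loops and duplicate/reciprocal pairs are removed first, then the
subcellular-location filter, then the largest connected component. A protein
is removed by the location filter only when it carries at least one
compartment annotation and *all* of its annotations fall inside the excluded
set (default: nucleus, mitochondrion, peroxisome, with a synonym list);
unannotated proteins are always kept, since absence of annotation is not
evidence of exclusive localization. Filtering before component extraction
guarantees the result is connected; the alternative order can change node
counts, so the choice is declared rather than silent. Largest-component ties
are broken toward the component containing the lexicographically smallest
identifier, purely for determinism.

## Connectivity between interactor sets

For mapped sets A and B the three statistics are |A∩B|; the number of edges
with one endpoint in each set (an edge inside A∩B is one edge and counts
once — the count is an edge-set cardinality and therefore symmetric); and
the number of nodes adjacent to ≥1 member of each set, where the node's own
membership does not count as adjacency and set members are eligible common
neighbors (a flag excludes them).

The null model randomizes node sets, not edges. Interactor sets are
ascertained by co-precipitation with the anchor, so they sit closer to it
than uniform random sets; random counterparts therefore preserve the
template's exact count of proteins at each shortest-path distance from the
anchor, drawn uniformly without replacement within each distance stratum
(the anchor itself is never drawn). Each of the `n_random` iterations
(default 500) re-randomizes *both* sets; fixing one is available behind a
flag. The empirical p of a statistic is the fraction of random pairs whose
value is ≥ the observed one — ties count toward p, so the test never
understates it — and a zero exceedance count is reported as the resolution
floor `<1/n_random` (numerically, 1/n_random).

## Neighbor enrichment and candidate ranking

The universe for a candidate's test excludes the candidate itself (a protein
is not its own neighbor): population N−1, successes = set members minus the
candidate, draws = the candidate's degree, and p = P(X ≥ overlap) from the
hypergeometric upper tail. Candidates for a set are all proteins with ≥1
neighbor in it; set members may be candidates. Within each set the lowest
⌈0.05·n_tested⌉ p-values qualify, boundary ties inclusive. No
multiple-testing correction is applied anywhere in this stage — the fixed
per-set top-fraction *is* the selection control, and p-values are reported
as ranks, not error rates.

Globally selected candidates must qualify in ≥1 set and have ≥3 edges into
each of ≥2 sets (both thresholds configurable; a stricter variant requiring
qualification in ≥2 sets is behind a flag). The final ordering sums ranks
over qualified sets only. Because sets where a candidate did not qualify
are discarded from the sum, the default convention gives the *largest* rank
value (n_tested) to the smallest p, so that qualifying broadly and strongly
both increase the rank sum; the opposite convention (smallest p = rank 1,
ascending order) is implemented behind `best_p_gets_largest_rank=False`.
Ties in p receive midranks; ties in rank sum are broken by candidate id.

## Bridge score

Paths are *simple* — no repeated nodes. Walks were rejected because
back-and-forth traversals would inflate length-4 counts without bound and
make the fractions degenerate. For pair (a, b) and length L ∈ {2, 3, 4},
f_L(c) is the fraction of simple L-edge a–b paths containing c; a length
with zero paths contributes 0 so every candidate's score is comparable. The
score 1·f2 + 0.5·f3 + 0.25·f4 lies in [0, 1.75]. The anchors of the pair
are never intermediates (by simplicity); other anchors may be.

Counting uses neighbor-set intersection (L=2) and nested neighborhood
enumeration with distinctness checks (L=3, 4), which is exact and fast on
dense subnetworks; an independent recursive-DFS enumerator lives in the
test suite as the oracle and the two agree exactly on random graphs.

Strong mediators for a pair are candidates whose score is ≥ the k-th
largest score for that pair, k = ⌈0.25·n_candidates⌉, boundary ties
included. (A naive "75th percentile of all scores" threshold collapses to 0
on score distributions where more than three quarters of candidates score
0, flagging everything; the k-th-largest rule is what "top 25%" means
operationally.)

## Hit-selection cascade

Filters run in a declared order (experimental-set exclusion → top-fraction
rank cut → expression → keywords → prior interactors → manual keep-list),
each removal attributed to exactly one filter in the audit trail. Unknown
proteins default to expression "not_available", no keywords, flags false;
"not_available" expression is *kept* by the expression filter. Keyword
matching is case-insensitive exact label matching against the annotation's
keyword set, not substring search, so the audit is unambiguous. The
literature-mining step of the motivating workflow is inherently manual; it
is modeled as an explicit keep-list that intersects (never extends) the
surviving list. Note the rank cut applies to the list as it stands when it
runs, so disabling an upstream filter can change which candidates the cut
keeps.

## Screen statistics

Traffic efficiency is the per-cell surface/total fluorescence ratio,
summarized per image by the median and excluded when the image holds fewer
than 20 cells; a condition is the mean of its QC-passing image medians.
Control SEM is the sample SD of per-well control mean TEs divided by √n
wells — the well is the unit of replication, matching plate-level controls.
DS = (TE_test − TE_control)/(2·SEM_control) is dimensionless and
scale-free (affine equivariance is property-tested).

The per-siRNA global effect is Σ|⟨DS_i⟩| over channel variants (wild-type,
mutant, corrector-rescued by default), with ⟨DS_i⟩ the mean over replicates.
Because every DS is normalized by the same controls, all cells of the
screen matrix are exchangeable under the null; the permutation test
shuffles *all* individual DS values across the full matrix (default 10,000
shuffles), recomputes every siRNA's effect sum per shuffle, and reports
p = count(≥ observed)/n_perm floored at 1/n_perm. Block or within-row
permutations are deliberately not offered — they would test a different
exchangeability assumption than the normalization licenses.

The decay fit normalizes the fluorescence trace to the mean of the
pre-addition baseline and fits offset + amplitude·exp(−rate·t) to the
post-addition samples by nonlinear least squares (rate bounded ≥ 0; a
2-parameter no-offset variant behind a flag). The reported initial influx
rate is the slope at the moment of addition, −amplitude·rate. Surface
retention is a plain percentage of a reference condition.

## Synthetic data: what it emulates, and what it does not

The generator produces uniform-random connected graphs (disconnected draws
are patched with one edge per extra component), with: interactor sets of
chosen size planted partly at distance 1 from the anchor, optional extra
intra-set and inter-set edges (the connectivity signal), an optional
anchor-degree boost so distance-1 strata are wide enough for matched
sampling, and planted bridge nodes wired anchor–X–factor; a factor id that
is not an existing node is created as a leaf, making the bridge the
factor's only route to the anchor so its mediation is total by
construction. Screen matrices are i.i.d. Gaussian DS noise (sd 1) plus
planted per-type means; decay traces are the exact model plus Gaussian
noise.

Uniform random graphs do not reproduce the heavy-tailed degree
distribution, clustering or ascertainment biases of literature-curated
interactomes, and Gaussian DS noise ignores plate and batch structure.
Passing tests therefore demonstrate statistical correctness and calibration
of the machinery under its stated assumptions — not that any particular
biological dataset satisfies those assumptions.

## Calibration and recovery checks

The test suite verifies, at scaled-down simulation sizes chosen to keep the
default run in the minutes range: uniformity of both empirical p-values
under their own nulls (300-node network, sets of 20, 200 randomizations;
12-siRNA null screens, 1,000 shuffles; 1,000 replicates each, rejection
rate at 0.05 required inside [0.03, 0.07]); detection of 40 planted
cross-set edges between sets of 30 on a 500-node network in ≥90% of seeds;
the planted bridge node attaining the maximal bridge score in every seed;
a planted (3, 3, 3) screen effect rejected at α=0.05 in ≥95% of seeds; and
decay-slope recovery within 5% per trace at noise sd 0.01. Exactness checks
run against enumeration oracles (union-find components, BFS distances,
subset-enumeration hypergeometric tails, DFS path enumeration).

## Known limitations

- Empirical p-values are lower-bounded at 1/n_random (1/n_perm); claims
  below that resolution require more randomizations.
- The connectivity statistics are counts; on very sparse networks or tiny
  sets their discreteness makes the randomization test conservative.
- Matched sampling requires each template stratum to fit inside the
  network's stratum population; templates containing the anchor are
  rejected.
- The filter cascade's rank cut interacts with filter order by design;
  audits, not invariance, are the guarantee there.
- No identifier mapping: sets and networks must share a namespace.
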