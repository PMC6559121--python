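"""Connectivity between interactor sets and its distance-matched null model.

Two protein sets mapped onto the interaction network are compared by three
statistics: the number of shared members (overlap), the number of network
edges joining a member of one set to a member of the other (direct
interactions), and the number of proteins adjacent to at least one member of
each set (common neighbors).

Significance is assessed against random interactor sets matched to the
observed ones in size *and* in their distribution of shortest-path distances
from an anchor protein (CFTR in the motivating study): within each distance
stratum the random set draws the same number of proteins as the template,
uniformly without replacement.  The empirical p-value of a statistic is the
fraction of random set pairs whose value is greater than or equal to the
observed one (ties count, so p is never understated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class ConnectivityStats:
    """The three set-pair connectivity statistics; symmetric in the two sets."""

    overlap: int
    direct_interactions: int
    common_neighbors: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.overlap, self.direct_interactions, self.common_neighbors)


@dataclass
class RandomizationResult:
    """Observed statistics with their distance-matched null summary.

    ``p_values`` maps statistic name -> count(random >= observed) / n_random.
    A zero exceedance count is floored at 1/n_random and rendered as
    ``"<1/n_random"`` in ``p_display`` (the smallest resolvable p).
    """

    observed: ConnectivityStats
    expected: dict[str, float]
    p_values: dict[str, float]
    exceedance_counts: dict[str, int]
    n_random: int
    seed: int | None = None
    p_display: dict[str, str] = field(default_factory=dict)


_STAT_NAMES = ("overlap", "direct_interactions", "common_neighbors")


def connectivity_stats(net: nx.Graph, a: set[str], b: set[str]) -> ConnectivityStats:
    """Compute overlap, direct interactions and common neighbors of two sets.

    Direct interactions are counted as undirected edges with one endpoint in
    each set; an edge internal to the overlap is a single edge and counts
    once.  A common neighbor is any node adjacent to >=1 member of each set
    (set members themselves are eligible; a node's own membership does not
    count as adjacency).
    """
    if not a or not b:
        raise ValueError("both sets must be non-empty after mapping")
    overlap = len(a & b)

    smaller, larger = (a, b) if len(a) <= len(b) else (b, a)
    direct = 0
    for u in smaller:
        if u not in net:
            continue
        for v in net[u]:
            if v in larger:
                # count each unordered edge once: edges inside the overlap
                # would otherwise be seen from both endpoints
                if u in larger and v in smaller:
                    if u < v:
                        direct += 1
                else:
                    direct += 1

    common = 0
    for x in net.nodes:
        nbrs = net[x]
        if any(n in a for n in nbrs) and any(n in b for n in nbrs):
            common += 1
    return ConnectivityStats(overlap, direct, common)


def sample_matched_set(
    net: nx.Graph,
    profile: Mapping[str, int],
    template: set[str],
    rng: np.random.Generator,
) -> set[str]:
    """Draw a random set with the template's per-distance stratum counts.

    ``profile`` maps node -> shortest-path distance from the anchor.  Within
    each distance stratum, members are drawn uniformly without replacement
    from all non-anchor nodes at that distance.  Sampling is deterministic
    under a seeded generator.
    """
    missing = [m for m in template if m not in profile]
    if missing:
        raise ValueError(f"template members unreachable from anchor: {missing[:5]}")
    needed: dict[int, int] = {}
    for m in template:
        d = profile[m]
        needed[d] = needed.get(d, 0) + 1

    strata: dict[int, list[str]] = {d: [] for d in needed}
    for node, d in profile.items():
        if d in strata and d > 0:  # the anchor (d == 0) is never sampled
            strata[d].append(node)

    sample: set[str] = set()
    for d in sorted(needed):
        population = sorted(strata[d])
        k = needed[d]
        if len(population) < k:
            raise ValueError(
                f"stratum at distance {d} has {len(population)} nodes, need {k}"
            )
        chosen = rng.choice(len(population), size=k, replace=False)
        sample.update(population[i] for i in chosen)
    return sample


def connectivity_significance(
    net: nx.Graph,
    profile: Mapping[str, int],
    a: set[str],
    b: set[str],
    n_random: int = 500,
    rng: np.random.Generator | int | None = None,
    rerandomize_both: bool = True,
) -> RandomizationResult:
    """Distance-matched randomization test for all three connectivity statistics.

    Each iteration draws matched random counterparts for both sets (or, with
    ``rerandomize_both=False``, only for ``b``) and recomputes the three
    statistics; ``expected`` is their mean and p the fraction of random pairs
    reaching the observed value (ties included).
    """
    seed = rng if isinstance(rng, int) else None
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    observed = connectivity_stats(net, a, b)
    obs = np.array(observed.as_tuple())

    draws = np.empty((n_random, 3), dtype=float)
    for i in range(n_random):
        ra = sample_matched_set(net, profile, a, gen) if rerandomize_both else a
        rb = sample_matched_set(net, profile, b, gen)
        draws[i] = connectivity_stats(net, ra, rb).as_tuple()

    counts = (draws >= obs).sum(axis=0)
    expected = dict(zip(_STAT_NAMES, draws.mean(axis=0)))
    p_values = {
        name: max(int(c), 1) / n_random for name, c in zip(_STAT_NAMES, counts)
    }
    p_display = {
        name: (f"<{1 / n_random:g}" if c == 0 else f"{c / n_random:g}")
        for name, c in zip(_STAT_NAMES, counts)
    }
    return RandomizationResult(
        observed=observed,
        expected=expected,
        p_values=p_values,
        exceedance_counts={n: int(c) for n, c in zip(_STAT_NAMES, counts)},
        n_random=n_random,
        seed=seed,
        p_display=p_display,
    )
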