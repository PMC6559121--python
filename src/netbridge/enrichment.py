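"""Specific common neighbors via per-candidate hypergeometric enrichment.

For a candidate protein with degree *n* in a network of *N* proteins, and an
interactor set with *K* members (the candidate itself excluded from both the
universe and the set — a protein is not its own neighbor), the number of set
members among the candidate's neighbors follows a hypergeometric
distribution under the null that neighbors are an unbiased draw from the
network.  The enrichment p-value is the upper tail P(X >= observed overlap).

Per interactor set, the candidates with p-values in the lowest ``top_fraction``
(default 5%) qualify as *specific neighbors* of that set.  Globally selected
candidates must qualify for at least one set and additionally have at least
``min_cross_interactions`` edges (default 3) into each of at least
``min_sets`` sets (default 2).  Selected candidates are ordered by a rank sum
over the sets where they qualified; by default the smallest p in a set earns
the largest rank (n_tested), so breadth across sets and within-set
significance both push a candidate up the list.  No multiple-testing
correction is applied: the fixed top-fraction cutoff per set is the device
that bounds the selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
from scipy.stats import hypergeom, rankdata


@dataclass(frozen=True)
class EnrichmentRecord:
    """Hypergeometric neighbor-enrichment result for one candidate and one set."""

    candidate: str
    set_label: str
    degree: int
    set_size: int
    overlap: int
    p: float
    rank: float | None = None  # midrank of p among the set's tested candidates
    qualified: bool = False


@dataclass(frozen=True)
class SelectionConfig:
    top_fraction: float = 0.05
    min_cross_interactions: int = 3
    min_sets: int = 2
    #: rank the smallest p as the largest rank value (True) or as rank 1 (False)
    best_p_gets_largest_rank: bool = True
    #: require qualification in >= min_sets sets instead of >= 1 set
    require_qualified_in_min_sets: bool = False

    def __post_init__(self):
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.min_cross_interactions < 1 or self.min_sets < 1:
            raise ValueError("thresholds must be >= 1")


@dataclass
class RankedCandidate:
    candidate: str
    qualified_sets: set[str]
    rank_sum: float
    per_set_p: dict[str, float] = field(default_factory=dict)
    cross_interactions: dict[str, int] = field(default_factory=dict)
    overall_rank: int = 0


def neighbor_enrichment_p(
    net: nx.Graph, candidate: str, members: set[str], set_label: str = ""
) -> EnrichmentRecord:
    """Upper-tail hypergeometric p for enrichment of a candidate's neighbors.

    Population = N-1 network proteins (candidate excluded), successes =
    set members other than the candidate, draws = the candidate's neighbors.
    """
    if candidate not in net:
        raise ValueError(f"candidate {candidate!r} not in network")
    degree = net.degree(candidate)
    if degree == 0:
        raise ValueError(f"candidate {candidate!r} is isolated")
    successes = members - {candidate}
    overlap = sum(1 for n in net[candidate] if n in successes)
    population = net.number_of_nodes() - 1
    # P(X >= overlap); sf(k-1) is the survival function at overlap-1
    p = float(hypergeom.sf(overlap - 1, population, len(successes), degree))
    p = min(p, 1.0)
    return EnrichmentRecord(
        candidate=candidate,
        set_label=set_label,
        degree=degree,
        set_size=len(successes),
        overlap=overlap,
        p=p,
    )


def enrichment_table(
    net: nx.Graph, label: str, members: set[str]
) -> list[EnrichmentRecord]:
    """Enrichment records for every protein with >=1 neighbor in the set.

    Records carry midranks of p (ascending: best p has midrank 1) and the
    top-fraction qualification is left to :func:`select_specific_neighbors`.
    """
    candidates = sorted(
        {x for m in members if m in net for x in net[m]}
    )
    records = [neighbor_enrichment_p(net, c, members, label) for c in candidates]
    ranks = rankdata([r.p for r in records], method="average")
    return [
        EnrichmentRecord(**{**r.__dict__, "rank": float(rank)})
        for r, rank in zip(records, ranks)
    ]


def _qualify_top_fraction(
    records: list[EnrichmentRecord], top_fraction: float
) -> list[EnrichmentRecord]:
    """Mark the lowest-p ``top_fraction`` of records qualified, ties inclusive."""
    n = len(records)
    if n == 0:
        return []
    k = math.ceil(top_fraction * n)
    cutoff = sorted(r.p for r in records)[k - 1]
    return [
        EnrichmentRecord(**{**r.__dict__, "qualified": r.p <= cutoff})
        for r in records
    ]


def select_specific_neighbors(
    net: nx.Graph,
    sets: dict[str, set[str]],
    cfg: SelectionConfig = SelectionConfig(),
) -> tuple[list[RankedCandidate], dict[str, list[EnrichmentRecord]]]:
    """Select and rank specific common neighbors of the interactor sets.

    Returns the ordered selection (best first) and, for inspection, the full
    per-set enrichment tables with qualification flags.  Candidate order is
    invariant to the order the sets are supplied: ties in rank sum are broken
    by candidate id.
    """
    if len(sets) < 2:
        raise ValueError("need at least two interactor sets")

    tables = {
        label: _qualify_top_fraction(enrichment_table(net, label, members), cfg.top_fraction)
        for label, members in sorted(sets.items())
    }

    by_candidate: dict[str, dict[str, EnrichmentRecord]] = {}
    for label, records in tables.items():
        n_tested = len(records)
        for r in records:
            by_candidate.setdefault(r.candidate, {})[label] = r

    selected: list[RankedCandidate] = []
    for candidate, recs in by_candidate.items():
        qualified = {label for label, r in recs.items() if r.qualified}
        if not qualified:
            continue
        cross = {
            label: sum(1 for n in net[candidate] if n in (members - {candidate}))
            for label, members in sets.items()
        }
        n_cross_sets = sum(
            1 for c in cross.values() if c >= cfg.min_cross_interactions
        )
        if n_cross_sets < cfg.min_sets:
            continue
        if cfg.require_qualified_in_min_sets and len(qualified) < cfg.min_sets:
            continue
        rank_sum = 0.0
        for label in qualified:
            r = recs[label]
            n_tested = len(tables[label])
            if cfg.best_p_gets_largest_rank:
                rank_sum += n_tested + 1 - r.rank
            else:
                rank_sum += r.rank
        selected.append(
            RankedCandidate(
                candidate=candidate,
                qualified_sets=qualified,
                rank_sum=rank_sum,
                per_set_p={label: r.p for label, r in recs.items()},
                cross_interactions=cross,
            )
        )

    reverse = cfg.best_p_gets_largest_rank  # higher rank_sum = better
    selected.sort(
        key=lambda rc: ((-rc.rank_sum if reverse else rc.rank_sum), rc.candidate)
    )
    for i, rc in enumerate(selected, start=1):
        rc.overall_rank = i
    return selected, tables
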