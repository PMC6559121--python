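"""Bridge score: short-path mediation between two anchor proteins.

The bridge score of a candidate node for an anchor pair (a, b) measures how
much of the short-path traffic between a and b passes through the candidate.
For each path length L in {2, 3, 4} let f_L be the fraction of simple paths
(no repeated nodes) of exactly L edges from a to b that contain the
candidate as an intermediate.  The score is the weighted sum

    score = 1.0 * f2 + 0.5 * f3 + 0.25 * f4

so mediation of shorter paths counts more.  A length with no paths at all
contributes 0.  Scores lie in [0, 1.75].

Candidates whose score for a given anchor pair falls in the top 25% of that
pair's scores are *strong mediators* of the pair.

Path counting for L <= 4 is done by direct neighbor-set enumeration
(intersection for L=2, edge-between-neighborhoods for L=3, two-hop middles
for L=4) with explicit distinctness checks; this is exact and much faster
than generic DFS on dense subnetworks.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import networkx as nx

PATH_WEIGHTS = {2: 1.0, 3: 0.5, 4: 0.25}


@dataclass(frozen=True)
class BridgeScoreRecord:
    candidate: str
    pair: tuple[str, str]
    f2: float
    f3: float
    f4: float
    score: float
    strong: bool = False


def assemble_subnetwork(
    net: nx.Graph, anchors: list[str], candidates: list[str]
) -> nx.Graph:
    """Induced subgraph on anchors + candidates, then the first anchor's component.

    Candidates that end up disconnected from the first anchor are dropped
    (their count is recoverable by comparing node sets).
    """
    for a in anchors:
        if a not in net:
            raise ValueError(f"anchor {a!r} not in network")
    keep = set(anchors) | set(candidates)
    sub = net.subgraph(keep & set(net.nodes))
    first = anchors[0]
    if first not in sub:
        raise ValueError(f"first anchor {first!r} excluded by induction")
    component = nx.node_connected_component(sub, first)
    out: nx.Graph = sub.subgraph(component).copy()
    out.graph["provenance"] = "subnetwork(%s)" % ",".join(anchors)
    return out


def count_paths(
    sub: nx.Graph, pair: tuple[str, str], length: int
) -> tuple[int, dict[str, int]]:
    """Count simple paths of exactly ``length`` edges between the pair's nodes.

    Returns the total count and, per intermediate node, the number of such
    paths containing it.  The anchors themselves are never intermediates.
    """
    a, b = pair
    if a == b:
        raise ValueError("anchor pair must be two distinct nodes")
    if a not in sub or b not in sub:
        raise ValueError("both anchor nodes must be in the subnetwork")
    if length not in (2, 3, 4):
        raise ValueError("path length must be 2, 3, or 4")

    adj = {n: set(sub[n]) for n in sub.nodes}
    per_node: Counter[str] = Counter()
    total = 0

    if length == 2:
        for x in adj[a] & adj[b]:
            if x not in (a, b):
                total += 1
                per_node[x] += 1
    elif length == 3:
        # a - x - y - b with x,y distinct and not anchors
        for x in adj[a]:
            if x in (a, b):
                continue
            for y in adj[x] & adj[b]:
                if y in (a, b) or y == x:
                    continue
                total += 1
                per_node[x] += 1
                per_node[y] += 1
    else:
        # a - x - y - z - b, all of x,y,z distinct and not anchors
        bn = adj[b]
        for x in adj[a]:
            if x in (a, b):
                continue
            for y in adj[x]:
                if y in (a, b) or y == x:
                    continue
                for z in adj[y] & bn:
                    if z in (a, b) or z == x or z == y:
                        continue
                    total += 1
                    per_node[x] += 1
                    per_node[y] += 1
                    per_node[z] += 1
    return total, dict(per_node)


def bridge_score(
    sub: nx.Graph,
    pair: tuple[str, str],
    candidate: str,
    _counts: dict[int, tuple[int, dict[str, int]]] | None = None,
) -> BridgeScoreRecord:
    """Weighted short-path mediation score of one candidate for one pair.

    ``_counts`` lets callers that score many candidates against one pair
    reuse the path counts (see :func:`bridge_scores_for_pair`).
    """
    if candidate in pair:
        raise ValueError("candidate must differ from both anchors")
    counts = _counts or {L: count_paths(sub, pair, L) for L in (2, 3, 4)}
    fractions = {}
    for L, (total, per_node) in counts.items():
        fractions[L] = per_node.get(candidate, 0) / total if total > 0 else 0.0
    score = sum(PATH_WEIGHTS[L] * fractions[L] for L in (2, 3, 4))
    return BridgeScoreRecord(
        candidate=candidate,
        pair=pair,
        f2=fractions[2],
        f3=fractions[3],
        f4=fractions[4],
        score=score,
    )


def bridge_scores_for_pair(
    sub: nx.Graph, pair: tuple[str, str], candidates: list[str] | None = None
) -> list[BridgeScoreRecord]:
    """Score every candidate (default: all non-anchor nodes) for one pair."""
    counts = {L: count_paths(sub, pair, L) for L in (2, 3, 4)}
    if candidates is None:
        candidates = sorted(n for n in sub.nodes if n not in pair)
    return [bridge_score(sub, pair, c, _counts=counts) for c in candidates]


def select_strong_mediators(
    records: list[BridgeScoreRecord], top_fraction: float = 0.25
) -> tuple[dict[str, list[tuple[str, str]]], list[BridgeScoreRecord]]:
    """Flag, per anchor pair, the candidates in the pair's top score fraction.

    The threshold for a pair is its k-th largest score with
    k = ceil(top_fraction * n_candidates); every score >= the threshold is
    strong (boundary ties included).  Returns a map candidate -> pairs for
    which it is strong, plus the records with ``strong`` flags set.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    by_pair: dict[tuple[str, str], list[BridgeScoreRecord]] = {}
    for r in records:
        by_pair.setdefault(r.pair, []).append(r)

    flagged: list[BridgeScoreRecord] = []
    strong_map: dict[str, list[tuple[str, str]]] = {}
    for pair, recs in by_pair.items():
        scores = sorted((r.score for r in recs), reverse=True)
        k = math.ceil(top_fraction * len(scores))
        threshold = scores[k - 1]
        for r in recs:
            strong = r.score >= threshold
            flagged.append(BridgeScoreRecord(**{**r.__dict__, "strong": strong}))
            if strong:
                strong_map.setdefault(r.candidate, []).append(pair)
    return strong_map, flagged
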