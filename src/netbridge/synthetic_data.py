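"""Synthetic networks, interactor sets, screen matrices and decay traces.

Every stage of the pipeline can be exercised without any external download:
the generators here produce (a) connected random interaction networks with
interactor-set modules planted near an anchor node, optional extra edges
*between* planted sets (the cross-set connectivity signal), and optional
planted bridge nodes wired to the anchor and one named stability factor;
(b) screen matrices of replicate deviation scores with a standard-normal
null component and planted per-type mean effects; and (c) random annotation
tables for the hit-selection cascade.

All generators are pure functions of (spec, seed): the same seed reproduces
the same output bit for bit.  The base graph is a uniform random graph
patched to connectivity with a minimum number of inter-component edges — a
deliberately simple null; no attempt is made to mimic the degree
distribution of real interactome snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .hit_selection import Annotation, AnnotationTable
from .traffic_stats import CFTR_TYPES


@dataclass(frozen=True)
class PlantedSetSpec:
    """One interactor set planted around the anchor."""

    label: str
    size: int = 30
    #: fraction of members wired directly to the anchor (network distance 1)
    frac_distance1: float = 0.5
    #: extra random edges added inside the set, as a multiple of its size
    internal_edge_boost: float = 1.0


@dataclass(frozen=True)
class NetworkSpec:
    n_nodes: int = 500
    n_edges: int = 1500
    anchor: str = "ANCHOR"
    #: extra random neighbors wired to the anchor, broadening the distance-1
    #: stratum so matched null sets are not forced onto planted members
    anchor_degree: int = 0
    sets: tuple[PlantedSetSpec, ...] = ()
    #: extra edges added between every pair of planted sets
    cross_set_edges: int = 0
    #: planted exclusive bridges: (node_id, factor_id) wired only anchor-X-factor
    bridges: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class ScreenSpec:
    n_sirnas: int = 12
    n_replicates: int = 3
    cftr_types: tuple[str, ...] = CFTR_TYPES
    noise_sd: float = 1.0
    #: sirna label -> per-type mean DS (tuple aligned with cftr_types)
    planted_effects: dict[str, tuple[float, ...]] = field(default_factory=dict)


@dataclass
class NetworkTruth:
    set_members: dict[str, set[str]]
    bridge_nodes: dict[str, str]  # node -> factor it bridges the anchor to


def _connect(g: nx.Graph, rng: np.random.Generator) -> None:
    """Patch a disconnected graph with one edge per extra component."""
    comps = [sorted(c) for c in nx.connected_components(g)]
    if len(comps) <= 1:
        return
    comps.sort(key=len, reverse=True)
    main = comps[0]
    for comp in comps[1:]:
        u = main[rng.integers(len(main))]
        v = comp[rng.integers(len(comp))]
        g.add_edge(u, v)


def generate_network(
    spec: NetworkSpec, seed: int | np.random.Generator = 0
) -> tuple[nx.Graph, NetworkTruth]:
    """Random connected network with planted modules; see module docstring."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_planted = sum(s.size for s in spec.sets)
    n_bridge = len(spec.bridges)
    if n_planted + n_bridge + 1 > spec.n_nodes:
        raise ValueError("planted nodes exceed n_nodes")

    nodes = [f"P{i:04d}" for i in range(spec.n_nodes - n_bridge - 1)]
    nodes.append(spec.anchor)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    # uniform random edges over the non-bridge nodes
    arr = np.array(nodes)
    added = 0
    max_tries = spec.n_edges * 20
    tries = 0
    while added < spec.n_edges and tries < max_tries:
        u, v = arr[rng.integers(len(arr), size=2)]
        tries += 1
        if u != v and not g.has_edge(u, v):
            g.add_edge(u, v)
            added += 1
    _connect(g, rng)

    # plant the interactor sets among ordinary nodes (never the anchor)
    pool = [n for n in nodes if n != spec.anchor]
    if spec.anchor_degree > 0:
        hub = rng.choice(len(pool), size=min(spec.anchor_degree, len(pool)), replace=False)
        for i in hub:
            g.add_edge(spec.anchor, pool[i])
    chosen = rng.choice(len(pool), size=n_planted, replace=False)
    members_flat = [pool[i] for i in chosen]
    truth = NetworkTruth(set_members={}, bridge_nodes={})
    offset = 0
    for sspec in spec.sets:
        members = members_flat[offset : offset + sspec.size]
        offset += sspec.size
        truth.set_members[sspec.label] = set(members)
        n_d1 = int(round(sspec.frac_distance1 * len(members)))
        for m in members[:n_d1]:
            g.add_edge(spec.anchor, m)
        n_internal = int(round(sspec.internal_edge_boost * len(members)))
        marr = np.array(members)
        for _ in range(n_internal):
            u, v = marr[rng.integers(len(marr), size=2)]
            if u != v:
                g.add_edge(u, v)

    # cross-set edge boost: the planted connectivity signal
    labels = [s.label for s in spec.sets]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = sorted(truth.set_members[labels[i]])
            b = sorted(truth.set_members[labels[j]])
            for _ in range(spec.cross_set_edges):
                g.add_edge(a[rng.integers(len(a))], b[rng.integers(len(b))])

    # planted exclusive bridge nodes: anchor - X - factor and nothing else.
    # A factor id not already in the network is created as a leaf whose only
    # route to the anchor is the bridge, making X's mediation total.
    for node, factor in spec.bridges:
        g.add_node(node)
        g.add_edge(spec.anchor, node)
        g.add_edge(node, factor)
        truth.bridge_nodes[node] = factor

    g.graph["provenance"] = "synthetic"
    return g, truth


def generate_screen(
    spec: ScreenSpec, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, dict[str, tuple[float, ...]]]:
    """Long-format DS matrix (sirna, cftr_type, replicate, ds) with ground truth."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sirnas = [f"si{i:03d}" for i in range(spec.n_sirnas)]
    unknown = set(spec.planted_effects) - set(sirnas)
    if unknown:
        raise ValueError(f"planted effects for unknown siRNAs: {sorted(unknown)}")
    rows = []
    for s in sirnas:
        effect = spec.planted_effects.get(s, (0.0,) * len(spec.cftr_types))
        for ti, t in enumerate(spec.cftr_types):
            noise = rng.normal(0.0, spec.noise_sd, size=spec.n_replicates)
            for r in range(spec.n_replicates):
                rows.append(
                    {
                        "sirna": s,
                        "cftr_type": t,
                        "replicate": r + 1,
                        "ds": effect[ti] + noise[r],
                    }
                )
    return pd.DataFrame(rows), dict(spec.planted_effects)


def generate_annotations(
    proteins: list[str],
    frac_low_expression: float = 0.0,
    frac_keyword: float = 0.0,
    keyword: str = "nuclear",
    frac_prior_interactor: float = 0.0,
    frac_experimental: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> AnnotationTable:
    """Random annotation table; each fraction flags proteins independently."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    table = AnnotationTable()
    for p in proteins:
        table[p] = Annotation(
            expression_level=(
                "low" if rng.random() < frac_low_expression else "not_available"
            ),
            keywords={keyword} if rng.random() < frac_keyword else set(),
            prior_interactor=bool(rng.random() < frac_prior_interactor),
            in_experimental_sets=bool(rng.random() < frac_experimental),
        )
    return table


def generate_decay_trace(
    amplitude: float = 0.9,
    rate: float = 0.08,
    offset: float = 0.1,
    noise_sd: float = 0.0,
    baseline_duration: float = 10.0,
    post_duration: float = 60.0,
    dt: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated fluorescence trace: flat baseline at 1, then exponential decay."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t_base = np.arange(0.0, baseline_duration, dt)
    t_post = np.arange(baseline_duration, baseline_duration + post_duration, dt)
    f_base = np.ones_like(t_base)
    f_post = offset + amplitude * np.exp(-rate * (t_post - baseline_duration))
    t = np.concatenate([t_base, t_post])
    f = np.concatenate([f_base, f_post])
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.size)
    return t, f
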