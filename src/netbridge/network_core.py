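"""Construction of the operational protein interaction network.

The analyses downstream (set connectivity, neighbor enrichment, bridge
scoring) all run on an undirected, unweighted, simple and connected graph of
protein identifiers.  This module reads raw edge lists (e.g. HuRI or APID
exports), cleans them (loop and multi-edge removal), applies the
subcellular-location filter that removes proteins exclusively annotated to
compartments where plasma-membrane-relevant interactions cannot occur
(nucleus, mitochondrion, peroxisome by default), and extracts the main
connected component.

Identifiers are opaque, case-sensitive strings (UniProt accessions or gene
symbols); no identifier mapping is performed.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: Compartments whose exclusive residents are removed from the network.
DEFAULT_EXCLUDED_COMPARTMENTS = frozenset({"nucleus", "mitochondrion", "peroxisome"})

#: Synonyms normalised onto the canonical compartment labels above.
COMPARTMENT_SYNONYMS = {
    "mitochondria": "mitochondrion",
    "mitochondrial": "mitochondrion",
    "peroxisomes": "peroxisome",
    "peroxisomal": "peroxisome",
    "nuclear": "nucleus",
}


def normalize_compartment(label: str) -> str:
    """Lower-case a compartment label and collapse known synonyms."""
    label = label.strip().lower()
    return COMPARTMENT_SYNONYMS.get(label, label)


def read_edge_list(
    path: str | Path,
    sep: str | None = None,
    columns: tuple[int, int] = (0, 1),
    comment: str = "#",
) -> list[tuple[str, str]]:
    """Read raw interaction pairs from a delimited text file.

    Duplicates, reciprocal pairs and self-loops are preserved verbatim;
    cleaning is :func:`build_network`'s job.

    Parameters
    ----------
    path
        Edge-list file; one interaction per row.
    sep
        Column separator. ``None`` splits on any whitespace; pass ``"\\t"``
        or ``","`` for strict TSV/CSV.
    columns
        Zero-based indices of the two identifier columns (extra columns,
        e.g. confidence scores, are ignored).
    comment
        Rows starting with this prefix are skipped.

    Raises
    ------
    ValueError
        On an empty file or a row lacking the identifier columns (the error
        names the offending line number).
    """
    path = Path(path)
    i, j = columns
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith(comment):
                continue
            fields = line.split(sep) if sep else line.split()
            if len(fields) <= max(i, j):
                raise ValueError(
                    f"{path}:{lineno}: expected at least {max(i, j) + 1} columns, "
                    f"got {len(fields)}: {line!r}"
                )
            a, b = fields[i].strip(), fields[j].strip()
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty identifier in row {line!r}")
            pairs.append((a, b))
    if not pairs:
        raise ValueError(f"{path}: no interaction rows found")
    logger.info("read %d raw pairs from %s", len(pairs), path)
    return pairs


def read_locations(path: str | Path) -> dict[str, set[str]]:
    """Read a protein → compartment table (TSV, one pair per row).

    Returns a mapping protein id → set of normalised compartment labels.
    Proteins absent from the table are unannotated.
    """
    locations: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"location row needs 2 columns: {row!r}")
            locations.setdefault(row[0].strip(), set()).add(
                normalize_compartment(row[1])
            )
    return locations


def _largest_component(g: nx.Graph) -> set[str]:
    """Largest connected component; ties broken by smallest member id."""
    components = list(nx.connected_components(g))
    biggest = max(len(c) for c in components)
    return min((c for c in components if len(c) == biggest), key=min)


def build_network(
    pairs: Iterable[tuple[str, str]],
    locations: Mapping[str, set[str]] | None = None,
    excluded_compartments: Iterable[str] = DEFAULT_EXCLUDED_COMPARTMENTS,
    provenance: str = "",
) -> nx.Graph:
    """Build the filtered operational network from raw pairs.

    Order of operations is fixed: (1) drop self-loops and collapse
    duplicate/reciprocal pairs into single undirected edges; (2) remove every
    protein whose (non-empty) compartment annotation is entirely contained in
    ``excluded_compartments`` — unannotated proteins are always kept;
    (3) keep the largest connected component (size ties broken by the
    component containing the lexicographically smallest id).

    Raises
    ------
    ValueError
        If no pairs are supplied or nothing survives filtering.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no interaction pairs supplied")
    excluded = {normalize_compartment(c) for c in excluded_compartments}

    g = nx.Graph()
    for a, b in pairs:
        if a != b:
            g.add_edge(a, b)
    if locations:
        drop = [
            n
            for n in g.nodes
            if locations.get(n)
            and {normalize_compartment(c) for c in locations[n]} <= excluded
        ]
        g.remove_nodes_from(drop)
        if drop:
            logger.info("location filter removed %d proteins", len(drop))
    if g.number_of_nodes() == 0:
        raise ValueError("network empty after cleaning/filtering")
    keep = _largest_component(g)
    net: nx.Graph = g.subgraph(keep).copy()
    net.graph["provenance"] = provenance
    logger.info(
        "built network: %d proteins, %d interactions",
        net.number_of_nodes(),
        net.number_of_edges(),
    )
    return net


def shortest_distances(net: nx.Graph, anchor: str) -> dict[str, int]:
    """Unweighted shortest-path distance from ``anchor`` to every node.

    On the connected operational network every node receives a finite
    distance; ``distances[anchor] == 0``.
    """
    if anchor not in net:
        raise ValueError(f"anchor {anchor!r} not in network")
    return dict(nx.single_source_shortest_path_length(net, anchor))


def write_network(net: nx.Graph, path: str | Path) -> None:
    """Serialize as a canonical sorted two-column TSV (smaller id first)."""
    rows = sorted(tuple(sorted(e)) for e in net.edges)
    with Path(path).open("w") as fh:
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


def read_network(path: str | Path) -> nx.Graph:
    """Read a network serialized by :func:`write_network` (round-trip exact)."""
    pairs = read_edge_list(path, sep="\t")
    g = nx.Graph()
    g.add_edges_from(pairs)
    g.graph["provenance"] = str(path)
    return g


def map_set(net: nx.Graph, members: Iterable[str], label: str = "") -> set[str]:
    """Restrict a protein set to network nodes, logging how many were dropped."""
    members = set(members)
    mapped = members & set(net.nodes)
    dropped = len(members) - len(mapped)
    if dropped:
        logger.info("set %s: dropped %d members absent from network", label, dropped)
    if not mapped:
        raise ValueError(f"set {label!r}: no members map onto the network")
    return mapped


def read_id_list(path: str | Path) -> list[str]:
    """Read a one-identifier-per-line protein list."""
    out = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
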