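"""Annotation-driven filter cascade reducing ranked candidates to testable hits.

The cascade mirrors a hit-selection narrative: starting from the ranked list
of specific common neighbors, (1) drop anything already present in the
experimentally derived interactor sets, (2) keep only the top fraction of
the list by rank sum, (3) drop proteins with low expression in the target
tissue (unknown expression is kept), (4) drop proteins carrying excluded
functional keywords (ribosomal / transcription factor / nuclear etc. —
case-insensitive exact label match against the annotation's keyword set),
(5) drop known prior interactors of the bait, and finally (6) intersect with
an explicit manual keep-list standing in for non-reproducible literature
mining.  Every filter's removals are logged in an audit trail; filters are
applied in the declared order and each removal is attributed to exactly one
filter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .enrichment import RankedCandidate

EXPRESSION_LEVELS = ("low", "medium", "high", "not_available")

DEFAULT_EXCLUDE_KEYWORDS = frozenset(
    {
        "ribosomal",
        "elongation",
        "transcription factor",
        "hnrnp",
        "rna processing",
        "nuclear",
    }
)


@dataclass
class Annotation:
    """Per-protein annotation; unknown proteins get the default record."""

    expression_level: str = "not_available"
    keywords: set[str] = field(default_factory=set)
    prior_interactor: bool = False
    in_experimental_sets: bool = False

    def __post_init__(self):
        if self.expression_level not in EXPRESSION_LEVELS:
            raise ValueError(f"unknown expression level {self.expression_level!r}")
        self.keywords = {k.strip().lower() for k in self.keywords}


class AnnotationTable(dict):
    """protein id -> :class:`Annotation`; missing ids yield the default."""

    def __missing__(self, key: str) -> Annotation:
        return Annotation()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationTable":
        """Read a long-format TSV: protein, field, value (one row per fact).

        Recognised fields: ``expression`` (a level), ``keyword`` (repeatable),
        ``prior_interactor`` and ``in_experimental_sets`` (true/false).
        """
        table = cls()
        with Path(path).open() as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                protein, kind, value = row[0], row[1].strip().lower(), row[2].strip()
                ann = table.setdefault(protein, Annotation())
                if kind == "expression":
                    ann.expression_level = value.lower()
                elif kind == "keyword":
                    ann.keywords.add(value.lower())
                elif kind in ("prior_interactor", "in_experimental_sets"):
                    setattr(ann, kind, value.lower() in ("1", "true", "yes"))
                else:
                    raise ValueError(f"unknown annotation field {kind!r}")
        return table


@dataclass
class FilterConfig:
    exclude_experimental_sets: bool = True
    top_fraction: float | None = 0.25
    exclude_expression_levels: frozenset[str] = frozenset({"low"})
    exclude_keywords: frozenset[str] = DEFAULT_EXCLUDE_KEYWORDS
    exclude_prior_interactors: bool = True
    manual_keep_list: frozenset[str] | None = None  # intersects, never adds


@dataclass(frozen=True)
class FilterAuditEntry:
    filter_name: str
    n_in: int
    n_removed: int
    n_out: int


def _keyword_hit(ann: Annotation, excluded: Iterable[str]) -> bool:
    excluded = {k.lower() for k in excluded}
    return bool(ann.keywords & excluded)


def apply_filters(
    ranked: Sequence[RankedCandidate],
    annotations: AnnotationTable,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[RankedCandidate], list[FilterAuditEntry]]:
    """Run the filter cascade; returns survivors (rank order kept) and audit.

    The rank cut keeps the first ceil(top_fraction * current length) of the
    list as it stands when that filter runs.  An empty final list is allowed.
    """
    import math

    current = list(ranked)
    audit: list[FilterAuditEntry] = []

    def step(name: str, keep_fn) -> None:
        nonlocal current
        n_in = len(current)
        kept = [rc for rc in current if keep_fn(rc)]
        audit.append(FilterAuditEntry(name, n_in, n_in - len(kept), len(kept)))
        current = kept

    if cfg.exclude_experimental_sets:
        step(
            "experimental_sets",
            lambda rc: not annotations[rc.candidate].in_experimental_sets,
        )
    if cfg.top_fraction is not None and cfg.top_fraction < 1.0:
        n_keep = math.ceil(cfg.top_fraction * len(current))
        top = set(id(rc) for rc in current[:n_keep])
        step("rank_cut", lambda rc: id(rc) in top)
    if cfg.exclude_expression_levels:
        levels = set(cfg.exclude_expression_levels)
        step(
            "expression",
            lambda rc: annotations[rc.candidate].expression_level not in levels,
        )
    if cfg.exclude_keywords:
        step(
            "keywords",
            lambda rc: not _keyword_hit(annotations[rc.candidate], cfg.exclude_keywords),
        )
    if cfg.exclude_prior_interactors:
        step(
            "prior_interactors",
            lambda rc: not annotations[rc.candidate].prior_interactor,
        )
    if cfg.manual_keep_list is not None:
        keep = set(cfg.manual_keep_list)
        step("manual_keep_list", lambda rc: rc.candidate in keep)
    return current, audit
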