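"""End-to-end orchestration: build -> connectivity -> enrichment ->
subnetwork -> bridge -> hits -> traffic, from one config mapping.

Every stage writes a TSV into the output directory and its SHA-256 hash is
recorded in ``manifest.json`` together with the full parameter set and all
seeds, so a rerun with an identical config reproduces identical hashes.
Inputs are either file paths (``inputs:`` section) or synthetic-generator
parameters (``synthetic:`` section).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import (
    bridging,
    connectivity,
    enrichment,
    hit_selection,
    network_core,
    synthetic_data,
    traffic_stats,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """All pipeline parameters; numeric defaults follow the motivating study."""

    anchor: str = "ANCHOR"
    factors: tuple[str, ...] = ()
    n_random: int = 500
    top_fraction: float = 0.05
    min_cross_interactions: int = 3
    min_sets: int = 2
    mediator_top_fraction: float = 0.25
    hit_top_fraction: float = 0.25
    min_cells: int = 20
    n_perm: int = 10_000
    alpha: float = 0.05
    seeds: dict[str, int] = field(
        default_factory=lambda: {"connectivity": 1, "traffic": 2, "synthetic": 3}
    )
    inputs: dict[str, Any] = field(default_factory=dict)
    synthetic: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: dict[str, Any]) -> "AnalysisConfig":
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.factors = tuple(cfg.factors)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with Path(path).open() as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_or_generate(cfg: AnalysisConfig):
    """Return (network, sets, annotations, ds_matrix) from files or generators."""
    if cfg.inputs:
        net = network_core.read_network(cfg.inputs["edges"])
        sets = {
            label: set(network_core.read_id_list(p))
            for label, p in cfg.inputs["sets"].items()
        }
        ann = (
            hit_selection.AnnotationTable.from_tsv(cfg.inputs["annotations"])
            if "annotations" in cfg.inputs
            else hit_selection.AnnotationTable()
        )
        ds = (
            pd.read_csv(cfg.inputs["ds_matrix"])
            if "ds_matrix" in cfg.inputs
            else None
        )
        return net, sets, ann, ds

    seed = cfg.seeds.get("synthetic", 0)
    net_kwargs = dict(cfg.synthetic.get("network", {}))
    set_specs = tuple(
        synthetic_data.PlantedSetSpec(**s) for s in net_kwargs.pop("sets", [])
    )
    bridges = tuple(tuple(b) for b in net_kwargs.pop("bridges", []))
    spec = synthetic_data.NetworkSpec(
        anchor=cfg.anchor, sets=set_specs, bridges=bridges, **net_kwargs
    )
    net, truth = synthetic_data.generate_network(spec, seed=seed)
    sets = truth.set_members

    screen_kwargs = dict(cfg.synthetic.get("screen", {}))
    planted = {
        k: tuple(v) for k, v in screen_kwargs.pop("planted_effects", {}).items()
    }
    ds, _ = synthetic_data.generate_screen(
        synthetic_data.ScreenSpec(planted_effects=planted, **screen_kwargs),
        seed=seed + 1,
    )
    ann_kwargs = cfg.synthetic.get("annotations", {})
    ann = synthetic_data.generate_annotations(
        sorted(net.nodes), seed=seed + 2, **ann_kwargs
    )
    return net, sets, ann, ds


def run_pipeline(cfg: AnalysisConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run all stages, write per-stage TSVs and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config": _jsonable(cfg), "stages": {}}

    def record(stage: str, path: Path, t0: float) -> None:
        manifest["stages"][stage] = {"output": path.name, "sha256": _sha256(path)}
        logger.info("stage %s -> %s (%.2fs)", stage, path.name, time.time() - t0)

    t0 = time.time()
    net, sets, annotations, ds_matrix = _load_or_generate(cfg)
    net_path = out / "network.tsv"
    network_core.write_network(net, net_path)
    record("build_network", net_path, t0)

    sets = {
        label: network_core.map_set(net, members, label)
        for label, members in sets.items()
    }
    profile = network_core.shortest_distances(net, cfg.anchor)

    t0 = time.time()
    rows = []
    for la, lb in itertools.combinations(sorted(sets), 2):
        res = connectivity.connectivity_significance(
            net,
            profile,
            sets[la],
            sets[lb],
            n_random=cfg.n_random,
            rng=cfg.seeds.get("connectivity", 0),
        )
        for stat in ("overlap", "direct_interactions", "common_neighbors"):
            rows.append(
                {
                    "set_a": la,
                    "set_b": lb,
                    "statistic": stat,
                    "observed": getattr(res.observed, stat),
                    "expected": round(res.expected[stat], 4),
                    "p": res.p_display[stat],
                }
            )
    conn_path = out / "connectivity.tsv"
    pd.DataFrame(rows).to_csv(conn_path, sep="\t", index=False)
    record("connectivity", conn_path, t0)

    t0 = time.time()
    sel_cfg = enrichment.SelectionConfig(
        top_fraction=cfg.top_fraction,
        min_cross_interactions=cfg.min_cross_interactions,
        min_sets=cfg.min_sets,
    )
    ranked, _tables = enrichment.select_specific_neighbors(net, sets, sel_cfg)
    ranked_path = out / "ranked_candidates.tsv"
    pd.DataFrame(
        [
            {
                "candidate": rc.candidate,
                "overall_rank": rc.overall_rank,
                "rank_sum": rc.rank_sum,
                "qualified_sets": ",".join(sorted(rc.qualified_sets)),
            }
            for rc in ranked
        ]
    ).to_csv(ranked_path, sep="\t", index=False)
    record("enrichment", ranked_path, t0)

    t0 = time.time()
    anchors = [cfg.anchor, *cfg.factors]
    sub = bridging.assemble_subnetwork(
        net, anchors, [rc.candidate for rc in ranked]
    )
    sub_path = out / "subnetwork.tsv"
    network_core.write_network(sub, sub_path)
    record("subnetwork", sub_path, t0)

    t0 = time.time()
    records = []
    for factor in cfg.factors:
        if factor not in sub:
            logger.warning("factor %s not in subnetwork; skipped", factor)
            continue
        records.extend(bridging.bridge_scores_for_pair(sub, (cfg.anchor, factor)))
    strong_map, flagged = (
        bridging.select_strong_mediators(records, cfg.mediator_top_fraction)
        if records
        else ({}, [])
    )
    med_path = out / "mediators.tsv"
    pd.DataFrame(
        [
            {
                "candidate": r.candidate,
                "pair": f"{r.pair[0]}-{r.pair[1]}",
                "f2": r.f2,
                "f3": r.f3,
                "f4": r.f4,
                "score": r.score,
                "strong": r.strong,
            }
            for r in flagged
        ]
    ).to_csv(med_path, sep="\t", index=False)
    record("bridge", med_path, t0)

    t0 = time.time()
    filter_cfg = hit_selection.FilterConfig(top_fraction=cfg.hit_top_fraction)
    hits, audit = hit_selection.apply_filters(ranked, annotations, filter_cfg)
    hits_path = out / "hits.tsv"
    pd.DataFrame(
        [
            {
                "candidate": rc.candidate,
                "rank_sum": rc.rank_sum,
                "strong_mediator_pairs": ";".join(
                    f"{a}-{b}" for a, b in strong_map.get(rc.candidate, [])
                ),
            }
            for rc in hits
        ]
    ).to_csv(hits_path, sep="\t", index=False)
    pd.DataFrame([a.__dict__ for a in audit]).to_csv(
        out / "hits_audit.tsv", sep="\t", index=False
    )
    record("hit_selection", hits_path, t0)

    t0 = time.time()
    traffic_path = out / "traffic.tsv"
    if ds_matrix is not None:
        results = traffic_stats.permutation_test(
            ds_matrix, n_perm=cfg.n_perm, rng=cfg.seeds.get("traffic", 0)
        )
        pd.DataFrame(
            [
                {
                    "sirna": r.sirna,
                    "effect_sum": r.observed_sum,
                    "p": r.p,
                    "significant": r.p < cfg.alpha,
                }
                for r in results
            ]
        ).to_csv(traffic_path, sep="\t", index=False)
    else:
        traffic_path.write_text("sirna\teffect_sum\tp\tsignificant\n")
    record("traffic", traffic_path, t0)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable(cfg: AnalysisConfig) -> dict[str, Any]:
    d = asdict(cfg)
    d["factors"] = list(d["factors"])
    return d
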