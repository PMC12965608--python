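"""End-to-end orchestration, run manifests, and graph/table export."""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .ensemble import (
    ConsensusGraph,
    EnsembleConfig,
    SubnetworkDAG,
    consensus_graph,
    dual_network_overlap,
    run_ensemble,
)
from .rpcn import RPCNConfig, RPCNetwork, centrality, fit_rpcn, predictability
from .schema import (
    CohortTable,
    ScreeningRule,
    apply_screens,
    complete_cases,
    screens_from_ranges,
)
from .structure import Blacklist
from .transforms import make_transform_suite, table_hash

__all__ = [
    "run_pipeline",
    "run_from_manifest",
    "export_graph",
    "consensus_table",
    "load_manifest",
]

CONSENSUS_COLUMNS = (
    "from", "to", "networks",
    "learned_strength", "grand_strength",
    "learned_direction", "grand_direction",
)


def consensus_table(graph: ConsensusGraph) -> pd.DataFrame:
    """Arc table mirroring the published column layout, sorted by
    (from, to); proportions at full precision."""
    rows = [
        {
            "from": a.from_, "to": a.to, "networks": a.k,
            "learned_strength": a.learned_strength,
            "grand_strength": a.grand_strength,
            "learned_direction": a.learned_direction,
            "grand_direction": a.grand_direction,
        }
        for a in sorted(graph.arcs, key=lambda a: (a.from_, a.to))
    ]
    return pd.DataFrame(rows, columns=list(CONSENSUS_COLUMNS))


def _dot_escape(s: str) -> str:
    return '"' + s.replace('"', '\\"') + '"'


def export_graph(graph, fmt: str, path: str | Path) -> Path:
    """Serialize an undirected weight network or a consensus DAG.

    Formats: graphml, dot, csv, json.  Arc/edge order is stable
    (sorted by node names) so exports are deterministic.
    """
    path = Path(path)
    if isinstance(graph, RPCNetwork):
        g = graph.to_graph()
        directed = False
        edges = sorted(
            (min(u, v), max(u, v), {"weight": d["weight"]})
            for u, v, d in g.edges(data=True)
        )
        nodes = list(graph.nodes)
    elif isinstance(graph, ConsensusGraph):
        directed = True
        nodes = list(graph.nodes)
        edges = [
            (a.from_, a.to, {
                "networks": a.k,
                "learned_strength": a.learned_strength,
                "grand_strength": a.grand_strength,
                "learned_direction": a.learned_direction,
                "grand_direction": a.grand_direction,
            })
            for a in sorted(graph.arcs, key=lambda a: (a.from_, a.to))
        ]
    else:
        raise TypeError(f"cannot export {type(graph).__name__}")

    if fmt == "graphml":
        g = nx.DiGraph() if directed else nx.Graph()
        g.add_nodes_from(nodes)
        for u, v, attrs in edges:
            g.add_edge(u, v, **attrs)
        nx.write_graphml(g, path)
    elif fmt == "dot":
        kind = "digraph" if directed else "graph"
        sep = "->" if directed else "--"
        lines = [f"{kind} G {{"]
        for n in nodes:
            lines.append(f"  {_dot_escape(n)};")
        for u, v, attrs in edges:
            attr_s = ", ".join(f'{k}="{val}"' for k, val in attrs.items())
            lines.append(f"  {_dot_escape(u)} {sep} {_dot_escape(v)} [{attr_s}];")
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "csv":
        if directed:
            consensus_table(graph).to_csv(path, index=False)
        else:
            rows = [{"node_i": u, "node_j": v, **a} for u, v, a in edges]
            pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(path, index=False)
    elif fmt == "json":
        if directed:
            path.write_text(json.dumps(graph.to_dict(), indent=2))
        else:
            path.write_text(json.dumps(
                {"nodes": nodes, "edges": [[u, v, a["weight"]] for u, v, a in edges]},
                indent=2,
            ))
    else:
        raise ValueError(f"unsupported export format {fmt!r}")
    return path


def _subnet_dict(sub: SubnetworkDAG) -> dict:
    return {
        "algorithm": sub.algorithm,
        "transformation": sub.transformation,
        "B": sub.B,
        "nodes": list(sub.nodes),
        "arcs": [
            {"from": u, "to": v, "strength": d["s"], "direction": d["d"]}
            for (u, v), d in sorted(sub.arcs.items())
        ],
        "dropped_direction_unresolved": [list(x) for x in sub.dropped_direction_unresolved],
    }


def subnet_from_dict(d: dict) -> SubnetworkDAG:
    nodes = sorted({x for a in d["arcs"] for x in (a["from"], a["to"])})
    return SubnetworkDAG(
        algorithm=d["algorithm"], transformation=d["transformation"], B=d["B"],
        nodes=d.get("nodes", nodes),
        arcs={(a["from"], a["to"]): {"s": a["strength"], "d": a["direction"]}
              for a in d["arcs"]},
        dropped_direction_unresolved=[tuple(x) for x in d.get("dropped_direction_unresolved", [])],
    )


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def run_from_manifest(manifest: dict | str | Path, cohort: CohortTable, out_dir: str | Path) -> dict:
    """Re-execute a pipeline from a recorded manifest.

    The input table must hash-match the manifest; all configuration
    (thresholds, grid, seeds) is taken from the manifest so deterministic
    outputs reproduce byte-identically."""
    if not isinstance(manifest, dict):
        manifest = load_manifest(manifest)
    if table_hash(cohort) != manifest["input_hash"]:
        raise ValueError("cohort does not match the manifest's input hash")
    cfg = manifest["config"]
    rpcn_config = RPCNConfig(**cfg["rpcn"])
    e = cfg["ensemble"]
    ensemble_config = EnsembleConfig(
        B=e["B"], strength_min=e["strength_min"],
        direction_min_count=e["direction_min_count"],
        algorithms=tuple(e["algorithms"]),
        transformations=tuple(e["transformations"]),
        min_transformations=e["min_transformations"], seed=e["seed"],
    )
    screens = [ScreeningRule(**s) for s in cfg["screens"]]
    blacklist = Blacklist.from_sinks(cfg["blacklist_sinks"])
    return run_pipeline(
        cohort, out_dir, rpcn_config=rpcn_config, ensemble_config=ensemble_config,
        screens=screens, blacklist=blacklist, rpcn_view=cfg["rpcn_view"],
    )


def run_pipeline(
    cohort: CohortTable,
    out_dir: str | Path,
    rpcn_config: RPCNConfig = RPCNConfig(),
    ensemble_config: EnsembleConfig = EnsembleConfig(),
    screens: list[ScreeningRule] | None = None,
    blacklist: Blacklist | None = None,
    rpcn_view: str = "disc5",
    progress: bool = False,
) -> dict:
    """Screens -> complete cases -> transform suite -> RPCN (on the
    five-level discretized view) -> bootstrap ensemble -> consensus ->
    dual-network overlap.  All outputs plus a run manifest land in
    `out_dir`; returns the manifest dict.

    On a stage failure the partial outputs written so far are retained
    and the manifest records the failure point.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if screens is None:
        screens = screens_from_ranges(cohort.schema)
    if blacklist is None:
        blacklist = Blacklist.from_sinks(cohort.sink_forbidden)
    manifest: dict = {
        "version": __version__,
        "input_hash": table_hash(cohort),
        "config": {
            "rpcn": asdict(rpcn_config),
            "ensemble": {
                "B": ensemble_config.B,
                "strength_min": ensemble_config.strength_min,
                "direction_min_count": ensemble_config.direction_count,
                "algorithms": list(ensemble_config.algorithms),
                "transformations": list(ensemble_config.transformations),
                "min_transformations": ensemble_config.min_transformations,
                "seed": ensemble_config.seed,
            },
            "screens": [asdict(s) for s in screens],
            "blacklist_sinks": sorted(blacklist.sink_forbidden),
            "rpcn_view": rpcn_view,
        },
        "timings": {},
        "warnings": [],
        "status": "running",
    }

    def _stage(name):
        manifest["timings"][name] = {"start": time.time()}

    def _done(name):
        manifest["timings"][name]["seconds"] = round(
            time.time() - manifest["timings"][name].pop("start"), 3
        )

    def _flush():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    try:
        _stage("exclusions")
        screened, vlog = apply_screens(cohort, screens)
        complete, rlog = complete_cases(screened)
        vlog.removed_rows_incomplete = rlog.removed_rows_incomplete
        vlog.n_final = rlog.n_final
        vlog.validate()
        (out / "exclusion_log.json").write_text(vlog.to_json())
        complete.to_csv(out / "cohort_clean.csv")
        manifest["n_initial"] = cohort.n
        manifest["n_final"] = complete.n
        _done("exclusions")

        _stage("transforms")
        suite = make_transform_suite(complete)
        for kind, view in suite.items():
            view.table.to_csv(out / f"view_{kind}.csv")
        (out / "transform_manifest.json").write_text(json.dumps(
            {k: {"provenance": v.provenance, "removed_rows": list(v.removed_rows)}
             for k, v in suite.items()}, indent=2, default=str))
        _done("transforms")

        _stage("rpcn")
        net = fit_rpcn(suite[rpcn_view], rpcn_config)
        cent = centrality(net)
        pred = predictability(suite[rpcn_view], net)
        pd.DataFrame({
            "node": cent.nodes, "strength": cent.strength,
            "expected_influence": cent.expected_influence,
            "closeness": cent.closeness, "betweenness": cent.betweenness,
            "predictability": pred,
        }).to_csv(out / "rpcn_centrality.csv", index=False)
        export_graph(net, "csv", out / "rpcn_edges.csv")
        export_graph(net, "graphml", out / "rpcn.graphml")
        manifest["rpcn"] = {
            "edge_count": net.edge_count,
            "selected_lambda": net.selected_lambda,
            "mean_predictability": float(np.mean(pred)),
        }
        _done("rpcn")

        _stage("ensemble")
        subnets = run_ensemble(suite, ensemble_config, blacklist, progress=progress)
        for (algo, kind), sub in sorted(subnets.items()):
            (out / f"subnet_{algo}_{kind}.json").write_text(
                json.dumps(_subnet_dict(sub), indent=2))
        _done("ensemble")

        _stage("consensus")
        cons = consensus_graph(subnets, ensemble_config)
        consensus_table(cons).to_csv(out / "consensus_arcs.csv", index=False)
        export_graph(cons, "graphml", out / "consensus.graphml")
        export_graph(cons, "dot", out / "consensus.dot")
        export_graph(cons, "json", out / "consensus.json")
        manifest["consensus"] = {
            "n_arcs": len(cons.arcs), "acyclic": cons.acyclic,
            "low_grand_direction": [
                [a.from_, a.to] for a in cons.low_grand_direction()
            ],
        }
        _done("consensus")

        _stage("overlap")
        overlap = dual_network_overlap(net, cons)
        (out / "overlap.json").write_text(json.dumps(asdict(overlap), indent=2))
        manifest["overlap"] = {
            "n_shared": overlap.n_shared,
            "shared_percentage": overlap.shared_percentage,
        }
        _done("overlap")

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failure"] = repr(exc)
        _flush()
        raise
    _flush()
    return manifest
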