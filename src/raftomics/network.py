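"""Focus-molecule over-representation scoring of interaction subnetworks.

A candidate subnetwork of ``n`` proteins drawn from a knowledge-base graph
of ``N`` proteins, containing ``f`` of the ``F`` experimental *focus
molecules* present in the graph, is scored by the right-tailed Fisher
exact (hypergeometric) test: score = -log10 P(X >= f).  The knowledge-base
growth algorithm that proposes candidate networks in commercial tools is
proprietary; :func:`generate_candidate_networks` is an explicitly labelled
greedy seed-and-extend stand-in that shares only the scoring rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx

from .enrichment import P_FLOOR, hypergeometric_right_tail

GENERATOR_LABEL = "greedy stand-in (not the proprietary knowledge-base growth algorithm)"


@dataclass(frozen=True)
class NetworkScore:
    """Hypergeometric over-representation score of one candidate subnetwork."""

    network_nodes: frozenset[str]
    focus_count: int  # f: focus molecules inside the network
    focus_total: int  # F: focus molecules present anywhere in the graph
    universe: int  # N: knowledge-base size
    p_value: float
    score: float  # -log10 p


def read_interaction_graph(path: str | Path) -> nx.Graph:
    """Read an edge-list TSV (node_a, node_b, direct|indirect).

    Direct vs indirect interactions share one connectivity role; the flag
    is preserved as an edge attribute for rendering.
    """
    g = nx.Graph()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated fields")
        a, b = parts[0].strip().upper(), parts[1].strip().upper()
        if a == b:
            raise ValueError(f"{path}:{lineno}: self-loop {a}")
        kind = parts[2] if len(parts) > 2 else "direct"
        if kind not in ("direct", "indirect"):
            raise ValueError(f"{path}:{lineno}: edge kind must be direct|indirect, got {kind!r}")
        g.add_edge(a, b, kind=kind)
    return g


def network_score(
    graph: nx.Graph, network_nodes: set[str], focus_set: set[str]
) -> NetworkScore:
    """Score one candidate subnetwork against the focus-molecule set."""
    if not network_nodes:
        raise ValueError("empty network")
    stray = network_nodes - set(graph.nodes)
    if stray:
        raise ValueError(f"network nodes not in graph: {sorted(stray)[:5]}")
    N = graph.number_of_nodes()
    F = len(focus_set & set(graph.nodes))
    n = len(network_nodes)
    f = len(network_nodes & focus_set)
    p = hypergeometric_right_tail(f, F, n, N)
    return NetworkScore(
        network_nodes=frozenset(network_nodes),
        focus_count=f,
        focus_total=F,
        universe=N,
        p_value=p,
        score=-math.log10(max(p, P_FLOOR)),
    )


def generate_candidate_networks(
    graph: nx.Graph,
    focus_set: set[str],
    max_size: int = 35,
    n_candidates: int = 10,
    seed: int | None = None,
) -> list[NetworkScore]:
    """Greedy seed-and-extend candidate generation (documented stand-in).

    From each focus node present in the graph, repeatedly add the neighbor
    that maximizes the marginal focus density of the growing node set
    until ``max_size`` is reached, recording the best-scoring prefix along
    the way.  Candidates are de-duplicated by node set and ranked by score
    descending; all ties break lexicographically so the output is
    deterministic (``seed`` is accepted for interface stability but the
    procedure itself is deterministic).
    """
    focus_in_graph = sorted(focus_set & set(graph.nodes))
    if not focus_in_graph:
        raise ValueError("no focus molecule is present in the graph")

    candidates: dict[frozenset[str], NetworkScore] = {}

    def consider(nodes: set[str]) -> None:
        key = frozenset(nodes)
        if key not in candidates:
            candidates[key] = network_score(graph, nodes, focus_set)

    for start in focus_in_graph:
        nodes = {start}
        consider(nodes)
        while len(nodes) < max_size:
            frontier = sorted(
                {nb for u in nodes for nb in graph.neighbors(u)} - nodes
            )
            if not frontier:
                break
            # prefer focus nodes, then higher focus-neighbor count, then name
            def cost(cand: str) -> tuple[int, int, str]:
                focus_nb = sum(1 for nb in graph.neighbors(cand) if nb in focus_set)
                return (-int(cand in focus_set), -focus_nb, cand)

            best = min(frontier, key=cost)
            nodes.add(best)
            consider(nodes)

    ranked = sorted(
        candidates.values(),
        key=lambda ns: (-ns.score, tuple(sorted(ns.network_nodes))),
    )
    return ranked[:n_candidates]


def scores_to_rows(scores: Sequence[NetworkScore]) -> list[dict]:
    return [
        {
            "rank": i + 1,
            "n_nodes": len(ns.network_nodes),
            "focus_count": ns.focus_count,
            "focus_total": ns.focus_total,
            "universe": ns.universe,
            "p_value": ns.p_value,
            "score": ns.score,
            "nodes": ",".join(sorted(ns.network_nodes)),
            "generator": GENERATOR_LABEL,
        }
        for i, ns in enumerate(scores)
    ]
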