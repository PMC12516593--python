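"""Player match networks and their community structure.

Two players who meet for a game share an edge; edge weights count the
games between the pair. Per period (era or time bin) the module reports
the classic small-world statistics — average shortest-path length (in
unweighted hops, over the main component) and average local clustering —
and a community partition of the main component found by greedy modularity
maximization (Clauset–Newman–Moore agglomeration, weight-aware).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .corpus import GameRecord
from .diversity import shannon_diversity, tally_variants


@dataclass
class MatchNetwork:
    graph: nx.Graph
    period: object | None = None
    n_skipped: int = 0            # games missing a player id

    @property
    def n_players(self) -> int:
        return self.graph.number_of_nodes()


def build_network(games: Sequence[GameRecord],
                  period: object | None = None) -> MatchNetwork:
    """Weighted player-player graph; weight = games between the pair.

    Games missing either player id (or played against oneself) are skipped
    and counted in ``n_skipped``.
    """
    g = nx.Graph()
    skipped = 0
    for game in games:
        a, b = game.black_player, game.white_player
        if not a or not b or a == b:
            skipped += 1
            continue
        if g.has_edge(a, b):
            g[a][b]["weight"] += 1
        else:
            g.add_edge(a, b, weight=1)
        for node, nat in ((a, game.nationality_black), (b, game.nationality_white)):
            if nat is not None:
                g.nodes[node]["nationality"] = nat
    return MatchNetwork(graph=g, period=period, n_skipped=skipped)


def main_component(net: MatchNetwork) -> nx.Graph:
    """The largest connected component (ties broken by smallest node id)."""
    if net.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = sorted(nx.connected_components(net.graph),
                   key=lambda c: (-len(c), min(c)))
    return net.graph.subgraph(comps[0]).copy()


@dataclass(frozen=True)
class NetworkStats:
    avg_path_length: float | None     # None for a single-node network
    avg_transitivity: float
    n_components: int
    main_component_size: int


def network_stats(net: MatchNetwork) -> NetworkStats:
    """Path length and clustering summaries.

    Path length averages unweighted shortest-path hops over all pairs of
    the main component; clustering averages the local coefficient over all
    nodes of the network, with degree-<2 nodes contributing 0.
    """
    main = main_component(net)
    if main.number_of_nodes() > 1:
        apl = nx.average_shortest_path_length(main)
    else:
        apl = None
    clustering = nx.average_clustering(net.graph, count_zeros=True)
    return NetworkStats(
        avg_path_length=apl,
        avg_transitivity=clustering,
        n_components=nx.number_connected_components(net.graph),
        main_component_size=main.number_of_nodes(),
    )


@dataclass
class CommunityPartition:
    assignment: dict[str, int]
    n_communities: int
    mean_size: float
    modularity: float
    communities: list[frozenset] = field(default_factory=list)


def detect_communities(net: MatchNetwork) -> CommunityPartition:
    """Greedy-modularity partition of the main component (weight-aware)."""
    main = main_component(net)
    if main.number_of_nodes() == 1:
        node = next(iter(main.nodes))
        return CommunityPartition({node: 0}, 1, 1.0, 0.0,
                                  [frozenset([node])])
    comms = nx.community.greedy_modularity_communities(main, weight="weight")
    comms = [frozenset(c) for c in comms]
    # deterministic community ids: order by (size desc, smallest member)
    comms.sort(key=lambda c: (-len(c), min(c)))
    assignment = {node: i for i, c in enumerate(comms) for node in c}
    mod = nx.community.modularity(main, comms, weight="weight")
    return CommunityPartition(
        assignment=assignment,
        n_communities=len(comms),
        mean_size=main.number_of_nodes() / len(comms),
        modularity=mod,
        communities=comms,
    )


def community_series(games_by_period: Mapping, depth: int = 2) -> pd.DataFrame:
    """Per-period network/community summary joined with opening diversity.

    Returns columns (period, n_games, n_players, n_components,
    main_component_size, n_communities, mean_size, modularity,
    avg_path_length, avg_transitivity, hill1).
    """
    rows = []
    for period in games_by_period:
        games = games_by_period[period]
        net = build_network(games, period=period)
        if net.graph.number_of_nodes() == 0:
            continue
        stats = network_stats(net)
        part = detect_communities(net)
        try:
            hill1 = shannon_diversity(tally_variants(games, depth=depth))
        except ValueError:
            hill1 = float("nan")
        rows.append({
            "period": str(period),
            "n_games": len(games),
            "n_players": net.n_players,
            "n_components": stats.n_components,
            "main_component_size": stats.main_component_size,
            "n_communities": part.n_communities,
            "mean_size": part.mean_size,
            "modularity": part.modularity,
            "avg_path_length": stats.avg_path_length,
            "avg_transitivity": stats.avg_transitivity,
            "hill1": hill1,
        })
    return pd.DataFrame(rows)


def edges_table(net: MatchNetwork) -> pd.DataFrame:
    rows = [{"player_a": min(a, b), "player_b": max(a, b), "weight": d["weight"]}
            for a, b, d in net.graph.edges(data=True)]
    rows.sort(key=lambda r: (r["player_a"], r["player_b"]))
    return pd.DataFrame(rows, columns=["player_a", "player_b", "weight"])


def communities_table(part: CommunityPartition,
                      period: object | None = None) -> pd.DataFrame:
    rows = [{"player": p, "community": c,
             "period": str(period) if period is not None else ""}
            for p, c in sorted(part.assignment.items())]
    return pd.DataFrame(rows, columns=["player", "community", "period"])
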