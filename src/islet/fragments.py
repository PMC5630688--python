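"""Within-genome origin-group analysis of islands.

Large inserts fragment over time, so several islands of one genome may
descend from a single acquisition.  Fragments of one insert should still
share high usage-pattern similarity (>80%) and sit at about the same
compositional distance from the host (within 15 percentage points).
Islands that have drifted to within 15% of the host pattern are excluded
as ameliorated — their mutual similarity may reflect the host, not a
common origin — and islands bridging two otherwise distinct groups are
set aside as intermediates.  At most 10 groups are reported per genome;
beyond that, groups would overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .oup import OUPattern, pattern_distance, pattern_similarity

__all__ = ["OriginGroupReport", "origin_groups", "islands_vs_origins"]


@dataclass
class OriginGroupReport:
    genome_id: str
    n_islands: int
    groups: list[tuple[str, ...]]                 # origin groups of size >= 2
    singletons: list[str]                         # lone unameliorated islands
    ameliorated: list[str]                        # host distance < min_host_dist
    intermediates: list[str]                      # linked into >1 group
    unresolved: list[str] = field(default_factory=list)  # beyond max_groups
    host_distances: dict[str, float] = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_origins_incl_singletons(self) -> int:
        return len(self.groups) + len(self.singletons)


def origin_groups(
    islands: dict[str, OUPattern],
    host_pattern: OUPattern,
    genome_id: str = "genome",
    sim_threshold: float = 80.0,
    host_dist_band: float = 15.0,
    min_host_dist: float = 15.0,
    max_groups: int = 10,
) -> OriginGroupReport:
    """Group one genome's islands into putative single-acquisition origins.

    Steps: (1) exclude ameliorated islands (pattern distance to host below
    ``min_host_dist``); (2) link remaining pairs with similarity above
    ``sim_threshold`` whose host distances differ by at most
    ``host_dist_band``; (3) set aside intermediates — islands that connect
    two components that are distinct without them; (4) groups are the
    remaining connected components of size >= 2; (5) only the
    ``max_groups`` largest groups are kept, the rest marked unresolved.
    Deterministic and independent of input order.
    """
    ids = sorted(islands)
    dist = {i: pattern_distance(islands[i], host_pattern) for i in ids}
    ameliorated = [i for i in ids if dist[i] < min_host_dist]
    kept = [i for i in ids if dist[i] >= min_host_dist]

    g = nx.Graph()
    g.add_nodes_from(kept)
    for a_idx in range(len(kept)):
        for b_idx in range(a_idx + 1, len(kept)):
            a, b = kept[a_idx], kept[b_idx]
            if (
                pattern_similarity(islands[a], islands[b]) > sim_threshold
                and abs(dist[a] - dist[b]) <= host_dist_band
            ):
                g.add_edge(a, b)

    # intermediates: removing the island leaves >= 2 components among its
    # neighbours -> it bridges distinct nascent groups
    intermediates = []
    for x in kept:
        nbrs = set(g.adj[x])
        if len(nbrs) < 2:
            continue
        h = g.copy()
        h.remove_node(x)
        comp_ids = set()
        for comp_idx, comp in enumerate(nx.connected_components(h)):
            if comp & nbrs:
                comp_ids.add(comp_idx)
        if len(comp_ids) >= 2:
            intermediates.append(x)
    g.remove_nodes_from(intermediates)

    comps = sorted(
        (tuple(sorted(c)) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c),
    )
    groups = [c for c in comps if len(c) >= 2]
    singletons = [c[0] for c in comps if len(c) == 1]

    unresolved: list[str] = []
    if len(groups) > max_groups:
        for extra in groups[max_groups:]:
            unresolved.extend(extra)
        groups = groups[:max_groups]

    return OriginGroupReport(
        genome_id=genome_id,
        n_islands=len(ids),
        groups=groups,
        singletons=sorted(singletons),
        ameliorated=ameliorated,
        intermediates=sorted(intermediates),
        unresolved=sorted(unresolved),
        host_distances=dist,
    )


def islands_vs_origins(reports) -> pd.DataFrame:
    """Scatter table of island count vs origin count per genome."""
    return pd.DataFrame(
        [
            (
                r.genome_id,
                r.n_islands,
                r.n_groups,
                r.n_origins_incl_singletons,
            )
            for r in reports
        ],
        columns=["genome", "n_islands", "n_groups", "n_origins_incl_singletons"],
    )
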