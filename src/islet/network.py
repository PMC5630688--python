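"""Island ontology network: OUP similarity graph, MCL clustering,
representatives, heuristic search and link statistics.

Islands whose usage patterns agree above a similarity floor (75% by
default) are assumed to share ancestry; the all-vs-all similarity graph is
clustered with the Markov Cluster algorithm.  Similarities above a ceiling
(85%) are weight-capped so that near-duplicate islands from closely
related genomes cannot dominate the random-walk flow.  Every cluster (and
every subcluster of clusters larger than 50) receives representatives —
the members with most links in the 75–85% band — chosen greedily until
every member is within the floor of some representative; a query is then
searched representative-first: only clusters whose representative matches
above the floor are scanned in full.

Sequence-homology links (BLAST tabular) are ingested, not computed, and
can be profiled against the OUP links per island and per taxonomic rank
of the host pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .oup import OUPattern, pattern_similarity

__all__ = [
    "SimilarityLink",
    "IslandCluster",
    "LinkProfile",
    "build_graph",
    "mcl",
    "subcluster",
    "select_representatives",
    "assign_representatives",
    "heuristic_search",
    "read_sequence_links",
    "link_profile",
    "TAXONOMIC_LEVELS",
]


@dataclass(frozen=True)
class SimilarityLink:
    """Undirected island-island link (ids in canonical order)."""

    island_a: str
    island_b: str
    oup_similarity: float | None = None
    clustering_weight: float | None = None
    seq_evalue: float | None = None


@dataclass
class IslandCluster:
    id: str
    members: list[str]
    representatives: list[str] = field(default_factory=list)
    subclusters: list["IslandCluster"] = field(default_factory=list)
    converged: bool = True

    @property
    def size(self) -> int:
        return len(self.members)

    def search_units(self) -> list["IslandCluster"]:
        """The units used for representative-first search: subclusters when
        present, otherwise the cluster itself."""
        return self.subclusters if self.subclusters else [self]


def build_graph(
    patterns: dict[str, OUPattern],
    floor: float = 75.0,
    ceiling: float = 85.0,
) -> nx.Graph:
    """All-vs-all similarity graph over ``patterns``.

    Edges exist for pairs at or above ``floor``; the MCL weight is the raw
    similarity capped at ``ceiling`` while the raw value is kept on the
    edge (``raw`` attribute).
    """
    ids = sorted(patterns)
    g = nx.Graph()
    g.add_nodes_from(ids)
    rank_matrix = np.vstack([patterns[i].ranks for i in ids])
    n = rank_matrix.shape[1]
    rmax = (n * n) // 2
    for i in range(len(ids)):
        disp = np.abs(rank_matrix[i + 1 :] - rank_matrix[i]).sum(axis=1)
        sims = 100.0 * (1.0 - disp / rmax)
        for j_off, s in enumerate(sims):
            if s >= floor:
                g.add_edge(
                    ids[i],
                    ids[i + 1 + j_off],
                    raw=float(s),
                    weight=float(min(s, ceiling)),
                )
    g.graph["floor"] = floor
    g.graph["ceiling"] = ceiling
    return g


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-6,
    prune: float = 1e-8,
    id_prefix: str = "C",
) -> list[IslandCluster]:
    """Markov Cluster algorithm on the weighted graph.

    Column-normalised adjacency with self-loops (weight = the node's
    maximum incident weight), iterating expansion (matrix square) and
    inflation (elementwise power, renormalise) to convergence; clusters
    are the connected components of the limit matrix's support.  Every
    node lands in exactly one cluster; disconnected input components can
    never merge.
    """
    if graph.number_of_nodes() == 0:
        return []
    nodes = sorted(graph.nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    loop = A.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(A, loop)
    M = A / A.sum(axis=0)

    converged = False
    for _ in range(max_iter):
        M2 = M @ M
        np.power(M2, inflation, out=M2)
        M2[M2 < prune] = 0.0
        colsum = M2.sum(axis=0)
        colsum[colsum == 0] = 1.0
        M2 /= colsum
        delta = float(np.abs(M2 - M).max())
        M = M2
        if delta < tol:
            converged = True
            break

    support = nx.Graph()
    support.add_nodes_from(range(len(nodes)))
    r, c = np.nonzero(M > prune)
    support.add_edges_from(zip(r.tolist(), c.tolist()))
    comps = [sorted(nodes[i] for i in comp) for comp in nx.connected_components(support)]
    comps.sort(key=lambda m: (-len(m), m[0]))
    return [
        IslandCluster(id=f"{id_prefix}{k + 1}", members=m, converged=converged)
        for k, m in enumerate(comps)
    ]


def subcluster(
    clusters: list[IslandCluster],
    graph: nx.Graph,
    size_threshold: int = 50,
    inflation_sub: float = 3.0,
) -> list[IslandCluster]:
    """Re-cluster every cluster larger than ``size_threshold`` at higher
    inflation on its induced subgraph; smaller clusters are untouched."""
    for cl in clusters:
        if cl.size > size_threshold:
            sub = graph.subgraph(cl.members)
            cl.subclusters = mcl(sub, inflation=inflation_sub, id_prefix=f"{cl.id}.S")
        else:
            cl.subclusters = []
    return clusters


# ---------------------------------------------------------------------------
# representatives
# ---------------------------------------------------------------------------

def _band_degree(graph: nx.Graph, u: str, pool: set[str], floor: float, ceiling: float) -> int:
    deg = 0
    for v in graph.adj[u]:
        if v in pool and v != u and floor <= graph.adj[u][v]["raw"] <= ceiling:
            deg += 1
    return deg


def select_representatives(
    members: list[str],
    graph: nx.Graph,
    floor: float = 75.0,
    ceiling: float = 85.0,
) -> list[str]:
    """Greedy omnipresent representative set for one cluster/subcluster.

    Repeatedly picks the uncovered member with the most links in the
    [floor, ceiling] band to other uncovered members (ties broken
    lexicographically); a member counts as covered once some
    representative matches it at or above the floor.  Terminates with
    every member covered.
    """
    uncovered = set(members)
    reps: list[str] = []
    while uncovered:
        best = max(
            sorted(uncovered),
            key=lambda u: _band_degree(graph, u, uncovered, floor, ceiling),
        )
        reps.append(best)
        newly = {best}
        for v in graph.adj[best]:
            if v in uncovered and graph.adj[best][v]["raw"] >= floor:
                newly.add(v)
        uncovered -= newly
    return reps


def assign_representatives(
    clusters: list[IslandCluster],
    graph: nx.Graph,
    floor: float = 75.0,
    ceiling: float = 85.0,
) -> list[IslandCluster]:
    """Populate representatives for every cluster and subcluster."""
    for cl in clusters:
        for sub in cl.subclusters:
            sub.representatives = select_representatives(sub.members, graph, floor, ceiling)
        if cl.subclusters:
            cl.representatives = sorted(
                {r for sub in cl.subclusters for r in sub.representatives}
            )
        else:
            cl.representatives = select_representatives(cl.members, graph, floor, ceiling)
    return clusters


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def heuristic_search(
    query: OUPattern,
    clusters: list[IslandCluster],
    patterns: dict[str, OUPattern],
    floor: float = 75.0,
) -> list[tuple[str, float]]:
    """Representative-first similarity search.

    Stage 1 compares the query with every cluster/subcluster
    representative; stage 2 scans all members of the units whose best
    representative scored at or above ``floor``.  Hits at or above the
    floor are returned sorted by descending similarity (ties by id).
    Units whose representative misses the floor are skipped entirely, so
    some true links may be overlooked — the price of the heuristic.
    """
    hits: dict[str, float] = {}
    for cl in clusters:
        for unit in cl.search_units():
            best = max(
                (pattern_similarity(query, patterns[r]) for r in unit.representatives),
                default=-1.0,
            )
            if best < floor:
                continue
            for m in unit.members:
                s = pattern_similarity(query, patterns[m])
                if s >= floor:
                    hits[m] = max(hits.get(m, -1.0), s)
    return sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# sequence links & statistics
# ---------------------------------------------------------------------------

def read_sequence_links(path, evalue_cutoff: float = 1e-6) -> dict[tuple[str, str], float]:
    """Read 12-column BLAST tabular output into undirected homology links.

    Records above the e-value cutoff and self-hits are dropped; duplicate
    pairs collapse to their best (lowest) e-value.  Malformed rows raise
    with their line number.
    """
    links: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            q, s = parts[0], parts[1]
            try:
                evalue = float(parts[10])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad e-value {parts[10]!r}") from exc
            if q == s or evalue > evalue_cutoff:
                continue
            key = (q, s) if q < s else (s, q)
            if key not in links or evalue < links[key]:
                links[key] = evalue
    return links


TAXONOMIC_LEVELS = (
    "Genome",
    "Strain",
    "Species",
    "Genus",
    "Family",
    "Order",
    "Phylum",
    "Domain",
)

# lineage strings are semicolon-delimited, most general rank first:
# Domain;Phylum;Order;Family;Genus;Species;Strain
_RANK_BY_FIELD = ("Domain", "Phylum", "Order", "Family", "Genus", "Species", "Strain")


def _pair_level(host_a: str, host_b: str, lin_a: str, lin_b: str) -> str:
    if host_a == host_b:
        return "Genome"
    fa, fb = lin_a.split(";"), lin_b.split(";")
    if len(fa) != len(_RANK_BY_FIELD) or len(fb) != len(_RANK_BY_FIELD):
        raise ValueError("lineage strings must have 7 semicolon-delimited ranks")
    for rank, a, b in zip(_RANK_BY_FIELD, fa, fb):
        if a != b:
            return rank
    return "Strain"  # identical lineage on different replicons


@dataclass
class LinkProfile:
    """Per-island link counts and the per-taxonomic-level OUP link table."""

    per_island: pd.DataFrame     # island, n_oup_links, n_seq_links
    rank_table: pd.DataFrame     # level, count, mean, q25, median, q75


def link_profile(
    oup_links,
    seq_links,
    hosts: dict[str, str],
    lineages: dict[str, str],
) -> LinkProfile:
    """Profile OUP links against sequence links.

    ``oup_links`` is an iterable of (island_a, island_b, similarity);
    ``seq_links`` an iterable of (island_a, island_b) pairs (or a mapping
    with such keys); ``hosts`` maps island id to its replicon and
    ``lineages`` maps replicon id to its lineage string.  Each OUP link is
    assigned to the lowest taxonomic level at which the two hosts differ;
    islands whose host lacks lineage data stay in the per-island counts
    but are excluded from the rank table.
    """
    oup_links = list(oup_links)
    seq_pairs = list(seq_links.keys()) if hasattr(seq_links, "keys") else list(seq_links)

    counts: dict[str, list[int]] = {}
    for a, b, _s in oup_links:
        for x in (a, b):
            counts.setdefault(x, [0, 0])[0] += 1
    for a, b in seq_pairs:
        for x in (a, b):
            counts.setdefault(x, [0, 0])[1] += 1
    per_island = pd.DataFrame(
        [(i, c[0], c[1]) for i, c in sorted(counts.items())],
        columns=["island", "n_oup_links", "n_seq_links"],
    )

    by_level: dict[str, list[float]] = {lvl: [] for lvl in TAXONOMIC_LEVELS}
    for a, b, s in oup_links:
        ha, hb = hosts.get(a), hosts.get(b)
        if ha is None or hb is None:
            continue
        la, lb = lineages.get(ha), lineages.get(hb)
        if (la is None or lb is None) and ha != hb:
            continue
        by_level[_pair_level(ha, hb, la or "", lb or "")].append(float(s))

    rows = []
    for lvl in TAXONOMIC_LEVELS:
        vals = np.array(by_level[lvl])
        if vals.size:
            rows.append(
                (lvl, vals.size, vals.mean(), *np.percentile(vals, [25, 50, 75]))
            )
        else:
            rows.append((lvl, 0, np.nan, np.nan, np.nan, np.nan))
    rank_table = pd.DataFrame(
        rows, columns=["level", "count", "mean", "q25", "median", "q75"]
    )
    return LinkProfile(per_island=per_island, rank_table=rank_table)
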