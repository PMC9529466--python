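"""WalkTrap community detection (random-walk distances, agglomerative merging,
modularity-optimal cut).

The algorithm exploits the fact that a short random walk started inside a
dense module tends to stay inside it.  For walk length ``t`` the node profile
is the i-th row of ``P^t`` with ``P = D^-1 A`` (transition by uniform edge
choice), and the distance between communities C1, C2 compares their mean
member profiles, weighted by inverse degree:

    r(C1, C2)^2 = sum_k (P_C1[k] - P_C2[k])^2 / d(k)

Starting from singleton communities, the pair of *adjacent* communities
minimizing the merge cost

    delta_sigma = (1/n) * |C1||C2| / (|C1| + |C2|) * r(C1, C2)^2

is merged repeatedly until one community per connected component remains.
The dendrogram is then cut at the merge level maximizing Newman-Girvan
modularity Q.  Components are processed independently (Q is additive over
components); isolated nodes bypass the walk and become singleton modules.

Dense ``P^t`` powers are used throughout: the target networks here are
seed-gene subnetworks of at most a few thousand nodes, where the O(n^3)
matrix power and the O(m n) merge updates are a non-issue.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .network import PPINetwork

logger = logging.getLogger(__name__)


class WalktrapError(ValueError):
    pass


def _nkey(node):
    # deterministic order even for mixed node types; numbers sort numerically
    if isinstance(node, (int, float)):
        return (0, node, "")
    return (1, 0, str(node))


def singleton_ids(net: "PPINetwork | nx.Graph") -> dict:
    """Node -> initial community id mapping used by the merge history (ids
    0..n-1 in deterministic node order; merged communities get ids n, n+1...
    in merge order)."""
    g = _as_graph(net)
    return {node: i for i, node in enumerate(sorted(g.nodes, key=_nkey))}


@dataclass(frozen=True)
class WalkParams:
    """Walk length ``t`` (>= 1).  t = 4 is the canonical default: long enough
    to feel module density, short enough not to mix across sparse cuts."""

    t: int = 4

    def __post_init__(self) -> None:
        if self.t < 1:
            raise WalktrapError("walk length t must be >= 1")


@dataclass
class CommunityPartition:
    assignment: dict[str, int]
    modularity: float
    merge_history: list[tuple[int, int, float]] = field(default_factory=list)

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, mid in self.assignment.items():
            out.setdefault(mid, []).append(node)
        for mid in out:
            out[mid].sort()
        return out


def _as_graph(net: PPINetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, PPINetwork) else net


def walk_probabilities(
    net: PPINetwork | nx.Graph, t: int
) -> tuple[list, np.ndarray]:
    """t-step transition probability matrix over the (sorted) non-isolated
    node set; each row sums to 1."""
    if t < 1:
        raise WalktrapError("walk length t must be >= 1")
    g = _as_graph(net)
    nodes = sorted(n for n in g.nodes if g.degree(n) > 0)
    if not nodes:
        return [], np.empty((0, 0))
    a = nx.to_numpy_array(g, nodelist=nodes)
    p = a / a.sum(axis=1, keepdims=True)
    return nodes, np.linalg.matrix_power(p, t)


def modularity(net: PPINetwork | nx.Graph, assignment: Mapping[str, int]) -> float:
    """Newman-Girvan Q = sum_c [ l_c/m - (d_c/2m)^2 ] over modules c, with m
    the total edge count, l_c within-module edges and d_c the module degree
    sum.  Defined as 0 (with a warning) for edgeless graphs."""
    g = _as_graph(net)
    missing = set(g.nodes) - set(assignment)
    if missing:
        raise WalktrapError(f"assignment does not cover nodes {sorted(missing)[:5]}")
    m = g.number_of_edges()
    if m == 0:
        logger.warning("modularity of an edgeless graph defined as 0")
        return 0.0
    within: dict[int, int] = {}
    degsum: dict[int, int] = {}
    for u, v in g.edges:
        if assignment[u] == assignment[v]:
            within[assignment[u]] = within.get(assignment[u], 0) + 1
    for node, d in g.degree():
        c = assignment[node]
        degsum[c] = degsum.get(c, 0) + d
    q = 0.0
    for c in set(assignment.values()):
        q += within.get(c, 0) / m - (degsum.get(c, 0) / (2.0 * m)) ** 2
    return q


def walktrap_partition(
    net: PPINetwork | nx.Graph, params: WalkParams = WalkParams()
) -> CommunityPartition:
    """Full WalkTrap run: merge history + modularity-optimal cut.

    Deterministic throughout: nodes are processed in sorted order, merge ties
    on delta-sigma break on the (smaller, larger) community-id pair, and the
    cut picks the earliest merge level attaining the maximal Q.  Final module
    ids are assigned by decreasing module size, ties by lexicographically
    smallest member.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise WalktrapError("empty network")

    m_total = g.number_of_edges()
    # community bookkeeping, global across components
    comm_members: dict[int, list] = {}
    merge_history: list[tuple[int, int, float]] = []
    # chosen (per component) community sets at the optimal cut
    final_groups: list[list] = []

    next_cid = 0
    node_cid: dict = {}
    for node in sorted(g.nodes, key=_nkey):
        node_cid[node] = next_cid
        comm_members[next_cid] = [node]
        next_cid += 1

    components = sorted(nx.connected_components(g), key=lambda c: min(_nkey(n) for n in c))
    for comp in components:
        comp_nodes = sorted(comp, key=_nkey)
        if len(comp_nodes) == 1 or g.subgraph(comp_nodes).number_of_edges() == 0:
            final_groups.append(list(comp_nodes))
            continue
        groups, history = _walktrap_component(
            g, comp_nodes, params.t, m_total, node_cid, comm_members, next_cid
        )
        next_cid += len(history)
        merge_history.extend(history)
        final_groups.extend(groups)

    # module ids by decreasing size, ties by smallest member
    final_groups.sort(key=lambda grp: (-len(grp), min(_nkey(n) for n in grp)))
    assignment = {
        node: mid for mid, grp in enumerate(final_groups) for node in grp
    }
    q = modularity(g, assignment) if m_total > 0 else 0.0
    return CommunityPartition(assignment=assignment, modularity=q, merge_history=merge_history)


def _walktrap_component(
    g: nx.Graph,
    comp_nodes: list,
    t: int,
    m_total: int,
    node_cid: dict,
    comm_members: dict[int, list],
    next_cid: int,
):
    """Agglomerate one connected component; returns (groups at optimal cut,
    merge history)."""
    idx = {n: i for i, n in enumerate(comp_nodes)}
    sub = g.subgraph(comp_nodes)
    a = nx.to_numpy_array(sub, nodelist=comp_nodes)
    deg = a.sum(axis=1)
    pt = np.linalg.matrix_power(a / deg[:, None], t)
    inv_deg = 1.0 / deg
    n_comp = len(comp_nodes)

    # live community state
    profile: dict[int, np.ndarray] = {}   # mean member profile
    size: dict[int, int] = {}
    neighbors: dict[int, set[int]] = {}
    within: dict[int, int] = {}           # within-community edge count
    degsum: dict[int, float] = {}
    between: dict[frozenset, int] = {}    # inter-community edge counts

    for node in comp_nodes:
        cid = node_cid[node]
        profile[cid] = pt[idx[node]]
        size[cid] = 1
        neighbors[cid] = set()
        within[cid] = 0
        degsum[cid] = deg[idx[node]]
    for u, v in sub.edges:
        cu, cv = node_cid[u], node_cid[v]
        neighbors[cu].add(cv)
        neighbors[cv].add(cu)
        between[frozenset((cu, cv))] = between.get(frozenset((cu, cv)), 0) + 1

    def delta_sigma(c1: int, c2: int) -> float:
        diff = profile[c1] - profile[c2]
        r2 = float(np.dot(diff * diff, inv_deg))
        s1, s2 = size[c1], size[c2]
        return (s1 * s2) / (s1 + s2) / n_comp * r2

    heap: list[tuple[float, int, int]] = []
    for c1 in sorted(neighbors):
        for c2 in neighbors[c1]:
            if c1 < c2:
                heapq.heappush(heap, (delta_sigma(c1, c2), c1, c2))

    alive = set(profile)
    # Q contribution of this component, tracked incrementally along merges
    q_now = sum(
        within[c] / m_total - (degsum[c] / (2.0 * m_total)) ** 2 for c in alive
    )
    q_levels = [q_now]
    history: list[tuple[int, int, float]] = []

    while len(alive) > 1:
        while True:
            d, c1, c2 = heapq.heappop(heap)
            if c1 in alive and c2 in alive:
                break
        new = next_cid + len(history)
        history.append((c1, c2, d))

        lk = frozenset((c1, c2))
        l12 = between.pop(lk, 0)
        q_now -= within[c1] / m_total - (degsum[c1] / (2.0 * m_total)) ** 2
        q_now -= within[c2] / m_total - (degsum[c2] / (2.0 * m_total)) ** 2
        size[new] = size[c1] + size[c2]
        within[new] = within[c1] + within[c2] + l12
        degsum[new] = degsum[c1] + degsum[c2]
        q_now += within[new] / m_total - (degsum[new] / (2.0 * m_total)) ** 2
        q_levels.append(q_now)

        profile[new] = (
            size[c1] * profile[c1] + size[c2] * profile[c2]
        ) / size[new]
        comm_members[new] = comm_members[c1] + comm_members[c2]
        nbrs = (neighbors[c1] | neighbors[c2]) - {c1, c2}
        neighbors[new] = nbrs
        for nb in nbrs:
            cnt = between.pop(frozenset((c1, nb)), 0) + between.pop(
                frozenset((c2, nb)), 0
            )
            if cnt:
                between[frozenset((new, nb))] = cnt
            neighbors[nb].discard(c1)
            neighbors[nb].discard(c2)
            neighbors[nb].add(new)
        alive.discard(c1)
        alive.discard(c2)
        alive.add(new)
        for c in (c1, c2):
            del profile[c], size[c], within[c], degsum[c], neighbors[c]
        for nb in sorted(nbrs):
            lo, hi = min(new, nb), max(new, nb)
            heapq.heappush(heap, (delta_sigma(lo, hi), lo, hi))

    best_level = int(np.argmax(q_levels))

    # replay merges up to the best level to recover the cut
    parent: dict[int, int] = {}
    for step, (c1, c2, _) in enumerate(history[:best_level]):
        new = next_cid + step
        parent[c1] = new
        parent[c2] = new

    def root(c: int) -> int:
        while c in parent:
            c = parent[c]
        return c

    groups: dict[int, list] = {}
    for node in comp_nodes:
        groups.setdefault(root(node_cid[node]), []).append(node)
    return list(groups.values()), history


def write_partition(
    part: CommunityPartition,
    net: PPINetwork | nx.Graph,
    assignment_path,
    summary_path,
    history_path,
) -> None:
    """Partition TSV (node, module_id), per-module summary (size, within
    edges) and the merge history for dendrogram reconstruction."""
    g = _as_graph(net)
    pd.DataFrame(
        sorted(part.assignment.items()), columns=["node", "module_id"]
    ).to_csv(assignment_path, sep="\t", index=False)
    within: dict[int, int] = {}
    for u, v in g.edges:
        if part.assignment[u] == part.assignment[v]:
            within[part.assignment[u]] = within.get(part.assignment[u], 0) + 1
    mods = part.modules()
    pd.DataFrame(
        [
            {"module_id": mid, "size": len(mods[mid]), "within_edges": within.get(mid, 0)}
            for mid in sorted(mods)
        ]
    ).to_csv(summary_path, sep="\t", index=False)
    pd.DataFrame(
        part.merge_history, columns=["module_a", "module_b", "delta_sigma"]
    ).to_csv(history_path, sep="\t", index=False)
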