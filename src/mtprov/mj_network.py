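"""Median-joining haplotype networks.

A clean-room implementation of the median-joining (MJ) network
construction of Bandelt, Forster & Röhl (1999).  Observed haplotypes are
reduced to their variable columns; the algorithm alternates between

1. building the epsilon-relaxed minimum spanning network (the union of
   all minimum spanning trees, plus any link whose length is within
   ``epsilon`` of the bottleneck cost of connecting its endpoints), and
2. proposing *median vectors* — majority-consensus sequences of
   connected triples (two links sharing a node) — and adding, as
   unobserved frequency-zero nodes, every new median whose triple
   connection cost (the summed distance to its three parents) is within
   ``epsilon`` of the round minimum,

until no new median exists.  Obsolete medians — those whose removal
leaves the connection cost (the minimum-spanning-tree length over the
node set) unchanged, or lowers it — are pruned at the end, so useless
intermediates admitted during the search do not survive.  On three-way
ties the median of a triple is ambiguous and every parental state is
kept, generating multiple candidates.  Relaxing ``epsilon`` admits more
links and medians and recovers more parsimonious alternatives, at the
price of a denser network.

Sequences carrying N at a variable site are rejected: medians over
missing states are ill-defined, so such samples must be excluded (or
resolved) upstream by the haplotype collapsing policy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from .haplotypes import HaplotypeTable

_MAX_ROUNDS = 200


class NetworkError(ValueError):
    """Raised for inputs the MJ algorithm cannot handle."""


@dataclass(frozen=True)
class NetworkNode:
    """A network node: an observed haplotype or an inferred median vector."""

    node_id: str
    sequence: str  # over variable-site columns only
    kind: str  # "observed" | "median"
    frequency: int  # 0 for median vectors
    subclade_label: str | None = None


@dataclass(frozen=True)
class HaplotypeNetwork:
    """A connected haplotype network with mutation-count edge weights."""

    graph: nx.Graph  # nodes keyed by node_id, attrs: sequence/kind/frequency
    epsilon: int
    connection_cost: int  # minimum spanning length over the final node set

    @property
    def nodes(self) -> list:
        return [
            NetworkNode(
                node_id=n,
                sequence=d["sequence"],
                kind=d["kind"],
                frequency=d["frequency"],
                subclade_label=d.get("subclade_label"),
            )
            for n, d in sorted(self.graph.nodes(data=True))
        ]

    @property
    def median_nodes(self) -> list:
        return [n for n in self.nodes if n.kind == "median"]

    @property
    def observed_nodes(self) -> list:
        return [n for n in self.nodes if n.kind == "observed"]


def _seq_matrix(seqs: list) -> np.ndarray:
    if not seqs:
        raise NetworkError("no sequences")
    return np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])


def _hamming(mat: np.ndarray) -> np.ndarray:
    if mat.shape[1] == 0:
        return np.zeros((mat.shape[0], mat.shape[0]), dtype=int)
    return (mat[:, None, :] != mat[None, :, :]).sum(axis=2)


def _mst_cost(dist: np.ndarray) -> int:
    if dist.shape[0] <= 1:
        return 0
    return int(round(minimum_spanning_tree(dist.astype(float)).sum()))


def _bottleneck_thresholds(dist: np.ndarray) -> np.ndarray:
    """alpha[i, j] = largest edge on the minimax path between i and j.

    Computed Kruskal-style: process distinct distances in increasing
    order; when two components merge at distance d, every cross pair gets
    threshold d.  An edge (i, j) belongs to some minimum spanning tree iff
    d(i, j) == alpha[i, j]; the epsilon-relaxed network admits every edge
    with d(i, j) <= alpha[i, j] + epsilon.
    """
    k = dist.shape[0]
    alpha = np.zeros((k, k), dtype=int)
    comp = np.arange(k)
    for d in np.unique(dist[np.triu_indices(k, 1)]) if k > 1 else []:
        for i, j in np.argwhere(np.triu(dist == d, 1)):
            if comp[i] != comp[j]:
                mi = comp == comp[i]
                mj = comp == comp[j]
                alpha[np.ix_(mi, mj)] = d
                alpha[np.ix_(mj, mi)] = d
                comp[mj] = comp[i]
    return alpha


def _relaxed_msn_edges(dist: np.ndarray, epsilon: int) -> list:
    alpha = _bottleneck_thresholds(dist)
    k = dist.shape[0]
    return [
        (i, j)
        for i in range(k)
        for j in range(i + 1, k)
        if dist[i, j] <= alpha[i, j] + epsilon
    ]


def _median_candidates(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> list:
    """Majority-state median(s) of a triple; 3-way ties branch per parent."""
    med = np.where((u == v) | (u == w), u, np.where(v == w, v, 0))
    ties = np.flatnonzero(med == 0)  # 0 cannot collide with a base's byte
    if ties.size == 0:
        return [med.astype(np.uint8)]
    out = []
    options = [sorted({int(u[t]), int(v[t]), int(w[t])}) for t in ties]
    for combo in itertools.product(*options):
        m = med.copy()
        m[ties] = combo
        out.append(m.astype(np.uint8))
    return out


def _mj_node_set(seq_mat: np.ndarray, epsilon: int) -> tuple:
    """Run the MJ iteration; returns (final matrix, n_observed kept first)."""
    n_observed = seq_mat.shape[0]
    current = seq_mat.copy()
    seen = {row.tobytes() for row in current}

    for _ in range(_MAX_ROUNDS):
        # drop obsolete medians first: unobserved nodes of degree <= 2 in
        # the current relaxed MSN whose removal keeps the connection cost,
        # or any median whose removal lowers it
        current = _prune(current, n_observed, epsilon)
        dist = _hamming(current)
        edges = _relaxed_msn_edges(dist, epsilon)
        adj: dict = {i: set() for i in range(current.shape[0])}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)

        # candidate medians come from every connected triple (two links
        # sharing a node); their connection cost lambda is the summed
        # distance of the median to its three parents
        candidates: dict = {}
        for u in range(current.shape[0]):
            for v, w in itertools.combinations(sorted(adj[u]), 2):
                for med in _median_candidates(current[u], current[v], current[w]):
                    key = med.tobytes()
                    if key in seen:
                        continue
                    lam = int(
                        (med != current[u]).sum()
                        + (med != current[v]).sum()
                        + (med != current[w]).sum()
                    )
                    if key not in candidates or lam < candidates[key][0]:
                        candidates[key] = (lam, med)
        if not candidates:
            break
        lam_min = min(lam for lam, _ in candidates.values())
        additions = [
            med
            for key, (lam, med) in sorted(candidates.items())
            if lam <= lam_min + epsilon
        ]
        current = np.vstack([current] + additions)
        seen.update(m.tobytes() for m in additions)

    return _prune(current, n_observed, epsilon), n_observed


def _prune(current: np.ndarray, n_observed: int, epsilon: int) -> np.ndarray:
    """Remove obsolete median vectors.

    Repeatedly delete the median whose removal lowers the connection cost
    the most; when no removal lowers it, delete degree-<=2 medians whose
    removal keeps it unchanged (a degree-2 median on a geodesic adds
    nothing).  Removal of a useful branching median would raise the cost,
    so such nodes are never dropped.
    """
    dist = _hamming(current)
    while current.shape[0] > n_observed:
        cost = _mst_cost(dist)
        edges = _relaxed_msn_edges(dist, epsilon)
        degree = np.zeros(current.shape[0], dtype=int)
        for i, j in edges:
            degree[i] += 1
            degree[j] += 1
        best_idx = None
        best_cost = cost
        equal_idx = None
        for idx in range(current.shape[0] - 1, n_observed - 1, -1):
            keep = np.array([x for x in range(current.shape[0]) if x != idx])
            new_cost = _mst_cost(dist[np.ix_(keep, keep)])
            if new_cost < best_cost:
                best_cost = new_cost
                best_idx = idx
            elif new_cost == cost and degree[idx] <= 2 and equal_idx is None:
                equal_idx = idx
        idx = best_idx if best_idx is not None else equal_idx
        if idx is None:
            break
        current = np.delete(current, idx, axis=0)
        dist = np.delete(np.delete(dist, idx, axis=0), idx, axis=1)
    return current


def mj_network_from_sequences(
    sequences: list,
    frequencies: list | None = None,
    epsilon: int = 0,
    node_ids: list | None = None,
) -> HaplotypeNetwork:
    """Build an MJ network from reduced (variable-column) sequences.

    ``sequences`` must be distinct, equal-length strings over
    ``{A, C, G, T, -}``.
    """
    if not sequences:
        raise NetworkError("at least one haplotype is required")
    if len(set(sequences)) != len(sequences):
        raise NetworkError("observed sequences must be distinct")
    for s in sequences:
        if "N" in s:
            raise NetworkError(
                "sequence contains N at a variable site; exclude or resolve "
                "missing data upstream (haplotype collapsing policy)"
            )
    if epsilon < 0:
        raise NetworkError("epsilon must be >= 0")
    frequencies = list(frequencies) if frequencies is not None else [1] * len(sequences)
    node_ids = list(node_ids) if node_ids is not None else [
        f"H{i + 1:03d}" for i in range(len(sequences))
    ]

    # deterministic internal ordering: by (descending frequency, sequence)
    order = sorted(
        range(len(sequences)), key=lambda i: (-frequencies[i], sequences[i])
    )
    seqs = [sequences[i] for i in order]
    freqs = [frequencies[i] for i in order]
    ids = [node_ids[i] for i in order]

    mat = _seq_matrix(seqs)
    final, n_obs = _mj_node_set(mat, epsilon)
    dist = _hamming(final)
    edges = _relaxed_msn_edges(dist, epsilon)

    graph = nx.Graph(epsilon=epsilon)
    labels = []
    for i in range(final.shape[0]):
        seq = final[i].tobytes().decode("ascii")
        if i < n_obs:
            labels.append(ids[i])
            graph.add_node(ids[i], sequence=seq, kind="observed", frequency=freqs[i])
        else:
            mid = f"mv{i - n_obs + 1}"
            labels.append(mid)
            graph.add_node(mid, sequence=seq, kind="median", frequency=0)
    for i, j in edges:
        graph.add_edge(labels[i], labels[j], weight=int(dist[i, j]))
    return HaplotypeNetwork(
        graph=graph, epsilon=epsilon, connection_cost=_mst_cost(dist)
    )


def build_mj_network(table: HaplotypeTable, epsilon: int = 0) -> HaplotypeNetwork:
    """MJ network over the haplotypes of a table (variable columns only).

    Node frequencies are haplotype carrier counts; node ids are the
    deterministic haplotype ids, so the network is reproducible.
    """
    cols = [c - 1 for c in table.variable_sites]
    seqs = ["".join(h.sequence[c] for c in cols) for h in table.haplotypes]
    freqs = [h.total_count for h in table.haplotypes]
    ids = [h.hap_id for h in table.haplotypes]
    net = mj_network_from_sequences(seqs, freqs, epsilon=epsilon, node_ids=ids)
    # annotate observed nodes with their locality breakdown for export
    for h in table.haplotypes:
        net.graph.nodes[h.hap_id]["localities"] = ";".join(
            f"{u}:{c}" for u, c in sorted(h.counts_by_locality.items())
        )
    return net


def subclade_grouping_check(
    network: HaplotypeNetwork, assignments: dict
) -> tuple:
    """Do the haplotypes of each subclade group together on the network?

    ``assignments`` maps every observed node id to its subclade label.
    Median nodes are attributed to the label of their nearest labeled
    neighbor (weighted shortest path; ties resolved toward the
    lexicographically smallest label).  Returns ``(ok, offenders)`` where
    ``offenders`` maps each non-grouping label to the node sets of its
    disconnected components.
    """
    g = network.graph
    observed = [n for n, d in g.nodes(data=True) if d["kind"] == "observed"]
    unlabeled = sorted(set(observed) - set(assignments))
    if unlabeled:
        raise NetworkError(f"unlabeled observed nodes: {unlabeled}")

    label_of = dict(assignments)
    for node, data in g.nodes(data=True):
        if data["kind"] != "median":
            continue
        dists = nx.single_source_dijkstra_path_length(g, node, weight="weight")
        best = min(
            ((dists[o], assignments[o]) for o in observed if o in dists),
            default=None,
        )
        if best is not None:
            label_of[node] = best[1]

    offenders: dict = {}
    for label in sorted(set(assignments.values())):
        members = [n for n, lbl in label_of.items() if lbl == label]
        sub = g.subgraph(members)
        if members and not nx.is_connected(sub):
            comps = sorted(
                (sorted(c) for c in nx.connected_components(sub)), key=len
            )
            offenders[label] = [c for c in comps]
    return (not offenders), offenders


def write_gml(network: HaplotypeNetwork, path) -> None:
    nx.write_gml(network.graph, str(path))


def write_dot(network: HaplotypeNetwork, path) -> None:
    lines = ["graph haplotype_network {"]
    for n, d in sorted(network.graph.nodes(data=True)):
        shape = "circle" if d["kind"] == "observed" else "point"
        lines.append(
            f'  "{n}" [shape={shape}, frequency={d["frequency"]}, '
            f'kind="{d["kind"]}"];'
        )
    for u, v, d in sorted(network.graph.edges(data=True)):
        lines.append(f'  "{u}" -- "{v}" [label={d["weight"]}];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
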