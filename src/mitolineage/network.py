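"""Haplotype classes, median-joining networks, and rooted genealogies.

Samples with identical masked variant profiles collapse into haplotype
classes; classes become binary presence/absence character vectors over the
observed variant labels.  The network builder follows the median-joining
construction: the minimum-spanning network (union of all minimum spanning
trees) over the observed classes is augmented with majority-consensus
median vectors of mutually adjacent triplets, iterated to a fixed point,
after which unsampled median nodes of degree <= 2 are discarded.

A rooted, mutation-weighted genealogy is then extracted for dating: on
small instances the minimum Steiner tree connecting the observed classes
(candidate junctions drawn from the median closure) is computed exactly by
the Dreyfus-Wagner dynamic program, which for binary characters attains
the most-parsimonious tree length; larger instances fall back to a
deterministic minimum-spanning-tree resolution that prefers fewer
mutations, then higher observed multiplicity, then label order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .refio import VariantProfile


class NetworkError(ValueError):
    pass


@dataclass
class HaplotypeClass:
    class_id: str
    profile: VariantProfile
    multiplicity: int
    members: list[str]

    @property
    def labels(self) -> frozenset[str]:
        return self.profile.label_set()


def collapse_haplotypes(profiles: Sequence[VariantProfile]) -> list[HaplotypeClass]:
    """Partition samples into classes of identical masked variant-label sets."""
    groups: dict[frozenset[str], list[VariantProfile]] = {}
    for p in profiles:
        groups.setdefault(p.label_set(), []).append(p)
    ordered = sorted(groups.items(), key=lambda kv: tuple(sorted(kv[0])))
    out = []
    for i, (labels, members) in enumerate(ordered, start=1):
        ids = sorted(m.sample_id for m in members)
        out.append(HaplotypeClass(
            class_id=f"hap{i:03d}", profile=members[0],
            multiplicity=len(members), members=ids))
    return out


# ---------------------------------------------------------------------------
# median-joining network


def _distance(a: frozenset, b: frozenset, weights: Mapping[str, float] | None) -> float:
    diff = a ^ b
    if weights is None:
        return float(len(diff))
    return float(sum(weights.get(ch, 1.0) for ch in diff))


def _msn_edges(nodes: dict[str, frozenset], epsilon: float,
               weights: Mapping[str, float] | None) -> list[tuple[str, str, float]]:
    """Minimum-spanning-network edges (all MST-tied links, plus epsilon slack).

    A pair is linked when its distance is within ``epsilon`` of the level at
    which its two components first become connected in the Kruskal sweep.
    """
    ids = sorted(nodes)
    if len(ids) == 1:
        return []
    d = {(u, v): _distance(nodes[u], nodes[v], weights)
         for u, v in itertools.combinations(ids, 2)}
    parent = {u: u for u in ids}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    conn_level: dict[tuple[str, str], float] = {}
    for level in sorted(set(d.values())):
        merging = [(u, v) for (u, v), dist in d.items()
                   if dist == level and find(u) != find(v)]
        # record the connection level for every pair joined at this sweep step
        comp_before = {u: find(u) for u in ids}
        for u, v in merging:
            parent[find(u)] = find(v)
        for u, v in itertools.combinations(ids, 2):
            if (u, v) not in conn_level and find(u) == find(v) \
                    and comp_before[u] != comp_before[v]:
                conn_level[(u, v)] = level
    edges = []
    for (u, v), dist in d.items():
        lvl = conn_level.get((u, v))
        if lvl is not None and dist <= lvl + epsilon and dist > 0:
            edges.append((u, v, dist))
    return edges


def _majority_median(a: frozenset, b: frozenset, c: frozenset) -> frozenset:
    votes: dict[str, int] = {}
    for s in (a, b, c):
        for ch in s:
            votes[ch] = votes.get(ch, 0) + 1
    return frozenset(ch for ch, n in votes.items() if n >= 2)


def build_network(classes: Sequence[HaplotypeClass], epsilon: float = 0,
                  weights: Mapping[str, float] | None = None,
                  max_median_rounds: int = 50) -> nx.Graph:
    """Median-joining network over haplotype classes.

    Nodes carry ``labels`` (frozenset of variant labels), ``observed``,
    ``multiplicity`` and ``members`` attributes; edges carry ``weight``
    (mutation count) and ``labels`` (the separating variants).  Construction
    depends only on the set of classes, not their input order.
    """
    if not classes:
        raise NetworkError("no haplotype classes")
    nodes: dict[str, frozenset] = {c.class_id: c.labels for c in classes}
    meta = {c.class_id: c for c in classes}
    known: set[frozenset] = set(nodes.values())
    n_median = 0
    for _ in range(max_median_rounds):
        edges = _msn_edges(nodes, epsilon, weights)
        adj: dict[str, set[str]] = {u: set() for u in nodes}
        for u, v, _w in edges:
            adj[u].add(v)
            adj[v].add(u)
        new_medians = []
        for u, v, w in sorted(itertools.combinations(sorted(nodes), 3)):
            if v in adj[u] and w in adj[u] and w in adj[v]:
                med = _majority_median(nodes[u], nodes[v], nodes[w])
                if med not in known:
                    known.add(med)
                    new_medians.append(med)
        if not new_medians:
            break
        for med in sorted(new_medians, key=lambda s: tuple(sorted(s))):
            n_median += 1
            nodes[f"mv{n_median:03d}"] = med

    # prune obsolete (unsampled, degree <= 2) medians, one at a time
    while True:
        edges = _msn_edges(nodes, epsilon, weights)
        deg: dict[str, int] = {u: 0 for u in nodes}
        for u, v, _w in edges:
            deg[u] += 1
            deg[v] += 1
        removable = sorted(u for u in nodes
                           if u.startswith("mv") and deg[u] <= 2)
        if not removable:
            break
        del nodes[removable[0]]

    G = nx.Graph()
    for u, labels in sorted(nodes.items()):
        if u in meta:
            c = meta[u]
            G.add_node(u, labels=labels, observed=True,
                       multiplicity=c.multiplicity, members=list(c.members))
        else:
            G.add_node(u, labels=labels, observed=False, multiplicity=0,
                       members=[])
    for u, v, w in _msn_edges(nodes, epsilon, weights):
        G.add_edge(u, v, weight=w, labels=sorted(nodes[u] ^ nodes[v]))
    return G


# ---------------------------------------------------------------------------
# rooted genealogy


@dataclass
class CladeGenealogy:
    """Rooted, mutation-weighted genealogy of haplotype classes.

    Edges point away from the root and carry ``m`` (mutation count) and
    ``labels``; nodes carry ``multiplicity`` (0 for inferred nodes).
    """
    graph: nx.DiGraph
    root: str

    @property
    def n(self) -> float:
        return sum(d["multiplicity"] for _, d in self.graph.nodes(data=True))

    @property
    def total_mutations(self) -> float:
        return sum(d["m"] for _, _, d in self.graph.edges(data=True))

    def leaves(self) -> list[str]:
        return [u for u in self.graph if self.graph.out_degree(u) == 0]

    def root_distance(self, node: str) -> float:
        dist = 0.0
        cur = node
        while cur != self.root:
            parent = next(self.graph.predecessors(cur))
            dist += self.graph[parent][cur]["m"]
            cur = parent
        return dist

    def to_newick(self) -> str:
        def rec(u):
            children = sorted(self.graph.successors(u))
            mult = self.graph.nodes[u]["multiplicity"]
            name = f"{u}x{mult}" if mult else u
            if not children:
                return name
            inner = ",".join(
                f"{rec(c)}:{self.graph[u][c]['m']:g}" for c in children)
            return f"({inner}){name}"
        return rec(self.root) + ";"


def genealogy_from_edges(edges: Iterable[tuple[str, str, float]],
                         multiplicities: Mapping[str, float],
                         root: str,
                         edge_labels: Mapping[tuple[str, str], list[str]] | None = None,
                         ) -> CladeGenealogy:
    """Assemble a genealogy directly from (parent, child, mutations) triples."""
    G = nx.DiGraph()
    for u, v, m in edges:
        labels = [] if edge_labels is None else edge_labels.get((u, v), [])
        G.add_edge(u, v, m=float(m), labels=labels)
    for u in G.nodes:
        G.nodes[u]["multiplicity"] = float(multiplicities.get(u, 0))
    if root not in G:
        G.add_node(root, multiplicity=float(multiplicities.get(root, 0)))
    if not nx.is_weakly_connected(G) or any(G.in_degree(u) > 1 for u in G):
        raise NetworkError("edges do not form a rooted tree")
    return CladeGenealogy(graph=G, root=root)


def _median_closure(sets: list[frozenset], cap: int = 1024) -> list[frozenset]:
    closure = list(dict.fromkeys(sets))
    seen = set(closure)
    frontier = closure
    while frontier and len(closure) < cap:
        new = []
        for a, b, c in itertools.combinations(closure, 3):
            med = _majority_median(a, b, c)
            if med not in seen:
                seen.add(med)
                new.append(med)
                if len(closure) + len(new) >= cap:
                    break
        closure.extend(new)
        frontier = new
    return closure


def _steiner_exact(candidates: list[frozenset], terminals: list[int],
                   weights: Mapping[str, float] | None) -> list[tuple[int, int]]:
    """Dreyfus-Wagner minimum Steiner tree on the metric closure.

    Returns the edge list (candidate indices); total weight is the minimum
    possible because Hamming distance is a metric and one relaxation pass of
    the dense min-plus product reaches the shortest-path closure.
    """
    V = len(candidates)
    W = np.zeros((V, V))
    for i in range(V):
        for j in range(i + 1, V):
            W[i, j] = W[j, i] = _distance(candidates[i], candidates[j], weights)
    t0, rest = terminals[0], terminals[1:]
    if not rest:
        return []
    nt = len(rest)
    full = (1 << nt) - 1
    INF = np.inf
    dp = np.full((full + 1, V), INF)
    predu = np.zeros((full + 1, V), dtype=np.int64)
    split = np.zeros((full + 1, V), dtype=np.int64)
    for i, t in enumerate(rest):
        S = 1 << i
        base = np.full(V, INF)
        base[t] = 0.0
        dp[S] = (base[:, None] + W).min(axis=0)
        predu[S] = (base[:, None] + W).argmin(axis=0)
    order = sorted(range(1, full + 1), key=lambda S: bin(S).count("1"))
    for S in order:
        if bin(S).count("1") < 2:
            continue
        base = np.full(V, INF)
        bsplit = np.zeros(V, dtype=np.int64)
        S1 = (S - 1) & S
        while S1 > S ^ S1:  # canonical: S1 > complement, each split once
            S2 = S ^ S1
            cand = dp[S1] + dp[S2]
            better = cand < base
            base[better] = cand[better]
            bsplit[better] = S1
            S1 = (S1 - 1) & S
        tot = base[:, None] + W
        dp[S] = np.minimum(base, tot.min(axis=0))
        predu[S] = np.where(base <= tot.min(axis=0), np.arange(V),
                            tot.argmin(axis=0))
        split[S] = bsplit

    edges: set[tuple[int, int]] = set()

    def reconstruct(S: int, v: int) -> None:
        if bin(S).count("1") == 1:
            t = rest[S.bit_length() - 1]
            u = int(predu[S][v])
            if u != v:
                edges.add((min(u, v), max(u, v)))
            if u != t:
                edges.add((min(u, t), max(u, t)))
            return
        u = int(predu[S][v])
        if u != v:
            edges.add((min(u, v), max(u, v)))
        S1 = int(split[S][u])
        reconstruct(S1, u)
        reconstruct(S ^ S1, u)

    reconstruct(full, t0)
    return sorted(edges)


def extract_genealogy(network: nx.Graph, root_profile: VariantProfile,
                      exact_max_terminals: int = 10,
                      exact_max_sites: int = 16) -> CladeGenealogy:
    """Orient the network into a rooted most-parsimonious genealogy.

    The caller supplies the ancestral (clade root) profile.  Small instances
    are solved exactly (minimum Steiner tree over the median closure of the
    network's node set); larger ones use a deterministic MST resolution.
    """
    root_labels = frozenset(root_profile.label_set())
    node_sets: dict[str, frozenset] = {
        u: d["labels"] for u, d in network.nodes(data=True)}
    root_id = None
    for u, labels in node_sets.items():
        if labels == root_labels:
            root_id = u
            break
    if root_id is None:
        root_id = "root"
        node_sets[root_id] = root_labels

    observed = [u for u, d in network.nodes(data=True) if d["observed"]]
    terminals = [root_id] + sorted(u for u in observed if u != root_id)
    all_chars = set().union(*node_sets.values()) if node_sets else set()

    if len(terminals) <= exact_max_terminals and len(all_chars) <= exact_max_sites:
        candidates = _median_closure(
            sorted(set(node_sets.values()), key=lambda s: tuple(sorted(s))))
        index = {}
        names = {}
        counter = 0
        for s in candidates:
            match = [u for u, ls in node_sets.items() if ls == s]
            if match:
                names[len(index)] = match[0]
            else:
                counter += 1
                names[len(index)] = f"steiner{counter:03d}"
            index[len(index)] = s
        cand_list = [index[i] for i in range(len(index))]
        term_idx = [cand_list.index(node_sets[t]) for t in terminals]
        edge_idx = _steiner_exact(cand_list, term_idx, None)
        T = nx.Graph()
        T.add_node(names[term_idx[0]])
        for i, j in edge_idx:
            T.add_edge(names[i], names[j],
                       weight=float(len(cand_list[i] ^ cand_list[j])),
                       labels=sorted(cand_list[i] ^ cand_list[j]))
        node_sets = {names[i]: cand_list[i] for i in range(len(cand_list))
                     if names[i] in T}
    else:
        G = network.copy()
        if root_id not in G:
            G.add_node(root_id, labels=root_labels, observed=False,
                       multiplicity=0, members=[])
            edges = _msn_edges({u: s for u, s in node_sets.items()}, 0, None)
            G.remove_edges_from(list(G.edges))
            for u, v, w in edges:
                G.add_edge(u, v, weight=w,
                           labels=sorted(node_sets[u] ^ node_sets[v]))
        if not nx.is_connected(G):
            raise NetworkError("root profile not connectable to the network")

        def mult(u):
            return G.nodes[u].get("multiplicity", 0) if u in network else 0

        ranked = sorted(
            G.edges(data=True),
            key=lambda e: (e[2]["weight"], -(mult(e[0]) + mult(e[1])),
                           tuple(e[2]["labels"]), min(e[0], e[1]), max(e[0], e[1])))
        T = nx.Graph()
        T.add_nodes_from(G.nodes)
        uf = {u: u for u in G.nodes}

        def find(u):
            while uf[u] != u:
                uf[u] = uf[uf[u]]
                u = uf[u]
            return u

        for u, v, d in ranked:
            if find(u) != find(v):
                uf[find(u)] = find(v)
                T.add_edge(u, v, **d)
        # prune unneeded latent leaves
        changed = True
        while changed:
            changed = False
            for u in sorted(T.nodes):
                if u != root_id and T.degree(u) <= 1 \
                        and not network.nodes.get(u, {}).get("observed", False):
                    T.remove_node(u)
                    changed = True

    D = nx.DiGraph()
    obs_meta = {u: d for u, d in network.nodes(data=True)}
    for u in T.nodes:
        meta = obs_meta.get(u, {})
        D.add_node(u, multiplicity=float(meta.get("multiplicity", 0)),
                   members=list(meta.get("members", [])),
                   labels=node_sets.get(u, frozenset()))
    root_name = root_id if root_id in T else next(iter(T.nodes))
    for u, v in nx.bfs_edges(T, root_name):
        D.add_edge(u, v, m=float(T[u][v]["weight"]), labels=T[u][v]["labels"])
    return CladeGenealogy(graph=D, root=root_name)


def export_genealogy(g: CladeGenealogy, newick_path, labels_path,
                     header_comment: str | None = None) -> None:
    """Write newick (edge lengths = mutation counts) plus an edge-label TSV."""
    with open(newick_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(g.to_newick() + "\n")
    with open(labels_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("parent\tchild\tm\tlabels\n")
        for u, v, d in sorted(g.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['m']:g}\t{' '.join(d['labels'])}\n")


def export_network(network: nx.Graph, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("node_u\tnode_v\tweight\tlabels\n")
        for u, v, d in sorted(network.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['weight']:g}\t{' '.join(d['labels'])}\n")
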