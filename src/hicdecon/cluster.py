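"""The hybrid clustering algorithm at the heart of the package.

Pipeline on the contact graph: restrict to the single largest connected
component; reweight edges by the Jarvis-Patrick shared-nearest-neighbor
rule (k = 100 by default), which makes the signal invariant to per-species
differences in absolute link density (abundance, lysis efficiency);
then merge nodes by average-linkage agglomerative clustering down to the
expected or predicted number of species.

The shared-neighbor rule: for each node, its neighborhood NN(v) is the
top-k graph neighbors ranked by normalized weight (ties broken by contig
id); an edge (u, v) is removed when |NN(u) & NN(v)| < min_shared and
otherwise reweighted to the shared-neighbor count (as a fraction of k by
default).  Because neighborhoods depend only on weight *ranks*, scaling
all links of one species by a constant leaves the reweighted graph
unchanged on separable data.

The number of clusters can be estimated from the merge trace via
intracluster link enrichment E(N) = (raw links inside clusters at the
N-cluster stage) / (total raw links): E grows steeply while merges reunite
fragments of one species and flattens once merges start fusing species,
so the elbow of the curve marks the species count.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .contacts import ContactGraph, build_graph
from .contigs_io import Contig
from .errors import DataError

UNCLUSTERED = "unclustered"

#: reasons a contig can end outside all clusters
REASON_ZERO_SITES = "zero_sites"
REASON_OUTSIDE_COMPONENT = "outside_largest_component"
REASON_JP_ISOLATED = "jp_isolated"


@dataclass(frozen=True)
class ClusterParams:
    """Knobs of the hybrid clustering.

    k:             Jarvis-Patrick neighborhood size (nodes with fewer
                   neighbors use all of them).
    n_clusters:    target cluster count, or "auto" to estimate it from the
                   link-enrichment curve.
    jp_weight_mode: "fraction" reweights edges to shared/k; "count" keeps
                   the raw shared-neighbor count.
    min_shared:    edges with fewer shared nearest neighbors are removed.
    """

    k: int = 100
    n_clusters: int | str = "auto"
    jp_weight_mode: str = "fraction"
    min_shared: int = 1

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.jp_weight_mode not in ("fraction", "count"):
            raise ValueError(f"unknown jp_weight_mode {self.jp_weight_mode!r}")
        if self.min_shared < 0:
            raise ValueError("min_shared must be >= 0")
        if self.n_clusters != "auto" and (not isinstance(self.n_clusters, int) or self.n_clusters < 1):
            raise ValueError("n_clusters must be a positive integer or 'auto'")


@dataclass
class ClusterAssignment:
    """A partition of a contig subset into named clusters.

    ``clusters`` maps cluster id -> member contig ids; ``unclustered``
    holds the remainder with a per-contig reason; ``merge_trace`` records
    every agglomerative merge as (step, (cluster_a, cluster_b), linkage).
    """

    clusters: dict[str, frozenset[str]]
    unclustered: frozenset[str]
    unclustered_reasons: dict[str, str]
    merge_trace: list[tuple[int, tuple[str, str], float]] = field(default_factory=list)

    def labels(self) -> dict[str, str]:
        out = {}
        for name, members in self.clusters.items():
            for cid in members:
                out[cid] = name
        for cid in self.unclustered:
            out[cid] = UNCLUSTERED
        return out

    def clustered_contigs(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.clusters.values():
            out.update(members)
        return frozenset(out)

    def validate(self, universe: Optional[Iterable[str]] = None) -> None:
        seen: set[str] = set()
        for name, members in self.clusters.items():
            if not members:
                raise DataError(f"cluster {name!r} is empty")
            if seen & members:
                raise DataError("clusters are not disjoint")
            seen.update(members)
        if seen & self.unclustered:
            raise DataError("a contig is both clustered and unclustered")
        if universe is not None:
            if seen | set(self.unclustered) != set(universe):
                raise DataError("clusters + unclustered do not cover the contig universe")


def largest_component(cg: ContactGraph) -> tuple[ContactGraph, frozenset[str]]:
    """Restrict to the single largest connected component.

    Ties on node count are broken by total sequence length, then by the
    lexicographically smallest member id.  Returns the restricted graph and
    the set of discarded contig ids.
    """
    import networkx as nx

    if cg.n_nodes == 0:
        raise DataError("contact graph is empty")
    comps = list(nx.connected_components(cg.graph))
    comps.sort(key=lambda c: (-len(c),
                              -sum(cg.graph.nodes[v]["length"] for v in c),
                              min(c)))
    keep = comps[0]
    discarded = frozenset(set(cg.graph.nodes) - keep)
    return cg.subgraph(keep), discarded


def jarvis_patrick(cg: ContactGraph, params: ClusterParams = ClusterParams()) -> ContactGraph:
    """Shared-nearest-neighbor edge removal and reweighting.

    Only existing graph edges are considered; a node is never in its own
    neighbor list.  Nodes isolated by edge removal remain in the graph
    (they are reported unclustered downstream).
    """
    if params.k < 1:
        raise ValueError("k must be >= 1")
    import networkx as nx

    g = cg.graph
    nn: dict[str, frozenset[str]] = {}
    for v in g.nodes:
        nbrs = sorted(g[v].items(), key=lambda kv: (-kv[1]["weight"], kv[0]))
        nn[v] = frozenset(u for u, _ in nbrs[: params.k])

    h = nx.Graph()
    for v, d in g.nodes(data=True):
        h.add_node(v, **d)
    for u, v, d in g.edges(data=True):
        shared = len(nn[u] & nn[v])
        if shared < params.min_shared:
            continue
        w = shared / params.k if params.jp_weight_mode == "fraction" else float(shared)
        h.add_edge(u, v, weight=w, raw_links=d["raw_links"], shared=shared)
    return ContactGraph(graph=h, intra_pairs=cg.intra_pairs)


def _agglomerate_engine(cg: ContactGraph, stop_n: int):
    """Average-linkage agglomeration by max linkage with deterministic ties.

    Clusters are keyed by their lexicographically smallest member id, so a
    heap ordered by (-linkage, key_a, key_b) resolves equal linkages by
    merging the pair whose smallest member id is least.  Returns
    ``(clusters, isolated, trace, states)`` where ``states`` is the list of
    (active cluster count, intracluster link enrichment) after each merge,
    prepended with the initial state.
    """
    g = cg.graph
    isolated = frozenset(v for v in g.nodes if g.degree(v) == 0)
    members: dict[str, set[str]] = {v: {v} for v in g.nodes if v not in isolated}
    # nbr[c][x] = [summed weight, summed raw links] between clusters c and x
    nbr: dict[str, dict[str, list]] = {c: {} for c in members}
    gen: dict[str, int] = {c: 0 for c in members}
    total_raw = 0
    heap: list[tuple] = []
    for u, v, d in g.edges(data=True):
        w, r = float(d["weight"]), int(d["raw_links"])
        nbr[u][v] = [w, r]
        nbr[v][u] = [w, r]
        total_raw += r
        a, b = (u, v) if u < v else (v, u)
        heap.append((-w, a, b, 0, 0))
    heapq.heapify(heap)

    n_active = len(members)
    intra_raw = 0
    step = 0
    trace: list[tuple[int, tuple[str, str], float]] = []
    states: list[tuple[int, float]] = [(n_active, 0.0)]

    while n_active > stop_n and heap:
        neg, a, b, ga, gb = heapq.heappop(heap)
        if a not in members or b not in members or gen[a] != ga or gen[b] != gb:
            continue
        step += 1
        trace.append((step, (a, b), -neg))
        intra_raw += nbr[a].get(b, (0.0, 0))[1]
        new = a  # heap entries are pushed with a < b; min member id survives
        merged_members = members.pop(a) | members.pop(b)
        merged_nbr: dict[str, list] = {}
        for src in (a, b):
            for x, (w, r) in nbr[src].items():
                if x == a or x == b:
                    continue
                e = merged_nbr.get(x)
                if e is None:
                    merged_nbr[x] = [w, r]
                else:
                    e[0] += w
                    e[1] += r
        del nbr[a], nbr[b]
        members[new] = merged_members
        nbr[new] = merged_nbr
        gen[new] = gen.get(new, 0) + 1
        size_new = len(merged_members)
        for x, (w, r) in merged_nbr.items():
            nbr[x].pop(a, None)
            nbr[x].pop(b, None)
            nbr[x][new] = [w, r]
            link = w / (size_new * len(members[x]))
            p, q = (new, x) if new < x else (x, new)
            heapq.heappush(heap, (-link, p, q, gen[p], gen[q]))
        n_active -= 1
        states.append((n_active, intra_raw / total_raw if total_raw else 0.0))

    clusters = {key: frozenset(m) for key, m in members.items()}
    return clusters, isolated, trace, states


def _name_clusters(clusters: dict[str, frozenset[str]], g) -> dict[str, frozenset[str]]:
    """Deterministic cluster names, largest total sequence length first."""
    ordered = sorted(
        clusters.values(),
        key=lambda m: (-sum(g.nodes[v]["length"] for v in m), min(m)),
    )
    width = max(3, len(str(len(ordered))))
    return {f"cluster_{i + 1:0{width}d}": m for i, m in enumerate(ordered)}


def agglomerate(cg: ContactGraph, n_clusters: int) -> ClusterAssignment:
    """Merge graph nodes to ``n_clusters`` clusters by max average linkage.

    linkage(A, B) = (sum of edge weights between A and B) / (|A| * |B|),
    absent edges contributing zero, so merging stops early if no pair with
    positive linkage remains (disconnected parts are never force-merged).
    Nodes isolated by Jarvis-Patrick edge removal are reported unclustered.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > cg.n_nodes:
        raise DataError(f"n_clusters={n_clusters} exceeds node count {cg.n_nodes}")
    clusters, isolated, trace, _ = _agglomerate_engine(cg, stop_n=n_clusters)
    return ClusterAssignment(
        clusters=_name_clusters(clusters, cg.graph),
        unclustered=isolated,
        unclustered_reasons={v: REASON_JP_ISOLATED for v in isolated},
        merge_trace=trace,
    )


def estimate_n_clusters(cg: ContactGraph, n_min: int, n_max: int
                        ) -> tuple[int, list[tuple[int, float]]]:
    """Predict the species count from the agglomeration of the contact graph.

    Runs the full agglomeration once.  The predicted N is the largest
    relative gap in the dendrogram's linkage sequence: with L(N) the
    average linkage of the merge that reduces the clustering to N
    clusters, the estimator returns

        argmax over N in [n_min, n_max] of  L(N) / L(N-1).

    While merges reunite fragments of one species, successive linkages are
    of the same order (strong within-species connectivity); the first
    merge that fuses two species has near-zero linkage, so the ratio
    spikes at exactly the species count.  If the reweighted graph
    disconnects into components and merging below some N is impossible,
    that N scores as an infinite gap.  Unlike enrichment *gains*, linkage
    is normalized by cluster-pair size, so large early merges cannot
    masquerade as the elbow.

    Also returns the intracluster link-enrichment curve E(N) — the
    fraction of raw links inside clusters at the N-cluster stage, read off
    the same trace — for plotting and manual inspection: E rises steeply
    while merges reunite species fragments and flattens at the elbow.
    """
    if not (2 <= n_min < n_max <= cg.n_nodes):
        raise DataError(f"invalid scan range [{n_min}, {n_max}] for {cg.n_nodes} nodes")
    _, _, trace, states = _agglomerate_engine(cg, stop_n=1)
    e_by_n = {n: e for n, e in states}
    n_start = states[0][0]
    n_end, e_end = states[-1]

    def E(n: int) -> float:
        if n >= n_start:
            return 0.0
        if n <= n_end:
            return e_end
        return e_by_n[n]

    curve = [(n, E(n)) for n in range(n_min, n_max + 1)]
    # linkage of the merge that reaches each cluster count
    link_at = {n_start - (i + 1): link for i, (_, _, link) in enumerate(trace)}
    best_n, best_score = n_min, -np.inf
    for n in range(n_min, n_max + 1):
        if n not in link_at:
            continue  # agglomeration never passed through this count
        below = link_at.get(n - 1)
        score = np.inf if below is None else link_at[n] / below
        if score > best_score:
            best_n, best_score = n, score
    return best_n, curve


@dataclass
class BootstrapResult:
    stability: dict[str, float]
    mean_stability: float
    ari: list[float]
    n_replicates: int
    original: ClusterAssignment


def _cluster_graph_nodes(pairs, contigs, params: ClusterParams, n_clusters: int,
                         normalization: str) -> ClusterAssignment:
    """Graph -> largest component -> Jarvis-Patrick -> agglomeration."""
    cg = build_graph(pairs, contigs, normalization=normalization)
    comp, discarded = largest_component(cg)
    jp = jarvis_patrick(comp, params)
    n = min(n_clusters, jp.n_nodes)
    assignment = agglomerate(jp, n)
    reasons = dict(assignment.unclustered_reasons)
    for cid in discarded:
        reasons[cid] = REASON_OUTSIDE_COMPONENT
    return ClusterAssignment(
        clusters=assignment.clusters,
        unclustered=frozenset(set(assignment.unclustered) | set(discarded)),
        unclustered_reasons=reasons,
        merge_trace=assignment.merge_trace,
    )


def bootstrap_stability(pairs, contigs: Sequence[Contig], params: ClusterParams,
                        n_clusters: int, B: int, seed: int,
                        normalization: str = "product") -> BootstrapResult:
    """Resampling stability of the clustering.

    B times: resample the filtered pair table with replacement to its
    original size, rebuild the graph, and recluster at the same N.  A
    contig is stable in a replicate when it lands in the replicate cluster
    that shares the greatest sequence-length overlap with the contig's
    original cluster (ties broken by replicate cluster name).  Per-contig
    stability is the fraction of such replicates; the summary carries the
    mean over originally clustered contigs and the adjusted Rand index of
    each replicate against the original assignment.  Fully reproducible
    from ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    lengths = {c.id: c.length for c in contigs}
    original = _cluster_graph_nodes(pairs, contigs, params, n_clusters, normalization)
    orig_labels = original.labels()
    scored = sorted(original.clustered_contigs())
    hits = {cid: 0 for cid in scored}
    aris: list[float] = []
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(pairs)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        rep_pairs = pairs.iloc[idx].reset_index(drop=True)
        rep = _cluster_graph_nodes(rep_pairs, contigs, params, n_clusters, normalization)
        rep_labels = rep.labels()
        # best replicate match of each original cluster, by overlap length
        best_match: dict[str, str] = {}
        for oname, omembers in original.clusters.items():
            overlaps: dict[str, int] = {}
            for cid in omembers:
                rname = rep_labels.get(cid, UNCLUSTERED)
                if rname != UNCLUSTERED:
                    overlaps[rname] = overlaps.get(rname, 0) + lengths[cid]
            if overlaps:
                best_match[oname] = min(overlaps, key=lambda r: (-overlaps[r], r))
        for cid in scored:
            oname = orig_labels[cid]
            rname = rep_labels.get(cid, UNCLUSTERED)
            if rname != UNCLUSTERED and best_match.get(oname) == rname:
                hits[cid] += 1
        aris.append(float(adjusted_rand_score(
            [orig_labels[c] for c in scored],
            [rep_labels.get(c, UNCLUSTERED) for c in scored],
        )))
    stability = {cid: hits[cid] / B for cid in scored}
    mean = float(np.mean(list(stability.values()))) if stability else float("nan")
    return BootstrapResult(stability=stability, mean_stability=mean,
                           ari=aris, n_replicates=B, original=original)
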