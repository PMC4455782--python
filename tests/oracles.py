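"""Independent brute-force reference implementations used to check the
package's optimized code paths.  Deliberately naive: quadratic scans,
full-matrix recomputation at every step, explicit flood fill."""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_sites(sequence: str, motif: str) -> list[int]:
    """O(|s|*|m|) scan of both strands with per-character comparison."""
    seq = sequence.upper()
    motif = motif.upper()
    rc = "".join(_COMP[c] for c in reversed(motif))
    hits = set()
    for pat in {motif, rc}:
        for i in range(len(seq) - len(pat) + 1):
            if all(seq[i + j] == pat[j] for j in range(len(pat))):
                hits.add(i)
    return sorted(hits)


def brute_components(graph) -> list[set]:
    """Connected components by explicit flood fill."""
    unseen = set(graph.nodes)
    comps = []
    while unseen:
        start = unseen.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            v = frontier.pop()
            for u in graph[v]:
                if u in unseen:
                    unseen.discard(u)
                    comp.add(u)
                    frontier.append(u)
        comps.append(comp)
    return comps


def brute_jp(graph, k: int, min_shared: int = 1, mode: str = "fraction"):
    """Shared-nearest-neighbor counts and surviving edge weights.

    Returns {frozenset((u, v)): (shared, new_weight)} for kept edges.
    """
    nn = {}
    for v in graph.nodes:
        ranked = sorted(graph[v], key=lambda u: (-graph[v][u]["weight"], u))
        nn[v] = set(ranked[:k])
    kept = {}
    for u, v in graph.edges:
        shared = sum(1 for x in nn[u] if x in nn[v])
        if shared >= min_shared:
            w = shared / k if mode == "fraction" else float(shared)
            kept[frozenset((u, v))] = (shared, w)
    return kept


def brute_agglomerate(graph, n_clusters: int):
    """Average-linkage agglomeration recomputing the full linkage matrix
    at every step.  Returns (clusters dict key->set, trace list of
    (step, (a, b), linkage)) with the same deterministic tie-breaking as
    the production engine: max linkage first, then the pair whose cluster
    keys (lexicographically smallest member ids) are least.
    """
    clusters = {v: {v} for v in graph.nodes if graph.degree(v) > 0}
    trace = []
    step = 0
    while len(clusters) > n_clusters:
        best = None
        keys = sorted(clusters)
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                w = 0.0
                for x in clusters[a]:
                    for y in clusters[b]:
                        if graph.has_edge(x, y):
                            w += graph[x][y]["weight"]
                if w <= 0.0:
                    continue
                link = w / (len(clusters[a]) * len(clusters[b]))
                cand = (-link, a, b)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        neg, a, b = best
        step += 1
        trace.append((step, (a, b), -neg))
        clusters[a] = clusters.pop(a) | clusters.pop(b)
        # key is the smallest member id; a < b so a stays the key
    return clusters, trace


def brute_filter(pairs_df, contigs_by_id, window: int):
    """Per-endpoint nearest-site distance by explicit minimization."""
    keep = []
    n_zero = n_window = 0
    for row in pairs_df.itertuples(index=False):
        sites1 = contigs_by_id[row.contig1].site_positions
        sites2 = contigs_by_id[row.contig2].site_positions
        if not sites1 or not sites2:
            n_zero += 1
            continue
        d1 = min(abs(row.pos1 - s) for s in sites1)
        d2 = min(abs(row.pos2 - s) for s in sites2)
        if d1 <= window and d2 <= window:
            keep.append(True)
        else:
            n_window += 1
            keep.append(False)
            continue
    kept = sum(1 for _ in filter(None, keep))
    return kept, n_window, n_zero


def brute_edge_tally(pairs_df):
    """Exhaustive inter-contig link counting."""
    tally = {}
    intra = 0
    for row in pairs_df.itertuples(index=False):
        if row.contig1 == row.contig2:
            intra += 1
            continue
        key = frozenset((row.contig1, row.contig2))
        tally[key] = tally.get(key, 0) + 1
    return tally, intra


def brute_purity(assignment, truth, lengths):
    """Per-cluster, per-species length fractions by direct tallying."""
    out = {}
    for cname, members in assignment.clusters.items():
        total = sum(lengths[c] for c in members)
        cells = {}
        for cid in members:
            for s in truth.membership.get(cid, frozenset({"unknown"})):
                cells[s] = cells.get(s, 0) + lengths[cid]
        out[cname] = {s: v / total for s, v in cells.items()}
    return out
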