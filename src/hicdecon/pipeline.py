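"""End-to-end orchestration: filter -> graph -> cluster -> full assignment.

This is the library-level equivalent of the CLI's ``run-all``: it threads
the contact table through the site filter, the normalized contact graph,
the largest-component restriction, Jarvis-Patrick reweighting, and
average-linkage agglomeration, and composes the final assignment over the
*whole* assembly, recording why each unclustered contig was left out
(zero restriction sites, outside the largest component, or isolated by
shared-neighbor edge removal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from . import cluster as _cluster
from .cluster import (REASON_OUTSIDE_COMPONENT, REASON_ZERO_SITES,
                      ClusterAssignment, ClusterParams, agglomerate,
                      estimate_n_clusters, jarvis_patrick, largest_component)
from .contacts import ContactGraph, FilterParams, FilterReport, build_graph, filter_pairs
from .contigs_io import Contig
from .errors import DataError


@dataclass
class PipelineResult:
    assignment: ClusterAssignment
    filter_report: FilterReport
    graph: ContactGraph
    jp_graph: ContactGraph
    n_clusters: int
    estimated_n: Optional[int] = None
    enrichment_curve: Optional[list[tuple[int, float]]] = None


def deconvolve(contigs: Sequence[Contig], pairs: pd.DataFrame,
               filter_params: FilterParams = FilterParams(),
               cluster_params: ClusterParams = ClusterParams(),
               normalization: str = "product",
               dedup: bool = False,
               n_range: tuple[int, int] = (2, 30)) -> PipelineResult:
    """Run the full deconvolution on an annotated assembly and a pair table.

    ``cluster_params.n_clusters`` may be an integer (the expected species
    count) or ``"auto"``, in which case the count is predicted from the
    intracluster link-enrichment curve scanned over ``n_range``.
    """
    filtered, report = filter_pairs(pairs, contigs, filter_params, dedup=dedup)
    graph = build_graph(filtered, contigs, normalization=normalization)
    if graph.n_nodes == 0:
        raise DataError("no site-bearing contigs; nothing to cluster")
    comp, discarded = largest_component(graph)
    jp = jarvis_patrick(comp, cluster_params)

    estimated = None
    curve = None
    if cluster_params.n_clusters == "auto":
        lo = max(2, n_range[0])
        hi = min(n_range[1], jp.n_nodes - 1)
        if hi <= lo:
            raise DataError(f"graph too small ({jp.n_nodes} nodes) to scan [{lo}, {n_range[1]}]")
        estimated, curve = estimate_n_clusters(jp, lo, hi)
        n_clusters = estimated
    else:
        n_clusters = int(cluster_params.n_clusters)
        if n_clusters > jp.n_nodes:
            raise DataError(f"n_clusters={n_clusters} exceeds clusterable node count {jp.n_nodes}")

    core = agglomerate(jp, n_clusters)

    reasons = dict(core.unclustered_reasons)
    unclustered = set(core.unclustered)
    for cid in discarded:
        unclustered.add(cid)
        reasons[cid] = REASON_OUTSIDE_COMPONENT
    for c in contigs:
        if c.site_count == 0:
            unclustered.add(c.id)
            reasons[c.id] = REASON_ZERO_SITES
    assignment = ClusterAssignment(
        clusters=core.clusters,
        unclustered=frozenset(unclustered),
        unclustered_reasons=reasons,
        merge_trace=core.merge_trace,
    )
    assignment.validate(universe=[c.id for c in contigs])
    return PipelineResult(
        assignment=assignment,
        filter_report=report,
        graph=graph,
        jp_graph=jp,
        n_clusters=n_clusters,
        estimated_n=estimated,
        enrichment_curve=curve,
    )
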