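"""Scoring a cluster assignment against species truth.

The central object is the purity matrix: clusters by species, each cell the
fraction of the cluster's total contig length belonging to contigs whose
truth set contains that species.  Because a contig may genuinely belong to
several species (shared or near-identical sequence), rows can sum to more
than 1.  Each cluster is called as the species of its length-weighted
argmax cell, and a contig counts as correctly placed when its cluster's
called species is among the contig's own labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ._util import atomic_write
from .cluster import REASON_ZERO_SITES, ClusterAssignment
from .contigs_io import Contig, SpeciesTruth

UNKNOWN = "unknown"


def _truth_sets(assignment: ClusterAssignment, truth: SpeciesTruth):
    """Truth label sets for every clustered contig; missing entries -> {unknown}."""
    sets = {}
    missing = 0
    for cid in assignment.clustered_contigs():
        labels = truth.get(cid)
        if labels is None:
            labels = frozenset({UNKNOWN})
            missing += 1
        sets[cid] = labels
    if missing:
        warnings.warn(f"{missing} clustered contig(s) have no truth entry; "
                      f"scored under the {UNKNOWN!r} label")
    return sets


def purity_matrix(assignment: ClusterAssignment, truth: SpeciesTruth,
                  contigs: Sequence[Contig]) -> pd.DataFrame:
    """Length-fraction matrix of clusters (rows) by species labels (columns)."""
    lengths = {c.id: c.length for c in contigs}
    sets = _truth_sets(assignment, truth)
    labels = sorted(truth.labels)
    if any(UNKNOWN in s for s in sets.values()) and UNKNOWN not in labels:
        labels.append(UNKNOWN)
    rows = sorted(assignment.clusters)
    mat = pd.DataFrame(0.0, index=rows, columns=labels)
    for cname in rows:
        members = assignment.clusters[cname]
        total = sum(lengths[c] for c in members)
        for cid in members:
            for s in sets[cid]:
                mat.loc[cname, s] += lengths[cid]
        mat.loc[cname] /= total
    return mat


def cluster_calls(matrix: pd.DataFrame) -> dict[str, str]:
    """Species call per cluster: length-weighted argmax, ties by column order."""
    return {cname: matrix.columns[matrix.loc[cname].to_numpy().argmax()]
            for cname in matrix.index}


@dataclass
class AccuracyResult:
    length_weighted: float
    count_weighted: float
    clustered_contigs: int
    clustered_length: int
    calls: dict[str, str]


def clustering_accuracy(assignment: ClusterAssignment, truth: SpeciesTruth,
                        contigs: Sequence[Contig],
                        include_unknown: bool = True) -> AccuracyResult:
    """Fraction of clustered sequence (and contigs) placed with a parent species.

    A contig is correct iff its cluster's called species is a member of the
    contig's truth set, so a multi-species contig is correct in either
    parent's cluster.  Unclustered contigs are excluded from both
    denominators.  With ``include_unknown=False``, contigs lacking any
    truth entry are also excluded (rather than counted as errors).
    """
    lengths = {c.id: c.length for c in contigs}
    sets = _truth_sets(assignment, truth)
    matrix = purity_matrix(assignment, truth, contigs)
    calls = cluster_calls(matrix)
    correct_len = total_len = 0
    correct_n = total_n = 0
    for cname, members in assignment.clusters.items():
        call = calls[cname]
        for cid in members:
            labels = sets[cid]
            if not include_unknown and labels == frozenset({UNKNOWN}):
                continue
            total_len += lengths[cid]
            total_n += 1
            if call in labels:
                correct_len += lengths[cid]
                correct_n += 1
    return AccuracyResult(
        length_weighted=correct_len / total_len if total_len else float("nan"),
        count_weighted=correct_n / total_n if total_n else float("nan"),
        clustered_contigs=total_n,
        clustered_length=total_len,
        calls=calls,
    )


@dataclass
class UnclusteredReport:
    total_length: int
    zero_site_length: int
    by_reason: dict[str, int]

    @property
    def zero_site_fraction(self) -> float:
        return self.zero_site_length / self.total_length if self.total_length else 0.0


def unclustered_report(assignment: ClusterAssignment,
                       contigs: Sequence[Contig]) -> UnclusteredReport:
    """Summarize the unclustered remainder by length and by reason."""
    lengths = {c.id: c.length for c in contigs}
    by_reason: dict[str, int] = {}
    total = zero = 0
    for cid in assignment.unclustered:
        n = lengths[cid]
        total += n
        reason = assignment.unclustered_reasons.get(cid, "unspecified")
        by_reason[reason] = by_reason.get(reason, 0) + n
        if reason == REASON_ZERO_SITES:
            zero += n
    return UnclusteredReport(total_length=total, zero_site_length=zero,
                             by_reason=by_reason)


def write_purity_matrix(matrix: pd.DataFrame, path) -> None:
    with atomic_write(path) as fh:
        matrix.round(6).to_csv(fh, sep="\t", index_label="cluster")


def write_accuracy(result: AccuracyResult, unclustered: UnclusteredReport, path) -> None:
    """Flat key=value summary file."""
    with atomic_write(path) as fh:
        fh.write(f"length_weighted_accuracy={result.length_weighted:.6f}\n")
        fh.write(f"count_weighted_accuracy={result.count_weighted:.6f}\n")
        fh.write(f"clustered_contigs={result.clustered_contigs}\n")
        fh.write(f"clustered_length={result.clustered_length}\n")
        fh.write(f"unclustered_length={unclustered.total_length}\n")
        fh.write(f"unclustered_zero_site_fraction={unclustered.zero_site_fraction:.6f}\n")
        for reason in sorted(unclustered.by_reason):
            fh.write(f"unclustered_length[{reason}]={unclustered.by_reason[reason]}\n")
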