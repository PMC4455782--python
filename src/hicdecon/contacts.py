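"""Hi-C contact ingestion, restriction-site proximity filtering, and the
normalized contig contact graph.

A usable Hi-C contact is a read pair whose two ends both align close to a
restriction site: ligation junctions form at digested fragment ends, so a
read far from any site is unlikely to represent a true proximity-ligation
product.  Surviving inter-contig pairs are tallied into a graph whose edge
weights are link counts normalized by the product of the two contigs' site
counts (the number of ligatable fragment-end combinations scales
multiplicatively).

Bulk pair collections are pandas DataFrames with columns ``PAIR_COLUMNS``;
positions are 0-based internally and converted to/from the 1-based
``.pairs`` text format at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._util import atomic_write
from .contigs_io import Contig
from .errors import DataError

PAIR_COLUMNS = ["read_id", "contig1", "pos1", "contig2", "pos2", "strand1", "strand2"]

_PAIRS_HEADER = "#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2"


class HiCPair(NamedTuple):
    """One read-pair contact: two (contig, 0-based 5' position, strand) ends."""

    read_id: str
    contig1: str
    pos1: int
    strand1: str
    contig2: str
    pos2: int
    strand2: str


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the restriction-site proximity filter.

    ``site_window`` is the maximum distance (bp, inclusive) from a read's 5'
    alignment position to the first base of the nearest site.
    """

    site_window: int = 500

    def __post_init__(self):
        if self.site_window < 0:
            raise ValueError("site_window must be >= 0")


@dataclass
class FilterReport:
    total: int
    kept: int
    dropped_window: int
    dropped_zero_site: int

    @property
    def dropped(self) -> int:
        return self.dropped_window + self.dropped_zero_site


@dataclass
class ContactGraph:
    """Contigs as nodes; inter-contig edges carry raw link counts and weights.

    Node attributes: ``length``, ``site_count``.  Edge attributes:
    ``raw_links`` (integer pair tally) and ``weight`` (normalized).
    Intra-contig pairs never form edges; they are tallied in
    ``intra_pairs`` for the conservation diagnostic.
    """

    graph: nx.Graph
    intra_pairs: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def total_raw_links(self) -> int:
        return int(sum(d["raw_links"] for _, _, d in self.graph.edges(data=True)))

    def subgraph(self, nodes: Iterable[str]) -> "ContactGraph":
        return ContactGraph(self.graph.subgraph(nodes).copy(), intra_pairs=self.intra_pairs)


def empty_pairs() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=(int if c.startswith("pos") else object))
                         for c in PAIR_COLUMNS})


def pairs_to_frame(pairs: Iterable[HiCPair]) -> pd.DataFrame:
    rows = list(pairs)
    if not rows:
        return empty_pairs()
    df = pd.DataFrame(rows, columns=HiCPair._fields)
    return df[PAIR_COLUMNS].reset_index(drop=True)


def read_pairs(path: str | Path) -> pd.DataFrame:
    """Read a 4DN-style ``.pairs`` text table (1-based positions)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["read_id", "contig1", "pos1", "contig2", "pos2", "strand1", "strand2"],
        dtype={"read_id": str, "contig1": str, "contig2": str,
               "pos1": np.int64, "pos2": np.int64, "strand1": str, "strand2": str},
    )
    if df.empty:
        return empty_pairs()
    df["pos1"] -= 1
    df["pos2"] -= 1
    return df[PAIR_COLUMNS]


def write_pairs(df: pd.DataFrame, path: str | Path) -> None:
    """Write the 4DN-style ``.pairs`` text table (positions converted to 1-based)."""
    out = df.copy()
    out["pos1"] = out["pos1"] + 1
    out["pos2"] = out["pos2"] + 1
    out = out[["read_id", "contig1", "pos1", "contig2", "pos2", "strand1", "strand2"]]
    with atomic_write(path) as fh:
        fh.write("## pairs format v1.0\n")
        fh.write(_PAIRS_HEADER + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def pairs_from_alignments(records) -> tuple[list[HiCPair], int]:
    """Translate name-grouped paired alignment records into contacts.

    ``records`` is an iterable of :class:`pysam.AlignedSegment` grouped by
    query name (e.g. a name-sorted SAM).  Pairs with an unmapped mate are
    dropped and counted; a read name appearing in more than one group, or a
    group of more than two records, is a hard error.

    Returns ``(pairs, n_dropped)``.
    """
    pairs: list[HiCPair] = []
    dropped = 0
    finished: set[str] = set()

    def flush(name: str, group: list) -> None:
        nonlocal dropped
        if len(group) > 2:
            raise DataError(f"read {name!r} has {len(group)} alignment records (expected <= 2)")
        mapped = [r for r in group if not r.is_unmapped]
        if len(group) == 2 and len(mapped) == 2:
            a, b = group
            pairs.append(HiCPair(
                read_id=name,
                contig1=a.reference_name, pos1=_five_prime(a), strand1="-" if a.is_reverse else "+",
                contig2=b.reference_name, pos2=_five_prime(b), strand2="-" if b.is_reverse else "+",
            ))
        else:
            dropped += 1
        finished.add(name)

    current: Optional[str] = None
    group: list = []
    for rec in records:
        name = rec.query_name
        if name != current:
            if current is not None:
                flush(current, group)
            if name in finished:
                raise DataError(f"input not name-grouped: read {name!r} reappears after its group")
            current, group = name, []
        group.append(rec)
    if current is not None:
        flush(current, group)
    return pairs, dropped


def _five_prime(rec) -> int:
    # 5' alignment position: leftmost base for forward reads, rightmost for reverse.
    return rec.reference_end - 1 if rec.is_reverse else rec.reference_start


def _check_known(df: pd.DataFrame, contig_map: dict[str, Contig]) -> None:
    for col in ("contig1", "contig2"):
        present = pd.unique(df[col])
        for cid in present:
            if cid not in contig_map:
                raise DataError(f"pair references unknown contig {cid!r}")


def _nearest_site_ok(df: pd.DataFrame, side: int, contig_map: dict[str, Contig],
                     window: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-endpoint (zero_site_mask, within_window_mask) for one pair side."""
    cids = df[f"contig{side}"].to_numpy()
    pos = df[f"pos{side}"].to_numpy(dtype=np.int64)
    zero = np.zeros(len(df), dtype=bool)
    ok = np.zeros(len(df), dtype=bool)
    codes, uniques = pd.factorize(cids)
    for u, cid in enumerate(uniques):
        contig = contig_map[cid]
        if contig.site_positions is None:
            raise DataError(f"contig {cid!r} has no site annotation; annotate before filtering")
        mask = codes == u
        p = pos[mask]
        if (p < 0).any() or (p >= contig.length).any():
            raise DataError(f"pair position out of bounds on contig {cid!r}")
        sites = np.asarray(contig.site_positions, dtype=np.int64)
        if sites.size == 0:
            zero[mask] = True
            continue
        idx = np.searchsorted(sites, p)
        left = sites[np.clip(idx - 1, 0, sites.size - 1)]
        right = sites[np.clip(idx, 0, sites.size - 1)]
        dist = np.minimum(np.abs(p - left), np.abs(p - right))
        ok[mask] = dist <= window
    return zero, ok


def filter_pairs(pairs: pd.DataFrame, contigs: Sequence[Contig],
                 params: FilterParams = FilterParams(),
                 dedup: bool = False) -> tuple[pd.DataFrame, FilterReport]:
    """Keep pairs whose BOTH ends lie within ``site_window`` bp of a site.

    Distance is |5' position - nearest site's first base|, inclusive at the
    boundary.  Pairs with an endpoint on a contig bearing zero sites are
    dropped and counted separately (such contigs cannot produce a genuine
    proximity-ligation signal).  ``dedup`` drops coordinate+strand exact
    duplicates first (off by default: duplicate removal is left to the
    caller's judgement).
    """
    contig_map = {c.id: c for c in contigs}
    if dedup:
        pairs = pairs.drop_duplicates(
            subset=["contig1", "pos1", "strand1", "contig2", "pos2", "strand2"]
        ).reset_index(drop=True)
    total = len(pairs)
    if total == 0:
        return empty_pairs(), FilterReport(0, 0, 0, 0)
    _check_known(pairs, contig_map)
    zero1, ok1 = _nearest_site_ok(pairs, 1, contig_map, params.site_window)
    zero2, ok2 = _nearest_site_ok(pairs, 2, contig_map, params.site_window)
    zero = zero1 | zero2
    keep = ~zero & ok1 & ok2
    report = FilterReport(
        total=total,
        kept=int(keep.sum()),
        dropped_zero_site=int(zero.sum()),
        dropped_window=int((~keep & ~zero).sum()),
    )
    return pairs[keep].reset_index(drop=True), report


def build_graph(pairs: pd.DataFrame, contigs: Sequence[Contig],
                normalization: str = "product") -> ContactGraph:
    """Tally filtered pairs into the normalized inter-contig contact graph.

    Nodes are all site-bearing contigs (zero-site contigs are excluded: the
    filter guarantees they receive no links).  For each unordered contig
    pair, ``raw_links`` is the pair tally and ``weight`` is raw_links
    divided by the product (default) or sum of the two contigs' site
    counts.  Intra-contig pairs are tallied but create no edge.
    """
    if normalization not in ("product", "sum"):
        raise ValueError(f"unknown normalization {normalization!r}")
    contig_map = {c.id: c for c in contigs}
    g = nx.Graph()
    for c in contigs:
        if c.site_count >= 1:
            g.add_node(c.id, length=c.length, site_count=c.site_count)

    intra = 0
    if len(pairs):
        _check_known(pairs, contig_map)
        c1 = pairs["contig1"].to_numpy()
        c2 = pairs["contig2"].to_numpy()
        intra_mask = c1 == c2
        intra = int(intra_mask.sum())
        inter1, inter2 = c1[~intra_mask], c2[~intra_mask]
        u = np.minimum(inter1, inter2)
        v = np.maximum(inter1, inter2)
        counts = pd.DataFrame({"u": u, "v": v}).groupby(["u", "v"], sort=True).size()
        for (a, b), raw in counts.items():
            sa, sb = contig_map[a].site_count, contig_map[b].site_count
            if sa == 0 or sb == 0:
                raise DataError(
                    f"pair links zero-site contig ({a!r}, {b!r}); filter pairs first"
                )
            denom = sa * sb if normalization == "product" else sa + sb
            g.add_edge(a, b, raw_links=int(raw), weight=float(raw) / denom)
    return ContactGraph(graph=g, intra_pairs=intra)


def write_links(cg: ContactGraph, path: str | Path) -> None:
    """Link-count TSV: contig1, contig2, raw_links, weight (sorted, reproducible)."""
    with atomic_write(path) as fh:
        fh.write("#contig1\tcontig2\traw_links\tweight\n")
        for u, v, d in sorted(cg.graph.edges(data=True)):
            a, b = (u, v) if u <= v else (v, u)
            fh.write(f"{a}\t{b}\t{d['raw_links']}\t{d['weight']:.10g}\n")


def read_links(path: str | Path, contigs: Sequence[Contig]) -> ContactGraph:
    cg = build_graph(empty_pairs(), contigs)
    g = cg.graph
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise DataError(f"{path}:{lineno}: expected 4 tab-separated fields")
            a, b, raw, w = fields
            if a not in g or b not in g:
                raise DataError(f"{path}:{lineno}: unknown or zero-site contig in link table")
            g.add_edge(a, b, raw_links=int(raw), weight=float(w))
    return cg
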