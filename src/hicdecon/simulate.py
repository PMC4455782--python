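"""Synthetic multi-species communities and Hi-C pair libraries.

The generator produces the statistical structure the clustering method
relies on, with none of the sequence-level realism it never uses: genomes
are i.i.d. uniform A/C/G/T (so restriction sites occur naturally with
expected spacing 4^|motif| bp), contigs are fixed-size bins of the
reference replicons (emulating a simulated draft assembly) or
lognormal-length fragments (emulating a real draft assembly), and pairs
are drawn per cell with configurable intra-chromosomal distance decay,
inter-replicon contacts, per-species abundance and lysis-efficiency
weights, and a fraction of spurious inter-cellular (noise) pairs.

Each endpoint is by default snapped to within ``site_window`` bp of the
nearest restriction site on its replicon, mirroring where real
proximity-ligation reads fall and making the downstream site filter's
behavior controllable.

Everything is reproducible from a single integer seed: genome synthesis
and pair sampling use independent streams spawned from it, so two configs
sharing a seed share genomes even if their library parameters differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .contacts import PAIR_COLUMNS, ContactGraph
from .contigs_io import Contig, SpeciesTruth, find_restriction_sites
from .errors import DataError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SpeciesSpec:
    label: str
    genome_length: int
    n_chromosomes: int = 1
    plasmid_length: int = 0
    abundance: float = 1.0
    lysis_efficiency: float = 1.0

    @property
    def total_length(self) -> int:
        return self.genome_length + self.plasmid_length


@dataclass(frozen=True)
class SharedSegment:
    """An exact sequence copy from ``donor`` into ``recipient``.

    Emulates near-identical sequence between close relatives: contigs
    overlapping the segment on either side carry both species labels in
    the truth table (any-alignment membership semantics).
    """

    donor: str
    recipient: str
    segment_length: int


@dataclass
class SimConfig:
    """Full parameterization of a synthetic community and its Hi-C library.

    contig_mode "fixed_bins" splits each replicon into ``bin_size`` bp
    contigs; "variable" draws lognormal contig lengths with the given mean
    and sd (bp).  ``cis_fraction`` of within-cell pairs are
    intra-chromosomal with genomic separation ~ s^-cis_decay_exponent on
    [min_separation, replicon length); the rest are uniform inter-replicon
    contacts within the cell.  ``noise_fraction`` of all pairs join two
    different species (spurious inter-cellular ligations).  If
    ``site_spacing`` > 0, motif copies are additionally planted every
    site_spacing bp, each jittered by up to ``site_placement_jitter`` bp.
    """

    seed: int
    species: list[SpeciesSpec]
    shared_segments: list[SharedSegment] = field(default_factory=list)
    enzyme_motif: str = "AAGCTT"
    contig_mode: str = "fixed_bins"
    bin_size: int = 10_000
    contig_length_mean: float = 10_000.0
    contig_length_sd: float = 5_000.0
    n_pairs: int = 100_000
    cis_fraction: float = 0.9
    cis_decay_exponent: float = 1.0
    noise_fraction: float = 0.0
    min_separation: int = 1_000
    site_window: int = 500
    snap_to_sites: bool = True
    site_spacing: int = 0
    site_placement_jitter: int = 0

    def validate(self) -> None:
        problems = []
        if not self.species:
            problems.append("species: at least one species required")
        labels = [sp.label for sp in self.species]
        if len(set(labels)) != len(labels):
            problems.append("species: labels must be unique")
        for sp in self.species:
            if sp.abundance <= 0 or sp.lysis_efficiency <= 0:
                problems.append(f"species {sp.label}: abundance and lysis_efficiency must be > 0")
            if sp.n_chromosomes < 1:
                problems.append(f"species {sp.label}: n_chromosomes must be >= 1")
            if sp.genome_length < sp.n_chromosomes * 1_000:
                problems.append(f"species {sp.label}: genome_length must be >= n_chromosomes x 1 kb")
            if sp.plasmid_length < 0:
                problems.append(f"species {sp.label}: plasmid_length must be >= 0")
        for seg in self.shared_segments:
            if seg.donor not in labels or seg.recipient not in labels:
                problems.append(f"shared_segments: unknown species in ({seg.donor}, {seg.recipient})")
            if seg.donor == seg.recipient:
                problems.append("shared_segments: donor and recipient must differ")
            if seg.segment_length <= 0:
                problems.append("shared_segments: segment_length must be > 0")
        if self.contig_mode not in ("fixed_bins", "variable"):
            problems.append(f"contig_mode: unknown mode {self.contig_mode!r}")
        if self.contig_mode == "fixed_bins" and self.bin_size < 1:
            problems.append("bin_size: must be >= 1")
        if not 0.0 <= self.cis_fraction <= 1.0:
            problems.append("cis_fraction: must be in [0, 1]")
        if not 0.0 <= self.noise_fraction <= 1.0:
            problems.append("noise_fraction: must be in [0, 1]")
        if self.noise_fraction > 0 and len(self.species) < 2:
            problems.append("noise_fraction: needs >= 2 species")
        if self.n_pairs < 0:
            problems.append("n_pairs: must be >= 0")
        if self.min_separation < 1:
            problems.append("min_separation: must be >= 1")
        if self.site_window < 0:
            problems.append("site_window: must be >= 0")
        if problems:
            raise DataError("invalid simulation config: " + "; ".join(problems))


@dataclass
class Replicon:
    species: str
    name: str
    sequence: str
    sites: np.ndarray          # sorted site positions (first base)
    bin_starts: np.ndarray     # contig start offsets, ascending, starting at 0
    contig_ids: list[str]

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SimulatedCommunity:
    config: SimConfig
    replicons: list[Replicon]
    contigs: list[Contig]
    truth: SpeciesTruth

    def replicons_of(self, label: str) -> list[int]:
        return [i for i, r in enumerate(self.replicons) if r.species == label]


def _random_sequence(rng: np.random.Generator, length: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())


def _chromosome_lengths(sp: SpeciesSpec) -> list[int]:
    base = sp.genome_length // sp.n_chromosomes
    lengths = [base] * sp.n_chromosomes
    lengths[0] += sp.genome_length - base * sp.n_chromosomes
    return lengths


def _bin_starts(rng: np.random.Generator, length: int, config: SimConfig) -> np.ndarray:
    if config.contig_mode == "fixed_bins":
        return np.arange(0, length, config.bin_size, dtype=np.int64)
    # variable: lognormal contig lengths chopped sequentially
    m, s = config.contig_length_mean, config.contig_length_sd
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2
    starts = [0]
    while starts[-1] < length:
        ln = max(1_000, int(rng.lognormal(mu, np.sqrt(sigma2))))
        starts.append(starts[-1] + ln)
    return np.asarray(starts[:-1], dtype=np.int64)


def simulate_genomes(config: SimConfig) -> SimulatedCommunity:
    """Synthesize replicon sequences, the contig set, and the truth table."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    motif = config.enzyme_motif.upper()
    mlen = len(motif)

    seqs: dict[str, dict[str, bytearray]] = {}
    for sp in config.species:
        reps: dict[str, bytearray] = {}
        for j, ln in enumerate(_chromosome_lengths(sp)):
            reps[f"{sp.label}_chr{j + 1}"] = _random_sequence(rng, ln)
        if sp.plasmid_length > 0:
            reps[f"{sp.label}_plasmid"] = _random_sequence(rng, sp.plasmid_length)
        seqs[sp.label] = reps

    if config.site_spacing > 0:
        jitter = config.site_placement_jitter
        motif_bytes = motif.encode()
        for reps in seqs.values():
            for seq in reps.values():
                anchors = np.arange(config.site_spacing, len(seq) - mlen, config.site_spacing)
                if jitter > 0 and anchors.size:
                    anchors = anchors + rng.integers(-jitter, jitter + 1, size=anchors.size)
                    anchors = np.clip(anchors, 0, len(seq) - mlen)
                for a in anchors:
                    seq[a:a + mlen] = motif_bytes

    # exact-copy shared segments: chr1 of donor -> chr1 of recipient
    extra_labels: list[tuple[str, int, int, str]] = []  # (replicon, start, end, extra label)
    for seg in config.shared_segments:
        donor_name = f"{seg.donor}_chr1"
        recip_name = f"{seg.recipient}_chr1"
        donor_seq = seqs[seg.donor][donor_name]
        recip_seq = seqs[seg.recipient][recip_name]
        if seg.segment_length > min(len(donor_seq), len(recip_seq)):
            raise DataError(f"shared segment ({seg.donor}, {seg.recipient}) longer than a chromosome")
        src = int(rng.integers(0, len(donor_seq) - seg.segment_length + 1))
        dst = int(rng.integers(0, len(recip_seq) - seg.segment_length + 1))
        recip_seq[dst:dst + seg.segment_length] = donor_seq[src:src + seg.segment_length]
        extra_labels.append((donor_name, src, src + seg.segment_length, seg.recipient))
        extra_labels.append((recip_name, dst, dst + seg.segment_length, seg.donor))

    replicons: list[Replicon] = []
    contigs: list[Contig] = []
    membership: dict[str, set[str]] = {}
    for sp in config.species:
        for name, seq in seqs[sp.label].items():
            text = seq.decode()
            starts = _bin_starts(rng, len(text), config)
            bounds = np.append(starts, len(text))
            ids = []
            for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
                cid = f"{name}_b{i:04d}"
                ids.append(cid)
                sub = text[a:b]
                contigs.append(Contig(
                    id=cid, length=len(sub), sequence=sub,
                    site_positions=tuple(find_restriction_sites(sub, motif)),
                ))
                labels = {sp.label}
                for rep_name, lo, hi, extra in extra_labels:
                    if rep_name == name and a < hi and b > lo:
                        labels.add(extra)
                membership[cid] = labels
            replicons.append(Replicon(
                species=sp.label, name=name, sequence=text,
                sites=np.asarray(find_restriction_sites(text, motif), dtype=np.int64),
                bin_starts=starts, contig_ids=ids,
            ))
    truth = SpeciesTruth({cid: frozenset(s) for cid, s in membership.items()})
    return SimulatedCommunity(config=config, replicons=replicons,
                              contigs=contigs, truth=truth)


def sample_cis_separation(rng: np.random.Generator, size: int, s_min: int,
                          s_max: int, alpha: float) -> np.ndarray:
    """Inverse-CDF sample of separations ~ s^-alpha on [s_min, s_max)."""
    if s_max <= s_min:
        return np.full(size, s_min, dtype=np.int64)
    u = rng.random(size)
    if abs(alpha - 1.0) < 1e-12:
        s = s_min * (s_max / s_min) ** u
    else:
        a = 1.0 - alpha
        s = (s_min ** a + u * (s_max ** a - s_min ** a)) ** (1.0 / a)
    return np.clip(s.astype(np.int64), s_min, s_max - 1)


def simulate_hic(config: SimConfig, community: SimulatedCommunity) -> pd.DataFrame:
    """Draw the Hi-C pair library; returns a pair table in contig coordinates."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_pairs
    reps = community.replicons
    n_species = len(config.species)
    sp_weight = np.array([sp.abundance * sp.lysis_efficiency * sp.total_length
                          for sp in config.species], dtype=float)
    sp_weight /= sp_weight.sum()
    rep_of_species = [community.replicons_of(sp.label) for sp in config.species]
    rep_len = np.array([r.length for r in reps], dtype=np.int64)
    rep_probs = []
    for idxs in rep_of_species:
        lens = rep_len[idxs].astype(float)
        rep_probs.append(lens / lens.sum())

    if config.noise_fraction == 0:
        for s, sp in enumerate(config.species):
            if all(reps[i].sites.size == 0 for i in rep_of_species[s]):
                warnings.warn(f"species {sp.label!r} has no restriction sites; "
                              "all of its pairs will be filtered out")

    rep1 = np.empty(n, dtype=np.int64)
    pos1 = np.empty(n, dtype=np.int64)
    rep2 = np.empty(n, dtype=np.int64)
    pos2 = np.empty(n, dtype=np.int64)

    is_noise = rng.random(n) < config.noise_fraction
    noise_idx = np.flatnonzero(is_noise)
    cell_idx = np.flatnonzero(~is_noise)

    # --- spurious inter-cellular pairs: two different species ---
    if noise_idx.size:
        sp_a = rng.choice(n_species, size=noise_idx.size, p=sp_weight)
        sp_b = rng.choice(n_species, size=noise_idx.size, p=sp_weight)
        clash = sp_a == sp_b
        while clash.any():
            sp_b[clash] = rng.choice(n_species, size=int(clash.sum()), p=sp_weight)
            clash = sp_a == sp_b
        for side, sp_arr, rep_arr, pos_arr in ((1, sp_a, rep1, pos1), (2, sp_b, rep2, pos2)):
            for s in range(n_species):
                m = np.flatnonzero(sp_arr == s)
                if not m.size:
                    continue
                chosen = rng.choice(rep_of_species[s], size=m.size, p=rep_probs[s])
                rep_arr[noise_idx[m]] = chosen
                pos_arr[noise_idx[m]] = rng.integers(0, rep_len[chosen])

    # --- within-cell pairs ---
    if cell_idx.size:
        sp = rng.choice(n_species, size=cell_idx.size, p=sp_weight)
        is_cis = rng.random(cell_idx.size) < config.cis_fraction
        for s in range(n_species):
            idxs = rep_of_species[s]
            sel = sp == s
            # cis: one replicon, power-law separation
            m = np.flatnonzero(sel & is_cis)
            if m.size:
                chosen = rng.choice(idxs, size=m.size, p=rep_probs[s])
                rows = cell_idx[m]
                for ri in np.unique(chosen):
                    sub = rows[chosen == ri]
                    L = int(rep_len[ri])
                    smax = max(L - 1, config.min_separation + 1)
                    s_sep = sample_cis_separation(rng, sub.size, config.min_separation,
                                                  smax, config.cis_decay_exponent)
                    s_sep = np.minimum(s_sep, L - 1)
                    p1 = rng.integers(0, rep_len[ri] - s_sep)
                    rep1[sub] = ri
                    rep2[sub] = ri
                    pos1[sub] = p1
                    pos2[sub] = p1 + s_sep
            # trans within the cell: two replicons, uniform positions
            m = np.flatnonzero(sel & ~is_cis)
            if m.size:
                rows = cell_idx[m]
                if len(idxs) == 1:
                    rep1[rows] = rep2[rows] = idxs[0]
                    pos1[rows] = rng.integers(0, rep_len[idxs[0]], size=rows.size)
                    pos2[rows] = rng.integers(0, rep_len[idxs[0]], size=rows.size)
                else:
                    r_a = rng.choice(idxs, size=rows.size, p=rep_probs[s])
                    r_b = rng.choice(idxs, size=rows.size, p=rep_probs[s])
                    clash = r_a == r_b
                    while clash.any():
                        r_b[clash] = rng.choice(idxs, size=int(clash.sum()), p=rep_probs[s])
                        clash = r_a == r_b
                    rep1[rows] = r_a
                    rep2[rows] = r_b
                    pos1[rows] = rng.integers(0, rep_len[r_a])
                    pos2[rows] = rng.integers(0, rep_len[r_b])

    if config.snap_to_sites:
        for rep_arr, pos_arr in ((rep1, pos1), (rep2, pos2)):
            for ri in np.unique(rep_arr):
                sites = reps[ri].sites
                if sites.size == 0:
                    continue
                m = np.flatnonzero(rep_arr == ri)
                p = pos_arr[m]
                idx = np.searchsorted(sites, p)
                left = sites[np.clip(idx - 1, 0, sites.size - 1)]
                right = sites[np.clip(idx, 0, sites.size - 1)]
                nearest = np.where(np.abs(p - left) <= np.abs(p - right), left, right)
                off = rng.integers(-config.site_window, config.site_window + 1, size=m.size)
                pos_arr[m] = np.clip(nearest + off, 0, rep_len[ri] - 1)

    # map replicon coordinates to (contig, offset)
    contig1 = np.empty(n, dtype=object)
    contig2 = np.empty(n, dtype=object)
    off1 = np.empty(n, dtype=np.int64)
    off2 = np.empty(n, dtype=np.int64)
    for rep_arr, cid_arr, off_arr, pos_arr in ((rep1, contig1, off1, pos1),
                                               (rep2, contig2, off2, pos2)):
        for ri in np.unique(rep_arr):
            r = reps[ri]
            m = np.flatnonzero(rep_arr == ri)
            b = np.searchsorted(r.bin_starts, pos_arr[m], side="right") - 1
            ids = np.asarray(r.contig_ids, dtype=object)
            cid_arr[m] = ids[b]
            off_arr[m] = pos_arr[m] - r.bin_starts[b]

    strands = np.array(["+", "-"], dtype=object)
    return pd.DataFrame({
        "read_id": [f"SIM{i:08d}" for i in range(n)],
        "contig1": contig1,
        "pos1": off1,
        "contig2": contig2,
        "pos2": off2,
        "strand1": strands[rng.integers(0, 2, size=n)],
        "strand2": strands[rng.integers(0, 2, size=n)],
    }, columns=PAIR_COLUMNS)


def simulate_planted_graph(n_species: int, nodes_per_species: int, seed: int,
                           within_density: float = 0.9,
                           between_density: float = 0.1,
                           within_mean_links: float = 40.0,
                           between_mean_links: float = 1.5,
                           contig_length: int = 10_000
                           ) -> tuple[ContactGraph, dict[str, str]]:
    """A planted-partition contact graph with known block structure.

    Nodes carry site_count 1, so normalized weights equal raw link counts;
    within-block edges are dense and heavy, between-block edges sparse and
    light (default mean weight ratio ~27x).  Returns the graph and the
    node -> block label map.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    g = nx.Graph()
    labels: dict[str, str] = {}
    blocks: list[list[str]] = []
    for s in range(n_species):
        block = [f"sp{s:02d}_n{j:03d}" for j in range(nodes_per_species)]
        blocks.append(block)
        for v in block:
            g.add_node(v, length=contig_length, site_count=1)
            labels[v] = f"sp{s:02d}"
    for s, block in enumerate(blocks):
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                if rng.random() < within_density:
                    raw = 1 + rng.poisson(within_mean_links - 1)
                    g.add_edge(block[i], block[j], raw_links=int(raw), weight=float(raw))
        for t in range(s + 1, n_species):
            for u in blocks[s]:
                for v in blocks[t]:
                    if rng.random() < between_density:
                        raw = 1 + rng.poisson(between_mean_links - 1)
                        g.add_edge(u, v, raw_links=int(raw), weight=float(raw))
    return ContactGraph(graph=g), labels


def pairs_from_graph(cg: ContactGraph) -> pd.DataFrame:
    """Expand a contact graph into one pair row per raw link (for resampling)."""
    c1, c2 = [], []
    for u, v, d in sorted(cg.graph.edges(data=True)):
        c1.extend([u] * d["raw_links"])
        c2.extend([v] * d["raw_links"])
    n = len(c1)
    return pd.DataFrame({
        "read_id": [f"G{i:08d}" for i in range(n)],
        "contig1": np.asarray(c1, dtype=object),
        "pos1": np.zeros(n, dtype=np.int64),
        "contig2": np.asarray(c2, dtype=object),
        "pos2": np.zeros(n, dtype=np.int64),
        "strand1": np.full(n, "+", dtype=object),
        "strand2": np.full(n, "-", dtype=object),
    }, columns=PAIR_COLUMNS)
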