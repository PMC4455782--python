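"""Assembly I/O, restriction-site annotation, and truth tables.

Contigs are read from standard multi-record FASTA.  Restriction sites are
exact motif occurrences on either strand (HindIII ``AAGCTT`` and NcoI
``CCATGG`` are both palindromic, so forward-only and both-strand searches
coincide for them).  Site counts per contig are the denominator of the
contact-graph normalization, and site positions drive the read-pair
proximity filter.

All coordinates are 0-based half-open internally; a site's position is the
offset of the motif's first base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from ._util import atomic_write
from .errors import DataError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(motif: str) -> str:
    return motif.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Contig:
    """A named assembly sequence with optional restriction-site annotation.

    ``site_positions`` is ``None`` until the contig has been annotated with
    :func:`annotate_sites`; afterwards it is a strictly increasing tuple of
    0-based offsets of the motif's first base.
    """

    id: str
    length: int
    site_positions: Optional[tuple[int, ...]] = None
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.length <= 0:
            raise DataError(f"contig {self.id!r} has non-positive length {self.length}")
        if self.site_positions is not None:
            pos = self.site_positions
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise DataError(f"contig {self.id!r}: site positions not strictly increasing")
            if pos and (pos[0] < 0 or pos[-1] >= self.length):
                raise DataError(f"contig {self.id!r}: site position out of bounds")

    @property
    def site_count(self) -> int:
        if self.site_positions is None:
            raise DataError(f"contig {self.id!r} has no site annotation")
        return len(self.site_positions)


def _scan(seq: str, pattern: str) -> Iterable[int]:
    i = seq.find(pattern)
    while i != -1:
        yield i
        i = seq.find(pattern, i + 1)  # overlapping occurrences allowed


def find_restriction_sites(sequence: str, motif: str) -> list[int]:
    """All exact occurrences of ``motif`` (either strand) in ``sequence``.

    Matching is case-insensitive and exact: IUPAC ambiguity codes in the
    sequence never match.  If the motif is not its own reverse complement,
    occurrences of the reverse complement are merged in.  Overlapping
    occurrences are each counted.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    if any(ch not in "ACGT" for ch in motif):
        raise ValueError(f"motif {motif!r} must contain only A/C/G/T")
    seq = sequence.upper()
    hits = set(_scan(seq, motif))
    rc = reverse_complement(motif)
    if rc != motif:
        hits.update(_scan(seq, rc))
    return sorted(hits)


def annotate_sites(contigs: Sequence[Contig], motif: str) -> list[Contig]:
    """Return copies of ``contigs`` with ``site_positions`` filled in."""
    out = []
    for c in contigs:
        if c.sequence is None:
            raise DataError(f"contig {c.id!r} has no sequence; cannot locate sites")
        out.append(replace(c, site_positions=tuple(find_restriction_sites(c.sequence, motif))))
    return out


def read_assembly(path: str | Path, motif: Optional[str] = None) -> list[Contig]:
    """Read a FASTA assembly; optionally annotate restriction sites.

    Sequences are retained on the returned contigs (needed for site
    finding and per-cluster FASTA export).  Duplicate record ids and empty
    files are hard errors.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        contigs.append(Contig(id=rec.id, length=len(seq), sequence=seq))
    if not contigs:
        raise DataError(f"no FASTA records found in {path}")
    if motif is not None:
        contigs = annotate_sites(contigs, motif)
    return contigs


def write_assembly(contigs: Sequence[Contig], path: str | Path) -> None:
    with atomic_write(path) as fh:
        SeqIO.write(
            (SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs),
            fh,
            "fasta",
        )


def write_sites_table(contigs: Sequence[Contig], path: str | Path) -> None:
    """TSV: contig_id, length, site_count, comma-joined site positions."""
    with atomic_write(path) as fh:
        for c in contigs:
            joined = ",".join(str(p) for p in (c.site_positions or ()))
            fh.write(f"{c.id}\t{c.length}\t{c.site_count}\t{joined}\n")


def read_sites_table(path: str | Path) -> list[Contig]:
    contigs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise DataError(f"{path}:{lineno}: expected 4 tab-separated fields")
            cid, length, count, joined = fields
            positions = tuple(int(p) for p in joined.split(",")) if joined else ()
            if int(count) != len(positions):
                raise DataError(f"{path}:{lineno}: site_count does not match positions")
            contigs.append(Contig(id=cid, length=int(length), site_positions=positions))
    if not contigs:
        raise DataError(f"no records in sites table {path}")
    return contigs


@dataclass(frozen=True)
class SpeciesTruth:
    """Contig id -> non-empty set of species labels (multi-membership allowed).

    Typically produced by aligning contigs against a combined reference: a
    contig belongs to every species whose genome it aligns to anywhere, so
    contigs shared between close relatives carry several labels.
    """

    membership: Mapping[str, frozenset[str]]

    def __post_init__(self):
        for cid, labels in self.membership.items():
            if not labels:
                raise DataError(f"truth entry for {cid!r} has no labels")

    @property
    def labels(self) -> list[str]:
        out: set[str] = set()
        for s in self.membership.values():
            out.update(s)
        return sorted(out)

    def get(self, contig_id: str) -> Optional[frozenset[str]]:
        return self.membership.get(contig_id)


def read_truth(path: str | Path, known_ids: Optional[Iterable[str]] = None) -> SpeciesTruth:
    """Read a two-column ``contig_id<TAB>species`` table (multi-row = multi-label).

    Contigs absent from ``known_ids`` (when given) trigger a warning but are
    kept, so truth tables for supersets of a partial assembly still load.
    """
    membership: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise DataError(f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}")
            cid, label = fields
            if not cid or not label:
                raise DataError(f"{path}:{lineno}: empty contig id or species label")
            membership.setdefault(cid, set()).add(label)
    if not membership:
        warnings.warn(f"truth table {path} is empty")
    if known_ids is not None:
        known = set(known_ids)
        unknown = sorted(set(membership) - known)
        if unknown:
            warnings.warn(
                f"truth table {path} names {len(unknown)} contig(s) absent from the assembly "
                f"(first: {unknown[0]!r})"
            )
    return SpeciesTruth({cid: frozenset(s) for cid, s in membership.items()})


def write_truth(truth: SpeciesTruth, path: str | Path) -> None:
    with atomic_write(path) as fh:
        for cid in sorted(truth.membership):
            for label in sorted(truth.membership[cid]):
                fh.write(f"{cid}\t{label}\n")
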