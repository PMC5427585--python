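"""Exact full-length read placement on allele typing sequences.

Only reads showing 100% identity with a typing sequence (on either strand)
are placed; everything else is discarded.  An ambiguous base N in a read
matches nothing, so any read containing N is unplaceable by construction.

Coordinates are 0-based inclusive.  Read centers are kept in doubled-integer
units (start + end) so half-integer midpoints of even-length reads stay
exact; downstream distance arithmetic divides by two when converting to
base pairs.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

from hlatyper.allele_db import AlleleName, RepresentativeGroup

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    mate: int | None = None


@dataclass(frozen=True)
class Placement:
    """An exact match of one read on one typing sequence."""

    read_id: str
    allele: AlleleName | None
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_center(p: Placement) -> int:
    """Center of a placement in doubled units: start + end = 2 × midpoint."""
    return p.start + p.end


def _find_all(needle: str, haystack: str) -> Iterator[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def place_read(
    read: Read, typing_sequence: str, allele: AlleleName | None = None
) -> list[Placement]:
    """All exact full-length placements of a read (or its reverse complement).

    Returns an empty list when the read does not match anywhere, is longer
    than the sequence, or contains N.  A palindromic read (equal to its own
    reverse complement) is reported once per position, on the + strand.
    """
    seq = read.sequence
    n = len(seq)
    if n == 0 or n > len(typing_sequence) or "N" in seq:
        return []
    placements = [
        Placement(read.id, allele, i, i + n - 1, "+")
        for i in _find_all(seq, typing_sequence)
    ]
    rc = reverse_complement(seq)
    if rc != seq:
        placements += [
            Placement(read.id, allele, i, i + n - 1, "-")
            for i in _find_all(rc, typing_sequence)
        ]
    placements.sort(key=lambda p: (p.start, p.strand))
    return placements


@dataclass(frozen=True)
class AlignmentProfile:
    """Placed reads on one representative allele plus their sorted centers."""

    allele: AlleleName
    placements: tuple[Placement, ...]
    centers: tuple[int, ...]
    region_length: int

    @property
    def read_ids(self) -> frozenset[str]:
        return frozenset(p.read_id for p in self.placements)


def build_profiles(
    reads: Sequence[Read], groups: Sequence[RepresentativeGroup]
) -> dict[str, AlignmentProfile]:
    """One profile per representative allele, keyed by rendered name.

    A read may contribute to many alleles; within one allele, duplicate
    placements of the same read at the same coordinates collapse to one.
    The result is independent of read order.
    """
    if not groups:
        raise ValueError("no representative groups supplied")
    profiles: dict[str, AlignmentProfile] = {}
    for g in groups:
        seen: set[tuple[str, int, int, str]] = set()
        placements: list[Placement] = []
        for read in reads:
            for p in place_read(read, g.typing_sequence, g.representative):
                key = (p.read_id, p.start, p.end, p.strand)
                if key not in seen:
                    seen.add(key)
                    placements.append(p)
        placements.sort(key=lambda p: (p.start, p.end, p.read_id, p.strand))
        centers = tuple(sorted(read_center(p) for p in placements))
        profiles[g.representative.render()] = AlignmentProfile(
            allele=g.representative,
            placements=tuple(placements),
            centers=centers,
            region_length=len(g.typing_sequence),
        )
    return profiles


def read_fastq(path: str | Path) -> list[Read]:
    """Load reads from a plain or gzipped FASTQ; qualities are ignored."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        return [Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


def placements_to_tsv(
    profiles: Mapping[str, AlignmentProfile] | Iterable[AlignmentProfile],
    handle: IO[str],
) -> None:
    """Write placements as TSV (read_id, allele, start, end, strand)."""
    items = profiles.values() if isinstance(profiles, Mapping) else profiles
    handle.write("read_id\tallele\tstart\tend\tstrand\n")
    for prof in items:
        for p in prof.placements:
            allele = p.allele.render() if p.allele else ""
            handle.write(f"{p.read_id}\t{allele}\t{p.start}\t{p.end}\t{p.strand}\n")
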