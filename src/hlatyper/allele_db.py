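"""Allele reference handling: nomenclature, FASTA parsing, representative grouping.

HLA alleles follow the colon-delimited field nomenclature
``gene*f1:f2[:f3[:f4]][suffix]`` (e.g. ``A*02:01:01:01`` or ``B*44:02:01:02S``).
The first field is the antigen group (two-digit resolution), the second the
protein (four-digit resolution); third and fourth fields add synonymous and
non-coding distinctions.  Fields are text, not integers: leading zeros are
significant (``02`` is not ``2``).

Because many alleles deposit identical sequences for the exons actually used
for typing, alleles are collapsed into *representative groups*: all alleles
whose typing-exon sequences are byte-identical form one group, named by the
longest shared leading-field prefix of its members.  Reads are placed against
the group's concatenated typing sequence, never against individual
indistinguishable alleles.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from Bio import SeqIO

_ALLELE_TOKEN_RE = re.compile(
    r"^(?:HLA-)?(?P<gene>[A-Z][A-Za-z0-9]*)\*(?P<fields>\d+(?::\d+){0,3})(?P<suffix>[A-Z]?)$"
)

_VALID_BASES = frozenset("ACGTN")

#: Gene → class membership used to pick the default exon policy.  The five
#: classical genes typed here are class I (A, B, C) and class II (DQB1, DRB1).
DEFAULT_GENE_CLASSES: dict[str, str] = {
    "A": "I",
    "B": "I",
    "C": "I",
    "DQB1": "II",
    "DRB1": "II",
}


@dataclass(frozen=True, order=True)
class AlleleName:
    """A parsed allele name in colon-delimited field notation."""

    gene: str
    fields: tuple[str, ...]
    suffix: str = ""

    def __post_init__(self) -> None:
        if not self.fields:
            raise ValueError("allele name needs at least one numeric field")
        if len(self.fields) > 4:
            raise ValueError(f"allele name has more than four fields: {self.fields}")

    def render(self) -> str:
        return f"{self.gene}*{':'.join(self.fields)}{self.suffix}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @classmethod
    def parse(cls, token: str) -> "AlleleName":
        """Parse one ``gene*f1:f2...`` token; raises ValueError if malformed."""
        m = _ALLELE_TOKEN_RE.match(token.strip())
        if m is None:
            raise ValueError(f"not an allele name: {token!r}")
        return cls(
            gene=m.group("gene"),
            fields=tuple(m.group("fields").split(":")),
            suffix=m.group("suffix"),
        )


def truncate_name(name: AlleleName, digits: int) -> AlleleName:
    """Truncate an allele name to a digit resolution (2, 4, 6 or 8).

    Two digits per field: four-digit resolution keeps the first two fields.
    The expression suffix is dropped unless every field is retained.  Names
    with fewer fields than requested are returned unchanged, which makes the
    operation idempotent and monotone across levels.
    """
    if digits not in (2, 4, 6, 8):
        raise ValueError(f"digits must be 2, 4, 6 or 8, got {digits}")
    keep = digits // 2
    if keep >= len(name.fields):
        return name
    return AlleleName(name.gene, name.fields[:keep], "")


@dataclass(frozen=True)
class AlleleRecord:
    """One named allele with its per-exon nucleotide sequences."""

    name: AlleleName
    exons: Mapping[int, str]
    source_id: str = ""

    def __post_init__(self) -> None:
        for idx, seq in self.exons.items():
            if idx < 1:
                raise ValueError(f"exon index must be >= 1, got {idx}")
            if not seq:
                raise ValueError(f"{self.name.render()}: exon {idx} is empty")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"{self.name.render()}: exon {idx} has invalid bases {sorted(bad)}"
                )

    def concat(self, exons: Sequence[int]) -> str:
        """Concatenate the requested exons that this record actually has."""
        return "".join(self.exons[e] for e in exons if e in self.exons)


@dataclass(frozen=True)
class ExonPolicy:
    """Primary typing exons, with fallback exons engaged only on ambiguity."""

    primary: tuple[int, ...]
    fallback: tuple[int, ...]


def default_policy(gene: str, gene_classes: Mapping[str, str] | None = None) -> ExonPolicy:
    """Default exon policy: class I → primary 2–3, fallback 4–5;
    class II (and unknown genes) → primary 2, fallback 3–4."""
    classes = DEFAULT_GENE_CLASSES if gene_classes is None else gene_classes
    if classes.get(gene, "II") == "I":
        return ExonPolicy(primary=(2, 3), fallback=(4, 5))
    return ExonPolicy(primary=(2,), fallback=(3, 4))


@dataclass
class AlleleDatabase:
    """A collection of allele records plus the per-gene exon policy."""

    records: list[AlleleRecord]
    gene_exon_policy: dict[str, ExonPolicy] = field(default_factory=dict)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        seen: dict[str, AlleleRecord] = {}
        for rec in self.records:
            key = rec.name.render()
            if key in seen:
                raise ValueError(f"duplicate allele name: {key}")
            seen[key] = rec
        self._by_name = seen

    def genes(self) -> list[str]:
        return sorted({rec.name.gene for rec in self.records})

    def records_for(self, gene: str) -> list[AlleleRecord]:
        return [rec for rec in self.records if rec.name.gene == gene]

    def get(self, name: AlleleName | str) -> AlleleRecord:
        key = name.render() if isinstance(name, AlleleName) else name
        try:
            return self._by_name[key]
        except KeyError:
            raise KeyError(f"allele not in database: {key}") from None

    def policy(self, gene: str) -> ExonPolicy:
        return self.gene_exon_policy.get(gene) or default_policy(gene)


def _name_from_description(description: str) -> AlleleName | None:
    for token in description.split():
        try:
            return AlleleName.parse(token)
        except ValueError:
            continue
    return None


def read_exon_map(path: str | Path) -> dict[str, dict[int, tuple[int, int]]]:
    """Read a TSV exon-boundary table (allele, exon, start, end; 1-based inclusive)."""
    table: dict[str, dict[int, tuple[int, int]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"allele", "exon", "start", "end"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"exon map needs columns {sorted(required)}")
        for row in reader:
            table.setdefault(row["allele"], {})[int(row["exon"])] = (
                int(row["start"]),
                int(row["end"]),
            )
    return table


def parse_allele_fasta(
    source: str | Path | IO[str],
    exon_map: Mapping[str, Mapping[int, tuple[int, int]]] | None = None,
    gene_classes: Mapping[str, str] | None = None,
) -> AlleleDatabase:
    """Parse an allele-reference FASTA into an :class:`AlleleDatabase`.

    The allele name is taken from the first whitespace token of each header
    that parses as ``gene*f1:f2...`` (IMGT-style headers such as
    ``HLA:HLA00005 A*02:01:01:01 1098 bp`` work as-is).  Records whose header
    contains no parseable name are skipped and counted in ``n_skipped``.

    Without an ``exon_map`` each FASTA record is treated as a single typing
    exon with index 2; with one, the listed 1-based inclusive slices become
    the record's exons.
    """
    records: list[AlleleRecord] = []
    n_skipped = 0
    n_fasta = 0
    for seqrec in SeqIO.parse(source, "fasta"):
        n_fasta += 1
        name = _name_from_description(seqrec.description)
        if name is None:
            n_skipped += 1
            continue
        seq = str(seqrec.seq).upper()
        rendered = name.render()
        if exon_map and rendered in exon_map:
            exons = {
                int(e): seq[start - 1 : end]
                for e, (start, end) in exon_map[rendered].items()
            }
            for e, (start, end) in exon_map[rendered].items():
                if start < 1 or end > len(seq) or start > end:
                    raise ValueError(
                        f"{rendered}: exon {e} bounds {start}-{end} outside record"
                    )
        else:
            exons = {2: seq}
        records.append(AlleleRecord(name=name, exons=exons, source_id=seqrec.id))
    if n_fasta == 0:
        raise ValueError("empty FASTA: no allele records found")
    genes = {rec.name.gene for rec in records}
    policy = {g: default_policy(g, gene_classes) for g in sorted(genes)}
    return AlleleDatabase(records=records, gene_exon_policy=policy, n_skipped=n_skipped)


@dataclass(frozen=True)
class RepresentativeGroup:
    """Alleles whose typing-exon sequences are identical, under one name.

    The representative name is the longest field prefix shared by all member
    names; when members share no field at all the lexicographically smallest
    member stands in and the group is flagged.
    """

    representative: AlleleName
    members: tuple[AlleleName, ...]
    typing_sequence: str
    exons_used: tuple[int, ...]
    flagged: bool = False


def _common_prefix_fields(names: Sequence[AlleleName]) -> tuple[str, ...]:
    first = names[0].fields
    keep = 0
    for i, f in enumerate(first):
        if all(len(n.fields) > i and n.fields[i] == f for n in names[1:]):
            keep = i + 1
        else:
            break
    return first[:keep]


def build_representative_groups(
    db: AlleleDatabase, gene: str, exons: Sequence[int]
) -> list[RepresentativeGroup]:
    """Partition a gene's alleles into groups with identical typing exons.

    Records are keyed by the exact sequences of the requested exons they
    carry; records missing some requested exon are grouped over the exons
    they do have (partially deposited alleles are compared on the available
    intersection rather than discarded).  Records carrying none of the
    requested exons are left out of the partition.
    """
    recs = db.records_for(gene)
    if not recs:
        raise ValueError(f"gene not in database: {gene}")
    buckets: dict[tuple[tuple[int, str], ...], list[AlleleRecord]] = {}
    for rec in recs:
        key = tuple((e, rec.exons[e]) for e in exons if e in rec.exons)
        if not key:
            continue
        buckets.setdefault(key, []).append(rec)

    groups: list[RepresentativeGroup] = []
    for key, members in buckets.items():
        names = tuple(sorted((m.name for m in members), key=AlleleName.render))
        flagged = False
        if len(names) == 1:
            rep = names[0]
        else:
            common = _common_prefix_fields(names)
            if common:
                rep = AlleleName(gene, common, "")
            else:
                rep = names[0]
                flagged = True
        groups.append(
            RepresentativeGroup(
                representative=rep,
                members=names,
                typing_sequence="".join(seq for _, seq in key),
                exons_used=tuple(e for e, _ in key),
                flagged=flagged,
            )
        )

    # Distinct groups can collapse onto one prefix name (e.g. {01:01:01,
    # 01:03} and {01:01:02, 01:02} both reduce to A*01); fall back to the
    # smallest member name so rendered representatives stay unique.
    by_name: dict[str, int] = {}
    for g in groups:
        by_name[g.representative.render()] = by_name.get(g.representative.render(), 0) + 1
    resolved = []
    for g in groups:
        if by_name[g.representative.render()] > 1:
            g = RepresentativeGroup(
                representative=g.members[0],
                members=g.members,
                typing_sequence=g.typing_sequence,
                exons_used=g.exons_used,
                flagged=True,
            )
        resolved.append(g)
    return sorted(resolved, key=lambda g: g.representative.render())


def groups_to_json(groups: Iterable[RepresentativeGroup]) -> str:
    """Serialize representative groups (name, members, exons used) as JSON."""
    payload = [
        {
            "representative": g.representative.render(),
            "members": [m.render() for m in g.members],
            "exons_used": list(g.exons_used),
            "flagged": g.flagged,
        }
        for g in groups
    ]
    return json.dumps(payload, indent=2)
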