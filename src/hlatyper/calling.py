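"""Duplicate-allele removal, unique-read phasing, and the final genotype call.

After score filtering, candidates that survive only because they share
sequence with a true allele are pruned in two ways.  First, alleles with
byte-identical typing exons were already collapsed to a representative
(:mod:`hlatyper.allele_db`).  Second, a candidate whose placed reads form a
proper subset of another candidate's reads carries no evidence of its own
and is removed here.  What remains is ranked by *unique* reads — reads
placed on exactly one retained candidate — which are the unit of evidence
that defeats short-read phasing ambiguity: a false recombinant candidate
can share reads with both true alleles but can never own a read that
neither true allele explains.

The call is heterozygous when the top two candidates both carry at least
one unique read, homozygous when only the top one does.  If no candidate
carries a unique read (legitimately possible after representative
collapsing) the top candidate by total read count is emitted as a
low-confidence homozygote rather than failing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from hlatyper.allele_db import (
    AlleleDatabase,
    AlleleName,
    RepresentativeGroup,
    build_representative_groups,
    truncate_name,
)
from hlatyper.aligner import Read, build_profiles
from hlatyper.scoring import ScoreParams, ScoredAllele, filter_by_score, score_profiles


@dataclass(frozen=True)
class Candidate:
    """A score-passing allele with its placed read-id set."""

    allele: AlleleName
    read_ids: frozenset[str]
    score: float
    group: RepresentativeGroup | None = None


@dataclass(frozen=True)
class CandidateSet:
    gene: str
    candidates: tuple[Candidate, ...]

    @classmethod
    def from_scored(
        cls,
        gene: str,
        scored: Sequence[ScoredAllele],
        groups: Sequence[RepresentativeGroup] = (),
    ) -> "CandidateSet":
        by_name = {g.representative.render(): g for g in groups}
        return cls(
            gene=gene,
            candidates=tuple(
                Candidate(
                    allele=s.allele,
                    read_ids=s.read_ids,
                    score=s.score,
                    group=by_name.get(s.allele.render()),
                )
                for s in scored
            ),
        )


def remove_subset_duplicates(cs: CandidateSet) -> CandidateSet:
    """Drop candidates whose read set is a proper subset of another's.

    A proper-subset candidate has, by definition, no read absent from its
    superset candidate, hence no unique sequence block of its own.
    Candidates with equal read sets are all retained (they are distinct
    typing sequences that happen to catch the same reads) and left to the
    ranking tie-breaks.  The operation is idempotent and order-invariant.
    """
    kept = tuple(
        c
        for c in cs.candidates
        if not any(c.read_ids < o.read_ids for o in cs.candidates if o is not c)
    )
    return CandidateSet(gene=cs.gene, candidates=kept)


def count_unique_reads(candidate: Candidate, others: Iterable[Candidate]) -> int:
    """Reads placed on this candidate and on no other given candidate."""
    covered: set[str] = set()
    for o in others:
        covered |= o.read_ids
    return len(candidate.read_ids - covered)


@dataclass(frozen=True)
class GenotypeCall:
    """Final one- or two-allele call for a gene, at representative level."""

    gene: str
    alleles: tuple[AlleleName, ...]
    zygosity: str  # "het" | "hom" | "nocall"
    unique_read_counts: tuple[int, ...] = ()
    total_reads: tuple[int, ...] = ()
    scores: tuple[float, ...] = ()
    resolution: int = 0
    exons_used: tuple[int, ...] = ()
    flags: tuple[str, ...] = ()
    confidence: float | None = None


def _resolution(alleles: Sequence[AlleleName]) -> int:
    return min((2 * len(a.fields) for a in alleles), default=0)


def call_genotype(cs: CandidateSet, exons_used: Sequence[int] = ()) -> GenotypeCall:
    """Rank the deduplicated candidates and emit the genotype.

    Ranking: unique read count, then total placed reads, then lower score,
    then name (the last three are deterministic tie-breaks).  The reported
    confidence is the ratio of the runner-up's unique count to the top
    count — near zero for a clean homozygote, near one for a balanced
    heterozygote.
    """
    cands = list(cs.candidates)
    if not cands:
        return GenotypeCall(
            gene=cs.gene, alleles=(), zygosity="nocall", flags=("no_candidates",),
            exons_used=tuple(exons_used),
        )
    uniq = {
        id(c): count_unique_reads(c, [o for o in cands if o is not c]) for c in cands
    }
    ranked = sorted(
        cands,
        key=lambda c: (-uniq[id(c)], -len(c.read_ids), c.score, c.allele.render()),
    )
    top = ranked[0]
    flags: tuple[str, ...] = ()
    if len(ranked) >= 2 and uniq[id(top)] >= 1 and uniq[id(ranked[1])] >= 1:
        final = [top, ranked[1]]
        zygosity = "het"
    elif uniq[id(top)] >= 1:
        final = [top]
        zygosity = "hom"
    else:
        # No candidate owns a unique read: full mutual redundancy.  Call the
        # best-covered candidate homozygous but mark it.
        best = min(cands, key=lambda c: (-len(c.read_ids), c.score, c.allele.render()))
        final = [best]
        zygosity = "hom"
        flags = ("low_confidence",)
    u1 = uniq[id(ranked[0])]
    u2 = uniq[id(ranked[1])] if len(ranked) >= 2 else 0
    confidence = (u2 / u1) if u1 > 0 else None
    return GenotypeCall(
        gene=cs.gene,
        alleles=tuple(c.allele for c in final),
        zygosity=zygosity,
        unique_read_counts=tuple(uniq[id(c)] for c in final),
        total_reads=tuple(len(c.read_ids) for c in final),
        scores=tuple(c.score for c in final),
        resolution=_resolution([c.allele for c in final]),
        exons_used=tuple(exons_used),
        flags=flags,
        confidence=confidence,
    )


def _rank_with_uniques(cands: Sequence[Candidate]) -> tuple[list[Candidate], dict[int, int]]:
    uniq = {
        id(c): count_unique_reads(c, [o for o in cands if o is not c]) for c in cands
    }
    ranked = sorted(
        cands,
        key=lambda c: (-uniq[id(c)], -len(c.read_ids), c.score, c.allele.render()),
    )
    return ranked, uniq


def _members_differ_on(
    group: RepresentativeGroup | None, db: AlleleDatabase, exons: Sequence[int]
) -> bool:
    """True when group members carry non-identical sequences over ``exons``."""
    if group is None or len(group.members) < 2:
        return False
    seen = set()
    for name in group.members:
        rec = db.get(name)
        seen.add(tuple((e, rec.exons.get(e)) for e in exons))
    return len(seen) > 1


def _run_cascade(
    gene: str,
    reads: Sequence[Read],
    db: AlleleDatabase,
    exons: Sequence[int],
    params: ScoreParams,
    restrict: set[str] | None = None,
    stage_log: dict | None = None,
) -> tuple[GenotypeCall, CandidateSet, dict[int, int]]:
    source = db
    if restrict is not None:
        source = AlleleDatabase(
            records=[r for r in db.records if r.name.render() in restrict],
            gene_exon_policy=dict(db.gene_exon_policy),
        )
    groups = build_representative_groups(source, gene, exons)
    profiles = build_profiles(reads, groups)
    scored = score_profiles(profiles, params)
    kept = filter_by_score(scored, params)
    cs = CandidateSet.from_scored(gene, kept, groups)
    deduped = remove_subset_duplicates(cs)
    exons_used = sorted({e for g in groups for e in g.exons_used})
    call = call_genotype(deduped, exons_used=exons_used)
    if stage_log is not None:
        stage_log.update(
            n_records=len(source.records_for(gene)),
            n_groups=len(groups),
            n_with_reads=sum(1 for s in scored if s.n_reads > 0),
            n_passed_score=len(kept),
            n_after_dedup=len(deduped.candidates),
            n_final=len(call.alleles),
        )
    _, uniq = _rank_with_uniques(deduped.candidates)
    return call, deduped, uniq


def type_gene(
    gene: str,
    reads: Sequence[Read],
    db: AlleleDatabase,
    params: ScoreParams | None = None,
    allow_fallback: bool = True,
    stage_log: dict | None = None,
) -> GenotypeCall:
    """Full per-gene cascade: group → place → score → filter → dedup → call.

    Typing runs on the gene's primary exons first.  Fallback exons are
    engaged only when the primary call is ambiguous: either more than two
    candidates remain tied at the top unique-read count after phasing, or a
    called representative group contains members that differ over the
    fallback exons (so further exons can actually split it).  The rerun is
    restricted to the alleles still in contention and its result replaces
    the primary call unless it comes back empty.
    """
    params = params or ScoreParams()
    policy = db.policy(gene)
    primary_log: dict = {}
    call, deduped, uniq = _run_cascade(
        gene, reads, db, policy.primary, params, stage_log=primary_log
    )
    if stage_log is not None:
        stage_log["primary"] = primary_log

    if not allow_fallback or not policy.fallback or not deduped.candidates:
        return call

    ranked, _ = _rank_with_uniques(deduped.candidates)
    second_u = uniq[id(ranked[min(1, len(ranked) - 1)])]
    tied_top = [c for c in ranked if uniq[id(c)] >= second_u]

    contention: set[str] = set()
    trigger = False
    if len(tied_top) > 2:
        trigger = True
        for c in tied_top:
            members = c.group.members if c.group else (c.allele,)
            contention.update(m.render() for m in members)
    called = [c for c in deduped.candidates if c.allele in call.alleles]
    for c in called:
        if _members_differ_on(c.group, db, policy.fallback):
            trigger = True
            members = c.group.members if c.group else (c.allele,)
            contention.update(m.render() for m in members)
    if not trigger:
        return call

    for c in called:
        members = c.group.members if c.group else (c.allele,)
        contention.update(m.render() for m in members)
    exons = tuple(dict.fromkeys(tuple(policy.primary) + tuple(policy.fallback)))
    fallback_log: dict = {}
    refined, _, _ = _run_cascade(
        gene, reads, db, exons, params, restrict=contention, stage_log=fallback_log
    )
    if stage_log is not None:
        stage_log["fallback"] = fallback_log
    if refined.zygosity == "nocall":
        return call
    return refined


def calls_to_table(
    calls: Mapping[str, GenotypeCall] | Sequence[tuple[str, GenotypeCall]],
    digits: int | None = None,
) -> pd.DataFrame:
    """Tabulate calls (one row per sample × gene) for TSV export.

    ``digits`` adds truncated-resolution allele columns next to the full
    representative-level names.
    """
    items = calls.items() if isinstance(calls, Mapping) else calls
    rows = []
    for sample, call in items:
        alleles = [a.render() for a in call.alleles]
        row = {
            "sample": sample,
            "gene": call.gene,
            "allele1": alleles[0] if len(alleles) > 0 else "",
            "allele2": alleles[1] if len(alleles) > 1 else "",
            "zygosity": call.zygosity,
            "unique_reads1": call.unique_read_counts[0] if call.unique_read_counts else 0,
            "unique_reads2": call.unique_read_counts[1] if len(call.unique_read_counts) > 1 else 0,
            "score1": call.scores[0] if call.scores else float("nan"),
            "score2": call.scores[1] if len(call.scores) > 1 else float("nan"),
            "resolution": call.resolution,
            "exons_used": ",".join(map(str, call.exons_used)),
            "flags": ";".join(call.flags),
            "confidence": call.confidence if call.confidence is not None else float("nan"),
        }
        if digits is not None:
            trunc = [truncate_name(a, digits).render() for a in call.alleles]
            row[f"allele1_{digits}d"] = trunc[0] if len(trunc) > 0 else ""
            row[f"allele2_{digits}d"] = trunc[1] if len(trunc) > 1 else ""
        rows.append(row)
    return pd.DataFrame(rows)


def calls_to_json(
    calls: Mapping[str, GenotypeCall] | Sequence[tuple[str, GenotypeCall]],
    handle: IO[str] | None = None,
) -> str:
    items = calls.items() if isinstance(calls, Mapping) else calls
    payload = [
        {
            "sample": sample,
            "gene": call.gene,
            "alleles": [a.render() for a in call.alleles],
            "zygosity": call.zygosity,
            "unique_read_counts": list(call.unique_read_counts),
            "total_reads": list(call.total_reads),
            "scores": list(call.scores),
            "resolution": call.resolution,
            "exons_used": list(call.exons_used),
            "flags": list(call.flags),
            "confidence": call.confidence,
        }
        for sample, call in items
    ]
    text = json.dumps(payload, indent=2)
    if handle is not None:
        handle.write(text)
    return text
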