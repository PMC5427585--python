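"""Synthetic allele panels, diploid read sets, and pipeline evaluation.

The generator emulates the structure the genotyping cascade has to cope
with: per gene, a panel of alleles derived from one ancestral exon set by
sparse substitutions; at least one quartet of alleles with byte-identical
exons (exercising representative collapsing); and configurable
near-duplicate pairs differing at exactly one base of a typing exon
(exercising single-variant discrimination).  Diploid samples draw
error-free or error-bearing fixed-length reads uniformly over each
haplotype's exon concatenation at a configurable mean depth.

Reads are drawn independently per haplotype with no PCR duplicates, and
sequencing errors are uniform substitutions only — an exact-match placer
discards an error-bearing read whatever the error type, so indel errors
would add nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

from hlatyper.allele_db import (
    AlleleDatabase,
    AlleleName,
    AlleleRecord,
    default_policy,
    build_representative_groups,
    truncate_name,
)
from hlatyper.aligner import Read, reverse_complement
from hlatyper.calling import GenotypeCall, type_gene
from hlatyper.scoring import ScoreParams

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic panel and read sets.

    Exon lengths follow typical class I / class II exon sizes (e.g. a
    270 bp exon 2 and 276 bp exon 3 for class I).  The substitution rate
    between alleles (2%) gives roughly a dozen differences over a class I
    typing region, comparable to the divergence of unrelated allele
    groups; near-duplicate pairs sit at Hamming distance exactly one.
    Depth spans the regimes of interest (5×–150×); the default matches
    30× whole-genome sequencing.  All randomness flows from ``seed``.
    """

    genes: tuple[str, ...] = ("A", "B", "C", "DQB1", "DRB1")
    n_alleles: int = 8
    exon_lengths_class1: Mapping[int, int] = field(
        default_factory=lambda: {2: 270, 3: 276, 4: 276, 5: 117}
    )
    exon_lengths_class2: Mapping[int, int] = field(
        default_factory=lambda: {2: 270, 3: 282, 4: 255}
    )
    substitution_rate: float = 0.02
    near_duplicate_pairs: int = 1
    identical_quartets: int = 1
    read_length: int = 150
    depth: float = 30.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alleles < 1 or self.near_duplicate_pairs < 0 or self.identical_quartets < 0:
            raise ValueError("counts must be non-negative (n_alleles >= 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    for i in np.flatnonzero(mask):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _substitute_one(
    exons: dict[int, str],
    typing_exons: Sequence[int],
    read_length: int,
    rng: np.random.Generator,
) -> dict[int, str]:
    """Copy ``exons`` with exactly one base changed inside a typing exon.

    The variant lands at least half a read length away from the ends of the
    concatenated typing region (when the region allows it), so that reads
    drawn uniformly over the region can actually cover it.
    """
    lengths = [len(exons[e]) for e in typing_exons]
    total = sum(lengths)
    if total < 1:
        raise ValueError("typing exons too short to host a variant")
    margin = read_length // 2
    lo, hi = (margin, total - margin) if total > 2 * margin else (0, total)
    pos = int(rng.integers(lo, hi))
    out = dict(exons)
    for e, ln in zip(typing_exons, lengths):
        if pos < ln:
            old = out[e][pos]
            new = [b for b in "ACGT" if b != old][rng.integers(0, 3)]
            out[e] = out[e][:pos] + new + out[e][pos + 1 :]
            return out
        pos -= ln
    raise AssertionError("unreachable")


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def simulate_allele_db(cfg: SimConfig) -> tuple[AlleleDatabase, dict]:
    """Generate a synthetic allele panel plus ground-truth metadata.

    Per gene: ``n_alleles`` base variants of one random ancestor; the first
    ``identical_quartets`` base alleles are each emitted as four records
    with identical exons (names ``gg:01:01:01`` … ``gg:01:01:04``); the
    last ``near_duplicate_pairs`` base alleles each gain a partner
    (``gg:02``) at Hamming distance exactly one over the typing exons.

    With a positive substitution rate the panel is regenerated (bounded
    retries) if chance produces extra identical or distance-one pairs, so
    the constructed near-duplicates are the only ones.  Metadata lists, per
    gene, every record name, the quartets, the near-duplicate pairs, and a
    ``truth_pool`` of names eligible as simulated truth alleles.
    """
    if cfg.identical_quartets + cfg.near_duplicate_pairs > cfg.n_alleles:
        raise ValueError("n_alleles too small for requested quartets and near-duplicates")
    rng = np.random.default_rng(cfg.seed)
    records: list[AlleleRecord] = []
    meta: dict = {"genes": {}}
    for gene in cfg.genes:
        policy = default_policy(gene)
        exon_lengths = (
            cfg.exon_lengths_class1 if policy.primary == (2, 3) else cfg.exon_lengths_class2
        )
        if any(l < 1 for l in exon_lengths.values()):
            raise ValueError("exon lengths must be >= 1")
        typing_exons = [e for e in policy.primary if e in exon_lengths]
        if not typing_exons:
            raise ValueError(f"{gene}: no typing exons in exon length table")

        for _attempt in range(50):
            ancestor = {e: _random_seq(l, rng) for e, l in sorted(exon_lengths.items())}
            variants = [
                {e: _mutate(s, cfg.substitution_rate, rng) for e, s in ancestor.items()}
                for _ in range(cfg.n_alleles)
            ]
            if cfg.substitution_rate <= 0:
                break
            typing = ["".join(v[e] for e in typing_exons) for v in variants]
            ok = all(
                _hamming(typing[i], typing[j]) >= 2
                for i in range(len(typing))
                for j in range(i + 1, len(typing))
            )
            if ok:
                break
        else:
            raise ValueError(f"{gene}: could not generate a well-separated panel")

        gene_records: list[AlleleRecord] = []
        quartets: list[list[str]] = []
        near_dups: list[tuple[str, str]] = []
        truth_pool: list[str] = []
        for i, exons in enumerate(variants, start=1):
            if i <= cfg.identical_quartets:
                group = []
                for k in range(1, 5):
                    name = AlleleName(gene, (f"{i:02d}", "01", "01", f"{k:02d}"))
                    gene_records.append(AlleleRecord(name, dict(exons), source_id="sim"))
                    group.append(name.render())
                quartets.append(group)
                truth_pool.append(group[0])
            else:
                name = AlleleName(gene, (f"{i:02d}", "01"))
                gene_records.append(AlleleRecord(name, dict(exons), source_id="sim"))
                truth_pool.append(name.render())
            if i > cfg.n_alleles - cfg.near_duplicate_pairs:
                partner_exons = _substitute_one(
                    dict(exons), typing_exons, cfg.read_length, rng
                )
                partner = AlleleName(gene, (f"{i:02d}", "02"))
                gene_records.append(AlleleRecord(partner, partner_exons, source_id="sim"))
                source_name = gene_records[-2].name.render()
                near_dups.append((source_name, partner.render()))
                truth_pool.append(partner.render())

        records.extend(gene_records)
        meta["genes"][gene] = {
            "alleles": [r.name.render() for r in gene_records],
            "quartets": quartets,
            "near_duplicates": near_dups,
            "truth_pool": truth_pool,
            "typing_exons": typing_exons,
        }
    db = AlleleDatabase(
        records=records,
        gene_exon_policy={g: default_policy(g) for g in cfg.genes},
    )
    return db, meta


def simulate_diploid_reads(
    db: AlleleDatabase,
    truth: Sequence[AlleleName | str],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    exons: Sequence[int] | None = None,
) -> list[Read]:
    """Draw fixed-length reads from both haplotypes of a diploid sample.

    Reads start uniformly over each haplotype's exon concatenation
    (defaulting to the gene's primary typing exons); each haplotype
    contributes ``depth × region_length / (2 × read_length)`` reads so the
    two together realize the configured mean depth.  Orientation is a fair
    coin; substitution errors are applied per base at ``error_rate``.
    """
    if len(truth) != 2:
        raise ValueError("truth must name exactly two alleles (hom: same name twice)")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    reads: list[Read] = []
    for hap, name in enumerate(truth):
        rec = db.get(name)
        exon_set = tuple(exons) if exons is not None else db.policy(rec.name.gene).primary
        source = rec.concat(exon_set)
        if len(source) < cfg.read_length:
            raise ValueError(
                f"{rec.name.render()}: region ({len(source)} bp) shorter than one read"
            )
        n = int(round(cfg.depth * len(source) / (2 * cfg.read_length)))
        starts = rng.integers(0, len(source) - cfg.read_length + 1, n)
        flips = rng.random(n) < 0.5
        for k, (s, flip) in enumerate(zip(starts, flips)):
            seq = source[s : s + cfg.read_length]
            if cfg.error_rate > 0:
                seq = _mutate(seq, cfg.error_rate, rng)
            if flip:
                seq = reverse_complement(seq)
            reads.append(Read(id=f"{rec.name.gene}|h{hap}|{k}", sequence=seq))
    return reads


def downsample_reads(
    reads: Sequence[Read], fraction: float, rng: np.random.Generator
) -> list[Read]:
    """Keep each read independently with the given probability."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    keep = rng.random(len(reads)) < fraction
    return [r for r, k in zip(reads, keep) if k]


def random_truth_pair(
    db: AlleleDatabase,
    meta: dict,
    gene: str,
    rng: np.random.Generator,
    het: bool = True,
) -> tuple[str, str]:
    """Sample a diploid truth genotype from the panel's truth pool.

    Heterozygous pairs are drawn from alleles with *distinct* primary
    typing sequences (alleles identical over the primary exons are one
    representative and cannot be separately recovered by construction).
    """
    pool = meta["genes"][gene]["truth_pool"]
    if not het or len(pool) < 2:
        name = pool[rng.integers(0, len(pool))]
        return name, name
    exons = db.policy(gene).primary
    for _ in range(100):
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[int(i)], pool[int(j)]
        if db.get(a).concat(exons) != db.get(b).concat(exons):
            return a, b
    raise ValueError(f"{gene}: could not sample a heterozygous pair")


def representative_map(db: AlleleDatabase, gene: str) -> dict[str, str]:
    """Member allele name → representative name over the primary exons."""
    groups = build_representative_groups(db, gene, db.policy(gene).primary)
    return {
        m.render(): g.representative.render() for g in groups for m in g.members
    }


def _call_slots(call: GenotypeCall | Sequence[str]) -> list[str]:
    if isinstance(call, GenotypeCall):
        names = [a.render() for a in call.alleles]
    else:
        names = [str(a) for a in call if str(a)]
    if len(names) == 1:
        names = names * 2  # a homozygote asserts two copies
    return names


def evaluate_calls(
    calls: Mapping[tuple[str, str], GenotypeCall | Sequence[str]],
    truth: Mapping[tuple[str, str], Sequence[AlleleName | str]],
    digits: int = 4,
) -> pd.DataFrame:
    """Per-gene and overall accuracy at a digit resolution.

    Keys are ``(sample, gene)``; each genotype contributes two allele
    slots, matched as an unordered pair after truncating both sides to
    ``digits``.  A no-call leaves both slots missing; correct + missing +
    wrong always sums to 2 × genotypes.
    """
    if set(calls) != set(truth):
        raise ValueError("calls and truth must cover the same (sample, gene) keys")

    def trunc(name: AlleleName | str) -> str:
        n = name if isinstance(name, AlleleName) else AlleleName.parse(str(name))
        return truncate_name(n, digits).render()

    counts: dict[str, dict[str, int]] = {}
    for key in sorted(calls):
        _, gene = key
        t_slots = [trunc(a) for a in truth[key]]
        if len(t_slots) != 2:
            raise ValueError(f"truth for {key} must have two alleles")
        c_slots = [trunc(a) for a in _call_slots(calls[key])]
        remaining = list(t_slots)
        correct = 0
        for a in c_slots:
            if a in remaining:
                remaining.remove(a)
                correct += 1
        row = counts.setdefault(gene, {"correct": 0, "missing": 0, "wrong": 0, "n_slots": 0})
        row["correct"] += correct
        row["wrong"] += len(c_slots) - correct
        row["missing"] += 2 - len(c_slots)
        row["n_slots"] += 2

    rows = []
    overall = {"correct": 0, "missing": 0, "wrong": 0, "n_slots": 0}
    for gene in sorted(counts):
        row = counts[gene]
        for k in overall:
            overall[k] += row[k]
        rows.append({"gene": gene, **row, "accuracy": row["correct"] / row["n_slots"]})
    if overall["n_slots"]:
        rows.append(
            {"gene": "overall", **overall, "accuracy": overall["correct"] / overall["n_slots"]}
        )
    return pd.DataFrame(rows)


def _sensitivity_specificity(
    call: GenotypeCall, truth_reps: set[str], panel_reps: set[str]
) -> tuple[float, float]:
    called = {a.render() for a in call.alleles}
    tp = len(called & truth_reps)
    fp = len(called - truth_reps)
    negatives = len(panel_reps - truth_reps)
    sens = tp / len(truth_reps)
    spec = 1.0 - fp / negatives if negatives else 1.0
    return sens, spec


def depth_sweep(
    db: AlleleDatabase,
    meta: dict,
    cfg: SimConfig,
    depths: Sequence[float],
    cutoffs: Sequence[float] = (125.0,),
    n_replicates: int = 10,
    seed: int = 0,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Allele-level sensitivity/specificity of the full pipeline per cell.

    For each replicate a fresh heterozygous truth genotype is drawn per
    gene; for each depth a fresh read set is simulated from it (paired
    across depths and cutoffs through the shared replicate truth), and the
    complete cascade is run at each score cutoff.  Sensitivity is the
    fraction of true representative alleles called; specificity the
    fraction of non-true panel representatives not called.
    """
    if not depths or not cutoffs:
        raise ValueError("need at least one depth and one cutoff")
    gene_list = list(genes) if genes is not None else list(cfg.genes)
    rep_maps = {g: representative_map(db, g) for g in gene_list}
    panels = {g: set(rep_maps[g].values()) for g in gene_list}

    rows = []
    for rep_i in range(n_replicates):
        truth_rng = np.random.default_rng([seed, 1, rep_i])
        truths = {g: random_truth_pair(db, meta, g, truth_rng) for g in gene_list}
        for d_i, depth in enumerate(depths):
            for g_i, gene in enumerate(gene_list):
                read_rng = np.random.default_rng([seed, 2, rep_i, d_i, g_i])
                reads = simulate_diploid_reads(
                    db, truths[gene], replace(cfg, depth=float(depth)), rng=read_rng
                )
                truth_reps = {rep_maps[gene][a] for a in truths[gene]}
                for cutoff in cutoffs:
                    params = ScoreParams(cutoff=float(cutoff))
                    call = type_gene(gene, reads, db, params)
                    sens, spec = _sensitivity_specificity(
                        call, truth_reps, panels[gene]
                    )
                    rows.append(
                        {
                            "replicate": rep_i,
                            "gene": gene,
                            "depth": float(depth),
                            "cutoff": float(cutoff),
                            "sensitivity": sens,
                            "specificity": spec,
                        }
                    )
    detail = pd.DataFrame(rows)
    summary = (
        detail.groupby(["depth", "cutoff"], as_index=False)[["sensitivity", "specificity"]]
        .mean()
        .assign(n=n_replicates * len(gene_list))
    )
    summary.attrs["detail"] = detail
    return summary


def write_fasta(db: AlleleDatabase, handle: IO[str] | str | Path) -> None:
    """Write the panel as FASTA, one record per allele over all its exons."""

    def _write(fh: IO[str]) -> None:
        for rec in db.records:
            exon_note = ",".join(str(e) for e in sorted(rec.exons))
            fh.write(f">{rec.name.render()} exons={exon_note}\n")
            fh.write("".join(rec.exons[e] for e in sorted(rec.exons)) + "\n")

    if isinstance(handle, (str, Path)):
        with open(handle, "w") as fh:
            _write(fh)
    else:
        _write(handle)


def exon_map_table(db: AlleleDatabase) -> pd.DataFrame:
    """Exon-boundary table (1-based inclusive) matching :func:`write_fasta`."""
    rows = []
    for rec in db.records:
        pos = 1
        for e in sorted(rec.exons):
            end = pos + len(rec.exons[e]) - 1
            rows.append(
                {"allele": rec.name.render(), "exon": e, "start": pos, "end": end}
            )
            pos = end + 1
    return pd.DataFrame(rows)


def write_fastq(reads: Sequence[Read], handle: IO[str] | str | Path) -> None:
    def _write(fh: IO[str]) -> None:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")

    if isinstance(handle, (str, Path)):
        with open(handle, "w") as fh:
            _write(fh)
    else:
        _write(handle)
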