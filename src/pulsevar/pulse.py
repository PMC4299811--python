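"""Pulsed-analysis machinery.

A *pulse* is an intermediate extraction and full reanalysis of sequencing
data at a predefined SBS cycle before the run completes: reads are truncated
to the bases available at that cycle (single-end early on, paired-end once
mate 2 exists), aligned, reduced to the target regions and re-called. The
functions here cover schedule construction, read truncation, alignment data
reduction, chunked-alignment planning and cross-pulse/callset QC metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .types import AlignmentRecord, FastqRead, Variant

__all__ = [
    "PulseSpec",
    "PulseSchedule",
    "CallsetComparison",
    "CallsetMetrics",
    "ChunkPlan",
    "make_schedule",
    "make_default_schedule",
    "truncate_reads",
    "reduce_to_regions",
    "plan_chunks",
    "callset_concordance",
    "callset_metrics",
    "pass_calls",
]

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


@dataclass(frozen=True)
class PulseSpec:
    cycle: int  # SBS cycles sequenced so far = available read length
    mode: str  # SE | PE

    def __post_init__(self) -> None:
        if self.cycle <= 0:
            raise ValueError(f"cycle must be positive, got {self.cycle}")
        if self.mode not in ("SE", "PE"):
            raise ValueError(f"mode must be SE or PE, got {self.mode!r}")

    @property
    def name(self) -> str:
        return f"{self.mode}{self.cycle}"


class PulseSchedule:
    """Ordered pulse checkpoints; the last pulse is the max-cycle PE spec."""

    def __init__(self, pulses: Sequence[PulseSpec]):
        if not pulses:
            raise ValueError("schedule must contain at least one pulse")
        for mode in ("SE", "PE"):
            cycles = [p.cycle for p in pulses if p.mode == mode]
            if any(b < a for a, b in zip(cycles, cycles[1:])):
                raise ValueError(f"{mode} cycles must be non-decreasing")
        final = pulses[-1]
        max_cycle = max(p.cycle for p in pulses)
        if final.mode != "PE" or final.cycle != max_cycle:
            raise ValueError(
                "final pulse must be the maximum-cycle PE spec, got "
                f"{final.name}"
            )
        self._pulses = list(pulses)

    def __iter__(self):
        return iter(self._pulses)

    def __len__(self) -> int:
        return len(self._pulses)

    def __getitem__(self, i: int) -> PulseSpec:
        return self._pulses[i]

    @property
    def final(self) -> PulseSpec:
        return self._pulses[-1]

    @property
    def names(self) -> list[str]:
        return [p.name for p in self._pulses]


def make_schedule(cycles: Iterable[int], pe_from: int) -> PulseSchedule:
    """SE pulses at every cycle, PE pulses at cycles >= ``pe_from``."""
    cycle_list = sorted(set(cycles))
    if not cycle_list:
        raise ValueError("cycle list must be non-empty")
    if cycle_list[0] <= 0:
        raise ValueError("cycles must be positive")
    pulses = [PulseSpec(c, "SE") for c in cycle_list]
    pulses += [PulseSpec(c, "PE") for c in cycle_list if c >= pe_from]
    if pulses[-1].mode != "PE":
        raise ValueError(
            f"no cycle reaches pe_from={pe_from}; a final PE pulse is required"
        )
    return PulseSchedule(pulses)


def make_default_schedule() -> PulseSchedule:
    """SE at 35/50/75/100 cycles, PE from 50 cycles onward."""
    return make_schedule([35, 50, 75, 100], pe_from=50)


def truncate_reads(reads: Iterable[FastqRead], cycle: int,
                   mode: str = "PE") -> list[FastqRead]:
    """Cut each read to the first ``cycle`` bases; SE mode drops mate 2."""
    if cycle <= 0:
        raise ValueError(f"cycle must be positive, got {cycle}")
    if mode not in ("SE", "PE"):
        raise ValueError(f"mode must be SE or PE, got {mode!r}")
    out = []
    for r in reads:
        if mode == "SE" and r.mate == 2:
            continue
        out.append(
            FastqRead(r.id, r.sequence[:cycle], r.quality[:cycle], mate=r.mate)
        )
    return out


def reduce_to_regions(
    alignments: Iterable[AlignmentRecord],
    regions: Mapping[str, Sequence[tuple[int, int]]],
) -> list[AlignmentRecord]:
    """Keep alignments overlapping any region by >= 1 bp; order preserved."""
    trees: dict[str, IntervalTree] = {}
    for contig, ivs in regions.items():
        tree = IntervalTree()
        for s, e in ivs:
            if e > s:
                tree.addi(s, e)
        trees[contig] = tree
    kept = []
    for a in alignments:
        tree = trees.get(a.contig)
        if tree is not None and tree.overlaps(a.start, a.end):
            kept.append(a)
    return kept


@dataclass
class ChunkPlan:
    """Partition of the read index space into alignment chunks."""

    chunk_size: int
    ranges: list[tuple[int, int]]
    max_chunks: int | None = None

    @property
    def n_chunks(self) -> int:
        return len(self.ranges)


def plan_chunks(n_reads: int, chunk_size: int,
                max_chunks: int | None = None) -> ChunkPlan:
    """ceil(n/chunk_size) chunks, merged evenly when a cap applies.

    Under a cap the raw chunks are distributed over ``max_chunks`` groups
    whose sizes differ by at most one chunk granule, so node load stays
    balanced while the number of nodes scales with the data volume only up
    to the cap.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if max_chunks is not None and max_chunks < 1:
        raise ValueError("max_chunks must be >= 1")
    n_raw = math.ceil(n_reads / chunk_size)
    if n_raw == 0:
        return ChunkPlan(chunk_size, [], max_chunks)
    k = n_raw if max_chunks is None else min(n_raw, max_chunks)
    boundaries = [i * n_raw // k for i in range(k + 1)]
    ranges = []
    for b0, b1 in zip(boundaries, boundaries[1:]):
        start = b0 * chunk_size
        end = min(b1 * chunk_size, n_reads)
        ranges.append((start, end))
    return ChunkPlan(chunk_size, ranges, max_chunks)


@dataclass
class CallsetComparison:
    """Reproduction of an early-pulse callset in a later callset."""

    n_early: int
    n_reproduced: int
    rate: float | None
    n_genotype_concordant: int = 0
    genotype_rate: float | None = None


def pass_calls(calls: Iterable[Variant]) -> list[Variant]:
    return [v for v in calls if v.filter == "PASS"]


def _genotypes_agree(a: Variant, b: Variant) -> bool:
    shared = set(a.genotypes) & set(b.genotypes)
    if not shared:
        return False
    for s in shared:
        ga, gb = a.genotypes[s], b.genotypes[s]
        if sorted(x for x in ga.alleles if x is not None) != sorted(
            x for x in gb.alleles if x is not None
        ):
            return False
    return True


def callset_concordance(early_calls: Sequence[Variant],
                        final_calls: Sequence[Variant]) -> CallsetComparison:
    """Fraction of early calls matched (contig, pos, ref, alt) in the final
    callset. Genotype agreement is reported separately and does not affect
    the match."""
    final_by_key = {v.key: v for v in final_calls}
    n_early = len(early_calls)
    n_reproduced = 0
    n_gt = 0
    for v in early_calls:
        hit = final_by_key.get(v.key)
        if hit is not None:
            n_reproduced += 1
            if _genotypes_agree(v, hit):
                n_gt += 1
    return CallsetComparison(
        n_early=n_early,
        n_reproduced=n_reproduced,
        rate=None if n_early == 0 else n_reproduced / n_early,
        n_genotype_concordant=n_gt,
        genotype_rate=None if n_reproduced == 0 else n_gt / n_reproduced,
    )


@dataclass
class CallsetMetrics:
    ts: int
    tv: int
    tstv: float | None
    het: int
    hom: int
    het_hom: float | None
    known_rate: float | None = None


def callset_metrics(calls: Sequence[Variant],
                    known_sites: Iterable[Variant | tuple] | None = None,
                    sample_id: str | None = None) -> CallsetMetrics:
    """Ts/Tv and het:hom ratios plus known-sites concordance.

    Ts/Tv and the known-sites rate are computed over SNVs (indels excluded);
    het/hom counts cover the designated sample's non-reference calls
    (default: the first sample seen).
    """
    snvs = [v for v in calls if v.is_snv]
    ts = sum(1 for v in snvs if (v.ref, v.alt) in TRANSITIONS)
    tv = len(snvs) - ts
    if sample_id is None:
        for v in calls:
            if v.genotypes:
                sample_id = next(iter(v.genotypes))
                break
    het = hom = 0
    for v in calls:
        gt = v.genotypes.get(sample_id) if sample_id else None
        if gt is None or not gt.known or not gt.has_alt:
            continue
        if gt.is_het:
            het += 1
        else:
            hom += 1
    known_rate = None
    if known_sites is not None:
        keys = {
            k.key if isinstance(k, Variant) else tuple(k) for k in known_sites
        }
        if snvs:
            known_rate = sum(1 for v in snvs if v.key in keys) / len(snvs)
    return CallsetMetrics(
        ts=ts,
        tv=tv,
        tstv=None if tv == 0 else ts / tv,
        het=het,
        hom=hom,
        # a callset with no hets (or no homs) has no meaningful ratio
        het_hom=None if hom == 0 or het == 0 else het / hom,
        known_rate=known_rate,
    )
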