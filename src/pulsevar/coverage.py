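"""Coverage analytics over transcript models.

Assessment regions are exon unions with each *internal* exon boundary
extended a few bases into the intron so the splice dinucleotides (the
GT/AG pairs flanking internal junctions) are assessed together with the
coding bases. Completeness is the fraction of assessed bases at or above a
depth cutoff (width = completeness at 1×); a transcript counts toward the
diagnostic yield only when every one of its assessed bases reaches the
cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .types import DepthProfile, GenePanel, PanelGene, TranscriptModel

__all__ = [
    "CoverageConfig",
    "CoverageReport",
    "DiagnosticYield",
    "build_assessment_regions",
    "completeness",
    "width",
    "diagnostic_yield",
    "coverage_report",
    "gene_completeness",
    "merge_intervals",
]


@dataclass(frozen=True)
class CoverageConfig:
    """cutoff: minimum read depth (default 10×); splice_flank: bases of
    intron assessed at each internal exon boundary (default 2, the splice
    dinucleotides)."""

    cutoff: int = 10
    splice_flank: int = 2

    def __post_init__(self) -> None:
        if self.cutoff < 1:
            raise ValueError("cutoff must be >= 1")
        if self.splice_flank < 0:
            raise ValueError("splice_flank must be >= 0")


def merge_intervals(intervals: Iterable[tuple[int, int]]
                    ) -> list[tuple[int, int]]:
    """Union of half-open intervals (adjacent intervals are joined)."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if e <= s:
            continue
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def build_assessment_regions(transcript: TranscriptModel,
                             config: CoverageConfig | None = None
                             ) -> list[tuple[int, int]]:
    """Exon union with internal boundaries extended ``splice_flank`` bp.

    The transcript's outer ends are never extended; extensions that meet
    across a short intron merge into one interval.
    """
    config = config or CoverageConfig()
    flank = config.splice_flank
    n = len(transcript.exons)
    extended = []
    for i, (s, e) in enumerate(transcript.exons):
        if i > 0:
            s -= flank
        if i < n - 1:
            e += flank
        extended.append((s, e))
    return merge_intervals(extended)


def _regions_by_contig(regions: Iterable[tuple[str, int, int]]
                       ) -> dict[str, list[tuple[int, int]]]:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, s, e in regions:
        by_contig.setdefault(contig, []).append((s, e))
    return {c: merge_intervals(ivs) for c, ivs in by_contig.items()}


def completeness(depth_profile: DepthProfile,
                 regions: Iterable[tuple[str, int, int]],
                 cutoff: int) -> float:
    """Fraction of region bases with depth >= cutoff.

    ``regions`` are (contig, start, end) half-open intervals; overlapping
    regions are unioned before counting so no base is counted twice.
    """
    merged = _regions_by_contig(regions)
    total = sum(e - s for ivs in merged.values() for s, e in ivs)
    if total == 0:
        raise ValueError("empty region set: completeness is undefined")
    covered = sum(
        depth_profile.bases_at_or_above(contig, s, e, cutoff)
        for contig, ivs in merged.items()
        for s, e in ivs
    )
    return covered / total


def width(depth_profile: DepthProfile,
          regions: Iterable[tuple[str, int, int]]) -> float:
    """Fraction of region bases with any coverage (completeness at 1×)."""
    return completeness(depth_profile, regions, cutoff=1)


def _transcript_regions(transcript: TranscriptModel,
                        config: CoverageConfig) -> list[tuple[str, int, int]]:
    if transcript.contig is None:
        raise ValueError(
            f"transcript {transcript.transcript_id} has no contig assigned"
        )
    return [
        (transcript.contig, s, e)
        for s, e in build_assessment_regions(transcript, config)
    ]


@dataclass
class DiagnosticYield:
    count: int
    fraction: float
    fully_covered: dict[str, bool]  # transcript_id -> flag


def diagnostic_yield(depth_profile: DepthProfile,
                     transcripts: Sequence[TranscriptModel],
                     config: CoverageConfig | None = None) -> DiagnosticYield:
    """Transcripts whose every assessed base reaches the depth cutoff."""
    if not transcripts:
        raise ValueError("diagnostic yield needs at least one transcript")
    config = config or CoverageConfig()
    flags: dict[str, bool] = {}
    for t in transcripts:
        regions = _transcript_regions(t, config)
        total = sum(e - s for _, s, e in regions)
        covered = sum(
            depth_profile.bases_at_or_above(c, s, e, config.cutoff)
            for c, s, e in regions
        )
        flags[t.transcript_id] = covered == total
    count = sum(flags.values())
    return DiagnosticYield(
        count=count, fraction=count / len(transcripts), fully_covered=flags
    )


def gene_completeness(depth_profile: DepthProfile, gene: PanelGene,
                      config: CoverageConfig | None = None) -> float:
    """Completeness over the union of a gene's transcript assessment
    regions (shared bases counted once)."""
    config = config or CoverageConfig()
    regions: list[tuple[str, int, int]] = []
    for t in gene.transcripts:
        if t.contig is None:
            t.contig = gene.contig
        regions.extend(_transcript_regions(t, config))
    return completeness(depth_profile, regions, config.cutoff)


@dataclass
class CoverageReport:
    """Per-region and aggregate coverage metrics plus diagnostic yield."""

    config: CoverageConfig
    per_region: list[dict] = field(default_factory=list)
    aggregate_completeness: float = 0.0
    aggregate_width: float = 0.0
    aggregate_mean_depth: float = 0.0
    yield_count: int = 0
    yield_fraction: float = 0.0
    fully_covered: dict[str, bool] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        return list(self.per_region)


def coverage_report(depth_profile: DepthProfile,
                    transcripts: Sequence[TranscriptModel],
                    config: CoverageConfig | None = None) -> CoverageReport:
    """Full coverage report for a set of transcripts."""
    config = config or CoverageConfig()
    if not transcripts:
        raise ValueError("coverage report needs at least one transcript")
    per_region = []
    all_regions: list[tuple[str, int, int]] = []
    for t in transcripts:
        regions = _transcript_regions(t, config)
        all_regions.extend(regions)
        total = sum(e - s for _, s, e in regions)
        at_cutoff = sum(
            depth_profile.bases_at_or_above(c, s, e, config.cutoff)
            for c, s, e in regions
        )
        at_one = sum(
            depth_profile.bases_at_or_above(c, s, e, 1) for c, s, e in regions
        )
        depth_sum = sum(
            depth_profile.total_depth(c, s, e) for c, s, e in regions
        )
        per_region.append(
            {
                "transcript_id": t.transcript_id,
                "gene": t.gene,
                "contig": t.contig,
                "bases": total,
                "completeness": at_cutoff / total,
                "width": at_one / total,
                "mean_depth": depth_sum / total,
            }
        )
    dy = diagnostic_yield(depth_profile, transcripts, config)
    merged = _regions_by_contig(all_regions)
    total = sum(e - s for ivs in merged.values() for s, e in ivs)
    covered = sum(
        depth_profile.bases_at_or_above(c, s, e, config.cutoff)
        for c, ivs in merged.items() for s, e in ivs
    )
    any_cov = sum(
        depth_profile.bases_at_or_above(c, s, e, 1)
        for c, ivs in merged.items() for s, e in ivs
    )
    depth_sum = sum(
        depth_profile.total_depth(c, s, e)
        for c, ivs in merged.items() for s, e in ivs
    )
    return CoverageReport(
        config=config,
        per_region=per_region,
        aggregate_completeness=covered / total,
        aggregate_width=any_cov / total,
        aggregate_mean_depth=depth_sum / total,
        yield_count=dy.count,
        yield_fraction=dy.fraction,
        fully_covered=dy.fully_covered,
    )
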