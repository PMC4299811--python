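"""Domain types shared by every pulsevar module.

Coordinate conventions: VCF positions are 1-based inclusive on the ``Variant``
type (mirroring the file format); every internal interval — exons, depth runs,
assessment regions, alignments — is 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "ALL_MODELS",
    "AlignmentRecord",
    "CompoundPair",
    "DepthProfile",
    "FastqRead",
    "GenePanel",
    "Genotype",
    "Individual",
    "PanelGene",
    "Pedigree",
    "PedigreeError",
    "TranscriptModel",
    "Variant",
    "X_CONTIGS",
    "is_x_contig",
]

_ALLELE_RE = re.compile(r"^[ACGT]+$")

#: Recognised Mendelian inheritance-model labels. The ``_dn`` suffix marks a
#: de novo event (allele absent from every genotyped parent).
ALL_MODELS = frozenset(
    {"AD", "AD_dn", "AR_hom", "AR_hom_dn", "AR_comp", "AR_comp_dn",
     "XR", "XR_dn", "XD", "XD_dn"}
)

X_CONTIGS = frozenset({"X", "chrX", "x", "chrx", "23"})


def is_x_contig(contig: str) -> bool:
    return contig in X_CONTIGS


class PedigreeError(ValueError):
    """Raised when a pedigree violates structural or sex-consistency rules."""


@dataclass
class Genotype:
    """One sample's call at one site.

    ``alleles`` holds allele indices relative to the (decomposed) variant:
    0 = reference, 1 = the variant's ALT. A single-element tuple denotes a
    hemizygous call; ``None`` entries denote unknown alleles.
    """

    sample_id: str
    alleles: tuple[int | None, ...]
    depth: int | None = None
    alt_depth: int | None = None
    phased: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError(f"genotype must carry 1 or 2 alleles, got {self.alleles}")
        for a in self.alleles:
            if a is not None and a < 0:
                raise ValueError(f"negative allele index in {self.alleles}")
        if self.depth is not None and self.alt_depth is not None:
            if not 0 <= self.alt_depth <= self.depth:
                raise ValueError(
                    f"alt_depth {self.alt_depth} outside [0, depth={self.depth}]"
                )

    @property
    def known(self) -> bool:
        return all(a is not None for a in self.alleles)

    @property
    def hemizygous(self) -> bool:
        return len(self.alleles) == 1

    @property
    def n_alt(self) -> int:
        """Number of non-reference alleles (unknown alleles count as 0)."""
        return sum(1 for a in self.alleles if a is not None and a > 0)

    @property
    def has_alt(self) -> bool:
        return self.n_alt >= 1

    @property
    def is_het(self) -> bool:
        if not self.known or self.hemizygous:
            return False
        return self.alleles[0] != self.alleles[1]

    @property
    def is_hom_alt(self) -> bool:
        if not self.known:
            return False
        return all(a is not None and a > 0 for a in self.alleles) and not self.is_het

    @property
    def is_hom_ref(self) -> bool:
        return self.known and all(a == 0 for a in self.alleles)


@dataclass
class Variant:
    """One allele change (always biallelic after decomposition)."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float | None = None
    filter: str = "PASS"
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    annotations: dict[str, object] = field(default_factory=dict)
    rank_score: int | None = None
    models: set[str] | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.contig}:{self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not _ALLELE_RE.match(allele):
                raise ValueError(
                    f"{name} allele {allele!r} at {self.contig}:{self.pos} "
                    "is not a non-empty A/C/G/T string"
                )
        maf = self.annotations.get("MAF")
        if maf is not None and not 0.0 <= float(maf) <= 1.0:
            raise ValueError(f"MAF {maf} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def sort_key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open span of the reference allele."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))

    def genotype(self, sample_id: str) -> Genotype | None:
        return self.genotypes.get(sample_id)


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"  # male | female | unknown
    affected: str = "unknown"  # yes | no | unknown

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"bad sex {self.sex!r} for {self.id}")
        if self.affected not in ("yes", "no", "unknown"):
            raise ValueError(f"bad affection {self.affected!r} for {self.id}")


class Pedigree:
    """A family: individuals with parent links, sex and affection status."""

    def __init__(self, individuals: Iterable[Individual], family_id: str = "FAM"):
        self.family_id = family_id
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._members:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._members[ind.id] = ind
        self._validate()

    def _validate(self) -> None:
        for ind in self:
            for role, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
                if pid is None:
                    continue
                parent = self._members.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.id!r} not in pedigree"
                    )
                want = "male" if role == "father" else "female"
                if parent.sex != "unknown" and parent.sex != want:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.id!r} has sex {parent.sex!r}"
                    )
        # no individual may be its own ancestor
        for ind in self:
            seen: set[str] = set()
            stack = [p for p in (ind.father_id, ind.mother_id) if p]
            while stack:
                pid = stack.pop()
                if pid == ind.id:
                    raise PedigreeError(f"{ind.id!r} is its own ancestor")
                if pid in seen:
                    continue
                seen.add(pid)
                parent = self._members[pid]
                stack.extend(p for p in (parent.father_id, parent.mother_id) if p)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._members

    def __getitem__(self, ind_id: str) -> Individual:
        return self._members[ind_id]

    @property
    def member_ids(self) -> list[str]:
        return list(self._members)

    @property
    def affected(self) -> list[Individual]:
        return [i for i in self if i.affected == "yes"]

    @property
    def unaffected(self) -> list[Individual]:
        return [i for i in self if i.affected == "no"]

    @property
    def founders(self) -> list[Individual]:
        return [i for i in self if i.father_id is None and i.mother_id is None]

    def parents_of(self, ind_id: str) -> list[Individual]:
        ind = self[ind_id]
        return [self[p] for p in (ind.father_id, ind.mother_id) if p is not None]

    def parent_child_pairs(self) -> list[tuple[Individual, Individual]]:
        """(parent, child) for every resolvable parent link."""
        out = []
        for child in self:
            for pid in (child.father_id, child.mother_id):
                if pid is not None:
                    out.append((self[pid], child))
        return out


@dataclass
class TranscriptModel:
    """Exon structure of one transcript; exons are 0-based half-open."""

    transcript_id: str
    gene: str
    strand: str
    exons: list[tuple[int, int]]
    contig: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise ValueError(
                    f"empty/inverted exon [{s},{e}) in {self.transcript_id}"
                )
            if s < prev_end:
                raise ValueError(
                    f"exons of {self.transcript_id} unsorted or overlapping"
                )
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class PanelGene:
    hgnc_symbol: str
    contig: str
    inheritance_modes: set[str] = field(default_factory=set)
    reduced_penetrance: bool = False
    disease_terms: list[str] = field(default_factory=list)
    transcripts: list[TranscriptModel] = field(default_factory=list)

    VALID_MODES = frozenset({"AR", "AD", "XL"})

    def __post_init__(self) -> None:
        bad = set(self.inheritance_modes) - self.VALID_MODES
        if bad:
            raise ValueError(
                f"unknown inheritance mode(s) {sorted(bad)} for {self.hgnc_symbol}"
            )

    @property
    def span(self) -> tuple[int, int] | None:
        if not self.transcripts:
            return None
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )


class GenePanel:
    """A versioned clinical gene panel, keyed by unique HGNC symbol."""

    def __init__(self, genes: Iterable[PanelGene], name: str = "panel",
                 version: str = "1.0"):
        self.name = name
        self.version = version
        self._genes: dict[str, PanelGene] = {}
        for g in genes:
            if g.hgnc_symbol in self._genes:
                raise ValueError(f"duplicate panel symbol {g.hgnc_symbol!r}")
            self._genes[g.hgnc_symbol] = g

    def __iter__(self) -> Iterator[PanelGene]:
        return iter(self._genes.values())

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._genes

    def __getitem__(self, symbol: str) -> PanelGene:
        return self._genes[symbol]

    def get(self, symbol: str) -> PanelGene | None:
        return self._genes.get(symbol)

    @property
    def symbols(self) -> list[str]:
        return list(self._genes)

    def transcripts(self) -> list[TranscriptModel]:
        return [t for g in self for t in g.transcripts]


@dataclass(frozen=True)
class CompoundPair:
    """Two heterozygous variants in one gene, candidate trans configuration."""

    v1: Variant
    v2: Variant
    origins: tuple[str, str] = ("unknown", "unknown")  # per member
    de_novo: bool = False

    def __post_init__(self) -> None:
        if self.v1.key == self.v2.key:
            raise ValueError("compound pair members must be distinct")
        for o in self.origins:
            if o not in ("maternal", "paternal", "unknown"):
                raise ValueError(f"bad origin {o!r}")

    @property
    def keys(self) -> frozenset:
        return frozenset((self.v1.key, self.v2.key))


class DepthProfile:
    """Per-base read depth as sorted, non-overlapping constant-depth runs.

    Positions not covered by any run have depth 0. Backed by numpy arrays so
    interval queries are vectorised.
    """

    def __init__(self, runs: Mapping[str, Sequence[tuple[int, int, int]]]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._depths: dict[str, np.ndarray] = {}
        for contig, contig_runs in runs.items():
            merged = self._normalise(contig, contig_runs)
            if merged:
                s, e, d = zip(*merged)
                self._starts[contig] = np.asarray(s, dtype=np.int64)
                self._ends[contig] = np.asarray(e, dtype=np.int64)
                self._depths[contig] = np.asarray(d, dtype=np.int64)

    @staticmethod
    def _normalise(contig: str, runs: Sequence[tuple[int, int, int]]
                   ) -> list[tuple[int, int, int]]:
        clean = []
        for s, e, d in sorted(runs):
            if d < 0:
                raise ValueError(f"negative depth {d} on {contig}")
            if e <= s:
                raise ValueError(f"empty depth run [{s},{e}) on {contig}")
            if d == 0:
                continue  # implicit-zero convention
            if clean and s < clean[-1][1]:
                if d != clean[-1][2]:
                    raise ValueError(
                        f"overlapping runs with conflicting depth on {contig} "
                        f"near position {s}"
                    )
                s = clean[-1][1]
                if e <= s:
                    continue
            if clean and s == clean[-1][1] and d == clean[-1][2]:
                clean[-1] = (clean[-1][0], e, d)
            else:
                clean.append((s, e, d))
        return clean

    @classmethod
    def from_alignments(cls, alignments: Iterable["AlignmentRecord"],
                        contig_lengths: Mapping[str, int] | None = None
                        ) -> "DepthProfile":
        """Pile up aligned spans into a depth profile."""
        arrays: dict[str, np.ndarray] = {}
        lengths = dict(contig_lengths or {})
        spans: dict[str, list[tuple[int, int]]] = {}
        for rec in alignments:
            spans.setdefault(rec.contig, []).append((rec.start, rec.start + rec.span))
        runs: dict[str, list[tuple[int, int, int]]] = {}
        for contig, ivs in spans.items():
            n = lengths.get(contig, max(e for _, e in ivs))
            diff = np.zeros(n + 1, dtype=np.int64)
            for s, e in ivs:
                diff[s] += 1
                diff[min(e, n)] -= 1
            depth = np.cumsum(diff[:-1])
            runs[contig] = cls._runs_from_array(depth)
        return cls(runs)

    @staticmethod
    def _runs_from_array(depth: np.ndarray) -> list[tuple[int, int, int]]:
        if depth.size == 0:
            return []
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [depth.size]))
        return [
            (int(s), int(e), int(depth[s]))
            for s, e in zip(starts, ends)
            if depth[s] > 0
        ]

    @property
    def contigs(self) -> list[str]:
        return list(self._starts)

    def runs(self, contig: str) -> list[tuple[int, int, int]]:
        if contig not in self._starts:
            return []
        return [
            (int(s), int(e), int(d))
            for s, e, d in zip(
                self._starts[contig], self._ends[contig], self._depths[contig]
            )
        ]

    def depth_at(self, contig: str, pos: int) -> int:
        """Depth at a single 0-based position."""
        starts = self._starts.get(contig)
        if starts is None:
            return 0
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < self._ends[contig][i]:
            return int(self._depths[contig][i])
        return 0

    def _overlaps(self, contig: str, start: int, end: int):
        starts = self._starts.get(contig)
        if starts is None or end <= start:
            return None
        ends = self._ends[contig]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return None
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return s, e, self._depths[contig][lo:hi]

    def bases_at_or_above(self, contig: str, start: int, end: int,
                          cutoff: int) -> int:
        """Number of bases in [start, end) with depth >= cutoff."""
        if cutoff <= 0:
            return max(0, end - start)
        ov = self._overlaps(contig, start, end)
        if ov is None:
            return 0
        s, e, d = ov
        keep = d >= cutoff
        return int(np.sum((e - s)[keep]))

    def total_depth(self, contig: str, start: int, end: int) -> int:
        """Sum of per-base depths over [start, end)."""
        ov = self._overlaps(contig, start, end)
        if ov is None:
            return 0
        s, e, d = ov
        return int(np.sum((e - s) * d))

    def mean_depth(self, contig: str, start: int, end: int) -> float:
        if end <= start:
            raise ValueError("empty interval")
        return self.total_depth(contig, start, end) / (end - start)


@dataclass
class FastqRead:
    id: str
    sequence: str
    quality: str
    mate: int = 1  # 1 | 2

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise ValueError(
                f"quality length {len(self.quality)} != sequence length "
                f"{len(self.sequence)} for read {self.id}"
            )
        if self.mate not in (1, 2):
            raise ValueError(f"mate must be 1 or 2, got {self.mate}")


@dataclass
class AlignmentRecord:
    read_id: str
    contig: str
    start: int  # 0-based
    span: int  # aligned bases on the reference
    strand: str = "+"
    mate: int = 1

    def __post_init__(self) -> None:
        if self.span < 1:
            raise ValueError(f"aligned span must be >= 1, got {self.span}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def end(self) -> int:
        return self.start + self.span

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)
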