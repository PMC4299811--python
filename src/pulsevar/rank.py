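"""Weighted-sum rank scoring of variants against a clinical gene panel.

The score is an integer sum of five category scores — consequence class,
minor allele frequency, inheritance-model compatibility, protein-prediction
verdicts and conservation — with most weight on inheritance pattern and
allele frequency. All weights live in :class:`RankConfig` and can be
overridden from a flat YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from . import io as pv_io
from .inheritance import OFF_PANEL, annotate_variants
from .types import GenePanel, Pedigree, Variant

__all__ = [
    "RankConfig",
    "ScoredVariant",
    "ClinicalCandidateList",
    "score_variant",
    "rank_candidates",
]

#: Prediction verdicts counted as damaging evidence.
DAMAGING_VERDICTS = frozenset(
    {"damaging", "deleterious", "probably_damaging", "possibly_damaging"}
)

CATEGORIES = ("consequence", "frequency", "inheritance", "predictions",
              "conservation")


def _default_consequence_scores() -> dict[str, int]:
    return {
        "stop_gain": 5,
        "frameshift": 5,
        "splice_acceptor": 5,
        "splice_donor": 5,
        "missense": 3,
        "inframe": 3,
        "synonymous": 0,
        "intronic": -2,
        "intergenic": -2,
        "unknown": -2,
    }


@dataclass
class RankConfig:
    """Category weights for the rank score.

    ``maf_bins`` is an ordered list of ``(upper_threshold, score)``; a
    variant scores the first bin whose threshold exceeds its MAF, else
    ``maf_above_score``. A missing frequency scores ``maf_missing_score``
    (never-observed alleles are treated as rare).
    """

    consequence_scores: dict[str, int] = field(
        default_factory=_default_consequence_scores
    )
    default_consequence_score: int = -2
    maf_bins: list[tuple[float, int]] = field(
        default_factory=lambda: [(0.005, 3), (0.02, 1)]
    )
    maf_above_score: int = -12
    maf_missing_score: int = 3
    model_score: int = 3
    no_model_penalty: int = -12
    prediction_score: int = 1
    prediction_cap: int = 2
    conservation_score: int = 1

    def __post_init__(self) -> None:
        thresholds = [t for t, _ in self.maf_bins]
        if any(not 0.0 <= t <= 1.0 for t in thresholds):
            raise ValueError("maf_bins thresholds must lie in [0, 1]")
        if any(b >= a for b, a in zip(thresholds, thresholds[1:])):
            raise ValueError("maf_bins thresholds must be strictly increasing")
        if self.prediction_cap < 0:
            raise ValueError("prediction_cap must be >= 0")

    @classmethod
    def from_yaml(cls, source) -> "RankConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            with open(source, "r", encoding="utf-8") as fh:
                data = yaml.safe_load(fh)
        data = data or {}
        if "maf_bins" in data:
            data["maf_bins"] = [(float(t), int(s)) for t, s in data["maf_bins"]]
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            "consequence_scores": dict(self.consequence_scores),
            "default_consequence_score": self.default_consequence_score,
            "maf_bins": [[t, s] for t, s in self.maf_bins],
            "maf_above_score": self.maf_above_score,
            "maf_missing_score": self.maf_missing_score,
            "model_score": self.model_score,
            "no_model_penalty": self.no_model_penalty,
            "prediction_score": self.prediction_score,
            "prediction_cap": self.prediction_cap,
            "conservation_score": self.conservation_score,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _consequence_score(variant: Variant, config: RankConfig) -> int:
    term = str(variant.annotations.get("Consequence", "unknown")).lower()
    return config.consequence_scores.get(term, config.default_consequence_score)


def _frequency_score(variant: Variant, config: RankConfig) -> int:
    maf = variant.annotations.get("MAF")
    if maf is None:
        return config.maf_missing_score
    maf = float(maf)
    for threshold, score in config.maf_bins:
        if maf < threshold:
            return score
    return config.maf_above_score


def _prediction_score(variant: Variant, config: RankConfig) -> int:
    raw = variant.annotations.get("Predictions")
    if raw is None:
        return 0
    verdicts = [
        t.strip().lower()
        for t in str(raw).replace("|", ",").split(",")
        if t.strip()
    ]
    n_damaging = sum(1 for t in verdicts if t in DAMAGING_VERDICTS)
    return min(n_damaging, config.prediction_cap) * config.prediction_score


def score_variant(variant: Variant, model_set: Iterable[str] | None,
                  config: RankConfig | None = None
                  ) -> tuple[int, dict[str, int]]:
    """Score one variant; returns (total, per-category breakdown)."""
    config = config or RankConfig()
    breakdown = {
        "consequence": _consequence_score(variant, config),
        "frequency": _frequency_score(variant, config),
        "inheritance": (
            config.model_score if model_set else config.no_model_penalty
        ),
        "predictions": _prediction_score(variant, config),
        "conservation": (
            config.conservation_score
            if variant.annotations.get("Conserved") else 0
        ),
    }
    return sum(breakdown.values()), breakdown


@dataclass
class ScoredVariant:
    variant: Variant
    score: int
    breakdown: dict[str, int]
    rank: int | None = None


@dataclass
class ClinicalCandidateList:
    """Rank-ordered on-panel candidates plus the off-panel reservoir.

    Nothing is ever deleted: every input variant is either a ranked entry or
    sits in the reservoir.
    """

    panel_name: str
    panel_version: str
    entries: list[ScoredVariant]
    reservoir: list[Variant]

    @property
    def variants(self) -> list[Variant]:
        return [e.variant for e in self.entries]

    def top(self, n: int = 10) -> list[ScoredVariant]:
        return self.entries[:n]

    def write(self, vcf_path, tsv_path) -> None:
        breakdowns = {e.variant.key: e.breakdown for e in self.entries}
        pv_io.write_ranked_output(self.variants, vcf_path, tsv_path,
                                  breakdowns=breakdowns)


def rank_candidates(variants: Sequence[Variant], panel: GenePanel,
                    pedigree: Pedigree, config: RankConfig | None = None
                    ) -> ClinicalCandidateList:
    """Annotate inheritance models, score and rank the on-panel variants.

    Off-panel variants are retained unranked in the reservoir. Output order
    is score descending, ties broken by (contig, pos, alt, ref), so the
    result is invariant under input permutation.
    """
    if len(panel) == 0:
        raise ValueError(
            "empty gene panel: the clinical candidate list is undefined"
        )
    config = config or RankConfig()
    grouped = annotate_variants(list(variants), pedigree, panel)
    on_panel_ids = {
        id(v)
        for symbol, vs in grouped.items() if symbol != OFF_PANEL
        for v in vs
    }
    scored: list[ScoredVariant] = []
    reservoir: list[Variant] = []
    for v in variants:
        if id(v) in on_panel_ids:
            total, breakdown = score_variant(v, v.models, config)
            v.rank_score = total
            scored.append(ScoredVariant(v, total, breakdown))
        else:
            reservoir.append(v)
    scored.sort(key=lambda e: (-e.score, *e.variant.sort_key, e.variant.ref))
    for i, entry in enumerate(scored, start=1):
        entry.rank = i
    reservoir.sort(key=lambda v: (*v.sort_key, v.ref))
    return ClinicalCandidateList(
        panel_name=panel.name,
        panel_version=panel.version,
        entries=scored,
        reservoir=reservoir,
    )
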