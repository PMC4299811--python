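"""Sample-integrity QC: sex inference and pedigree relationship checks.

Sex is inferred from X-chromosome heterozygosity (males carry one X, so
almost no het calls among their non-reference X genotypes) with an optional
X:autosome depth-ratio corroboration (males ≈ 0.5, females ≈ 1.0).
Relationships are verified by counting Mendelian-inconsistent sites per
parent-child pair — sites where the child carries no allele the parent
could have transmitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .types import DepthProfile, Pedigree, Variant, is_x_contig

__all__ = [
    "SexThresholds",
    "SexCheckResult",
    "RelationshipCheckResult",
    "infer_sex",
    "sex_check",
    "check_relationships",
]


@dataclass(frozen=True)
class SexThresholds:
    """Decision thresholds; the checks are standard but cutoffs are
    configuration, not biology."""

    male_het_max: float = 0.10
    female_het_min: float = 0.25
    male_depth_ratio_max: float = 0.65
    female_depth_ratio_min: float = 0.85
    min_sites: int = 20


@dataclass
class SexCheckResult:
    sample_id: str
    predicted: str  # male | female | unknown
    x_het_fraction: float | None
    x_autosome_depth_ratio: float | None
    n_x_sites: int
    consistent_with_ped: bool | None = None
    reason: str = ""


def _in_par(pos: int, contig: str,
            par_regions: Mapping[str, Sequence[tuple[int, int]]] | None
            ) -> bool:
    if not par_regions:
        return False
    for s, e in par_regions.get(contig, ()):
        if s <= pos - 1 < e:
            return True
    return False


def _depth_ratio(profile: DepthProfile) -> float | None:
    """Mean X depth over mean autosomal depth (covered bases only)."""
    x_bases = x_sum = a_bases = a_sum = 0
    for contig in profile.contigs:
        for s, e, d in profile.runs(contig):
            if is_x_contig(contig):
                x_bases += e - s
                x_sum += (e - s) * d
            else:
                a_bases += e - s
                a_sum += (e - s) * d
    if x_bases == 0 or a_bases == 0 or a_sum == 0:
        return None
    return (x_sum / x_bases) / (a_sum / a_bases)


def infer_sex(variants: Iterable[Variant], sample_id: str,
              depth_profile: DepthProfile | None = None,
              par_regions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
              thresholds: SexThresholds | None = None) -> SexCheckResult:
    """Predict a sample's sex from X genotypes and optional depth.

    Genotype evidence (X het fraction over non-reference calls) takes
    precedence; when both lines of evidence are definite and disagree the
    prediction is ``unknown``. Too little X data yields ``unknown`` with a
    reason rather than an error.
    """
    th = thresholds or SexThresholds()
    n_nonref = n_het = 0
    for v in variants:
        if not is_x_contig(v.contig) or _in_par(v.pos, v.contig, par_regions):
            continue
        gt = v.genotypes.get(sample_id)
        if gt is None or not gt.known or not gt.has_alt:
            continue
        n_nonref += 1
        if gt.is_het:
            n_het += 1
    het_fraction = n_het / n_nonref if n_nonref else None

    geno_call = None
    if n_nonref >= th.min_sites:
        if het_fraction < th.male_het_max:
            geno_call = "male"
        elif het_fraction > th.female_het_min:
            geno_call = "female"
        else:
            geno_call = "unknown"

    ratio = _depth_ratio(depth_profile) if depth_profile is not None else None
    depth_call = None
    if ratio is not None:
        if ratio < th.male_depth_ratio_max:
            depth_call = "male"
        elif ratio >= th.female_depth_ratio_min:
            depth_call = "female"
        else:
            depth_call = "unknown"

    definite = ("male", "female")
    if geno_call in definite:
        if depth_call in definite and depth_call != geno_call:
            predicted, reason = "unknown", (
                f"genotype evidence says {geno_call} but depth ratio says "
                f"{depth_call}"
            )
        else:
            predicted, reason = geno_call, "X heterozygosity"
    elif depth_call in definite:
        predicted, reason = depth_call, "X:autosome depth ratio"
    elif geno_call == "unknown" or depth_call == "unknown":
        predicted, reason = "unknown", "evidence inconclusive"
    else:
        predicted, reason = "unknown", (
            f"insufficient X data ({n_nonref} non-reference sites, "
            f"min {th.min_sites}; no usable depth profile)"
        )
    return SexCheckResult(
        sample_id=sample_id,
        predicted=predicted,
        x_het_fraction=het_fraction,
        x_autosome_depth_ratio=ratio,
        n_x_sites=n_nonref,
        reason=reason,
    )


def sex_check(pedigree: Pedigree, variants: Sequence[Variant],
              depth_profiles: Mapping[str, DepthProfile] | None = None,
              par_regions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
              thresholds: SexThresholds | None = None
              ) -> list[SexCheckResult]:
    """Run :func:`infer_sex` for every pedigree member and compare with the
    recorded sex."""
    results = []
    for ind in pedigree:
        res = infer_sex(
            variants, ind.id,
            depth_profile=(depth_profiles or {}).get(ind.id),
            par_regions=par_regions,
            thresholds=thresholds,
        )
        if res.predicted != "unknown" and ind.sex != "unknown":
            res.consistent_with_ped = res.predicted == ind.sex
        results.append(res)
    return results


@dataclass
class RelationshipCheckResult:
    parent_id: str
    child_id: str
    n_sites: int
    n_errors: int
    error_rate: float | None
    flagged: bool


def check_relationships(pedigree: Pedigree, variants: Sequence[Variant],
                        error_threshold: float = 0.05
                        ) -> list[RelationshipCheckResult]:
    """Mendelian-inconsistency rate for every genotyped parent-child pair.

    A site is inconsistent when the child shares no allele value with the
    parent (e.g. child 1/1 vs parent 0/0). Only autosomal diploid genotypes
    with both calls known are tested; pairs whose rate exceeds
    ``error_threshold`` are flagged.
    """
    results = []
    for parent, child in pedigree.parent_child_pairs():
        n_sites = n_errors = 0
        for v in variants:
            if is_x_contig(v.contig):
                continue
            gp = v.genotypes.get(parent.id)
            gc = v.genotypes.get(child.id)
            if gp is None or gc is None or not gp.known or not gc.known:
                continue
            if gp.hemizygous or gc.hemizygous:
                continue
            n_sites += 1
            if not set(gc.alleles) & set(gp.alleles):
                n_errors += 1
        if n_sites == 0:
            continue
        rate = n_errors / n_sites
        results.append(
            RelationshipCheckResult(
                parent_id=parent.id,
                child_id=child.id,
                n_sites=n_sites,
                n_errors=n_errors,
                error_rate=rate,
                flagged=rate > error_threshold,
            )
        )
    if not results:
        warnings.warn(
            "no genotyped parent-child pairs to check", stacklevel=2
        )
    return results
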