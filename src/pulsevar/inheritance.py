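"""Mendelian inheritance-model annotation.

Each variant is labelled with the set of genetic models compatible with the
observed family genotypes and affection statuses:

``AD``/``AD_dn``
    autosomal dominant — every affected carries at least one alternative
    allele; no unaffected does (unless the gene has reduced penetrance).
``AR_hom``/``AR_hom_dn``
    autosomal recessive — every affected is homozygous alternative; no
    unaffected is.
``AR_comp``/``AR_comp_dn``
    autosomal recessive compound heterozygote — two distinct heterozygous
    variants in the same gene on opposite parental haplotypes.
``XR``/``XR_dn``, ``XD``/``XD_dn``
    the X-linked recessive/dominant counterparts; hemizygous males count as
    carriers of a full recessive genotype. ``XD`` is retained for
    heterozygous affected females, since several X-linked enzyme
    deficiencies manifest in carrier females.

The ``_dn`` (de novo) label applies when the allele is absent from every
genotyped parent of each affected; the plain label requires that the allele
*could* have been transmitted by a parent (carrier or ungenotyped). Unknown
genotypes never exclude a model.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .types import (
    CompoundPair,
    GenePanel,
    Genotype,
    Individual,
    PanelGene,
    Pedigree,
    Variant,
    is_x_contig,
)

__all__ = [
    "OFF_PANEL",
    "group_by_gene",
    "annotate_models",
    "find_compound_pairs",
    "annotate_variants",
]

logger = logging.getLogger(__name__)

#: Sentinel gene key for variants outside every panel gene.
OFF_PANEL = "__off_panel__"


def group_by_gene(variants: Iterable[Variant], panel: GenePanel
                  ) -> dict[str, list[Variant]]:
    """Assign variants to panel genes by annotation or transcript overlap.

    A variant lands in every gene whose symbol matches its ``Gene``
    annotation or whose transcript span overlaps the variant's reference
    interval; variants in no panel gene land under :data:`OFF_PANEL`.
    """
    trees: dict[str, IntervalTree] = {}
    for gene in panel:
        span = gene.span
        if span is None:
            continue
        trees.setdefault(gene.contig, IntervalTree()).addi(
            span[0], span[1], gene.hgnc_symbol
        )
    grouped: dict[str, list[Variant]] = {}
    for v in variants:
        symbols: set[str] = set()
        annotated = v.annotations.get("Gene")
        if annotated is not None and str(annotated) in panel:
            symbols.add(str(annotated))
        tree = trees.get(v.contig)
        if tree is not None:
            s, e = v.interval
            symbols.update(hit.data for hit in tree.overlap(s, e))
        if not symbols:
            grouped.setdefault(OFF_PANEL, []).append(v)
        for sym in sorted(symbols):
            grouped.setdefault(sym, []).append(v)
    return grouped


# ---------------------------------------------------------------------------
# Single-variant model logic
# ---------------------------------------------------------------------------

def _known(gt: Genotype | None) -> bool:
    return gt is not None and gt.known


def _required(gt: Genotype, model: str, ind: Individual) -> bool:
    """Does an affected individual's genotype fit the model's requirement?"""
    if model == "AD" or model == "XD":
        return gt.has_alt
    if model == "AR_hom":
        return gt.is_hom_alt
    if model == "XR":
        if ind.sex == "male":
            return gt.is_hom_alt  # hemizygous alt or hom alt
        return gt.is_hom_alt and not gt.hemizygous
    raise ValueError(model)


def _sufficient(gt: Genotype, model: str, ind: Individual) -> bool:
    """Would this genotype make an (unaffected) individual affected?"""
    if model == "AD" or model == "XD":
        return gt.has_alt
    if model == "AR_hom":
        return gt.is_hom_alt
    if model == "XR":
        if ind.sex == "male":
            return gt.has_alt
        return gt.is_hom_alt and not gt.hemizygous
    raise ValueError(model)


def _male_het_on_x(v: Variant, pedigree: Pedigree) -> bool:
    for ind in pedigree:
        if ind.sex != "male":
            continue
        gt = v.genotype(ind.id)
        if gt is not None and gt.is_het:
            return True
    return False


def _relevant_parents(ind: Individual, pedigree: Pedigree,
                      on_x: bool) -> list[Individual]:
    """Parents who could have transmitted the allele (mother only for a
    male's X allele — the father contributes the Y)."""
    parents = pedigree.parents_of(ind.id)
    if on_x and ind.sex == "male":
        parents = [p for p in parents if p.sex != "male"]
    return parents


def _carrier_status(parent: Individual, v: Variant) -> bool | None:
    """True/False when the parent's genotype is known, None when unknown."""
    gt = v.genotype(parent.id)
    if not _known(gt):
        return None
    return gt.has_alt


def _n_required_sources(gt: Genotype, model: str, ind: Individual) -> int:
    """How many parental transmissions the affected genotype implies."""
    if model in ("AD", "XD"):
        return 1
    if model == "AR_hom":
        return 1 if gt.hemizygous else 2
    if model == "XR":
        return 1 if (ind.sex == "male" or gt.hemizygous) else 2
    raise ValueError(model)


def annotate_models(gene_variants: Sequence[Variant], pedigree: Pedigree,
                    panel_gene: PanelGene | None = None) -> dict[tuple, set[str]]:
    """Compute the compatible single-variant models for each variant.

    Returns a mapping from :attr:`Variant.key` to the model set, and stores
    the set on each variant's ``models`` attribute (compound models are added
    separately by :func:`find_compound_pairs`).
    """
    reduced = bool(panel_gene.reduced_penetrance) if panel_gene else False
    result: dict[tuple, set[str]] = {}
    for v in gene_variants:
        models = _models_for_variant(v, pedigree, reduced)
        if v.models is None:
            v.models = set()
        v.models |= models
        result[v.key] = models
    return result


def _models_for_variant(v: Variant, pedigree: Pedigree,
                        reduced_penetrance: bool) -> set[str]:
    affected = pedigree.affected
    if not affected:
        return set()
    on_x = is_x_contig(v.contig)
    if on_x:
        if _male_het_on_x(v, pedigree):
            logger.warning(
                "male heterozygous genotype on X at %s:%d — treated as a "
                "genotype error; no X model assigned", v.contig, v.pos,
            )
            return set()
        families = ["XR", "XD"]
    else:
        families = ["AD", "AR_hom"]
    dominant = {"AD", "XD"}
    out: set[str] = set()
    for model in families:
        # affected individuals must fit the model's genotype
        ok = all(
            _required(v.genotype(a.id), model, a)
            for a in affected
            if _known(v.genotype(a.id))
        )
        if not ok:
            continue
        # no unaffected individual may carry an affection-sufficient genotype
        if not (reduced_penetrance and model in dominant):
            bad = any(
                _sufficient(v.genotype(u.id), model, u)
                for u in pedigree.unaffected
                if _known(v.genotype(u.id))
            )
            if bad:
                continue
        inherited_ok = True
        de_novo_ok = True
        dn_assessable = False
        for a in affected:
            gt = v.genotype(a.id)
            if not _known(gt) or not gt.has_alt:
                continue
            parents = _relevant_parents(a, pedigree, on_x)
            if not parents:
                continue
            statuses = [_carrier_status(p, v) for p in parents]
            if any(s is not None for s in statuses):
                dn_assessable = True
            if any(s is True for s in statuses):
                de_novo_ok = False
            n_sources = _n_required_sources(gt, model, a)
            if n_sources >= 2 and not on_x:
                # both parents must be carrier-or-unknown
                father = [p for p in parents if p.sex == "male"]
                mother = [p for p in parents if p.sex != "male"]
                for side in (father, mother):
                    if side and _carrier_status(side[0], v) is False:
                        inherited_ok = False
            elif n_sources >= 2 and on_x:
                for p in parents:
                    st = _carrier_status(p, v)
                    if st is False:
                        inherited_ok = False
            else:
                if all(_carrier_status(p, v) is False for p in parents):
                    inherited_ok = False
        if inherited_ok:
            out.add(model)
        if de_novo_ok and dn_assessable:
            out.add(model + "_dn")
    return out


# ---------------------------------------------------------------------------
# Compound heterozygotes
# ---------------------------------------------------------------------------

def _member_origin(v: Variant, affected: Individual,
                   pedigree: Pedigree) -> tuple[str, bool]:
    """(origin, absent_from_both_genotyped_parents) for one pair member."""
    father = next(
        (p for p in pedigree.parents_of(affected.id) if p.sex == "male"), None
    )
    mother = next(
        (p for p in pedigree.parents_of(affected.id) if p.sex != "male"), None
    )
    f_st = _carrier_status(father, v) if father else None
    m_st = _carrier_status(mother, v) if mother else None
    if m_st is True and f_st is False:
        return "maternal", False
    if f_st is True and m_st is False:
        return "paternal", False
    absent = (f_st is False and m_st is False)
    return "unknown", absent


def find_compound_pairs(het_variants_in_gene: Sequence[Variant],
                        pedigree: Pedigree,
                        reduced_penetrance: bool = False) -> list[CompoundPair]:
    """Candidate compound-heterozygote pairs among one gene's variants.

    A pair is emitted when some affected individual is heterozygous for both
    members, no unaffected individual carries both (unless reduced penetrance
    applies), and the two members do not definitively trace to the same
    parent. Members of emitted pairs gain ``AR_comp`` (``AR_comp_dn`` when a
    member is absent from both genotyped parents).
    """
    pairs: list[CompoundPair] = []
    ordered = sorted(het_variants_in_gene, key=lambda v: v.sort_key)
    for v1, v2 in combinations(ordered, 2):
        if v1.key == v2.key:
            continue
        supporters = [
            a for a in pedigree.affected
            if _known(v1.genotype(a.id)) and v1.genotype(a.id).is_het
            and _known(v2.genotype(a.id)) and v2.genotype(a.id).is_het
        ]
        if not supporters:
            continue
        if not reduced_penetrance:
            carrier_of_both = any(
                _known(v1.genotype(u.id)) and v1.genotype(u.id).has_alt
                and _known(v2.genotype(u.id)) and v2.genotype(u.id).has_alt
                for u in pedigree.unaffected
            )
            if carrier_of_both:
                continue
        emitted = None
        for a in sorted(supporters, key=lambda i: i.id):
            o1, absent1 = _member_origin(v1, a, pedigree)
            o2, absent2 = _member_origin(v2, a, pedigree)
            if o1 == o2 and o1 in ("maternal", "paternal"):
                continue  # definitively cis for this supporter
            emitted = CompoundPair(
                v1, v2, origins=(o1, o2), de_novo=absent1 or absent2
            )
            break
        if emitted is None:
            continue
        label = "AR_comp_dn" if emitted.de_novo else "AR_comp"
        for member in (v1, v2):
            if member.models is None:
                member.models = set()
            member.models.add(label)
        pairs.append(emitted)
    return pairs


# ---------------------------------------------------------------------------
# Whole-callset driver
# ---------------------------------------------------------------------------

def annotate_variants(variants: Sequence[Variant], pedigree: Pedigree,
                      panel: GenePanel) -> dict[str, list[Variant]]:
    """Group variants by panel gene, annotate models and compound pairs.

    Each variant's ``models`` ends up as the union over all genes it falls
    in; off-panel variants get an empty model set. Returns the gene grouping.
    """
    grouped = group_by_gene(variants, panel)
    for v in variants:
        v.models = set()
    for symbol, gene_variants in grouped.items():
        if symbol == OFF_PANEL:
            continue
        gene = panel.get(symbol)
        annotate_models(gene_variants, pedigree, gene)
        hets = [
            v for v in gene_variants
            if any(
                _known(v.genotype(a.id)) and v.genotype(a.id).is_het
                for a in pedigree.affected
            )
        ]
        find_compound_pairs(
            hets, pedigree,
            reduced_penetrance=bool(gene.reduced_penetrance) if gene else False,
        )
    return grouped
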