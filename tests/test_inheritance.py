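"""Inheritance-model annotation: examples, oracle equivalence, properties."""

from __future__ import annotations

import itertools

import pytest

from pulsevar.inheritance import (
    OFF_PANEL,
    annotate_models,
    find_compound_pairs,
    group_by_gene,
)
from pulsevar.types import (
    GenePanel,
    Genotype,
    Individual,
    PanelGene,
    Pedigree,
    TranscriptModel,
    Variant,
)

from conftest import make_variant
from oracle_inheritance import oracle_compound_pairs, oracle_single_models


def models_of(variant, pedigree, reduced=False):
    gene = PanelGene("G", variant.contig, reduced_penetrance=reduced,
                     inheritance_modes=set())
    v = make_variant(variant.contig, variant.pos, variant.ref, variant.alt)
    v.genotypes = variant.genotypes
    return annotate_models([v], pedigree, gene)[v.key]


class TestGroupByGene:
    def _panel(self):
        return GenePanel([
            PanelGene("PCCB", "1", {"AR"}, transcripts=[
                TranscriptModel("PCCB-201", "PCCB", "+",
                                [(100, 200), (300, 400)], contig="1")
            ]),
            PanelGene("OVL", "1", {"AD"}, transcripts=[
                TranscriptModel("OVL-201", "OVL", "+", [(350, 600)], contig="1")
            ]),
        ])

    def test_exonic_variant_assigned(self):
        v = make_variant("1", 150, gts={"s": (0, 1)})
        grouped = group_by_gene([v], self._panel())
        assert grouped == {"PCCB": [v]}

    def test_variant_in_two_overlapping_genes_appears_in_both(self):
        # 1-based 380 lies in PCCB's second exon and inside OVL's span
        v = make_variant("1", 380)
        grouped = group_by_gene([v], self._panel())
        assert set(grouped) == {"PCCB", "OVL"}
        assert grouped["PCCB"] == [v] and grouped["OVL"] == [v]

    def test_intergenic_variant_goes_off_panel(self):
        v = make_variant("1", 5000)
        grouped = group_by_gene([v], self._panel())
        assert grouped == {OFF_PANEL: [v]}

    def test_gene_annotation_respected(self):
        v = make_variant("1", 5000, ann={"Gene": "PCCB"})
        grouped = group_by_gene([v], self._panel())
        assert grouped == {"PCCB": [v]}


class TestModelExamples:
    def test_singleton_homozygous_gets_ar_hom_and_ad(self, singleton):
        v = make_variant("1", 100, gts={"proband": (1, 1)})
        assert models_of(v, singleton) == {"AR_hom", "AD"}

    def test_trio_de_novo_dominant(self, trio):
        v = make_variant("1", 100, gts={
            "child": (0, 1), "father": (0, 0), "mother": (0, 0)
        })
        assert models_of(v, trio) == {"AD_dn"}

    def test_x_recessive_carrier_mother(self, trio_boy):
        v = make_variant("X", 100, gts={
            "child": (1,), "father": (0,), "mother": (0, 1)
        })
        assert models_of(v, trio_boy) == {"XR"}

    def test_x_models_never_assigned_on_autosome(self, trio_boy):
        v = make_variant("1", 100, gts={
            "child": (1, 1), "father": (0, 1), "mother": (0, 1)
        })
        assert not models_of(v, trio_boy) & {"XR", "XD", "XR_dn", "XD_dn"}

    def test_male_het_on_x_is_treated_as_genotype_error(self, trio_boy):
        v = make_variant("X", 100, gts={
            "child": (0, 1), "father": (0,), "mother": (0, 1)
        })
        assert models_of(v, trio_boy) == set()

    def test_reduced_penetrance_exempts_dominant_carrier_check(self, trio):
        v = make_variant("1", 100, gts={
            "child": (0, 1), "father": (0, 1), "mother": (0, 0)
        })
        assert "AD" not in models_of(v, trio, reduced=False)
        assert "AD" in models_of(v, trio, reduced=True)
        # recessive carrier logic is untouched by the flag
        hom = make_variant("1", 100, gts={
            "child": (1, 1), "father": (1, 1), "mother": (0, 1)
        })
        assert "AR_hom" not in models_of(hom, trio, reduced=True)


# ---------------------------------------------------------------------------
# Exhaustive oracle equivalence
# ---------------------------------------------------------------------------

_DIPLOID = [(0, 0), (0, 1), (1, 1), None]
_MALE_X = [(0,), (1,), (0, 0), (0, 1), (1, 1), None]
_AFFECTION = ["yes", "no", "unknown"]


def _trio_members(child_sex):
    return [
        {"id": "father", "sex": "male", "affected": "no", "father": None,
         "mother": None},
        {"id": "mother", "sex": "female", "affected": "no", "father": None,
         "mother": None},
        {"id": "child", "sex": child_sex, "affected": "yes",
         "father": "father", "mother": "mother"},
    ]


def _build(members, geno, contig):
    ped = Pedigree([
        Individual(m["id"], father_id=m["father"], mother_id=m["mother"],
                   sex=m["sex"], affected=m["affected"])
        for m in members
    ])
    gts = {
        mid: Genotype(mid, gt) for mid, gt in geno.items() if gt is not None
    }
    for mid, gt in geno.items():
        if gt is None:
            gts[mid] = Genotype(mid, (None, None))
    v = Variant(contig=contig, pos=100, ref="A", alt="G", genotypes=gts)
    return ped, v


def _implementation_models(members, geno, contig, reduced):
    ped, v = _build(members, geno, contig)
    gene = PanelGene("G", contig, reduced_penetrance=reduced)
    return annotate_models([v], ped, gene)[v.key]


def test_autosomal_models_match_truth_table_exhaustively():
    """Every trio genotype x affection configuration agrees with the
    independently coded rule enumeration (autosomes)."""
    members_base = _trio_members("female")
    n = 0
    for affections in itertools.product(_AFFECTION, repeat=3):
        members = [dict(m) for m in members_base]
        for m, aff in zip(members, affections):
            m["affected"] = aff
        for gts in itertools.product(_DIPLOID, repeat=3):
            geno = {
                "father": gts[0], "mother": gts[1], "child": gts[2]
            }
            for reduced in (False, True):
                expect = oracle_single_models("1", members, geno, reduced)
                got = _implementation_models(members, geno, "1", reduced)
                assert got == expect, (affections, geno, reduced)
                n += 1
    assert n == 27 * 64 * 2


def test_x_models_match_truth_table_exhaustively():
    """X-chromosome model assignment agrees with the truth table for both
    child sexes, including hemizygous and impossible male genotypes."""
    for child_sex in ("male", "female"):
        members_base = _trio_members(child_sex)
        child_gts = _MALE_X if child_sex == "male" else _DIPLOID
        for affections in itertools.product(_AFFECTION, repeat=3):
            members = [dict(m) for m in members_base]
            for m, aff in zip(members, affections):
                m["affected"] = aff
            for f_gt in _MALE_X:
                for m_gt in _DIPLOID:
                    for c_gt in child_gts:
                        geno = {"father": f_gt, "mother": m_gt, "child": c_gt}
                        for reduced in (False, True):
                            expect = oracle_single_models(
                                "X", members, geno, reduced
                            )
                            got = _implementation_models(
                                members, geno, "X", reduced
                            )
                            assert got == expect, (
                                child_sex, affections, geno, reduced
                            )


def test_adding_all_unknown_individual_never_changes_models(trio):
    """Monotonicity: an extra member with unknown genotypes is inert."""
    configs = list(itertools.product(_DIPLOID[:3], repeat=3))
    for contig in ("1", "X"):
        for gts in configs:
            geno = {"father": gts[0], "mother": gts[1], "child": gts[2]}
            members = _trio_members("female")
            before = oracle_single_models(contig, members, geno)
            ped_small, v_small = _build(members, geno, contig)
            gene = PanelGene("G", contig)
            got_small = annotate_models([v_small], ped_small, gene)[v_small.key]

            extended = members + [
                {"id": "aunt", "sex": "female", "affected": "no",
                 "father": None, "mother": None}
            ]
            geno_ext = dict(geno, aunt=None)
            ped_big, v_big = _build(extended, geno_ext, contig)
            got_big = annotate_models([v_big], ped_big, gene)[v_big.key]
            assert got_small == got_big == before


# ---------------------------------------------------------------------------
# Compound heterozygotes
# ---------------------------------------------------------------------------

def _pair_variants(geno1, geno2):
    v1 = make_variant("1", 100, "A", "G", gts={
        k: v for k, v in geno1.items() if v is not None
    })
    v2 = make_variant("1", 200, "C", "T", gts={
        k: v for k, v in geno2.items() if v is not None
    })
    return v1, v2


class TestCompoundExamples:
    def test_trans_pair_from_both_parents(self, trio):
        v1, v2 = _pair_variants(
            {"child": (0, 1), "father": (0, 0), "mother": (0, 1)},
            {"child": (0, 1), "father": (0, 1), "mother": (0, 0)},
        )
        pairs = find_compound_pairs([v1, v2], trio)
        assert len(pairs) == 1
        assert pairs[0].origins == ("maternal", "paternal")
        assert v1.models == {"AR_comp"} and v2.models == {"AR_comp"}

    def test_cis_pair_from_one_parent_excluded(self, trio):
        v1, v2 = _pair_variants(
            {"child": (0, 1), "father": (0, 0), "mother": (0, 1)},
            {"child": (0, 1), "father": (0, 0), "mother": (0, 1)},
        )
        assert find_compound_pairs([v1, v2], trio) == []

    def test_singleton_pair_has_unknown_origins(self, singleton):
        v1, v2 = _pair_variants(
            {"proband": (0, 1)}, {"proband": (0, 1)}
        )
        pairs = find_compound_pairs([v1, v2], singleton)
        assert len(pairs) == 1
        assert pairs[0].origins == ("unknown", "unknown")
        assert not pairs[0].de_novo

    def test_de_novo_member_labels_pair_ar_comp_dn(self, trio):
        v1, v2 = _pair_variants(
            {"child": (0, 1), "father": (0, 0), "mother": (0, 1)},
            {"child": (0, 1), "father": (0, 0), "mother": (0, 0)},
        )
        pairs = find_compound_pairs([v1, v2], trio)
        assert len(pairs) == 1 and pairs[0].de_novo
        assert "AR_comp_dn" in v1.models

    def test_unaffected_carrier_of_both_excludes_pair(self):
        ped = Pedigree([
            Individual("father", sex="male", affected="no"),
            Individual("mother", sex="female", affected="no"),
            Individual("child", father_id="father", mother_id="mother",
                       sex="female", affected="yes"),
            Individual("sib", father_id="father", mother_id="mother",
                       sex="male", affected="no"),
        ])
        v1, v2 = _pair_variants(
            {"child": (0, 1), "sib": (0, 1), "father": (0, 1),
             "mother": (0, 1)},
            {"child": (0, 1), "sib": (0, 1), "father": (0, 1),
             "mother": (0, 1)},
        )
        assert find_compound_pairs([v1, v2], ped) == []

    def test_output_invariant_under_input_order(self, trio):
        def build():
            return _pair_variants(
                {"child": (0, 1), "father": (0, 0), "mother": (0, 1)},
                {"child": (0, 1), "father": (0, 1), "mother": (0, 0)},
            )

        v1, v2 = build()
        w1, w2 = build()
        p_fwd = find_compound_pairs([v1, v2], trio)
        p_rev = find_compound_pairs([w2, w1], trio)
        assert [(p.v1.key, p.v2.key, p.origins) for p in p_fwd] == [
            (p.v1.key, p.v2.key, p.origins) for p in p_rev
        ]


def test_compound_pairs_match_truth_table_exhaustively(subtests=None):
    """Trio pairs over all genotype combinations and yes/no affection
    assignments agree with the independent enumeration."""
    for affections in itertools.product(["yes", "no"], repeat=3):
        members = _trio_members("female")
        for m, aff in zip(members, affections):
            m["affected"] = aff
        ped = Pedigree([
            Individual(m["id"], father_id=m["father"], mother_id=m["mother"],
                       sex=m["sex"], affected=m["affected"])
            for m in members
        ])
        for gts1 in itertools.product(_DIPLOID, repeat=3):
            g1 = {"father": gts1[0], "mother": gts1[1], "child": gts1[2]}
            for gts2 in itertools.product(_DIPLOID, repeat=3):
                g2 = {"father": gts2[0], "mother": gts2[1], "child": gts2[2]}
                expect = oracle_compound_pairs(members, g1, g2)
                v1, v2 = _pair_variants(
                    {k: v for k, v in g1.items()},
                    {k: v for k, v in g2.items()},
                )
                got = find_compound_pairs([v1, v2], ped)
                if expect is None:
                    assert got == [], (affections, g1, g2)
                else:
                    assert len(got) == 1, (affections, g1, g2)
                    assert got[0].origins == expect[0], (affections, g1, g2)
                    assert got[0].de_novo == expect[1], (affections, g1, g2)
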