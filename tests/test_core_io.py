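"""Domain types and format round-trips."""

from __future__ import annotations

import io

import numpy as np
import pytest

from pulsevar import io as pv_io
from pulsevar.types import DepthProfile, Genotype, PedigreeError, Variant

from conftest import make_variant

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1,length=100000>\n"
    "##contig=<ID=X,length=100000>\n"
    '##INFO=<ID=Gene,Number=A,Type=String,Description="g">\n'
    '##INFO=<ID=MAF,Number=A,Type=Float,Description="f">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
)


def vcf_stream(body: str, samples=("s1",)) -> io.StringIO:
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    for s in samples:
        cols += f"\t{s}"
    return io.StringIO(VCF_HEADER + cols + "\n" + body)


class TestParseVariants:
    def test_simple_het_record(self):
        vs = pv_io.parse_variants(
            vcf_stream("1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n")
        )
        assert len(vs) == 1
        v = vs[0]
        assert (v.contig, v.pos, v.ref, v.alt) == ("1", 100, "A", "G")
        assert v.genotypes["s1"].is_het

    def test_multiallelic_decomposition_matches_manual(self):
        # Manual per-allele decomposition of "A -> G,T" with GT 1/2:
        # for ALT G the sample carries one G allele and one allele that is
        # neither ref nor G (unknown); symmetrically for T.
        vs = pv_io.parse_variants(
            vcf_stream("1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t1/2\n")
        )
        assert [(v.pos, v.alt) for v in vs] == [(100, "G"), (100, "T")]
        assert vs[0].genotypes["s1"].alleles == (1, None)
        assert vs[1].genotypes["s1"].alleles == (None, 1)

    def test_decomposition_conserves_alt_count(self):
        body = (
            "1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t1/2\n"
            "1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\n"
            "1\t300\t.\tG\tA,C,T\t.\tPASS\t.\tGT\t0/1\n"
        )
        vs = pv_io.parse_variants(vcf_stream(body))
        assert len(vs) == 2 + 1 + 3

    def test_hemizygous_single_index_gt(self):
        vs = pv_io.parse_variants(
            vcf_stream("X\t500\t.\tC\tT\t.\tPASS\t.\tGT\t1\n")
        )
        g = vs[0].genotypes["s1"]
        assert g.hemizygous and g.alleles == (1,)

    def test_missing_genotype_is_unknown_not_ref(self):
        vs = pv_io.parse_variants(
            vcf_stream("1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t./.\n")
        )
        g = vs[0].genotypes["s1"]
        assert not g.known and g.alleles == (None, None)

    def test_malformed_header_raises(self):
        with pytest.raises(pv_io.VcfParseError):
            pv_io.parse_variants(io.StringIO("not a vcf\n"))

    def test_per_alt_info_selected(self):
        vs = pv_io.parse_variants(
            vcf_stream(
                "1\t100\t.\tA\tG,T\t.\tPASS\tMAF=0.1,0.4\tGT\t1/2\n"
            )
        )
        assert vs[0].annotations["MAF"] == pytest.approx(0.1, abs=1e-6)
        assert vs[1].annotations["MAF"] == pytest.approx(0.4, abs=1e-6)


class TestVariantInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pos": 0},
            {"ref": "G", "alt": "G"},
            {"ref": ""},
            {"alt": "<DEL>"},
            {"ann": {"MAF": 1.5}},
        ],
    )
    def test_invalid_variant_rejected(self, kwargs):
        base = dict(contig="1", pos=100, ref="A", alt="G")
        ann = kwargs.pop("ann", None)
        base.update(kwargs)
        with pytest.raises(ValueError):
            make_variant(**base, ann=ann)

    def test_genotype_depth_invariant(self):
        with pytest.raises(ValueError):
            Genotype("s", (0, 1), depth=5, alt_depth=9)


class TestPedigree:
    def test_trio(self):
        ped = pv_io.parse_pedigree(io.StringIO(
            "F1\tfather\t0\t0\t1\t1\n"
            "F1\tmother\t0\t0\t2\t1\n"
            "F1\tchild\tfather\tmother\t2\t2\n"
        ))
        assert len(ped) == 3
        assert [i.id for i in ped.affected] == ["child"]
        assert ped["child"].father_id == "father"

    def test_singleton_founder(self):
        ped = pv_io.parse_pedigree(io.StringIO("F1\tp\t0\t0\t0\t0\n"))
        assert len(ped.founders) == 1
        assert ped["p"].sex == "unknown" and ped["p"].affected == "unknown"

    def test_father_with_female_sex_rejected(self):
        with pytest.raises(PedigreeError):
            pv_io.parse_pedigree(io.StringIO(
                "F1\tdad\t0\t0\t2\t1\n"
                "F1\tkid\tdad\t0\t1\t2\n"
            ))

    def test_dangling_parent_rejected(self):
        with pytest.raises(PedigreeError):
            pv_io.parse_pedigree(io.StringIO("F1\tkid\tghost\t0\t1\t2\n"))

    def test_duplicate_id_rejected(self):
        with pytest.raises(PedigreeError):
            pv_io.parse_pedigree(io.StringIO(
                "F1\tp\t0\t0\t1\t1\nF1\tp\t0\t0\t1\t1\n"
            ))

    def test_roundtrip(self, tmp_path, trio):
        path = tmp_path / "fam.ped"
        pv_io.write_pedigree(trio, path)
        back = pv_io.parse_pedigree(path)
        assert {i.id for i in back} == {i.id for i in trio}
        assert back["child"].sex == "female" and back["child"].affected == "yes"


PANEL_TSV = (
    "hgnc_symbol\tcontig\tinheritance_modes\treduced_penetrance\t"
    "disease_terms\ttranscripts\n"
    "PCCB\t3\tAR\tno\tpropionic_acidemia\tPCCB-201|+|100-200,300-400\n"
    "PDHA1\tX\tXL\tyes\tPDH_deficiency\tPDHA1-201|+|1000-1100\n"
)


class TestPanel:
    def test_parse(self):
        panel = pv_io.parse_panel(io.StringIO(PANEL_TSV))
        assert panel["PCCB"].inheritance_modes == {"AR"}
        assert panel["PDHA1"].inheritance_modes == {"XL"}
        assert panel["PDHA1"].reduced_penetrance
        assert panel["PCCB"].transcripts[0].exons == [(100, 200), (300, 400)]
        assert panel["PCCB"].transcripts[0].contig == "3"

    def test_empty_panel_warns_not_errors(self):
        header_only = PANEL_TSV.splitlines()[0] + "\n"
        with pytest.warns(UserWarning):
            panel = pv_io.parse_panel(io.StringIO(header_only))
        assert len(panel) == 0

    def test_unknown_inheritance_token_rejected(self):
        bad = PANEL_TSV.replace("AR\tno", "QX\tno")
        with pytest.raises(pv_io.FormatError):
            pv_io.parse_panel(io.StringIO(bad))

    def test_duplicate_symbol_rejected(self):
        dup = PANEL_TSV + "PCCB\t3\tAR\tno\t.\t.\n"
        with pytest.raises(pv_io.FormatError):
            pv_io.parse_panel(io.StringIO(dup))

    def test_roundtrip(self, tmp_path):
        panel = pv_io.parse_panel(io.StringIO(PANEL_TSV))
        path = tmp_path / "panel.tsv"
        pv_io.write_panel(panel, path)
        back = pv_io.parse_panel(path)
        for sym in panel.symbols:
            assert back[sym].inheritance_modes == panel[sym].inheritance_modes
            assert back[sym].reduced_penetrance == panel[sym].reduced_penetrance
            assert [t.exons for t in back[sym].transcripts] == [
                t.exons for t in panel[sym].transcripts
            ]


class TestDepth:
    def test_single_run(self):
        prof = pv_io.parse_depth(io.StringIO("chr1\t0\t100\t12\n"))
        assert prof.runs("chr1") == [(0, 100, 12)]

    def test_adjacent_equal_depth_runs_merge(self):
        prof = pv_io.parse_depth(
            io.StringIO("chr1\t0\t50\t12\nchr1\t50\t100\t12\n")
        )
        assert prof.runs("chr1") == [(0, 100, 12)]
        # per-base expansion identical before and after merging
        assert all(prof.depth_at("chr1", p) == 12 for p in range(100))

    def test_uncovered_position_is_zero(self):
        prof = pv_io.parse_depth(io.StringIO("chr1\t10\t20\t5\n"))
        assert prof.depth_at("chr1", 5) == 0
        assert prof.depth_at("chr2", 5) == 0

    def test_conflicting_overlap_rejected(self):
        with pytest.raises(pv_io.FormatError):
            pv_io.parse_depth(
                io.StringIO("chr1\t0\t50\t12\nchr1\t25\t75\t9\n")
            )

    def test_negative_depth_rejected(self):
        with pytest.raises(pv_io.FormatError):
            pv_io.parse_depth(io.StringIO("chr1\t0\t50\t-3\n"))

    def test_roundtrip(self, tmp_path):
        prof = pv_io.parse_depth(
            io.StringIO("chr1\t0\t50\t12\nchr1\t60\t100\t3\nchr2\t5\t9\t1\n")
        )
        path = tmp_path / "d.bedgraph"
        pv_io.write_depth(prof, path)
        back = pv_io.parse_depth(path)
        for c in prof.contigs:
            assert back.runs(c) == prof.runs(c)

    def test_interval_queries_match_bruteforce(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            depth = rng.integers(0, 6, size=500)
            runs = DepthProfile._runs_from_array(depth)
            prof = DepthProfile({"c": runs})
            s = int(rng.integers(0, 450))
            e = int(s + rng.integers(1, 50))
            cutoff = int(rng.integers(1, 6))
            expect = int(np.sum(depth[s:e] >= cutoff))
            assert prof.bases_at_or_above("c", s, e, cutoff) == expect
            assert prof.total_depth("c", s, e) == int(np.sum(depth[s:e]))


class TestRankedOutput:
    def _scored(self):
        v1 = make_variant("1", 100, gts={"s1": (0, 1)},
                          ann={"Gene": "PCCB", "Consequence": "missense"})
        v2 = make_variant("1", 50, gts={"s1": (0, 1)},
                          ann={"Gene": "PCCB", "Consequence": "missense"})
        v3 = make_variant("2", 10, gts={"s1": (1, 1)},
                          ann={"Gene": "PAH", "Consequence": "stop_gain"})
        v1.rank_score, v1.models = 7, {"AD"}
        v2.rank_score, v2.models = 7, {"AD"}
        v3.rank_score, v3.models = 14, {"AR_hom"}
        return [v1, v2, v3]

    def test_rankscore_key_emitted_and_roundtrips(self, tmp_path):
        vs = self._scored()
        vcf = tmp_path / "ranked.vcf"
        pv_io.write_ranked_output(vs, vcf, tmp_path / "ranked.tsv")
        text = vcf.read_text()
        assert "RankScore=" in text and "GeneticModels=" in text
        back = pv_io.parse_variants(vcf)
        assert {v.key: v.rank_score for v in back} == {
            v.key: v.rank_score for v in vs
        }
        assert {v.key: v.models for v in back} == {v.key: v.models for v in vs}

    def test_ties_break_by_contig_pos_alt(self, tmp_path):
        vs = self._scored()
        pv_io.write_ranked_output(vs, tmp_path / "r.vcf", tmp_path / "r.tsv")
        back = pv_io.parse_variants(tmp_path / "r.vcf")
        # highest score first, then the two score-7 variants by position
        assert [v.pos for v in back] == [10, 50, 100]

    def test_unscored_variant_rejected(self, tmp_path):
        v = make_variant("1", 100)
        with pytest.raises(ValueError):
            pv_io.write_ranked_output([v], tmp_path / "x.vcf", tmp_path / "x.tsv")


class TestFastxRoundtrip:
    def test_fasta(self, tmp_path):
        contigs = {"c1": "ACGTACGT", "c2": "GGGG"}
        pv_io.write_fasta(contigs, tmp_path / "r.fasta")
        assert pv_io.read_fasta(tmp_path / "r.fasta") == contigs

    def test_fastq_preserves_sequence_quality_and_mate(self, tmp_path):
        from pulsevar.types import FastqRead

        reads = [
            FastqRead("r1/1", "ACGT", "IIII", mate=1),
            FastqRead("r1/2", "TTTT", "II#I", mate=2),
        ]
        pv_io.write_fastq(reads, tmp_path / "r.fastq")
        back = pv_io.read_fastq(tmp_path / "r.fastq")
        assert [(r.id, r.sequence, r.quality, r.mate) for r in back] == [
            (r.id, r.sequence, r.quality, r.mate) for r in reads
        ]

    def test_bed12_roundtrip(self, tmp_path):
        from pulsevar.types import TranscriptModel

        t = TranscriptModel("T1", "G1", "+", [(100, 200), (300, 400)], contig="1")
        pv_io.write_transcripts_bed([t], tmp_path / "t.bed")
        back = pv_io.parse_transcripts_bed(tmp_path / "t.bed")
        assert back[0].exons == t.exons
        assert back[0].gene == "G1" and back[0].contig == "1"
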