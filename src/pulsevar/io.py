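"""Readers and writers for the standard formats the toolkit touches.

VCF parsing/writing is delegated to pysam; multi-allelic decomposition,
genotype-index remapping and the annotation conventions are applied on top.
Annotation INFO keys consumed elsewhere in the package: ``Gene``,
``Consequence``, ``MAF`` (fraction in [0,1]), ``Predictions`` (comma list of
protein-prediction verdicts), ``Conserved`` (flag), ``Known`` (flag); scoring
emits ``RankScore`` (integer) and ``GeneticModels`` (``gene:m1|m2,...``).
"""

from __future__ import annotations

import os
import tempfile
import warnings
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    ALL_MODELS,
    AlignmentRecord,
    DepthProfile,
    FastqRead,
    GenePanel,
    Genotype,
    Individual,
    PanelGene,
    Pedigree,
    TranscriptModel,
    Variant,
)

__all__ = [
    "FormatError",
    "VcfParseError",
    "parse_variants",
    "write_vcf",
    "write_ranked_output",
    "parse_pedigree",
    "write_pedigree",
    "parse_panel",
    "write_panel",
    "parse_depth",
    "write_depth",
    "parse_transcripts_bed",
    "write_transcripts_bed",
    "parse_regions_bed",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_alignments",
    "write_alignments",
]


class FormatError(ValueError):
    """A malformed input file."""


class VcfParseError(FormatError):
    """A malformed VCF header or record."""


#: INFO meta-lines for the annotation keys the toolkit understands.
_INFO_META = {
    "Gene": ("A", "String", "Gene symbol"),
    "Consequence": ("A", "String", "Consequence term"),
    "MAF": ("A", "Float", "Minor allele frequency"),
    "Predictions": ("A", "String", "Protein prediction verdicts (|-separated)"),
    "Conserved": ("0", "Flag", "Position in a conserved region"),
    "Known": ("0", "Flag", "Present in the known-sites catalogue"),
    "RankScore": ("A", "Integer", "Weighted-sum rank score"),
    "GeneticModels": ("A", "String", "Compatible inheritance models gene:m1|m2"),
}


def _materialise(source) -> tuple[str, bool]:
    """Return a filesystem path for a path-or-stream source."""
    if hasattr(source, "read"):
        tmp = tempfile.NamedTemporaryFile(
            "w", suffix=".vcf", delete=False, encoding="utf-8"
        )
        tmp.write(source.read())
        tmp.close()
        return tmp.name, True
    return os.fspath(source), False


def _open_text(source) -> tuple[TextIO, bool]:
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", encoding="utf-8"), True


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _decode_models(raw: str) -> set[str]:
    models: set[str] = set()
    for gene_part in str(raw).split(","):
        part = gene_part.split(":", 1)[-1]
        for label in part.split("|"):
            if label in ALL_MODELS:
                models.add(label)
    return models


def _alt_indexed(value, i: int, n_alts: int):
    """Pick the i-th entry of a Number=A INFO tuple, else pass through."""
    if isinstance(value, tuple):
        if len(value) == n_alts:
            return value[i]
        return value[0] if len(value) == 1 else value
    return value


def parse_variants(source) -> list[Variant]:
    """Parse a VCF 4.x file (path or text stream) into decomposed Variants.

    Multi-allelic records yield one ``Variant`` per ALT allele; genotype
    allele indices are remapped so 1 refers to that ALT, and alleles that
    point at a *different* ALT become unknown. Sample order is preserved.
    """
    path, is_tmp = _materialise(source)
    try:
        try:
            vf = pysam.VariantFile(path)
        except Exception as exc:  # malformed header
            raise VcfParseError(f"cannot parse VCF header: {exc}") from exc
        variants: list[Variant] = []
        samples = list(vf.header.samples)
        rec_no = 0
        try:
            with vf:
                for rec in vf:
                    rec_no += 1
                    variants.extend(_decompose(rec, samples, rec_no))
        except FormatError:
            raise
        except Exception as exc:
            raise VcfParseError(
                f"malformed VCF record #{rec_no + 1}: {exc}"
            ) from exc
        return variants
    finally:
        if is_tmp:
            os.unlink(path)


def _decompose(rec, samples: Sequence[str], rec_no: int) -> list[Variant]:
    alts = rec.alts or ()
    if not alts:
        return []
    out = []
    filt = list(rec.filter.keys())
    filter_label = ";".join(filt) if filt else "PASS"
    for i, alt in enumerate(alts):
        if not set(alt) <= set("ACGT"):
            raise VcfParseError(
                f"record #{rec_no} ({rec.contig}:{rec.pos}): unsupported ALT "
                f"{alt!r} (symbolic/breakend alleles are out of scope)"
            )
        annotations: dict[str, object] = {}
        rank_score = None
        models = None
        for key, value in rec.info.items():
            value = _alt_indexed(value, i, len(alts))
            if key == "RankScore":
                rank_score = int(value)
            elif key == "GeneticModels":
                models = _decode_models(value)
            elif key == "MAF":
                annotations[key] = float(value)
            elif value is True:
                annotations[key] = True
            else:
                annotations[key] = str(value)
        genotypes: dict[str, Genotype] = {}
        for s in samples:
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None:
                gt = (None,)
            alleles = tuple(
                None if a is None else (1 if a == i + 1 else (0 if a == 0 else None))
                for a in gt
            )
            depth = call.get("DP")
            ad = call.get("AD")
            alt_depth = None
            if ad is not None and len(ad) > i + 1 and ad[i + 1] is not None:
                alt_depth = int(ad[i + 1])
            genotypes[s] = Genotype(
                sample_id=s,
                alleles=alleles,
                depth=None if depth is None else int(depth),
                alt_depth=alt_depth,
                phased=bool(getattr(call, "phased", False)),
            )
        try:
            out.append(
                Variant(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    qual=rec.qual,
                    filter=filter_label,
                    genotypes=genotypes,
                    annotations=annotations,
                    rank_score=rank_score,
                    models=models,
                )
            )
        except ValueError as exc:
            raise VcfParseError(f"record #{rec_no}: {exc}") from exc
    return out


def _build_header(variants: Sequence[Variant], samples: Sequence[str],
                  contig_lengths: Mapping[str, int] | None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    lengths: dict[str, int] = dict(contig_lengths or {})
    contig_order: list[str] = []
    extra_keys: list[str] = []
    filters: list[str] = []
    for v in variants:
        if v.contig not in contig_order:
            contig_order.append(v.contig)
        lengths[v.contig] = max(lengths.get(v.contig, 0), v.pos + len(v.ref))
        for key in v.annotations:
            if key not in _INFO_META and key not in extra_keys:
                extra_keys.append(key)
        for f in v.filter.split(";"):
            if f not in ("PASS", ".") and f not in filters:
                filters.append(f)
    for contig in contig_order:
        header.contigs.add(contig, length=lengths[contig])
    for key, (num, typ, desc) in _INFO_META.items():
        header.info.add(key, num, typ, desc)
    for key in extra_keys:
        header.info.add(key, "1", "String", "Annotation")
    for f in filters:
        header.filters.add(f, None, None, "Failed filter")
    header.formats.add("GT", "1", "String", "Genotype")
    header.formats.add("DP", "1", "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for s in samples:
        header.add_sample(s)
    return header


def _format_models(v: Variant) -> str:
    gene = str(v.annotations.get("Gene", "-"))
    return f"{gene}:{'|'.join(sorted(v.models or ()))}"


def write_vcf(variants: Sequence[Variant], path,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write decomposed variants as a VCF 4.2 file (one record per variant)."""
    samples: list[str] = []
    for v in variants:
        for s in v.genotypes:
            if s not in samples:
                samples.append(s)
    header = _build_header(variants, samples, contig_lengths)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.contig,
                start=v.pos - 1,
                alleles=(v.ref, v.alt),
                qual=v.qual,
            )
            for f in v.filter.split(";"):
                rec.filter.add(f if f != "." else "PASS")
            for key, value in v.annotations.items():
                if _INFO_META.get(key, ("", "", ""))[1] == "Flag":
                    if value:
                        rec.info[key] = True
                elif key == "MAF":
                    rec.info[key] = float(value)
                else:
                    rec.info[key] = str(value)
            if v.rank_score is not None:
                rec.info["RankScore"] = v.rank_score
            if v.models is not None:
                rec.info["GeneticModels"] = _format_models(v)
            for s in samples:
                g = v.genotypes.get(s)
                if g is None:
                    rec.samples[s]["GT"] = (None,)
                    continue
                rec.samples[s]["GT"] = g.alleles
                rec.samples[s].phased = g.phased
                if g.depth is not None:
                    rec.samples[s]["DP"] = g.depth
                    if g.alt_depth is not None:
                        rec.samples[s]["AD"] = (g.depth - g.alt_depth, g.alt_depth)
            out.write(rec)


def write_ranked_output(variants: Sequence[Variant], vcf_path, tsv_path,
                        breakdowns: Mapping[tuple, Mapping[str, int]] | None = None,
                        contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write scored variants as an annotated VCF plus a rank-sorted TSV.

    Variants must carry ``rank_score``; order is score descending with ties
    broken by (contig, pos, alt). Round-tripping the VCF through
    :func:`parse_variants` recovers scores and models exactly.
    """
    for v in variants:
        if v.rank_score is None:
            raise ValueError(f"unscored variant {v.contig}:{v.pos} {v.ref}>{v.alt}")
    ordered = sorted(variants, key=lambda v: (-v.rank_score, *v.sort_key))
    write_vcf(ordered, vcf_path, contig_lengths=contig_lengths)
    rows = []
    for rank, v in enumerate(ordered, start=1):
        row = {
            "rank": rank,
            "contig": v.contig,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.annotations.get("Gene", "-"),
            "rank_score": v.rank_score,
            "models": "|".join(sorted(v.models or ())),
        }
        if breakdowns and v.key in breakdowns:
            for cat, sc in breakdowns[v.key].items():
                row[f"score_{cat}"] = sc
        rows.append(row)
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX_CODE = {"1": "male", "2": "female"}
_PHENO_CODE = {"2": "yes", "1": "no"}


def parse_pedigree(source) -> Pedigree:
    """Parse a PLINK 6-column PED file (path or stream)."""
    handle, close = _open_text(source)
    try:
        individuals = []
        family_id = "FAM"
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(
                    f"PED line {lineno}: expected 6 columns, got {len(fields)}"
                )
            fam, iid, father, mother, sex, pheno = fields[:6]
            family_id = fam
            individuals.append(
                Individual(
                    id=iid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX_CODE.get(sex, "unknown"),
                    affected=_PHENO_CODE.get(pheno, "unknown"),
                )
            )
        return Pedigree(individuals, family_id=family_id)
    finally:
        if close:
            handle.close()


def write_pedigree(pedigree: Pedigree, path) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    pheno_code = {"yes": "2", "no": "1", "unknown": "0"}
    with open(path, "w", encoding="utf-8") as out:
        for ind in pedigree:
            out.write(
                "\t".join(
                    [
                        pedigree.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        sex_code[ind.sex],
                        pheno_code[ind.affected],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene panel TSV
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = [
    "hgnc_symbol", "contig", "inheritance_modes", "reduced_penetrance",
    "disease_terms", "transcripts",
]

_TRUTHY = {"yes", "true", "1"}
_FALSY = {"no", "false", "0", ""}


def _parse_transcript_spec(spec: str, gene: str) -> list[TranscriptModel]:
    """Decode ``tid|strand|s-e,s-e;tid2|...`` into transcript models."""
    spec = spec.strip()
    if spec in ("", "."):
        return []
    out = []
    for part in spec.split(";"):
        try:
            tid, strand, exon_str = part.split("|")
            exons = []
            for iv in exon_str.split(","):
                s, e = iv.split("-")
                exons.append((int(s), int(e)))
        except ValueError as exc:
            raise FormatError(
                f"bad transcript spec {part!r} for gene {gene}"
            ) from exc
        out.append(TranscriptModel(tid, gene, strand, exons))
    return out


def _attach_gene_contigs(gene: PanelGene) -> None:
    for t in gene.transcripts:
        t.contig = gene.contig


def _format_transcript_spec(transcripts: Sequence[TranscriptModel]) -> str:
    if not transcripts:
        return "."
    return ";".join(
        f"{t.transcript_id}|{t.strand}|"
        + ",".join(f"{s}-{e}" for s, e in t.exons)
        for t in transcripts
    )


def parse_panel(source, name: str = "panel", version: str = "1.0") -> GenePanel:
    """Parse a clinical gene-panel TSV (header + one row per gene)."""
    handle, close = _open_text(source)
    try:
        df = pd.read_csv(handle, sep="\t", dtype=str, keep_default_na=False)
    finally:
        if close:
            handle.close()
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"panel TSV missing column(s): {missing}")
    if df.empty:
        warnings.warn("gene panel is empty (header only)", stacklevel=2)
    genes = []
    for _, row in df.iterrows():
        modes = {
            m.strip() for m in str(row["inheritance_modes"]).split(",") if m.strip()
        }
        rp_raw = str(row["reduced_penetrance"]).strip().lower()
        if rp_raw in _TRUTHY:
            reduced = True
        elif rp_raw in _FALSY:
            reduced = False
        else:
            raise FormatError(
                f"bad reduced_penetrance value {row['reduced_penetrance']!r} "
                f"for {row['hgnc_symbol']}"
            )
        try:
            gene = PanelGene(
                hgnc_symbol=row["hgnc_symbol"],
                contig=row["contig"],
                inheritance_modes=modes,
                reduced_penetrance=reduced,
                disease_terms=[
                    t.strip() for t in str(row["disease_terms"]).split(",")
                    if t.strip() and t.strip() != "."
                ],
                transcripts=_parse_transcript_spec(
                    str(row["transcripts"]), row["hgnc_symbol"]
                ),
            )
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
        for t in gene.transcripts:
            t.gene = gene.hgnc_symbol
        _attach_gene_contigs(gene)
        genes.append(gene)
    try:
        return GenePanel(genes, name=name, version=version)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_panel(panel: GenePanel, path) -> None:
    rows = []
    for g in panel:
        rows.append(
            {
                "hgnc_symbol": g.hgnc_symbol,
                "contig": g.contig,
                "inheritance_modes": ",".join(sorted(g.inheritance_modes)),
                "reduced_penetrance": "yes" if g.reduced_penetrance else "no",
                "disease_terms": ",".join(g.disease_terms) or ".",
                "transcripts": _format_transcript_spec(g.transcripts),
            }
        )
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED-graph depth
# ---------------------------------------------------------------------------

def parse_depth(source) -> DepthProfile:
    """Parse per-base depth from a BED-graph (contig, start, end, depth)."""
    handle, close = _open_text(source)
    runs: dict[str, list[tuple[int, int, int]]] = {}
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(
                    f"BED-graph line {lineno}: expected 4 columns"
                )
            contig, start, end, depth = fields[:4]
            try:
                runs.setdefault(contig, []).append(
                    (int(start), int(end), int(depth))
                )
            except ValueError as exc:
                raise FormatError(f"BED-graph line {lineno}: {exc}") from exc
    finally:
        if close:
            handle.close()
    try:
        return DepthProfile(runs)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_depth(profile: DepthProfile, path) -> None:
    with open(path, "w", encoding="utf-8") as out:
        for contig in profile.contigs:
            for s, e, d in profile.runs(contig):
                out.write(f"{contig}\t{s}\t{e}\t{d}\n")


# ---------------------------------------------------------------------------
# Transcripts as BED12; plain regions as BED3
# ---------------------------------------------------------------------------

def parse_transcripts_bed(source) -> list[TranscriptModel]:
    """Parse transcript models from BED12; the name field is ``tid|gene``."""
    handle, close = _open_text(source)
    out = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"BED12 line {lineno}: expected 12 columns")
            chrom_start = int(f[1])
            name = f[3]
            tid, _, gene = name.partition("|")
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                raise FormatError(f"BED12 line {lineno}: block count mismatch")
            exons = [
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            try:
                out.append(
                    TranscriptModel(tid, gene or tid, f[5], exons, contig=f[0])
                )
            except ValueError as exc:
                raise FormatError(f"BED12 line {lineno}: {exc}") from exc
    finally:
        if close:
            handle.close()
    return out


def write_transcripts_bed(transcripts: Sequence[TranscriptModel], path,
                          contigs: Mapping[str, str] | None = None) -> None:
    """Write transcripts as BED12. ``contigs`` overrides per-transcript contigs."""
    with open(path, "w", encoding="utf-8") as out:
        for t in transcripts:
            contig = (contigs or {}).get(t.transcript_id, t.contig or t.gene)
            start, end = t.span
            sizes = ",".join(str(e - s) for s, e in t.exons)
            starts = ",".join(str(s - start) for s, _ in t.exons)
            out.write(
                "\t".join(
                    [
                        contig, str(start), str(end), f"{t.transcript_id}|{t.gene}",
                        "0", t.strand, str(start), str(end), "0",
                        str(len(t.exons)), sizes, starts,
                    ]
                )
                + "\n"
            )


def parse_regions_bed(source) -> dict[str, list[tuple[int, int]]]:
    """Parse a 3-column BED into per-contig half-open intervals."""
    handle, close = _open_text(source)
    regions: dict[str, list[tuple[int, int]]] = {}
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split()
            if len(f) < 3:
                raise FormatError(f"BED line {lineno}: expected 3 columns")
            regions.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    finally:
        if close:
            handle.close()
    for ivs in regions.values():
        ivs.sort()
    return regions


# ---------------------------------------------------------------------------
# FASTA / FASTQ / alignments
# ---------------------------------------------------------------------------

def read_fasta(source) -> dict[str, str]:
    handle, close = _open_text(source)
    try:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    finally:
        if close:
            handle.close()


def write_fasta(contigs: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()
    ]
    with open(path, "w", encoding="utf-8") as out:
        SeqIO.write(records, out, "fasta")


def _mate_from_id(read_id: str) -> int:
    if read_id.endswith("/2"):
        return 2
    return 1


def read_fastq(source) -> list[FastqRead]:
    """Read phred+33 FASTQ; mate index is taken from a ``/1``/``/2`` suffix."""
    handle, close = _open_text(source)
    try:
        reads = []
        for rec in SeqIO.parse(handle, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            reads.append(
                FastqRead(rec.id, str(rec.seq), qual, mate=_mate_from_id(rec.id))
            )
        return reads
    finally:
        if close:
            handle.close()


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.quality]
        records.append(rec)
    with open(path, "w", encoding="utf-8") as out:
        SeqIO.write(records, out, "fastq")


_ALN_COLUMNS = ["read_id", "contig", "start", "span", "strand", "mate"]


def read_alignments(source) -> list[AlignmentRecord]:
    handle, close = _open_text(source)
    try:
        df = pd.read_csv(handle, sep="\t", dtype={"read_id": str, "contig": str})
    finally:
        if close:
            handle.close()
    missing = [c for c in _ALN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"alignment TSV missing column(s): {missing}")
    return [
        AlignmentRecord(
            str(r.read_id), str(r.contig), int(r.start), int(r.span),
            str(r.strand), int(r.mate),
        )
        for r in df.itertuples(index=False)
    ]


def write_alignments(alignments: Iterable[AlignmentRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "read_id": a.read_id, "contig": a.contig, "start": a.start,
                "span": a.span, "strand": a.strand, "mate": a.mate,
            }
            for a in alignments
        ],
        columns=_ALN_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
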