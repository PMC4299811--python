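"""Seeded synthetic-data harness.

Generates everything the toolkit needs without real genomes: a small diploid
reference with panel genes (autosomal and X stand-ins), a family carrying a
planted causal variant under a chosen inheritance model plus
frequency-annotated decoy SNVs, error-free or erroneous paired-end reads
(350 bp fragments, 2x100 by default), and a deliberately simple toy
aligner/genotyper (exact k-mer seeding, ungapped extension, pileup
genotyping) standing in for a production alignment/calling stack. All
operations are deterministic for a fixed seed.

The generator emits SNVs only: the toy aligner is ungapped, so simulated
indels would break their own alignment. Decoys emulate benign panel
polymorphisms — they never carry loss-of-function consequence terms and at
most one damaging protein prediction.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .pulse import (
    CallsetComparison,
    CallsetMetrics,
    callset_concordance,
    callset_metrics,
    pass_calls,
    truncate_reads,
)
from .types import (
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
    is_x_contig,
)

__all__ = [
    "SimulationParams",
    "Reference",
    "TruthSet",
    "PulsedRunResult",
    "simulate_reference",
    "simulate_family",
    "simulate_reads",
    "toy_align_and_call",
    "run_pulse_experiment",
    "singleton_pedigree",
    "trio_pedigree",
    "write_fixtures",
]

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SUPPORTED_CAUSAL_MODELS = frozenset(
    {"AD", "AD_dn", "AR_hom", "AR_comp", "XR", "XR_dn", "XD", "XD_dn"}
)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _rng(seed: int, *streams: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *streams])


def _id_stream(name: str) -> int:
    return zlib.crc32(name.encode())


@dataclass
class SimulationParams:
    """Study conditions for the synthetic harness.

    Defaults mirror the emulated study: 2x100 nt paired-end reads from
    350 bp fragments at 30x autosomal depth, error-free, on a 100 kb diploid
    genome carrying 150 decoy SNVs (half heterozygous in each founder).
    """

    seed: int = 7
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 40_000, "2": 30_000, "X": 30_000}
    )
    n_decoys: int = 150
    decoy_het_fraction: float = 0.5
    decoy_common_fraction: float = 0.8
    decoy_in_gene_fraction: float = 0.5
    causal_model: str = "AR_hom"
    causal_consequence: str = "missense"
    read_length: int = 100
    fragment_size: int = 350
    mean_depth: float = 30.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.read_length < 1 or self.fragment_size < self.read_length:
            raise ValueError("need fragment_size >= read_length >= 1")
        if not 0.0 <= self.decoy_het_fraction <= 1.0:
            raise ValueError("decoy_het_fraction must lie in [0, 1]")
        if not 0.0 <= self.decoy_in_gene_fraction <= 1.0:
            raise ValueError("decoy_in_gene_fraction must lie in [0, 1]")
        if self.causal_model not in SUPPORTED_CAUSAL_MODELS:
            raise ValueError(
                f"causal_model {self.causal_model!r} not in "
                f"{sorted(SUPPORTED_CAUSAL_MODELS)}"
            )


@dataclass
class Reference:
    contigs: dict[str, str]
    panel: GenePanel

    @property
    def transcripts(self) -> list[TranscriptModel]:
        return self.panel.transcripts()

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.contigs.items()}


# Gene stand-ins: (symbol, contig, fractional offset, modes, reduced
# penetrance). PCCB (autosomal recessive propionic acidemia) and PDHA1
# (X-linked pyruvate dehydrogenase deficiency, manifesting in het females)
# anchor the two clinical scenarios.
_GENE_LAYOUT = [
    ("PCCB", "1", 0.25, {"AR"}, False, ["propionic_acidemia"]),
    ("ACAT1", "1", 0.625, {"AR"}, False, ["beta-ketothiolase_deficiency"]),
    ("PAH", "2", 0.33, {"AR"}, False, ["phenylketonuria"]),
    ("PDHA1", "X", 0.25, {"XL"}, True, ["PDH_deficiency"]),
    ("OTC", "X", 0.625, {"XL"}, False, ["OTC_deficiency"]),
]

_N_EXONS = 4
_EXON_LEN = 150
_INTRON_LEN = 350


def _gene_exons(offset: int) -> list[tuple[int, int]]:
    exons = []
    pos = offset
    for _ in range(_N_EXONS):
        exons.append((pos, pos + _EXON_LEN))
        pos += _EXON_LEN + _INTRON_LEN
    return exons


_TRANSCRIPT_SPAN = _N_EXONS * _EXON_LEN + (_N_EXONS - 1) * _INTRON_LEN


def simulate_reference(params: SimulationParams) -> Reference:
    """Random contigs plus a small clinical panel with stand-in genes."""
    for contig, length in params.contig_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {contig!r} has non-positive length")
    contigs: dict[str, str] = {}
    for i, (contig, length) in enumerate(sorted(params.contig_lengths.items())):
        rng = _rng(params.seed, 101, i)
        contigs[contig] = "".join(_BASES[rng.integers(0, 4, length)])
    genes = []
    for symbol, contig, frac, modes, reduced, terms in _GENE_LAYOUT:
        if contig not in params.contig_lengths:
            continue
        length = params.contig_lengths[contig]
        if length < _TRANSCRIPT_SPAN:
            raise ValueError(
                f"contig {contig!r} ({length} bp) is shorter than one "
                f"transcript span ({_TRANSCRIPT_SPAN} bp)"
            )
        offset = min(int(length * frac), length - _TRANSCRIPT_SPAN)
        tx = TranscriptModel(
            transcript_id=f"{symbol}-201",
            gene=symbol,
            strand="+",
            exons=_gene_exons(offset),
            contig=contig,
        )
        genes.append(
            PanelGene(
                hgnc_symbol=symbol,
                contig=contig,
                inheritance_modes=set(modes),
                reduced_penetrance=reduced,
                disease_terms=list(terms),
                transcripts=[tx],
            )
        )
    return Reference(
        contigs=contigs,
        panel=GenePanel(genes, name="synthetic-iem-panel", version="1.0"),
    )


def singleton_pedigree(sex: str = "female", ind_id: str = "proband") -> Pedigree:
    return Pedigree(
        [Individual(ind_id, sex=sex, affected="yes")], family_id="SIM"
    )


def trio_pedigree(child_sex: str = "female",
                  child_affected: bool = True) -> Pedigree:
    return Pedigree(
        [
            Individual("father", sex="male", affected="no"),
            Individual("mother", sex="female", affected="no"),
            Individual(
                "child", father_id="father", mother_id="mother",
                sex=child_sex, affected="yes" if child_affected else "no",
            ),
        ],
        family_id="SIM",
    )


@dataclass
class TruthSet:
    """Simulated truth variants with per-member genotypes."""

    variants: list[Variant]
    causal_keys: list[tuple]

    @property
    def causal(self) -> list[Variant]:
        by_key = {v.key: v for v in self.variants}
        return [by_key[k] for k in self.causal_keys]

    def known_sites(self, include_causal: bool = False) -> list[Variant]:
        """The dbSNP-like catalogue: decoys, optionally plus the causal
        variant(s)."""
        return [
            v for v in self.variants
            if include_causal or v.annotations.get("Known")
        ]


def _n_haps(ind: Individual, contig: str) -> int:
    if is_x_contig(contig) and ind.sex == "male":
        return 1
    return 2


class _FamilyBuilder:
    """Allele bookkeeping: founder haplotypes plus whole-haplotype
    transmission (no recombination) so families are Mendelian-consistent by
    construction."""

    def __init__(self, reference: Reference, pedigree: Pedigree,
                 params: SimulationParams):
        self.ref = reference
        self.ped = pedigree
        self.params = params
        self.rng = _rng(params.seed, 202)
        # child -> contig -> {"father": hap_idx|None, "mother": hap_idx}
        self.transmission: dict[str, dict[str, dict[str, int | None]]] = {}
        self._plan_transmission()
        # site -> member -> per-hap alleles
        self.sites: list[dict] = []

    def _topo_members(self) -> list[Individual]:
        ordered, placed = [], set()
        pending = list(self.ped)
        while pending:
            progress = False
            for ind in list(pending):
                parents = [p for p in (ind.father_id, ind.mother_id) if p]
                if all(p in placed for p in parents):
                    ordered.append(ind)
                    placed.add(ind.id)
                    pending.remove(ind)
                    progress = True
            if not progress:  # unreachable given pedigree validation
                raise RuntimeError("pedigree ordering failed")
        return ordered

    def _plan_transmission(self) -> None:
        for ind in self._topo_members():
            if ind.father_id is None and ind.mother_id is None:
                continue
            per_contig: dict[str, dict[str, int | None]] = {}
            for contig in self.ref.contigs:
                on_x = is_x_contig(contig)
                father = self.ped[ind.father_id] if ind.father_id else None
                mother = self.ped[ind.mother_id] if ind.mother_id else None
                f_hap: int | None = None
                if father is not None and not (on_x and ind.sex == "male"):
                    f_hap = int(self.rng.integers(0, _n_haps(father, contig)))
                m_hap: int | None = None
                if mother is not None:
                    m_hap = int(self.rng.integers(0, _n_haps(mother, contig)))
                per_contig[contig] = {"father": f_hap, "mother": m_hap}
            self.transmission[ind.id] = per_contig

    def _derive_child_alleles(self, site: dict, contig: str) -> None:
        """Fill non-founder per-hap alleles from parental haplotypes."""
        for ind in self._topo_members():
            if ind.id in site["alleles"]:
                continue
            trans = self.transmission.get(ind.id)
            if trans is None:  # founder without alleles: absent
                site["alleles"][ind.id] = tuple([0] * _n_haps(ind, contig))
                continue
            haps = []
            on_x = is_x_contig(contig)
            f_hap = trans[contig]["father"]
            m_hap = trans[contig]["mother"]
            if not (on_x and ind.sex == "male"):
                if ind.father_id is not None and f_hap is not None:
                    haps.append(site["alleles"][ind.father_id][f_hap])
                else:
                    haps.append(0)
            if ind.mother_id is not None and m_hap is not None:
                haps.append(site["alleles"][ind.mother_id][m_hap])
            else:
                haps.append(0)
            site["alleles"][ind.id] = tuple(haps)

    def new_site(self, contig: str, pos: int, ref: str, alt: str,
                 annotations: dict) -> dict:
        site = {
            "contig": contig, "pos": pos, "ref": ref, "alt": alt,
            "annotations": annotations, "alleles": {},
        }
        self.sites.append(site)
        return site

    def finish_site(self, site: dict) -> None:
        contig = site["contig"]
        for ind in self.ped:
            if ind.id not in site["alleles"] and (
                ind.father_id is None and ind.mother_id is None
            ):
                site["alleles"][ind.id] = tuple([0] * _n_haps(ind, contig))
        self._derive_child_alleles(site, contig)


def _pick_causal_gene(panel: GenePanel, on_x: bool) -> PanelGene:
    symbol = "PDHA1" if on_x else "PCCB"
    gene = panel.get(symbol)
    if gene is None or not gene.transcripts:
        raise ValueError(f"reference panel lacks the {symbol} stand-in gene")
    return gene


def _exon_mid(gene: PanelGene, exon_index: int) -> int:
    s, e = gene.transcripts[0].exons[exon_index]
    return (s + e) // 2


def _plant_causal(builder: _FamilyBuilder, reference: Reference,
                  params: SimulationParams) -> list[dict]:
    model = params.causal_model
    ped = builder.ped
    affected = sorted(ped.affected, key=lambda i: i.id)
    if len(affected) != 1:
        raise ValueError(
            "the generator plants the causal variant for exactly one "
            f"affected individual, pedigree has {len(affected)}"
        )
    a = affected[0]
    on_x = model.startswith("X")
    gene = _pick_causal_gene(reference.panel, on_x)
    contig = gene.contig
    seq = reference.contigs[contig]
    father = ped[a.father_id] if a.father_id else None
    mother = ped[a.mother_id] if a.mother_id else None
    is_founder = father is None and mother is None
    trans = builder.transmission.get(a.id, {}).get(contig, {})

    def make_site(exon_index: int) -> dict:
        pos0 = _exon_mid(gene, exon_index)
        ref = seq[pos0]
        alt = _TRANSITION[ref]
        ann = {
            "Gene": gene.hgnc_symbol,
            "Consequence": params.causal_consequence,
            "Predictions": "damaging,deleterious",
            "Conserved": True,
            "Known": False,
        }
        return builder.new_site(contig, pos0 + 1, ref, alt, ann)

    def fail(reason: str):
        raise ValueError(
            f"causal model {model} is infeasible for this pedigree: {reason}"
        )

    sites: list[dict]
    if model == "AR_hom":
        site = make_site(1)
        if is_founder:
            site["alleles"][a.id] = tuple([1] * _n_haps(a, contig))
        else:
            if father is None or mother is None:
                fail("homozygote needs both parents present or none")
            for parent, role in ((father, "father"), (mother, "mother")):
                hap = trans[role]
                if hap is None:
                    fail(f"no {role} transmission to {a.id} on {contig}")
                alleles = [0] * _n_haps(parent, contig)
                alleles[hap] = 1
                site["alleles"][parent.id] = tuple(alleles)
        sites = [site]
    elif model == "AD":
        if not is_founder:
            fail(
                "dominant inheritance with unaffected parents is "
                "contradictory; use AD_dn for a de novo event"
            )
        site = make_site(1)
        alleles = [0] * _n_haps(a, contig)
        alleles[0] = 1
        site["alleles"][a.id] = tuple(alleles)
        sites = [site]
    elif model == "AD_dn":
        if is_founder:
            fail("a de novo event needs at least one parent in the pedigree")
        site = make_site(1)
        sites = [site]
    elif model == "AR_comp":
        s1, s2 = make_site(1), make_site(2)
        if is_founder:
            s1["alleles"][a.id] = (1, 0)
            s2["alleles"][a.id] = (0, 1)
        else:
            if father is None or mother is None:
                fail("compound het in trans needs both parents or none")
            for site, parent, role in ((s1, mother, "mother"),
                                       (s2, father, "father")):
                hap = trans[role]
                if hap is None:
                    fail(f"no {role} transmission on {contig}")
                alleles = [0] * _n_haps(parent, contig)
                alleles[hap] = 1
                site["alleles"][parent.id] = tuple(alleles)
        sites = [s1, s2]
    elif model in ("XR", "XR_dn"):
        if a.sex != "male":
            fail("X-linked recessive planting needs an affected male")
        site = make_site(1)
        if model == "XR":
            if mother is not None:
                hap = trans["mother"]
                alleles = [0, 0]
                alleles[hap] = 1
                site["alleles"][mother.id] = tuple(alleles)
            else:
                site["alleles"][a.id] = (1,)
        else:
            if is_founder:
                fail("a de novo event needs a parent in the pedigree")
        sites = [site]
    elif model in ("XD", "XD_dn"):
        site = make_site(1)
        if model == "XD":
            if not is_founder:
                fail(
                    "X-linked dominant with unaffected parents is "
                    "contradictory; use XD_dn"
                )
            alleles = [0] * _n_haps(a, contig)
            alleles[0] = 1
            site["alleles"][a.id] = tuple(alleles)
        else:
            if is_founder:
                fail("a de novo event needs a parent in the pedigree")
        sites = [site]
    else:  # pragma: no cover - guarded by SimulationParams
        raise ValueError(model)

    for site in sites:
        builder.finish_site(site)
    # de novo overrides: add the allele to the affected's genotype after
    # transmission (parents stay reference)
    if model.endswith("_dn"):
        for site in sites:
            current = list(site["alleles"][a.id])
            current[-1] = 1  # mutate the maternally derived haplotype
            site["alleles"][a.id] = tuple(current)
    return sites


def _decoy_annotations(rng: np.random.Generator, contig: str, pos0: int,
                       panel: GenePanel, params: SimulationParams) -> dict:
    gene_symbol = None
    in_exon = False
    for gene in panel:
        if gene.contig != contig or gene.span is None:
            continue
        if gene.span[0] <= pos0 < gene.span[1]:
            gene_symbol = gene.hgnc_symbol
            in_exon = any(
                s <= pos0 < e
                for t in gene.transcripts
                for s, e in t.exons
            )
            break
    if gene_symbol is None:
        consequence = "intergenic"
    elif not in_exon:
        consequence = "intronic"
    else:
        consequence = "synonymous" if rng.random() < 0.7 else "missense"
    ann: dict = {"Consequence": consequence, "Known": True}
    if gene_symbol is not None:
        ann["Gene"] = gene_symbol
    if rng.random() < params.decoy_common_fraction:
        ann["MAF"] = round(float(rng.uniform(0.05, 0.45)), 4)
    else:
        ann["MAF"] = round(float(rng.uniform(1e-4, 0.004)), 6)
    if consequence == "missense":
        # benign polymorphisms rarely show concordant damaging evidence:
        # at most one damaging verdict
        ann["Predictions"] = (
            "damaging" if rng.random() < 0.2 else "tolerated"
        )
    if rng.random() < 0.2:
        ann["Conserved"] = True
    return ann


def simulate_family(reference: Reference, pedigree: Pedigree,
                    params: SimulationParams
                    ) -> tuple[TruthSet, dict[str, dict[str, list[str]]]]:
    """Plant the causal variant and decoys; return truth + haplotypes.

    Haplotypes are per member, per contig: two sequences on diploid contigs,
    one on a male's X. Decoy genotypes are drawn per founder (heterozygous
    with ``decoy_het_fraction``, else homozygous alternative; present with
    probability 0.5 on a male founder's X) and children receive whole
    parental haplotypes, so transmission is Mendelian-consistent by
    construction.
    """
    builder = _FamilyBuilder(reference, pedigree, params)
    causal_sites = _plant_causal(builder, reference, params)
    causal_pos = {(s["contig"], s["pos"]) for s in causal_sites}

    rng = _rng(params.seed, 203)
    contig_names = sorted(reference.contigs)
    lengths = np.array([len(reference.contigs[c]) for c in contig_names],
                       dtype=float)
    probs = lengths / lengths.sum()
    # exome-targeted emulation: a share of decoys lands inside panel genes
    gene_spans = [
        (g.contig, *g.span) for g in reference.panel if g.span is not None
    ]
    taken: set[tuple[str, int]] = set(causal_pos)
    decoy_sites = []
    while len(decoy_sites) < params.n_decoys:
        if gene_spans and rng.random() < params.decoy_in_gene_fraction:
            contig, gs, ge = gene_spans[int(rng.integers(0, len(gene_spans)))]
            pos0 = int(rng.integers(gs, ge))
        else:
            contig = contig_names[int(rng.choice(len(contig_names), p=probs))]
            length = len(reference.contigs[contig])
            pos0 = int(rng.integers(50, length - 50))
        if (contig, pos0 + 1) in taken:
            continue
        taken.add((contig, pos0 + 1))
        ref = reference.contigs[contig][pos0]
        others = [b for b in "ACGT" if b != ref]
        alt = others[int(rng.integers(0, 3))]
        ann = _decoy_annotations(rng, contig, pos0, reference.panel, params)
        site = builder.new_site(contig, pos0 + 1, ref, alt, ann)
        for founder in pedigree.founders:
            n = _n_haps(founder, contig)
            if n == 1:
                alleles = (1,) if rng.random() < 0.5 else (0,)
            elif rng.random() < params.decoy_het_fraction:
                alleles = [0, 0]
                alleles[int(rng.integers(0, 2))] = 1
                alleles = tuple(alleles)
            else:
                alleles = (1, 1)
            site["alleles"][founder.id] = alleles
        builder.finish_site(site)
        decoy_sites.append(site)

    variants = []
    for site in sorted(builder.sites, key=lambda s: (s["contig"], s["pos"])):
        genotypes = {}
        for ind in pedigree:
            haps = site["alleles"][ind.id]
            genotypes[ind.id] = Genotype(
                sample_id=ind.id, alleles=tuple(sorted(haps))
            )
        variants.append(
            Variant(
                contig=site["contig"], pos=site["pos"], ref=site["ref"],
                alt=site["alt"], qual=None, filter="PASS",
                genotypes=genotypes, annotations=dict(site["annotations"]),
            )
        )
    truth = TruthSet(
        variants=variants,
        causal_keys=[
            (s["contig"], s["pos"], s["ref"], s["alt"]) for s in causal_sites
        ],
    )

    haplotypes: dict[str, dict[str, list[str]]] = {}
    for ind in pedigree:
        per_contig: dict[str, list[str]] = {}
        for contig, seq in reference.contigs.items():
            n = _n_haps(ind, contig)
            hap_lists = [list(seq) for _ in range(n)]
            for site in builder.sites:
                if site["contig"] != contig:
                    continue
                alleles = site["alleles"][ind.id]
                for h, allele in enumerate(alleles):
                    if allele == 1:
                        hap_lists[h][site["pos"] - 1] = site["alt"]
            per_contig[contig] = ["".join(h) for h in hap_lists]
        haplotypes[ind.id] = per_contig
    return truth, haplotypes


def simulate_reads(haplotypes: Mapping[str, Sequence[str]],
                   params: SimulationParams,
                   sample_id: str = "sample") -> list[FastqRead]:
    """Paired-end reads from one individual's haplotypes.

    Fragments are sampled uniformly per haplotype copy so a diploid contig
    receives the full ``mean_depth`` and a hemizygous X half of it. Mate 1
    reads the fragment start on the forward strand; mate 2 is the reverse
    complement of the fragment end. Sequencing errors are substitutions at
    ``error_rate`` with quality 2 ('#'); correct bases get quality 40 ('I').
    """
    if not haplotypes:
        raise ValueError("haplotypes must be non-empty")
    rng = _rng(params.seed, 303, _id_stream(sample_id))
    rl, frag = params.read_length, params.fragment_size
    reads: list[FastqRead] = []
    for contig in sorted(haplotypes):
        for hap_idx, seq in enumerate(haplotypes[contig]):
            length = len(seq)
            if frag > length:
                raise ValueError(
                    f"fragment size {frag} exceeds contig {contig!r} "
                    f"length {length}"
                )
            n_frags = int(round(params.mean_depth / 2 * length / (2 * rl)))
            starts = rng.integers(0, length - frag + 1, n_frags)
            for i, s in enumerate(starts):
                s = int(s)
                m1 = seq[s:s + rl]
                m2 = _revcomp(seq[s + frag - rl:s + frag])
                base_id = f"{sample_id}:{contig}:{hap_idx}:{i}"
                for mate, mseq in ((1, m1), (2, m2)):
                    if params.error_rate > 0:
                        err = rng.random(rl) < params.error_rate
                        if err.any():
                            chars = list(mseq)
                            for j in np.flatnonzero(err):
                                chars[j] = "ACGT"[
                                    (("ACGT".index(chars[j]))
                                     + int(rng.integers(1, 4))) % 4
                                ]
                            mseq = "".join(chars)
                        qual = "".join(
                            "#" if e else "I" for e in err
                        )
                    else:
                        qual = "I" * rl
                    reads.append(
                        FastqRead(f"{base_id}/{mate}", mseq, qual, mate=mate)
                    )
    return reads


# ---------------------------------------------------------------------------
# Toy aligner / genotyper
# ---------------------------------------------------------------------------

_SEED_K = 21
_MIN_CALL_DEPTH = 4
_HOM_FRACTION = 0.8
_HET_FRACTION = 0.3


def _build_index(contigs: Mapping[str, str], k: int
                 ) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for contig, seq in contigs.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], []).append((contig, i))
    return index


def _count_mismatches(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def toy_align_and_call(
    reads: Sequence[FastqRead],
    reference_contigs: Mapping[str, str],
    params: SimulationParams | None = None,
    sample_id: str = "sample",
) -> tuple[list[AlignmentRecord], list[Variant]]:
    """Exact k-mer seed + ungapped extension alignment, then pileup calls.

    Genotyping per site: depth >= 4 required for PASS; alternative-allele
    fraction >= 0.8 calls homozygous alt, [0.3, 0.8) heterozygous, below 0.3
    reference (no call). A harness, not a production caller: thresholds are
    fixed constants so cross-pulse comparisons stay stable.
    """
    k = _SEED_K
    index = _build_index(reference_contigs, k)
    seqs = dict(reference_contigs)
    alignments: list[AlignmentRecord] = []
    depth: dict[str, np.ndarray] = {
        c: np.zeros(len(s), dtype=np.int32) for c, s in seqs.items()
    }
    alt_counts: dict[tuple[str, int], Counter] = {}

    for read in reads:
        if len(read.sequence) < k:
            continue
        max_mm = max(2, int(0.05 * len(read.sequence)))
        best = None  # (mm, contig, start, strand, oriented_seq)
        for strand, oriented in (("+", read.sequence),
                                 ("-", _revcomp(read.sequence))):
            n = len(oriented)
            offsets = list(range(0, n - k + 1, k))
            if offsets[-1] != n - k:
                offsets.append(n - k)
            for off in offsets:
                for contig, hit in index.get(oriented[off:off + k], ()):
                    start = hit - off
                    if start < 0 or start + n > len(seqs[contig]):
                        continue
                    mm = _count_mismatches(
                        oriented, seqs[contig][start:start + n], max_mm
                    )
                    if mm > max_mm:
                        continue
                    if best is None or mm < best[0]:
                        best = (mm, contig, start, strand, oriented)
                    if best[0] == 0:
                        break
                if best is not None and best[0] == 0:
                    break
            if best is not None and best[0] == 0:
                break
        if best is None:
            continue
        mm, contig, start, strand, oriented = best
        n = len(oriented)
        alignments.append(
            AlignmentRecord(read.id, contig, start, n, strand, read.mate)
        )
        depth[contig][start:start + n] += 1
        if mm:
            ref_slice = seqs[contig][start:start + n]
            for j in range(n):
                if oriented[j] != ref_slice[j]:
                    alt_counts.setdefault(
                        (contig, start + j), Counter()
                    )[oriented[j]] += 1

    calls: list[Variant] = []
    for (contig, pos0), counter in sorted(alt_counts.items()):
        d = int(depth[contig][pos0])
        if d == 0:
            continue
        alt, n_alt = counter.most_common(1)[0]
        fraction = n_alt / d
        if fraction < _HET_FRACTION:
            continue
        if fraction >= _HOM_FRACTION:
            alleles = (1, 1)
        else:
            alleles = (0, 1)
        calls.append(
            Variant(
                contig=contig,
                pos=pos0 + 1,
                ref=seqs[contig][pos0],
                alt=alt,
                qual=None,
                filter="PASS" if d >= _MIN_CALL_DEPTH else "lowdepth",
                genotypes={
                    sample_id: Genotype(
                        sample_id, alleles, depth=d, alt_depth=n_alt
                    )
                },
            )
        )
    return alignments, calls


# ---------------------------------------------------------------------------
# End-to-end pulsed experiment
# ---------------------------------------------------------------------------

@dataclass
class PulsedRunResult:
    truth: TruthSet
    pedigree: Pedigree
    reference: Reference
    early_pass: list[Variant]
    final_pass: list[Variant]
    concordance: CallsetComparison
    metrics: CallsetMetrics
    alignments_final: list[AlignmentRecord]


def run_pulse_experiment(params: SimulationParams,
                         pedigree: Pedigree | None = None,
                         early_cycle: int = 50,
                         known_include_causal: bool = True
                         ) -> PulsedRunResult:
    """Simulate one individual end to end and compare an early SE pulse
    against the final PE callset.

    Reads are simulated once at full length, truncated to the early
    single-end pulse, and both read sets are aligned and genotyped with the
    toy caller. Concordance counts early PASS calls reproduced (same contig,
    position, ref, alt) in the final PASS callset; callset metrics are
    evaluated against the simulated known-sites catalogue.
    """
    reference = simulate_reference(params)
    ped = pedigree or singleton_pedigree()
    truth, haplotypes = simulate_family(reference, ped, params)
    proband = sorted(ped.affected, key=lambda i: i.id)[0]
    reads = simulate_reads(haplotypes[proband.id], params,
                           sample_id=proband.id)
    early_reads = truncate_reads(reads, early_cycle, mode="SE")
    _, early_calls = toy_align_and_call(
        early_reads, reference.contigs, params, sample_id=proband.id
    )
    aln_final, final_calls = toy_align_and_call(
        reads, reference.contigs, params, sample_id=proband.id
    )
    early_pass = pass_calls(early_calls)
    final_pass = pass_calls(final_calls)
    comparison = callset_concordance(early_pass, final_pass)
    metrics = callset_metrics(
        final_pass,
        known_sites=truth.known_sites(include_causal=known_include_causal),
        sample_id=proband.id,
    )
    return PulsedRunResult(
        truth=truth,
        pedigree=ped,
        reference=reference,
        early_pass=early_pass,
        final_pass=final_pass,
        concordance=comparison,
        metrics=metrics,
        alignments_final=aln_final,
    )


def write_fixtures(outdir, reference: Reference, truth: TruthSet,
                   pedigree: Pedigree,
                   reads: Sequence[FastqRead] | None = None) -> None:
    """Write FASTA/VCF/PED/TSV/BED(12)/FASTQ fixtures into a directory."""
    import os

    from . import io as pv_io

    os.makedirs(outdir, exist_ok=True)
    pv_io.write_fasta(reference.contigs, os.path.join(outdir, "reference.fasta"))
    pv_io.write_panel(reference.panel, os.path.join(outdir, "panel.tsv"))
    pv_io.write_transcripts_bed(
        reference.transcripts, os.path.join(outdir, "transcripts.bed")
    )
    pv_io.write_pedigree(pedigree, os.path.join(outdir, "family.ped"))
    pv_io.write_vcf(
        truth.variants, os.path.join(outdir, "truth.vcf"),
        contig_lengths=reference.contig_lengths,
    )
    if reads is not None:
        pv_io.write_fastq(
            [r for r in reads if r.mate == 1],
            os.path.join(outdir, "reads_R1.fastq"),
        )
        pv_io.write_fastq(
            [r for r in reads if r.mate == 2],
            os.path.join(outdir, "reads_R2.fastq"),
        )
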