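"""Shared fixtures and construction helpers for the test suite."""

from __future__ import annotations

import pytest

from pulsevar.types import Genotype, Individual, Pedigree, Variant


def make_variant(contig="1", pos=100, ref="A", alt="G", gts=None,
                 ann=None, filt="PASS") -> Variant:
    """Build a variant from a {sample: allele-tuple} mapping."""
    genotypes = {
        s: Genotype(sample_id=s, alleles=tuple(a)) for s, a in (gts or {}).items()
    }
    return Variant(
        contig=contig, pos=pos, ref=ref, alt=alt, filter=filt,
        genotypes=genotypes, annotations=dict(ann or {}),
    )


@pytest.fixture
def trio() -> Pedigree:
    """Affected child, unaffected genotyped parents."""
    return Pedigree(
        [
            Individual("father", sex="male", affected="no"),
            Individual("mother", sex="female", affected="no"),
            Individual("child", father_id="father", mother_id="mother",
                       sex="female", affected="yes"),
        ]
    )


@pytest.fixture
def trio_boy() -> Pedigree:
    return Pedigree(
        [
            Individual("father", sex="male", affected="no"),
            Individual("mother", sex="female", affected="no"),
            Individual("child", father_id="father", mother_id="mother",
                       sex="male", affected="yes"),
        ]
    )


@pytest.fixture
def singleton() -> Pedigree:
    return Pedigree([Individual("proband", sex="female", affected="yes")])
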