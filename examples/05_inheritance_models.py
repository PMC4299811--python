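"""Mendelian inheritance-model annotation on hand-built trios.

Three textbook configurations: a de novo dominant variant (child het,
parents reference), an X-linked recessive variant in a boy with a carrier
mother, and a compound heterozygote (two variants in one gene inherited
from opposite parents). The model set on each variant is exactly what a
clinician filters on.
"""

from pulsevar.inheritance import annotate_models, find_compound_pairs
from pulsevar.types import (
    Genotype,
    Individual,
    PanelGene,
    Pedigree,
    Variant,
)


def variant(contig, pos, gts):
    return Variant(contig=contig, pos=pos, ref="A", alt="G", genotypes={
        s: Genotype(s, alleles) for s, alleles in gts.items()
    })


trio = Pedigree([
    Individual("father", sex="male", affected="no"),
    Individual("mother", sex="female", affected="no"),
    Individual("child", father_id="father", mother_id="mother",
               sex="female", affected="yes"),
])
boy_trio = Pedigree([
    Individual("father", sex="male", affected="no"),
    Individual("mother", sex="female", affected="no"),
    Individual("child", father_id="father", mother_id="mother",
               sex="male", affected="yes"),
])

de_novo = variant("1", 1000, {
    "child": (0, 1), "father": (0, 0), "mother": (0, 0)
})
models = annotate_models([de_novo], trio, PanelGene("GENE1", "1"))
print("child het, parents ref ->", sorted(models[de_novo.key]))

xlr = variant("X", 5000, {
    "child": (1,), "father": (0,), "mother": (0, 1)
})
models = annotate_models([xlr], boy_trio, PanelGene("GENE2", "X"))
print("hemizygous boy, carrier mother ->", sorted(models[xlr.key]))

v1 = variant("1", 2000, {"child": (0, 1), "father": (0, 0),
                         "mother": (0, 1)})
v2 = variant("1", 2100, {"child": (0, 1), "father": (0, 1),
                         "mother": (0, 0)})
annotate_models([v1, v2], trio, PanelGene("GENE3", "1"))
pairs = find_compound_pairs([v1, v2], trio)
for p in pairs:
    print(f"compound pair {p.v1.pos}+{p.v2.pos}: origins={p.origins}, "
          f"models={sorted(p.v1.models)}")
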