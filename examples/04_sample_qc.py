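"""Sample-integrity QC on a simulated trio.

Checks that each member's genetic sex (from X heterozygosity) matches the
pedigree and that parent-child links show no Mendelian inconsistencies.
Then deliberately swaps in an unrelated child to show the relationship
check flagging the mismatch.
"""

from pulsevar.qc import check_relationships, sex_check
from pulsevar.synth import (
    SimulationParams,
    simulate_family,
    simulate_reference,
    trio_pedigree,
)
from pulsevar.types import Genotype

params = SimulationParams(seed=43, causal_model="AR_hom", n_decoys=400)
reference = simulate_reference(params)
pedigree = trio_pedigree(child_sex="male")
truth, _ = simulate_family(reference, pedigree, params)

print("sex check (X het fraction over non-reference X genotypes):")
for res in sex_check(pedigree, truth.variants):
    print(f"  {res.sample_id:<8} predicted={res.predicted:<7} "
          f"het_fraction={res.x_het_fraction:.2f} "
          f"n_sites={res.n_x_sites} ped_consistent={res.consistent_with_ped}")

print("\nrelationship check (true family):")
for rel in check_relationships(pedigree, truth.variants):
    print(f"  {rel.parent_id}->{rel.child_id}: "
          f"{rel.n_errors}/{rel.n_sites} Mendelian errors "
          f"(flagged={rel.flagged})")

other, _ = simulate_family(reference, trio_pedigree(child_sex="male"),
                           SimulationParams(seed=44, n_decoys=400))
swap = {v.key: v.genotypes["child"] for v in other.variants}
for v in truth.variants:
    g = swap.get(v.key)
    v.genotypes["child"] = (Genotype("child", g.alleles) if g
                            else Genotype("child", (0, 0)))
print("\nrelationship check after swapping in an unrelated child:")
for rel in check_relationships(pedigree, truth.variants):
    print(f"  {rel.parent_id}->{rel.child_id}: "
          f"error rate {rel.error_rate:.1%} (flagged={rel.flagged})")
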