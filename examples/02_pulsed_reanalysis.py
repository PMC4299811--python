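"""Pulsed reanalysis end to end: early SE pulse vs final PE callset.

Simulates a 100 kb diploid genome with 150 SNVs, error-free 2x100 nt
paired-end reads (350 bp fragments, 30x), truncates them to the 50-cycle
single-end pulse, aligns and genotypes both read sets with the toy caller
and compares the callsets. The reproduction rate says how trustworthy the
early, cheap callset is; the known-sites rate mirrors a dbSNP concordance
check of the final calls.
"""

from pulsevar import make_default_schedule
from pulsevar.synth import SimulationParams, run_pulse_experiment

schedule = make_default_schedule()
print("pulse schedule:", " -> ".join(schedule.names))

result = run_pulse_experiment(SimulationParams(seed=7), early_cycle=50)
c = result.concordance
m = result.metrics
print(f"\ntruth variants: {len(result.truth.variants)}")
print(f"SE-50 PASS calls: {c.n_early}; final PE-100 PASS calls: "
      f"{len(result.final_pass)}")
print(f"early calls reproduced in final callset: "
      f"{c.n_reproduced}/{c.n_early} = {100 * c.rate:.2f}%")
print(f"genotype-concordant among reproduced: {100 * c.genotype_rate:.2f}%")
print(f"final-call known-sites concordance: {100 * m.known_rate:.2f}%")
print(f"final callset het/hom: {m.het}/{m.hom} "
      f"(ratio {m.het_hom:.2f}); Ts/Tv {m.tstv:.2f}")
print("\n(high reproduction means an early pulse already supports "
      "clinical review; decoy alt alleles are drawn uniformly, so Ts/Tv "
      "is ~0.5 by construction rather than the ~3 of real exomes)")
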