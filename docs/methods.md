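# Methods

This note documents the models and procedures pulsevar implements, the
parameter defaults and why they were chosen, what the synthetic harness
does and does not emulate, and the numerical/degenerate-input conventions.

## Coordinates and variant representation

VCF input is 1-based inclusive; every internal interval (exons, depth runs,
assessment regions, alignments) is 0-based half-open. Multi-allelic VCF
records are decomposed into one biallelic variant per ALT allele; genotype
allele indices are remapped so `1` means "this ALT", and an allele pointing
at a *different* ALT becomes unknown rather than reference — mapping it to
reference would fabricate evidence and could wrongly exclude an inheritance
model. Missing genotypes (`./.`) are unknown, never reference, for the same
reason. Symbolic/breakend ALTs and BCF are out of scope.

## Inheritance-model annotation

A variant's model set is decided by three checks per model family
(`AD`/`AR_hom` on autosomes, `XR`/`XD` on X):

1. **Affected fit** — every affected individual with a known genotype
   carries the model's defining genotype: at least one alternative allele
   (AD, XD); homozygous alternative (AR_hom); hemizygous or homozygous
   alternative for males, homozygous for females (XR). Unknown genotypes
   never exclude a model.
2. **Unaffected exclusion** — no unaffected individual carries a genotype
   sufficient to be affected under that model. A panel gene's
   reduced-penetrance flag exempts the *dominant* models (AD, XD) from this
   check only: an unaffected dominant carrier is plausible under reduced
   penetrance, an unaffected recessive homozygote is not.
3. **Transmission split** — the plain label requires that each affected's
   alternative allele(s) could have come from a parent (a carrier or an
   ungenotyped parent; for a homozygote, one such parent on each side). The
   `_dn` label requires the allele to be absent from every genotyped
   relevant parent, and at least one relevant parent genotyped. The two are
   therefore mutually exclusive when both parents are genotyped, and both
   are reported when a parent is missing — the data cannot distinguish
   inheritance from a de novo event. On X, the relevant parent of an
   affected male is the mother alone (the father contributes the Y).

A heterozygous male genotype on X is biologically impossible outside the
pseudoautosomal regions (out of scope here); it is treated as a genotype
error: the variant receives no X model for that configuration, with a
logged warning. `XD` is retained for heterozygous affected females because
several X-linked enzyme deficiencies manifest severely in carrier females.
Singleton homozygotes report both `AR_hom` and `AD` (one alternative allele
is present and no relative contradicts dominance); prioritisation between
them is the rank model's job, not the annotator's.

**Compound heterozygotes.** Two distinct heterozygous variants in one gene
form a candidate pair when some affected individual is heterozygous for
both, no unaffected individual carries both (unless reduced penetrance
applies), and the two members do not definitively trace to the same parent
(cis). Origins are called maternal/paternal only when exactly one parent
carries the member; a member absent from both genotyped parents makes the
pair de novo (`AR_comp_dn`). Without parental genotypes phase is unknown
and the pair is reported with unknown origins — a deliberate
phase-unaware over-call that downstream review must resolve.

These rules are verified exhaustively: every trio genotype × sex ×
affection configuration for one and two variants is compared against an
independently coded truth-table implementation (`tests/oracle_inheritance.py`).

## Rank score

The score is an integer sum over five categories; integers keep results
exactly reproducible and trivially comparable. Defaults (all overridable
via a flat YAML file):

| category      | default                                                        |
|---------------|----------------------------------------------------------------|
| consequence   | stop_gain/frameshift/splice_acceptor/splice_donor +5; missense/inframe +3; synonymous 0; intronic/intergenic/unknown −2 |
| frequency     | MAF < 0.005 → +3; < 0.02 → +1; ≥ 0.02 → −12; missing → +3      |
| inheritance   | ≥ 1 compatible model → +3; none → −12                          |
| predictions   | +1 per damaging verdict, capped at 2                           |
| conservation  | conserved flag → +1                                            |

The −12 penalties implement the emphasis on inheritance pattern and allele
frequency: with these defaults, any variant with MAF > 0.02 scores
strictly below any model-supported, rare (< 0.005), coding variant —
asserted by an exhaustive sweep over category combinations in the tests. A
missing frequency scores like a rare one: alleles never observed in
reference populations are the interesting ones in rare disease. A
variant's inheritance category uses the union of model sets across the
genes it overlaps. Ties are broken by (contig, position, alt, ref), so the
candidate list is a pure function of the input set.

## Coverage

Assessment regions are the union of a transcript's exons with each
*internal* exon boundary extended `splice_flank` bases (default 2) into
the intron — the GT/AG splice dinucleotides — and extensions merging
across short introns. Transcript outer ends are never extended: there is
no splice site beyond a terminal exon. Completeness at cutoff *c* is the
fraction of assessed bases with depth ≥ *c* (inclusive: depth 10 passes a
10× test, the conventional reading of "covered at 10×"); width is
completeness at 1×. A transcript counts toward diagnostic yield only when
every assessed base reaches the cutoff — a single shallow base fails it.
Gene-level metrics union the gene's transcript regions first so shared
bases count once. An empty region set or transcript list is an error (the
denominator is undefined), not a zero. Depth profiles are run-length
encoded; splitting or merging runs at equal depth cannot change any
metric, and interval queries are tested against per-base brute force.

## Pulse machinery

The default schedule runs single-end pulses at 35/50/75/100 SBS cycles and
paired-end pulses from 50 cycles, ending — by construction and by
invariant — with the maximum-cycle PE pulse. Truncation cuts sequence and
quality to the first `cycle` bases (both mates to the same cycle:
symmetric chemistry) and drops mate 2 in SE mode; it is idempotent and
composes as the minimum of cycles. Region reduction keeps an alignment on
any ≥ 1 bp overlap with a target region (no mate rescue). Chunk planning
makes `ceil(n/chunk_size)` chunks and, over a node cap, merges them into
groups differing by at most one chunk granule.

Callset comparison matches on (contig, position, ref, alt) — *site and
alleles, not genotype* — because the question an early pulse answers is
"is this variant real", not "is its genotype final"; genotype agreement is
reported separately. Ts/Tv counts transitions (A↔G, C↔T) among SNVs only;
het/hom counts the designated sample's non-reference calls; the het:hom
ratio is reported as unset when either count is zero (a degenerate callset
has no meaningful ratio). Known-sites concordance is the fraction of SNV
calls present in a provided catalogue.

## Sample QC

Sex inference uses the fraction of heterozygous calls among a sample's
non-reference X genotypes (< 0.10 → male, > 0.25 → female, needing ≥ 20
informative sites) with an optional X:autosome mean-depth ratio (< 0.65 →
male, ≥ 0.85 → female). Genotype evidence takes precedence; two definite
but conflicting lines of evidence yield "unknown", as does insufficient
data — never an exception. The thresholds are configuration with
generous dead zones, not biology. Pseudoautosomal regions are excluded
only when a PAR BED is supplied; otherwise the whole X is used (documented
limitation — PAR heterozygosity in males slightly inflates the het
fraction). Relationship checks count sites where a child shares no allele
with a putative parent (e.g. child 1/1 vs parent 0/0) over autosomal
diploid sites with both genotypes known; X is skipped entirely so
father-son hemizygosity cannot masquerade as error. The default flag
threshold of 5% is far above sequencing-error expectations and far below
the ~25-50% rate an unrelated sample produces.

## Synthetic harness

The generator's defaults are the study conditions the rest of the package
is evaluated under: a 100 kb diploid genome (contigs of 40/30/30 kb, one
of them X), five panel stand-in genes with 4 × 150 bp exons (`PCCB`
autosomal-recessive and `PDHA1` X-linked with reduced penetrance anchor
the two clinical scenarios), 150 decoy SNVs (half heterozygous per
founder; half placed inside panel genes to emulate an exome-focused
workflow; 80% annotated with common MAFs 0.05-0.45, the rest rare),
error-free 2×100 nt paired-end reads from 350 bp fragments at 30× mean
autosomal depth. Fragments are sampled per haplotype copy, so a male's
single X naturally receives half depth. Families are built by whole-
haplotype transmission (no recombination), which makes them Mendelian-
consistent by construction; the causal variant is planted by placing
carrier alleles on the specific parental haplotypes the chosen model
requires, or by a post-transmission override for de novo models.

Decoys carry annotations directly (no population simulation): MAF,
consequence from position (exonic → synonymous/missense, intronic,
intergenic), at most one damaging prediction and never a loss-of-function
consequence — benign panel polymorphisms rarely show concordant damaging
evidence, and this guarantees the planted variant's rank-1 position is a
property of the scoring model rather than of a lucky draw. The causal
variant defaults to a missense consequence with two damaging predictions
and a conservation flag, matching the clinical scenarios emulated (both
anchor variants are nonsynonymous single-nucleotide changes). The
known-sites catalogue flags decoys as known and the causal allele as
novel; the acceptance computation evaluates final calls against all truth
variants.

The toy aligner seeds with exact 21-mers, extends ungapped allowing
mismatches up to max(2, 5% of read length), and genotypes from the pileup:
PASS requires depth ≥ 4; alternative fraction ≥ 0.8 calls hom-alt, 0.3-0.8
het. It is a harness with fixed constants so cross-pulse comparisons are
stable — not a reimplementation of a production caller. Because it is
ungapped, the generator emits SNVs only; indel-carrying VCFs are still
parsed, scored and model-annotated, but not simulated.

**What passing tests do and do not show.** The synthetic runs demonstrate
that the machinery is self-consistent: error-free reads at 30× reproduce
early-pulse calls in the final callset and recover truth genotypes almost
perfectly. They say nothing about real-genome complications — repeats and
mismapping, indels and realignment, base-quality miscalibration, GC
coverage bias, population structure in allele frequencies — all of which
sit upstream of this toolkit in a production pipeline. Problem sizes
(100 kb genome, 150 variants, 30×) were chosen so a full end-to-end run
completes in seconds on one core while every per-site behaviour of the
caller is still exercised; the uniform random decoy alternative alleles
make the synthetic Ts/Tv ≈ 0.5 by construction, so that metric is reported
but not asserted against human-exome expectations (~2.8-3.1).

## Degenerate inputs and tie-breaks

Empty cycle lists, empty panels, empty region sets, zero-length contigs,
fragments longer than contigs, infeasible causal model/pedigree
combinations and unscored variants in the ranked writer are errors with
named causes. Zero reads give an empty callset; an empty early callset
gives an unset concordance rate; a pedigree with no genotyped parent-child
pairs gives an empty QC result with a warning. All orderings (ranked
lists, emitted files, compound pairs) are total and deterministic.
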