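# Methods

## Coordinate and strand model

All positions are 1-based and inclusive on the heavy (H) strand of the
circular mitochondrial genome, matching `m.<pos>` notation; arithmetic wraps
modulo the genome length (16,569 b for the bundled human map), so the
control region is annotated as a single wrapping feature (16024..576) and
positions 16093 and 73 both resolve to it. Features come from a versioned
TSV of the standard human gene map (gene, start, end, strand, feature
class); users can substitute their own. Where annotations overlap (e.g.
MT-ATP8/MT-ATP6, MT-TC/MT-TY), a position is owned by exactly one feature
under the fixed precedence tRNA > rRNA > protein-coding > control region,
ties broken by start coordinate — every position therefore maps to exactly
one gene, with an intergenic fallback for the few unannotated gaps. Light
(L)-strand genes are read off the complementary strand: a variant stated
`T>C` on the H strand is reported `A>G` in gene notation, and gene offsets
count from the feature's rightmost coordinate leftward.

N bases are tolerated in samples (sequencing inputs may be incomplete) but
rejected in references, which must be total.

## Variant model and extraction

A variant is a substitution, short insertion, or short deletion in reference
orientation. The table dialect writes `ref-alt` (`T-C`); an insertion is an
extended alt anchored on the first base of the run it duplicates (`310
C-CC`). Extraction diffs two complete genomes linearized at the same origin
with a deterministic anchored scan: mismatches are emitted per position
(adjacent substitutions stay separate calls, which is what lets dense
clusters like 13753/13754 be reported as two events), while an indel of ≤ 5
bases is called only where the sequences re-synchronize over a clean 10-base
flank, then left-normalized through repeat runs. The extracted set is
verified by round-trip — re-applying it must reproduce the sample exactly —
and inputs violating the isolated-variant model raise an ambiguity error
rather than guessing. An exact pairwise-alignment formulation (edit-distance
path) was considered and rejected: on realistic variant tables the optimal
edit path can trade clustered complementary substitutions plus a distant
insertion for a cost-equal insertion/deletion pair placed inside the
cluster, silently changing the call representation.

Coding effects are computed from sequence under the vertebrate mitochondrial
genetic code (NCBI table 2; notably ATA = Met, so `CTA>ATA` is Leu→Met):
silent when the codon translation is unchanged, missense with a
`RefPosAlt`-style three-letter annotation otherwise. Indels in coding
regions, variants in incomplete terminal codons, and stop gain/loss are
classified `other` and excluded from silent/missense tallies. Homoplasmy is
a carried flag, not inferred — the pipeline has no read-level data.

## tRNA cloverleaf and conservation index

The cloverleaf is fixed in canonical tRNA numbering with stem pairs
(1–7)/(72–66), (10–13)/(25–22), (27–31)/(43–39), (49–53)/(65–61); position
30 pairs with 40, the anticodon occupies 34–36. Multi-species alignments are
block-structured: one column per domain, each block anchored at the
canonical number of its first column. Stem blocks must be fixed-width across
species (this is what makes column-wise statistics well defined, and is
asserted at parse time); loop and variable-region blocks are left-aligned
and may be ragged, and mitochondrial tRNAs shorter than the canonical 76-mer
simply skip canonical numbers (the bundled human tRNA-Cys covers D-loop
positions 14–16, skipping 17–21). Genome positions convert to canonical
numbers through the gene-strand offset plus this human block layout; m.5802
is sequential base 25 of the 66-base gene and canonical position 30.

CI at a position is 100 × (non-human species carrying the human base) /
(non-human species compared). Policy choices: a gap or missing base in a
non-human row counts as a mismatch (the denominator is all compared rows); a
gap in the human row leaves CI undefined at that position — reported absent,
never zero — because the statistic is anchored on the human wild-type base;
with zero comparison rows a defined position is trivially 100% conserved.
The human row can be included via a flag, but the default excludes it since
including it can only inflate the index. Computed from the bundled
17-species alignment as printed, CI at position 30 is 15/16 = 93.75% — one
lemur row carries G there — which clears the 75% screening threshold; the
package reports the computed value rather than forcing full conservation.

## Pathogenicity screen

Criterion thresholds (<1% control frequency, >75% CI) are strict
inequalities and configurable. Criterion 3 is operationalized as
stem-paired-or-anticodon-loop membership in the cloverleaf — the computable
core of "potential structural alteration"; molecular-dynamics evidence is
out of scope. Verdict logic: any failing criterion ⇒ not a candidate; all
three passing ⇒ candidate; otherwise (an input unavailable, e.g.
conservation for a non-tRNA variant) ⇒ indeterminate. This makes the verdict
monotone — worsening one criterion can never promote a variant — and encodes
honestly that structure is only evaluated for tRNA variants.

Fisher's exact test (two-sided) is computed by summing hypergeometric
probabilities of all tables with the observed margins whose probability does
not exceed the observed table's, with a 1e-7 relative slack for
floating-point ties (the convention used by standard statistical software);
the test suite cross-checks it exhaustively against a direct enumeration
oracle for all tables with margins ≤ 12 and against an independent library
implementation.

## Haplogroup matching

Haplogroups are scored as the fraction of their defining markers present in
the sample's variant set, ranked descending with lexicographic tie-breaks.
This flat set-concordance model deliberately omits tree walking and
back-mutations; the bundled marker file is demo-only (a handful of
well-known lineage positions) and is not a curated phylogeny.

## Clinical and pedigree computations

BMI = weight kg / (height m)², reported to one decimal with
round-half-away-from-zero, matching the precision of printed clinical
tables; subject records validate their stated BMI against the recomputation
at that precision. Obesity classes come from user-supplied age–sex
percentile cutoff files (the bundled one is demo-only): strictly above the
99th percentile is severe obesity, above the 95th obesity, above an optional
85th-percentile column overweight. A missing age band returns
`unclassified`, never a silent adult default. Pedigrees are child→mother
maps with affected and carrier flags; maternal links must be acyclic, and —
because a homoplasmic mtDNA variant transmits deterministically — every
carrier's in-pedigree mother must be a carrier, which is validated at
construction. The matrilineal summary counts affected members over the
proband's matriline (everyone sharing the proband's founding matriarch
through mother links) and reports the penetrance fraction.

## Synthetic data

Generators are pure functions of (config, seed), with one independent seed
stream per sub-generator so adding one never perturbs another. Defaults
encode the study conditions: a 16,569 b genome, 106 controls with candidate
carrier frequency 0, a 17-species alignment, per-column match probability
0.75 where unspecified.

The surrogate reference is random DNA made consistent with a supplied
variant table — it is a synthetic stand-in, not the GenBank rCRS record. Ref
alleles are pinned at every tabulated position; the human tRNA-Cys gene
sequence is embedded (reverse-complemented) at the MT-TC locus so strand
conversion and cloverleaf mapping run against real gene content; the base
left of an insertion anchor is forced to differ from the inserted run so
indel placement stays unambiguous; and codon contexts at coding variant
sites are solved from the table's silent/missense annotations under the
mitochondrial code (first satisfying codon in lexicographic order, with
multiple constraints resolved jointly when two variants share a codon).
Classification from the surrogate's sequence therefore reproduces the
table's annotations by construction of the *inputs*, while still exercising
the full sequence-level classification path. What passing tests on this
surrogate do **not** show: correctness of codon contexts elsewhere in the
real genome, behavior on heteroplasmy or read-level noise, or structural
variation — none of which the pipeline models.

Control cohorts carry the haplogroup backbone with probability 1 by default
(a regionally matched cohort) and the candidate at the configured frequency;
carrier counts are Binomial(n, freq). Pedigree genomes implement strict
maternal transmission of a homoplasmic variant: carrier members receive
backbone + candidate, everyone else backbone only, so siblings of one mother
have identical mtDNA. Generated alignments reuse the human block layout and
draw each non-human base to match the human one independently with the
domain's match probability — real alignments have phylogenetic correlation
between species, which the generator does not model; parameter-recovery
tests therefore check the binomial statistics of the generator, not
evolutionary realism.

## Problem sizes and numerical choices

The test suite runs desk-scale by design: round-trip properties use 200
random 800-base genomes, the Fisher cross-check enumerates all 2×2 tables
with margins ≤ 12, conservation parameter recovery uses 17-species
alignments at match probabilities 0.5/0.75/0.9 with a 3-standard-error
band over 42 stem columns, and maternal propagation is checked on 100
random pedigrees of 3–15 members. End-to-end screens run the full 16,569 b
genome with 106 controls. The whole suite completes in a few seconds.

## Known limitations

- No heteroplasmy quantification, read-level (FASTQ/BAM) processing, or
  structural variants; variants are desk-scale point events.
- Circularity is handled in coordinates and wrapping features, but sample
  and reference are assumed linearized at the same origin; rotated
  assemblies must be re-anchored first.
- Haplogroup calling is illustrative set matching, not Phylotree-based.
- The structural criterion is a topological proxy (stem/anticodon-loop
  membership); it does not assess thermodynamic stability.
- Criterion 3 is undefined for non-tRNA variants, which can therefore at
  best be indeterminate — the screen is a tRNA-variant filter with
  frequency/conservation support for the rest.
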