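# Methods

## Model

A structural variant (SV) locus is genotyped from `D` covering long reads.
Read `r` supplies an allele observation `X_r ∈ {0, 1}` and a probability
`p_r` of originating from haplotype 1, produced upstream by SNP-based
pre-phasing (which parent is "haplotype 1" is arbitrary per phase set; the
likelihood is invariant under `p_r → 1 − p_r`, so no reconciliation across
phase sets is needed or attempted). For a phased genotype `H = (H1, H2)` the
likelihood is the product over reads of the two-component haplotype mixture
`p_r·P(X_r|H1) + (1−p_r)·P(X_r|H2)`, with emission `P(X_r|H_h) = 1 − e` on
match and `e` on mismatch. The unphased genotype `G ∈ {0, 1, 2}` collapses
the four phased configurations, with the heterozygote as the equal mixture of
`(0,1)` and `(1,0)`. Posteriors use a uniform prior; `GQ` is the Phred scale
of `1 − max GP`.

Assumptions worth stating: reads are conditionally independent given the
phased genotype; `e` is one global scalar — not per-read, not
quality-dependent, not estimated from data; the prior over genotypes is
uniform (no population allele-frequency information); loci are bi-allelic
(reference vs one SV allele). Multi-allelic sites, non-uniform priors and
data-driven `e` are out of scope.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `e` | 0.01 | probability | per-read SV-assignment error; must lie in (0, 0.5) |
| `window` | 500 | bp | max distance between an indel signature and the SV position |
| `size_sim` | 0.7 | ratio | min `min(l1,l2)/max(l1,l2)` between signature and SV length |
| `min_flank` | 100 | bp | alignment overhang required on both sides for a reference call |
| `min_mapq` | 20 | Phred | minimum mapping quality for any observation |
| `min_siglen` | 30 | bp | minimum CIGAR indel length to seed a signature |
| `merge_dist` | 500 | bp | same-type signatures on one read closer than this merge |

The assignment defaults mirror common long-read SV-caller conventions; they
are configurable on every CLI and constructor. GQ is an integer
(`floor`, capped at 99 — the VCF convention for the `GQ` FORMAT field).
Argmax ties break toward the smaller genotype, so a locus with no covering
reads is emitted (forced calling never drops records) as `0/0` with the flat
posterior's GQ of 1 and `DP=0`; consumers should filter on depth or GQ
rather than expect missing genotypes.

## Read assignment

Only intra-alignment (CIGAR) evidence is used: each I/D operation of at
least `min_siglen` bp becomes a signature (deletions at their reference
start, insertions at the anchor base), and same-type signatures within
`merge_dist` are merged by summing lengths at the length-weighted mean
position — this recovers SVs that the aligner fragments into nearby smaller
operations. A read supports the SV allele when a same-type signature lies
within `window` bp of the SV at a size ratio ≥ `size_sim`; it supports the
reference only when it has no such signature *and* spans the locus with
`min_flank` bp on both sides; anything else is unassigned and excluded from
`D`. (Including unassigned reads as reference evidence would bias hom-ref
calls at long SVs; exclusion was chosen, and the interface also accepts
externally produced observation tables so a different assigner can be
swapped in.) Split-read and soft-clip evidence is not used, so SVs much
longer than the read length will be under-assigned — a documented
limitation; duplicate, QC-fail, secondary and supplementary alignments never
contribute.

Coordinates: VCF `POS` is 1-based and addresses the base before a symbolic
event, so the event's 0-based start equals `POS`; all internal arithmetic is
0-based half-open and the conversion happens exactly once, at VCF read.

## Phasing input

Probabilities are consumed as given and never thresholded — a read phased at
0.6 contributes weakly informative evidence rather than being dropped. Reads
absent from the phase map default to the uninformative 0.5; with every read
at 0.5 the genotyper is bit-identical to the standard no-phase binomial
model, which is also the exact behavior of `hard_tag_confidence = 0.5` for
haplotag input.

## Evaluation statistics

Discordance is the fraction of calls differing from a truth set matched by
exact record identity (CHROM, POS, ID — forced calling guarantees shared
records). Ranked comparisons take the top-N calls by GQ; because many calls
tie at the boundary GQ, the last bin is filled by seeded uniform sampling
without replacement, so any N is reachable and results are reproducible per
seed (and seed-independent when N equals the number of calls). Missing calls
are never counted as discordant; the retained call rate is reported
alongside. Neighbor counting uses interval gap ≤ radius (default 1000 bp)
with insertions as points — a fixed, brute-force-tested definition.

Trio patterns: the 27 ordered parent/parent/child genotype triples collapse
to 10 canonical classes after sorting the parents and polarizing to the
trio's minor allele (flip all genotypes when the trio carries more than 3 of
its 6 alleles; an exact tie keeps the lexicographically smaller orientation —
any deterministic tie rule yields the same 10 classes). Mendelian errors are
patterns unreachable by transmitting one allele per parent, verified against
brute-force enumeration of the 2×2 transmissions. Mendelian error is a lower
bound on genotype error — two heterozygous parents can never produce one —
so rates are also stratified by parent class: same-allele homozygous ("00",
where any non-matching child is an error but het-parent errors hide),
discordant homozygous ("02", where any non-het child is an error), and
heterozygous-involved (everything else). Trios with any missing genotype are
excluded from pattern counts and reported via the call rate.

## Simulator

The generator emulates exactly the statistical structure the model assumes:
Hardy–Weinberg genotypes at a population SV-allele frequency (default 0.3,
typical of a polymorphic SV panel), Mendelian transmission for trios,
Poisson read depth per SV (default mean 10, matching routinely generated
long-read cohort data), per-read allele-observation error (default 0.01),
and a phasing-informativeness model: the reported probability favors the
read's true haplotype with probability `phase_quality` and has magnitude
`0.5 + 0.5·Beta(phase_sharpness, 1)` — `sharpness = ∞` gives exact 0/1
probabilities (perfect phasing), `0` collapses to 0.5 (uninformative).
Randomness is one stream per scenario split deterministically per SV, so
output is reproducible and independent of processing order.

BAM fixtures are synthesized at the alignment level: reads carry explicit
CIGARs (carriers get the D/I operation at the planted event, reference reads
are pure matches over random sequence), spaced SVs alternate DEL/INS with
lengths 50–200 bp, 5 kb apart, read length 2 kb with at least 300 bp of
flank. No aligner is invoked. What this does *not* emulate: base-level
sequencing error, alignment ambiguity in repeats, clustered/nested SVs,
reference bias, chimeric reads, or realistic read-length distributions.
Passing tests therefore demonstrate correctness of the genotyping and
evaluation machinery under the model's own assumptions, not performance on
real data.

Experiment problem sizes: the recovery experiments run 2,000 SVs at mean
depths 5–30 with depths coupled by Poisson thinning (one read stream per SV
at the maximum depth, nested subsets below), which makes the depth
comparison a matched-pairs design; the phasing comparison genotypes the same
read cores twice (exact 0/1 probabilities vs all-0.5). These sizes give
sub-percent standard errors on the discordance estimates while keeping the
whole suite in seconds.

## Numerical choices

Natural-log space throughout; the heterozygote's ½-mixture and the per-read
mixtures use stable log-sum-exp forms; GLs are reported as log10 normalized
to max 0 and `PL = round(−10·GL10)` with minimum entry 0. `GP` sums to 1
within 1e-9 up to D = 10,000. Under uninformative phasing the heterozygous
likelihood equals 0.5^D — exactly in real arithmetic, to a few ulps
(≲ 1e-15 relative) through the log/exp path. Degenerate inputs: empty
observation sets are legal (flat GLs); `e = 0` is accepted at the emission
level (likelihoods may hit −inf) but `ErrorModel` requires 0 < e < 0.5;
probabilities outside [0, 1] in a phase table are hard errors, duplicate
read ids keep the last entry with a warning.

## Known limitations

- Only deletions and insertions are genotyped; other SVTYPEs pass through
  with missing genotypes.
- Assignment is CIGAR-only; very long SVs relative to read length are
  under-assigned.
- `e` is global; no per-read or per-base-quality error modelling.
- Uniform genotype prior; no population or pedigree information enters the
  likelihood.
- Output GTs are unphased even though phasing informed the likelihood —
  emitting phased GTs would require cross-SV phase-set bookkeeping the model
  does not define.
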