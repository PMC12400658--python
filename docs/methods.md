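# Methods

## The estimator

Per-site differentiation uses the Weir & Cockerham (1984) analysis of
variance for r = 2 populations.  With called diploid sample sizes
n₁, n₂, ALT frequencies p₁, p₂ and heterozygote proportions h₁, h₂, define
n̄ = (n₁+n₂)/2, n_c = 2n̄ − (n₁²+n₂²)/(2n̄), p̄ = (n₁p₁+n₂p₂)/(2n̄),
s² = [n₁(p₁−p̄)² + n₂(p₂−p̄)²]/n̄ and h̄ = (n₁h₁+n₂h₂)/(2n̄).  Then

    a = (n̄/n_c) · [ s² − (1/(n̄−1)) · ( p̄(1−p̄) − s²/2 − h̄/4 ) ]
    b = (n̄/(n̄−1)) · [ p̄(1−p̄) − s²/2 − ((2n̄−1)/(4n̄))·h̄ ]
    c = h̄/2

F_ST over any site set is Σa / Σ(a+b+c) — the ratio of averages, which is
the standard windowing choice and what sliding-window packages in this field
compute.  One estimator serves windows and the genome-wide value alike, so
the two are always self-consistent.  Negative per-window values are reported
as computed (the upper-tail selection never sees them); the estimator is
undefined when a population has no called genotype or the mean sample size
is ≤ 1, and such sites are excluded upstream.

All allele frequencies, heterozygote proportions and fixation tests are
evaluated over *called* alleles only.  Missing-data policy: each frequency
denominator uses called samples; the diverged-SNV test additionally demands
`min_called` (default 5) called samples per population, so near-empty
genotype columns cannot produce spurious fixation calls.

## Windowing conventions

Windows are 10 kb advanced by 1 kb (both configurable), anchored at
position 0 of each scaffold, half-open `[start, start+window)`, and only
full windows are formed (`start + window ≤ scaffold length`).  Scaffolds
must be strictly longer than 10 kb to be scanned; windows never span
scaffolds.  Windows with no polymorphic site (denominator zero) are
dropped rather than reported as 0/0.  Selection takes k = ⌈q·N⌉ windows by
descending F_ST (nearest rank); ties at the threshold are all included.
The genome-wide estimate ignores the scaffold-length filter and sums over
every retained site.

"Adjacent" in HDR merging means gap = 0 in half-open coordinates
(book-ended intervals merge).  With a 1 kb step and 10 kb windows,
consecutive selected windows always overlap, so this choice only matters
across an unselected stretch; it is the smallest faithful reading of
merging "adjacent and overlapping" windows.  Merging is transitive,
idempotent and order-invariant, and each HDR carries its member windows and
contained diverged SNVs.

## Filtering

Hard filters default to the canonical GATK SNV set — QD < 2.0, FS > 60.0,
MQ < 40.0, SOR > 3.0, MQRankSum < −12.5, ReadPosRankSum < −8.0 — and every
threshold is overridable, since published pipelines routinely apply "minor
modifications" without stating them.  A site lacking an annotation is never
removed for that annotation (rank-sum statistics are genuinely absent at
sites without heterozygous calls).  The depth rule masks individual
genotypes, not sites: a call is kept iff DP > 3 (i.e. `min_dp = 4`), and a
site is dropped only when a population loses all of its called genotypes.
Hard filters and the depth mask commute on the surviving sites.

## Effect annotation

A genomic SNV is mapped into the spliced, strand-oriented CDS (minus-strand
genes reverse-complemented, the first transcribed segment's phase trimmed),
the affected codon is substituted and both alleles are translated with the
standard code.  The implementation is validated against an oracle that
mutates the whole genome, re-splices and re-translates, on both strands and
across multi-exon genes.  The VCF REF base must match the reference FASTA
at the site; a mismatch aborts, because it indicates a coordinate or
assembly inconsistency rather than a biological signal.  SNVs inside the
gene span but outside the CDS are reported as noncoding, or flagged as
splice-region when within 2 bp of a CDS boundary on the intronic side.

Consensus CDSs substitute one sample's genotypes into the reference CDS:
hom-ALT → ALT base, heterozygote → IUPAC two-base code, missing →
reference base (logged).  Pairwise divergence is the p-distance with
pairwise deletion — sites where either base is not a plain A/C/G/T are
excluded — so heterozygous consensus positions do not count as
differences; this is conservative and is the default distance family for
near-identical coding sequences.  A Jukes–Cantor correction is available
(`divergence(..., model="jc")`) but at divergences of order 10⁻³ it is
indistinguishable from p.

## Candidate genes and expression

A gene is a candidate iff its span (introns and UTRs included; `cds_only`
narrows to CDS) contains at least one diverged SNV lying inside an HDR.
Homology-hit filtering keeps, per query, only the top hit by bit score and
only if it has e-value ≤ 1e−30 *and* identity ≥ 90%.  The e-value
inequality is implemented as ≤ (a lower e-value is a stronger hit); both
thresholds are arguments.

TPM_g = 10⁶ · (c_g/L_g) / Σ_j (c_j/L_j) per condition, with gene length
taken as the spliced CDS length from the GFF3 (effective-length modelling
is out of scope).  "Expressed" means TPM > 0 (configurable).  The rank
percentile is 100 · (#expressed genes with strictly greater TPM) /
(#expressed genes): the top gene is at 0, ties share a percentile, and
"under 50" selects the upper half — consistent with a moderately high gene
reporting percentiles in the 20–40 range.  The screen flags a gene under
the cutoff in ≥ 1 condition and is monotone under count increases.

## The synthetic-data generator

The generator emulates the study design the scan assumes: two diploid
populations (defaults 11 and 14 samples), several scaffolds including one
at or below the 10 kb cutoff, one SNV per ~200 bp, and background
differentiation F = 0.10.  Background sites follow the Balding–Nichols
model — ancestral frequency uniform on [0.05, 0.95] (avoiding a
monomorphic-site excess), population frequencies Beta(p(1−F)/F,
(1−p)(1−F)/F), genotypes Binomial(2, p_pop) — because the scan only needs a
controllable stationary F_ST, not a demographic history.  Sites that come
out monomorphic across all samples are rejected and resampled.  Planted
regions place SNVs on a 1/density grid in two modes: `fixed_difference`
(population B hom-ALT, population A hom-REF) and `fixed_with_het`
(population B hom-ALT, a fixed 20% of population A heterozygous), both of
which satisfy the diverged-SNV criterion by construction.  Gene models are
multi-exon, on both strands, anchored over planted regions first; their
coding sequence is written back into the reference (start codon, no
internal stops), which is why gene models are generated before genotypes
are drawn — REF alleles must agree with the final FASTA.  Per-genotype
depth is 4 + Poisson(mean−4) with a 2% low-depth fraction drawn uniformly
from {0..3}; 2% of background sites fail exactly one hard-filter criterion
(planted at background sites only, keeping filter truth separable from
divergence truth); 10% of passing sites lack rank-sum annotations;
per-genotype missingness is 1%.  Expression counts are negative binomial
(size 5) around lognormal gene means with mild per-condition jitter.
Every stage draws from a labeled child stream of one master seed, so adding
a stage never shifts another stage's draws and all outputs are
byte-reproducible.

What the generator does *not* emulate: linkage and recombination (site
placement is positional only), demographic history, read-level artifacts
(mapping bias, allele dropout), indels, and genuinely correlated
quality-annotation failures.  Passing the planted-recovery tests therefore
demonstrates the pipeline's correctness and sensitivity under the assumed
sampling model, not its behaviour on real short-read data.

## Validation problem sizes and the selection fraction

The parameter-recovery check uses ~20,000 background sites (4 Mb at 1/200)
over 10 seeded replicates; measured genome-wide estimates at F = 0.10 fall
within ±0.003 per replicate, well inside the ±0.03 acceptance band.  The
planted-recovery experiment uses a 5 Mb genome (five 1 Mb scaffolds,
~4,955 windows) with ten 2 kb planted regions, which overlap ~110 windows
(~2.2% of all windows).  At the scan's headline top-0.1% selection,
⌈0.001·4955⌉ = 5 windows would be selected — arithmetically incapable of
covering ten regions — so the validation run sets the selection fraction to
0.02, matching the planted-truth geometry; every other parameter keeps its
default.  On real genomes (hundreds of Mb) the 0.1% default is the
appropriate scale.  The small README fixture (~98 windows, two planted
regions spanning ~22 windows) uses 0.15 for the same reason.

## Known limitations

* Two populations only; the variance components are specialized to r = 2.
* Gene length for TPM is the spliced CDS length; UTR-aware effective
  lengths would shift TPMs slightly but not ranks within a condition.
* Multi-transcript genes are annotated per transcript; the candidate rule
  deduplicates by gene id.
* Indel genotyping and structural variation are out of scope; the
  consensus-CDS machinery substitutes SNVs only.
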