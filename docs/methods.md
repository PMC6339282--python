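# Methods

This note documents the statistical model, conventions and design choices
behind `a3pop`, and what the synthetic data can and cannot demonstrate.

## Data model and coordinates

All positions are 1-based nucleotides within a transcript's coding sequence
(CDS), so the four genes are handled identically and strand never enters.
Genotypes are unordered ref/alt allele pairs stored as alt-allele dose
(0/1/2, −1 missing); phase separators in VCF input are accepted but phase is
discarded, because the genotypes this package targets come from short-read
calling and are effectively unphased. Multi-allelic records are rejected at
ingest (split them upstream, e.g. `bcftools norm -m-`); the study's loci are
all biallelic per row, with the adjacent T238A/T238I substitutions kept as
separate variants. The A3H N15 deletion is modelled as a biallelic indel —
ref allele `CAA`, alt allele `-` — whose annotation reports an in-frame
deletion of one asparagine. Per-gene cohort sizes are defined as samples
with at least one non-missing call in the gene (168/154/165/133 of 192 in
the study data).

### CDS fixtures

The package does not redistribute the Ensembl transcripts. Instead it
constructs synthetic CDS sequences that carry the study's reference codons
at the correct codon numbers and a neutral alanine codon everywhere else
(the A3H deletion site gets an `AAC AAC` context so that removing `CAA` at
CDS 45–47 deletes one asparagine in frame). Coding-effect annotation only
ever reads the affected codons, so these fixtures are exact for every
annotation the pipeline produces; they are synthetic everywhere else and
must not be used as real transcript sequence. Transcript IDs are carried as
metadata only.

## Hardy–Weinberg testing

The test is the classical chi-squared goodness of fit of the three genotype
classes against (p²n, 2pqn, q²n), df = 1, no continuity correction and no
pooling of small expected classes. This convention reproduces the study's
printed A3D/A3F/A3G statistics exactly (4.02, 7.04, 6.09, 0.73, 0.20,
0.001, …), including rows with expected homozygote counts well below 5 —
where the chi-squared approximation is poor as a test but is what was
computed. A Yates-corrected variant exists behind a flag, default off.
Monomorphic sites return X² = 0, p = 1 and a `monomorphic` flag. The
published A3H statistics do not reproduce from the published genotype
counts under any single-df convention (e.g. the N15 deletion's counts give
7.27, not 10.25); they are treated as unverifiable and excluded from exact
checks. Internal values are never rounded; report output rounds half away
from zero (1 dp frequencies, 3 dp statistics).

An exact (enumeration-based) HWE test is deliberately out of scope: the
goal is faithful reproduction of the chi-squared pipeline, not the best
available test.

## Cross-population comparison

Cohort allele counts are compared to a reference panel in a 2×2 table. The
two-sided Fisher p-value is the point-probability convention — the sum of
probabilities of all tables with the observed margins no more probable than
the observed table — which is the convention of common online calculators;
mid-p and doubled one-tail variants give different numbers. Panels larger
than 10 000 chromosomes (ExAC-sized) use the Pearson chi-squared test
instead; the cutoff splits the study's six panels exactly as published.
Published panels give only percentages and 2n, so allele counts are
reconstructed by half-away-from-zero rounding; the reconstructed table is
reported next to each p-value and exact counts override it when supplied.
Significance is flagged at p ≤ 0.05 with no multiple-testing correction —
a faithful-reproduction choice, not a statistical endorsement; apply your
own correction to the emitted p-values if you need one. The asymptotic and
exact tests agree closely only with hundreds of observations per cell
(measured: ~10% relative at cells ≥ 200 and p ≥ 0.05; up to ~50% at cells
of 20–200), which is why the large-panel/chi-squared split is by panel
size, not convenience.

## Linkage disequilibrium and EM phasing

For a variant pair, samples non-missing at both loci form a 3×3 genotype
table. Two-locus haplotype frequencies are estimated by EM: every genotype
class except the double heterozygote contributes gametes of known phase;
the double heterozygote splits its two gametes between coupling (AB/ab) and
repulsion (Ab/aB) in proportion to the current estimates. Convergence is
declared when the log-likelihood changes by < 1e-8 (max 1000 iterations;
non-convergence is flagged, not raised). EM is restarted from three
deterministic points — linkage equilibrium at the observed allele
frequencies and the two extreme phase assignments — and the best likelihood
wins, ties resolved toward the earlier start. The extra starts matter: the
likelihood can have two maxima, and on small tables the equilibrium point
is occasionally itself a stationary saddle where a single-start EM stalls
(an all-double-heterozygote table is the extreme case: the tied global
maxima are full coupling and full repulsion, and the deterministic
tie-break returns the coupling family).

From the estimated frequencies: D = f_AB − p_A·p_B; D′ = |D|/D_max with
D_max = min(p_A q_B, q_A p_B) for D > 0 and min(p_A p_B, q_A q_B)
otherwise; R² = D²/(p_A q_A p_B q_B); and a goodness-of-fit chi-square
X² = R²·n over n = 2 × complete samples, tested at df = 1. LD is undefined
(raised) at monomorphic loci. The study's printed LD values (D′ = 1,
R² = 0.122 for rs61748819–rs184448269 genome-wide; R² = 0.108 for
H186R–Q275E in AFR) were computed on 1000 Genomes phase-3 haplotypes; to
reproduce them, download the phase-3 panel, extract phased haplotypes at
the two rsIDs for the population of interest, and feed the four haplotype
frequencies to `ld_from_haplotypes`. This is intentionally a documented
recipe, not a packaged test — no network data ships with or is fetched by
the package. The study's LD report threshold "> 0.1" does not name its
statistic; reports flag pairs by R² > 0.1 and always print D′ alongside.

## Haplotype assignment and A3H stability

Assignment sites per gene are the nonsynonymous variants with MAF ≥ 5%,
with three configured adjustments that mirror the study's actual site
choices: A3D keeps T238A (MAF 4.2%); A3F uses the full printed site list
48/78/87/108/231/307; A3H always uses the five canonical sites
(15, 18, 105, 121, 178) and never 140 (K140E is fixed hom-alt in every
panel and treated as a probable reference-genome error). Novel variants
(no rsID) are never assignment sites.

With unphased genotypes, a sample heterozygous at ≤ 1 assignment site has a
uniquely determined haplotype pair (*confirmed*); ≥ 2 heterozygous sites
leave phase ambiguous (*unconfirmed*, no pair reported — statistical
phasing is out of scope). Samples whose only non-reference calls are at
excluded sites are *other*; a missing call at any assignment site is
*no_call* and drops the sample from both numerator and denominator (the
study reported only whole-gene failures, so this is slightly stricter).
Confirmed combinations outside the shipped named tables (reference
combination `i` plus the study's printed combinations, and A3H II/III/IV/X)
mint deterministic labels from the allele pattern (`novel-0101`), so labels
never depend on processing order.

A3H haplotype stability: II, V and VII are stable (long protein half-life,
HIV-1-restricting); I, III, IV, VI and any haplotype carrying the N15
deletion are unstable; everything else is unknown. Per-sample stability is
resolved by enumerating every phase configuration consistent with the
genotypes: when all configurations give the same number of stable
haplotypes, that number (0/1/2) is reported — notably every deletion
homozygote is 0-stable regardless of phase — otherwise "unknown".

## Synthetic cohorts: what they emulate and what they do not

`simulate_cohort` draws two haplotypes per sample per gene from configured
haplotype frequencies — independently with probability 1−F, identical by
descent with probability F (Wright's inbreeding coefficient, the single
HWE-deviation knob) — and emits unphased genotypes, with whole-gene
missingness applied per sample and the hidden truth (haplotype identities)
written to a sidecar. Defaults are the study's conditions: 192 samples,
whole-gene failure rates 24/192, 38/192, 27/192, 59/192, and haplotype
frequencies composed from the cohort's allele frequencies (A3D i/ii/iii/iv
= .786/.062/.042/.110; A3F i/iii/iv/vi = .574/.176/.049/.201; A3G
i/ii/iii/iv = .399/.370/.179/.052; A3H i/ii/iii/iv/x =
.050/.352/.300/.060/.238, putting the deletion-carrying haplotypes at
0.598). The generator draws haplotypes at the assignment sites only and
does not simulate sequencing error, per-site missingness, allelic dropout
or recombination; passing tests on simulated cohorts therefore demonstrate
the statistical machinery under clean genotypes, not robustness to calling
artifacts.

Two deterministic fixture families reconstruct the study's printed tables.
`tally_cohorts()` reproduces every per-variant genotype tally exactly,
using a block layout (rotated per variant for A3D/F/G; curated for A3H so
that all rare genotypes fall inside the deletion-homozygote block, making
the zero-stable count equal the 55 deletion homozygotes).
`category_cohorts()` expands the printed per-individual haplotype categories
sample by sample. Two families are needed because the published A3H
genotype tallies and per-individual categories are mutually inconsistent
(the categories imply 38 deletion-free homozygote individuals and at most
48 deletion homozygotes; the tallies say 29 and 55) — no single cohort can
match both, so each summary is computed on the fixture that defines it.
For A3D/F/G the per-variant tallies and the category tables also disagree
in detail (e.g. 19 R97C heterozygotes tallied vs 18 in the categories);
the block-layout family privileges the tallies and makes no claim about
multi-site structure.

## Numerical conventions and edge cases

* Rounding for report output is half away from zero; internal computation
  is never rounded.
* Degenerate Fisher margins (an empty row or column) define p = 1; zero
  margins under chi-squared raise with a pointer to the exact test.
* `maf_filter` uses a strict-< exclusion (MAF exactly at the threshold is
  kept), matching a "< 5% excluded" rule.
* All randomness flows through `numpy.random.default_rng(seed)`; same seed,
  same platform-independent integer draws, identical cohorts.
* EM tolerance 1e-8 on the log-likelihood, max 1000 iterations; the
  two-locus simulator rejects inadmissible D with the admissible interval
  in the message.

## Known limitations

* The chi-squared HWE test is anticonservative for rare alleles (expected
  classes < 5); this is inherited from the reproduced pipeline by design.
* Diplotype assignment does not statistically phase ≥ 2-het samples, so
  cohorts with long heterozygous site runs yield mostly "unconfirmed".
* Reference-panel counts reconstructed from rounded percentages can be off
  by ±0.5 counts per cell, which moves borderline p-values; supply exact
  counts where available.
* The A3F dual isoforms are handled by annotating against one transcript
  per variant; no splice-aware annotation is attempted.
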