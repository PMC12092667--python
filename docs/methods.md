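# Methods

This note documents the models, conventions and numerical choices behind
`beditscan`, and what its synthetic data do and do not emulate.

## Coordinates and target sites

Protospacer positions are 1-based from the PAM-distal 5′ end, with the PAM
3′ of the protospacer; "C10" is the tenth protospacer base. A
`TargetSite` pins the protospacer to an amplicon on either strand; base
calls are always reported on the protospacer strand (reverse-complemented
when the protospacer lies on the amplicon-reverse strand).

The Cas9n nick on the sgRNA-complementary strand sits between protospacer
positions `nick_offset` and `nick_offset+1`; the default `nick_offset = 17`
places it 3 bp 5′ of the PAM, the canonical Cas9 HNH cut. The
quantification window is centred on the protospacer base at `nick_offset`
and extends `window_halfwidth` (default 10) bases each way, so positions
~7–27 of a 21-nt protospacer are covered. Only events inside this window
affect classification.

The three built-in sites are synthetic stand-ins with the study geometry: a
reporter-like site whose window contains exactly one target C (fluorescent
reporters are codon-optimised to remove bystander cytosines), a HEK3-like
site with target Cs at positions 10 and 16 (C16 one base from the nick),
and an RNF2-like site with target Cs at 10 and 14, placed on the
amplicon-reverse strand so both orientations are exercised by default.
Real sites can be supplied through site files.

## Read simulation

`simulate_reads` draws category counts from a multinomial over a declared
outcome specification (e.g. 15.6% single C→T, 6.6% single C→G, 1.3% C→A,
2% indel, rest WT — the negative-control-like mix; the point-mutation
fractions are anchored to the study's non-targeting control efficiencies,
C→A is smallest because it is the least frequent outcome, and the indel
fraction matches the reporter's measured frameshift rate). Substitution
categories apply their base changes at the target C positions; the indel
category samples a deletion of 1–10 nt or an insertion of 1–3 nt
overlapping the window. Per-base substitution errors (default 0.1%) are
then applied uniformly; quality strings are constant Q30 because the
caller does not quality-filter. What is *not* modelled: PCR amplification
bias, paired-end structure and read merging, position-dependent error
profiles, and sequencing indel errors. Recovery tests on these reads
therefore demonstrate correctness of the calling arithmetic, not
robustness to real instrument artefacts.

## Outcome calling

Reads are globally aligned to the amplicon with affine gaps (match +2,
mismatch −3, gap open −10, gap extend −1; a gap of length L costs
10 + (L−1)). Equal-length reads with ≤4 mismatches take an ungapped fast
path, which is provably optimal with these penalties (any gapped global
alignment of equal-length sequences needs two gap openings, costing more
than four substitutions). Reads are marked unalignable below 0.6 of the
perfect score, with terminal-gap penalties discounted so a truncated but
clean read is judged on its aligned part; truncated reads that do not
cover the window are dropped and tallied separately.

Classification precedence inside the window: (1) any gap → indel (an
insertion abutting a window edge counts, since equivalent optimal
placements can shift an insertion along a repeat); (2) otherwise the base
calls at the target Cs form the allele key (`T@10|C@16`); (3) reads whose
only window substitutions are at non-target positions are tallied as
"other-edit" and excluded from the outcome taxonomy, on the view that an
isolated non-target substitution is most likely a sequencing error.
Conservation holds by construction: classified + other-edit + dropped +
unalignable = total input reads.

Absolute efficiencies are percentages of classified reads (the mutually
exclusive joint categories plus WT sum to 100); relative efficiencies are
percentages of edited (non-WT) reads and are reported as absent, not zero,
when nothing is edited. Indel reads count as edited by default
(`include_indels_in_edited=False` reproduces the alternative convention).
Per-position conversion marginals sum the joint categories containing that
conversion. Excluding other-edit reads shrinks the denominator slightly
(≈1.5% relative at 0.1% error over a 21-base window), a deliberate
consequence of keeping the taxonomy mutually exclusive.

## Screen simulation

`simulate_screen` models the sorted-population composition at the count
level rather than per cell. Per sgRNA *s* of gene *g*: a lognormal library
weight w_s (σ = 0.3) models cloning skew; the reporter-conversion
probability is π_s = min(1, π₀·effect(g)) with π₀ = 0.132, the baseline
GFP⁺ fraction of the study's screens; day-13 populations multiply
essential-gene sgRNAs by a dropout factor (default 0.3). Bulk counts are
NB(depth·w_s·d_s, α) with depth = 200 reads/sgRNA (the screen's minimum
coverage) and dispersion α = 0.05, a typical pooled-screen value; sorted
counts redistribute the same total depth proportionally to w_s·d_s·π_s.
The ground-truth expected sorted-vs-bulk LFC is log₂(π_s/π̄) with π̄ the
weighted mean conversion probability. The default library is 2015 genes ×
5 sgRNAs + 2243 non-targeting controls = 12,318 sgRNAs. Not modelled:
per-cell infection (MOI), FACS gate impurity, growth competition between
knockdowns beyond the essential flag, and replicate-specific batch
effects — so simulated replicate correlations are driven only by shared
library skew and essential dropout and are lower than in real screens.

## Enrichment testing

Normalization is median-of-ratios: each sample's size factor is the median
over sgRNAs (with positive geometric mean) of count/geometric-mean, and
size factors are rescaled to geometric mean 1, which makes the operation
idempotent without affecting any ratio. All-zero sgRNAs are dropped with a
logged tally; sgRNAs with a zero in any compared sample are removed before
testing.

The per-sgRNA test is the negative-binomial comparison in its exact
conditional form. If each replicate count is NB(m, α) with a shared
per-sgRNA abundance m, then given the treatment+control total the
treatment sum is BetaBinomial(total, n_t/α, n_c/α): the nuisance abundance
cancels and only the pooled dispersion α enters. α is fitted by maximising
this conditional likelihood over the non-targeting sgRNAs (falling back to
all sgRNAs, with a warning, below 10 controls). Two-sided p-values double
the smaller mid-p tail, the standard discreteness correction. The α → 0
limit is Binomial(total, n_t/(n_t+n_c)) — the classical exact two-sample
Poisson test — and is selected automatically when the fit collapses, or by
passing `dispersion=0`. We chose the conditional form over the common
plug-in "treatment count versus control-estimated mean" tail because the
plug-in version is measurably mis-calibrated (the control mean's sampling
noise correlates with the residual, and the plug-in NB skew does not match
the near-symmetric null): under simulated null screens the conditional
test's p-values are uniform by KS test, which the package treats as a
contract. The LFC reported alongside is log₂((treat+0.5)/(ctrl+0.5)) on
normalized counts, averaged over replicates.

Gene phenotype is the median LFC of the gene's surviving sgRNAs (mean of
the central pair for even counts).

α-RRA: sgRNAs are ranked in the tested direction (ties get average ranks,
which is deterministic and permutation-safe) and converted to percentiles
in (0,1]. For a gene with k sgRNAs and sorted percentiles r₍₁₎ ≤ … ≤ r₍ₖ₎,
only the k′ sgRNAs with r ≤ α (default α = 0.25) contribute, and
ρ = min over j ≤ k′ of P(Beta(j, k−j+1) ≤ r₍ⱼ₎), the probability that the
j-th order statistic of k uniforms falls at or below r₍ⱼ₎; genes with
k′ = 0 get ρ = 1. The permutation null redraws gene-sized percentile sets
from the full (sorted, hence row-order-invariant) pool, stratified by gene
size, with p = (1 + #{ρ_perm ≤ ρ_obs})/(1 + n_perm); when `exact=True` and
C(n,k) is small the null is enumerated exhaustively and p is the plain
fraction. Depletion and enrichment are separate one-sided analyses; the
primary contrast is sorted vs bulk+dox. BH-FDR is applied across genes per
direction. Note the designed conservatism of the α screen: under the null
a 0.75⁵ ≈ 24% fraction of 5-sgRNA genes has no contributing sgRNA and
receives p = 1, so gene-level p-values are uniform only with the screen
disabled (α = 1) — the calibration contract is stated that way.

Screen QC reports the median day-13-vs-day-0 LFC of essential versus
non-targeting sgRNAs and the Pearson r between replicate LFC vectors,
flagging r < 0.7.

## Validation statistics

z-scores use Eq. z = (x − μ)/σ with μ, σ from the pooled negative-control
efficiencies (all NC sgRNAs × replicates; at least 3 values required).
σ is the sample SD (ddof = 1) by default and exposed as a flag — the
convention is not fixed by the underlying formulas, and the printed worked
examples are insensitive at one-decimal precision. |z| > 3 (strict) flags
a strong effect. The replicate-adjusted z-score is |mean(z)| − σ(z), with
tiers ns/*/**/*** at 1.5/2/3; the thresholds' boundaries are assigned to
the higher tier (≥2 → **, ≥3 → ***) to keep the mapping monotone, since
strict-inequality definitions leave the boundary values unassigned. A
single replicate falls back to |z| with a warning.

Fold changes are ratios of the larger to the smaller mean efficiency,
rounded half-up to one decimal (this reproduces every printed fold change
from the printed means), with a direction flag; the log₂ fold change is
left unrounded. Rescue fractions are (rescue − kd)/(nc − kd), so movement
toward the control is positive regardless of effect direction, 1 is full
rescue, and nc = kd is undefined (NaN). Relative expression from qPCR is
2^(−ΔΔCt) (Livak); a printed "−2^ΔΔCt" form is a typesetting artefact, as
expression levels cannot be negative.

## Problem sizes and determinism

The shipped tests and the acceptance script run the pipeline at desk
scale: 20,000–50,000 reads for recovery checks, screens of 200–1,000 genes
plus 500–2,243 non-targeting controls, 1,000–2,000 permutations, and 20
seeded spike-recovery screens. These sizes keep every stochastic check
well-powered while completing in minutes on one CPU. Every random draw
flows from a single `numpy` Generator seeded explicitly; identical
configurations and seeds give byte-identical FASTQ, count tables and
result files, and the pipeline driver records SHA-256 digests of all
outputs in its manifest.

## Known limitations

* The aligner assumes single amplicon reads; merged/overlapping paired
  ends, UMIs and quality-based filtering are out of scope (an optional
  minimum-mean-quality flag is the only concession).
* The conditional NB test assumes a single pooled dispersion; strongly
  abundance-dependent overdispersion would call for a fitted mean–variance
  relation instead.
* The sorting model reweights count compositions; phenomena that only a
  per-cell simulation can produce (gate impurity, multi-infection) are not
  represented.
* "Other-edit" reads are excluded from the efficiency denominator; with
  elevated error rates this inflates category percentages by roughly the
  per-window error mass.
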