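# beditscan

Simulation and analysis of FACS-sorted CRISPRi screens for cytosine
base-editing outcomes.

Cytosine base editors (CBEs) deaminate a target C within the protospacer to
uracil while nicking the opposite strand; cellular repair of this U•G
intermediate yields C•G→T•A or C•G→G•C point mutations (and, more rarely,
C•G→A•T conversions and indels). To find the repair genes steering these
outcomes, reporter cell lines carrying fluorescent readouts of a single
editing outcome can be combined with a pooled CRISPRi knockdown library:
cells are sorted by reporter state, and genes whose sgRNAs are enriched or
depleted in the sorted population point to factors promoting or inhibiting
that outcome. `beditscan` implements the full computational chain of such a
screen for people who want to analyse — or prototype against simulated
versions of — this kind of experiment:

* **`beditscan.synthetic_data`** — generators for edited amplicon reads
  (multinomial outcome alleles with per-base sequencing error and sampled
  indels) and pooled-screen sgRNA count matrices (negative-binomial counts,
  lognormal library skew, a gene-effect model linking knockdown to
  reporter-conversion probability π_s = min(1, π₀·effect), essential-gene
  dropout), both carrying ground truth for recovery tests.
* **`beditscan.amplicon_outcomes`** — allele-level outcome calling: global
  affine-gap alignment of each read to the amplicon, classification at the
  target cytosines (indel ≻ per-target-C base calls ≻ WT, within a
  nick-centred quantification window), and aggregation into absolute
  (% of all reads) and relative (% of edited reads) efficiencies.
* **`beditscan.screen_enrichment`** — median-of-ratios normalization,
  per-sgRNA log₂ fold changes with an exact conditional negative-binomial
  test, gene phenotype (median LFC of a gene's sgRNAs), and one-sided
  robust rank aggregation: for a gene with k sgRNAs at rank percentiles
  r₍₁₎ ≤ … ≤ r₍ₖ₎,

  ρ = min over j ≤ k′ of P(Beta(j, k−j+1) ≤ r₍ⱼ₎),

  over the k′ sgRNAs passing the α screen, with a stratified permutation
  p-value and Benjamini–Hochberg FDR.
* **`beditscan.validation_stats`** — the arrayed-validation statistics:
  z = (x − μ)/σ against non-targeting controls (|z| > 3 = strong effect),
  the replicate-adjusted z-score |mean(z)| − σ(z) with significance tiers
  \*/\*\*/\*\*\* at 1.5/2/3, fold changes and LFC heat-map values, relative
  outcome percentages, rescue fractions, and ΔΔCt relative expression.
* **`beditscan.io_cli`** — plain-text formats (FASTQ, TSV/CSV, site files,
  flat configs), a seeded end-to-end pipeline driver with an output
  manifest, and the `beditscan` command line.

## Worked example

Simulate 20,000 reads of a reporter-like site under a negative-control-like
outcome mix (15.6% C→T, 6.6% C→G, 1.3% C→A, 2% indels, 0.1% per-base
error), call outcomes, and compute a knockdown fold change:

```python
from beditscan.synthetic_data import (SimConfig, make_default_sites,
                                      nc_like_outcome_spec, simulate_reads)
from beditscan.amplicon_outcomes import call_outcomes
from beditscan.validation_stats import fold_change

site = make_default_sites()[0]                    # reporter-like, one target C
reads, truth = simulate_reads(site, nc_like_outcome_spec(site),
                              SimConfig(n_reads=20_000, error_rate=0.001, seed=1))
table, profile = call_outcomes(reads, site)
print(f"total editing : {profile.total_editing:.1f}%")
for cat in ("T@10", "G@10", "A@10", "indel"):
    print(f"  {cat:<6} absolute {profile.absolute[cat]:5.2f}%   "
          f"relative {profile.relative[cat]:5.2f}%")
fc = fold_change(nc_mean=15.6, kd_mean=7.5)
print(f"MSH2-like knockdown: {fc.fold}-fold {fc.direction}")
```

prints

```
total editing : 25.6%
  T@10   absolute 15.72%   relative 61.40%
  G@10   absolute  6.46%   relative 25.23%
  A@10   absolute  1.37%   relative  5.34%
  indel  absolute  2.06%   relative  8.03%
MSH2-like knockdown: 2.1-fold down
```

The caller recovers the generating allele frequencies to within binomial
sampling error (`T@10` is the single C→T conversion at protospacer position
10; `relative` percentages are of edited, non-WT reads). The fold change is
the ratio of the larger to the smaller mean efficiency, rounded half-up to
one decimal, with the direction of the knockdown effect.

The same stages are available from the shell:

```bash
beditscan simulate-reads --site-id reporter_like --n-reads 20000 --seed 1 --out-dir sim/
beditscan call-outcomes  --site sim/sites.tsv --fastq sim/reporter_like.fq --out calls/
beditscan simulate-screen --n-genes 200 --out-dir screen/
beditscan screen-test    --counts screen/counts.tsv --treat sorted --ctrl bulk_dox \
                         --alpha 0.25 --n-perm 2000 --seed 1 --out genes.tsv
beditscan run            --seed 1 --out-dir demo/      # all four stages + manifest
```

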