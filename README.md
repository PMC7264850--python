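# hzclines

Geographic cline analysis for hybrid zones — from 2-D field coordinates
to fitted clines, cline comparisons, and hybrid-class inference.

## What it does

When two diverged taxa meet and interbreed, the transition in allele
frequencies and trait means across the contact zone — the *geographic
cline* — records the balance of dispersal and selection. Narrow,
coincident clines with stepped centers and long introgression tails are
the signature of a tension zone: strong selection against early
generation hybrids across much of the genome. `hzclines` implements the
full analysis for a two-taxon zone sampled in two dimensions (the
motivating system is the Joshua tree contact zone, *Yucca brevifolia* ×
*Y. jaegeriana*, with its obligate yucca-moth pollinators):

1. **Transect** — interpolate the hybrid index q over space (thin-plate
   spline), trace the 0.5 iso-contour (marching squares), sign each
   tree's shortest distance to it (west negative), and group trees into
   250-m bins, collapsing bins with fewer than 3 trees.
2. **Cline fitting** — fit, by Metropolis–Hastings MCMC, a logistic
   cline Φ(d) = 1/(1+exp(−4(d−c)/w)) with center c and width w, either
   plain (model I), with symmetric exponential introgression tails
   (model II), or with independent tails per side (model III), each
   scaled between asymptotes pmin/pmax; choose among them and a no-cline
   null by AIC (simplest model wins when ΔAIC < 2). Binomial likelihood
   for allele/haplotype/species counts, Gaussian for standardized trait
   means (traits gated first by a linear-regression null check).
3. **Comparison** — coincidence (centers) and concordance (widths) by
   disjointness of 2-log-likelihood support intervals; category
   summaries excluding null clines; west/east offset classification.
4. **Hybrid classes** — hybrid index HI and interclass heterozygosity H
   per tree; expected (HI, H) clouds for F1, F2 and backcrosses by
   in-silico crossing of the empirical parental pools (free
   recombination, 500 simulated individuals per class); assignment by
   Mahalanobis distance with a χ² gate, else "advanced/unassigned".
5. **Pollinator host choice** — Pearson correlation of hybrid index with
   position, and a binomial GLM of moth species counts ~ hybrid index +
   distance.
6. **Synthetic zones** — a seeded generator of whole datasets with known
   ground truth (curved center lines, semi-diagnostic SNPs, an offset
   chloroplast cline, clinal traits, pollinator counts) for recovery
   testing.

See `docs/methods.md` for the model details, parameter conventions and
design decisions.

## Worked example

Simulate one SNP-like frequency cline (19 bins × 40 alleles, width
2236.39 m, semi-diagnostic ends 0.02/0.99), fit all four model
families, and select by AIC:

```python
import numpy as np
from hzclines import ClineModel, FitConfig, generate_bin_table
from hzclines.fitting import select_model

table = generate_bin_table(
    ClineModel("I", center=0.0, width=2236.39, pmin=0.02, pmax=0.99),
    np.linspace(-5000, 5000, 19), [40] * 19, seed=1,
)
fit = select_model(table, FitConfig(n_chains=2, n_steps=3000, burn_in=500, seed=1),
                   "frequency", "snp_qscore")
```

Output:

```
best model : I
center     :    -31.2 m  (2LL interval -228.1 .. 165.6)
width      :   2360.8 m
pmin/pmax  : 0.026 / 1.000
AIC        : null=514.0, I=347.6, II=351.7, III=355.6
```

The fitter recovers the generating cline: the simple sigmoid wins
(tailed models gain no likelihood worth their extra parameters), the
estimated center's 2-log-likelihood support interval covers the true
center 0, and the width estimate is within ~6% of truth.

The same machinery runs end-to-end from files:

```sh
hzclines simulate --n-trees 400 --n-snps 84 --seed 1 --outdir zone/
hzclines run-all --config pipeline.json   # full transect -> fits -> classes
```

producing a cline summary TSV (character, best model, center, width,
2LL bounds, pmin/pmax), pairwise comparison matrices, per-tree ancestry
and class assignments, pollinator coefficients, and a manifest with
checksums — byte-identical on rerun with the same seed.

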