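# Methods

## Overview

`psncohort` implements a pathway-centric analysis of somatic mutation data
from immunotherapy-treated lung cancer cohorts. The pipeline has five
stages, run in this order:

1. **Deleterious filtering and pathway profiling.** A mutation is
   *deleterious* when at least one of its two pathogenicity flags (frozen
   COSMIC / ClinVar assessments supplied as input columns) is true; an
   AND-rule is available via `StratificationConfig(pathogenicity_rule="all")`.
   Each patient is reduced to a binary vector x ∈ {0,1}¹¹ over a fixed,
   ordered catalog of 11 signaling pathways (cell cycle, Hippo, Myc, Notch,
   oxidative stress/Nrf2, PI3K, RTK/RAS/MAP, TGF-β, p53, β-catenin/Wnt,
   DDR): x_p = 1 iff the patient has ≥ 1 deleterious mutation in a member
   gene of pathway p. A gene may belong to several pathways and then sets
   several bits. Genes absent from the catalog are ignored for profiling.

2. **Stratification.** Tumor mutation burden (TMB, Mut/Mb) is an input,
   never recomputed from mutation counts. High TMB is *strictly* greater
   than the cutoff (default 10 Mut/Mb; a patient at exactly 10.0 is
   low-TMB). Current and former smokers form the S class; never-smokers
   the NS class. The four subgroups S/H, S/L, NS/H, NS/L partition the
   cohort.

3. **Enrichment.** Over-representation of a mutated pathway in a subgroup
   of n patients against a background of N (K mutated) is the exact
   hypergeometric upper tail P(X ≥ k). One comparison family = the 11
   pathways of one subgroup-vs-background contrast, adjusted together with
   Benjamini–Hochberg; families are never pooled, which keeps the FDR
   interpretable per contrast. The background is explicit per call; the
   pipeline default is the subgroup's parent smoking stratum (e.g. all
   never-smokers for the NS/H subgroup).

4. **Patient similarity network.** Pairwise Euclidean distance between
   binary profiles (equal to the square root of the Hamming distance),
   then the scaled exponential similarity kernel with locally adaptive
   bandwidth:

       W_ij = exp( − d_ij² / (μ · ε_ij) ),
       ε_ij = [ mean d(i, kNN_i) + mean d(j, kNN_j) + d_ij ] / 3,

   with kNN_i the k nearest neighbors of i excluding itself. Duplicate
   profiles (common for 11-bit vectors) get d = 0 and weight 1; ε = 0 can
   only arise at d = 0 and is defined as weight 1 by continuity.
   Communities are found with the Louvain modularity heuristic on the full
   weighted graph, best of `n_restarts` runs (seeds `seed..seed+r−1`) by
   modularity Q, ties to the lowest seed. Labels are canonicalized by
   descending community size, ties by smallest member index, so "C1" is
   stable. A partition "has community structure" when it has ≥ 2
   communities and Q ≥ q_min (default 0.05).

5. **Characterization and outcomes.** Per community: the percentage of
   members mutated per pathway, median TMB, a tie-corrected Kruskal–Wallis
   contrast of TMB across communities (χ² approximation, g−1 df), the
   hypergeometric over-representation of high-TMB patients (background =
   the stratum the network was built on), Kaplan–Meier overall survival
   with an unweighted (Mantel–Haenszel) log-rank test across communities,
   and objective response / disease control rates (ORR = CR+PR,
   DCR = CR+PR+SD; non-evaluable patients count in the denominator by
   default). Median follow-up uses the reverse Kaplan–Meier estimator.

## Parameters that matter

| parameter | default | units / range | rationale |
|---|---|---|---|
| `tmb_cutoff` | 10 | Mut/Mb | the standard high-TMB threshold for immunotherapy benefit; strict `>` |
| `k_neighbors` | min(n−1, 20) | patients | local-scaling neighborhood; the kernel's source method recommends 10–30 |
| `mu` | 0.5 | dimensionless, 0.3–0.8 | kernel decay; larger = flatter weights, denser effective graph |
| `sparsify_k` | off | patients | optional union-kNN edge pruning before community detection |
| `resolution` | 1.0 | — | classic modularity |
| `n_restarts` | 100 | — | best-of-restarts by Q; Louvain is greedy and seed-dependent |
| `alpha` | 0.05 | — | significance for the per-family BH q-values |

## Numerical choices

- **Hypergeometric tail** is computed with exact integer arithmetic
  (suffix sums of `math.comb` terms, converted through `Fraction` to the
  correctly rounded double). This is exact at any cohort size used here;
  `scipy.stats.hypergeom` serves as an independent cross-check in the test
  suite, never as the implementation.
- **BH adjustment** is the standard step-up `q_(i) = min_{j≥i} p_(j)·m/j`,
  capped at 1, mapped back to input order; verified against statsmodels.
- **Louvain tie-breaking.** Binary profiles produce many exactly tied edge
  weights, which can make the Louvain local-move phase oscillate without
  terminating. Each restart therefore multiplies the weights by
  (1 + 10⁻⁹·u_ij) with u drawn from the restart's seed; Q is always
  recomputed on the unperturbed weights. The perturbation is ~7 orders of
  magnitude below any meaningful weight difference.
- **Spearman p-values for 11-element profiles** use a seeded Monte-Carlo
  permutation null (10⁶ permutations, accurate to ~3 decimals, never
  exactly zero thanks to the +1 correction); the t-approximation is
  unreliable at n = 11 and is not used. ρ itself uses average ranks.
- **Kaplan–Meier conventions:** events before censorings at tied times;
  median = smallest t with S(t) ≤ 0.5, undefined (None) when S never
  reaches 0.5. Kruskal–Wallis on all-identical values is degenerate and
  reported as H = 0, p = 1 with a flag rather than an error.
- Percentages in the stratum summary are rounded half-up to one decimal,
  matching the cohort-table formatting convention.

## Synthetic data: what it emulates, what it does not

The **deterministic fixture** (`build_realworld_fixture`) encodes the
published real-world cohort summary exactly: 142 patients (111 S / 31 NS),
per-pathway mutated-patient counts per smoking stratum, 53 high-TMB
patients, stratum TMB medians 8 / 4 / 16.39 Mut/Mb, and an 11-patient NS/H
subgroup with 8 DDR-mutated members, all responders, and a product-limit
OS median of exactly 27.95 months. Within-patient co-occurrence is only
published for the NS/H subgroup (hand-encoded to the reported dense C1-like
pattern: cell cycle, RTK/RAS/MAP, p53 in 7/8; DDR, Notch in 6/8; Nrf2,
Wnt in 5/8); everywhere else the published column sums are completed by a
deterministic rotating greedy fill — one of many valid completions, so
community structure outside the NS/H block is illustrative, not a claim
about the real cohort.

The **stochastic generator** (`generate_cohort`) samples stratum sizes
binomially, pathway bits independently per pathway at the published
marginal frequencies (S stratum: the 11 published rates; NS stratum: the
low-TMB-implied base rates 6/20 for DDR and 0 for Wnt, with the planted
NS/H subgroup boosted to the published subgroup rates 8/11 and 5/11), TMB
log-normally per stratum (medians 8 and 4 Mut/Mb, log-sd 0.9; non-planted
never-smokers truncated below the cutoff so the planted patients are
precisely the NS/H stratum; planted TMB = cutoff + log-normal with median
6.39), exponential survival (medians 18.3 / 12.2 months OS / PFS; planted
hazard multiplied by 18.3/27.95), uniform administrative censoring on
(6, 28.1) months (median follow-up 17.05), and categorical best response
(planted patients CR/PR only). `validation_scale_config()` is a
structurally similar scale variant (853 patients, 16% never-smokers,
planted NS/H subgroup of 18 with DDR rate 17/18) for power testing; it
does not emulate any real trial's patient-level data.

What the generator deliberately does **not** reproduce: within-patient
pathway correlation outside the planted subgroup (bits are independent),
gene-level recurrence (one synthetic pathogenic call per mutated pathway),
panel-specific TMB measurement error, or non-exponential hazards (a
Weibull-shaped alternative would change medians only through the shape
parameter, which is out of scope). Passing tests therefore demonstrate
that the machinery is correct and calibrated under these assumptions, not
that the biological findings generalize.

## Calibration experiments

- **Planted-partition recovery** uses four 11-bit block templates at the
  maximum possible pairwise Hamming distance for four binary words of
  length 11 (≥ 7, the Plotkin bound), block sizes 8/4/7/12 and bit-flip
  noise 0.05. The calibration runs the kernel at μ = 0.6 (mid-range of the
  recommended 0.3–0.8). Recovery is sensitive to μ and k: at other
  settings a small fraction of seeds yield partitions whose modularity
  genuinely exceeds that of the planted labels (a modularity-landscape
  property, not an optimizer failure), so perfect-ARI rates there are a
  few points lower. The acceptance script reports the measured rate.
- **Enrichment controls** run at the validation-cohort scale (~140
  never-smokers, planted subgroup of 18, DDR rate 17/18 vs base 0.3),
  where the planted signal is strongly powered; at the real-world scale
  (31 never-smokers, subgroup of 11, 8/11 vs 6/20) the same contrast is
  *not* reliably significant after BH adjustment — the package reports the
  honest q-value (≈ 0.10 on the fixture) rather than the published
  sub-0.05 claim, which cannot be reconstructed from the printed counts.

## Known limitations

- Gene symbols are matched by exact uppercase string equality; no alias or
  identifier mapping.
- Pathogenicity is an input flag; no live database queries, no HGVS
  validation.
- Published values that require undeposited patient-level data (external
  validation p-values, community survival contrasts, survival medians) are
  recorded in `CALIBRATION_TARGETS` with `reproducible=False`; they tune
  the generator and are never treated as method-validation truth.
- Single-layer networks only; no cross-data-type similarity fusion.
- The log-rank test is the unweighted variant; no Cox modeling.
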