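# Methods

## Screen scoring

A pooled CRISPR knockout screen is scored against the plasmid library that
the cell population was infected from. The four steps, in order:

1. **Depth normalization.** Each sample column is scaled to reads per
   million of its own total raw reads. Totals are taken over *all* guides,
   before any filtering, so every normalized column sums to 10⁶ and the
   statistic is invariant to sequencing depth.
2. **Low-count filter.** Guides with fewer than 30 raw reads are excluded.
   The filter is evaluated on raw counts. Which column(s) the 30-read rule
   applies to is genuinely open; the default requires ≥ 30 reads in *both*
   members of the compared pair (sample and reference), protecting both the
   numerator and the denominator of the fold-change from shot noise.
   `filter_scope="sample"` restricts it to the compared sample only.
3. **Log2 fold-change.** `lfc = log2((a_s + c) / (a_r + c))` with
   pseudocount `c = 1`. The pseudocount is added on the reads-per-million
   scale by default (depth-invariant); `pseudocount_scale="raw"` adds it to
   raw counts instead. Antisymmetry holds exactly in exact arithmetic and
   to ≤ 1e-12 in floating point.
4. **Second-best gene ranking.** Per gene, over guides that passed the
   filter: the second-largest LFC (`second_best_enriched`) and the
   second-smallest (`second_best_depleted`). Genes are ranked by each
   statistic (descending / ascending); ties break on the gene label so
   output is deterministic. A gene with fewer than two passed guides has no
   second-best statistic and is excluded with reason `lt2_guides` rather
   than falling back to its single guide. Control pseudo-genes are reported
   but never ranked. No p-values are attached: the screen's readout is the
   ranking itself.

## Regulator scan

Expression of a 13-gene panel of ERK negative-feedback regulators (DUSP1–6,
SPRY1–4, SPRED1–3) is compared between tumors carrying an activating
mutation in a driver of interest (any of a `|`-separated list of annotation
flags, e.g. `EGFR|KRAS`) and tumors wild-type for all of them. Per gene: a
two-tailed two-sample t-test — Welch's form by default, with
`equal_var=True` available for the pooled variant — then Bonferroni
correction `p_adj = min(1, p·13)` and the significance score `−log2(p_adj)`
against α = 0.01. The score is computed on the adjusted p by default
(`score_on="raw"` exposes the alternative) so that a single per-gene value
is compared against a single 0.01 threshold line.

Companion analyses:

* **Heatmap normalization** — per row, `(x − median) / MAD` with the
  unscaled median absolute deviation; constant rows become missing with a
  warning. Output rows have median 0 and MAD 1 and the transform is
  invariant to positive affine changes of a row's units.
* **Mann-Whitney U** — exact enumeration when the pooled sample has at most
  16 observations and no ties, otherwise the normal approximation with tie
  and continuity corrections. One-tailed comparisons test "first group
  greater" and are used only where the direction is predicted in advance
  (phospho-marker comparisons); expression comparisons are two-tailed.
* **Quartile split** — with k = ⌈n/4⌉, the high group is every sample whose
  value is at least the k-th largest and the low group every sample at most
  the k-th smallest; ties expand groups by ≥/≤ inclusion. This symmetric
  top-k rule gives 46/46 groups for cohorts of both 182 and 184 and reduces
  to the obvious {top 2, bottom 2} for n = 8.
* **Pearson correlation** of a phospho-marker with log2 expression, with
  the p-value from t = r·√((n−2)/(1−r²)) on t(n−2); one-tailed tests
  positive association.

## Dose-response

Viability signals are normalized to the vehicle (dose 0) wells of each
series — or to an explicit control condition — giving mean ± SEM fractions
per dose. Curves are fit with a four-parameter logistic on linear dose,

    v(d) = bottom + (top − bottom) / (1 + (d / IC50)^hill),

by unweighted least squares on per-dose replicate means (the fit is
therefore invariant to replicate order and duplication). Parameters are
optimized as (bottom, top, log IC50, log hill) with bottom, top ∈ [−0.2,
1.5], from a multi-start grid of five log-spaced IC50 values across the
positive dose range crossed with hill starts {0.5, 1, 2, 4}; the best
residual sum of squares wins. IC50 is the curve *midpoint* parameter; the
absolute-50% dose is also reported when the curve crosses 0.5. A fit whose
plateaus collapse (top − bottom < 0.05) resolves no dose effect and is
flagged with IC50 missing; a midpoint outside the tested dose range is
flagged extrapolated.

Sensitivity tiers: **sensitive** iff IC50 ∈ [1, 3] µM and fitted viability
at the 3.2 µM reference dose is below 0.10; **insensitive** iff IC50 ≥ 5 µM,
or the fit is flagged while viability at the top dose stays above 0.5;
**intermediate** otherwise. The boundaries are module constants with a
config override.

Small companion operations: rescue-grid normalization (each well of a
primary-drug × rescue-drug grid divided by its zero-primary-dose partner),
ΔΔCt relative quantification `2^(−ΔΔCt)` on replicate-mean cycle
thresholds, and densitometry ratios (phospho/total relative to a control
lane; the loading control cancels algebraically).

## Synthetic data

Each generator is a pure function of its spec; every output table draws
from its own RNG stream derived from the master seed by stable named
sub-seeding (`SeedSequence([seed, crc32(name)])`), so adding a table never
perturbs the others.

* **Screen** — guide abundances follow a lognormal(0, 1) profile
  renormalized to proportions (realistic library skew with no extra
  parameters); counts are negative-binomial with variance m + φ·m²
  (φ = `nb_dispersion`, Poisson at φ = 0) around depth × abundance for
  three samples: plasmid (reference), untreated final, treated final.
  Planted gene effects multiply treated abundances by 2^effect with
  per-guide jitter N(0, 0.25) in log2 space so the second-best statistic is
  exercised on non-identical guides. Defaults: 4 guides/gene, 50 control
  guides, 500 reads/guide, φ = 0.2. At φ = 0.2 the per-sample count CV is
  ≈ 0.45, hence a null per-guide LFC spread of ≈ 0.95 log2 units — with
  1000 genes this noise level lets a +2 log2 planted gene take enrichment
  rank 1 in only about half of runs, which the acceptance measurements
  report as observed; recovery is near-certain at φ ≤ 0.05.
* **Cohort** — per-gene baseline log2 abundance uniform on [6, 12]
  (an RSEM-like scale), per-sample noise N(0, σ) in log2 with σ = 0.5,
  107 mutant vs 123 wild-type samples with KRAS/EGFR flags alternating
  among the mutants. The effect gene (DUSP6 by default) is multiplied by
  2^effect in mutants only. The phospho-ERK RPPA marker is
  slope·log2(expression) + N(0, 0.5); the P-p38-like and P-JNK-like markers
  are pure N(0, 1) noise.
* **Dose plates** — signal = v(d) × 10⁴ × (1 + N(0, cv)) over the 17-point
  0–8 µM series in quadruplicate at cv = 0.05. The three default lines
  plant the three phenotypes: IC50 2 µM/hill 6/floor 0.02 (a steep curve is
  required for >90% kill at 3.2 µM with a midpoint of 2), IC50 4.5/hill
  3/floor 0.05, and IC50 6/hill 3/floor 0.40. The insensitive line's
  midpoint lies near the top of the dose range, so its fitted IC50 is the
  least precise — its classification is correct in ≈ 97% of runs rather
  than always, which mirrors the practical difficulty of pinning an IC50
  beyond the highest tested dose.

What the generators do **not** emulate: sequencing-read structure, batch
and clonal effects in screens, copy-number confounding, inter-gene
expression correlation, heteroscedastic RPPA noise, plate-position
(edge) effects. Passing tests therefore demonstrate correctness of the
computations and recoverability of planted effects under idealized noise,
not performance on real cohorts.

## Numerical choices

* Ranking ties break on gene label ascending; quartile ties expand groups.
* Mann-Whitney falls back from exact to asymptotic exactly when ties exist
  or the pooled n exceeds 16; an all-tied pooled sample returns p = 1
  directly (the tie-corrected variance is zero).
* Both-groups-constant-and-equal input to the t-test returns p = 1 with a
  warning rather than NaN.
* Result tables serialize floats at 12 significant digits; write-then-read
  reproduces values to better than 1e-9 relative error.
* 4PL multi-start stops early on an exact fit (cost < 1e-14).

## Problem sizes

The acceptance measurements use 100 random instances of ≤ 50 guides for
oracle agreement, 100 seeded screens of 1000 genes × 4 guides for planted
recovery, 1000 null cohorts of 100 vs 100 samples for type-I control, 100
cohorts of 107 vs 123 for planted-scan recovery, a 10⁶-resample permutation
oracle for the Mann-Whitney approximation, and 100 seeded three-line plate
simulations for IC50 recovery and classification.

## Known limitations

* The screen model scores one sample pair at a time; replicate-aware
  variance modeling, FDR estimation and copy-number correction are out of
  scope by design.
* IC50s beyond the tested dose range are reported but flagged
  `extrapolated`; the sensitivity call then rests on a weakly identified
  parameter.
* Gene and sample labels are opaque case-sensitive strings; no symbol
  aliasing is attempted.
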