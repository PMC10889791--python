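# Methods

## Data model

A screen is a genes × samples matrix of Ct values with per-sample metadata
(treatment group, biological replicate, technical replicate) and a per-gene
amplification factor `A = 1 + E/100` (default 2.0, i.e. perfect doubling;
valid range [1.5, 2.3]). Ct values must lie in (0, 45] — 40-cycle protocols
with margin. Missing values (``Undetermined``/``NA`` wells) are permitted
only before technical-replicate aggregation.

Technical replicates are averaged as the arithmetic mean of Ct (not of
linear-scale quantities); a cell whose replicates disagree by more than
`max_tech_sd` (default 0.5 cycles) yields a warning record written to the
run log. After aggregation the matrix must be complete: a sample missing any
gene is either dropped (with `drop_incomplete_samples`, logged) or an error,
because all four stability algorithms assume a complete matrix.

Log-ratio methods operate on relative quantities
`Q[g, s] = A_g^(minCt_g − Ct[g, s])`, calibrated per gene so the most
abundant sample has Q = 1. When no standard curve is supplied, `A = 2` for
every gene; per-gene efficiency correction is supported by passing fitted
amplification factors into the table.

## Standard curves

Ct is regressed (OLS) on log₁₀ of relative concentration, replicates
entering as individual points; R² is the squared Pearson correlation, which
for simple regression equals the coefficient of determination. Efficiency is
`E = (10^(−1/slope) − 1) × 100`, reported unrounded and formatted to one
decimal only at presentation time. A non-negative slope is reported but
flagged invalid. Fewer than three distinct concentrations is an error. The
default simulated series uses five 5-fold dilutions (1/5 … 1/3125).

## Stability algorithms

All four return per-gene values where lower = more stable, plus ranks.

**Delta-Ct.** For every ordered gene pair (i, j), the per-sample difference
`D_s = Ct[i, s] − Ct[j, s]` has a sample SD (denominator n−1); a gene's
stability is the mean SD over its partners. Per-sample loading offsets cancel
in the differences.

**geNorm.** On `L = log₂ Q`, the pairwise variation
`V_ij = SD_s(L[i, ·] − L[j, ·])` and `M(i) = mean_{j≠i} V_ij`. The ranking
removes the largest-M gene from the surviving subset until two remain; ties
are broken by removing the lexicographically last name. Each gene's reported
value is its M at the step it was excluded; the final pair both carry the
two-gene M and take ranks 1–2 ordered by their M in the last three-gene
step. Because the procedure itself is a deterministic total order, geNorm
ranks are a strict permutation — rank averaging applies only to the
value-sorted methods. The V-curve uses normalization factors
`NF_n[s] = geometric mean of Q over the n best-ranked genes`;
`V_n = SD_s log₂(NF_n/NF_{n+1})` for n = 2..k−1. The smallest n with
`V_n < 0.15` is the optimal reference-gene count; if no V clears the cutoff
the argmin is used and flagged as a fallback rather than failing silently.

**NormFinder.** On sample-centered log₂ quantities, the ungrouped estimator
removes each gene's mean and pools squared residuals into raw variances
`v_g`. These are biased because the sample-centering mixed every gene's
noise into every residual; solving `v_g = (1 − 2/k)σ²_g + T/k²` with
`T = Σv_g/(1 − 1/k)` gives bias-corrected `σ²_g` (clipped at 0); stability
is `σ_g`. With groups, per-group means and bias-corrected within-group
variances are computed the same way; the intergroup component `d_{gγ}`
(deviation of a gene's group mean from its grand mean) is shrunk by
`w = γ̂/(γ̂ + σ²_{gγ}/n_γ)` where `γ̂` is the method-of-moments estimate of
the intergroup variance (clipped at 0; `w = 0` when both components vanish),
and stability is `ρ_g = mean_γ(|d_{gγ}w| + √(σ²_{gγ}/n_γ))`. Log base 2 is
a convention; changing base rescales values without changing ranks. The
original NormFinder add-in's exact shrinkage constants are not published;
this decomposition is specified exactly so results are reproducible, and
bit-for-bit agreement with the Excel tool is not claimed.

**BestKeeper.** Operates on raw Ct: per-gene n, geometric and arithmetic
mean, min, max, deviation (sample SD by default; mean absolute deviation via
`deviation="mad"` for fidelity to the original tool), `CV = 100·dev/mean`,
and Pearson correlation with the BestKeeper index (per-sample geometric mean
Ct over all candidates; correlation is undefined, NaN, for a constant gene).
Ranking is ascending by deviation, ties by CV then name. Because it works on
raw Ct, shared loading offsets inflate BestKeeper's deviations — the
documented contrast with the three log-ratio methods, and the reason
BestKeeper can miss a moderately dysregulated gene when loading variation is
large.

Ranks elsewhere use average tie handling (`scipy.stats.rankdata`); min-rank
is available by flag and affects downstream geometric means only when exact
value ties occur.

## Consensus and selection

The comprehensive value per gene is the geometric mean of its per-method
ranks; the final ordering is ascending by geomean with ties broken by
arithmetic mean rank, then gene name. A gene missing from any contributing
method is an error naming both. The optimal *number* of reference genes
comes from the geNorm V-curve and the optimal *identity* from the consensus
head — the two-source rule screens conventionally use. The web RefFinder's
undocumented rank weighting is deliberately not reproduced; the plain
geometric mean is used.

## Expression validation

`ΔCt[s] = Ct[target, s] − mean_r Ct[r, s]` (arithmetic mean over the
reference set, equal to geometric-mean-of-quantities normalization at equal
amplification factors), `ΔΔCt[s] = ΔCt[s] − mean ΔCt over the calibrator
group`, `fold[s] = 2^−ΔΔCt`. The calibrator group's geometric mean fold is
exactly 1; its arithmetic mean fold is 1 exactly when computed on the group
mean ΔCt. An efficiency-corrected variant uses each gene's own amplification
factor in the exponent and reduces to the plain form at A = 2 everywhere.
Group summaries are mean ± SE on the fold-change scale; SE is not propagated
through the calibrator. Two groups are compared with a two-sided
pooled-variance Student's t (zero pooled variance with unequal means is
flagged degenerate with p = 0); three or more with one-way ANOVA and Tukey
HSD p-values from the studentized-range distribution. Compact letters are
assigned by insert-and-absorb on the significance graph: start with one
letter column holding all groups, split any column containing a
significantly different pair, absorb subset columns, and label columns
alphabetically from the group with the largest mean. Groups sharing no
letter differ at the chosen alpha.

## Synthetic data generator

`Ct[g, γ, b, τ] = baseline_g + δ_{g,γ} + a_{γ,b} + ε` with
`δ ~ N(0, condition_sd_g)` drawn once per (gene, group) — treatment-driven
dysregulation, the biological meaning of an unstable reference —
`a ~ N(0, sample_loading_sd)` once per biological sample (the RNA-input
offset shared by all genes), and `ε ~ N(0, tech_sd)` per well. Values are
clipped to (5, 45) with clipping counted in the ground truth. An optional
target gene receives a per-group Ct shift of `−log₂(fold)/log₂(A)`.
Everything is reproducible from the spec's seed. The ground-truth stability
ordering is the ascending `condition_sd` ordering (name tiebreak).

The `paper-like` preset emulates a 15-candidate hemipteran screen: baselines
evenly spread over 17–31 cycles, six treatment groups (a water control and
five insecticides), 3 biological × 3 technical replicates, loading SD 0.5
and technical SD 0.3 cycles. The per-gene condition SDs are graded 0.0–1.4
cycles in steps of 0.1 so the preset carries a known stability gradient;
real screens have no such clean gradient, and the generator also does not
model amplification-curve artifacts, inhibitor effects, heteroscedastic
noise at high Ct, or missing wells. Passing tests therefore demonstrate
correctness of the algorithms and their documented invariances, not
instrument-level realism.

Dilution series are simulated on the ideal line
`Ct = intercept − log₁₀(c)/log₁₀(A)` plus Gaussian noise.

## Numerical and design choices

- Problem sizes in the test and acceptance runs: 15 genes × 6 groups × 3 × 3
  replicates for pipeline runs; oracle-equivalence checks on k ≤ 5–6 genes,
  n ≤ 8 samples against brute-force loops at 1e−12; parameter-recovery over
  100 seeded replicates of a 15-gene, 3-group × 3-replicate screen with one
  gene at condition SD 2.0 and technical SD 0.3 as the only noise sources.
- The recovery experiment deliberately omits loading offsets so that all four
  methods — including BestKeeper, whose raw-Ct deviations absorb loading
  variance — see the same contrast.
- Delta-Ct/geNorm/NormFinder invariance to per-sample shifts is asserted at
  1e−9; oracle equivalence at 1e−12; both far below any scientifically
  meaningful difference in cycles.
- Degenerate inputs: constant genes (SD 0, CV 0, undefined index
  correlation), two-gene geNorm (warned, no exclusion possible), zero
  within-group variance in the t test (flagged), V-curves never below the
  cutoff (argmin fallback, flagged).

## Known limitations

- The four algorithms are reproducible specifications of the published
  method families, not byte-level ports of the original closed-source tools
  (geNorm/NormFinder Excel add-ins, BestKeeper spreadsheet, RefFinder web
  service).
- BestKeeper's deviation is computed on Ct cycles and is not comparable in
  units to the other three methods; only its ranks feed the consensus.
- No support for >2-level nested replicate designs inside the algorithms;
  aggregation happens upstream.
- No instrument-native file parsing or melting-curve analysis.
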