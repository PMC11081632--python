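# Methods

This note documents the statistical models behind each module, the
defaults and why, the synthetic-data assumptions, and the numerical
choices a maintainer would otherwise have to reverse-engineer.

## Expression-stratified differential essentiality screen

**Model.** For a query gene with expression x across N cell lines, the
high group is the k = ⌊qN⌋ lines with the largest x and the low group the
k smallest (N counts lines with non-missing query expression). Boundary
ties are broken by ascending cell-line id so stratification is a pure
function of the input. For every other gene, essentiality scores in the
two groups are compared with a two-sided Wilcoxon rank-sum test; the
effect is summarized by Δ = median(high) − median(low), computed on
exactly the observations the test used (missing values are dropped
per gene, never imputed — imputation would fabricate ranks).

**Directionality.** Because more negative scores mean more essential,
Δ < 0 with p < α is a GOF (synthetic dosage lethal) call — the gene is
more essential where the query gene is high — and Δ > 0 is LOF
(synthetic lethal). A single two-sided test with the direction read from
the sign of Δ avoids the α-doubling of two one-sided tests.

**Test mechanics.** Exact null distribution when the pooled sample has
≤ 20 observations without ties; otherwise normal approximation with
midranks, tie correction and continuity correction (scipy's
`mannwhitneyu` supplies both regimes). Genes with fewer than `min_obs`
(default 3) scores per group are skipped rather than reported with p = 1,
so the output never contains artificially non-significant records.

**Multiplicity.** Significance is by raw p < α (default 0.05), matching
how such screens are normally reported when hits feed into experimental
validation; Benjamini–Hochberg q-values over the tested genes of each
dataset are emitted as an informational column. Note that step-up BH is
*not* idempotent in general (e.g. p = (0.01, 0.5) adjusts to (0.02, 0.5),
which adjusts again to (0.04, 0.5)); only the standard single application
is provided.

**Consensus.** Datasets from different technologies are screened
independently — RNAi and CRISPR scores live on different scales and are
never pooled — and reconciled per gene: ≥ 1 GOF and 0 LOF ⇒ GOF (LOF
symmetric); both directions ⇒ inconsistent; otherwise none. Absence from
a dataset contributes no direction.

**Ranking.** Within each dataset, significant genes are ordered by
decreasing |Δ|, then non-significant ones likewise; whether to rank by
signed or absolute difference was an open choice, and absolute value with
the sign reported separately keeps GOF and LOF hits comparable on one
scale.

**Coexpression.** Spearman ρ uses midranks; p comes from the
t-approximation for n > 10 and from exact enumeration of all n! rank
pairings for n ≤ 10 (the denominator is permutation-invariant, so only
cross-products are enumerated, in vectorized chunks). The |ρ| ≥ 0.2 flag
is the conventional, admittedly arbitrary, detection threshold.

## Over-representation analysis

Hypergeometric upper tail P(X ≥ k) with universe N = genes actually
tested in the screen (the essentiality coverage defines the sampling
frame; using the genome would inflate enrichment), K = set ∩ universe,
n = hits. One-tailed enrichment only; depletion is not reported. BH FDR
across the sets of a collection.

## Logistic growth and relative knockdown effect

N(t) = K·N₀/(N₀ + (K − N₀)e^(−rt)), fitted per replicate by bounded
least squares. "Proliferation rate" means r (1/h): it is the only
rate-like parameter of the curve. Initialization: N₀ from the first
observation (clipped ≥ 0.1%), K = 1.05 × max observation, r from the
log-linear slope of the first half of the series; bounds r ∈ [−1, 1] 1/h
(negative rates are flagged, not rejected), K, N₀ ∈ (0, 200]%.
Convergence additionally requires K > N₀ > 0. A constant series returns a
non-converged fit with a diagnostic instead of raising, since plate scans
routinely contain dead wells. All points are weighted equally — no
variance model is assumed.

The relative effect of a knockdown is (r_target − r̄_control)/r̄_control
per target replicate against the mean control rate of the same cell line
(replicate-level fits propagate biological scatter into the reported SD;
fitting the replicate mean would hide it). 0 = no effect, −1 = complete
arrest, positive = growth activation.

## 4PL dose-response and profile-likelihood IC50 intervals

f(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill), hill > 0, fitted with
the IC50 on the log10 scale. Untreated (c = 0) wells enter exactly
through the top plateau ((c/IC50)^hill → 0), so they constrain the fit
without a log-scale dodge. Design requirements: ≥ 5 distinct positive
doses spanning ≥ 1.5 log10 units. A series with no dose-dependent decline
(Spearman ρ of response vs dose ≥ 0) is flagged non-converged.

The 95% CI for the IC50 is the likelihood profile: RSS(log10 IC50),
re-minimized over the other three parameters, intersected with
RSS_min · (1 + F(0.95; 1, n−4)/(n−4)). Bracketing proceeds in 0.25-decade
steps to ±6 decades (an unreached side is reported at that scan limit,
i.e. effectively unbounded), then Brent root-finding at 10⁻⁴ decades.
Profile intervals reproduce the strongly asymmetric intervals seen in
sparse cytotoxicity designs, which symmetric Wald intervals cannot.
Measured over 500 simulated titrations (8 doses 1–1000 µM, duplicate
wells, response noise SD 0.05), interval coverage of the true IC50 is
0.94 (test suite).

## Binding models

**Ligand-depletion quadratic.** For n independent sites, B =
((nP + L + K_d) − sqrt((nP + L + K_d)² − 4nPL))/2, evaluated in the
product form 2nPL/(s + sqrt(s² − 4nPL)) to avoid catastrophic
cancellation when K_d is tiny. B ≤ min(nP, L) always; the P → 0 limit is
the familiar hyperbola L/(L + K_d).

**ITC forward model.** Cumulative dilution factor f_i = Π(1 − dV_j/V0),
protein P_i = P0·f_i, cell ligand L_i = Ls(1 − f_i), and
q_i = V0·ΔH·(B_i − B_{i−1}(1 − dV_i/V0)) + q_dil. This is the standard
instantaneous-displacement treatment of a perfusion cell; it is verified
by internal consistency (round-trip fits and the conservation limit
Σq → n·ΔH·P0·V0 for K_d → 0 with excess ligand), not against any
instrument's unpublished correction. q_dil is a constant per-injection
offset, the fitting analogue of subtracting a buffer blank titration.

**ITC fitting.** Least squares over (log10 K_d, n, ΔH, q_dil), scaled per
parameter. Initialization: n = 1; ΔH from the first two injections per
mole of ligand delivered (minus the tail-estimated q_dil); K_d from the
molar ratio at the steepest heat change; q_dil from the last two
injections. Titrations need ≥ 8 injections. Fits with c = n·P0/K_d < 1
are flagged `low_c` (shallow isotherms cannot pin n and K_d separately);
fits whose total binding heat is < 2% of the summed |q| are flagged
`no_binding`.

**Direct binding.** Signal = S_free + (S_bound − S_free)·B/P with B from
the quadratic at stoichiometry 1; fitted over (log10 K_d, S_free,
S_bound). Needs ≥ 6 distinct positive ligand concentrations spanning
≥ 1.5 decades; a flat signal series is returned flagged `degenerate`.

## Synthetic data

The screen generator emulates a pan-cancer corpus: defaults of 1028 cell
lines and four screening datasets (alternating RNAi/CRISPR labels) match
the scale such compendia actually have; 3000 genes is a desk-scale
default (a genome-wide 18k-gene corpus changes nothing statistically,
only runtime). Query expression is Normal(5, 1) on the log2 scale;
background essentiality is Normal(0, σ) i.i.d.; a planted GOF gene's
scores are shifted by −δ·σ·z per line, where z is the line's standardized
query expression and δ = 1.5 by default (LOF: +δ); 5% of essentiality
entries are deleted uniformly at random. Coupling is linear in z rather
than thresholded at the screen's own quantile cut, so the planted truth
does not leak the analysis's stratification rule into the data.

What the generator does *not* model — lineage and copy-number structure,
batch effects between screening technologies, off-target reagent
effects, heteroscedastic scores for essential genes — bounds what passing
tests show: the pipeline is correct and calibrated under clean
exchangeable nulls, not robust to confounding, which real analyses
address with covariates out of scope here.

Assay generators add i.i.d. Gaussian noise to the exact forward models:
confluency every 8 h to 120 h (16 points, noise SD 2% confluency,
clipped to [0, 100]); 8 doses log-spaced 1–1000 µM in duplicate (noise SD
0.05, floored at 0); ITC geometry of 0.5 mM ligand titrated in 20 × 2 µl
injections into 0.17 ml of 25 µM protein. Every generator is a pure
function of (config, seed) via `numpy.random.default_rng`.

## Problem sizes and determinism

The validation suite runs the screen at 600 lines × 3000 genes (power)
and 500 × 5000 (calibration), 100 growth fits, 500 dose-response fits and
100 ITC fits — sizes chosen so each property is measured with useful
Monte-Carlo precision while the whole suite stays interactive. All
randomness flows from explicit seeds; there is no global random state,
and the CLI's end-to-end outputs are byte-identical under a fixed seed
(timestamps live only in the run manifest, never in result tables).

## Known limitations

- No covariate adjustment (lineage, copy number) or continuous-expression
  regression variant of the screen; quantile stratification only.
- Enrichment is the hypergeometric ORA, not a weighted-KS GSEA; results
  on the same hit lists will differ from GSEA outputs.
- The ITC model is single-site; multi-site, cooperative and competition
  titrations are out of scope, as is raw power-trace integration.
- Dose-response assumes a monotone 4PL; biphasic responses are rejected
  as non-converged rather than modeled.
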