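# Methods

## Data model and scope

The unit of analysis is a case–control study of a biallelic SNP (alleles C
and T), summarised by genotype counts (TT, TC, CC) per group plus
stratification metadata: country, control source (hospital-based HB vs
population-based PB), sample-size class, and cancer-subtype label. The
bundled dataset holds 14 such studies of *PRKAA1* rs13361707 and gastric
cancer. Two of its rows are sub-studies that reuse a single control series
of 3,227 subjects; they carry a common `shared_control_key`. Pooled analyses
use the rows exactly as tabulated (so those controls are double-counted, as
in the per-row Ns of the source tables), while subject-level summaries —
the 14,792 unique-control total and the control allele frequency —
deduplicate by that key. Both conventions are reported side by side in the
analysis report because both totals are meaningful.

The subtype labels are stored as printed in the source table even though
its own subtype-stratified summary rows cannot be reconciled with them;
subgroup analyses stratify by the stored labels and make no attempt to guess
a different grouping.

## Genetic models

Five dichotomisations of the genotype are supported: allelic (T vs C),
homozygote (TT vs CC), heterozygote (TC vs CC), dominant (TT+TC vs CC),
recessive (TT vs TC+CC). The allelic model counts the 2n alleles of n
subjects as independent observations — standard practice, exact only under
Hardy–Weinberg equilibrium, and documented here as an approximation. The
homozygote/heterozygote contrasts drop the excluded genotype rather than
erroring (the conventional per-genotype OR); a contrast that empties a 2×2
margin raises a degenerate-contrast error instead of producing a table.

## Hardy–Weinberg testing

Controls are checked against HWE with the plain Pearson chi-square on the
three genotype cells (expected np², 2npq, nq²; df = 1), without Yates
correction and without an exact test — the variant that matches the
published per-study column. Of the 14 published values, 11 agree with this
computation under half-up rounding at 2 dp and the other three (0.9853,
0.9589, 0.6755 printed as 0.98, 0.95, 0.67) only under truncation; the
source column evidently mixes rounding conventions, so the regression test
asserts agreement within one unit of the printed last digit. A monomorphic
group (p = 0 or 1) is an error, since the expected counts degenerate.

## Effect estimation and pooling

Per-study: log OR with the Woolf SE; when any cell is zero, 0.5 (the
`cc_increment` parameter) is added to all four cells of that study only
(Haldane–Anscombe). The bundled data have no zero cells, so this path only
affects general inputs. CIs use the exact 97.5% normal quantile
(1.959964…), not 1.96.

Heterogeneity: Cochran's Q from inverse-variance fixed weights (the
DerSimonian–Laird convention), Higgins I² = max(0, (Q−df)/Q), and the DL
moment estimator τ̂² = max(0, (Q−df)/(Σw − Σw²/Σw)). A single study returns
the degenerate convention Q = 0, df = 0, P = 1, I² = τ² = 0.

Fixed-effect pooling defaults to the Mantel–Haenszel point estimate with
the Robins–Breslow–Greenland variance of the log OR; this — not plain
inverse-variance — reproduces the published hospital-based heterozygote
upper bound of 0.84. Inverse-variance fixed pooling is retained as an
option and underlies Q and τ². Random effects are DerSimonian–Laird; with
τ̂² = 0 the DL result coincides bit-for-bit with IV fixed pooling.

Model selection follows the operational rule consistent with the published
result tables: the Q-test P-value below the threshold (default 0.10,
strict inequality) selects random effects, otherwise Mantel–Haenszel fixed
effects. (The prose description of this rule in the source is
self-contradictory; the table-consistent direction is implemented.)
Significance of the pooled OR is the two-sided normal Z-test on
log OR / SE.

## Publication bias and sensitivity

Egger's test is the unweighted OLS regression of θ̂ᵢ/SEᵢ on 1/SEᵢ with the
intercept t-statistic on k−2 df (k ≥ 3 required); the regression is
delegated to statsmodels. Begg's test standardizes deviations from the IV
fixed mean by √(vᵢ − 1/Σw), takes Kendall's S against the variances, and
uses the tie-corrected normal approximation; the continuity-corrected z is
available behind a flag but off by default. Both tests always use crude
per-study effects. On the bundled allelic effects this yields Egger
t = −0.480 (P = 0.640, df = 12) and Begg S = 7, z = 0.383 (P = 0.702);
an independent reference implementation (metafor's `regtest`/`ranktest`)
agrees to all printed digits, while the values quoted in the source
publication (t = −0.49, z = 0.44) differ slightly in the last digits and —
for Begg — match the recessive model's continuity-corrected statistic
instead, suggesting its example was quoted from a different run.

Leave-one-out sensitivity re-runs the full pipeline (effects → Q →
selection → pooling) on each k−1 subset, in input order. "The conclusion
changed" is operationalized as: the CI's inclusion of OR = 1 differs from
the full analysis. On the bundled allelic data, two omissions (the first
and third sub-studies of the shared GWAS publication) give upper bounds of
0.9998 — intervals that exclude 1 by 2×10⁻⁴ at full precision yet print as
1.00 at the conventional 2-dp display; robustness claims are therefore
judged at printed precision, and the full-precision bounds are always
available in the report.

Subgroup analysis groups on any categorical metadata column
(trimmed, case-insensitive matching), pools each stratum with its own
heterogeneity test and model selection, and reports single-study strata as
trivially pooled (k = 1) rather than erroring.

## Synthetic data

`simulate_study` draws control genotypes from a multinomial with HWE
probabilities (p², 2pq, q²) at a specified T-allele frequency, and case
genotypes from the same probabilities exponentially tilted by
exp(g·logOR), renormalized, where g is the dose the chosen genetic model
assigns to each genotype — (2, 1, 0) allelic, (1, 1, 0) dominant, (1, 0, 0)
recessive/homozygote, (0, 1, 0) heterozygote. Under HWE this tilt makes the
population allelic odds ratio exactly exp(logOR) for the allelic dose
(odds of a case chromosome carrying T are e^θ·p/q), and the per-genotype
odds exact for the indicator doses; finite-sample estimates still scatter,
so recovery checks carry tolerances. `simulate_meta` draws per-study true
log ORs from Normal(μ, τ²), sizes uniformly from configured ranges, and
fills metadata strata round-robin (two countries, HB/PB) so subgroup code
paths are exercisable. Default conditions mirror the bundled dataset:
k = 14 studies, control T-allele frequency 0.55 (the East Asian value),
per-arm sizes 60–3,245.

Each study consumes an independent substream spawned from the single seed
with a fixed per-study key, so enlarging k appends studies without
reshuffling earlier ones, and identical configurations are byte-identical.

What the generator does *not* emulate: linkage disequilibrium, covariates
and confounding, population stratification, genotyping error, shared
control series, or selective publication. Passing calibration tests
therefore demonstrate the estimators' statistical behaviour under the
stated sampling model, not robustness to those real-data complications.

## Numerical and reporting choices

- Display rounding is half-up (decimal, not binary) at 2 dp for ORs/CIs and
  3 dp for P-values; full-precision values always accompany display strings
  in the JSON report, and a P printed as "0.000" means < 0.0005.
- The JSON report is deterministic for fixed input and settings (sorted
  keys, no timestamps) and is validated against a shipped structural
  schema on write.
- No multiple-testing adjustment is applied anywhere; all P-values are raw
  and the report says so in a notes field.
- Study tables are UTF-8, comma-delimited by default with a tab dialect
  auto-detected from the header; counts must be plain integers without
  thousands separators.

## Test problem sizes

The calibration suites use sizes chosen to make Monte-Carlo error small
relative to the asserted bands while keeping the whole suite fast on one
CPU: HWE null uniformity at 10,000 groups of n = 500; Q-test size at 1,000
simulated 14-study meta-analyses; bias-test size at 1,000 replicates of
k = 14; fixed-CI coverage at 2,000 meta-analyses of k = 10 with 300
subjects per arm; DL parameter recovery at k = 200 studies of 2,000–3,000
per arm. Estimator equivalence against independent brute-force formulas is
asserted at 10⁻¹⁰ on 100 random small inputs.

## Known limitations

- Only the Woolf/MH/DL toolkit is offered: no Peto OR, Hartung–Knapp,
  REML/Paule–Mandel τ², meta-regression, trim-and-fill or fail-safe N.
- HWE testing is the asymptotic chi-square only (no exact test), biallelic
  autosomal only.
- The allelic contrast's independence assumption is inherited from the
  literature it reproduces.
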