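# Methods

## The adjusted response variable

The primary quantity is the achieved percentage of the expected LDL-C
reduction, `P = 100·Δ%/E`, with `Δ% = 100·(pre − post)/pre`. The point of
the normalisation is to compare patients on *different* maximal regimens:
a 45% reduction is excellent on atorvastatin 10 mg (E = 40) and mediocre
on atorvastatin 80 mg + ezetimibe. `P` is computed at full precision and
rounded (half away from zero, one decimal) only at report boundaries;
negative responses are retained, and `P` is not capped at 100.

Assumptions baked into `P`:

* The expected reductions are population averages from trials; applying
  them per patient assumes the regimen effect is multiplicative on
  baseline LDL-C and dose-equivalence across statins holds.
* The evolocumab add-on expectation (54%) is applied against the LDL-C on
  the background regimen, so the background and add-on phases are
  assessed independently.

## Regimen efficacy table

Expected reductions: 40/46/52/56% at atorvastatin-equivalent 10/20/40/80
mg/day, 61/66% at 20/40 mg with ezetimibe. The 80 mg + ezetimibe entry is
not published; the default of 70% extrapolates the ≈14-point ezetimibe
increment observed between the 40 mg rows and is flagged in the log
whenever used — override it in the YAML config if a different convention
is preferred. The potency ladder (rosuvastatin 5/10/20/40 ↔ atorvastatin
10/20/40/80; simvastatin 20/40/80 ↔ 10/20/40; pitavastatin 2/4 ↔ 10/20)
is pinned only at the moderate-intensity rung by the escalation protocol;
the rest follows standard intensity classifications and is configurable.
Unknown agents and intermediate doses fail loudly rather than guess.

## Variant classification

LDLR variants are null when they are predicted to produce no functional
receptor: stop-gains, frameshifting indels, exon-level rearrangements,
and missense variants in the fifth cysteine-rich repeat (LR5) of the
ligand-binding domain. Everything else in-frame — other missense,
in-frame indels, promoter/regulatory variants — is defective. The LR5
residue interval is not standardised; the default (195, 232), in
mature-protein numbering, is an explicit config value and tests exercise
its overridability. The numbering convention must match between the
variant table and the interval (a ±21 shift if the signal peptide is
counted). APOB/PCSK9 variants are pathogenic for FH but outside the
null/defective dichotomy.

Patient grouping counts pathogenic alleles: zero → PV-negative; one →
LDLR-null / LDLR-defective / APOB-PCSK9 by the variant; two (homozygous
or compound heterozygous — rarely distinguishable in registry data, so
one combined group) → compound/homozygous, with a flag for whether any
allele is null. More than two alleles is rejected.

## 4-SNP score

`S = Σ βᵢgᵢ / Σ βᵢ` — a weighted mean of effect-allele dosages, bounded
in [0, 2]. The published description ("weighted mean") does not pin the
normalisation; the unnormalised sum `Σ βᵢgᵢ` is available by flag, and
because the two differ by a constant factor, regression R² and p-values
against any outcome are identical under either. Negative betas are
reoriented internally (dosage → 2 − g, β → |β|), making the score
invariant to allele-coding flips. Missing dosages renormalise over the
observed SNPs; all-missing patients are excluded, never imputed. The
shipped weight file is a clearly-labelled synthetic placeholder — the
real East-Asian GWAS betas are inputs, not package claims.

## Statistics

* **Quantiles**: type-6 (`h = (n+1)p`, linear interpolation, clamped),
  via `numpy.quantile(method="weibull")`. This is the rule that
  reproduces the published six-patient interquartile ranges exactly, and
  it is the SPSS percentile default; type-7 (numpy's default) does not
  reproduce them.
* **Mann–Whitney U**: exact enumeration when `n1·n2 ≤ 400` with no ties;
  otherwise normal approximation with mid-ranks, tie-corrected variance,
  and *no* continuity correction (the SPSS asymptotic convention).
  Without the correction the worst-case deviation from the exact p at
  n1 = n2 = 10 is 0.034 (exhaustively enumerated); the property test
  asserts that bound.
* **Contingency**: Pearson chi-square without Yates correction; 2×2
  tables with any expected cell < 5 fall back to Fisher's exact test,
  recorded in the result.
* **Regression**: OLS with the t-test p for the slope; fitted on the full
  cohort, on patients without any null variant, and on PV-negative
  patients. Two-sided tests at α = 0.05 throughout; no multiplicity
  adjustment (none is applied in the source analyses this mirrors).

## Synthetic cohort generator

The generator's defaults encode the registry structure: 83 patients in
proportions 53/10/17/3 (PV-negative / LDLR-null / LDLR-defective /
APOB-PCSK9); baseline LDL-C log-normal around group medians
206/256/248/205 mg/dL with log-sd 0.15 (right-skewed, IQR-scale
dispersion); regimens drawn from the observed maximal-regimen frequencies
with an escalation bias (`odds × 1.8^±rank`) that pushes PV-positive
patients toward higher-intensity regimens, as observed; independent
binomial(2, pᵢ) dosages with placeholder frequencies 0.35/0.25/0.45/0.30.

The response model is multiplicative on the expectation:

```
P  = 100·f_g − 100·c·(S − E[S]) + ε,   ε ~ N(0, σ_P)
Δ% = min(100, P·E/100),  post = pre·(1 − Δ%/100)
```

with group factors `f_g` = 0.953/0.769/0.886/0.895 (group medians of P),
noise σ_P = 30 points (back-solved from the published interquartile width
of P, ≈ 43 points), and score effect `c` = 0.21 per score unit,
calibrated so the score explains R² ≈ 0.045 of P at n = 83. Centring the
score term on `E[S] = Σβ·2p/Σβ` keeps `f_g` interpretable as the group's
median achieved fraction regardless of `c`. A single seed fans out into
named substreams (group, baseline, regimen, agent, genotype, response,
variant, follow-up) so adding a stage never perturbs earlier draws and a
fixed seed reproduces byte-identical tables.

What the generator does *not* emulate: linkage disequilibrium between
the SNPs, family structure, visit-level longitudinal dynamics, adherence,
and the correlation between baseline LDL-C and response beyond the group
structure. Consequently the simulated target-attainment rate runs higher
than the registry's (the noise tail creates strong responders the real
cohort lacked), and passing calibration tests demonstrate that the
*pipeline* recovers what the generator encodes — not that the generator
reproduces every marginal of the real data.

Calibration checks run at two scales: a single n = 2000 cohort with noise
σ_P = 15 and a 12.5-point group difference must recover the group medians
within ±2 points; 200 such replicates must reject the null in ≥ 95%; and
1000 null replicates at the registry size (n = 83, equal factors) must
reject in 5% ± 2%. These sizes keep the default suite within a few
minutes on one CPU while leaving the Monte-Carlo error well inside the
asserted bands.

## Numerical and degenerate-input choices

Rounding is half-away-from-zero (via `decimal`), matching clinical table
conventions rather than banker's rounding. Percent reductions chain at
full precision — recomputing `P` from a rounded `Δ%` visibly corrupts the
one-decimal reproduction of reference values. Constant-y regressions
return slope 0 / R² 0 / p 1; constant-x raises. Empty samples, all-zero
contingency margins, zero betas, dosages outside {0, 1, 2}, and
non-positive baselines all raise typed errors rather than propagating
NaNs. Patients with unmappable regimens are excluded row-by-row with
reasons and the accounting `n_analysed + n_excluded = n_input` is part of
every report.

## Known limitations

Three of the published per-patient achieved-percentage cells (27.5, 52.2,
34.0) are not reproducible from their own printed pre/post LDL-C pairs
under the uniform 54% add-on rule, which yields 21.9, 41.6 and 36.6; the
package implements the stated rule and documents the discrepancy rather
than fitting per-patient expectations. The LR5 interval and the
equivalence ladder beyond the moderate-intensity rung are conventions,
not published coordinates. The shipped SNP weights and allele frequencies
are placeholders for machinery testing only.
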