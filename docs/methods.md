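# Methods

This note documents the statistical conventions, defaults, and numerical
choices the package makes, and what its synthetic-data experiments do and
do not demonstrate.

## Data model and harmonization

A `VariantAssociation` is one variant's record in one GWAS: alleles,
optional effect-allele frequency (eaf), effect size, SE, and p-value.
Binary-trait effects reported as odds ratios are converted with the natural
logarithm at ingestion and flagged (`from_odds_ratio`); all downstream
arithmetic is on the log-odds scale.  P-values parsed from text are floored
at 1e-300 because published GWAS p-values (down to ~1e-343 in the bundled
tables) underflow IEEE doubles to zero.

Instrument selection keeps variants with p below the genome-wide threshold
(default 5e-8).  A variant absent from the outcome study may be replaced by
an LD proxy with r² ≥ 0.40, ranked by (1) highest r², (2) smallest absolute
distance to the lead, optionally (3) non-palindromic alleles, with the
proxy rsid as a deterministic final tie-break.  The proxy's own exposure
association is used as reported — no r²-rescaling — matching the treatment
of proxies in the bundled tables.  A proxy row inherits its lead's
discovery-stage significance, so its p-value in the analysis subset may
exceed the selection threshold (the bundled reverse table contains such
rows; the set constructor logs, rather than rejects, this condition).

Harmonization matches by rsid (positions are annotation only, since builds
differ between studies), orients the outcome effect onto the exposure's
effect allele (allele swap → negate beta, complement eaf), and attempts a
strand flip (allele complementation) for non-palindromic mismatches before
declaring alleles incompatible.  Palindromic variants (A/T, C/G) are
excluded by default regardless of frequency — the convention of the source
analysis, whose tables flag palindromes at eaf 0.22 and 0.82 as excluded.
An opt-in policy (`keep_inferable_palindromic`) retains palindromes whose
minor-allele frequency is clearly below 0.42 (configurable) in both
studies, using frequency agreement to resolve the strand.  Indel alleles
are never classified palindromic (strand logic is undefined); they
harmonize only by exact or swapped match.

## Estimators

With J harmonized instruments (β_Xj, σ_Xj, β_Yj, σ_Yj) and weights
w_j = σ_Yj⁻²:

* **Wald ratio** (J = 1): θ̂ = β_Y/β_X, SE σ_Y/|β_X| (first-order delta).
  A second-order option adds β_Y²σ_X²/β_X⁴ under the root but is not the
  default: the first-order form reproduces the published single-SNP SEs
  digit for digit in the reverse direction.
* **IVW** (J ≥ 2): θ̂ = Σw β_X β_Y / Σw β_X², the weighted least-squares
  slope through the origin.  Default SE is multiplicative random effects:
  the fixed-effect SE times max(1, √(Q/(J−1))).  The floor means
  under-dispersion never *narrows* the interval.  P-values are standard
  normal.
* **MR-Egger** (J ≥ 3): instruments are first oriented so every β_Xj > 0
  (the intercept is only defined up to this convention), then a weighted
  regression with intercept is fit.  Both SEs carry a residual scale
  max(1, Q/(J−2)); inference is t with J−2 df.  This combination
  reproduces all four printed reverse-direction Egger numbers exactly.
* **Weighted median** (J ≥ 3): ratio estimates weighted by (β_X/σ_Y)²;
  sort, accumulate standardized weights s_j = (Σ_{k≤j} w_k − w_j/2)/Σw, and
  interpolate θ at s = 0.5.  SE from a parametric bootstrap (default 1000
  draws, seed required): both betas are perturbed by their Gaussian SEs
  while the weights stay fixed, the convention of the original estimator's
  published code.
* **Mode-based estimate** (J ≥ 3): mode of a Gaussian-kernel density of
  the ratios on a 512-point grid spanning the data range ± 3 bandwidths.
  Bandwidth = φ · 0.9 · min(sd, mad) · J^(−1/5) with φ = 1 and mad scaled
  to the normal (×1.4826), the modified-Silverman rule of the MBE
  literature.  If all ratios coincide the mode is that value.  Weighted
  variant uses normalized (β_X/σ_Y)² weights.  The published simple/
  weighted mode rows do not state their kernel settings, so these point
  estimates are validated approximately (±0.05), not digit-exactly.
* **MR-PRESSO** (J ≥ 4): the observed statistic is
  RSS = Σ w_j (β_Yj − θ̂₍₋ⱼ₎ β_Xj)² with leave-one-out IVW estimates, so a
  gross outlier cannot mask itself.  The null is simulated (default 1000
  draws): β*_Yj ~ N(θ̂₍₋ⱼ₎β_Xj, σ_Yj), recomputing the leave-one-out
  estimates per draw.  Global p = (1 + #{RSS* ≥ RSS})/(n_sim + 1); per-SNP
  outlier p-values use each SNP's simulated residual distribution with
  Bonferroni adjustment, outliers at adjusted p < 0.05.  The raw estimate
  is the IVW-type weighted regression with SE scaled by √(RSS_w/(J−1))
  (no floor) and t inference at J−1 df.  When outliers exist, the corrected
  estimate refits without them and a distortion test compares raw vs
  corrected against a null built by removing random same-size subsets of
  non-outlier instruments.  Instruments are sign-oriented before
  simulation, which makes all outputs bit-invariant under instrument
  re-orientation and bit-reproducible for a fixed seed.

All estimators consume only included instruments (proxy-substituted rows
count as included) and record the count used.

## Diagnostics

Cochran's Q is the weighted residual sum of squares of the no-intercept
(IVW, df J−1) or with-intercept (Egger, df J−2) fit, with an upper-tail
chi-square p-value.  Leave-one-out rows re-run the *default* IVW
(multiplicative random effects with the SE floor) on each J−1 subset; the
TSV report also prints the unfloored SE since the floor convention can
decide borderline significance for small J.  Funnel data pair each ratio
estimate with its precision |β_X|/σ_Y.

The F-statistic implements the standard multi-instrument form
(R²/(1−R²))·(n−k−1)/k from the exposure study's R², sample size n, and
instrument count k.  For the bundled forward study (R² = 0.0284,
n = 79,366, k = 6) this gives F ≈ 386.6.  The source analysis prints
F = 1558.762 (forward) and 21,867.14 (reverse), which are not reproducible
from any standard formula with the stated inputs; the package reports its
own formula's value and documents the discrepancy rather than emulating an
unknown computation.  Either way F ≫ 10, so the weak-instrument conclusion
is unaffected.

## Power

For a binary outcome the two-sided Wald test of the causal log odds ratio
b has non-centrality parameter NCP = N·R²·K(1−K)·b², giving
power = Φ(√NCP − z₁₋α/₂) (the opposite-tail term is negligible and
conventionally dropped — hence power → α/2 as OR → 1).  The minimal
detectable OR inverts this in closed form; the round-trip identity holds to
1e-10.  With the bundled outcome study (N = 53,293, K = 19,099/53,293,
R² = 0.0284): detectable OR at 80% power = 1.162, and power at OR 1.27
exceeds 0.99 — matching the published claims of "1.159" and "100%" at
their rounding.  The European-subset sample size is the default; the full
ADHD sample is accepted input if a user prefers it.

## Synthetic data

The generator draws true exposure effects γ_j, direct (pleiotropic) outcome
effects α_j — optionally correlated with γ_j to violate InSIDE — and sets
the true outcome effect to θγ_j + α_j.  Observed statistics add Gaussian
noise: the exposure SE is |γ_j|/z_gw scaled by √(n_ref/n_exposure)
(z_gw the two-sided genome-wide z ≈ 5.45; n_ref = 20,000 by default, so the
default 79,366-sample exposure clears p < 5e-8 with overwhelming margin);
the outcome SE is the standard GWAS approximation
1/√(2p(1−p)·N·K(1−K)) for a binary outcome (1/√(2p(1−p)·N) continuous),
with eaf p drawn uniformly on a configurable range.  For common alleles at
the bundled study's N and K this lands on 0.012–0.017, matching the
magnitude of the real outcome SEs.  Palindromic allele pairs and
missing-from-outcome variants are injected on request.  Scenario defaults
emulate the forward study: six instruments, γ ~ N(0.04, 0.03²), binary
outcome with N = 53,293 and K = 0.358, one palindrome in six, θ = 0, no
pleiotropy.

What the generator does *not* emulate: linkage disequilibrium between
instruments (the real instruments are independent loci), allele-frequency–
dependent effect sizes, sample overlap between studies, and winner's-curse
inflation of discovery effects.  Passing recovery tests therefore
demonstrate correctness of the estimators under their own assumptions, not
robustness to these real-data complications.

Recovery experiments derive per-replicate seeds deterministically from the
scenario seed, report bias, empirical and mean estimated SE, 95% coverage
and rejection rates, and count (rather than fail on) replicates where an
estimator cannot run.  Two caveats the experiments make visible: the Egger
intercept identifies mean directional pleiotropy only in the
positive-oriented frame and only when exposure-side measurement error is
small relative to the spread of true effects (otherwise regression dilution
leaks causal signal into the intercept); and the weighted median's
robustness advantage requires the invalid instruments' offsets to be large
relative to the sampling noise of the ratio estimates.

## Problem sizes and reproducibility

The bundled analyses are desk-scale (5–6 instruments; every published
number recomputes in well under a second).  Stochastic components — median/
mode bootstraps (default 1000 draws), MR-PRESSO simulation (default 1000),
recovery experiments (500 replicates at 100 instruments in the test suite)
— take explicit integer seeds and are bit-reproducible; two runs of the
pipeline with the same configuration and seed produce byte-identical JSON
reports.  Bootstrap SEs at 10,000 draws agree across seeds within
Monte-Carlo error (≈ se/√(2n)).

## Known limitations

- No multivariable MR, Steiger directionality filtering, I², or
  Rücker model-selection framework (both Q statistics are reported).
- Proxy search consumes a user-supplied LD table; the package performs no
  LD computation or online lookups.
- The distortion test is exercised only on synthetic planted-outlier data;
  neither bundled direction yields outliers.
- Forward-direction published values are reproducible only within the
  rounding of the source table's two-significant-figure exposure effects;
  the test suite encodes those bounds explicitly (3% relative or 0.002
  absolute).
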