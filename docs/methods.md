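# Methods

## Setting and assumptions

Two-sample Mendelian randomization treats genetic variants as instruments
for an exposure and requires three conditions: the instruments associate
robustly with the exposure (relevance), affect the outcome only through the
exposure (exclusion restriction), and are independent of confounders of the
exposure-outcome relationship. The package operationalises these as, in
order: a genome-wide significance filter with LD clumping and per-SNP
F-statistics; pleiotropy diagnostics (Egger intercept, RSS outlier test);
and a user-supplied exclusion list of SNPs known to associate with
confounding traits (the package performs no live database lookups — the
list is an input, so runs are reproducible and offline).

All effects are per-allele log odds ratios. Exposure and outcome samples
are assumed non-overlapping and from the same ancestry group; the package
does not check either.

## Instrument selection

`filter_significant` uses a strict inequality (p < threshold), with
5×10⁻⁸ the conventional default and 5×10⁻⁶ the relaxed threshold used for
small exposure GWAS. `ld_clump` is the standard greedy procedure: take the
most significant remaining SNP as an index, remove same-chromosome SNPs
within the window (default 10,000 kb) with r² ≥ the threshold (default
0.001), repeat. Ties in p break lexicographically by snp_id so output never
depends on input order. LD is an injected dependency — a pairwise r² table —
because the package deliberately ships no reference panel; with
`strict=False`, pairs absent from the table are treated as r² = 0
(distance-only fallback) with a warning. Published instrument counts
obtained against a specific reference panel are therefore not exactly
reproducible without that panel; the algorithm, not the panel, is the
contract here.

Instrument strength: R² = 2·EAF·(1−EAF)·β² and F = R²(n−k−1)/[k(1−R²)].
The default is per-SNP (k = 1), matching how minimum-F values are usually
reported; `joint_strength` sums R² over the set with k = its size. F ≤ 10
flags a weak instrument (strict >). Records without EAF are flagged "not
scorable" rather than raising, since many public tables omit EAF. The
record's own n takes precedence over a trait-level n supplied by config.

## Harmonization

Matching is by snp_id only (no chr:pos fallback). Outcome alleles equal to
the exposure's are kept; swapped alleles flip the sign of beta_out and
reflect EAF; when neither matches, the pair is strand-complemented and the
two checks repeated; irreconcilable pairs are dropped. Palindromic SNPs
(A/T, C/G) carry no strand information in their alleles, so they are
aligned by EAF concordance, and dropped when either EAF is missing or the
exposure EAF lies within 0.08 of 0.5 (default window, i.e. EAF in
0.42–0.58) — a conservative, standard choice made here as a design
decision, since drop-versus-align conventions differ between studies.
Duplicate snp_ids within a trait keep the lowest-p row. No proxy-SNP search
is attempted for instruments missing from the outcome; they are dropped and
logged. Every exposure SNP appears in the output exactly once with an
action tag (kept, sign_flipped, dropped_palindromic, dropped_missing,
dropped_incompatible), which makes the bookkeeping auditable and gives the
count-conservation invariant the tests assert.

## Estimators

Wald ratio SEs use the first-order delta method only (se_out/|beta_exp|);
the second-order term is omitted deliberately — it changes SEs by O(1/F)
and would make the estimate surface depend on exposure SEs that some tables
omit.

IVW's random-effects variant is multiplicative: the fixed-effect SE is
scaled by √(Q/(k−1)), floored at 1 so random-effects SEs never undercut
fixed ones. `model="auto"` applies the conventional switch: fixed when the
Q-test p > 0.05, random otherwise. One SNP degenerates to its Wald ratio.

MR-Egger orients every SNP to beta_exp ≥ 0 before fitting (the intercept is
meaningless under mixed orientation), fits WLS with weights 1/se_out², and
uses multiplicative overdispersion floored at 1 for both slope and
intercept SEs. p-values use t with k−2 degrees of freedom; CIs use the
fixed normal quantile 1.959964 like every other method, so all reported
CIs are constructed identically (the t/normal mismatch is deliberate and
documented here).

The weighted median sorts ratios, normalises inverse-variance weights,
forms cumulative midpoints p_j = (S_j − w_j/2)/S_k, and interpolates at
p = 0.5. Its SE is a parametric bootstrap: resample (beta_exp, beta_out)
from normals centred at the observed values with the observed SEs, recompute
the median, take the SD over n_boot (default 1000) resamples; a single
`numpy` generator seeded per call makes estimates bit-reproducible.

## Sensitivity diagnostics

Cochran's Q is computed about the fixed-effect IVW mean with weights
1/se(θ̂)²; df = k−1. When the random-effects scale exceeds 1, Q equals
(k−1)·scale² by construction — an identity the tests assert. Leave-one-out
re-estimates IVW k times and flags exclusions that change the sign
conclusion of the 95 % CI (above the null / below / spanning). Funnel data
pairs each ratio with its precision; "approximate symmetry" is made
quantitative as the weighted skewness of ratios about the IVW estimate.

The outlier test follows the MR-PRESSO recipe: the observed global
statistic is the sum over SNPs of (beta_out − leave-one-out IVW
prediction)²/se_out²; its null distribution comes from n_sim (default 1000,
the published default) parametric simulations of beta_out under the
no-pleiotropy model, with the leave-one-out predictions recomputed inside
each simulation. Global p = (1 + #{RSS_sim ≥ RSS_obs})/(n_sim + 1), so it is
a proper Monte-Carlo p bounded below by 1/(n_sim+1). Per-SNP contributions
are compared with their own simulated distributions and
Bonferroni-adjusted over k; SNPs below 0.05 are outliers. When outliers
exist, the distortion p compares the relative change in the IVW estimate
after removal against removals of random subsets of the same size. Fewer
than 4 SNPs: reported as not applicable. The simulation matrix is
vectorised (n_sim × k), so the default settings cost milliseconds per pair.

## Multiplicity

BH-FDR and Bonferroni adjustments are computed from unrounded raw p-values
via statsmodels; the report layer rounds. The default family is the set of
exposures tested against one outcome (m = 6 in a six-disorder study) —
the grouping that reproduces published adjusted tables of this design —
configurable to per-exposure or global.

## Synthetic data generator

The generator emulates the data structure of a psychiatric-disorder /
cancer summary-statistics study, with all parameters fixed once as study
conditions:

- **Instrument count** 13 — the panic-disorder instrument count, the
  smallest exposure set in the motivating design and hence the conservative
  default.
- **Sample sizes** as effective n for case/control GWAS,
  n_eff = 4/(1/n_cases + 1/n_controls): exposure default 7,018 (from
  2,248/7,992) and outcome default 2,541 (from 636/455,640). The SE model
  is the continuous-trait approximation se = 1/√(2·EAF·(1−EAF)·n_eff).
- **Instrument effects** γ ~ N(0.15, 0.03) on the log-odds scale, chosen so
  per-SNP F falls in ≈ 25–80 at these sample sizes — instruments that have
  passed a selection threshold, matching reported minimum F values above
  ~20 for small-GWAS exposures.
- **EAF** ~ U(0.05, 0.95); alleles are assigned non-palindromic and
  positions are spaced 50 Mb apart so generated tables pass cleanly through
  harmonization and clumping.

Observed effects are beta_exp ~ N(γ, se_exp) and
beta_out ~ N(causal·γ + α, se_out), with pleiotropy α either absent,
balanced N(0, sd), or directional N(μ, sd). Scope of pleiotropy: with
`prop_invalid = 0` (default) a pleiotropy mode applies to *every*
instrument — the pervasive-pleiotropy scenario in which InSIDE holds by
construction and the Egger intercept estimates μ; with `prop_invalid > 0`
only that fraction of instruments is pleiotropic — the invalid-subset
scenario in which the weighted median retains consistency. p-values are
floored at 1e-300 to stay within (0, 1].

What the generator does **not** emulate: LD between instruments (clumping
is tested against explicit r² tables instead), winner's-curse selection of
instrument effects, sample overlap between the two GWAS, allele-frequency
mismatch between cohorts, and the exact binomial sampling of case/control
effect estimates (the effective-n Gaussian approximation is used). Passing
calibration tests therefore demonstrate correctness of the estimators under
the stated generative model, not robustness to those real-data features.

## Pipeline and numerical conventions

Per-pair seeds derive deterministically from the config seed (seed +
1000·exposure_index + outcome_index), so reruns are byte-identical and
pairs are independent of each other's presence. IVW model selection is
"auto" and the choice is recorded per pair in the manifest. Human-readable
tables round OR/CI/p to 2 decimals; machine tables keep full precision, and
every rendered number is traceable to an unrounded value. Pairs with too
few instruments are reported "not estimable" with the reason rather than
dropped. The CI multiplier is fixed at 1.959964 everywhere.

Problem sizes used by the calibration suite — 1000 null replicates for
type-I error, 500 for CI coverage, 300 for Egger-intercept recovery, 50
replicates × 1000 simulations for the outlier test — were chosen to bound
Monte-Carlo error at a few per cent, which the whole suite completes in
seconds thanks to the vectorised simulators.

## Known limitations

- No proxy-SNP lookup, no liftover, no VCF input, no SE imputation from
  p-values; records lacking required fields are logged and dropped.
- MR-Egger CIs use the normal quantile while its p-values use t(k−2); with
  very few SNPs the CI is therefore slightly narrower than the p-value
  implies.
- MR-Egger inherits the usual regression-dilution sensitivity: when the
  spread of true instrument effects is modest relative to their measurement
  error, the slope attenuates slightly and the intercept absorbs the
  difference, so intercept recovery under simulated directional pleiotropy
  is accurate only to within a small positive offset (visible in the
  calibration suite as a mean intercept a couple of Monte-Carlo SEs above
  the injected value).
- The distortion test uses random-subset removal rather than the original
  bootstrap refinement.
- Reverse-direction MR, multivariable MR, MR-RAPS and mode-based
  estimators are out of scope.
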