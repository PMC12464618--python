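# Methods

This note records the statistical model behind each component, the
conventions that matter for reproducing published numbers, and the
design choices made where more than one defensible reading existed.

## Effect estimates and the SE convention

All credibility metrics are computed from a pooled odds ratio and its
95% CI alone.  The log-scale standard error is derived from the *upper*
limit only,

    SE = (ln UCI − ln OR) / 1.96,

not from the full CI width, and the observed significance level is
always recomputed as α = 2(1 − Φ(|ln OR|/SE)) rather than read from a
printed (possibly truncated, e.g. "<0.0001") p-value.  These are the
conventions of the FPRP and BFDP calculator spreadsheets in common use,
and the only pair that reproduces published grids cell-for-cell; the
full-width alternative is available via `se_convention="full_width"`.
Protective estimates (OR < 1) are assessed on |ln OR| with the SE still
taken from the literal printed upper limit, so a harmful estimate and
its reciprocal carry the same evidence whenever the printed interval is
log-symmetric.  The 1.96 multiplier is used exactly (not Φ⁻¹(0.975),
not a t quantile) because published intervals are built with it.

Reproduction quality on the packaged evidence table: 17 of 23 rows
match every printed FPRP/BFDP cell to ≤ 0.002 (most to ≤ 0.0007); the
remaining six differ by up to 0.012, consistent with the source tables
printing rounded ORs/CIs while the original calculations used unrounded
values — one printed row is internally inconsistent (its FPRP cells and
its BFDP cell cannot be produced by any single OR/CI input).  The unit
suite pins exactly this set of input-limited rows.

## FPRP

FPRP = α(1−π) / (α(1−π) + (1−β)π), with power

    1 − β = 1 − Φ(z_c − μ) + Φ(−z_c − μ),   z_c = Φ⁻¹(1 − α/2),
    μ = ln(OR_target)/SE,

i.e. the probability that a two-sided test at the *observed* α rejects
when the true effect is the target OR.  Target ORs are stated above 1
(defaults 1.5 and 2.0; reciprocals implied for protective effects), and
priors default to the conventional candidate-gene expectations 0.05
(medium) and 0.001 (low).  In the zero-power limit FPRP is defined as 1.

A comparison is FPRP-noteworthy at prior π when FPRP < 0.2 at **all**
target ORs (configurable to "any" via `fprp_rule`).  The all-targets
rule is what published reappraisals apply — under the any-rule,
borderline comparisons with power only against large effects would be
promoted at strict priors, contradicting the published conclusions the
fixture tests assert.

## BFDP

Wakefield's normal-approximation Bayes factor with prior variance W
anchored at a 97.5th prior percentile OR of 1.5, W = (ln 1.5/1.96)².
BFDP is the posterior probability of the null; the noteworthiness
threshold 0.8 corresponds to a false non-discovery being four times as
costly as a false discovery.  The quadrature identity ABF =
N(θ̂; 0, V) / ∫N(θ̂; θ, V)N(θ; 0, W)dθ is verified to 1e-6 in the tests.

## Venice criteria

Domain boundaries, frozen here and in the tests:

* amount of evidence: A > 1000 subjects/alleles, B (100, 1000], C ≤ 100;
* consistency: A I² < 25%, B [25, 50], C > 50% (not applicable if I²
  unknown);
* protection from bias: not applicable when the Egger p is not
  calculable (fewer than three studies); C when Egger p ≤ 0.05 — the
  boundary p = 0.05 grades C, matching published usage — or when the
  pooled OR lies in the small-effect band [0.87, 1.15] (a small pooled
  effect is explicable by modest bias; rule switchable); B when the
  analyst flags potential concerns; A otherwise.

"Potential concerns" is an explicit analyst input (`bias_concern`
column) rather than a numeric heuristic: published gradings are not
monotone in the Egger p within the 0.05–0.10 band (0.061 graded B,
0.09 graded A), so a band heuristic cannot reproduce them.  An optional
`concern_band` exists for users who want one.

Overall: Strong only for AAA, Weak if any domain is C, Moderate
otherwise, N/A if any domain is not applicable.  Two rows of the
packaged table print grades that contradict these stated thresholds
(one AAA/S despite an OR inside the small-effect band; one consistency
B despite I² = 0); the tests assert them as known discrepancies rather
than bending the rules to fit.

## AMSTAR-2

Overall confidence from 16 Y/PY/N responses: more than one N on a
critical domain (items 2, 4, 7, 9, 11, 13, 15) → Critically low;
exactly one → Low; otherwise more than one non-critical weakness →
Moderate, else High.  PY counts as partial adherence (a non-critical
weakness), not a flaw, unless configured per item via `py_is_flaw_on`;
the packaged 32-review table rates 32/32 Critically low under either
setting.

## Pipeline

Parenthesized cells ("(0.045)") are estimated values and keep an
`estimated` flag; "<x" cells are upper bounds and are never used
numerically (α is recomputed from the CI); NA/NC cells propagate as
missing.  Deduplication keeps the largest study per (variant, contrast,
subgroup) — subgroups are never merged — and retains ties with a
warning.  A comparison is `credible_noteworthy` only when noteworthy at
the strictest prior *and* its Venice label is not Weak.  Report
probabilities are rounded half-up to 3 decimals (so a vanishing FPRP
prints 0.000) only at serialization; a JSON sidecar keeps full
precision and run metadata.

## Synthetic literatures

Per study i: θᵢ ~ N(ln OR_true, τ²); per-arm sizes log-uniform on the
configured ranges; control exposure count ~ Binomial(n₀, f); case
exposure count ~ Binomial(n₁, expit(logit(f) + θᵢ)).  Zero cells get
the Haldane–Anscombe +0.5 on all four cells.  Defaults (true OR 1.5,
τ² = 0.05, k = 10 studies of 50–1000 per arm, control exposure
frequency f = 0.3, no selection) are sized like a typical candidate-gene
AED-resistance literature: minor-allele-frequency-scale exposure,
tens-to-hundreds of patients per arm, a handful of studies per variant.

Publication selection is directional: a study is published with
certainty only when significant (two-sided p < 0.05) *in the
hypothesized risk direction* (log-OR > 0); all other studies are
published with probability γ.  Symmetric selection — keeping
significant results of either sign — retains both funnel tails and
provably induces no asymmetry, so it cannot generate the small-study
effects the Egger test exists to detect; the directional form is the
standard selection model.  Streams are keyed by (master seed, study
index), so literatures are reproducible and the selection setting does
not perturb the simulated studies themselves.

What the generator does *not* emulate: linkage disequilibrium and
correlated SNPs, genotype-level (three-class) models, meta-level
selection (e.g. suppression of whole meta-analyses), covariate
confounding, and heterogeneity in exposure frequency across studies.
Passing operating-characteristic tests therefore show that the decision
rules behave correctly under the assumed two-group binomial model, not
that they are robust to those real-data complications.

Measured operating characteristics (seeded, in the test suite): Egger
size ≈ nominal at k = 15 studies of 100–1000 per arm; with γ = 0.2 the
test's rejection rate roughly doubles and the mean intercept is
positive by > 3 standard errors on matched literatures of 300 small
(10–60 per arm) studies — many small studies are needed because, at
γ = 0.2, only ~11% of a published null literature is selection-biased
and the Egger test has little power below ~30 published studies.

## Numerical choices and degenerate inputs

* p-values are never truncated internally; formatting happens only in
  the report layer (half-up rounding via `decimal`).
* An all-zero 2×2 table, an empty study list, an inverted CI, and an
  entirely suppressed literature are errors with named messages, not
  silent NAs; a two-study Egger test returns a missing p-value ("NC")
  because that is a value the downstream grading consumes.
* DerSimonian–Laird τ̂² is floored at 0; with one study or Q ≤ df the
  random-effects result equals the fixed-effect result exactly.
* Heterogeneity p is the upper tail of χ²(df = k − 1) at Q, defined as
  1 for a single study.

## Problem sizes

The deterministic fixtures are small (23 comparisons, 32 reviews).
Stochastic checks use 50 000 draws for FPRP frequency calibration,
300–400 simulated literatures per Egger arm, and a 20-study parameter
recovery at 2000 per arm — sizes at which the Monte-Carlo error bands
(3 SEs) are narrow enough for the assertions to be informative.
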