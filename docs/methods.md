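# Methods

## Model

Risk is the product of the probability of a harmful event and the severity
of its consequences. Applied to pesticide residues in vegetables sampled
from circulation:

- **Unit of analysis.** A *stratum* is one province *i* × vegetable
  category *j* cell of the surveillance database; each sampled batch *n*
  within it carries a panel of residue measurements C_ijnk (mg/kg) with
  limits MRL_jk from the national standard. MRLs depend only on the
  (vegetable, pesticide) pair, never on the province or batch.
- **Compliance.** A batch is non-compliant iff some detection strictly
  exceeds its limit (C > MRL; equality is the acceptable maximum and
  compliant) or a banned pesticide is detected at any level.
- **Severity.** Per batch, the worst-case hazard S_ijn = max_k C_ijnk /
  MRL_jk over violating detections — standardizing by the MRL makes
  pesticides with different toxicities comparable, and taking the maximum
  avoids underestimating risk. Per stratum, S_ij is the mean of S_ijn.
- **Probability.** P_ij = M_ij / N_ij, non-compliant over sampled batches.
- **Index and threshold.** IR_ij = P_ij × S_ij. The regulatory benchmark of
  a ≥ 98% pass rate gives an acceptable probability of 2%; with acceptable
  hazard 1 the threshold is IR₀ = 0.02, and IR ≥ IR₀ is high-risk.
- **Direct weighting.** Vegetable-level: P_j = Σ_i M_ij / Σ_i N_ij and
  S_j = Σ_i S_ij·N_ij / Σ_i N_ij over the I_j provinces where *j* was
  sampled; province-level symmetrically over the J_i categories sampled in
  *i*. IR = P × S again at every level.
- **Spatial centroid.** For year *t*, (Long_t, La_t) = Σ_i (Long_i, La_i) ·
  IR_it / Σ_i IR_it with provincial capitals as reference points. The
  year-over-year transfer reports the degree-space displacement
  √(ΔLong² + ΔLa²), the great-circle distance, and the bearing
  atan2(ΔLong, ΔLa) mapped to [0°, 360°) with 0° due north, clockwise.

## Conventions where the method is underdetermined

**Stratum-severity denominator.** Averaging S_ijn over *all* N_ij batches
(compliant ones contributing 0) and averaging over only the M_ij
non-compliant ones are both defensible readings of "mean hazard". Only the
latter is consistent with the joint behaviour expected of surveillance
data — S_ij = 0 exactly when P_ij = 0 but *typically above 1* whenever
P_ij > 0, and stratum severities an order of magnitude above stratum
probabilities — so the non-compliant mean is the default
(`s_denominator="noncompliant"`); `"all"` restores the literal all-sample
mean. The two readings are algebraically linked: under the non-compliant
mean, IR_ij = (M_ij/N_ij) × (Σ S_ijn / M_ij) = Σ S_ijn / N_ij — the index
collapses to the all-sample mean hazard — so the choice moves S and the
interpretation of IR, and results are reported as configured, never mixed.

**Aggregation weights.** The direct-weighting formula for S_j uses sampled
batch counts N_ij as weights (default, `s_weights="batches"`). Under the
non-compliant-mean reading the exactly self-consistent pooling weight would
be M_ij (`s_weights="noncompliant"`); both are available, and the exact
pooling identity — aggregate equals recomputation on the concatenated
assessment table — holds for the two matched pairings (all-sample mean with
N-weights; non-compliant mean with M-weights) and is tested for both.
An N-weighted S_j can fall below 1 for rarely-exceeding vegetables because
zero-hazard strata enter the average at full weight.

**Banned pesticides.** Detections of banned substances are non-compliant at
any concentration. A banned substance with no tolerance is scored against a
policy reference limit Q (default 0.01 mg/kg, a typical default/detection
tolerance magnitude); one with a listed tolerance is scored against that
tolerance. Both contributions are floored at the acceptable-maximum hazard
(`banned_floor`, default 1.0), so any banned detection contributes S ≥ 1;
setting the floor to 0 gives the plain ratio. Q and the floor are logged
configuration, not data.

**No-limit detections.** A detection with no entry in the MRL table is not
a violation by default (`no_limit_policy="ignore"`) — no standard exists to
exceed — but the policy can escalate it to a configuration error.

**Outliers.** No extreme-outlier rule is hard-wired. An optional cap
(`CleaningConfig.outlier_cap`, default off) drops measurements whose
C/MRL ratio exceeds the cap, each drop counted and warned; data are never
silently altered.

**Rounding.** All internal computation is in full double precision;
percentages are fractions internally. Report rendering rounds half-up at
the boundary only: P to two decimals as a percent, S and IR to three
decimals.

**Ranking ties** are broken by pooled batch count descending, then key
lexicographically.

**Geometry.** The degree-space displacement treats longitude and latitude
degrees as commensurate (it is a descriptive volatility measure, not a
metric distance); kilometre distances use the haversine formula at mean
Earth radius 6371.0 km (configurable). On published two-year centroid
coordinates this reproduces the six published transfer distances within 1%
(within ~0.3% for the whole-vegetable and celery tracks), which is the
package's validation that the convention matches the original geometry to
reporting precision. Transfer labels collapse to the four diagonal
quadrants (NE/SE/SW/NW) as "<origin> to <destination>" with the destination
taken from the bearing and the origin its opposite; exact cardinal
displacements use the cardinal name, and a zero displacement is
"stationary" with bearing undefined.

## Synthetic data

The generator emulates the statistical structure a national supervision
database exhibits, so the pipeline is testable without the undeposited
source data:

- strata are explicit (province, vegetable, year, N, p_exceed, severity
  parameters, pesticide panel); batch counts across categories are heavily
  skewed (ratios > 10 between common and rare categories);
- each batch is non-compliant with probability p_exceed; stratum
  probabilities stay within [0, 0.29], the magnitude range national
  surveillance shows;
- a non-compliant batch carries one violating pesticide at C = m × limit
  with m drawn from a shifted log-normal 1 + LogNormal(μ, σ) — support
  strictly above 1, so violations exceed their limit by construction.
  Stratum mean severities span ~2–18 with tail draws reaching ~48; the
  log-normal family is a modelling choice (only means and a maximum are
  published), with μ set from the target mean via
  `severity_log_mean_for(mean, σ)`;
- compliant batches carry sub-limit detections per pesticide-specific
  background rates (uniform on [0, MRL)); banned panel entries are never
  detected in compliant batches, since any detection is by definition a
  violation; batches with no detections are recorded with an explicit
  no-detection row so the sampling denominator is preserved;
- ~10% of compliant detection rows are emitted in µg/kg to exercise unit
  normalization;
- all randomness flows from one `numpy` generator seeded by the config:
  identical configs and seeds reproduce the tables byte for byte.

`paper_like_scenario()` packages 12 provinces × 14 vegetable categories ×
2021–2023 (504 strata, ≈16,000 batches at scale 1.0) with a banned
pesticide (chlorpyrifos) in four panels and regional exceedance multipliers
(northeast ×2.5 in 2021, southwest ×2.5 in 2023) that plant a known
northeast → southwest migration of the risk centroid. The batch volume is
deliberately ~5% of a real national campaign so a full pipeline run takes
well under a second; probabilities and severities, not volume, carry the
statistical structure, and tests that need tighter sampling error set their
own stratum sizes (e.g. n = 2,000 for parameter recovery).

What the generator does *not* emulate: province-by-pesticide correlation
structure, seasonal within-year patterns, reporting-format heterogeneity
across bureaus, and measurement error near detection limits. Passing tests
therefore demonstrate correctness of the computational pipeline and its
statistical calibration under the stated model — not fidelity of any
particular real-world ranking.

## Calibration checks

- Parameter recovery: at n = 2,000 batches, p_exceed = 0.05, mean severity
  5.0, the pipeline estimate of P lies within 3 binomial standard errors
  and S within 3 standard errors of the log-normal mean (fixed seed).
- Unbiasedness: over 200 seeded replicates of a 500-batch stratum the mean
  empirical exceedance fraction sits within 2 Monte-Carlo standard errors
  of p_exceed.
- Worst-case scoring agrees with an exhaustive per-ratio oracle on 1,000
  random panels; aggregation agrees exactly with pooled recomputation on
  1,000 random strata.

## Limitations

- The compliance conventions for banned substances (reference limit Q,
  floor) are declared policy, not regulation; results for
  banned-dominated strata scale with Q.
- The non-compliant-mean severity convention makes S_ij undefined in
  principle for M_ij = 0; it is reported as 0 there, which is the natural
  continuation but means S is not a mean over the same population across
  strata.
- Centroid coordinates are capital-city proxies; within-province spatial
  structure is invisible.
- Annual centroids require at least one province with IR > 0; an all-zero
  year has no defined centroid and is skipped in the track.
- Sampling intensity per capita, dietary exposure, and toxicological
  end-points are out of scope; the index measures regulatory-limit
  exceedance, not health outcome.
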