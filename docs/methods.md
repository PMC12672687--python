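# Methods

## Model

All methods assume Beer–Lambert additivity: the absorbance of a mixture at
each wavelength is the concentration-weighted sum of the pure-component
absorptivities, `X = C·S + E`, with `X` (samples × 1801 wavelengths, AU) the
measured block over 220.0–400.0 nm at 0.1 nm, `C` (samples × 4, µg/mL) the
concentrations, `S` the unit spectra and `E` instrument error. Calibration
inverts this relation by latent-variable regression of `C` on `X`.

**PCR.** The centred `X` block is decomposed by SVD; the first *A* principal
components (ordered by decreasing variance) give scores `T = U·diag(s)`, and
`Y` is regressed on the scores by least squares. Components with a singular
value below `max(n, p)·eps·s₁` are treated as numerically null (their
regression coefficient is zero), so saturated fits on rank-deficient data
stay stable.

**PLS.** NIPALS with X-block deflation, joint (PLS2) over all four analytes
by default; a per-analyte (PLS1) mode is provided. Each weight vector is the
fixed point of the NIPALS update; the iteration is warm-started at the
dominant singular direction of `XᵀY` (computed from the 4 × 4 Gram matrix),
which is that fixed point, and refined until the weight changes by less than
1e-10 (relative) or 500 iterations, after which a convergence error names
the offending component. For a single response the update is closed-form.
Coefficients are assembled as `B = W(PᵀW)⁻¹Qᵀ`; prediction via `B` and via
the score recursion agree to machine precision, and both are exposed.

**Sign convention.** Every weight/loading vector is flipped so its
largest-magnitude element is positive, making saved models and repeated fits
comparable across runs.

**Saturation identity.** With as many components as the rank of centred `X`,
both PCR and PLS coincide with ordinary least squares on the `X` column
space; the test suite asserts this against a normal-equations oracle, which
pins down the algebra of both fitting paths.

## Preprocessing

Latent-variable regression needs a centred `X`/`Y` for scores to be
variance/covariance directions, so the default is mean centring of both
blocks, with `none` and `autoscale` selectable; the Y block always mirrors
the X-block method. Parameters are estimated on calibration (or
training-fold) data only and applied unchanged to new data; a sentinel test
confirms that cross-validation folds never see held-out means. Whether
centring "helps" on the real instrument data is not decidable here — raw
and autoscaled paths are provided precisely because practice varies.

## Cross-validation and model size

Folds: leave-one-out, venetian blinds (sample *i* → fold *i* mod
`n_splits`), contiguous blocks (ordered runs) and seeded random subsets.
Per fold, preprocessing and model are refitted on the training part and
held-out predictions accumulated; `RMSECV_A = sqrt(Σ(ŷ−y)²/n)` is reported
per analyte and pooled (root of the mean squared error over all analytes
and samples — a single figure for a four-analyte model requires pooling,
and the plain pooled MSE is the obvious aggregate). The number of latent
variables is the global RMSECV minimum, ties resolved toward fewer
components. A 0-LV (intercept-only) baseline is always reported.

## siPLS

The axis is cut into `n` equidistant intervals — with `r = L mod n`, the
first `r` intervals take `⌈L/n⌉` columns and the rest `⌊L/n⌋`; any
remainder rule is defensible, this one is fixed so results are comparable
across runs. All combinations of 2, 3 and 4 intervals (C(n,2)+C(n,3)+C(n,4)
models; 2500 for n = 16) are cross-validated at every LV count from 1 to
`max_lv` (counts infeasible for a combination are skipped and recorded), and
combinations are ranked by their best pooled RMSECV, ties toward fewer LVs
then lexicographic order. The default of 16 intervals is explicit and
overridable: the winning four-interval combination the method is known for
implies at least 14 intervals but no total, so the package never guesses one
silently. Because the search is exhaustive, correctness is checked against
a second, independently coded brute-force loop rather than a heuristic
reference.

The inner loop of the search (joint PLS with mean centring, out-of-fold
predictions at all LV counts) is also compiled with numba; the compiled
kernel implements the identical recursion and is asserted against the
numpy path. Without numba the search falls back to the numpy path and is
roughly three times slower.

## Validation statistics

Per analyte on the external validation set: RMSEP; mean recovery %
(100·ŷ/y), its sample SD (n−1 denominator, the convention of assay
validation tables) and RSD % = 100·SD/mean; slope, intercept and Pearson r
of the OLS line of predicted on true; LOD = 3.3·SD/S and LOQ = 10·SD/S with
SD the standard deviation of the predicted-vs-true regression residuals
(n−2 degrees of freedom) and S that regression's slope. LOQ is derived from
LOD, so LOQ/LOD = 10/3.3 to machine precision. Standard-addition recovery
of the pure added standard is `100·(total_found − base_found)/added`.
Method comparison uses the equal-variance two-sample t statistic and the
variance-ratio F (larger variance in the numerator), both with two-sided
p-values. Report rendering rounds recoveries to 2 dp, regression parameters
to 4 dp and errors/limits to 3 dp; internal computation is full precision.

## Synthetic data

The generator emulates a double-beam UV instrument measuring quaternary
mixtures:

* **Pure components** — sums of 2–3 Gaussian bands per analyte. The default
  four-component set shares a strong end-absorption band near 225 nm plus
  distinct secondary bands, giving pairwise Pearson correlations of the unit
  spectra of 0.70–0.95 (severe overlap, the regime where univariate methods
  fail) while keeping the 4-spectrum system well conditioned (condition
  number ≈ 14). All maxima lie in 226–233 nm.
* **Design** — the packaged 25-mixture, five-level, four-factor design
  (SAF 3–23, HBD 1–5, HYD 2.5–6.5, OXD 5–13 µg/mL; each level in exactly
  five mixtures), split 17 calibration / 8 external validation. A seedable
  random multilevel design generator is also provided.
* **Noise** — i.i.d. additive Gaussian noise, default SD 0.002 AU (typical
  photometric noise for a bench double-beam instrument), plus an optional
  per-sample linear baseline drift parameterised as AU per 100 nm. All
  stochastic operations take explicit seeds; identical seeds give
  bit-identical spectra.

What the generator does **not** emulate: wavelength-dependent
(heteroscedastic) noise, stray-light nonlinearity at high absorbance, band
shifts with solvent or temperature, and real excipient backgrounds. Passing
tests therefore demonstrate that the algorithms are implemented correctly
and behave as the theory predicts under a linear, well-conditioned system —
not that any particular laboratory assay meets its specifications.

## Simulation studies

* **Recovery study** — 50 replicates of the packaged design at 0.002 AU
  noise; per replicate, PCR and PLS (LVs by leave-one-out RMSECV, max 8) and
  siPLS (16 intervals, sizes 2–4, max 5 LVs) are fitted and scored on the
  8 validation mixtures. A replicate passes for a model when every analyte's
  mean recovery lies in [98, 102]% with RSD < 3%. The siPLS `max_lv` of 5 is
  the same reduced search depth used in the exhaustive-search cross-check; a
  rank-4 system with small noise needs no more.
* **Interval-benefit study** — 50 replicates of localized-signal mixtures:
  a 361-point grid (0.5 nm step) split into 12 intervals, with two analytes'
  bands confined to interval 3 and two to interval 8, so no single interval
  identifies all four; noise 0.002 AU plus baseline-drift slope SD
  0.005 AU/100 nm. Drift is broadband, which is exactly why restricting the
  model to informative intervals helps; without some such structured error
  both models sit at the noise floor and the comparison is uninformative.
  The best size-2 siPLS model fixes the mask and LV count; full-spectrum
  PLS at the same LV count is the comparator, both scored by pooled RMSEP
  on the validation mixtures.

Replicate seeds are spawned from one base seed via a seeded PRNG, so both
studies are exactly reproducible. Problem sizes (50 replicates, 16/12
intervals, `max_lv` 5/4) keep a full run in the minutes range on one CPU
while leaving the binomial pass-rate thresholds well separated from their
observed values.

## Numerical choices and edge cases

* NIPALS tolerance 1e-10 (relative weight change), 500 iteration cap —
  tighter than any assertion made about the results.
* PCR singular-value cutoff `max(n, p)·eps·s₁` (pinv-style).
* Grid commensurability tolerance: (end−start)/step must be within 1e-6 of
  an integer; wavelength-header matching tolerance 1e-6 nm; headers written
  at 0.1 nm print resolution, values at full float precision (`%.17g`).
* X/Y blocks are aligned by sample id, never by row position; id mismatch
  is an error that names the differing ids.
* Zero-variance columns reject autoscaling (named column); empty interval
  combinations, out-of-range interval indices, non-positive concentrations
  and non-finite absorbances are all rejected at construction.
* Ties in LV selection and in the siPLS ranking resolve to fewer LVs, then
  lexicographic combination order.

## Limitations

* The spectral band shapes are modelling stand-ins, not fits to measured
  spectra of the real four compounds; conclusions about the real assay's
  accuracy cannot be drawn from the synthetic studies.
* siPLS is exhaustive over sizes {2, 3, 4} only; no genetic-algorithm or
  moving-window selection, no backward elimination.
* No derivative/smoothing/scatter-correction preprocessing; no kernel or
  orthogonal-signal-corrected PLS variants; no coefficient uncertainty
  intervals.
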