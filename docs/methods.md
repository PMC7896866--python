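# Methods

This note documents the models, numerical choices and fixture design behind
`irquant`, in the order the pipeline runs.

## Measurement model and preprocessing

A spectrum is absorbance on a uniform, strictly descending wavenumber grid
(2000→400 cm⁻¹ at 4 cm⁻¹ by default). Analysis is confined to the
1800–1300 cm⁻¹ window — 126 grid points, both ends inclusive — because the
excipient matrix is assumed weak there while the analyte and
internal-standard bands are strong and non-overlapping.

Preprocessing is applied in a fixed order: **window → peak normalization →
MSC**. The order is a contract of this package: the window must precede MSC
so the scatter reference is defined on the analysis zone only, and
normalization precedes MSC so the reference is built from gain-free spectra.
Anyone comparing against a commercial chemometrics package should check its
internal ordering first.

* **Normalization** divides the scan by its absorbance at the grid point
  nearest 1697.6 cm⁻¹. That target is off any 4 cm⁻¹ grid anchored at
  integers, and the true instrument grid anchor is unknowable in general,
  so the nearest-point rule is used, with ties broken toward the higher
  wavenumber (on the default grid the anchor lands at 1696 cm⁻¹).
  An anchor absorbance ≤ 1e-6 (the floor that catches all-zero synthetic
  scans) raises a degenerate-spectrum error rather than producing a silent
  division blow-up.
* **MSC** regresses each scan on a reference by ordinary least squares,
  s ≈ a + b·ref, and returns (s − a)/b. The reference is the point-wise mean
  of the *normalized, windowed calibration* spectra, frozen inside the model
  at fit time; prediction-time scans are always corrected against it, never
  against test-set statistics (no information leakage). Slopes |b| < 1e-8
  raise an error: such a scan carries no mixture signal.

## Calibration

The split follows the one-split design: per mixture, 8 of the 10 scans go to
the calibration set and 2 to the validation set, drawn by a single seeded
permutation stream. Splitting per mixture (rather than per R level) keeps
both independently prepared duplicates of every level in both halves, so the
validation error stays sensitive to preparation error.

PLS-1 is fitted by NIPALS on centered data: per factor, w ∝ Xᵀy (unit norm),
t = Xw, p = Xᵀt/(tᵀt), q = yᵀt/(tᵀt), deflate X and y; the regression
vector is b = W(PᵀW)⁻¹q. NIPALS factors are nested, so one fit at k_max
yields the whole factor scan. If the residual collapses before the requested
factor count (routine for noiseless, low-rank synthetic data) the achieved
count is returned with a warning. An independent SIMPLS implementation and
scikit-learn's PLSRegression serve as cross-check oracles in the tests; the
NIPALS code here is normative.

The factor scan reports, for k = 1..k_max on the same split: RMSEC, RMSEV,
Pearson r_c and r_v, and the mean relative error over validation spectra
whose true R lies within ±5 points of the working level (50 % by default;
reported as missing when no spectrum falls in the band). Selection returns
the smallest k with r_c ≥ 0.998 and r_v ≥ 0.998 — taking the first crossing
also means a larger qualifying k with a wider RMSEV−RMSEC overfitting gap is
never preferred. r_c and r_v are computed on the single fixed split
(calibration predictions for r_c, held-out predictions for r_v), matching
the one-split design; no cross-validation folds are involved.

## Quantitation and validation

Per-scan R predictions of a test mixture are aggregated by arithmetic mean
(the per-scan values are retained for dispersion reporting), then converted
to content by C = 100·[R/(100−R)]·m_par·P_par/m_p, the exact algebraic
inverse of the design ratio — the round-trip identity holds to 1e-12 and is
property-tested. Internal arithmetic is double precision throughout;
half-up rounding happens only at the presentation layer (one decimal for
percentages, two for mg).

Two constants deserve comment. The stock-powder content is 0.3794 (fraction
m/m) by the normative assay; a second assay of the same material reported
0.3764, which is kept as a selectable alternative constant
(`ALT_STOCK_CONTENT`), never silently substituted. The shipped bench records
are internally consistent with 0.3794 at the rounding precision of their R
values; their *design* R column is not exactly reproducible under any single
constant tried (differences of ~0.03–0.05 points suggest an effective
content near 0.380 was used at preparation time), which is why recomputed
design ratios, not transcribed ones, are normative in this package.

Validation: mean recovery per level within 98.0–102.0 %, RSD ≤ 2.0 %
(three levels, ≥ 6 replicates each); repeatability over ≥ 6 same-day
replicates at the working level; intermediate precision pools a second day's
replicates. One replayed bench statistic is knowingly not reproducible from
its own printed table: the two-day pooled RSD printed as 1.6 % recomputes to
≈1.3 % from the rounded per-replicate contents, so the per-table values are
used and the printed pooled figure is not asserted anywhere.

## Synthetic data model

Each component (analyte surrogate, internal-standard surrogate, excipient
matrix) is a sum of Gaussian bands on the instrument grid. Band *positions*
follow the real system: the analyte maximum at 1697.6 cm⁻¹ plus five
secondary analyte bands, the five internal-standard maxima
(1651.4…1434.9 cm⁻¹), and broad (σ ≥ 40 cm⁻¹) weak matrix bands inside the
window with a stronger carbohydrate-like feature outside it. Heights and
widths are fixture constants of this package — engineering choices, not
fits to measured spectra.

A noiseless scan is the exact mass-fraction-weighted sum of the component
spectra, with fractions (analyte, standard, matrix) =
(m_p·c_s, m_par·P_par, m_p·(1−c_s) + m_par·(1−P_par)) normalized to 1.
Per scan, the noise model applies: log-normal multiplicative gain
(σ = 0.05), a random linear baseline (offset σ = 5e-3, slope σ = 1e-5 per
cm⁻¹), independent multiplicative jitter of the three mass fractions
(σ = 0.01, renormalized — powder heterogeneity between scan positions), and
additive white noise (σ = 2e-3). The calibration campaign solves masses at a
fixed 360 mg total so the designed R hits each target up to a preparation
error (σ = 0.3 R-points), rounds masses to the 0.01 mg balance readability,
and derives labels from the recorded masses — so regression labels carry no
error, as on a real bench. All randomness flows from one integer seed via
`numpy.random.SeedSequence` spawning.

### Why the band heights are balanced, and the curvature limit

Peak normalization makes the processed spectrum a *projective* function of
the two masses: x(t) = (t·T_a + T_i)/(C·t + D), where t = a/i is the
analyte/standard mass ratio and T_a, T_i the effective component profiles.
The target R = 100·t/(t + 1) is a Möbius function with a *different*
denominator, so an affine functional of x can reproduce R exactly only if
the two denominators are proportional — equivalently, if the MSC-reference
covariances with T_a and T_i are equal. Generically they are not, and the
residual is a smooth curvature error that **no number of PLS factors can
remove** (the noiseless spectra span only two dimensions). This is the same
phenomenon a real bench shows as a ~1 % "relative error due to linear
regression" at the working ratio.

The fixture's internal-standard heights are therefore scaled so that the
two covariances nearly balance (ratio ≈ 1.04), leaving a noiseless
curvature of ≈ 0.07 R-points RMS over the design (≈ 0.16 % relative at
R = 50, ≈ 0.3 % in back-calculated content). Consequences documented by the
tests: noiseless quantitation recovers a 37.94 % m/m truth to ≈ 0.12 points
(not to machine precision — the curvature is a structural property of
peak-normalized ratio calibration, not a bug), and with the default noise
the factor scan sits at r_c, r_v ≈ 0.9997 with RMSEC ≈ 0.35 R-points.

### What the synthetic results do and do not show

The generator reproduces the *statistical structure* the pipeline assumes —
linear mixing, scatter/gain, baseline, heterogeneity, repeated scans — but
its noiseless spectra are exactly rank-2 in composition, whereas real tablet
spectra contain band-shape changes, moisture, particle-size effects and
instrument drift that raise the effective rank. The automatic rule therefore
selects 1 factor on synthetic campaigns (stable across seeds) where a real
system needed 5; passing the synthetic end-to-end tests demonstrates the
correctness of the algorithms and their plumbing, not instrument-level
performance. Problem sizes in the test-suite simulations (100-spectrum
campaigns, 20 seeds for stability, 20 test mixtures for parameter recovery)
are the package's chosen defaults, mirroring the bench design.

## Known limitations

* JCAMP-DX support covers the AFFN `(X++(Y..Y))` and `XYPOINTS` forms only;
  compressed (SQZ/DIF/DUP) data is rejected explicitly, never misparsed.
* No derivative/SNV/smoothing pretreatments, no PLS-2, no outlier
  diagnostics beyond the residual table, no prediction intervals.
* Numeric agreement with proprietary chemometrics software is not claimed;
  the preprocessing order above is this package's contract.
* The back-calculation assumes the internal standard and analyte do not
  interact chemically and that grinding/mixing achieves homogeneity at the
  ATR sampling scale; violations surface as inflated per-scan R dispersion.
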