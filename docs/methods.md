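# Methods

This note records the models implemented in `cardioafm`, the numerical
choices behind the fits, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the underlying procedures
are conventionally underspecified.

## Conventions and units

All internal quantities are SI (m, s, N, Pa); reports and examples print
nN, µm, kPa, pN as appropriate. `piezo_position` is the piezo extension
toward the sample (increasing on approach, constant in dwell, decreasing
on retract); `deflection` is positive in repulsive contact. The
tip–sample separation coordinate is `piezo_position − deflection`, so the
indentation past a contact at z₀ is δ = (z − z₀) − (d − d₀). When a
segment column is absent, segments are inferred from piezo motion with a
stationarity tolerance of 0.1 nm per sample. Stiffness maps use a 0-based
row-major grid with (x, y) in µm at pixel centers; pixels whose force
curve was discarded are stored as NaN and excluded from every statistic.
Whether a file's force column is raw deflection or calibrated force is
declared via the column map / `calibrated` flag, since exports are
ambiguous on this point.

## Elasticity

Contact models: Hertz sphere F = (4/3)·E/(1−ν²)·√R·δ^{3/2}; Sneddon cone
F = (2/π)·E/(1−ν²)·tan α·δ²; a four-sided pyramid uses the conical form
with an effective half-angle, default 35° (typical of MLCT-class probes),
configurable. ν defaults to 0.5 (incompressible soft tissue). DMT and JKR
adhesive contact models are deliberately not implemented.

Both models are linear in E at a fixed contact position, so E has a
closed-form least-squares solution once z₀ is known. `fit_youngs_modulus`
therefore profiles a 1-D cost over z₀: for each trial position the
pre-contact baseline (offset + slope) is refitted, E is solved in closed
form on the window δ ∈ (0, fit_fraction·δ_max], and the mean squared
residual of the piecewise model (flat baseline, then contact model) is
evaluated over the whole approach. An 80-point grid scan is refined by
bounded scalar minimization. Including the baseline region in the
residual is what pins z₀: a contact placed too deep leaves visible force
in the "baseline" and is penalized. The standalone detectors
(`detect_contact_point`) implement ratio-of-variance and gradient-kink
rules; the ratio-of-variance maximum is systematically late (deep) on
noisy curves because the variance contrast keeps growing with indentation
— it is kept as a coarse locator, and the profile search is the default
path to E. At 2% force noise the median recovery error is below 1% per
geometry; the acceptance bound is 5%.

`fit_fraction` (default 1.0) can be reduced to exclude deep indentation
where substrate effects grow. The thin-sample flag is inclusive at the
10% boundary: δ_max ≤ 0.10 × height passes.

## Stress relaxation

The dwell decay is rebased by the pre-contact force baseline (not the
instrument zero) and divided by its maximum, so g(0) = 1 by construction.
An optional stress channel divides by a contact area; when none is
supplied the Hertzian sphere area πRδ at maximum indentation is the
documented default. Normalization order (before vs after the area
division) does not affect the dimensionless fit.

The generalized Maxwell fit G(t) = G₀ + Σ Gᵢ·e^{−t/τᵢ} (n = 1, 2, 3
terms; 2 default) uses bounded nonlinear least squares in (G₀, Gᵢ, log
τᵢ) with multi-start initialization: τ seeds on a log grid between twice
the sampling interval and the dwell duration, all ascending combinations;
weights seeded from the endpoint value. Output τ are sorted ascending and
ηᵢ = Gᵢτᵢ is reported per element. Fits where a weight falls below 10⁻³
or adjacent τ coalesce within a factor 1.5 are flagged degenerate — the
trace does not support the requested order. `compare_exponential_orders`
tabulates RSS/AIC/BIC per order and recommends 2 unless a higher order
improves BIC beyond a margin (default 10): one exponential misses the
fast early decay, a third adds parameters without measurable gain.

Percent relaxation is [1 − G(t_end)]×100 evaluated on the normalized
trace (linear interpolation at t_end, default the dwell duration of
60 s); a trace ending early uses its final sample with a warning. With
the reference parameters (G₀ = 0.5, G₁ = 0.3, G₂ = 0.2, τ₁ = 1 s,
τ₂ = 20 s) the 60 s value is 49.0% — the residual slow-element
contribution keeps it just below the t→∞ limit of 50%.

## Adhesion

The zero-force line is the median of the last 10% of retract samples (the
far-from-surface tail). Maximum adhesion force is the magnitude of the
deepest excursion below that line; its distance is measured from the
first retract sample, along tip–sample separation when the deflection
channel exists, else along piezo travel (the axis choice is recorded in
the call, not guessed). Work of adhesion integrates only the negative
excursion by trapezoid; it is exactly additive under any interior split.
Event detection finds runs of consecutive force increments ≥ min_step;
the pre-step loading slope (least-squares over a window, default 10
samples) classifies rupture vs tether with a plateau tolerance of 5% of
the step per 100 nm — the rule-based stand-in for a distinction that is
qualitative in practice, with every constant configurable. Which side
carried the cell (functionalized tip vs cell-on-cantilever) does not
change the computation and is stored as metadata.

## Worm-like chain

The Marko–Siggia interpolation is fitted per rising branch with analytic
Jacobians, residuals nondimensionalized by the branch peak force, and a
coarse (L_c, p) grid start (L_c/x_max ∈ [1.02, 3], p ∈ [0.1, 3] nm).
These three choices are load-bearing: finite-difference steps on ~10⁻¹⁰ N
residuals trigger spurious gradient-convergence at the start point, and
the (L_c, p) surface is a narrow curved valley that traps a locally
started solver. Samples below 2% of the branch peak force are excluded
(no shape information near zero extension). Temperature defaults to
298 K. A shared-persistence mode refits all branches with one p;
per-peak and shared fits agree within 1% on clean data. Fitted L_c
sequences should increase monotonically across peaks; the per-peak table
makes violations visible rather than silently reordering.

## Beating and Poincaré variability

Beats are prominence-gated peaks with a minimum spacing; each beat's
baseline is interpolated between the flanking minima, the beat force is
peak minus baseline, and FWHM is found by linear interpolation of the
half-height crossings. Frequency is (n−1)/(t_last − t_first). The
Poincaré map plots each interval against its predecessor (standard lag-1
convention); SD1/SD2 are sample (n−1) standard deviations of the
projections perpendicular to / along the identity line, fixed
package-wide by a projection-oracle test, so SD1² + SD2² equals the sum
of the two marginal variances exactly. SD2 = 0 yields an infinite ratio
sentinel (NaN when SD1 is also 0), never an exception. The contact force
used during acquisition (e.g. 2 nN) is metadata only. Ellipse axes
(2·SD1, 2·SD2, centred at the mean interval, rotated 45°) are provided
for plotting.

## Stiffness-map segmentation

Rendering applies a named matplotlib colormap over an explicit value
range; the default `viridis` has a monotonically increasing green
channel, which makes the image-space route (green-channel threshold,
Otsu by default, polarity configurable) equivalent to thresholding the
modulus values directly. Because the true colormap/polarity of
vendor-rendered images varies, both are explicit configuration, and the
value-space route is the recommended scientific path whenever the
numeric TSV exists — it also exports the full per-class value lists so
no region value has to be picked out one by one. Rendered images carry no
scale bar, so no crop step is needed. Per-scanline height offsets are
removed by line-median subtraction (or per-line linear detrending),
touching only the height channel. Vessels and tissue boundary can be
excluded via a user-supplied mask. Scan defaults mirror a 10,000 µm²
region at 256×256 pixels (>60,000 force curves per scan).

## Histology quantification

PSR positivity is the conjunction of (i) red > green and red > blue,
(ii) green below a threshold (Otsu on the green channel by default; the
value used is always recorded in the output metadata), (iii) hue in the
circular red interval — ≥ 0.8 or ≤ hue_low, with hue_low = 0 as the
strict default and exposed because an exactly-zero hue is fragile on real
stains, and (iv) saturation in [0.125, 1]. HSV uses hue ∈ [0, 1) and
saturation (max−min)/max on images normalized to [0, 1]; this is stated
because HSV variants differ. SHG positivity is red channel > threshold
(Otsu default); single-channel SHG exports should be loaded as grayscale
RGB. Both fractions are pure per-pixel rules, hence invariant to pixel
permutation, and monotone in their thresholds in the expected directions.

## Group statistics

The parametric branch runs one-way ANOVA with pairwise t tests adjusted
by Holm–Šidák step-down (adjusted p(i) = max over j ≤ i of
1 − (1 − p(j))^{m−j+1}); the nonparametric branch runs Kruskal–Wallis
with Dunn's tie-corrected two-sided z contrasts, Holm-adjusted by
default. All six contrasts among the four groups are computed at
α = 0.05. Group summaries are mean ± SE (SD/√n). The branch is chosen by
per-group Shapiro–Wilk at a Šidák-split per-group level so that a fully
normal table is demoted to ranks at the stated family-wise rate
(`normality_alpha`) regardless of group count; groups with n < 3 force
the nonparametric branch. All-constant groups degrade the parametric
branch to ranks with a note.

The fibrosis pipeline screens normality at family-wise 1% rather than
the generic 5%: with n = 5 per group the Shapiro test has essentially no
power against real non-normality, while a 5% screen needlessly demotes
one fully-normal cohort in twenty to rank tests — and Dunn contrasts at
n = 5 with Holm adjustment cannot reach significance at any effect size,
so a demotion silently destroys the comparison. The per-sample AFM
summary defaults to the median map modulus (robust to the right-skewed
pixel distribution); the mean is available.

## Synthetic data

Every generator returns a `GroundTruth` record sufficient to recompute
each downstream statistic independently, and identical (seed, parameters)
give bit-identical artifacts.

- *Indentation curves*: exact forward model — the cantilever bending at
  each piezo position solves F(δ) = k·d with δ = travel − d — plus an
  optional linear baseline tilt and additive Gaussian deflection noise
  (absolute, or a fraction of the peak force). Indentation speeds are
  validated against the plausible 50 nm/s–10 µm/s range.
- *Relaxation traces*: the two-element Maxwell decay on a uniform 60 s
  grid (600 samples), noise added, then renormalized by the maximum as
  measured dwell data would be; this costs a ~2–3% scale bias at 1% noise,
  well inside the 10% recovery target.
- *Sawtooths*: WLC branches with contour lengths L₀ + i·ΔL_c truncated
  at the unfolding force (rupture extensions solved exactly), default
  ΔL_c = 28 nm and p = 0.4 nm — an immunoglobulin-like domain scale.
- *Adhesion retracts*: triangular dip with closed-form work
  (|F_peak|·d_detach/2), optionally decorated with rupture/tether motifs
  on the return flank.
- *Beat traces*: asymmetric triangular pulses (closed-form FWHM =
  (rise + fall)/2) on intervals from an i.i.d. Gaussian, alternating, or
  AR(1) model, so Poincaré outputs have analytic references
  (SD1² = Var·(1−φ), SD2² = Var·(1+φ) for AR(1)).
- *Tissue maps*: blob-shaped stiff-ECM patches made by thresholding a
  smoothed Gaussian random field at the exact-fraction quantile — giving
  connected scar-like regions and a ground-truth area fraction exact to
  one pixel — with lognormal within-class modulus scatter (σ = 0.2),
  5 kPa myocyte / 25 kPa ECM medians.
- *Stain images*: positive pixels constructed to satisfy the full PSR
  rule (deep red, hue 0, high saturation) or the SHG red threshold at an
  exact count. The decisive channel of the minority/background class is
  single-valued because Otsu's argmax settles on the first empty bin
  above the lower mode, so pixels straddling that bin would otherwise
  break the constructed-label guarantee.

The default four-group cohort encodes a hidden-fibrosis scenario: ECM
area fractions 0.05/0.05/0.40/0.35 and stain fractions at sham level for
the far-infarct group (PSR 0.025, SHG 0.03, vs 0.12/0.10 in the scar).
Between-sample biology is a lognormal modulus scale factor (σ = 0.03), an
ECM-fraction jitter (SD 0.01) and one shared per-sample collagen level
feeding both stains (SD 0.003, plus 0.0005 stain noise). No effect sizes
are published for this design — only the significance pattern — so these
are free parameters chosen once to represent a strong, detectable
remodeling contrast (Cohen's d ≈ 4 on the AFM metric at n = 5/group);
the tests reproduce the qualitative pattern, not any numeric p-value.

What the generators do **not** emulate: instrument drift and hydrodynamic
drag on force curves, heavy-tailed or correlated noise (additive Gaussian
throughout), partial-volume pixels and stain variability at class
boundaries, spatial correlation between a sample's stiffness map and its
stain images, and real optical artifacts (uneven illumination, bubbles).
Passing tests therefore demonstrate correctness of the computations and
recoverability under the stated noise models, not robustness to every
failure mode of real acquisitions.

## Problem sizes and tolerances

Default verification scales: 200 noisy curves per tip geometry
(elasticity), 100 relaxation traces, 1,000 random adhesion retracts,
25 noisy sawtooths, 1,000 random interval series plus one n = 10,000
i.i.d. series, 256×256 maps and images, 1,000 null replicates for type-I
calibration, and 100 simulated cohorts for the hidden-fibrosis rate.
Numerical comparisons use 10⁻¹² relative tolerance for algebraic
identities (round-trips, work integrals, variance identities), 10⁻³ for
noiseless nonlinear-fit recovery, and the documented statistical bounds
elsewhere. Known limitations: no bottom-effect (finite-thickness) Hertz
correction, no creep-compliance or frequency-domain microrheology, no
Bell–Evans loading-rate analysis, no stain normalization or fiber
orientation metrics, and no proprietary binary instrument formats.
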