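# Methods

## Waveform model and marker extraction

ERG recordings are uniformly sampled voltage series (default 4 kHz,
150 ms epoch, 30 ms pre-stimulus) aligned to stimulus onset.
Conditioning applies, in order: a second-order zero-phase Butterworth
band-pass (0.3–100 Hz, applied forward and backward with
`sosfiltfilt`, so latencies are undistorted and the effective
magnitude response is |H|²); rejection of any sweep whose absolute
voltage exceeds 150 µV (blink/eye-movement artifacts); and pointwise
averaging. Marker placement on the averaged trace follows fixed rules:
the b-wave is the global maximum of the post-stimulus segment (no
latency window imposed), the a-wave the minimum between onset and b,
the i-wave the first local maximum after b with prominence of at least
0.5 µV (configurable; the prominence floor rejects noise wiggles on
the falling phase), PhNR1 the minimum between b and i, and PhNR2 the
first prominent local minimum after i, falling back to the deepest
later sample when the trough is still falling at the epoch end.

All five amplitudes are referenced to the mean of the pre-stimulus
window. A configuration switch measures the b-wave from the a-trough
instead (peak-to-trough convention); baseline-referencing is the
default, matching the extended PhNR protocol convention. Whether the
original convention was baseline- or trough-referenced is genuinely
open; both are supported.

Each discrete extremum is refined to sub-sample precision by a local
least-squares parabola, with the fit window scaled to the expected
width of the component (±1 ms for the sharp a/i deflections up to
±2.5 ms for the broad PhNR2 trough). This is the standard remedy for
single-sample jitter at flat extrema under residual noise; the
refinement falls back to the raw sample when the local curvature has
the wrong sign. Under protocol conditions (125 averaged sweeps) the
resulting marker times are accurate to well under one sample period
and amplitudes to ~0.2 µV against analytic ground truth.

## The eRGC severity outcome

The outcome is the combined structure–function estimated RGC count.
Sensitivities map to local ganglion-cell density in dB via the
human/SITA eccentricity-dependent linear maps (slope
m = 0.07128·ec + 0.91, intercept b = −1.98·ec − 14.8,
gl = (s − 1 − b)/m + 4.7); the original primate maps
(m = 0.054·ec + 0.91, b = −1.5·ec − 14.8, gl = (s − b)/m) are provided
for reference. The perimetry count sums 10^(0.1·gl) over test points.
The 24-2 test-point grid is not standardized in any single table, so
the package ships the conventional right-eye layout: a 6°-spaced
lattice offset 3° from the meridians with the nasal column extended to
27°, 54 points, minus the two blind-spot points at (15°, ±3°), leaving
K = 52; eccentricity is √(x² + y²). Coordinates are overridable.

The OCT count uses axon density d = −0.007·age + 1.4 axons/µm², the
MD correction c = −0.26·MD + 0.12, and
OCTrgc = 10^{0.1[10·log₁₀(10870·d·rnfl) − c]}, computed in the log
form and verified in tests against the algebraic simplification
(10870·d·rnfl)·10^(−0.1c) to < 1e−12 relative error. A sectionwise
mode (a = 21.2·mh·px·d per scan section) is available when
per-section mean heights are supplied. The final estimate
eRGC = (1 + MD/30)·OCTrgc − (MD/30)·SAPrgc is a convex combination for
MD ∈ [−30, 0]; MD outside that range is clamped with a logged warning,
since the weighting was defined on that interval. Floor sensitivities
(s < 0 dB) pass through the maps unchanged — no floor substitution.

## Linear and MARS models

Degree-1 MARS represents eRGC as an intercept plus hinge functions
max(0, ±(x − t)) of the marker amplitudes, with no interaction terms.
The forward pass greedily adds the reflected hinge pair minimizing
residual sum of squares, with candidate knots at every observed data
value (no minspan/endspan thinning — exhaustive candidates are cheap
at n ≈ 100, though they occasionally split a true hinge across two
adjacent knots, an equivalent-fit reparametrization). Candidate
evaluation residualizes both hinge columns against the current basis
via its QR factorization and solves each 2×2 normal system in closed
form, so an iteration over all variables and knots is a handful of
matrix products. `max_terms` (default 40) caps hinge basis functions,
excluding the intercept; `max_terms=2` therefore fits exactly one
reflected pair — a single-knot segmented regression, which the tests
verify against exhaustive enumeration. The forward pass stops early
when the best RSS improvement falls below 1e−10·var(y); ties break
toward the smaller knot.

The backward pass deletes, at each step, the term whose removal most
improves generalized cross-validation,
GCV = (RSS/n)/(1 − C/n)² with C = (basis functions incl. intercept) +
penalty·(distinct knots) and penalty 2 for degree-1 models
(configurable). Model size is tuned by k-fold cross-validation
(default tenfold): each fold contributes out-of-fold RMSE for every
size on its training pruning path, and the selected size is the
smallest within one standard error of the minimizing size (the usual
parsimony rule for flat tuning curves; the strict minimizer is
available via `selection="best"`). Folds are grouped by individual by
default so paired eyes share a fold — the conservative choice for the
paired-eye design — with plain ungrouped folds available
(`--cv plain`). R² on a constant outcome is defined as 0 so
comparisons stay well defined.

## Cluster bootstrap and paired-eye diagnostics

Model comparisons resample individuals with replacement (n = 1000
resamples by default), carrying all of a drawn individual's eyes into
the replicate, which respects the within-person correlation structure.
By default the tuned model structures are re-estimated
(coefficients refit) on each replicate and scored by apparent R² —
comparing the "final models" — with flags for full re-tuning per
replicate and for within-replicate cross-validated scoring. The
one-sided p-value is the fraction of replicates with ΔR² ≤ 0
(alternative: the second model predicts better); ties count toward the
null, and exchanging the models obeys p_ab + p_ba ≥ 1.

Two caveats are documented deliberately. First, apparent R² of nested
feature sets is biased toward the larger set; for nested comparisons
near the null, `score="cv"` is the sounder choice. Second, at an exact
equal-skill, zero-signal null, ΔR̂² is a degenerate second-order
statistic and the percentile bootstrap is conservative — its measured
one-sided type-I rate at nominal 0.05 is about 1–2% rather than 5%.
It never over-rejects, and power away from the null is unaffected (a
true ΔR² of 0.2 at 50 individuals is detected essentially always).

The between-eye intraclass correlation uses the one-way ANOVA form for
cluster samples, ICC = 1 − M/(M−1)·SSW/SSTO, with M the mean cluster
size over all clusters (singletons contribute nothing to the
within-cluster sum of squares but count toward M and the total).
Other ICC variants exist (design-effect and mixed-model forms); the
ANOVA form is implemented because it is exact on degenerate clusters
and matches the design-effect effective sample size
n_eff = n_eyes/(1 + (m̄ − 1)·ICC) used alongside it.

## Synthetic cohort generator

The generator emulates the statistical structure of a
glaucoma cohort, not its biophysics. Defaults: 55 individuals with
bilateral inclusion probability 48/55 (expected 103 eyes); per-eye
mean deviation MD = −exp(N(log 2.5, 1.1²)) clipped to [−30, 0] dB
(median ≈ −2.5 dB, spanning mild to advanced loss); ages N(73, 9²)
clipped to [50, 90]; RNFL = 80 + 3·MD − 0.1·(age − 70) + N(0, 4) µm
clipped to [40, 120] (median ≈ 73 µm at the median MD). Between-eye
dependence is induced on the latent severity scale as
z = √ρ·z_individual + √(1−ρ)·z_eye with ρ the ICC target (default
0.011) — the closed-form calibration; the realized eRGC ICC is
unbiased around the target with a per-cohort sampling sd of ~0.15 at
55 individuals, so calibration checks use larger cohorts. Field
sensitivities are the normal surface 33.5 − 0.1·ec plus
eccentricity-weighted loss (weights ∝ 1 + 0.03·ec, mean 1) and 1.5 dB
noise, clipped to the perimeter range [−2, 50].

ERG component amplitudes are links of the eye's eRGC. The default
saturating link is floor + (ceil − floor)·(1 − 2^(−eRGC/half)) with
half-saturation 1.8e5 cells for the RGC-driven components (i, PhNR1,
PhNR2) and 1.35e5 for the gain-dominated a/b waves, placing the bulk
of the cohort (median eRGC ≈ 6e5) in the saturated regime — the
regime in which hinge models should outperform linear ones — plus
0.8 µV eye-level jitter; a linear link variant exists for
identifiability tests. Raw sweeps are sums of fixed-latency Gaussian
component templates (a 15 ms, b 30 ms, PhNR1 40 ms, i 45 ms, PhNR2
55 ms for the chromatic stimulus; the achromatic variant shifts the
i-wave 2 ms later, scales it up 15% and the rest down 15%) with white
noise per sweep (default 10 µV, 125 sweeps). Latencies are fixed, not
severity-dependent, because only amplitudes feed the models.

Because the templates overlap, each component's true marker is the
extremum of the summed waveform, not the component's own peak; ground
truth is therefore computed by bounded continuous optimization of the
noiseless analytic waveform, independent of the discrete marker logic
under test. What passing tests show is that the pipeline recovers the
structure this generator encodes; real ERGs differ in ways the
generator does not model (latency shifts with severity, oscillatory
potentials, drift and line noise, inter-subject template variation),
so results here do not certify performance on clinical recordings.

## Problem sizes and numerical choices

The test and acceptance runs use the cohort's own scale (55
individuals, ~103 eyes, 125 sweeps/eye) for end-to-end checks;
bootstrap calibration uses 200 outer replicates × 200 resamples and
the comparison grid 100–200 resamples, with 1000 the library default
for single comparisons. Degenerate bootstrap replicates (constant
outcome or too few rows) are redrawn and logged; more than 10%
redraws raises an error. OLS solves use `lstsq`; rank-deficient
designs raise a collinearity error rather than silently pseudo-
inverting. Seeds propagate explicitly: cohorts, fold assignment and
resampling are all reproducible bit-for-bit from a single integer.

## Known limitations

- Marker rules assume the canonical photopic morphology; severely
  attenuated i-waves raise a missing-i-wave error rather than falling
  back to a single-PhNR measurement.
- The generator's link functions are configurable fictions for
  testing, not estimates of the true amplitude–severity relationship.
- Apparent-R² bootstrap comparisons of nested specs are biased toward
  the larger spec (see above).
- Latency and spectral features, degree-2 interactions, and OCT
  segmentation are out of scope; mean RNFL is an input.
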