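# Methods

This note documents the models implemented in `salibench`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Shear rheology

Flow curves (apparent shear viscosity η_shear against shear rate γ̇, typically
0.1–1000 s⁻¹ at 37 °C) are the classification input. Interpolation is done in
log–log space because flow curves span decades and are locally near power-law;
querying outside the measured range raises an error rather than extrapolating.

Classification uses the apparent viscosity at a reference shear rate
(default 50 s⁻¹, the orally relevant rate):

* liquid: η < 0.10 Pa·s
* viscous liquid: 0.10 ≤ η ≤ 1.0 Pa·s (boundaries closed on this side)
* gel: η > 1.0 Pa·s

The closed-interval convention for the middle class follows from the strict
inequalities used for the outer classes.

For the Trouton-ratio denominator a rate-dependent shear viscosity is needed
over a wide rate range, so a four-parameter Cross model

η(γ̇) = η_∞ + (η₀ − η_∞) / (1 + (λγ̇)^m)

is least-squares fitted in log-viscosity space (fitting in log space weights
the decades evenly and keeps the fit positive). Initialisation is
deterministic: η₀ from the largest measured viscosity, η_∞ from the smallest,
λ from the reciprocal rate at the geometric-mean viscosity, m = 1. The Cross
family reproduces both near-Newtonian liquids (plateau from ~1 s⁻¹) and
strongly shear-thinning gels (three-decade decay) with one functional form.
On a constant (Newtonian) curve the two plateaus coincide and λ is
unidentifiable; the fit still returns η₀ = η_∞ = the constant with ~zero
residual, which is the correct degenerate behaviour.

Replicate curves are aggregated pointwise (mean and sample SD); replicates
must share an identical rate grid — no silent regridding.

## Extensional rheology (CaBER)

A capillary-breakup run records the minimum filament diameter D_min(t)
between two plates (D₀ = 6 mm, initial separation h₀ = 3 mm → aspect ratio
0.5, final separation h_f = 10 mm) with a laser micrometer of resolution
20 µm. Diameters at the resolution floor are censored there; **breakup** is
operationally the earliest sustained crossing of the floor (a single noise
dip below it is ignored).

Two thinning models are fitted:

* **elastic** (upper-convected Maxwell, elastocapillary balance):
  D_min(t) ∝ exp(−t/(3λ_c)). Fitted by linear regression of ln D on t.
* **power-law**: D_min(t) = 2φ₀ (σ/K)(t_b − t)ⁿ with φ₀ = 0.142 fixed, σ the
  measured surface tension (a required scalar input; its measurement is out
  of scope). Fitted by nonlinear least squares in log-diameter space over
  (log K, n, t_b), with t_b initialised from the detected breakup (or the last
  sample plus one interval) and constrained past the last usable sample.
  Note the prefactor 2φ₀ = 0.284 is implemented exactly as stated even though
  it is twice the commonly cited visco-capillary diameter coefficient.

Model selection fits both and picks the lower rms log residual, ties going to
the power-law model; if only one converges, it is chosen.

Fit-window rules (the window is not prescribed by the underlying theory, so
these are package decisions):

* the initial plateau — the run of samples before the diameter last exceeds
  95% of the start value (median of the first 5 samples) — is excluded; the
  "last excursion" form makes the rule robust to noise dips;
* samples below **2× the resolution floor** are excluded from regressions:
  censoring truncates the noise distribution just above the floor, and those
  high-leverage points otherwise bias log-space fits (empirically, including
  them inflated the error on K from <1% to ~20% at 2% noise);
* beads-on-a-string artifacts — samples whose diameter rises >5% above their
  predecessor inside the thinning window — are dropped from regressions
  without breaking window contiguity;
* the elastic fit scans a deterministic grid of contiguous sub-windows
  (12 lengths × ≤16 offsets) and keeps the longest whose rms log residual is
  below a configurable threshold (default 0.05, ≈2.5× the log-residual of 2%
  multiplicative noise); if none passes, the smallest-residual candidate is
  used.

From the trace the pipeline computes the Hencky strain ε = −2 ln(D_min/D₀)
(unit-free: the ratio sits inside the log), the instantaneous strain rate
ε̇ = −(2/D_min) dD_min/dt = −2 d(ln D_min)/dt, the apparent extensional
viscosity η_E = (2σ/D_min)/ε̇, and the Trouton ratio
T_r(ε̇) = η_E(ε̇)/η_shear(ε̇), where the denominator is the fitted Cross model
evaluated at a shear rate numerically equal to ε̇ — deliberately without the
conventional √3 kinematic conversion, matching the definition used for the
benchmark.

Numerical differentiation uses a local second-order polynomial
(Savitzky–Golay on uniform grids, per-point quadratic fits otherwise) with a
window of 5% of the trace length (minimum 5 samples). Raw finite differences
would amplify the micrometer's quantisation noise. The derivative of a local
quadratic is exact on exponential traces (ln D linear in t) but biased near
the t_b log-singularity of power-law traces: the relative bias is
≈ H²/(5Δ²) for half-window H and time-to-breakup Δ, so symbolic agreement to
<0.5% holds for points more than one window past the thinning onset and more
than four windows before breakup. The validation suite uses exactly those
interior margins.

The valid window for profile maxima keeps samples with diameter strictly
between the resolution floor and 95% of the post-plateau start value and with
ε̇ above a configurable floor (default 10⁻³ s⁻¹; η_E diverges as ε̇ → 0).
Maxima of η_E and T_r are taken independently over that window — they need
not occur at the same time or strain.

## Tribology

**Hertz contact.** For the ball-on-disc geometry (PDMS ball, diameter 19 mm,
on a PDMS disc) both bodies are assigned the same modulus, so the effective
modulus is E* = E/(2(1 − ν²)); the contact radius is a = (3FR/(4E*))^(1/3),
mean pressure F/(πa²), peak pressure 1.5× mean. PDMS is treated as an
incompressible elastomer, ν = 0.5 (the Poisson ratio is not printed with the
geometry; ν = 0.5 is the standard elastomer value and reproduces the quoted
~200 kPa peak pressure: the package computes 196.8 kPa).

**Plate-on-plate conversion.** μ = M/(R·F_N) with R = 0.025 m and
F_N = 1.0 N by default, and entrainment speed U = Ω·R. Speeds are handled in
m/s throughout (a 1.2 s⁻¹ × 0.025 m sweep tops out at U = 0.03 m/s).

**Stribeck segmentation.** On the log U–log μ curve, smoothed by a local
linear fit over 5-point windows (shifted inward at the edges rather than
shrunk, so edge slopes keep their full averaging length), the boundary
plateau is the initial run where |d log μ/d log U| < 0.1; its last point is
`boundary_end` and the boundary friction coefficient is the median raw μ over
the run. The curve minimum is sought from the plateau end onward (so the
ordering boundary_end ≤ minimum_speed ≤ hydrodynamic_start holds by
construction), and the hydrodynamic regime starts at the first post-minimum
point with slope > +0.1 (the last speed if the rise never steepens that far
within the sweep). A curve that is not flat at its lowest speeds has no
boundary plateau and raises an error. Because "boundary friction" is quoted
sometimes as a point reading and sometimes as a plateau statistic, both are
exposed: the plateau median and the log–log-interpolated μ at configurable
reference speeds (defaults 0.01 m/s for smooth PDMS, 0.0007 m/s for the
biomimetic tongue surface, 0.25 m/s for the hydrodynamic comparison).

Percent friction reduction of a sample against a reference is
100·(1 − μ_sample/μ_reference).

## QCM-D adsorption

Adsorption makes the resonance-frequency shift Δf negative (in proportion to
adsorbed mass); summaries report magnitudes |Δf|. Three quantities are
estimated per trace:

* plateaus before/after rinsing: medians over the trailing 10% of the
  adsorption phase and of the post-rinse phase (≥20 samples each); trailing
  medians resist drift and spikes;
* saturation time: first time after injection at which the median-smoothed
  |Δf| (window 41 samples, shifted inward at the edges) crosses 98% of the
  pre-rinse plateau and stays above it until the rinse, reported relative to
  injection. The 98% sustained criterion is a package decision — saturation
  is otherwise only verbally defined. For exponential adsorption with time
  constant τ the criterion equals τ·ln 50 ≈ 3.912τ, which is the closed form
  the tests check against. The 41-sample median keeps the sustained-crossing
  estimator within 10% of that value at 0.5 Hz counter noise;
* desorption extent: 100·(|Δf|_before − |Δf|_after)/|Δf|_before, scale
  invariant, reported unclamped (negative values mean adsorption continued
  after the rinse). The "in vitro coating index" language is kept as a note
  only: the number stored is the removal percentage, and higher removal means
  a poorer coating — the polarity is not re-encoded.

Only the fundamental-frequency shift is modelled; dissipation, overtones and
Sauerbrey mass conversion are out of scope.

## Synthetic-data generator

The generator is the test bed: each modality has a closed-form law plus
seeded noise, and noiseless runs match the law to better than 1e−12 relative
error at every sample, so the analysis stages can be validated against exact
oracles and by parameter recovery.

* **Flow curves**: Cross model on a log-spaced rate grid (default
  0.1–1000 s⁻¹, 30 points, 3 replicates) with multiplicative lognormal noise.
* **Thinning traces**: diameter D₀ during an initial plateau, then the
  elastic or power-law law; multiplicative noise; values below the 20 µm
  floor censored to the floor (mirroring the micrometer and exercising
  breakup detection). Power-law parameter sets whose model diameter would
  exceed the plate diameter at the plateau end are rejected — physically the
  plateau must last until the law drops below D₀.
* **Stribeck curves**: a logistic blend (in log speed) of a boundary plateau
  and a rising hydrodynamic branch c·(η·U)^k, k = 0.6 by default;
  multiplicative noise.
* **QCM-D traces**: flat baseline, exponential adsorption toward −|Δf|_max,
  then exponential relaxation toward −|Δf|_max(1 − removal) after the rinse;
  additive Gaussian noise (counter noise is not scale-proportional).

Noise defaults to a 2% coefficient of variation (multiplicative) and 0.2 Hz
(QCM-D): instrument noise levels are not published for these datasets, so
these are the package's choices of a realistic bench-top level, fixed once.

Presets (`liquid`, `viscous_liquid`, `gel`, `saliva`) place the noiseless
summary statistics in the measured ranges for each archetype — e.g. the
liquid preset gives η(50 s⁻¹) ≈ 0.026 Pa·s, an elastic filament hitting the
floor at ≈0.03 s and 28% removal; the gel preset gives ≈5.4 Pa·s, a
power-law filament with t_b = 24 s and 47% removal; the saliva preset gives
≈2.7 mPa·s, t_b ≈ 2 s, |Δf| ≈ 63.6 Hz, 4% removal and ≈30 min saturation.
The saliva preset classifies as a *liquid* — correctly, since its viscosity
is far below the 0.10 Pa·s threshold.

What the generator does **not** emulate: temperature dependence, yield
stress and thixotropy, inertio-capillary thinning, beads-on-a-string
dynamics (the analysis masks such artifacts but the generator does not
produce them), wear or surface damage in the tribometer, QCM-D dissipation,
drift, or multi-rinse protocols. Passing tests therefore demonstrate
correctness of the estimators under the stated laws and noise, not
robustness to every behaviour of real instruments. In particular the
presets' extensional maxima (max η_E, max T_r) follow from the chosen
generator parameters and are not calibrated to any published maxima.

## Benchmark report

`run_benchmark` composes the four stages over a YAML/dict manifest.
Replicates (default 3) are averaged before analysis: flow curves pointwise
(identical grids by construction), friction and QCM-D traces pointwise, and
thinning replicates are fitted individually with the scalar outputs averaged
— pointwise averaging is ill-defined across censored breakup tails. Per-
sample failures are recorded in the table row, not fatal to the run.
Rendering writes a CSV (stable ordering and formatting: re-rendering the same
table is byte-identical; absent fields are empty cells), a YAML run log and
comparison plots. Significance testing is deliberately not reimplemented; the
CSV carries an empty `p_value` hook column for externally computed tests.
Problem sizes throughout (trace lengths of ~10²–10³ samples, 50-seed recovery
suites) are chosen so the entire validation suite runs in seconds while
keeping Monte-Carlo error well below the asserted tolerances.

## Known limitations

* The Cross-model fit can be slow to identify λ on curves with no visible
  low-rate plateau; parameters remain well-defined in the fitted range but η₀
  is then an extrapolation.
* The elastic-fit window search is a deterministic heuristic (grid of
  sub-windows), not an exhaustive optimum.
* Strain-rate-based quantities are biased within a few smoothing windows of
  the breakup singularity; maxima extracted near breakup inherit that bias.
* The saturation-time estimator references the *measured* plateau, so traces
  still adsorbing at the rinse saturate relative to their own trailing
  median unless |Δf| is declining there.
* `segment_regimes` assumes a monotone speed grid spanning ≥1.5 decades and
  ≥8 points; sparser sweeps are rejected rather than guessed at.
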