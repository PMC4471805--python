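# Methods

This note documents the models implemented in `oligomass`, their
assumptions, the numerical choices behind them, and what the synthetic-data
generators do and do not emulate.

## Mass-action assembly model

An `AssemblyScheme` consists of an indivisible **base unit** — a monomer,
or an *obligate dimer* when one interface is so tight that it never
dissociates over the experimental concentration range (for SAS-5, dimers
persist down to 20 nM, ~two orders of magnitude below the lowest on-column
concentrations, so treating the dimer as obligate introduces no observable
error) — and an ordered series of association steps. The first step
assembles its product directly from the required number of base units
(e.g. 3 M ⇌ T with kd₃ = [M]³/[T], units μM²); each later step adds base
units to the previous product ([P·b] = [P][b]/kd, units μM per base unit
added). All totals are quoted as **protomer-equivalent μM**: a hexamer at
1 μM contributes 6 μM.

At total concentration c the free base-unit level x is the unique
nonnegative root of the strictly increasing polynomial
Σᵢ orderᵢ·[Sᵢ](x) = c. The root is bracketed in [0, c/base_order] and
found by Brent's method at machine-precision tolerance, so no starting
guess exists to go wrong and mass conservation holds to ~10⁻¹² relative
(tested at 10⁻⁹, and against a naive fixed-iteration bisection oracle at
10⁻⁸). c = 0 short-circuits to an all-zero distribution.

The MALS observable is the weight-average mass
MW_w = Σ cᵢMᵢ²/Σ cᵢMᵢ, strictly increasing in total concentration and
bounded by the smallest and largest species masses. A fusion tag enters
only through the per-protomer mass, so it rescales the MW curve by a
common factor without touching the equilibrium populations — fitted
dissociation constants are tag-invariant, which the tests verify.

### Apparent Kd

Experimentalists quote a single "apparent Kd" per construct even for
multi-step schemes. The default estimator is observable-level: the total
concentration at which the model MW crosses the midpoint
(M_min + M_max)/2. For a direct monomer↔trimer step this has the closed
form c_mid = 2·√(kd₃/3) (midpoint ⇔ equal mass fractions ⇔ [M] = 3[T]).
A second estimator — the zero of d²MW/d(log₁₀c)², the literal inflection
of the sigmoid — is available behind a flag; the two differ by a
scheme-dependent factor of order one. Because the community is ambiguous
about whether such constants are quoted on the protomer or particle
concentration scale, both are exposed (`scale="protomer"`, the default and
the scale matching tabulated on-column concentrations, or
`scale="particle"`).

### Association fitting

Free stepwise constants are optimized in log₁₀ space (bounds 10⁻⁴–10⁴ on
the μM scale, which both enforces positivity and gives the optimizer a
well-scaled variable), by trust-region least squares on the MW residuals,
weighted by per-point σ when available. Multi-step fits start from the
template's constants; the shipped presets use equal stepwise constants,
which is also the natural tie-break when data cannot separate the steps.
A constant pinned at a bound — the signature of non-associating data — is
reported as `converged=False` rather than an exception. Confidence
intervals come from a case-resampling bootstrap (default 200 replicates,
seed 1729, 2.5/97.5 percentiles) because no analytic uncertainty is
defensible for the strongly nonlinear midpoint functional. The default fit
for coiled-coil data is direct monomer↔trimer; an explicit dimer
intermediate (`monomer_dimer_trimer`) is provided for users who prefer it,
since MW data of this quality rarely distinguish the two.

## SEC-MALS trace processing

Per elution slice: mass concentration c = Δn/(dn/dc) with dn/dc =
0.1850 ml/g applied to all constructs (tags shift the true value by a few
percent; a single value is used deliberately, matching standard practice),
and MW = LS/(k·c) with one lumped calibration constant k. The full
multi-angle Zimm formalism is omitted on purpose: these constructs are far
below the angular-dependence size limit, where every angle carries the
same information. Baselines are the median of the outer 5% of slices —
robust, parameter-free, and exactly invariant to constant detector offsets
(tested to <0.1%). Slices below 5% of the apex concentration are masked,
not raised: MW there is a ratio of two small noisy numbers.

Each injection reduces to one binding point: the **apex-slice**
concentration (the single value tabulated per injection; a window average
is the other defensible choice and would read systematically lower) and
the concentration-weighted mean MW over the half-height window. Under the
fast-exchange assumption — the observed MW reflects equilibrium at each
slice's concentration, the same assumption implicit in plotting MW against
on-column concentration — the window mean sits genuinely below MW at the
apex concentration, so the round-trip contract (1% noiseless) is stated
against the window average of the generative profile, which is what the
detector inversion can recover. Re-equilibration during on-column dilution
is not modeled. Peaks whose leading/trailing half-widths differ by more
than 3× are flagged as overloaded and excluded from fits by default; the
threshold is a heuristic, since overloading is usually judged by eye.

## CD spectra

Smoothing is Savitzky–Golay (scipy, `mode="interp"`: polynomial fits on
truncated windows at the edges). Wavelengths with detector high-tension
voltage above 800 V are dropped before smoothing. Mean-residue ellipticity
uses the standard θ/(10·C_M·l·N_res) conversion.

Secondary-structure deconvolution is nonnegative least squares against a
three-component basis, with coefficients renormalized to fractions summing
to 1 and the rms residual reported. The shipped basis consists of
**synthetic idealized** helix/strand/coil spectra (sums of Gaussian bands
at the canonical extrema: helix 192/208/222 nm, strand 196/217 nm, coil
198 nm), constructed in `synthetic_basis`. Against real spectra the
decomposition is therefore semi-quantitative — as CD secondary-structure
estimation generally is — while recovery of fractions for spectra blended
from the same components is exact at zero noise and within ±0.05 at 2%
noise.

## Thermal unfolding

θ₂₂₂(T) is modeled as one or two independent two-state transitions between
linear folded and unfolded baselines:

θ(T) = (1−F)·B_f(T) + F·B_u(T),  F(T) = Σⱼ wⱼ fⱼ(T),
fⱼ = Kⱼ/(1+Kⱼ),  Kⱼ = exp[−(ΔHⱼ/R)(1/T − 1/Tmⱼ)]  (T in kelvin),

with ΔCp = 0 and weights wⱼ ≥ 0, Σwⱼ = 1 partitioning the folded→unfolded
change (the per-transition amplitude in ellipticity units,
wⱼ·(B_u−B_f)(Tmⱼ), is derived and reported). This parameterization keeps
both baselines meaningful for two transitions while guaranteeing the
expected limits: θ is the exact folded/unfolded midpoint at Tm for flat
baselines, a step function as ΔH → ∞, a baseline blend as ΔH → 0, and a
straight line when all weights vanish. The two transitions are treated as
thermodynamically independent (additive), which is the natural reading of
two structurally separate domains.

Fitting is multi-start nonlinear least squares: candidate Tm values every
10 °C across the data range (ordered pairs for two transitions), a capped
exploration from each start, and an uncapped polish of the winner;
baselines initialize from linear fits to the outer 15% of points; bounds
keep Tm inside the data range, ΔH in 5–3000 kJ/mol and w₁ in 0.02–0.98.
Residuals are weighted by inverse signal magnitude (floored at 5% of the
maximum) because detector noise scales with the signal: the folded-state
ellipticity is large and noisy while the unfolded baseline is small and
quiet, and unweighted fitting audibly skews high-temperature midpoints.
Transitions are reported sorted by Tm. The apparent Tm is the fitted
midpoint; a model-free derivative-maximum estimator
(`tm_from_derivative`) is provided as a cross-check, and the two agree to
within the transition width for well-resolved data.

A transition is flagged **non-cooperative** when any of: its amplitude is
below 3× the residual noise; its van't Hoff 10–90% width,
ln(81)·R·Tm²/ΔH, exceeds the measured temperature span (a "transition"
broader than the data is a baseline in disguise); or an F-test (1% level)
shows that dropping one transition does not significantly worsen the fit,
in which case the smallest-amplitude transition takes the flag. The
3σ-amplitude rule alone passes pseudo-transitions fitted to noise, which
is why the width and model-comparison checks exist.

ΔTm between two independently fitted curves is a plain difference of
matched transitions, requiring equal transition counts and convergence of
both fits.

## Synthetic data

The generators reproduce the statistical structure the analysis assumes,
at the published experimental designs:

- **Dilution series**: concentrations top·2⁻ⁱ. The default design (top
  152 μM, 11 points, 3% multiplicative lognormal MW noise) matches the
  coiled-coil construct's tabulated range (0.18–152 μM; 11 two-fold steps
  from 152 μM reach 0.148 μM, the right span). MW noise is lognormal
  because MALS noise grows with signal. The per-construct design table
  (monomeric masses, columns, concentration ranges) ships in
  `sec_mals_designs()`.
- **Chromatograms**: (split-)Gaussian concentration profile; per-slice
  composition from the equilibrium model at that slice's concentration
  (fast exchange); detector forward models exactly inverse to the
  processing module; additive Gaussian noise scaled to each trace's apex
  (detector noise does not vanish off-peak). The generator takes the apex
  concentration directly; the instrument-dependent dilution between loaded
  and on-column concentration is not modeled.
- **Melts**: forward model plus multiplicative noise (2% default) on a
  4–90 °C, 1 °C/min-style grid.
- **Native MS**: forward m/z prediction only, m/z = (M_Da + z·1.00728)/z;
  no adducts, charge reduction or in-flight dissociation, and no intensity
  model.

Every generator is bit-reproducible from its seed, and its noiseless
output is exactly the corresponding forward model (inverse-pair tests).
What passing these tests shows is that the estimators recover the truth
**under the assumed noise models**; real data add band broadening,
inter-detector delays, baseline drift, scan-rate effects and aggregation,
none of which are simulated, so accuracy there depends on how well those
effects are controlled upstream.

## Benchmark problem sizes

The recovery benchmarks in `scripts/acceptance.py` use the designs above
directly: 87-point melts (4–90 °C at 1 °C) at 2% noise for the Tm and ΔTm
recoveries, and a 12-point geometric grid spanning ~17 orders of magnitude
for the zero-concentration MW limit (the limit is already converged to
10⁻⁶ relative well before the last point). The dilution-series Kd recovery
in the test suite uses 11 × 3 points at 3% noise, the full tabulated
design. These sizes are the experiments' own; nothing is scaled down.

## Known limitations

- Hetero-association, assembly kinetics, and temperature/pressure
  dependence of the constants are out of scope.
- The single-constant Rayleigh relation ignores angular dependence;
  inappropriate for particles approaching λ/20.
- ΔCp = 0 means fitted ΔH is a van't Hoff enthalpy at Tm only; melting
  of marginally stable proteins with strong cold denaturation will
  misfit.
- The deconvolution basis is idealized; for publication-grade secondary
  structure content use a curated reference set on a matched wavelength
  range.
- Overload detection by asymmetry ratio is a heuristic and will miss
  overloading that broadens symmetrically.
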