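# Methods

This note documents the models, estimators and numerical choices behind
`kexlitmus`, in the package's own words.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Kinetic laws and their validity

The exchange rate observed by relaxation dispersion on a residue of the
protein P is modeled as the slowest nonzero relaxation rate of the
single-molecule jump process at a *fixed* equilibrium free-ligand
concentration [L]_eq.  For the three-state mechanisms (CS, IF) this is the
smaller root of λ² − Sλ + Q = 0 with S = k₁₂ + k₂₁ + k₊[L]_eq + k₋ and a
mechanism-specific Q; for two-state binding it is k_on[L]_eq + k_off.
These laws hold at all concentrations — no pseudo-first-order excess of
either partner is assumed.  The implementation evaluates the smaller root
in the cancellation-free form 2Q/(S + √(S² − 4Q)); the naive form loses up
to half the significant digits when Q ≪ S².

Assumptions: exactly two protein conformations, one binding site,
equilibrium conditions (titration, not mixing), and fast exchange on the
chemical-shift timescale so that a single population-averaged resonance is
observed.

An independent eigenvalue oracle (`relaxation_oracle`) rebuilds the 2- or
3-state generator matrix and extracts its nonzero eigenvalues numerically.
Eigenvalues are polished with two Newton steps on the characteristic
polynomial assembled from matrix invariants (trace, second invariant,
determinant) in extended (80-bit) precision: the second invariant suffers
catastrophic cancellation when rates span six decades, which otherwise
limits agreement with the closed forms to ~1e-9 relative; with the polish
the two routes agree to better than 1e-10 over random log-uniform rates in
[1, 1e6].

## Equilibrium free ligand

[L]_eq is the positive root of the quadratic mass balance in [P]₀, [L]₀
and K_d, evaluated by the closed form followed by one Newton step on the
mass-balance residual f(L) = L + [P]₀L/(K_d + L) − [L]₀, which suppresses
cancellation when [L]₀ ≈ [P]₀ and K_d ≪ [P]₀.  K_d = 0 is defined by
continuity as the stoichiometric limit max([L]₀ − [P]₀, 0).

## Dispersion layer

`R2_eff = −(1/T)·ln(I/I₀)` with the constant-time delay T (default 60 ms).
The fast-exchange model's field factor is implemented as b₀ = 2π·field_MHz
(rad·s⁻¹ per ppm), so the amplitude ψ_ex carries units of ppm² and equals
p_A·p_B·Δδ² for two-site exchange.  Only the *ratio* of fields affects
k_ex; the convention fixes the scale of ψ_ex.

Joint fits share ψ_ex and k_ex across fields with one R₂,₀ per field,
weight points by 1/σ², optimize log(k_ex) and log(ψ_ex) for positivity
(multi-start at k_ex = 10³, 10⁴, 3·10⁴ s⁻¹ against the shallow-valley
minima typical of fast-exchange fits), and report errors from the
residual-scaled covariance s²(JᵀJ)⁻¹ evaluated in *linear* parameter
space.  The linear-space covariance matters: delta-method errors derived
from log-space standard errors are exactly proportional to the estimate,
and inverse-variance pooling of such (value, σ ∝ value) pairs
systematically favors downward fluctuations.

A fitted amplitude smaller than twice its own error is flagged
`no_dispersion`: k_ex is unidentifiable from a flat profile, and such
conditions are excluded from k_ex-vs-concentration profiles.

Measurement uncertainty follows the reference-residue protocol: a global σ
as the mean standard deviation of R₂,eff over the frequency grid for a set
of non-exchanging residues (default: the 5 residues with the lowest
standard deviation), residue-specific σ from repeat measurements at one
frequency, and the larger of the two assigned per residue.

## Profile fits and identifiability

Titration profiles are short (6–9 concentrations), so the mechanism fits
are constrained:

- **CS (default)**: free {k₁₂, k₋}; k₂₁ = C − k₁₂ with C the free-protein
  conformational-exchange floor (default 20,000 s⁻¹, configurable); k₊
  derived from a *fixed* dissociation constant (default 370 µM).  K_d is
  always measured independently by titration in this experimental design;
  letting it float (available via `cs_float_kd`) opens a ridge between
  k₁₂ and K_d that biases the plateau estimate by tens of percent at
  realistic noise (Monte-Carlo: mean k₁₂ −35% at σ_kex = 150 s⁻¹ with
  floating K_d, unbiased with fixed K_d).  A full 4-parameter fit exists
  behind `cs_full` for long, precise titrations.
- **TS (default)**: single parameter k_off, k_on tied through the same
  K_d; free 2-parameter mode via `ts_free`.
- **IF**: free {k₁₂, k₂₁, k₋} with k₊ tied through K_d.

The objective is least squares on **ln k_ex** with weights (k_ex/σ)²:
dispersion-derived exchange rates carry approximately constant *relative*
error, and linear-scale weighting by the self-estimated σ over-weights
downward noise excursions (whose absolute σ is smaller), biasing intercept
and plateau estimates low by 10–25% at 30% relative noise (Monte-Carlo in
the test suite's regime); on the log scale the weights are scale-free and
the bias largely disappears.  Multi-start initial guesses come from a
half-decade grid scored by the same objective.

Model comparison uses AICc in the known-variance Gaussian form
AICc = wSSE + 2k + 2k(k+1)/(n−k−1) with k the number of free parameters:
the σ are propagated measurement errors, not estimated from the profile
residuals, so no variance parameter is counted.  With n = 6–7 points the
estimated-variance form would add a ~15-unit penalty difference between a
2- and a 1-parameter model and make the comparison insensitive to a
tenfold fit-quality difference.

## Classification

Per residue: a profile whose best fit does not beat the
concentration-independent (flat) model by ΔAICc ≥ 2 is "ambiguous".  A
decreasing fitted profile can only be CS; the verdict "CS" additionally
requires the CS fit to beat the runner-up by ΔAICc ≥ 2 (threshold
configurable).  Increasing profiles are assigned TS or IF by the same
margin, with "TS (IF not excluded)" when they cannot be separated — and an
increasing CS branch (k₁₂ > k₋) is *never* excluded by the litmus; the
test is decisive only for decreasing profiles.

Study level (`run_litmus`): per-residue weighted-regression slopes of
k_ex vs. [L]₀ are pooled by inverse variance; a pooled slope negative
(positive) beyond 2σ gives a decreasing (increasing) study, and the
mechanism follows as above with TS-vs-IF decided by summed AICc.  This
aggregates evidence across residues without sharing kinetic parameters
between them — individual residues are often individually ambiguous at
realistic noise while the study-level trend is decisive.

Pooling: `weighted_average` is plain inverse-variance with the pooled σ
inflated by √χ²_red of the between-entry scatter when entries disagree
beyond their stated errors.  `run_litmus` applies it to rate parameters on
the log scale (entries (ln k, σ/k)) because σ_k of rate fits is strongly
correlated with k itself (r ≈ 0.8 in simulation); linear-scale pooling of
such entries is biased low by ~20% even with perfectly calibrated errors.

## Bloch–McConnell simulator

Two-site transverse magnetization is propagated through the CPMG echo
train: free evolution under the 2×2 complex matrix (shift difference on
the minor site; exchange rates p_B·k_ex and p_A·k_ex), ideal 180° pulses
as complex conjugation, echo unit τ–180–τ with τ = 1/(4ν).  Nominal CPMG
frequencies snap to the nearest even echo count inside the constant-time
delay, mirroring constant-time CPMG practice; the realized frequency is
what the generator writes to file.  R₂,eff → the population-weighted
intrinsic R₂ as ν → ∞, and the deviation from the Luz–Meiboom closed form
grows monotonically as Δω/k_ex leaves the fast-exchange regime (asserted
at three regimes in the tests; within 2% on the full grid for
k_ex ≥ 50·Δδ·field).  Anti-phase/in-phase relaxation interconversion, pulse
imperfections and off-resonance effects are not modeled; the simulator
treats one effective coherence.

## Synthetic data generator

The generator emulates a titration relaxation-dispersion study: observed
protein at 1 mM; partner stepped over the titration series; 14 CPMG
frequencies (66.7–6000 Hz); two ¹⁵N fields 60.795/96.313 MHz (a
single-field variant reproduces the partner-side design at 81.1 MHz);
T = 60 ms; Gaussian intensity noise of a given fraction of the reference
intensity (default 5%).  For each concentration the mechanism's exact
k_ex law and the jump process's bound fraction parameterize an effective
two-site spin system (unbound vs. bound; for CS the two unbound conformers
are averaged into one site — inter-conformer shifts of the free protein
are not modeled, a documented approximation).  R₂,eff comes from the
Luz–Meiboom form or the Bloch–McConnell propagator (selectable).

Noise enters R₂,eff as Gaussian with σ = f/(T·I/I₀), the first-order
propagation of intensity noise (fraction f of the reference intensity)
through the log transform.  Adding noise to intensities and applying the
exact log instead injects a Jensen-inequality bias and breaks down
entirely where the signal decays below the noise floor; the first-order
form keeps the level and the heteroscedastic structure (points with little
surviving signal get proportionally large σ) while leaving the k_ex
estimator unbiased.  L₀ = 0 is skipped: with no partner there is no bound
population and no binding-related exchange contrast.

Default bound-vs-unbound shift difference: 2 ppm (¹⁵N), default intrinsic
R₂,₀ 10 s⁻¹.  At the titration's highest bound fractions this yields
exchange amplitudes up to ~90 s⁻¹, i.e. conditions where much of the
low-frequency dispersion is strongly relaxed; the heteroscedastic σ
handles this by down-weighting, but users emulating a specific system
should set `ShiftModel.delta_ppm` to the observed shift change (typical
¹⁵N titration shifts are a few tenths of a ppm to a few ppm).

What passing synthetic-data tests do **not** show: robustness to
peak-overlap and picking errors, B₁ inhomogeneity and off-resonance
effects, sample heating, scalar-coupling/anti-phase effects, or deviations
from two-conformation kinetics — none of which the generator emulates.

## Conformer populations

Wild-type "in"/"out" populations interpolate the wild-type chemical shift
between mutant anchor shifts per nucleus,
p_in = (δ_wt − δ_out)/(δ_in − δ_out), combined across nuclei by
inverse-variance weighting (the weighting scheme is this package's choice;
simple averaging differs negligibly for the anchors' typical separations).
The wild-type position error is ½·linewidth/SNR converted to ppm.
Binding-induced population shifts use the two-conformer competitive-binding
relation p_bound,in ∝ p_in/K_d,in, with first-order error propagation from
the conformer dissociation constants; this closed form is the adopted
interpretation of "population shift from the ratio of dissociation
constants".

## Problem sizes and replication

Simulation studies in the tests and the acceptance script use 22-residue
(two-field, CS) and 12-residue (single-field, TS) synthetic studies, 100
and 40 seeded replicates respectively, chosen as the smallest ensembles
that give stable verdict rates and pooled-parameter distributions.
Parameter recovery is judged against the *per-study* pooled uncertainty
(~10–15% for k₁₂), the precision scale such a study actually delivers.
Residual small-sample biases at the default 5% intensity noise — pooled
k₁₂ typically ~10% low, pooled k_off ~5% low — are visible in the
acceptance output and shrink with noise.

## Known limitations

- The litmus cannot distinguish TS from IF, or from CS with k₁₂ > k₋, on
  increasing profiles within a sampled concentration range that does not
  resolve curvature/plateau.
- The constrained CS scheme inherits its k₂₁ from the configured
  conformational-exchange floor C; k₁₂/(k₁₂+k₂₁) is therefore an upper
  bound on the excited population, not an estimate.
- Slow- and intermediate-exchange CPMG regimes (distinct peaks,
  Carver–Richards lineshapes) are out of scope; inputs violating fast
  exchange will fit but with model error that the Bloch–McConnell oracle
  can quantify.
- `weighted_average` assumes independent entries; residues sharing
  systematic errors (e.g. a common miscalibrated field) violate this.
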