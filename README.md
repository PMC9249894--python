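# kexlitmus

Classify protein–partner recognition mechanisms — two-state binding (TS),
induced fit (IF), or conformational selection (CS) — from
ligand-concentration-dependent CPMG relaxation-dispersion NMR, for binding
kinetics too fast for stopped-flow mixing (k_off ≳ 1000 s⁻¹, microsecond to
sub-millisecond exchange).

## Who this is for

Solution-NMR groups measuring high-power ¹⁵N CPMG relaxation dispersion on
an observed protein while titrating an unlabeled partner, who want a
reproducible, scriptable version of the "litmus test": the *sign* of the
exchange rate's dependence on total partner concentration identifies the
recognition mechanism.

## The model

A protein **P** binds a ligand **L** directly or through a conformational
step:

```
TS:  P + L ⇌ PL                        (k_on, k_off)
CS:  P₁ ⇌ P₂;  P₂ + L ⇌ P₂L            (k₁₂, k₂₁; k₊, k₋)
IF:  P₁ + L ⇌ P₁L;  P₁L ⇌ P₂L          (k₊, k₋; k₁₂, k₂₁)
```

The NMR-visible exchange rate is the slowest nonzero relaxation rate of the
single-molecule jump process at the equilibrium free-ligand concentration
[L]_eq (quadratic mass balance in [P]₀, [L]₀, K_d):

- k_ex^TS = k_on·[L]_eq + k_off
- k_ex^CS, k_ex^IF = ½(S − √(S² − 4Q)), S = k₁₂ + k₂₁ + k₊[L]_eq + k₋,
  with Q = k₁₂(k₊[L]_eq + k₋) + k₋k₂₁ (CS) or Q = k₊[L]_eq(k₁₂+k₂₁) + k₂₁k₋ (IF)

TS and IF always give k_ex *increasing* with [L]₀; CS gives a *decreasing*
k_ex whenever the conformational excitation rate k₁₂ is smaller than the
unbinding rate k₋ — the litmus.  Per sample condition, k_ex is extracted by
jointly fitting multi-field R₂,eff(ν) dispersion profiles with the
fast-exchange (Luz–Meiboom) model

```
R₂,eff = R₂,₀(B₀) + (ψ_ex B₀²/k_ex)(1 − (4ν/k_ex)·tanh(k_ex/4ν))
```

with one baseline R₂,₀ per field and shared ψ_ex, k_ex.  Per-residue
k_ex([L]₀) profiles are then fitted with each mechanism's law, residues are
classified by slope sign and small-sample Akaike weights, and the rate
parameters are pooled by inverse-variance weighting.  A Bloch–McConnell
CPMG propagator provides a numerical oracle for the fast-exchange
approximation, and a seeded generator produces synthetic titration datasets
for power analysis and validation.

## Worked example

Simulate a conformational-selection titration study (observed protein 1 mM,
partner 0.02–1 mM, 14 CPMG frequencies 66.7–6000 Hz at ¹⁵N 60.795 and
96.313 MHz, 60 ms constant time, 5% intensity noise), then run the full
analysis:

```python
import kexlitmus as kx

truth = kx.MechanismParams.conf_selection(
    k12=1280.0, k21=18720.0, k_plus=1.0224e8, k_minus=2420.0
)  # K_d = 370 uM
design = kx.TitrationDesign(P0=1e-3, L0_series=(0, 2e-5, 5e-5, 1e-4, 2.5e-4, 5e-4, 1e-3))
exp = kx.ExperimentDesign(noise_sigma_intensity=0.05, seed=7)
shifts = {f"R{i:02d}": kx.ShiftModel() for i in range(8)}

table, provenance = kx.simulate_study(truth, design, exp, shifts)
profiles = kx.profiles_from_dispersion(kx.curves_from_frame(table), P0=design.P0)
verdict = kx.run_litmus(profiles)

print(verdict.study_verdict)
for name, (value, sigma) in verdict.pooled.items():
    print(f"{name} = {value:.0f} +/- {sigma:.0f} s^-1")
```

Output:

```
CS
k12 = 928 +/- 168 s^-1
k_off = 2201 +/- 136 s^-1
```

The study is classified as conformational selection because the pooled
k_ex-vs-[L]₀ slope is negative beyond 2σ.  The pooled conformational
excitation rate k₁₂ and unbinding rate k_off sit within roughly two pooled
standard errors of the generating values (1280 and 2420 s⁻¹); the median
over many replicate studies lands at about −10% and −5% of truth
respectively (see `docs/methods.md` on small-sample bias at this noise
level).  The bound on the
excited unbound-state population follows from the free-protein
conformational exchange floor:

```python
>>> kx.excited_population_bound(1280.0, 20000.0)
0.064
```

The same steps are available as a CLI for shell pipelines:

```
kexlitmus simulate --mechanism CS --params params.yaml --design design.yaml --seed 7 --out sim/
kexlitmus fit-dispersion --input sim/dispersion.csv --out fits/run1
kexlitmus litmus --kex-table fits/run1_kex.csv --p0 1mM --out fits/run1
kexlitmus report --verdict fits/run1_verdict.json
```

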