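# presteady

Presteady-state kinetics and implicit-membrane electrostatics of
electrogenic membrane transporters.

Secondary-active transporters such as the Na⁺-coupled neutral amino acid
exchanger ASCT2 move fractions of an elementary charge across the membrane
electric field with every partial reaction — substrate binding, Na⁺
loading, occlusion. Rapid solution exchange on voltage-clamped cells turns
those partial reactions into transient currents whose amplitudes, signs and
relaxation times report binding affinities, turnover rates and the
*apparent valence* z_Q of each step. `presteady` is a toolkit for both
sides of that analysis, built for people who study transporter mechanisms
with whole-cell electrophysiology and structure-based electrostatics:

* **Electrostatics** — a finite-difference solver for the linearized
  Poisson–Boltzmann equation with an implicit membrane slab and an applied
  transmembrane potential,

      −∇·(ε∇φ) + κ̄²φ = (source of ρ) + κ̄² V f(r),

  where f(r) marks the connected intracellular solution. The valence of a
  binding or conformational transition is the slope of the bound-minus-free
  energy difference versus voltage, z = d(ΔE)/dV / F, with
  E = Σᵢ qᵢ φ(rᵢ). Inputs are PQR structures (coordinates + partial
  charges + radii); charge variants (e.g. a ligand with only its
  carboxylate charged) and bound/free state pairs are first-class objects.

* **Kinetics** — voltage-dependent Markov schemes of electrogenic carriers
  integrated under arbitrary solution-exchange and voltage protocols. Each
  transition carries a rate k₀ and a valence z_Q with the symmetric Eyring
  voltage factor k(V) = k₀ exp(−z_Q F V / 2RT); transport currents are
  I = −eN Σ z_Q·(net flux) (outward positive) and anion currents flow
  through conducting states. A calibrated 6-state competitive-inhibition
  scheme of a Na⁺-dependent amino acid exchanger ships as the default.

* **Synthetic data & fitting** — seeded generators for the canonical
  protocols (paired pulses, inhibitor displacement, dose–response and
  voltage families) with realistic exchange blur and noise, plus the
  matching estimator suite: mono-/bi-exponential fits
  I = I_max(1 − e^(−t/τ)) and I = I₁e^(−t/τ_rise) + I₂e^(−t/τ_decay),
  one- and two-site dose–response fits I = I_max·c/(K_m + c) and
  I = I₁c/(K_m1 + c) + I₂c/(K_m2 + c), paired-pulse recovery assembly,
  and the ln(k)–V regression z_Q = slope · 2RT/F.

## Worked example

```python
import dataclasses
import numpy as np
import presteady as ps

# 1. apparent valence from a measured ln(k)-voltage slope
V = np.array([-100.0, 0.0, 60.0])
k_off = 8.3 * np.exp(-0.0037 * V)            # dissociation rates, 1/s
vfit = ps.fit_voltage_dependence(V, k_off, temperature_K=297.0)
print(f"apparent binding valence zQ = {vfit.zQ:+.3f}")

# 2. simulate a ligand-displacement experiment and fit the biphasic rise
scheme = ps.asct2_default_scheme()
proto = dataclasses.replace(
    ps.displacement_protocol(1.0, preincubation_ms=300, observe_ms=800),
    exchange_profile="erf")
trace = ps.generate_synthetic_traces(scheme, [proto]).traces[0]
fit = ps.fit_displacement_rise(trace, deadtime_ms=5.0)
print(f"displacement rise: tau_fast = {fit.tau_rise_ms:.1f} ms, "
      f"tau_slow = {fit.tau_decay_ms:.1f} ms")

# 3. equilibrium inhibitor occupancy at 1 uM (Kd = 0.83 uM)
occ = ps.equilibrium_occupancy(scheme, {"Na": 140.0, "S": 0.0, "I": 0.001})
print(f"inhibitor-bound fraction at 1 uM = {occ[scheme.index('TNaI')]:.3f}")
```

prints

```
apparent binding valence zQ = -0.189
displacement rise: tau_fast = 5.0 ms, tau_slow = 119.3 ms
inhibitor-bound fraction at 1 uM = 0.546
```

A ln(k)–V slope of −0.0037/mV corresponds to about a fifth of an elementary
charge crossing the field on binding (zQ ≈ −0.19; negative = net negative
charge moving inward, which is why such binding produces *outward* transient
currents despite a net-neutral ligand). The displacement trace rises
biphasically: the ~5 ms phase is substrate activation of the unblocked
transporter fraction, the ~120 ms phase is rate-limited by inhibitor
dissociation (k_off = 8.3 1/s). At 1 μM of a 0.83 μM-K_d inhibitor, 54.6%
of transporters start blocked — which sets the two phases' amplitude split.

A command-line interface wraps the same functionality:

```bash
presteady valence --bound bound.pqr --free free.pqr --slab -15:15 \
        --voltages -100,-50,0,50,100
presteady simulate --protocol paired-pulse --ligand S --conc 2.0 \
        --intervals 10,20,40 --seed 1 --out run1
presteady fit --kind mono-exp --trace run1/trace_000.csv
```

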