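# Methods

This note documents the models, conventions, numerical choices and known
limitations of `presteady`. It covers the two halves of the package — the
implicit-membrane electrostatics used to predict charge-movement valences,
and the kinetic simulation/fitting pipeline used to analyse presteady-state
transporter currents — and the synthetic-data conditions under which the
parameter-recovery benchmarks run.

## Implicit-membrane electrostatics

### Model

The electrostatic potential u(r) (in thermal units kT/e) of a protein in an
implicit membrane under an applied intracellular potential V solves a
modified linearized Poisson–Boltzmann equation:

    -∇·(ε(r) ∇u) + κ̄²(r) u = 4π l_B ρ(r) + κ̄²(r) u_V f(r)

* ε(r): dielectric map — ε_protein inside the probe-inflated atomic
  envelope, ε_membrane inside the slab, ε_solvent elsewhere;
* κ̄²(r) = 8π l_B I_n: modified screening coefficient, nonzero only in
  ion-accessible solvent (outside the Stern shell and the membrane), with
  l_B the vacuum Bjerrum length and I_n the ion number density;
* ρ(r): the atomic partial charges (PQR input), spread onto the grid by
  trilinear (cloud-in-cell) assignment;
* f(r): Heaviside indicator of the *connected* intracellular solution —
  ion-accessible nodes 6-connected to the lower grid face; solvent pockets
  not connected to the lower bath get f = 0;
* u_V = V/(kT/e): the applied potential in thermal units. In the far field
  the equation forces u → u_V wherever f = 1 and u → 0 in the extracellular
  bath, i.e. the membrane potential is imposed through the electrolyte
  screening term, not as an electrode boundary.

The total electrostatic energy is the plain charge–potential sum
E = Σᵢ qᵢ φ(rᵢ) (kcal/mol), with φ interpolated trilinearly at the atom
positions. No ½ charging factor is applied; absolute energies are therefore
convention-dependent (and contain grid self-energy), but every quantity the
package reports — energy *differences* at fixed geometry and slopes versus
V — is independent of both. The **valence** of a transition between a bound
and a free configuration is

    z = d(ΔE)/dV / F,   ΔE(V) = E_bound(V) − E_free(V),

with F = 0.0230609 kcal/(mol·mV·e); z > 0 means net positive charge
displaced toward the intracellular side. The free state is the complex with
the ligand deleted; for a net-neutral ligand the voltage-coupled energy of
the ligand in bulk is zero, so deletion and bulk relocation give identical
slopes. For a *charged* ligand the deletion convention implicitly references
the extracellular bulk (where the voltage profile is zero); this is
documented rather than hidden because no other reference is uniquely
canonical.

### Discretization and solver

7-point finite differences on a uniform grid; harmonic mean of ε on cell
faces; Dirichlet boundary values from the screened-Coulomb superposition of
all charges plus u_V times the closed-form one-dimensional bare-membrane
profile (exponential relaxation with the Debye length in each bath, linear
across the slab). The symmetric positive-definite system is solved by
Jacobi-preconditioned conjugate gradients to a relative residual of 1e-6
(default), with the boundary field as initial guess. Defaults: ε 2/2/80
(protein/membrane/solvent), 150 mM 1:1 salt, 298.15 K, 2 Å Stern layer,
1.4 Å probe, 30 Å slab, 1 Å spacing, voltages {−100, −50, 0, +50, +100} mV.

Verification is against three independent closed forms (asserted in the
test suite): the Debye–Hückel point-charge potential in uniform solvent
(within 5% for r ≥ 6 Å on a 1 Å grid; measured ≤ 1.5%), the 1D
two-dielectric capacitor profile of a chargeless slab at −100 mV (within
2% of V), and the full-translocation limit — a +1 e charge moved from one
bulk to the other carries valence +1.00 ± 0.02. Grid-refinement stability
and superposition of the charge and voltage source terms are asserted as
properties.

The package ships no experimentally derived structures. Valence
calculations on a deposited transporter structure require a PQR with
force-field partial charges prepared upstream; the test suite demonstrates
the full machinery (including single-group charge variants: a lone −1 e
carboxylate, a lone +1 e amino charge) on a synthetic zwitterion toy, where
the buried-anion geometry reproduces the expected sign pattern —
z(carboxylate-only) < z(zwitterion) < 0 < z(amino-only), with
|z(amino)| < |z(carboxylate)| and component additivity by superposition.

## Kinetic model

### Rates, voltage, currents

A carrier is a continuous-time Markov chain. Each directed transition has a
0 mV rate k₀ (multiplied by a ligand concentration in mM when tagged with a
species) and a valence z_Q — the fraction of an elementary charge it moves
toward the cytoplasm. Voltage enters through the symmetric Eyring factor:
the transition's electrical energy change is z_Q F V, half of which tilts
each direction, so the rate of a transition is

    k(V) = k₀ · exp(−z_Q V / (2·RT/F)),

making the forward/backward ratio reproduce the Boltzmann factor
exp(−z_Q F V/RT). A consequence worth stating explicitly because sign
conventions in this area are error-prone: the ln(k)–V slope of a
*dissociation* rate equals the *binding* step's valence over 2RT/F with its
own sign — a binding valence of −0.19 at 297 K gives a dissociation-rate
slope of −0.0037/mV (faster unbinding at negative potentials, i.e. longer
residency at positive potentials), which is exactly how apparent valences
are read off displacement experiments. RT/F = 25.69 mV at 298.15 K; the
rate-law temperature defaults to 297 K (room temperature) and is exposed
everywhere because z_Q scales linearly with it.

Occupancies follow dp/dt = p·Q(t). Within stretches where every input is
constant the propagator is the exact matrix exponential (cached per step
size); during exchange-filtered concentration ramps the master equation is
integrated with an implicit stiff stepper (BDF, rtol 1e-8, atol 1e-12) with
the analytic Jacobian. Occupancy is projected and conservation-checked to
|Σp − 1| ≤ 1e-9 at every output sample; the integrator is verified against
the eigendecomposition closed form to 1e-8.

Recorded current (outward positive, in pA) has two components:

* transport (charge movement): I_t = −e·N·Σ z_Q,ij · p_i k_ij over directed
  transitions — inward displacement of positive charge plots negative;
  zero at any stationary distribution; its time integral obeys charge
  bookkeeping (−e·N × occupancy-weighted valence change) to 0.1%;
* anion: occupancy-weighted aggregate conductance of the conducting states
  times a driving force; positive driving corresponds to permeant-anion
  efflux, an inward (negative) current. The anion channel is treated as
  ohmic with a lumped driving force — no GHK rectification.

### The default exchanger scheme

Six states: T ⇌ TNa ⇌ TNaS ⇌ TNa2S ⇌ TSocc, with the dead-end inhibitor
branch TNa ⇌ TNaI. T and TNa carry the constitutive anion leak
(16.7 nS aggregate ≈ 1 nA at 60 mV driving); TNaI blocks it; the
substrate-activated anion conductance (50 nS) is carried by the occluded
intermediate TSocc. Assigning the activated conductance to the occluded
state rather than to TNa2S is deliberate: if both carried it, the occlusion
relaxation would shuffle occupancy between equally conducting states and be
electrically invisible, leaving the activation time constant unidentifiable
from anion currents; placing the channel-open conformation at the
translocation intermediate is also the standard view for this transporter
family.

Equilibrium constants are the measured apparent affinities: Na⁺ at the
high-affinity (apo) site K_m 0.04 mM; Na⁺ at the substrate-gated site K_m
49 mM; inhibitor K_d 0.83 μM with k_off 8.3 1/s (120 ms residency);
substrate K_d 0.5 mM with diffusion-fast binding (3·10⁶ M⁻¹s⁻¹) — substrate
residency is short, a requirement for fast exchange turnover. Binding steps
are fast so that the occlusion step is cleanly rate-limiting; its forward
and backward rates are *calibrated*, by deterministic nested 1D
root-solving on the generator's eigenvalues at construction time, so that
the slowest substrate-pathway relaxation equals 19 ms during washout
(the turnover/recovery constant) and 4.9 ms during 2 mM substrate
application (the activation constant). The smallest-root branch is selected
so the de-occlusion step, not a degenerate mode crossing, is the
rate-limiting reset.

Valences: substrate/inhibitor binding −0.08 (the structure-based estimate;
the electrophysiologically apparent binding valence −0.19 can be set via
the exposed override, and is used by the voltage-dependence experiment);
Na2 loading +0.4 and occlusion +0.3 are free synthetic parameters chosen so
that substrate application at high Na⁺ produces a net inward transient
while at ≤1 mM Na⁺ (Na2 site unloadable) the binding valence dominates and
the transient reverses outward — the polarity logic asserted in the tests.

The scheme leaves the inhibitor-slowed recovery question open: recovery
after inhibitor exposure is simulated either at the displacement-derived
k_off (120 ms) or at the recovery-derived value (230 ms) by overriding
k_off; the package does not assert which reflects rebinding during washout.

## Protocols and synthetic data

Solution protocols are piecewise-constant command concentrations; a
solution exchange filter converts commands into what the cell sees. Two
profiles are provided:

* `exponential` (default): relaxation toward the command with τ = 5 ms.
  Simple, but its slow tail keeps a washed-out ligand above
  binding-competitive levels for ~3τ, which *delays washout-clocked
  observables*: with 2 mM substrate against a 0.5 mM K_d, a 19 ms washout
  relaxation reads as ≈38 ms from paired-pulse peaks.
* `erf`: a sigmoidal interface passage centred at τ with 10–90% width
  1.28τ (≈6.4 ms at τ = 5 ms, within the instrument's stated 5–10 ms
  resolution), emulating a piezo-stepped laminar interface. Because the
  on- and off-latencies are equal and the profile has no long tail, the
  latencies cancel in interval-timed protocols. The standardized
  experiments use this profile.

Voltage protocols are piecewise constant within −100…+60 mV. Noise is
additive white Gaussian (optionally one-pole low-passed), applied to the
summed current after simulation; the (seed, stream) pair fully determines
every sample, and noise SD is always derived as peak amplitude / SNR from
the noiseless trace (SNR 10 in all benchmarks), never hand-set. Output
sampling is 0.1 ms (10 kHz).

What the generator emulates: concentration jumps with realistic exchange
blur, paired pulses with variable interval, preincubation/displacement,
dose–response families, voltage families, leak block, biphasic activation,
and stationary noise at realistic SNR. What it does not: series-resistance
and capacitive artefacts, cell-to-cell parameter variability, drift, 1/f
noise, liquid-junction offsets. Passing recovery benchmarks therefore show
estimator correctness under the modelled acquisition physics, not
robustness to every artefact of real recordings.

## Estimators

All nonlinear fits are trust-region least squares with deterministic
multi-start grids (τ over {1, 3, 10, 30, 100, 300, 1000} ms; K_m over the
log-decades of the sampled range, ordered pairs for the two-site model),
ties broken by SSE. Uncertainties are local-curvature (Jacobian) proxies.

* Mono-exponential: I = I_max(1 − e^(−t/τ)); flat data raise a degenerate
  error; I_max can be pinned (normalized recovery curves).
* Bi-exponential: I = I₁e^(−t/τ_rise) + I₂e^(−t/τ_decay), canonically
  ordered τ_rise ≤ τ_decay, with an F-test (α = 0.05) fallback to one
  component when the second is unsupported.
* Dose–response: one- and two-site hyperbolas with free-sign amplitudes
  (leak block and activation can coexist); two-site requires ≥5 levels and
  flags K_m ratios < 3 as indistinct.
* Voltage dependence: OLS of ln k on V; z_Q = slope · 2RT/F — pure algebra
  beyond the line fit.

Trace-level conventions (fixed for reproducibility, chosen for statistical
sanity rather than inherited from any particular lab):

* Baseline: mean over the 50 ms before the (first) jump. Peak window:
  100 ms after the jump command.
* Paired-pulse assembly: the first pulses of a family are identical
  stimuli, so the peak latency is located once on the family-averaged
  first-pulse response and every amplitude is read at that latency.
  Searching each noisy window for its extremum instead carries an
  extreme-value bias (max of N noise samples) that at SNR 10 drags a 19 ms
  recovery fit to ~13 ms. Traces are lightly smoothed (2 ms boxcar) before
  measurement. Intervals are deadtime-corrected by the exchange time so
  they count ligand-free time; recovery is fitted with the
  mono-exponential form, I_max free by default.
* Displacement rise: the approach to the post-switch plateau
  (plateau − I(t), plateau from the last 15% of samples) is fitted
  bi-exponentially, with the clock started one exchange time after the
  switch command — exponential tails are invariant under the symmetric
  exchange blur, so this removes the early-sample bias on the fast
  constant without deconvolution.

## Parameter-recovery benchmarks

The `experiments` module runs generation + analysis end to end at SNR 10
over 8 noise seeds: paired-pulse recovery (ground truth 19 ms turnover;
230 ms with the slow-inhibitor override), displacement (4.9/120 ms;
4-sweep averages per seed, as sweeps are averaged in practice),
single-site Na⁺ affinity via a weak inhibitor probe at K_d/20 (a
saturating probe would shift the apparent constant by 1 + [I]/K_d through
the coupled binding equilibria, so probing weakly is what measures the
intrinsic 0.04 mM), the two-site Na⁺ pair (0.04/49 mM; curve-model
samples, 6-cell means per level — the estimator-consistency design), and
the displacement-rate voltage dependence (binding valence −0.19 from
ln k_off vs V at −100…+60 mV). Recovery and dose–response statistics are
medians over seeds, mirroring reporting of means over 6–10 cells;
the displacement pair is checked per seed. Problem sizes (5–6 intervals,
13 dose levels, 8 seeds, 10 kHz sampling) keep each benchmark in the
tens-of-seconds range on one CPU.

## Known limitations

* Absolute PB energies include grid self-energy and omit the ½ charging
  factor; only ΔE differences and V-slopes are meaningful.
* The dielectric boundary is the probe-inflated van der Waals envelope, not
  a true solvent-excluded (reentrant) surface; valences, which depend on
  the V-linear far-field coupling, are insensitive to this, but absolute
  solvation-style energies would not be.
* No protonation, charge-assignment or structure-repair logic; PQR inputs
  are taken as given.
* The kinetic integrator is deterministic (master equation); no
  single-channel stochastics.
* The two-site dose–response benchmark is estimator-consistency, not a
  mechanistic steady-state curve: the scheme's coupled equilibria shift
  apparent constants away from the microscopic ones, which is itself the
  reason the weak-probe design exists for the single-site case.
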