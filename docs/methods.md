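# Methods

## Model

The system is a rectangular box of transverse area A = L′² (periodic in
y and z) bounded along x by a fixed grafting wall at x = 0 and a mobile
wall at x = L.  It contains N_f grafted filaments and a fluctuating
number N₁ of free monomers.  Each monomer carries topological indices
(n, k): n = 0 for free monomers, n ≥ 1 the filament, k the rank along
it.  Ranks 1 and 2 are immobile seed monomers at (h_n, y_n, z_n) and
(h_n + d, y_n, z_n); filament sizes never drop below 2.  For N_f = 2l²
the seeds occupy a body-centered square lattice of cell a = L′/l, and
the "homogeneous bundle" staggers the seeds longitudinally by
h_n = (n − N_f/2 − 1/2)·d/N_f — N_f equally spaced phases covering one
monomer length, symmetric about zero.  The printed source for this
staggering formula is ambiguous; uniform phase coverage is the defining
property of a homogeneous bundle and is what the package implements.

Interactions (reduced units d = k_BT = τ_D = 1 throughout):

| term | form | default |
|------|------|---------|
| bond | −ε₀ + k_s(r−d)²/2 | ε₀ = 13.644143, k_s = 4000 |
| bend | κ(1−cos θ) per adjacent-bond triple | κ = 5370 = L_p/d |
| wall | ε_w{(3√3/2)[(d/s)⁹−(d/s)³]+1}, truncated at s_c = 3^{1/6} d | ε_w = 0.1 |

A filament of j monomers carries (j−2) bond terms and (j−2) bend terms;
the seed bond is rigid and the seed triple (1,2,3) anchors the filament
normal to the wall.  Free monomers are ideal (wall interactions only).
The bulk equilibrium constant of the tip reaction follows in closed
form, K₀ = e^{βε₀}(2πd⁴/L_p)√(2π/(βk_s d²))[1−e^{−2L_p/d}] = 39.07 d³.
With the printed constants the relation U_w(s) = k_BT is crossed at
s* = 3^{−1/6} d ≈ 0.833 d (some sources quote 0.846 d for the same
potential; we implement the formula as written).

## Dynamics

Monomers (3D) and the wall (1D) follow underdamped Langevin equations;
the wall additionally feels the trap force −κ_T L and the mean
second-chamber gas pressure −pA with p = k_BT ρ₁.  Integration uses the
two-Gaussian stochastic velocity-Verlet scheme of Vanden-Eijnden and
Ciccotti: position update with the O(h^{3/2}) displacement noise
σh^{3/2}(ξ/2 + η/(2√3)), force recomputation, closing velocity update;
with σ = γ = 0 it reduces exactly to velocity Verlet (energy drift
< 10⁻⁶ relative over 10⁵ steps in the trap-oscillator test).  The time
step h = 5.33×10⁻⁵ τ_D resolves the stiffest mode (bond stretching,
τ_s = 5.9×10⁻³ τ_D).  Default masses and frictions give an overdamped
bare wall in the trap: τ_w,in² ≤ M_w/(4κ_T) for both reference traps.

## Reaction Monte Carlo

Each filament carries two independent Poisson attempt clocks of rate
ν = 7.1×10⁴ τ_D⁻¹, one per direction; events execute at the first
integration-step boundary at or after their scheduled time (h is ~10⁵
times shorter than any mean event waiting time, so the boundary
rounding is negligible; simultaneous events run in time order,
reactions before reservoir moves).

* **Capture** — a candidate is drawn uniformly among the N_r free
  monomers within r_c = 1.5 d of the tip (reservoir sampling; minimum
  image transversally) and becomes the new tip *in place*, accepted
  with min(1, N_r e^{−β·el}) where el is the spring + bend energy of
  the created bond.
* **Release** — the tip monomer becomes free in place (position and
  velocity retained; identical masses keep the kinetic distribution),
  accepted with e^{−βε₀}·min(1, e^{+β·el}/N_r′), where N_r′ counts the
  candidates around the new tip after release, including the freed
  monomer.  A reversibility guard rejects a release whose bond length
  exceeds r_c, and release at j = 2 is always rejected (seeds are
  permanent).

The pointwise acceptance ratio is N_r e^{−βΔU} with ΔU = −ε₀ + el, so
the pair satisfies detailed balance with respect to the Boltzmann
measure.  Splitting the bond-formation factor e^{βε₀} entirely into the
release move (rather than placing e^{−βΔU} in the capture move) is what
reproduces the physical rate hierarchy: the bulk effective
depolymerization rate is then W̃₀ = ν e^{−βε₀}⟨min(1, e^{β·el}/N_r′)⟩
≈ 0.95 ν e^{−βε₀} ≈ 0.080 τ_D⁻¹, and detailed balance fixes
Ũ₀ = ρ̂₁ W̃₀.  Had the e^{βε₀} factor entered the capture acceptance,
any candidate wandering into the small bond-compatible volume would be
captured with probability ~1 and the bulk rates would come out ~30×
too fast.  Near the wall the Brownian-ratchet gate emerges on its own:
candidates in a closing gap are never in bond-compatible positions, so
e^{−β·el} suppresses capture (the measured U_m falls to zero for
m ≥ 0).

Two kinetic regimes follow from the same rules.  The *counted* event
rates (what the m-resolved estimators report, and what the reference
rate plots show) are dominated by correlated capture–release pairs: a
just-released monomer sits in the binding volume and is usually
recaptured before diffusing away.  *Persistent* size changes require a
fresh monomer to arrive (or a freed one to escape) and are
diffusion-limited, which contributes the chemical component of the slow
wall relaxation.  Both regimes share the same equilibrium measure.

## Grand-canonical reservoir

Insertion and deletion attempts (equal probability) run on a Poisson
clock of rate ν_GC = 187.5 τ_D⁻¹.  For this confined ideal gas the
activity equals the target density ρ₁ = ρ̂₁/K₀, giving the standard
acceptances min(1, ρ₁V e^{−βΔU}/(N₁+1)) and min(1, N₁ e^{+βΔU}/(ρ₁V))
with V = A·L the instantaneous chamber volume and ΔU the wall energy of
the exchanged monomer.  Monomers within r_c of any tip are never
inserted or deleted; the exclusion is applied symmetrically so the
reservoir and reaction chains remain jointly reversible.  Measured
acceptance at defaults is ≈ 0.93; the stationary gas reproduces
ρ(s) = ρ₁e^{−βU_w(s)} near the walls and ⟨N₁⟩ = ρ₁A(L − 2δ) with
δ = ∫(1−e^{−βU_w}) ds ≈ 0.87 d the skin depletion depth per wall.

## Observables and estimators

Per step and per filament the relative size m = j_n − z_n,
z_n = 1 + ⌊(L−h_n)/d⌋ (floor; arguments positive in practice), indexes
residence counters ⟨Q_m⟩ and, on reaction events, attempt/success
counters tagged with the pre-event m.  Effective rates are successes
divided by residence time (counter × h).  Plateau (bulk) rates pool
m ≤ −1 for depolymerization and m ≤ −2 for polymerization, the regions
where the wall no longer modulates the rates.  Equilibrium enforces
per-size flux balance Q_m U_m = Q_{m+1} W_{m+1}, so the plateau rate
ratio and the ln⟨Q_m⟩ slope are two views of ρ̂₁.

Autocorrelation functions of the trace observables (L, bundle size I,
filament size i, end-to-end components X and R_⊥) are computed by FFT
with unbiased normalization and fitted by one or two exponentials over
a window iterated once to 3× the initial time estimate.  Standard
errors of means are block averages (10 blocks by default); the trap
length additionally uses the fitted relaxation time to set its
effective sample count.

## Synthetic-data generator and initial conditions

Initial states are bare seeds (or straight chains of a requested
length, for restarts) plus a free-monomer gas drawn as a homogeneous
spatial Poisson process of density ρ₁ with Maxwell–Boltzmann
velocities.  The longitudinal coordinate is rejection-sampled against
e^{−βU_w} at both walls — the equilibrium barometric profile — because
a uniform draw can land in the repulsive core and destabilize the first
steps.  The generator emulates the ideal reactive mixture of the model
exactly; it does not emulate excluded volume, ATP/ADP monomer states,
or capping/branching chemistry, so passing tests say nothing about
those aspects of real actin.

## Problem sizes used by the tests and the acceptance script

Production-scale studies of this system pool tens of independent
trajectories of 1–6×10⁴ τ_D each.  This package's test suite and acceptance
script use single trajectories of 3.5–4.5×10³ τ_D production after
500 τ_D of mobile-wall equilibration, started from a straight chain one
monomer short of the crossover size at L_H (equivalent to growing from
bare seeds at a fraction of the cost; conformations relax in ~30 τ_D).
That is 3–5 wall relaxation times, so trap-length means carry standard
errors of a few d and all statistical assertions use the run's own
error bars.  The two-state detailed-balance oracle runs with a
deliberately softened bond (k_s = 200, κ = 100, ε₀ = 8, ν = 10³) in a
small box: the acceptance rules are parameter-generic, and the soft
bond raises the persistent transition rate by two orders of magnitude,
giving the occupancy-ratio comparison against direct quadrature of the
two configurational integrals ~600 transitions of statistics instead
of ~60.

## Numerical choices and edge cases

* Transverse periodic wrapping applies to free monomers only; filament
  coordinates stay unwrapped (contiguous), and a captured monomer is
  shifted to the image nearest the tip.  x is confined by walls, never
  wrapped.
* A monomer crossing a wall plane (s ≤ 0) aborts the run with a
  diagnostic — it signals a too-large time step.
* Event logs record every successful reaction by default; logging all
  attempts (2ν ≈ 1.4×10⁵ τ_D⁻¹ per filament) is available for short
  diagnostic runs.
* Deletion attempts on an empty gas are counted as refusals.
* Checkpoints pickle the full state including all four labelled RNG
  streams (thermostat, reactions, reservoir, placement) and pending
  event times, so resumed runs reproduce uninterrupted ones bitwise
  when split at step boundaries.
* The m counters clip to |m| ≤ 100; the wall-position histogram uses
  0.1 d bins by default, resolving the monomer-scale oscillations a
  single filament imprints on P(L).

## Known limitations

* Excluded-volume interactions between monomers are not implemented
  (the model is validated in ideal conditions).
* Counted effective rates include correlated capture–release pairs (see
  above); at the production stiffness the persistent event rate is
  diffusion-limited, so very long runs are needed for slow-mode
  statistics — reproduced here only at reduced precision.
* Single monomer species; no ATP/ADP distinction, capping, branching,
  or flexible obstacles.
* The escaping-filament regime (growth parallel to the wall) is outside
  the validated parameter range; trap strengths should keep
  ⟨L⟩ within the non-escaping window.
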