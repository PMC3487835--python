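# Methods

## The toy filter system

The synthetic system replaces an all-atom channel with a one-dimensional
pore axis *z* (increasing toward the extracellular side) carrying eight
named regions — Sint, S5, S4, S3, S2, S1, S0, Sext — ordered
intracellular → extracellular; S1–S4 are the canonical filter sites
numbered from the extracellular side.  The single-ion potential is a sum
of Gaussian wells at the site centers (σ = 0.45 Å) and Gaussian barriers
at the midpoints (σ = 0.35 Å); with the default 3.1 Å spacing (a typical
carbonyl-cage spacing in K⁺ filters) the neighboring tails are
negligible, so the potential at a site center equals minus that site's
well depth.  Ions interact through a screened repulsion
*A*/r · e^(−r/κ) (defaults *A* = 20 kcal·Å/mol, κ = 2 Å, about
1.4 kcal/mol at one site spacing), which diverges at contact and
therefore enforces single-file order in one dimension, and a soft
harmonic confinement (5 kcal/mol/Å² beyond 2 Å past the outer sites)
stands in for the boundary potentials that keep ions near the filter.
Default well depths (3 kcal/mol) and barriers (2.5 kcal/mol) are chosen
once as a realistic low-conductance filter scale — deep enough for
metastable occupancy states, shallow enough that the desk-scale runs
equilibrate.

Dynamics is overdamped (position-only) Langevin,
dz = (D/kT)·F·dt + √(2 D dt)·ξ, with time in ps and D in Å²/ps.  The
Euler–Maruyama step is stable for D·k·dt/kT < 1 on a harmonic mode of
stiffness k and biases the equilibrium variance by a relative
D·k·dt/(2kT); the default dt keeps this below ~2 %, which the
equipartition test measures directly.  What the surrogate deliberately
omits: inertia, explicit water, a force field, and any filter backbone
dynamics coupled to the ions — so passing tests validate the estimators
and the pipeline, not any all-atom prediction.

`exact_fes` integrates the Boltzmann factor of the analytic potential by
brute-force quadrature over the non-tagged ions (restricted to the
ordered sector, since single-file dynamics cannot relabel ions) and is
the oracle for every free-energy estimator; its own convergence is
checked by resolution doubling (< 0.05 kcal/mol change).

## Collective variables

Path CVs use the standard forms: progress
S = Σ (i−1)e^(−λDᵢ) / [(P−1) Σ e^(−λDᵢ)], normalized to [0, 1], and
distance Z = −(1/λ) ln Σ e^(−λDᵢ), with Dᵢ the MSD of the potassium
ions after least-squares superposition on the rigid scaffold.  The
normalized convention is the default because the occupancy states of
the permeation cycle map naturally to S = 0.00 … 1.00; the raw 1…P
scale is exposed via `normalized=False`.  Ions are indistinguishable,
so the measured ions are relabeled by ascending z before the metric is
computed.  Both CVs are evaluated with the distance-shifted
(log-sum-exp-stable) form; a configuration whose nearest frame is
further than 700/λ raises an error suggesting a λ/metric check rather
than silently returning 0/0.

The reference permeation path interpolates the ion triplet through the
occupancy-state waypoints Sint,[S4,S2] → S5,[S4,S2] → S5,[S3,S1] →
[S4,S3,S1] → [S4,S2],S0 → [S4,S2],Sext and equalizes adjacent-frame
chords by a fixed-point reparameterization (raw arc-length spacing
shortens chords at waypoint kinks); the residual inhomogeneity is below
1 %, comfortably inside the 10 % contract.  P defaults to 16, and λ
defaults to 9.21/⟨adjacent MSD⟩ so a neighboring frame carries weight
e^(−9.21) ≈ 10⁻⁴.

N_θ = Σ ½(1 + cos(θᵢ − θᵢ^ref)) is the only common similarity with
range [0, n] and maximum at the reference, hence its adoption.  The
parameterizations follow the filter-folding conventions: ψ of Val625
and Gly626 over four subunits (n = 8, "N_S2,S3"), N-CA-C-O of Phe627
(n = 4, "N_S1"), and χ₁ (C-CA-CB-OG) of Ser624 (n = 4, "N_S4"; the
reference rotamer −60° points the hydroxyl into the S4 cage).

## The PDB fixture

The tetramer fixture (chains A–D, residues Ser624–Asn629, backbone plus
the Ser624 side chain) is built by internal-coordinate (NeRF) chain
extension, so requested torsions are reproduced to < 10⁻¹² degrees in
memory.  Reference torsion values other than the literature-anchored
Ser624 χ₁ ≈ −60° are synthetic stand-ins fixed once in
`REFERENCE_ANGLES`; any user-supplied reference PDB can replace them.
PDB coordinate fields carry three decimals, so dihedrals recomputed
after a file round trip agree to ~0.05°; N_θ at the reference point is
second-order insensitive to this (error < 10⁻⁶), which is what the
file-level tests assert.

## Metadynamics

Standard (non-well-tempered) metadynamics: fixed-height Gaussians
(default 0.06 kcal/mol, σ = 0.2 along S and Z, 0.1 along N_θ) deposited
every 2 ps of toy time; CV walls are one-sided harmonic (default
10 kcal/mol per unit², a package choice); biasing forces on the ion
coordinates use analytic CV gradients where available and centered
finite differences (10⁻⁴ Å) otherwise.  Walkers march synchronously and
share the merged hill history, sorted by (time, walker id); the bias a
walker feels at time t equals the offline sum of hills with deposition
time ≤ t, which a test asserts exactly.

The FES estimate is −(accumulated bias), optionally time-averaged over
the last 25 % of the deposition history to damp the characteristic
oscillation of standard metadynamics.  On the 3 kcal/mol double well,
2 500 hills give a maximum error ≈ 0.3 kcal/mol against the exact
profile.

## Histogram reweighting

Frames after a burn-in (default: the first half, deposited while the
bias was still filling wells) are weighted by e^{+V(ξₜ)/kT} and the
permeation profile is W(z) = −kT ln(weighted z-histogram), min-shifted.
The reweighting potential defaults to the bias *time-averaged over the
retained window* rather than the terminal hill sum: the terminal sum
carries the full metadynamics ripple (≈ 0.6 kcal/mol error on the toy
benchmark), while the window average is the effective potential the
retained frames actually sampled (≈ 0.2 kcal/mol).  Because each
averaging snapshot is the hill sum truncated at a later time, the
average is computed exactly by scaling each window hill's height by the
fraction of snapshots it is active in — one hill-sum evaluation in any
dimension.  The terminal-sum scheme remains available as
`mode="final"`.  Weight degeneracy is guarded by an effective-sample-
size check (error below ESS = 10).

## KMC permeation model

A single-ion, 1D discrete-state Markov chain on a uniform grid; the
minimal model consistent with treating instantaneous ion positions as a
discrete-state chain and counting translocation events (a multi-ion
single-file chain is out of scope and flagged as such).  Rates use the
symmetric split-barrier rule k = (D/δ²)e^(−ΔG/2kT), which satisfies
detailed balance exactly and converges to Smoluchowski diffusion as
δ → 0 (the discrete-vs-quadrature MFPT test quantifies the residual:
~3 % at δ = 0.25 Å for a σ = 0.45 Å barrier).  The membrane potential
enters as a constant-field ramp across the channel span with
V = φ_in − φ_out, so positive V drives K⁺ outward and outward current
is positive.  Reservoir exchange: entries at
entry_rate_scale × concentration; exit rates fixed by detailed balance
against the reservoir electrochemical potentials, with the exit attempt
frequency referenced to 100 mM so entries and exits balance at
physiological concentration (the reference cancels from the cycle
affinity, making the reversal voltage exactly (kT/q)·ln(c_out/c_in) —
61.5 mV for a 10:1 gradient at 310 K, which the KMC reproduces within
statistics).  The default D = 0.5 Å²/ns is of the order of bulk K⁺
diffusivity reduced for a pore and is configurable.

Currents come from event counting, I = e(N_out − N_in)/T; chord
conductance is I/V (flagged undefined at V = 0) and slope conductance a
linear fit of the I–V rows.  Mean first-passage times for the barrier
benchmarks use a vectorized lockstep variant of the residence-time
algorithm (identical chain and statistics; validated against the exact
birth–death MFPT formula), because sequential event-by-event simulation
of a 6 kcal/mol barrier would be needlessly slow.

## Problem sizes

The bundled benchmarks are sized for a single CPU: 10⁶ Langevin steps
(≈ 5 ns of toy time, 2 500 hills) for the metadynamics and reweighting
recoveries; 4 × 10⁶ steps for the two-ion sampling oracle; 10–40 µs of
KMC time per conductance point, with 10²–10³ replicas for first-passage
statistics.  These lengths were chosen by convergence checks against
the exact oracles and are fixed in the tests with explicit seeds.

## Known limitations

* The toy system validates estimators, not channel biology: no filter
  flexibility coupled to ion occupancy, no water, no force field.
* Standard metadynamics only; no well-tempered or adaptive variants.
* The KMC chain holds at most one ion; multi-ion single-file kinetics
  (knock-on correlations in time) are outside the model.
* Reweighting assumes the retained window is quasi-stationary; runs
  stopped mid-fill will trip the ESS guard or show boundary artifacts.
* Published absolute conductances for real channels require the
  all-atom free-energy surface as input; the package demonstrates
  order-of-magnitude and trend behavior on user-supplied profiles.
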