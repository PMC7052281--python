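# Methods

`dpdgel` builds coarse-grained bead–spring models of single-network
polyacrylamide (PAAm) hydrogels by simulating the crosslinking of a
precursor mixture with dissipative particle dynamics (DPD), classifies the
resulting network topology, deforms the gel in incompressible uniaxial
tension, and evaluates a Langevin-chain constitutive model with a
bond-stretch fracture criterion. This note records the model, the
numerical choices, and what the reduced-scale defaults do and do not
demonstrate.

## Reduced units and coarse-graining

Mass, thermal energy at the reference temperature and the interaction
cutoff are all unity (m = kT = R_c = 1); T = 1 corresponds to 300 K. One
water bead lumps 8 water molecules, one AAM bead 2 acrylamide monomers,
one MBAA bead a single methylenebisacrylamide crosslinker, so bead masses
are comparable. AAM and MBAA interact as a single "polymer" species but
carry different bonding valences (2 and 4) — the valences follow from the
two vinyl half-bonds of a two-monomer unit and the tetrafunctionality of
the crosslinker, and give the maximum bond count N_AAm + 2·N_MBAA used in
the crosslink rate.

The real length of the cutoff is R_cr = 6.98 Å (from the volume of one
water bead) and the time unit maps to real time through the water
diffusivity, τ = N_m·D_simu·R_cr²/D_water with D_water = 2.43×10⁻⁹ m²/s;
with the measured D_simu ≈ 0.21 this gives ≈ 340 ps per DPD time unit.

## Force field

Pair forces use the standard soft conservative / dissipative / random
triplet with weight w(r) = 1 − r/R_c:

* F^C = a_ij w r̂ with a_ii = 75·kT/ρ and ρ = 2 evaluated at the
  reference temperature (a_ii = 37.5); the polymer–water repulsion adds
  the Flory–Huggins increment 3.27·kT·χ with χ = 0.57 (hydrophilic
  polymer: small χ). The repulsion table is a material property: elevated
  crosslinking temperatures retarget the thermostat but do not rescale
  the repulsions.
* F^D = −γ w² (r̂·v_ij) r̂ and F^R = σ w α Δt^(−1/2) r̂ with α ~ N(0,1),
  one draw per interacting pair per step, applied antisymmetrically.
  σ = 3 is fixed and γ = σ²/(2kT) enforces the fluctuation–dissipation
  balance at every temperature (γ = 4.5 at kT=1, 0.5 at kT=9).
* Bonds are harmonic with a restoring force of magnitude C(r − r₀),
  r₀ = R_c = 1; C = 4 during gelation (a soft bond that lets the network
  form without stiff-oscillation time-step limits) and C = 116,000 during
  tension (the realistic ratio of C–C bond stiffness to thermal energy).

Two distinct densities appear deliberately. ρ = 2 enters only the a_ii
rule. The **box** number density defaults to √2 ≈ 1.414: at closest
packing with unit spacing the soft repulsion between neighbours just
vanishes, and this value simultaneously reproduces the reference box
(44.54 R_c)³ for 125,000 beads and the polymer bead spacing 1.52 R_c.
Both are configurable.

## Integrator

Modified velocity-Verlet with half-step velocity prediction (λ = 0.5),
Δt = 0.01 for gelation, Δt = 0.001 for tension. Single-threaded with one
seeded RNG stream: trajectories are bit-reproducible for a given seed
within one build. Momentum is conserved to round-off by pairwise
antisymmetry; the long-run kinetic temperature stays within a few percent
of target over kT ∈ [1, 11]. Forces use a linked-cell search (cells ≥
R_c, rebuilt every step — soft forces, small Δt) that falls back to an
all-pairs minimum-image loop when the box is narrower than three cells;
the two paths agree to near machine precision and the O(N²) numpy
implementation is retained as the test oracle. A per-step displacement
larger than half a box edge aborts with the step index.

Wrapped coordinates live in [0, L) per axis; an unwrapped copy advances
identically for transport observables.

## Gelation protocol

Relax 10,000 steps at the crosslinking temperature; then every 10 steps,
bond all polymer–polymer pairs closer than R_c greedily in
increasing-distance order (ties by bead index), each bond consuming
valence on both partners, skipping already-bonded pairs; water never
bonds and bonds are never deleted. Then cool linearly to kT = 1 over
100,000 steps (the thermostat target ramps, γ follows the balance at
fixed σ) and relax another 100,000 steps. Self-bonds are forbidden; multi-bead
cycles are allowed — loops are a real reaction product. The crosslink
phase may stop early once every valence is saturated, which at reduced
scale happens long before the nominal step budget.

The greedy shortest-first rule is one deterministic realisation of
"bond what is close"; with bivalent monomers it will close a triangle of
three mutually-close beads (all three bonds) since no valence fills after
the first two.

## Network classification

The polymer graph carries one integer image-shift vector per bond. A
connected component **percolates** along an axis when some cycle has
nonzero net image shift (it winds the periodic box); this is invariant
under wrapping and rigid translation, unlike span-the-box heuristics.
Within a percolating component, degree-1 beads are pruned iteratively
(pruned trees → BRANCH, one record per pendant piece including its anchor
bond) and any subgraph hanging from a single bridge whose removal leaves
it non-winding is detached as BRANCH too (this covers pendant loops). The
surviving core is segmented into EFFECTIVE chains: maximal paths between
junctions (core degree ≥ 3), or a single cycle record when a core piece
is a pure cycle — its end-to-end vector is then the winding displacement.
Non-percolating components become ISOLATED_CHAIN (acyclic),
CROSSLINKING_LOOP (cyclic, contains MBAA) or ISOLATED_LOOP (cyclic, AAM
only); the loop split by crosslinker membership is an interpretation, as
is treating degree-2 MBAA beads as chain interior. Every bond lands in
exactly one record; number and length fractions each sum to one.

Chain geometry: contour length N_b in bonds, end-to-end vector from the
consistent lift of minimum-image bond vectors, initial length ratio
l0 = |L₀|/(N_b·r₀) ∈ [0, 1], orientation angles θ ∈ [0, 2π) (azimuth)
and φ ∈ [0, π] (polar).

## Tension and observables

Incompressible uniaxial tension applies a per-step affine rescaling
λ₁ = exp(ε̇t), λ₂ = λ₃ = exp(−ε̇t/2) (true strain rates; volume constant
to round-off) followed by NVT dynamics at kT = 1 with the stiff bond.
Because switching C = 4 → 116,000 abruptly would store C/2·⟨δr²⟩_soft ≈
10⁴ kT per bond, `prepare_for_tension` anneals C geometrically over ~10
stages with a short NVT run each, letting the thermostat drain the
excess.

Stress is tension-positive Cauchy stress σ = −(K + W)/V with K the
kinetic term and W the pair virial (all force contributions, the random
impulse included — it is a real momentum transfer in DPD); the
mechanical pressure is −tr σ/3. The sign is chosen so P11 =
(2σ₁ − σ₂ − σ₃)/(2λ) is positive when pulling; the hydrostatic part
cancels in P11 identically. Stresses are accumulated **every step** and
reported as interval averages: the stiff-bond virial fluctuates with an
amplitude ~√(C·kT) per bond, but the fluctuation is a fast, weakly damped
oscillation whose time integral is small, so per-step accumulation tames
it where sparse sampling would alias it.

Per-chain bond stretch λ_b(c) is the mean minimum-image bond length of a
chain over r₀; the model-level λ_b averages over all effective-chain
bonds.

Transport: the multi-origin MSD is computed by the FFT autocorrelation
method. D_simu is the zero-intercept least-squares fit of ⟨r²⟩ = 6Dt over
lags ≤ 2 DPD time units — the through-origin form of the diffusivity law,
evaluated on the window in which a bead displaces by about one cutoff;
the diffusion length per DPD time unit is √(6·D_simu). The free-intercept
asymptotic slope (larger, because the hydrodynamic velocity correlation
builds up slowly) is exposed as `D_slope`. At kT = 1 the defaults give
D_simu ≈ 0.21 and a diffusion length ≈ 1.12 R_c for water and polymer
beads alike.

## Chain theory and fracture

The Langevin chain free energy is W = kT·N·(xβ + ln(β/sinh β)) with
β = L⁻¹(x); L⁻¹ uses the Padé start y(3 − y²)/(1 − y²) refined by Newton
to 10⁻¹² residual. The singularity at full extension is removed by
letting the entropic tension stretch the backbone bonds: the force
balance gives

    √(I₁/3) = (λ_b / l0) · L( (N_b/2N)·(C r₀²/kT)·λ_b(λ_b − 1) ),

with ⟨λ_c⟩ = √(I₁/3) the mean chain stretch under I₁ = λ² + 2/λ. The
λ_b(λ) solver brackets on [1, √(I₁/3)·l0 + 10] and is monotone in λ.
N (Kuhn segments) defaults to N_b — one segment per bond, appropriate
for these nearly freely jointed chains. l0 defaults to the measured
ensemble mean of the gel at hand.

Dimensional consistency requires the √(I₁/3) (not I₁/3) reading of the
mean chain stretch and the λ_b/l0 (not λ_b·l0) placement of the initial
length ratio; with l0 ≈ 0.16, N_b ≈ 600 and C/kT = 116,000 the relation
then yields theoretical fracture stretches ≈ 11, matching the reference
analysis. Both readings are isolated in `bond_chain_relation`.

Fracture: a chain breaks when one bond reaches the critical single-bond
stretch λ_b^cr; spreading the critical elastic energy
W_cr = C/2·r₀²(λ_b^cr − 1)² over N_b bonds gives the critical mean bond
stretch λ̄_b^cr = 1 + (λ_b^cr − 1)/√N_b, decreasing to 1 as N_b → ∞.
Inverting at the two-monomer atomistic reference chain (fracture strain
0.225, taken as a fixed input constant) gives λ_b^cr = 1.318. On a
tension trace the **lower** fracture bound is the first model stretch at
which any tracked chain crosses its own threshold λ̄_b^cr(N_b(c)); the
**upper** bound is where the all-chain mean crosses the threshold at the
mean bond count; unsynchronised chain stretching (a wide l0
distribution) widens the window.

## Reduced-scale study conditions

The reference systems hold 125,000 beads; the bundled tests and the
acceptance script run the same protocols at desk scale, with sizes chosen
once:

* **Water diffusivity**: 4,000 beads, 2,000 equilibration + 20,000
  production steps, three seeds.
* **Gelation to saturation (kT = 9)**: 4,000 beads at the production
  ratio 1:0.002, crosslink phase capped at the nominal 500,000-step
  budget in the library default and at 300,000 steps in the acceptance
  script, with early stop at valence saturation (reached near ~30,000
  steps at this size).
* **Temperature trends**: 2,000 beads, three seeds per temperature, mass
  ratio 0.02. The larger crosslinker content keeps the expected chain
  contour (~25 bonds) below the box winding scale; at the production
  ratio a 2,000-bead model is one ~400-bond chain that winds an 11 R_c
  box even when bonded purely locally, which would make percolation
  trivially true at any temperature. Trends are asserted as orderings of
  seed means (effective fraction rising with crosslinking temperature,
  isolated-loop fraction falling), not as absolute values: the literal
  "no percolation at kT = 1" of the full-size study is a large-box
  feature that a ~11 R_c box cannot express, and the kT = 3 vs kT = 9
  contrast sits below the seed-to-seed noise floor at this size (both
  temperatures fully mix an 11 R_c box before saturation), so that
  comparison carries little power here too.
* **Mechanics sanity**: a 500-bead gel at mass ratio 0.01 (the smallest
  ratio with ≥ 1 crosslinker bead at that size). In a ~7 R_c box the
  gelation protocol occasionally closes a winding bond cycle with fewer
  bonds than its periodic span requires; once the bonds stiffen such a
  sample is permanently taut (residually stressed and anisotropic) and is
  not a valid undeformed reference state. Sample preparation therefore
  rejects candidates whose maximum bond stretch exceeds 1.1 after
  stiffening and retries with the next seed, then equilibrates ~25,000
  further steps so the weakly thermostat-coupled bond-mode heat drains
  (the dissipative weight w(r₀) vanishes on an unstretched bond). A
  full-size box does not have this failure mode. The loading-rate
  ordering of P11 is measured against the three reference rates with
  repeated runs of the faster rates; at this size the viscous stress
  difference between the two slowest rates (~2×10⁻³ in reduced units) is
  at the edge of the achievable statistical resolution, so that
  comparison carries the least power of the suite.

What the reduced models do **not** show: the per-model production
statistics (≈93% effective length fraction, mean contour ≈ 289, fracture
windows at stretches 5–9) need the full 46-crosslinker models — a
2,000–4,000-bead mixture at the production ratio holds exactly one MBAA
bead, so its class fractions are dominated by one or two giant chains.
Those claims are covered instead by invariant tests (partition and
normalisation, percolation against a brute-force supercell oracle, force
path equivalence, thermostat accuracy, solver round-trips and trend
directions, fracture-window ordering).

## Known limitations

* The integrator parameter λ and the exact bond-creation bookkeeping of
  the reference implementation are not published; per-step trajectories
  are therefore not reproducible, only statistical observables.
* Bit-level determinism holds per build (seeded single-stream RNG) but
  compiled fastmath kernels may round differently across CPU
  generations.
* No angle/dihedral terms, no energy-conserving DPD variants, no
  barostat: the tension protocol is strictly NVT with affine remapping.
* Fracture is a post-hoc criterion on bond stretch; bonds are never
  deleted during dynamics.
* Real-unit pressure is not calibrated (ρ = 2 abandons compressibility
  matching by design); only the time and length mappings are physical.
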