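# Methods

`astroca` simulates Ca²⁺ and IP₃ dynamics in the finest compartments of an
astrocyte — the node/shaft meshwork of the spongiform domain — and couples
one such node to a glutamatergic synapse.  This note documents the model,
its parameters and units, the numerical scheme, the synthetic-morphology
fixtures, and the design choices made where the design was genuinely open.

## The compartmental model

The morphology is a typed graph of three compartment kinds:

* **nodes** — spheres of diameter `w_node` (default 0.4 µm, measured range
  0.2–0.8 µm).  Nodes carry endoplasmic reticulum and are the initiation
  sites of Ca²⁺ events.
* **shafts** — cylinders of diameter `w_shaft` (default 0.2 µm, range
  0.1–0.4 µm) and length `l_shaft` (default 1 µm, range 1–4 µm).  Shafts
  contain no organelles: both species diffuse through them with no
  reaction terms.
* **one parent process** — a cylinder (default 1 µm × 5 µm; not stated by
  the source data, chosen an order of magnitude above node scale so that
  fine-morphology sweeps cannot perturb it).

Volumes are the closed sphere/cylinder forms.  Diffusion between adjacent
compartments i ← j is Fickian with a geometry-dependent rate

    D_{i←j} = d · Sc / (V_i · d_ij)      [1/s]

where `d` is the cytosolic diffusion constant of the species, `Sc` the
cross-section of the connecting aperture, `V_i` the receiving volume and
`d_ij` the center distance.  `Sc` is always the *shaft* cross-section
(π/4·w_shaft²): the narrower aperture is the physical bottleneck, which is
what makes thin shafts compartmentalize nodes.  Center distances:
node–shaft (w_node + l_shaft)/2, shaft–shaft l_shaft, shaft–parent
(l_shaft + w_parent)/2.  Because D_{i←j}·V_i = D_{j←i}·V_j holds exactly
for every edge, the discrete operator conserves the total amount
Σ V_i·c_i to rounding error — this is tested.

### Node kinetics

Each node holds a cluster of N = 20 IP₃ receptor channels.  Every channel
carries three stochastic h-gates; a channel conducts only when all three
are open.  Gates open at α_h = a₂·d₂·(IP₃+d₁)/(IP₃+d₃) and close at
β_h = a₂·Ca, and are advanced per time step by exact exponential jump
probabilities (1 − e^(−rate·Δt)), at most one jump per channel per step.
The cytosolic balance is

    dCa/dt = J_chan + J_leak − J_SERCA + J_diff
    J_chan  = v₁ m∞³ n∞³ (N_open/N) (Ca_ER − Ca)
    J_leak  = v₂ (Ca_ER − Ca)
    J_SERCA = v₃ Ca² / (Ca² + k₃²)

with m∞ = IP₃/(IP₃+d₁), n∞ = Ca/(Ca+d₅) and the ER pool algebraic:
Ca_ER = (c₀ − Ca)/c₁.  IP₃ is produced by glutamate-dependent PLCβ
(Hill 0.3 in glutamate, half at k_g = 0.78 µM) and Ca²⁺-dependent PLCδ,
and degraded toward the steady level IP₃* = 0.16 µM.

### Parent-process kinetics

The parent adds plasma-membrane exchange (constant influx v₅, extrusion
k₁·Ca), keeps a dynamic ER pool (the ER loses 1/c₁ of what the cytosol
gains), and replaces the per-channel Markov chain by the continuous gate
h with a Wiener term σ_h·dW (Euler–Maruyama; σ_h = 0.05 s^−1/2 by
default, not stated by the source; zero recovers the deterministic
limit).  Its slower, larger transients against the nodes' fast small ones
are an emergent property, not imposed.

## Working parameter set

`AstroParams` defaults are exactly the published parameter table.  Two of
those printed values are internally inconsistent with the model's own
documented behavior, so simulations default to `AstroParams.calibrated()`:

1. **IP₃ loss rate.**  The printed 0.14 s⁻¹ cannot balance the printed
   production terms (≈ 0.56 µM/s at rest): IP₃ would run away to 4–8 µM
   and nodes would sit on a ~1 µM plateau with no discrete events, while
   the degradation term is described as enforcing the steady state IP₃*.
   The calibrated set reads the printed 0.14 as the time constant in
   seconds, i.e. a loss rate of 7.143 s⁻¹, which pins IP₃ at 0.2–0.3 µM
   and restores discrete node transients.
2. **Diffusion constants.**  At the printed d_Ca = 0.1 and d_IP₃ = 1
   µm²/s every inter-compartment coupling is ≤ 0.15 s⁻¹ — negligible
   against reaction fluxes for *every* geometry in the measured ranges,
   so no morphology could influence Ca²⁺ activity at all.  The calibrated
   set uses d_Ca = 1 and d_IP₃ = 10 µm²/s (same 10× ratio; still well
   below the physical effective values of ~13–65 and ~280 µm²/s, i.e.
   strong compartmentalization is retained).

With the calibrated set the model reproduces the documented qualitative
behavior: node peak counts and amplitudes rise with node width and with
the node/shaft width ratio and then plateau (from ratio ≈ 3–4 on), fall
with shaft width, are insensitive to shaft length, and leave the parent
process unaffected.  The calibration was chosen against those qualitative
behaviors only.

### Known divergences from the source's figure-level claims

* The claim that mesh nodes gaining extra connecting shafts produce
  *more* peaks does not emerge here: extra shafts to active but
  desynchronized neighbors drain a node during its own excursions at
  least as strongly as neighbor events excite it, so the effect is
  flat-to-mildly-negative across every coupling strength tried.  The
  parent's insensitivity to the mesh change does reproduce.
* The width-ratio peak-count curve *saturates* above ratio ≈ 3 rather
  than peaking there; on the resulting plateau the argmax bin is a noise
  draw anywhere in 3–8.  The corresponding test and acceptance quantity
  report whatever the computation yields.
* The star-model parent's peak frequency rises strongly with node count;
  its amplitude decrease is present but tiny (≈ 0.63 → 0.62 µM over
  8 → 40 nodes) and below one-sided detection at the suite's scale.

## Tripartite synapse

One node (with its shaft and parent) is embedded in a closed signalling
loop: a Hodgkin–Huxley bouton (squid-type rates, constant drive
I_app = 10 µA/cm², tonic ~68 Hz); an N-type VGCC feeding a fast Ca²⁺
pool (current converted by A/(z·F·V) with a 0.6 µm-radius bouton) that is
cleared by a PMCA pump within ~2 ms so that release stays spike-locked; a
five-site Ca²⁺ sensor (per-site K_d = γ/θ = 10 µM) whose fusion-competent
isomer triggers vesicle fusion, plus a Poisson spontaneous pathway with
sigmoidal rate λ(Ca) (supremum a₃ = 2 s⁻¹) active only below −60 mV;
release/effective/inactive vesicle pools on an exact simplex (an n-vesicle
fusion transfers the exactly integrated fraction 1 − e^(−n) of the
releasable pool); cleft glutamate (source n_v·g_v·E, clearance
r = 100 s⁻¹, peaks 0.1–0.7 mM) gating AMPA (Destexhe-type rates) and NMDA
receptors (printed α/β and Mg²⁺ block) on a spine with input resistance
r_m·A_spine = 0.5 GΩ; spine Ca²⁺ from the η/λ fractional receptor
currents with rapid-buffer capacity θ_post = 100; and the astrocytic
return path — cleft glutamate drives node PLCβ, node Ca²⁺ above the
0.19669 µM threshold opens the three release gates, and extrasynaptic
glutamate (scaled to the sensitive range of k_g) drives bouton IP₃
(its own loss rate keeps the printed 0.14 s⁻¹, which *is* self-consistent
there because production is capped at v_g = 0.2 µM/s) and hence ER Ca²⁺
and release facilitation.

Every constant the source defers to earlier bouton/sensor modelling work
ships as an explicit, individually overridable field of `SynapseParams`
with a provenance comment.  The calibration targets were qualitative:
spike-locked evoked release, sub-millimolar cleft transients,
few-millivolt EPSPs, micromolar spine Ca²⁺, and a gliotransmission output
that modulates — rather than saturates — the presynaptic IP₃ drive.

### Atrophy scenarios

The runner fires a 4 s burst and compares conditions over the following
20 s, where transmission is carried by the spontaneous (astrocyte-
modulated) pathway with a recovered vesicle pool:

* `release_deficit`: node width 0.4 → 0.2 µm.  The shrunken node is
  diffusion-dominated, spends less time above the release threshold,
  gliotransmission collapses, bouton IP₃/Ca²⁺ fall, and mean cleft
  glutamate, depolarization and spine Ca²⁺ all drop.
* `uptake_deficit`: release probability ×2 (the δ and λ rates) and cleft
  clearance ×0.5.  Cleft glutamate accumulates; EPSP and spine Ca²⁺ rise.

EPSP size is reported as the mean depolarization above rest over the
analysis window (plus the peak, for reference).

## Numerics

Fixed-step Euler–Maruyama; Δt = 1 ms for microdomain runs (all
deterministic rates ≤ ~10 s⁻¹) and 10 µs for the synapse (HH rates
~10³ s⁻¹, sensor rates ~10⁴ s⁻¹).  Markov transitions use exact
exponential probabilities; mover counts per gate state are sampled by
inverse-CDF binomials with a fast zero-mover path.  Euler overshoot below
zero concentration is clipped and counted; runs clipping > 0.1% of steps
are flagged.  Halving Δt moves trial-averaged peak counts by less than
the across-trial spread (tested).  Non-finite states abort with the
offending compartment and time.  One root seed expands through
`numpy.random.SeedSequence.spawn` into per-trial, per-condition
substreams, so identical seeds give bit-identical trajectories and adding
a condition never perturbs another.

In the deterministic limit (σ_h = 0, expected-value gating q³) the Euler
path agrees with a high-accuracy LSODA integration of the same
right-hand side to < 10⁻³ µM sup-norm at Δt = 0.2 ms.

## Analysis

A peak is a maximal run of samples strictly above mean + 2·STD of the
trace (sample STD, ddof = 1), its amplitude the maximum of the run;
statistics use the post-burn-in window only (default 20 s of 140 s).
Across seeded trials, peak count and mean amplitude are reported as
mean ± STD.  Supra-threshold runs separated by even a single
sub-threshold sample count as distinct peaks.

## Fixtures and what they do (not) represent

The published 15- and 30-node topologies are drawn, not listed, so the
package ships deterministic stand-ins: the 15-node fixture is a node path
whose two terminal shafts attach to the parent (closing a mesh loop
through it); the 30-node fixture adds 15 nodes in short branches so that
nodes n5 and n8 gain two connecting shafts and n12 one, while n1, n6 and
n10 keep their degree.  The star fixtures attach every node by its own
shaft directly to the parent.  These capture the degree structure the
experiments compare but not the loop statistics, spatial embedding or
heterogeneity of the real gliapil; conclusions about absolute event rates
in tissue should not be drawn from them.  Test problem sizes (typically
5–10 trials of 60–120 s windows; full protocol 20 × 120 s in
`scripts/acceptance.py`) preserve the direction of every trend at reduced
confidence.

## Limitations

No ryanodine receptors, store-operated entry, mitochondrial fluxes,
TRPA1/NCX, extracellular Ca²⁺ diffusion, endogenous buffers (beyond the
spine's lumped capacity), receptor desensitization, or gap-junction
coupling between microdomains.  Compartments are well-mixed; diffusion is
a two-point flux, not a spatial PDE.  The synapse's deferred constants
are calibrated, not fitted to data.
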