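# Methods

## Model

N particles live in a two-dimensional phase space.  Particle i has
position `x_i`, log evidence `μ_i ∈ R⁴` over four identities, and a
chemical emitter `a_ψ,i ∈ R⁴`.  Identity semantics are fixed: index 0 =
internal state of ensemble A, 1 = blanket state of A, 2 = blanket state
of B, 3 = internal state of B.  Beliefs are `ψ = softmax(μ)`; the
emitter broadcasts the belief (with a small noise increment), so the
4-channel signal field at a point is `m_k = Σ_j a_ψ,j,k · exp(-|x_j -
x|²/2)`.

Particles do not sense intensities directly but the flow vector of each
channel, `R⃗_k = ∇m_k / m_k`, whose closed form is the emitter-weighted
mean offset to the other particles; it points at the intensity-weighted
source and its norm `R_k` is the weighted source distance.  The shared
generative model holds Gaussian priors over those norms conditional on
identity, encoded in the 4×4 distance template (entries `D` or `2D`):
internal states expect the opposing ensemble far (`2D`), blanket states
tolerate proximity (`D`) to the opposing blanket.  Expectations are
belief-weighted averages `R̄ = ψᵀ R_ψ`.

Perception and action descend precision-weighted prediction errors:

* log evidence: `μ̇ = J·(R_ψ·(Π_R ∘ ε_R)) + J·(Π_ψ ∘ ε_ψ) − Π_μ μ +
  drive`, with `J = diag(ψ) − ψψᵀ` the softmax Jacobian, `ε_R = s_R −
  R̄`, `ε_ψ = s_ψ − ψ`;
* motion: `ẋ = −(∇_x R)·(Π_R ∘ ε_R)` and `ẍ = (∇_x R)·(λ Π_R ∘ Ṙ)` with
  `Ṙ = (J μ̇)ᵀ R_ψ`; friction is neglected;
* emitter: `a_ψ ← ψ + Π_ψ Ω Δt` with standard-normal `Ω` (an optional
  flag switches to `1/√Π_ψ` scaling);
* integration: synchronous Euler/Taylor step `x += ẋΔt + ẍΔt²/2`,
  `μ += μ̇Δt`, all particles updated from the time-t field, so the step
  is permutation-equivariant.

Sensing is noisy: each channel of `s_ψ` and `s_R` carries Gaussian noise
of variance `1/Π` (none on zero-precision channels; a `noise_free` flag
gives the deterministic limit).

An external stimulus field `f(x, t) ∈ [0, 1]` (disc with a Gaussian
shoulder) adds the log-evidence drive `κ·(f, f, 1−f, 1−f)`: intensity is
evidence for membership of ensemble A, its complement for ensemble B,
so the total drive is spatially constant and only the balance varies.
Protocols gate the field at an onset step and optionally switch it to a
second field at a switch step (half-open: the new field applies at
exactly the switch step).

## Sensor model

Two departures from the idealised flow equations are needed for a
well-posed simulation; both are config-exposed and default-on:

* **Magnitude saturation.**  Raw flow magnitudes are exact for a single
  source, but for a nearly-empty channel the intensity-weighted centroid
  is hypersensitive to position: its spatial gradient grows like the
  squared source distance, and with noisy prediction errors this injects
  unbounded velocities (isolated particles accelerate away
  indefinitely).  Magnitudes are therefore sensed through
  `r_sat·tanh(R/r_sat)` and motion uses the gradient of the saturated
  reading, so sources beyond the kernel's reach read as "far" and exert
  no force.  The default `r_sat = 2.12·D` sits just above the farthest
  represented distance `2D`: high enough that a "far" reading is still
  evidence *for* internal identities, low enough that the
  internal/blanket belief crossover (where the sensed reading passes
  `1.5·D`) falls well outside the blanket-test interaction radius.
  Values ≤ `2D` make "far" exactly satisfy internal expectations and
  blanket rings never form; values ≫ `2D` thin the belts until internal
  states of opposite ensembles touch.
* **Evidence saturation.**  Log evidence is bounded (`mu_max`, default
  15) by a structured clip: the ensemble-membership contrast (the gap
  between the pair means of identities (0, 1) and (2, 3)) and the two
  within-pair contrasts are each clipped, and the components recomposed
  around a zero mean (softmax is shift-invariant, so the mean carries no
  information).  Bounding the membership contrast bounds belief
  hysteresis: after a stimulus relocation, beliefs reverse within ~30
  steps instead of ~70, which is what makes re-formation observable
  within the 200-step post-switch window.  A naive per-component clip
  would erase the within-pair differences whenever both components of
  the favoured pair ride the ceiling, collapsing the internal/blanket
  structure — hence the structured form.

An optional `intensity_floor` makes channels with negligible intensity
read as maximally far instead of near-zero.  It is off by default: the
blanket rings at ensemble interfaces are mutually sustained — the
template distinguishes blanket from internal only through the *opposing
blanket* channel — and that evidence is carried by weak residual
emitters that the floor would blank out, dissolving the rings.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `D` | 1.25 | proximity scale of the distance priors (kernel units) |
| `prec_R` | 2.0 | flow-sensing precision (inverse noise variance; also the weight of `ε_R` in belief and motion updates) |
| `prec_psi` | 0.05 | emitter/self-sensing precision; sets the emitter noise amplitude `Π_ψ·Δt` |
| `prec_mu` | 0.1 | evidence leak rate; `1/prec_mu` is the belief time constant |
| `stim_gain` κ | 8.0 | stimulus log-evidence injection per unit time |
| `lambda_smooth` λ | 0.3 | fluctuation autocorrelation; scales the second-order motion term |
| `mu_max` | 15 | evidence saturation bound (see above) |
| `r_sat` | 2.12·D | sensor saturation scale (see above) |
| `dt`, `steps` | 0.1, 400 | Euler step and horizon; stimulus onset step 10, switch step 200 |
| `N`, box | 64, `2√N` | particle count and initial box side (mean nearest-neighbour spacing ≈ 1 kernel unit) |
| blanket-test radius | 2.0 | interaction radius of the geometric graph; kernel factor `exp(-2) ≈ 0.135` |

The paper-level structure (template form, flow sensing, update
equations, onset/switch steps, N, uniform initial beliefs) is fixed;
the numerical values above are this package's calibration, chosen once
so that the three stimulation experiments exhibit the documented regime
— packet emergence with wrapped blanket rings, dissolution of a vacated
packet, faster re-formation under an overlapping relocation — and then
frozen.  Load-bearing choices: `D` and `r_sat` set the width of the
internal/blanket belts relative to the interaction radius; λ damps the
boundary churn that otherwise produces sporadic internal–internal
contacts; `mu_max` trades belief stability against re-formation speed.

Stimulus geometry: the static disc covers ~25 % of the initial box.  The
relocation protocols use ~13 % discs — the largest for which two
genuinely disjoint sites fit inside populated territory; the disjoint
displacement is two radii plus a margin wider than the soft shoulder,
the overlapping displacement 0.75 radii.  (A displacement below two
radii would make the "disjoint" sites overlap and the vacated-region
diagnostics meaningless.)

## Diagnostics

Roles are MAP identities (ties break to the lowest index; particles with
max belief < 0.4 are flagged low-confidence).  `blanket_test` builds the
geometric graph at the interaction radius, deletes all blanket-role
nodes, and reports separation iff no connected component contains both
an internal_A and an internal_B particle (at least one of each must
exist; a missing role fails with a reason code).  An exhaustive
path-enumeration oracle cross-checks the verdict on small
configurations.  `evidence_trace` reports ensemble-mean beliefs (and
mean log evidence) over time, optionally masked to a spatial region.
`reformation_time` scans post-switch snapshots for the first time the
separation test passes with the internal_A centroid inside the new
stimulus support.  `free_energy_proxy` is the particle-mean
precision-weighted squared prediction error evaluated on the
deterministic field — the quantity that falls as the ensemble
self-organises.

## What the simulations do and do not show

The default experiments run N=64 particles for 400 steps (the
acceptance script's study scale; the full-size configuration N=256 runs
in a few seconds too).  Randomness enters through initial positions,
sensing noise, and emitter noise; every run is reproducible from its
seed, and all stochastic claims are evaluated over seed batteries.

Findings are about this model, not cortical tissue: particles are point
agents with a single isotropic signalling kernel, identical generative
models, no synaptic connectivity, no conduction delays, and a stimulus
that is a static scalar field.  The blanket diagnostic is structural
(geometric separation given signal reach), not a statistical
conditional-independence test on time series.  Two further caveats:

* The separation verdict flickers near its margin — single
  internal/internal contacts at the interaction radius appear and vanish
  over tens of steps.  Final-state separation holds in ~85–95 % of
  seeds; "once separated, always separated" does not hold literally.
* The final four-role census is only marginally robust to halving the
  integration step (mean change ≈ 4–6 % of particles, heavy-tailed
  across seeds): individual belt-crossover particles are chaotic, while
  macroscopic observables (separation verdict, ensemble-A count) are
  step-size stable.

## Numerical notes

* The flow closed form is validated against a central-difference oracle
  of `∇m/m` (relative agreement < 1e-4) and is exact for two particles
  (magnitude = distance to 1e-10 for separations in (0.1, 5]).
* The intensity regulariser is a pure 0/0 guard (1e-300); any larger
  value measurably biases magnitudes for low-intensity channels.
* Spatial derivatives of sensed magnitudes use central differences
  (step 1e-5), validated on the exact two-particle case (unit gradient).
* Stationarity at zero prediction error requires the evidence-decay term
  to vanish as well (`μ = 0` or `prec_mu = 0`); the fixed-point tests
  use such configurations, stored in the saturated canonical form.
* Degenerate inputs: empty signal channels give zero flow; an ensemble
  needs ≥ 2 particles; non-finite states raise an integration error
  naming the particle and step.
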