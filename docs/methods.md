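# Model and methods

`myxosim` simulates the collective motility of gliding rod bacteria
(*Myxococcus xanthus* is the motivating organism) as self-propelled
flexible rods on a two-dimensional substrate, together with the
quantification used to characterize the patterns they form: cluster size
distributions, nematic orientation correlations and visit-frequency
maps. This note records the model, its assumptions, the numerical
choices, and what the synthetic scenarios do and do not show.

## The cell model

Each cell is a chain of N = 7 nodes joined by rotational joints:

* **Linear springs** (constant k_l) between neighbouring nodes resist
  stretch away from the rest length l0 = L_c/(N−1), keeping the cell
  length near L_c = 5 μm.
* **Angular springs** (constant k_b) resist deviation from collinearity
  at each interior node: E_b = ½ k_b Σ φ_j² with φ_j the signed turning
  angle, giving the cell its flexural elasticity.
* **Propulsion**: every node except the tail receives a force of
  magnitude F_T/(N−1) directed toward the next node headward — the
  distributed thrust of gliding-motility motor complexes. The head
  node's force direction is the steering handle: it follows the body
  tangent, is redirected during turn events, and is split toward slime
  trails (below).
* **Drag**: node velocities obey the overdamped balance v = F/c. The
  drag coefficient is calibrated so a free glider runs at
  v_c = 4 μm/min: c = F_T/(N·v_c).
* **Substrate adhesion**: interior nodes carry breakable "focal
  adhesion" anchors. An anchor pulls its node with k_a times the
  *lateral* offset (the component perpendicular to the node's propulsion
  tangent); it translocates freely along the gliding axis, so adhesion
  never opposes forward gliding, only sideways displacement. Above the
  breaking force F_a,max = 50 pN the anchor detaches and instantly
  re-forms at the node's current position — under sustained lateral
  load the cell side-slips against a bounded, ratcheting friction.
* **Head friction and slime lubrication**: the leading pole carries
  nascent adhesions that have not matured into anchors; they are modeled
  as a transverse viscous drag on the head node, `head_drag_factor` (χ)
  times the body drag. On wet slime the head recovers full transverse
  mobility — trails act as low-resistance paths. This asymmetry lets
  trail steering capture cells efficiently while the same-magnitude
  turn-noise force produces only small course changes on bare
  substrate.
* **Excluded volume**: cells are capsule chains of width W_c = 0.5 μm.
  Overlapping inter-cell segment pairs feel a penalty force k_ev·δ along
  the mutual normal, split to segment endpoints by closest-point
  weights; Newton's third law holds pairwise. k_ev is tied to the
  propulsion scale so a head-on two-cell compression equilibrates at
  4.6% of W_c overlap.
* **Lateral cell–cell adhesion** (optional, off by default): nodes of
  distinct cells at perpendicular distance W_c ≤ d⊥ < d_thr attract with
  magnitude ramping linearly from 0 at contact to k_adh·F_T/N near
  d_thr, applied normal to the propulsion tangent. This reproduces the
  published functional form exactly, including its counter-intuitive
  growth with separation.

### Behavioral events

* **Reversals**: a deterministic per-cell timer flips head and tail
  every τ_r = 8 min (phases randomized at start; no period noise). A
  reversal relabels the nodes — positions are untouched — and the
  travel direction flips.
* **Turn noise**: a second timer fires every τ_t = 5 min and starts a
  1-minute episode during which the head force is steered toward a
  lab-frame direction fixed at onset: the heading then, rotated ±90°
  (sign equiprobable). Steering toward a fixed target yields a net
  course change of ~10° per event at the default χ; the naive
  alternative — rotating the instantaneous heading by 90° every step —
  makes the head chase itself at ~v/l0 rad/min and pirouettes the cell
  by ~270° per event, which is why it is not used. While a cell senses
  a wet trail the turn override is suppressed entirely: trails are the
  orientation memory that reduces random direction changes, and the
  steering split is applied to the body tangent.

### Slime field

Cells secrete slime at rate S_r into a square grid of element width W_c;
each element dries exponentially (dS/dt = −k_d·S) and counts as wet
while S ≥ S_thr (an absolute volume, 0.01). The tail node deposits, so a
mover lays a one-element-wide trail. The head senses the forward
semicircle of radius L_c/2, split into five 36° sectors; among sectors
holding ≥ 80% of the maximal sector volume, the one closest to the
current heading wins (symmetric ties broken pseudorandomly), defining
the trail direction ê_s and the local trail strength S (the strongest
wet element in that sector). The head propulsion is then split,

    F_s = ε_s · min(1, S/S0) · F_T/(N−1) · ê_s,
    F_c = (F_T/(N−1) − |F_s|) · ê_h,

with S0 the fresh-deposit reference (the volume laid during one
element crossing). The component magnitudes sum to the undisturbed head
propulsion; the resultant norm is not preserved (the printed
decomposition is applied as-is).

The closed-form trail length behind a single glider is
L_s = v_c·ln(S_τ1/S_thr)/k_d with S_τ1 = (1−e^{−k_d·W_c/v_c})·S_r/k_d.
Requesting a target L_s rescales (S_r, k_d) jointly — preserving the
steady total slime volume S_r/k_d — by a factor solved by bisection on
the decreasing branch of the unimodal L_s(f) curve.

Sensing is refreshed every 0.01 min (≈12 integration steps) rather than
every step; a gliding cell moves ≈0.04 μm between refreshes, a tenth of
a grid element, so the cached trail direction is effectively current.
The wet/dry threshold applies at sensing only: sub-threshold slime keeps
decaying and can be re-wetted, because pruning the field every step
would erase fresh deposits (a single step deposits S_r·dt ≪ S_thr).

## Update loop and numerics

Per step of dt = 8×10⁻⁴ min: behavior events → slime decay/deposit (+
sensing at the cadence above) → head-direction composition → all forces
→ explicit overdamped Euler update → anchor translocation → periodic
wrap. Everything is deterministic given (parameters, seed): placement,
head coins and timer phases come from one PCG64 stream; turn-event signs
are pre-drawn per agent; sector tie-breaks hash (agent id, step).

Stability: explicit overdamped Euler requires dt < 2c/k for the
stiffest coupling. The internode spring chain's stiffest normal mode has
eigenvalue 4·k_l, so validation enforces dt ≤ c/max(2·k_l, k_ev, k_a).
With the defaults the contact stiffness binds: dt_max = c/k_ev =
0.046·W_c/(N·v_c) ≈ 8.2×10⁻⁴ min, independent of F_T because both c and
k_ev scale with it. The slime field uses exact exponential decay (lazy,
timestamped in the compiled path; eager in the reference path — the two
agree to machine precision, which is tested).

Two implementations exist on purpose: readable reference operations
(numpy, one function per force law or event) composed by
`engine.step`, and a fused numba kernel driven by `engine.run` with a
cell-list broad phase for contacts. An equivalence test drives both over
identical worlds with every feature active.

## Parameters

Printed, fixed values: N = 7, k_b = 1×10⁻¹⁷ N·m, F_a,max = 50 pN,
τ_r = 8 min, τ_t = 5 min, turn duration 1 min, turn angle 90°,
d_thr = 0.75 μm, S_thr = 0.01, five sectors at 80% acceptance,
180-min runs with 1-min snapshots.

Calibrated values (the source's parameter table is not public; these
are this package's own choices, each with its reason):

| parameter | default | rationale |
|---|---|---|
| L_c, W_c | 5, 0.5 μm | typical vegetative cell geometry; d_thr = 1.5·W_c |
| v_c | 4 μm/min | typical gliding speed |
| F_T | 30 pN | per-node thrust 4.3 pN ≪ F_a,max, so propulsion cannot rip anchors: cluster-interior cells are blocked by their anchored neighbours ("unable to leave"), and the bending response at k_b = 10⁻¹⁷ N·m stays gently flexible rather than floppy |
| k_l | 2×10⁻⁴ N/m | relative stretch ≈ 2% per node-thrust; same stretch-per-thrust ratio at any F_T |
| k_a | 2×10⁻⁴ N/m | anchor yields its 50 pN breaking range over 0.25 μm, half a cell width |
| k_ev | F_T/(0.046·W_c) | head-on compression overlap 4.6% of W_c |
| head_drag_factor χ | 25 | per-turn-event course change ≈ 11°; see below |
| k_adh | 2.8 | peak lateral adhesion ≈ 60 pN per cell, the midpoint of the published 30–120 pN scan |
| L_sim, η | 100 μm, 0.24 | headline density; domain scaled down in tests (stated per test) |
| ε_s, L_s | 1.0, 11 μm | headline trail-following operating point |

χ was calibrated against the qualitative battery the model must
reproduce simultaneously: non-reversing populations must coarsen into
clusters of >10² cells and sit well above the always-reversing baseline
(weak noise), generic oblique collisions must still end nematically
aligned (finite head mobility), turn events must still measurably
redirect isolated cells, and trail steering must capture crossing cells
(full head mobility on slime — guaranteed by lubrication independent of
χ).

## What the scenarios show — and what they do not

The synthetic worlds are the study conditions themselves: random
uniform, non-overlapping, isotropic initial packings of identical
straight cells at a nominal area fraction, with deterministic reversal
clocks and equiprobable turn signs. They emulate the dilute-monolayer
regime of gliding assays. They do not emulate: cell growth or division,
length/speed heterogeneity, reversal-period noise, twitching (pilus)
motility, multilayering at high density, or chemical signaling. Passing
tests therefore support the mechanical-clustering mechanism under
idealized monolayer conditions, not a quantitative match to any
particular experiment.

Domain sizes in the test-suite and acceptance runs are reduced
(≈50–70 μm boxes, 160–300 agents) relative to the 100 μm reference
domain; cluster sizes are then bounded by the agent count, and the
mass-weighted ⟨m⟩ fluctuates more than in larger systems. Where a
threshold (e.g. "a cluster larger than 100 cells") is checked at
reduced scale, the test states the scale it uses.

## Quantification conventions

* Clusters: two cells are adjacent when their capsule center-lines come
  within 1.2·W_c (surfaces within 20% of a cell width); clusters are
  connected components, singletons count. The factor is a config knob;
  at 1.2 a random non-overlapping packing at η = 0.24 registers
  ⟨m⟩ ≈ 1.5 (the floor is near-ideal), while dynamically formed
  side-by-side contacts register robustly.
* p(m) = m·n_m/M is the probability a *cell* sits in an m-cluster;
  ⟨m⟩ = Σ m·p(m) is the mass-weighted mean (the number-weighted mean is
  available via the n_m themselves). Steady-state values average the
  final hour unless stated.
* C(r) bins all pairs by center-node distance (1 μm bins, minimum
  image) and averages cos 2Δθ; parallel and antiparallel both score +1.
* Visit maps count each cell's center node once per minute per W_c
  grid site; p(N) is over visited sites only.
* The cluster-size power-law exponent β is the least-squares slope of
  log p(m) vs log m over ≥5 occupied logarithmic bins (5 per decade)
  for m ≥ 10, with R² < 0.9 flagged as a poor fit.

## Known limitations

* The contact model is a penalty force; transient overlaps up to a few
  percent of W_c occur and the contact set, not the impulse history, is
  what is validated against oracles.
* Exactly perpendicular two-cell collisions stall head-on against the
  flank instead of aligning (the head's transverse friction suppresses
  the alignment instability's seed forces at 90°); oblique collisions
  (30–60°) align to within a few degrees. Real perpendicular encounters
  resolve by climbing into a second layer, which a monolayer model
  cannot express.
* The mass-weighted ⟨m⟩ of *reversing, non-trail-following* populations
  at η = 0.24 sits near 30–45 at the 150–260-agent scales used here,
  because abundant transient collision contacts register as clusters;
  contrasts against this baseline (trail-following rescue) are
  therefore compressed relative to a quantification that ignores
  transient contacts.
* Because any sensed trail — regardless of its length — lubricates the
  head and suppresses turn noise, short-but-strong trails already confer
  most of the orientation-memory benefit. The dependence of ⟨m⟩ on the
  trail length L_s is therefore weak and scale-sensitive in this
  implementation (the long-trail connectivity advantage is visible in
  trail-network snapshots but not in the ⟨m⟩ rank order at ≲150-agent
  scales), while the dependence on density η and on ε_s is robust.
* Lateral adhesion implements the published separation-growing ramp
  verbatim even though a decaying law would seem more physical.
* ⟨m⟩ at reduced scale is noisy; contrasts between conditions should be
  read from time-averaged windows and multiple seeds, as the tests do.
* The head-friction/lubrication closure (χ) is the package's own
  resolution of an underdetermined part of the source model; its value
  changes the noise response quantitatively but none of the qualitative
  contrasts.
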