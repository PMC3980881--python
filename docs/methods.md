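# Methods

## The optimizer

One run is a pure function of (instance, configuration, seed).  The seed
spawns two independent substreams: the *main* stream drives temperature
tuning, the initial conformation and every Metropolis proposal; the *chaos*
stream is owned by the chaotic driver and supplies its re-seeds and the
variable choices of the chaotic local search (CLS).  Because the chaotic
variant and the `mqa_dep` baseline therefore consume identical main streams
at a shared seed, paired comparisons between them are controlled experiments
(common random numbers): any difference in outcome is attributable to the
CLS, not to stream divergence.

**Proposals and acceptance.**  A Metropolis proposal redraws one uniformly
chosen torsion fresh on (−180°, 180°].  Moves with ΔE < 0 are accepted;
others with probability exp(−ΔE/T).  A tie ΔE = 0 always passes (exp(0) = 1
exceeds any uniform draw in [0, 1)).  Each temperature cycle runs
L = 10·m proposals by default — standard dimension-scaled practice; L is
configurable.

**Quenching dynamics.**  The quench law T ← α_Q(1 − τ)T with τ ← τ² cools
brutally at first (τ₀ = 0.90 gives a factor α_Q·0.1 on the first cycle) and
relaxes toward the geometric law as τ → 0.  With τ₀ = 0.90 and the cutoff
0.0009, τ crosses the cutoff after exactly 7 squarings, so the CLS fires on
every 7th cycle of a subphase and one full subphase multiplies T by ≈ 9.4e-4.
The crossover default `t_threshold_frac = 1e-3` therefore gives the
multiquenching phase exactly one full subphase (one CLS firing) by default.
A larger fraction such as 0.1 would end the phase after two cycles — before
the CLS can ever fire — and silently degenerate the algorithm to its
baseline; users who want several subphases lower the fraction (each further
subphase costs another factor ≈ 9.4e-4 of temperature headroom, which the
tuned T_f must still fit under).

**Chaotic driver.**  The four maps are sine functions with singularities at
0 (and 1), evaluated only inside a guarded interval (guard 1e-6); evaluation
at a guarded point is an error, never a clamp.  The literature shows these
maps as curves without an iteration rule, so the iteration is this package's
choice: x ← |f(x)| folded into (guard, 1−guard), with a deterministic
re-seed from the chaos substream whenever the fold lands in a guard band or
on a fixed point.  No formal chaoticity (Lyapunov) claim is made; what the
CLS needs is a bounded, reproducible, erratic driver, and that is what is
tested.  A CLS step moves one torsion by y·amplitude (amplitude default 90°)
and keeps the result only if it strictly improves the best-so-far energy, so
the CLS is greedy and monotone by construction; it touches only the
best-so-far solution, never the Metropolis walker.

**Stopping rule.**  Below the arming temperature T_fa = 10·T_f the
end-of-cycle energy E_i (the walker's energy, not the running minimum, which
would flatline early) streams into a window of n = 30 values; the run stops
when the closed-form least-squares slope of the window is within ε = 1e-3 of
zero.  Window length and ε are configurable; neither is prescribed by the
method's source, so they are package defaults chosen at desk scale.

**Temperature tuning.**  ΔZ_max/ΔZ_min are the largest/smallest positive
energy changes seen over 100·m uniform-walk steps spread across 10 random
starts.  P_hot = 0.95 and P_cold = 0.01 make T₀ accept nearly everything and
T_f nearly nothing.  A constant landscape yields no deterioration and is
reported as an error rather than a guessed temperature.

## The reduced protein model

Variables are enumerated per residue in the fixed order φ, ψ, ω, χ₁…χ_k.
The χ count table includes terminal rotors (Met ε-methyl, Tyr hydroxyl),
which is the convention under which the classic 5-mer YGGFM spans
10 backbone + 9 side-chain = 19 torsions.  Two termini conventions exist:
`charged` (default) places a terminal H and OXT, making φ₁ and ψ_n well
defined; `free` drops both as undefined at bare termini.  ω is fixed at 180°
unless requested as a variable.

Coordinates are built by sequential internal-coordinate placement from a
fixed bond-length/angle table (Engh–Huber-like values); each variable's
defining atom quadruple is recorded, so torsions re-measured from the built
coordinates reproduce the inputs to < 1e-6°.  Side chains are reduced to CB
plus one pseudo-atom per χ in a linear chain — the search-space *structure*
(dimension, coupling of χ to the frame of the preceding atoms) is preserved,
not side-chain chemistry.

The energy is the four-component surrogate
E = E_LJ + E_elec + E_torsion + E_hbond with 1-2/1-3 bonded pairs excluded,
geometric-mean LJ combination, screened Coulomb (332·q_iq_j/(D·r), D = 2),
cosine torsion barriers, and a 12-10 term replacing LJ on N···O donor–
acceptor pairs (well ≈ 2 kcal/mol at 2.9 Å).  All constants live in the
versioned `data/energy_params.yaml`.  Absolute values are **not** comparable
with any production force field; what the surrogate preserves is the
anatomy of the landscape (clashes, electrostatics, torsional multimodality,
hydrogen bonding) over the correct variable space.  Coincident atoms incur a
large finite penalty (1e6) rather than an overflow.

## The planted landscape

Validation needs a certified optimum.  The planted landscape is separable:
per coordinate, depth·(1 − cos δ) with δ the offset from the planted optimum;
trap coordinates are multiplied by 1 − f·((1 + cos(δ − s))/2)^q with
f = 0.8, q = 6 and shift |s| ∈ [100°, 160°].  Because the factor is bounded
below by 1 − f > 0, the global minimum is *provably* exactly 0 at the
planted conformation, while each trap carves a strictly positive secondary
local minimum.  Construction verifies both claims by a dense per-coordinate
scan and raises otherwise; `descent_check` re-verifies by random sampling
plus Nelder–Mead descent from each trap centre.

What a green recovery test establishes: the full pipeline (tuning, quench,
CLS, annealing, stopping rule) reliably drives a 19-dimensional multimodal
landscape to its global minimum within its evaluation budget.  What it does
not establish: performance on real protein landscapes, whose coordinates are
*coupled* through the chain geometry; separability makes the planted
landscape easier than a protein of equal dimension.  Full-range proposal
redraws also weaken the traps (any coordinate can jump its trap in one move),
so the planted benchmark bounds the optimizer's bookkeeping and schedule
logic more than its escape ability.

## Numerical choices

- Angles in degrees on (−180°, 180°]; wrapping keeps +180 and maps −180 to
  +180.  Dihedral measurement uses the atan2 formulation (IUPAC sign).
- The equilibrium slope uses the equally-spaced closed form; its agreement
  with the general two-parameter regression to < 1e-9 over random windows is
  an invariant of the test suite, not an implementation detail.
- Baseline comparisons cap the baselines at the chaotic variant's evaluation
  count (`EnergyBudget`); all energy evaluations — tuning, Metropolis, CLS —
  count against one budget.
- Run results serialize to JSON with the full materialized config snapshot;
  a snapshot plus its seed replays the run bit for bit.

## Known limitations

- The energy surrogate has no solvation, no rotamer chemistry, no explicit
  hydrogens (beyond the terminal reference H); its minima are not native
  structures and its units are not transferable kcal/mol.
- dRMSD defaults to CA atoms and needs a user-supplied reference structure;
  without one the report column is empty.
- The annealing-phase cooling factor follows the sweep convention
  (α_Annealing, default 0.95); sources disagree on whether the quenching
  factor should be reused there, so both are exposed.
- Wall-clock time is recorded but never asserted on (hardware-dependent).
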