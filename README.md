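# cmqa

Chaotic multiquenching annealing for dihedral-angle protein-conformation
energy minimization.

Ab-initio protein structure prediction reduces to a global-optimization
problem: given a sequence of n amino acids, find the vector of dihedral
angles σ = (σ₁, …, σ_m) — backbone φ/ψ (optionally ω) and side-chain χ — that
minimizes a free-energy function f(σ₁, …, σ_m).  The landscape is rugged and
high-dimensional, and classical simulated annealing (SA) converges slowly on
it.  This package implements a three-phase SA variant designed for that
regime, together with the baselines needed to evaluate it:

1. **Multiquenching phase (MQP)** — repeated quenching subphases cool with
   the quadratic law T_{k+1} = α_Q (1 − τ) T_k, where τ ← τ² each Metropolis
   cycle.  When τ has squared its way below a cutoff, a **chaotic local
   search (CLS)** greedily refines the best-so-far conformation using
   perturbations drawn from one of four sine maps with singularities
   (e.g. f(x) = sin(1/x)), then τ resets and a new subphase begins.
2. **Annealing phase (AP)** — classical SA with geometric cooling
   T_{k+1} = α_A T_k from the crossover temperature down.
3. **Dynamical equilibrium (DEP)** — end-of-cycle energies stream into a
   fixed window; the run stops early when the least-squares slope
   a = [12 Σ xᵢEᵢ − 6(n−1) Σ Eᵢ] / (n³ − n) of the window is flat.

The temperature range is tuned analytically from the Boltzmann acceptance
probability P(ΔZ) = exp(−ΔZ/T): T₀ = −ΔZ_max/ln P_hot and
T_f = −ΔZ_min/ln P_cold, with the deteriorations ΔZ estimated by a short
random walk.  Two baselines share every proposal and acceptance rule:
`csa` (single-phase classical SA) and `mqa_dep` (the same pipeline with the
chaotic search disabled).

Proteins are reduced to a torsion-driven chain (backbone N/CA/C/O plus CB and
one pseudo-atom per χ) with an ECEPP-family energy surrogate: Lennard-Jones
12-6, screened Coulomb, cosine torsion barriers, and 12-10 hydrogen bonds.
Synthetic *planted landscapes* with a certified global minimum of exactly 0
(plus optional trap wells) validate the optimizer end to end.

## Worked example

Minimize a tiny peptide from a FASTA file:

```
$ cmqa fold --fasta tiny.fasta --seed 1 --out out/
INFO cmqa: instance with m=6 variables; variant=cmqa
INFO cmqa: finished: best energy 33.1506 after 277 cycles (16627 evals); quenching ended at cycle 7, equilibrium trigger 276
best energy: 33.150596
outputs in out
```

For the 3-residue alanine peptide there are m = 6 torsion variables (φ and ψ
per residue, charged-termini convention).  Quenching ends after 7 cycles (one
full subphase, i.e. one chaotic local search), the equilibrium detector
stopped the annealing phase at cycle 276, and the best reduced-model energy
found was 33.15 (arbitrary surrogate units — not comparable to any full force
field).  `out/` contains the best structure (`best.pdb`), the per-cycle trace
(`trace.csv`: temperature, energy, running minimum, acceptance rate), the
result JSON, and a fully materialized `config_snapshot.yaml` that replays the
run bit for bit.

Library use mirrors the CLI:

```python
import numpy as np
from cmqa import planted_landscape, run_cmqa

ls = planted_landscape(19, n_traps=5, rng=np.random.default_rng(123))
res = run_cmqa(ls, seed=1)
print(res.best_energy)        # ~1e-3: the certified minimum is 0
```

Other verbs: `cmqa compare --variants cmqa,mqa_dep,csa --seeds 10` (paired
seeds, equal evaluation budgets, summary CSV of mean energy / time / dRMSD),
`cmqa sweep --alpha-annealing 0.75,...,0.95 --maps M1,M2,M3,M4` (grid CSV),
and `cmqa fixtures` (deterministic FASTA / planted-landscape / config-suite
generation).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds the 19-variable planted landscape, runs the full three-phase
optimizer and both baselines at the given seed under one shared evaluation
budget, prints their best energies, cycle counts and timings, and writes the
results JSON.
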