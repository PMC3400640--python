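# Methods

## Model

A decoy is represented purely in torsion space: per-residue (φ, ψ, ω)
triplets in degrees, wrapped into (−180°, 180°]. Cartesian N/Cα/C backbones
are rebuilt deterministically from torsions whenever scoring or comparison
needs them, using ideal bond geometry (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N
1.329 Å; N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°) and a canonical
first-residue frame, so identical torsions give bitwise-identical
coordinates. Bond lengths and angles are never perturbed; only torsions
move, and only through fragment insertion (an optional Gaussian φ/ψ jitter
after insertion exists but is off by default).

Fragment libraries hold, for every insertion window (9-mer windows
1…L−8, 3-mer windows 1…L−2), a rank-ordered list of N candidate fragments
(N defaults to 200 for parsed Robetta-style libraries; the synthetic
fixtures use 25). Insertion overwrites the covered residues' torsions.
Each residue written by a 9-mer insertion records the fragment identity as
a key `key = p·N + k` (p = position in window, k = rank), decoded as
`(key // N, key % N)`. Keys are unique per residue by construction, which
is what makes fragment usage recoverable from a finished decoy.

## The estimation-of-distribution loop

State: one PMF per 9-mer window over ranks 0…N−1. Iteration 1 is uniform
(restricted uniform over the top-K ranks when the rank restriction is
active). Each iteration:

1. re-initialize a population of `pool_per_iteration` decoys from the
   sequence and run sample-and-minimize on each under the current PMFs;
2. keep all decoys in the final pool;
3. select the ⌈15%⌉ lowest-energy decoys of the iteration's population
   (stable sort; ties broken by insertion order);
4. reconstruct per-window fragment frequencies F from provenance keys;
5. update `P ← κ·P + (1−κ)·F` with conservation rate κ = 0.6, renormalize,
   and continue.

PMFs are learned on 9-mers only; 3-mer proposals stay uniform over the top
ranks as a deliberate diversity-preserving channel. Windows with no
surviving attribution in the selected set keep their previous PMF (resetting
to uniform would discard learned signal and is not what κ-mixing implies).
κ = 1 short-circuits to an exact copy — the uniform-proposal control arm is
then bit-stable by construction.

**Frequency attribution.** Overlapping later insertions routinely destroy
full 9/9 key agreement, so a decoy contributes a count to (window, rank)
when ≥ 5 of the window's 9 residues carry keys decoding to that rank at the
matching in-window positions (configurable; `min_agreement=9` gives strict
mode). 3-mer insertions intentionally do **not** erase 9-mer attribution:
erasing would starve the frequency counts that the whole method depends on.

## Sample-and-minimize

Defaults (the full-scale operating point):

| parameter | default | meaning |
|---|---|---|
| population / iteration | 100 desk, 5·10⁴ full-scale preset | decoys per iteration |
| iterations | 4 | EDA updates |
| top fraction | 15% | selected for frequency estimation |
| κ | 0.6 | conservation rate |
| SA moves (extensive) | 4000 | final-stage annealing budget; non-extensive = half |
| T_init → T_final | 3.5 → 0.5 | geometric decay, endpoints exact |
| hill-climb iterations | 3 | local-search/perturbation alternations |
| top-K rank restriction | 25 | SA/HC proposals; perturbations ignore it |

Schedule: stage 0 SA; stage 1 SA; stage 2 SA + iterated hill climbing;
stage 3 twice (SA, SA, hill climbing) with the doubled extensive budget.
Moves pick 9-mers with probability 0.5 (else 3-mers), a window uniformly,
and a rank by roulette over the window's PMF (9-mers) or uniformly over the
top-K (3-mers); acceptance is Metropolis. The temperature schedule is
geometric because only the endpoints are prescribed; it resets per stage.
With a single move the first/last-move rule degenerates to T_init.

One hill-climbing iteration visits every 9-mer window exactly once in a
random permutation and, per window, draws up to a capped number of distinct
candidates by roulette without replacement, keeping the first insertion
that strictly decreases the stage energy. The iterated version alternates
sweeps with one perturbation — a 9-mer insertion uniform over *all* ranks,
deliberately outside both the PMFs and the rank restriction — and returns
the best state visited; no perturbation follows the last sweep. Hill
climbing therefore never worsens the energy it returns.

Seeding: every decoy's generator derives from
`SeedSequence((master_seed, iteration, index))`, so results are identical
for any worker count and scheduling order; the only synchronization point
is the PMF update between iterations.

## Staged energy

Four CA-level, rigid-invariant terms stand in for a full centroid force
field, preserving the progressive term-enabling structure the search
depends on (the scorer is injectable — anything exposing
`score(φ, ψ, ω, stage)` plugs in):

- `clash` = Σ max(0, 4.0 − d_ij)² over CA pairs |i−j| ≥ 3 (Å²);
- `rg` = (Rg − 2.2·L^0.38)² (Å²), a compaction target;
- `contact` = −1 per hydrophobic pair ({A,V,L,I,M,F,W,Y,C}, |i−j| ≥ 4)
  within 8 Å;
- `ss_local` = count of residues outside their target basin
  (H: φ∈[−100,−30], ψ∈[−80,−5]; E: φ∈[−180,−90], ψ∈[90,180]; L: free).

Stage weights: 0 {clash}; 1 {+ss_local}; 2 {+rg}; 3 {+contact}, all at 1.
Using CA proxies instead of side-chain centroids keeps the builder at three
atoms per residue; this is a fidelity trade-off, not a claim about real
force fields.

## Synthetic fixtures and what they show

`make_toy_target` builds a toy native from a topology string (default: a
40-residue three-helix bundle with two 2-residue loops). Loop torsions are
drawn from a broad coil-conformer set (PPII, extended, α-like, bridge,
left-handed; ±10° jitter) and the best of 256 seeded joint draws under the
contact-free stage-2 energy is kept, making the native compact and
clash-free. Hydrophobic residues are then placed *from the native
geometry* — on pairs actually in contact in the native, capped at 14 —
so the contact term rewards the native packing rather than generic
collapse. Torsions are quantized to 0.001° so fragment-file round trips
are exact.

`make_planted_library` hides the (optionally jittered) native fragment at a
seeded random rank in every window; all other ranks hold noise fragments
drawn from the wrong secondary-structure basins or broad coil. This
realizes the regime an energy-guided resampling method needs: on the
canonical fixture the native scores below all of 200 random-assembly
decoys and pool energy correlates with CARMSD (Spearman ρ ≈ 0.98).
Two-residue loops matter: every 3-mer window then overlaps a constrained
residue, so no insertion can repack the fold without paying a
secondary-structure penalty. A deceptive variant (`make_deceptive_scorer`,
H/E swapped) realizes the opposite regime — random decoys undercut the
native's energy — for documentation of the failure mode.

These fixtures do **not** emulate real libraries (near-native fragments at
many ranks, realistic torsion noise, PSIPRED confidence profiles) or real
energy landscapes, which are far less separable. Passing tests demonstrate
the machinery — key bookkeeping, frequency estimation, PMF dynamics, the
staged search — not field performance on PDB targets. Landscape quality
varies with the generation seed (some seeds admit deep repacked minima
below the native); the canonical fixture is the seed-0 target, and the
acceptance script pins it while varying only the sampling seed.

## Problem sizes and numerical choices

Desk-scale runs (tests, acceptance script) use the canonical 40-residue
fixture, 4 iterations × 100 decoys, library depth 25, and
`SamplerParams.desk()` (extensive budget 200 moves, hill-climb draw cap 3)
— the same protocol shape as the full defaults at a size a laptop handles
in seconds per decoy. The full-scale preset (5·10⁴ decoys/iteration,
4000 extensive moves, depth 200) is configuration, not a different code
path. Hot kernels (backbone build, energy terms) are numba-compiled;
everything else is numpy.

Numerics: PMFs renormalized after every update (float drift < 1e−9 over 4
iterations); roulette via inverse-CDF with the last CDF entry clamped to 1;
energy caches on decoys always equal a from-scratch rescore to 1e−9;
CARMSD by Kabsch SVD with reflection excluded, all residues, unweighted.
Degenerate inputs: empty pools, zero-move schedules, single-decoy pools and
size-1 comparisons are handled explicitly (the Mann-Whitney report flags
pools smaller than 8 per side as underpowered).

## Known limitations

- The lowest-energy decoy is frequently not the lowest-CARMSD decoy
  (`carmsd_by_energy_top1` ≫ `carmsd_top1` even on the canonical fixture);
  model selection is treated as post-processing, all decoys are written.
- The simplified energy cannot rank real protein conformations; quantitative
  comparisons with centroid force-field scores are out of scope.
- PMFs factorize over windows: correlations between distant windows are not
  modeled, so cooperative errors (consistent wrong packing) can be learned
  when the landscape rewards them.
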