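# Methods

## The scoring model

Given an ensemble S = {S_1, …, S_N} of N ≥ 2 RNA 3D decoys modelling the
same sequence, each decoy is scored by its agreement with the rest of the
pool, measured simultaneously at the 3D and 2D levels.

Two symmetric N×N similarity matrices are built over all unordered decoy
pairs:

- **T**, with T_ij = TM-score(S_i, S_j): superposition-based global fold
  similarity of the C1′ traces, normalized by the common chain length so
  that T is symmetric.
- **I**, with I_ij = INF(S_i^bp, S_j^bp): Interaction Network Fidelity
  between the base-pair maps extracted from each decoy,
  INF = √(precision · recall) over the two pair sets.

These are combined element-wise into the consensus matrix

    M = T ∘ I,   M_ij = T_ij · I_ij,

and each decoy's quality score is its mean off-diagonal row value

    Q_i = (1 / (N − 1)) Σ_{j≠i} M_ij ∈ [0, 1].

A high Q_i means decoy i is supported by both the folds and the pairing
patterns of the other decoys. The `no_bp` baseline variant computes Q from
T alone; since I ≤ 1 elementwise, Q(consensus) ≤ Q(no_bp) always, and the
gap isolates decoys whose base pairing disagrees with the pool even though
their backbone fold does not.

The underlying assumption of any consensus scorer applies: the ensemble's
mode must be informative. Pools dominated by a shared wrong fold, or
bistable RNAs with two equally plausible conformations, can defeat the
consensus signal.

## TM-score

For decoys in 1:1 positional residue correspondence,

    TM = max over rigid superpositions of (1/L) Σ_k 1 / (1 + (d_k/d0)²)

with d_k the distance between corresponding representative atoms (C1′,
falling back to C4′ then P), L the common chain length, and the
nucleic-acid distance scale d0 = 0.6·√(L − 0.5) − 2.5 Å, floored at 0.3 Å.
Residues missing the representative atom in either decoy are dropped from
the sum while L is kept, so incompleteness penalizes.

The maximization is seeded from contiguous chain fragments, each refined by
iterating Kabsch superposition on the residue pairs within a shrinking
distance cutoff (8 → 4.5 Å, ≤20 iterations per cutoff, minimum 3 residues).
For chains up to 64 nt every contiguous fragment of length ≥ 4 is a seed;
refinement trajectories are memoized on their (cutoff stage, selected
residue set) states, so seeds falling into an already-explored basin stop
immediately — the returned maximum is identical to running every seed to
convergence, at a fraction of the cost. Beyond 64 nt a geometric fragment
ladder (L, L/2, L/4, … ≥ 4, stride L/10) bounds the work. The dense regime
was chosen because sparse ladders measurably under-converge on distorted
pairs (deficits up to 0.02 TM units at 3 Å noise), which both breaks
agreement with an exhaustive-search reference and injects rank noise into
the consensus scores.

A precomputed pairwise TM-score CSV can replace the internal engine, so
results can be reproduced with any external TM-score program.

## Base-pair annotation and INF

The built-in geometric annotator emits a pair (i, j) when all hold:
C1′–C1′ distance in [8, 12] Å; at least 2 donor–acceptor heavy-atom
contacts between the base edges at ≤ 3.5 Å; base-plane angle ≤ 65°
(planes fitted to the ring atoms by SVD); and the residues are not
sequence-adjacent (separation ≥ 2 within a chain — residues on different
chains are never adjacent, which matters at the junction of a two-chain
duplex). A–U/G–C pairs with N1–N3 contact geometry are labelled canonical,
G–U wobble, everything else noncanonical. All thresholds are configurable;
the defaults are deliberately permissive about non-canonical geometry
because INF counts all base–base pairs, not only Watson–Crick ones.
External annotations (MC-annotate/FR3D/RNAView-style pair lists, 1-based
"i j label" lines) can be ingested instead.

INF matches on residue-index pairs by default, ignoring edge/orientation
labels, because label taxonomies differ across annotators; a strict-label
mode is available. Conventions at the empty edge: two empty maps agree
perfectly (INF = 1) — two unpaired single strands should not zero out an
otherwise similar pair of decoys in the product M — and exactly one empty
map scores 0.

## Evaluation harness

Predicted scores are assessed against ground-truth metrics (composite
G = 0.3·TM + 0.3·GDT_TS + 0.4·lDDT, INF-All, TM, GDT_TS, lDDT, or negated
RMSD; truth components are consumed as given numbers, never recomputed from
coordinates). Raw predictions and truths are min–max normalized within each
target before pooling for the global Pearson r and Spearman ρ (constant
vectors map to 0.5 to stay finite). Per-target r and ρ are averaged both
arithmetically and via Fisher's z (r clipped to ±(1−10⁻¹²) before atanh).
Targets with a zero-variance vector are dropped from correlation averages
and counted. The per-target top-1 loss is |truth(argmax predicted) −
max truth| on the normalized truth, with predicted ties broken
lexicographically by decoy id so "arbitrary" tie-breaking is reproducible.

## Synthetic decoy pools

The generator emulates a CASP-style pool with controllable, known quality
structure. The reference conformation is an ideal A-form duplex (rise
2.81 Å, twist 32.7°/bp, −4.4 Å x-displacement, standard base reference
frames; backbone C4′/P placed as fixed offsets from C1′). Decoys are
derived by (a) i.i.d. Gaussian coordinate noise of chosen σ plus a random
rigid transform, and/or (b) glycosidic disruption: rotating one partner's
base 90–150° about its C1′–N9/N1 bond, which destroys pairing geometry
while leaving the C1′ trace — and hence TM-score — essentially unchanged.
Ground-truth quality is the TM-score to the unperturbed reference.

The default pool is 12 decoys on a 32-nt duplex in three noise tiers
(σ = 0.1, 1.0, 3.0 Å, four decoys each), spanning near-native to
essentially misfolded (mean TM to reference ≈ 0.97 / 0.3 / 0.08). Passing
tests on these pools demonstrates that the pipeline recovers a known
quality ordering and that the base-pair emphasis isolates pairing defects;
it does not demonstrate performance on real prediction ensembles, whose
error structure (shared systematic misfolds, loop/junction variability,
partial models) the generator does not attempt to mimic.

## Numerical choices

- Kabsch superposition via SVD with a determinant correction, so rotations
  are always proper.
- Pair evaluations are partitioned into batches over unordered pairs and
  optionally dispatched to worker processes; each matrix cell is written
  once, so results are bit-identical for any worker count or batch size.
  Pair measures are invoked with operands in id-canonical order, making
  ensemble scoring exactly equivariant under input permutations.
- Quality-score row sums use exactly-rounded summation (math.fsum), so Q
  is independent of summation order.
- Matrix diagonals are set to 1 by convention; they are never consumed by
  the quality scores.
- Decoy ranking breaks ties lexicographically by id.
- Emitted files use 1-based residue indices; everything in memory is
  0-based.

## Problem sizes in the distributed checks

The test suite and the acceptance script work at desk scale: duplexes of
15–20 bp, pools of 5–12 decoys, three synthetic targets (24/32/40 nt) for
the evaluation benchmark, and 10 generator seeds for the recovery study.
These sizes were chosen so a full closed loop — generate, score, evaluate
against known truth — runs in well under a minute per study on one core
while leaving every code path exercised.

## Known limitations

- The annotator's fixed geometric thresholds are a simplification of
  dedicated annotation programs; borderline non-canonical geometries will
  be classified differently than by MC-annotate/FR3D/RNAView. For faithful
  reproduction of an external annotator's taxonomy, feed its pair lists in.
- Residue correspondence is positional; decoys with missing residues
  relative to the target sequence are excluded from the pool rather than
  aligned.
- The all-vs-all design is O(N²) in ensemble size.
- Sequence-order-independent alignment and protein parameterizations are
  out of scope (the d0 formula is configurable).
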