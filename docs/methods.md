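# Methods

## Problem and model

fragalign computes sequential (order-preserving) residue-level alignments
between protein backbones represented as Cα traces. A comparison takes a
target chain Q (length L_Q) and a database chain P (length L_P) and returns
an ordered set of residue pairs R = {(q_i, p_i)} together with the proper
rigid transform T that superimposes the paired target residues onto the
database chain, plus quality statistics. The method assumes single chains,
Cα-only geometry, and sequential topology (no non-sequential alignments,
no quaternary structure).

## Seeding: matched fragment sets

Chains are tiled into non-overlapping fragments of L_f = 8 residues
(N_f = ⌊L/L_f⌋ per chain; up to 7 trailing residues stay unfragmented but
remain alignable at residue level). A fragment's feature vector is the
vector of its 28 intra-fragment pairwise Cα–Cα distances in lexicographic
pair order — invariant under rigid motion (and under reflection; chirality
is resolved later because the superposition stage admits proper rotations
only). Fragment similarity is the inverse-cosine score
s_f = 1 − arccos(⟨D_A,D_B⟩/(‖D_A‖‖D_B‖)) ∈ [1−π, 1], with the cosine
argument clamped to [−1, 1] against rounding.

Candidate fragment pairs are all (i, j) with s_f ≥ τ_f (default 0.8).
Pairs are grouped into matched fragment sets by spatial consistency: two
pairs are compatible when they preserve backbone order on both chains and
their fragment-centroid separations agree within ε_d (default 2.0 Å). Every
compatible anchor pair spawns the set of all candidate pairs compatible
with both anchors; anchor enumeration is restricted to the 200
best-scoring candidate pairs to bound cost. Sets are ranked by

    S_MFS = w₁·N_Q/N_f^Q + w₂·N_P/N_f^P + w₃·min(N_Q,N_P)/max(N_Q,N_P)

(defaults w₁ = w₂ = w₃ = 1/3: chain coverage on either side plus a balance
term), de-duplicated by a greedy keep-best Jaccard filter over the tagged
fragment membership (threshold 0.7), and truncated to N_seed (default 20).
If no set exists the fallback seed pairs all fragments of both chains, so
every comparison produces at least one seed. When either chain is shorter
than one fragment the pipeline falls back to a residue-only diagonal seed
and flags the report `short_trace`.

## Alignment stages

**Fragment-level.** Needleman–Wunsch-style DP on the seed's s_f submatrix
with gap penalty G_f (default −0.6, the TM-align family's convention; the
value is not critical because the residue stages re-derive the pairing).
End gaps are free: the boundary row/column is initialised to zero and the
optimum is read off the last row/column, so length differences carry no
terminal penalty. Traceback tie-breaking is diagonal > up > left, making
paths deterministic. Matched fragments (i, j) expand to residue pairs
(i·L_f + t, j·L_f + t), t = 0…7.

**Residue-level.** The optimal transform over the current pairs is fitted
(QCP), all of Q is superimposed, and DP runs on the full L_Q × L_P matrix
of TM-align scores S_r = 1/(1 + (d_ij/d0)²) with G_r = 0. The distance
scale d0(L) = max(1.24·(L−15)^⅓ − 1.8, 0.5 Å) is parameterised by
L = min(L_Q, L_P), consistent with the z-score's use of the minimum chain
length (the alternative, L_Q, changes little; min makes a perfect
self-alignment reach TM-score 1).

**Maximal alignment search.** For each of the L_R − L_W + 1 windows of
L_W = 4 consecutive pairs (an alignment shorter than L_W degenerates to a
single whole-alignment window): fit T to the window, superimpose Q's side
of every pair in R, admit pairs strictly under 4.0 Å, and repeat N_MS = 4
times or until membership stabilises. The refined window with the largest
TM-score S_a (normalised by min(L_Q, L_P)) is the maximal subset M. Its
transform re-superimposes the whole chain, and the next-round alignment is
the gap-0 DP path restricted to pairs under 4.0 Å — routing through the DP
preserves strict monotonicity, which raw proximity selection would break.
L_W and N_MS are small by design: a 4-residue window is the shortest seed
that determines a rigid transform robustly, and membership stabilises in a
few rounds.

Stages residue-level + maximal search repeat N_iter times (default 3) per
seed, each seed refined independently; after each round near-duplicate
alignments are dropped (same greedy Jaccard rule, threshold 0.7, over
residue-pair sets) and the best (S_a, alignment) seen so far is kept. The
loop exits early when the best alignment stops changing — with the
keep-best rule this cannot alter the result, only the runtime. Because the
running best is never discarded, the final S_a is non-decreasing in both
N_iter and N_seed.

## Superposition numerics

QCP: both point sets are centred; the 3×3 inner-product matrix forms the
4×4 symmetric key matrix K; the largest eigenvalue is found by Newton
iteration on the quartic characteristic polynomial (coefficients from the
principal minors of K), seeded at (E_X + E_Y)/2 which upper-bounds it, with
tolerance 1e-11 and at most 50 iterations, falling back to a dense
symmetric eigen-decomposition when the iteration stalls. The rotation comes
from the eigenvector quaternion, extracted as the smallest-singular-value
right vector of K − λI; when the two smallest singular values nearly
coincide (clustered top spectrum — near-planar or near-collinear sets,
where Newton's λ error can exceed the eigen-gap) the eigenvector is taken
from the dense decomposition instead.

The reported RMSD is always measured directly from the recovered rotation
rather than through √((E_X+E_Y−2λ)/N): the closed form subtracts two large
numbers and inherits the quartic's conditioning (errors up to ~1e-4 Å on
near-collinear chains), while the rotation itself is insensitive there
because the optimum is flat along the degenerate directions. Direct
measurement restores machine-precision agreement with the Kabsch oracle
(<1e-8 Å across random and degenerate instances) at the cost of one 4×4
SVD and an N×3 product. Exactly coincident sets therefore report 0. For
collinear/planar inputs the rotation is non-unique; any optimal proper
rotation is acceptable and only the RMSD is contractual. Reflections are
never returned (the quaternion parameterisation covers SO(3) only; the
Kabsch oracle applies the determinant sign correction).

## Assessment

- Ne = |R| final pairs; cRMSD = minimal RMSD over those pairs.
- PSI = 100·|{pairs with d < 4.0 Å under the final transform}| / k with
  k = min(L_Q, L_P). The min-chain-length denominator makes PSI comparable
  to the null parameters μ_PSI(k), σ_PSI(k), which are functions of the
  minimum chain length; a pair-count denominator would inflate short
  alignments.
- z = (PSI − 375.64·k^−0.5295)/(99.67·k^−0.5885); the power-law constants
  are used as given, not re-fitted.
- RMSD100 = cRMSD/(1 + ln(Ne/100)) normalises cRMSD to the value expected
  for 100-residue chains. The denominator crosses zero near Ne ≈ 36.8, so
  for Ne < 37 the report carries the raw cRMSD and a `short_alignment`
  flag instead.
- The 4.0 Å cutoff is strict (< 4.0); a pair at exactly 4.0 Å is excluded.

## Structure I/O conventions

PDB parsing is delegated to gemmi. First model only; alternate locations
keep the blank/'A' conformer; residue identity is (resSeq, iCode) with
author numbering preserved for output while all internal indexing is dense
and 0-based; residues lacking a Cα are skipped with a warning; HETATM
residues carrying a Cα (e.g. MSE) are included; chain breaks (consecutive
Cα–Cα distance > 4.5 Å) are logged but the trace is kept whole — fragments
spanning a break still carry valid distance patterns.

## Synthetic structures

The fixture generators emulate backbone geometry only: an ideal α-helix
(rise 1.5 Å, twist 100°, radius 2.3 Å ⇒ ~3.8 Å Cα spacing), isotropic
Gaussian coordinate noise (per-coordinate σ), seeded uniform random proper
rigid motion (quaternion rotation, U(−50, 50) Å translation), and
fixed-step (3.8 Å) self-avoiding random walks (minimum 3.0 Å separation of
non-neighbours; a stalled walk restarts deterministically with seed+1) as
length-matched decoys. Real chains mix secondary structures, have loops,
compact packing, and correlated (not isotropic) coordinate error, so
passing the synthetic tests demonstrates the machinery — fixed points,
rigid invariance, noise robustness, decoy separation — not benchmark
accuracy on real folds. Default test problem sizes (chains of 80–400
residues, 10–20 noise seeds) keep the full suite and the acceptance script
within a few minutes on one CPU.

## Known limitations

- Sequential alignments only; circular permutations and non-sequential
  similarities are invisible.
- The distance-pattern fragment score cannot see chirality; mirror-image
  folds are only separated at the superposition stage.
- Seeding is direct all-vs-all fragment matching, O(N_f^Q · N_f^P) per
  pair; there is no persistent database index, so very large databases pay
  the full cost per query.
- The z-score null constants were fitted elsewhere; on synthetic fixtures
  they serve as a fixed reference scale, and absolute z values on real
  structures should be interpreted against that provenance.
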