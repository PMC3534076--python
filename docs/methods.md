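# Methods

This note documents the models implemented in `modesteer`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical conventions a user should know before trusting a
result.

## Elastic network and normal modes

The protein is coarse-grained to its Cα atoms.  Nodes within a cutoff
radius `r_c` (default 15 Å) are joined by identical Hookean springs of
constant γ (default 1.0 energy/Å²); both values are standard Cα-ANM
practice and are exposed in every entry point.  The Hessian of the
harmonic energy at the input geometry is assembled from per-edge
super-elements

    H_ij = −(γ / d_ij²) · Δr_ij Δr_ijᵀ      (i ≠ j, d_ij ≤ r_c)

with diagonal blocks equal to minus the sum of the off-diagonal blocks in
their row.  The full spectrum is obtained by dense symmetric
diagonalization (`scipy.linalg.eigh`); at the sizes this package targets
(hundreds of residues) this is fast and avoids the convergence edge cases
of sparse solvers near the six-fold degenerate null space.

Conventions:

- **Zero modes.**  Eigenvalues below `1e-8 · λ_max` are classified as
  rigid-body.  A connected, non-collinear network has exactly six; a
  collinear one has five (accepted with a warning); disconnected networks
  warn at construction time and carry extra zero modes.
- **Mode numbering.**  Public "mode k" is the k-th *non-rigid* eigenpair,
  so mode 1 is the softest internal motion (the 7th eigenpair of a
  connected network).
- **Sign convention.**  Each eigenvector's largest-magnitude component is
  made positive, so plus/minus direction labels are reproducible across
  runs and platforms.

### Collectivity

The degree of collectivity of mode k is the entropy-based measure

    κ_k = (1/N) · exp(−Σ_i p_i ln p_i),   p_i = |u_k,i|² / Σ_j |u_k,j|²

where `u_k,i` is the 3-vector displacement of residue i.  κ = 1 when all
residues move equally and 1/N when a single residue carries the whole
mode.  The cooperativity criterion used for mode selection is stated in
the literature without a formula; this entropy form is the standard
concretization and is what the selection uses.

### Mode selection

`select_modes` looks for the largest relative spectral gap
`(λ_{m+1} − λ_m)/λ_m` among the first `2·fallback_count` non-rigid modes
(ties to the lower index).  If it exceeds `gap_ratio_threshold`
(default 1.0) the prefix ending there is taken and then shortened until
every included mode has κ ≥ `min_collectivity` (default 0.3); otherwise
the first `fallback_count` modes (default 9) are returned.  On the
canonical synthetic bundle the spectrum is gapless at this threshold and
selection falls back to nine modes.  The thresholds are calibration
knobs, not physics: different systems will justify different values, and
all three are exposed.

## Mode-restrained steering

For mode k and amplitude `a` (Å) two targets are built:

    target± = start ± a·√N·u_k   (per-node reshape)

so the unsuperposed Cα RMSD from start to either target is exactly `a`
and the midpoint of the two targets is the start.  The default amplitude
of 1.5 Å matches the per-run excursion scale of the protocol this
package implements.

Steering minimizes

    E(x) = E_ENM(x; anchored at start) + (k_r/2) · Σ_i |x_i − x_i^target|²

by damped gradient descent with backtracking line search, where
`E_ENM = Σ_edges (γ/2)(|r_ij| − L_ij)²` takes its rest lengths `L` from
the run's starting conformer.  This coordinate-descent engine is a
deliberate desk-scale surrogate for restrained all-atom molecular
dynamics: it preserves the protocol's structure (harmonic pull along one
collective mode, then relaxation) while running in milliseconds, and it
sits behind a small interface so a heavier sampling backend could be
substituted without touching the round/tree logic.

Numerical choices:

- **Restraint constant.**  The minimizer of the quadratic model sits at
  distance ≈ `a·λ_k/(k_r + λ_k)` from the target, so `k_r` must dominate
  the eigenvalues of the followed band.  The default `k_r = 60` parks
  noiseless runs within ~0.1·amplitude of the target across the first
  nine modes of typical bundle networks (λ ≈ 1–4 at γ = 1), which is also
  the default convergence tolerance (0.15 Å for a 1.5 Å amplitude).
- **Descent.**  Initial step 0.02, halved until the trial energy does not
  increase (40 halvings → an explicit divergence error naming the step).
  With zero noise the recorded energy is therefore non-increasing at
  every step; with noise > 0 a seeded Gaussian kick is added after each
  accepted step and runs are bit-reproducible for a fixed seed.
- **Frames.**  Trajectories are subsampled every 10 steps (plus the first
  and final states) — enough to resolve RMSD-vs-step curves at bounded
  memory.
- **Relaxation.**  After steering, a short restraint-free descent on the
  same start-anchored ENM settles the strained geometry.  Its drift from
  the steered conformer is capped at 0.5 Å so relaxation cannot undo the
  excursion (on a single-basin ENM surface the unconstrained minimum is
  the start itself, so the cap is what makes relaxation meaningful in
  the surrogate).
- **Lifting.**  Steering acts on Cα nodes; full-atom conformers are
  produced by moving every atom of residue i rigidly by that residue's
  Cα displacement.  Intra-residue geometry is preserved exactly, which
  is sufficient for distance monitors and contact shells but does not
  model side-chain repacking.

### Rounds and the conformer tree

A round rebuilds the network and modes on its input conformer (rather
than reusing the initial mode set — recursion should follow the current
structure's own soft directions) and emits `2·|modes|` steered-and-relaxed
conformers labeled `kP`/`kM`.  The tree applies a per-depth schedule of
(mode set, amplitude) breadth-first; node keys are slash-joined labels
(`"1P/2M"`).  Unpruned growth is `Σ_d (2m)^d`, so a node cap (default
500) aborts with a clear message *before* any steering runs.  Per-node
seeds are derived from the user seed and the path label (CRC32), so a
tree is reproducible as a whole and any subtree is reproducible in
isolation.  Amplitude is interpreted per round, not cumulatively.

### Mode overlap

The overlap between a steered conformer and a mode is the cosine between
the superposed displacement vector (final onto start, Kabsch) and the
mode eigenvector.  A numerically zero displacement returns a flagged
null (`None`) rather than 0, because "no motion" and "orthogonal motion"
must not be conflated.

## Ensemble analysis and clustering

Pairwise conformer distance is the superposed RMSD over a residue/atom
selection.  By default each pair is superposed *on the selection itself*
(config-switchable to whole-Cα superposition): the binding-site
rearrangements of interest are then measured in their own local frame
rather than being inflated by global motion.  The clustering criterion
defaults to all atoms of the configured residues (side chains are what
distinguish binding-site rearrangements) with a Cα-only switch; the
β2AR binding-site residue list ships as the preset
`B2AR_BINDING_SITE_RESIDUES`.

Single-link clustering is built as Kruskal's MST construction: edges
ascending by (weight, i, j) — ties therefore break on the lowest item
index pair — joined when they bridge distinct clusters; the accepted
edge weights are the merge heights.  Level j (after j merges, n−j
clusters) has threshold distance `h_j`, and its separation ratio is

    ratio(j) = min inter-cluster distance at level j / h_j

computed definitionally from the matrix; for single linkage this equals
`h_{j+1}/h_j`, and the test suite cross-checks both routes.  Levels with
a zero threshold (duplicate conformers) and the single-cluster level are
flagged unusable (NaN), never silently infinite.  The chosen level
maximizes the ratio, ties preferring fewer clusters; each cluster is
represented by its medoid (minimum summed intra-cluster distance, ties
to the lowest index), which is deterministic and testable where the
original tool's representative rule is unspecified.

Distance monitors report, per conformer, either the minimum pairwise
distance between two atom groups or a named atom–atom distance.

## Interaction fingerprints

Ligand chemistry is explicit input: poses carry typed features (donor,
acceptor, cation, ring, contact group), never perception from
connectivity — this keeps detection deterministic and chemistry
assumptions visible.  The protein side is typed from residue/atom names
via a built-in table (carboxylate oxygens, cationic nitrogens, aromatic
rings, polar donors/acceptors, backbone N/O).  Thresholds live in one
config block with common-practice defaults:

| interaction | criterion | default |
|---|---|---|
| hydrogen bond | donor–acceptor heavy-atom distance; D–H…A angle when H annotated | ≤ 3.5 Å; ≥ 120° |
| salt bridge | cationic N – carboxylate O | ≤ 4.0 Å |
| π-stack | centroid distance; interplanar angle | ≤ 5.5 Å; ≤ 30° (parallel) or ≥ 60° (T-shaped) |
| contact | fraction of residue atoms within the shell | ≥ 50% at 3.5 Å |

Heavy-atom criteria are the default; `place_polar_hydrogen` provides an
idealized H on a donor lacking one (extend the antecedent→donor bond by
1.0 Å) for measuring H…O distances where needed.  A requested
interaction type with no matching ligand feature raises an explicit
"untyped ligand" error — a silent empty result would be
indistinguishable from a true non-interaction.

A checklist pairs residues with the ligand feature class expected to
engage them; the shipped β2AR agonist preset encodes the
experimentally supported interactions (the published source table lists
"Try316", an evident typo which the preset corrects to Tyr316).  Triage
sorts complexes by their externally supplied docking score (consumed as
given, never computed), filters by checklist fraction, breaks ties by
higher fraction then input order, and reports rejected score-best poses
rather than dropping them.

## Synthetic generators

All generators are pure functions of (spec, seed).

- **Helix bundles** use ideal α-helix Cα geometry (1.5 Å rise, 100°
  twist, 2.3 Å helix radius) with helix axes on a circle sized to the
  requested spacing; the all-atom variant adds idealized backbone N/C/O
  and a Cβ stub.  The canonical test system is 3 helices × 20 residues
  at 10 Å spacing — a desk-scale stand-in for a transmembrane bundle.
  It does not model loops, helix kinks, sequence, or side-chain packing.
- **Planted complexes** lay one residue per requested interaction
  radially around a ligand (SER for hydrogen bonds, ASP for salt
  bridges, PHE for π-stacks, VAL for contact patches) with geometry at
  least 0.3 Å / 10° inside the detection thresholds and all unplanted
  pairs at least 0.3 Å outside; an inert ligand core carries one feature
  of every kind far from the protein so detection over the full type
  set is well-posed even when nothing is planted.  The radial layout
  bounds capacity at 6 planted interactions (an explicit error beyond
  that).  A seeded jitter (±0.04 Å) and a random joint rotation vary
  the instances without eroding the margins.
- **Two-state ensembles** displace a bundle by ±d Å RMSD along a chosen
  normal mode plus per-atom Gaussian noise, returning true labels — a
  planted partition whose recovery validates the full
  RMSD → single-link → separation-ratio → medoid chain.

Passing tests on these fixtures demonstrates the machinery (eigenproblem,
steering contracts, clustering optimality, detector geometry) — not that
the protocol's biological conclusions transfer to any particular
receptor, which additionally depends on force-field realism and docking
accuracy that are out of scope here.

## Problem sizes and defaults used in the shipped analyses

The test suite and `scripts/acceptance.py` run on the 3×20 bundle
(60 nodes), ensembles of 8–18 conformers, clustering instances of
5–13 items, and 50 planted complexes — sizes chosen so the full
pipeline (modes → steering round → clustering → fingerprints) is
re-demonstrated from scratch in seconds.

## Known limitations

- The steering engine is a surrogate: no solvent, membrane, thermostat,
  or all-atom force field; time has no physical meaning and step counts
  are analogues, not equivalents, of MD run lengths.
- The single-basin ENM cannot produce genuinely new local minima;
  relaxation is bounded drift, not basin hopping.
- Rigid per-residue lifting moves side chains with their Cα; monitors
  that depend on side-chain rotamer changes will not see them.
- Ligand feature typing is manual; there is no protonation, tautomer, or
  aromaticity perception.
- Mode selection thresholds are calibrated to bundle-like spectra; dense
  globular proteins may need a different gap threshold to isolate a
  separable band.
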