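# modesteer

Elastic-network mode-restrained conformational ensembles for proteins:
anisotropic network model (ANM) normal modes, harmonic-restraint steering
toward plus/minus mode targets, recursive conformer trees, binding-site
single-link clustering with separation-ratio level selection, and
geometric protein–ligand interaction fingerprints for triaging externally
scored poses.

## The problem

A single crystal structure rarely explains why chemically different
agonists of the same receptor behave differently: ligands select among
*conformers*, and the functionally interesting conformers of, say, a
GPCR's binding site are excursions along a few collective motions of the
helix bundle. `modesteer` implements the complete desk-scale protocol
for generating and triaging such conformers:

1. **ANM modes.** Cα atoms become nodes of an elastic network (springs of
   constant γ between all pairs within a cutoff, default 15 Å).  The
   3N×3N Hessian has super-elements −(γ/d²)·Δr Δrᵀ per spring; its
   eigenvectors `u_k` are the normal modes, with exactly six zero
   eigenvalues for rigid-body motion.  Modes are ranked by eigenvalue
   (softest first) and a separable low-frequency subset is picked by the
   spectral-gap and collectivity criteria, where collectivity
   κ = (1/N)·exp(−Σ pᵢ ln pᵢ) with pᵢ the normalized squared residue
   displacement.
2. **Mode-restrained steering.**  For each selected mode k two targets
   are built at ±a·√N·u_k (so the target sits exactly `a` Å RMSD from
   the start, default 1.5 Å), and the structure is driven toward each
   target by minimizing E_ENM + (k_r/2)·Σ|r_i − r_i^target|², followed by
   a short restraint-free relaxation.  Applying every mode in both
   directions to every conformer of the previous round grows a recursive
   conformer tree with path labels like `1P/2M/3M`.
3. **Clustering.**  Conformers are compared by superposed RMSD over a
   binding-site residue selection, merged by agglomerative single-link
   clustering (equivalent to ascending minimum-spanning-tree edges), and
   the clustering level with the highest *separation ratio* — shortest
   inter-cluster distance over the threshold distance defining the
   level — is kept, one medoid per cluster.
4. **Fingerprints and triage.**  Conformer–ligand complexes are screened
   against an interaction checklist (hydrogen bonds ≤ 3.5 Å, salt
   bridges ≤ 4.0 Å, π-stacks ≤ 5.5 Å and parallel/T-shaped, 3.5 Å
   majority-contact shells); poses are ranked by their externally
   supplied docking score and filtered by checklist satisfaction.  A
   β2AR agonist checklist (Asp113/β-OH, Ser203·204·207/head-group OHs,
   Asn293/protonated amine, Tyr308·Asn312·Tyr316/ethanolamine tail, …)
   ships as a preset.

Everything is exercisable on synthetic structures with known ground
truth — ideal α-helix bundles, planted two-state ensembles, and toy
complexes with planted interactions — generated by `modesteer.synthgen`.

## Worked example

```python
import numpy as np
from modesteer import anm, ensemble, steering, synthgen

bundle = synthgen.make_helix_bundle(synthgen.BundleSpec())  # 3 helices x 20 residues
network = anm.build_network(bundle, cutoff=15.0)
modes = anm.compute_modes(network)
print(f"zero modes: {modes.n_zero}, softest eigenvalue: {modes.frequency(1):.3f}")
print(f"collectivity of mode 1: {anm.collectivity(modes, 1):.3f}")
print(f"selected modes: {anm.select_modes(modes)}")

target_plus, _ = anm.make_target_pair(bundle, modes, 1, amplitude=1.5)
result = steering.steer_to_target(bundle, target_plus)
print(f"excursion: {result.rmsd_to_start[-1]:.3f} A (converged: {result.converged})")
overlap = steering.mode_overlap(bundle.coords[0][bundle.calpha_indices()],
                                result.final_coords, modes.mode_vector(1))
print(f"overlap with commanded mode: {overlap:.3f}")

conformers, labels = synthgen.make_two_state_ensemble(4, 4, displacement=3.0,
                                                      noise=0.1, seed=0)
matrix = ensemble.pairwise_rmsd(conformers)
hierarchy = ensemble.cluster_single_link(matrix)
level, clusters, reps = ensemble.choose_clustering(hierarchy, matrix)
print(f"chosen level {level}: clusters {clusters}, representatives {reps}")
```

prints

```
zero modes: 6, softest eigenvalue: 0.999
collectivity of mode 1: 0.549
selected modes: [1, 2, 3, 4, 5, 6, 7, 8, 9]
excursion: 1.494 A (converged: True)
overlap with commanded mode: 1.000
chosen level 6: clusters [[0, 1, 2, 3], [4, 5, 6, 7]], representatives [0, 4]
```

The bundle's network is rigid (exactly 6 zero modes); the nine softest
internal modes pass the gap/collectivity selection; a commanded 1.5 Å
excursion along mode 1 converges at 1.494 Å from the start while moving
essentially only along that mode (overlap 1.000); and the planted
two-group ensemble is recovered exactly, with one medoid representative
per group.

## Command line

The same stages are available as subcommands, each writing into a fresh
run directory together with its resolved configuration:

```sh
modesteer synth    --out run/s --kind bundle
modesteer modes    --input run/s/bundle.pdb --out run/m
modesteer ensemble --input run/s/bundle.pdb --out run/e --modes 1,2,3 --depth 1
modesteer cluster  --input run/e/ensemble.pdb --residues 1-60 --atoms calpha --out run/c
modesteer monitor  --input run/e/ensemble.pdb --group-a :1:CA --group-b :60:CA --out run/d
modesteer triage   --conformers prot.pdb --poses poses.json --out run/t
```

To run the protocol on a real receptor, download a structure (e.g. the
inactive β2AR crystal structure, PDB 2RH1) and pass it as `--input`,
restricting chain and residue range with the selection options.

## Layout

- `modesteer.structio` — PDB I/O, selections, Kabsch superposition, RMSD profiles
- `modesteer.anm` — elastic network, Hessian, modes, collectivity, targets
- `modesteer.steering` — restrained descent, relaxation, rounds, conformer trees
- `modesteer.ensemble` — monitors, pairwise RMSD, single-link clustering
- `modesteer.fingerprint` — interaction detection, checklists, pose triage
- `modesteer.synthgen` — synthetic bundles, planted ensembles and complexes
- `modesteer.cli` — the subcommands above

See `docs/methods.md` for the model details, parameter choices and known
limitations.
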