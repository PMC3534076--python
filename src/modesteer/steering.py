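"""Mode-restrained steering on the elastic-network energy surface.

A conformer is driven toward a mode-displaced target by minimizing

    E(x) = E_ENM(x; anchored at the start) + (k_r/2)·Σ_i |x_i − x_i^target|²

with damped gradient descent on the Cα nodes (optionally with seeded
Langevin-style noise), followed by a short relaxation with the restraint
off.  The ENM springs take the starting conformer's pair distances as
rest lengths, so each round begins from a locally relaxed surface.  This
is deliberately a coarse-grained surrogate for restrained all-atom
dynamics: it preserves the protocol's structure — a harmonic restraint
pulls the excursion along one collective mode, a minimization then
settles the strained geometry — behind an interface that a heavier
sampling backend could replace.

Rounds apply every selected mode in both directions (labels "1P", "1M",
…), and the recursive conformer tree uses each round's output conformers
as inputs to the next, re-deriving the network and its modes per node.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import anm
from .structio import Structure, apply_transform, plain_rmsd, superpose

__all__ = [
    "SteeringOptions",
    "SteeringResult",
    "EnsembleTree",
    "DivergenceError",
    "steer_to_target",
    "relax",
    "run_round",
    "build_tree",
    "mode_overlap",
]


class DivergenceError(Exception):
    """The descent produced a non-finite energy (step-size blowup)."""


@dataclass(frozen=True)
class SteeringOptions:
    """Tunables for one restrained run.

    ``k_restraint`` is calibrated so a noiseless run parks within about a
    tenth of the commanded amplitude from its target on typical bundle
    networks.  ``noise`` = 0 gives deterministic, monotone descent; with
    noise > 0 the run is still bit-reproducible for a fixed seed.
    """

    k_restraint: float = 60.0     # energy/Å² toward the target
    max_steps: int = 2000
    step_size: float = 0.02       # initial descent step (backtracked)
    noise: float = 0.0            # Å, per-step thermal kick
    seed: int = 0
    tolerance: float = 0.15       # Å, convergence on RMSD-to-target
    relax_steps: int = 200
    relax_max_drift: float = 0.5  # Å, cap on relaxation drift
    frame_interval: int = 10
    cutoff: float = 15.0          # network rebuild parameters
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class SteeringResult:
    """Trajectory summary of one restrained run."""

    frames: np.ndarray            # (n_frames, N, 3), subsampled
    rmsd_to_start: np.ndarray     # Å, one per frame
    rmsd_to_target: np.ndarray
    energies: np.ndarray          # total restrained energy per frame
    final_coords: np.ndarray      # (N, 3); equals frames[-1]
    converged: bool
    label: str


def _enm_gradient(network: anm.ElasticNetwork, coords: np.ndarray,
                  rest_lengths: np.ndarray) -> np.ndarray:
    i, j = network.edges[:, 0], network.edges[:, 1]
    d = coords[j] - coords[i]
    r = np.linalg.norm(d, axis=1)
    # force magnitude γ(r − L) along the bond; guard exact overlaps
    safe_r = np.where(r > 1e-12, r, 1.0)
    f = (network.gamma * (r - rest_lengths) / safe_r)[:, None] * d
    grad = np.zeros_like(coords)
    np.add.at(grad, i, -f)
    np.add.at(grad, j, f)
    return grad


def _descend(coords: np.ndarray, energy_fn, grad_fn, steps: int,
             step_size: float, rng: np.random.Generator | None,
             noise: float, frame_interval: int,
             stop_fn=None, max_drift_from=None, max_drift=None,
             ) -> tuple[np.ndarray, list[np.ndarray], list[float]]:
    """Backtracking gradient descent; returns (final, frames, energies).

    Frames include step 0 and the final state.  With ``noise`` = 0 the
    recorded energy is strictly non-increasing.
    """
    x = coords.copy()
    e = energy_fn(x)
    if not np.isfinite(e):
        raise DivergenceError("non-finite energy at step 0")
    frames = [x.copy()]
    energies = [e]
    for step in range(1, steps + 1):
        g = grad_fn(x)
        alpha = step_size
        for _ in range(40):
            trial = x - alpha * g
            e_trial = energy_fn(trial)
            if np.isfinite(e_trial) and e_trial <= e:
                break
            alpha *= 0.5
        else:
            raise DivergenceError(f"no descent direction found at step {step}")
        if noise > 0 and rng is not None:
            kicked = trial + rng.normal(0.0, noise, trial.shape)
            e_kicked = energy_fn(kicked)
            if not np.isfinite(e_kicked):
                raise DivergenceError(f"non-finite energy at step {step}")
            trial, e_trial = kicked, e_kicked
        if max_drift_from is not None:
            drift = plain_rmsd(trial, max_drift_from)
            if drift > max_drift:
                break
        x, e = trial, e_trial
        if step % frame_interval == 0:
            frames.append(x.copy())
            energies.append(e)
        if stop_fn is not None and stop_fn(x):
            break
        if float(np.linalg.norm(g)) < 1e-10:
            break
    if not np.array_equal(frames[-1], x):
        frames.append(x.copy())
        energies.append(e)
    return x, frames, energies


def steer_to_target(structure: Structure | np.ndarray,
                    target: anm.TargetConformation,
                    opts: SteeringOptions = SteeringOptions(),
                    network: anm.ElasticNetwork | None = None,
                    ) -> SteeringResult:
    """Steer the Cα nodes toward a mode target under a harmonic restraint.

    The run terminates at convergence (RMSD-to-target ≤ tolerance) or at
    ``max_steps``.  With noise = 0 the total energy is non-increasing at
    every recorded step; with a fixed seed the run is bit-reproducible.
    """
    if isinstance(structure, Structure):
        start = structure.coords[0][structure.calpha_indices()].copy()
    else:
        start = np.asarray(structure, dtype=float).copy()
    tgt = np.asarray(target.coords, dtype=float)
    if start.shape != tgt.shape:
        raise ValueError(f"node count mismatch: {start.shape} vs {tgt.shape}")
    if network is None:
        network = anm.build_network(start, cutoff=opts.cutoff, gamma=opts.gamma)
    i, j = network.edges[:, 0], network.edges[:, 1]
    rest = np.linalg.norm(start[j] - start[i], axis=1)
    kr = opts.k_restraint

    def energy(x: np.ndarray) -> float:
        r = np.linalg.norm(x[j] - x[i], axis=1)
        e_enm = 0.5 * network.gamma * float(np.sum((r - rest) ** 2))
        return e_enm + 0.5 * kr * float(np.sum((x - tgt) ** 2))

    def grad(x: np.ndarray) -> np.ndarray:
        return _enm_gradient(network, x, rest) + kr * (x - tgt)

    rng = np.random.default_rng(opts.seed) if opts.noise > 0 else None
    tol = opts.tolerance

    final, frames, energies = _descend(
        start, energy, grad, opts.max_steps, opts.step_size, rng,
        opts.noise, opts.frame_interval,
        stop_fn=lambda x: plain_rmsd(x, tgt) <= tol)

    frames_arr = np.asarray(frames)
    r2s = np.array([plain_rmsd(f, start) for f in frames])
    r2t = np.array([plain_rmsd(f, tgt) for f in frames])
    return SteeringResult(
        frames=frames_arr, rmsd_to_start=r2s, rmsd_to_target=r2t,
        energies=np.asarray(energies), final_coords=final,
        converged=bool(r2t[-1] <= tol), label=target.label)


def relax(coords: Structure | np.ndarray, steps: int = 200,
          network: anm.ElasticNetwork | None = None,
          rest_coords: np.ndarray | None = None,
          max_drift: float = 0.5,
          opts: SteeringOptions = SteeringOptions()) -> np.ndarray:
    """Short restraint-free minimization of the ENM energy.

    ``rest_coords`` anchors the spring rest lengths (default: the input
    conformer itself, in which case the input is already minimal and is
    returned unchanged).  The drift from the input is capped at
    ``max_drift`` Å so relaxation settles strain without undoing the
    mode excursion.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if isinstance(coords, Structure):
        x0 = coords.coords[0][coords.calpha_indices()].copy()
    else:
        x0 = np.asarray(coords, dtype=float).copy()
    if steps == 0:
        return x0
    if network is None:
        network = anm.build_network(x0, cutoff=opts.cutoff, gamma=opts.gamma)
    anchor = x0 if rest_coords is None else np.asarray(rest_coords, float)
    i, j = network.edges[:, 0], network.edges[:, 1]
    rest = np.linalg.norm(anchor[j] - anchor[i], axis=1)

    def energy(x: np.ndarray) -> float:
        r = np.linalg.norm(x[j] - x[i], axis=1)
        return 0.5 * network.gamma * float(np.sum((r - rest) ** 2))

    def grad(x: np.ndarray) -> np.ndarray:
        return _enm_gradient(network, x, rest)

    final, _frames, _energies = _descend(
        x0, energy, grad, steps, opts.step_size, None, 0.0,
        max(steps, 1), max_drift_from=x0, max_drift=max_drift)
    return final


def _child_seed(seed: int, label: str) -> int:
    return (seed + zlib.crc32(label.encode())) % (2**31 - 1)


def run_round(structure: Structure, mode_indices: list[int],
              amplitude: float, opts: SteeringOptions = SteeringOptions(),
              ) -> list[tuple[str, Structure, SteeringResult]]:
    """One steering round: every mode, both directions, steer then relax.

    The elastic network and its modes are recomputed on the input
    structure, so recursion always follows the current conformer's own
    soft directions.  Returns 2·|modes| (label, conformer, result)
    triples; conformers carry the full atom roster via rigid per-residue
    lifting of the Cα displacement.
    """
    if not mode_indices:
        raise ValueError("mode list is empty")
    ca_idx = structure.calpha_indices()
    start = structure.coords[0][ca_idx]
    network = anm.build_network(start, cutoff=opts.cutoff, gamma=opts.gamma)
    modes = anm.compute_modes(network)
    out = []
    for k in mode_indices:
        for target in anm.make_target_pair(start, modes, k, amplitude):
            run_opts = replace(opts, seed=_child_seed(opts.seed, target.label))
            result = steer_to_target(start, target, run_opts, network=network)
            relaxed = relax(result.final_coords, steps=opts.relax_steps,
                            network=network, rest_coords=start,
                            max_drift=opts.relax_max_drift, opts=opts)
            conformer = anm.lift_displacement(structure, relaxed - start)
            result = replace_final(result, relaxed)
            out.append((target.label, conformer, result))
    return out


def replace_final(result: SteeringResult, final: np.ndarray) -> SteeringResult:
    """Swap in post-relaxation coordinates as the final frame."""
    frames = np.concatenate([result.frames, final[None]], axis=0)
    start = result.frames[0]
    return SteeringResult(
        frames=frames,
        rmsd_to_start=np.append(result.rmsd_to_start, plain_rmsd(final, start)),
        rmsd_to_target=np.append(result.rmsd_to_target, result.rmsd_to_target[-1]),
        energies=np.append(result.energies, result.energies[-1]),
        final_coords=final, converged=result.converged, label=result.label)


@dataclass
class TreeNode:
    key: str
    parent: str | None
    structure: Structure
    result: SteeringResult | None


@dataclass
class EnsembleTree:
    """Conformers indexed by mode-direction path labels ("1P/2M/…")."""

    nodes: dict[str, TreeNode] = field(default_factory=dict)

    def keys(self) -> list[str]:
        return list(self.nodes)

    def __getitem__(self, key: str) -> TreeNode:
        return self.nodes[key]

    def __contains__(self, key: str) -> bool:
        return key in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def conformers(self, include_root: bool = False) -> list[tuple[str, Structure]]:
        return [(k, n.structure) for k, n in self.nodes.items()
                if include_root or k != ""]


def build_tree(start: Structure,
               schedule: list[tuple[list[int], float]],
               opts: SteeringOptions = SteeringOptions(),
               node_cap: int = 500) -> EnsembleTree:
    """Grow the recursive conformer tree breadth-first.

    ``schedule`` gives (mode indices, amplitude) per round; round r is
    applied to every conformer produced by round r−1.  An unpruned
    depth-d schedule over m modes yields Σ_j (2m)^j non-root nodes, so a
    node cap (checked before any steering runs) guards the exponential.
    """
    expected = 1
    level = 1
    for mode_indices, _amp in schedule:
        level *= 2 * len(mode_indices)
        expected += level
    if expected > node_cap:
        raise ValueError(
            f"schedule would create {expected} nodes, above the cap of "
            f"{node_cap}; prune modes or depth, or raise node_cap")

    tree = EnsembleTree()
    tree.nodes[""] = TreeNode("", None, start, None)
    frontier = [""]
    for mode_indices, amplitude in schedule:
        next_frontier = []
        for parent_key in frontier:
            parent = tree.nodes[parent_key]
            round_opts = replace(opts, seed=_child_seed(opts.seed, parent_key))
            for label, conformer, result in run_round(
                    parent.structure, mode_indices, amplitude, round_opts):
                key = f"{parent_key}/{label}" if parent_key else label
                tree.nodes[key] = TreeNode(key, parent_key, conformer, result)
                next_frontier.append(key)
        frontier = next_frontier
    return tree


def mode_overlap(start: Structure | np.ndarray, final: Structure | np.ndarray,
                 mode_vector: np.ndarray) -> float | None:
    """Cosine between the superposed displacement and a mode vector.

    The final conformer is rigid-body superposed onto the start first.
    Returns ``None`` (a flagged null, not 0) when the displacement is
    numerically zero — a zero overlap would wrongly read as "orthogonal".
    """
    a = start.coords[0][start.calpha_indices()] if isinstance(start, Structure) \
        else np.asarray(start, float)
    b = final.coords[0][final.calpha_indices()] if isinstance(final, Structure) \
        else np.asarray(final, float)
    R, t, _ = superpose(b, a)
    disp = (apply_transform(b, R, t) - a).ravel()
    norm = np.linalg.norm(disp)
    if norm < 1e-10:
        return None
    u = np.asarray(mode_vector, float).ravel()
    return float(disp @ u / (norm * np.linalg.norm(u)))
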