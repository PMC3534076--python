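"""Anisotropic network model: elastic network, normal modes, mode targets.

The network places a node at every Cα and connects pairs within a cutoff
radius by identical Hookean springs of constant γ.  The Hessian of the
harmonic energy, evaluated at the input geometry, is the 3N×3N block
matrix with super-elements ``−(γ/d²)·Δr Δrᵀ`` for each edge and diagonal
blocks equal to the negative sum of the off-diagonal blocks in their row.
Its eigenvectors are the normal modes; the six smallest (numerically zero)
eigenvalues correspond to rigid-body translation and rotation of a
connected, non-collinear network.

Public mode numbering starts at the first non-rigid mode: "mode 1" is the
7th eigenpair of a connected network, i.e. the softest internal motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .structio import Structure

__all__ = [
    "ElasticNetwork",
    "ModeSet",
    "TargetConformation",
    "build_network",
    "hessian",
    "compute_modes",
    "collectivity",
    "select_modes",
    "make_target_pair",
    "lift_displacement",
]

#: eigenvalues below this fraction of the largest are classed as rigid-body
ZERO_MODE_TOL = 1e-8


@dataclass
class ElasticNetwork:
    """Cα elastic network: node coordinates, cutoff, spring constant, edges."""

    coords: np.ndarray          # (N, 3) Å
    cutoff: float               # Å
    gamma: float                # energy/Å²
    edges: np.ndarray           # (E, 2) int, i < j

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def is_connected(self) -> bool:
        n = self.n_nodes
        adj: list[list[int]] = [[] for _ in range(n)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        seen = {0}
        stack = [0]
        while stack:
            for m in adj[stack.pop()]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return len(seen) == n


@dataclass
class ModeSet:
    """Full eigen-decomposition of an elastic-network Hessian.

    ``eigenvalues`` ascend; ``eigenvectors[:, k]`` is the unit 3N vector of
    the k-th eigenpair.  ``n_zero`` counts near-zero (rigid-body)
    eigenvalues.  Public mode index k (1-based) maps to eigenpair
    ``n_zero + k - 1``.
    """

    eigenvalues: np.ndarray     # (3N,)
    eigenvectors: np.ndarray    # (3N, 3N), columns
    n_zero: int
    n_nodes: int

    @property
    def n_nonzero(self) -> int:
        return len(self.eigenvalues) - self.n_zero

    def _col(self, k: int) -> int:
        if not 1 <= k <= self.n_nonzero:
            raise IndexError(f"mode {k} out of range 1..{self.n_nonzero}")
        return self.n_zero + k - 1

    def frequency(self, k: int) -> float:
        """Eigenvalue λ_k of public (non-rigid) mode k."""
        return float(self.eigenvalues[self._col(k)])

    def mode_vector(self, k: int) -> np.ndarray:
        """Unit 3N eigenvector of public mode k."""
        return self.eigenvectors[:, self._col(k)].copy()

    def mode_displacements(self, k: int) -> np.ndarray:
        """Per-node (N, 3) displacement pattern of public mode k."""
        return self.mode_vector(k).reshape(self.n_nodes, 3)


@dataclass
class TargetConformation:
    """Mode-displaced target: start ± amplitude·√N·u_k, at the node level."""

    mode_index: int
    direction: str              # "P" or "M"
    amplitude: float            # Å (RMSD from start)
    coords: np.ndarray          # (N, 3)

    @property
    def label(self) -> str:
        return f"{self.mode_index}{self.direction}"


def build_network(structure: Structure | np.ndarray, cutoff: float = 15.0,
                  gamma: float = 1.0) -> ElasticNetwork:
    """Build the Cα elastic network of a structure (first model).

    Edges are exactly the Cα pairs at distance ≤ cutoff.  Defaults
    (cutoff 15 Å, γ = 1) are standard Cα-ANM practice.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(structure, Structure):
        ca = structure.calpha_indices()
        coords = structure.coords[0][ca]
    else:
        coords = np.asarray(structure, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 Cα atoms")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    within = dist[iu, ju] <= cutoff
    edges = np.stack([iu[within], ju[within]], axis=1)
    net = ElasticNetwork(coords=coords, cutoff=float(cutoff),
                         gamma=float(gamma), edges=edges)
    if edges.shape[0] == 0 or not net.is_connected():
        warnings.warn("elastic network is disconnected; expect extra zero modes",
                      stacklevel=2)
    return net


def hessian(network: ElasticNetwork) -> np.ndarray:
    """Assemble the 3N×3N ANM Hessian."""
    n = network.n_nodes
    H = np.zeros((3 * n, 3 * n))
    for i, j in network.edges:
        d = network.coords[j] - network.coords[i]
        d2 = float(d @ d)
        block = -(network.gamma / d2) * np.outer(d, d)
        H[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        H[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
        H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        H[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return H


def enm_energy(network: ElasticNetwork, coords: np.ndarray,
               rest_coords: np.ndarray | None = None) -> float:
    """Explicit pairwise ENM energy Σ_edges (γ/2)(|r_ij| − L_ij)².

    Rest lengths L are taken from ``rest_coords`` (default: the network's
    own coordinates).  This is the anharmonic energy whose quadratic
    expansion at the rest geometry is ½dᵀHd.
    """
    rest = network.coords if rest_coords is None else np.asarray(rest_coords, float)
    coords = np.asarray(coords, float)
    i, j = network.edges[:, 0], network.edges[:, 1]
    L = np.linalg.norm(rest[j] - rest[i], axis=1)
    r = np.linalg.norm(coords[j] - coords[i], axis=1)
    return float(0.5 * network.gamma * np.sum((r - L) ** 2))


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Make each column's largest-|component| positive (reproducible P/M)."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def compute_modes(network: ElasticNetwork, n_modes: int | None = None) -> ModeSet:
    """Diagonalize the Hessian and return the full mode set.

    Exactly 6 near-zero eigenvalues are expected for a connected,
    non-collinear network (5 for collinear geometries, accepted with a
    warning; more for disconnected ones).
    """
    H = hessian(network)
    vals, vecs = scipy.linalg.eigh(H)
    lam_max = float(vals[-1]) if vals[-1] > 0 else 1.0
    n_zero = int(np.sum(vals < ZERO_MODE_TOL * lam_max))
    vals = np.where(np.abs(vals) < ZERO_MODE_TOL * lam_max, np.abs(vals), vals)
    vecs = _fix_signs(vecs)
    if n_zero == 5:
        warnings.warn("5 zero modes: collinear node geometry", stacklevel=2)
    if n_modes is not None and n_modes > len(vals) - n_zero:
        raise ValueError(
            f"n_modes={n_modes} exceeds {len(vals) - n_zero} non-rigid modes")
    return ModeSet(eigenvalues=vals, eigenvectors=vecs,
                   n_zero=n_zero, n_nodes=network.n_nodes)


def collectivity(modeset: ModeSet, k: int) -> float:
    """Entropy-based degree of collectivity κ_k ∈ [1/N, 1].

    κ = (1/N)·exp(−Σᵢ pᵢ ln pᵢ) with pᵢ the normalized squared
    displacement of residue i in mode k.  κ = 1 when every residue moves
    equally; κ = 1/N when a single residue carries all the motion.
    """
    disp = modeset.mode_displacements(k)
    p = np.sum(disp ** 2, axis=1)
    p = p / p.sum()
    nz = p > 0
    entropy = -np.sum(p[nz] * np.log(p[nz]))
    return float(np.exp(entropy) / modeset.n_nodes)


def select_modes(modeset: ModeSet, gap_ratio_threshold: float = 1.0,
                 min_collectivity: float = 0.3,
                 fallback_count: int = 9) -> list[int]:
    """Pick a separable subset of soft modes by spectral gap + collectivity.

    The candidate cut m is the position of the largest relative spectral
    gap (λ_{m+1} − λ_m)/λ_m among the first ``2·fallback_count`` non-rigid
    modes (ties → lower index).  If that gap does not exceed
    ``gap_ratio_threshold`` the first ``fallback_count`` modes are taken.
    The prefix is then shortened so every included mode has
    κ ≥ ``min_collectivity``.  Returns 1-based public mode indices.
    """
    nn = modeset.n_nonzero
    if nn == 0:
        raise ValueError("empty spectrum: no non-rigid modes")
    horizon = min(2 * fallback_count, nn - 1)
    best_m, best_gap = None, -np.inf
    for m in range(1, horizon + 1):
        lam_m = modeset.frequency(m)
        if lam_m <= 0:
            continue
        gap = (modeset.frequency(m + 1) - lam_m) / lam_m
        if gap > best_gap + 1e-15:
            best_m, best_gap = m, gap
    if best_m is None or best_gap < gap_ratio_threshold:
        m = min(fallback_count, nn)
    else:
        # trim the gap-derived prefix so every included mode is collective
        m = best_m
        for k in range(1, best_m + 1):
            if collectivity(modeset, k) < min_collectivity:
                m = k - 1
                break
    return list(range(1, m + 1))


def make_target_pair(structure: Structure | np.ndarray, modeset: ModeSet,
                     k: int, amplitude: float
                     ) -> tuple[TargetConformation, TargetConformation]:
    """Plus/minus targets displaced ``amplitude`` Å (RMSD) along mode k.

    target± = start ± amplitude·√N·u_k per node, so that the unsuperposed
    RMSD from start equals the amplitude exactly and the midpoint of the
    two targets is the start.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if isinstance(structure, Structure):
        start = structure.coords[0][structure.calpha_indices()]
    else:
        start = np.asarray(structure, dtype=float)
    if start.shape[0] != modeset.n_nodes:
        raise ValueError("structure node count does not match mode set")
    disp = amplitude * np.sqrt(modeset.n_nodes) * modeset.mode_displacements(k)
    return (
        TargetConformation(k, "P", float(amplitude), start + disp),
        TargetConformation(k, "M", float(amplitude), start - disp),
    )


def write_nmd(modeset: ModeSet, path, n_modes: int | None = None) -> None:
    """Export modes as a plain-text NMD-style file.

    One ``mode <k> <eigenvalue> <flattened eigenvector>`` line per
    non-rigid mode, preceded by a coordinates stanza-free minimal header.
    """
    n = n_modes if n_modes is not None else min(modeset.n_nonzero, 20)
    with open(path, "w") as fh:
        fh.write(f"nmd modes={n} nodes={modeset.n_nodes}\n")
        for k in range(1, n + 1):
            vec = " ".join(f"{v:.6f}" for v in modeset.mode_vector(k))
            fh.write(f"mode {k} {modeset.frequency(k):.8g} {vec}\n")


def mode_table(modeset: ModeSet, n_modes: int | None = None):
    """Per-mode eigenvalue and collectivity as a DataFrame."""
    import pandas as pd

    n = n_modes if n_modes is not None else min(modeset.n_nonzero, 20)
    return pd.DataFrame({
        "mode": np.arange(1, n + 1),
        "eigenvalue": [modeset.frequency(k) for k in range(1, n + 1)],
        "collectivity": [collectivity(modeset, k) for k in range(1, n + 1)],
    })


def lift_displacement(structure: Structure,
                      calpha_displacements: np.ndarray) -> Structure:
    """Move every atom of residue i rigidly by that residue's Cα displacement.

    Lifts a Cα-level (network-node) displacement field to the full atom
    roster so all-atom monitors (side-chain distances, contacts) can be
    evaluated on coarse-grained conformers.  Residues lacking a Cα are
    left in place.  Intra-residue geometry is preserved exactly.
    """
    disp = np.asarray(calpha_displacements, dtype=float)
    res_atoms = structure.residue_atom_indices()
    ca_residues = [key for key, idx in res_atoms.items()
                   if "CA" in structure.atom_name[idx]]
    if disp.shape != (len(ca_residues), 3):
        raise ValueError(
            f"expected {len(ca_residues)} displacement vectors, got {disp.shape}")
    coords = structure.coords.copy()
    for vec, key in zip(disp, ca_residues):
        coords[:, res_atoms[key], :] += vec
    return structure.with_coords(coords)
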