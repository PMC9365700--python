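"""Gaussian and anisotropic elastic network models.

A bead model becomes a harmonic spring network: GNM builds the N × N
Kirchhoff (graph Laplacian) matrix at a 10 Å contact cutoff, ANM the
3N × 3N Hessian at 15 Å, both with spring constant γ = 1.0 by default.
Mode variances follow the pseudo-inverse covariance convention
(variance ∝ 1/λ over non-zero modes), and ensembles are generated by
displacing along a mode to an exact target RMSD (default 25 Å).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import BeadModel

__all__ = ["ModeSet", "build_gnm", "build_anm", "variance_fractions", "generate_ensemble"]

ZERO_MODE_RTOL = 1e-8  # relative to the largest eigenvalue


@dataclass
class ModeSet:
    kind: str                 # "GNM" | "ANM"
    cutoff: float             # Å
    gamma: float
    eigenvalues: np.ndarray   # ascending
    eigenvectors: np.ndarray  # columns, orthonormal; N-dim (GNM) or 3N-dim (ANM)
    n_zero: int
    n_components: int = 1

    @property
    def nonzero_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.n_zero:]

    def mode(self, i: int) -> np.ndarray:
        """i-th non-rigid mode (0 = lowest non-zero frequency)."""
        return self.eigenvectors[:, self.n_zero + i]


def _contact_pairs(coords: np.ndarray, cutoff: float) -> np.ndarray:
    tree = cKDTree(coords)
    return tree.query_pairs(cutoff, output_type="ndarray")


def _n_components(n: int, pairs: np.ndarray) -> int:
    # union-find over the contact graph
    parent = np.arange(n)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    return len({find(i) for i in range(n)})


def build_gnm(model: BeadModel, cutoff: float = 10.0, gamma: float = 1.0) -> ModeSet:
    """Gaussian network model: eigendecomposition of the Kirchhoff matrix.

    Γij = −γ for contacts within the cutoff, diagonal minus the row sum;
    a connected contact graph leaves exactly one zero mode.
    """
    n = len(model)
    if n < 2:
        raise ValueError("GNM needs at least 2 beads")
    pairs = _contact_pairs(model.coords, cutoff)
    K = np.zeros((n, n))
    if len(pairs):
        K[pairs[:, 0], pairs[:, 1]] = -gamma
        K[pairs[:, 1], pairs[:, 0]] = -gamma
    np.fill_diagonal(K, -K.sum(axis=1))
    ncomp = _n_components(n, pairs)
    if ncomp > 1:
        warnings.warn(f"contact graph has {ncomp} connected components")
    evals, evecs = np.linalg.eigh(K)
    n_zero = int(np.sum(evals < ZERO_MODE_RTOL * max(evals.max(), 1.0)))
    return ModeSet(kind="GNM", cutoff=cutoff, gamma=gamma, eigenvalues=evals,
                   eigenvectors=evecs, n_zero=n_zero, n_components=ncomp)


def build_anm(model: BeadModel, cutoff: float = 15.0, gamma: float = 1.0) -> ModeSet:
    """Anisotropic network model: eigendecomposition of the 3N × 3N Hessian.

    Off-diagonal super-elements Hij = −γ·(rij rijᵀ)/|rij|² for contacts,
    diagonal super-elements minus the super-row sum; a connected,
    non-collinear structure leaves exactly the 6 rigid-body zero modes.
    """
    n = len(model)
    if n < 2:
        raise ValueError("ANM needs at least 2 beads")
    coords = model.coords
    pairs = _contact_pairs(coords, cutoff)
    H = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        r = coords[j] - coords[i]
        d2 = float(r @ r)
        if d2 == 0.0:
            continue
        block = -gamma * np.outer(r, r) / d2
        H[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        H[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
        H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        H[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    ncomp = _n_components(n, pairs)
    if ncomp > 1:
        warnings.warn(f"contact graph has {ncomp} connected components")
    evals, evecs = np.linalg.eigh(H)
    n_zero = int(np.sum(evals < ZERO_MODE_RTOL * max(evals.max(), 1.0)))
    if n_zero > 6 and ncomp == 1:
        warnings.warn(f"{n_zero} zero modes (collinear or degenerate geometry?)")
    return ModeSet(kind="ANM", cutoff=cutoff, gamma=gamma, eigenvalues=evals,
                   eigenvectors=evecs, n_zero=n_zero, n_components=ncomp)


def variance_fractions(modes: ModeSet, k: int) -> float:
    """Fraction of total fluctuation variance in the k lowest non-zero modes.

    Mode variance is proportional to 1/λ (pseudo-inverse covariance), so the
    fraction is Σ_{i≤k} λi⁻¹ / Σ_all λj⁻¹ over the non-zero spectrum.
    """
    lam = modes.nonzero_eigenvalues
    if k == 0:
        return 0.0
    if k > len(lam):
        raise ValueError(f"k={k} exceeds the {len(lam)} non-zero modes")
    inv = 1.0 / lam
    return float(inv[:k].sum() / inv.sum())


def generate_ensemble(model: BeadModel, modes: ModeSet, mode_index: int = 0,
                      target_rmsd: float = 25.0):
    """Displace the structure ± along one ANM mode to an exact target RMSD.

    x± = x ± α·v with α = target_rmsd·√N for the unit-norm 3N mode vector,
    so RMSD(x±, x) without re-superposition equals target_rmsd exactly.
    Returns ``(plus, minus)`` BeadModels.
    """
    if modes.kind != "ANM":
        raise ValueError("ensemble generation needs ANM (Cartesian) modes")
    if mode_index < 0 or mode_index >= len(modes.nonzero_eigenvalues):
        raise ValueError("mode_index must address a non-zero mode")
    n = len(model)
    v = modes.mode(mode_index)
    v = v / np.linalg.norm(v)
    disp = (target_rmsd * np.sqrt(n)) * v.reshape(n, 3)
    plus = BeadModel(coords=model.coords + disp, masses=model.masses.copy(), labels=list(model.labels))
    minus = BeadModel(coords=model.coords - disp, masses=model.masses.copy(), labels=list(model.labels))
    return plus, minus
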