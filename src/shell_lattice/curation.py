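"""Geometric particle curation and lattice-order diagnostics.

Implements the two cleaning rules used after oversampled subtomogram
alignment — score-ranked duplicate removal at a centre-to-centre cutoff
(default 90 Å, i.e. 9 nm) and a neighbour-count filter (keep particles with
at least 3 neighbours at 100–130 Å) — plus neighbour plots and lattice
parameter estimation from the particle geometry alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.spatial import cKDTree

from .io_formats import ParticleTable

__all__ = [
    "CurationParams",
    "LatticeEstimate",
    "remove_duplicates",
    "neighbor_count_filter",
    "neighbor_plot",
    "estimate_lattice",
]


@dataclass
class CurationParams:
    dup_min_dist: float = 90.0       # Å, centre-to-centre duplicate cutoff
    neighbor_rmin: float = 100.0     # Å
    neighbor_rmax: float = 130.0     # Å
    neighbor_min_count: int = 3

    def __post_init__(self):
        if self.dup_min_dist <= 0:
            raise ValueError("dup_min_dist must be positive")
        if not self.neighbor_rmin < self.neighbor_rmax:
            raise ValueError("neighbor_rmin must be below neighbor_rmax")
        if self.neighbor_min_count < 0:
            raise ValueError("neighbor_min_count must be non-negative")


def remove_duplicates(table: ParticleTable, params: CurationParams = CurationParams()) -> ParticleTable:
    """Greedy duplicate removal in descending score order.

    A particle is accepted iff no already-accepted particle lies within
    ``dup_min_dist``; of any close pair the higher-scoring member therefore
    survives.  Ties in score break deterministically on particle id.
    """
    n = len(table)
    if n == 0:
        return table.copy()
    scores = table.scores
    if scores is None:
        warnings.warn("no scores present; treating all scores as 0")
        scores = np.zeros(n)
    order = np.lexsort((table.ids, -scores))  # descending score, ascending id
    accepted_mask = np.zeros(n, dtype=bool)
    accepted_list: list[int] = []
    for idx in order:
        ok = True
        for j in accepted_list:
            if np.linalg.norm(table.positions[idx] - table.positions[j]) < params.dup_min_dist:
                ok = False
                break
        if ok:
            accepted_list.append(idx)
            accepted_mask[idx] = True
    keep = np.flatnonzero(accepted_mask)
    return table.select(keep)


def neighbor_count_filter(table: ParticleTable, params: CurationParams = CurationParams()) -> ParticleTable:
    """Single-pass removal of particles with too few neighbours.

    Neighbour counts are computed once on the input set (not iterated to a
    fixed point): a particle survives iff at least ``neighbor_min_count``
    others lie at centre distance within [rmin, rmax].
    """
    n = len(table)
    if n == 0:
        return table.copy()
    tree = cKDTree(table.positions)
    counts = np.zeros(n, dtype=int)
    pairs = tree.query_pairs(params.neighbor_rmax, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(table.positions[pairs[:, 0]] - table.positions[pairs[:, 1]], axis=1)
        good = d >= params.neighbor_rmin
        np.add.at(counts, pairs[good, 0], 1)
        np.add.at(counts, pairs[good, 1], 1)
    return table.select(counts >= params.neighbor_min_count)


def neighbor_plot(table: ParticleTable, rmax: float = 200.0, bin_size: float = 10.0):
    """3-D histogram of neighbour offsets in each particle's local frame.

    For every particle, offset vectors to all neighbours within ``rmax`` are
    rotated into its own frame (R.T @ Δp) and accumulated on a regular grid
    spanning [-rmax, rmax]³.  Returns ``(counts, edges)`` where ``edges`` is
    the common bin-edge array applied to each axis.
    """
    nbins = max(1, int(np.ceil(2 * rmax / bin_size)))
    edges = np.linspace(-rmax, rmax, nbins + 1)
    counts = np.zeros((nbins, nbins, nbins))
    n = len(table)
    if n == 0:
        return counts, edges
    tree = cKDTree(table.positions)
    pairs = tree.query_pairs(rmax, output_type="ndarray")
    if len(pairs) == 0:
        return counts, edges
    R = table.rotation_matrices()
    offsets = []
    for i, j in ((0, 1), (1, 0)):
        dp = table.positions[pairs[:, j]] - table.positions[pairs[:, i]]
        local = np.einsum("nij,ni->nj", R[pairs[:, i]], dp)  # R.T @ dp
        offsets.append(local)
    local = np.vstack(offsets)
    h, _ = np.histogramdd(local, bins=(edges, edges, edges))
    return h, edges


@dataclass
class LatticeEstimate:
    a: float                     # Å, first lattice constant (a ≤ b)
    b: float                     # Å
    gamma: float                 # degrees
    group_call: str              # p4 | p2 | disordered
    spacing_histogram: tuple     # (counts, bin_edges) of pair distances


def estimate_lattice(table: ParticleTable, rmax: float = 250.0,
                     bin_size: float = 4.0) -> LatticeEstimate:
    """Estimate lattice constants and wallpaper-group class from positions.

    The first-shell peak of the pair-distance histogram gives ``a``; the
    second basis vector comes from the distance and in-plane angle structure
    of the next shell.  Classification: p4 if |a−b|/a < 0.1 and |γ−90°| < 8°,
    p2 if an ordered second shell exists but fails those bounds, disordered
    if no first-shell peak rises 3-fold above background.
    """
    n = len(table)
    if n < 20:
        raise ValueError(f"need at least 20 particles, got {n}")
    tree = cKDTree(table.positions)
    pairs = tree.query_pairs(rmax, output_type="ndarray")
    d = np.linalg.norm(table.positions[pairs[:, 0]] - table.positions[pairs[:, 1]], axis=1)
    edges = np.arange(0.0, rmax + bin_size, bin_size)
    hist, _ = np.histogram(d, bins=edges)
    smooth = uniform_filter1d(hist.astype(float), size=3)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # shell-area correction: raw counts grow ~ r², compare densities instead
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(centers >= bin_size, smooth / centers ** 2, 0.0)
    # background over everything past the excluded-volume hole, zeros included
    first_nonzero = int(np.argmax(density > 0)) if np.any(density > 0) else len(density)
    background = float(np.median(density[first_nonzero:])) if first_nonzero < len(density) else 0.0

    # a real shell concentrates a visible fraction of all pairs in a few bins
    peaks = _local_maxima(density, smooth, min_count=max(4.0, 0.02 * len(d)))
    hist_tuple = (hist, edges)
    ordered = bool(peaks) and (background == 0.0 or max(density[p] for p in peaks) > 3.0 * background)
    if not ordered:
        a0 = centers[peaks[0]] if peaks else float("nan")
        return LatticeEstimate(a=a0, b=a0, gamma=90.0, group_call="disordered",
                               spacing_histogram=hist_tuple)

    # first shell: earliest peak carrying at least half the strongest density
    dmax = max(density[p] for p in peaks)
    a_bin = next(p for p in peaks if density[p] >= 0.5 * dmax)
    a = _refine_peak(d, centers[a_bin], bin_size * 3.5)

    # Second shell: next peak beyond the first
    b_cand = None
    for p in peaks:
        if centers[p] > a * 1.1 and density[p] >= 0.25 * dmax:
            b_cand = _refine_peak(d, centers[p], bin_size * 3.5)
            break

    gamma = _modal_neighbor_angle(table, tree, a, a)
    if b_cand is None:
        # single shell: square or near-square lattice
        b, gcall = a, "p4" if abs(gamma - 90.0) < 8.0 else "p2"
        return LatticeEstimate(a=a, b=b, gamma=gamma, group_call=gcall,
                               spacing_histogram=hist_tuple)

    if abs(b_cand - np.sqrt(2.0) * a) / (np.sqrt(2.0) * a) < 0.05 and abs(gamma - 90.0) < 8.0:
        # second peak is the diagonal shell of a square lattice
        return LatticeEstimate(a=a, b=a, gamma=gamma, group_call="p4",
                               spacing_histogram=hist_tuple)

    gamma_ab = _modal_neighbor_angle(table, tree, a, b_cand)
    gcall = "p4" if (abs(b_cand - a) / a < 0.1 and abs(gamma_ab - 90.0) < 8.0) else "p2"
    return LatticeEstimate(a=min(a, b_cand), b=max(a, b_cand), gamma=gamma_ab,
                           group_call=gcall, spacing_histogram=hist_tuple)


def _local_maxima(density, smooth, min_count: float = 4.0):
    idx = []
    for i in range(1, len(density) - 1):
        if density[i] >= density[i - 1] and density[i] > density[i + 1] and smooth[i] >= min_count:
            idx.append(i)
    # merge plateaus / adjacent bins: keep first of any run
    merged = []
    for i in idx:
        if not merged or i - merged[-1] > 1:
            merged.append(i)
    return merged


def _refine_peak(distances, center, halfwidth, iters: int = 4):
    """Mean-shift refinement: the windowed mean of a symmetric shell
    converges to its centre even when the initial bin is offset by the
    1/r² density tilt."""
    c = float(center)
    for _ in range(iters):
        sel = np.abs(distances - c) <= halfwidth
        if not np.any(sel):
            return c
        c = float(np.mean(distances[sel]))
    return c


def _modal_neighbor_angle(table, tree, r1, r2, tol_frac: float = 0.12):
    """Modal acute angle between shell-r1 and shell-r2 neighbour vectors."""
    angles = []
    pos = table.positions
    for i in range(len(pos)):
        nb = tree.query_ball_point(pos[i], max(r1, r2) * (1 + tol_frac))
        vecs = [pos[j] - pos[i] for j in nb if j != i]
        if len(vecs) < 2:
            continue
        v1 = [v for v in vecs if abs(np.linalg.norm(v) - r1) <= tol_frac * r1]
        v2 = [v for v in vecs if abs(np.linalg.norm(v) - r2) <= tol_frac * r2]
        for p in v1:
            for q in v2:
                c = float(p @ q / (np.linalg.norm(p) * np.linalg.norm(q)))
                if c > 0.999:  # same vector
                    continue
                ang = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
                ang = min(ang, 180.0 - ang)
                if ang > 5.0:
                    angles.append(ang)
    if not angles:
        return 90.0
    hist, edges = np.histogram(angles, bins=np.arange(0.0, 95.0, 5.0))
    k = int(np.argmax(hist))
    sel = [x for x in angles if edges[k] <= x < edges[k + 1] + 5.0]
    return float(np.mean(sel)) if sel else 90.0
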