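"""Curvature, bend angles and compartment morphometrics.

Principal curvatures are estimated per mesh vertex by local quadric fitting
in the normal frame.  Curvature converts to an inter-unit bend angle through

    θ = 2·arctan(s / (2 r)),    r = 1/κ,

where ``s`` (default 57.5 Å) is the side length of the polygon circumscribed
by the curved surface — half the 11.5 nm lattice repeat, so θ is the hinge
angle between adjacent half-unit facets.  Positive κ and θ mean convex
toward the outside (cytosol).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .io_formats import ParticleTable

__all__ = [
    "CurvatureField",
    "CompartmentStats",
    "principal_curvatures",
    "curvature_to_angle",
    "neighbor_bend_angles",
    "sphere_morphometrics",
    "usb_report",
    "diameter_from_profile",
]

DEFAULT_POLYGON_SIDE = 57.5  # Å; half of the 115 Å tetramer repeat


@dataclass
class CurvatureField:
    """Per-vertex principal curvatures (κ₁ ≥ κ₂, Å⁻¹) and bend angles (deg).

    ``valid`` marks vertices with enough neighbours for a stable fit;
    curvatures at invalid vertices are NaN, never fabricated.
    """

    kappa1: np.ndarray
    kappa2: np.ndarray
    theta1: np.ndarray
    theta2: np.ndarray
    valid: np.ndarray
    polygon_side: float = DEFAULT_POLYGON_SIDE


def principal_curvatures(mesh: trimesh.Trimesh, radius_hint: float | None = None,
                         polygon_side: float = DEFAULT_POLYGON_SIDE) -> CurvatureField:
    """Per-vertex principal curvature by quadric fitting in the normal frame.

    Neighbours within ``radius_hint`` (default 3× the mean edge length) are
    projected into the tangent frame of the outward vertex normal and a
    quadric h = ax² + bxy + cy² (+ linear terms, absorbed as tilt) is fitted
    by least squares; κ₁ ≥ κ₂ are the eigenvalues of [[2a, b], [b, 2c]],
    signed positive-convex-outward.  Vertices with fewer than 6 usable
    neighbours are marked invalid.
    """
    edge_mean = float(mesh.edges_unique_length.mean())
    if radius_hint is None:
        radius_hint = 3.0 * edge_mean
    if radius_hint < 2.0 * edge_mean:
        raise ValueError("radius_hint must be at least twice the mean edge length")

    verts = mesh.vertices.view(np.ndarray)
    normals = mesh.vertex_normals.view(np.ndarray)
    tree = cKDTree(verts)
    n = len(verts)
    kappa1 = np.full(n, np.nan)
    kappa2 = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)

    neighbor_lists = tree.query_ball_point(verts, radius_hint)
    for i in range(n):
        nb = [j for j in neighbor_lists[i] if j != i]
        if len(nb) < 6:
            continue
        nrm = normals[i]
        nrm = nrm / np.linalg.norm(nrm)
        from .geometry import orthonormal_tangent_basis

        u, v = orthonormal_tangent_basis(nrm)
        rel = verts[nb] - verts[i]
        x = rel @ u
        y = rel @ v
        h = rel @ nrm
        # design: [x², xy, y², x, y]; linear terms absorb normal-estimate tilt
        A = np.column_stack([x * x, x * y, y * y, x, y])
        coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        a, b, c = coef[:3]
        # Height h is measured along the outward normal: a cap bulging toward
        # +n has negative second-order coefficients, so flip the sign to make
        # convex-outward positive.
        W = -np.array([[2 * a, b], [b, 2 * c]])
        ev = np.linalg.eigvalsh(W)
        kappa1[i], kappa2[i] = ev[1], ev[0]
        valid[i] = True

    return CurvatureField(
        kappa1=kappa1,
        kappa2=kappa2,
        theta1=curvature_to_angle(kappa1, polygon_side),
        theta2=curvature_to_angle(kappa2, polygon_side),
        valid=valid,
        polygon_side=polygon_side,
    )


def curvature_to_angle(kappa, s: float = DEFAULT_POLYGON_SIDE):
    """Signed bend angle θ = 2·arctan(s·κ/2) in degrees (r = 1/κ).

    Odd and strictly increasing in κ; θ→±180° as κ→±∞; θ(0) = 0.
    """
    if s <= 0:
        raise ValueError("polygon side s must be positive")
    kappa = np.asarray(kappa, dtype=float)
    theta = np.degrees(2.0 * np.arctan(s * kappa / 2.0))
    return theta if theta.ndim else float(theta)


def neighbor_bend_angles(table: ParticleTable, rmin: float = 100.0, rmax: float = 130.0):
    """Signed bend angle for every neighbour pair at distance in [rmin, rmax].

    Unsigned angle = arccos(n_i · n_j) between the particles' +Z axes; the
    sign is that of (p_j − p_i)·(n_j − n_i): positive when the normals
    diverge (convex toward the outside), negative when they converge
    (concave).  Returns ``(pairs, angles_deg)``.
    """
    tree = cKDTree(table.positions)
    pairs = tree.query_pairs(rmax, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(-1, 2), np.empty(0)
    d = np.linalg.norm(table.positions[pairs[:, 0]] - table.positions[pairs[:, 1]], axis=1)
    sel = d >= rmin
    pairs = pairs[sel]
    nrm = table.z_axes()
    ni, nj = nrm[pairs[:, 0]], nrm[pairs[:, 1]]
    dots = np.clip((ni * nj).sum(axis=1), -1.0, 1.0)
    unsigned = np.degrees(np.arccos(dots))
    dp = table.positions[pairs[:, 1]] - table.positions[pairs[:, 0]]
    sign = np.sign((dp * (nj - ni)).sum(axis=1))
    sign[sign == 0] = 1.0
    return pairs, unsigned * sign


@dataclass
class CompartmentStats:
    diameter_nm: float
    volume_um3: float


def sphere_morphometrics(diameter_nm: float) -> CompartmentStats:
    """Internal volume of a spherical compartment from its diameter.

    volume = (π/6)·d³, reported in μm³ to 3 significant figures.
    """
    if diameter_nm <= 0:
        raise ValueError("diameter must be positive")
    volume_nm3 = (np.pi / 6.0) * diameter_nm ** 3
    volume_um3 = volume_nm3 * 1e-9
    return CompartmentStats(diameter_nm=float(diameter_nm),
                            volume_um3=_round_sig(volume_um3, 3))


def usb_report(diameters_by_group: dict[str, float],
               genome_sizes_kb: dict[str, float] | None = None) -> dict:
    """Batch compartment morphometrics with pairwise volume (and genome) ratios.

    Ratios are taken between the 3-significant-figure volumes, largest first,
    and printed at 2 decimal places — matching how such numbers are reported.
    """
    out = {"groups": {}, "ratios": {}}
    for name, d in diameters_by_group.items():
        stats = sphere_morphometrics(d)
        out["groups"][name] = {"diameter_nm": stats.diameter_nm, "volume_um3": stats.volume_um3}
    names = list(diameters_by_group)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            va, vb = out["groups"][a]["volume_um3"], out["groups"][b]["volume_um3"]
            hi, lo = (a, b) if va >= vb else (b, a)
            ratio = out["groups"][hi]["volume_um3"] / out["groups"][lo]["volume_um3"]
            out["ratios"][f"volume_{hi}_over_{lo}"] = round(ratio, 2)
            if genome_sizes_kb and a in genome_sizes_kb and b in genome_sizes_kb:
                g = genome_sizes_kb[hi] / genome_sizes_kb[lo]
                out["ratios"][f"genome_{hi}_over_{lo}"] = round(g, 2)
    return out


def diameter_from_profile(profile: np.ndarray, pixel_size: float) -> float:
    """Apparent diameter from a 1-D line intensity profile, in nm.

    The level halfway between the background plateau (bright, profile ends)
    and the interior plateau (dark minimum) is crossed on the way in and on
    the way out; the distance between the outermost crossings, linearly
    interpolated, is the diameter.  ``pixel_size`` is nm per sample.
    """
    profile = np.asarray(profile, dtype=float)
    if len(profile) < 5:
        raise ValueError("profile too short")
    k = max(2, len(profile) // 10)
    background = 0.5 * (np.median(profile[:k]) + np.median(profile[-k:]))
    interior = float(profile.min())
    level = 0.5 * (background + interior)
    below = profile < level
    if not below.any() or background <= interior:
        raise ValueError("profile has no interior dip; cannot measure a diameter")
    first = int(np.argmax(below))
    last = len(profile) - 1 - int(np.argmax(below[::-1]))
    if first == 0 or last == len(profile) - 1:
        raise ValueError("interior dip touches the profile ends; profile too short")

    def interp_cross(i0, i1):
        y0, y1 = profile[i0], profile[i1]
        if y1 == y0:
            return float(i1)
        return i0 + (level - y0) / (y1 - y0) * (i1 - i0)

    x_in = interp_cross(first - 1, first)
    x_out = interp_cross(last + 1, last)
    return abs(x_out - x_in) * pixel_size


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))
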