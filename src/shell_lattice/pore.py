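"""Channel radius profiles, restrictive diameters and pore volumes.

At each station z along a chosen axis the free radius is the clearance of
the largest probe sphere centred in the station plane:

    R(z) = max_u min_i ( |x_i − u| − r_i ),

with u fixed to the axis point (``relax=False``) or locally maximized from
the axis seed by deterministic in-plane coordinate ascent (``relax=True``).
Negative clearances clamp to zero ("closed").  The restrictive diameter is
twice the minimal bounded R(z) and the pore volume is the solid of
revolution π∫R²dz, both reported in nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import BeadModel

__all__ = ["PoreProfile", "pore_profile", "restrictive_diameter", "pore_volume", "profile_series"]


@dataclass
class PoreProfile:
    z: np.ndarray                  # station grid, Å
    radius: np.ndarray             # free radius per station, Å (NaN = unbounded)
    bounded: np.ndarray            # station had beads within the slab
    axis_point: np.ndarray
    axis_dir: np.ndarray

    @property
    def restrictive_diameter_nm(self) -> float:
        return restrictive_diameter(self)

    def volume_nm3(self) -> float:
        return pore_volume(self)


def pore_profile(model: BeadModel, axis_point=(0.0, 0.0, 0.0), axis_dir=(0.0, 0.0, 1.0),
                 zrange=(-50.0, 50.0), dz: float = 1.0, relax: bool = False,
                 radii: np.ndarray | None = None, slab_halfwidth: float = 15.0) -> PoreProfile:
    """Free-radius profile of a channel along an axis.

    ``radii`` overrides per-bead radii (defaults to ``model.radii`` or 1.7 Å,
    a carbon-like van der Waals radius).  Stations with no bead within
    ``slab_halfwidth`` along the axis are marked unbounded (NaN radius) and
    excluded from the restrictive diameter.
    """
    radii = _resolve_radii(model, radii)
    p0 = np.asarray(axis_point, dtype=float)
    d = np.asarray(axis_dir, dtype=float)
    d = d / np.linalg.norm(d)
    lo, hi = zrange
    if hi <= lo:
        raise ValueError("zrange must be increasing")
    n_st = int(round((hi - lo) / dz)) + 1
    zs = lo + np.arange(n_st) * dz

    coords = model.coords
    axial = (coords - p0) @ d
    # in-plane basis for relaxation
    from .geometry import orthonormal_tangent_basis

    u_hat, v_hat = orthonormal_tangent_basis(d)

    radius = np.full(n_st, np.nan)
    bounded = np.zeros(n_st, dtype=bool)
    for k, z in enumerate(zs):
        in_slab = np.abs(axial - z) <= slab_halfwidth
        if not np.any(in_slab):
            continue
        bounded[k] = True
        center = p0 + z * d
        if relax:
            center = _ascend_inplane(center, u_hat, v_hat, coords, radii)
        clearance = np.linalg.norm(coords - center, axis=1) - radii
        radius[k] = max(0.0, float(clearance.min()))
    return PoreProfile(z=zs, radius=radius, bounded=bounded, axis_point=p0, axis_dir=d)


def _resolve_radii(model: BeadModel, radii) -> np.ndarray:
    if radii is not None:
        radii = np.asarray(radii, dtype=float)
        if radii.ndim == 0:
            radii = np.full(len(model), float(radii))
    elif model.radii is not None:
        radii = model.radii
    else:
        radii = np.full(len(model), 1.7)
    if np.any(radii <= 0):
        raise ValueError("bead radii must be positive")
    return radii


def _ascend_inplane(center, u_hat, v_hat, coords, radii,
                    step0: float = 2.0, min_step: float = 1e-3) -> np.ndarray:
    """Deterministic in-plane coordinate ascent of the clearance objective.

    From the axis seed, try ± steps along the two in-plane directions and
    keep any improvement; halve the step when no direction improves, down
    to ``min_step`` Å.
    """

    def clearance(c):
        return float((np.linalg.norm(coords - c, axis=1) - radii).min())

    best = clearance(center)
    step = step0
    while step >= min_step:
        improved = False
        for direction in (u_hat, -u_hat, v_hat, -v_hat):
            cand = center + step * direction
            val = clearance(cand)
            if val > best + 1e-12:
                center, best = cand, val
                improved = True
        if not improved:
            step *= 0.5
    return center


def restrictive_diameter(profile: PoreProfile) -> float:
    """2 × min bounded free radius, in nm (0 means closed)."""
    if not profile.bounded.any():
        raise ValueError("all stations unbounded; no channel detected")
    rmin = np.nanmin(profile.radius[profile.bounded])
    return float(2.0 * rmin / 10.0)


def pore_volume(profile: PoreProfile, zrange=None) -> float:
    """Solid-of-revolution volume π∫R²dz by the trapezoid rule, in nm³."""
    z, r, b = profile.z, profile.radius, profile.bounded
    if zrange is not None:
        sel = (z >= zrange[0]) & (z <= zrange[1])
        z, r, b = z[sel], r[sel], b[sel]
    if len(z) < 2:
        raise ValueError("need at least two stations for a volume")
    if not b.all():
        raise ValueError("unbounded stations inside the integration range")
    vol_a3 = np.pi * np.trapezoid(r ** 2, z)
    return float(vol_a3 / 1000.0)  # Å³ -> nm³


def profile_series(models, axis_point=(0, 0, 0), axis_dir=(0, 0, 1),
                   zrange=(-50.0, 50.0), dz: float = 1.0, relax: bool = False,
                   radii=None, exclude_frames=()):
    """Per-frame profiles plus mean ± s.d. summaries across frames.

    All frames must share bead identity (equal bead counts).  Frames listed
    in ``exclude_frames`` are dropped from the statistics and the reported n
    shrinks accordingly.  Returns ``(profiles, summary_dict)``; standard
    deviations are population (ddof=0).
    """
    models = list(models)
    if not models:
        raise ValueError("no frames")
    n0 = len(models[0])
    for f, m in enumerate(models):
        if len(m) != n0:
            raise ValueError(f"frame {f} has {len(m)} beads, expected {n0}")
    keep = [f for f in range(len(models)) if f not in set(exclude_frames)]
    profiles = [pore_profile(models[f], axis_point, axis_dir, zrange, dz, relax, radii)
                for f in keep]
    diams = np.array([restrictive_diameter(p) for p in profiles])
    vols = np.array([pore_volume(p) for p in profiles])
    summary = {
        "n_frames": len(keep),
        "restrictive_diameter_nm_mean": float(diams.mean()),
        "restrictive_diameter_nm_sd": float(diams.std()),
        "volume_nm3_mean": float(vols.mean()),
        "volume_nm3_sd": float(vols.std()),
    }
    return profiles, summary
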