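"""Rotation conventions, point groups and mesh geometry helpers.

Orientations throughout the package are ZYZ intrinsic Euler triples
``(rot, tilt, psi)`` in degrees.  The associated matrix

    R = Rz(rot) @ Ry(tilt) @ Rz(psi)

maps coordinates expressed in the particle frame into the tomogram frame;
the particle's +Z axis in tomogram coordinates is therefore ``R[:, 2]``.
``tilt`` is kept in [0, 180] and at the gimbal-locked poles
(tilt = 0 or 180) ``rot`` is canonically zero.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation


def euler_to_matrix(euler_deg: np.ndarray) -> np.ndarray:
    """(…, 3) ZYZ intrinsic (rot, tilt, psi) degrees -> (…, 3, 3) matrices."""
    e = np.asarray(euler_deg, dtype=float)
    return Rotation.from_euler("ZYZ", e.reshape(-1, 3), degrees=True).as_matrix().reshape(e.shape[:-1] + (3, 3))


def matrix_to_euler(matrices: np.ndarray) -> np.ndarray:
    """(…, 3, 3) -> ZYZ intrinsic (rot, tilt, psi), tilt in [0, 180].

    At gimbal lock (tilt = 0 or 180) the convention rot := 0 is applied and
    the remaining in-plane angle is carried entirely by psi.
    """
    m = np.asarray(matrices, dtype=float)
    flat = m.reshape(-1, 3, 3)
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        eul = Rotation.from_matrix(flat).as_euler("ZYZ", degrees=True)
    # scipy returns tilt in [0, 180] for proper ZYZ; at gimbal lock it zeroes
    # the *third* angle.  Re-canonicalize: rot := 0, fold everything into psi.
    locked = np.abs(np.abs(flat[:, 2, 2]) - 1.0) < 1e-12
    if np.any(locked):
        sub = flat[locked]
        # tilt = 0: R = Rz(rot+psi) -> psi = ang.
        # tilt = 180: R = Rz(rot-psi)·Ry(180) = [[-cos δ, -sin δ, 0],
        # [-sin δ, cos δ, 0], [0, 0, -1]] with δ = rot - psi, so
        # atan2(m10, m00) = δ - 180 and psi := -δ = 180 - ang.
        ang = np.degrees(np.arctan2(sub[:, 1, 0], sub[:, 0, 0]))
        tilt = np.where(sub[:, 2, 2] > 0, 0.0, 180.0)
        psi = np.where(sub[:, 2, 2] > 0, ang, 180.0 - ang)
        eul[locked, 0] = 0.0
        eul[locked, 1] = tilt
        eul[locked, 2] = psi
    eul[:, 0] = wrap_angle(eul[:, 0])
    eul[:, 2] = wrap_angle(eul[:, 2])
    return eul.reshape(m.shape[:-2] + (3,))


def wrap_angle(deg):
    """Wrap angles into (-180, 180]."""
    a = -np.mod(-np.asarray(deg, dtype=float) + 180.0, 360.0) + 180.0
    return a


def rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_axis(axis, deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.radians(deg) * axis).as_matrix()


# ---------------------------------------------------------------------------
# Rotational point groups

def group_c4() -> np.ndarray:
    """The 4 rotations of C4 about +z."""
    return np.stack([rot_z(90.0 * k) for k in range(4)])


def group_c1() -> np.ndarray:
    return np.eye(3)[None]


def group_d4() -> np.ndarray:
    """The 8 rotations of D4: C4 about +z plus four 2-fold axes in the xy plane."""
    ops = [rot_z(90.0 * k) for k in range(4)]
    for ax in ([1, 0, 0], [0, 1, 0], [1, 1, 0], [1, -1, 0]):
        ops.append(rot_axis(ax, 180.0))
    return np.stack(ops)


def group_o() -> np.ndarray:
    """The 24 rotations of the octahedral group O (rotation group of the cube).

    Generated by closure from the 4-fold z rotation and a 3-fold rotation
    about the body diagonal, then verified to have order 24.
    """
    gens = [rot_z(90.0), rot_axis([1.0, 1.0, 1.0], 120.0)]
    ops = [np.eye(3)]

    def contains(mats, m):
        return any(np.allclose(m, x, atol=1e-10) for x in mats)

    changed = True
    while changed:
        changed = False
        for a, b in itertools.product(list(ops), gens):
            m = a @ b
            if not contains(ops, m):
                ops.append(m)
                changed = True
    assert len(ops) == 24, f"octahedral closure gave {len(ops)} elements"
    return np.stack(ops)


def right_coset_representatives(group: np.ndarray, subgroup: np.ndarray) -> np.ndarray:
    """One representative per right coset ``subgroup @ g`` of subgroup in group.

    Representatives are ordered deterministically (first occurrence in the
    group's own enumeration order).
    """
    reps: list[np.ndarray] = []
    for g in group:
        in_existing = False
        for r in reps:
            # same coset iff g r^-1 ∈ subgroup
            d = g @ r.T
            if any(np.allclose(d, s, atol=1e-9) for s in subgroup):
                in_existing = True
                break
        if not in_existing:
            reps.append(g)
    n_expected = len(group) // len(subgroup)
    assert len(reps) == n_expected, (len(reps), n_expected)
    return np.stack(reps)


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform (Haar) random rotation matrices from a seeded generator."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return Rotation.from_quat(q).as_matrix()


# ---------------------------------------------------------------------------
# Point-to-mesh projection (no rtree dependency)

class MeshProjector:
    """Project query points onto a triangle mesh.

    Candidate faces are found with a KD-tree on face centroids; the exact
    closest point on each candidate triangle is then computed and the best
    kept.  ``k`` nearest centroids are examined, which is exact as long as
    the true nearest triangle is among them; ``k`` defaults generously
    relative to typical mesh regularity.
    """

    def __init__(self, mesh, k: int = 16):
        self.mesh = mesh
        self.tri = mesh.triangles  # (F, 3, 3)
        self.centroids = self.tri.mean(axis=1)
        self.k = min(k, len(self.tri))
        self._tree = cKDTree(self.centroids)
        # max face circumradius bounds how far the true face centroid can be
        self._r_max = np.sqrt(((self.tri - self.centroids[:, None, :]) ** 2).sum(-1)).max()

    def project(self, points: np.ndarray):
        """Return (closest_points, distances, face_indices) for (N, 3) input."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        _, idx = self._tree.query(points, k=self.k)
        idx = np.atleast_2d(idx)
        cand = self.tri[idx]  # (N, k, 3, 3)
        closest = _closest_point_on_triangles(points[:, None, :], cand)
        d2 = ((closest - points[:, None, :]) ** 2).sum(-1)
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(points))
        return closest[rows, best], np.sqrt(d2[rows, best]), idx[rows, best]

    def face_normals(self, face_indices):
        return self.mesh.face_normals[np.asarray(face_indices)]


def _closest_point_on_triangles(p, tri):
    """Closest point on triangles for broadcastable p (…, 3), tri (…, 3, 3).

    Standard barycentric region-walk (Ericson, Real-Time Collision
    Detection), vectorized.
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = (ab * ap).sum(-1)
    d2 = (ac * ap).sum(-1)
    bp = p - b
    d3 = (ab * bp).sum(-1)
    d4 = (ac * bp).sum(-1)
    cp = p - c
    d5 = (ab * cp).sum(-1)
    d6 = (ac * cp).sum(-1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    result = a + v[..., None] * ab + w[..., None] * ac  # interior case

    # edge/vertex regions overwrite the interior guess
    # vertex A
    mask = (d1 <= 0) & (d2 <= 0)
    result = np.where(mask[..., None], a, result)
    # vertex B
    m = (d3 >= 0) & (d4 <= d3)
    result = np.where(m[..., None] & ~mask[..., None], b, result)
    mask |= m
    # vertex C
    m = (d6 >= 0) & (d5 <= d6)
    result = np.where(m[..., None] & ~mask[..., None], c, result)
    mask |= m
    # edge AB
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where((d1 - d3) != 0, d1 / (d1 - d3), 0.0)
    result = np.where(m[..., None] & ~mask[..., None], a + t[..., None] * ab, result)
    mask |= m
    # edge AC
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where((d2 - d6) != 0, d2 / (d2 - d6), 0.0)
    result = np.where(m[..., None] & ~mask[..., None], a + t[..., None] * ac, result)
    mask |= m
    # edge BC
    m = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(((d4 - d3) + (d5 - d6)) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    result = np.where(m[..., None] & ~mask[..., None], b + t[..., None] * (c - b), result)
    return result


def orthonormal_tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic tangent basis (u, v) with u × v = n for a unit normal."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(helper, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v
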