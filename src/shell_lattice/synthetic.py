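"""Synthetic inputs with known ground truth.

Everything downstream — seeding, curation, curvature, elastic networks, pore
profiling — is exercised on surfaces, particle tables, bead models, channels
and line profiles produced here, so every generator is a pure function of its
spec plus an integer seed (bit-identical reruns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import (
    MeshProjector,
    euler_to_matrix,
    matrix_to_euler,
    orthonormal_tangent_basis,
    rot_axis,
)
from .io_formats import BeadModel, ParticleTable

__all__ = [
    "SurfaceSpec",
    "CorruptionSpec",
    "make_surface",
    "decorate_lattice",
    "corrupt_particles",
    "make_channel",
    "make_sheet_beads",
    "make_line_profile",
]


@dataclass
class SurfaceSpec:
    """Parameters of a synthetic annotated surface.

    kind : plane | sphere | ellipsoid | perturbed_sphere | box
    size : Å — plane/box edge lengths (1–3 values) or sphere radius or
        ellipsoid semi-axes.
    resolution : target mesh edge length, Å.
    """

    kind: str
    size: tuple
    resolution: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if np.isscalar(self.size):
            self.size = (float(self.size),)
        self.size = tuple(float(s) for s in self.size)
        if any(s <= 0 for s in self.size):
            raise ValueError("size parameters must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        # perturbed_sphere carries (radius, bump amplitude): only the radius
        # is an object dimension
        dims = self.size[:1] if self.kind == "perturbed_sphere" else self.size
        if self.resolution > min(dims):
            raise ValueError("mesh resolution is coarser than the object size")


@dataclass
class CorruptionSpec:
    """Noise/corruption applied to a ground-truth particle table."""

    jitter_sigma_pos: float = 0.0   # Å
    jitter_sigma_ang: float = 0.0   # degrees
    false_positive_rate: float = 0.0
    false_negative_rate: float = 0.0
    flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.false_positive_rate, self.false_negative_rate, self.flip_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.jitter_sigma_pos < 0 or self.jitter_sigma_ang < 0:
            raise ValueError("jitter sigmas must be non-negative")


# ---------------------------------------------------------------------------
# Surfaces

def _icosphere_for_resolution(radius: float, resolution: float) -> trimesh.Trimesh:
    # icosahedron edge ≈ 1.051 R; each subdivision halves edge length
    subdivisions = int(np.clip(np.ceil(np.log2(1.051 * radius / resolution)), 1, 7))
    return trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)


def make_surface(spec: SurfaceSpec) -> trimesh.Trimesh:
    """Build a triangle mesh: closed for sphere/ellipsoid/perturbed_sphere/box,
    an open patch for plane.  Winding is consistent with outward normals."""
    kind = spec.kind
    if kind == "plane":
        w = spec.size[0]
        h = spec.size[1] if len(spec.size) > 1 else spec.size[0]
        return _plane_mesh(w, h, spec.resolution)
    if kind == "sphere":
        return _icosphere_for_resolution(spec.size[0], spec.resolution)
    if kind == "ellipsoid":
        a, b, c = (spec.size + spec.size[-1:] * 2)[:3]
        mesh = _icosphere_for_resolution(max(a, b, c), spec.resolution)
        r = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
        mesh.vertices = r * np.array([a, b, c])
        return mesh
    if kind == "perturbed_sphere":
        radius = spec.size[0]
        amp = spec.size[1] if len(spec.size) > 1 else 0.05 * radius
        mesh = _icosphere_for_resolution(radius, spec.resolution)
        rng = np.random.default_rng(spec.seed)
        # smooth deterministic bump field: a few random plane-wave modes
        k = rng.normal(size=(4, 3)) * (2.0 / radius)
        phase = rng.uniform(0, 2 * np.pi, size=4)
        weight = rng.uniform(0.5, 1.0, size=4)
        v = mesh.vertices
        bump = sum(w * np.sin(v @ ki + p) for ki, p, w in zip(k, phase, weight)) / np.sum(weight)
        radial = v / np.linalg.norm(v, axis=1, keepdims=True)
        mesh.vertices = v + radial * (amp * bump)[:, None]
        return mesh
    if kind == "box":
        ext = (spec.size + spec.size[-1:] * 2)[:3]
        mesh = trimesh.creation.box(extents=ext)
        while mesh.edges_unique_length.max() > spec.resolution and len(mesh.faces) < 2 ** 17:
            mesh = mesh.subdivide()
        return mesh
    raise ValueError(f"unknown surface kind {kind!r}")


def _plane_mesh(w: float, h: float, resolution: float) -> trimesh.Trimesh:
    nx = max(1, int(np.ceil(w / resolution)))
    ny = max(1, int(np.ceil(h / resolution)))
    xs = np.linspace(0.0, w, nx + 1)
    ys = np.linspace(0.0, h, ny + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    faces = []
    for i in range(nx):
        for j in range(ny):
            v00 = i * (ny + 1) + j
            v01 = v00 + 1
            v10 = v00 + (ny + 1)
            v11 = v10 + 1
            # CCW seen from +z (outward normal +z)
            faces.append([v00, v10, v11])
            faces.append([v00, v11, v01])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


# ---------------------------------------------------------------------------
# Lattice decoration

@dataclass
class DecoratedLattice:
    """decorate_lattice output: the particle table plus ground truth."""

    table: ParticleTable
    neighbor_edges: np.ndarray      # (E, 2) int, realized lattice adjacency
    frames: np.ndarray              # (N, 3, 3) particle frames [u v n]


def decorate_lattice(mesh: trimesh.Trimesh, group: str = "p4", a: float = 115.0,
                     b: float | None = None, gamma: float = 90.0,
                     min_dist_frac: float = 0.8) -> DecoratedLattice:
    """Wrap a 2-D Bravais lattice over a surface by tangent-plane stepping.

    On a plane the result is an exact lattice; on curved surfaces each step
    moves ``a`` (or ``b``) along the local tangent directions and re-projects
    onto the mesh, producing the quasi-lattice that variable curvature
    allows.  Particles are oriented with +Z along the outward normal and +X
    along the local first lattice vector.  The realized neighbour graph is
    returned as ground truth.
    """
    if group == "p4":
        b = a if b is None else b
        gamma = 90.0
    elif group == "p2":
        if b is None:
            raise ValueError("p2 lattice needs both a and b")
    else:
        raise ValueError(f"unknown wallpaper group {group!r}")
    if a <= 0 or b <= 0:
        raise ValueError("lattice constants must be positive")
    if not 0.0 < gamma < 180.0:
        raise ValueError("gamma must lie in (0, 180) degrees")
    extent = float(np.linalg.norm(mesh.bounds[1] - mesh.bounds[0]))
    if max(a, b) > extent:
        raise ValueError("lattice constant larger than the surface")

    proj = MeshProjector(mesh)
    min_ab = min(a, b)
    # a candidate closer than this to an existing particle is the same node;
    # on curved surfaces a generous radius keeps seam collisions from
    # packing spurious half-spacing particles into the quasi-lattice
    accept_dist = min_dist_frac * min_ab
    max_residual = 0.3 * min_ab

    center = mesh.bounds.mean(axis=0)
    p0, _, f0 = proj.project(center[None])
    p0 = p0[0]
    n0 = proj.face_normals([f0[0]])[0]
    u0, v0 = orthonormal_tangent_basis(n0)

    cell = min_ab
    grid: dict[tuple, list[int]] = {}

    def grid_key(p):
        return tuple(np.floor(p / cell).astype(int))

    def near_indices(p):
        kx, ky, kz = grid_key(p)
        out = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    out.extend(grid.get((kx + dx, ky + dy, kz + dz), ()))
        return out

    positions = [p0]
    frames = [np.column_stack([u0, v0, n0])]
    grid[grid_key(p0)] = [0]
    edges: set[tuple[int, int]] = set()

    cg, sg = np.cos(np.radians(gamma)), np.sin(np.radians(gamma))
    queue = [0]
    head = 0
    while head < len(queue):
        i = queue[head]
        head += 1
        p = positions[i]
        u, v, n = frames[i].T
        e1 = a * u
        e2 = b * (cg * u + sg * v)
        for step in (e1, -e1, e2, -e2):
            q = p + step
            qp, dist, fi = proj.project(q[None])
            qp, fi = qp[0], fi[0]
            if dist > max_residual:
                continue
            nearby = near_indices(qp)
            hit = None
            for j in nearby:
                if np.linalg.norm(positions[j] - qp) < accept_dist:
                    hit = j
                    break
            if hit is not None:
                if hit != i:
                    edges.add((min(i, hit), max(i, hit)))
                continue
            # accept a new particle; parallel-transport the frame
            n_new = proj.face_normals([fi])[0]
            axis = np.cross(n, n_new)
            norm = np.linalg.norm(axis)
            if norm > 1e-12:
                ang = np.degrees(np.arctan2(norm, float(n @ n_new)))
                u_new = rot_axis(axis, ang) @ u
            else:
                u_new = u.copy()
            u_new = u_new - (u_new @ n_new) * n_new
            u_new /= np.linalg.norm(u_new)
            v_new = np.cross(n_new, u_new)
            j = len(positions)
            positions.append(qp)
            frames.append(np.column_stack([u_new, v_new, n_new]))
            grid.setdefault(grid_key(qp), []).append(j)
            edges.add((min(i, j), max(i, j)))
            queue.append(j)

    positions = np.array(positions)
    frames_arr = np.array(frames)
    eulers = matrix_to_euler(frames_arr)
    table = ParticleTable(
        ids=np.arange(len(positions)),
        tomo_id=np.array(["synthetic"] * len(positions), dtype=object),
        positions=positions,
        eulers=eulers,
        scores=np.ones(len(positions)),
    )
    edge_arr = np.array(sorted(edges), dtype=int).reshape(-1, 2)
    return DecoratedLattice(table=table, neighbor_edges=edge_arr, frames=frames_arr)


# ---------------------------------------------------------------------------
# Corruption

def corrupt_particles(table: ParticleTable, spec: CorruptionSpec,
                      mesh: trimesh.Trimesh | None = None) -> ParticleTable:
    """Jitter, delete, flip and contaminate a particle table, reproducibly.

    False positives are placed near the surface the true particles decorate:
    each one is anchored at a randomly chosen input particle, offset uniformly
    in its tangent plane by up to two lattice-ish spacings (and re-projected
    onto ``mesh`` when given).  Their scores are uniform on [0, 0.9] —
    spurious picks cross-correlate worse than real subunits, which is the
    premise of score-ranked duplicate removal.
    """
    if spec == CorruptionSpec(seed=spec.seed):
        return table.copy()
    rng = np.random.default_rng(spec.seed)
    n = len(table)

    keep = rng.random(n) >= spec.false_negative_rate
    out = table.select(keep)
    m = len(out)

    R = out.rotation_matrices()
    if spec.jitter_sigma_pos > 0:
        out.positions = out.positions + rng.normal(0.0, spec.jitter_sigma_pos, (m, 3))
    if spec.jitter_sigma_ang > 0:
        axes = rng.normal(size=(m, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        angles = np.abs(rng.normal(0.0, spec.jitter_sigma_ang, m))
        from scipy.spatial.transform import Rotation

        pert = Rotation.from_rotvec(np.radians(angles)[:, None] * axes).as_matrix()
        R = pert @ R
    if spec.flip_rate > 0:
        flip = rng.random(m) < spec.flip_rate
        rx180 = rot_axis([1.0, 0.0, 0.0], 180.0)
        R[flip] = R[flip] @ rx180
    out.eulers = matrix_to_euler(R)

    n_fp = int(rng.binomial(n, spec.false_positive_rate)) if spec.false_positive_rate > 0 else 0
    if n_fp > 0 and m > 0:
        anchors = rng.integers(0, m, n_fp)
        Ranch = euler_to_matrix(out.eulers[anchors])
        offsets_2d = rng.uniform(-230.0, 230.0, (n_fp, 2))
        normal_off = rng.normal(0.0, 5.0, n_fp)
        pos = (out.positions[anchors]
               + Ranch[:, :, 0] * offsets_2d[:, 0:1]
               + Ranch[:, :, 1] * offsets_2d[:, 1:2]
               + Ranch[:, :, 2] * normal_off[:, None])
        if mesh is not None:
            proj = MeshProjector(mesh)
            pos, _, _ = proj.project(pos)
        from .geometry import random_rotations

        fp_eul = matrix_to_euler(random_rotations(n_fp, rng))
        fp_scores = rng.uniform(0.0, 0.9, n_fp)
        next_id = (int(table.ids.max()) + 1) if n else 0
        out = ParticleTable(
            ids=np.concatenate([out.ids, next_id + np.arange(n_fp)]),
            tomo_id=np.concatenate([out.tomo_id, np.array(["synthetic_fp"] * n_fp, dtype=object)]),
            positions=np.vstack([out.positions, pos]),
            eulers=np.vstack([out.eulers, fp_eul]),
            scores=None if out.scores is None else np.concatenate([out.scores, fp_scores]),
            group_label=out.group_label,
        )
    return out


# ---------------------------------------------------------------------------
# Channels, sheets, line profiles

@dataclass
class ChannelFixture:
    """Bead-lined z-axis channel with its analytic free-radius profile."""

    model: BeadModel
    ring_z: np.ndarray          # z of each ring plane, Å
    analytic_radius: object     # callable z (Å) -> free radius (Å)


def make_channel(kind: str, ring_radius: float, atom_radius: float, length: float,
                 waist: float | None = None, ring_spacing: float = 2.0,
                 beads_per_ring: int = 24) -> ChannelFixture:
    """Rings of beads lining a channel along z with a known radius profile.

    cylinder: R(z) = ring_radius − atom_radius.
    hourglass: ring radius tapers linearly from ring_radius at the ends to
    ``waist`` at z = 0, so R(z) = ρ(z) − atom_radius.
    """
    if ring_radius <= atom_radius:
        raise ValueError("ring_radius must exceed atom_radius")
    if kind == "hourglass":
        if waist is None:
            raise ValueError("hourglass channel needs a waist radius")
        if waist <= atom_radius:
            raise ValueError("waist must exceed atom_radius")
    elif kind != "cylinder":
        raise ValueError(f"unknown channel kind {kind!r}")

    n_rings = int(round(length / ring_spacing)) + 1
    zs = np.linspace(-length / 2.0, length / 2.0, n_rings)
    if kind == "cylinder":
        rho = np.full(n_rings, ring_radius)

        def analytic(z):
            return np.full_like(np.asarray(z, dtype=float), ring_radius - atom_radius)
    else:
        slope = (ring_radius - waist) / (length / 2.0)

        def rho_of(z):
            return waist + slope * np.abs(z)

        rho = rho_of(zs)

        def analytic(z):
            return rho_of(np.asarray(z, dtype=float)) - atom_radius

    theta = np.linspace(0.0, 2 * np.pi, beads_per_ring, endpoint=False)
    coords = np.concatenate([
        np.column_stack([r * np.cos(theta), r * np.sin(theta), np.full(beads_per_ring, z)])
        for r, z in zip(rho, zs)
    ])
    model = BeadModel(
        coords=coords,
        masses=np.full(len(coords), 12.011),
        labels=[("X", i, "BEAD") for i in range(len(coords))],
        radii=np.full(len(coords), atom_radius),
    )
    return ChannelFixture(model=model, ring_z=zs, analytic_radius=analytic)


def make_sheet_beads(n: int, m: int, a: float = 115.0, beads_per_unit: int = 100,
                     thickness: float = 60.0, seed: int = 0) -> BeadModel:
    """n × m blocks of beads on a plane with block spacing ``a``.

    Each block is a regular bead grid filling 0.9a × 0.9a × thickness with a
    small seeded jitter (5% of the grid pitch), recentred so every block's
    centroid sits exactly on its lattice node.  The regular fill gives each
    unit a quasi-rigid elastic core with softer coupling across block
    boundaries — an elastic-network stand-in for a sheet of tetramer units.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be ≥ 1")
    rng = np.random.default_rng(seed)
    # near-cubic grid with at least beads_per_unit sites; keep the first
    # beads_per_unit in deterministic raster order
    span = np.array([0.9 * a, 0.9 * a, thickness])
    nz = max(1, int(round((beads_per_unit * (span[2] / span[0]) ** 2) ** (1.0 / 3.0))))
    nxy = int(np.ceil(np.sqrt(beads_per_unit / nz)))
    while nxy * nxy * nz < beads_per_unit:
        nxy += 1
    gx = np.linspace(-0.5, 0.5, nxy) * span[0]
    gz = (np.linspace(-0.5, 0.5, nz) if nz > 1 else np.array([0.0])) * span[2]
    site = np.array([[x, y, z] for z in gz for x in gx for y in gx])[:beads_per_unit]
    pitch = span[0] / max(nxy - 1, 1)
    coords, labels = [], []
    for i in range(n):
        for j in range(m):
            center = np.array([i * a, j * a, 0.0])
            pts = site + rng.normal(0.0, 0.05 * pitch, site.shape)
            pts = pts - pts.mean(axis=0) + center
            coords.append(pts)
            labels.extend([(f"B{i}{j}", k, "BEAD") for k in range(beads_per_unit)])
    coords = np.concatenate(coords)
    return BeadModel(coords=coords, masses=np.full(len(coords), 110.0), labels=labels)


def make_line_profile(diameter: float, edge_width: float = 0.0, noise_sigma: float = 0.0,
                      seed: int = 0, length: float | None = None,
                      pixel_size: float = 2.0) -> np.ndarray:
    """1-D intensity line profile across a dark spherical compartment.

    Bright background at 1, dark interior at 0, edges are error-function
    ramps of width ``edge_width`` (nm) centred on the true boundary, plus
    additive Gaussian noise.  ``pixel_size`` is in nm per sample.  Returns
    the intensity array; positions are ``np.arange(n) * pixel_size``.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if length is None:
        length = 2.5 * diameter
    if length < diameter:
        raise ValueError("profile length must be at least the diameter")
    from scipy.special import erf

    x = np.arange(0.0, length + pixel_size / 2, pixel_size)
    c = length / 2.0
    left, right = c - diameter / 2.0, c + diameter / 2.0
    if edge_width > 0:
        s = edge_width / 2.0
        interior = 0.5 * (erf((x - left) / (np.sqrt(2) * s)) - erf((x - right) / (np.sqrt(2) * s)))
    else:
        interior = ((x >= left) & (x <= right)).astype(float)
    profile = 1.0 - interior
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        profile = profile + rng.normal(0.0, noise_sigma, profile.shape)
    return profile
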