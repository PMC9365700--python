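"""Ideal assemblies of the 11.5 nm tetramer unit and symmetry bookkeeping.

The square tetramer unit (side 115 Å, thickness 60 Å, four 69.5 kDa
protomers, internal C4) tiles a p442 sheet, closes into the minimal
O-symmetric cube of six units (24 protomers, 1.67 MDa) and into the
D4-symmetric prism of ten units (40 protomers, 2.78 MDa).  The module also
performs cube→sheet unfolding with hinge accounting, linker-span
measurement from anchor points, and point-group symmetry expansion of
particle tables with exact coset counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    euler_to_matrix,
    group_c1,
    group_c4,
    group_d4,
    group_o,
    matrix_to_euler,
    right_coset_representatives,
    rot_axis,
    rot_z,
)
from .io_formats import ParticleTable

__all__ = [
    "TetramerUnit",
    "SegmentMap",
    "AssemblyModel",
    "build_sheet",
    "build_cube",
    "build_prism",
    "unfold_cube_to_sheet",
    "linker_spans",
    "symmetry_expand",
    "assembly_to_particle_table",
    "point_group_check",
]


@dataclass
class TetramerUnit:
    """The square C4 tetramer building block."""

    side: float = 115.0            # Å
    thickness: float = 60.0        # Å
    protomer_mass_kda: float = 69.5

    def __post_init__(self):
        if self.side <= 0 or self.thickness <= 0:
            raise ValueError("side and thickness must be positive")

    @property
    def tetramer_mass_kda(self) -> float:
        return 4.0 * self.protomer_mass_kda

    def default_anchors(self) -> dict:
        """Synthetic segment-terminus anchors, per protomer (0–3).

        Protomer 0 occupies the +x+y quadrant of the unit; protomer k is
        rotated by k·90° about the unit +z.  Coordinates are in the unit
        frame, Å.  The anchors are plausible stand-ins for the termini of
        the ordered segments flanking the two disordered linkers: the end of
        the C-terminal domain (residue 581), the span of CTS1 (590–611) and
        the start of CTS2 (622).
        """
        s = self.side
        base = {
            "CTD_end": np.array([0.32 * s, 0.32 * s, 0.10 * self.thickness]),
            "CTS1_start": np.array([0.42 * s, 0.40 * s, 0.05 * self.thickness]),
            "CTS1_end": np.array([0.47 * s, 0.47 * s, 0.0]),
            "CTS2_start": np.array([0.45 * s, 0.52 * s, -0.08 * self.thickness]),
        }
        anchors = {}
        for k in range(4):
            R = rot_z(90.0 * k)
            anchors[k] = {name: R @ xyz for name, xyz in base.items()}
        return anchors


@dataclass
class SegmentMap:
    """Residue ranges of the flexible segments and their linkers."""

    nts: tuple = (48, 61)
    cts1: tuple = (590, 611)
    cts2: tuple = (622, 631)
    linker1: tuple = (582, 589)    # C-terminal domain → CTS1
    linker2: tuple = (612, 621)    # CTS1 → CTS2

    def __post_init__(self):
        ranges = [self.nts, self.linker1, self.cts1, self.linker2, self.cts2]
        for lo, hi in ranges:
            if lo > hi:
                raise ValueError("segment ranges must be ascending")
        for (a, b), (c, d) in zip(ranges, ranges[1:]):
            if b >= c:
                raise ValueError("segment ranges must not overlap")

    def linker_residues(self, which: int) -> int:
        lo, hi = self.linker1 if which == 1 else self.linker2
        return hi - lo + 1

    def max_extension(self, which: int, per_residue: float = 3.5) -> float:
        """Maximal contour extension of a linker in Å (3.5 Å per residue)."""
        return per_residue * self.linker_residues(which)


@dataclass
class AssemblyModel:
    """Rigid placements of a tetramer unit."""

    unit: TetramerUnit
    rotations: np.ndarray       # (N, 3, 3), unit frame → assembly frame
    translations: np.ndarray    # (N, 3), Å
    topology: str               # sheet(n,m) | cube | prism | custom
    symmetry: str               # p442 | O | D4 | none
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.rotations = np.asarray(self.rotations, dtype=float).reshape(-1, 3, 3)
        self.translations = np.asarray(self.translations, dtype=float).reshape(-1, 3)
        if len(self.rotations) != len(self.translations):
            raise ValueError("rotations/translations length mismatch")
        for i in range(len(self.translations)):
            for j in range(i + 1, len(self.translations)):
                if (np.allclose(self.rotations[i], self.rotations[j])
                        and np.allclose(self.translations[i], self.translations[j])):
                    raise ValueError("duplicate placements")

    def __len__(self):
        return len(self.rotations)

    @property
    def n_protomers(self) -> int:
        return 4 * len(self)

    @property
    def mass_kda(self) -> float:
        return self.n_protomers * self.unit.protomer_mass_kda

    @property
    def mass_mda(self) -> float:
        return self.mass_kda / 1000.0

    def envelope(self) -> np.ndarray:
        """Axis-aligned bounding extents (Å) of the tile footprints."""
        s, t = self.unit.side / 2.0, self.unit.thickness / 2.0
        corners = np.array([[sx, sy, sz] for sx in (-s, s) for sy in (-s, s) for sz in (-t, t)])
        world = np.einsum("nij,kj->nki", self.rotations, corners) + self.translations[:, None, :]
        pts = world.reshape(-1, 3)
        return pts.max(axis=0) - pts.min(axis=0)


def assembly_to_particle_table(model: AssemblyModel) -> ParticleTable:
    """Placements as a particle table (+Z of each particle = tile outward normal)."""
    eulers = matrix_to_euler(model.rotations)
    n = len(model)
    return ParticleTable(
        ids=np.arange(n),
        tomo_id=np.array([model.topology] * n, dtype=object),
        positions=model.translations.copy(),
        eulers=eulers,
        scores=np.ones(n),
        group_label=model.symmetry,
    )


# ---------------------------------------------------------------------------
# Builders

def build_sheet(unit: TetramerUnit = TetramerUnit(), n: int = 3, m: int = 3) -> AssemblyModel:
    """n × m flat sheet with tile spacing = side; p442 wallpaper symmetry.

    Four-fold axes pierce tile centres and tile corners, two-fold axes the
    edge midpoints; all placements share the sheet normal +z.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be ≥ 1")
    rot = np.tile(np.eye(3), (n * m, 1, 1))
    trans = np.array([[i * unit.side, j * unit.side, 0.0] for i in range(n) for j in range(m)])
    trans = trans - trans.mean(axis=0)
    labels = [f"tile_{i}_{j}" for i in range(n) for j in range(m)]
    return AssemblyModel(unit=unit, rotations=rot, translations=trans,
                         topology=f"sheet({n},{m})", symmetry="p442", labels=labels)


_CUBE_FACES = {
    "+z": (np.eye(3), np.array([0.0, 0.0, 1.0])),
    "-z": (rot_axis([1, 0, 0], 180.0), np.array([0.0, 0.0, -1.0])),
    "+x": (rot_axis([0, 1, 0], 90.0), np.array([1.0, 0.0, 0.0])),
    "-x": (rot_axis([0, 1, 0], -90.0), np.array([-1.0, 0.0, 0.0])),
    "+y": (rot_axis([1, 0, 0], -90.0), np.array([0.0, 1.0, 0.0])),
    "-y": (rot_axis([1, 0, 0], 90.0), np.array([0.0, -1.0, 0.0])),
}


def build_cube(unit: TetramerUnit = TetramerUnit()) -> AssemblyModel:
    """Six tiles on the faces of a cube of edge = tile side, +Z outward.

    24 protomers; at the default protomer mass the assembly is 1.67 MDa.
    The placement set is invariant under the 24 rotations of O (modulo the
    tile's internal C4), which `point_group_check` verifies exactly.
    """
    half = unit.side / 2.0
    rots, trans, labels = [], [], []
    for name, (R, axis) in _CUBE_FACES.items():
        rots.append(R)
        trans.append(axis * half)
        labels.append(name)
    return AssemblyModel(unit=unit, rotations=np.array(rots), translations=np.array(trans),
                         topology="cube", symmetry="O", labels=labels)


def build_prism(unit: TetramerUnit = TetramerUnit()) -> AssemblyModel:
    """Ten-tile D4 prism: two square caps and two rings of four side tiles.

    40 protomers (2.78 MDa at defaults); the tile footprints span an
    envelope of 220 × 220 × 335 Å at the default unit dimensions.
    """
    s, t = unit.side, unit.thickness
    cap_z = 335.0 / 2.0 - t / 2.0          # cap outer surface at ±167.5 Å
    ring_r = 220.0 / 2.0 - t / 2.0         # side outer surface at ±110 Å
    ring_z = s / 2.0
    rots, trans, labels = [], [], []
    rots.append(np.eye(3)); trans.append([0.0, 0.0, cap_z]); labels.append("cap_top")
    rots.append(rot_axis([1, 0, 0], 180.0)); trans.append([0.0, 0.0, -cap_z]); labels.append("cap_bottom")
    Ry90 = rot_axis([0, 1, 0], 90.0)
    for k in range(4):
        Rz = rot_z(90.0 * k)
        for zsign, tag in ((1.0, "up"), (-1.0, "lo")):
            rots.append(Rz @ Ry90)
            trans.append(Rz @ np.array([ring_r, 0.0, zsign * ring_z]))
            labels.append(f"side_{k * 90}_{tag}")
    return AssemblyModel(unit=unit, rotations=np.array(rots), translations=np.array(trans),
                         topology="prism", symmetry="D4", labels=labels)


# ---------------------------------------------------------------------------
# Symmetry checking

_GROUPS = {"C1": group_c1, "C4": group_c4, "D4": group_d4, "O": group_o}


def point_group_check(model: AssemblyModel, group: str, tol: float = 1e-8) -> bool:
    """True iff every group rotation permutes the placements.

    A rotation g maps placement (R_i, t_i) onto (g·R_i, g·t_i); the image
    must coincide with some placement (R_j, t_j) up to the tile's internal
    C4 (g·R_i = R_j·c).
    """
    ops = _GROUPS[group]()
    c4 = group_c4()
    R, T = model.rotations, model.translations
    for g in ops:
        for i in range(len(model)):
            ti = g @ T[i]
            Ri = g @ R[i]
            matched = False
            for j in range(len(model)):
                if np.linalg.norm(ti - T[j]) > 1e-6:
                    continue
                for c in c4:
                    if np.abs(Ri - R[j] @ c).max() < 1e-6:
                        matched = True
                        break
                if matched:
                    break
            if not matched:
                return False
    return True


def wallpaper_p442_check(model: AssemblyModel, tol: float = 1e-6) -> bool:
    """Partial p442 check on a finite sheet.

    Verifies 4-fold axes at tile centres and at interior tile corners and
    2-fold axes at interior edge midpoints: any image placement that lands
    inside the finite tiling must coincide with an existing placement
    (modulo internal C4).  Boundary images that leave the sheet are ignored.
    """
    c4 = group_c4()
    R, T = model.rotations, model.translations
    s = model.unit.side
    centers = [t for t in T]
    corners = set()
    for t in T:
        for dx in (-s / 2, s / 2):
            for dy in (-s / 2, s / 2):
                corners.add((round(t[0] + dx, 6), round(t[1] + dy, 6), round(t[2], 6)))
    axes = [(np.array(c), 90.0) for c in corners] + [(t, 90.0) for t in centers]
    edges = set()
    for t in T:
        for off in ((s / 2, 0), (-s / 2, 0), (0, s / 2), (0, -s / 2)):
            edges.add((round(t[0] + off[0], 6), round(t[1] + off[1], 6), round(t[2], 6)))
    axes += [(np.array(e), 180.0) for e in edges]

    any_checked = False
    for center, angle in axes:
        g = rot_z(angle)
        for i in range(len(model)):
            ti = g @ (T[i] - center) + center
            Ri = g @ R[i]
            # inside the tiling?
            dists = np.linalg.norm(T - ti, axis=1)
            j = int(np.argmin(dists))
            if dists[j] > 1e-6:
                continue  # image left the finite sheet
            any_checked = True
            ok = any(np.abs(Ri - R[j] @ c).max() < tol for c in c4)
            if not ok:
                return False
    return any_checked


# ---------------------------------------------------------------------------
# Unfolding

_NET_TREE = [  # (child face, parent face); the cross-shaped net
    ("+x", "+z"), ("-x", "+z"), ("+y", "+z"), ("-y", "+z"), ("-z", "+x"),
]


def unfold_cube_to_sheet(cube: AssemblyModel):
    """Unfold the six cube faces into a planar cross-shaped net.

    The +z face stays fixed; the four side faces hinge 90° outward about
    their shared top edges and the -z face rides on +x with a second 90°
    hinge (180° total travel).  Returns ``(sheet_model, report)`` where the
    report lists per-hinge rotations and the rotation implied for the CTS1
    segment by mapping each cube corner's three-fold axis onto the sheet
    corner's four-fold axis: arccos(1/√3) ≈ 54.7°, the geometric origin of
    the ≈55° segment rotation.
    """
    if cube.topology != "cube":
        raise ValueError("input must be a cube assembly")
    by_label = {lab: i for i, lab in enumerate(cube.labels)}
    if set(by_label) != set(_CUBE_FACES):
        raise ValueError("cube labels do not match canonical faces")

    unfolds = _unfold_transforms(cube.unit)
    world: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for face in _CUBE_FACES:
        Rg, tg = unfolds[face]
        world[face] = (Rg @ cube.rotations[by_label[face]],
                       Rg @ cube.translations[by_label[face]] + tg)

    order = list(_CUBE_FACES)
    rots = np.array([world[f][0] for f in order])
    trans = np.array([world[f][1] for f in order])
    sheet = AssemblyModel(unit=cube.unit, rotations=rots, translations=trans,
                          topology="custom", symmetry="none", labels=[f"net_{f}" for f in order])

    # CTS1 rotation implied by mapping a cube-corner 3-fold axis to the
    # sheet-corner 4-fold axis (the sheet normal)
    three_fold = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
    four_fold = np.array([0.0, 0.0, 1.0])
    cts1_rot = float(np.degrees(np.arccos(np.clip(three_fold @ four_fold, -1, 1))))

    report = {
        "n_tiles": len(order),
        "n_hinges": len(_NET_TREE),
        "hinge_rotation_deg": {child: 90.0 for child, _ in _NET_TREE},
        "net_bend_angles_deg": [0.0] * len(_NET_TREE),
        "cts1_rotation_deg": cts1_rot,
        "hinge_tree": list(_NET_TREE),
    }
    return sheet, report


def _unfold_transforms(unit: TetramerUnit) -> dict:
    """Affine unfold transform (R, t): x_sheet = R @ x_cube + t, per face.

    Each child face folds 90° about the edge it shares with its parent in
    the net tree; a child's hinge is applied first in the static cube frame
    and then carried along by its ancestors' unfolds.
    """
    half = unit.side / 2.0
    hinges = {
        "+x": (np.array([half, 0.0, half]), np.array([0.0, 1.0, 0.0]), -90.0),
        "-x": (np.array([-half, 0.0, half]), np.array([0.0, 1.0, 0.0]), 90.0),
        "+y": (np.array([0.0, half, half]), np.array([1.0, 0.0, 0.0]), 90.0),
        "-y": (np.array([0.0, -half, half]), np.array([1.0, 0.0, 0.0]), -90.0),
        "-z": (np.array([half, 0.0, -half]), np.array([0.0, 1.0, 0.0]), -90.0),
    }
    chains: dict[str, list] = {f: [] for f in _CUBE_FACES}
    for child, parent in _NET_TREE:
        chains[child] = chains[parent] + [child]
    out = {}
    for face in _CUBE_FACES:
        R = np.eye(3)
        t = np.zeros(3)
        # root-to-leaf order; compose so the child's own (deepest) hinge acts
        # first in the static cube frame: T_total = G(anc1) ∘ … ∘ G(own)
        for hinge_face in chains[face]:
            point, axis, angle = hinges[hinge_face]
            g = rot_axis(axis, angle)
            # current accumulated transform acts after this hinge?  No —
            # hinges closer to the root act later, so prepend:
            R_h, t_h = g, point - g @ point
            R, t = R @ R_h, R @ t_h + t
        out[face] = (R, t)
    return out


def refold_sheet_to_cube(sheet: AssemblyModel, unit: TetramerUnit | None = None) -> AssemblyModel:
    """Invert :func:`unfold_cube_to_sheet` by applying the inverse per-face
    unfold transforms to the net placements."""
    unit = unit or sheet.unit
    unfolds = _unfold_transforms(unit)
    labels = [lab.removeprefix("net_") for lab in sheet.labels]
    if set(labels) != set(_CUBE_FACES):
        raise ValueError("input is not the canonical cross net")
    rots, trans = [], []
    for lab, R, t in zip(labels, sheet.rotations, sheet.translations):
        Rg, tg = unfolds[lab]
        rots.append(Rg.T @ R)
        trans.append(Rg.T @ (t - tg))
    return AssemblyModel(unit=unit, rotations=np.array(rots), translations=np.array(trans),
                         topology="cube", symmetry="O",
                         labels=labels)


# ---------------------------------------------------------------------------
# Linker spans

def linker_spans(model: AssemblyModel, segments: SegmentMap = SegmentMap(),
                 anchors: dict | None = None) -> pd.DataFrame:
    """Euclidean span of each disordered linker, per placement and protomer.

    ``anchors`` maps protomer index -> {name -> xyz in the unit frame}; the
    builder's synthetic defaults are used when omitted.  Linker 1 runs from
    the end of the C-terminal domain (CTD_end) to the start of CTS1;
    linker 2 from the end of CTS1 to the start of CTS2.  Missing anchors
    yield NaN spans for that protomer.
    """
    anchors = anchors if anchors is not None else model.unit.default_anchors()
    rows = []
    for p in range(len(model)):
        R, t = model.rotations[p], model.translations[p]
        for k in range(4):
            a = anchors.get(k, {})
            row = {"placement": p, "protomer": k}
            for which, (start, end) in (("linker1", ("CTD_end", "CTS1_start")),
                                        ("linker2", ("CTS1_end", "CTS2_start"))):
                if start in a and end in a:
                    p1 = R @ a[start] + t
                    p2 = R @ a[end] + t
                    row[f"{which}_span_A"] = float(np.linalg.norm(p2 - p1))
                else:
                    row[f"{which}_span_A"] = float("nan")
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["linker1_max_extension_A"] = segments.max_extension(1)
    df.attrs["linker2_max_extension_A"] = segments.max_extension(2)
    return df


# ---------------------------------------------------------------------------
# Symmetry expansion

def symmetry_expand(table: ParticleTable, from_group: str, to_group: str,
                    dedup_tol_deg: float = 1e-4) -> ParticleTable:
    """Replicate each record once per right coset of ``to_group`` in
    ``from_group``, composing orientations with the coset representatives.

    |O|/|C4| = 6, |C4|/|C1| = 4.  A replicate whose (tilt, psi) pair matches
    an earlier replicate of the same particle within ``dedup_tol_deg`` is
    redundant (it differs only by an in-plane symmetry rotation) and is
    removed; for generic orientations nothing is removed and the output has
    exactly input × coset-count records.
    """
    if from_group not in _GROUPS or to_group not in _GROUPS:
        raise ValueError(f"unknown point group in {from_group}->{to_group}")
    G = _GROUPS[from_group]()
    H = _GROUPS[to_group]()
    if len(H) >= len(G) or len(G) % len(H):
        raise ValueError(f"{to_group} is not a proper subgroup of {from_group}")
    # subgroup containment check
    for h in H:
        if not any(np.allclose(h, g, atol=1e-9) for g in G):
            raise ValueError(f"{to_group} is not a subgroup of {from_group}")
    reps = right_coset_representatives(G, H)
    k = len(reps)
    n = len(table)
    R = table.rotation_matrices()                    # (n, 3, 3)
    expanded = np.einsum("nij,kjl->nkil", R, reps)   # R @ g_k, particle frame
    eulers = matrix_to_euler(expanded.reshape(-1, 3, 3)).reshape(n, k, 3)

    keep = np.ones((n, k), dtype=bool)
    for a in range(1, k):
        for b in range(a):
            clash = (np.abs(eulers[:, a, 1] - eulers[:, b, 1]) < dedup_tol_deg) & \
                    (np.abs(_angdiff(eulers[:, a, 2], eulers[:, b, 2])) < dedup_tol_deg) & \
                    keep[:, b]
            keep[:, a] &= ~clash

    flat_keep = keep.ravel()
    src = np.repeat(np.arange(n), k)[flat_keep]
    out_eulers = eulers.reshape(-1, 3)[flat_keep]
    out_pos = np.repeat(table.positions, k, axis=0)[flat_keep]
    out_tomo = np.repeat(table.tomo_id, k)[flat_keep]
    out_scores = None if table.scores is None else np.repeat(table.scores, k)[flat_keep]
    extras = pd.DataFrame({"_slSourceId": table.ids[src]})
    return ParticleTable(
        ids=np.arange(len(out_pos)),
        tomo_id=out_tomo,
        positions=out_pos,
        eulers=out_eulers,
        scores=out_scores,
        group_label=to_group,
        extras=extras,
    )


def _angdiff(a, b):
    return (np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0
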