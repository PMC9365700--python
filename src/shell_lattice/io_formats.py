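"""Domain containers and file I/O: STAR particle tables, PDB/mmCIF structures,
PLY/OBJ triangle meshes, CSV/JSON reports.

Internal conventions
--------------------
* All lengths are stored in Å.  Readers convert on the way in; report writers
  that print nm say so per column.
* Euler angles are ZYZ intrinsic ``(rot, tilt, psi)`` in degrees, particle
  frame → tomogram frame (see :mod:`shell_lattice.geometry`).
* Meshes are `trimesh.Trimesh` objects with counter-clockwise winding seen
  from outside when ``orientation_flag`` is truthy.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "ParticleTable",
    "BeadModel",
    "read_particle_table",
    "write_particle_table",
    "read_structure",
    "read_mesh",
    "write_mesh",
    "RESIDUE_MASS_DA",
]

STAR_COLUMNS = {
    "x": "_rlnCoordinateX",
    "y": "_rlnCoordinateY",
    "z": "_rlnCoordinateZ",
    "rot": "_rlnAngleRot",
    "tilt": "_rlnAngleTilt",
    "psi": "_rlnAnglePsi",
    "tomo_id": "_rlnMicrographName",
    "score": "_rlnAutopickFigureOfMerit",
}

MANDATORY_TAGS = [
    "_rlnCoordinateX",
    "_rlnCoordinateY",
    "_rlnCoordinateZ",
    "_rlnAngleRot",
    "_rlnAngleTilt",
    "_rlnAnglePsi",
]


class FormatError(ValueError):
    """Raised when a file does not conform to the expected format."""


@dataclass
class ParticleTable:
    """Positions, orientations and scores of lattice subunits.

    Attributes
    ----------
    ids : (N,) int array, unique
    tomo_id : (N,) object array of tomogram names
    positions : (N, 3) float array, Å
    eulers : (N, 3) float array, (rot, tilt, psi) degrees, ZYZ intrinsic
    scores : (N,) float array in [0, 1], or None
    group_label : optional point-group text (e.g. "O", "C4")
    extras : DataFrame of unknown columns carried opaquely through I/O
    """

    ids: np.ndarray
    tomo_id: np.ndarray
    positions: np.ndarray
    eulers: np.ndarray
    scores: np.ndarray | None = None
    group_label: str | None = None
    extras: pd.DataFrame | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=int)
        self.tomo_id = np.asarray(self.tomo_id, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.eulers = np.asarray(self.eulers, dtype=float).reshape(-1, 3)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
        self.validate()

    def validate(self):
        n = len(self.ids)
        if len(np.unique(self.ids)) != n:
            raise FormatError("particle ids must be unique")
        for name, arr, length in (
            ("tomo_id", self.tomo_id, n),
            ("positions", self.positions, n),
            ("eulers", self.eulers, n),
        ):
            if len(arr) != length:
                raise FormatError(f"{name} length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise FormatError("non-finite coordinates")
        if not np.all(np.isfinite(self.eulers)):
            raise FormatError("non-finite Euler angles")
        tilt = self.eulers[:, 1]
        if n and (tilt.min() < -1e-9 or tilt.max() > 180.0 + 1e-9):
            raise FormatError(f"tilt out of [0, 180]: range [{tilt.min()}, {tilt.max()}]")
        if self.scores is not None:
            if len(self.scores) != n:
                raise FormatError("scores length mismatch")
            if n and (np.nanmin(self.scores) < -1e-9 or np.nanmax(self.scores) > 1 + 1e-9):
                raise FormatError("scores must lie in [0, 1]")

    def __len__(self):
        return len(self.ids)

    def select(self, mask_or_index) -> "ParticleTable":
        idx = np.asarray(mask_or_index)
        extras = None
        if self.extras is not None:
            extras = self.extras.iloc[np.flatnonzero(idx) if idx.dtype == bool else idx]
            extras = extras.reset_index(drop=True)
        return ParticleTable(
            ids=self.ids[idx],
            tomo_id=self.tomo_id[idx],
            positions=self.positions[idx],
            eulers=self.eulers[idx],
            scores=None if self.scores is None else self.scores[idx],
            group_label=self.group_label,
            extras=extras,
        )

    def copy(self) -> "ParticleTable":
        return ParticleTable(
            ids=self.ids.copy(),
            tomo_id=self.tomo_id.copy(),
            positions=self.positions.copy(),
            eulers=self.eulers.copy(),
            scores=None if self.scores is None else self.scores.copy(),
            group_label=self.group_label,
            extras=None if self.extras is None else self.extras.copy(),
        )

    def rotation_matrices(self) -> np.ndarray:
        from .geometry import euler_to_matrix

        return euler_to_matrix(self.eulers)

    def z_axes(self) -> np.ndarray:
        """Particle +Z directions in the tomogram frame, (N, 3)."""
        return self.rotation_matrices()[:, :, 2]


@dataclass
class BeadModel:
    """Coarse-grained point model: coordinates (Å), masses (Da), labels."""

    coords: np.ndarray
    masses: np.ndarray
    labels: list = field(default_factory=list)
    radii: np.ndarray | None = None  # optional per-bead radii, Å

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
        if len(self.coords) < 1:
            raise FormatError("BeadModel needs at least one bead")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite bead coordinates")
        if len(self.masses) != len(self.coords):
            raise FormatError("masses length mismatch")
        if np.any(self.masses <= 0):
            raise FormatError("masses must be positive")

    def __len__(self):
        return len(self.coords)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())


# ---------------------------------------------------------------------------
# STAR particle tables

_UNIT_SCALE = {"A": 1.0, "angstrom": 1.0, "nm": 10.0}


def read_particle_table(path, length_unit: str = "A", pixel_size: float | None = None) -> ParticleTable:
    """Read a single-loop STAR particle table.

    Parameters
    ----------
    length_unit : "A", "nm" or "pixel".  Positions are converted to Å.
    pixel_size : Å per pixel, required when ``length_unit == "pixel"``.
    """
    if length_unit == "pixel":
        if pixel_size is None:
            raise ValueError("pixel_size is required when length_unit='pixel'")
        scale = float(pixel_size)
    else:
        try:
            scale = _UNIT_SCALE[length_unit]
        except KeyError:
            raise ValueError(f"unknown length_unit {length_unit!r}") from None

    doc = gemmi.cif.read_file(os.fspath(path))
    block = doc.sole_block()
    loop = None
    for item in block:
        if item.loop is not None:
            loop = item.loop
            break
    if loop is None:
        raise FormatError("no loop block found in STAR file")
    tags = list(loop.tags)
    for tag in MANDATORY_TAGS:
        if tag not in tags:
            raise FormatError(f"missing mandatory column {tag}")

    ncol = len(tags)
    values = np.array(loop.values, dtype=object).reshape(-1, ncol)
    df = pd.DataFrame(values, columns=tags)

    def numeric(tag):
        col = df[tag].to_numpy(dtype=object)
        try:
            # numpy's string->float conversion is correctly rounded
            return col.astype(np.float64)
        except ValueError:
            for row, cell in enumerate(col):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric value {cell!r} in column {tag}, data row {row}") from None
            raise

    pos = np.column_stack([numeric(STAR_COLUMNS[k]) for k in ("x", "y", "z")]) * scale
    eulers = np.column_stack([numeric(STAR_COLUMNS[k]) for k in ("rot", "tilt", "psi")])
    if STAR_COLUMNS["tomo_id"] in tags:
        tomo = df[STAR_COLUMNS["tomo_id"]].to_numpy(dtype=object)
    else:
        tomo = np.array(["tomo_1"] * len(df), dtype=object)
    scores = numeric(STAR_COLUMNS["score"]) if STAR_COLUMNS["score"] in tags else None

    if "_slParticleId" in tags:
        ids = numeric("_slParticleId").astype(int)
    else:
        ids = np.arange(len(df))
    known = set(MANDATORY_TAGS) | {STAR_COLUMNS["tomo_id"], STAR_COLUMNS["score"], "_slParticleId"}
    extra_tags = [t for t in tags if t not in known]
    extras = df[extra_tags].reset_index(drop=True) if extra_tags else None

    return ParticleTable(ids=ids, tomo_id=tomo, positions=pos, eulers=eulers, scores=scores, extras=extras)


def write_particle_table(table: ParticleTable, path) -> None:
    """Write a ParticleTable as a one-loop STAR file (deterministic layout)."""
    table.validate()
    buf = io.StringIO()
    buf.write("\ndata_particles\n\nloop_\n")
    tags = ["_slParticleId"] + [STAR_COLUMNS[k] for k in ("x", "y", "z", "rot", "tilt", "psi", "tomo_id")]
    if table.scores is not None:
        tags.append(STAR_COLUMNS["score"])
    extra_tags = list(table.extras.columns) if table.extras is not None else []
    tags += extra_tags
    for i, t in enumerate(tags, start=1):
        buf.write(f"{t} #{i}\n")
    for i in range(len(table)):
        fields = [str(int(table.ids[i]))]
        fields += [f"{v:.17g}" for v in table.positions[i]]
        fields += [f"{v:.17g}" for v in table.eulers[i]]
        fields.append(str(table.tomo_id[i]))
        if table.scores is not None:
            fields.append(f"{table.scores[i]:.17g}")
        for t in extra_tags:
            fields.append(str(table.extras[t].iloc[i]))
        buf.write(" ".join(fields) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Structures

# Average residue masses in Da (amino acid minus one water), standard values.
RESIDUE_MASS_DA = {
    "ALA": 71.0788, "ARG": 156.1875, "ASN": 114.1038, "ASP": 115.0886,
    "CYS": 103.1388, "GLU": 129.1155, "GLN": 128.1307, "GLY": 57.0519,
    "HIS": 137.1411, "ILE": 113.1594, "LEU": 113.1594, "LYS": 128.1741,
    "MET": 131.1926, "PHE": 147.1766, "PRO": 97.1167, "SER": 87.0782,
    "THR": 101.1051, "TRP": 186.2132, "TYR": 163.1760, "VAL": 99.1326,
}


def read_structure(path, coarse_grain: str = "CA") -> BeadModel:
    """Read a PDB/mmCIF file into a BeadModel.

    coarse_grain="CA": one bead per amino-acid residue at its Cα, with the
    standard average residue mass.  coarse_grain="all": one bead per atom
    with elemental masses.
    """
    st = gemmi.read_structure(os.fspath(path))
    st.setup_entities()
    coords, masses, labels = [], [], []
    model = st[0]
    for chain in model:
        for res in chain:
            if coarse_grain == "CA":
                ca = res.find_atom("CA", "*")
                if ca is None:
                    continue
                coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
                masses.append(RESIDUE_MASS_DA.get(res.name.upper(), 110.0))
                labels.append((chain.name, res.seqid.num, res.name))
            elif coarse_grain == "all":
                for atom in res:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    masses.append(atom.element.weight)
                    labels.append((chain.name, res.seqid.num, atom.name))
            else:
                raise ValueError(f"unknown coarse_grain mode {coarse_grain!r}")
    if not coords:
        raise FormatError(f"no parseable atoms in {path}")
    return BeadModel(coords=np.array(coords), masses=np.array(masses), labels=labels)


def read_structure_frames(path, coarse_grain: str = "CA") -> list[BeadModel]:
    """Read a multi-model PDB as a sequence of BeadModel frames."""
    st = gemmi.read_structure(os.fspath(path))
    frames = []
    for model in st:
        coords, masses, labels = [], [], []
        for chain in model:
            for res in chain:
                if coarse_grain == "CA":
                    ca = res.find_atom("CA", "*")
                    if ca is None:
                        continue
                    coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
                    masses.append(RESIDUE_MASS_DA.get(res.name.upper(), 110.0))
                    labels.append((chain.name, res.seqid.num, res.name))
                else:
                    for atom in res:
                        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                        masses.append(atom.element.weight)
                        labels.append((chain.name, res.seqid.num, atom.name))
        if coords:
            frames.append(BeadModel(coords=np.array(coords), masses=np.array(masses), labels=labels))
    if not frames:
        raise FormatError(f"no parseable atoms in {path}")
    return frames


# ---------------------------------------------------------------------------
# Meshes

def read_mesh(path, strict: bool = False) -> trimesh.Trimesh:
    """Read an ASCII PLY or OBJ triangle mesh.

    Non-triangular faces are fan-triangulated by default; with
    ``strict=True`` they raise a FormatError instead.
    """
    path = os.fspath(path)
    if strict:
        _assert_triangular(path)
    mesh = trimesh.load_mesh(path, process=False)
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        if not geoms:
            raise FormatError(f"no geometry in {path}")
        mesh = trimesh.util.concatenate(geoms)
    return mesh


def _assert_triangular(path):
    lower = path.lower()
    if lower.endswith(".obj"):
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.startswith("f "):
                    if len(line.split()) - 1 != 3:
                        raise FormatError(f"non-triangular face at {path}:{lineno}")
    elif lower.endswith(".ply"):
        with open(path, "rb") as fh:
            header = []
            for raw in fh:
                header.append(raw.decode("ascii", "replace").strip())
                if header[-1] == "end_header":
                    break
            if not any(h.startswith("format ascii") for h in header):
                raise FormatError("strict mode supports ASCII PLY only")
            n_vert = n_face = 0
            for h in header:
                parts = h.split()
                if parts[:2] == ["element", "vertex"]:
                    n_vert = int(parts[2])
                if parts[:2] == ["element", "face"]:
                    n_face = int(parts[2])
            lines = fh.read().decode("ascii", "replace").splitlines()
            for line in lines[n_vert:n_vert + n_face]:
                if line.strip() and int(line.split()[0]) != 3:
                    raise FormatError("non-triangular face in PLY")


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    """Write a mesh as ASCII PLY or OBJ, by extension."""
    path = os.fspath(path)
    if path.lower().endswith(".ply"):
        data = trimesh.exchange.ply.export_ply(mesh, encoding="ascii")
        with open(path, "wb") as fh:
            fh.write(data)
    elif path.lower().endswith(".obj"):
        text = trimesh.exchange.obj.export_obj(mesh, include_texture=False)
        with open(path, "w") as fh:
            fh.write(text)
    else:
        raise ValueError(f"unsupported mesh extension for {path}")
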