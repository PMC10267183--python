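"""Craniometric measurements: 47 linear dimensions, cranial module and
indices, cavity volumes, and the cube-root / proportional volume views.

The dimension table ships as editable package data
(``data/linear_dimensions.csv``): 46 inter-landmark distances plus the
cranial-circumference special case (entry 3), measured in the plane that
passes through Glabella and Opisthocranion perpendicular to the
midsagittal plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import trimesh

from .landmarks import LandmarkSet, fit_midsagittal_plane
from .meshgeom import closed_mesh_volume, make_mesh, plane_circumference, \
    points_inside
from .synthetic import boundary_loops

__all__ = [
    "load_dimension_table",
    "linear_dimensions",
    "IndexPanel",
    "index_panel",
    "VolumeSet",
    "volume_set",
    "cavity_volume",
    "measure_specimen",
    "measurement_report",
]

VOLUME_NAMES = ("ICV", "LOV", "NCV", "UIV")


def load_dimension_table() -> pd.DataFrame:
    """The packaged 47-entry dimension table."""
    with resources.files("craniogrow.data").joinpath(
            "linear_dimensions.csv").open() as fh:
        df = pd.read_csv(fh)
    if len(df) != 47:
        raise ValueError(f"dimension table must have 47 entries, has {len(df)}")
    return df


def linear_dimensions(landmarks: LandmarkSet,
                      mesh: trimesh.Trimesh | None = None,
                      table: pd.DataFrame | None = None) -> pd.Series:
    """All 47 linear dimensions (mm) of one specimen.

    ``mesh`` is only needed for the circumference entry; passing None
    leaves that entry NaN.
    """
    if table is None:
        table = load_dimension_table()
    values, names = [], []
    for row in table.itertuples():
        for endpoint in (row.endpoint_a, row.endpoint_b):
            if endpoint not in landmarks:
                raise KeyError(
                    f"dimension {row.index} ({row.name}): landmark "
                    f"{endpoint!r} missing")
        if row.kind == "circumference":
            if mesh is None:
                values.append(np.nan)
            else:
                _, normal = fit_midsagittal_plane(landmarks)
                values.append(plane_circumference(
                    mesh, landmarks[row.endpoint_a],
                    landmarks[row.endpoint_b], normal))
        else:
            values.append(float(np.linalg.norm(
                landmarks[row.endpoint_a] - landmarks[row.endpoint_b])))
        names.append(row.name)
    return pd.Series(values, index=names, name="mm")


@dataclass(frozen=True)
class IndexPanel:
    """Cranial module (mm) and the seven ratio indices (x100)."""

    CM: float
    CI: float
    CFI: float
    UFI: float
    LOI: float
    NI: float
    PI: float
    FMI: float

    def as_series(self) -> pd.Series:
        return pd.Series(vars(self))


def index_panel(dims: pd.Series) -> IndexPanel:
    """The cranial module and indices from the 47-dimension panel.

    CM  = (max cranial length + max cranial breadth + basion-bregma)/3
    CI  = breadth/length x100, CFI = bizygomatic/breadth x100,
    UFI = upper facial height/bizygomatic x100, LOI = left orbital
    height/breadth x100, NI = nasal breadth/height x100, PI = internal
    palatal width/palatal length x100, FMI = foramen magnum
    breadth/length x100.
    """
    def d(name):
        v = float(dims[name])
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"dimension {name!r} missing or nonpositive")
        return v

    ratios = {
        "CI": ("Maximum cranial breadth", "Maximum cranial length"),
        "CFI": ("Bizygomatic breadth", "Maximum cranial breadth"),
        "UFI": ("Upper facial height", "Bizygomatic breadth"),
        "LOI": ("Orbital height (left)", "Orbital breadth (left)"),
        "NI": ("Nasal breadth", "Nasal height"),
        "PI": ("Internal palatal width", "Maximum palatal length"),
        "FMI": ("Foramen magnum breadth", "Foramen magnum length"),
    }
    cm = (d("Maximum cranial length") + d("Maximum cranial breadth")
          + d("Basion-bregma height")) / 3.0
    vals = {k: d(num) / d(den) * 100.0 for k, (num, den) in ratios.items()}
    return IndexPanel(CM=cm, **vals)


@dataclass(frozen=True)
class VolumeSet:
    """The four cavity volumes with cube-root and proportional views.

    ``cvols`` are cube roots (mm); ``cpvols`` are each cube root as a
    percentage of the sum of the four cube roots (sum = 100).
    """

    volumes: dict

    def __post_init__(self):
        for name in VOLUME_NAMES:
            v = self.volumes.get(name)
            if v is None or not np.isfinite(v) or v <= 0:
                raise ValueError(f"volume {name} must be positive, got {v}")

    @property
    def raw(self) -> np.ndarray:
        return np.array([self.volumes[n] for n in VOLUME_NAMES])

    @property
    def cvols(self) -> np.ndarray:
        return np.cbrt(self.raw)

    @property
    def cpvols(self) -> np.ndarray:
        c = self.cvols
        return 100.0 * c / c.sum()

    def as_series(self) -> pd.Series:
        out = {}
        for i, n in enumerate(VOLUME_NAMES):
            out[n] = self.raw[i]
        for i, n in enumerate(VOLUME_NAMES):
            out[f"C{n}"] = self.cvols[i]
        for i, n in enumerate(VOLUME_NAMES):
            out[f"CP{n}"] = self.cpvols[i]
        return pd.Series(out)


def volume_set(icv: float, lov: float, ncv: float, uiv: float) -> VolumeSet:
    return VolumeSet(volumes={"ICV": icv, "LOV": lov, "NCV": ncv,
                              "UIV": uiv})


def cavity_volume(mesh: trimesh.Trimesh, seed_point: np.ndarray,
                  loops: list | None = None) -> float:
    """Volume (mm^3) of the cavity shell enclosing ``seed_point``.

    Cap-and-enclose: each aperture loop (ordered vertex indices; boundary
    loops are auto-detected when None) is closed with a triangle fan about
    its centroid, oriented against the directed boundary edges so the
    capped shell stays consistently wound.  Connected components are then
    extracted and the smallest watertight component containing the seed is
    measured with the divergence-theorem volume (the outer shell also
    contains the seed, so "smallest enclosing" selects the cavity itself).
    """
    seed = np.asarray(seed_point, float)
    vertices = mesh.vertices.view(np.ndarray).copy()
    faces = mesh.faces.view(np.ndarray).copy()
    if loops is None:
        loops = boundary_loops(faces)
    new_faces = [faces]
    new_vertices = [vertices]
    next_idx = len(vertices)
    for loop in loops:
        loop = list(loop)
        if len(loop) < 3:
            raise ValueError("aperture loop with fewer than 3 vertices")
        centroid = vertices[loop].mean(axis=0)
        new_vertices.append(centroid[None])
        fan = [[loop[(i + 1) % len(loop)], loop[i], next_idx]
               for i in range(len(loop))]
        new_faces.append(np.asarray(fan, dtype=faces.dtype))
        next_idx += 1
    capped = make_mesh(np.vstack(new_vertices), np.vstack(new_faces))
    best = None
    for comp in capped.split(only_watertight=False):
        if not comp.is_watertight:
            continue
        if not points_inside(comp, seed)[0]:
            continue
        vol = closed_mesh_volume(comp)
        if best is None or vol < best:
            best = vol
    if best is None:
        raise ValueError("no watertight component encloses the seed point "
                         "(seed outside, or loops not closable)")
    return best


def measure_specimen(landmarks: LandmarkSet,
                     mesh: trimesh.Trimesh | None = None,
                     cavity_meshes: dict | None = None,
                     cavity_seeds: dict | None = None) -> pd.Series:
    """One specimen's full measurement row: dimensions, indices, volumes."""
    dims = linear_dimensions(landmarks, mesh=mesh)
    out = dims.copy()
    panel = index_panel(dims)
    out = pd.concat([out, panel.as_series()])
    if cavity_meshes is not None:
        vols = {}
        for name in VOLUME_NAMES:
            cav_mesh, loops = cavity_meshes[name]
            vols[name] = cavity_volume(cav_mesh, cavity_seeds[name],
                                       loops=loops)
        out = pd.concat([out, VolumeSet(volumes=vols).as_series()])
    return out


def measurement_report(cohort) -> pd.DataFrame:
    """Per-specimen measurement table for a synthetic cohort."""
    rows = []
    for s in cohort.specimens:
        seeds = {n: c.center for n, c in s.cavities.items()}
        row = measure_specimen(s.landmarks, mesh=s.mesh,
                               cavity_meshes=s.cavity_meshes,
                               cavity_seeds=seeds)
        row["id"] = s.specimen_id
        row["age_days"] = s.age_days
        row["age_months"] = s.age_months
        row["sex"] = s.sex
        rows.append(row)
    df = pd.DataFrame(rows).set_index("id")
    return df
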