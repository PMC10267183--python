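"""Synthetic growing crania with analytic cavities and known ground truth.

The outer shell is a superellipsoid (default exponent 2, an ellipsoid) so
its enclosed volume has a closed form; the four internal cavities
(intracranial ICV, left orbital LOV, nasal NCV, upper intraoral UIV) are
axis-aligned ellipsoids with a small polar aperture cut into each surface
mesh, so every true volume is 4/3*pi*abc exactly.  Growth is a monotone
fast-then-slow size curve plus a shared allometric shape displacement
proportional to the change in log centroid size; sexes share the allometric
vector by default and differ only in size-for-age (heterochrony), with an
optional divergence angle for power experiments.  Ages follow the
convention of 1 month = 30.41 days.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy.special import gamma

from .landmarks import LandmarkSet, load_roster, write_landmarks_csv
from .meshgeom import make_mesh
from .procrustes import centroid_size
from .tps import tps_fit

__all__ = [
    "DAYS_PER_MONTH",
    "LogisticCurve",
    "AffineCurve",
    "SizeCurve",
    "CavityShape",
    "GrowthParams",
    "default_params",
    "SyntheticSpecimen",
    "Cohort",
    "make_template_skull",
    "grow_skull",
    "generate_cohort",
    "superellipsoid_volume",
    "write_cohort",
]

DAYS_PER_MONTH = 30.41
TEMPLATE_AGE_DAYS = 365  # ~12 months, the reference individual's age

# patch label codes carried per-face on shell meshes
PATCH_NONE, PATCH_MIDFACIAL, PATCH_CALVARIAL, PATCH_LOWER_OCCIPITAL = 0, 1, 2, 3
PATCH_NAMES = {"midfacial": PATCH_MIDFACIAL, "calvarial": PATCH_CALVARIAL,
               "lower_occipital": PATCH_LOWER_OCCIPITAL}


@dataclass(frozen=True)
class LogisticCurve:
    """Saturating volume curve V(t) = v_max / (1 + exp(-k (t - t0)))."""

    v_max: float
    k: float
    t0: float

    def __call__(self, t_months):
        return self.v_max / (1.0 + np.exp(-self.k * (np.asarray(t_months,
                                                                float) - self.t0)))


@dataclass(frozen=True)
class AffineCurve:
    """Linear volume curve V(t) = intercept + slope * t."""

    intercept: float
    slope: float

    def __call__(self, t_months):
        return self.intercept + self.slope * np.asarray(t_months, float)


@dataclass(frozen=True)
class SizeCurve:
    """Centroid size (mm) vs age: cs(t) = scale * (a + b*(1 - exp(-c t))).

    Fast-then-slow: strictly increasing, with most of the gain in the first
    18 months for the default rate.
    """

    a: float = 0.72
    b: float = 0.38
    c: float = 0.13  # 1/month
    scale: float = 400.0  # mm; calibrated so cs(12) ~ the template's CS

    def __call__(self, t_months):
        t = np.asarray(t_months, float)
        return self.scale * (self.a + self.b * (1.0 - np.exp(-self.c * t)))


@dataclass(frozen=True)
class CavityShape:
    """Analytic ellipsoid cavity: centre + semi-axes (mm), axis-aligned.

    ``aperture_dir`` is the outward direction of the polar aperture cut
    into the surface mesh; ``aperture_cos`` the cone cosine threshold.
    """

    name: str
    center: np.ndarray
    semi_axes: np.ndarray
    aperture_dir: np.ndarray
    aperture_cos: float = 0.95

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        q = (np.atleast_2d(points) - self.center) / self.semi_axes
        return (q ** 2).sum(axis=1) < (1.0 - margin) ** 2


def superellipsoid_volume(axes, exponent: float) -> float:
    """Closed-form volume of |x/A|^p + |y/B|^p + |z/C|^p = 1."""
    a, b, c = axes
    p = exponent
    return 8.0 * a * b * c * gamma(1.0 + 1.0 / p) ** 3 / gamma(1.0 + 3.0 / p)


@dataclass(frozen=True)
class GrowthParams:
    """Ground-truth parameters of a synthetic cohort.

    ``allometric_vector`` is a unit-Frobenius-norm displacement field over
    the 88 template landmarks, orthogonal to similarity transforms of the
    template; applied shape displacement is
    ``allometric_scale * allometric_vector * (Ln(CS) - Ln(CS_template))``.
    ``trajectory_divergence_deg`` rotates the male vector away from the
    female one for power experiments (0 = fully shared trajectory).
    """

    shell_axes: tuple[float, float, float] = (82.0, 68.0, 62.0)
    shell_exponent: float = 2.0
    size_curve: SizeCurve = field(default_factory=SizeCurve)
    sex_size_offset: float = 1.03
    icv_curve: LogisticCurve = field(
        default_factory=lambda: LogisticCurve(v_max=5.0e5, k=0.12, t0=10.0))
    lov_curve: LogisticCurve = field(
        default_factory=lambda: LogisticCurve(v_max=1.4e4, k=0.10, t0=4.0))
    ncv_curve: AffineCurve = field(
        default_factory=lambda: AffineCurve(intercept=2500.0, slope=95.0))
    uiv_curve: AffineCurve = field(
        default_factory=lambda: AffineCurve(intercept=4000.0, slope=210.0))
    landmark_noise_sd: float = 0.5
    allometric_scale: float = 0.18
    trajectory_divergence_deg: float = 0.0
    allometric_vector: np.ndarray | None = None  # filled by default_params

    def volume_curves(self) -> dict:
        return {"ICV": self.icv_curve, "LOV": self.lov_curve,
                "NCV": self.ncv_curve, "UIV": self.uiv_curve}

    def sex_allometric_vector(self, sex: str) -> np.ndarray:
        """The generating shape vector for a sex (unit Frobenius norm)."""
        v = self.allometric_vector
        if sex == "F" or self.trajectory_divergence_deg == 0.0:
            return v
        w = _secondary_field(_template_unit_shape(self))
        theta = np.deg2rad(self.trajectory_divergence_deg)
        return np.cos(theta) * v + np.sin(theta) * w


# cavity template geometry at the reference age (12 months, female):
# centre and axis ratios; semi-axes are rescaled to match the volume curves.
_CAVITY_TEMPLATE = {
    "ICV": {"center": (-16.0, 0.0, 8.0), "ratios": (1.3, 0.92, 0.95),
            "aperture_dir": (0.0, 0.0, -1.0)},
    "LOV": {"center": (50.0, 28.0, 6.0), "ratios": (0.95, 0.75, 0.9),
            "aperture_dir": (1.0, 0.0, 0.0)},
    "NCV": {"center": (54.0, 0.0, -4.0), "ratios": (1.0, 0.5, 1.15),
            "aperture_dir": (1.0, 0.0, -0.3)},
    "UIV": {"center": (40.0, 0.0, -29.5), "ratios": (1.25, 0.95, 0.55),
            "aperture_dir": (0.0, 0.0, -1.0)},
}


def _roster_directions():
    roster = load_roster()
    dirs = roster[["ux", "uy", "uz"]].to_numpy(float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return roster, dirs


def _superellipsoid_map(directions: np.ndarray, axes, exponent: float
                        ) -> np.ndarray:
    """Radially project unit directions onto the superellipsoid surface."""
    d = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    scaled = np.abs(d / np.asarray(axes, float))
    t = (scaled ** exponent).sum(axis=1) ** (-1.0 / exponent)
    return d * t[:, None]


def _template_landmarks(params: GrowthParams) -> LandmarkSet:
    roster, dirs = _roster_directions()
    coords = _superellipsoid_map(dirs, params.shell_axes,
                                 params.shell_exponent)
    return LandmarkSet(
        names=roster["name"].tolist(),
        coords=coords,
        roles=roster["role"].tolist(),
        sides=roster["side"].tolist(),
        gpa_excluded=roster["gpa_excluded"].to_numpy(bool),
    )


def _template_unit_shape(params: GrowthParams) -> np.ndarray:
    c = _template_landmarks(params).coords
    c = c - c.mean(axis=0)
    return c / np.linalg.norm(c)


def _project_out_similarity(field: np.ndarray, shape: np.ndarray
                            ) -> np.ndarray:
    """Remove translation, rotation and scaling components from a field.

    ``shape`` is the centred unit-norm template; the similarity tangent
    space at it is spanned by the 3 translations, 3 infinitesimal
    rotations, and the radial (scaling) direction.
    """
    k = len(shape)
    basis = []
    for ax in range(3):
        t = np.zeros((k, 3))
        t[:, ax] = 1.0
        basis.append(t)
    gens = [np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], float),
            np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], float),
            np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], float)]
    for g in gens:
        basis.append(shape @ g.T)
    basis.append(shape)
    out = field.copy()
    for b in basis:
        bn = np.linalg.norm(b)
        if bn > 0:
            out -= (np.sum(out * b) / bn ** 2) * b
    return out


def _primary_field(shape: np.ndarray) -> np.ndarray:
    """Default allometric pattern: relative facial expansion, vault lag.

    Outward displacement weighted towards anterior-inferior points,
    mimicking the dominance of facial over neurocranial relative growth.
    """
    u = shape / np.linalg.norm(shape, axis=1, keepdims=True).clip(1e-12)
    w = 0.5 + 0.8 * u[:, 0] - 0.5 * u[:, 2]
    f = _project_out_similarity(u * w[:, None], shape)
    return f / np.linalg.norm(f)

def _secondary_field(shape: np.ndarray) -> np.ndarray:
    """A second smooth field, orthogonal to the primary (for divergence)."""
    u = shape / np.linalg.norm(shape, axis=1, keepdims=True).clip(1e-12)
    w = 0.6 * u[:, 2] + 0.7 * u[:, 0] * u[:, 2]
    f = _project_out_similarity(u * w[:, None], shape)
    v = _primary_field(shape)
    f -= np.sum(f * v) * v
    return f / np.linalg.norm(f)


def default_params(**overrides) -> GrowthParams:
    """Default GrowthParams with the allometric field constructed."""
    params = GrowthParams(**{k: v for k, v in overrides.items()
                             if k != "allometric_vector"})
    if overrides.get("allometric_vector") is not None:
        vec = np.asarray(overrides["allometric_vector"], float)
        vec = vec / np.linalg.norm(vec)
    else:
        vec = _primary_field(_template_unit_shape(params))
    return replace(params, allometric_vector=vec)


@dataclass
class SyntheticSpecimen:
    """One synthetic cranium: shell mesh, 88 landmarks, cavities, truth."""

    specimen_id: str
    age_days: int
    sex: str
    landmarks: LandmarkSet
    cavities: dict[str, CavityShape]
    true_volumes: dict[str, float]
    mesh: trimesh.Trimesh | None = None
    cavity_meshes: dict | None = None  # name -> (mesh, ordered rim loops)

    @property
    def age_months(self) -> float:
        return self.age_days / DAYS_PER_MONTH


@dataclass
class Cohort:
    specimens: list[SyntheticSpecimen]
    metadata: pd.DataFrame
    params: GrowthParams
    seed: int

    def __len__(self):
        return len(self.specimens)

    def landmark_sets(self) -> list[LandmarkSet]:
        return [s.landmarks for s in self.specimens]


def _shell_patch_labels(mesh_dirs: np.ndarray, faces: np.ndarray
                        ) -> np.ndarray:
    """Label faces by angular sector of the face-centroid direction.

    One side only (left, y > 0): midfacial = anterior band, calvarial =
    superior cap, lower_occipital = posterior-inferior band.  The right
    side stays unlabelled; templates are built one-sided then mirrored.
    """
    cent = mesh_dirs[faces].mean(axis=1)
    cent /= np.linalg.norm(cent, axis=1, keepdims=True)
    x, y, z = cent.T
    labels = np.full(len(faces), PATCH_NONE, dtype=np.int8)
    left = y > 1e-9
    labels[left & (z > 0.25)] = PATCH_CALVARIAL
    labels[left & (z <= 0.25) & (x > 0.55)] = PATCH_MIDFACIAL
    labels[left & (z <= 0.25) & (z > -0.75) & (x < -0.45)] = \
        PATCH_LOWER_OCCIPITAL
    return labels


def _build_shell(params: GrowthParams, resolution: int) -> trimesh.Trimesh:
    ico = trimesh.creation.icosphere(subdivisions=resolution, radius=1.0)
    dirs = ico.vertices.view(np.ndarray)
    verts = _superellipsoid_map(dirs, params.shell_axes,
                                params.shell_exponent)
    labels = _shell_patch_labels(dirs, ico.faces.view(np.ndarray))
    return make_mesh(verts, ico.faces, patch_labels=labels)


def _build_cavity_mesh(cav: CavityShape, resolution: int):
    """Ellipsoid surface with a polar aperture; returns (mesh, rim loops).

    Rim loops are ordered vertex-index loops following the directed
    boundary edges, ready for fan capping.
    """
    ico = trimesh.creation.icosphere(subdivisions=max(3, resolution - 1),
                                     radius=1.0)
    dirs = ico.vertices.view(np.ndarray)
    d = np.asarray(cav.aperture_dir, float)
    d = d / np.linalg.norm(d)
    keep_face = ~(dirs[ico.faces] @ d > cav.aperture_cos).all(axis=1)
    faces = ico.faces[keep_face]
    used = np.unique(faces)
    remap = -np.ones(len(dirs), dtype=np.int64)
    remap[used] = np.arange(len(used))
    faces = remap[faces]
    verts = cav.center + dirs[used] * cav.semi_axes
    mesh = make_mesh(verts, faces)
    loops = boundary_loops(faces)
    return mesh, loops


def boundary_loops(faces: np.ndarray) -> list[list[int]]:
    """Ordered vertex loops of directed boundary edges of a triangle soup."""
    edges = {}
    for f in np.asarray(faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edges[(int(a), int(b))] = edges.get((int(a), int(b)), 0) + 1
    boundary = {a: b for (a, b) in edges if (b, a) not in edges}
    loops = []
    while boundary:
        start, nxt = next(iter(boundary.items()))
        loop = [start]
        del boundary[start]
        while nxt != start:
            loop.append(nxt)
            nxt = boundary.pop(nxt)
        loops.append(loop)
    return loops


def _cavities_at(params: GrowthParams, age_months: float, scale: float
                 ) -> tuple[dict[str, CavityShape], dict[str, float]]:
    """Cavity shapes whose analytic volumes equal the growth curves."""
    cavities, volumes = {}, {}
    for name, curve in params.volume_curves().items():
        spec = _CAVITY_TEMPLATE[name]
        v = float(curve(age_months))
        if v <= 0:
            raise ValueError(f"{name} volume curve nonpositive at "
                             f"{age_months} months")
        ratios = np.asarray(spec["ratios"], float)
        unit_v = 4.0 / 3.0 * np.pi * np.prod(ratios)
        semi = ratios * (v / unit_v) ** (1.0 / 3.0)
        cavities[name] = CavityShape(
            name=name,
            center=np.asarray(spec["center"], float) * scale,
            semi_axes=semi,
            aperture_dir=np.asarray(spec["aperture_dir"], float),
        )
        volumes[name] = v
    return cavities, volumes


def make_template_skull(resolution: int = 3,
                        params: GrowthParams | None = None
                        ) -> SyntheticSpecimen:
    """The reference individual: female, ~12 months, noise-free.

    Landmarks sit at analytically defined surface positions (poles, equator
    points and facial/basicranial features of the superellipsoid shell);
    the roster includes the paired Euryon points flagged for exclusion from
    superimposition.
    """
    if resolution < 2:
        raise ValueError(f"resolution must be >= 2, got {resolution}")
    if params is None:
        params = default_params()
    lms = _template_landmarks(params)
    mesh = _build_shell(params, resolution)
    t_ref = TEMPLATE_AGE_DAYS / DAYS_PER_MONTH
    cavities, volumes = _cavities_at(params, t_ref, scale=1.0)
    cavity_meshes = {name: _build_cavity_mesh(c, resolution)
                     for name, c in cavities.items()}
    return SyntheticSpecimen(
        specimen_id="template",
        age_days=TEMPLATE_AGE_DAYS,
        sex="F",
        landmarks=lms,
        cavities=cavities,
        true_volumes=volumes,
        mesh=mesh,
        cavity_meshes=cavity_meshes,
    )


def grow_skull(template: SyntheticSpecimen, age_days: int, sex: str,
               params: GrowthParams, rng_seed, specimen_id: str = "grown",
               build_meshes: bool = True) -> SyntheticSpecimen:
    """Deform the template to a given age and sex, with landmark noise.

    Landmark positions are the template's unit shape displaced along the
    sex's allometric vector by ``allometric_scale * (Ln(CS)-Ln(CS_ref))``,
    rescaled to the target centroid size, plus i.i.d. Gaussian measurement
    noise.  The shell mesh follows by a TPS warp anchored on the noise-free
    landmarks; cavity geometry is regenerated analytically so true volumes
    match the growth curves exactly.
    """
    if age_days < 0:
        raise ValueError(f"age_days must be >= 0, got {age_days}")
    if params.landmark_noise_sd < 0:
        raise ValueError("landmark_noise_sd must be >= 0")
    if sex not in ("F", "M"):
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    if params.allometric_vector is None:
        raise ValueError("params.allometric_vector unset; use default_params()")
    rng = np.random.default_rng(rng_seed)
    months = age_days / DAYS_PER_MONTH
    t_ref = template.age_days / DAYS_PER_MONTH

    cs_ref = centroid_size(template.landmarks)
    curve = params.size_curve
    factor = float(curve(months) / curve(t_ref))
    if sex == "M":
        factor *= params.sex_size_offset
    cs_target = cs_ref * factor
    dln = np.log(cs_target) - np.log(cs_ref)

    L0 = template.landmarks.coords
    centroid0 = L0.mean(axis=0)
    u0 = (L0 - centroid0) / cs_ref
    v = params.sex_allometric_vector(sex)
    u = u0 + params.allometric_scale * v * dln
    u -= u.mean(axis=0)
    u /= np.linalg.norm(u)
    L_clean = u * cs_target + centroid0 * factor

    noise = rng.normal(scale=params.landmark_noise_sd, size=L_clean.shape) \
        if params.landmark_noise_sd > 0 else 0.0
    lms = template.landmarks.with_coords(L_clean + noise)

    scale = factor
    cavities, volumes = _cavities_at(params, months, scale=scale)

    mesh = None
    cavity_meshes = None
    if build_meshes:
        warp = tps_fit(L0, L_clean)
        mesh = make_mesh(warp.apply(template.mesh.vertices.view(np.ndarray)),
                         template.mesh.faces,
                         patch_labels=template.mesh.metadata.get(
                             "patch_labels"))
        resolution = _resolution_of(template)
        cavity_meshes = {name: _build_cavity_mesh(c, resolution)
                         for name, c in cavities.items()}
    return SyntheticSpecimen(
        specimen_id=specimen_id,
        age_days=int(age_days),
        sex=sex,
        landmarks=lms,
        cavities=cavities,
        true_volumes=volumes,
        mesh=mesh,
        cavity_meshes=cavity_meshes,
    )


def _resolution_of(template: SyntheticSpecimen) -> int:
    n_faces = len(template.mesh.faces)
    # icosphere at subdivision s has 20 * 4**s faces
    return int(round(np.log(n_faces / 20.0) / np.log(4.0)))


def uniform_age_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    """Default sampler: ages uniform on [0, 1460] days (0-48 months)."""
    return rng.integers(0, 1461, size=n)


def skewed_age_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    """Age sampler mimicking a clinically skewed distribution: dense in the
    first year, sparse towards 48 months (piecewise-uniform mixture
    88:60:48:21 over the four year-bands, after the reported cohort)."""
    band = rng.choice(4, size=n, p=np.array([88, 60, 48, 21]) / 217.0)
    lo = np.array([0, 365, 730, 1095])[band]
    hi = np.array([365, 730, 1095, 1461])[band]
    return lo + (rng.random(n) * (hi - lo)).astype(int)


def generate_cohort(n: int, params: GrowthParams | None = None,
                    sex_ratio: float = 123.0 / 217.0,
                    age_sampler=uniform_age_sampler, seed: int = 0,
                    resolution: int = 3, build_meshes: bool = True
                    ) -> Cohort:
    """Generate a cohort of n specimens with known ground truth.

    ``sex_ratio`` is the male fraction; the male count is round(n * ratio)
    exactly (the default reproduces 123 males and 94 females at n = 217).
    One seed sequence is spawned per specimen by counter, so cohorts are
    reproducible regardless of construction order.
    """
    if n < 2:
        raise ValueError(f"cohort size must be >= 2, got {n}")
    if not 0.0 < sex_ratio < 1.0:
        raise ValueError("sex_ratio must be strictly between 0 and 1")
    if params is None:
        params = default_params()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n + 1)
    rng = np.random.default_rng(children[0])
    ages = np.asarray(age_sampler(rng, n))
    n_male = int(round(n * sex_ratio))
    sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
    rng.shuffle(sexes)

    template = make_template_skull(resolution=resolution, params=params) \
        if build_meshes else _landmark_only_template(params)
    specimens = []
    for i in range(n):
        specimens.append(grow_skull(
            template, int(ages[i]), str(sexes[i]), params,
            rng_seed=children[i + 1], specimen_id=f"S{i:03d}",
            build_meshes=build_meshes))
    meta = pd.DataFrame({
        "id": [s.specimen_id for s in specimens],
        "age_days": [s.age_days for s in specimens],
        "age_months": [round(s.age_months, 2) for s in specimens],
        "sex": [s.sex for s in specimens],
    })
    return Cohort(specimens=specimens, metadata=meta, params=params,
                  seed=seed)


def _landmark_only_template(params: GrowthParams) -> SyntheticSpecimen:
    t_ref = TEMPLATE_AGE_DAYS / DAYS_PER_MONTH
    cavities, volumes = _cavities_at(params, t_ref, scale=1.0)
    return SyntheticSpecimen(
        specimen_id="template", age_days=TEMPLATE_AGE_DAYS, sex="F",
        landmarks=_template_landmarks(params), cavities=cavities,
        true_volumes=volumes, mesh=None, cavity_meshes=None)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write meshes (PLY), landmark CSVs, metadata and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in cohort.specimens:
        if s.mesh is not None:
            s.mesh.export(outdir / f"{s.specimen_id}.ply")
        write_landmarks_csv(s.landmarks, outdir / f"{s.specimen_id}_lms.csv")
    cohort.metadata.to_csv(outdir / "metadata.csv", index=False)
    p = cohort.params
    truth = {
        "seed": cohort.seed,
        "shell_axes": list(p.shell_axes),
        "shell_exponent": p.shell_exponent,
        "size_curve": {"a": p.size_curve.a, "b": p.size_curve.b,
                       "c": p.size_curve.c, "scale": p.size_curve.scale},
        "sex_size_offset": p.sex_size_offset,
        "icv_curve": vars(p.icv_curve) | {},
        "lov_curve": vars(p.lov_curve) | {},
        "ncv_curve": vars(p.ncv_curve) | {},
        "uiv_curve": vars(p.uiv_curve) | {},
        "landmark_noise_sd": p.landmark_noise_sd,
        "allometric_scale": p.allometric_scale,
        "trajectory_divergence_deg": p.trajectory_divergence_deg,
        "allometric_vector": p.allometric_vector.tolist(),
        "true_volumes": {s.specimen_id: s.true_volumes
                         for s in cohort.specimens},
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
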