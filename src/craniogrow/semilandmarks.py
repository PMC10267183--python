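"""Surface semilandmarks: template construction, projection, and sliding.

The template seeds points approximately evenly (farthest-point sampling)
over three labelled patches on one side of the reference cranium --
100 midfacial, 1000 calvarial, 52 lower occipital -- mirrors them across
the midsagittal plane and projects the mirrored set back to the surface,
giving 2304 semilandmarks in total (200 mid-facial, 2104 neurocranial).
On each target the template semilandmarks are TPS-warped (anchored on the
anatomical landmarks), projected to the target surface, and slid within
their tangent planes to minimise the bending energy of the thin-plate
spline from the reference configuration (Gunz-style closed-form step,
re-projected each iteration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .landmarks import LandmarkSet, fit_midsagittal_plane
from .meshgeom import closest_on_mesh, face_areas, surface_frames
from .tps import bending_energy_matrix, tps_fit

__all__ = [
    "DEFAULT_PATCH_COUNTS",
    "SemilandmarkTemplate",
    "sample_patch",
    "mirror_points",
    "build_template",
    "project_template",
    "slide_semilandmarks",
    "SlideResult",
]

#: one-sided patch counts of the study configuration
DEFAULT_PATCH_COUNTS = {"midfacial": 100, "calvarial": 1000,
                        "lower_occipital": 52}

_PATCH_CODES = {"midfacial": 1, "calvarial": 2, "lower_occipital": 3}
#: patches belonging to the neurocranial module (vs the mid-face)
NEUROCRANIAL_PATCHES = ("calvarial", "lower_occipital")


def _patch_faces(mesh: trimesh.Trimesh, patch_label: str) -> np.ndarray:
    labels = mesh.metadata.get("patch_labels")
    if labels is None:
        raise ValueError("mesh carries no patch labels")
    code = _PATCH_CODES.get(patch_label)
    if code is None:
        raise ValueError(f"unknown patch {patch_label!r}")
    faces = np.flatnonzero(np.asarray(labels) == code)
    if faces.size == 0:
        raise ValueError(f"patch {patch_label!r} has no faces")
    return faces


def sample_patch(mesh: trimesh.Trimesh, patch_label: str, count: int,
                 seed: int, oversample: int = 20) -> np.ndarray:
    """Approximately even points on a labelled patch (farthest-point).

    A dense area-weighted candidate pool is drawn on the patch faces and
    thinned greedily by the farthest-point criterion, which bounds the
    ratio of nearest-neighbour distances and gives near-even coverage.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    faces = _patch_faces(mesh, patch_label)
    areas = face_areas(mesh.vertices, mesh.faces[faces])
    n_pool = max(count * oversample, 500)
    if count > 4 * len(faces):
        raise ValueError(
            f"count {count} too large for patch {patch_label!r} at this "
            f"resolution ({len(faces)} faces); refine the mesh")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(faces), size=n_pool, p=areas / areas.sum())
    tri = mesh.triangles.view(np.ndarray)[faces[pick]]
    # uniform barycentric samples
    r1 = np.sqrt(rng.random(n_pool))
    r2 = rng.random(n_pool)
    pool = (tri[:, 0] * (1 - r1)[:, None]
            + tri[:, 1] * (r1 * (1 - r2))[:, None]
            + tri[:, 2] * (r1 * r2)[:, None])
    # greedy farthest-point thinning, seeded at the pool centroid's nearest
    d0 = np.linalg.norm(pool - pool.mean(axis=0), axis=1)
    first = int(d0.argmin())
    chosen = [first]
    dist = np.linalg.norm(pool - pool[first], axis=1)
    for _ in range(count - 1):
        nxt = int(dist.argmax())
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(pool - pool[nxt], axis=1))
    return pool[chosen]


def mirror_points(points: np.ndarray, plane_point: np.ndarray,
                  plane_normal: np.ndarray) -> np.ndarray:
    """Reflect points across the plane (point, normal)."""
    n = np.asarray(plane_normal, float)
    nn = np.linalg.norm(n)
    if nn < 1e-15:
        raise ValueError("zero-length plane normal")
    n = n / nn
    p = np.atleast_2d(np.asarray(points, float))
    d = (p - np.asarray(plane_point, float)) @ n
    return p - 2.0 * d[:, None] * n


@dataclass
class SemilandmarkTemplate:
    """The reference semilandmark configuration.

    ``slm_points`` are ordered left-side-first per patch, then the mirrored
    right side, matching ``patch_tags``/``side_tags``.  ``anchor_landmarks``
    is the full 88-landmark roster on the reference.
    """

    reference_mesh: trimesh.Trimesh
    anchor_landmarks: LandmarkSet
    slm_points: np.ndarray
    patch_tags: np.ndarray  # patch name per SLM
    side_tags: np.ndarray  # "L" or "R" per SLM
    counts: dict
    seed: int

    @property
    def n_slm(self) -> int:
        return len(self.slm_points)

    def module_mask(self, module: str) -> np.ndarray:
        """Boolean SLM mask for 'cranium', 'face' or 'neurocranium'."""
        if module == "cranium":
            return np.ones(self.n_slm, dtype=bool)
        if module == "face":
            return self.patch_tags == "midfacial"
        if module == "neurocranium":
            return np.isin(self.patch_tags, NEUROCRANIAL_PATCHES)
        raise ValueError(f"unknown module {module!r}")

    def full_configuration(self) -> LandmarkSet:
        """Anchors + SLMs as one LandmarkSet (SLMs never GPA-excluded)."""
        lm = self.anchor_landmarks
        names = list(lm.names) + [f"SLM_{i:04d}" for i in range(self.n_slm)]
        coords = np.vstack([lm.coords, self.slm_points])
        roles = list(lm.roles) + ["SLM"] * self.n_slm
        sides = list(lm.sides) + list(self.side_tags)
        excl = np.concatenate([lm.gpa_excluded,
                               np.zeros(self.n_slm, dtype=bool)])
        return LandmarkSet(names=names, coords=coords, roles=roles,
                           sides=sides, gpa_excluded=excl)


def build_template(reference_mesh: trimesh.Trimesh,
                   anchor_landmarks: LandmarkSet,
                   counts: dict | None = None, seed: int = 0
                   ) -> SemilandmarkTemplate:
    """Sample one side, mirror across the midsagittal plane, project back.

    With the study counts (100/1000/52 one-sided) this yields 2304 SLMs:
    200 over the mid-face and 2104 over the neurocranium.
    """
    counts = dict(DEFAULT_PATCH_COUNTS if counts is None else counts)
    plane_pt, plane_n = fit_midsagittal_plane(anchor_landmarks)
    points, patches, sides = [], [], []
    for patch in ("midfacial", "calvarial", "lower_occipital"):
        sampled = sample_patch(reference_mesh, patch, counts[patch],
                               seed=seed + _PATCH_CODES[patch])
        points.append(sampled)
        patches += [patch] * len(sampled)
        sides += ["L"] * len(sampled)
    one_side = np.vstack(points)
    mirrored = mirror_points(one_side, plane_pt, plane_n)
    projected, _, _ = closest_on_mesh(reference_mesh, mirrored)
    slm = np.vstack([one_side, projected])
    patches = np.array(patches + patches)
    sides = np.array(sides + ["R"] * len(one_side))
    return SemilandmarkTemplate(
        reference_mesh=reference_mesh,
        anchor_landmarks=anchor_landmarks,
        slm_points=slm,
        patch_tags=patches,
        side_tags=sides,
        counts=counts,
        seed=seed,
    )


def project_template(template: SemilandmarkTemplate,
                     target_mesh: trimesh.Trimesh,
                     target_lms: LandmarkSet) -> np.ndarray:
    """Initial SLM positions on a target cranium.

    TPS anchored on the 88 landmarks carries the template SLMs toward the
    target; a closest-point projection then puts them on its surface.
    """
    missing = [n for n in template.anchor_landmarks.names
               if n not in target_lms]
    if missing:
        raise ValueError(f"target lacks anchor landmarks: {missing[:5]}"
                         f"{'...' if len(missing) > 5 else ''}")
    src = template.anchor_landmarks.coords
    tgt = np.stack([target_lms[n] for n in template.anchor_landmarks.names])
    warp = tps_fit(src, tgt)
    carried = warp.apply(template.slm_points)
    projected, _, _ = closest_on_mesh(target_mesh, carried)
    return projected


@dataclass
class SlideResult:
    slid_points: np.ndarray  # SLM positions after sliding
    energy_trace: list  # bending energy before/after each accepted step
    n_iterations: int


def slide_semilandmarks(initial_slm: np.ndarray,
                        target_mesh: trimesh.Trimesh,
                        target_lms: np.ndarray,
                        reference_config: np.ndarray,
                        max_iter: int = 3, tol: float = 1e-6) -> SlideResult:
    """Slide SLMs along tangent planes to minimise TPS bending energy.

    The reference configuration (anchor LMs followed by SLMs, matching the
    target ordering) defines the bending-energy matrix; each iteration
    solves the tangent-restricted quadratic programme in closed form,
    re-projects the slid points onto the surface, and accepts the step if
    the energy did not increase (within ``tol`` relative).  Landmarks stay
    fixed; only semilandmarks move.
    """
    ref = np.asarray(reference_config, float)
    lms = np.atleast_2d(np.asarray(target_lms, float))
    slm = np.asarray(initial_slm, float).copy()
    n_lm, n_slm = len(lms), len(slm)
    if ref.shape != (n_lm + n_slm, 3):
        raise ValueError("reference_config must stack target LMs + SLMs")
    B = bending_energy_matrix(ref)
    if not np.all(np.isfinite(B)):
        raise ValueError("non-finite bending-energy matrix "
                         "(degenerate reference)")
    B_ss = B[n_lm:, n_lm:]

    def energy(points):
        Y = np.vstack([lms, points])
        return float(np.einsum("kd,kl,ld->", Y, B, Y))

    e = energy(slm)
    trace = [e]
    n_done = 0
    for _ in range(max_iter):
        _, normals, T = surface_frames(target_mesh, slm)
        Y0 = np.vstack([lms, slm])
        G = np.einsum("ixa,jxb->iajb", T, T)
        M = (B_ss[:, None, :, None] * G).reshape(2 * n_slm, 2 * n_slm)
        g = np.einsum("ix,ixa->ia", (B @ Y0)[n_lm:], T).reshape(-1)
        # tiny ridge keeps the tangent system well-posed for flat patches
        M[np.diag_indices_from(M)] += 1e-12 * max(np.trace(M) / len(M), 1e-30)
        t = np.linalg.solve(M, -g)
        cand = slm + np.einsum("ixa,ia->ix", T, t.reshape(n_slm, 2))
        cand, _, _ = closest_on_mesh(target_mesh, cand)
        e_new = energy(cand)
        if e_new > e * (1.0 + 1e-9) + 1e-15:
            break  # projection undid the gain; keep the previous state
        converged = e > 0 and abs(e - e_new) / max(e, 1e-300) < tol
        slm = cand
        e = e_new
        trace.append(e)
        n_done += 1
        if converged:
            break
    return SlideResult(slid_points=slm, energy_trace=trace,
                       n_iterations=n_done)
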