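"""Superimposition: centroid size, OPA, and generalized Procrustes analysis.

Full Procrustes convention: every configuration is scaled to unit centroid
size, so size is removed from the shape coordinates and re-attached
downstream as a log-centroid-size column (the "form" construction).
Rotations are proper (reflections forbidden) unless explicitly allowed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkSet

__all__ = [
    "centroid_size",
    "ordinary_procrustes",
    "procrustes_distance",
    "gpa",
    "ProcrustesResult",
]


def centroid_size(config: LandmarkSet | np.ndarray) -> float:
    """Square root of summed squared deviations from the centroid (mm)."""
    coords = config.coords if isinstance(config, LandmarkSet) else \
        np.asarray(config, dtype=float)
    if coords.size == 0:
        raise ValueError("empty landmark configuration")
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt((centred ** 2).sum()))


def _as_coords(x) -> np.ndarray:
    return x.coords if isinstance(x, LandmarkSet) else np.asarray(x, float)


def _optimal_rotation(moving: np.ndarray, fixed: np.ndarray,
                      allow_reflection: bool) -> np.ndarray:
    """Rotation R minimising ||moving @ R - fixed|| (Kabsch/SVD)."""
    u, _, vt = np.linalg.svd(moving.T @ fixed)
    R = u @ vt
    if not allow_reflection and np.linalg.det(R) < 0:
        u[:, -1] *= -1.0
        R = u @ vt
    return R


def ordinary_procrustes(moving, fixed, allow_reflection: bool = False):
    """Align ``moving`` to ``fixed`` by translation, scaling and rotation.

    Both are reduced to centred unit-centroid-size shapes; the optimal
    rotation comes from the SVD of the cross-covariance with a determinant
    correction unless reflections are allowed.

    Returns
    -------
    (aligned, distance) : aligned unit-size coordinates of ``moving`` and
    the root summed squared residual between the two unit-size shapes
    (the partial Procrustes distance).
    """
    m = _as_coords(moving)
    f = _as_coords(fixed)
    if m.shape != f.shape:
        raise ValueError(f"point count mismatch: {m.shape} vs {f.shape}")
    if len(m) < 3:
        raise ValueError("need at least 3 points")
    m0 = (m - m.mean(axis=0)) / centroid_size(m)
    f0 = (f - f.mean(axis=0)) / centroid_size(f)
    R = _optimal_rotation(m0, f0, allow_reflection)
    aligned = m0 @ R
    dist = float(np.linalg.norm(aligned - f0))
    return aligned, dist


def procrustes_distance(a, b, allow_reflection: bool = False) -> float:
    return ordinary_procrustes(a, b, allow_reflection)[1]


def _canonical_frame(mean: np.ndarray) -> np.ndarray:
    """Proper rotation taking a centred mean shape to principal axes.

    Column signs are fixed so the largest-magnitude coordinate along each
    of the first two axes is positive; the third axis is their cross
    product, forbidding reflection.
    """
    _, _, vt = np.linalg.svd(mean - mean.mean(axis=0), full_matrices=True)
    R = vt.T
    for j in range(2):
        col = mean @ R[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            R[:, j] *= -1.0
    R[:, 2] = np.cross(R[:, 0], R[:, 1])
    return R


@dataclass
class ProcrustesResult:
    """Output of GPA over a cohort.

    ``shape_coordinates`` is n x (3m) with m the points that entered the
    superimposition; ``used_names`` records which those were.  Excluded
    (flagged) landmarks are not aligned on but remain available in the
    original specimen frames for linear measurements.
    """

    shape_coordinates: np.ndarray
    mean_shape: np.ndarray
    centroid_sizes: np.ndarray
    ln_cs: np.ndarray
    used_names: list[str]
    n_iterations: int

    @property
    def n_specimens(self) -> int:
        return self.shape_coordinates.shape[0]

    @property
    def n_points(self) -> int:
        return self.mean_shape.shape[0]

    def shapes_3d(self) -> np.ndarray:
        return self.shape_coordinates.reshape(self.n_specimens, -1, 3)


def gpa(cohort_landmarks: list[LandmarkSet], exclude_flagged: bool = True,
        tol: float = 1e-10, max_iter: int = 100) -> ProcrustesResult:
    """Generalized Procrustes analysis of a cohort.

    Iteratively aligns unit-size configurations to the updating mean until
    the relative change of the mean falls below ``tol``.  With
    ``exclude_flagged`` the roster's flagged points (the Euryon pair on the
    88-landmark template) are left out, passing 86 landmarks plus any
    semilandmarks into the superimposition.
    """
    if len(cohort_landmarks) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    roster = cohort_landmarks[0].names
    for lm in cohort_landmarks[1:]:
        if lm.names != roster:
            missing = sorted(set(roster) - set(lm.names))
            raise ValueError(
                f"roster mismatch across cohort; missing from one specimen: "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    first = cohort_landmarks[0]
    if exclude_flagged:
        keep = ~first.gpa_excluded
    else:
        keep = np.ones(len(first), dtype=bool)
    used_names = [n for n, k in zip(roster, keep) if k]

    configs = np.stack([lm.coords[keep] for lm in cohort_landmarks])
    n, m, _ = configs.shape
    cs = np.array([centroid_size(c) for c in configs])
    unit = (configs - configs.mean(axis=1, keepdims=True)) / cs[:, None, None]

    mean = unit[0].copy()
    mean /= np.linalg.norm(mean)
    aligned = unit.copy()
    n_it = 0
    for n_it in range(1, max_iter + 1):
        for i in range(n):
            R = _optimal_rotation(unit[i], mean, allow_reflection=False)
            aligned[i] = unit[i] @ R
        new_mean = aligned.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= np.linalg.norm(new_mean)
        delta = np.linalg.norm(new_mean - mean) / np.linalg.norm(mean)
        mean = new_mean
        if delta < tol:
            break
    # canonical orientation: principal axes of the mean with a fixed sign
    # convention, so the output frame is invariant to how inputs were posed
    R = _canonical_frame(mean)
    mean = mean @ R
    aligned = aligned @ R
    return ProcrustesResult(
        shape_coordinates=aligned.reshape(n, 3 * m),
        mean_shape=mean,
        centroid_sizes=cs,
        ln_cs=np.log(cs),
        used_names=used_names,
        n_iterations=n_it,
    )
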