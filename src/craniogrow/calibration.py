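"""Statistical calibration and parameter-recovery experiments.

These routines exercise the permutation tests against the generator's
known ground truth on landmark-only cohorts: type-I error of the
multivariate regression permutation test under an independent covariate,
operating characteristics of the trajectory-angle test when the sexes
share (or diverge from) a common allometric vector, and recovery of the
generating allometric vector by regression of shape on Ln(CS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphostats import (form_matrix, multivariate_regression, pca,
                          trajectory_angle_test)
from .procrustes import gpa
from .synthetic import GrowthParams, default_params, generate_cohort

__all__ = [
    "regression_type1_error",
    "trajectory_test_rates",
    "RecoveryResult",
    "allometric_recovery",
]


def regression_type1_error(n_replicates: int = 200, n: int = 50,
                           n_columns: int = 20, n_perm: int = 200,
                           alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the regression permutation test under the null.

    Each replicate regresses an i.i.d. Gaussian response matrix on an
    independent covariate; the returned rate should sit inside the
    binomial confidence band around ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for i in range(n_replicates):
        Y = rng.normal(size=(n, n_columns))
        x = rng.normal(size=n)
        res = multivariate_regression(Y, x, n_perm=n_perm,
                                      seed=int(rng.integers(2 ** 31)))
        rejections += res.p_value <= alpha
    return rejections / n_replicates


def trajectory_test_rates(n_replicates: int = 100, n: int = 50,
                          divergence_deg: float = 0.0,
                          noise_sd: float = 0.5, n_perm: int = 200,
                          alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the sex-trajectory angle test on synthetic cohorts.

    With ``divergence_deg = 0`` the sexes share the generating allometric
    vector, so the rate is the test's size (should be ~alpha or below);
    with a large divergence and low noise it is the power.
    """
    rejections = 0
    for i in range(n_replicates):
        params = default_params(landmark_noise_sd=noise_sd,
                                trajectory_divergence_deg=divergence_deg)
        coh = generate_cohort(n, params=params, seed=seed * 100_003 + i,
                              build_meshes=False)
        res = gpa(coh.landmark_sets())
        sex = coh.metadata["sex"].to_numpy()
        f = sex == "F"
        comp = trajectory_angle_test(
            res.shape_coordinates[f], res.ln_cs[f],
            res.shape_coordinates[~f], res.ln_cs[~f],
            n_perm=n_perm, seed=seed * 7 + i, labels=("F", "M"))
        rejections += comp.p_value <= alpha
    return rejections / n_replicates


@dataclass
class RecoveryResult:
    angle_deg: float  # estimated vs generating allometric vector
    r_squared: float  # shape ~ Ln(CS)
    pc1_lncs_loading: float  # form-space PC1 loading on the Ln(CS) column


def allometric_recovery(n: int = 200, noise_sd: float = 0.1,
                        seed: int = 0,
                        params: GrowthParams | None = None
                        ) -> RecoveryResult:
    """Recover the generating allometric vector from a synthetic cohort.

    Regresses pooled-sex GPA shape coordinates on Ln(CS) and measures the
    angle between the estimated coefficient vector and the generator's
    stored vector (restricted to the 86 superimposed landmarks).  The GPA
    output frame is arbitrary, so the coefficient vector is first rotated
    by the ordinary-Procrustes rotation taking the GPA mean onto the
    template shape.  Also reports the form-space PC1 loading on Ln(CS).
    """
    from .procrustes import _optimal_rotation

    if params is None:
        params = default_params(landmark_noise_sd=noise_sd)
    coh = generate_cohort(n, params=params, seed=seed, build_meshes=False)
    res = gpa(coh.landmark_sets())
    reg = multivariate_regression(res.shape_coordinates, res.ln_cs,
                                  n_perm=0)
    keep = ~coh.specimens[0].landmarks.gpa_excluded
    truth = params.allometric_vector[keep]
    truth = truth / np.linalg.norm(truth)
    from .synthetic import _template_landmarks

    template = _template_landmarks(params).coords[keep]
    template = template - template.mean(axis=0)
    template /= np.linalg.norm(template)
    R = _optimal_rotation(res.mean_shape, template, allow_reflection=False)
    est = reg.unit_vector.reshape(-1, 3) @ R
    cos = abs(float(est.reshape(-1) @ truth.reshape(-1)))
    angle = float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
    form_pc = pca(form_matrix(res))
    return RecoveryResult(
        angle_deg=angle,
        r_squared=reg.r_squared,
        pc1_lncs_loading=float(abs(form_pc.loadings[-1, 0])),
    )
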