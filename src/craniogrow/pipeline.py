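"""Config-driven orchestration of the full analysis battery.

``run_study`` executes: cohort generation (or loading) -> semilandmark
template -> projection + sliding -> GPA -> measurements and cavity
volumes -> form-space and volume PCAs -> per-sex multivariate regressions
with trajectory-angle comparisons -> two-block PLS (cranium / face /
neurocranium shape vs CPVols; form vs CVols) -> regression warps with
per-face area-change maps; and writes CSV reports plus a provenance JSON.
A single global seed fans out to named substreams so each stage is
independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .craniometrics import VOLUME_NAMES, measurement_report
from .landmarks import LandmarkSet
from .meshgeom import area_change_map, make_mesh, write_face_scalar_ply
from .morphostats import (DEFAULT_AGE_GROUP_EDGES, assign_age_groups,
                          form_matrix, group_means, multivariate_regression,
                          pca, trajectory_angle_test, two_block_pls,
                          warp_along_regression)
from .procrustes import gpa
from .semilandmarks import (DEFAULT_PATCH_COUNTS, build_template,
                            project_template, slide_semilandmarks)
from .synthetic import (default_params, generate_cohort, make_template_skull,
                        write_cohort)
from .tps import tps_fit

__all__ = ["RunConfig", "run_study", "StageError"]


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage and specimen id."""

    def __init__(self, stage: str, specimen: str | None, cause: Exception):
        self.stage = stage
        self.specimen = specimen
        at = f" (specimen {specimen})" if specimen else ""
        super().__init__(f"stage {stage!r}{at}: {cause}")


@dataclass
class RunConfig:
    """Study configuration; defaults reproduce the study settings
    (patch counts 100/1000/52 one-sided, 1000 permutations)."""

    n_specimens: int = 40
    resolution: int = 3
    seed: int = 0
    sex_ratio: float = 123.0 / 217.0
    landmark_noise_sd: float = 0.5
    trajectory_divergence_deg: float = 0.0
    patch_counts: dict = field(
        default_factory=lambda: dict(DEFAULT_PATCH_COUNTS))
    slide_iterations: int = 3
    slide_tol: float = 1e-6
    slide_against_mean: bool = False
    age_group_edges: tuple = DEFAULT_AGE_GROUP_EDGES
    n_permutations: int = 1000
    output_dir: str = "results/study"
    write_meshes: bool = False
    cohort_dir: str | None = None  # load a written cohort instead

    def validate(self) -> None:
        if self.n_specimens < 2:
            raise ValueError("n_specimens must be >= 2")
        if self.resolution < 2:
            raise ValueError("resolution must be >= 2")
        if not 0 < self.sex_ratio < 1:
            raise ValueError("sex_ratio must be in (0, 1)")
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark_noise_sd must be >= 0")
        if set(self.patch_counts) != set(DEFAULT_PATCH_COUNTS):
            raise ValueError(f"patch_counts must name "
                             f"{sorted(DEFAULT_PATCH_COUNTS)}")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.age_group_edges, list):
            cfg.age_group_edges = tuple(cfg.age_group_edges)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["age_group_edges"] = list(self.age_group_edges)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seed(seed: int, stage: int) -> int:
    return int((seed * 1_000_003 + stage) % (2 ** 31 - 1))


_CSV_FMT = "%.12g"


def run_study(config: RunConfig) -> dict:
    """Run the full battery; returns a dict of in-memory results and
    writes all report files under ``config.output_dir``.  Warnings raised
    during the run are recorded in the provenance log."""
    import warnings as _warnings

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        return _run_study(config, caught)


def _run_study(config: RunConfig, _caught: list) -> dict:
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    # --- cohort -----------------------------------------------------------
    stage = "generate_cohort"
    try:
        params = default_params(
            landmark_noise_sd=config.landmark_noise_sd,
            trajectory_divergence_deg=config.trajectory_divergence_deg)
        cohort = generate_cohort(
            config.n_specimens, params=params, sex_ratio=config.sex_ratio,
            seed=_stage_seed(config.seed, 1), resolution=config.resolution)
        template_specimen = make_template_skull(config.resolution, params)
    except Exception as exc:
        raise StageError(stage, None, exc) from exc
    cohort.metadata.to_csv(out / "metadata.csv", index=False,
                           float_format=_CSV_FMT)
    if config.write_meshes:
        write_cohort(cohort, out / "cohort")

    # --- semilandmark template -------------------------------------------
    stage = "build_template"
    try:
        template = build_template(
            template_specimen.mesh, template_specimen.landmarks,
            counts=config.patch_counts, seed=_stage_seed(config.seed, 2))
    except Exception as exc:
        raise StageError(stage, None, exc) from exc

    # --- project + slide per specimen ------------------------------------
    # sliding anchors are the 86 superimposition landmarks; the Euryon
    # pair stays out of the bending-energy reference just as it stays out
    # of GPA, but is carried through for linear measurements
    anchor_keep = ~template.anchor_landmarks.gpa_excluded
    reference_config = np.vstack([
        template.anchor_landmarks.coords[anchor_keep],
        template.slm_points])
    template_full = template.full_configuration()
    full_sets: list[LandmarkSet] = []
    for s in cohort.specimens:
        stage = "slide_semilandmarks"
        try:
            init = project_template(template, s.mesh, s.landmarks)
            slid = slide_semilandmarks(
                init, s.mesh, s.landmarks.coords[anchor_keep],
                reference_config,
                max_iter=config.slide_iterations, tol=config.slide_tol)
            coords = np.vstack([s.landmarks.coords, slid.slid_points])
            full_sets.append(template_full.with_coords(coords))
        except Exception as exc:
            raise StageError(stage, s.specimen_id, exc) from exc

    # --- GPA --------------------------------------------------------------
    stage = "gpa"
    try:
        gpa_res = gpa(full_sets, exclude_flagged=True)
        if config.slide_against_mean:
            # optional second pass: slide against the sample mean form
            mean_ref = gpa_res.mean_shape * float(
                np.exp(gpa_res.ln_cs.mean()))
            n_lm = len(template.anchor_landmarks)
            for i, s in enumerate(cohort.specimens):
                slid = slide_semilandmarks(
                    full_sets[i].coords[n_lm:], s.mesh,
                    s.landmarks.coords[anchor_keep], mean_ref,
                    max_iter=config.slide_iterations, tol=config.slide_tol)
                coords = np.vstack([s.landmarks.coords, slid.slid_points])
                full_sets[i] = full_sets[i].with_coords(coords)
            gpa_res = gpa(full_sets, exclude_flagged=True)
    except Exception as exc:
        raise StageError(stage, None, exc) from exc

    # --- measurements -----------------------------------------------------
    stage = "measurements"
    try:
        meas = measurement_report(cohort)
    except Exception as exc:
        raise StageError(stage, None, exc) from exc
    meas.to_csv(out / "measurements.csv", float_format=_CSV_FMT)

    ages = cohort.metadata["age_months"].to_numpy(float)
    sexes = cohort.metadata["sex"].to_numpy()
    labels = assign_age_groups(ages, config.age_group_edges)
    ln_cs = gpa_res.ln_cs
    shape = gpa_res.shape_coordinates
    form = form_matrix(gpa_res)
    cvols = meas[[f"C{n}" for n in VOLUME_NAMES]].to_numpy(float)
    cpvols = meas[[f"CP{n}" for n in VOLUME_NAMES]].to_numpy(float)

    # --- PCAs -------------------------------------------------------------
    stage = "pca"
    try:
        form_pca = pca(form)
        cvols_pca = pca(cvols)
    except Exception as exc:
        raise StageError(stage, None, exc) from exc
    pd.DataFrame({
        "component": np.arange(1, len(form_pca.variance_fractions) + 1),
        "variance_fraction": form_pca.variance_fractions,
    }).to_csv(out / "form_pca_variance.csv", index=False,
              float_format=_CSV_FMT)
    pd.DataFrame({
        "quantity": ["form_pc1_lncs_loading"],
        "value": [abs(form_pca.loadings[-1, 0])],
    }).to_csv(out / "form_pca_summary.csv", index=False,
              float_format=_CSV_FMT)
    pd.DataFrame(
        cvols_pca.loadings[:, :2], index=list(VOLUME_NAMES),
        columns=["PC1", "PC2"],
    ).rename_axis("volume").to_csv(out / "cvols_pca_loadings.csv",
                                   float_format=_CSV_FMT)
    pd.DataFrame({
        "component": np.arange(1, len(cvols_pca.variance_fractions) + 1),
        "variance_fraction": cvols_pca.variance_fractions,
    }).to_csv(out / "cvols_pca_variance.csv", index=False,
              float_format=_CSV_FMT)
    gm = group_means(form_pca.scores[:, :2], labels, sexes)
    gm.columns = ["PC1", "PC2"]
    gm.to_csv(out / "form_pca_group_means.csv", float_format=_CSV_FMT)

    # --- regressions & trajectory comparisons -----------------------------
    stage = "regressions"
    analyses = [
        ("shape_vs_lncs", shape, ln_cs),
        ("shape_vs_age", shape, ages),
        ("form_vs_lncs", form, ln_cs),
        ("form_vs_age", form, ages),
        ("cvols_vs_lncs", cvols, ln_cs),
        ("cvols_vs_age", cvols, ages),
        ("cpvols_vs_lncs", cpvols, ln_cs),
        ("cpvols_vs_age", cpvols, ages),
    ]
    rows = []
    try:
        f_mask = sexes == "F"
        m_mask = ~f_mask
        for i, (name, Y, x) in enumerate(analyses):
            reg_f = multivariate_regression(
                Y[f_mask], x[f_mask], n_perm=config.n_permutations,
                seed=_stage_seed(config.seed, 10 + 3 * i))
            reg_m = multivariate_regression(
                Y[m_mask], x[m_mask], n_perm=config.n_permutations,
                seed=_stage_seed(config.seed, 11 + 3 * i))
            comp = trajectory_angle_test(
                Y[f_mask], x[f_mask], Y[m_mask], x[m_mask],
                n_perm=config.n_permutations,
                seed=_stage_seed(config.seed, 12 + 3 * i),
                labels=("F", "M"))
            rows.append({
                "analysis": name,
                "r2_female": reg_f.r_squared, "p_female": reg_f.p_value,
                "r2_male": reg_m.r_squared, "p_male": reg_m.p_value,
                "angle_deg": comp.angle_deg, "p_angle": comp.p_value,
            })
    except Exception as exc:
        raise StageError(stage, None, exc) from exc
    table1 = pd.DataFrame(rows)
    table1.to_csv(out / "trajectory_comparisons.csv", index=False,
                  float_format=_CSV_FMT)

    # --- two-block PLS ----------------------------------------------------
    stage = "pls"
    n_lm_used = len(gpa_res.used_names) - template.n_slm
    slm_cols = np.zeros(form.shape[1] - 1, dtype=bool)
    slm_cols[3 * n_lm_used:] = True

    def module_cols(module):
        mask = np.zeros_like(slm_cols)
        mm = template.module_mask(module)
        sl = np.repeat(mm, 3)
        mask[3 * n_lm_used:] = sl
        return mask

    pls_rows = []
    try:
        pls_specs = [
            ("cranium_vs_cpvols", shape[:, slm_cols], cpvols),
            ("face_vs_cpvols", shape[:, module_cols("face")], cpvols),
            ("neurocranium_vs_cpvols",
             shape[:, module_cols("neurocranium")], cpvols),
            ("form_vs_cvols", form, cvols),
        ]
        for i, (name, b1, b2) in enumerate(pls_specs):
            res = two_block_pls(b1, b2, n_perm=config.n_permutations,
                                seed=_stage_seed(config.seed, 40 + i))
            pls_rows.append({
                "analysis": name,
                "r_axis1": res.score_correlations[0],
                "covariance_percent_axis1": res.covariance_percent[0],
                "var_block1_percent": res.var_block1_percent,
                "p_value": res.p_value,
            })
    except Exception as exc:
        raise StageError(stage, None, exc) from exc
    pd.DataFrame(pls_rows).to_csv(out / "pls_summary.csv", index=False,
                                  float_format=_CSV_FMT)

    # --- warps + area-change maps ----------------------------------------
    stage = "warps"
    try:
        reg_pool = multivariate_regression(shape, ln_cs, n_perm=0)
        lo, hi = float(ln_cs.min()), float(ln_cs.max())
        shape_lo = warp_along_regression(reg_pool, lo)
        shape_hi = warp_along_regression(reg_pool, hi)
        ref_full = np.vstack([template.anchor_landmarks.coords,
                              template.slm_points])
        used_mask = np.concatenate([
            ~template.anchor_landmarks.gpa_excluded,
            np.ones(template.n_slm, dtype=bool)])
        src = ref_full[used_mask]
        mesh_lo = make_mesh(
            tps_fit(src, shape_lo).apply(
                template_specimen.mesh.vertices.view(np.ndarray)),
            template_specimen.mesh.faces)
        mesh_hi = make_mesh(
            tps_fit(src, shape_hi).apply(
                template_specimen.mesh.vertices.view(np.ndarray)),
            template_specimen.mesh.faces)
        amap = area_change_map(mesh_lo, mesh_hi)
    except Exception as exc:
        raise StageError(stage, None, exc) from exc
    amap.to_dataframe().to_csv(out / "area_change_map.csv", index=False,
                               float_format=_CSV_FMT)
    pd.DataFrame({
        "quantity": ["area_change_min_percent", "area_change_max_percent"],
        "value": list(amap.range),
    }).to_csv(out / "area_change_summary.csv", index=False,
              float_format=_CSV_FMT)
    if config.write_meshes:
        mesh_lo.export(out / "warp_min_lncs.ply", encoding="ascii")
        mesh_hi.export(out / "warp_max_lncs.ply", encoding="ascii")
        write_face_scalar_ply(mesh_hi, amap.percent,
                              out / "area_change_on_target.ply")

    # --- provenance -------------------------------------------------------
    warnings_log.extend(sorted({str(w.message) for w in _caught}))
    prov = {
        "package_version": __version__,
        "config": json.loads(json.dumps(asdict(config), default=list)),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_slm": int(template.n_slm),
        "n_gpa_points": int(gpa_res.n_points),
        "warnings": warnings_log,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=1, sort_keys=True)

    return {
        "cohort": cohort,
        "template": template,
        "gpa": gpa_res,
        "measurements": meas,
        "form_pca": form_pca,
        "cvols_pca": cvols_pca,
        "table1": table1,
        "pls": pd.DataFrame(pls_rows),
        "area_change": amap,
    }
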