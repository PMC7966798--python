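"""End-to-end analysis pipeline with persisted, reproducible outputs.

Stage order follows the analysis workflow: align (GPA) -> slide
semilandmarks -> symmetrize -> residualize optional covariates -> SShD
scores and allometric decomposition -> disparity and permutation tests ->
trajectory analysis -> preference models.  Every stochastic stage takes an
explicit seed from the config, the config is persisted verbatim next to the
outputs, and reruns with the same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from . import resampling as rs
from . import sshd as sc
from . import preference as pref
from .superimpose import (
    AlignedDataset,
    detect_outliers,
    gpa,
    slide_semilandmarks,
    symmetrize,
)
from .synthetic import default_spec, generate_dataset

__all__ = ["RunConfig", "run_pipeline", "write_aligned", "read_aligned"]

logger = logging.getLogger(__name__)

_META_COLS = ["id", "sex", "population", "height", "weight", "focal_length",
              "attractiveness"]


def write_aligned(aligned: AlignedDataset, csv_path: str | Path) -> None:
    """Persist an aligned dataset as wide CSV + JSON provenance sidecar."""
    csv_path = Path(csv_path)
    coord = aligned.to_frame().drop(columns=["id"])
    meta = aligned.meta.reindex(columns=_META_COLS)
    pd.concat([meta.reset_index(drop=True), coord], axis=1).to_csv(
        csv_path, index=False
    )
    sidecar = {
        "provenance": aligned.provenance(),
        "consensus": aligned.consensus.tolist(),
        "k": aligned.k,
    }
    csv_path.with_suffix(".provenance.json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_aligned(csv_path: str | Path,
                 template: dio.LandmarkTemplate) -> AlignedDataset:
    """Load an aligned dataset written by :func:`write_aligned`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, dtype={"id": str})
    sidecar = json.loads(
        csv_path.with_suffix(".provenance.json").read_text()
    )
    k = sidecar["k"]
    shapes = np.empty((len(df), 2 * k))
    for j in range(k):
        shapes[:, 2 * j] = df[f"x{j + 1}"]
        shapes[:, 2 * j + 1] = df[f"y{j + 1}"]
    prov = sidecar["provenance"]
    return AlignedDataset(
        shapes=shapes,
        centroid_sizes=df["centroid_size"].to_numpy(),
        consensus=np.asarray(sidecar["consensus"]),
        meta=df[[c for c in _META_COLS if c in df.columns]].copy(),
        template=template,
        slid=prov["slid"],
        symmetrized=prov["symmetrized"],
        residualized_on=tuple(prov["residualized_on"]),
        gpa_iterations=prov["gpa_iterations"],
    )


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``tps_path``/``metadata_path``/``template_path`` point at input
    files, or ``synthetic=True`` generates the default synthetic study.
    """

    output_dir: str = "dimorph_run"
    # inputs
    synthetic: bool = True
    synthetic_n_populations: int = 8
    synthetic_n_per_sex: int = 100
    tps_path: str | None = None
    metadata_path: str | None = None
    template_path: str | None = None
    flip_y: bool = False
    # superimposition
    gpa_tol: float = 1e-10
    gpa_max_iter: int = 100
    project_to_tangent: bool = True
    slide: bool = True
    slide_iterations: int = 3
    do_symmetrize: bool = True
    outlier_multiplier: float = 1.5
    # analysis
    scope: str = "per-population"
    residualize: tuple[str, ...] = ()  # e.g. ("log_focal_length", "weight")
    region_of: dict = field(default_factory=dict)
    focal_region: str | None = None
    n_perm_disparity: int = 999
    n_perm_trajectory: int = 999
    n_perm_randomization: int = 999
    seed: int = 1

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "residualize" in data and data["residualize"] is not None:
            data["residualize"] = tuple(data["residualize"])
        return cls(**data)


def _residualize(aligned: AlignedDataset, covariate: str) -> AlignedDataset:
    """Partial a covariate out of the aligned shapes (residuals + mean)."""
    if covariate == "log_focal_length":
        vals = np.log(aligned.meta["focal_length"].to_numpy(dtype=float))
    elif covariate in aligned.meta.columns:
        vals = aligned.meta[covariate].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown covariate {covariate!r}")
    ok = np.isfinite(vals)
    if not ok.all():
        raise ValueError(
            f"covariate {covariate!r} missing for {int((~ok).sum())} rows; "
            "drop them before residualizing"
        )
    _, resid, _ = sc.regress_shape_on_covariate(aligned.shapes, vals)
    shapes = resid + aligned.shapes.mean(axis=0)
    return dataclasses.replace(
        aligned,
        shapes=shapes,
        consensus=shapes.mean(axis=0),
        residualized_on=aligned.residualized_on + (covariate,),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the machine-readable summary.

    Writes into ``config.output_dir``: the verbatim config, aligned shapes,
    per-individual score table, angle summary, disparity tables, trajectory
    and permutation results, the preference-model table, and
    ``summary.json``.  Stage timings go to the log.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"seed": config.seed, "stages": {}}
    t_all = time.perf_counter()

    def _stage(name):
        t = time.perf_counter()

        def done():
            dt = time.perf_counter() - t
            summary["stages"][name] = round(dt, 3)
            logger.info("stage %s: %.2fs", name, dt)

        return done

    # ---- input ----------------------------------------------------------
    done = _stage("input")
    if config.synthetic:
        spec = default_spec(
            seed=config.seed,
            n_populations=config.synthetic_n_populations,
            n_per_sex=config.synthetic_n_per_sex,
        )
        data = generate_dataset(spec)
        configs, metadata, template = data.configs, data.metadata, data.template
        summary["input"] = {"kind": "synthetic", "n": len(configs)}
    else:
        configs = dio.read_tps(config.tps_path, flip_y=config.flip_y)
        metadata = dio.read_metadata(config.metadata_path)
        template = dio.read_template(config.template_path)
        summary["input"] = {"kind": "files", "n": len(configs)}
    raw = dio.assemble_dataset(configs, metadata, template)
    raw.counts.to_csv(out / "counts.csv", index=False)
    done()

    # ---- superimposition -------------------------------------------------
    done = _stage("align")
    aligned = gpa(raw, tol=config.gpa_tol, max_iter=config.gpa_max_iter,
                  project_to_tangent=config.project_to_tangent)
    if config.slide and template.semilandmark_indices:
        aligned = slide_semilandmarks(aligned,
                                      iterations=config.slide_iterations)
    if config.do_symmetrize and template.bilateral_pairs:
        aligned = symmetrize(aligned)
    for cov in config.residualize:
        aligned = _residualize(aligned, cov)
    write_aligned(aligned, out / "aligned.csv")
    outliers = detect_outliers(aligned, config.outlier_multiplier)
    (out / "outliers.json").write_text(json.dumps(outliers))
    summary["superimposition"] = {
        **aligned.provenance(),
        "n_outliers_flagged": len(outliers),
    }
    done()

    # ---- SShD decomposition ----------------------------------------------
    done = _stage("sshd")
    heights = aligned.meta["height"].to_numpy(dtype=float)
    result = None
    if np.isfinite(heights).sum() >= 4:
        result = sc.allometric_decomposition(aligned, scope=config.scope)
        result.to_frame().to_csv(out / "scores.csv", index=False)
        (out / "angles.json").write_text(
            json.dumps(result.angles_summary(), indent=1)
        )
        if result.per_population is not None:
            result.per_population.to_csv(out / "sshd_per_population.csv",
                                         index=False)
        summary["sshd"] = result.angles_summary()
    done()

    # ---- disparity -------------------------------------------------------
    done = _stage("disparity")
    sex = aligned.meta["sex"].to_numpy()
    popl = aligned.meta["population"].to_numpy()
    group = np.char.add(np.char.add(popl.astype(str), ":"), sex.astype(str))
    disp_groups = rs.morphological_disparity(
        aligned.shapes, group, n_perm=config.n_perm_disparity,
        seed=config.seed + 1,
    )
    disp_total = rs.morphological_disparity(
        aligned.shapes, popl, n_perm=config.n_perm_disparity,
        seed=config.seed + 2,
    )
    disp_nosex = rs.morphological_disparity(
        aligned.shapes, popl, partial_out_group_means=True, sex=sex,
        n_perm=config.n_perm_disparity, seed=config.seed + 3,
    )
    for name, d in (("disparity_by_population_sex", disp_groups),
                    ("disparity_total", disp_total),
                    ("disparity_without_sex", disp_nosex)):
        frames = d.to_frames()
        frames["variances"].to_csv(out / f"{name}.csv", index=False)
        if "pairwise_p" in frames:
            frames["pairwise_p"].to_csv(out / f"{name}_pairwise_p.csv")
    summary["disparity"] = {
        "by_population": dict(zip(disp_total.groups,
                                  disp_total.variances.tolist())),
        "by_population_without_sex": dict(
            zip(disp_nosex.groups, disp_nosex.variances.tolist())
        ),
    }
    done()

    # ---- trajectory analysis ---------------------------------------------
    done = _stage("trajectory")
    traj = sc.trajectory_analysis(aligned, n_perm=config.n_perm_trajectory,
                                  seed=config.seed + 4)
    for name, frame in traj.to_frames().items():
        frame.to_csv(out / f"trajectory_{name}.csv",
                     index=name != "magnitudes")
    summary["trajectory"] = {
        "magnitudes": dict(zip(traj.populations, traj.magnitudes.tolist())),
    }
    done()

    # ---- regional median-distance contrast -------------------------------
    if config.focal_region and result is not None:
        done = _stage("median_distance")
        raw_scores = sc.sexscore(
            aligned.shapes,
            sc.sex_difference_vector(aligned.shapes, sex),
        )

        def contrast_stat(pop_labels: np.ndarray) -> float:
            return rs.median_distance_statistic(
                raw_scores, sex, pop_labels, config.region_of,
                config.focal_region,
            )["contrast"]

        perm = rs.randomization_test(
            contrast_stat, popl, sex, n_perm=config.n_perm_randomization,
            seed=config.seed + 5, label="median_distance_contrast",
        )
        summary["median_distance"] = {
            "contrast": perm.observed,
            "p_value": perm.p_value,
            "null_mean": perm.null_mean,
            "null_sd": perm.null_sd,
        }
        done()

    # ---- preference models -----------------------------------------------
    ratings = aligned.meta["attractiveness"].to_numpy(dtype=float)
    if result is not None and np.isfinite(ratings).sum() >= 8:
        done = _stage("preference")
        frame = result.to_frame()
        # decomposition kept rows with finite height, in aligned order
        frame["rating"] = ratings[np.isfinite(heights)]
        std_scores = pref.standardize_ratings(
            frame["score_overall"].to_numpy(), frame["population"].to_numpy()
        )
        lmm = pref.fit_attractiveness_lmm(
            std_scores, frame["rating"].to_numpy(),
            frame["sex"].to_numpy(), frame["population"].to_numpy(),
        )
        lmm.to_frame().to_csv(out / "preference_model.csv", index=False)
        summary["preference"] = {
            "fixed_effects": {
                t: round(v, 6)
                for t, v in lmm.fixed_effects["estimate"].items()
            },
            "converged": lmm.converged,
            "singular": lmm.singular,
            "method": lmm.method,
        }
        # population-level Bayesian regression: sex height gap vs ||v1_p||
        if result.per_population is not None and len(traj.populations) >= 3:
            hgap = []
            for p in traj.populations:
                mask = popl == p
                hm = heights[mask & (sex == "male")]
                hf = heights[mask & (sex == "female")]
                hgap.append(np.nanmean(hm) - np.nanmean(hf))
            x = np.asarray(hgap)
            y = traj.magnitudes
            xs = (x - x.mean()) / x.std(ddof=1)
            ys = (y - y.mean()) / y.std(ddof=1)
            quap = pref.bayes_linear_quap(xs, ys)
            summary["bayes_height_vs_dimorphism"] = {
                "slope_map": float(quap.map_estimate[1]),
                "slope_sd": float(quap.posterior_sd[1]),
                "slope_89": quap.interval_89[1].tolist(),
            }
        done()

    summary["runtime_s"] = round(time.perf_counter() - t_all, 3)
    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True,
                   default=lambda o: o.item() if hasattr(o, "item") else str(o))
    )
    return json.loads((out / "summary.json").read_text())
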