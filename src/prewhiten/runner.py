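"""Experiment enumeration, the evaluation battery, and NIfTI-1 I/O.

A battery crosses synthetic datasets (grid + noise model + optional true
design) with assumed designs and pre-whitening methods, runs the full
first-level pipeline per subject (simulate, build design, OLS, estimate
noise model, pre-whitened refit, residual spectra, smoothness, cluster
inference), aggregates the comparison metrics (percent significant
voxels, positive rate, pooled spectra, flatness), and runs the two group
models on the first-level coefficient and standard-error maps.

Every (dataset, design) pair is classified as null (rest data, or task
data analyzed under a design other than its true one) or true-design;
on null data the positive rate is the familywise error rate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .core import VolumeSeries
from .design import build_design_matrix
from .diagnostics import pool_spectra, residual_power_spectrum, flatness_metrics
from .inference import (DEFAULT_CDT, estimate_smoothness, grf_cluster_inference,
                        group_mixed_effects, group_summary_statistic,
                        percent_significant, positive_rate)
from .simulate import (DesignSpec, GridSpec, NoiseSpec, boxcar,
                       gen_design_timeline, gen_resting_volume, gen_task_volume)
from .whiten import estimate_model, fit_ols, prewhitened_glm

logger = logging.getLogger(__name__)

GROUP_MODELS = ("summary", "mixed")


@dataclass
class DatasetSpec:
    """One synthetic dataset: geometry, noise, cohort size, optional task."""

    name: str
    grid: GridSpec
    noise: NoiseSpec
    n_subjects: int
    true_design: DesignSpec | None = None
    designs: list = field(default_factory=list)  # assumed designs to test
    effect_size: float = 0.0                      # percent signal, task datasets

    @property
    def is_task(self) -> bool:
        return self.true_design is not None


def default_boxcar_designs() -> list:
    """The 16 assumed block designs: boxcar10 plus boxcar12..40 in 2 s steps."""
    return [boxcar(10)] + [boxcar(k) for k in range(12, 41, 2)]


@dataclass
class BatteryConfig:
    """Full factorial evaluation battery."""

    datasets: list
    methods: list = field(default_factory=lambda: ["none", "spm_ar1wn",
                                                   "afni_arma11", "fsl_tukey",
                                                   "fast"])
    group_models: list = field(default_factory=lambda: list(GROUP_MODELS))
    alpha: float = 0.05
    cdt: float = DEFAULT_CDT
    group_n: int = 20
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.datasets or not self.methods or not self.group_models:
            raise ValueError("datasets, methods and group_models must be non-empty")
        for ds in self.datasets:
            if not ds.designs:
                raise ValueError(f"dataset {ds.name!r} has no assumed designs")


@dataclass(frozen=True)
class AnalysisDescriptor:
    """One group-level analysis cell of the factorial battery."""

    group_model: str
    method: str
    dataset: str
    design_label: str
    is_null: bool


def _is_null(ds: DatasetSpec, design: DesignSpec) -> bool:
    return (ds.true_design is None
            or design.label != ds.true_design.label)


def enumerate_experiment(config: BatteryConfig) -> list:
    """Full factorial expansion in deterministic order.

    One descriptor per (group model x method x dataset x assumed
    design); e.g. 2 group models x 4 methods x (10 datasets x 16
    designs + 1 dataset x 4 designs) = 1312 group analyses, 164 per
    (group model, method) combination.
    """
    descriptors = []
    for gm in config.group_models:
        for method in config.methods:
            for ds in config.datasets:
                for design in ds.designs:
                    descriptors.append(AnalysisDescriptor(
                        group_model=gm, method=method, dataset=ds.name,
                        design_label=design.label,
                        is_null=_is_null(ds, design)))
    return descriptors


def count_analyses(config: BatteryConfig) -> dict:
    """Closed-form battery size summary."""
    desc = enumerate_experiment(config)
    per_combo = sum(len(ds.designs) for ds in config.datasets)
    n_null = sum(1 for d in desc
                 if d.group_model == config.group_models[0]
                 and d.method == config.methods[0] and d.is_null)
    return {"n_group_analyses": len(desc),
            "n_per_combo": per_combo,
            "n_null_per_combo": n_null}


def subject_seed(master_seed: int, dataset_index: int, subject_index: int) -> int:
    """Reproducible, independent per-subject seeds (kept below 2^31)."""
    return (master_seed + dataset_index * 10_000 + subject_index) % (2**31 - 1)


@dataclass
class EvaluationReport:
    """Aggregated battery outputs.

    ``first_level``: one row per (method, dataset, design) with percent
    significant voxels (mean over subjects), positive rate and CI, and
    the flatness metrics of the pooled residual spectrum.
    ``group_level``: one row per (group model, method, dataset, design)
    with the group cluster summary.  ``spectra`` maps
    (method, dataset, design) to the pooled PowerSpectrum.
    """

    first_level: pd.DataFrame
    group_level: pd.DataFrame
    spectra: dict
    config_echo: dict

    def to_dir(self, outdir) -> None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.first_level.to_csv(out / "first_level.tsv", sep="\t", index=False)
        self.group_level.to_csv(out / "group_level.tsv", sep="\t", index=False)
        (out / "config.json").write_text(json.dumps(self.config_echo, indent=2,
                                                    default=str))
        for (method, ds, design), spec in self.spectra.items():
            spec.to_tsv(out / f"spectrum_{method}_{ds}_{design}.tsv")


def _simulate_subject(ds: DatasetSpec, seed: int) -> VolumeSeries:
    if ds.is_task and ds.effect_size > 0:
        timeline = gen_design_timeline(ds.true_design, ds.grid.duration_s,
                                       seed=seed)
        active = np.zeros(ds.grid.shape, dtype=bool)
        cx, cy, cz = (s // 2 for s in ds.grid.shape)
        active[max(cx - 2, 0):cx + 3, max(cy - 2, 0):cy + 3,
               max(cz - 1, 0):cz + 2] = True
        return gen_task_volume(ds.grid, ds.noise, timeline, ds.effect_size,
                               active, seed)
    return gen_resting_volume(ds.grid, ds.noise, seed)


def run_battery(config: BatteryConfig) -> EvaluationReport:
    """Run the full battery; fully reproducible from ``master_seed``.

    Per-descriptor errors are caught, logged, and recorded in the
    report row so one failing cell cannot abort the battery.
    """
    first_rows: list = []
    group_rows: list = []
    spectra: dict = {}

    for ds_i, ds in enumerate(config.datasets):
        subjects = [_simulate_subject(ds, subject_seed(config.master_seed, ds_i, s))
                    for s in range(ds.n_subjects)]
        mask = subjects[0].mask
        for design in ds.designs:
            timeline = gen_design_timeline(
                design, ds.grid.duration_s,
                seed=subject_seed(config.master_seed, ds_i, 9999))
            X = build_design_matrix(timeline, ds.grid)
            for method in config.methods:
                key = (method, ds.name, design.label)
                t0 = time.time()
                try:
                    res = _first_level_cell(config, ds, subjects, mask, X, method)
                except Exception as exc:  # pragma: no cover - battery resilience
                    logger.exception("first-level cell %s failed", key)
                    first_rows.append({"method": method, "dataset": ds.name,
                                       "design": design.label, "error": str(exc)})
                    continue
                spectra[key] = res["spectrum"]
                flat = flatness_metrics(res["spectrum"])
                pr = res["positive_rate"]
                first_rows.append({
                    "method": method, "dataset": ds.name, "design": design.label,
                    "is_null": _is_null(ds, design),
                    "pct_significant_mean": float(np.mean(res["pct_significant"])),
                    "positive_rate": pr.rate, "ci_low": pr.ci_low,
                    "ci_high": pr.ci_high, "n_subjects": pr.n,
                    "low_excess": flat["low_excess"],
                    "error": "", "seconds": round(time.time() - t0, 2)})
                for gm in config.group_models:
                    try:
                        zg = _group_cell(gm, res, config.group_n)
                        smooth = res["group_smoothness"]
                        zvol = subjects[0].from_matrix(zg)
                        cres = grf_cluster_inference(zvol, mask, smooth,
                                                     cdt=config.cdt,
                                                     alpha=config.alpha)
                        group_rows.append({
                            "group_model": gm, "method": method,
                            "dataset": ds.name, "design": design.label,
                            "is_null": _is_null(ds, design),
                            "n_significant_clusters": cres.n_significant,
                            "pct_significant": percent_significant(
                                cres.sig_mask, mask),
                            "error": ""})
                    except Exception as exc:  # pragma: no cover
                        logger.exception("group cell failed")
                        group_rows.append({"group_model": gm, "method": method,
                                           "dataset": ds.name,
                                           "design": design.label,
                                           "error": str(exc)})

    report = EvaluationReport(
        first_level=pd.DataFrame(first_rows),
        group_level=pd.DataFrame(group_rows),
        spectra=spectra,
        config_echo=_config_echo(config))
    return report


def _first_level_cell(config: BatteryConfig, ds: DatasetSpec, subjects: list,
                      mask: np.ndarray, X, method: str) -> dict:
    """All per-subject analyses for one (dataset, design, method) cell."""
    pcts, cluster_results, subj_spectra = [], [], []
    coef_maps, se_maps = [], []
    smooth_last = None
    for subj in subjects:
        Y = subj.to_matrix()
        fit0 = fit_ols(Y, X)
        model = estimate_model(method, fit0)
        fit = prewhitened_glm(Y, X, model) if method != "none" else fit0
        subj_spectra.append(residual_power_spectrum(fit.residuals, subj.tr))
        resid_vol = VolumeSeries(subj.from_matrix(fit.residuals), subj.tr, mask)
        smooth = estimate_smoothness(resid_vol, mask,
                                     voxel_size=ds.grid.voxel_size)
        zvol = subj.from_matrix(fit.zmap) if fit.zmap is not None else None
        if zvol is not None:
            cres = grf_cluster_inference(zvol, mask, smooth, cdt=config.cdt,
                                         alpha=config.alpha)
            cluster_results.append(cres)
            pcts.append(percent_significant(cres.sig_mask, mask))
        c = X.task_contrast
        if c is not None:
            coef_maps.append(fit.coefficients @ c)
            se_maps.append(fit.se_map)
        smooth_last = smooth
    return {
        "pct_significant": pcts,
        "positive_rate": positive_rate(cluster_results),
        "spectrum": pool_spectra(subj_spectra),
        "coef_maps": np.array(coef_maps),
        "se_maps": np.array(se_maps),
        "group_smoothness": smooth_last,
    }


def _group_cell(group_model: str, res: dict, group_n: int) -> np.ndarray:
    n = min(group_n, res["coef_maps"].shape[0])
    coefs = res["coef_maps"][:n]
    if group_model == "summary":
        return group_summary_statistic(coefs)
    if group_model == "mixed":
        return group_mixed_effects(coefs, res["se_maps"][:n])
    raise ValueError(f"unknown group model {group_model!r}")


def _config_echo(config: BatteryConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj
    return enc(config)


# ---------------------------------------------------------------------------
# NIfTI-1 I/O


def save_bold(vol: VolumeSeries, path, mask_path=None) -> None:
    """Write a 4D NIfTI-1 with TR in the time-dimension pitch."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), np.eye(4))
    zooms = list(img.header.get_zooms())
    zooms[3] = vol.tr
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), np.eye(4)),
                 str(mask_path))


def load_bold(path, tr: float | None = None,
              mask_path=None) -> VolumeSeries:
    """Load a 4D NIfTI-1; TR from the header pitch unless overridden.

    The mask comes from a companion file if given, else from the
    nonzero-variance heuristic.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D BOLD image, got {data.ndim}D: {path}")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not tr > 0:
            raise ValueError(
                "TR missing from NIfTI header; pass tr= explicitly")
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = data.std(axis=3) > 0
    return VolumeSeries(data=data, tr=tr, mask=mask)


def save_map(volume: np.ndarray, path) -> None:
    """Write a 3D statistic map as NIfTI-1."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("save_map expects a 3D array")
    nib.save(nib.Nifti1Image(volume.astype(np.float32), np.eye(4)), str(path))


def load_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)
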