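"""End-to-end pipeline: simulate -> preprocess -> split -> train SOM ->
repeated evaluation -> SOMDI -> NNLS decomposition -> biomarker statistics.

Configuration is a validated, strictly-typed tree (unknown keys rejected);
every stage draws its randomness from a seed derived deterministically from
the global seed and the stage name, so one (config, seed) pair fixes every
number in the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import biomarkers, decompose, preprocess, skinet, synthetic
from .spectra import SpectralMap

__all__ = ["PipelineConfig", "run_pipeline", "report_to_json", "stage_seed"]

log = logging.getLogger("retispec")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: global seed combined with a stable hash of the stage
    name through a SeedSequence; always below 2**31."""
    salt = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return int(np.random.SeedSequence([global_seed, salt]).generate_state(1)[0]
               % (2 ** 31))


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticSection(_Section):
    n_tbi_samples: int = 39
    n_control_samples: int = 12
    spectra_per_sample: int = 400
    axis_start: float = 500.0
    axis_stop: float = 3500.0
    axis_step: float = 1.0
    ratio_median_tbi: float = 2.34
    ratio_iqr_tbi: float = 0.63
    ratio_median_control: float = 0.48
    ratio_iqr_control: float = 0.12
    baseline_amplitude: float = 2.0
    noise_sd: float = 0.02
    cosmic_ray_rate: float = 0.05
    band_jitter_sd: float = 0.05


class PreprocessingSection(_Section):
    despike_z: float = 8.0
    baseline_method: str = "modified_poly"
    n_nodes: int = 11
    poly_order: int = 9
    noise_tolerance: float = 1.50
    normalization: str = "snv"
    region_lo: float = 2800.0
    region_hi: float = 3200.0


class SkinetSection(_Section):
    rows: int = 10
    cols: int = 10
    epochs: int = 9
    steps: Optional[int] = None
    alpha0: float = 0.3
    test_fraction: float = 0.2
    n_repeats: int = 10


class DecompositionSection(_Section):
    range_lo: float = 1200.0
    range_hi: float = 3000.0
    normalize: bool = True


class BiomarkerSection(_Section):
    half_window: float = 10.0


class PipelineConfig(_Section):
    seed: int = 0
    log_level: str = "INFO"
    synthetic_data: SyntheticSection = SyntheticSection()
    preprocessing: PreprocessingSection = PreprocessingSection()
    skinet: SkinetSection = SkinetSection()
    decomposition: DecompositionSection = DecompositionSection()
    biomarker_stats: BiomarkerSection = BiomarkerSection()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on a simulated cohort and return a structured
    report (plain dicts/lists, JSON-serializable) sufficient to regenerate
    every number from (config, seed)."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    report: dict = {"config": config.model_dump(), "seed": config.seed}

    # --- simulate -----------------------------------------------------------
    cohort_cfg = synthetic.CohortConfig(
        **config.synthetic_data.model_dump(),
        seed=stage_seed(config.seed, "simulate"))
    dataset = _stage("simulate")(synthetic.simulate_cohorts)(cohort_cfg)

    # --- preprocess ---------------------------------------------------------
    pp = config.preprocessing
    bl_cfg = preprocess.BaselineConfig(
        method=pp.baseline_method, n_nodes=pp.n_nodes, poly_order=pp.poly_order,
        noise_tolerance=pp.noise_tolerance)

    @_stage("preprocess")
    def _preprocess():
        # despike within each sample map, then per-sample averages for the
        # biomarker/decomposition track and SNV'd cropped spectra for SKiNET
        sample_means, corrected_blocks = [], []
        for sid, idx in dataset.map.meta.groupby("sample_id").groups.items():
            sub = dataset.map.subset(np.asarray(idx))
            sub = (preprocess.remove_cosmic_rays(sub, pp.despike_z)
                   if len(sub) >= 2 else sub)
            corrected = []
            for spec in sub:
                c, _ = preprocess.subtract_baseline(spec, bl_cfg)
                corrected.append(c.intensity)
            corrected = np.stack(corrected)
            corrected_blocks.append((np.asarray(idx), corrected))
            label = sub.meta["label"].iloc[0]
            sample_means.append((sid, label, corrected.mean(axis=0)))
        full = np.empty_like(dataset.map.intensities)
        for idx, block in corrected_blocks:
            full[idx] = block
        corrected_map = SpectralMap(dataset.map.axis, full, dataset.map.meta)
        return sample_means, corrected_map

    sample_means, corrected_map = _preprocess()
    axis = corrected_map.axis

    # --- SKiNET track -------------------------------------------------------
    sk = config.skinet

    @_stage("skinet")
    def _skinet():
        region = (pp.region_lo, pp.region_hi)
        sel = (axis >= region[0]) & (axis <= region[1])
        X = corrected_map.intensities[:, sel]
        if pp.normalization == "snv":
            X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        labels = corrected_map.meta["label"].to_numpy()
        tr, te = skinet.stratified_split(
            labels, sk.test_fraction, seed=stage_seed(config.seed, "split"))
        som_cfg = skinet.SOMConfig(rows=sk.rows, cols=sk.cols, epochs=sk.epochs,
                                   steps=sk.steps, alpha0=sk.alpha0,
                                   seed=stage_seed(config.seed, "train"))
        evaluation = skinet.evaluate_repeated(
            som_cfg, X[tr], labels[tr], X[te], labels[te], n_repeats=sk.n_repeats)
        model = skinet.train(som_cfg, X[tr], labels[tr], axis=axis[sel])
        profiles = skinet.somdi(model)
        return evaluation, profiles

    evaluation, profiles = _skinet()
    cm = evaluation["confusion"]
    report["confusion_matrix"] = {
        "class_names": [str(c) for c in cm.class_names],
        "counts": cm.counts.tolist(),
        "per_repeat_accuracy": evaluation["accuracies"].tolist(),
    }
    metrics = biomarkers.confusion_metrics(
        cm.counts[::-1][:, ::-1] if str(cm.class_names[0]) == "control"
        else cm.counts)
    report["classification_metrics"] = {
        "sensitivity": metrics.sensitivity, "specificity": metrics.specificity,
        "accuracy": metrics.accuracy, "undefined": list(metrics.undefined)}
    report["somdi"] = {
        "axis": profiles.axis.tolist(),
        "profiles": {str(c): profiles.profiles[i].tolist()
                     for i, c in enumerate(profiles.class_names)},
        "top_peaks": {str(c): profiles.peaks[c][:5]
                      for c in profiles.class_names},
    }

    # --- decomposition track ------------------------------------------------
    dc = config.decomposition

    @_stage("decompose")
    def _decompose():
        lib = synthetic.make_component_library(
            np.arange(dc.range_lo, dc.range_hi + 1.0))
        rows = []
        for sid, label, mean_int in sample_means:
            fit = decompose.nnls_fit(
                decompose.average_spectrum(
                    SpectralMap(axis, mean_int[None, :]), {"sample_id": sid}),
                lib, dc.range_lo, dc.range_hi, normalize=dc.normalize)
            row = {"sample_id": sid, "label": label,
                   "residual_norm": fit.residual_norm}
            row.update({n: float(c) for n, c in zip(fit.names, fit.coefficients)})
            rows.append(row)
        table = pd.DataFrame(rows)
        effects = decompose.compare_groups(
            table.drop(columns=["sample_id", "residual_norm"]))
        return table, effects

    coef_table, effects = _decompose()
    report["nnls_coefficients"] = coef_table.to_dict(orient="records")
    report["nnls_group_comparison"] = effects.to_dict(orient="records")

    # --- biomarker track ----------------------------------------------------
    bm = config.biomarker_stats

    @_stage("biomarkers")
    def _biomarkers():
        rows = []
        for sid, label, mean_int in sample_means:
            spec = SpectralMap(axis, mean_int[None, :])[0]
            bc = biomarkers.barcode(spec, half_window=bm.half_window)
            row = {"sample_id": sid, "label": label}
            row.update(bc.as_dict())
            rows.append(row)
        feats = pd.DataFrame(rows)
        boxes = {}
        for label, grp in feats.groupby("label"):
            vals = grp["ratio_2930_2850"].to_numpy()
            if vals.size < 4:  # summary undefined below 4 samples
                boxes[str(label)] = {"n": int(vals.size),
                                     "median": float(np.median(vals))}
                continue
            s = biomarkers.boxplot_summary(vals)
            boxes[str(label)] = {
                "n": int(vals.size),
                "median": s.median, "q1": s.q1, "q3": s.q3, "iqr": s.iqr,
                "whisker_low": s.whisker_low, "whisker_high": s.whisker_high,
                "n_outliers": int(s.outliers.size)}
        roc = biomarkers.roc_auc(feats["ratio_2930_2850"].to_numpy(),
                                 feats["label"].to_numpy(), positive_label="tbi")
        return feats, boxes, roc

    feats, boxes, roc = _biomarkers()
    report["barcode_features"] = feats.to_dict(orient="records")
    report["ratio_boxplots"] = boxes
    report["roc"] = {
        "auc": roc.auc, "n_pos": roc.n_pos, "n_neg": roc.n_neg,
        "sensitivity": roc.sensitivity.tolist(),
        "specificity": roc.specificity.tolist(),
    }
    return report


def report_to_json(report: dict) -> str:
    """Deterministic serialization: sorted keys, repr-exact floats."""
    return json.dumps(report, sort_keys=True, indent=1)
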