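"""End-to-end DESI pipeline: NIfTI volume + landmarks -> index + report.

Stage order follows the published workflow: read -> RAS reorientation ->
bias correction -> rigid AC-PC resampling -> per-slice segmentation ->
3D reconstruction -> small-component filtering -> volumetry (Sylvian total
and wedge-restricted superior sulcal volume on the native-spacing grid) ->
DESI ratio -> threshold classification.  An oracle-mask mode substitutes a
provided label volume for the model, which decouples the deterministic
geometry from the learned segmentation stage.

Every report embeds the config echo, a config hash, the seed and the
package version, so a run is reproducible from its own output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acpc import LandmarkSet, WedgeSpec, resample_to_acpc
from .image_io import VolumeImage, correct_bias_field, read_volume, reorient_to_ras, write_volume
from .masks import MultiLabelMask
from .metrics import (ClassifierConfig, DesiResult, classify_desi,
                      compute_desi, evaluate_cohort)
from .seg import load_checkpoint, segment_volume
from .volumetrics import DEFAULT_MIN_COMPONENT_MM3, VolumeReport, compute_volume_report


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    volume_path: str = None
    landmarks_path: str = None
    model_checkpoint: str = None
    oracle_labels_path: str = None      # label NIfTI bypassing the model
    output_dir: str = None
    wedge_opening_deg: float = 30.0
    min_component_mm3: float = DEFAULT_MIN_COMPONENT_MM3
    threshold: float = ClassifierConfig().desh_vs_other_groups
    bias_correction: bool = True
    slab_only: bool = True
    seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _log(cfg, msg):
    if cfg.verbosity:
        print(f"desi: {msg}")


def analyze_aligned(seg: MultiLabelMask, lm: LandmarkSet,
                    wedge: WedgeSpec = None,
                    min_mm3: float = DEFAULT_MIN_COMPONENT_MM3,
                    threshold: float = None,
                    slab_only: bool = True):
    """Volumetry + DESI from an AC-PC-aligned 3D segmentation.

    Returns (VolumeReport, DesiResult).
    """
    report = compute_volume_report(seg, lm, wedge or WedgeSpec(),
                                   min_mm3, slab_only=slab_only)
    result = compute_desi(report)
    if threshold is not None:
        result = classify_desi(result, threshold)
    return report, result


def run_pipeline(cfg: PipelineConfig,
                 volume: VolumeImage = None,
                 landmarks: LandmarkSet = None,
                 oracle_labels: VolumeImage = None):
    """Execute the full pipeline for one scan.

    Inputs may be given as paths in ``cfg`` or as in-memory objects.  With
    ``oracle_labels`` (a label-coded volume in the same frame as the scan)
    the segmentation model is bypassed.  Returns a dict report; if
    ``cfg.output_dir`` is set, the report (JSON), the aligned volume and
    the segmentation masks (NIfTI) are written there.
    """
    stage = "read"
    try:
        vol = volume if volume is not None else read_volume(cfg.volume_path)
    except Exception as e:  # noqa: BLE001 - stage-named rethrow
        raise PipelineError(stage, str(e)) from e

    stage = "landmarks"
    try:
        lm = landmarks if landmarks is not None else LandmarkSet.from_json(cfg.landmarks_path)
    except FileNotFoundError as e:
        raise PipelineError(stage, f"landmark file not found: {cfg.landmarks_path}") from e
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    stage = "reorient"
    try:
        vol = reorient_to_ras(vol)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    _log(cfg, f"reoriented to RAS, shape {vol.voxels.shape}, spacing {np.round(vol.spacing, 3)}")

    if cfg.bias_correction:
        stage = "bias-correction"
        try:
            vol = correct_bias_field(vol)
        except Exception as e:
            raise PipelineError(stage, str(e)) from e
        _log(cfg, "bias field corrected")

    stage = "acpc-resample"
    try:
        vol_aligned, lm_aligned = resample_to_acpc(vol, lm)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    _log(cfg, f"AC-PC aligned, shape {vol_aligned.voxels.shape}")

    stage = "segmentation"
    try:
        labels = oracle_labels
        if labels is None and cfg.oracle_labels_path:
            labels = read_volume(cfg.oracle_labels_path)
        if labels is not None:
            lab_ras = reorient_to_ras(labels)
            lab_aligned, _ = resample_to_acpc(lab_ras, lm, interpolation="nearest")
            seg = MultiLabelMask.from_labels(
                np.rint(lab_aligned.voxels).astype(np.uint8),
                spacing=tuple(lab_aligned.spacing),
                origin=tuple(lab_aligned.origin))
            mode = "oracle-mask"
        else:
            if not cfg.model_checkpoint:
                raise ValueError("need a model checkpoint or oracle labels")
            model, seg_cfg = load_checkpoint(cfg.model_checkpoint)
            seg = segment_volume(model, vol_aligned, lm_aligned, seg_cfg)
            mode = "model"
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    _log(cfg, f"segmentation done ({mode})")

    stage = "volumetry"
    try:
        report, result = analyze_aligned(
            seg, lm_aligned, WedgeSpec(cfg.wedge_opening_deg),
            cfg.min_component_mm3, cfg.threshold, cfg.slab_only)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    _log(cfg, f"DESI = {result.desi:.3f} ({result.label})"
         if result.defined else "DESI undefined (zero superior volume)")

    out = {
        "desi": result.to_dict(),
        "volumes": report.to_dict(),
        "segmentation_mode": mode,
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "version": __version__,
    }

    if cfg.output_dir:
        stage = "write-outputs"
        try:
            outdir = Path(cfg.output_dir)
            outdir.mkdir(parents=True, exist_ok=True)
            with open(outdir / "desi_report.json", "w") as fh:
                json.dump(out, fh, indent=2, default=float)
            write_volume(vol_aligned, outdir / "volume_acpc.nii.gz")
            write_volume(VolumeImage(seg.to_labels(), vol_aligned.affine),
                         outdir / "segmentation_labels.nii.gz")
            pd.DataFrame([{**report.to_dict(), "desi": result.desi}]
                         ).drop(columns=["n_components_removed"]).to_csv(
                outdir / "volumes.csv", index=False)
        except Exception as e:
            raise PipelineError(stage, str(e)) from e
    return out


def run_cohort(case_reports, labels, fixed_threshold: float = None,
               output_dir: str = None):
    """Cohort evaluation from per-case pipeline reports.

    ``case_reports`` is a sequence of dicts as returned by
    :func:`run_pipeline` (or bare DESI scores); ``labels`` the binary truth
    per case.  Undefined DESI values enter as +inf (classified positive).
    Returns metrics at the Youden-optimal threshold and, if supplied, at a
    fixed published threshold.
    """
    scores = []
    for r in case_reports:
        if isinstance(r, dict):
            v = r["desi"]["desi"]
            defined = r["desi"]["defined"]
        elif isinstance(r, DesiResult):
            v, defined = r.desi, r.defined
        else:
            v, defined = float(r), not np.isnan(float(r))
        scores.append(v if defined else np.inf)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(scores) < 2:
        raise ValueError("cohort evaluation needs at least two cases")
    out = {
        "scores": scores.tolist(),
        "labels": labels.tolist(),
        "best": evaluate_cohort(scores, labels).to_dict(),
    }
    if fixed_threshold is not None:
        out["fixed"] = evaluate_cohort(scores, labels, fixed_threshold).to_dict()
    if output_dir:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"case": np.arange(len(scores)), "desi": scores,
                      "true_label": labels}).to_csv(outdir / "cohort_desi.csv",
                                                    index=False)
        with open(outdir / "cohort_metrics.json", "w") as fh:
            json.dump(out, fh, indent=2, default=float)
    return out
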