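"""End-to-end orchestration: meshes → fitted templates → landmarks → report.

The pipeline mirrors the measurement workflow: per bone, the cascaded fit
places the corresponded template onto the patient surface; direct landmarks
ride the correspondence and are snapped back to the raw surface; indirect
landmarks are derived (sphere fit, region centroids, midpoints); the knee
and foot–ankle frames are constructed; and the 28 measurements are
evaluated. Left limbs are mirrored to the right-handed convention before
fitting and mirrored back afterwards, so one template set serves both sides.

Everything is deterministic: no randomness enters after the inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, IncompleteLandmarkError
from .fitting import FitResult, cascade_fit
from .frames import AnatomicalFrame, build_foot_frame, build_knee_frame
from .landmarks import derive_indirect, transfer_direct
from .measurements import MeasurementReport, measure_all
from .meshdata import (
    BoneLabel,
    LandmarkSet,
    Provenance,
    Side,
    TemplateDefinition,
    TriangleMesh,
)
from .ssm import (
    CorrespondedCohort,
    ShapeModel,
    build_local_ssm,
    build_ssm,
    extract_local_region,
    generalized_procrustes,
)

#: Bones that get terminal-region local model refinement (long bones).
LOCAL_REFINED_BONES = (BoneLabel.femur, BoneLabel.tibia)


@dataclass
class BoneModels:
    """Trained artefacts for one bone: template + global and local models."""

    template: TemplateDefinition
    global_model: ShapeModel
    local_models: list[ShapeModel] = field(default_factory=list)


def train_bone_models(
    template: TemplateDefinition,
    cohort: CorrespondedCohort,
    variance_threshold: float = 0.98,
    local_fraction: float = 0.20,
    with_local: bool | None = None,
) -> BoneModels:
    """GPA + PCA on a corresponded training cohort of one bone.

    Local models cover the proximal and distal 20% slabs along the bone's
    long axis; by default they are built for the long bones only.
    """
    if cohort.vertex_count != len(template.mesh.vertices):
        raise ValueError("cohort is not in correspondence with the template")
    aligned, _ = generalized_procrustes(cohort)
    global_model = build_ssm(aligned, variance_threshold)
    if with_local is None:
        with_local = template.bone_label in LOCAL_REFINED_BONES
    local_models = []
    if with_local:
        for end in ("proximal", "distal"):
            region = extract_local_region(template, local_fraction, end)
            local_models.append(build_local_ssm(aligned, region, variance_threshold))
    return BoneModels(template, global_model, local_models)


@dataclass
class PipelineResult:
    """Everything one subject produces, plus a structured event log."""

    subject: str
    side: Side
    fit_results: dict[BoneLabel, FitResult]
    fitted_surfaces: dict[BoneLabel, TriangleMesh]
    landmarks: LandmarkSet
    frames: dict[str, AnatomicalFrame]
    report: MeasurementReport
    log: list[dict] = field(default_factory=list)

    def write_log(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.log:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")


def _mirror_landmarks(landmarks: LandmarkSet) -> LandmarkSet:
    out = LandmarkSet(subject=landmarks.subject, side=landmarks.side)
    for k, p in landmarks.points.items():
        q = p.copy()
        q[0] = -q[0]
        out.set(k, q, landmarks.provenance.get(k, Provenance.direct))
    return out


def process_subject(
    meshes: dict[BoneLabel, TriangleMesh],
    models: dict[BoneLabel, BoneModels],
    side: Side = Side.right,
    subject: str = "",
    vertical=(0.0, 0.0, 1.0),
) -> PipelineResult:
    """Fit, landmark, frame and measure one subject's bone meshes.

    Bones with no trained model are ignored; measurements whose landmarks
    or frames are unavailable come back as NaN with a flag rather than
    failing the subject.
    """
    log: list[dict] = []
    work = dict(meshes)
    if side == Side.left:
        work = {b: m.mirrored() for b, m in work.items()}
        log.append({"event": "mirrored_to_right", "side": side.value})

    fit_results: dict[BoneLabel, FitResult] = {}
    fitted: dict[BoneLabel, TriangleMesh] = {}
    landmarks = LandmarkSet(subject=subject, side=side)
    templates = {}
    for bone, mesh in work.items():
        if bone not in models:
            log.append({"event": "skipped_bone", "bone": bone.value,
                        "reason": "no trained model"})
            continue
        bundle = models[bone]
        templates[bone] = bundle.template
        result = cascade_fit(
            bundle.global_model, mesh, bundle.template.mesh.faces,
            bundle.local_models,
        )
        fit_results[bone] = result
        fitted[bone] = TriangleMesh(
            result.fitted_surface.vertices, bundle.template.mesh.faces, bone, side
        )
        direct, snap = transfer_direct(bundle.template, fitted[bone], mesh)
        landmarks.update(direct)
        log.append({
            "event": "bone_fitted",
            "bone": bone.value,
            "stages": [m.as_dict() for m in result.stage_metrics],
            "flags": {k: (float(v) if isinstance(v, float) else bool(v))
                      for k, v in result.flags.items()},
            "max_snap_mm": max(snap.values()) if snap else 0.0,
        })

    landmarks = derive_indirect(landmarks, fitted, templates)

    frames: dict[str, AnatomicalFrame] = {}
    try:
        frames["knee"] = build_knee_frame(landmarks, Side.right)
    except (IncompleteLandmarkError, DegenerateGeometryError) as exc:
        log.append({"event": "frame_failed", "frame": "knee", "reason": str(exc)})
    foot_bones = (BoneLabel.calcaneus, BoneLabel.talus, BoneLabel.metatarsal2)
    if all(b in fitted for b in foot_bones):
        try:
            head_region = None
            mt = templates.get(BoneLabel.metatarsal2)
            if mt is not None and "metatarsal_head" in mt.regions:
                head_region = mt.regions["metatarsal_head"]
            frames["foot"] = build_foot_frame(
                landmarks,
                fitted[BoneLabel.calcaneus],
                fitted[BoneLabel.talus],
                fitted[BoneLabel.metatarsal2],
                metatarsal_head_region=head_region,
                vertical=vertical,
            )
        except (IncompleteLandmarkError, DegenerateGeometryError) as exc:
            log.append({"event": "frame_failed", "frame": "foot", "reason": str(exc)})
    else:
        log.append({"event": "frame_failed", "frame": "foot",
                    "reason": "missing foot bone meshes"})

    report = measure_all(landmarks, frames, side=side, subject=subject)
    for acr, why in report.flags.items():
        log.append({"event": "measurement_flagged", "measurement": acr, "reason": why})

    if side == Side.left:
        landmarks = _mirror_landmarks(landmarks)
        fitted = {b: m.mirrored() for b, m in fitted.items()}

    return PipelineResult(subject, side, fit_results, fitted, landmarks,
                          frames, report, log)


def reports_to_frame(reports: list[MeasurementReport]) -> pd.DataFrame:
    """Stack per-subject reports into one tidy table (one row per subject)."""
    return pd.DataFrame([r.as_dict() for r in reports])


def write_report_csv(reports: list[MeasurementReport], path) -> None:
    reports_to_frame(reports).to_csv(path, index=False)


def write_report_json(reports: list[MeasurementReport], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.as_dict() for r in reports], fh, indent=2, sort_keys=True,
                  default=lambda o: None if (isinstance(o, float) and np.isnan(o)) else o)
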