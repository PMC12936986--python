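"""The 28 lower-limb alignment and morphology measurements.

Every angular measurement is the angle between two landmark-defined lines
after orthogonal projection onto one anatomical plane of either the knee
frame or the foot–ankle frame; TT-TG is the single distance measurement
(mediolateral offset between the tibial tuberosity and the trochlear
groove in the axial plane).

Reporting conventions (which endpoint order a line uses and whether the
angle is *directed* [0°, 180°], *acute* [0°, 90°], *complement*
(90° − acute, the slope reading) or *signed*
(−180°, 180°]) are not part of the landmark table; they are fixed here,
once, such that neutral anatomy lands in the characteristic ranges
(HKA ≈ 180°, FMA ≈ 87°, JLCA small positive, PT signed). Angles are
always computed with atan2 on the projected components, never through
arccos of a clipped dot product, for stability near 0° and 180°.

Knee measurements use the knee frame; the five ankle measurements (TT,
LDTA, HA, ADTA, CPA) use the foot–ankle frame, whose axes also serve as
reference lines for HA and CPA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import IncompleteLandmarkError
from .frames import AnatomicalFrame, project_to_plane
from .meshdata import LandmarkSet, Side

DEGENERATE_PROJECTION_MM = 1e-9


@dataclass(frozen=True)
class MeasurementDefinition:
    """One row of the measurement table.

    ``line1``/``line2`` are ordered landmark pairs (vector = second −
    first) or, for HA and CPA, a frame axis reference ``("axis", name)``.
    ``convention`` ∈ {"directed", "acute", "complement", "signed"};
    ``output`` is
    "angle_deg" except for TT-TG ("distance_mm").
    """

    acronym: str
    line1: tuple[str, str]
    line2: tuple[str, str]
    plane: str
    frame: str  # "knee" | "foot"
    convention: str = "directed"
    output: str = "angle_deg"


_D = MeasurementDefinition

#: The shipped definitions table (28 entries; ordered as reported).
MEASUREMENT_DEFINITIONS: tuple[MeasurementDefinition, ...] = (
    # -- coronal, knee frame -------------------------------------------------
    _D("HKA", ("COK", "FHC"), ("COK", "TCD"), "coronal", "knee", "directed"),
    _D("FMA", ("COK", "FHC"), ("FMC", "FLC"), "coronal", "knee", "directed"),
    _D("TMA", ("TCD", "TCP"), ("TLCL", "TMCM"), "coronal", "knee", "directed"),
    _D("FAA", ("FA2", "FA1"), ("FMC", "FLC"), "coronal", "knee", "directed"),
    _D("TAA", ("TA2", "TA1"), ("TLCL", "TMCM"), "coronal", "knee", "directed"),
    _D("FMvsA", ("FA2", "FA1"), ("COK", "FHC"), "coronal", "knee", "acute"),
    _D("JLCA", ("FLC", "FMC"), ("TLCL", "TMCM"), "coronal", "knee", "acute"),
    _D("FNSA", ("FNC", "FHC"), ("FA1", "FA2"), "coronal", "knee", "directed"),
    # -- coronal, foot frame -------------------------------------------------
    _D("TT", ("LDTAS", "MDTAS"), ("TDL", "TDM"), "coronal", "foot", "acute"),
    _D("LDTA", ("LDTAS", "MDTAS"), ("TA2", "TA1"), "coronal", "foot", "directed"),
    _D("HA", ("CIP", "TDC"), ("axis", "z"), "coronal", "foot", "signed"),
    # -- axial, knee frame ---------------------------------------------------
    _D("aTEA-PCL", ("FME", "FLE"), ("FMCP", "FLCP"), "axial", "knee", "acute"),
    _D("sTEA-PCL", ("FMS", "FLE"), ("FMCP", "FLCP"), "axial", "knee", "acute"),
    _D("asTEA", ("FME", "FLE"), ("FMS", "FLE"), "axial", "knee", "acute"),
    _D("FAVA", ("FNC", "FHC"), ("FLCP", "FMCP"), "axial", "knee", "signed"),
    _D("TTA-PCL", ("TMCC", "TLCC"), ("FMCP", "FLCP"), "axial", "knee", "acute"),
    _D("FTA-PCL", ("FMCC", "FLCC"), ("FMCP", "FLCP"), "axial", "knee", "acute"),
    _D("FTA-TTA", ("FMCC", "FLCC"), ("TMCC", "TLCC"), "axial", "knee", "acute"),
    _D("FTA-TAPA", ("FLCC", "FMCC"), ("COK", "TGCP"), "axial", "knee", "directed"),
    _D("TEVA", ("TMM", "TLM"), ("TPPPM", "TPPPL"), "axial", "knee", "acute"),
    _D("TT-TG", ("TGCP", "TTP"), ("TGCP", "TTP"), "axial", "knee",
       "signed", output="distance_mm"),
    _D("SA", ("TRLP", "TGCP"), ("TRMP", "TGCP"), "axial", "knee", "directed"),
    _D("PT", ("PMP", "PLP"), ("FMCP", "FLCP"), "axial", "knee", "signed"),
    _D("LTI", ("TGCP", "TRLP"), ("FMCP", "FLCP"), "axial", "knee", "acute"),
    # -- sagittal ------------------------------------------------------------
    _D("MTS", ("TMCA", "TMCP"), ("TA1", "TA2"), "sagittal", "knee", "complement"),
    _D("LTS", ("TLCA", "TLCP"), ("TA1", "TA2"), "sagittal", "knee", "complement"),
    _D("ADTA", ("ADTAS", "PDTAS"), ("TA2", "TA1"), "sagittal", "foot", "directed"),
    _D("CPA", ("CIPA", "CIP"), ("axis", "y"), "sagittal", "foot", "acute"),
)

assert len(MEASUREMENT_DEFINITIONS) == 28
DEFINITIONS_BY_ACRONYM = {d.acronym: d for d in MEASUREMENT_DEFINITIONS}


@dataclass
class MeasurementReport:
    """Per-subject report: 28 values (degrees, TT-TG in mm) + flags."""

    subject: str = ""
    side: Side | None = None
    values: dict[str, float] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {"subject": self.subject, "side": self.side.value if self.side else None}
        out.update(self.values)
        for k, v in self.flags.items():
            out[f"flag_{k}"] = v
        return out


# ---------------------------------------------------------------------------


def angle_between_projected(
    v1: np.ndarray,
    v2: np.ndarray,
    frame: AnatomicalFrame,
    plane: str,
    convention: str = "directed",
) -> float:
    """Angle (degrees) between two 3D directions after projection to a plane.

    ``directed`` is the rotation magnitude in [0°, 180°]; ``acute`` folds
    it to [0°, 90°]; ``complement`` is the slope reading 90° − acute
    (angle to the perpendicular of the reference line, for the tibial
    slopes); ``signed`` keeps the orientation of the rotation from v1 to
    v2 in the plane's (first-axis, second-axis) basis, in (−180°, 180°].
    """
    p1 = project_to_plane(v1, frame, plane)
    p2 = project_to_plane(v2, frame, plane)
    n1, n2 = np.linalg.norm(p1), np.linalg.norm(p2)
    if n1 < DEGENERATE_PROJECTION_MM or n2 < DEGENERATE_PROJECTION_MM:
        raise IncompleteLandmarkError("zero-length projection")
    cross = p1[0] * p2[1] - p1[1] * p2[0]
    dot = p1 @ p2
    theta = math.degrees(math.atan2(cross, dot))  # signed, (-180, 180]
    if convention == "signed":
        return theta
    theta = abs(theta)
    if convention == "acute":
        return min(theta, 180.0 - theta)
    if convention == "complement":
        return 90.0 - min(theta, 180.0 - theta)
    return theta  # directed


def _line_vector(pair, landmarks: LandmarkSet, frame: AnatomicalFrame):
    if pair[0] == "axis":
        return frame.axis(pair[1])
    a, b = pair
    return landmarks[b] - landmarks[a]


def tt_tg(landmarks: LandmarkSet, knee_frame: AnatomicalFrame) -> tuple[float, float]:
    """TT-TG distance (mm): mediolateral offset of TTP from TGCP.

    Both points are projected onto the axial plane; the measurement is the
    magnitude of the component of (TTP − TGCP) along the frame x-axis (the
    posterior-condylar-line direction). Returns ``(distance, signed)`` with
    positive signed values lateral.
    """
    offset = landmarks["TTP"] - landmarks["TGCP"]
    signed = float(project_to_plane(offset, knee_frame, "axial")[0])
    return abs(signed), signed


def compute_measurement(
    defn: MeasurementDefinition,
    landmarks: LandmarkSet,
    frames: dict[str, AnatomicalFrame],
) -> float:
    """Evaluate one definition; raises IncompleteLandmarkError when degenerate."""
    frame = frames[defn.frame]
    if defn.output == "distance_mm":
        return tt_tg(landmarks, frames["knee"])[0]
    v1 = _line_vector(defn.line1, landmarks, frame)
    v2 = _line_vector(defn.line2, landmarks, frame)
    return angle_between_projected(v1, v2, frame, defn.plane, defn.convention)


def measure_all(
    landmarks: LandmarkSet,
    frames: dict[str, AnatomicalFrame],
    side: Side | None = None,
    subject: str = "",
) -> MeasurementReport:
    """Evaluate all 28 definitions; per-measurement problems become flags."""
    report = MeasurementReport(subject=subject, side=side or landmarks.side)
    for defn in MEASUREMENT_DEFINITIONS:
        try:
            if defn.frame not in frames or frames[defn.frame] is None:
                raise IncompleteLandmarkError(f"missing {defn.frame} frame")
            report.values[defn.acronym] = compute_measurement(defn, landmarks, frames)
        except IncompleteLandmarkError as exc:
            report.values[defn.acronym] = float("nan")
            report.flags[defn.acronym] = str(exc)
    return report


def definitions_as_json() -> list[dict]:
    """The shipped definitions table in serializable form (for export)."""
    return [
        {
            "acronym": d.acronym,
            "line1": list(d.line1),
            "line2": list(d.line2),
            "plane": d.plane,
            "frame": d.frame,
            "convention": d.convention,
            "output": d.output,
        }
        for d in MEASUREMENT_DEFINITIONS
    ]
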