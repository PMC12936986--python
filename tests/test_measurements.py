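"""Measurement oracles: closed-form constructed angles, rigid invariance,
conventions, and graceful degradation on incomplete inputs."""

import math

import numpy as np
import pytest

import limbmark as lm
from limbmark.frames import AnatomicalFrame
from limbmark.measurements import (
    DEFINITIONS_BY_ACRONYM,
    angle_between_projected,
    definitions_as_json,
)

from .conftest import random_rotation

WORLD = AnatomicalFrame(np.zeros(3), [1, 0, 0], [0, 1, 0], [0, 0, 1])


def test_definitions_table_shape():
    assert len(lm.MEASUREMENT_DEFINITIONS) == 28
    assert sum(d.output == "distance_mm" for d in lm.MEASUREMENT_DEFINITIONS) == 1
    rows = definitions_as_json()
    assert len(rows) == 28 and all("convention" in r for r in rows)


def test_constructed_rotation_angles_exact():
    v1 = np.array([1.0, 0.0, 0.0])
    for deg in (5.0, 30.0, 90.0, 150.0, 179.5):
        r = math.radians(deg)
        v2 = np.array([math.cos(r), math.sin(r), 0.0])
        assert angle_between_projected(v1, v2, WORLD, "axial", "directed") == \
            pytest.approx(deg, abs=1e-9)
    # the 5-degree constructed case, signed and acute
    r = math.radians(5.0)
    v2 = np.array([math.cos(r), math.sin(r), 0.0])
    assert angle_between_projected(v1, v2, WORLD, "axial", "signed") == \
        pytest.approx(5.0, abs=1e-9)
    assert angle_between_projected(v2, v1, WORLD, "axial", "signed") == \
        pytest.approx(-5.0, abs=1e-9)
    assert angle_between_projected(v1, -v2, WORLD, "axial", "acute") == \
        pytest.approx(5.0, abs=1e-9)
    assert angle_between_projected(v1, v2, WORLD, "axial", "complement") == \
        pytest.approx(85.0, abs=1e-9)


def test_angle_near_180_stable():
    v1 = np.array([1.0, 0.0, 0.0])
    v2 = np.array([-1.0, 1e-12, 0.0])
    a = angle_between_projected(v1, v2, WORLD, "axial", "directed")
    assert a == pytest.approx(180.0, abs=1e-9)


def test_degenerate_projection_raises():
    with pytest.raises(lm.IncompleteLandmarkError):
        angle_between_projected([0, 0, 1.0], [1.0, 0, 0], WORLD, "axial")


def test_hka_collinear_is_180():
    lms = lm.LandmarkSet()
    lms.set("FHC", [0.0, 0.0, 400.0], lm.Provenance.manual)
    lms.set("COK", [0.0, 0.0, 0.0], lm.Provenance.manual)
    lms.set("TCD", [0.0, 0.0, -400.0], lm.Provenance.manual)
    val = lm.compute_measurement(DEFINITIONS_BY_ACRONYM["HKA"], lms, {"knee": WORLD})
    assert val == pytest.approx(180.0, abs=1e-9)


def test_jlca_parallel_zero_and_five_degrees():
    lms = lm.LandmarkSet()
    for name, p in {
        "FLC": [40.0, 0.0, 0.0], "FMC": [-40.0, 0.0, 0.0],
        "TLCL": [40.0, 0.0, -10.0], "TMCM": [-40.0, 0.0, -10.0],
    }.items():
        lms.set(name, p, lm.Provenance.manual)
    defn = DEFINITIONS_BY_ACRONYM["JLCA"]
    assert lm.compute_measurement(defn, lms, {"knee": WORLD}) == \
        pytest.approx(0.0, abs=1e-9)
    # rotate the tibial line by exactly 5 degrees in the coronal plane
    r = math.radians(5.0)
    lms.set("TLCL", [40 * math.cos(r), 0.0, -10 + 40 * math.sin(r)], lm.Provenance.manual)
    lms.set("TMCM", [-40 * math.cos(r), 0.0, -10 - 40 * math.sin(r)], lm.Provenance.manual)
    assert lm.compute_measurement(defn, lms, {"knee": WORLD}) == \
        pytest.approx(5.0, abs=1e-9)


def test_tt_tg_axis_decomposition_exact():
    lms = lm.LandmarkSet()
    lms.set("TGCP", [0.0, 20.0, -5.0], lm.Provenance.manual)
    lms.set("TTP", [14.25, 30.0, -80.0], lm.Provenance.manual)
    dist, signed = lm.tt_tg(lms, WORLD)
    assert dist == pytest.approx(14.25, abs=1e-12)
    assert signed == pytest.approx(14.25, abs=1e-12)
    # rotate everything: the frame co-rotates, the reading is unchanged
    rng = np.random.default_rng(4)
    R = random_rotation(rng)
    t = rng.uniform(-30, 30, 3)
    moved_frame = WORLD.transformed(R, t)
    dist2, signed2 = lm.tt_tg(lms.transformed(R, t), moved_frame)
    assert dist2 == pytest.approx(14.25, abs=1e-9)
    # medial offset flips the sign but not the distance
    lms.set("TTP", [-14.25, 30.0, -80.0], lm.Provenance.manual)
    dist3, signed3 = lm.tt_tg(lms, WORLD)
    assert dist3 == pytest.approx(14.25, abs=1e-12)
    assert signed3 == pytest.approx(-14.25, abs=1e-12)


def test_all_measurements_rigid_invariant(truth_landmarks, truth_frames, templates):
    base = lm.measure_all(truth_landmarks, truth_frames)
    assert not base.flags
    for seed in range(3):
        rng = np.random.default_rng(seed + 40)
        R = random_rotation(rng)
        t = rng.uniform(-80, 80, 3)
        moved_lms = truth_landmarks.transformed(R, t)
        moved_frames = {k: f.transformed(R, t) for k, f in truth_frames.items()}
        moved = lm.measure_all(moved_lms, moved_frames)
        for acr, val in base.values.items():
            assert moved.values[acr] == pytest.approx(val, abs=1e-9), acr


def test_measurement_value_ranges(truth_landmarks, truth_frames):
    rep = lm.measure_all(truth_landmarks, truth_frames)
    for d in lm.MEASUREMENT_DEFINITIONS:
        v = rep.values[d.acronym]
        if d.output == "distance_mm":
            assert v >= 0
        elif d.convention == "directed":
            assert 0 <= v <= 180
        elif d.convention in ("acute", "complement"):
            assert 0 <= v <= 90
        else:
            assert -180 < v <= 180


def test_missing_landmarks_flagged_not_fatal(truth_landmarks, truth_frames):
    partial = lm.LandmarkSet(side=lm.Side.right)
    for k in ("FHC", "COK", "TCD", "FMC", "FLC"):
        partial.set(k, truth_landmarks[k], lm.Provenance.manual)
    rep = lm.measure_all(partial, truth_frames)
    assert rep.values["HKA"] == pytest.approx(
        lm.measure_all(truth_landmarks, truth_frames).values["HKA"], abs=1e-9)
    assert np.isnan(rep.values["TT-TG"])
    assert "TT-TG" in rep.flags
    assert len(rep.values) == 28


def test_missing_foot_frame_flags_ankle_measurements(truth_landmarks, truth_frames):
    rep = lm.measure_all(truth_landmarks, {"knee": truth_frames["knee"]})
    for acr in ("TT", "LDTA", "HA", "ADTA", "CPA"):
        assert np.isnan(rep.values[acr])
        assert acr in rep.flags
    assert np.isfinite(rep.values["HKA"])


def test_report_as_dict(truth_landmarks, truth_frames):
    rep = lm.measure_all(truth_landmarks, truth_frames, side=lm.Side.right,
                         subject="s01")
    d = rep.as_dict()
    assert d["subject"] == "s01" and d["side"] == "R"
    assert "HKA" in d and "TT-TG" in d
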