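import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vmatflux as vf
from vmatflux.synthetic import film_plane, film_slab_phantom, five_cp_arc, toy_beam_data

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hdmlc():
    return vf.build_hdmlc()


@pytest.fixture(scope="session")
def millennium():
    return vf.build_millennium()


@pytest.fixture(scope="session")
def five_cp():
    return five_cp_arc()


@pytest.fixture(scope="session")
def beam_data():
    return toy_beam_data()


@pytest.fixture(scope="session")
def phantom():
    return film_slab_phantom()


@pytest.fixture(scope="session")
def plane():
    return film_plane()


@pytest.fixture(scope="session")
def five_cp_doses(five_cp, beam_data, phantom, plane):
    """Dose planes of the 5-CP arc in all three modes (computed once)."""
    return {
        mode: vf.compute_plan_dose(five_cp, mode, beam_data, phantom, plane)
        for mode in vf.MODES
    }


def write_synthetic_rtplan(path, plan, rotation="CW"):
    """Write an ArcPlan as a minimal synthetic DICOM RT Plan (cm -> mm)."""
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.uid import ImplicitVRLittleEndian, generate_uid

    fm = FileMetaDataset()
    fm.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.5")
    fm.MediaStorageSOPInstanceUID = generate_uid()
    fm.TransferSyntaxUID = ImplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=fm, preamble=b"\x00" * 128)
    ds.SOPClassUID = fm.MediaStorageSOPClassUID
    ds.SOPInstanceUID = fm.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = plan.metadata.get("plan_id", "synthetic")

    beam = Dataset()
    beam.BeamType = "DYNAMIC"
    beam.NumberOfControlPoints = plan.n_cp
    bld = Dataset()
    bld.RTBeamLimitingDeviceType = "MLCX"
    bld.NumberOfLeafJawPairs = plan.machine.n_pairs
    bld.LeafPositionBoundaries = [float(b) for b in plan.machine.boundaries]
    beam.BeamLimitingDeviceSequence = [bld]

    cps = []
    for i, cp in enumerate(plan.control_points):
        c = Dataset()
        c.ControlPointIndex = i
        c.GantryAngle = cp.gantry_angle
        if i == 0:
            c.GantryRotationDirection = rotation
        c.BeamLimitingDeviceAngle = cp.collimator_angle
        px = Dataset()
        px.RTBeamLimitingDeviceType = "ASYMX"
        px.LeafJawPositions = [cp.jaws.x1 * 10, cp.jaws.x2 * 10]
        py = Dataset()
        py.RTBeamLimitingDeviceType = "ASYMY"
        py.LeafJawPositions = [cp.jaws.y1 * 10, cp.jaws.y2 * 10]
        ml = Dataset()
        ml.RTBeamLimitingDeviceType = "MLCX"
        ml.LeafJawPositions = [float(v) for v in np.concatenate([cp.bank_a, cp.bank_b]) * 10]
        c.BeamLimitingDevicePositionSequence = [px, py, ml]
        c.CumulativeMetersetWeight = cp.cumulative_mu
        cps.append(c)
    beam.ControlPointSequence = cps
    ds.BeamSequence = [beam]
    ds.save_as(str(path))
    return path
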