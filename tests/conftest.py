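import numpy as np
import pytest

from eaequant import kinematics, pose_io
from eaequant.synthetic import GaitSimParams, gen_gait_recording


@pytest.fixture(scope="session")
def clean_recording():
    """A noiseless six-cycle treadmill recording with its ground truth."""
    track, truth = gen_gait_recording(GaitSimParams(seed=42))
    return track, truth


def process_recording(track, truth, **phase_kwargs):
    """Calibrate -> angles -> phases -> representative cycle, as the pipeline does."""
    cal = pose_io.compute_calibration(truth.marker_px, 7.0, 4.0)
    ctrack = pose_io.calibrate_track(
        track, cal, image_height_px=truth.params.image_height_px
    )
    angles = kinematics.joint_angle_series(ctrack)
    params = kinematics.PhaseParams(**phase_kwargs) if phase_kwargs else None
    seg = kinematics.detect_phases(ctrack, params)
    cycle = kinematics.representative_cycle(angles, seg)
    return ctrack, angles, seg, cycle


@pytest.fixture(scope="session")
def processed_clean(clean_recording):
    track, truth = clean_recording
    return process_recording(track, truth)
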