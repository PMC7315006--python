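import numpy as np
import pytest

from cuttlekin.pipeline import analyze_track
from cuttlekin.pose_io import ALL_PARTS, PoseTrack, TrialMetadata, make_pose_frame
from cuttlekin.simulate import SimScenario, StrikeCommand, simulate_trial


@pytest.fixture
def metadata() -> TrialMetadata:
    return TrialMetadata(animal_id="T", trial_id="1", fps=90.0, mm_per_px=0.5)


@pytest.fixture
def random_track(metadata) -> PoseTrack:
    """A 100-frame track with uniform random coordinates and likelihoods."""
    rng = np.random.default_rng(42)
    data = make_pose_frame(100)
    for part in ALL_PARTS:
        data[(part.value, "x")] = rng.uniform(0, 2048, 100)
        data[(part.value, "y")] = rng.uniform(0, 2048, 100)
        data[(part.value, "likelihood")] = rng.uniform(0, 1, 100)
    return PoseTrack(metadata=metadata, data=data)


@pytest.fixture(scope="session")
def clean_trial():
    """A noise-free 30 s trial with one predictive strike, plus its analysis."""
    scenario = SimScenario(
        seed=11,
        duration_s=30.0,
        noise_sigma_px=0.0,
        occlusion_prob=0.0,
        strikes=(StrikeCommand(time_s=20.0, predictive=True),),
    )
    track, truth = simulate_trial(scenario)
    return scenario, track, truth, analyze_track(track)


@pytest.fixture(scope="session")
def noisy_trial():
    """A 30 s trial at the default noise/occlusion levels, plus its analysis."""
    scenario = SimScenario(
        seed=5,
        duration_s=30.0,
        strikes=(StrikeCommand(time_s=20.0, predictive=True),),
    )
    track, truth = simulate_trial(scenario)
    return scenario, track, truth, analyze_track(track)
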