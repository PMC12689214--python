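import pytest

from tagshift.design import DesignParams, TrialSchedule, build_schedule
from tagshift.montage import default_montage
from tagshift.simulate import GroundTruthEnvelope, generate_subject


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def schedule_1000():
    return build_schedule(DesignParams(seed=11))


@pytest.fixture(scope="session")
def schedule_250():
    return build_schedule(DesignParams(n_trials=250, seed=12))


@pytest.fixture(scope="session")
def no_event_250(schedule_250):
    """Trials without post-cue events from the 250-trial schedule."""
    return TrialSchedule(
        schedule_250.no_event_trials.reset_index(drop=True), schedule_250.params
    )


@pytest.fixture(scope="session")
def noisy_recording(no_event_250, montage):
    """A realistic-noise subject recording (160 trials)."""
    return generate_subject(no_event_250, GroundTruthEnvelope(), montage, seed=21)


@pytest.fixture(scope="session")
def noiseless_recording(no_event_250, montage):
    """A noiseless subject recording with the default (modulated) truth."""
    return generate_subject(
        no_event_250, GroundTruthEnvelope(), montage,
        noise=dict(pink_scale=0.0, white_scale=0.0), seed=22,
    )
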