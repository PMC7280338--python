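import pytest

from weargaze.stream_assembly import parse_recording
from weargaze.synth import five_fixation_script, generate_recording


@pytest.fixture(scope="session")
def five_fix_result(tmp_path_factory):
    """A noise-free five-fixation/four-saccade recording on disk."""
    out = tmp_path_factory.mktemp("five_fix")
    return generate_recording(five_fixation_script(noise_sd=0.0, seed=1), out)


@pytest.fixture(scope="session")
def five_fix_recording(five_fix_result):
    recording, report = parse_recording(five_fix_result.recording_dir)
    return recording, report, five_fix_result
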