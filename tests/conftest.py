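import numpy as np
import pytest

from emgchart import simulate as sim
from emgchart import preprocess as pp


@pytest.fixture(scope="session")
def tiny_protocol():
    """A scaled-down finger-motion protocol: 2 subjects, 2 channels,
    4 motions, 4 trials, 1 s at 512 Hz."""
    return sim.ProtocolConfig(
        name="tiny", n_subjects=2, n_channels=2,
        motions=("thumb", "index", "middle", "ring"),
        n_trials=4, record_duration=1.0, sampling_rate=512.0,
        band=(20.0, 250.0))


@pytest.fixture(scope="session")
def tiny_recordings(tiny_protocol):
    profiles = sim.default_motion_profiles(tiny_protocol)
    return sim.generate_dataset(tiny_protocol, profiles, seed=7)


@pytest.fixture(scope="session")
def record_table(tiny_recordings):
    """Whole-record battery values, standardized per (subject, channel)."""
    table = pp.extract_feature_table(tiny_recordings, "unit")
    return pp.standardize_features(table.droplevel("start"))


@pytest.fixture(scope="session")
def windowed_table(tiny_recordings):
    """Sliding-window battery values (250 ms / 125 ms), standardized."""
    table = pp.extract_feature_table(tiny_recordings, "unit",
                                     win_ms=250.0, inc_ms=125.0)
    return pp.GroupStandardizer().fit_transform(table)


def rms_windows(recordings, win_ms=250.0, inc_ms=125.0):
    """Cheap per-window RMS matrix builder used by separability tests:
    (windows x channels, motion labels) per subject."""
    import pandas as pd

    rows, keys = [], []
    for rec in recordings:
        for w in pp.segment_record(rec, win_ms, inc_ms):
            x = w.samples
            rows.append(float(np.sqrt(np.mean(x ** 2))))
            keys.append((rec.subject, rec.channel, rec.trial, rec.motion,
                         rec.repetition, w.start))
    frame = pd.DataFrame(
        {"RMS": rows},
        index=pd.MultiIndex.from_tuples(
            keys, names=["subject", "channel", "trial", "motion",
                         "repetition", "start"]))
    out = {}
    for subject in sorted({k[0] for k in keys}):
        sub = frame.xs(subject, level="subject")["RMS"]
        wide = sub.unstack(level="channel")
        out[subject] = (wide.to_numpy(),
                        wide.index.get_level_values("motion").to_numpy())
    return out
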