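import numpy as np
import pytest

import thermoface as tf


@pytest.fixture(scope="session")
def small_config():
    """Spatially scaled-down session config (study timing, small frames)."""
    return tf.SessionConfig(noise_sd=0.0, seed=0).scaled(1 / 3)


@pytest.fixture(scope="session")
def short_config():
    """Short-duration, small-frame config for fast structural tests."""
    return tf.SessionConfig(baseline_seconds=2.0, emotion_seconds=4.0,
                            noise_sd=0.0, seed=0).scaled(1 / 3)


@pytest.fixture(scope="session")
def null_session(short_config):
    """Noiseless session with no planted effects."""
    return tf.generate_session(short_config)


@pytest.fixture(scope="session")
def effect_session(small_config):
    """Noiseless full-schedule session with the example effect pattern."""
    return tf.generate_session(small_config, tf.example_effects())


@pytest.fixture(scope="session")
def noisy_features():
    """Feature matrix of a noisy (sd 2) high-SNR session, study timing."""
    cfg = tf.SessionConfig(noise_sd=2.0, seed=7).scaled(1 / 3)
    sess = tf.generate_session(cfg, tf.example_effects())
    return tf.segment_features(sess.frames, sess.roi_set, sess.segments)


def session_features(session):
    return tf.segment_features(session.frames, session.roi_set,
                               session.segments)


@pytest.fixture(scope="session")
def null_features(null_session):
    return session_features(null_session)
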