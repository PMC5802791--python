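import numpy as np
import pytest

from memloop import decoder, sigproc, synthgen
from memloop.config import profile_config


@pytest.fixture(scope="session")
def cfg():
    """Small lateral-temporal study arm used across tests."""
    return profile_config("lateral_temporal", n_subjects=2, seed=123)


@pytest.fixture(scope="session")
def profile(cfg):
    return synthgen.make_subject(cfg, 0)


@pytest.fixture(scope="session")
def record_session(cfg, profile):
    """One record-only session: (events, un-normalized features)."""
    return synthgen.simulate_record_session(cfg, profile, 0)


@pytest.fixture(scope="session")
def trained_model(cfg, profile):
    """Classifier trained on two record-only sessions of the fixture subject."""
    X, y = [], []
    for s in range(2):
        events, feats = synthgen.simulate_record_session(cfg, profile, s)
        z = sigproc.normalize_features(feats, "within_session")
        X.append(z.values)
        y.append(events["recalled"].to_numpy())
    return decoder.train(
        np.vstack(X), np.concatenate(y),
        pair_labels=profile.pair_labels, freqs=sigproc.analysis_freqs(),
    )


@pytest.fixture(scope="session")
def closed_loop_run(cfg, profile, trained_model):
    """A full closed-loop session driven by the trained fixture model."""
    from memloop import loopsim

    sched = synthgen.make_schedule(cfg, cfg.seed_for("loop", profile.site, "sched"))
    events = synthgen.simulate_recall(
        sched, cfg, seed=cfg.seed_for("loop", profile.site, "recall"),
        profile=profile, session=2,
    )
    feats = synthgen.simulate_features(
        events, cfg, seed=cfg.seed_for("loop", profile.site, "feats"), profile=profile
    )
    log, out = loopsim.run_closed_loop_session(
        trained_model, feats, sched, events, config=cfg, profile=profile
    )
    return log, out
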