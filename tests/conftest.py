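"""Shared fixtures: small synthetic worlds reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from dyadsync import CANONICAL_BANDS, SynthConfig, generate_dyad_session
from dyadsync.prep import Epoch, EpochSet


@pytest.fixture(scope="session")
def bands():
    return list(CANONICAL_BANDS)


def make_epochset(arrays, rate=250.0, topics=("t0", "t1"), role="listen",
                  rest=None, ch_names=None):
    """Build an EpochSet from raw per-topic arrays (channels x T each)."""
    arrays = [np.asarray(a, dtype=np.float64) for a in arrays]
    nch = arrays[0].shape[0]
    names = ch_names or [f"c{i}" for i in range(nch)]
    eps = [Epoch(role, t, a) for t, a in zip(topics, arrays)]
    if rest is not None:
        eps.append(Epoch("rest", None, np.asarray(rest, dtype=np.float64)))
    return EpochSet(eps, rate, names)


@pytest.fixture(scope="session")
def small_world():
    """A 2-dyad, 3-channel world with one coupled pair and one entrained channel.

    Channel 0 (listener) <-> channel 1 (speaker) are directly coupled in
    alpha; channel 2 entrains to the speech envelope in theta when speaking.
    """
    cfg = SynthConfig(
        n_dyads=2, n_channels=3, epoch_len=15.0, gap_len=2.0, n_topics=3,
        coupling_table={(0, 1, "alpha"): 1.0},
        envelope_coupling={("speak", 2, "theta"): 0.9},
        kappa_spread=0.0, seed=11)
    session, gt = generate_dyad_session(cfg, 0)
    return cfg, session, gt


@pytest.fixture(scope="session")
def small_epochsets(small_world):
    from dyadsync import extract_epochs, preprocess_recording

    cfg, session, _ = small_world
    return {pid: extract_epochs(preprocess_recording(raw, 1.0, 20.0), cfg.epoch_len)
            for pid, raw in session.recordings.items()}
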