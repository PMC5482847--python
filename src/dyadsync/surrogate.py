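"""Trial-shuffled surrogate datasets for the null hypothesis of no coupling.

Surrogates pair signals from *different* topics while preserving each
participant's role: the listener's epoch for topic i is paired with the
speaker's epoch for topic j (i != j), destroying genuine moment-to-moment
coupling but preserving every marginal property of the signals. With 5
topics this enumerates all 20 ordered non-matching combinations; the
surrogate map is their average, so it is deterministic given the epochs. The
same rest-baseline subtraction (interbrain) or intra-brain correction
(envelope) applied to the real data is applied to the surrogates.
"""

from __future__ import annotations

import numpy as np

from .bands import BandSpec
from .envelope import (EnvelopePLV, _align, envelope_phase, envelope_plv_from_phases,
                       intrabrain_mean_from_phases)
from .phase import DEFAULT_TRIM, CaseCouplingMap, analytic_phase, plv_matrix
from .prep import EpochSet


def enumerate_surrogate_pairings(n_topics: int) -> list[tuple[int, int]]:
    """All ordered (listener-trial, speaker-trial) index pairs with i != j."""
    if n_topics < 2:
        raise ValueError("need at least 2 topics to form surrogates")
    return [(i, j) for i in range(n_topics) for j in range(n_topics) if i != j]


def _role_phases(es: EpochSet, role: str, topics: list[str], bands, trim):
    """Per-band phase stacks (n_topics, ch, T') for one role, plus rest."""
    stack = np.stack([es.get(role, t).data for t in topics]).astype(np.float64)
    rest = es.get("rest").data.astype(np.float64)[None]
    out = {}
    for band in bands:
        out[band.name] = (analytic_phase(stack, es.rate, band, trim, axis=-1),
                          analytic_phase(rest, es.rate, band, trim, axis=-1)[0])
    return out


def surrogate_interbrain(listener: EpochSet, speaker: EpochSet,
                         bands: list[BandSpec], trim: int = DEFAULT_TRIM,
                         case_id: tuple | None = None) -> CaseCouplingMap:
    """Surrogate interbrain coupling map (rest-subtracted, pairing-averaged)."""
    topics = [ep.topic for ep in listener.epochs if ep.role == "listen"]
    s_topics = {ep.topic for ep in speaker.epochs if ep.role == "speak"}
    if set(topics) != s_topics:
        raise ValueError("listener and speaker topic sets differ")
    pairings = enumerate_surrogate_pairings(len(topics))
    l_ph = _role_phases(listener, "listen", topics, bands, trim)
    s_ph = _role_phases(speaker, "speak", topics, bands, trim)
    out = np.zeros((listener.n_channels, speaker.n_channels, len(bands)))
    for bi, band in enumerate(bands):
        lp, l_rest = l_ph[band.name]
        sp, s_rest = s_ph[band.name]
        rest = plv_matrix(l_rest, s_rest)
        acc = np.zeros_like(rest)
        for i, j in pairings:
            acc += plv_matrix(lp[i], sp[j]) - rest
        out[:, :, bi] = acc / len(pairings)
    return CaseCouplingMap(out, list(bands), case_id)


def surrogate_envelope(epochs: EpochSet, envelopes: dict[str, np.ndarray],
                       role: str, bands: list[BandSpec],
                       trim: int = DEFAULT_TRIM, case_id: tuple | None = None,
                       align_tol_s: float = 0.5) -> EnvelopePLV:
    """Surrogate brain-to-envelope PLV with intra-brain correction applied.

    Every envelope from topic i is paired with the same participant's
    same-role EEG epoch from topic j != i; the corrected PLV is averaged over
    all pairings.
    """
    if role not in ("speak", "listen"):
        raise ValueError("role must be 'speak' or 'listen'")
    topics = [ep.topic for ep in epochs.epochs if ep.role == role]
    if set(topics) != set(envelopes):
        raise ValueError("envelope topics do not match epoch topics")
    pairings = enumerate_surrogate_pairings(len(topics))
    tol = int(round(align_tol_s * epochs.rate))
    acc = np.zeros((epochs.n_channels, len(bands)))
    for bi, band in enumerate(bands):
        eeg_ph = np.stack([analytic_phase(epochs.get(role, t).data, epochs.rate, band, trim)
                           for t in topics])
        env_ph = np.stack([envelope_phase(_align(np.asarray(envelopes[t]), epochs.T, tol),
                                          epochs.rate, band, trim) for t in topics])
        intra = np.array([intrabrain_mean_from_phases(eeg_ph[j]) for j in range(len(topics))])
        for i, j in pairings:
            acc[:, bi] += envelope_plv_from_phases(eeg_ph[j], env_ph[i]) - intra[j]
    return EnvelopePLV(acc / len(pairings), list(bands), role, corrected=True,
                       case_id=case_id)
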