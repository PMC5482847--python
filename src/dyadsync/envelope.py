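"""Speech amplitude envelope extraction and brain-to-envelope PLV.

The envelope is obtained from a short-time power spectrogram of the speech
waveform (power summed over an acoustic band, square-rooted back to an
amplitude) and resampled to the EEG rate. Entrainment of each EEG channel to
the envelope is quantified with the same single-trial PLV used for
interbrain coupling, after band-filtering both the channel and the envelope.

Because volume conduction makes channels of one brain mutually synchronous,
the raw brain-envelope PLV carries an intra-brain offset: the mean PLV over
all within-subject sensor pairs is therefore subtracted per band
(the "intra-brain correction").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .bands import BandSpec
from .phase import DEFAULT_TRIM, analytic_phase, plv_matrix
from .prep import EpochSet


@dataclass
class EnvelopePLV:
    """Brain-to-envelope PLV per channel x band for one participant-case.

    ``corrected`` marks whether the intra-brain mean PLV has been subtracted
    (after which values may be negative).
    """

    values: np.ndarray  # channels x bands
    bands: list[BandSpec]
    role: str  # "speak" or "listen"
    corrected: bool = False
    case_id: tuple | None = None


def amplitude_envelope(audio: np.ndarray, audio_rate: float,
                       out_rate: float = 250.0,
                       window_s: float = 0.025, hop_s: float = 0.004,
                       band: tuple[float, float] = (100.0, 4000.0)) -> np.ndarray:
    """Amplitude envelope of a speech waveform via a power spectrogram.

    Hamming-windowed short-time power is summed over ``band`` and
    square-rooted, then linearly resampled to ``out_rate``. With the default
    4 ms hop the native frame rate is already 250 Hz for common audio rates.
    """
    from scipy import signal as sps

    audio = np.asarray(audio, dtype=np.float64).ravel()
    if audio_rate < 8000:
        raise ValueError("audio rate must be >= 8 kHz for speech")
    if not np.any(audio):
        warnings.warn("all-zero audio: returning an all-zero envelope")
    nperseg = max(int(round(window_s * audio_rate)), 8)
    hop = max(int(round(hop_s * audio_rate)), 1)
    freqs, times, sxx = sps.spectrogram(
        audio, fs=audio_rate, window="hamming", nperseg=nperseg,
        noverlap=nperseg - hop, mode="psd", detrend=False)
    lo, hi = band
    hi = min(hi, audio_rate / 2.0)
    sel = (freqs >= lo) & (freqs <= hi)
    if not np.any(sel):
        raise ValueError("acoustic band empty at this audio rate")
    env_native = np.sqrt(sxx[sel].sum(axis=0))
    n_out = int(round(len(audio) / audio_rate * out_rate))
    t_out = np.arange(n_out) / out_rate
    return np.interp(t_out, times, env_native)


def envelope_phase(env: np.ndarray, rate: float, band: BandSpec,
                   trim: int = DEFAULT_TRIM) -> np.ndarray:
    """Band-filtered Hilbert phase of the envelope's fluctuations."""
    env = np.asarray(env, dtype=np.float64)
    return analytic_phase((env - env.mean())[None, :], rate, band, trim)[0]


def _align(env: np.ndarray, T: int, tol_samples: int) -> np.ndarray:
    if abs(len(env) - T) > tol_samples:
        raise ValueError(f"envelope length {len(env)} does not match epoch length {T}")
    if len(env) >= T:
        return env[:T]
    return np.pad(env, (0, T - len(env)), mode="edge")


def envelope_plv_from_phases(epoch_phase: np.ndarray, env_ph: np.ndarray) -> np.ndarray:
    """PLV of each channel's phase against one envelope phase series."""
    return plv_matrix(epoch_phase, env_ph[None, :])[:, 0]


def intrabrain_mean_from_phases(epoch_phase: np.ndarray) -> float:
    """Mean PLV over all distinct within-subject sensor pairs (n*(n-1)/2)."""
    n = epoch_phase.shape[0]
    if n < 2:
        raise ValueError("need at least 2 channels for intra-brain PLV")
    m = plv_matrix(epoch_phase, epoch_phase)
    iu = np.triu_indices(n, k=1)
    return float(m[iu].mean())


def brain_envelope_plv(epochs: EpochSet, envelopes: dict[str, np.ndarray],
                       role: str, bands: list[BandSpec],
                       trim: int = DEFAULT_TRIM, case_id: tuple | None = None,
                       align_tol_s: float = 0.5) -> EnvelopePLV:
    """Uncorrected brain-to-envelope PLV, averaged across topics.

    ``envelopes`` maps each topic to the envelope heard (listener role) or
    produced (speaker role) in that participant's turn of the topic.
    """
    if role not in ("speak", "listen"):
        raise ValueError("role must be 'speak' or 'listen'")
    tol = int(round(align_tol_s * epochs.rate))
    topics = [ep.topic for ep in epochs.epochs if ep.role == role]
    if set(topics) != set(envelopes):
        raise ValueError("envelope topics do not match epoch topics")
    acc = np.zeros((epochs.n_channels, len(bands)))
    for topic in topics:
        ep = epochs.get(role, topic)
        env = _align(np.asarray(envelopes[topic]), epochs.T, tol)
        for bi, band in enumerate(bands):
            ph = analytic_phase(ep.data, epochs.rate, band, trim)
            acc[:, bi] += envelope_plv_from_phases(ph, envelope_phase(env, epochs.rate, band, trim))
    return EnvelopePLV(acc / len(topics), list(bands), role, corrected=False, case_id=case_id)


def intrabrain_correction(env_plv: EnvelopePLV, epochs: EpochSet,
                          bands: list[BandSpec] | None = None,
                          trim: int = DEFAULT_TRIM) -> EnvelopePLV:
    """Subtract the per-band mean intra-brain PLV from every channel.

    The intra-brain mean is computed per topic epoch of the same role and
    averaged across topics, mirroring the topic-collapse of the envelope PLV
    (the two orders of operations are equivalent because the correction is a
    per-band constant shift).
    """
    if env_plv.corrected:
        raise ValueError("intra-brain correction already applied")
    bands = list(env_plv.bands) if bands is None else list(bands)
    topics = [ep.topic for ep in epochs.epochs if ep.role == env_plv.role]
    means = np.zeros(len(bands))
    for topic in topics:
        ep = epochs.get(env_plv.role, topic)
        for bi, band in enumerate(bands):
            ph = analytic_phase(ep.data, epochs.rate, band, trim)
            means[bi] += intrabrain_mean_from_phases(ph)
    means /= len(topics)
    out = replace(env_plv)
    out.values = env_plv.values - means[None, :]
    out.corrected = True
    return out
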