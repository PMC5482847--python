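"""Band-limited instantaneous phase and phase-locking value (PLV).

The single-trial PLV between two phase time series ``phi`` and ``psi`` is the
modulus of the time-averaged unit phasor of their difference::

    PLV = (1/T) |sum_t exp(i (phi_t - psi_t))|

It ranges from 0 (independent phases) to 1 (constant phase lag). Interbrain
coupling is measured by computing this for every listener-channel x
speaker-channel pair in each frequency band and each 90-s trial, subtracting
the resting-trial baseline, and averaging across conversation topics.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import fft as sfft

from .bands import BandSpec
from .prep import EpochSet, design_fir

DEFAULT_TRIM = 250  # samples removed per edge (1 s at 250 Hz) before PLV


@dataclass
class PhaseSeries:
    """Instantaneous phase per channel, wrapped to (-pi, pi]."""

    phase: np.ndarray  # channels x T'
    band: BandSpec
    trim: int


@dataclass
class PLVTensor:
    """PLV for listener-ch x speaker-ch x band x trial; the last trial is rest."""

    values: np.ndarray
    bands: list[BandSpec]
    topics: list[str]

    def __post_init__(self) -> None:
        L, S, B, K = self.values.shape
        if B != len(self.bands) or K != len(self.topics) + 1:
            raise ValueError("tensor shape inconsistent with band/topic labels")

    @property
    def rest(self) -> np.ndarray:
        return self.values[..., -1]


@dataclass
class CaseCouplingMap:
    """Rest-subtracted, topic-averaged interbrain PLV for one analysis case."""

    values: np.ndarray  # listener-ch x speaker-ch x band, in [-1, 1]
    bands: list[BandSpec]
    case_id: tuple | None = None


def _wrap(phase: np.ndarray) -> np.ndarray:
    # np.angle yields [-pi, pi]; fold the closed lower edge onto +pi
    phase[phase == -np.pi] = np.pi
    return phase


@lru_cache(maxsize=64)
def _fir_taps(rate: float, lo: float, hi: float) -> np.ndarray:
    return design_fir(rate, lo, hi)


def analytic_signal(data: np.ndarray, rate: float, band: BandSpec,
                    axis: int = -1) -> np.ndarray:
    """Zero-phase FIR band-pass plus analytic signal in one FFT pass.

    The signal is odd-reflect padded, multiplied in the frequency domain by
    the forward-backward magnitude response |B(f)|^2 of the windowed-sinc
    band-pass FIR (identical to filtering the FIR forward and backward), the
    negative frequencies are zeroed (Hilbert step), and the pad is cropped.
    float32 input stays in single precision, which halves the FFT cost for
    the bulk pipeline; float64 is the default elsewhere.
    """
    band.validate_rate(rate)
    x = np.asarray(data)
    if x.dtype not in (np.float32, np.float64):
        x = x.astype(np.float64)
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    taps = _fir_taps(rate, band.lo, band.hi)
    padlen = min(len(taps), n - 1)
    if padlen < 1:
        raise ValueError("epoch too short for this band's filter")
    left = 2.0 * x[..., :1] - x[..., 1:padlen + 1][..., ::-1]
    right = 2.0 * x[..., -1:] - x[..., -padlen - 1:-1][..., ::-1]
    xp = np.concatenate([left, x, right], axis=-1)
    nfft = sfft.next_fast_len(max(xp.shape[-1], 2 * len(taps) - 1), real=True)
    gain = np.abs(sfft.rfft(taps, nfft)) ** 2
    X = sfft.rfft(xp, nfft, axis=-1)
    cdtype = np.complex64 if x.dtype == np.float32 else np.complex128
    half = (X * gain.astype(x.dtype)).astype(cdtype)
    half *= 2.0
    half[..., 0] *= 0.5
    if nfft % 2 == 0:
        half[..., -1] *= 0.5
    spec = np.zeros(xp.shape[:-1] + (nfft,), dtype=cdtype)
    spec[..., : half.shape[-1]] = half
    y = sfft.ifft(spec, axis=-1)[..., padlen:padlen + n]
    return np.moveaxis(y, -1, axis)


def analytic_phasors(data: np.ndarray, rate: float, band: BandSpec,
                     trim: int = DEFAULT_TRIM, axis: int = -1) -> np.ndarray:
    """Unit phasors exp(i*phase) of the band-limited analytic signal.

    Identical information to :func:`analytic_phase` (z = exp(i*angle(y)) =
    y/|y|) but skips the angle/exp round trip, which matters for the bulk
    pipeline where only phase differences via products of phasors are needed.
    """
    T = data.shape[axis]
    if 2 * trim >= T:
        raise ValueError("trim removes the entire epoch")
    y = analytic_signal(data, rate, band, axis=axis)
    sl = [slice(None)] * y.ndim
    sl[axis] = slice(trim, T - trim) if trim else slice(None)
    y = np.ascontiguousarray(y[tuple(sl)])
    mag = np.abs(y)
    mag[mag == 0] = 1.0
    y /= mag
    return y


def analytic_phase(data: np.ndarray, rate: float, band: BandSpec, trim: int = DEFAULT_TRIM,
                   axis: int = -1) -> np.ndarray:
    """Band-limited instantaneous phase of every channel, edges trimmed."""
    T = data.shape[axis]
    if 2 * trim >= T:
        raise ValueError("trim removes the entire epoch")
    phase = np.angle(analytic_signal(data, rate, band, axis=axis))
    sl = [slice(None)] * phase.ndim
    sl[axis] = slice(trim, T - trim) if trim else slice(None)
    return _wrap(np.ascontiguousarray(phase[tuple(sl)]))


def instantaneous_phase(data: np.ndarray, rate: float, band: BandSpec,
                        trim: int = DEFAULT_TRIM) -> PhaseSeries:
    """Instantaneous phase of each channel of a single epoch in one band."""
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    return PhaseSeries(analytic_phase(data, rate, band, trim), band, trim)


def plv(phi: np.ndarray, psi: np.ndarray) -> float:
    """Scalar single-trial PLV between two equal-length phase sequences."""
    phi = np.asarray(phi, dtype=np.float64).ravel()
    psi = np.asarray(psi, dtype=np.float64).ravel()
    if phi.shape != psi.shape:
        raise ValueError("phase sequences must have equal length")
    if phi.size < 2:
        raise ValueError("need at least 2 time points")
    return float(np.abs(np.exp(1j * (phi - psi)).mean()))


def plv_matrix(phases_a: np.ndarray, phases_b: np.ndarray) -> np.ndarray:
    """All-pairs PLV between two channel sets sharing a time axis.

    Vectorized as a complex matrix product; equals :func:`plv` applied to
    every (row of a, row of b) pair.
    """
    if phases_a.shape[-1] != phases_b.shape[-1]:
        raise ValueError("phase arrays must share the time axis length")
    T = phases_a.shape[-1]
    za = np.exp(1j * phases_a)
    zb = np.exp(1j * phases_b)
    return np.abs(za @ zb.conj().T) / T


def epochset_phases(es: EpochSet, bands: list[BandSpec],
                    trim: int = DEFAULT_TRIM) -> dict[str, np.ndarray]:
    """Phases of every epoch in every band, computed in one vectorized pass.

    Returns ``{band.name: array of shape (n_epochs, channels, T')}`` with the
    epoch axis in ``es.epochs`` order.
    """
    stack = np.stack([ep.data for ep in es.epochs]).astype(np.float64)
    return {b.name: analytic_phase(stack, es.rate, b, trim, axis=-1) for b in bands}


def _aligned_trials(listener: EpochSet, speaker: EpochSet):
    """Match the listener's listening epochs with the speaker's speaking epochs
    topic-for-topic, appending the rest-for-rest pair last."""
    if listener.rate != speaker.rate or listener.T != speaker.T:
        raise ValueError("epoch sets differ in rate or epoch length")
    topics = [ep.topic for ep in listener.epochs if ep.role == "listen"]
    s_topics = [ep.topic for ep in speaker.epochs if ep.role == "speak"]
    if set(topics) != set(s_topics) or len(topics) != len(s_topics):
        raise ValueError("listener and speaker trial sets are misaligned")
    pairs = [(t, listener.get("listen", t), speaker.get("speak", t)) for t in topics]
    pairs.append(("rest", listener.get("rest"), speaker.get("rest")))
    return topics, pairs


def interbrain_plv(listener: EpochSet, speaker: EpochSet, bands: list[BandSpec],
                   trim: int = DEFAULT_TRIM) -> PLVTensor:
    """Single-trial PLV for all listener x speaker channel pairs.

    For the canonical 27-channel montage and 5 topics this produces the
    27 x 27 x 4 x 6 tensor (5 topics + 1 rest trial).
    """
    topics, pairs = _aligned_trials(listener, speaker)
    L, S = listener.n_channels, speaker.n_channels
    out = np.empty((L, S, len(bands), len(pairs)))
    l_stack = np.stack([lp.data for _, lp, _ in pairs]).astype(np.float64)
    s_stack = np.stack([sp.data for _, _, sp in pairs]).astype(np.float64)
    for bi, band in enumerate(bands):
        ph_l = analytic_phase(l_stack, listener.rate, band, trim, axis=-1)
        ph_s = analytic_phase(s_stack, speaker.rate, band, trim, axis=-1)
        for k in range(len(pairs)):
            out[:, :, bi, k] = plv_matrix(ph_l[k], ph_s[k])
    return PLVTensor(out, list(bands), topics)


def rest_subtract_and_collapse(tensor: PLVTensor, case_id: tuple | None = None) -> CaseCouplingMap:
    """Subtract the resting-trial PLV from each topic trial, then average topics."""
    if len(tensor.topics) < 1:
        raise ValueError("tensor has no topic trials")
    diff = tensor.values[..., :-1] - tensor.rest[..., None]
    return CaseCouplingMap(diff.mean(axis=-1), tensor.bands, case_id)
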