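"""Preprocessing of raw dual-EEG recordings into role-labelled epochs.

The in-scope preprocessing chain is: off-line re-referencing to a named
electrode (or the common average), a zero-phase high-pass FIR at 1 Hz, a
zero-phase low-pass FIR at 20 Hz, and extraction of the fixed-length
role-labelled epochs (one per conversational turn plus one resting epoch).

Artifact correction stages that require human data (ICA component rejection,
PREP-style bad-channel detection) are deliberately not implemented; an
externally cleaned recording can be passed straight in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

REST_LABEL = "rest"
ROLES = ("speak", "listen", "rest")


@dataclass
class RawRecording:
    """A continuous multichannel recording with event markers.

    ``data`` is channels x time in microvolts; ``markers`` is a list of
    ``(sample_index, label)`` with labels ``"speak/<topic>"``,
    ``"listen/<topic>"`` or ``"rest"``. Sample indices are 0-based and mark
    the first sample of a turn; turns occupy half-open intervals
    ``[start, start + T)``.
    """

    data: np.ndarray
    rate: float
    ch_names: list[str]
    reference: str = "none"
    markers: list[tuple[int, str]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x time")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("channel name count does not match data")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel names must be unique")
        for idx, label in self.markers:
            if not (0 <= idx < self.data.shape[1]):
                raise ValueError(f"marker {label!r} at sample {idx} outside recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class Epoch:
    role: str
    topic: str | None
    data: np.ndarray  # channels x T


@dataclass
class EpochSet:
    """Role/topic-labelled fixed-length segments for one participant."""

    epochs: list[Epoch]
    rate: float
    ch_names: list[str]

    @property
    def T(self) -> int:
        return self.epochs[0].data.shape[1]

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)

    def get(self, role: str, topic: str | None = None) -> Epoch:
        for ep in self.epochs:
            if ep.role == role and (topic is None or ep.topic == topic):
                return ep
        raise KeyError((role, topic))

    def topics(self) -> list[str]:
        seen: list[str] = []
        for ep in self.epochs:
            if ep.role != "rest" and ep.topic not in seen:
                seen.append(ep.topic)
        return seen


# ---------------------------------------------------------------------------
# Zero-phase FIR filtering
# ---------------------------------------------------------------------------

def design_fir(rate: float, lo: float | None, hi: float | None,
               cycles: float = 3.0, min_taps: int | None = None) -> np.ndarray:
    """Design a windowed-sinc (Hamming) FIR band/low/high-pass filter.

    The order is chosen so the filter spans at least ``cycles`` cycles of the
    lowest nonzero corner frequency and at least one second of signal, which
    keeps the transition band narrow enough for the low EEG bands.
    """
    nyq = rate / 2.0
    for f in (lo, hi):
        if f is not None and not (0.0 < f < nyq):
            raise ValueError(f"cutoff {f} Hz outside (0, Nyquist={nyq})")
    if lo is None and hi is None:
        raise ValueError("at least one cutoff required")
    f_low_edge = lo if lo is not None else hi
    if min_taps is None:
        min_taps = int(rate)  # >= 1 s of taps
    numtaps = max(int(np.ceil(cycles * rate / f_low_edge)), min_taps)
    numtaps |= 1  # odd length -> type-I linear phase, valid for high-pass
    if lo is not None and hi is not None:
        taps = signal.firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=rate)
    elif lo is not None:
        taps = signal.firwin(numtaps, lo, pass_zero=False, window="hamming", fs=rate)
    else:
        return signal.firwin(numtaps, hi, pass_zero=True, window="hamming", fs=rate)
    # null the residual DC gain of the windowed-sinc design exactly
    return taps - taps.sum() / numtaps


def _apply_zero_phase_kernel(x: np.ndarray, kernel: np.ndarray, padlen: int,
                             axis: int = -1) -> np.ndarray:
    """Convolve with a symmetric zero-phase kernel under odd-reflect padding."""
    x = np.asarray(x, dtype=np.float64)
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    padlen = min(padlen, n - 1)
    if padlen < 1:
        raise ValueError("signal too short for this filter")
    left = 2.0 * x[..., :1] - x[..., 1:padlen + 1][..., ::-1]
    right = 2.0 * x[..., -1:] - x[..., -padlen - 1:-1][..., ::-1]
    xp = np.concatenate([left, x, right], axis=-1)
    y = signal.oaconvolve(xp, kernel.reshape((1,) * (xp.ndim - 1) + (-1,)),
                          mode="same", axes=-1)
    return np.moveaxis(y[..., padlen:padlen + n], -1, axis)


def zero_phase_filter(x: np.ndarray, taps: np.ndarray, axis: int = -1) -> np.ndarray:
    """Apply an FIR forward and backward (zero net phase shift).

    Equivalent to ``scipy.signal.filtfilt(taps, 1, x, padtype="odd",
    padlen=len(taps))`` but runs through a single FFT overlap-add convolution
    with the forward-backward kernel (the filter's autocorrelation), which is
    orders of magnitude faster for the long low-frequency FIRs used here.
    """
    kernel = np.convolve(taps, taps[::-1])  # symmetric, zero-phase
    return _apply_zero_phase_kernel(x, kernel, len(taps), axis=axis)


def zero_phase_cascade(x: np.ndarray, taps_list: list[np.ndarray],
                       axis: int = -1) -> np.ndarray:
    """Several forward-backward FIRs applied as one combined zero-phase kernel."""
    kernel = np.ones(1)
    padlen = 0
    for taps in taps_list:
        kernel = np.convolve(kernel, np.convolve(taps, taps[::-1]))
        padlen += len(taps)
    return _apply_zero_phase_kernel(x, kernel, padlen, axis=axis)


def bandpass(x: np.ndarray, rate: float, lo: float, hi: float, axis: int = -1) -> np.ndarray:
    """Zero-phase band-pass; the single filtering routine reused pipeline-wide."""
    return zero_phase_filter(x, design_fir(rate, lo, hi), axis=axis)


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def rereference(raw: RawRecording, new_reference: str) -> RawRecording:
    """Re-reference to a named channel (that channel becomes zeros) or "average"."""
    if new_reference == "average":
        ref = raw.data.mean(axis=0, keepdims=True)
    else:
        if new_reference not in raw.ch_names:
            raise ValueError(f"reference channel {new_reference!r} not in recording")
        ref = raw.data[raw.ch_names.index(new_reference)][None, :]
    out = replace(raw)
    out.data = raw.data - ref
    out.reference = new_reference
    out.provenance = {**raw.provenance, "reference": new_reference}
    return out


def preprocess_recording(raw: RawRecording, highpass: float | None = 1.0,
                         lowpass: float | None = 20.0,
                         new_reference: str | None = None) -> RawRecording:
    """Re-reference then apply zero-phase high-pass and low-pass FIRs."""
    nyq = raw.rate / 2.0
    for name, f in (("highpass", highpass), ("lowpass", lowpass)):
        if f is not None and f >= nyq:
            raise ValueError(f"{name} cutoff {f} Hz >= Nyquist {nyq} Hz")
    out = rereference(raw, new_reference) if new_reference is not None else replace(
        raw, provenance=dict(raw.provenance))
    data = np.asarray(out.data, dtype=np.float64)
    prov = dict(out.provenance)
    taps_list = []
    if highpass is not None:
        taps = design_fir(raw.rate, highpass, None)
        taps_list.append(taps)
        prov["highpass_hz"] = highpass
        prov["highpass_taps"] = len(taps)
    if lowpass is not None:
        taps = design_fir(raw.rate, None, lowpass)
        taps_list.append(taps)
        prov["lowpass_hz"] = lowpass
        prov["lowpass_taps"] = len(taps)
    if taps_list:
        data = zero_phase_cascade(data, taps_list, axis=-1)
    out.data = data
    out.provenance = prov
    return out


def extract_epochs(raw: RawRecording, epoch_len: float) -> EpochSet:
    """Cut the fixed-length turn epochs out of a continuous recording.

    One epoch per marker; a full conversational session yields one epoch per
    turn plus exactly one resting epoch. Raises if any marked epoch would run
    past the end of the recording.
    """
    T = epoch_len * raw.rate
    if abs(T - round(T)) > 1e-9:
        raise ValueError("epoch_len x rate must be an integer sample count")
    T = int(round(T))
    epochs: list[Epoch] = []
    for start, label in sorted(raw.markers):
        if start + T > raw.n_samples:
            raise ValueError(
                f"epoch for marker {label!r} at sample {start} is truncated "
                f"(needs {T} samples, {raw.n_samples - start} available)")
        if label == REST_LABEL:
            role, topic = "rest", None
        else:
            role, _, topic = label.partition("/")
            if role not in ("speak", "listen") or not topic:
                raise ValueError(f"unrecognised marker label {label!r}")
        epochs.append(Epoch(role, topic, raw.data[:, start:start + T].copy()))
    n_rest = sum(ep.role == "rest" for ep in epochs)
    if n_rest == 0:
        import warnings
        warnings.warn("no resting epoch found; rest-baseline subtraction unavailable")
    return EpochSet(epochs, raw.rate, list(raw.ch_names))
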