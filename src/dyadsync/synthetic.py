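"""Synthetic dyad sessions with known ground-truth coupling.

No public hyperscanning dataset accompanies this pipeline, so every stage is
validated against simulated conversations. A session emulates the study
design: two participants alternate speaker/listener roles over five topics
(ten 90-s turns) plus one joint resting trial, recorded at 250 Hz.

Each EEG channel is a sum of band-limited stochastic phase oscillators (one
per analysis band) on top of 1/f background noise. Interbrain coupling is
injected through shared drivers: for a coupled (listener-channel,
speaker-channel, band) triple both channels' band oscillators are attracted
toward a common stochastic driver phase, with attraction strength scaled by
``kappa`` in [0, 1]. Speech entrainment couples a channel's band oscillator
to the phase of the current turn's band-filtered speech envelope. Resting
trials contain no cross-participant coupling of any kind.

The phase update per sample is::

    theta[t+1] = theta[t] + 2*pi*f/rate
               + kappa * gain * sin(psi[t] - theta[t])
               + phase_noise_sd * N(0, 1)

which gives a continuous, monotone dial from independence (kappa = 0) to
near-perfect phase locking (kappa = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .bands import CANONICAL_BANDS, BandSpec
from .prep import RawRecording

DEFAULT_TOPICS = ("sports", "movies", "animals", "music", "travel")

# 27-electrode 10-20 montage used by the canonical configuration
MONTAGE_27 = [
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "FC1", "FC2", "FC5", "FC6",
    "C3", "C4", "T7", "T8", "CP1", "CP2", "CP5", "CP6", "P3", "P4",
    "P7", "P8", "O1", "O2", "Fz", "Cz", "Pz",
]


def default_channel_names(n: int) -> list[str]:
    if n <= len(MONTAGE_27):
        return MONTAGE_27[:n]
    return MONTAGE_27 + [f"CH{i:02d}" for i in range(len(MONTAGE_27), n)]


@dataclass
class SynthConfig:
    """Parameters of a simulated hyperscanning study.

    ``coupling_table`` maps ``(listener_ch, speaker_ch, band_name) -> kappa``
    (direct interbrain coupling via a shared driver independent of speech);
    ``envelope_coupling`` maps ``(role, ch, band_name) -> kappa`` with role in
    {"speak", "listen"} (entrainment to the turn's speech envelope).
    ``kappa_spread`` models between-dyad variability: each dyad's kappas are
    scaled by a factor drawn uniformly from [1 - kappa_spread, 1].
    """

    n_dyads: int = 15
    n_channels: int = 27
    rate: float = 250.0
    epoch_len: float = 90.0
    n_topics: int = 5
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS
    coupling_table: dict[tuple[int, int, str], float] = field(default_factory=dict)
    envelope_coupling: dict[tuple[str, int, str], float] = field(default_factory=dict)
    syllable_rate: float = 5.0
    noise_exponent: float = 1.0
    seed: int = 0
    # signal-scale knobs
    osc_amp: float = 1.0
    noise_amp: float = 1.0
    phase_noise_sd: float = 0.15      # rad per sample
    driver_jitter_sd: float = 0.05    # rad per sample, shared-driver frequency wander
    attraction_gain: float = 0.2      # rad per sample at kappa = 1
    kappa_spread: float = 0.3
    gap_len: float = 15.0             # seconds between consecutive turns
    topics: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_dyads < 1 or self.n_channels < 1 or self.n_topics < 1:
            raise ValueError("counts must be positive")
        if self.rate <= 0 or self.epoch_len <= 0:
            raise ValueError("rate and epoch_len must be positive")
        if abs(self.rate * self.epoch_len - round(self.rate * self.epoch_len)) > 1e-9:
            raise ValueError("rate x epoch_len must be an integer sample count")
        band_names = {b.name for b in self.bands}
        for (l, s, b), k in self.coupling_table.items():
            if not (0 <= l < self.n_channels and 0 <= s < self.n_channels):
                raise ValueError(f"coupling channel out of range: {(l, s, b)}")
            if b not in band_names:
                raise ValueError(f"unknown band in coupling_table: {b!r}")
            if not 0.0 <= k <= 1.0:
                raise ValueError("kappa must lie in [0, 1]")
        for (role, c, b), k in self.envelope_coupling.items():
            if role not in ("speak", "listen"):
                raise ValueError(f"role must be 'speak' or 'listen', got {role!r}")
            if not 0 <= c < self.n_channels:
                raise ValueError(f"envelope_coupling channel out of range: {(role, c, b)}")
            if b not in band_names:
                raise ValueError(f"unknown band in envelope_coupling: {b!r}")
            if not 0.0 <= k <= 1.0:
                raise ValueError("kappa must lie in [0, 1]")
        if not 0.0 <= self.kappa_spread < 1.0:
            raise ValueError("kappa_spread must lie in [0, 1)")
        if self.topics is None:
            base = list(DEFAULT_TOPICS)
            while len(base) < self.n_topics:
                base.append(f"topic{len(base)}")
            self.topics = tuple(base[: self.n_topics])
        elif len(self.topics) != self.n_topics:
            raise ValueError("topics length must equal n_topics")
        # a channel-band oscillator follows at most one driver
        attached: set[tuple[str, int, str]] = set()
        for (l, s, b) in self.coupling_table:
            for key in (("listen", l, b), ("speak", s, b)):
                if key in attached or key in self.envelope_coupling:
                    raise ValueError(
                        f"channel-band {key} attached to more than one driver")
                attached.add(key)

    @property
    def T(self) -> int:
        return int(round(self.rate * self.epoch_len))


@dataclass(frozen=True)
class GroundTruth:
    """The coupling actually injected: exactly the config entries with kappa > 0."""

    coupled_pairs: frozenset  # of (listener_ch, speaker_ch, band_name)
    entrained_channels: frozenset  # of (role, ch, band_name)


@dataclass
class TurnInfo:
    block: int
    topic: str | None  # None for rest
    speaker: str | None  # participant id, None for rest
    start: int  # sample index of epoch onset


@dataclass
class DyadSession:
    """One simulated dyad: two recordings, per-turn envelopes, turn table."""

    dyad_id: str
    participants: tuple[str, str]
    recordings: dict[str, RawRecording]
    envelopes: dict[tuple[str, str], np.ndarray]  # (topic, speaker_pid) -> 250 Hz env
    turns: list[TurnInfo]
    rate: float
    epoch_len: float


# ---------------------------------------------------------------------------
# Speech envelope
# ---------------------------------------------------------------------------

def _quasi_rhythmic_phase(n: int, f: float, rate: float, rel_jitter: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Phase advancing at ~f Hz with multiplicative rate jitter (quasi-rhythm)."""
    base = 2 * np.pi * f / rate
    inc = base * (1.0 + rel_jitter * rng.standard_normal(n))
    return np.cumsum(inc) + rng.uniform(0, 2 * np.pi)


def generate_speech_envelope(duration: float, rate: float = 250.0,
                             syllable_rate: float = 5.0,
                             seed: int | np.random.Generator = 0) -> np.ndarray:
    """A non-negative quasi-rhythmic speech amplitude envelope.

    Sum of two half-wave-rectified modulators: a slow ~2 Hz (phrasal/delta)
    component and a dominant syllabic component at ``syllable_rate`` (theta
    range for natural speech), both with stochastic rate jitter so that the
    rhythm is quasi-periodic rather than strictly periodic.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    if not (0.5 < syllable_rate < 10.0):
        raise ValueError("syllable_rate must lie in (0.5, 10) Hz")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * rate))
    # generous rate jitter: natural speech is quasi-rhythmic, and distinct
    # utterances must decorrelate within a few seconds
    slow = np.maximum(np.sin(_quasi_rhythmic_phase(n, 2.0, rate, 0.3, rng)), 0.0)
    syl = np.maximum(np.sin(_quasi_rhythmic_phase(n, syllable_rate, rate, 0.4, rng)), 0.0)
    return 0.05 + 0.5 * slow + 1.0 * syl


def synthesize_speech_audio(envelope: np.ndarray, env_rate: float,
                            audio_rate: int = 8000,
                            seed: int | np.random.Generator = 0) -> np.ndarray:
    """Noise-carrier audio whose amplitude envelope follows ``envelope``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_audio = int(round(len(envelope) * audio_rate / env_rate))
    t_env = np.arange(len(envelope)) / env_rate
    t_audio = np.arange(n_audio) / audio_rate
    env_up = np.interp(t_audio, t_env, envelope)
    carrier = rng.standard_normal(n_audio)
    audio = env_up * carrier
    peak = np.max(np.abs(audio))
    return audio / peak * 0.9 if peak > 0 else audio


# ---------------------------------------------------------------------------
# Oscillator integration
# ---------------------------------------------------------------------------

@njit(cache=False)
def _locked_phases(theta0, omega, gain, driver, noise):  # pragma: no cover - numba
    M, T = noise.shape
    out = np.empty((M, T))
    th = theta0.copy()
    for t in range(T):
        for m in range(M):
            th[m] = th[m] + omega[m] + gain[m] * np.sin(driver[m, t] - th[m]) + noise[m, t]
            out[m, t] = th[m]
    return out


def _free_phases(theta0: np.ndarray, omega: np.ndarray, noise: np.ndarray) -> np.ndarray:
    return theta0[:, None] + np.cumsum(omega[:, None] + noise, axis=1)


def _pink_noise(shape: tuple[int, int], exponent: float,
                rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise, unit variance per channel (spectral synthesis)."""
    from scipy import fft as sfft

    n = shape[-1]
    nf = n // 2 + 1
    spec = (rng.standard_normal(shape[:-1] + (nf,))
            + 1j * rng.standard_normal(shape[:-1] + (nf,)))
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = sfft.irfft(spec * scale, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _envelope_band_phase(env: np.ndarray, rate: float, band: BandSpec) -> np.ndarray:
    from .phase import analytic_phase

    return analytic_phase((env - env.mean())[None, :], rate, band, trim=0)[0]


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------

def _epoch_band_phases(cfg: SynthConfig, pids: tuple[str, str], roles: dict[str, str],
                       env_phase: dict[str, np.ndarray] | None, kappa_scale: float,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Phases theta[pid] of shape (n_channels, n_bands, T) for one epoch."""
    T = cfg.T
    nb = len(cfg.bands)
    # shared drivers: one per coupling entry active this epoch (topic turns only)
    drivers: dict[tuple[int, int, str], np.ndarray] = {}
    coupling_active = env_phase is not None  # rest epochs carry no coupling
    if coupling_active:
        for (l, s, bname), k in cfg.coupling_table.items():
            if k > 0:
                band = next(b for b in cfg.bands if b.name == bname)
                omega = 2 * np.pi * band.center / cfg.rate
                inc = omega + cfg.driver_jitter_sd * rng.standard_normal(T)
                drivers[(l, s, bname)] = rng.uniform(0, 2 * np.pi) + np.cumsum(inc)

    # map (pid, ch, band) -> (driver phase series, effective gain, omega)
    attach: dict[tuple[str, int, int], tuple[np.ndarray, float, float]] = {}
    if coupling_active:
        listener = next(p for p, r in roles.items() if r == "listen")
        speaker = next(p for p, r in roles.items() if r == "speak")
        for (l, s, bname), k in cfg.coupling_table.items():
            if k <= 0:
                continue
            bi = [b.name for b in cfg.bands].index(bname)
            band = cfg.bands[bi]
            omega = 2 * np.pi * band.center / cfg.rate
            gain = cfg.attraction_gain * k * kappa_scale
            attach[(listener, l, bi)] = (drivers[(l, s, bname)], gain, omega)
            attach[(speaker, s, bi)] = (drivers[(l, s, bname)], gain, omega)
        for (role, c, bname), k in cfg.envelope_coupling.items():
            if k <= 0:
                continue
            pid = next(p for p, r in roles.items() if r == role)
            bi = [b.name for b in cfg.bands].index(bname)
            band = cfg.bands[bi]
            omega = 2 * np.pi * band.center / cfg.rate
            gain = cfg.attraction_gain * k * kappa_scale
            attach[(pid, c, bi)] = (env_phase[bname], gain, omega)

    out: dict[str, np.ndarray] = {}
    for pid in pids:
        phases = np.empty((cfg.n_channels, nb, T))
        free_idx, free_omega = [], []
        lock_idx, lock_theta0, lock_omega, lock_gain, lock_driver = [], [], [], [], []
        for c in range(cfg.n_channels):
            for bi, band in enumerate(cfg.bands):
                key = (pid, c, bi)
                if key in attach:
                    drv, gain, omega = attach[key]
                    lock_idx.append((c, bi))
                    lock_theta0.append(rng.uniform(0, 2 * np.pi))
                    lock_omega.append(omega)
                    lock_gain.append(gain)
                    lock_driver.append(drv)
                else:
                    free_idx.append((c, bi))
                    free_omega.append(2 * np.pi * rng.uniform(band.lo, band.hi) / cfg.rate)
        if free_idx:
            noise = cfg.phase_noise_sd * rng.standard_normal((len(free_idx), T),
                                                             dtype=np.float32)
            theta0 = rng.uniform(0, 2 * np.pi, len(free_idx))
            th = _free_phases(theta0, np.array(free_omega), noise)
            for row, (c, bi) in enumerate(free_idx):
                phases[c, bi] = th[row]
        if lock_idx:
            noise = cfg.phase_noise_sd * rng.standard_normal((len(lock_idx), T))
            th = _locked_phases(np.array(lock_theta0), np.array(lock_omega),
                                np.array(lock_gain), np.vstack(lock_driver), noise)
            for row, (c, bi) in enumerate(lock_idx):
                phases[c, bi] = th[row]
        out[pid] = phases
    return out


def generate_dyad_session(config: SynthConfig, dyad_index: int = 0
                          ) -> tuple[DyadSession, GroundTruth]:
    """Simulate one dyad's full session (10 conversation turns + 1 rest).

    Returns continuous marker-annotated recordings for both participants plus
    the per-turn speech envelopes and the injected ground truth. Bit-identical
    output for identical config, seed and dyad index.
    """
    if not 0 <= dyad_index < config.n_dyads:
        raise ValueError("dyad_index out of range")
    ss = np.random.SeedSequence(config.seed).spawn(config.n_dyads)[dyad_index]
    rng = np.random.default_rng(ss)

    pids = (f"d{dyad_index:02d}A", f"d{dyad_index:02d}B")
    T, G = config.T, int(round(config.gap_len * config.rate))
    pad = int(round(2.0 * config.rate))

    kappa_scale = 1.0 - config.kappa_spread * rng.uniform()

    # block order: topics plus one rest trial, shuffled; within a topic the
    # starting speaker alternates randomly
    blocks: list[tuple[str | None]] = [(t,) for t in config.topics] + [(None,)]
    rng.shuffle(blocks)

    turns: list[TurnInfo] = []  # epoch-level schedule
    pos = pad
    for bi, (topic,) in enumerate(blocks):
        if topic is None:
            turns.append(TurnInfo(bi, None, None, pos))
            pos += T + G
        else:
            first = pids[int(rng.integers(2))]
            second = pids[1] if first == pids[0] else pids[0]
            for spk in (first, second):
                turns.append(TurnInfo(bi, topic, spk, pos))
                pos += T + G
    total = pos - G + pad

    env_rate = config.rate
    envelopes: dict[tuple[str, str], np.ndarray] = {}
    data = {pid: np.zeros((config.n_channels, total)) for pid in pids}
    markers: dict[str, list[tuple[int, str]]] = {pid: [] for pid in pids}

    for turn in turns:
        if turn.topic is None:
            roles = {pids[0]: "rest", pids[1]: "rest"}
            env_phase = None
            for pid in pids:
                markers[pid].append((turn.start, "rest"))
        else:
            speaker = turn.speaker
            listener = pids[1] if speaker == pids[0] else pids[0]
            roles = {speaker: "speak", listener: "listen"}
            env = generate_speech_envelope(config.epoch_len, env_rate,
                                           config.syllable_rate, rng)
            envelopes[(turn.topic, speaker)] = env
            env_phase = {b.name: _envelope_band_phase(env, env_rate, b)
                         for b in config.bands
                         if any(bn == b.name for (_, _, bn) in config.envelope_coupling)}
            markers[speaker].append((turn.start, f"speak/{turn.topic}"))
            markers[listener].append((turn.start, f"listen/{turn.topic}"))
        phases = _epoch_band_phases(config, pids, roles, env_phase, kappa_scale, rng)
        for pid in pids:
            seg = config.osc_amp * np.cos(phases[pid]).sum(axis=1)
            data[pid][:, turn.start:turn.start + T] += seg

    recordings = {}
    ch_names = default_channel_names(config.n_channels)
    for pid in pids:
        if config.noise_amp > 0:
            data[pid] += config.noise_amp * _pink_noise(
                (config.n_channels, total), config.noise_exponent, rng)
        recordings[pid] = RawRecording(
            data[pid], config.rate, list(ch_names), reference="none",
            markers=markers[pid],
            provenance={"synthetic": True, "dyad": dyad_index, "seed": config.seed})

    gt = GroundTruth(
        frozenset(k for k, v in config.coupling_table.items() if v > 0),
        frozenset(k for k, v in config.envelope_coupling.items() if v > 0))
    session = DyadSession(f"dyad{dyad_index:02d}", pids, recordings, envelopes,
                          turns, config.rate, config.epoch_len)
    return session, gt


def generate_study(config: SynthConfig):
    """Yield ``(DyadSession, GroundTruth)`` for every dyad in the study."""
    for d in range(config.n_dyads):
        yield generate_dyad_session(config, d)
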