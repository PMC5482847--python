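"""Session I/O: the plain fixture format, WAV audio, and standard EEG readers.

A session directory holds one raw float32 matrix per participant plus a JSON
manifest (rate, channel names, marker table, turn schedule, audio files).
Speech audio is stored as one mono WAV per speaking turn. BrainVision and
EDF+ recordings are read through MNE when available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .prep import RawRecording
from .synthetic import DyadSession, TurnInfo, synthesize_speech_audio

MANIFEST_NAME = "manifest.json"


def write_wav(path: Path | str, audio: np.ndarray, rate: int) -> None:
    wavfile.write(str(path), rate, audio.astype(np.float32))


def read_wav(path: Path | str) -> tuple[np.ndarray, int]:
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # noqa: BLE001 - surface the offending file
        raise IOError(f"cannot read audio file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(np.float64), int(rate)


def write_session(session: DyadSession, path: Path | str,
                  audio_rate: int = 8000, write_audio: bool = True,
                  audio_seed: int = 0) -> Path:
    """Write a dyad session in the fixture format (float32 + JSON manifest)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "dyad_id": session.dyad_id,
        "participants": list(session.participants),
        "rate": session.rate,
        "epoch_len": session.epoch_len,
        "turns": [{"block": t.block, "topic": t.topic, "speaker": t.speaker,
                   "start": t.start} for t in session.turns],
        "recordings": {},
        "audio": {},
    }
    for pid, rec in session.recordings.items():
        fname = f"{pid}.bin"
        rec.data.astype(np.float32).tofile(path / fname)
        manifest["recordings"][pid] = {
            "file": fname,
            "shape": list(rec.data.shape),
            "ch_names": rec.ch_names,
            "reference": rec.reference,
            "markers": [[int(i), lab] for i, lab in rec.markers],
        }
    if write_audio:
        for k, ((topic, speaker), env) in enumerate(sorted(session.envelopes.items())):
            fname = f"audio_{speaker}_{topic}.wav"
            audio = synthesize_speech_audio(env, session.rate, audio_rate,
                                            seed=audio_seed + k)
            write_wav(path / fname, audio, audio_rate)
            manifest["audio"][f"{topic}|{speaker}"] = fname
    (path / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))
    return path


def read_session(path: Path | str) -> tuple[dict[str, RawRecording],
                                            dict[tuple[str, str], tuple[np.ndarray, int]],
                                            dict]:
    """Read a fixture-format session.

    Returns ``(recordings, audio, manifest)`` where ``audio`` maps
    ``(topic, speaker_pid)`` to ``(waveform, rate)``.
    """
    path = Path(path)
    mpath = path / MANIFEST_NAME
    if not mpath.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {path}")
    manifest = json.loads(mpath.read_text())
    recordings: dict[str, RawRecording] = {}
    rates = set()
    for pid, spec in manifest["recordings"].items():
        fpath = path / spec["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"missing recording file {fpath}")
        data = np.fromfile(fpath, dtype=np.float32).reshape(spec["shape"])
        recordings[pid] = RawRecording(
            data.astype(np.float64), manifest["rate"], list(spec["ch_names"]),
            reference=spec.get("reference", "none"),
            markers=[(int(i), lab) for i, lab in spec["markers"]],
            provenance={"source": str(fpath)})
        rates.add(manifest["rate"])
    if len(rates) > 1:
        raise ValueError("participants recorded at different rates")
    audio: dict[tuple[str, str], tuple[np.ndarray, int]] = {}
    for key, fname in manifest.get("audio", {}).items():
        topic, speaker = key.split("|")
        audio[(topic, speaker)] = read_wav(path / fname)
    # every speaking turn needs audio when any audio is shipped
    if manifest.get("audio"):
        for t in manifest["turns"]:
            if t["topic"] is not None and (t["topic"], t["speaker"]) not in audio:
                raise ValueError(f"missing audio for speaking turn "
                                 f"{t['topic']!r} by {t['speaker']!r}")
    return recordings, audio, manifest


def session_from_manifest(path: Path | str) -> DyadSession:
    """Rebuild a :class:`DyadSession` (without envelopes) from a fixture dir."""
    recordings, _, manifest = read_session(path)
    turns = [TurnInfo(t["block"], t["topic"], t["speaker"], t["start"])
             for t in manifest["turns"]]
    return DyadSession(manifest["dyad_id"], tuple(manifest["participants"]),
                       recordings, {}, turns, manifest["rate"], manifest["epoch_len"])


# ---------------------------------------------------------------------------
# Standard EEG container readers (BrainVision / EDF+), via MNE
# ---------------------------------------------------------------------------

def read_eeg_file(path: Path | str) -> RawRecording:
    """Read a BrainVision (.vhdr) or EDF (.edf) recording into a RawRecording.

    Annotations become markers (sample index of onset, description).
    """
    import mne  # local import: only needed for real acquisition files

    path = Path(path)
    if path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG container: {path.suffix}")
    data = raw.get_data() * 1e6  # volts -> microvolts
    rate = float(raw.info["sfreq"])
    markers = [(int(round(ann["onset"] * rate)), str(ann["description"]))
               for ann in raw.annotations]
    return RawRecording(data, rate, list(raw.ch_names), markers=markers,
                        provenance={"source": str(path)})
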