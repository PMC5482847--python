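"""End-to-end pipeline: sessions -> coupling maps -> statistics -> exclusion.

Stage order follows the analysis logic: preprocess and epoch both
recordings, compute real and surrogate interbrain coupling maps and real and
surrogate (intra-brain-corrected) envelope entrainment per case, run the
bootstrap real-vs-surrogate group tests with joint FDR correction, fit the
mediation regressions, and derive the final exclusion mask of interbrain
coupling not explained by the speech envelope.

Each dyad contributes two analysis cases (each participant serves once as
speaker and once as listener), so the default 15-dyad study yields 30 cases.
Phases are computed once per participant/band and shared across the real,
surrogate and envelope analyses.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import CANONICAL_BANDS, BandSpec
from .mediation import ExclusionMask, MediationScan, exclusion_mask, mediation_scan
from .phase import DEFAULT_TRIM, analytic_phasors
from .prep import EpochSet, extract_epochs, preprocess_recording
from .stats import GroupStatResult, apply_fdr, bootstrap_paired_test, zscore_map
from .surrogate import enumerate_surrogate_pairings
from .synthetic import DyadSession, SynthConfig, generate_study

log = logging.getLogger("dyadsync")


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    synth: SynthConfig | None = None
    session_dirs: list[str] | None = None
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS
    highpass: float | None = 1.0
    lowpass: float | None = 20.0
    reference: str | None = None  # None: keep the recording's reference
    trim: int = DEFAULT_TRIM
    n_boot: int = 10000
    q: float = 0.05
    mediation_alpha: float = 0.05
    seed: int = 0
    out_dir: str | None = None
    use_audio: bool = False  # recover envelopes from WAV audio when present

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.session_dirs is None):
            raise ValueError("configure exactly one of synth or session_dirs")
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")
        if self.trim < 0:
            raise ValueError("trim must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synth is not None:
            d["synth"]["bands"] = [asdict(b) for b in self.synth.bands]
            d["synth"]["coupling_table"] = [
                [l, s, b, k] for (l, s, b), k in self.synth.coupling_table.items()]
            d["synth"]["envelope_coupling"] = [
                [r, c, b, k] for (r, c, b), k in self.synth.envelope_coupling.items()]
        d["bands"] = [asdict(b) for b in self.bands]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class CaseResult:
    case_id: tuple[str, str]  # (dyad_id, speaker_pid)
    bb_real: np.ndarray       # L x S x bands
    bb_surr: np.ndarray
    env_l_real: np.ndarray    # L x bands (listener role, corrected)
    env_l_surr: np.ndarray
    env_s_real: np.ndarray    # S x bands (speaker role, corrected)
    env_s_surr: np.ndarray


@dataclass
class ResultsBundle:
    """Everything a run produces, plus the provenance to reproduce it."""

    config: PipelineConfig
    case_ids: list[tuple[str, str]]
    bb_real: np.ndarray
    bb_surr: np.ndarray
    env_l_real: np.ndarray
    env_l_surr: np.ndarray
    env_s_real: np.ndarray
    env_s_surr: np.ndarray
    interbrain_stats: GroupStatResult | None = None
    envelope_stats: GroupStatResult | None = None
    bb_sig: np.ndarray | None = None
    env_sig_listener: np.ndarray | None = None
    env_sig_speaker: np.ndarray | None = None
    scan: MediationScan | None = None
    mask: ExclusionMask | None = None
    env_zmap: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def band_names(self) -> list[str]:
        return [b.name for b in self.config.bands]

    # ---- long-format tables -------------------------------------------------
    def interbrain_table(self) -> pd.DataFrame:
        st = self.interbrain_stats
        n, L, S, B = self.bb_real.shape
        l, s, b = np.unravel_index(np.arange(L * S * B), (L, S, B))
        df = pd.DataFrame({
            "listener_ch": l, "speaker_ch": s,
            "band": np.array(self.band_names)[b],
            "mean_real": self.bb_real.mean(0).ravel(),
            "mean_surrogate": self.bb_surr.mean(0).ravel(),
            "t": st.t, "p_raw": st.p_raw, "p_fdr": st.p_fdr,
            "significant": st.significant, "direction": st.direction,
        })
        df["df"] = st.df
        return df

    def envelope_table(self) -> pd.DataFrame:
        st = self.envelope_stats
        n, L, B = self.env_l_real.shape
        S = self.env_s_real.shape[1]
        roles = ["listen"] * (L * B) + ["speak"] * (S * B)
        ch = np.concatenate([np.repeat(np.arange(L), B), np.repeat(np.arange(S), B)])
        bands = np.array(self.band_names)[
            np.concatenate([np.tile(np.arange(B), L), np.tile(np.arange(B), S)])]
        df = pd.DataFrame({
            "role": roles, "channel": ch, "band": bands,
            "mean_real": np.concatenate([self.env_l_real.mean(0).ravel(),
                                         self.env_s_real.mean(0).ravel()]),
            "mean_surrogate": np.concatenate([self.env_l_surr.mean(0).ravel(),
                                              self.env_s_surr.mean(0).ravel()]),
            "zscore_diff": self.env_zmap,
            "t": st.t, "p_raw": st.p_raw, "p_fdr": st.p_fdr,
            "significant": st.significant, "direction": st.direction,
        })
        df["df"] = st.df
        return df

    def write(self, out_dir: Path | str) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.interbrain_table().to_csv(out / "interbrain_stats.tsv", sep="\t", index=False)
        self.envelope_table().to_csv(out / "envelope_stats.tsv", sep="\t", index=False)
        self.scan.to_frame().to_csv(out / "mediation_fits.tsv", sep="\t", index=False)
        self.mask.to_frame().to_csv(out / "surviving_pairs.tsv", sep="\t", index=False)
        prov = {"config": self.config.to_dict(),
                "config_hash": self.config.config_hash(),
                **self.provenance}
        (out / "provenance.json").write_text(json.dumps(prov, indent=1, default=str))
        return out


# ---------------------------------------------------------------------------
# Per-dyad case engine
# ---------------------------------------------------------------------------

def _epoch_index(es: EpochSet) -> dict[tuple[str, str | None], int]:
    return {(ep.role, ep.topic): k for k, ep in enumerate(es.epochs)}


def _intra_mean(z: np.ndarray, T: int) -> float:
    """Mean PLV over distinct within-subject sensor pairs from unit phasors."""
    m = np.abs(z @ z.conj().T) / T
    iu = np.triu_indices(z.shape[0], k=1)
    return float(m[iu].mean())


def analyze_dyad(epochsets: dict[str, EpochSet],
                 envelopes: dict[tuple[str, str], np.ndarray],
                 bands: list[BandSpec], trim: int = DEFAULT_TRIM,
                 dyad_id: str = "dyad",
                 compute_envelope: bool = True) -> list[CaseResult]:
    """Compute both cases of one dyad.

    Phases are computed once per participant/band (single precision: PLV is
    an average over >= 2e4 samples, so float32 phase error is negligible) and
    every topic x topic PLV matrix — real trials, the 20 surrogate pairings
    and the rest baseline — comes out of one batched Gram product of unit
    phasors per case and band.
    """
    pids = sorted(epochsets)
    if len(pids) != 2:
        raise ValueError("a dyad has exactly two participants")
    es = {p: epochsets[p] for p in pids}
    idx = {p: _epoch_index(es[p]) for p in pids}
    topics = es[pids[0]].topics()
    nt = len(topics)
    pairings = enumerate_surrogate_pairings(nt)
    cases = [(pids[0], pids[1]), (pids[1], pids[0])]  # (speaker, listener)
    nch = {p: es[p].n_channels for p in pids}
    nb = len(bands)

    out = {spk: CaseResult(
        (dyad_id, spk),
        np.zeros((nch[lst], nch[spk], nb)), np.zeros((nch[lst], nch[spk], nb)),
        np.zeros((nch[lst], nb)), np.zeros((nch[lst], nb)),
        np.zeros((nch[spk], nb)), np.zeros((nch[spk], nb)))
        for spk, lst in cases}

    off_diag = [(i, j) for i, j in pairings]
    for bi, band in enumerate(bands):
        z = {}
        for p in pids:
            stack = np.stack([ep.data for ep in es[p].epochs]).astype(np.float32)
            z[p] = analytic_phasors(stack, es[p].rate, band, trim, axis=-1)
        Tp = next(iter(z.values())).shape[-1]
        if compute_envelope:
            env_z = {}
            rate0, T0 = es[pids[0]].rate, es[pids[0]].T
            for key, env in envelopes.items():
                e = np.asarray(env[:T0], dtype=np.float32)
                env_z[key] = analytic_phasors((e - e.mean())[None, :], rate0,
                                              band, trim)[0]
        for spk, lst in cases:
            res = out[spk]
            L, S = nch[lst], nch[spk]
            Zl = np.concatenate([z[lst][idx[lst][("listen", t)]] for t in topics])
            Zs = np.concatenate([z[spk][idx[spk][("speak", t)]] for t in topics])
            G = np.abs(Zl @ Zs.conj().T) / Tp  # (nt*L, nt*S)
            G = G.reshape(nt, L, nt, S)
            rest = np.abs(z[lst][idx[lst][("rest", None)]]
                          @ z[spk][idx[spk][("rest", None)]].conj().T) / Tp
            real = np.mean([G[i, :, i, :] for i in range(nt)], axis=0)
            surr = np.mean([G[i, :, j, :] for i, j in off_diag], axis=0)
            res.bb_real[:, :, bi] = real - rest
            res.bb_surr[:, :, bi] = surr - rest

            if not compute_envelope:
                continue
            Ze = np.stack([env_z[(t, spk)] for t in topics])  # (nt, Tp)
            El = (np.abs(Zl @ Ze.conj().T) / Tp).reshape(nt, L, nt)  # eeg i, ch, env j
            Es = (np.abs(Zs @ Ze.conj().T) / Tp).reshape(nt, S, nt)
            intra_l = [_intra_mean(z[lst][idx[lst][("listen", t)]], Tp) for t in topics]
            intra_s = [_intra_mean(z[spk][idx[spk][("speak", t)]], Tp) for t in topics]
            res.env_l_real[:, bi] = np.mean(
                [El[k, :, k] - intra_l[k] for k in range(nt)], axis=0)
            res.env_s_real[:, bi] = np.mean(
                [Es[k, :, k] - intra_s[k] for k in range(nt)], axis=0)
            res.env_l_surr[:, bi] = np.mean(
                [El[j, :, i] - intra_l[j] for i, j in off_diag], axis=0)
            res.env_s_surr[:, bi] = np.mean(
                [Es[j, :, i] - intra_s[j] for i, j in off_diag], axis=0)
    return [out[spk] for spk, _ in cases]


def _dyad_epochsets(session: DyadSession, config: PipelineConfig) -> dict[str, EpochSet]:
    epochsets = {}
    for pid, raw in session.recordings.items():
        pre = preprocess_recording(raw, config.highpass, config.lowpass, config.reference)
        epochsets[pid] = extract_epochs(pre, session.epoch_len)
    return epochsets


def _dyad_envelopes(session: DyadSession, config: PipelineConfig,
                    audio: dict | None) -> dict[tuple[str, str], np.ndarray]:
    if config.use_audio and audio:
        from .envelope import amplitude_envelope

        return {key: amplitude_envelope(wave, rate, out_rate=session.rate)
                for key, (wave, rate) in audio.items()}
    if not session.envelopes:
        raise ValueError("session has neither envelopes nor usable audio")
    return session.envelopes


def iter_sessions(config: PipelineConfig):
    """Yield (session, audio-or-None) per dyad from synth or from disk."""
    if config.synth is not None:
        for session, _ in generate_study(config.synth):
            yield session, None
    else:
        from .io import read_session, session_from_manifest

        for d in config.session_dirs:
            session = session_from_manifest(d)
            _, audio, _ = read_session(d)
            if config.use_audio:
                yield session, audio
            else:
                raise ValueError(
                    "disk sessions carry no stored envelopes; set use_audio=True")


def collect_cases(config: PipelineConfig,
                  compute_envelope: bool = True) -> list[CaseResult]:
    """Run preprocessing + coupling analysis for every dyad and case."""
    bands = list(config.bands)
    results: list[CaseResult] = []
    for session, audio in iter_sessions(config):
        t0 = time.time()
        epochsets = _dyad_epochsets(session, config)
        envs = _dyad_envelopes(session, config, audio) if compute_envelope else {}
        results.extend(analyze_dyad(epochsets, envs, bands, config.trim,
                                    session.dyad_id, compute_envelope))
        log.info("dyad %s: 2 cases analyzed in %.1fs", session.dyad_id,
                 time.time() - t0)
    return results


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Execute every stage and return (and optionally write) all results."""
    t_start = time.time()
    cases = collect_cases(config)
    bundle = ResultsBundle(
        config=config,
        case_ids=[c.case_id for c in cases],
        bb_real=np.stack([c.bb_real for c in cases]),
        bb_surr=np.stack([c.bb_surr for c in cases]),
        env_l_real=np.stack([c.env_l_real for c in cases]),
        env_l_surr=np.stack([c.env_l_surr for c in cases]),
        env_s_real=np.stack([c.env_s_real for c in cases]),
        env_s_surr=np.stack([c.env_s_surr for c in cases]),
    )
    n, L, S, B = bundle.bb_real.shape
    log.info("collected %d cases (%d x %d channels, %d bands) in %.1fs",
             n, L, S, B, time.time() - t_start)

    ss_inter, ss_env = np.random.SeedSequence(config.seed).spawn(2)

    st = bootstrap_paired_test(bundle.bb_real.reshape(n, -1),
                               bundle.bb_surr.reshape(n, -1),
                               config.n_boot, np.random.default_rng(ss_inter))
    apply_fdr(st, config.q)
    bundle.interbrain_stats = st
    bundle.bb_sig = st.enhanced.reshape(L, S, B)
    log.info("interbrain test: %d features, %d significant enhancements",
             st.p_raw.size, int(bundle.bb_sig.sum()))

    env_real = np.concatenate([bundle.env_l_real.reshape(n, -1),
                               bundle.env_s_real.reshape(n, -1)], axis=1)
    env_surr = np.concatenate([bundle.env_l_surr.reshape(n, -1),
                               bundle.env_s_surr.reshape(n, -1)], axis=1)
    st_env = bootstrap_paired_test(env_real, env_surr, config.n_boot,
                                   np.random.default_rng(ss_env))
    apply_fdr(st_env, config.q)
    bundle.envelope_stats = st_env
    enh = st_env.enhanced
    bundle.env_sig_listener = enh[: L * B].reshape(L, B)
    bundle.env_sig_speaker = enh[L * B:].reshape(S, B)
    band_of_feature = np.concatenate([np.tile(np.arange(B), L), np.tile(np.arange(B), S)])
    bundle.env_zmap = zscore_map(env_real, env_surr, band_of_feature)
    log.info("envelope test: %d features, %d significant enhancements",
             enh.size, int(enh.sum()))

    bundle.scan = mediation_scan(bundle.bb_real, bundle.env_l_real,
                                 bundle.env_s_real, bundle.band_names,
                                 config.mediation_alpha)
    bundle.mask = exclusion_mask(bundle.bb_sig, bundle.scan,
                                 bundle.env_sig_listener, bundle.env_sig_speaker)
    log.info("mediation scan done; %d surviving pairs",
             int(bundle.mask.surviving.sum()))

    bundle.provenance = {
        "n_cases": n, "n_listener_ch": L, "n_speaker_ch": S,
        "bands": bundle.band_names, "elapsed_s": round(time.time() - t_start, 2),
    }
    if config.out_dir is not None:
        bundle.write(config.out_dir)
    return bundle
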