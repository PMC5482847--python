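"""Regression-based mediation of interbrain coupling by speech entrainment.

For each listener-channel A x speaker-channel B pair and band, the
interbrain coupling Y across the 30 cases is regressed on the listener's
envelope entrainment at A (x1) and the speaker's envelope entrainment at B
(x2)::

    full:          Y = b0 + b1*x1 + b2*x2 + b12*x1*x2 + e
    listener_only: Y = b0 + b1*x1 + e
    speaker_only:  Y = b0 + b1*x2 + e

A pair whose interbrain coupling is predicted by any of the three models
(overall-model F-test, p < 0.05 uncorrected) is considered speech-mediated.
The final exclusion mask keeps, per band, the significantly coupled pairs
that are (i) not mediated by any model and (ii) do not contain a channel
itself significantly entrained to the envelope in that band for its role —
the "pure" interbrain coupling not explained by the shared speech signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

MODELS = ("full", "listener_only", "speaker_only")

# provenance codes for the exclusion mask
SURVIVES = 0
REMOVED_MEDIATION = 1
REMOVED_ENV_CHANNEL = 2
REMOVED_BOTH = 3


@dataclass
class MediationFit:
    """OLS fit of one model for one channel pair and band."""

    pair: tuple[int, int]
    band: str
    model: str
    beta: np.ndarray
    r2: float
    F: float
    df: tuple[int, int]
    p: float
    ok: bool = True  # False when predictors were collinear/constant


def _design(x1: np.ndarray, x2: np.ndarray, model: str) -> np.ndarray:
    one = np.ones_like(x1)
    if model == "full":
        return np.column_stack([one, x1, x2, x1 * x2])
    if model == "listener_only":
        return np.column_stack([one, x1])
    if model == "speaker_only":
        return np.column_stack([one, x2])
    raise ValueError(f"unknown model {model!r}")


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, float, tuple[int, int], float, bool]:
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    k = p - 1
    df2 = n - p
    ok = rank == p and ss_tot > 0 and df2 > 0
    if not ok:
        return beta, np.nan, np.nan, (k, df2), np.nan, False
    r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    if r2 >= 1.0:
        return beta, 1.0, np.inf, (k, df2), 0.0, True
    F = (r2 / k) / ((1.0 - r2) / df2)
    pval = float(sstats.f.sf(F, k, df2))
    return beta, r2, F, (k, df2), pval, True


def fit_mediation(y: np.ndarray, x1: np.ndarray, x2: np.ndarray, model: str,
                  pair: tuple[int, int] = (-1, -1), band: str = "") -> MediationFit:
    """Ordinary least squares for one mediation model (closed form)."""
    y = np.asarray(y, dtype=np.float64).ravel()
    x1 = np.asarray(x1, dtype=np.float64).ravel()
    x2 = np.asarray(x2, dtype=np.float64).ravel()
    if not (len(y) == len(x1) == len(x2)):
        raise ValueError("y, x1, x2 must have equal length")
    X = _design(x1, x2, model)
    if len(y) < X.shape[1] + 1:
        raise ValueError("too few observations for this model")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("inputs must be finite")
    beta, r2, F, dfs, pval, ok = _ols(y, X)
    return MediationFit(pair, band, model, beta, r2, F, dfs, pval, ok)


@dataclass
class MediationScan:
    """Model fits for every (listener-ch, speaker-ch, band) cell.

    Arrays are keyed by model name, each of shape (L, S, n_bands).
    """

    r2: dict[str, np.ndarray]
    F: dict[str, np.ndarray]
    p: dict[str, np.ndarray]
    bands: list[str]
    alpha: float = 0.05

    def significant(self, model: str, alpha: float | None = None) -> np.ndarray:
        a = self.alpha if alpha is None else alpha
        with np.errstate(invalid="ignore"):
            return self.p[model] < a

    def significant_any(self, alpha: float | None = None) -> np.ndarray:
        masks = [self.significant(m, alpha) for m in MODELS]
        return np.logical_or.reduce(masks)

    def to_frame(self) -> pd.DataFrame:
        L, S, B = self.r2["full"].shape
        rows = []
        for bi, band in enumerate(self.bands):
            for l in range(L):
                for s in range(S):
                    for m in MODELS:
                        rows.append((l, s, band, m, self.r2[m][l, s, bi],
                                     self.F[m][l, s, bi], self.p[m][l, s, bi]))
        return pd.DataFrame(rows, columns=["listener_ch", "speaker_ch", "band",
                                           "model", "r2", "F", "p"])


def mediation_scan(bb: np.ndarray, env_l: np.ndarray, env_s: np.ndarray,
                   bands: list[str], alpha: float = 0.05) -> MediationScan:
    """Fit all three models for every channel pair and band.

    ``bb`` is cases x L x S x bands (interbrain coupling), ``env_l`` cases x
    L x bands (listener entrainment), ``env_s`` cases x S x bands (speaker
    entrainment). 27-channel montages give 729 fits per model per band.
    """
    bb = np.asarray(bb, dtype=np.float64)
    env_l = np.asarray(env_l, dtype=np.float64)
    env_s = np.asarray(env_s, dtype=np.float64)
    n, L, S, B = bb.shape
    if env_l.shape != (n, L, B) or env_s.shape != (n, S, B):
        raise ValueError("case/channel/band dimensions are inconsistent")
    if B != len(bands):
        raise ValueError("band labels do not match the band axis")
    r2 = {m: np.empty((L, S, B)) for m in MODELS}
    F = {m: np.empty((L, S, B)) for m in MODELS}
    p = {m: np.empty((L, S, B)) for m in MODELS}
    for bi in range(B):
        for l in range(L):
            x1 = env_l[:, l, bi]
            for s in range(S):
                x2 = env_s[:, s, bi]
                y = bb[:, l, s, bi]
                for m in MODELS:
                    _, r2_, F_, _, p_, _ = _ols(y, _design(x1, x2, m))
                    r2[m][l, s, bi] = r2_
                    F[m][l, s, bi] = F_
                    p[m][l, s, bi] = p_
    return MediationScan(r2, F, p, list(bands), alpha)


@dataclass
class ExclusionMask:
    """Surviving "pure" interbrain pairs per band, with removal provenance."""

    surviving: np.ndarray  # bool, L x S x bands
    provenance: np.ndarray  # int codes, L x S x bands (only meaningful where bb_sig)
    bands: list[str]
    meta: dict = field(default_factory=dict)

    def pairs(self, band: str) -> set[tuple[int, int]]:
        bi = self.bands.index(band)
        ls, ss = np.nonzero(self.surviving[:, :, bi])
        return set(zip(ls.tolist(), ss.tolist()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bi, band in enumerate(self.bands):
            for l, s in sorted(self.pairs(band)):
                rows.append((l, s, band))
        return pd.DataFrame(rows, columns=["listener_ch", "speaker_ch", "band"])


def exclusion_mask(bb_sig: np.ndarray, scan: MediationScan,
                   env_sig_listener: np.ndarray, env_sig_speaker: np.ndarray,
                   alpha: float | None = None) -> ExclusionMask:
    """Remove speech-explained pairs from the significant interbrain set.

    ``bb_sig`` is bool L x S x bands; ``env_sig_listener``/``env_sig_speaker``
    are bool channels x bands masks of significant envelope entrainment per
    role. A pair is removed if any mediation model is significant for it, or
    if its listener channel (listener role) or speaker channel (speaker role)
    shows significant envelope entrainment in that band.
    """
    bb_sig = np.asarray(bb_sig, dtype=bool)
    L, S, B = bb_sig.shape
    if env_sig_listener.shape != (L, B) or env_sig_speaker.shape != (S, B):
        raise ValueError("envelope significance masks have inconsistent shape")
    med = scan.significant_any(alpha)
    env_pair = env_sig_listener[:, None, :] | env_sig_speaker[None, :, :]
    surviving = bb_sig & ~med & ~env_pair
    prov = np.full((L, S, B), SURVIVES, dtype=int)
    prov[med & ~env_pair] = REMOVED_MEDIATION
    prov[~med & env_pair] = REMOVED_ENV_CHANNEL
    prov[med & env_pair] = REMOVED_BOTH
    return ExclusionMask(surviving, prov, list(scan.bands))
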