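"""Group-level inference: real vs surrogate contrasts across analysis cases.

The test is a nonparametric bootstrap paired t-test: for each feature
(channel pair x band, or role x channel x band) the paired differences
``d = real - surrogate`` across the 30 cases give an observed
``t = mean(d) / (sd(d)/sqrt(n))``; a null distribution is built by
resampling the mean-centered differences with replacement, and the
two-sided p uses the (1+k)/(n_boot+1) convention so p is never zero.
Benjamini-Hochberg FDR correction is applied jointly over all features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupStatResult:
    """Per-feature statistics for a real-vs-surrogate contrast."""

    t: np.ndarray
    p_raw: np.ndarray
    direction: np.ndarray  # sign of mean(real - surrogate)
    df: int
    p_fdr: np.ndarray | None = None
    significant: np.ndarray | None = None
    q: float | None = None
    feature_labels: list | None = None
    n_boot: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def enhanced(self) -> np.ndarray:
        """Significant features with a positive real-minus-surrogate mean."""
        if self.significant is None:
            raise ValueError("run fdr_correct first")
        return self.significant & (self.direction > 0)

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t, "p_raw": self.p_raw, "direction": self.direction}
        if self.p_fdr is not None:
            data["p_fdr"] = self.p_fdr
            data["significant"] = self.significant
        df = pd.DataFrame(data)
        df["df"] = self.df
        if self.feature_labels is not None:
            df.insert(0, "feature", self.feature_labels)
        return df


def bootstrap_paired_test(real: np.ndarray, surrogate: np.ndarray,
                          n_boot: int = 10000,
                          seed: int | np.random.Generator = 0,
                          feature_labels: list | None = None) -> GroupStatResult:
    """Bootstrap paired t-test per feature (columns), cases in rows.

    Vectorized over bootstrap draws through a resample-count matrix, so the
    cost is two (n_boot x n_cases) @ (n_cases x n_features) products.
    """
    real = np.atleast_2d(np.asarray(real, dtype=np.float64))
    surrogate = np.atleast_2d(np.asarray(surrogate, dtype=np.float64))
    if real.shape != surrogate.shape:
        raise ValueError("real and surrogate must have matching shapes")
    n, F = real.shape
    if n < 2:
        raise ValueError("need at least 2 cases")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    d = real - surrogate
    mean_d = d.mean(axis=0)
    sd_d = d.std(axis=0, ddof=1)
    degenerate = sd_d == 0
    if np.any(degenerate):
        warnings.warn(f"{int(degenerate.sum())} feature(s) with zero-variance "
                      "differences; their p set to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs = np.where(degenerate, 0.0, mean_d / (sd_d / np.sqrt(n)))

    dc = d - mean_d  # centered: null hypothesis of zero mean difference
    # resampling with replacement <=> multinomial counts over the n cases
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).astype(np.float64)
    s1 = counts @ dc
    s2 = counts @ (dc ** 2)
    mean_b = s1 / n
    var_b = np.clip((s2 - n * mean_b ** 2) / (n - 1), 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_b = mean_b / np.sqrt(var_b / n)
    t_b[(var_b == 0) & (mean_b == 0)] = 0.0
    t_b[(var_b == 0) & (mean_b != 0)] = np.inf

    exceed = (np.abs(t_b) >= np.abs(t_obs)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_boot + 1.0)
    p[degenerate] = 1.0
    return GroupStatResult(t=t_obs, p_raw=p, direction=np.sign(mean_d), df=n - 1,
                           feature_labels=feature_labels, n_boot=n_boot)


def fdr_correct(p_raw: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg adjusted p values and the significance mask."""
    p_raw = np.asarray(p_raw, dtype=np.float64)
    if p_raw.size == 0:
        return p_raw.copy(), np.zeros(0, dtype=bool)
    if np.any((p_raw < 0) | (p_raw > 1)):
        raise ValueError("p values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p_raw, alpha=q, method="fdr_bh")
    return p_adj, p_adj < q


def apply_fdr(result: GroupStatResult, q: float = 0.05) -> GroupStatResult:
    """Attach FDR-adjusted p values and the mask at level ``q`` in place."""
    result.p_fdr, result.significant = fdr_correct(result.p_raw, q)
    result.q = q
    return result


def zscore_map(real: np.ndarray, surrogate: np.ndarray,
               band_of_feature: np.ndarray | None = None) -> np.ndarray:
    """Mean over cases of the difference of within-band z-scored PLVs.

    Per case, features are z-scored across all features sharing a band label
    (all features jointly when ``band_of_feature`` is None); the map is the
    case-mean of real_z - surrogate_z, as displayed on topographic plots.
    """
    real = np.atleast_2d(np.asarray(real, dtype=np.float64))
    surrogate = np.atleast_2d(np.asarray(surrogate, dtype=np.float64))
    if real.shape != surrogate.shape:
        raise ValueError("real and surrogate must have matching shapes")
    F = real.shape[1]
    bands = np.zeros(F) if band_of_feature is None else np.asarray(band_of_feature)

    def _z(x: np.ndarray) -> np.ndarray:
        out = np.empty_like(x)
        for b in np.unique(bands):
            cols = bands == b
            mu = x[:, cols].mean(axis=1, keepdims=True)
            sd = x[:, cols].std(axis=1, ddof=1, keepdims=True)
            if np.any(sd == 0):
                warnings.warn("zero variance across features within a band; z undefined")
                sd = np.where(sd == 0, np.nan, sd)
            out[:, cols] = (x[:, cols] - mu) / sd
        return out

    return (_z(real) - _z(surrogate)).mean(axis=0)
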