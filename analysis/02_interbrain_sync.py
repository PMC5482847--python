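#!/usr/bin/env python
"""Interbrain synchronization: real vs trial-shuffled surrogate coupling.

Runs preprocessing, phase extraction and the all-pairs PLV analysis for every
case of the study defined by 01_simulate.py, then the bootstrap paired test
with joint BH-FDR correction over all channel pairs x bands. Writes
results/interbrain_stats.tsv and reports the significantly enhanced pairs
against the injected ground truth.
"""

import json
from pathlib import Path

import numpy as np

from dyadsync.cli import load_config
from dyadsync.pipeline import collect_cases
from dyadsync.stats import apply_fdr, bootstrap_paired_test

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = load_config(RESULTS / "study_config.json")
    cases = collect_cases(cfg, compute_envelope=False)
    n = len(cases)
    L, S, B = cases[0].bb_real.shape
    real = np.stack([c.bb_real for c in cases]).reshape(n, -1)
    surr = np.stack([c.bb_surr for c in cases]).reshape(n, -1)
    st = apply_fdr(bootstrap_paired_test(real, surr, cfg.n_boot,
                                         np.random.default_rng(cfg.seed)), cfg.q)
    bands = [b.name for b in cfg.bands]
    frame = st.to_frame()
    l, s, b = np.unravel_index(np.arange(L * S * B), (L, S, B))
    frame.insert(0, "band", np.array(bands)[b])
    frame.insert(0, "speaker_ch", s)
    frame.insert(0, "listener_ch", l)
    RESULTS.mkdir(exist_ok=True)
    frame.to_csv(RESULTS / "interbrain_stats.tsv", sep="\t", index=False)

    enhanced = st.enhanced.reshape(L, S, B)
    truth = json.loads((RESULTS / "study_config.json").read_text())["synth"]
    direct = {(dl, ds, db) for dl, ds, db, _ in truth["coupling_table"]}
    print(f"{n} cases; {L * S * B} tests, "
          f"{int(enhanced.sum())} significantly enhanced pairs at q={cfg.q}")
    for bi, band in enumerate(bands):
        pairs = [(int(x[0]), int(x[1])) for x in np.argwhere(enhanced[:, :, bi])]
        marks = ["*" if (p[0], p[1], band) in direct else "" for p in pairs]
        print(f"  {band}: {len(pairs)} pairs "
              + ", ".join(f"{p}{m}" for p, m in zip(pairs, marks)))
    print("(* = injected direct coupling; unmarked theta pairs arise from the "
          "shared speech envelope)")
    print(f"wrote {RESULTS / 'interbrain_stats.tsv'}")


if __name__ == "__main__":
    main()
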