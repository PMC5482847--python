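"""Synthetic dyad generator: envelope rhythm, coupling dial, determinism."""

import numpy as np
import pytest
from scipy import signal as sps

from dyadsync import (SynthConfig, generate_dyad_session, generate_speech_envelope,
                      plv)
from dyadsync.bands import band_by_name
from dyadsync.phase import analytic_phase

RATE = 250.0


class TestSpeechEnvelope:
    def test_length_and_nonnegativity(self):
        env = generate_speech_envelope(90.0, RATE, 5.0, seed=1)
        assert env.shape == (22500,)
        assert np.all(env >= 0)

    def test_fluctuation_spectrum_peaks_in_theta(self):
        """Periodogram oracle: the dominant fluctuation is syllabic (4-8 Hz)."""
        env = generate_speech_envelope(90.0, RATE, 5.0, seed=2)
        f, p = sps.welch(env - env.mean(), fs=RATE, nperseg=4096)
        peak = f[np.argmax(p)]
        assert 4.0 <= peak <= 8.0

    def test_slow_delta_component_present(self):
        env = generate_speech_envelope(90.0, RATE, 5.0, seed=3)
        f, p = sps.welch(env - env.mean(), fs=RATE, nperseg=4096)
        delta_fraction = p[(f >= 1) & (f <= 3)].sum() / p.sum()
        assert delta_fraction > 0.1

    def test_deterministic_under_seed(self):
        a = generate_speech_envelope(10.0, RATE, 5.0, seed=7)
        b = generate_speech_envelope(10.0, RATE, 5.0, seed=7)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("kwargs", [
        {"duration": -1.0}, {"duration": 10.0, "rate": 0.0},
        {"duration": 10.0, "syllable_rate": 0.2},
        {"duration": 10.0, "syllable_rate": 12.0},
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_speech_envelope(**{"rate": RATE, **kwargs})


class TestConfigValidation:
    def test_coupling_channel_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            SynthConfig(n_channels=3, coupling_table={(0, 5, "alpha"): 0.5})

    def test_kappa_outside_unit_interval(self):
        with pytest.raises(ValueError, match="kappa"):
            SynthConfig(coupling_table={(0, 1, "alpha"): 1.5})

    def test_unknown_band(self):
        with pytest.raises(ValueError, match="band"):
            SynthConfig(coupling_table={(0, 1, "gamma"): 0.5})

    def test_channel_band_single_driver(self):
        with pytest.raises(ValueError, match="driver"):
            SynthConfig(coupling_table={(0, 1, "alpha"): 0.5, (0, 2, "alpha"): 0.5})

    def test_non_integer_sample_count(self):
        with pytest.raises(ValueError, match="integer"):
            SynthConfig(rate=250.0, epoch_len=0.0101)


class TestSession:
    def test_structure_and_ground_truth(self, small_world):
        cfg, session, gt = small_world
        for pid in session.participants:
            labels = [lab for _, lab in session.recordings[pid].markers]
            assert sum(lab.startswith("speak/") for lab in labels) == cfg.n_topics
            assert sum(lab.startswith("listen/") for lab in labels) == cfg.n_topics
            assert labels.count("rest") == 1
        assert gt.coupled_pairs == {(0, 1, "alpha")}
        assert gt.entrained_channels == {("speak", 2, "theta")}
        assert len(session.envelopes) == 2 * cfg.n_topics

    def test_default_config_gives_11_epochs(self):
        cfg = SynthConfig(n_dyads=1, n_channels=2, epoch_len=2.0, gap_len=0.5, seed=0)
        session, _ = generate_dyad_session(cfg, 0)
        assert len(session.recordings[session.participants[0]].markers) == 11

    def test_bit_identical_under_same_seed(self):
        cfg = SynthConfig(n_dyads=2, n_channels=2, epoch_len=4.0, gap_len=1.0,
                          n_topics=2, seed=42)
        s1, _ = generate_dyad_session(cfg, 1)
        s2, _ = generate_dyad_session(cfg, 1)
        for pid in s1.participants:
            assert np.array_equal(s1.recordings[pid].data, s2.recordings[pid].data)
            assert s1.recordings[pid].markers == s2.recordings[pid].markers

    def test_different_dyads_differ(self):
        cfg = SynthConfig(n_dyads=2, n_channels=2, epoch_len=4.0, gap_len=1.0,
                          n_topics=2, seed=42)
        s1, _ = generate_dyad_session(cfg, 0)
        s2, _ = generate_dyad_session(cfg, 1)
        assert not np.array_equal(s1.recordings[s1.participants[0]].data,
                                  s2.recordings[s2.participants[0]].data)


def _pair_plv(session, cfg, l_ch, s_ch, band_name, topic, speaker):
    """PLV of the coupled pair's band components in one turn, via the
    band-filter + Hilbert + PLV oracle on the generated signals."""
    band = band_by_name(band_name)
    listener = [p for p in session.participants if p != speaker][0]
    T = cfg.T
    start = next(t.start for t in session.turns
                 if t.topic == topic and t.speaker == speaker)
    seg_l = session.recordings[listener].data[l_ch, start:start + T]
    seg_s = session.recordings[speaker].data[s_ch, start:start + T]
    ph_l = analytic_phase(seg_l[None], cfg.rate, band, trim=250)[0]
    ph_s = analytic_phase(seg_s[None], cfg.rate, band, trim=250)[0]
    return plv(ph_l, ph_s)


class TestCouplingDial:
    def test_full_coupling_without_noise_locks_phases(self):
        """kappa=1, no noise: the pair's band components reach PLV > 0.95."""
        cfg = SynthConfig(n_dyads=1, n_channels=2, epoch_len=20.0, gap_len=1.0,
                          n_topics=1, coupling_table={(0, 1, "alpha"): 1.0},
                          phase_noise_sd=0.0, noise_amp=0.0, kappa_spread=0.0,
                          seed=5)
        session, _ = generate_dyad_session(cfg, 0)
        for turn in session.turns:
            if turn.topic is None:
                continue
            v = _pair_plv(session, cfg, 0, 1, "alpha", turn.topic, turn.speaker)
            assert v > 0.95

    def test_rest_epoch_has_no_cross_participant_coupling(self):
        cfg = SynthConfig(n_dyads=1, n_channels=2, epoch_len=20.0, gap_len=1.0,
                          n_topics=1, coupling_table={(0, 1, "alpha"): 1.0},
                          phase_noise_sd=0.15, noise_amp=0.0, kappa_spread=0.0,
                          seed=5)
        session, _ = generate_dyad_session(cfg, 0)
        band = band_by_name("alpha")
        rest_start = next(t.start for t in session.turns if t.topic is None)
        a, b = session.participants
        ph = [analytic_phase(session.recordings[p].data[c, rest_start:rest_start + cfg.T][None],
                             cfg.rate, band, 250)[0] for p, c in ((a, 0), (b, 1))]
        assert plv(ph[0], ph[1]) < 0.3

    def test_mean_plv_monotone_in_kappa(self):
        """The coupling strength dial: mean pair PLV is non-decreasing in kappa."""
        means = []
        for kappa in (0.0, 0.25, 0.5, 1.0):
            vals = []
            for rep in range(3):
                table = {(0, 1, "theta"): kappa} if kappa > 0 else {}
                cfg = SynthConfig(n_dyads=1, n_channels=2, epoch_len=15.0,
                                  gap_len=1.0, n_topics=2, coupling_table=table,
                                  noise_amp=0.3, kappa_spread=0.0, seed=100 + rep)
                session, _ = generate_dyad_session(cfg, 0)
                for turn in session.turns:
                    if turn.topic is None:
                        continue
                    vals.append(_pair_plv(session, cfg, 0, 1, "theta",
                                          turn.topic, turn.speaker))
            means.append(np.mean(vals))
        assert all(b >= a - 0.02 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0] + 0.3

    def test_envelope_entrainment_drives_band_phase(self):
        """An entrained channel locks to the envelope's band-filtered phase."""
        cfg = SynthConfig(n_dyads=1, n_channels=1, epoch_len=20.0, gap_len=1.0,
                          n_topics=1,
                          envelope_coupling={("speak", 0, "theta"): 1.0},
                          phase_noise_sd=0.02, noise_amp=0.0, kappa_spread=0.0,
                          seed=6)
        session, _ = generate_dyad_session(cfg, 0)
        band = band_by_name("theta")
        turn = next(t for t in session.turns if t.topic is not None)
        env = session.envelopes[(turn.topic, turn.speaker)]
        seg = session.recordings[turn.speaker].data[0, turn.start:turn.start + cfg.T]
        ph_eeg = analytic_phase(seg[None], cfg.rate, band, 250)[0]
        ph_env = analytic_phase((env - env.mean())[None], cfg.rate, band, 250)[0]
        assert plv(ph_eeg, ph_env) > 0.8
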