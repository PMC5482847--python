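"""Instantaneous phase and phase-locking value identities and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from dyadsync.bands import CANONICAL_BANDS, band_by_name
from dyadsync.phase import (PLVTensor, analytic_phase, analytic_phasors,
                            instantaneous_phase, interbrain_plv, plv, plv_matrix,
                            rest_subtract_and_collapse)
from tests.conftest import make_epochset

RATE = 250.0
ALPHA = band_by_name("alpha")


class TestInstantaneousPhase:
    def test_sinusoid_phase_advances_at_its_frequency(self):
        """Analytic phase of a 10 Hz tone is linear with slope 2*pi*10/s."""
        t = np.arange(10000) / RATE
        x = np.cos(2 * np.pi * 10.0 * t)
        ps = instantaneous_phase(x, RATE, ALPHA, trim=500)
        phase = np.unwrap(ps.phase[0])
        slope = np.polyfit(np.arange(len(phase)) / RATE, phase, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10.0, rel=0.01)

    def test_quadrature_pair_has_constant_half_pi_lag(self):
        t = np.arange(10000) / RATE
        c = instantaneous_phase(np.cos(2 * np.pi * 10 * t), RATE, ALPHA, 500).phase[0]
        s = instantaneous_phase(np.sin(2 * np.pi * 10 * t), RATE, ALPHA, 500).phase[0]
        diff = np.angle(np.exp(1j * (c - s)))
        circ_sd = np.sqrt(-2 * np.log(np.abs(np.exp(1j * diff).mean())))
        assert np.abs(np.angle(np.exp(1j * diff).mean()) - np.pi / 2) < 0.02
        assert circ_sd < 0.05

    def test_trim_arithmetic(self):
        x = np.zeros((3, 22500))
        x[:] = np.cos(2 * np.pi * 10 * np.arange(22500) / RATE)
        ps = instantaneous_phase(x, RATE, ALPHA, trim=250)
        assert ps.phase.shape == (3, 22000)

    def test_band_above_nyquist_rejected(self):
        from dyadsync.bands import BandSpec
        with pytest.raises(ValueError):
            instantaneous_phase(np.zeros((1, 1000)), RATE, BandSpec("x", 100, 130), 0)

    def test_phases_wrapped_to_half_open_interval(self):
        rng = np.random.default_rng(0)
        ps = instantaneous_phase(rng.standard_normal((2, 4000)), RATE, ALPHA, 100)
        assert np.all(ps.phase > -np.pi) and np.all(ps.phase <= np.pi)

    def test_phasors_agree_with_phases(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 3000))
        z = analytic_phasors(x, RATE, ALPHA, 100)
        ph = analytic_phase(x, RATE, ALPHA, 100)
        assert np.allclose(z, np.exp(1j * ph), atol=1e-9)
        assert np.allclose(np.abs(z), 1.0, atol=1e-12)


class TestPLV:
    def test_identical_sequences_give_exactly_one(self):
        rng = np.random.default_rng(2)
        phi = rng.uniform(-np.pi, np.pi, 22500)
        assert plv(phi, phi) == pytest.approx(1.0, abs=1e-12)

    def test_cancelling_differences_give_zero(self):
        phi = np.zeros(1000)
        psi = np.tile([0.0, np.pi], 500)
        assert plv(phi, psi) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_phase_null_level(self):
        """Monte-Carlo oracle: mean PLV of independent uniform phases is
        ~sqrt(pi/(4T)); 95% of replicates stay below 0.015 at T=22500."""
        rng = np.random.default_rng(3)
        T, reps = 22500, 200
        vals = np.array([plv(rng.uniform(-np.pi, np.pi, T),
                             rng.uniform(-np.pi, np.pi, T)) for _ in range(reps)])
        assert vals.mean() == pytest.approx(np.sqrt(np.pi / (4 * T)), abs=1e-3)
        assert np.quantile(vals, 0.95) < 0.015

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            plv(np.zeros(10), np.zeros(11))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(phi=hnp.arrays(np.float64, st.integers(2, 200),
                          elements=st.floats(-10, 10)),
           c=st.floats(-7, 7))
    def test_range_symmetry_offset_invariance(self, phi, c):
        rng = np.random.default_rng(len(phi))
        psi = rng.uniform(-np.pi, np.pi, len(phi))
        v = plv(phi, psi)
        assert 0.0 <= v <= 1.0 + 1e-12
        assert v == pytest.approx(plv(psi, phi), abs=1e-12)
        assert v == pytest.approx(plv(phi + c, psi), abs=1e-10)


class TestInterbrainPLV:
    def test_vectorized_matches_scalar_loop(self):
        """plv_matrix equals the scalar plv applied pairwise, to 1e-12."""
        rng = np.random.default_rng(4)
        a = rng.uniform(-np.pi, np.pi, (4, 600))
        b = rng.uniform(-np.pi, np.pi, (3, 600))
        m = plv_matrix(a, b)
        loop = np.array([[plv(a[i], b[j]) for j in range(3)] for i in range(4)])
        assert np.allclose(m, loop, atol=1e-12)

    def test_identical_signals_give_unit_diagonal(self):
        rng = np.random.default_rng(5)
        arrays = [rng.standard_normal((3, 3000)) for _ in range(2)]
        rest = rng.standard_normal((3, 3000))
        listener = make_epochset(arrays, topics=("a", "b"), role="listen", rest=rest)
        speaker = make_epochset(arrays, topics=("a", "b"), role="speak", rest=rest)
        tensor = interbrain_plv(listener, speaker, list(CANONICAL_BANDS), trim=250)
        for bi in range(4):
            for k in range(3):
                assert np.allclose(np.diag(tensor.values[:, :, bi, k]), 1.0, atol=1e-6)

    def test_tensor_shape_topics_plus_rest(self):
        rng = np.random.default_rng(6)
        mk = lambda role: make_epochset([rng.standard_normal((2, 2500))
                                         for _ in range(3)],
                                        topics=("a", "b", "c"), role=role,
                                        rest=rng.standard_normal((2, 2500)))
        tensor = interbrain_plv(mk("listen"), mk("speak"), list(CANONICAL_BANDS), 250)
        assert tensor.values.shape == (2, 2, 4, 4)
        assert np.all((tensor.values >= 0) & (tensor.values <= 1))

    def test_misaligned_topics_rejected(self):
        rng = np.random.default_rng(7)
        l = make_epochset([rng.standard_normal((2, 2500))], topics=("a",),
                          role="listen", rest=np.zeros((2, 2500)))
        s = make_epochset([rng.standard_normal((2, 2500))], topics=("b",),
                          role="speak", rest=np.zeros((2, 2500)))
        with pytest.raises(ValueError, match="misaligned"):
            interbrain_plv(l, s, list(CANONICAL_BANDS), 250)


class TestRestSubtract:
    def _tensor(self, values):
        return PLVTensor(values, list(CANONICAL_BANDS)[: values.shape[2]],
                         [f"t{i}" for i in range(values.shape[3] - 1)])

    def test_topics_equal_rest_gives_zero(self):
        v = np.tile(np.random.default_rng(8).uniform(size=(3, 3, 2, 1)), (1, 1, 1, 4))
        out = rest_subtract_and_collapse(self._tensor(v))
        assert np.allclose(out.values, 0.0)

    def test_constant_shift_recovered(self):
        rng = np.random.default_rng(9)
        rest = rng.uniform(0, 0.5, (2, 2, 1, 1))
        v = np.concatenate([rest + 0.2] * 3 + [rest], axis=3)
        out = rest_subtract_and_collapse(self._tensor(v))
        assert np.allclose(out.values, 0.2)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(10)
        v = rng.uniform(size=(3, 4, 2, 6))
        out = rest_subtract_and_collapse(self._tensor(v))
        expect = np.zeros((3, 4, 2))
        for l in range(3):
            for s in range(4):
                for b in range(2):
                    acc = 0.0
                    for k in range(5):
                        acc += v[l, s, b, k] - v[l, s, b, 5]
                    expect[l, s, b] = acc / 5
        assert np.allclose(out.values, expect, atol=1e-12)
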