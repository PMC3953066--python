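"""Forward relaxation model, domain-type invariants and the decay generator."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from seednmr.core import (
    AcquisitionConfig,
    Component,
    ComponentSet,
    DecayCurve,
    InvalidModelError,
    NoiseModel,
    SampleMeta,
    evaluate_model,
    simulate_decay,
    simulate_imbibition_series,
)
from seednmr.reference import reference_set


def raw_multiexp(amplitudes, t2s, t):
    """Independent arithmetic oracle: sum_i A_i exp(-t/T2_i) via math.exp."""
    return sum(a * math.exp(-t / t2) for a, t2 in zip(amplitudes, t2s))


class TestEvaluateModel:
    def test_t0_limit_is_total_amplitude(self):
        cs = ComponentSet.from_amplitudes([100.0], [100.0])
        tiny = np.finfo(float).tiny
        assert evaluate_model(cs, [tiny])[0] == pytest.approx(100.0, rel=1e-12)

    def test_wt_dry_value_at_first_echo(self, wt_dry):
        # hand evaluation of the 4-component wild-type dry set at t = 0.2 ms
        expected = raw_multiexp(
            [49.1, 11.5, 20.2, 19.2], [0.0164, 0.231, 35.2, 138.0], 0.2
        )
        assert expected == pytest.approx(44.10, abs=0.01)
        assert evaluate_model(wt_dry, [0.2])[0] == pytest.approx(expected, rel=1e-9)

    def test_fully_relaxed_bound(self, wt_imb):
        t = 10.0 * wt_imb.t2s.max()
        assert evaluate_model(wt_imb, [t])[0] < 0.005

    def test_rejects_nonpositive_times(self, wt_dry):
        with pytest.raises(InvalidModelError):
            evaluate_model(wt_dry, [0.0, 1.0])

    @given(
        amps=st.lists(st.floats(1.0, 100.0), min_size=1, max_size=4),
        t2_logs=st.lists(st.floats(-2.0, 3.0), min_size=1, max_size=4, unique=True),
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_and_linearity(self, amps, t2_logs):
        n = min(len(amps), len(t2_logs))
        t2s = np.sort(10.0 ** np.asarray(sorted(t2_logs[:n])))
        assume(np.all(np.diff(t2s) > 1e-9 * t2s[:-1])) if n > 1 else None
        amps, t2s = amps[:n], list(t2s)
        cs = ComponentSet.from_amplitudes(amps, t2s)
        # conservation: the t->0 extrapolation equals the normalized total
        tiny = np.finfo(float).tiny
        assert evaluate_model(cs, [tiny])[0] == pytest.approx(100.0, rel=1e-6)
        # linearity: the normalized model times its raw scale is additive
        t = np.array([0.01, 1.0, 50.0])
        total = sum(amps)
        combined = evaluate_model(cs, t) * total / 100.0
        parts = sum(
            a * np.exp(-t / t2) for a, t2 in zip(amps, t2s)
        )
        np.testing.assert_allclose(combined, parts, rtol=1e-9)

    def test_noiseless_decay_strictly_decreasing(self, wt_imb):
        curve = simulate_decay(wt_imb, AcquisitionConfig.cpmg(n_points=2000))
        assert np.all(np.diff(curve.signal) < 0)


class TestSimulateDecay:
    def test_zero_noise_reproduces_model(self, wt_dry):
        curve = simulate_decay(wt_dry, AcquisitionConfig.cpmg(), NoiseModel(0.0, 1))
        np.testing.assert_array_equal(
            curve.signal, evaluate_model(wt_dry, curve.times)
        )
        assert curve.signal[0] == pytest.approx(
            raw_multiexp([49.1, 11.5, 20.2, 19.2], [0.0164, 0.231, 35.2, 138.0], 0.2),
            rel=1e-9,
        )

    def test_seeded_reproducibility(self, wt_dry):
        a = simulate_decay(wt_dry, AcquisitionConfig.cpmg(), NoiseModel(0.3, 42))
        b = simulate_decay(wt_dry, AcquisitionConfig.cpmg(), NoiseModel(0.3, 42))
        np.testing.assert_array_equal(a.signal, b.signal)
        c = simulate_decay(wt_dry, AcquisitionConfig.cpmg(), NoiseModel(0.3, 43))
        assert not np.array_equal(a.signal, c.signal)

    def test_fid_window_sees_only_the_solid(self, wt_dry):
        curve = simulate_decay(wt_dry, AcquisitionConfig.fid())
        assert len(curve) == 150
        assert curve.times[-1] == pytest.approx(0.06)
        # by the end of the FID the solid (T2 = 0.0164 ms) is < 3 % remaining
        assert math.exp(-0.06 / 0.0164) < 0.03

    def test_default_acquisitions_match_instrument_settings(self):
        cpmg = AcquisitionConfig.cpmg()
        fid = AcquisitionConfig.fid()
        assert (cpmg.echo_time, cpmg.n_points, cpmg.n_scans) == (0.2, 8000, 16)
        assert (fid.dwell_time, fid.n_points, fid.n_scans) == (0.0004, 150, 16)
        assert cpmg.time_grid()[0] == 0.2 and fid.time_grid()[0] == 0.0004


class TestImbibitionSeries:
    def test_limits(self, wt_dry, wt_imb):
        acq = AcquisitionConfig.cpmg(n_points=500)
        start_curve = simulate_decay(wt_dry, acq)
        # t=0 reproduces the start set exactly
        series = simulate_imbibition_series(wt_dry, wt_imb, [1.0] * 5, [0.0], acq)
        np.testing.assert_allclose(series[0].signal, start_curve.signal, rtol=1e-12)
        # tau -> infinity: every timepoint stays at the start set
        series = simulate_imbibition_series(wt_dry, wt_imb, [1e12] * 5, [5.0, 24.0], acq)
        for c in series:
            np.testing.assert_allclose(c.signal, start_curve.signal, rtol=1e-9)

    def test_e_folding_mixture(self, wt_dry, wt_imb):
        # closed form: at t = tau the amplitudes sit at the 1/e mixing point
        tau, t = 0.5, 0.5
        acq = AcquisitionConfig.cpmg(n_points=500)
        series = simulate_imbibition_series(wt_dry, wt_imb, [tau] * 5, [t], acq)
        mix = math.exp(-1.0)
        start_amps = np.append(wt_dry.amplitudes, 0.0)
        expected = wt_imb.amplitudes + (start_amps - wt_imb.amplitudes) * mix
        lnt2 = np.log(wt_imb.t2s) + (
            np.log(np.append(wt_dry.t2s, wt_imb.t2s[-1])) - np.log(wt_imb.t2s)
        ) * mix
        cs = ComponentSet.from_amplitudes(expected, np.exp(lnt2), state="imbibed")
        np.testing.assert_allclose(series[0].signal, evaluate_model(cs, series[0].times),
                                   rtol=1e-9)

    def test_rejects_nonpositive_tau(self, wt_dry, wt_imb):
        with pytest.raises(InvalidModelError):
            simulate_imbibition_series(wt_dry, wt_imb, [0.0] * 5, [1.0],
                                       AcquisitionConfig.cpmg(n_points=10))


class TestTypeInvariants:
    def test_component_guards(self):
        with pytest.raises(InvalidModelError):
            Component(10.0, -1.0)
        with pytest.raises(InvalidModelError):
            Component(-5.0, 1.0)
        with pytest.raises(InvalidModelError):
            Component(10.0, 1.0, label="water")

    def test_component_set_requires_normalized_increasing(self):
        with pytest.raises(InvalidModelError):
            ComponentSet((Component(50.0, 1.0), Component(49.0, 2.0)))
        with pytest.raises(InvalidModelError):
            ComponentSet.from_amplitudes([50, 50], [2.0, 2.0])
        cs = ComponentSet.from_amplitudes([30, 10], [5.0, 1.0])
        assert cs.amplitudes.sum() == pytest.approx(100.0)
        assert np.all(np.diff(cs.t2s) > 0)

    def test_decay_curve_guards(self):
        acq = AcquisitionConfig.cpmg(n_points=3)
        with pytest.raises(InvalidModelError):
            DecayCurve(np.array([0.0, 0.2, 0.4]), np.zeros(3), acq)
        with pytest.raises(InvalidModelError):
            DecayCurve(np.array([0.2, 0.2, 0.4]), np.zeros(3), acq)
        with pytest.raises(InvalidModelError):
            DecayCurve(np.array([0.2, 0.4]), np.array([1.0, np.nan]), acq)

    def test_sample_meta_dry_consistency(self):
        with pytest.raises(InvalidModelError):
            SampleMeta(seed_mass=200.0, added_water_mass=50.0, imbibition_time=0.0)
        meta = SampleMeta(seed_mass=210.0, added_water_mass=180.0, imbibition_time=24.0)
        assert meta.total_mass == pytest.approx(390.0)

    def test_reference_rows_shape(self):
        for name in ("wt-dry", "mum2-dry", "myb5-dry"):
            assert len(reference_set(name)) == 4
        for name in ("wt-imb-24h", "mum2-imb-24h", "myb5-imb-24h"):
            assert len(reference_set(name)) == 5
        assert len(reference_set("wt-wsm-imb-1h")) == 4
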