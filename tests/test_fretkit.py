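"""FRET calibration, E computation, trace selection, population decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smtirfkit.fretkit import (
    CalibrationConstants,
    FretTrace,
    GaussianComponent,
    PopulationSummary,
    annotate_bleach_events,
    build_efret_histogram,
    classify_center,
    compute_efret,
    detect_bleach_steps,
    ensemble_fret,
    estimate_beta_gamma,
    fit_three_gaussians,
    qc_preparation,
    select_traces,
)
from smtirfkit.simkit import TraceNoise

from conftest import REF_BETA, REF_GAMMA, make_fret_trace

CALIB = CalibrationConstants(beta=REF_BETA, gamma=REF_GAMMA)


def as_fret_trace(sim, background=0.0, **kwargs):
    return FretTrace(
        times=sim.times,
        f_d=sim.f_d,
        f_a=sim.f_a,
        donor_bleach_frame=sim.donor_bleach_frame,
        acceptor_bleach_frame=sim.acceptor_bleach_frame,
        background=background,
        **kwargs,
    )


def synthetic_histogram(weights, centers, sigmas, bin_width=0.02):
    edges = np.arange(-0.2, 1.2 + bin_width / 2, bin_width)
    x = 0.5 * (edges[:-1] + edges[1:])
    y = sum(
        w * np.exp(-((x - c) ** 2) / (2 * s**2)) / (s * np.sqrt(2 * np.pi))
        for w, c, s in zip(weights, centers, sigmas)
    ) * bin_width
    return x, y


class TestEnsembleFret:
    @pytest.mark.parametrize(
        "f_da,f_d,expected", [(1000.0, 1000.0, 0.0), (0.0, 1000.0, 1.0), (800.0, 1000.0, 0.2)]
    )
    def test_donor_quenching_values(self, f_da, f_d, expected):
        assert ensemble_fret(f_da, f_d) == pytest.approx(expected)

    def test_zero_donor_reference_rejected(self):
        with pytest.raises(ValueError):
            ensemble_fret(100.0, 0.0)


class TestBleachSteps:
    def test_acceptor_bleach_located_within_two_frames(self, rng):
        sim, _ = make_fret_trace(
            e_levels=((0.4, 3000.0),), acceptor_bleach_rate=1 / 20.0, n_frames=600, seed=21,
            noise=TraceNoise(background=100.0, read_noise_sd=10.0, shot_noise=True),
        )
        assert sim.acceptor_bleach_frame is not None
        steps = detect_bleach_steps(sim.f_a)
        down = [k for k in steps if sim.f_a[k:k + 5].mean() < sim.f_a[k - 5:k].mean()]
        assert any(abs(k - sim.acceptor_bleach_frame) <= 2 for k in down)

    def test_no_bleach_trace_has_no_steps(self, rng):
        x = rng.normal(1000.0, 20.0, 400)
        assert detect_bleach_steps(x) == []

    def test_blinking_trace_counted_and_rejected(self):
        x = np.concatenate([np.full(100, 1000.0), np.full(50, 100.0), np.full(100, 1000.0)])
        steps = detect_bleach_steps(x)
        assert len(steps) == 2
        tr = FretTrace(times=np.arange(250) * 0.1, f_d=x, f_a=np.full(250, 500.0))
        events = annotate_bleach_events(tr)
        assert events["anomalous"]

    def test_cross_channel_echo_is_one_event(self):
        # donor bleach drops F_D and its bleed-through in F_A simultaneously
        sim, _ = make_fret_trace(
            e_levels=((0.4, 3000.0),), donor_bleach_rate=1 / 20.0,
            acceptor_bleach_rate=1 / 8.0, n_frames=600, seed=3,
        )
        tr = as_fret_trace(sim)
        events = annotate_bleach_events(tr)
        assert not events["anomalous"]
        assert len(events["acceptor"]) <= 1 and len(events["donor"]) <= 1


class TestBetaGamma:
    def test_noiseless_roundtrip_exact(self):
        sim, _ = make_fret_trace(
            e_levels=((0.4, 3000.0),), acceptor_bleach_rate=1 / 25.0, n_frames=600, seed=11
        )
        calib = estimate_beta_gamma([as_fret_trace(sim)])
        assert calib.beta == pytest.approx(REF_BETA, abs=1e-9)
        assert calib.gamma == pytest.approx(REF_GAMMA, abs=1e-9)
        e = compute_efret(sim.f_d, sim.f_a, calib)
        pre = slice(0, sim.acceptor_bleach_frame - 1)
        assert np.allclose(e[pre], 0.4, atol=1e-9)

    def test_zero_bleedthrough_recovered(self):
        sim, _ = make_fret_trace(
            e_levels=((0.3, 3000.0),), beta=0.0, acceptor_bleach_rate=1 / 25.0,
            n_frames=600, seed=12,
        )
        calib = estimate_beta_gamma([as_fret_trace(sim)])
        assert calib.beta == pytest.approx(0.0, abs=1e-9)

    def test_noisy_median_within_five_percent(self):
        traces = []
        seed = 0
        while len(traces) < 20:
            sim, _ = make_fret_trace(
                e_levels=((0.4, 3000.0),), acceptor_bleach_rate=1 / 25.0, n_frames=600,
                noise=TraceNoise(background=100.0, read_noise_sd=10.0, shot_noise=True),
                seed=100 + seed,
            )
            seed += 1
            if sim.acceptor_bleach_frame is not None and 20 < sim.acceptor_bleach_frame < 560:
                traces.append(as_fret_trace(sim, background=100.0))
        calib = estimate_beta_gamma(traces)
        assert calib.beta == pytest.approx(REF_BETA, rel=0.05)
        assert calib.gamma == pytest.approx(REF_GAMMA, rel=0.05)

    def test_no_qualifying_traces_rejected(self):
        sim, _ = make_fret_trace(e_levels=((0.4, 3000.0),), n_frames=200)
        with pytest.raises(ValueError):
            estimate_beta_gamma([as_fret_trace(sim)])


class TestComputeEfret:
    def test_symmetric_calibration_half(self):
        calib = CalibrationConstants(beta=0.0, gamma=1.0)
        assert compute_efret(np.array([500.0]), np.array([500.0]), calib)[0] == pytest.approx(0.5)

    def test_pure_bleedthrough_is_zero(self):
        e = compute_efret(np.array([1000.0]), np.array([REF_BETA * 1000.0]), CALIB)
        assert e[0] == pytest.approx(0.0, abs=1e-12)

    def test_printed_constants_hand_value(self):
        # (500 - 0.073*1000) / ((500 - 0.073*1000) + 0.423*1000) = 427/850
        e = compute_efret(np.array([1000.0]), np.array([500.0]), CALIB)
        assert e[0] == pytest.approx(427.0 / 850.0, abs=1e-12)

    def test_invalid_denominator_flagged_nan(self):
        e = compute_efret(np.array([-100.0]), np.array([-100.0]), CALIB)
        assert np.isnan(e[0])

    @given(
        f_a=st.floats(10.0, 5000.0),
        delta=st.floats(1.0, 500.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_acceptor(self, f_a, delta):
        f_d = np.array([1000.0])
        lo = compute_efret(f_d, np.array([f_a]), CALIB)[0]
        hi = compute_efret(f_d, np.array([f_a + delta]), CALIB)[0]
        assert hi > lo

    @given(f_d=st.floats(50.0, 5000.0), f_a=st.floats(50.0, 5000.0))
    @settings(max_examples=50, deadline=None)
    def test_reduces_to_proximity_ratio(self, f_d, f_a):
        calib = CalibrationConstants(beta=0.0, gamma=1.0)
        e = compute_efret(np.array([f_d]), np.array([f_a]), calib)[0]
        assert e == pytest.approx(f_a / (f_a + f_d))


def _compliant_trace(seed=0):
    sim, _ = make_fret_trace(
        e_levels=((0.4, 3000.0),),
        acceptor_bleach_rate=1 / 30.0,
        n_frames=600,
        noise=TraceNoise(background=100.0, read_noise_sd=10.0, shot_noise=True),
        seed=seed,
    )
    return as_fret_trace(sim, background=100.0, acceptor_direct_excitation=True)


class TestSelectTraces:
    def test_compliant_trace_accepted(self):
        for seed in range(5):
            tr = _compliant_trace(seed)
            if tr.acceptor_bleach_frame is not None and 60 < tr.acceptor_bleach_frame < 550:
                break
        accepted = select_traces([tr], CALIB)
        assert tr.accepted, tr.flags
        assert accepted == [tr]

    def test_each_criterion_fails_distinctly(self):
        """Five traces, each violating exactly one criterion, plus a clean one."""
        n = 600
        t = np.arange(n) * 0.1
        i_tot = 3000.0
        f_d_level = i_tot * 0.6
        f_a_level = REF_GAMMA * i_tot * 0.4 + REF_BETA * f_d_level

        def base():
            f_d = np.full(n, f_d_level)
            f_a = np.full(n, f_a_level)
            # acceptor bleach at frame 400, well separated from the end
            f_a[400:] = REF_BETA * i_tot
            f_d[400:] = i_tot
            return f_d, f_a

        # (i) blinking: donor drops and recovers
        f_d, f_a = base()
        f_d[200:240] = 0.0
        t_i = FretTrace(times=t, f_d=f_d, f_a=f_a, acceptor_direct_excitation=True)

        # (ii) dim: total emission scaled below 2000 counts
        f_d, f_a = base()
        t_ii = FretTrace(times=t, f_d=f_d * 0.3, f_a=f_a * 0.3, acceptor_direct_excitation=True)

        # (iii) donor bleaches 1 s before the movie ends: baseline too short
        f_d, f_a = base()
        f_d[590:] = 0.0
        f_a[590:] = 0.0
        t_iii = FretTrace(times=t, f_d=f_d, f_a=f_a, acceptor_direct_excitation=True)

        # (iv) donor bleaches at 4 s
        f_d, f_a = base()
        f_d, f_a = f_d.copy(), f_a.copy()
        f_d[40:] = 0.0
        f_a[40:] = 0.0
        f_a[:40] = f_a_level
        t_iv = FretTrace(times=t, f_d=f_d, f_a=f_a, acceptor_direct_excitation=True)

        # (v) no acceptor: donor-only trace, donor bleaches mid-movie
        f_d = np.full(n, i_tot)
        f_d[300:] = 0.0
        f_a = REF_BETA * f_d
        t_v = FretTrace(times=t, f_d=f_d, f_a=f_a, acceptor_direct_excitation=False)

        clean = FretTrace(times=t, f_d=base()[0], f_a=base()[1], acceptor_direct_excitation=True)

        traces = [t_i, t_ii, t_iii, t_iv, t_v, clean]
        accepted = select_traces(traces, CALIB)
        assert accepted == [clean]
        failed = [
            [k for k, ok in tr.flags.items() if not ok] for tr in (t_i, t_ii, t_iii, t_iv, t_v)
        ]
        assert failed == [["i"], ["ii"], ["iii"], ["iv"], ["v"]]

    def test_aggregation_prefilter(self):
        f_d, f_a = np.full(300, 9000.0), np.full(300, 1000.0)
        f_d[200:] = 0.0
        tr = FretTrace(times=np.arange(300) * 0.1, f_d=f_d, f_a=f_a, acceptor_direct_excitation=True)
        select_traces([tr], CALIB)
        assert not tr.flags["prefilter"]


class TestHistogram:
    def test_constant_trace_single_bin(self):
        tr = FretTrace(
            times=np.arange(300) * 0.1,
            f_d=np.full(300, 1000.0),
            f_a=np.full(300, 1000.0),
            e_fret=np.full(300, 0.31),
        )
        centers, dens = build_efret_histogram([tr])
        assert dens.sum() == pytest.approx(1.0)
        assert dens.max() == pytest.approx(1.0)
        assert abs(centers[np.argmax(dens)] - 0.31) <= 0.01

    def test_unequal_length_traces_contribute_equally(self):
        short = FretTrace(
            times=np.arange(60) * 0.1, f_d=np.zeros(60), f_a=np.zeros(60),
            e_fret=np.full(60, 0.30),
        )
        long = FretTrace(
            times=np.arange(600) * 0.1, f_d=np.zeros(600), f_a=np.zeros(600),
            e_fret=np.full(600, 0.50),
        )
        _, dens = build_efret_histogram([short, long])
        peaks = np.sort(dens[dens > 0.4])
        assert len(peaks) == 2
        assert peaks[0] == pytest.approx(peaks[1])

    def test_bimodal_mixture_equal_masses(self):
        traces = []
        for k in range(10):
            e = 0.3 if k % 2 == 0 else 0.5
            traces.append(
                FretTrace(
                    times=np.arange(100) * 0.1, f_d=np.zeros(100), f_a=np.zeros(100),
                    e_fret=np.full(100, e),
                )
            )
        centers, dens = build_efret_histogram(traces)
        m_lo = dens[np.abs(centers - 0.3) < 0.02].sum()
        m_hi = dens[np.abs(centers - 0.5) < 0.02].sum()
        assert m_lo == pytest.approx(m_hi, rel=1e-9)
        assert m_lo + m_hi == pytest.approx(1.0)


class TestThreeGaussians:
    def test_analytic_peak_area(self):
        comp = GaussianComponent(amplitude=1.0, center=0.3, sigma=1.0)
        assert comp.area == pytest.approx(np.sqrt(2 * np.pi), abs=1e-12)
        assert comp.area == pytest.approx(2.50663, abs=1e-5)

    def test_known_mixture_decomposed(self):
        weights = (0.2, 0.3, 0.5)
        x, y = synthetic_histogram(weights, (0.05, 0.30, 0.50), (0.04, 0.05, 0.06))
        comps, summary = fit_three_gaussians(x, y)
        assert np.allclose([c.center for c in comps], (0.05, 0.30, 0.50), atol=0.01)
        shares = np.array([c.area for c in comps])
        shares = 100 * shares / shares.sum()
        assert np.allclose(shares, 100 * np.asarray(weights), atol=3.0)
        assert summary.lf_percent + summary.mf_percent + summary.hf_percent == pytest.approx(100.0)

    def test_compact_regime_is_hf_majority(self):
        # dominant population near E~0.5 with a minor one at 0.3
        x, y = synthetic_histogram((0.1, 0.25, 0.65), (0.05, 0.30, 0.50), (0.04, 0.05, 0.06))
        _, summary = fit_three_gaussians(x, y)
        assert summary.hf_percent > 50.0
        assert summary.hf_percent > summary.mf_percent > summary.lf_percent

    def test_center_classification_boundaries(self):
        assert classify_center(0.19) == "LF"
        assert classify_center(0.2) == "MF"
        assert classify_center(0.4) == "MF"
        assert classify_center(0.41) == "HF"

    def test_share_invariance_under_bin_origin_shift(self):
        weights = (0.2, 0.3, 0.5)
        x1, y1 = synthetic_histogram(weights, (0.05, 0.30, 0.50), (0.04, 0.05, 0.06))
        x2 = x1 + 0.01  # half-bin shift
        y2 = sum(
            w * np.exp(-((x2 - c) ** 2) / (2 * s**2)) / (s * np.sqrt(2 * np.pi))
            for w, c, s in zip(weights, (0.05, 0.30, 0.50), (0.04, 0.05, 0.06))
        ) * 0.02
        _, s1 = fit_three_gaussians(x1, y1)
        _, s2 = fit_three_gaussians(x2, y2)
        assert s1.hf_percent == pytest.approx(s2.hf_percent, abs=2.0)
        assert s1.lf_percent == pytest.approx(s2.lf_percent, abs=2.0)

    def test_sparse_histogram_rejected(self):
        x = np.arange(-0.2, 1.2, 0.02)
        y = np.zeros_like(x)
        y[5] = 1.0
        with pytest.raises(ValueError):
            fit_three_gaussians(x, y)


class TestQcGate:
    @pytest.mark.parametrize("lf,expected", [(60.0, False), (10.0, True), (50.0, False)])
    def test_lf_population_gate(self, lf, expected):
        summary = PopulationSummary(lf_percent=lf, mf_percent=100 - lf, hf_percent=0.0, n_traces=10)
        assert qc_preparation(summary) is expected
        assert summary.qc_pass is expected
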