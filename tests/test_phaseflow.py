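import numpy as np
import pytest

from okntrack.phaseflow import (
    PhaseStack,
    SingularSystemError,
    compute_phase_stack,
    extract_point_trace,
    median_filter_phase,
    phase_delta,
    solve_displacement,
    temporal_unwrap,
)

from conftest import fft_shift, make_texture


# ---------------------------------------------------------------------------
# temporal unwrapping
# ---------------------------------------------------------------------------

def test_unwrap_passthrough_without_jumps():
    x = np.array([0.1, 0.2, 0.3])
    assert np.allclose(temporal_unwrap(x), x)


def test_unwrap_minimal_two_pi_correction():
    out = temporal_unwrap(np.array([3.0, -3.0]))
    assert out[0] == 3.0
    assert out[1] == pytest.approx(3.0 + (2 * np.pi - 6.0))


def test_unwrap_constant_series():
    x = np.full(10, -2.5)
    assert np.array_equal(temporal_unwrap(x), x)


def test_unwrap_properties_random_walk():
    """Output differs from input by multiples of 2*pi; consecutive diffs small."""
    rng = np.random.default_rng(0)
    truth = np.cumsum(rng.normal(0, 1.0, size=200))
    wrapped = np.mod(truth + np.pi, 2 * np.pi) - np.pi
    out = temporal_unwrap(wrapped)
    k = (out - wrapped) / (2 * np.pi)
    assert np.allclose(k, np.round(k), atol=1e-9)
    d = np.diff(out)
    assert np.all(d > -np.pi) and np.all(d <= np.pi)


def test_unwrap_empty_errors():
    with pytest.raises(ValueError):
        temporal_unwrap(np.array([]))


# ---------------------------------------------------------------------------
# phase stack operations
# ---------------------------------------------------------------------------

def _toy_stack(T=8, L=3, h=5, w=5, seed=0):
    rng = np.random.default_rng(seed)
    phase = rng.normal(size=(T, L, h, w)).cumsum(axis=0) * 0.1
    amp = np.abs(rng.normal(1.0, 0.1, size=(T, L, h, w)))
    return PhaseStack(t=np.arange(T, dtype=float), phase=phase, amplitude=amp)


def test_phase_delta_zero_at_reference():
    st = _toy_stack()
    assert np.all(phase_delta(st, 0) == 0)
    assert np.all(np.isfinite(phase_delta(st, 5)))


def test_phase_delta_temporal_ramp():
    T = 10
    omega = 0.37
    phase = (omega * np.arange(T))[:, None, None, None] * np.ones((1, 2, 3, 3))
    st = PhaseStack(t=np.arange(T, dtype=float), phase=phase,
                    amplitude=np.ones_like(phase))
    for t in range(T):
        assert phase_delta(st, t) == pytest.approx(omega * t)


def test_median_filter_identity_and_spike_removal():
    st = _toy_stack()
    assert median_filter_phase(st, 1) is st

    T = 11
    series = 0.2 * np.arange(T)
    series_sp = series.copy()
    series_sp[5] += 2.0  # single-sample impulse
    phase = series_sp[:, None, None, None] * np.ones((1, 1, 3, 3))
    st2 = PhaseStack(t=np.arange(T, dtype=float), phase=phase,
                     amplitude=np.ones_like(phase))
    filtered = median_filter_phase(st2, 3).phase[:, 0, 1, 1]
    # sliding-median oracle on the 1-D series
    padded = np.concatenate([series_sp[:1], series_sp, series_sp[-1:]])
    oracle = np.array([np.median(padded[i:i + 3]) for i in range(T)])
    assert np.allclose(filtered, oracle)
    # the 2.0-radian spike is suppressed to its neighbourhood's level
    assert abs(filtered[5] - series[5]) <= 0.2 + 1e-12


def test_median_filter_preserves_monotonicity():
    st = _toy_stack()
    mono = np.sort(st.phase, axis=0)
    st_mono = PhaseStack(t=st.t, phase=mono, amplitude=st.amplitude)
    out = median_filter_phase(st_mono, 5).phase
    assert np.all(np.diff(out, axis=0) >= 0)


def test_median_filter_even_window_rejected():
    with pytest.raises(ValueError):
        median_filter_phase(_toy_stack(), 4)


# ---------------------------------------------------------------------------
# weighted least-squares solve
# ---------------------------------------------------------------------------

def _constructed_stack(gradients, deltas, amps=None):
    """Stack with prescribed per-level spatial gradients and phase deltas at
    the center pixel of a 5x5 window, two frames."""
    L = len(gradients)
    h = w = 5
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    phase0 = np.stack([gx * xx + gy * yy for gx, gy in gradients])
    phase1 = phase0 + np.array(deltas)[:, None, None]
    phase = np.stack([phase0, phase1])
    amp = np.ones((2, L, h, w)) if amps is None else np.broadcast_to(
        np.asarray(amps)[None, :, None, None], (2, L, h, w)).copy()
    return PhaseStack(t=np.array([0.0, 1.0]), phase=phase, amplitude=amp)


def test_solve_consistent_system_exact():
    """Deltas constructed as grad_x * 0.3 with an independent y level recover
    (0.3, 0.0)."""
    gradients = [(0.5, 0.0), (0.8, 0.0), (0.3, 0.0), (0.0, 0.6)]
    deltas = [0.5 * 0.3, 0.8 * 0.3, 0.3 * 0.3, 0.0]
    st = _constructed_stack(gradients, deltas)
    dx, dy = solve_displacement(st, pixel=(2, 2), t_index=1)
    assert dx == pytest.approx(0.3, abs=1e-10)
    assert dy == pytest.approx(0.0, abs=1e-10)


def test_solve_two_orthogonal_levels_closed_form():
    """With exactly two orthogonal levels the solution equals the hand-solved
    2x2 inverse: dx = delta_x / gx, dy = delta_y / gy."""
    gx, gy = 0.7, 0.4
    dmx, dmy = 0.21, -0.1
    st = _constructed_stack([(gx, 0.0), (0.0, gy)], [dmx, dmy])
    dx, dy = solve_displacement(st, pixel=(2, 2), t_index=1)
    assert dx == pytest.approx(dmx / gx, abs=1e-10)
    assert dy == pytest.approx(dmy / gy, abs=1e-10)


def test_solve_weighted_normal_equations():
    """Weights A_l(x,t)*A_l(x,0) enter the normal equations: the solution of
    an inconsistent system matches an independent lstsq with those weights."""
    gradients = [(0.5, 0.1), (0.2, 0.7), (0.9, -0.3)]
    deltas = [0.2, -0.05, 0.4]
    amps = [1.0, 2.0, 0.5]
    st = _constructed_stack(gradients, deltas, amps)
    dx, dy = solve_displacement(st, pixel=(2, 2), t_index=1)
    A = np.array(gradients)
    b = np.array(deltas)
    W = np.diag(np.array(amps))  # sqrt of amplitude-product weights
    ref, *_ = np.linalg.lstsq(W @ A, W @ b, rcond=None)
    assert np.allclose([dx, dy], ref, atol=1e-10)


def test_solve_single_orientation_singular():
    st = _constructed_stack([(0.5, 0.0), (0.8, 0.0)], [0.1, 0.16])
    with pytest.raises(SingularSystemError, match="x=2"):
        solve_displacement(st, pixel=(2, 2), t_index=1)


def test_solve_zero_amplitude_singular():
    st = _constructed_stack([(0.5, 0.0), (0.0, 0.5)], [0.1, 0.1],
                            amps=[0.0, 0.0])
    with pytest.raises(SingularSystemError):
        solve_displacement(st, pixel=(2, 2), t_index=1)


# ---------------------------------------------------------------------------
# point traces on synthetic texture (FFT shift oracle)
# ---------------------------------------------------------------------------

def test_static_video_zero_trace(texture192, bank192):
    video = np.stack([texture192] * 5)
    tr = extract_point_trace(video, bank192, (96, 96))
    assert np.all(tr.valid)
    assert np.allclose(tr.dx, 0.0, atol=1e-6)
    assert np.allclose(tr.dy, 0.0, atol=1e-6)


def test_constant_subpixel_shift_recovery(texture192, bank192):
    delta = 0.30
    video = np.stack([texture192] + [fft_shift(texture192, delta)] * 4)
    tr = extract_point_trace(video, bank192, (96, 96))
    est = float(np.median(tr.dx[1:]))
    assert abs(est - delta) / delta < 0.10
    assert np.max(np.abs(tr.dy[1:])) < 0.05


def test_tiny_sinusoidal_translation(texture192, bank192):
    """Amplitude 0.01 px sinusoidal motion over 40 frames recovered within
    25% on noiseless texture."""
    amp = 0.01
    T = 40
    motion = amp * np.sin(2 * np.pi * np.arange(T) / 20.0)
    video = np.stack([fft_shift(texture192, d) for d in motion])
    tr = extract_point_trace(video, bank192, (96, 96))
    est = float(np.max(np.abs(tr.dx)))
    assert abs(est - amp) / amp < 0.25


def test_linearity_small_amplitudes(texture192, bank192):
    """Doubling a 0.1 px translation doubles the estimate within 5%."""
    ests = []
    for d in (0.1, 0.2):
        video = np.stack([texture192, fft_shift(texture192, d)])
        tr = extract_point_trace(video, bank192, (96, 96))
        ests.append(tr.dx[1])
    assert ests[1] / ests[0] == pytest.approx(2.0, rel=0.05)


def test_direction_fidelity(texture192, bank192):
    """Pure horizontal motion leaks less than 10% into the vertical output."""
    video = np.stack([texture192, fft_shift(texture192, 0.5)])
    tr = extract_point_trace(video, bank192, (96, 96))
    assert abs(tr.dy[1]) <= 0.1 * abs(tr.dx[1])


def test_no_temporal_differentiation(texture192, bank192):
    """Samples depend only on their own frame and the reference: removing an
    interior frame changes nothing about the other samples."""
    motion = [0.0, 0.1, 0.25, 0.4, 0.3]
    frames = [fft_shift(texture192, d) for d in motion]
    # median_window=1: the temporal median smoothing is the one (optional)
    # stage that couples neighbouring frames; the estimator itself does not
    tr_full = extract_point_trace(
        np.stack(frames), bank192, (96, 96), median_window=1
    )
    tr_cut = extract_point_trace(
        np.stack(frames[:2] + frames[3:]), bank192, (96, 96), median_window=1
    )
    kept = [0, 1, 3, 4]
    assert np.allclose(tr_full.dx[kept], tr_cut.dx, atol=1e-9)


def test_point_near_border_rejected(texture192, bank192):
    with pytest.raises(ValueError, match="border"):
        extract_point_trace(np.stack([texture192] * 2), bank192, (2, 96))


def test_amplitude_range_graceful_degradation(texture192, bank192):
    """Relative error stays within 10% at 0.5 px and 25% at 0.01 px."""
    for delta, tol in [(0.5, 0.10), (0.01, 0.25)]:
        video = np.stack([texture192, fft_shift(texture192, delta)])
        tr = extract_point_trace(video, bank192, (96, 96))
        assert abs(tr.dx[1] - delta) / delta < tol


def test_compute_phase_stack_double_matches_single(texture192, bank192):
    video = np.stack([texture192, fft_shift(texture192, 0.2)])
    s1 = compute_phase_stack(video, bank192, (96, 96), 7, precision="single")
    s2 = compute_phase_stack(video, bank192, (96, 96), 7, precision="double")
    assert np.allclose(s1.phase, s2.phase, atol=1e-4)
    assert np.allclose(s1.amplitude, s2.amplitude, rtol=1e-4, atol=1e-4)
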