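"""Stokes reconstruction, calibration fitting/application, DoLP and AoP."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pclar import (CalibrationMatrix, DetectorConfig, StokesLinear,
                   StokesSweep, aop, apply_calibration, dolp, fit_calibration,
                   stokes_linear)
from pclar.calibration import (DegenerateSweepError, IllConditionedError,
                               UndefinedAngleError, read_calibration,
                               write_calibration)
from pclar.instrument import (generate_calibration_sweep, measure_beam,
                              render_rows, rows_to_stokes)


@pytest.mark.parametrize("rows,expected", [
    ((0.5, 0.0, 0.5), (1.0, 0.0, 1.0)),   # ideal 45°-linear beam
    ((1.0, 0.5, 0.0), (1.0, 1.0, 0.0)),   # ideal 0°-linear beam
    ((0.25, 0.25, 0.25), (0.5, 0.0, 0.0)),  # unpolarized beam
])
def test_stokes_from_three_rows(rows, expected):
    s = stokes_linear(*rows)
    assert (float(s.I), float(s.Q), float(s.U)) == pytest.approx(expected)


def test_negative_row_intensity_rejected():
    with pytest.raises(ValueError):
        stokes_linear(-0.1, 0.0, 0.0)


def test_q_u_undefined_at_zero_intensity():
    s = stokes_linear(0.0, 0.0, 0.0)
    with pytest.raises(ZeroDivisionError):
        _ = s.q


@settings(deadline=None, max_examples=50, derandomize=True)
@given(I=st.floats(0.1, 1e3), p=st.floats(0.0, 1.0), ang=st.floats(-90.0, 90.0))
def test_ideal_render_then_reconstruct_is_identity(I, p, ang):
    """Rendering any physical beam through ideal analyzer rows and applying
    the three-row reconstruction recovers (I, Q, U)."""
    a = np.deg2rad(2 * ang)
    beam = StokesLinear(I=I, Q=I * p * np.cos(a), U=I * p * np.sin(a))
    det = DetectorConfig()
    rows = render_rows(beam, det)
    s = stokes_linear(rows[0], rows[1], rows[2])
    assert np.allclose(s.I, I, rtol=1e-12)
    assert np.allclose(s.Q, beam.Q, rtol=1e-12, atol=1e-12 * I)
    assert np.allclose(s.U, beam.U, rtol=1e-12, atol=1e-12 * I)


def test_fit_identity_when_measured_equals_reference():
    ref = StokesSweep.ideal_rotating_polarizer()
    cal = fit_calibration(ref, ref)
    assert np.abs(cal.A[0] - np.eye(3)).max() < 1e-12


def test_fit_recovers_known_linear_map():
    rng = np.random.default_rng(0)
    ref = StokesSweep.ideal_rotating_polarizer(1000.0)
    G = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
    cal = fit_calibration(StokesSweep(G @ ref.matrix), ref)
    assert np.abs(cal.A[0] - G).max() < 1e-10


def test_degenerate_sweep_rejected():
    col = np.array([1.0, 1.0, 0.0])
    degenerate = StokesSweep(np.tile(col[:, None], (1, 18)))
    ref = StokesSweep.ideal_rotating_polarizer()
    with pytest.raises(DegenerateSweepError):
        fit_calibration(ref, degenerate)


def test_apply_identity_calibration_is_identity():
    cal = CalibrationMatrix.identity()
    s = StokesLinear(I=2.0, Q=0.5, U=-0.3)
    out = apply_calibration(cal, s)
    assert (out.I, out.Q, out.U) == pytest.approx((2.0, 0.5, -0.3))


def test_ill_conditioned_calibration_rejected():
    A = np.diag([1.0, 1.0, 1e-15])[None]
    cal = CalibrationMatrix(A=A)
    with pytest.raises(IllConditionedError):
        apply_calibration(cal, StokesLinear(1.0, 0.0, 0.0))


def test_fit_then_apply_returns_reference_sweep():
    det = DetectorConfig.perturbed(seed=12)
    measured, ref = generate_calibration_sweep(det, add_noise=False)
    per_pixel = rows_to_stokes(measured).transpose(2, 1, 0)
    cal = fit_calibration(per_pixel, ref)
    # apply to every sweep column of one pixel
    pix = 500
    sub = CalibrationMatrix(A=cal.A[pix])
    for k in range(18):
        s_meas = StokesLinear(*per_pixel[pix, :, k])
        out = apply_calibration(sub, s_meas)
        assert np.allclose([out.I, out.Q, out.U], ref.matrix[:, k],
                           rtol=1e-10, atol=1e-10 * ref.matrix[0, k])


@pytest.mark.parametrize("beam,expected_dolp,expected_aop", [
    (StokesLinear.linear_beam(1.0, 10.0), 1.0, 10.0),
    (StokesLinear(1.0, 0.0, 1.0), 1.0, 45.0),
])
def test_dolp_aop_known_beams(beam, expected_dolp, expected_aop):
    assert dolp(beam) == pytest.approx(expected_dolp, abs=1e-12)
    assert aop(beam) == pytest.approx(expected_aop, abs=1e-10)


def test_unpolarized_beam_has_zero_dolp_and_undefined_aop():
    beam = StokesLinear(1.0, 0.0, 0.0)
    assert dolp(beam) == 0.0
    with pytest.raises(UndefinedAngleError):
        aop(beam)


def test_aop_quadrant_handling():
    """½·atan2 resolves the Q<0 ambiguity of a naive arctan(U/Q)."""
    beam = StokesLinear.linear_beam(1.0, 80.0)
    assert aop(beam) == pytest.approx(80.0, abs=1e-10)
    beam = StokesLinear.linear_beam(1.0, -80.0)
    assert aop(beam) == pytest.approx(-80.0, abs=1e-10)
    # the 90° boundary maps to −90° (half-open interval)
    beam = StokesLinear(1.0, -1.0, 0.0)
    assert aop(beam) == pytest.approx(-90.0, abs=1e-10)


def _recover_10deg_beam(seed: int):
    det = DetectorConfig.perturbed(seed=seed)
    measured, ref = generate_calibration_sweep(det, seed=3 * seed + 1)
    cal = fit_calibration(rows_to_stokes(measured).transpose(2, 1, 0), ref)
    rng = np.random.default_rng(3 * seed + 2)
    rows = measure_beam(StokesLinear.linear_beam(2000.0, 10.0), det, rng=rng)
    sm = rows_to_stokes(rows[None, :3, :])[0]
    s_meas = StokesLinear(I=sm[0], Q=sm[1], U=sm[2])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s_cor = apply_calibration(cal, s_meas)
    return s_meas, s_cor


@pytest.mark.parametrize("seed", range(5))
def test_calibration_recovers_10deg_beam(seed):
    """Perturbed detectors (gain ±10%, angle ±3°, extinction 200:1):
    calibration pulls ≥99% of pixels to |DoLP−1|<0.02 and |AoP−10°|<0.5°,
    and always narrows the pixel-to-pixel DoLP spread."""
    s_meas, s_cor = _recover_10deg_beam(seed)
    D, A = dolp(s_cor), aop(s_cor)
    assert np.mean(np.abs(D - 1.0) < 0.02) >= 0.99
    assert np.mean(np.abs(A - 10.0) < 0.5) >= 0.99
    assert dolp(s_cor).std() < dolp(s_meas).std()
    rms = lambda v: float(np.sqrt(np.mean(np.square(v))))
    assert rms(D - 1.0) < rms(dolp(s_meas) - 1.0)
    assert rms(A - 10.0) < rms(aop(s_meas) - 10.0)


def test_calibration_file_round_trip(tmp_path):
    det = DetectorConfig.perturbed(seed=2)
    measured, ref = generate_calibration_sweep(det, add_noise=False)
    cal = fit_calibration(rows_to_stokes(measured).transpose(2, 1, 0), ref)
    path = tmp_path / "cal.csv"
    write_calibration(cal, path)
    back = read_calibration(path)
    assert np.array_equal(back.A, cal.A)
    assert np.allclose(back.condition, cal.condition)
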