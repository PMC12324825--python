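"""Surface-redox CV simulation: closed forms, symmetry, interactions, I/O."""

import numpy as np
import pytest

from quinox import (
    SurfaceRedoxParams,
    Voltammogram,
    coverage_isotherm,
    detect_peaks,
    read_voltammogram,
    simulate_cv,
    to_she,
    write_voltammogram,
)
from quinox.constants import FARADAY as F
from quinox.constants import GAS_CONSTANT as R


def test_she_conversion_exact():
    assert to_she(0.0) == pytest.approx(0.199, abs=1e-12)
    assert to_she(-0.199) == pytest.approx(0.0, abs=1e-12)
    assert to_she(-0.142) == pytest.approx(0.057, abs=1e-12)


class TestCoverageIsotherm:
    def test_half_coverage_at_formal_potential(self):
        for G in (0.0, 1.0, -1.0, 3.0):
            p = SurfaceRedoxParams(e0=-0.1, a_ox=G / 2, a_red=G / 2)
            assert coverage_isotherm(-0.1, p).x == pytest.approx(0.5, abs=1e-9)

    def test_nernst_sigmoid_at_zero_interaction(self):
        p = SurfaceRedoxParams(e0=-0.1, n_e=2, temperature=298.0)
        res = coverage_isotherm(-0.1 - 0.0295, p)
        assert res.x == pytest.approx(0.909, abs=2e-3)
        assert not res.bistable

    def test_bistability_flagged_for_strong_attraction(self):
        p = SurfaceRedoxParams(e0=-0.1, a_ox=1.5, a_red=1.5)  # G = 3 > 2
        res = coverage_isotherm(-0.1 - 0.002, p)
        assert res.bistable
        assert 0.0 < res.x < 1.0


class TestLangmuirReversibleLimit:
    """Laviron closed forms at a_O = a_R = 0 and fast kinetics."""

    def test_peak_potentials_at_formal_potential(self, reversible_params, reversible_peaks):
        for pk in (reversible_peaks.cathodic, reversible_peaks.anodic):
            assert pk is not None
            assert abs(pk.potential - reversible_params.e0) < 1e-3

    def test_fwhm_closed_form(self, reversible_params, reversible_peaks):
        p = reversible_params
        fwhm_theory = 3.53 * R * p.temperature / (p.n_e * F)  # 45.3 mV at n=2
        assert reversible_peaks.cathodic.fwhm == pytest.approx(fwhm_theory, rel=0.02)
        assert reversible_peaks.anodic.fwhm == pytest.approx(fwhm_theory, rel=0.02)

    def test_peak_current_closed_form(self, reversible_params, reversible_peaks):
        p = reversible_params
        ip = p.n_e**2 * F**2 * 0.02 * p.area_cm2 * p.gamma_T / (4 * R * p.temperature)
        assert ip == pytest.approx(9.5e-7, rel=0.01)  # hand evaluation
        assert abs(reversible_peaks.cathodic.current) == pytest.approx(ip, rel=0.02)
        assert abs(reversible_peaks.anodic.current) == pytest.approx(ip, rel=0.02)

    def test_peak_charge_is_total_adsorbate_charge(self, reversible_params, reversible_peaks):
        p = reversible_params
        q = p.n_e * F * p.area_cm2 * p.gamma_T
        assert q == pytest.approx(2.43e-6, rel=0.01)  # hand evaluation
        assert reversible_peaks.cathodic.charge == pytest.approx(q, rel=0.01)
        assert reversible_peaks.anodic.charge == pytest.approx(q, rel=0.01)


def test_charge_conservation_across_kinetic_regimes():
    """Cathodic charge = anodic charge = n F A Gamma_T for full conversion."""
    for k_s, a_ox, a_red in [(100.0, 0.0, 0.0), (5.0, 0.9, 0.0), (2.0, -0.5, 0.8)]:
        p = SurfaceRedoxParams(e0=-0.142, k_s=k_s, a_ox=a_ox, a_red=a_red)
        v = simulate_cv(p, 0.12, -0.45)
        pk = detect_peaks(v)
        q = p.n_e * F * p.area_cm2 * p.gamma_T
        assert pk.cathodic.charge == pytest.approx(q, rel=0.01)
        assert pk.anodic.charge == pytest.approx(q, rel=0.01)


def test_attractive_interactions_narrow_repulsive_broaden():
    widths = []
    for G in (-1.0, -0.5, 0.0, 0.5, 1.0):
        p = SurfaceRedoxParams(
            e0=-0.142, k_s=500.0, a_ox=G / 2, a_red=G / 2, temperature=298.0
        )
        v = simulate_cv(p, 0.1, -0.45, points_per_segment=1101)
        widths.append(detect_peaks(v).cathodic.fwhm)
    assert all(w1 > w2 for w1, w2 in zip(widths, widths[1:])), widths


def test_one_sided_attraction_gives_sharp_cathodic_broad_anodic():
    """Attractive interactions on the oxidised form only, finite kinetics."""
    p = SurfaceRedoxParams(e0=-0.142, k_s=5.0, a_ox=0.9, a_red=0.0)
    pk = detect_peaks(simulate_cv(p, 0.1, -0.45))
    assert pk.cathodic.fwhm < pk.anodic.fwhm


def test_reversible_symmetric_branches_mirror():
    """Symmetric parameters: anodic branch mirrors cathodic about (E0', 0)."""
    p = SurfaceRedoxParams(
        e0=-0.142, k_s=500.0, a_ox=0.5, a_red=0.5, temperature=298.0
    )
    v = simulate_cv(p, 0.1, -0.45, points_per_segment=2751)
    (s0, e_c, i_c), (s1, e_a, i_a) = list(v.segments())
    mirrored = np.interp(2 * p.e0 - e_c, e_a, i_a)
    err = np.max(np.abs(i_c + mirrored)) / np.max(np.abs(i_c))
    assert err < 1e-3


def test_fast_integrator_agrees_with_lsoda():
    """The compiled integrator reproduces scipy's LSODA on the same ODE."""
    for p in (
        SurfaceRedoxParams(e0=-0.142, k_s=500.0, temperature=298.0),
        SurfaceRedoxParams(e0=-0.142, k_s=5.0, a_ox=0.9, a_red=0.0),
        SurfaceRedoxParams(e0=-0.1, n_e=1, k_s=0.5, a_ox=-0.8, a_red=0.4),
    ):
        fast = simulate_cv(p, 0.15, -0.45)
        ref = simulate_cv(p, 0.15, -0.45, backend="scipy")
        scale = np.max(np.abs(ref.current))
        assert np.max(np.abs(fast.current - ref.current)) / scale < 1e-4


def test_current_sign_convention():
    """Cathodic (reduction) current negative, anodic positive."""
    p = SurfaceRedoxParams(e0=-0.142)
    v = simulate_cv(p, 0.1, -0.45)
    segs = list(v.segments())
    assert segs[0][2].min() < 0  # negative-going sweep: reduction
    assert segs[1][2].max() > 0


def test_non_bracketing_window_rejected():
    p = SurfaceRedoxParams(e0=-0.142)
    with pytest.raises(ValueError, match="bracket"):
        simulate_cv(p, -0.05, -0.45)


def test_simulation_starts_from_equilibrium():
    p = SurfaceRedoxParams(e0=-0.142)
    v = simulate_cv(p, 0.1, -0.45)
    assert abs(v.current[0]) < 1e-3 * np.max(np.abs(v.current))


class TestVoltammogramContainer:
    def test_requires_monotonic_segments(self):
        e = np.array([0.0, 0.1, 0.05, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        with pytest.raises(ValueError, match="monotonic"):
            Voltammogram(e, np.zeros(10), np.zeros(10, int), scan_rate=0.02)

    def test_io_roundtrip_and_units(self, tmp_path):
        p = SurfaceRedoxParams(e0=-0.142)
        v = simulate_cv(p, 0.1, -0.45, points_per_segment=150)
        path = tmp_path / "cv.tsv"
        write_voltammogram(v, path)
        back = read_voltammogram(path, scan_rate=0.02)
        assert np.allclose(back.potential, v.potential)
        assert np.allclose(back.current, v.current)
        # mV / uA declaration reproduces the same physical curve
        import pandas as pd

        df = pd.DataFrame({
            "potential": v.potential * 1000, "current": v.current * 1e6
        })
        path2 = tmp_path / "cv_mv_ua.csv"
        df.to_csv(path2, index=False)
        back2 = read_voltammogram(
            path2, scan_rate=0.02, potential_unit="mV", current_unit="uA"
        )
        assert np.allclose(back2.potential, v.potential)
        assert np.allclose(back2.current, v.current, atol=1e-15)

    def test_segment_autosplit_at_reversal(self, tmp_path):
        p = SurfaceRedoxParams(e0=-0.142)
        v = simulate_cv(p, 0.1, -0.45, points_per_segment=120)
        import pandas as pd

        path = tmp_path / "noseg.csv"
        pd.DataFrame(
            {"potential": v.potential, "current": v.current}
        ).to_csv(path, index=False)
        back = read_voltammogram(path, scan_rate=0.02)
        assert len(np.unique(back.segment)) == 2
        assert back.segment_direction(0) == -1
        assert back.segment_direction(1) == 1
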