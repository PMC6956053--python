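"""Circuit models, complex least-squares fitting, and EIS variance series."""

import cmath

import numpy as np
import pytest

from microcolony.changestats import sample_variance
from microcolony.eisfit import (CircuitParams, EISSession, FullCircuitParams,
                                ImpedanceSample, cpe_impedance,
                                eis_variance_series, fit_circuit,
                                full_circuit_impedance, max_change_frequency,
                                parameter_trajectory, scale_impedance,
                                simplified_circuit_impedance)
from microcolony.synthdata import (AFTER_COLONIZATION, BEFORE_COLONIZATION, EISScenario,
                                   default_frequencies, generate_eis_session)

FREQS = default_frequencies()
OMEGA = 2 * np.pi * FREQS


def polar_cpe(Q, n, w):
    """Independent polar-form evaluation of 1/(Q (jw)^n)."""
    mag = 1.0 / (Q * w ** n)
    phase = -n * cmath.pi / 2
    return mag * cmath.exp(1j * phase)


def test_cpe_reduces_to_ideal_capacitor():
    assert cpe_impedance(1.0, 1.0, 1.0) == pytest.approx(-1j)
    w = np.logspace(1, 5, 7)
    assert np.allclose(cpe_impedance(2e-6, 1.0, w), 1.0 / (1j * w * 2e-6))


def test_cpe_matches_polar_oracle():
    Q, n = 31.37848e-9, 0.77428
    for w in (2 * np.pi * 200.0, 2 * np.pi * 50e3):
        got = complex(cpe_impedance(Q, n, w))
        want = polar_cpe(Q, n, w)
        assert got == pytest.approx(want, rel=1e-10)


def test_cpe_rejects_nonpositive_frequency():
    with pytest.raises(ValueError):
        cpe_impedance(1e-9, 0.8, 0.0)


def test_simplified_high_frequency_limit_is_series_resistance():
    z = simplified_circuit_impedance(BEFORE_COLONIZATION, 1e12)
    assert abs(z - BEFORE_COLONIZATION.R_elec) / BEFORE_COLONIZATION.R_elec < 1e-3


def test_simplified_low_frequency_dominates_high():
    for p in (BEFORE_COLONIZATION, AFTER_COLONIZATION):
        z = simplified_circuit_impedance(p, 2 * np.pi * np.array([200.0, 50e3]))
        assert abs(z[0]) > abs(z[1])


def test_simplified_reduces_to_series_rc():
    # huge R_b with negligible CPE admittance removes the faradaic branch
    p = CircuitParams(R_elec=1e4, C_belec=1e-9, R_b=1e18, Q_i=1e-30, n_i=0.9)
    z = simplified_circuit_impedance(p, OMEGA)
    rc = p.R_elec + 1.0 / (1j * OMEGA * p.C_belec)
    assert np.allclose(z, rc, rtol=1e-6)


def test_simplified_real_part_monotone_and_bounded():
    w = np.logspace(1, 7, 200)
    for p in (BEFORE_COLONIZATION, AFTER_COLONIZATION):
        re = simplified_circuit_impedance(p, w).real
        assert np.all(np.diff(re) <= 1e-9)
        assert np.all(re >= p.R_elec - 1e-9)


def test_full_circuit_reduces_to_simplified():
    full = FullCircuitParams(
        R_ELEC_a=8e3, R_ELEC_c=7.96e3, R_act=1e-9, R_cct=1e-9,
        C_adl=0.0, C_cdl=0.0, C_elec=0.5e-9, C_b=0.419e-9,
        R_b=BEFORE_COLONIZATION.R_b, Q_i=BEFORE_COLONIZATION.Q_i, n_i=BEFORE_COLONIZATION.n_i)
    simplified = CircuitParams(
        R_elec=full.R_ELEC_a + full.R_ELEC_c,
        C_belec=full.C_elec + full.C_b,
        R_b=full.R_b, Q_i=full.Q_i, n_i=full.n_i)
    za = full_circuit_impedance(full, OMEGA)
    zb = simplified_circuit_impedance(simplified, OMEGA)
    assert np.allclose(za, zb, rtol=1e-6)


def test_full_circuit_high_frequency_limit():
    full = FullCircuitParams(
        R_ELEC_a=8e3, R_ELEC_c=8e3, R_act=2e3, R_cct=2e3,
        C_adl=1e-11, C_cdl=1e-11, C_elec=0.5e-9, C_b=0.5e-9,
        R_b=5e6, Q_i=3e-8, n_i=0.8)
    z = complex(full_circuit_impedance(full, 1e14))
    assert z.real == pytest.approx(16e3, rel=1e-3)
    z_hi = full_circuit_impedance(full, np.logspace(5, 7, 20))
    assert np.all(z_hi.imag < 0)


def test_scale_impedance_scales_spectrum_linearly():
    scaled = scale_impedance(BEFORE_COLONIZATION, 2.5)
    assert np.allclose(simplified_circuit_impedance(scaled, OMEGA),
                       2.5 * simplified_circuit_impedance(BEFORE_COLONIZATION, OMEGA))


@pytest.mark.parametrize("params", [BEFORE_COLONIZATION, AFTER_COLONIZATION])
def test_noiseless_fit_recovers_printed_regimes(params):
    z = simplified_circuit_impedance(params, OMEGA)
    res = fit_circuit(ImpedanceSample(FREQS, z, 0.0))
    assert res.converged
    for name in ("R_elec", "C_belec", "R_b", "Q_i", "n_i"):
        assert getattr(res.params, name) == pytest.approx(
            getattr(params, name), rel=1e-3)


def test_noiseless_round_trip_across_parameter_draws():
    """Simulate-and-fit recovers every parameter within 0.1% over random
    draws spanning the magnitudes of both circuit regimes."""
    rng = np.random.default_rng(42)
    failures = 0
    for _ in range(20):
        p = CircuitParams(
            R_elec=10 ** rng.uniform(3.5, 4.3),
            C_belec=10 ** rng.uniform(-9.1, -8.1),
            R_b=10 ** rng.uniform(5.0, 6.8),
            Q_i=10 ** rng.uniform(-8.5, -7.0),
            n_i=rng.uniform(0.7, 0.95))
        z = simplified_circuit_impedance(p, OMEGA)
        res = fit_circuit(ImpedanceSample(FREQS, z, 0.0))
        ok = res.converged and all(
            abs(getattr(res.params, k) - getattr(p, k)) / getattr(p, k) < 1e-3
            for k in ("R_elec", "C_belec", "R_b", "Q_i", "n_i"))
        failures += not ok
    assert failures == 0


def test_fit_residual_not_worse_than_truth(colonized_eis):
    session, truth = colonized_eis
    spec = session.spectra[0]
    res = fit_circuit(spec)
    omega = 2 * np.pi * spec.frequencies
    z_true = simplified_circuit_impedance(truth["params_before"], omega)
    d = (z_true - spec.impedance) / np.abs(spec.impedance)
    resid_truth = np.linalg.norm(np.concatenate([d.real, d.imag]))
    assert res.residual_norm <= resid_truth + 1e-8


def test_variance_series_matches_oracle(colonized_eis):
    session, _ = colonized_eis
    (z_vs, _), (ph_vs, _) = eis_variance_series(session)
    for i, spec in enumerate(session.spectra[:10]):
        assert z_vs.sigma2[i] == pytest.approx(
            sample_variance(np.abs(spec.impedance)), rel=1e-12)
        assert ph_vs.sigma2[i] == pytest.approx(
            sample_variance(np.degrees(np.angle(spec.impedance))), rel=1e-12)


def test_variance_series_identical_spectra_degenerate():
    z = simplified_circuit_impedance(BEFORE_COLONIZATION, OMEGA)
    spectra = [ImpedanceSample(FREQS, z, 1800.0 * i) for i in range(6)]
    (z_vs, z_cp), _ = eis_variance_series(EISSession(spectra))
    assert z_vs.degenerate and z_cp.degenerate


def test_impedance_variance_drops_at_colonization(colonized_eis):
    session, truth = colonized_eis
    (z_vs, z_cp), _ = eis_variance_series(session)
    assert abs(z_cp.time_s - truth["event_time_s"]) <= 1800.0
    assert z_cp.change_ratio < 0.5


def test_trajectory_control_is_flat():
    scenario = EISScenario(rel_noise_sd=0.002, seed=5)
    session, _ = generate_eis_session(scenario, 6 * 3600.0)
    traj = parameter_trajectory(session)
    r = [f.params.R_elec for f in traj["fits"] if f.converged]
    assert np.std(r) / np.mean(r) < 0.05


def test_trajectory_epoch_summary_sees_rb_drop(colonized_eis):
    session, truth = colonized_eis
    traj = parameter_trajectory(session, truth["event_time_s"])
    drop = traj["before"]["R_b"] / traj["after"]["R_b"]
    injected = truth["params_before"].R_b / truth["params_after"].R_b
    assert drop > injected / 4


def test_trajectory_cpe_magnitude_rises_when_injected_so():
    """With an unscaled colonized-regime transition the CPE magnitude
    increases across the event and the fits track that."""
    scenario = EISScenario(params_after=AFTER_COLONIZATION,
                           colonization_time_s=4 * 3600.0, seed=9)
    session, _ = generate_eis_session(scenario, 12 * 3600.0)
    traj = parameter_trajectory(session, 4 * 3600.0)
    assert traj["after"]["Q_i"] > BEFORE_COLONIZATION.Q_i


def test_max_change_frequency_grid_recovery():
    z_b = simplified_circuit_impedance(BEFORE_COLONIZATION, OMEGA)
    z_a = simplified_circuit_impedance(AFTER_COLONIZATION, OMEGA)
    spectra = [ImpedanceSample(FREQS, z_b, 0.0),
               ImpedanceSample(FREQS, z_b, 1800.0),
               ImpedanceSample(FREQS, z_a, 3600.0),
               ImpedanceSample(FREQS, z_a, 5400.0)]
    out = max_change_frequency(EISSession(spectra), 3600.0)
    expected = FREQS[int(np.argmax(np.abs(np.abs(z_a) - np.abs(z_b))))]
    assert out["impedance_hz"] == pytest.approx(expected)
    assert not out["degenerate"]


def test_max_change_frequency_identical_epochs_degenerate():
    z = simplified_circuit_impedance(BEFORE_COLONIZATION, OMEGA)
    spectra = [ImpedanceSample(FREQS, z, 1800.0 * i) for i in range(4)]
    out = max_change_frequency(EISSession(spectra), 3600.0)
    assert out["degenerate"]


def test_max_change_frequency_needs_both_epochs():
    z = simplified_circuit_impedance(BEFORE_COLONIZATION, OMEGA)
    spectra = [ImpedanceSample(FREQS, z, 1800.0 * i) for i in range(4)]
    with pytest.raises(ValueError):
        max_change_frequency(EISSession(spectra), 1e9)
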