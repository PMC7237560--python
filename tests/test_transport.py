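"""CSDA transport: stopping power, ranges, kernel, overlap scoring, tracks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import microdosim as md
from microdosim.transport import (
    TransportConfig,
    expected_deposit,
    mean_track_nucleus_deposit,
    water_collision_stopping_power,
)

# reference collision stopping powers (MeV cm^2/g) and CSDA ranges (um)
# for liquid water from the standard tabulation
REFERENCE_S = {10.0: 22.56, 100.0: 4.115, 1000.0: 1.849}
REFERENCE_RANGE = {10.0: 2.52, 30.0: 17.6, 100.0: 143.0, 500.0: 1766.0}


def test_stopping_power_matches_reference_values(water_table):
    for e, ref in REFERENCE_S.items():
        assert float(water_table(e)) * 10 == pytest.approx(ref, rel=0.015)


def test_stopping_power_positive_and_decreasing(water_table):
    e = np.geomspace(0.3, 1000.0, 200)
    s = water_table(e)
    assert np.all(s > 0)
    assert np.all(np.diff(s) < 0)


def test_table_consistent_with_formula(water_table):
    np.testing.assert_allclose(
        water_table.s_kev_per_um,
        water_collision_stopping_power(water_table.energy_kev),
        rtol=1e-4,
    )


def test_table_rejects_out_of_range(water_table):
    with pytest.raises(ValueError):
        water_table(0.01)
    with pytest.raises(ValueError):
        md.csda_range(1e5, water_table)


def test_bad_tables_rejected():
    with pytest.raises(ValueError):
        md.StoppingPowerTable(np.array([1.0, 2, 2, 3]), np.ones(4))
    with pytest.raises(ValueError):
        md.StoppingPowerTable(np.array([1.0, 2, 3, 4]), np.array([1, -1, 1, 1.0]))


def test_csda_range_reference_and_monotone(water_table):
    for e, ref in REFERENCE_RANGE.items():
        assert float(md.csda_range(e, water_table)) == pytest.approx(ref, rel=0.03)
    e = water_table.energy_kev
    r = md.csda_range(e, water_table)
    assert np.all(np.diff(r) > 0)
    assert np.all(md.csda_range(2 * e[e < 1000], water_table) > r[e < 1000])
    # E -> 0 limit
    assert float(md.csda_range(water_table.e_min, water_table)) < 0.02


def test_csda_range_quadrature_self_consistency(water_table):
    """Halving the quadrature grid changes ranges by < 0.5%."""
    e = np.array([1.0, 10.0, 100.0, 500.0])
    full = md.csda_range(e, water_table, n_points=4000)
    half = md.csda_range(e, water_table, n_points=2000)
    np.testing.assert_allclose(half, full, rtol=5e-3)


def test_kernel_cumulative_profile_invariants(kernel, water_table):
    for e in (1.0, 10.0, 100.0, 500.0):
        r_full = float(md.csda_range(e, water_table))
        assert float(kernel.F(0.0, e)) == 0.0
        assert float(kernel.F(r_full, e)) == pytest.approx(1.0, abs=1e-6)
        assert float(kernel.F(2 * r_full, e)) == 1.0
        r = np.linspace(0, 1.1 * r_full, 300)
        f = kernel.F(r, e)
        assert np.all(np.diff(f) >= -1e-12)
        assert np.all((0 <= f) & (f <= 1))


def test_deposition_is_back_loaded(kernel, water_table):
    """S(E) rises as the electron slows, so less than half the energy is
    deposited over the first half of the path.  Cross-checked against a
    direct stepwise integration of dE/ds = -S(E)."""
    e0 = 100.0
    r_half = float(md.csda_range(e0, water_table)) / 2
    f_kernel = float(kernel.F(r_half, e0))
    assert f_kernel < 0.5
    # independent fine Euler integration of the slowing-down equation
    e, ds = e0, r_half / 20000
    for _ in range(20000):
        e -= float(water_table(e)) * ds
    f_direct = (e0 - e) / e0
    assert f_kernel == pytest.approx(f_direct, abs=0.01)


def test_kernel_radial_refinement_converges(water_table):
    coarse = md.build_kernel(water_table, n_radial=64)
    fine = md.build_kernel(water_table, n_radial=256)
    for rho, e in ((4.0, 30.0), (7.0, 100.0), (2.0, 10.0)):
        a = expected_deposit(rho, e, 5.0, coarse)
        b = expected_deposit(rho, e, 5.0, fine)
        assert float(a) == pytest.approx(float(b), rel=0.01)


def test_shell_overlap_closed_form_cases():
    assert md.shell_overlap_fraction(0.0, 3.0, 5.0) == 1.0
    assert md.shell_overlap_fraction(10.0, 20.0, 5.0) == 0.0
    assert md.shell_overlap_fraction(5.0, 5.0, 5.0) == pytest.approx(0.25)


def test_shell_overlap_against_isotropic_monte_carlo(rng):
    """MC oracle: fraction of isotropic directions from a source at rho
    whose endpoint at distance r lands inside the target ball."""
    rho, r, r_target = 5.0, 5.0, 5.0
    u = rng.normal(size=(1_000_000, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = np.array([0.0, 0.0, rho]) + r * u
    frac = (np.linalg.norm(pts, axis=1) < r_target).mean()
    assert md.shell_overlap_fraction(rho, r, r_target) == pytest.approx(
        frac, abs=2e-3
    )


@given(
    rho=st.floats(0.0, 30.0),
    r=st.floats(1e-3, 50.0),
    r_target=st.floats(0.5, 20.0),
)
def test_shell_overlap_bounded_and_monotone_in_target(rho, r, r_target):
    f = float(md.shell_overlap_fraction(rho, r, r_target))
    assert 0.0 <= f <= 1.0
    assert float(md.shell_overlap_fraction(rho, r, r_target + 1.0)) >= f - 1e-12


def test_energy_to_target_containment_and_reach(kernel, water_table):
    # whole range inside the target: everything is absorbed
    assert md.energy_to_target([0, 0, 0], 10.0, [0, 0, 0], 5.0, kernel) == (
        pytest.approx(10.0, rel=1e-9)
    )
    # out of reach: no deposit
    e = 30.0
    r_full = float(md.csda_range(e, water_table))
    far = r_full + 5.0 + 1.0
    assert md.energy_to_target([far, 0, 0], e, [0, 0, 0], 5.0, kernel) == 0.0
    # all-space target: energy conservation
    assert md.energy_to_target([3, 2, 1], 300.0, [0, 0, 0], 1e6, kernel) == (
        pytest.approx(300.0, rel=1e-9)
    )


def test_energy_below_table_floor_deposits_locally(kernel):
    assert float(expected_deposit(1.0, 0.05, 5.0, kernel)) == 0.05
    assert float(expected_deposit(6.0, 0.05, 5.0, kernel)) == 0.0


def test_shell_target_is_difference_of_balls(kernel):
    from microdosim.transport import energy_to_shell_target

    point, e = [6.0, 0, 0], 50.0
    d = energy_to_shell_target(point, e, [0, 0, 0], 5.0, 6.99, kernel)
    d_out = md.energy_to_target(point, e, [0, 0, 0], 6.99, kernel)
    d_in = md.energy_to_target(point, e, [0, 0, 0], 5.0, kernel)
    assert d == pytest.approx(d_out - d_in, rel=1e-12)
    assert d >= 0


def test_kernel_agrees_with_track_monte_carlo(kernel, rng):
    """Expected nucleus deposit: kernel vs 1e5 stepped straight tracks."""
    expected = md.energy_to_target([4.0, 0, 0], 30.0, [0, 0, 0], 5.0, kernel)
    mean, sem = mean_track_nucleus_deposit(
        [4.0, 0, 0], 30.0, [[0.0, 0, 0]], 5.0, 100_000, rng
    )
    assert expected == pytest.approx(float(mean[0]), rel=0.02)


def test_track_mode_conserves_energy_exactly():
    cells = [md.CellModel()]
    dep = md.track_mode_deposit([6.0, 0, 0], 80.0, [0.3, -0.5, 0.8], cells)
    assert sum(dep.values()) == pytest.approx(80.0, rel=1e-9)
    assert all(v >= 0 for v in dep.values())


def test_track_from_nucleus_centre_stays_in_nucleus():
    cells = [md.CellModel()]
    dep = md.track_mode_deposit([0.0, 0, 0], 20.0, [1, 0, 0], cells)
    # range(20 keV) ~ 8.6 um > 5 um: some energy must leave the nucleus;
    # a 10 keV electron (range ~2.5 um) deposits everything inside
    dep10 = md.track_mode_deposit([0.0, 0, 0], 10.0, [1, 0, 0], cells)
    assert set(dep10) == {(0, "nucleus")}
    assert dep[(0, "nucleus")] < 20.0


def test_transport_config_validation():
    with pytest.raises(ValueError):
        TransportConfig(mode="warp")
    with pytest.raises(ValueError):
        TransportConfig(cutoff_energy_ev=0.0)
    with pytest.raises(ValueError):
        TransportConfig(step_fraction=1.5)


def test_local_deposition_kernel_is_degenerate():
    k = md.local_deposition_kernel()
    assert float(expected_deposit(4.9, 500.0, 5.0, k)) == 500.0
    assert float(expected_deposit(5.1, 500.0, 5.0, k)) == 0.0
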