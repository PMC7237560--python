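"""Emission models: calibration to the summary decay data, spectral shape,
per-decay sampling, and the optional user-supplied table loaders."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import microdosim as md
from microdosim.emissions import branch_mean_energy, load_beta_branches, load_emission_lines

REFS = {
    "lu177": {"beta_mean": 133.3, "ce": 13.52, "ae": 1.13, "total": 147.9,
              "ce_range": (6.2, 206.3), "ae_range": (0.01, 61.7),
              "ce_avg": 87.0, "ae_avg": 1.0},
    "tb161": {"beta_mean": 154.3, "ce": 39.28, "ae": 8.94, "total": 202.5,
              "ce_range": (3.3, 98.3), "ae_range": (0.018, 50.9),
              "ce_avg": 28.0, "ae_avg": 0.8},
}


def test_build_radionuclide_reference_values(lu177, tb161):
    assert tb161.mean_beta_energy_ref == 154.3
    assert lu177.total_electron_energy_ref == 147.9
    assert lu177.half_life_days == pytest.approx(6.647)
    assert tb161.name == "tb161"


def test_build_radionuclide_rejects_unknown():
    with pytest.raises(md.UnsupportedRadionuclideError):
        md.build_radionuclide("xx99")


@pytest.mark.parametrize("name", ["lu177", "tb161"])
def test_model_energy_budget_matches_decay_characteristics(name):
    """Analytic model means reproduce the per-decay energy budget."""
    nuc = md.build_radionuclide(name)
    ref = REFS[name]
    assert nuc.mean_beta_energy() == pytest.approx(ref["beta_mean"], rel=0.02)
    assert nuc.line_energy_per_decay("CE") == pytest.approx(ref["ce"], rel=0.05)
    assert nuc.line_energy_per_decay("AE") == pytest.approx(ref["ae"], rel=0.05)
    assert nuc.mean_energy_per_decay() == pytest.approx(ref["total"], rel=0.05)
    assert md.weighted_average_energy(nuc.ce_lines) == pytest.approx(
        ref["ce_avg"], rel=0.01
    )
    assert md.weighted_average_energy(nuc.ae_lines) == pytest.approx(
        ref["ae_avg"], rel=0.01
    )
    lo, hi = ref["ce_range"]
    assert all(lo <= l.energy_kev <= hi for l in nuc.ce_lines)
    lo, hi = ref["ae_range"]
    assert all(lo <= l.energy_kev <= hi for l in nuc.ae_lines)


def test_weighted_average_energy_examples():
    mk = lambda pairs: [md.EmissionLine("CE", e, w) for e, w in pairs]
    assert md.weighted_average_energy(mk([(10, 1), (20, 1)])) == pytest.approx(15)
    assert md.weighted_average_energy(mk([(10, 3), (30, 1)])) == pytest.approx(15)
    assert md.weighted_average_energy(mk([(5, 0.2)])) == pytest.approx(5)
    with pytest.raises(ValueError):
        md.weighted_average_energy([])


@given(
    st.lists(
        st.tuples(
            st.floats(1.0, 500.0), st.floats(0.01, 5.0)
        ),
        min_size=1,
        max_size=8,
    )
)
def test_weighted_average_bounded_by_line_energies(pairs):
    lines = [md.EmissionLine("AE", e, w) for e, w in pairs]
    avg = md.weighted_average_energy(lines)
    energies = [e for e, _ in pairs]
    assert min(energies) - 1e-9 <= avg <= max(energies) + 1e-9


def test_beta_spectrum_pdf_shape(tb161):
    branch = max(tb161.beta_branches, key=lambda b: b.fraction)
    q = branch.endpoint_kev
    assert md.beta_spectrum_pdf(branch, q) == 0.0
    assert md.beta_spectrum_pdf(branch, -1.0) == 0.0
    assert md.beta_spectrum_pdf(branch, q + 10) == 0.0
    e = np.linspace(0.0, q, 4096)
    assert np.trapezoid(md.beta_spectrum_pdf(branch, e), e) == pytest.approx(
        1.0, abs=1e-6
    )
    assert np.all(md.beta_spectrum_pdf(branch, e) >= 0)


@pytest.mark.parametrize("name", ["lu177", "tb161"])
def test_calibrated_beta_mean_matches_reference(name):
    nuc = md.build_radionuclide(name)
    mean = sum(b.fraction * branch_mean_energy(b) for b in nuc.beta_branches)
    assert mean == pytest.approx(REFS[name]["beta_mean"], rel=0.02)


def test_single_effective_branch_option():
    nuc = md.build_radionuclide("tb161", single_effective_beta=True)
    assert len(nuc.beta_branches) == 1
    assert nuc.beta_branches[0].shape == "effective_single"
    assert nuc.mean_beta_energy() == pytest.approx(154.3, rel=0.02)


@pytest.mark.parametrize("name", ["lu177", "tb161"])
def test_sampled_energies_match_budget_and_ranges(name):
    nuc = md.build_radionuclide(name)
    sample = md.sample_emissions(nuc, 200_000, rng_seed=11)
    ref = REFS[name]
    assert sample.total_energies().mean() == pytest.approx(ref["total"], rel=0.01)
    assert sample.beta_energies.mean() == pytest.approx(ref["beta_mean"], rel=0.02)
    assert sample.beta_energies.min() > 0
    assert sample.beta_energies.max() < max(b.endpoint_kev for b in nuc.beta_branches)
    # integer line counts with the right expectation
    yields = np.array([l.yield_per_decay for l in nuc.lines])
    np.testing.assert_allclose(
        sample.line_counts.mean(axis=0), yields, rtol=0.05, atol=0.005
    )
    assert sample.line_counts.dtype.kind == "i"


def test_sampling_deterministic_and_seed_sensitive(lu177):
    a = md.sample_emissions(lu177, 5000, rng_seed=3)
    b = md.sample_emissions(lu177, 5000, rng_seed=3)
    c = md.sample_emissions(lu177, 5000, rng_seed=4)
    np.testing.assert_array_equal(a.beta_energies, b.beta_energies)
    np.testing.assert_array_equal(a.line_counts, b.line_counts)
    assert not np.array_equal(a.beta_energies, c.beta_energies)


def test_sample_emissions_validates_n(lu177):
    with pytest.raises(ValueError):
        md.sample_emissions(lu177, 0, rng_seed=1)


def test_event_iteration_consistent_with_arrays(tb161):
    sample = md.sample_emissions(tb161, 50, rng_seed=5)
    events = list(sample)
    assert len(events) == 50
    totals = np.array([sum(e) for e in events])
    np.testing.assert_allclose(totals, sample.total_energies(), rtol=1e-12)
    assert all(min(e) > 0 for e in events)


def test_line_table_loader_roundtrip(tmp_path, lu177):
    path = tmp_path / "lines.csv"
    rows = ["kind,energy_keV,yield_per_decay"]
    rows += [f"{l.kind},{l.energy_kev},{l.yield_per_decay}" for l in lu177.lines]
    path.write_text("\n".join(rows) + "\n")
    loaded = load_emission_lines(path)
    assert loaded == lu177.lines
    nuc = md.build_radionuclide("lu177", lines_table=path)
    assert nuc.lines == lu177.lines


def test_line_table_loader_rejects_headerless(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("CE,10,0.5\n")
    with pytest.raises(ValueError):
        load_emission_lines(path)


def test_beta_table_loader_checks_fraction_sum(tmp_path):
    path = tmp_path / "beta.csv"
    path.write_text("endpoint_keV,fraction\n500,0.6\n200,0.2\n")
    with pytest.raises(ValueError):
        load_beta_branches(path)
    path.write_text("endpoint_keV,fraction\n500,0.8\n200,0.2\n")
    assert load_beta_branches(path) == [(500.0, 0.8), (200.0, 0.2)]


def test_invalid_domain_objects_rejected():
    with pytest.raises(ValueError):
        md.EmissionLine("CE", -1.0, 0.5)
    with pytest.raises(ValueError):
        md.EmissionLine("XX", 10.0, 0.5)
    with pytest.raises(ValueError):
        md.BetaBranch(endpoint_kev=100.0, fraction=1.5, daughter_z=72)
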