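"""Kinetic-constant estimation: recovery, oracle equivalence, QC rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myripbk import (
    IncubationDataset,
    KineticConstants,
    MichaelisMentenModel,
    FirstOrderModel,
    fit_michaelis_menten,
    fit_first_order,
    catalytic_efficiency_invitro,
    check_conversion_fraction,
)
from myripbk.exceptions import DegenerateDataError

CONCS = np.array([25.0, 50.0, 100.0, 200.0, 300.0, 500.0, 750.0, 1000.0])


def mm_dataset(vmax, km, concs=CONCS, noise=None, replicates=1, seed=0):
    v = vmax * concs / (km + concs)
    rates = np.tile(v, (replicates, 1))
    if noise:
        rng = np.random.default_rng(seed)
        rates = np.clip(rates * (1 + rng.normal(0, noise, rates.shape)), 0, None)
    return IncubationDataset("HM", concs, rates)


def test_noiseless_mm_recovery_is_exact():
    """Noiseless saturable data return the generating (Vmax, Km) pair."""
    kc = fit_michaelis_menten(mm_dataset(0.86, 102.0))
    assert kc.vmax == pytest.approx(0.86, rel=1e-3)
    assert kc.km == pytest.approx(102.0, rel=1e-3)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    vmax=st.floats(0.01, 100.0),
    km=st.floats(1.0, 1e4),
)
def test_noiseless_recovery_property(vmax, km):
    """For any (Vmax, Km) in the physiological range, fitting noiseless
    data generated on the tested grid recovers the pair to 0.1%."""
    concs = np.geomspace(max(1.0, km / 20), max(50.0, km * 10), 8)
    kc = fit_michaelis_menten(mm_dataset(vmax, km, concs=concs))
    assert kc.vmax == pytest.approx(vmax, rel=1e-3)
    assert kc.km == pytest.approx(km, rel=1e-3)


def test_noisy_fit_beats_grid_search_oracle():
    """The optimiser's SSR is no worse than a dense grid search over
    (Vmax, Km) on the same pooled data."""
    data = mm_dataset(1.3, 33.0, noise=0.05, replicates=3, seed=42)
    res = MichaelisMentenModel(data).fit()
    s, v = data.pooled()
    vmax_grid = np.linspace(0.5 * 1.3, 2.0 * 1.3, 120)
    km_grid = np.linspace(0.2 * 33, 5.0 * 33, 150)
    ssr_grid = np.full((vmax_grid.size, km_grid.size), np.inf)
    for i, vm in enumerate(vmax_grid):
        pred = vm * s[None, :] / (km_grid[:, None] + s[None, :])
        ssr_grid[i] = np.sum((v[None, :] - pred) ** 2, axis=1)
    i, j = np.unravel_index(np.argmin(ssr_grid), ssr_grid.shape)
    assert res.ssr <= ssr_grid[i, j] + 1e-12
    assert res.params["vmax"] == pytest.approx(vmax_grid[i], rel=0.05)
    assert res.params["km"] == pytest.approx(km_grid[j], rel=0.10)


def test_saturation_limit_constant_rates():
    """Constant rates at all concentrations mean Km below the tested
    range and Vmax at the plateau value."""
    rates = np.full_like(CONCS, 0.7)
    kc = fit_michaelis_menten(IncubationDataset("HM", CONCS, rates))
    assert kc.km < CONCS.min()
    assert kc.vmax == pytest.approx(0.7, rel=1e-3)


def test_mm_all_zero_rates_is_degenerate():
    data = IncubationDataset("HM", CONCS, np.zeros_like(CONCS))
    with pytest.raises(DegenerateDataError):
        fit_michaelis_menten(data)


@pytest.mark.parametrize("scale", [0.1, 3.0, 250.0])
def test_km_invariant_under_rate_rescaling(scale):
    """Rescaling all rates leaves Km unchanged and scales Vmax."""
    base = MichaelisMentenModel(mm_dataset(0.86, 102.0, noise=0.08, replicates=3, seed=7)).fit()
    data = mm_dataset(0.86, 102.0, noise=0.08, replicates=3, seed=7)
    scaled = IncubationDataset("HM", data.substrate_concs, data.rates * scale)
    res = MichaelisMentenModel(scaled).fit()
    assert res.params["km"] == pytest.approx(base.params["km"], rel=1e-6)
    assert res.params["vmax"] == pytest.approx(base.params["vmax"] * scale, rel=1e-6)


# -- first-order ----------------------------------------------------------


def test_first_order_noiseless_recovery():
    concs = np.geomspace(10, 6000, 8)
    data = IncubationDataset("HMS", concs, 17.6e-6 * concs, protein_basis="s9")
    kc = fit_first_order(data)
    assert kc.k == pytest.approx(17.6e-6, rel=1e-12)


def test_first_order_slope_equals_closed_form():
    """The fitted slope equals sum(S*v)/sum(S^2) on noisy data."""
    rng = np.random.default_rng(3)
    concs = np.geomspace(10, 6000, 8)
    rates = np.clip(16.3e-6 * concs * (1 + rng.normal(0, 0.1, (3, concs.size))), 0, None)
    data = IncubationDataset("HMS", concs, rates, protein_basis="s9")
    res = FirstOrderModel(data).fit()
    s, v = data.pooled()
    assert res.params["k"] == pytest.approx(np.sum(s * v) / np.sum(s * s), rel=1e-12)


def test_first_order_zero_rates_degenerate():
    concs = np.array([10.0, 100.0, 1000.0])
    data = IncubationDataset("HMS", concs, np.zeros_like(concs), protein_basis="s9")
    with pytest.raises(DegenerateDataError):
        fit_first_order(data)


# -- catalytic efficiency and conversion QC -------------------------------


@pytest.mark.parametrize(
    "vmax,km,expected",
    [(0.86, 102.0, 8.431), (1.3, 33.0, 39.394)],
)
def test_invitro_catalytic_efficiency(vmax, km, expected):
    kc = KineticConstants("x", "michaelis_menten", vmax=vmax, km=km)
    assert catalytic_efficiency_invitro(kc) == pytest.approx(expected, abs=5e-4)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(c=st.floats(1e-3, 1e3), vmax=st.floats(1e-3, 1e2), km=st.floats(1.0, 1e4))
def test_efficiency_homogeneous_in_vmax(c, vmax, km):
    kc1 = KineticConstants("x", "michaelis_menten", vmax=vmax, km=km)
    kc2 = KineticConstants("x", "michaelis_menten", vmax=c * vmax, km=km)
    assert catalytic_efficiency_invitro(kc2) == pytest.approx(
        c * catalytic_efficiency_invitro(kc1), rel=1e-9
    )


def test_conversion_fraction_rule():
    """Conversion below 10% passes, at exactly 10% passes (inclusive
    boundary), well above fails."""
    # linear pathway: fraction = k * protein * t, independent of conc
    kc = KineticConstants("HMS", "first_order", k=1e-4, protein_basis="s9")
    assert check_conversion_fraction(kc, 100.0, 500.0, 1.0).fraction == pytest.approx(0.05)
    assert check_conversion_fraction(kc, 100.0, 500.0, 1.0).passed
    assert check_conversion_fraction(kc, 100.0, 1000.0, 1.0).passed  # exactly 0.10
    check = check_conversion_fraction(kc, 100.0, 5000.0, 1.0)
    assert check.fraction == pytest.approx(0.5)
    assert not check.passed


def test_dataset_table_roundtrip(tmp_path):
    data = mm_dataset(0.86, 102.0, noise=0.05, replicates=3, seed=1)
    path = tmp_path / "hm.tsv"
    data.to_table(path)
    back = IncubationDataset.from_table(path)
    np.testing.assert_allclose(back.substrate_concs, data.substrate_concs)
    np.testing.assert_allclose(back.rates, data.rates)
    assert back.pathway_id == data.pathway_id
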