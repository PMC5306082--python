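"""PBK model assembly, mass balance, linear limits and dose response."""

import numpy as np
import pytest
from scipy.linalg import expm

from myripbk import (
    PBKModel,
    PBKState,
    PartitionCoefficients,
    ScaledKineticConstants,
    SpeciesPhysiology,
    derivatives,
    dose_response,
)
from myripbk.exceptions import ConfigurationError
from myripbk.pbk import METABOLITES, PARENT_PATHWAYS, STATE_NAMES, _IDX


def test_rat_model_assembly(rat_model):
    """Rat liver mass and whole-liver Vmax follow from the volume
    fraction and the per-g scaled constant."""
    assert rat_model.physiology.liver_mass_g == pytest.approx(0.25 * 1000 * 0.034)
    vmax, km = rat_model.parent_pathways["HM"]
    assert vmax == pytest.approx(1.806 * 8.5, rel=1e-9)
    assert km == pytest.approx(102.0)


def test_human_model_assembly(human_model):
    assert human_model.physiology.liver_mass_g == pytest.approx(60 * 1000 * 0.026)
    # slowly perfused flow is the remainder of cardiac output
    assert human_model.physiology.flow_fractions["slowly_perfused"] == pytest.approx(0.248)


def test_missing_pathway_is_configuration_error(rat_config):
    scaled = rat_config.scaled_constants()
    del scaled["HMS"]
    with pytest.raises(ConfigurationError, match="HMS"):
        PBKModel.from_scaled(rat_config.physiology, rat_config.partition, scaled)


def test_zero_state_has_zero_derivative(rat_model):
    d = derivatives(PBKState(), rat_model)
    assert all(getattr(d, name) == 0.0 for name in STATE_NAMES)


def test_gi_only_state_feeds_liver_only(rat_model):
    """With the dose still in the GI tract, uptake goes directly to the
    liver and no other compartment moves."""
    d = derivatives(PBKState(AGI=10.0), rat_model)
    assert d.AGI == pytest.approx(-10.0 * rat_model.ka_per_h)
    assert d.AL == pytest.approx(10.0 * rat_model.ka_per_h)
    for name in ("AF", "AR", "AS", "AB", "AL_HM", "A_DHM", "A_3HM", "A_DHA"):
        assert getattr(d, name) == 0.0


def _linearized_matrix(model):
    """Exact dynamics matrix of the model when every pathway is in its
    linear regime (independent closed-form oracle via expm)."""
    phys, part = model.physiology, model.partition
    V = {t: phys.tissue_volume_L(t) for t in part.parent}
    VB = phys.tissue_volume_L("blood")
    Q = {t: phys.tissue_flow_L_h(t) for t in part.parent}
    n = len(STATE_NAMES)
    A = np.zeros((n, n))
    i = _IDX
    A[i["AGI"], i["AGI"]] = -model.ka_per_h
    A[i["AL"], i["AGI"]] = model.ka_per_h
    lu = 1.0 / (V["liver"] * part.parent["liver"])  # AL -> CL/PL
    for pid, (vmax, km) in model.parent_pathways.items():
        A[i["AL"], i["AL"]] -= (vmax / km) * lu
        if pid != "HM":  # the 1'-hydroxy flux feeds the liver metabolite pool
            A[i[f"A_{pid}"], i["AL"]] += (vmax / km) * lu
    A[i["AL"], i["AL"]] -= Q["liver"] * lu
    A[i["AL"], i["AB"]] += Q["liver"] / VB
    for tissue, state in (("fat", "AF"), ("rapidly_perfused", "AR"), ("slowly_perfused", "AS")):
        tu = 1.0 / (V[tissue] * part.parent[tissue])
        A[i[state], i[state]] = -Q[tissue] * tu
        A[i[state], i["AB"]] = Q[tissue] / VB
        A[i["AB"], i[state]] = Q[tissue] * tu
    A[i["AB"], i["AL"]] += Q["liver"] * lu
    A[i["AB"], i["AB"]] = -sum(Q.values()) / VB
    hmu = 1.0 / (V["liver"] * part.metabolite_liver)
    vmax_hm, km_hm = model.parent_pathways["HM"]
    A[i["AL_HM"], i["AL"]] = (vmax_hm / km_hm) * lu
    for pid in ("HMG", "HMO"):
        vmax, km = model.metabolite_pathways[pid]
        A[i["AL_HM"], i["AL_HM"]] -= (vmax / km) * hmu
        A[i[f"A_{pid}"], i["AL_HM"]] += (vmax / km) * hmu
    A[i["AL_HM"], i["AL_HM"]] -= model.k_hms_L_h * hmu
    A[i["A_HMS"], i["AL_HM"]] += model.k_hms_L_h * hmu
    # HM is not a cumulative state; remove the bookkeeping row added above
    return A


def test_linear_regime_matches_matrix_exponential(rat_config):
    """At trace doses every clearance term is first order and the model
    must match the closed-form solution of the linearized system."""
    model = rat_config.build_model()
    res = model.simulate(1e-6, duration_h=48.0)
    A = _linearized_matrix(model)
    y0 = np.zeros(len(STATE_NAMES))
    y0[_IDX["AGI"]] = res.dose_umol
    for t in (1.0, 6.0, 12.0, 24.0):
        exact = expm(A * t) @ y0
        sim = res.state_at(t)
        # atol masks residues at the integrator's absolute-tolerance floor
        np.testing.assert_allclose(sim, exact, rtol=5e-3, atol=res.dose_umol * 1e-6)


@pytest.mark.parametrize("dose", [0.05, 300.0])
def test_mass_conservation(sims, dose):
    """Parent pools plus cumulative metabolite pools equal the dose at
    every saved time, to well below 1e-6 relative."""
    for sp in ("rat", "human"):
        assert sims[(sp, dose)].mass_balance_error() < 1e-6


def test_zero_dose_gives_identically_zero_trajectories(rat_model):
    res = rat_model.simulate(0.0)
    assert np.all(res.states == 0.0)
    assert res.percent_of_dose("HMS") == 0.0
    assert res.amount_per_g_liver("HM") == 0.0


@pytest.mark.parametrize("dose", [0.05, 300.0])
def test_rat_complete_clearance_within_720h(sims, dose):
    """In rat the parent compound in GI tract and liver is gone
    (<1e-6 % of dose) by 720 h at any dose in the studied range."""
    res = sims[("rat", dose)]
    y = res.state_at(720.0)
    assert y[_IDX["AGI"]] < 1e-8 * res.dose_umol
    assert y[_IDX["AL"]] < 1e-8 * res.dose_umol


def test_metabolite_percentages_sum_to_100(sims):
    """Metabolite shares account for the whole dose at 720 h: exactly in
    rat, and to within the small parent residue still partitioned into
    fat in human (the human terminal phase is fat-limited)."""
    for (sp, _dose), res in sims.items():
        total = sum(res.percent_of_dose(m) for m in ("DHM", "3HM", "DHA", "HM"))
        assert total == pytest.approx(100.0, abs=1e-4 if sp == "rat" else 0.6)
        # conservation proper: metabolites plus remaining parent is exact
        remaining = sum(
            res.state_at(720.0)[_IDX[name]] for name in ("AGI", "AL", "AF", "AR", "AS", "AB")
        )
        assert total + remaining / res.dose_umol * 100 == pytest.approx(100.0, abs=1e-6)


def test_low_dose_linearity(rat_model):
    """Doubling a trace dose doubles every cumulative amount within 0.1%."""
    res1 = rat_model.simulate(1e-3)
    res2 = rat_model.simulate(2e-3)
    for m in METABOLITES:
        a1 = res1.metabolite_amount_umol(m)
        a2 = res2.metabolite_amount_umol(m)
        assert a2 / a1 == pytest.approx(2.0, rel=1e-3)


def test_low_dose_shares_equal_efficiency_ratios(rat_config, human_config, sims):
    """At the low-dose limit, parent metabolite shares equal the ratios
    of whole-liver catalytic efficiencies (analytic limit)."""
    for config, sp in ((rat_config, "rat"), (human_config, "human")):
        scaled = config.scaled_constants()
        eff = {p: scaled[p].efficiency_invivo for p in PARENT_PATHWAYS}
        total = sum(eff.values())
        res = sims[(sp, 0.05)]
        for pid in PARENT_PATHWAYS:
            share_pct = 100.0 * eff[pid] / total
            metab = "HM" if pid == "HM" else pid
            assert res.percent_of_dose(metab) == pytest.approx(share_pct, abs=1.0)


def test_hydroxy_branch_fractions_match_clearance_ratios(rat_config, sims):
    """Within the 1'-hydroxy submodel the product split equals the ratio
    of linear-regime clearances at trace doses."""
    scaled = rat_config.scaled_constants()
    cl = {p: scaled[p].clearance_L_per_h_g for p in ("HMG", "HMO", "HMS")}
    total = sum(cl.values())
    res = sims[("rat", 0.05)]
    pool = res.metabolite_amount_umol("HM")
    for pid in ("HMG", "HMO", "HMS"):
        assert res.metabolite_amount_umol(pid) / pool == pytest.approx(
            cl[pid] / total, rel=0.02
        )


def test_solver_tolerance_robustness(rat_model):
    """Tightening rtol/atol tenfold moves 720 h outputs by <0.01%."""
    base = rat_model.simulate(0.05)
    tight = rat_model.simulate(0.05, rtol=1e-9, atol=1e-13)
    for m in METABOLITES:
        assert tight.percent_of_dose(m) == pytest.approx(
            base.percent_of_dose(m), rel=1e-4
        )


def test_dose_response_table(rat_model):
    """Duplicated doses give identical rows; table covers the grid."""
    frame = dose_response(rat_model, [0.05, 0.05], metabolite_ids=("DHA", "HMS"))
    assert len(frame) == 4
    first = frame.iloc[:2].reset_index(drop=True)
    second = frame.iloc[2:].reset_index(drop=True)
    assert first.equals(second)
    with pytest.raises(ValueError):
        dose_response(rat_model, [])
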