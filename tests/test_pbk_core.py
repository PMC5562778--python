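"""PBK model assembly, mass balance and simulation behaviour."""

import copy

import numpy as np
import pytest

from estragole_pbk.pbk_core import (
    METABOLITES,
    STATE_NAMES,
    amount_per_g_liver,
    build_model_spec,
    derive_flows_volumes,
    ode_rhs,
    percent_of_dose,
    simulate,
)


def mass_total(states_row):
    """All tracked material except the AM_HE bookkeeping column (1'-hydroxy-
    estragole appears both as pools and as its three products)."""
    skip = {"AM_HE"}
    return sum(v for k, v in zip(STATE_NAMES, states_row) if k not in skip)


def test_derived_liver_volumes(chinese_spec, caucasian_spec):
    volumes, _, _ = derive_flows_volumes(chinese_spec.physiology)
    assert volumes["liver"] == pytest.approx(1.38, rel=1e-12)  # 2.3% of 60 kg
    volumes, _, _ = derive_flows_volumes(caucasian_spec.physiology)
    assert volumes["liver"] == pytest.approx(1.82, rel=1e-12)  # 2.6% of 70 kg


def test_derived_flows_sum_and_scale(chinese_spec):
    phys = chinese_spec.physiology
    _, flows, total = derive_flows_volumes(phys)
    cardiac = phys.cardiac_output_constant * phys.body_weight_kg**0.74
    assert flows["liver"] == pytest.approx(0.263 * cardiac, rel=1e-12)
    # total blood-side flow is the tissue-flow sum (flow fractions sum to 100.15%)
    assert total == pytest.approx(sum(flows.values()), rel=1e-15)
    assert total == pytest.approx(1.0015 * cardiac, rel=1e-10)


def test_rhs_closed_system_at_rest(chinese_config):
    """Zero Vmax everywhere and Ka = 0: nothing moves from a dosed GI depot."""
    config = copy.deepcopy(chinese_config)
    config.ka_per_h = 0.0
    for kin in config.kinetics.values():
        kin.vmax_invitro = 0.0
    spec = build_model_spec(config)
    state = np.zeros(len(STATE_NAMES))
    state[0] = 10.0
    assert np.allclose(ode_rhs(state, spec), 0.0)


def test_rhs_initial_uptake_is_first_order(chinese_spec):
    dose = 4.0
    state = np.zeros(len(STATE_NAMES))
    state[STATE_NAMES.index("AGI_E")] = dose
    dy = ode_rhs(state, chinese_spec)
    ka = chinese_spec.ka_per_h
    assert dy[STATE_NAMES.index("AGI_E")] == pytest.approx(-ka * dose, rel=1e-12)
    assert dy[STATE_NAMES.index("AL_E")] == pytest.approx(ka * dose, rel=1e-12)


def test_rhs_conserves_mass_at_random_states(chinese_spec):
    """All transport terms cancel: the total tracked-material derivative is
    zero at any state (numeric check at random positive states)."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        state = rng.uniform(0.0, 50.0, size=len(STATE_NAMES))
        dy = ode_rhs(state, chinese_spec)
        assert mass_total(dy) == pytest.approx(0.0, abs=1e-9)


def test_zero_dose_gives_identically_zero_result(chinese_spec):
    res = simulate(chinese_spec, 0.0)
    assert res.states.to_numpy().max() == 0.0
    assert all(v == 0.0 for v in res.percent_of_dose.values())


@pytest.mark.parametrize("dose", [0.01, 150.0])
def test_mass_conservation_along_trajectory(chinese_spec, dose):
    res = simulate(chinese_spec, dose)
    totals = res.states.drop(columns="AM_HE").sum(axis=1).to_numpy()
    assert np.max(np.abs(totals - res.dose_umol)) / res.dose_umol < 1e-6


def test_states_nonnegative(chinese_spec, low_dose_results):
    for res in (low_dose_results["chinese"], simulate(chinese_spec, 150.0)):
        assert res.states.to_numpy().min() >= -1e-9


def test_low_dose_percent_summaries_are_dose_linear(chinese_spec):
    """At doses far below every Km the model is first-order, so %-of-dose
    summaries at 0.001 and 0.01 mg/kg agree within 1% relative."""
    lo = simulate(chinese_spec, 0.001).percent_of_dose
    hi = simulate(chinese_spec, 0.01).percent_of_dose
    for m in METABOLITES:
        assert hi[m] == pytest.approx(lo[m], rel=0.01), m


def test_low_dose_branch_split_follows_scaled_efficiencies(chinese_spec):
    """As dose -> 0 the HEG/OE/HES split converges to the ratio of the scaled
    catalytic efficiencies (analytic first-order limit)."""
    res = simulate(chinese_spec, 0.001)
    eff = {p.pathway_id: p.efficiency_scaled for p in chinese_spec.pathways}
    eff_total = eff["HEG"] + eff["OE"] + eff["HES"]
    formed = {m: res.cumulative_umol[m] for m in ("HEG", "OE", "HES")}
    formed_total = sum(formed.values())
    for m in ("HEG", "OE", "HES"):
        assert formed[m] / formed_total == pytest.approx(eff[m] / eff_total, rel=1e-3), m


def test_solver_tolerance_robustness(chinese_spec):
    """Halving the solver tolerances moves every 24-h summary by < 0.1%."""
    base = simulate(chinese_spec, 5.0).percent_of_dose
    tight = simulate(chinese_spec, 5.0, rtol=0.5e-8, atol=0.5e-12).percent_of_dose
    for m in METABOLITES:
        assert tight[m] == pytest.approx(base[m], rel=1e-3), m


def test_population_is_parameterization_not_code_path(chinese_config, caucasian_config):
    """A 'Chinese' config with every value replaced by Caucasian values is
    bit-identical in output to the Caucasian run."""
    clone = copy.deepcopy(caucasian_config)
    clone.name = "chinese"
    res_clone = simulate(build_model_spec(clone), 0.01)
    res_cauc = simulate(build_model_spec(caucasian_config), 0.01)
    assert np.array_equal(res_clone.states.to_numpy(), res_cauc.states.to_numpy())


def test_percent_and_per_gram_accessors(low_dose_results):
    res = low_dose_results["chinese"]
    assert percent_of_dose(res, "HE") == pytest.approx(
        res.cumulative_umol["HE"] * 100 / res.dose_umol, rel=1e-12
    )
    # published prediction: ~1.2 nmol/(g liver) 1'-oxoestragole at 0.01 mg/kg
    assert amount_per_g_liver(res, "OE") == pytest.approx(1.2, abs=0.15)
    with pytest.raises(KeyError):
        percent_of_dose(res, "XYZ")


def test_liver_he_exposure_metrics_are_consistent(low_dose_results):
    res = low_dose_results["chinese"]
    volumes, _, _ = derive_flows_volumes(res.spec.physiology)
    conc = res.states["AL_HE"].to_numpy() / volumes["liver"]
    assert res.liver_he_cmax_uM == pytest.approx(conc.max(), rel=1e-12)
    assert res.liver_he_auc_uM_h == pytest.approx(np.trapezoid(conc, res.time_h), rel=1e-12)
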