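"""Dose-response comparison, dose equivalence and Margin of Exposure."""

import pytest

from estragole_pbk.interethnic_risk import (
    dose_response_sweep,
    equivalent_dose,
    interethnic_fold,
    margin_of_exposure,
)

FAST = dict(rtol=1e-6, atol=1e-10, grid_step_h=0.1)


class TestMarginOfExposure:
    def test_dietary_intake_range(self):
        """BMDL10 3.3-6.5 mg/kg bw/day over an intake of 0.01 gives the
        published MOE range 330-650, below the 10,000 action threshold."""
        moe = margin_of_exposure(3.3, 6.5, 0.01)
        assert moe.moe_low == pytest.approx(330.0, rel=1e-12)
        assert moe.moe_high == pytest.approx(650.0, rel=1e-12)
        assert moe.priority_for_risk_management

    def test_supplement_intake_range(self):
        moe = margin_of_exposure(3.3, 6.5, 5.0)
        assert moe.moe_low == pytest.approx(0.66, rel=1e-12)
        assert moe.moe_high == pytest.approx(1.3, rel=1e-12)

    def test_identity_and_monotonicity(self):
        assert margin_of_exposure(2.0, 2.0, 2.0).moe_low == 1.0
        assert margin_of_exposure(3.3, 6.5, 0.02).moe_low < 330.0  # decreasing in EDI
        assert margin_of_exposure(4.0, 6.5, 0.01).moe_low > 330.0  # increasing in BMDL

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            margin_of_exposure(3.3, 6.5, 0.0)
        with pytest.raises(ValueError):
            margin_of_exposure(6.5, 3.3, 0.01)


class TestDoseResponse:
    def test_single_dose_single_row(self, chinese_spec):
        table = dose_response_sweep(chinese_spec, [0.01], population="chinese", **FAST)
        assert len(table.table) == 1
        assert table.value("HE", 0.01) > 0

    def test_rejects_unsorted_or_nonpositive_doses(self, chinese_spec):
        with pytest.raises(ValueError):
            dose_response_sweep(chinese_spec, [5.0, 0.01], **FAST)
        with pytest.raises(ValueError):
            dose_response_sweep(chinese_spec, [-1.0], **FAST)

    def test_oxidation_saturates_with_dose(self, dose_tables):
        """The dominant detoxification route falls from ~39-42% of dose at
        low doses to ~19% (Chinese) / ~28% (Caucasian) at 150 mg/kg."""
        chinese, caucasian = dose_tables["chinese"], dose_tables["caucasian"]
        assert chinese.value("OE", 0.01) == pytest.approx(42.0, abs=3.0)
        assert chinese.value("OE", 150.0) == pytest.approx(19.0, abs=3.0)
        assert caucasian.value("OE", 150.0) == pytest.approx(28.0, abs=3.0)

    def test_missing_cell_raises(self, dose_tables):
        with pytest.raises(KeyError):
            dose_tables["chinese"].value("HES", 1.23)


class TestInterethnicFold:
    def test_identical_tables_give_unity(self, dose_tables):
        fold = interethnic_fold(dose_tables["chinese"], dose_tables["chinese"], "HES", 5.0)
        assert fold.ratio == 1.0

    def test_sulfation_fold_at_dietary_dose(self, dose_tables):
        """~4.5-fold lower bioactivation for Chinese at 0.01 mg/kg bw."""
        fold = interethnic_fold(
            dose_tables["caucasian"], dose_tables["chinese"], "HES", 0.01
        )
        assert fold.lower == "chinese"
        assert fold.ratio == pytest.approx(4.5, rel=0.10)

    def test_glucuronidation_folds(self, dose_tables):
        """HEG folds: ~2.4 at 0.01 and ~3.4 at 150 mg/kg bw (percent basis)."""
        args = (dose_tables["caucasian"], dose_tables["chinese"], "HEG")
        assert interethnic_fold(*args, 0.01).ratio == pytest.approx(2.4, rel=0.10)
        assert interethnic_fold(*args, 150.0).ratio == pytest.approx(3.4, rel=0.10)

    def test_sulfation_fold_nondecreasing_in_dose(self, dose_tables):
        args = (dose_tables["caucasian"], dose_tables["chinese"], "HES")
        folds = [interethnic_fold(*args, d).ratio for d in (0.01, 5.0, 150.0)]
        assert folds == sorted(folds)

    def test_amount_basis_differs_by_body_weight_ratio(self, dose_tables):
        """% of dose and absolute amount fold differ exactly by 70/60 at the
        same mg/kg dose."""
        args = (dose_tables["caucasian"], dose_tables["chinese"], "HES", 150.0)
        pct = interethnic_fold(*args, basis="percent").ratio
        amt = interethnic_fold(*args, basis="amount").ratio
        assert amt == pytest.approx(pct * 70.0 / 60.0, rel=1e-9)


class TestEquivalentDose:
    def test_same_population_is_identity(self, chinese_spec):
        for method in ("linear", "root"):
            dose = equivalent_dose(chinese_spec, chinese_spec, 0.5, method=method, **FAST)
            assert dose == pytest.approx(0.5, rel=1e-3)

    def test_linear_equivalence_at_dietary_dose(self, caucasian_spec, chinese_spec):
        """A Caucasian intake of 0.01 mg/kg bw is matched by a ~5-fold higher
        Chinese intake (~0.05 mg/kg bw)."""
        dose = equivalent_dose(chinese_spec, caucasian_spec, 0.01, **FAST)
        assert dose == pytest.approx(0.05, rel=0.10)

    def test_root_method_matches_linear_in_first_order_regime(
        self, caucasian_spec, chinese_spec
    ):
        lin = equivalent_dose(chinese_spec, caucasian_spec, 0.01, method="linear", **FAST)
        root = equivalent_dose(chinese_spec, caucasian_spec, 0.01, method="root", **FAST)
        assert root == pytest.approx(lin, rel=0.01)

    def test_root_method_round_trips(self, caucasian_spec, chinese_spec):
        """Swapping reference and target recovers the original dose."""
        forward = equivalent_dose(chinese_spec, caucasian_spec, 1.0, method="root", **FAST)
        back = equivalent_dose(caucasian_spec, chinese_spec, forward, method="root", **FAST)
        assert back == pytest.approx(1.0, rel=0.005)

    def test_monotone_in_reference_dose(self, caucasian_spec, chinese_spec):
        d1 = equivalent_dose(chinese_spec, caucasian_spec, 1.0, **FAST)
        d2 = equivalent_dose(chinese_spec, caucasian_spec, 5.0, **FAST)
        assert d2 > d1

    def test_rejects_nonpositive_reference(self, caucasian_spec, chinese_spec):
        with pytest.raises(ValueError):
            equivalent_dose(chinese_spec, caucasian_spec, 0.0, **FAST)
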