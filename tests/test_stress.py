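import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soyflood.stress import (
    DEFAULT_SD_TABLE,
    OxdefParams,
    PiecewiseMultiplier,
    RecoveryCarry,
    StageSeverity,
    apply_stage_severity,
    drought_photo_stress,
    evaluate_multiplier,
    oxdef_fix,
    oxdef_pheno,
    oxdef_photo,
    perturb_params,
    post_flood_recovery,
)

PHOTO = PiecewiseMultiplier((0.0, 0.8, 1.0), (1.0, 1.0, 0.75))
VEG, REP = 2.0, 4.5  # stage codes well inside each phase


class TestPiecewise:
    def test_anchor(self):
        assert evaluate_multiplier(PHOTO, 0.0) == 1.0

    def test_midpoint_interpolation(self):
        assert evaluate_multiplier(PHOTO, 0.9) == pytest.approx(0.875)

    def test_clamped_beyond_range(self):
        assert evaluate_multiplier(PHOTO, 1.3) == 0.75

    @pytest.mark.parametrize(
        "xs,ys",
        [((0.0,), (1.0,)), ((0.0, 0.0), (1.0, 1.0)), ((0.0, 1.0), (1.0, 1.5))],
    )
    def test_validation(self, xs, ys):
        with pytest.raises(ValueError):
            PiecewiseMultiplier(xs, ys)


class TestDrought:
    def test_no_stress_above_unity_ratio(self):
        assert drought_photo_stress(5.0, 4.0) == 1.0

    def test_ratio_below_one(self):
        assert drought_photo_stress(2.0, 4.0) == 0.5

    def test_zero_demand_is_unstressed(self):
        assert drought_photo_stress(0.0, 0.0) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            drought_photo_stress(-1.0, 1.0)


class TestStageSeverity:
    def test_no_stress_unchanged_at_any_stage(self):
        sev = StageSeverity()
        for stage in (0.0, 3.0, 4.0, 6.0):
            assert apply_stage_severity(1.0, stage, sev) == 1.0

    def test_identity_severity(self):
        assert apply_stage_severity(0.75, VEG, StageSeverity()) == pytest.approx(0.75)

    def test_doubled_depth(self):
        sev = StageSeverity(severity_veg=2.0, severity_rep=2.0)
        assert apply_stage_severity(0.75, REP, sev) == pytest.approx(0.5)

    def test_reproductive_at_least_as_severe(self):
        sev = StageSeverity()
        for y in (0.2, 0.5, 0.9):
            assert apply_stage_severity(y, REP, sev) <= apply_stage_severity(y, VEG, sev)


class TestOxdefFunctions:
    def test_photo_no_stress_until_80pct_submerged(self):
        p = OxdefParams()
        for x in (0.0, 0.4, 0.8):
            assert oxdef_photo(x, VEG, p) == 1.0

    def test_photo_full_submergence_vegetative(self):
        # 25% reduction, inside the 16-33% range reported for 48-h V4 floods
        assert oxdef_photo(1.0, VEG, OxdefParams()) == pytest.approx(0.75)

    def test_photo_full_submergence_reproductive(self):
        # 30% reduction, inside the 22-32% range reported at R2
        assert oxdef_photo(1.0, REP, OxdefParams()) == pytest.approx(0.70)

    def test_pheno_anchor_and_interpolation(self):
        p = OxdefParams()
        assert oxdef_pheno(0.0, VEG, p) == 1.0
        assert oxdef_pheno(1.0, VEG, p) == pytest.approx(p.pheno.ys[-1])
        mid = 0.5 * (1.0 + p.pheno.ys[-1])
        assert oxdef_pheno(0.9, VEG, p) == pytest.approx(mid)

    def test_fix_minor_until_half_excess(self):
        p = OxdefParams()
        for x in (0.0, 0.3, 0.5):
            assert oxdef_fix(x, VEG, p) == 1.0

    def test_fix_zero_at_saturation_every_stage(self):
        p = OxdefParams()
        for stage in (0.0, 2.0, 3.5, 4.5, 6.0):
            assert oxdef_fix(1.0, stage, p) == 0.0

    def test_fix_interpolation(self):
        assert oxdef_fix(0.75, VEG, OxdefParams()) == pytest.approx(0.5)

    def test_fix_terminal_anchor_enforced(self):
        with pytest.raises(ValueError):
            OxdefParams(fix=PiecewiseMultiplier((0.0, 1.0), (1.0, 0.2)))

    @given(
        x=st.floats(0, 1),
        stage=st.floats(0, 6),
        fn=st.sampled_from(["photo", "pheno", "fix"]),
    )
    def test_all_multipliers_in_unit_interval(self, x, stage, fn):
        p = OxdefParams()
        f = {"photo": oxdef_photo, "pheno": oxdef_pheno, "fix": oxdef_fix}[fn]
        assert 0.0 <= f(x, stage, p) <= 1.0

    @given(
        x=st.floats(0, 0.98),
        dx=st.floats(0.001, 0.5),
        stage=st.floats(0, 6),
        fn=st.sampled_from(["photo", "pheno", "fix"]),
    )
    def test_monotone_non_increasing_in_predictor(self, x, dx, stage, fn):
        p = OxdefParams()
        f = {"photo": oxdef_photo, "pheno": oxdef_pheno, "fix": oxdef_fix}[fn]
        assert f(min(1.0, x + dx), stage, p) <= f(x, stage, p) + 1e-12


class TestRecovery:
    def test_vegetative_flood_fully_recovers(self):
        p = OxdefParams()
        carry = RecoveryCarry()
        for _ in range(10):  # long flood, entirely before R1
            _, carry = post_flood_recovery(0.75, True, VEG, p, carry, full_stress_y=0.75)
        eff, carry = post_flood_recovery(1.0, False, VEG, p, carry)
        assert eff == 1.0

    def test_reproductive_exposure_caps_until_maturity(self):
        p = OxdefParams()
        carry = RecoveryCarry()
        days = 5
        for _ in range(days):
            _, carry = post_flood_recovery(0.0, True, REP, p, carry, full_stress_y=0.0)
        eff, _ = post_flood_recovery(1.0, False, REP, p, carry)
        expected = 1.0 - p.recovery_persistence * days / p.recovery_saturation_days
        assert eff == pytest.approx(expected)

    def test_damage_saturates(self):
        p = OxdefParams()
        carry = RecoveryCarry()
        for _ in range(100):
            _, carry = post_flood_recovery(0.0, True, REP, p, carry, full_stress_y=0.0)
        eff, _ = post_flood_recovery(1.0, False, REP, p, carry)
        assert eff == pytest.approx(1.0 - p.recovery_persistence)

    def test_zero_persistence_always_recovers(self):
        p = OxdefParams(recovery_persistence=0.0)
        carry = RecoveryCarry()
        for _ in range(20):
            _, carry = post_flood_recovery(0.0, True, REP, p, carry, full_stress_y=0.0)
        eff, _ = post_flood_recovery(1.0, False, REP, p, carry)
        assert eff == 1.0

    def test_partial_depth_counts_partially(self):
        p = OxdefParams()
        a, b = RecoveryCarry(), RecoveryCarry()
        # one day at the photo floor vs one day at half that depth
        _, a = post_flood_recovery(0.70, True, REP, p, a, full_stress_y=0.70)
        _, b = post_flood_recovery(0.85, True, REP, p, b, full_stress_y=0.70)
        assert a.exposure == pytest.approx(1.0)
        assert b.exposure == pytest.approx(0.5)


class TestPerturbation:
    def test_fix_saturation_anchor_never_moves(self):
        p = OxdefParams()
        for n in (-2, -1, 1, 2):
            assert perturb_params(p, "fix", n).fix.ys[-1] == 0.0

    def test_photo_terminal_shift(self):
        p = OxdefParams()
        out = perturb_params(p, "photo", 2, {"photo": (0.0, 0.0, 0.05)})
        assert out.photo.ys[-1] == pytest.approx(0.85)

    def test_shifts_clamped_to_unit_interval(self):
        p = OxdefParams()
        out = perturb_params(p, "fix", -2, {"fix": (0.0, 0.6, 0.0)})
        assert all(0.0 <= y <= 1.0 for y in out.fix.ys)

    def test_unknown_function_rejected(self):
        with pytest.raises(ValueError):
            perturb_params(OxdefParams(), "senescence", 1)

    def test_default_sd_table_covers_all_functions(self):
        assert set(DEFAULT_SD_TABLE) == {"photo", "pheno", "fix"}
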