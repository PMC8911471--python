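"""Constraint-tier classification, gold overlay, and workflow aggregation."""

import numpy as np
import pandas as pd
import pytest

from adaptqa.dosimetry import DoseGrid
from adaptqa.evaluate import (
    ConstraintResult,
    ConstraintSpec,
    Disposition,
    FractionOutcome,
    PrescriptionSpec,
    Tier,
    TierResult,
    aggregate,
    classify,
    default_constraints,
    gold_overlay_eval,
    outcome_matrix,
    round_pct,
)
from adaptqa.grid import GridCompatibilityError, Role, StructureMask, VoxelGrid


def _grid():
    return VoxelGrid((0, 0, 0), (1, 1, 1), (20, 20, 10))


def _mask(grid, lo, hi, name):
    data = np.zeros(grid.shape, bool)
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return StructureMask(name, Role.OAR, grid, data)


def _tier_result(tier: Tier) -> TierResult:
    c = ConstraintSpec("bladder", "Dmean", 40.0, 44.0)
    value = {Tier.MET: 30.0, Tier.ACCEPTABLE_VARIATION: 42.0, Tier.FAIL: 50.0}[tier]
    return TierResult((ConstraintResult(c, value, tier),))


class TestPrescription:
    def test_tiers_from_dose_per_fraction(self):
        assert PrescriptionSpec(2.0, 25).tier.value == "CONVENTIONAL"
        assert PrescriptionSpec(1.8, 25).tier.value == "CONVENTIONAL"
        assert PrescriptionSpec(5.0, 5).tier.value == "SHORT"
        assert PrescriptionSpec(2.0, 25).total_gy == 50.0

    def test_unmapped_dose_per_fraction_rejected(self):
        with pytest.raises(ValueError, match="3.0"):
            PrescriptionSpec(3.0, 10)


class TestDefaultConstraints:
    def test_conventional_limits(self):
        cs = {c.structure: c for c in default_constraints(PrescriptionSpec(2.0, 25))}
        assert (cs["bladder"].ideal_gy, cs["bladder"].acceptable_gy) == (40.0, 44.0)
        assert (cs["bowel"].ideal_gy, cs["bowel"].acceptable_gy) == (50.0, 55.0)
        assert cs["bladder"].metric == "Dmean" and cs["bowel"].metric == "D0.03cc"

    def test_short_course_limits(self):
        cs = {c.structure: c for c in default_constraints(PrescriptionSpec(5.0, 5))}
        assert (cs["bladder"].ideal_gy, cs["bladder"].acceptable_gy) == (22.0, 24.0)
        assert (cs["bowel"].ideal_gy, cs["bowel"].acceptable_gy) == (27.5, 30.0)

    def test_constraint_spec_validation(self):
        with pytest.raises(ValueError, match="exceeds"):
            ConstraintSpec("bladder", "Dmean", 44.0, 40.0)


class TestClassify:
    def _setup(self, bladder_gy, bowel_gy):
        grid = _grid()
        bladder = _mask(grid, (0, 0, 0), (10, 10, 10), "bladder")
        bowel = _mask(grid, (10, 0, 0), (20, 10, 10), "bowel")
        dose = np.zeros(grid.shape)
        dose[0:10, 0:10, 0:10] = bladder_gy
        dose[10:20, 0:10, 0:10] = bowel_gy
        return DoseGrid(grid, dose), {"bladder": bladder, "bowel": bowel}

    def test_all_met(self):
        dose, structs = self._setup(39.0, 49.0)
        res = classify(dose, structs, default_constraints(PrescriptionSpec(2.0, 25)))
        assert res.plan_tier is Tier.MET and res.passed

    def test_boundary_equality_belongs_to_better_tier(self):
        dose, structs = self._setup(44.0, 40.0)
        res = classify(dose, structs, default_constraints(PrescriptionSpec(2.0, 25)))
        assert res.results[0].tier is Tier.ACCEPTABLE_VARIATION
        dose, structs = self._setup(40.0, 40.0)
        res = classify(dose, structs, default_constraints(PrescriptionSpec(2.0, 25)))
        assert res.results[0].tier is Tier.MET

    def test_worst_tier_wins(self):
        dose, structs = self._setup(30.0, 56.0)
        res = classify(dose, structs, default_constraints(PrescriptionSpec(2.0, 25)))
        assert res.plan_tier is Tier.FAIL and not res.passed

    def test_missing_structure_named_in_error(self):
        dose, structs = self._setup(30.0, 40.0)
        del structs["bowel"]
        with pytest.raises(KeyError, match="bowel"):
            classify(dose, structs, default_constraints(PrescriptionSpec(2.0, 25)))


class TestGoldOverlay:
    def test_identical_structures_give_identical_tiers(self):
        grid = _grid()
        bladder = _mask(grid, (0, 0, 0), (10, 10, 10), "bladder")
        bowel = _mask(grid, (10, 0, 0), (20, 10, 10), "bowel")
        dose = DoseGrid(grid, np.full(grid.shape, 30.0))
        constraints = default_constraints(PrescriptionSpec(2.0, 25))
        clinical = classify(dose, {"bladder": bladder, "bowel": bowel}, constraints)
        gold = gold_overlay_eval(
            dose, {"bladder": bladder.copy(), "bowel": bowel.copy()}, constraints
        )
        assert gold.plan_tier == clinical.plan_tier

    def test_undercontoured_bowel_near_hotspot_fails_only_gold(self):
        # adapter's bowel misses the hotspot; the specialist's bowel covers it
        grid = _grid()
        bladder = _mask(grid, (0, 0, 0), (5, 5, 5), "bladder")
        obs_bowel = _mask(grid, (10, 0, 0), (15, 10, 10), "bowel")
        gold_bowel = _mask(grid, (10, 0, 0), (18, 10, 10), "bowel")
        dose = np.full(grid.shape, 20.0)
        dose[15:18, 0:10, 0:10] = 58.0  # hotspot in the missed region
        dose_grid = DoseGrid(grid, dose)
        constraints = default_constraints(PrescriptionSpec(2.0, 25))
        clinical = classify(
            dose_grid, {"bladder": bladder, "bowel": obs_bowel}, constraints
        )
        gold = gold_overlay_eval(
            dose_grid, {"bladder": bladder, "bowel": gold_bowel}, constraints
        )
        assert clinical.plan_tier is Tier.MET
        assert gold.plan_tier is Tier.FAIL

    def test_larger_gold_bladder_away_from_dose_changes_nothing(self):
        grid = _grid()
        obs_bladder = _mask(grid, (0, 0, 0), (8, 8, 8), "bladder")
        gold_bladder = _mask(grid, (0, 0, 0), (12, 12, 8), "bladder")
        bowel = _mask(grid, (15, 15, 0), (20, 20, 5), "bowel")
        dose = DoseGrid(grid, np.full(grid.shape, 10.0))
        constraints = default_constraints(PrescriptionSpec(2.0, 25))
        clinical = classify(dose, {"bladder": obs_bladder, "bowel": bowel}, constraints)
        gold = gold_overlay_eval(
            dose, {"bladder": gold_bladder, "bowel": bowel}, constraints
        )
        assert gold.plan_tier == clinical.plan_tier is Tier.MET

    def test_grid_incompatibility_is_an_error_not_a_resample(self):
        grid = _grid()
        other = VoxelGrid((0, 0, 0), (2, 2, 2), (20, 20, 10))
        dose = DoseGrid(grid, np.zeros(grid.shape))
        gold = _mask(other, (0, 0, 0), (5, 5, 5), "bladder")
        with pytest.raises(GridCompatibilityError):
            gold_overlay_eval(dose, {"bladder": gold}, [])


def _outcome(i, clinical: Tier, gold: Tier | None, observer="T1") -> FractionOutcome:
    return FractionOutcome(
        patient_id=f"P{i // 2}",
        fraction_id=f"fx{i % 2}",
        observer_id=observer,
        clinical=_tier_result(clinical),
        gold=None if gold is None else _tier_result(gold),
    )


class TestDispositions:
    def test_logic_is_total_and_mutually_exclusive(self):
        for clin in Tier:
            for gold in list(Tier) + [None]:
                o = _outcome(0, clin, gold)
                d = o.disposition
                if clin is Tier.FAIL:
                    assert d is Disposition.HALTED_FOR_REVIEW
                elif gold is Tier.FAIL:
                    assert d is Disposition.DELIVERED_SUBOPTIMAL
                else:
                    assert d is Disposition.DELIVERED_OK


class TestAggregate:
    def test_ninety_percent_pass_rate_from_counts(self):
        outcomes = (
            [_outcome(i, Tier.MET, Tier.MET) for i in range(68)]
            + [_outcome(i, Tier.ACCEPTABLE_VARIATION, Tier.MET) for i in range(68, 72)]
            + [_outcome(i, Tier.FAIL, Tier.FAIL) for i in range(72, 80)]
        )
        summary = aggregate(outcomes)
        assert summary.overall.clinical_pass == 72
        assert summary.overall.clinical_pass_rate_pct == 90.0

    def test_safety_rate_counts_halts_as_safe(self):
        # 8 clinical FAILs (halted); 2 silent gold FAILs slip through
        outcomes = (
            [_outcome(i, Tier.MET, Tier.MET) for i in range(70)]
            + [_outcome(i, Tier.MET, Tier.FAIL) for i in range(70, 72)]
            + [_outcome(i, Tier.FAIL, Tier.FAIL) for i in range(72, 80)]
        )
        summary = aggregate(outcomes)
        assert summary.overall.n_safe == 78
        assert summary.overall.safety_rate_pct == 97.5
        assert summary.overall.treated_after_fail_rate_pct == 2.5

    def test_all_met_gives_all_hundreds(self):
        outcomes = [_outcome(i, Tier.MET, Tier.MET) for i in range(10)]
        s = aggregate(outcomes).overall
        assert s.clinical_pass_rate_pct == s.gold_pass_rate_pct == 100.0
        assert s.safety_rate_pct == 100.0

    def test_safety_rate_never_below_gold_pass_rate(self):
        rng = np.random.default_rng(13)
        tiers = list(Tier)
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            outcomes = [
                _outcome(i, tiers[rng.integers(3)], tiers[rng.integers(3)])
                for i in range(n)
            ]
            s = aggregate(outcomes).overall
            assert s.safety_rate_pct >= s.gold_pass_rate_pct

    def test_by_class_split(self):
        outcomes = [
            _outcome(i, Tier.MET, Tier.MET, observer="D1") for i in range(4)
        ] + [_outcome(i, Tier.FAIL, Tier.FAIL, observer="S1") for i in range(4)]
        summary = aggregate(outcomes, {"D1": "physician", "S1": "student"})
        assert summary.by_class["physician"].clinical_pass_rate_pct == 100.0
        assert summary.by_class["student"].clinical_pass_rate_pct == 0.0

    def test_raw_fractions_reported_next_to_percentages(self):
        outcomes = [_outcome(i, Tier.MET, Tier.FAIL) for i in range(3)]
        d = aggregate(outcomes).overall.as_dict()
        assert d["gold_pass"] == [0, 3] and d["safe"] == [0, 3]

    def test_empty_outcomes_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])


class TestRounding:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(73, 80, 91.2), (78, 80, 97.5), (72, 80, 90.0), (2, 80, 2.5),
         (1, 3, 33.3), (85, 1000, 8.5), (125, 1000, 12.5)],
    )
    def test_half_even_to_one_decimal(self, num, den, expected):
        assert round_pct(num, den) == expected


class TestOutcomeMatrix:
    def test_hand_enumerated_two_by_two(self):
        outcomes = [
            FractionOutcome("P1", "fx1", "A", _tier_result(Tier.MET), _tier_result(Tier.MET)),
            FractionOutcome("P1", "fx2", "A", _tier_result(Tier.FAIL), _tier_result(Tier.FAIL)),
            FractionOutcome("P1", "fx1", "B", _tier_result(Tier.MET), _tier_result(Tier.FAIL)),
            FractionOutcome("P1", "fx2", "B", _tier_result(Tier.ACCEPTABLE_VARIATION), _tier_result(Tier.MET)),
        ]
        m = outcome_matrix(outcomes)
        assert m.frame.loc[("P1", "fx1"), ("A", "clinical")] == "MET"
        assert m.frame.loc[("P1", "fx2"), ("A", "gold")] == "FAIL"
        assert m.frame.loc[("P1", "fx2"), ("B", "clinical")] == "ACCEPTABLE_VARIATION"
        for basis in ("clinical", "gold"):
            assert sum(m.cell_counts(basis).values()) == 4

    def test_heatmap_render_writes_image(self, tmp_path):
        outcomes = [
            FractionOutcome("P1", "fx1", "A", _tier_result(Tier.MET), _tier_result(Tier.MET))
        ]
        path = tmp_path / "heat.png"
        outcome_matrix(outcomes).plot(path)
        assert path.stat().st_size > 0


class TestRoundPctProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(num=st.integers(min_value=0, max_value=2000),
           den=st.integers(min_value=1, max_value=2000))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_rounding_stays_within_half_a_decimal(self, num, den):
        if num > den:
            num = num % (den + 1)
        pct = round_pct(num, den)
        assert 0.0 <= pct <= 100.0
        assert abs(pct - 100.0 * num / den) <= 0.05 + 1e-9
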