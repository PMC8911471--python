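"""Tiered dose-constraint classification and workflow outcome aggregation.

A plan is scored against per-structure dosimetric constraints, each with an
*ideal* limit and a looser *acceptable variation* limit (upper bounds, Gy;
boundary equality belongs to the better tier).  The plan tier is the worst
constraint tier.  "Pass" means MET or ACCEPTABLE_VARIATION.

Each adapted fraction is evaluated twice: once against the adapter's own
structures (the clinical evaluation that gates delivery) and once against
the specialist gold-standard structures overlaid on the same dose.  The
workflow disposition follows:

* clinical FAIL                     -> HALTED_FOR_REVIEW (on-table review)
* clinical pass but gold FAIL       -> DELIVERED_SUBOPTIMAL (silent failure,
  caught only by offline review)
* otherwise                         -> DELIVERED_OK

The safety rate counts fractions that were either delivered acceptably or
halted before delivery; only silent failures reduce it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dosimetry import DoseGrid, MetricSpec, dose_metric, parse_metric
from .grid import StructureMask


class Tier(enum.IntEnum):
    """Constraint tier, ordered by severity."""

    MET = 0
    ACCEPTABLE_VARIATION = 1
    FAIL = 2


class Disposition(str, enum.Enum):
    DELIVERED_OK = "DELIVERED_OK"
    HALTED_FOR_REVIEW = "HALTED_FOR_REVIEW"
    DELIVERED_SUBOPTIMAL = "DELIVERED_SUBOPTIMAL"


class FractionationTier(str, enum.Enum):
    CONVENTIONAL = "CONVENTIONAL"  # 1.8-2 Gy per fraction
    SHORT = "SHORT"  # 5 Gy per fraction


@dataclass(frozen=True)
class PrescriptionSpec:
    """Course prescription: dose per fraction and total fraction count."""

    dose_per_fraction_gy: float
    n_fractions: int

    def __post_init__(self) -> None:
        self.tier  # validate at construction

    @property
    def total_gy(self) -> float:
        return self.dose_per_fraction_gy * self.n_fractions

    @property
    def tier(self) -> FractionationTier:
        d = self.dose_per_fraction_gy
        if 1.8 <= d <= 2.0:
            return FractionationTier.CONVENTIONAL
        if d == 5.0:
            return FractionationTier.SHORT
        raise ValueError(
            f"no constraint tier is defined for {d} Gy per fraction "
            "(expected 1.8-2 Gy or 5 Gy)"
        )


@dataclass(frozen=True)
class ConstraintSpec:
    """One dosimetric rule with ideal and acceptable-variation upper bounds."""

    structure: str
    metric: str
    ideal_gy: float
    acceptable_gy: float

    def __post_init__(self) -> None:
        if self.ideal_gy > self.acceptable_gy:
            raise ValueError(
                f"ideal limit {self.ideal_gy} Gy exceeds acceptable limit "
                f"{self.acceptable_gy} Gy for {self.structure} {self.metric}"
            )
        parse_metric(self.metric)

    def classify_value(self, value_gy: float) -> Tier:
        if value_gy <= self.ideal_gy:
            return Tier.MET
        if value_gy <= self.acceptable_gy:
            return Tier.ACCEPTABLE_VARIATION
        return Tier.FAIL


#: Bladder-Dmean / bowel-D(0.03 cc) constraint tiers by dose per fraction,
#: scaled from the NRG-GI002 conventions used for pelvic adaptive plans.
_CONSTRAINT_TABLE: dict[FractionationTier, list[ConstraintSpec]] = {
    FractionationTier.CONVENTIONAL: [
        ConstraintSpec("bladder", "Dmean", 40.0, 44.0),
        ConstraintSpec("bowel", "D0.03cc", 50.0, 55.0),
    ],
    FractionationTier.SHORT: [
        ConstraintSpec("bladder", "Dmean", 22.0, 24.0),
        ConstraintSpec("bowel", "D0.03cc", 27.5, 30.0),
    ],
}


def default_constraints(rx: PrescriptionSpec) -> list[ConstraintSpec]:
    """The bladder/bowel constraint pair for the prescription's tier."""
    return list(_CONSTRAINT_TABLE[rx.tier])


@dataclass(frozen=True)
class ConstraintResult:
    constraint: ConstraintSpec
    value_gy: float
    tier: Tier


@dataclass(frozen=True)
class TierResult:
    """Per-constraint measured values and the worst-tier plan result."""

    results: tuple[ConstraintResult, ...]

    @property
    def plan_tier(self) -> Tier:
        return Tier(max(r.tier for r in self.results))

    @property
    def passed(self) -> bool:
        return self.plan_tier is not Tier.FAIL

    def value(self, structure: str) -> float:
        for r in self.results:
            if r.constraint.structure == structure:
                return r.value_gy
        raise KeyError(structure)


def classify(
    dose: DoseGrid,
    structures: Mapping[str, StructureMask],
    constraints: Sequence[ConstraintSpec],
) -> TierResult:
    """Evaluate a dose distribution against tiered constraints.

    ``structures`` maps each constraint's structure name to the mask the
    dose should be scored on (e.g. the cranially limited bowel).
    """
    results = []
    for c in constraints:
        if c.structure not in structures:
            raise KeyError(
                f"constraint references structure '{c.structure}' which is "
                f"not among {sorted(structures)}"
            )
        value = dose_metric(dose, structures[c.structure], c.metric)
        results.append(ConstraintResult(c, value, c.classify_value(value)))
    return TierResult(tuple(results))


def gold_overlay_eval(
    dose: DoseGrid,
    gold_structures: Mapping[str, StructureMask],
    constraints: Sequence[ConstraintSpec],
) -> TierResult:
    """Re-evaluate an adapter's dose against the specialist gold structures.

    The gold masks must live on a grid compatible with the dose; there is
    no resampling.
    """
    for mask in gold_structures.values():
        dose.grid.require_compatible(mask.grid)
    return classify(dose, gold_structures, constraints)


@dataclass(frozen=True)
class FractionOutcome:
    """Clinical and gold-standard evaluation of one adapted fraction."""

    patient_id: str
    fraction_id: str
    observer_id: str
    clinical: TierResult
    gold: TierResult | None = None

    @property
    def disposition(self) -> Disposition:
        if self.clinical.plan_tier is Tier.FAIL:
            return Disposition.HALTED_FOR_REVIEW
        if self.gold is not None and self.gold.plan_tier is Tier.FAIL:
            return Disposition.DELIVERED_SUBOPTIMAL
        return Disposition.DELIVERED_OK


def round_pct(numerator: int, denominator: int) -> float:
    """Exact percentage rounded half-even to one decimal."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator for a percentage")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


def _tier_counts(tiers: Iterable[Tier]) -> dict[str, int]:
    counts = {t.name: 0 for t in Tier}
    for t in tiers:
        counts[t.name] += 1
    return counts


@dataclass
class GroupSummary:
    """Counts and rates for one observer class (or the whole cohort)."""

    n: int
    clinical_counts: dict[str, int]
    gold_counts: dict[str, int]
    n_gold: int
    disposition_counts: dict[str, int]

    @property
    def clinical_pass(self) -> int:
        return self.clinical_counts["MET"] + self.clinical_counts["ACCEPTABLE_VARIATION"]

    @property
    def clinical_pass_rate_pct(self) -> float:
        return round_pct(self.clinical_pass, self.n)

    @property
    def gold_pass(self) -> int:
        return self.gold_counts["MET"] + self.gold_counts["ACCEPTABLE_VARIATION"]

    @property
    def gold_pass_rate_pct(self) -> float | None:
        if self.n_gold == 0:
            return None
        return round_pct(self.gold_pass, self.n_gold)

    @property
    def n_safe(self) -> int:
        return (
            self.disposition_counts[Disposition.DELIVERED_OK.value]
            + self.disposition_counts[Disposition.HALTED_FOR_REVIEW.value]
        )

    @property
    def safety_rate_pct(self) -> float:
        return round_pct(self.n_safe, self.n)

    @property
    def treated_after_fail_rate_pct(self) -> float:
        return round_pct(
            self.disposition_counts[Disposition.DELIVERED_SUBOPTIMAL.value], self.n
        )

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "clinical_counts": self.clinical_counts,
            "gold_counts": self.gold_counts,
            "n_gold": self.n_gold,
            "disposition_counts": self.disposition_counts,
            "clinical_pass": [self.clinical_pass, self.n],
            "clinical_pass_rate_pct": self.clinical_pass_rate_pct,
            "gold_pass": [self.gold_pass, self.n_gold],
            "gold_pass_rate_pct": self.gold_pass_rate_pct,
            "safe": [self.n_safe, self.n],
            "safety_rate_pct": self.safety_rate_pct,
            "treated_after_fail_rate_pct": self.treated_after_fail_rate_pct,
        }


@dataclass
class WorkflowSummary:
    overall: GroupSummary
    by_class: dict[str, GroupSummary]
    crosstab: pd.DataFrame  # clinical tier x gold tier counts

    def as_dict(self) -> dict:
        return {
            "overall": self.overall.as_dict(),
            "by_class": {k: v.as_dict() for k, v in self.by_class.items()},
            "crosstab_clinical_x_gold": {
                c: {g: int(self.crosstab.loc[c, g]) for g in self.crosstab.columns}
                for c in self.crosstab.index
            },
        }


def _summarize(outcomes: Sequence[FractionOutcome]) -> GroupSummary:
    with_gold = [o for o in outcomes if o.gold is not None]
    disp = {d.value: 0 for d in Disposition}
    for o in outcomes:
        disp[o.disposition.value] += 1
    return GroupSummary(
        n=len(outcomes),
        clinical_counts=_tier_counts(o.clinical.plan_tier for o in outcomes),
        gold_counts=_tier_counts(o.gold.plan_tier for o in with_gold),
        n_gold=len(with_gold),
        disposition_counts=disp,
    )


def aggregate(
    outcomes: Sequence[FractionOutcome],
    observer_classes: Mapping[str, str] | None = None,
) -> WorkflowSummary:
    """Workflow safety aggregation over a set of fraction outcomes.

    ``observer_classes`` maps observer ids to a class label (e.g.
    physician / therapist / student, or physician / non-physician); when
    omitted each observer id forms its own class.  Raw counts are always
    reported next to the rounded percentages so rounding can never hide a
    discrepancy.
    """
    if not outcomes:
        raise ValueError("cannot aggregate an empty outcome list")
    classes = observer_classes or {}
    by_class: dict[str, list[FractionOutcome]] = {}
    for o in outcomes:
        label = classes.get(o.observer_id, o.observer_id)
        by_class.setdefault(label, []).append(o)

    tiers = [t.name for t in Tier]
    cross = pd.DataFrame(0, index=tiers, columns=tiers, dtype=int)
    for o in outcomes:
        if o.gold is not None:
            cross.loc[o.clinical.plan_tier.name, o.gold.plan_tier.name] += 1

    return WorkflowSummary(
        overall=_summarize(outcomes),
        by_class={k: _summarize(v) for k, v in sorted(by_class.items())},
        crosstab=cross,
    )


@dataclass
class OutcomeMatrix:
    """Per-fraction three-state outcome grid (the heat-map layout).

    Rows are (patient, fraction); columns are (observer, basis) with basis
    in {clinical, gold}; cells hold tier names.
    """

    frame: pd.DataFrame

    def cell_counts(self, basis: str) -> dict[str, int]:
        cols = [c for c in self.frame.columns if c[1] == basis]
        values = self.frame[cols].to_numpy().ravel()
        return {t.name: int((values == t.name).sum()) for t in Tier}

    def plot(self, path) -> None:
        """Render the matrix as a green/yellow/red heat map image."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        code = {t.name: i for i, t in enumerate(Tier)}
        arr = np.array(
            [[code.get(v, np.nan) for v in row] for row in self.frame.to_numpy()],
            dtype=float,
        )
        cmap = ListedColormap(["#2ca25f", "#f6e151", "#de2d26"])
        fig, ax = plt.subplots(
            figsize=(1 + 0.45 * arr.shape[1], 1 + 0.3 * arr.shape[0])
        )
        ax.pcolormesh(arr, cmap=cmap, vmin=-0.5, vmax=2.5, edgecolors="w")
        ax.set_xticks(np.arange(arr.shape[1]) + 0.5)
        ax.set_xticklabels([f"{o}\n{b}" for o, b in self.frame.columns], fontsize=7)
        ax.set_yticks(np.arange(arr.shape[0]) + 0.5)
        ax.set_yticklabels([f"{p} {f}" for p, f in self.frame.index], fontsize=7)
        ax.invert_yaxis()
        ax.set_title("Plan outcomes (green MET / yellow ACCEPTABLE / red FAIL)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def outcome_matrix(outcomes: Sequence[FractionOutcome]) -> OutcomeMatrix:
    """Cross-tabulate per-fraction clinical and gold tiers per observer."""
    if not outcomes:
        raise ValueError("cannot build an outcome matrix from no outcomes")
    rows = sorted({(o.patient_id, o.fraction_id) for o in outcomes})
    observers = sorted({o.observer_id for o in outcomes})
    cols = pd.MultiIndex.from_tuples(
        [(obs, basis) for obs in observers for basis in ("clinical", "gold")]
    )
    frame = pd.DataFrame(index=pd.MultiIndex.from_tuples(rows), columns=cols, dtype=object)
    for o in outcomes:
        frame.loc[(o.patient_id, o.fraction_id), (o.observer_id, "clinical")] = (
            o.clinical.plan_tier.name
        )
        if o.gold is not None:
            frame.loc[(o.patient_id, o.fraction_id), (o.observer_id, "gold")] = (
                o.gold.plan_tier.name
            )
    return OutcomeMatrix(frame)
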