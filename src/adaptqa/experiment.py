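"""Cohort experiments: phantom simulation wired into the evaluation core.

The default configuration mirrors the study design: 10 pelvic patients
(six conventional 1.8–2 Gy/fraction courses, four short 5 Gy/fraction
courses), 2 adapted fractions each, and a panel of 6 observers (two
physicians, three therapists, one student) with increasing contour-noise
levels.  For each (patient, fraction, observer) cell the pipeline

1. deforms the planning anatomy into the day's truth anatomy,
2. perturbs bladder/bowel with the observer's noise profile,
3. applies the Boolean target rules to the observer's structures,
4. synthesizes the adapted dose (sparing only the observer's contours),
5. evaluates the dose against the observer's structures (clinical) and
   against the truth structures (gold standard).

Everything is deterministic under the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .dosimetry import conformity_index
from .evaluate import (
    ConstraintSpec,
    FractionOutcome,
    PrescriptionSpec,
    TierResult,
    WorkflowSummary,
    aggregate,
    classify,
    default_constraints,
    gold_overlay_eval,
    outcome_matrix,
)
from .grid import VoxelGrid
from .metrics import AnovaResult, PairwiseDSITable, anova_oneway, pairwise_dsi
from .phantom import (
    AnatomyParams,
    DoseModelParams,
    ObserverProfile,
    generate_fraction,
    generate_observer_contours,
    generate_planning_case,
    synthesize_dose,
)
from .rt_io import FractionBundle, read_bundle, write_bundle
from .targets import (
    BOWEL_EVAL_NAME,
    CTVPLAN_NAME,
    PTV_NAME,
    PlanningRuleConfig,
    limit_bowel,
    make_ctvplan,
    make_ptv,
)

log = logging.getLogger("adaptqa")


# ---------------------------------------------------------------------------
# configuration schema (unknown keys are rejected loudly)
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridSpec(_Strict):
    shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (1.5, 1.5, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def build(self) -> VoxelGrid:
        return VoxelGrid(origin=self.origin, spacing=self.spacing, shape=self.shape)


class PatientSpec(_Strict):
    id: str
    dose_per_fraction_gy: float
    n_fractions_total: int

    def prescription(self) -> PrescriptionSpec:
        return PrescriptionSpec(self.dose_per_fraction_gy, self.n_fractions_total)


class ObserverSpec(_Strict):
    id: str
    role: Literal["physician", "therapist", "student"]
    noise_amplitude_mm: float = 0.0
    correlation_length_mm: float = 10.0
    bias_mm: float = 0.0

    def profile(self, seed_offset: int) -> ObserverProfile:
        return ObserverProfile(
            observer_id=self.id,
            noise_amplitude_mm=self.noise_amplitude_mm,
            correlation_length_mm=self.correlation_length_mm,
            bias_mm=self.bias_mm,
            seed_offset=seed_offset,
        )


class RuleSpec(_Strict):
    bladder_trim_depth_mm: float = 3.0
    ptv_margin_mm: float = 3.0
    bowel_cranial_limit_mm: float = 15.0

    def build(self) -> PlanningRuleConfig:
        return PlanningRuleConfig(
            bladder_trim_depth_mm=self.bladder_trim_depth_mm,
            ptv_margin_mm=self.ptv_margin_mm,
            bowel_cranial_limit_mm=self.bowel_cranial_limit_mm,
        )


class DoseSpec(_Strict):
    falloff_scale_mm: float = 8.0
    conformity_bulge_mm: float = 4.0
    noise_amplitude: float = 0.05
    noise_correlation_mm: float = 20.0
    oar_cap_fraction: Optional[float] = 0.93
    oar_cap_margin_mm: float = 2.0


def _default_patients() -> list[PatientSpec]:
    courses = [
        ("P01", 2.0, 25),
        ("P02", 5.0, 5),
        ("P03", 2.0, 28),
        ("P04", 5.0, 5),
        ("P05", 2.0, 29),
        ("P06", 1.8, 25),
        ("P07", 1.8, 25),
        ("P08", 5.0, 3),
        ("P09", 5.0, 5),
        ("P10", 1.8, 25),
    ]
    return [
        PatientSpec(id=i, dose_per_fraction_gy=d, n_fractions_total=n)
        for i, d, n in courses
    ]


def _default_observers() -> list[ObserverSpec]:
    rows = [
        ("D1", "physician", 1.0, 0.0),
        ("D2", "physician", 1.2, 0.0),
        ("T1", "therapist", 1.4, 0.0),
        ("T2", "therapist", 1.6, -0.2),
        ("T3", "therapist", 1.8, 0.0),
        ("S1", "student", 2.2, -0.5),
    ]
    return [
        ObserverSpec(id=i, role=r, noise_amplitude_mm=a, bias_mm=b)
        for i, r, a, b in rows
    ]


class ExperimentConfig(_Strict):
    patients: list[PatientSpec] = Field(default_factory=_default_patients)
    fractions_per_patient: int = 2
    observers: list[ObserverSpec] = Field(default_factory=_default_observers)
    grid: GridSpec = Field(default_factory=GridSpec)
    rules: RuleSpec = Field(default_factory=RuleSpec)
    dose: DoseSpec = Field(default_factory=DoseSpec)
    deformation_amplitude_mm: float = 4.0
    master_seed: int = 1234

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=False)

    def observer_classes(self) -> dict[str, str]:
        return {o.id: o.role for o in self.observers}


def _derived_seed(*parts: int) -> int:
    """Stable sub-seed (< 2**31) from a tuple of integers."""
    state = np.random.SeedSequence(list(parts)).generate_state(1)[0]
    return int(state % (2**31))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class FractionRecord:
    """Gold (truth) bundle plus all observer bundles for one fraction."""

    patient_id: str
    fraction_id: str
    prescription: PrescriptionSpec
    gold: FractionBundle
    observers: dict[str, FractionBundle]


def _adapt_plan(
    observer_bundle: FractionBundle,
    rules: PlanningRuleConfig,
    dose_spec: DoseSpec,
    rx: PrescriptionSpec,
    seed: int,
) -> None:
    """Apply target rules and synthesize the adapted dose, in place."""
    ctv = observer_bundle["ctv"]
    bladder = observer_bundle["bladder"]
    bowel = observer_bundle["bowel"]
    ctvplan = make_ctvplan(ctv, bladder, bowel, rules)
    ptv = make_ptv(ctvplan, rules)
    bowel_eval = limit_bowel(bowel, ctv, rules)
    observer_bundle.add(ctvplan)
    observer_bundle.add(ptv)
    observer_bundle.add(bowel_eval)
    params = DoseModelParams(
        prescription_gy=rx.total_gy,
        falloff_scale_mm=dose_spec.falloff_scale_mm,
        conformity_bulge_mm=dose_spec.conformity_bulge_mm,
        noise_amplitude=dose_spec.noise_amplitude,
        noise_correlation_mm=dose_spec.noise_correlation_mm,
        oar_cap_fraction=dose_spec.oar_cap_fraction,
        oar_cap_margin_mm=dose_spec.oar_cap_margin_mm,
        seed=seed,
    )
    observer_bundle.dose = synthesize_dose(
        ptv, {"bladder": bladder, "bowel": bowel_eval}, params
    )


def simulate_cohort(config: ExperimentConfig) -> list[FractionRecord]:
    """Run the phantom cohort in memory; fully deterministic per config."""
    grid = config.grid.build()
    rules = config.rules.build()
    records: list[FractionRecord] = []
    for p_idx, patient in enumerate(config.patients):
        rx = patient.prescription()
        anatomy = AnatomyParams.sampled(_derived_seed(config.master_seed, p_idx, 0xA))
        planning = generate_planning_case(
            anatomy, grid, patient_id=patient.id, prescription=rx
        )
        for f_idx in range(config.fractions_per_patient):
            fraction_id = f"fx{f_idx + 1}"
            truth = generate_fraction(
                planning,
                config.deformation_amplitude_mm,
                seed=_derived_seed(config.master_seed, p_idx, f_idx, 0xF),
                fraction_id=fraction_id,
            )
            gold = FractionBundle(
                patient_id=patient.id,
                fraction_id=fraction_id,
                observer_id="gold",
                grid=grid,
                prescription=rx,
            )
            for mask in truth.structures.values():
                gold.add(mask.copy())
            gold.add(limit_bowel(truth["bowel"], truth["ctv"], rules))

            observers: dict[str, FractionBundle] = {}
            for o_idx, obs in enumerate(config.observers):
                profile = obs.profile(seed_offset=o_idx)
                bundle = generate_observer_contours(
                    truth,
                    profile,
                    seed=_derived_seed(config.master_seed, p_idx, f_idx, o_idx, 0xC),
                )
                _adapt_plan(
                    bundle,
                    rules,
                    config.dose,
                    rx,
                    seed=_derived_seed(config.master_seed, p_idx, f_idx, o_idx, 0xD),
                )
                observers[obs.id] = bundle
                log.info(
                    "simulated %s %s %s: PTV %.1f cc",
                    patient.id, fraction_id, obs.id,
                    bundle[PTV_NAME].volume_cc,
                )
            records.append(
                FractionRecord(patient.id, fraction_id, rx, gold, observers)
            )
    return records


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    dsi: PairwiseDSITable
    dsi_anova: AnovaResult | None
    ci_table: pd.DataFrame
    ci_values: pd.DataFrame
    outcomes: list[FractionOutcome]
    summary: WorkflowSummary
    matrix: "object"

    def summary_json(self) -> dict:
        return {
            "workflow": self.summary.as_dict(),
            "dsi_anova": (
                None
                if self.dsi_anova is None
                else {
                    "f_statistic": self.dsi_anova.f_statistic,
                    "p_value": self.dsi_anova.p_value,
                    "significant_at_0.05": self.dsi_anova.significant,
                }
            ),
            "mean_ci_by_observer": {
                str(k): float(v) for k, v in self.ci_table["mean"].items()
            },
        }


def evaluate_cohort(
    records: Sequence[FractionRecord],
    observer_classes: dict[str, str] | None = None,
    constraints_override: Sequence[ConstraintSpec] | None = None,
    reference_observer: str | None = None,
    benchmark_observer: str | None = None,
) -> EvalReport:
    """Contour agreement, conformity, tier classification and aggregation."""
    if not records:
        raise ValueError("no fraction records to evaluate")
    observer_ids = list(records[0].observers)
    reference = reference_observer or observer_ids[0]
    benchmark = benchmark_observer or (
        observer_ids[1] if len(observer_ids) > 1 else None
    )

    masks = {
        obs: {
            (r.patient_id, r.fraction_id): {
                "bladder": r.observers[obs]["bladder"],
                "bowel": r.observers[obs][BOWEL_EVAL_NAME],
            }
            for r in records
        }
        for obs in observer_ids
    }
    dsi = pairwise_dsi(masks, reference, ("bladder", "bowel"), benchmark=benchmark)
    groups = [
        g["dsi"].to_numpy() for _, g in dsi.values.groupby("pair", sort=True)
    ]
    # comparing comparison pairs needs at least two of them
    dsi_anova = anova_oneway(groups) if len(groups) >= 2 else None

    ci_records = []
    outcomes: list[FractionOutcome] = []
    for r in records:
        constraints = (
            list(constraints_override)
            if constraints_override is not None
            else default_constraints(r.prescription)
        )
        gold_structs = {
            "bladder": r.gold["bladder"],
            "bowel": r.gold[BOWEL_EVAL_NAME],
        }
        for obs_id, bundle in r.observers.items():
            ci = conformity_index(
                bundle.dose, bundle[PTV_NAME], r.prescription.total_gy
            )
            ci_records.append(
                {
                    "patient": r.patient_id,
                    "fraction": r.fraction_id,
                    "observer": obs_id,
                    "ci": ci,
                }
            )
            clinical = classify(
                bundle.dose,
                {"bladder": bundle["bladder"], "bowel": bundle[BOWEL_EVAL_NAME]},
                constraints,
            )
            gold = gold_overlay_eval(bundle.dose, gold_structs, constraints)
            for res, basis in ((clinical, "clinical"), (gold, "gold")):
                for c in res.results:
                    log.info(
                        "%s %s %s [%s] %s %s = %.2f Gy -> %s",
                        r.patient_id, r.fraction_id, obs_id, basis,
                        c.constraint.structure, c.constraint.metric,
                        c.value_gy, c.tier.name,
                    )
            outcomes.append(
                FractionOutcome(
                    patient_id=r.patient_id,
                    fraction_id=r.fraction_id,
                    observer_id=obs_id,
                    clinical=clinical,
                    gold=gold,
                )
            )

    ci_values = pd.DataFrame.from_records(ci_records)
    ci_table = ci_values.groupby("observer")["ci"].agg(
        mean="mean", sd=lambda x: x.std(ddof=1), n="count"
    )
    summary = aggregate(outcomes, observer_classes)
    return EvalReport(
        dsi=dsi,
        dsi_anova=dsi_anova,
        ci_table=ci_table,
        ci_values=ci_values,
        outcomes=outcomes,
        summary=summary,
        matrix=outcome_matrix(outcomes),
    )


# ---------------------------------------------------------------------------
# disk round-trip (used by the CLI)
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cohort(records: Sequence[FractionRecord], out_dir: str | Path,
                 config: ExperimentConfig | None = None) -> Path:
    """Write every bundle plus a manifest with content digests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for r in records:
        for tag, bundle in [("gold", r.gold), *r.observers.items()]:
            name = f"{r.patient_id}_{r.fraction_id}_{tag}.bundle.zip"
            write_bundle(bundle, out / name)
            entries.append(
                {
                    "path": name,
                    "patient": r.patient_id,
                    "fraction": r.fraction_id,
                    "observer": tag,
                    "dose_per_fraction_gy": r.prescription.dose_per_fraction_gy,
                    "n_fractions_total": r.prescription.n_fractions,
                    "sha256": _sha256(out / name),
                }
            )
    manifest = out / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"bundles": entries}, fh, indent=1)
    if config is not None:
        config.to_yaml(out / "config.yaml")
    return manifest


def read_cohort(in_dir: str | Path) -> list[FractionRecord]:
    """Rebuild fraction records from a bundle directory with a manifest."""
    root = Path(in_dir)
    manifest = root / "manifest.json"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.json in {root}")
    with open(manifest) as fh:
        entries = json.load(fh)["bundles"]
    cells: dict[tuple[str, str], dict] = {}
    for e in entries:
        bundle = read_bundle(root / e["path"])
        key = (e["patient"], e["fraction"])
        cell = cells.setdefault(
            key,
            {
                "rx": PrescriptionSpec(
                    e["dose_per_fraction_gy"], e["n_fractions_total"]
                ),
                "gold": None,
                "observers": {},
            },
        )
        if e["observer"] == "gold":
            cell["gold"] = bundle
        else:
            cell["observers"][e["observer"]] = bundle
    records = []
    for (patient, fraction), cell in sorted(cells.items()):
        if cell["gold"] is None:
            raise FileNotFoundError(
                f"missing gold bundle for {patient} {fraction}"
            )
        records.append(
            FractionRecord(patient, fraction, cell["rx"], cell["gold"], cell["observers"])
        )
    return records


def write_report(report: EvalReport, report_dir: str | Path) -> None:
    out = Path(report_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.dsi.table.to_csv(out / "dsi_pairwise.csv")
    report.dsi.values.to_csv(out / "dsi_values.csv", index=False)
    report.ci_table.to_csv(out / "ci_by_observer.csv")
    report.ci_values.to_csv(out / "ci_values.csv", index=False)
    rows = []
    for o in report.outcomes:
        rows.append(
            {
                "patient": o.patient_id,
                "fraction": o.fraction_id,
                "observer": o.observer_id,
                "clinical_tier": o.clinical.plan_tier.name,
                "gold_tier": o.gold.plan_tier.name if o.gold else None,
                "disposition": o.disposition.value,
                **{
                    f"clinical_{c.constraint.structure}_gy": c.value_gy
                    for c in o.clinical.results
                },
                **(
                    {
                        f"gold_{c.constraint.structure}_gy": c.value_gy
                        for c in o.gold.results
                    }
                    if o.gold
                    else {}
                ),
            }
        )
    pd.DataFrame(rows).to_csv(out / "outcomes.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary_json(), fh, indent=1)
    report.matrix.plot(out / "outcome_heatmap.png")
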