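"""Boolean planning rules: CTV -> CTVplan -> PTV, and the bowel cranial limit.

The clinical protocol derives the planning target automatically from the
physician CTV and the day's organs at risk:

1. the CTV is trimmed so it extends at most 3 mm deep into the bladder;
2. the result is subtracted out of the bowel, giving the CTVplan;
3. the CTVplan is expanded isotropically by 3 mm to give the PTV.

The PTV is *not* re-trimmed against the organs after expansion — it may
re-enter the bladder or bowel by up to the margin, which matters for the
dose these organs then receive.  For evaluation (both contour comparison
and DVH scoring) the bowel is cropped at a superior limit 15 mm cranial to
the CTV's most cranial slice.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .grid import (
    Role,
    StructureMask,
    crop_above,
    expand,
    superior_extent_mm,
    trim_to_depth,
)

#: Reserved names under which derived structures are written into bundles.
CTVPLAN_NAME = "CTVplan"
PTV_NAME = "PTV"
BOWEL_EVAL_NAME = "Bowel_eval"


@dataclass(frozen=True)
class PlanningRuleConfig:
    """Parameters of the Boolean target rules (all in mm, all >= 0).

    The rule order is fixed: bladder depth-trim, then bowel subtraction,
    then PTV expansion.  The config is attached to every derived structure
    for provenance.
    """

    bladder_trim_depth_mm: float = 3.0
    ptv_margin_mm: float = 3.0
    bowel_cranial_limit_mm: float = 15.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")


def make_ctvplan(
    ctv: StructureMask,
    bladder: StructureMask,
    bowel: StructureMask,
    cfg: PlanningRuleConfig = PlanningRuleConfig(),
) -> StructureMask:
    """CTVplan = depth-trim(CTV, bladder) minus bowel.

    The result is a subset of the CTV, reaches at most the configured depth
    into the bladder, and shares no voxel with the bowel.  A CTVplan that
    comes out empty indicates pathological anatomy and raises rather than
    propagating an empty target.
    """
    if ctv.is_empty:
        raise ValueError("CTV is empty")
    ctv.grid.require_compatible(bladder.grid)
    ctv.grid.require_compatible(bowel.grid)
    trimmed = trim_to_depth(ctv, bladder, cfg.bladder_trim_depth_mm)
    result = trimmed.data & ~bowel.data
    if not result.any():
        raise ValueError(
            "CTVplan is empty after applying the Boolean rules; anatomy is "
            "pathological and needs review"
        )
    return StructureMask(
        CTVPLAN_NAME,
        Role.DERIVED,
        ctv.grid,
        result,
        meta={
            "rule_config": asdict(cfg),
            "inputs": [ctv.name, bladder.name, bowel.name],
            "rule_order": ["bladder_depth_trim", "bowel_subtract"],
        },
    )


def make_ptv(
    ctvplan: StructureMask, cfg: PlanningRuleConfig = PlanningRuleConfig()
) -> StructureMask:
    """PTV = CTVplan expanded by the configured margin (no re-trim)."""
    if ctvplan.is_empty:
        raise ValueError("CTVplan is empty")
    ptv = expand(ctvplan, cfg.ptv_margin_mm)
    ptv.name = PTV_NAME
    ptv.role = Role.DERIVED
    ptv.meta = {
        "rule_config": asdict(cfg),
        "inputs": [ctvplan.name],
        "rule_order": ["ptv_expand"],
    }
    return ptv


def limit_bowel(
    bowel: StructureMask,
    ctv: StructureMask,
    cfg: PlanningRuleConfig = PlanningRuleConfig(),
) -> StructureMask:
    """Crop the bowel at the evaluation limit above the CTV.

    Slices whose centre lies more than ``bowel_cranial_limit_mm`` above the
    CTV's most cranial occupied slice are cleared; the limited bowel is
    used for both the contour comparison and DVH evaluation.
    """
    if ctv.is_empty:
        raise ValueError("CTV is empty: bowel cranial limit is undefined")
    bowel.grid.require_compatible(ctv.grid)
    z_limit = superior_extent_mm(ctv) + cfg.bowel_cranial_limit_mm
    out = crop_above(bowel, z_limit)
    out.name = BOWEL_EVAL_NAME
    out.role = Role.DERIVED
    out.meta = {
        "rule_config": asdict(cfg),
        "inputs": [bowel.name, ctv.name],
        "z_limit_mm": z_limit,
    }
    return out
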