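"""Synthetic pelvic phantom: anatomy, daily variation, observer noise, dose.

This module stands in for the study cohort (patients, daily fractions, and
a panel of observers adapting contours) so the whole evaluation pipeline
can run without patient data.  It emulates:

* a planning anatomy — ellipsoidal bladder, a looping bowel tube, and a
  CTV that deliberately penetrates a controlled depth (default 10 mm) into
  the bladder and overlaps the bowel, as pelvic targets are contoured;
* per-fraction anatomical variation — a smooth band-limited random
  displacement field applied to bladder and bowel with a bounded volume
  change, while target contours are copied rigidly to the fraction;
* per-observer contour noise — a Gaussian random field added to the
  structure's signed distance function (amplitude in mm, correlation
  length default 10 mm), plus a systematic margin bias, giving smooth
  over/under-contouring whose expected Dice against truth is controllable
  and calibratable by simulation;
* a conformal dose surrogate — a plateau at prescription inside the PTV,
  a controllable bulge of the 95% isodose beyond the PTV, exponential
  falloff with distance, multiplicative hot/cold noise, and sparing of the
  *observer's* organs at risk via a dose cap inside a small margin around
  them.  The sparing sees only the contours the adapter drew, which is
  exactly how contouring errors translate into unnoticed dose errors on
  the true anatomy.

All generators are deterministic given their seeds; a single seed stream
is split per structure so adding a structure never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .dosimetry import DoseGrid
from .grid import Role, StructureMask, VoxelGrid, expand, interior_depth_mm
from .rt_io import FractionBundle


def default_grid(
    shape: tuple[int, int, int] = (96, 96, 64),
    spacing: tuple[float, float, float] = (1.5, 1.5, 3.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> VoxelGrid:
    """Planning-resolution grid (1.5 x 1.5 x 3 mm) covering a pelvis FOV."""
    return VoxelGrid(origin=origin, spacing=spacing, shape=shape)


# ---------------------------------------------------------------------------
# random-field helpers
# ---------------------------------------------------------------------------

def _smooth_field(
    shape: tuple[int, ...],
    spacing: Sequence[float],
    correlation_mm: float,
    rng: np.random.Generator,
    normalize: str = "std",
) -> np.ndarray:
    """Band-limited Gaussian random field, normalized to unit std or unit max."""
    noise = rng.standard_normal(shape)
    sigma = [max(correlation_mm / s, 0.5) for s in spacing]
    fld = ndimage.gaussian_filter(noise, sigma=sigma)
    scale = fld.std() if normalize == "std" else np.abs(fld).max()
    if scale <= 0:
        return np.zeros(shape)
    return fld / scale


def signed_distance_mm(mask: StructureMask) -> np.ndarray:
    """Signed Euclidean distance (mm): negative inside, positive outside."""
    data = mask.data
    if not data.any():
        raise ValueError(f"structure '{mask.name}' is empty: no distance map")
    outside = ndimage.distance_transform_edt(~data, sampling=mask.grid.spacing)
    inside = ndimage.distance_transform_edt(data, sampling=mask.grid.spacing)
    return outside - inside


# ---------------------------------------------------------------------------
# anatomy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnatomyParams:
    """Geometric parameters (mm) of the phantom pelvis.

    The CTV is built from a base ellipsoid that reaches deep into the
    bladder and is then trimmed back so its maximum depth of penetration
    equals ``ctv_bladder_penetration_mm`` — the same way the clinical
    contouring convention caps the target's extension into the bladder.
    """

    bladder_center: tuple[float, float, float] = (71.0, 50.0, 72.0)
    bladder_semi_axes: tuple[float, float, float] = (33.0, 25.0, 28.0)
    bladder_filling: float = 1.0
    ctv_center: tuple[float, float, float] = (71.0, 86.0, 68.0)
    ctv_semi_axes: tuple[float, float, float] = (26.0, 28.0, 30.0)
    ctv_bladder_penetration_mm: float = 10.0
    bowel_radius_mm: float = 10.0
    bowel_loops: int = 3
    bowel_z_top_mm: float = 165.0
    bowel_clearance_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.bladder_semi_axes + self.ctv_semi_axes):
            raise ValueError("all semi-axes must be > 0")
        if self.bowel_radius_mm <= 0 or self.bladder_filling <= 0:
            raise ValueError("bowel radius and bladder filling must be > 0")
        if self.ctv_bladder_penetration_mm < 0:
            raise ValueError("penetration depth must be >= 0")

    @classmethod
    def sampled(cls, seed: int) -> "AnatomyParams":
        """Per-patient anatomy: defaults jittered by a seeded generator."""
        rng = np.random.default_rng(seed)
        jig = lambda v, lo, hi: tuple(  # noqa: E731
            float(x + rng.uniform(lo, hi)) for x in v
        )
        base = cls()
        return cls(
            bladder_center=jig(base.bladder_center, -4, 4),
            bladder_semi_axes=tuple(
                float(s * rng.uniform(0.9, 1.1)) for s in base.bladder_semi_axes
            ),
            bladder_filling=float(rng.uniform(0.9, 1.1)),
            ctv_center=jig(base.ctv_center, -3, 3),
            ctv_semi_axes=tuple(
                float(s * rng.uniform(0.92, 1.08)) for s in base.ctv_semi_axes
            ),
            bowel_radius_mm=float(base.bowel_radius_mm * rng.uniform(0.9, 1.1)),
            seed=seed,
        )


def _ellipsoid(grid: VoxelGrid, center, semi_axes) -> np.ndarray:
    coords = [
        (grid.axis_coords(a) - center[a]) / semi_axes[a] for a in range(3)
    ]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    return x * x + y * y + z * z <= 1.0


def _bowel_tube(grid: VoxelGrid, params: AnatomyParams) -> np.ndarray:
    """Looping tube descending from the upper abdomen to graze the CTV top."""
    n_ctrl = 6 * params.bowel_loops + 1
    t = np.linspace(0.0, 1.0, n_ctrl)
    cx, cy, _ = params.ctv_center
    path = np.column_stack(
        [
            71.0 + 30.0 * np.sin(2 * np.pi * params.bowel_loops * t),
            95.0 + 10.0 * np.cos(np.pi * params.bowel_loops * t),
            params.bowel_z_top_mm - (params.bowel_z_top_mm - 105.0) * t,
        ]
    )
    # final descent into the CTV's cranial aspect
    tail = np.array([[cx + 2.0, cy + 4.0, 93.0]])
    path = np.vstack([path, tail])
    from scipy.interpolate import make_interp_spline

    s = np.linspace(0.0, 1.0, path.shape[0])
    spline = make_interp_spline(s, path, k=3)
    dense = spline(np.linspace(0.0, 1.0, 600))
    centerline = np.zeros(grid.shape, dtype=bool)
    idx = np.round(
        (dense - np.asarray(grid.origin)) / np.asarray(grid.spacing)
    ).astype(int)
    idx = np.clip(idx, 0, np.asarray(grid.shape) - 1)
    centerline[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    dist = ndimage.distance_transform_edt(~centerline, sampling=grid.spacing)
    return dist <= params.bowel_radius_mm


def _check_clearance(mask: StructureMask, clearance_mm: float = 5.0) -> None:
    grid = mask.grid
    for axis in range(3):
        coords = grid.axis_coords(axis)
        lo = coords[0] + clearance_mm
        hi = coords[-1] - clearance_mm
        proj = mask.data.any(
            axis=tuple(a for a in range(3) if a != axis)
        )
        occupied = coords[proj]
        if occupied.size and (occupied.min() < lo or occupied.max() > hi):
            raise ValueError(
                f"structure '{mask.name}' comes within {clearance_mm} mm of "
                f"the grid boundary on axis {axis}; enlarge the grid"
            )


def generate_planning_case(
    params: AnatomyParams,
    grid: VoxelGrid | None = None,
    patient_id: str = "P01",
    prescription=None,
) -> FractionBundle:
    """Reference-state anatomy bundle: bladder, bowel and CTV masks.

    Guarantees by construction: the CTV's maximum depth of penetration into
    the bladder equals the requested value (up to voxel quantization), and
    bladder and bowel are disjoint.
    """
    grid = grid or default_grid()
    bladder_axes = tuple(
        s * params.bladder_filling for s in params.bladder_semi_axes
    )
    bladder = StructureMask(
        "bladder", Role.OAR, grid, _ellipsoid(grid, params.bladder_center, bladder_axes)
    )
    bowel_data = _bowel_tube(grid, params)
    bowel_data &= ~expand(bladder, params.bowel_clearance_mm).data
    bowel = StructureMask("bowel", Role.OAR, grid, bowel_data)

    ctv_base = _ellipsoid(grid, params.ctv_center, params.ctv_semi_axes)
    depth = interior_depth_mm(bladder)
    too_deep = bladder.data & (depth > params.ctv_bladder_penetration_mm)
    ctv = StructureMask("ctv", Role.TARGET, grid, ctv_base & ~too_deep)
    if ctv.is_empty or bladder.is_empty or bowel.is_empty:
        raise ValueError("degenerate phantom anatomy: an organ came out empty")
    for mask in (bladder, bowel, ctv):
        _check_clearance(mask)

    bundle = FractionBundle(
        patient_id=patient_id,
        fraction_id="planning",
        observer_id="gold",
        grid=grid,
        prescription=prescription,
    )
    for mask in (bladder, bowel, ctv):
        bundle.add(mask)
    return bundle


# ---------------------------------------------------------------------------
# per-fraction variation
# ---------------------------------------------------------------------------

def generate_fraction(
    planning: FractionBundle,
    deformation_amplitude_mm: float,
    seed: int,
    fraction_id: str = "fx1",
    correlation_mm: float = 30.0,
    max_volume_change: float = 0.3,
) -> FractionBundle:
    """Daily anatomy: organs warped smoothly, targets copied rigidly.

    Bladder and bowel are advected through a smooth random displacement
    field whose RMS magnitude equals the requested amplitude; the field is
    damped (never amplified) until each organ's volume change stays within
    ``max_volume_change`` of planning.
    """
    if deformation_amplitude_mm < 0:
        raise ValueError("deformation amplitude must be >= 0")
    grid = planning.grid
    out = FractionBundle(
        patient_id=planning.patient_id,
        fraction_id=fraction_id,
        observer_id=planning.observer_id,
        grid=grid,
        prescription=planning.prescription,
    )
    if deformation_amplitude_mm == 0:
        for name, mask in planning.structures.items():
            out.add(mask.copy())
        return out

    rng_streams = np.random.SeedSequence([int(seed), 0x5EED]).spawn(3)
    disp = np.stack(
        [
            _smooth_field(grid.shape, grid.spacing, correlation_mm,
                          np.random.default_rng(s))
            for s in rng_streams
        ]
    ) * (deformation_amplitude_mm / np.sqrt(3.0))

    base_idx = np.indices(grid.shape, dtype=float)
    spacing = np.asarray(grid.spacing).reshape(3, 1, 1, 1)

    def warp(mask: StructureMask, scale: float) -> np.ndarray:
        coords = base_idx + scale * disp / spacing
        sampled = ndimage.map_coordinates(
            mask.data.astype(np.float32), coords, order=1, mode="constant", cval=0.0
        )
        return sampled >= 0.5

    for name, mask in planning.structures.items():
        if mask.role is Role.TARGET:
            out.add(mask.copy())  # rigid copy, never edited
            continue
        scale = 1.0
        warped = warp(mask, scale)
        for _ in range(20):
            ref = mask.voxel_count
            if ref == 0 or abs(int(warped.sum()) - ref) / ref <= max_volume_change:
                break
            scale *= 0.8
            warped = warp(mask, scale)
        out.add(StructureMask(name, mask.role, grid, warped, meta=dict(mask.meta)))

    # organs may not interpenetrate after warping
    if "bladder" in out.structures and "bowel" in out.structures:
        out.structures["bowel"].data &= ~out.structures["bladder"].data
    return out


# ---------------------------------------------------------------------------
# observer contour noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverProfile:
    """Contouring-variation model for one observer.

    ``noise_amplitude_mm`` is the standard deviation of a correlated
    boundary displacement field; ``bias_mm`` shifts the whole boundary
    outward (positive, over-contouring) or inward (negative).  Zero
    amplitude and zero bias reproduce the reference contour exactly.
    """

    observer_id: str
    noise_amplitude_mm: float = 0.0
    correlation_length_mm: float = 10.0
    bias_mm: float = 0.0
    seed_offset: int = 0

    def __post_init__(self) -> None:
        if self.noise_amplitude_mm < 0 or self.correlation_length_mm <= 0:
            raise ValueError("noise amplitude >= 0 and correlation length > 0")


def perturb_mask(
    mask: StructureMask,
    amplitude_mm: float,
    correlation_mm: float,
    bias_mm: float,
    rng: np.random.Generator,
) -> StructureMask:
    """One noisy re-contour: threshold the SDF at a random smooth level set."""
    if amplitude_mm == 0 and bias_mm == 0:
        return mask.copy()
    sdf = signed_distance_mm(mask)
    level = bias_mm
    if amplitude_mm > 0:
        level = bias_mm + amplitude_mm * _smooth_field(
            mask.grid.shape, mask.grid.spacing, correlation_mm, rng
        )
    out = mask.copy()
    out.data = sdf <= level
    return out


def generate_observer_contours(
    truth: FractionBundle,
    profile: ObserverProfile,
    structures: Sequence[str] = ("bladder", "bowel"),
    seed: int = 0,
) -> FractionBundle:
    """Perturbed bladder/bowel contours for one observer on one fraction.

    Targets (and any structure not listed) are copied unchanged — target
    contours are rigidly transferred, not edited, in the workflow.
    """
    for s in structures:
        if s not in truth.structures:
            raise KeyError(
                f"structure '{s}' not present in the truth bundle "
                f"(has {sorted(truth.structures)})"
            )
    out = FractionBundle(
        patient_id=truth.patient_id,
        fraction_id=truth.fraction_id,
        observer_id=profile.observer_id,
        grid=truth.grid,
        prescription=truth.prescription,
    )
    for i, (name, mask) in enumerate(truth.structures.items()):
        if name in structures:
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), int(profile.seed_offset), i])
            )
            out.add(
                perturb_mask(
                    mask,
                    profile.noise_amplitude_mm,
                    profile.correlation_length_mm,
                    profile.bias_mm,
                    rng,
                )
            )
        else:
            out.add(mask.copy())
    return out


def calibrate_noise_amplitude(
    truth_mask: StructureMask,
    target_dice: float,
    correlation_mm: float = 10.0,
    bias_mm: float = 0.0,
    amplitudes: Sequence[float] | None = None,
    n_reps: int = 8,
    seed: int = 0,
) -> float:
    """Amplitude whose expected Dice against truth equals ``target_dice``.

    Monte-Carlo calibration: the mean Dice is estimated at a ladder of
    amplitudes (expected Dice is monotone non-increasing in amplitude) and
    the target is inverted by linear interpolation.
    """
    from .metrics import dice

    if not 0 < target_dice <= 1:
        raise ValueError("target Dice must be in (0, 1]")
    if target_dice == 1.0:
        return 0.0
    amps = np.asarray(
        amplitudes if amplitudes is not None else [0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4]
    )
    sdf = signed_distance_mm(truth_mask)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCAB]))
    ref_count = truth_mask.voxel_count
    mean_dice = np.empty(amps.size)
    probe = truth_mask.copy()
    for i, a in enumerate(amps):
        vals = []
        for _ in range(n_reps):
            level = bias_mm + a * _smooth_field(
                truth_mask.grid.shape, truth_mask.grid.spacing, correlation_mm, rng
            )
            probe.data = sdf <= level
            vals.append(dice(truth_mask, probe))
        mean_dice[i] = float(np.mean(vals))
    order = np.argsort(mean_dice)
    return float(np.interp(target_dice, mean_dice[order], amps[order]))


# ---------------------------------------------------------------------------
# dose surrogate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseModelParams:
    """Conformal dose surrogate parameters.

    The dose plateaus at prescription inside the PTV, crosses 95% of
    prescription ``conformity_bulge_mm`` outside it (the knob governing
    conformity: the 95% isodose surface is the PTV expanded by the bulge),
    then falls off exponentially with Euclidean distance on the scale
    ``falloff_scale_mm``.  ``noise_amplitude`` adds bounded multiplicative
    hot/cold spots.  ``oar_cap_fraction`` emulates optimizer sparing: dose
    inside each supplied OAR (plus ``oar_cap_margin_mm`` of penumbra) is
    capped at that fraction of prescription.  There is no beam physics.
    """

    prescription_gy: float
    falloff_scale_mm: float = 8.0
    conformity_bulge_mm: float = 4.0
    noise_amplitude: float = 0.05
    noise_correlation_mm: float = 20.0
    oar_cap_fraction: float | None = 0.93
    oar_cap_margin_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be > 0 Gy")
        if self.conformity_bulge_mm < 0 or self.falloff_scale_mm <= 0:
            raise ValueError("bulge >= 0 and falloff scale > 0 required")
        if not 0 <= self.noise_amplitude < 1:
            raise ValueError("noise amplitude must be in [0, 1)")

    @classmethod
    def ideal(cls, prescription_gy: float, seed: int = 0) -> "DoseModelParams":
        """Noise-free, tightly conformal settings (no OAR cap)."""
        return cls(
            prescription_gy=prescription_gy,
            conformity_bulge_mm=0.5,
            noise_amplitude=0.0,
            oar_cap_fraction=None,
            seed=seed,
        )


def synthesize_dose(
    ptv: StructureMask,
    oars: Mapping[str, StructureMask] | Sequence[StructureMask] = (),
    params: DoseModelParams | None = None,
) -> DoseGrid:
    """Deterministic conformal dose surrogate around a PTV.

    The OARs passed in should be the *adapter's own* evaluated organ masks:
    the surrogate, like a real optimizer, spares only what was contoured.
    """
    if params is None:
        raise ValueError("DoseModelParams required (prescription is mandatory)")
    if ptv.is_empty:
        raise ValueError("PTV is empty: cannot synthesize dose")
    grid = ptv.grid
    rx = params.prescription_gy
    dist = ndimage.distance_transform_edt(~ptv.data, sampling=grid.spacing)

    dose = np.empty(grid.shape, dtype=float)
    bulge = params.conformity_bulge_mm
    inside = dist == 0
    dose[inside] = rx
    outside = ~inside
    if bulge > 0:
        ramp = outside & (dist <= bulge)
        dose[ramp] = rx * (1.0 - 0.05 * dist[ramp] / bulge)
        tail = outside & (dist > bulge)
    else:
        tail = outside
    dose[tail] = 0.95 * rx * np.exp(-(dist[tail] - bulge) / params.falloff_scale_mm)

    if params.noise_amplitude > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 0xD05E]))
        fld = _smooth_field(
            grid.shape, grid.spacing, params.noise_correlation_mm, rng,
            normalize="max",
        )
        dose *= 1.0 + params.noise_amplitude * fld

    if params.oar_cap_fraction is not None:
        cap = params.oar_cap_fraction * rx
        masks = oars.values() if isinstance(oars, Mapping) else oars
        for oar in masks:
            grid.require_compatible(oar.grid)
            region = expand(oar, params.oar_cap_margin_mm).data
            np.minimum(dose, cap, out=dose, where=region)

    return DoseGrid(grid, np.clip(dose, 0.0, None))
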