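"""DVH engine and scalar dose metrics.

Implements the metrics used for plan evaluation: mean and maximum dose,
dose to the hottest x% of a structure's volume (Dx%), dose to the hottest
v cc (D(v cc)), cumulative dose-volume histograms, and the RTOG conformity
index CI = V_RI / V_PTV with the reference isodose at 95% of prescription.

Volume-indexed metrics use the sorted voxel doses with each voxel's volume
centred at its cumulative position (midpoint convention) and linear
interpolation between voxels; no sub-voxel partial-volume model is applied.
Scalar metrics are computed from raw voxel doses, never from the binned DVH.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .grid import StructureMask, VoxelGrid


class MetricSpecError(ValueError):
    """Raised for an unparseable or out-of-range dose-metric request."""


@dataclass
class DoseGrid:
    """Scalar absorbed dose (Gy) on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"dose array shape {self.data.shape} does not match grid "
                f"shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("dose values must be finite")
        if np.any(self.data < 0):
            raise ValueError("dose values must be >= 0 Gy")


@dataclass(frozen=True)
class MetricSpec:
    """Parsed dosimetric metric: Dmean, Dmax, D<x>% or D<v>cc."""

    kind: str  # "mean" | "max" | "pct" | "cc"
    value: float | None = None

    def __str__(self) -> str:
        if self.kind == "mean":
            return "Dmean"
        if self.kind == "max":
            return "Dmax"
        if self.kind == "pct":
            return f"D{self.value:g}%"
        return f"D{self.value:g}cc"


_METRIC_RE = re.compile(r"^d\s*(?:(mean)|(max)|([0-9.]+)\s*(%|cc))$")


def parse_metric(spec: str) -> MetricSpec:
    """Parse the metric mini-grammar: "Dmean", "Dmax", "D95%", "D0.03cc"."""
    m = _METRIC_RE.match(spec.strip().lower())
    if not m:
        raise MetricSpecError(f"unrecognized dose metric spec: {spec!r}")
    if m.group(1):
        return MetricSpec("mean")
    if m.group(2):
        return MetricSpec("max")
    value = float(m.group(3))
    if m.group(4) == "%":
        if not 0 < value <= 100:
            raise MetricSpecError(f"Dx% requires x in (0, 100], got {value}")
        return MetricSpec("pct", value)
    if value <= 0:
        raise MetricSpecError(f"D(v cc) requires v > 0, got {value}")
    return MetricSpec("cc", value)


def _structure_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    dose.grid.require_compatible(mask.grid)
    if mask.is_empty:
        raise ValueError(f"structure '{mask.name}' is empty: no dose metrics")
    return dose.data[mask.data]


def _dose_at_volume(values: np.ndarray, v_cc: float, voxel_cc: float) -> float:
    """Minimum dose received by the hottest ``v_cc`` of the sampled volume.

    Sorted-descending voxel doses are placed at cumulative volumes
    (i + 0.5) * voxel_cc and linearly interpolated; requests hotter than
    half a voxel clamp to Dmax, requests beyond the last midpoint clamp to
    the minimum voxel dose.
    """
    total = values.size * voxel_cc
    if v_cc > total + 1e-12:
        raise MetricSpecError(
            f"requested volume {v_cc} cc exceeds structure volume {total} cc"
        )
    desc = np.sort(values)[::-1]
    centres = (np.arange(desc.size) + 0.5) * voxel_cc
    return float(np.interp(v_cc, centres, desc))


def dose_metric(dose: DoseGrid, mask: StructureMask, spec: str | MetricSpec) -> float:
    """Evaluate one scalar dose metric (Gy) for a structure."""
    if isinstance(spec, str):
        spec = parse_metric(spec)
    values = _structure_doses(dose, mask)
    if spec.kind == "mean":
        return float(values.mean())
    if spec.kind == "max":
        return float(values.max())
    voxel_cc = mask.grid.voxel_volume_cc
    if spec.kind == "pct":
        v_cc = spec.value / 100.0 * values.size * voxel_cc
        return _dose_at_volume(values, v_cc, voxel_cc)
    return _dose_at_volume(values, spec.value, voxel_cc)


@dataclass
class CumulativeDVH:
    """Cumulative dose-volume histogram on uniform dose bins.

    ``volume_cc[j]`` is the structure volume receiving at least
    ``bin_edges_gy[j]``; the first entry equals the total structure volume
    and the curve is monotone non-increasing.
    """

    structure: str
    bin_edges_gy: np.ndarray
    volume_cc: np.ndarray
    total_volume_cc: float

    def volume_at_dose(self, dose_gy: float) -> float:
        """Binned volume (cc) receiving at least ``dose_gy``."""
        idx = np.searchsorted(self.bin_edges_gy, dose_gy, side="right") - 1
        if idx < 0:
            return float(self.total_volume_cc)
        if idx >= self.volume_cc.size:
            return 0.0
        return float(self.volume_cc[idx])

    def mean_dose_gy(self) -> float:
        """Bin-weighted mean dose (differential re-binning of the curve)."""
        diff = -np.diff(np.append(self.volume_cc, 0.0))
        centres = self.bin_edges_gy + 0.5 * (self.bin_edges_gy[1] - self.bin_edges_gy[0])
        return float((diff * centres).sum() / self.total_volume_cc)


def dvh(dose: DoseGrid, mask: StructureMask, bin_width_gy: float = 0.1) -> CumulativeDVH:
    """Cumulative DVH from the multiset of voxel doses inside the mask."""
    if bin_width_gy <= 0:
        raise ValueError("bin width must be > 0 Gy")
    values = _structure_doses(dose, mask)
    voxel_cc = mask.grid.voxel_volume_cc
    n_bins = int(np.floor(values.max() / bin_width_gy)) + 2
    edges = np.arange(n_bins) * bin_width_gy
    counts = (values[None, :] >= edges[:, None]).sum(axis=1)
    return CumulativeDVH(
        structure=mask.name,
        bin_edges_gy=edges,
        volume_cc=counts * voxel_cc,
        total_volume_cc=values.size * voxel_cc,
    )


def conformity_index(
    dose: DoseGrid, ptv: StructureMask, prescription_gy: float
) -> float:
    """RTOG conformity index: V_RI / V_PTV.

    V_RI is the total volume — anywhere in the dose grid, not only inside
    the PTV or a body contour — receiving at least 95% of prescription
    (inclusive threshold).  Values above 1 indicate dose spilling beyond
    the target; the ratio is inflated accordingly when dose spills into
    unsegmented tissue.
    """
    dose.grid.require_compatible(ptv.grid)
    if prescription_gy <= 0:
        raise ValueError("prescription must be > 0 Gy")
    if ptv.is_empty:
        raise ValueError("PTV is empty: conformity index undefined")
    v_ri = float((dose.data >= 0.95 * prescription_gy).sum()) * dose.grid.voxel_volume_cc
    return v_ri / ptv.volume_cc
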