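"""Radiotherapy format adapters and the portable fraction bundle.

Two input paths exist: standard DICOM (RT Structure Set contours, RT Dose
grids) and an internal *fraction bundle* archive, so the rest of the
pipeline is format-agnostic.  A bundle is one zip archive holding a JSON
metadata document (grid geometry, structure names and roles, prescription,
schema version) plus one ``.npy`` array per structure mask and optionally
one for the dose grid.  Round-trips are lossless: masks bit-exact, dose to
float64 precision, metadata exact.

DICOM here is an adapter, not the core path; only axis-aligned geometry
(identity direction cosines) is accepted, and nothing is ever resampled.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pydicom

from .evaluate import PrescriptionSpec
from .dosimetry import DoseGrid
from .grid import GridCompatibilityError, Role, SlicePolygonSet, StructureMask, VoxelGrid

BUNDLE_SCHEMA_VERSION = "1"

#: Default case-insensitive aliases mapping exported ROI names onto the
#: canonical structure names the pipeline uses.
DEFAULT_NAME_ALIASES: dict[str, str] = {
    "bladder": "bladder",
    "bladder_full": "bladder",
    "urinary bladder": "bladder",
    "bowel": "bowel",
    "bowel_loops": "bowel",
    "bowel bag": "bowel",
    "smallbowel": "bowel",
    "ctv": "ctv",
}


class BundleFormatError(ValueError):
    """Raised for corrupt, truncated, or unsupported bundle archives."""


class DicomFormatError(ValueError):
    """Raised when a DICOM file does not match the expected modality/layout."""


def canonical_name(roi_name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Map an exported ROI name to its canonical pipeline name.

    Matching is case-insensitive; unknown names pass through lowercased.
    """
    table = DEFAULT_NAME_ALIASES if aliases is None else aliases
    return table.get(roi_name.strip().lower(), roi_name.strip().lower())


@dataclass
class FractionBundle:
    """All per-fraction data for one (patient, fraction, observer) cell."""

    patient_id: str
    fraction_id: str
    observer_id: str
    grid: VoxelGrid
    structures: dict[str, StructureMask] = field(default_factory=dict)
    dose: DoseGrid | None = None
    prescription: PrescriptionSpec | None = None

    def __post_init__(self) -> None:
        names = list(self.structures)
        if len(set(names)) != len(names):
            raise ValueError("structure names must be unique within a bundle")
        for mask in self.structures.values():
            self.grid.require_compatible(mask.grid)
        if self.dose is not None:
            self.grid.require_compatible(self.dose.grid)

    def add(self, mask: StructureMask) -> None:
        self.grid.require_compatible(mask.grid)
        if mask.name in self.structures:
            raise ValueError(f"duplicate structure name '{mask.name}'")
        self.structures[mask.name] = mask

    def __getitem__(self, name: str) -> StructureMask:
        return self.structures[name]


# ---------------------------------------------------------------------------
# Internal bundle archive
# ---------------------------------------------------------------------------

def write_bundle(bundle: FractionBundle, path: str | Path) -> None:
    """Write a bundle as a zip archive (JSON metadata + npy arrays)."""
    meta = {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "patient_id": bundle.patient_id,
        "fraction_id": bundle.fraction_id,
        "observer_id": bundle.observer_id,
        "grid": {
            "origin": list(bundle.grid.origin),
            "spacing": list(bundle.grid.spacing),
            "shape": list(bundle.grid.shape),
        },
        "structures": [
            {"name": m.name, "role": m.role.value, "meta": m.meta}
            for m in bundle.structures.values()
        ],
        "has_dose": bundle.dose is not None,
        "prescription": (
            None
            if bundle.prescription is None
            else {
                "dose_per_fraction_gy": bundle.prescription.dose_per_fraction_gy,
                "n_fractions": bundle.prescription.n_fractions,
            }
        ),
    }
    def _entry(name: str) -> zipfile.ZipInfo:
        # fixed timestamp so identical bundles are byte-identical on disk
        info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
        info.compress_type = zipfile.ZIP_DEFLATED
        return info

    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr(_entry("meta.json"), json.dumps(meta, indent=1))
        for i, mask in enumerate(bundle.structures.values()):
            buf = io.BytesIO()
            np.save(buf, np.packbits(mask.data))
            zf.writestr(_entry(f"masks/{i:03d}.npy"), buf.getvalue())
        if bundle.dose is not None:
            buf = io.BytesIO()
            np.save(buf, bundle.dose.data.astype(np.float64))
            zf.writestr(_entry("dose.npy"), buf.getvalue())


def read_bundle(path: str | Path) -> FractionBundle:
    """Read a bundle archive; raises :class:`BundleFormatError` on damage."""
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            version = meta.get("schema_version")
            if version != BUNDLE_SCHEMA_VERSION:
                raise BundleFormatError(
                    f"unsupported bundle schema version {version!r} "
                    f"(supported: {BUNDLE_SCHEMA_VERSION!r})"
                )
            grid = VoxelGrid(
                origin=tuple(meta["grid"]["origin"]),
                spacing=tuple(meta["grid"]["spacing"]),
                shape=tuple(meta["grid"]["shape"]),
            )
            n_vox = int(np.prod(grid.shape))
            structures: dict[str, StructureMask] = {}
            for i, entry in enumerate(meta["structures"]):
                packed = np.load(io.BytesIO(zf.read(f"masks/{i:03d}.npy")))
                data = np.unpackbits(packed, count=n_vox).reshape(grid.shape)
                structures[entry["name"]] = StructureMask(
                    entry["name"],
                    Role(entry["role"]),
                    grid,
                    data.astype(bool),
                    meta=entry.get("meta", {}),
                )
            dose = None
            if meta["has_dose"]:
                dose = DoseGrid(grid, np.load(io.BytesIO(zf.read("dose.npy"))))
            rx = None
            if meta.get("prescription"):
                rx = PrescriptionSpec(
                    dose_per_fraction_gy=meta["prescription"]["dose_per_fraction_gy"],
                    n_fractions=meta["prescription"]["n_fractions"],
                )
    except BundleFormatError:
        raise
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, ValueError, OSError) as exc:
        raise BundleFormatError(f"corrupt or partial bundle at {path}: {exc}") from exc
    return FractionBundle(
        patient_id=meta["patient_id"],
        fraction_id=meta["fraction_id"],
        observer_id=meta["observer_id"],
        grid=grid,
        structures=structures,
        dose=dose,
        prescription=rx,
    )


# ---------------------------------------------------------------------------
# DICOM adapters
# ---------------------------------------------------------------------------

def read_rtstruct(path: str | Path) -> dict[str, SlicePolygonSet]:
    """Read a DICOM RT Structure Set into per-ROI slice polygon sets.

    ROI names are preserved verbatim as keys; contour coordinates are kept
    in patient millimetres.  Only CLOSED_PLANAR contours are supported.
    """
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise DicomFormatError(
            f"expected RTSTRUCT modality, got {getattr(ds, 'Modality', None)!r}"
        )
    names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in getattr(ds, "StructureSetROISequence", [])
    }
    out: dict[str, SlicePolygonSet] = {}
    for roi_contour in getattr(ds, "ROIContourSequence", []):
        number = int(roi_contour.ReferencedROINumber)
        name = names.get(number, f"ROI_{number}")
        if "ContourSequence" not in roi_contour:
            raise DicomFormatError(f"ROI '{name}' has no contour sequence")
        slices: dict[float, list[np.ndarray]] = {}
        for contour in roi_contour.ContourSequence:
            gtype = getattr(contour, "ContourGeometricType", "CLOSED_PLANAR")
            if gtype != "CLOSED_PLANAR":
                raise DicomFormatError(
                    f"ROI '{name}' has unsupported contour type {gtype!r}"
                )
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            z = float(pts[0, 2])
            slices.setdefault(z, []).append(pts[:, :2])
        out[name] = SlicePolygonSet(name=name, slices=slices)
    return out


def read_rtdose(path: str | Path, grid: VoxelGrid) -> DoseGrid:
    """Read a DICOM RT Dose file onto an expected grid (no resampling).

    Stored pixel values are scaled by DoseGridScaling into Gy.  The dose
    geometry (origin, pixel spacing, frame offsets, shape) must match
    ``grid`` exactly; a mismatch raises with both geometries printed.
    """
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise DicomFormatError(
            f"expected RTDOSE modality, got {getattr(ds, 'Modality', None)!r}"
        )
    ipp = [float(v) for v in ds.ImagePositionPatient]
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)  # (y, x) spacing
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(offsets[1] - offsets[0]) if offsets.size > 1 else grid.spacing[2]
    if offsets.size > 1 and not np.allclose(np.diff(offsets), dz):
        raise DicomFormatError("non-uniform GridFrameOffsetVector is unsupported")
    # pixel_array is (frames, rows, cols) == (z, y, x)
    raw = ds.pixel_array.astype(np.float64) * float(ds.DoseGridScaling)
    found = VoxelGrid(
        origin=(ipp[0], ipp[1], ipp[2] + float(offsets[0])),
        spacing=(col_sp, row_sp, dz),
        shape=(raw.shape[2], raw.shape[1], raw.shape[0]),
    )
    if not found.compatible_with(grid):
        raise GridCompatibilityError(
            f"RT Dose geometry does not match the expected grid:\n"
            f"  file:     {found}\n  expected: {grid}"
        )
    return DoseGrid(grid, np.ascontiguousarray(raw.transpose(2, 1, 0)))
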