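"""AHA 16-segment model on short-axis left-ventricular stacks.

The left-ventricular myocardium is divided into 6 basal, 6 mid-cavity and 4
apical segments (the apex cap is not modelled).  On each short-axis slice
the wall voxels are binned by polar angle about the LV centre into equal
sectors; sector boundaries start at the anterior interventricular groove
(whose angle the stack records) and proceed counterclockwise as viewed from
the apex.  Labels are 1-6 (basal), 7-12 (mid), 13-16 (apical).

The wall is further split into an endocardial (inner) and epicardial (outer)
layer at a configurable normalized transmural depth, and per-segment ROI
statistics (mean attenuation, enhancement over a pre-contrast stack) are
measured over whole layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib

from .errors import GeometryError, InputError

__all__ = [
    "LEVELS",
    "SEGMENTS_PER_LEVEL",
    "LEVEL_LABEL_OFFSET",
    "ShortAxisStack",
    "SegmentMap",
    "SegmentRecord",
    "build_segment_map",
    "split_layers",
    "measure_segments",
    "records_to_frame",
    "save_stack",
    "load_stack",
]

LEVELS = ("basal", "mid", "apical")
SEGMENTS_PER_LEVEL = {"basal": 6, "mid": 6, "apical": 4}
LEVEL_LABEL_OFFSET = {"basal": 0, "mid": 6, "apical": 12}


@dataclass
class ShortAxisStack:
    """Short-axis LV image stack with wall masks and geometry.

    Attributes
    ----------
    voxels : float array, shape (n_slices, n_rows, n_cols)
        HU values.
    wall_mask : bool array, same shape
        True on myocardial-wall voxels.
    lv_center : float array, shape (n_slices, 2)
        (row, col) of the LV centre on each slice.
    slice_thickness_mm : float
    level_assignment : tuple of str
        One of ``"basal" | "mid" | "apical"`` per slice.
    groove_angle_rad : float
        Angle of the anterior interventricular groove, the origin of the
        segment sector boundaries.
    """

    voxels: np.ndarray
    wall_mask: np.ndarray
    lv_center: np.ndarray
    slice_thickness_mm: float
    level_assignment: tuple
    groove_angle_rad: float = 0.0

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.wall_mask = np.asarray(self.wall_mask, dtype=bool)
        self.lv_center = np.asarray(self.lv_center, dtype=float)
        if self.voxels.ndim != 3:
            raise GeometryError("voxels must be a 3-D (slice, row, col) grid")
        if self.wall_mask.shape != self.voxels.shape:
            raise GeometryError("wall_mask shape must match voxels")
        if self.lv_center.shape != (self.voxels.shape[0], 2):
            raise GeometryError("lv_center must give (row, col) per slice")
        if self.slice_thickness_mm <= 0:
            raise GeometryError("slice_thickness_mm must be positive")
        self.level_assignment = tuple(self.level_assignment)
        if len(self.level_assignment) != self.voxels.shape[0]:
            raise GeometryError("level_assignment must have one entry per slice")
        unknown = set(self.level_assignment) - set(LEVELS)
        if unknown:
            raise GeometryError(f"unknown slice levels: {sorted(unknown)}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass(frozen=True)
class SegmentMap:
    """Integer label grid: 0 = background, 1..16 = AHA segment."""

    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3 or not np.issubdtype(labels.dtype, np.integer):
            raise GeometryError("labels must be a 3-D integer grid")
        object.__setattr__(self, "labels", labels)


@dataclass(frozen=True)
class SegmentRecord:
    """Per-segment layer attenuations and enhancement."""

    segment_id: int
    endo_attenuation: float
    epi_attenuation: float
    endo_enhancement: float
    n_voxels_endo: int
    n_voxels_epi: int


def _polar(stack: ShortAxisStack, s: int):
    """Radius and angle (from the groove, counterclockwise) of slice voxels."""
    n_rows, n_cols = stack.voxels.shape[1:]
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    dy = rows - stack.lv_center[s, 0]
    dx = cols - stack.lv_center[s, 1]
    radius = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(dy, dx) - stack.groove_angle_rad, 2 * np.pi)
    return radius, theta


def build_segment_map(stack: ShortAxisStack) -> SegmentMap:
    """Bin wall voxels into AHA segments by polar angle about the LV centre.

    Each slice's wall is split into 6 (basal, mid) or 4 (apical) equal
    angular sectors; nonzero labels exactly cover the wall mask.
    """
    labels = np.zeros(stack.voxels.shape, dtype=np.int16)
    for s in range(stack.n_slices):
        mask = stack.wall_mask[s]
        if not mask.any():
            raise GeometryError(f"slice {s} has an empty wall mask")
        level = stack.level_assignment[s]
        n_sectors = SEGMENTS_PER_LEVEL[level]
        offset = LEVEL_LABEL_OFFSET[level]
        _, theta = _polar(stack, s)
        sector = np.floor(theta / (2 * np.pi / n_sectors)).astype(np.int16)
        sector = np.clip(sector, 0, n_sectors - 1)  # guard theta == 2*pi
        labels[s][mask] = offset + sector[mask] + 1
    return SegmentMap(labels=labels)


def transmural_depth(stack: ShortAxisStack) -> np.ndarray:
    """Normalized radial depth of every wall voxel, 0 at the endocardial
    border, 1 at the epicardial border; NaN off the wall.

    The borders are taken per slice as the min/max radius of masked voxels.
    """
    depth = np.full(stack.voxels.shape, np.nan)
    for s in range(stack.n_slices):
        mask = stack.wall_mask[s]
        if not mask.any():
            raise GeometryError(f"slice {s} has an empty wall mask")
        radius, _ = _polar(stack, s)
        r = radius[mask]
        r_endo, r_epi = r.min(), r.max()
        if r_epi - r_endo < 1.0:
            raise GeometryError(f"slice {s}: wall thinner than 2 voxels")
        depth[s][mask] = (radius[mask] - r_endo) / (r_epi - r_endo)
    return depth


def split_layers(
    stack: ShortAxisStack,
    segment_map: SegmentMap,
    endo_fraction: float = 0.5,
):
    """Partition the wall into endocardial and epicardial layers.

    A wall voxel is endocardial when its normalized transmural depth is
    below ``endo_fraction``; the two masks partition the wall exactly.
    """
    if not 0.0 < endo_fraction < 1.0:
        raise InputError("endo_fraction must be in (0, 1)")
    depth = transmural_depth(stack)
    endo = stack.wall_mask & (depth < endo_fraction)
    epi = stack.wall_mask & ~endo
    return endo, epi


def measure_segments(
    static_stack: ShortAxisStack,
    baseline_stack: ShortAxisStack,
    segment_map: SegmentMap,
    layers,
) -> list[SegmentRecord]:
    """Mean layer attenuation per segment, plus enhancement over baseline.

    ``endo_enhancement`` is the endocardial mean in the static (contrast)
    stack minus the mean of the same voxels in the pre-contrast stack.
    """
    if static_stack.voxels.shape != baseline_stack.voxels.shape:
        raise InputError("static and baseline stacks must share geometry")
    if segment_map.labels.shape != static_stack.voxels.shape:
        raise InputError("segment map must share the stack geometry")
    endo_mask, epi_mask = layers
    records = []
    for seg_id in range(1, 17):
        in_seg = segment_map.labels == seg_id
        endo = in_seg & endo_mask
        epi = in_seg & epi_mask
        n_endo, n_epi = int(endo.sum()), int(epi.sum())
        if n_endo == 0 or n_epi == 0:
            raise GeometryError(f"segment {seg_id} has an empty layer ROI")
        endo_hu = float(static_stack.voxels[endo].mean())
        epi_hu = float(static_stack.voxels[epi].mean())
        endo_enh = endo_hu - float(baseline_stack.voxels[endo].mean())
        records.append(
            SegmentRecord(
                segment_id=seg_id,
                endo_attenuation=endo_hu,
                epi_attenuation=epi_hu,
                endo_enhancement=endo_enh,
                n_voxels_endo=n_endo,
                n_voxels_epi=n_epi,
            )
        )
    return records


def records_to_frame(records, patient_id: str) -> pd.DataFrame:
    """Segment records as a table with stable column names."""
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "segment_id": [r.segment_id for r in records],
            "endo_hu": [r.endo_attenuation for r in records],
            "epi_hu": [r.epi_attenuation for r in records],
            "endo_enh_hu": [r.endo_enhancement for r in records],
            "n_endo": [r.n_voxels_endo for r in records],
            "n_epi": [r.n_voxels_epi for r in records],
        }
    )


# --- NIfTI persistence ------------------------------------------------------
# The voxel grid is stored with the slice axis last (x, y, z convention) and
# the slice thickness in the header zooms; stack metadata that NIfTI cannot
# carry (centres, levels, groove angle) goes to a JSON sidecar.

def save_stack(stack: ShortAxisStack, path, compress: bool = False) -> Path:
    path = Path(path)
    if path.suffix not in {".nii", ".gz"}:
        path = path.with_suffix(".nii.gz" if compress else ".nii")
    data = np.transpose(stack.voxels, (1, 2, 0)).astype(np.float32)
    affine = np.diag([1.0, 1.0, stack.slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((1.0, 1.0, stack.slice_thickness_mm))
    nib.save(img, str(path))
    sidecar = {
        "lv_center": stack.lv_center.tolist(),
        "level_assignment": list(stack.level_assignment),
        "groove_angle_rad": stack.groove_angle_rad,
        "wall_mask_rle": _encode_mask(stack.wall_mask),
        "shape": list(stack.voxels.shape),
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def load_stack(path) -> ShortAxisStack:
    path = Path(path)
    img = nib.load(str(path))
    voxels = np.transpose(np.asarray(img.dataobj, dtype=float), (2, 0, 1))
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    mask = _decode_mask(meta["wall_mask_rle"], tuple(meta["shape"]))
    return ShortAxisStack(
        voxels=voxels,
        wall_mask=mask,
        lv_center=np.asarray(meta["lv_center"], dtype=float),
        slice_thickness_mm=float(img.header.get_zooms()[2]),
        level_assignment=tuple(meta["level_assignment"]),
        groove_angle_rad=float(meta["groove_angle_rad"]),
    )


def _encode_mask(mask: np.ndarray) -> list:
    """Run-length encode a boolean grid (flat, starts with a False run)."""
    flat = mask.ravel()
    changes = np.flatnonzero(np.diff(flat)) + 1
    runs = np.diff(np.concatenate(([0], changes, [flat.size])))
    lead = [] if flat[0] == False else [0]  # noqa: E712
    return [int(x) for x in (lead + runs.tolist())]


def _decode_mask(runs, shape) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for run in runs:
        if val:
            flat[pos:pos + run] = True
        pos += run
        val = not val
    return flat.reshape(shape)
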