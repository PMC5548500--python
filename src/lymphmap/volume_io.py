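"""Reading, resampling and cropping of co-registered three-channel arm volumes.

The whole package works in one coordinate convention: axis 0 runs along the
arm from the wrist toward the shoulder (increasing slice index = more
proximal), axes 1 and 2 are the in-plane (transaxial) axes. Volumes are
analysed at 1 mm isotropic resolution, so one voxel is 1 mm^3 = 0.001 mL.
Readers are expected to deliver data in this orientation; the phantom
generator produces it natively.

Slice indices are 0-based everywhere, including the landmark sidecar files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from scipy.ndimage import map_coordinates

from .exceptions import LandmarkError, LymphmapError, ShapeMismatchError

#: fraction of the elbow-to-shoulder distance defining the proximal end of
#: the standardized analysis extent
UPPER_ARM_FRACTION = 0.65

#: volume of one voxel at 1 mm isotropic resolution, in mL
VOXEL_ML = 0.001


@dataclass
class ScalarVolume:
    """A 3D scalar image with per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise LymphmapError(f"volume must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise LymphmapError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        return np.allclose(self.spacing, 1.0)


@dataclass
class Landmarks:
    """Anatomical slice indices along axis 0 (0-based, wrist < elbow < shoulder)."""

    wrist_slice: int
    elbow_slice: int
    shoulder_tip_slice: int

    def __post_init__(self) -> None:
        w, e, s = self.wrist_slice, self.elbow_slice, self.shoulder_tip_slice
        if not (isinstance(w, (int, np.integer)) and isinstance(e, (int, np.integer))
                and isinstance(s, (int, np.integer))):
            raise LandmarkError("landmark slice indices must be integers")
        if w < 0:
            raise LandmarkError(f"wrist_slice must be >= 0, got {w}")
        if not (w < e < s):
            raise LandmarkError(f"landmarks must satisfy wrist < elbow < shoulder, got {w}, {e}, {s}")

    def check_within(self, n_slices: int) -> None:
        if self.shoulder_tip_slice >= n_slices:
            raise LandmarkError(
                f"shoulder_tip_slice {self.shoulder_tip_slice} outside volume of {n_slices} slices")


@dataclass
class ChannelStack:
    """Three co-registered channels (Dixon water, Dixon fat, STIR) of one arm."""

    water: ScalarVolume
    fat: ScalarVolume
    stir: ScalarVolume
    laterality: str = "right"
    status: str = "unaffected"
    subject_id: str = ""

    def __post_init__(self) -> None:
        vols = (self.water, self.fat, self.stir)
        shapes = {v.shape for v in vols}
        if len(shapes) != 1:
            raise ShapeMismatchError(f"channel shapes differ: {[v.shape for v in vols]}")
        spacings = np.array([v.spacing for v in vols])
        if not np.allclose(spacings, spacings[0], rtol=1e-3, atol=1e-3):
            raise ShapeMismatchError(f"channel spacings differ: {spacings.tolist()}")
        for name, v in zip(("water", "fat", "stir"), vols):
            if np.any(v.data < 0):
                raise LymphmapError(f"{name} channel contains negative intensities")
        if self.laterality not in ("left", "right"):
            raise LymphmapError(f"laterality must be 'left' or 'right', got {self.laterality!r}")
        if self.status not in ("affected", "unaffected"):
            raise LymphmapError(f"status must be 'affected' or 'unaffected', got {self.status!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.water.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.water.spacing

    def features(self) -> np.ndarray:
        """Voxel intensities as an (n_voxels, 3) array: (water, fat, stir)."""
        return np.column_stack([
            self.water.data.ravel().astype(np.float64),
            self.fat.data.ravel().astype(np.float64),
            self.stir.data.ravel().astype(np.float64),
        ])


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def upper_arm_mark(landmarks: Landmarks) -> int:
    """Slice index of the 65% upper-arm mark.

    The proximal boundary of the analysis extent lies 65% of the way from the
    elbow to the shoulder tip; the fractional position is rounded
    half-away-from-zero to the nearest slice.
    """
    pos = landmarks.elbow_slice + UPPER_ARM_FRACTION * (
        landmarks.shoulder_tip_slice - landmarks.elbow_slice)
    return _round_half_away(pos)


def resample_isotropic(volume: ScalarVolume, order: int = 1) -> ScalarVolume:
    """Resample a volume to 1 mm isotropic spacing.

    Output voxel ``i`` along an axis sits at physical position ``i`` mm and is
    interpolated from the input grid (voxel ``j`` at ``j * spacing`` mm).
    ``order=1`` is linear interpolation (intensity images); label volumes must
    use ``order=0`` (nearest neighbour) to stay categorical.
    """
    if volume.is_isotropic:
        return ScalarVolume(volume.data.copy(), (1.0, 1.0, 1.0))
    new_shape = tuple(
        max(1, int(math.floor((n - 1) * s)) + 1)
        for n, s in zip(volume.shape, volume.spacing))
    grids = np.meshgrid(
        *[np.arange(n, dtype=np.float64) / s for n, s in zip(new_shape, volume.spacing)],
        indexing="ij")
    data = map_coordinates(
        volume.data.astype(np.float64), np.array(grids), order=order, mode="nearest")
    if order == 0:
        data = data.astype(volume.data.dtype)
    return ScalarVolume(data, (1.0, 1.0, 1.0))


def crop_to_analysis_extent(
        stack: ChannelStack, landmarks: Landmarks) -> tuple[ChannelStack, Landmarks]:
    """Crop a stack to the standardized extent: wrist to 65% upper-arm mark.

    Both boundary slices are included. Returned landmarks are re-expressed in
    cropped coordinates (wrist at slice 0); the shifted shoulder-tip index may
    point beyond the cropped array, it is retained for the 65%-mark arithmetic.
    """
    landmarks.check_within(stack.shape[0])
    mark = upper_arm_mark(landmarks)
    lo, hi = landmarks.wrist_slice, mark + 1
    if hi <= lo:
        raise LandmarkError(f"empty analysis extent: wrist={lo}, mark={mark}")
    cropped = ChannelStack(
        water=ScalarVolume(stack.water.data[lo:hi].copy(), stack.spacing),
        fat=ScalarVolume(stack.fat.data[lo:hi].copy(), stack.spacing),
        stir=ScalarVolume(stack.stir.data[lo:hi].copy(), stack.spacing),
        laterality=stack.laterality, status=stack.status, subject_id=stack.subject_id)
    shifted = Landmarks(
        wrist_slice=0,
        elbow_slice=landmarks.elbow_slice - lo,
        shoulder_tip_slice=landmarks.shoulder_tip_slice - lo)
    return cropped, shifted


# ---------------------------------------------------------------------------
# File I/O

def read_scalar_volume(path: str | Path) -> ScalarVolume:
    """Read a NIfTI file; spacing is taken from the header zooms."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise LymphmapError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ScalarVolume(np.asarray(data), spacing)


def write_scalar_volume(path: str | Path, volume: ScalarVolume) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.data, affine), str(path))


def read_channel_stack(
        water_path: str | Path,
        fat_path: str | Path,
        stir_path: str | Path,
        laterality: str = "right",
        status: str = "unaffected",
        subject_id: str = "",
        resample: bool = True) -> ChannelStack:
    """Read and validate the three channels of one arm.

    With ``resample=True`` (default) each channel is brought to 1 mm isotropic
    spacing before validation, so channels acquired at different voxel sizes
    over the same physical volume can be stacked.
    """
    vols = {}
    for name, p in (("water", water_path), ("fat", fat_path), ("stir", stir_path)):
        v = read_scalar_volume(p)
        if resample:
            v = resample_isotropic(v)
        vols[name] = v
    return ChannelStack(
        water=vols["water"], fat=vols["fat"], stir=vols["stir"],
        laterality=laterality, status=status, subject_id=subject_id)


def read_sidecar(path: str | Path) -> tuple[Landmarks, dict]:
    """Read a JSON/YAML landmark sidecar.

    Expected keys: ``wrist_slice``, ``elbow_slice``, ``shoulder_tip_slice``
    (0-based slice indices), ``laterality``, ``status``, ``subject_id``.
    Returns the Landmarks plus the remaining metadata.
    """
    path = Path(path)
    text = path.read_text()
    meta = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    lm = Landmarks(
        wrist_slice=int(meta.pop("wrist_slice")),
        elbow_slice=int(meta.pop("elbow_slice")),
        shoulder_tip_slice=int(meta.pop("shoulder_tip_slice")))
    return lm, meta


def write_sidecar(path: str | Path, landmarks: Landmarks, meta: dict | None = None) -> None:
    path = Path(path)
    payload = {
        "wrist_slice": int(landmarks.wrist_slice),
        "elbow_slice": int(landmarks.elbow_slice),
        "shoulder_tip_slice": int(landmarks.shoulder_tip_slice),
        **(meta or {}),
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


__all__ = [
    "ScalarVolume", "ChannelStack", "Landmarks", "upper_arm_mark",
    "resample_isotropic", "crop_to_analysis_extent", "read_scalar_volume",
    "write_scalar_volume", "read_channel_stack", "read_sidecar", "write_sidecar",
    "UPPER_ARM_FRACTION", "VOXEL_ML",
]
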