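"""External / fascial mask construction and compartment classification.

Working slice by slice through the transaxial cross-sections, two masks are
built from the tissue label map: the external mask (the whole arm
cross-section, image noise excluded) and the subfascial mask (the interior of
the fascial contour enclosing the muscle and the other deep tissues). The
epifascial compartment — where lymphoedema fat and fluid accumulate — is the
set difference between the two, so the three compartments partition each
slice exactly.

Masks are extracted with classical binary morphology: a small opening removes
salt-and-pepper misclassifications, the largest connected component isolates
the arm (or the muscle), and a closing plus hole-filling produces a solid,
simply-connected region. The paper's method names erosion/dilation at this
stage but no sizes; the radii here are package parameters (mm, = voxels at
isotropic resolution) exposed in :class:`MorphologyParams`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from shapely.geometry import box
from shapely.ops import unary_union
from skimage.measure import label as cc_label
from skimage.morphology import closing as _closing
from skimage.morphology import disk
from skimage.morphology import opening as _opening

from .exceptions import EmptySliceError, LymphmapError, ShapeMismatchError
from .segmentation import Tissue


class Compartment:
    """Integer coding of compartments in compartment map volumes."""

    OUTSIDE = 0
    SUBFASCIAL = 1
    EPIFASCIAL = 2


@dataclass
class MorphologyParams:
    """Structuring-element radii (mm) for mask extraction.

    r_open cleans isolated misclassified voxels before component analysis;
    r_close_external closes the arm cross-section; r_close_fascia closes the
    muscle mask so that vessels, bone and other non-muscle subfascial tissue
    fall inside the fascial contour.
    """

    r_open: float = 3.0
    r_close_external: float = 3.0
    r_close_fascia: float = 5.0


@dataclass
class SliceMasks:
    """External and subfascial masks of one transaxial slice."""

    external: np.ndarray
    subfascial: np.ndarray
    slice_index: int = 0
    muscle_empty: bool = False


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab = cc_label(mask, connectivity=1)
    if lab.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == int(np.argmax(counts))


def _solid_mask(mask: np.ndarray, r_open: float, r_close: float) -> np.ndarray:
    m = mask.astype(bool)
    if r_open > 0:
        m = _opening(m, disk(int(round(r_open)))).astype(bool)
    m = _largest_component(m)
    if not m.any():
        return m
    if r_close > 0:
        m = _closing(m, disk(int(round(r_close)))).astype(bool)
        m = _largest_component(m)
    return binary_fill_holes(m)


def build_slice_masks(
        labels2d: np.ndarray,
        params: MorphologyParams | None = None,
        slice_index: int = 0) -> SliceMasks:
    """Build the external and subfascial masks of one labelled slice.

    The external mask is the largest connected component of non-noise voxels
    after opening, closed and hole-filled. The subfascial mask is built the
    same way from the muscle voxels (with the wider fascial closing radius)
    and constrained to the external mask. A slice with no non-noise voxels
    raises :class:`EmptySliceError`; a slice with no muscle voxels yields an
    empty subfascial mask flagged via ``muscle_empty``.
    """
    params = params or MorphologyParams()
    labels2d = np.asarray(labels2d)
    if labels2d.ndim != 2:
        raise LymphmapError(f"expected a 2D label slice, got ndim={labels2d.ndim}")
    non_noise = labels2d != Tissue.NOISE
    if not non_noise.any():
        raise EmptySliceError(f"slice {slice_index}: no non-noise voxels")
    external = _solid_mask(non_noise, params.r_open, params.r_close_external)
    if not external.any():
        raise EmptySliceError(f"slice {slice_index}: external mask empty after morphology")

    muscle = labels2d == Tissue.MUSCLE
    muscle_empty = not muscle.any()
    if muscle_empty:
        subfascial = np.zeros_like(external)
    else:
        subfascial = _solid_mask(muscle, params.r_open, params.r_close_fascia) & external
        muscle_empty = not subfascial.any()
    return SliceMasks(external=external, subfascial=subfascial,
                      slice_index=slice_index, muscle_empty=muscle_empty)


def build_all_masks(
        labels: np.ndarray,
        params: MorphologyParams | None = None) -> list[SliceMasks]:
    """Build masks for every slice of a label volume.

    Slices without any non-noise voxel (possible at the distal end of real
    acquisitions) are returned as empty masks with a warning rather than an
    error, so the surrounding volume can still be analysed.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise LymphmapError(f"expected a 3D label volume, got ndim={labels.ndim}")
    out: list[SliceMasks] = []
    for z in range(labels.shape[0]):
        try:
            out.append(build_slice_masks(labels[z], params, slice_index=z))
        except EmptySliceError:
            warnings.warn(f"slice {z}: empty (no arm cross-section); counted as outside")
            empty = np.zeros(labels.shape[1:], dtype=bool)
            out.append(SliceMasks(external=empty, subfascial=empty.copy(),
                                  slice_index=z, muscle_empty=True))
    return out


def extract_contour(mask: np.ndarray) -> np.ndarray:
    """Trace the boundary of a mask as a closed polygon in mm coordinates.

    The polygon follows the outer edges of the voxel squares (voxel centres
    at integer mm, footprint from -0.5 to +0.5 around them), so its area
    equals the voxel count exactly. Returns an (n_vertices, 2) array of
    (x=column, y=row) mm coordinates; first and last vertices coincide.
    Raises on empty or multi-component masks.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise LymphmapError(f"expected a 2D mask, got ndim={mask.ndim}")
    if not mask.any():
        raise LymphmapError("cannot extract a contour from an empty mask")
    if cc_label(mask, connectivity=2).max() > 1:
        raise LymphmapError("mask has multiple connected components")
    rows, cols = np.nonzero(mask)
    squares = [box(c - 0.5, r - 0.5, c + 0.5, r + 0.5) for r, c in zip(rows, cols)]
    poly = unary_union(squares)
    if poly.geom_type != "Polygon":
        raise LymphmapError("mask did not merge into a single polygon")
    ring = poly.exterior.simplify(0)
    return np.asarray(ring.coords, dtype=np.float64)


def contour_area(contour: np.ndarray) -> float:
    """Shoelace area (mm^2) of a closed contour from :func:`extract_contour`."""
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


def build_compartment_map(labels: np.ndarray, masks: list[SliceMasks]) -> np.ndarray:
    """Classify every voxel as outside / subfascial / epifascial.

    epifascial = external and not subfascial, so per slice and globally
    subfascial + epifascial voxel counts equal the external count exactly.
    Returns a uint8 volume of :class:`Compartment` codes.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3 or len(masks) != labels.shape[0]:
        raise ShapeMismatchError(
            f"label volume of {labels.shape[0] if labels.ndim == 3 else '?'} slices "
            f"vs {len(masks)} slice masks")
    comp = np.zeros(labels.shape, dtype=np.uint8)
    for z, m in enumerate(masks):
        if m.external.shape != labels.shape[1:]:
            raise ShapeMismatchError(f"slice {z}: mask shape {m.external.shape} "
                                     f"vs label slice {labels.shape[1:]}")
        comp[z][m.external] = Compartment.EPIFASCIAL
        comp[z][m.subfascial] = Compartment.SUBFASCIAL
    return comp


__all__ = ["Compartment", "MorphologyParams", "SliceMasks", "build_slice_masks",
           "build_all_masks", "extract_contour", "contour_area",
           "build_compartment_map"]
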