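"""Synthetic three-channel arm phantoms with voxel-exact ground truth.

The phantom emulates the contrast structure the segmentation relies on: an
arm modelled as a tapered circular cylinder with a concentric muscle core
(the fascia at its boundary), an epifascial layer of fat containing optional
fluid pockets, and a dark background. Each tissue has a characteristic mean
intensity triple over the (Dixon water, Dixon fat, STIR) channels — muscle
bright on water, fat bright on the fat image, fluid bright on STIR and
moderate on water — with optional additive Gaussian noise (clipped at zero)
and an optional smooth multiplicative bias field.

Ground truth is exact by construction: labels and compartments are the
voxelized geometry, and true volumes are 0.001 mL per voxel counted over the
standardized analysis extent (wrist to the 65% upper-arm mark).

Paired and cohort generators inject target excess volumes of epifascial fat
(by growing the external radius), epifascial fluid (by a calibrated
annulus-sector pocket) and optionally muscle into the affected arm. Targets
are hit to within a few tens of voxels by choosing per-slice radius / angle
cuts on the discrete voxel grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compartments import Compartment
from .exceptions import ContrastError, GeometryError, LymphmapError
from .segmentation import Tissue
from .volume_io import (VOXEL_ML, ChannelStack, Landmarks, ScalarVolume,
                        upper_arm_mark)

#: default mean intensity per tissue over (water, fat, stir), arbitrary units
DEFAULT_TISSUE_MEANS: dict[str, tuple[float, float, float]] = {
    "background": (30.0, 30.0, 30.0),
    "muscle": (100.0, 10.0, 25.0),
    "fat": (15.0, 100.0, 10.0),
    "fluid": (60.0, 8.0, 100.0),
}

_TISSUE_CODE = {"background": Tissue.NOISE, "muscle": Tissue.MUSCLE,
                "fat": Tissue.FAT, "fluid": Tissue.FLUID}

#: margin (voxels) kept between the arm surface and the image border so that
#: morphological closing never touches the edge
EDGE_MARGIN = 6.0


@dataclass
class FluidPocket:
    """A fluid inclusion in the epifascial layer (or, for misclassification
    experiments, inside the subfascial compartment).

    ``extent_mm`` is the blob diameter, or the longitudinal span for
    annulus-sector pockets (which additionally have ``width_deg``).
    ``honeycomb`` interleaves fluid with fat on a period-2 voxel lattice,
    emulating the trabecular pattern of fluid trapped between fat septa.
    """

    center_slice: int
    angle_deg: float = 270.0
    layer: str = "external"            # internal | external | subfascial
    extent_mm: float = 12.0
    shape: str = "blob"                # blob | annulus-sector
    width_deg: float = 60.0
    honeycomb: bool = False

    def __post_init__(self) -> None:
        if self.layer not in ("internal", "external", "subfascial"):
            raise LymphmapError(f"unknown pocket layer {self.layer!r}")
        if self.shape not in ("blob", "annulus-sector"):
            raise LymphmapError(f"unknown pocket shape {self.shape!r}")


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise description of one synthetic arm.

    Radius profiles may be a scalar (constant), a (wrist, shoulder) pair
    (linear taper) or a full per-slice array, in mm. Slice 0 is the wrist,
    the last slice the shoulder tip; the elbow defaults to 55% of the way
    up. ``noise_sigma`` is the additive Gaussian standard deviation, either
    one value for all channels or a per-channel triple; the helper
    :meth:`sigma_for_fraction` expresses it as a fraction of the minimum
    inter-tissue contrast.
    """

    n_slices: int = 200
    in_plane_size: int = 120
    arm_radius: float | tuple[float, float] | np.ndarray = (32.0, 48.0)
    muscle_radius: float | tuple[float, float] | np.ndarray = (20.0, 32.0)
    elbow_slice: int | None = None
    fluid_pockets: list[FluidPocket] = field(default_factory=list)
    tissue_means: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    noise_sigma: float | tuple[float, float, float] = 0.0
    bias_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 4 or self.in_plane_size < 16:
            raise GeometryError("phantom too small to carry an arm")
        if self.elbow_slice is None:
            self.elbow_slice = int(round(0.55 * (self.n_slices - 1)))
        if not (0 < self.elbow_slice < self.n_slices - 1):
            raise GeometryError(f"elbow_slice {self.elbow_slice} outside (0, {self.n_slices - 1})")
        arm = self.arm_profile()
        mus = self.muscle_profile()
        if np.any(mus >= arm):
            raise GeometryError("muscle radius must be < arm radius at every slice")
        if np.any(mus <= 0):
            raise GeometryError("muscle radius must be positive")
        if np.any(arm > (self.in_plane_size - 1) / 2 - 2):
            raise GeometryError("arm radius leaves no background margin")
        _validate_contrast(self.tissue_means)

    def _profile(self, value) -> np.ndarray:
        if np.isscalar(value):
            return np.full(self.n_slices, float(value))
        value = np.asarray(value, dtype=np.float64)
        if value.shape == (2,):
            return np.linspace(value[0], value[1], self.n_slices)
        if value.shape != (self.n_slices,):
            raise GeometryError(f"radius profile must be scalar, pair or length "
                                f"{self.n_slices}, got shape {value.shape}")
        return value

    def arm_profile(self) -> np.ndarray:
        return self._profile(self.arm_radius)

    def muscle_profile(self) -> np.ndarray:
        return self._profile(self.muscle_radius)

    def landmarks(self) -> Landmarks:
        return Landmarks(wrist_slice=0, elbow_slice=int(self.elbow_slice),
                         shoulder_tip_slice=self.n_slices - 1)

    @property
    def center(self) -> tuple[float, float]:
        c = (self.in_plane_size - 1) / 2.0
        return (c, c)

    def min_contrast(self) -> float:
        """Minimum Euclidean distance between any two tissue mean triples."""
        means = [np.asarray(self.tissue_means[t], float) for t in DEFAULT_TISSUE_MEANS]
        return min(float(np.linalg.norm(a - b))
                   for i, a in enumerate(means) for b in means[i + 1:])

    def sigma_for_fraction(self, fraction: float) -> float:
        return fraction * self.min_contrast()


def _validate_contrast(means: dict[str, tuple[float, float, float]]) -> None:
    """Each tissue must dominate its characteristic channel; background must
    have the smallest channel sum."""
    try:
        m = {t: np.asarray(means[t], dtype=np.float64) for t in DEFAULT_TISSUE_MEANS}
    except KeyError as exc:
        raise ContrastError(f"tissue_means missing entry: {exc}")
    for tissue, channel in (("muscle", 0), ("fat", 1), ("fluid", 2)):
        for other in DEFAULT_TISSUE_MEANS:
            if other != tissue and m[other][channel] >= m[tissue][channel]:
                raise ContrastError(
                    f"{tissue} must dominate channel {channel}: "
                    f"{other} has {m[other][channel]} >= {m[tissue][channel]}")
    sums = {t: v.sum() for t, v in m.items()}
    if min(sums, key=sums.get) != "background":
        raise ContrastError("background must have the smallest channel sum")


@dataclass
class GroundTruth:
    """Voxel-exact reference data accompanying a generated arm.

    ``labels`` uses :class:`~lymphmap.segmentation.Tissue` codes (mixed never
    occurs), ``compartments`` uses :class:`~lymphmap.compartments.Compartment`
    codes, ``sublayers`` splits the epifascial layer at the geometric
    mid-radius (0 = n/a, 1 = internal, 2 = external). ``true_volumes`` holds
    the six per-arm volumes in mL counted over the analysis extent
    ``[0, analysis_stop)``.
    """

    labels: np.ndarray
    compartments: np.ndarray
    sublayers: np.ndarray
    landmarks: Landmarks
    analysis_stop: int
    true_volumes: dict[str, float]


# ---------------------------------------------------------------------------
# geometry helpers

def _grids(in_plane: int) -> tuple[np.ndarray, np.ndarray]:
    c = (in_plane - 1) / 2.0
    rows, cols = np.meshgrid(np.arange(in_plane), np.arange(in_plane), indexing="ij")
    r = np.hypot(rows - c, cols - c)
    ang = np.degrees(np.arctan2(rows - c, cols - c)) % 360.0
    return r, ang


def _ang_dist(angles: np.ndarray, center_deg: float) -> np.ndarray:
    return np.abs((angles - center_deg + 180.0) % 360.0 - 180.0)


def _pocket_mask(pocket: FluidPocket, arm_r: np.ndarray, mus_r: np.ndarray,
                 r2d: np.ndarray, ang2d: np.ndarray, n_slices: int) -> np.ndarray:
    """Boolean volume of one pocket, restricted to its layer band."""
    mask = np.zeros((n_slices,) + r2d.shape, dtype=bool)
    mid = (arm_r + mus_r) / 2.0

    def band(z: int) -> np.ndarray:
        if pocket.layer == "internal":
            return (r2d > mus_r[z]) & (r2d <= mid[z])
        if pocket.layer == "external":
            return (r2d > mid[z]) & (r2d <= arm_r[z])
        return r2d <= mus_r[z]          # subfascial

    if pocket.shape == "annulus-sector":
        half = pocket.extent_mm / 2.0
        lo = max(0, int(math.ceil(pocket.center_slice - half)))
        hi = min(n_slices - 1, int(math.floor(pocket.center_slice + half)))
        sector = _ang_dist(ang2d, pocket.angle_deg) <= pocket.width_deg / 2.0
        for z in range(lo, hi + 1):
            mask[z] = band(z) & sector
    else:  # blob (sphere)
        z0 = pocket.center_slice
        if pocket.layer == "subfascial":
            rc = 0.5 * mus_r[z0]
        elif pocket.layer == "internal":
            rc = 0.5 * (mus_r[z0] + mid[z0])
        else:
            rc = 0.5 * (mid[z0] + arm_r[z0])
        c = (r2d.shape[0] - 1) / 2.0
        py = c + rc * math.sin(math.radians(pocket.angle_deg))
        px = c + rc * math.cos(math.radians(pocket.angle_deg))
        rad = pocket.extent_mm / 2.0
        rows, cols = np.meshgrid(np.arange(r2d.shape[0]), np.arange(r2d.shape[1]),
                                 indexing="ij")
        planar2 = (rows - py) ** 2 + (cols - px) ** 2
        zlo = max(0, int(math.ceil(z0 - rad)))
        zhi = min(n_slices - 1, int(math.floor(z0 + rad)))
        for z in range(zlo, zhi + 1):
            sphere = planar2 + (z - z0) ** 2 <= rad ** 2
            mask[z] = band(z) & sphere
    if pocket.honeycomb:
        zz, yy, xx = np.meshgrid(np.arange(n_slices), np.arange(r2d.shape[0]),
                                 np.arange(r2d.shape[1]), indexing="ij")
        mask &= (zz + yy + xx) % 2 == 0
    return mask


def _build_truth_arrays(arm_r: np.ndarray, mus_r: np.ndarray, in_plane: int,
                        pockets: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labels, compartments and sublayers from per-slice radii + pocket masks."""
    n = arm_r.shape[0]
    r2d, _ = _grids(in_plane)
    labels = np.zeros((n, in_plane, in_plane), dtype=np.uint8)
    comp = np.zeros_like(labels)
    sub = np.zeros_like(labels)
    mid = (arm_r + mus_r) / 2.0
    for z in range(n):
        arm = r2d <= arm_r[z]
        mus = r2d <= mus_r[z]
        labels[z][arm] = Tissue.FAT
        labels[z][mus] = Tissue.MUSCLE
        comp[z][arm] = Compartment.EPIFASCIAL
        comp[z][mus] = Compartment.SUBFASCIAL
        epi = arm & ~mus
        sub[z][epi & (r2d <= mid[z])] = 1
        sub[z][epi & (r2d > mid[z])] = 2
    for pm in pockets:
        labels[pm] = Tissue.FLUID
    return labels, comp, sub


def _synthesize(labels: np.ndarray, means: dict, noise_sigma, bias_amplitude: float,
                rng: np.random.Generator) -> list[np.ndarray]:
    """Channel images: tissue mean x bias field + clipped Gaussian noise."""
    lut = np.zeros((5, 3))
    for name, code in _TISSUE_CODE.items():
        lut[int(code)] = means[name]
    sigma = np.broadcast_to(np.asarray(noise_sigma, dtype=np.float64).ravel(), (3,)) \
        if np.ndim(noise_sigma) else np.full(3, float(noise_sigma))

    bias = None
    if bias_amplitude > 0:
        axes = [np.linspace(-1.0, 1.0, s) for s in labels.shape]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        terms = [zz, yy, xx, zz * yy, zz * xx, yy * xx, zz ** 2, yy ** 2, xx ** 2]
        coeffs = rng.uniform(-1.0, 1.0, size=len(terms))
        fld = sum(c * t for c, t in zip(coeffs, terms))
        fld /= max(np.abs(fld).max(), 1e-12)
        bias = 1.0 + bias_amplitude * fld

    channels = []
    for c in range(3):
        img = lut[labels, c]
        if bias is not None:
            img = img * bias
        if sigma[c] > 0:
            img = img + rng.normal(0.0, sigma[c], size=labels.shape)
        channels.append(np.clip(img, 0.0, None))
    return channels


def _true_volumes(labels: np.ndarray, comp: np.ndarray, stop: int) -> dict[str, float]:
    lab, cmp_ = labels[:stop], comp[:stop]
    sub = cmp_ == Compartment.SUBFASCIAL
    epi = cmp_ == Compartment.EPIFASCIAL
    return {
        "total_arm": float(sub.sum() + epi.sum()) * VOXEL_ML,
        "subfascial": float(sub.sum()) * VOXEL_ML,
        "epifascial": float(epi.sum()) * VOXEL_ML,
        "muscle_subfascial": float((sub & (lab == Tissue.MUSCLE)).sum()) * VOXEL_ML,
        "fat_epifascial": float((epi & (lab == Tissue.FAT)).sum()) * VOXEL_ML,
        "fluid_epifascial": float((epi & (lab == Tissue.FLUID)).sum()) * VOXEL_ML,
    }


def _make_stack(channels: list[np.ndarray], laterality: str, status: str,
                subject_id: str) -> ChannelStack:
    return ChannelStack(
        water=ScalarVolume(channels[0]), fat=ScalarVolume(channels[1]),
        stir=ScalarVolume(channels[2]),
        laterality=laterality, status=status, subject_id=subject_id)


def generate_arm(spec: PhantomSpec, laterality: str = "right",
                 status: str = "unaffected", subject_id: str = "phantom",
                 rng: np.random.Generator | None = None) -> tuple[ChannelStack, GroundTruth]:
    """Generate one synthetic arm and its ground truth.

    Deterministic given ``spec.seed`` (an explicit ``rng`` overrides it, used
    by the pair generator to keep the two arms' noise streams independent).
    """
    arm_r, mus_r = spec.arm_profile(), spec.muscle_profile()
    r2d, ang2d = _grids(spec.in_plane_size)
    pockets = [_pocket_mask(p, arm_r, mus_r, r2d, ang2d, spec.n_slices)
               for p in spec.fluid_pockets]
    labels, comp, sublayers = _build_truth_arrays(arm_r, mus_r, spec.in_plane_size, pockets)
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    channels = _synthesize(labels, spec.tissue_means, spec.noise_sigma,
                           spec.bias_amplitude, rng)
    lm = spec.landmarks()
    stop = upper_arm_mark(lm) + 1
    truth = GroundTruth(labels=labels, compartments=comp, sublayers=sublayers,
                        landmarks=lm, analysis_stop=stop,
                        true_volumes=_true_volumes(labels, comp, stop))
    return _make_stack(channels, laterality, status, subject_id), truth


# ---------------------------------------------------------------------------
# calibrated excess injection

@dataclass
class ExcessSpec:
    """Target excess volumes to inject into the affected arm.

    Fat excess is realized by growing the external radius over
    ``fat_slices`` (default: the whole analysis extent); fluid excess by a
    calibrated annulus-sector pocket centred longitudinally at the elbow
    (``fluid_center_slice`` overrides) spanning ``fluid_span_mm``;
    ``fluid_layer`` may be ``internal``, ``external`` or ``full`` (whole
    epifascial thickness). Optional muscle excess grows the muscle core.
    Targets are achieved to within a few tens of voxels (well below 1%).
    """

    fat_excess_ml: float = 100.0
    fluid_excess_ml: float = 50.0
    muscle_excess_ml: float = 0.0
    fat_slices: tuple[int, int] | None = None
    fluid_center_slice: int | None = None
    fluid_span_mm: float = 80.0
    fluid_angle_deg: float = 270.0
    fluid_layer: str = "external"

    def __post_init__(self) -> None:
        if min(self.fat_excess_ml, self.fluid_excess_ml, self.muscle_excess_ml) < 0:
            raise GeometryError("excess targets must be non-negative")
        if self.fluid_layer not in ("internal", "external", "full"):
            raise LymphmapError(f"unknown fluid_layer {self.fluid_layer!r}")


def _boundary_index(vals: np.ndarray, idx: int, lo: int, hi: int) -> int:
    """Nearest index in [lo, hi] at which vals can be cut between distinct
    values (or at either end)."""
    def ok(i: int) -> bool:
        return i <= lo or i >= hi or vals[i - 1] < vals[i]
    if ok(idx):
        return idx
    down, up = idx, idx
    while not ok(down):
        down -= 1
    while not ok(up):
        up += 1
    return down if idx - down <= up - idx else up

def _cut_value(vals: np.ndarray, idx: int) -> float:
    if idx <= 0:
        return float(vals[0]) - 1.0
    if idx >= len(vals):
        return float(vals[-1]) + 1.0
    return 0.5 * (float(vals[idx - 1]) + float(vals[idx]))


def _calibrate_cuts(vals_list: list[np.ndarray], base_counts: list[int],
                    cap_counts: list[int], target: int,
                    what: str) -> tuple[list[float], int]:
    """Choose per-slice cut values so that the summed extra voxel count hits
    ``target`` as closely as the voxel grid permits. Returns (cuts, achieved)."""
    capacity = sum(c - b for c, b in zip(cap_counts, base_counts))
    if target > capacity:
        raise GeometryError(f"{what} excess target of {target} voxels exceeds "
                            f"geometric capacity of {capacity} voxels")
    cuts: list[float] = []
    remaining = float(target)
    left = len(vals_list)
    achieved = 0
    for vals, b, cap in zip(vals_list, base_counts, cap_counts):
        share = remaining / left if left else 0.0
        idx = int(round(b + share))
        idx = min(max(idx, b), cap)
        idx = _boundary_index(vals, idx, b, cap)
        got = idx - b
        cuts.append(_cut_value(vals, idx))
        achieved += got
        remaining -= got
        left -= 1
    return cuts, achieved


@dataclass
class _PairPlan:
    """Calibrated geometry of an affected/unaffected pair (internal)."""

    spec_u: PhantomSpec
    arm_u: np.ndarray
    mus_u: np.ndarray
    arm_a: np.ndarray
    mus_a: np.ndarray
    fluid_cuts: list[float]          # per-slice angular half-width, deg
    fluid_zlo: int
    fluid_angle: float
    fluid_band: tuple[str, float]    # layer name; band uses unaffected radii
    achieved_fat: int
    achieved_fluid: int
    achieved_muscle: int
    analysis_stop: int


def _plan_pair(spec_u: PhantomSpec, excess: ExcessSpec) -> _PairPlan:
    arm_u, mus_u = spec_u.arm_profile(), spec_u.muscle_profile()
    lm = spec_u.landmarks()
    stop = upper_arm_mark(lm) + 1
    r2d, ang2d = _grids(spec_u.in_plane_size)
    sorted_r = np.sort(r2d.ravel())
    cap_radius = (spec_u.in_plane_size - 1) / 2.0 - EDGE_MARGIN
    cap_idx = int(np.searchsorted(sorted_r, cap_radius, side="right"))

    def base_idx(radii: np.ndarray) -> list[int]:
        return [int(np.searchsorted(sorted_r, r, side="right")) for r in radii]

    # 1. muscle growth
    t_mus = int(round(excess.muscle_excess_ml / VOXEL_ML))
    mus_a = mus_u.copy()
    got_mus = 0
    if t_mus > 0:
        zs = list(range(stop))
        caps = [int(np.searchsorted(sorted_r, arm_u[z] - 2.0, side="right")) for z in zs]
        cuts, got_mus = _calibrate_cuts([sorted_r] * len(zs), base_idx(mus_u[:stop]),
                                        caps, t_mus, "muscle")
        for z, c in zip(zs, cuts):
            mus_a[z] = max(mus_u[z], c)

    # 2. fluid sector in the affected arm's epifascial layer
    t_fl = int(round(excess.fluid_excess_ml / VOXEL_ML))
    center = excess.fluid_center_slice if excess.fluid_center_slice is not None \
        else lm.elbow_slice
    half = excess.fluid_span_mm / 2.0
    zlo = max(0, int(math.ceil(center - half)))
    zhi = min(stop - 1, int(math.floor(center + half)))
    mid_u = (arm_u + mus_u) / 2.0
    fluid_cuts: list[float] = []
    got_fl = 0
    if t_fl > 0:
        vals_list, caps = [], []
        base_pocket = np.zeros((spec_u.n_slices,) + r2d.shape, dtype=bool)
        for p in spec_u.fluid_pockets:
            base_pocket |= _pocket_mask(p, arm_u, mus_u, r2d, ang2d, spec_u.n_slices)
        for z in range(zlo, zhi + 1):
            if excess.fluid_layer == "internal":
                band = (r2d > mus_a[z]) & (r2d <= mid_u[z])
            elif excess.fluid_layer == "external":
                band = (r2d > mid_u[z]) & (r2d <= arm_u[z])
            else:
                band = (r2d > mus_a[z]) & (r2d <= arm_u[z])
            band &= ~base_pocket[z]
            d = np.sort(_ang_dist(ang2d[band], excess.fluid_angle_deg))
            vals_list.append(d)
            caps.append(len(d))
        fluid_cuts, got_fl = _calibrate_cuts(vals_list, [0] * len(vals_list),
                                             caps, t_fl, "fluid")

    # 3. external radius growth: fat target plus what fluid/muscle consumed
    t_fat = int(round(excess.fat_excess_ml / VOXEL_ML))
    arm_a = arm_u.copy()
    got_fat = 0
    if t_fat + got_fl + got_mus > 0:
        f_lo, f_hi = excess.fat_slices if excess.fat_slices is not None else (0, stop - 1)
        f_hi = min(f_hi, stop - 1)
        zs = list(range(f_lo, f_hi + 1))
        cuts, got_arm = _calibrate_cuts([sorted_r] * len(zs),
                                        base_idx(arm_u[list(zs)]),
                                        [cap_idx] * len(zs),
                                        t_fat + got_fl + got_mus, "fat")
        for z, c in zip(zs, cuts):
            arm_a[z] = max(arm_u[z], c)
        got_fat = got_arm - got_fl - got_mus

    return _PairPlan(spec_u=spec_u, arm_u=arm_u, mus_u=mus_u, arm_a=arm_a,
                     mus_a=mus_a, fluid_cuts=fluid_cuts, fluid_zlo=zlo,
                     fluid_angle=excess.fluid_angle_deg,
                     fluid_band=(excess.fluid_layer, 0.0),
                     achieved_fat=got_fat, achieved_fluid=got_fl,
                     achieved_muscle=got_mus, analysis_stop=stop)


def _build_pair(plan: _PairPlan, subject_id: str,
                affected_laterality: str = "left"
                ) -> tuple[tuple[ChannelStack, GroundTruth], tuple[ChannelStack, GroundTruth]]:
    spec = plan.spec_u
    r2d, ang2d = _grids(spec.in_plane_size)
    base_pockets_u = [_pocket_mask(p, plan.arm_u, plan.mus_u, r2d, ang2d, spec.n_slices)
                      for p in spec.fluid_pockets]
    # base pockets are identical voxel sets in both arms (defined on the
    # unaffected geometry, which the affected arm contains)
    extra = np.zeros((spec.n_slices,) + r2d.shape, dtype=bool)
    mid_u = (plan.arm_u + plan.mus_u) / 2.0
    layer = plan.fluid_band[0]
    for i, cut in enumerate(plan.fluid_cuts):
        z = plan.fluid_zlo + i
        if layer == "internal":
            band = (r2d > plan.mus_a[z]) & (r2d <= mid_u[z])
        elif layer == "external":
            band = (r2d > mid_u[z]) & (r2d <= plan.arm_u[z])
        else:
            band = (r2d > plan.mus_a[z]) & (r2d <= plan.arm_u[z])
        for bp in base_pockets_u:
            band &= ~bp[z]
        extra[z] = band & (_ang_dist(ang2d, plan.fluid_angle) <= cut)

    labels_u, comp_u, sub_u = _build_truth_arrays(
        plan.arm_u, plan.mus_u, spec.in_plane_size, base_pockets_u)
    labels_a, comp_a, sub_a = _build_truth_arrays(
        plan.arm_a, plan.mus_a, spec.in_plane_size, base_pockets_u + [extra])

    seeds = np.random.SeedSequence(spec.seed).spawn(2)
    chans_a = _synthesize(labels_a, spec.tissue_means, spec.noise_sigma,
                          spec.bias_amplitude, np.random.default_rng(seeds[0]))
    chans_u = _synthesize(labels_u, spec.tissue_means, spec.noise_sigma,
                          spec.bias_amplitude, np.random.default_rng(seeds[1]))

    lm = spec.landmarks()
    stop = plan.analysis_stop
    gt_a = GroundTruth(labels_a, comp_a, sub_a, lm, stop,
                       _true_volumes(labels_a, comp_a, stop))
    gt_u = GroundTruth(labels_u, comp_u, sub_u, lm, stop,
                       _true_volumes(labels_u, comp_u, stop))
    other = "right" if affected_laterality == "left" else "left"
    stack_a = _make_stack(chans_a, affected_laterality, "affected", subject_id)
    stack_u = _make_stack(chans_u, other, "unaffected", subject_id)
    return (stack_a, gt_a), (stack_u, gt_u)


def generate_pair(spec_unaffected: PhantomSpec, excess: ExcessSpec,
                  subject_id: str = "phantom", affected_laterality: str = "left"
                  ) -> tuple[tuple[ChannelStack, GroundTruth], tuple[ChannelStack, GroundTruth]]:
    """Generate an affected/unaffected arm pair with calibrated excesses.

    Returns ``((stack_affected, truth_affected), (stack_unaffected,
    truth_unaffected))``. Both arms share elbow-aligned landmarks; the
    affected arm's ground-truth fat/fluid (and optionally muscle) volumes
    exceed the unaffected one's by the requested targets to within
    voxelization error (well under 1% relative).
    """
    plan = _plan_pair(spec_unaffected, excess)
    return _build_pair(plan, subject_id, affected_laterality)


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class CohortParams:
    """Population distributions for synthetic cohorts.

    Fat excess is drawn normally; fluid excess is linearly coupled to fat
    (``fluid = slope x fat + noise``), with floors keeping both positive.
    Defaults emulate a unilateral-lymphoedema population in which the fat
    excess is about twice the fluid excess and the two are strongly
    linearly correlated.
    """

    n_slices: int = 100
    in_plane_size: int = 128
    shoulder_radius_mean: float = 36.0
    shoulder_radius_sd: float = 2.0
    wrist_fraction: float = 0.70
    muscle_fraction: float = 0.66
    fat_excess_mean: float = 120.0
    fat_excess_sd: float = 40.0
    fluid_slope: float = 1.0 / 2.1
    fluid_noise_sd: float = 16.8
    muscle_excess_ml: float = 0.0
    fluid_layer: str = "full"
    fluid_span_mm: float = 999.0
    noise_fraction: float = 0.1
    fat_floor_ml: float = 30.0
    fluid_floor_ml: float = 5.0
    #: angular width of the physiological fluid pocket present in BOTH arms
    #: (unaffected arms carry baseline interstitial fluid; a five-cluster
    #: model needs every tissue population represented)
    base_fluid_width_deg: float = 120.0

    def population_pearson(self) -> float:
        """Pearson correlation of the generating (pre-floor) fat/fluid law."""
        num = self.fluid_slope * self.fat_excess_sd
        return num / math.hypot(num, self.fluid_noise_sd)


def generate_cohort(n_subjects: int = 13, params: CohortParams | None = None,
                    seed: int = 0, materialize: bool = False
                    ) -> tuple[list, pd.DataFrame]:
    """Generate a cohort of affected/unaffected pairs plus its truth table.

    Returns ``(subjects, truth)``. Each subject entry is a dict holding the
    unaffected :class:`PhantomSpec` and :class:`ExcessSpec`; with
    ``materialize=True`` it additionally holds the generated ``pair``
    (expensive: full image volumes). The truth table has one row per subject
    with the achieved (voxel-exact) excess volumes and the unaffected arm's
    epifascial and total volumes, and is reproducible given ``seed``.
    """
    params = params or CohortParams()
    if n_subjects < 2:
        raise LymphmapError("a cohort needs at least 2 subjects")
    if params.fat_excess_sd <= 0:
        raise GeometryError("fat_excess_sd must be positive: zero variance "
                            "makes the requested fat/fluid coupling degenerate")
    master = np.random.SeedSequence(seed)
    subject_seeds = master.spawn(n_subjects)
    rng = np.random.default_rng(master.spawn(1)[0])

    subjects, rows = [], []
    r2d, _ = _grids(params.in_plane_size)
    sorted_r = np.sort(r2d.ravel())
    for i in range(n_subjects):
        shoulder = rng.normal(params.shoulder_radius_mean, params.shoulder_radius_sd)
        shoulder = float(np.clip(shoulder, 10.0,
                                 (params.in_plane_size - 1) / 2.0 - EDGE_MARGIN - 2))
        wrist = params.wrist_fraction * shoulder
        fat = max(params.fat_floor_ml, rng.normal(params.fat_excess_mean,
                                                  params.fat_excess_sd))
        fluid = max(params.fluid_floor_ml,
                    params.fluid_slope * fat + rng.normal(0.0, params.fluid_noise_sd))
        # guard against rare extreme draws exceeding the geometric capacity;
        # conservative estimates, deterministic rescaling
        cap_radius = (params.in_plane_size - 1) / 2.0 - EDGE_MARGIN
        n_extent = int(round(0.84 * params.n_slices))   # approx analysis extent
        r_mean = 0.5 * (wrist + shoulder)
        fluid_cap_ml = (math.pi * r_mean ** 2 * (1 - params.muscle_fraction ** 2)
                        * n_extent * VOXEL_ML)          # epifascial band volume
        if params.fluid_layer != "full":
            fluid_cap_ml *= 0.5
        # the physiological base pocket (internal layer) is unavailable to
        # the excess sector
        occupied = params.base_fluid_width_deg / 360.0
        if params.fluid_layer == "full":
            fluid_cap_ml *= 1.0 - occupied / 2.0
        elif params.fluid_layer == "internal":
            fluid_cap_ml *= 1.0 - occupied
        fluid = min(fluid, 0.8 * fluid_cap_ml)
        fat_cap_ml = (math.pi * (cap_radius ** 2 - shoulder ** 2)
                      * n_extent * VOXEL_ML)            # outer growth ring
        total = fat + fluid + params.muscle_excess_ml
        if total > 0.9 * fat_cap_ml:
            scale = 0.9 * fat_cap_ml / total
            fat, fluid = fat * scale, fluid * scale
        sub_seed = int(subject_seeds[i].generate_state(1)[0] % (2**31))
        base_pockets = []
        if params.base_fluid_width_deg > 0:
            base_pockets.append(FluidPocket(
                center_slice=params.n_slices // 2, extent_mm=float(params.n_slices),
                shape="annulus-sector", width_deg=params.base_fluid_width_deg,
                angle_deg=250.0, layer="internal"))
        spec_u = PhantomSpec(
            n_slices=params.n_slices, in_plane_size=params.in_plane_size,
            arm_radius=(wrist, shoulder),
            muscle_radius=(params.muscle_fraction * wrist,
                           params.muscle_fraction * shoulder),
            fluid_pockets=base_pockets,
            seed=sub_seed)
        spec_u.noise_sigma = spec_u.sigma_for_fraction(params.noise_fraction)
        excess = ExcessSpec(fat_excess_ml=fat, fluid_excess_ml=fluid,
                            muscle_excess_ml=params.muscle_excess_ml,
                            fluid_layer=params.fluid_layer,
                            fluid_span_mm=params.fluid_span_mm)
        plan = _plan_pair(spec_u, excess)

        # voxel-exact unaffected volumes from the calibrated geometry
        stop = plan.analysis_stop
        arm_counts = np.searchsorted(sorted_r, plan.arm_u[:stop], side="right")
        mus_counts = np.searchsorted(sorted_r, plan.mus_u[:stop], side="right")
        entry = {"subject_id": f"S{i + 1:02d}", "spec_unaffected": spec_u,
                 "excess": excess}
        if materialize:
            entry["pair"] = _build_pair(plan, entry["subject_id"])
        subjects.append(entry)
        rows.append({
            "subject_id": entry["subject_id"],
            "fat_excess_ml": plan.achieved_fat * VOXEL_ML,
            "fluid_excess_ml": plan.achieved_fluid * VOXEL_ML,
            "muscle_excess_ml": plan.achieved_muscle * VOXEL_ML,
            "epifascial_excess_ml": (plan.achieved_fat + plan.achieved_fluid) * VOXEL_ML,
            "unaffected_epifascial_ml": float((arm_counts - mus_counts).sum()) * VOXEL_ML,
            "unaffected_total_ml": float(arm_counts.sum()) * VOXEL_ML,
        })
    return subjects, pd.DataFrame(rows)


__all__ = ["DEFAULT_TISSUE_MEANS", "FluidPocket", "PhantomSpec", "GroundTruth",
           "ExcessSpec", "CohortParams", "generate_arm", "generate_pair",
           "generate_cohort"]
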