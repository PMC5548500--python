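"""Longitudinal profiles, segment excess maps and radial fluid-excess maps.

Three visualization products summarize how the swelling distributes:

* a longitudinal profile of per-slice tissue volumes (muscle, epifascial fat,
  epifascial fluid, total) along the arm, with affected and unaffected arms
  aligned at the elbow;
* a 10-segment longitudinal excess map (the forearm divided into 6 segments,
  the upper arm into 4) of fluid excess, fat excess (mL) and the epifascial
  increase (% of the unaffected volume), each normalized to its per-arm peak;
* a 16-segment radial map (2 epifascial sublayers x 8 angular sectors) of
  fluid excess summed along the arm, with the torso-facing side always
  rendered on the right regardless of which arm was imaged.

Conventions: the forearm comprises the aligned slices before the elbow
index, the upper arm the elbow slice onward. Left arms are mirrored about
the vertical image axis so that medial (torso) structures appear on the
right of the radial map. Angular sectors start at the image horizontal axis
and advance in 45-degree steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .compartments import Compartment
from .exceptions import LymphmapError, ShapeMismatchError
from .segmentation import Tissue
from .volume_io import VOXEL_ML, Landmarks

N_FOREARM_SEGMENTS = 6
N_UPPER_SEGMENTS = 4
N_SECTORS = 8


@dataclass
class LongitudinalProfile:
    """Per-slice volumes (mL per 1 mm slice) along the analysis extent."""

    muscle: np.ndarray
    fat: np.ndarray
    fluid: np.ndarray
    epifascial: np.ndarray
    total: np.ndarray
    elbow_index: int

    @property
    def n_slices(self) -> int:
        return len(self.total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "slice": np.arange(self.n_slices),
            "muscle_ml": self.muscle, "fat_ml": self.fat, "fluid_ml": self.fluid,
            "epifascial_ml": self.epifascial, "total_ml": self.total})


def longitudinal_profile(labels: np.ndarray, compartments: np.ndarray,
                         landmarks: Landmarks) -> LongitudinalProfile:
    """Per-slice voxel counts of each tissue/compartment, converted to mL."""
    labels = np.asarray(labels)
    compartments = np.asarray(compartments)
    if labels.shape != compartments.shape:
        raise ShapeMismatchError(f"labels {labels.shape} vs compartments "
                                 f"{compartments.shape}")
    axes = (1, 2)
    sub = compartments == Compartment.SUBFASCIAL
    epi = compartments == Compartment.EPIFASCIAL
    return LongitudinalProfile(
        muscle=(sub & (labels == Tissue.MUSCLE)).sum(axis=axes) * VOXEL_ML,
        fat=(epi & (labels == Tissue.FAT)).sum(axis=axes) * VOXEL_ML,
        fluid=(epi & (labels == Tissue.FLUID)).sum(axis=axes) * VOXEL_ML,
        epifascial=epi.sum(axis=axes) * VOXEL_ML,
        total=(sub | epi).sum(axis=axes) * VOXEL_ML,
        elbow_index=landmarks.elbow_slice)


@dataclass
class AlignedPair:
    """Two profiles trimmed to a common extent with coincident elbows.

    ``range_affected`` / ``range_unaffected`` give the (start, stop) slice
    window of each original volume contributing to the aligned extent, so
    that voxel-level products (e.g. the radial map) can use the same
    alignment.
    """

    affected: LongitudinalProfile
    unaffected: LongitudinalProfile
    elbow_index: int
    range_affected: tuple[int, int]
    range_unaffected: tuple[int, int]

    @property
    def n_slices(self) -> int:
        return self.affected.n_slices


def _trim(p: LongitudinalProfile, lo: int, hi: int, elbow: int) -> LongitudinalProfile:
    return LongitudinalProfile(
        muscle=p.muscle[lo:hi], fat=p.fat[lo:hi], fluid=p.fluid[lo:hi],
        epifascial=p.epifascial[lo:hi], total=p.total[lo:hi], elbow_index=elbow)


def align_pair_at_elbow(affected: LongitudinalProfile,
                        unaffected: LongitudinalProfile) -> AlignedPair:
    """Shift two profiles so their elbow indices coincide and trim both to
    the common extent (the overlap of their spans on each side of the elbow)."""
    left = min(affected.elbow_index, unaffected.elbow_index)
    right = min(affected.n_slices - affected.elbow_index,
                unaffected.n_slices - unaffected.elbow_index)
    if left + right <= 0:
        raise LymphmapError("profiles have no overlap after elbow alignment")
    lo_a = affected.elbow_index - left
    lo_u = unaffected.elbow_index - left
    return AlignedPair(
        affected=_trim(affected, lo_a, lo_a + left + right, left),
        unaffected=_trim(unaffected, lo_u, lo_u + left + right, left),
        elbow_index=left,
        range_affected=(lo_a, lo_a + left + right),
        range_unaffected=(lo_u, lo_u + left + right))


def segment_bounds(n_slices: int, elbow_index: int,
                   n_forearm: int = N_FOREARM_SEGMENTS,
                   n_upper: int = N_UPPER_SEGMENTS) -> list[tuple[int, int]]:
    """Contiguous (start, stop) slice windows of the longitudinal segments.

    The forearm (slices before the elbow) is split into ``n_forearm``
    segments and the upper arm (elbow slice onward) into ``n_upper``.
    Remainder slices are distributed one per segment starting from the
    distal (wrist) end of each region.
    """
    def split(lo: int, hi: int, k: int) -> list[tuple[int, int]]:
        n = hi - lo
        if n < k:
            raise LymphmapError(f"cannot split {n} slices into {k} segments")
        base, rem = divmod(n, k)
        bounds, start = [], lo
        for i in range(k):
            stop = start + base + (1 if i < rem else 0)
            bounds.append((start, stop))
            start = stop
        return bounds

    return split(0, elbow_index, n_forearm) + split(elbow_index, n_slices, n_upper)


@dataclass
class LongitudinalExcessMap:
    """Per-segment excess measures: fluid and fat excess (mL, affected minus
    unaffected) and the epifascial increase (% of the unaffected volume;
    NaN where the unaffected segment volume is zero). ``peaks`` records the
    per-measure normalization constants (max absolute value)."""

    fluid_excess: np.ndarray
    fat_excess: np.ndarray
    epifascial_increase_pct: np.ndarray
    bounds: list[tuple[int, int]]
    peaks: dict[str, float]
    n_forearm: int = N_FOREARM_SEGMENTS
    n_upper: int = N_UPPER_SEGMENTS

    def normalized(self, measure: str) -> np.ndarray:
        """Values scaled to [-1, 1] by the per-measure peak (0 if the peak
        is zero); at least one entry has magnitude 1 when any excess exists."""
        values = getattr(self, measure)
        peak = self.peaks[measure]
        if peak == 0:
            return np.zeros_like(values)
        return np.where(np.isnan(values), np.nan, values / peak)

    def to_frame(self) -> pd.DataFrame:
        region = ["forearm"] * self.n_forearm + ["upper_arm"] * self.n_upper
        return pd.DataFrame({
            "segment": np.arange(len(self.fluid_excess)),
            "region": region,
            "start_slice": [b[0] for b in self.bounds],
            "stop_slice": [b[1] for b in self.bounds],
            "fluid_excess_ml": self.fluid_excess,
            "fat_excess_ml": self.fat_excess,
            "epifascial_increase_pct": self.epifascial_increase_pct})


def longitudinal_excess_map(aligned: AlignedPair,
                            n_forearm: int = N_FOREARM_SEGMENTS,
                            n_upper: int = N_UPPER_SEGMENTS) -> LongitudinalExcessMap:
    """Segment-wise excess volumes of an elbow-aligned pair.

    The segment sums partition the aligned extent, so the 10 fluid (fat)
    entries add up exactly to the total fluid (fat) excess over the extent.
    """
    bounds = segment_bounds(aligned.n_slices, aligned.elbow_index, n_forearm, n_upper)
    fl, fa, ep = [], [], []
    for lo, hi in bounds:
        fl.append(aligned.affected.fluid[lo:hi].sum()
                  - aligned.unaffected.fluid[lo:hi].sum())
        fa.append(aligned.affected.fat[lo:hi].sum()
                  - aligned.unaffected.fat[lo:hi].sum())
        u = aligned.unaffected.epifascial[lo:hi].sum()
        a = aligned.affected.epifascial[lo:hi].sum()
        ep.append(100.0 * (a - u) / u if u > 0 else np.nan)
    fl, fa, ep = np.array(fl), np.array(fa), np.array(ep)
    peaks = {
        "fluid_excess": float(np.max(np.abs(fl))) if len(fl) else 0.0,
        "fat_excess": float(np.max(np.abs(fa))) if len(fa) else 0.0,
        "epifascial_increase_pct": float(np.nanmax(np.abs(ep)))
        if np.any(~np.isnan(ep)) else 0.0,
    }
    return LongitudinalExcessMap(fluid_excess=fl, fat_excess=fa,
                                 epifascial_increase_pct=ep, bounds=bounds,
                                 peaks=peaks, n_forearm=n_forearm, n_upper=n_upper)


# ---------------------------------------------------------------------------
# radial map

def split_epifascial_layers(compartments: np.ndarray) -> np.ndarray:
    """Split the epifascial compartment at the midcontour.

    Implemented by per-slice distance comparison, which realizes the curve
    equidistant from the fascial and external contours without constructing
    it: an epifascial voxel is *internal* (the layer above the muscle) when
    its Euclidean distance to the subfascial region does not exceed its
    distance to the exterior, *external* (the layer below the skin)
    otherwise; ties count as internal. Returns a uint8 volume
    (0 outside the epifascial layer, 1 internal, 2 external).
    """
    comp = np.asarray(compartments)
    if comp.ndim != 3:
        raise LymphmapError(f"expected 3D compartment map, got ndim={comp.ndim}")
    epi_total = comp == Compartment.EPIFASCIAL
    if not epi_total.any():
        raise LymphmapError("compartment map has no epifascial voxels")
    out = np.zeros(comp.shape, dtype=np.uint8)
    for z in range(comp.shape[0]):
        sl = comp[z]
        epi = sl == Compartment.EPIFASCIAL
        if not epi.any():
            continue
        has_sub = bool((sl == Compartment.SUBFASCIAL).any())
        has_out = bool((sl == Compartment.OUTSIDE).any())
        d_fascia = distance_transform_edt(sl != Compartment.SUBFASCIAL) \
            if has_sub else np.full(sl.shape, np.inf)
        d_skin = distance_transform_edt(sl != Compartment.OUTSIDE) \
            if has_out else np.full(sl.shape, np.inf)
        internal = epi & (d_fascia <= d_skin)
        out[z][internal] = 1
        out[z][epi & ~internal] = 2
    return out


def radial_fluid_histogram(labels: np.ndarray, compartments: np.ndarray,
                           laterality: str,
                           sublayers: np.ndarray | None = None,
                           slice_range: tuple[int, int] | None = None) -> np.ndarray:
    """Accumulate epifascial fluid volume into 2 layers x 8 sectors (mL).

    Per slice, the eight sectors are bounded by the horizontal, vertical and
    45-degree lines through the centre of mass of the subfascial
    cross-section (falling back to the whole-arm centre where the muscle
    mask is empty). Left arms are mirrored about the vertical axis so the
    torso-facing side lies on the right. Row 0 is the internal layer, row 1
    the external one.
    """
    labels = np.asarray(labels)
    comp = np.asarray(compartments)
    if labels.shape != comp.shape:
        raise ShapeMismatchError(f"labels {labels.shape} vs compartments {comp.shape}")
    if sublayers is None:
        sublayers = split_epifascial_layers(comp)
    lo, hi = slice_range if slice_range is not None else (0, labels.shape[0])
    hist = np.zeros((2, N_SECTORS))
    mirror = laterality == "left"
    for z in range(lo, hi):
        sl_lab, sl_comp, sl_sub = labels[z], comp[z], sublayers[z]
        ref = sl_comp == Compartment.SUBFASCIAL
        if not ref.any():
            ref = sl_comp != Compartment.OUTSIDE
            if not ref.any():
                continue
        rows, cols = np.nonzero(ref)
        cy, cx = rows.mean(), cols.mean()
        fluid = (sl_lab == Tissue.FLUID) & (sl_comp == Compartment.EPIFASCIAL)
        if not fluid.any():
            continue
        fr, fc = np.nonzero(fluid)
        dx = fc - cx
        if mirror:
            dx = -dx
        ang = np.degrees(np.arctan2(fr - cy, dx)) % 360.0
        sector = np.minimum((ang // 45.0).astype(int), N_SECTORS - 1)
        # a voxel centred exactly on a sector boundary line is cut in half
        # by it; splitting its volume between the adjacent sectors avoids a
        # systematic bias between diagonal- and axis-bounded sectors
        frac = ang % 45.0
        on_boundary = np.isclose(frac, 0.0, atol=1e-9) | np.isclose(frac, 45.0, atol=1e-9)
        weight = np.where(on_boundary, 0.5, 1.0) * VOXEL_ML
        layer = sl_sub[fr, fc]          # 1 internal, 2 external
        for lay in (1, 2):
            sel = layer == lay
            if sel.any():
                np.add.at(hist[lay - 1], sector[sel], weight[sel])
                both = sel & on_boundary
                np.add.at(hist[lay - 1], (sector[both] - 1) % N_SECTORS,
                          weight[both])
    return hist


@dataclass
class RadialExcessMap:
    """16-segment radial distribution of the fluid excess volume (mL),
    affected minus unaffected, summed along the aligned extent. Row 0 holds
    the internal sublayer (above the muscle), row 1 the external one (below
    the skin); the torso side is on the right by convention."""

    excess: np.ndarray               # (2, 8)
    affected_hist: np.ndarray
    unaffected_hist: np.ndarray
    torso_side: str = "right"

    @property
    def peak(self) -> float:
        return float(np.max(np.abs(self.excess)))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for layer, name in ((0, "internal"), (1, "external")):
            for s in range(N_SECTORS):
                rows.append({"layer": name, "sector": s,
                             "angle_start_deg": 45.0 * s,
                             "fluid_excess_ml": self.excess[layer, s]})
        return pd.DataFrame(rows)


def radial_excess_map(labels_affected: np.ndarray, comp_affected: np.ndarray,
                      laterality_affected: str,
                      labels_unaffected: np.ndarray, comp_unaffected: np.ndarray,
                      laterality_unaffected: str,
                      range_affected: tuple[int, int] | None = None,
                      range_unaffected: tuple[int, int] | None = None) -> RadialExcessMap:
    """Radial fluid-excess map of an elbow-aligned pair.

    Each arm is binned in its own (mirrored, for left arms) frame, then the
    per-bin difference is taken; the 16 entries sum exactly to the total
    fluid excess over the aligned extent.
    """
    ha = radial_fluid_histogram(labels_affected, comp_affected,
                                laterality_affected, slice_range=range_affected)
    hu = radial_fluid_histogram(labels_unaffected, comp_unaffected,
                                laterality_unaffected, slice_range=range_unaffected)
    return RadialExcessMap(excess=ha - hu, affected_hist=ha, unaffected_hist=hu)


# ---------------------------------------------------------------------------
# rendering

TISSUE_COLORS = {"muscle": "red", "fat": "gold", "fluid": "blue", "total": "green"}
MEASURE_CMAPS = {"fluid_excess": "Blues", "fat_excess": "Oranges",
                 "epifascial_increase_pct": "Greens"}


def render_longitudinal_profiles(affected: LongitudinalProfile,
                                 unaffected: LongitudinalProfile,
                                 path: str) -> str:
    """Side-by-side per-slice volume plots with the elbow marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, prof, title in ((axes[0], affected, "affected"),
                            (axes[1], unaffected, "unaffected")):
        x = np.arange(prof.n_slices)
        ax.fill_between(x, prof.muscle, color=TISSUE_COLORS["muscle"],
                        alpha=0.6, label="muscle")
        ax.fill_between(x, prof.fat, color=TISSUE_COLORS["fat"],
                        alpha=0.6, label="epifascial fat")
        ax.fill_between(x, prof.fluid, color=TISSUE_COLORS["fluid"],
                        alpha=0.6, label="epifascial fluid")
        ax.plot(x, prof.total, color=TISSUE_COLORS["total"], lw=1.5, label="total")
        ax.axvline(prof.elbow_index, color="black", lw=1)
        ax.set_title(title)
        ax.set_xlabel("slice (wrist → shoulder)")
    axes[0].set_ylabel("volume per slice (mL)")
    axes[0].legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def render_longitudinal_excess_map(lmap: LongitudinalExcessMap, path: str) -> str:
    """Three one-row intensity strips (fluid, fat, epifascial increase),
    darker = greater, each normalized to its per-arm peak (quoted in the
    caption so absolute values remain recoverable)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(7, 3.2))
    labels = {"fluid_excess": "fluid excess", "fat_excess": "fat excess",
              "epifascial_increase_pct": "epifascial increase"}
    units = {"fluid_excess": "mL", "fat_excess": "mL",
             "epifascial_increase_pct": "%"}
    for ax, measure in zip(axes, MEASURE_CMAPS):
        vals = np.nan_to_num(lmap.normalized(measure))[None, :]
        ax.imshow(vals, cmap=MEASURE_CMAPS[measure], vmin=0, vmax=1, aspect="auto")
        ax.axvline(lmap.n_forearm - 0.5, color="black", lw=1)
        ax.set_yticks([])
        ax.set_xticks([])
        ax.set_ylabel(labels[measure], rotation=0, ha="right", va="center", fontsize=8)
        ax.set_title(f"peak = {lmap.peaks[measure]:.1f} {units[measure]}", fontsize=8)
    axes[-1].set_xlabel("wrist → 65% mark (elbow at the black line)", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def render_radial_excess_map(rmap: RadialExcessMap, path: str) -> str:
    """Polar 2-ring x 8-sector map of fluid excess; torso side on the right."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(4.2, 4.2))
    ax = fig.add_subplot(projection="polar")
    theta = np.linspace(0, 2 * np.pi, N_SECTORS + 1)
    radii = [0.4, 0.7, 1.0]              # inner ring = internal layer
    peak = rmap.peak if rmap.peak > 0 else 1.0
    cmap = plt.get_cmap("Blues")
    for layer in (0, 1):
        for s in range(N_SECTORS):
            val = max(rmap.excess[layer, s], 0.0) / peak
            ax.bar(x=(theta[s] + theta[s + 1]) / 2, height=radii[layer + 1] - radii[layer],
                   width=theta[1] - theta[0], bottom=radii[layer],
                   color=cmap(val), edgecolor="gray", linewidth=0.5)
    ax.set_xticks([]); ax.set_yticks([])
    ax.set_title(f"fluid excess, peak = {rmap.peak:.1f} mL (torso side right)",
                 fontsize=9)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def render_cohort_array(lmaps: list[LongitudinalExcessMap],
                        rmaps: list[RadialExcessMap],
                        subject_ids: list[str], path: str) -> str:
    """One row per subject: radial map plus the three longitudinal strips,
    each normalized to the subject's own peaks."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(lmaps)
    fig, axes = plt.subplots(n, 4, figsize=(9, 1.1 * n + 0.8), squeeze=False)
    for i, (lmap, rmap, sid) in enumerate(zip(lmaps, rmaps, subject_ids)):
        rpeak = rmap.peak if rmap.peak > 0 else 1.0
        axes[i][0].imshow(np.maximum(rmap.excess, 0) / rpeak, cmap="Blues",
                          vmin=0, vmax=1, aspect="auto")
        for j, measure in enumerate(MEASURE_CMAPS, start=1):
            vals = np.nan_to_num(lmap.normalized(measure))[None, :]
            axes[i][j].imshow(vals, cmap=MEASURE_CMAPS[measure], vmin=0, vmax=1,
                              aspect="auto")
        axes[i][0].set_ylabel(sid, rotation=0, ha="right", va="center", fontsize=7)
        for ax in axes[i]:
            ax.set_xticks([]); ax.set_yticks([])
    for j, title in enumerate(["radial fluid", "fluid", "fat", "epifascial"]):
        axes[0][j].set_title(title, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


__all__ = ["LongitudinalProfile", "AlignedPair", "LongitudinalExcessMap",
           "RadialExcessMap", "longitudinal_profile", "align_pair_at_elbow",
           "segment_bounds", "longitudinal_excess_map", "split_epifascial_layers",
           "radial_fluid_histogram", "radial_excess_map",
           "render_longitudinal_profiles", "render_longitudinal_excess_map",
           "render_radial_excess_map", "render_cohort_array",
           "N_FOREARM_SEGMENTS", "N_UPPER_SEGMENTS", "N_SECTORS"]
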