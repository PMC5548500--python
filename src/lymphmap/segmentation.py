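"""Five-class tissue segmentation of the three-channel intensity feature space.

Each voxel contributes a point (water, fat, stir) to a 3D feature space which
is partitioned into k = 5 clusters with Lloyd's k-means. Three clusters carry
the tissues of interest (muscle, fat, fluid); the remaining two absorb voxels
with no signal (image noise / background) and voxels of mixed composition at
tissue interfaces. Clusters are mapped to tissue classes by a centroid
dominance rule: the dominant channel of each tissue (water for muscle, fat
for fat, STIR for fluid) identifies its cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
import json
from pathlib import Path

import warnings

import numpy as np
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .exceptions import LymphmapError
from .volume_io import ChannelStack


class Tissue(IntEnum):
    """Integer coding of tissue classes, used in all label volumes."""

    NOISE = 0
    MUSCLE = 1
    FAT = 2
    FLUID = 3
    MIXED = 4


#: channel order of the feature space and of centroid rows
CHANNELS = ("water", "fat", "stir")


@dataclass
class ClusterModel:
    """A fitted k-means model over the (water, fat, stir) feature space."""

    centroids: np.ndarray          # (k, 3), raw intensity units
    seed: int
    assignment: dict[int, Tissue] | None = None
    inertia: float | None = None
    n_iter: int | None = None

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "channels": list(CHANNELS),
            "centroids": np.asarray(self.centroids).tolist(),
            "seed": int(self.seed),
            "assignment": {str(i): t.name for i, t in (self.assignment or {}).items()},
            "inertia": None if self.inertia is None else float(self.inertia),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        payload = json.loads(Path(path).read_text())
        model = cls(centroids=np.array(payload["centroids"], dtype=np.float64),
                    seed=int(payload["seed"]),
                    inertia=payload.get("inertia"))
        if payload.get("assignment"):
            model.assignment = {int(i): Tissue[name] for i, name in payload["assignment"].items()}
        return model


def _as_features(stack_or_features: ChannelStack | np.ndarray) -> np.ndarray:
    if isinstance(stack_or_features, ChannelStack):
        return stack_or_features.features()
    X = np.asarray(stack_or_features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != 3:
        raise LymphmapError(f"feature array must be (n, 3), got {X.shape}")
    return X


def fit_kmeans(
        stack_or_features: ChannelStack | np.ndarray,
        k: int = 5,
        seed: int = 0,
        n_init: int = 10,
        max_iter: int = 300,
        tol: float = 1e-4,
        sample_limit: int = 400_000,
        standardize: bool = False) -> ClusterModel:
    """Fit k-means to the voxel intensity feature space.

    Lloyd's algorithm with k-means++ initialization, ``n_init`` seeded
    restarts keeping the lowest within-cluster sum of squares. Volumes larger
    than ``sample_limit`` voxels are fitted on a seeded random subsample (the
    subsequent :func:`segment` pass always labels every voxel); set
    ``sample_limit=None`` to force fitting on all voxels.

    ``standardize=True`` z-scores each channel before clustering (off by
    default: the method operates on raw intensities); reported centroids are
    always in raw intensity units.
    """
    X = _as_features(stack_or_features)
    if k < 2:
        raise LymphmapError(f"k must be >= 2, got {k}")
    if X.shape[0] < k:
        raise LymphmapError(f"need at least k={k} feature vectors, got {X.shape[0]}")
    if X.shape[0] <= 10_000 and np.unique(X, axis=0).shape[0] < k:
        raise LymphmapError(f"fewer than k={k} distinct feature vectors")

    rng = np.random.default_rng(seed)
    fit_X = X
    if sample_limit is not None and X.shape[0] > sample_limit:
        idx = rng.choice(X.shape[0], size=sample_limit, replace=False)
        fit_X = X[idx]

    mean = fit_X.mean(axis=0)
    std = fit_X.std(axis=0)
    if standardize:
        std = np.where(std > 0, std, 1.0)
        fit_X = (fit_X - mean) / std

    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, max_iter=max_iter,
                tol=tol, algorithm="lloyd", random_state=int(seed) % (2**31))
    with warnings.catch_warnings():
        # duplicate feature vectors (e.g. noise-free phantoms) legitimately
        # yield fewer than k distinct clusters; the empty cluster is benign
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        km.fit(fit_X)
    centroids = km.cluster_centers_
    if standardize:
        centroids = centroids * std + mean
    return ClusterModel(centroids=np.asarray(centroids, dtype=np.float64),
                        seed=seed, inertia=float(km.inertia_), n_iter=int(km.n_iter_))


def assign_tissue_classes(model: ClusterModel) -> dict[int, Tissue]:
    """Map the five clusters to tissue classes by centroid dominance.

    Fixed priority order: the centroid with the smallest channel sum is
    noise; among the rest, the largest fat-channel value is fat, then the
    largest STIR value is fluid, then the largest water value is muscle; the
    last cluster is mixed. Ties (exact or within floating-point dust) are
    broken by the lower cluster index, making the assignment a deterministic
    bijection consistent with nearest-centroid labelling.
    """
    if model.k != 5:
        raise LymphmapError(f"tissue assignment requires k=5, got k={model.k}")
    c = np.asarray(model.centroids, dtype=np.float64)
    remaining = list(range(5))
    # near-ties (e.g. duplicated centroids differing by float rounding after
    # an empty-cluster relocation) resolve to the lower cluster index, the
    # same rule nearest-centroid labelling uses
    tol = 1e-9 * max(1.0, float(np.abs(c).max()))

    def take(scores: np.ndarray, best: str) -> int:
        vals = scores[remaining]
        extreme = vals.min() if best == "min" else vals.max()
        for idx, v in zip(remaining, vals):
            if abs(v - extreme) <= tol:
                remaining.remove(idx)
                return idx
        raise AssertionError("unreachable")

    assignment: dict[int, Tissue] = {}
    assignment[take(c.sum(axis=1), "min")] = Tissue.NOISE
    assignment[take(c[:, 1], "max")] = Tissue.FAT
    assignment[take(c[:, 2], "max")] = Tissue.FLUID
    assignment[take(c[:, 0], "max")] = Tissue.MUSCLE
    assignment[remaining.pop()] = Tissue.MIXED
    model.assignment = assignment
    return assignment


def _nearest_centroid(X: np.ndarray, centroids: np.ndarray, chunk: int = 2_000_000) -> np.ndarray:
    """Index of the nearest centroid per row.

    Ties — including near-ties within floating-point dust, as produced by
    duplicated centroids — go to the lower cluster index, matching the
    assignment heuristic's tie rule.
    """
    out = np.empty(X.shape[0], dtype=np.uint8)
    c2 = (centroids ** 2).sum(axis=1)
    tol = 1e-9 * max(1.0, float(c2.max()))
    for lo in range(0, X.shape[0], chunk):
        block = X[lo:lo + chunk]
        # squared distance up to the per-point constant ||x||^2
        d = block @ centroids.T
        d *= -2.0
        d += c2
        dmin = d.min(axis=1, keepdims=True)
        out[lo:lo + chunk] = np.argmax(d <= dmin + tol, axis=1)
    return out


def segment(stack: ChannelStack, model: ClusterModel) -> np.ndarray:
    """Label every voxel with the tissue class of its nearest centroid.

    Returns a uint8 volume of :class:`Tissue` codes with the stack's shape.
    """
    if model.assignment is None:
        assign_tissue_classes(model)
    X = stack.features()
    cluster_idx = _nearest_centroid(X, np.asarray(model.centroids, dtype=np.float64))
    lut = np.zeros(model.k, dtype=np.uint8)
    for i, t in model.assignment.items():
        lut[i] = int(t)
    return lut[cluster_idx].reshape(stack.shape)


def segment_arm(stack: ChannelStack, k: int = 5, seed: int = 0,
                **fit_kwargs) -> tuple[np.ndarray, ClusterModel]:
    """Convenience: fit, assign and segment one arm in a single call."""
    model = fit_kmeans(stack, k=k, seed=seed, **fit_kwargs)
    assign_tissue_classes(model)
    return segment(stack, model), model


__all__ = ["Tissue", "CHANNELS", "ClusterModel", "fit_kmeans",
           "assign_tissue_classes", "segment", "segment_arm"]
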