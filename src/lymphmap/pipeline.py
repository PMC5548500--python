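"""End-to-end orchestration: volumes in, segmentations, volumetry, maps out.

The workflow follows the method's three processing steps — volume selection
(crop to the wrist-to-65%-mark extent), volume segmentation (k = 5 k-means
over the three-channel feature space) and volume extraction (external and
fascial masks) — followed by voxel-count volumetry and, for pairs, the
excess maps and cohort statistics. Every stochastic step derives from the
seed in :class:`SegmentationParams`, and a run with the same configuration
reproduces byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import maps, volumetry
from .compartments import (MorphologyParams, SliceMasks, build_all_masks,
                           build_compartment_map)
from .exceptions import LymphmapError
from .segmentation import ClusterModel, Tissue, assign_tissue_classes, fit_kmeans, segment
from .stats_reporting import cohort_report, format_report, relative_excess_table
from .volume_io import (ChannelStack, Landmarks, ScalarVolume,
                        crop_to_analysis_extent, read_channel_stack,
                        read_sidecar, write_scalar_volume, write_sidecar)

log = logging.getLogger("lymphmap")

LABEL_LEGEND = {int(t): t.name.lower() for t in Tissue}
COMPARTMENT_LEGEND = {0: "outside", 1: "subfascial", 2: "epifascial"}


@dataclass
class SegmentationParams:
    k: int = 5
    seed: int = 0
    n_init: int = 10
    max_iter: int = 300
    tol: float = 1e-4
    sample_limit: int = 400_000
    standardize: bool = False


@dataclass
class PipelineParams:
    """Full configuration of a run; serializable to/from YAML."""

    seg: SegmentationParams = field(default_factory=SegmentationParams)
    morph: MorphologyParams = field(default_factory=MorphologyParams)
    n_forearm: int = maps.N_FOREARM_SEGMENTS
    n_upper: int = maps.N_UPPER_SEGMENTS

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        seg = SegmentationParams(**d.get("seg", {}))
        morph = MorphologyParams(**d.get("morph", {}))
        return cls(seg=seg, morph=morph,
                   n_forearm=d.get("n_forearm", maps.N_FOREARM_SEGMENTS),
                   n_upper=d.get("n_upper", maps.N_UPPER_SEGMENTS))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class ArmResult:
    """All per-arm artifacts of one pipeline run."""

    stack: ChannelStack                 # cropped to the analysis extent
    landmarks: Landmarks                # in cropped coordinates
    model: ClusterModel
    labels: np.ndarray
    masks: list[SliceMasks]
    compartments: np.ndarray
    volumes: volumetry.CompartmentVolumes
    profile: maps.LongitudinalProfile
    qc: dict


def run_arm(stack: ChannelStack, landmarks: Landmarks,
            params: PipelineParams | None = None,
            outdir: str | Path | None = None) -> ArmResult:
    """Process one arm: crop, segment, contour, measure.

    Logs per-stage voxel accounting and QC flags (slices without muscle,
    fluid voxels found below the fascia). With ``outdir``, writes the label
    and compartment volumes (NIfTI + JSON legends), the fitted cluster
    model, the six volumes and the longitudinal profile as CSV.
    """
    params = params or PipelineParams()
    cropped, lm = crop_to_analysis_extent(stack, landmarks)
    log.info("analysis extent: %d slices of %s", cropped.shape[0], cropped.shape[1:])

    model = fit_kmeans(cropped, k=params.seg.k, seed=params.seg.seed,
                       n_init=params.seg.n_init, max_iter=params.seg.max_iter,
                       tol=params.seg.tol, sample_limit=params.seg.sample_limit,
                       standardize=params.seg.standardize)
    assign_tissue_classes(model)
    labels = segment(cropped, model)
    counts = {t.name.lower(): int(np.sum(labels == t)) for t in Tissue}
    log.info("label counts: %s (total %d)", counts, labels.size)

    masks = build_all_masks(labels, params.morph)
    comp = build_compartment_map(labels, masks)
    vols = volumetry.measure_volumes(labels, comp)
    profile = maps.longitudinal_profile(labels, comp, lm)

    qc = {
        "empty_muscle_slices": int(sum(m.muscle_empty for m in masks)),
        "subfascial_fluid_voxels": vols.subfascial_fluid_voxels,
        "label_counts": counts,
    }
    if qc["empty_muscle_slices"]:
        log.warning("%d slices had an empty muscle mask", qc["empty_muscle_slices"])
    if qc["subfascial_fluid_voxels"]:
        log.warning("%d fluid voxels below the fascia (counted subfascial, "
                    "not epifascial fluid)", qc["subfascial_fluid_voxels"])

    result = ArmResult(stack=cropped, landmarks=lm, model=model, labels=labels,
                       masks=masks, compartments=comp, volumes=vols,
                       profile=profile, qc=qc)
    if outdir is not None:
        _write_arm(result, Path(outdir))
    return result


def _write_arm(res: ArmResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_scalar_volume(outdir / "labels.nii.gz", ScalarVolume(res.labels))
    write_scalar_volume(outdir / "compartments.nii.gz", ScalarVolume(res.compartments))
    (outdir / "legend.json").write_text(json.dumps(
        {"labels": LABEL_LEGEND, "compartments": COMPARTMENT_LEGEND}, indent=2) + "\n")
    res.model.to_json(outdir / "cluster_model.json")
    row = {"subject_id": res.stack.subject_id, "laterality": res.stack.laterality,
           "status": res.stack.status, **res.volumes.as_dict()}
    pd.DataFrame([row]).to_csv(outdir / "volumes.csv", index=False)
    res.profile.to_frame().to_csv(outdir / "profile.csv", index=False)
    (outdir / "qc.json").write_text(json.dumps(res.qc, indent=2) + "\n")


@dataclass
class PairResult:
    affected: ArmResult
    unaffected: ArmResult
    comparison: volumetry.ArmComparison
    aligned: maps.AlignedPair
    longitudinal_map: maps.LongitudinalExcessMap
    radial_map: maps.RadialExcessMap


def compare_results(res_a: ArmResult, res_u: ArmResult,
                    params: PipelineParams | None = None) -> PairResult:
    """Pair two processed arms: align at the elbow, compare volumes over the
    matched extent of equal slice count, and build both excess maps."""
    params = params or PipelineParams()
    aligned = maps.align_pair_at_elbow(res_a.profile, res_u.profile)
    (lo_a, hi_a), (lo_u, hi_u) = aligned.range_affected, aligned.range_unaffected
    vols_a = volumetry.measure_volumes(res_a.labels[lo_a:hi_a],
                                       res_a.compartments[lo_a:hi_a])
    vols_u = volumetry.measure_volumes(res_u.labels[lo_u:hi_u],
                                       res_u.compartments[lo_u:hi_u])
    comparison = volumetry.compare_arms(vols_a, vols_u)
    lmap = maps.longitudinal_excess_map(aligned, params.n_forearm, params.n_upper)
    rmap = maps.radial_excess_map(
        res_a.labels, res_a.compartments, res_a.stack.laterality,
        res_u.labels, res_u.compartments, res_u.stack.laterality,
        range_affected=aligned.range_affected,
        range_unaffected=aligned.range_unaffected)
    return PairResult(affected=res_a, unaffected=res_u, comparison=comparison,
                      aligned=aligned, longitudinal_map=lmap, radial_map=rmap)


def run_pair(stack_affected: ChannelStack, lm_affected: Landmarks,
             stack_unaffected: ChannelStack, lm_unaffected: Landmarks,
             params: PipelineParams | None = None,
             outdir: str | Path | None = None) -> PairResult:
    """Process both arms of one subject and compare them."""
    params = params or PipelineParams()
    res_a = run_arm(stack_affected, lm_affected, params,
                    None if outdir is None else Path(outdir) / "affected")
    res_u = run_arm(stack_unaffected, lm_unaffected, params,
                    None if outdir is None else Path(outdir) / "unaffected")
    pair = compare_results(res_a, res_u, params)
    if outdir is not None:
        _write_pair(pair, Path(outdir))
    return pair


def _write_pair(pair: PairResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pair.comparison.to_frame().to_csv(outdir / "comparison.csv", index=False)
    pair.longitudinal_map.to_frame().to_csv(outdir / "longitudinal_map.csv", index=False)
    pair.radial_map.to_frame().to_csv(outdir / "radial_map.csv", index=False)
    meta = {
        "peaks": pair.longitudinal_map.peaks,
        "radial_peak_ml": pair.radial_map.peak,
        "torso_side": pair.radial_map.torso_side,
        "laterality_affected": pair.affected.stack.laterality,
        "laterality_unaffected": pair.unaffected.stack.laterality,
        "aligned_slices": pair.aligned.n_slices,
        "elbow_index": pair.aligned.elbow_index,
    }
    (outdir / "map_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    maps.render_longitudinal_profiles(pair.aligned.affected, pair.aligned.unaffected,
                                      str(outdir / "profiles.png"))
    maps.render_longitudinal_excess_map(pair.longitudinal_map,
                                        str(outdir / "longitudinal_map.png"))
    maps.render_radial_excess_map(pair.radial_map, str(outdir / "radial_map.png"))


@dataclass
class CohortResult:
    table: pd.DataFrame
    report: dict
    pairs: list[PairResult]


def run_cohort(subjects: list[tuple[ChannelStack, Landmarks, ChannelStack, Landmarks]],
               params: PipelineParams | None = None,
               outdir: str | Path | None = None,
               subject_ids: list[str] | None = None) -> CohortResult:
    """Process a cohort of affected/unaffected pairs and report statistics.

    ``subjects`` holds (affected stack, its landmarks, unaffected stack, its
    landmarks) per subject. Produces the per-subject volumes table (with
    excesses and relative excesses), the statistics report, and the cohort
    array figure when ``outdir`` is given.
    """
    if len(subjects) < 3:
        raise LymphmapError("a cohort run needs at least 3 pairs")
    params = params or PipelineParams()
    ids = subject_ids or [f"S{i + 1:02d}" for i in range(len(subjects))]
    pairs, rows = [], []
    for sid, (sa, la, su, lu) in zip(ids, subjects):
        pair_dir = None if outdir is None else Path(outdir) / sid
        pair = run_pair(sa, la, su, lu, params, pair_dir)
        pairs.append(pair)
        row = {"subject_id": sid}
        for m in volumetry.METRICS:
            row[f"{m}_affected_ml"] = pair.comparison.affected[m]
            row[f"{m}_unaffected_ml"] = pair.comparison.unaffected[m]
        row["epifascial_excess_ml"] = pair.comparison.excess["epifascial"]
        row["fat_excess_ml"] = pair.comparison.excess["fat_epifascial"]
        row["fluid_excess_ml"] = pair.comparison.excess["fluid_epifascial"]
        row["unaffected_epifascial_ml"] = pair.comparison.unaffected["epifascial"]
        rows.append(row)
    table = relative_excess_table(pd.DataFrame(rows))
    report = cohort_report(table)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "cohort.csv", index=False)
        (outdir / "stats_report.json").write_text(json.dumps(report, indent=2) + "\n")
        (outdir / "stats_report.txt").write_text(format_report(report))
        maps.render_cohort_array([p.longitudinal_map for p in pairs],
                                 [p.radial_map for p in pairs], ids,
                                 str(outdir / "cohort_array.png"))
    return CohortResult(table=table, report=report, pairs=pairs)


# ---------------------------------------------------------------------------
# directory conventions used by the CLI and the phantom writer

ARM_FILES = ("water.nii.gz", "fat.nii.gz", "stir.nii.gz", "sidecar.json")


def write_arm_inputs(outdir: str | Path, stack: ChannelStack,
                     landmarks: Landmarks) -> None:
    """Write one arm's three channels plus its landmark sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_scalar_volume(outdir / "water.nii.gz", stack.water)
    write_scalar_volume(outdir / "fat.nii.gz", stack.fat)
    write_scalar_volume(outdir / "stir.nii.gz", stack.stir)
    write_sidecar(outdir / "sidecar.json", landmarks,
                  {"laterality": stack.laterality, "status": stack.status,
                   "subject_id": stack.subject_id})


def read_arm_inputs(indir: str | Path) -> tuple[ChannelStack, Landmarks]:
    """Read an arm directory written by :func:`write_arm_inputs`."""
    indir = Path(indir)
    lm, meta = read_sidecar(indir / "sidecar.json")
    stack = read_channel_stack(
        indir / "water.nii.gz", indir / "fat.nii.gz", indir / "stir.nii.gz",
        laterality=meta.get("laterality", "right"),
        status=meta.get("status", "unaffected"),
        subject_id=meta.get("subject_id", indir.name))
    return stack, lm


__all__ = ["SegmentationParams", "PipelineParams", "ArmResult", "PairResult",
           "CohortResult", "run_arm", "run_pair", "run_cohort",
           "compare_results", "write_arm_inputs", "read_arm_inputs",
           "LABEL_LEGEND", "COMPARTMENT_LEGEND"]
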