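"""End-to-end orchestration: deconvolve -> register -> stack -> detect ->
colocalize -> classify -> proximity, with a replayable run manifest.

All physical parameters are in microns; pixel conversions happen inside the
stage functions.  Coordinates are 0-based, pixel-center origin, x rightward,
y downward.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .destain import default_threshold
from .phenotype import (
    DetectedObject,
    PathologyObject,
    PhenotypeGate,
    colocalize,
    count_phenotypes,
    default_gate,
    detect_objects,
    detect_pathology,
    objects_to_frame,
)
from .proximity import association_summary, proximity_profile
from .registration import (
    ChannelStack,
    RegisteredRound,
    Transform,
    compose_stack,
    estimate_transform,
)
from .stain import (
    CalibratedImage,
    DensityMap,
    StainMatrix,
    deconvolve,
    default_stain_matrix,
    rgb_to_od,
)

log = logging.getLogger("cycihc")

__all__ = ["PipelineConfig", "PipelineResult", "auto_thresholds", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Analysis parameters for one run; defaults follow the protocol's
    stated values (40 um^2 cell exclusion, 100 um proximity radius)."""

    panel: tuple[str, ...]
    cell_channel: str = "IBA1"
    plaque_channel: str = "Abeta"
    tangle_channel: str = "PHF1"
    min_cell_area_um2: float = 40.0
    max_cell_area_um2: float | None = None
    pathology_min_diameter_um: float = 100.0
    proximity_radius_um: float = 100.0
    proximity_bin_um: float = 20.0
    overlap_fraction: float = 0.25
    touch_tolerance_um: float = 0.0
    registration_mode: str = "rigid"
    similarity_floor: float = 0.2
    thresholds: dict[str, float] = field(default_factory=dict)
    white_point: float = 255.0
    seed: int = 0

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    stack: ChannelStack
    cells: list[DetectedObject]
    pathology: list[PathologyObject]
    cell_table: pd.DataFrame
    phenotype_counts: pd.Series
    profiles: dict
    associations: list
    transforms: dict[str, Transform]
    qc: dict
    manifest: dict


def auto_thresholds(
    stack: ChannelStack,
    markers: Sequence[str],
    min_threshold: float = 0.1,
) -> dict[str, float]:
    """Per-channel Otsu positivity thresholds with an OD floor.

    The floor keeps near-blank channels (where Otsu would split noise) from
    producing spurious positives.
    """
    out = {}
    for m in markers:
        d = stack.density(m)
        out[m] = max(default_threshold(d), min_threshold)
    return out


def run_pipeline(
    cfg: PipelineConfig,
    round_images: Sequence[CalibratedImage],
    stain_matrix: StainMatrix | None = None,
    vessels: Sequence[PathologyObject] | None = None,
) -> PipelineResult:
    """Execute the full analysis on one ordered set of round images.

    ``round_images[i]`` is the brightfield RGB image of staining round i,
    whose chromogen is ``cfg.panel[i]``.  Vessel regions cannot be derived
    from the panel and are supplied externally when available.
    """
    if len(round_images) != len(cfg.panel):
        raise ValueError(
            f"{len(cfg.panel)} rounds expected per panel, got {len(round_images)}"
        )
    stain_matrix = stain_matrix or default_stain_matrix()
    t_start = time.perf_counter()
    qc: dict = {"clip_fraction": {}, "registration": {}}

    # stage 1: deconvolution
    rounds: list[RegisteredRound] = []
    for i, (marker, img) in enumerate(zip(cfg.panel, round_images)):
        od = rgb_to_od(img, white_point=cfg.white_point)
        maps, dqc = deconvolve(od, stain_matrix)
        chrom, hema = maps[0], maps[1]
        chrom.stain = marker
        hema.stain = "hematoxylin"
        qc["clip_fraction"][marker] = dqc["clip_fraction"]
        rounds.append(RegisteredRound(i, img.round_id or f"round{i + 1:02d}",
                                      marker, chrom, hema))
    log.info("deconvolved %d rounds", len(rounds))

    # stage 2: registration onto round 1's counterstain
    ref = rounds[0]
    for r in rounds[1:]:
        t = estimate_transform(
            ref.counterstain, r.counterstain, mode=cfg.registration_mode,
            similarity_floor=cfg.similarity_floor,
            fixed_round=ref.round_id, moving_round=r.round_id,
        )
        r.transform = t
        qc["registration"][r.marker] = {"score": t.score,
                                        "translation_px": t.offset.tolist()}
    log.info("registered %d rounds to %s", len(rounds) - 1, ref.round_id)

    # stage 3: stack composition
    stack = compose_stack(rounds)

    # stage 4: thresholds
    markers = [m for m in stack.channel_names if m != stack.counterstain_name]
    thresholds = dict(cfg.thresholds)
    for m, thr in auto_thresholds(stack, [m for m in markers if m not in thresholds]).items():
        thresholds[m] = thr

    # stage 5: cell + pathology detection
    cells, markup = detect_objects(
        stack.density(cfg.cell_channel), thresholds[cfg.cell_channel],
        min_area_um2=cfg.min_cell_area_um2, max_area_um2=cfg.max_cell_area_um2,
        validity=stack.validity,
    )
    pathology: list[PathologyObject] = []
    for channel, kind in ((cfg.plaque_channel, "abeta_plaque"),
                          (cfg.tangle_channel, "phf1_tangle")):
        if channel in stack.channels:
            pathology.extend(
                detect_pathology(stack.density(channel), kind, thresholds[channel],
                                 min_diameter_um=cfg.pathology_min_diameter_um,
                                 validity=stack.validity)
            )
    log.info("detected %d cells, %d pathology objects", len(cells), len(pathology))

    # stage 6-7: colocalize and classify
    gate = default_gate()
    gate_markers = [m for m in gate.markers if m in stack.channels]
    cells = colocalize(cells, stack, thresholds,
                       overlap_fraction=cfg.overlap_fraction, markers=markers)
    for c in cells:
        for m in gate.markers:
            c.marker_vector.setdefault(m, False)
    counts = count_phenotypes(cells, gate)

    # stage 8: proximity + association
    profiles = proximity_profile(cells, pathology, radius_um=cfg.proximity_radius_um,
                                 bin_width_um=cfg.proximity_bin_um) if pathology else {}
    plaques = [p for p in pathology if p.kind == "abeta_plaque"]
    tangles = [p for p in pathology if p.kind == "phf1_tangle"]
    associations = association_summary(
        cells, plaques, tangles, vessels, touch_tolerance_um=cfg.touch_tolerance_um
    )

    manifest = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "seed": cfg.seed,
        "panel": list(cfg.panel),
        "thresholds": thresholds,
        "n_cells": len(cells),
        "n_pathology": len(pathology),
    }
    log.info("pipeline finished in %.1f s", time.perf_counter() - t_start)
    return PipelineResult(
        stack=stack, cells=cells, pathology=pathology,
        cell_table=objects_to_frame(cells), phenotype_counts=counts,
        profiles=profiles, associations=associations,
        transforms={r.round_id: r.transform for r in rounds if r.transform is not None},
        qc=qc, manifest=manifest,
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write the run's tables, profiles and manifest with stable ordering."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = result.cell_table
    if not table.empty:
        table = table.sort_values("id")
    table.to_csv(outdir / "cells.csv", index=False)
    result.phenotype_counts.to_csv(outdir / "phenotype_counts.csv",
                                   index_label="label")
    prof_frames = [p.to_frame() for p in result.profiles.values()]
    if prof_frames:
        pd.concat(prof_frames).to_csv(outdir / "proximity_profiles.csv", index=False)
    else:
        pd.DataFrame().to_csv(outdir / "proximity_profiles.csv", index=False)
    with open(outdir / "associations.json", "w") as fh:
        json.dump([a.to_dict() for a in result.associations], fh, indent=2,
                  sort_keys=True)
    with open(outdir / "qc.json", "w") as fh:
        json.dump(result.qc, fh, indent=2, sort_keys=True)
    with open(outdir / "transforms.json", "w") as fh:
        json.dump({k: t.to_dict() for k, t in sorted(result.transforms.items())},
                  fh, indent=2, sort_keys=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)
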