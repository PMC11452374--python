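"""Batch orchestration: preprocess → sort → ICCS → tables, plots, manifest.

A batch is a set of frames acquired under one experimental condition.  The
sorting thresholds are population statistics, so measurements are pooled
across all frames of the batch before thresholds are derived, and are never
carried over to another batch.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import preprocess
from .iccs import IccsSettings, iccs_per_nucleus
from .io import ChannelImage, CountMask, read_count_mask, read_image_set, write_count_mask
from .sorting import (
    NucleusRecord,
    SortingParams,
    classify,
    derive_thresholds,
    measure_nuclei,
    records_frame,
)
from .stats import group_summary, mann_whitney

log = logging.getLogger("replisort")

PHASE_COLORS = {"G1G2": "tab:blue", "EARLY": "black", "MIDDLE": "tab:red",
                "LATE": "tab:green", "EXCLUDED": "tab:gray"}


@dataclass
class FrameInput:
    """Paths of one frame: either one multi-page TIFF or one file per role."""

    paths: list[str]
    channel_roles: list[str]
    frame_id: str | None = None
    mask_path: str | None = None  # optional pre-made count mask
    excluded_labels: list[int] = field(default_factory=list)


@dataclass
class RunConfig:
    """Everything needed to (re)run one batch; serialized into the manifest."""

    frames: list[FrameInput]
    output_dir: str = "replisort-out"
    pixel_size_nm: float | None = None
    # preprocessing
    ball_radius_px: int = preprocess.DEFAULT_BALL_RADIUS_PX
    foci_threshold_factor: float = preprocess.DEFAULT_FOCI_FACTOR
    explicit_foci_threshold: float | None = None
    background_level: float | None = None
    reference_labels: list[int] = field(default_factory=list)
    min_area_px: int = preprocess.DEFAULT_MIN_AREA_PX
    fill_holes: bool = True
    # sorting
    n_min: int = 10
    k_rho: float = 0.4
    k: float = 3.0
    k_size: float = 1.2
    rho_thr_max: float | None = None
    # ICCS
    run_iccs: bool = True
    max_lag_px: int = 32
    min_overlap: int = 200
    convention: str = "asymmetric"
    pad_px: int = 8
    seed: int = 0
    log_level: str = "INFO"

    def sorting_params(self) -> SortingParams:
        return SortingParams(self.n_min, self.k_rho, self.k, self.k_size, self.rho_thr_max)

    def iccs_settings(self) -> IccsSettings:
        return IccsSettings(self.max_lag_px, self.min_overlap, self.convention,
                            self.pad_px, self.n_min)


def config_to_dict(config: RunConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    d["frames"] = [FrameInput(**f) for f in d.get("frames", [])]
    return RunConfig(**d)


def save_manifest(config: RunConfig, thresholds, path: str | Path) -> None:
    """Write the run manifest: full config plus the derived thresholds."""
    doc = {
        "config": config_to_dict(config),
        "derived_thresholds": {
            "rho_min": thresholds.rho_min,
            "rho_thr": thresholds.rho_thr,
            "i_thr": thresholds.i_thr,
            "mean_n_nuc": thresholds.mean_n_nuc,
            "rho_max": thresholds.rho_max,
            "i_min_subgroup": thresholds.i_min_subgroup,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_manifest(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    return config_from_dict(doc["config"])


def plot_scatter(records: Sequence[NucleusRecord], path: str | Path) -> None:
    """Density-vs-intensity scatter of the sorted population."""
    fig, ax = plt.subplots(figsize=(5, 4))
    frame = records_frame(list(records))
    for phase, grp in frame.groupby("phase"):
        ax.scatter(grp["rho_rf"], grp["i_rf"], s=12,
                   color=PHASE_COLORS.get(phase, "tab:purple"), label=phase)
    ax.set_xlabel(r"replication foci pixel density $\rho_{RF}$")
    ax.set_ylabel(r"replication foci pixel intensity $I_{RF}$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class FrameData:
    """In-memory channels and mask of one frame (ready for analysis)."""

    dna: ChannelImage | None
    rf: ChannelImage
    tf: ChannelImage | None
    mask: CountMask


def _load_frame(cfg: RunConfig, fr: FrameInput) -> FrameData:
    images = read_image_set(fr.paths, fr.channel_roles, fr.frame_id, cfg.pixel_size_nm)
    by_role = {img.channel_role: img for img in images}
    if "RF" not in by_role:
        raise ValueError("every frame needs an RF (replication foci) channel")
    if fr.mask_path:
        mask = read_count_mask(fr.mask_path, set(fr.excluded_labels))
    else:
        if "DNA" not in by_role:
            raise ValueError("need a DNA channel or a pre-made count mask")
        mask = preprocess.segment_nuclei(by_role["DNA"], cfg.min_area_px, cfg.fill_holes)
        mask.excluded_labels = set(fr.excluded_labels)
    return FrameData(by_role.get("DNA"), by_role["RF"], by_role.get("TF"), mask)


def analyze_frames(
    frames: list[FrameData], config: RunConfig
) -> tuple[list[NucleusRecord], "DerivedThresholds"]:
    """Core batch analysis on in-memory frames.

    Background level: explicit value > user reference labels on the first
    frame > automatic pick of the dimmest quartile of first-frame nuclei
    (first-pass G1/G2 identification).  Measurements from all frames are
    pooled, thresholds derived once, phases assigned, then ICCS run on each
    frame's S-phase nuclei if a TF channel is present.
    """
    if not frames:
        raise ValueError("empty batch")
    first = frames[0]
    if config.explicit_foci_threshold is not None:
        background = config.background_level
        threshold = config.explicit_foci_threshold
    else:
        if config.background_level is not None:
            background = config.background_level
        else:
            refs = (set(config.reference_labels) or
                    preprocess.auto_reference_labels(first.rf, first.mask))
            background = preprocess.estimate_background_level(first.rf, first.mask, refs)
        threshold = None

    records: list[NucleusRecord] = []
    prepared = []
    for i, fd in enumerate(frames):
        foci = preprocess.binarize_foci(
            fd.rf, background, config.foci_threshold_factor, threshold
        )
        rf_sub = preprocess.subtract_background(fd.rf, config.ball_radius_px)
        frame_records = measure_nuclei(fd.mask, rf_sub, foci)
        log.info("frame %s: %d nuclei", fd.rf.frame_id or i, len(frame_records))
        records.extend(frame_records)
        prepared.append((fd, rf_sub))

    if not records:
        raise ValueError("no nuclei found in any frame")

    params = config.sorting_params()
    thresholds = derive_thresholds(records, params)
    records = classify(records, thresholds, params)

    if config.run_iccs:
        settings = config.iccs_settings()
        by_frame: dict[str, list[NucleusRecord]] = {}
        for rec in records:
            by_frame.setdefault(rec.frame_id, []).append(rec)
        out: list[NucleusRecord] = []
        for fd, rf_sub in prepared:
            frame_recs = by_frame.get(rf_sub.frame_id, [])
            if fd.tf is None:
                out.extend(frame_recs)
                continue
            tf_sub = preprocess.subtract_background(fd.tf, config.ball_radius_px)
            out.extend(iccs_per_nucleus(rf_sub, tf_sub, fd.mask, frame_recs, settings))
        records = out
    return records, thresholds


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run the full batch from files on disk; writes CSV, plots, manifest.

    Frames that fail to load or analyze are logged and skipped; the batch
    fails only when no frame succeeds.  Outputs: ``cells.csv`` (one row per
    non-excluded nucleus), ``summary.csv`` (per-phase mean ± s.e.m. of f1,
    plus median/IQR), ``scatter.png`` and ``manifest.yaml``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    frames: list[FrameData] = []
    for fr in config.frames:
        try:
            frames.append(_load_frame(config, fr))
        except Exception as err:  # noqa: BLE001 - frame-level isolation
            log.error("skipping frame %s: %s", fr.frame_id or fr.paths, err)
    if not frames:
        raise RuntimeError("no frame could be loaded")

    records, thresholds = analyze_frames(frames, config)

    frame = records_frame(records)
    frame.to_csv(outdir / "cells.csv", index=False, float_format="%.6g")
    group_summary(frame, "f1").to_csv(outdir / "summary.csv", index=False,
                                      float_format="%.6g")
    plot_scatter(records, outdir / "scatter.png")
    save_manifest(config, thresholds, outdir / "manifest.yaml")
    counts = frame["phase"].value_counts().to_dict()
    log.info("phase counts: %s", counts)
    if all(p == "G1G2" for p in frame["phase"]):
        log.warning("all nuclei classified G1/G2: no foci above threshold")
    return frame


def phase_comparisons(frame: pd.DataFrame, value: str = "f1"):
    """Pairwise Mann–Whitney comparisons of one value across phase groups."""
    phases = [p for p in ("EARLY", "MIDDLE", "LATE") if (frame["phase"] == p).any()]
    out = []
    for i, pa in enumerate(phases):
        for pb in phases[i + 1:]:
            va = frame.loc[frame["phase"] == pa, value].dropna()
            vb = frame.loc[frame["phase"] == pb, value].dropna()
            va = va[np.isfinite(va)]
            vb = vb[np.isfinite(vb)]
            if len(va) and len(vb):
                out.append(mann_whitney(va, vb, pa, pb))
    return out


def total_content(
    zstack_edu: list[ChannelImage],
    zstack_dna: list[ChannelImage],
    mask: CountMask,
) -> pd.DataFrame:
    """Per-nucleus total EdU and DNA content summed over z-sections.

    The z-stack cross-validation: integrating each channel over all optical
    sections and all mask pixels of a nucleus approximates its total content,
    the quantity conventional cell-cycle staging is based on.
    """
    if len(zstack_edu) != len(zstack_dna):
        raise ValueError("section-count mismatch between channels")
    if len(zstack_edu) == 0:
        raise ValueError("empty z-stack")
    for img in (*zstack_edu, *zstack_dna):
        if img.shape != mask.shape:
            raise ValueError("section shape differs from mask")
    labels = mask.present_labels()
    if not labels:
        return pd.DataFrame(columns=["label", "total_edu", "total_dna"])
    from scipy import ndimage

    edu_sum = np.sum([img.pixels for img in zstack_edu], axis=0)
    dna_sum = np.sum([img.pixels for img in zstack_dna], axis=0)
    index = np.asarray(labels)
    total_edu = ndimage.sum_labels(edu_sum, mask.labels, index)
    total_dna = ndimage.sum_labels(dna_sum, mask.labels, index)
    return pd.DataFrame(
        {"label": labels, "total_edu": total_edu, "total_dna": total_dna}
    )
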