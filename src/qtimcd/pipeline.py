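"""End-to-end pipeline: simulate -> smooth -> fit -> classify -> report.

Each stage is usable on its own (and exposed as a CLI subcommand); this
module wires them together on in-memory arrays and orchestrates the on-disk
artifacts, writing a manifest that reproduces every stochastic output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .btensor import AcquisitionProtocol, build_protocol, write_sidecar
from .classify import (
    AveragedDistribution,
    RoiSample,
    ThresholdResult,
    average_distributions,
    build_report,
    classify_wm_percent,
    extract_roi,
    histogram_edges,
    normalize_intensity,
    roc_threshold,
)
from .config import RunConfig
from .io import write_nifti
from .phantom import Phantom, build_phantom
from .preprocess import exclude_csf_voxels, gaussian_smooth
from .qti import fit_volume

__all__ = ["PipelineResult", "analyze", "run_pipeline"]

log = logging.getLogger("qtimcd")

_CONTRAST_KEYS = {"T1w": "t1w", "FLAIR": "flair", "FA": "fa", "MKA": "mk_a"}


@dataclass
class PipelineResult:
    """In-memory results of one end-to-end run."""

    phantom: Phantom
    metrics: dict[str, np.ndarray]
    thresholds: dict[str, ThresholdResult]
    distributions: dict[str, dict[str, AveragedDistribution]]
    report: pd.DataFrame


def _lesion_indices(rois: dict[str, np.ndarray]) -> list[tuple[int, str]]:
    out = []
    for name in rois:
        if name.startswith("lesion_"):
            _, idx, kind = name.split("_", 2)
            out.append((int(idx), kind))
    return sorted(out)


def analyze(
    phantom: Phantom,
    metrics: dict[str, np.ndarray],
    config: RunConfig,
) -> PipelineResult:
    """Classification back end on fitted maps.

    Extracts per-ROI samples (after CSF exclusion on the fitted MD),
    normalizes structural intensities (lesion and cortex T1w against the
    adjacent normal white matter, FLAIR against the deep-WM reference
    region), derives per-contrast ROC thresholds from the averaged
    normal-cortex and normal-WM distributions, and classifies each lesion's
    voxels to produce the WM% table.
    """
    rois = phantom.rois
    md = metrics["md"]
    valid = metrics["valid"]
    thr_csf = config.preprocess.md_csf_threshold

    cleaned: dict[str, np.ndarray] = {}
    for name, mask in rois.items():
        m = mask & valid
        m, n_removed = exclude_csf_voxels(m, md, thr_csf)
        if not m.any():
            log.warning("ROI %s empty after CSF exclusion; dropped", name)
        cleaned[name] = m
        log.debug("ROI %s: %d voxels (%d removed)", name, int(m.sum()), n_removed)

    volumes = {
        "T1w": phantom.t1w,
        "FLAIR": phantom.flair,
        "FA": metrics["fa"],
        "MKA": metrics["mk_a"],
    }
    contrasts = [c for c in config.classify.contrasts if c in volumes]
    lesions = _lesion_indices(rois)

    def sample(name: str, ltype: str, contrast: str) -> RoiSample:
        return extract_roi(volumes[contrast], cleaned[name], name, ltype, contrast)

    ref_sample = {
        c: sample("reference", "WM", c) for c in contrasts if cleaned["reference"].any()
    }

    def normalized(name: str, ltype: str, contrast: str, wm_adj: str) -> RoiSample:
        s = sample(name, ltype, contrast)
        if contrast == "T1w":
            return normalize_intensity(s, sample(wm_adj, "WM", "T1w"))
        if contrast == "FLAIR":
            return normalize_intensity(s, ref_sample["FLAIR"])
        return s

    thresholds: dict[str, ThresholdResult] = {}
    dists: dict[str, dict[str, AveragedDistribution]] = {}
    for c in contrasts:
        ctx_samples, wm_samples = [], []
        for i, kind in lesions:
            ctx_name, wm_name = f"cortex_{i}", f"wm_adj_{i}"
            if not (cleaned[ctx_name].any() and cleaned[wm_name].any()):
                continue
            ctx_samples.append(normalized(ctx_name, "cortex", c, wm_name))
            wm_samples.append(normalized(wm_name, "WM", c, wm_name))
        if not ctx_samples:
            raise ValueError("no usable normal-tissue ROIs for ROC analysis")
        edges = histogram_edges(ctx_samples + wm_samples, config.classify.n_bins)
        ctx_dist = average_distributions(ctx_samples, bin_edges=edges, tissue_class="cortex")
        wm_dist = average_distributions(wm_samples, bin_edges=edges, tissue_class="WM")
        thresholds[c] = roc_threshold(ctx_dist, wm_dist)
        dists[c] = {"cortex": ctx_dist, "WM": wm_dist}
        log.info(
            "%s: AUC %.3f, threshold %.4g (%s side is WM-like)",
            c, thresholds[c].auc, thresholds[c].threshold, thresholds[c].polarity,
        )

    rows = []
    for i, kind in lesions:
        name = f"lesion_{i}_{kind}"
        if not cleaned[name].any():
            continue
        row: dict = {
            "lesion_id": name,
            "lesion_type": kind,
            "n_voxels": int(cleaned[name].sum()),
        }
        for c in contrasts:
            s = normalized(name, kind, c, f"wm_adj_{i}")
            pct, _ = classify_wm_percent(s, thresholds[c])
            row[c] = pct
        rows.append(row)
    report = build_report(rows, contrasts=contrasts)
    return PipelineResult(phantom, metrics, thresholds, dists, report)


def run_pipeline(config: RunConfig, outdir: str | Path) -> PipelineResult:
    """Run the full pipeline and write all artifacts under ``outdir``.

    Stages: simulate the phantom, smooth the diffusion data, fit the QTI
    model, classify lesion voxels, and write the WM% report.  A manifest
    (config + seed + version) makes every stochastic output reproducible.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(config.phantom.voxel_size) + [1.0])

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("simulate")
        protocol = build_protocol(
            config.protocol.shells, config.protocol.n_b0, seed=config.seed
        )
        phantom = build_phantom(config.phantom, protocol)
        write_nifti(phantom.dwi, affine, outdir / "dwi.nii.gz")
        write_sidecar(protocol, outdir / "dwi.btens")
        write_nifti(phantom.t1w, affine, outdir / "t1w.nii.gz")
        write_nifti(phantom.flair, affine, outdir / "flair.nii.gz")
        # auxiliary myelin-weighted contrast: T1w / FLAIR ratio
        ratio = np.divide(
            phantom.t1w, phantom.flair,
            out=np.zeros_like(phantom.t1w), where=phantom.flair > 1e-6,
        )
        write_nifti(ratio, affine, outdir / "t1w_flair_ratio.nii.gz")
        write_nifti(phantom.labels, affine, outdir / "labels.nii.gz", dtype=np.int16)
        for name, mask in phantom.rois.items():
            write_nifti(mask, affine, outdir / f"roi_{name}.nii.gz")
        for key in ("md", "fa", "mk_a"):
            write_nifti(phantom.ground_truth[key], affine, outdir / f"gt_{key}.nii.gz")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {exc}") from exc

    try:
        stage("smooth+fit")
        smoothed = gaussian_smooth(
            phantom.dwi, config.phantom.voxel_size, config.preprocess.smoothing()
        )
        metrics = fit_volume(smoothed, protocol, mask=phantom.brain_mask)
        for key in ("md", "fa", "mk_a", "mk_i", "mk_t", "s0"):
            write_nifti(metrics[key], affine, outdir / f"fit_{key}.nii.gz")
        write_nifti(metrics["valid"], affine, outdir / "fit_valid.nii.gz")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fit' failed: {exc}") from exc

    try:
        stage("classify")
        result = analyze(phantom, metrics, config)
        thr_rows = [
            {"contrast": c, "threshold": t.threshold, "polarity": t.polarity, "auc": t.auc}
            for c, t in result.thresholds.items()
        ]
        pd.DataFrame(thr_rows).to_csv(outdir / "thresholds.tsv", sep="\t", index=False)
        result.report.to_csv(
            outdir / "report.tsv", sep="\t", index=False, float_format="%.6g"
        )
        rounded = result.report.copy()
        for c in result.thresholds:
            rounded[c] = rounded[c].round().astype(int)
        rounded.to_csv(outdir / "report_rounded.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'classify' failed: {exc}") from exc

    config.to_yaml(outdir / "config.yaml")
    manifest = [
        f"qtimcd_version={__version__}",
        f"seed={config.seed}",
        f"n_volumes={len(protocol)}",
        f"grid={'x'.join(str(s) for s in config.phantom.shape)}",
        "config=config.yaml",
    ]
    (outdir / "manifest.txt").write_text("\n".join(manifest) + "\n")
    return result
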